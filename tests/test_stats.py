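"""Tests for the GEE pipeline-comparison layer.

Point estimates are checked against an independent pooled-OLS oracle
(numpy lstsq); marginal means and contrasts against hand-built averages
on synthetic tables with known effects.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from amypipe.errors import CoverageError, ParameterError
from amypipe.pipelines import enumerate_pipelines
from amypipe.stats import (
    cluster_bootstrap_se,
    compare_main_pipelines,
    descriptive_summary,
    fit_gee,
    overall_contrasts,
    pairwise_contrast,
    significance_tier,
)

SPECS = enumerate_pipelines()


def make_table(seed=0, n_ad=6, n_hc=8, effects=None, subject_sd=0.1,
               noise_sd=0.05):
    """Long-format cohort table with additive factor effects."""
    rng = np.random.default_rng(seed)
    effects = effects or {}
    rows = []
    for i in range(n_ad + n_hc):
        dx = "AD" if i < n_ad else "HC"
        sid = f"S{i:02d}"
        base = (1.6 if dx == "AD" else 1.0) + rng.normal(0, subject_sd)
        for sp in SPECS:
            val = base + rng.normal(0, noise_sd)
            val += effects.get(("space", sp.space), 0.0)
            val += effects.get(("transform", sp.transform), 0.0)
            val += effects.get(("gm_def", sp.gm_def), 0.0)
            rows.append({
                "subject_id": sid, "diagnosis": dx, "space": sp.space,
                "transform": sp.transform, "gm_def": sp.gm_def,
                "suvr_mean": val,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GEE vs pooled OLS oracle


@given(st.integers(0, 10_000))
def test_gee_equals_pooled_ols(seed):
    tab = make_table(seed=seed, effects={("space", "standard"): 0.07})
    res = fit_gee(tab, "suvr_mean")
    # rebuild the identical design with the module's own builder, solve by
    # plain least squares: with the independent working correlation the
    # GEE point estimates must coincide
    from amypipe.stats import _design_from_cells_fixed, _keep_for, FACTORS

    levels = {f: sorted(res.cells[f].unique()) for f in FACTORS}
    X, _, _, _ = _design_from_cells_fixed(tab, levels)
    X = X[:, _keep_for(res, X)]
    y = tab["suvr_mean"].to_numpy()
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    assert np.allclose(res.params, beta, atol=1e-8)


def test_gee_drops_nan_rows_per_metric():
    tab = make_table(seed=1)
    tab.loc[tab["space"] == "native", "suvr_mean"] = np.nan
    res = fit_gee(tab, "suvr_mean")
    assert res.nobs == int((tab["space"] == "standard").sum())
    assert (res.cells["space"] == "standard").all()


def test_gee_requires_metric_column():
    with pytest.raises(ParameterError):
        fit_gee(make_table(), "no_such_metric")


def test_gee_requires_two_subjects():
    tab = make_table(n_ad=1, n_hc=1)
    tab = tab[tab["subject_id"] == "S00"]
    with pytest.raises(ParameterError):
        fit_gee(tab, "suvr_mean")


# ---------------------------------------------------------------------------
# marginal means and contrasts


def test_marginal_means_recover_known_effects():
    eff = 0.12
    tab = make_table(seed=2, effects={("space", "standard"): eff},
                     subject_sd=0.0, noise_sd=0.0)
    res = fit_gee(tab, "suvr_mean")
    d = res.marginal_mean("space", "standard") - res.marginal_mean(
        "space", "native"
    )
    assert d == pytest.approx(eff, abs=1e-10)


def test_pairwise_contrast_percent_of_reference():
    tab = make_table(seed=3, effects={("gm_def", "TEs"): -0.1},
                     subject_sd=0.0, noise_sd=0.0)
    res = fit_gee(tab, "suvr_mean")
    c = pairwise_contrast(res, "gm_def", "TEs", "MRn")
    ref = res.marginal_mean("gm_def", "MRn")
    assert c.mean_diff == pytest.approx(-0.1, abs=1e-10)
    assert c.mean_diff_pct == pytest.approx(-0.1 / ref * 100.0, abs=1e-8)
    assert c.ci95_pct[0] <= c.mean_diff_pct <= c.ci95_pct[1]


def test_pairwise_contrast_null_effect_not_significant():
    tab = make_table(seed=4)
    res = fit_gee(tab, "suvr_mean")
    c = pairwise_contrast(res, "transform", "MAPc", "MAPa")
    assert c.p > 0.05
    assert c.tier == "N.S."


def test_pairwise_contrast_detects_strong_effect():
    tab = make_table(seed=5, effects={("space", "standard"): 0.5},
                     noise_sd=0.02)
    res = fit_gee(tab, "suvr_mean")
    c = pairwise_contrast(res, "space", "standard", "native")
    assert c.p < 0.001


def test_pairwise_contrast_unknown_factor():
    res = fit_gee(make_table(), "suvr_mean")
    with pytest.raises(ParameterError):
        pairwise_contrast(res, "flavour", "a", "b")


def test_overall_contrasts_battery_shape():
    tab = make_table(seed=6)
    oc = overall_contrasts(tab, metrics=("suvr_mean",))
    # 5 all-space comparisons + 2 standard-space MRs comparisons
    assert len(oc) == 7
    assert set(oc["factor"]) == {"space", "transform", "gm_def"}
    assert oc["p"].between(0, 1).all()


def test_significance_tiers():
    assert significance_tier(0.0005) == "p < 0.001"
    assert significance_tier(0.005) == "p < 0.01"
    assert significance_tier(0.03) == "p < 0.05"
    assert significance_tier(0.2) == "N.S."


# ---------------------------------------------------------------------------
# main-pipeline paired comparison


def test_main_pipeline_comparison_oracle():
    tab = make_table(seed=7, effects={("space", "standard"): 0.2},
                     subject_sd=0.0, noise_sd=0.0)
    out = compare_main_pipelines(tab, metrics=("suvr_mean",))
    row = out.iloc[0]
    nat = tab[(tab.space == "native") & (tab["transform"] == "USM")
              & (tab.gm_def == "MRn")]["suvr_mean"].mean()
    assert row["diff_pct"] == pytest.approx(0.2 / nat * 100.0, abs=1e-8)
    assert row["n"] == tab["subject_id"].nunique()


def test_main_pipeline_comparison_missing_subject_raises():
    tab = make_table(seed=8)
    drop = (tab["subject_id"] == "S00") & (tab["space"] == "standard") \
        & (tab["transform"] == "USM") & (tab["gm_def"] == "MRn")
    with pytest.raises(CoverageError):
        compare_main_pipelines(tab[~drop], metrics=("suvr_mean",))


def test_main_pipeline_comparison_nan_pairs_dropped():
    tab = make_table(seed=9)
    sel = (tab["subject_id"] == "S01") & (tab["space"] == "native") \
        & (tab["transform"] == "USM") & (tab["gm_def"] == "MRn")
    tab.loc[sel, "suvr_mean"] = np.nan
    out = compare_main_pipelines(tab, metrics=("suvr_mean",))
    assert out.iloc[0]["n"] == tab["subject_id"].nunique() - 1


# ---------------------------------------------------------------------------
# descriptive summaries


def test_descriptive_summary_quartiles_and_whiskers():
    rng = np.random.default_rng(10)
    vals = rng.normal(0, 1, 40)
    vals[0] = 9.0  # clear outlier
    rows = [
        {"subject_id": f"S{i}", "diagnosis": "AD", "space": "native",
         "transform": "USM", "gm_def": "MRn", "suvr_mean": v}
        for i, v in enumerate(vals)
    ]
    out = descriptive_summary(pd.DataFrame(rows), metrics=("suvr_mean",))
    row = out.iloc[0]
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    assert row["q1"] == pytest.approx(q1)
    assert row["median"] == pytest.approx(med)
    assert row["q3"] == pytest.approx(q3)
    iqr = q3 - q1
    inside = vals[(vals >= q1 - 1.5 * iqr) & (vals <= q3 + 1.5 * iqr)]
    assert row["whisker_hi"] == pytest.approx(inside.max())
    assert 9.0 in row["outliers"]


def test_descriptive_summary_empty_raises():
    with pytest.raises(ParameterError):
        descriptive_summary(pd.DataFrame())


# ---------------------------------------------------------------------------
# bootstrap


def test_cluster_bootstrap_se_deterministic():
    tab = make_table(seed=11)
    a = cluster_bootstrap_se(tab, "suvr_mean", ("space", "standard", "native"),
                             n_boot=50, seed=3)
    b = cluster_bootstrap_se(tab, "suvr_mean", ("space", "standard", "native"),
                             n_boot=50, seed=3)
    assert a == b
    c = cluster_bootstrap_se(tab, "suvr_mean", ("space", "standard", "native"),
                             n_boot=50, seed=4)
    assert a != c
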