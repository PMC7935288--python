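"""Inferential layer: GEE pipeline comparison and descriptive summaries.

Each metric is modelled with a generalized estimating equation on the
linear (identity) scale: categorical main effects for analysis space,
transform method and GM definition plus all two-way interactions, subjects
as clusters, an *independent* working correlation and a robust (sandwich)
covariance.  With the independent working correlation the point estimates
coincide with pooled ordinary least squares; the clustering only affects
the standard errors.

Pairwise factor comparisons are reported the way pipeline-comparison
studies print them: the difference of estimated marginal means (averaged
over the valid factor cells -- the native x MRs cell does not exist) as a
percentage of the reference level's marginal mean, with a Wald 95% CI and
p-value, uncorrected for multiplicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import CoverageError, ParameterError
from .pipelines import MAIN_PIPELINES
from .quantification import METRIC_COLUMNS

FACTORS = ("space", "transform", "gm_def")
Z95 = 1.959963984540054


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "p < 0.001"
    if p < 0.01:
        return "p < 0.01"
    if p < 0.05:
        return "p < 0.05"
    return "N.S."


@dataclass
class Contrast:
    label: str
    mean_diff: float
    mean_diff_pct: float
    ci95_pct: tuple
    p: float
    tier: str = ""

    def __post_init__(self):
        self.tier = significance_tier(self.p)


@dataclass
class GEEResult:
    metric: str
    params: np.ndarray
    robust_cov: np.ndarray
    columns: list
    cells: pd.DataFrame          # valid factor combinations
    cell_design: np.ndarray      # design rows for each cell
    nobs: int
    n_clusters: int

    def _emm_vector(self, factor: str, level: str) -> np.ndarray:
        sel = self.cells[factor] == level
        if not sel.any():
            raise ParameterError(f"level {level!r} not present for {factor!r}")
        return self.cell_design[sel.to_numpy()].mean(axis=0)

    def marginal_mean(self, factor: str, level: str) -> float:
        return float(self._emm_vector(factor, level) @ self.params)


def _design_from_cells(cells: pd.DataFrame):
    """Main effects + two-way interactions, reference-coded, full rank.

    Columns that cannot be estimated on the observed cells (e.g. the
    native x MRs interaction) are dropped: a column nearly dependent on
    the columns before it (small diagonal in the QR factor) is removed.
    """
    levels = {f: sorted(cells[f].unique()) for f in FACTORS}
    X, names, _, _ = _design_from_cells_fixed(cells, levels)
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    keep = diag > 1e-8 * max(1.0, diag.max())
    if keep.size < X.shape[1]:
        keep = np.concatenate([keep, np.zeros(X.shape[1] - keep.size, bool)])
    return X[:, keep], [n for n, k in zip(names, keep) if k], keep, levels


def fit_gee(table: pd.DataFrame, metric: str) -> GEEResult:
    """Fit the pipeline-comparison GEE for one metric.

    Rows where the metric is missing (e.g. TAB for amyloid-free subjects)
    are dropped for that metric only.  Deterministic: no random starts.
    """
    if metric not in table.columns:
        raise ParameterError(f"metric column {metric!r} missing")
    df = table.dropna(subset=[metric]).copy()
    if df["subject_id"].nunique() < 2:
        raise ParameterError("need at least two subjects")
    cells = (
        df[list(FACTORS)].drop_duplicates().sort_values(list(FACTORS))
        .reset_index(drop=True)
    )
    _, names, keep, levels = _design_from_cells(cells)

    def build_X(frame):
        full, _, _, _ = _design_from_cells_fixed(frame, levels)
        return full[:, keep]

    X = build_X(df)
    y = df[metric].to_numpy(dtype=float)
    groups = df["subject_id"].to_numpy()
    model = sm.GEE(
        y, X, groups=groups, family=sm.families.Gaussian(),
        cov_struct=sm.cov_struct.Independence(),
    )
    res = model.fit()
    cell_design = build_X(cells)
    return GEEResult(
        metric=metric,
        params=np.asarray(res.params),
        robust_cov=np.asarray(res.cov_params()),
        columns=names,
        cells=cells,
        cell_design=cell_design,
        nobs=len(df),
        n_clusters=df["subject_id"].nunique(),
    )


def _design_from_cells_fixed(frame: pd.DataFrame, levels: dict):
    """Like :func:`_design_from_cells` but with a fixed level ordering."""
    cols, names = [np.ones(len(frame))], ["Intercept"]
    dummies = {}
    for f in FACTORS:
        for lev in levels[f][1:]:
            d = (frame[f] == lev).to_numpy(dtype=float)
            dummies[(f, lev)] = d
            cols.append(d)
            names.append(f"{f}[{lev}]")
    fpairs = [(FACTORS[i], FACTORS[j]) for i in range(3) for j in range(i + 1, 3)]
    for fa, fb in fpairs:
        for la in levels[fa][1:]:
            for lb in levels[fb][1:]:
                cols.append(dummies[(fa, la)] * dummies[(fb, lb)])
                names.append(f"{fa}[{la}]:{fb}[{lb}]")
    return np.column_stack(cols), names, None, levels


def pairwise_contrast(
    result: GEEResult, factor: str, level_a: str, level_b: str
) -> Contrast:
    """Marginal-mean contrast ``level_a - level_b`` on one factor.

    Reported as a percentage of the reference (second-named) level's
    marginal mean, with a Wald 95% CI and p-value from the robust
    covariance; no multiplicity correction.
    """
    if factor not in FACTORS:
        raise ParameterError(f"unknown factor {factor!r}")
    La = result._emm_vector(factor, level_a)
    Lb = result._emm_vector(factor, level_b)
    L = La - Lb
    diff = float(L @ result.params)
    var = float(L @ result.robust_cov @ L)
    se = math.sqrt(max(var, 0.0))
    ref = float(Lb @ result.params)
    if abs(ref) < 1e-300:
        raise ParameterError("reference marginal mean is zero")
    if se == 0.0:
        p = 1.0 if diff == 0.0 else 0.0
    else:
        p = 2.0 * (1.0 - sps.norm.cdf(abs(diff) / se))
    scale = 100.0 / ref
    ci = ((diff - Z95 * se) * scale, (diff + Z95 * se) * scale)
    return Contrast(
        label=f"{level_a}—{level_b}",
        mean_diff=diff,
        mean_diff_pct=diff * scale,
        ci95_pct=(min(ci), max(ci)),
        p=p,
    )


def overall_contrasts(table: pd.DataFrame,
                      metrics=METRIC_COLUMNS) -> pd.DataFrame:
    """The standard battery of pairwise comparisons for every metric:
    reference spaces, transforms, and GM definitions (GM contrasts
    involving MRs are evaluated in standard space only)."""
    rows = []
    for metric in metrics:
        res = fit_gee(table, metric)
        pairs = [
            ("space", "standard", "native"),
            ("transform", "MAPc", "MAPa"),
            ("transform", "USM", "MAPa"),
            ("transform", "USM", "MAPc"),
            ("gm_def", "TEs", "MRn"),
        ]
        for factor, a, b in pairs:
            c = pairwise_contrast(res, factor, a, b)
            rows.append({"metric": metric, "factor": factor,
                         "comparison": c.label, "diff_pct": c.mean_diff_pct,
                         "ci_lo_pct": c.ci95_pct[0], "ci_hi_pct": c.ci95_pct[1],
                         "p": c.p, "tier": c.tier})
        # MRs comparisons restricted to standard space
        std = table[table["space"] == "standard"]
        res_std = fit_gee(std, metric)
        for factor, a, b in [("gm_def", "MRs", "MRn"), ("gm_def", "TEs", "MRs")]:
            c = pairwise_contrast(res_std, factor, a, b)
            rows.append({"metric": metric, "factor": factor,
                         "comparison": c.label + " (standard)",
                         "diff_pct": c.mean_diff_pct,
                         "ci_lo_pct": c.ci95_pct[0], "ci_hi_pct": c.ci95_pct[1],
                         "p": c.p, "tier": c.tier})
    return pd.DataFrame(rows)


def compare_main_pipelines(table: pd.DataFrame,
                           metrics=METRIC_COLUMNS) -> pd.DataFrame:
    """Paired contrast [standard+MRn+USM] - [native+MRn+USM] per metric.

    Uses the per-subject paired differences (subjects are the clusters, one
    pair each, so the robust SE reduces to the SE of the mean difference).
    The percent scale is relative to the native-pipeline mean.
    """
    sel = {}
    for spec in MAIN_PIPELINES:
        sub = table[
            (table["space"] == spec.space)
            & (table["transform"] == spec.transform)
            & (table["gm_def"] == spec.gm_def)
        ].set_index("subject_id")
        sel[spec.space] = sub
    all_subjects = set(table["subject_id"])
    for space, sub in sel.items():
        missing = all_subjects - set(sub.index)
        if missing:
            raise CoverageError(
                f"main pipeline ({space}) missing for subjects: {sorted(missing)}"
            )
    rows = []
    for metric in metrics:
        a = sel["standard"][metric]
        b = sel["native"][metric]
        pair = pd.concat([a, b], axis=1, keys=["std", "nat"]).dropna()
        d = (pair["std"] - pair["nat"]).to_numpy(dtype=float)
        n = d.size
        if n == 0:
            rows.append({"metric": metric, "diff_pct": math.nan,
                         "ci_lo_pct": math.nan, "ci_hi_pct": math.nan,
                         "p": math.nan, "n": 0, "tier": ""})
            continue
        mean_d = float(d.mean())
        se = float(d.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        ref = float(pair["nat"].mean())
        scale = 100.0 / ref if ref != 0 else math.nan
        if se == 0.0:
            p = 1.0 if mean_d == 0.0 else 0.0
        else:
            p = 2.0 * (1.0 - sps.norm.cdf(abs(mean_d) / se))
        rows.append({
            "metric": metric,
            "diff_pct": mean_d * scale,
            "ci_lo_pct": (mean_d - Z95 * se) * scale,
            "ci_hi_pct": (mean_d + Z95 * se) * scale,
            "p": p,
            "n": n,
            "tier": significance_tier(p),
        })
    return pd.DataFrame(rows)


def descriptive_summary(table: pd.DataFrame,
                        metrics=METRIC_COLUMNS) -> pd.DataFrame:
    """Boxplot-style summaries per (pipeline, diagnosis, metric).

    Quartiles use linear interpolation (type 7); whiskers extend to the
    most extreme datum within 1.5 x IQR of the quartiles, and data beyond
    the whiskers are listed as outliers.
    """
    if table.empty:
        raise ParameterError("empty metric table")
    rows = []
    keys = ["space", "transform", "gm_def", "diagnosis"]
    for vals, grp in table.groupby(keys, sort=True):
        for metric in metrics:
            x = grp[metric].dropna().to_numpy(dtype=float)
            if x.size == 0:
                continue
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            iqr = q3 - q1
            lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = x[(x >= lo_fence) & (x <= hi_fence)]
            wlo = float(inside.min()) if inside.size else float(med)
            whi = float(inside.max()) if inside.size else float(med)
            outliers = sorted(x[(x < wlo) | (x > whi)].tolist())
            rows.append(dict(
                zip(keys, vals),
                metric=metric,
                n=int(x.size),
                mean=float(x.mean()),
                sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
                median=float(med),
                q1=float(q1), q3=float(q3),
                whisker_lo=wlo, whisker_hi=whi,
                outliers=outliers,
            ))
    return pd.DataFrame(rows)


def cluster_bootstrap_se(
    table: pd.DataFrame,
    metric: str,
    contrast: tuple,
    n_boot: int = 500,
    seed: int = 0,
) -> float:
    """Nonparametric cluster (subject) bootstrap SE of a pairwise contrast.

    Refits the pooled least-squares solution (identical to the GEE point
    estimates under the independent working correlation) on each resample
    of whole subjects; used as an independent check on the sandwich SE.
    """
    factor, level_a, level_b = contrast
    rng = np.random.default_rng(seed)
    base = fit_gee(table, metric)
    levels = {f: sorted(base.cells[f].unique()) for f in FACTORS}
    La = base._emm_vector(factor, level_a)
    Lb = base._emm_vector(factor, level_b)
    L = La - Lb
    df = table.dropna(subset=[metric])
    subjects = df["subject_id"].unique()
    groups = {s: g for s, g in df.groupby("subject_id")}
    X_cols = None
    vals = []
    for _ in range(n_boot):
        draw = rng.choice(subjects, size=len(subjects), replace=True)
        boot = pd.concat([groups[s] for s in draw], ignore_index=True)
        Xb, _, _, _ = _design_from_cells_fixed(boot, levels)
        Xb = Xb[:, _keep_for(base, Xb)]
        yb = boot[metric].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
        vals.append(float(L @ beta))
    return float(np.std(vals, ddof=1))


def _keep_for(result: GEEResult, X_full: np.ndarray) -> np.ndarray:
    """Column mask reproducing the fitted design's rank reduction."""
    # the fitted design kept len(result.columns) columns in original order;
    # rebuild the mask from the stored names
    full_names = _design_from_cells_fixed(
        result.cells, {f: sorted(result.cells[f].unique()) for f in FACTORS}
    )[1]
    kept = set(result.columns)
    return np.array([n in kept for n in full_names])
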