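"""Statistical battery: residualization, partial correlations, clinical
group splits, and three-group ANOVA with Tukey HSD post hoc tests.

Correlations between connectivity measures and structural/clinical
variables are partial correlations: both variables are residualized on the
covariate design (age, sex, optionally center dummies) and the Pearson
correlation of the residuals is tested with n - 2 - k degrees of freedom.
Each family of tests (the tests shown together in one table or figure) is
Bonferroni-corrected within itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "StatResult",
    "GroupComparison",
    "residualize",
    "partial_correlation",
    "bonferroni",
    "split_groups",
    "anova_tukey",
    "run_correlation_battery",
    "battery_report",
]

EDSS_CUTOFF = 3.0
SDMT_CUTOFF = 40


@dataclass
class StatResult:
    """One partial-correlation test."""

    x: str
    y: str
    r: float
    n: int
    p_raw: float
    p_corrected: float
    family: str
    family_size: int
    covariates: tuple[str, ...]

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["covariates"] = "+".join(self.covariates)
        return d


@dataclass
class GroupComparison:
    """One-way ANOVA over clinical groups with Tukey HSD pairwise table."""

    metric: str
    groups: tuple[str, ...]
    group_n: tuple[int, ...]
    f_stat: float
    p_value: float
    tukey: pd.DataFrame  # columns: group1, group2, mean_diff, p_adj, reject
    n_excluded: int = 0


def _design_matrix(covariates, n: int) -> np.ndarray:
    """Intercept plus covariate columns; categorical columns are dummy-coded."""
    cols = [np.ones(n)]
    names = ["intercept"]
    if covariates is not None:
        cov = covariates if isinstance(covariates, pd.DataFrame) else _cov_frame(covariates, n)
        for name in cov.columns:
            col = cov[name]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col, prefix=name, drop_first=True)
                for dname in dummies.columns:
                    cols.append(dummies[dname].to_numpy(dtype=float))
                    names.append(str(dname))
            else:
                cols.append(col.to_numpy(dtype=float))
                names.append(str(name))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"collinear covariate design: columns {names}")
    return X


def _cov_frame(covariates, n: int) -> pd.DataFrame:
    arr = np.asarray(covariates)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != n:
        arr = arr.T
    return pd.DataFrame(arr)


def residualize(y, covariates=None) -> np.ndarray:
    """Remove the least-squares projection of y on [intercept, covariates].

    Always removes the mean; with no covariates this is plain centering.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    X = _design_matrix(covariates, n)
    if n <= X.shape[1] + 1:
        raise ValueError(f"n={n} too small for design with {X.shape[1]} columns")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_correlation(x, y, covariates=None, *, x_name="x", y_name="y",
                        family="", family_size=1) -> StatResult:
    """Pearson correlation of covariate residuals, with adjusted df.

    Two-sided p from the t transform with n - 2 - k degrees of freedom,
    k the number of (non-intercept) covariate columns.
    """
    rx = residualize(x, covariates)
    ry = residualize(y, covariates)
    n = rx.shape[0]
    k = _design_matrix(covariates, n).shape[1] - 1
    sx, sy = rx.std(), ry.std()
    if sx <= 0 or sy <= 0:
        raise ValueError("zero-variance residuals: correlation undefined")
    r = float(np.clip((rx * ry).mean() / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom ({df})")
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return StatResult(x=x_name, y=y_name, r=r, n=n, p_raw=p,
                      p_corrected=min(1.0, family_size * p),
                      family=family, family_size=family_size,
                      covariates=tuple() if covariates is None else
                      tuple(map(str, getattr(covariates, "columns", range(k)))))


def bonferroni(p_values, family_size: int | None = None) -> np.ndarray:
    """min(1, m * p) for each p; m defaults to the number of tests."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = len(p) if family_size is None else family_size
    if m < len(p):
        raise ValueError(f"family size {m} smaller than number of tests {len(p)}")
    return np.minimum(1.0, m * p)


def split_groups(
    records: pd.DataFrame,
    score: str,
    *,
    edss_cutoff: float = EDSS_CUTOFF,
    sdmt_cutoff: float = SDMT_CUTOFF,
    boundary_high: bool = True,
) -> tuple[pd.Series, int]:
    """Three-way clinical split: HC plus low/high patient groups.

    EDSS: high disability iff edss >= cutoff (3.0); SDMT: preserved
    ("high") iff sdmt >= cutoff (40), impaired below. The boundary value
    goes to the "high" side by default (``boundary_high``). HC subjects
    always form their own group regardless of missing scores; patients
    missing the score are excluded and counted.

    Returns (labels indexed like records with NaN for excluded rows,
    n_excluded).
    """
    if score not in ("edss", "sdmt"):
        raise ValueError("score must be 'edss' or 'sdmt'")
    cutoff = edss_cutoff if score == "edss" else float(sdmt_cutoff)
    labels = pd.Series(index=records.index, dtype=object)
    is_hc = records["diagnosis"].astype(str).str.upper().eq("HC")
    labels[is_hc] = "HC"
    vals = pd.to_numeric(records.loc[~is_hc, score], errors="coerce")
    missing = vals.isna()
    high = vals >= cutoff if boundary_high else vals > cutoff
    labels[vals.index[high & ~missing]] = f"high_{score}"
    labels[vals.index[~high & ~missing]] = f"low_{score}"
    return labels, int(missing.sum())


def anova_tukey(values, group_labels, *, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA across groups plus all-pairs Tukey HSD.

    Unequal group sizes use the Tukey-Kramer form (statsmodels). Requires
    at least two groups with >= 2 observations each.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray([str(g) for g in group_labels])
    ok = np.isfinite(values) & (labels != "nan") & (labels != "None")
    values, labels = values[ok], labels[ok]
    levels = sorted(set(labels))
    groups = [values[labels == lv] for lv in levels]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    small = [lv for lv, g in zip(levels, groups) if len(g) < 2]
    if small:
        raise ValueError(f"groups with < 2 values: {small}")
    if np.ptp(values) == 0:
        # identical data everywhere: F is 0/0, define as 0 with p=1
        f_stat, p = 0.0, 1.0
        pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
        tukey = pd.DataFrame({
            "group1": [a for a, _ in pairs], "group2": [b for _, b in pairs],
            "mean_diff": 0.0, "p_adj": 1.0, "reject": False,
        })
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_stat, p = sps.f_oneway(*groups)
        res = pairwise_tukeyhsd(values, labels, alpha=alpha)
        tukey = pd.DataFrame({
            "group1": [str(r[0]) for r in res.summary().data[1:]],
            "group2": [str(r[1]) for r in res.summary().data[1:]],
            "mean_diff": res.meandiffs,
            "p_adj": res.pvalues,
            "reject": res.reject,
        })
    return GroupComparison(
        metric="", groups=tuple(levels), group_n=tuple(len(g) for g in groups),
        f_stat=float(f_stat), p_value=float(p), tukey=tukey,
        n_excluded=int((~ok).sum()),
    )


# measures entering the battery
INTER_MEASURES = ["commissural_ratio", "cc_ratio"]
INTRA_MEASURES = ["spl_mean", "eff_mean"]
RATIO_MEASURES = [
    "ratio_commissural_spl", "ratio_commissural_eff",
    "ratio_ccratio_spl", "ratio_ccratio_eff",
]
CLINICAL_TARGETS = ["gmf", "wmf", "lvf", "edss", "sdmt"]


def _check_alignment(metrics: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    if not metrics.index.equals(records.index):
        if set(metrics.index) != set(records.index):
            raise ValueError(
                "metrics and records tables list different subject ids"
            )
        records = records.loc[metrics.index]
    return records


def run_correlation_battery(
    metrics: pd.DataFrame,
    records: pd.DataFrame,
    *,
    include_center_covariate: bool = False,
) -> list[StatResult]:
    """The three correlation families of the analysis.

    (a) inter- vs intrahemispheric measure pairs, separately in HC and in
        patients (4 pairs x 2 groups = family of 8);
    (b) agreement between the two interhemispheric measures, plus the raw
        CC area, in the full cohort (family of 2);
    (c) measures and inter/intra ratios against GMF/WMF/LVF/EDSS/SDMT in
        patients (8 x 5 = family of 40).

    Covariates: age and sex (harmonized data); with
    ``include_center_covariate`` center dummies are added to family (c),
    matching an analysis corrected by center, age, and sex.
    Both tables must be indexed by the same subject ids.
    """
    records = _check_alignment(metrics, records)
    is_ms = ~records["diagnosis"].astype(str).str.upper().eq("HC")
    results: list[StatResult] = []

    def cov_for(idx, with_center=False):
        cols = {"age": records.loc[idx, "age"].astype(float),
                "sex": records.loc[idx, "sex"].astype(float)}
        df = pd.DataFrame(cols, index=idx)
        if with_center:
            df["center"] = records.loc[idx, "center"].astype(str)
        return df

    # family (a): conservation structure, split by diagnosis
    fam_a = []
    for group, mask in (("HC", ~is_ms), ("MS", is_ms)):
        idx = metrics.index[mask]
        for inter in INTER_MEASURES:
            for intra in INTRA_MEASURES:
                fam_a.append((f"{inter} [{group}]", intra, idx, inter, intra))
    m_a = len(fam_a)
    for name_x, name_y, idx, inter, intra in fam_a:
        results.append(partial_correlation(
            metrics.loc[idx, inter], metrics.loc[idx, intra],
            cov_for(idx), x_name=name_x, y_name=name_y,
            family="inter_vs_intra", family_size=m_a))

    # family (b): do the two interhemispheric measures agree?
    idx = metrics.index
    fam_b = [("commissural_ratio", "cc_ratio", metrics["cc_ratio"]),
             ("commissural_ratio", "cc_area", records["cc_area"].astype(float))]
    for name_x, name_y, yvals in fam_b:
        results.append(partial_correlation(
            metrics[name_x], yvals, cov_for(idx),
            x_name=name_x, y_name=name_y,
            family="inter_measure_agreement", family_size=len(fam_b)))

    # family (c): measures and ratios vs structure and clinical scores, patients
    ms_idx = metrics.index[is_ms]
    measures = INTER_MEASURES + INTRA_MEASURES + RATIO_MEASURES
    pairs = []
    for meas in measures:
        for target in CLINICAL_TARGETS:
            tvals = pd.to_numeric(records.loc[ms_idx, target], errors="coerce")
            keep = ms_idx[tvals.notna()]
            if len(keep) < 10:
                warnings.warn(f"skipping {meas} vs {target}: n={len(keep)}")
                continue
            pairs.append((meas, target, keep))
    m_c = len(pairs)
    for meas, target, keep in pairs:
        results.append(partial_correlation(
            metrics.loc[keep, meas],
            pd.to_numeric(records.loc[keep, target]),
            cov_for(keep, with_center=include_center_covariate),
            x_name=meas, y_name=target,
            family="clinical_structure", family_size=m_c))
    return results


def battery_report(results: list[StatResult]) -> str:
    """Plain-text report: one block per family, family sizes stated."""
    lines = []
    for family in dict.fromkeys(r.family for r in results):
        fam = [r for r in results if r.family == family]
        lines.append(f"== family: {family} (m = {fam[0].family_size} tests, "
                     f"Bonferroni within family) ==")
        for r in fam:
            star = " *" if r.p_corrected < 0.05 else ""
            lines.append(
                f"  {r.x:32s} vs {r.y:22s} r={r.r:+.3f} n={r.n:4d} "
                f"p={r.p_raw:.2e} p_corr={r.p_corrected:.2e}{star}"
            )
        lines.append("")
    return "\n".join(lines)
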