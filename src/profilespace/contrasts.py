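"""Parcel-wise group statistics: GLM sex contrasts, FDR, effect sizes,
hormone subgrouping, cross-comparison ANOVA, QC filtering, and split-half
reliability.

The core model regresses each parcel's measure on an intercept, a sex
indicator (female = 1, so positive contrasts mean "higher in females"), age,
intracranial volume and the surface Euler number (a data-quality proxy),
fitted by ordinary least squares with a shared design matrix across parcels
(mass-univariate).  Two-sided p-values from the t distribution are corrected
by Benjamini-Hochberg FDR per contrast map, and significant t values are
converted to Cohen's d via the standard two-group relation
``d = t * sqrt(1/n1 + 1/n2)``.

Hormone proxies follow a binned menstrual-cycle design: naturally cycling
(NC) females reporting a cycle day of 7-23 form the high-estrogen group and
the remaining days (0-6, 24-28: just before and during menstruation) the
low-estrogen group; progesterone is low before day 15 and high from day 15
on.  The two binnings overlap by design.  Oral-contraceptive (OC) users form
their own group regardless of cycle day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_COVARIATES = ("age", "icv", "euler_number")

SUBGROUPS = ("OC", "low_estrogen", "high_estrogen",
             "low_progesterone", "high_progesterone")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_outlier_filter(
    subject_summary_metrics: pd.DataFrame, sd_threshold: float = 2.5
) -> tuple[pd.Index, pd.DataFrame]:
    """Exclude subjects deviating more than ``sd_threshold`` group SDs on any metric.

    The boundary is strict: a subject exactly at the threshold is retained.
    Zero-variance metrics are skipped with a warning.  Returns the included
    subject index and a per-metric exclusion-count report.
    """
    m = subject_summary_metrics
    if len(m) < 3:
        raise ValueError("need at least 3 subjects")
    if m.shape[1] < 1:
        raise ValueError("need at least 1 metric")
    excluded = pd.Series(False, index=m.index)
    counts = {}
    for col in m.columns:
        x = m[col].astype(float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"metric {col!r} has zero variance; skipped",
                          RuntimeWarning)
            counts[col] = 0
            continue
        out = (x - x.mean()).abs() > sd_threshold * sd
        counts[col] = int(out.sum())
        excluded |= out
    report = pd.DataFrame({"n_excluded": counts})
    return m.index[~excluded], report


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    """Per-parcel statistics for one group contrast (positive = higher in
    the first/female group)."""

    comparison: str
    t: np.ndarray
    dof: int
    p: np.ndarray
    fdr_mask: np.ndarray
    cohen_d: np.ndarray
    n1: int
    n2: int
    q: float = 0.05
    parcel_names: list[str] | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        idx = self.parcel_names or [f"p{i:03d}" for i in range(len(self.t))]
        return pd.DataFrame(
            {
                "parcel": idx,
                "t": self.t,
                "dof": self.dof,
                "p": self.p,
                "q_sig": self.fdr_mask,
                "cohen_d": self.cohen_d,
            }
        )


def build_design(
    cohort: pd.DataFrame, covariates: tuple[str, ...] = DEFAULT_COVARIATES
) -> tuple[np.ndarray, list[str]]:
    """Design matrix [intercept, sex(female=1), covariates...] for a cohort slice."""
    cols = ["intercept", "sex"] + list(covariates)
    sex = (cohort["sex"] == "female").to_numpy(dtype=float)
    parts = [np.ones(len(cohort)), sex]
    missing_rows = []
    for c in covariates:
        v = cohort[c].to_numpy(dtype=float)
        if np.any(~np.isfinite(v)):
            missing_rows.extend(
                cohort.loc[~np.isfinite(v), "subject_id"].tolist()
            )
        parts.append(v)
    if missing_rows:
        raise ValueError(f"missing covariate values for subjects: {missing_rows}")
    x = np.column_stack(parts)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # name the offending columns via the QR diagonal
        _, r = np.linalg.qr(x)
        bad = [cols[i] for i in range(x.shape[1])
               if abs(r[i, i]) < 1e-10 * max(1.0, abs(r[0, 0]))]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return x, cols


def t_to_cohen_d(t, n1: int, n2: int):
    """Standard two-group conversion ``d = t * sqrt(1/n1 + 1/n2)``."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both group sizes must be >= 2")
    return np.asarray(t, dtype=float) * np.sqrt(1.0 / n1 + 1.0 / n2)


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def fit_parcel_glm(
    measure: pd.DataFrame | np.ndarray,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    q: float = 0.05,
    comparison: str = "female_vs_male",
) -> ContrastResult:
    """Mass-univariate OLS of a subjects x parcels measure on the sex design.

    The t statistic of the sex coefficient, its two-sided p-value with
    ``n - k`` residual degrees of freedom, the BH-FDR mask at level ``q``,
    and the t-derived Cohen's d are returned per parcel.
    """
    if isinstance(measure, pd.DataFrame):
        y = measure.to_numpy(dtype=float)
        parcel_names = list(measure.columns)
    else:
        y = np.asarray(measure, dtype=float)
        parcel_names = None
    if y.shape[0] != len(cohort):
        raise ValueError("measure rows do not match cohort rows")
    x, cols = build_design(cohort, covariates)
    n, k = x.shape
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    j = cols.index("sex")
    se = np.sqrt(sigma2 * xtx_inv[j, j])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[j] / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    n1 = int((cohort["sex"] == "female").sum())
    n2 = int((cohort["sex"] == "male").sum())
    return ContrastResult(
        comparison=comparison,
        t=t,
        dof=dof,
        p=p,
        fdr_mask=bh_fdr(p, q),
        cohen_d=t_to_cohen_d(t, n1, n2),
        n1=n1,
        n2=n2,
        q=q,
        parcel_names=parcel_names,
    )


# ---------------------------------------------------------------------------
# Hormone proxy groups
# ---------------------------------------------------------------------------

@dataclass
class HormoneGroups:
    """Boolean membership of each female subject in the five proxy groups.

    Estrogen labels partition the NC females with a usable cycle day, as do
    progesterone labels; the two binnings overlap by design.  OC users are
    disjoint from all NC groups.
    """

    membership: pd.DataFrame  # index subject_id, one bool column per subgroup
    day_windows: dict

    def subjects(self, group: str) -> pd.Index:
        return self.membership.index[self.membership[group]]


def assign_hormone_groups(cohort: pd.DataFrame) -> HormoneGroups:
    """Assign females to OC / estrogen / progesterone proxy groups.

    High estrogen: NC females with cycle day 7-23 (mid-cycle); low estrogen:
    days 0-6 or 24-28.  Low progesterone: day <= 14 (follicular); high
    progesterone: day >= 15 (luteal).  NC females without a usable cycle day
    in [0, 28] belong to no NC subgroup.  Males with a cycle_day entry
    trigger a consistency warning.
    """
    male_cd = (cohort["sex"] == "male") & cohort["cycle_day"].notna()
    if male_cd.any():
        warnings.warn(
            f"males with a cycle_day entry: "
            f"{cohort.loc[male_cd, 'subject_id'].tolist()}",
            RuntimeWarning,
        )
    fem = cohort[cohort["sex"] == "female"]
    oc = fem["oc_user"].to_numpy(dtype=bool)
    day = fem["cycle_day"].to_numpy(dtype=float)
    valid = ~oc & np.isfinite(day) & (day >= 0) & (day <= 28)
    membership = pd.DataFrame(
        {
            "OC": oc,
            "low_estrogen": valid & ((day <= 6) | (day >= 24)),
            "high_estrogen": valid & (day >= 7) & (day <= 23),
            "low_progesterone": valid & (day <= 14),
            "high_progesterone": valid & (day >= 15),
        },
        index=pd.Index(fem["subject_id"], name="subject_id"),
    )
    windows = {
        "high_estrogen": (7, 23),
        "low_estrogen": ((0, 6), (24, 28)),
        "low_progesterone": (0, 14),
        "high_progesterone": (15, 28),
    }
    return HormoneGroups(membership=membership, day_windows=windows)


def run_group_comparisons(
    measure: pd.DataFrame,
    cohort: pd.DataFrame,
    groups: HormoneGroups,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    q: float = 0.05,
) -> dict[str, ContrastResult]:
    """All sex/hormone contrasts for one measure.

    Baseline (all females vs all males), each of the five female subgroups vs
    all males, and within-female contrasts (OC vs all NC, OC vs each NC
    subgroup, low vs high estrogen, low vs high progesterone).  Within-female
    contrasts recode the first-listed group as the positive "sex" level.
    Empty subgroups are skipped with a warning.
    """
    cohort = cohort.set_index("subject_id", drop=False).loc[measure.index]
    males = cohort.index[cohort["sex"] == "male"]
    results: dict[str, ContrastResult] = {}

    def fit(sub_idx: pd.Index, name: str, pos: pd.Index, neg: pd.Index):
        if len(pos) < 2 or len(neg) < 2:
            warnings.warn(f"skipping {name}: a group has < 2 subjects",
                          RuntimeWarning)
            return
        sub = cohort.loc[sub_idx].copy()
        # recode: members of `pos` play the "female" role in the design
        sub["sex"] = np.where(sub.index.isin(pos), "female", "male")
        results[name] = fit_parcel_glm(
            measure.loc[sub_idx], sub, covariates, q, comparison=name
        )

    females = cohort.index[cohort["sex"] == "female"]
    fit(females.union(males), "all_females_vs_males", females, males)
    for g in SUBGROUPS:
        sub = groups.subjects(g)
        fit(sub.union(males), f"{g}_vs_males", sub, males)

    nc_any = groups.membership.index[
        groups.membership[["low_estrogen", "high_estrogen"]].any(axis=1)
    ]
    oc = groups.subjects("OC")
    fit(oc.union(nc_any), "OC_vs_NC", oc, nc_any)
    for g in SUBGROUPS[1:]:
        sub = groups.subjects(g)
        fit(oc.union(sub), f"OC_vs_{g}", oc, sub)
    fit(
        groups.subjects("low_estrogen").union(groups.subjects("high_estrogen")),
        "low_vs_high_estrogen",
        groups.subjects("low_estrogen"),
        groups.subjects("high_estrogen"),
    )
    fit(
        groups.subjects("low_progesterone").union(
            groups.subjects("high_progesterone")
        ),
        "low_vs_high_progesterone",
        groups.subjects("low_progesterone"),
        groups.subjects("high_progesterone"),
    )
    return results


def effectsize_anova_tukey(
    d_maps: dict[str, np.ndarray],
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA over parcel-wise Cohen's d maps, with Tukey HSD post hoc.

    Parcels are treated as observations and the comparison as the factor,
    replicating the common practice of comparing effect-size maps; note that
    parcels are spatially autocorrelated, so the nominal p-values are
    anticonservative in that respect (reported as-is, caveat documented).
    """
    if len(d_maps) < 2:
        raise ValueError("need at least 2 comparison groups")
    names = list(d_maps)
    arrays = [np.asarray(d_maps[k], dtype=float) for k in names]
    sizes = {a.shape for a in arrays}
    if len(sizes) > 1:
        raise ValueError("d maps must have equal parcel counts")
    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]):
        # identical maps: no between- or within-group variation
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*arrays)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            with np.errstate(invalid="ignore", divide="ignore"):
                ci = res.confidence_interval()
            p_ij = float(res.pvalue[i, j])
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                    "p_tukey": 1.0 if np.isnan(p_ij) else p_ij,
                    "ci_low": float(ci.low[i, j]),
                    "ci_high": float(ci.high[i, j]),
                }
            )
    return float(f_stat), float(p_val), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Split-half reliability
# ---------------------------------------------------------------------------

@dataclass
class ReliabilityResult:
    r: np.ndarray  # per-split Pearson r between the two half t-maps
    mean: float
    ci: tuple[float, float]  # 5th / 95th percentile across splits


def split_half_reliability(
    measure: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    n_perm: int = 1000,
    seed: int = 0,
) -> ReliabilityResult:
    """Sex-contrast reproducibility across random split-halves.

    Each split partitions the subjects into two disjoint halves with equal
    sex ratios (an odd count per sex sends the extra subject to the first
    half), fits the sex GLM in each half, and correlates the two
    unthresholded t-maps.  Reports the per-split r, its mean, and the
    5th/95th percentiles.
    """
    cohort = cohort.set_index("subject_id", drop=False).loc[measure.index]
    fem = np.flatnonzero((cohort["sex"] == "female").to_numpy())
    mal = np.flatnonzero((cohort["sex"] == "male").to_numpy())
    if len(fem) < 4 or len(mal) < 4:
        raise ValueError("need at least 4 subjects per sex")
    rng = np.random.default_rng(seed)
    y = measure.to_numpy(dtype=float)
    rs = np.empty(n_perm)
    for s in range(n_perm):
        fp = rng.permutation(fem)
        mp = rng.permutation(mal)
        half_a = np.concatenate([fp[: (len(fem) + 1) // 2], mp[: (len(mal) + 1) // 2]])
        half_b = np.setdiff1d(np.arange(len(cohort)), half_a)
        tmaps = []
        for idx in (half_a, half_b):
            res = fit_parcel_glm(
                y[idx], cohort.iloc[idx], covariates, comparison="split"
            )
            tmaps.append(res.t)
        rs[s] = np.corrcoef(tmaps[0], tmaps[1])[0, 1]
    return ReliabilityResult(
        r=rs,
        mean=float(rs.mean()),
        ci=(float(np.percentile(rs, 5)), float(np.percentile(rs, 95))),
    )
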