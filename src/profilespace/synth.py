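"""Synthetic study generator: cohort, depth profiles, reference maps.

The generator emulates the statistical structure of a large young-adult
surface-MRI study: T1w/T2w depth profiles with parcel-specific baselines and
spatially autocorrelated fields, a sex effect on profile mean and skewness,
menstrual-cycle / oral-contraceptive modulation of that effect, nuisance
covariates (age, intracranial volume, surface Euler number, family
structure), and parcel-wise reference maps (a gene panel with controllable
spatial coupling to the true effect map, an ordinal cortical-type atlas and
arterial/venous density maps).  Every planted quantity is returned as ground
truth so downstream estimators have a recoverable target.

Effect calibration
------------------
The sex shift added at parcel ``p`` is ``d_p * sigma_p`` where ``sigma_p`` is
the realized between-subject standard deviation of the parcel's nuisance
components (subject intercept + subject field + aggregated sampling noise),
so the planted Cohen's d equals ``mean_effect_map`` at population level under
the generator's own noise.  Skewness effects are added as a zero-mean,
depth-asymmetric shape whose amplitude is calibrated by a finite-difference
probe of the skewness response; the contract is correct sign and ordering,
not an exact skew-d.

Hormone modulation multiplies the per-subject effect by
``1 + m_p * h(subject)`` with ``h`` piecewise-constant over oral-contraceptive
status and four cycle-day bins (0-6, 7-14, 15-23, 24-28), mirroring a binned
cycle-phase design and making per-bin recovery targets exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .geometry import (
    SphereGeometry,
    smooth_parcel_fields,
)
from .profiles import ProfileArray, depth_grid

COHORT_COLUMNS = [
    "subject_id",
    "sex",
    "age",
    "icv",
    "euler_number",
    "cycle_day",
    "oc_user",
    "family_id",
]

#: cycle-day bins for the piecewise-constant hormone modulation h(subject)
CYCLE_BINS = ((0, 6), (7, 14), (15, 23), (24, 28))


def simulate_cohort(
    n_female: int = 594,
    n_male: int = 499,
    oc_fraction: float = 170 / 594,
    missing_cycle_fraction: float = 140 / 424,
    twin_fraction: float = 0.44,
    age_range: tuple[int, int] = (22, 37),
    icv_median: dict | None = None,
    icv_log_sd: float = 0.065,
    euler_rate: float = 40.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a cohort covariate table.

    Females split into oral-contraceptive (OC) users, naturally cycling (NC)
    females with a self-reported cycle day uniform on {0..28}, and a fraction
    with no usable cycle report.  Defaults mirror a cohort of 594 females
    (170 OC, 284 NC with valid cycle day) and 499 males aged 22-37, with
    sex-specific lognormal intracranial volume, a Poisson-defect surface
    Euler number, and a twin fraction sharing family ids.  The ICV and Euler
    distributions are plausibility placeholders and fully configurable.
    """
    if n_female < 0 or n_male < 0:
        raise ValueError("subject counts must be nonnegative")
    if not 0 <= oc_fraction <= 1:
        raise ValueError("oc_fraction must lie in [0, 1]")
    if not 0 <= missing_cycle_fraction <= 1:
        raise ValueError("missing_cycle_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    icv_median = icv_median or {"female": 1.45e6, "male": 1.60e6}

    n = n_female + n_male
    sex = np.array(["female"] * n_female + ["male"] * n_male, dtype=object)
    subject_id = np.array([f"sub-{i:04d}" for i in range(n)], dtype=object)
    age = rng.integers(age_range[0], age_range[1] + 1, size=n)
    med = np.where(sex == "female", icv_median["female"], icv_median["male"])
    icv = np.exp(np.log(med) + rng.normal(0, icv_log_sd, size=n))
    euler = 4 - 2 * rng.poisson(euler_rate, size=n)

    n_oc = int(round(oc_fraction * n_female))
    oc_user = np.zeros(n, dtype=bool)
    fem_idx = rng.permutation(n_female)
    oc_user[fem_idx[:n_oc]] = True
    nc_idx = fem_idx[n_oc:]
    n_missing = int(round(missing_cycle_fraction * nc_idx.size))
    cycle_day = np.full(n, np.nan)
    reporting = nc_idx[n_missing:]
    cycle_day[reporting] = rng.integers(0, 29, size=reporting.size)

    family_id = np.array([f"fam-{i:04d}" for i in range(n)], dtype=object)
    n_pairs = int(twin_fraction * n) // 2
    paired = rng.permutation(n)[: 2 * n_pairs]
    for a, b in paired.reshape(-1, 2):
        family_id[b] = family_id[a]

    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "sex": sex,
            "age": age.astype(float),
            "icv": icv,
            "euler_number": euler.astype(int),
            "cycle_day": cycle_day,
            "oc_user": oc_user,
            "family_id": family_id,
        }
    )


def validate_cohort(cohort: pd.DataFrame) -> list[str]:
    """Return a list of consistency warnings (empty if the table is clean)."""
    issues = []
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing columns: {missing}")
    male = cohort["sex"] == "male"
    if cohort.loc[male, "cycle_day"].notna().any():
        bad = cohort.loc[male & cohort["cycle_day"].notna(), "subject_id"].tolist()
        issues.append(f"males with a cycle_day entry: {bad}")
    if cohort.loc[male, "oc_user"].any():
        bad = cohort.loc[male & cohort["oc_user"], "subject_id"].tolist()
        issues.append(f"males flagged as OC users: {bad}")
    cd = cohort["cycle_day"].dropna()
    if ((cd < 0) | (cd > 28)).any():
        issues.append("cycle_day values outside [0, 28]")
    return issues


@dataclass
class GroundTruthEffects:
    """Planted effect maps and noise configuration (all maps length P).

    ``mean_effect_map`` / ``skew_effect_map`` are per-parcel true Cohen's d
    for the female-male difference in profile mean / skewness.
    ``hormone_modulation`` is the per-parcel coefficient ``m_p`` of the
    multiplicative modulation ``1 + m_p * h(subject)``; ``h_bins`` gives the
    piecewise-constant h for OC users and the four cycle-day bins (NC females
    with no usable cycle day get h = 0).
    """

    mean_effect_map: np.ndarray
    skew_effect_map: np.ndarray
    hormone_modulation: np.ndarray
    h_bins: dict = field(
        default_factory=lambda: {"oc": 0.0, "bins": (0.0, 0.0, 0.0, 0.0)}
    )
    noise_sd: float = 0.15  # i.i.d. intensity noise per vertex and depth
    smoothness: int = 10  # rounds of neighbourhood averaging for fields
    subject_sd: float = 0.06  # global subject intercept (T1w/T2w units)
    subject_field_sd: float = 0.035  # subject x parcel smooth variation
    baseline_field_sd: float = 0.10  # parcel baseline offsets
    slope_field_sd: float = 0.08  # parcel-specific profile slope variation
    curve_field_sd: float = 0.04  # parcel-specific profile curvature variation
    template_range: tuple[float, float] = (1.2, 1.8)  # superficial -> deep

    @classmethod
    def null(cls, n_parcels: int, **kwargs) -> "GroundTruthEffects":
        z = np.zeros(n_parcels)
        return cls(z.copy(), z.copy(), z.copy(), **kwargs)

    def check(self, n_parcels: int) -> None:
        for name in ("mean_effect_map", "skew_effect_map", "hormone_modulation"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n_parcels,):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected ({n_parcels},)"
                )
            setattr(self, name, arr)
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def hormone_h(cohort: pd.DataFrame, h_bins: dict) -> np.ndarray:
    """Per-subject modulation level h: 0 for males, piecewise-constant for females."""
    h = np.zeros(len(cohort))
    female = (cohort["sex"] == "female").to_numpy()
    oc = cohort["oc_user"].to_numpy(dtype=bool)
    h[female & oc] = h_bins["oc"]
    day = cohort["cycle_day"].to_numpy(dtype=float)
    for (lo, hi), val in zip(CYCLE_BINS, h_bins["bins"]):
        in_bin = female & ~oc & (day >= lo) & (day <= hi)
        h[in_bin] = val
    return h


def simulate_profiles(
    geometry: SphereGeometry,
    cohort: pd.DataFrame,
    effects: GroundTruthEffects,
    n_depths: int = 12,
    seed: int = 0,
) -> ProfileArray:
    """Generate subject x parcel x depth T1w/T2w profiles with planted effects.

    The profile of subject s at parcel p is

        T(k) + B_p + c_p*S(k) + e_p*Q(k) + u_s + f_sp + eps_spk
        + female_s * (1 + m_p*h_s) * (delta_p + a_p*q(k))

    with T a monotone depth template (higher toward the white matter), B/c/e
    smooth parcel fields (baseline, slope, curvature -- the source of
    profile-covariance structure), u a subject intercept, f a subject-level
    smooth field, and eps the parcel-aggregated i.i.d. vertex noise, drawn
    directly at parcel level with its exact N(0, noise_sd^2/V_p) law.
    ``delta_p`` and ``a_p`` are calibrated as described in the module
    docstring.
    """
    if n_depths < 3:
        raise ValueError("n_depths must be >= 3")
    p = geometry.n_parcels
    effects.check(p)
    rng = np.random.default_rng(seed)
    n_sub = len(cohort)
    alphas = depth_grid(n_depths)

    lo, hi = effects.template_range
    template = lo + (hi - lo) * alphas  # alpha measured toward the white matter

    fields = smooth_parcel_fields(geometry, 3, effects.smoothness, rng)
    b_p = effects.baseline_field_sd * fields[:, 0]
    c_p = effects.slope_field_sd * fields[:, 1]
    e_p = effects.curve_field_sd * fields[:, 2]
    s_k = alphas - alphas.mean()
    s_k = s_k / np.linalg.norm(s_k)
    q_k = (alphas - alphas.mean()) ** 2
    q_k -= q_k.mean()
    q_k = q_k / np.linalg.norm(q_k)

    u_s = effects.subject_sd * rng.standard_normal(n_sub)
    f_sp = smooth_parcel_fields(geometry, n_sub, effects.smoothness, rng).T
    f_sp *= effects.subject_field_sd

    v_p = np.bincount(geometry.parcel_labels, minlength=p).astype(float)
    eps = rng.standard_normal((n_sub, p, n_depths)) * (
        effects.noise_sd / np.sqrt(v_p)[None, :, None]
    )

    base = (
        template[None, None, :]
        + (b_p[:, None] + c_p[:, None] * s_k[None, :]
           + e_p[:, None] * q_k[None, :])[None, :, :]
        + u_s[:, None, None]
        + f_sp[:, :, None]
        + eps
    )

    female = (cohort["sex"] == "female").to_numpy(dtype=float)
    mod = 1.0 + effects.hormone_modulation[None, :] * hormone_h(
        cohort, effects.h_bins
    )[:, None]

    # mean-effect calibration against the realized nuisance SD of the parcel mean
    nuisance_mean = u_s[:, None] + f_sp + eps.mean(axis=2)
    sigma_p = nuisance_mean.std(axis=0, ddof=1)
    delta_p = effects.mean_effect_map * sigma_p

    # skew-effect calibration: finite-difference probe of the skewness response
    a_p = np.zeros(p)
    if np.any(effects.skew_effect_map != 0):
        from .profiles import moment_skewness

        skew_base, _ = moment_skewness(base, axis=2)
        sigma_skew = skew_base.std(axis=0, ddof=1)
        probe = 0.05 * (hi - lo)
        # asymmetric unit shape: zero-mean exponential ramp along depth
        ramp = np.exp(3 * alphas)
        q_shape = ramp - ramp.mean()
        q_shape = q_shape / np.linalg.norm(q_shape)
        skew_probe, _ = moment_skewness(base + probe * q_shape, axis=2)
        slope = (skew_probe.mean(axis=0) - skew_base.mean(axis=0)) / probe
        slope = np.where(np.abs(slope) < 1e-6, 1e-6, slope)
        a_p = effects.skew_effect_map * sigma_skew / slope
    else:
        q_shape = np.zeros(n_depths)

    shift = female[:, None] * mod * delta_p[None, :]
    skew_shift = (female[:, None] * mod * a_p[None, :])[:, :, None] * q_shape[
        None, None, :
    ]
    values = base + shift[:, :, None] + skew_shift
    return ProfileArray(
        values=values,
        depth_fractions=alphas,
        subject_ids=list(cohort["subject_id"]),
    )


def srs_normalize(values: np.ndarray, rescale: bool = True) -> np.ndarray:
    """Scaled robust sigmoid normalization to [0, 1].

    ``y = 1 / (1 + exp(-(x - median) / (IQR / 1.35)))`` followed by min-max
    rescaling; strictly order-preserving and robust to outliers (the IQR/1.35
    factor matches the normal-consistent robust scale estimate).  With
    ``rescale=False`` the raw sigmoid stage is returned (a value at the
    median maps to 0.5); note the min-max stage necessarily moves all
    outputs when an extreme value extends the observed range.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3 or not np.all(np.isfinite(x)):
        raise ValueError("need >= 3 finite values in a 1-d array")
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        raise DegenerateInputError("zero interquartile range")
    y = 1.0 / (1.0 + np.exp(-(x - np.median(x)) / (iqr / 1.35)))
    if not rescale:
        return y
    return (y - y.min()) / (y.max() - y.min())


@dataclass
class ReferenceMaps:
    """Parcel-wise reference maps for enrichment and decoding analyses."""

    gene_panel: pd.DataFrame  # parcels x genes, SRS-normalized
    coupled: np.ndarray  # per-gene bool: planted coupling to the effect map
    cortical_types: np.ndarray  # ordinal 1..6 per parcel
    artery_map: np.ndarray
    vein_map: np.ndarray


def simulate_reference_maps(
    geometry: SphereGeometry,
    effect_map: np.ndarray,
    n_genes: int = 25,
    n_coupled: int = 5,
    coupling: float = 0.6,
    smoothness: int = 10,
    seed: int = 0,
) -> ReferenceMaps:
    """Generate a gene panel, cortical-type atlas and vascular maps.

    Coupled genes are ``coupling * z(effect_map) + sqrt(1-coupling^2) * z(field)``
    with an independent smooth field; uncoupled genes are pure smooth fields.
    All gene maps pass through :func:`srs_normalize`.  Cortical types are a
    discretized smooth latitudinal gradient (six quantile bins of the
    centroid z-coordinate plus a smooth perturbation); arterial and venous
    densities are independent smooth fields.
    """
    if not 0 <= n_coupled <= n_genes:
        raise ValueError("need 0 <= n_coupled <= n_genes")
    if not -1 <= coupling <= 1:
        raise ValueError("coupling must lie in [-1, 1]")
    p = geometry.n_parcels
    effect_map = np.asarray(effect_map, dtype=float)
    if effect_map.shape != (p,):
        raise ValueError(f"effect_map must have length {p}")
    rng = np.random.default_rng(seed)

    z_eff = effect_map - effect_map.mean()
    sd = z_eff.std()
    z_eff = z_eff / sd if sd > 0 else z_eff

    fields = smooth_parcel_fields(geometry, n_genes + 3, smoothness, rng)
    genes = np.empty((p, n_genes))
    coupled = np.zeros(n_genes, dtype=bool)
    coupled[:n_coupled] = True
    for g in range(n_genes):
        if coupled[g]:
            raw = coupling * z_eff + np.sqrt(1 - coupling**2) * fields[:, g]
            if abs(coupling) == 1:  # exact copy; keep rank order intact
                raw = coupling * z_eff
        else:
            raw = fields[:, g]
        genes[:, g] = srs_normalize(raw)
    panel = pd.DataFrame(
        genes,
        index=[f"p{i:03d}" for i in range(p)],
        columns=[f"GENE{g:02d}" for g in range(n_genes)],
    )

    lat = geometry.parcel_centroids[:, 2] + 0.3 * fields[:, n_genes]
    ranks = np.argsort(np.argsort(lat))
    types = 1 + (ranks * 6) // p
    return ReferenceMaps(
        gene_panel=panel,
        coupled=coupled,
        cortical_types=types.astype(int),
        artery_map=fields[:, n_genes + 1].copy(),
        vein_map=fields[:, n_genes + 2].copy(),
    )
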