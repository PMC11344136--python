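"""Equivolumetric depth sampling and per-parcel profile measures.

An equivolumetric surface at volume fraction ``alpha`` is placed at the
normalized depth ``rho`` where the cortical volume enclosed between the inner
boundary and the surface equals ``alpha`` of the total segment volume, under
the standard model in which the cross-sectional area varies linearly with
depth between the inner (white-matter) area ``a_in`` and the outer (pial)
area ``a_out``.  This compensates intensity sampling for cortical folding:
in gyral crowns (``a_out > a_in``) surfaces are pushed toward the pial side,
in sulcal fundi the reverse.

Profiles (intensity as a function of depth) are summarized by their depth
mean and their moment skewness; skewness contrasts the dominance of
superficial versus deep sampling points and is rescaled to [0, 1] within
subject for comparability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MissingDataError

EQUAL_AREA_RTOL = 1e-9


def equivolumetric_fraction(a_out, a_in, alpha):
    """Normalized depth ``rho`` of the equivolumetric surface at fraction ``alpha``.

    rho = (-a_in + sqrt(alpha * a_out**2 + (1 - alpha) * a_in**2)) / (a_out - a_in)

    measured from the inner (white-matter) boundary.  When the two boundary
    areas agree to within ``EQUAL_AREA_RTOL`` the continuous limit
    ``rho = alpha`` is returned.  Inputs broadcast like numpy ufuncs.
    """
    a_out = np.asarray(a_out, dtype=float)
    a_in = np.asarray(a_in, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(a_out <= 0):
        raise ValueError("a_out must be positive")
    if np.any(a_in < 0):
        raise ValueError("a_in must be nonnegative")
    if np.any((alpha < 0) | (alpha > 1)):
        raise ValueError("alpha must lie in [0, 1]")
    diff = a_out - a_in
    degenerate = np.abs(diff) < EQUAL_AREA_RTOL * a_out
    safe_diff = np.where(degenerate, 1.0, diff)
    rho = (-a_in + np.sqrt(alpha * a_out**2 + (1 - alpha) * a_in**2)) / safe_diff
    rho = np.where(degenerate, alpha, rho)
    return rho if rho.ndim else float(rho)


def depth_grid(n_surfaces: int = 12) -> np.ndarray:
    """Strictly interior, evenly spaced volume fractions ``k/(n+1)``.

    The surfaces sit *between* the pial and white-matter boundaries, so the
    boundary fractions 0 and 1 are excluded.
    """
    if n_surfaces < 1:
        raise ValueError("n_surfaces must be >= 1")
    return np.arange(1, n_surfaces + 1) / (n_surfaces + 1)


def equivolumetric_depths(a_out, a_in, n_surfaces: int = 12) -> np.ndarray:
    """Depth positions of ``n_surfaces`` equivolumetric surfaces.

    Broadcasts ``(a_out, a_in)`` pairs (e.g. per parcel) against the interior
    volume-fraction grid; returns shape ``(..., n_surfaces)``.
    """
    alphas = depth_grid(n_surfaces)
    a_out = np.asarray(a_out, dtype=float)[..., None]
    a_in = np.asarray(a_in, dtype=float)[..., None]
    return equivolumetric_fraction(a_out, a_in, alphas[None, ...] * np.ones_like(a_out))


@dataclass
class ProfileArray:
    """Subject x parcel x depth intensity profiles (e.g. T1w/T2w ratio)."""

    values: np.ndarray
    depth_fractions: np.ndarray
    subject_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.depth_fractions = np.asarray(self.depth_fractions, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be subject x parcel x depth")
        if self.values.shape[2] != self.depth_fractions.size:
            raise ValueError("depth axis does not match depth_fractions")
        if self.depth_fractions.size < 3:
            raise ValueError("need at least 3 depth samples")
        d = self.depth_fractions
        if np.any(d <= 0) or np.any(d >= 1) or np.any(np.diff(d) <= 0):
            raise ValueError("depth_fractions must be strictly increasing in (0, 1)")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids does not match subject axis")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]

    @property
    def n_depths(self) -> int:
        return self.values.shape[2]


@dataclass
class MeasureTable:
    """One scalar microstructural measure per subject and parcel."""

    name: str  # mean | skewness_raw | skewness_scaled | gradient1
    values: pd.DataFrame  # index subject_id, columns p000..pNNN
    scaling: str = "none"  # none | per_subject_minmax | global_minmax
    degenerate: pd.DataFrame | None = field(default=None, repr=False)

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy()


def parcel_columns(n_parcels: int) -> list[str]:
    return [f"p{i:03d}" for i in range(n_parcels)]


def parcel_profiles(vertex_profiles: np.ndarray, parcel_labels: np.ndarray) -> np.ndarray:
    """Average vertex-wise depth profiles into parcels.

    Parameters
    ----------
    vertex_profiles : (..., V, K) array
    parcel_labels : (V,) int array, contiguous 0-based parcel ids

    Returns the unweighted mean profile per parcel, shape ``(..., P, K)``.
    """
    vertex_profiles = np.asarray(vertex_profiles, dtype=float)
    parcel_labels = np.asarray(parcel_labels)
    n_parcels = int(parcel_labels.max()) + 1
    counts = np.bincount(parcel_labels, minlength=n_parcels)
    if np.any(counts == 0):
        raise MissingDataError(
            f"parcels with no vertices: {np.flatnonzero(counts == 0).tolist()}"
        )
    lead = vertex_profiles.shape[:-2]
    k = vertex_profiles.shape[-1]
    flat = vertex_profiles.reshape(-1, vertex_profiles.shape[-2], k)
    out = np.zeros((flat.shape[0], n_parcels, k))
    for p in range(n_parcels):
        out[:, p, :] = flat[:, parcel_labels == p, :].mean(axis=1)
    return out.reshape(*lead, n_parcels, k)


def moment_skewness(x: np.ndarray, axis: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """Bias-uncorrected moment skewness g1 = m3 / m2**1.5 along ``axis``.

    Constant inputs get skewness 0 with the degeneracy flag set.
    """
    x = np.asarray(x, dtype=float)
    m2 = np.var(x, axis=axis)
    degenerate = m2 == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        g1 = stats.skew(x, axis=axis, bias=True)
    g1 = np.where(degenerate, 0.0, g1)
    return g1, degenerate


def _minmax_rows(a: np.ndarray) -> np.ndarray:
    lo = a.min(axis=1, keepdims=True)
    rng = a.max(axis=1, keepdims=True) - lo
    rng = np.where(rng == 0, 1.0, rng)
    return (a - lo) / rng


def profile_measures(
    profiles: ProfileArray, skew_scaling: str = "per_subject_minmax"
) -> tuple[MeasureTable, MeasureTable, MeasureTable]:
    """Compute the two local profile measures.

    Returns (mean, skewness_raw, skewness_scaled).  Skewness is min-max
    rescaled to [0, 1]; the default scope is within subject across parcels
    (``skew_scaling='global_minmax'`` rescales over the whole table instead).
    """
    if profiles.n_depths < 3:
        raise ValueError("need at least 3 depths")
    cols = parcel_columns(profiles.n_parcels)
    idx = pd.Index(profiles.subject_ids, name="subject_id")
    mean = profiles.values.mean(axis=2)
    g1, degen = moment_skewness(profiles.values, axis=2)
    if degen.any():
        warnings.warn(
            f"{int(degen.sum())} constant profiles; their skewness is set to 0",
            RuntimeWarning,
        )
    if skew_scaling == "per_subject_minmax":
        scaled = _minmax_rows(g1)
    elif skew_scaling == "global_minmax":
        lo, hi = g1.min(), g1.max()
        scaled = (g1 - lo) / (hi - lo if hi > lo else 1.0)
    else:
        raise ValueError(f"unknown skew_scaling: {skew_scaling}")
    mk = lambda name, arr, sc: MeasureTable(
        name,
        pd.DataFrame(arr, index=idx, columns=cols),
        scaling=sc,
        degenerate=pd.DataFrame(degen, index=idx, columns=cols),
    )
    return (
        mk("mean", mean, "none"),
        mk("skewness_raw", g1, "none"),
        mk("skewness_scaled", scaled, skew_scaling),
    )
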