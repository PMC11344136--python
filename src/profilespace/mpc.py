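"""Microstructural profile covariance (MPC) and gradient decomposition.

The MPC entry for parcels i, j is the partial correlation of their depth
profiles controlling for the cortex-average profile,

    MPC(i, j) = (r_ij - r_ic * r_jc) / sqrt((1 - r_ic^2) (1 - r_jc^2)),

averaged over participants.  The matrix is log-transformed (Fisher z on
positive entries), row-wise sparsified to the top 10% strongest similarities,
converted to a normalized-angle affinity, and decomposed by anisotropic
diffusion-map embedding into gradients -- eigenvectors ordering parcels along
axes of microstructural differentiation.  Individual gradients are Procrustes
aligned to a group reference and the first component min-max rescaled.

Any strictly increasing transform of the positive entries leaves the retained
top-10% edge set unchanged; Fisher z is used because it is the conventional
variance-stabilizing "log transform" of correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.linalg import orthogonal_procrustes
from scipy.sparse.csgraph import connected_components

from .errors import DegenerateInputError


@dataclass
class MPCMatrix:
    values: np.ndarray  # P x P
    n_subjects: int
    transform: str = "none"  # none | fisher_z
    sparsity: str = "none"  # none | row_top_fraction
    keep_fraction: float | None = None


@dataclass
class GradientSet:
    components: np.ndarray  # P x n_components
    eigenvalues: np.ndarray  # nonincreasing
    aligned_to: str | None = None
    rescaled: bool = False


def partial_profile_correlation(subject_profiles: np.ndarray) -> np.ndarray:
    """P x P partial correlation of depth profiles given the cortex-average profile.

    ``subject_profiles`` is one subject's (P, K) parcel x depth array.  The
    diagonal is set to 0.
    """
    x = np.asarray(subject_profiles, dtype=float)
    if x.ndim != 2 or x.shape[1] < 3:
        raise ValueError("subject_profiles must be (P, K) with K >= 3")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise DegenerateInputError(f"constant profiles at parcels {bad}")
    cortex = x.mean(axis=0)
    if cortex.std() == 0:
        raise DegenerateInputError("cortex-average profile is constant")
    full = np.corrcoef(np.vstack([x, cortex]))
    r = full[:-1, :-1]
    r_c = full[:-1, -1]
    if np.any(np.abs(r_c) >= 1 - 1e-15):
        bad = np.flatnonzero(np.abs(r_c) >= 1 - 1e-15).tolist()
        raise DegenerateInputError(
            f"profile perfectly correlated with cortex average at parcels {bad}"
        )
    denom = np.sqrt(np.outer(1 - r_c**2, 1 - r_c**2))
    out = (r - np.outer(r_c, r_c)) / denom
    np.fill_diagonal(out, 0.0)
    return out


def group_mpc(per_subject: list[np.ndarray] | np.ndarray) -> MPCMatrix:
    """Element-wise mean of per-subject MPC matrices."""
    mats = np.asarray(per_subject, dtype=float)
    if mats.ndim == 2:
        mats = mats[None, ...]
    if mats.ndim != 3 or mats.shape[1] != mats.shape[2]:
        raise ValueError("expected a stack of square matrices of equal size")
    return MPCMatrix(values=mats.mean(axis=0), n_subjects=mats.shape[0])


def subject_mpc(profiles) -> list[np.ndarray]:
    """Per-subject MPC matrices from a :class:`~.profiles.ProfileArray`."""
    return [partial_profile_correlation(profiles.values[s])
            for s in range(profiles.n_subjects)]


def log_threshold_sparsify(
    matrix: MPCMatrix | np.ndarray, keep_fraction: float = 0.10
) -> MPCMatrix:
    """Fisher-z transform positive entries, zero the rest, keep row-wise top edges.

    Per row, the ``ceil(keep_fraction * (P - 1))`` largest off-diagonal
    entries are retained (ties broken toward the lower column index); all
    other entries are set to 0.  The result is generally asymmetric.
    """
    m = matrix.values if isinstance(matrix, MPCMatrix) else np.asarray(matrix, float)
    n_sub = matrix.n_subjects if isinstance(matrix, MPCMatrix) else 1
    p = m.shape[0]
    off = ~np.eye(p, dtype=bool)
    if np.any(np.abs(m[off]) >= 1):
        raise ValueError("entries must lie strictly inside (-1, 1)")
    z = np.where(m > 0, np.arctanh(np.clip(m, 0, None)), 0.0)
    np.fill_diagonal(z, 0.0)
    if not np.any(z > 0):
        warnings.warn("no positive similarities; sparsified graph is empty",
                      RuntimeWarning)
    k = int(np.ceil(keep_fraction * (p - 1)))
    out = np.zeros_like(z)
    for i in range(p):
        row = z[i].copy()
        row[i] = -np.inf
        order = np.argsort(-row, kind="stable")  # ties -> lower index first
        keep = order[:k]
        keep = keep[row[keep] > 0]  # never retain nonpositive entries
        out[i, keep] = row[keep]
    return MPCMatrix(
        values=out,
        n_subjects=n_sub,
        transform="fisher_z",
        sparsity="row_top_fraction",
        keep_fraction=keep_fraction,
    )


def normalized_angle_affinity(matrix: MPCMatrix | np.ndarray) -> np.ndarray:
    """Row-wise normalized-angle similarity: 1 - arccos(cosine(i, j)) / pi.

    Identical rows give 1, orthogonal rows 0.5, antiparallel rows 0.  Rows
    that are entirely zero are flagged and get affinity 0 to all others
    (1 to self).
    """
    m = matrix.values if isinstance(matrix, MPCMatrix) else np.asarray(matrix, float)
    norms = np.linalg.norm(m, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"all-zero rows at parcels {np.flatnonzero(zero).tolist()}",
            RuntimeWarning,
        )
    safe = np.where(zero, 1.0, norms)
    unit = m / safe[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    aff = 1.0 - np.arccos(cos) / np.pi
    aff[zero, :] = 0.0
    aff[:, zero] = 0.0
    aff[np.ix_(zero, zero)] = 0.0
    np.fill_diagonal(aff, 1.0)
    return aff


def diffusion_embedding(
    affinity: np.ndarray,
    n_components: int = 10,
    anisotropy: float = 0.5,
    orient_to: np.ndarray | None = None,
) -> GradientSet:
    """Anisotropic diffusion-map embedding of a nonnegative affinity matrix.

    The kernel is normalized as ``W' = D^-a W D^-a`` (a = anisotropy), turned
    into a Markov transition matrix, and eigendecomposed through its
    symmetric conjugate.  The trivial constant eigenvector is dropped and the
    next ``n_components`` eigenvectors are returned scaled by
    ``lambda / (1 - lambda)`` (automatic diffusion time).  If the affinity
    graph is disconnected the leading unit eigenspace is rotated so its first
    basis vector is the global stationary direction, which makes the first
    gradient sign-separate the components; a warning reports the component
    count.  If ``orient_to`` is given, the first component's sign is chosen
    to correlate positively with it; other components get a deterministic
    max-|entry|-positive sign convention.
    """
    w = np.asarray(affinity, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("affinity must be square")
    if np.any(w < 0):
        raise ValueError("affinity must be nonnegative")
    if not np.allclose(w, w.T, atol=1e-8):
        raise ValueError("affinity must be symmetric within 1e-8")
    w = (w + w.T) / 2
    p = w.shape[0]

    n_comp_graph, comp_labels = connected_components(
        sparse.csr_matrix((w > 0).astype(int)), directed=False
    )
    if n_comp_graph > 1:
        warnings.warn(
            f"affinity graph has {n_comp_graph} connected components",
            RuntimeWarning,
        )

    d = w.sum(axis=1)
    d = np.where(d == 0, 1.0, d)
    w_a = w / np.outer(d**anisotropy, d**anisotropy)
    d_a = w_a.sum(axis=1)
    d_a = np.where(d_a == 0, 1.0, d_a)
    inv_sqrt = 1.0 / np.sqrt(d_a)
    sym = w_a * np.outer(inv_sqrt, inv_sqrt)
    evals, evecs = np.linalg.eigh(sym)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, -1.0, 1.0)

    # rotate the (possibly multiple) unit eigenspace so the first basis
    # vector is the global stationary direction
    unit = evals >= 1 - 1e-10
    if unit.sum() > 1:
        k = int(unit.sum())
        basis = evecs[:, :k]
        target = np.sqrt(d_a)
        target /= np.linalg.norm(target)
        coef = basis.T @ target
        coef /= np.linalg.norm(coef)
        q, _ = np.linalg.qr(
            np.column_stack([coef, np.eye(k)[:, : k - 1]])
        )
        # ensure the first rotated vector points along +target
        if q[:, 0] @ coef < 0:
            q[:, 0] *= -1
        evecs[:, :k] = basis @ q

    psi = evecs * inv_sqrt[:, None]
    anchor = psi[:, 0]
    anchor = np.where(np.abs(anchor) < 1e-300, 1e-300, anchor)
    psi = psi / anchor[:, None]

    n_keep = min(n_components, p - 1)
    lam = evals[1 : n_keep + 1]
    scale = lam / np.clip(1 - lam, 1e-9, None)
    comps = psi[:, 1 : n_keep + 1] * scale[None, :]

    for j in range(comps.shape[1]):
        col = comps[:, j]
        if orient_to is not None and j == 0:
            ref = np.asarray(orient_to, dtype=float)
            flip = np.corrcoef(col, ref)[0, 1] < 0 if col.std() > 0 else False
        else:
            flip = col[np.argmax(np.abs(col))] < 0
        if flip:
            comps[:, j] = -col
    return GradientSet(components=comps, eigenvalues=lam)


def align_and_rescale(
    individual: GradientSet, reference: GradientSet
) -> GradientSet:
    """Orthogonal Procrustes alignment to a reference, then rescale gradient 1.

    The individual component matrix is rotated (no scaling) onto the
    reference; the first aligned component is min-max rescaled to [0, 1].
    """
    x = individual.components
    ref = reference.components
    if x.shape != ref.shape:
        raise ValueError("component matrices must have matching shapes")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        warnings.warn("rank-deficient component matrix", RuntimeWarning)
    rot, _ = orthogonal_procrustes(x, ref)
    aligned = x @ rot
    g1 = aligned[:, 0]
    rng_ = g1.max() - g1.min()
    aligned = aligned.copy()
    aligned[:, 0] = (g1 - g1.min()) / (rng_ if rng_ > 0 else 1.0)
    return GradientSet(
        components=aligned,
        eigenvalues=individual.eigenvalues.copy(),
        aligned_to="reference",
        rescaled=True,
    )


def gradient_pipeline(
    profiles,
    keep_fraction: float = 0.10,
    n_components: int = 10,
    orient_to: np.ndarray | None = None,
) -> tuple[GradientSet, np.ndarray, MPCMatrix]:
    """Group-level MPC -> sparsify -> affinity -> embedding, plus per-subject
    aligned first gradients.

    Returns ``(group_gradients, gradient1_matrix, group_mpc_raw)`` where
    ``gradient1_matrix`` is subjects x parcels, each row a per-subject first
    gradient aligned to the group reference and rescaled to [0, 1].
    """
    per_sub = subject_mpc(profiles)
    group = group_mpc(per_sub)
    if orient_to is None:
        orient_to = profiles.values.mean(axis=(0, 2))
    grp_sparse = log_threshold_sparsify(group, keep_fraction)
    grp_aff = normalized_angle_affinity(grp_sparse)
    grp_grad = diffusion_embedding(grp_aff, n_components, orient_to=orient_to)
    g1 = np.empty((profiles.n_subjects, profiles.n_parcels))
    for s, m in enumerate(per_sub):
        aff = normalized_angle_affinity(log_threshold_sparsify(
            MPCMatrix(values=m, n_subjects=1), keep_fraction))
        gs = diffusion_embedding(aff, n_components, orient_to=orient_to)
        g1[s] = align_and_rescale(gs, grp_grad).components[:, 0]
    return grp_grad, g1, group
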