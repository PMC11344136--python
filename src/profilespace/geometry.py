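"""Spherical surface models and parcellations.

Each hemisphere is represented as its own full unit sphere (the convention of
surface-based MRI registration targets), triangulated by the convex hull of a
quasi-uniform vertex lattice.  Parcels are spherical Voronoi cells around
farthest-point-sampled centroids, which keeps them spatially contiguous on the
face graph.  The same machinery also produces a rectangular "unfolded
hippocampus" grid with subfield bands for analyses that operate on a flat
topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import ConvexHull

from .errors import MissingDataError

HIPPOCAMPAL_SUBFIELDS = ("Sub", "CA1", "CA2", "CA3", "CA4")


@dataclass
class SphereGeometry:
    """A parcellated spherical (or grid) surface.

    Attributes
    ----------
    vertex_coords : (V, 3) float array
        Unit-norm coordinates (one full sphere per hemisphere).
    faces : (F, 3) int array
        Triangle vertex indices.
    parcel_labels : (V,) int array
        0-based parcel id per vertex, contiguous ``0..P-1``.
    parcel_centroids : (P, 3) float array
        Unit-normalized mean of member-vertex coordinates.
    parcel_hemispheres : (P,) array of {"L", "R"}
    vertex_hemispheres : (V,) array of {"L", "R"}
    """

    vertex_coords: np.ndarray
    faces: np.ndarray
    parcel_labels: np.ndarray
    parcel_centroids: np.ndarray
    parcel_hemispheres: np.ndarray
    vertex_hemispheres: np.ndarray
    is_sphere: bool = True
    _adjacency: sparse.csr_matrix | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_vertices(self) -> int:
        return int(self.vertex_coords.shape[0])

    @property
    def n_parcels(self) -> int:
        return int(self.parcel_centroids.shape[0])

    def vertex_adjacency(self) -> sparse.csr_matrix:
        """Symmetric 0/1 vertex adjacency from the face graph (cached)."""
        if self._adjacency is None:
            f = self.faces
            i = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
            j = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
            v = self.n_vertices
            a = sparse.coo_matrix(
                (np.ones(i.size), (i, j)), shape=(v, v)
            ).tocsr()
            a = ((a + a.T) > 0).astype(float)
            a.setdiag(0)
            a.eliminate_zeros()
            self._adjacency = a.tocsr()
        return self._adjacency

    def parcel_membership(self) -> sparse.csr_matrix:
        """(P, V) row-stochastic matrix averaging vertices into parcels."""
        p = self.n_parcels
        counts = np.bincount(self.parcel_labels, minlength=p).astype(float)
        if np.any(counts == 0):
            empty = np.flatnonzero(counts == 0)
            raise MissingDataError(f"parcels with no vertices: {empty.tolist()}")
        data = 1.0 / counts[self.parcel_labels]
        return sparse.csr_matrix(
            (data, (self.parcel_labels, np.arange(self.n_vertices))),
            shape=(p, self.n_vertices),
        )

    def parcel_adjacency(self) -> sparse.csr_matrix:
        """Symmetric 0/1 parcel adjacency (parcels sharing a mesh edge)."""
        a = self.vertex_adjacency().tocoo()
        pi = self.parcel_labels[a.row]
        pj = self.parcel_labels[a.col]
        keep = pi != pj
        p = self.n_parcels
        m = sparse.coo_matrix(
            (np.ones(keep.sum()), (pi[keep], pj[keep])), shape=(p, p)
        ).tocsr()
        return (m + m.T > 0).astype(float)


def _fibonacci_sphere(n: int, rng: np.random.Generator, jitter: float) -> np.ndarray:
    """Quasi-uniform unit-sphere lattice with seeded jitter."""
    k = np.arange(n)
    golden = (1 + 5**0.5) / 2
    z = 1 - (2 * k + 1) / n
    theta = 2 * np.pi * k / golden
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    spacing = np.sqrt(4 * np.pi / n)
    pts = pts + rng.normal(scale=jitter * spacing, size=pts.shape)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def _farthest_point_sample(coords: np.ndarray, k: int, start: int) -> np.ndarray:
    """Indices of k quasi-uniformly spread points (greedy farthest-point)."""
    chosen = [start]
    d = np.linalg.norm(coords - coords[start], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(coords - coords[nxt], axis=1))
    return np.asarray(chosen)


def make_sphere_parcellation(
    n_vertices: int,
    n_parcels: int,
    hemispheres: tuple[str, ...] = ("L", "R"),
    seed: int = 0,
    jitter: float = 0.15,
) -> SphereGeometry:
    """Build a two-hemisphere spherical surface with contiguous parcels.

    Vertices are split evenly across hemispheres; each hemisphere is a full
    unit sphere.  ``n_parcels`` is divided proportionally to vertex counts,
    and each vertex is assigned to the nearest of the seeded parcel centers,
    yielding spherical Voronoi parcels.
    """
    if n_parcels < 1 or n_vertices < n_parcels:
        raise ValueError(
            f"need n_vertices >= n_parcels >= 1, got {n_vertices}, {n_parcels}"
        )
    if not hemispheres or any(h not in ("L", "R") for h in hemispheres):
        raise ValueError(f"hemispheres must be drawn from 'L','R': {hemispheres}")
    rng = np.random.default_rng(seed)
    n_h = len(hemispheres)

    # vertex counts per hemisphere (even split, remainder to the first)
    base = n_vertices // n_h
    v_counts = [base + (1 if i < n_vertices % n_h else 0) for i in range(n_h)]
    # parcel counts proportional to vertex share, at least 1 each when P >= n_h
    if n_parcels >= n_h:
        p_counts = [max(1, round(n_parcels * c / n_vertices)) for c in v_counts]
        while sum(p_counts) > n_parcels:
            p_counts[int(np.argmax(p_counts))] -= 1
        while sum(p_counts) < n_parcels:
            p_counts[int(np.argmin(p_counts))] += 1
    else:  # single parcel spanning everything (degenerate but legal)
        p_counts = [n_parcels] + [0] * (n_h - 1)

    coords, faces, labels, vert_hemi = [], [], [], []
    centroids, parcel_hemi = [], []
    v_off, p_off = 0, 0
    for hemi, vc, pc in zip(hemispheres, v_counts, p_counts):
        pts = _fibonacci_sphere(vc, rng, jitter)
        hull = ConvexHull(pts)
        coords.append(pts)
        faces.append(hull.simplices + v_off)
        vert_hemi.extend([hemi] * vc)
        if pc > 0:
            seeds = _farthest_point_sample(pts, pc, start=int(rng.integers(vc)))
            d = np.linalg.norm(pts[:, None, :] - pts[seeds][None, :, :], axis=2)
            lab = np.argmin(d, axis=1)
            labels.append(lab + p_off)
            for k in range(pc):
                c = pts[lab == k].mean(axis=0)
                nrm = np.linalg.norm(c)
                centroids.append(c / nrm if nrm > 1e-12 else np.array([0.0, 0.0, 1.0]))
                parcel_hemi.append(hemi)
            p_off += pc
        else:  # vertices of a parcel-less hemisphere join parcel 0
            labels.append(np.zeros(vc, dtype=int))
        v_off += vc

    geom = SphereGeometry(
        vertex_coords=np.vstack(coords),
        faces=np.vstack(faces),
        parcel_labels=np.concatenate(labels).astype(int),
        parcel_centroids=np.asarray(centroids),
        parcel_hemispheres=np.asarray(parcel_hemi, dtype=object),
        vertex_hemispheres=np.asarray(vert_hemi, dtype=object),
    )
    if n_parcels == 1:  # recompute the global centroid over both hemispheres
        c = geom.vertex_coords.mean(axis=0)
        nrm = np.linalg.norm(c)
        geom.parcel_centroids = (
            c / nrm if nrm > 1e-12 else np.array([0.0, 0.0, 1.0])
        )[None, :]
    return geom


def make_unfolded_grid(
    n_rows: int = 16,
    n_cols: int = 40,
    subfields: tuple[str, ...] = HIPPOCAMPAL_SUBFIELDS,
) -> SphereGeometry:
    """Rectangular "unfolded" grid with longitudinal subfield bands.

    Emulates a flattened hippocampal sheet: columns run along the proximal-
    distal axis and are divided into contiguous bands labelled by subfield.
    Spins are undefined on this topology (``is_sphere`` is False).
    """
    if n_rows < 2 or n_cols < len(subfields):
        raise ValueError("grid too small for the requested subfields")
    r, c = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    coords = np.column_stack(
        [c.ravel() / (n_cols - 1), r.ravel() / (n_rows - 1), np.zeros(r.size)]
    )
    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    tri_a = np.column_stack(
        [idx[:-1, :-1].ravel(), idx[:-1, 1:].ravel(), idx[1:, :-1].ravel()]
    )
    tri_b = np.column_stack(
        [idx[1:, 1:].ravel(), idx[1:, :-1].ravel(), idx[:-1, 1:].ravel()]
    )
    band = np.minimum((c * len(subfields)) // n_cols, len(subfields) - 1)
    labels = band.ravel().astype(int)
    centroids = np.vstack(
        [coords[labels == k].mean(axis=0) for k in range(len(subfields))]
    )
    return SphereGeometry(
        vertex_coords=coords,
        faces=np.vstack([tri_a, tri_b]),
        parcel_labels=labels,
        parcel_centroids=centroids,
        parcel_hemispheres=np.asarray(["L"] * len(subfields), dtype=object),
        vertex_hemispheres=np.asarray(["L"] * coords.shape[0], dtype=object),
        is_sphere=False,
    )


def smooth_vertex_fields(
    geom: SphereGeometry,
    n_fields: int,
    rounds: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(V, n_fields) spatially autocorrelated Gaussian fields.

    White noise is diffused by ``rounds`` rounds of neighbourhood averaging
    (vertex + its mesh neighbours), then re-standardized per field so the
    amplitude is independent of the amount of smoothing.
    """
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    x = rng.standard_normal((geom.n_vertices, n_fields))
    a = geom.vertex_adjacency().tolil()
    a.setdiag(1.0)
    a = a.tocsr()
    a = sparse.diags(1.0 / np.asarray(a.sum(axis=1)).ravel()) @ a
    for _ in range(rounds):
        x = a @ x
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    return x


def smooth_parcel_fields(
    geom: SphereGeometry,
    n_fields: int,
    rounds: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(P, n_fields) smooth fields aggregated to parcel level, standardized."""
    f = geom.parcel_membership() @ smooth_vertex_fields(geom, n_fields, rounds, rng)
    return (f - f.mean(axis=0)) / f.std(axis=0)


def morans_i(values: np.ndarray, adjacency: sparse.spmatrix) -> float:
    """Moran's I spatial autocorrelation on a 0/1 adjacency."""
    z = np.asarray(values, float) - np.mean(values)
    w = adjacency.tocoo()
    num = float(np.sum(w.data * z[w.row] * z[w.col]))
    den = float(np.sum(z**2))
    return (len(z) / w.data.sum()) * num / den
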