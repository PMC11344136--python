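"""Spatial-null inference: spin permutations and map-map enrichment tests.

Brain maps are spatially autocorrelated, so parametric map-map correlation
p-values are badly anticonservative.  The spin test builds a null by rigidly
rotating one map's spherical representation: each permutation samples a
uniform (Haar) random 3D rotation, applies it to the left-hemisphere parcel
centroids and its x-mirrored twin to the right hemisphere, and re-labels
parcels by an optimal within-hemisphere assignment between rotated and
original centroids.  The assignment (Hungarian algorithm on centroid
distances) is a true permutation, so the multiset of map values is preserved
exactly, and the identity rotation maps to the identity permutation.

Derived tests: correlation of a phenotype map with single reference maps
(genes, cortical types, vascular densities), a multivariate gene-set F-test,
and a transcriptomic baseline principal component for specificity checks.
Permutation p-values use the add-one rule p = (1 + #{null >= obs}) /
(1 + n_perm), bounded below by 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .contrasts import bh_fdr
from .errors import DegenerateInputError
from .geometry import SphereGeometry

_XFLIP = np.diag([-1.0, 1.0, 1.0])


@dataclass
class SpinNull:
    """Spin permutations and (optionally) a realized null distribution."""

    permutations: np.ndarray  # (n_perm, P) int: spun_map = map[permutations[k]]
    n_parcels: int
    null_stats: np.ndarray | None = None
    p_value: float | None = None
    sidedness: str | None = None

    @property
    def n_perm(self) -> int:
        return self.permutations.shape[0]


def generate_spins(
    geometry: SphereGeometry, n_perm: int, seed: int = 0
) -> SpinNull:
    """Sample ``n_perm`` spin permutations of the parcel set.

    One Haar-uniform rotation per permutation is applied to the left
    hemisphere and its x-mirrored version to the right, and rotated centroids
    are matched to original centroids within hemisphere by minimum-cost
    assignment, yielding a bijective relabelling.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not geometry.is_sphere:
        raise ValueError("spin permutations require a spherical geometry")
    rng = np.random.default_rng(seed)
    cents = geometry.parcel_centroids
    hemis = geometry.parcel_hemispheres
    perms = np.empty((n_perm, geometry.n_parcels), dtype=int)
    hemi_idx = {h: np.flatnonzero(hemis == h) for h in ("L", "R")}
    for k in range(n_perm):
        rot = stats.special_ortho_group.rvs(3, random_state=rng)
        for h, idx in hemi_idx.items():
            if idx.size == 0:
                continue
            r = rot if h == "L" else _XFLIP @ rot @ _XFLIP
            rotated = cents[idx] @ r.T
            # cost = distance from rotated position i to original position j
            cost = np.linalg.norm(
                rotated[:, None, :] - cents[idx][None, :, :], axis=2
            )
            rows, cols = linear_sum_assignment(cost)
            # parcel idx[i] moved to the site of parcel idx[cols[i]]:
            # the spun map takes, at site idx[cols[i]], the value of idx[i]
            perm = np.empty(idx.size, dtype=int)
            perm[cols] = rows
            perms[k, idx] = idx[perm]
    return SpinNull(permutations=perms, n_parcels=geometry.n_parcels)


def _check_map(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.std() == 0:
        raise DegenerateInputError(f"{name} is constant; correlation undefined")
    return m


def _corr_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``a`` (n x P) against vector ``b`` (P,)."""
    az = (a - a.mean(axis=1, keepdims=True))
    az /= np.linalg.norm(az, axis=1, keepdims=True)
    bz = b - b.mean()
    bz /= np.linalg.norm(bz)
    return az @ bz


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=-1)


def _perm_p(null: np.ndarray, obs: float, sidedness: str) -> float:
    """Add-one permutation p-value."""
    n = null.size
    if sidedness == "two":
        count = int(np.sum(np.abs(null) >= abs(obs)))
    elif sidedness == "one":
        # one-sided in the direction of the observed statistic
        count = (
            int(np.sum(null >= obs)) if obs >= 0 else int(np.sum(null <= obs))
        )
    else:
        raise ValueError("sidedness must be 'one' or 'two'")
    return (1 + count) / (1 + n)


def spin_correlation_test(
    map_a: np.ndarray,
    map_b: np.ndarray,
    spins: SpinNull,
    method: str = "pearson",
    sidedness: str = "one",
) -> tuple[float, float]:
    """Correlation between two parcel maps with a spin-permutation p-value.

    ``map_a`` is the map being spun (conventionally the phenotype map).
    Returns ``(r, p)``.
    """
    a = _check_map(map_a, "map_a")
    b = _check_map(map_b, "map_b")
    if method == "spearman":
        a, b = _rank(a), _rank(b)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    obs = float(_corr_matrix(a[None, :], b)[0])
    null = _corr_matrix(a[spins.permutations], b)
    return obs, _perm_p(null, obs, sidedness)


def gene_set_ftest(
    phenotype_map: np.ndarray,
    gene_panel: pd.DataFrame | np.ndarray,
    spins: SpinNull,
) -> tuple[float, float]:
    """Overall F of the phenotype regressed on the full gene panel, spin p.

    The phenotype map is spun; the gene design is fixed.  p is the add-one
    proportion of permuted F statistics at least as large as the observed.
    """
    y = _check_map(phenotype_map, "phenotype_map")
    x = np.asarray(gene_panel, dtype=float)
    p, g = x.shape
    if p <= g + 1:
        raise ValueError("need more parcels than genes + 1")
    xc = x - x.mean(axis=0)
    q, r = np.linalg.qr(xc)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * np.abs(r[0, 0])))
    if rank < g:
        raise ValueError("gene panel is collinear")

    def f_of(yv: np.ndarray) -> np.ndarray:
        yc = yv - yv.mean(axis=-1, keepdims=True)
        ss_tot = (yc**2).sum(axis=-1)
        fitted = yc @ q  # projections onto the gene column space
        ss_mod = (fitted**2).sum(axis=-1)
        ss_res = ss_tot - ss_mod
        return (ss_mod / g) / (ss_res / (p - g - 1))

    f_obs = float(f_of(y))
    f_null = f_of(y[spins.permutations])
    p_val = (1 + int(np.sum(f_null >= f_obs))) / (1 + spins.n_perm)
    return f_obs, p_val


@dataclass
class GenePanelResult:
    per_gene: pd.DataFrame  # columns: measure, gene, rho, p_spin, q_sig
    f_stat: float | None = None
    f_p: float | None = None
    baseline: pd.DataFrame | None = None  # measure, rho, p_spin


def per_gene_association(
    phenotype_maps: dict[str, np.ndarray],
    gene_panel: pd.DataFrame,
    spins: SpinNull,
    fdr_q: float = 0.05,
    sidedness: str = "one",
) -> GenePanelResult:
    """Spearman association of each (measure, gene) pair with spin p-values.

    BH-FDR is applied over the pooled gene x measure family.  Gene maps with
    missing parcels are handled by listwise exclusion of those parcels for
    that gene (with re-spun index filtering).
    """
    rows = []
    for mname, pmap in phenotype_maps.items():
        pmap = _check_map(pmap, mname)
        ranks_a = _rank(pmap)
        spun = ranks_a[spins.permutations]
        for gene in gene_panel.columns:
            gmap = gene_panel[gene].to_numpy(dtype=float)
            ok = np.isfinite(gmap)
            if not ok.all():
                rb = _rank(gmap[ok])
                obs = float(stats.spearmanr(pmap[ok], gmap[ok]).statistic)
                null = _corr_matrix(_rank(pmap[spins.permutations[:, ok]]), rb)
            else:
                rb = _rank(gmap)
                obs = float(_corr_matrix(ranks_a[None, :], rb)[0])
                null = _corr_matrix(spun, rb)
            rows.append(
                {
                    "measure": mname,
                    "gene": gene,
                    "rho": obs,
                    "p_spin": _perm_p(null, obs, sidedness),
                }
            )
    table = pd.DataFrame(rows)
    table["q_sig"] = bh_fdr(table["p_spin"].to_numpy(), q=fdr_q)
    return GenePanelResult(per_gene=table)


def baseline_component(full_gene_panel: pd.DataFrame) -> np.ndarray:
    """First principal component of the column-standardized gene panel.

    Zero-variance genes are dropped with a warning.  The sign is oriented so
    the component correlates nonnegatively with mean expression across genes.
    """
    x = np.asarray(full_gene_panel, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 genes")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        import warnings

        warnings.warn(
            f"dropping zero-variance genes: "
            f"{[full_gene_panel.columns[i] for i in np.flatnonzero(sd == 0)]}",
            RuntimeWarning,
        )
        x = x[:, sd > 0]
        sd = sd[sd > 0]
    z = (x - x.mean(axis=0)) / sd
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    pc1 = u[:, 0] * s[0]
    mean_expr = np.asarray(full_gene_panel, dtype=float).mean(axis=1)
    if np.corrcoef(pc1, mean_expr)[0, 1] < 0:
        pc1 = -pc1
    return pc1


def contextual_decoding(
    phenotype_maps: dict[str, np.ndarray],
    cortical_types: np.ndarray,
    artery_map: np.ndarray,
    vein_map: np.ndarray,
    spins: SpinNull,
    fdr_q: float = 0.05,
    sidedness: str = "one",
) -> pd.DataFrame:
    """Spearman decoding of phenotype maps against cytoarchitectural and
    vascular references, with spin p-values and FDR over the whole family.

    ``cortical_types`` is the ordinal 1..6 laminar-differentiation hierarchy
    (agranular -> koniocortex); rank correlation makes the result invariant
    to any monotone relabelling of the levels.
    """
    types = np.asarray(cortical_types)
    if not np.all(np.isin(types, np.arange(1, 7))):
        raise ValueError("cortical types must take values in 1..6")
    refs = {
        "cortical_types": types.astype(float),
        "artery": np.asarray(artery_map, dtype=float),
        "vein": np.asarray(vein_map, dtype=float),
    }
    rows = []
    for mname, pmap in phenotype_maps.items():
        for rname, rmap in refs.items():
            rho, p = spin_correlation_test(
                pmap, rmap, spins, method="spearman", sidedness=sidedness
            )
            rows.append({"map": mname, "reference": rname, "rho": rho, "p_spin": p})
    table = pd.DataFrame(rows)
    table["q_sig"] = bh_fdr(table["p_spin"].to_numpy(), q=fdr_q)
    return table
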