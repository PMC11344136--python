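"""Self-validation suite: oracle agreement, statistical calibration, and
ground-truth recovery on synthetic studies.

Each function runs one focused experiment end to end -- generating its own
inputs, running the package's estimators, and measuring the result against
an independent oracle or the planted truth -- and returns a small dict of
scalar outcomes plus the problem size used.  The pytest acceptance suite and
``scripts/acceptance.py`` both call these functions, so the numbers a report
shows are always recomputed from scratch.

Problem sizes are chosen so the whole suite runs in a few minutes on one
CPU: oracle checks run at small algebraic sizes, calibration suites at the
smallest scale where binomial noise is well inside the tolerance, and the
spin calibration at the 400-parcel resolution of a standard whole-cortex
parcellation, where parcel-level spins are well behaved.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import integrate, stats

from . import contrasts as ct
from . import mpc as mpcmod
from . import spatial as sp
from . import synth
from .geometry import make_sphere_parcellation, smooth_parcel_fields
from .pipeline import RunConfig, run_pipeline
from .profiles import equivolumetric_fraction, profile_measures
from .spatial import _corr_matrix


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence((seed, k)).generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# 1. equivolumetric depth model
# ---------------------------------------------------------------------------

def check_equivolume(seed: int = 0) -> dict:
    """Boundary values, strict monotonicity, and frustum volume conservation
    of the equivolumetric depth rule (numeric integration oracle)."""
    rng = np.random.default_rng(_sub_seed(seed, 1))
    alphas = np.linspace(0, 1, 101)
    boundary_err = 0.0
    mono_ok = True
    vol_err = 0.0
    for _ in range(20):
        a_out = rng.uniform(0.5, 4.0)
        a_in = rng.uniform(0.0, 3.0)
        if abs(a_out - a_in) < 1e-3:
            a_in += 0.1
        rho = equivolumetric_fraction(a_out, a_in, alphas)
        boundary_err = max(boundary_err, abs(rho[0]), abs(rho[-1] - 1))
        mono_ok = mono_ok and bool(np.all(np.diff(rho) > 0))
        area = lambda r: a_in + r * (a_out - a_in)
        total, _ = integrate.quad(area, 0, 1)
        for alpha in np.linspace(0.1, 0.9, 5):
            r_a = equivolumetric_fraction(a_out, a_in, alpha)
            vol, _ = integrate.quad(area, 0, r_a)
            vol_err = max(vol_err, abs(vol - alpha * total))
    return {
        "boundary_error": boundary_err,
        "monotone": float(mono_ok),
        "volume_conservation_max_err": vol_err,
        "n": 20 * len(alphas),
    }


# ---------------------------------------------------------------------------
# 2. MPC partial correlation vs residualization oracle
# ---------------------------------------------------------------------------

def check_mpc_oracle(seed: int = 0, n_sets: int = 200) -> dict:
    """Partial-correlation MPC equals correlation of profiles residualized
    on the cortex-average profile."""
    rng = np.random.default_rng(_sub_seed(seed, 2))
    max_err = 0.0
    for _ in range(n_sets):
        x = rng.normal(size=(8, 12))
        got = mpcmod.partial_profile_correlation(x)
        cortex = x.mean(axis=0)
        design = np.column_stack([np.ones_like(cortex), cortex])
        beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
        resid = x.T - design @ beta
        want = np.corrcoef(resid.T)
        np.fill_diagonal(want, 0.0)
        max_err = max(max_err, float(np.max(np.abs(got - want))))
    return {"max_abs_diff": max_err, "n": n_sets}


# ---------------------------------------------------------------------------
# 3. diffusion embedding vs dense eigensolver; two-block separation
# ---------------------------------------------------------------------------

def check_embedding(seed: int = 0, n_random: int = 10, n_blocks: int = 100) -> dict:
    """Embedding agreement with an independent dense eigendecomposition of
    the normalized Markov operator, and exact sign separation of planted
    two-block affinities by the first gradient."""
    rng = np.random.default_rng(_sub_seed(seed, 3))
    max_err = 0.0
    for _ in range(n_random):
        a = rng.uniform(0.1, 1.0, (50, 50))
        w = (a + a.T) / 2
        np.fill_diagonal(w, 1.0)
        gs = mpcmod.diffusion_embedding(w, n_components=5)
        d = w.sum(axis=1)
        w_a = w / np.outer(d**0.5, d**0.5)
        d_a = w_a.sum(axis=1)
        markov = w_a / d_a[:, None]
        evals, evecs = np.linalg.eig(markov)
        order = np.argsort(-evals.real)
        evals, evecs = evals.real[order], evecs.real[:, order]
        sym = np.sqrt(d_a)[:, None] * evecs
        sym /= np.linalg.norm(sym, axis=0, keepdims=True)
        psi = sym / np.sqrt(d_a)[:, None]
        psi = psi / psi[:, [0]]  # normalize by the trivial eigenvector
        for j in range(5):
            lam = evals[1 + j]
            want = psi[:, 1 + j] * lam / (1 - lam)
            got = gs.components[:, j]
            err = min(np.max(np.abs(got - want)), np.max(np.abs(got + want)))
            max_err = max(max_err, float(err))
    separated = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_blocks):
            w = np.zeros((40, 40))
            a = rng.uniform(0.5, 1.0, (20, 20))
            w[:20, :20] = (a + a.T) / 2
            b = rng.uniform(0.5, 1.0, (20, 20))
            w[20:, 20:] = (b + b.T) / 2
            np.fill_diagonal(w, 1.0)
            g1 = mpcmod.diffusion_embedding(w, 3).components[:, 0]
            ok = (np.all(g1[:20] > 0) and np.all(g1[20:] < 0)) or (
                np.all(g1[:20] < 0) and np.all(g1[20:] > 0)
            )
            separated += ok
    return {
        "max_abs_diff": max_err,
        "block_separation_runs": separated,
        "n": n_blocks,
    }


# ---------------------------------------------------------------------------
# 4. GLM / FDR statistical correctness
# ---------------------------------------------------------------------------

def check_glm_stats(seed: int = 0, n_fdr: int = 1000, n_null: int = 2000) -> dict:
    """BH-FDR vs brute-force step-up; GLM t vs the Frisch-Waugh
    residualization oracle; type-I error of the parcel GLM under the null."""
    rng = np.random.default_rng(_sub_seed(seed, 4))

    fdr_mismatches = 0
    for _ in range(n_fdr):
        m = int(rng.integers(1, 60))
        p = rng.uniform(size=m)
        got = ct.bh_fdr(p, q=0.05)
        order = np.argsort(p, kind="stable")
        sp_ = p[order]
        below = np.flatnonzero(sp_ <= (np.arange(1, m + 1) / m) * 0.05)
        want = np.zeros(m, dtype=bool)
        if below.size:
            want[order[: below.max() + 1]] = True
        fdr_mismatches += int(not np.array_equal(got, want))

    cohort = synth.simulate_cohort(60, 60, seed=_sub_seed(seed, 5))
    y = rng.normal(size=(120, 8))
    res = ct.fit_parcel_glm(y, cohort)
    x, cols = ct.build_design(cohort)
    j = cols.index("sex")
    others = np.delete(np.arange(x.shape[1]), j)
    q, _ = np.linalg.qr(x[:, others])
    sex_r = x[:, j] - q @ (q.T @ x[:, j])
    y_r = y - q @ (q.T @ y)
    beta = sex_r @ y_r / (sex_r @ sex_r)
    resid = y_r - np.outer(sex_r, beta)
    dof = x.shape[0] - x.shape[1]
    se = np.sqrt((resid**2).sum(axis=0) / dof / (sex_r @ sex_r))
    t_oracle = beta / se
    glm_err = float(np.max(np.abs(res.t - t_oracle)))

    cohort_n = synth.simulate_cohort(50, 50, seed=_sub_seed(seed, 6))
    rej = 0
    tot = 0
    for _ in range(n_null):
        y0 = rng.normal(size=(100, 20))
        r0 = ct.fit_parcel_glm(y0, cohort_n)
        rej += int((r0.p < 0.05).sum())
        tot += 20
    return {
        "fdr_mismatches": fdr_mismatches,
        "glm_t_max_abs_diff": glm_err,
        "type_one_error": rej / tot,
        "n": n_null,
    }


# ---------------------------------------------------------------------------
# 5. spin-test calibration
# ---------------------------------------------------------------------------

def check_spin_calibration(
    seed: int = 0,
    n_parcels: int = 400,
    n_vertices: int = 8000,
    n_perm: int = 999,
    n_sim: int = 1000,
    smoothness: int = 20,
) -> dict:
    """Empirical size of the two-sided spin correlation test at nominal 0.05
    on pairs of independent smooth null maps."""
    geom = make_sphere_parcellation(n_vertices, n_parcels,
                                    seed=_sub_seed(seed, 7))
    spins = sp.generate_spins(geom, n_perm, seed=_sub_seed(seed, 8))
    rng = np.random.default_rng(_sub_seed(seed, 9))
    fa = smooth_parcel_fields(geom, n_sim, smoothness, rng)
    fb = smooth_parcel_fields(geom, n_sim, smoothness, rng)
    rej = 0
    for i in range(n_sim):
        a, b = fa[:, i], fb[:, i]
        obs = float(np.corrcoef(a, b)[0, 1])
        null = _corr_matrix(a[spins.permutations], b)
        p = (1 + int(np.sum(np.abs(null) >= abs(obs)))) / (1 + n_perm)
        rej += int(p < 0.05)
    return {"rejection_rate": rej / n_sim, "n": n_sim}


# ---------------------------------------------------------------------------
# 6. ground-truth recovery
# ---------------------------------------------------------------------------

def check_dmap_recovery(seed: int = 0, n_rep: int = 5) -> dict:
    """Correlation between a planted sex-effect d-map (d 0.2-0.5 on 10% of
    parcels) and the GLM-estimated d-map at n=400/400."""
    p, v = 200, 4000
    geom = make_sphere_parcellation(v, p, seed=_sub_seed(seed, 10))
    cors = []
    for r in range(n_rep):
        rng = np.random.default_rng(_sub_seed(seed, 11 + r))
        d = np.zeros(p)
        idx = rng.choice(p, p // 10, replace=False)
        d[idx] = rng.uniform(0.2, 0.5, p // 10)
        cohort = synth.simulate_cohort(400, 400, oc_fraction=0.3,
                                       missing_cycle_fraction=0.2,
                                       seed=_sub_seed(seed, 31 + r))
        eff = synth.GroundTruthEffects(d, np.zeros(p), np.zeros(p))
        prof = synth.simulate_profiles(geom, cohort, eff,
                                       seed=_sub_seed(seed, 51 + r))
        mean_t, _, _ = profile_measures(prof)
        res = ct.fit_parcel_glm(mean_t.values, cohort)
        cors.append(float(np.corrcoef(d, res.cohen_d)[0, 1]))
    return {"mean_correlation": float(np.mean(cors)),
            "min_correlation": float(np.min(cors)), "n": n_rep}


def check_hormone_ordering(seed: int = 0, n_seeds: int = 100) -> dict:
    """With a monotone planted cycle-bin modulation, the four subgroup-mean
    effect sizes recover the injected order."""
    p, v = 60, 1200
    geom = make_sphere_parcellation(v, p, seed=_sub_seed(seed, 12))
    bins = synth.CYCLE_BINS
    ok = 0
    for s in range(n_seeds):
        cohort = synth.simulate_cohort(1000, 400, oc_fraction=0.0,
                                       missing_cycle_fraction=0.0,
                                       seed=_sub_seed(seed, 100 + s))
        eff = synth.GroundTruthEffects(
            np.full(p, 0.2), np.zeros(p), np.full(p, 1.0),
            h_bins={"oc": 0.0, "bins": (0.0, 1.0, 2.0, 3.0)},
        )
        prof = synth.simulate_profiles(geom, cohort, eff,
                                       seed=_sub_seed(seed, 300 + s))
        mean_t, _, _ = profile_measures(prof)
        day = cohort["cycle_day"].to_numpy()
        male = (cohort["sex"] == "male").to_numpy()
        means = []
        for lo, hi in bins:
            sel = male | ((day >= lo) & (day <= hi))
            sub = cohort[sel]
            res = ct.fit_parcel_glm(
                mean_t.values.loc[sub["subject_id"]], sub
            )
            means.append(float(res.cohen_d.mean()))
        ok += int(np.all(np.diff(means) > 0))
    return {"ordered_runs": ok, "n": n_seeds}


def check_oc_specific_recovery(seed: int = 0) -> dict:
    """A planted OC-only effect shows up in the OC-vs-NC within-female
    contrast and not in the NC-vs-NC contrasts."""
    p, v = 80, 1500
    geom = make_sphere_parcellation(v, p, seed=_sub_seed(seed, 13))
    rng = np.random.default_rng(_sub_seed(seed, 14))
    target = rng.choice(p, 8, replace=False)
    d = np.zeros(p)
    d[target] = 0.3
    m_p = np.zeros(p)
    m_p[target] = 1.0
    # effect multiplier 1 + m*h: OC keep the effect (h=0), NC cancel it (h=-1)
    eff = synth.GroundTruthEffects(
        d, np.zeros(p), m_p,
        h_bins={"oc": 0.0, "bins": (-1.0, -1.0, -1.0, -1.0)},
    )
    cohort = synth.simulate_cohort(600, 400, oc_fraction=0.4,
                                   missing_cycle_fraction=0.0,
                                   seed=_sub_seed(seed, 15))
    prof = synth.simulate_profiles(geom, cohort, eff, seed=_sub_seed(seed, 16))
    mean_t, _, _ = profile_measures(prof)
    groups = ct.assign_hormone_groups(cohort)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = ct.run_group_comparisons(mean_t.values, cohort, groups)
    oc_nc = res["OC_vs_NC"]
    nc_sig = int(res["low_vs_high_estrogen"].fdr_mask.sum()
                 + res["low_vs_high_progesterone"].fdr_mask.sum())
    return {
        "oc_recovered_fraction": float(oc_nc.fdr_mask[target].mean()),
        "oc_false_positives": int(oc_nc.fdr_mask[
            ~np.isin(np.arange(p), target)].sum()),
        "nc_vs_nc_significant": nc_sig,
        "n": 8,
    }


# ---------------------------------------------------------------------------
# 7. split-half reliability regimes
# ---------------------------------------------------------------------------

def check_split_half(seed: int = 0, n_splits: int = 200,
                     n_null_cohorts: int = 8) -> dict:
    """Split-half t-map reproducibility: near zero for pure noise, high for
    a strong planted effect (d up to 0.5) at n=500/500.

    For a single finite cohort the split-mean r converges to a small
    cohort-specific constant, because complementary halves share the
    cohort's realized noise contrast; its spread across cohorts scales with
    the inverse square root of the map's effective degrees of freedom.  The
    null regime therefore uses an i.i.d. pure-noise measure at 400 parcels
    averaged over several independent cohorts; the signal regime, whose
    expectation is far from the band edge, uses one generated cohort.
    """
    import pandas as pd

    from .profiles import parcel_columns

    p, v = 100, 2000
    geom = make_sphere_parcellation(v, p, seed=_sub_seed(seed, 17))
    p_null = 400
    null_means = []
    for c in range(n_null_cohorts):
        rng0 = np.random.default_rng(_sub_seed(seed, 450 + c))
        cohort0 = synth.simulate_cohort(500, 500, oc_fraction=0.3,
                                        missing_cycle_fraction=0.2,
                                        seed=_sub_seed(seed, 400 + c))
        y0 = pd.DataFrame(
            rng0.normal(size=(1000, p_null)),
            index=pd.Index(cohort0["subject_id"], name="subject_id"),
            columns=parcel_columns(p_null),
        )
        r0 = ct.split_half_reliability(
            y0, cohort0, n_perm=n_splits, seed=_sub_seed(seed, 500 + c))
        null_means.append(r0.mean)
    cohort = synth.simulate_cohort(500, 500, oc_fraction=0.3,
                                   missing_cycle_fraction=0.2,
                                   seed=_sub_seed(seed, 18))
    rng = np.random.default_rng(_sub_seed(seed, 21))
    d = rng.uniform(0.0, 0.5, p)
    eff1 = synth.GroundTruthEffects(d, np.zeros(p), np.zeros(p))
    prof1 = synth.simulate_profiles(geom, cohort, eff1,
                                    seed=_sub_seed(seed, 22))
    m1, _, _ = profile_measures(prof1)
    r1 = ct.split_half_reliability(m1.values, cohort, n_perm=n_splits,
                                   seed=_sub_seed(seed, 23))
    return {"null_mean_r": float(np.mean(null_means)),
            "signal_mean_r": r1.mean, "n": n_splits}


# ---------------------------------------------------------------------------
# 8. pipeline determinism
# ---------------------------------------------------------------------------

def check_determinism(seed: int = 0, out_root: str = "scratch") -> dict:
    """Two demo-pipeline runs with the same seed produce bit-identical
    output files."""
    import shutil
    import tempfile
    from pathlib import Path

    tmp = Path(tempfile.mkdtemp(prefix="psdet_", dir=None))
    try:
        hashes = []
        for tag in ("a", "b"):
            cfg = RunConfig.from_dict(dict(
                seed=_sub_seed(seed, 24),
                out_dir=str(tmp / tag),
                n_vertices=600, n_parcels=40,
                n_female=60, n_male=50,
                n_perm=50, n_splits=20, n_genes=8, n_coupled=2,
            ))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = run_pipeline(cfg)
            hashes.append({k.split("/")[-1]: v for k, v in rep.files.items()})
        identical = hashes[0] == hashes[1]
        return {"identical": float(identical), "n": len(hashes[0])}
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
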