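"""Spin permutations and spatial enrichment tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import profilespace as ps
from profilespace.errors import DegenerateInputError


@pytest.fixture(scope="module")
def spins(small_geom_mod):
    # seed chosen so none of the 99 rotations is small enough to collapse to
    # the identity permutation on this coarse parcellation (a near-identity
    # spin ties with the observed statistic and raises p by 1/(n_perm+1))
    return ps.generate_spins(small_geom_mod, 99, seed=2)


@pytest.fixture(scope="module")
def small_geom_mod():
    return ps.make_sphere_parcellation(1000, 60, seed=1)


class TestGenerateSpins:
    def test_permutations_are_bijections(self, spins):
        for k in range(0, 99, 10):
            assert np.array_equal(
                np.sort(spins.permutations[k]), np.arange(spins.n_parcels)
            )

    def test_hemisphere_contract(self, small_geom_mod, spins):
        hemi = small_geom_mod.parcel_hemispheres
        for k in range(0, 99, 7):
            assert np.all(hemi[spins.permutations[k]] == hemi)

    def test_value_conservation(self, spins, rng):
        m = rng.normal(size=spins.n_parcels)
        spun = m[spins.permutations[5]]
        assert np.array_equal(np.sort(spun), np.sort(m))

    def test_identity_rotation_identity_permutation(self, small_geom_mod,
                                                    monkeypatch):
        monkeypatch.setattr(
            stats.special_ortho_group, "rvs",
            lambda dim, random_state=None: np.eye(3),
        )
        s = ps.generate_spins(small_geom_mod, 1, seed=0)
        assert np.array_equal(s.permutations[0],
                              np.arange(small_geom_mod.n_parcels))

    def test_determinism_and_validation(self, small_geom_mod):
        a = ps.generate_spins(small_geom_mod, 5, seed=7)
        b = ps.generate_spins(small_geom_mod, 5, seed=7)
        assert np.array_equal(a.permutations, b.permutations)
        with pytest.raises(ValueError):
            ps.generate_spins(small_geom_mod, 0)


class TestSpinCorrelationTest:
    def test_self_correlation_minimal_p(self, small_geom_mod, spins):
        m = small_geom_mod.parcel_centroids[:, 2]
        r, p = ps.spin_correlation_test(m, m, spins)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_matches_direct_correlation_oracle(self, spins, rng):
        a, b = rng.normal(size=(2, spins.n_parcels))
        r, _ = ps.spin_correlation_test(a, b, spins, method="pearson")
        assert r == pytest.approx(stats.pearsonr(a, b).statistic, abs=1e-12)
        r_s, _ = ps.spin_correlation_test(a, b, spins, method="spearman")
        assert r_s == pytest.approx(stats.spearmanr(a, b).statistic, abs=1e-12)

    def test_sign_flip_antisymmetry(self, small_geom_mod, spins):
        m = small_geom_mod.parcel_centroids[:, 2]
        r_pos, p_pos = ps.spin_correlation_test(m, m, spins, sidedness="one")
        r_neg, p_neg = ps.spin_correlation_test(m, -m, spins, sidedness="one")
        assert r_neg == pytest.approx(-r_pos)
        # one-sided on the observed (negative) direction is again minimal;
        # two-sided of the perfect |r|=1 is minimal too
        _, p_two = ps.spin_correlation_test(m, -m, spins, sidedness="two")
        assert p_two == pytest.approx(1 / 100)

    def test_constant_map_rejected(self, spins):
        with pytest.raises(DegenerateInputError):
            ps.spin_correlation_test(np.ones(spins.n_parcels),
                                     np.arange(spins.n_parcels), spins)

    def test_p_bounded_below(self, spins, rng):
        for _ in range(5):
            a, b = rng.normal(size=(2, spins.n_parcels))
            _, p = ps.spin_correlation_test(a, b, spins)
            assert 1 / 100 <= p <= 1


class TestGeneSetFTest:
    def test_toy_closed_form_oracle(self, spins, rng):
        """6+ parcels, 2 genes: F matches the explicit sums-of-squares
        regression oracle."""
        p = spins.n_parcels
        x = rng.normal(size=(p, 2))
        y = rng.normal(size=p)
        f, _ = ps.gene_set_ftest(y, x, spins)
        # oracle: full OLS with intercept
        design = np.column_stack([np.ones(p), x])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        ss_res = (resid**2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        f_oracle = ((ss_tot - ss_res) / 2) / (ss_res / (p - 3))
        assert f == pytest.approx(f_oracle, abs=1e-8)

    def test_exact_linear_combination_minimal_p(self, spins, rng):
        x = rng.normal(size=(spins.n_parcels, 3))
        y = x @ np.array([1.0, -2.0, 0.5])
        f, p = ps.gene_set_ftest(y, x, spins)
        assert p == pytest.approx(1 / 100)

    def test_too_many_genes_rejected(self, spins, rng):
        x = rng.normal(size=(spins.n_parcels, spins.n_parcels))
        with pytest.raises(ValueError):
            ps.gene_set_ftest(rng.normal(size=spins.n_parcels), x, spins)


class TestPerGeneAssociation:
    def test_identical_gene_minimal_p(self, small_geom_mod, spins):
        m = small_geom_mod.parcel_centroids[:, 2].copy()
        panel = pd.DataFrame({"SAME": m, "OTHER": np.roll(m, 7)})
        out = ps.per_gene_association({"mean": m}, panel, spins)
        row = out.per_gene.set_index("gene").loc["SAME"]
        assert row["rho"] == pytest.approx(1.0)
        assert row["p_spin"] == pytest.approx(1 / 100)

    def test_fdr_flags_match_oracle(self, spins, rng):
        panel = pd.DataFrame(
            rng.normal(size=(spins.n_parcels, 8)),
            columns=[f"G{i}" for i in range(8)],
        )
        maps = {"a": rng.normal(size=spins.n_parcels),
                "b": rng.normal(size=spins.n_parcels)}
        out = ps.per_gene_association(maps, panel, spins)
        from test_contrasts import brute_force_bh

        assert np.array_equal(
            out.per_gene["q_sig"].to_numpy(),
            brute_force_bh(out.per_gene["p_spin"].to_numpy(), 0.05),
        )

    def test_missing_parcels_listwise(self, spins, rng):
        g = rng.normal(size=spins.n_parcels)
        g[3] = np.nan
        panel = pd.DataFrame({"G0": g})
        m = rng.normal(size=spins.n_parcels)
        out = ps.per_gene_association({"m": m}, panel, spins)
        ok = np.isfinite(g)
        want = stats.spearmanr(m[ok], g[ok]).statistic
        assert out.per_gene["rho"].iloc[0] == pytest.approx(want, abs=1e-12)


class TestBaselineComponent:
    def test_identical_genes_recover_map(self, rng):
        m = rng.normal(size=50)
        panel = pd.DataFrame({f"G{i}": m for i in range(4)})
        pc = ps.baseline_component(panel)
        assert abs(stats.spearmanr(pc, m).statistic) == pytest.approx(1.0)

    def test_aligns_with_dominant_direction(self, rng):
        """With two orthogonal structures of unequal variance the component
        follows the dominant one (dense eigendecomposition oracle)."""
        n = 200
        u = rng.normal(size=n)
        v = rng.normal(size=n)
        v -= u * (u @ v) / (u @ u)
        panel = pd.DataFrame(
            {**{f"A{i}": 3 * u + 0.1 * rng.normal(size=n) for i in range(5)},
             **{f"B{i}": v + 0.1 * rng.normal(size=n) for i in range(2)}}
        )
        pc = ps.baseline_component(panel)
        z = np.asarray(panel, float)
        z = (z - z.mean(0)) / z.std(0)
        evals, evecs = np.linalg.eigh(np.cov(z.T))
        pc_oracle = z @ evecs[:, -1]
        assert abs(np.corrcoef(pc, pc_oracle)[0, 1]) > 1 - 1e-10
        assert abs(np.corrcoef(pc, u)[0, 1]) > 0.95

    def test_sign_contract(self, rng):
        panel = pd.DataFrame(rng.normal(size=(40, 6)),
                             columns=[f"G{i}" for i in range(6)])
        pc = ps.baseline_component(panel)
        assert np.corrcoef(pc, panel.mean(axis=1))[0, 1] >= 0

    def test_zero_variance_gene_dropped(self, rng):
        panel = pd.DataFrame({"G0": rng.normal(size=30),
                              "G1": np.ones(30),
                              "G2": rng.normal(size=30)})
        with pytest.warns(RuntimeWarning, match="G1"):
            pc = ps.baseline_component(panel)
        assert pc.shape == (30,)


class TestContextualDecoding:
    def test_type_hierarchy_self_correlation(self, small_geom_mod, spins, rng):
        types = 1 + (np.argsort(np.argsort(
            small_geom_mod.parcel_centroids[:, 2])) * 6) // small_geom_mod.n_parcels
        arte = rng.normal(size=small_geom_mod.n_parcels)
        vein = rng.normal(size=small_geom_mod.n_parcels)
        out = ps.contextual_decoding({"m": types.astype(float)}, types, arte,
                                     vein, spins)
        row = out[(out["map"] == "m") & (out["reference"] == "cortical_types")]
        assert row["rho"].iloc[0] == pytest.approx(1.0)
        assert row["p_spin"].iloc[0] == pytest.approx(1 / 100)

    def test_monotone_relabeling_invariance(self, small_geom_mod, spins, rng):
        types = 1 + (np.argsort(np.argsort(
            small_geom_mod.parcel_centroids[:, 2])) * 6) // small_geom_mod.n_parcels
        m = rng.normal(size=small_geom_mod.n_parcels)
        arte = rng.normal(size=small_geom_mod.n_parcels)
        vein = rng.normal(size=small_geom_mod.n_parcels)
        a = ps.contextual_decoding({"m": m}, types, arte, vein, spins)
        # relabel 1..6 -> 10..60 via spearman invariance: compare directly
        rho_a = a[a["reference"] == "cortical_types"]["rho"].iloc[0]
        rho_b = stats.spearmanr(m, types * 10.0).statistic
        assert rho_a == pytest.approx(rho_b, abs=1e-12)

    def test_invalid_types_rejected(self, small_geom_mod, spins, rng):
        bad = np.zeros(small_geom_mod.n_parcels, dtype=int)
        with pytest.raises(ValueError):
            ps.contextual_decoding(
                {"m": rng.normal(size=small_geom_mod.n_parcels)},
                bad,
                rng.normal(size=small_geom_mod.n_parcels),
                rng.normal(size=small_geom_mod.n_parcels),
                spins,
            )
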