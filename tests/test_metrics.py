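import numpy as np
import pytest

from bbvae.ensemble import Ensemble
from bbvae.metrics import (
    cluster_by_rmsd,
    compare_ensembles,
    dihedral_distributions,
    js_divergence,
    mean_distance_map_mse,
    one_against_all_rmsd,
    pairwise_rmsd,
    pca_embed,
    rg_values,
    wrap_omega,
)
from bbvae.synthetic import BasinSpec, make_ensemble

from conftest import random_rigid_transform


class TestPairwiseRmsd:
    def test_self_and_rigid_copies_zero(self, helix_ensemble, rng):
        vals = pairwise_rmsd(helix_ensemble, helix_ensemble)
        np.testing.assert_allclose(vals, 0.0, atol=1e-12)
        moved = Ensemble(
            [c.transformed(*random_rigid_transform(rng)) for c in helix_ensemble]
        )
        np.testing.assert_allclose(pairwise_rmsd(helix_ensemble, moved), 0.0, atol=1e-8)

    def test_matches_per_pair_oracle(self, rng):
        from bbvae.geometry import kabsch_rmsd

        a = make_ensemble(L=5, n=2, seed=1)
        b = make_ensemble(L=5, n=2, seed=2)
        vals = pairwise_rmsd(a, b)
        expected = [kabsch_rmsd(a[i].atoms(), b[i].atoms()) for i in range(2)]
        np.testing.assert_allclose(vals, expected, atol=1e-12)

    def test_size_mismatch_rejected(self):
        a = make_ensemble(L=5, n=2, seed=1)
        b = make_ensemble(L=5, n=3, seed=2)
        with pytest.raises(ValueError):
            pairwise_rmsd(a, b)


class TestOneAgainstAll:
    def test_identical_copies_all_zero(self):
        conf = make_ensemble(L=5, n=1, seed=0)[0]
        ens = Ensemble([conf, conf, conf])
        np.testing.assert_allclose(one_against_all_rmsd(ens), 0.0, atol=1e-12)

    def test_count_for_three_members(self):
        ens = make_ensemble(L=5, n=3, seed=0)
        assert len(one_against_all_rmsd(ens)) == 6

    def test_subsample_consistent_with_full(self):
        ens = make_ensemble(L=5, n=50, seed=0)
        full = one_against_all_rmsd(ens)
        sub = one_against_all_rmsd(ens, max_pairs=400, seed=1)
        assert len(sub) == 800
        assert abs(sub.mean() - full.mean()) / full.mean() < 0.05


class TestJsDivergence:
    def test_identical_zero_and_disjoint_ln2(self, rng):
        x = rng.normal(0, 1, 5000)
        assert js_divergence(x, x) == pytest.approx(0.0, abs=1e-12)
        assert js_divergence(
            np.linspace(0, 1, 1000), np.linspace(10, 11, 1000)
        ) == pytest.approx(np.log(2), abs=1e-9)

    def test_constant_samples_convention(self):
        assert js_divergence(np.ones(10), np.ones(10)) == 0.0

    def test_symmetry_and_bounds(self, rng):
        a = rng.normal(0, 1, 2000)
        b = rng.normal(1.5, 2, 2000)
        ab = js_divergence(a, b)
        assert ab == pytest.approx(js_divergence(b, a), abs=1e-12)
        assert 0 <= ab <= np.log(2)

    def test_matches_numeric_integration_oracle(self):
        rng = np.random.default_rng(0)
        n = 100_000
        a = rng.normal(0, 1, n)
        b = rng.normal(3, 1, n)
        ours = js_divergence(a, b, bins=50)
        # oracle: integrate the binned densities directly
        lo, hi = min(a.min(), b.min()), max(a.max(), b.max())
        edges = np.linspace(lo, hi, 51)
        p, _ = np.histogram(a, bins=edges, density=True)
        q, _ = np.histogram(b, bins=edges, density=True)
        w = np.diff(edges)
        m = 0.5 * (p + q)

        def kl(r, s):
            mask = r > 0
            return np.sum(w[mask] * r[mask] * np.log(r[mask] / s[mask]))

        expected = 0.5 * kl(p, m) + 0.5 * kl(q, m)
        assert ours == pytest.approx(expected, abs=0.02)

    def test_omega_wrap_removes_trans_split(self, rng):
        # trans peak straddles ±180°: raw binning splits it, wrapping does not
        omega = np.concatenate([rng.normal(178, 2, 3000), rng.normal(-178, 2, 3000)])
        wrapped = wrap_omega(omega)
        assert wrapped.min() > 160 and wrapped.max() < 200


class TestDihedralPools:
    def test_pool_counts(self):
        ens = make_ensemble(L=6, n=10, seed=0)
        pools = dihedral_distributions(ens)
        assert all(len(pools[k]) == 50 for k in ("phi", "psi", "omega"))

    def test_trans_fixture_omega_near_180(self):
        ens = make_ensemble(L=6, n=10, seed=0)
        wrapped = wrap_omega(dihedral_distributions(ens)["omega"])
        assert np.abs(wrapped - 180).max() < 25  # 5 sigma of the generator jitter


class TestDistanceMapMse:
    def test_self_zero(self, helix_ensemble):
        assert mean_distance_map_mse(helix_ensemble, helix_ensemble) == 0.0

    def test_constant_offset_closed_form(self):
        ens = make_ensemble(L=5, n=4, seed=0)
        from bbvae.metrics import mean_distance_map

        base = mean_distance_map(ens)
        c = 0.7
        shifted = base + c * (1 - np.eye(5))
        L = 5
        expected = c**2 * (L**2 - L) / L**2
        got = np.mean((base - shifted) ** 2)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_direct_recompute(self):
        a = make_ensemble(L=5, n=3, seed=1)
        b = make_ensemble(L=5, n=4, seed=2)
        from bbvae.geometry import ca_distance_map

        ma = np.mean([ca_distance_map(c) for c in a], axis=0)
        mb = np.mean([ca_distance_map(c) for c in b], axis=0)
        assert mean_distance_map_mse(a, b) == pytest.approx(
            float(np.mean((ma - mb) ** 2)), abs=1e-12
        )


class TestPcaEmbed:
    def test_duplicated_ensemble_identical_clouds(self):
        ens = make_ensemble(L=6, n=10, seed=0)
        (a, b), evr = pca_embed([ens, ens])
        np.testing.assert_allclose(a, b, atol=1e-10)
        assert evr.sum() <= 1.0 + 1e-12

    def test_first_component_separates_outlier(self):
        tight = make_ensemble(
            [BasinSpec("h", -63, 1e-6, -43, 1e-6)], L=6, n=3, seed=0
        )
        outlier = make_ensemble(
            [BasinSpec("e", -120, 1e-6, 135, 1e-6)], L=6, n=1, seed=0
        )
        ens = Ensemble(list(tight) + list(outlier))
        (scores,), _ = pca_embed([ens])
        assert np.argmax(np.abs(scores[:, 0])) == 3

    def test_full_rank_embedding_preserves_distances(self):
        ens = make_ensemble(L=4, n=5, seed=3)
        from bbvae.metrics import _distance_features

        feats = _distance_features(ens)
        rank = np.linalg.matrix_rank(feats - feats.mean(0))
        (scores,), _ = pca_embed([ens], components=rank)
        d_feat = np.linalg.norm(feats[:, None] - feats[None], axis=-1)
        d_emb = np.linalg.norm(scores[:, None] - scores[None], axis=-1)
        np.testing.assert_allclose(d_emb, d_feat, atol=1e-6)


class TestClustering:
    def test_recovers_well_separated_basins(self):
        specs = [
            BasinSpec("helix", -63, 2, -43, 2),
            BasinSpec("extended", -120, 2, 135, 2),
            BasinSpec("left", 60, 2, 60, 2),
        ]
        members, labels = [], []
        for i, s in enumerate(specs):
            e = make_ensemble([s], L=8, n=6, seed=i)
            members.extend(list(e))
            labels.extend([i] * 6)
        ens = Ensemble(members)
        assign, medoids = cluster_by_rmsd(ens, n_clusters=3, seed=0)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, assign) == 1.0

    def test_single_cluster_medoid_is_central_member(self):
        from bbvae.geometry import kabsch_rmsd

        ens = make_ensemble(L=6, n=8, seed=4)
        assign, medoids = cluster_by_rmsd(ens, n_clusters=1, seed=0)
        atoms = [c.atoms() for c in ens]
        totals = [
            sum(kabsch_rmsd(atoms[i], atoms[j]) for j in range(8)) for i in range(8)
        ]
        assert medoids[0] == int(np.argmin(totals))
        assert (assign == 0).all()

    def test_deterministic_given_seed_and_duplicates_together(self):
        conf_sets = [make_ensemble(L=6, n=4, seed=s) for s in (0, 1)]
        members = list(conf_sets[0]) + list(conf_sets[0]) + list(conf_sets[1])
        ens = Ensemble(members)
        a1, m1 = cluster_by_rmsd(ens, n_clusters=2, seed=3)
        a2, m2 = cluster_by_rmsd(ens, n_clusters=2, seed=3)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(m1, m2)
        # duplicated conformations always land in the same cluster
        for i in range(4):
            assert a1[i] == a1[i + 4]


def test_compare_ensembles_report_summary(helix_ensemble):
    report = compare_ensembles(helix_ensemble, helix_ensemble, seed=0)
    s = report.summary()
    assert s["mean_pairwise_rmsd"] == pytest.approx(0.0, abs=1e-10)
    assert s["js_omega"] == pytest.approx(0.0, abs=1e-12)
    assert s["mean_distance_map_mse"] == 0.0
    assert 0 <= s["js_rg"] <= np.log(2)
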