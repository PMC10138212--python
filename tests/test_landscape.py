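import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from codescape.codons import AA_INDEX, GeneticCode, codon_index, sgc
from codescape.ga import delta_pr_of_vectors
from codescape.landscape import (
    assign_clusters,
    average_code,
    average_code_table,
    cluster_occupancy,
    elbow_k,
    fit_clusters,
    landscape_stack,
    name_clusters,
    pca_fit,
    vectorize,
)
from codescape.scales import polar_requirement
from codescape.synthetic import planted_blobs


class TestVectorize:
    def test_sgc_maxima_at_asp_glu_codons(self):
        v = vectorize(sgc().assign)[0]
        top4 = set(np.argsort(v)[-4:])
        asp_glu = {codon_index(c) for c in ("GAU", "GAC", "GAA", "GAG")}
        assert top4 == asp_glu

    def test_equal_value_codes_map_identically(self):
        a = sgc().assign.copy()
        b = a.copy()
        b[a == AA_INDEX["L"]] = AA_INDEX["I"]  # same polar requirement
        V = vectorize(np.stack([a, b]))
        np.testing.assert_array_equal(V[0], V[1])

    def test_round_trip_through_serialization(self):
        code = sgc()
        reparsed = GeneticCode(code.to_string())
        np.testing.assert_array_equal(
            vectorize(code.assign), vectorize(reparsed.assign)
        )

    def test_stop_positions_constant(self):
        from codescape.codons import STOP_CODONS

        V = vectorize(sgc().assign, stop_value=-7.0)[0]
        assert all(V[c] == -7.0 for c in STOP_CODONS)


class TestPCAFit:
    def test_identical_vectors_reported_degenerate(self):
        V = np.tile(vectorize(sgc().assign), (10, 1))
        proj = pca_fit(V, np.zeros(10), cutoff=1.0)
        assert proj.degenerate
        assert (proj.explained_variance_ratio == 0).all()

    def test_planted_blobs_separate_on_leading_components(self):
        # four blobs in a plane of a 64-dim space: PC1/PC2 recover the plane
        rng = np.random.default_rng(0)
        plane, labels = planted_blobs(4, separation=10, n_per_blob=100, dim=2, seed=0)
        pts = np.zeros((len(plane), 64))
        pts[:, :2] = plane
        pts += 0.1 * rng.standard_normal(pts.shape)
        proj = pca_fit(pts, np.zeros(len(pts)), cutoff=1.0, n_components=2)
        emb = proj.transform(pts)[:, :2]
        model = fit_clusters(emb, 4, seed=0, n_restarts=10)
        assert adjusted_rand_score(labels, model.labels) > 0.99

    def test_cutoff_restricts_fit_set(self):
        rng = np.random.default_rng(0)
        V = rng.standard_normal((100, 64))
        costs = np.linspace(0, 10, 100)
        proj = pca_fit(V, costs, cutoff=5.0)
        np.testing.assert_allclose(proj.mean, V[costs < 5.0].mean(axis=0))
        with pytest.raises(ValueError):
            pca_fit(V, costs, cutoff=-1.0)

    def test_sgc_pc1_sign_convention(self):
        rng = np.random.default_rng(1)
        base = vectorize(sgc().assign)[0]
        V = base + rng.standard_normal((200, 64))
        proj = pca_fit(V, np.zeros(200), cutoff=1.0)
        assert proj.transform(vectorize(sgc().assign))[0, 0] >= 0

    def test_explained_variance_ratios_nonincreasing(self):
        pts, _ = planted_blobs(3, separation=6, n_per_blob=80, dim=64, seed=2)
        proj = pca_fit(pts, np.zeros(len(pts)), cutoff=1.0, n_components=3)
        evr = proj.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all() and (evr >= 0).all() and (evr <= 1).all()


class TestElbow:
    def test_recovers_planted_k_four(self):
        pts, labels = planted_blobs(4, separation=10, n_per_blob=200, dim=2, seed=3)
        k, sse = elbow_k(pts, k_max=8, seed=0, n_restarts=10)
        assert k == 4
        model = fit_clusters(pts, 4, seed=0, n_restarts=10)
        assert adjusted_rand_score(labels, model.labels) > 0.99

    def test_recovery_across_seeds(self):
        hits = 0
        for s in range(10):
            pts, _ = planted_blobs(4, separation=8, n_per_blob=150, dim=2, seed=s)
            k, _ = elbow_k(pts, k_max=8, seed=s, n_restarts=10)
            hits += k == 4
        assert hits >= 9

    def test_single_blob_reports_no_elbow(self):
        pts, _ = planted_blobs(1, separation=0, n_per_blob=500, dim=2, seed=4)
        k, _ = elbow_k(pts, k_max=8, seed=0, n_restarts=10)
        assert k == 1

    def test_identical_points_degenerate(self):
        pts = np.zeros((50, 2))
        k, sse = elbow_k(pts, k_max=4, seed=0, n_restarts=5)
        assert k == 1 and sse[0] == 0.0

    def test_zero_separation_recovery_at_chance(self):
        pts, labels = planted_blobs(4, separation=0, n_per_blob=150, dim=2, seed=5)
        model = fit_clusters(pts, 4, seed=0, n_restarts=10)
        assert adjusted_rand_score(labels, model.labels) < 0.05

    def test_fewer_points_than_k_rejected(self):
        with pytest.raises(ValueError):
            elbow_k(np.zeros((3, 2)), k_max=8)


class TestClusters:
    def _synthetic_peaks(self):
        """Four blobs of 64-dim code vectors with known identities."""
        rng = np.random.default_rng(6)
        scale = polar_requirement()
        base = vectorize(sgc().assign, scale)[0]
        # mirrored (left/right swapped) variant: negative Delta_PR
        perm = np.arange(64)
        for c in range(64):
            b2 = (c >> 2) & 3
            perm[c] = (c & ~12) | ({0: 2, 1: 3, 2: 0, 3: 1}[b2] << 2)
        mirrored = base[np.argsort(perm)]
        far1 = np.roll(base, 7)
        far2 = np.roll(base, 21)
        sizes = {"green": 120, "blue": 30, "red": 300, "orange": 200}
        blobs = {
            "green": base,
            "blue": mirrored,
            "red": far1,
            "orange": far2,
        }
        V, truth = [], []
        for name, center in blobs.items():
            V.append(center + 0.2 * rng.standard_normal((sizes[name], 64)))
            truth += [name] * sizes[name]
        return np.concatenate(V), np.array(truth)

    def test_peak_naming_rules(self):
        V, truth = self._synthetic_peaks()
        model = fit_clusters(V, 4, seed=0, n_restarts=10)
        model = name_clusters(model, V)
        named = model.color_labels()
        for color in ("green", "blue", "red", "orange"):
            majority = np.array([named[i] for i in range(len(truth)) if truth[i] == color])
            assert (majority == color).mean() > 0.95

    def test_occupancy_sums_to_one(self):
        V, _ = self._synthetic_peaks()
        model = fit_clusters(V, 4, seed=0, n_restarts=10)
        costs = np.linspace(2.0, 3.0, len(V))
        occ = cluster_occupancy(model.labels, costs, (2.0, 3.5), 4)
        assert occ.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_cluster_occupancy_is_one(self):
        occ = cluster_occupancy(np.zeros(10, int), np.full(10, 2.6), (2.5, 2.7), 1)
        assert occ[0] == 1.0

    def test_empty_slice_rejected(self):
        with pytest.raises(ValueError):
            cluster_occupancy(np.zeros(10, int), np.full(10, 9.0), (2.5, 2.7), 1)

    def test_assign_clusters_nearest_center(self):
        V, _ = self._synthetic_peaks()
        model = fit_clusters(V, 4, seed=0, n_restarts=10)
        relabeled = assign_clusters(model, V)
        assert (relabeled == model.labels).mean() > 0.999


class TestAverageCode:
    def test_single_member_is_own_vector(self):
        v = average_code(sgc().assign[None, :])
        np.testing.assert_array_equal(v, vectorize(sgc().assign)[0])

    def test_table_layout_shape(self):
        t = average_code_table(np.arange(64.0))
        assert t.shape == (16, 4)
        # row 0 = UUx (x = 3rd base), columns = 2nd base
        assert t[0, 0] == 0.0 and t[0, 1] == 4.0 and t[1, 0] == 1.0


class TestLandscapeStack:
    def test_slabs_ordered_decreasing_and_empty_preserved(self):
        coords = np.array([[0.0, 0.0], [1.0, 1.0]])
        costs = np.array([2.6, 4.1])
        layers = landscape_stack(coords, costs, slab_width=0.5, cost_range=(2.5, 4.5))
        los = [l["lo"] for l in layers]
        assert los == sorted(los, reverse=True)
        sizes = [len(l["coords"]) for l in layers]
        assert sum(sizes) == 2 and 0 in sizes
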