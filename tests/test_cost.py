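import itertools

import numpy as np
import pytest

from codescape.codons import (
    AA_INDEX,
    AMINO_ACIDS,
    GeneticCode,
    STOP_CODONS,
    codon_from_index,
    sgc,
)
from codescape.cost import (
    CostConfig,
    CostEvaluator,
    SubstitutionPenalty,
    code_cost,
    delta_cost,
    misreading_weights,
)
from codescape.scales import PropertyScale, polar_requirement


class TestMisreadingWeights:
    def test_each_codon_has_nine_neighbors_with_raw_sum(self):
        m = misreading_weights()
        assert m.neighbors.shape == (64, 9)
        # 3*1 (third base) + 1 + 2*0.5 (first) + 0.5 + 2*0.1 (second) = 5.7
        np.testing.assert_allclose(m.raw_weights.sum(axis=1), 5.7)

    @pytest.mark.parametrize(
        "c1,c2,expected",
        [
            ("GUG", "GUA", 1.0),  # 3rd base, any change
            ("GUG", "AUG", 1.0),  # 1st base transition
            ("GUG", "CUG", 0.5),  # 1st base transversion
            ("GUG", "GAG", 0.1),  # 2nd base transversion (U -> A)
            ("GUG", "GCG", 0.5),  # 2nd base transition (U -> C)
            ("GUG", "AUA", 0.0),  # double change
            ("UUU", "GGG", 0.0),  # triple change
        ],
    )
    def test_weight_classes(self, c1, c2, expected):
        from codescape.codons import codon_index

        m = misreading_weights()
        assert m.weight(codon_index(c1), codon_index(c2)) == expected

    def test_raw_weights_symmetric(self):
        m = misreading_weights()
        W = np.zeros((64, 64))
        for c in range(64):
            for k in range(9):
                W[c, m.neighbors[c, k]] = m.raw_weights[c, k]
        np.testing.assert_array_equal(W, W.T)

    def test_normalization_excludes_stop_pairs(self):
        m = misreading_weights()
        assert m.normalization() < 64 * 5.7
        assert m.normalization(stop_positions=()) == pytest.approx(64 * 5.7)


class TestCodeCost:
    def test_sgc_cost_matches_printed_value(self, evaluator, standard_code):
        assert evaluator.cost(standard_code) == pytest.approx(2.6283, abs=1e-3)

    def test_single_amino_acid_code_costs_nothing(self, evaluator, standard_code):
        a = standard_code.assign.copy()
        a[a >= 0] = AA_INDEX["A"]
        assert evaluator.cost(GeneticCode(a)) == 0.0

    def test_matches_exhaustive_pair_enumeration(self, standard_code):
        # independent oracle: loop over all ordered codon pairs
        scale = polar_requirement()
        pur = set("AG")
        def raw(c1, c2):
            diff = [k for k in range(3) if c1[k] != c2[k]]
            if len(diff) != 1:
                return 0.0
            k = diff[0]
            ts = (c1[k] in pur) == (c2[k] in pur)
            return [1.0 if ts else 0.5, 0.5 if ts else 0.1, 1.0][k]

        s = standard_code.to_string()
        num = den = 0.0
        for i, j in itertools.product(range(64), range(64)):
            if i == j or s[i] == "*" or s[j] == "*":
                continue
            w = raw(codon_from_index(i), codon_from_index(j))
            num += w * (scale.value(s[i]) - scale.value(s[j])) ** 2
            den += w
        ev = CostEvaluator()
        assert ev.cost(standard_code) == pytest.approx(num / den, rel=1e-12)

    def test_batch_agrees_with_scalar(self, evaluator, standard_code):
        rng = np.random.default_rng(0)
        batch = np.tile(standard_code.assign, (5, 1))
        for r in range(1, 5):
            sense = np.flatnonzero(batch[r] >= 0)
            for _ in range(10):
                batch[r, rng.choice(sense)] = rng.integers(0, 20)
        costs = evaluator.batch_costs(batch)
        for r in range(5):
            assert costs[r] == pytest.approx(evaluator.cost(batch[r]), rel=1e-12)

    def test_value_permutation_invariance(self, evaluator, standard_code):
        # relabeling amino acids with equal property values leaves cost fixed
        vals = polar_requirement().values.copy()
        i, j = AA_INDEX["L"], AA_INDEX["I"]  # both 4.9
        assert vals[i] == vals[j]
        a = standard_code.assign.copy()
        swapped = a.copy()
        swapped[a == i] = j
        swapped[a == j] = i
        assert evaluator.cost(swapped) == pytest.approx(evaluator.cost(a), rel=1e-12)

    def test_first_base_purine_swap_symmetry(self, evaluator):
        # exchanging A<->G in the first base maps the code table onto itself
        # (transition/transversion classes are preserved, stops stay in the
        # U row), so cost is invariant under the induced relabeling
        rng = np.random.default_rng(3)
        from codescape.sampling import naive_sample

        batch = naive_sample(3, seed=5, evaluator=evaluator)
        perm = np.arange(64)
        for c in range(64):
            b1 = c >> 4
            if b1 == 2:
                perm[c] = (3 << 4) | (c & 15)
            elif b1 == 3:
                perm[c] = (2 << 4) | (c & 15)
        for r in range(3):
            a = batch.assigns[r]
            swapped = np.empty_like(a)
            swapped[perm] = a
            assert evaluator.cost(swapped) == pytest.approx(
                evaluator.cost(a), rel=1e-12
            )

    def test_missing_scale_value_rejected(self):
        with pytest.raises(ValueError):
            PropertyScale.from_mapping("partial", {"A": 1.0})


class TestDeltaCost:
    def test_thousand_random_flips_match_full_recompute(self, evaluator):
        from codescape.sampling import naive_sample

        rng = np.random.default_rng(11)
        batch = naive_sample(10, seed=11, evaluator=evaluator)
        for r in range(10):
            a = batch.assigns[r].copy()
            sense = np.flatnonzero(a >= 0)
            base = evaluator.cost(a)
            for _ in range(100):
                pos = int(rng.choice(sense))
                new = int(rng.integers(0, 19))
                if new >= a[pos]:
                    new += 1
                d = evaluator.delta(a, pos, new)
                flipped = a.copy()
                flipped[pos] = new
                full = evaluator.cost(flipped)
                assert d == pytest.approx(full - base, abs=1e-9)
                a, base = flipped, full

    def test_equal_value_flip_is_free(self, evaluator, standard_code):
        # Leu -> Ile: identical polar requirement
        a = standard_code.assign.copy()
        pos = int(np.flatnonzero(a == AA_INDEX["L"])[0])
        assert evaluator.delta(a, pos, AA_INDEX["I"]) == pytest.approx(0.0, abs=1e-12)

    def test_reverse_flip_negates_delta(self, evaluator, standard_code):
        a = standard_code.assign.copy()
        pos, new = 0, AA_INDEX["W"]
        d = evaluator.delta(a, pos, new)
        flipped = a.copy()
        flipped[pos] = new
        assert evaluator.delta(flipped, pos, int(a[pos])) == pytest.approx(-d, rel=1e-9)

    def test_stop_position_rejected(self, evaluator, standard_code):
        with pytest.raises(ValueError):
            evaluator.delta(standard_code.assign, STOP_CODONS[0], 0)
        with pytest.raises(ValueError):
            delta_cost(sgc(), 0, sgc().symbol(0))


class TestPenaltyVariants:
    def test_squared_difference_properties(self):
        pen = SubstitutionPenalty.squared_difference(polar_requirement())
        D = pen.matrix
        assert np.allclose(np.diag(D), 0)
        assert np.allclose(D, D.T)
        assert (D >= 0).all()

    def test_blosum_penalty_is_a_distance_like_transform(self, standard_code):
        pen = SubstitutionPenalty.blosum62()
        D = pen.matrix
        assert np.allclose(np.diag(D), 0)
        assert np.allclose(D, D.T)
        assert (D[~np.eye(20, dtype=bool)] > 0).all()
        cost = CostEvaluator(config=CostConfig(pen)).cost(standard_code)
        assert cost > 0

    def test_source_frequency_weighting_changes_cost(self, standard_code):
        pen = SubstitutionPenalty.squared_difference(polar_requirement())
        freq = np.ones(20)
        freq[AA_INDEX["D"]] = 10.0
        ev_w = CostEvaluator(config=CostConfig(pen, source_weights=freq))
        ev_u = CostEvaluator(config=CostConfig(pen))
        cw, cu = ev_w.cost(standard_code), ev_u.cost(standard_code)
        assert cw != pytest.approx(cu)
        # uniform weights reduce to the unweighted cost
        ev_flat = CostEvaluator(config=CostConfig(pen, source_weights=np.ones(20)))
        assert ev_flat.cost(standard_code) == pytest.approx(cu, rel=1e-12)

    def test_stop_costs_shift_baseline_only(self, standard_code):
        pen = SubstitutionPenalty.squared_difference(polar_requirement())
        ev0 = CostEvaluator(config=CostConfig(pen))
        ev1 = CostEvaluator(config=CostConfig(pen, c0=2.0, c1=1.0))
        shift = ev1.cost(standard_code) - ev0.cost(standard_code)
        assert shift > 0
        other = standard_code.assign.copy()
        other[0] = AA_INDEX["W"]
        assert ev1.cost(other) - ev0.cost(other) == pytest.approx(shift, rel=1e-12)
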