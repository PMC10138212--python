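import numpy as np
import pytest

from codescape.multicanonical import (
    CostGrid,
    DOSEstimate,
    WangLandauError,
    WangLandauSchedule,
    WeightFunction,
    empirical_dos,
    estimate_dos,
    multicanonical_sample,
    tail_fraction,
    wang_landau_train,
)
from codescape.synthetic import enumerate_states, exact_dos, make_toy


def _toy_grid(toy, width=0.5):
    _, costs = enumerate_states(toy)
    return CostGrid(np.floor(costs.min()), np.ceil(costs.max()) + width, width)


def _trained(toy, grid, seed=5, log_f_min=1e-5, max_steps=20_000_000):
    sched = WangLandauSchedule(
        log_f_min=log_f_min, check_every=20_000, max_steps=max_steps
    )
    return wang_landau_train(toy.system(), grid, sched, seed=seed)


class TestCostGrid:
    def test_bins_partition_half_open(self):
        g = CostGrid(0.0, 1.0, 0.25)
        assert g.nbins == 4
        np.testing.assert_array_equal(g.bin_of([0.0, 0.249, 0.25, 0.999]), [0, 0, 1, 3])

    def test_out_of_range_clamps(self):
        g = CostGrid(1.0, 2.0, 0.5)
        np.testing.assert_array_equal(g.bin_of([-5.0, 99.0]), [0, 1])

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            CostGrid(1.0, 1.0, 0.1)


class TestWangLandau:
    def test_toy_dos_matches_enumeration(self, toy36):
        grid = _toy_grid(toy36)
        wl = _trained(toy36, grid)
        assert wl.converged
        exact = exact_dos(toy36, grid)
        m = exact > 0
        # exp(log_g) matches exact per-bin counts within 10% after normalization
        g = np.exp(wl.log_g[m] - wl.log_g[m].max())
        est = g / g.sum() * exact.sum()
        np.testing.assert_allclose(est, exact[m], rtol=0.10)
        assert set(np.flatnonzero(wl.weight.visited)) == set(np.flatnonzero(m))

    def test_nonconvergence_raises_with_diagnostics(self, toy36):
        grid = _toy_grid(toy36)
        sched = WangLandauSchedule(log_f_min=1e-12, check_every=1000, max_steps=5000)
        with pytest.raises(WangLandauError, match="log_f"):
            wang_landau_train(toy36.system(), grid, sched, seed=1)

    def test_seeded_determinism_bit_for_bit(self, toy36):
        grid = _toy_grid(toy36)
        wl1 = _trained(toy36, grid, seed=8)
        wl2 = _trained(toy36, grid, seed=8)
        np.testing.assert_array_equal(wl1.log_g, wl2.log_g)
        np.testing.assert_array_equal(wl1.final_state, wl2.final_state)
        assert wl1.steps == wl2.steps

    def test_weight_tsv_round_trip(self, toy36, tmp_path):
        grid = _toy_grid(toy36)
        wl = _trained(toy36, grid)
        wl.weight.to_tsv(tmp_path / "w.tsv")
        back = WeightFunction.from_tsv(tmp_path / "w.tsv")
        np.testing.assert_allclose(back.log_w, wl.weight.log_w)
        assert back.grid.nbins == grid.nbins


class TestMulticanonicalSampling:
    def test_flat_histogram_with_trained_weights(self, toy36):
        grid = _toy_grid(toy36)
        wl = _trained(toy36, grid)
        run = multicanonical_sample(toy36.system(), wl.weight, steps=2_000_000, seed=6)
        assert run.flat_ratio() >= 0.8

    def test_constant_weight_reduces_to_plain_random_walk(self, toy36):
        # with w = const every constraint-satisfying candidate is accepted,
        # so the sampled histogram reproduces the ensemble distribution
        grid = _toy_grid(toy36)
        flat = WeightFunction(grid, np.zeros(grid.nbins), np.ones(grid.nbins, bool))
        run = multicanonical_sample(toy36.system(), flat, steps=2_000_000, seed=7)
        exact = exact_dos(toy36, grid)
        frac = run.hist / run.hist.sum()
        np.testing.assert_allclose(frac[exact > 0], exact[exact > 0] / exact.sum(), atol=0.01)

    def test_detailed_balance_flow_symmetry(self, toy36):
        grid = _toy_grid(toy36)
        wl = _trained(toy36, grid)
        run = multicanonical_sample(
            toy36.system(), wl.weight, steps=2_000_000, seed=9, track_flows=True
        )
        F = run.flows
        for i in range(grid.nbins):
            for j in range(i + 1, grid.nbins):
                tot = F[i, j] + F[j, i]
                if tot > 500:
                    z = abs(int(F[i, j]) - int(F[j, i])) / np.sqrt(tot)
                    assert z < 5.0

    def test_seeded_determinism(self, toy36):
        grid = _toy_grid(toy36)
        wl = _trained(toy36, grid)
        r1 = multicanonical_sample(toy36.system(), wl.weight, steps=100_000, seed=3, thinning=10)
        r2 = multicanonical_sample(toy36.system(), wl.weight, steps=100_000, seed=3, thinning=10)
        np.testing.assert_array_equal(r1.hist, r2.hist)
        np.testing.assert_array_equal(r1.rec_assigns, r2.rec_assigns)

    def test_records_respect_threshold(self, toy36):
        grid = _toy_grid(toy36)
        wl = _trained(toy36, grid)
        thr = float(np.median(grid.centers))
        run = multicanonical_sample(
            toy36.system(), wl.weight, steps=500_000, seed=4, thinning=50, record_below=thr
        )
        assert run.rec_costs.size > 0
        assert (run.rec_costs < thr).all()


class TestDOSEstimate:
    def test_toy_dos_within_per_bin_tolerance(self, toy_large):
        # 0.2 log10 per-bin agreement with exact enumeration at 1e7 steps
        grid = _toy_grid(toy_large, width=1.0)
        wl = _trained(toy_large, grid, max_steps=30_000_000)
        run = multicanonical_sample(toy_large.system(), wl.weight, steps=10_000_000, seed=13)
        dos = estimate_dos(run.hist, wl.weight, mode="fraction")
        exact = exact_dos(toy_large, grid)
        m = (exact > 0) & dos.mask()
        est_log10 = dos.log_dos[m] / np.log(10)
        exact_log10 = np.log10(exact[m] / exact.sum())
        assert np.abs(est_log10 - exact_log10).max() <= 0.2

    def test_fraction_mode_sums_to_one(self, toy36):
        grid = _toy_grid(toy36)
        wl = _trained(toy36, grid)
        run = multicanonical_sample(toy36.system(), wl.weight, steps=500_000, seed=2)
        dos = estimate_dos(run.hist, wl.weight, mode="fraction")
        assert np.exp(dos.log_dos[dos.mask()]).sum() == pytest.approx(1.0, abs=1e-9)

    def test_absolute_mode_anchors_to_ensemble_count(self, toy36):
        from codescape.synthetic import toy_count

        grid = _toy_grid(toy36)
        wl = _trained(toy36, grid)
        run = multicanonical_sample(toy36.system(), wl.weight, steps=2_000_000, seed=2)
        total = toy_count(toy36)
        dos = estimate_dos(run.hist, wl.weight, mode="absolute", total=total)
        assert np.exp(dos.log_dos[dos.mask()]).sum() == pytest.approx(total, rel=1e-6)

    def test_empty_bins_masked_not_zero(self, toy36):
        grid = CostGrid(0.0, 100.0, 1.0)  # much wider than the spectrum
        wl = _trained(toy36, grid)
        run = multicanonical_sample(toy36.system(), wl.weight, steps=200_000, seed=2)
        dos = estimate_dos(run.hist, wl.weight, mode="relative")
        assert np.isnan(dos.log_dos[~dos.mask()]).all()
        assert (~dos.mask()).any()


class TestTailFraction:
    def test_matches_enumeration(self, toy36):
        grid = _toy_grid(toy36)
        wl = _trained(toy36, grid)
        run = multicanonical_sample(toy36.system(), wl.weight, steps=4_000_000, seed=10)
        dos = estimate_dos(run.hist, wl.weight, mode="fraction")
        _, costs = enumerate_states(toy36)
        exact = exact_dos(toy36, grid)
        for thr in np.quantile(costs, [0.2, 0.5, 0.8]):
            est = tail_fraction(dos, thr)
            ref = exact[grid.centers < thr].sum() / exact.sum()
            assert est == pytest.approx(ref, rel=0.1)

    def test_monotone_in_threshold_and_edges(self, toy36):
        grid = _toy_grid(toy36)
        wl = _trained(toy36, grid)
        run = multicanonical_sample(toy36.system(), wl.weight, steps=1_000_000, seed=10)
        dos = estimate_dos(run.hist, wl.weight, mode="fraction")
        thresholds = np.linspace(grid.lo - 1, grid.hi + 1, 30)
        tails = [tail_fraction(dos, t) for t in thresholds]
        assert tails[0] == 0.0
        assert tails[-1] == pytest.approx(1.0, abs=1e-9)
        assert all(b >= a for a, b in zip(tails, tails[1:]))

    def test_empirical_dos_agrees_on_toy(self, toy36):
        # direct uniform enumeration histogram vs estimator API
        _, costs = enumerate_states(toy36)
        grid = _toy_grid(toy36)
        dos = empirical_dos(costs, grid)
        exact = exact_dos(toy36, grid)
        m = exact > 0
        np.testing.assert_allclose(
            np.exp(dos.log_dos[m]), exact[m] / exact.sum(), rtol=1e-9
        )
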