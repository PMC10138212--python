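"""Numba kernels shared by the samplers and the genetic algorithm.

All kernels operate on plain arrays so that the full 64-codon system and
the enumerable toy systems run through identical code paths:

- ``nb`` (n_sites, max_nb) int64: neighbor site indices (padding allowed);
- ``w``  (n_sites, max_nb) float64: effective misreading weights, already
  zeroed for pairs involving an excluded (stop) position and for padding;
- ``norm`` float64: normalization (total weight over counted pairs);
- ``D`` (S, S) float64: substitution penalty matrix;
- ``sense`` int64 array: positions free to mutate;
- ``minima`` int64 (S,): per-symbol minimum multiplicities;
- ``assign`` int8 (n_sites,): current assignment, -1 at excluded positions.

Deltas are computed over the flipped position's neighbors only; weights
are symmetric, so each undirected neighbor pair contributes twice its
one-way weight.  Every kernel seeds numba's RNG from an explicit integer,
giving bit-reproducible chains.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def cost_full(assign, nb, w, norm, D):
    acc = 0.0
    n_sites, max_nb = nb.shape
    for c in range(n_sites):
        a = assign[c]
        if a < 0:
            continue
        for k in range(max_nb):
            wk = w[c, k]
            if wk == 0.0:
                continue
            a2 = assign[nb[c, k]]
            if a2 < 0:
                continue
            acc += wk * D[a, a2]
    return acc / norm


@njit(cache=True)
def delta_flip(assign, pos, new, nb, w, norm, D):
    old = assign[pos]
    acc = 0.0
    for k in range(nb.shape[1]):
        wk = w[pos, k]
        if wk == 0.0:
            continue
        a2 = assign[nb[pos, k]]
        if a2 < 0:
            continue
        acc += 2.0 * wk * (D[new, a2] - D[old, a2])
    return acc / norm


@njit(cache=True)
def random_valid_assign(assign_template, sense, minima, n_symbols, max_tries):
    """Uniform draw from the constrained ensemble by rejection.

    ``assign_template`` supplies excluded positions (-1); sense positions
    are overwritten.  Returns (assign, counts, ok flag).
    """
    n_sense = sense.shape[0]
    S = n_symbols
    assign = assign_template.copy()
    counts = np.zeros(S, dtype=np.int64)
    for _ in range(max_tries):
        for s in range(S):
            counts[s] = 0
        for i in range(n_sense):
            a = np.random.randint(0, S)
            assign[sense[i]] = np.int8(a)
            counts[a] += 1
        ok = True
        for s in range(S):
            if counts[s] < minima[s]:
                ok = False
                break
        if ok:
            return assign, counts, True
    return assign, counts, False


@njit(cache=True)
def _clamp_bin(cost, lo, width, nbins):
    b = int((cost - lo) / width)
    if b < 0:
        b = 0
    elif b >= nbins:
        b = nbins - 1
    return b


@njit(cache=True)
def wang_landau_kernel(
    assign,
    counts,
    nb,
    w,
    norm,
    D,
    sense,
    minima,
    lo,
    width,
    nbins,
    log_f0,
    log_f_min,
    flatness,
    check_every,
    max_steps,
    seed,
):
    """Wang-Landau training of the multicanonical weight.

    Accumulates log density-of-states estimates ``log_g`` (the trained
    multicanonical log-weight is ``-log_g``); the modification factor is
    halved in log space whenever the histogram over visited bins is flat
    (every bin >= ``flatness`` times the mean).  Returns
    (log_g, visited, steps_used, final_log_f, converged, n_passes).
    Constraint-violating candidates are rejected in place (the current bin
    is re-counted), preserving the constrained stationary distribution.
    """
    np.random.seed(seed)
    S = minima.shape[0]
    n_sense = sense.shape[0]
    log_g = np.zeros(nbins, dtype=np.float64)
    hist = np.zeros(nbins, dtype=np.int64)
    visited = np.zeros(nbins, dtype=np.bool_)

    cost = cost_full(assign, nb, w, norm, D)
    b = _clamp_bin(cost, lo, width, nbins)
    log_f = log_f0
    steps = 0
    n_passes = 0
    converged = False

    while steps < max_steps:
        block = min(check_every, max_steps - steps)
        for _ in range(block):
            pos = sense[np.random.randint(0, n_sense)]
            old = assign[pos]
            new = np.random.randint(0, S - 1)
            if new >= old:
                new += 1
            accept = counts[old] - 1 >= minima[old]
            if accept:
                d = delta_flip(assign, pos, new, nb, w, norm, D)
                new_cost = cost + d
                b2 = _clamp_bin(new_cost, lo, width, nbins)
                if log_g[b2] > log_g[b]:
                    accept = np.log(np.random.random()) < log_g[b] - log_g[b2]
                if accept:
                    assign[pos] = np.int8(new)
                    counts[old] -= 1
                    counts[new] += 1
                    cost = new_cost
                    b = b2
            log_g[b] += log_f
            hist[b] += 1
            visited[b] = True
        steps += block
        # periodic exact refresh against float drift
        cost = cost_full(assign, nb, w, norm, D)
        b = _clamp_bin(cost, lo, width, nbins)
        # flatness over ALL bins ever visited: a pass only completes once
        # the chain has re-covered the full discovered range, so that
        # late-discovered bins are properly integrated into log_g
        nvis = 0
        total = 0
        minc = np.int64(1) << 62
        for i in range(nbins):
            if visited[i]:
                nvis += 1
                total += hist[i]
                if hist[i] < minc:
                    minc = hist[i]
        if nvis > 0 and minc >= flatness * (total / nvis):
            n_passes += 1
            log_f *= 0.5
            for i in range(nbins):
                hist[i] = 0
            if log_f < log_f_min:
                converged = True
                break
    return log_g, visited, steps, log_f, converged, n_passes


@njit(cache=True)
def muca_kernel(
    assign,
    counts,
    nb,
    w,
    norm,
    D,
    sense,
    minima,
    log_w,
    lo,
    width,
    nbins,
    steps,
    thin,
    record_below,
    max_records,
    track_flows,
    seed,
):
    """Fixed-weight multicanonical sampling.

    Metropolis rule min(1, w(cost')/w(cost)) on the supplied log-weight;
    rejected steps re-record the current state in the histogram.  States
    with cost below ``record_below`` are retained every ``thin`` steps (up
    to ``max_records``).  If ``track_flows`` the per-step bin-to-bin
    transition counts are accumulated (for detailed-balance diagnostics;
    use small grids only).  Returns (hist, rec_assign, rec_costs, n_rec,
    flows, all_costs_hist_steps).
    """
    np.random.seed(seed)
    S = minima.shape[0]
    n_sense = sense.shape[0]
    n_sites = assign.shape[0]
    hist = np.zeros(nbins, dtype=np.int64)
    rec_assign = np.zeros((max_records, n_sites), dtype=np.int8)
    rec_costs = np.zeros(max_records, dtype=np.float64)
    n_rec = 0
    flows = np.zeros((nbins if track_flows else 1, nbins if track_flows else 1), dtype=np.int64)

    cost = cost_full(assign, nb, w, norm, D)
    b = _clamp_bin(cost, lo, width, nbins)
    refresh = 1 << 20

    for step in range(steps):
        pos = sense[np.random.randint(0, n_sense)]
        old = assign[pos]
        new = np.random.randint(0, S - 1)
        if new >= old:
            new += 1
        accept = counts[old] - 1 >= minima[old]
        if accept:
            d = delta_flip(assign, pos, new, nb, w, norm, D)
            new_cost = cost + d
            b2 = _clamp_bin(new_cost, lo, width, nbins)
            if log_w[b2] < log_w[b]:
                accept = np.log(np.random.random()) < log_w[b2] - log_w[b]
            if accept:
                assign[pos] = np.int8(new)
                counts[old] -= 1
                counts[new] += 1
                cost = new_cost
                if track_flows:
                    flows[b, b2] += 1
                b = b2
            elif track_flows:
                flows[b, b] += 1
        elif track_flows:
            flows[b, b] += 1
        hist[b] += 1
        if thin > 0 and step % thin == 0:
            if cost < record_below and n_rec < max_records:
                for i in range(n_sites):
                    rec_assign[n_rec, i] = assign[i]
                rec_costs[n_rec] = cost
                n_rec += 1
        if step % refresh == refresh - 1:
            cost = cost_full(assign, nb, w, norm, D)
            b = _clamp_bin(cost, lo, width, nbins)
    return hist, rec_assign, rec_costs, n_rec, flows


@njit(cache=True)
def ga_kernel(
    n_runs,
    pop_size,
    n_gen,
    mu,
    retry_cap,
    nb,
    w,
    norm,
    D,
    sense,
    minima,
    vals,
    col_right,
    slice_lo,
    slice_hi,
    mutate_survivors,
    seed,
):
    """Batch of independent truncation-selection GA runs.

    Each generation the population is ranked by cost, the best half is
    kept, each survivor is copied exactly once (sampling without
    replacement), and the copies are mutated per element at rate ``mu``;
    a mutated copy that violates the ensemble constraints is redrawn from
    scratch.  With ``mutate_survivors`` nonzero the survivors are mutated
    too (the alternative reading of the scheme); the default 0 keeps them
    intact, which makes the best cost nonincreasing.

    Per run and generation the best individual's cost and its Delta_PR
    (mean property over right-half minus left-half sense codons) are
    recorded; the latest best code whose cost falls in
    [slice_lo, slice_hi) is retained for landscape analysis.
    Returns (best_cost, best_dpr, slice_assign, has_slice, final_assign,
    final_cost, n_retry_failures).
    """
    np.random.seed(seed)
    S = minima.shape[0]
    n_sense = sense.shape[0]
    n_sites = nb.shape[0]
    half = pop_size // 2

    best_cost = np.zeros((n_runs, n_gen), dtype=np.float64)
    best_dpr = np.zeros((n_runs, n_gen), dtype=np.float64)
    slice_assign = np.zeros((n_runs, n_sites), dtype=np.int8)
    has_slice = np.zeros(n_runs, dtype=np.bool_)
    final_assign = np.zeros((n_runs, n_sites), dtype=np.int8)
    final_cost = np.zeros(n_runs, dtype=np.float64)
    n_fail = 0

    # right/left column sizes over sense positions (fixed across codes)
    n_right = 0
    n_left = 0
    for i in range(n_sense):
        if col_right[sense[i]]:
            n_right += 1
        else:
            n_left += 1

    template = np.full(n_sites, -1, dtype=np.int8)

    pop = np.zeros((pop_size, n_sites), dtype=np.int8)
    cnt = np.zeros((pop_size, S), dtype=np.int64)
    costs = np.zeros(pop_size, dtype=np.float64)
    new_pop = np.zeros((pop_size, n_sites), dtype=np.int8)
    new_cnt = np.zeros((pop_size, S), dtype=np.int64)
    new_costs = np.zeros(pop_size, dtype=np.float64)
    work = np.zeros(n_sites, dtype=np.int8)
    work_cnt = np.zeros(S, dtype=np.int64)

    for run in range(n_runs):
        for i in range(pop_size):
            a0, c0, ok = random_valid_assign(template, sense, minima, S, 100000)
            pop[i] = a0
            cnt[i] = c0
            costs[i] = cost_full(a0, nb, w, norm, D)

        ib = 0
        for gen in range(n_gen):
            order = np.argsort(costs)
            # survivors + one mutated copy of each survivor
            for r in range(half):
                src = order[r]
                new_pop[r] = pop[src]
                new_cnt[r] = cnt[src]
                new_costs[r] = costs[src]
            first_mut = 0 if mutate_survivors else half
            for r in range(half, pop_size):
                new_pop[r] = new_pop[r - half]
                new_cnt[r] = new_cnt[r - half]
                new_costs[r] = new_costs[r - half]
            for r in range(first_mut, pop_size):
                ok = False
                for _try in range(retry_cap):
                    for i in range(n_sites):
                        work[i] = new_pop[r, i]
                    for s in range(S):
                        work_cnt[s] = new_cnt[r, s]
                    wcost = new_costs[r]
                    for i in range(n_sense):
                        if np.random.random() < mu:
                            posn = sense[i]
                            olda = work[posn]
                            na = np.random.randint(0, S - 1)
                            if na >= olda:
                                na += 1
                            wcost += delta_flip(work, posn, na, nb, w, norm, D)
                            work[posn] = np.int8(na)
                            work_cnt[olda] -= 1
                            work_cnt[na] += 1
                    valid = True
                    for s in range(S):
                        if work_cnt[s] < minima[s]:
                            valid = False
                            break
                    if valid:
                        ok = True
                        break
                if ok:
                    for i in range(n_sites):
                        new_pop[r, i] = work[i]
                    for s in range(S):
                        new_cnt[r, s] = work_cnt[s]
                    new_costs[r] = wcost
                else:
                    n_fail += 1  # keep the unmutated copy
            pop[:, :] = new_pop
            cnt[:, :] = new_cnt
            costs[:] = new_costs

            ib = 0
            for i in range(1, pop_size):
                if costs[i] < costs[ib]:
                    ib = i
            bc = costs[ib]
            sr = 0.0
            sl = 0.0
            for i in range(n_sense):
                v = vals[pop[ib, sense[i]]]
                if col_right[sense[i]]:
                    sr += v
                else:
                    sl += v
            best_cost[run, gen] = bc
            best_dpr[run, gen] = sr / n_right - sl / n_left
            if slice_lo <= bc < slice_hi:
                slice_assign[run] = pop[ib]
                has_slice[run] = True
        final_assign[run] = pop[ib]
        final_cost[run] = costs[ib]
    return best_cost, best_dpr, slice_assign, has_slice, final_assign, final_cost, n_fail
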