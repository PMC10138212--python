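"""Exact enumeration of constrained code ensembles.

The number of assignments of ``n`` free codons to an alphabet of amino
acids, subject to per-amino-acid minimum multiplicities, is computed by
inclusion-exclusion through exponential generating functions: each amino
acid with floor m contributes a factor (e^x - sum_{j<m} x^j/j!), and the
count is n! times the x^n coefficient of the product.  All arithmetic is
exact (Python integers / fractions).
"""

from __future__ import annotations

import math
from fractions import Fraction

from .codons import N_AA, N_SENSE
from .codons import EnsembleConstraints


def count_assignments(n_slots: int, minima) -> int:
    """Exact number of maps from ``n_slots`` slots onto symbols with the
    given per-symbol minimum multiplicities.

    ``minima[i] = 0`` leaves symbol i unconstrained, 1 requires presence
    (surjectivity), 2 requires two or more copies, etc.
    """
    minima = [int(m) for m in minima]
    if any(m < 0 for m in minima):
        raise ValueError("minima must be nonnegative")
    if sum(minima) > n_slots:
        return 0

    # DP over factors: terms[k] = polynomial coefficients (Fractions) of
    # the product of the non-exponential parts, for k factors contributing
    # their e^x part.  Each factor is (e^x - t_m(x)), t_m = truncated exp.
    terms: dict[int, list[Fraction]] = {0: [Fraction(1)]}
    for m in minima:
        trunc = [Fraction(-1, math.factorial(j)) for j in range(m)]
        new: dict[int, list[Fraction]] = {}

        def _acc(k, poly):
            cur = new.setdefault(k, [])
            if len(cur) < len(poly):
                cur.extend([Fraction(0)] * (len(poly) - len(cur)))
            for t, c in enumerate(poly):
                cur[t] += c

        for k, poly in terms.items():
            _acc(k + 1, poly)  # this factor takes e^x
            if trunc:  # this factor takes -t_m(x)
                prod = [Fraction(0)] * (len(poly) + len(trunc) - 1)
                for t1, c1 in enumerate(poly):
                    if c1 == 0:
                        continue
                    for t2, c2 in enumerate(trunc):
                        prod[t1 + t2] += c1 * c2
                _acc(k, prod)
        terms = new

    # n! [x^n] x^t e^{kx} = n!/(n-t)! * k^(n-t)
    total = Fraction(0)
    for k, poly in terms.items():
        for t, c in enumerate(poly):
            if c == 0 or t > n_slots:
                continue
            ff = math.perm(n_slots, t)
            power = k ** (n_slots - t) if n_slots > t else 1
            if k == 0 and n_slots > t:
                power = 0
            total += c * ff * power
    if total.denominator != 1:
        raise AssertionError("inclusion-exclusion did not yield an integer")
    return int(total)


def count_ensemble(constraints: EnsembleConstraints) -> tuple[int, float]:
    """Exact size of the constrained random-code ensemble and its log10.

    The three stop codons are pinned, leaving 61 free codons over 20 amino
    acids; the default constraints (all 20 present, >= 2 Asp and Glu) give
    about 6.1e78 codes.
    """
    if not constraints.stop_positions_fixed:
        raise ValueError("counting assumes the stop positions are fixed")
    count = count_assignments(N_SENSE, constraints.minima())
    log10 = _log10_int(count) if count > 0 else float("-inf")
    return count, log10


def _log10_int(n: int) -> float:
    """log10 of a (possibly huge) positive integer, to float precision."""
    digits = len(str(n))
    scale = max(digits - 17, 0)
    return math.log10(n // 10 ** scale) + scale


def brute_force_count(n_slots: int, n_symbols: int, minima) -> int:
    """Direct enumeration oracle for tiny spaces (n_symbols**n_slots states)."""
    import itertools

    if n_symbols ** n_slots > 10 ** 7:
        raise ValueError("brute-force space too large")
    total = 0
    for a in itertools.product(range(n_symbols), repeat=n_slots):
        counts = [0] * n_symbols
        for x in a:
            counts[x] += 1
        if all(c >= m for c, m in zip(counts, minima)):
            total += 1
    return total
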