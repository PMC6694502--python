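"""Independent oracles used across the test suite.

Each oracle recomputes a quantity by a route deliberately different from
the package implementation: exhaustive enumeration, exact integer
arithmetic, or a second formulation of the same optimization problem.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

from sgprflux.integration import IntegrationConfig, ReactionScoreSet, imat_partition
from sgprflux.model import MetabolicModel
from sgprflux.solver import InfeasibleProblemError, ProblemBuilder


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by column-wise exact enumeration.

    Counts orderings by distributing the first-row total over the two
    columns (the implementation distributes the first-column total over
    rows); probabilities are exact rationals, so ties are exact.
    """
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def count(k: int) -> int:
        # choose which of the col1 first-column items fall in row 1 (k of them)
        # and which of the n - col1 second-column items fall in row 1
        if k < 0 or k > col1 or row1 - k < 0 or row1 - k > n - col1:
            return 0
        return math.comb(col1, k) * math.comb(n - col1, row1 - k)

    observed = count(a)
    total = math.comb(n, row1)
    tail = sum(count(k) for k in range(0, col1 + 1) if 0 < count(k) <= observed)
    return Fraction(tail, total)


def mannwhitney_two_sided_oracle(x: list[float], y: list[float]) -> Fraction:
    """Exact two-sided Mann-Whitney p by full permutation enumeration.

    Enumerates every C(n+m, n) split of the pooled (tie-free) sample and
    counts splits whose U statistic is at least as extreme as observed.
    """
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free samples"
    n = len(x)

    def u_stat(xs: tuple[float, ...]) -> int:
        ys = [v for v in pooled if v not in xs]
        return sum(1 for xi in xs for yj in ys if xi > yj)

    observed = u_stat(tuple(x))
    mean_u = len(x) * len(y) / 2
    dev = abs(observed - mean_u)
    hits = total = 0
    for xs in itertools.combinations(pooled, n):
        total += 1
        if abs(u_stat(xs) - mean_u) >= dev - 1e-12:
            hits += 1
    return Fraction(hits, total)


def imat_bruteforce_optimum(
    model: MetabolicModel,
    scores: ReactionScoreSet,
    config: IntegrationConfig,
) -> int:
    """Max iMAT reward by enumerating all activity assignments.

    Every highly-expressed reaction independently tries
    {forward-active, backward-active, unrewarded}; every lowly-expressed
    reaction tries {off, unrewarded}.  Each combination is checked for LP
    feasibility; the best feasible reward is returned.
    """
    labels, _ = imat_partition(scores, config)
    high = sorted(r for r, l in labels.items() if l == "high")
    low = sorted(r for r, l in labels.items() if l == "low")
    eps, eps0 = config.flux_epsilon, config.activity_epsilon

    def feasible(assign_high: tuple[str, ...], assign_low: tuple[bool, ...]) -> bool:
        pb = ProblemBuilder()
        names = model.add_flux_variables(pb)
        for rid, choice in zip(high, assign_high):
            if choice == "fwd":
                pb.add_constraint({names[rid]: 1.0}, eps)
            elif choice == "rev":
                pb.add_constraint({names[rid]: 1.0}, -math.inf, -eps)
        for rid, off in zip(low, assign_low):
            if off:
                pb.add_constraint({names[rid]: 1.0}, -eps0, eps0)
        try:
            pb.solve()
            return True
        except InfeasibleProblemError:
            return False

    best = 0
    for hi_choice in itertools.product(("fwd", "rev", "none"), repeat=len(high)):
        reward_hi = sum(1 for c in hi_choice if c != "none")
        for lo_choice in itertools.product((True, False), repeat=len(low)):
            reward = reward_hi + sum(lo_choice)
            if reward <= best:
                continue
            if feasible(hi_choice, lo_choice):
                best = reward
    return best
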