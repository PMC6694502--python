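"""Prediction-vs-measurement evaluation and pathway over-activation.

The qualitative evaluation loop: replicate metabolite peak areas at two
incubation time points are turned into consumption/production calls
(exact Mann-Whitney between t0 and t5h, direction by median change);
predicted exchange activity (a metabolite is predicted exchanged when
either its uptake or secretion reaction carries flux) is tabulated
against those calls in a 2x2 table; agreement is summarized as the
right-prediction proportion with a two-sided Fisher exact p-value, and
the S-GPR-over-GPR improvement as the percentage-point gain in that
proportion.  Pathway over-activation compares per-pathway active-reaction
counts between two conditions (relative weight, exclusivity, t-test).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Literal

import pandas as pd
from scipy import stats

from .integration import ActivityState

__all__ = [
    "MetaboliteMeasurement",
    "ExchangeCall",
    "ComparisonResult",
    "PathwayActivity",
    "PathwayActivityReport",
    "fisher_exact_2x2",
    "call_exchanges",
    "compare_predictions",
    "improvement",
    "activity_difference",
    "pathway_overactivation",
    "read_measurements",
    "write_measurements",
]

logger = logging.getLogger(__name__)

#: above this per-group size the large-sample Mann-Whitney approximation is used
EXACT_TEST_MAX_N = 25


@dataclass
class MetaboliteMeasurement:
    """Replicate peak areas for one metabolite at t0 and t5h."""

    metabolite_id: str
    t0: list[float]
    t5: list[float]
    condition: str = ""

    def __post_init__(self) -> None:
        for areas in (self.t0, self.t5):
            if any(a <= 0 for a in areas):
                raise ValueError(
                    f"{self.metabolite_id!r}: peak areas must be positive, got {areas}"
                )


@dataclass
class ExchangeCall:
    """Measured consumption/production calls per metabolite."""

    calls: dict[str, Literal["consumed", "produced", "unchanged"]]
    p_value: dict[str, float]
    untestable: set[str] = field(default_factory=set)


@dataclass
class ComparisonResult:
    """2x2 agreement between predicted exchange activity and measurement.

    Orientation: rows = predicted {active, inactive}, columns = measured
    {exchange, no exchange}; a and d are the concordant (right) cells.
    """

    a: int  # predicted active,   measured exchange
    b: int  # predicted active,   measured no exchange
    c: int  # predicted inactive, measured exchange
    d: int  # predicted inactive, measured no exchange
    fisher_p: float
    metabolites: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def right_proportion(self) -> float:
        return (self.a + self.d) / self.n


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table, by hypergeometric tail sum.

    All tables with the observed margins are enumerated; those whose
    probability does not exceed the observed table's are summed.  The
    comparison is done on exact integer numerators (every table shares the
    denominator C(N, a+c)), so probability ties are handled exactly.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    row1, col1 = a + b, a + c
    count = lambda k: math.comb(row1, k) * math.comb(n - row1, col1 - k)
    observed = count(a)
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    total = math.comb(n, col1)
    tail = sum(count(k) for k in range(lo, hi + 1) if count(k) <= observed)
    return tail / total


def call_exchanges(
    measurements: list[MetaboliteMeasurement], alpha: float = 0.05
) -> ExchangeCall:
    """Mann-Whitney consumption/production calls from replicate peak areas.

    A metabolite is called exchanged when the two-sided test between t0
    and t5h replicates is significant at ``alpha``; direction follows the
    median change (increase -> produced, decrease -> consumed).  Exact
    p-values are used up to 25 replicates per group, the normal
    approximation above.  Metabolites with fewer than 2 replicates in
    either group are flagged untestable.
    """
    calls: dict[str, str] = {}
    pvals: dict[str, float] = {}
    untestable: set[str] = set()
    for m in measurements:
        if len(m.t0) < 2 or len(m.t5) < 2:
            untestable.add(m.metabolite_id)
            continue
        method = "exact" if max(len(m.t0), len(m.t5)) <= EXACT_TEST_MAX_N else "asymptotic"
        p = float(stats.mannwhitneyu(m.t0, m.t5, alternative="two-sided", method=method).pvalue)
        pvals[m.metabolite_id] = p
        if p < alpha:
            calls[m.metabolite_id] = "produced" if median(m.t5) > median(m.t0) else "consumed"
        else:
            calls[m.metabolite_id] = "unchanged"
    return ExchangeCall(calls=calls, p_value=pvals, untestable=untestable)  # type: ignore[arg-type]


def compare_predictions(
    pred: ActivityState,
    calls: ExchangeCall,
    metabolite_exchanges: dict[str, list[str]],
    alpha: float = 0.05,
) -> ComparisonResult:
    """Tabulate predicted exchange activity against measured calls.

    ``metabolite_exchanges`` maps each measured metabolite to its
    uptake/secretion exchange reaction ids; the metabolite is
    predicted-active when any of them is active.  Only metabolites with
    both a testable call and a mapping are evaluable.
    """
    a = b = c = d = 0
    used: list[str] = []
    for met, call in sorted(calls.calls.items()):
        rids = [r for r in metabolite_exchanges.get(met, []) if r in pred.states]
        if not rids:
            continue
        used.append(met)
        predicted_active = any(pred.states[r] == "active" for r in rids)
        measured_exchange = call != "unchanged"
        if predicted_active and measured_exchange:
            a += 1
        elif predicted_active:
            b += 1
        elif measured_exchange:
            c += 1
        else:
            d += 1
    if not used:
        raise ValueError("no evaluable metabolites (no overlap of calls and exchange map)")
    return ComparisonResult(
        a=a, b=b, c=c, d=d, fisher_p=fisher_exact_2x2(a, b, c, d), metabolites=tuple(used)
    )


def improvement(gpr_result: ComparisonResult, sgpr_result: ComparisonResult) -> float:
    """Percentage-point gain of S-GPR over GPR in right-prediction proportion."""
    if set(gpr_result.metabolites) != set(sgpr_result.metabolites):
        raise ValueError("comparison results cover different metabolite sets")
    return 100.0 * (sgpr_result.right_proportion - gpr_result.right_proportion)


def activity_difference(state_a: ActivityState, state_b: ActivityState) -> float:
    """Percent of reactions whose activity label differs between two states."""
    if set(state_a.states) != set(state_b.states):
        raise ValueError("activity states cover different reaction sets")
    if not state_a.states:
        raise ValueError("empty activity states")
    diff = sum(1 for r, s in state_a.states.items() if state_b.states[r] != s)
    return 100.0 * diff / len(state_a.states)


@dataclass
class PathwayActivity:
    pathway: str
    n_active: dict[str, int]  # condition -> active reaction count
    n_reactions: int
    relative_weight: float | None  # treated / reference; None when EXCLUSIVE or 0/0
    exclusive: bool  # active only in the treated condition
    p_value: float


@dataclass
class PathwayActivityReport:
    reference_condition: str
    treated_condition: str
    pathways: dict[str, PathwayActivity]

    def overactivated(self, alpha: float = 0.05) -> list[PathwayActivity]:
        """Pathways more active in the treated condition (weight > 1 or exclusive)."""
        out = [
            p
            for p in self.pathways.values()
            if (p.exclusive or (p.relative_weight or 0.0) > 1.0) and p.p_value < alpha
        ]
        return sorted(out, key=lambda p: p.pathway)


def _indicator_ttest(x: list[int], y: list[int]) -> float:
    """Two-sample t-test on 0/1 activity indicators; degenerate-safe."""
    if x == y:
        return 1.0
    if len(set(x)) == 1 and len(set(y)) == 1:
        # constant but different vectors: no within-group variance at all
        return 0.0 if x[0] != y[0] else 1.0
    return float(stats.ttest_ind(x, y).pvalue)


def pathway_overactivation(
    states_by_condition: dict[str, ActivityState],
    pathway_map: dict[str, str],
) -> PathwayActivityReport:
    """Per-pathway activity comparison between two conditions.

    ``states_by_condition`` must hold exactly two entries; the first is
    the reference (denominator of the relative weight), the second the
    treated condition.  A pathway with active reactions only in the
    treated condition is flagged exclusive instead of getting a weight.
    Significance is a two-sample t-test on the pathway's per-reaction 0/1
    activity indicators between conditions.
    """
    if len(states_by_condition) != 2:
        raise ValueError("pathway comparison requires exactly two conditions")
    (ref_name, ref_state), (trt_name, trt_state) = states_by_condition.items()
    pathways: dict[str, list[str]] = {}
    for rid, pw in pathway_map.items():
        if pw is not None:
            pathways.setdefault(pw, []).append(rid)

    report: dict[str, PathwayActivity] = {}
    for pw, rids in sorted(pathways.items()):
        rids = [r for r in rids if r in ref_state.states and r in trt_state.states]
        if not rids:
            logger.info("pathway %s has no reactions in the activity states; skipped", pw)
            continue
        rids.sort()
        ref_ind = [1 if ref_state.states[r] == "active" else 0 for r in rids]
        trt_ind = [1 if trt_state.states[r] == "active" else 0 for r in rids]
        n_ref, n_trt = sum(ref_ind), sum(trt_ind)
        exclusive = n_ref == 0 and n_trt > 0
        weight = (n_trt / n_ref) if n_ref > 0 else None
        report[pw] = PathwayActivity(
            pathway=pw,
            n_active={ref_name: n_ref, trt_name: n_trt},
            n_reactions=len(rids),
            relative_weight=weight,
            exclusive=exclusive,
            p_value=_indicator_ttest(ref_ind, trt_ind),
        )
    return PathwayActivityReport(
        reference_condition=ref_name, treated_condition=trt_name, pathways=report
    )


# ---------------------------------------------------------------------------
# Measurement table I/O (TSV: metabolite, timepoint, area; one row/replicate)
# ---------------------------------------------------------------------------

def read_measurements(path: str | Path, condition: str = "") -> list[MetaboliteMeasurement]:
    df = pd.read_csv(path, sep="\t")
    required = {"metabolite", "timepoint", "area"}
    if missing := required - set(df.columns):
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    out = []
    for met, grp in df.groupby("metabolite", sort=True):
        t0 = grp.loc[grp.timepoint == "t0", "area"].astype(float).tolist()
        t5 = grp.loc[grp.timepoint == "t5", "area"].astype(float).tolist()
        out.append(MetaboliteMeasurement(str(met), t0, t5, condition=condition))
    return out


def write_measurements(measurements: list[MetaboliteMeasurement], path: str | Path) -> None:
    rows = []
    for m in measurements:
        rows += [{"metabolite": m.metabolite_id, "timepoint": "t0", "area": a} for a in m.t0]
        rows += [{"metabolite": m.metabolite_id, "timepoint": "t5", "area": a} for a in m.t5]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
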