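"""Differential AS event calling with the replicate direction-consistency rule.

Replicates of each condition are pooled and a single Bayes factor is
computed on the pooled counts; an event is called differential when the
pooled BF reaches the threshold (default 20) AND the per-replicate dPSI
point estimates all share the sign of the pooled dPSI.  Replicates are
paired by index across conditions (replicate i of A against replicate i of
B).  Events whose pooled read total falls below an information floor in
either condition are reported untestable instead of called.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from typing import Iterable, Sequence

from .models import (
    ContrastResult,
    DifferentialCall,
    EventCounts,
    SpliceEvent,
    sign,
)
from .psi import DEFAULT_GRID_SIZE, bayes_factor, estimate_psi

logger = logging.getLogger(__name__)

DEFAULT_BF_THRESHOLD = 20.0
DEFAULT_MIN_INFO = 10


def pool_replicates(counts: Iterable[EventCounts | tuple[int, int]]) -> tuple[int, int]:
    """Element-wise sum of (n_inc, n_exc) over replicates of one condition."""
    total_inc = total_exc = 0
    n = 0
    for c in counts:
        if isinstance(c, EventCounts):
            total_inc += c.n_inc
            total_exc += c.n_exc
        else:
            total_inc += int(c[0])
            total_exc += int(c[1])
        n += 1
    if n == 0:
        raise ValueError("pool_replicates requires at least one replicate")
    return total_inc, total_exc


def call_differential(
    event: SpliceEvent,
    counts_a: Sequence[tuple[int, int]],
    counts_b: Sequence[tuple[int, int]],
    bf_threshold: float = DEFAULT_BF_THRESHOLD,
    min_info: int = DEFAULT_MIN_INFO,
    epsilon: float = 0.0,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> DifferentialCall:
    """Two-part differential call for one event.

    ``counts_a`` / ``counts_b`` are per-replicate (n_inc, n_exc) pairs in
    matching order.  A per-replicate |dPSI| <= ``epsilon`` (default 0, i.e.
    only an exact zero) fails the same-direction requirement.
    """
    if len(counts_a) != len(counts_b):
        raise ValueError(
            f"event {event.event_id!r}: {len(counts_a)} replicates in A vs "
            f"{len(counts_b)} in B; replicates must pair by index"
        )
    if not counts_a:
        raise ValueError("at least one replicate per condition is required")
    pooled_a = pool_replicates(counts_a)
    pooled_b = pool_replicates(counts_b)

    testable = sum(pooled_a) >= min_info and sum(pooled_b) >= min_info
    if not testable:
        return DifferentialCall(
            event_id=event.event_id,
            category=event.category,
            gene_id=event.gene_id,
            bf=math.nan,
            delta_psi_pooled=math.nan,
            replicate_delta_psis=(),
            direction="none",
            significant=False,
            testable=False,
        )

    bf_res = bayes_factor(
        pooled_a, pooled_b, event.l_inc, event.l_exc, grid_size, event.event_id
    )
    rep_dpsis = []
    for (ai, ae), (bi, be) in zip(counts_a, counts_b):
        psi_a = estimate_psi(ai, ae, event.l_inc, event.l_exc, grid_size).psi_mean
        psi_b = estimate_psi(bi, be, event.l_inc, event.l_exc, grid_size).psi_mean
        rep_dpsis.append(psi_b - psi_a)

    pooled_sign = sign(bf_res.delta_psi)
    consistent = pooled_sign != 0 and all(
        abs(d) > epsilon and sign(d) == pooled_sign for d in rep_dpsis
    )
    significant = bf_res.bf >= bf_threshold and consistent and not bf_res.uninformative
    if significant:
        direction = "included" if bf_res.delta_psi > 0 else "excluded"
    else:
        direction = "none"
    return DifferentialCall(
        event_id=event.event_id,
        category=event.category,
        gene_id=event.gene_id,
        bf=bf_res.bf,
        delta_psi_pooled=bf_res.delta_psi,
        replicate_delta_psis=tuple(rep_dpsis),
        direction=direction,
        significant=significant,
        testable=True,
    )


def _counts_by_event_condition(
    counts: Iterable[EventCounts],
) -> dict[str, dict[str, list[EventCounts]]]:
    table: dict[str, dict[str, list[EventCounts]]] = defaultdict(lambda: defaultdict(list))
    for c in counts:
        table[c.event_id][c.condition].append(c)
    for conds in table.values():
        for reps in conds.values():
            reps.sort(key=lambda c: c.replicate)
    return table


def run_contrast(
    catalog: Sequence[SpliceEvent],
    counts: Iterable[EventCounts],
    condition_a: str,
    condition_b: str,
    contrast_label: str,
    bf_threshold: float = DEFAULT_BF_THRESHOLD,
    min_info: int = DEFAULT_MIN_INFO,
    epsilon: float = 0.0,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> ContrastResult:
    """Call every catalog event for one contrast (condition B minus A).

    Events with no counts in either condition are skipped; events below the
    information floor are kept as untestable calls.
    """
    table = _counts_by_event_condition(counts)
    calls = []
    for event in catalog:
        conds = table.get(event.event_id)
        if not conds or condition_a not in conds or condition_b not in conds:
            continue
        reps_a = [(c.n_inc, c.n_exc) for c in conds[condition_a]]
        reps_b = [(c.n_inc, c.n_exc) for c in conds[condition_b]]
        calls.append(
            call_differential(
                event, reps_a, reps_b, bf_threshold, min_info, epsilon, grid_size
            )
        )
    result = ContrastResult(contrast_label=contrast_label, calls=calls)
    logger.info(
        "contrast %s: %d events with counts, %d testable, %d significant",
        contrast_label,
        len(calls),
        result.n_tested,
        result.n_significant,
    )
    return result
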