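"""Gene-set enrichment of differentially spliced genes and dPSI comparisons.

Two questions about an RBP substrate set (or a cancer gene list): are the
genes whose splicing changed over-represented in the set (upper-tail
hypergeometric on the universe of genes eligible for testing), and do the
dPSI values of events in substrate genes follow a different distribution
from those in non-substrate genes (two-sample Kolmogorov-Smirnov, on
|dPSI| by default since the question is about magnitude)?

Enrichment is gene-level (a gene counts once however many events it has);
the K-S comparison keeps event-level granularity.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

from scipy import stats

from .models import (
    DifferentialCall,
    EnrichmentResult,
    KsComparison,
    SubstrateSet,
)

logger = logging.getLogger(__name__)

# Both samples at or below this size use the exact K-S null distribution.
KS_EXACT_MAX_N = 25


def hypergeometric_enrichment(
    differential_genes: Iterable[str],
    substrate_set: SubstrateSet,
    universe_genes: Iterable[str],
) -> EnrichmentResult:
    """P(X >= k) for the overlap of differential genes with a gene set.

    The set is intersected with the universe before testing; differential
    genes must all lie inside the universe.
    """
    universe = set(universe_genes)
    if not universe:
        raise ValueError("universe is empty")
    diff = set(differential_genes)
    outside = diff - universe
    if outside:
        raise ValueError(
            f"{len(outside)} differential genes outside the universe, "
            f"e.g. {sorted(outside)[:3]}"
        )
    members = substrate_set.gene_ids & universe
    N, K, n = len(universe), len(members), len(diff)
    k = len(diff & members)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
    return EnrichmentResult(
        set_name=substrate_set.set_name, k=k, n=n, K=K, N=N, p_value=min(p, 1.0)
    )


def ks_delta_psi(
    calls: Sequence[DifferentialCall],
    substrate_set: SubstrateSet,
    magnitude_mode: str = "absolute",
) -> KsComparison:
    """Two-sample K-S test of dPSI between substrate and non-substrate events.

    ``magnitude_mode`` "absolute" compares |dPSI| (the default — the
    scientific question is whether the *magnitude* of splicing change
    differs), "signed" compares raw dPSI.  Returns NaN statistics when
    either group is empty (untested).
    """
    if magnitude_mode not in ("absolute", "signed"):
        raise ValueError(f"unknown magnitude_mode {magnitude_mode!r}")
    transform = abs if magnitude_mode == "absolute" else float
    in_set: list[float] = []
    out_set: list[float] = []
    for call in calls:
        value = transform(call.delta_psi_pooled)
        (in_set if call.gene_id in substrate_set.gene_ids else out_set).append(value)
    if not in_set or not out_set:
        logger.warning(
            "K-S for %s untested: %d substrate vs %d non-substrate events",
            substrate_set.set_name,
            len(in_set),
            len(out_set),
        )
        return KsComparison(
            set_name=substrate_set.set_name,
            d_statistic=0.0,
            p_value=math.nan,
            n_substrate_events=len(in_set),
            n_other_events=len(out_set),
            magnitude_mode=magnitude_mode,
        )
    method = (
        "exact"
        if len(in_set) <= KS_EXACT_MAX_N and len(out_set) <= KS_EXACT_MAX_N
        else "asymp"
    )
    res = stats.ks_2samp(in_set, out_set, method=method)
    return KsComparison(
        set_name=substrate_set.set_name,
        d_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_substrate_events=len(in_set),
        n_other_events=len(out_set),
        magnitude_mode=magnitude_mode,
    )
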