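"""Treatment/disease intersection and switch-toward-non-tumor classification.

Events called differential in BOTH contrasts (treatment: drug vs control;
disease: tumor vs normal, dPSI oriented tumor minus normal) are
intersected by event id.  A shared event is *switched* when the treatment
dPSI sign opposes the disease dPSI sign — the drug moves splicing away
from the tumor profile, toward the non-tumor one.  Sign opposition alone
defines the switch; an optional stricter mode additionally requires the
treatment to restore the non-tumor magnitude within a tolerance.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from typing import Sequence

from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .composition import SMALL_CELL_FISHER
from .models import (
    ContrastResult,
    EnrichmentResult,
    SwitchCall,
    SwitchSummary,
)
from .enrichment import hypergeometric_enrichment
from .models import SubstrateSet

logger = logging.getLogger(__name__)


def intersect_contrasts(
    treatment: ContrastResult, disease: ContrastResult
) -> list[dict]:
    """Events significant in both contrasts, with both dPSI values attached.

    Returns one record per shared event: event_id, category, treat_dpsi,
    disease_dpsi.  Warns when the two contrasts share no event ids at all.
    """
    treat_sig = {c.event_id: c for c in treatment.significant_calls()}
    disease_sig = {c.event_id: c for c in disease.significant_calls()}
    all_treat = {c.event_id for c in treatment.calls}
    all_disease = {c.event_id for c in disease.calls}
    if all_treat and all_disease and not (all_treat & all_disease):
        logger.warning(
            "contrasts %s and %s share no event ids; intersection is empty",
            treatment.contrast_label,
            disease.contrast_label,
        )
    shared = []
    for event_id in sorted(set(treat_sig) & set(disease_sig)):
        t, d = treat_sig[event_id], disease_sig[event_id]
        shared.append(
            {
                "event_id": event_id,
                "category": t.category,
                "treat_dpsi": t.delta_psi_pooled,
                "disease_dpsi": d.delta_psi_pooled,
            }
        )
    return shared


def classify_switch(
    shared: Sequence[dict],
    require_magnitude_restoration: bool = False,
    magnitude_tolerance: float = 0.1,
) -> list[SwitchCall]:
    """Switch verdict for every shared event.

    Switched = both dPSI nonzero with opposite signs.  With
    ``require_magnitude_restoration`` the treatment |dPSI| must also lie
    within ``magnitude_tolerance`` of the disease |dPSI|.
    """
    calls = []
    for rec in shared:
        t, d = rec["treat_dpsi"], rec["disease_dpsi"]
        switched = t != 0 and d != 0 and (t > 0) != (d > 0)
        if switched and require_magnitude_restoration:
            switched = abs(abs(t) - abs(d)) <= magnitude_tolerance
            # the stricter mode can only veto, keeping the flag-invariant
            # sign semantics: a vetoed event is reported as not switched
            if not switched:
                calls.append(
                    SwitchCall(
                        event_id=rec["event_id"],
                        category=rec["category"],
                        treat_dpsi=t,
                        disease_dpsi=d,
                        switched=False,
                    )
                )
                continue
        calls.append(
            SwitchCall(
                event_id=rec["event_id"],
                category=rec["category"],
                treat_dpsi=t,
                disease_dpsi=d,
                switched=switched,
            )
        )
    return calls


def switch_summary(
    treatment: ContrastResult | int,
    shared: Sequence[dict] | int,
    switch_calls: Sequence[SwitchCall] | int,
) -> SwitchSummary:
    """Counts and percentages of the intersection and switched subset.

    Accepts the pipeline objects, or raw integers for printed-count
    arithmetic (e.g. checking a published 254-of-406 figure).
    """
    n_treat = (
        treatment if isinstance(treatment, int) else treatment.n_significant
    )
    n_shared = shared if isinstance(shared, int) else len(shared)
    n_switched = (
        switch_calls
        if isinstance(switch_calls, int)
        else sum(1 for c in switch_calls if c.switched)
    )
    return SwitchSummary.from_counts(n_treat, n_shared, n_switched)


def overlap_significance(
    treatment: ContrastResult, disease: ContrastResult
) -> EnrichmentResult:
    """Hypergeometric test of the shared-set size at event granularity.

    Universe = events testable in both contrasts; is the overlap of the two
    significant sets larger than chance?
    """
    universe = {c.event_id for c in treatment.calls if c.testable} & {
        c.event_id for c in disease.calls if c.testable
    }
    treat_sig = {c.event_id for c in treatment.significant_calls()} & universe
    disease_sig = {c.event_id for c in disease.significant_calls()} & universe
    disease_set = SubstrateSet(
        set_name=f"{disease.contrast_label}_significant",
        gene_ids=frozenset(disease_sig) if disease_sig else frozenset({"__none__"}),
    )
    return hypergeometric_enrichment(treat_sig, disease_set, universe)


def switched_category_enrichment(
    switch_calls: Sequence[SwitchCall],
    disease_counts_by_category: dict[str, int],
) -> dict[str, tuple[float, float]]:
    """Per-category (raw, Bonferroni-adjusted) p comparing the category mix of
    switched events against the disease-dysregulated mix.

    Two-proportion test of (switched in category / all switched) vs
    (disease-dysregulated in category / all disease-dysregulated), Fisher's
    exact for small cells.  All-zero switched events → NaN everywhere.
    """
    switched = [c for c in switch_calls if c.switched]
    n_switched = len(switched)
    n_disease = sum(disease_counts_by_category.values())
    categories = sorted(
        set(disease_counts_by_category) | {c.category for c in switched}
    )
    if n_switched == 0 or n_disease == 0:
        return {cat: (math.nan, math.nan) for cat in categories}
    switched_by_cat = Counter(c.category for c in switched)
    raw: dict[str, float] = {}
    for cat in categories:
        k1 = switched_by_cat.get(cat, 0)
        k2 = disease_counts_by_category.get(cat, 0)
        if k1 == 0 and k2 == 0:
            raw[cat] = math.nan
            continue
        cells = (k1, n_switched - k1, k2, n_disease - k2)
        if min(cells) < SMALL_CELL_FISHER:
            table = [[k1, n_switched - k1], [k2, n_disease - k2]]
            raw[cat] = float(stats.fisher_exact(table, alternative="two-sided")[1])
        else:
            _, p = proportions_ztest(
                [k1, k2], [n_switched, n_disease], alternative="two-sided"
            )
            raw[cat] = float(p)
    m = sum(1 for p in raw.values() if not math.isnan(p))
    return {
        cat: (p, min(p * m, 1.0) if not math.isnan(p) else math.nan)
        for cat, p in raw.items()
    }
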