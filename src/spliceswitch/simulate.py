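"""Synthetic splice-junction data with known ground truth.

Emulates the study design downstream stages expect: two contrasts over the
same event catalog — a treatment contrast (apigenin vs DMSO in tumor cells)
and a disease contrast (TNBC tumors vs normal breast tissue) — each with
replicate inclusion/exclusion read counts per event, plus a truth table
recording the planted per-condition psi, differential flags, RBP substrate
labels and switch events (sign opposition between the two contrasts).

Three stages, each with its own RNG stream spawned from the master seed:

1. ``generate_event_catalog`` — events over the seven categories with
   effective lengths and plausible coordinates; some genes carry several
   events.
2. ``simulate_truth`` — per-event true psi in all four conditions.  A
   differential event gets a signed effect |dpsi| drawn from a stated range;
   the baseline psi is drawn Beta(2,2)-shaped on the interval that keeps
   psi + effect inside [margin, 1-margin], so every requested effect is
   representable.  Substrate membership is planted per gene with an odds
   multiplier conditional on the gene carrying a treatment-differential
   event, and an optional |dpsi| magnitude shift for one RBP's substrates.
3. ``simulate_counts`` — per sample, a total read count from a
   negative-binomial (or Poisson) coverage model, then inclusion reads
   binomial in the length-corrected read-class probability f(psi_true).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .models import (
    CATEGORIES,
    DISEASE_CONDITIONS,
    RBP_NAMES,
    TREATMENT_CONDITIONS,
    EventCounts,
    SimTruth,
    SpliceEvent,
)

# Margin keeping true psi away from the [0,1] boundary, where the binomial
# read model degenerates and no effect could be planted in one direction.
PSI_MARGIN = 0.02

#: Number of segments drawn per category (alternative regions involved).
_SEGMENTS_PER_CATEGORY = {
    "SE": 3,
    "RI": 2,
    "A5SS": 2,
    "A3SS": 2,
    "MXE": 4,
    "AFE": 2,
    "ALE": 2,
}


@dataclass(frozen=True)
class SubstrateParams:
    """Planted substrate structure for one RBP.

    ``rate`` is the marginal membership probability per gene;
    ``enrichment_odds`` multiplies the membership odds for genes carrying at
    least one treatment-differential event; ``magnitude_shift`` is added to
    |dpsi| of treatment-differential events in substrate genes (0 = none).
    """

    rate: float = 0.12
    enrichment_odds: float = 3.0
    magnitude_shift: float = 0.0


#: Default substrate structure: all three RBPs enriched among differentially
#: spliced genes, but only hnRNPA2 substrates carry a dPSI magnitude shift.
DEFAULT_SUBSTRATE_CONFIG: dict[str, SubstrateParams] = {
    "hnRNPA2": SubstrateParams(rate=0.12, enrichment_odds=3.0, magnitude_shift=0.15),
    "MSI2": SubstrateParams(rate=0.12, enrichment_odds=3.0, magnitude_shift=0.0),
    "CELF1": SubstrateParams(rate=0.12, enrichment_odds=3.0, magnitude_shift=0.0),
}


@dataclass(frozen=True)
class CategoryBias:
    """Optional per-category skew of the treatment contrast.

    ``differential_odds`` multiplies the event's chance of being treatment-
    differential; ``prob_excluded`` is the probability that a differential
    effect is negative (exclusion).  Defaults are neutral.
    """

    differential_odds: float = 1.0
    prob_excluded: float = 0.5


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_event_catalog(
    n_per_category: int,
    length_range: tuple[int, int] = (20, 200),
    seed: int = 0,
    events_per_gene_mean: float = 1.5,
) -> list[SpliceEvent]:
    """Draw ``7 * n_per_category`` events, ``n_per_category`` per category.

    Gene ids are assigned so that genes carry on average
    ``events_per_gene_mean`` events, giving multi-event genes for gene-level
    deduplication downstream.  Deterministic given ``seed``.
    """
    if n_per_category < 1:
        raise ValueError(f"n_per_category must be >= 1, got {n_per_category}")
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError(f"bad length range {length_range}")
    rng = _streams(seed, 1)[0]
    n_events = 7 * n_per_category
    n_genes = max(1, int(round(n_events / events_per_gene_mean)))
    gene_of = rng.integers(0, n_genes, size=n_events)
    events: list[SpliceEvent] = []
    idx = 0
    for category in CATEGORIES:
        for _ in range(n_per_category):
            chrom = f"chr{rng.integers(1, 23)}"
            strand = "+" if rng.random() < 0.5 else "-"
            n_seg = _SEGMENTS_PER_CATEGORY[category]
            pos = int(rng.integers(10_000, 100_000_000))
            segments = []
            for _ in range(n_seg):
                seg_len = int(rng.integers(50, 500))
                segments.append((pos, pos + seg_len - 1))
                pos += seg_len + int(rng.integers(100, 5_000))
            events.append(
                SpliceEvent(
                    event_id=f"{category}_{idx:06d}",
                    gene_id=f"GENE{gene_of[idx]:05d}",
                    category=category,
                    chrom=chrom,
                    strand=strand,
                    segments=tuple(segments),
                    l_inc=int(rng.integers(lo, hi + 1)),
                    l_exc=int(rng.integers(lo, hi + 1)),
                )
            )
            idx += 1
    return events


def _draw_baseline(rng: np.random.Generator, effect: float) -> float:
    """Baseline psi, Beta(2,2)-shaped on the interval where psi+effect fits."""
    lo, hi = PSI_MARGIN, 1.0 - PSI_MARGIN
    if effect > 0:
        hi -= effect
    else:
        lo -= effect
    if hi <= lo:  # effect fills the whole admissible range
        return lo
    return lo + (hi - lo) * rng.beta(2.0, 2.0)


def simulate_truth(
    catalog: list[SpliceEvent],
    frac_differential: float | tuple[float, float] = 0.2,
    effect_range: tuple[float, float] = (0.25, 0.6),
    frac_switch: float = 0.6,
    substrate_config: dict[str, SubstrateParams] | None = None,
    category_bias: dict[str, CategoryBias] | None = None,
    seed: int = 0,
) -> list[SimTruth]:
    """Plant per-event ground truth for the two contrasts.

    ``frac_differential`` applies to both contrasts, or pass a (treatment,
    disease) pair.  ``frac_switch`` is the fraction of jointly differential
    events whose treatment and disease effects get opposed signs (the rest
    get the same sign, so the switch flag is exactly the opposed subset).
    """
    if isinstance(frac_differential, (int, float)):
        frac_treat = frac_dis = float(frac_differential)
    else:
        frac_treat, frac_dis = map(float, frac_differential)
    for name, frac in [("treatment", frac_treat), ("disease", frac_dis), ("switch", frac_switch)]:
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"frac_{name} must be in [0,1], got {frac}")
    eff_lo, eff_hi = effect_range
    if not (0.0 < eff_lo <= eff_hi <= 1.0):
        raise ValueError(f"effect range must satisfy 0 < lo <= hi <= 1, got {effect_range}")
    if substrate_config is None:
        substrate_config = DEFAULT_SUBSTRATE_CONFIG
    category_bias = category_bias or {}

    rng = _streams(seed, 1)[0]
    t_a, t_b = TREATMENT_CONDITIONS
    d_a, d_b = DISEASE_CONDITIONS

    records: list[dict] = []
    for event in catalog:
        bias = category_bias.get(event.category, CategoryBias())
        p_diff = frac_treat
        if bias.differential_odds != 1.0 and 0.0 < frac_treat < 1.0:
            odds = frac_treat / (1.0 - frac_treat) * bias.differential_odds
            p_diff = odds / (1.0 + odds)
        is_dt = rng.random() < p_diff
        is_dd = rng.random() < frac_dis
        sign_t = -1.0 if rng.random() < bias.prob_excluded else 1.0
        is_switch = False
        if is_dt and is_dd:
            is_switch = rng.random() < frac_switch
            sign_d = -sign_t if is_switch else sign_t
        else:
            sign_d = -1.0 if rng.random() < 0.5 else 1.0
        eff_t = sign_t * rng.uniform(eff_lo, eff_hi) if is_dt else 0.0
        eff_d = sign_d * rng.uniform(eff_lo, eff_hi) if is_dd else 0.0
        records.append(
            dict(event=event, is_dt=is_dt, is_dd=is_dd, eff_t=eff_t, eff_d=eff_d, is_switch=is_switch)
        )

    # Substrate membership per gene, enriched among genes with >= 1
    # treatment-differential event.
    genes = sorted({e.gene_id for e in catalog})
    diff_genes = {r["event"].gene_id for r in records if r["is_dt"]}
    membership: dict[str, set[str]] = {g: set() for g in genes}
    for rbp in RBP_NAMES:
        params = substrate_config.get(rbp, SubstrateParams(enrichment_odds=1.0))
        if not 0.0 < params.rate < 1.0:
            raise ValueError(f"substrate rate for {rbp} must be in (0,1)")
        base_odds = params.rate / (1.0 - params.rate)
        for gene in genes:
            odds = base_odds * (params.enrichment_odds if gene in diff_genes else 1.0)
            if rng.random() < odds / (1.0 + odds):
                membership[gene].add(rbp)

    # Optional magnitude shift on treatment effects of substrate events.
    shifted_rbps = [r for r in RBP_NAMES if substrate_config.get(r, SubstrateParams()).magnitude_shift]
    truths: list[SimTruth] = []
    for rec in records:
        event = rec["event"]
        subs = frozenset(membership[event.gene_id])
        eff_t = rec["eff_t"]
        if rec["is_dt"]:
            for rbp in shifted_rbps:
                if rbp in subs:
                    shift = substrate_config[rbp].magnitude_shift
                    eff_t = math.copysign(
                        min(abs(eff_t) + shift, 1.0 - 2 * PSI_MARGIN), eff_t
                    )
        base_t = _draw_baseline(rng, eff_t)
        base_d = _draw_baseline(rng, rec["eff_d"])
        truths.append(
            SimTruth(
                event_id=event.event_id,
                psi_by_condition={
                    t_a: base_t,
                    t_b: base_t + eff_t,
                    d_a: base_d,
                    d_b: base_d + rec["eff_d"],
                },
                is_differential_treatment=rec["is_dt"],
                is_differential_disease=rec["is_dd"],
                effect_treatment=eff_t,
                effect_disease=rec["eff_d"],
                substrate_of=subs,
                is_switch=rec["is_switch"],
            )
        )
    return truths


def simulate_counts(
    truth: list[SimTruth],
    catalog: list[SpliceEvent],
    mean_coverage: float = 100.0,
    dispersion: float = 0.3,
    n_replicates: int = 3,
    distribution: str = "negative_binomial",
    seed: int = 0,
    conditions: tuple[str, ...] | None = None,
) -> list[EventCounts]:
    """Replicate-level read counts for every event in every condition.

    Per sample the total informative read count is negative-binomial with
    the given mean and dispersion (variance mu + dispersion*mu^2), or
    Poisson; inclusion reads are then Binomial(total, f(psi_true)) with the
    length-corrected read-class probability f.
    """
    if mean_coverage < 0:
        raise ValueError("mean_coverage must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if distribution not in ("negative_binomial", "poisson"):
        raise ValueError(f"unknown coverage distribution {distribution!r}")
    if conditions is None:
        conditions = TREATMENT_CONDITIONS + DISEASE_CONDITIONS
    events_by_id = {e.event_id: e for e in catalog}
    truth_by_id = {t.event_id: t for t in truth}
    missing = set(truth_by_id) - set(events_by_id)
    if missing:
        raise ValueError(f"truth records without catalog events: {sorted(missing)[:3]}")

    rng = _streams(seed, 1)[0]
    counts: list[EventCounts] = []
    for event_id in sorted(truth_by_id):
        t = truth_by_id[event_id]
        event = events_by_id[event_id]
        for condition in conditions:
            psi = t.psi_by_condition[condition]
            f = psi * event.l_inc / (psi * event.l_inc + (1.0 - psi) * event.l_exc)
            for rep in range(1, n_replicates + 1):
                if mean_coverage == 0:
                    total = 0
                elif distribution == "poisson":
                    total = int(rng.poisson(mean_coverage))
                else:
                    shape = 1.0 / dispersion
                    total = int(
                        rng.negative_binomial(shape, shape / (shape + mean_coverage))
                    )
                n_inc = int(rng.binomial(total, f)) if total else 0
                counts.append(
                    EventCounts(
                        event_id=event_id,
                        sample_id=f"{condition}_rep{rep}",
                        condition=condition,
                        replicate=rep,
                        n_inc=n_inc,
                        n_exc=total - n_inc,
                    )
                )
    return counts
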