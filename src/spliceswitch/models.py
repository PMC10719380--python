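"""Domain types shared across the pipeline.

An alternative-splicing (AS) *event* is a local choice between two isoform
forms of one gene — e.g. a skipped exon is either included or excluded from
the mature transcript.  Read evidence for an event is a pair of counts:
reads supporting the inclusion form and reads supporting the exclusion form.
PSI (percent spliced in, psi) is the fraction of transcripts carrying the
inclusion form; dPSI is the PSI difference between two conditions, with
positive values read as "included" and negative as "excluded" under
treatment or disease.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

#: The seven recognised event categories: skipped exon, retained intron,
#: alternative 5'/3' splice sites, mutually exclusive exons and alternative
#: first/last exons.
CATEGORIES: tuple[str, ...] = ("SE", "RI", "A5SS", "A3SS", "MXE", "AFE", "ALE")

#: RNA-binding proteins whose CLIP-defined substrate sets are tested for
#: enrichment among differentially spliced genes.
RBP_NAMES: tuple[str, ...] = ("hnRNPA2", "MSI2", "CELF1")

#: Condition labels of the treatment contrast (A, B); dPSI is B minus A.
TREATMENT_CONDITIONS: tuple[str, str] = ("DMSO", "apigenin")
#: Condition labels of the disease contrast (A, B); dPSI is tumor minus normal.
DISEASE_CONDITIONS: tuple[str, str] = ("NBT", "TNBC")

TREATMENT_LABEL = "treatment"
DISEASE_LABEL = "disease"


class SchemaError(ValueError):
    """A file or record violated the declared schema.

    Carries the offending file line number when known.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


@dataclass(frozen=True)
class SpliceEvent:
    """One annotated AS event.

    ``l_inc`` / ``l_exc`` are the effective lengths — the number of read
    positions informative for the inclusion / exclusion form — used to
    length-correct the read-class probability when estimating PSI.
    """

    event_id: str
    gene_id: str
    category: str
    chrom: str
    strand: str
    segments: tuple[tuple[int, int], ...]
    l_inc: int
    l_exc: int

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise SchemaError(
                f"unknown category {self.category!r} for event {self.event_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise SchemaError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.l_inc < 1 or self.l_exc < 1:
            raise SchemaError(
                f"effective lengths must be >= 1 (event {self.event_id!r})"
            )
        if not self.segments:
            raise SchemaError(f"event {self.event_id!r} has no segments")
        for start, end in self.segments:
            if start < 1 or end < start:
                raise SchemaError(
                    f"bad segment ({start}, {end}) in event {self.event_id!r}"
                )


@dataclass(frozen=True)
class EventCounts:
    """Inclusion/exclusion read counts for one event in one sample."""

    event_id: str
    sample_id: str
    condition: str
    replicate: int
    n_inc: int
    n_exc: int

    def __post_init__(self):
        if self.n_inc < 0 or self.n_exc < 0:
            raise SchemaError(
                f"negative counts for event {self.event_id!r}, "
                f"sample {self.sample_id!r}"
            )
        if self.replicate < 1:
            raise SchemaError(f"replicate must be >= 1, got {self.replicate}")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated event.

    ``psi_by_condition`` maps each of the four condition labels (two per
    contrast) to the true psi.  Effects are the signed true dPSI (B minus A)
    per contrast; zero when the event is not differential in that contrast.
    ``is_switch`` marks a planted sign opposition between the two contrasts.
    """

    event_id: str
    psi_by_condition: Mapping[str, float]
    is_differential_treatment: bool
    is_differential_disease: bool
    effect_treatment: float
    effect_disease: float
    substrate_of: frozenset[str]
    is_switch: bool

    def __post_init__(self):
        for cond, psi in self.psi_by_condition.items():
            if not 0.0 <= psi <= 1.0:
                raise ValueError(f"psi out of [0,1] for {cond}: {psi}")
        for eff in (self.effect_treatment, self.effect_disease):
            if abs(eff) > 1.0:
                raise ValueError(f"|effect| > 1: {eff}")
        if self.is_switch:
            if not (self.is_differential_treatment and self.is_differential_disease):
                raise ValueError("switch events must be differential in both contrasts")
            if math.copysign(1, self.effect_treatment) != -math.copysign(
                1, self.effect_disease
            ):
                raise ValueError("switch events must have opposed effect signs")


@dataclass(frozen=True)
class PsiEstimate:
    """Posterior summary of psi for one event in one sample."""

    event_id: str
    sample_id: str
    psi_mean: float
    ci_low: float
    ci_high: float
    n_total: int

    def __post_init__(self):
        if not (0.0 <= self.ci_low <= self.psi_mean + 1e-12):
            raise ValueError("require 0 <= ci_low <= psi_mean")
        if not (self.psi_mean <= self.ci_high + 1e-12 and self.ci_high <= 1.0):
            raise ValueError("require psi_mean <= ci_high <= 1")


@dataclass(frozen=True)
class BayesFactorResult:
    """Bayes factor for differential splicing between two conditions.

    ``bf`` is the marginal-likelihood ratio of the two-psi model over the
    shared-psi model; ``delta_psi`` is posterior-mean psi(B) minus psi(A).
    ``uninformative`` flags the all-zero-counts convention (bf = 1).
    """

    event_id: str
    bf: float
    delta_psi: float
    uninformative: bool = False

    def __post_init__(self):
        if self.bf < 0:
            raise ValueError("Bayes factor must be >= 0")
        if not -1.0 <= self.delta_psi <= 1.0:
            raise ValueError("delta_psi must be in [-1, 1]")


@dataclass(frozen=True)
class DifferentialCall:
    """Differential verdict for one event in one contrast.

    ``significant`` requires pooled ``bf`` at or above the threshold AND every
    per-replicate dPSI sharing the sign of the pooled dPSI (an exact zero
    counts as inconsistent).  ``bf`` is NaN for untestable events (pooled
    information below the floor in either condition).
    """

    event_id: str
    category: str
    gene_id: str
    bf: float
    delta_psi_pooled: float
    replicate_delta_psis: tuple[float, ...]
    direction: str  # "included" | "excluded" | "none"
    significant: bool
    testable: bool = True

    def __post_init__(self):
        if self.direction not in ("included", "excluded", "none"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.significant:
            if self.direction == "none":
                raise ValueError("significant calls must carry a direction")
            want = "included" if self.delta_psi_pooled > 0 else "excluded"
            if self.direction != want:
                raise ValueError("direction inconsistent with pooled dPSI sign")


@dataclass
class ContrastResult:
    """All differential calls for one contrast."""

    contrast_label: str
    calls: list[DifferentialCall] = field(default_factory=list)

    @property
    def n_tested(self) -> int:
        return sum(1 for c in self.calls if c.testable)

    @property
    def n_significant(self) -> int:
        return sum(1 for c in self.calls if c.significant)

    def significant_calls(self) -> list[DifferentialCall]:
        return [c for c in self.calls if c.significant]


@dataclass(frozen=True)
class CategoryComposition:
    """Direction-of-change composition of one event category."""

    category: str
    n_tested: int
    n_significant: int
    n_included: int
    n_excluded: int
    ratio: float  # orientation chosen by the caller; may be inf or NaN
    proportion_p_raw: float
    proportion_p: float
    imbalance_p_raw: float
    imbalance_p: float


@dataclass(frozen=True)
class ConcordanceResult:
    """Least-squares agreement between two PSI measurement methods."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class SubstrateSet:
    """A named gene set (RBP substrates or a cancer gene list)."""

    set_name: str
    gene_ids: frozenset[str]
    description: str = ""

    def __post_init__(self):
        if not self.gene_ids:
            raise ValueError(f"gene set {self.set_name!r} is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    """Upper-tail hypergeometric overlap of differential genes with a set.

    ``k`` of the ``n`` differential genes fall in the set, which covers ``K``
    of the ``N`` universe genes.
    """

    set_name: str
    k: int
    n: int
    K: int
    N: int
    p_value: float

    def __post_init__(self):
        if not (max(0, self.n + self.K - self.N) <= self.k <= min(self.n, self.K)):
            raise ValueError("overlap count outside hypergeometric support")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p must be in (0, 1]")


@dataclass(frozen=True)
class KsComparison:
    """Two-sample Kolmogorov-Smirnov comparison of dPSI distributions."""

    set_name: str
    d_statistic: float
    p_value: float
    n_substrate_events: int
    n_other_events: int
    magnitude_mode: str  # "signed" | "absolute"

    def __post_init__(self):
        if not 0.0 <= self.d_statistic <= 1.0:
            raise ValueError("D statistic must be in [0, 1]")


@dataclass(frozen=True)
class SwitchCall:
    """One event significant in both contrasts, with the switch verdict.

    ``switched`` means the treatment moves splicing against the tumor-vs-
    normal direction, i.e. toward the non-tumor profile: the two dPSI values
    are both nonzero with opposite signs.
    """

    event_id: str
    category: str
    treat_dpsi: float
    disease_dpsi: float
    switched: bool

    def __post_init__(self):
        opposed = (
            self.treat_dpsi != 0
            and self.disease_dpsi != 0
            and (self.treat_dpsi > 0) != (self.disease_dpsi > 0)
        )
        # switched requires sign opposition; the converse holds in the
        # default mode but the stricter magnitude-restoration mode may veto
        if self.switched and not opposed:
            raise ValueError("switched flag requires opposed dPSI signs")


@dataclass(frozen=True)
class SwitchSummary:
    """Counts and percentages of the treatment/disease intersection."""

    n_treatment_significant: int
    n_shared: int
    n_switched: int
    pct_shared_of_treatment: float  # NaN when the denominator is 0
    pct_switched_of_shared: float

    def __post_init__(self):
        if not self.n_switched <= self.n_shared <= self.n_treatment_significant:
            raise ValueError("require n_switched <= n_shared <= n_treatment_significant")

    @classmethod
    def from_counts(
        cls, n_treatment_significant: int, n_shared: int, n_switched: int
    ) -> "SwitchSummary":
        pct_shared = (
            100.0 * n_shared / n_treatment_significant
            if n_treatment_significant
            else math.nan
        )
        pct_switched = 100.0 * n_switched / n_shared if n_shared else math.nan
        return cls(
            n_treatment_significant=n_treatment_significant,
            n_shared=n_shared,
            n_switched=n_switched,
            pct_shared_of_treatment=pct_shared,
            pct_switched_of_shared=pct_switched,
        )


def sign(x: float) -> int:
    """Sign of ``x`` as -1, 0 or +1."""
    return (x > 0) - (x < 0)


def segments_to_str(segments: Sequence[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in segments)


def segments_from_str(text: str) -> tuple[tuple[int, int], ...]:
    out = []
    for chunk in text.split(";"):
        start_s, _, end_s = chunk.partition("-")
        out.append((int(start_s), int(end_s)))
    return tuple(out)
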