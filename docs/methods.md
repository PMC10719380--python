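# Methods

## The exon-centric two-isoform model

Each alternative-splicing event is treated as a binary choice between an
inclusion form and an exclusion form of one gene; ψ (PSI) is the fraction
of transcripts carrying the inclusion form. Reads informative for the
event are multinomial over the two forms, with the inclusion-read
probability length-corrected as

    f(ψ) = ψ·L_inc / (ψ·L_inc + (1 − ψ)·L_exc),

where L_inc and L_exc count the read positions informative for each form
(supplied by the event catalog; set both to 1 for no correction). This is
the standard exon-centric simplification: events with three or more
isoforms, paired-end insert modelling and positional read biases are out
of scope.

Assumptions: reads are independent given ψ; the effective lengths are
known and condition-independent; replicates of a condition share one ψ
(they are pooled for the Bayes factor).

## Posterior PSI

The prior is uniform on ψ — the reported scale — not on f(ψ). The
posterior is evaluated on a regular grid over [0, 1] (default 1001
points, forced odd) and integrated with composite Simpson's rule;
credible bounds are central 2.5 %/97.5 % quantiles interpolated linearly
on the cumulative-trapezoid CDF. With equal effective lengths the
posterior is exactly Beta(n_inc+1, n_exc+1); the quadrature reproduces the
Beta mean and the closed-form Beta-function Bayes factor to better than
1e-6 (relative), which the test suite asserts. A sample with zero reads
returns the prior (mean 0.5, CI [0.025, 0.975]).

All marginal-likelihood integrals are computed max-shifted in log space,
so events with thousands of pooled reads do not underflow.

## Differential calling

The Bayes factor compares "independent ψ per condition" against "shared
ψ", both under uniform priors:

    BF = [∫P(D_A|ψ)dψ · ∫P(D_B|ψ)dψ] / ∫P(D_A|ψ)P(D_B|ψ)dψ.

MISO, the standard exon-centric tool for this comparison, scores it
with a sampling-based Bayes factor; here the two-model marginal-likelihood
ratio is computed exactly by quadrature, which is deterministic and
testable against closed forms. Numerical BF values therefore differ from
MISO's; only the threshold behaviour (BF ≥ 20, kept as the default)
carries over.

A call is significant when (1) the pooled BF is at or above the threshold
and (2) every per-replicate ΔPSI point estimate (posterior means,
replicate i of A paired with replicate i of B) shares the sign of the
pooled ΔPSI. Design choices behind rule (2):

- Replicates pair by index; mismatched replicate counts raise an error
  rather than guessing a pairing (the rule presumes matched replicate
  cultures). Comparing each replicate against pooled opposite-condition
  data instead would be equally defensible; pairing by index is this
  package's choice.
- A per-replicate ΔPSI of exactly 0 fails the same-direction requirement
  (strict reading of "same direction"); a tolerance ε is configurable and
  defaults to 0.
- An event whose pooled read total in either condition is below
  `min_info` (default 10) is reported *untestable* — BF recorded as NaN,
  excluded from `n_tested` denominators — because near-empty events
  produce degenerate Bayes factors. The floor value is a package
  choice.

Raising the BF threshold can only shrink the significant set (tested as a
monotonicity property). No FDR correction is applied across events: the
two-part rule is a hard BF cutoff, not an FDR procedure.

## Composition statistics

Per event category (SE, RI, A5SS, A3SS, MXE, AFE, ALE):

- **Direction ratio** — excluded/included (or the inverse; both
  orientations exist in practice and the orientation is explicit per
  call). 0 in the denominator with a nonzero numerator reports infinity;
  0/0 reports NaN.
- **Proportion test** — each category's significant/tested rate against
  the pooled rate of the remaining categories, as a two-sided
  two-proportion z-test with pooled variance; Fisher's exact test replaces
  it when any 2×2 cell is below 5. Comparing each category against its
  own total rather than the pooled remainder would be an alternative
  reading; category-vs-complement is implemented.
- **Imbalance test** — included vs excluded against 50:50 as a 1-df χ²
  with Yates continuity correction (the R default, and within 10 % of the
  exact binomial tail at n = 100, which is asserted); the exact two-sided
  binomial replaces it below 20 significant events.
- Bonferroni multiplier = number of categories actually tested (≤ 7);
  adjusted p capped at 1. Untestable categories report NaN.

PSI concordance between two measurement methods (e.g. RT-PCR vs RNA-seq)
is an ordinary least-squares line; R² is the squared Pearson correlation;
zero variance in either coordinate yields NaN.

## Enrichment

Gene-level: the universe is the set of genes with ≥ 1 testable event in
the contrast (not the whole genome — that is the population actually
eligible to be called; other universes are defensible and the choice is
configurable). Genes are deduplicated (a gene counts once
regardless of its event count); gene sets are intersected with the
universe; p is the exact upper tail P(X ≥ k) of
Hypergeometric(N, K, n).

Event-level: ΔPSI distributions of substrate vs non-substrate events are
compared by the two-sample Kolmogorov–Smirnov test, exact when both
groups have ≤ 25 events, asymptotic otherwise. The default compares
|ΔPSI| because the scientific claim is about the *magnitude* of splicing
change; a signed mode exists, and the mode used is recorded per run.

## Switch classification

Disease ΔPSI is fixed as tumor minus normal (stated in every output
header). A shared event — significant in both contrasts under identical
thresholds — is *switched toward the non-tumor profile* when its
treatment and disease ΔPSI are both nonzero with opposite signs. Sign
opposition alone defines the switch; an optional stricter mode also
requires |ΔPSI_treat| within a tolerance of |ΔPSI_disease| (off by
default, and it can only veto, never add). Zero ΔPSI in either contrast is
"not switched". The intersection is event-level, not gene-level. The
shared-set size is tested against chance with the same hypergeometric
machinery at event granularity, on the universe of events testable in
both contrasts.

## Synthetic data

The generator emulates the study design: a treatment contrast (apigenin
vs DMSO in tumor cells) and a disease contrast (TNBC vs normal breast
tissue) over one event catalog, with per-event true ψ in all four
conditions and replicate-level counts. Defaults, chosen as the study
conditions the recovery tests run under:

- catalog: equal numbers per category; effective lengths uniform in
  [20, 200]; gene ids assigned so genes average 1.5 events (multi-event
  genes exercise gene-level deduplication);
- 20 % of events differential per contrast; |Δψ| uniform in [0.25, 0.6]
  (0.25 is the planted-effect floor the recall/FDP bounds refer to);
  baseline ψ drawn Beta(2,2)-shaped on the interval that keeps
  ψ + Δψ inside [0.02, 0.98], so every requested effect is representable;
- 60 % of jointly differential events planted with opposed signs between
  the contrasts (the switch fraction); jointly differential non-switch
  events get the same sign, so the switch flag is exactly the opposed
  subset;
- substrate membership per gene at marginal rate 0.12 with a 3× odds
  multiplier for genes carrying a treatment-differential event, for all
  three RBPs; only hnRNPA2 substrates additionally receive a +0.15 |Δψ|
  shift, so the K–S magnitude test should flag hnRNPA2 and not MSI2/CELF1;
- coverage per sample: negative binomial, mean 100, dispersion 0.3
  (variance μ + 0.3 μ²) — realistic overdispersion at desk scale; a
  Poisson option exists; inclusion reads are Binomial(total, f(ψ));
- 3 replicates per condition; one RNG stream per stage (catalog, truth,
  counts), seeded separately for stage-level reproducibility.

What the simulator does **not** model — and hence what passing recovery
tests do not demonstrate about real data: read-level sequences and
alignment artefacts, positional biases within isoforms, correlated
effects between the two contrasts (the planted treatment and disease
flags are independent, so the event-level overlap sits at chance level
unless the caller plants otherwise), shared-gene effect correlation,
library-size differences between samples, and annotation errors in
effective lengths.

Problem sizes in the shipped tests and acceptance script — 3,920 events
(~2,000 genes) for the main recovery run, 2,002 events for the null
calibration, 3,010 events at a raised differential rate for
switch-fraction recovery — are the package's desk-scale defaults; they
keep a full run in the tens of seconds while leaving binomial sampling
error well inside the asserted bounds.

## Numerical and degenerate-input conventions

- Grid size defaults to 1001 and is forced odd for Simpson's rule.
- Both conditions all-zero in the Bayes factor: BF = 1 by convention,
  flagged uninformative, never significant.
- Ratios: x/0 → inf, 0/0 → NaN; untestable statistics → NaN; adjusted
  p-values capped at 1.
- TSV is the interchange dialect ('#'-prefixed header comments: stage,
  config hash, schema); GFF3 (1-based, inclusive) is export-only for the
  catalog; GMT for gene sets; YAML for configuration; JSON for summaries
  and manifests. Coordinates are stored as read, with no silent
  conversion. The config hash excludes the output directory, so identical
  analyses written to different locations hash identically.

## Known limitations

- Two-isoform events only; no Dirichlet multi-isoform model.
- The Bayes factor is exact under this package's model but not numerically
  comparable to MISO's sampled values; only the ≥ 20 threshold role is
  preserved.
- Per-replicate direction uses point estimates; replicate-level posterior
  uncertainty does not enter the consistency rule — the pooled Bayes
  factor alone carries the evidence weight.
- The hypergeometric universe choice materially affects enrichment p
  values; the default (genes with a testable event) is one defensible
  choice among several.
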