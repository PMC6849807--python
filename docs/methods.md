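# Methods

## Scope and model

`sporetrace` treats thermophilic endospores in cold sediment as inert
tracers: their density field along an estuary is set entirely by deposition
from sources, and a pasteurized 50 °C incubation is the detector that makes
them visible against the (dead) ambient community. The package covers the
inference chain from OTU table to dispersal-history label, the MPN
quantitation, ontology profiling, and a generative twin of the experiment.
Upstream read processing (quality filtering, OTU clustering, chimera
removal, taxonomy assignment) and the sequence-similarity retrieval behind
ontology annotations are consumed as finished tables, not computed.

## Rarefaction and relative abundance

Every library is subsampled without replacement to the depth of the
smallest library (a multivariate hypergeometric draw per sample), the
QIIME-era convention the enrichment cutoffs were defined against.
A single run seed is recorded; each sample's stream derives
deterministically from (seed, sample id), so results are independent of
column order and reproducible per sample under parallelism. A single draw
is used rather than an average over repeated rarefactions. All downstream
rules operate on rarefied relative abundances; raw tables serve only
`confirm_absent`, which distinguishes "truly absent" from "lost to
subsampling" for OTUs with zero rarefied count.

## Enrichment rule

An OTU is enriched at a station iff its 0 h (unincubated,
pre-pasteurization) relative abundance is strictly below
`baseline_max_fraction` (default 0.001) **and** its maximum over the
station's heated timepoints is strictly above `enriched_min_fraction`
(default 0.01). Exceedance at a single timepoint suffices; requiring
consecutive timepoints was considered and rejected because staggered blooms
(early sulfate reducers, late fermenters) are the norm, not noise. An OTU
absent at 0 h has baseline 0. Taxonomy is never a filter — that enriched
OTUs all turn out to be Firmicutes is a diagnostic observation, which keeps
the rule falsifiable on synthetic data.

## Source classification

Enrichment flags are OR-ed within station classes (non-tidal / tidal /
marine) and labels follow a three-way partition of the enriched set:
cosmopolitan ⇔ non-tidal ∧ marine; marine ⇔ marine ∧ ¬non-tidal;
terrestrial ⇔ (non-tidal ∨ tidal) ∧ ¬marine. An OTU enriched only at the
marine station is labelled marine — this case lies outside the original
estuary universe but is the natural extension of the "not upstream, at
sea" rule. Classification without a marine station is refused rather than
guessed. Sub-threshold evidence (e.g. trace unrarefied counts at sea for a
terrestrial OTU) never changes a label. The summary reports integer
percentages over enriched OTUs and a terrestrial-derived share pooling
terrestrial and cosmopolitan.

## MPN estimation

The single-hit Poisson model gives tube-positivity probability
1 − e^(−λm) for inoculum mass m. The point estimate solves the score
equation by bracketed Brent root finding (relative tolerance 1e-12;
equivalence with a 10⁴-point log-grid likelihood maximization is enforced
in tests over the full 64-outcome space of the 3-level/3-tube design).
Reported values round to 2 significant figures. All-negative patterns are
flagged below-detection (upper limit only); all-positive above-range
(lower limit only).

Exact confidence limits enumerate the design's outcome space, order
outcomes by point estimate (ties by total positives), and invert the two
tail probabilities by bisection in log density. The per-side tail levels
default to 0.050 (lower) and 0.045 (upper): these are calibrated so the
nominal "95 %" interval reproduces the classic three-tube tables — (3,0,0)
at 0.1/0.01/0.001 g gives 23 (4.6, 94), (3,1,0) gives 43 (9.0, 180) —
whose published limits sit at those exact tail probabilities rather than
at textbook 2.5 % tails. The resulting two-sided coverage is ≈ 90–95 %
(exactly 97.4 % at λ = 50 g⁻¹ on the standard design), consistent with
the real coverage of the classic tables; a Monte-Carlo coverage bound of
≥ 0.90 is enforced in tests. Cochran's log-normal interval
(log₁₀ half-width 1.96 · 0.58 · √(log₁₀ a / n) for dilution factor a and
n tubes per level) is available as the alternative method.

For series longer than three levels the conventional reading window is
applied by default: the most dilute level with all tubes positive plus the
next two lower levels (highest-mass levels if none is all-positive,
lowest-mass levels if all are). The full-series MLE is available via
`window=False` and generally differs.

Tube scoring from sulfide readings uses mean(blanks) + 3·sd(blanks) as the
positivity threshold, sd taken as 0 with a single blank.

## Synthetic experiments

The generator emulates the study design: six stations (one non-tidal at
−2 km relative to the tidal limit, four tidal at 4/10/16/28 km, one marine
at 50 km), sampling at 0/24/48/72/96/120 h, 75 OTUs (40 terrestrial, 10
marine, 10 cosmopolitan spore-formers; 15 vegetative background taxa).

**Deposition.** Terrestrial spores enter at the most upstream station and
decay e-fold per `downstream_decay_km` moving seaward; marine spores enter
at the marine station, decay per `upstream_decay_km` moving landward, and
are exactly zero above the tidal limit (tides cannot carry particles past
it). Cosmopolitan taxa sum both contributions. Realized densities are
Poisson draws around these means; means below an establishment floor
(50 spores/g) truncate to zero so presence/absence patterns reflect the
dispersal model rather than single-spore lottery events.

**Microcosms.** Pasteurization kills vegetative biomass, which persists as
relic DNA halving every 24 h — DNA-based profiling sees dead cells, so the
Firmicutes fraction climbs over the incubation instead of jumping to 100 %
at 24 h. Spores whose salinity tolerance includes the medium germinate
(probability 0.5) and grow exponentially. Sulfate reducers (rate 0.5 h⁻¹)
draw a shared pool of 20 mM sulfate in 2 ml medium per g sediment at a
yield of 1.5e10 cells per mmol and stop at exhaustion; sulfate maps 1:1
onto sulfide, and conservation holds to solver tolerance (explicit stepping
at 0.25 h). Fermenters grow independently of sulfate to a stationary-phase
cap; Monod half-saturation is deliberately omitted because 24 h sampling
cannot constrain it. Caps and rates are staggered in four "waves" timed so
each wave peaks near a different sampling time — fractions at any single
timepoint sum to 1, so staggering is what lets ~50 co-occurring taxa each
clear the 1 % rule at their own peak. Dynamics are deterministic given
densities; all stochasticity lives in deposition and sequencing.

**Sequencing.** Library sizes are log-normal (μ = 10.100, σ = 0.332),
calibrated so a 36-library run has minimum ≈ 12 852 and mean ≈ 25 729
reads; reads are multinomial on relative DNA biomass including relic
background.

**Ground truth.** A noise-free twin of the dynamics is scored with a 3×
safety margin on both cutoffs (baseline < 0.1 %/3, peak > 3 × 1 %) to flag
per-station enrichability; labels derive from those flags by the
classifier's own rule. The margin makes flags robust to Poisson and
multinomial noise, and the label-determining stations (the non-tidal and
marine ones) are kept far from the gray zone by construction: source-side
densities are high and the structural zeros (tidal limit, salinity
intolerance) are exact. Tidal-station calls near the 1 % line may flip
between seeds; labels are insensitive to those flips. Tests verify exact
label recovery over 20 seeded runs, and that cutting deposition 100-fold
degrades detectability (the recovery test is not vacuous).

## What the generator does not emulate

Real amplicon data carry primer and copy-number bias, chimeras, overdispersed
(non-multinomial) counts, compositional correlations among background taxa,
tributary inputs that break monotone decay, and relic-DNA kinetics that are
unmeasured rather than geometric. Passing the synthetic suite therefore
demonstrates correctness of the inference rules under the stated generative
model, not robustness to every artifact of real libraries. The enrichment
thresholds themselves are inherited conventions, not estimated quantities.

## Numerical choices and degenerate inputs

Strict inequalities at both enrichment cutoffs (a baseline exactly at
0.1 % or a peak exactly at 1 % is not enriched); empty samples are rejected
before rarefaction; duplicate identifiers and mixed station classes are
format errors; identifier matching is case-sensitive and
whitespace-stripped. Heatmap term rows order by total frequency descending
with lexicographic tie-break; ontology profiles are absent (never
zero-filled) when no hit passes the 97 % identity cutoff with at least one
term. Multi-term hits contribute each term once (term-occurrence
weighting); for single-term hits this reduces to hit-fraction weighting.

## Limitations

The de Man-style interval is calibrated to the classic tables rather than
to a nominal coverage; users needing guaranteed ≥ 95 % coverage should
widen the tails to 0.025/0.025. Pattern-rarity screening (flagging
improbable tube patterns) is not implemented; patterns are taken at face
value. The pipeline assumes one pooled library per station × timepoint —
replicate microcosms must be pooled upstream, as there is no replicate
axis in the schema.
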