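# Methods

## The two-state escape model

A fermentation population is modelled as producers P (paying a
growth-rate cost for biosynthesis) and non-producers N (having shed it),
with irreversible conversion P → N:

    dP/dg = (μ − c − k) P
    dN/dg = μ N + k P,        P(0) = p0, N(0) = 0

* **c — production load** (dimensionless, per generation, 0 ≤ c < 1):
  absolute growth-rate deficit of producers relative to non-producers; the
  selection coefficient favouring escape mutants.  Defaults in the
  generators: 0.281, the free-fit value for a mevalonic-acid-type pathway.
* **k — escape rate** (per generation, ≥ 0): first-order flux of producers
  into the non-producing state, aggregating all disruptive error modes (IS
  transposition, SNPs, illegitimate recombination).  Default 2.1 × 10⁻⁷.
* **μ — non-producer growth rate** (per generation, default 1).  The
  producer fraction f = P/(P+N) is independent of μ; it enters only when
  absolute counts matter (the stochastic model).

Closed forms: ρ(g) = N/P = (k/(c+k))(e^{(c+k)g} − 1), f = 1/(1+ρ), and the
half-life g½ = ln(1 + (c+k)/k)/(c+k), the generations until f = ½ from a
pure producing start.  Escape is modelled as continuous conversion rather
than a division-coupled event; at k ≪ 1 the two differ at O(k), far below
observable resolution.  Relative product titer is taken proportional to
the producer fraction, so the titer observable is f(g)/f(g_ref) and the
mobile-element observable is 1 − f(g) (no normalisation: the starting
population is known pure).

Numerics: f is evaluated as (c+k)e^{−x} / ((c)e^{−x} + k) with
x = (c+k)g, which neither overflows nor loses precision out to x of
several hundred; N(g) uses expm1 to avoid cancellation at small (c+k)g;
the half-life is solved in closed form, never by grid search.  k = 0 is a
well-defined limit everywhere (ρ ≡ 0, half-life = ∞ reported as a
distinguished "never" value).

## Stochastic counterpart

An exact Gillespie (direct-method) simulation with three channels:
producer division at (μ−c)P, non-producer division at μN, escape at kP.
One named generator per run, seeded explicitly; identical seeds give
bit-identical runs.  A population cap (default 10⁶ cells) bounds runtime
and marks truncated runs.  Because expectations of this linear system obey
the ODEs exactly, the matched ensemble statistic for comparison with the
deterministic fraction is the *pooled* fraction ΣP/Σ(P+N), not the mean of
per-run fractions (which carries a Jensen bias of order the squared
coefficient of variation of N).

`hybrid_run` follows the regime split that motivates the deterministic
model: exact SSA while the population is below a threshold (default 1000
cells, where discreteness matters), then deterministic continuation from
the stochastic state.  Reaching industrially relevant generation numbers
by pure SSA is not meaningful desk-side — a run to g = 20 from 10³ cells
implies ~10⁹ division events — so ensemble checks at such horizons use the
hybrid scheme with the threshold raised until the stochastic phase
contains hundreds of escape events.

## Fitting stability series

Least squares over the free subset of {c, k} against either observable,
unweighted by default (points are replicate means; 1/sem² weighting by
flag).  k is fitted as log₁₀k (bounds 10⁻¹² – 10⁻³; c ∈ [0, 0.95]) with a
multistart over seven log-spaced k initials (and two c initials) so the
reported optimum is never a local minimum of the sigmoid's flat tails.
CI95 is the nls-style Jacobian linearisation **in the fitted parameter
space** — natural for c, log₁₀ for k — with t-quantiles at n − p degrees
of freedom, mapped back to natural-scale intervals (asymmetric for k).
Linearising in natural k instead understates the strongly right-skewed
sampling error of k and undercovers by ~10 percentage points in synthetic
calibration.  A seeded residual bootstrap is available as an alternative
interval.  Boundary estimates and flat (non-identifiable) series are
flagged, never silently reported.

## Insertion-sequence pipeline

Reads are mapped to the circular plasmid by an exact-seeded (20-mer),
ungapped aligner over the doubled reference sequence; each candidate
diagonal is scanned for the longest window with ≤ 3 mismatches, and window
edges are trimmed so no mismatch sits within 4 bases of an end.  The trim
is what keeps junction evidence sharp: without it an alignment absorbs up
to the mismatch budget of foreign bases past the junction, smearing clip
coordinates and polluting the pileup near insertion sites.  Alignment is
ungapped by design — substitution errors dominate the emulated data, and
indel-bearing reads simply surface as clipped/broken alignments; pre-aligned
SAM input (whose CIGARs carry indels) is accepted with identical
downstream semantics.

**Breakpoints.**  Reads with a soft-clipped tail ≥ 20 bases are clustered
by (clip coordinate, side); tails are consensus-called by per-column
majority.  Insertions with a target-site duplication of t bases produce a
crossed-over cluster pair whose reference gap equals t; pairs are accepted
when the gap lies in the signature range 3–12 bp and both tail consensus
sequences match the same catalogued element's two termini (either
orientation; semi-global edlib placement, ≤ 10% divergence).  Junction
microhomology shifts apparent breakpoints deterministically; the offset of
the tail within the element corrects the reported position.  Pairing is
strongest-first, and weaker same-subgroup events within the signature
radius of a stronger one are suppressed as jitter satellites — the
resolution limit is therefore one event per subgroup per ~12 bp.
Coordinates are 1-based, plus-strand, with the insertion position defined
as the last reference base before inserted material.  Unpaired or
unmatched clusters are reported as unassigned structural variation.

**Junction quantification.**  Per event, two 80-bp junction probes
(40 bp flank + 40 bp terminus, TSD- and orientation-aware) and one 80-bp
uninterrupted reference probe *per junction side*.  Candidate reads
(alignments overlapping a junction window, plus unmapped reads sharing an
exact midpoint 14-mer with a junction probe) are aligned locally to their
side's probe pair; support requires the best alignment to cover the probe
midpoint with ≥ 10 aligned bases on each side at ≥ 0.6 identity over the
aligned region, ties are discarded as ambiguous, and a junction vote on
either side overrides a reference vote produced by the read's duplicated
target site on the other side.  The reported frequency is the mean over
junction sides with ≥ 1 junction read of the per-side ratio
junction/(junction+reference).  Per-side ratios matter: each disrupted
molecule exposes two junctions while an intact molecule presents one
uninterrupted site, so pooling both junction counts against a
deduplicated reference count would roughly double the apparent frequency.
Sides without junction-spanning reads are disregarded; events with no
junction-spanning reads on either side are dropped from the table.

**Mobile-element fraction.**  Competitive mapping against plasmid + all
catalogued subgroups; each read contributes its aligned bases to its best
hit; the statistic is summed mean subgroup depth over mean plasmid depth.
It is ~0 for intact populations and approaches 1 when every molecule
carries one element (junction-adjacent clipped bases cost a few percent).

**Variants.**  Pileup over unclipped aligned segments only; per position
and alternative allele a one-sided binomial test of the alt count against
a fixed per-base error rate (default 0.3%; the full rate is used per
allele, which is conservative by ~3×).  Calls require p < 1%,
frequency ≥ 0.25% and ≥ 3 supporting reads; no multiple-testing
correction beyond the fixed alpha.  At 7200× the 3-read floor corresponds
to 0.04%.

**Time courses.**  Per-feature frequencies across samples are assembled
into a tidy table; enrichment is the OLS slope of ln(frequency) on
generation over a chosen window, reported as 100(e^slope − 1) percent per
generation.  While rare, every mode enriches at ≈ (c + k_total) per
generation, so a 0.24/generation exponent reads out as ~27%/generation.

## Growth rates

Blank-corrected OD (mean of un-inoculated wells subtracted, floored at
10⁻⁴ for log safety), rolling 5-point OLS of ln(OD) on time in hours, and
the arithmetic mean of local rates where corrected OD lies strictly inside
(0.04, 0.4).  Regression on ln(OD) rather than raw OD is the standard
exponential-phase estimator and makes a rate like 0.84/h dimensionally
coherent; `log_od=False` provides the literal raw-OD alternative.
Production load = 1 − r_producer/r_nonproducer.

## Synthetic data: what it emulates, what it does not

Generators default to the emulated experimental design: ~7 kb circular plasmid with a
three-gene operon annotation, 2 × 150 bp paired-end reads at 7200× mean
depth, normal insert sizes (300 ± 60), uniform substitution errors at
0.3%, five sampling points across ~70 generations, 10-min OD sampling with
a logistic capacity of 10 OD units (far above the 0.04–0.4 band, so the
band sits in near-pure exponential phase).  Escape spectra assign each
mode a rate share of the aggregate k; mode frequencies follow the
multi-type closed form N_i/P = (k_i/(c+K))(e^{(c+K)g} − 1), which sums to
the two-state model exactly.  Fragments are sampled per *base* (mass
weighting), so longer disrupted molecules yield proportionally more
fragments, as in real shotgun libraries.  All sequences are random under
fixed seeds; catalog entries carry the emulated subgroup names, lengths
and genomic copy numbers but are synthetic stand-ins.

Not modelled: instrument quality-score profiles, indel sequencing errors
(off by default to keep variant tests interpretable), PCR duplicates, GC
bias, secondary-structure artefacts, real IS target-site preferences, and
fitness differences among non-producer modes (all modes confer full load
alleviation).  Passing round-trip tests therefore demonstrates the
pipeline's statistical correctness under its stated error model, not
robustness to every artefact of real libraries.

## Design choices on genuinely open points

* Among natural formulation alternatives (doubling-based exponents,
  relative load c·μ, division-coupled escape), the convention above
  (absolute load c, μ = 1, continuous escape) is adopted because it alone
  reproduces all benchmark model predictions
  (half-lives 47/63/66 generations, the 10-generation extension for a
  28→23% load reduction, 96% takeover at g = 60, <3% at g = 37)
  simultaneously.
* Whether the half-life observable is defined on producer fraction or on
  relative titer is immaterial under the proportionality assumption; the
  fraction definition is used.
* Global mapping of 150-bp reads against 80-bp probes at identity 0.6 is
  under-specified at the read ends; the implementation keeps the two
  operative constraints — identity ≥ 0.6 and junction-spanning coverage —
  as best-local-alignment with the midpoint-span rule.
* Breakpoint calling uses explicit min-clip/min-support thresholds rather
  than a p-value on the unaligned-read fraction, whose definition is not
  reproducible.
* The mobile-element denominator is plasmid-only coverage (the benchmark
  end point is ~100%, which a plasmid+element denominator could not reach).
* Reactor-volume annotation keeps a single anchor (60 generations ↔ 2 m³)
  and labels generations only within ±2 of an anchor; other rows are user
  input.
* Merged subgroups (IS10R/L → IS10, IS1A/B/F → IS1) keep the first
  member's sequence as representative; competitive coverage is summed
  under the merged name.

## Problem sizes used by the shipped analyses

The drivers and the test suite run the full pipeline at 7200× where the
claim concerns that depth (detection floor, round-trip recovery) and at
400–2000× for controls and time courses; stochastic ensembles use 120–300
seeds with the hybrid threshold at 5 × 10⁴ cells.  These sizes are the
package's own defaults for desk-side reproduction; all are parameters.

## Known limitations

FASTQ-path variant calling is substitution-only; short indels appear as
breakpoint clusters rather than VariantCalls.  Events of the same subgroup
within ~12 bp are unresolvable.  The error model is a single uniform
substitution rate; per-base qualities are parsed but not yet used by the
caller.  The fit assumes independent homoscedastic residuals across time
points; replicate correlation is not modelled.
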