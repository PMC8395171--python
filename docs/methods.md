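# Methods

## The screening model

A chromosome-painting library is a pool of short oligos (modelled at 45
nt) tiling a source chromosome. Whether a probe transfers to a related
species is reduced to a per-oligo retention question: an oligo is
retained on a target locus when the ungapped placement matches at least
`max(min_match_bp, ceil(min_homology_frac x oligo_length))` bases —
defaults 32 bp and 0.70, which coincide at 45 nt (0.70 x 45 rounds up
to 32). N bases never match. The aligner is seed-and-extend: exact
k-mers of the oligo are looked up in a sorted-array index of both
genome strands; each seed fixes a gapless diagonal; all seeds on one
(chromosome, strand, diagonal) collapse into a single full-length
placement scored in one pass. Hits are reported best-first
(matched bases, then chromosome, then coordinate) with a per-oligo cap.

**Why ungapped.** At 45 nt the retention criterion is a matched-length
cutoff; indels would change the bookkeeping (span vs. matched bases)
without changing the question being asked, and an ungapped model admits
an exact brute-force oracle (every placement of every oligo scored by
direct comparison) against which the screen is tested for set equality
on small instances. A gapped mode is deliberately out of scope, and the
divergence simulator is substitution-only for consistency.

**Seed length and sensitivity.** `seed_k` defaults to 16, which is
near-exhaustive for conspecific or lightly diverged screens and keeps
index lookups specific. Detection requires one exact k-run of matches,
so sensitivity falls with divergence: measured on simulated 45-mers,
the probability that a *retained* oligo still contains a clean 16-run
is ~0.54 at 12% substitution and ~0.20 at 20%, versus ~0.93 and ~0.70
for an 10-mer seed. The synthetic presets therefore screen with
`seed_k=10`. No single-seed choice is exhaustive for diverged probes (a
retained 45-mer with 13 substitutions can lack even an 8-run), which is
why statements about the retention *rule* (e.g. its binomial behaviour
under divergence, below) are evaluated at the true loci recorded in the
simulation truth log, while the screen itself is characterized by
set-equality against the brute-force oracle on instances whose retained
hits are exact copies, and by monotonicity under divergence.

## Counts, densities, signal calls

The count matrix records, per probe set and chromosome, the number of
*distinct* oligos with at least one retained hit: an oligo hitting one
chromosome at three loci counts once there, but an oligo hitting three
homoeologous chromosomes counts on each (row sums may exceed the pool
size in a polyploid). Density profiles bin hits into fixed windows
(default 500 kb, 0-based half-open, assignment by hit start; the last
window may be short) without per-oligo deduplication, so window sums
carry locus multiplicity and are >= the matrix cell.

Counts are thresholded into three levels. `candidate_min` (default
1000) separates "no visible signal expected" from "candidate".
`confident_min` (default 3000) bounds an *uncertain* band: in the
packaged published matrix, counts of 1390 and 2548 produced no observed
microscope signal while 2888 did, so a single cutoff cannot reproduce
microscopy and the band makes that ambiguity explicit rather than
hiding it. Pattern vectors (window densities normalized to sum 1) are
attached to candidate-level cells only; sub-candidate profiles are
treated as noise. The synthetic presets scale both thresholds to the
library (10% and 30% of the smallest probe set) because absolute
full-genome cutoffs are meaningless at desk scale.

## Identification plans

A chromosome's barcode over a probe subset is the binary vector of
positive signals. Plan verification treats *confident*-level calls as
positive by default (`signal_level="present"`): uncertain counts have
empirically produced unobservable signals, so they cannot anchor a
positive identification; candidate-level verification is available as a
configuration. Within a group sharing a barcode, two chromosomes are
separable when, for some shared probe, their window-density patterns
differ by total-variation distance > 0.2 after both are resampled as
densities over relative chromosome position onto a common grid. The
threshold is this package's quantification of "visually distinct
signal morphology"; nothing in the source material quantifies it. At
most one chromosome may be identified by exclusion (the single leftover
after all others are positively named); a chromosome with an all-zero
barcode is never positively identified, only excluded.

The planner is greedy: repeatedly add the probe that newly resolves the
most chromosomes (ties: smaller candidate set, then label order), and
keep adding probes while capacity remains even at zero marginal gain,
because a probe can discriminate only jointly with a later one. Since
adding a probe never un-resolves a chromosome, the greedy planner with
capacity >= the probe count succeeds whenever any subset succeeds —
the property checked against exhaustive enumeration
(`enumerate_optimal`, guarded to 12 probes x 12 chromosomes). Probes
are packed two per round in selection order (digoxigenin/red then
biotin/green); single-locus markers such as 5S/35S rDNA may share a
round and fluorophore with a painting probe because a dot is visually
distinct from a paint, so the per-round constraint counts distinct
fluorophores. Probes are never reused across rounds (re-probing strips
prior signal). Round composition beyond packing order is not optimized.

## Karyotype conventions

Within each cell, homolog copies of a chromosome are averaged first
(cells can miss a copy; per-cell homolog means keep cells comparable),
then means and sample SDs (ddof 1; 0 for a single cell) are taken
across cells of the long arm, short arm, total (= long + short per
cell) and ratio (= long/short per cell). The ratio is the **mean of
per-cell ratios, not the ratio of mean arms** — published tables are
only consistent with per-cell averaging (e.g. mean arms 2.02/1.56 give
1.29 while the printed ratio is 1.30). Reported tables round half-up
to 2 decimals. Centromere classes use the classical arm-ratio
boundaries 1.7 / 3.0 / 7.0 (inclusive on the left class), configurable
because the underlying convention is cited, not tabulated, in the
source material. Input records with short > long are swapped with a
logged warning rather than rejected.

Target chromosomes are named after reference chromosomes by exact
binary-barcode match over shared probe rows. Nothing is assigned
silently: no-match and multi-match targets are flagged, and reference
numbers claimed by several targets (the expected outcome for
homoeologous groups of a polyploid) are reported as shared.

Idiograms are deterministic SVG/JSON documents: bars ordered by label
(numeric suffixes compare numerically), lengths proportional to mean
total length, centromere at the arm boundary, annotation regions
`whole`, `distal-long`, `distal-short`, `pericentromeric`.

## The synthetic study system

The generator emulates the study conditions at desk scale with full
ground truth:

* **Reference genome** — 10 chromosomes, i.i.d. uniform bases, default
  lengths 2.0 down to 0.8 Mb (longest first, like a real karyotype).
  Uniform composition is deliberate: GC realism is irrelevant to the
  screened properties. rDNA analogs are *tagged intervals* (5S
  pericentromeric on the chr9 analog, 35S distal on the chr6 analog),
  not repeat sequences.
* **Library** — 45-nt oligos at evenly spaced starts, 0.25 oligos/kb,
  one probe set per source chromosome; oligos occurring more than once
  in the genome (either strand) are locally resampled (single-copy
  filter), and an unachievable density is an error reporting the
  achieved value.
* **Divergence** — per-site independent substitution at a scenario
  rate; scenario labels map million-year divergences through a crude
  fixed clock (0.01 subs/site/MY: 9 MY -> 0.09, 11.9 -> 0.119,
  18 -> 0.18) that organizes experiments and claims no realism. Under
  this model the retention rule obeys a closed form: an oligo is
  retained at its true locus with probability
  P(Binom(45, 1 - rate) >= 32), the oracle used for the divergence
  grid. Optional translocations move tagged segments (the
  tripidium-like preset moves the 5S analog from the chr9 analog to
  the chr5 analog) and update the truth log.
* **Polyploidy** — each basic chromosome becomes ploidy-level copies
  (default 2n = 60, x = 10, i.e. six homoeologs) with independent
  low-rate jitter substitutions (default 0.02).
* **Measurements** — per cell and homolog copy, arms are truth plus
  Gaussian noise (default SD 0.15 um, redrawn while non-positive),
  copies drop out at a missing-copy rate (default 0.05, at least one
  copy kept per cell), and long/short ordering is enforced per record,
  as a measurer would. Enforcing order makes the summary estimate
  *order-statistic* means: for chromosomes with close arms the sample
  long-arm mean estimates E[max], which exceeds the nominal long arm
  (+0.026 um for arms 1.38/1.21 at SD 0.15). Recovery tests therefore
  compare against Monte-Carlo order-statistic estimands rather than
  the raw truth, with a family-calibrated bound (|z| <= 3.5 across 10
  chromosomes x 3 quantities; empirically ~1% family-wise at the
  chosen design) instead of a per-quantity 2-SE check whose joint pass
  probability would be ~25% for a correct implementation.

What passing these tests does *not* show about real data: no repeat
landscape or biased composition, no indels or rearrangement breakpoint
complexity beyond whole-segment translocation, no hybridization
chemistry (signal strength is a pure oligo count), and no decay of
signal across sequential rounds.

## Problem sizes and numerical choices

The test and acceptance workloads use desk-scale instances chosen to
exercise every code path with tight statistical oracles: oracle
equivalence on 100 seeded instances of ~6–14 kb chromosomes with 20
oligos each; the divergence grid on a 600 kb reference with 152 oligos
(exact-binomial 3-sigma bands, which behave correctly where a normal
3-SE band fails at retention probabilities near 1); planner
greedy-vs-exhaustive on 150 random instances up to 6 probes x 10
chromosomes; recovery at the stated 10 cells / 6 copies / 0.15 um.
Synthetic presets shrink chromosomes by a configurable `length_scale`
(default 0.1). Determinism is part of the contract: every generator is
a pure function of (config, seed), screens are byte-identical across
runs, and the pipeline writes a content-hashed run report whose hash is
invariant across reruns of the same configuration. Seeds passed on the
command line are folded with fixed multipliers and reduced mod 2^31.

Degenerate inputs follow explicit rules: ties in extrema are reported
in label order; a zero matrix calls everything "none"; an empty probe
subset collides all chromosomes; a single cell yields SD 0; boundary
arm ratios classify into the lower class; window boundaries are
half-open (a hit at 499,999 belongs to window 0, at 500,000 to window
1).

## Known limitations

The screen is a detector, not a guarantee: at deep divergence it
undercounts retained loci by the seed-sensitivity factor documented
above, so cross-species count matrices are conservative. Pattern
separability collapses qualitative "signal morphology" into one number
(TV > 0.2) on window densities; real microscopes integrate intensity,
focus and neighbourhood context. The planner optimizes probe count and
round count only — not fluorophore assignment quality, probe cost, or
hybridization efficiency decay across rounds. Published full-genome
thresholds (1000/3000 oligos) are library- and microscope-specific and
should be recalibrated for other systems.
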