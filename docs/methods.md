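# Methods

This note documents the models, conventions and numerical choices behind
trflpkit, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinates and fragment lengths

Sequence coordinates are 0-based and half-open throughout. A terminal
restriction fragment (T-RF) is measured from the 5' base of the labeled
forward primer to the cut: for an enzyme with recognition site `S` and
cut offset `k` (BsuRI `GGCC`, k = 2; RsaI `GTAC`, k = 2), the length is
`(site_start − primer_offset) + k` bases. The primer is part of the
detected fragment because the fluorescent label sits on it. The default
sizing window is the closed interval [50, 500] bp, the range a capillary
run sizes reliably; first sites beyond it make a taxon invisible to that
enzyme, which is a modeled outcome (`out_of_window`), not an error —
single-enzyme fingerprints genuinely miss such groups, which is why two
enzymes are run.

The digest scan is conservative: IUPAC ambiguity codes in a clone never
match a site (`GGCN` is not read as `GGCC`), because a real digest may or
may not cut there; an ambiguous potential site upstream of the first
certain site is noted in the log. Primer location tolerates up to 2
mismatches by default (sequencing-error tolerance without spurious
anchors) and handles the degenerate 8F positions by IUPAC expansion.
Only the given strand is scanned; callers handle orientation.

## Fingerprint matrix

Profiles are reduced to relative areas (area, not height, is the default
abundance proxy; height is available), thresholded at a minimum relative
area of 0.5% — a standard noise floor for capillary T-RFLP — and binned
in 1 bp half-open bins `[c, c+1)` anchored at the window minimum, with
500.0 absorbed by the final bin. All three parameters are in `RunConfig`.
Binning conserves row sums exactly; bins empty in every sample are
dropped. Because true fragment lengths are integers sitting exactly on
bin edges, sizing noise can split one taxon's mass between two adjacent
bins; analyses that need per-taxon recovery should aggregate a ±1 bp
neighborhood (the tests do).

## Peak attribution

Predicted fragments drive the matching loop — clones are the typed
evidence, peaks the noisy observations. Each detected fragment is
assigned to the nearest peak within ±1 bp (ties toward the smaller peak
size); a peak may collect fragments from several taxa. Coverage
percentages are computed over **total** profile area; peaks whose
matched taxa disagree at the reporting level form a combined `A+B` label
so shared peak intervals are reported once and never double-counted (an
equal-split mode exists behind a flag). The unattributed percentage is
defined as the exact complement of the attributed total, so the
conservation identity holds to the last bit. Replicate aggregation uses
the sample standard deviation with absent groups counted as 0%.

## Chimera detection and bookkeeping

PCR chimeras are modeled as two parents joined at one breakpoint. The
detector slides breakpoints on a 50 bp grid over the pre-aligned clone;
at each, the 300 bp flanks left and right of the breakpoint are matched
against every reference, and the clone is called chimeric when the best
two-distinct-parent assignment beats the best single parent's mean flank
identity by more than 0.03. Flank windows (rather than whole-segment
identity) localize the signal near the recombination site; window, step
and margin are configurable. With ~10%-divergent parents the detector
recovers ≥ 90% of central-breakpoint chimeras with essentially no false
positives on chimera-free libraries (both properties are tested).
Breakpoint resolution is on the order of the window, which is sufficient
for the splitting bookkeeping it feeds.

Called chimeras are cut at the breakpoint; the halves (ids suffixed
`a`/`b`) enter library statistics as independent sequences. For
distance-based statistics the halves can be N-padded back to alignment
length; N positions are excluded from pairwise comparisons, and a pair
sharing no comparable position (two complementary halves) is assigned
the saturation ceiling rather than an error. Library chimera
percentages are half-up rounded to one decimal.

## Diversity statistics

- **Shannon** uses natural log; profile-based Shannon treats binned
  relative areas as the probabilities.
- **Chao1** is `S_obs + n₁²/(2 n₂)`; with no doubletons that form
  divides by zero, so the standard bias-corrected
  `S_obs + n₁(n₁−1)/(2(n₂+1))` is used, which coincides with the plain
  form whenever n₂ > 0.
- **Jukes–Cantor** distances exclude positions with a non-ACGT code in
  either sequence; mismatch fractions at or past 3/4 are assigned a
  saturation ceiling (default 2.0, beyond any grid used here). Inputs
  are assumed pre-aligned; alignment is out of scope.
- **OTU clustering** is furthest-neighbor (complete-linkage)
  agglomeration cut at the distance threshold, matching the era's
  default in the standard OTU software; partitions are relabeled by
  smallest member id so output is deterministic. The linkage criterion
  is the only one guaranteed to bound within-OTU distances by the
  cutoff.
- **Coverage curves**: `C_X(D)` is the fraction of X sequences with
  another X sequence within distance D; `C_XY(D)` the fraction with a Y
  sequence within D. The library comparison integrates
  `(C_X − C_XY)²` over a grid (default D = 0…0.5, step 0.01) and builds
  the null by shuffling library labels over the pooled sequences with
  sizes preserved; `p = (1 + #{null ≥ observed})/(n_perm + 1)` with 999
  permutations by default. For the reciprocal pair of comparisons the
  Bonferroni-corrected threshold is α/2 = 0.025. Note that comparing a
  library against an exact copy of itself is *maximally* significant
  under this statistic — every sequence's perfect partner sits in the
  other library, so heterologous coverage jumps to 1 at D = 0 — the
  same behavior as the established implementations; the test is
  calibrated for independently sampled libraries (type-I error ≈ the
  nominal level, verified by simulation).
- **NMDS** minimizes Kruskal stress-1 by SMACOF iterative majorization
  with monotone (isotonic) regression, run from a classical-scaling
  start plus 4 seeded random restarts (best solution wins); results are
  deterministic for a fixed seed. Stress of an exactly embeddable
  configuration converges to 0.

## Synthetic data: what it emulates

The generator reproduces the study conditions end to end: a 30-taxon
community (geometric rank-abundance, ratio 0.9 — moderately uneven, with
the dominant taxon near 10%), 1400 bp references evolved from one
ancestor by substitutions at a rate chosen so the mean *pairwise*
divergence equals the requested value (default 0.10), labeled cyclically
from the five class-level groups that dominate harbor sediments. Every
reference carries the 8F primer at position 0 and planted first
restriction sites giving well-separated T-RFs inside (50, 500) for both
enzymes. Clone libraries are multinomial samples with 0.5% per-base
error; chimeras replace a Bernoulli fraction of clones with two-parent
recombinants broken uniformly in the middle 60% of the alignment. The
default library scale mirrors the emulated study: 101 and 93 clones with
chimera rates 0.119 and 0.043. Electropherograms cover 5 sites × 3
replicates × 2 enzymes: one peak per taxon at the true T-RF plus
Gaussian sizing noise (sd 0.3 bp), areas proportional to site-perturbed
abundances (lognormal site effect sd 0.5, replicate noise sd 0.2), plus
Poisson-count (mean 2) spurious peaks of 0.05–0.3% area each. All
generators are deterministic under their seed, and truth tables record
everything needed to score every downstream stage.

What it does **not** emulate: indels and alignment uncertainty, rRNA
secondary-structure constraints on substitution, 16S copy-number
variation, partial digestion and pseudo-T-RF artifacts, dye pull-up, or
cross-run size-calibration drift. Passing the recovery tests therefore
shows the pipeline's logic is correct under its stated assumptions, not
that real electropherograms will attribute as cleanly.

## Problem sizes used in tests

The test suite runs the oracle comparisons at 10³ random sequences or
abundance vectors, the clustering oracle at 100 random 20-sequence
matrices, the detector operating characteristics at 100 chimeras / 100
clean clones, and the permutation-test calibration at 200 same-community
replicate pairs (50 + 50 sequences, 999 permutations) plus 100
disjoint-community pairs — sizes chosen so the whole suite documents the
statistical behavior in a few minutes on one CPU.

## Known limitations

- Distance-based statistics require pre-aligned input; real libraries
  need an external aligner first.
- The chimera detector is a transparent stand-in with the same downstream
  bookkeeping as the original screening workflow, not a reimplementation
  of any published detector's score; only its calls (counts, breakpoints)
  feed the pipeline.
- Attribution across enzymes by intersection is future work; each
  enzyme's electropherogram is attributed independently.
- Quantitative interpretation of coverage percentages inherits all
  T-RFLP caveats (amplification bias, copy number, shared peak
  intervals).
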