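# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `markereval`. Everything stated here is computed by the
package's tests or by `scripts/acceptance.py`; nothing is quoted from
external data.

## Scope and design

The package compares DNA metabarcoding markers along three axes — sequence
recovery, inter-species divergence, and taxonomic annotation — in two arms:
an *in-silico* arm operating on reference sequences with known taxonomy,
and a *reads* arm operating on simulated paired-end amplicon reads from
mixed-template samples. Both arms are orchestrated by `workflow.RunConfig`,
a single hashable configuration; the config hash and seed are embedded in
every output table so reports are self-describing and byte-reproducible.

Several steps are deliberately contract-level stand-ins for heavyweight
external tools (read-pair assembly, quality filtering, denoising, greedy
clustering, seeded database search). They implement the documented
behaviour of those steps — thresholds, tie-breaks, filter semantics — not
their internals, which keeps the pipeline dependency-free, deterministic,
and testable against oracles.

## Sequence comparison

**Alignment.** Needleman–Wunsch global and Smith–Waterman local alignment
under linear gap scoring, default `(+1, −1, −2)` for match/mismatch/gap.
Traceback ties are resolved deterministically (diagonal > up > left; the
local traceback starts at the first row-major maximal cell), so every
derived distance and identity is a pure function of its inputs. IUPAC
ambiguity codes are compared by degeneracy-set intersection: overlapping
sets count as a match. The dynamic-programming fills are numba-compiled.

**p-distance.** Uncorrected proportion of differing sites over columns
where both sequences have a base (pairwise deletion). No model correction
(Jukes–Cantor, K2P) is applied anywhere. Pairwise alignment replaces a
multiple alignment; on low-divergence sequences the two agree closely, and
removing the MSA dependency makes distances reproducible bit-for-bit.

**Clustering identity.** matches / alignment columns after excluding
terminal gap runs; internal gaps count against identity. Excluding
overhangs makes the criterion tolerant of length variation in short
marker classes.

**NND.** A species' nearest-neighbour distance is the minimum off-diagonal
entry of the species-mean distance matrix (ties broken by lexicographically
first neighbour). A raw-pair mode (`raw_pair_nnd`) that takes the minimum
over individual sequence pairs instead of species means is provided; the
matrix-based definition is the default because the summary is extracted
from the mean inter-species distance matrix.

## In-silico PCR

Primer sites are located by exhaustive ungapped scan of both strands with
at most `max_mismatch` set-intersection mismatches (default 2 — a
configuration default, not an empirical value). Among all valid
forward/reverse site pairs the shortest product is taken, mimicking the
dominant PCR product; primers are trimmed from the emitted amplicon so mock
reads are comparable to primer-trimmed HTS reads (a flag retains them).
Records lacking a site are skipped with a logged reason. There is no
thermodynamic annealing model and no chimera formation.

## Seeded search and consensus taxonomy

Candidate references must share at least one exact word with the query on
either strand (word size 28 for long markers, 12 for short ones);
candidates are locally aligned and gated on percent identity (98% at high
stringency, 70% for the screening search), an approximate E-value
`k·m·n·exp(−λ·score)` with fixed Karlin–Altschul constants (λ = 1.33,
k = 0.621 for ±1 scoring; the E-value only gates hits, and all thresholds
are exposed in `SearchParams`), and a minimum aligned query fraction
(default 0.8, an addition that suppresses spurious short local hits).

All hits tying for top score (exact integer score equality) are
consolidated rank by rank: unanimity assigns the name, any disagreement
assigns `AMBIGUOUS`, and ambiguity propagates to all finer ranks. A rank at
which all tied hits are `UNKNOWN` stays `UNKNOWN`; mixtures of known and
unknown count as disagreement. Against known truth each rank is classified
as correct / incorrect / ambiguous / no-match; `UNKNOWN` consensus counts
as ambiguous (unassigned), while no-match is reserved for queries with zero
passing hits, and the two are reported separately.

## Read pipeline

- **Merging:** the reverse mate is reverse-complemented and slid against
  the forward read; the longest overlap ≥ `min_overlap` (default 20) with
  mismatch rate ≤ 0.1 is accepted, disagreements resolved toward the
  higher-quality base (forward wins ties). Markers whose amplicons exceed
  the combined read length are instead concatenated with an all-N spacer
  sized to the uncovered middle, keeping coordinates aligned; N matches
  every base, so the spacer is neutral in identity computations.
- **Quality/length filter:** mean phred ≥ `min_mean_q` (default 30) and
  length within bounds; boundaries inclusive.
- **Denoising stand-in:** exact dereplication plus an abundance floor
  (default 2), sorted by abundance with lexicographic tie-break. This keeps
  the stage deterministic; it does not model per-base error correction.
- **OTU clustering:** greedy centroid clustering in abundance order at 98%
  identity (95% for the high-divergence spacer profile). Each unique joins
  the first centroid within the radius, else founds one; centroids are
  mutually below the threshold at founding time. Read order cannot change
  the result because the input order is itself deterministic.
- **Screening:** OTU centroids are searched at low stringency against a
  combined target + non-target database; OTUs whose best passing hit is
  outside the target group — or that have no passing hit — are removed.
- **Presence filters:** per-sample counts below 10 are zeroed, then rows
  totalling below 100 are dropped (both inclusive, applied in that order;
  idempotent). Richness pooling operates on presence after these filters.

## Marker metrics

Recovery is summarised as the per-stage median and unscaled MAD (no 1.4826
consistency factor) of per-sample counts. Specificity is the fraction of
assigned reads per sample outside the target group; samples with no
assigned reads are excluded with a warning. Resolution is the proportion of
target order-assigned reads left unassigned (including ambiguous) at
family, genus and species.

Compositional dispersion uses presence/absence Jaccard dissimilarity,
classical-scaling PCoA (double-centred Gram matrix, `scipy.linalg.eigh`;
axes below 1e−10 relative magnitude dropped, negative-eigenvalue axes
retained separately), and the geometric median by iteratively re-weighted
averaging (Weiszfeld, tolerance 1e−9, ≤1000 iterations, with the
Vardi–Zhang step when an iterate coincides with a data point). One median
is computed jointly over all retained axes — separate medians per axis sign
would be non-unique whenever a sign subspace is one-dimensional with an
even point count — and each marker's corrected distance is
`sqrt(max(0, d²₊ − d²₋))`, splitting the squared distance to the median by
eigenvalue sign.

## Statistics

- **Friedman rank sum:** within-block midranks, chi-square approximation
  with the standard tie correction, k−1 df (verified identical to an
  independent implementation and calibrated to 5% ± 1.5% type-I error at
  α = 0.05 over 5000 null simulations of 4 treatments × 35 blocks).
- **Wilcoxon signed rank:** zeros dropped, midranks on |d|; exact p by
  enumeration of all 2ⁿ sign patterns for n ≤ 12, otherwise normal
  approximation with tie-corrected variance and continuity correction;
  two-sided p doubles the smaller tail, capped at 1. Post hoc families are
  Holm-adjusted (raw p-values are reported alongside; the choice of Holm is
  a package decision flagged in output metadata).
- **Randomized-block ANOVA:** two-way decomposition without interaction
  (treatment + block) on complete blocks; F on the treatment mean square
  against the residual with (k−1)(b−1) error df; Tukey HSD p-values from
  the studentized range with the blocked model's error df. Incomplete
  blocks are dropped by `BlockedData.from_long` before testing.
- **Compact letter displays:** greedy insertion-order assignment satisfying
  both constraints (non-significant pairs share a letter; significant pairs
  share none), brute-force verified in tests.

## Synthetic data: what it emulates, and what it does not

Sequences evolve on a star-like hierarchy: one random ancestor per family,
genus ancestors mutated from it, species from their genus ancestor,
replicates from the species sequence. The planted parameters `d_genus`,
`d_species`, `d_intra` are expected *pairwise* p-distances; each daughter
branch mutates at rate d/2, giving an expected pairwise distance
2r(1−r) + 2r²/3 ≈ d at the rates used. Substitutions draw uniformly from
the three alternative bases; there are no indels by default (p-distances
then compose additively), though the alignment stack handles them.
Coverage gaps (species lacking any reference) and duplicate amplicons
(congeneric pairs made byte-identical — a planted resolution failure) are
Bernoulli draws recorded exactly in truth tables. Reads are generated from
the truth amplicons of *all* community species, including those omitted
from a marker's database: presence in the environment does not depend on
database coverage, and this is what produces no-match and misassignment
outcomes downstream.

Communities draw a species pool per sampling instance and
Dirichlet-multinomial template counts per replicate; read counts per taxon
use deterministic largest-remainder allocation so they stay exactly
proportional to template counts. Contaminant reads (a per-marker fraction)
come from a non-target reference pool and are cropped to the marker's
amplicon length, since the same primers produce them. Quality is constant
or linearly decaying per base, with an optional per-read offset
(sd ≈ 4) so mean-quality filtering removes a realistic tail rather than
acting as an all-or-nothing gate.

**Default study conditions** (`workflow.default_config`): a 48-species
taxonomy (4 orders × 2 families × 3 genera × 2 species), 12 sampling
instances × 3 replicates = 36 samples, 400 read pairs per sample and
marker, error rate 0.001, and four marker profiles emulating the
characteristic contrasts among a low-recovery barcode (multiplier 0.4,
concatenated mates), a low-divergence barcode (d_species 0.02, frequent
duplicate amplicons), a high-divergence nuclear spacer (d_species 0.10,
50% non-target contamination, 95% clustering), and a short loop
(120 nt, 31% coverage gaps, frequent duplicates). These scales are chosen
so a full two-arm run completes in about a minute while every statistic
retains enough samples and blocks to be meaningful; they are a scaled-down
idealisation, not a reproduction of any particular survey.

What passing tests on these data do **not** show: robustness to indel
sequencing error, chimeras, PCR bias, intragenomic marker variation,
taxonomic synonymy, or database mislabelling — none of which the generator
models (a single planted mislabel fixture exercises the incorrect-outcome
path). Real-data conclusions require real references and reads.

## Known limitations

- The seeded search is a stand-in: no two-hit seeding, X-drop, or
  composition-based statistics; E-values are approximate and only gate
  hits. Equivalence with exhaustive Smith–Waterman is verified on random
  databases of ≤50 references.
- Greedy clustering is order-dependent by construction (as in the tools it
  stands in for); determinism comes from the fixed abundance/lexicographic
  input order.
- The concatenation mode assumes the uncovered middle length is known from
  the configured amplicon length; with real reads of unknown insert size
  the spacer would misalign coordinates.
- Presence-filter thresholds (≥10/sample, ≥100/OTU) are fixed rule-of-thumb
  values; occupancy-model alternatives are out of scope.
- `friedman_test` requires complete blocks; blocks with missing cells must
  be dropped beforehand.
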