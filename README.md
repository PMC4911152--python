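# markereval

Evaluation framework for DNA metabarcoding markers, aimed at plant
environmental-DNA (eDNA) surveys from soil. When a mixed-template sample is
profiled with a single amplicon marker, what that marker reports depends on
three things that vary sharply among candidate loci (e.g. the plant barcodes
*rbc*L and *mat*K, the nuclear spacer ITS2, and the short plastid *trn*L P6
loop):

1. **Recovery** — are sequences of sufficient quality retained for the taxa
   present?
2. **Resolution** — is there enough divergence at the locus to tell taxa
   apart?
3. **Annotation** — can reference databases assign complete, correct
   taxonomy to the sequences?

`markereval` implements the full comparison pipeline for these questions as
a tested Python library, driven by a synthetic-data generator that plants
known divergence, database gaps, shared amplicons, contamination, and
sequencing error — so every metric can be checked against ground truth.

## What it computes

**In-silico arm** (database sequences with known taxonomy):

- per-rank coverage of a target taxa list, with the sequence:species ratio;
- in-silico PCR: degenerate-primer site location (IUPAC set-intersection
  matching, ungapped scan of both strands) and cropping of references to
  mock amplicons;
- mean interspecific uncorrected p-distances (pairwise global alignment,
  pairwise deletion of gap columns) and each species' nearest-neighbour
  distance, NND<sub>s</sub> = min<sub>t≠s</sub> d(s, t) — the barcode gap;
- seeded similarity search (exact shared word → Smith–Waterman extension →
  identity/E-value/coverage gates) with consolidation of all hits tying for
  top score: ranks where tied hits disagree become `AMBIGUOUS`;
- per-rank proportions of correct / incorrect / ambiguous / no-match
  assignments, and Friedman rank-sum tests (post hoc Wilcoxon signed-rank,
  Holm-adjusted) blocked by species.

**Reads arm** (paired-end reads from simulated soil samples):

- pair merging by overlap consensus (or concatenation with a neutral
  N-spacer for non-overlapping long markers), mean-quality and length
  filtering, exact dereplication with an abundance floor, greedy centroid
  OTU clustering at a percent-identity radius, low-stringency target-group
  screening, and the presence filters (≥10 reads per sample to count a
  taxon/OTU as present, ≥100 reads total to keep an OTU);
- recovery by stage (median ± MAD per sample), specificity (fraction of
  assigned reads outside the target group), taxonomic resolution
  (proportion of order-assigned reads unassigned at family/genus/species),
  pooled cumulative richness, and compositional dispersion: Jaccard
  dissimilarities → principal coordinates analysis → distance of each
  marker to the per-instance spatial (geometric) median, with the
  negative-eigenvalue correction d² = d²₊ − d²₋ for non-Euclidean input;
- randomized-block ANOVA with Tukey HSD and Friedman tests blocked by
  sample or sampling instance, summarised as compact letter displays.

## Worked example

```python
from markereval import (generate_taxonomy, generate_references,
                        extract_amplicons, species_distance_matrix,
                        nearest_neighbour_distances)
from markereval.workflow import default_config

taxonomy = generate_taxonomy(4, 2, 3, 2, seed=7)      # 48 species
markers = default_config(seed=7).markers
refdbs, _ = generate_references(taxonomy, [m.profile for m in markers], seed=7)

for mc in markers:
    amps, _ = extract_amplicons(refdbs[mc.name], mc.profile.primers)
    groups = {}
    for a in amps:
        groups.setdefault(a.truth.species, []).append(a.sequence)
    nnd = nearest_neighbour_distances(species_distance_matrix(groups))
    print(mc.name, round(float(nnd["nnd"].median()), 3), "over", len(nnd), "species")
```

prints (formatted as in `examples/02_insilico_pcr_and_divergence.py`):

```
 matK:  86 amplicons (0 skipped), median NND 0.048 over 43 species
 rbcL:  86 amplicons (0 skipped), median NND 0.012 over 43 species
 ITS2:  82 amplicons (0 skipped), median NND 0.097 over 41 species
 trnL:  68 amplicons (0 skipped), median NND 0.050 over 34 species
```

Each number is a marker's median barcode gap over the species it covers: a
median NND of 0.097 means the typical species differs from its closest
relative at ~9.7% of ITS2 amplicon sites, while the 0.012 median for the
low-divergence *rbc*L profile sits below the 2% identity margin used at
assignment time — such species pairs cluster into shared OTUs and return
ambiguous species calls. The *trn*L column is computed over fewer species
because its planted database gaps remove a third of the reference set.

The `examples/` directory holds one short script per capability: coverage,
divergence, consensus assignment, the read pipeline, and marker
complementarity. A thin CLI (`markereval coverage|insilico-pcr|nnd|assign|
insilico-eval|reads-eval`) wraps the same functions for shell use.

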