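"""The in-situ read pipeline on one synthetic marker.

Simulates paired-end soil-sample reads with sequencing error and fungal
contamination, then walks them through merging, quality filtering,
dereplication, OTU clustering, target screening and the presence filters,
printing how many reads each sample retains at every stage.
"""

import warnings

from markereval.workflow import run_reads_eval
from markereval.insilico_pcr import PrimerPair
from markereval.synthetic_data import MarkerProfile, QualityModel
from markereval.workflow import MarkerConfig, RunConfig

marker = MarkerConfig(
    profile=MarkerProfile(
        name="demo", amplicon_length=150,
        primers=PrimerPair("ATGCGTCAAGGCTTACGTGA", "TGCACGTTAGCCATGGATCA"),
        d_species=0.1, d_genus=0.35),
    merge_mode="overlap", contamination_fraction=0.2,
    quality=QualityModel(36, 36, read_sd=3.0))

cfg = RunConfig(seed=11, n_orders=2, n_families_per_order=1,
                n_genera_per_family=2, n_species_per_genus=2,
                n_instances=3, n_replicates=2, n_species_per_instance=4,
                reads_per_sample=120, read_length=100, error_rate=0.002,
                presence_min_per_sample=5, presence_min_total=20,
                n_contaminants=5, contaminant_length=300, markers=(marker,))

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = run_reads_eval(cfg)

res = report.per_marker["demo"]
print("per-sample read counts by stage:\n")
print(res.stage_log.to_frame().T)
print("\nspecificity (fraction non-target per sample):")
print(res.specificity.round(3).to_string())
print("\nCounts can only fall from stage to stage; about 20% of assigned"
      "\nreads are reported as non-target, matching the planted fungal"
      "\ncontamination fraction.")
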