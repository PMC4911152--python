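"""End-to-end orchestration of the two evaluation arms.

The *in-silico* arm mirrors a database-sequence evaluation: reference
coverage of a target list, mock-amplicon extraction, nearest-neighbour
divergence over species shared by all markers, self-assignment accuracy,
and Friedman/Wilcoxon tests blocked by species.

The *reads* arm mirrors a soil-sample evaluation: paired-end
merge/concatenation, quality filtering, dereplication, greedy OTU
clustering, low-stringency target screening, high-stringency taxonomy
assignment, presence filters, and the recovery / specificity / resolution
/ richness / dispersion metrics with tests blocked by sample or sampling
instance.

Every run is fully determined by a :class:`RunConfig` (single seed, TOML
serialisable); output tables embed the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import marker_metrics as mm
from . import reads_pipeline as rp
from . import stats as st
from .divergence import (nearest_neighbour_distances, restrict_to_shared_species,
                         species_distance_matrix)
from .insilico_pcr import PrimerPair, extract_amplicons
from .refdb import RefDB, RefRecord, coverage_summary
from .synthetic_data import (CommunityTruth, MarkerProfile, QualityModel,
                             ReferenceTruth, Taxonomy, generate_community,
                             generate_contaminants, generate_reads,
                             generate_references, generate_taxonomy)
from .taxassign import (LOW_STRINGENCY, AssignmentResult, assign_query,
                        accuracy_summary, params_for_marker)
from .taxonomy import AMBIGUOUS, UNKNOWN, Lineage

TARGET_KINGDOM = "Plantae"


def is_target_lineage(lineage: Lineage) -> bool:
    """Group membership used for screening/specificity: vascular-plant-like."""
    return lineage.kingdom == TARGET_KINGDOM


# ----------------------------------------------------------------- config

@dataclass(frozen=True)
class MarkerConfig:
    """One marker's synthesis, pipeline and search settings."""

    profile: MarkerProfile
    cluster_identity: float = 98.0
    merge_mode: str = "overlap"  # or "concat" for non-overlapping mates
    recovery_multiplier: float = 1.0
    contamination_fraction: float = 0.0
    quality: QualityModel = field(default_factory=QualityModel)

    @property
    def name(self) -> str:
        return self.profile.name


@dataclass(frozen=True)
class RunConfig:
    """Complete, hashable description of a synthetic benchmark run."""

    seed: int = 0
    alpha: float = 0.05
    # taxonomy scale
    n_orders: int = 4
    n_families_per_order: int = 2
    n_genera_per_family: int = 3
    n_species_per_genus: int = 2
    # community / reads
    n_instances: int = 12
    n_replicates: int = 3
    n_species_per_instance: int = 10
    reads_per_sample: int = 400
    read_length: int = 250
    error_rate: float = 0.001
    # pipeline thresholds
    min_overlap: int = 20
    max_mismatch_rate: float = 0.1
    min_mean_q: float = 30.0
    min_len: int = 50
    max_len: int = 2000
    min_abundance: int = 2
    presence_min_per_sample: int = 10
    presence_min_total: int = 100
    # contaminant pool
    n_contaminants: int = 20
    contaminant_length: int = 600
    markers: tuple[MarkerConfig, ...] = ()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        markers = []
        for m in raw.pop("markers", []):
            prof = m.pop("profile")
            prof["primers"] = PrimerPair(**prof.pop("primers"))
            quality = QualityModel(**m.pop("quality", {}))
            markers.append(MarkerConfig(profile=MarkerProfile(**prof),
                                        quality=quality, **m))
        return cls(markers=tuple(markers), **raw)


def default_config(seed: int = 0) -> RunConfig:
    """The default four-marker benchmark scenario.

    The marker profiles emulate the contrasts observed among the two
    full-length plant barcodes, a nuclear spacer, and a short plastid
    loop: divergence ordering ITS2 > matK > trnL > rbcL, a pronounced
    species-level coverage gap for trnL, frequent indistinguishable
    amplicons for trnL and rbcL, low recovery for matK, and heavy
    non-target contamination for ITS2.
    """
    matk = MarkerConfig(
        profile=MarkerProfile(
            name="matK", amplicon_length=520,
            primers=PrimerPair("ATGCGTCAAGGCTTACGTRA", "TGCACGTTAGCCATGGATCA"),
            d_species=0.05, d_genus=0.15,
            coverage_gap_rate=0.17, duplicate_amplicon_rate=0.10,
            n_seqs_per_species=2),
        merge_mode="concat", recovery_multiplier=0.4,
        contamination_fraction=0.0, quality=QualityModel(33, 33, read_sd=4.0))
    rbcl = MarkerConfig(
        profile=MarkerProfile(
            name="rbcL", amplicon_length=520,
            primers=PrimerPair("GGCAAGTCTTACGCATGGTA", "CATGCGATTGGAACCTAGCA"),
            d_species=0.02, d_genus=0.12,
            coverage_gap_rate=0.18, duplicate_amplicon_rate=0.20,
            n_seqs_per_species=2),
        merge_mode="concat", recovery_multiplier=1.0,
        contamination_fraction=0.09, quality=QualityModel(33, 33, read_sd=4.0))
    its2 = MarkerConfig(
        profile=MarkerProfile(
            name="ITS2", amplicon_length=350,
            primers=PrimerPair("TACGCATGGTTGAGCCATGA", "GCATCGTTACGGATGCAAGT"),
            d_species=0.10, d_genus=0.25,
            coverage_gap_rate=0.19, duplicate_amplicon_rate=0.0,
            n_seqs_per_species=2),
        cluster_identity=95.0, merge_mode="overlap", recovery_multiplier=1.0,
        contamination_fraction=0.50, quality=QualityModel(36, 36, read_sd=4.0))
    trnl = MarkerConfig(
        profile=MarkerProfile(
            name="trnL", amplicon_length=120,
            primers=PrimerPair("AGTTCGACCTGGATTACGCA", "CCATGTAGCTTGACGTACGA"),
            d_species=0.04, d_genus=0.12,
            coverage_gap_rate=0.31, duplicate_amplicon_rate=0.30,
            n_seqs_per_species=2),
        merge_mode="overlap", recovery_multiplier=1.0,
        contamination_fraction=0.06, quality=QualityModel(36, 36, read_sd=4.0))
    return RunConfig(seed=seed, markers=(matk, rbcl, its2, trnl))


# ---------------------------------------------------------- in-silico arm

@dataclass
class InsilicoReport:
    coverage: pd.DataFrame          # marker × rank coverage
    nnd_wide: pd.DataFrame          # shared species × marker NND
    nnd_summary: pd.DataFrame       # marker: median, mad, n
    accuracy: pd.DataFrame          # (marker, rank) outcome proportions
    friedman: st.TestResult | None
    taxonomy: Taxonomy
    refdbs: dict[str, RefDB]
    truth: ReferenceTruth
    assignments: dict[str, list[AssignmentResult]]
    config_hash: str = ""
    seed: int = 0


def _build_synthetic_inputs(cfg: RunConfig):
    taxonomy = generate_taxonomy(cfg.n_orders, cfg.n_families_per_order,
                                 cfg.n_genera_per_family, cfg.n_species_per_genus,
                                 seed=cfg.seed)
    profiles = [m.profile for m in cfg.markers]
    refdbs, truth = generate_references(taxonomy, profiles, seed=cfg.seed)
    return taxonomy, refdbs, truth


def run_insilico_eval(cfg: RunConfig, out_dir: str | Path | None = None) -> InsilicoReport:
    """Coverage → in-silico PCR → shared-species NND → self-assignment →
    blocked tests, over the configured synthetic references."""
    if not cfg.markers:
        raise ValueError("config defines no markers")
    taxonomy, refdbs, truth = _build_synthetic_inputs(cfg)
    targets = taxonomy.species

    coverage_rows = []
    amplicons = {}
    for mc in cfg.markers:
        db = refdbs[mc.name]
        cov = coverage_summary(db, targets)
        for rank, row in cov.rows.iterrows():
            coverage_rows.append({"marker": mc.name, "rank": rank, **row.to_dict(),
                                  "seq_to_species_ratio": cov.seq_to_species_ratio})
        amps, skip_log = extract_amplicons(db, mc.profile.primers)
        if not amps:
            warnings.warn(f"marker {mc.name}: zero amplicons extracted; flagged")
        if len(skip_log):
            warnings.warn(f"marker {mc.name}: {len(skip_log)} records skipped in PCR")
        amplicons[mc.name] = amps
    coverage = pd.DataFrame(coverage_rows)

    per_marker_species = {
        name: {a.truth.species for a in amps} for name, amps in amplicons.items()
    }
    shared = restrict_to_shared_species(per_marker_species)

    nnd_cols = {}
    for mc in cfg.markers:
        groups = {a.truth.species: [] for a in amplicons[mc.name] if a.truth.species in shared}
        for a in amplicons[mc.name]:
            if a.truth.species in shared:
                groups[a.truth.species].append(a.sequence)
        if len(groups) >= 2:
            dm = species_distance_matrix(groups)
            nnd = nearest_neighbour_distances(dm).set_index("species")["nnd"]
            nnd_cols[mc.name] = nnd
    nnd_wide = pd.DataFrame(nnd_cols).dropna().sort_index()

    nnd_summary = pd.DataFrame({
        name: {"median_nnd": float(col.median()),
               "mad_nnd": mm.median_absolute_deviation(col.to_numpy()),
               "n_species": int(col.size)}
        for name, col in nnd_wide.items()
    }).T

    friedman = None
    if nnd_wide.shape[0] >= 2 and nnd_wide.shape[1] >= 2:
        friedman = st.friedman_with_posthoc(
            st.BlockedData(values=nnd_wide.to_numpy(),
                           blocks=list(nnd_wide.index),
                           treatments=list(nnd_wide.columns)),
            alpha=cfg.alpha)

    assignments: dict[str, list[AssignmentResult]] = {}
    acc_rows = []
    for mc in cfg.markers:
        db = refdbs[mc.name]
        params = params_for_marker(mc.profile.amplicon_length)
        results = [
            assign_query(a.source_id, a.sequence, db, params, truth=a.truth)
            for a in amplicons[mc.name]
        ]
        assignments[mc.name] = results
        if results:
            acc = accuracy_summary(results)
            for rank, row in acc.iterrows():
                acc_rows.append({"marker": mc.name, "rank": rank, **row.to_dict()})
    accuracy = pd.DataFrame(acc_rows)

    report = InsilicoReport(coverage=coverage, nnd_wide=nnd_wide,
                            nnd_summary=nnd_summary, accuracy=accuracy,
                            friedman=friedman, taxonomy=taxonomy, refdbs=refdbs,
                            truth=truth, assignments=assignments,
                            config_hash=cfg.config_hash, seed=cfg.seed)
    if out_dir is not None:
        write_insilico_report(report, out_dir)
    return report


# -------------------------------------------------------------- reads arm

@dataclass
class MarkerReadsResult:
    """Per-marker intermediate products of the reads arm."""

    stage_log: rp.StageLog
    otu_table: rp.OTUTable                 # screened, presence-filtered counts
    otu_counts: pd.DataFrame
    assign_counts: pd.DataFrame            # per unique: consensus ranks + per-sample counts
    resolution: pd.DataFrame
    specificity: pd.Series
    taxon_sets: dict[str, dict[str, dict[str, set]]]  # rank -> sample -> set


@dataclass
class ReadsReport:
    community: CommunityTruth
    per_marker: dict[str, MarkerReadsResult]
    recovery: pd.DataFrame                 # stage × marker medians (with MAD)
    recovery_test: st.TestResult | None
    specificity: pd.DataFrame              # per sample × marker non-target fraction
    resolution_test: st.TestResult | None
    richness: pd.DataFrame                 # marker × level per-pool mean + total
    richness_tests: dict[str, st.TestResult]
    dispersion: dict[str, mm.DispersionResult]   # per rank
    dispersion_tests: dict[str, st.TestResult]
    config_hash: str = ""
    seed: int = 0


def _process_marker_reads(cfg: RunConfig, mc: MarkerConfig,
                          pairs: dict, screen_db: RefDB,
                          assign_db: RefDB) -> MarkerReadsResult:
    samples = sorted({s for (s, m) in pairs if m == mc.name})
    log = rp.StageLog()
    log.append("raw", {s: len(pairs[(s, mc.name)][0]) for s in samples})

    spacer_len = max(0, mc.profile.amplicon_length - 2 * cfg.read_length)
    merged: dict[str, rp.ReadSet] = {}
    for s in samples:
        fwd, rev = pairs[(s, mc.name)]
        if mc.merge_mode == "concat":
            merged[s] = rp.concat_pairs(fwd, rev, spacer="N" * spacer_len) \
                if spacer_len else rp.concat_pairs(fwd, rev, spacer="")
        else:
            merged[s], _ = rp.merge_pairs(fwd, rev, cfg.min_overlap, cfg.max_mismatch_rate)
    log.append("merged", {s: len(merged[s]) for s in samples})

    filtered = {s: rp.quality_filter(merged[s], cfg.min_mean_q, cfg.min_len, cfg.max_len)
                for s in samples}
    log.append("quality_filtered", {s: len(filtered[s]) for s in samples})

    per_sample_seqs = {s: [r.sequence for r in filtered[s].reads] for s in samples}
    pooled = [seq for s in samples for seq in per_sample_seqs[s]]
    uniques = rp.dereplicate(pooled, cfg.min_abundance)
    kept = {seq for seq, _ in uniques}
    log.append("dereplicated",
               {s: sum(1 for q in per_sample_seqs[s] if q in kept) for s in samples})

    table = rp.cluster_otus(uniques, mc.cluster_identity)
    counts = rp.otu_counts(table, per_sample_seqs)
    log.append("clustered", {s: int(counts[s].sum()) for s in samples})

    screened = rp.screen_target_group(table, screen_db, LOW_STRINGENCY, is_target_lineage)
    log.append("screened",
               {s: int(screened.counts[s].sum()) if screened.counts is not None else 0
                for s in samples})

    filtered_counts = rp.apply_presence_filters(
        screened.counts if screened.counts is not None else pd.DataFrame(columns=samples),
        cfg.presence_min_per_sample, cfg.presence_min_total)
    log.append("presence_filtered", {s: int(filtered_counts[s].sum()) for s in samples})

    # taxonomy arm: assign surviving uniques at high stringency
    params = params_for_marker(mc.profile.amplicon_length)
    rows = []
    unique_counts = {
        s: pd.Series(per_sample_seqs[s]).value_counts() for s in samples
    }
    for idx, (seq, _) in enumerate(uniques):
        res = assign_query(f"u{idx}", seq, assign_db, params)
        cons = res.consensus
        row = {"unique": f"u{idx}", "sequence": seq,
               "assigned": not res.no_match,
               "is_target": (not res.no_match) and is_target_lineage(cons)}
        for rank in ("order", "family", "genus", "species"):
            val = cons.at(rank)
            row[rank] = val
            row[f"{rank}_resolved"] = val not in (UNKNOWN, AMBIGUOUS)
        for s in samples:
            row[f"count_{s}"] = int(unique_counts[s].get(seq, 0))
        rows.append(row)
    assign_counts = pd.DataFrame(rows)

    # per-read tables for specificity and resolution
    spec_flags: dict[str, list[bool]] = {s: [] for s in samples}
    res_rows = []
    if len(assign_counts):
        assigned = assign_counts[assign_counts["assigned"]]
        for _, row in assigned.iterrows():
            for s in samples:
                n = row[f"count_{s}"]
                if n:
                    spec_flags[s].extend([bool(row["is_target"])] * n)
        target_rows = assign_counts[assign_counts["is_target"]]
        for _, row in target_rows.iterrows():
            if not row["order_resolved"]:
                continue
            for s in samples:
                n = row[f"count_{s}"]
                if n:
                    res_rows.extend([{
                        "sample": s, "order_assigned": True,
                        "family_resolved": bool(row["family_resolved"]),
                        "genus_resolved": bool(row["genus_resolved"]),
                        "species_resolved": bool(row["species_resolved"]),
                    }] * n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        specificity = mm.specificity_per_sample(spec_flags)
        resolution = (mm.resolution_profile(pd.DataFrame(res_rows))
                      if res_rows else pd.DataFrame())

    # per-sample presence of target taxa (>= presence_min_per_sample reads)
    taxon_sets: dict[str, dict[str, set]] = {}
    for rank in ("order", "family", "genus"):
        per_sample: dict[str, set] = {s: set() for s in samples}
        if len(assign_counts):
            resolved = assign_counts[
                assign_counts["is_target"] & assign_counts[f"{rank}_resolved"]]
            for taxon, grp in resolved.groupby(rank):
                for s in samples:
                    if grp[f"count_{s}"].sum() >= cfg.presence_min_per_sample:
                        per_sample[s].add(taxon)
        taxon_sets[rank] = per_sample

    return MarkerReadsResult(stage_log=log, otu_table=screened,
                             otu_counts=filtered_counts, assign_counts=assign_counts,
                             resolution=resolution, specificity=specificity,
                             taxon_sets=taxon_sets)


def run_reads_eval(cfg: RunConfig, out_dir: str | Path | None = None) -> ReadsReport:
    """Full read-pipeline arm on the configured synthetic scenario."""
    if not cfg.markers:
        raise ValueError("config defines no markers")
    taxonomy, refdbs, truth = _build_synthetic_inputs(cfg)
    contaminants = generate_contaminants(cfg.n_contaminants, cfg.contaminant_length,
                                         seed=cfg.seed)
    community = generate_community(
        taxonomy, cfg.n_instances, cfg.n_replicates, cfg.n_species_per_instance,
        cfg.reads_per_sample,
        contamination_fraction={mc.name: mc.contamination_fraction for mc in cfg.markers},
        marker_multipliers={mc.name: mc.recovery_multiplier for mc in cfg.markers},
        seed=cfg.seed)

    pairs: dict = {}
    for mc in cfg.markers:
        coll = generate_reads(community, truth, [mc.name], cfg.read_length,
                              cfg.error_rate, mc.quality, contaminants,
                              contaminant_template_length=mc.profile.amplicon_length,
                              seed=cfg.seed)
        pairs.update(coll.pairs)

    # combined search database: marker references plus the non-target pool
    per_marker: dict[str, MarkerReadsResult] = {}
    for mc in cfg.markers:
        combined = RefDB(marker=mc.name)
        for rec in refdbs[mc.name].records:
            combined.add(rec)
        for rec in contaminants.records:
            combined.add(RefRecord(id=rec.id, marker=mc.name,
                                   sequence=rec.sequence, lineage=rec.lineage))
        per_marker[mc.name] = _process_marker_reads(cfg, mc, pairs, combined, combined)

    marker_names = [mc.name for mc in cfg.markers]
    samples = sorted(community.samples)

    recovery_frames = []
    for name in marker_names:
        r = mm.recovery_by_stage(per_marker[name].stage_log)
        r["marker"] = name
        recovery_frames.append(r.reset_index(names="stage"))
    recovery = pd.concat(recovery_frames, ignore_index=True)

    final_counts = pd.DataFrame({
        name: per_marker[name].stage_log.to_frame()["presence_filtered"]
        for name in marker_names
    }).loc[samples]
    recovery_test = None
    if len(marker_names) >= 2 and final_counts.notna().all().all():
        recovery_test = st.friedman_with_posthoc(
            st.BlockedData(final_counts.to_numpy(), samples, marker_names), cfg.alpha)

    specificity = pd.DataFrame(
        {name: per_marker[name].specificity for name in marker_names})

    resolution_test = None
    res_wide = pd.DataFrame({
        name: per_marker[name].resolution["unassigned_genus"]
        for name in marker_names if len(per_marker[name].resolution)
    }).dropna()
    if res_wide.shape[0] >= 2 and res_wide.shape[1] >= 2:
        resolution_test = st.friedman_with_posthoc(
            st.BlockedData(res_wide.to_numpy(), list(res_wide.index),
                           list(res_wide.columns)), cfg.alpha)

    # richness: pooled replicate unions at OTU and taxon levels
    pooling = community.pooling
    instances = sorted(set(pooling.values()))
    richness_rows = []
    richness_tests: dict[str, st.TestResult] = {}
    level_pool_values: dict[str, pd.DataFrame] = {}
    for level in ("otu", "order", "family", "genus"):
        per_marker_pools = {}
        for name in marker_names:
            if level == "otu":
                counts = per_marker[name].otu_counts
                sample_sets = {
                    s: set(counts.index[counts[s] > 0]) if s in counts.columns else set()
                    for s in samples}
            else:
                sample_sets = per_marker[name].taxon_sets[level]
            per_pool, total = mm.cumulative_richness(sample_sets, pooling)
            per_pool = per_pool.reindex(instances, fill_value=0)
            per_marker_pools[name] = per_pool
            richness_rows.append({"level": level, "marker": name,
                                  "mean_pool_richness": float(per_pool.mean()),
                                  "total_richness": int(total)})
        wide = pd.DataFrame(per_marker_pools)
        level_pool_values[level] = wide
        if wide.shape[0] >= 2 and wide.shape[1] >= 2:
            richness_tests[level] = st.blocked_anova_tukey(
                st.BlockedData(wide.to_numpy(), list(wide.index),
                               list(wide.columns)), cfg.alpha)
    richness = pd.DataFrame(richness_rows)

    dispersion: dict[str, mm.DispersionResult] = {}
    dispersion_tests: dict[str, st.TestResult] = {}
    for rank in ("order", "family", "genus"):
        comp: dict[str, dict[str, set]] = {}
        for inst in instances:
            inst_samples = [s for s in samples if pooling[s] == inst]
            comp[inst] = {}
            for name in marker_names:
                pooled_set: set = set()
                for s in inst_samples:
                    pooled_set |= per_marker[name].taxon_sets[rank][s]
                comp[inst][name] = pooled_set
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            usable = {}
            for g, ms in comp.items():
                nonempty = {k: v for k, v in ms.items() if v}
                if len(nonempty) >= 2:
                    usable[g] = nonempty
            disp = mm.dispersion_distances(usable) if usable else None
        if disp is not None and len(disp.distances):
            dispersion[rank] = disp
            d = disp.distances.dropna(axis=1, how="all").dropna()
            if d.shape[0] >= 2 and d.shape[1] >= 2:
                dispersion_tests[rank] = st.blocked_anova_tukey(
                    st.BlockedData(d.to_numpy(), list(d.index), list(d.columns)),
                    cfg.alpha)

    report = ReadsReport(community=community, per_marker=per_marker,
                         recovery=recovery, recovery_test=recovery_test,
                         specificity=specificity, resolution_test=resolution_test,
                         richness=richness, richness_tests=richness_tests,
                         dispersion=dispersion, dispersion_tests=dispersion_tests,
                         config_hash=cfg.config_hash, seed=cfg.seed)
    if out_dir is not None:
        write_reads_report(report, out_dir)
    return report


# ----------------------------------------------------------------- output

def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str, seed: int,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\tseed={seed}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def write_insilico_report(report: InsilicoReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h, s = report.config_hash, report.seed
    _write_tsv(report.coverage, out / "coverage.tsv", h, s)
    _write_tsv(report.nnd_wide.reset_index(names="species"), out / "nnd.tsv", h, s)
    _write_tsv(report.nnd_summary.reset_index(names="marker"),
               out / "nnd_summary.tsv", h, s)
    _write_tsv(report.accuracy, out / "assignment_accuracy.tsv", h, s)
    if report.friedman is not None:
        fr = report.friedman
        lines = pd.DataFrame([{"statistic": fr.statistic, "p_value": fr.p_value,
                               "df": fr.df[0],
                               "letters": json.dumps(fr.letters)}])
        _write_tsv(lines, out / "nnd_friedman.tsv", h, s)


def write_reads_report(report: ReadsReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h, s = report.config_hash, report.seed
    _write_tsv(report.recovery, out / "recovery.tsv", h, s)
    _write_tsv(report.specificity.reset_index(names="sample"),
               out / "specificity.tsv", h, s)
    _write_tsv(report.richness, out / "richness.tsv", h, s)
    for name, res in report.per_marker.items():
        _write_tsv(res.stage_log.to_frame().reset_index(names="sample"),
                   out / f"stage_log_{name}.tsv", h, s)
        if len(res.resolution):
            _write_tsv(res.resolution.reset_index(names="sample"),
                       out / f"resolution_{name}.tsv", h, s)
    for rank, disp in report.dispersion.items():
        _write_tsv(disp.distances.reset_index(names="instance"),
                   out / f"dispersion_{rank}.tsv", h, s)
    tests = []
    for label, t in [("recovery_friedman", report.recovery_test),
                     ("resolution_friedman", report.resolution_test),
                     *[(f"richness_anova_{k}", v) for k, v in report.richness_tests.items()],
                     *[(f"dispersion_anova_{k}", v) for k, v in report.dispersion_tests.items()]]:
        if t is not None:
            tests.append({"test": label, "statistic": t.statistic, "p_value": t.p_value,
                          "letters": json.dumps(t.letters) if t.letters else ""})
    if tests:
        _write_tsv(pd.DataFrame(tests), out / "tests.tsv", h, s)
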