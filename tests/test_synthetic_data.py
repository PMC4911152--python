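"""Ground-truth generator: taxonomy, references, communities, reads."""

import numpy as np
import pytest

from markereval.divergence import species_distance_matrix
from markereval.insilico_pcr import PrimerPair, extract_amplicons
from markereval.refdb import coverage_summary
from markereval.synthetic_data import (CommunityTruth, MarkerProfile,
                                       QualityModel, SyntheticError,
                                       generate_community,
                                       generate_contaminants, generate_reads,
                                       generate_references, generate_taxonomy,
                                       mutate_sequence, substream)

from conftest import tiny_marker


class TestGenerateTaxonomy:
    def test_counts_multiply(self):
        tax = generate_taxonomy(2, 2, 2, 2, seed=7)
        assert len(tax.species) == 16
        assert len({s.genus for s in tax.species}) == 8
        assert len({s.family for s in tax.species}) == 4
        assert len({s.order for s in tax.species}) == 2

    def test_same_seed_identical(self):
        t1 = generate_taxonomy(2, 2, 2, 2, seed=7)
        t2 = generate_taxonomy(2, 2, 2, 2, seed=7)
        assert t1.species == t2.species

    def test_different_seed_same_shape_different_leaves(self):
        t1 = generate_taxonomy(2, 2, 2, 3, seed=1)
        t2 = generate_taxonomy(2, 2, 2, 3, seed=2)
        assert {s.genus for s in t1.species} == {s.genus for s in t2.species}
        assert [s.species for s in t1.species] != [s.species for s in t2.species]

    def test_zero_counts_raise(self):
        with pytest.raises(SyntheticError):
            generate_taxonomy(0, 1, 1, 1)

    def test_binomials_nest_in_genus(self):
        tax = generate_taxonomy(1, 2, 2, 2, seed=3)
        assert all(s.species.split()[0] == s.genus for s in tax.species)


class TestMutateSequence:
    def test_rate_zero_identity(self):
        seq = "ACGT" * 25
        assert mutate_sequence(seq, 0.0, substream(0, "m")) == seq

    def test_rate_one_changes_every_base(self):
        seq = "ACGT" * 25
        out = mutate_sequence(seq, 1.0, substream(0, "m"))
        assert all(a != b for a, b in zip(seq, out))

    def test_realized_fraction_near_rate(self):
        rng = substream(42, "m")
        seq = "A" * 10_000
        out = mutate_sequence(seq, 0.1, rng)
        frac = sum(a != b for a, b in zip(seq, out)) / len(seq)
        assert 0.08 <= frac <= 0.12

    def test_non_acgt_untouched(self):
        assert mutate_sequence("NNNN", 1.0, substream(0, "m")) == "NNNN"

    def test_invalid_rate_raises(self):
        with pytest.raises(SyntheticError):
            mutate_sequence("ACGT", 1.5, substream(0, "m"))


class TestGenerateReferences:
    def profiles(self, **kw):
        return [tiny_marker("m1", 300, d_species=0.05, **kw)]

    def test_planted_congeneric_divergence(self):
        tax = generate_taxonomy(2, 2, 3, 2, seed=5)
        dbs, truth = generate_references(tax, self.profiles(), seed=5)
        amps, _ = extract_amplicons(dbs["m1"], self.profiles()[0].primers)
        by_genus = {}
        for a in amps:
            by_genus.setdefault(a.truth.genus, {}).setdefault(
                a.truth.species, []).append(a.sequence)
        dists = []
        for genus, groups in by_genus.items():
            if len(groups) >= 2:
                dm = species_distance_matrix(groups)
                n = dm.shape[0]
                arr = np.asarray(dm.data)
                dists.extend(arr[i, j] for i in range(n) for j in range(i + 1, n))
        assert 0.03 <= float(np.mean(dists)) <= 0.07

    def test_coverage_gaps_recorded_exactly(self):
        tax = generate_taxonomy(2, 2, 2, 2, seed=9)  # 16 species
        profiles = [tiny_marker("m1", 200, coverage_gap_rate=0.25)]
        dbs, truth = generate_references(tax, profiles, seed=9)
        gapped = truth.gaps["m1"]
        in_db = {r.lineage.species for r in dbs["m1"].records}
        assert gapped.isdisjoint(in_db)
        assert gapped | in_db == {s.species for s in tax.species}
        cov = coverage_summary(dbs["m1"], tax.species)
        expected = 100.0 * (16 - len(gapped)) / 16
        assert cov.rows.loc["species", "percent"] == pytest.approx(expected)

    def test_duplicate_amplicons_byte_identical(self):
        tax = generate_taxonomy(1, 1, 3, 2, seed=3)
        profiles = [tiny_marker("m1", 200, duplicate_amplicon_rate=1.0)]
        dbs, truth = generate_references(tax, profiles, seed=3)
        assert truth.duplicates["m1"], "every congeneric pair should be duplicated"
        for a, b in truth.duplicates["m1"]:
            assert truth.amplicons[("m1", a)] == truth.amplicons[("m1", b)]

    def test_primer_sites_intact(self):
        tax = generate_taxonomy(1, 1, 1, 2, seed=1)
        prof = self.profiles()[0]
        dbs, truth = generate_references(tax, [prof], seed=1)
        amps, log = extract_amplicons(dbs["m1"], prof.primers)
        assert len(log) == 0
        assert len(amps) == len(dbs["m1"])
        for a in amps:
            assert a.sequence == truth.amplicons[("m1", a.truth.species)]

    def test_profile_validation(self):
        with pytest.raises(SyntheticError):
            MarkerProfile(name="bad", amplicon_length=100,
                          primers=PrimerPair("ACGTACGTAC", "ACGTACGTAC"),
                          d_species=0.3, d_genus=0.1)


class TestGenerateCommunity:
    def test_sample_counts_sum_to_depth(self):
        tax = generate_taxonomy(2, 2, 2, 2, seed=4)
        com = generate_community(tax, n_instances=3, n_replicates=2,
                                 n_species_per_instance=5, reads_per_sample=100,
                                 seed=4)
        assert len(com.samples) == 6
        for counts in com.samples.values():
            assert sum(counts.values()) == 100

    def test_pooling_maps_replicates_to_instances(self):
        tax = generate_taxonomy(2, 2, 2, 2, seed=4)
        com = generate_community(tax, 3, 2, 5, 50, seed=4)
        assert set(com.pooling.values()) == {"I01", "I02", "I03"}

    def test_oversized_pool_raises(self):
        tax = generate_taxonomy(1, 1, 1, 2, seed=0)
        with pytest.raises(SyntheticError):
            generate_community(tax, 1, 1, 99, 10, seed=0)


class TestGenerateReads:
    def setup_scenario(self, seed=0, **profile_kw):
        tax = generate_taxonomy(2, 1, 2, 2, seed=seed)
        prof = tiny_marker("m1", 150, **profile_kw)
        dbs, truth = generate_references(tax, [prof], seed=seed)
        return tax, prof, dbs, truth

    def test_error_free_reads_match_templates(self):
        tax, prof, dbs, truth = self.setup_scenario()
        sp = [s.species for s in tax.species][:2]
        com = CommunityTruth(samples={"S1": {sp[0]: 50, sp[1]: 50}},
                             pooling={"S1": "I1"})
        coll = generate_reads(com, truth, ["m1"], read_length=100,
                              error_rate=0.0, seed=0)
        fwd, rev = coll.pairs[("S1", "m1")]
        assert len(fwd) == len(rev) == 100
        sources = coll.provenance.set_index("read_id")["source"]
        for read, (_, row) in zip(fwd.reads, coll.provenance.iterrows()):
            tmpl = truth.amplicons[("m1", row["source"])]
            assert read.sequence == tmpl[:100]
        assert sorted(coll.provenance["source"].value_counts().to_dict().values()) \
            == [50, 50]

    def test_contamination_fraction_respected(self):
        tax, prof, dbs, truth = self.setup_scenario(seed=2)
        sp = tax.species[0].species
        com = CommunityTruth(samples={"S1": {sp: 1000}}, pooling={"S1": "I1"},
                             contamination_fraction=0.3)
        pool = generate_contaminants(5, 300, seed=2)
        coll = generate_reads(com, truth, ["m1"], 100, 0.0,
                              contaminant_db=pool, seed=2)
        n_contam = int(coll.provenance["is_contaminant"].sum())
        assert 270 <= n_contam <= 330

    def test_zero_multiplier_zero_reads(self):
        tax, prof, dbs, truth = self.setup_scenario(seed=3)
        sp = tax.species[0].species
        com = CommunityTruth(samples={"S1": {sp: 100}}, pooling={"S1": "I1"},
                             marker_multipliers={"m1": 0.0})
        coll = generate_reads(com, truth, ["m1"], 100, 0.0, seed=3)
        fwd, rev = coll.pairs[("S1", "m1")]
        assert len(fwd) == 0 and len(rev) == 0

    def test_unknown_taxon_raises(self):
        tax, prof, dbs, truth = self.setup_scenario(seed=4)
        com = CommunityTruth(samples={"S1": {"Nullius species": 10}},
                             pooling={"S1": "I1"})
        with pytest.raises(SyntheticError):
            generate_reads(com, truth, ["m1"], 100, 0.0, seed=4)

    def test_reads_reproducible_for_seed(self):
        tax, prof, dbs, truth = self.setup_scenario(seed=5)
        sp = tax.species[0].species
        com = CommunityTruth(samples={"S1": {sp: 30}}, pooling={"S1": "I1"})
        c1 = generate_reads(com, truth, ["m1"], 80, 0.01, seed=5)
        c2 = generate_reads(com, truth, ["m1"], 80, 0.01, seed=5)
        r1 = [r.sequence for r in c1.pairs[("S1", "m1")][0].reads]
        r2 = [r.sequence for r in c2.pairs[("S1", "m1")][0].reads]
        assert r1 == r2


class TestQualityModel:
    def test_constant_profile(self):
        q = QualityModel(38, 38).profile(10)
        assert (q == 38).all()

    def test_linear_decay(self):
        q = QualityModel(40, 20).profile(21)
        assert q[0] == 40 and q[-1] == 20
        assert (np.diff(q.astype(int)) <= 0).all()

    def test_offset_clipped(self):
        q = QualityModel(38, 38).profile(5, offset=100)
        assert (q == 41).all()
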