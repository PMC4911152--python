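"""Seeded search, tied-top-hit consolidation, and outcome classification."""

import pytest

from markereval.refdb import RefDB, RefRecord
from markereval.synthetic_data import mutate_sequence, substream
from markereval.taxassign import (Hit, SearchError, SearchParams,
                                  accuracy_summary, assign_query,
                                  classify_against_truth, consolidate_taxonomy,
                                  seeded_search, top_tied_hits)
from markereval.taxonomy import AMBIGUOUS, Lineage

from conftest import lineage, random_dna

PERMISSIVE = SearchParams(word_size=8, min_identity=1.0, max_evalue=1e9,
                          min_align_fraction=0.0)


def ref(rid, seq, lin=None):
    return RefRecord(id=rid, marker="m", sequence=seq, lineage=lin or lineage())


class TestSeededSearch:
    def test_self_match_is_top_hit(self, rng):
        seqs = {f"R{i}": random_dna(rng, 300) for i in range(5)}
        db = RefDB(marker="m", records=[ref(r, s) for r, s in seqs.items()])
        hits = seeded_search(seqs["R2"], db, SearchParams(word_size=28,
                                                         min_identity=98,
                                                         max_evalue=1e-20))
        assert hits[0].ref_id == "R2"
        assert hits[0].identity == pytest.approx(100.0)

    def test_no_shared_word_no_hits(self):
        db = RefDB(marker="m", records=[ref("R1", "A" * 50)])
        assert seeded_search("C" * 40, db, PERMISSIVE) == []

    def test_query_shorter_than_word_raises(self):
        db = RefDB(marker="m", records=[ref("R1", "ACGTACGTACGT")])
        with pytest.raises(SearchError):
            seeded_search("ACG", db, PERMISSIVE)

    def test_equidistant_refs_tie_for_top(self, rng):
        base = random_dna(rng, 200)
        v1 = base[:50] + ("A" if base[50] != "A" else "C") + base[51:]
        v2 = base[:120] + ("A" if base[120] != "A" else "C") + base[121:]
        db = RefDB(marker="m", records=[ref("R1", v1), ref("R2", v2)])
        hits = seeded_search(base, db, PERMISSIVE)
        tied = top_tied_hits(hits)
        assert {h.ref_id for h in tied} == {"R1", "R2"}
        assert hits[0].score == hits[1].score

    def test_reverse_strand_query_found(self, rng):
        from markereval.iupac import reverse_complement
        seq = random_dna(rng, 150)
        db = RefDB(marker="m", records=[ref("R1", seq)])
        hits = seeded_search(reverse_complement(seq), db, PERMISSIVE)
        assert hits and hits[0].ref_id == "R1"
        assert hits[0].identity == pytest.approx(100.0)

    def test_appending_unrelated_refs_keeps_top_scores(self, rng):
        base = random_dna(rng, 200)
        db = RefDB(marker="m", records=[ref("R1", base)])
        before = {h.ref_id: h.score for h in seeded_search(base, db, PERMISSIVE)}
        for i in range(5):
            db.add(ref(f"X{i}", random_dna(rng, 200)))
        after = {h.ref_id: h.score
                 for h in seeded_search(base, db, PERMISSIVE) if h.ref_id in before}
        assert before == after

    def test_identity_threshold_gates_hits(self, rng):
        base = random_dna(rng, 300)
        diverged = mutate_sequence(base, 0.05, substream(0, "t"))
        db = RefDB(marker="m", records=[ref("R1", diverged)])
        strict = SearchParams(word_size=12, min_identity=98.0, max_evalue=1e9,
                              min_align_fraction=0.0)
        loose = SearchParams(word_size=12, min_identity=70.0, max_evalue=1e9,
                             min_align_fraction=0.0)
        assert seeded_search(base, db, strict) == []
        assert len(seeded_search(base, db, loose)) == 1


class TestConsolidateTaxonomy:
    def hit(self, lin, score=10):
        return Hit(ref_id="r", score=score, identity=99.0, evalue=0.0, lineage=lin)

    def test_congeneric_tie_is_species_ambiguous(self):
        hits = [self.hit(lineage(genus="Carex", family="Cyperaceae",
                                 species="Carex aquatilis")),
                self.hit(lineage(genus="Carex", family="Cyperaceae",
                                 species="Carex utriculata"))]
        cons = consolidate_taxonomy(hits)
        assert cons.genus == "Carex"
        assert cons.species == AMBIGUOUS

    def test_single_hit_full_lineage(self):
        lin = lineage()
        assert consolidate_taxonomy([self.hit(lin)]) == lin

    def test_cross_family_tie_ambiguous_below_order(self):
        hits = [self.hit(lineage(family="Poaceae", genus="Poa",
                                 species="Poa annua")),
                self.hit(lineage(family="Cyperaceae", genus="Carex",
                                 species="Carex limosa"))]
        cons = consolidate_taxonomy(hits)
        assert cons.order == "Poales"
        assert cons.family == AMBIGUOUS
        assert cons.genus == AMBIGUOUS
        assert cons.species == AMBIGUOUS

    def test_ambiguity_propagates_to_finer_ranks(self):
        hits = [self.hit(lineage(order="Poales")), self.hit(lineage(order="Asterales",
                                                                    family="Asteraceae",
                                                                    genus="Aster",
                                                                    species="Aster alpinus"))]
        cons = consolidate_taxonomy(hits)
        for rank in ("order", "family", "genus", "species"):
            assert cons.at(rank) == AMBIGUOUS

    def test_empty_hit_set_raises(self):
        with pytest.raises(SearchError):
            consolidate_taxonomy([])


class TestClassifyAgainstTruth:
    def result(self, consensus, n_tied=1):
        from markereval.taxassign import AssignmentResult
        return AssignmentResult(query_id="q", consensus=consensus, n_tied_top=n_tied)

    def test_correct(self):
        assert classify_against_truth(self.result(lineage()), lineage(), "genus") == "correct"

    def test_incorrect(self):
        got = self.result(lineage(genus="Carex", family="Cyperaceae",
                                  species="Carex limosa"))
        assert classify_against_truth(got, lineage(), "genus") == "incorrect"

    def test_no_match(self):
        res = self.result(Lineage(), n_tied=0)
        assert classify_against_truth(res, lineage(), "species") == "no_match"

    def test_ambiguous(self):
        cons = lineage().replace(species=AMBIGUOUS)
        assert classify_against_truth(self.result(cons), lineage(), "species") == "ambiguous"

    def test_unknown_truth_raises(self):
        with pytest.raises(SearchError):
            classify_against_truth(self.result(lineage()), Lineage(), "genus")


class TestAccuracySummary:
    def test_constructed_outcome_mixture(self, rng):
        """10 mock reads: 8 unique-match, 1 cross-genus mislabel, 1 of a
        duplicated-amplicon pair -> 0.8 / 0.1 / 0.1 / 0.0 at species rank."""
        records = []
        queries = []
        for i in range(8):
            seq = random_dna(rng, 250)
            lin = lineage(genus=f"Gen{i}", species=f"Gen{i} sp")
            records.append(ref(f"U{i}", seq, lin))
            queries.append((f"q{i}", seq, lin))
        # planted mislabel: query is an exact copy of a ref whose label
        # differs from the query's truth at genus and species
        seq_mis = random_dna(rng, 250)
        records.append(ref("MIS", seq_mis, lineage(genus="Wrong", species="Wrong sp")))
        queries.append(("q_mis", seq_mis, lineage(genus="Right", species="Right sp")))
        # duplicated amplicon shared by two species of one genus
        seq_dup = random_dna(rng, 250)
        records.append(ref("D1", seq_dup, lineage(genus="Dup", species="Dup una")))
        records.append(ref("D2", seq_dup, lineage(genus="Dup", species="Dup altera")))
        queries.append(("q_dup", seq_dup, lineage(genus="Dup", species="Dup una")))
        db = RefDB(marker="m", records=records)
        params = SearchParams(word_size=28, min_identity=98, max_evalue=1e-20)
        results = [assign_query(qid, seq, db, params, truth=truth)
                   for qid, seq, truth in queries]
        acc = accuracy_summary(results)
        assert acc.loc["species", "correct"] == pytest.approx(0.8)
        assert acc.loc["species", "incorrect"] == pytest.approx(0.1)
        assert acc.loc["species", "ambiguous"] == pytest.approx(0.1)
        assert acc.loc["species", "no_match"] == 0.0
        row = acc.loc["species"]
        assert row[["correct", "incorrect", "ambiguous", "no_match"]].sum() == pytest.approx(1.0)

    def test_all_self_matches_fully_correct(self, rng):
        records = [ref(f"R{i}", random_dna(rng, 200),
                       lineage(genus=f"G{i}", species=f"G{i} sp"))
                   for i in range(4)]
        db = RefDB(marker="m", records=records)
        params = SearchParams(word_size=28, min_identity=98, max_evalue=1e-20)
        results = [assign_query(r.id, r.sequence, db, params, truth=r.lineage)
                   for r in records]
        acc = accuracy_summary(results)
        assert acc.loc["species", "correct"] == 1.0
        assert acc.loc["genus", "correct"] == 1.0

    def test_empty_db_all_no_match(self, rng):
        db = RefDB(marker="m", records=[ref("R1", "G" * 200)])
        params = SearchParams(word_size=28, min_identity=98, max_evalue=1e-20)
        res = assign_query("q", random_dna(rng, 200), db, params, truth=lineage())
        acc = accuracy_summary([res])
        assert acc.loc["species", "no_match"] == 1.0

    def test_empty_results_raise(self):
        with pytest.raises(SearchError):
            accuracy_summary([])
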