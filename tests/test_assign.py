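"""Consensus/identity scoring and the four assignment methods."""

import numpy as np
import pytest

from barcodecv.assign import (
    EVAL_RANKS,
    RankAssignment,
    TopNPlusParams,
    assign_tophit,
    assign_tophitplus,
    assign_topn,
    assign_topnplus,
    consensus_scores,
    identity_for_taxon,
)
from barcodecv.search import HitRecord

from conftest import brassica_hits, make_lineage, random_hit_table


def _hit(sid, pident, bits, rank, length=300, evalue=1e-50):
    return HitRecord("q", sid, pident, length, evalue, bits, rank)


class TestConsensusScores:
    def test_worked_brassica_example(self):
        """2x B. napus + 6x B. nigra + 2x S. alba: 60% species consensus
        for B. nigra, 80% genus for Brassica, 100% family."""
        hits, taxmap = brassica_hits()
        assert consensus_scores(hits, taxmap, "species") == {
            "Brassica napus": 20.0, "Brassica nigra": 60.0, "Sinapis alba": 20.0}
        assert consensus_scores(hits, taxmap, "genus") == {
            "Brassica": 80.0, "Sinapis": 20.0}
        assert consensus_scores(hits, taxmap, "family") == {"Brassicaceae": 100.0}

    def test_unknown_rank_hits_excluded_from_entries(self):
        hits, taxmap = brassica_hits()
        taxmap["s9"] = make_lineage(genus="Sinapis", species="unknown")
        cons = consensus_scores(hits, taxmap, "species")
        assert "unknown" not in cons
        assert sum(cons.values()) == pytest.approx(90.0)  # denominator stays 10

    def test_unresolvable_subject_errors(self):
        hits, taxmap = brassica_hits()
        del taxmap["s3"]
        with pytest.raises(KeyError, match="s3"):
            consensus_scores(hits, taxmap, "species")

    def test_consensus_sums_to_at_most_100(self, rng):
        """Property over random tables: entries sum to <= 100, == 100
        when no hit is rank-unknown."""
        for _ in range(300):
            hits, taxmap = random_hit_table(rng, allow_unknown=True)
            for rank in EVAL_RANKS:
                cons = consensus_scores(hits, taxmap, rank)
                total = sum(cons.values())
                assert total <= 100.0 + 1e-9
                n_known = sum(
                    taxmap[h.subject_id].taxon_at(rank) != "unknown" for h in hits)
                if n_known == len(hits):
                    assert total == pytest.approx(100.0)


class TestIdentityForTaxon:
    def test_bitscore_beats_raw_identity(self):
        """98% over 400 bp at high bit score wins over 100% over 50 bp."""
        taxmap = {"a": make_lineage(), "b": make_lineage()}
        hits = [_hit("a", 98.0, 686.7, 1, length=400),
                _hit("b", 100.0, 91.4, 2, length=50)]
        assert identity_for_taxon(hits, taxmap, "species", "Brassica nigra") == 98.0

    def test_single_hit(self):
        taxmap = {"a": make_lineage()}
        assert identity_for_taxon([_hit("a", 99.4, 100, 1)], taxmap,
                                  "species", "Brassica nigra") == 99.4

    def test_tie_broken_by_input_rank(self):
        taxmap = {"a": make_lineage(), "b": make_lineage()}
        hits = [_hit("a", 97.0, 120.0, 1), _hit("b", 99.0, 120.0, 2)]
        assert identity_for_taxon(hits, taxmap, "species", "Brassica nigra") == 97.0

    def test_no_matching_hit_errors(self):
        taxmap = {"a": make_lineage()}
        with pytest.raises(ValueError):
            identity_for_taxon([_hit("a", 99.0, 100, 1)], taxmap,
                               "species", "Salix alba")


class TestTopHit:
    def test_best_bitscore_wins_every_rank(self):
        hits, taxmap = brassica_hits()  # s0 (B. napus) has the top bitscore
        res = assign_tophit("q", hits, taxmap)
        assert res.at("species").taxon == "Brassica napus"
        assert res.at("genus").taxon == "Brassica"
        assert res.at("family").taxon == "Brassicaceae"
        assert res.at("species").consensus == 20.0
        assert res.at("genus").consensus == 80.0

    def test_empty_hits_unassigned(self):
        res = assign_tophit("q", [], {})
        assert all(not ra.assigned for ra in res.ranks)

    def test_tie_broken_by_input_rank(self):
        taxmap = {"a": make_lineage(species="Brassica nigra"),
                  "b": make_lineage(species="Brassica napus")}
        hits = [_hit("a", 99.0, 120.0, 1), _hit("b", 99.5, 120.0, 2)]
        res = assign_tophit("q", hits, taxmap)
        assert res.at("species").taxon == "Brassica nigra"


class TestTopHitPlus:
    def test_tie_broken_by_consensus(self):
        taxmap = {
            "a": make_lineage(species="Brassica napus"),
            "b": make_lineage(species="Brassica nigra"),
            "c": make_lineage(species="Brassica napus"),
            "d": make_lineage(species="Brassica napus"),
            "e": make_lineage(species="Brassica napus"),
        }
        hits = [_hit("a", 99.0, 120.0, 1), _hit("b", 99.5, 120.0, 2),
                _hit("c", 98.0, 100.0, 3), _hit("d", 98.0, 100.0, 4),
                _hit("e", 98.0, 90.0, 5)]
        res = assign_tophitplus("q", hits, taxmap)
        # ties at 120: napus (consensus 80) vs nigra (20) -> napus
        assert res.at("species").taxon == "Brassica napus"
        assert res.at("species").consensus == 80.0

    def test_residual_tie_alphabetical(self):
        taxmap = {"a": make_lineage(species="Brassica zz"),
                  "b": make_lineage(species="Brassica aa")}
        hits = [_hit("a", 99.0, 120.0, 1), _hit("b", 99.0, 120.0, 2)]
        res = assign_tophitplus("q", hits, taxmap)
        assert res.at("species").taxon == "Brassica aa"

    def test_equals_tophit_when_best_unique(self, rng):
        """Property: with a unique best bit score the two methods agree
        at every rank."""
        checked = 0
        for _ in range(500):
            hits, taxmap = random_hit_table(rng)
            best = max(h.bitscore for h in hits)
            if sum(h.bitscore == best for h in hits) != 1:
                continue
            checked += 1
            a = assign_tophit("q", hits, taxmap)
            b = assign_tophitplus("q", hits, taxmap)
            for rank in EVAL_RANKS:
                assert (a.at(rank).taxon, a.at(rank).identity,
                        a.at(rank).consensus) == (
                        b.at(rank).taxon, b.at(rank).identity,
                        b.at(rank).consensus)
        assert checked > 50


class TestTopN:
    def test_worked_example(self):
        hits, taxmap = brassica_hits()
        res = assign_topn("q", hits, taxmap)
        assert res.at("species").taxon == "Brassica nigra"
        assert res.at("species").consensus == 60.0
        assert res.at("genus").taxon == "Brassica"
        assert res.at("genus").consensus == 80.0
        assert res.at("family").taxon == "Brassicaceae"
        assert res.at("family").consensus == 100.0

    def test_rank_inconsistency_possible(self):
        """5x species A (genus G1) vs 3+2 split over genus G2: species A
        wins at species rank while G2 wins the genus tie on identity."""
        taxmap = {}
        hits = []
        for i in range(5):
            taxmap[f"a{i}"] = make_lineage(genus="G1", species="G1 alpha")
            hits.append(_hit(f"a{i}", 95.0, 100.0 - i, i + 1))
        for i in range(3):
            taxmap[f"b{i}"] = make_lineage(genus="G2", species="G2 beta")
            hits.append(_hit(f"b{i}", 99.0, 120.0 - i, 6 + i))
        for i in range(2):
            taxmap[f"c{i}"] = make_lineage(genus="G2", species="G2 gamma")
            hits.append(_hit(f"c{i}", 98.0, 90.0 - i, 9 + i))
        res = assign_topn("q", hits, taxmap)
        assert res.at("species").taxon == "G1 alpha"       # 50% beats 30/20
        assert res.at("genus").taxon == "G2"               # 50/50 tie, 99 > 95
        assert res.at("species").taxon.split()[0] != res.at("genus").taxon

    def test_single_hit_full_lineage(self):
        taxmap = {"a": make_lineage()}
        res = assign_topn("q", [_hit("a", 99.0, 100.0, 1)], taxmap)
        for rank in EVAL_RANKS:
            assert res.at(rank).assigned
            assert res.at(rank).consensus == 100.0


class TestTopNPlus:
    def test_unanimous_high_quality(self):
        taxmap = {f"s{i}": make_lineage() for i in range(10)}
        hits = [_hit(f"s{i}", 99.5, 200.0 - i, i + 1, length=350, evalue=0.0)
                for i in range(10)]
        res = assign_topnplus("q", hits, taxmap)
        assert res.at("species").taxon == "Brassica nigra"
        assert res.at("species").consensus == 100.0

    def test_identity_floor_per_rank(self):
        """pident 95 fails the species floor (97) but passes genus (90)."""
        taxmap = {f"s{i}": make_lineage() for i in range(10)}
        hits = [_hit(f"s{i}", 95.0, 200.0 - i, i + 1, length=350, evalue=0.0)
                for i in range(10)]
        res = assign_topnplus("q", hits, taxmap)
        assert not res.at("species").assigned
        assert res.at("genus").taxon == "Brassica"
        assert res.at("family").taxon == "Brassicaceae"

    def test_identity_window_excludes_distant_hit(self):
        """Best hit at 100%: a 98.7% hit falls outside the 1% species
        window; consensus is over the two survivors."""
        taxmap = {"a": make_lineage(species="Brassica nigra"),
                  "b": make_lineage(species="Brassica nigra"),
                  "c": make_lineage(species="Brassica napus")}
        hits = [_hit("a", 100.0, 300.0, 1, length=350, evalue=0.0),
                _hit("b", 99.5, 280.0, 2, length=350, evalue=0.0),
                _hit("c", 98.7, 250.0, 3, length=350, evalue=0.0)]
        res = assign_topnplus("q", hits, taxmap)
        assert res.at("species").taxon == "Brassica nigra"
        assert res.at("species").consensus == 100.0  # 2/2 survivors

    def test_length_and_evalue_filters(self):
        taxmap = {"a": make_lineage(), "b": make_lineage()}
        hits = [_hit("a", 99.0, 200.0, 1, length=99, evalue=0.0),   # too short
                _hit("b", 99.0, 180.0, 2, length=350, evalue=1e-5)]  # E too big
        res = assign_topnplus("q", hits, taxmap)
        assert all(not res.at(rank).assigned for rank in EVAL_RANKS)

    def test_permissive_thresholds_equal_topn(self, rng):
        """Property: with no-op thresholds TopNPlus reduces to TopN."""
        permissive = TopNPlusParams(
            min_align_length=0,
            max_evalue=float("inf"),
            identity_floor={"species": 0.0, "genus": 0.0, "family": 0.0},
            identity_window={"species": float("inf"), "genus": float("inf"),
                             "family": float("inf")},
        )
        for _ in range(500):
            hits, taxmap = random_hit_table(rng)
            a = assign_topn("q", hits, taxmap)
            b = assign_topnplus("q", hits, taxmap, permissive)
            for rank in EVAL_RANKS:
                assert (a.at(rank).taxon, a.at(rank).identity,
                        a.at(rank).consensus) == (
                        b.at(rank).taxon, b.at(rank).identity,
                        b.at(rank).consensus)


class TestInvariants:
    def test_attributed_identity_is_a_real_pident(self, rng):
        """Every attributed identity equals the pident of some hit
        matching the assigned taxon (no fabricated scores)."""
        for _ in range(200):
            hits, taxmap = random_hit_table(rng, allow_unknown=True)
            for method in (assign_tophit, assign_tophitplus, assign_topn):
                res = method("q", hits, taxmap)
                for rank in EVAL_RANKS:
                    ra = res.at(rank)
                    if not ra.assigned:
                        continue
                    matching = [h.pident for h in hits
                                if taxmap[h.subject_id].taxon_at(rank) == ra.taxon]
                    assert ra.identity in matching

    def test_rank_assignment_all_or_none(self):
        with pytest.raises(ValueError):
            RankAssignment("species", "A", None, 50.0, "TopHit")
        with pytest.raises(ValueError):
            RankAssignment("species", "A", 99.0, 0.0, "TopHit")
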