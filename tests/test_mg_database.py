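"""Database construction: admission, assignment, clustering, consensus taxonomy."""

import math

import pytest

from mgotu.core_io import (
    MG_FAMILIES,
    GenomeMGSet,
    MGDatabase,
    MarkerGeneSeq,
    TaxLineage,
)
from mgotu.fixtures import make_marker_family, make_species_clusters, mutate_to_identity
from mgotu.mg_database import (
    admit_genome,
    annotate_consensus,
    assign_genome,
    cluster_new_genomes,
    extend_database,
    map_mgs_to_db,
    pairwise_mg_identity,
    update_unassigned,
)
from mgotu._align import revcomp


def _genome(gid, n_families, seed=7, length=600):
    members = {
        fam: MarkerGeneSeq(gid, fam, make_marker_family(length, seed + i))
        for i, fam in enumerate(MG_FAMILIES[:n_families])
    }
    return GenomeMGSet(gid, members)


def _mutated_copy(g, gid, identity, seed):
    members = {
        fam: MarkerGeneSeq(gid, fam, mutate_to_identity(mg.seq, identity, seed + i))
        for i, (fam, mg) in enumerate(sorted(g.members.items()))
    }
    return GenomeMGSet(gid, members)


class TestAdmission:
    @pytest.mark.parametrize("n,expected", [(5, False), (6, True), (10, True)])
    def test_six_of_ten_family_boundary(self, n, expected):
        assert admit_genome(_genome("g", n)) is expected


class TestPairwiseIdentity:
    def test_self_identity_is_one(self):
        g = _genome("g", 4)
        per_fam, mean = pairwise_mg_identity(g, g)
        assert mean == 1.0 and all(v == 1.0 for v in per_fam.values())

    def test_mean_is_arithmetic_over_shared_families(self):
        a = _genome("a", 2, length=1000)
        b = GenomeMGSet(
            "b",
            {
                MG_FAMILIES[0]: MarkerGeneSeq(
                    "b", MG_FAMILIES[0], mutate_to_identity(a.members[MG_FAMILIES[0]].seq, 0.90, 1)
                ),
                MG_FAMILIES[1]: MarkerGeneSeq("b", MG_FAMILIES[1], a.members[MG_FAMILIES[1]].seq),
            },
        )
        per_fam, mean = pairwise_mg_identity(a, b)
        assert per_fam[MG_FAMILIES[1]] == 1.0
        assert math.isclose(per_fam[MG_FAMILIES[0]], 0.90, abs_tol=0.002)
        assert math.isclose(mean, 0.95, abs_tol=0.001)

    def test_insufficient_shared_families_rejected(self):
        a = _genome("a", 1)
        b = GenomeMGSet(
            "b",
            {MG_FAMILIES[5]: MarkerGeneSeq("b", MG_FAMILIES[5], make_marker_family(600, 9))},
        )
        with pytest.raises(ValueError, match="share"):
            pairwise_mg_identity(a, b)


class TestMapMGs:
    def test_identical_query_hits_at_one(self, small_db, planted_genomes):
        genomes, _ = planted_genomes
        hits = map_mgs_to_db(genomes[0], small_db)
        assert any(h.identity == 1.0 for h in hits)

    def test_distant_query_yields_no_candidates(self, small_db):
        g = _genome("far", 10, seed=999)  # unrelated random genes
        assert map_mgs_to_db(g, small_db) == []

    def test_strand_symmetry(self, small_db, planted_genomes):
        genomes, _ = planted_genomes
        g = genomes[0]
        rc = GenomeMGSet(
            "rc",
            {f: MarkerGeneSeq("rc", f, revcomp(mg.seq)) for f, mg in g.members.items()},
        )
        fwd = {(h.family, h.motu_id, round(h.identity, 6)) for h in map_mgs_to_db(g, small_db)}
        rev = {(h.family, h.motu_id, round(h.identity, 6)) for h in map_mgs_to_db(rc, small_db)}
        assert fwd == rev


class TestAssignGenome:
    def test_identical_genome_assigned_to_its_motu(self, small_db, planted_genomes):
        genomes, _ = planted_genomes
        target = assign_genome(genomes[0], small_db)
        assert target is not None
        assert genomes[0].genome_id in small_db.entries[target].genomes

    def test_below_cutoff_genome_unassigned(self, small_db, planted_genomes):
        genomes, _ = planted_genomes
        g = _mutated_copy(genomes[0], "dist", 0.90, seed=11)
        assert assign_genome(g, small_db) is None

    def test_tie_breaks_to_lexicographically_smaller_motu(self):
        from mgotu.core_io import MOTUEntry

        g = _genome("q", 6)
        entries = {
            motu_id: MOTUEntry(
                motu_id=motu_id,
                category="ext",
                genomes={motu_id},
                sequences={f: [mg] for f, mg in _genome(motu_id, 6, seed=7).members.items()},
            )
            for motu_id in ("motu_b", "motu_a")
        }
        db = MGDatabase(entries=entries)
        # both entries hold sequences identical to the query: mean identity ties
        assert assign_genome(g, db) == "motu_a"


class TestClusterNewGenomes:
    def test_identical_genomes_form_one_cluster(self):
        gs = [_genome(f"g{i}", 10) for i in range(3)]
        entries = cluster_new_genomes(gs)
        assert len(entries) == 1
        assert entries[0].genomes == {"g0", "g1", "g2"}

    def test_distant_genomes_stay_singletons(self):
        base = _genome("a", 10, length=1000)
        gs = [base] + [_mutated_copy(base, f"g{i}", 0.85, seed=50 * i) for i in (1, 2)]
        # pairwise identities ~0.85 or lower, cutoff 0.965
        assert len(cluster_new_genomes(gs)) == 3

    def test_greedy_chain_follows_centroid_rule(self):
        # A--B at 0.97, B--C at 0.97 via disjoint sites, hence A--C at 0.94:
        # A founds, B joins A, C fails vs centroid A and founds its own.
        a = _genome("a", 2, length=1000)
        b = _mutated_copy(a, "b", 0.97, seed=3)
        c = _mutated_copy(b, "c", 0.97, seed=300)
        _pf, id_ab = pairwise_mg_identity(a, b)
        _pf, id_bc = pairwise_mg_identity(b, c)
        _pf, id_ac = pairwise_mg_identity(a, c)
        assert id_ab >= 0.965 and id_bc >= 0.965 and id_ac < 0.965
        entries = cluster_new_genomes([a, b, c])
        clusters = sorted(sorted(e.genomes) for e in entries)
        assert clusters == [["a", "b"], ["c"]]

    def test_empty_input(self):
        assert cluster_new_genomes([]) == []

    def test_cluster_count_monotone_in_cutoff(self):
        genomes, _ = make_species_clusters(4, 2, 0.99, 0.90, seed=17)
        counts = []
        for cutoff in (1.0, 0.985, 0.95, 0.85):
            cutoffs = {fam: cutoff for fam in MG_FAMILIES}
            counts.append(len(cluster_new_genomes(genomes, cutoffs)))
        assert counts == sorted(counts, reverse=True)


class TestExtendDatabase:
    def test_extension_is_idempotent(self, small_db, planted_genomes):
        genomes, _ = planted_genomes
        db2, report = extend_database(small_db, genomes)
        assert report.n_new_motus == 0
        assert report.n_assigned == len(genomes)
        assert sorted(db2.entries) == sorted(small_db.entries)

    def test_distant_genomes_found_new_motus(self):
        genomes, truth = make_species_clusters(4, 1, 0.99, 0.88, seed=23)
        db, report = extend_database(MGDatabase.empty(), genomes)
        assert report.n_new_motus == len(set(truth.values())) == 4

    def test_sparse_genome_rejected_and_absent(self, small_db):
        g = _genome("sparse", 5)
        db2, report = extend_database(small_db, [g])
        assert report.n_rejected == 1
        assert all("sparse" not in e.genomes for e in db2.entries.values())

    def test_every_genome_has_exactly_one_fate(self, small_db, planted_genomes):
        genomes, _ = planted_genomes
        extra = _genome("new1", 10, seed=400)
        _db2, report = extend_database(small_db, list(genomes) + [extra, _genome("sparse", 4)])
        assert sorted(report.fates["genome_id"]) == sorted(
            [g.genome_id for g in genomes] + ["new1", "sparse"]
        )
        assert set(report.fates["fate"]) <= {"rejected", "assigned", "new"}


class TestUpdateUnassigned:
    def _mg(self, gid, seq, fam=MG_FAMILIES[0]):
        return MarkerGeneSeq(gid, fam, seq)

    def test_identical_leftovers_collapse_to_one_representative(self, small_db):
        seq = make_marker_family(800, 31)
        leftovers = [self._mg(f"l{i}", seq) for i in range(5)]
        db2 = update_unassigned(small_db, leftovers)
        assert len(db2.unassigned_entry.sequences[MG_FAMILIES[0]]) == 1

    def test_distant_leftovers_each_represented(self, small_db):
        s1 = make_marker_family(800, 32)
        s2 = mutate_to_identity(s1, 0.80, 1)
        db2 = update_unassigned(small_db, [self._mg("l1", s1), self._mg("l2", s2)])
        assert len(db2.unassigned_entry.sequences[MG_FAMILIES[0]]) == 2

    def test_duplicate_of_existing_representative_adds_nothing(self, small_db):
        seq = make_marker_family(800, 33)
        db2 = update_unassigned(small_db, [self._mg("l1", seq)])
        db3 = update_unassigned(db2, [self._mg("l2", seq)])
        assert len(db3.unassigned_entry.sequences[MG_FAMILIES[0]]) == 1


class TestConsensusAnnotation:
    def _entry(self, small_db):
        return small_db.entries[small_db.motu_ids()[0]]

    def test_unanimous_annotation_agrees(self, small_db):
        lins = [TaxLineage.from_names("B", "P", "C", "O", "F", "G", "S")] * 10
        taxonomy, consistency = annotate_consensus(self._entry(small_db), lins)
        assert taxonomy.name_at("species") == "S"
        assert all(c == "agreeing" for c in consistency.values())

    def test_majority_wins_above_half(self, small_db):
        lins = [TaxLineage.from_names("B", "P", "C", "O", "F", "Gx")] * 6
        lins += [TaxLineage.from_names("B", "P", "C", "O", "F", "Gy")] * 4
        taxonomy, consistency = annotate_consensus(self._entry(small_db), lins)
        assert taxonomy.name_at("genus") == "Gx"
        assert consistency["genus"] == "majority"

    def test_even_split_truncates_lineage(self, small_db):
        lins = [TaxLineage.from_names("B", "P", "C", "O", "F", "Gx", "S1")] * 5
        lins += [TaxLineage.from_names("B", "P", "C", "O", "F", "Gy", "S2")] * 5
        taxonomy, consistency = annotate_consensus(self._entry(small_db), lins)
        assert taxonomy.name_at("genus") is None
        assert consistency["genus"] == "not_agreeing"
        assert taxonomy.name_at("species") is None

    def test_unannotated_rank_category(self, small_db):
        lins = [TaxLineage.from_names("B", "P")] * 3
        taxonomy, consistency = annotate_consensus(self._entry(small_db), lins)
        assert consistency["class"] == "not_annotated"
        assert taxonomy.name_at("phylum") == "P"
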