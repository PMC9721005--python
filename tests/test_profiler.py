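"""Insert profiling: alignment, resolution, quantification, rarefaction, QC."""

import math

import numpy as np
import pytest

from mgotu._align import infix_identity_both_strands, revcomp
from mgotu.core_io import (
    MG_FAMILIES,
    UNASSIGNED,
    CountProfile,
    RelAbundanceProfile,
    TaxLineage,
)
from mgotu.fixtures import CommunitySpec, mutate_to_identity, simulate_inserts
from mgotu.profiler import (
    AlignmentHit,
    aggregate_to_rank,
    align_inserts,
    assign_insert,
    prevalence_detected,
    profile_sample,
    quantify,
    rarefy,
    resolve_inserts,
    sample_qc,
    shannon_index,
)


def _first_gene(db):
    motu = db.motu_ids()[0]
    fam = sorted(db.entries[motu].sequences)[0]
    return motu, fam, db.entries[motu].sequences[fam][0].seq


class TestAlignInserts:
    def test_verbatim_insert_hits_its_gene_at_one(self, small_db):
        motu, fam, gene = _first_gene(small_db)
        hits = align_inserts([("r1", gene[100:250])], small_db)
        best = max(hits, key=lambda h: h.identity)
        assert (best.motu_id, best.family, best.identity) == (motu, fam, 1.0)

    def test_random_sequence_has_no_hits(self, small_db):
        rng = np.random.default_rng(99)
        junk = "".join(rng.choice(list("ACGT"), 150))
        assert align_inserts([("r1", junk)], small_db) == []

    def test_mutated_insert_identity_matches_exhaustive_alignment(self, small_db):
        # oracle: brute-force semi-global alignment against every db gene
        motu, fam, gene = _first_gene(small_db)
        read = mutate_to_identity(gene[200:500], 0.95, seed=8)
        hits = align_inserts([("r1", read)], small_db)
        best = max(h.identity for h in hits)
        oracle = max(
            infix_identity_both_strands(read, mg.seq)[0]
            for _m, _f, mg in small_db.iter_sequences()
        )
        assert math.isclose(best, oracle, abs_tol=1e-12)
        assert abs(best - 0.95) <= 0.01

    def test_paired_mates_merge_into_one_insert(self, small_db):
        motu, fam, gene = _first_gene(small_db)
        r1 = [("i1", gene[100:250])]
        r2 = [("i1_mate", gene[400:550])]
        hits = align_inserts(r1, small_db, reads2=r2)
        assert len({h.insert_id for h in hits}) == 1
        assignments = resolve_inserts(hits, small_db)
        assert len(assignments) == 1 and assignments[0].motu_id == motu


class TestAssignInsert:
    def _hit(self, motu, ident, fam=MG_FAMILIES[0], alen=150):
        return AlignmentHit("i", motu, fam, ident, alen)

    def test_above_cutoff_assigns_to_motu(self, small_db):
        a = assign_insert([self._hit("m1", 0.99)], small_db)
        assert a.motu_id == "m1"

    def test_between_floor_and_cutoff_pools_as_unassigned(self, small_db):
        a = assign_insert([self._hit("m1", 0.94)], small_db)
        assert a.motu_id == UNASSIGNED

    def test_no_hits_discards(self, small_db):
        assert assign_insert([], small_db) is None

    def test_hit_on_unassigned_entry_counts_as_unassigned(self, small_db):
        a = assign_insert([self._hit(UNASSIGNED, 1.0)], small_db)
        assert a.motu_id == UNASSIGNED

    def test_tie_breaks_identity_then_length_then_id(self, small_db):
        hits = [
            self._hit("m_b", 0.99, alen=150),
            self._hit("m_a", 0.99, alen=150),
            self._hit("m_c", 0.99, alen=200),
        ]
        assert assign_insert(hits, small_db).motu_id == "m_c"
        assert assign_insert(hits[:2], small_db).motu_id == "m_a"


class TestQuantify:
    def test_counts_to_relabund_with_equal_gene_lengths(self, small_db):
        # equal-length genes: relative abundances equal count fractions
        from mgotu.profiler import InsertAssignment

        ids = small_db.motu_ids()[:2]
        assignments = []
        k = 0
        for motu, n in zip(ids + [UNASSIGNED], (30, 60, 10)):
            for fam in MG_FAMILIES:
                for _ in range(n // 10):
                    assignments.append(InsertAssignment(f"i{k}", motu, fam))
                    k += 1
        counts = quantify(assignments, small_db, mode="counts")
        assert counts.counts[ids[0]] == 30 and counts.counts[UNASSIGNED] == 10
        assert counts.total_inserts == 100
        rel = quantify(assignments, small_db, mode="relabund")
        assert math.isclose(rel.get(ids[0]), 0.3, abs_tol=1e-9)
        assert math.isclose(rel.get(ids[1]), 0.6, abs_tol=1e-9)
        assert math.isclose(rel.unassigned_fraction, 0.1, abs_tol=1e-9)

    def test_single_motu_community(self, small_db):
        from mgotu.profiler import InsertAssignment

        motu = small_db.motu_ids()[0]
        assignments = [InsertAssignment(f"i{k}", motu, MG_FAMILIES[0]) for k in range(5)]
        rel = quantify(assignments, small_db, mode="relabund")
        assert rel.get(motu) == 1.0

    def test_relabund_requires_assigned_inserts(self, small_db):
        with pytest.raises(ValueError):
            quantify([], small_db, mode="relabund")


class TestRecovery:
    def test_simulated_community_recovered_within_l1(self, small_db):
        ids = small_db.motu_ids()
        spec = CommunitySpec(
            species=ids,
            abundances=[0.4, 0.3, 0.15, 0.1, 0.05],
            n_inserts=3000,
            read_length=150,
            error_rate=0.005,
            seed=13,
        )
        inserts, truth = simulate_inserts(small_db, spec)
        prof = profile_sample(inserts, small_db, mode="relabund")
        taxa = set(prof.abundances) | set(truth.abundances)
        l1 = sum(abs(prof.get(t) - truth.get(t)) for t in taxa)
        assert l1 < 0.05

    def test_profiling_invariant_to_read_order_and_strand(self, small_db):
        ids = small_db.motu_ids()[:2]
        spec = CommunitySpec(ids, [0.5, 0.5], n_inserts=200, seed=21)
        inserts, _ = simulate_inserts(small_db, spec)
        prof = profile_sample(inserts, small_db, mode="counts")
        flipped = [(n, revcomp(s)) for n, s in reversed(inserts)]
        prof2 = profile_sample(flipped, small_db, mode="counts")
        assert prof.counts == prof2.counts


class TestAggregateToRank:
    def _db_with_taxonomy(self, small_db):
        import copy

        db = copy.deepcopy(small_db)
        ids = db.motu_ids()
        db.entries[ids[0]].taxonomy = TaxLineage.from_names("B", "P", "C", "O", "F", "G", "S1")
        db.entries[ids[1]].taxonomy = TaxLineage.from_names("B", "P", "C", "O", "F", "G", "S2")
        db.entries[ids[2]].taxonomy = TaxLineage.from_names("B", "P", "C", "O", "F")
        return db, ids

    def test_sibling_species_merge_at_genus(self, small_db):
        db, ids = self._db_with_taxonomy(small_db)
        prof = RelAbundanceProfile("s", "motu", {ids[0]: 0.6, ids[1]: 0.4})
        agg = aggregate_to_rank(prof, db, "genus")
        assert math.isclose(agg.get("B;P;C;O;F;G"), 1.0)

    def test_unannotated_mass_tracked_separately(self, small_db):
        db, ids = self._db_with_taxonomy(small_db)
        prof = RelAbundanceProfile("s", "motu", {ids[0]: 0.8, ids[2]: 0.2})
        agg = aggregate_to_rank(prof, db, "genus")
        assert math.isclose(agg.get("unannotated@genus"), 0.2)
        assert math.isclose(sum(agg.abundances.values()), 1.0)

    def test_re_aggregation_is_identity(self, small_db):
        db, ids = self._db_with_taxonomy(small_db)
        prof = RelAbundanceProfile("s", "motu", {ids[0]: 0.6, ids[1]: 0.4})
        agg = aggregate_to_rank(prof, db, "family")
        assert aggregate_to_rank(agg, db, "family") == agg

    def test_unknown_rank_rejected(self, small_db):
        prof = RelAbundanceProfile("s", "motu", {small_db.motu_ids()[0]: 1.0})
        with pytest.raises(ValueError):
            aggregate_to_rank(prof, small_db, "kingdom")


class TestRarefy:
    def test_output_total_is_exactly_depth(self):
        prof = CountProfile("s", {"A": 12000, "B": 8000})
        out = rarefy(prof, depth=5000, seed=1)
        assert out.total_inserts == 5000

    def test_single_taxon_keeps_everything_on_it(self):
        prof = CountProfile("s", {"A": 9000})
        out = rarefy(prof, depth=5000, seed=1)
        assert out.counts["A"] == 5000

    def test_depth_above_total_rejected(self):
        with pytest.raises(ValueError):
            rarefy(CountProfile("s", {"A": 100}), depth=5000, seed=1)

    def test_expected_counts_match_hypergeometric_mean(self):
        prof = CountProfile("s", {"A": 6000, "B": 3000, "C": 1000})
        depth, n_rep = 2000, 300
        draws = np.array(
            [[rarefy(prof, depth, seed=s).counts[t] for t in ("A", "B", "C")]
             for s in range(n_rep)]
        )
        total = prof.total_inserts
        for j, taxon in enumerate(("A", "B", "C")):
            n_t = prof.counts[taxon]
            mean = depth * n_t / total
            var = depth * (n_t / total) * (1 - n_t / total) * (total - depth) / (total - 1)
            se = math.sqrt(var / n_rep)
            assert abs(draws[:, j].mean() - mean) < 3 * se


class TestQCAndDetection:
    @pytest.mark.parametrize("n,keep", [(4999, False), (5000, True), (0, False)])
    def test_sample_qc_boundary_is_strict(self, n, keep):
        prof = CountProfile("s", {"A": n})
        assert sample_qc(prof) is keep

    def test_prevalence_detection_boundaries(self):
        everywhere = [
            RelAbundanceProfile(f"s{i}", "motu", {"A": 1.0}) for i in range(10)
        ]
        assert prevalence_detected(everywhere) == {"A"}
        absent = [
            RelAbundanceProfile(f"s{i}", "motu", {"A": 1.0, "B": 0.0})
            for i in range(10)
        ]
        assert "B" not in prevalence_detected(absent)

    def test_prevalence_exactly_at_threshold_not_detected(self):
        # 1 of 1000 samples = prevalence 0.001, strict > excludes it
        cohort = [CountProfile(f"s{i}", {"A": 1}) for i in range(1)]
        cohort += [CountProfile(f"s{i+1}", {"B": 1}) for i in range(999)]
        detected = prevalence_detected(cohort, threshold=0.001)
        assert "A" not in detected and "B" in detected


class TestShannon:
    def test_single_taxon_zero(self):
        prof = RelAbundanceProfile("s", "motu", {"A": 1.0})
        assert shannon_index(prof) == 0.0

    def test_even_pair_is_ln2(self):
        prof = RelAbundanceProfile("s", "motu", {"A": 0.5, "B": 0.5})
        assert math.isclose(shannon_index(prof), math.log(2))

    @pytest.mark.parametrize("k", [3, 7, 20])
    def test_uniform_over_k_is_ln_k(self, k):
        prof = RelAbundanceProfile("s", "motu", {f"t{i}": 1 / k for i in range(k)})
        assert math.isclose(shannon_index(prof), math.log(k), abs_tol=1e-12)

    def test_unassigned_exclusion_renormalizes(self):
        prof = RelAbundanceProfile(
            "s", "motu", {"A": 0.25, "B": 0.25, UNASSIGNED: 0.5}
        )
        assert math.isclose(shannon_index(prof, exclude_unassigned=True), math.log(2))
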