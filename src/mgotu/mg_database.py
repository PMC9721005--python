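"""Build and extend the marker-gene OTU database.

The pipeline admits genomes carrying at least six of the ten marker-gene
(MG) families, assigns them to existing mOTUs when their MGs align within
the per-family identity cutoffs (species boundary, default 96.5%), clusters
the remainder de novo into new ext-mOTUs by greedy centroid clustering, and
maintains the single pooled "unassigned" entry of MGs that belong to no
mOTU.  Taxonomy is attached by per-rank majority consensus over the
annotations of an entry's marker genes.
"""

from __future__ import annotations

import copy
import dataclasses
from collections import Counter
from typing import Optional, Sequence

import pandas as pd

from ._align import global_identity, global_identity_both_strands
from .core_io import (
    MG_FAMILIES,
    RANKS,
    UNASSIGNED,
    GenomeMGSet,
    MarkerGeneSeq,
    MGDatabase,
    MOTUEntry,
    TaxLineage,
)


def admit_genome(g: GenomeMGSet, min_families: int = 6) -> bool:
    """Genomes enter the database only with >= `min_families` MG families."""
    return len(g.families) >= min_families


def pairwise_mg_identity(
    a: GenomeMGSet, b: GenomeMGSet, min_shared: int = 2
) -> tuple[dict[str, float], float]:
    """Per-family global identities between two genomes and their mean.

    The mean is the arithmetic mean over shared families; at least
    `min_shared` families must be shared.
    """
    shared = sorted(a.families & b.families)
    if len(shared) < min_shared:
        raise ValueError(
            f"genomes {a.genome_id} and {b.genome_id} share only "
            f"{len(shared)} families (need {min_shared})"
        )
    per_family = {
        fam: global_identity(a.members[fam].seq, b.members[fam].seq) for fam in shared
    }
    return per_family, sum(per_family.values()) / len(per_family)


@dataclasses.dataclass(frozen=True)
class MGHit:
    """One candidate alignment of a query MG against a database sequence."""

    family: str
    motu_id: str
    identity: float


def map_mgs_to_db(g: GenomeMGSet, db: MGDatabase) -> list[MGHit]:
    """All same-family database hits at identity >= the 80% prefilter.

    Both strands are considered (the reverse complement of the query is
    aligned as well).  An empty hit list is a valid result.
    """
    hits: list[MGHit] = []
    for fam in sorted(g.families):
        query = g.members[fam].seq
        for motu_id, mg in db.family_sequences(fam):
            ident = global_identity_both_strands(query, mg.seq)
            if ident >= db.prefilter_id:
                hits.append(MGHit(family=fam, motu_id=motu_id, identity=ident))
    return hits


def _best_hits_per_motu(hits: Sequence[MGHit]) -> dict[str, dict[str, float]]:
    """motu_id -> {family: best identity}."""
    best: dict[str, dict[str, float]] = {}
    for h in hits:
        fams = best.setdefault(h.motu_id, {})
        if h.identity > fams.get(h.family, -1.0):
            fams[h.family] = h.identity
    return best


def assign_genome(
    g: GenomeMGSet,
    db: MGDatabase,
    min_assign_families: int = 3,
    hits: Optional[Sequence[MGHit]] = None,
) -> Optional[str]:
    """Assign a genome to the best-matching existing mOTU, if any.

    A mOTU is eligible when at least `min_assign_families` of the genome's
    families have a best hit meeting that family's identity cutoff.  Among
    eligible mOTUs the one maximizing the mean per-family best-hit identity
    wins; ties break to the lexicographically smaller motu_id.  The pooled
    unassigned entry is never an assignment target.
    """
    if not admit_genome(g, db.min_families):
        raise ValueError(f"genome {g.genome_id} does not pass admission")
    if hits is None:
        hits = map_mgs_to_db(g, db)
    best = None  # (mean_identity, motu_id) with tie rule
    for motu_id, fams in _best_hits_per_motu(hits).items():
        if motu_id == UNASSIGNED:
            continue
        n_pass = sum(1 for fam, ident in fams.items() if ident >= db.cutoffs[fam])
        if n_pass < min_assign_families:
            continue
        mean_id = sum(fams.values()) / len(fams)
        key = (-mean_id, motu_id)
        if best is None or key < best:
            best = key
    return best[1] if best is not None else None


def _mean_cutoff(cutoffs: dict[str, float], families: Sequence[str]) -> float:
    return sum(cutoffs[f] for f in families) / len(families)


def cluster_new_genomes(
    gs: Sequence[GenomeMGSet],
    cutoffs: Optional[dict[str, float]] = None,
    min_shared: int = 2,
    id_prefix: str = "ext_motu",
    start_index: int = 0,
) -> list[MOTUEntry]:
    """Greedy centroid clustering of unassigned genomes into new ext-mOTUs.

    Genomes are processed sorted by family count (descending), then by
    genome_id; each joins the first centroid whose mean MG identity over
    shared families reaches the mean of the per-family cutoffs, else founds
    a new centroid.  Deterministic given the input set.
    """
    if cutoffs is None:
        cutoffs = {fam: 0.965 for fam in MG_FAMILIES}
    ordered = sorted(gs, key=lambda g: (-len(g.families), g.genome_id))
    centroids: list[GenomeMGSet] = []
    members: list[list[GenomeMGSet]] = []
    for g in ordered:
        placed = False
        for i, centroid in enumerate(centroids):
            shared = sorted(g.families & centroid.families)
            if len(shared) < min_shared:
                continue
            _, mean_id = pairwise_mg_identity(g, centroid, min_shared=min_shared)
            if mean_id >= _mean_cutoff(cutoffs, shared):
                members[i].append(g)
                placed = True
                break
        if not placed:
            centroids.append(g)
            members.append([g])
    entries = []
    for i, group in enumerate(members):
        sequences: dict[str, list[MarkerGeneSeq]] = {}
        for g in group:
            for fam in sorted(g.members):
                sequences.setdefault(fam, []).append(g.members[fam])
        entries.append(
            MOTUEntry(
                motu_id=f"{id_prefix}_{start_index + i:05d}",
                category="ext",
                genomes={g.genome_id for g in group},
                sequences=sequences,
            )
        )
    return entries


@dataclasses.dataclass
class ExtensionReport:
    """Per-genome fates of a database extension run."""

    fates: pd.DataFrame  # columns: genome_id, fate, motu_id
    n_rejected: int
    n_assigned: int
    n_new_motus: int

    @classmethod
    def from_records(cls, records: list[tuple[str, str, str]], n_new: int) -> "ExtensionReport":
        df = pd.DataFrame(records, columns=["genome_id", "fate", "motu_id"])
        return cls(
            fates=df,
            n_rejected=int((df["fate"] == "rejected").sum()),
            n_assigned=int((df["fate"] == "assigned").sum()),
            n_new_motus=n_new,
        )


def extend_database(
    db: MGDatabase,
    gs: Sequence[GenomeMGSet],
    min_assign_families: int = 3,
) -> tuple[MGDatabase, ExtensionReport]:
    """Extend the database with new genomes: admit -> assign -> cluster.

    Genomes assigned to an existing mOTU are recorded but their sequences
    are not added (they are already represented); unassigned admitted
    genomes are clustered de novo into ext-mOTUs.  Every input genome gets
    exactly one fate: rejected | assigned | new ext-mOTU member.  The
    operation is idempotent: re-extending with the same genomes assigns all
    of them and creates no new entries.
    """
    new_db = copy.deepcopy(db)
    records: list[tuple[str, str, str]] = []
    leftovers: list[GenomeMGSet] = []
    for g in sorted(gs, key=lambda g: g.genome_id):
        if not admit_genome(g, new_db.min_families):
            records.append((g.genome_id, "rejected", ""))
            continue
        target = assign_genome(g, new_db, min_assign_families=min_assign_families)
        if target is not None:
            new_db.entries[target].genomes.add(g.genome_id)
            records.append((g.genome_id, "assigned", target))
        else:
            leftovers.append(g)
    start = sum(1 for e in new_db.entries.values() if e.category == "ext")
    new_entries = cluster_new_genomes(leftovers, new_db.cutoffs, start_index=start)
    for entry in new_entries:
        new_db.entries[entry.motu_id] = entry
        for gid in sorted(entry.genomes):
            records.append((gid, "new", entry.motu_id))
    return new_db, ExtensionReport.from_records(records, n_new=len(new_entries))


def update_unassigned(db: MGDatabase, leftover_mgs: Sequence[MarkerGeneSeq]) -> MGDatabase:
    """Fold leftover marker genes into the pooled unassigned entry.

    Leftovers (MGs failing all family cutoffs against the database) are
    clustered per family at that family's cutoff, with the existing
    unassigned representatives seeding the centroids so that duplicates add
    nothing; the longest member of each new cluster becomes its
    representative.
    """
    new_db = copy.deepcopy(db)
    entry = new_db.unassigned_entry
    by_family: dict[str, list[MarkerGeneSeq]] = {}
    for mg in leftover_mgs:
        by_family.setdefault(mg.family, []).append(mg)
    for fam in sorted(by_family):
        cutoff = new_db.cutoffs[fam]
        existing = list(entry.sequences.get(fam, []))
        centroids = [mg.seq for mg in existing]
        clusters: list[list[MarkerGeneSeq]] = [[] for _ in centroids]
        ordered = sorted(by_family[fam], key=lambda m: (-m.length, m.genome_id))
        for mg in ordered:
            for i, cseq in enumerate(centroids):
                if global_identity_both_strands(mg.seq, cseq) >= cutoff:
                    clusters[i].append(mg)
                    break
            else:
                centroids.append(mg.seq)
                clusters.append([mg])
        # new clusters (beyond the seeded ones) contribute one representative
        for cluster in clusters[len(existing):]:
            rep = max(cluster, key=lambda m: (m.length, m.genome_id))
            entry.sequences.setdefault(fam, []).append(rep)
    return new_db


def annotate_consensus(
    entry: MOTUEntry, per_mg_lineages: Sequence[TaxLineage]
) -> tuple[TaxLineage, dict[str, str]]:
    """Per-rank majority-consensus taxonomy over marker-gene annotations.

    At each rank the name held by more than half of the annotated MGs is
    assigned.  Consistency categories: ``agreeing`` when unanimous,
    ``majority`` when >50% but not all, ``not_agreeing`` when no name
    reaches a majority (the rank becomes unannotated), and
    ``not_annotated`` when no MG carries an annotation at that rank.  Once
    a rank is unannotated, all lower ranks are forced unannotated.
    """
    if not per_mg_lineages:
        raise ValueError("need at least one lineage")
    names: list[Optional[str]] = []
    consistency: dict[str, str] = {}
    truncated = False
    for i, rank in enumerate(RANKS):
        if truncated:
            names.append(None)
            consistency[rank] = consistency.get(rank, "not_annotated")
            continue
        annotated = [lin.ranks[i] for lin in per_mg_lineages if lin.ranks[i] is not None]
        if not annotated:
            names.append(None)
            consistency[rank] = "not_annotated"
            truncated = True
            continue
        (top_name, top_count), = Counter(annotated).most_common(1)
        if top_count * 2 > len(annotated):
            names.append(top_name)
            consistency[rank] = "agreeing" if top_count == len(annotated) else "majority"
        else:
            names.append(None)
            consistency[rank] = "not_agreeing"
            truncated = True
    return TaxLineage(tuple(names)), consistency
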