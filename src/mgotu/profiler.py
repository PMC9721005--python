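"""Insert-level profiling against the marker-gene OTU database.

Inserts (single reads, or read pairs counting once) are aligned to all
database marker genes, resolved to their best-matching mOTU when the hit
passes the family's species-level identity cutoff, pooled into the
"unassigned" fraction when the hit clears the report floor but not the
cutoff, and discarded otherwise.  Counts are turned into relative
abundances by length-normalized per-family scoring, aggregated to
taxonomic ranks, rarefied, and summarized (QC, prevalence, Shannon index).
"""

from __future__ import annotations

import dataclasses
import math
from collections import defaultdict
from typing import Optional, Sequence

import numpy as np

from ._align import infix_identity_both_strands, revcomp
from .core_io import (
    RANKS,
    UNASSIGNED,
    CountProfile,
    MGDatabase,
    RelAbundanceProfile,
)

DEFAULT_REPORT_FLOOR = 0.93
DEFAULT_MIN_ALIGN_LENGTH = 45
_INDEX_K = 14


@dataclasses.dataclass(frozen=True)
class AlignmentHit:
    """Read-level alignment evidence against one database marker gene."""

    insert_id: str
    motu_id: str
    family: str
    identity: float
    aligned_length: int


class DBIndex:
    """K-mer seed index over all database marker genes, both strands.

    Candidate target sequences for an insert are those sharing at least one
    k-mer with the insert (on either strand); candidates are then verified
    by semi-global alignment.
    """

    def __init__(self, db: MGDatabase, k: int = _INDEX_K):
        self.db = db
        self.k = k
        self.targets: list[tuple[str, str, str]] = []  # (motu_id, family, seq)
        self.kmer_map: dict[str, set[int]] = defaultdict(set)
        for motu_id, fam, mg in db.iter_sequences():
            idx = len(self.targets)
            self.targets.append((motu_id, fam, mg.seq))
            seq = mg.seq
            for i in range(len(seq) - k + 1):
                self.kmer_map[seq[i : i + k]].add(idx)
        if not self.targets:
            raise ValueError("cannot index an empty database")

    def candidates(self, read: str) -> set[int]:
        out: set[int] = set()
        k = self.k
        for strand_seq in (read, revcomp(read)):
            for i in range(len(strand_seq) - k + 1):
                hit = self.kmer_map.get(strand_seq[i : i + k])
                if hit:
                    out |= hit
        return out


def align_inserts(
    reads: Sequence[tuple[str, str]],
    db: MGDatabase,
    reads2: Optional[Sequence[tuple[str, str]]] = None,
    min_identity: float = DEFAULT_REPORT_FLOOR,
    min_align_length: int = DEFAULT_MIN_ALIGN_LENGTH,
    index: Optional[DBIndex] = None,
) -> list[AlignmentHit]:
    """Align inserts to the database; report hits above the identity floor.

    `reads` are (insert_id, sequence); when `reads2` is given, mates are
    paired positionally and the two reads contribute one insert whose
    evidence against each target is the better mate's alignment.
    """
    if index is None:
        index = DBIndex(db)
    if reads2 is not None and len(reads2) != len(reads):
        raise ValueError("reads and reads2 differ in length")
    hits: list[AlignmentHit] = []
    for i, (insert_id, seq) in enumerate(reads):
        mates = [seq]
        if reads2 is not None:
            mates.append(reads2[i][1])
        best_per_target: dict[int, tuple[float, int]] = {}
        for mate in mates:
            for t in index.candidates(mate):
                ident, alen = infix_identity_both_strands(mate, index.targets[t][2])
                prev = best_per_target.get(t)
                if prev is None or (ident, alen) > prev:
                    best_per_target[t] = (ident, alen)
        for t, (ident, alen) in best_per_target.items():
            if ident >= min_identity and alen >= min_align_length:
                motu_id, fam, _ = index.targets[t]
                hits.append(
                    AlignmentHit(
                        insert_id=insert_id,
                        motu_id=motu_id,
                        family=fam,
                        identity=ident,
                        aligned_length=alen,
                    )
                )
    return hits


@dataclasses.dataclass(frozen=True)
class InsertAssignment:
    insert_id: str
    motu_id: str  # a real mOTU id or UNASSIGNED
    family: str


def assign_insert(hits: Sequence[AlignmentHit], db: MGDatabase) -> Optional[InsertAssignment]:
    """Resolve one insert's hits to a mOTU, the unassigned pool, or nothing.

    The best hit (identity, then aligned length, then lexicographic
    motu_id) decides: passing its family cutoff assigns the insert to that
    mOTU (hits on unassigned-entry sequences count as unassigned); clearing
    the report floor but not the cutoff pools it as unassigned; no hits
    discards the insert (returns None).
    """
    if not hits:
        return None
    ids = {h.insert_id for h in hits}
    if len(ids) != 1:
        raise ValueError(f"hits from multiple inserts: {sorted(ids)}")
    best = min(hits, key=lambda h: (-h.identity, -h.aligned_length, h.motu_id))
    if best.identity >= db.cutoffs[best.family] and best.motu_id != UNASSIGNED:
        return InsertAssignment(best.insert_id, best.motu_id, best.family)
    return InsertAssignment(best.insert_id, UNASSIGNED, best.family)


def resolve_inserts(hits: Sequence[AlignmentHit], db: MGDatabase) -> list[InsertAssignment]:
    """Group hits by insert and resolve each one; discarded inserts drop out."""
    grouped: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        grouped[h.insert_id].append(h)
    out = []
    for insert_id in sorted(grouped):
        a = assign_insert(grouped[insert_id], db)
        if a is not None:
            out.append(a)
    return out


def _family_kb(db: MGDatabase, motu_id: str, family: str) -> float:
    seqs = db.entries[motu_id].family_sequences(family)
    return sum(mg.length for mg in seqs) / 1000.0


def _db_mean_family_kb(db: MGDatabase, family: str) -> float:
    lengths = [mg.length for _m, mg in db.family_sequences(family)]
    if not lengths:
        return 1.0
    return (sum(lengths) / len(lengths)) / 1000.0


def quantify(
    assignments: Sequence[InsertAssignment],
    db: MGDatabase,
    mode: str = "counts",
    sample_id: str = "sample",
) -> CountProfile | RelAbundanceProfile:
    """Turn insert assignments into a count or relative-abundance profile.

    Counts mode reports integer insert counts per mOTU (unassigned key
    always present).  Relative-abundance mode scores each mOTU as the mean
    over its families of (inserts assigned to the family / total family
    sequence length in kb) and normalizes the scores — including the
    unassigned pool, whose per-family counts are normalized by the
    database-wide mean family gene length — to sum to 1.
    """
    if mode not in ("counts", "relabund"):
        raise ValueError(f"unknown mode {mode!r}")
    counts: dict[str, int] = {UNASSIGNED: 0}
    fam_counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for a in assignments:
        counts[a.motu_id] = counts.get(a.motu_id, 0) + 1
        fam_counts[a.motu_id][a.family] += 1
    if mode == "counts":
        return CountProfile(sample_id=sample_id, counts=counts)
    if not assignments:
        raise ValueError("no assigned inserts; cannot compute relative abundances")
    scores: dict[str, float] = {}
    for motu_id, per_fam in fam_counts.items():
        if motu_id == UNASSIGNED:
            continue
        fams = sorted(db.entries[motu_id].families)
        per = [per_fam.get(f, 0) / _family_kb(db, motu_id, f) for f in fams]
        scores[motu_id] = sum(per) / len(per)
    ua = fam_counts.get(UNASSIGNED, {})
    if ua:
        fams = sorted(db.cutoffs)
        per = [ua.get(f, 0) / _db_mean_family_kb(db, f) for f in fams]
        scores[UNASSIGNED] = sum(per) / len(per)
    else:
        scores[UNASSIGNED] = 0.0
    total = sum(scores.values())
    return RelAbundanceProfile(
        sample_id=sample_id,
        rank="motu",
        abundances={m: s / total for m, s in scores.items()},
    )


def profile_sample(
    reads: Sequence[tuple[str, str]],
    db: MGDatabase,
    reads2: Optional[Sequence[tuple[str, str]]] = None,
    mode: str = "counts",
    sample_id: str = "sample",
    index: Optional[DBIndex] = None,
) -> CountProfile | RelAbundanceProfile:
    """Convenience wrapper: align, resolve, quantify."""
    hits = align_inserts(reads, db, reads2=reads2, index=index)
    assignments = resolve_inserts(hits, db)
    return quantify(assignments, db, mode=mode, sample_id=sample_id)


def aggregate_to_rank(
    profile: RelAbundanceProfile, db: MGDatabase, rank: str
) -> RelAbundanceProfile:
    """Sum mOTU abundances by lineage name at a taxonomic rank.

    Taxa are keyed by the full ``;``-joined lineage path down to the rank
    (so homonymous names under different parents stay separate).  Mass from
    mOTUs unannotated at the rank is reported under ``unannotated@<rank>``;
    the unassigned fraction is carried through unchanged, so the total
    still sums to 1.  Aggregating an already rank-aggregated profile to the
    same rank is the identity.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if profile.rank == rank:
        return profile
    if profile.rank != "motu":
        raise ValueError(f"cannot aggregate a {profile.rank}-level profile to {rank}")
    out: dict[str, float] = {}
    for taxon, ab in profile.abundances.items():
        if taxon == UNASSIGNED:
            key = UNASSIGNED
        else:
            lineage = db.taxonomy_of(taxon)
            if lineage.name_at(rank) is None:
                key = f"unannotated@{rank}"
            else:
                key = ";".join(str(n) for n in lineage.prefix(rank))
        out[key] = out.get(key, 0.0) + ab
    out.setdefault(UNASSIGNED, 0.0)
    return RelAbundanceProfile(sample_id=profile.sample_id, rank=rank, abundances=out)


def rarefy(counts: CountProfile, depth: int = 5000, seed: int = 0) -> CountProfile:
    """Subsample insert counts without replacement to a fixed depth.

    Multivariate-hypergeometric draw; the output totals exactly `depth`.
    Requesting more inserts than the sample holds is an error.
    """
    total = counts.total_inserts
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds total inserts {total}")
    rng = np.random.default_rng(seed)
    taxa = sorted(counts.counts)
    colors = np.array([counts.counts[t] for t in taxa])
    drawn = rng.multivariate_hypergeometric(colors, depth)
    return CountProfile(
        sample_id=counts.sample_id,
        counts={t: int(c) for t, c in zip(taxa, drawn)},
    )


def sample_qc(profile: CountProfile, min_inserts: int = 5000) -> bool:
    """Keep a sample only if it has at least `min_inserts` mapped inserts.

    Returns True (keep) when total_inserts >= min_inserts; the boundary is
    strict in the drop direction ("less than" drops).
    """
    return profile.total_inserts >= min_inserts


def prevalence_detected(
    cohort: Sequence[RelAbundanceProfile | CountProfile],
    threshold: float = 0.001,
) -> set[str]:
    """Taxa whose prevalence (fraction of samples with abundance > 0) exceeds
    `threshold` (strictly)."""
    if not cohort:
        raise ValueError("empty cohort")
    presence: dict[str, int] = defaultdict(int)
    for prof in cohort:
        values = prof.counts if isinstance(prof, CountProfile) else prof.abundances
        for taxon, v in values.items():
            if v > 0:
                presence[taxon] += 1
    n = len(cohort)
    return {t for t, k in presence.items() if k / n > threshold}


def shannon_index(profile: RelAbundanceProfile, exclude_unassigned: bool = False) -> float:
    """Shannon diversity, -sum(p ln p) in nats, over positive abundances.

    With `exclude_unassigned` the unassigned fraction is removed and the
    remaining abundances renormalized first.
    """
    abunds = dict(profile.abundances)
    if exclude_unassigned:
        abunds.pop(UNASSIGNED, None)
    total = sum(abunds.values())
    if total <= 0:
        raise ValueError("no positive abundances")
    return -sum(
        (p / total) * math.log(p / total) for p in abunds.values() if p > 0
    )
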