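"""Domain types and file I/O for marker-gene OTU databases and profiles.

The package works with species-level operational taxonomic units (mOTUs)
defined by sequence identity of ten universal, single-copy, protein-coding
marker-gene (MG) families.  This module holds the shared containers —
per-genome MG sets, database entries, taxonomic lineages, count and
relative-abundance profiles — and readers/writers for FASTA, profile TSV,
the CAMI/Bioboxes profiling format, and the on-disk database layout.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The ten marker-gene families used for mOTU delineation.
MG_FAMILIES: tuple[str, ...] = (
    "COG0012",
    "COG0016",
    "COG0018",
    "COG0172",
    "COG0215",
    "COG0495",
    "COG0525",
    "COG0533",
    "COG0541",
    "COG0552",
)

#: The seven taxonomic ranks used throughout, root-first.
RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Key under which the pooled unassigned fraction is reported in profiles.
UNASSIGNED: str = "unassigned"

#: taxon_id used for the unassigned row in profile TSV files.
UNASSIGNED_TAXID: str = "-1"

MIN_MG_LENGTH = 100

_VALID_BASES = frozenset("ACGTN")


def validate_family(label: str, families: Sequence[str] = MG_FAMILIES) -> str:
    if label not in families:
        raise ValueError(f"unknown family {label!r}")
    return label


@dataclasses.dataclass(frozen=True)
class MarkerGeneSeq:
    """One marker-gene sequence from one genome."""

    genome_id: str
    family: str
    seq: str

    def __post_init__(self) -> None:
        validate_family(self.family)
        if len(self.seq) < MIN_MG_LENGTH:
            raise ValueError(
                f"marker gene {self.genome_id}|{self.family} is "
                f"{len(self.seq)} nt; minimum is {MIN_MG_LENGTH}"
            )
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise ValueError(f"invalid bases {sorted(bad)} in {self.genome_id}|{self.family}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclasses.dataclass
class GenomeMGSet:
    """A genome's marker-gene complement: at most one sequence per family."""

    genome_id: str
    members: dict[str, MarkerGeneSeq]

    def __post_init__(self) -> None:
        if not 1 <= len(self.members) <= len(MG_FAMILIES):
            raise ValueError(
                f"genome {self.genome_id}: expected 1-{len(MG_FAMILIES)} families, "
                f"got {len(self.members)}"
            )
        for fam, mg in self.members.items():
            if mg.family != fam:
                raise ValueError(f"genome {self.genome_id}: key {fam} holds family {mg.family}")

    @property
    def families(self) -> frozenset[str]:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclasses.dataclass(frozen=True)
class TaxLineage:
    """Seven-rank lineage; None marks an unannotated rank.

    Once a rank is unannotated every lower rank must be too, mirroring how
    consensus annotation truncates lineages.
    """

    ranks: tuple[Optional[str], ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(RANKS):
            raise ValueError(f"expected {len(RANKS)} ranks, got {len(self.ranks)}")
        seen_na = False
        for name in self.ranks:
            if name is None:
                seen_na = True
            elif seen_na:
                raise ValueError(f"annotated rank below an unannotated one: {self.ranks}")

    @classmethod
    def from_names(cls, *names: Optional[str]) -> "TaxLineage":
        padded = list(names) + [None] * (len(RANKS) - len(names))
        return cls(tuple(padded))

    @classmethod
    def unannotated(cls) -> "TaxLineage":
        return cls((None,) * len(RANKS))

    def name_at(self, rank: str) -> Optional[str]:
        return self.ranks[RANKS.index(rank)]

    def prefix(self, rank: str) -> tuple[Optional[str], ...]:
        """Lineage truncated at `rank` (inclusive), used as a tree path."""
        return self.ranks[: RANKS.index(rank) + 1]

    def to_string(self) -> str:
        return ";".join("NA" if n is None else n for n in self.ranks)

    @classmethod
    def from_string(cls, s: str) -> "TaxLineage":
        parts = s.split(";")
        return cls(tuple(None if p == "NA" else p for p in parts))


#: Marker-gene consistency categories per rank (consensus annotation).
CONSISTENCY_CATEGORIES = ("agreeing", "majority", "not_agreeing", "not_annotated")

MOTU_CATEGORIES = ("ref", "meta", "ext", "unassigned")


@dataclasses.dataclass
class MOTUEntry:
    """One database entry: a species-level cluster of genomes' marker genes.

    Categories: ``ref`` (anchored by a reference genome), ``meta``
    (metagenomic contigs), ``ext`` (newly added cultivation-independent
    genomes), and the single pooled ``unassigned`` entry that holds marker
    genes not belonging to any mOTU.
    """

    motu_id: str
    category: str
    genomes: set[str]
    sequences: dict[str, list[MarkerGeneSeq]]
    taxonomy: TaxLineage = dataclasses.field(default_factory=TaxLineage.unannotated)
    consistency: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in MOTU_CATEGORIES:
            raise ValueError(f"unknown mOTU category {self.category!r}")
        if self.category == "unassigned":
            if self.genomes:
                raise ValueError("the unassigned entry carries no genomes")
            if any(n is not None for n in self.taxonomy.ranks):
                raise ValueError("the unassigned entry carries no taxonomy")
        elif not self.genomes:
            raise ValueError(f"mOTU {self.motu_id} has no genomes")
        for fam in self.sequences:
            validate_family(fam)

    def family_sequences(self, family: str) -> list[MarkerGeneSeq]:
        return self.sequences.get(family, [])

    @property
    def families(self) -> frozenset[str]:
        return frozenset(f for f, seqs in self.sequences.items() if seqs)


DEFAULT_CUTOFF = 0.965  # species-level marker-gene identity boundary
DEFAULT_PREFILTER_ID = 0.80
DEFAULT_MIN_FAMILIES = 6


def default_cutoffs() -> dict[str, float]:
    return {fam: DEFAULT_CUTOFF for fam in MG_FAMILIES}


@dataclasses.dataclass
class MGDatabase:
    """The mOTU database: entries plus the per-family identity cutoffs."""

    entries: dict[str, MOTUEntry]
    cutoffs: dict[str, float] = dataclasses.field(default_factory=default_cutoffs)
    prefilter_id: float = DEFAULT_PREFILTER_ID
    min_families: int = DEFAULT_MIN_FAMILIES
    version: str = "0"

    def __post_init__(self) -> None:
        if UNASSIGNED not in self.entries:
            self.entries[UNASSIGNED] = MOTUEntry(
                motu_id=UNASSIGNED, category="unassigned", genomes=set(), sequences={}
            )
        n_unassigned = sum(1 for e in self.entries.values() if e.category == "unassigned")
        if n_unassigned != 1:
            raise ValueError("database must contain exactly one unassigned entry")
        for fam, cut in self.cutoffs.items():
            validate_family(fam)
            if not 0 < cut <= 1:
                raise ValueError(f"cutoff for {fam} outside (0,1]: {cut}")

    @classmethod
    def empty(cls, version: str = "0") -> "MGDatabase":
        return cls(entries={}, version=version)

    @property
    def unassigned_entry(self) -> MOTUEntry:
        return self.entries[UNASSIGNED]

    def motu_ids(self, include_unassigned: bool = False) -> list[str]:
        ids = sorted(m for m in self.entries if m != UNASSIGNED)
        if include_unassigned:
            ids.append(UNASSIGNED)
        return ids

    def iter_sequences(self) -> Iterator[tuple[str, str, MarkerGeneSeq]]:
        """Yield (motu_id, family, sequence) over all entries, sorted."""
        for motu_id in sorted(self.entries):
            entry = self.entries[motu_id]
            for fam in sorted(entry.sequences):
                for mg in entry.sequences[fam]:
                    yield motu_id, fam, mg

    def family_sequences(self, family: str) -> list[tuple[str, MarkerGeneSeq]]:
        out = []
        for motu_id in sorted(self.entries):
            for mg in self.entries[motu_id].family_sequences(family):
                out.append((motu_id, mg))
        return out

    def taxonomy_of(self, motu_id: str) -> TaxLineage:
        if motu_id == UNASSIGNED:
            return TaxLineage.unannotated()
        return self.entries[motu_id].taxonomy


@dataclasses.dataclass
class CountProfile:
    """Per-sample insert counts per mOTU; the unassigned key is always present."""

    sample_id: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        self.counts.setdefault(UNASSIGNED, 0)
        for taxon, c in self.counts.items():
            if c < 0 or c != int(c):
                raise ValueError(f"negative or non-integer count for {taxon}: {c}")

    @property
    def total_inserts(self) -> int:
        return sum(self.counts.values())

    def to_relabund(self, rank: str = "motu") -> "RelAbundanceProfile":
        total = self.total_inserts
        if total == 0:
            raise ValueError(f"sample {self.sample_id}: no inserts to normalize")
        return RelAbundanceProfile(
            sample_id=self.sample_id,
            rank=rank,
            abundances={t: c / total for t, c in self.counts.items()},
        )


@dataclasses.dataclass
class RelAbundanceProfile:
    """Rank-resolved relative abundances summing to 1, unassigned included."""

    sample_id: str
    rank: str
    abundances: dict[str, float]

    def __post_init__(self) -> None:
        if self.rank != "motu" and self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        for taxon, a in self.abundances.items():
            if a < 0:
                raise ValueError(f"negative abundance for {taxon}: {a}")
        total = sum(self.abundances.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"abundances sum to {total}, expected 1")

    def get(self, taxon: str) -> float:
        return self.abundances.get(taxon, 0.0)

    @property
    def unassigned_fraction(self) -> float:
        return self.abundances.get(UNASSIGNED, 0.0)


# ---------------------------------------------------------------------------
# FASTA I/O for marker genes
# ---------------------------------------------------------------------------

def read_mg_fasta(
    path: str | Path,
    duplicate_policy: str = "longest",
) -> list[GenomeMGSet]:
    """Read per-genome marker genes from FASTA.

    Header grammar: ``genome_id|family`` (e.g. ``>g1|COG0012``).  Sequences
    are grouped by genome and validated against the ten known families.
    Duplicate (genome, family) pairs violate the single-copy contract;
    ``duplicate_policy`` is ``"longest"`` (keep the longer sequence) or
    ``"reject"`` (raise).
    """
    if duplicate_policy not in ("longest", "reject"):
        raise ValueError(f"unknown duplicate policy {duplicate_policy!r}")
    genomes: dict[str, dict[str, MarkerGeneSeq]] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ValueError(f"malformed header {rec.id!r}; expected genome_id|family")
        genome_id, family = parts
        validate_family(family)
        mg = MarkerGeneSeq(genome_id=genome_id, family=family, seq=str(rec.seq).upper())
        if genome_id not in genomes:
            genomes[genome_id] = {}
            order.append(genome_id)
        bucket = genomes[genome_id]
        if family in bucket:
            if duplicate_policy == "reject":
                raise ValueError(f"duplicate marker gene ({genome_id}, {family})")
            if mg.length > bucket[family].length:
                bucket[family] = mg
        else:
            bucket[family] = mg
    return [GenomeMGSet(genome_id=g, members=genomes[g]) for g in order]


def write_mg_fasta(genomes: Iterable[GenomeMGSet], path: str | Path) -> None:
    """Write marker genes using the ``genome_id|family`` header grammar."""
    records = []
    for g in genomes:
        for fam in sorted(g.members):
            mg = g.members[fam]
            records.append(SeqRecord(Seq(mg.seq), id=f"{g.genome_id}|{fam}", description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Profile TSV
# ---------------------------------------------------------------------------

def write_profile_tsv(
    profile: CountProfile | RelAbundanceProfile,
    path: str | Path,
    lineages: Optional[Mapping[str, TaxLineage]] = None,
) -> None:
    """Write a profile as TSV with columns (taxon_id, lineage, value).

    The unassigned fraction is emitted under taxon_id ``-1``.  Metadata
    (sample id, profile kind, rank) goes in comment lines so that a
    round-trip read reconstructs an equal profile.
    """
    if isinstance(profile, CountProfile):
        kind, rank, values = "counts", "motu", profile.counts
    else:
        kind, rank, values = "relabund", profile.rank, profile.abundances
    lineages = lineages or {}
    with open(path, "w") as fh:
        fh.write(f"# sample_id={profile.sample_id}\tkind={kind}\trank={rank}\n")
        fh.write("taxon_id\tlineage\tvalue\n")
        for taxon in sorted(values):
            if taxon == UNASSIGNED:
                continue
            lin = lineages.get(taxon)
            lin_str = lin.to_string() if lin is not None else "NA"
            fh.write(f"{taxon}\t{lin_str}\t{values[taxon]}\n")
        if UNASSIGNED in values:
            fh.write(f"{UNASSIGNED_TAXID}\tNA\t{values[UNASSIGNED]}\n")


def read_profile_tsv(path: str | Path) -> CountProfile | RelAbundanceProfile:
    """Read a profile written by :func:`write_profile_tsv`."""
    with open(path) as fh:
        meta_line = fh.readline().strip()
        if not meta_line.startswith("# "):
            raise ValueError(f"{path}: missing metadata line")
        meta = dict(field.split("=", 1) for field in meta_line[2:].split("\t"))
        header = fh.readline().strip().split("\t")
        if header != ["taxon_id", "lineage", "value"]:
            raise ValueError(f"{path}: unexpected columns {header}")
        values: dict[str, float] = {}
        for line in fh:
            taxon_id, _lineage, value = line.rstrip("\n").split("\t")
            taxon = UNASSIGNED if taxon_id == UNASSIGNED_TAXID else taxon_id
            values[taxon] = float(value)
    if meta["kind"] == "counts":
        return CountProfile(
            sample_id=meta["sample_id"], counts={t: int(v) for t, v in values.items()}
        )
    return RelAbundanceProfile(sample_id=meta["sample_id"], rank=meta["rank"], abundances=values)


# ---------------------------------------------------------------------------
# CAMI (Bioboxes) profiling format
# ---------------------------------------------------------------------------

_CAMI_VERSION = "0.9.1"


def write_cami_profile(
    rank_profiles: Mapping[str, RelAbundanceProfile],
    sample_id: str,
    path: str | Path,
) -> None:
    """Write rank-resolved profiles in the CAMI/Bioboxes profiling format.

    Requires a profile for each of the seven ranks.  Percentages are per
    rank; the unassigned fraction carries no taxonomic path and is omitted,
    so per-rank sums equal ``100 * (1 - unassigned)``.  Taxon identifiers in
    the profiles must be full lineage strings (``;``-joined, as produced by
    :meth:`TaxLineage.to_string` truncated at the rank) or plain names whose
    path is just themselves; here we require ``;``-joined paths of length
    equal to the rank depth.
    """
    missing = [r for r in RANKS if r not in rank_profiles]
    if missing:
        raise ValueError(f"missing rank profiles: {missing}")
    with open(path, "w") as fh:
        fh.write(f"@SampleID:{sample_id}\n")
        fh.write(f"@Version:{_CAMI_VERSION}\n")
        fh.write("@Ranks:" + "|".join(RANKS) + "\n")
        fh.write("@@TAXID\tRANK\tTAXPATH\tTAXPATHSN\tPERCENTAGE\n")
        for rank in RANKS:
            prof = rank_profiles[rank]
            depth = RANKS.index(rank) + 1
            for taxon in sorted(prof.abundances):
                if taxon == UNASSIGNED or taxon.startswith("unannotated@"):
                    continue
                names = taxon.split(";")
                if len(names) != depth:
                    raise ValueError(
                        f"taxon {taxon!r} at rank {rank}: expected a "
                        f"{depth}-element ;-joined path"
                    )
                taxpath = "|".join(names)
                pct = prof.abundances[taxon] * 100.0
                fh.write(f"{names[-1]}\t{rank}\t{taxpath}\t{taxpath}\t{pct:.10g}\n")


def read_cami_profile(path: str | Path) -> tuple[str, dict[str, dict[str, float]]]:
    """Read a CAMI profile; returns (sample_id, {rank: {path: percentage}})."""
    sample_id = ""
    per_rank: dict[str, dict[str, float]] = {r: {} for r in RANKS}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@SampleID:"):
                sample_id = line.split(":", 1)[1]
            elif line.startswith("@"):
                continue
            else:
                _taxid, rank, taxpath, _sn, pct = line.split("\t")
                per_rank[rank][taxpath.replace("|", ";")] = float(pct)
    return sample_id, per_rank


# ---------------------------------------------------------------------------
# On-disk database layout
# ---------------------------------------------------------------------------
# directory/
#   COG00xx.fasta  per-family marker genes, headers motu_id|genome_id|family|i
#   entries.tsv    motu_id, category, genomes, consistency
#   cutoffs.tsv    family, cutoff
#   taxonomy.tsv   motu_id, lineage
#   VERSION        version string + prefilter/min_families parameters

def save_database(db: MGDatabase, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    per_family: dict[str, list[SeqRecord]] = {fam: [] for fam in MG_FAMILIES}
    for motu_id, fam, mg in db.iter_sequences():
        idx = len(per_family[fam])
        header = f"{motu_id}|{mg.genome_id}|{fam}|{idx}"
        per_family[fam].append(SeqRecord(Seq(mg.seq), id=header, description=""))
    for fam, records in per_family.items():
        SeqIO.write(records, str(directory / f"{fam}.fasta"), "fasta")
    with open(directory / "entries.tsv", "w") as fh:
        fh.write("motu_id\tcategory\tgenomes\tconsistency\n")
        for motu_id in sorted(db.entries):
            e = db.entries[motu_id]
            genomes = ",".join(sorted(e.genomes))
            cons = ",".join(f"{r}:{c}" for r, c in sorted(e.consistency.items()))
            fh.write(f"{motu_id}\t{e.category}\t{genomes}\t{cons}\n")
    with open(directory / "cutoffs.tsv", "w") as fh:
        fh.write("family\tcutoff\n")
        for fam in MG_FAMILIES:
            fh.write(f"{fam}\t{db.cutoffs[fam]}\n")
    with open(directory / "taxonomy.tsv", "w") as fh:
        fh.write("motu_id\tlineage\n")
        for motu_id in sorted(db.entries):
            fh.write(f"{motu_id}\t{db.entries[motu_id].taxonomy.to_string()}\n")
    with open(directory / "VERSION", "w") as fh:
        fh.write(f"version={db.version}\n")
        fh.write(f"prefilter_id={db.prefilter_id}\n")
        fh.write(f"min_families={db.min_families}\n")


def load_database(directory: str | Path) -> MGDatabase:
    directory = Path(directory)
    params: dict[str, str] = {}
    with open(directory / "VERSION") as fh:
        for line in fh:
            key, value = line.strip().split("=", 1)
            params[key] = value
    cutoffs: dict[str, float] = {}
    with open(directory / "cutoffs.tsv") as fh:
        next(fh)
        for line in fh:
            fam, cut = line.strip().split("\t")
            cutoffs[fam] = float(cut)
    taxonomies: dict[str, TaxLineage] = {}
    with open(directory / "taxonomy.tsv") as fh:
        next(fh)
        for line in fh:
            motu_id, lin = line.rstrip("\n").split("\t")
            taxonomies[motu_id] = TaxLineage.from_string(lin)
    entries: dict[str, MOTUEntry] = {}
    with open(directory / "entries.tsv") as fh:
        next(fh)
        for line in fh:
            motu_id, category, genomes_s, cons_s = line.rstrip("\n").split("\t")
            genomes = set(genomes_s.split(",")) if genomes_s else set()
            consistency = {}
            if cons_s:
                for item in cons_s.split(","):
                    r, c = item.split(":")
                    consistency[r] = c
            entries[motu_id] = MOTUEntry(
                motu_id=motu_id,
                category=category,
                genomes=genomes,
                sequences={},
                taxonomy=taxonomies.get(motu_id, TaxLineage.unannotated()),
                consistency=consistency,
            )
    for fam in MG_FAMILIES:
        fasta = directory / f"{fam}.fasta"
        if not fasta.exists():
            continue
        for rec in SeqIO.parse(str(fasta), "fasta"):
            motu_id, genome_id, family, _idx = rec.id.split("|")
            mg = MarkerGeneSeq(genome_id=genome_id, family=family, seq=str(rec.seq).upper())
            entries[motu_id].sequences.setdefault(family, []).append(mg)
    return MGDatabase(
        entries=entries,
        cutoffs=cutoffs,
        prefilter_id=float(params["prefilter_id"]),
        min_families=int(params["min_families"]),
        version=params["version"],
    )
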