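"""Synthetic marker genes, genomes, communities, reads, and cohorts.

Every generator is deterministic given (parameters, seed) and uses a
substitution-only mutation model: divergence is introduced by substituting
a fixed number of positions sampled without replacement, so the realized
global-alignment identity to the source equals the target exactly (up to
rounding of the substitution count).  This makes identity thresholds
testable by construction.  Indels are deliberately not modeled.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    MG_FAMILIES,
    UNASSIGNED,
    GenomeMGSet,
    MarkerGeneSeq,
    MGDatabase,
    RelAbundanceProfile,
)
from ._align import revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclasses.dataclass
class CommunitySpec:
    """Ground-truth description of a simulated community."""

    species: list[str]
    abundances: list[float]
    n_inserts: int
    read_length: int = 150
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species) != len(self.abundances):
            raise ValueError("species and abundances differ in length")
        if self.n_inserts < 0:
            raise ValueError("n_inserts must be non-negative")
        if not math.isclose(sum(self.abundances), 1.0, abs_tol=1e-9):
            raise ValueError(f"abundances sum to {sum(self.abundances)}, expected 1")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate outside [0, 0.5)")


def _random_dna(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def make_marker_family(length: int, seed: int) -> str:
    """Uniform-random DNA sequence acting as a marker-family founder."""
    if length < 100:
        raise ValueError(f"marker genes must be >= 100 nt, got {length}")
    return _random_dna(length, np.random.default_rng(seed))


def substitute_positions(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    """Substitute each listed position with a different base."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    for pos in positions:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode()


def mutate_to_identity(seq: str, target_identity: float, seed: int | np.random.Generator) -> str:
    """Mutate `seq` so its identity to the original equals `target_identity`.

    Substitution-only: round(len * (1 - target)) positions are sampled
    without replacement and each changed to a different base, so the
    Hamming (and hence global-alignment) identity matches the target to
    within half a position.
    """
    if not 0.5 <= target_identity <= 1.0:
        raise ValueError(f"target identity {target_identity} outside [0.5, 1.0]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sub = round(len(seq) * (1.0 - target_identity))
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    return substitute_positions(seq, positions, rng)


def _disjoint_blocks(length: int, sizes: Sequence[int], rng: np.random.Generator) -> list[np.ndarray]:
    """Disjoint position sets so pairwise divergences add up exactly."""
    total = sum(sizes)
    if total > length:
        raise ValueError(
            f"requested divergence needs {total} substitution sites but sequences "
            f"are only {length} nt; lower divergence or raise gene length"
        )
    pool = rng.permutation(length)
    blocks, start = [], 0
    for size in sizes:
        blocks.append(pool[start : start + size])
        start += size
    return blocks


def make_species_clusters(
    n_species: int,
    genomes_per_species: int,
    within_id: float,
    between_id: float,
    seed: int,
    gene_length: int = 1000,
    n_families: int = len(MG_FAMILIES),
    cutoff: float = 0.965,
) -> tuple[list[GenomeMGSet], dict[str, str]]:
    """Planted species clusters straddling an identity cutoff.

    Each species has a founder MG set; conspecific genomes are mutated copies
    of the founder at `within_id`, while founders of different species sit at
    `between_id` to each other.  Substitution sites are disjoint across
    genomes, so within-species identities stay strictly above between-species
    identities by construction.  Returns (genomes, truth) where truth maps
    genome_id -> species label.
    """
    if not between_id < cutoff <= within_id:
        raise ValueError(
            f"need between_id < cutoff <= within_id, got "
            f"{between_id} / {cutoff} / {within_id}"
        )
    rng = np.random.default_rng(seed)
    families = list(MG_FAMILIES[:n_families])
    founder_block = round(gene_length * (1.0 - between_id) / 2.0)
    genome_block = round(gene_length * (1.0 - within_id))
    sizes = [founder_block] * n_species + [genome_block] * (n_species * (genomes_per_species - 1))

    genomes: list[GenomeMGSet] = []
    truth: dict[str, str] = {}
    per_family_blocks = {}
    ancestors = {}
    for fam in families:
        ancestors[fam] = make_marker_family(gene_length, int(rng.integers(2**31)))
        per_family_blocks[fam] = _disjoint_blocks(gene_length, sizes, rng)
    for s in range(n_species):
        founder_seqs = {}
        for fam in families:
            blocks = per_family_blocks[fam]
            founder_seqs[fam] = substitute_positions(ancestors[fam], blocks[s], rng)
        for g in range(genomes_per_species):
            gid = f"s{s:03d}_g{g:03d}"
            members = {}
            for fam in families:
                if g == 0:
                    seq = founder_seqs[fam]
                else:
                    blocks = per_family_blocks[fam]
                    block = blocks[n_species + s * (genomes_per_species - 1) + (g - 1)]
                    seq = substitute_positions(founder_seqs[fam], block, rng)
                members[fam] = MarkerGeneSeq(genome_id=gid, family=fam, seq=seq)
            genomes.append(GenomeMGSet(genome_id=gid, members=members))
            truth[gid] = f"species_{s:03d}"
    return genomes, truth


@dataclasses.dataclass
class SyntheticGenome:
    """A simulated genome carrying a conserved locus and a marker-gene set."""

    genome_id: str
    genome_seq: str
    locus_seq: str
    mgs: GenomeMGSet
    divergence: float  # substitution rate applied relative to the ancestor


def make_16s_like_genomes(
    n_genomes: int,
    genome_divergence_range: tuple[float, float],
    seed: int,
    genome_length: int = 40_000,
    locus_length: int = 1500,
    gene_length: int = 1000,
    locus_conservation: float = 5.0,
    locus_variable_fraction: float = 0.1,
) -> list[SyntheticGenome]:
    """Genomes whose conserved locus mimics the 16S rRNA gene.

    Each genome is mutated from a common ancestor at a rate drawn uniformly
    from `genome_divergence_range`; its marker genes are mutated at the same
    genome-wide rate.  The conserved locus accumulates substitution events
    at 1/`locus_conservation` of that rate, and only within a small set of
    variable sites (`locus_variable_fraction` of the locus), with recurrent
    hits and back-mutations allowed.  Locus identity therefore saturates —
    it cannot drop below ~(1 - variable fraction) and homoplasy blurs it —
    while whole-genome identity spans the full range: the phenomenon that
    makes conserved-locus OTUs coarser than, and less predictive of,
    whole-genome divergence compared to marker genes.
    """
    lo, hi = genome_divergence_range
    if not (0 <= lo <= hi <= 0.3):
        raise ValueError(f"divergence range {genome_divergence_range} outside [0, 0.3]")
    rng = np.random.default_rng(seed)
    anc_genome = _random_dna(genome_length, rng)
    anc_locus = _random_dna(locus_length, rng)
    variable_sites = rng.choice(
        locus_length, size=round(locus_length * locus_variable_fraction), replace=False
    )
    anc_mgs = {fam: _random_dna(gene_length, rng) for fam in MG_FAMILIES}
    out = []
    for i in range(n_genomes):
        d = float(rng.uniform(lo, hi))
        gid = f"g{i:03d}"
        genome_seq = mutate_to_identity(anc_genome, 1.0 - d, rng) if d > 0 else anc_genome
        n_events = round(locus_length * d / locus_conservation)
        if n_events:
            hit = np.unique(rng.choice(variable_sites, size=n_events, replace=True))
            arr = np.frombuffer(anc_locus.encode(), dtype="S1").copy()
            arr[hit] = rng.choice(_BASES, size=len(hit))  # back-mutation allowed
            locus_seq = arr.tobytes().decode()
        else:
            locus_seq = anc_locus
        members = {
            fam: MarkerGeneSeq(
                genome_id=gid,
                family=fam,
                seq=mutate_to_identity(anc_mgs[fam], 1.0 - d, rng) if d > 0 else anc_mgs[fam],
            )
            for fam in MG_FAMILIES
        }
        out.append(
            SyntheticGenome(
                genome_id=gid,
                genome_seq=genome_seq,
                locus_seq=locus_seq,
                mgs=GenomeMGSet(genome_id=gid, members=members),
                divergence=d,
            )
        )
    return out


def simulate_inserts(
    db: MGDatabase,
    spec: CommunitySpec,
) -> tuple[list[tuple[str, str]], RelAbundanceProfile]:
    """Simulate sequencing inserts from the marker genes of a community.

    Inserts are drawn from member MG sequences of each species with
    probability proportional to (species abundance x gene length), start
    positions uniform, per-base substitution errors applied, and strand
    chosen uniformly.  Returns (inserts, truth) where inserts are
    (insert_id, sequence) and truth is the mOTU-level ground-truth profile
    (unassigned fraction 0 unless the spec names it).
    """
    rng = np.random.default_rng(spec.seed)
    pool: list[tuple[str, str]] = []  # (species, gene seq)
    weights: list[float] = []
    for sp, ab in zip(spec.species, spec.abundances):
        if sp not in db.entries:
            raise ValueError(f"species {sp} missing from database")
        entry = db.entries[sp]
        seqs = [mg.seq for fam in sorted(entry.sequences) for mg in entry.sequences[fam]]
        if not seqs:
            raise ValueError(f"species {sp} has no marker genes in the database")
        for s in seqs:
            if spec.read_length > len(s):
                raise ValueError(
                    f"read_length {spec.read_length} exceeds gene length {len(s)} in {sp}"
                )
            pool.append((sp, s))
            weights.append(ab * len(s))
    w = np.asarray(weights)
    w = w / w.sum()
    inserts: list[tuple[str, str]] = []
    choices = rng.choice(len(pool), size=spec.n_inserts, p=w)
    for i, idx in enumerate(choices):
        sp, gene = pool[idx]
        start = int(rng.integers(0, len(gene) - spec.read_length + 1))
        read = gene[start : start + spec.read_length]
        if spec.error_rate > 0:
            n_err = rng.binomial(spec.read_length, spec.error_rate)
            if n_err:
                positions = rng.choice(spec.read_length, size=n_err, replace=False)
                read = substitute_positions(read, positions, rng)
        if rng.random() < 0.5:
            read = revcomp(read)
        inserts.append((f"insert_{i:06d}|{sp}", read))
    truth_ab = dict(zip(spec.species, spec.abundances))
    truth_ab.setdefault(UNASSIGNED, 0.0)
    truth = RelAbundanceProfile(sample_id="truth", rank="motu", abundances=truth_ab)
    return inserts, truth


def write_fastq(inserts: Sequence[tuple[str, str]], path: str) -> None:
    """Write simulated inserts as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for name, seq in inserts:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def make_two_group_cohort(
    n_per_group: int,
    n_taxa: int,
    planted: Mapping[str, float],
    seed: int,
    sigma: float = 0.3,
    baseline_sigma: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Two-group cohort of relative-abundance profiles with planted effects.

    Baseline per-taxon means are log-normal; per-sample abundances add
    log-normal noise with log10 standard deviation `sigma`; group-B means are
    multiplied by the planted fold changes before renormalization.  Returns
    (profiles, design, truth): profiles is a samples x taxa DataFrame of
    relative abundances (rows sum to 1), design maps sample -> "A"/"B", and
    truth records the planted fold change per taxon (1.0 when none).
    """
    if n_per_group < 3:
        raise ValueError("need at least 3 samples per group")
    for taxon, fc in planted.items():
        if fc <= 0:
            raise ValueError(f"fold change for {taxon} must be positive, got {fc}")
    rng = np.random.default_rng(seed)
    taxa = [f"taxon_{i:03d}" for i in range(n_taxa)]
    unknown = set(planted) - set(taxa)
    if unknown:
        raise ValueError(f"planted taxa outside the cohort: {sorted(unknown)}")
    # log10 scale; sorted ascending so taxon indices are interpretable
    # (taxon_000 rarest ... taxon_{n-1} most abundant)
    log_means = np.sort(rng.normal(loc=-3.0, scale=baseline_sigma, size=n_taxa))
    rows = {}
    design = {}
    for group, prefix in (("A", "a"), ("B", "b")):
        for j in range(n_per_group):
            sample = f"{prefix}{j:02d}"
            design[sample] = group
            logs = log_means + rng.normal(scale=sigma, size=n_taxa)
            if group == "B":
                for taxon, fc in planted.items():
                    logs[taxa.index(taxon)] += math.log10(fc)
            vals = 10.0**logs
            rows[sample] = vals / vals.sum()
    profiles = pd.DataFrame.from_dict(rows, orient="index", columns=taxa)
    truth = pd.Series({t: planted.get(t, 1.0) for t in taxa}, name="fold_change")
    return profiles, pd.Series(design, name="group"), truth
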