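"""Clustering-congruence machinery: sketch distances, identity clustering,
V-measure, and distance-distance correlations.

Used to compare species-level groupings produced from marker genes,
whole-genome average nucleotide identity (ANI), and conserved-locus (16S
rRNA-like) sequence identity, and to quantify how well each distance tracks
whole-genome divergence.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._align import global_identity_both_strands
from .core_io import GenomeMGSet
from .mg_database import pairwise_mg_identity

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    vals = np.zeros(arr.shape, dtype=np.uint64)
    vals[arr == ord("C")] = 1
    vals[arr == ord("G")] = 2
    vals[arr == ord("T")] = 3
    return vals


def _canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical (strand-independent) 2-bit-packed k-mers of a sequence."""
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} shorter than k={k}")
    vals = _encode(seq)
    powers = (np.uint64(4) ** np.arange(k, dtype=np.uint64)).astype(np.uint64)
    windows = np.lib.stride_tricks.sliding_window_view(vals, k)
    fwd = windows @ powers[::-1]
    rc_windows = np.lib.stride_tricks.sliding_window_view(
        np.uint64(3) - vals, k
    )
    rc = rc_windows @ powers  # reversed complement = complement with reversed weights
    return np.minimum(fwd, rc)


def _splitmix64(x: np.ndarray, seed: int) -> np.ndarray:
    """Deterministic 64-bit mixing hash, vectorized."""
    with np.errstate(over="ignore"):
        z = x + np.uint64(0x9E3779B97F4A7C15) * np.uint64(seed + 1)
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return z ^ (z >> np.uint64(31))


def minhash_sketch(seq: str, k: int = 21, sketch_size: int = 1000, seed: int = 0) -> np.ndarray:
    """Bottom-s MinHash sketch of the canonical k-mer set of a genome."""
    hashes = np.unique(_splitmix64(_canonical_kmers(seq, k), seed))
    return hashes[:sketch_size]


def sketch_jaccard(sa: np.ndarray, sb: np.ndarray, sketch_size: int = 1000) -> float:
    """Jaccard estimate from two bottom-s sketches (merge-based estimator)."""
    union = np.union1d(sa, sb)[:sketch_size]
    shared = np.intersect1d(sa, sb, assume_unique=True)
    inter = np.isin(union, shared, assume_unique=True).sum()
    return float(inter) / len(union)


def sketch_distance(
    genome_a: str,
    genome_b: str,
    k: int = 21,
    sketch_size: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """MinHash-based genome distance: (jaccard, mash_distance, ani_estimate).

    mash_distance = -(1/k) * ln(2j / (1+j)); ani_estimate = 1 - mash_distance.
    Identical genomes give (1, 0, 1); disjoint k-mer sets give distance 1
    (capped) and ANI 0.
    """
    if min(len(genome_a), len(genome_b)) < 5000:
        raise ValueError("genomes must be at least 5000 nt for sketching")
    sa = minhash_sketch(genome_a, k, sketch_size, seed)
    sb = minhash_sketch(genome_b, k, sketch_size, seed)
    j = sketch_jaccard(sa, sb, sketch_size)
    if j <= 0:
        return 0.0, 1.0, 0.0
    d = min(1.0, -math.log(2 * j / (1 + j)) / k)
    return j, d, 1.0 - d


def identity_cluster(
    seqs: Sequence[tuple[str, str]],
    cutoff: float,
) -> dict[str, str]:
    """Greedy centroid clustering of sequences by global identity.

    Inputs (id, sequence) are processed sorted by length descending then by
    id; each sequence joins the first centroid it matches at >= `cutoff`
    identity, else founds a new cluster.  Returns item -> cluster label.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    if not 0 < cutoff <= 1:
        raise ValueError(f"cutoff {cutoff} outside (0, 1]")
    ordered = sorted(seqs, key=lambda x: (-len(x[1]), x[0]))
    centroids: list[tuple[str, str]] = []
    assignment: dict[str, str] = {}
    for sid, seq in ordered:
        for cid, cseq in centroids:
            if global_identity_both_strands(seq, cseq) >= cutoff:
                assignment[sid] = cid
                break
        else:
            centroids.append((sid, seq))
            assignment[sid] = sid
    return assignment


def ani_cluster(
    genomes: Sequence[tuple[str, str]],
    cutoff: float = 0.95,
    k: int = 21,
    sketch_size: int = 1000,
    seed: int = 0,
) -> dict[str, str]:
    """Greedy centroid clustering of genomes by sketch-estimated ANI."""
    if not genomes:
        raise ValueError("no genomes to cluster")
    sketches = {gid: minhash_sketch(seq, k, sketch_size, seed) for gid, seq in genomes}
    ordered = sorted(genomes, key=lambda x: (-len(x[1]), x[0]))
    centroids: list[str] = []
    assignment: dict[str, str] = {}
    for gid, _seq in ordered:
        for cid in centroids:
            j = sketch_jaccard(sketches[gid], sketches[cid], sketch_size)
            if j <= 0:
                continue
            ani = 1.0 - min(1.0, -math.log(2 * j / (1 + j)) / k)
            if ani >= cutoff:
                assignment[gid] = cid
                break
        else:
            centroids.append(gid)
            assignment[gid] = gid
    return assignment


def _entropy(labels: Sequence) -> float:
    n = len(labels)
    return -sum(
        (c / n) * math.log(c / n) for c in Counter(labels).values()
    )


def _conditional_entropy(target: Sequence, given: Sequence) -> float:
    """H(target | given) from the joint empirical distribution."""
    n = len(target)
    joint = Counter(zip(given, target))
    marginal = Counter(given)
    h = 0.0
    for (g, _t), c in joint.items():
        h -= (c / n) * math.log(c / marginal[g])
    return h


def v_measure(
    truth: Mapping[str, str], pred: Mapping[str, str], beta: float = 1.0
) -> tuple[float, float, float]:
    """Homogeneity, completeness, and their harmonic mean (V-measure).

    h = 1 - H(truth|pred)/H(truth) (each predicted cluster holds a single
    true class), c = 1 - H(pred|truth)/H(pred) (each true class lands in a
    single predicted cluster); conventions h=1 when H(truth)=0 and c=1 when
    H(pred)=0.  V = (1+beta) h c / (beta h + c).
    """
    if set(truth) != set(pred):
        raise ValueError("truth and pred must label the same items")
    items = sorted(truth)
    t = [truth[i] for i in items]
    p = [pred[i] for i in items]
    ht, hp = _entropy(t), _entropy(p)
    h = 1.0 if ht == 0 else 1.0 - _conditional_entropy(t, p) / ht
    c = 1.0 if hp == 0 else 1.0 - _conditional_entropy(p, t) / hp
    v = 0.0 if (h + c) == 0 else (1 + beta) * h * c / (beta * h + c)
    return h, c, v


def distance_correlation_table(
    genome_seqs: Mapping[str, str],
    mg_sets: Mapping[str, GenomeMGSet],
    loci: Mapping[str, str],
    k: int = 21,
    sketch_size: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, float]:
    """Pairwise (genome, mean-MG, conserved-locus) distances and their r².

    Distances are 1 - identity (sketch-estimated ANI for genomes, mean
    global alignment identity over shared MG families, global identity for
    the conserved locus).  Returns (table, r²(mg vs genome), r²(locus vs
    genome)); r² is the squared Pearson correlation of the distance columns
    and NaN when either column is constant.
    """
    ids = sorted(genome_seqs)
    if len(ids) < 3:
        raise ValueError("need at least 3 genomes")
    if set(ids) != set(mg_sets) or set(ids) != set(loci):
        raise ValueError("genome, MG-set, and locus ids must match")
    sketches = {g: minhash_sketch(genome_seqs[g], k, sketch_size, seed) for g in ids}
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            j = sketch_jaccard(sketches[a], sketches[b], sketch_size)
            if j <= 0:
                gdist = 1.0
            else:
                gdist = min(1.0, -math.log(2 * j / (1 + j)) / k)
            _per_fam, mg_mean = pairwise_mg_identity(mg_sets[a], mg_sets[b])
            ldist = 1.0 - global_identity_both_strands(loci[a], loci[b])
            rows.append((a, b, gdist, 1.0 - mg_mean, ldist))
    table = pd.DataFrame(
        rows, columns=["genome_a", "genome_b", "genome_dist", "mean_mg_dist", "locus_dist"]
    )

    def _r2(x: pd.Series, y: pd.Series) -> float:
        if x.std() == 0 or y.std() == 0:
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1] ** 2)

    r2_mg = _r2(table["mean_mg_dist"], table["genome_dist"])
    r2_locus = _r2(table["locus_dist"], table["genome_dist"])
    return table, r2_mg, r2_locus
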