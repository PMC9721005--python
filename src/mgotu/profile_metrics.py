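"""Profile-quality statistics for benchmarking taxonomic profilers.

Implements the standard CAMI/OPAL-style measures — presence/absence F1,
L1 norm error, completeness, purity, weighted UniFrac error over the
taxonomy tree — plus the sum-of-ranks composite score and Spearman
congruence against a reference profiler.  The unassigned fraction carries
no taxonomic label and is excluded before any metric is computed; gold
standards enumerate named taxa only.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional

import pandas as pd
from scipy import stats

from .core_io import RANKS, UNASSIGNED, RelAbundanceProfile

_HIGHER_IS_BETTER = {"f1": True, "completeness": True, "purity": True,
                     "l1": False, "unifrac": False}


def _named_abundances(
    profile: RelAbundanceProfile, renormalize: bool = True
) -> dict[str, float]:
    """Drop the unassigned / unannotated mass; optionally renormalize."""
    named = {
        t: a
        for t, a in profile.abundances.items()
        if t != UNASSIGNED and not t.startswith("unannotated@") and a > 0
    }
    if renormalize:
        total = sum(named.values())
        if total > 0:
            named = {t: a / total for t, a in named.items()}
    return named


def presence_absence_f1(
    pred: RelAbundanceProfile, gold: RelAbundanceProfile
) -> tuple[float, float, float]:
    """Precision, recall, and F1 of predicted taxon presence at one rank."""
    if pred.rank != gold.rank:
        raise ValueError(f"rank mismatch: {pred.rank} vs {gold.rank}")
    pset = set(_named_abundances(pred, renormalize=False))
    gset = set(_named_abundances(gold, renormalize=False))
    if not gset:
        raise ValueError("empty gold taxon set")
    tp = len(pset & gset)
    precision = tp / len(pset) if pset else 0.0
    recall = tp / len(gset)
    f1 = 0.0 if tp == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def l1_norm_error(
    pred: RelAbundanceProfile, gold: RelAbundanceProfile, renormalize: bool = True
) -> float:
    """Sum over taxa of |pred - gold| abundance; ranges over [0, 2]."""
    if pred.rank != gold.rank:
        raise ValueError(f"rank mismatch: {pred.rank} vs {gold.rank}")
    p = _named_abundances(pred, renormalize)
    g = _named_abundances(gold, renormalize)
    taxa = set(p) | set(g)
    return sum(abs(p.get(t, 0.0) - g.get(t, 0.0)) for t in taxa)


def completeness_purity(
    pred: RelAbundanceProfile,
    gold: RelAbundanceProfile,
    filter_threshold: float = 0.0,
) -> tuple[float, float]:
    """Completeness (recall of gold taxa) and purity (precision of
    predictions above `filter_threshold`).

    An empty prediction yields completeness 0 and, purity being undefined,
    purity 0 with a warning.
    """
    if pred.rank != gold.rank:
        raise ValueError(f"rank mismatch: {pred.rank} vs {gold.rank}")
    p = _named_abundances(pred, renormalize=False)
    pset = {t for t, a in p.items() if a > filter_threshold}
    gset = set(_named_abundances(gold, renormalize=False))
    completeness = len(pset & gset) / len(gset) if gset else 0.0
    if not pset:
        warnings.warn("empty prediction: purity undefined, reported as 0")
        return completeness, 0.0
    return completeness, len(pset & gset) / len(pset)


def weighted_unifrac_error(
    pred_ranks: Mapping[str, RelAbundanceProfile],
    gold_ranks: Mapping[str, RelAbundanceProfile],
    renormalize: bool = True,
) -> float:
    """Weighted UniFrac error over the taxonomy tree built from lineages.

    The tree is the union of the ``;``-joined lineage paths in both profile
    sets, with unit branch lengths between consecutive ranks (root to
    domain included).  The error is the sum over edges of |pred subtree
    mass - gold subtree mass|, where the mass at a node is the abundance of
    its taxon at that rank.  Identical profiles give 0.
    """
    masses: dict[tuple[str, ...], list[float]] = {}
    for which, rank_profiles in enumerate((pred_ranks, gold_ranks)):
        for rank in RANKS:
            if rank not in rank_profiles:
                raise ValueError(f"missing rank {rank}")
            named = _named_abundances(rank_profiles[rank], renormalize)
            for taxon, ab in named.items():
                path = tuple(taxon.split(";"))
                if len(path) != RANKS.index(rank) + 1:
                    raise ValueError(
                        f"taxon {taxon!r} at rank {rank}: path depth mismatch"
                    )
                node = masses.setdefault(path, [0.0, 0.0])
                node[which] += ab
    # consistency: a node must not appear under two different parents — the
    # path encoding rules that out by construction.
    return sum(abs(p - g) for p, g in masses.values())


def opal_sum_of_scores(
    metric_values: pd.DataFrame,
    higher_is_better: Optional[Mapping[str, bool]] = None,
) -> pd.Series:
    """Sum-of-ranks composite score across samples, ranks, and metrics.

    `metric_values` has columns (tool, sample, rank, metric, value).  Per
    (sample, rank, metric) cell the tools are ranked 0 = best, ties sharing
    the mean rank; the score is each tool's summed rank over all cells.
    Lower is better.  Metric direction defaults to the standard set (F1,
    completeness, purity: higher better; L1, UniFrac errors: lower better).
    """
    needed = {"tool", "sample", "rank", "metric", "value"}
    if not needed <= set(metric_values.columns):
        raise ValueError(f"expected columns {sorted(needed)}")
    direction = dict(_HIGHER_IS_BETTER)
    if higher_is_better:
        direction.update(higher_is_better)
    tools = sorted(metric_values["tool"].unique())
    if len(tools) < 2:
        raise ValueError("need at least 2 tools to rank")
    scores = {t: 0.0 for t in tools}
    grouped = metric_values.groupby(["sample", "rank", "metric"], sort=True)
    n_cells = 0
    for (_s, _r, metric), cell in grouped:
        if sorted(cell["tool"]) != tools:
            raise ValueError(f"missing tool values in cell {(_s, _r, metric)}")
        if metric not in direction:
            raise ValueError(f"unknown metric {metric!r}; pass higher_is_better")
        vals = cell.set_index("tool")["value"]
        ranked = stats.rankdata(-vals.values if direction[metric] else vals.values) - 1.0
        for tool, r in zip(vals.index, ranked):
            scores[tool] += r
        n_cells += 1
    if n_cells == 0:
        raise ValueError("no metric cells to rank")
    return pd.Series(scores, name="opal_score").sort_index()


def spearman_vs_reference(
    profiles: Mapping[str, RelAbundanceProfile],
    reference: Mapping[str, RelAbundanceProfile],
    renormalize: bool = True,
) -> float:
    """Spearman rho between a profiler and a reference over a cohort.

    Per-sample abundance vectors are aligned on the union of named taxa
    (zero-filled) and concatenated across samples before computing the
    correlation.  A constant vector makes the correlation undefined and
    returns NaN.
    """
    samples = sorted(profiles)
    if sorted(reference) != samples:
        raise ValueError("sample sets differ")
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    xs: list[float] = []
    ys: list[float] = []
    for s in samples:
        p = _named_abundances(profiles[s], renormalize)
        r = _named_abundances(reference[s], renormalize)
        taxa = sorted(set(p) | set(r))
        xs.extend(p.get(t, 0.0) for t in taxa)
        ys.extend(r.get(t, 0.0) for t in taxa)
    if len(set(xs)) <= 1 or len(set(ys)) <= 1:
        return float("nan")
    rho, _p = stats.spearmanr(xs, ys)
    return float(rho)
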