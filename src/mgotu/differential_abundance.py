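"""Two-group differential-abundance workflow for taxonomic profiles.

Pipeline: filter taxa by maximum relative abundance, test each remaining
taxon with a two-sided Wilcoxon rank-sum test, correct p-values with
Benjamini-Hochberg, and report the generalized fold change (gFC) — the
mean difference of log10 group quantiles — as the effect size.  A taxon is
called significant when q < alpha and |gFC| exceeds the effect-size floor
(defaults: 5% FDR and |gFC| > 1, i.e. at least a tenfold shift).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_QUANTILES = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))
DEFAULT_PSEUDO = 1e-5


@dataclasses.dataclass(frozen=True)
class DAResult:
    """Per-taxon differential-abundance call."""

    taxon: str
    gfc: float  # log10 units; positive = higher in group B
    p: float
    q: float
    significant: bool


def abundance_filter(profiles: pd.DataFrame, threshold: float = 0.001) -> list[str]:
    """Taxa whose maximum relative abundance over samples exceeds `threshold`.

    `profiles` is samples x taxa.  The boundary is strict: a taxon peaking
    exactly at the threshold is dropped.
    """
    if profiles.empty:
        raise ValueError("empty profile table")
    keep = profiles.max(axis=0) > threshold
    return [t for t in profiles.columns if keep[t]]


def _two_groups(design: pd.Series) -> tuple[str, str]:
    groups = sorted(design.unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    return groups[0], groups[1]


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values: q_(i) = min_{j>=i} p_(j) * m / j."""
    _rej, qvals, _a, _b = multipletests(pvals, method="fdr_bh")
    return qvals


def wilcoxon_bh(
    profiles: pd.DataFrame,
    design: pd.Series,
    alpha: float = 0.05,
    exact_max_n: int = 25,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per taxon with Benjamini-Hochberg q-values.

    The exact null distribution is used when both groups have at most
    `exact_max_n` samples and the taxon has no tied values; otherwise the
    normal approximation with continuity and tie correction.  Returns a
    DataFrame indexed by taxon with columns p and q.
    """
    ga, gb = _two_groups(design)
    a_samples = design.index[design == ga]
    b_samples = design.index[design == gb]
    if len(a_samples) < 3 or len(b_samples) < 3:
        raise ValueError("need at least 3 samples per group")
    pvals = []
    for taxon in profiles.columns:
        xa = profiles.loc[a_samples, taxon].to_numpy()
        xb = profiles.loc[b_samples, taxon].to_numpy()
        no_ties = len(np.unique(np.concatenate([xa, xb]))) == len(xa) + len(xb)
        if no_ties and max(len(xa), len(xb)) <= exact_max_n:
            method = "exact"
        else:
            method = "asymptotic"
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        pvals.append(res.pvalue)
    _rej, qvals, _a, _b = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return pd.DataFrame({"p": pvals, "q": qvals}, index=profiles.columns)


def generalized_fold_change(
    group_a: Sequence[float],
    group_b: Sequence[float],
    quantiles: Sequence[float] = DEFAULT_QUANTILES,
    pseudo: float = DEFAULT_PSEUDO,
) -> float:
    """Generalized fold change: mean log10 quantile difference (B - A).

    gFC = mean over the quantile grid q of
    log10(Q_q(B) + pseudo) - log10(Q_q(A) + pseudo), with linear (type-7)
    quantile interpolation.  A group whose abundances are exactly ten times
    the other's has gFC = 1 when the pseudo-count is negligible; the
    measure is antisymmetric under group swap.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    qa = np.quantile(a, quantiles, method="linear")
    qb = np.quantile(b, quantiles, method="linear")
    return float(np.mean(np.log10(qb + pseudo) - np.log10(qa + pseudo)))


def run_da(
    profiles: pd.DataFrame,
    design: pd.Series,
    alpha: float = 0.05,
    gfc_min: float = 1.0,
    abundance_threshold: float = 0.001,
    quantiles: Sequence[float] = DEFAULT_QUANTILES,
    pseudo: float = DEFAULT_PSEUDO,
) -> list[DAResult]:
    """Full workflow: abundance filter -> Wilcoxon -> BH -> gFC.

    `profiles` is samples x taxa relative abundances; `design` maps sample
    to one of two group labels (gFC is positive when the taxon is higher in
    the lexicographically larger group).  Significant means q < alpha and
    |gFC| > gfc_min.  Deterministic given the input.
    """
    missing = set(profiles.index) - set(design.index)
    if missing:
        raise ValueError(f"samples without a group label: {sorted(missing)}")
    kept = abundance_filter(profiles, abundance_threshold)
    if not kept:
        return []
    sub = profiles[kept]
    tests = wilcoxon_bh(sub, design.loc[profiles.index], alpha=alpha)
    ga, gb = _two_groups(design)
    a_samples = design.index[design == ga]
    b_samples = design.index[design == gb]
    results = []
    for taxon in kept:
        gfc = generalized_fold_change(
            sub.loc[a_samples, taxon], sub.loc[b_samples, taxon],
            quantiles=quantiles, pseudo=pseudo,
        )
        p = float(tests.loc[taxon, "p"])
        q = float(tests.loc[taxon, "q"])
        results.append(
            DAResult(
                taxon=taxon,
                gfc=gfc,
                p=p,
                q=q,
                significant=(q < alpha) and (abs(gfc) > gfc_min),
            )
        )
    return results


def results_to_frame(results: Sequence[DAResult]) -> pd.DataFrame:
    """Tabulate DA results (taxon, gfc, p, q, significant)."""
    return pd.DataFrame(
        [(r.taxon, r.gfc, r.p, r.q, r.significant) for r in results],
        columns=["taxon", "gfc", "p", "q", "significant"],
    )
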