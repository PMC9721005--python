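"""Pairwise alignment helpers shared across the package.

Identity is defined as matches / alignment columns of a global alignment,
where columns include internal gaps.  This definition must be pinned: all
identity cutoffs in the database (species boundary, prefilter, report floor)
are interpreted against it.
"""

from __future__ import annotations

import edlib

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _columns_from_cigar(cigar: str) -> int:
    """Total alignment columns (M + I + D) encoded in an edlib cigar."""
    cols = 0
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            cols += num
            num = 0
    return cols


def global_identity(a: str, b: str) -> float:
    """Global (Needleman-Wunsch) alignment identity between two sequences.

    Returns matches / alignment columns in [0, 1].  With unit edit costs,
    matches = columns - edit_distance, since every substitution, insertion
    or deletion consumes exactly one non-matching column.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    res = edlib.align(a, b, mode="NW", task="path")
    cols = _columns_from_cigar(res["cigar"])
    return 1.0 - res["editDistance"] / cols


def global_identity_both_strands(a: str, b: str) -> float:
    """Best global identity of `a` or its reverse complement against `b`."""
    fwd = global_identity(a, b)
    if fwd == 1.0:
        return fwd
    return max(fwd, global_identity(revcomp(a), b))


def infix_alignment(query: str, target: str) -> tuple[float, int]:
    """Best semi-global alignment of `query` inside `target`.

    The query aligns end-to-end while the target may be clipped on either
    side (edlib "HW" mode) — the natural mode for placing a short sequencing
    insert on a full-length marker gene.  Returns (identity, aligned_length)
    where aligned_length counts alignment columns.
    """
    if len(query) > len(target):
        # swap so the shorter sequence is the infix query
        query, target = target, query
    res = edlib.align(query, target, mode="HW", task="path")
    cols = _columns_from_cigar(res["cigar"])
    return 1.0 - res["editDistance"] / cols, cols


def infix_identity_both_strands(query: str, target: str) -> tuple[float, int]:
    """Best infix identity of `query` on either strand of `target`."""
    fwd = infix_alignment(query, target)
    if fwd[0] == 1.0:
        return fwd
    rev = infix_alignment(revcomp(query), target)
    return fwd if fwd >= rev else rev
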