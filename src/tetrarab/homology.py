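"""Pairwise alignment, percent identity, and reciprocal-best-hit orthology.

Protein-vs-protein affine-gap alignment (BLOSUM62, open 11 / extend 1 by
default, i.e. a gap of length L costs 11 + L) provides the scoring behind a
reciprocal-best-hit (RBH) orthology screen: two sequences, one per set, are
called orthologs when each is the unique top-scoring hit of the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices


class DuplicateIdError(ValueError):
    """Duplicate sequence identifiers within one input set."""


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    aligned_a: str
    aligned_b: str
    mode: str  # "local" | "global"


@dataclass(frozen=True)
class RbhPair:
    id_a: str
    id_b: str
    score_ab: float
    score_ba: float


def _make_aligner(
    mode: str,
    substitution_matrix: str | object = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> Align.PairwiseAligner:
    if mode not in ("local", "global"):
        raise ValueError("mode must be 'local' or 'global'")
    if gap_open < 0 or gap_extend < 0:
        raise ValueError("gap penalties must be >= 0")
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if isinstance(substitution_matrix, str):
        substitution_matrix = substitution_matrices.load(substitution_matrix)
    aligner.substitution_matrix = substitution_matrix
    # first gap position costs open+extend, each further position extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_pair(
    a: str,
    b: str,
    mode: str = "global",
    substitution_matrix: str | object = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal affine-gap alignment of two protein sequences.

    Local mode is Smith–Waterman-like (score floored at 0, possibly empty
    alignment); global is Needleman–Wunsch with end gaps penalized.
    """
    if not a or not b:
        raise ValueError("zero-length input sequence")
    aligner = _make_aligner(mode, substitution_matrix, gap_open, gap_extend)
    score = aligner.score(a, b)
    if mode == "local" and score <= 0:
        return AlignmentResult(0.0, "", "", mode)
    aln = next(iter(aligner.align(a, b)))
    return AlignmentResult(float(score), str(aln[0]), str(aln[1]), mode)


def alignment_score(
    a: str,
    b: str,
    mode: str = "local",
    substitution_matrix: str | object = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Alignment score only (cheaper than materializing the alignment)."""
    if not a or not b:
        raise ValueError("zero-length input sequence")
    aligner = _make_aligner(mode, substitution_matrix, gap_open, gap_extend)
    score = float(aligner.score(a, b))
    return max(score, 0.0) if mode == "local" else score


def percent_identity(
    a: str,
    b: str,
    mode: str = "global",
    count_gaps: bool = True,
    **aligner_kwargs,
) -> float:
    """Percent identity over the optimal alignment, in [0, 100].

    With ``count_gaps`` (default) gapped columns enter the denominator;
    otherwise only columns with residues in both rows are counted.
    """
    result = align_pair(a, b, mode=mode, **aligner_kwargs)
    ga, gb = result.aligned_a, result.aligned_b
    if not ga:
        return 0.0
    identical = sum(x == y and x != "-" for x, y in zip(ga, gb))
    if count_gaps:
        denom = sum(not (x == "-" and y == "-") for x, y in zip(ga, gb))
    else:
        denom = sum(x != "-" and y != "-" for x, y in zip(ga, gb))
    return 100.0 * identical / denom if denom else 0.0


def reciprocal_best_hits(
    set_a: Mapping[str, str] | Sequence[tuple[str, str]],
    set_b: Mapping[str, str] | Sequence[tuple[str, str]],
    mode: str = "local",
    exclude_self: bool = False,
    **aligner_kwargs,
) -> list[RbhPair]:
    """Mutual-top-hit pairs between two sequence sets.

    A query whose top score is shared by two or more targets yields no pair
    (ambiguous hits are dropped rather than broken arbitrarily).  With
    ``exclude_self`` a target with the same id as the query is skipped,
    for screens of a set against itself.
    """
    seqs_a = dict(set_a)
    seqs_b = dict(set_b)
    if len(seqs_a) != len(list(set_a)) or len(seqs_b) != len(list(set_b)):
        raise DuplicateIdError("duplicate sequence ids in input")
    if not seqs_a or not seqs_b:
        raise ValueError("both sets must be non-empty")

    scores: dict[tuple[str, str], float] = {}
    for ia, sa in seqs_a.items():
        for ib, sb in seqs_b.items():
            if exclude_self and ia == ib:
                continue
            scores[(ia, ib)] = alignment_score(sa, sb, mode=mode, **aligner_kwargs)

    def unique_top(vals: list[tuple[float, str]]) -> str | None:
        if not vals:
            return None
        best = max(s for s, _ in vals)
        top = [t for s, t in vals if s == best]
        return top[0] if len(top) == 1 else None

    pairs = []
    for ia in seqs_a:
        ib = unique_top([(s, b) for (a, b), s in scores.items() if a == ia])
        if ib is None:
            continue
        back = unique_top([(s, a) for (a, b), s in scores.items() if b == ib])
        if back == ia:
            s = scores[(ia, ib)]
            pairs.append(RbhPair(ia, ib, s, s))
    return pairs
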