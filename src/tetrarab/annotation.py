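"""Rab / Rab-like / non-Rab annotation from diagnostic sequence motifs.

Rab GTPases carry five short family-diagnostic motifs (RabF-style motifs)
distributed in order along the G domain, and authentic Rabs additionally end
in a C-terminal cysteine arrangement to which geranylgeranyl anchors are
attached.  A sequence that scores like a Rab on the motif set but lacks the
prenylatable C terminus is called *Rab-like*.  Candidate sequences are
discriminated against the other small-GTPase families (Ras, Rho, Arf/Sar,
Ran) by comparing total matched-residue scores over per-family consensus
motif sets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: The five Rab-family diagnostic motifs, in N→C order.
RAB_MOTIFS = ("IGVDF", "KLQIW", "RFRSIT", "YYRGA", "LVYDIT")

#: Consensus motifs for the other small-GTPase families, transcribed from
#: canonical human members (HRAS, RHOA, ARF1, RAN).  Two motifs per family:
#: a family-specific P-loop/effector segment and a switch-II-adjacent one.
OTHER_FAMILY_MOTIFS = {
    "Ras": ("YDPTIED", "EYSAMRD"),
    "Rho": ("DGACGKT", "EDYDRLR"),
    "Arf/Sar": ("GLDAAGKT", "NVETVEY"),
    "Ran": ("GDGGTGKT", "QEKFGGL"),
}

#: Extra named motifs with diagnostic value beyond family assignment.  The
#: WDIAGQE switch-II variant marks a deep clade of lysosome-related-organelle
#: Rabs shared between animals, Dictyostelium and ciliates.
DIAGNOSTIC_MOTIFS = {"WDIAGQE": "WDIAGQE"}

#: C-terminal prenylation patterns, tested in this order (X = any residue).
PRENYL_PATTERNS = ("CC", "CXC", "CCX", "CCXX", "CXXX")


class InvalidAlphabetError(ValueError):
    """Sequence contains characters outside the one-letter amino-acid code."""


class EmptyInputError(ValueError):
    """Empty sequence where a non-empty one is required."""


class TooShortError(ValueError):
    """Sequence too short for the requested operation."""


@dataclass(frozen=True)
class MotifLibrary:
    """Motif sets used for Rab identification and family discrimination."""

    rab_motifs: tuple[str, ...] = RAB_MOTIFS
    other_family_motifs: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(OTHER_FAMILY_MOTIFS)
    )
    diagnostic_motifs: dict[str, str] = field(
        default_factory=lambda: dict(DIAGNOSTIC_MOTIFS)
    )

    def __post_init__(self) -> None:
        if len(self.rab_motifs) != 5:
            raise ValueError("rab_motifs must contain exactly 5 motifs")
        for m in self.rab_motifs:
            if not (4 <= len(m) <= 7):
                raise ValueError(f"Rab motif {m!r} not 4-7 residues")
            _check_alphabet(m)
        for fam, motifs in self.other_family_motifs.items():
            if not motifs:
                raise ValueError(f"family {fam!r} has no motifs")
            for m in motifs:
                _check_alphabet(m)

    @property
    def families(self) -> dict[str, tuple[str, ...]]:
        """All family motif sets including Rab."""
        return {"Rab": self.rab_motifs, **self.other_family_motifs}

    @classmethod
    def from_config(cls, path: str) -> "MotifLibrary":
        """Read a motif library from a family-sectioned plain-text file.

        Format: ``[FamilyName]`` section headers, one motif per line,
        ``#`` comments.  Sections ``Rab`` and ``diagnostic`` are special;
        every other section defines another GTPase family.
        """
        sections: dict[str, list[str]] = {}
        current = None
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if line.startswith("[") and line.endswith("]"):
                    current = line[1:-1].strip()
                    sections.setdefault(current, [])
                elif current is None:
                    raise ValueError("motif before any [section] header")
                else:
                    sections[current].append(line.upper())
        rab = tuple(sections.pop("Rab", RAB_MOTIFS))
        diag = {m: m for m in sections.pop("diagnostic", [])} or dict(
            DIAGNOSTIC_MOTIFS
        )
        other = {fam: tuple(ms) for fam, ms in sections.items()} or dict(
            OTHER_FAMILY_MOTIFS
        )
        return cls(rab_motifs=rab, other_family_motifs=other, diagnostic_motifs=diag)


@dataclass(frozen=True)
class MotifHit:
    """Best ungapped window match of one Rab motif.  Positions are 1-based."""

    motif_index: int  # 1..5
    position: int
    mismatches: int
    score: float  # matched residues / motif length

    def __post_init__(self) -> None:
        if not 0 < self.score <= 1:
            raise ValueError("score must be in (0, 1]")


@dataclass(frozen=True)
class FamilyCall:
    family: str  # Rab | Ras | Rho | Arf/Sar | Ran | unknown
    per_family_score: dict[str, int]
    margin: int
    tie: bool = False


@dataclass(frozen=True)
class PrenylCall:
    pattern: str  # CC | CXC | CCX | CCXX | CXXX | none
    prenylatable: bool

    def __post_init__(self) -> None:
        if self.prenylatable != (self.pattern != "none"):
            raise ValueError("prenylatable must mirror pattern != none")


@dataclass(frozen=True)
class RabClass:
    """Final verdict for one sequence with its full evidence chain."""

    status: str  # Rab | Rab-like | non-Rab
    motif_hits: tuple[MotifHit, ...]
    family_call: FamilyCall
    prenyl_call: PrenylCall


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise InvalidAlphabetError(
            f"non-amino-acid characters: {sorted(bad)!r}"
        )


def _best_window(seq: str, motif: str, start: int = 0) -> tuple[int, int] | None:
    """Best-matching ungapped window of ``motif`` in ``seq[start:]``.

    Returns (0-based position, matched residue count) of the highest-scoring
    window, leftmost on ties; None if no window fits.
    """
    m = len(motif)
    best: tuple[int, int] | None = None
    for i in range(start, len(seq) - m + 1):
        matched = sum(a == b for a, b in zip(seq[i : i + m], motif))
        if best is None or matched > best[1]:
            best = (i, matched)
    return best


def scan_rab_motifs(
    seq: str,
    library: MotifLibrary | None = None,
    max_mismatch: int = 2,
    ordered: bool = True,
) -> list[MotifHit]:
    """Locate the five Rab motifs in a protein sequence.

    For each motif the best-scoring ungapped window with at most
    ``max_mismatch`` mismatches is reported.  With ``ordered`` (default) the
    motifs must occur at strictly increasing positions, mirroring their fixed
    order along the G domain: motif *i* is searched only downstream of the
    reported motif *i-1*.
    """
    if not seq:
        raise EmptyInputError("empty protein sequence")
    _check_alphabet(seq)
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    library = library or MotifLibrary()
    hits: list[MotifHit] = []
    search_from = 0
    for idx, motif in enumerate(library.rab_motifs, start=1):
        best = _best_window(seq, motif, start=search_from if ordered else 0)
        if best is None:
            continue
        pos, matched = best
        mism = len(motif) - matched
        if mism > max_mismatch:
            continue
        hits.append(
            MotifHit(
                motif_index=idx,
                position=pos + 1,
                mismatches=mism,
                score=matched / len(motif),
            )
        )
        if ordered:
            search_from = pos + 1
    return hits


def classify_gtpase_family(
    seq: str,
    library: MotifLibrary | None = None,
    max_mismatch: int = 2,
    score_floor_fraction: float = 0.4,
) -> FamilyCall:
    """Assign a small-GTPase family by total matched-residue score.

    Each family's score is the sum, over its motifs, of the matched residue
    count of the best ungapped window.  The winning family must reach
    ``score_floor_fraction`` of its maximum possible score and strictly beat
    the runner-up (tie tolerance 0); otherwise the call is ``unknown``.
    """
    if not seq:
        raise EmptyInputError("empty protein sequence")
    _check_alphabet(seq)
    library = library or MotifLibrary()
    scores: dict[str, int] = {}
    floors: dict[str, float] = {}
    for fam, motifs in library.families.items():
        total = 0
        for motif in motifs:
            best = _best_window(seq, motif)
            if best is not None:
                total += best[1]
        scores[fam] = total
        floors[fam] = score_floor_fraction * sum(len(m) for m in motifs)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    best_fam, best_score = ranked[0]
    second_score = ranked[1][1] if len(ranked) > 1 else 0
    margin = best_score - second_score
    tie = margin == 0
    if best_score < floors[best_fam] or tie:
        return FamilyCall("unknown", scores, margin, tie=tie)
    return FamilyCall(best_fam, scores, margin)


def classify_prenylation(seq: str) -> PrenylCall:
    """Test the last four residues against the prenylation pattern set.

    Patterns are anchored at the C terminus and tried in the order
    CC, CXC, CCX, CCXX, CXXX; the first match wins.
    """
    if len(seq) < 4:
        raise TooShortError("need at least 4 residues for the prenylation test")
    tail = seq[-4:]
    for pattern in PRENYL_PATTERNS:
        window = tail[-len(pattern):]
        if all(p == "X" or p == c for p, c in zip(pattern, window)):
            return PrenylCall(pattern, True)
    return PrenylCall("none", False)


def call_rab_status(
    seq: str,
    library: MotifLibrary | None = None,
    max_mismatch: int = 2,
    min_motifs: int = 3,
) -> RabClass:
    """Full annotation verdict: Rab, Rab-like, or non-Rab.

    Rab: Rab-family call, at least ``min_motifs`` of the five motifs present,
    and a prenylatable C terminus.  Rab-like: same but no prenylation motif.
    Everything else: non-Rab.
    """
    if not 1 <= min_motifs <= 5:
        raise ValueError("min_motifs must be in 1..5")
    library = library or MotifLibrary()
    family = classify_gtpase_family(seq, library, max_mismatch)
    hits = tuple(scan_rab_motifs(seq, library, max_mismatch))
    prenyl = classify_prenylation(seq)
    if family.family != "Rab" or len(hits) < min_motifs:
        status = "non-Rab"
    elif prenyl.prenylatable:
        status = "Rab"
    else:
        status = "Rab-like"
    return RabClass(status, hits, family, prenyl)


def detect_diagnostic_motif(
    seq: str, motif_name: str, library: MotifLibrary | None = None
) -> list[int]:
    """All exact occurrences (1-based positions) of a named diagnostic motif."""
    library = library or MotifLibrary()
    if motif_name not in library.diagnostic_motifs:
        raise KeyError(f"unknown diagnostic motif {motif_name!r}")
    motif = library.diagnostic_motifs[motif_name]
    positions = []
    start = seq.find(motif)
    while start != -1:
        positions.append(start + 1)
        start = seq.find(motif, start + 1)
    return positions


def annotate_fasta(
    records: Iterable[tuple[str, str]],
    library: MotifLibrary | None = None,
    max_mismatch: int = 2,
    min_motifs: int = 3,
) -> list[dict]:
    """Annotate (id, protein) pairs; one report row per sequence."""
    library = library or MotifLibrary()
    rows = []
    for seq_id, seq in records:
        call = call_rab_status(seq, library, max_mismatch, min_motifs)
        rows.append(
            {
                "id": seq_id,
                "family": call.family_call.family,
                "n_motifs": len(call.motif_hits),
                "prenyl_pattern": call.prenyl_call.pattern,
                "status": call.status,
            }
        )
    return rows


def write_annotation_tsv(rows: Sequence[dict], path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=["id", "family", "n_motifs", "prenyl_pattern", "status"],
            delimiter="\t",
        )
        writer.writeheader()
        writer.writerows(rows)
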