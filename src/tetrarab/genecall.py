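"""ORF prediction under the ciliate nuclear genetic code.

Tetrahymena uses a variant nuclear code in which UAA and UAG encode
glutamine and UGA is the only stop codon.  Rab gene models are therefore
called by translating the mRNA in all three forward frames, finding the
frame that carries the ordered Rab motifs, taking the nearest in-frame ATG
at or upstream of the first motif as the start, and the first in-frame TGA
downstream of the last motif as the stop.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import MotifLibrary, scan_rab_motifs

NT_ALPHABET = frozenset("ACGT")

# Standard-code amino acids for the 64 codons in TTT..GGG lexicographic
# order over (T, C, A, G) — the conventional codon-table layout.
_STANDARD_AAS = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
_BASES = "TCAG"


def _build_ciliate_code() -> dict[str, str]:
    code = {}
    i = 0
    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                code[b1 + b2 + b3] = _STANDARD_AAS[i]
                i += 1
    # ciliate nuclear reassignments: UAA/UAG -> Gln; UGA remains the sole stop
    code["TAA"] = "Q"
    code["TAG"] = "Q"
    return code


#: Codon → amino acid under the ciliate nuclear code ("*" = stop, TGA only).
CILIATE_CODE: dict[str, str] = _build_ciliate_code()

#: Amino acid → synonymous ciliate-code codons (stop excluded).
CILIATE_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CILIATE_CODE.items()):
    if _aa != "*":
        CILIATE_CODONS.setdefault(_aa, ())
        CILIATE_CODONS[_aa] = CILIATE_CODONS[_aa] + (_codon,)


class InvalidNucleotideError(ValueError):
    """Characters outside {A, C, G, T, U}."""


class NoOrfError(ValueError):
    """No reading frame contains a Rab motif hit."""


class MissingStartError(ValueError):
    """No in-frame ATG at or upstream of the first motif."""


class MissingStopError(ValueError):
    """No in-frame TGA downstream of the last motif."""


class PrematureStopError(ValueError):
    """In-frame TGA between the first and last motif hits."""


@dataclass(frozen=True)
class OrfCall:
    """Predicted gene model.  Coordinates are 1-based nucleotide positions;
    ``stop`` points at the first base of the TGA stop codon."""

    frame: int
    start: int
    stop: int
    peptide: str

    def __post_init__(self) -> None:
        if (self.stop - self.start) % 3 != 0:
            raise ValueError("start and stop not in the same frame")
        if "*" in self.peptide:
            raise ValueError("peptide contains a stop character")


def _clean(na: str) -> str:
    na = na.upper().replace("U", "T")
    bad = set(na) - NT_ALPHABET
    if bad:
        raise InvalidNucleotideError(f"invalid nucleotides: {sorted(bad)!r}")
    return na


def translate_ciliate(na: str, frame: int = 1, to_first_stop: bool = False) -> str:
    """Translate under the ciliate nuclear code (TAA/TAG → Q, TGA = stop).

    ``frame`` is 1-based; a trailing partial codon is ignored.  With
    ``to_first_stop`` translation ends at the first TGA; otherwise TGA is
    rendered as ``*``.
    """
    if frame not in (1, 2, 3):
        raise ValueError("frame must be 1, 2 or 3")
    na = _clean(na)
    out = []
    for i in range(frame - 1, len(na) - 2, 3):
        aa = CILIATE_CODE[na[i : i + 3]]
        if aa == "*" and to_first_stop:
            break
        out.append(aa)
    return "".join(out)


def predict_orf(
    mrna: str,
    library: MotifLibrary | None = None,
    max_mismatch: int = 2,
    max_start_distance: int | None = None,
    on_internal_stop: str = "error",
) -> OrfCall:
    """Call the Rab ORF on an mRNA (frame, start ATG, stop TGA, peptide).

    The frame is the one whose ciliate-code translation carries the most
    ordered Rab-motif hits (lowest frame wins ties).  The start is the
    nearest in-frame ATG at or upstream of the first motif hit, optionally
    capped at ``max_start_distance`` nucleotides upstream; the stop is the
    first in-frame TGA after the last motif hit.  A TGA between motifs
    raises :class:`PrematureStopError` (``on_internal_stop="truncate"``
    instead ends the model at that TGA).
    """
    mrna = _clean(mrna)
    if len(mrna) < 60:
        raise ValueError("mRNA shorter than 60 nt")
    if on_internal_stop not in ("error", "truncate"):
        raise ValueError("on_internal_stop must be 'error' or 'truncate'")
    library = library or MotifLibrary()

    best_frame, best_hits = None, []
    for frame in (1, 2, 3):
        pep = translate_ciliate(mrna, frame)
        # motif scan tolerates '*' positions as plain mismatches
        hits = scan_rab_motifs(pep.replace("*", "A") if "*" in pep else pep,
                               library, max_mismatch) if pep else []
        if hits and len(hits) > len(best_hits):
            best_frame, best_hits = frame, hits
    if best_frame is None:
        raise NoOrfError("no reading frame carries a Rab motif")

    pep = translate_ciliate(mrna, best_frame)
    # nucleotide offset (0-based) of amino acid j in this frame
    def nt_of(aa_pos_1based: int) -> int:
        return (best_frame - 1) + 3 * (aa_pos_1based - 1)

    first_nt = nt_of(best_hits[0].position)
    last_motif = library.rab_motifs[best_hits[-1].motif_index - 1]
    last_hit_end_aa = best_hits[-1].position + len(last_motif)  # 1-based, past end
    start_nt = None
    for i in range(first_nt, (best_frame - 1) - 1, -3):
        if mrna[i : i + 3] == "ATG":
            start_nt = i
            break
        if max_start_distance is not None and first_nt - i > max_start_distance:
            break
    if start_nt is None:
        raise MissingStartError("no in-frame ATG upstream of the first motif")

    stop_nt = None
    for i in range(nt_of(last_hit_end_aa), len(mrna) - 2, 3):
        if mrna[i : i + 3] == "TGA":
            stop_nt = i
            break
    if stop_nt is None:
        raise MissingStopError("no in-frame TGA downstream of the last motif")

    peptide = translate_ciliate(mrna[start_nt:stop_nt], 1)
    if "*" in peptide:
        if on_internal_stop == "error":
            raise PrematureStopError(
                "in-frame TGA inside the motif-bearing region"
            )
        cut = peptide.index("*")
        stop_nt = start_nt + 3 * cut
        peptide = peptide[:cut]
    return OrfCall(
        frame=best_frame, start=start_nt + 1, stop=stop_nt + 1, peptide=peptide
    )
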