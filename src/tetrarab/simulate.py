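"""Seeded generators for synthetic inputs with known ground truth.

Every generator is a pure function of (seed, parameters) and returns,
alongside its data, a :class:`SimTruth` record carrying the planted ground
truth, so the annotation, gene-calling, phylogenetic, expression and
colocalization modules can be exercised end to end with no external data.

Deliberate simplifications (documented in the methods note): amino-acid
evolution uses a uniform-replacement (Jukes–Cantor-like) model rather than
an empirical matrix; back-translation draws uniformly among synonymous
ciliate-code codons; expression noise is iid multiplicative log-normal;
puncta are isotropic Gaussians of equal amplitude.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np

from .annotation import OTHER_FAMILY_MOTIFS, MotifLibrary
from .expression import STAGES, ExpressionProfile
from .genecall import CILIATE_CODONS
from .phylo import MsAlignment, read_newick

_AA = "ACDEFGHIKLMNPQRSTVWY"
# linker residues exclude M (would create decoy in-frame starts) and C
# (would create decoy prenylation signals near the C terminus)
_LINKER_AA = "".join(a for a in _AA if a not in "MC")
_NT = "ACGT"


@dataclass
class SimTruth:
    """Serializable ground-truth sidecar for one simulated dataset."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(
            {"kind": self.kind, "seed": self.seed, "params": self.params,
             "truth": self.truth},
            indent=2, sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "SimTruth":
        if source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(**obj)


def _random_aa(rng: np.random.Generator, n: int, alphabet: str = _AA) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _mutate_motif(rng: np.random.Generator, motif: str, n_sub: int) -> str:
    if n_sub <= 0:
        return motif
    n_sub = min(n_sub, len(motif))
    positions = rng.choice(len(motif), size=n_sub, replace=False)
    chars = list(motif)
    for p in positions:
        choices = [a for a in _AA if a != chars[p]]
        chars[p] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = []
    for aa in protein:
        options = CILIATE_CODONS[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def rab_scaffold_protein(
    rng: np.random.Generator,
    library: MotifLibrary | None = None,
    mutations_per_motif: int = 0,
    tail_length: int = 30,
    terminal: str = "SNCC",
) -> tuple[str, list[int]]:
    """A protein carrying the five ordered Rab motifs on random linkers.

    Returns the sequence and the 1-based start positions of the motifs.
    """
    library = library or MotifLibrary()
    parts = ["M", _random_aa(rng, 8, _LINKER_AA)]
    positions = []
    for motif in library.rab_motifs:
        positions.append(sum(len(p) for p in parts) + 1)
        parts.append(_mutate_motif(rng, motif, mutations_per_motif))
        parts.append(_random_aa(rng, 10, _LINKER_AA))
    if tail_length > 4:
        parts.append(_random_aa(rng, tail_length - 4, _LINKER_AA))
    parts.append(terminal)
    return "".join(parts), positions


def simulate_rab_gene(
    seed: int,
    class_label: str = "Rab",
    mutations_per_motif: int = 0,
    tail_pattern: str | None = None,
    library: MotifLibrary | None = None,
) -> tuple[str, str, SimTruth]:
    """One synthetic Rab/Rab-like/non-Rab coding gene with UTRs.

    Returns (mRNA, protein, truth).  The mRNA is the ciliate-code
    back-translation of the protein flanked by random UTRs, ending in the
    sole ciliate stop codon TGA; the reading frame is set by the random
    5' UTR length.  Rab and Rab-like proteins carry the five ordered Rab
    motifs (mutated as requested); non-Rab proteins carry Ras motifs
    instead.  The C terminus follows the class: prenylatable for Rab,
    cysteine-free for Rab-like.
    """
    if class_label not in ("Rab", "Rab-like", "non-Rab"):
        raise ValueError(f"invalid class label {class_label!r}")
    rng = np.random.default_rng(seed)
    library = library or MotifLibrary()

    from .annotation import classify_prenylation

    if class_label == "Rab":
        terminal = tail_pattern if tail_pattern is not None else "SNCC"
        if not classify_prenylation(("AAAA" + terminal)[-4:]).prenylatable:
            raise ValueError(
                "contradictory parameters: Rab with non-prenylatable tail"
            )
    elif class_label == "Rab-like":
        terminal = tail_pattern if tail_pattern is not None else "AKSQ"
        if classify_prenylation(("AAAA" + terminal)[-4:]).prenylatable:
            raise ValueError(
                "contradictory parameters: Rab-like with prenylatable tail"
            )
    else:
        terminal = tail_pattern if tail_pattern is not None else "AKSQ"

    if class_label in ("Rab", "Rab-like"):
        protein, motif_pos = rab_scaffold_protein(
            rng, library, mutations_per_motif, terminal=terminal
        )
    else:
        ras = OTHER_FAMILY_MOTIFS["Ras"]
        parts = ["M", _random_aa(rng, 8, _LINKER_AA)]
        motif_pos = []
        for motif in ras:
            motif_pos.append(sum(len(p) for p in parts) + 1)
            parts.append(motif)
            parts.append(_random_aa(rng, 20, _LINKER_AA))
        parts.append(_random_aa(rng, 26, _LINKER_AA))
        parts.append(terminal)
        protein = "".join(parts)

    utr5 = _random_aa(rng, int(rng.integers(10, 41)), _NT)
    utr3 = _random_aa(rng, int(rng.integers(10, 41)), _NT)
    cds = _back_translate(rng, protein)
    mrna = utr5 + cds + "TGA" + utr3
    truth = SimTruth(
        kind="rab_gene",
        seed=seed,
        params={
            "class_label": class_label,
            "mutations_per_motif": mutations_per_motif,
            "tail_pattern": terminal,
        },
        truth={
            "frame": len(utr5) % 3 + 1,
            "start": len(utr5) + 1,
            "stop": len(utr5) + len(cds) + 1,
            "protein": protein,
            "motif_positions": motif_pos,
        },
    )
    return mrna, protein, truth


def simulate_family(
    tree: dendropy.Tree | str,
    rate: float = 1.0,
    seed: int = 0,
    root_seq: str | None = None,
    seq_length: int = 150,
    tail_length: int = 0,
) -> tuple[MsAlignment, SimTruth]:
    """Evolve a protein family along a tree by independent-site substitution.

    Each site on a branch of length *b* is replaced with probability
    1 - exp(-rate·b) by a uniformly chosen different residue.  Optional
    per-leaf hypervariable tails of iid residues are appended (uncorrelated
    across leaves), emulating the Rab C terminus.  The emitted alignment is
    gapless.
    """
    if isinstance(tree, str):
        tree = read_newick(tree)
    leaves = [l for l in tree.leaf_node_iter()]
    if not leaves or any(l.taxon is None for l in leaves):
        raise ValueError("tree has no labeled leaves")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    if root_seq is None:
        root_seq = _random_aa(rng, seq_length)

    seqs: dict[int, str] = {id(tree.seed_node): root_seq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        b = node.edge.length or 0.0
        p_sub = 1.0 - math.exp(-rate * b)
        chars = list(parent_seq)
        hit = rng.random(len(chars)) < p_sub
        for i in np.flatnonzero(hit):
            choices = [a for a in _AA if a != chars[i]]
            chars[i] = choices[rng.integers(len(choices))]
        seqs[id(node)] = "".join(chars)

    ids, rows = [], []
    for leaf in leaves:
        ids.append(leaf.taxon.label)
        row = seqs[id(leaf)]
        if tail_length:
            row += _random_aa(rng, tail_length)
        rows.append(row)
    truth = SimTruth(
        kind="family",
        seed=seed,
        params={
            "rate": rate,
            "seq_length": len(root_seq),
            "tail_length": tail_length,
        },
        truth={"newick": tree.as_string(schema="newick").strip()},
    )
    return MsAlignment(ids, rows), truth


def simulate_expression(
    n_genes: int,
    planted_peaks: Mapping[int, tuple[str, float]] | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
    baseline: float = 1000.0,
) -> tuple[list[ExpressionProfile], SimTruth]:
    """Synthetic 20-stage expression cohort with planted discrete peaks.

    ``planted_peaks`` maps gene index -> (stage label, fold > 1): that
    gene's signal is ``baseline`` everywhere and ``fold × baseline`` at the
    peak stage.  All measurements are multiplied by iid log-normal noise of
    the given coefficient of variation (mean 1).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    planted = dict(planted_peaks or {})
    for idx, (stage, fold) in planted.items():
        if stage not in STAGES:
            raise ValueError(f"invalid stage label {stage!r}")
        if fold <= 1:
            raise ValueError("peak folds must be > 1")
        if not 0 <= idx < n_genes:
            raise ValueError(f"gene index {idx} out of range")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0
    profiles = []
    for g in range(n_genes):
        gene_id = f"gene{g:04d}"
        signal = {s: baseline for s in STAGES}
        if g in planted:
            stage, fold = planted[g]
            signal[stage] = fold * baseline
        if sigma > 0:
            noise = rng.lognormal(-0.5 * sigma**2, sigma, size=len(STAGES))
        else:
            noise = np.ones(len(STAGES))
        values = {s: float(signal[s] * noise[k]) for k, s in enumerate(STAGES)}
        profiles.append(ExpressionProfile(gene_id, values))
    truth = SimTruth(
        kind="expression",
        seed=seed,
        params={"n_genes": n_genes, "noise_cv": noise_cv, "baseline": baseline},
        truth={
            "planted_peaks": {
                f"gene{g:04d}": [stage, fold] for g, (stage, fold) in planted.items()
            }
        },
    )
    return profiles, truth


def simulate_coloc_image(
    shape: tuple[int, int] = (96, 96),
    n_green: int = 8,
    n_red: int = 8,
    coloc_fraction: float = 0.5,
    psf_sigma: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 100.0,
) -> tuple[np.ndarray, np.ndarray, SimTruth]:
    """Two-channel punctum image pair with a known colocalized fraction.

    ``round(coloc_fraction × n_green)`` green puncta share centers with red
    puncta; all remaining puncta get their own well-separated centers.
    Puncta are isotropic Gaussians of equal amplitude at integer pixel
    centers (so every punctum has an identical above-threshold footprint);
    optional additive Gaussian noise is clipped at zero.
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValueError("coloc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_shared = int(round(coloc_fraction * n_green))
    n_centers = n_green + n_red - n_shared
    margin = int(math.ceil(4 * psf_sigma))
    min_sep = 6 * psf_sigma
    h, w = shape
    if h <= 2 * margin or w <= 2 * margin:
        raise ValueError("image too small for the point-spread margin")

    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < n_centers:
        attempts += 1
        if attempts > 10000 * n_centers:
            raise ValueError("more puncta than can be placed in the image")
        y = int(rng.integers(margin, h - margin))
        x = int(rng.integers(margin, w - margin))
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_sep**2 for cy, cx in centers):
            centers.append((y, x))

    shared = centers[:n_shared]
    green_only = centers[n_shared : n_green]
    red_only = centers[n_green:]

    yy, xx = np.mgrid[0:h, 0:w]

    def render(pts: list[tuple[int, int]]) -> np.ndarray:
        img = np.zeros(shape)
        for cy, cx in pts:
            img += amplitude * np.exp(
                -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * psf_sigma**2)
            )
        return img

    green = render(shared + green_only)
    red = render(shared + red_only)
    if noise_sd > 0:
        green = np.clip(green + rng.normal(0, noise_sd, shape), 0, None)
        red = np.clip(red + rng.normal(0, noise_sd, shape), 0, None)
    truth = SimTruth(
        kind="coloc_image",
        seed=seed,
        params={
            "shape": list(shape), "n_green": n_green, "n_red": n_red,
            "coloc_fraction": coloc_fraction, "psf_sigma": psf_sigma,
            "noise_sd": noise_sd, "amplitude": amplitude,
        },
        truth={
            "n_shared": n_shared,
            "shared": [list(c) for c in shared],
            "green_only": [list(c) for c in green_only],
            "red_only": [list(c) for c in red_only],
        },
    )
    return green, red, truth
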