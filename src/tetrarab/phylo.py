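"""Distance-based phylogenetics and multi-method conservation classification.

The workflow mirrors how protein-family trees are built for deep
divergences: trim the hypervariable C terminus and all gapped columns from
a multiple alignment, compute p- or Poisson-corrected distances with
pairwise deletion, build a neighbor-joining tree, attach bootstrap supports
by column resampling, and combine trees from several inference methods
(externally computed maximum-likelihood or Bayesian trees enter as Newick)
into per-gene conservation calls:

* conserved — in at least ``conserved_quorum`` (default 2) of the method
  trees, the smallest supported clade containing the query also contains a
  non-ciliate reference;
* lineage-restricted — in every method tree that clade contains only
  ciliate sequences;
* divergent — neither condition holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio import AlignIO, SeqIO

from .annotation import AA_ALPHABET, MotifLibrary, scan_rab_motifs


class AlignmentTooShortError(ValueError):
    """Trimming left fewer than the minimum number of columns."""


class InfiniteDistanceError(ValueError):
    """Poisson correction undefined (p-distance >= 1)."""


# ---------------------------------------------------------------------------
# alignments


@dataclass
class MsAlignment:
    """A protein multiple alignment: ordered (id, gapped row) records."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        for row in self.rows:
            bad = set(row) - AA_ALPHABET - {"-"}
            if bad:
                raise ValueError(f"invalid alignment characters {sorted(bad)!r}")

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    @classmethod
    def from_fasta(cls, path: str) -> "MsAlignment":
        recs = list(SeqIO.parse(path, "fasta"))
        return cls([r.id for r in recs], [str(r.seq).upper() for r in recs])

    @classmethod
    def from_phylip(cls, path: str) -> "MsAlignment":
        aln = AlignIO.read(path, "phylip-relaxed")
        return cls([r.id for r in aln], [str(r.seq).upper() for r in aln])

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")

    def take_columns(self, cols: Sequence[int]) -> "MsAlignment":
        return MsAlignment(
            list(self.ids), ["".join(r[c] for c in cols) for r in self.rows]
        )


@dataclass(frozen=True)
class TrimConfig:
    remove_gap_columns: bool = True
    cterm_trim: int | str = "auto"  # residue count, or "auto"
    max_mismatch: int = 2
    min_columns: int = 10


def _ungapped_to_column(row: str) -> list[int]:
    """Map 0-based ungapped residue index -> alignment column."""
    return [c for c, ch in enumerate(row) if ch != "-"]


def trim_alignment(
    aln: MsAlignment,
    config: TrimConfig | None = None,
    library: MotifLibrary | None = None,
) -> MsAlignment:
    """Remove the C-terminal hypervariable region and gapped columns.

    In ``auto`` mode every column beyond the alignment column of the last
    Rab-motif residue (maximized over rows, so no sequence loses motif
    columns) is dropped; hypervariable tails in Rabs are typically 30-80
    residues.  An integer ``cterm_trim`` instead gaps out that many
    C-terminal residues of every sequence.  Gap-bearing columns are then
    removed entirely.  Idempotent.
    """
    config = config or TrimConfig()
    library = library or MotifLibrary()
    rows = list(aln.rows)

    if config.cterm_trim == "auto":
        cut_col = None
        for row in rows:
            seq = row.replace("-", "")
            if not seq:
                continue
            hits = scan_rab_motifs(seq, library, config.max_mismatch)
            if not hits:
                continue
            motif = library.rab_motifs[hits[-1].motif_index - 1]
            last_res = hits[-1].position + len(motif) - 2  # 0-based last residue
            col = _ungapped_to_column(row)[last_res]
            cut_col = col if cut_col is None else max(cut_col, col)
        if cut_col is not None:
            rows = [r[: cut_col + 1] for r in rows]
    else:
        k = int(config.cterm_trim)
        if k < 0:
            raise ValueError("cterm_trim must be >= 0")
        if k:
            trimmed = []
            for row in rows:
                cols = _ungapped_to_column(row)
                chars = list(row)
                for c in cols[len(cols) - k :]:
                    chars[c] = "-"
                trimmed.append("".join(chars))
            rows = trimmed

    out = MsAlignment(list(aln.ids), rows)
    if config.remove_gap_columns:
        keep = [
            c for c in range(out.ncols) if all(r[c] != "-" for r in out.rows)
        ]
        out = out.take_columns(keep)
    if out.ncols < config.min_columns:
        raise AlignmentTooShortError(
            f"only {out.ncols} columns left after trimming"
        )
    return out


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    model: str = "p"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix not symmetric")
        if (m < 0).any() or np.diag(m).any():
            raise ValueError("distances must be >= 0 with zero diagonal")
        if not np.isfinite(m).all():
            raise ValueError("non-finite distances")
        self.matrix = m

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.ids) + "\n")
            for sid, row in zip(self.ids, self.matrix):
                fh.write(sid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def compute_distances(aln: MsAlignment, model: str = "p") -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gapped sites.

    ``p``: mismatches / compared sites.  ``poisson``: -ln(1 - p).
    """
    if model not in ("p", "poisson"):
        raise ValueError("model must be 'p' or 'poisson'")
    n = len(aln.ids)
    if n < 3:
        raise ValueError("need at least 3 sequences")
    arr = np.array([list(r) for r in aln.rows])
    gap = arr == "-"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            compared = int(ok.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable sites between {aln.ids[i]} and {aln.ids[j]}"
                )
            p = float((arr[i, ok] != arr[j, ok]).sum()) / compared
            if model == "poisson":
                if p >= 1.0:
                    raise InfiniteDistanceError(
                        f"p-distance {p} saturated between "
                        f"{aln.ids[i]} and {aln.ids[j]}"
                    )
                p = -math.log1p(-p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(list(aln.ids), d, model)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of cluster labels (a cluster is labeled by its smallest leaf id).
    Negative branch lengths are clamped to zero.  The result is an unrooted
    tree represented with a trifurcating seed node.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")

    tns = dendropy.TaxonNamespace(sorted(ids))
    nodes: list[dendropy.Node] = []
    for sid in ids:
        node = dendropy.Node(taxon=tns.get_taxon(sid))
        nodes.append(node)
    labels = list(ids)  # cluster label = smallest member id
    d = dm.matrix.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None  # (q, label_pair, i, j)
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair = tuple(sorted((labels[i], labels[j])))
                key = (round(q, 12), pair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(vi, 0.0)
        nodes[j].edge.length = max(vj, 0.0)
        new_d = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d = d2
        new_label = min(labels[i], labels[j])
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [new_label]

    # final three clusters joined at an unrooted trifurcation
    (a, b, c) = range(3)
    va = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    vb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    vc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = dendropy.Node()
    for node, v in zip(nodes, (va, vb, vc)):
        root.add_child(node)
        node.edge.length = max(v, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# splits, bootstrap, consensus


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(l.taxon.label for l in tree.leaf_node_iter())


def _canonical(side: frozenset[str], leaves: frozenset[str]) -> frozenset[str]:
    """Canonical representation of an unrooted split: the side that does not
    contain the alphabetically first leaf."""
    ref = min(leaves)
    return frozenset(leaves - side) if ref in side else side


def tree_splits(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Node]:
    """Nontrivial unrooted splits of a tree, keyed canonically."""
    leaves = leaf_labels(tree)
    n = len(leaves)
    out: dict[frozenset[str], dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(side) < n - 1:
            out[_canonical(side, leaves)] = node
    return out


def node_support(node: dendropy.Node, default: float = 100.0) -> float:
    """Support value of an internal node (label, else ``default``).

    Externally computed trees without support annotations are treated as
    fully supported.
    """
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            pass
    return default


def bootstrap_support(
    aln: MsAlignment,
    model: str = "p",
    n_reps: int = 100,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree with bootstrap supports from column resampling.

    Each replicate resamples alignment columns with replacement, rebuilds
    the NJ tree, and the frequency of each full-data bipartition among
    replicates (as a percentage) is written onto the full-data tree's
    internal node labels.  Deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    full = neighbor_joining(compute_distances(aln, model))
    counts: dict[frozenset[str], int] = {}
    ncols = aln.ncols
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        rep = aln.take_columns(list(cols))
        rep_tree = neighbor_joining(compute_distances(rep, model))
        for split in tree_splits(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    for split, node in tree_splits(full).items():
        pct = 100.0 * counts.get(split, 0) / n_reps
        node.label = f"{pct:g}"
    return full


def majority_consensus(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Majority-rule consensus: splits in >50% of trees, supports = percent.

    All trees must share one leaf set.  Retained splits are mutually
    compatible by the strict-majority rule, so the consensus topology is
    well defined; branch lengths are not assigned.
    """
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    leaves = leaf_labels(trees[0])
    for t in trees[1:]:
        if leaf_labels(t) != leaves:
            raise ValueError("trees have mismatched leaf sets")
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for split in tree_splits(t):
            counts[split] = counts.get(split, 0) + 1
    majority = {
        s: 100.0 * c / len(trees)
        for s, c in counts.items()
        if c / len(trees) > 0.5
    }
    return _tree_from_clades(leaves, majority)


def _tree_from_clades(
    leaves: frozenset[str], clades: Mapping[frozenset[str], float]
) -> dendropy.Tree:
    """Build a tree from a laminar set of clades (canonical split sides).

    The tree is rooted at a node whose children are the reference leaf
    (alphabetically first) and the top-level groups; support percentages
    are written to internal node labels.
    """
    ref = min(leaves)
    tns = dendropy.TaxonNamespace(sorted(leaves))
    root = dendropy.Node()
    ordered = sorted(clades, key=lambda s: (-len(s), sorted(s)))
    clade_nodes: dict[frozenset[str], dendropy.Node] = {}
    for clade in ordered:
        node = dendropy.Node()
        node.label = f"{clades[clade]:g}"
        parent = root
        for other in ordered:  # smallest strict superset seen so far
            if other is not clade and clade < other:
                parent = clade_nodes[other]
        parent.add_child(node)
        clade_nodes[clade] = node
    for leaf in sorted(leaves):
        node = dendropy.Node(taxon=tns.get_taxon(leaf))
        if leaf == ref:
            root.add_child(node)
            continue
        best = None
        for clade in ordered:
            if leaf in clade and (best is None or len(clade) < len(best)):
                best = clade
        (clade_nodes[best] if best is not None else root).add_child(node)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# conservation classification


@dataclass(frozen=True)
class CladeCall:
    query: str
    status: str  # conserved | lineage-restricted | divergent
    supporting_methods: int
    clade_members: tuple[frozenset[str], ...]  # per input tree (None -> empty)


def smallest_supported_clade(
    tree: dendropy.Tree, query: str, support_threshold: float = 50.0
) -> frozenset[str] | None:
    """Smallest supported clade containing the query and >=1 other leaf.

    Clades are subtrees under internal nodes of the tree as rooted for
    display (published method trees are judged on their displayed
    orientation); the root itself carries no support and is excluded.
    Returns None when no internal node containing the query reaches the
    support threshold.
    """
    leaves = leaf_labels(tree)
    if query not in leaves:
        raise ValueError(f"query {query!r} absent from tree")
    best: frozenset[str] | None = None
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if query not in side or len(side) < 2:
            continue
        if node_support(node) < support_threshold:
            continue
        if best is None or len(side) < len(best):
            best = side
    return best


def classify_conservation(
    query_ids: Iterable[str],
    trees: Sequence[dendropy.Tree],
    lineage_map: Mapping[str, str],
    support_threshold: float = 50.0,
    conserved_quorum: int = 2,
    ciliate_tag: str = "ciliate",
) -> list[CladeCall]:
    """Classify each query as conserved, lineage-restricted, or divergent.

    ``trees`` holds one tree per inference method.  ``lineage_map`` assigns
    every leaf a lineage tag; leaves tagged ``ciliate_tag`` count as ciliate.
    """
    if not trees:
        raise ValueError("empty tree list")
    for t in trees:
        missing = leaf_labels(t) - set(lineage_map)
        if missing:
            raise ValueError(f"leaves missing from lineage_map: {sorted(missing)}")
    calls = []
    for query in query_ids:
        clades = [
            smallest_supported_clade(t, query, support_threshold) for t in trees
        ]
        n_conserved = sum(
            1
            for c in clades
            if c is not None
            and any(lineage_map[m] != ciliate_tag for m in c if m != query)
        )
        all_restricted = all(
            c is not None
            and all(lineage_map[m] == ciliate_tag for m in c)
            for c in clades
        )
        if n_conserved >= conserved_quorum:
            status, nsup = "conserved", n_conserved
        elif all_restricted:
            status, nsup = "lineage-restricted", len(trees)
        else:
            status, nsup = "divergent", 0
        calls.append(
            CladeCall(
                query,
                status,
                nsup,
                tuple(c if c is not None else frozenset() for c in clades),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# newick I/O


def read_newick(source: str) -> dendropy.Tree:
    """Read a Newick tree from a path or a literal Newick string."""
    if ";" in source or source.lstrip().startswith("("):
        return dendropy.Tree.get(
            data=source, schema="newick", suppress_internal_node_taxa=True
        )
    return dendropy.Tree.get(
        path=source, schema="newick", suppress_internal_node_taxa=True
    )


def write_newick(tree: dendropy.Tree, path: str | None = None) -> str:
    text = tree.as_string(
        schema="newick", suppress_rooting=True, real_value_format_specifier=".6f"
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
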