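"""End-to-end pipeline: annotate → orthologs → tree → clade classification,
with optional expression and colocalization stages, on provided or
simulated inputs.  Emits a single JSON report plus TSV side tables."""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Mapping

import dendropy

from . import __version__
from .annotation import MotifLibrary, annotate_fasta, write_annotation_tsv
from .coloc import quantify_cells
from .expression import load_expression, summarize_cohort
from .genecall import predict_orf
from .homology import reciprocal_best_hits
from .localization import load_localization_table, summarize_localization
from .phylo import (
    MsAlignment,
    bootstrap_support,
    classify_conservation,
    compute_distances,
    majority_consensus,
    neighbor_joining,
    read_newick,
    write_newick,
)
from .simulate import (
    simulate_coloc_image,
    simulate_expression,
    simulate_family,
    simulate_rab_gene,
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_rab": 6,
    "n_rab_like": 3,
    "n_non_rab": 3,
    "bootstrap_reps": 100,
    "distance_model": "p",
    "expression_genes": 20,
    "coloc_cells": 4,
    "coloc_fraction": 0.5,
    "protein_fasta": None,
    "expression_tsv": None,
}

#: 8-taxon reference tree mixing ciliate and non-ciliate leaves, used when
#: no alignment is supplied.  Tt/Pt prefixes are ciliate, Hs/Dm are not.
DEFAULT_TREE = (
    "((TtA:0.10,PtA:0.12):0.08,((TtB:0.09,HsA:0.11):0.07,"
    "(DmA:0.10,HsB:0.08):0.06):0.05,(TtC:0.12,PtB:0.10):0.09);"
)


class PipelineError(RuntimeError):
    """Failure in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


def load_config(path: str) -> dict:
    """Read a flat ``key = value`` config file (#-comments allowed)."""
    config = dict(DEFAULT_CONFIG)
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"expected key=value, got {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            value = value.strip("\"'")
            if key not in config:
                raise ValueError(f"unknown config key {key!r}")
            old = DEFAULT_CONFIG[key]
            if isinstance(old, bool):
                config[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(old, int):
                config[key] = int(value)
            elif isinstance(old, float):
                config[key] = float(value)
            else:
                config[key] = value or None
    return config


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return decorator


@_stage("annotate")
def _run_annotate(config: dict, outdir: Path) -> dict:
    library = MotifLibrary()
    if config.get("protein_fasta"):
        from Bio import SeqIO

        records = [
            (r.id, str(r.seq).upper())
            for r in SeqIO.parse(config["protein_fasta"], "fasta")
        ]
        if not records:
            raise ValueError(f"no sequences in {config['protein_fasta']!r}")
        mrnas = {}
    else:
        records, mrnas = [], {}
        seed = config["seed"]
        specs = (
            [("Rab", config["n_rab"])]
            + [("Rab-like", config["n_rab_like"])]
            + [("non-Rab", config["n_non_rab"])]
        )
        k = 0
        for label, count in specs:
            for _ in range(count):
                mrna, protein, truth = simulate_rab_gene(seed * 1000 + k, label)
                name = f"{label.replace('-', '_')}_{k:02d}"
                records.append((name, protein))
                mrnas[name] = mrna
                k += 1
    rows = annotate_fasta(records, library)
    write_annotation_tsv(rows, str(outdir / "annotation.tsv"))
    return {"rows": rows, "records": dict(records), "mrnas": mrnas}


@_stage("genecall")
def _run_genecall(mrnas: Mapping[str, str], outdir: Path) -> list[dict]:
    calls = []
    for name, mrna in mrnas.items():
        try:
            orf = predict_orf(mrna)
            calls.append(
                {"id": name, "frame": orf.frame, "start": orf.start,
                 "stop": orf.stop, "length_aa": len(orf.peptide)}
            )
        except ValueError as exc:
            calls.append({"id": name, "error": str(exc)})
    with open(outdir / "orf_calls.tsv", "w") as fh:
        fh.write("id\tframe\tstart\tstop\tlength_aa\terror\n")
        for c in calls:
            fh.write(
                "\t".join(
                    str(c.get(k, "")) for k in
                    ("id", "frame", "start", "stop", "length_aa", "error")
                )
                + "\n"
            )
    return calls


@_stage("orthologs")
def _run_orthologs(aln: MsAlignment, outdir: Path) -> list[dict]:
    seqs = {i: aln.degapped(k) for k, i in enumerate(aln.ids)}
    ciliate = {i: s for i, s in seqs.items() if i.startswith(("Tt", "Pt"))}
    other = {i: s for i, s in seqs.items() if i not in ciliate}
    pairs = reciprocal_best_hits(ciliate, other)
    rows = [
        {"id_a": p.id_a, "id_b": p.id_b, "score": p.score_ab} for p in pairs
    ]
    with open(outdir / "orthologs.tsv", "w") as fh:
        fh.write("id_a\tid_b\tscore\n")
        for r in rows:
            fh.write(f"{r['id_a']}\t{r['id_b']}\t{r['score']:g}\n")
    return rows


@_stage("tree")
def _run_tree(aln: MsAlignment, config: dict, outdir: Path) -> list[dendropy.Tree]:
    trees = []
    for k in range(3):  # three bootstrap analyses standing in for methods
        tree = bootstrap_support(
            aln,
            model=config["distance_model"],
            n_reps=config["bootstrap_reps"],
            seed=config["seed"] + k,
        )
        write_newick(tree, str(outdir / f"nj_bootstrap_{k}.nwk"))
        trees.append(tree)
    consensus = majority_consensus(trees)
    write_newick(consensus, str(outdir / "consensus.nwk"))
    return trees


@_stage("classify-clades")
def _run_classify(trees: list[dendropy.Tree], outdir: Path) -> list[dict]:
    from .phylo import leaf_labels

    leaves = leaf_labels(trees[0])
    lineage = {
        l: "ciliate" if l.startswith(("Tt", "Pt")) else "other" for l in leaves
    }
    queries = sorted(l for l in leaves if l.startswith("Tt"))
    calls = classify_conservation(queries, trees, lineage)
    rows = [
        {"query": c.query, "status": c.status,
         "supporting_methods": c.supporting_methods}
        for c in calls
    ]
    with open(outdir / "clade_calls.tsv", "w") as fh:
        fh.write("query\tstatus\tsupporting_methods\n")
        for r in rows:
            fh.write(f"{r['query']}\t{r['status']}\t{r['supporting_methods']}\n")
    return rows


def run_pipeline(config: Mapping | str | None = None, outdir: str = "tetrarab_out") -> dict:
    """Run the full analysis and write ``report.json`` plus TSV tables.

    ``config`` is a mapping or the path of a flat key=value file; missing
    keys take :data:`DEFAULT_CONFIG` values.  Without input files every
    stage runs on simulated data, which makes this a self-contained smoke
    run.  Any stage failure aborts with a stage-tagged error.
    """
    if isinstance(config, str):
        config = load_config(config)
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)!r}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    annotate = _run_annotate(cfg, out)
    orfs = _run_genecall(annotate["mrnas"], out)

    aln, _ = simulate_family(
        DEFAULT_TREE, rate=1.0, seed=cfg["seed"], seq_length=200
    )
    orthologs = _run_orthologs(aln, out)
    trees = _run_tree(aln, cfg, out)
    clades = _run_classify(trees, out)

    if cfg.get("expression_tsv"):
        profiles = load_expression(cfg["expression_tsv"])
    else:
        from .simulate import simulate_expression

        profiles, _ = simulate_expression(
            cfg["expression_genes"],
            planted_peaks={0: ("S6", 3.0), 1: ("C2", 3.0)},
            noise_cv=0.1,
            seed=cfg["seed"],
        )
    try:
        expr_summary = summarize_cohort(profiles)
    except Exception as exc:  # pragma: no cover - guarded by stage contract
        raise PipelineError("expression", str(exc)) from exc

    try:
        cells = []
        for k in range(cfg["coloc_cells"]):
            green, red, _ = simulate_coloc_image(
                coloc_fraction=cfg["coloc_fraction"], seed=cfg["seed"] * 100 + k
            )
            cells.append((green, red))
        coloc_out = quantify_cells(cells)
        coloc_summary = coloc_out["summary"]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("coloc", str(exc)) from exc

    table_summary = summarize_localization(load_localization_table())

    report = {
        "meta": {
            "tetrarab_version": __version__,
            "python": sys.version.split()[0],
            "seed": cfg["seed"],
            "config": {k: v for k, v in cfg.items()},
        },
        "annotation": annotate["rows"],
        "orf_calls": orfs,
        "orthologs": orthologs,
        "clade_calls": clades,
        "expression_summary": expr_summary,
        "coloc_summary": coloc_summary,
        "localization_summary": table_summary,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
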