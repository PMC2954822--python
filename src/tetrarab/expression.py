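"""Stage-grid expression analysis for the Tetrahymena culture conditions.

Microarray intensities are organized on a fixed 20-stage grid: growth at
three culture densities (Ll exponential, Lm deceleratory, Lh stationary),
seven starvation time points (S0-S24 h) and ten conjugation time points
(C0-C18 h).  The module calls genes expressed above background, finds the
highest-expressing condition, and detects *discrete peaks*: a stage whose
intensity strictly exceeds a fold threshold (default 2) times the largest
other in-condition value.  S0 is excluded by default because it coincides
with the medium change and is hard to interpret.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

GROWTH_STAGES = ("Ll", "Lm", "Lh")
STARVATION_STAGES = ("S0", "S3", "S6", "S9", "S12", "S15", "S24")
CONJUGATION_STAGES = tuple(f"C{h}" for h in range(0, 20, 2))

#: condition name -> ordered stage labels
CONDITIONS: dict[str, tuple[str, ...]] = {
    "growth": GROWTH_STAGES,
    "starvation": STARVATION_STAGES,
    "conjugation": CONJUGATION_STAGES,
}

#: all 20 stage labels in grid order
STAGES: tuple[str, ...] = GROWTH_STAGES + STARVATION_STAGES + CONJUGATION_STAGES


class ExpressionFormatError(ValueError):
    """Malformed expression table (unknown/missing column, bad cell)."""


@dataclass
class ExpressionProfile:
    """Per-gene intensities (arbitrary units) over the 20-stage grid."""

    gene_id: str
    values: dict[str, float]
    flagged: bool = False  # True when some stage was missing in the source

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(STAGES)
        if unknown:
            raise ExpressionFormatError(f"unknown stages {sorted(unknown)!r}")
        missing = [s for s in STAGES if s not in self.values
                   or self.values[s] is None
                   or (isinstance(self.values[s], float) and math.isnan(self.values[s]))]
        if missing:
            self.flagged = True
            for s in missing:
                self.values[s] = float("nan")

    def condition_values(self, condition: str) -> list[float]:
        if condition not in CONDITIONS:
            raise KeyError(f"unknown condition {condition!r}")
        return [self.values[s] for s in CONDITIONS[condition]]


@dataclass(frozen=True)
class PeakCall:
    gene_id: str
    condition: str
    stage: str
    fold: float


def load_expression(path: str) -> list[ExpressionProfile]:
    """Read a stage-labeled TSV (gene id in the first column).

    Stage columns may appear in any order but all 20 must be present.
    Rows with missing values are flagged, not dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    gene_col = df.columns[0]
    cols = set(df.columns) - {gene_col}
    unknown = cols - set(STAGES)
    if unknown:
        raise ExpressionFormatError(f"unknown column(s) {sorted(unknown)!r}")
    missing = set(STAGES) - cols
    if missing:
        raise ExpressionFormatError(f"missing column(s) {sorted(missing)!r}")
    for s in STAGES:
        if not pd.api.types.is_numeric_dtype(df[s]):
            bad = df[s][pd.to_numeric(df[s], errors="coerce").isna()]
            raise ExpressionFormatError(
                f"non-numeric cell in column {s!r}: {bad.iloc[0]!r}"
            )
    profiles = []
    for _, row in df.iterrows():
        values = {s: float(row[s]) for s in STAGES}
        profiles.append(ExpressionProfile(str(row[gene_col]), values))
    return profiles


def write_expression(profiles: Sequence[ExpressionProfile], path: str) -> None:
    df = pd.DataFrame(
        [{"gene": p.gene_id, **{s: p.values[s] for s in STAGES}} for p in profiles]
    )
    df.to_csv(path, sep="\t", index=False)


def call_expressed(
    profile: ExpressionProfile, background_threshold: float, condition: str
) -> bool:
    """True iff any in-condition stage is strictly above background."""
    if background_threshold <= 0:
        raise ValueError("background_threshold must be > 0")
    vals = profile.condition_values(condition)
    return any(v > background_threshold for v in vals if not math.isnan(v))


def find_discrete_peaks(
    profile: ExpressionProfile,
    fold_threshold: float = 2.0,
    exclude_stages: frozenset[str] | set[str] = frozenset({"S0"}),
) -> list[PeakCall]:
    """Discrete expression peaks within each condition block.

    Stage *t* is a peak iff value(t) strictly exceeds ``fold_threshold``
    times the maximum over the other non-excluded stages of the same
    condition.  At most one peak per condition can satisfy this.  Fold is
    infinite when all other stages are zero but the peak is not; an
    all-zero block yields no peak.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    unknown = set(exclude_stages) - set(STAGES)
    if unknown:
        raise ExpressionFormatError(f"unknown stage(s) {sorted(unknown)!r}")
    peaks = []
    for condition, stages in CONDITIONS.items():
        usable = [
            s
            for s in stages
            if s not in exclude_stages and not math.isnan(profile.values[s])
        ]
        if len(usable) < 2:
            continue
        for stage in usable:
            v = profile.values[stage]
            others = max(profile.values[s] for s in usable if s != stage)
            if v <= 0:
                continue
            if others <= 0:
                peaks.append(PeakCall(profile.gene_id, condition, stage, math.inf))
                break
            fold = v / others
            if fold > fold_threshold:
                peaks.append(PeakCall(profile.gene_id, condition, stage, fold))
                break
    return peaks


def highest_stage(profile: ExpressionProfile) -> str:
    """Stage with the global maximum intensity (first in grid order on ties)."""
    return max(STAGES, key=lambda s: (
        -math.inf if math.isnan(profile.values[s]) else profile.values[s],
        -STAGES.index(s),
    ))


def summarize_cohort(
    profiles: Sequence[ExpressionProfile],
    background_threshold: float = 100.0,
    fold_threshold: float = 2.0,
    exclude_stages: frozenset[str] | set[str] = frozenset({"S0"}),
) -> dict:
    """Cohort-level summary.

    Returns fractions of genes expressed per condition, fractions whose
    global maximum falls in each condition, and per-stage discrete-peak
    tallies.
    """
    if not profiles:
        raise ValueError("empty cohort")
    n = len(profiles)
    expressed = {
        cond: sum(call_expressed(p, background_threshold, cond) for p in profiles) / n
        for cond in CONDITIONS
    }
    max_cond = {cond: 0 for cond in CONDITIONS}
    for p in profiles:
        stage = highest_stage(p)
        for cond, stages in CONDITIONS.items():
            if stage in stages:
                max_cond[cond] += 1
                break
    peak_tally: dict[str, int] = {}
    n_peak_genes = 0
    for p in profiles:
        calls = find_discrete_peaks(p, fold_threshold, exclude_stages)
        if calls:
            n_peak_genes += 1
        for call in calls:
            peak_tally[call.stage] = peak_tally.get(call.stage, 0) + 1
    return {
        "n_genes": n,
        "fraction_expressed": expressed,
        "fraction_max_in_condition": {c: k / n for c, k in max_cond.items()},
        "peak_tally": peak_tally,
        "n_genes_with_peak": n_peak_genes,
    }
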