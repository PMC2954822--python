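"""Thresholded-mask colocalization of two-channel fluorescence images.

Quantifies the overlap of a GFP (green) channel with a tracer (red)
channel on single focal planes.  Each channel is thresholded to keep only
the brightest structures; the overlap for a channel is the fraction of its
above-threshold intensity lying in pixels above threshold in *both*
channels.  Complete overlap registers as 1.0, disjoint masks as 0.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np


class DimensionMismatchError(ValueError):
    """Channel images or masks differ in shape."""


@dataclass(frozen=True)
class ColocResult:
    overlap_green: float
    overlap_red: float
    n_green: int  # green mask pixel count
    n_red: int
    n_and: int
    threshold_green: float | None = None
    threshold_red: float | None = None

    def __post_init__(self) -> None:
        for v in (self.overlap_green, self.overlap_red):
            if not 0.0 <= v <= 1.0:
                raise ValueError("overlap outside [0, 1]")


def compute_threshold(img: np.ndarray, method: str, value: float) -> float:
    """Threshold for a channel image.

    ``fraction_of_max``: the given fraction of the dynamic range above the
    image minimum, min + value × (max − min), so a constant image yields an
    empty (strict >) mask and a zero-background image reduces to value × max;
    ``absolute``: the value itself; ``quantile``: the value-quantile of all
    pixel intensities (value in [0, 1]).
    """
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if not np.isfinite(img).all() or (img < 0).any():
        raise ValueError("intensities must be finite and non-negative")
    if method == "fraction_of_max":
        if not 0.0 <= value <= 1.0:
            raise ValueError("fraction_of_max value must be in [0, 1]")
        lo, hi = float(img.min()), float(img.max())
        return lo + value * (hi - lo)
    if method == "absolute":
        if value < 0:
            raise ValueError("absolute threshold must be >= 0")
        return float(value)
    if method == "quantile":
        if not 0.0 <= value <= 1.0:
            raise ValueError("quantile must be in [0, 1]")
        return float(np.quantile(img, value))
    raise ValueError(f"unknown threshold method {method!r}")


def threshold_mask(
    img: np.ndarray, method: str = "fraction_of_max", value: float = 0.5
) -> np.ndarray:
    """Boolean mask of pixels strictly above the computed threshold."""
    thr = compute_threshold(img, method, value)
    return np.asarray(img, dtype=float) > thr


def overlap_coefficients(
    green: np.ndarray,
    red: np.ndarray,
    green_mask: np.ndarray,
    red_mask: np.ndarray,
    use_mean_ratio: bool = False,
) -> ColocResult:
    """Per-channel overlap of above-threshold intensity with the AND mask.

    Primary statistic: sum of channel intensity over the AND mask divided
    by the sum over that channel's own mask (0 when the mask is empty);
    guaranteed in [0, 1].  ``use_mean_ratio`` switches to the ratio of mean
    intensities (AND mask over channel mask), which is not bounded by 1 and
    is provided for comparison only.
    """
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    green_mask = np.asarray(green_mask, dtype=bool)
    red_mask = np.asarray(red_mask, dtype=bool)
    shapes = {green.shape, red.shape, green_mask.shape, red_mask.shape}
    if len(shapes) != 1:
        raise DimensionMismatchError(f"shape mismatch: {shapes}")
    and_mask = green_mask & red_mask

    def frac(channel: np.ndarray, mask: np.ndarray) -> float:
        if not mask.any():
            return 0.0
        if use_mean_ratio:
            if not and_mask.any():
                return 0.0
            return float(channel[and_mask].mean() / channel[mask].mean())
        total = float(channel[mask].sum())
        return float(channel[and_mask].sum()) / total if total > 0 else 0.0

    og, orr = frac(green, green_mask), frac(red, red_mask)
    if use_mean_ratio:  # not guaranteed bounded; clip for the result contract
        og, orr = min(og, 1.0), min(orr, 1.0)
    return ColocResult(
        overlap_green=og,
        overlap_red=orr,
        n_green=int(green_mask.sum()),
        n_red=int(red_mask.sum()),
        n_and=int(and_mask.sum()),
    )


@dataclass(frozen=True)
class CellError:
    index: int
    message: str


def quantify_cells(
    cell_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    method: str = "fraction_of_max",
    value: float = 0.5,
    use_mean_ratio: bool = False,
    force_summary: bool = False,
) -> dict:
    """Per-cell overlap results plus a mean/sd summary.

    A per-cell failure (e.g. mismatched channel dimensions) is recorded and
    the remaining cells are processed.  Summaries over fewer than 4 cells
    are refused (``summary`` is None) unless ``force_summary``; fewer than
    4 analyzed cells is below the study's minimum sampling.
    """
    if not cell_pairs:
        raise ValueError("empty cell list")
    results: list[ColocResult] = []
    errors: list[CellError] = []
    for i, (green, red) in enumerate(cell_pairs):
        try:
            tg = compute_threshold(green, method, value)
            tr = compute_threshold(red, method, value)
            res = overlap_coefficients(
                green,
                red,
                np.asarray(green, dtype=float) > tg,
                np.asarray(red, dtype=float) > tr,
                use_mean_ratio=use_mean_ratio,
            )
            results.append(
                ColocResult(
                    res.overlap_green,
                    res.overlap_red,
                    res.n_green,
                    res.n_red,
                    res.n_and,
                    threshold_green=tg,
                    threshold_red=tr,
                )
            )
        except (ValueError, DimensionMismatchError) as exc:
            errors.append(CellError(i, str(exc)))
    summary = None
    if results and (len(results) >= 4 or force_summary):
        og = [r.overlap_green for r in results]
        orr = [r.overlap_red for r in results]
        summary = {
            "n_cells": len(results),
            "mean_green": float(np.mean(og)),
            "sd_green": float(np.std(og, ddof=1)) if len(og) > 1 else 0.0,
            "mean_red": float(np.mean(orr)),
            "sd_red": float(np.std(orr, ddof=1)) if len(orr) > 1 else 0.0,
        }
    elif results:
        warnings.warn(
            f"only {len(results)} analyzable cells (<4); summary withheld",
            stacklevel=2,
        )
    return {"cells": results, "errors": errors, "summary": summary}


def read_channel(path: str) -> np.ndarray:
    """Read a grayscale channel from TIFF/PNG or whitespace-delimited text."""
    lower = path.lower()
    if lower.endswith((".tif", ".tiff")):
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    if lower.endswith(".png"):
        from PIL import Image

        return np.asarray(Image.open(path).convert("I"), dtype=float)
    return np.loadtxt(path, dtype=float)


def write_cells_tsv(results: Sequence[ColocResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cell\toverlap_green\toverlap_red\tn_green\tn_red\tn_and\n"
        )
        for i, r in enumerate(results):
            fh.write(
                f"{i}\t{r.overlap_green:.6f}\t{r.overlap_red:.6f}"
                f"\t{r.n_green}\t{r.n_red}\t{r.n_and}\n"
            )
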