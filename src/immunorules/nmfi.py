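"""Normalized MFI (nMFI) scoring of raw median fluorescence intensities.

For each antigen a negative and a positive reference cell population
(observable in healthy donor samples) defines an antigen-specific scale:
the MFI range between the two references is divided into 10 equal steps.
The negative reference maps to score 0 and the positive reference to
score 10; the scale extrapolates upwards, so overexpression on leukemic
blasts yields scores above 10. Scores are integers: a score of k means the
measured MFI lies at least k full steps above the negative reference
(floor binning, clamped at zero below the negative reference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import MarkerSpec

__all__ = ["NMFIScale", "build_scale", "score", "score_array",
           "scales_from_specs", "convert_mfi_table"]

# relative guard against float noise at bin edges (keeps the positive
# reference exactly at score 10 even when (pos-neg)/step rounds to 9.999...)
_EDGE_EPS = 1e-9


@dataclass(frozen=True)
class NMFIScale:
    """An antigen-specific nMFI conversion scale."""

    marker: str
    neg_ref_mfi: float
    pos_ref_mfi: float
    step_width: float

    def __post_init__(self) -> None:
        if not self.pos_ref_mfi > self.neg_ref_mfi:
            raise ValueError(
                f"{self.marker}: positive reference MFI ({self.pos_ref_mfi}) must "
                f"exceed the negative reference ({self.neg_ref_mfi})"
            )


def build_scale(marker: str, neg_ref_mfi: float, pos_ref_mfi: float) -> NMFIScale:
    """Build the 10-step scale anchored at the two reference populations."""
    if not pos_ref_mfi > neg_ref_mfi:
        raise ValueError(
            f"{marker}: positive reference MFI ({pos_ref_mfi}) must exceed "
            f"the negative reference ({neg_ref_mfi})"
        )
    return NMFIScale(marker, float(neg_ref_mfi), float(pos_ref_mfi),
                     (pos_ref_mfi - neg_ref_mfi) / 10.0)


def score(scale: NMFIScale, mfi: float) -> int:
    """Integer nMFI score of a raw MFI value.

    ``floor((mfi - neg_ref) / step)`` clamped at zero; monotone
    non-decreasing in ``mfi`` and invariant under rescaling all MFIs by a
    common positive factor.
    """
    if not math.isfinite(mfi):
        raise ValueError(f"MFI must be finite, got {mfi!r}")
    steps = (mfi - scale.neg_ref_mfi) / scale.step_width
    return max(0, int(math.floor(steps + _EDGE_EPS * max(1.0, abs(steps)))))


def score_array(scale: NMFIScale, mfi: np.ndarray) -> np.ndarray:
    """Vectorized :func:`score`; NaN passes through as NaN."""
    mfi = np.asarray(mfi, dtype=float)
    steps = (mfi - scale.neg_ref_mfi) / scale.step_width
    out = np.floor(steps + _EDGE_EPS * np.maximum(1.0, np.abs(steps)))
    out = np.maximum(out, 0.0)
    out[np.isnan(mfi)] = np.nan
    return out


def scales_from_specs(specs: list[MarkerSpec]) -> dict[str, NMFIScale]:
    """Scales for every graded marker carrying both reference MFIs."""
    scales = {}
    for spec in specs:
        if spec.scale == "graded" and spec.neg_ref_mfi is not None \
                and spec.pos_ref_mfi is not None:
            scales[spec.name] = build_scale(spec.name, spec.neg_ref_mfi,
                                            spec.pos_ref_mfi)
    return scales


def convert_mfi_table(raw: pd.DataFrame, scales: dict[str, NMFIScale]) -> pd.DataFrame:
    """Convert a patient x marker table of raw MFIs to nMFI scores.

    Columns without a scale (e.g. binary markers) are passed through
    unchanged; missing cells stay missing.
    """
    out = raw.copy()
    for name, scale in scales.items():
        if name in out.columns:
            out[name] = score_array(scale, out[name].to_numpy(dtype=float))
    return out
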