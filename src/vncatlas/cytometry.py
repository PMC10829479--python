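"""ROI-table quantification: corrected total cell fluorescence (CTCF),
trimodal intensity classification, and anterior-posterior position counts.

CTCF = integrated density - (ROI area x mean background fluorescence).
Tyrosine-hydroxylase immunoreactivity classes: low below 15,000 CTCF, high
above 50,000, medium in between (the boundary values themselves fall in
medium, the only gap-free completion of the stated open intervals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ctcf",
    "classify_th",
    "GanglionFrame",
    "posterior_fraction",
    "TH_LOW_MAX",
    "TH_HIGH_MIN",
]

TH_LOW_MAX = 15_000.0
TH_HIGH_MIN = 50_000.0


def ctcf(
    integrated_density: np.ndarray | float,
    area: np.ndarray | float,
    background_mean: np.ndarray | float,
) -> np.ndarray | float:
    """Corrected total cell fluorescence; negative values are legal (signal
    below background) but flagged with a warning."""
    out = np.asarray(integrated_density, dtype=float) - np.asarray(area, dtype=float) * np.asarray(
        background_mean, dtype=float
    )
    if np.any(out < 0):
        warnings.warn("negative CTCF values (signal below background)", stacklevel=2)
    return out if out.ndim else float(out)


def ctcf_table(rois: pd.DataFrame) -> pd.DataFrame:
    """Append ``ctcf`` and ``th_class`` columns to an ROI table."""
    out = rois.copy()
    out["ctcf"] = ctcf(
        out["integrated_density"].to_numpy(),
        out["area"].to_numpy(),
        out["background_mean"].to_numpy(),
    )
    out["th_class"] = classify_th(out["ctcf"].to_numpy())
    return out


def classify_th(
    values: np.ndarray | float,
    low_max: float = TH_LOW_MAX,
    high_min: float = TH_HIGH_MIN,
) -> np.ndarray | str:
    """Trimodal intensity class: low < ``low_max`` <= medium <= ``high_min``
    < high."""
    v = np.asarray(values, dtype=float)
    out = np.where(v < low_max, "low", np.where(v > high_min, "high", "medium"))
    return out.astype(object) if out.ndim else str(out)


@dataclass(frozen=True)
class GanglionFrame:
    """Anterior/posterior bounds of a ganglion along the image y axis.

    With the "anterior is up" convention, y increases toward posterior, so
    ``anterior_y < posterior_y``; set ``flipped=True`` for the opposite
    image orientation.
    """

    anterior_y: float
    posterior_y: float
    flipped: bool = False

    def __post_init__(self) -> None:
        lo, hi = sorted((self.anterior_y, self.posterior_y))
        if lo == hi:
            raise ValueError("frame has zero extent")
        if not self.flipped and self.anterior_y >= self.posterior_y:
            raise ValueError("expect anterior_y < posterior_y unless flipped")

    @property
    def midpoint(self) -> float:
        return (self.anterior_y + self.posterior_y) / 2.0


def posterior_fraction(rois: pd.DataFrame, frame: GanglionFrame) -> float:
    """Fraction of ROI centroids in the posterior half of the frame.

    ROIs outside the frame bounds are flagged with a warning but still
    counted by their side of the midpoint. Empty tables return NaN.
    """
    if len(rois) == 0:
        warnings.warn("posterior_fraction of empty ROI table is undefined", stacklevel=2)
        return float("nan")
    y = rois["y"].to_numpy(dtype=float)
    lo, hi = sorted((frame.anterior_y, frame.posterior_y))
    outside = (y < lo) | (y > hi)
    if outside.any():
        warnings.warn(f"{int(outside.sum())} ROIs outside the ganglion frame", stacklevel=2)
    posterior = y < frame.midpoint if frame.flipped else y > frame.midpoint
    return float(posterior.mean())
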