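"""P2RY12 mean-intensity measurement and grouped summaries.

P2RY12 marks resident (non-activated) microglia and is down-regulated on
activation, so its mean signal level tracks activation state.  The measure
is the whole-field average of the green channel, expressed as a percentage
of the 8-bit maximum:

    percent = 100 * (sum of pixel values / number of pixels) / 255

No masking to Iba-1+ regions is applied by default, because the average is
defined over the total number of pixels of the image; a mask-restricted
variant is available for sensitivity analysis.  Comparisons are only valid
across images taken with equal exposure, which callers should enforce via
:func:`check_exposure`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FieldImage

logger = logging.getLogger(__name__)

MAX_8BIT = 255.0


@dataclass
class IntensityRecord:
    field_id: str
    mean_intensity_percent: float
    n_pixels: int
    layer: str = ""
    group: str = ""
    day: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_intensity_percent <= 100.0:
            raise ValueError("mean intensity percent must be in [0, 100]")


def mean_intensity_percent(
    img: FieldImage, bit_depth: int = 8, mask: np.ndarray | None = None
) -> float:
    """Whole-field mean of the channel as a percentage of 255.

    16-bit inputs are rescaled to the 8-bit range (divide by 257) with a
    log message before averaging.  ``mask`` optionally restricts the
    average to labelled pixels (sensitivity-analysis pathway; the default
    whole-field average is the canonical measure).
    """
    pixels = img.pixels
    if pixels.size == 0:
        raise ValueError("empty image")
    if bit_depth == 16:
        logger.info("rescaling 16-bit channel to 8-bit range (factor 1/257)")
        pixels = pixels / 257.0
    elif bit_depth != 8:
        raise ValueError("bit_depth must be 8 or 16")
    if mask is not None:
        if not mask.any():
            raise ValueError("mask selects no pixels")
        pixels = pixels[mask]
    return 100.0 * float(pixels.mean()) / MAX_8BIT


def check_exposure(exposures) -> bool:
    """True when all exposure metadata values in a comparison set agree.

    Emits a warning (and returns False) otherwise; intensity comparisons
    across unequal exposures are not interpretable.
    """
    vals = set(exposures)
    if len(vals) > 1:
        warnings.warn(
            f"comparison set mixes exposure settings {sorted(vals)}; "
            "intensity percentages are not comparable",
            stacklevel=2,
        )
        return False
    return True


def summarize_intensity(
    records, by: tuple[str, ...] = ("layer", "group", "day")
) -> pd.DataFrame:
    """Mean +- SD (n-1 denominator) of intensity percent per grouping cell.

    ``records`` is an iterable of :class:`IntensityRecord` or a DataFrame
    with a ``mean_intensity_percent`` column and the grouping columns.  A
    single-record cell has no defined SD; it is reported as 0 with
    ``sd_undefined`` set.  Empty cells are simply absent (with a warning
    when the input itself is empty).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "field_id": r.field_id,
                    "mean_intensity_percent": r.mean_intensity_percent,
                    "layer": r.layer,
                    "group": r.group,
                    "day": r.day,
                }
                for r in records
            ]
        )
    if df.empty:
        warnings.warn("no intensity records to summarize", stacklevel=2)
        return pd.DataFrame(
            columns=[*by, "mean", "sd", "n", "sd_undefined"]
        )
    grouped = df.groupby(list(by), dropna=False)["mean_intensity_percent"]
    out = grouped.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    out["sd_undefined"] = out["n"] < 2
    out.loc[out["sd_undefined"], "sd"] = 0.0
    return out
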