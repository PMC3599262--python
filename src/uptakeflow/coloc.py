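"""Pixel-wise Pearson colocalization between two channels within a mask.

The Pearson coefficient over masked pixel pairs runs from +1 (perfect
positive linear relationship) through 0 (no relationship) to -1 (perfect
anticorrelation).  Per-image coefficients are aggregated as mean +- sample
standard deviation, the convention used when reporting colocalization over
several images.  No Costes thresholding or randomization is applied: this is
plain (JACoP-style) Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConstantChannelError, ValidationError
from .features import _get_channel
from .segmask import MaskPair
from .simgen import CellEvent

MASK_CHOICES = ("whole_cell", "internal", "full_frame")


@dataclass
class ColocResult:
    pearson_r: float
    n_pixels: int
    mask_used: str
    per_image: list[float] = field(default_factory=list)
    mean_r: float = np.nan
    sd_r: float = np.nan
    n_excluded: int = 0


def pearson_r(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    mask: np.ndarray | None = None,
    mask_used: str = "whole_cell",
) -> ColocResult:
    """Pearson correlation of two channels over the masked pixels.

    Raises :class:`ConstantChannelError` when either channel is constant
    within the mask — the coefficient is undefined there and silently
    returning 0 would fake "no relationship".
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("channels have different shapes")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
        mask_used = "full_frame"
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValidationError("mask shape does not match channels")
    xa, xb = a[mask], b[mask]
    if xa.size < 2:
        raise ValidationError("mask must contain at least 2 pixels")
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise ConstantChannelError("a channel is constant within the mask")
    r = float(stats.pearsonr(xa, xb).statistic)
    return ColocResult(
        pearson_r=r,
        n_pixels=int(xa.size),
        mask_used=mask_used,
        per_image=[r],
        mean_r=r,
        sd_r=np.nan,
    )


def _select_mask(mask_pair: MaskPair, mask_used: str, shape) -> np.ndarray:
    if mask_used == "whole_cell":
        return mask_pair.whole_mask
    if mask_used == "internal":
        if mask_pair.internal_mask is None:
            raise ValidationError("MaskPair has no internal mask")
        return mask_pair.internal_mask
    return np.ones(shape, dtype=bool)


def batch_coloc(
    events: Sequence[CellEvent],
    masks: Sequence[MaskPair],
    pair: tuple[str, str] = ("probe", "marker"),
    mask_used: str = "whole_cell",
) -> ColocResult:
    """Per-event Pearson coefficients aggregated as mean +- sample SD.

    Events where the coefficient is undefined (constant channel within the
    mask) are excluded and counted in ``n_excluded``; if every event is
    undefined an error is raised.
    """
    if mask_used not in MASK_CHOICES:
        raise ValidationError(f"mask_used must be one of {MASK_CHOICES}")
    if len(events) < 1:
        raise ValidationError("need at least one event")
    if len(events) != len(masks):
        raise ValidationError("events and masks differ in length")
    per_image: list[float] = []
    n_pixels = 0
    n_excluded = 0
    for event, mask_pair in zip(events, masks):
        ch_a = _get_channel(event, pair[0])
        ch_b = _get_channel(event, pair[1])
        mask = _select_mask(mask_pair, mask_used, ch_a.shape)
        try:
            res = pearson_r(ch_a, ch_b, mask, mask_used)
        except (ConstantChannelError, ValidationError):
            n_excluded += 1
            continue
        per_image.append(res.pearson_r)
        n_pixels += res.n_pixels
    if not per_image:
        raise ConstantChannelError(
            "Pearson coefficient undefined for every event in the batch"
        )
    arr = np.asarray(per_image)
    if np.ptp(arr) == 0:  # identical coefficients: SD is exactly zero
        sd = 0.0
    else:
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return ColocResult(
        pearson_r=float(arr.mean()),
        n_pixels=n_pixels,
        mask_used=mask_used,
        per_image=per_image,
        mean_r=float(arr.mean()),
        sd_r=sd,
        n_excluded=n_excluded,
    )
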