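"""Per-event intensity partitioning and the Internalization Score.

For each cell the probe intensity is summed over the internal (eroded) mask,
over the membrane shell, and over the whole-cell mask.  The Internalization
Score compares the internal and shell sums on a log scale,

    IS = log10((I_in + eps) / (I_out + eps)),

so IS > 0 means mostly internalized signal, IS < 0 mostly surface-associated
signal, and IS = 0 an exactly equal split.  The raw internal/total ratio is
reported alongside as ``ratio_in_total``.  The same machinery applies to a
side-scatter channel, which serves as a label-free intensity proxy for
light-diffracting particles.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ChannelNotFoundError, ValidationError
from .segmask import MaskPair, membrane_shell
from .simgen import CellEvent

BACKGROUND_POLICIES = ("none", "median_outside")


def _get_channel(event: CellEvent, channel: str) -> np.ndarray:
    if channel == "brightfield":
        return event.brightfield
    if channel == "scatter":
        if event.scatter is None:
            raise ChannelNotFoundError("event has no scatter channel")
        return event.scatter
    try:
        return event.fluorescence[channel]
    except KeyError:
        raise ChannelNotFoundError(
            f"channel {channel!r} not in {sorted(event.fluorescence)}"
        ) from None


def _background_corrected(
    img: np.ndarray, whole_mask: np.ndarray, background: str
) -> np.ndarray:
    if background not in BACKGROUND_POLICIES:
        raise ValidationError(
            f"background policy must be one of {BACKGROUND_POLICIES}"
        )
    img = np.asarray(img, dtype=float)
    if background == "none":
        return img
    outside = ~whole_mask
    if not outside.any():
        return img
    return np.clip(img - np.median(img[outside]), 0, None)


def intensity_partition(
    event: CellEvent,
    masks: MaskPair,
    channel: str = "probe",
    background: str = "none",
) -> tuple[float, float, float]:
    """Sum a channel over the internal mask, the shell, and the whole mask.

    Returns ``(I_in, I_out, I_total)`` with ``I_total = I_in + I_out`` by
    construction, so the partition identity holds exactly.  ``background``
    is either ``"none"`` (raw sums) or ``"median_outside"`` (subtract the
    median intensity outside the whole-cell mask, clip at zero).
    """
    img = _get_channel(event, channel)
    if img.shape != masks.whole_mask.shape:
        raise ValidationError("masks and event have different geometry")
    if masks.internal_mask is None:
        raise ValidationError("MaskPair has no internal mask; run erode_mask first")
    if not masks.whole_mask.any():
        return 0.0, 0.0, 0.0
    img = _background_corrected(img, masks.whole_mask, background)
    i_in = float(img[masks.internal_mask].sum())
    i_out = float(img[membrane_shell(masks)].sum())
    return i_in, i_out, i_in + i_out


def internalization_score(i_in: float, i_out: float, epsilon: float = 1.0) -> float:
    """Log-ratio Internalization Score ``log10((I_in + eps)/(I_out + eps))``.

    ``epsilon`` (in the same intensity units as the sums) regularizes empty
    compartments; it bounds the score by ``+-log10((I_total + eps)/eps)``.
    The sign tracks which compartment dominates: positive for internal,
    negative for surface, exactly zero for an equal split.
    """
    if epsilon <= 0:
        raise ValidationError("epsilon must be > 0")
    if i_in < 0 or i_out < 0:
        raise ValidationError("intensities must be >= 0")
    return math.log10((i_in + epsilon) / (i_out + epsilon))


@dataclass
class ScatterInternal:
    total: float
    mean_per_px: float
    n_pixels: int


def scatter_internal_intensity(
    event: CellEvent, masks: MaskPair, background: str = "none"
) -> ScatterInternal:
    """Side-scatter intensity inside the eroded internal mask.

    Sum and per-pixel mean of the scatter channel over the internal mask,
    with the same background-handling options as the fluorescence path.
    """
    if event.scatter is None:
        raise ChannelNotFoundError("event has no scatter channel")
    i_in, _, _ = intensity_partition(event, masks, "scatter", background)
    if masks.internal_mask is None:
        raise ValidationError("MaskPair has no internal mask")
    n = int(masks.internal_mask.sum())
    return ScatterInternal(total=i_in, mean_per_px=i_in / n if n else 0.0, n_pixels=n)


FEATURE_COLUMNS = [
    "event_id",
    "channel",
    "I_total",
    "I_in",
    "I_out",
    "IS",
    "ratio_in_total",
    "mean_internal_intensity",
    "saturation_fraction",
    "included",
    "qc_no_cell_found",
    "qc_touches_border",
    "qc_below_area_gate",
    "qc_internal_mask_empty",
]


def extract_features(
    events: Sequence[CellEvent],
    masks: Sequence[MaskPair],
    channels: Iterable[str] | None = None,
    epsilon: float = 1.0,
    background: str = "none",
    saturation_level: float | None = None,
) -> pd.DataFrame:
    """Build the per-(event, channel) feature table.

    One row per event and channel, in input order.  Events whose mask QC
    raised ``no_cell_found`` or ``below_area_gate`` are retained in the table
    but marked ``included = False`` so population summaries can exclude them.
    """
    if len(events) != len(masks):
        raise ValidationError(
            f"events ({len(events)}) and masks ({len(masks)}) differ in length"
        )
    rows = []
    for event, mask_pair in zip(events, masks):
        if channels is None:
            ev_channels = list(event.fluorescence)
            if event.scatter is not None:
                ev_channels.append("scatter")
        else:
            ev_channels = list(channels)
        qc = mask_pair.qc.as_dict()
        included = not (qc["qc_no_cell_found"] or qc["qc_below_area_gate"])
        n_internal = (
            int(mask_pair.internal_mask.sum())
            if mask_pair.internal_mask is not None
            else 0
        )
        n_whole = int(mask_pair.whole_mask.sum())
        for channel in ev_channels:
            i_in, i_out, i_total = intensity_partition(
                event, mask_pair, channel, background
            )
            img = _get_channel(event, channel)
            if saturation_level is not None and n_whole:
                sat = float(
                    (img[mask_pair.whole_mask] >= saturation_level).mean()
                )
            else:
                sat = 0.0
            rows.append(
                {
                    "event_id": event.event_id,
                    "channel": channel,
                    "I_total": i_total,
                    "I_in": i_in,
                    "I_out": i_out,
                    "IS": internalization_score(i_in, i_out, epsilon),
                    "ratio_in_total": i_in / i_total if i_total > 0 else np.nan,
                    "mean_internal_intensity": i_in / n_internal if n_internal else 0.0,
                    "saturation_fraction": sat,
                    "included": included,
                    **qc,
                }
            )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
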