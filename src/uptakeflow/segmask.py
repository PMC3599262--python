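"""Whole-cell segmentation from brightfield and fixed-depth mask erosion.

The whole-cell mask is the largest connected object obtained by global
thresholding of the brightfield image (cells may be darker or brighter than
the background), followed by hole filling.  The internal mask is the set of
cell pixels whose Euclidean distance to the nearest background pixel is at
least the erosion depth expressed in pixels; with the default 3 um depth and
0.5 um pixels this is a 6-pixel erosion.  The ring between the two masks is
the membrane shell, the compartment where surface-adsorbed particles live.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .errors import ValidationError

_POLARITIES = ("darker", "brighter", "auto")


@dataclass(frozen=True)
class MaskParams:
    """Parameters of mask construction.

    Attributes
    ----------
    erosion_depth_um:
        Physical depth of the inward erosion that defines the internal mask.
        Default 3.0 um.
    pixel_size_um:
        Pixel pitch of the images.  Default 0.5 um/px, so the default erosion
        is 6 px.
    min_cell_area_um2:
        Objects smaller than this area are flagged as debris (``below_area_gate``).
    brightfield_polarity:
        Whether cells are darker or brighter than the background in
        brightfield, or ``auto`` to threshold the absolute deviation from the
        median background level.
    """

    erosion_depth_um: float = 3.0
    pixel_size_um: float = 0.5
    min_cell_area_um2: float = 50.0
    brightfield_polarity: str = "auto"

    def __post_init__(self) -> None:
        if self.erosion_depth_um < 0:
            raise ValidationError("erosion_depth_um must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        if self.min_cell_area_um2 < 0:
            raise ValidationError("min_cell_area_um2 must be >= 0")
        if self.brightfield_polarity not in _POLARITIES:
            raise ValidationError(
                f"brightfield_polarity must be one of {_POLARITIES}, "
                f"got {self.brightfield_polarity!r}"
            )

    @property
    def erosion_px(self) -> int:
        """Erosion depth in pixels, rounded half-to-even."""
        return int(round(self.erosion_depth_um / self.pixel_size_um))


@dataclass
class QCFlags:
    no_cell_found: bool = False
    touches_border: bool = False
    below_area_gate: bool = False
    internal_mask_empty: bool = False

    def as_dict(self) -> dict[str, bool]:
        return {
            "qc_no_cell_found": self.no_cell_found,
            "qc_touches_border": self.touches_border,
            "qc_below_area_gate": self.below_area_gate,
            "qc_internal_mask_empty": self.internal_mask_empty,
        }


@dataclass
class MaskPair:
    """Whole-cell mask and (once eroded) the internal mask for one event."""

    whole_mask: np.ndarray
    internal_mask: np.ndarray | None = None
    qc: QCFlags = field(default_factory=QCFlags)

    @property
    def shell(self) -> np.ndarray:
        return membrane_shell(self)


def erode_binary(mask: np.ndarray, erosion_px: int) -> np.ndarray:
    """Erode a binary mask by a Euclidean distance of ``erosion_px``.

    A pixel survives iff its distance to the nearest background pixel is
    >= ``erosion_px``.  Squared distances are computed exactly in integer
    arithmetic from the nearest-background indices of the distance transform,
    so the result matches a brute-force minimum-distance check pixel for
    pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValidationError("mask must be 2-D")
    if erosion_px < 0:
        raise ValidationError("erosion_px must be >= 0")
    if erosion_px == 0 or not mask.any():
        return mask.copy()
    if mask.all():  # no background: nothing to erode from
        return mask.copy()
    nearest = ndi.distance_transform_edt(
        mask, return_distances=False, return_indices=True
    )
    ii, jj = np.indices(mask.shape)
    d2 = (ii - nearest[0]) ** 2 + (jj - nearest[1]) ** 2
    return mask & (d2 >= erosion_px**2)


def _threshold_foreground(brightfield: np.ndarray, polarity: str) -> np.ndarray:
    if polarity == "auto":
        dev = np.abs(brightfield - np.median(brightfield))
        thr = threshold_otsu(dev)
        return dev > thr
    thr = threshold_otsu(brightfield)
    if polarity == "darker":
        return brightfield < thr
    return brightfield > thr


def segment_whole_cell(
    brightfield: np.ndarray, params: MaskParams | None = None
) -> MaskPair:
    """Derive the whole-cell mask from the brightfield channel.

    Global threshold (Otsu), hole filling, then the largest connected
    component.  A blank or constant image yields an empty mask with the
    ``no_cell_found`` flag set rather than an exception; debris-sized objects
    set ``below_area_gate``.
    """
    if params is None:
        params = MaskParams()
    bf = np.asarray(brightfield, dtype=float)
    if bf.ndim != 2:
        raise ValidationError("brightfield must be a 2-D grid")
    if not np.all(np.isfinite(bf)):
        raise ValidationError("brightfield contains non-finite values")

    qc = QCFlags()
    empty = np.zeros(bf.shape, dtype=bool)
    if np.ptp(bf) == 0:
        qc.no_cell_found = True
        return MaskPair(whole_mask=empty, qc=qc)

    fg = _threshold_foreground(bf, params.brightfield_polarity)
    fg = ndi.binary_fill_holes(fg)
    labels, n = ndi.label(fg)
    if n == 0:
        qc.no_cell_found = True
        return MaskPair(whole_mask=empty, qc=qc)
    sizes = ndi.sum_labels(fg, labels, index=np.arange(1, n + 1))
    whole = labels == (int(np.argmax(sizes)) + 1)

    area_um2 = whole.sum() * params.pixel_size_um**2
    if area_um2 < params.min_cell_area_um2:
        qc.below_area_gate = True
    border = np.zeros_like(whole)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    qc.touches_border = bool((whole & border).any())
    return MaskPair(whole_mask=whole, qc=qc)


def erode_mask(mask_pair_or_mask, params: MaskParams | None = None) -> MaskPair:
    """Compute the internal mask by physical-distance erosion of the whole mask.

    Accepts either a :class:`MaskPair` (QC flags are carried over) or a bare
    binary array.  Sets ``internal_mask_empty`` when the erosion removes every
    pixel.
    """
    if params is None:
        params = MaskParams()
    if isinstance(mask_pair_or_mask, MaskPair):
        whole = mask_pair_or_mask.whole_mask
        qc = replace(mask_pair_or_mask.qc)
    else:
        whole = np.asarray(mask_pair_or_mask, dtype=bool)
        qc = QCFlags()
    internal = erode_binary(whole, params.erosion_px)
    qc.internal_mask_empty = bool(whole.any() and not internal.any())
    return MaskPair(whole_mask=np.asarray(whole, dtype=bool), internal_mask=internal, qc=qc)


def compute_masks(brightfield: np.ndarray, params: MaskParams | None = None) -> MaskPair:
    """Segment the whole cell then erode: the standard two-step mask recipe."""
    if params is None:
        params = MaskParams()
    return erode_mask(segment_whole_cell(brightfield, params), params)


def membrane_shell(mask_pair: MaskPair) -> np.ndarray:
    """Membrane-shell compartment: whole-cell mask minus internal mask.

    Together with the internal mask this partitions the whole mask, so the
    shell holds the surface-adsorbed signal the erosion is meant to exclude.
    """
    if mask_pair.internal_mask is None:
        raise ValidationError("MaskPair has no internal mask; run erode_mask first")
    return mask_pair.whole_mask & ~mask_pair.internal_mask
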