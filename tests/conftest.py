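import numpy as np
import pytest

from uptakeflow import CellSpec, make_cell_event
from uptakeflow.segmask import MaskParams, compute_masks


@pytest.fixture
def noiseless_spec():
    """Clean event: no noise, no background, default geometry."""
    return CellSpec(noise_model="none", background_level=0.0)


@pytest.fixture
def noiseless_event(noiseless_spec):
    return make_cell_event(noiseless_spec, seed=7)


@pytest.fixture
def default_params():
    return MaskParams()


@pytest.fixture
def noiseless_masks(noiseless_event, default_params):
    return compute_masks(noiseless_event.brightfield, default_params)


def random_blob_mask(rng: np.random.Generator, side: int) -> np.ndarray:
    """Random connected-ish blob for erosion property tests."""
    from scipy import ndimage as ndi

    noise = rng.random((side, side))
    smooth = ndi.gaussian_filter(noise, sigma=rng.uniform(2, 6))
    mask = smooth > np.quantile(smooth, rng.uniform(0.5, 0.85))
    return mask


def brute_force_erode(mask: np.ndarray, erosion_px: int) -> np.ndarray:
    """O(N^2) oracle: keep mask pixels whose min distance to background >= depth."""
    mask = np.asarray(mask, dtype=bool)
    if erosion_px == 0 or not mask.any() or mask.all():
        return mask.copy()
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    out = np.zeros_like(mask)
    d2min = (
        ((fg[:, None, :] - bg[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    )
    keep = fg[d2min >= erosion_px**2]
    out[keep[:, 0], keep[:, 1]] = True
    return out
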