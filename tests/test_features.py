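"""Intensity partitioning and Internalization Score behavior."""

import math

import numpy as np
import pytest

from uptakeflow import (
    CellSpec,
    extract_features,
    intensity_partition,
    internalization_score,
    make_cell_event,
    make_cohort,
    scatter_internal_intensity,
)
from uptakeflow.errors import ChannelNotFoundError, ValidationError
from uptakeflow.segmask import MaskPair, QCFlags, compute_masks


def clean_event(seed=0, **kw):
    base = dict(noise_model="none", background_level=0.0)
    base.update(kw)
    return make_cell_event(CellSpec(**base), seed=seed)


class TestIntensityPartition:
    def test_partition_identity(self):
        ev = make_cell_event(CellSpec(n_spots=10), seed=4)
        masks = compute_masks(ev.brightfield)
        i_in, i_out, i_total = intensity_partition(ev, masks)
        assert i_in + i_out == i_total
        assert i_in >= 0 and i_out >= 0

    def test_all_internal_event_has_zero_shell_signal(self):
        ev = clean_event(internal_fraction=1.0)
        masks = compute_masks(ev.brightfield)
        _, i_out, _ = intensity_partition(ev, masks)
        assert i_out == 0.0

    def test_known_internal_fraction_recovered(self):
        ev = clean_event(internal_fraction=0.7, probe_total_intensity=10000.0)
        masks = compute_masks(ev.brightfield)
        i_in, _, i_total = intensity_partition(ev, masks)
        assert i_in / i_total == pytest.approx(0.70, abs=0.02)

    def test_median_outside_background_subtraction(self):
        ev = make_cell_event(
            CellSpec(noise_model="none", background_level=5.0,
                     internal_fraction=0.7), seed=2
        )
        masks = compute_masks(ev.brightfield)
        i_in, _, i_total = intensity_partition(ev, masks, background="median_outside")
        assert i_in / i_total == pytest.approx(0.70, abs=0.02)
        assert i_total == pytest.approx(10000.0, rel=0.05)

    def test_missing_channel_raises(self, noiseless_event, noiseless_masks):
        with pytest.raises(ChannelNotFoundError):
            intensity_partition(noiseless_event, noiseless_masks, "dapi")

    def test_empty_whole_mask_gives_zero_sums(self, noiseless_event):
        empty = np.zeros_like(noiseless_event.brightfield, dtype=bool)
        masks = MaskPair(whole_mask=empty, internal_mask=empty,
                         qc=QCFlags(no_cell_found=True))
        assert intensity_partition(noiseless_event, masks) == (0.0, 0.0, 0.0)


class TestInternalizationScore:
    def test_equal_compartments_score_zero(self):
        assert internalization_score(500.0, 500.0) == 0.0

    def test_all_internal_closed_form(self):
        assert internalization_score(1000.0, 0.0, epsilon=1.0) == pytest.approx(
            math.log10(1001.0), abs=1e-12
        )

    def test_sign_convention(self):
        assert internalization_score(10.0, 1.0) > 0
        assert internalization_score(1.0, 10.0) < 0

    def test_strictly_monotone_in_split(self):
        total = 1000.0
        scores = [
            internalization_score(f * total, (1 - f) * total)
            for f in np.linspace(0, 1, 21)
        ]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_scale_invariance_with_rescaled_epsilon(self):
        for c in (0.01, 3.7, 1e4):
            base = internalization_score(800.0, 200.0, epsilon=1.0)
            scaled = internalization_score(800.0 * c, 200.0 * c, epsilon=c)
            assert abs(scaled - base) < 1e-3

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            internalization_score(-1.0, 5.0)
        with pytest.raises(ValidationError):
            internalization_score(1.0, 5.0, epsilon=0.0)


class TestScatterPath:
    def test_zero_scatter_channel(self, noiseless_event, noiseless_masks):
        ev = noiseless_event
        ev.scatter = np.zeros_like(ev.brightfield)
        res = scatter_internal_intensity(ev, noiseless_masks)
        assert res.total == 0.0 and res.mean_per_px == 0.0

    def test_scatter_equals_fluorescence_partition_when_copied(
        self, noiseless_event, noiseless_masks
    ):
        ev = noiseless_event
        ev.scatter = ev.fluorescence["probe"].copy()
        res = scatter_internal_intensity(ev, noiseless_masks)
        i_in, _, _ = intensity_partition(ev, noiseless_masks, "probe")
        assert res.total == i_in

    def test_missing_scatter_raises(self, noiseless_event, noiseless_masks):
        with pytest.raises(ChannelNotFoundError):
            scatter_internal_intensity(noiseless_event, noiseless_masks)

    def test_doubled_scatter_amplitude_doubles_internal_signal(self):
        def internal_scatter(amplitude, seed):
            spec = CellSpec(scatter_total_intensity=amplitude, background_level=0.0,
                            noise_model="none")
            cohort = make_cohort(spec, n_cells=20, seed=seed)
            vals = []
            for ev in cohort:
                masks = compute_masks(ev.brightfield)
                vals.append(scatter_internal_intensity(ev, masks).total)
            return np.mean(vals)

        low = internal_scatter(4000.0, seed=31)
        high = internal_scatter(8000.0, seed=31)
        assert high / low == pytest.approx(2.0, rel=0.05)


class TestExtractFeatures:
    def test_one_row_per_event_and_channel(self):
        cohort = make_cohort(CellSpec(scatter_total_intensity=1000.0), 10, seed=2)
        masks = [compute_masks(e.brightfield) for e in cohort]
        table = extract_features(cohort, masks)
        assert len(table) == 20  # probe + scatter
        assert set(table["channel"]) == {"probe", "scatter"}

    @pytest.mark.parametrize("fraction,sign", [(0.9, 1), (0.1, -1)])
    def test_cohort_is_sign_tracks_true_fraction(self, fraction, sign):
        cohort = make_cohort(CellSpec(internal_fraction=fraction), 60, seed=13)
        masks = [compute_masks(e.brightfield) for e in cohort]
        table = extract_features(cohort, masks, background="median_outside")
        assert (np.sign(table["IS"]) == sign).mean() > 0.95

    def test_flagged_events_retained_but_not_included(self):
        cohort = make_cohort(CellSpec(), 3, seed=1)
        masks = [compute_masks(e.brightfield) for e in cohort]
        # blank one event's brightfield -> empty mask, no_cell_found
        cohort[1].brightfield = np.full_like(cohort[1].brightfield, 50.0)
        masks[1] = compute_masks(cohort[1].brightfield)
        table = extract_features(cohort, masks)
        assert len(table) == 3
        assert not table.loc[table["qc_no_cell_found"], "included"].any()

    def test_mismatched_collections_raise(self):
        cohort = make_cohort(CellSpec(), 3, seed=1)
        with pytest.raises(ValidationError):
            extract_features(cohort, [])
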