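"""Differential entropy, LDS smoothing, and topographic-map rendering."""

import numpy as np
import pytest
from scipy.linalg import solve_banded
from scipy.spatial import Delaunay

from eegaug.features import (BandSet, DEFeature, EEGSegment, ElectrodeLayout,
                             InvalidBandError, LayoutError, LDSConfig,
                             compute_de, lds_smooth, make_topomap,
                             synthetic_layout, topomaps_from_session)
from eegaug.synthetic_data import _band_noise

BANDS = BandSet()
UNIT_NORM = np.tile([[0.0, 1.0]], (5, 1))


def _band_segment(rng, lo, hi, var=1.0, n=800, fs=200.0, channels=1):
    x = _band_noise(rng, channels, n, fs, lo, hi, np.full(channels, var))
    return EEGSegment(data=x, fs=fs, channel_names=tuple(f"c{i}" for i in range(channels)))


class TestComputeDE:
    def test_zero_entropy_at_reference_variance(self, rng):
        """Band variance 1/(2 pi e) makes the log argument 1, hence DE = 0."""
        seg = _band_segment(rng, 14, 31, var=1.0 / (2 * np.pi * np.e),
                            n=4000, channels=8)
        de = compute_de(seg, BANDS).values[:, 3]
        assert np.abs(de.mean()) < 0.05

    def test_doubling_amplitude_adds_ln2_exactly(self, rng):
        seg = _band_segment(rng, 8, 14, channels=3)
        doubled = EEGSegment(data=2.0 * seg.data, fs=seg.fs,
                             channel_names=seg.channel_names)
        d1 = compute_de(seg, BANDS).values
        d2 = compute_de(doubled, BANDS).values
        assert np.allclose(d2 - d1, np.log(2.0), atol=1e-9)

    def test_monotone_in_band_variance(self, rng):
        """For a fixed band, DE strictly increases with signal variance."""
        base = _band_segment(rng, 4, 8, channels=2)
        des = []
        for scale in [0.5, 1.0, 2.0, 4.0]:
            seg = EEGSegment(data=np.sqrt(scale) * base.data, fs=base.fs,
                             channel_names=base.channel_names)
            des.append(compute_de(seg, BANDS).values[:, 1].mean())
        assert np.all(np.diff(des) > 0)

    def test_band_above_nyquist_rejected(self, rng):
        seg = _band_segment(rng, 1, 4, fs=80.0, n=320)
        with pytest.raises(InvalidBandError):
            compute_de(seg, BANDS)  # gamma edge 50 Hz > 40 Hz Nyquist

    def test_silent_channel_clamped_finite(self):
        seg = EEGSegment(data=np.zeros((1, 800)), fs=200.0, channel_names=("c0",))
        de = compute_de(seg, BANDS)
        assert np.isfinite(de.values).all()


class TestLDSSmooth:
    def test_constant_trajectory_unchanged(self):
        feats = [DEFeature(values=np.full((2, 3), 4.2)) for _ in range(6)]
        out = lds_smooth(feats)
        for f in out:
            assert np.allclose(f.values, 4.2)

    def test_single_element_returned_unchanged(self):
        feats = [DEFeature(values=np.ones((2, 2)))]
        out = lds_smooth(feats)
        assert len(out) == 1 and np.array_equal(out[0].values, feats[0].values)

    def test_step_response_matches_map_oracle(self):
        """The posterior mean equals the MAP solution of the random-walk
        objective sum (y-x)^2/r + sum (dx)^2/q — a tridiagonal solve."""
        y = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0])
        q, r = 1e-3, 1e-1
        feats = [DEFeature(values=np.array([[v]])) for v in y]
        smoothed = np.array([f.values[0, 0]
                             for f in lds_smooth(feats, LDSConfig(q=q, r=r))])
        T = len(y)
        ab = np.zeros((3, T))
        ab[1] = 1.0 / r + 2.0 / q
        ab[1, 0] = ab[1, -1] = 1.0 / r + 1.0 / q
        ab[0, 1:] = ab[2, :-1] = -1.0 / q
        oracle = solve_banded((1, 1), ab, y / r)
        assert np.allclose(smoothed, oracle, atol=1e-10)
        # and the expected qualitative behaviour across the step
        assert (smoothed > 0).all() and (smoothed < 10).all()
        assert np.all(np.diff(smoothed) > 0)

    def test_reduces_noise_around_constant(self, rng):
        truth = 2.0
        feats = [DEFeature(values=truth + 0.5 * rng.standard_normal((3, 5)))
                 for _ in range(40)]
        out = lds_smooth(feats, LDSConfig(q=1e-3, r=1e-1))
        mse_before = np.mean([(f.values - truth) ** 2 for f in feats])
        mse_after = np.mean([(f.values - truth) ** 2 for f in out])
        assert mse_after < mse_before

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LDSConfig(q=0.0)
        with pytest.raises(ValueError):
            LDSConfig(r=-1.0)


class TestTopoMap:
    def test_constant_field_gives_constant_image(self, layout62, channel_names62):
        feat = DEFeature(values=np.full((62, 5), 3.0))
        norm = np.tile([[2.0, 4.0]], (5, 1))      # symmetric around 3.0
        tm = make_topomap(feat, layout62, channel_names62, norm)
        assert np.allclose(tm.image, 0.5, atol=1e-6)

    def test_linear_field_reproduced_in_interior(self, layout62, channel_names62):
        pts = layout62.coords(channel_names62)
        feat = DEFeature(values=np.tile(pts[:, 0][:, None], (1, 5)))
        tm = make_topomap(feat, layout62, channel_names62, UNIT_NORM)
        gx, gy = layout62.grid_axes()
        xx, yy = np.meshgrid(gx, gy)
        inside = Delaunay(pts).find_simplex(np.c_[xx.ravel(), yy.ravel()]) >= 0
        err = np.abs(tm.image[0].ravel()[inside] - xx.ravel()[inside])
        assert err.max() < 1e-6

    def test_pixel_on_electrode_reproduces_value(self, rng, layout62, channel_names62):
        g = np.linspace(0, 1, 32)
        positions = dict(layout62.positions)
        positions[channel_names62[0]] = (g[10], 1.0 - g[7])
        layout = ElectrodeLayout(positions)
        vals = rng.uniform(0.2, 0.8, 62)
        tm = make_topomap(DEFeature(values=np.tile(vals[:, None], (1, 5))),
                          layout, channel_names62, UNIT_NORM)
        assert abs(tm.image[0][7, 10] - vals[0]) < 1e-6

    def test_permutation_equivariance(self, rng, layout62, channel_names62):
        vals = rng.uniform(0, 1, (62, 5))
        perm = rng.permutation(62)
        names_p = [channel_names62[i] for i in perm]
        a = make_topomap(DEFeature(values=vals), layout62, channel_names62, UNIT_NORM)
        b = make_topomap(DEFeature(values=vals[perm]), layout62, names_p, UNIT_NORM)
        assert np.allclose(a.image, b.image, atol=1e-12)

    def test_degenerate_band_maps_to_zero(self, layout62, channel_names62):
        feat = DEFeature(values=np.full((62, 5), 1.0))
        tm = make_topomap(feat, layout62, channel_names62)  # own min == max
        assert np.allclose(tm.image, 0.0)

    def test_collinear_layout_rejected(self):
        layout = ElectrodeLayout({f"c{i}": (0.1 * i, 0.5) for i in range(5)})
        with pytest.raises(LayoutError):
            make_topomap(DEFeature(values=np.ones((5, 5))), layout,
                         [f"c{i}" for i in range(5)], UNIT_NORM)


class TestStandardMontage:
    CHANNELS = ["FP1", "FP2", "F7", "F3", "FZ", "F4", "F8", "T7", "C3", "CZ",
                "C4", "T8", "P7", "P3", "PZ", "P4", "P8", "O1", "OZ", "O2"]

    def test_projected_positions_are_plausible(self):
        mne = pytest.importorskip("mne")  # noqa: F841  (optional extra)
        from eegaug.features import standard_montage_layout

        layout = standard_montage_layout(self.CHANNELS)
        pts = layout.coords(self.CHANNELS)
        assert ((pts >= 0.0) & (pts <= 1.0)).all()
        pos = dict(zip(self.CHANNELS, pts))
        # anterior electrodes toward y=1, occipital toward y=0, left at low x
        assert pos["FP1"][1] > pos["O1"][1]
        assert pos["F7"][0] < pos["F8"][0]
        assert abs(pos["CZ"][0] - 0.5) < 0.1 and abs(pos["CZ"][1] - 0.5) < 0.1

    def test_unknown_electrode_raises_named_error(self):
        pytest.importorskip("mne")
        from eegaug.features import standard_montage_layout

        with pytest.raises(LayoutError, match="CB1"):
            standard_montage_layout(["FP1", "CB1"])


class TestSessionPipeline:
    def _segments(self, rng, n=8):
        out = []
        for _ in range(n):
            out.append(EEGSegment(
                data=rng.standard_normal((62, 400)), fs=200.0,
                channel_names=tuple(f"ch{i:02d}" for i in range(62))))
        return out

    def test_length_and_determinism(self, rng, layout62):
        segs = self._segments(rng)
        maps1, norm1 = topomaps_from_session(segs, layout62)
        maps2, norm2 = topomaps_from_session(segs, layout62)
        assert len(maps1) == len(segs)
        assert np.array_equal(norm1, norm2)
        for a, b in zip(maps1, maps2):
            assert np.array_equal(a.image, b.image)

    def test_normalizer_spans_unit_interval(self, rng, layout62):
        """Per band, the session maps cover [0, 1] when the normalizer comes
        from that session — up to the offset between the extreme electrode
        and its nearest pixel center (grid resolution 1/31)."""
        maps, _ = topomaps_from_session(self._segments(rng), layout62)
        stack = np.stack([m.image for m in maps])
        assert stack.min() >= 0.0 and stack.max() <= 1.0
        for b in range(5):
            assert stack[:, b].min() == pytest.approx(0.0, abs=0.05)
            assert stack[:, b].max() == pytest.approx(1.0, abs=0.05)

    def test_inconsistent_channels_rejected(self, rng, layout62):
        segs = self._segments(rng, n=3)
        bad = EEGSegment(data=rng.standard_normal((3, 400)), fs=200.0,
                         channel_names=("a", "b", "c"))
        with pytest.raises(ValueError):
            topomaps_from_session(segs + [bad], layout62)
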