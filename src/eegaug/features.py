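"""Differential-entropy (DE) features and topographic map images from EEG.

The feature pipeline is: cut EEG into fixed windows, estimate per-band
signal variance from short-time Fourier power (Welch averaging with Hann
windows, 50% overlap), convert to differential entropy

    h = 1/2 * ln(2 * pi * e * sigma^2)          [nats]

per channel and band, temporally smooth each channel x band trajectory
with a random-walk linear dynamic system, and render each smoothed feature
vector as a stack of interpolated scalp images (default 5 bands x 32 x 32,
min-max scaled to [0, 1]) — the sample space of the generative model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.interpolate import CloughTocher2DInterpolator, NearestNDInterpolator

#: Five classical EEG rhythms (Hz): delta, theta, alpha, beta, gamma.
DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 14.0),
    ("beta", 14.0, 31.0),
    ("gamma", 31.0, 50.0),
)


class InvalidBandError(ValueError):
    pass


@dataclass(frozen=True)
class BandSet:
    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS

    def __post_init__(self):
        for name, lo, hi in self.bands:
            if not lo < hi:
                raise InvalidBandError(f"band {name!r}: need low < high, got {lo}, {hi}")

    def __len__(self):
        return len(self.bands)

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]

    @property
    def highest_edge(self) -> float:
        return max(b[2] for b in self.bands)


@dataclass
class EEGSegment:
    """One fixed-length window of multi-channel EEG (microvolts)."""

    data: np.ndarray          # (n_channels, n_samples)
    fs: float
    channel_names: tuple[str, ...]
    label: int | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        self.channel_names = tuple(self.channel_names)
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("one channel name per data row required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.data.shape[1] < self.fs:
            raise ValueError("segment must span at least one second")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class DEFeature:
    """Per-channel, per-band differential entropy (nats) for one segment."""

    values: np.ndarray        # (n_channels, n_bands)
    segment_index: int = 0
    label: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("DE values must be (n_channels, n_bands)")


def compute_de(segment: EEGSegment, bands: BandSet = BandSet(),
               variance_floor: float = 1e-12,
               window_s: float = 2.0) -> DEFeature:
    """Gaussian differential entropy per channel and band.

    The band variance is the integral of the Welch power spectral density
    (Hann windows of ``window_s`` seconds — capped at the segment length —
    with 50% overlap; mean short-time Fourier power corrected for window
    power) over the band's frequency bins. The 2 s default keeps the
    spectral resolution fine enough that the narrow delta band (1-4 Hz)
    is estimated without material edge-leakage bias. Variances are clamped
    at ``variance_floor`` so silent channels give a finite (very negative)
    entropy instead of -inf.
    """
    nyquist = segment.fs / 2.0
    if bands.highest_edge > nyquist:
        raise InvalidBandError(
            f"band edge {bands.highest_edge} Hz above Nyquist {nyquist} Hz")
    n = segment.data.shape[1]
    nperseg = min(int(round(window_s * segment.fs)), n)
    freqs, psd = signal.welch(segment.data, fs=segment.fs, window="hann",
                              nperseg=nperseg, noverlap=nperseg // 2,
                              detrend="constant", scaling="density", axis=-1)
    df = freqs[1] - freqs[0]
    values = np.empty((segment.n_channels, len(bands)))
    for j, (_, lo, hi) in enumerate(bands.bands):
        sel = (freqs >= lo) & (freqs < hi)
        if not sel.any():
            raise InvalidBandError(
                f"no spectral bins inside [{lo}, {hi}) Hz at fs={segment.fs}")
        var = psd[:, sel].sum(axis=-1) * df
        values[:, j] = 0.5 * np.log(2.0 * np.pi * np.e
                                    * np.maximum(var, variance_floor))
    return DEFeature(values=values, label=segment.label)


# ------------------------------------------------------------- smoothing

@dataclass(frozen=True)
class LDSConfig:
    """Random-walk state-space smoother: state x_t = x_{t-1} + w_t with
    process variance q, observation y_t = x_t + v_t with variance r.
    q << r trusts the trajectory's smoothness over single observations."""

    q: float = 1e-3
    r: float = 1e-1

    def __post_init__(self):
        if self.q <= 0 or self.r <= 0:
            raise ValueError("q and r must be positive")


def lds_smooth(sequence: list[DEFeature],
               config: LDSConfig = LDSConfig()) -> list[DEFeature]:
    """Posterior-mean (Kalman filter + RTS smoother) of each channel x band
    trajectory under the random-walk model, with a diffuse initial state."""
    if len(sequence) == 0:
        raise ValueError("need at least one feature")
    if len(sequence) == 1:
        return [replace(sequence[0])]
    y = np.stack([f.values for f in sequence])       # (T, C, B)
    T = y.shape[0]
    q, r = config.q, config.r
    means = np.empty_like(y)
    variances = np.empty(T)
    # forward filter (diffuse init: posterior after y_0 is y_0 with var r)
    means[0], variances[0] = y[0], r
    for t in range(1, T):
        p_pred = variances[t - 1] + q
        k = p_pred / (p_pred + r)
        means[t] = means[t - 1] + k * (y[t] - means[t - 1])
        variances[t] = (1.0 - k) * p_pred
    # Rauch-Tung-Striebel backward pass
    smoothed = means.copy()
    for t in range(T - 2, -1, -1):
        c = variances[t] / (variances[t] + q)
        smoothed[t] = means[t] + c * (smoothed[t + 1] - means[t])
    return [replace(f, values=smoothed[t]) for t, f in enumerate(sequence)]


# ------------------------------------------------------------- topomaps

class LayoutError(ValueError):
    pass


@dataclass(frozen=True)
class ElectrodeLayout:
    """Planar electrode positions in [0, 1]^2; y = 1 is anterior (nose)."""

    positions: dict[str, tuple[float, float]]
    grid_size: int = 32

    def __post_init__(self):
        pts = list(self.positions.values())
        if len({tuple(np.round(p, 12)) for p in pts}) != len(pts):
            raise LayoutError("electrode positions must be pairwise distinct")

    def coords(self, channel_names) -> np.ndarray:
        missing = [c for c in channel_names if c not in self.positions]
        if missing:
            raise LayoutError(f"no layout position for channels {missing}")
        return np.array([self.positions[c] for c in channel_names])

    def grid_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinates: image row 0 is y = 1 (anterior)."""
        g = self.grid_size
        x = np.linspace(0.0, 1.0, g)
        y = 1.0 - np.linspace(0.0, 1.0, g)
        return x, y


def synthetic_layout(n_channels: int, grid_size: int = 32,
                     radius: float = 0.45) -> ElectrodeLayout:
    """Quasi-uniform sunflower arrangement of n points on a scalp disc.

    Stands in for a measured montage so nothing needs downloading; channel
    names are ``ch00, ch01, ...``.
    """
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(n_channels)
    rr = radius * np.sqrt((k + 0.5) / n_channels)
    th = k * golden
    xs = 0.5 + rr * np.cos(th)
    ys = 0.5 + rr * np.sin(th)
    names = [f"ch{i:02d}" for i in range(n_channels)]
    return ElectrodeLayout(dict(zip(names, zip(xs.tolist(), ys.tolist()))),
                           grid_size=grid_size)


def standard_montage_layout(channel_names, grid_size: int = 32,
                            montage: str = "standard_1005") -> ElectrodeLayout:
    """Planar layout for 10-20-system electrode labels.

    3-D template positions (from mne's built-in montage files) are mapped
    by an azimuthal-equidistant projection about the vertex, then rescaled
    into [0, 1]^2 with the nose toward y = 1.
    """
    import mne  # optional dependency; only needed for real montages

    mont = mne.channels.make_standard_montage(montage)
    pos3d = mont.get_positions()["ch_pos"]
    lookup = {k.upper(): np.asarray(v) for k, v in pos3d.items()}
    missing = [c for c in channel_names if c.upper() not in lookup]
    if missing:
        raise LayoutError(
            f"channels {missing} not in montage {montage!r}; supply a custom "
            "ElectrodeLayout for non-standard electrodes")
    planar = {}
    for c in channel_names:
        x, y, z = lookup[c.upper()]
        rho = np.hypot(x, y)
        theta = np.arctan2(rho, z)          # polar angle from the vertex
        phi = np.arctan2(y, x)              # +y is the nose direction
        planar[c] = (theta * np.cos(phi), theta * np.sin(phi))
    pts = np.array(list(planar.values()))
    center = pts.mean(axis=0)
    scale = np.abs(pts - center).max()
    positions = {c: (0.5 + 0.45 * (p[0] - center[0]) / scale,
                     0.5 + 0.45 * (p[1] - center[1]) / scale)
                 for c, p in planar.items()}
    return ElectrodeLayout(positions, grid_size=grid_size)


@dataclass
class TopoMap:
    """Multi-band scalp image: (n_bands, grid, grid) with pixels in [0, 1]."""

    image: np.ndarray
    label: int | None = None
    normalizer: np.ndarray | None = None   # (n_bands, 2) per-band (min, max)


def _interpolate_band(points: np.ndarray, values: np.ndarray,
                      gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    xx, yy = np.meshgrid(gx, gy)           # yy rows follow image rows
    try:
        ct = CloughTocher2DInterpolator(points, values)
    except Exception as exc:  # qhull failure on degenerate layouts
        raise LayoutError(f"cannot triangulate electrode layout: {exc}") from exc
    img = ct(xx, yy)
    outside = np.isnan(img)
    if outside.any():
        nearest = NearestNDInterpolator(points, values)
        img[outside] = nearest(xx[outside], yy[outside])
    return img


def make_topomap(feature: DEFeature, layout: ElectrodeLayout,
                 channel_names, normalizer: np.ndarray | None = None) -> TopoMap:
    """Interpolate one DE feature onto the scalp grid, band by band.

    Scattered channel values are interpolated with a piecewise-cubic
    (Clough-Tocher) scheme, which reproduces planar fields exactly; pixels
    outside the electrode convex hull take the nearest electrode's value.
    Each band is then min-max scaled to [0, 1] — with the supplied
    dataset-level ``normalizer`` (n_bands, 2) or, failing that, this
    feature's own per-band range. A degenerate band (min == max) maps to
    all zeros.
    """
    points = layout.coords(channel_names)
    gx, gy = layout.grid_axes()
    n_bands = feature.values.shape[1]
    raw = np.stack([_interpolate_band(points, feature.values[:, b], gx, gy)
                    for b in range(n_bands)])
    if normalizer is None:
        normalizer = np.stack([feature.values.min(axis=0),
                               feature.values.max(axis=0)], axis=1)
    normalizer = np.asarray(normalizer, dtype=np.float64)
    image = np.empty_like(raw)
    for b in range(n_bands):
        lo, hi = normalizer[b]
        if hi > lo:
            image[b] = np.clip((raw[b] - lo) / (hi - lo), 0.0, 1.0)
        else:
            image[b] = 0.0
    return TopoMap(image=image.astype(np.float32), label=feature.label,
                   normalizer=normalizer)


def topomaps_from_session(segments: list[EEGSegment],
                          layout: ElectrodeLayout,
                          bands: BandSet = BandSet(),
                          lds: LDSConfig | None = LDSConfig(),
                          ) -> tuple[list[TopoMap], np.ndarray]:
    """Full per-session pipeline: DE -> LDS smoothing -> shared-scale maps.

    The per-band (min, max) normalizer is computed over the whole session's
    smoothed features so every map shares one scale; it is returned so test
    sessions can be rendered on the training scale.
    """
    if not segments:
        raise ValueError("empty session")
    names = segments[0].channel_names
    if any(s.channel_names != names for s in segments):
        raise ValueError("inconsistent channel sets across segments")
    feats = [compute_de(s, bands) for s in segments]
    for i, f in enumerate(feats):
        f.segment_index = i
    if lds is not None:
        feats = lds_smooth(feats, lds)
    stacked = np.stack([f.values for f in feats])      # (T, C, B)
    normalizer = np.stack([stacked.min(axis=(0, 1)),
                           stacked.max(axis=(0, 1))], axis=1)
    maps = [make_topomap(f, layout, names, normalizer) for f in feats]
    return maps, normalizer
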