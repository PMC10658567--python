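"""Activation mapping: beat segmentation, (dV/dt)max detection, isochrones,
time-lapse frames, conduction velocity, and earliest-activation origin.

Activation time per channel is the instant of steepest *negative* slope of
the unipolar electrogram within a beat window (the unipolar convention for
"(dV/dt)max"; a strict |dV/dt| mode is available and coincides on the
simulator's wavelet).  Isochrone maps divide the total activation time —
(max − min) over valid channels — into 15 equal segments, colour convention
early = red, late = blue.  Local conduction velocity comes from a
least-squares plane fit T(x, y) = a + b·x + c·y over each electrode's
neighbourhood: |∇T| is the slowness, so CV = 1/√(b² + c²) in m/s (mm/ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InvalidArgumentError
from .layout import AdjacencyGraph, ElectrodeLayout, build_adjacency
from .recording import ElectrogramRecording

__all__ = [
    "ActivationMap",
    "IsochroneMap",
    "ConductionVelocityMap",
    "OriginEstimate",
    "segment_beats",
    "detect_activation",
    "build_isochrones",
    "activation_frames",
    "estimate_cv",
    "localize_origin",
]

COLOR_CONVENTION = "early=red late=blue"


@dataclass(frozen=True)
class ActivationMap:
    """Per-channel activation times for one beat."""

    beat_index: int
    channel_ids: np.ndarray
    times_ms: np.ndarray          # NaN where invalid
    slope_mv_per_ms: np.ndarray   # magnitude of the extremal derivative
    valid: np.ndarray

    def __post_init__(self) -> None:
        if not np.any(self.valid):
            raise InvalidArgumentError("activation map needs >= 1 valid channel")

    @property
    def time_range_ms(self) -> tuple[float, float]:
        t = self.times_ms[self.valid]
        return float(np.min(t)), float(np.max(t))


@dataclass(frozen=True)
class IsochroneMap:
    """15-band (default) quantization of an activation map."""

    edges_ms: np.ndarray        # n_bands + 1 monotone edges
    band: np.ndarray            # per-channel band index, -1 where invalid
    n_bands: int
    degenerate: bool            # all valid times equal: everything in band 0
    color_convention: str = COLOR_CONVENTION


@dataclass(frozen=True)
class ConductionVelocityMap:
    channel_ids: np.ndarray
    cv_m_per_s: np.ndarray       # NaN where the local fit failed
    direction: np.ndarray        # (n, 3) unit propagation direction, NaN rows invalid
    valid: np.ndarray
    mean_m_per_s: float
    sd_m_per_s: float


@dataclass(frozen=True)
class OriginEstimate:
    channel_id: int
    position_mm: np.ndarray
    time_ms: float


def segment_beats(
    rec: ElectrogramRecording,
    min_separation_ms: float = 250.0,
    rel_threshold: float = 0.2,
    floor_mv: float = 1e-6,
) -> list[tuple[float, float]]:
    """Beat windows (start, end in ms) from the global deflection-energy
    envelope: mean squared signal over channels, smoothed over 25 ms; peaks
    are beats, window boundaries sit at midpoints between adjacent peaks.
    """
    env = np.mean(rec.signals**2, axis=0)
    win = max(1, int(round(0.025 * rec.sample_rate)))
    env = np.convolve(env, np.ones(win) / win, mode="same")
    peak = float(env.max())
    if peak < floor_mv**2:
        return []
    distance = max(1, int(round(min_separation_ms / 1000.0 * rec.sample_rate)))
    idx, _ = sps.find_peaks(env, height=rel_threshold * peak, distance=distance)
    if idx.size == 0:
        return []
    t = idx / rec.sample_rate * 1000.0
    bounds = np.concatenate([[0.0], (t[1:] + t[:-1]) / 2.0, [rec.n_samples / rec.sample_rate * 1000.0]])
    return [(float(bounds[i]), float(bounds[i + 1])) for i in range(t.size)]


def detect_activation(
    rec: ElectrogramRecording,
    window_ms: tuple[float, float],
    polarity: str = "steepest_negative",
    beat_index: int = 0,
    invalid_channels: set | None = None,
) -> ActivationMap:
    """(dV/dt)max activation detection within one beat window.

    The derivative is the central difference of the (already filtered)
    trace; ties break to the earliest sample.  Channels flagged bad
    upstream carry no time.
    """
    if polarity not in ("steepest_negative", "steepest_absolute"):
        raise InvalidArgumentError(f"unknown polarity {polarity!r}")
    fs = rec.sample_rate
    a = max(0, int(math.floor(window_ms[0] / 1000.0 * fs)))
    b = min(rec.n_samples, int(math.ceil(window_ms[1] / 1000.0 * fs)) + 1)
    if b - a < 3:
        raise InvalidArgumentError("beat window must span at least 3 samples")
    seg = rec.signals[:, a:b]
    deriv = np.gradient(seg, axis=1) * fs / 1000.0  # mV/ms
    score = deriv if polarity == "steepest_negative" else -np.abs(deriv)
    pick = np.argmin(score, axis=1)  # first occurrence on ties -> earliest
    times = (a + pick) / fs * 1000.0
    slope = np.abs(deriv[np.arange(rec.n_channels), pick])

    bad = invalid_channels or set()
    valid = np.array([cid not in bad for cid in rec.channel_ids])
    times = np.where(valid, times, np.nan)
    slope = np.where(valid, slope, np.nan)
    return ActivationMap(
        beat_index=beat_index,
        channel_ids=rec.channel_ids.copy(),
        times_ms=times,
        slope_mv_per_ms=slope,
        valid=valid,
    )


def build_isochrones(amap: ActivationMap, n_bands: int = 15) -> IsochroneMap:
    """Quantize activation times into ``n_bands`` equal time segments.

    Edges are ``linspace(min, max, n_bands + 1)``; the channel at exactly
    the max time belongs to the last band.  An all-equal map collapses to a
    single band and is flagged degenerate.
    """
    if n_bands < 1:
        raise InvalidArgumentError("n_bands must be >= 1")
    tmin, tmax = amap.time_range_ms
    band = np.full(amap.times_ms.size, -1, dtype=int)
    if tmax == tmin:
        edges = np.full(n_bands + 1, tmin)
        band[amap.valid] = 0
        return IsochroneMap(edges_ms=edges, band=band, n_bands=n_bands, degenerate=True)
    edges = np.linspace(tmin, tmax, n_bands + 1)
    t = amap.times_ms[amap.valid]
    idx = np.minimum(
        np.floor((t - tmin) / (tmax - tmin) * n_bands).astype(int), n_bands - 1
    )
    band[amap.valid] = idx
    return IsochroneMap(edges_ms=edges, band=band, n_bands=n_bands, degenerate=False)


def activation_frames(amap: ActivationMap, interval_ms: float) -> list[np.ndarray]:
    """Time-lapse frames: frame k holds the channels activating in
    ``[min + k·interval, min + (k+1)·interval)`` (the channel at exactly the
    max time joins the last frame).  Frames partition the valid channels;
    the 5 and 10 ms intervals reproduce the time-lapse views of sequential
    vs fibrillatory activation.
    """
    if interval_ms <= 0:
        raise InvalidArgumentError("frame interval must be positive")
    tmin, tmax = amap.time_range_ms
    span = tmax - tmin
    n_frames = max(1, int(math.ceil(span / interval_ms - 1e-12)))
    t = amap.times_ms
    frames = []
    for k in range(n_frames):
        lo = tmin + k * interval_ms
        hi = tmin + (k + 1) * interval_ms
        sel = amap.valid & (t >= lo) & ((t < hi) | ((k == n_frames - 1) & (t <= tmax)))
        frames.append(amap.channel_ids[sel])
    return frames


def _tangent_basis(points: np.ndarray) -> np.ndarray:
    """Two orthonormal in-plane directions from the local point cloud."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[:2]


def estimate_cv(
    amap: ActivationMap,
    layout: ElectrodeLayout,
    graph: AdjacencyGraph | None = None,
    radius_mm: float | None = None,
    min_neighbors: int = 3,
) -> ConductionVelocityMap:
    """Local plane-fit conduction velocity at every channel.

    The neighbourhood is the channel plus its graph neighbours (default
    8-neighbour grid adjacency) or all channels within ``radius_mm``.
    Channels whose neighbourhood has < ``min_neighbors`` valid neighbours,
    is collinear, or yields a vanishing gradient are skipped.
    """
    if graph is None and radius_mm is None:
        graph = build_adjacency(layout, "grid8" if layout.has_grid else "knn")
    ids = layout.channel_ids
    n = ids.size
    cv = np.full(n, np.nan)
    direction = np.full((n, 3), np.nan)
    valid_amap = {int(c): t for c, t, v in zip(amap.channel_ids, amap.times_ms, amap.valid) if v}

    for j, cid in enumerate(ids):
        if int(cid) not in valid_amap:
            continue
        if radius_mm is not None:
            d = np.linalg.norm(layout.positions - layout.positions[j], axis=1)
            neigh = [int(c) for c in ids[(d > 0) & (d <= radius_mm)]]
        else:
            neigh = [int(c) for c in graph.neighbors(int(cid))]
        neigh = [c for c in neigh if c in valid_amap]
        if len(neigh) < min_neighbors:
            continue
        members = [int(cid)] + neigh
        midx = layout.index_of(np.array(members))
        pts = layout.positions[midx]
        basis = _tangent_basis(pts)
        uv = (pts - pts[0]) @ basis.T
        # non-collinearity: the projected neighbourhood must be 2-D
        centered = uv - uv.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[1] <= 1e-8 * max(sv[0], 1e-12):
            continue
        tvals = np.array([valid_amap[c] for c in members])
        A = np.column_stack([np.ones(len(members)), uv])
        coef, *_ = np.linalg.lstsq(A, tvals, rcond=None)
        grad = coef[1:]  # ms/mm slowness vector
        gnorm = float(np.linalg.norm(grad))
        if gnorm < 1e-9:
            continue
        cv[j] = 1.0 / gnorm  # mm/ms == m/s
        d3 = (grad / gnorm) @ basis
        direction[j] = d3 / np.linalg.norm(d3)

    ok = np.isfinite(cv)
    if not np.any(ok):
        raise InvalidArgumentError("no channel had a usable CV neighbourhood")
    return ConductionVelocityMap(
        channel_ids=ids.copy(),
        cv_m_per_s=cv,
        direction=direction,
        valid=ok,
        mean_m_per_s=float(np.mean(cv[ok])),
        sd_m_per_s=float(np.std(cv[ok])),
    )


def localize_origin(
    amap: ActivationMap,
    layout: ElectrodeLayout,
    graph: AdjacencyGraph | None = None,
) -> OriginEstimate:
    """Earliest-activation site (focal/PVC/VT origin).

    Ties at the minimum time break toward the channel whose neighbours lag
    it the most — the truer source of a spreading wavefront.
    """
    t = amap.times_ms
    tmin = np.nanmin(t[amap.valid])
    cand = np.flatnonzero(amap.valid & (t == tmin))
    if cand.size > 1:
        if graph is None:
            graph = build_adjacency(layout, "grid8" if layout.has_grid else "knn")
        tmap = {int(c): tt for c, tt, v in zip(amap.channel_ids, t, amap.valid) if v}
        best, best_delay = cand[0], -np.inf
        for j in cand:
            cid = int(amap.channel_ids[j])
            lags = [tmap[c] - tmin for c in graph.neighbors(cid) if int(c) in tmap]
            delay = np.mean(lags) if lags else -np.inf
            if delay > best_delay:
                best_delay, best = delay, j
    else:
        best = cand[0]
    cid = int(amap.channel_ids[best])
    return OriginEstimate(
        channel_id=cid,
        position_mm=layout.positions[layout.index_of(cid)].copy(),
        time_ms=float(t[best]),
    )
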