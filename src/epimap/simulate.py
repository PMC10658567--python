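"""Synthetic multichannel electrograms with known ground truth.

The generator stands in for in vivo / ex vivo recordings that cannot be
shipped: it renders unipolar electrogram fixtures for every mapped rhythm
(sinus plane waves, paced retrograde spread, conduction block around an
ablation lesion, ischemic slow zones, focal ectopy, and fibrillatory
signals with a spatially varying dominant frequency), plus optional
far-field ventricular contamination and additive noise.

Wavefront model
---------------
Activation spreads as a multi-source shortest path over the electrode
adjacency graph: the travel time of an edge is its Euclidean length divided
by the harmonic mean of the endpoint conduction velocities (1 mm/ms =
1 m/s), so a slow zone behaves as a resistive region in either traversal
direction.  Lesion electrodes are removed from the graph before the search;
electrodes cut off entirely are flagged unreachable.  This geodesic model
reproduces plane waves, retrograde paced spread, detours around a lesion
and ischemic slowing without committing to tissue-level physics.  On an
8-neighbour grid the graph metric exceeds the Euclidean one by at most a
factor ``2/(sqrt(2)+... )`` ~ 8% for propagation directions midway between
an axis and a diagonal; line sources along a grid edge (the sinus default)
are free of this error.

Waveform model
--------------
Each activation contributes a Gaussian-derivative deflection

    V(t) = -A * ((t - t0)/sigma) * exp(-(t - t0)^2 / (2 sigma^2))

whose steepest *negative* slope falls exactly at ``t0``, so derivative-based
activation detection recovers the ground-truth time by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .errors import ConfigurationError, InvalidArgumentError, InvalidScenarioError
from .layout import AdjacencyGraph, ElectrodeLayout, build_adjacency, grid_layout
from .recording import ElectrogramRecording

__all__ = [
    "Source",
    "PropagationScenario",
    "DFField",
    "GroundTruth",
    "geodesic_activation_times",
    "deflection_waveform",
    "render_recording",
    "af_recording",
    "default_layout",
    "sinus_scenario",
    "focal_scenario",
    "paced_scenario",
    "slow_zone_cv",
    "snr_noise_rms",
    "FarField",
    "qrst_template",
]

# Fixture defaults mirroring the mapped hardware: 16x16 array, 3.5 mm pitch,
# 2048 Hz acquisition, sinus at 114 beats/min with CV 1.04 m/s.
DEFAULT_SAMPLE_RATE_HZ = 2048.0
DEFAULT_SPACING_MM = 3.5
DEFAULT_SIGMA_MS = 2.0
DEFAULT_AMPLITUDE_MV = 1.0
DEFAULT_SINUS_RATE_BPM = 114.0
DEFAULT_CV_M_PER_S = 1.04
_BEAT_MARGIN_MS = 150.0  # lead-in before the first beat


def default_layout() -> ElectrodeLayout:
    """The default whole-chamber fixture array: 16 x 16 at 3.5 mm."""
    return grid_layout(16, 16, DEFAULT_SPACING_MM)


@dataclass(frozen=True)
class Source:
    """A wavefront origin: an electrode id (or 3-vector, snapped to the
    nearest electrode) firing at ``onset_ms`` after each beat."""

    location: int | tuple | np.ndarray
    onset_ms: float = 0.0


@dataclass(frozen=True)
class PropagationScenario:
    """Generative description of one rhythm on one array."""

    sources: tuple = ()
    cv_m_per_s: float | np.ndarray = DEFAULT_CV_M_PER_S
    lesions: frozenset = frozenset()
    rate_bpm: float = DEFAULT_SINUS_RATE_BPM
    n_beats: int | None = None
    rhythm: str = "sinus"  # sinus | paced | focal | fibrillatory

    def __post_init__(self) -> None:
        if self.rate_bpm <= 0:
            raise InvalidArgumentError("beat rate must be positive")
        cv = np.asarray(self.cv_m_per_s, dtype=float)
        if np.any(cv <= 0):
            raise InvalidArgumentError("conduction velocities must be positive")
        if self.rhythm != "fibrillatory" and len(self.sources) == 0:
            raise InvalidArgumentError(
                f"{self.rhythm!r} rhythm needs at least one source"
            )
        object.__setattr__(self, "sources", tuple(self.sources))
        object.__setattr__(self, "lesions", frozenset(int(c) for c in self.lesions))

    def cv_per_channel(self, layout: ElectrodeLayout) -> np.ndarray:
        cv = np.asarray(self.cv_m_per_s, dtype=float)
        if cv.ndim == 0:
            return np.full(layout.n_channels, float(cv))
        if cv.shape != (layout.n_channels,):
            raise InvalidArgumentError("per-channel CV field must match layout")
        return cv


@dataclass(frozen=True)
class DFField:
    """Per-channel target dominant frequency (Hz) for fibrillatory fixtures."""

    df_hz: np.ndarray
    jitter: float = 0.1  # relative SD of inter-deflection intervals

    def __post_init__(self) -> None:
        df = np.asarray(self.df_hz, dtype=float)
        if np.any(df <= 0) or not np.all(np.isfinite(df)):
            raise InvalidArgumentError("dominant frequencies must be positive")
        if self.jitter < 0:
            raise InvalidArgumentError("jitter must be >= 0")
        object.__setattr__(self, "df_hz", df)


@dataclass
class GroundTruth:
    """What the pipeline is expected to recover from a fixture."""

    activation_ms: np.ndarray | None = None   # (n_beats, n_channels); NaN unreachable
    beat_times_ms: np.ndarray | None = None
    cv_m_per_s: np.ndarray | None = None
    source_channels: np.ndarray | None = None
    unreachable: np.ndarray | None = None
    farfield_beat_times_ms: np.ndarray | None = None
    df_hz: np.ndarray | None = None
    deflection_times_ms: dict = field(default_factory=dict)  # AF: per-channel trains


def _snap_source(layout: ElectrodeLayout, src: Source, lesions: frozenset) -> int:
    if np.ndim(src.location) == 0:
        cid = int(src.location)
        layout.index_of(cid)  # raises on unknown id
    else:
        p = np.asarray(src.location, dtype=float)
        cid = int(layout.channel_ids[np.argmin(np.linalg.norm(layout.positions - p, axis=1))])
    if cid in lesions:
        raise InvalidScenarioError(f"source channel {cid} lies on a lesion")
    return cid


def geodesic_activation_times(
    layout: ElectrodeLayout,
    graph: AdjacencyGraph,
    scenario: PropagationScenario,
) -> tuple[np.ndarray, np.ndarray]:
    """Multi-source shortest-path arrival time per channel.

    Returns ``(times_ms, reachable)`` aligned with ``layout.channel_ids``;
    lesion, inactive and cut-off channels carry NaN and ``reachable=False``.
    """
    cv = scenario.cv_per_channel(layout)
    lesions = scenario.lesions
    keep = np.array(
        [cid in set(graph.channel_ids) and cid not in lesions for cid in layout.channel_ids]
    )
    node_ids = layout.channel_ids[keep]
    id_set = set(node_ids)
    emask = np.array([(a in id_set) and (b in id_set) for a, b in graph.edges])
    sub = AdjacencyGraph(
        channel_ids=node_ids,
        edges=graph.edges[emask],
        lengths=graph.lengths[emask],
    )
    # edge travel time (ms) = length / harmonic mean of endpoint CVs (mm/ms)
    cv_by_id = dict(zip(layout.channel_ids, cv))
    va = np.array([cv_by_id[a] for a, b in sub.edges])
    vb = np.array([cv_by_id[b] for a, b in sub.edges])
    hmean = 2.0 * va * vb / (va + vb)
    weights = sub.lengths / hmean
    mat = sub.to_sparse(weights=weights)

    src_ids = [_snap_source(layout, s, lesions) for s in scenario.sources]
    onsets = np.array([s.onset_ms for s in scenario.sources], dtype=float)
    lut = {cid: i for i, cid in enumerate(sub.channel_ids)}
    src_idx = []
    for cid in src_ids:
        if cid not in lut:
            raise InvalidScenarioError(f"source channel {cid} is not in the graph")
        src_idx.append(lut[cid])

    dist = dijkstra(mat, directed=False, indices=src_idx)
    arrival_sub = np.min(dist + onsets[:, None], axis=0)

    times = np.full(layout.n_channels, np.nan)
    reachable = np.zeros(layout.n_channels, dtype=bool)
    for cid, t in zip(sub.channel_ids, arrival_sub):
        if np.isfinite(t):
            j = layout.index_of(int(cid))
            times[j] = t
            reachable[j] = True
    return times, reachable


def deflection_waveform(
    t_ms: np.ndarray, t0_ms: float, sigma_ms: float, amplitude_mv: float
) -> np.ndarray:
    """Gaussian-derivative unipolar deflection, steepest negative slope at t0."""
    if sigma_ms <= 0:
        raise InvalidArgumentError("sigma must be positive")
    u = (np.asarray(t_ms, dtype=float) - t0_ms) / sigma_ms
    return -amplitude_mv * u * np.exp(-0.5 * u * u)


@dataclass(frozen=True)
class FarField:
    """Shared ventricular QRS-T contamination of every channel.

    One broad template (QRS-like biphasic deflection followed by a smooth
    T hump) is rendered at its own beat schedule and added to each channel
    scaled by ``scale`` (scalar, or per-channel array), emulating far-field
    ventricular signal on atrial electrodes.  The clean template train is
    also exposed as the recording's reference lead.
    """

    rate_bpm: float = 72.0
    scale: float | np.ndarray = 0.5
    amplitude_mv: float = 2.0
    offset_ms: float = 80.0  # shifts the ventricular schedule off the atrial one


def qrst_template(t_ms: np.ndarray, t0_ms: float, amplitude_mv: float = 2.0) -> np.ndarray:
    """Far-field ventricular complex: broad QRS-like biphasic deflection at
    ``t0`` plus a T-like hump ~160 ms later."""
    qrs = deflection_waveform(t_ms, t0_ms, sigma_ms=12.0, amplitude_mv=amplitude_mv)
    u = (np.asarray(t_ms, dtype=float) - t0_ms - 160.0) / 35.0
    t_wave = 0.35 * amplitude_mv * np.exp(-0.5 * u * u)
    return qrs + t_wave


def snr_noise_rms(clean_signals: np.ndarray, snr_db: float) -> float:
    """Noise RMS giving the requested SNR against the clean fixture."""
    sig_rms = float(np.sqrt(np.mean(clean_signals**2)))
    return sig_rms / (10.0 ** (snr_db / 20.0))


def _check_resolution(sample_rate: float, sigma_ms: float) -> None:
    if sigma_ms * sample_rate / 1000.0 < 2.0:
        raise ConfigurationError(
            f"sample rate {sample_rate} Hz cannot resolve sigma={sigma_ms} ms "
            "(need sigma >= 2 samples)"
        )


def render_recording(
    layout: ElectrodeLayout,
    scenario: PropagationScenario,
    sample_rate: float = DEFAULT_SAMPLE_RATE_HZ,
    duration_s: float = 2.0,
    noise_rms: float = 0.0,
    farfield: FarField | None = None,
    seed: int = 0,
    sigma_ms: float = DEFAULT_SIGMA_MS,
    amplitude_mv: float = DEFAULT_AMPLITUDE_MV,
    graph: AdjacencyGraph | None = None,
) -> tuple[ElectrogramRecording, GroundTruth]:
    """Render a beat-scheduled rhythm fixture with full ground truth.

    The per-beat activation time of each channel is the beat time plus its
    geodesic arrival; each activation contributes one deflection.  Output is
    deterministic for a fixed seed.
    """
    _check_resolution(sample_rate, sigma_ms)
    if graph is None:
        graph = build_adjacency(layout, "grid8" if layout.has_grid else "knn")
    tau, reachable = geodesic_activation_times(layout, graph, scenario)

    duration_ms = duration_s * 1000.0
    period_ms = 60_000.0 / scenario.rate_bpm
    tau_max = float(np.nanmax(tau)) if np.any(reachable) else 0.0
    tail_ms = tau_max + 4.0 * sigma_ms
    n_fit = int(np.floor((duration_ms - _BEAT_MARGIN_MS - tail_ms) / period_ms)) + 1
    n_beats = scenario.n_beats if scenario.n_beats is not None else n_fit
    if n_beats < 1 or n_fit < 1:
        raise InvalidArgumentError(
            f"duration {duration_s} s too short for one beat at {scenario.rate_bpm} bpm"
        )
    beat_times = _BEAT_MARGIN_MS + np.arange(n_beats) * period_ms

    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * sample_rate))
    t = np.arange(n_samples) / sample_rate * 1000.0
    signals = np.zeros((layout.n_channels, n_samples))
    activation = np.full((n_beats, layout.n_channels), np.nan)
    for b, bt in enumerate(beat_times):
        activation[b, reachable] = bt + tau[reachable]
        for j in np.flatnonzero(reachable):
            signals[j] += deflection_waveform(t, bt + tau[j], sigma_ms, amplitude_mv)

    reference = None
    ff_beats = None
    if farfield is not None:
        ff_period = 60_000.0 / farfield.rate_bpm
        ff_beats = farfield.offset_ms + np.arange(
            max(1, int(np.floor((duration_ms - farfield.offset_ms - 350.0) / ff_period)) + 1)
        ) * ff_period
        template_train = np.zeros(n_samples)
        for bt in ff_beats:
            template_train += qrst_template(t, bt, farfield.amplitude_mv)
        scale = np.broadcast_to(
            np.asarray(farfield.scale, dtype=float), (layout.n_channels,)
        )
        signals += scale[:, None] * template_train[None, :]
        reference = template_train.copy()

    if noise_rms > 0:
        signals = signals + rng.normal(0.0, noise_rms, size=signals.shape)

    rec = ElectrogramRecording(
        sample_rate=sample_rate,
        signals=signals,
        channel_ids=layout.channel_ids,
        reference=reference,
    )
    truth = GroundTruth(
        activation_ms=activation,
        beat_times_ms=beat_times,
        cv_m_per_s=scenario.cv_per_channel(layout),
        source_channels=np.array(
            [_snap_source(layout, s, scenario.lesions) for s in scenario.sources]
        ),
        unreachable=~reachable,
        farfield_beat_times_ms=ff_beats,
    )
    return rec, truth


def af_recording(
    layout: ElectrodeLayout,
    df_field: DFField,
    sample_rate: float = DEFAULT_SAMPLE_RATE_HZ,
    duration_s: float = 8.0,
    amplitude_scale: float = 0.3,
    seed: int = 0,
    sigma_ms: float = DEFAULT_SIGMA_MS,
    noise_rms: float = 0.0,
) -> tuple[ElectrogramRecording, GroundTruth]:
    """Fibrillatory fixture: per-channel jittered deflection trains.

    Each channel fires independently at its target dominant frequency with
    relative interval jitter, at amplitudes scaled down versus sinus
    fixtures — low-amplitude, high-rate, spatially incoherent activity whose
    local rate the frequency pipeline must recover.  No coherent wavefront
    is rendered; AF physics (re-entry, wavebreak) is out of scope.
    """
    _check_resolution(sample_rate, sigma_ms)
    df = df_field.df_hz
    if df.shape != (layout.n_channels,):
        raise InvalidArgumentError("DF field must give one frequency per channel")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * sample_rate))
    t = np.arange(n_samples) / sample_rate * 1000.0
    amplitude = amplitude_scale * DEFAULT_AMPLITUDE_MV
    signals = np.zeros((layout.n_channels, n_samples))
    trains: dict[int, np.ndarray] = {}
    n_clipped = 0
    for j, cid in enumerate(layout.channel_ids):
        mean_interval = 1000.0 / df[j]
        times = []
        tt = 4.0 * sigma_ms + rng.uniform(0.0, mean_interval)
        while tt < duration_s * 1000.0 - 4.0 * sigma_ms:
            times.append(tt)
            interval = mean_interval * (1.0 + df_field.jitter * rng.standard_normal())
            if interval <= 0.25 * mean_interval:
                interval = 0.25 * mean_interval
                n_clipped += 1
            tt += interval
        times = np.asarray(times)
        trains[int(cid)] = times
        # deflection-to-deflection variability bounded above so the fixture
        # peak-to-peak never exceeds amplitude_scale x the sinus amplitude
        amp = amplitude * rng.uniform(0.6, 1.0, times.size)
        for t0, a in zip(times, amp):
            signals[j] += deflection_waveform(t, t0, sigma_ms, a)
    if n_clipped:
        warnings.warn(
            f"{n_clipped} inter-deflection intervals clipped to stay positive",
            stacklevel=2,
        )
    if noise_rms > 0:
        signals = signals + rng.normal(0.0, noise_rms, size=signals.shape)
    rec = ElectrogramRecording(
        sample_rate=sample_rate, signals=signals, channel_ids=layout.channel_ids
    )
    truth = GroundTruth(df_hz=df.copy(), deflection_times_ms=trains)
    return rec, truth


# --------------------------------------------------------------- scenarios
def sinus_scenario(
    layout: ElectrodeLayout,
    cv_m_per_s: float | np.ndarray = DEFAULT_CV_M_PER_S,
    rate_bpm: float = DEFAULT_SINUS_RATE_BPM,
    edge: str = "left",
) -> PropagationScenario:
    """Sinus-like plane wave entering from one border of a grid array.

    The whole edge fires simultaneously (a line source), so propagation is a
    plane wave orthogonal to that border — the activation pattern seen in
    normal sinus rhythm sweeping across a mapped chamber.
    """
    if not layout.has_grid:
        raise ConfigurationError("sinus plane-wave scenario needs a grid layout")
    sel = {
        "left": layout.cols == layout.cols.min(),
        "right": layout.cols == layout.cols.max(),
        "top": layout.rows == layout.rows.min(),
        "bottom": layout.rows == layout.rows.max(),
    }[edge]
    sources = tuple(Source(int(c)) for c in layout.channel_ids[sel])
    return PropagationScenario(
        sources=sources, cv_m_per_s=cv_m_per_s, rate_bpm=rate_bpm, rhythm="sinus"
    )


def focal_scenario(
    layout: ElectrodeLayout,
    channel: int,
    cv_m_per_s: float | np.ndarray = DEFAULT_CV_M_PER_S,
    rate_bpm: float = DEFAULT_SINUS_RATE_BPM,
) -> PropagationScenario:
    """Focal ectopy (PVC-like): a single-electrode origin."""
    return PropagationScenario(
        sources=(Source(int(channel)),),
        cv_m_per_s=cv_m_per_s,
        rate_bpm=rate_bpm,
        rhythm="focal",
    )


def paced_scenario(
    layout: ElectrodeLayout,
    pair: tuple[int, int],
    cv_m_per_s: float | np.ndarray = DEFAULT_CV_M_PER_S,
    rate_bpm: float = 150.0,
) -> PropagationScenario:
    """Bipolar pacing through two adjacent electrodes (retrograde spread)."""
    return PropagationScenario(
        sources=(Source(int(pair[0])), Source(int(pair[1]))),
        cv_m_per_s=cv_m_per_s,
        rate_bpm=rate_bpm,
        rhythm="paced",
    )


def slow_zone_cv(
    layout: ElectrodeLayout,
    baseline_m_per_s: float,
    center_mm,
    radius_mm: float,
    factor: float,
) -> np.ndarray:
    """Per-channel CV field with an ischemic slow zone: channels within
    ``radius_mm`` of ``center_mm`` conduct at ``factor`` x baseline."""
    if factor <= 0:
        raise InvalidArgumentError("slow-zone factor must be positive")
    cv = np.full(layout.n_channels, float(baseline_m_per_s))
    d = np.linalg.norm(layout.positions - np.asarray(center_mm, float), axis=1)
    cv[d <= radius_mm] *= factor
    return cv
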