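"""Pulse isolation, pairwise TDoA estimation, and in-plane bearing inference.

The bio-logger carries three hydrophones in an "L" on one plane.  A distant
transient (a sperm whale click) reaches the hydrophones with relative delays
set by the source direction; under the far-field plane-wave assumption the
delay between hydrophones i and j for a source at in-plane azimuth θ is

    τ_ij(θ) = u(θ)·(p_i − p_j) / c

with u(θ) the unit vector toward the source (0° along the tag-frame +x axis,
counter-clockwise) and c the sound speed.  The pipeline is: detect pulses on
a reference channel from a robust envelope threshold, estimate each pair's
delay by the peak of the normalized cross-correlation over physically
feasible lags, then find the azimuth minimizing the sum of squared delay
residuals.  With only two hydrophones (or any collinear layout) the solution
is mirror-ambiguous about the baseline and both candidates are reported.

Because delays are quantized to the sample clock, a geometry has a finite
expected angular resolution: for each pair, the feasible integer lags k map
to angles asin(k·c/(fs·d)) and the mean adjacent spacing of those angles —
averaged over pairs — is the resolution returned by
`expected_angular_resolution`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import butter, correlate, correlation_lags, hilbert, sosfiltfilt

from .audio import MultichannelAudio

__all__ = [
    "ArrayGeometry",
    "PulseEvent",
    "TdoaSet",
    "BearingEstimate",
    "InfeasibleDelayError",
    "DegeneratePairError",
    "default_l_array",
    "envelope",
    "isolate_pulses",
    "estimate_tdoa",
    "solve_bearing",
    "expected_angular_resolution",
]

_COLLINEAR_TOL_M = 1e-9


class InfeasibleDelayError(ValueError):
    """One or more delays exceed what the geometry can physically produce."""


class DegeneratePairError(ValueError):
    """A hydrophone pair too closely spaced to resolve even one sample of lag."""


@dataclass(frozen=True)
class ArrayGeometry:
    """Planar hydrophone positions (metres, tag frame, origin at hydrophone 1)
    together with the sound speed and sample rate used for delay math."""

    positions: np.ndarray
    sound_speed_m_s: float = 1491.2
    sample_rate_sps: float = 96_000.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 2:
            raise ValueError("positions must be an (n>=2, 2) array of planar coordinates")
        object.__setattr__(self, "positions", pos)
        for i, j in combinations(range(len(pos)), 2):
            if np.linalg.norm(pos[i] - pos[j]) == 0.0:
                raise ValueError(f"hydrophones {i} and {j} are coincident")
        if self.sound_speed_m_s <= 0 or self.sample_rate_sps <= 0:
            raise ValueError("sound speed and sample rate must be positive")

    @property
    def n_hydrophones(self) -> int:
        return len(self.positions)

    def pairs(self) -> list[tuple[int, int]]:
        return list(combinations(range(self.n_hydrophones), 2))

    def baseline(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.positions[i] - self.positions[j]))

    @property
    def max_baseline(self) -> float:
        return max(self.baseline(i, j) for i, j in self.pairs())

    @property
    def collinear(self) -> bool:
        """True when every hydrophone lies within 1e-9 m of one line."""
        pos = self.positions
        if len(pos) == 2:
            return True
        d = pos[1] - pos[0]
        d = d / np.linalg.norm(d)
        offsets = (pos - pos[0]) @ np.array([-d[1], d[0]])
        return bool(np.max(np.abs(offsets)) < _COLLINEAR_TOL_M)

    def baseline_angle_deg(self) -> float:
        """Orientation of the first baseline, for mirror reflections."""
        d = self.positions[1] - self.positions[0]
        return math.degrees(math.atan2(d[1], d[0]))

    def max_lag_samples(self, i: int, j: int) -> int:
        return int(math.ceil(self.baseline(i, j) / self.sound_speed_m_s * self.sample_rate_sps)) + 2

    def predicted_delays(self, azimuth_deg: float) -> dict[tuple[int, int], float]:
        """Plane-wave delays τ_ij (s) for a source at the given azimuth."""
        u = _unit_vector(azimuth_deg)
        return {
            (i, j): float(u @ (self.positions[i] - self.positions[j])) / self.sound_speed_m_s
            for i, j in self.pairs()
        }


def default_l_array(
    arm_m: float = 0.125, sound_speed_m_s: float = 1491.2, sample_rate_sps: float = 96_000.0
) -> ArrayGeometry:
    """Default three-element L: arms of ``arm_m`` along +x and +y from the
    origin hydrophone.  Arm length is a configuration value — the deployed
    device's exact spacing is not public — chosen at the scale of the tag."""
    positions = np.array([[0.0, 0.0], [arm_m, 0.0], [0.0, arm_m]])
    return ArrayGeometry(positions, sound_speed_m_s, sample_rate_sps)


@dataclass
class PulseEvent:
    """One detected transient: onset on the reference channel plus the
    analysis window (half-open sample interval) used for correlation."""

    onset_sample: int
    window: tuple[int, int]
    peak_envelope: float
    channel_onsets: dict[int, int] | None = None

    def __post_init__(self) -> None:
        start, end = self.window
        if not start <= self.onset_sample < end:
            raise ValueError("onset must lie inside the window")


@dataclass
class TdoaSet:
    """Pairwise delays τ_ij in seconds (positive when channel j receives
    later) with their normalized correlation peaks."""

    delays: dict[tuple[int, int], float]
    correlation_peaks: dict[tuple[int, int], float] = field(default_factory=dict)

    def delay(self, i: int, j: int) -> float:
        if (i, j) in self.delays:
            return self.delays[(i, j)]
        if (j, i) in self.delays:
            return -self.delays[(j, i)]
        raise KeyError((i, j))


@dataclass
class BearingEstimate:
    azimuth_deg: float
    residual_s2: float
    ambiguous: bool = False
    mirror_azimuth_deg: float | None = None


def _unit_vector(azimuth_deg: float) -> np.ndarray:
    a = math.radians(azimuth_deg)
    return np.array([math.cos(a), math.sin(a)])


def envelope(x: np.ndarray, sample_rate_sps: float, method: str = "analytic", smooth_s: float = 0.5e-3) -> np.ndarray:
    """Amplitude envelope: |analytic signal| (default) or rectify-and-smooth,
    both followed by a moving average of ``smooth_s`` seconds."""
    x = np.asarray(x, dtype=float)
    if method == "analytic":
        env = np.abs(hilbert(x))
    elif method == "rectify":
        env = np.abs(x)
    else:
        raise ValueError(f"unknown envelope method {method!r}")
    n = max(1, int(round(smooth_s * sample_rate_sps)))
    if n > 1:
        kernel = np.ones(n) / n
        env = np.convolve(env, kernel, mode="same")
    return env


def isolate_pulses(
    audio: MultichannelAudio,
    threshold_k: float = 12.0,
    min_separation_s: float = 10e-3,
    window_s: float = 10e-3,
    channel: int = 0,
    envelope_method: str = "analytic",
    band_hz: tuple[float, float] | None = (2000.0, 20000.0),
    smooth_s: float = 0.2e-3,
) -> list[PulseEvent]:
    """Detect pulse onsets on the reference channel.

    The channel is band-pass filtered to the click band (zero-phase
    Butterworth; ``band_hz=None`` disables) before envelope extraction, the
    usual first stage of a click detector since it rejects out-of-band noise
    without shifting onsets.  The onset is the first sample whose envelope
    exceeds a robust threshold, median + ``threshold_k`` × MAD of the
    envelope; onsets closer than ``min_separation_s`` are merged into the
    first.  The analysis window spans 1 ms before the onset to ``window_s``
    after it, which comfortably exceeds twice the geometric delay of a
    tag-scale array.
    """
    if threshold_k <= 0:
        raise ValueError("threshold_k must be positive")
    if audio.n_frames == 0:
        return []
    fs = audio.sample_rate_sps
    x = audio.samples[channel].astype(float)
    if np.ptp(x) == 0.0:
        return []  # constant signal (silence or DC) has no pulses
    if band_hz is not None and audio.n_frames > 32:
        lo, hi = band_hz
        sos = butter(4, [lo, min(hi, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
        x = sosfiltfilt(sos, x)
    env = envelope(x, fs, method=envelope_method, smooth_s=smooth_s)
    med = float(np.median(env))
    mad = float(np.median(np.abs(env - med)))
    if mad == 0.0:
        return []  # constant signal (silence or DC) has no pulses
    threshold = med + threshold_k * mad
    above = env > threshold
    onsets = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))

    min_sep = int(round(min_separation_s * fs))
    pre = int(round(1e-3 * fs))
    post = int(round(window_s * fs))
    events: list[PulseEvent] = []
    last_onset = -min_sep - 1
    for onset in onsets:
        if onset - last_onset < min_sep:
            continue
        last_onset = int(onset)
        start = max(0, int(onset) - pre)
        end = min(audio.n_frames, int(onset) + post)
        events.append(
            PulseEvent(int(onset), (start, end), float(env[start:end].max()))
        )
    return events


def _bounded_xcorr(x: np.ndarray, y: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation restricted to |lag| <= max_lag; lag is the
    shift of y relative to x (positive when y lags x)."""
    corr = correlate(y, x, mode="full", method="fft")
    lags = correlation_lags(len(y), len(x), mode="full")
    keep = np.abs(lags) <= max_lag
    norm = math.sqrt(float(np.dot(x, x)) * float(np.dot(y, y)))
    return lags[keep], corr[keep] / norm


def estimate_tdoa(
    audio: MultichannelAudio,
    event: PulseEvent,
    pair: tuple[int, int],
    geometry: ArrayGeometry,
    refine_subsample: bool = False,
    use_envelope: bool = False,
) -> tuple[float, float]:
    """Delay τ_ij (s) and normalized correlation peak for one pulse and pair.

    The delay is the argmax of the normalized cross-correlation over lags
    bounded by the pair's geometric maximum plus two samples.  Ties break
    toward the smallest |lag|, then the negative lag.  Optional parabolic
    interpolation refines the peak below one sample (off by default so that
    one-sample quantization behavior stays observable).
    """
    i, j = pair
    start, end = event.window
    if start < 0 or end > audio.n_frames:
        raise IndexError(f"event window [{start}, {end}) outside audio bounds")
    fs = audio.sample_rate_sps
    x = audio.samples[i, start:end].astype(float)
    y = audio.samples[j, start:end].astype(float)
    if use_envelope:
        x = envelope(x, fs)
        y = envelope(y, fs)
    x = x - x.mean()
    y = y - y.mean()
    ex, ey = float(np.dot(x, x)), float(np.dot(y, y))
    if ex == 0.0 or ey == 0.0:
        raise ValueError("zero-energy window: correlation undefined")
    max_lag = geometry.max_lag_samples(i, j)
    if end - start < 2 * max_lag:
        raise ValueError("window shorter than twice the maximum geometric lag")
    lags, corr = _bounded_xcorr(x, y, max_lag)
    peak = float(corr.max())
    ties = lags[corr == corr.max()]
    order = np.lexsort((ties, np.abs(ties)))  # smallest |lag|, negative first
    best = int(ties[order[0]])
    lag = float(best)
    if refine_subsample:
        k = int(np.flatnonzero(lags == best)[0])
        if 0 < k < len(lags) - 1:
            c_m, c_0, c_p = corr[k - 1], corr[k], corr[k + 1]
            denom = c_m - 2 * c_0 + c_p
            if denom != 0.0:
                lag += 0.5 * (c_m - c_p) / denom
    return lag / fs, peak


def _delay_cost(theta_deg: np.ndarray, tdoas: TdoaSet, geometry: ArrayGeometry) -> np.ndarray:
    theta = np.radians(np.atleast_1d(theta_deg))
    u = np.stack([np.cos(theta), np.sin(theta)], axis=1)  # (m, 2)
    cost = np.zeros(len(theta))
    for (i, j), obs in tdoas.delays.items():
        pred = (u @ (geometry.positions[i] - geometry.positions[j])) / geometry.sound_speed_m_s
        cost += (obs - pred) ** 2
    return cost


def solve_bearing(
    tdoas: TdoaSet, geometry: ArrayGeometry, grid_step_deg: float = 0.1
) -> BearingEstimate:
    """Least-squares in-plane azimuth from a set of pairwise delays.

    A 0.1° grid search locates the global minimum of the summed squared
    delay residuals; golden-section refinement brings it to 0.01°.  For
    collinear geometries (including any two-hydrophone array) the mirror
    solution about the baseline is returned as well, flagged ambiguous.
    """
    if not tdoas.delays:
        raise ValueError("empty TDoA set")
    bad = []
    for (i, j), obs in tdoas.delays.items():
        # accept anything the bounded correlator can report (geometric max
        # plus two samples of search slack); beyond that is unphysical input
        bound = geometry.max_lag_samples(i, j) / geometry.sample_rate_sps
        if abs(obs) > bound + 1e-12:
            bad.append((i, j))
    if bad:
        raise InfeasibleDelayError(f"delays exceed physical bounds for pairs {bad}")

    grid = np.arange(0.0, 360.0, grid_step_deg)
    cost = _delay_cost(grid, tdoas, geometry)
    best = float(grid[int(np.argmin(cost))])
    res = minimize_scalar(
        lambda t: float(_delay_cost(t, tdoas, geometry)[0]),
        bracket=(best - grid_step_deg, best, best + grid_step_deg),
        method="golden",
        options={"xtol": 1e-4},
    )
    azimuth = float(res.x) % 360.0
    residual = float(res.fun)
    if geometry.collinear:
        mirror = (2.0 * geometry.baseline_angle_deg() - azimuth) % 360.0
        return BearingEstimate(azimuth, residual, ambiguous=True, mirror_azimuth_deg=mirror)
    return BearingEstimate(azimuth, residual, ambiguous=False)


def expected_angular_resolution(geometry: ArrayGeometry) -> float:
    """Mean angular step between adjacent feasible one-sample lags, averaged
    over hydrophone pairs (degrees).

    For a pair at spacing d the feasible integer lags satisfy
    |k·c/(fs·d)| <= 1 and map to angles asin(k·c/(fs·d)); the mean adjacent
    spacing of those angles is that pair's single-sample resolution.
    """
    c, fs = geometry.sound_speed_m_s, geometry.sample_rate_sps
    per_pair = []
    for i, j in geometry.pairs():
        d = geometry.baseline(i, j)
        step = c / (fs * d)
        k_max = int(math.floor(1.0 / step))
        if k_max < 1:
            raise DegeneratePairError(
                f"pair ({i}, {j}) spacing {d:.4g} m resolves no lag beyond zero "
                f"(needs d >= c/fs = {c / fs:.4g} m)"
            )
        angles = [math.degrees(math.asin(k * step)) for k in range(-k_max, k_max + 1)]
        diffs = np.abs(np.diff(angles))
        per_pair.append(float(np.mean(diffs)))
    return float(np.mean(per_pair))


def bearing_for_event(
    audio: MultichannelAudio, event: PulseEvent, geometry: ArrayGeometry, **tdoa_kwargs
) -> BearingEstimate:
    """Convenience wrapper: estimate all pairwise delays for one event and
    solve the bearing."""
    delays, peaks = {}, {}
    for pair in geometry.pairs():
        delay, peak = estimate_tdoa(audio, event, pair, geometry, **tdoa_kwargs)
        delays[pair] = delay
        peaks[pair] = peak
    return solve_bearing(TdoaSet(delays, peaks), geometry)
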