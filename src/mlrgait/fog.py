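"""Freezing-of-gait detection from lower-leg signals.

The detector follows the clinically used wearable-sensor approach: the
*freeze ratio* of a window of lower-leg anteroposterior acceleration is
the spectral power in the freeze band (3-10 Hz) divided by the power in
the locomotor band (0-3 Hz), computed with the FFT of the mean-detrended
window. Trembling raises the ratio; normal stepping keeps it low. A
window is FOG-positive when the freeze ratio is high AND the left/right
lower-leg angular velocities are weakly correlated (legs decoupled);
consecutive positive windows merge into episodes, and episodes shorter
than a minimum duration are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FogEpisode",
    "band_power",
    "freeze_ratio",
    "bilateral_correlation",
    "detect_fog",
]


@dataclass
class FogEpisode:
    """One detected freezing episode."""

    start: float  # s
    end: float  # s
    peak_freeze_ratio: float
    mean_correlation: float

    def __post_init__(self):
        if not self.end > self.start >= 0:
            raise ValueError("episode must satisfy end > start >= 0")


def band_power(window: np.ndarray, fs: float, low: float, high: float) -> float:
    """One-sided periodogram power in [low, high) Hz of a detrended window.

    The boundary bin at ``high`` is excluded, so contiguous bands
    partition the spectrum (the 3 Hz bin belongs to the freeze band,
    not the locomotor band).
    """
    w = np.asarray(window, dtype=np.float64)
    w = w - w.mean()  # keep the DC bin from swamping the 0-3 Hz band
    spec = np.abs(np.fft.rfft(w)) ** 2
    freqs = np.fft.rfftfreq(len(w), d=1.0 / fs)
    mask = (freqs >= low) & (freqs < high)
    return float(spec[mask].sum())


def _windows(n: int, window: int, hop: int):
    start = 0
    while start + window <= n:
        yield start, start + window
        start += hop


def freeze_ratio(accel: np.ndarray, fs: float, cfg: dict) -> tuple[np.ndarray, np.ndarray]:
    """Windowed freeze ratio of one acceleration series.

    Returns (window center times, ratio per window). When the locomotor
    band power is below the configured floor the ratio is reported at
    the cap if there is freeze-band power, else 0 (degenerate window,
    e.g. an all-zero signal).
    """
    if fs <= 20.0:
        raise ValueError("sampling rate must exceed 20 Hz")
    accel = np.asarray(accel, dtype=np.float64)
    win = int(round(cfg["window"] * fs))
    hop = max(1, int(round(cfg["hop"] * fs)))
    if win > len(accel):
        raise ValueError("series shorter than one analysis window")
    fb = cfg["freeze_band"]
    lb = cfg["locomotor_band"]
    floor = cfg["power_floor"]
    cap = cfg["ratio_cap"]
    times, ratios = [], []
    for a, b in _windows(len(accel), win, hop):
        w = accel[a:b]
        p_freeze = band_power(w, fs, fb[0], fb[1])
        p_loco = band_power(w, fs, lb[0], lb[1])
        if p_loco < floor:
            r = cap if p_freeze >= floor else 0.0
        else:
            r = min(p_freeze / p_loco, cap)
        times.append((a + b) / 2.0 / fs)
        ratios.append(r)
    return np.asarray(times), np.asarray(ratios)


def bilateral_correlation(left: np.ndarray, right: np.ndarray, fs: float,
                          cfg: dict) -> tuple[np.ndarray, np.ndarray]:
    """Windowed Pearson correlation of left/right angular velocities.

    Zero-variance windows yield a correlation of 0 (degenerate).
    """
    left = np.asarray(left, dtype=np.float64)
    right = np.asarray(right, dtype=np.float64)
    if left.shape != right.shape:
        raise ValueError("left/right series must have equal length")
    win = int(round(cfg["window"] * fs))
    hop = max(1, int(round(cfg["hop"] * fs)))
    if win > len(left):
        raise ValueError("series shorter than one analysis window")
    times, corrs = [], []
    for a, b in _windows(len(left), win, hop):
        lw = left[a:b] - left[a:b].mean()
        rw = right[a:b] - right[a:b].mean()
        denom = np.sqrt((lw**2).sum() * (rw**2).sum())
        r = float((lw * rw).sum() / denom) if denom > 0 else 0.0
        times.append((a + b) / 2.0 / fs)
        corrs.append(r)
    return np.asarray(times), np.asarray(corrs)


def detect_fog(accel_left, accel_right, omega_left, omega_right, fs: float,
               cfg: dict, analysis_window: tuple[float, float] | None = None
               ) -> tuple[list[FogEpisode], bool]:
    """Declare FOG episodes from lower-leg signals.

    A window is FOG-positive when the freeze ratio exceeds the threshold
    and the bilateral correlation falls below its threshold. The per-leg
    ratios are combined according to ``cfg['leg_mode']`` ('max' or
    'mean'). ``is_fog`` is True when any episode intersects
    ``analysis_window`` (default: the whole record).
    """
    t_r, ratio_l = freeze_ratio(accel_left, fs, cfg)
    _, ratio_r = freeze_ratio(accel_right, fs, cfg)
    if cfg.get("leg_mode", "max") == "mean":
        ratio = 0.5 * (ratio_l + ratio_r)
    else:
        ratio = np.maximum(ratio_l, ratio_r)
    _, corr = bilateral_correlation(omega_left, omega_right, fs, cfg)
    positive = (ratio > cfg["freeze_ratio_threshold"]) & (
        np.abs(corr) < cfg["correlation_threshold"]
    )
    # bridge brief negative gaps between positive windows (transient
    # re-correlation inside one freezing episode)
    gap_windows = int(round(cfg.get("merge_gap", 1.0) / cfg["hop"]))
    if gap_windows > 0:
        pos_idx = np.flatnonzero(positive)
        for a, b in zip(pos_idx[:-1], pos_idx[1:]):
            if 1 < b - a <= gap_windows + 1:
                positive[a:b] = True
    half = cfg["window"] / 2.0

    episodes: list[FogEpisode] = []
    i = 0
    while i < len(positive):
        if not positive[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(positive) and positive[j + 1]:
            j += 1
        start = max(0.0, t_r[i] - half)
        end = t_r[j] + half
        if end - start >= cfg["min_episode"]:
            episodes.append(
                FogEpisode(
                    start=start,
                    end=end,
                    peak_freeze_ratio=float(ratio[i : j + 1].max()),
                    mean_correlation=float(corr[i : j + 1].mean()),
                )
            )
        i = j + 1

    if analysis_window is None:
        is_fog = bool(episodes)
    else:
        a, b = analysis_window
        is_fog = any(ep.start < b and ep.end > a for ep in episodes)
    return episodes, is_fog


def detect_fog_trajectory(trajectory, cfg_fog: dict,
                          analysis_window: tuple[float, float] | None = None):
    """Run the detector on a simulated :class:`~mlrgait.simulate.Trajectory`."""
    return detect_fog(
        trajectory.shank_accel[:, 0],
        trajectory.shank_accel[:, 1],
        trajectory.shank_omega[:, 0],
        trajectory.shank_omega[:, 1],
        trajectory.sampling_rate,
        cfg_fog,
        analysis_window=analysis_window,
    )
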