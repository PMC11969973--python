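"""Deterministic synthetic-input generators.

Every downstream stage (FOG detection, clustering, statistics) is
testable without running a simulation: anti-phase sinusoidal "gait"
signals with planted trembling intervals emulate the lower-leg
acceleration/angular-velocity features the detector consumes, and
seeded Gaussian blobs in (s_PPN, s_CnF) space emulate FOG parameter
clusters. All generators are pure functions of their spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import default_config

__all__ = [
    "SignalSpec",
    "BlobSpec",
    "synthetic_gait_signals",
    "synthetic_cluster_points",
    "default_parameters",
]


@dataclass
class SignalSpec:
    """Specification of a synthetic lower-leg signal bundle.

    ``intervals`` entries are (start_s, end_s, tremble_hz, lr_correlation):
    inside each interval the locomotor rhythm is replaced by band-limited
    trembling with the given left/right correlation.
    """

    rate: float = 100.0  # Hz
    duration: float = 15.0  # s
    locomotor_hz: float = 1.0
    locomotor_amp: float = 2.0
    tremble_amp: float = 1.5
    noise_amp: float = 0.0
    intervals: list = field(default_factory=list)
    seed: int = 0

    def validate(self):
        nyq = self.rate / 2.0
        if self.locomotor_hz >= nyq:
            raise ValueError("locomotor frequency above Nyquist")
        for (a, b, f, rho) in self.intervals:
            if not 0 <= a < b <= self.duration:
                raise ValueError("interval outside duration")
            if f >= nyq:
                raise ValueError("tremble frequency above Nyquist")
            if not -1.0 <= rho <= 1.0:
                raise ValueError("correlation must be in [-1, 1]")


@dataclass
class BlobSpec:
    """Gaussian blobs in (s_PPN, s_CnF) in [0, 2]^2 with known labels."""

    centers: list = field(default_factory=lambda: [(0.3, 0.3), (1.6, 1.6)])
    counts: list = field(default_factory=lambda: [20, 20])
    spreads: list = field(default_factory=lambda: [0.08, 0.08])
    seed: int = 0

    def validate(self):
        if not (len(self.centers) == len(self.counts) == len(self.spreads)):
            raise ValueError("centers/counts/spreads must have equal length")
        if any(c < 1 for c in self.counts):
            raise ValueError("counts must be >= 1")
        if any(s <= 0 for s in self.spreads):
            raise ValueError("spreads must be positive")


def _bandlimited(rng, t, f_center, half_width=1.2, n_comp=8):
    """Unit-RMS multi-sine noise confined to a band around f_center (Hz)."""
    lo = max(3.2, f_center - half_width)
    hi = f_center + half_width
    sig = np.zeros_like(t)
    for _ in range(n_comp):
        f = rng.uniform(lo, hi)
        ph = rng.uniform(0, 2 * np.pi)
        sig += np.sin(2 * np.pi * f * t + ph)
    rms = np.sqrt(np.mean(sig**2))
    return sig / rms if rms > 0 else sig


def synthetic_gait_signals(spec: SignalSpec):
    """Generate (t, accel_left, accel_right, omega_left, omega_right, truth).

    Baseline: anti-phase sinusoids at the locomotor frequency (legs
    perfectly out of phase, bilateral correlation -1). Planted intervals
    replace the baseline with trembling at the given frequency whose
    left/right correlation is controlled by mixing a shared and an
    independent component. ``truth`` is the list of planted intervals.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    acc_l = spec.locomotor_amp * np.sin(2 * np.pi * spec.locomotor_hz * t)
    acc_r = spec.locomotor_amp * np.sin(2 * np.pi * spec.locomotor_hz * t + np.pi)
    om_l = acc_l.copy()
    om_r = acc_r.copy()
    for (a, b, f_tremble, rho) in spec.intervals:
        mask = (t >= a) & (t < b)
        # three mutually independent band-limited components (multi-sine
        # noise around the tremble frequency); mixing the shared one with
        # weight sqrt(|rho|) sets the left/right correlation to ~rho
        shared = _bandlimited(rng, t[mask], f_tremble)
        ind_l = _bandlimited(rng, t[mask], f_tremble)
        ind_r = _bandlimited(rng, t[mask], f_tremble)
        w_sh = np.sqrt(abs(rho))
        w_in = np.sqrt(1.0 - abs(rho))
        sgn = 1.0 if rho >= 0 else -1.0
        trem_l = spec.tremble_amp * (w_sh * shared + w_in * ind_l)
        trem_r = spec.tremble_amp * (sgn * w_sh * shared + w_in * ind_r)
        acc_l[mask] = trem_l
        acc_r[mask] = trem_r
        om_l[mask] = trem_l
        om_r[mask] = trem_r
    if spec.noise_amp > 0:
        acc_l = acc_l + spec.noise_amp * rng.standard_normal(n)
        acc_r = acc_r + spec.noise_amp * rng.standard_normal(n)
        om_l = om_l + spec.noise_amp * rng.standard_normal(n)
        om_r = om_r + spec.noise_amp * rng.standard_normal(n)
    truth = [(a, b) for (a, b, _, _) in spec.intervals]
    return t, acc_l, acc_r, om_l, om_r, truth


def synthetic_cluster_points(spec: BlobSpec):
    """Seeded Gaussian blobs clipped to [0, 2]^2 with ground-truth labels."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    points, labels = [], []
    for lab, (center, count, spread) in enumerate(
        zip(spec.centers, spec.counts, spec.spreads), start=1
    ):
        pts = rng.normal(loc=center, scale=spread, size=(count, 2))
        points.append(np.clip(pts, 0.0, 2.0))
        labels.extend([lab] * count)
    return np.vstack(points), np.asarray(labels)


def default_parameters() -> dict:
    """The packaged configuration bundle with every constant at its default.

    Printed model constants carry their published values; unpublished
    quantities are surrogates and are listed under ``surrogates``.
    """
    return default_config()
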