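"""Synthetic surface-EMG generation and window segmentation.

Real forearm recordings behind this pipeline come from an 8-channel
armband sampled at 200 Hz over the 0–100 Hz band.  The generator
emulates the two statistical properties the downstream stages rely on:

* **gesture separability** — each hand gesture activates the eight
  electrode channels with a distinct amplitude pattern, modelled as a
  per-gesture 8-vector of channel RMS amplitudes modulating a
  band-limited (20–95 Hz) Gaussian carrier;
* **fatigue signature** — sustained contraction compresses the power
  spectrum toward lower frequencies while the amplitude rises, modelled
  as a carrier centre frequency that falls and an RMS gain that grows
  with the muscular-condition level (1 = nonfatigue, 2 = transition,
  3 = fatigue).

No power-line component is generated (the emulated recordings are
notch-filtered at source), so no notch stage exists downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy import signal

GESTURES = ("IT-P", "MT-P", "RT-P", "PT-P", "CH")
"""Gesture labels: index/middle/ring/pinkie–thumb pinches and closed hand."""

N_CHANNELS = 8
DEFAULT_FS = 200.0

#: Per-gesture channel RMS amplitude templates (mV).  Each pinch loads a
#: different subset of the circumferential electrodes; the closed hand
#: activates all channels roughly evenly.
GESTURE_TEMPLATES: dict[str, np.ndarray] = {
    "IT-P": np.array([30.0, 22.0, 10.0, 5.0, 4.0, 6.0, 12.0, 18.0]),
    "MT-P": np.array([12.0, 28.0, 25.0, 10.0, 5.0, 4.0, 6.0, 8.0]),
    "RT-P": np.array([5.0, 12.0, 26.0, 28.0, 12.0, 6.0, 4.0, 5.0]),
    "PT-P": np.array([4.0, 6.0, 10.0, 24.0, 30.0, 14.0, 6.0, 4.0]),
    "CH": np.array([20.0, 20.0, 18.0, 18.0, 20.0, 22.0, 20.0, 20.0]),
}

#: Fatigue level -> (carrier centre frequency Hz, RMS amplitude gain).
#: Canonical sEMG fatigue signature: median frequency falls, amplitude rises.
FATIGUE_LEVELS: dict[int, tuple[float, float]] = {
    1: (80.0, 1.0),
    2: (60.0, 1.2),
    3: (45.0, 1.4),
}

FATIGUE_BASE_RMS_MV = 20.0
REST_RMS_MV = 2.0


class ProtocolError(ValueError):
    """Invalid acquisition-protocol or segmentation parameters."""


@dataclass
class EmgRecording:
    """A multichannel sEMG recording with labels.

    Attributes
    ----------
    samples : ndarray, shape (channels, time)
        Signal matrix in mV.
    fs : float
        Sampling rate in Hz.
    gesture : str or None
        One of :data:`GESTURES`, if this is a labelled gesture repetition.
    fatigue_level : int or None
        Muscular-condition level in {1, 2, 3}, if applicable.
    subject_id : str
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    gesture: str | None = None
    fatigue_level: int | None = None
    subject_id: str = "S1"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if np.isnan(self.samples).any():
            raise ValueError("recording contains NaN samples")
        if self.gesture is not None and self.gesture not in GESTURES:
            raise ValueError(f"unknown gesture {self.gesture!r}")
        if self.fatigue_level is not None and self.fatigue_level not in FATIGUE_LEVELS:
            raise ValueError(f"unknown fatigue level {self.fatigue_level!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def to_csv(self, path: str | Path) -> None:
        """Write samples as CSV (one row per time sample, columns ch1..chN)
        with a JSON sidecar carrying fs and labels."""
        path = Path(path)
        cols = [f"ch{i + 1}" for i in range(self.n_channels)]
        pd.DataFrame(self.samples.T, columns=cols).to_csv(path, index=False)
        meta = {
            "fs": self.fs,
            "gesture": self.gesture,
            "fatigue_level": self.fatigue_level,
            "subject_id": self.subject_id,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "EmgRecording":
        path = Path(path)
        frame = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            samples=frame.to_numpy().T,
            fs=float(meta.get("fs", DEFAULT_FS)),
            gesture=meta.get("gesture"),
            fatigue_level=meta.get("fatigue_level"),
            subject_id=meta.get("subject_id", "S1"),
        )


@dataclass
class AcquisitionProtocol:
    """Gesture-acquisition protocol: repetitions x movements x series x subjects.

    Defaults reproduce the emulated study protocol: 10 repetitions of each
    of 5 movements in 5 series by 5 subjects, 2 s per repetition at 200 Hz,
    yielding 1250 recordings (250 per gesture).
    """

    n_repetitions: int = 10
    n_movements: int = 5
    n_series: int = 5
    n_subjects: int = 5
    rep_duration_s: float = 2.0
    fs: float = DEFAULT_FS
    subject_gain_sd: float = 0.10  # inter-subject multiplicative spread
    rep_gain_sd: float = 0.05  # repetition-to-repetition amplitude jitter
    common_noise_rms: float = 2.0  # mV, common-mode noise floor
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_repetitions", "n_movements", "n_series", "n_subjects"):
            if getattr(self, name) < 1:
                raise ProtocolError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_movements > len(GESTURES):
            raise ProtocolError(
                f"n_movements must be <= {len(GESTURES)}, got {self.n_movements}"
            )
        if self.rep_duration_s <= 0 or self.fs <= 0:
            raise ProtocolError("rep_duration_s and fs must be positive")

    @property
    def n_total(self) -> int:
        return self.n_repetitions * self.n_movements * self.n_series * self.n_subjects


@dataclass
class SegmentationSpec:
    """Sliding-window segmentation: window length (s) and fractional overlap."""

    window_s: float
    overlap_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ProtocolError(f"window_s must be positive, got {self.window_s}")
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ProtocolError(
                f"overlap_frac must be in [0, 1), got {self.overlap_frac}"
            )


def _bandlimited_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    fs: float,
    band: tuple[float, float],
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to `band` (Hz), per channel."""
    lo, hi = band
    nyq = fs / 2.0
    sos = signal.butter(4, [lo / nyq, min(hi, nyq * 0.99) / nyq], btype="band", output="sos")
    # pad to let the filter settle, then trim
    pad = int(fs)
    white = rng.standard_normal((n_channels, n_samples + 2 * pad))
    x = signal.sosfilt(sos, white, axis=-1)[:, pad : pad + n_samples]
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def generate_gesture_recording(
    gesture: str,
    rng: np.random.Generator,
    duration_s: float = 2.0,
    fs: float = DEFAULT_FS,
    subject_id: str = "S1",
    subject_gain: np.ndarray | float = 1.0,
    rep_gain_sd: float = 0.05,
    common_noise_rms: float = 2.0,
) -> EmgRecording:
    """One labelled repetition: template-modulated band-limited carrier."""
    if gesture not in GESTURE_TEMPLATES:
        raise ValueError(f"unknown gesture {gesture!r}")
    n = int(round(duration_s * fs))
    if n < 1:
        raise ValueError("duration too short for one sample")
    carrier = _bandlimited_noise(rng, N_CHANNELS, n, fs, (20.0, 95.0))
    rep_gain = 1.0 + rep_gain_sd * rng.standard_normal()
    amps = GESTURE_TEMPLATES[gesture] * np.asarray(subject_gain) * max(rep_gain, 0.1)
    samples = carrier * amps[:, None]
    if common_noise_rms > 0:
        samples = samples + common_noise_rms * rng.standard_normal((N_CHANNELS, n))
    return EmgRecording(samples=samples, fs=fs, gesture=gesture, subject_id=subject_id)


def generate_gesture_dataset(protocol: AcquisitionProtocol) -> list[EmgRecording]:
    """Generate the full labelled gesture dataset.

    Returns one :class:`EmgRecording` per repetition —
    ``n_repetitions * n_movements * n_series * n_subjects`` in total,
    balanced across gestures.  Bit-identical under a fixed protocol seed.
    """
    rng = np.random.default_rng(protocol.seed)
    recordings: list[EmgRecording] = []
    gestures = GESTURES[: protocol.n_movements]
    for s in range(protocol.n_subjects):
        subject_id = f"S{s + 1}"
        subject_gain = np.exp(
            protocol.subject_gain_sd * rng.standard_normal(N_CHANNELS)
        )
        for _series in range(protocol.n_series):
            for gesture in gestures:
                for _rep in range(protocol.n_repetitions):
                    recordings.append(
                        generate_gesture_recording(
                            gesture,
                            rng,
                            duration_s=protocol.rep_duration_s,
                            fs=protocol.fs,
                            subject_id=subject_id,
                            subject_gain=subject_gain,
                            rep_gain_sd=protocol.rep_gain_sd,
                            common_noise_rms=protocol.common_noise_rms,
                        )
                    )
    return recordings


def generate_fatigue_recording(
    level: int,
    duration_s: float,
    seed: int,
    fs: float = DEFAULT_FS,
    base_rms: float = FATIGUE_BASE_RMS_MV,
    band_halfwidth: float = 22.0,
    subject_id: str = "S1",
) -> EmgRecording:
    """Sustained-contraction recording at a given muscular-condition level.

    Higher levels shift the carrier band downward (median-frequency
    decline) and scale the RMS amplitude up, so the three levels are
    separable by the spectral and amplitude fatigue features.
    """
    if level not in FATIGUE_LEVELS:
        raise ValueError(f"fatigue level must be in {sorted(FATIGUE_LEVELS)}, got {level!r}")
    n = int(round(duration_s * fs))
    if n < 1:
        raise ValueError(f"duration_s={duration_s} yields an empty signal")
    centre, gain = FATIGUE_LEVELS[level]
    rng = np.random.default_rng(seed)
    band = (max(centre - band_halfwidth, 1.0), min(centre + band_halfwidth, fs / 2 * 0.99))
    carrier = _bandlimited_noise(rng, N_CHANNELS, n, fs, band)
    samples = carrier * (base_rms * gain)
    return EmgRecording(
        samples=samples, fs=fs, fatigue_level=level, subject_id=subject_id
    )


def generate_rest_recording(
    duration_s: float, seed: int, fs: float = DEFAULT_FS, rms: float = REST_RMS_MV
) -> EmgRecording:
    """Low-amplitude rest recording used for the CFM rest baseline."""
    n = int(round(duration_s * fs))
    if n < 1:
        raise ValueError("duration too short for one sample")
    rng = np.random.default_rng(seed)
    samples = rms * _bandlimited_noise(rng, N_CHANNELS, n, fs, (20.0, 95.0))
    return EmgRecording(samples=samples, fs=fs, subject_id="rest")


def segment(recording: EmgRecording, spec: SegmentationSpec) -> list[np.ndarray]:
    """Split a recording into channels x window_samples views.

    Window count is ``floor((N - W) / step) + 1`` with ``W = window_s * fs``
    and ``step = round(W * (1 - overlap_frac))``; trailing samples that do
    not fill a window are dropped.
    """
    w = int(round(spec.window_s * recording.fs))
    n = recording.n_samples
    if w > n:
        raise ProtocolError(
            f"window of {w} samples longer than signal of {n} samples"
        )
    step = max(int(round(w * (1.0 - spec.overlap_frac))), 1)
    starts = range(0, n - w + 1, step)
    return [recording.samples[:, s : s + w] for s in starts]
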