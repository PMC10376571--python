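"""Time- and frequency-domain sEMG features and normalization.

Two feature vectors are produced:

* the **gesture vector** (length 40): five time-domain kernels — MAV,
  WAMP, VAR, WL, ZC — per channel, ordered feature-major
  ``[MAV x 8ch, WAMP x 8ch, VAR x 8ch, WL x 8ch, ZC x 8ch]``;
* the **fatigue vector** ψ (length 100): nine per-channel features
  ``[ACNI, ZC, MTW-Hamming, MTW-Trapezoidal, MTW-Slepian, CFM, ASD,
  MNF, MDF]`` feature-major over 8 channels, plus 28 muscle-coactivation
  ratios (pairwise channel RMS ratios, unordered pairs m < j).

VAR is the raw second moment Σx²/(N−1) — deliberately not mean-centred;
pass ``centered=True`` for the textbook sample variance.  The power rate
(PR) is computed by :func:`spectral_features` but is not part of ψ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
import json
from pathlib import Path

import numpy as np
from scipy import integrate
from scipy import signal as sps

N_CHANNELS = 8
GESTURE_FEATURES = ("MAV", "WAMP", "VAR", "WL", "ZC")
FATIGUE_FEATURES = (
    "ACNI",
    "ZC",
    "MTW_hamming",
    "MTW_trapezoidal",
    "MTW_slepian",
    "CFM",
    "ASD",
    "MNF",
    "MDF",
)

WAMP_THRESHOLD_MV = 5.0
FATIGUE_ZC_THRESHOLD_MV = 5.0
_POWER_FLOOR = 1e-12


def _as_window(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty window")
    return x


# ---------------------------------------------------------------------------
# Gesture (time-domain) kernels
# ---------------------------------------------------------------------------

def mav(x) -> float:
    """Mean absolute value: (1/N) Σ|xᵢ|."""
    return float(np.mean(np.abs(_as_window(x))))


def wamp(x, threshold_mV: float = WAMP_THRESHOLD_MV) -> int:
    """Willison amplitude: number of consecutive-sample jumps |xᵢ − xᵢ₊₁|
    at or above the threshold (default 5 mV)."""
    x = _as_window(x)
    if x.size < 2:
        raise ValueError(f"WAMP needs at least 2 samples, got {x.size}")
    return int(np.count_nonzero(np.abs(np.diff(x)) >= threshold_mV))


def var(x, centered: bool = False) -> float:
    """Signal power Σxᵢ²/(N−1); with ``centered=True`` the mean is removed
    first (textbook sample variance)."""
    x = _as_window(x)
    if x.size < 2:
        raise ValueError(f"VAR needs at least 2 samples, got {x.size}")
    if centered:
        x = x - x.mean()
    return float(np.sum(x**2) / (x.size - 1))


def wl(x) -> float:
    """Waveform length: Σ|xᵢ₊₁ − xᵢ|."""
    x = _as_window(x)
    return float(np.sum(np.abs(np.diff(x))))


def zc_gesture(x) -> int:
    """Zero crossings: count of strict sign alternations
    (xᵢ₊₁ > 0 and xᵢ < 0, or xᵢ₊₁ < 0 and xᵢ > 0)."""
    x = _as_window(x)
    return int(np.count_nonzero(x[:-1] * x[1:] < 0))


def extract_gesture_features(
    window: np.ndarray, wamp_threshold_mV: float = WAMP_THRESHOLD_MV
) -> np.ndarray:
    """40-element gesture vector from an 8 x W window (feature-major)."""
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if window.shape[0] != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS} channels, got {window.shape[0]}")
    blocks = [
        [mav(ch) for ch in window],
        [wamp(ch, wamp_threshold_mV) for ch in window],
        [var(ch) for ch in window],
        [wl(ch) for ch in window],
        [zc_gesture(ch) for ch in window],
    ]
    return np.concatenate([np.asarray(b, dtype=float) for b in blocks])


def gesture_feature_names(n_channels: int = N_CHANNELS) -> list[str]:
    return [f"{f}_ch{c + 1}" for f in GESTURE_FEATURES for c in range(n_channels)]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationParams:
    """Per-feature min/max learned on training data for [0,1] rescaling."""

    xmin: np.ndarray
    xmax: np.ndarray

    def __post_init__(self) -> None:
        self.xmin = np.asarray(self.xmin, dtype=float)
        self.xmax = np.asarray(self.xmax, dtype=float)
        if self.xmin.shape != self.xmax.shape:
            raise ValueError("xmin/xmax shape mismatch")
        if np.any(self.xmax < self.xmin):
            raise ValueError("xmax must be >= xmin")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"xmin": self.xmin.tolist(), "xmax": self.xmax.tolist()})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationParams":
        d = json.loads(Path(path).read_text())
        return cls(xmin=np.array(d["xmin"]), xmax=np.array(d["xmax"]))


def minmax_normalize(
    X: np.ndarray, params: NormalizationParams | None = None
) -> tuple[np.ndarray, NormalizationParams]:
    """Min–max rescale each feature column to [0, 1]: (x − xmin)/(xmax − xmin).

    When ``params`` is given (test-set use) it is applied unchanged, so
    out-of-range test values may fall outside [0, 1].  Constant training
    columns map to 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("need at least one observation")
    if params is None:
        params = NormalizationParams(xmin=X.min(axis=0), xmax=X.max(axis=0))
    elif params.xmin.size != X.shape[1]:
        raise ValueError(
            f"params have {params.xmin.size} features, data has {X.shape[1]}"
        )
    span = params.xmax - params.xmin
    safe = np.where(span > 0, span, 1.0)
    Xn = (X - params.xmin) / safe
    Xn[:, span == 0] = 0.0
    return Xn, params


def zscore(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Standardize to zero mean, unit population std; constant input → zeros."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    return np.divide(x - mu, sd, out=np.zeros_like(x, dtype=float), where=sd > 0)


# ---------------------------------------------------------------------------
# Fatigue kernels
# ---------------------------------------------------------------------------

def acni(x, fs: float) -> float:
    """Cumulative trapezoidal integration of the signal, scaled by 1/N,
    with uniform sample spacing 1/fs."""
    x = _as_window(x)
    if x.size < 2:
        raise ValueError("ACNI needs at least 2 samples")
    return float(integrate.trapezoid(x, dx=1.0 / fs) / x.size)


def zc_fatigue(x, threshold_mV: float = FATIGUE_ZC_THRESHOLD_MV) -> int:
    """Thresholded zero crossings: sign changes whose consecutive-sample
    amplitude difference is at least the threshold."""
    x = _as_window(x)
    if x.size < 2:
        raise ValueError("ZC needs at least 2 samples")
    sign_change = x[:-1] * x[1:] < 0
    big_enough = np.abs(np.diff(x)) >= threshold_mV
    return int(np.count_nonzero(sign_change & big_enough))


def _trapezoid_window(n: int, ramp_frac: float = 0.1) -> np.ndarray:
    ramp = max(int(round(n * ramp_frac)), 1)
    idx = np.arange(n, dtype=float)
    return np.clip(np.minimum(idx / ramp, (n - 1 - idx) / ramp), 0.0, 1.0)


def mtw(x, kind: str, squared_weights: bool = False) -> float:
    """Multiple-time-window energy of the signal under a taper.

    kind ∈ {"hamming", "trapezoidal", "slepian"}.  The Hamming variant
    squares the weighted samples, Σ(Wᵢxᵢ)²; the trapezoidal and Slepian
    variants weight the squared samples, ΣWᵢxᵢ².  ``squared_weights=True``
    forces Σ(Wᵢxᵢ)² for every taper (the 6-feature variant).
    """
    x = _as_window(x)
    n = x.size
    if kind == "hamming":
        w = sps.windows.hamming(n, sym=True)
        return float(np.sum((w * x) ** 2))
    if kind == "trapezoidal":
        w = _trapezoid_window(n)
    elif kind == "slepian":
        w = sps.windows.dpss(n, NW=2.5)
        w = w / w.max()
    else:
        raise ValueError(f"unknown MTW kind {kind!r}")
    if squared_weights:
        return float(np.sum((w * x) ** 2))
    return float(np.sum(w * x**2))


def vrms(x) -> float:
    """Root-mean-square amplitude."""
    x = _as_window(x)
    return float(np.sqrt(np.mean(x**2)))


def cfm(x, rest_vrms: float) -> float:
    """Contraction force measure: window RMS over rest RMS."""
    if rest_vrms <= 0:
        raise ValueError(f"rest baseline VRMS must be positive, got {rest_vrms}")
    return vrms(x) / rest_vrms


def spectral_features(x, fs: float) -> tuple[float, float, float, float]:
    """(ASD, MNF, MDF, PR) from the periodogram of the window.

    The spectrum is a Hamming-tapered periodogram over the positive
    (non-DC) frequency bins, M of them.  ASD = (1/M) ΣPⱼ;
    MNF = ΣfⱼPⱼ / ΣPⱼ; MDF is the frequency at which cumulative power
    first reaches half the total; PR = max(P)/min(P) with the denominator
    floored at 1e-12.
    """
    x = _as_window(x)
    if x.size < 4:
        raise ValueError("spectral features need at least 4 samples")
    f, p = sps.periodogram(x, fs=fs, window="hamming")
    f, p = f[1:], p[1:]  # drop DC
    total = float(np.sum(p))
    asd = float(np.mean(p))
    if total <= 0:
        return asd, 0.0, 0.0, 1.0
    mnf = float(np.sum(f * p) / total)
    mdf = float(f[min(np.searchsorted(np.cumsum(p), total / 2.0), f.size - 1)])
    pr = float(np.max(p) / max(np.min(p), _POWER_FLOOR))
    return asd, mnf, mdf, pr


def mca_pairs(n_channels: int = N_CHANNELS) -> list[tuple[int, int]]:
    """Unordered channel pairs (m < j) for the coactivation block."""
    return list(combinations(range(n_channels), 2))


def extract_fatigue_features(
    window: np.ndarray,
    rest_baseline: np.ndarray,
    fs: float,
    zc_threshold_mV: float = FATIGUE_ZC_THRESHOLD_MV,
) -> np.ndarray:
    """100-element fatigue vector ψ from an 8 x W window.

    ``rest_baseline`` is the per-channel RMS of a designated rest
    recording; it must be strictly positive (CFM is undefined otherwise).
    Layout: 9 per-channel features feature-major (ACNI_ch1..8, ..., MDF_ch1..8)
    followed by the 28 coactivation ratios VRMS(m)/VRMS(j), m < j.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if window.shape[0] != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS} channels, got {window.shape[0]}")
    rest_baseline = np.asarray(rest_baseline, dtype=float).ravel()
    if rest_baseline.size != N_CHANNELS:
        raise ValueError("rest_baseline must give one VRMS per channel")
    if np.any(rest_baseline <= 0):
        raise ValueError("rest baseline VRMS must be strictly positive (CFM undefined)")

    per_channel = np.empty((len(FATIGUE_FEATURES), N_CHANNELS))
    rms = np.empty(N_CHANNELS)
    for c, ch in enumerate(window):
        asd, mnf, mdf, _pr = spectral_features(ch, fs)
        per_channel[:, c] = [
            acni(ch, fs),
            zc_fatigue(ch, zc_threshold_mV),
            mtw(ch, "hamming"),
            mtw(ch, "trapezoidal"),
            mtw(ch, "slepian"),
            cfm(ch, rest_baseline[c]),
            asd,
            mnf,
            mdf,
        ]
        rms[c] = vrms(ch)
    mca = np.array([rms[m] / rms[j] for m, j in mca_pairs()])
    return np.concatenate([per_channel.ravel(), mca])


def fatigue_feature_names(n_channels: int = N_CHANNELS) -> list[str]:
    names = [f"{f}_ch{c + 1}" for f in FATIGUE_FEATURES for c in range(n_channels)]
    names += [f"MCA_ch{m + 1}_ch{j + 1}" for m, j in mca_pairs(n_channels)]
    return names


def feature_matrix_to_csv(X: np.ndarray, names: list[str], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(np.atleast_2d(X), columns=names).to_csv(path, index=False)
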