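"""Signal conditioning and windowing for wrist accelerometer recordings.

A recording is 50 Hz triaxial acceleration in m/s^2 with optional
per-sample label tracks (rest/non-rest, tremor/non-tremor, unknown).
Windows are 128 samples (2.56 s) with 50% overlap. Two model input
representations are produced per window:

* ``raw384`` — the per-axis 0.5-10 Hz band-passed signal, affinely mapped
  from the sensor full scale (+/-2 g = +/-19.6133 m/s^2) to [0, 1];
* ``fft64`` — one-sided magnitude bins 1..64 (DC dropped, 2/N scaling) of
  the 128-point DFT of the band-passed Euclidean-norm signal.

The Euclidean norm is taken on the *raw* axes (gravity included) and the
band-pass is then applied to that scalar channel. Gravity acts as a
carrier: the norm of gravity-plus-tremor keeps the tremor oscillation at
its physical frequency, whereas the norm of zero-mean filtered axes would
rectify it to twice the frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = [
    "POSITIVE", "NEGATIVE", "UNKNOWN", "INVALID", "FULL_SCALE_MS2",
    "Recording", "Window", "bandpass", "bandpass_signal", "euclidean_norm",
    "make_windows", "assign_window_label", "fft_representation",
    "normalize_raw", "threshold_prelabel", "WindowSet", "build_window_set",
]

# per-sample track codes / window label codes
POSITIVE = 1
NEGATIVE = 0
UNKNOWN = -1   # per-sample only
INVALID = -1   # window label: discarded for the corresponding task

#: sensor full scale, 2 g with g = 9.80665 m/s^2
FULL_SCALE_MS2 = 19.6133

WINDOW_SAMPLES = 128
WINDOW_STRIDE = 64


@dataclass
class Recording:
    """One subject-visit of triaxial acceleration with optional label tracks."""
    subject_id: str
    visit_id: str
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sample_rate_hz: float = 50.0
    rest_labels: np.ndarray | None = None
    tremor_labels: np.ndarray | None = None

    def __post_init__(self):
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise ValueError("axes must have equal length")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        for name in ("rest_labels", "tremor_labels"):
            track = getattr(self, name)
            if track is not None:
                track = np.asarray(track, dtype=np.int8)
                if len(track) != len(self.ax):
                    raise ValueError(f"{name} length does not match signal")
                setattr(self, name, track)

    @property
    def n_samples(self) -> int:
        return len(self.ax)

    @property
    def xyz(self) -> np.ndarray:
        return np.stack([self.ax, self.ay, self.az], axis=1)


@dataclass
class Window:
    start_index: int
    filtered_xyz: np.ndarray   # (128, 3), m/s^2, band-passed per axis
    norm_signal: np.ndarray    # (128,), m/s^2, band-passed norm channel
    rest_label: int = INVALID
    tremor_label: int = INVALID

    @property
    def rest_valid(self) -> bool:
        return self.rest_label != INVALID

    @property
    def tremor_valid(self) -> bool:
        return self.tremor_label != INVALID


def bandpass_signal(x: np.ndarray, sample_rate_hz: float, low_hz: float = 0.5,
                    high_hz: float = 10.0, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the first axis."""
    nyq = sample_rate_hz / 2.0
    if not 0.0 < low_hz < high_hz < nyq:
        raise ValueError(f"band ({low_hz}, {high_hz}) Hz outside (0, {nyq}) Hz")
    b, a = butter(order, [low_hz / nyq, high_hz / nyq], btype="bandpass")
    return filtfilt(b, a, np.asarray(x, dtype=float), axis=0)


def bandpass(recording: Recording, low_hz: float = 0.5, high_hz: float = 10.0,
             order: int = 3) -> Recording:
    """Band-pass each axis of a recording; labels carried over unchanged."""
    return replace(
        recording,
        ax=bandpass_signal(recording.ax, recording.sample_rate_hz, low_hz, high_hz, order),
        ay=bandpass_signal(recording.ay, recording.sample_rate_hz, low_hz, high_hz, order),
        az=bandpass_signal(recording.az, recording.sample_rate_hz, low_hz, high_hz, order),
    )


def euclidean_norm(window_xyz: np.ndarray) -> np.ndarray:
    """Per-sample magnitude sqrt(ax^2 + ay^2 + az^2)."""
    arr = np.asarray(window_xyz, dtype=float)
    return np.sqrt(np.sum(arr * arr, axis=-1))


def assign_window_label(per_sample_track: np.ndarray,
                        window_samples: int = WINDOW_SAMPLES) -> int:
    """Strict-majority window label.

    Positive (negative) only when strictly more than half of the samples
    are positive (negative); everything else — exact ties and windows
    dominated by unknown samples — is INVALID and discarded for training.
    """
    track = np.asarray(per_sample_track)
    if len(track) != window_samples:
        raise ValueError(f"expected {window_samples} samples, got {len(track)}")
    half = window_samples // 2
    n_pos = int(np.sum(track == POSITIVE))
    n_neg = int(np.sum(track == NEGATIVE))
    if n_pos > half:
        return POSITIVE
    if n_neg > half:
        return NEGATIVE
    return INVALID


def make_windows(recording: Recording, window_samples: int = WINDOW_SAMPLES,
                 overlap: float = 0.5, low_hz: float = 0.5, high_hz: float = 10.0,
                 order: int = 3) -> list[Window]:
    """Slice a recording into 50%-overlapping windows.

    Filtering happens on the whole recording before slicing (axes per-axis;
    the norm channel is computed from the raw axes and then filtered). A
    trailing partial segment is dropped; a recording shorter than one
    window yields an empty list with a warning.
    """
    n = recording.n_samples
    stride = int(round(window_samples * (1.0 - overlap)))
    if n < window_samples:
        warnings.warn("recording shorter than one window; no windows produced")
        return []
    filtered = bandpass(recording, low_hz, high_hz, order)
    fxyz = filtered.xyz
    norm = bandpass_signal(euclidean_norm(recording.xyz), recording.sample_rate_hz,
                           low_hz, high_hz, order)
    windows = []
    for start in range(0, n - window_samples + 1, stride):
        sl = slice(start, start + window_samples)
        w = Window(start_index=start, filtered_xyz=fxyz[sl], norm_signal=norm[sl])
        if recording.rest_labels is not None:
            w.rest_label = assign_window_label(recording.rest_labels[sl], window_samples)
        if recording.tremor_labels is not None:
            w.tremor_label = assign_window_label(recording.tremor_labels[sl], window_samples)
        windows.append(w)
    return windows


def fft_representation(norm_signal: np.ndarray) -> np.ndarray:
    """64 one-sided DFT magnitude features of a 128-sample norm window.

    128-point DFT, 2/N magnitude scaling, DC bin dropped, bins 1..64 kept
    (bin k sits at 0.390625*k Hz at 50 Hz sampling).
    """
    x = np.asarray(norm_signal, dtype=float)
    if x.shape != (WINDOW_SAMPLES,):
        raise ValueError(f"expected {WINDOW_SAMPLES} samples, got {x.shape}")
    spectrum = np.abs(np.fft.rfft(x)) * (2.0 / WINDOW_SAMPLES)
    return spectrum[1:65]


def normalize_raw(window_xyz_filtered: np.ndarray) -> np.ndarray:
    """Fixed affine map from the sensor range [-FS, +FS] to [0, 1].

    The same map is applied to every window (no per-window min-max), so
    relative amplitude is preserved and no statistics leak across folds.
    Out-of-range values are clipped.
    """
    arr = np.clip(np.asarray(window_xyz_filtered, dtype=float),
                  -FULL_SCALE_MS2, FULL_SCALE_MS2)
    return (arr + FULL_SCALE_MS2) / (2.0 * FULL_SCALE_MS2)


def denormalize_raw(values: np.ndarray) -> np.ndarray:
    return np.asarray(values, dtype=float) * (2.0 * FULL_SCALE_MS2) - FULL_SCALE_MS2


def threshold_prelabel(recording: Recording, band=(3.5, 7.5),
                       threshold_ms2: float = 0.1) -> np.ndarray:
    """Threshold-based tremor pre-labeling.

    Sliding tremor-band RMS (window 128, hop 64, Parseval band RMS of the
    raw Euclidean norm) compared with ``threshold_ms2``: samples covered by
    at least one above-threshold window are positive, all others negative.
    """
    from .assessment import band_rms  # local import to avoid a module cycle

    if threshold_ms2 <= 0:
        raise ValueError("threshold_ms2 must be positive")
    norm = euclidean_norm(recording.xyz)
    track = np.full(recording.n_samples, NEGATIVE, dtype=np.int8)
    for start in range(0, recording.n_samples - WINDOW_SAMPLES + 1, WINDOW_STRIDE):
        seg = norm[start:start + WINDOW_SAMPLES]
        if band_rms(seg, band=band, sample_rate_hz=recording.sample_rate_hz) > threshold_ms2:
            track[start:start + WINDOW_SAMPLES] = POSITIVE
    return track


@dataclass
class WindowSet:
    """Column-oriented window container for model training and evaluation."""
    subject_id: np.ndarray     # (n,) str
    visit_id: np.ndarray       # (n,) str
    start_index: np.ndarray    # (n,) int
    raw: np.ndarray            # (n, 128, 3) in [0, 1]
    fft: np.ndarray            # (n, 64)
    norm: np.ndarray           # (n, 128) m/s^2 (un-normalized, for La)
    rest_label: np.ndarray     # (n,) {1, 0, -1}
    tremor_label: np.ndarray   # (n,) {1, 0, -1}

    def __len__(self) -> int:
        return len(self.start_index)

    def features(self, representation: str) -> np.ndarray:
        if representation == "raw":
            return self.raw
        if representation == "fft":
            return self.fft[:, :, None]
        raise ValueError(f"unknown representation {representation!r}")

    def subset(self, mask: np.ndarray) -> "WindowSet":
        return WindowSet(*(getattr(self, f)[mask] for f in (
            "subject_id", "visit_id", "start_index", "raw", "fft", "norm",
            "rest_label", "tremor_label")))

    @property
    def subjects(self) -> list[str]:
        seen = dict.fromkeys(self.subject_id.tolist())
        return list(seen)


def build_window_set(recordings) -> WindowSet:
    """Window every recording and assemble the feature arrays."""
    cols = {f: [] for f in ("subject_id", "visit_id", "start_index", "raw",
                            "fft", "norm", "rest_label", "tremor_label")}
    for rec in recordings:
        for w in make_windows(rec):
            cols["subject_id"].append(rec.subject_id)
            cols["visit_id"].append(rec.visit_id)
            cols["start_index"].append(w.start_index)
            cols["raw"].append(normalize_raw(w.filtered_xyz))
            cols["fft"].append(fft_representation(w.norm_signal))
            cols["norm"].append(w.norm_signal)
            cols["rest_label"].append(w.rest_label)
            cols["tremor_label"].append(w.tremor_label)
    return WindowSet(
        subject_id=np.array(cols["subject_id"], dtype=object),
        visit_id=np.array(cols["visit_id"], dtype=object),
        start_index=np.array(cols["start_index"], dtype=int),
        raw=np.array(cols["raw"]),
        fft=np.array(cols["fft"]),
        norm=np.array(cols["norm"]),
        rest_label=np.array(cols["rest_label"], dtype=np.int8),
        tremor_label=np.array(cols["tremor_label"], dtype=np.int8),
    )
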