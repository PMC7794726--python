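"""Clinical surrogate indicators for resting tremor.

Two per-visit numbers summarise the symptom:

* **amplitude** — the 75th percentile, over windows classified as
  rest-with-tremor, of the acceleration level La = 20*log10(a/a0) in dB,
  where a is the 3.5-7.5 Hz band-limited RMS of the window's norm signal
  and a0 = 1 um/s^2 is the ISO 1683 reference acceleration;
* **constancy** — the percentage of rest windows in which tremor is
  detected (optionally of all windows).

Band-limited RMS is computed in the frequency domain via Parseval's
theorem: with X_k the N-point DFT of the mean-removed signal, the one-sided
band power is sum over band bins of w_k |X_k/N|^2 with w_k = 2 except at
the Nyquist bin, and the RMS is its square root. With the full band this
equals the time-domain RMS exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import preprocessing
from .preprocessing import Window, WindowSet

__all__ = [
    "REFERENCE_ACCELERATION_MS2", "TREMOR_BAND_HZ", "Spectrum",
    "AccelerationLevel", "VisitAssessment", "band_rms", "acceleration_level",
    "assess_visit", "assess_windowset", "assess_visit_with_models",
]

#: ISO 1683 reference acceleration, 1 um/s^2
REFERENCE_ACCELERATION_MS2 = 1e-6

#: parkinsonian rest-tremor band
TREMOR_BAND_HZ = (3.5, 7.5)


@dataclass
class Spectrum:
    """One-sided magnitude spectrum with 2/N scaling."""
    frequencies_hz: np.ndarray
    magnitudes: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.frequencies_hz) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be non-negative")


def one_sided_spectrum(signal: np.ndarray, sample_rate_hz: float = 50.0) -> Spectrum:
    x = np.asarray(signal, dtype=float)
    n = len(x)
    mags = np.abs(np.fft.rfft(x)) * (2.0 / n)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    return Spectrum(frequencies_hz=freqs, magnitudes=mags)


def band_rms(norm_signal: np.ndarray, band=TREMOR_BAND_HZ,
             sample_rate_hz: float = 50.0) -> float:
    """Band-limited RMS (m/s^2) of a signal window via Parseval's theorem.

    The mean is removed first; band edges are inclusive. No taper is
    applied, so with the full band the result equals the time-domain RMS
    of the mean-removed signal exactly.
    """
    low, high = band
    if not 0.0 <= low < high <= sample_rate_hz / 2.0 + 1e-12:
        raise ValueError(f"band {band} outside (0, {sample_rate_hz / 2}] Hz")
    x = np.asarray(norm_signal, dtype=float)
    n = len(x)
    x = x - x.mean()
    X = np.fft.rfft(x) / n
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    power = np.abs(X) ** 2
    weights = np.full(len(power), 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0  # Nyquist bin is not doubled
    sel = (freqs >= low - 1e-12) & (freqs <= high + 1e-12)
    return float(np.sqrt(np.sum(weights[sel] * power[sel])))


@dataclass
class AccelerationLevel:
    """Acceleration level La = 20*log10(a / a0), dB re 1 um/s^2."""
    rms_ms2: float
    la_db: float | None
    reference_ms2: float = REFERENCE_ACCELERATION_MS2

    @property
    def defined(self) -> bool:
        return self.la_db is not None


def acceleration_level(rms_ms2: float) -> AccelerationLevel:
    """dB level of an RMS acceleration; zero RMS gives an undefined level
    (flagged, not -inf)."""
    if rms_ms2 < 0:
        raise ValueError("RMS acceleration must be non-negative")
    if rms_ms2 == 0:
        return AccelerationLevel(rms_ms2=0.0, la_db=None)
    return AccelerationLevel(
        rms_ms2=float(rms_ms2),
        la_db=float(20.0 * np.log10(rms_ms2 / REFERENCE_ACCELERATION_MS2)),
    )


@dataclass
class VisitAssessment:
    amplitude_db: float | None
    constancy_pct: float
    n_rest_windows: int
    n_tremor_windows: int
    percentile: float = 75.0
    denominator: str = "rest"
    subject_id: str | None = None
    visit_id: str | None = None

    def to_json(self) -> str:
        return json.dumps({
            "subject": self.subject_id,
            "visit": self.visit_id,
            "amplitude_db": self.amplitude_db,
            "constancy_pct": self.constancy_pct,
            "n_rest_windows": self.n_rest_windows,
            "n_tremor_windows": self.n_tremor_windows,
            "percentile": self.percentile,
            "denominator": self.denominator,
        }, indent=2)


def _assess(norms, rest_pred, tremor_pred, percentile, denominator,
            sample_rate_hz=50.0, band=TREMOR_BAND_HZ, **ids):
    rest_pred = np.asarray(rest_pred, dtype=bool)
    tremor_pred = np.asarray(tremor_pred, dtype=bool)
    if not len(norms) == len(rest_pred) == len(tremor_pred):
        raise ValueError("predictions are not aligned with windows")
    both = rest_pred & tremor_pred
    la = []
    for norm in (norms[i] for i in np.flatnonzero(both)):
        level = acceleration_level(band_rms(norm, band=band, sample_rate_hz=sample_rate_hz))
        if level.defined:
            la.append(level.la_db)
    amplitude = float(np.percentile(la, percentile)) if la else None

    n_rest = int(rest_pred.sum())
    n_both = int(both.sum())
    if denominator == "rest":
        constancy = 100.0 * n_both / n_rest if n_rest else 0.0
    elif denominator == "total":
        constancy = 100.0 * n_both / len(norms) if len(norms) else 0.0
    else:
        raise ValueError(f"denominator must be 'rest' or 'total', got {denominator!r}")
    return VisitAssessment(amplitude_db=amplitude, constancy_pct=constancy,
                           n_rest_windows=n_rest, n_tremor_windows=n_both,
                           percentile=percentile, denominator=denominator, **ids)


def assess_visit(windows: list[Window], rest_pred, tremor_pred,
                 percentile: float = 75.0, denominator: str = "rest",
                 sample_rate_hz: float = 50.0) -> VisitAssessment:
    """Amplitude and constancy from per-window rest/tremor decisions.

    La is computed on the un-normalized filtered norm signal of each
    window flagged rest-and-tremor; the amplitude indicator is the
    linear-interpolation percentile of those levels. Constancy is the
    share of rest windows (or of all windows) flagged as tremor.
    """
    norms = [w.norm_signal for w in windows]
    return _assess(norms, rest_pred, tremor_pred, percentile, denominator,
                   sample_rate_hz=sample_rate_hz)


def assess_windowset(ws: WindowSet, rest_pred, tremor_pred,
                     percentile: float = 75.0, denominator: str = "rest") -> VisitAssessment:
    subject = ws.subject_id[0] if len(ws) else None
    visit = ws.visit_id[0] if len(ws) else None
    return _assess(ws.norm, rest_pred, tremor_pred, percentile, denominator,
                   subject_id=subject, visit_id=visit)


def _model_representation(spec) -> str:
    return "fft" if tuple(spec.input_shape) == (64, 1) else "raw"


def assess_visit_with_models(recording, context_model, tremor_model=None,
                             threshold_context: float = 0.5,
                             threshold_tremor: float = 0.5,
                             percentile: float = 75.0,
                             denominator: str = "rest") -> VisitAssessment:
    """Full pipeline: filter -> window -> features -> CNN probabilities ->
    thresholded decisions -> amplitude/constancy.

    ``context_model`` may be a multitask model (heads ``context`` and
    ``tremor``), in which case ``tremor_model`` is omitted; otherwise two
    single-output models are composed hierarchically.
    """
    from . import models as _models

    ws = preprocessing.build_window_set([recording])
    if len(ws) == 0:
        return VisitAssessment(amplitude_db=None, constancy_pct=0.0,
                               n_rest_windows=0, n_tremor_windows=0,
                               percentile=percentile, denominator=denominator,
                               subject_id=recording.subject_id,
                               visit_id=recording.visit_id)
    if context_model is None:
        raise ValueError("a trained context (or multitask) model is required")

    heads = context_model.spec.head_names
    if "context" in heads and "tremor" in heads:
        probs = _models.predict_proba(
            context_model, ws.features(_model_representation(context_model.spec)))
        p_rest, p_tremor = probs["context"], probs["tremor"]
    else:
        if tremor_model is None:
            raise ValueError("single-output pipeline needs both a context and a tremor model")
        p_rest = _models.predict_proba(
            context_model, ws.features(_model_representation(context_model.spec)))["output"]
        p_tremor = _models.predict_proba(
            tremor_model, ws.features(_model_representation(tremor_model.spec)))["output"]
    return assess_windowset(ws, p_rest >= threshold_context, p_tremor >= threshold_tremor,
                            percentile=percentile, denominator=denominator)
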