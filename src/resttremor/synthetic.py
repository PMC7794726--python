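"""Seeded simulator for multi-subject wrist-accelerometer visits.

Emulates the study protocol: a ~6 min visit alternating scripted activity
with rest blocks of at least 30 s, recorded at 50 Hz on a +/-2 g triaxial
accelerometer. Resting tremor is injected only during rest blocks as an
amplitude-modulated quasi-sinusoid in the 3.5-7.5 Hz band (plus a second
harmonic), projected on a random spatial direction, active for a
controlled fraction of rest time (constancy) and calibrated so that the
measurable tremor-band RMS of the band-passed norm signal matches the
profile's target. Activity blocks carry band-limited (0.5-3 Hz) movement
with RMS far above tremor level; gravity sits on a slowly rotating
direction during activity and is static at rest; white sensor noise is
added and the result is clipped to the sensor range.

The generator is a measurement model for the *pipeline*, not a
biomechanical model of exercises: its purpose is ground-truthed, seeded
data on which context and tremor classification are non-trivial but
learnable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .assessment import TREMOR_BAND_HZ
from .preprocessing import FULL_SCALE_MS2, Recording, bandpass_signal

__all__ = [
    "SubjectProfile", "VisitScript", "GroundTruth", "CohortDataset",
    "SEVERITY_BAND_RMS_MS2", "default_visit_script", "simulate_visit",
    "simulate_cohort",
]

GRAVITY_MS2 = 9.80665

#: default mapping from UPDRS 3.17-like severity class to tremor band RMS,
#: chosen so that class means are separated by ~14 dB in acceleration level
SEVERITY_BAND_RMS_MS2 = {0: 0.0, 1: 0.3, 2: 1.5}

#: per-axis RMS of scripted-activity movement (m/s^2), far above tremor level
ACTIVITY_RMS_MS2 = 3.0

AM_DEPTH = 0.2          # +/-20% slow amplitude modulation of the tremor
AM_FREQUENCY_HZ = 0.1
RAMP_SECONDS = 0.3      # cosine on/off ramps at tremor segment edges


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    has_tremor: bool
    tremor_frequency_hz: float = 5.0
    severity_class: int = 0
    target_band_rms_ms2: float = 0.0
    constancy_fraction: float = 0.0
    harmonic_ratio: float = 0.3
    noise_sigma_ms2: float = 0.05

    def __post_init__(self):
        no_tremor = (self.severity_class == 0)
        if no_tremor != (not self.has_tremor) or \
           no_tremor != (self.target_band_rms_ms2 == 0.0) or \
           no_tremor != (self.constancy_fraction == 0.0):
            raise ValueError(
                "severity_class 0, has_tremor False, zero target RMS and zero "
                "constancy must all coincide")
        if self.has_tremor and not 3.5 <= self.tremor_frequency_hz <= 7.5:
            raise ValueError("tremor frequency must lie in [3.5, 7.5] Hz")
        if 2.0 * self.tremor_frequency_hz >= 25.0:
            raise ValueError("first harmonic must stay below the 25 Hz Nyquist")
        if not 0.0 <= self.constancy_fraction <= 1.0:
            raise ValueError("constancy_fraction must be in [0, 1]")
        if not 0.0 <= self.harmonic_ratio < 1.0:
            raise ValueError("harmonic_ratio must be in [0, 1)")
        if self.target_band_rms_ms2 < 0 or self.noise_sigma_ms2 < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class VisitScript:
    blocks: tuple            # of (kind, duration_s); kinds alternate
    sample_rate_hz: float = 50.0

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("script needs at least one block")
        for kind, duration in self.blocks:
            if kind not in ("activity", "rest"):
                raise ValueError(f"unknown block kind {kind!r}")
            if duration <= 0:
                raise ValueError("block durations must be positive")
            if kind == "rest" and duration < 30.0:
                raise ValueError("rest blocks must last at least 30 s")
        kinds = [k for k, _ in self.blocks]
        if any(a == b for a, b in zip(kinds, kinds[1:])):
            raise ValueError("blocks must alternate activity/rest")

    @property
    def total_duration_s(self) -> float:
        return sum(d for _, d in self.blocks)


def default_visit_script(n_cycles: int = 6, activity_s: float = 30.0,
                         rest_s: float = 30.0) -> VisitScript:
    """Six activity/rest cycles of 30 s each: a 360 s (6 min) visit."""
    blocks = []
    for _ in range(n_cycles):
        blocks.append(("activity", activity_s))
        blocks.append(("rest", rest_s))
    return VisitScript(blocks=tuple(blocks))


@dataclass
class GroundTruth:
    rest_mask: np.ndarray
    tremor_mask: np.ndarray
    true_constancy_pct: float
    true_severity_class: int


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    while np.linalg.norm(v) < 1e-9:
        v = rng.normal(size=3)
    return _unit(v)


def _gravity_track(rest_mask: np.ndarray, fs: float, rng) -> np.ndarray:
    """(N, 3) gravity vector: static at rest, slowly reorienting in activity."""
    n = len(rest_mask)
    steps = rng.normal(scale=0.02, size=(n, 3))
    steps[rest_mask] = 0.0
    walk = np.cumsum(steps, axis=0)
    # smooth the orientation drift to sub-0.5 Hz wander
    if n > 64:
        from scipy.signal import butter, filtfilt
        b, a = butter(2, 0.3 / (fs / 2.0), btype="low")
        walk = filtfilt(b, a, walk, axis=0)
    direction = _random_unit(rng) + walk
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    return GRAVITY_MS2 * direction


def _activity_track(rest_mask: np.ndarray, fs: float, rng) -> np.ndarray:
    """Band-limited (0.5-3 Hz) movement on all axes during activity blocks."""
    n = len(rest_mask)
    noise = rng.normal(size=(n, 3))
    shaped = bandpass_signal(noise, fs, 0.5, 3.0, order=3)
    shaped *= ACTIVITY_RMS_MS2 / np.sqrt(np.mean(shaped ** 2, axis=0, keepdims=True))
    shaped[rest_mask] = 0.0
    return shaped


def _tremor_mask(rest_mask: np.ndarray, block_slices, fraction: float, rng) -> np.ndarray:
    """Contiguous tremor-on run inside each rest block covering ``fraction``."""
    mask = np.zeros(len(rest_mask), dtype=bool)
    for start, stop in block_slices:
        length = stop - start
        n_on = int(round(fraction * length))
        if n_on == 0:
            continue
        offset = int(rng.integers(0, length - n_on + 1))
        mask[start + offset:start + offset + n_on] = True
    return mask


def _tremor_waveform(n: int, fs: float, profile: SubjectProfile, mask: np.ndarray,
                     rng) -> np.ndarray:
    t = np.arange(n) / fs
    f = profile.tremor_frequency_hz
    phi0, phi1, phi_am = rng.uniform(0, 2 * np.pi, size=3)
    envelope = 1.0 + AM_DEPTH * np.sin(2 * np.pi * AM_FREQUENCY_HZ * t + phi_am)
    wave = envelope * (np.sin(2 * np.pi * f * t + phi0)
                       + profile.harmonic_ratio * np.sin(2 * np.pi * 2 * f * t + phi1))
    gate = np.zeros(n)
    ramp = max(1, int(round(RAMP_SECONDS * fs)))
    on = np.flatnonzero(mask)
    if len(on):
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            seg = np.ones(stop - start)
            k = min(ramp, len(seg) // 2)
            if k:
                win = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
                seg[:k] = win
                seg[-k:] = win[::-1]
            gate[start:stop] = seg
    return wave * gate


def _block_band_rms(filtered_norm: np.ndarray, start: int, stop: int,
                    on: np.ndarray, fs: float) -> float:
    """Tremor-band RMS over a rest block's tremor-on samples, measured the
    way the assessment stage measures it: per-window Parseval bin sums on
    the 0.5-10 Hz filtered norm channel, mean-square combined.

    Falls back to the time-domain RMS of a 3.5-7.5 Hz refilter when the
    tremor segment is too short to hold a full analysis window.
    """
    from .assessment import band_rms

    idx = np.flatnonzero(on)
    window, stride = 128, 64
    vals = []
    if len(idx):
        seg_start, seg_stop = start + idx[0], start + idx[-1] + 1
        for w0 in range(seg_start, seg_stop - window + 1, stride):
            vals.append(band_rms(filtered_norm[w0:w0 + window],
                                 band=TREMOR_BAND_HZ, sample_rate_hz=fs))
    if vals:
        return float(np.sqrt(np.mean(np.square(vals))))
    block = filtered_norm[start:stop]
    refilter = bandpass_signal(block, fs, TREMOR_BAND_HZ[0], TREMOR_BAND_HZ[1], order=3)
    return float(np.sqrt(np.mean(refilter[on] ** 2)))


def simulate_visit(profile: SubjectProfile, script: VisitScript | None = None,
                   seed: int = 0, subject_id: str | None = None,
                   visit_id: str = "visit_01") -> tuple[Recording, GroundTruth]:
    """Generate one ground-truthed visit.

    Identical (profile, script, seed) triples give identical output. The
    tremor component is rescaled once (a deterministic calibration pass)
    so the band RMS measured on the norm channel — the quantity the
    assessment stage sees — matches ``profile.target_band_rms_ms2``.
    """
    if script is None:
        script = default_visit_script()
    fs = script.sample_rate_hz
    rng = np.random.default_rng(seed)

    counts = [int(round(d * fs)) for _, d in script.blocks]
    n = int(sum(counts))
    rest_mask = np.zeros(n, dtype=bool)
    rest_slices = []
    pos = 0
    for (kind, _), cnt in zip(script.blocks, counts):
        if kind == "rest":
            rest_mask[pos:pos + cnt] = True
            rest_slices.append((pos, pos + cnt))
        pos += cnt

    gravity = _gravity_track(rest_mask, fs, rng)
    activity = _activity_track(rest_mask, fs, rng)
    noise = rng.normal(scale=profile.noise_sigma_ms2, size=(n, 3))

    tremor_mask = np.zeros(n, dtype=bool)
    tremor_xyz = np.zeros((n, 3))
    if profile.has_tremor and rest_slices:
        tremor_mask = _tremor_mask(rest_mask, rest_slices, profile.constancy_fraction, rng)
        if tremor_mask.any():
            g_dir = _unit(gravity[0])
            direction = _random_unit(rng)
            while abs(direction @ g_dir) < 0.3:
                direction = _random_unit(rng)
            wave = _tremor_waveform(n, fs, profile, tremor_mask, rng)
            # initial guess: undo the projection onto the gravity carrier
            amp = profile.target_band_rms_ms2 / (np.sqrt(0.5) * abs(direction @ g_dir))
            tremor_xyz = amp * wave[:, None] * direction
            # Calibrate per rest block: the norm channel projects the tremor
            # onto the (block-wise static) gravity direction, so each block
            # gets its own scale to realise the target band RMS exactly as
            # the assessment stage will measure it.
            for _ in range(3):
                composite = gravity + activity + tremor_xyz + noise
                norm = np.sqrt(np.sum(composite ** 2, axis=1))
                filtered_norm = bandpass_signal(norm, fs, 0.5, 10.0, order=3)
                for start, stop in rest_slices:
                    on = tremor_mask[start:stop]
                    if not on.any():
                        continue
                    measured = _block_band_rms(filtered_norm, start, stop, on, fs)
                    if measured > 1e-12:
                        scale = profile.target_band_rms_ms2 / measured
                        tremor_xyz[start:stop] *= min(scale, 10.0)

    signal = np.clip(gravity + activity + tremor_xyz + noise,
                     -FULL_SCALE_MS2, FULL_SCALE_MS2)

    n_rest = int(rest_mask.sum())
    constancy = 100.0 * tremor_mask.sum() / n_rest if n_rest else 0.0
    recording = Recording(
        subject_id=subject_id or profile.subject_id,
        visit_id=visit_id,
        ax=signal[:, 0], ay=signal[:, 1], az=signal[:, 2],
        sample_rate_hz=fs,
        rest_labels=rest_mask.astype(np.int8),
        tremor_labels=tremor_mask.astype(np.int8),
    )
    truth = GroundTruth(rest_mask=rest_mask, tremor_mask=tremor_mask,
                        true_constancy_pct=float(constancy),
                        true_severity_class=profile.severity_class)
    return recording, truth


@dataclass
class CohortDataset:
    profiles: list
    visits: list   # of (profile, visit_id, Recording, GroundTruth)
    manifest: dict


def _draw_profile(subject_id: str, severity: int, rng,
                  severity_rms=SEVERITY_BAND_RMS_MS2) -> SubjectProfile:
    if severity == 0:
        return SubjectProfile(subject_id=subject_id, has_tremor=False)
    return SubjectProfile(
        subject_id=subject_id,
        has_tremor=True,
        tremor_frequency_hz=float(rng.uniform(3.5, 7.5)),
        severity_class=severity,
        target_band_rms_ms2=float(severity_rms[severity] * rng.uniform(0.85, 1.15)),
        constancy_fraction=float(rng.uniform(0.3, 0.9)),
        harmonic_ratio=float(rng.uniform(0.1, 0.4)),
    )


def simulate_cohort(n_subjects: int = 18, visits_per_subject: int = 1,
                    class_mix: dict | None = None, seed: int = 0,
                    script: VisitScript | None = None,
                    out_dir: str | Path | None = None,
                    severity_rms=SEVERITY_BAND_RMS_MS2) -> CohortDataset:
    """Simulate a whole cohort; the study default is 18 subjects of which
    4 are tremor-free (class mix {0: 4, 1: 7, 2: 7}).

    Profiles and all visit signals are drawn deterministically from
    ``seed``. With ``out_dir`` set, visits are written as CSV + label JSON
    plus a cohort manifest via the I/O layer.
    """
    if class_mix is None:
        class_mix = {0: 4, 1: 7, 2: 7}
    if sum(class_mix.values()) != n_subjects:
        raise ValueError(f"class_mix {class_mix} does not sum to n_subjects={n_subjects}")
    if script is None:
        script = default_visit_script()

    severities = [sev for sev in sorted(class_mix) for _ in range(class_mix[sev])]
    root = np.random.SeedSequence(seed)
    profile_seeds = root.spawn(n_subjects)

    profiles, visits = [], []
    for i, severity in enumerate(severities):
        subject_id = f"subject_{i + 1:02d}"
        srng = np.random.default_rng(profile_seeds[i])
        profile = _draw_profile(subject_id, severity, srng, severity_rms)
        profiles.append(profile)
        for v in range(visits_per_subject):
            visit_id = f"visit_{v + 1:02d}"
            # deterministic per-(subject, visit) seed derived from the root seed
            visit_seed = int(np.random.SeedSequence([seed, i, v]).generate_state(1)[0] % (2 ** 31))
            rec, truth = simulate_visit(profile, script, seed=visit_seed,
                                        visit_id=visit_id)
            visits.append((profile, visit_id, rec, truth))

    manifest = {
        "seed": seed,
        "n_subjects": n_subjects,
        "visits_per_subject": visits_per_subject,
        "class_mix": {str(k): v for k, v in sorted(class_mix.items())},
        "sample_rate_hz": script.sample_rate_hz,
        "subjects": [
            {
                "subject_id": p.subject_id,
                "severity_class": p.severity_class,
                "profile": asdict(p),
                "visits": [
                    {
                        "visit_id": vid,
                        "recording_csv": f"{p.subject_id}_{vid}.csv",
                        "labels_json": f"{p.subject_id}_{vid}.labels.json",
                        "true_constancy_pct": truth.true_constancy_pct,
                    }
                    for q, vid, rec, truth in visits if q.subject_id == p.subject_id
                ],
            }
            for p in profiles
        ],
    }

    dataset = CohortDataset(profiles=profiles, visits=visits, manifest=manifest)
    if out_dir is not None:
        from . import io as _io
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for profile, visit_id, rec, truth in visits:
            base = f"{profile.subject_id}_{visit_id}"
            _io.write_recording_csv(out / f"{base}.csv", rec)
            _io.write_labels_json(out / f"{base}.labels.json", rec,
                                  severity_class=profile.severity_class,
                                  constancy_pct=truth.true_constancy_pct)
        _io.write_manifest(out / "manifest.json", manifest)
    return dataset
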