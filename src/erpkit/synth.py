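"""Synthetic N-back ERP cohort generator.

Produces multichannel continuous recordings with the statistical structure
an ERP classification pipeline assumes: target-locked P300-like deflections
over centro-parietal channels, a stimulus-locked theta (4-8 Hz) component,
ocular (blink) artifacts on dedicated EOG channels that leak into frontal
scalp channels through fixed mixing weights, and 1/f (pink) background
noise. Group structure (patient vs. control) enters through per-subject
parameters drawn from configurable group distributions: patients have
prolonged P300 latency, reduced amplitude, and reduced theta power.

All randomness flows through a single ``numpy.random.Generator`` seeded
explicitly; identical (spec, seed) pairs yield bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

#: Electrode montage: 2 EOG channels followed by 16 scalp channels
#: placed per the 10-20 system.
CHANNELS: tuple = (
    "EOG1", "EOG2",
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz",
    "C3", "Cz", "C4", "P3", "Pz", "P4", "O1", "Oz", "O2",
)

SCALP_CHANNELS: tuple = CHANNELS[2:]

#: Fixed forward-projection pattern of the P300-like source over the 16
#: scalp channels: maximal at Pz, falling off toward frontal/occipital
#: sites (the classical centro-parietal topography).
P300_TOPOGRAPHY: Dict[str, float] = {
    "Fp1": 0.05, "Fp2": 0.05, "F3": 0.20, "F4": 0.20, "F7": 0.10,
    "F8": 0.10, "Fz": 0.30, "C3": 0.50, "Cz": 0.70, "C4": 0.50,
    "P3": 0.80, "Pz": 1.00, "P4": 0.80, "O1": 0.45, "Oz": 0.60,
    "O2": 0.45,
}

#: Frontal-midline topography for the stimulus-locked theta component.
THETA_TOPOGRAPHY: Dict[str, float] = {
    "Fp1": 0.30, "Fp2": 0.30, "F3": 0.60, "F4": 0.60, "F7": 0.35,
    "F8": 0.35, "Fz": 1.00, "C3": 0.55, "Cz": 0.90, "C4": 0.55,
    "P3": 0.40, "Pz": 0.55, "P4": 0.40, "O1": 0.15, "Oz": 0.20,
    "O2": 0.15,
}

#: Leakage of the blink source into frontal scalp channels (the EOG
#: channels themselves carry the source with weight 1.0 / 0.9).
BLINK_LEAKAGE: Dict[str, float] = {
    "EOG1": 1.00, "EOG2": 0.90,
    "Fp1": 0.40, "Fp2": 0.40, "F7": 0.20, "F8": 0.20,
    "F3": 0.15, "F4": 0.15, "Fz": 0.10,
}

#: Full width at half maximum of the P300-like Gaussian bump, ms.
P300_FWHM_MS = 120.0
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Offset of the first stimulus into the recording, s (leaves room for a
#: pre-stimulus baseline window on the first trial).
STIM_LEAD_S = 0.5


@dataclass(frozen=True)
class ParadigmSpec:
    """Recording/paradigm parameters of the verbal N-back task."""

    fs: float = 256.0
    n_channels: int = 18
    stim_dur: float = 0.5
    isi: float = 2.5
    n_sessions: int = 3
    trials_per_session: int = 40
    target_fraction: float = 0.5

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.n_channels < 3:
            raise ValueError("need at least 3 channels (2 EOG + 1 scalp)")
        n_targets = self.trials_per_session * self.target_fraction
        if abs(n_targets - round(n_targets)) > 1e-9:
            raise ValueError(
                f"trials_per_session * target_fraction = {n_targets} "
                "is not an integer"
            )

    @property
    def trial_len_s(self) -> float:
        return self.stim_dur + self.isi

    @property
    def n_targets(self) -> int:
        return int(round(self.trials_per_session * self.target_fraction))

    @property
    def channel_names(self) -> List[str]:
        return list(CHANNELS[: self.n_channels])


def _group_field(control: float, patient: float) -> Dict[str, float]:
    return {"control": control, "patient": patient}


@dataclass(frozen=True)
class GroupEffectSpec:
    """Group-level distributions of the per-subject ERP parameters.

    Patients show prolonged P300 latency, reduced amplitude, and reduced
    theta power relative to controls; each group's mean is independently
    settable so a zero-effect (null) cohort is expressible.
    """

    latency_mean_ms: Dict[str, float] = field(
        default_factory=lambda: _group_field(330.0, 390.0))
    amplitude_mean_uv: Dict[str, float] = field(
        default_factory=lambda: _group_field(10.0, 6.0))
    theta_power_scale: Dict[str, float] = field(
        default_factory=lambda: _group_field(1.0, 0.6))
    latency_between_sd_ms: float = 15.0
    amplitude_between_sd_uv: float = 1.5
    theta_scale_between_sd: float = 0.1
    latency_jitter_sd_ms: float = 10.0
    amplitude_jitter_sd_uv: float = 1.0
    noise_sd_uv: float = 6.0
    eog_rate_per_min: float = 12.0
    eog_amplitude_uv: float = 120.0
    theta_base_uv: float = 3.0
    theta_freq_hz: float = 6.0

    def __post_init__(self):
        for name in ("latency_between_sd_ms", "amplitude_between_sd_uv",
                     "theta_scale_between_sd", "latency_jitter_sd_ms",
                     "amplitude_jitter_sd_uv", "noise_sd_uv",
                     "eog_rate_per_min", "eog_amplitude_uv",
                     "theta_base_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for d in (self.amplitude_mean_uv, self.theta_power_scale):
            if any(v < 0 for v in d.values()):
                raise ValueError("amplitudes and scales must be >= 0")


@dataclass(frozen=True)
class SubjectParams:
    """Realized per-subject ERP parameters (the simulation ground truth)."""

    latency_ms: float
    amplitude_uv: float
    theta_scale: float
    theta_freq_hz: float = 6.0
    theta_base_uv: float = 3.0
    latency_jitter_sd_ms: float = 0.0
    amplitude_jitter_sd_uv: float = 0.0
    noise_sd_uv: float = 0.0
    eog_rate_per_min: float = 0.0
    eog_amplitude_uv: float = 0.0


@dataclass
class Recording:
    """One continuous subject-session recording plus its event table."""

    data: np.ndarray            # n_channels x n_samples, microvolts
    fs: float
    channel_names: List[str]
    events: pd.DataFrame        # onset_sample, type, session
    subject: str = ""
    session: int = 0

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def target_onsets(self) -> np.ndarray:
        return self.events.loc[
            self.events["type"] == "target", "onset_sample"].to_numpy()


@dataclass
class Cohort:
    """A set of subject-session recordings with labels and ground truth."""

    recordings: List[Recording]
    labels: Dict[str, str]                  # subject -> patient | control
    ground_truth: pd.DataFrame              # one row per subject
    paradigm: ParadigmSpec
    seed: int


def _pink_noise(rng: np.random.Generator, n_channels: int,
                n_samples: int) -> np.ndarray:
    """Unit-variance 1/f noise, independently per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    sd = pink.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def _gauss_bump(t: np.ndarray, center_s: float, fwhm_ms: float) -> np.ndarray:
    sigma = (fwhm_ms / 1000.0) * _FWHM_TO_SIGMA
    return np.exp(-0.5 * ((t - center_s) / sigma) ** 2)


def _blink_waveform(fs: float) -> np.ndarray:
    """300 ms raised-cosine blink template, unit peak."""
    n = max(int(round(0.3 * fs)), 4)
    return np.hanning(n)


def generate_subject_session(paradigm: ParadigmSpec,
                             subject_params: SubjectParams,
                             seed: int) -> Recording:
    """Simulate one continuous subject-session recording.

    The signal is the sum of (i) pink background noise on every channel,
    (ii) on target trials, a Gaussian P300-like bump peaking at the
    subject's latency after stimulus onset, projected through the fixed
    centro-parietal topography, (iii) a stimulus-locked theta burst under
    the same temporal envelope, projected fronto-centrally and scaled by
    the subject's theta scale, and (iv) Poisson-arriving blink artifacts
    on the EOG channels with fixed frontal leakage.
    """
    if seed is None:
        raise ValueError("seed is required (reproducibility contract)")
    rng = np.random.default_rng(seed)
    fs = paradigm.fs
    n_trials = paradigm.trials_per_session
    trial_len = int(round(paradigm.trial_len_s * fs))
    n_samples = n_trials * trial_len
    names = paradigm.channel_names
    n_ch = paradigm.n_channels

    onsets = np.arange(n_trials) * trial_len + int(round(STIM_LEAD_S * fs))
    flags = np.concatenate([
        np.ones(paradigm.n_targets, dtype=bool),
        np.zeros(n_trials - paradigm.n_targets, dtype=bool)])
    flags = rng.permutation(flags)

    data = np.zeros((n_ch, n_samples))
    if subject_params.noise_sd_uv > 0:
        data += subject_params.noise_sd_uv * _pink_noise(rng, n_ch, n_samples)

    t = np.arange(n_samples) / fs
    p300_w = np.array([P300_TOPOGRAPHY.get(c, 0.0) for c in names])
    theta_w = np.array([THETA_TOPOGRAPHY.get(c, 0.0) for c in names])

    p = subject_params
    for onset, is_target in zip(onsets, flags):
        if not is_target:
            continue
        lat = p.latency_ms + rng.normal() * p.latency_jitter_sd_ms
        amp = p.amplitude_uv + rng.normal() * p.amplitude_jitter_sd_uv
        center = onset / fs + lat / 1000.0
        # evaluate only on a local window around the bump for speed
        half = int(round(0.6 * fs))
        c_idx = int(round(center * fs))
        lo, hi = max(c_idx - half, 0), min(c_idx + half, n_samples)
        seg_t = t[lo:hi]
        bump = _gauss_bump(seg_t, center, P300_FWHM_MS)
        data[:, lo:hi] += amp * np.outer(p300_w, bump)
        if p.theta_scale > 0:
            env = _gauss_bump(seg_t, center, 2.0 * P300_FWHM_MS)
            # theta burst phase rides with the response peak so that its
            # phase relation to the P300 deflection is latency-invariant
            osc = np.sin(2 * np.pi * p.theta_freq_hz * (seg_t - center))
            theta = p.theta_base_uv * p.theta_scale * env * osc
            data[:, lo:hi] += np.outer(theta_w, theta)

    if p.eog_rate_per_min > 0 and p.eog_amplitude_uv > 0:
        n_blinks = rng.poisson(p.eog_rate_per_min * n_samples / fs / 60.0)
        template = _blink_waveform(fs)
        leak = np.array([BLINK_LEAKAGE.get(c, 0.0) for c in names])
        for _ in range(n_blinks):
            start = rng.integers(0, max(n_samples - len(template), 1))
            amp = p.eog_amplitude_uv * (0.8 + 0.4 * rng.random())
            seg = amp * template
            data[:, start:start + len(template)] += np.outer(
                leak, seg[: n_samples - start])

    events = pd.DataFrame({
        "onset_sample": onsets,
        "type": np.where(flags, "target", "nontarget"),
        "session": 0,
    })
    return Recording(data=data, fs=fs, channel_names=names, events=events)


def draw_subject_params(group: str, effects: GroupEffectSpec,
                        rng: np.random.Generator) -> SubjectParams:
    """Draw one subject's true ERP parameters from the group distributions."""
    lat = rng.normal(effects.latency_mean_ms[group],
                     effects.latency_between_sd_ms)
    amp = max(rng.normal(effects.amplitude_mean_uv[group],
                         effects.amplitude_between_sd_uv), 0.0)
    theta = max(rng.normal(effects.theta_power_scale[group],
                           effects.theta_scale_between_sd), 0.0)
    return SubjectParams(
        latency_ms=lat, amplitude_uv=amp, theta_scale=theta,
        theta_freq_hz=effects.theta_freq_hz,
        theta_base_uv=effects.theta_base_uv,
        latency_jitter_sd_ms=effects.latency_jitter_sd_ms,
        amplitude_jitter_sd_uv=effects.amplitude_jitter_sd_uv,
        noise_sd_uv=effects.noise_sd_uv,
        eog_rate_per_min=effects.eog_rate_per_min,
        eog_amplitude_uv=effects.eog_amplitude_uv,
    )


def generate_cohort(paradigm: ParadigmSpec, effects: GroupEffectSpec,
                    n_patients: int, n_controls: int, seed: int) -> Cohort:
    """Simulate a full patient/control cohort, one recording per session."""
    if n_patients < 1 or n_controls < 1:
        raise ValueError("need at least one subject per group")
    rng = np.random.default_rng(seed)
    subjects = ([f"P{i:02d}" for i in range(1, n_patients + 1)] +
                [f"C{i:02d}" for i in range(1, n_controls + 1)])
    groups = ["patient"] * n_patients + ["control"] * n_controls

    recordings: List[Recording] = []
    labels: Dict[str, str] = {}
    gt_rows = []
    for subj, grp in zip(subjects, groups):
        params = draw_subject_params(grp, effects, rng)
        labels[subj] = grp
        gt_rows.append({
            "subject": subj, "group": grp,
            "latency_ms": params.latency_ms,
            "amplitude_uv": params.amplitude_uv,
            "theta_scale": params.theta_scale,
            "theta_freq_hz": params.theta_freq_hz,
        })
        for sess in range(paradigm.n_sessions):
            child_seed = int(rng.integers(0, 2**31 - 1))
            rec = generate_subject_session(paradigm, params, child_seed)
            rec.subject = subj
            rec.session = sess
            rec.events["session"] = sess
            recordings.append(rec)
    return Cohort(recordings=recordings, labels=labels,
                  ground_truth=pd.DataFrame(gt_rows),
                  paradigm=paradigm, seed=seed)


def null_effects(effects: Optional[GroupEffectSpec] = None) -> GroupEffectSpec:
    """A copy of ``effects`` with all patient/control differences removed."""
    e = effects or GroupEffectSpec()
    return replace(
        e,
        latency_mean_ms=_group_field(e.latency_mean_ms["control"],
                                     e.latency_mean_ms["control"]),
        amplitude_mean_uv=_group_field(e.amplitude_mean_uv["control"],
                                       e.amplitude_mean_uv["control"]),
        theta_power_scale=_group_field(e.theta_power_scale["control"],
                                       e.theta_power_scale["control"]),
    )


def make_radial_feature_table(n_patients: int = 13, n_controls: int = 13,
                              n_sessions: int = 3, n_channels: int = 16,
                              seed: int = 0,
                              noise_sd: float = 0.3) -> pd.DataFrame:
    """Feature-space cohort whose group difference is radially nonlinear.

    Two latent coordinates carry a circle-in-ring structure: control
    samples scatter around the origin, patient samples around a ring of
    radius 2, so the group means coincide and no linear discriminant
    separates the groups, while a kernel machine keying on the radius
    can. The latent pair is mixed into all channels through a fixed
    random projection (mimicking how volume conduction spreads one
    source over many electrodes) plus small per-channel noise. Returns a
    table in the layout of :func:`erpkit.features.extract_feature_table`
    (one row per subject-session).
    """
    rng = np.random.default_rng(seed)
    mixing = np.linalg.qr(rng.standard_normal((n_channels, 2)))[0]
    rows = []
    subjects = ([f"P{i:02d}" for i in range(1, n_patients + 1)] +
                [f"C{i:02d}" for i in range(1, n_controls + 1)])
    groups = ["patient"] * n_patients + ["control"] * n_controls
    # per-subject base angle: sessions of one subject cluster together
    for subj, grp in zip(subjects, groups):
        angle = rng.uniform(0, 2 * np.pi)
        for sess in range(n_sessions):
            a = angle + rng.normal(0, 0.3)
            if grp == "patient":
                r = 2.0 + rng.normal(0, noise_sd)
            else:
                r = abs(rng.normal(0, noise_sd))
            uv = np.array([r * np.cos(a), r * np.sin(a)])
            x = mixing @ uv + rng.normal(0, 0.15, n_channels)
            row = {"subject": subj, "session": sess, "task": "0-back",
                   "label": grp}
            row.update({f"ch{i:02d}": v for i, v in enumerate(x)})
            rows.append(row)
    return pd.DataFrame(rows)
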