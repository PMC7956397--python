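"""Synthetic thigh-worn accelerometer recordings with ground truth.

The generator reduces thigh kinematics to a single inclination angle θ
(0° upright, 90° horizontal) and a sinusoidal gait oscillation:

* longitudinal axis  = cos θ(t) g (+ vertical gait component) + noise
* anterior-posterior = sin θ(t) g + gait / sway oscillation + noise
* medio-lateral      = noise

Posture changes interpolate θ linearly over a transition ramp (default 2 s)
placed at the start of the new posture's segment — a sit-to-stand takes the
thigh from horizontal to vertical over the ramp.  DYNAMIC segments carry a
sinusoidal anterior-posterior gait oscillation for their whole duration (the
anterior-posterior signal dominates in slow, aided hospital gait, which is
why amplitudes are specified on that axis) plus a smaller vertical component
at twice the step frequency.  STANDING segments may carry a small
postural-sway/fidgeting oscillation; hospitalized patients rarely stand
perfectly still, and without it no standing window could ever approach an
activity threshold.  All randomness flows from one seed through numpy's
splittable SeedSequence; no global random state is touched.

Scenario presets emulate the two study populations (orthopedic patients and
acutely hospitalized elderly with more shuffling, lower-amplitude gait) plus
a noise-controlled ``well_separated`` verification scenario whose bout
durations align with the 4 s analysis grid.  The amplitude regimes are
package-documented stipulations, not measured hospital statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .classify import ActivityLabel
from .metrics import ReferenceEvents
from .signal import AccelRecording, AxisRoles

__all__ = [
    "SCENARIOS",
    "ActivityScript",
    "GaitProfile",
    "ScenarioSpec",
    "Segment",
    "SimulatedSubject",
    "build_script",
    "scale_gait_amplitudes",
    "simulate_cohort",
    "simulate_subject",
]

_UPRIGHT_DEG = 0.0
_SEDENTARY_DEG = 90.0


@dataclass(frozen=True)
class GaitProfile:
    """Sinusoidal gait model for one dynamic bout."""

    step_frequency_hz: float = 1.8
    ap_amplitude_g: float = 0.35
    vertical_amplitude_g: float = 0.15

    def __post_init__(self) -> None:
        if self.step_frequency_hz <= 0:
            raise ValueError("step frequency must be positive")
        if self.ap_amplitude_g < 0 or self.vertical_amplitude_g < 0:
            raise ValueError("gait amplitudes must be non-negative")


@dataclass(frozen=True)
class Segment:
    """One scripted bout of a single activity."""

    label: ActivityLabel
    duration_s: float
    gait: GaitProfile | None = None
    sway_amplitude_g: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("segment duration must be positive")
        if self.sway_amplitude_g < 0:
            raise ValueError("sway amplitude must be non-negative")
        object.__setattr__(self, "label", ActivityLabel(self.label))
        if self.label is ActivityLabel.DYNAMIC and self.gait is None:
            object.__setattr__(self, "gait", GaitProfile())


@dataclass(frozen=True)
class ActivityScript:
    """Scripted activity sequence driving one simulated recording."""

    segments: tuple[Segment, ...]
    transition_ramp_s: float = 2.0
    noise_sd_g: float = 0.02
    sway_frequency_hz: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if len(self.segments) == 0:
            raise ValueError("script must contain at least one segment")
        if self.transition_ramp_s < 0 or self.noise_sd_g < 0:
            raise ValueError("ramp and noise must be non-negative")
        if self.sway_frequency_hz <= 0:
            raise ValueError("sway frequency must be positive")

    @property
    def total_duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))


@dataclass
class SimulatedSubject:
    """A synthetic recording with its exact ground-truth annotation."""

    recording: AccelRecording
    truth: ReferenceEvents
    script: ActivityScript


def _is_upright(label: ActivityLabel) -> bool:
    return label is not ActivityLabel.SEDENTARY


def simulate_subject(
    script: ActivityScript,
    sample_rate_hz: float = 25.0,
    subject_id: str = "sim",
    axis_roles: AxisRoles | None = None,
) -> SimulatedSubject:
    """Render a script into a recording plus matching reference events."""
    axis_roles = axis_roles or AxisRoles()
    nyq = sample_rate_hz / 2.0
    for seg in script.segments:
        if seg.gait is not None and seg.gait.step_frequency_hz >= nyq:
            raise ValueError(f"gait frequency {seg.gait.step_frequency_hz} Hz is at/above Nyquist ({nyq} Hz)")

    n = int(np.floor(script.total_duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz

    onsets = np.cumsum([0.0] + [s.duration_s for s in script.segments])
    angle_deg = np.empty(n)
    ap_extra = np.zeros(n)
    long_extra = np.zeros(n)

    prev_label: ActivityLabel | None = None
    for k, seg in enumerate(script.segments):
        on, off = onsets[k], onsets[k + 1]
        idx = np.flatnonzero((t >= on - 1e-12) & (t < off - 1e-12))
        if idx.size == 0:
            prev_label = seg.label
            continue
        tau = t[idx] - on
        base = _SEDENTARY_DEG if seg.label is ActivityLabel.SEDENTARY else _UPRIGHT_DEG
        angle_deg[idx] = base
        if prev_label is not None and _is_upright(prev_label) != _is_upright(seg.label):
            ramp = min(script.transition_ramp_s, seg.duration_s)
            if ramp > 0:
                prev_base = _SEDENTARY_DEG if prev_label is ActivityLabel.SEDENTARY else _UPRIGHT_DEG
                in_ramp = tau < ramp
                angle_deg[idx[in_ramp]] = prev_base + (base - prev_base) * tau[in_ramp] / ramp
        if seg.label is ActivityLabel.DYNAMIC and seg.gait is not None:
            g = seg.gait
            ap_extra[idx] += g.ap_amplitude_g * np.sin(2 * np.pi * g.step_frequency_hz * tau)
            long_extra[idx] += g.vertical_amplitude_g * np.sin(2 * np.pi * 2 * g.step_frequency_hz * tau)
        elif seg.label is ActivityLabel.STANDING and seg.sway_amplitude_g > 0:
            ap_extra[idx] += seg.sway_amplitude_g * np.sin(2 * np.pi * script.sway_frequency_hz * tau)
        prev_label = seg.label

    angle = np.deg2rad(angle_deg)
    longitudinal = np.cos(angle) + long_extra
    anterior_posterior = np.sin(angle) + ap_extra

    rng = np.random.default_rng(script.seed)
    noise = rng.normal(0.0, script.noise_sd_g, size=(n, 3)) if script.noise_sd_g > 0 else np.zeros((n, 3))

    samples = np.zeros((n, 3))
    for role, trace in (
        ("longitudinal", longitudinal),
        ("anterior_posterior", anterior_posterior),
        ("medio_lateral", np.zeros(n)),
    ):
        col, sign = axis_roles.column(role)
        samples[:, col] = sign * trace
    samples += noise
    np.clip(samples, -8.0, 8.0, out=samples)

    recording = AccelRecording(
        samples=samples, sample_rate_hz=sample_rate_hz, axis_roles=axis_roles, subject_id=subject_id
    )
    truth = ReferenceEvents.from_segments((s.label, s.duration_s) for s in script.segments)
    return SimulatedSubject(recording=recording, truth=truth, script=script)


def scale_gait_amplitudes(script: ActivityScript, scale: float) -> ActivityScript:
    """Multiply every dynamic bout's gait amplitudes by ``scale``.

    Noise, sway, durations and the seed are untouched, so a scaled script
    reuses the identical noise realization — the tool for amplitude-ladder
    experiments probing how shuffling-level gait degrades classification.
    """
    if scale < 0:
        raise ValueError("scale must be non-negative")
    segments = []
    for seg in script.segments:
        if seg.label is ActivityLabel.DYNAMIC and seg.gait is not None:
            gait = replace(
                seg.gait,
                ap_amplitude_g=seg.gait.ap_amplitude_g * scale,
                vertical_amplitude_g=seg.gait.vertical_amplitude_g * scale,
            )
            segments.append(replace(seg, gait=gait))
        else:
            segments.append(seg)
    return replace(script, segments=tuple(segments))


@dataclass(frozen=True)
class ScenarioSpec:
    """Distributions from which a scenario draws per-subject scripts.

    Duration ranges are uniform in seconds; amplitude/frequency ranges are
    uniform per bout.  ``grid_align_s`` rounds bout durations up to a
    multiple (used by the verification scenario so bouts tile the analysis
    windows exactly).
    """

    name: str
    session_min_range: tuple[float, float] = (8.0, 15.0)
    sed_range_s: tuple[float, float] = (40.0, 120.0)
    stand_range_s: tuple[float, float] = (8.0, 30.0)
    dyn_range_s: tuple[float, float] = (30.0, 90.0)
    gait_amp_range_g: tuple[float, float] = (0.25, 0.50)
    gait_freq_range_hz: tuple[float, float] = (1.4, 2.0)
    vertical_ratio: float = 0.5
    sway_range_g: tuple[float, float] = (0.02, 0.06)
    noise_sd_g: float = 0.02
    transition_ramp_s: float = 2.0
    grid_align_s: float | None = None


SCENARIOS: dict[str, ScenarioSpec] = {
    # Elective knee/hip arthroplasty patients: slow but clearly oscillatory gait.
    "orthopedic": ScenarioSpec(name="orthopedic"),
    # Acutely hospitalized elderly: shuffling, low-amplitude, slower cadence,
    # longer sedentary bouts, slightly more fidgeting while standing.
    "elderly_shuffling": ScenarioSpec(
        name="elderly_shuffling",
        sed_range_s=(60.0, 180.0),
        stand_range_s=(10.0, 40.0),
        dyn_range_s=(20.0, 60.0),
        gait_amp_range_g=(0.08, 0.22),
        gait_freq_range_hz=(1.1, 1.7),
        sway_range_g=(0.03, 0.08),
    ),
    # Noise-controlled verification scenario: bouts aligned to the 4 s grid,
    # quiet standing, vigorous well-separated gait, near-zero sensor noise.
    "well_separated": ScenarioSpec(
        name="well_separated",
        session_min_range=(5.0, 8.0),
        sed_range_s=(32.0, 60.0),
        stand_range_s=(12.0, 32.0),
        dyn_range_s=(32.0, 60.0),
        gait_amp_range_g=(0.45, 0.45),
        gait_freq_range_hz=(2.0, 2.0),
        sway_range_g=(0.0, 0.0),
        noise_sd_g=0.005,
        grid_align_s=4.0,
    ),
}


def _draw_duration(rng: np.random.Generator, lo_hi: tuple[float, float], align: float | None) -> float:
    d = float(rng.uniform(*lo_hi))
    if align is not None:
        d = float(np.ceil(d / align) * align)
    return d


def build_script(spec: ScenarioSpec, rng: np.random.Generator) -> ActivityScript:
    """Draw one subject's script: SED → DYN → STAND → DYN cycles, ending SED.

    Upright bouts start with a dynamic segment (patients stand up and walk),
    so every session contains at least one of every activity and at least
    one sedentary→upright postural transition.
    """
    target_s = float(rng.uniform(*spec.session_min_range)) * 60.0
    align = spec.grid_align_s

    def dyn_segment() -> Segment:
        amp = float(rng.uniform(*spec.gait_amp_range_g))
        return Segment(
            label=ActivityLabel.DYNAMIC,
            duration_s=_draw_duration(rng, spec.dyn_range_s, align),
            gait=GaitProfile(
                step_frequency_hz=float(rng.uniform(*spec.gait_freq_range_hz)),
                ap_amplitude_g=amp,
                vertical_amplitude_g=spec.vertical_ratio * amp,
            ),
        )

    segments: list[Segment] = []
    while not segments or sum(s.duration_s for s in segments) < target_s:
        segments.append(Segment(ActivityLabel.SEDENTARY, _draw_duration(rng, spec.sed_range_s, align)))
        segments.append(dyn_segment())
        segments.append(
            Segment(
                ActivityLabel.STANDING,
                _draw_duration(rng, spec.stand_range_s, align),
                sway_amplitude_g=float(rng.uniform(*spec.sway_range_g)),
            )
        )
        segments.append(dyn_segment())
    segments.append(Segment(ActivityLabel.SEDENTARY, _draw_duration(rng, spec.sed_range_s, align)))

    return ActivityScript(
        segments=tuple(segments),
        transition_ramp_s=spec.transition_ramp_s,
        noise_sd_g=spec.noise_sd_g,
        seed=int(rng.integers(2**31)),
    )


def simulate_cohort(
    n_subjects: int,
    scenario: str | ScenarioSpec = "orthopedic",
    seed: int = 0,
    sample_rate_hz: float = 25.0,
) -> list[SimulatedSubject]:
    """Simulate ``n_subjects`` independent subjects from one scenario.

    Per-subject randomness is split from ``seed`` via SeedSequence, so the
    cohort is reproducible and subjects are statistically independent.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    spec = SCENARIOS[scenario] if isinstance(scenario, str) else scenario
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    subjects = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        script = build_script(spec, rng)
        subjects.append(
            simulate_subject(script, sample_rate_hz=sample_rate_hz, subject_id=f"{spec.name}-{i:03d}")
        )
    return subjects
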