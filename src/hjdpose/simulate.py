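"""Synthetic supine-infant motion-capture cohorts.

The generator emulates the statistical structure the HJD pipeline assumes:
12 markers at 100 Hz on a supine skeleton, with limb motion modelled as an
Ornstein-Uhlenbeck (OU) process around a rest posture.  Stage identity
modulates the process — diffuse exploration in the spontaneous baseline
(B1), globally reduced amplitude with freeze bouts when the experimenter
moves the mobile (B2), alternating freeze/move with rising amplitude in the
first tethered minute (CR1), a raised, vertically oscillating trigger foot
late in tethering (CR2), and elevated diffuse activity after decoupling
(DC).  A single ``separation`` knob (delta in [0, 1]) scales every
stage-profile difference: at delta = 0 all stages share the baseline
profile and carry no class signal.

Each subject is rigidly re-posed (random yaw + translation) in the capture
volume, so view invariance of downstream descriptors is exercised by
construction.  Marker jitter, spike outliers and occlusion gaps can be
layered on with :func:`inject_artifacts`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import KeypointSchema, MocapRecording, StageAnnotation, STAGES

__all__ = [
    "StageProfile",
    "CohortSpec",
    "ArtifactMask",
    "REST_POSTURE",
    "generate_subject",
    "inject_artifacts",
    "generate_cohort",
]

#: Supine rest posture in a canonical body frame (mm): x lateral (left to
#: right), y longitudinal toward the head, z up out of the belly.
REST_POSTURE = {
    "Head": (0.0, 320.0, 30.0),
    "CenterPelvis": (0.0, 0.0, 0.0),
    "LHip": (-40.0, 10.0, 0.0),
    "RHip": (40.0, 10.0, 0.0),
    "LShoulder": (-70.0, 250.0, 20.0),
    "RShoulder": (70.0, 250.0, 20.0),
    "LHand": (-110.0, 150.0, 40.0),
    "RHand": (110.0, 150.0, 40.0),
    "LKnee": (-60.0, -90.0, 50.0),
    "RKnee": (60.0, -90.0, 50.0),
    "LFoot": (-70.0, -180.0, 40.0),
    "RFoot": (70.0, -180.0, 40.0),
}

DEFAULT_DURATIONS = {"B1": 120.0, "B2": 120.0, "CR1": 60.0, "CR2": 120.0, "DC": 120.0}


@dataclass(frozen=True)
class StageProfile:
    """Motion parameters of one joint in one stage.

    The joint follows a sinusoidal mean path around its rest position
    (per-body-axis amplitudes ``path_amp_mm`` and frequencies
    ``path_freq_hz``, subject-random phases), which sets the *spatial
    topology* of the movement — how many direction bins the joint sweeps —
    while an OU process of stationary sd ``amp_mm`` rides on top as motor
    noise.  Freeze bouts are a two-state Markov gate (entry rate per
    second, mean bout duration in seconds) that halts the joint;
    ``offset_z_mm`` raises the mean posture along the body-vertical axis.
    """

    amp_mm: float = 12.0
    reversion_rate: float = 1.5
    path_amp_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    path_freq_hz: tuple[float, float, float] = (0.25, 0.2, 0.18)
    freeze_rate: float = 0.0
    freeze_dur_s: float = 1.0
    offset_z_mm: float = 0.0


@dataclass(frozen=True)
class CohortSpec:
    """Study-level generation parameters.

    Defaults mirror the study conditions: five subjects, trigger foot on
    the left for subjects 1, 3, 5 and the right for 2 and 4, and nominal
    stage durations of 120/120/60/120/120 s for B1/B2/CR1/CR2/DC.
    """

    seed: int
    n_subjects: int = 5
    trigger_sides: tuple[str, ...] = ("L", "R", "L", "R", "L")
    stage_durations: dict = field(default_factory=lambda: dict(DEFAULT_DURATIONS))
    separation: float = 1.0
    sample_rate: float = 100.0
    jitter_sd_mm: float = 0.5
    spike_rate: float = 0.0
    spike_mm: float = 300.0
    gap_rate: float = 0.0
    gap_mean_len: int = 20

    def __post_init__(self):
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError("separation must lie in [0, 1]")
        if len(self.trigger_sides) < self.n_subjects:
            raise ValueError("need a trigger side per subject")
        for s in self.trigger_sides[: self.n_subjects]:
            if s not in ("L", "R"):
                raise ValueError("trigger sides must be 'L' or 'R'")


@dataclass
class ArtifactMask:
    """Ground-truth artifact locations from :func:`inject_artifacts`."""

    spikes: np.ndarray  # (F, K) bool
    gaps: np.ndarray    # (F, K) bool


# Per-role stage profiles at full separation.  The B1 row doubles as the
# delta = 0 baseline for its role, so every parameter interpolates linearly
# between its B1 value and its stage value.  The trigger-foot rows encode
# the study's qualitative stage signatures: widespread slow wander at
# baseline, near-stationary foot with freeze bouts when the mobile moves on
# its own, lateral exploration with freeze/move alternation early in
# tethering, a raised foot pumping along the body-vertical axis late in
# tethering, and the broadest, most vigorous wander after decoupling.
_PROFILES = {
    "trigger_foot": {
        "B1": StageProfile(amp_mm=15.0, path_amp_mm=(90.0, 40.0, 90.0)),
        "B2": StageProfile(amp_mm=6.0, path_amp_mm=(10.0, 5.0, 10.0),
                           freeze_rate=0.20, freeze_dur_s=2.0),
        "CR1": StageProfile(amp_mm=13.0, path_amp_mm=(130.0, 25.0, 50.0),
                            path_freq_hz=(0.6, 0.4, 0.5),
                            freeze_rate=0.25, freeze_dur_s=1.2, offset_z_mm=15.0),
        "CR2": StageProfile(amp_mm=8.0, path_amp_mm=(15.0, 10.0, 130.0),
                            path_freq_hz=(0.3, 0.3, 0.8), offset_z_mm=80.0),
        "DC": StageProfile(amp_mm=18.0, path_amp_mm=(110.0, 60.0, 110.0),
                           path_freq_hz=(0.4, 0.3, 0.5)),
    },
    "other_foot": {
        "B1": StageProfile(amp_mm=15.0, path_amp_mm=(90.0, 40.0, 90.0)),
        "B2": StageProfile(amp_mm=8.0, path_amp_mm=(25.0, 12.0, 25.0),
                           freeze_rate=0.10, freeze_dur_s=1.5),
        "CR1": StageProfile(amp_mm=13.0, path_amp_mm=(110.0, 30.0, 60.0),
                            path_freq_hz=(0.5, 0.4, 0.45),
                            freeze_rate=0.12, freeze_dur_s=1.0),
        "CR2": StageProfile(amp_mm=10.0, path_amp_mm=(35.0, 20.0, 90.0),
                            path_freq_hz=(0.35, 0.3, 0.6), offset_z_mm=40.0),
        "DC": StageProfile(amp_mm=16.0, path_amp_mm=(100.0, 50.0, 100.0),
                           path_freq_hz=(0.4, 0.3, 0.45)),
    },
    "hand": {
        "B1": StageProfile(amp_mm=10.0, path_amp_mm=(55.0, 25.0, 40.0),
                           path_freq_hz=(0.3, 0.25, 0.35)),
        "B2": StageProfile(amp_mm=8.0, path_amp_mm=(40.0, 18.0, 28.0),
                           path_freq_hz=(0.3, 0.25, 0.35),
                           freeze_rate=0.08, freeze_dur_s=1.5),
        "CR1": StageProfile(amp_mm=10.0, path_amp_mm=(58.0, 26.0, 42.0),
                            path_freq_hz=(0.3, 0.25, 0.35)),
        "CR2": StageProfile(amp_mm=10.0, path_amp_mm=(60.0, 27.0, 44.0),
                            path_freq_hz=(0.3, 0.25, 0.35)),
        "DC": StageProfile(amp_mm=13.0, path_amp_mm=(66.0, 30.0, 48.0),
                           path_freq_hz=(0.3, 0.25, 0.35)),
    },
    "knee": {
        "B1": StageProfile(amp_mm=8.0, path_amp_mm=(45.0, 18.0, 45.0),
                           path_freq_hz=(0.3, 0.25, 0.3)),
        "B2": StageProfile(amp_mm=6.0, path_amp_mm=(28.0, 11.0, 28.0),
                           path_freq_hz=(0.3, 0.25, 0.3),
                           freeze_rate=0.10, freeze_dur_s=1.5),
        "CR1": StageProfile(amp_mm=9.0, path_amp_mm=(50.0, 20.0, 48.0),
                            path_freq_hz=(0.35, 0.25, 0.33)),
        "CR2": StageProfile(amp_mm=8.0, path_amp_mm=(20.0, 12.0, 62.0),
                            path_freq_hz=(0.3, 0.25, 0.5), offset_z_mm=18.0),
        "DC": StageProfile(amp_mm=12.0, path_amp_mm=(56.0, 24.0, 56.0),
                           path_freq_hz=(0.35, 0.3, 0.4)),
    },
    # trunk markers keep the body frame stable; no stage modulation
    "core": {s: StageProfile(amp_mm=2.0, reversion_rate=2.0) for s in STAGES},
}


def _role_of(name: str, trigger_side: str) -> str:
    if name.endswith("Foot"):
        return "trigger_foot" if name.startswith(trigger_side) else "other_foot"
    if name.endswith("Hand"):
        return "hand"
    if name.endswith("Knee"):
        # the knee on the trigger side co-moves with the tethered foot
        return "knee"
    return "core"


def _lerp(a: float, b: float, delta: float) -> float:
    return a + delta * (b - a)


def _stage_profile(role: str, stage: str, delta: float) -> StageProfile:
    base = _PROFILES[role]["B1"]
    tgt = _PROFILES[role][stage]
    return StageProfile(
        amp_mm=_lerp(base.amp_mm, tgt.amp_mm, delta),
        reversion_rate=_lerp(base.reversion_rate, tgt.reversion_rate, delta),
        path_amp_mm=tuple(
            _lerp(a, b, delta) for a, b in zip(base.path_amp_mm, tgt.path_amp_mm)
        ),
        path_freq_hz=tuple(
            _lerp(a, b, delta) for a, b in zip(base.path_freq_hz, tgt.path_freq_hz)
        ),
        freeze_rate=_lerp(base.freeze_rate, tgt.freeze_rate, delta),
        freeze_dur_s=_lerp(base.freeze_dur_s, tgt.freeze_dur_s, delta),
        offset_z_mm=_lerp(base.offset_z_mm, tgt.offset_z_mm, delta),
    )


def _annotation(spec: CohortSpec) -> StageAnnotation:
    t, ivs = 0.0, []
    for s in STAGES:
        d = float(spec.stage_durations[s])
        ivs.append((t, t + d, s))
        t += d
    return StageAnnotation(tuple(ivs))


def generate_subject(spec: CohortSpec, subject_index: int):
    """Simulate one subject; returns ``(MocapRecording, StageAnnotation)``.

    The trajectory is generated in the canonical supine frame and then
    rigidly re-posed with a subject-specific yaw and translation.
    Determinism: the subject's stream derives from ``(spec.seed,
    subject_index)`` only.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(subject_index)]))
    schema = KeypointSchema()
    fs = spec.sample_rate
    dt = 1.0 / fs
    ann = _annotation(spec)
    frames_per_stage = [int(round(float(spec.stage_durations[s]) * fs)) for s in STAGES]
    F = sum(frames_per_stage)
    K = len(schema.names)
    trigger = spec.trigger_sides[subject_index]

    # per-frame stage index
    stage_idx = np.repeat(np.arange(5), frames_per_stage)
    t_axis = np.arange(F) * dt

    rest = np.array([REST_POSTURE[n] for n in schema.names])
    roles = [_role_of(n, trigger) for n in schema.names]
    profs = [[_stage_profile(r, s, spec.separation) for s in STAGES] for r in roles]

    # per-frame parameter tables (F, K)
    amp = np.empty((F, K))
    theta = np.empty((F, K))
    fz_in = np.empty((F, K))
    fz_out = np.empty((F, K))
    mu = np.empty((F, K, 3))
    phase = rng.uniform(0, 2 * np.pi, size=(K, 3))
    for k in range(K):
        for si in range(5):
            p = profs[k][si]
            m = stage_idx == si
            amp[m, k] = p.amp_mm
            theta[m, k] = p.reversion_rate
            fz_in[m, k] = p.freeze_rate * dt
            fz_out[m, k] = dt / p.freeze_dur_s
            mu[m, k, :] = rest[k]
            mu[m, k, 2] += p.offset_z_mm
            for ax in range(3):
                if p.path_amp_mm[ax] > 0:
                    mu[m, k, ax] += p.path_amp_mm[ax] * np.sin(
                        2 * np.pi * p.path_freq_hz[ax] * t_axis[m] + phase[k, ax]
                    )

    xi = rng.standard_normal((F, K, 3))
    sigma = amp * np.sqrt(2.0 * theta)  # stationary sd = amp
    u = rng.random((F, K))  # freeze-gate transitions

    pos = np.empty((F, K, 3))
    x = mu[0].copy()
    frozen = np.zeros(K, dtype=bool)
    for f in range(F):
        frozen = np.where(frozen, u[f] >= fz_out[f], u[f] < fz_in[f])
        gate = (~frozen)[:, None]
        drift = theta[f][:, None] * (mu[f] - x) * dt
        diff = sigma[f][:, None] * np.sqrt(dt) * xi[f]
        x = x + gate * (drift + diff)
        pos[f] = x

    pos += rng.normal(0.0, spec.jitter_sd_mm, size=pos.shape)

    # rigid re-pose in the capture volume
    yaw = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(yaw), np.sin(yaw)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    T = rng.uniform(-500.0, 500.0, size=3)
    pos = pos @ R.T + T

    rec = MocapRecording(f"S{subject_index + 1}", pos, fs, 0.0, schema)
    return rec, ann


def inject_artifacts(rec: MocapRecording, spec: CohortSpec, seed: int | None = None):
    """Add seeded spike outliers and occlusion gaps to a clean recording.

    Spikes displace isolated (frame, marker) samples by ``spike_mm`` (far
    beyond three standard deviations of any series the generator produces);
    gaps are contiguous NaN runs with geometric lengths.  Returns the
    corrupted recording and the ground-truth :class:`ArtifactMask`.
    """
    if np.isnan(rec.positions).any():
        raise ValueError("input recording must be sentinel-free")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed if seed is None else seed), 98321])
    )
    F, K, _ = rec.positions.shape
    pos = rec.positions.copy()

    spikes = rng.random((F, K)) < spec.spike_rate
    signs = rng.choice([-1.0, 1.0], size=(F, K, 3))
    pos[spikes] += (spec.spike_mm * signs)[spikes]

    gaps = np.zeros((F, K), dtype=bool)
    starts = rng.random((F, K)) < spec.gap_rate
    if spec.gap_rate > 0:
        lens = rng.geometric(1.0 / max(spec.gap_mean_len, 1), size=(F, K))
        for f, k in zip(*np.nonzero(starts)):
            gaps[f : f + lens[f, k], k] = True
    pos[gaps] = np.nan

    out = MocapRecording(rec.subject_id, pos, rec.sample_rate, rec.start_time, rec.schema)
    return out, ArtifactMask(spikes & ~gaps, gaps)


def generate_cohort(spec: CohortSpec, artifacts: bool = False):
    """Generate ``n_subjects`` independent subjects plus a manifest.

    Returns ``(subjects, manifest)`` where ``subjects`` is a list of
    ``(recording, annotation)`` (or ``(recording, annotation, mask)`` when
    ``artifacts`` is set) and the manifest records the spec and a content
    hash for provenance.
    """
    subjects = []
    for i in range(spec.n_subjects):
        rec, ann = generate_subject(spec, i)
        if artifacts:
            rec, mask = inject_artifacts(rec, spec, seed=spec.seed + i + 1)
            subjects.append((rec, ann, mask))
        else:
            subjects.append((rec, ann))
    payload = json.dumps(asdict(spec), sort_keys=True, default=str)
    manifest = {
        "spec": asdict(spec),
        "spec_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "subjects": [f"S{i + 1}" for i in range(spec.n_subjects)],
        "trigger_sides": list(spec.trigger_sides[: spec.n_subjects]),
    }
    return subjects, manifest
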