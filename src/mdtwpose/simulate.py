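"""Synthetic lower-limb kinematics for the twelve posture classes.

The generator emulates the structure the classifier assumes: each trial
is a stand -> descend -> 5 s hold -> ascend -> stand angle profile per
joint, built from raised-cosine ramps, with class-specific peak flexion,
per-subject depth and tempo offsets, per-trial jitter, truncated
Gaussian measurement noise, optional lead-in/lead-out steps for the
non-seated classes, and periodic multi-stride gait for walking. Profile
numbers are fixture parameters chosen to respect the qualitative posture
descriptions (high-flexion classes exceed 120 deg of knee flexion,
stooping hinges at the hip with the knee below 90 deg, standing stays at
baseline); they are an editable table, not measured data.

One master seed fans out deterministically: the random stream for any
single trial is seeded by (master_seed, subject index, class index,
trial index, purpose), so every trial is regenerable in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .classify import TemplateLibrary
from .preprocessing import make_template, relabel_class, segment_gait_cycles
from .sequences import CHANNELS, CLASS_ORDER, MovementSequence, SequenceError

__all__ = [
    "ClassKinematicProfile",
    "SubjectOffsets",
    "SyntheticCohort",
    "DEFAULT_PROFILES",
    "generate_trial",
    "generate_gait",
    "generate_cohort",
]

#: Standing baseline angles (degrees of flexion) per channel.
BASELINE = {"r_knee": 5.0, "l_knee": 5.0, "r_ankle": 2.0, "l_ankle": 2.0,
            "r_hip": 5.0, "l_hip": 5.0}


@dataclass(frozen=True)
class ClassKinematicProfile:
    """Fixture parameters describing one posture class.

    ``peaks`` gives the fully-flexed angle per channel (degrees, flexion
    positive; plantarflexion is negative ankle flexion). Durations are
    in seconds; ``duration_jitter`` is the relative half-range of
    per-trial uniform duration jitter; ``peak_jitter_sd`` and
    ``noise_sd`` are in degrees. ``lead_steps`` prepends/appends a
    half-stride step, as performed for the non-seated postures.
    """

    class_id: str
    peaks: dict[str, float]
    descent_s: float = 1.5
    hold_s: float = 5.0  # fully flexed pose held for 5 s
    ascent_s: float = 1.5
    stand_s: float = 0.8  # quiet standing before/after the movement
    duration_jitter: float = 0.1
    peak_jitter_sd: float = 2.0
    noise_sd: float = 1.0
    lead_steps: bool = True
    depth_scale: dict[str, float] = field(default_factory=dict)

    def peak(self, channel: str) -> float:
        return self.peaks.get(channel, BASELINE[channel])


def _profile(class_id, r_knee, l_knee, r_ankle, l_ankle, r_hip, l_hip, **kw):
    return ClassKinematicProfile(
        class_id=class_id,
        peaks={"r_knee": r_knee, "l_knee": l_knee, "r_ankle": r_ankle,
               "l_ankle": l_ankle, "r_hip": r_hip, "l_hip": l_hip},
        **kw,
    )


#: Per-class peak angles. High-flexion classes keep the right knee above
#: 120 deg; DK/PK/SK differ chiefly in ankle sign (dorsi- vs
#: plantarflexed feet); heels-up squatting has raised heels
#: (plantarflexed ankles) where flatfoot squatting is deeply dorsiflexed;
#: side sitting is asymmetric; stooping is hip-dominant with the knee
#: kept below 90 deg. Scale normalization preserves only between-joint
#: amplitude ratios, so the profiles are chosen to keep each class's
#: (hip/knee, ankle/knee) ratio pair well separated.
DEFAULT_PROFILES: dict[str, ClassKinematicProfile] = {
    "HS": _profile("HS", 145, 143, -20, -19, 95, 93),
    "FS": _profile("FS", 138, 136, 35, 34, 112, 110),
    "DK": _profile("DK", 150, 149, 28, 27, 75, 74),
    "PK": _profile("PK", 150, 149, -35, -34, 70, 69),
    "SK": _profile("SK", 122, 121, -22, -21, 105, 104),
    "ACS": _profile("ACS", 92, 91, 10, 9, 70, 69, lead_steps=False),
    "CCS": _profile("CCS", 128, 127, 20, 19, 122, 120, lead_steps=False),
    "CLS": _profile("CLS", 130, 110, -12, -10, 100, 98, lead_steps=False),
    "SS": _profile("SS", 140, 115, -25, -8, 55, 95, lead_steps=False),
    "STP": _profile("STP", 62, 60, 6, 6, 102, 100),
    "STD": _profile("STD", 5, 5, 2, 2, 5, 5, lead_steps=False),
    # walking: swing-phase peaks; trial shape comes from generate_gait
    "WLK": _profile("WLK", 62, 62, 14, 14, 32, 32, lead_steps=False),
}


@dataclass(frozen=True)
class SubjectOffsets:
    """Per-subject systematic deviations from the nominal profiles.

    Depth offsets are drawn independently per joint pair, emulating how
    individuals reach different knee depths, hip inclinations and ankle
    mobility within one posture; this changes the between-joint
    amplitude ratios that survive scale normalization, which is what
    makes novel subjects genuinely harder than held-in ones.
    """

    subject_id: str
    depth_knee: float = 0.0  # degrees added to knee peaks
    depth_hip: float = 0.0  # degrees added to hip peaks
    depth_ankle: float = 0.0  # degrees added to ankle peaks
    tempo: float = 0.0  # relative speed offset; durations scale by (1 + tempo)

    def depth(self, channel: str) -> float:
        if channel.endswith("knee"):
            return self.depth_knee
        if channel.endswith("hip"):
            return self.depth_hip
        return self.depth_ankle


def _cosine_ramp(n: int) -> np.ndarray:
    """Monotone 0 -> 1 raised-cosine ramp over n samples."""
    tau = np.linspace(0.0, 1.0, max(n, 2))
    return 0.5 * (1.0 - np.cos(np.pi * tau))


def _noise(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    """Measurement noise: Gaussian truncated at +/-3 sd."""
    if sd <= 0:
        return np.zeros(shape)
    return np.clip(rng.normal(0.0, sd, shape), -3.0 * sd, 3.0 * sd)


def _step_bump(n: int, knee_amp: float, right_leads: bool) -> dict[str, np.ndarray]:
    """A half-stride step: a knee flexion bump with hip/ankle co-motion."""
    tau = np.linspace(0.0, 1.0, max(n, 2))
    bump = np.sin(np.pi * tau) ** 2
    lead, trail = ("r_", "l_") if right_leads else ("l_", "r_")
    out = {c: np.zeros_like(tau) for c in CHANNELS}
    out[lead + "knee"] = knee_amp * bump
    out[trail + "knee"] = 0.35 * knee_amp * bump
    out[lead + "hip"] = 0.45 * knee_amp * bump
    out[trail + "hip"] = 0.15 * knee_amp * bump
    out[lead + "ankle"] = 0.18 * knee_amp * bump
    out[trail + "ankle"] = 0.08 * knee_amp * bump
    return out


def trial_rng(
    master_seed: int, subject_idx: int, class_idx: int, trial_idx: int, purpose: int = 0
) -> np.random.Generator:
    """Deterministic per-trial random stream (counter-based seeding)."""
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, subject_idx, class_idx, trial_idx, purpose])
    )


def generate_trial(
    class_id: str,
    profile: Optional[ClassKinematicProfile] = None,
    subject: Optional[SubjectOffsets] = None,
    seed: int | np.random.Generator = 0,
    sample_rate: float = 60.0,
    include_steps: Optional[bool] = None,
) -> MovementSequence:
    """One labelled stand->descend->hold->ascend->stand trial.

    ``include_steps`` overrides the profile's lead-in/lead-out step
    convention (segmented exemplar trials omit the steps, continuous
    movement sequences include them for the stepping classes).
    """
    profile = profile or DEFAULT_PROFILES[class_id]
    if class_id == "WLK":
        return generate_gait(3, profile=profile, subject=subject, seed=seed,
                             sample_rate=sample_rate)
    subject = subject or SubjectOffsets(subject_id="S00")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if min(profile.descent_s, profile.hold_s, profile.ascent_s) <= 0:
        raise SequenceError("phase durations must be positive")

    tempo = (1.0 + subject.tempo) * (
        1.0 + rng.uniform(-profile.duration_jitter, profile.duration_jitter)
    )
    tempo = max(tempo, 0.2)

    def n_of(seconds: float) -> int:
        return max(2, int(round(seconds * tempo * sample_rate)))

    n_stand = n_of(profile.stand_s)
    n_desc, n_hold, n_asc = n_of(profile.descent_s), n_of(profile.hold_s), n_of(profile.ascent_s)

    use_steps = profile.lead_steps if include_steps is None else include_steps
    n_step = n_of(0.7) if use_steps else 0

    rows = []
    step_in = _step_bump(n_step, 50.0, right_leads=True) if use_steps else None
    step_out = _step_bump(n_step, 50.0, right_leads=True) if use_steps else None
    for c in CHANNELS:
        base = BASELINE[c]
        peak = profile.peak(c)
        if abs(peak - base) > 1e-9:  # moving channel: subject depth + trial jitter
            peak += subject.depth(c) * np.sign(peak - base)
            peak += rng.normal(0.0, profile.peak_jitter_sd)
        parts = [np.full(n_stand, base)]
        if use_steps:
            parts.append(base + step_in[c])
        parts.append(base + (peak - base) * _cosine_ramp(n_desc))
        parts.append(np.full(n_hold, peak))
        parts.append(peak + (base - peak) * _cosine_ramp(n_asc))
        if use_steps:
            parts.append(base + step_out[c])
        parts.append(np.full(n_stand, base))
        rows.append(np.concatenate(parts))
    angles = np.vstack(rows)
    angles += _noise(rng, angles.shape, profile.noise_sd)
    return MovementSequence(
        angles=angles,
        label=class_id,
        subject_id=subject.subject_id,
        sample_rate=sample_rate,
        meta={"synthetic": True, "steps": bool(use_steps)},
    )


def generate_gait(
    n_strides: int,
    profile: Optional[ClassKinematicProfile] = None,
    subject: Optional[SubjectOffsets] = None,
    seed: int | np.random.Generator = 0,
    sample_rate: float = 60.0,
    stride_s: float = 1.1,
    stand_s: float = 0.0,
) -> MovementSequence:
    """A walking trial of ``n_strides`` concatenated gait cycles.

    Each stride is a periodic knee-flexion bump (swing phase) with
    sinusoidal hip motion and a small ankle bump; the contralateral leg
    runs half a stride out of phase. Strides start and end at maximum
    knee extension, so trough-based segmentation recovers them.
    ``stand_s`` seconds of quiet standing are prepended and appended
    when nonzero, as in an unsegmented walk bout recorded from a
    standing start.
    """
    if n_strides < 1:
        raise SequenceError("n_strides must be >= 1")
    profile = profile or DEFAULT_PROFILES["WLK"]
    subject = subject or SubjectOffsets(subject_id="S00")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def bump(tau: np.ndarray, center: float, width: float) -> np.ndarray:
        phase = np.clip((tau - (center - width)) / (2 * width), 0.0, 1.0)
        return np.sin(np.pi * phase) ** 2

    rows = {c: [] for c in CHANNELS}
    for _ in range(n_strides):
        dur = stride_s * (1.0 + subject.tempo) * (
            1.0 + rng.uniform(-profile.duration_jitter, profile.duration_jitter)
        )
        n = max(8, int(round(dur * sample_rate)))
        tau = np.arange(n) / n  # [0, 1): stride ends just before next heel strike
        amp = {
            c: profile.peak(c)
            - BASELINE[c]
            + (rng.normal(0.0, profile.peak_jitter_sd) if profile.peak(c) != BASELINE[c] else 0.0)
            for c in CHANNELS
        }
        tau_l = (tau + 0.5) % 1.0
        rows["r_knee"].append(BASELINE["r_knee"] + amp["r_knee"] * bump(tau, 0.72, 0.22))
        rows["l_knee"].append(BASELINE["l_knee"] + amp["l_knee"] * bump(tau_l, 0.72, 0.22))
        rows["r_hip"].append(BASELINE["r_hip"] + amp["r_hip"] * np.sin(np.pi * tau) ** 2)
        rows["l_hip"].append(BASELINE["l_hip"] + amp["l_hip"] * np.sin(np.pi * tau_l) ** 2)
        rows["r_ankle"].append(BASELINE["r_ankle"] + amp["r_ankle"] * bump(tau, 0.55, 0.3))
        rows["l_ankle"].append(BASELINE["l_ankle"] + amp["l_ankle"] * bump(tau_l, 0.55, 0.3))
    if stand_s > 0:
        n_stand = max(2, int(round(stand_s * sample_rate)))
        for c in CHANNELS:
            pad = np.full(n_stand, BASELINE[c])
            rows[c] = [pad] + rows[c] + [pad]
    angles = np.vstack([np.concatenate(rows[c]) for c in CHANNELS])
    angles += _noise(rng, angles.shape, profile.noise_sd)
    return MovementSequence(
        angles=angles,
        label="WLK",
        subject_id=subject.subject_id,
        sample_rate=sample_rate,
        meta={"synthetic": True, "n_strides": n_strides},
    )


@dataclass
class SyntheticCohort:
    """Templates plus held-out queries generated from one master seed."""

    library: TemplateLibrary
    build_queries: list[MovementSequence]  # segmented-style, build subjects
    novel_queries: list[MovementSequence]  # segmented-style, novel subjects
    sequence_queries: list[MovementSequence]  # unsegmented, with steps / multi-stride
    build_subjects: list[str]
    novel_subjects: list[str]
    master_seed: int


def _subject_offsets(
    master_seed: int, n_subjects: int, depth_sd: float, tempo_sd: float
) -> list[SubjectOffsets]:
    rng = np.random.default_rng(np.random.SeedSequence([master_seed, 999]))
    return [
        SubjectOffsets(
            subject_id=f"S{i:02d}",
            depth_knee=float(rng.normal(0.0, depth_sd)),
            depth_hip=float(rng.normal(0.0, 0.75 * depth_sd)),
            depth_ankle=float(rng.normal(0.0, 0.5 * depth_sd)),
            tempo=float(rng.normal(0.0, tempo_sd)),
        )
        for i in range(n_subjects)
    ]


def generate_cohort(
    n_subjects: int = 10,
    n_novel: int = 3,
    trials_per_class: int = 3,
    queries_per_class: int = 3,
    profiles: Optional[dict[str, ClassKinematicProfile]] = None,
    master_seed: int = 0,
    depth_sd: float = 8.0,
    tempo_sd: float = 0.08,
    classes: Sequence[str] = CLASS_ORDER,
    scale_scope: str = "per_trial",
    walk_sequence_strides: int = 8,
) -> SyntheticCohort:
    """Generate a template library and held-out query sets.

    The first ``n_subjects - n_novel`` subjects contribute segmented
    template trials (walking trials are split into single-stride
    templates); all subjects contribute held-out query trials generated
    from independent random streams. ``build_queries`` come from the
    template-contributing subjects, ``novel_queries`` from the reserved
    novel subjects, both segmented-style; ``sequence_queries`` are
    continuous sequences (lead-in/out steps for stepping classes,
    three-stride gait for walking).
    """
    if n_subjects < 2 or not (0 < n_novel < n_subjects):
        raise SequenceError(
            f"need >= 2 subjects and 0 < n_novel < n_subjects; "
            f"got {n_subjects=}, {n_novel=}"
        )
    profiles = profiles or DEFAULT_PROFILES
    if depth_sd < 0 or tempo_sd < 0:
        raise SequenceError("variability parameters must be >= 0")
    offsets = _subject_offsets(master_seed, n_subjects, depth_sd, tempo_sd)
    build, novel = offsets[: n_subjects - n_novel], offsets[n_subjects - n_novel:]

    templates = []
    for si, subj in enumerate(build):
        for ci, cls in enumerate(classes):
            prof = replace(profiles[cls], lead_steps=False)
            for ti in range(trials_per_class):
                rng = trial_rng(master_seed, si, ci, ti, purpose=0)
                if cls == "WLK":
                    trial = generate_gait(3, profile=prof, subject=subj, seed=rng)
                    cycles, _ = segment_gait_cycles(trial)
                    for wi, cyc in enumerate(cycles):
                        templates.append(
                            make_template(
                                cyc, f"{subj.subject_id}-{cls}-{ti}c{wi}", scope=scale_scope
                            )
                        )
                else:
                    trial = generate_trial(cls, prof, subj, seed=rng, include_steps=False)
                    templates.append(
                        make_template(trial, f"{subj.subject_id}-{cls}-{ti}", scope=scale_scope)
                    )

    def make_queries(subjects, offset_base, purpose):
        seg, seqs = [], []
        for si, subj in enumerate(subjects):
            for ci, cls in enumerate(classes):
                prof = profiles[cls]
                for qi in range(queries_per_class):
                    rng = trial_rng(master_seed, offset_base + si, ci, 100 + qi, purpose)
                    if cls == "WLK":
                        # segmented query: one stride; sequence query: a full
                        # multi-stride walk, as recorded before segmentation
                        full = generate_gait(3, profile=prof, subject=subj, seed=rng)
                        cycles, _ = segment_gait_cycles(full)
                        one = cycles[0] if cycles else full
                        seg.append(_normalize_query(one, scale_scope))
                        rng2 = trial_rng(master_seed, offset_base + si, ci, 200 + qi, purpose)
                        walk = generate_gait(
                            walk_sequence_strides, profile=prof, subject=subj,
                            seed=rng2, stand_s=1.0,
                        )
                        seqs.append(_normalize_query(walk, scale_scope))
                    else:
                        iso = generate_trial(cls, prof, subj, seed=rng, include_steps=False)
                        seg.append(_normalize_query(iso, scale_scope))
                        rng2 = trial_rng(master_seed, offset_base + si, ci, 200 + qi, purpose)
                        stepped = generate_trial(cls, prof, subj, seed=rng2)
                        seqs.append(_normalize_query(stepped, scale_scope))
        return seg, seqs

    build_seg, build_seqs = make_queries(build, 0, purpose=1)
    novel_seg, novel_seqs = make_queries(novel, n_subjects - n_novel, purpose=1)

    lib = TemplateLibrary(
        templates=templates,
        provenance={
            "master_seed": master_seed,
            "build_subjects": [s.subject_id for s in build],
            "novel_subjects": [s.subject_id for s in novel],
            "trials_per_class": trials_per_class,
        },
    )
    return SyntheticCohort(
        library=lib,
        build_queries=build_seg,
        novel_queries=novel_seg,
        sequence_queries=build_seqs + novel_seqs,
        build_subjects=[s.subject_id for s in build],
        novel_subjects=[s.subject_id for s in novel],
        master_seed=master_seed,
    )


def _normalize_query(seq: MovementSequence, scope: str = "per_trial") -> MovementSequence:
    from .preprocessing import resample_to_length, scale_normalize

    out = scale_normalize(resample_to_length(seq), scope=scope)
    out.label = relabel_class(seq.label) if seq.label else None
    return out
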