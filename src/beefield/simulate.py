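"""Synthetic paired-visitation studies and field fixtures.

Emulates the structure of a paired floral-visitation experiment: in each
trial a treatment flower and a Paired Control flower are watched for 120
minutes and every honeybee landing is logged to the nearest minute. Control
landings follow a homogeneous Poisson process at ``base_rate`` landings per
minute; treatment landings follow an inhomogeneous Poisson process at rate
``base_rate * s(t)``, where the suppression ratio ``s(t)`` interpolates from
an initial value s0 at stimulus onset to a final value s_inf at the end of
the trial (exponential, linear or constant recovery).

The built-in presets encode the qualitative treatment dynamics of the system
this package analyses — strong initial AC suppression with rapid partial
rebound, gradual linear recovery for +DC, a near-control flat ratio for -DC,
and a no-effect NULL — as synthetic conventions for testing the pipeline,
not as measured field values.

Inhomogeneous sampling uses Poisson thinning of a homogeneous process at the
peak rate: exact, simple and stable under a fixed seed. Per-trial seeds are
derived from the study master seed with ``numpy.random.SeedSequence.spawn``,
so trials are independent but the whole study is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .permutation import PairedTrial
from .transect import (
    DEFAULT_CEILING_VPM,
    DEFAULT_HEIGHTS_M,
    DEFAULT_HORIZONTAL_M,
    TransectGrid,
)

__all__ = [
    "ScenarioPreset",
    "StudyDesign",
    "VisitEvent",
    "PRESETS",
    "ROLE_TREATMENT",
    "ROLE_CONTROL",
    "suppression_at",
    "mean_suppression",
    "simulate_trial",
    "simulate_study",
    "simulate_study_events",
    "synth_transect",
    "transect_field",
    "events_to_frame",
    "events_from_frame",
    "read_events_csv",
    "write_events_csv",
]

ROLE_TREATMENT = "treatment"
ROLE_CONTROL = "paired_control"
RECOVERY_SHAPES = ("exponential", "linear", "constant")


@dataclass(frozen=True)
class ScenarioPreset:
    """Treatment scenario: control landing rate and suppression trajectory.

    Parameters
    ----------
    name
        Scenario label (AC, POS_DC, NEG_DC, NULL, or a custom label).
    base_rate
        Expected control landings per minute (lambda, 1/min).
    initial_suppression, final_suppression
        Treatment/control rate ratio s(t) at stimulus onset and at the end
        of the trial, both in [0, 1].
    recovery_shape
        How s(t) moves from s0 to s_inf: "exponential" (time constant
        ``recovery_timescale``), "linear" (over the trial duration), or
        "constant" (s0 throughout; requires s0 == s_inf).
    recovery_timescale
        Exponential time constant in minutes (exponential shape only).
    """

    name: str
    base_rate: float
    initial_suppression: float
    final_suppression: float
    recovery_shape: str = "constant"
    recovery_timescale: float | None = None

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive (landings per minute)")
        for fld in ("initial_suppression", "final_suppression"):
            v = getattr(self, fld)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{fld} must lie in [0, 1], got {v}")
        if self.recovery_shape not in RECOVERY_SHAPES:
            raise ValueError(
                f"recovery_shape must be one of {RECOVERY_SHAPES}, "
                f"got {self.recovery_shape!r}"
            )
        if self.recovery_shape == "exponential":
            if self.recovery_timescale is None or self.recovery_timescale <= 0:
                raise ValueError(
                    "recovery_timescale (minutes, > 0) is required for "
                    "exponential recovery"
                )
        if self.recovery_shape == "constant":
            if self.initial_suppression != self.final_suppression:
                raise ValueError(
                    "constant recovery_shape requires initial_suppression == "
                    "final_suppression"
                )


@dataclass(frozen=True)
class StudyDesign:
    """Number of paired trials, trial duration, and the study master seed."""

    n_trials: int = 8
    duration_min: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.duration_min <= 0:
            raise ValueError("duration_min must be positive")


@dataclass(frozen=True)
class VisitEvent:
    """One landing: trial, flower role, and minute-resolution timestamp."""

    trial_id: int
    flower_role: str
    time_min: int


#: Default presets; suppression trajectories follow the observed
#: percent-of-control dynamics for each treatment class (synthetic
#: conventions; see docs/methods.md). base_rate 0.1/min gives ~12 expected
#: control landings per 120-min trial.
PRESETS: dict[str, ScenarioPreset] = {
    "AC": ScenarioPreset("AC", 0.1, 0.059, 0.681, "exponential", 10.0),
    "POS_DC": ScenarioPreset("POS_DC", 0.1, 0.40, 0.75, "linear"),
    "NEG_DC": ScenarioPreset("NEG_DC", 0.1, 0.744, 0.744, "constant"),
    "NULL": ScenarioPreset("NULL", 0.1, 1.0, 1.0, "constant"),
}


def suppression_at(
    preset: ScenarioPreset, t_min: np.ndarray | float, duration_min: float = 120.0
) -> np.ndarray | float:
    """Suppression ratio s(t) at time t minutes after stimulus onset."""
    s0, s_inf = preset.initial_suppression, preset.final_suppression
    t = np.asarray(t_min, dtype=float)
    if preset.recovery_shape == "constant":
        out = np.full_like(t, s0)
    elif preset.recovery_shape == "linear":
        out = s0 + (s_inf - s0) * t / duration_min
    else:  # exponential
        out = s_inf + (s0 - s_inf) * np.exp(-t / preset.recovery_timescale)
    return out if out.ndim else float(out)


def mean_suppression(preset: ScenarioPreset, duration_min: float = 120.0) -> float:
    """Time-averaged suppression (1/T) * integral of s(t) dt, in closed form."""
    s0, s_inf = preset.initial_suppression, preset.final_suppression
    if preset.recovery_shape == "constant":
        return s0
    if preset.recovery_shape == "linear":
        return (s0 + s_inf) / 2.0
    tau = preset.recovery_timescale
    return s_inf + (s0 - s_inf) * tau / duration_min * (1.0 - np.exp(-duration_min / tau))


def simulate_trial(
    preset: ScenarioPreset,
    duration_min: float = 120.0,
    seed: int | np.random.Generator | None = None,
    trial_id: int = 0,
) -> list[VisitEvent]:
    """Simulate one paired trial; returns control and treatment landings.

    Control events are a homogeneous Poisson process at ``base_rate``;
    treatment events are thinned from a homogeneous process at the same rate,
    each candidate kept with probability s(t). Event counts are fixed by the
    generated event set; only the logged timestamps are rounded to the
    nearest minute (two landings in one minute stay two rows).
    """
    rng = np.random.default_rng(seed)
    lam = preset.base_rate
    events: list[VisitEvent] = []
    # control: homogeneous at lam
    n_control = rng.poisson(lam * duration_min)
    t_control = np.sort(rng.uniform(0.0, duration_min, size=n_control))
    # treatment: thin a homogeneous process at the peak rate lam
    n_cand = rng.poisson(lam * duration_min)
    t_cand = np.sort(rng.uniform(0.0, duration_min, size=n_cand))
    keep = rng.random(n_cand) < suppression_at(preset, t_cand, duration_min)
    t_treat = t_cand[keep]
    for role, times in ((ROLE_CONTROL, t_control), (ROLE_TREATMENT, t_treat)):
        for t in times:
            events.append(VisitEvent(trial_id, role, int(round(t))))
    return events


def _trial_rngs(design: StudyDesign) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(design.seed).spawn(design.n_trials)]


def simulate_study_events(
    preset: ScenarioPreset, design: StudyDesign
) -> tuple[list[PairedTrial], list[VisitEvent]]:
    """Simulate a full study; returns per-trial counts and the event log."""
    pairs: list[PairedTrial] = []
    events: list[VisitEvent] = []
    for trial_id, rng in enumerate(_trial_rngs(design)):
        trial_events = simulate_trial(preset, design.duration_min, rng, trial_id)
        events.extend(trial_events)
        t = sum(1 for e in trial_events if e.flower_role == ROLE_TREATMENT)
        c = sum(1 for e in trial_events if e.flower_role == ROLE_CONTROL)
        pairs.append(PairedTrial(trial_id, t, c))
    return pairs, events


def simulate_study(preset: ScenarioPreset, design: StudyDesign) -> list[PairedTrial]:
    """Simulate ``design.n_trials`` independent paired trials (counts only)."""
    return simulate_study_events(preset, design)[0]


# ---------------------------------------------------------------------------
# transect fixture


def transect_field(
    horizontal_m,
    height_m,
    source_height_m: float = 10.0,
    amplitude: float = 150_000.0,
    decay_power: float = 2.0,
):
    """Noise-free synthetic field: amplitude / r**p from an overhead source."""
    r = np.hypot(np.asarray(horizontal_m, float), source_height_m - np.asarray(height_m, float))
    return amplitude / r**decay_power


def synth_transect(
    ceiling_vpm: float = DEFAULT_CEILING_VPM,
    noise_sd_vpm: float = 10.0,
    seed: int | np.random.Generator | None = None,
    horizontal_m: np.ndarray = DEFAULT_HORIZONTAL_M,
    heights_m: np.ndarray = DEFAULT_HEIGHTS_M,
    source_height_m: float = 10.0,
    amplitude: float = 150_000.0,
    decay_power: float = 2.0,
) -> TransectGrid:
    """Synthetic transmission-line transect grid with an instrument ceiling.

    Field strength decays as ``amplitude / r**decay_power`` with r the
    distance to a line source ``source_height_m`` above the 0 m mark, plus
    additive Gaussian measurement noise (floored at 0). Values at or above
    the ceiling are stored at the ceiling and flagged overrange, emulating a
    saturating survey meter.
    """
    if ceiling_vpm <= 0:
        raise ValueError("ceiling must be positive")
    rng = np.random.default_rng(seed)
    hh, xx = np.meshgrid(np.asarray(heights_m, float), np.asarray(horizontal_m, float), indexing="ij")
    field = transect_field(xx, hh, source_height_m, amplitude, decay_power)
    if noise_sd_vpm > 0:
        field = np.maximum(field + rng.normal(0.0, noise_sd_vpm, field.shape), 0.0)
    over = field >= ceiling_vpm
    field = np.where(over, ceiling_vpm, field)
    return TransectGrid(np.asarray(horizontal_m, float), np.asarray(heights_m, float), field, over, ceiling_vpm)


# ---------------------------------------------------------------------------
# event-log I/O (shared CSV schema: trial_id,flower_role,time_min)


def events_to_frame(events: list[VisitEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_id": [e.trial_id for e in events],
            "flower_role": [e.flower_role for e in events],
            "time_min": [e.time_min for e in events],
        }
    )


def events_from_frame(frame: pd.DataFrame) -> list[VisitEvent]:
    required = {"trial_id", "flower_role", "time_min"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"event log is missing columns: {sorted(missing)}")
    bad = set(frame["flower_role"]) - {ROLE_TREATMENT, ROLE_CONTROL}
    if bad:
        raise ValueError(
            f"unknown flower_role values {sorted(bad)}; expected "
            f"{ROLE_TREATMENT!r} or {ROLE_CONTROL!r}"
        )
    return [
        VisitEvent(int(r.trial_id), str(r.flower_role), int(r.time_min))
        for r in frame.itertuples(index=False)
    ]


def write_events_csv(events: list[VisitEvent], path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events_csv(path) -> list[VisitEvent]:
    return events_from_frame(pd.read_csv(path))
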