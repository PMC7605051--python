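"""Generative observer models producing per-trial binary responses.

Two experiments are emulated:

* **baseline** — the observer judges a disparity-defined half cylinder as
  convex or concave; responses are Bernoulli draws from a logistic
  psychometric function with location ``theta`` (disparity of 50% "convex")
  and width ``omega`` (a large width means disparity barely influences the
  response, the operational signature of impaired stereovision).

* **coupling** — the observer reports the front-plane motion direction of an
  ambiguous full cylinder presented next to a +/-4.6 arcmin inducer; the
  response is a mixture of a motion-coupling pathway (probability ``m``:
  percept follows the inducer dots' direction), a depth-coupling pathway
  (probability ``g``, condition specific), and a fair coin.

Scoring of coupling follows the depth-appropriate convention: for a *near*
(convex) inducer a correct response moves **with** the inducer pattern, for a
*far* (concave) inducer a correct response moves **opposite** to it (the far
surface of the implied full cylinder is the inducer's own surface).  Under
pure motion coupling this yields 100% correct in the near condition and 0% in
the far condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimulus import TrialSpec, baseline_trial_schedule

__all__ = [
    "PF_SLOPE_CONSTANT",
    "ObserverParams",
    "CouplingObserverParams",
    "psychometric_prob",
    "simulate_baseline_subject",
    "simulate_coupling_subject",
    "simulate_cohort",
    "default_cohort",
    "RESPONSE_COLUMNS",
]

#: Slope constant of the psychometric function; 4.39 ~= 2*ln(9), so theta +/-
#: omega/2 maps to 10%/90% convex-report probability.
PF_SLOPE_CONSTANT = 4.39

RESPONSE_COLUMNS = [
    "subject_id",
    "experiment",
    "trial_index",
    "disparity_arcmin",
    "condition",
    "response",
    "coupled_correct",
]


@dataclass(frozen=True)
class ObserverParams:
    """Baseline psychometric observer: location theta, width omega (arcmin).

    ``lapse_rate`` mixes in stimulus-independent coin flips (default 0, i.e.
    the pure logistic model).
    """

    theta_arcmin: float = 0.0
    omega_arcmin: float = 10.0
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.omega_arcmin <= 0:
            raise ValueError("omega must be positive")
        if not 0.0 <= self.lapse_rate <= 0.5:
            raise ValueError("lapse rate must lie in [0, 0.5]")


@dataclass(frozen=True)
class CouplingObserverParams:
    """Coupling observer: motion-coupling probability m, depth-coupling g per condition."""

    g_near: float = 0.0
    g_far: float = 0.0
    m: float = 0.0

    def __post_init__(self) -> None:
        for name in ("g_near", "g_far", "m"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")


def psychometric_prob(params: ObserverParams, disparity_arcmin: float) -> float:
    """Probability of reporting "convex" at a signed disparity.

    lapse/2 + (1 - lapse) / (1 + exp(-(4.39/omega) * (disparity - theta))).
    """
    k = PF_SLOPE_CONSTANT / params.omega_arcmin
    z = k * (disparity_arcmin - params.theta_arcmin)
    # stable logistic
    core = 0.5 * (1.0 + math.tanh(z / 2.0))
    return params.lapse_rate / 2.0 + (1.0 - params.lapse_rate) * core


def simulate_baseline_subject(
    params: ObserverParams,
    schedule: list[TrialSpec],
    seed: int,
    subject_id: str = "S1",
) -> pd.DataFrame:
    """Bernoulli responses to a baseline schedule; deterministic given seed."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, trial in enumerate(schedule):
        if trial.experiment != "baseline":
            raise ValueError("baseline simulation requires baseline trials")
        p = psychometric_prob(params, trial.disparity_arcmin)
        response = "convex" if rng.random() < p else "concave"
        rows.append(
            (subject_id, "baseline", i, trial.disparity_arcmin,
             trial.inducer_shape, response, None)
        )
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def simulate_coupling_subject(
    params: CouplingObserverParams,
    condition: str,
    n_trials: int,
    seed: int,
    subject_id: str = "S1",
) -> pd.DataFrame:
    """Front-plane direction reports under a near or far inducer.

    Per trial: with probability m the percept follows the inducer pattern
    direction; otherwise with probability g (condition-matched) it couples
    depth-appropriately; otherwise a fair coin decides.
    """
    if condition not in ("near", "far"):
        raise ValueError("condition must be 'near' or 'far'")
    if n_trials < 0:
        raise ValueError("n_trials must be non-negative")
    rng = np.random.default_rng(seed)
    g = params.g_near if condition == "near" else params.g_far
    inducer_disp = 4.6 if condition == "near" else -4.6
    flip = {"up": "down", "down": "up"}
    rows = []
    for i in range(n_trials):
        inducer_dir = "up" if rng.random() < 0.5 else "down"
        if rng.random() < params.m:
            response = inducer_dir
        elif rng.random() < g:
            # depth-appropriate: near couples with the inducer dots,
            # far couples opposite
            response = inducer_dir if condition == "near" else flip[inducer_dir]
        else:
            response = "up" if rng.random() < 0.5 else "down"
        correct = (response == inducer_dir) if condition == "near" else (response != inducer_dir)
        rows.append(
            (subject_id, "coupling", i, inducer_disp, condition, response, bool(correct))
        )
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


@dataclass(frozen=True)
class SubjectSpec:
    """One synthetic subject: id plus baseline and coupling parameters."""

    subject_id: str
    baseline: ObserverParams
    coupling: CouplingObserverParams


def default_cohort() -> list[SubjectSpec]:
    """The packaged 18-subject cohort: 8 stereoscopic + 10 impaired archetypes.

    Stereoscopic archetypes have steep psychometric curves (omega 3-10 arcmin),
    small biases (theta within -2.4..4.4 arcmin) and mostly strong far depth
    coupling with chance-level near coupling; two members have weak far
    coupling, mirroring the spread seen in real stereoscopic groups.  Impaired
    archetypes have very flat curves (omega ~100-300 arcmin), biases spread
    over +/-40 arcmin and no coupling of either kind.
    """
    steep_omega = [3.0, 3.8, 4.6, 5.4, 6.4, 7.5, 8.7, 10.0]
    steep_theta = list(np.linspace(-2.4, 4.4, 8))
    steep_gfar = [0.95, 0.9, 0.95, 0.85, 0.9, 0.85, 0.4, 0.0]
    flat_omega = [105.0, 120.0, 135.0, 150.0, 165.0, 180.0, 200.0, 230.0, 260.0, 300.0]
    flat_theta = list(np.linspace(-40.0, 40.0, 10))
    cohort = []
    for i in range(8):
        cohort.append(
            SubjectSpec(
                subject_id=f"S{i + 1:02d}",
                baseline=ObserverParams(steep_theta[i], steep_omega[i]),
                coupling=CouplingObserverParams(g_near=0.0, g_far=steep_gfar[i], m=0.0),
            )
        )
    for i in range(10):
        cohort.append(
            SubjectSpec(
                subject_id=f"S{i + 9:02d}",
                baseline=ObserverParams(flat_theta[i], flat_omega[i]),
                coupling=CouplingObserverParams(g_near=0.0, g_far=0.0, m=0.0),
            )
        )
    return cohort


def simulate_cohort(
    cohort: list[SubjectSpec],
    seed: int,
    repeats: int = 20,
    disparity_levels_arcmin: list[float] | None = None,
    coupling_trials_per_condition: int = 20,
) -> tuple[pd.DataFrame, dict]:
    """Simulate baseline + coupling data for every subject.

    The global seed expands into independent per-subject, per-stage substreams
    so any subject can be regenerated in isolation.  Returns the concatenated
    response table and a truth dict of generating parameters.
    """
    levels = [0.0, 2.3, 4.6] if disparity_levels_arcmin is None else disparity_levels_arcmin
    root = np.random.SeedSequence(seed)
    frames = []
    truth = {}
    for subj_seq in zip(cohort, root.spawn(len(cohort))):
        spec, seq = subj_seq
        s_sched, s_base, s_near, s_far = (
            int(s.generate_state(1)[0]) & 0x7FFFFFFF for s in seq.spawn(4)
        )
        schedule = baseline_trial_schedule(repeats, levels, s_sched)
        frames.append(
            simulate_baseline_subject(spec.baseline, schedule, s_base, spec.subject_id)
        )
        frames.append(
            simulate_coupling_subject(
                spec.coupling, "near", coupling_trials_per_condition, s_near, spec.subject_id
            )
        )
        frames.append(
            simulate_coupling_subject(
                spec.coupling, "far", coupling_trials_per_condition, s_far, spec.subject_id
            )
        )
        truth[spec.subject_id] = {
            "theta_arcmin": spec.baseline.theta_arcmin,
            "omega_arcmin": spec.baseline.omega_arcmin,
            "lapse_rate": spec.baseline.lapse_rate,
            "g_near": spec.coupling.g_near,
            "g_far": spec.coupling.g_far,
            "m": spec.coupling.m,
        }
    if not frames:
        return pd.DataFrame(columns=RESPONSE_COLUMNS), {}
    return pd.concat(frames, ignore_index=True), truth
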