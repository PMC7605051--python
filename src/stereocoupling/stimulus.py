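"""Geometry and scheduling of the rotating structure-from-motion cylinder stimulus.

The stimulus is a random-dot cylinder rotating about a horizontal axis: two
transparent dot layers (front/back) move vertically in opposite directions,
evoking a bistable rotating-cylinder percept.  Stereoscopic depth is added as a
horizontal-disparity gradient whose cross-section is circular, so the maximum
disparity corresponds to a perfectly round cylinder.

All public angles are in visual degrees (disparities in arcmin); internal
trigonometry is in radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ViewingGeometry",
    "CylinderSpec",
    "Dot",
    "TrialSpec",
    "angular_velocity",
    "sample_dot_field",
    "projected_speed",
    "mean_abs_speed",
    "max_disparity_arcmin",
    "disparity_profile",
    "baseline_trial_schedule",
    "session_duration_s",
    "dot_trajectory",
]

ARCMIN_PER_RAD = 60.0 * 180.0 / math.pi


@dataclass(frozen=True)
class ViewingGeometry:
    """Observer geometry: screen distance and interocular separation, in cm."""

    viewing_distance_cm: float = 100.0
    interocular_distance_cm: float = 6.3

    def __post_init__(self) -> None:
        if self.viewing_distance_cm <= 0 or self.interocular_distance_cm <= 0:
            raise ValueError("viewing and interocular distances must be positive")
        if self.interocular_distance_cm >= self.viewing_distance_cm:
            raise ValueError("interocular distance must be smaller than viewing distance")


@dataclass(frozen=True)
class CylinderSpec:
    """Physical parameters of one cylinder stimulus.

    ``n_layers`` is 2 for the full (bistable) cylinder and 1 for the half
    cylinder used as the disparity-defined inducer.  ``dot_density_per_deg2``
    is the aggregate density over both layers of a full cylinder.
    """

    width_deg: float = 3.0
    height_deg: float = 3.0
    rotation_period_s: float = 3.0
    dot_density_per_deg2: float = 12.0
    dot_diameter_deg: float = 0.11
    n_layers: int = 2
    stimulus_separation_deg: float = 0.5
    radius_deg: float = field(init=False)

    def __post_init__(self) -> None:
        if self.rotation_period_s <= 0:
            raise ValueError("rotation period must be positive")
        if self.dot_density_per_deg2 < 0:
            raise ValueError("dot density must be non-negative")
        if self.n_layers not in (1, 2):
            raise ValueError("n_layers must be 1 (half cylinder) or 2 (full cylinder)")
        object.__setattr__(self, "radius_deg", self.width_deg / 2.0)


@dataclass(frozen=True)
class Dot:
    """One dot on the cylinder surface.

    ``phase_rad`` is the rotation angle on the circumference (0 projects onto
    the cylinder axis, where projected speed is maximal); ``axial_pos_deg`` is
    the position along the rotation axis.
    """

    phase_rad: float
    axial_pos_deg: float
    layer: str  # "front" | "back"
    polarity: str  # "black" | "white"

    def __post_init__(self) -> None:
        if not 0.0 <= self.phase_rad < 2.0 * math.pi:
            raise ValueError("phase must lie in [0, 2*pi)")


@dataclass(frozen=True)
class TrialSpec:
    """One trial's condition.

    ``disparity_arcmin`` is signed: positive = convex (near), negative =
    concave (far).  Baseline trials probe the half cylinder's shape; coupling
    trials pair a +/-4.6 arcmin inducer with an ambiguous (0 arcmin) test
    cylinder.
    """

    experiment: str  # "baseline" | "coupling"
    disparity_arcmin: float
    inducer_shape: str  # "convex" | "concave" | "none"
    pattern_direction: str  # "up" | "down"
    stim_duration_s: float = 1.0
    isi_s: float = 1.5


def angular_velocity(spec: CylinderSpec) -> float:
    """Rotation speed in deg/s (360 degrees per period)."""
    return 360.0 / spec.rotation_period_s


def _n_dots(spec: CylinderSpec) -> int:
    # density is the two-layer aggregate: a full 3x3 deg cylinder at
    # 12 dots/deg^2 carries 108 dots (54 per layer).
    per_layer = spec.dot_density_per_deg2 * spec.width_deg * spec.height_deg / 2.0
    return int(round(per_layer * spec.n_layers))


def sample_dot_field(spec: CylinderSpec, seed: int) -> list[Dot]:
    """Sample a random dot field for one stimulus presentation.

    Dots are uniform in the projected aperture (axial position x vertical
    position), then assigned the circumference phase consistent with their
    projected vertical position; layers alternate so both are equally
    populated.  Dots may overlap.
    """
    rng = np.random.default_rng(seed)
    n = _n_dots(spec)
    axial = rng.uniform(-spec.width_deg / 2.0, spec.width_deg / 2.0, size=n)
    y = rng.uniform(-spec.radius_deg, spec.radius_deg, size=n) if spec.radius_deg > 0 else np.zeros(n)
    polarity = rng.choice(["black", "white"], size=n)
    dots = []
    for i in range(n):
        front = (i % 2 == 0) or spec.n_layers == 1
        base = math.asin(y[i] / spec.radius_deg) if spec.radius_deg > 0 else 0.0
        phase = base if front else math.pi - base
        dots.append(
            Dot(
                phase_rad=phase % (2.0 * math.pi),
                axial_pos_deg=float(axial[i]),
                layer="front" if front else "back",
                polarity=str(polarity[i]),
            )
        )
    return dots


def projected_speed(dot: Dot, spec: CylinderSpec) -> float:
    """Instantaneous projected (vertical) dot speed in deg/s.

    The projection of uniform rotation is sinusoidal: |omega * r * cos(phase)|.
    """
    omega = 2.0 * math.pi / spec.rotation_period_s
    return abs(omega * spec.radius_deg * math.cos(dot.phase_rad))


def mean_abs_speed(spec: CylinderSpec) -> float:
    """Time-averaged |projected speed| of a dot over one rotation: 4r/T.

    The mean of |cos| over a cycle is 2/pi, so the average is
    (2/pi) * (2*pi/T) * r = 4r/T; for the 3-deg cylinder turning in 3 s this
    is the "about 2 deg/s" figure.
    """
    return 4.0 * spec.radius_deg / spec.rotation_period_s


def max_disparity_arcmin(view: ViewingGeometry, radius_deg: float) -> float:
    """Peak horizontal disparity (arcmin) of a round cylinder of given radius.

    Depth of the cylinder apex is d = D * tan(radius); under the small-angle
    convention the disparity is IOD * d / D^2 radians.
    """
    if radius_deg >= 90.0:
        raise ValueError("radius must be below 90 visual degrees")
    depth_cm = view.viewing_distance_cm * math.tan(math.radians(radius_deg))
    disparity_rad = view.interocular_distance_cm * depth_cm / view.viewing_distance_cm**2
    return disparity_rad * ARCMIN_PER_RAD


def disparity_profile(
    offset_deg: float, radius_deg: float, delta_max_arcmin: float, shape: str
) -> float:
    """Disparity (arcmin) at a given offset from the cylinder axis.

    The cross-section is circular, so the magnitude follows
    delta_max * sqrt(1 - (offset/radius)^2); convex stimuli are positive
    (near), concave negative (far).
    """
    if abs(offset_deg) > radius_deg:
        raise ValueError("offset lies outside the stimulus aperture")
    if shape not in ("convex", "concave"):
        raise ValueError(f"unknown shape {shape!r}")
    magnitude = delta_max_arcmin * math.sqrt(1.0 - (offset_deg / radius_deg) ** 2)
    return magnitude if shape == "convex" else -magnitude


def baseline_trial_schedule(
    repeats: int, disparity_levels_arcmin: list[float], seed: int
) -> list[TrialSpec]:
    """Build the baseline block: repeats x levels x {convex, concave}.

    Each unsigned level appears in both convex (+) and concave (-) fashion, so
    0 arcmin occurs twice per repeat (a flat stimulus labelled either way).
    Pattern direction is drawn per trial and the order is shuffled, both from
    the seed.
    """
    if repeats < 0:
        raise ValueError("repeats must be non-negative")
    if any(lv < 0 for lv in disparity_levels_arcmin):
        raise ValueError("disparity levels are unsigned magnitudes")
    rng = np.random.default_rng(seed)
    trials = []
    for _ in range(repeats):
        for level in disparity_levels_arcmin:
            for shape, sign in (("convex", 1.0), ("concave", -1.0)):
                trials.append(
                    TrialSpec(
                        experiment="baseline",
                        disparity_arcmin=sign * level,
                        inducer_shape=shape,
                        pattern_direction="up",  # placeholder, randomized below
                    )
                )
    order = rng.permutation(len(trials))
    directions = rng.choice(["up", "down"], size=len(trials))
    return [
        TrialSpec(
            experiment=t.experiment,
            disparity_arcmin=t.disparity_arcmin,
            inducer_shape=t.inducer_shape,
            pattern_direction=str(directions[i]),
            stim_duration_s=t.stim_duration_s,
            isi_s=t.isi_s,
        )
        for i, t in enumerate(np.array(trials, dtype=object)[order])
    ]


def session_duration_s(n_trials: int, stim_s: float = 1.0, isi_s: float = 1.5) -> float:
    """Total block duration: each trial is stimulus plus inter-stimulus interval."""
    if n_trials < 0 or stim_s < 0 or isi_s < 0:
        raise ValueError("trial count and durations must be non-negative")
    return n_trials * (stim_s + isi_s)


def dot_trajectory(
    spec: CylinderSpec,
    view: ViewingGeometry,
    times_s: np.ndarray,
    seed: int,
    direction: str = "up",
    shape: str = "convex",
):
    """Per-frame projected dot positions and disparities for a preview export.

    Returns a list of rows (frame, t_s, dot_id, x_deg, y_deg, layer,
    disparity_arcmin).  The front layer moves in ``direction``; disparity
    follows the circular profile with the sign of ``shape`` for the front
    layer and the opposite sign for the back layer.
    """
    dots = sample_dot_field(spec, seed)
    omega = 2.0 * math.pi / spec.rotation_period_s
    if direction == "down":
        omega = -omega
    delta_max = max_disparity_arcmin(view, spec.radius_deg)
    other = {"convex": "concave", "concave": "convex"}
    rows = []
    for frame, t in enumerate(np.asarray(times_s, dtype=float)):
        for dot_id, dot in enumerate(dots):
            phase = dot.phase_rad + omega * t
            y = spec.radius_deg * math.sin(phase)
            front = math.cos(phase) >= 0
            disparity = disparity_profile(
                y, spec.radius_deg, delta_max, shape if front else other[shape]
            )
            rows.append(
                (frame, float(t), dot_id, dot.axial_pos_deg, y,
                 "front" if front else "back", disparity)
            )
    return rows
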