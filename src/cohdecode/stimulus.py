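"""Gabor-path stimulus geometry and block schedules.

Six drifting Gabor elements: five on a circular arc (a "curved imaginary
path") plus one distractor diagonally opposite the middle (curve) element.
In the *coherent* context each Gabor's carrier orientation is orthogonal to
the path, so its drift is tangential to it; the *incoherent* context swaps
the orientations of the elements flanking the curve element (outer with
outer, inner with inner), destroying global coherence while leaving the
curve element — and the pairwise orientation differences between
neighbours — unchanged.

Angles are in degrees. Polar angle 0° is the right horizontal meridian,
counter-clockwise positive. Orientations live in [0, 180), drift
directions in [0, 360), with drift always perpendicular to orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

CONDITION_LABELS = ("coh_acw", "coh_cw", "incoh_acw", "incoh_cw")

# printed stimulus parameters
SPATIAL_FREQUENCY = 2.7   # cycles/degree
ENVELOPE_SD = 0.55        # degrees
PATH_SECTOR = 160.0       # degrees of arc spanned by the five path elements
PATH_SEPARATION = 5.5     # degrees of visual angle between neighbours
ECC_MIN = 4.1             # degrees; also the distractor eccentricity
ECC_MAX = 8.4             # degrees

_ANGLE_TOL = 1e-9


def _norm180(a: float) -> float:
    return a % 180.0


def _norm360(a: float) -> float:
    return a % 360.0


@dataclass(frozen=True)
class GaborElement:
    """One drifting Gabor patch, located in polar visual-field coordinates."""

    eccentricity: float
    polar_angle: float
    orientation: float
    drift_direction: float
    spatial_frequency: float = SPATIAL_FREQUENCY
    envelope_sd: float = ENVELOPE_SD
    role: str = "inducer"

    def __post_init__(self):
        if self.envelope_sd <= 0 or self.spatial_frequency <= 0:
            raise ValueError("envelope_sd and spatial_frequency must be positive")
        if self.role not in ("inducer", "curve", "distractor"):
            raise ValueError(f"unknown role {self.role!r}")
        if not (0 <= self.orientation < 180):
            raise ValueError("orientation must lie in [0, 180)")
        if not (0 <= self.drift_direction < 360):
            raise ValueError("drift_direction must lie in [0, 360)")
        # drift is the carrier's motion, perpendicular to its orientation
        mism = (_norm180(self.drift_direction) - _norm180(self.orientation + 90.0)) % 180.0
        if min(mism, 180.0 - mism) > 1e-6:
            raise ValueError("drift_direction must be perpendicular to orientation")

    @property
    def position(self) -> tuple[float, float]:
        """Cartesian position (degrees), fixation at the origin."""
        th = math.radians(self.polar_angle)
        return (self.eccentricity * math.cos(th), self.eccentricity * math.sin(th))


@dataclass(frozen=True)
class StimulusConfiguration:
    """Six elements: five on the path (curve element in the middle) + distractor.

    ``elements`` keeps path order (outer, inner, curve, inner, outer) with
    the distractor last once added.
    """

    elements: tuple[GaborElement, ...]
    context: str
    curve_quadrant: str
    rotation: str
    path_radius: float
    path_center: tuple[float, float]
    realised_eccentricity_range: tuple[float, float] = (float("nan"), float("nan"))

    def __post_init__(self):
        if self.context not in ("coherent", "incoherent"):
            raise ValueError(f"unknown context {self.context!r}")
        roles = [e.role for e in self.elements]
        if roles.count("curve") != 1:
            raise ValueError("exactly one curve element required")
        if roles.count("distractor") > 1:
            raise ValueError("at most one distractor")

    @property
    def path_elements(self) -> tuple[GaborElement, ...]:
        return tuple(e for e in self.elements if e.role != "distractor")

    @property
    def curve_element(self) -> GaborElement:
        return next(e for e in self.elements if e.role == "curve")

    @property
    def distractor(self) -> GaborElement | None:
        return next((e for e in self.elements if e.role == "distractor"), None)

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "role": e.role,
                "eccentricity": e.eccentricity,
                "polar_angle": e.polar_angle,
                "orientation": e.orientation,
                "drift_direction": e.drift_direction,
            }
            for e in self.elements
        ]
        return pd.DataFrame(rows)


_QUADRANT_AXIS = {"lower_right": -45.0, "upper_left": 135.0}


def _solve_center_distance(radius: float, half_sector: float,
                           ecc_min: float = ECC_MIN, ecc_max: float = ECC_MAX) -> float:
    """Distance fixation→path-circle centre, fixation inside the circle.

    The curve element sits at the point of the circle nearest fixation
    (eccentricity R − D); the outermost elements sit half a sector away
    (eccentricity sqrt(D² + R² − 2DR cos half_sector)). The printed range
    over-determines D, so D is the least-squares compromise and the
    realised range is reported on the configuration.
    """
    c = math.cos(math.radians(half_sector))

    def loss(d):
        outer = math.sqrt(d * d + radius * radius - 2 * d * radius * c)
        return (radius - d - ecc_min) ** 2 + (outer - ecc_max) ** 2

    res = optimize.minimize_scalar(loss, bounds=(1e-6, radius - 1e-6), method="bounded")
    return float(res.x)


def build_coherent_path(curve_quadrant: str, n_elements: int = 5,
                        sector: float = PATH_SECTOR, separation: float = PATH_SEPARATION,
                        rotation: str = "acw", with_distractor: bool = True,
                        ecc_min: float = ECC_MIN, ecc_max: float = ECC_MAX,
                        center_distance: float | None = None) -> StimulusConfiguration:
    """Place ``n_elements`` Gabors on a circular arc, coherent context.

    Neighbouring elements are separated by ``separation`` degrees of visual
    angle along chords of a circle whose radius follows from
    chord = 2 R sin(step/2) with step = sector/(n_elements − 1). Each
    element's orientation is orthogonal to the local tangent, so its drift
    (sign set by ``rotation``: anticlockwise ``acw`` or clockwise ``cw``)
    is tangential to the path. The middle element is the curve element,
    placed in ``curve_quadrant``.
    """
    if sector <= 0 or separation <= 0:
        raise ValueError("sector and separation must be positive")
    if n_elements < 3 or n_elements % 2 == 0:
        raise ValueError("n_elements must be odd and >= 3")
    if rotation not in ("acw", "cw"):
        raise ValueError(f"unknown rotation {rotation!r}")
    if curve_quadrant not in _QUADRANT_AXIS:
        raise ValueError(f"unknown curve_quadrant {curve_quadrant!r}")

    step = sector / (n_elements - 1)
    radius = separation / (2.0 * math.sin(math.radians(step / 2.0)))
    if center_distance is None:
        center_distance = _solve_center_distance(radius, sector / 2.0, ecc_min, ecc_max)
    if not (0 < center_distance < radius):
        raise ValueError("fixation must lie strictly inside the path circle")

    psi = _QUADRANT_AXIS[curve_quadrant]  # polar angle of the curve element
    cx = -center_distance * math.cos(math.radians(psi))
    cy = -center_distance * math.sin(math.radians(psi))

    mid = (n_elements - 1) // 2
    drift_off = 90.0 if rotation == "acw" else -90.0
    elements = []
    for k in range(n_elements):
        gamma = psi + (k - mid) * step  # angle on the path circle, at its centre
        gr = math.radians(gamma)
        x = cx + radius * math.cos(gr)
        y = cy + radius * math.sin(gr)
        ecc = math.hypot(x, y)
        pol = _norm360(math.degrees(math.atan2(y, x)))
        role = "curve" if k == mid else "inducer"
        elements.append(GaborElement(
            eccentricity=ecc, polar_angle=pol,
            orientation=_norm180(gamma), drift_direction=_norm360(gamma + drift_off),
            role=role))

    eccs = [e.eccentricity for e in elements]
    config = StimulusConfiguration(
        elements=tuple(elements), context="coherent", curve_quadrant=curve_quadrant,
        rotation=rotation, path_radius=radius, path_center=(cx, cy),
        realised_eccentricity_range=(min(eccs), max(eccs)))
    if with_distractor:
        config = add_distractor(config)
    return config


def add_distractor(config: StimulusConfiguration,
                   eccentricity: float = ECC_MIN) -> StimulusConfiguration:
    """Append the distractor: diagonally opposite the curve element, same
    orientation, opposite drift direction."""
    curve = config.curve_element
    distractor = GaborElement(
        eccentricity=eccentricity,
        polar_angle=_norm360(curve.polar_angle + 180.0),
        orientation=curve.orientation,
        drift_direction=_norm360(curve.drift_direction + 180.0),
        role="distractor")
    path = tuple(e for e in config.elements if e.role != "distractor")
    return replace(config, elements=path + (distractor,))


def make_incoherent(config: StimulusConfiguration) -> StimulusConfiguration:
    """Swap flanker orientations to break global coherence.

    Outer inducers exchange orientation and drift direction with each
    other, as do the inner inducers; positions, the curve element and the
    distractor are untouched. Precondition: a coherent 5-element path.
    """
    if config.context != "coherent":
        raise ValueError("make_incoherent requires a coherent configuration")
    path = list(config.path_elements)
    if len(path) != 5:
        raise ValueError("incoherent swap is defined for 5-element paths")

    def swapped(a: GaborElement, b: GaborElement) -> GaborElement:
        return replace(a, orientation=b.orientation, drift_direction=b.drift_direction)

    new_path = [
        swapped(path[0], path[4]),
        swapped(path[1], path[3]),
        path[2],
        swapped(path[3], path[1]),
        swapped(path[4], path[0]),
    ]
    tail = tuple(e for e in config.elements if e.role == "distractor")
    return replace(config, elements=tuple(new_path) + tail, context="incoherent")


def carrier_drift_speed(phase_step: float, frame_rate: float = 60.0) -> float:
    """Carrier drift in cycles/s from the per-frame phase advance (degrees)."""
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    return phase_step / 360.0 * frame_rate


@dataclass(frozen=True)
class RunDesign:
    """One scanner run: ordered (condition, onset, duration) blocks.

    Onsets are in seconds relative to the first retained (post-dummy)
    volume; the ``n_dummy_volumes`` discarded volumes precede them.
    """

    blocks: tuple[tuple[str, float, float], ...]
    tr: float
    n_dummy_volumes: int
    n_volumes: int
    seed: int | None = None

    def __post_init__(self):
        onsets = [b[1] for b in self.blocks]
        if any(o2 <= o1 for o1, o2 in zip(onsets, onsets[1:])):
            raise ValueError("block onsets must be strictly increasing")
        for (_, o1, d1), (_, o2, _) in zip(self.blocks, self.blocks[1:]):
            if o1 + d1 > o2 + 1e-9:
                raise ValueError("blocks overlap")
        for lab, _, dur in self.blocks:
            if abs(dur / self.tr - round(dur / self.tr)) > 1e-9:
                raise ValueError(f"duration of block {lab!r} is not a multiple of tr")
        stim = self.stimulus_blocks
        for (a, *_), (b, *_) in zip(stim, stim[1:]):
            if a == b:
                raise ValueError("same condition in two consecutive stimulus blocks")

    @property
    def stimulus_blocks(self) -> tuple[tuple[str, float, float], ...]:
        return tuple(b for b in self.blocks if b[0] != "blank")

    @property
    def n_retained_volumes(self) -> int:
        return self.n_volumes - self.n_dummy_volumes

    def to_events_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"onset": o, "duration": d, "trial_type": c} for c, o, d in self.blocks])


def _constrained_order(labels: Sequence[str], reps: int, rng: np.random.Generator,
                       max_tries: int = 100_000) -> list[str]:
    """Uniform draw over orderings with no immediate repeat (rejection sampling)."""
    pool = list(labels) * reps
    for _ in range(max_tries):
        order = [pool[i] for i in rng.permutation(len(pool))]
        if all(a != b for a, b in zip(order, order[1:])):
            return order
    raise ValueError("could not satisfy the no-immediate-repeat constraint")


def generate_run_schedule(n_conditions: int = 4, reps: int = 2,
                          block_dur: float = 19.2, blank_dur: float = 19.2,
                          tr: float = 3.2, n_dummy: int = 6, rng_seed: int = 0,
                          condition_labels: Sequence[str] | None = None) -> RunDesign:
    """Pseudo-randomised block schedule: leading blank, then (stimulus,
    blank) pairs, no condition twice in a row.

    Default parameters give the main experiment's run: 8 stimulus blocks of
    19.2 s interleaved with 19.2 s blanks at TR 3.2 s, 108 volumes
    including 6 dummies.
    """
    for name, dur in (("block_dur", block_dur), ("blank_dur", blank_dur)):
        if abs(dur / tr - round(dur / tr)) > 1e-9:
            raise ValueError(f"{name} must be an integer multiple of tr")
    if condition_labels is None:
        if n_conditions > len(CONDITION_LABELS):
            raise ValueError("supply condition_labels for n_conditions > 4")
        condition_labels = CONDITION_LABELS[:n_conditions]
    if len(condition_labels) != n_conditions:
        raise ValueError("condition_labels length must equal n_conditions")
    if n_conditions == 1 and reps > 1:
        raise ValueError("no-repeat constraint infeasible: 1 condition, >1 rep")

    rng = np.random.default_rng(rng_seed)
    order = _constrained_order(condition_labels, reps, rng)

    # track time as an integer volume count to avoid float accumulation
    n_block = int(round(block_dur / tr))
    n_blank = int(round(blank_dur / tr))
    blocks: list[tuple[str, float, float]] = []
    v = 0
    blocks.append(("blank", v * tr, blank_dur))
    v += n_blank
    for cond in order:
        blocks.append((cond, v * tr, block_dur))
        v += n_block
        blocks.append(("blank", v * tr, blank_dur))
        v += n_blank
    n_volumes = n_dummy + v
    return RunDesign(blocks=tuple(blocks), tr=tr, n_dummy_volumes=n_dummy,
                     n_volumes=n_volumes, seed=rng_seed)


def element_localiser_schedule(rng_seed: int = 0) -> RunDesign:
    """Element-localiser run: 8 blocks of 25.6 s (checkerboards alternating
    between the distractor and curve positions) with 9.6 s fixation
    periods; 97 volumes including dummies."""
    return generate_run_schedule(
        n_conditions=2, reps=4, block_dur=25.6, blank_dur=9.6, tr=3.2,
        n_dummy=6, rng_seed=rng_seed,
        condition_labels=("element_curve_pos", "element_distractor_pos"))


def parse_condition(label: str) -> tuple[str, int]:
    """Split a condition label into (context, direction sign).

    Sign is +1 for anticlockwise, −1 for clockwise drift around the path.
    """
    context = {"coh": "coherent", "incoh": "incoherent"}.get(label.split("_")[0])
    sign = {"acw": 1, "cw": -1}.get(label.split("_")[-1])
    if context is None or sign is None:
        raise ValueError(f"unknown condition label {label!r}")
    return context, sign
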