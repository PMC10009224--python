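"""Dose accumulation to circulating blood elements over beams and fractions.

Each treatment fraction delivers the per-fraction organ dose (the composite
plan DVH with its dose axis divided by the number of fractions) at a uniform
rate during beam-on windows; the fine time structure of delivery is not
modelled beyond the beam-on time (default 60 s per beam).  While an element
sits in a dose-source organ during beam-on it accrues a voxel dose drawn from
that organ's per-fraction differential DVH, weighted by the fraction of total
beam-on time the visit covers.  One voxel dose is drawn per organ visit, so
blood moving through a heterogeneous dose field samples the field anew on
each pass; elements in the remainder pool accrue nothing.

The full course sums independent per-fraction evaluations with blood paths
and voxel draws resampled each fraction, sub-seeded deterministically from
the course seed, so the 30-fraction distribution is genuinely narrower than a
single fraction scaled up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circulation import BloodPathSet, CompartmentModel, simulate_paths
from .dvh_io import OrganDVH, to_differential

__all__ = [
    "BeamSchedule",
    "CoursePlan",
    "BloodDoseDistribution",
    "fraction_dose",
    "accumulate_course",
]


@dataclass(frozen=True)
class BeamSchedule:
    """Beam delivery timing for one fraction: beams back-to-back."""

    n_beams: int = 2
    beam_on_s: float = 60.0
    inter_beam_gap_s: float = 0.0

    def __post_init__(self):
        if self.n_beams < 1 or self.beam_on_s <= 0 or self.inter_beam_gap_s < 0:
            raise ValueError("need n_beams >= 1, beam_on_s > 0, gap >= 0")

    @property
    def total_beam_on_s(self) -> float:
        return self.n_beams * self.beam_on_s

    @property
    def fraction_duration_s(self) -> float:
        return self.n_beams * self.beam_on_s + (self.n_beams - 1) * self.inter_beam_gap_s

    def beam_on_overlap(self, t_entry: np.ndarray, t_exit: np.ndarray) -> np.ndarray:
        """Seconds of [t_entry, t_exit) overlapping any beam-on window."""
        out = np.zeros_like(np.asarray(t_entry, dtype=float))
        period = self.beam_on_s + self.inter_beam_gap_s
        for k in range(self.n_beams):
            lo, hi = k * period, k * period + self.beam_on_s
            out += np.clip(np.minimum(t_exit, hi) - np.maximum(t_entry, lo), 0.0, None)
        return out


@dataclass(frozen=True)
class CoursePlan:
    """Fractionation of the composite plan."""

    n_fractions: int = 30

    def __post_init__(self):
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")

    def per_fraction_dvh(self, dvh: OrganDVH) -> OrganDVH:
        """Differential per-fraction DVH: dose axis scaled by 1/n_fractions."""
        diff = dvh if dvh.representation == "differential" else to_differential(dvh)
        return OrganDVH(
            diff.organ,
            diff.dose_grid / self.n_fractions,
            diff.volume,
            "differential",
        )


@dataclass
class BloodDoseDistribution:
    """Accumulated dose per blood element after all fractions."""

    doses: np.ndarray  # GyE, length n_elements
    element_volume_ml: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        if self.doses.ndim != 1 or self.doses.size == 0:
            raise ValueError("doses must be a non-empty 1-d array")
        if np.any(self.doses < 0):
            raise ValueError("element doses must be non-negative")

    @property
    def n_elements(self) -> int:
        return self.doses.size


def fraction_dose(
    paths: BloodPathSet,
    organ_dvhs: dict,
    schedule: BeamSchedule,
    course: CoursePlan,
    seed,
) -> np.ndarray:
    """Per-element dose (GyE) accrued during one fraction.

    ``organ_dvhs`` maps dose-source organ names to composite-plan DVHs
    (cumulative or differential); the per-fraction dose axis is derived via
    ``course``.  One voxel-dose draw per visit; accrual is
    ``voxel_dose * beam_on_overlap(visit) / total_beam_on``.
    """
    if paths.duration_s + 1e-9 < schedule.fraction_duration_s:
        raise ValueError("paths do not cover the fraction's beam schedule")
    rng = np.random.default_rng(seed)
    dose = np.zeros(paths.n_elements)
    total_on = schedule.total_beam_on_s
    for ci, comp in enumerate(paths.compartments):
        organ = paths.dose_sources.get(comp)
        if organ is None:
            continue
        if organ not in organ_dvhs:
            raise KeyError(
                f"compartment {comp!r} sources dose from organ {organ!r} "
                "but no DVH was supplied"
            )
        frac_dvh = course.per_fraction_dvh(organ_dvhs[organ])
        sel = paths.comp == ci
        overlap = schedule.beam_on_overlap(paths.t_entry[sel], paths.t_exit[sel])
        p = frac_dvh.volume / frac_dvh.volume.sum()
        draws = frac_dvh.dose_grid[rng.choice(len(p), size=sel.sum(), p=p)]
        np.add.at(dose, paths.elem[sel], draws * overlap / total_on)
    return dose


def _fraction_seeds(seed, k: int):
    """Splitting rule: fraction k uses SeedSequence(entropy, spawn_key=(k,)).

    ``seed`` may be an int or a SeedSequence (reduced to its entropy state).
    """
    if isinstance(seed, np.random.SeedSequence):
        seed = int(seed.generate_state(1, np.uint32)[0])
    ss = np.random.SeedSequence(seed, spawn_key=(k,))
    return ss.spawn(2)


def accumulate_course(
    model: CompartmentModel,
    organ_dvhs: dict,
    schedule: BeamSchedule,
    course: CoursePlan,
    seed,
    n_elements: int | None = None,
    metadata: dict | None = None,
) -> BloodDoseDistribution:
    """Sum independent per-fraction doses into the course distribution.

    Fraction ``k`` draws its paths and voxel doses from two RNG streams
    spawned from ``SeedSequence(seed, spawn_key=(k,))``, so the course is
    reproducible and fractions are mutually independent.
    """
    n = model.n_elements if n_elements is None else int(n_elements)
    total = np.zeros(n)
    for k in range(course.n_fractions):
        path_seed, draw_seed = _fraction_seeds(seed, k)
        paths = simulate_paths(model, schedule.fraction_duration_s, path_seed, n)
        total += fraction_dose(paths, organ_dvhs, schedule, course, draw_seed)
    meta = {"seed": seed, "n_fractions": course.n_fractions, "n_beams": schedule.n_beams}
    meta.update(metadata or {})
    return BloodDoseDistribution(
        doses=total, element_volume_ml=model.element_volume_ml, metadata=meta
    )
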