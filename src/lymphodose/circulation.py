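"""Compartmental blood-circulation model and blood-element path sampling.

Circulating blood is discretised into equal-volume elements (default
5.3 L / 0.053 mL = 100,000 elements) that cycle through a closed chain of
compartments.  The default topology is heart -> lungs -> remainder -> heart,
with blood-volume fractions taken from ICRP Publication 89 reference-adult
values; only the heart and lungs act as dose sources, so finer systemic
anatomy would be unidentifiable and the remainder pool exists purely to keep
transit timing right.

The mean transit time through compartment ``c`` is
``fraction_c * total_blood_volume / cardiac_output``; sojourn times are drawn
either exponentially with that mean (memoryless renewal cycle, the default)
or as the fixed mean (sensitivity option).  Elements start in the stationary
distribution with a residual-life draw so that even short beam-on windows see
unbiased occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Compartment",
    "CompartmentModel",
    "BloodPathSet",
    "build_default_model",
    "simulate_paths",
    "occupancy_in_window",
    "occupancy_fractions",
]

DEFAULT_COMPARTMENTS = [
    # (name, blood volume fraction, dose source organ)
    ("heart", 0.090, "heart"),
    ("lungs", 0.105, "lungs"),
    ("remainder", 0.805, None),
]
DEFAULT_CARDIAC_OUTPUT_L_MIN = 6.5
DEFAULT_TOTAL_BLOOD_VOLUME_L = 5.3
DEFAULT_ELEMENT_VOLUME_ML = 0.053


@dataclass(frozen=True)
class Compartment:
    name: str
    fraction: float
    dose_source: str | None = None


@dataclass(frozen=True)
class CompartmentModel:
    """Closed single-cycle circulation topology with volume bookkeeping."""

    compartments: tuple
    topology: dict  # name -> successor name, a single closed cycle
    cardiac_output_l_min: float = DEFAULT_CARDIAC_OUTPUT_L_MIN
    total_blood_volume_l: float = DEFAULT_TOTAL_BLOOD_VOLUME_L
    element_volume_ml: float = DEFAULT_ELEMENT_VOLUME_ML
    transit_law: str = "exponential"

    def __post_init__(self):
        object.__setattr__(self, "compartments", tuple(self.compartments))
        fr = sum(c.fraction for c in self.compartments)
        if abs(fr - 1.0) > 1e-9:
            raise ValueError(f"blood volume fractions sum to {fr!r}, expected 1")
        if self.cardiac_output_l_min <= 0 or self.total_blood_volume_l <= 0:
            raise ValueError("cardiac output and blood volume must be positive")
        n = self.total_blood_volume_l * 1000.0 / self.element_volume_ml
        if abs(n - round(n)) > 1e-6 or round(n) < 1:
            raise ValueError(
                f"total volume / element volume = {n} must be a positive integer"
            )
        names = [c.name for c in self.compartments]
        if set(self.topology) != set(names) or set(self.topology.values()) != set(names):
            raise ValueError("topology must be a permutation over all compartments")
        # single closed cycle covering every compartment
        seen, cur = [], names[0]
        for _ in names:
            seen.append(cur)
            cur = self.topology[cur]
        if cur != names[0] or len(set(seen)) != len(names):
            raise ValueError("topology must form a single closed cycle")
        if self.transit_law not in ("exponential", "fixed"):
            raise ValueError(f"unknown transit law {self.transit_law!r}")

    @property
    def n_elements(self) -> int:
        return int(round(self.total_blood_volume_l * 1000.0 / self.element_volume_ml))

    @property
    def names(self) -> list:
        return [c.name for c in self.compartments]

    @property
    def fractions(self) -> np.ndarray:
        return np.array([c.fraction for c in self.compartments])

    def mean_transit_s(self, name: str) -> float:
        """Mean sojourn time in seconds: fraction * V / cardiac output."""
        frac = {c.name: c.fraction for c in self.compartments}[name]
        return frac * self.total_blood_volume_l / self.cardiac_output_l_min * 60.0

    def dose_sources(self) -> dict:
        return {c.name: c.dose_source for c in self.compartments}


def build_default_model(config: dict | None = None) -> CompartmentModel:
    """Build the circulation model from a config mapping (YAML/JSON-style).

    Recognised keys: ``total_blood_volume_l``, ``element_volume_ml``,
    ``cardiac_output_l_min``, ``transit_law`` and ``compartments`` (list of
    mappings with ``name``, ``fraction``, optional ``dose_source``).  Omitted
    keys fall back to the ICRP reference-adult defaults.
    """
    config = dict(config or {})
    comp_cfg = config.get("compartments")
    if comp_cfg is None:
        comps = [Compartment(n, f, s) for n, f, s in DEFAULT_COMPARTMENTS]
    else:
        comps = [
            Compartment(c["name"], float(c["fraction"]), c.get("dose_source"))
            for c in comp_cfg
        ]
    names = [c.name for c in comps]
    topology = {names[i]: names[(i + 1) % len(names)] for i in range(len(names))}
    return CompartmentModel(
        compartments=tuple(comps),
        topology=topology,
        cardiac_output_l_min=float(
            config.get("cardiac_output_l_min", DEFAULT_CARDIAC_OUTPUT_L_MIN)
        ),
        total_blood_volume_l=float(
            config.get("total_blood_volume_l", DEFAULT_TOTAL_BLOOD_VOLUME_L)
        ),
        element_volume_ml=float(
            config.get("element_volume_ml", DEFAULT_ELEMENT_VOLUME_ML)
        ),
        transit_law=config.get("transit_law", "exponential"),
    )


@dataclass
class BloodPathSet:
    """Sampled per-element compartment visit timelines on [0, duration_s].

    Visits are stored in flat arrays (element index, compartment index, entry
    and exit times) sorted by element then time; per element the visits tile
    the window with no gaps or overlaps.
    """

    n_elements: int
    duration_s: float
    elem: np.ndarray
    comp: np.ndarray
    t_entry: np.ndarray
    t_exit: np.ndarray
    compartments: list
    dose_sources: dict
    seed: object = None

    def visits_of(self, element: int):
        """(compartment name, t_entry, t_exit) tuples for one element."""
        sel = self.elem == element
        return [
            (self.compartments[c], float(a), float(b))
            for c, a, b in zip(self.comp[sel], self.t_entry[sel], self.t_exit[sel])
        ]

    def validate(self) -> None:
        """Check the tiling invariant: visits cover [0, duration] per element."""
        if np.any(self.t_exit <= self.t_entry):
            raise ValueError("found visit with t_exit <= t_entry")
        order = np.lexsort((self.t_entry, self.elem))
        e, a, b = self.elem[order], self.t_entry[order], self.t_exit[order]
        starts = np.searchsorted(e, np.arange(self.n_elements), side="left")
        ends = np.searchsorted(e, np.arange(self.n_elements), side="right")
        if np.any(starts == ends):
            raise ValueError("element with no visits")
        if np.any(np.abs(a[starts] - 0.0) > 1e-9) or np.any(
            np.abs(b[ends - 1] - self.duration_s) > 1e-9
        ):
            raise ValueError("visits do not span [0, duration]")
        inner = np.ones(len(e), dtype=bool)
        inner[ends - 1] = False
        if np.any(np.abs(b[inner] - a[np.roll(np.arange(len(e)), -1)[inner]]) > 1e-9):
            raise ValueError("gap or overlap between consecutive visits")


def _sojourn(rng, law, mean, size):
    if law == "exponential":
        return rng.exponential(mean, size=size)
    return np.full(size, mean)


def _residual(rng, law, mean, size):
    # stationary residual life: exponential is memoryless; fixed -> U(0, mean)
    if law == "exponential":
        return rng.exponential(mean, size=size)
    return rng.uniform(0.0, mean, size=size)


def simulate_paths(
    model: CompartmentModel,
    duration_s: float,
    seed,
    n_elements: int | None = None,
) -> BloodPathSet:
    """Sample element paths through the circulation cycle.

    Each element starts in a compartment drawn from the stationary
    distribution (the blood-volume fractions) with a residual sojourn, then
    follows the cycle with sojourns drawn per the model's transit law.
    Deterministic given (model, duration_s, seed, n_elements).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n = model.n_elements if n_elements is None else int(n_elements)
    names = model.names
    succ = np.array([names.index(model.topology[c]) for c in names])
    means = np.array([model.mean_transit_s(c) for c in names])

    comp0 = rng.choice(len(names), size=n, p=model.fractions)
    stay0 = _residual(rng, model.transit_law, means[comp0], n)

    elems, comps, entries, exits = [], [], [], []
    active = np.arange(n)
    cur_comp = comp0
    t = np.zeros(n)
    stay = stay0
    while active.size:
        end = np.minimum(t + stay, duration_s)
        elems.append(active.copy())
        comps.append(cur_comp.copy())
        entries.append(t.copy())
        exits.append(end)
        alive = t + stay < duration_s
        active = active[alive]
        t = (t + stay)[alive]
        cur_comp = succ[cur_comp[alive]]
        stay = _sojourn(rng, model.transit_law, means[cur_comp], active.size)

    elem = np.concatenate(elems)
    order = np.lexsort((np.concatenate(entries), elem))
    return BloodPathSet(
        n_elements=n,
        duration_s=float(duration_s),
        elem=elem[order],
        comp=np.concatenate(comps)[order],
        t_entry=np.concatenate(entries)[order],
        t_exit=np.concatenate(exits)[order],
        compartments=list(names),
        dose_sources=model.dose_sources(),
        seed=seed,
    )


def occupancy_in_window(paths: BloodPathSet, t0_s: float, t1_s: float) -> np.ndarray:
    """Seconds each element spends in each compartment within [t0, t1).

    Returns an ``(n_elements, n_compartments)`` array whose rows sum to
    ``t1 - t0``.
    """
    if not (0.0 <= t0_s < t1_s <= paths.duration_s + 1e-9):
        raise ValueError(
            f"window [{t0_s}, {t1_s}) must be non-degenerate and inside "
            f"[0, {paths.duration_s}]"
        )
    overlap = np.clip(
        np.minimum(paths.t_exit, t1_s) - np.maximum(paths.t_entry, t0_s), 0.0, None
    )
    out = np.zeros((paths.n_elements, len(paths.compartments)))
    np.add.at(out, (paths.elem, paths.comp), overlap)
    return out


def occupancy_fractions(paths: BloodPathSet) -> np.ndarray:
    """Time-averaged occupancy fraction of each compartment over all elements."""
    occ = occupancy_in_window(paths, 0.0, paths.duration_s)
    return occ.sum(axis=0) / (paths.n_elements * paths.duration_s)
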