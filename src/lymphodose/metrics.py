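"""Blood and organ dose metrics: bDVH curves, Dx%, V_xGyE, mean dose, BED.

Dx% is the minimum dose received by the most-irradiated x% of the blood
volume (empirical quantile with a lower-value tie-break), so D10 >= D90.
V_xGyE is the percentage of volume receiving at least x GyE (closed at the
threshold; with continuous simulated doses the distinction is measure-zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dvh_io import OrganDVH, to_differential
from .dose_engine import BloodDoseDistribution

__all__ = [
    "CBCMetrics",
    "bdvh_cumulative",
    "binned_bdvh",
    "d_percent",
    "v_threshold",
    "organ_metrics",
    "bed",
    "cbc_metrics",
    "metrics_table",
]

D_LEVELS = tuple(range(10, 100, 10))
V_LEVELS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5)
LUNG_V_LEVELS = (5.0, 10.0, 20.0)
HEART_V_LEVELS = (30.0, 45.0)
BDVH_BIN_GYE = 0.01


def _doses(dist) -> np.ndarray:
    arr = dist.doses if isinstance(dist, BloodDoseDistribution) else np.asarray(dist, float)
    if arr.size == 0:
        raise ValueError("empty dose distribution")
    return arr


def bdvh_cumulative(dist, grid) -> np.ndarray:
    """Percent of blood elements receiving >= each grid dose."""
    doses = np.sort(_doses(dist))
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be 1-d and strictly increasing")
    idx = np.searchsorted(doses, grid, side="left")
    return (doses.size - idx) / doses.size * 100.0


def binned_bdvh(dist, bin_gye: float = BDVH_BIN_GYE) -> pd.DataFrame:
    """Exportable bDVH curve on a regular dose grid (default 0.01 GyE bins)."""
    doses = _doses(dist)
    top = (np.floor(doses.max() / bin_gye) + 1) * bin_gye
    grid = np.arange(0.0, top + bin_gye / 2, bin_gye)
    return pd.DataFrame({"dose_gye": grid, "volume_pct": bdvh_cumulative(doses, grid)})


def d_percent(dist, x: float) -> float:
    """Dose to the hottest x% of blood: largest d with >= x% of elements >= d."""
    if not 0 < x < 100:
        raise ValueError("x must be in (0, 100)")
    doses = np.sort(_doses(dist))
    n = doses.size
    # fraction >= doses[i] is (n - i)/n; want the largest i with (n-i)/n >= x/100
    i = int(np.floor(n - n * x / 100.0 + 1e-12))
    return float(doses[min(max(i, 0), n - 1)])


def v_threshold(dist, t_gye: float) -> float:
    """Percent of blood elements receiving >= t GyE."""
    if t_gye < 0:
        raise ValueError("threshold must be non-negative")
    doses = _doses(dist)
    return float(np.mean(doses >= t_gye) * 100.0)


def organ_metrics(dvh: OrganDVH, v_levels=None) -> dict:
    """Mean organ dose and V_t% metrics from a cumulative organ DVH.

    The mean is the differential bin-mass-weighted representative dose; V_t is
    read off the cumulative curve with linear interpolation between grid
    points (values beyond the grid clamp to the end points).
    """
    if dvh.representation != "cumulative":
        raise ValueError("organ_metrics expects a cumulative DVH")
    if v_levels is None:
        v_levels = LUNG_V_LEVELS if dvh.organ == "lungs" else HEART_V_LEVELS
    out = {"mean_gye": dvh.mean_dose}
    for t in v_levels:
        out[f"v{t:g}_pct"] = float(
            np.interp(t, dvh.dose_grid, dvh.volume) * 100.0
        )
    return out


def bed(total_dose: float, n_fractions: int, alpha_beta: float = 10.0) -> float:
    """Biologically effective dose, n*d*(1 + d/(alpha/beta)), to 1 decimal."""
    if total_dose <= 0 or n_fractions <= 0 or alpha_beta <= 0:
        raise ValueError("total_dose, n_fractions and alpha_beta must be positive")
    d = total_dose / n_fractions
    return round(total_dose * (1.0 + d / alpha_beta), 1)


@dataclass(frozen=True)
class CBCMetrics:
    """Scalar dose metrics of the circulating-blood dose distribution."""

    patient_id: str
    mean_gye: float
    d_percent: dict  # x (%) -> Dx in GyE
    v_gye: dict  # t (GyE) -> V_t in %

    def __post_init__(self):
        dx = [self.d_percent[x] for x in sorted(self.d_percent)]
        if np.any(np.diff(dx) > 1e-12):
            raise ValueError("Dx must be non-increasing in x")
        vt = [self.v_gye[t] for t in sorted(self.v_gye)]
        if np.any(np.diff(vt) > 1e-12):
            raise ValueError("V_t must be non-increasing in t")


def cbc_metrics(dist, patient_id: str = "", d_levels=D_LEVELS, v_levels=V_LEVELS) -> CBCMetrics:
    doses = _doses(dist)
    return CBCMetrics(
        patient_id=patient_id,
        mean_gye=float(doses.mean()),
        d_percent={x: d_percent(doses, x) for x in d_levels},
        v_gye={t: v_threshold(doses, t) for t in v_levels},
    )


def metrics_table(blood_dists: dict, organ_dvhs: dict) -> pd.DataFrame:
    """One metrics row per patient: blood Dx/V_t plus lung/heart organ metrics.

    ``blood_dists`` maps patient_id -> BloodDoseDistribution (or dose array);
    ``organ_dvhs`` maps (patient_id, organ) -> cumulative OrganDVH.
    """
    rows = []
    for pid, dist in blood_dists.items():
        m = cbc_metrics(dist, patient_id=str(pid))
        row = {"patient_id": str(pid), "mean_cbc_gye": m.mean_gye}
        for x, v in m.d_percent.items():
            row[f"d{x}_gye"] = v
        for t, v in m.v_gye.items():
            row[f"v{str(t).replace('.', 'p')}_pct"] = v
        for organ in ("lungs", "heart"):
            dvh = organ_dvhs.get((pid, organ))
            if dvh is not None:
                for k, v in organ_metrics(dvh).items():
                    row[f"{organ}_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
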