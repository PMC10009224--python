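"""Tabular I/O for organ dose–volume histograms (DVHs) and patient cohort tables.

The canonical DVH dialect is a long-format CSV with columns
``patient_id, organ, dose_gye, volume_pct`` holding cumulative curves
(percent of organ volume receiving at least each dose, in GyE).  Planning
systems export many dialects; converters should target this one.

Cohort tables are one row per patient with columns
``patient_id, modality, gtv_cc, ctv_cc, ptv_cc, total_dose_gye, n_fractions,
baseline_alc, alc_w1..alc_wK, os_time, os_event, pfs_time, pfs_event`` plus
optional covariates.  Weekly absolute lymphocyte counts (ALC, cells/µL) may
contain gaps; gaps are kept as NaN and never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import re

import numpy as np
import pandas as pd

__all__ = [
    "OrganDVH",
    "PatientRecord",
    "DVHFormatError",
    "DVHValidationError",
    "read_dvh_table",
    "write_dvh_table",
    "to_differential",
    "cumulative_from_differential",
    "read_cohort",
    "write_cohort",
]

_ATOL = 1e-9


class DVHFormatError(ValueError):
    """A tabular file does not conform to the canonical dialect."""


class DVHValidationError(ValueError):
    """Values violate a DVH or cohort invariant."""


@dataclass(frozen=True)
class OrganDVH:
    """One organ's dose–volume curve for one patient plan.

    Parameters
    ----------
    organ : str
        Organ identifier (``heart`` and ``lungs`` for the circulation model;
        open set otherwise).
    dose_grid : ndarray
        Strictly increasing dose values in GyE; cumulative curves start at 0.
    volume : ndarray
        Cumulative: fraction of organ volume receiving >= dose (non-increasing,
        1 at dose 0).  Differential: non-negative bin masses summing to 1, each
        located at its representative dose.
    representation : {"cumulative", "differential"}
    """

    organ: str
    dose_grid: np.ndarray
    volume: np.ndarray
    representation: str = "cumulative"

    def __post_init__(self):
        dose = np.asarray(self.dose_grid, dtype=float)
        vol = np.asarray(self.volume, dtype=float)
        object.__setattr__(self, "dose_grid", dose)
        object.__setattr__(self, "volume", vol)
        if dose.ndim != 1 or dose.shape != vol.shape or dose.size == 0:
            raise DVHValidationError("dose_grid and volume must be equal-length 1-d arrays")
        if dose[0] < 0 or np.any(np.diff(dose) <= 0):
            raise DVHValidationError(
                f"dose grid for organ {self.organ!r} must be nonnegative and strictly increasing"
            )
        if self.representation == "cumulative":
            if abs(dose[0]) > _ATOL:
                raise DVHValidationError("cumulative DVH must start at dose 0")
            if abs(vol[0] - 1.0) > 1e-6:
                raise DVHValidationError("cumulative DVH must have volume 1 at dose 0")
            if np.any(np.diff(vol) > 1e-12):
                bad = int(np.argmax(np.diff(vol) > 1e-12))
                raise DVHValidationError(
                    f"cumulative volume increases at grid index {bad + 1} (organ {self.organ!r})"
                )
            if np.any(vol < -_ATOL) or np.any(vol > 1 + 1e-6):
                raise DVHValidationError("cumulative volume fractions must lie in [0, 1]")
        elif self.representation == "differential":
            if np.any(vol < -_ATOL):
                raise DVHValidationError("differential bin masses must be non-negative")
            if abs(vol.sum() - 1.0) > 1e-9:
                raise DVHValidationError(
                    f"differential bin masses sum to {vol.sum():.12f}, expected 1"
                )
        else:
            raise DVHValidationError(f"unknown representation {self.representation!r}")

    @property
    def mean_dose(self) -> float:
        """Mean organ dose in GyE (via the differential representation)."""
        if self.representation == "differential":
            d = self
        else:
            d = to_differential(self)
        return float(np.dot(d.dose_grid, d.volume))


def to_differential(dvh: OrganDVH) -> OrganDVH:
    """Convert a cumulative DVH to a differential one.

    Bin ``i`` carries mass ``V(d_i) - V(d_{i+1})`` at the representative dose
    ``(d_i + d_{i+1}) / 2`` (midpoint); the terminal bin carries the residual
    mass ``V(d_last)`` at ``d_last``.  Masses sum to 1.
    """
    if dvh.representation != "cumulative":
        raise DVHValidationError("to_differential expects a cumulative DVH")
    d, v = dvh.dose_grid, dvh.volume
    if d.size == 1:
        return OrganDVH(dvh.organ, d.copy(), np.array([1.0]), "differential")
    mids = 0.5 * (d[:-1] + d[1:])
    masses = np.clip(v[:-1] - v[1:], 0.0, None)
    grid = np.append(mids, d[-1])
    mass = np.append(masses, max(v[-1], 0.0))
    mass = mass / mass.sum()
    return OrganDVH(dvh.organ, grid, mass, "differential")


def cumulative_from_differential(dvh: OrganDVH, grid: np.ndarray) -> np.ndarray:
    """Fraction of differential mass at dose >= each grid value.

    Inverts :func:`to_differential` at the original grid points: the half-open
    ``>=`` convention matches the "volume receiving over X GyE" definition.
    """
    if dvh.representation != "differential":
        raise DVHValidationError("expects a differential DVH")
    grid = np.asarray(grid, dtype=float)
    order = np.argsort(dvh.dose_grid)
    doses = dvh.dose_grid[order]
    tail = np.concatenate([np.cumsum(dvh.volume[order][::-1])[::-1], [0.0]])
    idx = np.searchsorted(doses, grid, side="left")
    return tail[idx]


_DVH_COLUMNS = ["patient_id", "organ", "dose_gye", "volume_pct"]


def read_dvh_table(path, dialect: str = "long_csv") -> dict:
    """Read cumulative organ DVHs from a long-format CSV.

    Returns a dict keyed by ``(patient_id, organ)`` mapping to cumulative
    :class:`OrganDVH` with volumes converted from percent to fraction.
    """
    if dialect != "long_csv":
        raise DVHFormatError(f"unknown DVH dialect {dialect!r}")
    df = pd.read_csv(path)
    for col in _DVH_COLUMNS:
        if col not in df.columns:
            raise DVHFormatError(f"DVH table missing required column {col!r}")
    out = {}
    for (pid, organ), grp in df.groupby(["patient_id", "organ"], sort=False):
        doses = grp["dose_gye"].to_numpy(dtype=float)
        if np.any(np.diff(doses) <= 0):
            row = grp.index[int(np.argmax(np.diff(doses) <= 0)) + 1]
            raise DVHValidationError(
                f"non-monotone dose grid for patient {pid!r} organ {organ!r} at row {row}"
            )
        out[(pid, organ)] = OrganDVH(
            organ=str(organ),
            dose_grid=doses,
            volume=grp["volume_pct"].to_numpy(dtype=float) / 100.0,
            representation="cumulative",
        )
    return out


def write_dvh_table(dvhs: dict, path) -> None:
    """Write cumulative DVHs (dict keyed by (patient_id, organ)) as long CSV."""
    rows = []
    for (pid, organ), dvh in dvhs.items():
        if dvh.representation != "cumulative":
            raise DVHValidationError("write_dvh_table expects cumulative DVHs")
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "organ": organ,
                    "dose_gye": dvh.dose_grid,
                    "volume_pct": dvh.volume * 100.0,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


@dataclass
class PatientRecord:
    """Covariates, weekly ALC series and survival endpoints for one patient."""

    patient_id: str
    modality: str
    ptv_cc: float
    ctv_cc: float
    gtv_cc: float
    total_dose_gye: float
    n_fractions: int
    baseline_alc: float  # x10^3 cells/µL
    weekly_alc: np.ndarray  # cells/µL, NaN = missing week
    os_time: float  # months from first day of chemoradiation
    os_event: int
    pfs_time: float
    pfs_event: int
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weekly_alc = np.asarray(self.weekly_alc, dtype=float)
        if self.modality not in ("IMRT", "PBSPT"):
            raise DVHValidationError(f"unknown modality {self.modality!r}")
        for name in ("ptv_cc", "ctv_cc", "gtv_cc"):
            if getattr(self, name) <= 0:
                raise DVHValidationError(f"{name} must be positive for {self.patient_id!r}")
        if self.n_fractions < 1:
            raise DVHValidationError("n_fractions must be >= 1")
        obs = self.weekly_alc[~np.isnan(self.weekly_alc)]
        if np.any(obs < 0):
            raise DVHValidationError(f"negative ALC for patient {self.patient_id!r}")
        if int(self.os_event) not in (0, 1) or int(self.pfs_event) not in (0, 1):
            raise DVHValidationError("event flags must be 0/1")

    @property
    def incomplete_alc(self) -> bool:
        """True when one or more weekly ALC values are missing."""
        return bool(np.isnan(self.weekly_alc).any()) or self.weekly_alc.size == 0


_REQUIRED_COHORT = [
    "patient_id", "modality", "gtv_cc", "ctv_cc", "ptv_cc",
    "total_dose_gye", "n_fractions", "baseline_alc",
    "os_time", "os_event", "pfs_time", "pfs_event",
]


def read_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV into validated :class:`PatientRecord` objects.

    Weekly ALC columns are recognised by the ``alc_w<k>`` prefix and ordered
    by week number; any remaining column is kept as an optional covariate.
    """
    df = pd.read_csv(path)
    for col in _REQUIRED_COHORT:
        if col not in df.columns:
            raise DVHFormatError(f"cohort table missing required column {col!r}")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if len(dup):
        raise DVHValidationError(f"duplicate patient_id {dup.iloc[0]!r} in cohort table")
    week_cols = sorted(
        (c for c in df.columns if re.fullmatch(r"alc_w\d+", c)),
        key=lambda c: int(c[5:]),
    )
    extra = [c for c in df.columns if c not in _REQUIRED_COHORT and c not in week_cols]
    records = []
    for _, row in df.iterrows():
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                modality=str(row["modality"]),
                ptv_cc=float(row["ptv_cc"]),
                ctv_cc=float(row["ctv_cc"]),
                gtv_cc=float(row["gtv_cc"]),
                total_dose_gye=float(row["total_dose_gye"]),
                n_fractions=int(row["n_fractions"]),
                baseline_alc=float(row["baseline_alc"]),
                weekly_alc=np.array([float(row[c]) for c in week_cols]),
                os_time=float(row["os_time"]),
                os_event=int(row["os_event"]),
                pfs_time=float(row["pfs_time"]),
                pfs_event=int(row["pfs_event"]),
                covariates={c: row[c] for c in extra},
            )
        )
    return records


def write_cohort(records: list[PatientRecord], path) -> None:
    """Write PatientRecords back to the canonical cohort CSV."""
    n_weeks = max((r.weekly_alc.size for r in records), default=0)
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "modality": r.modality,
            "gtv_cc": r.gtv_cc,
            "ctv_cc": r.ctv_cc,
            "ptv_cc": r.ptv_cc,
            "total_dose_gye": r.total_dose_gye,
            "n_fractions": r.n_fractions,
            "baseline_alc": r.baseline_alc,
            "os_time": r.os_time,
            "os_event": r.os_event,
            "pfs_time": r.pfs_time,
            "pfs_event": r.pfs_event,
        }
        for k in range(n_weeks):
            row[f"alc_w{k + 1}"] = r.weekly_alc[k] if k < r.weekly_alc.size else np.nan
        row.update(r.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
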