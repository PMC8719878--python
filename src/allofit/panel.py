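"""Data model and I/O for mutant dose-response panels.

A panel is a set of datasets, one per (construct, replicate), each holding
the simultaneously measured sensor crosslink fraction and reporter activity
(Miller units) at the five growth ligand concentrations.  Replicates are
stored as separate datasets so that they enter the fit residuals with equal
weight each.

The on-disk dialect is tidy long-format CSV/TSV with columns
``mutant_id, replicate, mg_mM, crosslink_fraction, activity_miller``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MutantDataset",
    "PanelData",
    "PanelValidationError",
    "miller_units",
    "crosslink_fraction",
    "load_panel",
    "write_panel",
    "rescale_activity",
    "COLUMNS",
]

COLUMNS = ["mutant_id", "replicate", "mg_mM", "crosslink_fraction", "activity_miller"]

#: growth-medium ligand grid, mM
DEFAULT_MG_GRID_MM = (0.1, 0.4, 1.6, 6.4, 25.6)


class PanelValidationError(ValueError):
    """Raised when a panel table violates the structural contract."""


def miller_units(od420, od550, od600, dilution_factor, minutes):
    """Beta-galactosidase reporter activity in Miller units.

    ``1000 * (OD420 - 1.75*OD550) / (OD600 * dilution_factor * minutes)``.
    May be negative for blank-dominated readings; clamping is the caller's
    decision.
    """
    od600 = np.asarray(od600, dtype=float)
    dilution_factor = np.asarray(dilution_factor, dtype=float)
    minutes = np.asarray(minutes, dtype=float)
    if np.any(od600 <= 0) or np.any(dilution_factor <= 0) or np.any(minutes <= 0):
        raise ValueError("od600, dilution_factor and minutes must be positive")
    return 1000.0 * (np.asarray(od420, dtype=float) - 1.75 * np.asarray(od550, dtype=float)) / (
        od600 * dilution_factor * minutes
    )


def crosslink_fraction(monomer_intensity, dimer_intensity, mass_weighted: bool = False):
    """Crosslinked (dimer) fraction from band densitometry intensities.

    Default convention is the raw intensity ratio ``dimer/(dimer+monomer)``.
    ``mass_weighted=True`` uses ``2*dimer/(2*dimer+monomer)``, counting each
    dimer band as two monomer equivalents; the densitometry convention of the
    original quantification is not specified, so both are offered.
    """
    m = np.asarray(monomer_intensity, dtype=float)
    d = np.asarray(dimer_intensity, dtype=float)
    if np.any(m < 0) or np.any(d < 0):
        raise ValueError("band intensities must be non-negative")
    if np.any(m + d <= 0):
        raise ValueError("monomer + dimer intensity must be positive")
    if mass_weighted:
        return 2.0 * d / (2.0 * d + m)
    return d / (d + m)


@dataclass(frozen=True)
class MutantDataset:
    """One replicate's five-point dual-observable dose-response curve."""

    mutant_id: str
    replicate: int
    mg_mM: np.ndarray
    crosslink: np.ndarray
    activity_miller: np.ndarray
    activity_refactored: Optional[np.ndarray] = None

    def __post_init__(self):
        for name in ("mg_mM", "crosslink", "activity_miller"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.activity_refactored is not None:
            object.__setattr__(
                self, "activity_refactored", np.asarray(self.activity_refactored, dtype=float)
            )
        n = len(self.mg_mM)
        if len(self.crosslink) != n or len(self.activity_miller) != n:
            raise PanelValidationError(
                f"{self.dataset_id}: observable sequences must match the dose grid"
            )
        if np.any(np.diff(self.mg_mM) <= 0):
            raise PanelValidationError(f"{self.dataset_id}: mg grid must be strictly increasing")

    @property
    def dataset_id(self) -> str:
        return f"{self.mutant_id}#{self.replicate}"

    @property
    def mg_molar(self) -> np.ndarray:
        """Ligand grid converted from mM to molar (model units)."""
        return self.mg_mM * 1e-3


@dataclass(frozen=True)
class PanelData:
    """A collection of datasets plus the activity rescale factor ``q``."""

    datasets: tuple
    q: Optional[float] = None
    rejection_report: tuple = field(default=(), compare=False)

    def __post_init__(self):
        object.__setattr__(self, "datasets", tuple(self.datasets))
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise PanelValidationError("duplicate dataset ids in panel")

    def __len__(self) -> int:
        return len(self.datasets)

    @property
    def mutant_ids(self) -> tuple:
        seen = dict.fromkeys(d.mutant_id for d in self.datasets)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.datasets:
            for i in range(len(d.mg_mM)):
                rows.append(
                    {
                        "mutant_id": d.mutant_id,
                        "replicate": d.replicate,
                        "mg_mM": d.mg_mM[i],
                        "crosslink_fraction": d.crosslink[i],
                        "activity_miller": d.activity_miller[i],
                    }
                )
        return pd.DataFrame(rows, columns=COLUMNS)

    def to_json(self) -> str:
        payload = {
            "q": self.q,
            "datasets": [
                {
                    "mutant_id": d.mutant_id,
                    "replicate": d.replicate,
                    "mg_mM": d.mg_mM.tolist(),
                    "crosslink": d.crosslink.tolist(),
                    "activity_miller": d.activity_miller.tolist(),
                    "activity_refactored": (
                        None if d.activity_refactored is None else d.activity_refactored.tolist()
                    ),
                }
                for d in self.datasets
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PanelData":
        payload = json.loads(text)
        datasets = [
            MutantDataset(
                mutant_id=d["mutant_id"],
                replicate=d["replicate"],
                mg_mM=d["mg_mM"],
                crosslink=d["crosslink"],
                activity_miller=d["activity_miller"],
                activity_refactored=d.get("activity_refactored"),
            )
            for d in payload["datasets"]
        ]
        return cls(datasets=tuple(datasets), q=payload.get("q"))


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def load_panel(
    path,
    *,
    allow_out_of_range: bool = False,
    clamp_negative_activity: bool = False,
) -> PanelData:
    """Load a tidy long-format panel table into :class:`PanelData`.

    Only (mutant, replicate) groups with a complete, duplicate-free set of
    measurements at every ligand concentration in the table's grid are
    admitted; incomplete groups are rejected and listed in the returned
    panel's ``rejection_report``.

    Parameters
    ----------
    allow_out_of_range : admit crosslink values outside [0, 1] (synthetic
        panels with additive noise can legitimately exceed the range).
    clamp_negative_activity : clip negative Miller-unit readings to zero
        (default off so residual statistics stay unbiased).
    """
    df = _read_table(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise PanelValidationError(f"missing required columns: {missing}")

    dup = df.duplicated(subset=["mutant_id", "replicate", "mg_mM"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()
        raise PanelValidationError(f"duplicate (mutant, replicate, mg) keys at rows {rows}")

    if not allow_out_of_range:
        bad = (df["crosslink_fraction"] < 0) | (df["crosslink_fraction"] > 1)
        if bad.any():
            rows = df.index[bad].tolist()
            raise PanelValidationError(
                f"crosslink_fraction outside [0, 1] at rows {rows}; "
                "pass allow_out_of_range=True for noisy synthetic panels"
            )

    grid = np.sort(df["mg_mM"].unique())
    datasets: List[MutantDataset] = []
    rejected: List[str] = []
    for (mutant, rep), grp in df.groupby(["mutant_id", "replicate"], sort=False):
        grp = grp.sort_values("mg_mM")
        if len(grp) != len(grid) or not np.array_equal(grp["mg_mM"].to_numpy(), grid):
            rejected.append(
                f"{mutant}#{rep}: expected measurements at all of {grid.tolist()} mM, "
                f"got {grp['mg_mM'].tolist()}"
            )
            continue
        activity = grp["activity_miller"].to_numpy(dtype=float)
        if clamp_negative_activity:
            activity = np.clip(activity, 0.0, None)
        datasets.append(
            MutantDataset(
                mutant_id=str(mutant),
                replicate=int(rep),
                mg_mM=grp["mg_mM"].to_numpy(dtype=float),
                crosslink=grp["crosslink_fraction"].to_numpy(dtype=float),
                activity_miller=activity,
            )
        )
    return PanelData(datasets=tuple(datasets), rejection_report=tuple(rejected))


def write_panel(panel: PanelData, path) -> None:
    """Write a panel back to the tidy CSV/TSV dialect (numeric round-trip)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    panel.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


def rescale_activity(panel: PanelData, q: Optional[float] = None) -> PanelData:
    """Fill ``activity_refactored = activity_miller / q`` on every dataset.

    By default ``q = mean(activity_miller) / mean(crosslink)`` over all data
    points (replicates included), which makes the two observable families
    carry equal weight in the fit residuals: after rescaling,
    ``mean(activity_refactored) == mean(crosslink)`` to machine precision.
    An explicit ``q`` (e.g. the known scale of a synthetic panel) overrides
    the empirical estimate.
    """
    if len(panel) == 0:
        raise PanelValidationError("cannot rescale an empty panel")
    if q is None:
        act = np.concatenate([d.activity_miller for d in panel.datasets])
        xl = np.concatenate([d.crosslink for d in panel.datasets])
        mean_xl = xl.mean()
        if mean_xl == 0:
            raise PanelValidationError("all-zero crosslink data; q is undefined")
        q = float(act.mean() / mean_xl)
    if q <= 0:
        raise PanelValidationError(f"rescale factor q must be positive, got {q}")
    datasets = tuple(
        replace(d, activity_refactored=d.activity_miller / q) for d in panel.datasets
    )
    return PanelData(datasets=datasets, q=q, rejection_report=panel.rejection_report)
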