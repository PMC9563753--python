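"""Replicate peak-list ingestion, ppm peak assignment, and replicate aggregation.

Each sample is deposited five times on the MALDI plate; every deposition
yields one averaged spectrum (a peak list).  Peaks are matched to the
annotation database within a relative (ppm) mass window and the five
replicate assignments are collapsed to per-sample median raw intensities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lipid_db import AnnotationDB

__all__ = [
    "PeakList",
    "IntensityMatrix",
    "read_peak_lists",
    "assign_peaks",
    "aggregate_replicates",
    "build_intensity_matrix",
]

logger = logging.getLogger(__name__)

MZ_RANGE = (400.0, 2000.0)
REPLICATES_EXPECTED = 5


@dataclass
class PeakList:
    """One replicate spectrum: sorted m/z values with intensities."""

    sample_id: str
    replicate_id: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class IntensityMatrix:
    """Samples x lipid channels of median raw intensities.

    Values below the limit of quantitation (LOQ) are recorded as 0; the
    ``loq_mask`` marks cells that are 0/censored.  Internal-standard
    channels are listed in ``is_channels``.
    """

    values: pd.DataFrame
    loq: float = 8000.0
    is_channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("intensities must be nonnegative")

    @property
    def loq_mask(self) -> pd.DataFrame:
        return self.values < self.loq

    @property
    def lipid_columns(self) -> list[str]:
        return [c for c in self.values.columns if c not in self.is_channels]

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), loq=self.loq, is_channels=self.is_channels)

    def to_csv(self, path, mask_path=None) -> None:
        self.values.to_csv(path, sep="\t")
        if mask_path is not None:
            self.loq_mask.astype(int).to_csv(mask_path, sep="\t")


REQUIRED_COLUMNS = ("sample_id", "replicate_id", "mz", "intensity")


def read_peak_lists(path) -> list[PeakList]:
    """Read delimited replicate peak lists (sample_id, replicate_id, mz, intensity)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak-list file is missing columns: {missing}")
    if df.empty:
        warnings.warn("peak-list file contains a header but no rows", stacklevel=2)
        return []
    for col in ("mz", "intensity"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    rep = pd.to_numeric(df["replicate_id"], errors="raise").astype(int)
    outside = ~rep.between(1, REPLICATES_EXPECTED)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} rows have replicate_id outside 1..{REPLICATES_EXPECTED}; kept",
            stacklevel=2,
        )
    df = df.assign(replicate_id=rep)
    out: list[PeakList] = []
    for (sample, replicate), grp in df.groupby(["sample_id", "replicate_id"], sort=True):
        out.append(
            PeakList(
                sample_id=str(sample),
                replicate_id=int(replicate),
                mz=grp["mz"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
            )
        )
    return out


def assign_peaks(pl: PeakList, db: AnnotationDB) -> dict[str, float]:
    """Match observed peaks to database lipids within the ppm tolerance.

    Each database entry receives the intensity of the unclaimed observed
    peak with the smallest |delta ppm| inside the window, or 0.  When two
    entries' windows overlap on one peak, the nearer entry wins and the
    other falls back to its next-nearest in-window candidate.
    """
    tol = db.tolerance_ppm
    entry_mz = np.asarray(db.mz_values())
    names = db.names()
    # candidate (|dppm|, entry index, peak index) pairs inside the window
    candidates: list[tuple[float, int, int]] = []
    for i, mz0 in enumerate(entry_mz):
        lo = np.searchsorted(pl.mz, mz0 * (1 - tol * 1e-6))
        hi = np.searchsorted(pl.mz, mz0 * (1 + tol * 1e-6), side="right")
        for j in range(lo, hi):
            dppm = abs(pl.mz[j] - mz0) / mz0 * 1e6
            candidates.append((dppm, i, j))
    candidates.sort()
    assigned: dict[str, float] = {name: 0.0 for name in names}
    used_entries: set[int] = set()
    used_peaks: set[int] = set()
    for dppm, i, j in candidates:
        if i in used_entries or j in used_peaks:
            continue
        assigned[names[i]] = float(pl.intensity[j])
        used_entries.add(i)
        used_peaks.add(j)
    return assigned


def aggregate_replicates(assignments: Sequence[Mapping[str, float]]) -> dict[str, float]:
    """Per-lipid median across replicate assignments (unassigned counts as 0)."""
    if not assignments:
        raise ValueError("at least one replicate assignment is required")
    names: list[str] = list(assignments[0].keys())
    out: dict[str, float] = {}
    for name in names:
        vals = np.array([a.get(name, 0.0) for a in assignments], dtype=float)
        out[name] = float(np.median(vals))
    return out


def build_intensity_matrix(
    peak_lists: Iterable[PeakList],
    db: AnnotationDB,
    is_channels: Sequence[str] = (),
    loq: float = 8000.0,
) -> IntensityMatrix:
    """Assign and aggregate replicate peak lists into an :class:`IntensityMatrix`.

    Samples with fewer than five replicates are accepted with a logged
    warning; aggregated medians below the LOQ are censored to 0.
    """
    by_sample: dict[str, list[PeakList]] = {}
    for pl in peak_lists:
        by_sample.setdefault(pl.sample_id, []).append(pl)
    rows = {}
    for sample, pls in by_sample.items():
        if len(pls) < REPLICATES_EXPECTED:
            logger.warning("sample %s has only %d replicates", sample, len(pls))
        rows[sample] = aggregate_replicates([assign_peaks(pl, db) for pl in pls])
    values = pd.DataFrame.from_dict(rows, orient="index", columns=db.names())
    values = values.reindex(columns=db.names()).fillna(0.0)
    values = values.where(values >= loq, 0.0)
    return IntensityMatrix(values=values, loq=loq, is_channels=tuple(is_channels))
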