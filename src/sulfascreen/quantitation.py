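"""Inclusion criteria, floor imputation, and concentration calculation.

Three inclusion criteria gate the quantitative analysis:

1. a lipid must be present (intensity above the 8000-count floor) in at
   least 50% of samples of *both* groups (controls N and cases T);
2. its coefficient of variation across pooled QC samples must be < 35%
   (computed on raw, unimputed intensities);
3. a subject is excluded when more than 50% of the panel lipids are below
   the limit of quantitation or the internal-standard signal itself is
   below the LOQ (high matrix effect).

Censored cells are then floor-imputed with the lowest reproducible
intensity (8000) and converted to molar concentrations (normalization to
the spiked internal standard of the lipid's class) and to relative
percentages within each class group (SM, sulfatides, StS).  Downstream
statistics default to the relative percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import IntensityMatrix
from .panels import CLASS_GROUPS, lipid_class_of

__all__ = [
    "QuantConfig",
    "QuantResult",
    "filter_presence",
    "filter_qc_cv",
    "exclude_subjects",
    "impute_floor",
    "to_molar",
    "relative_within_class",
    "run_quantitation",
    "class_group_map",
]

logger = logging.getLogger(__name__)


@dataclass
class QuantConfig:
    """Quantitation parameters (defaults follow the processing workflow)."""

    presence_min_fraction: float = 0.5
    qc_cv_max: float = 0.35
    floor_intensity: float = 8000.0
    subject_exclusion_fraction: float = 0.5
    #: IS channel name -> {"amount": nmol/mL, "classes": covered lipid classes}
    is_declarations: dict[str, dict[str, object]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.presence_min_fraction <= 1.0):
            raise ValueError("presence_min_fraction must be in (0, 1]")
        if not (0.0 < self.subject_exclusion_fraction <= 1.0):
            raise ValueError("subject_exclusion_fraction must be in (0, 1]")
        if self.floor_intensity <= 0:
            raise ValueError("floor_intensity must be positive")
        if self.qc_cv_max <= 0:
            raise ValueError("qc_cv_max must be positive")


def class_group_map(columns: Sequence[str]) -> dict[str, str]:
    """Map channel names to their relative-quantitation class group."""
    return {c: CLASS_GROUPS[lipid_class_of(c)] for c in columns}


def filter_presence(
    m: IntensityMatrix,
    groups: pd.Series,
    cfg: QuantConfig,
) -> list[str]:
    """Inclusion criterion 1: presence in >= 50% of samples of both groups.

    Presence means intensity above the floor.  ``groups`` holds N/T labels
    indexed by sample id; IS channels are not subject to the criterion.
    """
    groups = groups.reindex(m.values.index).dropna()
    labels = groups.unique()
    if len(labels) < 2:
        raise ValueError("both groups (N and T) must be nonempty")
    present = m.values.loc[groups.index] > cfg.floor_intensity
    retained = []
    for lipid in m.lipid_columns:
        fracs = present[lipid].groupby(groups).mean()
        if (fracs >= cfg.presence_min_fraction).all():
            retained.append(lipid)
    return retained


def filter_qc_cv(
    m: IntensityMatrix,
    qc_sample_ids: Sequence[str],
    cfg: QuantConfig,
) -> tuple[list[str], dict[str, str]]:
    """Inclusion criterion 2: QC coefficient of variation below 35%.

    The CV (sample sd / mean, n-1 denominator) is computed on raw,
    unimputed QC intensities.  Returns (retained lipids, drop reasons).
    """
    qc_ids = [s for s in qc_sample_ids if s in m.values.index]
    if len(qc_ids) < 3:
        raise ValueError("at least 3 QC samples are required for the CV criterion")
    qc = m.values.loc[qc_ids]
    retained: list[str] = []
    dropped: dict[str, str] = {}
    for lipid in m.lipid_columns:
        vals = qc[lipid].to_numpy()
        mean = vals.mean()
        if mean == 0:
            dropped[lipid] = "qc_mean_zero"
            logger.info("lipid %s dropped: zero mean QC intensity", lipid)
            continue
        cv = vals.std(ddof=1) / mean
        if cv < cfg.qc_cv_max:
            retained.append(lipid)
        else:
            dropped[lipid] = f"qc_cv={cv:.3f}"
    return retained, dropped


def exclude_subjects(
    m: IntensityMatrix,
    cfg: QuantConfig,
) -> tuple[list[str], pd.DataFrame]:
    """Inclusion criterion 3: drop subjects dominated by sub-LOQ signal.

    A sample is excluded when strictly more than 50% of the (non-IS) panel
    lipids are below the LOQ, or when any declared IS channel is below the
    LOQ.  Returns (retained sample ids, exclusion report with reasons).
    """
    is_cols = [c for c in m.is_channels if c in m.values.columns]
    if not is_cols:
        raise ValueError("intensity matrix has no internal-standard channel")
    lipid_cols = m.lipid_columns
    below = m.loq_mask[lipid_cols]
    frac_below = below.mean(axis=1)
    is_below = m.loq_mask[is_cols].any(axis=1)
    records = []
    retained = []
    for sample in m.values.index:
        reasons = []
        if frac_below.loc[sample] > cfg.subject_exclusion_fraction:
            reasons.append("sub_loq_fraction")
        if is_below.loc[sample]:
            reasons.append("is_below_loq")
        if reasons:
            records.append(
                {
                    "sample_id": sample,
                    "reason": "+".join(reasons),
                    "frac_below_loq": float(frac_below.loc[sample]),
                }
            )
        else:
            retained.append(sample)
    report = pd.DataFrame(records, columns=["sample_id", "reason", "frac_below_loq"])
    return retained, report


def impute_floor(m: IntensityMatrix, cfg: QuantConfig) -> IntensityMatrix:
    """Replace censored cells (0 / below LOQ) by the floor intensity.

    Idempotent: cells at or above the floor are untouched.
    """
    values = m.values.where(m.values >= cfg.floor_intensity, cfg.floor_intensity)
    return IntensityMatrix(values=values, loq=m.loq, is_channels=m.is_channels)


def _is_for_class(cfg: QuantConfig, lipid_class: str) -> str:
    for is_name, decl in cfg.is_declarations.items():
        if lipid_class in tuple(decl.get("classes", ())):
            return is_name
    raise ValueError(f"no internal standard declared for lipid class {lipid_class!r}")


def to_molar(m: IntensityMatrix, cfg: QuantConfig) -> pd.DataFrame:
    """Molar concentrations (nmol/mL): intensity / class IS intensity x spike.

    Requires the matrix to be floor-imputed (all IS intensities positive).
    """
    out = {}
    for lipid in m.lipid_columns:
        is_name = _is_for_class(cfg, lipid_class_of(lipid))
        if is_name not in m.values.columns:
            raise ValueError(f"IS channel {is_name!r} missing from the matrix")
        amount = float(cfg.is_declarations[is_name]["amount"])  # type: ignore[arg-type]
        is_signal = m.values[is_name]
        if (is_signal <= 0).any():
            raise ValueError(f"IS channel {is_name!r} has nonpositive intensities")
        out[lipid] = m.values[lipid] / is_signal * amount
    return pd.DataFrame(out, index=m.values.index)


def relative_within_class(
    m: IntensityMatrix,
    class_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Percent abundance of each lipid within its class group, per sample.

    IS channels are excluded from the class sums.  Requires a floor-imputed
    matrix so every class sum is positive.
    """
    lipid_cols = m.lipid_columns
    if class_map is None:
        class_map = class_group_map(lipid_cols)
    unmapped = [c for c in lipid_cols if c not in class_map]
    if unmapped:
        raise ValueError(f"lipids without a class mapping: {unmapped}")
    values = m.values[lipid_cols]
    out = pd.DataFrame(index=values.index, columns=lipid_cols, dtype=float)
    classes = pd.Series({c: class_map[c] for c in lipid_cols})
    for cls in classes.unique():
        cols = classes.index[classes == cls].tolist()
        total = values[cols].sum(axis=1)
        if (total <= 0).any():
            raise ValueError(f"nonpositive class sum for {cls!r}; impute the floor first")
        out[cols] = values[cols].div(total, axis=0) * 100.0
    return out


@dataclass
class QuantResult:
    """Bundle of quantitation outputs."""

    relative: pd.DataFrame
    molar: pd.DataFrame
    imputed: IntensityMatrix
    retained_lipids: list[str]
    dropped_presence: list[str]
    dropped_qc: dict[str, str]
    excluded_samples: pd.DataFrame


def run_quantitation(
    m: IntensityMatrix,
    groups: pd.Series,
    qc_sample_ids: Sequence[str],
    cfg: QuantConfig,
) -> QuantResult:
    """Full quantitation flow: presence -> QC-CV -> subject exclusion ->
    imputation -> molar + relative concentrations.

    ``groups`` maps cohort sample ids to N/T; QC samples are used only for
    criterion 2 and are absent from the returned concentration tables.
    """
    retained1 = filter_presence(m, groups, cfg)
    retained2, dropped_qc = filter_qc_cv(m, qc_sample_ids, cfg)
    retained = [c for c in retained1 if c in set(retained2)]
    dropped_presence = [c for c in m.lipid_columns if c not in set(retained1)]

    cohort_ids = [s for s in m.values.index if s in set(groups.index)]
    cols = retained + [c for c in m.is_channels if c in m.values.columns]
    trimmed = IntensityMatrix(
        values=m.values.loc[cohort_ids, cols].copy(),
        loq=m.loq,
        is_channels=m.is_channels,
    )
    kept_samples, excluded = exclude_subjects(trimmed, cfg)
    trimmed = IntensityMatrix(
        values=trimmed.values.loc[kept_samples],
        loq=m.loq,
        is_channels=m.is_channels,
    )
    imputed = impute_floor(trimmed, cfg)
    molar = to_molar(imputed, cfg) if cfg.is_declarations else pd.DataFrame(index=imputed.values.index)
    relative = relative_within_class(imputed)
    return QuantResult(
        relative=relative,
        molar=molar,
        imputed=imputed,
        retained_lipids=retained,
        dropped_presence=dropped_presence,
        dropped_qc=dropped_qc,
        excluded_samples=excluded,
    )
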