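"""Synthetic MALDI-MS lipidomics cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes so
that every pipeline stage is testable without patient data: log-normal
between-subject lipid intensities, group-wise dysregulation multipliers
that grow from the early (T1-2) to the late (T3-4) stage bracket, five
technical replicates per sample with multiplicative noise, LOQ censoring,
pooled QC samples with bounded CV, spiked internal-standard channels,
designated low-signal subjects (matrix effect) that the subject-exclusion
criterion must flag, missing BMI values, and replicate peak lists with
ppm mass jitter plus decoy peaks.

Default cohort sizes follow the study design: 207 controls / 143 cases
(plasma), 70 / 100 before exclusion (urine, with 3 + 24 designated
low-signal subjects), and 77 tumor/nontumor tissue pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .ingest import IntensityMatrix
from .lipid_db import AnnotationDB, build_database, parse_shorthand, LipidParseError
from .panels import EffectSizes, PanelChannel, default_effect_map, default_panel
from .quantitation import QuantConfig

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticStudy",
    "generate_cohort",
    "generate_intensities",
    "generate_peak_lists",
    "simulate_study",
    "quant_config_for",
    "null_effect_map",
    "channel_db_name",
]

_DEFAULT_SIZES = {"plasma": (207, 143), "urine": (70, 100), "tissue": (0, 77)}
_DEFAULT_LOW_SIGNAL = {"plasma": (0, 0), "urine": (3, 24), "tissue": (0, 0)}


def _default_stage_probs() -> dict[str, float]:
    return {"T1": 0.40, "T2": 0.12, "T3": 0.40, "T4": 0.08}


@dataclass
class GeneratorConfig:
    """Synthetic-cohort parameters (defaults emulate the study conditions)."""

    seed: int = 0
    matrix: str = "plasma"
    n_controls: int | None = None
    n_cases: int | None = None
    stage_probs: dict[str, float] = field(default_factory=_default_stage_probs)
    between_subject_sigma: float = 0.6  # natural-log sd of subject intensities
    replicate_cv: float = 0.10  # CV of the five technical depositions
    n_replicates: int = 5
    n_qc: int = 10
    qc_cv: float = 0.15
    loq: float = 8000.0
    n_low_signal_controls: int | None = None
    n_low_signal_cases: int | None = None
    low_signal_scale: float = 0.02  # global suppression factor (matrix effect)
    missing_bmi_fraction: float = 0.05
    ppm_jitter: float = 2.0
    n_decoy_peaks: int = 5
    effect_scale: float = 1.0  # scales log-multipliers of the effect map
    tissue_pair_sigma: float = 0.3  # shared per-subject random effect
    tissue_within_sigma: float = 0.4
    # demographic distributions (controls, cases); cases skew male, older,
    # and slightly heavier, as in the study population
    male_fraction: tuple[float, float] = (0.45, 0.65)
    age_mean_sd: tuple[tuple[float, float], tuple[float, float]] = ((55.0, 10.0), (63.0, 9.0))
    bmi_mean_sd: tuple[tuple[float, float], tuple[float, float]] = ((26.0, 4.0), (27.5, 4.5))
    panel: list[PanelChannel] | None = None
    effect_map: dict[str, EffectSizes] | None = None

    def __post_init__(self) -> None:
        nc, nt = _DEFAULT_SIZES[self.matrix]
        if self.n_controls is None:
            self.n_controls = nc
        if self.n_cases is None:
            self.n_cases = nt
        lc, lt = _DEFAULT_LOW_SIGNAL[self.matrix]
        if self.n_low_signal_controls is None:
            self.n_low_signal_controls = lc
        if self.n_low_signal_cases is None:
            self.n_low_signal_cases = lt
        if self.panel is None:
            self.panel = default_panel(self.matrix)
        if self.effect_map is None:
            self.effect_map = default_effect_map(self.matrix)
        if self.n_controls < 0 or self.n_cases < 0:
            raise ValueError("cohort sizes must be nonnegative")
        if self.ppm_jitter < 0:
            raise ValueError("ppm jitter must be nonnegative")
        if any(m.early <= 0 or m.late <= 0 for m in self.effect_map.values()):
            raise ValueError("effect multipliers must be positive")
        total = sum(self.stage_probs.values())
        if total <= 0:
            raise ValueError("stage probabilities must sum to a positive value")
        self.stage_probs = {k: v / total for k, v in self.stage_probs.items()}


def null_effect_map() -> dict[str, EffectSizes]:
    """Effect map with no dysregulation (all multipliers 1)."""
    return {}


def fully_null_config(**kwargs) -> "GeneratorConfig":
    """A cohort with no group differences at all.

    Beyond a null effect map, the demographic distributions (gender, age,
    BMI) are matched between controls and cases and no rare channel
    differs in presence, so labels are independent of every model input.
    """
    panel = kwargs.pop("panel", None)
    cfg = GeneratorConfig(
        effect_map=null_effect_map(),
        male_fraction=(0.5, 0.5),
        age_mean_sd=((58.0, 10.0), (58.0, 10.0)),
        bmi_mean_sd=((26.5, 4.0), (26.5, 4.0)),
        panel=panel,
        **kwargs,
    )
    cfg.panel = [
        replace(ch, presence=(ch.presence[0], ch.presence[0])) if ch.role == "rare" else ch
        for ch in cfg.panel
    ]
    return cfg


def channel_db_name(channel_name: str) -> str:
    """Database key of a panel channel (species-level names normalized)."""
    try:
        return parse_shorthand(channel_name).name
    except LipidParseError:
        return channel_name


@dataclass
class GroundTruth:
    """What the generator actually injected, keyed by database channel name."""

    direction: dict[str, str]  # up / down / null per non-IS channel
    multipliers: dict[str, tuple[float, float]]  # (T1-2, T3-4) multipliers
    low_signal_samples: list[str]  # samples the exclusion criterion must flag
    rare_channels: list[str]
    is_channels: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "channel": name,
                "direction": self.direction[name],
                "mult_early": self.multipliers[name][0],
                "mult_late": self.multipliers[name][1],
            }
            for name in sorted(self.direction)
        ]
        return pd.DataFrame(rows)


def _rngs(cfg: GeneratorConfig) -> tuple[np.random.Generator, ...]:
    ss = np.random.SeedSequence([int(cfg.seed) % (2**31), 0x5F1D])
    return tuple(np.random.default_rng(child) for child in ss.spawn(4))


def _stage_bracket(stage: str) -> str:
    return "T1-2" if stage in ("T1", "T2") else "T3-4"


def generate_cohort(cfg: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw subject metadata and the injected ground truth.

    Plasma/urine cohorts get one row per subject (groups N and T); the
    tissue cohort emits paired nontumor/tumor rows per patient.  Cases
    receive a TNM stage (and a grade loosely tracking it); a configured
    number of subjects per group is designated low-signal.
    """
    rng_cohort, _, _, _ = _rngs(cfg)
    male_n, male_t = cfg.male_fraction
    (age_n, age_n_sd), (age_t, age_t_sd) = cfg.age_mean_sd
    (bmi_n, bmi_n_sd), (bmi_t, bmi_t_sd) = cfg.bmi_mean_sd
    rows = []
    if cfg.matrix == "tissue":
        for i in range(cfg.n_cases):
            subject = f"S{i + 1:03d}"
            gender = "M" if rng_cohort.random() < male_t else "F"
            age = float(np.clip(rng_cohort.normal(age_t, age_t_sd), 30, 85).round(1))
            bmi = float(np.clip(rng_cohort.normal(bmi_t, bmi_t_sd), 17, 45).round(1))
            stage = str(
                rng_cohort.choice(list(cfg.stage_probs), p=list(cfg.stage_probs.values()))
            )
            grade = int(np.clip(int(stage[1]) + rng_cohort.integers(-1, 2), 1, 4))
            for part, group in (("NT", "N"), ("TU", "T")):
                rows.append(
                    {
                        "sample_id": f"{subject}-{part}",
                        "subject_id": subject,
                        "group": group,
                        "matrix": cfg.matrix,
                        "gender": gender,
                        "age": age,
                        "bmi": bmi,
                        "stage": stage,
                        "grade": grade,
                        "pair_id": subject,
                    }
                )
    else:
        for i in range(cfg.n_controls):
            rows.append(
                {
                    "sample_id": f"N{i + 1:03d}",
                    "subject_id": f"N{i + 1:03d}",
                    "group": "N",
                    "matrix": cfg.matrix,
                    "gender": "M" if rng_cohort.random() < male_n else "F",
                    "age": float(np.clip(rng_cohort.normal(age_n, age_n_sd), 25, 85).round(1)),
                    "bmi": float(np.clip(rng_cohort.normal(bmi_n, bmi_n_sd), 17, 45).round(1)),
                    "stage": "",
                    "grade": 0,
                    "pair_id": "",
                }
            )
        for i in range(cfg.n_cases):
            stage = str(
                rng_cohort.choice(list(cfg.stage_probs), p=list(cfg.stage_probs.values()))
            )
            rows.append(
                {
                    "sample_id": f"T{i + 1:03d}",
                    "subject_id": f"T{i + 1:03d}",
                    "group": "T",
                    "matrix": cfg.matrix,
                    "gender": "M" if rng_cohort.random() < male_t else "F",
                    "age": float(np.clip(rng_cohort.normal(age_t, age_t_sd), 30, 85).round(1)),
                    "bmi": float(np.clip(rng_cohort.normal(bmi_t, bmi_t_sd), 17, 45).round(1)),
                    "stage": stage,
                    "grade": int(np.clip(int(stage[1]) + rng_cohort.integers(-1, 2), 1, 4)),
                    "pair_id": "",
                }
            )
    cohort = pd.DataFrame(rows).set_index("sample_id", drop=False)

    # missing BMI
    n_missing = int(round(cfg.missing_bmi_fraction * len(cohort)))
    if n_missing:
        miss = rng_cohort.choice(cohort.index.to_numpy(), size=n_missing, replace=False)
        cohort.loc[miss, "bmi"] = np.nan

    # designated low-signal subjects (criterion-3 exclusions)
    low: list[str] = []
    for group, n_low in (("N", cfg.n_low_signal_controls), ("T", cfg.n_low_signal_cases)):
        ids = cohort.index[cohort["group"] == group].to_numpy()
        if n_low > len(ids):
            raise ValueError(f"more low-signal subjects than group {group} members")
        if n_low:
            low.extend(rng_cohort.choice(ids, size=n_low, replace=False).tolist())

    direction: dict[str, str] = {}
    multipliers: dict[str, tuple[float, float]] = {}
    rare = []
    is_channels = []
    for ch in cfg.panel:
        name = channel_db_name(ch.name)
        if ch.role == "is":
            is_channels.append(name)
            continue
        if ch.role == "rare":
            rare.append(name)
            p_n, p_t = ch.presence
            direction[name] = "up" if p_t > p_n else "down" if p_t < p_n else "null"
            multipliers[name] = (1.0, 1.0)
            continue
        eff = cfg.effect_map.get(ch.name)
        if eff is None:
            direction[name] = "null"
            multipliers[name] = (1.0, 1.0)
        else:
            s = cfg.effect_scale
            early = float(np.exp(s * np.log(eff.early)))
            late = float(np.exp(s * np.log(eff.late)))
            multipliers[name] = (early, late)
            direction[name] = "up" if late > 1 else "down" if late < 1 else "null"
    truth = GroundTruth(
        direction=direction,
        multipliers=multipliers,
        low_signal_samples=sorted(low),
        rare_channels=rare,
        is_channels=is_channels,
    )
    return cohort, truth


@dataclass
class SyntheticStudy:
    """One simulated study: cohort, ground truth, and measured intensities."""

    config: GeneratorConfig
    cohort: pd.DataFrame
    truth: GroundTruth
    matrix: IntensityMatrix  # cohort + QC rows, LOQ-censored medians
    qc_ids: list[str]
    db: AnnotationDB
    replicate_intensities: np.ndarray  # (samples, replicates, channels), pre-censoring
    peak_lists: pd.DataFrame | None = None
    peak_truth: pd.DataFrame | None = None


def generate_intensities(
    cohort: pd.DataFrame,
    truth: GroundTruth,
    cfg: GeneratorConfig,
) -> SyntheticStudy:
    """Draw per-sample, per-replicate raw intensities for the whole panel.

    intensity = lognormal(baseline) x stage-bracket multiplier (cases),
    with the T3-4 multiplier farther from 1 than T1-2; five replicates add
    multiplicative noise at the replicate CV; medians below the LOQ are
    censored to 0; designated low-signal subjects are globally suppressed;
    QC samples are drawn around the pooled control baseline at the QC CV.
    """
    _, rng_int, rng_rep, _ = _rngs(cfg)
    panel = cfg.panel
    names = [channel_db_name(ch.name) for ch in panel]
    db = build_database([ch.record() for ch in panel])
    n_ch = len(panel)
    sigma_rep = float(np.sqrt(np.log1p(cfg.replicate_cv**2)))

    sample_ids = cohort.index.tolist()
    n_s = len(sample_ids)
    subj_level = np.zeros((n_s, n_ch))

    groups = cohort["group"].to_numpy()
    stages = cohort["stage"].to_numpy()
    low_set = set(truth.low_signal_samples)

    pair_effect: dict[str, np.ndarray] = {}
    if cfg.matrix == "tissue":
        for pid in cohort["pair_id"].unique():
            pair_effect[pid] = rng_int.normal(0.0, cfg.tissue_pair_sigma, size=n_ch)

    for j, ch in enumerate(panel):
        name = names[j]
        if ch.role == "is":
            subj_level[:, j] = ch.base * np.exp(rng_int.normal(0.0, 0.05, size=n_s))
            continue
        if ch.role == "rare":
            p_n, p_t = ch.presence
            p = np.where(groups == "T", p_t, p_n)
            present = rng_int.random(n_s) < p
            level = ch.base * np.exp(rng_int.normal(0.0, 0.3, size=n_s))
            subj_level[:, j] = np.where(present, level, 0.0)
            continue
        early, late = truth.multipliers[name]
        mult = np.ones(n_s)
        case = groups == "T"
        if case.any():
            brackets = np.array([_stage_bracket(s) if s else "" for s in stages])
            mult = np.where(case & (brackets == "T1-2"), early, mult)
            mult = np.where(case & (brackets == "T3-4"), late, mult)
        if cfg.matrix == "tissue":
            shared = np.array([pair_effect[p][j] for p in cohort["pair_id"]])
            noise = rng_int.normal(0.0, cfg.tissue_within_sigma, size=n_s)
            base_mult = np.where(case, mult, 1.0)
            subj_level[:, j] = ch.base * base_mult * np.exp(shared + noise)
        else:
            z = rng_int.normal(0.0, cfg.between_subject_sigma, size=n_s)
            subj_level[:, j] = ch.base * mult * np.exp(z)

    low_mask = np.array([s in low_set for s in sample_ids])
    subj_level[low_mask] *= cfg.low_signal_scale

    reps = subj_level[:, None, :] * np.exp(
        rng_rep.normal(0.0, sigma_rep, size=(n_s, cfg.n_replicates, n_ch))
    )
    reps[subj_level[:, None, :].repeat(cfg.n_replicates, axis=1) == 0.0] = 0.0
    medians = np.median(reps, axis=1)

    # pooled QC samples
    qc_ids = [f"QC{i + 1:02d}" for i in range(cfg.n_qc)]
    qc_rows = np.zeros((cfg.n_qc, n_ch))
    for j, ch in enumerate(panel):
        cv = ch.qc_cv if ch.qc_cv is not None else cfg.qc_cv
        sigma_qc = float(np.sqrt(np.log1p(cv**2)))
        base = ch.base if ch.role != "rare" else max(ch.base, cfg.loq * 2)
        qc_rows[:, j] = base * np.exp(rng_rep.normal(0.0, sigma_qc, size=cfg.n_qc))

    values = pd.DataFrame(
        np.vstack([medians, qc_rows]),
        index=sample_ids + qc_ids,
        columns=names,
    )
    values = values.where(values >= cfg.loq, 0.0)
    matrix = IntensityMatrix(values=values, loq=cfg.loq, is_channels=tuple(truth.is_channels))
    return SyntheticStudy(
        config=cfg,
        cohort=cohort,
        truth=truth,
        matrix=matrix,
        qc_ids=qc_ids,
        db=db,
        replicate_intensities=reps,
    )


def generate_peak_lists(study: SyntheticStudy) -> SyntheticStudy:
    """Emit replicate peak lists (with mass jitter and decoys) plus truth.

    Peaks are placed at the theoretical channel m/z times (1 + jitter),
    jitter ~ Uniform(-ppm_jitter, +ppm_jitter) — a bounded mass error, so
    with jitter below the matching tolerance every generated peak stays
    inside its channel's window; decoy peaks fall at random m/z at least
    50 ppm away from every panel channel.
    """
    cfg = study.config
    _, _, _, rng_peaks = _rngs(cfg)
    names = study.db.names()
    mz0 = np.array(study.db.mz_values())
    reps = study.replicate_intensities
    n_s, n_r, n_ch = reps.shape
    sample_ids = study.cohort.index.tolist()
    rows_sample = []
    rows_rep = []
    rows_mz = []
    rows_int = []
    rows_src = []
    for si, sample in enumerate(sample_ids):
        for r in range(n_r):
            intensities = reps[si, r]
            live = intensities > 0
            jitter = rng_peaks.uniform(-cfg.ppm_jitter, cfg.ppm_jitter, size=int(live.sum()))
            mzs = mz0[live] * (1.0 + jitter * 1e-6)
            for mz, inten, name in zip(mzs, intensities[live], np.array(names)[live]):
                rows_sample.append(sample)
                rows_rep.append(r + 1)
                rows_mz.append(mz)
                rows_int.append(inten)
                rows_src.append(name)
            for _ in range(cfg.n_decoy_peaks):
                while True:
                    mz = rng_peaks.uniform(400.0, 2000.0)
                    if np.min(np.abs(mz - mz0) / mz0) * 1e6 > 50.0:
                        break
                rows_sample.append(sample)
                rows_rep.append(r + 1)
                rows_mz.append(mz)
                rows_int.append(float(2e4 * np.exp(rng_peaks.normal(0.0, 0.5))))
                rows_src.append("decoy")
    peaks = pd.DataFrame(
        {
            "sample_id": rows_sample,
            "replicate_id": rows_rep,
            "mz": rows_mz,
            "intensity": rows_int,
        }
    )
    truth = peaks.assign(source=rows_src)
    study.peak_lists = peaks
    study.peak_truth = truth
    return study


def simulate_study(cfg: GeneratorConfig, peaks: bool = False) -> SyntheticStudy:
    """Generate a full synthetic study (optionally with peak lists)."""
    cohort, truth = generate_cohort(cfg)
    study = generate_intensities(cohort, truth, cfg)
    if peaks:
        study = generate_peak_lists(study)
    return study


def quant_config_for(cfg: GeneratorConfig) -> QuantConfig:
    """Quantitation config matching the generator's panel and LOQ."""
    decls: dict[str, dict[str, object]] = {}
    for ch in cfg.panel:
        if ch.role == "is":
            decls[channel_db_name(ch.name)] = {
                "amount": ch.is_amount,
                "classes": list(ch.is_classes),
            }
    return QuantConfig(floor_intensity=cfg.loq, is_declarations=decls)


def write_study(study: SyntheticStudy, outdir) -> dict[str, str]:
    """Write cohort, peak lists, QC manifest, IS declarations, and truth.

    All files are delimited text with the seed recorded in a header line.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    cfg = study.config
    header = f"# sulfascreen synthetic study; matrix={cfg.matrix}; seed={cfg.seed}\n"
    paths: dict[str, str] = {}

    def _write(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = os.path.join(outdir, name)
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=index)
        paths[name] = path

    _write("cohort.tsv", study.cohort.reset_index(drop=True))
    _write("intensity_matrix.tsv", study.matrix.values, index=True)
    _write("qc_manifest.tsv", pd.DataFrame({"sample_id": study.qc_ids}))
    decls = quant_config_for(cfg).is_declarations
    _write(
        "is_declarations.tsv",
        pd.DataFrame(
            [
                {"channel": k, "amount_nmol_per_ml": v["amount"],
                 "classes": "+".join(v["classes"])}  # type: ignore[arg-type]
                for k, v in decls.items()
            ]
        ),
    )
    _write("ground_truth.tsv", study.truth.to_frame())
    if study.peak_lists is not None:
        _write("peak_lists.tsv", study.peak_lists)
        _write("peak_truth.tsv", study.peak_truth)
    return paths
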