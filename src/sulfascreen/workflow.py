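"""End-to-end task runners: quantify -> statistics -> classification.

Convenience layer over the module functions, used by the command-line
interface and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classify as cl
from . import stats as st
from .quantitation import QuantResult, run_quantitation
from .synthetic import GeneratorConfig, SyntheticStudy, quant_config_for, simulate_study

__all__ = ["StatsBundle", "quantify", "analyze", "classify_tasks", "run_all"]


def quantify(study: SyntheticStudy) -> QuantResult:
    """Apply the inclusion criteria and concentration calculation."""
    groups = study.cohort["group"]
    cfg = quant_config_for(study.config)
    return run_quantitation(study.matrix, groups, study.qc_ids, cfg)


@dataclass
class StatsBundle:
    """Tabular statistics outputs of one study."""

    group_table: pd.DataFrame
    stage_table: pd.DataFrame | None
    presence_table: pd.DataFrame
    spearman_age: pd.DataFrame
    spearman_bmi: pd.DataFrame
    cluster: st.ClusterSummary | None


def _stage_table(relative: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    brackets = cohort.loc[relative.index].apply(
        lambda r: "N" if r["group"] == "N"
        else ("T1-2" if r["stage"] in ("T1", "T2") else "T3-4"),
        axis=1,
    )
    order = ["N", "T1-2", "T3-4"]
    rows = []
    for lipid in relative.columns:
        groups = [relative.loc[brackets == g, lipid].to_numpy() for g in order]
        h, p, eps2 = st.kruskal_wallis(groups)
        row = {"lipid": lipid, "H": h, "p_raw": p, "epsilon_sq": eps2}
        if p < 0.05:
            ph = st.conover_posthoc(groups)
            for (i, j) in ((0, 1), (0, 2), (1, 2)):
                row[f"conover_{order[i]}_vs_{order[j]}"] = float(ph.iat[i, j])
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q_fdr"] = st.bh_fdr(out["p_raw"].to_numpy())
    return out


def analyze(study: SyntheticStudy, quant: QuantResult, cluster_top: int = 8) -> StatsBundle:
    """Run the per-lipid statistics appropriate for the study's design."""
    relative = quant.relative
    cohort = study.cohort.loc[relative.index]
    paired = study.config.matrix == "tissue"
    if paired:
        pairs = pd.DataFrame(
            {
                "nontumor": [s for s in relative.index if s.endswith("-NT")],
                "tumor": [s.replace("-NT", "-TU") for s in relative.index if s.endswith("-NT")],
            }
        )
        group_table = st.paired_stats(relative, pairs)
        stage_table = None
        # sub-inclusion lipids: presence/absence on the pre-filter matrix
        failed = [c for c in quant.dropped_presence if c in study.matrix.values.columns]
        cohort_matrix = study.matrix.values.loc[cohort.index]
        m = study.matrix.copy()
        m.values = cohort_matrix
        presence = st.presence_tables(m, pairs, failed, paired=True)
    else:
        labels = cohort["group"]
        group_table = st.group_stats(relative, labels)
        stage_table = _stage_table(relative, cohort)
        failed = [c for c in quant.dropped_presence if c in study.matrix.values.columns]
        m = study.matrix.copy()
        m.values = study.matrix.values.loc[cohort.index]
        presence = st.presence_tables(m, labels, failed, paired=False)
    spearman_age = st.spearman_screen(cohort["age"], relative)
    spearman_bmi = st.spearman_screen(cohort["bmi"], relative)
    cluster = None
    if len(relative) >= 2 and len(group_table):
        top = group_table.nsmallest(min(cluster_top, len(group_table)), "q_fdr")["lipid"]
        transformed, _ = cl.preprocess(
            relative, fit_on=relative.index, lipid_columns=list(relative.columns)
        )
        cluster = st.cluster_summary(transformed, list(top))
    return StatsBundle(
        group_table=group_table,
        stage_table=stage_table,
        presence_table=presence,
        spearman_age=spearman_age,
        spearman_bmi=spearman_bmi,
        cluster=cluster,
    )


def classify_tasks(
    study: SyntheticStudy,
    quant: QuantResult,
    spec: cl.ModelSpec,
    tasks: list[str] | None = None,
) -> dict[str, dict]:
    """Run the classification tasks defined for the study's matrix."""
    if tasks is None:
        tasks = (
            ["plasma-all", "plasma-early", "plasma-late"]
            if study.config.matrix == "plasma"
            else ["urine-all"]
            if study.config.matrix == "urine"
            else []
        )
    cohort = study.cohort.loc[quant.relative.index]
    return {task: cl.run_task(quant.relative, cohort, task, spec) for task in tasks}


def run_all(cfg: GeneratorConfig, model_seed: int | None = None) -> dict:
    """Simulate, quantify, analyze, and classify one synthetic study."""
    study = simulate_study(cfg)
    quant = quantify(study)
    bundle = analyze(study, quant)
    spec = cl.ModelSpec(seed=cfg.seed if model_seed is None else model_seed)
    reports = classify_tasks(study, quant, spec)
    return {
        "study": study,
        "quant": quant,
        "stats": bundle,
        "classifiers": reports,
    }
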