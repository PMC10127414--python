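"""End-to-end orchestration: simulate or ingest a cohort, subgroup the
SCD subjects, and run demographics, volumetric, correlation, network and
follow-up analyses, writing one delimited table per report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as scio
from .clinical import (
    ancova_group_effect,
    chi_square_test,
    composite_zscores,
    fdr_adjust,
    fisher_exact_two_tailed,
    lsd_posthoc,
    oneway_anova,
    split_scd_by_score,
    two_sample_t,
    StatResult,
)
from .config import AnalysisConfig
from .inference import AUC_LABELS, metric_curves, nodal_permutation_fdr, permutation_test_auc
from .network import covariance_matrix, smallest_connected_sparsity, sparsity_grid, strongest_fraction_edges
from .nodes import (
    BASAL_FOREBRAIN_SUBFIELDS,
    DEFAULT_NODE_SET,
    GROUPS,
    NodeSet,
    RIGHT_HIPPOCAMPAL_SUBFIELDS,
    SUBCORTICAL_NUCLEI,
    sanitize_label,
)
from .synthetic import CohortSpec, generate_cohort
from .clinical import partial_correlation

logger = logging.getLogger(__name__)

#: post hoc letter codes for the six group pairs
PAIR_CODES = {
    ("NC", "G-SCD"): "a",
    ("NC", "B-SCD"): "b",
    ("NC", "MCI"): "c",
    ("G-SCD", "B-SCD"): "d",
    ("G-SCD", "MCI"): "e",
    ("B-SCD", "MCI"): "f",
}


@dataclass
class RunManifest:
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # stage -> "ok" | error text
    files: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def warn(self, stage: str, message: str, **context) -> None:
        self.warnings.append({"stage": stage, "message": message, **context})
        logger.warning("[%s] %s", stage, message)


def _mean_sd(x: pd.Series) -> str:
    return f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"


def _posthoc_codes(pairs: dict[tuple[str, str], StatResult], alpha: float) -> str:
    codes = []
    for (a, b), res in pairs.items():
        code = PAIR_CODES.get((a, b)) or PAIR_CODES.get((b, a))
        if code and res.p < alpha:
            codes.append(code)
    return "".join(sorted(codes))


def assign_groups(
    cohort: pd.DataFrame, config: AnalysisConfig, manifest: RunManifest | None = None
) -> pd.DataFrame:
    """Label the SCD subjects G-SCD/B-SCD by the configured score.

    The default score is navigation (mean distance error over all 16
    trials, lower = better); composites (memory/language/executive,
    higher = better) reproduce the alternative-grouping re-analysis.
    """
    out = cohort.copy()
    comp = composite_zscores(out)
    if config.grouping_score == "navigation":
        score = comp["navigation"]
        lower_better = True
    else:
        score = comp[config.grouping_score]
        lower_better = False
    out["group"] = split_scd_by_score(out, score, lower_is_better=lower_better)
    for d in comp.columns:
        out[f"composite_{d}"] = comp[d]
    if manifest is not None:
        sizes = out["group"].value_counts().to_dict()
        manifest.stages["group"] = f"ok (sizes {sizes})"
    return out


def demographics_table(cohort: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Group summaries with one-way ANOVA for continuous variables and
    chi-square for sex and scanner."""
    groups_present = [g for g in GROUPS if g in set(cohort["group"])]
    rows = []
    cont_vars = [
        ("age", "Age"),
        ("education_years", "Education years"),
        ("scd_q", "SCD-Q"),
        ("mmse", "MMSE"),
        ("composite_memory", "Memory function"),
        ("composite_language", "Language function"),
        ("composite_executive", "Executive function"),
        ("composite_navigation", "Navigation distance errors"),
        ("tiv", "TIV"),
        ("iqr", "IQR"),
    ]
    g = cohort["group"].to_numpy()
    for col, label in cont_vars:
        if col not in cohort.columns:
            continue
        vals = cohort[col].to_numpy(dtype=float)
        res = oneway_anova(vals, g)
        row = {"variable": label, "statistic": res.statistic, "p": res.p, "test": "F"}
        for grp in groups_present:
            row[grp] = _mean_sd(cohort.loc[cohort["group"] == grp, col])
        rows.append(row)
    for col, label, level in (("sex", "Sex (male/female)", "M"), ("scanner", "MRI (TX/CX)", "TX")):
        if col not in cohort.columns:
            continue
        tab = pd.crosstab(cohort[col], cohort["group"])[groups_present]
        res = chi_square_test(tab.to_numpy())
        row = {"variable": label, "statistic": res.statistic, "p": res.p, "test": "chi2"}
        for grp in groups_present:
            sub = cohort.loc[cohort["group"] == grp, col]
            row[grp] = f"{int((sub == level).sum())}/{int((sub != level).sum())}"
        rows.append(row)
    return pd.DataFrame(rows)


def volumetric_table(
    cohort: pd.DataFrame,
    rois: tuple[str, ...],
    config: AnalysisConfig,
    fdr_family: bool = True,
) -> pd.DataFrame:
    """ANCOVA per ROI (group effect adjusting for the configured
    covariates) with LSD post hoc letter codes and FDR across the ROI
    family."""
    groups_present = [g for g in GROUPS if g in set(cohort["group"])]
    g = cohort["group"].to_numpy()
    cov = cohort.loc[:, list(config.covariates)]
    rows = []
    for roi in rois:
        vals = cohort[roi].to_numpy(dtype=float)
        fit = ancova_group_effect(vals, g, cov)
        pairs = lsd_posthoc(fit)
        row = {
            "roi": roi,
            "F": fit.result.statistic,
            "p": fit.result.p,
            "posthoc": _posthoc_codes(pairs, config.alpha),
        }
        for grp in groups_present:
            row[grp] = _mean_sd(cohort.loc[cohort["group"] == grp, roi])
            row[f"adj_mean_{grp}"] = fit.result.group_means.get(grp, np.nan)
        rows.append(row)
    table = pd.DataFrame(rows)
    if fdr_family and len(table):
        table["p_fdr"] = fdr_adjust(table["p"].to_numpy())
        table["significant_fdr"] = table["p_fdr"] < config.alpha
    return table


def correlation_table(
    cohort: pd.DataFrame,
    rois: tuple[str, ...],
    config: AnalysisConfig,
    domains: tuple[str, ...] = ("memory", "language", "executive", "navigation"),
) -> pd.DataFrame:
    """Partial correlations (volume x domain composite) adjusted for the
    configured covariates, FDR over the whole grid."""
    cov = cohort.loc[:, list(config.covariates)]
    rows = []
    for roi in rois:
        for d in domains:
            col = f"composite_{d}"
            if col not in cohort.columns:
                continue
            res = partial_correlation(
                cohort[roi].to_numpy(dtype=float), cohort[col].to_numpy(dtype=float), cov
            )
            rows.append({"roi": roi, "domain": d, "r": res.statistic, "p": res.p})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_fdr"] = fdr_adjust(table["p"].to_numpy())
        table["significant_fdr"] = table["p_fdr"] < config.alpha
    return table


def compare_followup(
    cohort: pd.DataFrame, groups: tuple[str, str] = ("G-SCD", "B-SCD")
) -> pd.DataFrame:
    """Follow-up comparison of two groups: Fisher's exact test on
    conversion and on sex, two-sample t tests on age, education and
    interval days (followed-up subjects only)."""
    fu = cohort[cohort["followup_outcome"].isin(["converter", "nonconverter"])]
    a = fu[fu["group"] == groups[0]]
    b = fu[fu["group"] == groups[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError(
            f"no followed-up subjects in one of {groups}; cannot compare outcomes"
        )
    rows = []

    def _summary(sub: pd.DataFrame, col: str) -> str:
        return _mean_sd(sub[col])

    for col, label in (("age", "Age"), ("education_years", "Education"), ("followup_days", "Interval (days)")):
        res = two_sample_t(a[col].to_numpy(float), b[col].to_numpy(float))
        rows.append(
            {
                "variable": label,
                groups[0]: _summary(a, col),
                groups[1]: _summary(b, col),
                "statistic": res.statistic,
                "test": "t",
                "p": res.p,
            }
        )
    sex_tab = np.array(
        [
            [(a["sex"] == "M").sum(), (a["sex"] != "M").sum()],
            [(b["sex"] == "M").sum(), (b["sex"] != "M").sum()],
        ]
    )
    res = fisher_exact_two_tailed(sex_tab)
    rows.append(
        {
            "variable": "Sex (male/female)",
            groups[0]: f"{sex_tab[0,0]}/{sex_tab[0,1]}",
            groups[1]: f"{sex_tab[1,0]}/{sex_tab[1,1]}",
            "statistic": np.nan,
            "test": "fisher",
            "p": res.p,
        }
    )
    conv_tab = np.array(
        [
            [(a["followup_outcome"] == "converter").sum(), (a["followup_outcome"] == "nonconverter").sum()],
            [(b["followup_outcome"] == "converter").sum(), (b["followup_outcome"] == "nonconverter").sum()],
        ]
    )
    res = fisher_exact_two_tailed(conv_tab)
    rows.append(
        {
            "variable": "Outcome (converters/nonconverters)",
            groups[0]: f"{conv_tab[0,0]}/{conv_tab[0,1]}",
            groups[1]: f"{conv_tab[1,0]}/{conv_tab[1,1]}",
            "statistic": np.nan,
            "test": "fisher",
            "p": res.p,
        }
    )
    return pd.DataFrame(rows)


def network_stage(
    cohort: pd.DataFrame,
    node_set: NodeSet,
    config: AnalysisConfig,
    out_dir: Path,
    manifest: RunManifest,
    contrasts: list[tuple[str, str]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-group covariance networks, metric/AUC curves, permutation
    contrasts and nodal FDR; exports matrices and edge lists."""
    groups_present = [g for g in GROUPS if g in set(cohort["group"])]
    grid = sparsity_grid(config.sparsity_min, config.sparsity_max, config.sparsity_step)
    auc_rows, curve_rows = [], []
    for gi, grp in enumerate(groups_present):
        sub = cohort[cohort["group"] == grp]
        cov = sub.loc[:, list(config.covariates)] if config.residualize_edges else None
        net = covariance_matrix(sub, node_set, grp, config.correlation_method, covariates=cov)
        safe = sanitize_label(grp)
        scio.write_matrix(net.R, node_set, out_dir / f"R_{safe}.csv")
        scio.write_matrix(net.R_plus, node_set, out_dir / f"R_plus_{safe}.csv")
        scio.write_edge_list(net.R_plus, node_set, out_dir / f"edges_{safe}.csv")
        top = strongest_fraction_edges(net, 0.25)
        top.to_csv(out_dir / f"top25_edges_{safe}.csv", index=False)
        s_conn = smallest_connected_sparsity(net, grid)
        if s_conn is None or s_conn > config.sparsity_min:
            manifest.warn(
                "network",
                f"group {grp}: graph first fully connected at sparsity {s_conn}",
                group=grp,
            )
        res = metric_curves(sub, node_set, config, grp, seed=config.seed + 101 + gi)
        if res["swap_deficit"]:
            manifest.warn(
                "network", f"group {grp}: swap deficit {res['swap_deficit']}", group=grp
            )
        for t, s in enumerate(grid):
            if res["achieved_edges"][t] < res["target_edges"][t]:
                manifest.warn(
                    "network",
                    f"group {grp}: achieved {res['achieved_edges'][t]} of "
                    f"{res['target_edges'][t]} edges at sparsity {s}",
                    group=grp,
                )
            if res["unreachable_pairs"][t]:
                manifest.warn(
                    "network",
                    f"group {grp}: {res['unreachable_pairs'][t]} unreachable pairs "
                    f"at sparsity {s}",
                    group=grp,
                )
        for name, curve in res["global"].items():
            auc_rows.append(
                {"group": grp, "metric": AUC_LABELS[name], "auc": curve.auc}
            )
            for s, v in zip(curve.sparsities, curve.values):
                curve_rows.append(
                    {"group": grp, "metric": name, "node": "global", "sparsity": s, "value": v}
                )
        for name, per_node in res["nodal"].items():
            for node, curve in per_node.items():
                auc_rows.append(
                    {"group": grp, "metric": f"a_{name}[{node}]", "auc": curve.auc}
                )
    tables = {
        "network_auc": pd.DataFrame(auc_rows),
        "network_curves": pd.DataFrame(curve_rows),
    }

    if contrasts is None:
        contrasts = [
            (a, b)
            for i, a in enumerate(groups_present)
            for b in groups_present[i + 1 :]
        ]
    perm_rows, nodal_rows = [], []
    for ci, (ga, gb) in enumerate(contrasts):
        A = cohort[cohort["group"] == ga]
        B = cohort[cohort["group"] == gb]
        res = permutation_test_auc(A, B, node_set, config, seed=config.seed + 1000 + ci)
        for name, pr in res.items():
            perm_rows.append(
                {
                    "contrast": f"{ga} vs {gb}",
                    "metric": AUC_LABELS[name],
                    ga: pr.observed_a,
                    gb: pr.observed_b,
                    "diff": pr.observed_diff,
                    "p": pr.p,
                }
            )
        nod = nodal_permutation_fdr(
            A, B, node_set, "nodal_efficiency", config, seed=config.seed + 2000 + ci
        )
        for node, pr in nod.items():
            nodal_rows.append(
                {
                    "contrast": f"{ga} vs {gb}",
                    "metric": "a_nodal_efficiency",
                    "node": node,
                    ga: pr.observed_a,
                    gb: pr.observed_b,
                    "p": pr.p,
                    "p_fdr": pr.p_fdr,
                }
            )
    tables["network_permutation"] = pd.DataFrame(perm_rows)
    tables["network_nodal_fdr"] = pd.DataFrame(nodal_rows)
    return tables


def run_pipeline(
    config: AnalysisConfig | None = None,
    cohort: pd.DataFrame | None = None,
    cohort_spec: CohortSpec | None = None,
    out_dir: str | Path = "results",
    node_set: NodeSet = DEFAULT_NODE_SET,
    contrasts: list[tuple[str, str]] | None = None,
) -> RunManifest:
    """Run every stage in order and write the report tables.

    Input is either an existing cohort table or a simulation spec
    (default: the calibrated synthetic cohort).  The pipeline is a pure
    function of (input, config, seed).
    """
    config = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seeds={"master": config.seed})
    tables: dict[str, pd.DataFrame] = {}

    def _stage(name, fn):
        try:
            result = fn()
            manifest.stages.setdefault(name, "ok")
            return result
        except Exception as err:  # noqa: BLE001 - manifest records the failure
            manifest.stages[name] = f"error: {err}"
            raise PipelineError(name, str(err), manifest) from err

    if cohort is None:
        spec = cohort_spec or CohortSpec(seed=config.seed)
        cohort = _stage("simulate", lambda: generate_cohort(spec))
        tables["cohort"] = cohort
    cohort = _stage("validate", lambda: scio.validate_cohort(cohort, node_set))
    cohort = _stage("group", lambda: assign_groups(cohort, config, manifest))
    tables["demographics"] = _stage(
        "demographics", lambda: demographics_table(cohort, config)
    )
    tables["subcortical_volumes"] = _stage(
        "volumetrics", lambda: volumetric_table(cohort, SUBCORTICAL_NUCLEI, config)
    )
    tables["basal_forebrain_subfields"] = _stage(
        "volumetrics_bf",
        lambda: volumetric_table(cohort, BASAL_FOREBRAIN_SUBFIELDS, config),
    )
    tables["right_hippocampal_subfields"] = _stage(
        "volumetrics_hipp",
        lambda: volumetric_table(cohort, RIGHT_HIPPOCAMPAL_SUBFIELDS, config),
    )
    tables["partial_correlations"] = _stage(
        "correlate",
        lambda: correlation_table(
            cohort, BASAL_FOREBRAIN_SUBFIELDS + RIGHT_HIPPOCAMPAL_SUBFIELDS, config
        ),
    )
    tables.update(
        _stage(
            "network",
            lambda: network_stage(cohort, node_set, config, out, manifest, contrasts),
        )
    )
    has_fu = cohort["followup_outcome"].isin(["converter", "nonconverter"]).any()
    if has_fu:
        tables["followup"] = _stage("followup", lambda: compare_followup(cohort))
    else:
        manifest.stages["followup"] = "skipped: no follow-up outcomes"

    log = scio.write_report_tables(
        tables, out, config=manifest.config, warnings_log=manifest.warnings
    )
    manifest.files = log["files"]
    return manifest


class PipelineError(RuntimeError):
    """A stage failed; the manifest records partial completion."""

    def __init__(self, stage: str, message: str, manifest: RunManifest):
        self.stage = stage
        self.manifest = manifest
        super().__init__(f"stage {stage!r} failed: {message}")
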