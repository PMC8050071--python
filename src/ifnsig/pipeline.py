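"""End-to-end pipeline: simulate -> quantify -> score -> stats -> report.

Each stage communicates with the next only through documented TSV files in
the output directory, so any stage can be rerun (or replaced) in
isolation.  A run ends with a manifest listing every product file with its
SHA-256 checksum; identical config + seed reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohortstats import anova_power, correlation_table, dunn_posthoc, kruskal_wallis
from .design import IRG_PANEL_PBMC, IRG_PANEL_WHOLE_BLOOD, StudyDesign, default_design
from .ifnscore import IFNPanel, calibrate_threshold, call_positivity, ifn_score, positivity_summary
from .relquant import delta_ct, qc_filter, relative_expression
from .simulate import generate_cohort, read_ct, read_samples, read_serum, write_dataset

log = logging.getLogger(__name__)

SERUM_MEASURES = {"cxcl10_pg_ml": "CXCL10", "mcp1_pg_ml": "MCP-1", "ccl19_pg_ml": "CCL19"}
CLINICAL_VARIABLES = ["bvas", "crp_mg_dl", "creatinine_umol_l"]
POWER_DELTAS = (0.0, 0.25, 0.5, 0.75)


class ConfigError(ValueError):
    """A pipeline-configuration field is invalid; the message names it."""


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    design: StudyDesign = field(default_factory=default_design)
    rin_min: float = 6.0
    yield_min: float = 30.0
    panels: dict[str, list[str]] = field(
        default_factory=lambda: {
            "whole_blood": list(IRG_PANEL_WHOLE_BLOOD),
            "pbmc": list(IRG_PANEL_PBMC),
        }
    )
    adjustment: str = "bonferroni"
    alpha: float = 0.05
    sd_ddof: int = 1
    power_convention: str = "textbook"

    def validate(self) -> None:
        self.design.validate()
        for specimen, genes in self.panels.items():
            if specimen not in ("whole_blood", "pbmc"):
                raise ConfigError(f"panels: unknown specimen {specimen!r}")
            for gene in genes:
                if gene not in self.design.genes:
                    raise ConfigError(f"panels[{specimen}]: unknown panel gene {gene!r}")
            if self.design.reference_gene in genes:
                raise ConfigError(
                    f"panels[{specimen}]: reference gene {self.design.reference_gene!r} "
                    "cannot be a signature gene"
                )
        if self.adjustment not in ("bonferroni", "holm", "sidak"):
            raise ConfigError(f"adjustment: unknown method {self.adjustment!r}")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha: must be in (0, 1)")
        if self.sd_ddof not in (0, 1):
            raise ConfigError("sd_ddof: must be 0 or 1")
        if self.power_convention not in ("textbook", "between-var"):
            raise ConfigError(f"power_convention: unknown convention {self.power_convention!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        d["design"] = self.design.to_dict()
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "design" in d:
            d["design"] = StudyDesign.from_dict(d["design"])
        d["outdir"] = Path(d["outdir"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# -- helpers -----------------------------------------------------------------

def _analysis_group(cohort: str) -> str:
    """Collapse treatment-split active-AAV arms into one analysis group."""
    if cohort in ("aav_a_tx", "aav_a_naive"):
        return "aav_a"
    return cohort


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# -- stages ------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Generate the synthetic cohort tables (samples, Ct, serum) and design snapshot."""
    samples, ct, serum = generate_cohort(config.design, seed=config.seed)
    paths = write_dataset(samples, ct, serum, config.outdir)
    design_path = config.outdir / "design.yaml"
    config.design.to_yaml(design_path)
    paths["design"] = design_path
    return paths


def stage_quantify(config: PipelineConfig) -> dict[str, Path]:
    """QC-filter samples and compute 2^-ddCt expression per specimen type."""
    outdir = config.outdir
    samples = read_samples(outdir / "samples.tsv")
    ct = read_ct(outdir / "ct.tsv")

    passing, rejections = qc_filter(samples, rin_min=config.rin_min, yield_min=config.yield_min)
    paths = {"qc_rejections": outdir / "qc_rejections.tsv"}
    rejections.to_csv(paths["qc_rejections"], sep="\t")

    hc_median_rows = []
    for specimen in config.panels:
        subset = passing.index[passing["specimen"] == specimen]
        if subset.empty:
            continue
        dct = delta_ct(ct.loc[subset], reference_gene=config.design.reference_gene)
        hc_cohorts = config.design.healthy_control_cohorts(specimen)
        hc_ids = passing.index[passing["cohort"].isin(hc_cohorts)]
        expr, hc_median = relative_expression(dct, hc_ids)
        path = outdir / f"expression_{specimen}.tsv"
        expr.to_csv(path, sep="\t", float_format="%.6f")
        paths[f"expression_{specimen}"] = path
        for gene, med in hc_median.items():
            hc_median_rows.append({"specimen": specimen, "gene": gene, "hc_median_dct": med})
    medians = pd.DataFrame(hc_median_rows)
    paths["hc_medians"] = outdir / "hc_medians.tsv"
    medians.to_csv(paths["hc_medians"], sep="\t", index=False, float_format="%.6f")
    return paths


def stage_score(config: PipelineConfig) -> dict[str, Path]:
    """Score samples, calibrate per-specimen thresholds, summarise positivity."""
    outdir = config.outdir
    samples = read_samples(outdir / "samples.tsv")
    all_calls = []
    for specimen, genes in config.panels.items():
        path = outdir / f"expression_{specimen}.tsv"
        if not path.exists():
            continue
        expr = pd.read_csv(path, sep="\t", index_col="sample_id")
        scores = ifn_score(expr, IFNPanel(specimen, tuple(genes)))
        hc_cohorts = config.design.healthy_control_cohorts(specimen)
        hc_ids = samples.index[samples["cohort"].isin(hc_cohorts)].intersection(scores.index)
        threshold = calibrate_threshold(scores.loc[hc_ids, "score"], ddof=config.sd_ddof)
        calls = call_positivity(scores, threshold)
        calls.insert(0, "specimen", specimen)
        all_calls.append(calls)
    combined = pd.concat(all_calls)
    paths = {"ifn_scores": outdir / "ifn_scores.tsv"}
    combined.to_csv(paths["ifn_scores"], sep="\t", float_format="%.6f")

    summaries = []
    for specimen in combined["specimen"].unique():
        part = combined[combined["specimen"] == specimen]
        designed = [c.name for c in config.design.cohorts if c.specimen == specimen]
        summary = (
            positivity_summary(part, samples)
            .reindex(designed)  # cohorts with no scored samples appear as n = 0
            .fillna({"n": 0, "n_positive": 0})
            .astype({"n": int, "n_positive": int})
            .reset_index()
        )
        summary.insert(0, "specimen", specimen)
        summaries.append(summary)
    paths["positivity_summary"] = outdir / "positivity_summary.tsv"
    pd.concat(summaries).to_csv(paths["positivity_summary"], sep="\t", index=False)
    return paths


def _comparison_rows(name: str, value_by_group: dict[str, pd.Series], adjustment: str) -> list[dict]:
    labels = [g for g, v in value_by_group.items() if len(v) > 0]
    groups = [value_by_group[g].to_numpy() for g in labels]
    h, df, p = kruskal_wallis(groups)
    rows = [
        {
            "analysis": name, "comparison": "omnibus", "group_1": "", "group_2": "",
            "statistic": h, "df": df, "p_raw": p, "p_adj": p,
            "mean_rank_1": float("nan"), "mean_rank_2": float("nan"),
        }
    ]
    for _, r in dunn_posthoc(groups, labels=labels, adjustment=adjustment).iterrows():
        rows.append(
            {
                "analysis": name,
                "comparison": f"{r['group_1']} vs {r['group_2']}",
                "group_1": r["group_1"], "group_2": r["group_2"],
                "statistic": r["z"], "df": float("nan"),
                "p_raw": r["p_raw"], "p_adj": r["p_adj"],
                "mean_rank_1": r["mean_rank_1"], "mean_rank_2": r["mean_rank_2"],
            }
        )
    return rows


def elevated_groups(
    comparisons: pd.DataFrame, analysis: str, control: str, alpha: float = 0.05
) -> set[str]:
    """Groups sitting significantly above ``control`` in one Dunn table.

    A group is flagged elevated when its pairwise comparison against the
    control has adjusted p < ``alpha`` and its mean rank exceeds the
    control's.
    """
    part = comparisons[(comparisons["analysis"] == analysis) & (comparisons["comparison"] != "omnibus")]
    flagged = set()
    for _, r in part.iterrows():
        if r["group_1"] == control and r["p_adj"] < alpha and r["mean_rank_2"] > r["mean_rank_1"]:
            flagged.add(r["group_2"])
        elif r["group_2"] == control and r["p_adj"] < alpha and r["mean_rank_1"] > r["mean_rank_2"]:
            flagged.add(r["group_1"])
    return flagged


def stage_stats(config: PipelineConfig) -> dict[str, Path]:
    """Cohort comparisons, clinical correlation matrix and the power report."""
    outdir = config.outdir
    samples = read_samples(outdir / "samples.tsv")
    serum = read_serum(outdir / "serum.tsv")
    scores = pd.read_csv(outdir / "ifn_scores.tsv", sep="\t", index_col="sample_id")
    groups_of = samples["cohort"].map(_analysis_group)

    rows: list[dict] = []
    # IFN score across cohorts, per specimen
    for specimen in scores["specimen"].unique():
        part = scores[scores["specimen"] == specimen]
        by_group = {
            g: part.loc[groups_of.loc[part.index] == g, "score"]
            for g in groups_of.loc[part.index].unique()
        }
        rows += _comparison_rows(f"ifn_score_{specimen}", by_group, config.adjustment)

    # serum proteins across whole-blood-arm analysis groups
    wb_ids = samples.index[samples["specimen"] == "whole_blood"]
    for column, label in SERUM_MEASURES.items():
        by_group = {
            g: serum.loc[wb_ids[groups_of.loc[wb_ids] == g], column]
            for g in groups_of.loc[wb_ids].unique()
        }
        rows += _comparison_rows(f"serum_{label}", by_group, config.adjustment)

    # treatment-status analysis within AAV (remission / treated active / naive active)
    aav_ids = wb_ids[samples.loc[wb_ids, "cohort"].isin(("aav_r", "aav_a_tx", "aav_a_naive"))]
    if len(aav_ids) > 0:
        for column, label in SERUM_MEASURES.items():
            by_group = {
                c: serum.loc[aav_ids[samples.loc[aav_ids, "cohort"] == c], column]
                for c in ("aav_r", "aav_a_tx", "aav_a_naive")
            }
            by_group = {c: v for c, v in by_group.items() if len(v) > 0}
            if len(by_group) >= 2:
                rows += _comparison_rows(f"aav_treatment_{label}", by_group, config.adjustment)

    comparisons = pd.DataFrame(rows)
    paths = {"group_comparisons": outdir / "group_comparisons.tsv"}
    comparisons.to_csv(paths["group_comparisons"], sep="\t", index=False, float_format="%.6g")

    # Correlation of IFN measures vs clinical severity over AAV (active + remission)
    expr_path = outdir / "expression_whole_blood.tsv"
    corr_rows = []
    if expr_path.exists() and len(aav_ids) > 0:
        expr = pd.read_csv(expr_path, sep="\t", index_col="sample_id")
        panel = config.panels["whole_blood"]
        measures = expr.reindex(columns=panel).join(
            serum.rename(columns=SERUM_MEASURES)[list(SERUM_MEASURES.values())], how="outer"
        )
        aav_measures = measures.loc[measures.index.intersection(aav_ids)]
        clinical = samples.loc[aav_measures.index, CLINICAL_VARIABLES]
        corr = correlation_table(aav_measures, clinical, CLINICAL_VARIABLES)
        corr_rows.append(corr)
    corr_table = (
        pd.concat(corr_rows) if corr_rows
        else pd.DataFrame(columns=["measure", "variable", "r", "p", "n", "strength", "strong_and_significant"])
    )
    paths["correlation_table"] = outdir / "correlation_table.tsv"
    corr_table.to_csv(paths["correlation_table"], sep="\t", index=False, float_format="%.6g")

    # balanced one-way ANOVA power at the mean analysed group size per assay
    power_rows = []
    analysed = ("hc", "dc", "aav_r", "aav_a")
    wb_scored = scores[scores["specimen"] == "whole_blood"].index
    counts_expr = [int((groups_of.loc[wb_scored] == g).sum()) for g in analysed]
    counts_serum = [int((groups_of.loc[wb_ids] == g).sum()) for g in analysed]
    for assay, counts in (("whole_blood_expression", counts_expr), ("serum", counts_serum)):
        counts = [c for c in counts if c > 0]
        if not counts:
            continue
        n_mean = round(sum(counts) / len(counts))
        spec = anova_power(
            k=4, n=n_mean, deltas=POWER_DELTAS, alpha=config.alpha,
            convention=config.power_convention,
        )
        power_rows.append(
            {
                "assay": assay, "k": spec.k, "n_per_group": spec.n,
                "deltas": "/".join(str(d) for d in spec.deltas),
                "alpha": spec.alpha, "noncentrality": spec.noncentrality,
                "power": spec.power,
            }
        )
    paths["power_report"] = outdir / "power_report.tsv"
    pd.DataFrame(power_rows).to_csv(paths["power_report"], sep="\t", index=False, float_format="%.6g")
    return paths


# -- orchestration -----------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write a checksummed manifest; returns the manifest."""
    config.validate()
    config.outdir.mkdir(parents=True, exist_ok=True)
    products: dict[str, Path] = {}
    for stage in (stage_simulate, stage_quantify, stage_score, stage_stats):
        name = stage.__name__.removeprefix("stage_")
        log.info("running stage %s", name)
        try:
            products.update(stage(config))
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    controls = {
        specimen: _analysis_group(hc[0])
        for specimen in config.panels
        if (hc := config.design.healthy_control_cohorts(specimen))
    }
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "controls": controls,
        "files": {key: {"path": str(p), "sha256": _sha256(p)} for key, p in sorted(products.items())},
    }
    manifest_path = config.outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["manifest_path"] = str(manifest_path)
    return manifest


def render_report(manifest: dict | str | Path, path: Path | None = None) -> str:
    """Render a Markdown report from a run manifest's product files.

    Every number comes from the stage TSVs; nothing is recomputed here.
    """
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    files = {key: Path(entry["path"]) for key, entry in manifest["files"].items()}
    for key in ("positivity_summary", "group_comparisons", "correlation_table", "power_report"):
        if key not in files or not files[key].exists():
            raise FileNotFoundError(f"manifest is missing the {key!r} product")

    lines = [
        "# Interferon signature report",
        "",
        f"Pipeline version {manifest['version']}, seed {manifest['seed']}, "
        f"config {manifest['config_hash']}.",
        "",
        "## IFN score positivity by cohort",
        "",
    ]
    summary = pd.read_csv(files["positivity_summary"], sep="\t")
    summary["pct_positive"] = [
        "" if n == 0 else f"{p:.1f}" for n, p in zip(summary["n"], summary["pct_positive"])
    ]
    lines += _md_table(summary)

    comparisons = pd.read_csv(files["group_comparisons"], sep="\t")
    lines += ["", "## Cohort comparisons (Kruskal-Wallis + Dunn post hoc)", ""]
    omnibus = comparisons[comparisons["comparison"] == "omnibus"].copy()
    omnibus["significant"] = omnibus["p_raw"] < 0.05
    lines += _md_table(omnibus[["analysis", "statistic", "df", "p_raw", "significant"]])

    for specimen, control in manifest.get("controls", {}).items():
        flagged = sorted(elevated_groups(comparisons, f"ifn_score_{specimen}", control))
        label = ", ".join(flagged) if flagged else "none"
        lines += ["", f"Cohorts with IFN scores elevated over {control} ({specimen}): {label}"]

    sig = comparisons[(comparisons["comparison"] != "omnibus") & (comparisons["p_adj"] < 0.05)]
    lines += ["", f"Significant post hoc pairs (adjusted p < 0.05): {len(sig)}", ""]
    if len(sig):
        lines += _md_table(sig[["analysis", "comparison", "statistic", "p_adj"]])

    lines += ["", "## Correlation with clinical severity (AAV, active + remission)", ""]
    corr = pd.read_csv(files["correlation_table"], sep="\t")
    if len(corr):
        wide = corr.pivot(index="measure", columns="variable", values="r").round(2)
        lines += _md_table(wide.reset_index())
        flagged = corr[corr["strong_and_significant"]]
        lines += ["", f"Strong and significant correlations: {len(flagged)}", ""]
    else:
        lines += ["(no AAV samples in this run)", ""]

    lines += ["", "## Balanced one-way ANOVA power", ""]
    lines += _md_table(pd.read_csv(files["power_report"], sep="\t"))

    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def _md_table(df: pd.DataFrame) -> list[str]:
    df = df.copy()
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            df[col] = df[col].map(lambda v: f"{v:.4g}" if pd.notna(v) else "")
    header = "| " + " | ".join(str(c) for c in df.columns) + " |"
    sep = "| " + " | ".join("---" for _ in df.columns) + " |"
    body = ["| " + " | ".join(str(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return [header, sep, *body]
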