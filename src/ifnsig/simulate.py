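"""Synthetic cohort generator.

Generates the three study tables — sample metadata, qPCR Ct values and
serum protein concentrations — from a :class:`~ifnsig.design.StudyDesign`.

Generating model for Ct values::

    Ct(gene, sample) = refCt(sample) + baseline_dCt(gene)
                       + shift(gene, cohort(sample)) + eps

with ``refCt(sample) ~ N(ref_ct_mean, ref_ct_sd)`` shared by every gene of
the sample (so it cancels exactly in delta-Ct) and ``eps`` i.i.d. Gaussian
measurement noise per well.  Fold changes are therefore lognormal, matching
the right-skew of real qPCR cohorts.  Serum proteins are lognormal with
per-cohort log-means; clinical covariates are drawn independently of every
interferon measure, which is the planted null for the correlation analysis.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import SERUM_PROTEINS, DesignValidationError, StudyDesign

SAMPLE_COLUMNS = [
    "cohort", "specimen", "treatment_status", "age", "sex", "rin", "rna_yield",
    "bvas", "crp_mg_dl", "creatinine_umol_l", "wbc", "neut", "lymph", "eos", "plt",
]

SERUM_COLUMNS = ["cxcl10_pg_ml", "mcp1_pg_ml", "ccl19_pg_ml"]


def generate_cohort(
    design: StudyDesign, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (samples, ct, serum) tables, each indexed by sample_id.

    Deterministic given ``seed`` (falls back to ``design.seed``).
    """
    design.validate()
    rng = np.random.default_rng(design.seed if seed is None else seed)

    sample_rows: list[dict] = []
    ct_rows: list[dict] = []
    serum_rows: list[dict] = []
    ids: list[str] = []

    for cohort in design.cohorts:
        for i in range(cohort.n):
            sid = f"{cohort.name}-{i + 1:03d}"
            ids.append(sid)
            sample_rows.append(_sample_record(design, cohort, rng))
            ct_rows.append(_ct_record(design, cohort.name, rng))
            serum_rows.append(_serum_record(design, cohort.name, rng))

    samples = pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS, index=pd.Index(ids, name="sample_id"))
    ct = pd.DataFrame(ct_rows, columns=list(design.genes), index=pd.Index(ids, name="sample_id"))
    serum = pd.DataFrame(serum_rows, columns=SERUM_COLUMNS, index=pd.Index(ids, name="sample_id"))
    return samples, ct, serum


def _sample_record(design: StudyDesign, cohort, rng: np.random.Generator) -> dict:
    lo, hi = design.age_range
    rin = round(float(rng.uniform(7.0, 9.8)), 1)
    rna_yield = round(float(np.exp(rng.normal(np.log(100.0), 0.4))), 1)
    if rng.random() < design.qc_fail_fraction:
        # force a QC failure in either metric (sometimes both)
        if rng.random() < 0.5:
            rin = round(float(rng.uniform(2.5, 6.0)), 1)
        else:
            rna_yield = round(float(rng.uniform(5.0, 30.0)), 1)
    if cohort.active:
        b_lo, b_hi = design.bvas_active_range
        bvas = int(rng.integers(b_lo, b_hi + 1))
    else:
        bvas = 0
    wbc = max(float(rng.normal(7.0, 1.8)), 1.0)
    neut_frac = float(np.clip(rng.normal(0.60, 0.07), 0.3, 0.85))
    lymph_frac = float(np.clip(rng.normal(0.30, 0.06), 0.05, 0.6))
    eos_frac = float(np.clip(rng.normal(0.03, 0.015), 0.0, 0.1))
    return {
        "cohort": cohort.name,
        "specimen": cohort.specimen,
        "treatment_status": cohort.treatment_status,
        "age": int(rng.integers(lo, hi + 1)),
        "sex": "male" if rng.random() < design.male_fraction else "female",
        "rin": rin,
        "rna_yield": rna_yield,
        "bvas": bvas,
        "crp_mg_dl": round(float(np.exp(rng.normal(design.crp_log_mean, design.crp_log_sd))), 2),
        "creatinine_umol_l": round(
            float(np.exp(rng.normal(design.creatinine_log_mean, design.creatinine_log_sd))), 1
        ),
        "wbc": round(wbc, 2),
        "neut": round(wbc * neut_frac, 2),
        "lymph": round(wbc * lymph_frac, 2),
        "eos": round(wbc * eos_frac, 3),
        "plt": round(max(float(rng.normal(250.0, 60.0)), 20.0), 0),
    }


def _ct_record(design: StudyDesign, cohort_name: str, rng: np.random.Generator) -> dict:
    ref_ct = rng.normal(design.ref_ct_mean, design.ref_ct_sd)
    row = {}
    for gene in design.genes:
        mean = (
            ref_ct
            + design.baseline_dct.get(gene, 0.0)
            + design.shift(cohort_name, gene)
        )
        row[gene] = float(mean + rng.normal(0.0, design.ct_noise_sd))
    return row


def _serum_record(design: StudyDesign, cohort_name: str, rng: np.random.Generator) -> dict:
    row = {}
    for protein, column in zip(SERUM_PROTEINS, SERUM_COLUMNS):
        params = design.serum_log_mean.get(protein, {"default": 0.0})
        mu = params.get(cohort_name, params["default"])
        sd = design.serum_log_sd.get(protein, 0.5)
        row[column] = float(np.exp(rng.normal(mu, sd)))
    return row


# -- dataset I/O -------------------------------------------------------------

def write_dataset(
    samples: pd.DataFrame, ct: pd.DataFrame, serum: pd.DataFrame, directory: str | Path
) -> dict[str, Path]:
    """Write the three tables as TSV; returns the file paths.

    Missing Ct values are written as empty fields.  All tables must agree on
    sample_id.
    """
    if not (samples.index.equals(ct.index) and samples.index.equals(serum.index)):
        raise ValueError("samples, ct and serum tables disagree on sample_id")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": directory / "samples.tsv",
        "ct": directory / "ct.tsv",
        "serum": directory / "serum.tsv",
    }
    samples.to_csv(paths["samples"], sep="\t")
    ct.to_csv(paths["ct"], sep="\t", float_format="%.6f")
    serum.to_csv(paths["serum"], sep="\t", float_format="%.6f")
    return paths


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def read_ct(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def read_serum(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
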