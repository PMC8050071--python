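"""Composite type I IFN score and healthy-control-calibrated positivity.

The score of a sample is the median fold change of a fixed panel of
interferon-regulated genes (IRGs).  Positivity is called against a
threshold calibrated on healthy controls as ``mean + 2 * SD`` of their
scores, separately for each specimen type (whole blood and PBMC never
share a calibration).  A sample is positive only if its score strictly
exceeds the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import IRG_PANEL_PBMC, IRG_PANEL_WHOLE_BLOOD

log = logging.getLogger(__name__)


class PanelError(ValueError):
    """Panel genes missing from the expression table, or an invalid panel."""


class CalibrationError(ValueError):
    """Not enough healthy-control scores to calibrate a threshold."""


@dataclass(frozen=True)
class IFNPanel:
    """An ordered, duplicate-free set of signature genes."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise PanelError(f"panel {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise PanelError(f"panel {self.name!r} contains duplicate genes")


WHOLE_BLOOD_PANEL = IFNPanel("whole_blood", IRG_PANEL_WHOLE_BLOOD)
PBMC_PANEL = IFNPanel("pbmc", IRG_PANEL_PBMC)

PANELS = {p.name: p for p in (WHOLE_BLOOD_PANEL, PBMC_PANEL)}


def ifn_score(expression: pd.DataFrame, panel: IFNPanel = WHOLE_BLOOD_PANEL) -> pd.DataFrame:
    """Per-sample IFN score: median panel fold change, missing genes excluded.

    Returns a DataFrame indexed by sample_id with columns ``score`` and
    ``n_genes_used``.  Samples with every panel gene missing are excluded
    and logged.
    """
    missing = [g for g in panel.genes if g not in expression.columns]
    if missing:
        raise PanelError(f"panel gene(s) absent from expression table: {', '.join(missing)}")
    sub = expression[list(panel.genes)]
    n_used = sub.notna().sum(axis=1)
    scores = pd.DataFrame({"score": sub.median(axis=1, skipna=True), "n_genes_used": n_used})
    dropped = scores.index[n_used == 0].tolist()
    if dropped:
        log.warning("excluded %d sample(s) with no panel measurements: %s", len(dropped), dropped)
    return scores.loc[n_used > 0]


def calibrate_threshold(hc_scores, ddof: int = 1) -> float:
    """Positivity threshold: mean + 2 * SD of healthy-control scores.

    ``ddof=1`` (sample SD) by default; requires at least 3 scores.
    """
    values = np.asarray(list(hc_scores), dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 3:
        raise CalibrationError(
            f"threshold calibration needs >= 3 healthy-control scores, got {values.size}"
        )
    return float(values.mean() + 2.0 * values.std(ddof=ddof))


def call_positivity(scores: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Label each sample positive iff score > threshold (ties are negative)."""
    if not np.isfinite(threshold):
        raise CalibrationError("positivity threshold must be finite")
    out = scores.copy()
    out["threshold"] = threshold
    out["call"] = np.where(out["score"] > threshold, "positive", "negative")
    return out


def positivity_summary(results: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort positive counts and percentages (one decimal place).

    Denominators are scored-sample counts, never recruited counts.
    """
    cohorts = samples.loc[results.index, "cohort"]
    grouped = results.assign(cohort=cohorts).groupby("cohort", sort=False)
    summary = grouped.agg(
        n=("call", "size"),
        n_positive=("call", lambda c: int((c == "positive").sum())),
    )
    summary["pct_positive"] = (100.0 * summary["n_positive"] / summary["n"]).round(1)
    summary.index.name = "cohort"
    return summary
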