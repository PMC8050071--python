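"""Sample QC filtering and 2^-ddCt relative quantification.

The relative-quantification convention: for each gene,
``dCt = Ct(gene) - Ct(reference gene)`` within a sample, then
``ddCt = dCt - median(dCt over healthy controls)`` and the reported
relative expression is the fold change ``FC = 2^-ddCt``.  A fold change of
1 therefore means "at the healthy-control median"; values above 1 mean
elevated expression.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class ReferenceGeneError(KeyError):
    """The endogenous control gene is absent from the Ct table."""


class MissingHealthyControlError(ValueError):
    """A gene has no non-missing healthy-control delta-Ct to normalise against."""


def qc_filter(
    samples: pd.DataFrame, rin_min: float = 6.0, yield_min: float = 30.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep samples with RIN > ``rin_min`` and RNA yield > ``yield_min``.

    Both inequalities are strict: a sample at exactly RIN 6 or 30 ng/ul is
    rejected.  Samples with a missing QC metric are kept and logged — real
    cohorts retain donors whose QC metadata was never recorded.

    Returns ``(passing, rejections)`` where ``rejections`` has one row per
    excluded sample with a ``reason`` column naming the failed rule.
    """
    rin = pd.to_numeric(samples.get("rin"), errors="coerce")
    rna_yield = pd.to_numeric(samples.get("rna_yield"), errors="coerce")

    fail_rin = rin.notna() & (rin <= rin_min)
    fail_yield = rna_yield.notna() & (rna_yield <= yield_min)
    missing = rin.isna() | rna_yield.isna()

    reasons = []
    for sid in samples.index[fail_rin | fail_yield]:
        parts = []
        if fail_rin.loc[sid]:
            parts.append(f"rin {rin.loc[sid]:g} <= {rin_min:g}")
        if fail_yield.loc[sid]:
            parts.append(f"rna_yield {rna_yield.loc[sid]:g} <= {yield_min:g}")
        reasons.append({"sample_id": sid, "reason": "; ".join(parts)})
    rejections = pd.DataFrame(reasons, columns=["sample_id", "reason"]).set_index("sample_id")

    n_missing = int(missing.sum())
    if n_missing:
        log.warning("%d sample(s) kept with missing QC metadata", n_missing)
    passing = samples.loc[~(fail_rin | fail_yield)]
    return passing, rejections


def delta_ct(ct: pd.DataFrame, reference_gene: str = "RPL27") -> pd.DataFrame:
    """Per-sample delta-Ct: ``Ct(gene) - Ct(reference)`` for every gene.

    The reference gene's own column is identically 0 where its Ct is
    present.  A sample missing the reference Ct gets all-missing delta-Ct;
    a missing target Ct propagates as missing.
    """
    if reference_gene not in ct.columns:
        raise ReferenceGeneError(
            f"reference gene {reference_gene!r} not found in Ct table columns"
        )
    return ct.sub(ct[reference_gene], axis=0)


def relative_expression(
    dct: pd.DataFrame, hc_ids: Iterable[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Fold change 2^-ddCt, normalised to the healthy-control median delta-Ct.

    ``hc_ids`` selects the calibration samples.  Per gene, the HC median is
    computed over non-missing values; a gene with no HC values at all is an
    error.  Returns ``(expression, hc_median_dct)``.
    """
    hc_ids = [s for s in hc_ids if s in dct.index]
    if not hc_ids:
        raise MissingHealthyControlError("no healthy-control samples present in delta-Ct table")
    hc_median = dct.loc[hc_ids].median(axis=0, skipna=True)
    empty = hc_median.index[hc_median.isna()].tolist()
    if empty:
        raise MissingHealthyControlError(
            f"gene(s) with no healthy-control delta-Ct values: {', '.join(empty)}"
        )
    ddct = dct.sub(hc_median, axis=1)
    fc = np.power(2.0, -ddct)
    hc_median.name = "hc_median_dct"
    return fc, hc_median
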