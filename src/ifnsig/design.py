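"""Study-design description for the synthetic multi-cohort simulator.

A :class:`StudyDesign` captures everything the generator needs: the cohorts
(name, size, specimen type, treatment status, disease activity), the qPCR
gene panel with its endogenous control, per-gene baseline expression levels
(as delta-Ct relative to the control gene), the planted per-cohort
expression effects (delta-delta-Ct shifts, in cycles: a *negative* shift
means *elevated* expression, since fold change is 2^-ddCt), serum-protein
lognormal parameters, and the clinical-covariate distributions.

The default design mirrors a multi-cohort vasculitis study: healthy and
disease controls, ANCA-associated vasculitis (AAV) in remission and in
active disease (the active arm split into treated and treatment-naive),
plus two type I interferonopathy positive-control cohorts — SLE sampled as
whole blood and primary Sjogren's syndrome (pSS) sampled as PBMC, each with
its own small control arm.  Planted effects: interferon-regulated genes
(IRGs) elevated in SLE and pSS only; MMP8/ANXA3 elevated in active AAV
only; serum CXCL10 elevated in treatment-naive active AAV only; clinical
covariates independent of every interferon measure within AAV.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

REFERENCE_GENE = "RPL27"

#: Seven-gene whole-blood interferon signature panel.
IRG_PANEL_WHOLE_BLOOD = ("ISG15", "SIGLEC1", "STAT1", "RSAD2", "IFI27", "IFI44L", "IFIT1")
#: Six-gene PBMC signature (IFIT1 dropped).
IRG_PANEL_PBMC = ("ISG15", "SIGLEC1", "STAT1", "RSAD2", "IFI27", "IFI44L")

NEUTROPHIL_MARKERS = ("MMP8", "ANXA3")

SERUM_PROTEINS = ("cxcl10", "mcp1", "ccl19")

SPECIMENS = ("whole_blood", "pbmc")
TREATMENT_STATUSES = ("treated", "naive", "not_applicable")


class DesignValidationError(ValueError):
    """A study-design field violates its constraints; the message names it."""


@dataclass
class CohortSpec:
    """One cohort arm: how many samples, from what specimen, and its clinical state."""

    name: str
    n: int
    specimen: str = "whole_blood"
    treatment_status: str = "not_applicable"
    active: bool = False          # active disease: BVAS drawn from the active range
    healthy_control: bool = False  # calibration cohort for its specimen type


@dataclass
class StudyDesign:
    cohorts: list[CohortSpec]
    genes: list[str]
    reference_gene: str = REFERENCE_GENE
    #: per-gene baseline delta-Ct (cycles above the reference gene), reference = 0
    baseline_dct: dict[str, float] = field(default_factory=dict)
    #: cohort name -> gene -> delta-delta-Ct shift (cycles; negative = elevated)
    shifts: dict[str, dict[str, float]] = field(default_factory=dict)
    ct_noise_sd: float = 1.0
    ref_ct_mean: float = 20.0
    ref_ct_sd: float = 0.5
    #: protein -> {"default": log-mean, <cohort>: override}; pg/ml scale
    serum_log_mean: dict[str, dict[str, float]] = field(default_factory=dict)
    serum_log_sd: dict[str, float] = field(default_factory=dict)
    bvas_active_range: tuple[int, int] = (3, 32)
    crp_log_mean: float = math.log(8.0)
    crp_log_sd: float = 0.9
    creatinine_log_mean: float = math.log(110.0)
    creatinine_log_sd: float = 0.45
    age_range: tuple[int, int] = (16, 87)
    male_fraction: float = 0.4
    #: fraction of samples generated to fail RNA quality control
    qc_fail_fraction: float = 0.05
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if not self.cohorts:
            raise DesignValidationError("cohorts: at least one cohort required")
        seen: set[str] = set()
        for c in self.cohorts:
            if c.name in seen:
                raise DesignValidationError(f"cohorts: duplicate cohort name {c.name!r}")
            seen.add(c.name)
            if not isinstance(c.n, int) or c.n < 0:
                raise DesignValidationError(f"cohorts[{c.name}].n: must be a non-negative integer")
            if c.specimen not in SPECIMENS:
                raise DesignValidationError(f"cohorts[{c.name}].specimen: {c.specimen!r} not in {SPECIMENS}")
            if c.treatment_status not in TREATMENT_STATUSES:
                raise DesignValidationError(
                    f"cohorts[{c.name}].treatment_status: {c.treatment_status!r} not in {TREATMENT_STATUSES}"
                )
        if self.reference_gene not in self.genes:
            raise DesignValidationError(
                f"genes: reference gene {self.reference_gene!r} missing from panel"
            )
        if len(set(self.genes)) != len(self.genes):
            raise DesignValidationError("genes: duplicate gene symbols")
        if not (self.ct_noise_sd > 0) or not math.isfinite(self.ct_noise_sd):
            raise DesignValidationError("ct_noise_sd: must be finite and > 0")
        for name, value in (
            ("ref_ct_mean", self.ref_ct_mean),
            ("ref_ct_sd", self.ref_ct_sd),
            ("crp_log_mean", self.crp_log_mean),
            ("crp_log_sd", self.crp_log_sd),
            ("creatinine_log_mean", self.creatinine_log_mean),
            ("creatinine_log_sd", self.creatinine_log_sd),
        ):
            if not math.isfinite(value):
                raise DesignValidationError(f"{name}: must be finite")
        for gene, dct in self.baseline_dct.items():
            if gene not in self.genes:
                raise DesignValidationError(f"baseline_dct: unknown gene {gene!r}")
            if not math.isfinite(dct):
                raise DesignValidationError(f"baseline_dct[{gene}]: must be finite")
        for cohort, gene_shifts in self.shifts.items():
            if cohort not in seen:
                raise DesignValidationError(f"shifts: unknown cohort {cohort!r}")
            for gene, shift in gene_shifts.items():
                if gene not in self.genes:
                    raise DesignValidationError(f"shifts[{cohort}]: unknown gene {gene!r}")
                if not math.isfinite(shift):
                    raise DesignValidationError(f"shifts[{cohort}][{gene}]: must be finite")
                if gene == self.reference_gene and shift != 0:
                    raise DesignValidationError(
                        f"shifts[{cohort}][{gene}]: reference gene shift must be 0"
                    )
        for protein, params in self.serum_log_mean.items():
            for key, mu in params.items():
                if key != "default" and key not in seen:
                    raise DesignValidationError(f"serum_log_mean[{protein}]: unknown cohort {key!r}")
                if not math.isfinite(mu):
                    raise DesignValidationError(f"serum_log_mean[{protein}][{key}]: must be finite")
        if not (0 <= self.qc_fail_fraction < 1):
            raise DesignValidationError("qc_fail_fraction: must be in [0, 1)")
        if not (0 <= self.male_fraction <= 1):
            raise DesignValidationError("male_fraction: must be in [0, 1]")
        lo, hi = self.bvas_active_range
        if not (3 <= lo <= hi):
            raise DesignValidationError("bvas_active_range: active disease requires BVAS >= 3")

    # -- convenience --------------------------------------------------------

    def shift(self, cohort: str, gene: str) -> float:
        return self.shifts.get(cohort, {}).get(gene, 0.0)

    def cohort(self, name: str) -> CohortSpec:
        for c in self.cohorts:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def n_total(self) -> int:
        return sum(c.n for c in self.cohorts)

    def healthy_control_cohorts(self, specimen: str) -> list[str]:
        return [c.name for c in self.cohorts if c.healthy_control and c.specimen == specimen]

    def restrict_cohorts(self, cohorts: list[CohortSpec]) -> "StudyDesign":
        """Replace the cohort list, dropping effects aimed at absent cohorts."""
        names = {c.name for c in cohorts}
        self.cohorts = cohorts
        self.shifts = {c: dict(s) for c, s in self.shifts.items() if c in names}
        self.serum_log_mean = {
            p: {k: v for k, v in params.items() if k == "default" or k in names}
            for p, params in self.serum_log_mean.items()
        }
        return self

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohorts"] = [dataclasses.asdict(c) for c in self.cohorts]
        d["bvas_active_range"] = list(self.bvas_active_range)
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        d = dict(d)
        d["cohorts"] = [CohortSpec(**c) for c in d["cohorts"]]
        for key in ("bvas_active_range", "age_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyDesign":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_design(seed: int = 0) -> StudyDesign:
    """The default multi-cohort design.

    Cohort sizes follow the per-assay arm sizes of a 217-participant study:
    the whole-blood arm (HC 62, DC 29, AAV remission 27, active treated 31,
    active naive 10, SLE 19) and the PBMC arm (HC 5, DC 4, AAV remission 6,
    AAV active 6, pSS 9).  Serum proteins are generated for every sample;
    healthy-control CXCL10 is centred so its median is ~93 pg/ml.
    """
    irgs = IRG_PANEL_WHOLE_BLOOD
    genes = [REFERENCE_GENE, *irgs, *NEUTROPHIL_MARKERS]
    cohorts = [
        CohortSpec("hc", 62, "whole_blood", healthy_control=True),
        CohortSpec("dc", 29, "whole_blood"),
        CohortSpec("aav_r", 27, "whole_blood", treatment_status="treated"),
        CohortSpec("aav_a_tx", 31, "whole_blood", treatment_status="treated", active=True),
        CohortSpec("aav_a_naive", 10, "whole_blood", treatment_status="naive", active=True),
        CohortSpec("sle", 19, "whole_blood"),
        CohortSpec("hc_pbmc", 5, "pbmc", healthy_control=True),
        CohortSpec("dc_pbmc", 4, "pbmc"),
        CohortSpec("aav_r_pbmc", 6, "pbmc", treatment_status="treated"),
        CohortSpec("aav_a_pbmc", 6, "pbmc", treatment_status="treated", active=True),
        CohortSpec("pss", 9, "pbmc"),
    ]
    baseline = {
        REFERENCE_GENE: 0.0,
        "ISG15": 5.0, "SIGLEC1": 8.0, "STAT1": 4.0, "RSAD2": 7.0,
        "IFI27": 6.0, "IFI44L": 7.5, "IFIT1": 6.5, "MMP8": 9.0, "ANXA3": 8.5,
    }
    shifts = {
        "sle": {g: -3.0 for g in irgs},
        "pss": {g: -3.0 for g in IRG_PANEL_PBMC},
        "aav_a_tx": {"MMP8": -1.5, "ANXA3": -1.5},
        "aav_a_naive": {"MMP8": -1.5, "ANXA3": -1.5},
    }
    serum_log_mean = {
        # HC median ~93 pg/ml; elevation restricted to treatment-naive active AAV
        "cxcl10": {"default": math.log(93.0), "aav_a_naive": math.log(93.0) + 0.9},
        "mcp1": {"default": math.log(200.0)},
        "ccl19": {"default": math.log(150.0)},
    }
    serum_log_sd = {"cxcl10": 0.5, "mcp1": 0.4, "ccl19": 0.4}
    return StudyDesign(
        cohorts=cohorts,
        genes=genes,
        baseline_dct=baseline,
        shifts=shifts,
        serum_log_mean=serum_log_mean,
        serum_log_sd=serum_log_sd,
        seed=seed,
    )


def null_design(seed: int = 0, **overrides) -> StudyDesign:
    """Default design with every expression and serum effect removed."""
    d = default_design(seed=seed)
    d.shifts = {}
    for protein in d.serum_log_mean:
        d.serum_log_mean[protein] = {"default": d.serum_log_mean[protein]["default"]}
    for key, value in overrides.items():
        setattr(d, key, value)
    return d
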