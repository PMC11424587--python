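"""Synthetic accumulating literatures with known truth.

Emulates the statistical structure the sequential meta-analysis assumes: a
control arm in Hardy-Weinberg equilibrium at a given minor-allele frequency,
a log-additive (allele-model) case/control odds ratio, optional
between-study heterogeneity as a normal shift of each study's log odds
ratio, and a publication-ordered sequence of studies of configurable sizes.
Not emulated (deliberately): linkage disequilibrium, genotyping error,
covariates, and publication bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .records import GenotypeCounts, StudyRecord


def derive_case_allele_freq(control_maf: float, true_or: float) -> float:
    """Case minor-allele frequency implied by an allele-model odds ratio.

    Inverts ``OR = (p1/(1-p1)) / (p2/(1-p2))`` for ``p1``:
    ``p1 = OR * p2 / (1 + p2 * (OR - 1))``.  With ``OR = 1`` the control
    frequency is returned unchanged.
    """
    if not 0 < control_maf < 1:
        raise ValueError(f"control_maf must lie in (0, 1), got {control_maf}")
    if not true_or > 0:
        raise ValueError(f"true_or must be positive, got {true_or}")
    return true_or * control_maf / (1.0 + control_maf * (true_or - 1.0))


def _hwe_probs(p: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities (mm, Mm, MM) at allele freq p."""
    return np.array([p * p, 2.0 * p * (1.0 - p), (1.0 - p) * (1.0 - p)])


@dataclass(frozen=True)
class ScenarioConfig:
    """One synthetic literature: a (snp, ethnicity) pair with known truth.

    ``true_or`` is the allele-model odds ratio for the minor allele;
    ``tau`` the between-study standard deviation of the log odds ratio;
    ``case_sizes``/``control_sizes`` give persons per arm for each of the
    ``n_studies`` studies, published one per year from ``start_year``.
    """

    snp_label: str
    ethnicity: str
    control_maf: float
    true_or: float
    tau: float
    n_studies: int
    case_sizes: tuple
    control_sizes: tuple
    start_year: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.control_maf < 1:
            raise ValueError("control_maf must lie in (0, 1)")
        if not self.true_or > 0:
            raise ValueError("true_or must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.n_studies < 0:
            raise ValueError("n_studies must be non-negative")
        object.__setattr__(self, "case_sizes", tuple(int(n) for n in self.case_sizes))
        object.__setattr__(self, "control_sizes", tuple(int(n) for n in self.control_sizes))
        if len(self.case_sizes) != self.n_studies or len(self.control_sizes) != self.n_studies:
            raise ValueError("case_sizes and control_sizes must each have n_studies entries")
        if any(n <= 0 for n in self.case_sizes + self.control_sizes):
            raise ValueError("per-study arm sizes must be positive")


def _study_rng(cfg: ScenarioConfig, study_index: int) -> np.random.Generator:
    """Deterministic per-study stream derived from the scenario root seed."""
    return np.random.default_rng(
        np.random.SeedSequence(cfg.seed).spawn(cfg.n_studies)[study_index]
    )


def simulate_study(
    cfg: ScenarioConfig, study_index: int, rng: np.random.Generator
) -> StudyRecord:
    """Draw one case-control study of the scenario's SNP.

    The study's own log odds ratio is ``Normal(ln(true_or), tau^2)``; its
    case minor-allele frequency follows from that via
    :func:`derive_case_allele_freq`.  Genotype counts are trinomial draws
    with Hardy-Weinberg frequencies in both arms (controls at
    ``control_maf``, cases at the study's case frequency), so the allele
    model holds on expectation while records stay in genotype form.
    """
    if not 0 <= study_index < cfg.n_studies:
        raise IndexError(f"study_index {study_index} out of range for {cfg.n_studies} studies")
    log_or = rng.normal(math.log(cfg.true_or), cfg.tau)
    p_case = derive_case_allele_freq(cfg.control_maf, math.exp(log_or))
    ctrl = rng.multinomial(cfg.control_sizes[study_index], _hwe_probs(cfg.control_maf))
    case = rng.multinomial(cfg.case_sizes[study_index], _hwe_probs(p_case))
    return StudyRecord(
        study_id=f"{cfg.snp_label}_{cfg.ethnicity}_s{study_index + 1:03d}",
        year=cfg.start_year + study_index,
        ethnicity=cfg.ethnicity,
        snp_label=cfg.snp_label,
        cases=GenotypeCounts(int(case[0]), int(case[1]), int(case[2])),
        controls=GenotypeCounts(int(ctrl[0]), int(ctrl[1]), int(ctrl[2])),
    )


def simulate_literature(cfg: ScenarioConfig) -> list[StudyRecord]:
    """All studies of a scenario, in strictly increasing year order.

    Each study draws from its own stream spawned from the root seed, so the
    first k records do not depend on whether later studies are generated.
    """
    return [
        simulate_study(cfg, i, _study_rng(cfg, i)) for i in range(cfg.n_studies)
    ]
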