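"""Domain records shared across the pipeline.

A :class:`StudyRecord` is one published case-control study's genotype
distribution for one SNP: person counts for the three genotypes
(minor-homozygote mm, heterozygote Mm, major-homozygote MM) in cases and in
controls, plus publication-year and ethnicity metadata.  The minor allele is
defined by the external reference frequency table, not re-derived per study,
so effect directions cannot flip between studies of the same locus.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GenotypeCounts:
    """Person counts for the three genotypes of a biallelic SNP.

    ``n_mm`` minor-allele homozygotes, ``n_Mm`` heterozygotes, ``n_MM``
    major-allele homozygotes.
    """

    n_mm: int
    n_Mm: int
    n_MM: int

    def __post_init__(self) -> None:
        for name in ("n_mm", "n_Mm", "n_MM"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("genotype counts must describe at least one person")

    @property
    def total(self) -> int:
        return self.n_mm + self.n_Mm + self.n_MM

    @property
    def minor_alleles(self) -> int:
        return 2 * self.n_mm + self.n_Mm

    @property
    def major_alleles(self) -> int:
        return 2 * self.n_MM + self.n_Mm


@dataclass(frozen=True)
class StudyRecord:
    """One case-control study of one SNP in one ethnicity stratum."""

    study_id: str
    year: int
    ethnicity: str
    snp_label: str
    cases: GenotypeCounts
    controls: GenotypeCounts

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValueError("study_id must be non-empty")
        if not self.ethnicity:
            raise ValueError("ethnicity must be non-empty")
        if not self.snp_label:
            raise ValueError("snp_label must be non-empty")
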