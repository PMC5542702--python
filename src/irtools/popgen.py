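"""Target-site (kdr) genotype analytics.

Knockdown resistance arises from point mutations in the voltage-gated
sodium channel gene (Vgsc); the loci analysed here are V1016I and F1534C.
Individuals are the sampling unit: inputs are genotype counts (wild-type
homozygote, heterozygote, mutant homozygote) per locus, population and
phenotype class; allele counts are derived, never input.

Both the between-population frequency comparison and the
genotype-phenotype association default to genotype-based 2x3 Fisher exact
tests (an allele-based 2x2 variant is available).  A fixed locus (allele
frequency 1) is reported with a fixation flag and never tested — there is
no variance to test against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .stats import TestResult

__all__ = [
    "GenotypeCounts",
    "AlleleFrequencyResult",
    "allele_frequency",
    "compare_population_frequencies",
    "association_test",
    "counts_from_individuals",
]

GENOTYPE_COLUMNS = ["locus", "population", "phenotype_class",
                    "n_wildtype_hom", "n_het", "n_mutant_hom"]


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of the three genotypes at a biallelic locus in one stratum."""

    locus: str
    population: str
    phenotype_class: str  # e.g. "cyfluthrin resistant" or "all"
    n_wildtype_hom: int
    n_het: int
    n_mutant_hom: int

    def __post_init__(self) -> None:
        for name in ("n_wildtype_hom", "n_het", "n_mutant_hom"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.n_wildtype_hom + self.n_het + self.n_mutant_hom

    def as_row(self) -> list:
        return [self.n_wildtype_hom, self.n_het, self.n_mutant_hom]

    def allele_counts(self) -> tuple:
        """(wild-type, mutant) allele counts among the 2N alleles."""
        mut = self.n_het + 2 * self.n_mutant_hom
        return 2 * self.n - mut, mut


@dataclass(frozen=True)
class AlleleFrequencyResult:
    """Relative frequency of the mutant allele in one stratum."""

    locus: str
    stratum: str
    frequency: float
    n_alleles: int
    fixed: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must be in [0, 1]")


def allele_frequency(counts: GenotypeCounts) -> AlleleFrequencyResult:
    """Mutant-allele frequency (n_het + 2*n_mutant_hom) / 2N."""
    if counts.n == 0:
        raise ValueError("no individuals in stratum")
    _, mut = counts.allele_counts()
    freq = mut / (2 * counts.n)
    return AlleleFrequencyResult(
        locus=counts.locus,
        stratum=f"{counts.population}/{counts.phenotype_class}",
        frequency=freq,
        n_alleles=2 * counts.n,
        fixed=freq == 1.0,
    )


def _two_strata_test(a: GenotypeCounts, b: GenotypeCounts, method: str) -> TestResult:
    if a.n == 0 or b.n == 0:
        raise ValueError("both strata need at least one individual")
    if method == "genotype":
        table = np.array([a.as_row(), b.as_row()], dtype=np.int64)
        # genotype categories unobserved in both strata carry no information
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] < 2:
            # only one genotype present anywhere: distributions are identical
            return TestResult(statistic=float("nan"), p_value=1.0,
                              method="fisher_exact_degenerate",
                              n=int(table.sum()), degenerate=True)
        return stats.fisher_exact(table)
    if method == "allele":
        table = np.array([a.allele_counts(), b.allele_counts()], dtype=np.int64)
        if (table.sum(axis=0) == 0).any():
            return TestResult(statistic=float("nan"), p_value=1.0,
                              method="fisher_exact_degenerate",
                              n=int(table.sum()), degenerate=True)
        return stats.fisher_exact(table)
    raise ValueError(f"unknown method {method!r} (use 'genotype' or 'allele')")


def compare_population_frequencies(a: GenotypeCounts, b: GenotypeCounts,
                                   method: str = "genotype") -> TestResult:
    """Exact test of genotype (or allele) distributions between populations."""
    if a.locus != b.locus:
        raise ValueError(f"locus mismatch: {a.locus!r} vs {b.locus!r}")
    return _two_strata_test(a, b, method)


def association_test(resistant: GenotypeCounts, susceptible: GenotypeCounts,
                     method: str = "genotype") -> dict:
    """Genotype-phenotype association at one locus.

    Returns the exact-test result together with the per-class mutant-allele
    frequencies.  Refuses a fixed locus (no variation to associate).
    """
    if resistant.locus != susceptible.locus:
        raise ValueError("phenotype classes must share a locus")
    f_res = allele_frequency(resistant)
    f_sus = allele_frequency(susceptible)
    if f_res.fixed and f_sus.fixed:
        raise ValueError(
            f"{resistant.locus}: mutant allele fixed in both classes; "
            "association testing is not possible")
    result = _two_strata_test(resistant, susceptible, method)
    return {
        "locus": resistant.locus,
        "test": result,
        "freq_resistant": f_res,
        "freq_susceptible": f_sus,
    }


def counts_from_individuals(individuals: pd.DataFrame,
                            phenotype_class: str | None = None) -> GenotypeCounts:
    """Aggregate a per-individual genotype table (one locus, one population)
    into :class:`GenotypeCounts`, optionally restricted to a phenotype."""
    df = individuals
    for col in ("locus", "population", "genotype"):
        if col not in df.columns:
            raise ValueError(f"individuals table missing column {col!r}")
    if df["locus"].nunique() != 1 or df["population"].nunique() != 1:
        raise ValueError("pass one locus and one population at a time")
    if phenotype_class is not None:
        df = df[df["phenotype"] == phenotype_class]
    counts = df["genotype"].value_counts()
    return GenotypeCounts(
        locus=df["locus"].iloc[0] if len(df) else individuals["locus"].iloc[0],
        population=individuals["population"].iloc[0],
        phenotype_class=phenotype_class or "all",
        n_wildtype_hom=int(counts.get("wildtype_hom", 0)),
        n_het=int(counts.get("het", 0)),
        n_mutant_hom=int(counts.get("mutant_hom", 0)),
    )
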