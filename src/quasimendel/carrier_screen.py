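"""Single-allele screening statistics for a candidate variant.

Carrier tallies, prevalence arithmetic, Hardy-Weinberg expected genotype
counts, fold enrichment, and the pairwise group comparisons (e.g. solved
cases vs unsolved cases vs controls) used to distinguish a diallelic from a
triallelic mode of action.  All contingency tables are allele-based: a group
of n genotyped diploids contributes 2n alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .cohort_sim import GenotypeMatrix
from .exact_stats import FisherResult, Table2x2, fisher_test, fold_enrichment

__all__ = [
    "CarrierTally",
    "GroupComparison",
    "tally",
    "prevalence",
    "hwe_expected",
    "compare_groups",
]


@dataclass(frozen=True)
class CarrierTally:
    """Genotype tallies for one allele in one group of individuals."""

    n_individuals: int
    n_het: int
    n_hom: int

    def __post_init__(self) -> None:
        if min(self.n_individuals, self.n_het, self.n_hom) < 0:
            raise ValueError("tallies must be non-negative")
        if self.n_het + self.n_hom > self.n_individuals:
            raise ValueError("carriers cannot outnumber individuals")

    @property
    def n_alleles(self) -> int:
        return self.n_het + 2 * self.n_hom

    @property
    def n_carriers(self) -> int:
        return self.n_het + self.n_hom

    @property
    def allele_freq(self) -> float:
        if self.n_individuals == 0:
            raise ValueError("empty tally has no allele frequency")
        return self.n_alleles / (2 * self.n_individuals)


@dataclass(frozen=True)
class GroupComparison:
    """One pairwise allele-count comparison between two groups."""

    group1: str
    group2: str
    table: Table2x2
    result: FisherResult
    fold: float


def tally(g: GenotypeMatrix, allele_id: str) -> CarrierTally:
    """Carrier tally of one variant; missing calls drop the individual."""
    col = g.column(allele_id)
    obs = col >= 0
    return CarrierTally(
        n_individuals=int(obs.sum()),
        n_het=int((col == 1).sum()),
        n_hom=int((col == 2).sum()),
    )


def prevalence(t: CarrierTally, mode: str = "homozygote_fraction") -> float:
    """Single-allele disease contribution in a patient cohort.

    ``homozygote_fraction`` is the share of patients homozygous for the
    allele (patients fully explained by it); ``allele_fraction`` is its
    allele frequency in the cohort.
    """
    if t.n_individuals == 0:
        raise ValueError("empty tally")
    if mode == "homozygote_fraction":
        return t.n_hom / t.n_individuals
    if mode == "allele_fraction":
        return t.allele_freq
    raise ValueError(f"unknown prevalence mode {mode!r}")


def hwe_expected(freq: float, n: int) -> tuple[float, float, float]:
    """Expected (hom-ref, het, hom-alt) counts in n diploids under HWE."""
    if not (0.0 <= freq <= 1.0):
        raise ValueError("allele frequency must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    q = freq
    return (n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2)


def compare_groups(tallies: dict[str, CarrierTally],
                   level: float = 0.95) -> list[GroupComparison]:
    """All pairwise allele-count exact tests between the given groups.

    Each comparison builds the alt/ref allele table (group1 in the first
    row), with Fisher p, CMLE odds ratio, exact CI and fold enrichment
    (group1 frequency over group2 frequency, infinite when group2 carries
    no alt allele).
    """
    if len(tallies) < 2:
        raise ValueError("need at least two groups")
    for name, t in tallies.items():
        if t.n_individuals == 0:
            raise ValueError(f"group {name!r} has no genotyped individuals")
    out = []
    for (n1, t1), (n2, t2) in combinations(tallies.items(), 2):
        table = Table2x2(
            t1.n_alleles, 2 * t1.n_individuals - t1.n_alleles,
            t2.n_alleles, 2 * t2.n_individuals - t2.n_alleles,
        )
        fold = (
            fold_enrichment(t1.allele_freq, t2.allele_freq)
            if t2.allele_freq > 0 else float("inf")
        )
        out.append(GroupComparison(n1, n2, table, fisher_test(table, level), fold))
    return out
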