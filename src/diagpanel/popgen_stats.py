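"""Heterozygosity and inbreeding-coefficient (F_IS) estimation.

F_IS measures the within-population heterozygote deficit: F_IS = 1 - Ho/He,
with Ho the observed fraction of heterozygotes among called individuals and
He = 2p(1-p) the Hardy-Weinberg expectation at the observed allele
frequency. Marine bivalves routinely show F_IS > 0 (null alleles, spatial
or temporal Wahlund effects, partial inbreeding), so the module also
provides a one-sided permutation test of the deficit: alleles are shuffled
among called individuals within each locus, which destroys the
within-individual allele correlation while preserving allele frequencies
and call patterns.

The global estimator is ratio-of-sums, fis_global = 1 - sum(Ho)/sum(He)
over loci with He > 0. It is deliberately simple (not Weir-Cockerham) and
is what the permutation test re-computes on each shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import HET, HOM_ALT, MISSING, GenotypeMatrix, Population

__all__ = [
    "fis_per_locus",
    "fis_global",
    "fis_permutation_test",
    "FisReport",
    "fis_report",
]


def _ho_he_arrays(
    gm: GenotypeMatrix, population: Population
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (n_called, Ho, He) arrays for one population."""
    sub = gm.calls[gm.population_mask(population)]
    n_called = np.count_nonzero(sub != MISSING, axis=0).astype(float)
    n_het = np.count_nonzero(sub == HET, axis=0)
    n_alt = np.count_nonzero(sub == HOM_ALT, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 1.0 - (2 * n_alt + n_het) / (2 * n_called)
        ho = n_het / n_called
    he = 2.0 * p * (1.0 - p)
    return n_called, ho, he


def fis_per_locus(
    gm: GenotypeMatrix, locus_id: str, population: Population
) -> tuple[float, float, float]:
    """(Ho, He, fis) at one locus; fis is NaN when He = 0 (monomorphic).

    Requires at least one called individual in the population.
    """
    j = gm.locus_index(locus_id)
    n_called, ho, he = _ho_he_arrays(gm, population)
    if n_called[j] == 0:
        raise ValueError(
            f"locus {locus_id!r}: no called individuals in {population.value}"
        )
    ho_j, he_j = float(ho[j]), float(he[j])
    fis = 1.0 - ho_j / he_j if he_j > 0 else float("nan")
    return ho_j, he_j, fis


def fis_global(gm: GenotypeMatrix, population: Population) -> float:
    """Ratio-of-sums global F_IS: 1 - sum(Ho)/sum(He) over loci with He > 0."""
    n_called, ho, he = _ho_he_arrays(gm, population)
    usable = (n_called > 0) & (he > 0)
    if not usable.any():
        raise ValueError(f"no polymorphic loci with calls in {population.value}")
    return float(1.0 - ho[usable].sum() / he[usable].sum())


def fis_permutation_test(
    gm: GenotypeMatrix,
    population: Population,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """One-sided permutation p-value for a heterozygote deficit (F_IS > 0).

    For each locus the 2n alleles of the called individuals are randomly
    re-paired into genotypes; He is unchanged by construction, Ho is
    recomputed, and the global ratio-of-sums F_IS of each replicate forms
    the null distribution. p = (1 + #{null >= observed}) / (1 + n_perm),
    so p is never exactly zero ("P = 0" is reported as < 1/(1+n_perm)).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a meaningful p-value")
    rng = np.random.default_rng(seed)
    sub = gm.calls[gm.population_mask(population)]
    n_called, ho, he = _ho_he_arrays(gm, population)
    usable = np.flatnonzero((n_called > 0) & (he > 0))
    if usable.size == 0:
        raise ValueError(f"no polymorphic loci with calls in {population.value}")
    observed = 1.0 - ho[usable].sum() / he[usable].sum()

    ho_null = np.zeros((n_perm, usable.size))
    for k, j in enumerate(usable):
        col = sub[:, j]
        called = col[col != MISSING]
        n = called.size
        # allele vector: 0 = ref, 1 = alt; HET contributes one of each
        n_alt_alleles = int(
            2 * np.count_nonzero(called == HOM_ALT) + np.count_nonzero(called == HET)
        )
        alleles = np.zeros(2 * n, dtype=np.int8)
        alleles[:n_alt_alleles] = 1
        pool = np.tile(alleles, (n_perm, 1))
        rng.permuted(pool, axis=1, out=pool)
        het = pool[:, 0::2] != pool[:, 1::2]
        ho_null[:, k] = het.sum(axis=1) / n
    fis_null = 1.0 - ho_null.sum(axis=1) / he[usable].sum()
    return float((1 + np.count_nonzero(fis_null >= observed)) / (1 + n_perm))


@dataclass
class FisReport:
    """Per-locus and global F_IS for one population, with the permutation p.

    ``per_locus`` maps locus_id -> (Ho, He, fis); fis is NaN where He = 0
    and such loci are excluded from the global estimate (``n_loci_excluded``
    reports how many).
    """

    population: Population
    per_locus: dict[str, tuple[float, float, float]]
    fis_global: float
    n_loci_used: int
    n_loci_excluded: int
    n_perm: int
    p_value: float
    seed: int

    @property
    def p_value_text(self) -> str:
        floor = 1.0 / (1 + self.n_perm)
        if self.p_value <= floor:
            return f"< {floor:.3g}"
        return f"{self.p_value:.4g}"


def fis_report(
    gm: GenotypeMatrix,
    population: Population,
    n_perm: int = 999,
    seed: int = 0,
) -> FisReport:
    """Full per-locus + global F_IS report with the permutation test."""
    n_called, ho, he = _ho_he_arrays(gm, population)
    per_locus = {}
    for j, locus in enumerate(gm.loci):
        if n_called[j] == 0:
            per_locus[locus.locus_id] = (float("nan"), float("nan"), float("nan"))
        else:
            fis = 1.0 - ho[j] / he[j] if he[j] > 0 else float("nan")
            per_locus[locus.locus_id] = (float(ho[j]), float(he[j]), float(fis))
    usable = (n_called > 0) & (he > 0)
    return FisReport(
        population=population,
        per_locus=per_locus,
        fis_global=fis_global(gm, population),
        n_loci_used=int(usable.sum()),
        n_loci_excluded=int((~usable).sum()),
        n_perm=n_perm,
        p_value=fis_permutation_test(gm, population, n_perm=n_perm, seed=seed),
        seed=seed,
    )
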