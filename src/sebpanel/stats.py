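"""Per-locus diversity statistics and exact/permutation tests.

The summary statistics follow the conventions of standard population
genetics packages (GenAlEx-style): observed heterozygosity H_O is the
fraction of heterozygous typed individuals; expected heterozygosity H_E is
the plain gene diversity ``1 - sum(p_i^2)`` over observed allele
frequencies (a small-sample-corrected variant is available behind a flag);
the inbreeding coefficient is ``F = (H_E - H_O) / H_E``, undefined (NaN)
at monomorphic loci.

Hardy-Weinberg departure is assessed with the biallelic exact test:
conditioning on the observed allele counts, the p-value sums the
probabilities of all heterozygote counts whose conditional probability
does not exceed that of the observed one. Sample sizes here (hundreds)
permit full enumeration, so no Monte Carlo approximation is used.

Genotypic linkage disequilibrium between locus pairs is tested by
permutation of a G statistic (log-likelihood ratio) on the
genotype-by-genotype contingency table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .model import (
    ALLELES,
    MISSING_CODE,
    GenotypeMatrix,
    GroupLabels,
    as_codes,
)

__all__ = [
    "LocusSummary",
    "allele_freqs",
    "expected_heterozygosity",
    "locus_summary",
    "hwe_exact_test",
    "ld_permutation_test",
    "g_statistic",
    "summary_table",
    "significance_stars",
    "write_summary_csv",
]


@dataclass(frozen=True)
class LocusSummary:
    """One row of the per-locus summary table."""

    locus: str
    n: int            # typed individuals
    na: int           # distinct alleles observed
    ho: float         # observed heterozygosity
    he: float         # expected heterozygosity (gene diversity)
    f: float          # inbreeding coefficient; NaN when He = 0
    maf: float        # minor allele frequency (0 when monomorphic)
    hwe_p: float      # exact-test p-value; NaN for >2 alleles
    a1: str
    a2: str           # "" when monomorphic


def allele_freqs(calls) -> dict[str, float]:
    """Allele frequencies over the 2N allele draws of one locus column.

    *calls* may be an ``(n, 2)`` code array, a list of ``Genotype`` or a
    list of string tokens. Raises if every call is missing.
    """
    codes = as_codes(calls)
    typed = codes[codes[:, 0] != MISSING_CODE]
    if typed.size == 0:
        raise ValueError("all calls missing: allele frequencies undefined")
    counts = np.bincount(typed.ravel(), minlength=len(ALLELES))
    total = counts.sum()
    return {ALLELES[i]: counts[i] / total for i in range(len(ALLELES)) if counts[i]}


def expected_heterozygosity(freqs: dict[str, float], unbiased: bool = False,
                            n: int | None = None) -> float:
    """Gene diversity ``1 - sum(p^2)``; optionally Nei's unbiased variant.

    The unbiased form multiplies by ``2n / (2n - 1)`` and needs the typed
    sample size *n*.
    """
    he = 1.0 - sum(p * p for p in freqs.values())
    if unbiased:
        if not n or n < 1:
            raise ValueError("unbiased He needs the typed sample size n")
        he *= 2 * n / (2 * n - 1)
    return he


def locus_summary(calls, locus_id: str = "locus", unbiased_he: bool = False) -> LocusSummary:
    """Compute N, Na, H_O, H_E, F, MAF and the HWE p-value for one locus."""
    codes = as_codes(calls)
    typed = codes[codes[:, 0] != MISSING_CODE]
    n = typed.shape[0]
    if n == 0:
        raise ValueError(f"{locus_id}: all calls missing")
    freqs = allele_freqs(codes)
    symbols = sorted(freqs)
    na = len(symbols)
    ho = float((typed[:, 0] != typed[:, 1]).mean())
    he = expected_heterozygosity(freqs, unbiased=unbiased_he, n=n)
    f = math.nan if he == 0.0 else (he - ho) / he
    maf = 0.0 if na < 2 else min(freqs.values())
    if na <= 1:
        hwe_p = 1.0
    elif na == 2:
        a, b = symbols
        hom_a = int(((typed[:, 0] == typed[:, 1]) & (typed[:, 0] == ALLELES.index(a))).sum())
        hom_b = int(((typed[:, 0] == typed[:, 1]) & (typed[:, 0] == ALLELES.index(b))).sum())
        het = n - hom_a - hom_b
        hwe_p = hwe_exact_test(hom_a, het, hom_b)
    else:
        hwe_p = math.nan
    return LocusSummary(
        locus=locus_id, n=n, na=na, ho=ho, he=he, f=f, maf=maf, hwe_p=hwe_p,
        a1=symbols[0], a2=symbols[1] if na > 1 else "",
    )


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test for a biallelic locus.

    Conditional on the observed allele counts, the probability of observing
    ``h`` heterozygotes among ``n`` individuals is

        P(h) = n! / (n_aa! h! n_bb!) * 2^h * nA! nB! / (2n)!

    and the p-value sums ``P(h')`` over all heterozygote counts with
    ``P(h') <= P(h_obs)``. Monomorphic input returns 1 by convention.
    """
    for c in (n_aa, n_ab, n_bb):
        if c < 0:
            raise ValueError("genotype counts must be >= 0")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    hets = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
    homs_a = (n_a - hets) // 2
    homs_b = (n_b - hets) // 2
    logp = (
        hets * math.log(2.0)
        - gammaln(homs_a + 1.0)
        - gammaln(hets + 1.0)
        - gammaln(homs_b + 1.0)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = int(np.searchsorted(hets, n_ab))
    p = float(probs[probs <= probs[obs] * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def g_statistic(table: np.ndarray) -> float:
    """G (log-likelihood ratio) statistic of an r x c contingency table."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total == 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    mask = table > 0
    return float(2.0 * (table[mask] * np.log(table[mask] / expected[mask])).sum())


def ld_permutation_test(calls_a, calls_b, n_perm: int = 999, seed: int = 0) -> float:
    """Genotypic LD test between two loci typed on the same individuals.

    The statistic is G on the genotype x genotype table of individuals
    typed at both loci; the null distribution permutes one locus' column.
    Returns ``(1 + #{G_perm >= G_obs}) / (n_perm + 1)``; 1.0 when either
    locus shows fewer than two distinct genotypes.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    ca, cb = as_codes(calls_a), as_codes(calls_b)
    if ca.shape[0] != cb.shape[0]:
        raise ValueError("locus columns cover different individuals")
    both = (ca[:, 0] != MISSING_CODE) & (cb[:, 0] != MISSING_CODE)
    ca, cb = ca[both], cb[both]
    if ca.shape[0] == 0:
        return 1.0
    # Factorise diploid genotypes to small integers.
    ga = ca[:, 0].astype(np.int32) * 4 + ca[:, 1]
    gb = cb[:, 0].astype(np.int32) * 4 + cb[:, 1]
    _, ia = np.unique(ga, return_inverse=True)
    _, ib = np.unique(gb, return_inverse=True)
    ka, kb = ia.max() + 1, ib.max() + 1
    if ka < 2 or kb < 2:
        return 1.0

    def joint_g(b_perm: np.ndarray) -> float:
        table = np.bincount(ia * kb + b_perm, minlength=ka * kb).reshape(ka, kb)
        return g_statistic(table)

    g_obs = joint_g(ib)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if joint_g(rng.permutation(ib)) >= g_obs - 1e-12:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def significance_stars(p: float) -> str:
    """Star coding used in the printed summary: *** p<0.001, ** p<0.01."""
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return "ns"


def summary_table(matrix: GenotypeMatrix, groups: GroupLabels | None = None,
                  unbiased_he: bool = False) -> pd.DataFrame:
    """Per-locus summary rows, one per locus in matrix order.

    Pooled over all individuals by default; when *groups* is given the
    table is computed within each group and stacked with a leading
    ``Group`` column. Values are unrounded; :func:`write_summary_csv`
    applies the 3-decimal display convention.
    """
    def table_for(m: GenotypeMatrix) -> pd.DataFrame:
        rows = []
        for j, locus in enumerate(m.loci):
            s = locus_summary(m.locus_calls(j), locus.id, unbiased_he=unbiased_he)
            rows.append(
                {
                    "Locus": s.locus, "N": s.n, "Na": s.na, "Ho": s.ho,
                    "He": s.he, "F": s.f, "Signif": significance_stars(s.hwe_p),
                    "MAF": s.maf, "A1": s.a1, "A2": s.a2,
                }
            )
        return pd.DataFrame(
            rows, columns=["Locus", "N", "Na", "Ho", "He", "F", "Signif",
                           "MAF", "A1", "A2"]
        )

    if groups is None:
        return table_for(matrix)
    groups.validate_against(matrix)
    parts = []
    for g in groups.group_names:
        part = table_for(matrix.subset_individuals(groups.members(g)))
        part.insert(0, "Group", g)
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def write_summary_csv(table: pd.DataFrame, path) -> None:
    """Write the summary with 3-decimal display rounding and NA for
    undefined inbreeding coefficients."""
    out = table.copy()
    for col in ("Ho", "He", "F", "MAF"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    out.to_csv(path, index=False)
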