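"""Published reference data for the North Atlantic Sebastes SNP panel.

Ships the printed per-locus summary of the 47 biallelic panel SNPs
(genotyped on 191 fish) and helpers to check its internal consistency:
expected heterozygosity recomputed from the printed minor allele
frequency, and the inbreeding coefficient recomputed from the printed
H_O/H_E. These are consistency checks on rounded, published numbers —
the raw genotypes behind them are not distributed here.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import expected_heterozygosity


def load_snp_summary() -> pd.DataFrame:
    """The published per-locus summary (47 biallelic SNPs, 191 fish).

    Columns: Locus, N, Na, Ho, He, F, Signif, MAF, A1, A2.
    """
    with resources.files("sebpanel.data").joinpath(
        "sebastes_panel_summary.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def he_from_maf(maf: float, decimals: int = 3) -> float:
    """Biallelic gene diversity ``2 p (1-p)`` from a minor allele
    frequency, rounded to the printed precision."""
    return round(expected_heterozygosity({"a": maf, "b": 1.0 - maf}), decimals)


def f_from_ho_he(ho: float, he: float, decimals: int = 3) -> float:
    """Inbreeding coefficient ``(He - Ho) / He`` at printed precision."""
    if he == 0:
        raise ValueError("F undefined when He = 0")
    return round((he - ho) / he, decimals)


def summary_ranges(table: pd.DataFrame | None = None) -> dict[str, float]:
    """Range statistics of the published table (min/max of Ho, He, F)."""
    df = load_snp_summary() if table is None else table
    return {
        "min_ho": float(df["Ho"].min()),
        "max_ho": float(df["Ho"].max()),
        "min_he": float(df["He"].min()),
        "max_he": float(df["He"].max()),
        "min_f": float(df["F"].min()),
        "max_f": float(df["F"].max()),
    }
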