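"""Synthetic multi-species genotype cohorts with planted diagnostic loci.

The generator emulates the kind of reduced-representation (ddRAD-style)
genotype set the panel-discovery pipeline consumes: a handful of
reproductively isolated groups, tens of loci, some of which are
reciprocally fixed between specific group pairs ("diagnostic"), the rest
polymorphic in every group ("shared"); overdispersed per-call read depths;
and optional missing-call and genotyping-error processes.

Within each group, genotypes are Hardy-Weinberg draws (two independent
alleles from the group's locus frequency). Between groups, shared-locus
frequencies spread around a common ancestral frequency via a Beta
distribution, so pooling groups produces the heterozygote deficiencies
(Wahlund effect) the real mixed-species collections show.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    ALLELE_CODES,
    ALLELES,
    MISSING_CODE,
    GenotypeMatrix,
    GroupLabels,
    LocusInfo,
)
from . import io as _io

#: Default group structure: four reproductively isolated units of 30 fish,
#: named after the North Atlantic Sebastes species/cryptic species the
#: toolkit targets.
DEFAULT_GROUPS: tuple[tuple[str, int], ...] = (
    ("mentella", 30),
    ("norvegicusA", 30),
    ("norvegicusB", 30),
    ("viviparus", 30),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Attributes
    ----------
    groups:
        ``(name, n_individuals)`` per group.
    n_diagnostic_per_pair:
        Reciprocally fixed loci planted for every unordered group pair.
    n_shared:
        Non-diagnostic polymorphic loci shared by all groups.
    shared_freq_divergence:
        Beta concentration controlling how far group frequencies spread
        around the ancestral frequency at shared loci (larger = tighter).
    depth_mean, depth_dispersion:
        Mean and negative-binomial size of per-call read depth; ddRAD
        coverage is overdispersed, so a Poisson would be too narrow.
    missing_rate:
        Per-call no-call probability (applied after the genotype draw;
        missing calls get depth 0).
    error_rate:
        Per-call probability of replacing the true genotype with a
        uniformly random genotype over the locus' two alleles (which may
        reproduce the true one).
    contig_length_range:
        Uniform range (bp) for the length of each locus' contig; every
        locus sits on its own contig.
    seed:
        Base seed; the whole cohort is reproducible from it.
    """

    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUPS
    n_diagnostic_per_pair: int = 3
    n_shared: int = 40
    shared_freq_divergence: float = 10.0
    depth_mean: float = 40.0
    depth_dispersion: float = 5.0
    missing_rate: float = 0.0
    error_rate: float = 0.0
    contig_length_range: tuple[int, int] = (25_000, 90_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) < 1 or any(n < 1 for _, n in self.groups):
            raise ValueError("every group needs at least one individual")
        names = [g for g, _ in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        if self.n_diagnostic_per_pair < 0 or self.n_shared < 0:
            raise ValueError("locus counts must be >= 0")
        if self.n_diagnostic_per_pair > 0 and len(self.groups) < 2:
            raise ValueError("diagnostic loci require at least two groups")
        for rate in (self.missing_rate, self.error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        lo, hi = self.contig_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid contig length range")


@dataclass(frozen=True)
class LocusTruth:
    """Ground truth for one simulated locus."""

    locus_id: str
    contig: str
    contig_length: int
    role: str  # "diagnostic" or "shared"
    pair: tuple[str, str] | None  # the group pair a diagnostic locus separates
    freqs: dict[str, dict[str, float]]  # group -> allele -> true frequency


@dataclass
class TruthTable:
    """Ground truth for the whole cohort; the oracle for discovery tests."""

    loci: list[LocusTruth]

    def diagnostic_pairs(self) -> dict[str, tuple[str, str]]:
        """Locus id -> separated pair, for planted diagnostic loci."""
        return {t.locus_id: t.pair for t in self.loci if t.role == "diagnostic"}

    def contig_lengths(self) -> dict[str, int]:
        return {t.contig: t.contig_length for t in self.loci}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.loci:
            rows.append(
                {
                    "locus": t.locus_id,
                    "contig": t.contig,
                    "contig_length": t.contig_length,
                    "role": t.role,
                    "pair": "|".join(t.pair) if t.pair else "",
                    "freqs": ";".join(
                        f"{g}:" + ",".join(f"{a}={p:.4f}" for a, p in sorted(fr.items()))
                        for g, fr in t.freqs.items()
                    ),
                }
            )
        return pd.DataFrame(rows)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, GroupLabels, TruthTable]:
    """Draw a full cohort: genotypes, depths, group labels, ground truth.

    Diagnostic loci for a pair (G1, G2) are fixed for one allele in G1 and
    the other in G2, and held at frequency 0.5/0.5 in every other group so
    that each planted locus is diagnostic for exactly its pair. Shared-locus
    group frequencies are Beta draws around an ancestral frequency, clipped
    to [0.1, 0.9] so shared loci stay polymorphic in expectation in every
    group (a locus drifting to fixation in two groups at once would be a
    spurious diagnostic).
    """
    rng = np.random.default_rng(config.seed)
    group_names = [g for g, _ in config.groups]
    sizes = dict(config.groups)

    truth_rows: list[LocusTruth] = []
    pairs = list(itertools.combinations(group_names, 2))
    lo, hi = config.contig_length_range

    def new_locus(idx: int) -> tuple[str, str, int, int, float]:
        contig = f"ctg{idx:04d}"
        length = int(rng.integers(lo, hi + 1))
        pos = int(rng.integers(1, length + 1))
        qual = float(rng.uniform(600.0, 3000.0))
        return f"SNP{idx:04d}", contig, length, pos, qual

    loci_info: list[LocusInfo] = []
    idx = 1
    for pair in pairs:
        for _ in range(config.n_diagnostic_per_pair):
            lid, contig, length, pos, qual = new_locus(idx)
            a, b = rng.choice(len(ALLELES), size=2, replace=False)
            a_sym, b_sym = ALLELES[a], ALLELES[b]
            freqs = {}
            for g in group_names:
                if g == pair[0]:
                    freqs[g] = {a_sym: 1.0, b_sym: 0.0}
                elif g == pair[1]:
                    freqs[g] = {a_sym: 0.0, b_sym: 1.0}
                else:
                    freqs[g] = {a_sym: 0.5, b_sym: 0.5}
            ref, alt = sorted((a_sym, b_sym))
            loci_info.append(LocusInfo(lid, contig, pos, ref, (alt,), qual))
            truth_rows.append(LocusTruth(lid, contig, length, "diagnostic", pair, freqs))
            idx += 1
    for _ in range(config.n_shared):
        lid, contig, length, pos, qual = new_locus(idx)
        a, b = rng.choice(len(ALLELES), size=2, replace=False)
        a_sym, b_sym = ALLELES[a], ALLELES[b]
        ancestral = float(rng.uniform(0.2, 0.8))
        c = config.shared_freq_divergence
        freqs = {}
        for g in group_names:
            p = float(np.clip(rng.beta(c * ancestral, c * (1.0 - ancestral)), 0.1, 0.9))
            freqs[g] = {a_sym: p, b_sym: 1.0 - p}
        ref, alt = sorted((a_sym, b_sym))
        loci_info.append(LocusInfo(lid, contig, pos, ref, (alt,), qual))
        truth_rows.append(LocusTruth(lid, contig, length, "shared", None, freqs))
        idx += 1

    individuals = [
        f"{g}_{i + 1:03d}" for g in group_names for i in range(sizes[g])
    ]
    mapping = {ind: ind.rsplit("_", 1)[0] for ind in individuals}
    n, L = len(individuals), len(loci_info)

    calls = np.full((n, L, 2), MISSING_CODE, dtype=np.int8)
    row0 = 0
    group_rows = {}
    for g in group_names:
        group_rows[g] = np.arange(row0, row0 + sizes[g])
        row0 += sizes[g]

    for j, (locus, truth) in enumerate(zip(loci_info, truth_rows)):
        a_sym, b_sym = sorted(truth.freqs[group_names[0]])  # the two alleles
        a_code, b_code = ALLELE_CODES[a_sym], ALLELE_CODES[b_sym]
        for g in group_names:
            p_a = truth.freqs[g][a_sym]
            dosage = rng.binomial(2, p_a, size=sizes[g])  # copies of allele a
            rows = group_rows[g]
            calls[rows, j, 0] = np.where(dosage >= 1, a_code, b_code)
            calls[rows, j, 1] = np.where(dosage == 2, a_code, b_code)

    # Genotyping error: replace flagged calls with a uniform random genotype
    # over the locus' two alleles (may coincide with the true call).
    if config.error_rate > 0:
        err = rng.random((n, L)) < config.error_rate
        draw = rng.integers(0, 3, size=(n, L))  # 0: aa, 1: ab, 2: bb
        for j, truth in enumerate(truth_rows):
            a_sym, b_sym = sorted(truth.freqs[group_names[0]])
            a_code, b_code = ALLELE_CODES[a_sym], ALLELE_CODES[b_sym]
            hit = err[:, j]
            if not hit.any():
                continue
            d = draw[hit, j]
            calls[hit, j, 0] = np.where(d <= 1, a_code, b_code)
            calls[hit, j, 1] = np.where(d == 0, a_code, b_code)

    k = config.depth_dispersion
    p_nb = k / (k + config.depth_mean)
    depths = rng.negative_binomial(k, p_nb, size=(n, L)).astype(np.int64)

    if config.missing_rate > 0:
        miss = rng.random((n, L)) < config.missing_rate
        calls[miss] = MISSING_CODE
        depths[miss] = 0

    truth = TruthTable(truth_rows)
    matrix = GenotypeMatrix(
        individuals=individuals,
        loci=loci_info,
        calls=calls,
        depths=depths,
        contig_lengths=truth.contig_lengths(),
        meta={"simulated": True, "seed": config.seed},
    )
    return matrix, GroupLabels(mapping), truth


def write_cohort_vcf(matrix: GenotypeMatrix, truth: TruthTable, path: str | Path) -> None:
    """Write the simulated cohort as a VCF with GT:DP and contig lengths."""
    if matrix.depths is None:
        raise ValueError("cohort has no depths; cannot write GT:DP VCF")
    _io.write_vcf(matrix, path, contig_lengths=truth.contig_lengths(),
                  require_depths=True)


def simulate_from_rules(
    rules: "DiagnosticRuleSet",  # noqa: F821 - imported lazily to avoid a cycle
    n_per_species: int | dict[str, int] = 30,
    missing_rate: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, GroupLabels]:
    """Cohort whose genotypes follow a diagnostic rule table exactly.

    Every individual of a species carries that species' multilocus
    signature, optionally perturbed by the same error/missing processes as
    :func:`simulate_cohort`. Useful for stressing the rule-based assigner
    with a known answer.
    """
    rng = np.random.default_rng(seed)
    locus_ids = rules.locus_ids()
    species = [r.species for r in rules.rules]
    sizes = (
        {s: n_per_species for s in species}
        if isinstance(n_per_species, int)
        else dict(n_per_species)
    )

    # Two alleles per locus, taken from the union over rules.
    locus_alleles: dict[str, tuple[str, str]] = {}
    for lid in locus_ids:
        seen = sorted(
            {a for r in rules.rules for a in (r.genotypes[lid].alleles or ())}
        )
        if len(seen) == 1:
            seen = seen * 2
        locus_alleles[lid] = (seen[0], seen[-1])

    individuals, mapping, rows = [], {}, []
    for rule in rules.rules:
        for i in range(sizes[rule.species]):
            ind = f"{rule.species}_{i + 1:03d}"
            individuals.append(ind)
            mapping[ind] = rule.species
            rows.append([rule.genotypes[lid] for lid in locus_ids])

    loci = [
        LocusInfo(lid, lid, 1, locus_alleles[lid][0],
                  (locus_alleles[lid][1],) if locus_alleles[lid][1] != locus_alleles[lid][0] else (),
                  qual=1000.0)
        for lid in locus_ids
    ]
    matrix = GenotypeMatrix.from_calls(individuals, loci, rows)

    n, L = matrix.n_individuals, matrix.n_loci
    if error_rate > 0:
        err = rng.random((n, L)) < error_rate
        draw = rng.integers(0, 3, size=(n, L))
        for j, lid in enumerate(locus_ids):
            a_code = ALLELE_CODES[locus_alleles[lid][0]]
            b_code = ALLELE_CODES[locus_alleles[lid][1]]
            hit = err[:, j]
            d = draw[hit, j]
            matrix.calls[hit, j, 0] = np.where(d <= 1, a_code, b_code)
            matrix.calls[hit, j, 1] = np.where(d == 0, a_code, b_code)
        matrix.calls.sort(axis=-1)
    if missing_rate > 0:
        miss = rng.random((n, L)) < missing_rate
        matrix.calls[miss] = MISSING_CODE
    return matrix, GroupLabels(mapping)
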