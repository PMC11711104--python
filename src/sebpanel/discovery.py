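"""Diagnostic-SNP panel discovery.

Three-stage selection of species-diagnostic markers from a genotyped
cohort, mirroring standard practice for reduced-representation data:

1. site-quality filter (Phred-scaled QUAL strictly greater than a
   threshold, default 500);
2. pairwise reciprocal-fixation scan: for each group pair, keep loci where
   every typed individual of one group is homozygous for one allele, every
   typed individual of the other group homozygous for a different allele,
   and mean read depth in each group strictly exceeds a coverage threshold
   (default 20x);
3. contig thinning: only contigs longer than a threshold (default 20 kb)
   are eligible, and at most one SNP is retained per such contig, to keep
   panel markers effectively unlinked.

All thresholds are strict inequalities. "Coverage in a group" is by
default the mean depth over the group's typed calls at the locus; a
stricter per-individual mode is available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .model import (
    ALLELES,
    MISSING_CODE,
    GenotypeMatrix,
    GroupLabels,
    LocusInfo,
)


@dataclass(frozen=True)
class DiscoveryConfig:
    """Thresholds for the three selection stages.

    min_qual : Phred-scaled site quality; loci must exceed it strictly.
    min_depth : coverage threshold in x; each group's depth must exceed
        it strictly (group mean, or every typed call when
        ``per_individual_depth``).
    min_contig_length : bp; only strictly longer contigs yield panel SNPs.
    max_group_missing : tolerated untyped fraction per group at a locus.
        The default 0 demands complete typing, the conservative reading
        when fixation must hold for *every* individual.
    """

    min_qual: float = 500.0
    min_depth: float = 20.0
    min_contig_length: int = 20_000
    max_group_missing: float = 0.0
    per_individual_depth: bool = False

    def __post_init__(self) -> None:
        if self.min_qual < 0 or self.min_depth < 0 or self.min_contig_length < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0.0 <= self.max_group_missing <= 1.0:
            raise ValueError("max_group_missing must lie in [0, 1]")


@dataclass(frozen=True)
class DiagnosticCandidate:
    """A locus reciprocally fixed between one group pair."""

    locus: LocusInfo
    pair: tuple[str, str]
    allele_g1: str
    allele_g2: str
    mean_depth_g1: float
    mean_depth_g2: float

    def __post_init__(self) -> None:
        if self.allele_g1 == self.allele_g2:
            raise ValueError(f"locus {self.locus.id}: alleles must differ")


@dataclass(frozen=True)
class PanelLocus:
    """One panel SNP with every group pair it separates."""

    locus: LocusInfo
    candidates: tuple[DiagnosticCandidate, ...]

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple(c.pair for c in self.candidates)


def filter_quality(
    loci: Sequence[LocusInfo], min_qual: float = 500.0
) -> list[LocusInfo]:
    """Keep loci with Phred quality strictly greater than *min_qual*."""
    return [locus for locus in loci if locus.qual > min_qual]


def find_pairwise_diagnostic(
    matrix: GenotypeMatrix,
    groups: GroupLabels,
    pair: tuple[str, str],
    config: DiscoveryConfig = DiscoveryConfig(),
) -> list[DiagnosticCandidate]:
    """Scan all loci for reciprocal fixed differences between one pair.

    A locus qualifies iff each group's typed individuals are all homozygous
    for a single allele, the two alleles differ, each group's missing
    fraction is within ``max_group_missing``, and each group's coverage
    strictly exceeds ``min_depth``.
    """
    g1, g2 = pair
    idx = {g: groups.indices(matrix, g) for g in (g1, g2)}
    if config.min_depth > 0 and matrix.depths is None:
        raise ValueError("min_depth > 0 requires per-call read depths")

    out: list[DiagnosticCandidate] = []
    for j, locus in enumerate(matrix.loci):
        fixed: dict[str, int] = {}
        depth: dict[str, float] = {}
        ok = True
        for g in (g1, g2):
            calls = matrix.calls[idx[g], j]
            typed = calls[:, 0] != MISSING_CODE
            n_typed = int(typed.sum())
            n_total = len(calls)
            if n_typed == 0 or (n_total - n_typed) / n_total > config.max_group_missing:
                ok = False
                break
            codes = np.unique(calls[typed])
            if len(codes) != 1:  # polymorphic or any heterozygote
                ok = False
                break
            fixed[g] = int(codes[0])
            if matrix.depths is not None:
                d = matrix.depths[idx[g], j][typed]
                depth[g] = float(d.mean())
                too_shallow = (
                    (d <= config.min_depth).any()
                    if config.per_individual_depth
                    else depth[g] <= config.min_depth
                )
                if config.min_depth > 0 and too_shallow:
                    ok = False
                    break
            else:
                depth[g] = float("nan")
        if not ok or fixed[g1] == fixed[g2]:
            continue
        out.append(
            DiagnosticCandidate(
                locus=locus,
                pair=(g1, g2),
                allele_g1=ALLELES[fixed[g1]],
                allele_g2=ALLELES[fixed[g2]],
                mean_depth_g1=depth[g1],
                mean_depth_g2=depth[g2],
            )
        )
    return out


def thin_by_contig(
    candidates: Sequence,
    contig_lengths: dict[str, int],
    config: DiscoveryConfig = DiscoveryConfig(),
) -> list:
    """Keep at most one SNP per contig strictly longer than the threshold.

    Within a contig the highest-QUAL entry wins, ties going to the smallest
    position; output is sorted by (contig, position). Works on any items
    carrying a ``.locus`` attribute (candidates or merged panel entries).
    """
    missing = sorted({c.locus.contig for c in candidates} - set(contig_lengths))
    if missing:
        raise ValueError(f"no length known for contigs: {missing}")
    eligible = [
        c for c in candidates
        if contig_lengths[c.locus.contig] > config.min_contig_length
    ]
    best: dict[str, object] = {}
    for c in eligible:
        cur = best.get(c.locus.contig)
        if cur is None or (-c.locus.qual, c.locus.position) < (
            -cur.locus.qual, cur.locus.position  # type: ignore[attr-defined]
        ):
            best[c.locus.contig] = c
    return sorted(best.values(), key=lambda c: (c.locus.contig, c.locus.position))


def discover_panel(
    matrix: GenotypeMatrix,
    groups: GroupLabels,
    config: DiscoveryConfig = DiscoveryConfig(),
    contig_lengths: dict[str, int] | None = None,
) -> list[PanelLocus]:
    """Full pipeline: pairwise scans, quality filter, contig thinning.

    Returns one :class:`PanelLocus` per retained SNP; a locus diagnostic
    for several pairs appears once with all its pairs listed.
    """
    groups.validate_against(matrix)
    names = groups.group_names
    if len(names) < 2:
        raise ValueError("panel discovery needs at least two groups")
    lengths = contig_lengths if contig_lengths is not None else matrix.contig_lengths
    if lengths is None:
        raise ValueError("contig lengths unavailable: supply contig_lengths "
                         "or read them from the VCF header")

    pooled: list[DiagnosticCandidate] = []
    for pair in itertools.combinations(names, 2):
        pooled.extend(find_pairwise_diagnostic(matrix, groups, pair, config))

    keep_ids = {l.id for l in filter_quality([c.locus for c in pooled], config.min_qual)}
    by_locus: dict[str, list[DiagnosticCandidate]] = {}
    for c in pooled:
        if c.locus.id in keep_ids:
            by_locus.setdefault(c.locus.id, []).append(c)
    merged = [
        PanelLocus(locus=cands[0].locus, candidates=tuple(cands))
        for cands in by_locus.values()
    ]
    return thin_by_contig(merged, lengths, config)


def panel_to_records(panel: Iterable[PanelLocus]) -> list[dict]:
    """JSON-friendly description of a discovered panel."""
    records = []
    for entry in panel:
        records.append(
            {
                "locus": entry.locus.id,
                "contig": entry.locus.contig,
                "position": entry.locus.position,
                "qual": entry.locus.qual,
                "pairs": [
                    {
                        "groups": list(c.pair),
                        "allele_g1": c.allele_g1,
                        "allele_g2": c.allele_g2,
                        "mean_depth_g1": c.mean_depth_g1,
                        "mean_depth_g2": c.mean_depth_g2,
                    }
                    for c in entry.candidates
                ],
            }
        )
    return records
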