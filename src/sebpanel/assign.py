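"""Species assignment from multilocus SNP genotypes.

Two complementary assigners:

* **Rule-based** — an explicit table mapping each species to its expected
  genotype at a few diagnostic loci (the deployment mode of a 3-SNP
  TaqMan panel). Scoring is exact genotype matching over non-missing
  loci; heterozygous observations at a rule locus count as conflicts and
  are surfaced in the result rather than averaged away, because in a
  fixed-difference panel a heterozygote is an anomaly worth flagging.

* **Likelihood-based** — for larger panels without full fixation, each
  group is scored by the Hardy-Weinberg log-likelihood of the observed
  genotypes under that group's allele frequencies, with frequencies
  floored at ``1/(2N+1)`` (an add-one-style guard scaled to the sample)
  so unseen alleles stay finite. The individual is assigned to the best
  group only when its log-likelihood margin over the runner-up reaches
  ``min_margin``.

The shipped Sebastes rule set encodes the published 3-SNP panel:
SEB29 separates S. viviparus, SEB39 separates S. mentella, and SEB25
separates the two cryptic S. norvegicus types A and B.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

from .divergence import GroupFrequencyTable
from .model import Genotype, GenotypeMatrix, GroupLabels

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class Rule:
    """Expected multilocus genotype signature for one species."""

    species: str
    genotypes: dict[str, Genotype]

    def __post_init__(self) -> None:
        if not self.genotypes:
            raise ValueError(f"rule for {self.species}: no loci")


@dataclass(frozen=True)
class DiagnosticRuleSet:
    """Ordered collection of species signatures over shared rule loci."""

    rules: tuple[Rule, ...]

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("empty rule set")
        signatures = set()
        for rule in self.rules:
            sig = tuple(sorted((lid, str(g)) for lid, g in rule.genotypes.items()))
            if sig in signatures:
                raise ValueError(
                    f"rule for {rule.species} duplicates another rule's signature"
                )
            signatures.add(sig)

    def locus_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rule in self.rules:
            for lid in rule.genotypes:
                seen.setdefault(lid, None)
        return list(seen)

    @classmethod
    def from_dict(cls, table: Mapping[str, Mapping[str, str]]) -> "DiagnosticRuleSet":
        """Build from ``{species: {locus: "CC", ...}, ...}``."""
        return cls(
            tuple(
                Rule(
                    species=species,
                    genotypes={
                        lid: Genotype.from_string(tok) for lid, tok in loci.items()
                    },
                )
                for species, loci in table.items()
            )
        )

    @classmethod
    def from_json(cls, path) -> "DiagnosticRuleSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def builtin_sebastes_rules() -> DiagnosticRuleSet:
    """The shipped 3-SNP North Atlantic Sebastes panel (SEB29/SEB39/SEB25)."""
    with resources.files("sebpanel.data").joinpath("sebastes_rules.json").open() as fh:
        return DiagnosticRuleSet.from_dict(json.load(fh))


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of assigning one individual."""

    individual: str
    species: str                     # species label, or UNASSIGNED
    matched: int
    conflicts: tuple[tuple[str, str, str], ...]  # (locus, observed, expected)
    missing: tuple[str, ...]
    method: str                      # "rules" or "likelihood"
    margin: float | None = None      # log-likelihood margin (nats)
    note: str = ""

    @property
    def assigned(self) -> bool:
        return self.species != UNASSIGNED


def assign_by_rules(
    genotypes: Mapping[str, Genotype],
    rules: DiagnosticRuleSet,
    max_conflicts: int = 0,
    max_missing: int = 0,
    individual: str = "",
) -> AssignmentResult:
    """Score each rule by exact genotype matches over non-missing loci.

    The unique rule with the most matches wins if its conflict and missing
    counts are within tolerance; a tie for best, or thresholds exceeded,
    yields UNASSIGNED with full diagnostics for the (first) best rule.
    """
    scored = []
    for rule in rules.rules:
        matched = 0
        conflicts: list[tuple[str, str, str]] = []
        missing: list[str] = []
        for lid, expected in rule.genotypes.items():
            observed = genotypes.get(lid, Genotype(None))
            if observed.is_missing:
                missing.append(lid)
            elif observed == expected:
                matched += 1
            else:
                conflicts.append((lid, str(observed), str(expected)))
        scored.append((matched, rule, tuple(conflicts), tuple(missing)))

    best_matched = max(s[0] for s in scored)
    winners = [s for s in scored if s[0] == best_matched]
    matched, rule, conflicts, missing = winners[0]
    if len(winners) > 1:
        tied = ", ".join(s[1].species for s in winners)
        return AssignmentResult(individual, UNASSIGNED, matched, conflicts,
                                missing, "rules", note=f"tie between {tied}")
    if len(conflicts) > max_conflicts or len(missing) > max_missing:
        return AssignmentResult(
            individual, UNASSIGNED, matched, conflicts, missing, "rules",
            note=f"best match {rule.species} outside tolerance",
        )
    return AssignmentResult(individual, rule.species, matched, conflicts,
                            missing, "rules")


def assign_by_likelihood(
    genotypes: Mapping[str, Genotype],
    freqs: GroupFrequencyTable,
    min_margin: float = 2.0,
    individual: str = "",
) -> AssignmentResult:
    """Hardy-Weinberg log-likelihood assignment over any panel loci.

    ``min_margin`` is in natural-log units; the default 2.0 demands the
    best group be about e^2 (roughly 7x) more likely than the runner-up.
    """
    loglik: dict[str, float] = {}
    typed_by_group: dict[str, int] = {}
    for group in freqs.groups:
        total = 0.0
        used = 0
        for lid in freqs.loci:
            g = genotypes.get(lid, Genotype(None))
            if g.is_missing:
                continue
            fr = freqs.freqs[group].get(lid) or {}
            n_typed = freqs.counts[group].get(lid, 0)
            if n_typed == 0:
                continue
            eps = 1.0 / (2.0 * n_typed + 1.0)
            a, b = g.alleles  # type: ignore[misc]
            pa = max(fr.get(a, 0.0), eps)
            pb = max(fr.get(b, 0.0), eps)
            prob = pa * pb if a == b else 2.0 * pa * pb
            total += math.log(prob)
            used += 1
        if used:
            loglik[group] = total
            typed_by_group[group] = used
    if not loglik:
        return AssignmentResult(individual, UNASSIGNED, 0, (), tuple(freqs.loci),
                                "likelihood", note="no typed loci")
    ranked = sorted(loglik.items(), key=lambda kv: (-kv[1], kv[0]))
    best_group, best_ll = ranked[0]
    margin = math.inf if len(ranked) == 1 else best_ll - ranked[1][1]
    matched = typed_by_group[best_group]
    missing = tuple(
        lid for lid in freqs.loci
        if genotypes.get(lid, Genotype(None)).is_missing
    )
    if margin < min_margin:
        return AssignmentResult(individual, UNASSIGNED, matched, (), missing,
                                "likelihood", margin=margin,
                                note="margin below threshold")
    return AssignmentResult(individual, best_group, matched, (), missing,
                            "likelihood", margin=margin)


def assign_matrix(
    matrix: GenotypeMatrix,
    rules: DiagnosticRuleSet | None = None,
    freqs: GroupFrequencyTable | None = None,
    method: str = "rules",
    **kwargs,
) -> list[AssignmentResult]:
    """Assign every individual of a matrix with one of the two methods."""
    if method == "rules":
        if rules is None:
            raise ValueError("method='rules' needs a rule set")
        return [
            assign_by_rules(matrix.genotypes_of(ind), rules, individual=ind, **kwargs)
            for ind in matrix.individuals
        ]
    if method == "likelihood":
        if freqs is None:
            raise ValueError("method='likelihood' needs a group frequency table")
        return [
            assign_by_likelihood(matrix.genotypes_of(ind), freqs,
                                 individual=ind, **kwargs)
            for ind in matrix.individuals
        ]
    raise ValueError(f"unknown method {method!r}")


def results_to_records(results: Sequence[AssignmentResult]) -> list[dict]:
    """CSV/JSON-friendly rows for a batch of assignment results."""
    return [
        {
            "individual": r.individual,
            "species": r.species,
            "matched": r.matched,
            "conflicts": ";".join(f"{l}:{o}!={e}" for l, o, e in r.conflicts),
            "missing": ";".join(r.missing),
            "method": r.method,
            "margin": "" if r.margin is None else f"{r.margin:.3f}",
            "note": r.note,
        }
        for r in results
    ]
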