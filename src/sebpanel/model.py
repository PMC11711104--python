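"""Core data model for diploid SNP genotype data.

The toolkit works on unphased diploid calls at single-nucleotide loci.
Genotypes are stored internally as a compact integer-coded numpy array
(``A=0, C=1, G=2, T=3``, missing ``-1``) so that allele counting, fixation
scans and bootstrap resampling stay vectorised; the :class:`Genotype`
dataclass is the user-facing value type.

Coordinates are 1-based throughout, matching the VCF convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Fixed allele alphabet and its integer coding. The order is load-bearing:
#: GENEPOP export codes alleles 01..04 in this order, and PCA dosage counts
#: the lexicographically first observed allele.
ALLELES: tuple[str, ...] = ("A", "C", "G", "T")
ALLELE_CODES: dict[str, int] = {a: i for i, a in enumerate(ALLELES)}
MISSING_CODE: int = -1

#: Tokens read_table / Genotype.from_string treat as "no call".
MISSING_TOKENS = frozenset(
    {"", ".", "./.", ".|.", "n", "nn", "-", "--", "0", "00", "000", "0000", "na"}
)


def validate_allele(symbol: str) -> str:
    """Return *symbol* if it is a valid uppercase single-base allele."""
    if symbol not in ALLELE_CODES:
        raise ValueError(
            f"invalid allele {symbol!r}: expected one of {', '.join(ALLELES)}"
        )
    return symbol


@dataclass(frozen=True)
class Genotype:
    """An unphased diploid genotype: an unordered allele pair, or missing.

    The pair is order-normalised at construction so ``Genotype(('T','C'))``
    equals ``Genotype(('C','T'))``. ``Genotype(None)`` (the module constant
    :data:`MISSING`) is the missing-call sentinel.
    """

    alleles: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.alleles is None:
            return
        pair = tuple(self.alleles)
        if len(pair) != 2:
            raise ValueError(f"a genotype needs exactly two alleles, got {pair!r}")
        for a in pair:
            validate_allele(a)
        object.__setattr__(self, "alleles", tuple(sorted(pair)))

    @classmethod
    def from_string(cls, token: str) -> "Genotype":
        """Parse tokens like ``"CT"``, ``"C/T"``, ``"C|T"`` or ``"NN"``.

        Raises ``ValueError`` on tokens that are neither a recognised
        missing sentinel nor a two-allele call.
        """
        raw = token.strip()
        if raw.lower() in MISSING_TOKENS:
            return MISSING
        compact = raw.replace("/", "").replace("|", "").upper()
        if len(compact) != 2:
            raise ValueError(f"cannot parse genotype token {token!r}")
        return cls((compact[0], compact[1]))

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    def codes(self) -> tuple[int, int]:
        if self.alleles is None:
            return (MISSING_CODE, MISSING_CODE)
        return (ALLELE_CODES[self.alleles[0]], ALLELE_CODES[self.alleles[1]])

    def __str__(self) -> str:
        return "NN" if self.alleles is None else "".join(self.alleles)


#: The missing-call sentinel.
MISSING = Genotype(None)


def genotype_from_codes(a: int, b: int) -> Genotype:
    if a == MISSING_CODE or b == MISSING_CODE:
        return MISSING
    return Genotype((ALLELES[a], ALLELES[b]))


@dataclass(frozen=True)
class LocusInfo:
    """Metadata for one SNP locus.

    ``qual`` is the Phred-scaled site quality from variant calling
    (0 when the source carries none, e.g. tabular genotype files).
    """

    id: str
    contig: str
    position: int
    ref: str
    alts: tuple[str, ...]
    qual: float = 0.0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"locus {self.id}: position must be >= 1")
        validate_allele(self.ref)
        object.__setattr__(self, "alts", tuple(self.alts))
        for a in self.alts:
            validate_allele(a)
        if self.ref in self.alts:
            raise ValueError(f"locus {self.id}: ref allele repeated in alts")
        if not (self.qual >= 0):
            raise ValueError(f"locus {self.id}: qual must be >= 0")

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref, *self.alts)


def as_codes(calls: object) -> np.ndarray:
    """Coerce one locus column of calls to an ``(n, 2)`` int8 code array.

    Accepts an integer-coded array, a sequence of :class:`Genotype`, or a
    sequence of string tokens understood by :meth:`Genotype.from_string`.
    """
    if isinstance(calls, np.ndarray):
        arr = calls.astype(np.int8, copy=True)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(f"expected an (n, 2) call array, got shape {arr.shape}")
    else:
        rows = []
        for item in calls:  # type: ignore[union-attr]
            g = item if isinstance(item, Genotype) else Genotype.from_string(str(item))
            rows.append(g.codes())
        arr = np.array(rows, dtype=np.int8).reshape(-1, 2)
    return _normalise_codes(arr)


def _normalise_codes(arr: np.ndarray) -> np.ndarray:
    """Sort allele pairs and force half-calls to fully missing."""
    half = (arr == MISSING_CODE).any(axis=-1)
    arr.sort(axis=-1)
    arr[half] = MISSING_CODE
    return arr


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid calls with optional per-call read depth.

    ``calls`` has shape ``(n_individuals, n_loci, 2)`` (int8 allele codes,
    sorted pairs, -1/-1 missing); ``depths`` the matching read counts.
    ``contig_lengths`` carries ``##contig`` header lengths when the matrix
    came from (or is headed for) a VCF.
    """

    individuals: list[str]
    loci: list[LocusInfo]
    calls: np.ndarray
    depths: np.ndarray | None = None
    contig_lengths: dict[str, int] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.individuals = list(self.individuals)
        self.loci = list(self.loci)
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual labels")
        ids = [l.id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus labels")
        self.calls = _normalise_codes(np.asarray(self.calls, dtype=np.int8).copy())
        expected = (len(self.individuals), len(self.loci), 2)
        if self.calls.shape != expected:
            raise ValueError(
                f"calls shape {self.calls.shape} does not match {expected}"
            )
        if self.depths is not None:
            self.depths = np.asarray(self.depths, dtype=np.int64)
            if self.depths.shape != expected[:2]:
                raise ValueError("depths shape does not match calls")
            if (self.depths < 0).any():
                raise ValueError("read depths must be non-negative")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_calls(
        cls,
        individuals: Sequence[str],
        loci: Sequence[LocusInfo],
        genotypes: Iterable[Iterable[Genotype | str]],
        depths: np.ndarray | None = None,
        **kwargs,
    ) -> "GenotypeMatrix":
        """Build a matrix from nested per-individual genotype sequences."""
        grid = np.full((len(individuals), len(loci), 2), MISSING_CODE, dtype=np.int8)
        for i, row in enumerate(genotypes):
            for j, item in enumerate(row):
                g = (
                    item
                    if isinstance(item, Genotype)
                    else Genotype.from_string(str(item))
                )
                grid[i, j] = g.codes()
        return cls(list(individuals), list(loci), grid, depths, **kwargs)

    # -- basic accessors --------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus: str | int) -> int:
        if isinstance(locus, int):
            return locus
        for j, l in enumerate(self.loci):
            if l.id == locus:
                return j
        raise KeyError(f"unknown locus {locus!r}")

    def individual_index(self, label: str) -> int:
        try:
            return self.individuals.index(label)
        except ValueError:
            raise KeyError(f"unknown individual {label!r}") from None

    def locus_calls(self, locus: str | int) -> np.ndarray:
        """The ``(n, 2)`` code array for one locus."""
        return self.calls[:, self.locus_index(locus), :]

    def genotype(self, individual: str | int, locus: str | int) -> Genotype:
        i = individual if isinstance(individual, int) else self.individual_index(individual)
        a, b = self.calls[i, self.locus_index(locus)]
        return genotype_from_codes(int(a), int(b))

    def genotypes_of(self, individual: str | int) -> dict[str, Genotype]:
        """Mapping locus id -> genotype for one individual."""
        i = individual if isinstance(individual, int) else self.individual_index(individual)
        return {
            l.id: genotype_from_codes(int(self.calls[i, j, 0]), int(self.calls[i, j, 1]))
            for j, l in enumerate(self.loci)
        }

    def typed_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` mask of non-missing calls."""
        return self.calls[:, :, 0] != MISSING_CODE

    # -- subsetting -------------------------------------------------------
    def subset_individuals(self, labels: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.individual_index(l) for l in labels]
        return GenotypeMatrix(
            [self.individuals[i] for i in idx],
            self.loci,
            self.calls[idx],
            None if self.depths is None else self.depths[idx],
            contig_lengths=self.contig_lengths,
            meta=dict(self.meta),
        )

    def subset_loci(self, loci: Sequence[str | int]) -> "GenotypeMatrix":
        idx = [self.locus_index(l) for l in loci]
        return GenotypeMatrix(
            self.individuals,
            [self.loci[j] for j in idx],
            self.calls[:, idx],
            None if self.depths is None else self.depths[:, idx],
            contig_lengths=self.contig_lengths,
            meta=dict(self.meta),
        )


@dataclass
class GroupLabels:
    """Assignment of individuals to groups (species / cryptic species)."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        self.mapping = dict(self.mapping)
        if not self.mapping:
            raise ValueError("empty group labelling")

    @property
    def group_names(self) -> list[str]:
        """Group names in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.mapping.values():
            seen.setdefault(g, None)
        return list(seen)

    def members(self, group: str) -> list[str]:
        out = [ind for ind, g in self.mapping.items() if g == group]
        if not out:
            raise KeyError(f"unknown group {group!r}")
        return out

    def indices(self, matrix: GenotypeMatrix, group: str) -> np.ndarray:
        """Row indices of a group's individuals within *matrix*."""
        return np.array(
            [matrix.individual_index(ind) for ind in self.members(group)], dtype=int
        )

    def validate_against(self, matrix: GenotypeMatrix) -> None:
        known = set(matrix.individuals)
        unknown = [ind for ind in self.mapping if ind not in known]
        if unknown:
            raise ValueError(
                f"group labels name individuals absent from the matrix: {unknown[:5]}"
            )
        unlabelled = known - set(self.mapping)
        if unlabelled:
            warnings.warn(
                f"{len(unlabelled)} individuals carry no group label and are "
                "ignored by group-wise analyses",
                stacklevel=2,
            )

    def group_of(self, individual: str) -> str:
        return self.mapping[individual]
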