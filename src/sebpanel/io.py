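"""Readers and writers: VCF (via pysam), GENEPOP, and CSV genotype tables.

Only the plumbing lives here — records go in and out unchanged. Records a
reader cannot represent (non-SNP alleles, symbolic alts) are rejected with
a counted warning rather than silently dropped: the count is stored under
``matrix.meta["rejected_records"]``.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .model import (
    ALLELE_CODES,
    ALLELES,
    MISSING_CODE,
    Genotype,
    GenotypeMatrix,
    GroupLabels,
    LocusInfo,
    _normalise_codes,
)

#: GENEPOP two-digit allele codes, fixed so exports are bit-reproducible.
_GENEPOP_CODE = {a: f"{i + 1:02d}" for i, a in enumerate(ALLELES)}
_GENEPOP_DECODE = {v: k for k, v in _GENEPOP_CODE.items()}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, sample_subset: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read a VCF v4.x with per-sample GT (and optionally DP) fields.

    One locus per record; multi-allelic records keep all alternate alleles.
    Half-calls and ``./.`` become missing; phase separators are ignored.
    Records whose alleles are not single A/C/G/T bases are counted as
    rejected (``meta["rejected_records"]``) and skipped with a warning.

    Parameters
    ----------
    path:
        VCF file (plain text or bgzipped).
    sample_subset:
        Optional sample labels to retain, in the given order. Unknown
        labels raise ``ValueError``.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc

    with vf:
        samples = list(vf.header.samples)
        if sample_subset is not None:
            unknown = [s for s in sample_subset if s not in samples]
            if unknown:
                raise ValueError(f"samples not present in {path}: {unknown}")

        contig_lengths = {
            name: rec.length
            for name, rec in vf.header.contigs.items()
            if rec.length is not None
        }

        loci: list[LocusInfo] = []
        call_rows: list[np.ndarray] = []
        depth_rows: list[np.ndarray] = []
        any_depth = False
        rejected = 0
        n = len(samples)

        for record_number, rec in enumerate(vf, start=1):
            alleles = rec.alleles
            if alleles is None or len(alleles) < 1 or any(
                len(a) != 1 or a.upper() not in ALLELE_CODES for a in alleles
            ):
                rejected += 1
                continue
            alleles = tuple(a.upper() for a in alleles)
            locus_id = rec.id or f"{rec.chrom}_{rec.pos}"
            try:
                loci.append(
                    LocusInfo(
                        id=locus_id,
                        contig=rec.chrom,
                        position=rec.pos,
                        ref=alleles[0],
                        alts=alleles[1:],
                        qual=float(rec.qual) if rec.qual is not None else 0.0,
                    )
                )
            except ValueError as exc:
                raise ValueError(
                    f"malformed VCF record {record_number} in {path}: {exc}"
                ) from exc

            codes = np.full((n, 2), MISSING_CODE, dtype=np.int8)
            depths = np.zeros(n, dtype=np.int64)
            for i, name in enumerate(samples):
                sample = rec.samples[name]
                gt = sample.get("GT")
                if gt is not None and len(gt) == 2 and None not in gt:
                    codes[i, 0] = ALLELE_CODES[alleles[gt[0]]]
                    codes[i, 1] = ALLELE_CODES[alleles[gt[1]]]
                dp = sample.get("DP")
                if dp is not None:
                    depths[i] = int(dp)
                    any_depth = True
            call_rows.append(codes)
            depth_rows.append(depths)

    if rejected:
        warnings.warn(
            f"{path}: rejected {rejected} non-SNP records", stacklevel=2
        )
    calls = (
        np.stack(call_rows, axis=1)
        if call_rows
        else np.empty((n, 0, 2), dtype=np.int8)
    )
    depths_arr = np.stack(depth_rows, axis=1) if (depth_rows and any_depth) else None
    matrix = GenotypeMatrix(
        individuals=samples,
        loci=loci,
        calls=calls,
        depths=depths_arr,
        contig_lengths=contig_lengths or None,
        meta={"rejected_records": rejected, "source": path},
    )
    if sample_subset is not None:
        matrix = matrix.subset_individuals(list(sample_subset))
    return matrix


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
    require_depths: bool = False,
) -> None:
    """Write the matrix as a VCF v4.2 with GT (and DP when depths exist)."""
    if require_depths and matrix.depths is None:
        raise ValueError("per-call depths are required but absent")
    lengths = contig_lengths if contig_lengths is not None else (matrix.contig_lengths or {})

    header = pysam.VariantHeader()
    seen: set[str] = set()
    for locus in matrix.loci:
        if locus.contig in seen:
            continue
        seen.add(locus.contig)
        if locus.contig in lengths:
            header.add_line(
                f"##contig=<ID={locus.contig},length={int(lengths[locus.contig])}>"
            )
        else:
            header.add_line(f"##contig=<ID={locus.contig}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if matrix.depths is not None:
        header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for name in matrix.individuals:
        header.add_sample(name)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, locus in enumerate(matrix.loci):
            rec = out.new_record(
                contig=locus.contig,
                start=locus.position - 1,
                alleles=locus.alleles,
                id=locus.id,
                qual=locus.qual,
            )
            index_of = {ALLELE_CODES[a]: k for k, a in enumerate(locus.alleles)}
            for i, name in enumerate(matrix.individuals):
                a, b = (int(x) for x in matrix.calls[i, j])
                if a == MISSING_CODE:
                    rec.samples[name]["GT"] = (None, None)
                else:
                    try:
                        rec.samples[name]["GT"] = (index_of[a], index_of[b])
                    except KeyError:
                        raise ValueError(
                            f"locus {locus.id}: call {ALLELES[a]}{ALLELES[b]} uses an "
                            "allele absent from ref/alts"
                        ) from None
                if matrix.depths is not None:
                    rec.samples[name]["DP"] = int(matrix.depths[i, j])
            out.write(rec)


# ---------------------------------------------------------------------------
# GENEPOP
# ---------------------------------------------------------------------------

def write_genepop(matrix: GenotypeMatrix, groups: GroupLabels, path: str | Path) -> None:
    """Write a GENEPOP file, one ``Pop`` block per group.

    Alleles are coded A=01, C=02, G=03, T=04; a missing call is ``0000``.
    """
    groups.validate_against(matrix)
    for locus in matrix.loci:
        if len(locus.alleles) > 4:
            raise ValueError(f"locus {locus.id}: more than 4 alleles not representable")
    lines = ["sebpanel genotype export"]
    lines += [locus.id for locus in matrix.loci]
    for group in groups.group_names:
        lines.append("Pop")
        for ind in groups.members(group):
            i = matrix.individual_index(ind)
            tokens = []
            for j in range(matrix.n_loci):
                a, b = (int(x) for x in matrix.calls[i, j])
                if a == MISSING_CODE:
                    tokens.append("0000")
                else:
                    tokens.append(_GENEPOP_CODE[ALLELES[a]] + _GENEPOP_CODE[ALLELES[b]])
            lines.append(f"{ind} ,  " + " ".join(tokens))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path: str | Path) -> tuple[GenotypeMatrix, GroupLabels]:
    """Read a GENEPOP file written by :func:`write_genepop`.

    Pop blocks become groups named after their first individual's block
    order (``pop1``, ``pop2``, ...) since GENEPOP stores no group names.
    """
    raw = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    if len(raw) < 3:
        raise ValueError(f"{path}: not a GENEPOP file")
    body = raw[1:]
    locus_ids: list[str] = []
    k = 0
    while k < len(body) and body[k].strip().lower() != "pop":
        locus_ids.extend(t.strip() for t in body[k].split(",") if t.strip())
        k += 1
    individuals: list[str] = []
    groups: dict[str, str] = {}
    rows: list[list[str]] = []
    pop = 0
    for line_no, line in enumerate(body[k:], start=k + 2):
        if not line.strip():
            continue
        if line.strip().lower() == "pop":
            pop += 1
            continue
        if "," not in line:
            raise ValueError(f"{path} line {line_no}: expected 'name , genotypes'")
        name, geno = line.split(",", 1)
        name = name.strip()
        tokens = geno.split()
        if len(tokens) != len(locus_ids):
            raise ValueError(
                f"{path} line {line_no}: {len(tokens)} genotypes for "
                f"{len(locus_ids)} loci"
            )
        individuals.append(name)
        groups[name] = f"pop{pop}"
        row = []
        for tok in tokens:
            if len(tok) != 4:
                raise ValueError(f"{path} line {line_no}: bad genotype token {tok!r}")
            if tok == "0000":
                row.append("NN")
            else:
                row.append(_GENEPOP_DECODE[tok[:2]] + _GENEPOP_DECODE[tok[2:]])
        rows.append(row)
    matrix = _matrix_from_tokens(individuals, locus_ids, rows)
    return matrix, GroupLabels(groups)


# ---------------------------------------------------------------------------
# CSV genotype tables
# ---------------------------------------------------------------------------

def read_table(path: str | Path) -> tuple[GenotypeMatrix, GroupLabels]:
    """Read a delimited genotype table.

    Dialect: comma-separated; first column the individual label, second the
    group, remaining columns loci named in the header. A locus occupies one
    two-character genotype column (``CT``) or two single-allele columns with
    a repeated header name. Unparseable genotype tokens become missing and
    are counted in ``meta["unparsed_tokens"]``; ragged rows are an error.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if len(header) < 3:
            raise ValueError(f"{path}: need id, group and at least one locus column")
        # Consecutive repeats of a header name mean a two-column locus.
        layout: list[tuple[str, int]] = []  # (locus id, n columns)
        cols = header[2:]
        c = 0
        while c < len(cols):
            if c + 1 < len(cols) and cols[c + 1] == cols[c]:
                layout.append((cols[c], 2))
                c += 2
            else:
                layout.append((cols[c], 1))
                c += 1
        width = 2 + sum(w for _, w in layout)

        individuals: list[str] = []
        mapping: dict[str, str] = {}
        rows: list[list[str]] = []
        unparsed = 0
        for row_no, cells in enumerate(reader, start=2):
            if not cells or not any(cell.strip() for cell in cells):
                continue
            if len(cells) != width:
                raise ValueError(
                    f"{path} row {row_no}: expected {width} fields, got {len(cells)}"
                )
            ind = cells[0].strip()
            if ind in mapping:
                raise ValueError(f"{path} row {row_no}: duplicated individual {ind!r}")
            individuals.append(ind)
            mapping[ind] = cells[1].strip()
            tokens = []
            c = 2
            for _, w in layout:
                raw = cells[c] if w == 1 else cells[c] + cells[c + 1]
                c += w
                try:
                    tokens.append(str(Genotype.from_string(raw)))
                except ValueError:
                    tokens.append("NN")
                    unparsed += 1
            rows.append(tokens)

    if unparsed:
        warnings.warn(f"{path}: {unparsed} unparseable genotype tokens set to missing",
                      stacklevel=2)
    matrix = _matrix_from_tokens(individuals, [lid for lid, _ in layout], rows)
    matrix.meta["unparsed_tokens"] = unparsed
    return matrix, GroupLabels(mapping)


def write_table(matrix: GenotypeMatrix, groups: GroupLabels, path: str | Path) -> None:
    """Write the one-column-per-locus CSV dialect read by :func:`read_table`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "group"] + [l.id for l in matrix.loci])
        for i, ind in enumerate(matrix.individuals):
            row = [ind, groups.mapping.get(ind, "")]
            for j in range(matrix.n_loci):
                a, b = (int(x) for x in matrix.calls[i, j])
                row.append("NN" if a == MISSING_CODE else ALLELES[a] + ALLELES[b])
            writer.writerow(row)


def read_group_labels(path: str | Path) -> GroupLabels:
    """Read a two-column ``individual,group`` CSV (header optional)."""
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row_no, cells in enumerate(csv.reader(fh), start=1):
            if not cells or not any(c.strip() for c in cells):
                continue
            if len(cells) < 2:
                raise ValueError(f"{path} row {row_no}: expected individual,group")
            ind, grp = cells[0].strip(), cells[1].strip()
            if row_no == 1 and ind.lower() in {"id", "individual", "sample"}:
                continue
            mapping[ind] = grp
    return GroupLabels(mapping)


def write_group_labels(groups: GroupLabels, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["individual", "group"])
        for ind, grp in groups.mapping.items():
            writer.writerow([ind, grp])


# ---------------------------------------------------------------------------

def _matrix_from_tokens(
    individuals: list[str], locus_ids: list[str], rows: list[list[str]]
) -> GenotypeMatrix:
    """Build a matrix from genotype tokens, inferring ref/alts per locus."""
    n, L = len(individuals), len(locus_ids)
    calls = np.full((n, L, 2), MISSING_CODE, dtype=np.int8)
    for i, row in enumerate(rows):
        for j, tok in enumerate(row):
            calls[i, j] = Genotype.from_string(tok).codes()
    calls = _normalise_codes(calls)
    loci = []
    for j, lid in enumerate(locus_ids):
        observed = sorted(
            {int(c) for c in calls[:, j].ravel() if c != MISSING_CODE}
        )
        symbols = [ALLELES[c] for c in observed] or ["A"]
        loci.append(
            LocusInfo(
                id=lid,
                contig=lid,
                position=1,
                ref=symbols[0],
                alts=tuple(symbols[1:]),
                qual=0.0,
            )
        )
    return GenotypeMatrix(individuals, loci, calls)
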