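"""Readers and writers for the panel's file formats.

Formats supported:

* genotype table — tab-delimited, one marker per row, header
  ``marker_id chrom pos allele_a allele_b <acc_1> ... <acc_n>`` with call
  tokens ``AA``/``BB``/``AB``/``NN``;
* accession metadata sidecar — tab-delimited
  ``accession_id country region chrono_class western_flag year``;
* chromosome table — tab-delimited ``name genome group length_bp``;
* VCF v4.2 (biallelic SNPs, GT only; read via cyvcf2, written as plain text);
* STRUCTURE one-row-per-individual input (two allele columns per marker,
  codes 1/2, missing -9).
"""

from __future__ import annotations

import logging
import os
import tempfile

import numpy as np
import pandas as pd

from .matrix import (
    ACCESSION_COLUMNS,
    CHROMOSOMES,
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    ChromosomeTable,
    GenotypeMatrix,
    PanelFormatError,
    make_accession_frame,
)

logger = logging.getLogger(__name__)

TOKEN_TO_CODE = {"AA": int(HOM_A), "AB": int(HET), "BB": int(HOM_B), "NN": int(MISSING)}
CODE_TO_TOKEN = {v: k for k, v in TOKEN_TO_CODE.items()}


def atomic_write_text(path, text: str) -> None:
    """Write a text file via a temp file + rename so partial runs stay clean."""
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# genotype table


def read_genotype_table(path, metadata=None) -> GenotypeMatrix:
    """Read the tab-delimited genotype-table dialect.

    Markers are returned sorted by (chromosome, position, marker_id).
    ``metadata`` may be a path to the metadata sidecar or a pre-built
    accession frame; otherwise default metadata is attached.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if cols[:5] != ["marker_id", "chrom", "pos", "allele_a", "allele_b"]:
            raise PanelFormatError(
                f"{path}: bad genotype-table header (first five columns must be "
                "marker_id chrom pos allele_a allele_b)"
            )
        acc_ids = cols[5:]
        if not acc_ids:
            raise PanelFormatError(f"{path}: no accession columns in header")
        if len(set(acc_ids)) != len(acc_ids):
            dup = pd.Index(acc_ids)[pd.Index(acc_ids).duplicated()][0]
            raise PanelFormatError(f"{path}: duplicate accession id {dup!r}")

        marker_rows, call_rows, seen = [], [], set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5 + len(acc_ids):
                raise PanelFormatError(
                    f"{path}:{lineno}: expected {5 + len(acc_ids)} fields, got {len(parts)}"
                )
            mid, chrom, pos, a, b = parts[:5]
            if mid in seen:
                raise PanelFormatError(f"{path}:{lineno}: duplicate marker id {mid!r}")
            seen.add(mid)
            try:
                codes = [TOKEN_TO_CODE[t] for t in parts[5:]]
            except KeyError as e:
                raise PanelFormatError(
                    f"{path}:{lineno}: unknown call token {e.args[0]!r}"
                ) from None
            marker_rows.append((mid, chrom, int(pos), a, b))
            call_rows.append(codes)

    if not marker_rows:
        raise PanelFormatError(f"{path}: empty data section")

    markers = pd.DataFrame(
        marker_rows, columns=["marker_id", "chrom", "pos", "allele_a", "allele_b"]
    ).set_index("marker_id")
    calls = np.asarray(call_rows, dtype=np.int8).T  # accessions x markers

    if metadata is None:
        accessions = make_accession_frame(acc_ids)
    elif isinstance(metadata, pd.DataFrame):
        accessions = metadata.loc[acc_ids]
    else:
        accessions = read_accession_metadata(metadata).loc[acc_ids]
    return GenotypeMatrix(accessions, markers, calls).sort_markers()


def write_genotype_table(gm: GenotypeMatrix, path) -> None:
    lines = ["\t".join(["marker_id", "chrom", "pos", "allele_a", "allele_b"] + gm.accession_ids)]
    calls = gm.calls
    for j, (mid, row) in enumerate(gm.markers.iterrows()):
        tokens = [CODE_TO_TOKEN[int(c)] for c in calls[:, j]]
        lines.append(
            "\t".join([mid, str(row.chrom), str(int(row.pos)), row.allele_a, row.allele_b] + tokens)
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# metadata and chromosome tables


def read_accession_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"accession_id": str})
    required = ["accession_id"] + ACCESSION_COLUMNS
    missing = set(required) - set(df.columns)
    if missing:
        raise PanelFormatError(f"{path}: metadata missing columns {sorted(missing)}")
    df = df.set_index("accession_id")
    df["western_flag"] = df["western_flag"].astype(bool)
    df["year"] = df["year"].astype("Int64")
    return df[ACCESSION_COLUMNS]


def write_accession_metadata(accessions: pd.DataFrame, path) -> None:
    out = accessions.reset_index()
    out.columns = ["accession_id"] + list(accessions.columns)
    atomic_write_text(path, out.to_csv(sep="\t", index=False))


def read_chromosome_table(path) -> ChromosomeTable:
    df = pd.read_csv(path, sep="\t")
    required = {"name", "genome", "group", "length_bp"}
    missing = required - set(df.columns)
    if missing:
        raise PanelFormatError(f"{path}: chromosome table missing columns {sorted(missing)}")
    df = df.rename(columns={"group": "homoeo_group"}).set_index("name")
    return ChromosomeTable(df[["genome", "homoeo_group", "length_bp"]])


def write_chromosome_table(ct: ChromosomeTable, path) -> None:
    out = ct.table.reset_index()
    out = out.rename(columns={"homoeo_group": "group"})[["name", "genome", "group", "length_bp"]]
    atomic_write_text(path, out.to_csv(sep="\t", index=False))


# ---------------------------------------------------------------------------
# VCF


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT-only biallelic SNP records."""
    header = [
        "##fileformat=VCFv4.2",
        "##source=wheatdiv",
    ]
    for chrom in list(dict.fromkeys(gm.markers["chrom"])):
        header.append(f"##contig=<ID={chrom}>")
    header.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.accession_ids)
    )
    gt_map = {int(HOM_A): "0/0", int(HET): "0/1", int(HOM_B): "1/1", int(MISSING): "./."}
    lines = header
    for j, (mid, row) in enumerate(gm.markers.iterrows()):
        gts = [gt_map[int(c)] for c in gm.calls[:, j]]
        lines.append(
            f"{row.chrom}\t{int(row.pos)}\t{mid}\t{row.allele_a}\t{row.allele_b}"
            "\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_vcf(path, metadata=None, on_multiallelic: str = "skip") -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF via cyvcf2.

    Multi-allelic records are skipped (with a logged count) or raise,
    per ``on_multiallelic`` in {"skip", "error"}. Non-SNP ALTs are skipped
    with a logged count. Records without GT raise.
    """
    from cyvcf2 import VCF

    if on_multiallelic not in ("skip", "error"):
        raise ValueError("on_multiallelic must be 'skip' or 'error'")
    vcf = VCF(str(path))
    acc_ids = list(vcf.samples)
    if not acc_ids:
        raise PanelFormatError(f"{path}: VCF has no samples")

    marker_rows, call_rows = [], []
    n_multi = n_nonsnp = 0
    for var in vcf:
        if len(var.ALT) != 1:
            if on_multiallelic == "error":
                raise PanelFormatError(f"{path}: multi-allelic record at {var.CHROM}:{var.POS}")
            n_multi += 1
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref == "." or alt == ".":
            n_nonsnp += 1
            continue
        if var.format("GT") is None and var.gt_types is None:
            raise PanelFormatError(f"{path}: record without GT at {var.CHROM}:{var.POS}")
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN/missing, 3=HOM_ALT
        codes = np.select(
            [var.gt_types == 0, var.gt_types == 1, var.gt_types == 3],
            [int(HOM_A), int(HET), int(HOM_B)],
            default=int(MISSING),
        ).astype(np.int8)
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        marker_rows.append((mid, var.CHROM, int(var.POS), ref, alt))
        call_rows.append(codes)
    vcf.close()
    if n_multi or n_nonsnp:
        logger.info("read_vcf: skipped %d multi-allelic and %d non-SNP records", n_multi, n_nonsnp)
    if not marker_rows:
        raise PanelFormatError(f"{path}: no usable biallelic SNP records")

    markers = pd.DataFrame(
        marker_rows, columns=["marker_id", "chrom", "pos", "allele_a", "allele_b"]
    ).set_index("marker_id")
    if markers.index.duplicated().any():
        dup = markers.index[markers.index.duplicated()][0]
        raise PanelFormatError(f"{path}: duplicate marker id {dup!r}")
    calls = np.asarray(call_rows, dtype=np.int8).T
    if metadata is None:
        accessions = make_accession_frame(acc_ids)
    elif isinstance(metadata, pd.DataFrame):
        accessions = metadata.loc[acc_ids]
    else:
        accessions = read_accession_metadata(metadata).loc[acc_ids]
    return GenotypeMatrix(accessions, markers, calls).sort_markers()


# ---------------------------------------------------------------------------
# STRUCTURE input


def write_structure_file(gm: GenotypeMatrix, path) -> None:
    """One row per accession: id then two allele-code columns per marker.

    Allele codes are 1 (allele_a) and 2 (allele_b); missing is -9 -9;
    heterozygous calls are written as 1 2.
    """
    pair = {
        int(HOM_A): ("1", "1"),
        int(HET): ("1", "2"),
        int(HOM_B): ("2", "2"),
        int(MISSING): ("-9", "-9"),
    }
    lines = []
    for i, acc in enumerate(gm.accession_ids):
        fields = [acc]
        for c in gm.calls[i]:
            fields.extend(pair[int(c)])
        lines.append(" ".join(fields))
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_structure_file(path, markers: pd.DataFrame, metadata=None) -> GenotypeMatrix:
    """Decode a STRUCTURE input file back into a GenotypeMatrix.

    The marker frame supplies ids, positions and alleles (STRUCTURE files
    carry neither). Mainly used for round-trip verification.
    """
    acc_ids, rows = [], []
    code = {("1", "1"): int(HOM_A), ("1", "2"): int(HET), ("2", "1"): int(HET),
            ("2", "2"): int(HOM_B), ("-9", "-9"): int(MISSING)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            acc_ids.append(parts[0])
            alleles = parts[1:]
            if len(alleles) != 2 * len(markers):
                raise PanelFormatError(
                    f"{path}:{lineno}: expected {2 * len(markers)} allele columns, "
                    f"got {len(alleles)}"
                )
            try:
                rows.append(
                    [code[(alleles[2 * j], alleles[2 * j + 1])] for j in range(len(markers))]
                )
            except KeyError as e:
                raise PanelFormatError(f"{path}:{lineno}: bad allele pair {e.args[0]}") from None
    accessions = (
        make_accession_frame(acc_ids)
        if metadata is None
        else (metadata if isinstance(metadata, pd.DataFrame) else read_accession_metadata(metadata)).loc[acc_ids]
    )
    return GenotypeMatrix(accessions, markers, np.asarray(rows, dtype=np.int8))
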