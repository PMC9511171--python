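"""Readers and writers for every external representation the pipeline touches.

Supported inputs
----------------
* VCF 4.x genotype matrices (only the GT field is consulted; multi-allelic
  records and indels are dropped with a logged count).
* ``snp_table`` — a tab-separated sample x marker table in the style of
  portal genotype exports: first column sample id, header row of marker ids,
  cells holding two-letter genotypes ("CC", "CA"), single bases, or a
  missing-data token ("N", "-", ".", "./.", ".|."). Optional ``##variant``
  comment lines pin down id/chrom/pos/ref/alt per marker; without them the
  reference allele is inferred as the majority base of the column.
* Tab-separated phenotype and sample-metadata tables.

All outputs are TSV with a ``#``-prefixed comment header recording the tool
version and the parameters of the run.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    ALT,
    HET,
    MISSING,
    REF,
    IUPAC_BASES,
    SUBPOPULATIONS,
    GRAIN_CLASSES,
    SampleMeta,
    Variant,
    VariantMatrix,
    validate_phenotypes,
)
from .errors import FormatError

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"N", "-", ".", "./.", ".|.", "NN", "--"}


def _comment_header(kind: str, params: dict | None = None) -> str:
    lines = [f"# haplopanel {kind} v{__version__}"]
    for key, value in (params or {}).items():
        lines.append(f"# {key}={value}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# genotype matrices
# ---------------------------------------------------------------------------

def read_variant_matrix(path, format: str = "vcf") -> VariantMatrix:
    """Read a genotype matrix for one region.

    Parameters
    ----------
    path : path-like
        Input file.
    format : {"vcf", "snp_table"}
        Input dialect.

    Returns
    -------
    VariantMatrix
        Biallelic SNP calls; dropped multi-allelic/indel record counts are
        recorded in ``provenance``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"genotype file not found: {path}")
    if format == "vcf":
        return _read_vcf(path)
    if format == "snp_table":
        return _read_snp_table(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> VariantMatrix:
    from cyvcf2 import VCF

    reader = VCF(str(path), gts012=True)
    samples = list(reader.samples)
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    multiallelic_dropped = 0
    indel_dropped = 0
    code = {0: REF, 1: HET, 2: ALT, 3: MISSING}
    for rec in reader:
        if len(rec.ALT) != 1:
            multiallelic_dropped += 1
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in IUPAC_BASES or alt not in IUPAC_BASES:
            indel_dropped += 1
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(Variant(vid, rec.CHROM, rec.POS, ref, alt))
        columns.append(np.array([code[g] for g in rec.gt_types], dtype=np.int8))
    reader.close()
    if multiallelic_dropped:
        logger.warning("%s: dropped %d multi-allelic record(s)", path, multiallelic_dropped)
    if indel_dropped:
        logger.warning("%s: dropped %d indel/non-SNP record(s)", path, indel_dropped)
    calls = (
        np.column_stack(columns)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    matrix = VariantMatrix(samples, variants, calls)
    matrix.provenance.update(
        multiallelic_dropped=multiallelic_dropped, indel_dropped=indel_dropped
    )
    return matrix


def _parse_variant_comments(path: Path) -> list[Variant]:
    variants = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("##variant\t"):
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 6:
                    raise FormatError(f"{path}: malformed ##variant line: {line!r}")
                _, vid, chrom, pos, ref, alt = fields
                variants.append(Variant(vid, chrom, int(pos), ref, alt))
    return variants


def _infer_column_variant(marker: str, ordinal: int, cells: pd.Series) -> Variant:
    counts: dict[str, int] = {}
    for cell in cells:
        token = str(cell).strip().upper()
        if token in MISSING_TOKENS:
            continue
        for base in token:
            if base in IUPAC_BASES:
                counts[base] = counts.get(base, 0) + 1
    if len(counts) > 2:
        raise FormatError(f"marker {marker}: more than two alleles observed")
    ordered = sorted(counts, key=lambda b: (-counts[b], b))
    ref = ordered[0] if ordered else "A"
    if len(ordered) == 2:
        alt = ordered[1]
    else:  # monomorphic column: pick a deterministic placeholder alt
        alt = next(b for b in "ACGT" if b != ref)
    return Variant(marker, ".", ordinal, ref, alt)


def _read_snp_table(path: Path) -> VariantMatrix:
    declared = _parse_variant_comments(path)
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if table.shape[1] < 1:
        raise FormatError(f"{path}: snp_table has no columns")
    sample_col = table.columns[0]
    markers = list(table.columns[1:])
    samples = [str(s).strip() for s in table[sample_col]]

    if declared:
        by_id = {v.id: v for v in declared}
        unknown = [m for m in markers if m not in by_id]
        if unknown:
            raise FormatError(f"{path}: markers missing a ##variant line: {unknown}")
        variants = [by_id[m] for m in markers]
    else:
        variants = [
            _infer_column_variant(m, j + 1, table[m]) for j, m in enumerate(markers)
        ]

    calls = np.empty((len(samples), len(markers)), dtype=np.int8)
    for j, (marker, variant) in enumerate(zip(markers, variants)):
        ref, alt = variant.ref_allele, variant.alt_allele
        for i, cell in enumerate(table[marker]):
            token = str(cell).strip().upper()
            if token in MISSING_TOKENS:
                calls[i, j] = MISSING
                continue
            if len(token) == 1:
                pair = token + token
            elif len(token) == 2:
                pair = token
            else:
                raise FormatError(
                    f"{path}: sample {samples[i]}, marker {marker}: bad cell {cell!r}"
                )
            for base in pair:
                if base not in (ref, alt):
                    raise FormatError(
                        f"{path}: sample {samples[i]}, marker {marker}: base {base!r} "
                        f"matches neither ref {ref!r} nor alt {alt!r}"
                    )
            if pair == ref + ref:
                calls[i, j] = REF
            elif pair == alt + alt:
                calls[i, j] = ALT
            else:
                calls[i, j] = HET
    return VariantMatrix(samples, variants, calls)


def write_variant_matrix(matrix: VariantMatrix, path, format: str = "vcf") -> None:
    """Write a genotype matrix as VCF 4.2 (GT only) or as a snp_table."""
    path = Path(path)
    if format == "vcf":
        _write_vcf(matrix, path)
    elif format == "snp_table":
        _write_snp_table(matrix, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


_GT = {REF: "0/0", ALT: "1/1", HET: "0/1", MISSING: "./."}


def _write_vcf(matrix: VariantMatrix, path: Path) -> None:
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write(f"##source=haplopanel {__version__}\n")
        for chrom in dict.fromkeys(v.chrom for v in matrix.variants):
            out.write(f"##contig=<ID={chrom}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j, v in enumerate(matrix.variants):
            gts = "\t".join(_GT[c] for c in matrix.calls[:, j])
            out.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def _write_snp_table(matrix: VariantMatrix, path: Path) -> None:
    with open(path, "w") as out:
        out.write("##snp_table\n")
        for v in matrix.variants:
            out.write(
                f"##variant\t{v.id}\t{v.chrom}\t{v.pos}\t{v.ref_allele}\t{v.alt_allele}\n"
            )
        out.write("sample_id\t" + "\t".join(matrix.variant_ids) + "\n")
        for i, sample in enumerate(matrix.samples):
            cells = []
            for j, v in enumerate(matrix.variants):
                call = matrix.calls[i, j]
                if call == REF:
                    cells.append(v.ref_allele * 2)
                elif call == ALT:
                    cells.append(v.alt_allele * 2)
                elif call == HET:
                    cells.append(v.ref_allele + v.alt_allele)
                else:
                    cells.append("N")
            out.write(sample + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# phenotypes and metadata
# ---------------------------------------------------------------------------

def read_phenotypes(path, trait: str = "grain_length") -> pd.DataFrame:
    """Read a tab-separated phenotype file.

    Expected columns: ``sample_id`` and ``value`` (header required), with
    optional ``environment`` and ``trait`` columns. When no ``trait`` column
    is present every row is assigned the ``trait`` argument. Rows whose value
    does not parse as a number are dropped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"phenotype file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.shape[1] == 0:
        logger.warning("%s: empty phenotype file", path)
        return pd.DataFrame(columns=["sample_id", "trait", "environment", "value"])
    if "sample_id" not in df.columns or "value" not in df.columns:
        # two-column headerless-style export: sample id then value
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype=str, keep_default_na=False, header=None
        )
        if df.shape[1] != 2:
            raise FormatError(
                f"{path}: expected 'sample_id'/'value' columns or a two-column table"
            )
        df.columns = ["sample_id", "value"]
        # drop a stray header row if present
        if not _is_number(df.iloc[0, 1]):
            df = df.iloc[1:]
    if "trait" not in df.columns:
        df["trait"] = trait
    if "environment" not in df.columns:
        df["environment"] = ""
    numeric = pd.to_numeric(df["value"], errors="coerce")
    bad = numeric.isna() & df["value"].astype(str).str.strip().ne("")
    if bad.any():
        logger.warning(
            "%s: dropped %d row(s) with unparseable values", path, int(bad.sum())
        )
    df = df[~numeric.isna()].copy()
    df["value"] = numeric[~numeric.isna()]
    if df.empty:
        logger.warning("%s: no phenotype rows parsed", path)
        return pd.DataFrame(columns=["sample_id", "trait", "environment", "value"])
    return validate_phenotypes(df)


def _is_number(token) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def write_phenotypes(df: pd.DataFrame, path) -> None:
    with open(path, "w") as out:
        out.write(_comment_header("phenotypes"))
        df.to_csv(out, sep="\t", index=False)


def read_sample_meta(path) -> list[SampleMeta]:
    """Read a tab-separated sample metadata file.

    Expected columns: ``sample_id`` plus optional ``subpopulation``,
    ``grain_class`` and ``release_year``; unlisted fields default to
    "unknown". Unknown category spellings raise a format error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: metadata requires a 'sample_id' column")
    out: list[SampleMeta] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        if sid in seen:
            raise FormatError(f"{path}: duplicate sample id {sid!r}")
        seen.add(sid)
        year_raw = str(row.get("release_year", "")).strip()
        out.append(
            SampleMeta(
                sample_id=sid,
                subpopulation=str(row.get("subpopulation", "unknown")).strip() or "unknown",
                grain_class=str(row.get("grain_class", "unknown")).strip() or "unknown",
                release_year=int(year_raw) if year_raw else None,
            )
        )
    return out


def write_sample_meta(meta: Iterable[SampleMeta], path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "subpopulation": m.subpopulation,
            "grain_class": m.grain_class,
            "release_year": "" if m.release_year is None else m.release_year,
        }
        for m in meta
    ]
    with open(path, "w") as out:
        out.write(_comment_header("sample_meta"))
        pd.DataFrame(rows).to_csv(out, sep="\t", index=False)


# ---------------------------------------------------------------------------
# haplotype reports and group definitions
# ---------------------------------------------------------------------------

def write_haplotype_report(partition, meta: Iterable[SampleMeta] | None, path,
                           params: dict | None = None) -> None:
    """Serialize a haplotype partition as a TSV report.

    One row per named haplotype group (member count, panel frequency,
    per-subpopulation counts, allele vector spelled in bases), followed by
    Rare, Unclassified and (if present) Novel rows. Samples absent from the
    metadata are counted under subpopulation "unknown".
    """
    lookup = {m.sample_id: m for m in meta} if meta is not None else {}
    total = len(partition.assignments)
    subpop_cols = list(SUBPOPULATIONS)
    grain_cols = [f"grain_{g}" for g in GRAIN_CLASSES]

    def subpop_counts(sample_ids):
        counts = dict.fromkeys(subpop_cols, 0)
        grains = dict.fromkeys(grain_cols, 0)
        for sid in sample_ids:
            m = lookup.get(sid)
            counts[m.subpopulation if m else "unknown"] += 1
            grains[f"grain_{m.grain_class if m else 'unknown'}"] += 1
        return counts, grains

    members: dict[str, list[str]] = {}
    for sid, label in partition.assignments.items():
        members.setdefault(label, []).append(sid)

    rows = []
    for group in partition.groups:
        vector = "".join(
            v.base_for(a) for v, a in zip(partition.variants, group.alleles)
        )
        counts, grains = subpop_counts(members.get(group.label, []))
        rows.append(
            {
                "group": group.label,
                "n": group.member_count,
                "frequency": group.member_count / total if total else 0.0,
                "allele_vector": vector,
                **counts,
                **grains,
            }
        )
    for label, ids in (
        ("Rare", sorted(partition.rare_samples)),
        ("Unclassified", sorted(partition.unclassified_samples)),
    ):
        counts, grains = subpop_counts(ids)
        rows.append(
            {
                "group": label,
                "n": len(ids),
                "frequency": len(ids) / total if total else 0.0,
                "allele_vector": ".",
                **counts,
                **grains,
            }
        )
    if getattr(partition, "novel_samples", None):
        ids = sorted(partition.novel_samples)
        counts, grains = subpop_counts(ids)
        rows.append(
            {
                "group": "Novel",
                "n": len(ids),
                "frequency": len(ids) / total if total else 0.0,
                "allele_vector": ".",
                **counts,
                **grains,
            }
        )
    with open(path, "w") as out:
        out.write(_comment_header("haplotype_report", params))
        pd.DataFrame(
            rows,
            columns=["group", "n", "frequency", "allele_vector"]
            + subpop_cols
            + grain_cols,
        ).to_csv(out, sep="\t", index=False, float_format="%.6g")


def read_haplotype_report(path) -> pd.DataFrame:
    """Parse a haplotype report back into a DataFrame (round-trip helper)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"group": str})
    df["n"] = df["n"].astype(int)
    return df


def write_group_definitions(groups, variants, path) -> None:
    """Export named haplotype groups as (label, snp, allele) rows.

    The export carries enough variant metadata (chrom/pos/ref/alt) for a
    reference panel's groups to be re-applied to any other panel.
    """
    rows = []
    for group in groups:
        for v, allele in zip(variants, group.alleles):
            rows.append(
                {
                    "label": group.label,
                    "snp_id": v.id,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref_allele,
                    "alt": v.alt_allele,
                    "allele": v.base_for(allele),
                    "member_count": group.member_count,
                }
            )
    with open(path, "w") as out:
        out.write(_comment_header("group_definitions"))
        pd.DataFrame(rows).to_csv(out, sep="\t", index=False)


def read_group_definitions(path):
    """Read a group-definition TSV back into (groups, variants)."""
    from .haplotyping import HaplotypeGroup

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"label": str})
    first = df[df["label"] == df["label"].iloc[0]]
    variants = [
        Variant(r.snp_id, str(r.chrom), int(r.pos), r.ref, r.alt)
        for r in first.itertuples()
    ]
    order = {v.id: k for k, v in enumerate(variants)}
    groups = []
    for label, sub in df.groupby("label", sort=False):
        alleles = np.full(len(variants), MISSING, dtype=np.int8)
        for r in sub.itertuples():
            j = order[r.snp_id]
            alleles[j] = REF if r.allele == variants[j].ref_allele else ALT
        if (alleles == MISSING).any():
            raise FormatError(f"{path}: group {label} does not cover every SNP")
        groups.append(
            HaplotypeGroup(
                label=str(label),
                alleles=alleles,
                member_count=int(sub["member_count"].iloc[0]),
            )
        )
    return groups, variants
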