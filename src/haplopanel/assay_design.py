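"""KASP-ready SNP context extraction.

A KASP (Kompetitive Allele-Specific PCR) assay is ordered from a SNP plus
~100 bp of flanking sequence on each side, written in the bracketed-allele
dialect ``<upstream>[REF/ALT]<downstream>``. Assays are emitted on the
forward strand of the supplied reference; no primer design is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .core import Variant
from .errors import BoundaryError, ConsistencyError


@dataclass
class FlankRequest:
    """One SNP's flank-extraction request against an indexed reference."""

    variant: Variant
    reference: object  # pyfaidx.Fasta or any mapping chrom -> sequence
    flank_length: int = 100

    def __post_init__(self):
        if self.flank_length < 1:
            raise ValueError("flank_length must be >= 1")


def _contig(reference, chrom: str):
    try:
        return reference[chrom]
    except KeyError:
        raise BoundaryError(f"reference has no contig {chrom!r}") from None


def extract_flanks(req: FlankRequest) -> str:
    """Extract ``flank + [REF/ALT] + flank`` around one SNP.

    The returned string is uppercase; for single-base alleles its length is
    ``2 * flank_length + 7``. The reference base at the SNP position must
    equal the variant's declared ref allele.

    Raises
    ------
    BoundaryError
        If either flank would run past the contig edge (no padding).
    ConsistencyError
        If the reference base disagrees with the declared ref allele.
    """
    v = req.variant
    contig = _contig(req.reference, v.chrom)
    length = len(contig)
    if v.pos - req.flank_length < 1 or v.pos + req.flank_length > length:
        raise BoundaryError(
            f"{v.id}: flanks of {req.flank_length} bp around position {v.pos} "
            f"exceed contig {v.chrom} (length {length})"
        )
    seq = str(contig[v.pos - req.flank_length - 1 : v.pos + req.flank_length]).upper()
    upstream = seq[: req.flank_length]
    site = seq[req.flank_length]
    downstream = seq[req.flank_length + 1 :]
    if site != v.ref_allele.upper():
        raise ConsistencyError(
            f"{v.id}: reference base {site!r} at {v.chrom}:{v.pos} does not "
            f"match declared ref allele {v.ref_allele!r}"
        )
    return f"{upstream}[{v.ref_allele}/{v.alt_allele}]{downstream}"


def write_assay_table(variants, fasta_path, out_path, flank_length: int = 100) -> pd.DataFrame:
    """Extract flanks for a list of SNPs from a FASTA and write an assay TSV."""
    from pyfaidx import Fasta

    reference = Fasta(str(fasta_path))
    rows = []
    for v in variants:
        assay = extract_flanks(FlankRequest(v, reference, flank_length))
        rows.append({"snp_id": v.id, "chrom": v.chrom, "pos": v.pos, "assay": assay})
    df = pd.DataFrame(rows)
    Path(out_path).write_text(
        "# haplopanel assay_table\n" + df.to_csv(sep="\t", index=False)
    )
    return df
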