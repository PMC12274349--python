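"""In-silico mutational saturation of a transcript region.

Every position of the chosen 5'UTR interval is substituted by each of the
three alternative nucleotides, producing an ordered, duplicate-free list of
transcript-space SNVs — 3 × region length variants in total. The list can be
round-tripped through a transcript-space VCF 4.2 file (CONTIG = transcript
id, POS = 1-based offset into utr5+cds, INFO/HGVSC = c. notation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

from .transcript import (
    CoordinateError,
    TranscriptModel,
    c_to_index,
)

__all__ = ["Snv", "VcfValidationError", "make_snv", "enumerate_snvs", "write_vcf", "read_vcf"]

BASES = "ACGT"


class VcfValidationError(ValueError):
    """A VCF record is inconsistent with the transcript sequence."""


@dataclass(frozen=True)
class Snv:
    """A single-nucleotide variant in HGVS c. space; ``ref`` must equal the
    transcript base at ``c_pos`` and ``alt`` must differ from it."""

    c_pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be A/C/G/T, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"alt equals ref ({self.ref}) at c.{self.c_pos}")

    @property
    def hgvs_c(self) -> str:
        return f"c.{self.c_pos}{self.ref}>{self.alt}"


def make_snv(t: TranscriptModel, c_pos: int, alt: str) -> Snv:
    """Build an SNV at ``c_pos``, reading the reference base from ``t``."""
    ref = t.seq[c_to_index(t, c_pos)]
    return Snv(c_pos=c_pos, ref=ref, alt=alt)


def validate_snv(t: TranscriptModel, snv: Snv) -> None:
    ref = t.seq[c_to_index(t, snv.c_pos)]
    if ref != snv.ref:
        raise VcfValidationError(
            f"REF mismatch at c.{snv.c_pos}: variant says {snv.ref}, transcript has {ref}"
        )


def apply_snv(t: TranscriptModel, snv: Snv) -> TranscriptModel:
    """Return a new transcript with the (5'UTR) variant applied."""
    validate_snv(t, snv)
    i = c_to_index(t, snv.c_pos)
    if i >= t.utr5_len:
        raise CoordinateError(f"c.{snv.c_pos} is not in the 5'UTR")
    utr5 = t.utr5[:i] + snv.alt + t.utr5[i + 1 :]
    return TranscriptModel(id=t.id, utr5=utr5, cds=t.cds, utr3=t.utr3)


def enumerate_snvs(
    t: TranscriptModel,
    region: Optional[Tuple[int, int]] = None,
) -> List[Snv]:
    """All possible SNVs in ``region`` (default: the whole 5'UTR), ordered
    by position 5'→3' then by alternative base (A<C<G<T)."""
    L = t.utr5_len
    lo, hi = region if region is not None else (-L, -1)
    if lo == 0 or hi == 0:
        raise CoordinateError("there is no position c.0")
    if not (-L <= lo <= hi <= -1):
        raise CoordinateError(
            f"region c.{lo}..c.{hi} is not within the 5'UTR (c.{-L}..c.-1)"
        )
    out: List[Snv] = []
    for c in range(lo, hi + 1):
        ref = t.utr5[c_to_index(t, c)]
        for alt in BASES:
            if alt != ref:
                out.append(Snv(c_pos=c, ref=ref, alt=alt))
    return out


def write_vcf(path: Union[str, Path], snvs: Sequence[Snv], t: TranscriptModel) -> None:
    """Write SNVs as a transcript-space VCF 4.2 file (one record per SNV)."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={t.id},length={len(t.seq)}>",
        '##INFO=<ID=HGVSC,Number=1,Type=String,Description="HGVS coding-coordinate notation">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for snv in snvs:
        validate_snv(t, snv)
        pos = c_to_index(t, snv.c_pos) + 1
        lines.append(
            f"{t.id}\t{pos}\t.\t{snv.ref}\t{snv.alt}\t.\t.\tHGVSC={snv.hgvs_c}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: Union[str, Path], t: TranscriptModel) -> List[Snv]:
    """Read a transcript-space VCF back into SNVs, validating REF bases."""
    import pysam

    snvs: List[Snv] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if len(rec.ref) != 1 or rec.alts is None:
                raise VcfValidationError(f"non-SNV record at POS {rec.pos}")
            i = rec.pos - 1
            if not 0 <= i < len(t.seq):
                raise VcfValidationError(f"POS {rec.pos} outside transcript {t.id}")
            c_pos = i - t.utr5_len if i < t.utr5_len else i - t.utr5_len + 1
            for alt in rec.alts:
                if len(alt) != 1:
                    raise VcfValidationError(f"non-SNV ALT {alt!r} at POS {rec.pos}")
                snv = Snv(c_pos=c_pos, ref=rec.ref, alt=alt)
                validate_snv(t, snv)
                snvs.append(snv)
    return snvs
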