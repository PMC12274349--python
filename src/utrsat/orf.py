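"""Upstream ORF engine: TIS scanning, ORF extension and typing.

An upstream translation initiation site (uTIS) is a canonical AUG or one of
the nine near-cognate codons differing from AUG by a single nucleotide.
Each uTIS, read in its own frame, runs to the first in-frame stop codon and
defines an upstream open reading frame (upORF) of one of three types:

* ``uORF``  — the stop codon lies entirely within the 5'UTR;
* ``uoORF`` — the ORF overlaps the CDS out of frame, ending at a stop
  codon inside the CDS (or straddling the UTR/CDS junction);
* ``eCDS``  — the uTIS is in frame with the CDS; with no internal in-frame
  stop in the CDS the ORF necessarily ends at the main stop codon,
  producing an N-terminally elongated protein.

Each uTIS is treated independently; no ribosome-scanning or re-initiation
model is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from .transcript import (
    STOP_CODONS,
    CoordinateError,
    TranscriptModel,
    c_to_index,
    index_to_c,
)

__all__ = [
    "CANONICAL_TIS",
    "NEAR_COGNATE_TIS",
    "TisSite",
    "UpOrf",
    "tis_codons",
    "tis_rank",
    "scan_tis",
    "extend_orf",
    "reference_uporfs",
]

CANONICAL_TIS = frozenset({"ATG"})
# the nine codons at Hamming distance 1 from ATG
NEAR_COGNATE_TIS = frozenset(
    {"CTG", "GTG", "TTG", "ACG", "AAG", "AGG", "ATA", "ATC", "ATT"}
)

_MODES = {
    "canonical": CANONICAL_TIS,
    "near_cognate": NEAR_COGNATE_TIS,
    "both": CANONICAL_TIS | NEAR_COGNATE_TIS,
}


def tis_codons(tis_mode: str = "both") -> frozenset:
    try:
        return _MODES[tis_mode]
    except KeyError:
        raise ValueError(f"unknown tis_mode {tis_mode!r}; use canonical/near_cognate/both")


def tis_rank(codon: str, tis_mode: str = "both") -> int:
    """Initiation-strength rank of a codon: 2 for AUG, 1 for a near-cognate
    (when the mode includes them), 0 otherwise."""
    if codon in CANONICAL_TIS:
        return 2
    if tis_mode != "canonical" and codon in NEAR_COGNATE_TIS:
        return 1
    return 0


def tis_created(ref_codon: str, alt_codon: str, tis_mode: str = "both") -> bool:
    """Does the REF→ALT codon change create a new uTIS identity?

    True when the ALT codon is a TIS of the chosen mode and differs from the
    REF codon, unless the REF codon is the canonical AUG: a change away from
    AUG is a downgrade (a TIS loss, which is not annotated), so AUA→AUG or
    ACG→AUA count as creations while AUG→AUA does not.
    """
    return (
        alt_codon in tis_codons(tis_mode)
        and alt_codon != ref_codon
        and ref_codon not in CANONICAL_TIS
    )


@dataclass(frozen=True)
class TisSite:
    """A translation initiation site; ``c_start`` is the first base of the
    triplet in HGVS c. coordinates."""

    c_start: int
    codon: str
    canonical: bool

    def __post_init__(self) -> None:
        if self.codon not in CANONICAL_TIS | NEAR_COGNATE_TIS:
            raise ValueError(f"{self.codon!r} is not a canonical or near-cognate TIS")
        if self.canonical != (self.codon in CANONICAL_TIS):
            raise ValueError("canonical flag inconsistent with codon")


@dataclass(frozen=True)
class UpOrf:
    """An upstream ORF. ``stop_c_start`` is the first base of the stop codon
    (HGVS c.); ``length_nt`` runs from the uTIS through the last stop base,
    stop codon included, and is always a multiple of 3."""

    tis: TisSite
    stop_c_start: int
    orf_type: str  # uORF | uoORF | eCDS
    length_nt: int
    ends_at_main_stop: bool = False


def _check_region(t: TranscriptModel, region: Optional[Tuple[int, int]]) -> Tuple[int, int]:
    L = t.utr5_len
    if region is None:
        return (-L, -1)
    lo, hi = region
    if lo == 0 or hi == 0:
        raise CoordinateError("there is no position c.0")
    if not (-L <= lo <= hi <= -1):
        raise CoordinateError(
            f"region c.{lo}..c.{hi} is not within the 5'UTR (c.{-L}..c.-1)"
        )
    return (lo, hi)


def scan_tis(
    t: TranscriptModel,
    region: Optional[Tuple[int, int]] = None,
    tis_mode: str = "both",
) -> List[TisSite]:
    """All TIS whose first base lies in ``region`` (default: whole 5'UTR),
    reading triplets that fit fully inside utr5+cds, ordered 5'→3'."""
    lo, hi = _check_region(t, region)
    codons = tis_codons(tis_mode)
    seq = t.utr5 + t.cds
    sites: List[TisSite] = []
    for c in range(lo, hi + 1):
        w = c_to_index(t, c)
        if w + 3 > len(seq):
            break
        codon = seq[w : w + 3]
        if codon in codons:
            sites.append(TisSite(c, codon, codon in CANONICAL_TIS))
    return sites


def extend_orf(t: TranscriptModel, tis: TisSite) -> Optional[UpOrf]:
    """Walk codons from the uTIS to the first in-frame stop and classify.

    Returns ``None`` when no in-frame stop exists before the transcript end
    (a "no-stop" situation, possible only on truncated input or exotic toy
    sequences) — such a site defines no upORF.
    """
    i0 = c_to_index(t, tis.c_start)
    if i0 >= t.utr5_len:
        raise CoordinateError(f"uTIS c.{tis.c_start} is not in the 5'UTR")
    seq = t.seq
    stop_i = None
    for i in range(i0, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            stop_i = i
            break
    if stop_i is None:
        return None
    in_frame = t.codon_frame(i0) == 0
    at_main = stop_i == t.main_stop_index
    if stop_i + 2 < t.utr5_len:
        orf_type = "uORF"  # even in frame 0: a UTR stop upstream of the CDS
    elif in_frame:
        orf_type = "eCDS"  # frame-0 walk past the UTR cannot stop before the main stop
    else:
        orf_type = "uoORF"
    return UpOrf(
        tis=tis,
        stop_c_start=index_to_c(t, stop_i),
        orf_type=orf_type,
        length_nt=stop_i + 3 - i0,
        ends_at_main_stop=at_main,
    )


def reference_uporfs(
    t: TranscriptModel,
    tis_mode: str = "both",
    region: Optional[Tuple[int, int]] = None,
) -> List[UpOrf]:
    """The reference upORF landscape: every uTIS in the 5'UTR extended to
    its stop, deduplicated by (uTIS, stop)."""
    seen = set()
    orfs: List[UpOrf] = []
    for tis in scan_tis(t, region=region, tis_mode=tis_mode):
        orf = extend_orf(t, tis)
        if orf is None:
            continue
        key = (orf.tis.c_start, orf.tis.codon, orf.stop_c_start)
        if key not in seen:
            seen.add(key)
            orfs.append(orf)
    return orfs
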