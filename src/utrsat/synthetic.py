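"""Synthetic transcripts and a brute-force annotation oracle.

Three things live here, all first-class, tested code:

* :func:`random_transcript` — seeded toy transcripts with optional planted
  motifs, used to exercise every module without external data;
* :func:`eng_like_transcript` — a SYNTHETIC stand-in for the human *ENG*
  MANE transcript (ENST00000373203.9): it reproduces the published local
  sequence context of the 5'UTR — the 303-nt UTR length, the 1977-nt CDS,
  the reference bases and Kozak 7-mers around the 14 known uTIS-creating
  variant sites, and the upstream stop-codon landscape (TGA at c.-166, TAA
  at c.-34 in the UTR; out-of-frame stops first at c.90 and c.125 in the
  CDS) — while every base not pinned by those constraints is deterministic
  filler. It is NOT the true ENG sequence; genome-wide tallies computed on
  it differ from tallies on the real transcript;
* :func:`brute_force_annotate` — an independent oracle for the windowed
  annotator: full rescan of the reference and variant ORF landscapes and a
  set diff, sharing no ORF-walking code with :mod:`utrsat.annotate`.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .annotate import AnnotationRecord
from .kozak import KozakCall
from .orf import TisSite, UpOrf
from .saturation import Snv, enumerate_snvs
from .transcript import TranscriptModel, TranscriptValidationError

__all__ = [
    "ToySpec",
    "GenerationError",
    "random_transcript",
    "eng_like_transcript",
    "brute_force_annotate",
    "normalize_records",
    "selftest",
]


class GenerationError(RuntimeError):
    """A planted motif made the generated transcript invalid."""


_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
]


@dataclass(frozen=True)
class ToySpec:
    """Recipe for a reproducible toy transcript. ``planted`` holds
    (offset, motif) substitutions applied to the concatenated sequence
    after generation (offsets are zero-based into utr5+cds)."""

    seed: int
    utr5_len: int
    cds_codons: int
    planted: Tuple[Tuple[int, str], ...] = ()


def random_transcript(spec: ToySpec, transcript_id: str = "toy") -> TranscriptModel:
    """Generate a valid toy transcript; identical spec → identical result."""
    if spec.utr5_len < 1:
        raise ValueError("utr5_len must be >= 1")
    if spec.cds_codons < 2:
        raise ValueError("cds_codons must be >= 2 (ATG + stop)")
    rng = random.Random(spec.seed)
    utr5 = "".join(rng.choice("ACGT") for _ in range(spec.utr5_len))
    body = [rng.choice(_NONSTOP_CODONS) for _ in range(spec.cds_codons - 2)]
    cds = "ATG" + "".join(body) + rng.choice(["TAA", "TAG", "TGA"])
    seq = list(utr5 + cds)
    for offset, motif in spec.planted:
        if offset < 0 or offset + len(motif) > len(seq):
            raise GenerationError(f"plant {motif!r} at {offset} outside transcript")
        seq[offset : offset + len(motif)] = list(motif)
    planted_seq = "".join(seq)
    try:
        return TranscriptModel(
            id=transcript_id,
            utr5=planted_seq[: spec.utr5_len],
            cds=planted_seq[spec.utr5_len :],
        )
    except TranscriptValidationError as exc:
        raise GenerationError(f"planted motifs broke transcript validity: {exc}") from exc


# ---------------------------------------------------------------------
# ENG-like synthetic stand-in

# Reference bases of the ENG 5'UTR that are fixed by published variant
# annotations (positions are HGVS c.; every entry is a REF base).
_ENG_PINNED: Dict[int, str] = {
    # c.-287C>A context (CATATGC) — ref CTG at -287
    -290: "C", -289: "A", -288: "T", -287: "C", -286: "T", -285: "G", -284: "C",
    # c.-271G>T context (GCCATGA) — ref AGG at -272
    -275: "G", -274: "C", -273: "C", -272: "A", -271: "G", -270: "G", -269: "A",
    # c.-249C>G context (GCCATGC) — ref ATC at -251
    -254: "G", -253: "C", -252: "C", -251: "A", -250: "T", -249: "C", -248: "C",
    # c.-182C>A context (TCCATGT) — ref CTG at -182
    -185: "T", -184: "C", -183: "C", -182: "C", -181: "T", -180: "G", -179: "T",
    # c.-167C>A context (CTCATGA) — ref CTG at -167; fixes the TGA stop at -166
    -170: "C", -169: "T", -168: "C", -167: "C", -166: "T", -165: "G", -164: "A",
    # c.-142A>T context (CAGATGG) — ref AAG at -143
    -146: "C", -145: "A", -144: "G", -143: "A", -142: "A", -141: "G", -140: "G",
    # c.-127C>T context (GGGATGC) — ref ACG at -128
    -131: "G", -130: "G", -129: "G", -128: "A", -127: "C", -126: "G", -125: "C",
    # c.-79C>T (CCCATGC) and c.-76C>T (ACGCTGG) contexts — ref ACG at -80, CCG at -77
    -83: "C", -82: "C", -81: "C", -80: "A", -79: "C", -78: "G",
    -77: "C", -76: "C", -75: "G", -74: "G",
    # c.-68G>A context (CCGATGC) — ref GTG at -68
    -71: "C", -70: "C", -69: "G", -68: "G", -67: "T", -66: "G", -65: "C",
    # c.-37G>T / c.-33A>G / c.-31G>T contexts (CACATGA / AGGATGA / ATAATGC)
    # — ref AGG at -38, ATA at -35, AGG at -32; fixes the TAA stop at -34
    -41: "C", -40: "A", -39: "C", -38: "A", -37: "G", -36: "G", -35: "A",
    -34: "T", -33: "A", -32: "A", -31: "G", -30: "G", -29: "C",
    # c.-10C>T context (CCCATGT) — ref ACG at -11
    -14: "C", -13: "C", -12: "C", -11: "A", -10: "C", -9: "G", -8: "T",
}

# Near-cognate uTIS planted to emulate the naturally occurring upORFs
# (frame-2 starts upstream of c.-166 and between c.-166 and c.-34).
_ENG_PLANTED_TIS: Dict[int, str] = {-298: "ACG", -262: "CTG", -157: "GTG", -121: "ACG"}

_ENG_UTR_LEN = 303
_ENG_CDS_LEN = 1977  # c.1 .. c.1977, 659 codons
_ENG_UTR_STOPS = {-166, -34}  # frame-2 stops inside the UTR
_ENG_CDS_STOPS = {90: "TGA", 125: "TGA"}  # first out-of-frame stops in the CDS


def eng_like_transcript(seed: int = 7, transcript_id: str = "ENG_SYNTH") -> TranscriptModel:
    """Build the synthetic ENG-like transcript (see module docstring).

    All pinned bases, planted uTIS and the stop-codon landscape are
    independent of ``seed``; the seed only varies the filler bases, so every
    property that the pinned landscape determines (the 14 variant-created
    upORFs with their sizes, Kozak 7-mers and shared stops) holds for any
    seed.
    """
    rng = random.Random(seed)
    utr = [rng.choice("ACGT") for _ in range(_ENG_UTR_LEN)]
    fixed = set()
    for c, base in _ENG_PINNED.items():
        utr[_ENG_UTR_LEN + c] = base
        fixed.add(_ENG_UTR_LEN + c)
    for c, motif in _ENG_PLANTED_TIS.items():
        for k, base in enumerate(motif):
            utr[_ENG_UTR_LEN + c + k] = base
            fixed.add(_ENG_UTR_LEN + c + k)

    body = [rng.choice(_NONSTOP_CODONS) for _ in range(_ENG_CDS_LEN // 3 - 2)]
    cds = list("ATG" + "".join(body) + "TAA")
    for c, stop in _ENG_CDS_STOPS.items():
        for k, base in enumerate(stop):
            cds[c - 1 + k] = base
            fixed.add(_ENG_UTR_LEN + c - 1 + k)
    # the main start and stop codons must never be touched by repairs
    fixed.update(range(_ENG_UTR_LEN, _ENG_UTR_LEN + 3))
    fixed.update(range(_ENG_UTR_LEN + _ENG_CDS_LEN - 3, _ENG_UTR_LEN + _ENG_CDS_LEN))

    seq = utr + cds
    # Out-of-frame stop codons are banned everywhere except the landscape
    # positions; C appears in no stop codon, so setting one free base per
    # offending window to C removes the stop without creating another.
    stops = {"TAA", "TAG", "TGA"}

    def repair(window_starts) -> None:
        for w in window_starts:
            if "".join(seq[w : w + 3]) in stops:
                free = [k for k in range(w, w + 3) if k not in fixed]
                if not free:  # pinned windows were chosen stop-free
                    raise GenerationError(f"stop pinned at window {w}")
                seq[free[0]] = "C"

    utr_ok = {_ENG_UTR_LEN + c for c in _ENG_UTR_STOPS}
    repair(w for w in range(_ENG_UTR_LEN) if w not in utr_ok)
    # CDS windows out of frame with the main ORF, upstream of their first
    # allowed stop (frame 1 first stops at c.125, frame 2 at c.90)
    repair(_ENG_UTR_LEN + c - 1 for c in range(2, 123, 3))
    repair(_ENG_UTR_LEN + c - 1 for c in range(3, 88, 3))

    t = TranscriptModel(
        id=transcript_id,
        utr5="".join(seq[:_ENG_UTR_LEN]),
        cds="".join(seq[_ENG_UTR_LEN:]),
    )
    _check_eng_landscape(t)
    return t


def _check_eng_landscape(t: TranscriptModel) -> None:
    seq = t.seq
    L = t.utr5_len
    stops = {"TAA", "TAG", "TGA"}
    assert seq[L - 166 : L - 163] == "TGA"
    assert seq[L - 34 : L - 31] == "TAA"
    assert seq[L + 89 : L + 92] == "TGA" and seq[L + 124 : L + 127] == "TGA"
    for w in range(L):
        if w not in (L - 166, L - 34):
            assert seq[w : w + 3] not in stops, f"unexpected UTR stop at index {w}"
    for c in range(2, 123, 3):
        assert seq[L + c - 1 : L + c + 2] not in stops, f"early frame-1 CDS stop at c.{c}"
    for c in range(3, 88, 3):
        assert seq[L + c - 1 : L + c + 2] not in stops, f"early frame-2 CDS stop at c.{c}"


# ---------------------------------------------------------------------
# brute-force oracle

_ORACLE_CANONICAL = {"ATG"}
_ORACLE_NEAR = {"CTG", "GTG", "TTG", "ACG", "AAG", "AGG", "ATA", "ATC", "ATT"}
_ORACLE_STOPS = {"TAA", "TAG", "TGA"}


def _o_is_tis(codon: str, tis_mode: str) -> bool:
    if tis_mode == "canonical":
        return codon in _ORACLE_CANONICAL
    if tis_mode == "near_cognate":
        return codon in _ORACLE_NEAR
    return codon in _ORACLE_CANONICAL or codon in _ORACLE_NEAR


def _o_created(ref_codon: str, alt_codon: str, tis_mode: str) -> bool:
    # a new TIS identity; never fired by a downgrade away from AUG
    return (
        _o_is_tis(alt_codon, tis_mode)
        and alt_codon != ref_codon
        and ref_codon not in _ORACLE_CANONICAL
    )


def _o_c(pos: int, L: int) -> int:
    return pos - L if pos < L else pos - L + 1


def _o_walk(seq: str, pos: int) -> Optional[int]:
    for k in range(pos, len(seq) - 2, 3):
        if seq[k : k + 3] in _ORACLE_STOPS:
            return k
    return None


def _o_orf(seq: str, L: int, cds_len: int, pos: int) -> Optional[UpOrf]:
    k = _o_walk(seq, pos)
    if k is None:
        return None
    codon = seq[pos : pos + 3]
    if k + 2 < L:
        orf_type = "uORF"
    elif (pos - L) % 3 == 0:
        orf_type = "eCDS"
    else:
        orf_type = "uoORF"
    return UpOrf(
        tis=TisSite(_o_c(pos, L), codon, codon in _ORACLE_CANONICAL),
        stop_c_start=_o_c(k, L),
        orf_type=orf_type,
        length_nt=k + 3 - pos,
        ends_at_main_stop=k == L + cds_len - 3,
    )


def _o_kozak(seq: str, pos: int) -> KozakCall:
    left = seq[max(0, pos - 3) : pos].rjust(3, "N")
    right = seq[pos + 3 : pos + 4].ljust(1, "N")
    sevenmer = left + seq[pos : pos + 3] + right
    m3, p4 = sevenmer[0], sevenmer[6]
    strength = (
        "strong"
        if m3 in "AG" and p4 == "G"
        else "moderate"
        if m3 in "AG" or p4 == "G"
        else "weak"
    )
    return KozakCall(sevenmer, m3, p4, strength, determined="N" not in sevenmer)


def brute_force_annotate(
    t: TranscriptModel,
    snv: Snv,
    tis_mode: str = "both",
    report_orphan_stops: bool = False,
) -> List[AnnotationRecord]:
    """Annotate one SNV by exhaustive rescanning — the independent oracle.

    Builds the complete TIS and stop-codon landscapes of the reference and
    the variant sequence, diffs them, and applies the same event semantics
    as the windowed annotator without any windowed shortcut.
    """
    L = t.utr5_len
    cds_len = len(t.cds)
    ref = t.seq
    i = L + snv.c_pos  # 5'UTR only
    if not 0 <= i < L:
        raise ValueError(f"{snv.hgvs_c} is not a 5'UTR SNV")
    if ref[i] != snv.ref:
        raise ValueError(f"REF mismatch for {snv.hgvs_c}")
    alt = ref[:i] + snv.alt + ref[i + 1 :]
    win_limit = L + cds_len  # windows must fit fully within utr5+cds

    ref_tis = {
        p: ref[p : p + 3]
        for p in range(L)
        if p + 3 <= win_limit and _o_is_tis(ref[p : p + 3], tis_mode)
    }
    records: List[AnnotationRecord] = []

    # uTIS creation = new TIS identity at a 5'UTR window
    for p in range(L):
        if p + 3 > win_limit:
            break
        if _o_created(ref[p : p + 3], alt[p : p + 3], tis_mode):
            orf = _o_orf(alt, L, cds_len, p)
            codon = alt[p : p + 3]
            records.append(
                AnnotationRecord(
                    snv=snv,
                    consequence="uTIS_created",
                    created_tis=TisSite(_o_c(p, L), codon, codon in _ORACLE_CANONICAL),
                    uporf=orf,
                    kozak=_o_kozak(alt, p),
                )
            )

    ref_stops = {
        w for w in range(win_limit - 2) if ref[w : w + 3] in _ORACLE_STOPS
    }
    alt_stops = {
        w for w in range(win_limit - 2) if alt[w : w + 3] in _ORACLE_STOPS
    }

    for w in sorted(alt_stops - ref_stops):
        linked = False
        for p in sorted(ref_tis):
            if p + 3 <= w and (w - p) % 3 == 0 and _o_walk(alt, p) == w:
                linked = True
                ref_orf = _o_orf(ref, L, cds_len, p)
                records.append(
                    AnnotationRecord(
                        snv=snv,
                        consequence="uStop_created",
                        uporf=_o_orf(alt, L, cds_len, p),
                        affected_ref_uporf=ref_orf,
                        kozak=_o_kozak(alt, p),
                        stop_c=_o_c(w, L),
                        is_shortening=ref_orf is not None and not ref_orf.ends_at_main_stop,
                    )
                )
        if not linked and report_orphan_stops:
            records.append(
                AnnotationRecord(snv=snv, consequence="uStop_created", stop_c=_o_c(w, L))
            )

    for w in sorted(ref_stops - alt_stops):
        for p in sorted(ref_tis):
            if p + 3 <= w and (w - p) % 3 == 0 and _o_walk(ref, p) == w:
                records.append(
                    AnnotationRecord(
                        snv=snv,
                        consequence="uStop_deleted",
                        uporf=_o_orf(alt, L, cds_len, p),
                        affected_ref_uporf=_o_orf(ref, L, cds_len, p),
                        kozak=_o_kozak(alt, p),
                        stop_c=_o_c(w, L),
                    )
                )

    return records


# ---------------------------------------------------------------------
# equivalence harness


def normalize_records(records: Sequence[AnnotationRecord]) -> List[tuple]:
    """Order-independent canonical form of a record list for comparisons."""

    def orf_key(orf: Optional[UpOrf]):
        if orf is None:
            return None
        return (orf.tis.c_start, orf.tis.codon, orf.stop_c_start, orf.orf_type,
                orf.length_nt, orf.ends_at_main_stop)

    out = []
    for r in records:
        out.append(
            (
                r.snv.c_pos,
                r.snv.alt,
                r.consequence,
                (r.created_tis.c_start, r.created_tis.codon) if r.created_tis else None,
                orf_key(r.uporf),
                orf_key(r.affected_ref_uporf),
                (r.kozak.sevenmer, r.kozak.strength) if r.kozak else None,
                r.stop_c,
                r.is_shortening,
            )
        )
    return sorted(out, key=repr)


def selftest(
    n_transcripts: int = 100,
    seed: int = 0,
    utr5_range: Tuple[int, int] = (20, 120),
    cds_codon_range: Tuple[int, int] = (6, 20),
    tis_mode: str = "both",
) -> Dict[str, int]:
    """Run the windowed-annotator vs brute-force-oracle equivalence sweep
    over seeded random transcripts × all their 5'UTR SNVs.

    Returns counts; ``mismatches`` must be 0.
    """
    from .annotate import annotate_variant

    rng = random.Random(seed)
    n_snvs = 0
    mismatches = 0
    for k in range(n_transcripts):
        spec = ToySpec(
            seed=rng.randrange(2**31),
            utr5_len=rng.randint(*utr5_range),
            cds_codons=rng.randint(*cds_codon_range),
        )
        t = random_transcript(spec)
        for snv in enumerate_snvs(t):
            n_snvs += 1
            fast = normalize_records(annotate_variant(t, snv, tis_mode=tis_mode))
            slow = normalize_records(brute_force_annotate(t, snv, tis_mode=tis_mode))
            if fast != slow:
                mismatches += 1
    return {"transcripts": n_transcripts, "snvs": n_snvs, "mismatches": mismatches}
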