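"""Per-variant upORF delta annotation and catalog assembly.

For each 5'UTR SNV only the (at most) three triplet windows overlapping the
variant can change, one per reading frame. Re-examining just those windows
against the reference decides whether the variant

* creates a uTIS (a new canonical or near-cognate TIS identity),
* creates a new upstream stop codon (TAA/TAG/TGA) in frame with at least
  one pre-existing uTIS — shortening that uTIS's ORF or giving it a new,
  earlier one,
* deletes an existing stop codon, elongating every upORF it terminated
  (a stop mutated into another stop codon is not a deletion).

Each event is resolved into an :class:`AnnotationRecord` carrying the
resulting upORF (computed on the variant-applied sequence) and, for stop
events, the pre-existing reference ORF it modifies. The windowed delta is
provably equivalent to a full rescan-and-diff of the reference and variant
ORF landscapes; the test suite checks this against an independent
brute-force oracle on randomized transcripts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .kozak import KozakCall, kozak_context
from .orf import (
    CANONICAL_TIS,
    TisSite,
    UpOrf,
    extend_orf,
    scan_tis,
    tis_codons,
    tis_created,
)
from .saturation import Snv, apply_snv, enumerate_snvs
from .transcript import (
    STOP_CODONS,
    CoordinateError,
    TranscriptModel,
    c_to_index,
    index_to_c,
)

__all__ = [
    "AnnotationRecord",
    "Catalog",
    "annotate_variant",
    "resolve_stop_deletion",
    "build_catalog",
    "write_catalog",
    "read_catalog",
]

CONSEQUENCES = ("uTIS_created", "uStop_created", "uStop_deleted")


@dataclass(frozen=True)
class AnnotationRecord:
    """One consequence of one SNV.

    ``uporf`` is the ORF after the variant: the created ORF for a uTIS gain,
    the shortened/new ORF for a stop gain, the elongated ORF for a stop loss
    (``None`` when the walk finds no stop). ``affected_ref_uporf`` is the
    pre-existing ORF a stop event modifies. ``stop_c`` is the created or
    deleted stop codon's first base for stop events.
    """

    snv: Snv
    consequence: str
    created_tis: Optional[TisSite] = None
    uporf: Optional[UpOrf] = None
    affected_ref_uporf: Optional[UpOrf] = None
    kozak: Optional[KozakCall] = None
    stop_c: Optional[int] = None
    is_shortening: Optional[bool] = None


@dataclass
class Catalog:
    """All annotation records for a saturated region plus summary tallies."""

    transcript_id: str
    records: List[AnnotationRecord]
    summary: Dict[str, object] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([_record_row(r) for r in self.records], columns=_COLUMNS)


# ---------------------------------------------------------------------
# per-variant delta annotation


def _changed_windows(t: TranscriptModel, i: int) -> List[int]:
    """Start indices of the triplet windows overlapping position ``i`` that
    fit fully within utr5+cds (one window per frame)."""
    limit = t.utr5_len + len(t.cds)
    return [w for w in (i - 2, i - 1, i) if w >= 0 and w + 3 <= limit]


def _upstream_inframe_tis(
    t: TranscriptModel, w: int, tis_mode: str
) -> List[TisSite]:
    """Reference uTIS in the 5'UTR upstream of window ``w`` and in frame
    with it. Such sites never overlap ``w`` (they end >= 3 bases before it),
    so they survive any variant inside ``w``."""
    sites = []
    for tis in scan_tis(t, tis_mode=tis_mode):
        j = c_to_index(t, tis.c_start)
        if j + 3 <= w and (w - j) % 3 == 0:
            sites.append(tis)
    return sites


def annotate_variant(
    t: TranscriptModel,
    snv: Snv,
    tis_mode: str = "both",
    report_orphan_stops: bool = False,
) -> List[AnnotationRecord]:
    """Annotate one 5'UTR SNV; returns an empty list when nothing changes.

    Records are emitted per (consequence, created site / affected reference
    ORF). With ``report_orphan_stops`` a created stop with no upstream
    in-frame uTIS is reported as a bare record (no linked ORF); by default
    such stops are silent since they alter no upORF.
    """
    i = c_to_index(t, snv.c_pos)
    if i >= t.utr5_len:
        raise CoordinateError(f"c.{snv.c_pos} is not in the 5'UTR; only 5'UTR SNVs are supported")
    alt_t = apply_snv(t, snv)
    ref_seq, alt_seq = t.seq, alt_t.seq
    records: List[AnnotationRecord] = []

    for w in _changed_windows(t, i):
        ref_codon = ref_seq[w : w + 3]
        alt_codon = alt_seq[w : w + 3]
        if ref_codon == alt_codon:  # cannot happen for a true SNV
            continue

        # --- uTIS creation (new TIS identity), TIS start must lie in the 5'UTR
        if w < t.utr5_len and tis_created(ref_codon, alt_codon, tis_mode):
            tis = TisSite(index_to_c(t, w), alt_codon, alt_codon in CANONICAL_TIS)
            orf = extend_orf(alt_t, tis)
            records.append(
                AnnotationRecord(
                    snv=snv,
                    consequence="uTIS_created",
                    created_tis=tis,
                    uporf=orf,
                    kozak=kozak_context(alt_t, tis),
                )
            )

        # --- uStop creation (stop-to-stop changes are neither gain nor loss)
        if alt_codon in STOP_CODONS and ref_codon not in STOP_CODONS:
            stop_c = index_to_c(t, w)
            linked = False
            for tis in _upstream_inframe_tis(t, w, tis_mode):
                new_orf = extend_orf(alt_t, tis)
                if new_orf is None or c_to_index(t, new_orf.stop_c_start) != w:
                    continue  # another stop intervenes before the new one
                linked = True
                ref_orf = extend_orf(t, tis)
                shortening = ref_orf is not None and not ref_orf.ends_at_main_stop
                records.append(
                    AnnotationRecord(
                        snv=snv,
                        consequence="uStop_created",
                        created_tis=None,
                        uporf=new_orf,
                        affected_ref_uporf=ref_orf,
                        kozak=kozak_context(alt_t, tis),
                        stop_c=stop_c,
                        is_shortening=shortening,
                    )
                )
            if not linked and report_orphan_stops:
                records.append(
                    AnnotationRecord(snv=snv, consequence="uStop_created", stop_c=stop_c)
                )

        # --- uStop deletion
        if ref_codon in STOP_CODONS and alt_codon not in STOP_CODONS:
            for tis in _upstream_inframe_tis(t, w, tis_mode):
                ref_orf = extend_orf(t, tis)
                if ref_orf is None or c_to_index(t, ref_orf.stop_c_start) != w:
                    continue  # this uTIS's ORF ends at an earlier stop
                records.append(resolve_stop_deletion(t, snv, ref_orf, alt_t=alt_t))

    return records


def resolve_stop_deletion(
    t: TranscriptModel,
    snv: Snv,
    ref_uporf: UpOrf,
    alt_t: Optional[TranscriptModel] = None,
) -> AnnotationRecord:
    """Resolve a stop-deleting SNV for one reference ORF: re-extend from the
    same uTIS on the variant sequence to find the elongated ORF."""
    if alt_t is None:
        alt_t = apply_snv(t, snv)
    w = c_to_index(t, ref_uporf.stop_c_start)
    if t.seq[w : w + 3] not in STOP_CODONS or alt_t.seq[w : w + 3] in STOP_CODONS:
        raise ValueError(
            f"{snv.hgvs_c} does not delete the stop at c.{ref_uporf.stop_c_start}"
        )
    new_orf = extend_orf(alt_t, ref_uporf.tis)
    return AnnotationRecord(
        snv=snv,
        consequence="uStop_deleted",
        uporf=new_orf,
        affected_ref_uporf=ref_uporf,
        kozak=kozak_context(alt_t, ref_uporf.tis),
        stop_c=ref_uporf.stop_c_start,
    )


# ---------------------------------------------------------------------
# catalog


def build_catalog(
    t: TranscriptModel,
    region: Optional[Tuple[int, int]] = None,
    tis_mode: str = "both",
    report_orphan_stops: bool = False,
) -> Catalog:
    """Saturate ``region`` (default: whole 5'UTR) and annotate every SNV."""
    snvs = enumerate_snvs(t, region=region)
    records: List[AnnotationRecord] = []
    per_snv: Dict[Snv, List[AnnotationRecord]] = {}
    for snv in snvs:
        recs = annotate_variant(
            t, snv, tis_mode=tis_mode, report_orphan_stops=report_orphan_stops
        )
        records.extend(recs)
        if recs:
            per_snv[snv] = recs
    summary = _summarize(snvs, per_snv)
    return Catalog(transcript_id=t.id, records=records, summary=summary)


def _summarize(
    snvs: Sequence[Snv], per_snv: Dict[Snv, List[AnnotationRecord]]
) -> Dict[str, object]:
    n_pure = {c: 0 for c in CONSEQUENCES}
    n_multi = 0
    orf_types = Counter()
    stop_tally: Counter = Counter()
    uporf_keys = set()
    n_uporfs_utis = 0
    for snv, recs in per_snv.items():
        classes = {r.consequence for r in recs}
        if len(classes) == 1:
            n_pure[next(iter(classes))] += 1
        else:
            n_multi += 1
        for r in recs:
            if r.uporf is not None:
                uporf_keys.add(
                    (snv.c_pos, snv.alt, r.uporf.tis.c_start, r.uporf.stop_c_start)
                )
            if r.consequence == "uTIS_created" and r.uporf is not None:
                n_uporfs_utis += 1
                orf_types[r.uporf.orf_type] += 1
                key = "main" if r.uporf.ends_at_main_stop else f"c.{r.uporf.stop_c_start}"
                stop_tally[f"{r.uporf.orf_type}@{key}"] += 1
    n_utis_snvs = sum(
        1 for recs in per_snv.values() if any(r.consequence == "uTIS_created" for r in recs)
    )
    return {
        "n_snvs": len(snvs),
        "n_annotated": len(per_snv),
        "n_uporfs": len(uporf_keys),
        "n_pure_uTIS": n_pure["uTIS_created"],
        "n_pure_uStop_new": n_pure["uStop_created"],
        "n_pure_uStop_del": n_pure["uStop_deleted"],
        "n_multi": n_multi,
        "n_uTIS_snvs": n_utis_snvs,
        "n_uporfs_uTIS_created": n_uporfs_utis,
        "n_uORF": orf_types.get("uORF", 0),
        "n_uoORF": orf_types.get("uoORF", 0),
        "n_eCDS": orf_types.get("eCDS", 0),
        "stop_position_tally": dict(sorted(stop_tally.items())),
    }


# ---------------------------------------------------------------------
# output

_COLUMNS = [
    "hgvs_c",
    "ref",
    "alt",
    "consequence",
    "tis_codon",
    "tis_c_start",
    "stop_c_start",
    "orf_type",
    "orf_len_nt",
    "kozak_7mer",
    "kozak_class",
    "ref_stop_c_start",
    "ref_orf_type",
    "ref_orf_len_nt",
    "is_shortening",
]


def _record_row(r: AnnotationRecord) -> dict:
    tis = r.created_tis or (r.uporf.tis if r.uporf else None) or (
        r.affected_ref_uporf.tis if r.affected_ref_uporf else None
    )
    new_stop = r.stop_c if r.consequence == "uStop_created" else (
        r.uporf.stop_c_start if r.uporf else None
    )
    return {
        "hgvs_c": r.snv.hgvs_c,
        "ref": r.snv.ref,
        "alt": r.snv.alt,
        "consequence": r.consequence,
        "tis_codon": tis.codon if tis else None,
        "tis_c_start": tis.c_start if tis else None,
        "stop_c_start": new_stop,
        "orf_type": r.uporf.orf_type if r.uporf else None,
        "orf_len_nt": r.uporf.length_nt if r.uporf else None,
        "kozak_7mer": r.kozak.sevenmer if r.kozak else None,
        "kozak_class": r.kozak.strength if r.kozak else None,
        "ref_stop_c_start": r.affected_ref_uporf.stop_c_start if r.affected_ref_uporf else None,
        "ref_orf_type": r.affected_ref_uporf.orf_type if r.affected_ref_uporf else None,
        "ref_orf_len_nt": r.affected_ref_uporf.length_nt if r.affected_ref_uporf else None,
        "is_shortening": r.is_shortening,
    }


def write_catalog(
    catalog: Catalog,
    prefix: Union[str, Path],
    t: Optional[TranscriptModel] = None,
) -> Tuple[Path, Optional[Path]]:
    """Write the catalog as ``<prefix>.tsv`` and, when the transcript is
    given, an annotated transcript-space VCF ``<prefix>.vcf`` with an
    UTRSAT_CSQ INFO field (pipe-delimited TSV columns, comma-joined per
    variant). Row order is deterministic (input record order)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv_path = prefix.with_suffix(".tsv")
    df = catalog.to_dataframe()
    df.to_csv(tsv_path, sep="\t", index=False)

    vcf_path = None
    if t is not None:
        vcf_path = prefix.with_suffix(".vcf")
        by_variant: Dict[Tuple[int, str, str], List[str]] = {}
        order: List[Tuple[int, str, str]] = []
        for r in catalog.records:
            row = _record_row(r)
            csq = "|".join("" if row[c] is None else str(row[c]) for c in _COLUMNS)
            key = (r.snv.c_pos, r.snv.ref, r.snv.alt)
            if key not in by_variant:
                by_variant[key] = []
                order.append(key)
            by_variant[key].append(csq)
        lines = [
            "##fileformat=VCFv4.2",
            f"##contig=<ID={t.id},length={len(t.seq)}>",
            '##INFO=<ID=HGVSC,Number=1,Type=String,Description="HGVS coding-coordinate notation">',
            '##INFO=<ID=UTRSAT_CSQ,Number=.,Type=String,Description="upORF consequence: '
            + "|".join(_COLUMNS)
            + '">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        ]
        for c_pos, ref, alt in sorted(order):
            i = c_to_index(t, c_pos)
            csqs = ",".join(by_variant[(c_pos, ref, alt)])
            lines.append(
                f"{t.id}\t{i + 1}\t.\t{ref}\t{alt}\t.\t.\t"
                f"HGVSC=c.{c_pos}{ref}>{alt};UTRSAT_CSQ={csqs}"
            )
        vcf_path.write_text("\n".join(lines) + "\n")
    return tsv_path, vcf_path


def read_catalog(path: Union[str, Path]) -> pd.DataFrame:
    """Read a catalog TSV back into a DataFrame (inverse of the TSV half of
    :func:`write_catalog`)."""
    return pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
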