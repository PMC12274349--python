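"""Transcript model and HGVS c.-coordinate arithmetic.

A transcript is represented in transcript space only: a 5'UTR, a CDS and an
optional 3'UTR, concatenated into one sequence. Positions follow the HGVS
coding (c.) convention: c.1 is the A of the main AUG, c.-1 the base
immediately 5' of it, and there is no position zero. All downstream modules
(saturation, ORF scanning, annotation) build on the conversions defined here.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

__all__ = [
    "TranscriptModel",
    "TranscriptValidationError",
    "CoordinateError",
    "c_to_index",
    "index_to_c",
    "c_distance",
    "load_transcript",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_VALID_BASES = re.compile(r"^[ACGT]+$")


class TranscriptValidationError(ValueError):
    """A transcript violates one of the model invariants."""


class CoordinateError(ValueError):
    """An HGVS c. position is zero or outside the transcript."""


def _normalize(seq: str, name: str) -> str:
    seq = seq.upper().replace("U", "T")
    if seq and not _VALID_BASES.match(seq):
        bad = next(i for i, b in enumerate(seq) if b not in "ACGT")
        raise TranscriptValidationError(
            f"{name} contains non-ACGT base {seq[bad]!r} at offset {bad}"
        )
    return seq


@dataclass(frozen=True)
class TranscriptModel:
    """A validated transcript: 5'UTR + CDS (+ optional 3'UTR).

    Invariants enforced at construction:

    * the CDS length is a positive multiple of 3;
    * the CDS starts with ATG and ends with TAA/TAG/TGA;
    * the CDS has no internal in-frame stop codon;
    * all sequences are A/C/G/T only (U is accepted and converted to T,
      lower case is upper-cased; ambiguity codes are rejected).
    """

    id: str
    utr5: str
    cds: str
    utr3: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "utr5", _normalize(self.utr5, "utr5"))
        object.__setattr__(self, "cds", _normalize(self.cds, "cds"))
        object.__setattr__(self, "utr3", _normalize(self.utr3, "utr3"))
        if len(self.utr5) < 1:
            raise TranscriptValidationError("utr5 must be non-empty")
        if len(self.cds) == 0 or len(self.cds) % 3 != 0:
            raise TranscriptValidationError(
                f"cds length {len(self.cds)} is not a positive multiple of 3"
            )
        if not self.cds.startswith("ATG"):
            raise TranscriptValidationError("cds does not begin with ATG")
        if self.cds[-3:] not in STOP_CODONS:
            raise TranscriptValidationError(
                f"cds final codon {self.cds[-3:]!r} is not a stop codon"
            )
        for i in range(0, len(self.cds) - 3, 3):
            if self.cds[i : i + 3] in STOP_CODONS:
                raise TranscriptValidationError(
                    f"cds has internal in-frame stop {self.cds[i:i + 3]} "
                    f"at c.{i + 1}"
                )

    # -- derived views -------------------------------------------------

    @property
    def seq(self) -> str:
        """Concatenated utr5 + cds + utr3."""
        return self.utr5 + self.cds + self.utr3

    @property
    def utr5_len(self) -> int:
        return len(self.utr5)

    @property
    def main_stop_index(self) -> int:
        """Zero-based index of the first base of the CDS stop codon."""
        return len(self.utr5) + len(self.cds) - 3

    @property
    def main_stop_c(self) -> int:
        """c. position of the first base of the CDS stop codon."""
        return len(self.cds) - 2

    def codon_frame(self, index: int) -> int:
        """Reading frame of a triplet starting at `index`, relative to the
        CDS (0 means in frame with the main ORF)."""
        return (index - len(self.utr5)) % 3


def c_to_index(t: TranscriptModel, p: int) -> int:
    """Map an HGVS c. position to a zero-based index in ``t.seq``.

    c.-L maps to 0 (first 5'UTR base), c.1 to len(utr5), and there is no
    position zero.
    """
    if not isinstance(p, int) or isinstance(p, bool):
        raise CoordinateError(f"c. position must be an integer, got {p!r}")
    if p == 0:
        raise CoordinateError("there is no position c.0")
    L = t.utr5_len
    if p < 0:
        idx = L + p
        if idx < 0:
            raise CoordinateError(f"c.{p} is upstream of the transcript (L={L})")
    else:
        idx = L + p - 1
        if idx >= len(t.seq):
            raise CoordinateError(
                f"c.{p} is beyond the transcript end (len={len(t.seq)})"
            )
    return idx


def index_to_c(t: TranscriptModel, index: int) -> int:
    """Inverse of :func:`c_to_index`."""
    if not 0 <= index < len(t.seq):
        raise CoordinateError(f"index {index} outside transcript of length {len(t.seq)}")
    L = t.utr5_len
    return index - L if index < L else index - L + 1


def c_distance(p: int, q: int) -> int:
    """Number of nucleotides from position p to q inclusive (p <= q).

    Respects the no-zero rule of HGVS c. coordinates: from c.-77 to c.127
    there are 77 + 127 = 204 bases.
    """
    if p == 0 or q == 0:
        raise CoordinateError("there is no position c.0")
    if p > q:
        raise CoordinateError(f"c.{p} is 3' of c.{q}")
    if (p > 0) == (q > 0):
        return q - p + 1
    return q - p  # p < 0 < q: the skipped zero cancels the +1


# ---------------------------------------------------------------------
# loading


def load_transcript(
    path: Union[str, Path],
    config: Union[str, Path, dict, None] = None,
    transcript_id: Optional[str] = None,
) -> TranscriptModel:
    """Load a transcript from a GenBank record or a FASTA + sidecar config.

    GenBank files (``.gb``/``.gbk``/``.genbank``) must carry a CDS feature;
    the record is split around it. FASTA files need a sidecar config — a
    YAML/JSON file or a dict — with either ``utr5_len`` (CDS assumed to run
    to the record end) or 1-based inclusive ``cds_start``/``cds_end``.
    Validation failures raise :class:`TranscriptValidationError` naming the
    violated rule.
    """
    from Bio import SeqIO

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".gb", ".gbk", ".genbank"}:
        record = SeqIO.read(str(path), "genbank")
        cds_features = [f for f in record.features if f.type == "CDS"]
        if not cds_features:
            raise TranscriptValidationError(f"{path}: no CDS feature in GenBank record")
        feat = cds_features[0]
        start, end = int(feat.location.start), int(feat.location.end)
        seq = str(record.seq)
        return TranscriptModel(
            id=transcript_id or record.id,
            utr5=seq[:start],
            cds=seq[start:end],
            utr3=seq[end:],
        )

    record = next(SeqIO.parse(str(path), "fasta"))
    seq = str(record.seq)
    cfg = _read_sidecar(path, config)
    if "utr5_len" in cfg:
        start = int(cfg["utr5_len"])
        end = int(cfg.get("cds_end", len(seq)))
    elif "cds_start" in cfg and "cds_end" in cfg:
        start = int(cfg["cds_start"]) - 1
        end = int(cfg["cds_end"])
    else:
        raise TranscriptValidationError(
            "sidecar config must provide utr5_len or cds_start/cds_end"
        )
    return TranscriptModel(
        id=transcript_id or cfg.get("id", record.id),
        utr5=seq[:start],
        cds=seq[start:end],
        utr3=seq[end:],
    )


def _read_sidecar(fasta_path: Path, config) -> dict:
    if isinstance(config, dict):
        return config
    if config is not None:
        text = Path(config).read_text()
    else:
        for ext in (".yaml", ".yml", ".json"):
            candidate = fasta_path.with_suffix(ext)
            if candidate.exists():
                text = candidate.read_text()
                break
        else:
            raise TranscriptValidationError(
                f"no sidecar config found next to {fasta_path}"
            )
    try:
        import yaml

        return yaml.safe_load(text)
    except ImportError:  # pragma: no cover
        return json.loads(text)
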