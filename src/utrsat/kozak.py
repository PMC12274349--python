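"""Kozak context extraction and strength classification.

The Kozak context of a TIS is the 7-mer spanning positions −3..−1, the TIS
triplet itself, and +4 (+1 being the first TIS base). Strength depends only
on the −3 and +4 positions:

* strong   — purine (A/G) at −3 AND G at +4;
* moderate — exactly one of the two;
* weak     — neither.

The same rule is applied to canonical and near-cognate TIS. For a
variant-created TIS the context must be read from the variant-applied
sequence, since the variant may sit inside its own 7-mer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable

from .orf import TisSite
from .transcript import TranscriptModel, c_to_index

__all__ = ["KozakCall", "kozak_context", "classify_strength", "classify_table"]

_PURINES = {"A", "G"}


@dataclass(frozen=True)
class KozakCall:
    sevenmer: str
    minus3: str
    plus4: str
    strength: str  # strong | moderate | weak
    determined: bool = True  # False when the context is truncated (N-padded)


def classify_strength(minus3: str, plus4: str) -> str:
    purine = minus3 in _PURINES
    gplus4 = plus4 == "G"
    if purine and gplus4:
        return "strong"
    if purine or gplus4:
        return "moderate"
    return "weak"


def kozak_context(t: TranscriptModel, tis: TisSite) -> KozakCall:
    """Extract the 7-mer context of a TIS and classify its strength.

    A TIS within the first three transcript bases (or, pathologically, with
    fewer than one base after its triplet) has a truncated context: missing
    bases are N-padded, the call is flagged undetermined, and the strength
    falls through the classifier as weak.
    """
    i0 = c_to_index(t, tis.c_start)
    seq = t.seq
    left = seq[max(0, i0 - 3) : i0].rjust(3, "N")
    right = seq[i0 + 3 : i0 + 4].ljust(1, "N")
    sevenmer = left + seq[i0 : i0 + 3] + right
    determined = "N" not in sevenmer
    return KozakCall(
        sevenmer=sevenmer,
        minus3=sevenmer[0],
        plus4=sevenmer[6],
        strength=classify_strength(sevenmer[0], sevenmer[6]),
        determined=determined,
    )


def classify_table(calls: Iterable[KozakCall]) -> Dict[str, int]:
    """Tally strength classes over a collection of Kozak calls."""
    tally = Counter(call.strength for call in calls)
    return {k: tally.get(k, 0) for k in ("strong", "moderate", "weak")}
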