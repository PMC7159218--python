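"""Qualitative TDLU involution categories.

Two slide-level classifications used in the breast-cancer-risk
literature:

* **Russo lobule types** — per-TDLU, by acinus count: type 1 (least
  developed, fewer than 12 acini), type 2 (12 to 80 acini), type 3
  (more than 80 acini).  A slide is summarized by its predominant
  (modal) type.  Type 4 (pregnancy/lactation) is out of scope.
* **Baer categories** — slide-level: ``no_type1`` (zero type-1
  lobules), ``predominantly_type1_no_type3`` (more than half type 1 and
  zero type 3), ``mixed`` (all others).

Counts are interpreted on the manual (calibrated) scale by default,
since the Russo thresholds were defined on manual counting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

from .measures import TDLURecord

BAER_CATEGORIES = ("no_type1", "mixed", "predominantly_type1_no_type3")


def russo_type(acini_count: float) -> int:
    """Russo lobule type for a single TDLU's acinus count.

    ``< 12 -> 1``, ``12..80 -> 2``, ``> 80 -> 3``.  The boundary value 80
    is assigned to type 2.
    """
    if acini_count < 0:
        raise ValueError("acini count must be non-negative")
    if acini_count < 12:
        return 1
    if acini_count <= 80:
        return 2
    return 3


def predominant_type(types: Sequence[int]) -> Optional[int]:
    """Modal Russo type of a slide; ties break toward the higher type.

    The higher (less involuted) type wins ties — a deterministic,
    conservative convention that flags less involution.  Empty input
    returns None.
    """
    if not types:
        return None
    counts = Counter(types)
    best = max(counts.values())
    return max(t for t, c in counts.items() if c == best)


def baer_category(types: Sequence[int]) -> Optional[str]:
    """Slide-level Baer category from the per-TDLU Russo types.

    ``no_type1`` when there are zero type-1 lobules;
    ``predominantly_type1_no_type3`` when type 1 holds a strict majority
    and there is no type 3; ``mixed`` otherwise.  Empty input -> None.
    """
    if not types:
        return None
    counts = Counter(types)
    if counts.get(1, 0) == 0:
        return "no_type1"
    if counts.get(1, 0) > len(types) / 2 and counts.get(3, 0) == 0:
        return "predominantly_type1_no_type3"
    return "mixed"


def consensus_vote(labels: Sequence) -> Optional[object]:
    """Strict-majority consensus among raters; None when there is none.

    A None result flags the case for adjudication rather than silently
    picking a winner.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("consensus requires at least 2 raters")
    counts = Counter(labels)
    label, n = counts.most_common(1)[0]
    if n > len(labels) / 2:
        return label
    return None


@dataclass
class QualitativeResult:
    """Per-TDLU Russo types plus the two slide-level summaries."""

    per_tdlu_types: List[int]
    predominant_type: Optional[int]
    baer_category: Optional[str]
    counts_by_type: dict

    @classmethod
    def from_types(cls, types: Sequence[int]) -> "QualitativeResult":
        types = [int(t) for t in types]
        counts = {t: 0 for t in (1, 2, 3)}
        for t in types:
            counts[t] += 1
        return cls(
            per_tdlu_types=types,
            predominant_type=predominant_type(types),
            baer_category=baer_category(types),
            counts_by_type=counts,
        )


def classify_slide(
    records: Iterable[TDLURecord], use_calibrated: bool = True
) -> QualitativeResult:
    """Russo/Baer classification of a slide from its per-TDLU records.

    By default the calibrated (manual-scale) acinus counts are used,
    matching the scale on which the Russo thresholds were defined; pass
    ``use_calibrated=False`` to classify on raw automated counts.
    """
    types = [
        russo_type(
            r.acini_count_calibrated if use_calibrated else r.acini_count_raw
        )
        for r in records
    ]
    return QualitativeResult.from_types(types)
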