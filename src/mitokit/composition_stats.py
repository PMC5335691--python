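"""Per-record composition summaries: AT content, gene counts by category,
intergenic spacers (overlaps negative) and control-region length."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .genbank_io import MitogenomeRecord
from .vocab import CATEGORY_CR, CATEGORY_PCG, CATEGORY_RRNA, CATEGORY_TRNA

__all__ = ["SummaryRow", "at_content", "intergenic_spacers",
           "summarize_record", "summaries_to_frame"]


@dataclass
class SummaryRow:
    record_id: str
    length: int
    at_percent: Optional[float]
    n_pcg: int
    n_trna: int
    n_rrna: int
    n_genes: int
    intergenic_total: int
    longest_noncoding: int
    cr_length: Optional[int]


def at_content(seq: str) -> float:
    """AT percentage over unambiguous bases; N is excluded from the
    denominator.  Invariant under rotation of the sequence."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    a = s.count("A")
    t = s.count("T")
    denom = a + t + s.count("C") + s.count("G")
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return 100.0 * (a + t) / denom


def _linear_end(feat, length: int) -> int:
    """End coordinate unwrapped past the origin for origin-spanning features."""
    return feat.end + length if feat.start > feat.end else feat.end


def intergenic_spacers(record: MitogenomeRecord) -> list[tuple[str, str, int]]:
    """(left gene, right gene, length) for consecutive feature pairs,
    including the circular wrap pair; overlaps come out negative."""
    feats = [f for f in record.sorted_features() if f.start is not None]
    if len(feats) < 2:
        raise ValueError("need at least two positioned features")
    out: list[tuple[str, str, int]] = []
    L = record.length
    for i in range(len(feats) - 1):
        a, b = feats[i], feats[i + 1]
        out.append((a.name or a.raw_label, b.name or b.raw_label,
                    b.start - _linear_end(a, L) - 1))
    last, first = feats[-1], feats[0]
    out.append((last.name or last.raw_label, first.name or first.raw_label,
                first.start + L - _linear_end(last, L) - 1))
    return out


def summarize_record(record: MitogenomeRecord) -> SummaryRow:
    """One summary row per record.  ``longest_noncoding`` is the larger of the
    longest positive spacer and the control-region span, so both readings of
    "control region length" are available."""
    feats = [f for f in record.sorted_features() if f.start is not None]
    n_pcg = sum(1 for f in feats if f.category == CATEGORY_PCG)
    n_trna = sum(1 for f in feats if f.category == CATEGORY_TRNA)
    n_rrna = sum(1 for f in feats if f.category == CATEGORY_RRNA)
    cr = next((f for f in feats if f.category == CATEGORY_CR), None)
    cr_length = cr.span(record.length) if cr is not None else None

    spacers = intergenic_spacers(record) if len(feats) >= 2 else []
    intergenic_total = sum(s for _, _, s in spacers)
    longest_spacer = max((s for _, _, s in spacers), default=0)
    longest_noncoding = max(longest_spacer, cr_length or 0)

    try:
        at = at_content(record.sequence) if record.sequence else None
    except ValueError:
        at = None
    return SummaryRow(
        record_id=record.record_id,
        length=record.length,
        at_percent=at,
        n_pcg=n_pcg,
        n_trna=n_trna,
        n_rrna=n_rrna,
        n_genes=n_pcg + n_trna + n_rrna,
        intergenic_total=intergenic_total,
        longest_noncoding=longest_noncoding,
        cr_length=cr_length,
    )


def summaries_to_frame(rows: list[SummaryRow]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in rows])
    return df.set_index("record_id")
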