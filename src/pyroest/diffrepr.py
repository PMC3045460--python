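"""Differential representation of contigs between two strain libraries.

Per-contig reads are counted by strain, normalized to library totals, and
scored with (r - s) / (r + s) on the normalized values: +1 means the contig
is exclusive to the resistant library, -1 exclusive to the susceptible one.
No significance test is attached; the score is a ranking statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .assembly import Assembly


@dataclass
class StrainCounts:
    contig_id: str
    r_raw: int
    s_raw: int
    unknown_raw: int = 0
    r_norm: float | None = None
    s_norm: float | None = None
    score: float | None = None


def count_by_strain(
    assembly: Assembly, r_label: str = "R", s_label: str = "S"
) -> list[StrainCounts]:
    """Raw per-contig read tallies; unlabelled reads reported separately."""
    out = []
    for cid, contig in assembly.contigs.items():
        r = sum(1 for p in contig.placements if p.strain == r_label)
        s = sum(1 for p in contig.placements if p.strain == s_label)
        u = len(contig.placements) - r - s
        out.append(StrainCounts(contig_id=cid, r_raw=r, s_raw=s, unknown_raw=u))
    return out


def normalize(
    counts: list[StrainCounts], r_total: int, s_total: int
) -> list[StrainCounts]:
    """Library-size normalization: per-library read proportions."""
    if r_total <= 0 or s_total <= 0:
        raise ValueError("library totals must be positive")
    out = []
    for c in counts:
        r_norm = c.r_raw / r_total
        s_norm = c.s_raw / s_total
        out.append(replace(c, r_norm=r_norm, s_norm=s_norm,
                           score=diff_score(r_norm, s_norm)))
    return out


def diff_score(r_norm: float, s_norm: float) -> float:
    """(r - s) / (r + s) on normalized counts; 0 when both are 0."""
    if r_norm < 0 or s_norm < 0:
        raise ValueError("normalized counts must be >= 0")
    total = r_norm + s_norm
    return 0.0 if total == 0 else (r_norm - s_norm) / total


def rank_table(
    counts: list[StrainCounts], direction: str = "R", top_n: int | None = None
) -> pd.DataFrame:
    """Ranked table for one direction ('R'-biased or 'S'-biased).

    Sorted by score in the requested direction; ties broken by larger total
    raw count, then contig id.
    """
    if direction not in ("R", "S"):
        raise ValueError("direction must be 'R' or 'S'")
    sign = 1 if direction == "R" else -1
    rows = sorted(
        counts,
        key=lambda c: (-sign * (c.score or 0.0), -(c.r_raw + c.s_raw),
                       c.contig_id),
    )
    if top_n is not None:
        rows = rows[:max(top_n, 0)]
    return pd.DataFrame([
        {"contig_id": c.contig_id, "r_raw": c.r_raw, "s_raw": c.s_raw,
         "r_norm": c.r_norm, "s_norm": c.s_norm, "score": c.score}
        for c in rows
    ], columns=["contig_id", "r_raw", "s_raw", "r_norm", "s_norm", "score"])
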