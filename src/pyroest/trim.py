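"""Read trimming for 454 cDNA reads: SMART adapters and poly-A/T tails.

The tail rule: a seed run of at least ``t_run`` consecutive T's starting within
``search_window`` bases of the read start is expanded rightwards through any
number of single-base gaps (each gap is exactly one non-T base and must be
followed by at least one T), and the read is trimmed from position 0 to the end
of the largest expansion.  Poly-A tails use the mirror-image rule at the 3'
end.  Adapters are removed by matching the longest substring of the adapter or
its reverse complement flush against either read end, tolerating a mismatch
fraction of up to ``max_adapter_error``.

Adapters are removed first (they physically flank the tails in SMART cDNA),
then tails are searched on the adapter-free core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from ._util import revcomp

SMART_ADAPTER = "AAGCAGTGGTATCAACGCAGAGT"


@dataclass(frozen=True)
class TrimSpec:
    """Parameters of the trimming procedure.

    max_adapter_error is the tolerated mismatch fraction in an adapter match;
    min_adapter_match prevents spuriously short matches trivially satisfying
    that fraction; t_run / search_window control the poly-tail seed; reads
    shorter than min_length after trimming fail the length filter.
    """

    adapter: str = SMART_ADAPTER
    max_adapter_error: float = 0.20
    min_adapter_match: int = 8
    t_run: int = 6
    search_window: int = 50
    min_length: int = 30

    def __post_init__(self) -> None:
        if not 0 <= self.max_adapter_error < 1:
            raise ValueError("max_adapter_error must be in [0, 1)")
        if self.t_run < 1:
            raise ValueError("t_run must be >= 1")
        if self.search_window < self.t_run:
            raise ValueError("search_window must be >= t_run")
        if len(self.adapter) < self.min_adapter_match:
            raise ValueError("adapter shorter than min_adapter_match")


@dataclass
class TrimmedRead:
    """A read with its kept interval and the record of what was removed."""

    read_id: str
    sequence: str                      # original, untrimmed
    kept: tuple[int, int]
    removals: list[tuple[int, int, str]] = field(default_factory=list)
    passed_length_filter: bool = True

    @property
    def kept_sequence(self) -> str:
        return self.sequence[self.kept[0]:self.kept[1]]

    @property
    def kept_length(self) -> int:
        return self.kept[1] - self.kept[0]


def find_polyT_prefix(sequence: str, spec: TrimSpec) -> int:
    """End offset (exclusive) of the largest gapped poly-T expansion, 0 if none.

    Among equally long expansions the right-most end is taken, maximizing the
    trimmed length.
    """
    n = len(sequence)
    best = 0
    i = 0
    while i < min(n, spec.search_window):
        if sequence[i] == "T":
            # length of the consecutive run starting here
            j = i
            while j < n and sequence[j] == "T":
                j += 1
            if j - i >= spec.t_run:
                # expand rightwards through single-base gaps
                end = j
                while end < n - 1 and sequence[end] != "T" and sequence[end + 1] == "T":
                    end += 1
                    while end < n and sequence[end] == "T":
                        end += 1
                best = max(best, end)
            i = j
        else:
            i += 1
    return best


def find_polyA_suffix(sequence: str, spec: TrimSpec) -> int:
    """Start offset of the largest gapped poly-A expansion at the 3' end.

    Returns len(sequence) when there is nothing to trim; the trim covers
    [trim_start, len).  Mirror image of :func:`find_polyT_prefix`.
    """
    return len(sequence) - find_polyT_prefix(revcomp(sequence), spec)


def _flush_match(window: str, spec: TrimSpec, at_start: bool) -> int:
    """Longest adapter (or revcomp) substring matching flush to one read end.

    Returns the matched length (0 if none).  ``window`` is the read itself;
    for ``at_start`` the substring is compared to window[:L], else window[-L:].
    """
    variants = (spec.adapter, revcomp(spec.adapter))
    max_l = min(len(window), len(spec.adapter))
    for length in range(max_l, spec.min_adapter_match - 1, -1):
        target = window[:length] if at_start else window[-length:]
        allowed = int(spec.max_adapter_error * length)
        for variant in variants:
            for off in range(len(variant) - length + 1):
                sub = variant[off:off + length]
                mism = 0
                for a, b in zip(sub, target):
                    if a != b:
                        mism += 1
                        if mism > allowed:
                            break
                if mism <= allowed:
                    return length
    return 0


def trim_adapter(
    sequence: str, spec: TrimSpec
) -> tuple[tuple[int, int] | None, tuple[int, int] | None]:
    """Intervals removed at the 5' and 3' read ends (None where no match)."""
    n = len(sequence)
    l5 = _flush_match(sequence, spec, at_start=True)
    iv5 = (0, l5) if l5 else None
    core = sequence[l5:]
    l3 = _flush_match(core, spec, at_start=False) if core else 0
    iv3 = (n - l3, n) if l3 else None
    return iv5, iv3


def trim_read(read_id: str, sequence: str, spec: TrimSpec) -> TrimmedRead:
    """Full trim of one read: adapters first, then poly-T/poly-A on the core."""
    if not sequence:
        warnings.warn(f"empty sequence for read {read_id!r}; skipped")
        return TrimmedRead(read_id, sequence, (0, 0), [], False)
    removals: list[tuple[int, int, str]] = []
    s, e = 0, len(sequence)
    iv5, iv3 = trim_adapter(sequence, spec)
    if iv5:
        removals.append((iv5[0], iv5[1], "adapter5"))
        s = iv5[1]
    if iv3:
        removals.append((iv3[0], iv3[1], "adapter3"))
        e = iv3[0]
    t = find_polyT_prefix(sequence[s:e], spec)
    if t:
        removals.append((s, s + t, "polyT"))
        s += t
    core = sequence[s:e]
    if core:
        a = find_polyA_suffix(core, spec)
        if a < len(core):
            removals.append((s + a, e, "polyA"))
            e = s + a
    removals.sort(key=lambda r: r[0])
    return TrimmedRead(
        read_id, sequence, (s, e), removals,
        passed_length_filter=(e - s) >= spec.min_length,
    )


def trim_batch(
    reads, spec: TrimSpec, thresholds: list[int] | None = None
) -> tuple[list[TrimmedRead], pd.DataFrame]:
    """Trim a batch and summarize survival per length threshold.

    ``reads`` is an iterable of (id, sequence) pairs or Bio SeqRecords.
    Returns the trimmed reads and a summary with one row per threshold:
    threshold, reads_in, survivors, bp_in, bp_kept (over survivors),
    mean_length.  Counts are non-increasing in threshold.
    """
    if thresholds is None:
        thresholds = [spec.min_length]
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    trimmed = []
    for read in reads:
        if hasattr(read, "seq"):
            rid, seq = read.id, str(read.seq)
        else:
            rid, seq = read
        trimmed.append(trim_read(rid, seq, spec))
    bp_in = sum(len(t.sequence) for t in trimmed)
    rows = []
    for thr in sorted(thresholds):
        kept = [t for t in trimmed if t.kept_length >= thr]
        bp_kept = sum(t.kept_length for t in kept)
        rows.append({
            "threshold": thr,
            "reads_in": len(trimmed),
            "survivors": len(kept),
            "bp_in": bp_in,
            "bp_kept": bp_kept,
            "mean_length": bp_kept / len(kept) if kept else 0.0,
        })
    return trimmed, pd.DataFrame(rows)
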