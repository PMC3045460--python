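"""Global protein alignment and percent-similarity conservation tables.

The aligner is Needleman-Wunsch with affine gaps (Gotoh's three-matrix
recursion) and deterministic tie-breaking: diagonal is preferred, then a gap
in the second sequence ("up"), then a gap in the first.  Percent similarity
is the share of alignment columns whose residue pair has a positive
substitution-matrix score (identities included); gap-vs-residue columns count
in the denominator, gap-gap columns never occur in a pairwise alignment.

Substitution matrices come from Bio.Align.substitution_matrices (BLOSUM62 by
default; the choice is configurable because "similarity" has no single
standard definition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

NEG_INF = -1e30


def load_matrix(matrix):
    """Accept a matrix name ('BLOSUM62'), a Bio Array, or a dict of pairs."""
    if isinstance(matrix, str):
        return substitution_matrices.load(matrix)
    return matrix


def _score(matrix, a: str, b: str) -> float:
    try:
        return float(matrix[a, b])
    except (KeyError, IndexError):
        return float(matrix[b, a])


@dataclass
class ProteinAlignment:
    aligned_a: str
    aligned_b: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")


def _check_residues(seq: str, matrix) -> None:
    alphabet = set(getattr(matrix, "alphabet", "ACDEFGHIKLMNPQRSTVWYBZX*"))
    bad = sorted({c for c in seq if c not in alphabet})
    if bad:
        raise ValueError(f"non-standard residues: {''.join(bad)}")


def global_align(
    seq_a: str,
    seq_b: str,
    matrix="BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> ProteinAlignment:
    """Optimal global alignment under affine gap penalties.

    A gap of length L costs gap_open + (L-1)*gap_extend (both values are
    scores, i.e. negative).  Setting gap_open == gap_extend gives linear gap
    scoring.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    matrix = load_matrix(matrix)
    _check_residues(seq_a, matrix)
    _check_residues(seq_b, matrix)
    n, m = len(seq_a), len(seq_b)
    # M: a_i aligned to b_j; X: gap in b (a_i vs '-'); Y: gap in a
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        si = seq_a[i - 1]
        for j in range(1, m + 1):
            s = _score(matrix, si, seq_b[j - 1])
            M[i, j] = max(M[i-1, j-1], X[i-1, j-1], Y[i-1, j-1]) + s
            X[i, j] = max(M[i-1, j] + gap_open, X[i-1, j] + gap_extend,
                          Y[i-1, j] + gap_open)
            Y[i, j] = max(M[i, j-1] + gap_open, Y[i, j-1] + gap_extend,
                          X[i, j-1] + gap_open)
    # traceback, preferring diagonal, then up (gap in b), then left
    i, j = n, m
    mats = {"M": M, "X": X, "Y": Y}
    best = max(M[n, m], X[n, m], Y[n, m])
    state = next(st for st in ("M", "X", "Y") if mats[st][n, m] == best)
    score = float(best)
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            s = _score(matrix, seq_a[i - 1], seq_b[j - 1])
            target = M[i, j] - s
            i, j = i - 1, j - 1
            for st, mat in (("M", M), ("X", X), ("Y", Y)):
                if abs(mat[i, j] - target) < 1e-9:
                    state = st
                    break
        elif state == "X":
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            target = X[i, j]
            i -= 1
            if abs(M[i, j] + gap_open - target) < 1e-9:
                state = "M"
            elif abs(X[i, j] + gap_extend - target) < 1e-9:
                state = "X"
            else:
                state = "Y"
        else:
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            target = Y[i, j]
            j -= 1
            if abs(M[i, j] + gap_open - target) < 1e-9:
                state = "M"
            elif abs(Y[i, j] + gap_extend - target) < 1e-9:
                state = "Y"
            else:
                state = "X"
    aln = ProteinAlignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                           score)
    assert aln.aligned_a.replace("-", "") == seq_a
    assert aln.aligned_b.replace("-", "") == seq_b
    return aln


def percent_similarity(alignment: ProteinAlignment, matrix="BLOSUM62") -> float:
    """100 x positive-score columns / columns (gap-gap excluded)."""
    matrix = load_matrix(matrix)
    num = den = 0
    for a, b in zip(alignment.aligned_a, alignment.aligned_b):
        if a == "-" and b == "-":
            continue
        den += 1
        if a != "-" and b != "-" and _score(matrix, a, b) > 0:
            num += 1
    return 100.0 * num / den if den else 0.0


def similarity_matrix(
    queries: dict[str, str],
    orthologs: dict[str, dict[str, str]],
    matrix="BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> pd.DataFrame:
    """Per-gene, per-species percent similarity (NaN where no ortholog).

    ``queries`` maps gene -> protein sequence; ``orthologs`` maps gene ->
    {species: protein sequence}.  Values are rounded to integers for table
    display, matching the conventions of published conservation tables.
    """
    matrix = load_matrix(matrix)
    species = sorted({sp for d in orthologs.values() for sp in d})
    rows = {}
    for gene, qseq in queries.items():
        row = {}
        for sp in species:
            oseq = orthologs.get(gene, {}).get(sp)
            if not oseq:
                row[sp] = np.nan
                continue
            aln = global_align(qseq, oseq, matrix, gap_open, gap_extend)
            row[sp] = round(percent_similarity(aln, matrix))
        rows[gene] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=species)


def conservation_table(
    similarities: pd.DataFrame, groups: dict[str, str]
) -> pd.DataFrame:
    """Append per-functional-group mean rows and an overall mean row.

    Group means are arithmetic means of per-gene values; absent cells (NaN)
    are excluded from the mean of their column.
    """
    missing = sorted(set(similarities.index) - set(groups))
    if missing:
        raise ValueError(f"genes without a functional group: {missing}")
    frames = []
    for group in dict.fromkeys(groups.values()):
        genes = [g for g in similarities.index if groups[g] == group]
        block = similarities.loc[genes].copy()
        mean_row = block.mean(skipna=True).to_frame().T
        mean_row.index = [f"{group}__mean"]
        frames.append(pd.concat([block, mean_row]))
    overall = similarities.mean(skipna=True).to_frame().T
    overall.index = ["overall__mean"]
    frames.append(overall)
    return pd.concat(frames)


def group_means(similarities: pd.DataFrame, groups: dict[str, str]) -> pd.DataFrame:
    """Just the per-group mean rows (index = group), plus 'overall'."""
    table = conservation_table(similarities, groups)
    means = table[table.index.str.endswith("__mean")].copy()
    means.index = [i.replace("__mean", "") for i in means.index]
    return means
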