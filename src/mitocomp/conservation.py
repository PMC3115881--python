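"""Alignment conservation statistics and affine-gap pairwise global alignment.

%INUC is the percentage of fully conserved columns in a multiple alignment
of orthologous sequences: a column counts as conserved only when every row
carries the same non-gap symbol (gap-containing columns are variable).
Pairwise comparisons report idNP (identical nucleotide pairs), %ID =
100·idNP/ALNL, and ALNL (alignment length); the aligner is a three-state
(Gotoh) global dynamic program with affine gap costs, which supports the
very relaxed gap parameters (opening 1, extension 3) used for fast-evolving
AT-rich control regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import Alignment

log = logging.getLogger(__name__)

NEG_INF = float("-inf")


@dataclass(frozen=True)
class AlignmentSummary:
    alnl: int
    conserved: int
    variable: int
    pct_inuc: float
    idnp: int | None = None     # pairwise mode only
    pct_id: float | None = None


@dataclass(frozen=True)
class GapParams:
    """Affine gap costs: a gap of length g costs gap_open + gap_extend·g."""

    gap_open: float = 15.0
    gap_extend: float = 6.6
    match: float = 1.0
    mismatch: float = 0.0

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap costs must be positive")


#: the relaxed control-region parameters (gap-opening 1, gap-extending 3)
RELAXED_GAPS = GapParams(gap_open=1.0, gap_extend=3.0)


def msa_summary(aln: Alignment) -> AlignmentSummary:
    """Conserved/variable column counts and %INUC for a multiple alignment."""
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 rows")
    cols = np.array([list(r) for r in aln.rows]).T
    conserved = 0
    for col in cols:
        first = col[0]
        if first != "-" and (col == first).all():
            conserved += 1
    alnl = len(aln)
    return AlignmentSummary(
        alnl=alnl, conserved=conserved, variable=alnl - conserved,
        pct_inuc=100.0 * conserved / alnl if alnl else 0.0,
    )


def _prep(seq: str) -> str:
    return seq.upper().replace("U", "T")


def pairwise_global_align(a: str, b: str, params: GapParams = RELAXED_GAPS
                          ) -> tuple[tuple[str, str], AlignmentSummary]:
    """Optimal global alignment under affine gap penalties.

    Three-state dynamic programming (match/insert-x/insert-y) with
    deterministic tie-breaking in the traceback: diagonal over up over
    left, and staying in a gap state over opening a new one.
    """
    a, b = _prep(a), _prep(b)
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    n, m = len(a), len(b)
    go, ge = params.gap_open, params.gap_extend
    sub = lambda x, y: params.match if x == y else params.mismatch

    # M[i][j]: best ending in a match/mismatch; X: gap in b (consume a); Y: gap in a
    # The fill is vectorized per row; the Y recurrence
    #   Y[i,j] = max(Y[i,j-1] − ge, max(M,X)[i,j-1] − go − ge)
    # unrolls to a running maximum of max(M,X)[i,k] − go + ge·k, so it is a
    # cumulative-maximum scan rather than a sequential loop.
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    X[1:, 0] = -(go + ge * np.arange(1, n + 1))
    Y[0, 1:] = -(go + ge * np.arange(1, m + 1))
    b_arr = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    js = np.arange(m + 1, dtype=float)
    for i in range(1, n + 1):
        s_row = np.where(b_arr == ord(a[i - 1]), params.match, params.mismatch)
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + s_row
        X[i] = np.maximum(X[i - 1] - ge,
                          np.maximum(M[i - 1], Y[i - 1]) - go - ge)
        X[i, 0] = -(go + ge * i)
        c = np.maximum(M[i], X[i]) - go + ge * js
        Y[i, 1:] = np.maximum.accumulate(c[:-1]) - ge * js[1:]
        Y[i, 0] = NEG_INF
        M[i, 0] = NEG_INF

    # traceback; preference: M (diagonal) > X (up) > Y (left)
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][n, m] * 1.0
                - {"M": 0, "X": 1e-12, "Y": 2e-12}[s])
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            s = sub(a[i - 1], b[j - 1])
            prev = M[i, j] - s
            i, j = i - 1, j - 1
            for cand, mat in (("M", M), ("X", X), ("Y", Y)):
                if np.isclose(mat[i, j], prev, atol=1e-9):
                    state = cand
                    break
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            here = X[i, j]
            i -= 1
            if np.isclose(X[i, j] - ge, here, atol=1e-9):
                state = "X"
            elif np.isclose(M[i, j] - ge - go, here, atol=1e-9):
                state = "M"
            else:
                state = "Y"
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            here = Y[i, j]
            j -= 1
            if np.isclose(Y[i, j] - ge, here, atol=1e-9):
                state = "Y"
            elif np.isclose(M[i, j] - ge - go, here, atol=1e-9):
                state = "M"
            else:
                state = "X"
        if i == 0 and j == 0:
            break
    row_a = "".join(reversed(out_a))
    row_b = "".join(reversed(out_b))
    alnl = len(row_a)
    idnp = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    summary = AlignmentSummary(
        alnl=alnl,
        conserved=idnp,
        variable=alnl - idnp,
        pct_inuc=100.0 * idnp / alnl,
        idnp=idnp,
        pct_id=100.0 * idnp / alnl,
    )
    return (row_a, row_b), summary


def alignment_score(row_a: str, row_b: str, params: GapParams) -> float:
    """Affine-gap score of a completed alignment (for oracles and checks)."""
    score = 0.0
    gap_a = gap_b = False
    for x, y in zip(row_a, row_b):
        if x == "-" and y == "-":
            raise ValueError("double-gap column")
        if x == "-":
            score -= (params.gap_extend if gap_a else params.gap_open + params.gap_extend)
            gap_a, gap_b = True, False
        elif y == "-":
            score -= (params.gap_extend if gap_b else params.gap_open + params.gap_extend)
            gap_a, gap_b = False, True
        else:
            score += params.match if x == y else params.mismatch
            gap_a = gap_b = False
    return score


def conservation_panel(aln_groups: dict[str, dict[str, Alignment]]) -> pd.DataFrame:
    """%INUC matrix: gene family × taxon group, with per-group mean ± SD.

    ``aln_groups`` maps taxon-group name to {gene family: Alignment}.
    Groups with fewer than 2 rows are skipped with a warning. The summary
    rows ``avg_inuc``/``sd_inuc`` hold each group's mean ± SD.
    """
    data: dict[str, dict[str, float]] = {}
    for group, fams in aln_groups.items():
        col = {}
        for fam, aln in fams.items():
            if aln.n_taxa < 2:
                log.warning("%s/%s: fewer than 2 rows; skipped", group, fam)
                continue
            col[fam] = msa_summary(aln).pct_inuc
        data[group] = col
    df = pd.DataFrame(data)
    summary = pd.DataFrame({
        g: {"avg_inuc": df[g].mean(), "sd_inuc": df[g].std(ddof=1)}
        for g in df.columns
    })
    return pd.concat([df, summary])
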