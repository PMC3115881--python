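"""Boundary refinement for protein-coding genes, feature accounting, spacers.

The 5' end of a PCG is placed at the first legitimate in-frame start codon
(ATN, GTG, TTG or GTT) that does not lie within the upstream gene encoded
on the same strand; atp6 and nad4 are exempt from the upstream constraint
because they habitually overlap atp8 and nad4L. The 3' end is placed at
the first in-frame stop codon (TAA/TAG under the invertebrate
mitochondrial code); when that stop lies inside the downstream same-strand
gene, the gene is truncated to a T or TA abutting the downstream gene —
completed to TAA by polyadenylation of the transcript. Truncated stops are
rendered with the genomic bases in upper case and the polyadenylated
completion in lower case (T → "Taa", TA → "TAa").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .genetic_code import START_CODONS, STOP_CODONS, revcomp
from .genome_io import (
    ALPHA,
    BETA,
    CONTROL_REGION,
    AnnotatedGenome,
    GeneFeature,
)

log = logging.getLogger(__name__)

#: genes allowed to start within their upstream same-strand neighbour
UPSTREAM_OVERLAP_EXEMPT = frozenset({"atp6", "nad4"})
#: downstream genes into which a full stop codon may legitimately reach
DOWNSTREAM_OVERLAP_EXEMPT = frozenset({"atp6", "nad4"})


# ---------------------------------------------------------------------------
# α <-> coding-strand coordinate bridging

class _CodingView:
    """Linearized coding-strand view of a circular genome for one strand."""

    def __init__(self, genome: AnnotatedGenome, strand: str):
        self.genome = genome
        self.strand = strand
        self.L = len(genome)
        self.seq = genome.sequence if strand == ALPHA else revcomp(genome.sequence)

    def from_alpha(self, pos: int) -> int:
        return pos if self.strand == ALPHA else self.L + 1 - pos

    def to_alpha(self, pos: int) -> int:
        pos = (pos - 1) % self.L + 1
        return pos if self.strand == ALPHA else self.L + 1 - pos

    def codon(self, pos: int) -> str:
        """Codon starting at 1-based coding position ``pos`` (circular)."""
        i = (pos - 1) % self.L
        s = self.seq + self.seq[:2]
        return s[i : i + 3]

    def interval(self, f: GeneFeature) -> tuple[int, int]:
        """Feature's (start5', end3') in this coding view (may wrap)."""
        if f.strand == ALPHA:
            a, b = f.start, f.end
        else:
            a, b = self.L + 1 - f.end, self.L + 1 - f.start
        if self.strand == BETA and f.strand == BETA:
            return a, b
        if self.strand == ALPHA and f.strand == ALPHA:
            return a, b
        raise ValueError("feature strand does not match view strand")

    def span(self, start: int, end: int) -> int:
        if end >= start:
            return end - start + 1
        return self.L - start + 1 + end


def _same_strand_features(genome: AnnotatedGenome, strand: str) -> list[GeneFeature]:
    return [f for f in genome.gene_features() if f.strand == strand]


def _circ_dist(a: int, b: int, L: int) -> int:
    """Forward distance from a to b on a circle of size L (0 when equal)."""
    return (b - a) % L


# ---------------------------------------------------------------------------
# Start / stop inference

@dataclass(frozen=True)
class StartCall:
    position: int        # α-strand 5' position of the inferred start codon
    codon: str
    canonical: bool


def infer_start(
    genome: AnnotatedGenome,
    gene: str,
    rough_start: int | None = None,
    search_window: int = 90,
    exempt: frozenset = UPSTREAM_OVERLAP_EXEMPT,
) -> StartCall:
    """Locate the start codon of a PCG near ``rough_start``.

    ``rough_start`` is the 5' α-strand position of the annotated start (for
    β genes this is the feature *end* coordinate); it anchors the reading
    frame. The scan walks in-frame codons from the upstream same-strand
    gene boundary (or ``rough_start − search_window`` for exempt genes)
    towards ``rough_start + search_window`` and returns the first
    legitimate start not separated from the gene body by an in-frame stop.
    If no legitimate codon exists in the window the annotated start is kept
    with ``canonical=False`` — the manual non-canonical override path.
    """
    if search_window >= len(genome):
        raise ValueError("search window exceeds sequence length")
    f = genome.feature(gene)
    if f.category != "PCG":
        raise ValueError(f"{gene} is not a protein-coding gene")
    view = _CodingView(genome, f.strand)
    g5, _ = view.interval(f)
    c_rough = g5 if rough_start is None else view.from_alpha(rough_start)

    # upstream same-strand boundary: 3' end of the nearest gene upstream
    lo = c_rough - search_window
    if gene not in exempt:
        best = None
        for other in _same_strand_features(genome, f.strand):
            if other.name == gene:
                continue
            _, o3 = view.interval(other)
            d = _circ_dist(o3 % view.L + 1, c_rough, view.L)
            if d < search_window and (best is None or d < best[0]):
                best = (d, o3)
        if best is not None:
            lo = max(lo, best[1] + 1)

    # work in extended coordinates when the boundary wraps past the origin
    if lo > c_rough:
        c_rough += view.L
    # align lo to the reading frame of c_rough
    lo += (c_rough - lo) % 3
    candidate = None
    p = lo
    while p <= c_rough + search_window:
        codon = view.codon(p)
        if p <= c_rough and codon in STOP_CODONS:
            candidate = None  # ORF broken upstream of the gene body
        elif codon in START_CODONS and candidate is None:
            candidate = p
        if p >= c_rough and candidate is not None:
            break
        p += 3
    if candidate is None:
        fallback = view.codon(c_rough)
        if fallback in STOP_CODONS:
            raise ValueError(f"{gene}: reading frame opens on a stop codon")
        log.warning("%s/%s: non-canonical start %s retained",
                    genome.identifier, gene, fallback)
        return StartCall(view.to_alpha(c_rough), fallback, False)
    return StartCall(view.to_alpha(candidate), view.codon(candidate), True)


@dataclass(frozen=True)
class StopCall:
    end: int            # α-strand 3' position of the (possibly truncated) stop
    codon: str          # "TAA"/"TAG" or truncated "TA"/"T"
    truncated: bool


def infer_stop(
    genome: AnnotatedGenome,
    gene: str,
    start: int | None = None,
    max_len: int = 6000,
    exempt_downstream: frozenset = DOWNSTREAM_OVERLAP_EXEMPT,
) -> StopCall:
    """Locate the stop of a PCG scanning in-frame from its start.

    Returns the first in-frame TAA/TAG; if the downstream same-strand gene
    begins before any stop completes, the gene is truncated to the T/TA
    abutting that gene. Genes whose downstream neighbour is in
    ``exempt_downstream`` (atp8→atp6, nad4L→nad4) may carry a full stop
    inside that neighbour.
    """
    f = genome.feature(gene)
    if f.category != "PCG":
        raise ValueError(f"{gene} is not a protein-coding gene")
    view = _CodingView(genome, f.strand)
    g5, _ = view.interval(f)
    s = g5 if start is None else view.from_alpha(start)

    # nearest downstream same-strand gene 5' boundary
    down_start = None
    down_name = None
    for other in _same_strand_features(genome, f.strand):
        if other.name == gene:
            continue
        o5, _ = view.interval(other)
        d = _circ_dist(s, o5, view.L)
        if d == 0:
            continue
        if down_start is None or d < _circ_dist(s, down_start, view.L):
            down_start, down_name = o5, other.name
    ignore_boundary = down_name in exempt_downstream if down_name else False

    p = s
    while view.span(s, p + 2) <= max_len:
        codon = view.codon(p)
        beyond = (
            down_start is not None
            and not ignore_boundary
            and _circ_dist(s, p + 2, view.L) >= _circ_dist(s, down_start, view.L)
        )
        if beyond:
            # truncate to the residue abutting the downstream gene
            residue_len = _circ_dist(p, down_start, view.L)
            residue = "".join(view.codon(p)[:residue_len]) if residue_len else ""
            if residue in ("T", "TA"):
                end = p + residue_len - 1
                return StopCall(view.to_alpha(end), residue, True)
            raise ValueError(
                f"{gene}: no in-frame stop and residue {residue!r} before "
                f"{down_name} is not a truncatable T/TA"
            )
        if codon in STOP_CODONS:
            return StopCall(view.to_alpha(p + 2), codon, False)
        p += 3
    raise ValueError(f"{gene}: no stop codon within {max_len} bp and no "
                     "downstream gene to truncate against")


def render_stop(codon: str) -> str:
    """Genomic stop bases upper-case, polyadenylated completion lower-case."""
    return codon.upper() + "a" * (3 - len(codon))


# ---------------------------------------------------------------------------
# Feature accounting (the genome-structure table)

def feature_account(genome: AnnotatedGenome) -> pd.DataFrame:
    """Per-feature table in α order: name, start, end, size, inc, fcd, scd.

    ``inc`` is the number of intergenic nucleotides to the next feature
    along α (negative when features overlap). ``fcd``/``scd`` are the first
    and (possibly truncated) stop codons of PCGs.
    """
    feats = sorted(genome.features, key=lambda f: f.start)
    if not feats:
        return pd.DataFrame(columns=["name", "start", "end", "size", "inc", "fcd", "scd"])
    L = len(genome)
    rows = []
    for i, f in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        inc = (nxt.start - f.end - 1) % L
        if inc > L // 2:  # large forward gap means overlap the short way
            inc -= L
        from .genome_io import extract_gene_sequence
        fcd = scd = ""
        if f.category == "PCG":
            cds = extract_gene_sequence(genome, f.name)
            fcd = cds[:3]
            r = len(cds) % 3
            tail = cds[-3:] if r == 0 else cds[-r:]
            scd = render_stop(tail) if tail.upper() in ("T", "TA", "TAA", "TAG") else tail
        rows.append({
            "name": f.name, "start": f.start, "end": f.end,
            "size": f.length(L), "inc": inc, "strand": f.strand,
            "fcd": fcd, "scd": scd,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spacers

@dataclass(frozen=True)
class NonCodingPortion:
    start: int
    end: int
    length: int
    label: str  # "" for unlabeled ncps, "s1", "s2", ... for spacers


@dataclass(frozen=True)
class SpacerSet:
    ncps: tuple[NonCodingPortion, ...]

    @property
    def spacers(self) -> tuple[NonCodingPortion, ...]:
        return tuple(p for p in self.ncps if p.label)


def find_spacers(genome: AnnotatedGenome, min_label_len: int = 15) -> SpacerSet:
    """Maximal gene-free runs (ncps); runs ≥ ``min_label_len`` get s1, s2, …

    Only the 37 genes cover the genome: an annotated control region is
    deliberately left uncovered so that it surfaces as the largest ncp, as
    the convention is in mitogenome structure tables.
    """
    L = len(genome)
    covered = bytearray(L)
    for f in genome.features:
        if f.name == CONTROL_REGION:
            continue
        if f.end >= f.start:
            for i in range(f.start - 1, f.end):
                covered[i] = 1
        else:
            for i in range(f.start - 1, L):
                covered[i] = 1
            for i in range(f.end):
                covered[i] = 1
    runs: list[tuple[int, int]] = []  # 0-based [start, end] inclusive
    i = 0
    while i < L:
        if not covered[i]:
            j = i
            while j + 1 < L and not covered[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    # merge a run touching the origin on both sides (circular genome)
    if genome.circular and len(runs) >= 2 and runs[0][0] == 0 and runs[-1][1] == L - 1:
        first, last = runs[0], runs.pop()
        runs[0] = (last[0], first[1])  # wraps; length handled below
    ncps = []
    n_label = 0
    for a, b in runs:
        length = (b - a + 1) if b >= a else (L - a + b + 1)
        ncps.append([a + 1, b + 1, length, ""])
    ncps.sort(key=lambda r: r[0])
    for rec in ncps:
        if rec[2] >= min_label_len:
            n_label += 1
            rec[3] = f"s{n_label}"
    return SpacerSet(tuple(NonCodingPortion(*r) for r in ncps))


# ---------------------------------------------------------------------------
# Start/stop report across genomes

def startstop_report(genomes) -> pd.DataFrame:
    """Start/stop codon table: one row per genome, ST/EN columns per PCG."""
    rows = []
    for g in genomes:
        acct = feature_account(g)
        rec: dict[str, str] = {"taxon": g.identifier}
        for r in acct.itertuples():
            if r.fcd:
                rec[f"{r.name}_ST"] = r.fcd
                rec[f"{r.name}_EN"] = r.scd
        rows.append(rec)
    return pd.DataFrame(rows)
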