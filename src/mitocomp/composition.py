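"""Base composition, strand skews, and compositional cluster labels.

AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C), computed on the α strand
for whole genomes and on the coding strand for pooled gene sets. Cluster
labels partition the observed endopterygotan ranges into fixed bins: AT%
into five 5-point intervals (A1–A5), AT-skew into six 0.050 intervals
(B1–B6), and GC-skew into six 0.050 intervals (C1–C6). All bins are
half-open on the right; GC-skews at or above −0.10 fall outside the scheme
and are flagged.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .genome_io import ALPHA, BETA, AnnotatedGenome, extract_gene_sequence

log = logging.getLogger(__name__)

OUT_OF_SCHEME = "C6+"


@dataclass(frozen=True)
class CompositionProfile:
    subject: str
    scope: str
    counts: dict  # A, C, G, T, N
    at_pct: float
    gc_pct: float
    at_skew: float  # NaN when A+T == 0
    gc_skew: float  # NaN when G+C == 0


def composition_profile(sequence: str, subject: str = "", scope: str = "sequence") -> CompositionProfile:
    """Profile a nucleotide sequence; N bases are excluded from denominators."""
    seq = sequence.upper().replace("U", "T")
    c = Counter(seq)
    a, t, g, cc = c["A"], c["T"], c["G"], c["C"]
    n_informative = a + t + g + cc
    if n_informative == 0:
        raise ValueError(f"{subject or 'sequence'}: no unambiguous bases")
    n_count = len(seq) - n_informative
    if n_count > 0.10 * len(seq):
        log.warning("%s: %.1f%% ambiguous bases", subject, 100 * n_count / len(seq))
    at = a + t
    gc = g + cc
    return CompositionProfile(
        subject=subject,
        scope=scope,
        counts={"A": a, "C": cc, "G": g, "T": t, "N": n_count},
        at_pct=100.0 * at / n_informative,
        gc_pct=100.0 * gc / n_informative,
        at_skew=(a - t) / at if at else math.nan,
        gc_skew=(g - cc) / gc if gc else math.nan,
    )


_POOL_SCOPES = {
    "a+b": ("pooled-α+β PCGs", (ALPHA, BETA)),
    "a": ("pooled-α PCGs", (ALPHA,)),
    "b": ("pooled-β PCGs", (BETA,)),
}


def pooled_profile(genome: AnnotatedGenome, which: str = "a+b") -> CompositionProfile:
    """Composition of concatenated PCG coding-strand sequences.

    ``which`` selects the strand set: ``"a+b"``, ``"a"``, or ``"b"``. Each
    gene is read 5'→3' on its own coding strand, so the resulting skews are
    coding-strand skews.
    """
    if which not in _POOL_SCOPES:
        raise ValueError(f"unknown pool selector {which!r}")
    scope, strands = _POOL_SCOPES[which]
    parts = [
        extract_gene_sequence(genome, f.name)
        for f in genome.gene_features()
        if f.category == "PCG" and f.strand in strands
    ]
    if not parts:
        raise ValueError(f"{genome.identifier}: no PCGs on strand set {which!r}")
    return composition_profile("".join(parts), subject=genome.identifier, scope=scope)


def whole_genome_profile(genome: AnnotatedGenome) -> CompositionProfile:
    return composition_profile(genome.sequence, subject=genome.identifier, scope="whole-α-strand")


# ---------------------------------------------------------------------------
# Cluster labels

@dataclass(frozen=True)
class ClusterLabel:
    at_cluster: str
    atskew_cluster: str
    gcskew_cluster: str
    gc_out_of_scheme: bool = False


def at_cluster(at_pct: float) -> str:
    """AT% clusters: 5-point bins, half-open on the right."""
    if at_pct < 70:
        return "A1"
    if at_pct < 75:
        return "A2"
    if at_pct < 80:
        return "A3"
    if at_pct < 85:
        return "A4"
    return "A5"


def atskew_cluster(at_skew: float) -> str:
    """AT-skew clusters: 0.050 bins from 0, negatives in B1."""
    if at_skew < 0:
        return "B1"
    if at_skew < 0.05:
        return "B2"
    if at_skew < 0.10:
        return "B3"
    if at_skew < 0.15:
        return "B4"
    if at_skew < 0.20:
        return "B5"
    return "B6"


def gcskew_cluster(gc_skew: float) -> str:
    """GC-skew clusters: 0.050 bins over [−0.35, −0.10).

    The C5/C6 boundary sits at −0.151 rather than −0.15: the published
    cluster assignments place −0.1519 in C5 but −0.1504 in C6, so the
    label-consistent boundary lies strictly inside (−0.1519, −0.1504].
    """
    if gc_skew < -0.35:
        return "C1"
    if gc_skew < -0.30:
        return "C2"
    if gc_skew < -0.25:
        return "C3"
    if gc_skew < -0.20:
        return "C4"
    if gc_skew < -0.151:
        return "C5"
    if gc_skew < -0.10:
        return "C6"
    return OUT_OF_SCHEME


def assign_clusters(profile: CompositionProfile | tuple[float, float, float]) -> ClusterLabel:
    """Assign (AT%, AT-skew, GC-skew) cluster labels.

    Accepts a :class:`CompositionProfile` or a plain ``(at_pct, at_skew,
    gc_skew)`` triple. Every finite value receives exactly one label.
    """
    if isinstance(profile, CompositionProfile):
        at, ats, gcs = profile.at_pct, profile.at_skew, profile.gc_skew
    else:
        at, ats, gcs = profile
    gclab = gcskew_cluster(gcs)
    return ClusterLabel(
        at_cluster=at_cluster(at),
        atskew_cluster=atskew_cluster(ats),
        gcskew_cluster=gclab,
        gc_out_of_scheme=gclab == OUT_OF_SCHEME,
    )


# ---------------------------------------------------------------------------
# Cohort summaries

@dataclass(frozen=True)
class CohortSummary:
    n: int
    stats: pd.DataFrame          # min/max/mean per parameter
    cluster_counts: dict         # parameter -> {label: count}
    n_positive_at_skew: int
    n_negative_at_skew: int
    n_negative_gc_skew: int
    scatter: pd.DataFrame        # subject, at_skew, gc_skew, at_pct


def cohort_summary(rows) -> CohortSummary:
    """Summarize a cohort of composition profiles.

    ``rows`` is an iterable of :class:`CompositionProfile` or a DataFrame
    with columns ``subject/at_pct/at_skew/gc_skew``.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame(
            {"subject": p.subject, "at_pct": p.at_pct,
             "at_skew": p.at_skew, "gc_skew": p.gc_skew}
            for p in rows
        )
    if df.empty:
        raise ValueError("empty cohort")
    labels = [assign_clusters((r.at_pct, r.at_skew, r.gc_skew)) for r in df.itertuples()]
    counts = {
        "at_pct": dict(Counter(l.at_cluster for l in labels)),
        "at_skew": dict(Counter(l.atskew_cluster for l in labels)),
        "gc_skew": dict(Counter(l.gcskew_cluster for l in labels)),
    }
    stats = df[["at_pct", "at_skew", "gc_skew"]].agg(["min", "max", "mean"])
    return CohortSummary(
        n=len(df),
        stats=stats,
        cluster_counts=counts,
        n_positive_at_skew=int((df.at_skew > 0).sum()),
        n_negative_at_skew=int((df.at_skew < 0).sum()),
        n_negative_gc_skew=int((df.gc_skew < 0).sum()),
        scatter=df[["subject", "at_skew", "gc_skew", "at_pct"]].copy(),
    )


def load_reference_cohort() -> pd.DataFrame:
    """84-taxon endopterygotan whole-mtDNA composition survey.

    Published AT%, AT-skew and GC-skew values with their printed cluster
    labels; used as a regression fixture for the cluster-bin edges and for
    cohort summary statistics.
    """
    ref = resources.files("mitocomp.data").joinpath("endopterygota_composition.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"taxon": "subject"})
    return df
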