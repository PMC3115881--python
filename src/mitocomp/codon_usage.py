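"""Codon-usage statistics for mitochondrial protein-coding genes.

Codon extraction drops each gene's first codon and its terminal stop,
whether complete (TAA/TAG) or truncated (T/TA), so unusual start codons
and polyadenylation-completed stops never bias the counts. Reporting
statistics (codons per thousand, RSCU, strand ratios) use the 22-family
scheme that splits Leu into CTN/TTR and Ser into AGN/TCN; Wright's
effective number of codons (ENC) is computed over the full-code synonymous
families (Leu 6-fold, Ser 8-fold), the sets over which the homozygosity
estimator is defined.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_code import (
    DEGENERACY_CLASSES,
    FAMILIES22,
    FAMILY22,
    FAMILY22_NAMES,
    FAMILY_FULL,
    FULL_FAMILIES,
    SENSE_CODONS,
    STOP_CODONS,
)
from .genome_io import ALPHA, BETA, AnnotatedGenome, extract_gene_sequence

log = logging.getLogger(__name__)

#: below this many codons ENC is considered unreliable (atp8-style exclusion)
MIN_CODONS_FOR_ENC = 55


class InternalStopError(ValueError):
    pass


def gene_codons(cds: str, gene: str = "?") -> list[str]:
    """Codons of one coding sequence after the exclusion rules.

    Drops the first codon and the terminal complete or truncated stop;
    raises :class:`InternalStopError` on a stop codon mid-gene.
    """
    cds = cds.upper()
    r = len(cds) % 3
    if r:  # truncated terminal stop
        tail = cds[-r:]
        if tail not in ("T", "TA"):
            raise ValueError(f"{gene}: length residue {tail!r} is not a truncated stop")
        body = cds[:-r]
    else:
        body = cds[:-3] if cds[-3:] in STOP_CODONS else cds
        if cds[-3:] not in STOP_CODONS:
            log.warning("%s: no terminal stop codon; counting to the end", gene)
    codons = [body[i : i + 3] for i in range(3, len(body), 3)]
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise InternalStopError(f"{gene}: internal stop {c} at codon {i + 2}")
    return codons


def extract_codons(genome: AnnotatedGenome, genes=None) -> Counter:
    """Pooled codon counts over a gene subset (default: all PCGs)."""
    counts: Counter = Counter()
    for f in genome.gene_features():
        if f.category != "PCG":
            continue
        if genes is not None and f.name not in genes:
            continue
        cds = extract_gene_sequence(genome, f.name)
        counts.update(gene_codons(cds, f.name))
    return counts


def strand_codon_counts(genome: AnnotatedGenome, strand: str) -> Counter:
    genes = [f.name for f in genome.gene_features()
             if f.category == "PCG" and f.strand == strand]
    return extract_codons(genome, genes)


# ---------------------------------------------------------------------------
# Per-codon table

@dataclass(frozen=True)
class CodonUsageTable:
    subject: str
    scope: str
    table: pd.DataFrame     # codon, family, aa_family, count, cdspt, rscu, absent
    total: int

    def family_totals(self) -> pd.Series:
        return self.table.groupby("family")["count"].sum()


def rscu(counts) -> dict[str, float]:
    """Relative synonymous codon usage under the 22-family scheme.

    RSCU(c) = count(c)·|F| / Σ_{c'∈F} count(c'); families with zero total
    get RSCU 0 for every member.
    """
    out: dict[str, float] = {}
    for fam, members in FAMILIES22.items():
        tot = sum(counts.get(c, 0) for c in members)
        for c in members:
            out[c] = counts.get(c, 0) * len(members) / tot if tot else 0.0
    return out


def codon_usage_table(counts, subject: str = "", scope: str = "pooled-α+β") -> CodonUsageTable:
    total = sum(counts.get(c, 0) for c in SENSE_CODONS)
    r = rscu(counts)
    rows = []
    for c in SENSE_CODONS:
        n = counts.get(c, 0)
        rows.append({
            "codon": c,
            "family": FAMILY22[c],
            "aa_family": FAMILY_FULL[c],
            "count": n,
            "cdspt": 1000.0 * n / total if total else 0.0,
            "rscu": r[c],
            "absent": n == 0,
        })
    return CodonUsageTable(subject=subject, scope=scope,
                           table=pd.DataFrame(rows), total=total)


# ---------------------------------------------------------------------------
# Wright's effective number of codons, generalized to the mt code

def _family_homozygosity(ns: list[int]) -> float | None:
    """F̂ = (nΣp²−1)/(n−1) for one synonymous family; None when n < 2."""
    n = sum(ns)
    if n < 2:
        return None
    s = sum((x / n) ** 2 for x in ns)
    f = (n * s - 1) / (n - 1)
    return f


def enc(counts, min_codons: int = MIN_CODONS_FOR_ENC) -> float:
    """Effective number of codons over the 62 sense codons.

    Per degeneracy class k the contribution is (families in class)/mean F̂;
    a class with no estimable family borrows the average "bias level"
    b = (F̂−1/k)/(1−1/k) of the estimable classes. The result is clamped to
    [number of families, 62].
    """
    total = sum(counts.get(c, 0) for c in SENSE_CODONS)
    if total < min_codons:
        raise ValueError(f"too few codons for a reliable ENC ({total} < {min_codons})")
    class_mean_f: dict[int, float | None] = {}
    biases: list[float] = []
    for k, fams in DEGENERACY_CLASSES.items():
        fs = []
        for fam in fams:
            members = FULL_FAMILIES[fam]
            f = _family_homozygosity([counts.get(c, 0) for c in members])
            if f is not None:
                fs.append(f)
        if fs:
            mean_f = float(np.mean(fs))
            class_mean_f[k] = mean_f
            biases.append((mean_f - 1 / k) / (1 - 1 / k))
        else:
            class_mean_f[k] = None
    if not biases:
        raise ValueError("no estimable synonymous family")
    b = float(np.mean(biases))
    value = 0.0
    for k, fams in DEGENERACY_CLASSES.items():
        mean_f = class_mean_f[k]
        if mean_f is None:
            mean_f = 1 / k + b * (1 - 1 / k)
            log.warning("degeneracy class %d unestimable; imputed F=%.4f", k, mean_f)
        mean_f = max(mean_f, 1e-9)
        value += len(fams) / mean_f
    n_families = len(FULL_FAMILIES)
    if value > 62 or value < n_families:
        log.warning("ENC %.3f outside [%d, 62]; clamped", value, n_families)
    return float(min(62.0, max(float(n_families), value)))


# ---------------------------------------------------------------------------
# Strand ratio of codon-family totals

@dataclass(frozen=True)
class StrandRatioTable:
    per_genome: pd.DataFrame   # genome × family ratio (NaN when β count 0)
    summary: pd.DataFrame      # family, avg_ratio, sd
    oavg: float
    oavg_sd: float


def strand_ratio(genomes) -> StrandRatioTable:
    """Family-wise α/β codon-count ratios, averaged across genomes.

    The overall ratio (oavg) is total α codons over total β codons per
    genome; its spread is computed across genomes. A family with zero β
    codons in a genome is flagged infinite and excluded from that family's
    average with a warning.
    """
    recs = []
    overall = []
    for g in genomes:
        ca = strand_codon_counts(g, ALPHA)
        cb = strand_codon_counts(g, BETA)
        tot_a = sum(ca.values())
        tot_b = sum(cb.values())
        if tot_b == 0 or tot_a == 0:
            raise ValueError(f"{g.identifier}: needs PCGs on both strands")
        overall.append(tot_a / tot_b)
        row = {"genome": g.identifier}
        for fam, members in FAMILIES22.items():
            na = sum(ca.get(c, 0) for c in members)
            nb = sum(cb.get(c, 0) for c in members)
            if nb == 0:
                log.warning("%s: family %s has no β-strand codons; ratio flagged",
                            g.identifier, fam)
                row[fam] = math.nan
            else:
                row[fam] = na / nb
        recs.append(row)
    per_genome = pd.DataFrame(recs).set_index("genome")
    summary = pd.DataFrame({
        "family": list(FAMILY22_NAMES),
        "avg_ratio": [per_genome[f].mean() for f in FAMILY22_NAMES],
        "sd": [per_genome[f].std(ddof=1) if len(per_genome) > 1 else 0.0
               for f in FAMILY22_NAMES],
    })
    overall_arr = np.asarray(overall)
    return StrandRatioTable(
        per_genome=per_genome,
        summary=summary,
        oavg=float(overall_arr.mean()),
        oavg_sd=float(overall_arr.std(ddof=1)) if len(overall_arr) > 1 else 0.0,
    )
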