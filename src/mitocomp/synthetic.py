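"""Synthetic insect mitogenomes and tree-evolved alignments.

The genome generator emulates the statistical structure the comparative
analyses assume: a circular 37-gene molecule in a configurable gene order
(ancestral insect by default, or with named translocations such as the
neuropteran trnC move), strand-specific base composition with target AT%
and AT-/GC-skews, protein-coding genes that start with a legitimate codon
and contain no internal stop under the invertebrate mitochondrial code,
small intergenic spacers, and an AT-rich control region with planted
homopolymer runs and repeated motifs of known identity.

Base sampling uses the strand-composition probabilities

    pA = f(1+s_AT)/2,  pT = f(1−s_AT)/2,
    pG = (1−f)(1+s_GC)/2,  pC = (1−f)(1−s_GC)/2,   f = AT%/100,

on the α strand; genes encoded on β sample their coding strand from the
complement-mirrored distribution so the α-strand totals still meet the
targets. Stop codons arising inside PCG bodies are rejected and resampled,
and after assembly a deterministic repair pass removes spurious in-frame
start codons upstream of each PCG (never touching another PCG) so that
boundary re-inference reproduces the annotation exactly.

Everything is deterministic under the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .annotate import infer_start
from .genetic_code import START_CODONS, STOP_CODONS, revcomp
from .genome_io import (
    ALPHA,
    BETA,
    BUILTIN_ORDERS,
    CONTROL_REGION,
    AnnotatedGenome,
    GeneFeature,
    GeneOrderSignature,
)
from .distances import Alignment, SubstitutionModel

NUC = np.array(list("ACGT"))

#: default PCG sizes in codons (start + body; terminal stop added separately)
DEFAULT_PCG_CODONS = {
    "atp6": 226, "atp8": 52, "cob": 378, "cox1": 511, "cox2": 228,
    "cox3": 262, "nad1": 311, "nad2": 340, "nad3": 117, "nad4": 446,
    "nad4L": 96, "nad5": 571, "nad6": 174,
}
DEFAULT_TRNA_LEN = 66
DEFAULT_RRNS_LEN = 780
DEFAULT_RRNL_LEN = 1300


@dataclass(frozen=True)
class RepeatSpec:
    length: int = 37
    identity: float = 0.757
    count: int = 2  # copies of the motif planted


@dataclass(frozen=True)
class ControlRegionSpec:
    length: int = 1049
    at_pct: float = 84.5
    at_skew: float = 0.03
    gc_skew: float = 0.0
    homopolymers: tuple = (("A", 11), ("T", 8), ("C", 5), ("G", 5))
    repeats: tuple = (RepeatSpec(),)


@dataclass(frozen=True)
class GenomeSpec:
    seed: int
    identifier: str = ""
    gene_order: str | GeneOrderSignature = "ancestral_insect"
    at_pct: float = 78.0
    at_skew: float = 0.02
    gc_skew: float = -0.20
    pcg_codons: dict = field(default_factory=lambda: dict(DEFAULT_PCG_CODONS))
    trna_len: int = DEFAULT_TRNA_LEN
    rrns_len: int = DEFAULT_RRNS_LEN
    rrnl_len: int = DEFAULT_RRNL_LEN
    #: (after_gene, length) intergenic spacers; the control region is separate
    spacers: tuple = (("trnI", 55), ("trnS2", 20))
    #: PCGs ending in a truncated stop ("T" or "TA") instead of TAA
    truncated_stops: dict = field(default_factory=dict)
    start_codon: str = "ATG"
    control_region: ControlRegionSpec = ControlRegionSpec()

    def __post_init__(self):
        if not (0 <= self.at_pct <= 100):
            raise ValueError("AT% out of range")
        if not (-1 < self.at_skew < 1 and -1 < self.gc_skew < 1):
            raise ValueError("skew out of range")
        if self.start_codon not in START_CODONS:
            raise ValueError(f"{self.start_codon} is not a legitimate start codon")


def _base_probs(at_pct: float, at_skew: float, gc_skew: float) -> np.ndarray:
    f = at_pct / 100.0
    p = np.array([
        f * (1 + at_skew) / 2,        # A
        (1 - f) * (1 - gc_skew) / 2,  # C
        (1 - f) * (1 + gc_skew) / 2,  # G
        f * (1 - at_skew) / 2,        # T
    ])
    return p / p.sum()


def _mirror(p: np.ndarray) -> np.ndarray:
    """Complement-mirrored base distribution (A<->T, C<->G)."""
    return p[[3, 2, 1, 0]]


def _sample_bases(rng: np.random.Generator, n: int, p: np.ndarray) -> str:
    return "".join(NUC[rng.choice(4, size=n, p=p)])


def _codon_sampling_probs(at_pct: float, at_skew: float, gc_skew: float
                          ) -> np.ndarray:
    """Base probabilities whose stop-rejected codon stream hits the AT target.

    Rejecting TAA/TAG removes AT-rich codons, so the accepted codons are
    AT-poorer than the raw base distribution. A fixed-point iteration on
    the sampling AT fraction corrects for the analytic acceptance bias:
    with q1 = P(TAA), q2 = P(TAG), the accepted AT fraction is
    (3f − 3q1 − 2q2) / (3(1 − q1 − q2)).
    """
    target_f = at_pct / 100.0
    f = target_f
    for _ in range(25):
        p = _base_probs(100 * f, at_skew, gc_skew)
        pa, pc, pg, pt = p
        q1 = pt * pa * pa
        q2 = pt * pa * pg
        f_acc = (3 * (pa + pt) - 3 * q1 - 2 * q2) / (3 * (1 - q1 - q2))
        f = float(np.clip(f + (target_f - f_acc), 0.01, 0.99))
    return _base_probs(100 * f, at_skew, gc_skew)


def _sample_codons(rng: np.random.Generator, n: int, p: np.ndarray) -> str:
    """n sense codons sampled base-wise with stop-codon rejection."""
    out = []
    while len(out) < n:
        c = _sample_bases(rng, 3, p)
        if c not in STOP_CODONS:
            out.append(c)
    return "".join(out)


def _control_region(rng: np.random.Generator, spec: ControlRegionSpec,
                    seed_k: int = 8) -> str:
    p = _base_probs(spec.at_pct, spec.at_skew, spec.gc_skew)
    seq = list(_sample_bases(rng, spec.length, p))
    cursor = 5
    for base, run in spec.homopolymers:
        if cursor + run >= spec.length:
            break
        seq[cursor : cursor + run] = base * run
        cursor += run + 13
    for rep in spec.repeats:
        motif = _sample_bases(rng, rep.length, p)
        n_mut = int((1 - rep.identity) * rep.length)
        # mutation sites avoid the first seed_k columns (an exact k-mer
        # anchor survives in every copy) and are spread evenly with small
        # seeded jitter, so no window of the pair dips far below the
        # nominal identity — the planted pair stays detectable by
        # seed-and-extend at its ground-truth identity
        base = np.linspace(seed_k + 1, rep.length - 2, n_mut)
        sites = np.round(base + rng.uniform(-1, 1, n_mut)).astype(int)
        sites = np.clip(sites, seed_k, rep.length - 1)
        for idx in range(1, n_mut):
            sites[idx] = max(sites[idx], sites[idx - 1] + 2)
        sites = np.minimum(sites, rep.length - 1)
        gap = rep.length + 25
        needed = rep.count * gap
        start = spec.length - needed - 5
        if start < cursor:
            raise ValueError("control region too short for requested repeats")
        for k in range(rep.count):
            copy = list(motif)
            if k > 0:  # mutate every copy after the first
                for s in sites:
                    alternatives = [b for b in "ACGT" if b != copy[s]]
                    copy[s] = alternatives[rng.integers(3)]
            pos = start + k * gap
            seq[pos : pos + rep.length] = copy
    return "".join(seq)


def _resolve_order(spec: GenomeSpec) -> GeneOrderSignature:
    if isinstance(spec.gene_order, GeneOrderSignature):
        return spec.gene_order
    try:
        return BUILTIN_ORDERS[spec.gene_order]
    except KeyError:
        raise ValueError(f"unknown gene order {spec.gene_order!r}") from None


def generate_genome(spec: GenomeSpec) -> AnnotatedGenome:
    """Generate one annotated genome per ``spec`` (deterministic under seed)."""
    rng = np.random.default_rng(spec.seed)
    order = _resolve_order(spec)
    # the control region has its own AT% target; compensate the gene-region
    # composition so the whole-genome expectation lands on spec.at_pct
    stop_len = {"TAA": 3, "TA": 2, "T": 1}
    gene_len = sum(
        3 * spec.pcg_codons[n] + stop_len[spec.truncated_stops.get(n, "TAA")]
        for n in spec.pcg_codons)
    gene_len += 22 * spec.trna_len + spec.rrns_len + spec.rrnl_len
    gene_len += sum(length for _, length in spec.spacers)
    l_cr = spec.control_region.length
    total = gene_len + l_cr
    at_genes = (spec.at_pct * total - spec.control_region.at_pct * l_cr) / gene_len
    at_genes = float(np.clip(at_genes, 1.0, 99.0))
    p_alpha = _base_probs(at_genes, spec.at_skew, spec.gc_skew)
    # stop-rejection-corrected sampling probabilities per coding strand
    p_pcg = {
        ALPHA: _codon_sampling_probs(at_genes, spec.at_skew, spec.gc_skew),
        BETA: _codon_sampling_probs(at_genes, -spec.at_skew, -spec.gc_skew),
    }
    spacer_after = dict(spec.spacers)

    parts: list[str] = []
    feats: list[GeneFeature] = []
    pos = 1
    for name, strand in order.order:
        p_coding = p_alpha if strand == ALPHA else _mirror(p_alpha)
        if name in spec.pcg_codons:
            ncod = spec.pcg_codons[name]
            body = _sample_codons(rng, ncod - 1, p_pcg[strand])
            stop = spec.truncated_stops.get(name, "TAA")
            if stop not in ("TAA", "TA", "T"):
                raise ValueError(f"{name}: invalid stop spec {stop!r}")
            coding = spec.start_codon + body + stop
        elif name in ("rrnS", "rrnL"):
            n = spec.rrns_len if name == "rrnS" else spec.rrnl_len
            coding = _sample_bases(rng, n, p_coding)
        else:
            coding = _sample_bases(rng, spec.trna_len, p_coding)
        alpha_side = coding if strand == ALPHA else revcomp(coding)
        start = pos
        end = pos + len(alpha_side) - 1
        feats.append(GeneFeature(name=name, start=start, end=end, strand=strand))
        parts.append(alpha_side)
        pos = end + 1
        gap = spacer_after.get(name, 0)
        if gap:
            parts.append(_sample_bases(rng, gap, p_alpha))
            pos += gap

    cr = _control_region(rng, spec.control_region)
    feats.append(GeneFeature(
        name=CONTROL_REGION, start=pos, end=pos + len(cr) - 1, strand=ALPHA))
    parts.append(cr)

    genome = AnnotatedGenome(
        identifier=spec.identifier or f"syn{spec.seed}",
        sequence="".join(parts),
        circular=True,
        features=feats,
    )
    genome = _repair_spurious_starts(genome, rng, p_alpha)
    return _balance_composition(genome, rng, spec)


def _repair_spurious_starts(genome: AnnotatedGenome, rng: np.random.Generator,
                            p_alpha: np.ndarray,
                            max_rounds: int = 200) -> AnnotatedGenome:
    """Mutate spurious upstream in-frame starts so re-inference is exact.

    A codon whose middle base is C or G is neither a legitimate start (all
    have a middle T) nor a stop (middle A), so resampling the middle base
    of the offending codon from {C, G} (on the PCG's coding strand, with
    odds matching the composition targets so strand skews stay unbiased)
    removes the candidate. PCG interiors are never touched; with the
    shipped gene orders the upstream windows contain only spacers and
    tRNA/rRNA filler.
    """
    seq = list(genome.sequence)
    pcg_ranges = []
    for f in genome.features:
        if f.category == "PCG":
            pcg_ranges.append((f.start, f.end))

    def in_pcg(p: int) -> bool:
        return any(a <= p <= b for a, b in pcg_ranges)

    pcgs = [f for f in genome.features if f.category == "PCG"]
    for _ in range(max_rounds):
        genome = AnnotatedGenome(genome.identifier, "".join(seq), True,
                                 list(genome.features))
        dirty = False
        for f in pcgs:
            anchor = f.start if f.strand == ALPHA else f.end
            call = infer_start(genome, f.name, rough_start=anchor)
            if call.position == anchor:
                continue
            dirty = True
            # α-strand position of the offending codon's middle base
            mid = call.position + 1 if f.strand == ALPHA else call.position - 1
            mid_i = (mid - 1) % len(seq)
            if in_pcg(mid_i + 1):
                raise RuntimeError(
                    f"{f.name}: spurious start inside a PCG; unsupported gene order")
            p_coding = p_alpha if f.strand == ALPHA else _mirror(p_alpha)
            p_g = p_coding[2] / (p_coding[1] + p_coding[2])
            base = "G" if rng.random() < p_g else "C"
            seq[mid_i] = base if f.strand == ALPHA else revcomp(base)
            break
        if not dirty:
            return genome
    raise RuntimeError("start repair did not converge")


def _balance_composition(genome: AnnotatedGenome, rng: np.random.Generator,
                         spec: GenomeSpec, margin: int = 100) -> AnnotatedGenome:
    """Nudge whole-α-strand base counts to the targets by filler swaps.

    A↔T and G↔C exchanges preserve AT%/GC% exactly while steering the two
    skews toward their targets. Swaps are restricted to rRNA filler
    interiors (``margin`` bp away from the feature ends), which carry no
    codon structure and lie outside every PCG start-scan window, so no
    annotation invariant can be disturbed. The reservoir is finite: any
    residual deviation is left in place (per-gene composition stays
    stochastic by design).
    """
    seq = list(genome.sequence)
    pool: list[int] = []
    for f in genome.features:
        if f.name in ("rrnS", "rrnL") and f.end - f.start > 2 * margin + 50:
            pool.extend(range(f.start - 1 + margin, f.end - margin))
    pool = np.array(pool)
    rng.shuffle(pool)
    counts = {b: 0 for b in "ACGT"}
    for b in genome.sequence:
        if b in counts:
            counts[b] += 1
    at_tot = counts["A"] + counts["T"]
    gc_tot = counts["G"] + counts["C"]
    need_a = round(at_tot * (1 + spec.at_skew) / 2) - counts["A"]
    need_g = round(gc_tot * (1 + spec.gc_skew) / 2) - counts["G"]
    jobs = [("T", "A", need_a) if need_a > 0 else ("A", "T", -need_a),
            ("C", "G", need_g) if need_g > 0 else ("G", "C", -need_g)]
    for lose, gain, delta in jobs:
        converted = 0
        for i in pool:
            if converted >= delta:
                break
            if seq[i] == lose:
                seq[i] = gain
                converted += 1
    return AnnotatedGenome(genome.identifier, "".join(seq), True,
                           list(genome.features))


# ---------------------------------------------------------------------------
# Alignment evolution along a tree

@dataclass(frozen=True)
class TreeSpec:
    newick: str
    model: SubstitutionModel
    length: int
    seed: int

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("alignment length must be positive")


def evolve_alignment(spec: TreeSpec) -> Alignment:
    """Evolve sequences along a tree under the given substitution model.

    The root sequence is drawn from the model's equilibrium frequencies;
    per-site rates follow the model's discrete-gamma/invariant mixture;
    states propagate edge by edge through exact transition matrices.
    """
    tree = dendropy.Tree.get(data=spec.newick, schema="newick")
    rng = np.random.default_rng(spec.seed)
    model = spec.model
    n_states = model.n_states
    states = np.array(list(model.states))

    weights, rates = model.rate_mixture()
    site_cat = rng.choice(len(rates), size=spec.length, p=weights)
    site_rate = rates[site_cat]

    root_seq = rng.choice(n_states, size=spec.length, p=model.freqs)
    seqs = {id(tree.seed_node): root_seq}
    tip_rows: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            current = root_seq
        else:
            parent = seqs[id(node.parent_node)]
            t = node.edge.length or 0.0
            current = parent.copy()
            if t > 0:
                for r in np.unique(site_rate):
                    sites = np.where(site_rate == r)[0]
                    if r == 0 or len(sites) == 0:
                        continue
                    p = model.transition_matrix(t * r)
                    # sample child states row-wise from P[parent]
                    u = rng.random(len(sites))
                    cum = np.cumsum(p[parent[sites]], axis=1)
                    current[sites] = (u[:, None] > cum).sum(axis=1)
            seqs[id(node)] = current
        if node.is_leaf():
            tip_rows[node.taxon.label] = "".join(states[current])
    moltype = "nt" if n_states == 4 else "aa"
    ids = sorted(tip_rows)
    return Alignment(ids, [tip_rows[i] for i in ids], moltype)


def planted_repeat_coords(cr: ControlRegionSpec) -> list[tuple[int, int]]:
    """1-based (start, end) of each planted repeat copy within the region."""
    out = []
    for rep in cr.repeats:
        gap = rep.length + 25
        start0 = cr.length - rep.count * gap - 5
        for k in range(rep.count):
            out.append((start0 + k * gap + 1, start0 + k * gap + rep.length))
    return out


# ---------------------------------------------------------------------------
# Cohorts

def fixture_cohort(n: int, regimes=None, seed: int = 0) -> list[AnnotatedGenome]:
    """Reproducible cohort of ``n`` genomes cycling composition regimes.

    ``regimes`` is a list of dicts of :class:`GenomeSpec` overrides (for
    example target AT%/skews or a gene order); defaults to a spread of
    composition regimes covering the common cluster range.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if regimes is None:
        regimes = [
            {"at_pct": 68.0, "at_skew": 0.12, "gc_skew": -0.24},
            {"at_pct": 72.5, "at_skew": 0.07, "gc_skew": -0.31},
            {"at_pct": 77.5, "at_skew": 0.02, "gc_skew": -0.22},
            {"at_pct": 82.0, "at_skew": -0.02, "gc_skew": -0.17},
            {"at_pct": 86.0, "at_skew": 0.01, "gc_skew": -0.12},
        ]
    out = []
    for i in range(n):
        overrides = dict(regimes[i % len(regimes)])
        overrides.setdefault("identifier", f"syn{i + 1}")
        out.append(generate_genome(GenomeSpec(seed=seed + i, **overrides)))
    return out
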