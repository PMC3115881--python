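"""Annotated mitogenome containers, readers/writers, and gene-order comparison.

Coordinates are 1-based inclusive positions on the α strand (the strand
carrying the majority of clockwise-oriented genes in the ancestral insect
arrangement). A single feature may wrap past the origin of a circular
molecule, in which case ``end < start``.

Gene names come from a closed 38-name vocabulary: the 13 protein-coding
genes, 22 tRNAs (with the two leucine and two serine isoacceptors
distinguished as trnL1/trnL2 and trnS1/trnS2), the two rRNAs, and the
control region. GenBank labels are canonicalized through a synonym table;
an unrecognizable label is an error, never silently dropped, because a
misnamed gene corrupts every pooled per-strand statistic downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

from Bio import SeqIO

from .genetic_code import revcomp

log = logging.getLogger(__name__)

ALPHA = "alpha"
BETA = "beta"

PCG_NAMES = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)
TRNA_NAMES = tuple(
    "trn" + x
    for x in ("A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2",
              "M", "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y")
)
RRNA_NAMES = ("rrnS", "rrnL")
GENE_NAMES = PCG_NAMES + TRNA_NAMES + RRNA_NAMES
CONTROL_REGION = "control_region"
ALL_NAMES = GENE_NAMES + (CONTROL_REGION,)

CATEGORY_OF = {n: "PCG" for n in PCG_NAMES}
CATEGORY_OF.update({n: "tRNA" for n in TRNA_NAMES})
CATEGORY_OF.update({n: "rRNA" for n in RRNA_NAMES})
CATEGORY_OF[CONTROL_REGION] = "control_region"


class AnnotationError(ValueError):
    """Raised for unresolvable gene names or inconsistent coordinates."""


@dataclass(frozen=True)
class GeneFeature:
    """One gene (or the control region) on the α-strand coordinate system."""

    name: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive; < start for origin-spanning features
    strand: str  # ALPHA | BETA
    category: str = ""

    def __post_init__(self):
        if self.name not in ALL_NAMES:
            raise AnnotationError(f"unknown canonical gene name: {self.name!r}")
        if self.start < 1 or self.end < 1:
            raise AnnotationError(f"{self.name}: coordinates must be >= 1")
        if self.strand not in (ALPHA, BETA):
            raise AnnotationError(f"{self.name}: strand must be {ALPHA!r} or {BETA!r}")
        if not self.category:
            object.__setattr__(self, "category", CATEGORY_OF[self.name])

    def length(self, genome_length: int) -> int:
        if self.end >= self.start:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end

    def wraps(self) -> bool:
        return self.end < self.start


@dataclass
class AnnotatedGenome:
    """A circular (or linear) mitogenome: α-strand sequence plus features."""

    identifier: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("U", "T")
        if not self.sequence:
            raise AnnotationError(f"{self.identifier}: empty sequence")
        seen: set[str] = set()
        for f in self.features:
            if f.name in seen:
                raise AnnotationError(f"{self.identifier}: duplicate feature {f.name}")
            seen.add(f.name)
            if not self.circular and (f.wraps() or f.end > len(self.sequence)):
                raise AnnotationError(
                    f"{self.identifier}: feature {f.name} exceeds linear sequence"
                )
            if f.start > len(self.sequence):
                raise AnnotationError(
                    f"{self.identifier}: feature {f.name} starts beyond sequence end"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"{self.identifier}: no feature named {name!r}")

    def has_feature(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def gene_features(self) -> list[GeneFeature]:
        """Features that are genes (control region excluded), in α order."""
        return sorted(
            (f for f in self.features if f.name != CONTROL_REGION),
            key=lambda f: f.start,
        )


# ---------------------------------------------------------------------------
# Name canonicalization

def _clean(label: str) -> str:
    return re.sub(r"[^a-z0-9]", "", label.lower())


_SYNONYMS: dict[str, str] = {}


def _add_syn(canonical: str, *labels: str) -> None:
    for lab in labels:
        _SYNONYMS[_clean(lab)] = canonical


for i in (1, 2, 3):
    _add_syn(f"cox{i}", f"cox{i}", f"co{i}", f"COX{'I' * i}", f"CO{'I' * i}",
             f"cytochrome c oxidase subunit {i}", f"cytochrome oxidase subunit {i}",
             f"coxsubunit{i}")
for i in (1, 2, 3, 4, 5, 6):
    _add_syn(f"nad{i}", f"nad{i}", f"nd{i}", f"nadh{i}",
             f"NADH dehydrogenase subunit {i}")
_add_syn("nad4L", "nad4L", "nd4l", "nadh4l", "NADH dehydrogenase subunit 4L")
_add_syn("atp6", "atp6", "atpase6", "atpase subunit 6", "ATP synthase F0 subunit 6")
_add_syn("atp8", "atp8", "atpase8", "atpase subunit 8", "ATP synthase F0 subunit 8")
_add_syn("cob", "cob", "cytb", "cyt b", "cytochrome b", "apocytochrome b")
_add_syn("rrnS", "rrnS", "12S", "12S rRNA", "12S ribosomal RNA", "srRNA",
         "s-rRNA", "small subunit ribosomal RNA", "rns")
_add_syn("rrnL", "rrnL", "16S", "16S rRNA", "16S ribosomal RNA", "lrRNA",
         "l-rRNA", "large subunit ribosomal RNA", "rnl")
_add_syn(CONTROL_REGION, "control region", "D-loop", "AT-rich region", "A+T-rich region")

_AA1 = {"Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
        "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
        "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
        "Tyr": "Y", "Val": "V"}
for three, one in _AA1.items():
    if one in ("L", "S"):
        continue
    _add_syn(f"trn{one}", f"trn{one}", f"tRNA-{three}", f"trna{three}", f"tRNA {three}")
_add_syn("trnL1", "trnL1", "tRNA-Leu(CUN)", "trnL(cun)", "tRNA-Leu (CUN)", "trnLcun")
_add_syn("trnL2", "trnL2", "tRNA-Leu(UUR)", "trnL(uur)", "tRNA-Leu (UUR)", "trnLuur")
_add_syn("trnS1", "trnS1", "tRNA-Ser(AGN)", "trnS(agn)", "tRNA-Ser (AGN)", "trnSagn")
_add_syn("trnS2", "trnS2", "tRNA-Ser(UCN)", "trnS(ucn)", "tRNA-Ser (UCN)", "trnSucn")


def canonical_name(label: str) -> str:
    """Map a free-text gene label to its canonical name.

    Raises :class:`AnnotationError` with the offending label when the name
    cannot be resolved.
    """
    key = _clean(label)
    if label in ALL_NAMES:
        return label
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    raise AnnotationError(f"cannot canonicalize gene label {label!r}")


# ---------------------------------------------------------------------------
# Readers / writers

def read_genbank(path) -> AnnotatedGenome:
    """Read a GenBank flat file into an :class:`AnnotatedGenome`.

    ``gene`` features are used only when no CDS/tRNA/rRNA feature provides
    the same canonical name; β-strand features receive α coordinates plus
    the strand flag.
    """
    record = SeqIO.read(str(path), "genbank")
    circular = record.annotations.get("topology", "circular") == "circular"
    n = len(record.seq)
    by_name: dict[str, tuple[str, GeneFeature]] = {}
    preferred = {"CDS", "tRNA", "rRNA", "misc_feature", "D-loop"}
    for feat in record.features:
        if feat.type not in preferred and feat.type != "gene":
            continue
        label = None
        for q in ("gene", "product", "note"):
            if q in feat.qualifiers:
                label = feat.qualifiers[q][0]
                break
        if label is None:
            if feat.type == "D-loop":
                label = "D-loop"
            else:
                continue
        name = canonical_name(label)
        parts = feat.location.parts
        start = int(parts[0].start) + 1
        end = int(parts[-1].end)
        if end > n:
            if not circular:
                raise AnnotationError(
                    f"{record.id}: {name} coordinates exceed linear sequence"
                )
            end -= n
        strand = BETA if feat.location.strand == -1 else ALPHA
        gf = GeneFeature(name=name, start=start, end=end, strand=strand)
        prev = by_name.get(name)
        if prev is None or (prev[0] == "gene" and feat.type in preferred):
            by_name[name] = (feat.type, gf)
    feats = sorted((gf for _, gf in by_name.values()), key=lambda f: f.start)
    return AnnotatedGenome(
        identifier=record.id or record.name,
        sequence=str(record.seq),
        circular=circular,
        features=feats,
    )


_STRAND_IN = {ALPHA: ALPHA, BETA: BETA, "+": ALPHA, "-": BETA, "a": ALPHA, "b": BETA}
_STRAND_OUT = {ALPHA: ALPHA, BETA: BETA}

TABLE_HEADER = "name\tstart\tend\tstrand\tcategory"


def read_feature_table(fasta_path, table_path) -> AnnotatedGenome:
    """Read the FASTA + TSV feature-table pair emitted by the generator."""
    record = SeqIO.read(str(fasta_path), "fasta")
    feats: list[GeneFeature] = []
    with open(table_path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if cols[:4] != ["name", "start", "end", "strand"]:
            raise AnnotationError(f"{table_path}: unexpected header {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            row = line.split("\t")
            name = canonical_name(row[0])
            try:
                start, end = int(row[1]), int(row[2])
            except ValueError as exc:
                raise AnnotationError(f"{table_path}: bad coordinates in {row}") from exc
            if start < 1 or end < 1:
                raise AnnotationError(f"{table_path}: non-positive coordinate in {row}")
            strand = _STRAND_IN.get(row[3])
            if strand is None:
                raise AnnotationError(f"{table_path}: bad strand {row[3]!r}")
            feats.append(GeneFeature(name=name, start=start, end=end, strand=strand))
    if not feats:
        log.warning("%s: empty feature table", table_path)
    return AnnotatedGenome(
        identifier=record.id,
        sequence=str(record.seq),
        circular=True,
        features=sorted(feats, key=lambda f: f.start),
    )


def write_feature_table(genome: AnnotatedGenome, fasta_path, table_path) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.identifier}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    with open(table_path, "w") as fh:
        fh.write(TABLE_HEADER + "\n")
        for f in sorted(genome.features, key=lambda f: f.start):
            fh.write(f"{f.name}\t{f.start}\t{f.end}\t{f.strand}\t{f.category}\n")


# ---------------------------------------------------------------------------
# Sequence extraction

def slice_circular(sequence: str, start: int, end: int) -> str:
    """1-based inclusive α-strand slice, wrapping past the origin if end<start."""
    if end >= start:
        return sequence[start - 1 : end]
    return sequence[start - 1 :] + sequence[:end]


def extract_gene_sequence(genome: AnnotatedGenome, name: str) -> str:
    """5'→3' coding-strand sequence of a named feature.

    β-strand genes are reverse-complemented; origin-spanning features are
    concatenated across the origin first.
    """
    f = genome.feature(name)
    raw = slice_circular(genome.sequence, f.start, f.end)
    return revcomp(raw) if f.strand == BETA else raw


# ---------------------------------------------------------------------------
# Gene order

@dataclass(frozen=True)
class GeneOrderSignature:
    """Anchored clockwise (gene, strand) sequence of a circular genome."""

    order: tuple[tuple[str, str], ...]

    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.order)

    def strand_of(self, gene: str) -> str:
        for g, s in self.order:
            if g == gene:
                return s
        raise KeyError(gene)

    def anchored(self, anchor: str) -> "GeneOrderSignature":
        genes = self.genes()
        if anchor not in genes:
            raise KeyError(f"anchor {anchor!r} absent from signature")
        i = genes.index(anchor)
        return GeneOrderSignature(self.order[i:] + self.order[:i])


#: the ancestral insect arrangement (the Drosophila yakuba order), anchored at trnI
ANCESTRAL_INSECT_ORDER = GeneOrderSignature(tuple(
    (g, BETA if b else ALPHA) for g, b in (
        ("trnI", 0), ("trnQ", 1), ("trnM", 0), ("nad2", 0), ("trnW", 0),
        ("trnC", 1), ("trnY", 1), ("cox1", 0), ("trnL2", 0), ("cox2", 0),
        ("trnK", 0), ("trnD", 0), ("atp8", 0), ("atp6", 0), ("cox3", 0),
        ("trnG", 0), ("nad3", 0), ("trnA", 0), ("trnR", 0), ("trnN", 0),
        ("trnS1", 0), ("trnE", 0), ("trnF", 1), ("nad5", 1), ("trnH", 1),
        ("nad4", 1), ("nad4L", 1), ("trnT", 0), ("trnP", 1), ("nad6", 0),
        ("cob", 0), ("trnS2", 0), ("nad1", 1), ("trnL1", 1), ("rrnL", 1),
        ("trnV", 1), ("rrnS", 1),
    )
))

#: the neuropteran arrangement: trnC translocated upstream of trnW
def _translocate(sig: GeneOrderSignature, gene: str, before: str) -> GeneOrderSignature:
    order = [gs for gs in sig.order if gs[0] != gene]
    moved = next(gs for gs in sig.order if gs[0] == gene)
    idx = next(i for i, gs in enumerate(order) if gs[0] == before)
    order.insert(idx, moved)
    return GeneOrderSignature(tuple(order))


NEUROPTERA_ORDER = _translocate(ANCESTRAL_INSECT_ORDER, "trnC", "trnW")

#: the lepidopteran arrangement: trnM translocated upstream of trnI
LEPIDOPTERA_ORDER = _translocate(ANCESTRAL_INSECT_ORDER, "trnM", "trnI")

BUILTIN_ORDERS = {
    "ancestral_insect": ANCESTRAL_INSECT_ORDER,
    "neuroptera": NEUROPTERA_ORDER,
    "lepidoptera": LEPIDOPTERA_ORDER,
}


def gene_order_signature(genome: AnnotatedGenome, anchor: str = "trnI") -> GeneOrderSignature:
    """Clockwise gene order along α, anchored at ``anchor``.

    Spacers and the control region are excluded. The anchored form is
    unique under rotation of the circular coordinate system.
    """
    feats = genome.gene_features()
    if not feats:
        raise AnnotationError(f"{genome.identifier}: no gene features")
    sig = GeneOrderSignature(tuple((f.name, f.strand) for f in feats))
    if len(feats) == 1:
        return sig
    return sig.anchored(anchor)


@dataclass(frozen=True)
class OrderComparison:
    missing_from_a: tuple[str, ...]
    missing_from_b: tuple[str, ...]
    strand_changes: tuple[str, ...]
    repositioned: tuple[str, ...]
    breakpoints: int


def _adjacencies(genes: tuple[str, ...]) -> set[tuple[str, str]]:
    n = len(genes)
    return {(genes[i], genes[(i + 1) % n]) for i in range(n)}


def _cyclic_equal(a: tuple[str, ...], b: tuple[str, ...]) -> bool:
    if len(a) != len(b):
        return False
    if not a:
        return True
    if a[0] not in b:
        return False
    i = b.index(a[0])
    return a == b[i:] + b[:i]


def compare_gene_orders(a: GeneOrderSignature, b: GeneOrderSignature) -> OrderComparison:
    """Report gene content, strand, and adjacency differences between orders.

    The breakpoint count is the number of circular adjacencies of ``a`` not
    present in ``b``, computed on the common gene set. The ``repositioned``
    set is the greedy-minimal set of genes whose removal makes the two
    circular orders identical — exact for isolated single-gene
    translocations, heuristic beyond that.
    """
    ga, gb = set(a.genes()), set(b.genes())
    common = ga & gb
    if not common:
        raise ValueError("gene orders share no genes")
    order_a = tuple(g for g in a.genes() if g in common)
    order_b = tuple(g for g in b.genes() if g in common)
    strand_changes = tuple(sorted(
        g for g in common if a.strand_of(g) != b.strand_of(g)
    ))
    breakpoints = len(_adjacencies(order_a) - _adjacencies(order_b))

    repositioned: list[str] = []
    cur_a, cur_b = order_a, order_b
    while not _cyclic_equal(cur_a, cur_b) and len(cur_a) > 2:
        best_gene, best_bp = None, None
        for g in cur_a:
            ta = tuple(x for x in cur_a if x != g)
            tb = tuple(x for x in cur_b if x != g)
            bp = len(_adjacencies(ta) - _adjacencies(tb))
            if best_bp is None or bp < best_bp:
                best_gene, best_bp = g, bp
        base_bp = len(_adjacencies(cur_a) - _adjacencies(cur_b))
        if best_bp is not None and best_bp < base_bp:
            repositioned.append(best_gene)
            cur_a = tuple(x for x in cur_a if x != best_gene)
            cur_b = tuple(x for x in cur_b if x != best_gene)
        else:
            break
    return OrderComparison(
        missing_from_a=tuple(sorted(gb - ga)),
        missing_from_b=tuple(sorted(ga - gb)),
        strand_changes=strand_changes,
        repositioned=tuple(repositioned),
        breakpoints=breakpoints,
    )
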