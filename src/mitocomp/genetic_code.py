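"""Invertebrate mitochondrial genetic code (NCBI transl_table 5) and codon families.

Relative to the standard code: TGA encodes Trp, ATA encodes Met, and AGA/AGG
encode Ser, leaving 62 sense codons and only two stops (TAA, TAG). Two codon
family partitions are used in this package:

* the 22-family *reporting* scheme, which splits Leu into Leu1 (CTN) and
  Leu2 (TTR) and Ser into Ser1 (AGN) and Ser2 (TCN) — the convention of
  strand-ratio and RSCU tables in the mitogenomics literature;
* the *full-code* synonymous families (Leu 6-fold, Ser 8-fold), over which
  Wright's effective number of codons is defined.
"""

from __future__ import annotations

from Bio.Data import CodonTable

NUCS = "ACGT"

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]

#: codon -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_TABLE5.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_TABLE5.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(a + b + c for a in NUCS for b in NUCS for c in NUCS if a + b + c not in STOP_CODONS)
)

assert len(SENSE_CODONS) == 62

#: canonical start codons accepted for mitochondrial PCGs: ATN, GTG, TTG, GTT
START_CODONS: frozenset[str] = frozenset(
    {"ATA", "ATC", "ATG", "ATT", "GTG", "TTG", "GTT"}
)

AA_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


def _family22(codon: str) -> str:
    aa = CODON_TO_AA[codon]
    if aa == "L":
        return "Leu1" if codon.startswith("C") else "Leu2"
    if aa == "S":
        return "Ser1" if codon.startswith("AG") else "Ser2"
    return AA_THREE[aa]


#: codon -> 22-family name (Leu1/Leu2, Ser1/Ser2 split)
FAMILY22: dict[str, str] = {c: _family22(c) for c in SENSE_CODONS}

FAMILY22_NAMES: tuple[str, ...] = tuple(
    sorted(set(FAMILY22.values()), key=lambda f: (f not in ("Leu1", "Leu2", "Ser1", "Ser2"), f))
)

#: codon -> full-code synonymous family (amino acid, Leu 6-fold / Ser 8-fold)
FAMILY_FULL: dict[str, str] = {c: AA_THREE[CODON_TO_AA[c]] for c in SENSE_CODONS}


def family_members(scheme: dict[str, str]) -> dict[str, tuple[str, ...]]:
    """Invert a codon->family map into family -> sorted member codons."""
    out: dict[str, list[str]] = {}
    for codon, fam in scheme.items():
        out.setdefault(fam, []).append(codon)
    return {f: tuple(sorted(m)) for f, m in out.items()}


FULL_FAMILIES: dict[str, tuple[str, ...]] = family_members(FAMILY_FULL)
FAMILIES22: dict[str, tuple[str, ...]] = family_members(FAMILY22)

# degeneracy classes of the full-code scheme: {2: 12 families, 4: 6, 6: 1, 8: 1}
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for fam, members in sorted(FULL_FAMILIES.items()):
    DEGENERACY_CLASSES.setdefault(len(members), tuple())
    DEGENERACY_CLASSES[len(members)] += (fam,)

_COMPL = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide sequence; stops become ``*``."""
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3].upper()
        if codon in STOP_CODONS:
            aas.append("*")
        else:
            aas.append(CODON_TO_AA.get(codon, "X"))
    return "".join(aas)
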