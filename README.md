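# mitocomp

Comparative mitochondrial genomics for insect mitogenomes: a tested,
reusable implementation of the analysis stack used to characterize newly
sequenced mitochondrial genomes against a cohort of published ones —
annotation accounting, compositional strand asymmetry, codon-usage bias,
phylogenetic-marker evaluation, and control-region motif structure.

It is written for molecular systematists and mitogenomicists who assemble
and annotate insect (or other metazoan) mtDNAs and want the standard
comparative battery as importable, deterministic functions rather than a
chain of GUI tools.

## What it computes

**Genome structure.** GenBank or FASTA+feature-table input; canonical
naming of the 37 mitochondrial genes; start-codon inference at the first
legitimate in-frame codon (ATN, GTG, TTG, GTT) outside the upstream
same-strand gene; stop inference with truncated T/TA stops completed by
polyadenylation; per-feature tables with intergenic counts (negative for
overlaps); non-coding portions with spacer labels; anchored gene-order
signatures and breakpoint comparisons (e.g., the neuropteran trnC
translocation).

**Composition.** AT% plus the strand-asymmetry skews

    AT-skew = (A − T)/(A + T),    GC-skew = (G − C)/(G + C)

on the α strand (the strand carrying the majority of clockwise genes) or
pooled over coding strands, with the fixed A1–A5/B1–B6/C1–C6 cluster bins
used for endopterygotan surveys, and cohort summaries.

**Codon usage.** Counts with first/stop codons excluded, codons per
thousand, relative synonymous codon usage RSCU(c) = n_c·|F| / Σ_{c'∈F}
n_{c'} under the 22-family scheme (Leu1/Leu2, Ser1/Ser2 split), Wright's
effective number of codons generalized to the invertebrate mitochondrial
code (62 sense codons; Leu 6-fold, Ser 8-fold), and the ratio_α/β
strand-distribution statistic per codon family.

**Marker evaluation.** Pairwise p-distances; maximum-likelihood pairwise
distances under GTR(+I+G) for nucleotides and mtREV24/JTT(+G) for
proteins (eigendecomposition + bounded 1-D likelihood optimization over
site-pattern counts); the saturation **m-slope** — the through-origin
regression slope of p-distances on corrected distances (m = 1: no
saturation; m ≪ 1: heavy saturation); and quartet likelihood mapping:
every taxon quartet is scored under its three topologies by the pruning
algorithm, the posterior weights are placed on the topology simplex, and
**%FRQ** is the percentage landing in a corner (fully resolved) region.

**Conservation and control regions.** %INUC (percent fully conserved
columns) for orthologous-gene alignments; affine-gap global alignment
(Gotoh three-state DP) with the relaxed gap costs (opening 1, extension 3)
used for fast-evolving AT-rich regions, reporting idNP/%ID/ALNL;
homopolymer runs, overlap-counted motif frequencies, and seed-and-extend
approximate repeats at a 75% identity floor with
parenthesized-alternative consensus strings.

**Synthetic data.** A seeded generator for annotated 37-gene circular
mitogenomes with target composition, legitimate ORFs, spacers, and an
AT-rich control region with planted homopolymers and repeats — plus a
GTR+Γ alignment evolver along arbitrary newick trees. Every analysis in
the package is testable end-to-end without downloading a single accession.

## Worked example

```python
from mitocomp.synthetic import GenomeSpec, generate_genome
from mitocomp.composition import whole_genome_profile, assign_clusters
from mitocomp.codon_usage import extract_codons, enc
from mitocomp.genome_io import (gene_order_signature, compare_gene_orders,
                                ANCESTRAL_INSECT_ORDER)

g = generate_genome(GenomeSpec(seed=7, gene_order="neuroptera"))
p = whole_genome_profile(g)
print(len(g), round(p.at_pct, 2), round(p.at_skew, 4), round(p.gc_skew, 4))
# 15831 78.74 0.02 -0.2002
print(assign_clusters(p))
# ClusterLabel(at_cluster='A3', atskew_cluster='B2', gcskew_cluster='C4', ...)
print(round(enc(extract_codons(g)), 3))
# 43.361
rep = compare_gene_orders(gene_order_signature(g), ANCESTRAL_INSECT_ORDER)
print(rep.repositioned, rep.breakpoints)
# ('trnC',) 3
```

The 15.8-kb genome realizes its composition targets (AT% 78.7, AT-skew
0.020, GC-skew −0.200 → clusters A3/B2/C4), shows the moderately biased
codon usage typical of AT-rich mitogenomes (ENC ≈ 43 of a possible 62),
and its gene order differs from the ancestral insect arrangement only by
the repositioned trnC (three broken adjacencies) — the diagnostic
neuropteran signature.

The `analysis/` directory holds the numbered study drivers
(`01_simulate_cohort.py` … `06_control_region.py`): they build a seeded
six-genome cohort spanning the composition clusters, then run structure
accounting, composition clustering (including the 84-taxon published
survey shipped as `mitocomp/data/endopterygota_composition.tsv`), codon
usage, marker-signal evaluation, and control-region analysis, writing
their tables under `results/`. A `mitocomp` CLI wraps the same functions
(`mitocomp simulate genome`, `mitocomp composition`, `mitocomp dist`,
`mitocomp align`, `mitocomp motifs`, `mitocomp run --config run.yaml`).

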