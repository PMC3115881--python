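# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind each part of the package. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates, strands, and gene names

Coordinates are 1-based inclusive positions on the α strand — the strand
carrying the majority of clockwise-oriented genes in the ancestral insect
gene arrangement. A circular molecule permits a single wrap-around feature
(`end < start`). The 38-name vocabulary comprises the 13 protein-coding
genes (atp6, atp8, cob, cox1–3, nad1–6, nad4L), 22 tRNAs (trnL1/trnL2 and
trnS1/trnS2 distinguished by codon family), rrnS/rrnL, and the control
region. GenBank labels are canonicalized through a synonym table
(COI→cox1, ND4L→nad4L, 16S→rrnL, tRNA-Leu(UUR)→trnL2, …); an
unrecognizable label raises an error rather than being dropped, because a
silently misnamed gene corrupts every pooled per-strand statistic
downstream.

Three gene orders ship as built-ins: the ancestral insect arrangement,
the neuropteran variant (trnC translocated upstream of trnW), and the
lepidopteran variant (trnM upstream of trnI). Gene-order comparison
reports content differences, strand changes, a circular breakpoint count
(adjacencies of one order absent from the other, on the common gene set),
and a repositioned-gene set found by greedily removing the gene whose
removal most reduces the breakpoint count until the circular orders
coincide — exact for isolated single-gene translocations, heuristic for
complex rearrangement histories, which are out of scope.

## Boundary inference

The 5' end of a PCG is the first legitimate in-frame start codon (ATN,
GTG, TTG, GTT) at or downstream of the 3' end of the upstream same-strand
gene, scanning a window (default 90 bp) around the annotated start; an
in-frame stop between a candidate and the gene body invalidates the
candidate (the ORF must be unbroken). atp6 and nad4 are exempt from the
upstream constraint because they habitually overlap atp8 and nad4L; the
exemption list is configurable. When no legitimate codon exists in the
window, the annotated start is kept and flagged non-canonical — the
manual-override path for starts like ACG, which in practice are resolved
by protein comparison, a step deliberately out of scope.

The 3' end is the first in-frame TAA/TAG (TGA is Trp under the
invertebrate mitochondrial code). A stop that would reach inside the
downstream same-strand gene truncates the CDS to the T or TA abutting
that gene, the transcript being completed to TAA by polyadenylation; a
full stop ending exactly at the downstream boundary is kept complete.
Genes whose downstream neighbour is atp6 or nad4 may carry a complete
stop inside that neighbour (the atp8–atp6 overlap case). Truncated stops
are rendered with genomic bases upper-case and the polyadenylated
completion lower-case: T → `Taa`, TA → `TAa`.

Non-coding portions (ncps) are maximal runs covered by no gene; an
annotated control region is deliberately excluded from coverage so it
surfaces as the largest ncp. Runs of at least 15 bp (configurable) are
labeled s1, s2, … by start coordinate.

## Composition and cluster bins

AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C). Whole-genome profiles
are computed on the α strand; pooled profiles concatenate PCG
coding-strand sequences for the selected strand set, so pooled skews are
coding-strand skews. N bases are excluded from all denominators;
sequences over 10% N trigger a warning; a zero denominator flags the skew
as undefined (NaN).

Cluster bins are fixed, half-open on the right:

* AT%: A1 < 70, A2 [70, 75), A3 [75, 80), A4 [80, 85), A5 ≥ 85;
* AT-skew: B1 < 0, then 0.050-wide bins B2–B5, B6 ≥ 0.20;
* GC-skew: C1 < −0.35, then 0.050-wide bins C2–C6 up to −0.10; values at
  or above −0.10 fall outside the scheme and are flagged.

One edge deviates from the naive 0.050 grid: the C5/C6 boundary sits at
−0.151, not −0.15, because the published cluster assignments in the
84-taxon survey place −0.1519 in C5 but −0.1504 in C6 — the
label-consistent boundary lies strictly inside (−0.1519, −0.1504]. The
shipped fixture `endopterygota_composition.tsv` (84 published taxa with
AT%, skews, and printed cluster labels) is regression-tested: all 84×3
labels must be re-derived exactly.

## Codon usage

Codon extraction drops each gene's first codon and its terminal stop,
complete (TAA/TAG) or truncated (T/TA); an internal stop is an error that
names the gene and codon index. Two family partitions serve different
purposes:

* the **22-family reporting scheme** (Leu1 = CTN, Leu2 = TTR, Ser1 = AGN,
  Ser2 = TCN, plus 18 amino-acid families) for codons-per-thousand, RSCU,
  and the strand-ratio table;
* the **full-code synonymous families** (Leu 6-fold, Ser 8-fold; classes
  2-fold ×12, 4-fold ×6, 6-fold ×1, 8-fold ×1) for Wright's ENC, which is
  defined over true synonym sets.

ENC uses the homozygosity estimator F̂ = (nΣp² − 1)/(n − 1) per family
(families with n < 2 are not estimable), class contributions
|class|/mean F̂, and a cap at 62 with a floor at the family count (20). A
class with no estimable family borrows the mean "bias level"
b = (F̂ − 1/k)/(1 − 1/k) of the estimable classes, giving F̂ = 1/k +
b(1 − 1/k). This imputation reproduces both analytic limits exactly:
uniform usage over all 62 sense codons → 24 + 24 + 6 + 8 = 62; one codon
per family → 20. ENC is refused below 55 codons (the reliability floor
that excludes atp8 from single-gene analysis; configurable).

ratio_α/β divides a family's pooled-α count by its pooled-β count per
genome, averaging across genomes; the overall ratio (oavg) is total α
codons over total β codons, its spread computed across genomes (the
alternative reading — spread across families — is noted as ambiguous in
the source material). A zero β count flags the ratio infinite and
excludes it from that family's average with a warning.

## Distances and substitution models

p-distances count differing over comparable sites, with pairwise deletion
by default (it maximizes comparable sites on patchy mitochondrial
alignments; complete deletion is available). Ambiguity codes are missing
data.

ML pairwise distances maximize Σ_sites log Σ_c w_c π_x P_c(x→y | t r_c)
over t ∈ [1e-9, 10]. The reversible rate matrix Q_ij = s_ij π_j is scaled
to one expected substitution per unit time at stationarity and
eigendecomposed once via the π^{1/2} symmetrization, so each rate class's
transition matrix is three matrix products. Rate mixtures use Yang's
discrete gamma (equal-probability categories, category-mean rates;
default 4 categories) plus an optional invariant class (variable-class
rates rescaled by 1/(1−pinv)). The optimization is scipy's bounded Brent
with xatol 1e-10; the JC special case agrees with the closed form
−(3/4)ln(1 − 4p/3) to 1e-6 (tested across p = 0.05…0.6), and the uniform
20-state protein model with the Poisson closed form. Distances reaching
98% of the cap (default 10) are flagged saturated.

GTR parameters default to empirical base frequencies plus exchangeabilities
estimated by maximizing the summed pairwise log-likelihood (Nelder–Mead on
the five free log-rates, re-optimizing distances each step); gamma shape
and pinv are user-set, not estimated. Protein distances use the mtREV24 or
JTT empirical replacement matrices, shipped as plain-text tables of the
published exchangeabilities and frequencies.

## Saturation and quartet signal

The m-slope is the through-origin least-squares slope Σxy/Σx² of
p-distances (y) on corrected distances (x) over unordered pairs.
Saturation-flagged pairs are excluded rather than winsorized — capped
values would bias the slope downward unpredictably. Identity data gives
m = 1 exactly; the all-zero degenerate case returns 1 (no saturation
signal in no divergence).

Quartet likelihood mapping scores each quartet under its three unrooted
topologies, maximizing the pruning-algorithm likelihood over the five
branch lengths (L-BFGS-B, bounds [1e-8, 10], a fixed start plus two
seeded random restarts). Posterior weights p_i = L_i/ΣL_j use log-sum-exp
stabilization. The simplex partition follows the canonical seven-region
geometry: corner i where p_i > 2/3 ("fully resolved"), edge regions where
the smallest weight is < 1/3 without a corner, center otherwise; both
thresholds are configurable so sensitivity can be tested. %FRQ evaluates
all quartets up to C(n,4) = 20,000, then falls back to a seeded uniform
sample of 10,000; non-convergent quartets are excluded from the
denominator with a warning. Because the original analyses delegated the
simplex geometry and model settings to external programs whose internals
are not recoverable, absolute published %FRQ and m-slope values are
reference points, not bit-exact targets; the package's acceptance surface
is the property set (closed-form oracles, slope monotone in tree depth,
resolved ≫ star-tree signal, 5% median recovery of true path lengths).

## Conservation and pairwise alignment

A column of a multiple alignment is conserved only if every row carries
the same non-gap symbol; gap-containing columns are variable. %INUC =
100·conserved/length. An optional majority-threshold mode exists but
defaults off.

The pairwise aligner is the Gotoh three-state global DP with affine costs
(a gap of length g costs open + extend·g). The fill is vectorized per
row; the insert-in-a recurrence unrolls into a cumulative-maximum scan,
so the DP is O(nm) numpy work rather than a Python double loop. Traceback
tie-breaking is fixed: diagonal over up over left, and staying in a gap
state over opening a new one — bit-reproducible alignments. Input is
case-insensitive, U maps to T. The relaxed control-region parameters
(opening 1, extension 3 against the standard 15/6.6) ship as a named
constant; note the relaxed opening is *smaller* than the extension, so no
open ≥ extend constraint is imposed. Scores are verified against an
exhaustive alignment-space oracle on short sequences; co-optimal
alignments can differ in length, so the oracle checks that the score is
exactly optimal and the produced length is attainable by an optimal
alignment.

## Control-region motifs

Motif counting slides a window and counts overlapping occurrences
(required for AT-rich regions where ATA-type motifs self-overlap).
Approximate repeats replace a spectral (Fourier) repeat finder, whose
parameters are not recoverable, with a deterministic seed-and-extend
scan: exact 8-mer seeds anchor candidate pairs; ungapped extension
continues while the running identity of the whole window stays at or
above the floor (default 75%), tolerating at most 4 consecutive
mismatches, then trims to end on matches; pairs overlapping at least 50%
reciprocally on both sides merge, keeping the longest. Consensus strings
group consecutive mismatch columns as parenthesized alternatives
(`ATAT(GT/AA)ATA`). All reported positions are 1-based and re-extractable.

## Synthetic data

The generator emulates exactly the statistical structure the analyses
consume: a circular 37-gene genome in a chosen order; per-strand base
composition with target AT% and skews via pA = f(1+s_AT)/2,
pT = f(1−s_AT)/2, pG = (1−f)(1+s_GC)/2, pC = (1−f)(1−s_GC)/2; PCGs with a
legitimate start (default ATG), stop-free bodies (stop codons rejected
and resampled), and TAA or requested truncated stops; tRNA/rRNA filler
sampled from the strand composition (no secondary-structure realism —
sufficient for every statistic in scope); configurable spacers (defaults:
55 bp after trnI, 20 bp after trnS2); and an AT-rich control region
(default 1049 bp at 84.5% AT) with planted homopolymer runs and repeat
pairs.

Three corrections keep realized whole-genome composition on target.
First, the gene-region AT% is solved from the whole-genome target and the
control region's own AT% so the length-weighted expectation lands on
target. Second, PCG codon sampling corrects analytically for stop
rejection (rejecting TAA/TAG removes AT-rich codons; a fixed-point
iteration on the sampling AT fraction using the acceptance-bias formula
(3f − 3q₁ − 2q₂)/(3(1 − q₁ − q₂)) restores the accepted-stream AT).
Third, after assembly, a balancing pass performs A↔T and G↔C exchanges —
which preserve AT%/GC% exactly — inside rRNA filler interiors (≥100 bp
from feature ends, hence outside every PCG start-scan window and free of
codon constraints) to steer both skews to target. Residual AT% error is
at the sub-percent level at 16 kb (regression-tested at ±1.5 points;
skews at ±0.03, in practice near-exact after balancing); per-gene
composition remains stochastic by design.

Two further generator guarantees matter for testing. Boundary
re-inference is exact: a repair pass rewrites spurious in-frame start
codons upstream of each PCG (middle base resampled from {C, G}, which can
produce neither a start — all legitimate starts have a middle T — nor a
stop, which have a middle A), touching only spacers and tRNA/rRNA filler.
And planted repeat mutations avoid the first 8 columns (so an exact seed
survives) and are spread evenly with small seeded jitter, so no window of
the pair dips far below the nominal identity and the pair remains
detectable by seed-and-extend at its ground-truth identity; recovery is
checked by coordinate overlap with the planted copies. AT-rich background
sequence also produces genuine chance repeats at a 75% floor — the report
is expected to contain more than the planted pair.

The alignment evolver draws the root from model equilibrium, assigns
per-site rates from the model's discrete-gamma/invariant mixture, and
propagates states edge by edge through exact transition matrices; it is
byte-deterministic under the mandatory seed. It plants no indels: gaps
enter only through real or constructed alignments.

What passing tests on synthetic data do *not* show: robustness to
annotation errors in real GenBank records, to secondary-structure
constraints in tRNA/rRNA evolution, to among-gene composition
heterogeneity beyond the strand model, or to alignment error — real
alignments arrive as input and their quality is the caller's
responsibility.

## Pipeline

`run_pipeline` executes features → composition → codons → motifs →
control-region alignments → (optional) marker profiles over a directory
of FASTA+TSV genomes, writing one TSV per analysis plus `summary.json`
and a `manifest.json` of input checksums, seeds, and parameters. Every
stochastic stage takes its seed from the config, which must carry one
explicitly; outputs are a pure function of (inputs, config) and reruns
are checksum-identical. A stage failure halts the run naming the stage;
completed outputs are preserved.

## Problem sizes

The test suite and acceptance script size their simulations for a
single-CPU desk run: alignments of 1.5–3 kb for slope/quartet behavior
(20 replicates per depth for the saturation trend), 10 kb pairs for
distance recovery (24 replicates), 6-taxon trees (15 quartets) for %FRQ
contrasts, a 6-genome cohort for the end-to-end pipeline, and 100–200
random short pairs for the alignment oracle. These sizes give the
properties under test comfortable statistical margins; all are package
choices and scale up linearly if heavier verification is wanted.

## Known limitations

* Re-annotation of published genomes cannot be validated against a
  printed coordinate table; only internal invariants (idempotence,
  truncation guarantee, coverage conservation) are enforced.
* Non-canonical starts (ACG-type) are flagged, never auto-chosen; the
  protein-homology adjudication step is out of scope.
* ENC on the full-code family scheme can differ from legacy
  implementations whose family treatment is undocumented; published ENC
  tables are treated as reference values.
* The repositioned-gene report is exact only for isolated single-gene
  translocations; no rearrangement-scenario inference is attempted.
* The aligner reports one optimal alignment under a fixed tie-break;
  co-optimal alignments with different lengths exist and published
  identity statistics from other engines may differ accordingly.
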