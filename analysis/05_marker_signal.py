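#!/usr/bin/env python
"""Marker evaluation: saturation, signal, divergence, and codon-usage depth.

Simulates per-marker alignments on a 6-taxon tree at three substitution
rates (emulating slow, average, and fast mitochondrial genes), then builds
the marker-profile table: percent of fully resolved quartets (%FRQ) from
likelihood mapping, the m-slope of observed vs model-corrected distances,
average pairwise p-distance, and average ENC from the cohort genomes.
Faster markers must show higher divergence and stronger saturation.
"""

from pathlib import Path

from mitocomp.distances import jc_model
from mitocomp.pipeline import load_genome_dir
from mitocomp.saturation import marker_profiles
from mitocomp.synthetic import TreeSpec, evolve_alignment

OUT = Path("results")
SEED = 23

TOPOLOGY = ("(((A:{r0},B:{r0}):{r1},(C:{r0},D:{r0}):{r1}):{r2},"
            "(E:{r0},F:{r0}):{r1});")
RATES = {"slow_marker": 0.05, "average_marker": 0.15, "fast_marker": 0.45}


def main() -> None:
    genomes = load_genome_dir(OUT / "cohort" / "genomes")
    alns = {}
    for i, (name, rate) in enumerate(RATES.items()):
        nwk = TOPOLOGY.format(r0=rate, r1=2 * rate, r2=rate / 4)
        alns[name] = evolve_alignment(
            TreeSpec(nwk, jc_model(), 1500, seed=SEED + i))
    alns["pooled-a+b"] = evolve_alignment(TreeSpec(
        TOPOLOGY.format(r0=0.12, r1=0.24, r2=0.03), jc_model(), 3000, seed=SEED + 9))

    df = marker_profiles(genomes, alns, seed=SEED)
    df = df.round({"frq": 2, "m_slope": 3, "avg_pd": 3, "sd_pd": 3,
                   "avg_enc": 2, "sd_enc": 2})
    df.to_csv(OUT / "marker_profiles.tsv", sep="\t", index=False)
    print(df.to_string(index=False))

    by = df.set_index("marker")
    assert by.loc["fast_marker", "avg_pd"] > by.loc["slow_marker", "avg_pd"]
    assert by.loc["fast_marker", "m_slope"] < by.loc["slow_marker", "m_slope"]
    print("\nfaster markers show higher divergence and lower m-slope, "
          "as the saturation model predicts.")


if __name__ == "__main__":
    main()
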