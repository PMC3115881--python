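"""End-to-end orchestration over a directory of annotated genomes.

Runs annotation accounting → composition/clusters → codon usage → control
region motifs → control-region pairwise alignments → (optionally) marker
profiles over supplied alignments, writing one TSV per analysis plus a
``summary.json`` of cohort-level numbers and a ``manifest.json`` recording
inputs, checksums, seeds and parameters. Outputs are a pure function of
(inputs, config): reruns are checksum-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import feature_account, find_spacers, startstop_report
from .codon_usage import codon_usage_table, extract_codons, enc, strand_ratio
from .composition import assign_clusters, cohort_summary, whole_genome_profile
from .conservation import RELAXED_GAPS, GapParams, pairwise_global_align
from .genome_io import (
    BUILTIN_ORDERS,
    CONTROL_REGION,
    AnnotatedGenome,
    compare_gene_orders,
    gene_order_signature,
    read_feature_table,
)
from .motifs import approximate_repeats, count_motifs, homopolymer_runs, run_length_ranges

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genomes_dir: str
    out_dir: str
    seed: int
    alignments_dir: str | None = None
    reference_order: str = "ancestral_insect"
    anchor: str = "trnI"
    spacer_min_len: int = 15
    gap_open: float = RELAXED_GAPS.gap_open
    gap_extend: float = RELAXED_GAPS.gap_extend
    motif_k_range: tuple = (2, 4)
    repeat_min_len: int = 30
    repeat_min_identity: float = 0.75
    stages: tuple = ("features", "composition", "codons", "motifs", "cr_align", "markers")

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("config must carry an explicit seed")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "seed" not in data:
            raise ValueError("config must carry an explicit seed")
        cfg = cls(**data)
        cfg.stages = tuple(cfg.stages)
        cfg.motif_k_range = tuple(cfg.motif_k_range)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["stages"] = list(self.stages)
        data["motif_k_range"] = list(self.motif_k_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_genome_dir(genomes_dir) -> list[AnnotatedGenome]:
    """Load every FASTA + .tsv feature-table pair in a directory."""
    d = Path(genomes_dir)
    genomes = []
    for fasta in sorted(d.glob("*.fa")) + sorted(d.glob("*.fasta")):
        table = fasta.with_suffix(".tsv")
        if table.exists():
            genomes.append(read_feature_table(fasta, table))
    if not genomes:
        raise FileNotFoundError(f"no FASTA+TSV genome pairs under {genomes_dir}")
    return genomes


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes = load_genome_dir(config.genomes_dir)
    summary: dict = {"n_genomes": len(genomes), "warnings": []}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {**{k: v for k, v in asdict(config).items() if k != "out_dir"},
                   "stages": list(config.stages),
                   "motif_k_range": list(config.motif_k_range)},
        "inputs": {
            p.name: _sha256(p)
            for p in sorted(Path(config.genomes_dir).iterdir()) if p.is_file()
        },
        "stages": [],
    }

    def stage(name):
        def deco(fn):
            if name not in config.stages:
                return lambda: None
            def wrapped():
                t0 = time.perf_counter()
                try:
                    fn()
                except Exception as exc:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                manifest["stages"].append(name)
                log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return wrapped
        return deco

    @stage("features")
    def _features():
        frames = []
        order_reports = {}
        spacer_rows = []
        for g in genomes:
            acct = feature_account(g)
            acct.insert(0, "genome", g.identifier)
            frames.append(acct)
            sig = gene_order_signature(g, anchor=config.anchor)
            cmp_ = compare_gene_orders(sig, BUILTIN_ORDERS[config.reference_order])
            order_reports[g.identifier] = {
                "breakpoints": cmp_.breakpoints,
                "repositioned": list(cmp_.repositioned),
                "strand_changes": list(cmp_.strand_changes),
            }
            sp = find_spacers(g, min_label_len=config.spacer_min_len)
            for p in sp.ncps:
                spacer_rows.append({
                    "genome": g.identifier, "start": p.start, "end": p.end,
                    "length": p.length, "label": p.label,
                })
        _write_tsv(pd.concat(frames, ignore_index=True), out / "features.tsv")
        _write_tsv(pd.DataFrame(spacer_rows), out / "spacers.tsv")
        _write_tsv(startstop_report(genomes), out / "startstop.tsv")
        summary["gene_order_vs_reference"] = order_reports

    @stage("composition")
    def _composition():
        profiles = [whole_genome_profile(g) for g in genomes]
        rows = []
        for p in profiles:
            lab = assign_clusters(p)
            rows.append({
                "subject": p.subject, "at_pct": p.at_pct, "at_skew": p.at_skew,
                "gc_skew": p.gc_skew, "at_cluster": lab.at_cluster,
                "at_skew_cluster": lab.atskew_cluster,
                "gc_skew_cluster": lab.gcskew_cluster,
            })
        _write_tsv(pd.DataFrame(rows), out / "composition.tsv")
        cs = cohort_summary(profiles)
        summary["composition"] = {
            "mean_at_pct": float(cs.stats.loc["mean", "at_pct"]),
            "mean_at_skew": float(cs.stats.loc["mean", "at_skew"]),
            "mean_gc_skew": float(cs.stats.loc["mean", "gc_skew"]),
            "cluster_counts": cs.cluster_counts,
            "n_positive_at_skew": cs.n_positive_at_skew,
        }
        _write_tsv(cs.scatter, out / "composition_scatter.tsv")

    @stage("codons")
    def _codons():
        frames = []
        encs = {}
        for g in genomes:
            counts = extract_codons(g)
            tab = codon_usage_table(counts, subject=g.identifier)
            df = tab.table.copy()
            df.insert(0, "genome", g.identifier)
            frames.append(df)
            encs[g.identifier] = enc(counts)
        _write_tsv(pd.concat(frames, ignore_index=True), out / "codon_usage.tsv")
        ratios = strand_ratio(genomes)
        _write_tsv(ratios.summary, out / "strand_ratios.tsv")
        summary["codons"] = {
            "oavg_ratio_ab": ratios.oavg, "oavg_ratio_ab_sd": ratios.oavg_sd,
            "enc": encs,
        }

    @stage("motifs")
    def _motifs():
        rows = []
        rep_rows = []
        for g in genomes:
            if not g.has_feature(CONTROL_REGION):
                summary["warnings"].append(f"{g.identifier}: no control region")
                continue
            from .genome_io import extract_gene_sequence
            cr = extract_gene_sequence(g, CONTROL_REGION)
            ranges = run_length_ranges(homopolymer_runs(cr, min_len=3))
            for base, (lo, hi) in sorted(ranges.items()):
                rows.append({"genome": g.identifier, "kind": "homopolymer",
                             "motif": base, "count": -1,
                             "detail": f"({base}){lo}-{hi}"})
            for mc in count_motifs(cr, k_range=config.motif_k_range, top=5):
                rows.append({"genome": g.identifier, "kind": "kmer",
                             "motif": mc.motif, "count": mc.count, "detail": ""})
            for rp in approximate_repeats(cr, min_len=config.repeat_min_len,
                                          min_identity=config.repeat_min_identity):
                rep_rows.append({
                    "genome": g.identifier, "start1": rp.start1, "end1": rp.end1,
                    "start2": rp.start2, "end2": rp.end2, "length": rp.length,
                    "identity": round(rp.identity, 4), "consensus": rp.consensus,
                })
        _write_tsv(pd.DataFrame(rows), out / "motifs.tsv")
        _write_tsv(pd.DataFrame(rep_rows), out / "repeats.tsv")
        summary["n_repeat_pairs"] = len(rep_rows)

    @stage("cr_align")
    def _cr_align():
        from .genome_io import extract_gene_sequence
        params = GapParams(gap_open=config.gap_open, gap_extend=config.gap_extend)
        crs = {g.identifier: extract_gene_sequence(g, CONTROL_REGION)
               for g in genomes if g.has_feature(CONTROL_REGION)}
        rows = []
        ids = sorted(crs)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                _, s = pairwise_global_align(crs[ids[i]], crs[ids[j]], params)
                rows.append({"a": ids[i], "b": ids[j], "idnp": s.idnp,
                             "pct_id": round(s.pct_id, 2), "alnl": s.alnl})
        _write_tsv(pd.DataFrame(rows), out / "cr_alignments.tsv")

    @stage("markers")
    def _markers():
        if config.alignments_dir is None:
            return
        from .distances import Alignment
        from .saturation import marker_profiles
        if not Path(config.alignments_dir).is_dir():
            raise FileNotFoundError(f"no such alignment directory: "
                                    f"{config.alignments_dir}")
        alns = {}
        for f in sorted(Path(config.alignments_dir).glob("*.fa*")):
            alns[f.stem] = Alignment.from_fasta(f, "nt")
        if not alns:
            return
        df = marker_profiles(genomes, alns, seed=config.seed)
        _write_tsv(df, out / "marker_profiles.tsv")
        summary["markers"] = {r.marker: {"frq": r.frq, "m_slope": r.m_slope}
                              for r in df.itertuples()}

    for fn in (_features, _composition, _codons, _motifs, _cr_align, _markers):
        fn()

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return summary
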