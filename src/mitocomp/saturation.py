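"""Marker-evaluation statistics: substitution saturation and quartet signal.

Two complementary diagnostics:

* the **m-slope** — the slope of the through-origin least-squares
  regression of observed p-distances on model-corrected distances over all
  taxon pairs. m = 1 means no saturation (corrections are negligible);
  m ≪ 1 means multiple hits dominate;
* **likelihood mapping** — every taxon quartet is scored under the three
  unrooted quartet topologies; the posterior weights (p1, p2, p3) place
  the quartet in a 2-simplex partitioned into three corner areas (fully
  resolved), three edge areas, and a center (star-like). %FRQ is the
  percentage of quartets landing in a corner.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .codon_usage import MIN_CODONS_FOR_ENC, enc, extract_codons
from .distances import (
    Alignment,
    DistanceMatrix,
    SubstitutionModel,
    _state_indices,
    empirical_freqs,
    gtr_model,
    ml_distance,
    p_distance,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# m-slope

def m_slope(p: DistanceMatrix, corrected: DistanceMatrix) -> float:
    """Through-origin regression slope of p-distances on corrected distances.

    Pairs with capped (saturation-flagged) corrected distances are excluded
    with a warning rather than winsorized.
    """
    if p.ids != corrected.ids:
        raise ValueError("distance matrices cover different taxa")
    xs, ys = [], []
    n_excluded = 0
    for i, j, x in corrected.pairs():
        if corrected.flagged[i, j]:
            n_excluded += 1
            continue
        xs.append(x)
        ys.append(p.matrix[i, j])
    if n_excluded:
        log.warning("m-slope: %d saturated pair(s) excluded", n_excluded)
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    finite = np.isfinite(xs) & np.isfinite(ys)
    xs, ys = xs[finite], ys[finite]
    if len(xs) < 2:
        raise ValueError("fewer than 2 usable pairs for the regression")
    denom = float((xs * xs).sum())
    if denom == 0:
        return 1.0  # all distances zero: identity data, no saturation signal
    return float((xs * ys).sum() / denom)


# ---------------------------------------------------------------------------
# Quartet likelihood mapping

_TOPOLOGIES = ((0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 1, 2))

#: simplex partition thresholds (corner: max weight > 2/3; edge: min < 1/3)
CORNER_THRESHOLD = 2.0 / 3.0
EDGE_THRESHOLD = 1.0 / 3.0


@dataclass(frozen=True)
class QuartetResult:
    taxa: tuple[str, str, str, str]
    logliks: tuple[float, float, float]
    weights: tuple[float, float, float]
    region: str  # corner1..3 | edge12/13/23 | center

    @property
    def resolved(self) -> bool:
        return self.region.startswith("corner")


def _pattern_counts(rows: list[str], states: str) -> tuple[np.ndarray, np.ndarray]:
    enc_rows = np.stack([_state_indices(r, states) for r in rows])
    cols = enc_rows.T
    patterns, counts = np.unique(cols, axis=0, return_counts=True)
    return patterns, counts.astype(float)


def _quartet_loglik(branches: np.ndarray, patterns: np.ndarray, counts: np.ndarray,
                    model: SubstitutionModel, topo: tuple[int, int, int, int]) -> float:
    """Pruning-algorithm likelihood of one quartet topology.

    ``topo`` = (a, b, c, d) meaning ((a,b),(c,d)); branches = 4 tip lengths
    (in taxon order 0..3) followed by the internal branch.
    """
    weights, rates = model.rate_mixture()
    n = model.n_states
    npat = patterns.shape[0]
    site_l = np.zeros(npat)
    for wgt, r in zip(weights, rates):
        if r == 0:
            ps = [np.eye(n)] * 4
            p_int = np.eye(n)
        else:
            ps = [model.transition_matrix(branches[k] * r) for k in range(4)]
            p_int = model.transition_matrix(branches[4] * r)
        tip_cond = []
        for k in range(4):
            st = patterns[:, k]
            cond = np.ones((n, npat))
            obs = st >= 0
            cond[:, obs] = ps[k][:, st[obs]]
            tip_cond.append(cond)
        a, b, c, d = topo
        fu = tip_cond[a] * tip_cond[b]          # (n, npat)
        fv = tip_cond[c] * tip_cond[d]
        site_l += wgt * np.einsum("x,xp,xp->p", model.freqs, fu, p_int @ fv)
    return float((counts * np.log(np.maximum(site_l, 1e-300))).sum())


def quartet_likelihoods(aln: Alignment, quartet, model: SubstitutionModel,
                        seed: int = 0, n_restarts: int = 2,
                        corner_threshold: float = CORNER_THRESHOLD,
                        edge_threshold: float = EDGE_THRESHOLD) -> QuartetResult:
    """Score one quartet under the three unrooted topologies.

    Each topology's likelihood is maximized over its five branch lengths
    (bounded L-BFGS-B with seeded random restarts); the posterior weights
    p_i = L_i/ΣL_j are computed with log-sum-exp stabilization and mapped
    to a simplex region.
    """
    sub = aln.subset(list(quartet))
    states = model.states
    patterns, counts = _pattern_counts(sub.rows, states)
    rng = np.random.default_rng(seed)
    bounds = [(1e-8, 10.0)] * 5
    logliks = []
    for topo in _TOPOLOGIES:
        starts = [np.full(5, 0.1)]
        for _ in range(n_restarts):
            starts.append(rng.uniform(0.02, 1.0, size=5))
        best = None
        for x0 in starts:
            res = minimize(
                lambda b: -_quartet_loglik(b, patterns, counts, model, topo),
                x0, method="L-BFGS-B", bounds=bounds,
            )
            if best is None or res.fun < best:
                best = res.fun
        if not np.isfinite(best):
            raise RuntimeError(f"quartet {quartet}: optimization failed")
        logliks.append(-best)
    ll = np.asarray(logliks)
    w = np.exp(ll - ll.max())
    w = w / w.sum()
    order = np.argsort(w)[::-1]
    if w[order[0]] > corner_threshold:
        region = f"corner{order[0] + 1}"
    elif w[order[2]] < edge_threshold:
        i, j = sorted((order[0], order[1]))
        region = f"edge{i + 1}{j + 1}"
    else:
        region = "center"
    return QuartetResult(tuple(quartet), tuple(ll), tuple(w), region)


def frq(aln: Alignment, model: SubstitutionModel, n_quartets="all",
        seed: int = 0, enumerate_cap: int = 20_000,
        sample_size: int = 10_000) -> float:
    """Percent of fully resolved quartets (corner-region quartets).

    All quartets are evaluated when C(n,4) is at most ``enumerate_cap`` and
    ``n_quartets`` is "all"; otherwise a seeded uniform sample is drawn.
    """
    if aln.n_taxa < 4:
        raise ValueError("likelihood mapping needs at least 4 taxa")
    all_q = list(itertools.combinations(aln.ids, 4))
    rng = np.random.default_rng(seed)
    if n_quartets != "all":
        k = min(int(n_quartets), len(all_q))
        idx = rng.choice(len(all_q), size=k, replace=False)
        quartets = [all_q[i] for i in idx]
    elif len(all_q) > enumerate_cap:
        idx = rng.choice(len(all_q), size=sample_size, replace=False)
        quartets = [all_q[i] for i in idx]
    else:
        quartets = all_q
    n_resolved = 0
    n_eval = 0
    for q in quartets:
        try:
            res = quartet_likelihoods(aln, q, model, seed=int(rng.integers(2**31)))
        except RuntimeError:
            log.warning("quartet %s failed to converge; excluded", q)
            continue
        n_eval += 1
        n_resolved += res.resolved
    if n_eval == 0:
        raise RuntimeError("no quartet could be evaluated")
    return 100.0 * n_resolved / n_eval


# ---------------------------------------------------------------------------
# Marker profiles

def default_model_factory(aln: Alignment) -> SubstitutionModel:
    """Empirical-frequency GTR with uniform exchangeabilities and Γ(0.5)."""
    if aln.moltype == "aa":
        from .distances import load_aa_model
        return load_aa_model("mtrev24", alpha=0.5)
    return gtr_model(empirical_freqs(aln), np.ones(6), alpha=0.5)


def marker_profiles(genomes, alignments_nt: dict, alignments_aa: dict | None = None,
                    model_factory=default_model_factory, seed: int = 0,
                    enc_min_codons: int = MIN_CODONS_FOR_ENC) -> pd.DataFrame:
    """Per-marker table of %FRQ, m-slope, avg p-distance, avg ENC.

    ``alignments_nt`` maps marker name (gene name or pooled-set label) to a
    nucleotide alignment; ``alignments_aa`` optionally to protein
    alignments. ENC is averaged across genomes; markers whose genes carry
    fewer than ``enc_min_codons`` codons (atp8) report no ENC.
    """
    genomes = list(genomes)
    rows = []
    items = [("nt", name, a) for name, a in alignments_nt.items()]
    if alignments_aa:
        items += [("aa", name, a) for name, a in alignments_aa.items()]
    rng = np.random.default_rng(seed)
    for moltype, name, aln in items:
        model = model_factory(aln)
        pd_mat = p_distance(aln)
        corr = ml_distance(aln, model)
        slope = m_slope(pd_mat, corr)
        pct_frq = frq(aln, model, seed=int(rng.integers(2**31)))
        pvals = [v for _, _, v in pd_mat.pairs()]
        rec = {
            "marker": name, "moltype": moltype,
            "frq": pct_frq, "m_slope": slope,
            "avg_pd": float(np.mean(pvals)),
            "sd_pd": float(np.std(pvals, ddof=1)) if len(pvals) > 1 else 0.0,
            "avg_enc": np.nan, "sd_enc": np.nan,
        }
        if moltype == "nt":
            encs = []
            for g in genomes:
                counts = _marker_codon_counts(g, name)
                if counts is None:
                    continue
                try:
                    encs.append(enc(counts, min_codons=enc_min_codons))
                except ValueError:
                    log.warning("%s/%s: too few codons for ENC", g.identifier, name)
            if encs:
                rec["avg_enc"] = float(np.mean(encs))
                rec["sd_enc"] = float(np.std(encs, ddof=1)) if len(encs) > 1 else 0.0
        rows.append(rec)
    return pd.DataFrame(rows)


def _marker_codon_counts(genome, marker: str):
    from .codon_usage import strand_codon_counts
    from .genome_io import ALPHA, BETA, PCG_NAMES

    if marker in PCG_NAMES:
        if not genome.has_feature(marker):
            return None
        return extract_codons(genome, [marker])
    if marker in ("pooled-a+b", "pooled-alpha+beta"):
        return extract_codons(genome)
    if marker in ("pooled-a", "pooled-alpha"):
        return strand_codon_counts(genome, ALPHA)
    if marker in ("pooled-b", "pooled-beta"):
        return strand_codon_counts(genome, BETA)
    return None
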