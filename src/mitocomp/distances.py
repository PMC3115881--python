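"""Pairwise distances on alignments: p-distances and ML model-corrected distances.

The corrected distance between two rows is the branch length t maximizing

    Σ_sites log Σ_c w_c · π_x · P_c(x→y | t·r_c)

where the transition matrices come from a reversible rate matrix (GTR for
nucleotides, an empirical replacement matrix such as mtREV24 or JTT for
proteins) scaled to one expected substitution per unit time at
stationarity, and the rate mixture is a discrete gamma (equal-probability
categories with category-mean rates) plus an optional invariant class.
The rate matrix is eigendecomposed once; each pair is then a bounded
one-dimensional likelihood optimization over the site-pattern counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from Bio import AlignIO

log = logging.getLogger(__name__)

NT_STATES = "ACGT"
AA_STATES = "ARNDCQEGHILKMFPSTWYV"

#: corrected distances above this are flagged as saturated
DEFAULT_MAX_DISTANCE = 10.0


@dataclass
class Alignment:
    """Equal-length rows over a nucleotide or amino-acid alphabet."""

    ids: list[str]
    rows: list[str]
    moltype: str = "nt"  # "nt" | "aa"

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        self.rows = [r.upper().replace("U", "T") if self.moltype == "nt" else r.upper()
                     for r in self.rows]

    def __len__(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    def subset(self, ids) -> "Alignment":
        idx = [self.ids.index(i) for i in ids]
        return Alignment([self.ids[i] for i in idx], [self.rows[i] for i in idx],
                         self.moltype)

    @classmethod
    def from_fasta(cls, path, moltype: str = "nt") -> "Alignment":
        msa = AlignIO.read(str(path), "fasta")
        return cls([r.id for r in msa], [str(r.seq) for r in msa], moltype)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, row in zip(self.ids, self.rows):
                fh.write(f">{i}\n{row}\n")


def _state_indices(row: str, states: str) -> np.ndarray:
    """Map a row to state indices; gaps/ambiguity become −1 (missing)."""
    lut = np.full(128, -1, dtype=np.int64)
    for i, s in enumerate(states):
        lut[ord(s)] = i
    arr = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
    return lut[arr]


# ---------------------------------------------------------------------------
# Substitution models

def discrete_gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    """Category-mean rates of an equal-probability discrete gamma (mean 1)."""
    if ncat == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.linspace(0, 1, ncat + 1), a=alpha, scale=1 / alpha)
    upper = gammainc(alpha + 1, edges[1:] * alpha)
    lower = gammainc(alpha + 1, edges[:-1] * alpha)
    rates = ncat * (upper - lower)
    return rates / rates.mean() * 1.0


@dataclass
class SubstitutionModel:
    """Reversible substitution model with optional gamma + invariant rates.

    ``exchangeabilities`` is the symmetric matrix of relative rates s_ij;
    the rate matrix Q_ij = s_ij π_j is scaled to mean rate 1 at
    stationarity.
    """

    states: str
    freqs: np.ndarray
    exchangeabilities: np.ndarray
    alpha: float | None = None    # gamma shape; None = equal rates
    ncat: int = 4
    pinv: float = 0.0
    name: str = "custom"
    _eig: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.freqs = self.freqs / self.freqs.sum()
        s = np.asarray(self.exchangeabilities, dtype=float)
        s = (s + s.T) / 2
        np.fill_diagonal(s, 0.0)
        q = s * self.freqs[None, :]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(self.freqs * np.diag(q)).sum()
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        q /= mu
        self.exchangeabilities = s / mu
        # symmetrized eigendecomposition for fast matrix exponentials
        d = np.sqrt(self.freqs)
        sym = (q * d[:, None]) / d[None, :]
        w, v = np.linalg.eigh((sym + sym.T) / 2)
        self._eig = (w, v, d)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def rate_mixture(self) -> tuple[np.ndarray, np.ndarray]:
        """(weights, rates) including the invariant class when pinv > 0."""
        rates = discrete_gamma_rates(self.alpha, self.ncat) if self.alpha else np.ones(1)
        weights = np.full(len(rates), 1.0 / len(rates))
        if self.pinv > 0:
            rates = np.concatenate([[0.0], rates / (1 - self.pinv)])
            weights = np.concatenate([[self.pinv], weights * (1 - self.pinv)])
        return weights, rates

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) for a single rate class (rate 1)."""
        w, v, d = self._eig
        p = (v * np.exp(w * t)) @ v.T
        p = p / d[:, None] * d[None, :]
        return np.clip(p, 0.0, None)

    def mixture_transition(self, t: float) -> np.ndarray:
        """Σ_c w_c P(t·r_c) — the pair likelihood kernel."""
        weights, rates = self.rate_mixture()
        n = self.n_states
        out = np.zeros((n, n))
        for wgt, r in zip(weights, rates):
            out += wgt * (np.eye(n) if r == 0 else self.transition_matrix(t * r))
        return out


def jc_model(alpha: float | None = None, ncat: int = 4) -> SubstitutionModel:
    """Equal-frequency, equal-exchangeability nucleotide model (JC limit)."""
    return SubstitutionModel(
        states=NT_STATES, freqs=np.full(4, 0.25),
        exchangeabilities=np.ones((4, 4)), alpha=alpha, ncat=ncat, name="JC",
    )


def gtr_model(freqs, rates, alpha: float | None = None, ncat: int = 4,
              pinv: float = 0.0) -> SubstitutionModel:
    """GTR from 6 exchangeabilities in the order AC, AG, AT, CG, CT, GT."""
    s = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for (i, j), r in zip(pairs, rates):
        s[i, j] = s[j, i] = r
    return SubstitutionModel(states=NT_STATES, freqs=freqs, exchangeabilities=s,
                             alpha=alpha, ncat=ncat, pinv=pinv, name="GTR")


def poisson_aa_model(alpha: float | None = None, ncat: int = 4) -> SubstitutionModel:
    return SubstitutionModel(
        states=AA_STATES, freqs=np.full(20, 0.05),
        exchangeabilities=np.ones((20, 20)), alpha=alpha, ncat=ncat, name="Poisson",
    )


def load_aa_model(name: str, alpha: float | None = None, ncat: int = 4) -> SubstitutionModel:
    """Named empirical amino-acid model: ``mtrev24`` or ``jtt``."""
    fname = {"mtrev24": "mtrev24.tsv", "mtrev": "mtrev24.tsv", "jtt": "jtt.tsv"}.get(name.lower())
    if fname is None:
        raise ValueError(f"unknown amino-acid model {name!r}")
    ref = resources.files("mitocomp.data").joinpath(fname)
    with resources.as_file(ref) as path:
        lines = [l.split("\t") for l in path.read_text().strip().splitlines()]
    header = [h.strip() for h in lines[0]]
    freqs_in = np.array([float(x) for x in lines[1]])
    s_in = np.zeros((20, 20))
    for i in range(2, 21):
        row = [float(x) for x in lines[i]]
        for j, val in enumerate(row):
            s_in[i - 1, j] = s_in[j, i - 1] = val
    order = [header.index(a) for a in AA_STATES]
    return SubstitutionModel(
        states=AA_STATES, freqs=freqs_in[order],
        exchangeabilities=s_in[np.ix_(order, order)],
        alpha=alpha, ncat=ncat, name=name.lower(),
    )


# ---------------------------------------------------------------------------
# Distance matrices

@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    metric: str
    eff_sites: np.ndarray
    flagged: np.ndarray = None  # pairs at the distance cap

    def __post_init__(self):
        if self.flagged is None:
            self.flagged = np.zeros_like(self.matrix, dtype=bool)

    def pairs(self):
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                yield i, j, self.matrix[i, j]

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def p_distance(aln: Alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """Proportion of differing sites per pair.

    ``deletion`` is ``"pairwise"`` (exclude sites missing in either member
    of the pair) or ``"complete"`` (exclude columns missing in any row).
    """
    states = NT_STATES if aln.moltype == "nt" else AA_STATES
    enc = np.stack([_state_indices(r, states) for r in aln.rows])
    if deletion == "complete":
        keep = (enc >= 0).all(axis=0)
        enc = enc[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    n = aln.n_taxa
    d = np.zeros((n, n))
    eff = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (enc[i] >= 0) & (enc[j] >= 0)
            m = int(ok.sum())
            if m == 0:
                raise ValueError(f"no comparable sites for pair ({aln.ids[i]}, {aln.ids[j]})")
            diff = int((enc[i][ok] != enc[j][ok]).sum())
            d[i, j] = d[j, i] = diff / m
            eff[i, j] = eff[j, i] = m
    return DistanceMatrix(list(aln.ids), d, "p", eff)


def _pair_count_matrix(xi: np.ndarray, xj: np.ndarray, n_states: int) -> np.ndarray:
    ok = (xi >= 0) & (xj >= 0)
    idx = xi[ok] * n_states + xj[ok]
    return np.bincount(idx, minlength=n_states * n_states).reshape(n_states, n_states).astype(float)


def _pair_loglik(t: float, counts: np.ndarray, model: SubstitutionModel) -> float:
    m = model.mixture_transition(t)
    joint = model.freqs[:, None] * m
    return float((counts * np.log(np.maximum(joint, 1e-300))).sum())


def ml_pair_distance(counts: np.ndarray, model: SubstitutionModel,
                     max_distance: float = DEFAULT_MAX_DISTANCE) -> tuple[float, bool]:
    """Maximize the pair likelihood over t; returns (distance, capped?)."""
    if counts.sum() == 0:
        raise ValueError("empty pair count matrix")
    off_diag = counts.sum() - np.trace(counts)
    if off_diag == 0:
        return 0.0, False
    res = minimize_scalar(
        lambda t: -_pair_loglik(t, counts, model),
        bounds=(1e-9, max_distance), method="bounded",
        options={"xatol": 1e-10},
    )
    if not np.isfinite(res.fun):
        raise ValueError("non-finite likelihood in distance optimization")
    t = float(res.x)
    capped = t >= 0.98 * max_distance
    if capped:
        log.warning("distance at saturation cap %.2f; flagged", max_distance)
    return t, capped


def ml_distance(aln: Alignment, model: SubstitutionModel,
                deletion: str = "pairwise",
                max_distance: float = DEFAULT_MAX_DISTANCE) -> DistanceMatrix:
    """ML pairwise distances under ``model`` (nt or aa, per ``aln.moltype``)."""
    enc = np.stack([_state_indices(r, model.states) for r in aln.rows])
    if deletion == "complete":
        keep = (enc >= 0).all(axis=0)
        enc = enc[:, keep]
    n = aln.n_taxa
    d = np.zeros((n, n))
    eff = np.zeros((n, n))
    flagged = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            counts = _pair_count_matrix(enc[i], enc[j], model.n_states)
            m = counts.sum()
            if m == 0:
                raise ValueError(f"no comparable sites for pair ({aln.ids[i]}, {aln.ids[j]})")
            t, capped = ml_pair_distance(counts, model, max_distance)
            d[i, j] = d[j, i] = t
            eff[i, j] = eff[j, i] = m
            flagged[i, j] = flagged[j, i] = capped
    metric = {"GTR": "GTR", "JC": "JC"}.get(model.name, model.name)
    if model.pinv > 0:
        metric += "+I"
    if model.alpha:
        metric += "+G"
    return DistanceMatrix(list(aln.ids), d, metric, eff, flagged)


ml_distance_nt = ml_distance
ml_distance_aa = ml_distance


# ---------------------------------------------------------------------------
# GTR parameter estimation from an alignment

def empirical_freqs(aln: Alignment) -> np.ndarray:
    states = NT_STATES if aln.moltype == "nt" else AA_STATES
    enc = np.stack([_state_indices(r, states) for r in aln.rows])
    counts = np.bincount(enc[enc >= 0], minlength=len(states)).astype(float)
    if counts.sum() == 0:
        raise ValueError("no unambiguous characters")
    return counts / counts.sum()


def estimate_gtr(aln: Alignment, alpha: float | None = None, ncat: int = 4,
                 pinv: float = 0.0, maxiter: int = 40) -> SubstitutionModel:
    """Estimate GTR exchangeabilities by maximizing summed pairwise likelihood.

    Base frequencies are empirical; the five free exchangeabilities
    (relative to GT = 1) are optimized on a log scale with Nelder–Mead,
    re-optimizing all pairwise distances at each step. Gamma shape and
    pinv are taken as given, not estimated.
    """
    freqs = empirical_freqs(aln)
    enc = np.stack([_state_indices(r, NT_STATES) for r in aln.rows])
    pair_counts = []
    n = aln.n_taxa
    for i in range(n):
        for j in range(i + 1, n):
            pair_counts.append(_pair_count_matrix(enc[i], enc[j], 4))

    def neg_total(logr):
        rates = np.concatenate([np.exp(logr), [1.0]])
        model = gtr_model(freqs, rates, alpha=alpha, ncat=ncat, pinv=pinv)
        tot = 0.0
        for counts in pair_counts:
            t, _ = ml_pair_distance(counts, model)
            tot += _pair_loglik(t, counts, model)
        return -tot

    res = minimize(neg_total, np.zeros(5), method="Nelder-Mead",
                   options={"maxiter": maxiter * 5, "xatol": 1e-3, "fatol": 1e-3})
    rates = np.concatenate([np.exp(res.x), [1.0]])
    return gtr_model(freqs, rates, alpha=alpha, ncat=ncat, pinv=pinv)


def jc_correct(p: float) -> float:
    """Closed-form Jukes–Cantor correction −(3/4)·ln(1 − 4p/3)."""
    return -0.75 * np.log1p(-4.0 * p / 3.0)
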