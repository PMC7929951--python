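"""Codon substitution model: rate matrix, pruning likelihood, simulation.

A Goldman–Yang-style Markov model on the 61 sense codons of the standard
genetic code.  Instantaneous rates between codons differing at exactly one
position are proportional to the target codon's equilibrium frequency,
multiplied by the transition/transversion ratio κ for transitions and by
ω (dN/dS) for nonsynonymous changes; multi-nucleotide changes have rate
zero.  The matrix is normalized to one expected substitution per codon
per unit branch length.

The same generator is used for fitting (Felsenstein pruning over the 61
states) and for sequence simulation, so simulated data and the fitted
model agree by construction; the pruning implementation is validated
against exhaustive summation over internal-state assignments in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import dendropy
import numpy as np

__all__ = [
    "SENSE_CODONS",
    "CODON_INDEX",
    "STOP_CODONS",
    "AA_OF_CODON",
    "codons_to_indices",
    "indices_to_codons",
    "f3x4_frequencies",
    "rate_matrix",
    "CodonRateModel",
    "pattern_compress",
    "tree_loglik",
    "evolve_codons",
]

_NUC = "ACGT"
_CODON_TABLE = {}
_BASES = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    c for c in sorted(_BASES) if _BASES[c] != "*"
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AA_OF_CODON = {c: _BASES[c] for c in SENSE_CODONS}
N_CODONS = len(SENSE_CODONS)  # 61

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _single_substitution_pairs():
    """(i, j, is_transition, is_synonymous) over single-nt codon pairs."""
    pairs = []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            pairs.append(
                (
                    i,
                    j,
                    diffs[0] in _TRANSITIONS,
                    AA_OF_CODON[ci] == AA_OF_CODON[cj],
                )
            )
    return pairs

_PAIRS = _single_substitution_pairs()
_PAIR_I = np.array([p[0] for p in _PAIRS])
_PAIR_J = np.array([p[1] for p in _PAIRS])
_PAIR_TS = np.array([p[2] for p in _PAIRS])
_PAIR_SYN = np.array([p[3] for p in _PAIRS])


def codons_to_indices(cds: str) -> np.ndarray:
    """Codon indices of an in-frame CDS; -1 for codons with gaps/N/stops."""
    n = len(cds) // 3
    out = np.full(n, -1, dtype=np.int64)
    for k in range(n):
        out[k] = CODON_INDEX.get(cds[3 * k:3 * k + 3].upper(), -1)
    return out


def indices_to_codons(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)


def f3x4_frequencies(codon_indices: np.ndarray) -> np.ndarray:
    """Equilibrium codon frequencies from positional nucleotide counts.

    The F3x4 estimator: empirical nucleotide frequencies at each codon
    position, multiplied across positions and renormalized over sense
    codons.  Frequencies are floored at 1e-6 to keep the generator
    irreducible when a nucleotide is unobserved at some position.
    """
    idx = np.asarray(codon_indices).ravel()
    idx = idx[idx >= 0]
    counts = np.zeros((3, 4))
    for i in idx:
        codon = SENSE_CODONS[i]
        for pos, nt in enumerate(codon):
            counts[pos, _NUC.index(nt)] += 1
    if counts.sum() == 0:
        counts[:] = 1.0
    pos_freq = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, _NUC.index(c[0])]
            * pos_freq[1, _NUC.index(c[1])]
            * pos_freq[2, _NUC.index(c[2])]
            for c in SENSE_CODONS
        ]
    )
    pi = np.maximum(pi, 1e-6)
    return pi / pi.sum()


def rate_matrix(
    kappa: float, omega: float, pi: np.ndarray
) -> np.ndarray:
    """Normalized instantaneous rate matrix Q(κ, ω, π)."""
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    Q = np.zeros((N_CODONS, N_CODONS))
    rate = np.where(_PAIR_TS, kappa, 1.0) * np.where(
        _PAIR_SYN, 1.0, omega
    )
    Q[_PAIR_I, _PAIR_J] = rate * pi[_PAIR_J]
    Q[np.diag_indices_from(Q)] = -Q.sum(axis=1)
    mu = -(pi * np.diag(Q)).sum()
    if mu <= 0:
        # omega == 0 and no synonymous path would freeze the chain
        mu = 1.0
    return Q / mu


@dataclass
class CodonRateModel:
    """Q with its spectral decomposition, for fast P(t) = exp(Qt).

    The GY generator is reversible with respect to π, so the similarity
    transform diag(√π)·Q·diag(1/√π) is symmetric and can be
    eigendecomposed stably.
    """

    kappa: float
    omega: float
    pi: np.ndarray

    def __post_init__(self) -> None:
        Q = rate_matrix(self.kappa, self.omega, self.pi)
        sqrt_pi = np.sqrt(self.pi)
        # S = D^{1/2} Q D^{-1/2} is symmetric for a reversible generator
        S = Q * sqrt_pi[:, None] / sqrt_pi[None, :]
        S = (S + S.T) / 2.0  # symmetrize numerical residue
        self._eigval, U = np.linalg.eigh(S)
        self._left = U / sqrt_pi[:, None] * 1.0  # D^{-1/2} U
        self._right = (U * sqrt_pi[:, None]).T  # U^T D^{1/2}
        self.Q = Q

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative branch length")
        P = (self._left * np.exp(self._eigval * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


# ---------------------------------------------------------------------------
# likelihood by pruning
# ---------------------------------------------------------------------------


def pattern_compress(
    tip_codons: dict[str, np.ndarray]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Collapse alignment columns into unique site patterns with weights."""
    labels = sorted(tip_codons)
    mat = np.stack([np.asarray(tip_codons[l]) for l in labels])  # (T, S)
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return labels, patterns, counts.astype(float)


def tree_loglik(
    tree: dendropy.Tree,
    tip_codons: dict[str, np.ndarray],
    pi: np.ndarray,
    kappa: float,
    branch_omega,
    branch_scale: float = 1.0,
) -> float:
    """Log-likelihood of codon data on a tree by Felsenstein pruning.

    ``branch_omega`` maps a node (the child end of each edge) to the ω of
    that edge — pass a callable ``node -> omega`` or a float for a single
    ω everywhere.  Branch lengths are edge lengths times
    ``branch_scale``.  Codon index -1 at a tip is treated as missing
    (partial likelihood of ones).
    """
    if callable(branch_omega):
        omega_of = branch_omega
    else:
        w = float(branch_omega)
        omega_of = lambda node: w

    labels, patterns, weights = pattern_compress(tip_codons)
    tip_row = {label: k for k, label in enumerate(labels)}
    n_pat = patterns.shape[1]

    models: dict[float, CodonRateModel] = {}

    def model_for(omega: float) -> CodonRateModel:
        if omega not in models:
            models[omega] = CodonRateModel(kappa, omega, pi)
        return models[omega]

    partial: dict[int, np.ndarray] = {}
    logscale: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            codons = patterns[tip_row[label]]
            L = np.zeros((n_pat, N_CODONS))
            known = codons >= 0
            L[known, codons[known]] = 1.0
            L[~known, :] = 1.0
            partial[id(node)] = L
            logscale[id(node)] = np.zeros(n_pat)
            continue
        L = np.ones((n_pat, N_CODONS))
        ls = np.zeros(n_pat)
        for child in node.child_nodes():
            t = (child.edge.length or 0.0) * branch_scale
            P = model_for(omega_of(child)).transition_matrix(t)
            L *= partial[id(child)] @ P.T
            ls += logscale[id(child)]
        m = L.max(axis=1)
        m[m == 0.0] = 1.0
        partial[id(node)] = L / m[:, None]
        logscale[id(node)] = ls + np.log(m)
    root = tree.seed_node
    site_l = partial[id(root)] @ pi
    site_l = np.maximum(site_l, 1e-300)
    return float(
        (weights * (np.log(site_l) + logscale[id(root)])).sum()
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def evolve_codons(
    parent: np.ndarray,
    model: CodonRateModel,
    t: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample child codon states after time ``t`` under ``model``."""
    if t <= 0:
        return parent.copy()
    P = model.transition_matrix(t)
    cum = np.cumsum(P, axis=1)
    u = rng.random(parent.shape[0])
    rows = cum[parent]
    child = (rows < u[:, None]).sum(axis=1)
    return np.minimum(child, N_CODONS - 1)
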