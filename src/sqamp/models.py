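"""Reversible amino-acid substitution models for phylogenetic placement.

A model is defined by a symmetric exchangeability factor S and stationary
frequencies pi; the rate matrix is Q_ij = S_ij * pi_j (i != j), with the
diagonal set so rows sum to zero and the whole matrix scaled to one expected
substitution per site per unit branch length.  Transition matrices P(t) =
exp(Qt) are computed through the eigendecomposition of the symmetrized
matrix diag(sqrt pi) Q diag(1/sqrt pi), which is numerically stable and
makes repeated P(t) evaluations cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._lg_data import LG_ALPHABET, LG_EXCHANGEABILITIES, LG_FREQUENCIES

AA_ALPHABET = LG_ALPHABET
N_STATES = 20
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


class SubstitutionModel:
    """Reversible 20-state substitution model with precomputed spectral form."""

    def __init__(self, exchangeabilities: np.ndarray, frequencies: np.ndarray,
                 name: str = "custom"):
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if S.shape != (N_STATES, N_STATES):
            raise ValueError("exchangeability matrix must be 20x20")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if pi.shape != (N_STATES,) or np.any(pi <= 0):
            raise ValueError("frequencies must be 20 positive values")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        Q[np.diag_indices(N_STATES)] = -Q.sum(axis=1)
        # scale to 1 expected substitution / site / unit time
        mu = -np.dot(pi, np.diag(Q))
        Q = Q / mu
        sp = np.sqrt(pi)
        B = (sp[:, None] * Q) / sp[None, :]
        B = 0.5 * (B + B.T)  # enforce exact symmetry
        eigval, eigvec = np.linalg.eigh(B)
        self.name = name
        self.frequencies = pi
        self.rate_matrix = Q
        self._eigval = eigval
        # P(t) = diag(1/sqrt pi) V exp(L t) V' diag(sqrt pi)
        self._left = eigvec / sp[:, None]
        self._right = eigvec.T * sp[None, :]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows = ancestral state, columns = descendant."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self._left * np.exp(self._eigval * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        return P


def lg_model() -> SubstitutionModel:
    """The LG general amino-acid replacement model (empirical)."""
    S = np.zeros((N_STATES, N_STATES))
    S[np.triu_indices(N_STATES, 1)] = LG_EXCHANGEABILITIES
    S = S + S.T
    return SubstitutionModel(S, np.array(LG_FREQUENCIES), name="LG")


def poisson_model() -> SubstitutionModel:
    """Equal-rates (Poisson) model: all exchanges equal, uniform frequencies."""
    S = np.ones((N_STATES, N_STATES))
    np.fill_diagonal(S, 0.0)
    return SubstitutionModel(S, np.full(N_STATES, 1.0 / N_STATES), name="poisson")


_MODEL_FACTORY = {"LG": lg_model, "lg": lg_model, "poisson": poisson_model}


@dataclass
class ModelConfig:
    """Placement model choice; `name` is one of 'LG' or 'poisson'."""

    name: str = "LG"

    def build(self) -> SubstitutionModel:
        try:
            return _MODEL_FACTORY[self.name]()
        except KeyError:
            raise ValueError(f"unknown substitution model {self.name!r}") from None


def encode_peptide(peptide: str) -> np.ndarray:
    """Map residues to state indices; gaps, X and other ambiguity become -1
    (missing data)."""
    out = np.full(len(peptide), -1, dtype=np.int64)
    for i, a in enumerate(peptide.upper()):
        out[i] = _AA_INDEX.get(a, -1)
    return out


def tip_partials(states: np.ndarray) -> np.ndarray:
    """(20, n_sites) conditional-likelihood array for an observed sequence;
    missing states (-1) contribute a vector of ones."""
    n = states.shape[0]
    M = np.zeros((N_STATES, n))
    miss = states < 0
    M[:, miss] = 1.0
    obs = ~miss
    M[states[obs], np.nonzero(obs)[0]] = 1.0
    return M
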