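"""Markov substitution models and pair-probability machinery.

A substitution model is a continuous-time Markov chain on a character
alphabet, specified by an instantaneous rate matrix ``Q`` and an equilibrium
frequency vector ``pi``.  Models are calibrated so that one unit of
evolutionary distance corresponds to one expected substitution per site,
i.e. ``-sum_u pi_u Q_uu = 1``.

Two families are supported:

* the r-state symmetric model (``N_r``; Jukes--Cantor for r = 4), with
  uniform equilibrium frequencies and equal rates between any two distinct
  states, for which closed forms exist; and
* general (time-reversible or not) Markov models, e.g. empirical amino-acid
  models read from PAML-format rate files.

The central quantity consumed downstream is the joint probability of an
aligned character pair at distance ``d`` and its first two derivatives with
respect to ``d``::

    d^(k)/dd^(k) p(u, v; d) = pi_u [Q^k e^{Qd}]_{uv},   k in {0, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

__all__ = [
    "SubstitutionModel",
    "make_nr_model",
    "read_paml_model",
    "write_paml_model",
    "transition_probability",
    "nr_mutation_probability",
    "PAML_AMINO_ACIDS",
    "NUCLEOTIDES",
]

NUCLEOTIDES = "ACGT"
#: Canonical PAML amino-acid ordering used by .dat rate files.
PAML_AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

_SYMMETRIZABLE_TOL = 1e-9


class ModelError(ValueError):
    """Raised for invalid model construction or malformed rate files."""


def _default_alphabet(r: int) -> tuple[str, ...]:
    if r == 4:
        return tuple(NUCLEOTIDES)
    if r == 20:
        return tuple(PAML_AMINO_ACIDS)
    if r <= 26:
        return tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ"[:r])
    return tuple(f"S{i}" for i in range(r))


@dataclass
class SubstitutionModel:
    """A calibrated continuous-time Markov substitution model.

    Parameters
    ----------
    Q:
        ``r x r`` instantaneous rate matrix; rows sum to zero, off-diagonal
        entries are nonnegative, and the expected substitution rate at
        equilibrium is one (``-sum_u pi_u Q_uu = 1``).
    pi:
        Equilibrium frequency vector; strictly positive, sums to one, and
        stationary for ``Q`` (``pi @ Q = 0``).
    alphabet:
        Ordered character labels; defaults to ACGT for r = 4 and the PAML
        amino-acid order for r = 20.
    name:
        Free-text label used in output headers.
    """

    Q: np.ndarray
    pi: np.ndarray
    alphabet: tuple[str, ...] | None = None
    name: str = "custom"
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        r = self.Q.shape[0]
        if self.Q.shape != (r, r) or r < 2:
            raise ModelError("Q must be square with at least two states")
        if self.pi.shape != (r,):
            raise ModelError("pi length must match alphabet size")
        if self.alphabet is None:
            self.alphabet = _default_alphabet(r)
        else:
            self.alphabet = tuple(self.alphabet)
            if len(self.alphabet) != r:
                raise ModelError("alphabet length must match alphabet size")
        off = self.Q - np.diag(np.diag(self.Q))
        if np.any(off < -1e-12):
            raise ModelError("off-diagonal rates must be nonnegative")
        if np.max(np.abs(self.Q.sum(axis=1))) > 1e-9:
            raise ModelError("rows of Q must sum to zero")
        if np.any(self.pi <= 0) or abs(self.pi.sum() - 1.0) > 1e-6:
            raise ModelError("pi must be positive and sum to one")
        if np.max(np.abs(self.pi @ self.Q)) > 1e-8:
            raise ModelError("pi must be stationary for Q")
        mu = -float(np.dot(self.pi, np.diag(self.Q)))
        if abs(mu - 1.0) > 1e-8:
            raise ModelError(
                f"Q must be calibrated to 1 expected substitution/site (got {mu:.6g})"
            )

    @property
    def r(self) -> int:
        """Alphabet size."""
        return self.Q.shape[0]

    @property
    def is_nr(self) -> bool:
        """True if this is the r-state symmetric model (uniform pi, equal rates)."""
        r = self.r
        if np.max(np.abs(self.pi - 1.0 / r)) > 1e-12:
            return False
        off = self.Q[~np.eye(r, dtype=bool)]
        return float(np.ptp(off)) < 1e-12

    @property
    def beta(self) -> float:
        """Saturation mismatch probability (r-1)/r of the N_r model."""
        if not self.is_nr:
            raise ModelError("beta is defined for the r-state symmetric model only")
        return (self.r - 1) / self.r

    def state_index(self, char: str) -> int:
        try:
            return self.alphabet.index(char)
        except ValueError:
            raise ModelError(f"character {char!r} not in model alphabet") from None

    # -- matrix exponential ------------------------------------------------

    def _eigendecomposition(self):
        """Spectral decomposition of Q, symmetrized through pi when reversible.

        For a reversible model B = D^{1/2} Q D^{-1/2} (D = diag(pi)) is
        symmetric, so Q = D^{-1/2} U diag(w) U' D^{1/2} with orthonormal U;
        e^{Qd} is then assembled from real eigenvalues.  Non-reversible
        models fall back to scipy's scaling-and-squaring expm per call.
        """
        if self._eig is None:
            sqrt_pi = np.sqrt(self.pi)
            B = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
            if np.max(np.abs(B - B.T)) < _SYMMETRIZABLE_TOL:
                w, U = np.linalg.eigh((B + B.T) / 2.0)
                left = U / sqrt_pi[:, None]   # D^{-1/2} U
                right = U.T * sqrt_pi[None, :]  # U' D^{1/2}
                self._eig = (w, left, right)
            else:
                self._eig = ("dense",)
        return self._eig

    def expm(self, d: float) -> np.ndarray:
        """Transition-probability matrix ``e^{Qd}`` (rows sum to one)."""
        if d < 0:
            raise ValueError("distance must be nonnegative")
        eig = self._eigendecomposition()
        if len(eig) == 1:
            return scipy.linalg.expm(self.Q * d)
        w, left, right = eig
        return (left * np.exp(w * d)) @ right


def make_nr_model(r: int) -> SubstitutionModel:
    """Build the r-state symmetric (``N_r``) substitution model.

    Uniform equilibrium frequencies (1/r each) and equal rates between any
    two distinct states, calibrated to one expected substitution per unit
    distance.  ``r = 4`` is the Jukes--Cantor model, with saturation
    mismatch probability ``beta = (r-1)/r = 3/4``.
    """
    if not isinstance(r, (int, np.integer)) or r < 2:
        raise ModelError("alphabet size r must be an integer >= 2")
    r = int(r)
    Q = np.full((r, r), 1.0 / (r - 1))
    np.fill_diagonal(Q, -1.0)
    pi = np.full(r, 1.0 / r)
    return SubstitutionModel(Q=Q, pi=pi, name=f"N{r}")


def nr_mutation_probability(r: int, d) -> float:
    """Mismatch probability of the N_r model at distance ``d``.

    ``p_m(d) = beta (1 - e^{-d/beta})`` with ``beta = (r-1)/r``; strictly
    increasing in ``d`` and bounded by ``beta``.
    """
    if r < 2:
        raise ModelError("alphabet size r must be >= 2")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    beta = (r - 1) / r
    out = beta * (1.0 - np.exp(-d / beta))
    return float(out) if out.ndim == 0 else out


def transition_probability(
    model: SubstitutionModel, d: float, k: int = 0
) -> np.ndarray:
    """Joint pair-probability matrix at distance ``d``, or its derivatives.

    Entry ``(u, v)`` equals ``pi_u [Q^k e^{Qd}]_{uv}``.  For ``k = 0`` the
    entries are the joint probabilities of observing the aligned pair
    ``(u, v)`` and sum to one; ``k = 1, 2`` give the first and second
    derivatives with respect to ``d``.
    """
    if d < 0:
        raise ValueError("distance must be nonnegative")
    if k not in (0, 1, 2):
        raise ValueError("derivative order k must be 0, 1 or 2")
    P = model.expm(d)
    M = P if k == 0 else (model.Q @ P if k == 1 else model.Q @ model.Q @ P)
    return model.pi[:, None] * M


# -- PAML-format rate files ------------------------------------------------


def read_paml_model(
    path: str | Path, r: int = 20, name: str | None = None
) -> SubstitutionModel:
    """Read a PAML-dialect rate file into a calibrated model.

    The file holds the lower triangle of the symmetric exchangeability
    matrix S (r-1 rows; row u lists s_{u,0} .. s_{u,u-1}) followed by the r
    equilibrium frequencies, all whitespace-separated; anything after those
    r(r-1)/2 + r numbers is ignored as comment.  The rate matrix is
    assembled as ``Q_uv = s_uv pi_v`` (u != v) with the diagonal set so rows
    sum to zero, then calibrated to one expected substitution per site.
    """
    path = Path(path)
    tokens: list[str] = []
    need = r * (r - 1) // 2 + r
    with open(path) as fh:
        for line in fh:
            for tok in line.split():
                try:
                    tokens.append(float(tok))
                except ValueError:
                    # first non-numeric token starts trailing comments
                    break
            else:
                continue
            if len(tokens) >= need:
                break
    if len(tokens) < need:
        raise ModelError(
            f"{path}: expected {need} numbers for alphabet size {r}, "
            f"found {len(tokens)}"
        )
    vals = np.array(tokens[:need], dtype=float)
    S = np.zeros((r, r))
    idx = 0
    for u in range(1, r):
        S[u, :u] = vals[idx : idx + u]
        idx += u
    S = S + S.T
    pi = vals[idx : idx + r]
    if abs(pi.sum() - 1.0) > 1e-4:
        raise ModelError(f"{path}: frequencies sum to {pi.sum():.6g}, not 1")
    pi = pi / pi.sum()
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(Q)))
    if mu <= 0:
        raise ModelError(f"{path}: degenerate rate matrix (zero total rate)")
    Q = Q / mu
    return SubstitutionModel(Q=Q, pi=pi, name=name or path.stem)


def write_paml_model(model: SubstitutionModel, path: str | Path) -> None:
    """Write a model as a PAML-dialect rate file (round-trips with the reader)."""
    r = model.r
    # recover exchangeabilities S_uv = Q_uv / pi_v (symmetric for reversible Q)
    S = model.Q / model.pi[None, :]
    lines = []
    for u in range(1, r):
        lines.append(" ".join(f"{S[u, v]:.12g}" for v in range(u)))
    lines.append("")
    lines.append(" ".join(f"{p:.12g}" for p in model.pi))
    lines.append("")
    Path(path).write_text("\n".join(lines))
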