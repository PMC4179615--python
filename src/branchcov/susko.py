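"""Sample-average (Susko) covariance for MSA-induced pairwise distances.

For two distances estimated from pairwise alignments induced by one MSA,
the covariance can be written as

    cov(d_ij_hat, d_kl_hat) = n V_ij V_kl E[ score_ij(X) * score_kl(X) ],

where the expectation is over quartet columns X and score_uv is the
derivative of the log pair probability with respect to the distance,
evaluated at the pair's distance.  The estimator replaces the expectation
with the sample average over the n MSA columns (a single linear pass) and
the true distances with the plug-in ML estimates.  Unlike the
branch-covariance it needs the columns themselves, so it applies to MSAs
only, and its runtime grows linearly in the sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from branchcov.models import SubstitutionModel

__all__ = ["QuartetColumns", "pair_score", "score_table", "susko_covariance"]


@dataclass
class QuartetColumns:
    """Gap-free MSA columns for four taxa, as state indices.

    ``columns`` is an n x 4 integer array; column order is (i, j, k, l).
    Columns where any of the four taxa carries a gap or ambiguity character
    must be dropped before construction (the expectation underlying the
    estimator is over complete quartets).
    """

    columns: np.ndarray

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns)
        if self.columns.ndim != 2 or self.columns.shape[1] != 4:
            raise ValueError("columns must be an n x 4 array")
        if self.columns.shape[0] < 1:
            raise ValueError("need at least one column")
        if np.any(self.columns < 0):
            raise ValueError("state indices must be nonnegative")

    @property
    def n(self) -> int:
        return self.columns.shape[0]

    @classmethod
    def from_sequences(
        cls, model: SubstitutionModel, seqs: tuple[str, str, str, str]
    ) -> "QuartetColumns":
        """Encode four aligned sequences, dropping quartet-incomplete columns."""
        lut = np.full(256, -1, dtype=np.int64)
        for i, c in enumerate(model.alphabet):
            lut[ord(c)] = i
            lut[ord(c.lower())] = i
        arrs = [
            lut[np.frombuffer(s.encode("ascii"), dtype=np.uint8)] for s in seqs
        ]
        if len({a.size for a in arrs}) != 1:
            raise ValueError("sequences must be aligned (equal length)")
        mat = np.stack(arrs, axis=1)
        keep = np.all(mat >= 0, axis=1)
        if not np.any(keep):
            raise ValueError("no quartet-complete columns")
        return cls(columns=mat[keep])


def score_table(model: SubstitutionModel, d: float) -> np.ndarray:
    """Per-pair score values ``[Q e^{Qd}]_{uv} / [e^{Qd}]_{uv}`` as an r x r table.

    This is the derivative of the log pair probability with respect to the
    distance (the equilibrium factor pi_u cancels).  Entries with zero
    transition probability are +/-inf by contract.
    """
    if d <= 0:
        raise ValueError("score requires d > 0")
    P = model.expm(d)
    QP = model.Q @ P
    with np.errstate(divide="ignore", invalid="ignore"):
        return QP / P


def pair_score(model: SubstitutionModel, u: int, v: int, d: float) -> float:
    """Score of one aligned character pair (u, v) at distance ``d``."""
    return float(score_table(model, d)[u, v])


def susko_covariance(
    model: SubstitutionModel,
    cols: QuartetColumns,
    d_ij_hat: float,
    d_kl_hat: float,
    v_ij: float,
    v_kl: float,
) -> float:
    """Sample-average covariance of d_ij_hat and d_kl_hat over MSA columns.

    ``n v_ij v_kl * mean_over_columns(score_ij * score_kl)`` with scores
    evaluated at the plug-in distance estimates.  May be negative (it is an
    unbiased sample average).  Degenerate inputs (a distance estimate at
    the zero boundary, e.g. constant columns) raise ``ValueError``.
    """
    r = model.r
    if np.any(cols.columns >= r):
        raise ValueError("column states outside the model alphabet")
    if d_ij_hat <= 0 or d_kl_hat <= 0:
        raise ValueError(
            "degenerate input: distance estimate at the zero boundary, "
            "no score variation"
        )
    s_ij = score_table(model, d_ij_hat)
    s_kl = score_table(model, d_kl_hat)
    c = cols.columns
    a = s_ij[c[:, 0], c[:, 1]]
    b = s_kl[c[:, 2], c[:, 3]]
    return float(cols.n * v_ij * v_kl * np.mean(a * b))
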