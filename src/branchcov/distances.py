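"""Pairwise maximum-likelihood distance estimation and variance estimators.

A pairwise alignment of n gap-free homologous character pairs is summarized
by an r x r count matrix F.  The log-likelihood of a separating distance d
is sum_{u,v} F_uv log(pi_u [e^{Qd}]_{uv}); its maximizer is the ML distance.
For the r-state symmetric model the number of differing sites I is
sufficient and the maximizer has the closed form

    d_hat = -beta ln(1 - I / (n beta)),    beta = (r-1)/r,

with Delta-method variance

    V(d_hat) = beta [(1-beta) e^{2d/beta} + (2beta-1) e^{d/beta} - beta] / n,

which coincides with the inverse Fisher information.  General models are
maximized numerically (safeguarded Newton--Raphson) and the variance is the
inverse Fisher information evaluated at d_hat (the "ML variance") or the
observed-information sample average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from branchcov.models import SubstitutionModel, transition_probability

__all__ = [
    "SitePairCounts",
    "DistanceEstimate",
    "pair_log_likelihood",
    "estimate_distance_ml",
    "nr_distance",
    "fisher_information",
    "ml_variance",
    "sample_average_variance",
    "nr_delta_variance",
    "SaturationError",
    "read_fasta",
    "site_pair_counts",
    "pairwise_distance_table",
    "write_distance_tsv",
    "write_phylip_matrix",
    "DEFAULT_CEILING",
]

DEFAULT_CEILING = 10.0
_NEWTON_TOL = 1e-9
_D_FLOOR = 1e-9


class SaturationError(ValueError):
    """Mismatch fraction at or beyond the model's saturation level."""


@dataclass
class SitePairCounts:
    """Summary of a pairwise alignment: counts of aligned character pairs.

    ``F[u, v]`` counts gap-free columns with state u in the first sequence
    and state v in the second; ``n`` is the total count and ``I`` the
    number of differing sites (off-diagonal mass).
    """

    F: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2 or self.F.shape[0] != self.F.shape[1]:
            raise ValueError("F must be a square count matrix")
        if np.any(self.F < 0):
            raise ValueError("counts must be nonnegative")
        if self.F.sum() < 1:
            raise ValueError("need at least one aligned pair")

    @property
    def n(self) -> int:
        return int(round(self.F.sum()))

    @property
    def I(self) -> int:  # noqa: E743 - field name from the sufficient statistic
        return int(round(self.F.sum() - np.trace(self.F)))


@dataclass
class DistanceEstimate:
    """An ML distance estimate with its variance and supporting column count."""

    d_hat: float
    variance: float
    n: int
    saturated: bool = False
    method: str = "closed-form"

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be nonnegative")


def site_pair_counts(
    model: SubstitutionModel, seq_a: str, seq_b: str
) -> SitePairCounts:
    """Count aligned character pairs, dropping gapped/ambiguous columns.

    Columns where either character is not in the model alphabet (gaps,
    ambiguity codes) are excluded.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned (equal length)")
    lut = np.full(256, -1, dtype=np.int64)
    for i, c in enumerate(model.alphabet):
        lut[ord(c)] = i
        lut[ord(c.lower())] = i
    a = lut[np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8)]
    b = lut[np.frombuffer(seq_b.encode("ascii"), dtype=np.uint8)]
    keep = (a >= 0) & (b >= 0)
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise ValueError("no gap-free columns shared by the two sequences")
    r = model.r
    F = np.bincount(a * r + b, minlength=r * r).reshape(r, r).astype(float)
    return SitePairCounts(F=F)


def pair_log_likelihood(
    model: SubstitutionModel, counts: SitePairCounts, d: float
) -> float:
    """Log-likelihood of distance ``d`` for the observed pair counts.

    Returns ``-inf`` (not an exception) when an observed pair has zero
    probability, e.g. mismatches at d = 0.
    """
    if d < 0:
        raise ValueError("distance must be nonnegative")
    P = transition_probability(model, d, 0)
    F = counts.F
    with np.errstate(divide="ignore"):
        logP = np.log(P)
    mask = F > 0
    if np.any(np.isinf(logP[mask])):
        return -np.inf
    return float(np.sum(F[mask] * logP[mask]))


def nr_distance(r: int, I: int, n: int) -> float:
    """Closed-form N_r ML distance from the count of differing sites.

    ``d_hat = -beta ln(1 - I/(n beta))``.  Raises :class:`SaturationError`
    when ``I/n >= beta`` (the log argument is nonpositive); the caller
    decides the ceiling.
    """
    if n < 1 or not (0 <= I <= n):
        raise ValueError("need 0 <= I <= n with n >= 1")
    beta = (r - 1) / r
    arg = 1.0 - I / (n * beta)
    if arg <= 0:
        raise SaturationError(
            f"mismatch fraction {I/n:.4g} at or beyond saturation level {beta:.4g}"
        )
    return float(-beta * np.log(arg))


def nr_delta_variance(r: int, d: float, n: int) -> float:
    """Delta-method variance of the N_r ML distance at distance ``d``.

    ``beta [(1-beta) e^{2d/beta} + (2beta-1) e^{d/beta} - beta] / n``;
    zero at d = 0 and strictly increasing in d.  For N_r this equals the
    inverse Fisher information exactly.
    """
    if d < 0:
        raise ValueError("distance must be nonnegative")
    if n < 1:
        raise ValueError("n must be >= 1")
    beta = (r - 1) / r
    e = np.exp(d / beta)
    return float(beta * ((1.0 - beta) * e * e + (2.0 * beta - 1.0) * e - beta) / n)


def fisher_information(model: SubstitutionModel, d: float, n: int) -> float:
    """Expected Fisher information for the distance at ``d`` from n sites.

    ``I_n(d) = -n E[d^2/dd^2 log p(X, d)]``, assembled from the pair
    probabilities and their first two derivatives; positive, linear in n,
    and divergent as d -> 0.
    """
    if d <= 0:
        raise ValueError("Fisher information requires d > 0")
    p0 = transition_probability(model, d, 0)
    p1 = transition_probability(model, d, 1)
    p2 = transition_probability(model, d, 2)
    # E[ d2/dd2 log p ] = sum p * (p''/p - (p'/p)^2) = sum (p'' - p'^2/p)
    mask = p0 > 1e-300
    val = np.sum(p2[mask] - p1[mask] ** 2 / p0[mask])
    return -n * float(val)


def ml_variance(model: SubstitutionModel, d_hat: float, n: int) -> float:
    """ML variance: inverse expected Fisher information at ``d_hat``.

    A nonpositive ``d_hat`` is a degenerate point (the information
    diverges); the variance is reported as 0 by contract.
    """
    if d_hat <= 0:
        return 0.0
    return 1.0 / fisher_information(model, d_hat, n)


def sample_average_variance(
    model: SubstitutionModel, counts: SitePairCounts, d_hat: float
) -> float:
    """Observed-information variance from the realized pair counts.

    The negative inverse of the summed second derivatives of the per-site
    log pair probabilities at ``d_hat``.  A nonpositive observed
    information (pathological counts) yields ``inf`` with a warning.
    """
    if d_hat <= 0:
        return 0.0
    p0 = transition_probability(model, d_hat, 0)
    p1 = transition_probability(model, d_hat, 1)
    p2 = transition_probability(model, d_hat, 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        dd = p2 / p0 - (p1 / p0) ** 2
    F = counts.F
    mask = F > 0
    observed_info = -float(np.sum(F[mask] * dd[mask]))
    if observed_info <= 0:
        warnings.warn("nonpositive observed information; degenerate counts")
        return np.inf
    return 1.0 / observed_info


def _newton_ml_distance(
    model: SubstitutionModel, counts: SitePairCounts, ceiling: float
) -> tuple[float, bool]:
    """Safeguarded Newton--Raphson maximization of the pair log-likelihood.

    Initialized from the observed mismatch fraction mapped through the N_r
    closed form; a bisection fallback on a bracketing interval catches
    Newton steps leaving [1e-9, ceiling].
    """
    F = counts.F
    n, I = counts.n, counts.I
    if I == 0:
        return 0.0, False
    r = model.r
    try:
        d = nr_distance(r, I, n)
    except SaturationError:
        d = ceiling
    d = float(np.clip(d, 1e-6, ceiling))

    def score_curv(x: float) -> tuple[float, float]:
        p0 = transition_probability(model, x, 0)
        p1 = transition_probability(model, x, 1)
        p2 = transition_probability(model, x, 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = p1 / p0
            c = p2 / p0 - s * s
        mask = F > 0
        return float(np.sum(F[mask] * s[mask])), float(np.sum(F[mask] * c[mask]))

    lo, hi = _D_FLOOR, ceiling
    s_lo, _ = score_curv(lo)
    if s_lo <= 0:  # likelihood decreasing from the floor: optimum at 0
        return 0.0, False
    s_hi, _ = score_curv(hi)
    if s_hi >= 0:  # still increasing at the ceiling: saturated
        return ceiling, True
    for _ in range(200):
        s, c = score_curv(d)
        if abs(s) < _NEWTON_TOL:
            return d, False
        if s > 0:
            lo = d
        else:
            hi = d
        step = -s / c if c < 0 else np.nan
        d_new = d + step if np.isfinite(step) else np.nan
        if not np.isfinite(d_new) or not (lo < d_new < hi):
            d_new = 0.5 * (lo + hi)
        if abs(d_new - d) < _NEWTON_TOL:
            return d_new, False
        d = d_new
    return d, False


def estimate_distance_ml(
    model: SubstitutionModel,
    counts: SitePairCounts,
    ceiling: float = DEFAULT_CEILING,
) -> DistanceEstimate:
    """ML distance estimate with ML variance for one pairwise alignment.

    Uses the N_r closed form when the model is r-state symmetric, otherwise
    safeguarded Newton--Raphson on the log-likelihood derivative.  When the
    mismatch fraction is at or beyond saturation the estimate is pinned to
    ``ceiling`` with the ``saturated`` flag set and the variance evaluated
    at the ceiling point (never infinity).
    """
    if ceiling <= 0:
        raise ValueError("ceiling must be positive")
    n = counts.n
    if model.is_nr:
        try:
            d_hat = min(nr_distance(model.r, counts.I, n), ceiling)
            saturated = d_hat >= ceiling
        except SaturationError:
            d_hat, saturated = ceiling, True
        method = "closed-form"
    else:
        d_hat, saturated = _newton_ml_distance(model, counts, ceiling)
        method = "newton"
    var = ml_variance(model, d_hat, n)
    return DistanceEstimate(
        d_hat=d_hat, variance=var, n=n, saturated=saturated, method=method
    )


# -- I/O -------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (identifier, sequence) pairs."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def pairwise_distance_table(
    model: SubstitutionModel,
    sequences: list[tuple[str, str]],
    ceiling: float = DEFAULT_CEILING,
) -> pd.DataFrame:
    """All-against-all ML distances for a set of aligned sequences.

    Returns a DataFrame with columns (taxon_a, taxon_b, d_hat, variance, n,
    saturated); gapped columns are dropped per pair, so n can differ across
    pairs.
    """
    rows = []
    for i in range(len(sequences)):
        for j in range(i + 1, len(sequences)):
            (name_a, seq_a), (name_b, seq_b) = sequences[i], sequences[j]
            counts = site_pair_counts(model, seq_a, seq_b)
            est = estimate_distance_ml(model, counts, ceiling)
            rows.append(
                dict(
                    taxon_a=name_a,
                    taxon_b=name_b,
                    d_hat=est.d_hat,
                    variance=est.variance,
                    n=est.n,
                    saturated=est.saturated,
                )
            )
    return pd.DataFrame(rows)


def write_distance_tsv(
    table: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None
) -> None:
    """Write a distance table as TSV, optionally preceded by '#' header lines."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_phylip_matrix(table: pd.DataFrame, path: str | Path) -> None:
    """Write the square distance matrix in PHYLIP format for tree tools."""
    taxa = sorted(set(table["taxon_a"]) | set(table["taxon_b"]))
    idx = {t: i for i, t in enumerate(taxa)}
    m = len(taxa)
    D = np.zeros((m, m))
    for _, row in table.iterrows():
        i, j = idx[row["taxon_a"]], idx[row["taxon_b"]]
        D[i, j] = D[j, i] = row["d_hat"]
    with open(path, "w") as fh:
        fh.write(f"{m}\n")
        for t in taxa:
            vals = " ".join(f"{x:.6f}" for x in D[idx[t]])
            fh.write(f"{t:<10s} {vals}\n")
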