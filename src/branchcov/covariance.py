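"""The branch-covariance estimator for pairwise ML distances.

Two pairwise distances whose leaf-to-leaf paths overlap on the underlying
tree covary because of shared mutation events.  The estimator implemented
here rests on the relation

    cov(d_ij_hat, d_kl_hat) = V(d_hat | d_t = delta_m),

i.e. the covariance equals the variance of an ML distance estimate whose
true distance is the shared path length ``delta_m`` (exact asymptotically
under the r-state symmetric model, conjectured and empirically supported
for general Markov models).  The pipeline for a quartet {i, j, k, l} is:

1. decide the topological relation of the two paths by weighted least
   squares over the six pairwise distances (dependence, or independence in
   which case the covariance is zero);
2. estimate ``delta_m`` by WLS (a negative unconstrained estimate is
   clamped and the covariance reported as zero);
3. evaluate the variance formula at ``delta_m``: closed form under N_r, or
   inverse expected Fisher information for general models, optionally via a
   precomputed lookup table.

The estimator runs in constant time in the sequence length once pairwise
distances and variances are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from branchcov.distances import fisher_information, nr_delta_variance
from branchcov.models import SubstitutionModel

__all__ = [
    "QuartetDistances",
    "TopologyFit",
    "CovarianceEstimate",
    "InfoTable",
    "SharedPath",
    "select_topology",
    "estimate_shared_path",
    "triplet_shared_path",
    "nr_covariance",
    "general_covariance",
    "branch_covariance",
    "build_info_table",
    "covariance_matrix",
    "DELTA_EPSILON",
]

#: Below this shared path length the covariance is reported as exactly zero
#: (the Fisher information diverges as delta_m -> 0).
DELTA_EPSILON = 1e-8

_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass
class QuartetDistances:
    """The six pairwise distance estimates among four taxa, with variances.

    Entries are indexed by unordered pairs of positions (0..3 map to the
    labels i, j, k, l); ``d``, ``v`` and ``n_pair`` hold the distance,
    variance and supporting column count for each of the six pairs.
    """

    labels: tuple[str, str, str, str]
    d: dict[frozenset, float]
    v: dict[frozenset, float]
    n_pair: dict[frozenset, int]

    def __post_init__(self) -> None:
        keys = {frozenset(p) for p in _PAIRS}
        for name, mapping in (("d", self.d), ("v", self.v), ("n_pair", self.n_pair)):
            if set(mapping) != keys:
                raise ValueError(f"{name} must hold exactly the six unordered pairs")
        if any(x < 0 for x in self.d.values()):
            raise ValueError("distances must be nonnegative")
        if any(x < 0 for x in self.v.values()):
            raise ValueError("variances must be nonnegative")

    @classmethod
    def from_arrays(cls, labels, d6, v6, n6) -> "QuartetDistances":
        """Build from six values ordered (ij, ik, il, jk, jl, kl)."""
        keys = [frozenset(p) for p in _PAIRS_ORDER]
        return cls(
            labels=tuple(labels),
            d=dict(zip(keys, map(float, d6))),
            v=dict(zip(keys, map(float, v6))),
            n_pair=dict(zip(keys, map(int, n6))),
        )

    def dist(self, a: int, b: int) -> float:
        return self.d[frozenset((a, b))]

    def var(self, a: int, b: int) -> float:
        return self.v[frozenset((a, b))]

    def npair(self, a: int, b: int) -> int:
        return self.n_pair[frozenset((a, b))]


#: Canonical ordering of the six pairs: ij, ik, il, jk, jl, kl.
_PAIRS_ORDER = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass
class TopologyFit:
    """Result of WLS topology selection over a quartet.

    ``topology`` is the best-fitting of T1 ((i,k),(j,l)), T2 ((i,l),(j,k))
    and T3 ((i,j),(k,l)); T1/T2 put i and j on opposite sides of the middle
    edge (the paths i--j and k--l share it), T3 makes them independent.
    """

    topology: str
    scores: dict[str, float]
    tied: bool = False


@dataclass
class CovarianceEstimate:
    """A branch-covariance value with its provenance."""

    cov: float
    delta_m_hat: float
    topology: TopologyFit
    n_effective: int
    zero_reason: str = "none"  # none | independent-topology | negative-delta

    def __post_init__(self) -> None:
        if self.zero_reason != "none" and self.cov != 0.0:
            raise ValueError("cov must be zero when a zero_reason is set")


class SharedPath(NamedTuple):
    """Unconstrained WLS shared-path estimate and its nonnegative clamp."""

    raw: float
    clamped: float


def select_topology(q: QuartetDistances) -> TopologyFit:
    """Pick the best-fitting quartet topology by weighted least squares.

    For each topology the four-point residual (the difference of the two
    cross-pair distance sums that should be equal under that topology) is
    squared and weighted by the sum of the four variances involved; the
    topology with the smallest score wins.  Ties involving T3 resolve to T3
    (zero covariance is the conservative report); a T1/T2 tie resolves to
    T1.
    """
    if any(x <= 0 for x in q.v.values()):
        raise ValueError("topology selection requires positive variances")
    d, v = q.dist, q.var
    s1 = (d(0, 1) + d(2, 3) - d(0, 3) - d(1, 2)) ** 2 / (
        v(0, 1) + v(2, 3) + v(0, 3) + v(1, 2)
    )
    s2 = (d(0, 1) + d(2, 3) - d(0, 2) - d(1, 3)) ** 2 / (
        v(0, 1) + v(2, 3) + v(0, 2) + v(1, 3)
    )
    s3 = (d(0, 2) + d(1, 3) - d(0, 3) - d(1, 2)) ** 2 / (
        v(0, 2) + v(1, 3) + v(0, 3) + v(1, 2)
    )
    scores = {"T1": s1, "T2": s2, "T3": s3}
    smin = min(scores.values())
    winners = [t for t, s in scores.items() if s == smin]
    if "T3" in winners:
        best = "T3"
    else:
        best = winners[0]
    return TopologyFit(topology=best, scores=scores, tied=len(winners) > 1)


def estimate_shared_path(q: QuartetDistances, fit: TopologyFit) -> SharedPath:
    """WLS estimate of the middle-branch (shared path) length ``delta_m``.

    Valid for the dependence topologies T1 and T2 only.  The unconstrained
    WLS solution can be negative; both the raw value and its max(., 0)
    clamp are returned, and a negative raw value means the covariance is
    estimated as zero.
    """
    d, v = q.dist, q.var
    if fit.topology == "T1":
        w_cross = v(0, 3) + v(1, 2)  # il, jk
        d_cross = d(0, 3) + d(1, 2)
        d_sister = d(0, 2) + d(1, 3)  # ik, jl: within-side pairs
    elif fit.topology == "T2":
        w_cross = v(0, 2) + v(1, 3)  # ik, jl
        d_cross = d(0, 2) + d(1, 3)
        d_sister = d(0, 3) + d(1, 2)  # il, jk
    else:
        raise ValueError("shared-path estimation requires topology T1 or T2")
    w_target = v(0, 1) + v(2, 3)
    denom = w_target + w_cross
    raw = (
        (d(0, 1) + d(2, 3)) * w_cross + d_cross * w_target
    ) / denom - d_sister
    raw *= 0.5
    return SharedPath(raw=raw, clamped=max(raw, 0.0))


def triplet_shared_path(d_ij: float, d_jk: float, d_ik: float) -> float:
    """Shared path length of two distances that share a taxon.

    For distances d_ij and d_jk the shared path runs from j to the junction
    of the three leaf paths; by the three-point formula it is
    ``(d_ij + d_jk - d_ik) / 2``, clamped at zero.
    """
    if min(d_ij, d_jk, d_ik) < 0:
        raise ValueError("distances must be nonnegative")
    return max((d_ij + d_jk - d_ik) / 2.0, 0.0)


def nr_covariance(r: int, delta_m: float, n: int) -> float:
    """Closed-form covariance of two N_r ML distances sharing ``delta_m``.

    ``beta [(1-beta) e^{2 delta_m/beta} + (2beta-1) e^{delta_m/beta} -
    beta] / n`` -- formally the N_r distance variance evaluated at a true
    distance of ``delta_m``.
    """
    return nr_delta_variance(r, delta_m, n)


@dataclass
class InfoTable:
    """Precomputed per-site expected information on a distance grid.

    ``values[g]`` is the negative expected second derivative of the
    per-site log pair probability at ``grid[g]`` (positive, decreasing in
    the distance).  The covariance at ``delta_m`` is the reciprocal of n
    times the information; lookups interpolate linearly between the two
    bracketing grid points on the reciprocal (per-site variance) scale,
    which is near-linear in the distance.
    """

    model_id: str
    grid: np.ndarray
    values: np.ndarray
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.values.shape:
            raise ValueError("grid and values must be 1-D and equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("information values must be positive")

    def per_site_variance(self, delta: float) -> float:
        """Interpolated reciprocal information at ``delta`` (no extrapolation)."""
        if not (self.grid[0] <= delta <= self.grid[-1]):
            raise ValueError(
                f"delta {delta:.6g} outside table range "
                f"[{self.grid[0]:.6g}, {self.grid[-1]:.6g}]"
            )
        return float(np.interp(delta, self.grid, 1.0 / self.values))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# model\t{self.model_id}\n")
            fh.write("delta\tneg_expected_info\n")
            for g, val in zip(self.grid, self.values):
                fh.write(f"{g:.12g}\t{val:.12g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InfoTable":
        model_id = "unknown"
        grid, values = [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    parts = line[1:].split("\t")
                    if parts[0].strip() == "model" and len(parts) > 1:
                        model_id = parts[1].strip()
                    continue
                if line.startswith("delta"):
                    continue
                a, b = line.split("\t")
                grid.append(float(a))
                values.append(float(b))
        return cls(model_id=model_id, grid=np.array(grid), values=np.array(values))


def build_info_table(
    model: SubstitutionModel,
    delta_min: float = 0.001,
    delta_max: float = 5.0,
    step: float = 0.001,
) -> InfoTable:
    """Tabulate the per-site expected information over a distance grid.

    Grid values equal the direct expected-information sums at the grid
    points; the table trades a one-off O(grid) precomputation for constant
    lookup cost afterwards.
    """
    if not (0 < delta_min < delta_max):
        raise ValueError("need 0 < delta_min < delta_max")
    if step <= 0 or step > (delta_max - delta_min):
        raise ValueError("step must be positive and no larger than the range")
    m = int(np.floor((delta_max - delta_min) / step + 1e-9)) + 1
    grid = delta_min + step * np.arange(m)
    values = np.array([fisher_information(model, g, 1) for g in grid])
    return InfoTable(model_id=model.name, grid=grid, values=values)


def general_covariance(
    model: SubstitutionModel,
    delta_m: float,
    n: int,
    table: InfoTable | None = None,
) -> float:
    """Covariance of two ML distances sharing path length ``delta_m``.

    Evaluates the inverse expected Fisher information at ``delta_m``
    divided by n, either directly from the model or via a precomputed
    lookup table.  A shared path below ``DELTA_EPSILON`` yields exactly
    zero (the information diverges, the covariance vanishes).
    """
    if delta_m < 0:
        raise ValueError("delta_m must be nonnegative")
    if n < 1:
        raise ValueError("n must be >= 1")
    if delta_m < DELTA_EPSILON:
        return 0.0
    if table is not None:
        return table.per_site_variance(delta_m) / n
    return 1.0 / fisher_information(model, delta_m, n)


def branch_covariance(
    model: SubstitutionModel,
    q: QuartetDistances,
    table: InfoTable | None = None,
    n_effective: str = "geomean",
) -> CovarianceEstimate:
    """Branch-covariance of the distance pair (d_ij, d_kl) of a quartet.

    Selects the quartet topology by WLS; T3 (independent paths) yields
    exactly zero.  Otherwise the shared path length is estimated by WLS
    (a negative unconstrained value also yields zero) and the covariance is
    the inverse expected information at the estimate.  When the two
    pairwise alignments differ in length the effective n is their geometric
    mean, rounded (``n_effective="min"`` uses the smaller count instead).
    """
    if n_effective not in ("geomean", "min"):
        raise ValueError("n_effective must be 'geomean' or 'min'")
    n_ij, n_kl = q.npair(0, 1), q.npair(2, 3)
    if n_effective == "geomean":
        n_eff = int(round(np.sqrt(float(n_ij) * float(n_kl))))
    else:
        n_eff = min(n_ij, n_kl)
    fit = select_topology(q)
    if fit.topology == "T3":
        return CovarianceEstimate(
            cov=0.0,
            delta_m_hat=0.0,
            topology=fit,
            n_effective=n_eff,
            zero_reason="independent-topology",
        )
    raw, clamped = estimate_shared_path(q, fit)
    if raw < 0:
        return CovarianceEstimate(
            cov=0.0,
            delta_m_hat=0.0,
            topology=fit,
            n_effective=n_eff,
            zero_reason="negative-delta",
        )
    cov = general_covariance(model, clamped, n_eff, table)
    return CovarianceEstimate(
        cov=cov,
        delta_m_hat=clamped,
        topology=fit,
        n_effective=n_eff,
        zero_reason="none",
    )


def covariance_matrix(
    model: SubstitutionModel,
    distance_table: pd.DataFrame,
    table: InfoTable | None = None,
    n_effective: str = "geomean",
) -> pd.DataFrame:
    """Covariances for every unordered pair of taxon-pairs in a distance table.

    ``distance_table`` is the output of
    :func:`branchcov.distances.pairwise_distance_table` over m taxa (all
    m(m-1)/2 pairs present).  Diagonal records carry the input variances;
    disjoint pairs route through the quartet pipeline, pairs sharing a
    taxon through the three-point shared-path formula.  Output columns:
    (pair_a, pair_b, topology, delta_m_hat, covariance, zero_reason).
    """
    taxa = sorted(set(distance_table["taxon_a"]) | set(distance_table["taxon_b"]))
    rec: dict[frozenset, dict] = {}
    for _, row in distance_table.iterrows():
        rec[frozenset((row["taxon_a"], row["taxon_b"]))] = row
    pairs = [(taxa[a], taxa[b]) for a in range(len(taxa)) for b in range(a + 1, len(taxa))]
    for p in pairs:
        if frozenset(p) not in rec:
            raise ValueError(f"distance table is missing pair {p}")

    def lookup(a, b):
        return rec[frozenset((a, b))]

    rows = []
    for ai in range(len(pairs)):
        pa = pairs[ai]
        ra = lookup(*pa)
        rows.append(
            dict(
                pair_a=f"{pa[0]}-{pa[1]}",
                pair_b=f"{pa[0]}-{pa[1]}",
                topology="self",
                delta_m_hat=np.nan,
                covariance=float(ra["variance"]),
                zero_reason="none",
            )
        )
        for bi in range(ai + 1, len(pairs)):
            pb = pairs[bi]
            shared = set(pa) & set(pb)
            if len(shared) == 0:
                labels = (pa[0], pa[1], pb[0], pb[1])
                d6, v6, n6 = [], [], []
                for u, v in _PAIRS_ORDER:
                    r6 = lookup(labels[u], labels[v])
                    d6.append(float(r6["d_hat"]))
                    v6.append(float(r6["variance"]))
                    n6.append(int(r6["n"]))
                q = QuartetDistances.from_arrays(labels, d6, v6, n6)
                est = branch_covariance(model, q, table=table, n_effective=n_effective)
                topo, dm, cov, reason = (
                    est.topology.topology,
                    est.delta_m_hat,
                    est.cov,
                    est.zero_reason,
                )
            else:
                (j,) = shared
                i = next(x for x in pa if x != j)
                k = next(x for x in pb if x != j)
                r_ij, r_jk, r_ik = lookup(i, j), lookup(j, k), lookup(i, k)
                dm = triplet_shared_path(
                    float(r_ij["d_hat"]), float(r_jk["d_hat"]), float(r_ik["d_hat"])
                )
                n_ij, n_jk = int(r_ij["n"]), int(r_jk["n"])
                if n_effective == "geomean":
                    n_eff = int(round(np.sqrt(float(n_ij) * float(n_jk))))
                else:
                    n_eff = min(n_ij, n_jk)
                cov = general_covariance(model, dm, n_eff, table)
                topo = "triplet"
                reason = "none" if cov > 0 else "negative-delta"
                if cov == 0.0:
                    dm = 0.0
            rows.append(
                dict(
                    pair_a=f"{pa[0]}-{pa[1]}",
                    pair_b=f"{pb[0]}-{pb[1]}",
                    topology=topo,
                    delta_m_hat=dm,
                    covariance=cov,
                    zero_reason=reason,
                )
            )
    return pd.DataFrame(rows)
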