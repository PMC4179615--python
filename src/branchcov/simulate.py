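"""Quartet simulation and Monte-Carlo validation harness.

Sequences are evolved along a four-leaf tree (a quartet) with five branch
lengths: four terminal branches and a middle branch of length ``delta_m``
whose shared mutation events induce the covariance between overlapping
pairwise distances.  The module provides

* a random quartet sampler (uniform branch lengths dilated by a U(0.5, 2)
  expansion/contraction factor),
* a Markov-chain sequence evolver (root drawn from the equilibrium
  distribution, states propagated with transition matrices ``e^{Q delta}``),
* an exact pattern-probability oracle enumerating all r^4 leaf patterns,
* optional indel corruption (Zipfian gap lengths) with global pairwise
  re-alignment, emulating distances estimated from optimal pairwise
  alignments rather than the true alignment, and
* Monte-Carlo experiments that measure the bias and mean squared error of
  the branch- and Susko-covariance estimators against the replicate sample
  covariance (an unbiased reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from branchcov.covariance import (
    QuartetDistances,
    branch_covariance,
    general_covariance,
    nr_covariance,
    triplet_shared_path,
)
from branchcov.distances import (
    DEFAULT_CEILING,
    SaturationError,
    SitePairCounts,
    estimate_distance_ml,
    nr_delta_variance,
    nr_distance,
    site_pair_counts,
)
from branchcov.models import SubstitutionModel, nr_mutation_probability
from branchcov.susko import score_table

__all__ = [
    "Quartet",
    "IndelModel",
    "MonteCarloResult",
    "MseComparison",
    "AlignmentScoring",
    "sample_quartet",
    "evolve_quartet",
    "joint_pattern_probability",
    "expected_mismatch_product",
    "nr_count_covariance_per_site",
    "apply_indels",
    "align_pair",
    "default_scoring",
    "monte_carlo_experiment",
    "pair_distance_replicates",
    "mse_comparison",
    "write_fasta",
]

_SIDES = {
    # leaf positions (of i, j, k, l) attached to each end of the middle edge
    "T1": ((0, 2), (1, 3)),
    "T2": ((0, 3), (1, 2)),
    "T3": ((0, 1), (2, 3)),
}

_PAIRS_ORDER = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass
class Quartet:
    """A four-leaf tree: five branch lengths and a labeling of the leaves.

    ``delta`` holds (delta_i, delta_j, delta_k, delta_l, delta_m) in
    expected substitutions per site.  ``topology`` names which leaf pairs
    flank the middle edge: under "T1" leaves (i, k) attach to one end and
    (j, l) to the other, so the paths i--j and k--l both traverse the
    middle branch (the dependence case for the distance pair d_ij, d_kl);
    "T3" puts (i, j) on one side and (k, l) on the other (independence).
    """

    delta: tuple[float, float, float, float, float]
    topology: str = "T1"
    labels: tuple[str, str, str, str] = ("i", "j", "k", "l")

    def __post_init__(self) -> None:
        self.delta = tuple(float(x) for x in self.delta)
        if len(self.delta) != 5 or any(x < 0 for x in self.delta):
            raise ValueError("delta must hold five nonnegative branch lengths")
        if self.topology not in _SIDES:
            raise ValueError("topology must be one of T1, T2, T3")
        if len(self.labels) != 4:
            raise ValueError("a quartet has four leaf labels")

    @property
    def delta_m(self) -> float:
        return self.delta[4]

    def sides(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return _SIDES[self.topology]

    def path_length(self, a: int, b: int) -> float:
        """Additive leaf-to-leaf distance between leaf positions a and b."""
        if a == b:
            return 0.0
        s1, _ = self.sides()
        same_side = (a in s1) == (b in s1)
        return self.delta[a] + self.delta[b] + (0.0 if same_side else self.delta_m)

    def shared_path(self, pair_a=(0, 1), pair_b=(2, 3)) -> float:
        """True shared path length between the paths of two leaf pairs."""
        common = set(pair_a) & set(pair_b)
        if common:
            (j,) = common
            i = next(x for x in pair_a if x != j)
            k = next(x for x in pair_b if x != j)
            return triplet_shared_path(
                self.path_length(i, j), self.path_length(j, k), self.path_length(i, k)
            )
        s1, _ = self.sides()
        split_a = (pair_a[0] in s1) != (pair_a[1] in s1)
        split_b = (pair_b[0] in s1) != (pair_b[1] in s1)
        return self.delta_m if (split_a and split_b) else 0.0

    def true_distances(self) -> list[float]:
        """The six additive pairwise distances in order ij, ik, il, jk, jl, kl."""
        return [self.path_length(a, b) for a, b in _PAIRS_ORDER]

    def to_newick(self) -> str:
        (a, b), (c, d) = self.sides()
        L, dl = self.labels, self.delta
        return (
            f"(({L[a]}:{dl[a]:.10g},{L[b]}:{dl[b]:.10g}):{self.delta_m:.10g},"
            f"{L[c]}:{dl[c]:.10g},{L[d]}:{dl[d]:.10g});"
        )

    @classmethod
    def from_newick(cls, newick: str) -> "Quartet":
        """Parse a quartet with branch lengths from a Newick string.

        The tree must have exactly four leaves and one internal edge (the
        middle branch).  The returned quartet uses topology "T1": the two
        leaves forming a cherry become positions i and k, the remaining two
        become j and l.
        """
        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.encode_bipartitions()
        leaves = [lf for lf in tree.leaf_node_iter()]
        if len(leaves) != 4:
            raise ValueError("a quartet Newick must have exactly four leaves")
        internal = [
            e
            for e in tree.preorder_edge_iter()
            if e.head_node is not None
            and not e.head_node.is_leaf()
            and e.tail_node is not None
        ]
        if len(internal) != 1:
            raise ValueError("a quartet Newick must have exactly one internal edge")
        delta_m = internal[0].length or 0.0
        cherry = [lf for lf in internal[0].head_node.leaf_iter()]
        others = [lf for lf in leaves if lf not in cherry]
        i, k = cherry
        j, l = others

        def el(node):
            return node.edge.length or 0.0

        return cls(
            delta=(el(i), el(j), el(k), el(l), delta_m),
            topology="T1",
            labels=(
                i.taxon.label,
                j.taxon.label,
                k.taxon.label,
                l.taxon.label,
            ),
        )


@dataclass
class IndelModel:
    """Gap process: per-site initiation with power-law gap lengths.

    A gap starts at each site independently with probability ``gap_rate``;
    its length is drawn from a Zipf distribution with exponent
    ``zipf_exponent`` truncated at ``max_gap``.
    """

    gap_rate: float = 0.01
    zipf_exponent: float = 1.821
    max_gap: int = 50

    def __post_init__(self) -> None:
        if not (0 <= self.gap_rate < 1):
            raise ValueError("gap_rate must be in [0, 1)")
        if self.zipf_exponent <= 1:
            raise ValueError("zipf_exponent must be > 1")
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")

    def length_pmf(self) -> np.ndarray:
        """Truncated Zipf pmf over gap lengths 1..max_gap."""
        k = np.arange(1, self.max_gap + 1, dtype=float)
        with np.errstate(over="ignore"):
            w = np.exp(-self.zipf_exponent * np.log(k))
        return w / w.sum()


# -- sampling and evolution ------------------------------------------------


def sample_quartet(
    seed,
    terminal_range: tuple[float, float] = (0.02, 0.8),
    middle_range: tuple[float, float] = (0.01, 0.5),
    scale_range: tuple[float, float] = (0.5, 2.0),
    topology: str = "T1",
    labels=("i", "j", "k", "l"),
) -> Quartet:
    """Draw a random quartet: uniform branch lengths times a dilation factor.

    The four terminal branch lengths are uniform on ``terminal_range`` and
    the middle branch on ``middle_range``; all five are then multiplied by
    a single expansion/contraction factor uniform on ``scale_range``
    (default U(0.5, 2)), exploring extremer regions of branch-length space
    while preserving the relative structure.
    """
    for name, rg in (
        ("terminal_range", terminal_range),
        ("middle_range", middle_range),
        ("scale_range", scale_range),
    ):
        if rg[0] > rg[1] or rg[0] <= 0:
            raise ValueError(f"{name} must be a nonempty positive range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = rng.uniform(terminal_range[0], terminal_range[1], size=4)
    m = rng.uniform(middle_range[0], middle_range[1])
    scale = rng.uniform(scale_range[0], scale_range[1])
    delta = tuple(float(x * scale) for x in (*t, m))
    return Quartet(delta=delta, topology=topology, labels=tuple(labels))


def _cumulative(P: np.ndarray) -> np.ndarray:
    c = np.cumsum(P, axis=-1)
    c[..., -1] = 1.0  # guard against roundoff in the last bin
    return c


def _propagate(rng: np.random.Generator, parent: np.ndarray, cumP: np.ndarray):
    """Sample child states site-wise from the categorical rows of cumP."""
    u = rng.random(parent.shape[0])
    return (u[:, None] > cumP[parent]).sum(axis=1)


def _evolve_states(
    model: SubstitutionModel, q: Quartet, length: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate quartet leaf states; returns an n x 4 int array (i, j, k, l)."""
    cum_pi = np.cumsum(model.pi)
    cum_pi[-1] = 1.0
    node1 = np.searchsorted(cum_pi, rng.random(length), side="right")
    node2 = _propagate(rng, node1, _cumulative(model.expm(q.delta_m)))
    s1, _ = q.sides()
    leaves = np.empty((length, 4), dtype=np.int64)
    for pos in range(4):
        parent = node1 if pos in s1 else node2
        leaves[:, pos] = _propagate(
            rng, parent, _cumulative(model.expm(q.delta[pos]))
        )
    return leaves


def evolve_quartet(
    model: SubstitutionModel, q: Quartet, length: int, seed
) -> tuple[str, str, str, str]:
    """Evolve four aligned gapless sequences along the quartet.

    The state at one end of the middle edge is drawn from the equilibrium
    distribution and propagated along each branch with the transition
    matrix ``e^{Q delta}``; sites are independent and the site index is the
    true alignment.  Reproducible as a pure function of ``seed``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = _evolve_states(model, q, length, rng)
    chars = np.array(list(model.alphabet))
    return tuple("".join(chars[states[:, p]]) for p in range(4))


def joint_pattern_probability(model: SubstitutionModel, q: Quartet) -> np.ndarray:
    """Exact probability of every r^4 leaf pattern of the quartet.

    Sums over the states of the two internal nodes:
    ``sum_{u,w} pi_u [e^{Q delta_m}]_{uw}`` times the four leaf branch
    factors.  The returned array is indexed by the states of (i, j, k, l)
    and sums to one; marginalizing any leaf pair reproduces the pairwise
    joint probability at the additive path length.
    """
    M = model.pi[:, None] * model.expm(q.delta_m)
    P = [model.expm(q.delta[p]) for p in range(4)]
    s1, _ = q.sides()
    parents = ["u" if p in s1 else "w" for p in range(4)]
    spec = "uw," + ",".join(f"{parents[p]}{'abcd'[p]}" for p in range(4)) + "->abcd"
    return np.einsum(spec, M, *P)


def expected_mismatch_product(
    model: SubstitutionModel, q: Quartet, pair_a=(0, 1), pair_b=(2, 3)
) -> float:
    """E[S_a S_b]: probability that both leaf pairs differ at a site.

    Computed exactly from the full pattern enumeration; this is the
    brute-force oracle behind the closed-form count covariance.
    """
    joint = joint_pattern_probability(model, q)
    r = model.r
    idx = np.arange(r)
    diff_a = idx.reshape([-1 if p == pair_a[0] else 1 for p in range(4)]) != idx.reshape(
        [-1 if p == pair_a[1] else 1 for p in range(4)]
    )
    diff_b = idx.reshape([-1 if p == pair_b[0] else 1 for p in range(4)]) != idx.reshape(
        [-1 if p == pair_b[1] else 1 for p in range(4)]
    )
    return float(np.sum(joint * (diff_a & diff_b)))


def nr_count_covariance_per_site(
    r: int, d_ij: float, d_kl: float, delta_m: float
) -> float:
    """Closed-form per-site covariance of the difference indicators under N_r.

    ``cov(S_ij, S_kl) = beta [(1-beta) e^{-(d_ij+d_kl-2 delta_m)/beta}
    + (2beta-1) e^{-(d_ij+d_kl-delta_m)/beta} - beta e^{-(d_ij+d_kl)/beta}]``.
    Multiplying by n gives the covariance of the mismatch counts.
    """
    beta = (r - 1) / r
    s = d_ij + d_kl
    return beta * (
        (1.0 - beta) * np.exp(-(s - 2.0 * delta_m) / beta)
        + (2.0 * beta - 1.0) * np.exp(-(s - delta_m) / beta)
        - beta * np.exp(-s / beta)
    )


# -- indels and alignment --------------------------------------------------


def apply_indels(sequences, im: IndelModel, seed):
    """Overlay deletion gaps on a gapless alignment.

    Per sequence and per site a gap starts with probability ``gap_rate``;
    its length is truncated-Zipf distributed.  Gapped positions are
    replaced by '-', so the returned sequences still form the true
    alignment (column indices unchanged).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pmf = im.length_pmf()
    out = []
    for seq in sequences:
        arr = np.array(list(seq))
        n = arr.size
        starts = np.flatnonzero(rng.random(n) < im.gap_rate)
        for s in starts:
            length = 1 + int(rng.choice(im.max_gap, p=pmf))
            arr[s : s + length] = "-"
        out.append("".join(arr))
    return tuple(out)


@dataclass
class AlignmentScoring:
    """Substitution scores plus affine gap penalties for global alignment.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend`` (both
    negative).
    """

    matrix: np.ndarray
    alphabet: str
    gap_open: float = -10.0
    gap_extend: float = -1.0


def default_scoring(
    model: SubstitutionModel, d_ref: float = 1.0
) -> AlignmentScoring:
    """Log-odds scores from the model at a reference distance, in half-bits.

    ``s(u, v) = 2 log2( p(u, v; d_ref) / (pi_u pi_v) )`` with affine gap
    penalties open -10, extend -1.
    """
    P = model.pi[:, None] * model.expm(d_ref)
    S = 2.0 * np.log2(P / np.outer(model.pi, model.pi))
    return AlignmentScoring(matrix=S, alphabet="".join(model.alphabet))


def align_pair(
    seq_a: str, seq_b: str, scoring: AlignmentScoring
) -> tuple[str, str, float]:
    """Optimal global pairwise alignment under the given scoring.

    Needleman--Wunsch with affine gaps; deterministic (the first optimal
    traceback is reported).  Returns the two gapped sequences and the
    score.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    m = substitution_matrices.Array(alphabet=scoring.alphabet, dims=2)
    for a, ca in enumerate(scoring.alphabet):
        for b, cb in enumerate(scoring.alphabet):
            m[ca, cb] = scoring.matrix[a, b]
    aligner.substitution_matrix = m
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    aln = aligner.align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


def write_fasta(sequences, labels, path) -> None:
    """Write sequences (gapped or ungapped) as FASTA."""
    with open(path, "w") as fh:
        for label, seq in zip(labels, sequences):
            fh.write(f">{label}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# -- Monte-Carlo harness ---------------------------------------------------


@dataclass
class EstimatorSummary:
    """Replicate summary of one covariance estimator against the MC reference."""

    mean: float
    sd: float
    se_mean: float
    bias: float
    mse: float


@dataclass
class MonteCarloResult:
    """Monte-Carlo reference values and per-estimator summaries.

    The reference covariance/variance are the replicate sample statistics
    of the two target ML distance estimates (unbiased for the true
    values); estimator summaries report the replicate mean, spread, bias
    and mean squared error against the reference covariance.
    """

    reps: int
    n_saturated: int
    length: int
    seed: int
    true_shared_path: float
    mc_cov: float
    mc_cov_se: float
    mc_var_a: float
    mc_var_a_se: float
    mc_var_b: float
    mc_var_b_se: float
    mean_ml_var_a: float
    mean_ml_var_b: float
    estimators: dict[str, EstimatorSummary] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reps < 2:
            raise ValueError("need at least two effective replicates")

    def summary(self) -> str:
        lines = [
            f"replicates: {self.reps} (saturated excluded: {self.n_saturated})",
            f"true shared path: {self.true_shared_path:.6g}",
            f"MC covariance: {self.mc_cov:.6g} (SE {self.mc_cov_se:.3g})",
            f"MC variance A: {self.mc_var_a:.6g} (SE {self.mc_var_a_se:.3g})",
            f"MC variance B: {self.mc_var_b:.6g} (SE {self.mc_var_b_se:.3g})",
            f"mean ML variance A: {self.mean_ml_var_a:.6g}",
            f"mean ML variance B: {self.mean_ml_var_b:.6g}",
        ]
        for name, s in self.estimators.items():
            lines.append(
                f"{name}: mean {s.mean:.6g} (SE {s.se_mean:.3g}), "
                f"bias {s.bias:.3g}, MSE {s.mse:.4g}"
            )
        return "\n".join(lines)


def _nr_estimate(r: int, I: int, n: int, ceiling: float):
    try:
        d = nr_distance(r, I, n)
        if d >= ceiling:
            return ceiling, True
        return d, False
    except SaturationError:
        return ceiling, True


def _counts_from_states(a: np.ndarray, b: np.ndarray, r: int) -> SitePairCounts:
    F = np.bincount(a * r + b, minlength=r * r).reshape(r, r).astype(float)
    return SitePairCounts(F=F)


def monte_carlo_experiment(
    model: SubstitutionModel,
    q: Quartet,
    length: int,
    reps: int,
    seed: int,
    gapped: bool = False,
    im: IndelModel | None = None,
    estimators: tuple[str, ...] = ("branch", "susko"),
    target: tuple[tuple[int, int], tuple[int, int]] = ((0, 1), (2, 3)),
    ceiling: float = DEFAULT_CEILING,
    scoring: AlignmentScoring | None = None,
    table=None,
) -> MonteCarloResult:
    """Replicate simulation measuring covariance estimators on one quartet.

    Per replicate: evolve the quartet (optionally corrupt with indels and
    re-align each pair globally), summarize the six pairwise alignments,
    estimate all six ML distances and variances, and evaluate the requested
    covariance estimators for the target pair of distances.  Replicates
    where a target distance saturates are counted and excluded; exceeding
    5% of replicates triggers a warning.  The result is a pure function of
    ``seed``.
    """
    if reps < 100:
        raise ValueError("need at least 100 replicates for stable references")
    if gapped and "susko" in estimators:
        raise ValueError(
            "the Susko estimator needs true MSA columns; not applicable to "
            "re-aligned (OPA) replicates"
        )
    if gapped and im is None:
        im = IndelModel()
    if gapped and scoring is None:
        scoring = default_scoring(model)
    rng = np.random.default_rng(seed)
    r = model.r
    is_nr = model.is_nr
    pair_a, pair_b = target
    shared_taxon = bool(set(pair_a) & set(pair_b))
    pair_index = {frozenset(p): idx for idx, p in enumerate(_PAIRS_ORDER)}
    ia, ib = pair_index[frozenset(pair_a)], pair_index[frozenset(pair_b)]

    d_a = np.empty(reps)
    d_b = np.empty(reps)
    v_a = np.empty(reps)
    v_b = np.empty(reps)
    est_vals = {name: np.empty(reps) for name in estimators}
    ok = np.zeros(reps, dtype=bool)

    chars = np.array(list(model.alphabet))
    for rep in range(reps):
        states = _evolve_states(model, q, length, rng)
        if gapped:
            seqs = tuple("".join(chars[states[:, p]]) for p in range(4))
            gapped_seqs = apply_indels(seqs, im, rng)
            degapped = [s.replace("-", "") for s in gapped_seqs]
            counts6 = []
            for a, b in _PAIRS_ORDER:
                al_a, al_b, _ = align_pair(degapped[a], degapped[b], scoring)
                counts6.append(site_pair_counts(model, al_a, al_b))
        else:
            counts6 = [
                _counts_from_states(states[:, a], states[:, b], r)
                for a, b in _PAIRS_ORDER
            ]
        d6 = np.empty(6)
        v6 = np.empty(6)
        n6 = np.empty(6, dtype=int)
        sat6 = np.zeros(6, dtype=bool)
        for p in range(6):
            c = counts6[p]
            n6[p] = c.n
            if is_nr:
                d6[p], sat6[p] = _nr_estimate(r, c.I, c.n, ceiling)
                v6[p] = nr_delta_variance(r, d6[p], c.n)
            else:
                est = estimate_distance_ml(model, c, ceiling)
                d6[p], sat6[p], v6[p] = est.d_hat, est.saturated, est.variance
        if sat6[ia] or sat6[ib]:
            continue
        d_a[rep], d_b[rep] = d6[ia], d6[ib]
        v_a[rep], v_b[rep] = v6[ia], v6[ib]
        ok[rep] = True
        if "branch" in estimators:
            if shared_taxon:
                (j,) = set(pair_a) & set(pair_b)
                i = next(x for x in pair_a if x != j)
                k = next(x for x in pair_b if x != j)
                ik = pair_index[frozenset((i, k))]
                dm = triplet_shared_path(d6[ia], d6[ib], d6[ik])
                n_eff = int(round(np.sqrt(float(n6[ia]) * float(n6[ib]))))
                if is_nr:
                    cov = nr_covariance(r, dm, n_eff) if dm > 1e-8 else 0.0
                else:
                    cov = general_covariance(model, dm, n_eff, table)
                est_vals["branch"][rep] = cov
            else:
                qd = QuartetDistances.from_arrays(q.labels, d6, v6, n6)
                if is_nr:
                    est_vals["branch"][rep] = _nr_branch_cov(r, qd)
                else:
                    est_vals["branch"][rep] = branch_covariance(
                        model, qd, table=table
                    ).cov
        if "susko" in estimators:
            cols = states[:, [pair_a[0], pair_a[1], pair_b[0], pair_b[1]]]
            s_a = score_table(model, d6[ia])
            s_b = score_table(model, d6[ib])
            prod = s_a[cols[:, 0], cols[:, 1]] * s_b[cols[:, 2], cols[:, 3]]
            est_vals["susko"][rep] = length * v6[ia] * v6[ib] * float(np.mean(prod))

    n_sat = int(reps - ok.sum())
    if n_sat > 0.05 * reps:
        warnings.warn(
            f"{n_sat}/{reps} replicates saturated and were excluded; "
            "references may be biased"
        )
    d_a, d_b, v_a, v_b = d_a[ok], d_b[ok], v_a[ok], v_b[ok]
    m = d_a.size
    za = (d_a - d_a.mean()) * (d_b - d_b.mean())
    mc_cov = za.sum() / (m - 1)
    mc_cov_se = float(za.std(ddof=1) / np.sqrt(m))
    zva = (d_a - d_a.mean()) ** 2
    zvb = (d_b - d_b.mean()) ** 2
    mc_var_a = zva.sum() / (m - 1)
    mc_var_b = zvb.sum() / (m - 1)
    summaries = {}
    for name in estimators:
        e = est_vals[name][ok]
        summaries[name] = EstimatorSummary(
            mean=float(e.mean()),
            sd=float(e.std(ddof=1)),
            se_mean=float(e.std(ddof=1) / np.sqrt(m)),
            bias=float(e.mean() - mc_cov),
            mse=float(np.mean((e - mc_cov) ** 2)),
        )
    return MonteCarloResult(
        reps=m,
        n_saturated=n_sat,
        length=length,
        seed=seed,
        true_shared_path=q.shared_path(pair_a, pair_b),
        mc_cov=float(mc_cov),
        mc_cov_se=mc_cov_se,
        mc_var_a=float(mc_var_a),
        mc_var_a_se=float(zva.std(ddof=1) / np.sqrt(m)),
        mc_var_b=float(mc_var_b),
        mc_var_b_se=float(zvb.std(ddof=1) / np.sqrt(m)),
        mean_ml_var_a=float(v_a.mean()),
        mean_ml_var_b=float(v_b.mean()),
        estimators=summaries,
    )


def _nr_branch_cov(r: int, qd: QuartetDistances) -> float:
    """Branch covariance for N_r input via the closed-form variance formula."""
    from branchcov.covariance import estimate_shared_path, select_topology

    fit = select_topology(qd)
    if fit.topology == "T3":
        return 0.0
    raw, clamped = estimate_shared_path(qd, fit)
    if raw < 0 or clamped < 1e-8:
        return 0.0
    n_eff = int(round(np.sqrt(float(qd.npair(0, 1)) * float(qd.npair(2, 3)))))
    return nr_covariance(r, clamped, n_eff)


def pair_distance_replicates(
    model: SubstitutionModel,
    d_true: float,
    length: int,
    reps: int,
    seed: int,
    ceiling: float = DEFAULT_CEILING,
) -> np.ndarray:
    """Replicated ML distance estimates for a single sequence pair.

    Simulates ``reps`` independent pairwise alignments of ``length`` sites
    at true distance ``d_true`` and returns the ML estimates (saturated
    replicates are dropped).  For the r-state symmetric model the mismatch
    count is binomial and the simulation is exact and vectorized.
    """
    rng = np.random.default_rng(seed)
    if model.is_nr:
        r = model.r
        p = nr_mutation_probability(r, d_true)
        I = rng.binomial(length, p, size=reps)
        beta = (r - 1) / r
        arg = 1.0 - I / (length * beta)
        keep = arg > 0
        d = -beta * np.log(arg[keep])
        return np.minimum(d, ceiling)
    cumP = _cumulative(model.expm(d_true))
    cum_pi = np.cumsum(model.pi)
    cum_pi[-1] = 1.0
    out = np.empty(reps)
    keep = np.zeros(reps, dtype=bool)
    for rep in range(reps):
        a = np.searchsorted(cum_pi, rng.random(length), side="right")
        b = _propagate(rng, a, cumP)
        counts = _counts_from_states(a, b, model.r)
        est = estimate_distance_ml(model, counts, ceiling)
        out[rep] = est.d_hat
        keep[rep] = not est.saturated
    return out[keep]


@dataclass
class MseComparison:
    """Aggregate MSE comparison of covariance estimators across quartets."""

    table: pd.DataFrame
    per_quartet: pd.DataFrame
    ratios: dict[str, float]
    conjecture: pd.DataFrame | None = None
    conjecture_slope: float | None = None


def mse_comparison(
    model: SubstitutionModel,
    quartets: list[Quartet],
    length: int,
    reps: int,
    seed: int,
    estimators: tuple[str, ...] = ("branch", "susko"),
    cases: tuple[str, ...] = ("dependence", "triplet", "independence"),
    conjecture: bool = False,
    conjecture_length: int = 10000,
    conjecture_reps: int = 2000,
    table=None,
) -> MseComparison:
    """Compare covariance estimators across quartets and topological cases.

    For each quartet the three relations between the two target distances
    are simulated: *dependence* (paths share the middle branch),
    *triplet* (distances share a taxon) and *independence* (true covariance
    zero).  Reported per case and estimator: average and median replicate
    MSE against the Monte-Carlo reference covariance, plus the average
    per-quartet MSE ratio of branch- to Susko-covariance.  With
    ``conjecture=True`` an additional long-sequence run regresses the
    Monte-Carlo covariance on the Monte-Carlo variance of a pairwise
    estimate at the true shared path length (expected slope 1).
    """
    if len(quartets) < 1:
        raise ValueError("need at least one quartet")
    ss = np.random.SeedSequence(seed)
    case_setup = {
        "dependence": ("T1", ((0, 1), (2, 3))),
        "triplet": ("T1", ((0, 1), (1, 2))),
        "independence": ("T3", ((0, 1), (2, 3))),
    }
    rows = []
    child_seeds = iter(ss.generate_state(len(quartets) * len(cases) * 2 + 2 * len(quartets)))
    for qi, q in enumerate(quartets):
        for case in cases:
            topo, target = case_setup[case]
            qc = Quartet(delta=q.delta, topology=topo, labels=q.labels)
            res = monte_carlo_experiment(
                model,
                qc,
                length,
                reps,
                seed=int(next(child_seeds)) % (2**31),
                estimators=estimators,
                target=target,
                table=table,
            )
            for name in estimators:
                s = res.estimators[name]
                rows.append(
                    dict(
                        quartet=qi,
                        case=case,
                        estimator=name,
                        length=length,
                        reps=reps,
                        mse=s.mse,
                        bias=s.bias,
                        mean=s.mean,
                        mc_cov=res.mc_cov,
                        mc_cov_se=res.mc_cov_se,
                        mc_var_a=res.mc_var_a,
                        mean_ml_var_a=res.mean_ml_var_a,
                        true_shared_path=res.true_shared_path,
                    )
                )
    per_quartet = pd.DataFrame(rows)
    agg = (
        per_quartet.groupby(["case", "estimator"])["mse"]
        .agg(avg_mse="mean", median_mse="median")
        .reset_index()
    )
    ratios = {}
    if "branch" in estimators and "susko" in estimators:
        for case in cases:
            sub = per_quartet[per_quartet["case"] == case]
            b = sub[sub["estimator"] == "branch"].set_index("quartet")["mse"]
            s = sub[sub["estimator"] == "susko"].set_index("quartet")["mse"]
            ratios[case] = float((b / s).mean())
    conj_df = None
    slope = None
    if conjecture:
        crows = []
        for qi, q in enumerate(quartets):
            qc = Quartet(delta=q.delta, topology="T1", labels=q.labels)
            res = monte_carlo_experiment(
                model,
                qc,
                conjecture_length,
                conjecture_reps,
                seed=int(next(child_seeds)) % (2**31),
                estimators=(),
            )
            d_reps = pair_distance_replicates(
                model,
                q.delta_m,
                conjecture_length,
                conjecture_reps,
                seed=int(next(child_seeds)) % (2**31),
            )
            crows.append(
                dict(
                    quartet=qi,
                    delta_m=q.delta_m,
                    mc_cov=res.mc_cov,
                    mc_cov_se=res.mc_cov_se,
                    mc_var_at_delta_m=float(np.var(d_reps, ddof=1)),
                )
            )
        conj_df = pd.DataFrame(crows)
        x = conj_df["mc_var_at_delta_m"].to_numpy()
        y = conj_df["mc_cov"].to_numpy()
        slope = float(np.sum(x * y) / np.sum(x * x))
    return MseComparison(
        table=agg,
        per_quartet=per_quartet,
        ratios=ratios,
        conjecture=conj_df,
        conjecture_slope=slope,
    )
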