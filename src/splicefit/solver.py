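"""Joint transcript selection and quantification over multiple samples.

The core inference problem: given a splicing graph with observed segment,
intron and read-pair counts in R samples, choose a binary transcript
matrix U (rows = source-to-sink paths) and non-negative normalized
abundances W (one column per sample, shared U across samples) minimizing

    sum_r [ L(V_obs_r, V_exp_r) + w_intron * L(I_obs_r, I_exp_r)
            + w_pair * pair_penalty_r ]
    + w_sparsity * (#novel rows + w_known_discount * #known rows)

where V_exp_r = c * U^T W_r with c the maximal observed segment count,
L is the convex proxy of the count NLL (see :mod:`splicefit.loss`), the
pair penalty charges read-pair-linked segment pairs contained in no
selected transcript, and the sparsity term implements Occam's razor over
the transcript set, discounted for annotated (known) rows.

Exact mode runs a best-first branch-and-bound over path-inclusion
indicators: candidate paths come from the graph (enumeration-capped), and
each node's lower bound is the convex quantification with all undecided
candidates admitted and sparsity charged only for decided inclusions —
admitting more transcripts can only lower the loss and pair terms, so the
bound is valid, and leaves are scored exactly.  Iterative mode adds the
single best new transcript at a time, freezing accepted rows, which
trades the optimality certificate for speed on complex loci.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .graph import ObservationSet, SegmentGraph
from .loss import LossModel, ProxyCurve, fit_proxy, nll_count

logger = logging.getLogger(__name__)


@dataclass
class HyperParams:
    """Trade-off weights of the objective.

    All weights are in loss units (negative log-likelihood); the sparsity
    weight is the price of admitting one novel transcript, discounted by
    ``w_known_discount`` for annotated rows.  ``k_max`` caps the number of
    transcripts returned.
    """

    w_sparsity: float = 1.0
    w_intron: float = 1.0
    w_pair: float = 1.0
    w_known_discount: float = 0.1
    k_max: int = 12

    def __post_init__(self):
        if min(self.w_sparsity, self.w_intron, self.w_pair) < 0:
            raise ValueError("weights must be >= 0")
        if not 0 <= self.w_known_discount <= 1:
            raise ValueError("w_known_discount must be in [0, 1]")


@dataclass
class TranscriptSet:
    """Binary transcript-by-segment matrix with per-row provenance."""

    U: np.ndarray  # (k, S)
    provenance: list  # 'known' | 'novel' per row
    edge_usage: np.ndarray = None  # (k, E), aligned with graph.edge_list

    def __post_init__(self):
        self.U = np.atleast_2d(np.asarray(self.U, dtype=np.int8))
        if len(self.provenance) != self.U.shape[0]:
            raise ValueError("provenance length must match number of rows")

    @property
    def k(self) -> int:
        return self.U.shape[0]

    @classmethod
    def from_paths(cls, graph: SegmentGraph, rows, provenance=None):
        rows = [np.asarray(r, dtype=np.int8) for r in rows]
        for r in rows:
            if r.any() and not graph.is_valid_path(r):
                raise ValueError(f"row {r.tolist()} is not a valid path in the graph")
        prov = list(provenance) if provenance is not None else ["novel"] * len(rows)
        u_mat = np.vstack(rows) if rows else np.zeros((0, graph.n_segments), dtype=np.int8)
        usage = (
            np.vstack([graph.path_edges(r) for r in rows])
            if rows
            else np.zeros((0, len(graph.edge_list)), dtype=np.int8)
        )
        return cls(U=u_mat, provenance=prov, edge_usage=usage)


@dataclass
class AbundanceMatrix:
    """Normalized abundances W (k x R) and the normalization constant c
    (maximal observed segment count), from which expected counts follow."""

    W: np.ndarray
    c: float

    def __post_init__(self):
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        if np.any(self.W < -1e-12):
            raise ValueError("abundances must be non-negative")
        self.W = np.maximum(self.W, 0.0)

    def expected_seg_counts(self, transcript_set: TranscriptSet) -> np.ndarray:
        """V_exp, shape (R, S): c * sum_t U[t,s] W[t,r]."""
        return self.c * (self.W.T @ transcript_set.U)

    def expected_intron_counts(self, transcript_set: TranscriptSet) -> np.ndarray:
        return self.c * (self.W.T @ transcript_set.edge_usage)


@dataclass
class SolveResult:
    transcripts: TranscriptSet
    abundances: AbundanceMatrix
    objective: float
    status: str  # optimal | approximate | time-capped
    breakdown: dict = field(default_factory=dict)
    n_nodes: int = 0

    def __post_init__(self):
        total = sum(self.breakdown.values())
        if self.breakdown and abs(total - self.objective) > 1e-6 * max(1.0, abs(total)):
            raise AssertionError("objective does not match its per-term breakdown")


# ---------------------------------------------------------------------------
# validity constraints over raw U entries
# ---------------------------------------------------------------------------


@dataclass
class ValidityConstraints:
    """Linear system A x <= b over one row of U (x in {0,1}^S) whose binary
    solutions are exactly the valid source-to-sink paths plus the zero row.
    For k rows the system repeats block-diagonally (``expand``)."""

    A: np.ndarray
    b: np.ndarray
    n_segments: int
    k: int

    def feasible_row(self, u) -> bool:
        u = np.asarray(u, dtype=float)
        return bool(np.all(self.A @ u <= self.b + 1e-9))

    def feasible(self, U) -> bool:
        return all(self.feasible_row(row) for row in np.atleast_2d(U))

    def expand(self):
        """Block-diagonal (A, b) over the flattened k x S matrix."""
        big_a = np.kron(np.eye(self.k), self.A)
        big_b = np.tile(self.b, self.k)
        return big_a, big_b


def build_validity_constraints(graph: SegmentGraph, k: int = 1) -> ValidityConstraints:
    """Constraints making each row of U a path (or all-zero).

    Three families: (1) for every forward pair (i, j) that is *not* an
    edge, selecting both requires some selected segment in between;
    (2) a selected non-initial segment needs a selected predecessor;
    (3) a selected non-terminal segment needs a selected successor.
    """
    n_seg = graph.n_segments
    if n_seg and not graph.initial_indices():
        raise ValueError("graph has no initial segment; no feasible path exists")
    if n_seg and not graph.terminal_indices():
        raise ValueError("graph has no terminal segment; no feasible path exists")
    rows, rhs = [], []
    for i in range(n_seg):
        for j in range(i + 1, n_seg):
            if (i, j) in graph.edges:
                continue
            row = np.zeros(n_seg)
            row[i] = 1.0
            row[j] = 1.0
            row[i + 1 : j] = -1.0
            rows.append(row)
            rhs.append(1.0)
    for s, seg in enumerate(graph.segments):
        if not seg.is_initial:
            row = np.zeros(n_seg)
            row[s] = 1.0
            row[:s] = -1.0
            rows.append(row)
            rhs.append(0.0)
        if not seg.is_terminal:
            row = np.zeros(n_seg)
            row[s] = 1.0
            row[s + 1 :] = -1.0
            rows.append(row)
            rhs.append(0.0)
    a_mat = np.vstack(rows) if rows else np.zeros((0, n_seg))
    return ValidityConstraints(A=a_mat, b=np.array(rhs), n_segments=n_seg, k=k)


# ---------------------------------------------------------------------------
# pair penalty
# ---------------------------------------------------------------------------


def pair_penalty(transcript_set: TranscriptSet, pair_counts_r: dict) -> float:
    """Sum of pair counts whose two segments are jointly contained in no
    selected transcript."""
    u_mat = transcript_set.U
    total = 0.0
    for (s1, s2), count in pair_counts_r.items():
        if u_mat.shape[0] == 0 or not np.any(u_mat[:, s1] & u_mat[:, s2]):
            total += count
    return float(total)


def _support_pair_penalty(u_mat: np.ndarray, pair_counts: list) -> float:
    total = 0.0
    for pc in pair_counts:
        for (s1, s2), count in pc.items():
            if u_mat.shape[0] == 0 or not np.any(u_mat[:, s1] & u_mat[:, s2]):
                total += count
    return float(total)


# ---------------------------------------------------------------------------
# convex quantification
# ---------------------------------------------------------------------------


class _CurveBank:
    """Stacked proxy curves for vectorized value/gradient evaluation."""

    def __init__(self, curves):
        self.curves = list(curves)
        if self.curves:
            self.knots = np.vstack([c.knots for c in self.curves])
            self.grads = np.vstack([c.grad_at_knots for c in self.curves])
            self.fvals = np.vstack([c._f_at_knots for c in self.curves])

    def value_grad(self, mu: np.ndarray):
        if not self.curves:
            return np.zeros(0), np.zeros(0)
        mu_col = mu[:, None]
        i = np.clip(np.sum(self.knots <= mu_col, axis=1) - 1, 0, self.knots.shape[1] - 2)
        rows = np.arange(len(self.curves))
        t0 = self.knots[rows, i]
        g0 = self.grads[rows, i]
        slope = (self.grads[rows, i + 1] - g0) / (self.knots[rows, i + 1] - t0)
        d = mu - t0
        vals = self.fvals[rows, i] + g0 * d + 0.5 * slope * d * d
        return vals, g0 + slope * d


class Quantifier:
    """Per-sample convex minimization of the proxy loss over W >= 0.

    Proxy curves are fitted once per distinct observed count and shared.
    The same object also evaluates the exact (non-proxy) NLL at a given W,
    which the statistical tests use.
    """

    def __init__(
        self,
        observations: ObservationSet,
        loss_model: LossModel,
        w_intron: float = 1.0,
        proxy_pieces: int = 6,
        w_max: float = 2.0,
    ):
        self.obs = observations
        self.model = loss_model
        self.w_intron = float(w_intron)
        self.w_max = w_max
        self.c = observations.max_count or 1.0
        self._curves: dict = {}
        self._pieces = proxy_pieces
        r_count = observations.n_samples
        self._seg_curves = [
            [self._curve(v) for v in observations.seg_counts[r]] for r in range(r_count)
        ]
        self._int_curves = [
            [self._curve(v) for v in observations.intron_counts[r]] for r in range(r_count)
        ]
        self._seg_banks = [_CurveBank(cs) for cs in self._seg_curves]
        self._int_banks = [_CurveBank(cs) for cs in self._int_curves]

    def _curve(self, v: float) -> ProxyCurve:
        key = round(float(v), 9)
        if key not in self._curves:
            self._curves[key] = fit_proxy(key, self.model, n_pieces=self._pieces)
        return self._curves[key]

    # -- proxy loss --------------------------------------------------------
    def _sample_loss_grad(self, r: int, u_mat, edge_use, w_r, want_grad=True):
        mu_seg = self.c * (w_r @ u_mat)
        mu_int = self.c * (w_r @ edge_use)
        seg_vals, g_seg = self._seg_banks[r].value_grad(mu_seg)
        int_vals, g_int = self._int_banks[r].value_grad(mu_int)
        loss = float(np.sum(seg_vals)) + self.w_intron * float(np.sum(int_vals))
        if not want_grad:
            return loss, None
        grad = self.c * (u_mat @ g_seg + self.w_intron * (edge_use @ g_int))
        return loss, grad

    def sample_loss(self, r: int, u_mat, edge_use, w_r) -> float:
        return self._sample_loss_grad(r, u_mat, edge_use, w_r, want_grad=False)[0]

    def fit(self, transcript_set: TranscriptSet, tied: bool = False, samples=None):
        """Optimal W for fixed U.  Returns (AbundanceMatrix, per-sample
        proxy losses).  ``tied=True`` shares one abundance vector across
        the selected samples."""
        u_mat = transcript_set.U.astype(float)
        edge_use = transcript_set.edge_usage.astype(float)
        k = u_mat.shape[0]
        r_idx = list(samples) if samples is not None else list(range(self.obs.n_samples))
        if k == 0:
            losses = [self.sample_loss(r, u_mat, edge_use, np.zeros(0)) for r in r_idx]
            return AbundanceMatrix(W=np.zeros((0, len(r_idx))), c=self.c), np.array(losses)

        bounds = [(0.0, self.w_max)] * k

        def fit_one(rows):
            def fun(w):
                total, grad = 0.0, np.zeros(k)
                for r in rows:
                    loss, g = self._sample_loss_grad(r, u_mat, edge_use, w)
                    total += loss
                    grad += g
                return total, grad

            x0 = self._warm_start(rows, u_mat, edge_use)
            res = minimize(fun, x0, jac=True, method="L-BFGS-B", bounds=bounds)
            return np.maximum(res.x, 0.0)

        if tied:
            w_shared = fit_one(r_idx)
            w_mat = np.tile(w_shared[:, None], (1, len(r_idx)))
        else:
            w_mat = np.column_stack([fit_one([r]) for r in r_idx])
        losses = np.array(
            [self.sample_loss(r, u_mat, edge_use, w_mat[:, i]) for i, r in enumerate(r_idx)]
        )
        return AbundanceMatrix(W=w_mat, c=self.c), losses

    def _warm_start(self, rows, u_mat, edge_use):
        design = np.hstack([u_mat, np.sqrt(self.w_intron) * edge_use]).T
        target = np.concatenate(
            [
                np.mean([self.obs.seg_counts[r] for r in rows], axis=0),
                np.sqrt(self.w_intron) * np.mean([self.obs.intron_counts[r] for r in rows], axis=0),
            ]
        )
        try:
            x0, *_ = np.linalg.lstsq(design, target / self.c, rcond=None)
        except np.linalg.LinAlgError:
            x0 = np.full(u_mat.shape[0], 0.1)
        return np.clip(x0, 0.0, self.w_max)

    def loss_components(self, transcript_set: TranscriptSet, abundances: AbundanceMatrix):
        """(segment proxy loss, weighted intron proxy loss) summed over samples."""
        mu_seg = abundances.expected_seg_counts(transcript_set)
        mu_int = abundances.expected_intron_counts(transcript_set)
        if transcript_set.k == 0:
            mu_seg = np.zeros_like(self.obs.seg_counts)
            mu_int = np.zeros_like(self.obs.intron_counts)
        seg_total = sum(
            curve(mu_seg[r, s])
            for r in range(self.obs.n_samples)
            for s, curve in enumerate(self._seg_curves[r])
        )
        int_total = self.w_intron * sum(
            curve(mu_int[r, e])
            for r in range(self.obs.n_samples)
            for e, curve in enumerate(self._int_curves[r])
        )
        return float(seg_total), float(int_total)

    # -- exact NLL ---------------------------------------------------------
    def exact_nll(self, transcript_set: TranscriptSet, abundances: AbundanceMatrix, samples=None):
        """True (non-proxy) NLL of the observations at the given W."""
        r_idx = list(samples) if samples is not None else list(range(self.obs.n_samples))
        mu_seg = abundances.expected_seg_counts(transcript_set)
        mu_int = abundances.expected_intron_counts(transcript_set)
        total = 0.0
        for i, r in enumerate(r_idx):
            total += float(
                np.sum(nll_count(self.obs.seg_counts[r], mu_seg[i], self.model))
            ) + self.w_intron * float(
                np.sum(nll_count(self.obs.intron_counts[r], mu_int[i], self.model))
            )
        return total


def quantify_fixed(
    transcript_set: TranscriptSet,
    observations: ObservationSet,
    loss_model: LossModel,
    w_intron: float = 1.0,
    tied: bool = False,
    samples=None,
    proxy_pieces: int = 6,
):
    """Convex abundance fit for a fixed transcript set, regularizers zeroed.

    Returns ``(AbundanceMatrix, per_sample_proxy_losses)``.
    """
    quantifier = Quantifier(observations, loss_model, w_intron, proxy_pieces)
    return quantifier.fit(transcript_set, tied=tied, samples=samples)


# ---------------------------------------------------------------------------
# branch-and-bound solver
# ---------------------------------------------------------------------------


def _lex_key(u_mat: np.ndarray):
    return tuple(sorted(tuple(int(x) for x in row) for row in u_mat))


class _Incumbent:
    """Best solution so far with the deterministic tie-break: lower
    objective, then fewer transcripts, then lexicographically smallest U."""

    TOL = 1e-9

    def __init__(self):
        self.objective = np.inf
        self.subset = None
        self.key = None

    def offer(self, objective, subset, u_mat) -> bool:
        key = (len(subset), _lex_key(u_mat))
        if objective < self.objective - self.TOL:
            better = True
        elif objective <= self.objective + self.TOL and (self.key is None or key < self.key):
            better = True
        else:
            better = False
        if better:
            self.objective = min(objective, self.objective)
            self.subset = subset
            self.key = key
        return better


def solve_joint(
    graph: SegmentGraph,
    observations: ObservationSet,
    loss_model: LossModel = None,
    hyper: HyperParams = None,
    known=None,
    mode: str = "exact",
    path_limit: int = 64,
    node_limit: int = 100000,
    proxy_pieces: int = 6,
) -> SolveResult:
    """Minimize the joint objective over transcript sets and abundances.

    ``known`` is an optional list of binary segment vectors (annotated
    transcripts); they enter as candidates whose sparsity price is
    discounted.  ``mode='exact'`` certifies optimality by branch-and-bound
    (status 'optimal', or 'time-capped' at ``node_limit``);
    ``mode='iterative'`` greedily adds one transcript at a time (status
    'approximate').
    """
    loss_model = loss_model or LossModel()
    hyper = hyper or HyperParams()
    known_rows = [np.asarray(r, dtype=np.int8) for r in (known or [])]
    if hyper.k_max < len(known_rows):
        raise ValueError("k_max must be >= number of known transcripts")

    paths = graph.enumerate_paths(limit=path_limit)
    known_keys = {tuple(r.tolist()) for r in known_rows}
    candidates = list(known_rows) + [p for p in paths if tuple(p.tolist()) not in known_keys]
    provenance = ["known"] * len(known_rows) + ["novel"] * (len(candidates) - len(known_rows))
    if not candidates:
        raise ValueError("graph admits no candidate transcripts")
    full_set = TranscriptSet.from_paths(graph, candidates, provenance)

    quantifier = Quantifier(observations, loss_model, hyper.w_intron, proxy_pieces)
    row_cost = np.array(
        [hyper.w_sparsity * (hyper.w_known_discount if p == "known" else 1.0) for p in provenance]
    )

    cache: dict = {}

    def eval_subset(subset: frozenset):
        """(loss_part + pair term, AbundanceMatrix) for a candidate subset."""
        if subset not in cache:
            sub = sorted(subset)
            tset = TranscriptSet(
                U=full_set.U[sub] if sub else np.zeros((0, graph.n_segments), dtype=np.int8),
                provenance=[provenance[i] for i in sub],
                edge_usage=full_set.edge_usage[sub]
                if sub
                else np.zeros((0, len(graph.edge_list)), dtype=np.int8),
            )
            w_mat, losses = quantifier.fit(tset)
            pair_term = hyper.w_pair * _support_pair_penalty(tset.U, observations.pair_counts)
            cache[subset] = (float(np.sum(losses)) + pair_term, w_mat)
        return cache[subset]

    def sparsity_of(subset) -> float:
        return float(sum(row_cost[i] for i in subset))

    def objective_of(subset: frozenset) -> float:
        return eval_subset(subset)[0] + sparsity_of(subset)

    n_cand = len(candidates)
    incumbent = _Incumbent()
    n_nodes = 0
    status = "optimal"

    if mode == "iterative":
        selected = frozenset()
        # annotated rows are seeded first (their discounted price still applies)
        for i, p in enumerate(provenance):
            if p == "known" and len(selected) < hyper.k_max:
                selected = selected | {i}
        current = objective_of(selected)
        eps = 1e-6
        while len(selected) < hyper.k_max:
            best_gain, best_idx = 0.0, None
            for i in range(n_cand):
                if i in selected:
                    continue
                trial = selected | {i}
                drop = (current - sparsity_of(selected)) - (
                    objective_of(trial) - sparsity_of(trial)
                )
                if drop - row_cost[i] * (1.0 - eps) > best_gain:
                    best_gain = drop - row_cost[i] * (1.0 - eps)
                    best_idx = i
            if best_idx is None:
                break
            selected = selected | {best_idx}
            current = objective_of(selected)
        incumbent.offer(current, selected, full_set.U[sorted(selected)])
        status = "approximate"
    elif mode == "exact":
        # best-first branch-and-bound over path-inclusion indicators
        def bound_of(included: frozenset, undecided: frozenset):
            loss_part, w_mat = eval_subset(included | undecided)
            return loss_part + sparsity_of(included), w_mat

        root_undecided = frozenset(range(n_cand))
        root_bound, _ = bound_of(frozenset(), root_undecided)
        counter = itertools.count()
        heap = [(root_bound, next(counter), frozenset(), root_undecided)]
        incumbent.offer(objective_of(frozenset()), frozenset(), np.zeros((0, graph.n_segments), np.int8))

        while heap:
            bound, _, included, undecided = heapq.heappop(heap)
            if bound > incumbent.objective + _Incumbent.TOL:
                continue
            n_nodes += 1
            if n_nodes > node_limit:
                status = "time-capped"
                break
            # score the decided-inclusion set exactly (also seeds incumbents)
            incumbent.offer(objective_of(included), included, full_set.U[sorted(included)])
            if not undecided:
                continue
            if len(included) >= hyper.k_max:
                continue
            # branch on the undecided candidate with the largest fitted
            # abundance in the relaxation (most load-bearing first)
            _, w_relax = eval_subset(included | undecided)
            order = sorted(included | undecided)
            load = {i: float(np.max(w_relax.W[j])) for j, i in enumerate(order) if i in undecided}
            pivot = max(load, key=lambda i: (load[i], -i))
            for child_inc, child_und in (
                (included | {pivot}, undecided - {pivot}),
                (included, undecided - {pivot}),
            ):
                child_bound, _ = bound_of(child_inc, child_und)
                if child_bound <= incumbent.objective + _Incumbent.TOL:
                    heapq.heappush(heap, (child_bound, next(counter), child_inc, child_und))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # assemble the result from the incumbent
    sub = sorted(incumbent.subset)
    tset = TranscriptSet(
        U=full_set.U[sub] if sub else np.zeros((0, graph.n_segments), dtype=np.int8),
        provenance=[provenance[i] for i in sub],
        edge_usage=full_set.edge_usage[sub]
        if sub
        else np.zeros((0, len(graph.edge_list)), dtype=np.int8),
    )
    _, w_mat = eval_subset(frozenset(sub))
    pair_term = hyper.w_pair * _support_pair_penalty(tset.U, observations.pair_counts)
    seg_loss, int_loss = quantifier.loss_components(tset, w_mat)
    breakdown = {
        "segment_loss": seg_loss,
        "intron_loss": int_loss,
        "pair_penalty": pair_term,
        "sparsity": sparsity_of(sub),
    }
    return SolveResult(
        transcripts=tset,
        abundances=w_mat,
        objective=float(incumbent.objective),
        status=status,
        breakdown=breakdown,
        n_nodes=n_nodes,
    )
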