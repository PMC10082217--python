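"""Locatability analysis and greedy observer selection.

Two nodes u, v are *indistinguishable* to the Pearson locator when their
observer-distance vectors are positively affinely related, d_v = k·d_u + c
with k > 0: the correlation of observer times with distances is invariant
under such a map, so the two candidates always receive the same score.
Distinguishability is analysed in the ideal (equal edge delay) regime, so
it depends only on topology and the observer set.

* ``locatability_index`` (x) counts unordered node pairs that *are*
  distinguishable under a given observer set; x = n(n−1)/2 means every pair
  can in principle be separated.
* ``q_index`` (q^p) is 1 minus the mean pairwise Pearson correlation among
  the per-node observer-distance columns; larger values mean more diverse
  distance signatures, which sharpens the contrast between source and
  non-source scores.
* ``greedy_observer_sequence`` adds observers one at a time, maximising x
  (ties broken by larger q^p, then by node identifier), and keeps
  maximising q^p once full distinguishability is reached, producing an
  ordered sequence whose every prefix is a usable observer set.
"""

from __future__ import annotations

from collections.abc import Hashable, Sequence
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .graphs import DistanceMatrix, Network, all_pairs_hop_distance

#: tolerance for the affine / correlation checks on integer distance vectors
_AFFINE_TOL = 1e-9


@dataclass
class ObserverDistanceMatrix:
    """k×n matrix of hop distances, one row per observer, one column per node."""

    observers: tuple[str, ...]
    nodes: tuple[str, ...]
    matrix: np.ndarray  # (k, n) integer hop counts

    def __post_init__(self) -> None:
        k, n = self.matrix.shape
        if k != len(self.observers) or n != len(self.nodes):
            raise ValueError("matrix shape inconsistent with labels")
        if np.any(self.matrix < 0):
            raise ValueError("distances must be non-negative")
        col = {v: j for j, v in enumerate(self.nodes)}
        for i, o in enumerate(self.observers):
            if self.matrix[i, col[o]] != 0:
                raise ValueError(f"observer {o!r} has non-zero self-distance")

    def column(self, node: Hashable) -> np.ndarray:
        return self.matrix[:, self.nodes.index(str(node))]


@dataclass
class LocatabilityReport:
    """Distinguishability summary for an (ordered) observer set."""

    x: int
    q: float
    observer_sequence: tuple[str, ...]
    x_steps: tuple[int, ...] = ()
    q_steps: tuple[float, ...] = ()
    n_nodes: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    @property
    def fully_locatable(self) -> bool:
        return self.n_nodes > 0 and self.x == self.n_pairs


def affinely_related(dv: Sequence[float], du: Sequence[float]) -> bool:
    """True iff dv = k·du + c elementwise for some real k > 0, c.

    Both-constant vectors are related (k arbitrary); exactly one constant is
    not (no positive slope can flatten a non-constant vector).  Otherwise k
    and c are fitted from two anchor coordinates with distinct du values and
    every coordinate is verified within a 1e-9 tolerance; the fitted slope
    must be positive.  Nodes whose observer-distance vectors satisfy this
    predicate are indistinguishable to the Pearson locator.
    """
    dv_a = np.asarray(dv, dtype=float)
    du_a = np.asarray(du, dtype=float)
    if dv_a.shape != du_a.shape:
        raise ValueError("length mismatch")
    if dv_a.size == 0:
        raise ValueError("vectors must be non-empty")
    du_const = np.ptp(du_a) == 0
    dv_const = np.ptp(dv_a) == 0
    if du_const and dv_const:
        return True
    if du_const or dv_const:
        return False
    j = int(np.nonzero(du_a != du_a[0])[0][0])
    k = (dv_a[j] - dv_a[0]) / (du_a[j] - du_a[0])
    if k <= 0:
        return False
    c = dv_a[0] - k * du_a[0]
    return bool(np.all(np.abs(dv_a - (k * du_a + c)) <= _AFFINE_TOL))


def observer_distance_matrix(
    net: Network,
    observers: Sequence[Hashable],
    dist: DistanceMatrix | None = None,
) -> ObserverDistanceMatrix:
    """Rows of the all-pairs distance matrix restricted to the observers."""
    obs = tuple(str(o) for o in observers)
    if not obs:
        raise ValueError("observer set must be non-empty")
    unknown = [o for o in obs if o not in net.index]
    if unknown:
        raise ValueError(f"unknown observer node(s): {unknown}")
    if dist is None:
        dist = all_pairs_hop_distance(net)
    rows = np.stack([dist.row(o) for o in obs])
    return ObserverDistanceMatrix(observers=obs, nodes=net.nodes, matrix=rows)


def _pair_relations(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise affine-relatedness and correlations of the columns.

    Returns ``(related, corr, const)`` where ``related[i, j]`` is True when
    columns i and j are positively affinely related, ``corr`` holds the
    normalised inner products of the centred columns (NaN when either is
    constant) and ``const`` flags constant columns.  Because distances are
    integers, correlation equal to 1 within a small tolerance is exactly the
    positive-affine condition.
    """
    m = np.asarray(matrix, dtype=float)
    centred = m - m.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centred, axis=0)
    const = norms == 0
    safe = np.where(const, 1.0, norms)
    z = centred / safe
    corr = z.T @ z
    corr[const, :] = np.nan
    corr[:, const] = np.nan
    related = corr > 1.0 - _AFFINE_TOL
    both_const = const[:, None] & const[None, :]
    related = np.where(both_const, True, related)
    related = np.where(np.isnan(corr) & ~both_const, False, related)
    return related.astype(bool), corr, const


def locatability_index(D: ObserverDistanceMatrix | np.ndarray) -> int:
    """Number of unordered node pairs distinguishable under the observers."""
    matrix = D.matrix if isinstance(D, ObserverDistanceMatrix) else np.asarray(D)
    n = matrix.shape[1]
    if n < 2:
        raise ValueError("need at least two nodes")
    related, _, _ = _pair_relations(matrix)
    iu = np.triu_indices(n, k=1)
    return int(np.count_nonzero(~related[iu]))


def q_index(D: ObserverDistanceMatrix | np.ndarray) -> float:
    """Measurement index q^p = 1 − mean pairwise column correlation.

    Column pairs involving a zero-variance vector have no defined
    correlation; they contribute 1 when the pair is affinely related (both
    constant) and 0 otherwise.  q lies in [0, 2]; larger values indicate
    more diverse observer-distance signatures.
    """
    matrix = D.matrix if isinstance(D, ObserverDistanceMatrix) else np.asarray(D)
    k, n = matrix.shape
    if k < 2:
        raise ValueError("need at least two observers")
    if n < 2:
        raise ValueError("need at least two nodes")
    related, corr, const = _pair_relations(matrix)
    contrib = np.where(np.isnan(corr), np.where(related, 1.0, 0.0), corr)
    iu = np.triu_indices(n, k=1)
    return float(1.0 - 2.0 / (n * (n - 1)) * contrib[iu].sum())


def _q_or_zero(matrix: np.ndarray) -> float:
    """q^p, defined as 0 for fewer than two observer rows (greedy bootstrap)."""
    if matrix.shape[0] < 2:
        return 0.0
    return q_index(matrix)


def greedy_observer_sequence(net: Network, budget: int) -> LocatabilityReport:
    """Greedy observer selection maximising the locatability index.

    Starting from the empty set, each step adds the node whose inclusion
    maximises x, breaking ties by the larger q^p and then by ascending node
    identifier.  Once every pair is distinguishable the remaining additions
    maximise q^p alone.  The report records (x, q) after every addition, so
    any prefix of the returned sequence is itself a greedy observer set.
    """
    n = net.n
    if not 2 <= budget <= n:
        raise ValueError("budget must be in [2, n]")
    dist = all_pairs_hop_distance(net)
    full = dist.matrix.astype(float)  # row i = distances from node i
    nodes = net.nodes
    chosen: list[int] = []
    x_steps: list[int] = []
    q_steps: list[float] = []
    for _ in range(budget):
        best: tuple[int, float, int] | None = None  # (x, q, candidate index)
        for cand in range(n):
            if cand in chosen:
                continue
            sub = full[chosen + [cand], :]
            x = locatability_index(sub)
            q = _q_or_zero(sub)
            if best is None or (x, q) > (best[0], best[1]):
                best = (x, q, cand)
        assert best is not None
        chosen.append(best[2])
        x_steps.append(best[0])
        q_steps.append(best[1])
    return LocatabilityReport(
        x=x_steps[-1],
        q=q_steps[-1],
        observer_sequence=tuple(nodes[i] for i in chosen),
        x_steps=tuple(x_steps),
        q_steps=tuple(q_steps),
        n_nodes=n,
    )


class GreedyObserverSelector(BaseEstimator):
    """Estimator interface to greedy locatability-driven observer selection.

    Parameters
    ----------
    budget
        Number of observers to select (2 ≤ budget ≤ n).

    Attributes
    ----------
    observers_ : tuple of str
        The ordered greedy sequence.
    report_ : LocatabilityReport
        Full per-step (x, q) trace.
    x_curve_, q_curve_ : ndarray
        Locatability index and q^p after each addition.
    """

    def __init__(self, budget: int = 2):
        self.budget = budget

    def fit(self, X: Network, y=None) -> "GreedyObserverSelector":
        self.report_ = greedy_observer_sequence(X, self.budget)
        self.observers_ = self.report_.observer_sequence
        self.x_curve_ = np.array(self.report_.x_steps)
        self.q_curve_ = np.array(self.report_.q_steps)
        return self

    def transform(self, r: int | None = None) -> tuple[str, ...]:
        """The first ``r`` selected observers (default: the whole sequence)."""
        if not hasattr(self, "observers_"):
            raise RuntimeError("selector is not fitted; call fit first")
        if r is None:
            return self.observers_
        if not 1 <= r <= len(self.observers_):
            raise ValueError("r out of range")
        return self.observers_[:r]
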