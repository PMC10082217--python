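"""ROC/AUC evaluation of source rankings, and the repeated-simulation loop.

A localization run labels the true sources positive and every other node
negative, sweeps a prefix of length ``l`` through the f-ranked candidate
list and traces (FPR(l), TPR(l)).  The area under that curve equals the
Mann–Whitney statistic

    AUC = [#(s, v) pairs with f_s > f_v  +  ½ · #ties] / (n_s · (n − n_s)),

over source/non-source pairs (s, v); tied scores receive half credit, which
makes the value independent of the arbitrary within-tie order.  AUC = 1
means every source outranks every non-source; 0.5 is chance level.
"""

from __future__ import annotations

import logging
from collections.abc import Hashable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dynamics import DelayModel, SIParams, simulate_diffusion, simulate_si
from .graphs import Network, all_pairs_hop_distance
from .locate import ObserverRecord, ScoreTable, score_all_nodes

logger = logging.getLogger(__name__)


@dataclass
class RocResult:
    """AUC plus the underlying ROC curve points."""

    auc: float
    curve: np.ndarray  # (k, 2) array of (FPR, TPR), from (0,0) to (1,1)

    def __post_init__(self) -> None:
        c = self.curve
        if not (np.all(np.diff(c[:, 0]) >= 0) and np.all(np.diff(c[:, 1]) >= 0)):
            raise ValueError("ROC curve coordinates must be non-decreasing")


def _source_set(sources: Sequence[Hashable]) -> set[str]:
    srcs = {str(s) for s in sources}
    if not srcs:
        raise ValueError("source set must be non-empty")
    return srcs


def tpr_at(ranking: Sequence[Hashable], sources: Sequence[Hashable], l: int) -> float:
    """True positive rate TP(l)/n_s after the top-l prefix of the ranking."""
    srcs = _source_set(sources)
    if not 0 <= l <= len(ranking):
        raise ValueError("prefix length out of range")
    top = {str(v) for v in ranking[:l]}
    return len(top & srcs) / len(srcs)


def fpr_at(ranking: Sequence[Hashable], sources: Sequence[Hashable], l: int) -> float:
    """False positive rate FP(l)/(n − n_s) after the top-l prefix."""
    srcs = _source_set(sources)
    n = len(ranking)
    if n <= len(srcs):
        raise ValueError("need at least one non-source node")
    if not 0 <= l <= n:
        raise ValueError("prefix length out of range")
    top = {str(v) for v in ranking[:l]}
    return len(top - srcs) / (n - len(srcs))


def roc_auc(scores: ScoreTable | dict, sources: Sequence[Hashable]) -> RocResult:
    """ROC AUC of f scores against the true source set.

    The curve is built at the distinct score thresholds (tied candidates
    move the curve diagonally in one segment), so its trapezoidal area
    coincides exactly with the half-credit Mann–Whitney statistic used for
    the reported ``auc``.
    """
    f = scores.f if isinstance(scores, ScoreTable) else dict(scores)
    srcs = _source_set(sources)
    nodes = sorted(f)
    unknown = srcs - set(nodes)
    if unknown:
        raise ValueError(f"source node(s) missing from scores: {sorted(unknown)}")
    n = len(nodes)
    ns = len(srcs)
    if n <= ns:
        raise ValueError("need at least one non-source node")
    values = np.array([f[v] for v in nodes], dtype=float)
    labels = np.array([v in srcs for v in nodes])

    # Mann–Whitney with midranks: ties between a source and a non-source
    # contribute half a concordant pair.
    ranks = rankdata(values)  # average ranks, ascending
    auc = (ranks[labels].sum() - ns * (ns + 1) / 2.0) / (ns * (n - ns))

    # step curve over distinct thresholds, descending score
    order = np.argsort(-values, kind="stable")
    sorted_vals = values[order]
    sorted_lab = labels[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        tp += int(sorted_lab[i:j].sum())
        fp += (j - i) - int(sorted_lab[i:j].sum())
        points.append((fp / (n - ns), tp / ns))
        i = j
    return RocResult(auc=float(auc), curve=np.array(points))


def step_curve_area(curve: np.ndarray) -> float:
    """Trapezoidal area under an ROC curve (independent of the AUC formula)."""
    return float(np.trapezoid(curve[:, 1], curve[:, 0]))


def _build_network(config, rng: np.random.Generator) -> Network:
    from .experiments import make_fixture_network
    from .graphs import generate_ba, generate_er, read_edge_list

    spec = config.network
    kind = spec["kind"]
    if kind == "er":
        return generate_er(spec["n"], spec["avg_degree"], rng)
    if kind == "ba":
        return generate_ba(spec["n"], spec["links_per_node"], rng)
    if kind == "fixture":
        return make_fixture_network(spec["name"])
    if kind == "file":
        return read_edge_list(spec["path"])
    raise ValueError(f"unknown network kind {kind!r}")


def _initial_times(config, sources: Sequence[str]) -> list[float]:
    """Source start times: first source at 0, later ones offset by Δ.

    The offset is Δ·u for diffusion (Δ in units of the mean edge delay) and
    Δ steps for SI, matching the staggered-start experiment design.
    """
    delta = float(getattr(config, "delta", 0.0))
    dyn = config.dynamics
    if dyn["kind"] == "diffusion":
        off = delta * float(dyn.get("u", 2.0))
    else:
        off = float(int(delta))
    return [0.0 if i == 0 else off for i in range(len(sources))]


def _simulate(config, net: Network, sources, init, rng: np.random.Generator):
    dyn = config.dynamics
    if dyn["kind"] == "diffusion":
        model = DelayModel(u=float(dyn.get("u", 2.0)), sigma=float(dyn.get("sigma", 0.25)))
        return simulate_diffusion(net, sources, init, model, seed=rng)
    if dyn["kind"] == "si":
        params = SIParams(lam=float(dyn.get("lam", 0.5)))
        return simulate_si(
            net, sources, init, params, seed=rng,
            max_steps=int(dyn.get("max_steps", 10_000)),
        )
    raise ValueError(f"unknown dynamics kind {dyn['kind']!r}")


def mean_auc_experiment(config) -> pd.DataFrame:
    """Repeated simulate–locate–evaluate runs under one configuration.

    Per repetition: draw (or reuse) the network, draw ``n_sources`` sources
    uniformly at random, draw observers (random fraction, or a prefix of
    the greedy locatability sequence), simulate the configured dynamics,
    score every node and compute the ROC AUC against the true sources.
    Observers and sources are drawn independently; overlap is permitted.

    Returns a DataFrame with one row per repetition; the mean and standard
    deviation of the AUC are stored in ``result.attrs``.  Per-repetition
    randomness derives from ``SeedSequence(seed, spawn_key=(rep,))`` so runs
    are independent and reproducible.
    """
    reps = int(config.repetitions)
    if reps < 1:
        raise ValueError("repetitions must be >= 1")
    fixed_net: Network | None = None
    greedy_seq: list[str] | None = None
    if not config.regenerate_network:
        fixed_net = _build_network(
            config, np.random.default_rng(np.random.SeedSequence(config.seed))
        )
    rows = []
    for rep in range(reps):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(rep,))
        )
        net = fixed_net if fixed_net is not None else _build_network(config, rng)
        nodes = list(net.nodes)
        ns = int(config.n_sources)
        if not 1 <= ns < net.n:
            raise ValueError("n_sources must be in [1, n)")
        sources = list(rng.choice(nodes, size=ns, replace=False))
        init = _initial_times(config, sources)

        r = config.observer_count
        if r is None:
            r = int(round(config.observer_fraction * net.n))
        if r < 3:
            raise ValueError(
                f"observer strategy yields r={r} < 3; increase the fraction"
            )
        if config.observer_strategy == "random":
            observers = list(rng.choice(nodes, size=r, replace=False))
        elif config.observer_strategy == "greedy":
            from .locatability import greedy_observer_sequence

            if fixed_net is not None:
                if greedy_seq is None:
                    greedy_seq = list(
                        greedy_observer_sequence(net, min(net.n, max(r, 2))).observer_sequence
                    )
                observers = greedy_seq[:r]
            else:
                observers = list(
                    greedy_observer_sequence(net, r).observer_sequence
                )
        else:
            raise ValueError(f"unknown observer strategy {config.observer_strategy!r}")

        result = _simulate(config, net, sources, init, rng)
        record = ObserverRecord(observers, result.times_for(observers))
        dist = all_pairs_hop_distance(net)
        table = score_all_nodes(net, record, dist=dist)
        auc = roc_auc(table, sources).auc
        rows.append(
            {
                "rep": rep,
                "auc": auc,
                "n": net.n,
                "m": net.m,
                "n_sources": ns,
                "r": len(observers),
            }
        )
        logger.debug("rep %d/%d auc=%.4f", rep + 1, reps, auc)
    df = pd.DataFrame(rows)
    df.attrs["mean_auc"] = float(df["auc"].mean())
    df.attrs["std_auc"] = float(df["auc"].std(ddof=1)) if reps > 1 else 0.0
    df.attrs["config"] = config.to_dict() if hasattr(config, "to_dict") else {}
    return df
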