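"""Forward propagation simulators producing per-node informed times.

Two spreading processes are supported:

* **Diffusion** — every edge carries an independent Gaussian-distributed
  delay; a newly informed node forwards the message to all neighbours, so a
  node's informed time is its earliest arrival over delay-weighted paths from
  any source.
* **SI epidemics** — discrete synchronous steps; an uninformed node with
  ``c`` informed neighbours becomes informed in one step with probability
  ``1 − (1 − λ)^c`` and then stays informed forever.

Both return a :class:`PropagationResult` mapping every node to the first
time it holds the message, the quantity the source locator consumes.
"""

from __future__ import annotations

import heapq
import json
from collections.abc import Hashable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graphs import Network, _as_rng


@dataclass(frozen=True)
class DelayModel:
    """Gaussian edge-delay distribution N(u, sigma^2) for diffusion.

    ``u`` is the mean delay per edge (time units, positive); ``sigma`` its
    standard deviation (non-negative).  Draws are resampled until strictly
    positive so that arrival times always advance along a path.
    """

    u: float
    sigma: float

    def __post_init__(self) -> None:
        if self.u <= 0:
            raise ValueError("mean delay u must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class SIParams:
    """Susceptible–infected parameters: uniform informed rate per contact."""

    lam: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("informed rate lam must lie in [0, 1]")


@dataclass
class PropagationResult:
    """Informed time of every node plus the ground-truth source description."""

    informed_time: dict[str, float]
    sources: tuple[str, ...]
    initial_times: dict[str, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.sources:
            if self.informed_time[s] != self.initial_times[s]:
                raise ValueError(f"source {s!r} informed time != its initial time")
        t0 = min(self.initial_times.values())
        if any(t < t0 for t in self.informed_time.values()):
            raise ValueError("informed time earlier than the first initial time")

    def times_for(self, nodes: Sequence[Hashable]) -> np.ndarray:
        return np.array([self.informed_time[str(v)] for v in nodes], dtype=float)

    def to_csv(self, path: str | Path) -> None:
        """Two-column CSV (node, informed_time) with a JSON header comment."""
        header = {
            "sources": list(self.sources),
            "initial_times": self.initial_times,
            **self.meta,
        }
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# {json.dumps(header, sort_keys=True)}\n")
            fh.write("node,informed_time\n")
            for v in sorted(self.informed_time):
                fh.write(f"{v},{self.informed_time[v]!r}\n")


def _normalize_sources(
    net: Network,
    sources: Sequence[Hashable],
    initial_times: Mapping[Hashable, float] | Sequence[float] | float | None,
) -> tuple[tuple[str, ...], dict[str, float]]:
    srcs = tuple(str(s) for s in sources)
    if not srcs:
        raise ValueError("source set must be non-empty")
    if len(set(srcs)) != len(srcs):
        raise ValueError("duplicate source nodes")
    unknown = [s for s in srcs if s not in net.index]
    if unknown:
        raise ValueError(f"unknown source node(s): {unknown}")
    if initial_times is None:
        init = {s: 0.0 for s in srcs}
    elif isinstance(initial_times, Mapping):
        init = {str(k): float(v) for k, v in initial_times.items()}
        if set(init) != set(srcs):
            raise ValueError("initial_times keys must match the source set")
    elif isinstance(initial_times, (int, float)):
        init = {s: float(initial_times) for s in srcs}
    else:
        if len(initial_times) != len(srcs):
            raise ValueError("initial_times length must match sources")
        init = {s: float(t) for s, t in zip(srcs, initial_times)}
    return srcs, init


def sample_edge_delays(
    net: Network,
    model: DelayModel,
    seed: int | np.random.Generator,
) -> dict[tuple[str, str], float]:
    """One positive Gaussian delay per undirected edge.

    A single value is drawn for each edge (shared by both directions) from
    N(u, sigma^2), resampled until strictly positive.  Keys are the sorted
    (u, v) pairs of :attr:`Network.edges`, so the mapping is deterministic
    given the seed.
    """
    rng = _as_rng(seed)
    delays: dict[tuple[str, str], float] = {}
    for edge in net.edges:
        d = rng.normal(model.u, model.sigma)
        while d <= 0:
            d = rng.normal(model.u, model.sigma)
        delays[edge] = float(d)
    return delays


def simulate_diffusion(
    net: Network,
    sources: Sequence[Hashable],
    initial_times: Mapping[Hashable, float] | Sequence[float] | float | None,
    model: DelayModel,
    seed: int | np.random.Generator | None = None,
    delays: Mapping[tuple[str, str], float] | None = None,
) -> PropagationResult:
    """Earliest-arrival diffusion with Gaussian edge delays.

    Each source ``s`` starts spreading at its initial time; a node newly
    informed at ``t`` delivers to each uninformed neighbour at ``t + θ``
    where ``θ`` is the sampled delay of the connecting edge.  The resulting
    informed time equals the minimum over sources of (initial time + least
    total delay along any path), computed by a Dijkstra-style
    earliest-arrival sweep seeded with every source.

    ``delays`` may inject a pre-sampled delay mapping (keys as in
    :func:`sample_edge_delays`); otherwise fresh delays are drawn from
    ``seed``.
    """
    if not net.is_connected():
        raise ValueError("network must be connected")
    srcs, init = _normalize_sources(net, sources, initial_times)
    if delays is None:
        delays = sample_edge_delays(net, model, _as_rng(seed))

    def edge_delay(a: str, b: str) -> float:
        return delays[(a, b) if a < b else (b, a)]

    arrival: dict[str, float] = {}
    heap: list[tuple[float, str]] = [(t, s) for s, t in sorted(init.items())]
    heapq.heapify(heap)
    while heap:
        t, v = heapq.heappop(heap)
        if v in arrival:
            continue
        arrival[v] = t
        for w in net.neighbors(v):
            if w not in arrival:
                heapq.heappush(heap, (t + edge_delay(v, w), w))
    # A source's informed time is by definition the time it began spreading,
    # even when another source's wave passes through it earlier.
    for s, t0 in init.items():
        arrival[s] = t0
    return PropagationResult(
        informed_time=arrival,
        sources=srcs,
        initial_times=init,
        meta={"dynamics": "diffusion", "u": model.u, "sigma": model.sigma},
    )


def infection_probability(params: SIParams, informed_neighbor_count: int) -> float:
    """Per-step probability 1 − (1 − λ)^c of catching the message.

    ``c`` is the number of informed neighbours at the start of the step; each
    contact independently transmits with rate λ.
    """
    if informed_neighbor_count < 0:
        raise ValueError("informed neighbour count must be non-negative")
    return 1.0 - (1.0 - params.lam) ** informed_neighbor_count


def simulate_si(
    net: Network,
    sources: Sequence[Hashable],
    initial_times: Mapping[Hashable, float] | Sequence[float] | float | None,
    params: SIParams,
    seed: int | np.random.Generator | None = None,
    max_steps: int = 10_000,
) -> PropagationResult:
    """Synchronous discrete-time SI epidemic until every node is informed.

    At integer time ``t`` the informed set is frozen; each uninformed node
    with ``c > 0`` informed neighbours becomes informed at ``t + 1`` with
    probability :func:`infection_probability`.  A source stays inert until
    its own (integer) initial time, which supports staggered-start
    experiments.  Raises if the epidemic has not covered the network within
    ``max_steps`` steps, naming the uninformed nodes.
    """
    if params.lam <= 0:
        raise ValueError("lam must be positive for the epidemic to terminate")
    if not net.is_connected():
        raise ValueError("network must be connected")
    srcs, init = _normalize_sources(net, sources, initial_times)
    for s, t in init.items():
        if t != int(t):
            raise ValueError(f"SI initial time for {s!r} must be an integer")
    rng = _as_rng(seed)
    nodes = net.nodes
    informed: dict[str, float] = {}
    t = int(min(init.values()))
    for s, t0 in init.items():
        if t0 == t:
            informed[s] = float(t)
    for _ in range(max_steps):
        if len(informed) == len(nodes):
            break
        newly: list[str] = []
        for v in nodes:
            if v in informed:
                continue
            c = sum(1 for w in net.neighbors(v) if w in informed)
            if c and rng.random() < infection_probability(params, c):
                newly.append(v)
        t += 1
        for v in newly:
            informed[v] = float(t)
        # late sources activate at their own initial time (if not already
        # reached by the epidemic)
        for s, t0 in init.items():
            if int(t0) == t and s not in informed:
                informed[s] = float(t)
    else:
        missing = sorted(set(nodes) - set(informed))
        raise RuntimeError(
            f"SI epidemic did not inform {len(missing)} node(s) within "
            f"{max_steps} steps: {missing[:10]}"
        )
    # a source's recorded informed time is the time it began spreading
    for s, t0 in init.items():
        informed[s] = float(t0)
    return PropagationResult(
        informed_time=informed,
        sources=srcs,
        initial_times=init,
        meta={"dynamics": "si", "lam": params.lam},
    )
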