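"""How duplication events move a regulator's average nearest neighbor degree.

The simulation tracks one focal regulator in a small hypothetical network —
two degree-5 hubs joined by an edge, each carrying four degree-1 targets (10
nodes, 9 edges) — and applies elementary evolutionary rewrites:

* ``target_duplication`` (and ``pervasive_edge``, modeled identically): the
  focal regulator gains one new degree-1 neighbor, so its degree k rises while
  the neighbor-degree sum S rises by only 1 and K_nn = S/k decays smoothly
  toward 1.
* ``regulator_duplication``: the focal regulator is copied with all its links
  (no focal–duplicate edge by default), so every neighbor's degree increments
  and K_nn jumps by exactly +1.
* ``other_regulator_duplication``: a different hub (with its link to the focal
  node) is copied, raising the focal K_nn through its neighbors.

Each state keeps (k, S, K_nn) incrementally and the trajectory re-verifies
K_nn against brute-force recomputation from the graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .grn_io import GeneNetwork, ROLE_REGULATOR, ROLE_TARGET

EVENT_KINDS = (
    "target_duplication",
    "regulator_duplication",
    "other_regulator_duplication",
    "pervasive_edge",
)

FOCAL = "R1"
OTHER_HUB = "R2"


@dataclass(frozen=True)
class EvolutionEvent:
    kind: str
    focal: str = FOCAL

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; one of {EVENT_KINDS}")


@dataclass(frozen=True)
class TrajectoryState:
    step: int
    event: str
    degree: int
    neighbor_degree_sum: int
    knn: float


@dataclass
class SimulationTrajectory:
    focal: str
    states: list[TrajectoryState] = field(default_factory=list)

    @property
    def knn_series(self) -> list[float]:
        return [s.knn for s in self.states]

    @property
    def degree_series(self) -> list[int]:
        return [s.degree for s in self.states]

    def degree_vs_knn(self) -> list[tuple[int, float]]:
        """(degree, K_nn) pairs for plotting against the identity line."""
        return [(s.degree, s.knn) for s in self.states]

    def to_rows(self) -> list[dict]:
        return [
            {
                "step": s.step,
                "event": s.event,
                "degree": s.degree,
                "neighbor_degree_sum": s.neighbor_degree_sum,
                "knn": s.knn,
            }
            for s in self.states
        ]


def initial_network() -> GeneNetwork:
    """The 10-node / 9-edge two-hub starting network.

    Both hubs have degree 5 (four private degree-1 targets plus the hub–hub
    edge); ``R1`` is the focal regulator whose K_nn is tracked, starting at
    (4·1 + 5)/5 = 1.8.
    """
    g = nx.Graph()
    g.add_edge(FOCAL, OTHER_HUB)
    for i in range(1, 5):
        g.add_edge(FOCAL, f"T{i}")
        g.add_edge(OTHER_HUB, f"U{i}")
    roles = {FOCAL: ROLE_REGULATOR, OTHER_HUB: ROLE_REGULATOR}
    for n in g.nodes:
        roles.setdefault(n, ROLE_TARGET)
    return GeneNetwork(graph=g, roles=roles, name="two-hub-fixture")


def focal_state(graph: nx.Graph, focal: str = FOCAL) -> tuple[int, int, float]:
    """(k, S, K_nn) of the focal node recomputed from scratch."""
    k = graph.degree(focal)
    if k == 0:
        raise ValueError(f"focal node {focal!r} is isolated; K_nn undefined")
    s = sum(graph.degree(j) for j in graph.neighbors(focal))
    return k, s, s / k


def apply_event(
    network: GeneNetwork,
    event: EvolutionEvent,
    *,
    link_duplicate: bool = False,
) -> GeneNetwork:
    """Apply one rewrite in place and return the network.

    ``link_duplicate=True`` additionally joins the focal regulator to its own
    duplicate during ``regulator_duplication`` (the drawn topology is
    ambiguous on this point; the default keeps the clean K_nn → K_nn + 1 law).
    """
    g = network.graph
    focal = event.focal
    if focal not in g:
        raise ValueError(f"focal regulator {focal!r} not in network")
    fresh = _name_factory(g)
    if event.kind in ("target_duplication", "pervasive_edge"):
        new = fresh("t")
        g.add_edge(focal, new)
        network.roles[new] = ROLE_TARGET
    elif event.kind == "regulator_duplication":
        new = fresh("r")
        neighbors = list(g.neighbors(focal))
        for nb in neighbors:
            g.add_edge(new, nb)
        if link_duplicate:
            g.add_edge(new, focal)
        network.roles[new] = ROLE_REGULATOR
    elif event.kind == "other_regulator_duplication":
        other = _pick_other_hub(g, focal)
        new = fresh("o")
        for nb in list(g.neighbors(other)):
            g.add_edge(new, nb)
        network.roles[new] = ROLE_REGULATOR
    else:  # pragma: no cover - EvolutionEvent validates kinds
        raise ValueError(f"unknown event kind {event.kind!r}")
    return network


def _pick_other_hub(g: nx.Graph, focal: str) -> str:
    """The highest-degree non-focal neighbor-bearing node (ties: name order)."""
    candidates = [n for n in g.nodes if n != focal and g.degree(n) > 1]
    if not candidates:
        candidates = [n for n in g.nodes if n != focal]
    if not candidates:
        raise ValueError("no non-focal node available to duplicate")
    return max(candidates, key=lambda n: (g.degree(n), n))


def _name_factory(g: nx.Graph):
    counter = [g.number_of_nodes()]

    def fresh(prefix: str) -> str:
        while True:
            counter[0] += 1
            name = f"new_{prefix}{counter[0]}"
            if name not in g:
                return name

    return fresh


def parse_event_spec(spec: str, focal: str = FOCAL) -> list[EvolutionEvent]:
    """Parse ``"target_dup:100,regulator_dup:10"`` into an event sequence.

    Accepted kinds (with shorthands): ``target_dup``, ``regulator_dup``,
    ``other_regulator_dup``, ``pervasive`` or any full kind name.
    """
    alias = {
        "target_dup": "target_duplication",
        "regulator_dup": "regulator_duplication",
        "other_regulator_dup": "other_regulator_duplication",
        "pervasive": "pervasive_edge",
    }
    events: list[EvolutionEvent] = []
    for part in spec.split(","):
        part = part.strip()
        if not part:
            continue
        kind, _, times = part.partition(":")
        kind = alias.get(kind, kind)
        events.extend(
            EvolutionEvent(kind=kind, focal=focal) for _ in range(int(times or 1))
        )
    return events


def knn_trajectory(
    events: list[EvolutionEvent] | str,
    network: GeneNetwork | None = None,
    *,
    link_duplicate: bool = False,
    verify: bool = True,
) -> SimulationTrajectory:
    """Apply events in order, recording (k, S, K_nn) at every state.

    State 0 is the untouched network.  With ``verify`` (default) the
    incremental bookkeeping is cross-checked against brute-force
    recomputation from the graph at every step.
    """
    if isinstance(events, str):
        events = parse_event_spec(events)
    if not events:
        raise ValueError("need at least one event")
    net = network if network is not None else initial_network()
    focal = events[0].focal
    traj = SimulationTrajectory(focal=focal)
    k, s, knn = focal_state(net.graph, focal)
    traj.states.append(TrajectoryState(0, "initial", k, s, knn))
    for step, ev in enumerate(events, start=1):
        apply_event(net, ev, link_duplicate=link_duplicate)
        k, s, knn = focal_state(net.graph, ev.focal)
        if verify:
            assert abs(knn - s / k) == 0.0  # K_nn == S/k by construction
        traj.states.append(TrajectoryState(step, ev.kind, k, s, knn))
    return traj


def trajectory_to_csv(traj: SimulationTrajectory, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(
            fh, fieldnames=["step", "event", "degree", "neighbor_degree_sum", "knn"]
        )
        w.writeheader()
        w.writerows(traj.to_rows())
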