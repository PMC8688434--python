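"""Duplication–divergence generator of labeled synthetic GRNs.

Real regulatory networks are scale-free, their regulators are predominantly
hubs, their targets predominantly degree-1 genes, and a small minority of
genes act in both roles.  The generator reproduces that structure by the
evolutionary process the analysis itself argues for: growth by gene
duplication with partial edge inheritance ("maintenance of ancient
interactions").  Starting from a small bipartite regulator→target motif, each
growth step either

* duplicates a random target (the copy inherits each regulator link with
  retention probability ρ, keeping at least one),
* duplicates a random regulator (its target links inherited likewise), or
* adds one fresh regulator→target edge (pervasive-transcription-like rewiring),

and finally a ``dual_role_fraction`` of targets is promoted to dual-role
genes by giving each one outgoing regulation.  Every draw flows from the
config seed, so equal seeds give identical networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import knn_evolution
from .grn_io import GeneNetwork, RegulatoryInteraction, build_network


@dataclass(frozen=True)
class SyntheticGRNConfig:
    """Growth parameters of the duplication–divergence generator.

    Defaults give networks of a few thousand genes with a regulator:target
    ratio of roughly 1:5 and ~5% dual-role genes, the order observed in
    curated species GRNs.
    """

    n_initial_regulators: int = 5
    n_initial_targets: int = 10
    n_growth_steps: int = 3000
    p_target_dup: float = 0.65
    p_regulator_dup: float = 0.10
    p_new_edge: float = 0.25
    edge_retention: float = 0.50
    dual_role_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        probs = (self.p_target_dup, self.p_regulator_dup, self.p_new_edge)
        if any(p < 0 for p in probs) or sum(probs) > 1 + 1e-9:
            raise ValueError("event probabilities must be non-negative and sum to <= 1")
        if not 0 < self.edge_retention <= 1:
            raise ValueError("edge_retention must be in (0, 1]")
        if not 0 <= self.dual_role_fraction < 1:
            raise ValueError("dual_role_fraction must be in [0, 1)")
        if self.n_initial_regulators < 1 or self.n_initial_targets < 1:
            raise ValueError("need at least one initial regulator and target")
        if self.n_growth_steps < 0:
            raise ValueError("n_growth_steps must be >= 0")


def generate_interactions(
    config: SyntheticGRNConfig,
) -> list[RegulatoryInteraction]:
    """Directed regulator→target interaction list of one grown network."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    regulators: list[str] = [f"reg{i}" for i in range(config.n_initial_regulators)]
    targets: list[str] = [f"tar{i}" for i in range(config.n_initial_targets)]
    # regulators-of each target; targets-of each regulator
    regs_of: dict[str, set[str]] = {t: set() for t in targets}
    tars_of: dict[str, set[str]] = {r: set() for r in regulators}

    def add_edge(r: str, t: str) -> None:
        regs_of[t].add(r)
        tars_of[r].add(t)

    # seed motif: every regulator gets a target (round-robin), rest random
    for i, t in enumerate(targets):
        r = regulators[i % len(regulators)] if i < len(regulators) else regulators[
            rng.integers(len(regulators))
        ]
        add_edge(r, t)

    p = np.array([config.p_target_dup, config.p_regulator_dup, config.p_new_edge])
    p_none = max(0.0, 1.0 - p.sum())
    probs = np.append(p, p_none)
    for step in range(config.n_growth_steps):
        ev = rng.choice(4, p=probs)
        if ev == 0:  # target duplication
            t = targets[rng.integers(len(targets))]
            parents = sorted(regs_of[t])
            keep = [r for r in parents if rng.random() < config.edge_retention]
            if not keep:
                keep = [parents[rng.integers(len(parents))]]
            new = f"tar{len(targets)}"
            targets.append(new)
            regs_of[new] = set()
            for r in keep:
                add_edge(r, new)
        elif ev == 1:  # regulator duplication
            r = regulators[rng.integers(len(regulators))]
            own = sorted(tars_of[r])
            keep = [t for t in own if rng.random() < config.edge_retention]
            if not keep:
                keep = [own[rng.integers(len(own))]]
            new = f"reg{len(regulators)}"
            regulators.append(new)
            tars_of[new] = set()
            for t in keep:
                add_edge(new, t)
        elif ev == 2:  # fresh regulator→target edge
            r = regulators[rng.integers(len(regulators))]
            t = targets[rng.integers(len(targets))]
            if t not in tars_of[r]:
                add_edge(r, t)

    # promote a minority of targets to dual-role genes
    n_dual = int(config.dual_role_fraction * len(targets))
    if n_dual > 0:
        promoted = rng.choice(len(targets), size=n_dual, replace=False)
        for ix in promoted:
            g = targets[ix]
            other = targets[int(rng.integers(len(targets)))]
            while other == g and len(targets) > 1:
                other = targets[int(rng.integers(len(targets)))]
            tars_of.setdefault(g, set())
            if other != g:
                add_edge(g, other)

    interactions = [
        RegulatoryInteraction(r, t)
        for r in sorted(tars_of)
        for t in sorted(tars_of[r])
    ]
    return interactions


def generate_synthetic_grn(config: SyntheticGRNConfig | None = None) -> GeneNetwork:
    """Grow one network and assemble it with true roles (regulator/target/both)."""
    config = config or SyntheticGRNConfig()
    interactions = generate_interactions(config)
    name = f"synthetic-dd-seed{config.seed}"
    return build_network(interactions, name=name)


def generate_worked_fixture() -> GeneNetwork:
    """The shared 10-node / 9-edge two-hub fixture (focal K_nn = 1.8)."""
    return knn_evolution.initial_network()
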