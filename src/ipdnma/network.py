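"""Treatment network structure: basic parameters, consistency map, loops.

A network of q+1 treatments is parameterised by q *basic* contrasts, one per
non-reference treatment, each measured against the designated reference.  Any
other contrast a -> b is obtained through the consistency equations as
beta_b - beta_a (with beta_reference identically 0).  Treatment loops — cycles
in the comparison graph — are where direct and indirect evidence can disagree,
and are the units to which inconsistency parameters attach.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .data import IPDDataset

__all__ = ["NetworkSpec", "build_network", "network_edge_table"]


class DisconnectedNetworkError(ValueError):
    """The comparison graph is not connected."""


@dataclass(frozen=True)
class NetworkSpec:
    """Treatments, reference, basic contrasts, consistency map and loops."""

    treatments: tuple[str, ...]
    reference: str
    basic_parameters: tuple[tuple[str, str], ...]  # (reference, treatment)
    loops: tuple[tuple[str, ...], ...]
    edges: tuple[tuple[str, str], ...]

    @property
    def n_basic(self) -> int:
        return len(self.basic_parameters)

    def basic_index(self, treatment: str) -> int | None:
        """Index of the basic parameter for ``treatment``; None for reference."""
        if treatment == self.reference:
            return None
        for i, (_, t) in enumerate(self.basic_parameters):
            if t == treatment:
                return i
        raise KeyError(f"treatment {treatment!r} not in network")

    def contrast_coefficients(self, a: str, b: str) -> dict[int, float]:
        """Consistency-map coefficients of contrast a -> b on the basic scale.

        Returns a sparse map {basic index: coefficient} such that
        logHR(a -> b) = sum coef * beta_basic.  For example in an {A, B, C}
        network with reference A, contrast B -> C is beta_C - beta_B.
        """
        coefs: dict[int, float] = {}
        for treat, sign in ((b, +1.0), (a, -1.0)):
            idx = self.basic_index(treat)
            if idx is not None:
                coefs[idx] = coefs.get(idx, 0.0) + sign
        return {k: v for k, v in coefs.items() if v != 0.0}


def build_network(dataset: IPDDataset, reference: str) -> NetworkSpec:
    """Derive the network structure from the trials in a dataset.

    The comparison graph has one node per treatment and an edge between every
    pair of treatments compared head-to-head within at least one trial.
    Connectivity is required; loops are the independent cycles of the graph
    (cycle basis), each reported as a treatment tuple.
    """
    present = set(dataset.table["treatment"])
    treatments = [t for t in dataset.treatments if t in present]
    if reference not in treatments:
        raise ValueError(f"reference treatment {reference!r} not present in data")

    graph = nx.Graph()
    graph.add_nodes_from(treatments)
    for _, arms in dataset.trials.items():
        arms = sorted(arms, key=treatments.index)
        for i in range(len(arms)):
            for j in range(i + 1, len(arms)):
                graph.add_edge(arms[i], arms[j])

    if not nx.is_connected(graph):
        comps = [sorted(c, key=treatments.index) for c in nx.connected_components(graph)]
        raise DisconnectedNetworkError(
            f"treatment network is disconnected; components: {comps}"
        )

    basic = tuple((reference, t) for t in treatments if t != reference)
    loops = tuple(
        tuple(sorted(cycle, key=treatments.index))
        for cycle in nx.cycle_basis(graph)
    )
    order = {t: i for i, t in enumerate(treatments)}
    edges = tuple(
        tuple(sorted(e, key=order.get)) for e in sorted(graph.edges, key=lambda e: sorted(order[t] for t in e))
    )
    return NetworkSpec(
        treatments=tuple(treatments),
        reference=reference,
        basic_parameters=basic,
        loops=loops,
        edges=edges,
    )


def network_edge_table(dataset: IPDDataset, network: NetworkSpec) -> pd.DataFrame:
    """Edge-list summary (treatA, treatB, n_trials, n_patients) for plotting."""
    rows = []
    trials = dataset.trials
    for a, b in network.edges:
        trial_ids = [t for t, arms in trials.items() if a in arms and b in arms]
        sub = dataset.table[
            dataset.table["trial"].isin(trial_ids)
            & dataset.table["treatment"].isin([a, b])
        ]
        rows.append(
            {"treatA": a, "treatB": b, "n_trials": len(trial_ids), "n_patients": len(sub)}
        )
    return pd.DataFrame(rows, columns=["treatA", "treatB", "n_trials", "n_patients"])
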