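"""Build weighted social networks from flock co-membership.

Edges are weighted by the simple ratio index (SRI): for a dyad (i, j) the
proportion of gathering events containing either bird in which both were
present,

    a_ij = n(i and j together) / n(events containing i or j),

which ranges from 0 (never in the same flock) to 1 (always).  One undirected
network is built per site x sampling weekend; no cross-site or cross-week
merging is done, so each network captures social structure at the small
spatiotemporal scale on which behavioural transmission plausibly acts.

Individuals observed in the period but never co-occurring with anyone are
retained as isolates (they can still acquire the behaviour asocially);
exclusions are applied at the whole-network level only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = [
    "SocialNetwork",
    "group_events",
    "build_sri_network",
    "build_networks",
    "filter_networks",
    "write_network_csv",
    "read_network_csv",
    "write_networks",
    "read_networks",
]

MIN_NETWORK_SIZE = 10


@dataclass
class SocialNetwork:
    """Undirected weighted network for one site x weekend.

    ``weights`` is the symmetric SRI matrix (zero diagonal, entries in
    [0, 1]) in the order of ``nodes``.
    """

    network_id: str
    location_id: str
    year: int
    week: int
    nodes: list
    weights: np.ndarray

    def __post_init__(self):
        self.nodes = list(self.nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise InputError(f"{self.network_id}: duplicate node identifiers")
        w = np.asarray(self.weights, dtype=float)
        n = len(self.nodes)
        if w.shape != (n, n):
            raise InputError(
                f"{self.network_id}: weight matrix {w.shape} does not match "
                f"{n} nodes"
            )
        if not np.allclose(w, w.T, atol=1e-12):
            raise InputError(f"{self.network_id}: weight matrix not symmetric")
        if np.any(np.diag(w) != 0):
            raise InputError(f"{self.network_id}: nonzero diagonal")
        if w.size and (w.min() < 0 or w.max() > 1 + 1e-12):
            raise InputError(f"{self.network_id}: weights outside [0, 1]")
        self.weights = w

    @property
    def size(self) -> int:
        return len(self.nodes)

    def strength(self) -> np.ndarray:
        return self.weights.sum(axis=1)


def _network_id(location_id, year, week) -> str:
    return f"{location_id}_y{year}_w{int(week):02d}"


def group_events(events: Iterable) -> dict:
    """Group events by (location_id, year, week), sorted keys."""
    groups: dict = {}
    for e in events:
        groups.setdefault((e.location_id, e.year, e.week), []).append(e)
    return dict(sorted(groups.items()))


def build_sri_network(events: Sequence) -> SocialNetwork:
    """Build the SRI network for the events of a single site x weekend.

    a_ij = (events containing both i and j) / (events containing i or j).
    """
    if not events:
        raise InputError("build_sri_network: no events")
    labels = {(e.location_id, e.year, e.week) for e in events}
    if len(labels) != 1:
        raise InputError(
            f"build_sri_network: events span multiple site/periods: {sorted(labels)}"
        )
    (location_id, year, week), = labels

    nodes = sorted(set().union(*(e.members for e in events)))
    index = {ind: k for k, ind in enumerate(nodes)}
    n = len(nodes)
    incidence = np.zeros((len(events), n), dtype=np.int64)
    for row, e in enumerate(events):
        for ind in e.members:
            incidence[row, index[ind]] = 1

    both = incidence.T @ incidence           # both[i, j] = events with i and j
    counts = np.diag(both).astype(float)     # events containing i
    either = counts[:, None] + counts[None, :] - both
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = np.where(either > 0, both / either, 0.0)
    np.fill_diagonal(weights, 0.0)

    return SocialNetwork(
        network_id=_network_id(location_id, year, week),
        location_id=location_id,
        year=int(year),
        week=int(week),
        nodes=nodes,
        weights=weights,
    )


def build_networks(events: Iterable) -> list:
    """One SRI network per site x weekend present in the event table."""
    return [build_sri_network(evs) for evs in group_events(events).values()]


def filter_networks(
    networks: Sequence,
    metrics_fn: Callable | None = None,
    min_size: int = MIN_NETWORK_SIZE,
) -> tuple:
    """Apply the network-level exclusion rules.

    Networks with fewer than ``min_size`` individuals are dropped, as are
    networks in which any of the three node metrics (strength, weighted
    clustering, weighted betweenness) shows no variation across nodes -- on
    such networks a rank correlation with acquisition order is undefined.

    Returns ``(retained, exclusion_log)`` where the log is a list of
    ``(network_id, reason)`` pairs.
    """
    if metrics_fn is None:
        from .metrics import node_metrics

        metrics_fn = node_metrics

    retained, log = [], []
    for net in networks:
        if net.size < min_size:
            log.append((net.network_id, f"fewer than {min_size} individuals"))
            continue
        table = metrics_fn(net)
        flat = [
            name
            for name in ("weighted_clustering", "weighted_degree", "weighted_betweenness")
            if np.nanstd(np.nan_to_num(table[name].to_numpy(dtype=float))) == 0
        ]
        if flat:
            log.append((net.network_id, "no metric variation: " + ", ".join(flat)))
            continue
        retained.append(net)
    return retained, log


# ---------------------------------------------------------------------------
# I/O: weighted edge list + node sidecar (isolates would otherwise be lost)


def write_network_csv(net: SocialNetwork, edges_path, nodes_path) -> None:
    iu = np.triu_indices(net.size, k=1)
    mask = net.weights[iu] > 0
    edges = pd.DataFrame(
        {
            "node_i": [net.nodes[i] for i in iu[0][mask]],
            "node_j": [net.nodes[j] for j in iu[1][mask]],
            "weight": net.weights[iu][mask],
        }
    )
    edges.to_csv(edges_path, index=False)
    pd.DataFrame(
        {
            "individual_id": net.nodes,
            "network_id": net.network_id,
            "location_id": net.location_id,
            "year": net.year,
            "week": net.week,
        }
    ).to_csv(nodes_path, index=False)


def read_network_csv(edges_path, nodes_path) -> SocialNetwork:
    from .cli_io import validate_network_file

    return validate_network_file(edges_path, nodes_path)


def write_networks(networks: Sequence, directory) -> pd.DataFrame:
    """Write every network plus a metadata table; returns the metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = []
    for net in networks:
        write_network_csv(
            net,
            directory / f"{net.network_id}_edges.csv",
            directory / f"{net.network_id}_nodes.csv",
        )
        meta.append(
            {
                "network_id": net.network_id,
                "location_id": net.location_id,
                "year": net.year,
                "week": net.week,
                "n_nodes": net.size,
            }
        )
    meta = pd.DataFrame(meta)
    meta.to_csv(directory / "networks_meta.csv", index=False)
    return meta


def read_networks(directory) -> list:
    directory = Path(directory)
    meta = pd.read_csv(directory / "networks_meta.csv")
    nets = []
    for nid in meta["network_id"]:
        nets.append(
            read_network_csv(
                directory / f"{nid}_edges.csv", directory / f"{nid}_nodes.csv"
            )
        )
    return nets
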