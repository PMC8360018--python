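"""Molecule-level aggregation via hydrogen-bond connectivity.

Two molecules belong to the same cluster when at least one hydrogen bond
connects them; only humic-substance (SOM) and protein molecules are graph
nodes, so water- or ion-mediated bridges do not merge clusters.  Clusters
are the connected components of the per-frame graph; isolated molecules
count as size-1 clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core import Species, Topology, Trajectory
from .hbonds import HBond, detect_hbonds

__all__ = ["ClusterSeries", "build_graph", "count_clusters", "cluster_series",
           "summarize_replicate_series"]


@dataclass
class ClusterSeries:
    times: np.ndarray        # ps
    n_clusters: np.ndarray   # per frame
    running_avg: np.ndarray  # centred moving average
    window_mean: float
    window_se: float = 0.0   # standard error over replicates (0 for one run)


def build_graph(hbonds: list[HBond], topology: Topology,
                frame_index: int) -> nx.Graph:
    """Hydrogen-bond graph over SOM and protein molecules for one frame."""
    g = nx.Graph(frame_index=frame_index)
    node_species = {}
    for mol in topology.molecules_of_species(Species.SOM, Species.PROTEIN):
        g.add_node(mol.id)
        node_species[mol.id] = mol.species
    for b in hbonds:
        if b.frame_index != frame_index or b.intramolecular:
            continue
        if b.donor_molecule in node_species and b.acceptor_molecule in node_species:
            g.add_edge(b.donor_molecule, b.acceptor_molecule)
    return g


def count_clusters(graph: nx.Graph) -> int:
    return nx.number_connected_components(graph)


def cluster_series(trajectory: Trajectory, window_ns: float = 1.0,
                   r_cut: float = 0.35, angle_cut: float = 30.0) -> ClusterSeries:
    """Per-frame cluster counts with a centred running average.

    The smoothing window is ``window_ns`` of simulated time (shrinking
    symmetrically at the series edges).
    """
    top = trajectory.topology
    times = trajectory.times
    span = times[-1] - times[0] if len(times) > 1 else 0.0
    window_ps = window_ns * 1000.0
    if span < window_ps:
        raise ValueError(
            f"trajectory span {span} ps shorter than the {window_ps} ps window"
        )
    counts = np.array([
        count_clusters(
            build_graph(detect_hbonds(f, top, r_cut, angle_cut, k), top, k)
        )
        for k, f in enumerate(trajectory.frames)
    ])
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    w = max(1, int(round(window_ps / dt)))
    running = (
        pd.Series(counts).rolling(w, center=True, min_periods=1).mean().to_numpy()
    )
    return ClusterSeries(
        times=times,
        n_clusters=counts,
        running_avg=running,
        window_mean=float(counts.mean()),
    )


def summarize_replicate_series(series: list[ClusterSeries]) -> tuple[float, float]:
    """Mean and standard error of the window means across replicates."""
    means = np.array([s.window_mean for s in series])
    se = means.std(ddof=1) / np.sqrt(len(means)) if len(means) > 1 else 0.0
    return float(means.mean()), float(se)
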