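"""Minimum-distance-function (MDF) contact analysis.

The MDF of a functional-group or ion instance is, per frame, the distance
between the closest pair of atoms from that instance and the protein.
Traces of all instances of one label are concatenated into a 200-bin
histogram whose counts are normalized by the number of instances, so the
frequency is a per-group quantity comparable between systems of different
composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Frame, Species, Topology, Trajectory
from .geometry import min_image_distance_matrix
from .synthetic import _group_instances as functional_group_instances

__all__ = [
    "MDFTrace",
    "MDFHistogram",
    "min_distance",
    "mdf_traces",
    "mdf_histogram",
    "mdf_peak",
    "functional_group_instances",
]


@dataclass
class MDFTrace:
    group_label: str
    group_instance_id: int
    distances: np.ndarray  # nm, one per frame


@dataclass
class MDFHistogram:
    label: str
    bin_edges: np.ndarray   # 201 edges for 200 bins
    frequency: np.ndarray   # counts / n_groups
    n_groups: int


def min_distance(frame: Frame, group_a_ids, group_b_ids, box=None) -> float:
    """Minimum-image distance between the closest atoms of two groups."""
    a = np.asarray(group_a_ids, dtype=int)
    b = np.asarray(group_b_ids, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("both atom groups must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValueError("atom groups must be disjoint")
    box = frame.box if box is None else np.asarray(box, dtype=float)
    d = float(min_image_distance_matrix(frame.coords[a], frame.coords[b], box).min())
    if d > box.min() / 2:
        warnings.warn(
            f"minimum distance {d:.3f} nm exceeds half the smallest box edge",
            stacklevel=2,
        )
    return d


def mdf_traces(trajectory: Trajectory, label: str) -> list[MDFTrace]:
    """Per-instance minimum-distance traces of one label against the protein."""
    top = trajectory.topology
    protein = top.atom_ids_of_species(Species.PROTEIN)
    if protein.size == 0:
        raise ValueError("no protein molecule in the topology")
    instances = functional_group_instances(top, label)
    if not instances:
        raise ValueError(f"no instances of {label!r} in the topology")
    traces = []
    for k, inst in enumerate(instances):
        dists = np.array(
            [min_distance(f, inst, protein) for f in trajectory.frames]
        )
        traces.append(MDFTrace(label, k, dists))
    return traces


def mdf_histogram(traces: list[MDFTrace], n_bins: int = 200,
                  range: tuple[float, float] = (0.0, 1.0)) -> MDFHistogram:
    """Concatenate same-label traces into a normalized histogram.

    Counts are divided by the number of traces (group instances), so
    replicating a trace leaves the frequencies unchanged.
    """
    if not traces:
        raise ValueError("at least one trace required")
    labels = {t.group_label for t in traces}
    if len(labels) > 1:
        raise ValueError(f"traces carry mixed labels: {sorted(labels)}")
    data = np.concatenate([t.distances for t in traces])
    counts, edges = np.histogram(data, bins=n_bins, range=range)
    return MDFHistogram(
        label=traces[0].group_label,
        bin_edges=edges,
        frequency=counts / len(traces),
        n_groups=len(traces),
    )


def mdf_peak(histogram: MDFHistogram) -> tuple[float, float]:
    """Bin centre and height of the histogram maximum (ties -> smaller r)."""
    if not np.any(histogram.frequency > 0):
        raise ValueError("histogram is empty")
    i = int(np.argmax(histogram.frequency))  # argmax takes the first maximum
    centers = 0.5 * (histogram.bin_edges[:-1] + histogram.bin_edges[1:])
    return float(centers[i]), float(histogram.frequency[i])
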