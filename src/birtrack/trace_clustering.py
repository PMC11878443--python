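"""Classify reflection traces by when in the series they are maximally excited.

Each trace is normalized to its own maximum, then k-means (default five
clusters, ten restarts, fixed seed) groups the normalized traces. Cluster
labels are canonicalized so that cluster 0 has the earliest mean
peak-excitation fluence, which makes runs comparable and gives the clusters
their physical reading: groups of reflections that enter and leave the
Bragg condition together as the lattice reorients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .spot_tracing import IntensityTraces

logger = logging.getLogger(__name__)

__all__ = ["ClusterResult", "normalize_per_trace", "cluster_traces"]


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-trace cluster index, 0..k-1
    k: int
    order: np.ndarray  # permutation of 0..k-1, earliest-peaking first
    seed: int
    inertia: float


def normalize_per_trace(traces: IntensityTraces) -> IntensityTraces:
    """Divide each trace by its own maximum; drop all-zero traces.

    Idempotent; preserves each trace's argmax. Dropped traces are logged.
    """
    maxima = traces.values.max(axis=1)
    keep = maxima > 0
    if not keep.all():
        logger.warning("normalize_per_trace: dropping %d all-zero trace(s)", int((~keep).sum()))
    values = traces.values[keep] / maxima[keep][:, None]
    return IntensityTraces(
        values=values,
        fluence_axis=traces.fluence_axis,
        ids=traces.ids[keep],
        normalization_state="per-trace-max",
        clipped=None if traces.clipped is None else traces.clipped[keep],
    )


def cluster_traces(traces: IntensityTraces, k: int = 5, seed: int = 0, n_init: int = 10) -> ClusterResult:
    """K-means on normalized traces, labels ordered by mean argmax fluence.

    The feature vector is the full normalized trace; the fluence of each
    trace's maximum is used only to order the cluster labels (cluster 0
    peaks earliest). Raises if there are fewer traces than clusters.
    """
    if traces.normalization_state != "per-trace-max":
        traces = normalize_per_trace(traces)
    n = traces.n_traces
    if n < k:
        raise ValueError(f"{n} traces < k={k}; choose a smaller k")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(traces.values)
    peak_fluence = traces.fluence_axis[np.argmax(traces.values, axis=1)]
    mean_peak = np.full(k, np.inf)
    for c in range(k):
        sel = raw == c
        if sel.any():
            mean_peak[c] = peak_fluence[sel].mean()
    order = np.argsort(mean_peak, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return ClusterResult(
        labels=relabel[raw],
        k=k,
        order=order,
        seed=seed,
        inertia=float(km.inertia_),
    )
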