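"""Community structure of the group-level state-transition graph.

States with low participant-wise occurrence are dropped, the group-mean
transition matrix is symmetrized and thresholded to the strongest
between-state transitions (by default the top 21% of off-diagonal pairs),
and modules are found by modularity maximization with a Louvain-style
locally greedy heuristic (restarted over seeded node orders).
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities

from .io import CohortManifest
from .metrics import fo_matrix, lt_matrix, tp_array

__all__ = [
    "TransitionGraph",
    "CommunityPartition",
    "drop_low_occurrence_states",
    "group_mean_tp",
    "threshold_transitions",
    "modularity",
    "louvain_partition",
    "module_report",
]


@dataclasses.dataclass(frozen=True)
class TransitionGraph:
    """Thresholded symmetric transition graph on retained states.

    ``nodes`` are 0-based state indices into the original model;
    ``weights`` is indexed by position within ``nodes``.
    """

    nodes: tuple[int, ...]
    weights: np.ndarray  # symmetric, zero diagonal
    retained_edges: tuple[tuple[int, int, float], ...]  # (i, j, w) with i < j
    proportion: float
    dropped_states: tuple[int, ...]


@dataclasses.dataclass(frozen=True)
class CommunityPartition:
    labels: dict[int, int]  # node (0-based state) -> module id
    q: float
    n_restarts_used: int
    resolution: float


def drop_low_occurrence_states(
    metrics: pd.DataFrame,
    min_participant_fraction: float = 0.5,
    min_fo: float = 0.01,
) -> tuple[list[int], pd.DataFrame]:
    """Retain states visited by enough participants with enough occupancy.

    A state is retained iff the fraction of participants with at least one
    visit is >= ``min_participant_fraction`` and the pooled median FO is
    >= ``min_fo``.  Returns (retained 0-based state indices, per-state
    diagnostics table).
    """
    fo = fo_matrix(metrics)
    K = fo.shape[1]
    nv = metrics[[f"n_visits_{k + 1}" for k in range(K)]].to_numpy(dtype=float)
    frac_visiting = (nv > 0).mean(axis=0)
    median_fo = np.median(fo, axis=0)
    retained = [
        k
        for k in range(K)
        if frac_visiting[k] >= min_participant_fraction and median_fo[k] >= min_fo
    ]
    diagnostics = pd.DataFrame(
        {
            "state": np.arange(1, K + 1),
            "participant_fraction": frac_visiting,
            "median_fo": median_fo,
            "retained": [k in retained for k in range(K)],
        }
    )
    if not retained:
        raise ValueError(
            "every state fell below the occurrence thresholds; relax "
            "min_participant_fraction / min_fo"
        )
    return retained, diagnostics


def group_mean_tp(metrics: pd.DataFrame) -> np.ndarray:
    """Mean transition matrix across subjects, using valid rows only."""
    tp, valid = tp_array(metrics)
    K = tp.shape[1]
    out = np.zeros((K, K))
    for k in range(K):
        mask = valid[:, k]
        if mask.any():
            out[k] = tp[mask, k, :].mean(axis=0)
    return out


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def threshold_transitions(
    mean_tp: np.ndarray,
    proportion: float,
    nodes: tuple[int, ...] | None = None,
) -> TransitionGraph:
    """Keep the strongest between-state transitions.

    Self-transitions are excluded, the matrix is symmetrized as
    W = (M + M^T) / 2, and the top ``round(proportion * n_pairs)``
    off-diagonal symmetric pairs by weight are retained (ties: larger
    weight first, then smaller (i, j) lexicographic).
    """
    M = np.asarray(mean_tp, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("mean_tp must be square")
    if not 0 < proportion <= 1:
        raise ValueError("proportion must lie in (0, 1]")
    n = M.shape[0]
    if nodes is None:
        nodes = tuple(range(n))
    W = 0.5 * (M + M.T)
    np.fill_diagonal(W, 0.0)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    m_keep = _round_half_away(proportion * len(pairs))
    order = sorted(pairs, key=lambda ij: (-W[ij], ij))
    kept = order[:m_keep]
    thresholded = np.zeros_like(W)
    for i, j in kept:
        thresholded[i, j] = thresholded[j, i] = W[i, j]
    edges = tuple(sorted((i, j, float(W[i, j])) for i, j in kept))
    return TransitionGraph(
        nodes=tuple(nodes),
        weights=thresholded,
        retained_edges=edges,
        proportion=float(proportion),
        dropped_states=(),
    )


def modularity(
    weights: np.ndarray, labels: np.ndarray, resolution: float = 1.0
) -> float:
    """Newman-Girvan weighted modularity.

    Q = (1/2m) sum_ij [W_ij - gamma k_i k_j / (2m)] delta(c_i, c_j)
    with k the weighted degree and 2m the total weight sum.
    """
    W = np.asarray(weights, dtype=float)
    labels = np.asarray(labels)
    two_m = W.sum()
    if two_m <= 0:
        raise ValueError("empty graph: total edge weight is zero")
    k = W.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    return float(((W - resolution * np.outer(k, k) / two_m) * same).sum() / two_m)


def louvain_partition(
    graph: TransitionGraph,
    resolution: float = 1.0,
    n_restarts: int = 100,
    seed: int | None = 0,
) -> CommunityPartition:
    """Best-modularity partition over restarted Louvain runs.

    Each restart runs the locally greedy node-move + aggregation heuristic
    from a differently seeded node order; the partition with the highest
    Q wins.  Deterministic given ``seed``.
    """
    n = len(graph.nodes)
    if n == 0 or graph.weights.sum() <= 0:
        raise ValueError("empty graph: nothing to partition")
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for a in range(n):
        for b in range(a + 1, n):
            if graph.weights[a, b] > 0:
                G.add_edge(a, b, weight=float(graph.weights[a, b]))

    seeds = np.random.SeedSequence(seed).generate_state(max(1, n_restarts))
    best_q = -np.inf
    best_labels: np.ndarray | None = None
    for s in seeds:
        comms = louvain_communities(
            G, weight="weight", resolution=resolution, seed=int(s) % (2**31)
        )
        labels = np.empty(n, dtype=int)
        for cid, members in enumerate(comms):
            for node in members:
                labels[node] = cid
        q = modularity(graph.weights, labels, resolution)
        if q > best_q + 1e-15:
            best_q = q
            best_labels = labels
    assert best_labels is not None
    # canonical module ids: ordered by smallest member node
    order = {}
    for node in range(n):
        order.setdefault(best_labels[node], len(order))
    labels_map = {graph.nodes[i]: order[best_labels[i]] for i in range(n)}
    return CommunityPartition(
        labels=labels_map,
        q=float(best_q),
        n_restarts_used=len(seeds),
        resolution=float(resolution),
    )


def module_report(
    partition: CommunityPartition,
    metrics: pd.DataFrame,
    manifest: CohortManifest,
    *,
    shared_band_fraction: float = 0.10,
) -> pd.DataFrame:
    """Per-module summary with a group-affinity label.

    The affinity score of a module is the patient-minus-control difference
    of group-median FO, summed over member states.  Modules whose absolute
    affinity falls below ``shared_band_fraction`` of the pooled median FO
    are labelled "shared"; otherwise "patient-leaning" / "control-leaning".
    """
    groups = np.array([r.group for r in manifest.records])
    fo = fo_matrix(metrics)
    lt = lt_matrix(metrics)
    is_patient = groups == "patient"
    pooled_median_fo = float(np.median(fo))
    band = shared_band_fraction * max(pooled_median_fo, 1e-12)

    modules: dict[int, list[int]] = {}
    for node, mid in partition.labels.items():
        modules.setdefault(mid, []).append(node)

    rows = []
    for mid in sorted(modules):
        members = sorted(modules[mid])
        affinity = 0.0
        fo_p, fo_c, lt_p, lt_c = [], [], [], []
        for k in members:
            mp = float(np.median(fo[is_patient, k])) if is_patient.any() else np.nan
            mc = float(np.median(fo[~is_patient, k])) if (~is_patient).any() else np.nan
            if np.isfinite(mp) and np.isfinite(mc):
                affinity += mp - mc
            fo_p.append(mp)
            fo_c.append(mc)
            lt_p.append(float(np.nanmedian(lt[is_patient, k])) if is_patient.any() else np.nan)
            lt_c.append(float(np.nanmedian(lt[~is_patient, k])) if (~is_patient).any() else np.nan)
        if affinity > band:
            label = "patient-leaning"
        elif affinity < -band:
            label = "control-leaning"
        else:
            label = "shared"
        rows.append(
            {
                "module": mid,
                "states": tuple(k + 1 for k in members),  # 1-based labels
                "median_fo_patient": float(np.nanmean(fo_p)),
                "median_fo_control": float(np.nanmean(fo_c)),
                "median_lt_patient": float(np.nanmean(lt_p)),
                "median_lt_control": float(np.nanmean(lt_c)),
                "affinity": affinity,
                "label": label,
            }
        )
    return pd.DataFrame(rows)
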