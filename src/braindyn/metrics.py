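"""Per-subject temporal characteristics of decoded state paths.

Fractional occupancy (FO): proportion of time points spent in each state.
Lifetime (LT): mean uninterrupted dwell per state, in seconds.
Switching frequency (SF): rate of between-state transitions along the
path, reported both per TR and per second.
Transition probability (TP): the subject's empirical K x K row-stochastic
transition matrix, with validity flags for rows that were never left from.

Paths are 0-based internally; table columns are labelled 1..K.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hmm import HMMModel, viterbi
from .io import CohortManifest, ConcatenatedDataset

__all__ = [
    "fractional_occupancy",
    "lifetimes",
    "switching_frequency",
    "subject_tp",
    "compute_metrics",
    "fo_matrix",
    "lt_matrix",
    "tp_array",
]


def _check_path(path, n_states: int) -> np.ndarray:
    path = np.asarray(path)
    if path.ndim != 1 or path.size < 1:
        raise ValueError("path must be a non-empty 1-D sequence")
    if path.min() < 0 or path.max() >= n_states:
        raise ValueError(f"path contains states outside 0..{n_states - 1}")
    return path.astype(np.intp)


def fractional_occupancy(path, n_states: int) -> np.ndarray:
    """Fraction of time points spent in each state; sums to 1."""
    path = _check_path(path, n_states)
    return np.bincount(path, minlength=n_states) / path.size


def _run_lengths(path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(state, length) pairs of the run-length encoding, scan edges included."""
    change = np.flatnonzero(np.diff(path) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [path.size]))
    return path[starts], ends - starts


def lifetimes(path, n_states: int, tr_seconds: float) -> np.ndarray:
    """Mean dwell per state in seconds; NaN where the state is unvisited.

    Runs truncated by the scan edges count as observed.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    path = _check_path(path, n_states)
    states, lengths = _run_lengths(path)
    out = np.full(n_states, np.nan)
    for k in range(n_states):
        mask = states == k
        if mask.any():
            out[k] = lengths[mask].mean() * tr_seconds
    return out


def n_visits(path, n_states: int) -> np.ndarray:
    """Number of distinct runs of each state."""
    path = _check_path(path, n_states)
    states, _ = _run_lengths(path)
    return np.bincount(states, minlength=n_states)


def switching_frequency(path, tr_seconds: float) -> tuple[float, float]:
    """(per-TR, per-second) rate of between-state transitions:
    switches / (T - 1)."""
    path = np.asarray(path)
    if path.size < 2:
        raise ValueError("switching frequency needs at least 2 time points")
    per_tr = float(np.count_nonzero(np.diff(path) != 0) / (path.size - 1))
    return per_tr, per_tr / tr_seconds


def subject_tp(path, n_states: int) -> tuple[np.ndarray, np.ndarray]:
    """Empirical transition-probability matrix with row validity flags.

    Rows with no outgoing transition are set to uniform 1/K and flagged
    invalid so group tests can exclude them.
    """
    path = _check_path(path, n_states)
    if path.size < 2:
        raise ValueError("transition matrix needs at least 2 time points")
    counts = np.zeros((n_states, n_states))
    np.add.at(counts, (path[:-1], path[1:]), 1.0)
    row_sums = counts.sum(axis=1)
    valid = row_sums > 0
    tp = np.full((n_states, n_states), 1.0 / n_states)
    tp[valid] = counts[valid] / row_sums[valid, None]
    return tp, valid


def compute_metrics(
    model: HMMModel | None,
    dataset: ConcatenatedDataset | None,
    manifest: CohortManifest,
    *,
    decode_mode: str = "viterbi",
    paths: dict[str, np.ndarray] | None = None,
    gamma: np.ndarray | None = None,
) -> pd.DataFrame:
    """One row of temporal metrics per subject.

    decode_mode:
      * ``"viterbi"`` (default) — hard paths from the fitted model;
      * ``"oracle"`` — caller supplies ``paths`` (e.g. simulation ground
        truth);
      * ``"gamma"`` — FO is gamma-weighted (caller supplies the N x K
        ``gamma``); LT/SF/TP still come from the Viterbi path.

    Columns: subject_id, group, decode_mode, fo_1..K, lt_1..K (seconds),
    n_visits_1..K, sf_per_tr, sf_per_second, tp_i_j (flattened) and
    tp_row_valid_1..K.
    """
    if decode_mode not in ("viterbi", "oracle", "gamma"):
        raise ValueError(f"unknown decode_mode {decode_mode!r}")
    if decode_mode == "oracle":
        if paths is None:
            raise ValueError("decode_mode='oracle' requires paths")
        K = int(max(p.max() for p in paths.values())) + 1
        if model is not None:
            K = max(K, model.K)
    else:
        if model is None or dataset is None:
            raise ValueError("model and dataset required for decoding")
        K = model.K
    if decode_mode == "gamma" and gamma is None:
        raise ValueError("decode_mode='gamma' requires gamma")

    tr_by_subject = {r.subject_id: r.tr_seconds for r in manifest.records}
    group_by_subject = {r.subject_id: r.group for r in manifest.records}

    rows = []
    for i, sid in enumerate(manifest.subject_ids):
        if decode_mode == "oracle":
            path = np.asarray(paths[sid], dtype=np.intp)
        else:
            s, e = dataset.boundaries[i]
            path = viterbi(model, dataset.data[s:e])
        tr = tr_by_subject[sid]
        if decode_mode == "gamma":
            s, e = dataset.boundaries[i]
            fo = gamma[s:e].mean(axis=0)
        else:
            fo = fractional_occupancy(path, K)
        lt = lifetimes(path, K, tr)
        nv = n_visits(path, K)
        sf_tr, sf_s = switching_frequency(path, tr)
        tp, valid = subject_tp(path, K)

        row: dict[str, object] = {
            "subject_id": sid,
            "group": group_by_subject[sid],
            "decode_mode": decode_mode,
        }
        for k in range(K):
            row[f"fo_{k + 1}"] = fo[k]
        for k in range(K):
            row[f"lt_{k + 1}"] = lt[k]
        for k in range(K):
            row[f"n_visits_{k + 1}"] = int(nv[k])
        row["sf_per_tr"] = sf_tr
        row["sf_per_second"] = sf_s
        for a in range(K):
            for b in range(K):
                row[f"tp_{a + 1}_{b + 1}"] = tp[a, b]
        for k in range(K):
            row[f"tp_row_valid_{k + 1}"] = bool(valid[k])
        rows.append(row)
    return pd.DataFrame(rows)


def _n_states_of(metrics: pd.DataFrame) -> int:
    return sum(1 for c in metrics.columns if c.startswith("fo_"))


def fo_matrix(metrics: pd.DataFrame) -> np.ndarray:
    """(n_subjects, K) fractional occupancies in table order."""
    K = _n_states_of(metrics)
    return metrics[[f"fo_{k + 1}" for k in range(K)]].to_numpy(dtype=float)


def lt_matrix(metrics: pd.DataFrame) -> np.ndarray:
    K = _n_states_of(metrics)
    return metrics[[f"lt_{k + 1}" for k in range(K)]].to_numpy(dtype=float)


def tp_array(metrics: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(n_subjects, K, K) TP stacks plus (n_subjects, K) row-validity."""
    K = _n_states_of(metrics)
    n = len(metrics)
    tp = np.empty((n, K, K))
    for a in range(K):
        for b in range(K):
            tp[:, a, b] = metrics[f"tp_{a + 1}_{b + 1}"].to_numpy(dtype=float)
    valid = metrics[[f"tp_row_valid_{k + 1}" for k in range(K)]].to_numpy(dtype=bool)
    return tp, valid
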