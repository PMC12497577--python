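"""Nonparametric group comparison and clinical correlation.

Per-state fractional occupancies and lifetimes are compared between
groups with the Mann-Whitney U test (rank-biserial effect size); the
global switching frequency and each transition-probability cell are
compared with a label-permutation test (default 5,000 permutations of the
group labels, two-sided, add-one p-value rule).  Benjamini-Hochberg FDR
correction is applied within each metric family.  Clinical covariates are
related to temporal metrics by Spearman rank correlation on
pairwise-complete patient subjects.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CohortManifest
from .metrics import fo_matrix, lt_matrix, tp_array

__all__ = [
    "mann_whitney_rb",
    "permutation_test",
    "spearman",
    "bh_fdr",
    "compare_groups",
    "correlate_clinical",
]


def mann_whitney_rb(x, y) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U test with rank-biserial effect size.

    Returns (U, p, r) where U counts pairs favouring ``x`` (ties half) and
    r = 2U/(n_x n_y) - 1, so r > 0 means x is stochastically larger.  The
    p-value is exact (full permutation distribution) when there are no
    ties and n_x * n_y <= 10^4, else the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (not has_ties and x.size * y.size <= 10_000) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    u_x = float(res.statistic)
    r = 2.0 * u_x / (x.size * y.size) - 1.0
    return u_x, float(res.pvalue), r


def _group_stat(values: np.ndarray, mask: np.ndarray, statistic: str) -> float:
    if statistic == "median_diff":
        return float(np.median(values[mask]) - np.median(values[~mask]))
    if statistic == "mean_diff":
        return float(values[mask].mean() - values[~mask].mean())
    raise ValueError(f"unknown statistic {statistic!r}")


def permutation_test(
    values,
    is_group_a,
    *,
    statistic: str = "median_diff",
    n_perm: int = 5000,
    seed: int | None = 0,
    perm_masks: np.ndarray | None = None,
) -> tuple[float, float]:
    """Two-sided label-permutation test of a group-difference statistic.

    p = (1 + #{|stat_perm| >= |stat_obs|}) / (n_perm + 1).  A constant
    metric yields p = 1.  ``perm_masks`` lets callers share one permuted
    label matrix across many metrics.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(is_group_a, dtype=bool)
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = _group_stat(values, mask, statistic)
    if np.ptp(values) == 0:
        return observed, 1.0
    if perm_masks is None:
        perm_masks = permutation_masks(mask, n_perm, seed)
    vals_a = np.where(perm_masks, values[None, :], np.nan)
    vals_b = np.where(perm_masks, np.nan, values[None, :])
    if statistic == "median_diff":
        stat_perm = np.nanmedian(vals_a, axis=1) - np.nanmedian(vals_b, axis=1)
    else:
        stat_perm = np.nanmean(vals_a, axis=1) - np.nanmean(vals_b, axis=1)
    n_extreme = int(np.count_nonzero(np.abs(stat_perm) >= abs(observed) - 1e-12))
    p = (1 + n_extreme) / (perm_masks.shape[0] + 1)
    return observed, float(p)


def permutation_masks(
    mask: np.ndarray, n_perm: int, seed: int | None
) -> np.ndarray:
    """(n_perm, n) boolean matrix of uniformly permuted group labels."""
    rng = np.random.default_rng(seed)
    tiled = np.tile(np.asarray(mask, dtype=bool), (n_perm, 1))
    return rng.permuted(tiled, axis=1)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation on pairwise-complete observations.

    rho uses midranks.  The p-value is exact (enumeration over all rank
    permutations) for n <= 9, else the usual t approximation.  Returns
    (nan, nan) if either ranked vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return math.nan, math.nan
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt((rxc**2).sum() * (ryc**2).sum())
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = float(rxc @ ryc[list(perm)]) / denom
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    res = sps.spearmanr(x, y)
    return rho, float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _direction(observed_diff: float) -> str:
    if observed_diff > 0:
        return "patient-higher"
    if observed_diff < 0:
        return "patient-lower"
    return "none"


def compare_groups(
    metrics: pd.DataFrame,
    manifest: CohortManifest,
    *,
    n_perm: int = 5000,
    seed: int | None = 0,
    statistic: str = "median_diff",
    min_visiting: int = 2,
) -> pd.DataFrame:
    """Full between-group battery over the temporal metrics table.

    Per state: FO and LT (LT restricted to subjects visiting the state)
    via the Mann-Whitney U test; global switching frequency and every
    transition-matrix cell (valid rows only) via the permutation test.
    BH-FDR is applied within each metric family (FO, LT, TP) separately;
    the single SF test keeps q = p.
    """
    groups = np.array([r.group for r in manifest.records])
    if not (np.any(groups == "patient") and np.any(groups == "control")):
        raise ValueError("group comparison requires both patients and controls")
    order = {sid: i for i, sid in enumerate(metrics["subject_id"])}
    idx = [order[sid] for sid in manifest.subject_ids]
    metrics = metrics.iloc[idx].reset_index(drop=True)
    is_patient = groups == "patient"

    fo = fo_matrix(metrics)
    lt = lt_matrix(metrics)
    tp, tp_valid = tp_array(metrics)
    K = fo.shape[1]
    sf = metrics["sf_per_tr"].to_numpy(dtype=float)

    rows: list[dict] = []

    for k in range(K):
        u, p, r = mann_whitney_rb(fo[is_patient, k], fo[~is_patient, k])
        diff = float(
            np.median(fo[is_patient, k]) - np.median(fo[~is_patient, k])
        )
        rows.append(
            dict(
                family="fo", metric="fo", state=k + 1, statistic=u, effect_r=r,
                p=p, direction=_direction(diff),
                n_patient=int(is_patient.sum()), n_control=int((~is_patient).sum()),
                note="",
            )
        )

    for k in range(K):
        xp = lt[is_patient, k]
        xc = lt[~is_patient, k]
        xp = xp[np.isfinite(xp)]
        xc = xc[np.isfinite(xc)]
        if xp.size < min_visiting or xc.size < min_visiting:
            rows.append(
                dict(
                    family="lt", metric="lt", state=k + 1, statistic=np.nan,
                    effect_r=np.nan, p=np.nan, direction="none",
                    n_patient=int(xp.size), n_control=int(xc.size),
                    note=f"skipped: fewer than {min_visiting} visiting subjects in a group",
                )
            )
            continue
        u, p, r = mann_whitney_rb(xp, xc)
        diff = float(np.median(xp) - np.median(xc))
        rows.append(
            dict(
                family="lt", metric="lt", state=k + 1, statistic=u, effect_r=r,
                p=p, direction=_direction(diff),
                n_patient=int(xp.size), n_control=int(xc.size), note="",
            )
        )

    obs, p = permutation_test(
        sf, is_patient, statistic=statistic, n_perm=n_perm, seed=seed
    )
    rows.append(
        dict(
            family="sf", metric="sf_per_tr", state=0, statistic=obs,
            effect_r=np.nan, p=p, direction=_direction(obs),
            n_patient=int(is_patient.sum()), n_control=int((~is_patient).sum()),
            note="global",
        )
    )

    perm_masks_cache: dict[tuple, np.ndarray] = {}
    for a in range(K):
        for b in range(K):
            mask_valid = tp_valid[:, a]
            pat = is_patient[mask_valid]
            if pat.sum() < 2 or (~pat).sum() < 2:
                rows.append(
                    dict(
                        family="tp", metric="tp", state=f"{a + 1}->{b + 1}",
                        statistic=np.nan, effect_r=np.nan, p=np.nan,
                        direction="none", n_patient=int(pat.sum()),
                        n_control=int((~pat).sum()),
                        note="skipped: too few subjects with a valid row",
                    )
                )
                continue
            key = tuple(np.flatnonzero(mask_valid))
            if key not in perm_masks_cache:
                perm_masks_cache[key] = permutation_masks(pat, n_perm, seed)
            obs, p = permutation_test(
                tp[mask_valid, a, b], pat, statistic=statistic,
                n_perm=n_perm, seed=seed, perm_masks=perm_masks_cache[key],
            )
            rows.append(
                dict(
                    family="tp", metric="tp", state=f"{a + 1}->{b + 1}",
                    statistic=obs, effect_r=np.nan, p=p,
                    direction=_direction(obs), n_patient=int(pat.sum()),
                    n_control=int((~pat).sum()), note="",
                )
            )

    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for family in ("fo", "lt", "tp"):
        sel = (table["family"] == family) & table["p"].notna()
        if sel.any():
            table.loc[sel, "q"] = bh_fdr(table.loc[sel, "p"].to_numpy())
    sel = table["family"] == "sf"
    table.loc[sel, "q"] = table.loc[sel, "p"]
    return table


def correlate_clinical(
    metrics: pd.DataFrame,
    manifest: CohortManifest,
    covariate: str,
    targets: list[tuple[str, int]],
    *,
    group: str = "patient",
) -> pd.DataFrame:
    """Spearman correlation of a clinical covariate with temporal metrics.

    ``targets`` lists (metric, state) pairs, metric in {"fo", "lt",
    "sf_per_tr", "sf_per_second"} (state ignored for the SF metrics).
    Computed on pairwise-complete subjects of ``group``; BH-FDR across
    the tested pairs.
    """
    order = {sid: i for i, sid in enumerate(metrics["subject_id"])}
    idx = [order[sid] for sid in manifest.subject_ids]
    metrics = metrics.iloc[idx].reset_index(drop=True)
    groups = np.array([r.group for r in manifest.records])
    cov = manifest.covariate(covariate)
    in_group = groups == group
    if np.count_nonzero(in_group & np.isfinite(cov)) < 3:
        raise ValueError(
            f"covariate {covariate!r} present for fewer than 3 {group} subjects"
        )

    rows = []
    for metric, state in targets:
        if metric == "fo":
            values = fo_matrix(metrics)[:, state - 1]
        elif metric == "lt":
            values = lt_matrix(metrics)[:, state - 1]
        elif metric in ("sf_per_tr", "sf_per_second"):
            values = metrics[metric].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        x = cov[in_group]
        y = values[in_group]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            rows.append(
                dict(metric=metric, state=state, rho=np.nan, p=np.nan,
                     n=int(ok.sum()), note="skipped: fewer than 3 complete pairs")
            )
            continue
        rho, p = spearman(x[ok], y[ok])
        rows.append(
            dict(metric=metric, state=state, rho=rho, p=p, n=int(ok.sum()), note="")
        )
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    sel = table["p"].notna()
    if sel.any():
        table.loc[sel, "q"] = bh_fdr(table.loc[sel, "p"].to_numpy())
    return table
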