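"""Synthetic multi-subject cohorts from the generative family the HMM assumes.

Each subject is a Markov chain over K hidden states with multivariate
Gaussian emissions.  The two groups share emission parameters (state mean
activations and covariances); only the transition structure differs:

* controls have a higher self-transition (stickiness) probability, so the
  patient group switches between states more often;
* entry into a designated set of "suppressed" states is down-weighted in
  patients, lowering those states' stationary (and hence fractional)
  occupancy;
* a clinical covariate (LDH-like, patients only) is planted as a rank
  (Gaussian-copula) association with the true lifetime of one target
  state, calibrated so the expected Spearman correlation matches a
  requested value.

The defaults mirror a two-group resting-state design: 36 patients vs 30
controls, 90 regions, 200 time points at TR = 2 s, 12 states, suppressed
states {5, 6}, and an LDH-like covariate tied to state 8's lifetime at
Spearman rho 0.693.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
from scipy.stats import norm, rankdata

from .hmm import HMMModel
from .io import (
    CohortManifest,
    ManifestRecord,
    ROITimeSeries,
    write_manifest,
    write_timeseries,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "sample_hmm_parameters",
    "simulate_subject",
    "simulate_cohort",
    "attach_covariate",
    "write_cohort",
]


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth cohort design.  State indices here are 1-based, matching
    reported state labels."""

    k_true: int = 12
    n_regions: int = 90
    n_timepoints: int = 200
    n_patients: int = 36
    n_controls: int = 30
    tr_seconds: float = 2.0
    state_mean_scale: float = 1.5
    covariance: str = "isotropic"  # or "random_spd"
    isotropic_sigma2: float = 1.0
    spd_condition_max: float = 10.0
    control_stickiness: float = 0.90
    patient_stickiness: float = 0.82
    suppressed_states: tuple[int, ...] = (5, 6)
    suppression_factor: float = 0.4
    covariate_name: str = "LDH"
    covariate_target_state: int = 8
    covariate_target_rho: float = 0.693
    seed: int = 0

    def validate(self) -> None:
        if self.k_true < 1 or self.n_regions < 2 or self.n_timepoints < 2:
            raise ValueError("k_true >= 1, n_regions >= 2, n_timepoints >= 2 required")
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.n_patients == 0 and self.n_controls == 0:
            raise ValueError("cohort must contain at least one subject")
        if not (0 < self.control_stickiness < 1 and 0 < self.patient_stickiness < 1):
            raise ValueError("stickiness probabilities must lie in (0, 1)")
        if not (0 < self.suppression_factor <= 1):
            raise ValueError("suppression_factor must lie in (0, 1]")
        bad = [s for s in self.suppressed_states if not 1 <= s <= self.k_true]
        if bad:
            raise ValueError(f"suppressed_states out of 1..{self.k_true}: {bad}")
        if not -1 <= self.covariate_target_rho <= 1:
            raise ValueError("covariate_target_rho must lie in [-1, 1]")
        if not 1 <= self.covariate_target_state <= self.k_true:
            raise ValueError("covariate_target_state out of range")
        if self.covariance not in ("isotropic", "random_spd"):
            raise ValueError(f"unknown covariance spec {self.covariance!r}")


@dataclasses.dataclass
class GroundTruth:
    """Hidden variables of a simulated cohort, kept for recovery scoring."""

    model_per_group: dict[str, HMMModel]
    paths: dict[str, np.ndarray]  # subject_id -> 0-based state path
    covariate_values: dict[str, float]  # patients only
    config: SimulationConfig


def _stationary_distribution(transition: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(transition.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _random_spd(rng: np.random.Generator, R: int, cond_max: float) -> np.ndarray:
    """Random SPD matrix with eigenvalues in [1/cond_max, 1] (bounded
    condition number), via a random orthogonal basis."""
    for _ in range(50):
        q, _ = np.linalg.qr(rng.standard_normal((R, R)))
        eigs = rng.uniform(1.0 / cond_max, 1.0, size=R)
        cov = (q * eigs) @ q.T
        cov = 0.5 * (cov + cov.T)
        if np.linalg.eigvalsh(cov).min() > 0:
            return cov
    raise RuntimeError("failed to draw an SPD covariance within retries")


def sample_hmm_parameters(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, HMMModel]:
    """Draw per-group ground-truth HMM parameters.

    Emissions are shared between groups: K mean vectors on a sphere of
    radius ``state_mean_scale`` plus per-state covariances.  Transition
    matrices have group-specific stickiness on the diagonal, uniform
    off-diagonal mass, and (patients only) suppressed-state columns
    multiplied by ``suppression_factor`` before row renormalization.
    Initial distributions are the stationary distributions.
    """
    config.validate()
    K, R = config.k_true, config.n_regions
    # means live on a sphere of radius state_mean_scale (in emission-SD
    # units); redraw until every pair is at least state_mean_scale apart so
    # no two states coincide by chance and the separation truly scales with
    # the configured value
    for _ in range(1000):
        directions = rng.standard_normal((K, R))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        means = config.state_mean_scale * directions
        if K == 1:
            break
        d = np.linalg.norm(means[:, None, :] - means[None, :, :], axis=2)
        if d[np.triu_indices(K, 1)].min() >= config.state_mean_scale:
            break
    else:
        raise RuntimeError(
            "could not place state means with the requested pairwise separation"
        )
    if config.covariance == "isotropic":
        covs = np.stack([config.isotropic_sigma2 * np.eye(R)] * K)
    else:
        covs = np.stack(
            [_random_spd(rng, R, config.spd_condition_max) for _ in range(K)]
        )

    models = {}
    for group, stick in (
        ("control", config.control_stickiness),
        ("patient", config.patient_stickiness),
    ):
        if K == 1:
            A = np.ones((1, 1))
        else:
            off = (1.0 - stick) / (K - 1)
            A = np.full((K, K), off)
            np.fill_diagonal(A, stick)
        if group == "patient" and config.suppressed_states:
            cols = [s - 1 for s in config.suppressed_states]
            A[:, cols] *= config.suppression_factor
            A /= A.sum(axis=1, keepdims=True)
        models[group] = HMMModel(
            K=K,
            means=means,
            covariances=covs,
            transition=A,
            initial=_stationary_distribution(A),
        )
    return models


def simulate_subject(
    model: HMMModel,
    n_timepoints: int,
    tr_seconds: float,
    rng: np.random.Generator,
    subject_id: str = "sim",
) -> tuple[ROITimeSeries, np.ndarray]:
    """Sample one subject: a Markov state path (0-based) and Gaussian
    observations from the active state at each time point."""
    K = model.K
    path = np.empty(n_timepoints, dtype=np.intp)
    path[0] = rng.choice(K, p=model.initial)
    for t in range(1, n_timepoints):
        path[t] = rng.choice(K, p=model.transition[path[t - 1]])
    chols = np.stack([np.linalg.cholesky(model.covariances[k]) for k in range(K)])
    noise = rng.standard_normal((n_timepoints, model.means.shape[1]))
    data = model.means[path] + np.einsum("tij,tj->ti", chols[path], noise)
    ts = ROITimeSeries(
        subject_id=subject_id, data=data, tr_seconds=tr_seconds, standardized=False
    )
    return ts, path


def _true_state_lifetimes(path: np.ndarray, state0: int, tr_seconds: float) -> float:
    """Mean run length (seconds) of one 0-based state; NaN if unvisited."""
    runs = []
    count = 0
    for z in path:
        if z == state0:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return float(np.mean(runs) * tr_seconds) if runs else math.nan


def attach_covariate(
    truth_lifetimes: np.ndarray,
    target_rho: float,
    rng: np.random.Generator,
    *,
    location: float = 250.0,
    scale: float = 128.0,
) -> np.ndarray:
    """Generate a clinical covariate rank-coupled to true state lifetimes.

    Uses a Gaussian copula: the lifetimes' normal scores are mixed with
    independent noise at latent correlation ``2 sin(pi * rho_s / 6)`` so the
    expected Spearman correlation equals ``target_rho``; the result is
    mapped to an LDH-like scale (U/L).  Subjects with NaN lifetime (target
    state never visited) receive a purely random covariate.
    """
    if not -1 <= target_rho <= 1:
        raise ValueError("target_rho must lie in [-1, 1]")
    lt = np.asarray(truth_lifetimes, dtype=float)
    n = lt.size
    if abs(target_rho) == 1.0:
        # exact monotone (or antitone) transform, no noise
        base = np.where(np.isnan(lt), np.nanmin(lt) - 1 if n else 0.0, lt)
        return location + scale * np.sign(target_rho) * (base - np.nanmean(base))
    observed = ~np.isnan(lt)
    z = np.zeros(n)
    if observed.sum() >= 2:
        ranks = rankdata(lt[observed])
        z[observed] = norm.ppf(ranks / (observed.sum() + 1))
    rho_latent = 2.0 * math.sin(math.pi * target_rho / 6.0)
    latent = rho_latent * z + math.sqrt(1.0 - rho_latent**2) * rng.standard_normal(n)
    return location + scale * latent


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[CohortManifest, list[ROITimeSeries], GroundTruth]:
    """Simulate the full two-group cohort.

    Deterministic given ``config.seed``.  Patients receive the planted
    clinical covariate; controls get a missing value (as for a
    disease-marker enzyme never assayed in healthy volunteers).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    models = sample_hmm_parameters(config, rng)

    subjects = [(f"sub-P{i + 1:03d}", "patient") for i in range(config.n_patients)]
    subjects += [(f"sub-C{i + 1:03d}", "control") for i in range(config.n_controls)]

    series: list[ROITimeSeries] = []
    paths: dict[str, np.ndarray] = {}
    for sid, group in subjects:
        ts, path = simulate_subject(
            models[group], config.n_timepoints, config.tr_seconds, rng, subject_id=sid
        )
        series.append(ts)
        paths[sid] = path

    patient_ids = [sid for sid, g in subjects if g == "patient"]
    covariate_values: dict[str, float] = {}
    if patient_ids:
        target0 = config.covariate_target_state - 1
        lts = np.array(
            [
                _true_state_lifetimes(paths[sid], target0, config.tr_seconds)
                for sid in patient_ids
            ]
        )
        cov = attach_covariate(lts, config.covariate_target_rho, rng)
        covariate_values = {sid: float(v) for sid, v in zip(patient_ids, cov)}

    records = []
    for sid, group in subjects:
        cov = {
            config.covariate_name: covariate_values.get(sid, math.nan)
        }
        records.append(
            ManifestRecord(
                subject_id=sid,
                group=group,
                path=f"{sid}.tsv",
                tr_seconds=config.tr_seconds,
                covariates=cov,
            )
        )
    manifest = CohortManifest(tuple(records))
    truth = GroundTruth(
        model_per_group=models,
        paths=paths,
        covariate_values=covariate_values,
        config=config,
    )
    return manifest, series, truth


def write_cohort(
    manifest: CohortManifest,
    series: list[ROITimeSeries],
    truth: GroundTruth,
    out_dir: str | Path,
) -> None:
    """Write manifest.csv, per-subject TSVs and ground_truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_manifest(manifest, out_dir / "manifest.csv")
    for ts in series:
        write_timeseries(ts, out_dir / f"{ts.subject_id}.tsv")
    payload = {
        "config": dataclasses.asdict(truth.config),
        "paths": {sid: p.tolist() for sid, p in truth.paths.items()},
        "covariate_values": truth.covariate_values,
        "models": {
            g: {
                "means": m.means.tolist(),
                "covariances": m.covariances.tolist(),
                "transition": m.transition.tolist(),
                "initial": m.initial.tolist(),
            }
            for g, m in truth.model_per_group.items()
        },
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(payload, fh)
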