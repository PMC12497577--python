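"""Variational-Bayes inference for Gaussian-emission hidden Markov models.

The model: a hidden chain z_1..z_T over K states per subject, shared
parameters across subjects, and a multivariate Gaussian emission per state
(a mean activation vector plus a full covariance matrix).  Inference is
mean-field variational Bayes with conjugate priors:

* transition rows and the initial distribution: Dirichlet,
* emission (mean, covariance): Normal-Inverse-Wishart.

Each update cycle runs an M-like step (refresh the Dirichlet and NIW
posteriors from the current responsibilities and expected transition
counts) followed by an E-like step (forward-backward per subject segment
using expected-log parameters).  The variational free energy — the
negative evidence lower bound — is computed after every cycle and is
non-increasing; it doubles as the model-order selection criterion.

States are indexed 0..K-1 internally; user-facing reports label them 1..K.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.special import digamma, gammaln, multigammaln
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .io import ConcatenatedDataset

__all__ = [
    "HMMModel",
    "VBPriors",
    "VBPosterior",
    "VBState",
    "KSelectionReport",
    "VariationalGaussianHMM",
    "forward_backward",
    "viterbi",
    "fit_hmm",
    "select_n_states",
]


@dataclasses.dataclass(frozen=True)
class HMMModel:
    """Point-estimate (posterior-mean) parameters of a fitted model."""

    K: int
    means: np.ndarray  # (K, R)
    covariances: np.ndarray  # (K, R, R), each SPD
    transition: np.ndarray  # (K, K) row-stochastic
    initial: np.ndarray  # (K,) simplex

    def validate(self) -> None:
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-10):
            raise ValueError("initial distribution must sum to 1")
        for k in range(self.K):
            np.linalg.cholesky(self.covariances[k])


@dataclasses.dataclass(frozen=True)
class VBPriors:
    alpha_trans: np.ndarray  # (K, K) Dirichlet counts per transition row
    alpha_init: np.ndarray  # (K,)
    m0: np.ndarray  # (R,) NIW location
    kappa0: float  # NIW scale count
    Psi0: np.ndarray  # (R, R) inverse-Wishart scale matrix
    nu0: float  # inverse-Wishart degrees of freedom (> R + 1)


@dataclasses.dataclass
class VBPosterior:
    alpha_trans: np.ndarray  # (K, K)
    alpha_init: np.ndarray  # (K,)
    m: np.ndarray  # (K, R)
    kappa: np.ndarray  # (K,)
    Psi: np.ndarray  # (K, R, R)
    nu: np.ndarray  # (K,)


@dataclasses.dataclass
class VBState:
    """One snapshot of the variational optimisation."""

    posterior: VBPosterior
    gamma: np.ndarray  # (N, K) responsibilities
    trans_counts: np.ndarray  # (S, K, K) expected transition counts per subject
    init_counts: np.ndarray  # (K,) summed first-time-point responsibilities
    log_norms: np.ndarray  # (S,) per-segment evidence contributions
    free_energy_trace: list[float]
    depleted: np.ndarray  # (K,) bool, responsibility mass below floor


@dataclasses.dataclass(frozen=True)
class KSelectionReport:
    grid: tuple[int, ...]
    free_energy: tuple[float, ...]
    median_fo: tuple[float, ...]
    selected_k: int
    rule_trace: str


# ---------------------------------------------------------------------------
# forward-backward (scaled, batched over equal-length segments)
# ---------------------------------------------------------------------------


def _forward_backward_batch(
    logb: np.ndarray, trans: np.ndarray, init: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward-backward for a (B, L, K) block of log-densities.

    ``trans`` and ``init`` may be sub-normalized (exponentials of expected
    log parameters); the returned log-normalizer absorbs the deficit.
    Returns (gamma (B,L,K), xi_counts (B,K,K), log_norm (B,)).
    """
    B, L, K = logb.shape
    shift = logb.max(axis=2, keepdims=True)  # (B, L, 1)
    btil = np.exp(logb - shift)

    alpha = np.empty((B, L, K))
    c = np.empty((B, L))
    a = init[None, :] * btil[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, L):
        a = (alpha[:, t - 1] @ trans) * btil[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    log_norm = np.log(c).sum(axis=1) + shift[:, :, 0].sum(axis=1)

    gamma = np.empty((B, L, K))
    xi = np.zeros((B, K, K))
    beta = np.ones((B, K))
    gamma[:, L - 1] = alpha[:, L - 1]
    for t in range(L - 2, -1, -1):
        w = btil[:, t + 1] * beta  # (B, K)
        xi += (
            alpha[:, t, :, None]
            * trans[None, :, :]
            * w[:, None, :]
            / c[:, t + 1, None, None]
        )
        beta = (w @ trans.T) / c[:, t + 1, None]
        gamma[:, t] = alpha[:, t] * beta
    return gamma, xi, log_norm


def forward_backward(
    log_emission: np.ndarray, log_transition: np.ndarray, log_initial: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior state marginals for one segment.

    Parameters
    ----------
    log_emission : (T, K) per-time-point log densities (may be expected
        log-densities from a variational posterior; sub-normalized is fine).
    log_transition, log_initial : log transition matrix and log initial
        weights (again possibly sub-normalized expected logs).

    Returns
    -------
    gamma : (T, K) posterior marginals, rows summing to 1.
    xi_counts : (K, K) summed pairwise posteriors (expected transition
        counts; total mass T - 1).
    log_norm : the segment's log normalizer (evidence contribution).
    """
    log_emission = np.asarray(log_emission, dtype=float)
    if log_emission.ndim != 2:
        raise ValueError("log_emission must be (T, K)")
    if not np.isfinite(log_emission).all():
        raise ValueError("non-finite log emission densities")
    trans = np.exp(np.asarray(log_transition, dtype=float))
    init = np.exp(np.asarray(log_initial, dtype=float))
    gamma, xi, log_norm = _forward_backward_batch(
        log_emission[None, :, :], trans, init
    )
    return gamma[0], xi[0], float(log_norm[0])


def _e_step_all(
    logb: np.ndarray,
    boundaries: Sequence[tuple[int, int]],
    trans: np.ndarray,
    init: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run forward-backward over every subject segment, batching segments
    of equal length together (the common case: equal scan lengths)."""
    N, K = logb.shape
    S = len(boundaries)
    gamma = np.empty((N, K))
    xi = np.empty((S, K, K))
    log_norms = np.empty(S)

    by_len: dict[int, list[int]] = {}
    for i, (s, e) in enumerate(boundaries):
        by_len.setdefault(e - s, []).append(i)
    for L, idxs in by_len.items():
        block = np.stack([logb[boundaries[i][0] : boundaries[i][1]] for i in idxs])
        g, x, ln = _forward_backward_batch(block, trans, init)
        for j, i in enumerate(idxs):
            s, e = boundaries[i]
            gamma[s:e] = g[j]
            xi[i] = x[j]
            log_norms[i] = ln[j]
    return gamma, xi, log_norms


# ---------------------------------------------------------------------------
# expected log parameters, M-step, KL terms
# ---------------------------------------------------------------------------


def _dirichlet_expected_log(alpha: np.ndarray, axis: int = -1) -> np.ndarray:
    return digamma(alpha) - digamma(alpha.sum(axis=axis, keepdims=True))


def _expected_log_lik(X: np.ndarray, post: VBPosterior, cov_reg: float) -> np.ndarray:
    """E_q[log N(x | mu_k, Sigma_k)] for every row and state: (N, K)."""
    N, R = X.shape
    K = post.m.shape[0]
    out = np.empty((N, K))
    i = np.arange(1, R + 1)
    for k in range(K):
        Psi = post.Psi[k] + cov_reg * np.eye(R)
        L = np.linalg.cholesky(Psi)
        logdet_psi = 2.0 * np.log(np.diag(L)).sum()
        elogdet_lam = (
            digamma((post.nu[k] + 1 - i) / 2).sum() + R * np.log(2.0) - logdet_psi
        )
        diff = X - post.m[k]
        sol = np.linalg.solve(L, diff.T)  # (R, N)
        maha = np.einsum("rn,rn->n", sol, sol)
        out[:, k] = 0.5 * elogdet_lam - 0.5 * R * np.log(2 * np.pi) - 0.5 * (
            R / post.kappa[k] + post.nu[k] * maha
        )
    return out


def _m_step(
    X: np.ndarray,
    gamma: np.ndarray,
    trans_counts: np.ndarray,
    init_counts: np.ndarray,
    priors: VBPriors,
) -> VBPosterior:
    N, R = X.shape
    K = gamma.shape[1]
    Nk = gamma.sum(axis=0)  # (K,)
    safe_Nk = np.maximum(Nk, 1e-300)
    xbar = (gamma.T @ X) / safe_Nk[:, None]  # (K, R)

    kappa = priors.kappa0 + Nk
    nu = priors.nu0 + Nk
    m = (priors.kappa0 * priors.m0[None, :] + Nk[:, None] * xbar) / kappa[:, None]
    Psi = np.empty((K, R, R))
    for k in range(K):
        diff = X - xbar[k]
        S = (gamma[:, k, None] * diff).T @ diff
        d0 = (xbar[k] - priors.m0)[:, None]
        Psi_k = priors.Psi0 + S + (priors.kappa0 * Nk[k] / kappa[k]) * (d0 @ d0.T)
        Psi[k] = 0.5 * (Psi_k + Psi_k.T)

    alpha_trans = priors.alpha_trans + trans_counts
    alpha_init = priors.alpha_init + init_counts
    return VBPosterior(
        alpha_trans=alpha_trans, alpha_init=alpha_init, m=m, kappa=kappa, Psi=Psi, nu=nu
    )


def _kl_dirichlet(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    a, a0 = np.asarray(alpha, float), np.asarray(alpha0, float)
    s, s0 = a.sum(), a0.sum()
    return float(
        gammaln(s)
        - gammaln(a).sum()
        - gammaln(s0)
        + gammaln(a0).sum()
        + ((a - a0) * (digamma(a) - digamma(s))).sum()
    )


def _kl_niw(
    m: np.ndarray,
    kappa: float,
    Psi: np.ndarray,
    nu: float,
    priors: VBPriors,
    cov_reg: float,
) -> float:
    """KL between Normal-Wishart posteriors/priors, precision parametrization
    W = Psi^{-1} (equivalent to the Normal-Inverse-Wishart statement)."""
    R = m.shape[0]
    eye = cov_reg * np.eye(R)
    L = np.linalg.cholesky(Psi + eye)
    L0 = np.linalg.cholesky(priors.Psi0 + eye)
    logdet_psi = 2.0 * np.log(np.diag(L)).sum()
    logdet_psi0 = 2.0 * np.log(np.diag(L0)).sum()
    i = np.arange(1, R + 1)
    elogdet_lam = digamma((nu + 1 - i) / 2).sum() + R * np.log(2.0) - logdet_psi

    # Normal part: E_Lambda[ KL(N(m, (kappa Lambda)^-1) || N(m0, (kappa0 Lambda)^-1)) ]
    diff = m - priors.m0
    sol = np.linalg.solve(L, diff)
    maha = float(sol @ sol)  # (m-m0)^T Psi^-1 (m-m0)
    kl_normal = 0.5 * (
        priors.kappa0 * nu * maha
        + R * priors.kappa0 / kappa
        - R
        + R * np.log(kappa / priors.kappa0)
    )

    # Wishart part, with log B(W, nu) = (nu/2) logdet Psi - (nu R/2) log 2 - logGamma_R(nu/2)
    log_b = 0.5 * nu * logdet_psi - 0.5 * nu * R * np.log(2.0) - multigammaln(nu / 2, R)
    log_b0 = (
        0.5 * priors.nu0 * logdet_psi0
        - 0.5 * priors.nu0 * R * np.log(2.0)
        - multigammaln(priors.nu0 / 2, R)
    )
    # tr(W0^{-1} W) = tr(Psi0 Psi^{-1})
    sol0 = np.linalg.solve(L, np.linalg.solve(L, priors.Psi0 + eye).T)
    tr = float(np.trace(sol0))
    kl_wishart = (
        log_b - log_b0 + 0.5 * (nu - priors.nu0) * elogdet_lam - 0.5 * nu * R + 0.5 * nu * tr
    )
    return kl_normal + kl_wishart


def _kl_total(post: VBPosterior, priors: VBPriors, cov_reg: float) -> float:
    K = post.m.shape[0]
    kl = _kl_dirichlet(post.alpha_init, priors.alpha_init)
    for j in range(K):
        kl += _kl_dirichlet(post.alpha_trans[j], priors.alpha_trans[j])
    for k in range(K):
        kl += _kl_niw(post.m[k], post.kappa[k], post.Psi[k], post.nu[k], priors, cov_reg)
    return kl


# ---------------------------------------------------------------------------
# point-estimate decoding
# ---------------------------------------------------------------------------


def _gaussian_loglik(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    N, R = X.shape
    K = means.shape[0]
    out = np.empty((N, K))
    for k in range(K):
        L = np.linalg.cholesky(covs[k])
        logdet = 2.0 * np.log(np.diag(L)).sum()
        sol = np.linalg.solve(L, (X - means[k]).T)
        maha = np.einsum("rn,rn->n", sol, sol)
        out[:, k] = -0.5 * (R * np.log(2 * np.pi) + logdet + maha)
    return out


def viterbi(model: HMMModel, data) -> np.ndarray:
    """Most probable state path (0-based labels) under the posterior-mean
    parameters, computed in log space."""
    X = data.data if hasattr(data, "data") and not isinstance(data, np.ndarray) else data
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"data has {X.shape[1]} regions, model expects {model.means.shape[1]}"
        )
    logb = _gaussian_loglik(X, model.means, model.covariances)
    with np.errstate(divide="ignore"):
        log_a = np.log(model.transition)
        log_pi = np.log(model.initial)
    T, K = logb.shape
    delta = log_pi + logb[0]
    back = np.empty((T, K), dtype=np.intp)
    for t in range(1, T):
        cand = delta[:, None] + log_a  # (from, to)
        back[t] = cand.argmax(axis=0)
        delta = cand[back[t], np.arange(K)] + logb[t]
    path = np.empty(T, dtype=np.intp)
    path[-1] = int(delta.argmax())
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------


class VariationalGaussianHMM(BaseEstimator):
    """Gaussian-emission HMM fitted by variational Bayes.

    Follows the scikit-learn estimator protocol; ``fit`` takes the row-
    stacked multi-subject matrix plus per-subject segment lengths (the
    hmmlearn convention) or a :class:`ConcatenatedDataset`.

    Parameters
    ----------
    n_states : number of hidden states K.
    n_restarts : independent seeded initializations; the restart with the
        lowest final free energy wins.
    max_iter, tol : per-restart iteration cap and relative free-energy
        convergence threshold.
    transition_prior_count : Dirichlet prior count on every transition
        entry (and on the initial distribution).
    transition_prior_diag_bonus : extra prior count on self-transitions
        ("stickiness prior"); 0 disables it.
    init_soft_eps : responsibility mass spread off the k-means label when
        softening the hard initialization.
    cov_reg : ridge added to covariance scale matrices before inversion.
    random_state : seed controlling k-means restarts; fits are
        deterministic given it.

    Attributes
    ----------
    means_, covariances_, transmat_, startprob_ : posterior-mean parameters.
    free_energy_ : final variational free energy (lower is better).
    free_energy_trace_ : per-iteration trace of the winning restart.
    converged_ : whether the winning restart met ``tol``.
    posterior_ : :class:`VBPosterior` hyperparameters.
    depleted_states_ : 0-based indices of states whose responsibility mass
        fell below the floor (kept; they shrink to the prior).
    """

    def __init__(
        self,
        n_states: int = 12,
        *,
        n_restarts: int = 5,
        max_iter: int = 500,
        tol: float = 1e-5,
        transition_prior_count: float = 1.0,
        transition_prior_diag_bonus: float = 10.0,
        kmeans_n_init: int = 5,
        init_soft_eps: float = 0.05,
        cov_reg: float = 1e-8,
        random_state: int | None = None,
    ):
        self.n_states = n_states
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.transition_prior_count = transition_prior_count
        self.transition_prior_diag_bonus = transition_prior_diag_bonus
        self.kmeans_n_init = kmeans_n_init
        self.init_soft_eps = init_soft_eps
        self.cov_reg = cov_reg
        self.random_state = random_state

    # -- plumbing ----------------------------------------------------------

    @staticmethod
    def _as_matrix_boundaries(X, lengths) -> tuple[np.ndarray, list[tuple[int, int]]]:
        if isinstance(X, ConcatenatedDataset):
            return np.asarray(X.data, dtype=float), list(X.boundaries)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D (time points x regions) matrix")
        if lengths is None:
            lengths = [X.shape[0]]
        boundaries = []
        start = 0
        for L in lengths:
            boundaries.append((start, start + int(L)))
            start += int(L)
        if start != X.shape[0]:
            raise ValueError("lengths do not tile the rows of X")
        return X, boundaries

    def _make_priors(self, X: np.ndarray) -> VBPriors:
        K, R = self.n_states, X.shape[1]
        alpha_trans = np.full((K, K), float(self.transition_prior_count))
        alpha_trans[np.diag_indices(K)] += float(self.transition_prior_diag_bonus)
        m0 = X.mean(axis=0)
        Psi0 = np.cov(X, rowvar=False, ddof=1)
        Psi0 = np.atleast_2d(Psi0) + self.cov_reg * np.eye(R)
        return VBPriors(
            alpha_trans=alpha_trans,
            alpha_init=np.full(K, float(self.transition_prior_count)),
            m0=m0,
            kappa0=1.0,
            Psi0=Psi0,
            nu0=float(R + 2),
        )

    def init_responsibilities(self, X: np.ndarray, seed: int) -> np.ndarray:
        """K-means hard labels softened to responsibilities."""
        K = self.n_states
        if K == 1:
            return np.ones((X.shape[0], 1))
        km = KMeans(
            n_clusters=K, n_init=self.kmeans_n_init, random_state=seed
        ).fit(X)
        labels = km.labels_
        eps = self.init_soft_eps
        resp = np.full((X.shape[0], K), eps / (K - 1))
        resp[np.arange(X.shape[0]), labels] = 1.0 - eps
        return resp

    # -- core cycle --------------------------------------------------------

    def _initial_counts(
        self, gamma: np.ndarray, boundaries: Sequence[tuple[int, int]]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Approximate transition/initial counts from responsibilities only
        (used before the first forward-backward pass)."""
        K = gamma.shape[1]
        S = len(boundaries)
        trans = np.zeros((S, K, K))
        init = np.zeros(K)
        for i, (s, e) in enumerate(boundaries):
            g = gamma[s:e]
            trans[i] = g[:-1].T @ g[1:]
            init += g[0]
        return trans, init

    def _vb_cycle(
        self,
        X: np.ndarray,
        boundaries: Sequence[tuple[int, int]],
        state: VBState,
        priors: VBPriors,
    ) -> VBState:
        """One full M-then-E cycle; appends the new free energy."""
        post = _m_step(
            X, state.gamma, state.trans_counts.sum(axis=0), state.init_counts, priors
        )
        logb = _expected_log_lik(X, post, self.cov_reg)
        trans = np.exp(_dirichlet_expected_log(post.alpha_trans, axis=1))
        init = np.exp(_dirichlet_expected_log(post.alpha_init, axis=0))
        gamma, xi, log_norms = _e_step_all(logb, boundaries, trans, init)
        init_counts = np.add.reduce([gamma[s] for s, _ in boundaries])
        f = -(log_norms.sum() - _kl_total(post, priors, self.cov_reg))
        depleted = gamma.sum(axis=0) < 1e-6 * X.shape[0]
        return VBState(
            posterior=post,
            gamma=gamma,
            trans_counts=xi,
            init_counts=np.atleast_1d(init_counts),
            log_norms=log_norms,
            free_energy_trace=state.free_energy_trace + [float(f)],
            depleted=depleted,
        )

    def _fit_single(
        self,
        X: np.ndarray,
        boundaries: Sequence[tuple[int, int]],
        resp0: np.ndarray,
        priors: VBPriors,
    ) -> tuple[VBState, bool, int]:
        trans0, init0 = self._initial_counts(resp0, boundaries)
        state = VBState(
            posterior=None,  # type: ignore[arg-type]
            gamma=resp0,
            trans_counts=trans0,
            init_counts=init0,
            log_norms=np.zeros(len(boundaries)),
            free_energy_trace=[],
            depleted=np.zeros(resp0.shape[1], dtype=bool),
        )
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            state = self._vb_cycle(X, boundaries, state, priors)
            trace = state.free_energy_trace
            if len(trace) >= 2:
                prev, cur = trace[-2], trace[-1]
                if abs(cur - prev) / max(abs(prev), 1e-12) < self.tol:
                    converged = True
                    break
        return state, converged, n_iter

    # -- public API --------------------------------------------------------

    def fit(self, X, lengths=None):
        X, boundaries = self._as_matrix_boundaries(X, lengths)
        if X.shape[0] <= self.n_states:
            raise ValueError("need more time points than states")
        priors = self._make_priors(X)
        seeds = np.random.SeedSequence(self.random_state).generate_state(
            max(1, self.n_restarts)
        )
        best: tuple[VBState, bool, int] | None = None
        for seed in seeds:
            resp0 = self.init_responsibilities(X, int(seed) % (2**31))
            result = self._fit_single(X, boundaries, resp0, priors)
            if best is None or result[0].free_energy_trace[-1] < best[0].free_energy_trace[-1]:
                best = result
        assert best is not None
        state, self.converged_, self.n_iter_ = best
        self._finalize(state, priors)
        return self

    def _finalize(self, state: VBState, priors: VBPriors) -> None:
        post = state.posterior
        K, R = post.m.shape
        self.posterior_ = post
        self.priors_ = priors
        self.vb_state_ = state
        self.means_ = post.m.copy()
        covs = np.empty((K, R, R))
        for k in range(K):
            denom = post.nu[k] - R - 1
            covs[k] = post.Psi[k] / denom if denom > 0 else post.Psi[k] / post.nu[k]
        self.covariances_ = covs
        self.transmat_ = post.alpha_trans / post.alpha_trans.sum(axis=1, keepdims=True)
        self.startprob_ = post.alpha_init / post.alpha_init.sum()
        self.free_energy_trace_ = list(state.free_energy_trace)
        self.free_energy_ = float(state.free_energy_trace[-1])
        self.depleted_states_ = tuple(int(i) for i in np.flatnonzero(state.depleted))

    @property
    def model_(self) -> HMMModel:
        return HMMModel(
            K=self.n_states,
            means=self.means_,
            covariances=self.covariances_,
            transition=self.transmat_,
            initial=self.startprob_,
        )

    def predict(self, X, lengths=None) -> np.ndarray:
        """Viterbi state path(s) under the posterior-mean parameters."""
        X, boundaries = self._as_matrix_boundaries(X, lengths)
        model = self.model_
        return np.concatenate([viterbi(model, X[s:e]) for s, e in boundaries])

    def predict_proba(self, X, lengths=None) -> np.ndarray:
        """Posterior state marginals gamma under the variational posterior."""
        X, boundaries = self._as_matrix_boundaries(X, lengths)
        post = self.posterior_
        logb = _expected_log_lik(X, post, self.cov_reg)
        trans = np.exp(_dirichlet_expected_log(post.alpha_trans, axis=1))
        init = np.exp(_dirichlet_expected_log(post.alpha_init, axis=0))
        gamma, _, _ = _e_step_all(logb, boundaries, trans, init)
        return gamma

    def free_energy(self, X, lengths=None) -> float:
        """Variational free energy of the fitted posterior on the data."""
        X, boundaries = self._as_matrix_boundaries(X, lengths)
        post = self.posterior_
        logb = _expected_log_lik(X, post, self.cov_reg)
        trans = np.exp(_dirichlet_expected_log(post.alpha_trans, axis=1))
        init = np.exp(_dirichlet_expected_log(post.alpha_init, axis=0))
        _, _, log_norms = _e_step_all(logb, boundaries, trans, init)
        return float(-(log_norms.sum() - _kl_total(post, self.priors_, self.cov_reg)))

    def score(self, X, lengths=None) -> float:
        """Negative free energy (higher is better), sklearn-style."""
        return -self.free_energy(X, lengths)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def fit_hmm(
    dataset: ConcatenatedDataset, n_states: int, **options
) -> tuple[HMMModel, VariationalGaussianHMM]:
    """Fit a VB Gaussian HMM on a concatenated cohort; thin wrapper over
    :class:`VariationalGaussianHMM`."""
    est = VariationalGaussianHMM(n_states=n_states, **options)
    est.fit(dataset)
    return est.model_, est


def select_n_states(
    dataset: ConcatenatedDataset,
    k_grid: Sequence[int],
    *,
    band: float = 0.01,
    median_fo_step: float = 0.005,
    **options,
) -> KSelectionReport:
    """Model-order selection over a grid of K.

    Fits each K (restarts per ``options``) and keeps the minimum-free-energy
    restart.  Selection rule: among the K whose free energy lies within
    ``band`` (relative) of the grid minimum, pick the smallest.  The median
    (across states) of the pooled fractional occupancy is reported as a
    secondary diagnostic: the first K past which it stops decreasing by
    more than ``median_fo_step`` is flagged in the trace.
    """
    k_grid = [int(k) for k in k_grid]
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    free_energies: list[float] = []
    median_fos: list[float] = []
    trace_lines: list[str] = []
    N = dataset.data.shape[0]
    for k in k_grid:
        try:
            model, est = fit_hmm(dataset, k, **options)
        except Exception as exc:  # noqa: BLE001 - recorded, K excluded
            free_energies.append(np.inf)
            median_fos.append(np.nan)
            trace_lines.append(f"K={k}: fit failed ({exc}); excluded")
            continue
        path = est.predict(dataset)
        pooled_fo = np.bincount(path, minlength=k) / N
        free_energies.append(est.free_energy_)
        median_fos.append(float(np.median(pooled_fo)))
        trace_lines.append(
            f"K={k}: free_energy={est.free_energy_:.4f} "
            f"median_pooled_FO={median_fos[-1]:.4f} converged={est.converged_}"
        )
    finite = [f for f in free_energies if np.isfinite(f)]
    if not finite:
        raise RuntimeError("every K in the grid failed to fit")
    f_min = min(finite)
    # band is relative to the spread of free energies across the grid:
    # the absolute level of F carries a data-scale offset that says nothing
    # about model-order differences
    spread = max(finite) - f_min
    threshold = f_min + band * spread
    candidates = [
        k for k, f in zip(k_grid, free_energies) if np.isfinite(f) and f <= threshold
    ]
    selected = min(candidates)
    trace_lines.append(
        f"rule: free-energy band {band:.3g} around min {f_min:.4f} -> "
        f"candidates {candidates} -> selected K={selected}"
    )
    # secondary diagnostic: where does median FO stop improving
    order = np.argsort(k_grid)
    plateau_k = None
    for a, b in zip(order[:-1], order[1:]):
        fa, fb = median_fos[a], median_fos[b]
        if np.isfinite(fa) and np.isfinite(fb) and (fa - fb) <= median_fo_step:
            plateau_k = k_grid[a]
            break
    if plateau_k is not None:
        trace_lines.append(
            f"diagnostic: median pooled FO stops decreasing by more than "
            f"{median_fo_step:.3g} beyond K={plateau_k}"
        )
    return KSelectionReport(
        grid=tuple(k_grid),
        free_energy=tuple(free_energies),
        median_fo=tuple(median_fos),
        selected_k=selected,
        rule_trace="\n".join(trace_lines),
    )
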