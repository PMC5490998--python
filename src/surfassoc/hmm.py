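"""Per-fish two-state multivariate-normal hidden Markov model.

Each individual's binned (diving amplitude, thermal habitat) series is
modelled with a two-state Gaussian HMM fitted by Baum-Welch EM.  The state
with the warmer mean thermal habitat is labelled *shallow*; its smoothed
(forward-backward) marginal probability is the basis of the
surface-association probability downstream.

Invalid bins are treated as censored observations: their emission
likelihood is 1 for both states, so the chain stays on the contiguous
3-hour grid and the smoother bridges gaps with model-predicted marginals.
All recursions run in log space and remain stable for series of 1e4+ bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import multivariate_normal

from .io_tags import RunConfig
from .preprocess import BinnedSeries

#: Eigenvalue floor applied to emission covariances (prevents singular
#: emissions on zero-variance synthetic input).
COV_EIGVAL_FLOOR = 1e-6

#: Temperature-mean difference (degC) below which state labelling falls back
#: to the diving-amplitude criterion.
LABEL_TEMP_TOL = 1e-2


class HmmFitError(RuntimeError):
    """All EM restarts failed or collapsed."""


class LabelError(ValueError):
    """States indistinguishable under both labelling criteria."""


# ---------------------------------------------------------------------------
# Forward-backward kernel (numba-accelerated when available)
# ---------------------------------------------------------------------------

def _fb_kernel(logB: np.ndarray, logA: np.ndarray, logpi: np.ndarray):
    """Log-space forward-backward.

    Returns (gamma, loglik, xi_sum) where gamma[t, k] is the smoothed
    marginal P(state=k | all data) and xi_sum[i, j] the expected transition
    count summed over time.
    """
    T, K = logB.shape
    la = np.empty((T, K))
    lb = np.empty((T, K))
    for k in range(K):
        la[0, k] = logpi[k] + logB[0, k]
    for t in range(1, T):
        for k in range(K):
            m = -np.inf
            for j in range(K):
                v = la[t - 1, j] + logA[j, k]
                if v > m:
                    m = v
            if m == -np.inf:
                la[t, k] = -np.inf
                continue
            s = 0.0
            for j in range(K):
                s += math.exp(la[t - 1, j] + logA[j, k] - m)
            la[t, k] = m + math.log(s) + logB[t, k]

    m = -np.inf
    for k in range(K):
        if la[T - 1, k] > m:
            m = la[T - 1, k]
    s = 0.0
    for k in range(K):
        s += math.exp(la[T - 1, k] - m)
    loglik = m + math.log(s)

    for k in range(K):
        lb[T - 1, k] = 0.0
    for t in range(T - 2, -1, -1):
        for k in range(K):
            m = -np.inf
            for j in range(K):
                v = logA[k, j] + logB[t + 1, j] + lb[t + 1, j]
                if v > m:
                    m = v
            if m == -np.inf:
                lb[t, k] = -np.inf
                continue
            s = 0.0
            for j in range(K):
                s += math.exp(logA[k, j] + logB[t + 1, j] + lb[t + 1, j] - m)
            lb[t, k] = m + math.log(s)

    gamma = np.empty((T, K))
    for t in range(T):
        s = 0.0
        for k in range(K):
            v = la[t, k] + lb[t, k]
            gamma[t, k] = 0.0 if v == -np.inf else math.exp(v - loglik)
            s += gamma[t, k]
        for k in range(K):
            gamma[t, k] /= s

    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        for i in range(K):
            for j in range(K):
                v = (la[t, i] + logA[i, j]
                     + logB[t + 1, j] + lb[t + 1, j])
                if v > -np.inf:
                    xi_sum[i, j] += math.exp(v - loglik)
    return gamma, loglik, xi_sum


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _fb = njit(cache=True)(_fb_kernel)
except Exception:  # pragma: no cover
    _fb = _fb_kernel


def forward_backward(logB: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Smoothed state marginals for given log-emissions and parameters.

    ``logB[t, k]`` is the log emission density of bin t under state k (use
    0.0 for censored/missing bins).  Returns ``(gamma, loglik, xi_sum)``.
    """
    with np.errstate(divide="ignore"):
        logA = np.log(np.asarray(A, dtype=float))
        logpi = np.log(np.asarray(pi, dtype=float))
    return _fb(np.ascontiguousarray(logB, dtype=float), logA, logpi)


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class HmmModel:
    """Fitted two-state Gaussian HMM for one fish."""

    means: np.ndarray                  # (2, 2): [state, (depth_sd, temp_mean)]
    covs: np.ndarray                   # (2, 2, 2)
    transition: np.ndarray             # (2, 2), rows sum to 1
    initial: np.ndarray                # (2,)
    shallow_state: int = 0
    log_likelihood: float = np.nan
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    restarts_used: int = 0
    degenerate: bool = False           # covariance floor active at optimum
    log_depth_sd: bool = False         # emissions fitted on log1p(depth_sd)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covs = np.asarray(self.covs, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")
        if not math.isclose(float(self.initial.sum()), 1.0, abs_tol=1e-8):
            raise ValueError("initial distribution must sum to 1")
        for c in self.covs:
            if not np.allclose(c, c.T):
                raise ValueError("covariances must be symmetric")
            if np.linalg.eigvalsh(c)[0] <= 0:
                raise ValueError("covariances must be positive definite")

    def log_emissions(self, binned: BinnedSeries) -> np.ndarray:
        """(T, 2) log emission matrix; zeros at invalid bins."""
        X = binned.observations()
        if self.log_depth_sd:
            X = X.copy()
            X[:, 0] = np.log1p(X[:, 0])
        logB = np.zeros((len(binned), 2))
        v = binned.valid
        for k in range(2):
            logB[v, k] = multivariate_normal.logpdf(
                X[v], mean=self.means[k], cov=self.covs[k])
        return logB

    def to_json_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "covariances": self.covs.tolist(),
            "transition": self.transition.tolist(),
            "initial": self.initial.tolist(),
            "shallow_state": int(self.shallow_state),
            "log_likelihood": float(self.log_likelihood),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "restarts_used": int(self.restarts_used),
            "degenerate": bool(self.degenerate),
            "log_depth_sd": bool(self.log_depth_sd),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "HmmModel":
        return cls(
            means=np.array(d["means"]),
            covs=np.array(d["covariances"]),
            transition=np.array(d["transition"]),
            initial=np.array(d["initial"]),
            shallow_state=int(d["shallow_state"]),
            log_likelihood=float(d["log_likelihood"]),
            n_iter=int(d.get("n_iter", 0)),
            converged=bool(d.get("converged", False)),
            restarts_used=int(d.get("restarts_used", 0)),
            degenerate=bool(d.get("degenerate", False)),
            log_depth_sd=bool(d.get("log_depth_sd", False)),
        )


@dataclass
class StatePosteriors:
    """Smoothed per-bin shallow-state probabilities on the bin grid."""

    bin_starts: "np.ndarray"
    p_shallow: np.ndarray
    log_likelihood: float

    def __post_init__(self) -> None:
        p = self.p_shallow
        if np.any((p < -1e-12) | (p > 1 + 1e-12)):
            raise ValueError("posterior probabilities outside [0, 1]")
        self.p_shallow = np.clip(p, 0.0, 1.0)

    def __len__(self) -> int:
        return len(self.p_shallow)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _floor_cov(cov: np.ndarray) -> tuple[np.ndarray, bool]:
    w, V = np.linalg.eigh((cov + cov.T) / 2.0)
    floored = bool(np.any(w < COV_EIGVAL_FLOOR))
    w = np.maximum(w, COV_EIGVAL_FLOOR)
    return (V * w) @ V.T, floored


def _moment_init(X: np.ndarray, rng: np.random.Generator,
                 perturb: bool) -> tuple[np.ndarray, np.ndarray]:
    """Initial state means/covariances from a temperature-median split."""
    med = np.median(X[:, 1])
    hi = X[:, 1] >= med
    if hi.all() or (~hi).all():          # constant temperature
        hi = np.zeros(len(X), dtype=bool)
        hi[: len(X) // 2] = True
    means = np.stack([X[hi].mean(axis=0), X[~hi].mean(axis=0)])
    covs = np.stack([np.cov(X[hi].T) if hi.sum() > 1 else np.eye(2),
                     np.cov(X[~hi].T) if (~hi).sum() > 1 else np.eye(2)])
    if perturb:
        scale = X.std(axis=0) + 1e-3
        means = means + rng.normal(scale=0.5 * scale, size=means.shape)
    covs = np.stack([_floor_cov(c)[0] for c in covs])
    return means, covs


def fit_hmm(binned: BinnedSeries, config: RunConfig | None = None, *,
            seed: int | None = None) -> HmmModel:
    """Fit the two-state Gaussian HMM to a binned series by Baum-Welch EM.

    Runs ``config.em_restarts`` initializations (a temperature-median moment
    split, then seeded random perturbations of it) and keeps the highest
    log-likelihood fit.  A restart is discarded as collapsed when a state's
    total responsibility over observed bins drops below 2 or its covariance
    degenerates.  Raises :class:`HmmFitError` when every restart collapses.
    """
    config = config or RunConfig()
    if binned.n_valid < config.min_valid_bins:
        raise HmmFitError(
            f"only {binned.n_valid} valid bins; need >= {config.min_valid_bins}")
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)

    X_full = binned.observations()
    if config.log_depth_sd:
        X_full = X_full.copy()
        X_full[:, 0] = np.log1p(X_full[:, 0])
    v = binned.valid
    X = X_full[v]
    T = len(binned)

    best: HmmModel | None = None
    diagnostics: list[str] = []
    for r in range(max(1, config.em_restarts)):
        means, covs = _moment_init(X, rng, perturb=(r > 0))
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        if r > 0:
            stay = rng.uniform(0.7, 0.98, size=2)
            A = np.array([[stay[0], 1 - stay[0]], [1 - stay[1], stay[1]]])
        pi = np.array([0.5, 0.5])

        trace: list[float] = []
        failed = None
        floored = False
        for it in range(config.em_max_iter):
            # E-step
            logB = np.zeros((T, 2))
            try:
                for k in range(2):
                    logB[v, k] = multivariate_normal.logpdf(
                        X, mean=means[k], cov=covs[k])
            except np.linalg.LinAlgError:
                failed = "singular emission covariance"
                break
            gamma, loglik, xi_sum = forward_backward(logB, A, pi)
            if not np.isfinite(loglik):
                failed = "non-finite log-likelihood"
                break
            trace.append(float(loglik))
            # M-step
            g = gamma[v]
            totals = g.sum(axis=0)
            if totals.min() < 2.0:
                failed = f"state collapse (responsibility {totals.min():.3f})"
                break
            means = (g.T @ X) / totals[:, None]
            floored = False
            new_covs = np.empty_like(covs)
            for k in range(2):
                d = X - means[k]
                c = (d.T * g[:, k]) @ d / totals[k]
                new_covs[k], fl = _floor_cov(c)
                floored |= fl
            covs = new_covs
            A = xi_sum / xi_sum.sum(axis=1, keepdims=True)
            A = np.clip(A, 1e-12, None)
            A /= A.sum(axis=1, keepdims=True)
            pi = np.clip(gamma[0], 1e-12, None)
            pi /= pi.sum()
            if len(trace) > 1:
                rel = (trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-300)
                if rel < -1e-8:
                    failed = "log-likelihood decreased"
                    break
                if abs(rel) < config.em_tol:
                    break
        if failed is not None:
            diagnostics.append(f"restart {r}: {failed} after {len(trace)} iters")
            continue

        model = HmmModel(
            means=means, covs=covs, transition=A, initial=pi,
            log_likelihood=trace[-1], loglik_trace=trace,
            n_iter=len(trace), converged=len(trace) < config.em_max_iter,
            restarts_used=r + 1, degenerate=floored,
            log_depth_sd=config.log_depth_sd,
        )
        if best is None or model.log_likelihood > best.log_likelihood:
            model.restarts_used = r + 1
            best = model

    if best is None:
        raise HmmFitError("all EM restarts degenerate: " + "; ".join(diagnostics))
    best.shallow_state = label_shallow_state(best)
    return best


def label_shallow_state(model: HmmModel) -> int:
    """Index of the warm-shallow state.

    Primary criterion: larger mean thermal habitat.  When the state
    temperature means agree to within ``LABEL_TEMP_TOL`` degC the state with
    the smaller mean diving amplitude is taken; an exact tie on both raises
    :class:`LabelError`.
    """
    temp = model.means[:, 1]
    if abs(temp[0] - temp[1]) > LABEL_TEMP_TOL:
        return int(np.argmax(temp))
    amp = model.means[:, 0]
    if amp[0] == amp[1]:
        raise LabelError("states tie on both temperature and diving amplitude")
    return int(np.argmin(amp))


def smooth_posteriors(binned: BinnedSeries, model: HmmModel) -> StatePosteriors:
    """Forward-backward smoothed P(shallow) on the full contiguous grid.

    Invalid bins contribute unit emission likelihood, so their marginals are
    the model-propagated (bridged) probabilities rather than gaps.
    """
    logB = model.log_emissions(binned)
    gamma, loglik, _ = forward_backward(logB, model.transition, model.initial)
    return StatePosteriors(
        bin_starts=binned.bin_starts,
        p_shallow=gamma[:, model.shallow_state],
        log_likelihood=float(loglik),
    )
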