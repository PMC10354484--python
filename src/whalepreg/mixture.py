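"""Two-component normal mixture models fit by expectation-maximization.

The pregnancy classifier at the heart of this package models a set of
whale-year measurements (log faecal progesterone, standardized body width
at 50% of total length, or both jointly) as a mixture of two normal
components: a "non-pregnant" component with low means and a "pregnant"
component with high means.  The posterior probability that a whale-year
belongs to the high component is the pregnancy probability.

The EM routine is implemented in batched form: ``B`` independent datasets
(e.g. bootstrap resamples) are fit simultaneously as ``(B, n, d)`` arrays
with ``d`` in {1, 2}.  A single-dataset fit is the special case ``B =
n_inits`` (one row per initialization, best log-likelihood wins).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

_LOG_2PI = float(np.log(2.0 * np.pi))

__all__ = [
    "MixtureFit",
    "ComponentLabels",
    "TwoComponentNormalMixture",
    "em_fit",
    "label_components",
    "posterior_pregnancy",
]


# ---------------------------------------------------------------------------
# batched EM core


def _as_batch(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim == 2:
        X = X[None]
    if X.ndim != 3:
        raise ValueError(f"expected (n,), (n, d) or (B, n, d) data, got shape {X.shape}")
    if X.shape[-1] not in (1, 2):
        raise ValueError("only 1- or 2-dimensional mixtures are supported")
    if not np.all(np.isfinite(X)):
        raise ValueError("data contain non-finite entries")
    return X


def _m_step(X: np.ndarray, resp: np.ndarray):
    """Weighted moment updates. X (B,n,d), resp (B,n,2) -> (w, mu, cov)."""
    n = X.shape[1]
    nk = resp.sum(axis=1)  # (B,2)
    nk = np.maximum(nk, 1e-300)
    w = nk / n
    mu = np.einsum("bnk,bnd->bkd", resp, X) / nk[..., None]
    diff = X[:, None, :, :] - mu[:, :, None, :]  # (B,2,n,d)
    cov = np.einsum("bnk,bknd,bkne->bkde", resp, diff, diff) / nk[..., None, None]
    return w, mu, cov


def _min_eigenvalue(cov: np.ndarray) -> np.ndarray:
    """Smallest eigenvalue of each 1x1 or 2x2 covariance. cov (B,2,d,d) -> (B,2)."""
    d = cov.shape[-1]
    if d == 1:
        return cov[..., 0, 0]
    a = cov[..., 0, 0]
    b = cov[..., 0, 1]
    c = cov[..., 1, 1]
    disc = np.sqrt(np.maximum((a - c) ** 2 + 4.0 * b * b, 0.0))
    return 0.5 * (a + c - disc)


def _log_components(X: np.ndarray, w, mu, cov, include_weights: bool = True):
    """Per-component log density (optionally + log weight). -> (B,n,2)."""
    d = X.shape[-1]
    if d == 1:
        var = np.maximum(cov[..., 0, 0], 1e-300)  # (B,2)
        dx = X[..., 0][:, :, None] - mu[..., 0][:, None, :]  # (B,n,2)
        logpdf = -0.5 * (_LOG_2PI + np.log(var)[:, None, :] + dx * dx / var[:, None, :])
    else:
        a = cov[..., 0, 0]
        b = cov[..., 0, 1]
        c = cov[..., 1, 1]
        det = np.maximum(a * c - b * b, 1e-300)  # (B,2)
        dx = X[..., 0][:, :, None] - mu[..., 0][:, None, :]
        dy = X[..., 1][:, :, None] - mu[..., 1][:, None, :]
        quad = (
            c[:, None, :] * dx * dx
            - 2.0 * b[:, None, :] * dx * dy
            + a[:, None, :] * dy * dy
        ) / det[:, None, :]
        logpdf = -0.5 * (2.0 * _LOG_2PI + np.log(det)[:, None, :] + quad)
    if include_weights:
        logpdf = logpdf + np.log(np.maximum(w, 1e-300))[:, None, :]
    return logpdf


def _logsumexp2(lc: np.ndarray) -> np.ndarray:
    m = lc.max(axis=-1)
    return m + np.log(np.exp(lc[..., 0] - m) + np.exp(lc[..., 1] - m))


def _rank_split_resp(X: np.ndarray) -> np.ndarray:
    """Hard responsibilities from a lower/upper half split on the first variable."""
    B, n, _ = X.shape
    order = np.argsort(X[..., 0], axis=1, kind="stable")
    resp = np.zeros((B, n, 2))
    rows = np.arange(B)[:, None]
    half = n // 2
    resp[rows, order[:, :half], 0] = 1.0
    resp[rows, order[:, half:], 1] = 1.0
    return resp


def _batch_em(
    X: np.ndarray,
    resp0: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 1000,
    var_floor: float = 1e-10,
    max_restarts: int = 0,
    rng=None,
    keep_history: bool = False,
):
    """Run EM on B datasets at once from initial responsibilities.

    Returns a dict with weights, means, covariances, loglik, n_iter,
    converged and (optionally) the per-iteration log-likelihood history.

    A dataset whose fit degenerates (a covariance eigenvalue below
    ``var_floor``, the unbounded-likelihood spike at a repeated data
    value) is restarted from fresh random responsibilities up to
    ``max_restarts`` times — the standard mixture-EM remedy — and flagged
    non-convergent only when the restart budget or ``max_iter`` (per
    start) is exhausted.
    """
    B, n, d = X.shape
    w, mu, cov = _m_step(X, resp0)
    loglik = np.full(B, -np.inf)
    converged = np.zeros(B, dtype=bool)
    failed = np.zeros(B, dtype=bool)
    n_iter = np.zeros(B, dtype=int)
    iters_row = np.zeros(B, dtype=int)  # iterations since the row's last (re)start
    attempts = np.zeros(B, dtype=int)
    history: list[np.ndarray] = []
    if max_restarts > 0 and rng is None:
        rng = np.random.default_rng(0)

    def _collapse(w_k, cov_k):
        return (_min_eigenvalue(cov_k) < var_floor).any(axis=1) | (w_k.min(axis=1) <= 0.0)

    def _restart_or_fail(rows):
        """Restart collapsed rows from random responsibilities; fail the rest."""
        can = attempts[rows] < max_restarts
        give_up = rows[~can]
        failed[give_up] = True
        active[give_up] = False
        redo = rows[can]
        if redo.size:
            attempts[redo] += 1
            u = rng.uniform(size=(redo.size, n))
            resp = np.stack([u, 1.0 - u], axis=-1)
            w_r, mu_r, cov_r = _m_step(X[redo], resp)
            w[redo], mu[redo], cov[redo] = w_r, mu_r, cov_r
            loglik[redo] = -np.inf
            iters_row[redo] = 0
            again = redo[_collapse(w_r, cov_r)]
            if again.size:
                _restart_or_fail(again)

    active = np.ones(B, dtype=bool)
    bad0 = np.flatnonzero(_collapse(w, cov))
    if bad0.size:
        _restart_or_fail(bad0)

    cap = max_iter * (1 + max_restarts)
    for _ in range(cap):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Xa = X[idx]
        lc = _log_components(Xa, w[idx], mu[idx], cov[idx])
        lse = _logsumexp2(lc)
        ll_new = lse.sum(axis=1)
        delta = np.abs(ll_new - loglik[idx])
        conv = delta <= tol * np.abs(ll_new)
        loglik[idx] = ll_new
        iters_row[idx] += 1
        n_iter[idx] += 1
        if keep_history:
            history.append(loglik.copy())
        converged[idx[conv]] = True
        active[idx[conv]] = False
        cont = ~conv
        if not cont.any():
            continue
        still = idx[cont]
        resp = np.exp(lc[cont] - lse[cont][..., None])
        w_s, mu_s, cov_s = _m_step(X[still], resp)
        w[still], mu[still], cov[still] = w_s, mu_s, cov_s
        bad = np.flatnonzero(_collapse(w_s, cov_s))
        if bad.size:
            _restart_or_fail(still[bad])
        # rows that exhausted their per-start iteration budget
        tired = still[iters_row[still] >= max_iter]
        if tired.size:
            tired = tired[active[tired]]
            failed[tired] = True
            active[tired] = False

    converged &= ~failed
    out = {
        "weights": w,
        "means": mu,
        "covariances": cov,
        "loglik": loglik,
        "n_iter": n_iter,
        "converged": converged,
    }
    if keep_history:
        out["history"] = np.array(history) if history else np.empty((0, B))
    return out


def _high_component(means: np.ndarray):
    """Index of the dominating (elementwise larger-mean) component per fit.

    means (B,2,d) -> (high (B,), valid (B,)).  ``valid`` is False when
    neither component dominates in every dimension; ``high`` then falls
    back to the component larger in the first variable.
    """
    gt = means[:, 1, :] > means[:, 0, :]  # (B,d)
    lt = means[:, 1, :] < means[:, 0, :]
    second = gt.all(axis=1)
    first = lt.all(axis=1)
    valid = second | first
    high = np.where(second, 1, 0)
    fallback = (means[:, 1, 0] > means[:, 0, 0]).astype(int)
    high = np.where(valid, high, fallback)
    return high, valid


def _posterior_high_batch(
    X0: np.ndarray,
    w: np.ndarray,
    mu: np.ndarray,
    cov: np.ndarray,
    high: np.ndarray,
    weighting_mode: str = "responsibility",
) -> np.ndarray:
    """P(high component | x) for every fit x record. -> (B, n0)."""
    include = weighting_mode == "responsibility"
    B = w.shape[0]
    Xb = np.broadcast_to(X0[None], (B,) + X0.shape)
    lc = _log_components(Xb, w, mu, cov, include_weights=include)
    high_is_1 = (high == 1)[:, None]
    l_high = np.where(high_is_1, lc[..., 1], lc[..., 0])
    l_low = np.where(high_is_1, lc[..., 0], lc[..., 1])
    return expit(l_high - l_low)


# ---------------------------------------------------------------------------
# public surface


@dataclass
class MixtureFit:
    """Parameters of a fitted two-component normal mixture."""

    dim: int
    weights: np.ndarray  # (2,)
    means: np.ndarray  # (2, dim)
    covariances: np.ndarray  # (2, dim, dim)
    loglik: float
    n_iter: int
    converged: bool
    loglik_path: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "dim": self.dim,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "loglik": float(self.loglik),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass
class ComponentLabels:
    """Which component is the putative 'pregnant' one.

    ``valid`` is True only when the high component's mean strictly exceeds
    the low component's mean in every modelled dimension; bootstrap
    replicates with invalid labels are discarded by the retention rules.
    """

    high: int
    low: int
    valid: bool


class TwoComponentNormalMixture(BaseEstimator):
    """Two-component (multivariate) normal mixture classifier for pregnancy.

    Parameters
    ----------
    tol : float
        Relative log-likelihood improvement below which EM is declared
        converged.
    max_iter : int
        Maximum EM iterations per initialization.
    n_restarts : int
        Number of random-responsibility restarts in addition to the
        deterministic rank-split initialization; the best converged
        log-likelihood wins.
    var_floor : float
        Lower bound on covariance eigenvalues; a fit crossing it is
        flagged degenerate (non-convergent).
    weighting_mode : {"responsibility", "literal"}
        Whether the pregnancy probability includes the mixing weights
        (the standard posterior responsibility) or is the bare density
        ratio phi_H / (phi_H + phi_L).
    random_state : int, Generator or None
        Seed for the restart initializations.

    Attributes
    ----------
    weights_, means_, covariances_ : fitted mixture parameters, component
        0 first.  ``means_`` has shape (2, d).
    loglik_ : float, final log-likelihood.
    n_iter_ : iterations used by the winning initialization.
    converged_ : bool.
    high_component_ : index of the component with larger means.
    labels_valid_ : True when one component dominates in every dimension.
    """

    def __init__(
        self,
        tol: float = 1e-8,
        max_iter: int = 1000,
        n_restarts: int = 10,
        var_floor: float = 1e-10,
        weighting_mode: str = "literal",
        random_state=None,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.var_floor = var_floor
        self.weighting_mode = weighting_mode
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y=None, keep_history: bool = False):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2:
            raise ValueError("X must be a vector or an (n, d) matrix")
        n, d = X.shape
        if n < 4:
            raise ValueError(f"need at least 4 observations, got {n}")
        if self.weighting_mode not in ("responsibility", "literal"):
            raise ValueError(f"unknown weighting_mode {self.weighting_mode!r}")
        Xb = _as_batch(X)

        n_init = 1 + int(self.n_restarts)
        Xrep = np.broadcast_to(Xb[0], (n_init, n, d))
        resp0 = np.empty((n_init, n, 2))
        resp0[0] = _rank_split_resp(Xb)[0]
        if self.n_restarts > 0:
            rng = np.random.default_rng(self.random_state)
            u = rng.uniform(size=(self.n_restarts, n))
            resp0[1:, :, 0] = u
            resp0[1:, :, 1] = 1.0 - u

        res = _batch_em(
            np.ascontiguousarray(Xrep),
            resp0,
            tol=self.tol,
            max_iter=self.max_iter,
            var_floor=self.var_floor,
            keep_history=keep_history,
        )
        ll = np.where(res["converged"], res["loglik"], -np.inf)
        if np.isinf(ll).all():
            best = int(np.argmax(res["loglik"]))
        else:
            best = int(np.argmax(ll))

        self.n_features_in_ = d
        self.weights_ = res["weights"][best]
        self.means_ = res["means"][best]
        self.covariances_ = res["covariances"][best]
        self.loglik_ = float(res["loglik"][best])
        self.n_iter_ = int(res["n_iter"][best])
        self.converged_ = bool(res["converged"][best])
        high, valid = _high_component(res["means"][best : best + 1])
        self.high_component_ = int(high[0])
        self.labels_valid_ = bool(valid[0])
        if keep_history:
            hist = res["history"][:, best]
            self.loglik_path_ = hist[np.isfinite(hist)]
        return self

    # -- inference --------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "means_"):
            raise AttributeError("estimator is not fitted; call fit() first")

    def pregnancy_probability(self, X, weighting_mode: str | None = None) -> np.ndarray:
        """Posterior probability of the high-mean ('pregnant') component."""
        self._check_fitted()
        mode = self.weighting_mode if weighting_mode is None else weighting_mode
        if mode not in ("responsibility", "literal"):
            raise ValueError(f"unknown weighting_mode {mode!r}")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None] if self.n_features_in_ == 1 else X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has the wrong number of variables for this fit")
        p = _posterior_high_batch(
            X,
            self.weights_[None],
            self.means_[None],
            self.covariances_[None],
            np.array([self.high_component_]),
            weighting_mode=mode,
        )
        return p[0]

    def predict_proba(self, X) -> np.ndarray:
        """(n, 2) matrix of [P(not pregnant), P(pregnant)]."""
        p = self.pregnancy_probability(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X, threshold: float = 0.75) -> np.ndarray:
        return (self.pregnancy_probability(X) >= threshold).astype(int)

    def score(self, X, y=None) -> float:
        """Mean per-observation log-likelihood under the fitted mixture."""
        self._check_fitted()
        Xb = _as_batch(np.asarray(X, dtype=float))
        lc = _log_components(Xb, self.weights_[None], self.means_[None], self.covariances_[None])
        return float(_logsumexp2(lc).mean())

    def to_fit(self) -> MixtureFit:
        self._check_fitted()
        return MixtureFit(
            dim=self.n_features_in_,
            weights=self.weights_.copy(),
            means=self.means_.copy(),
            covariances=self.covariances_.copy(),
            loglik=self.loglik_,
            n_iter=self.n_iter_,
            converged=self.converged_,
            loglik_path=getattr(self, "loglik_path_", None),
        )


def em_fit(
    data,
    init_strategy: str = "rank+random",
    tol: float = 1e-8,
    max_iter: int = 1000,
    rng=None,
    n_restarts: int | None = None,
    var_floor: float = 1e-10,
) -> MixtureFit:
    """Fit a two-component normal mixture by EM and return its parameters.

    ``init_strategy`` is either "rank" (deterministic lower/upper-half
    split on the first variable) or "rank+random" (the split plus
    ``n_restarts`` random-responsibility restarts, best likelihood wins).
    """
    if init_strategy not in ("rank", "rank+random"):
        raise ValueError(f"unknown init_strategy {init_strategy!r}")
    if n_restarts is None:
        n_restarts = 10 if init_strategy == "rank+random" else 0
    if init_strategy == "rank":
        n_restarts = 0
    est = TwoComponentNormalMixture(
        tol=tol,
        max_iter=max_iter,
        n_restarts=n_restarts,
        var_floor=var_floor,
        random_state=rng,
    )
    est.fit(data, keep_history=True)
    return est.to_fit()


def label_components(fit: MixtureFit) -> ComponentLabels:
    """Identify the 'pregnant' (elementwise higher-mean) component."""
    high, valid = _high_component(fit.means[None])
    h = int(high[0])
    return ComponentLabels(high=h, low=1 - h, valid=bool(valid[0]))


def posterior_pregnancy(
    fit: MixtureFit,
    labels: ComponentLabels,
    x,
    weighting_mode: str = "literal",
) -> np.ndarray | float:
    """Posterior probability that ``x`` belongs to the pregnant component.

    Computed in log space so that points far in the tails of both
    components still yield a finite probability.  With
    ``weighting_mode="responsibility"`` the mixing weights enter
    (lambda_H phi_H / (lambda_H phi_H + lambda_L phi_L)); with
    ``"literal"`` the bare density ratio phi_H / (phi_H + phi_L) is used.
    """
    if not labels.valid:
        raise ValueError("component labels are not valid (no dominating component)")
    if weighting_mode not in ("responsibility", "literal"):
        raise ValueError(f"unknown weighting_mode {weighting_mode!r}")
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0 or (x.ndim == 1 and fit.dim > 1)
    if x.ndim == 0:
        x = x[None, None]
    elif x.ndim == 1:
        x = x[None, :] if fit.dim > 1 else x[:, None]
    if x.shape[1] != fit.dim:
        raise ValueError("x has the wrong dimension for this fit")
    p = _posterior_high_batch(
        x,
        fit.weights[None],
        fit.means[None],
        fit.covariances[None],
        np.array([labels.high]),
        weighting_mode=weighting_mode,
    )[0]
    return float(p[0]) if scalar else p
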