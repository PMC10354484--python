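"""Constrained non-parametric bootstrap for per-whale pregnancy probabilities.

Records from confirmed-pregnant females (PF) are few, so they are forced
into every bootstrap sample; the remaining slots are drawn with
replacement from the other records.  Each replicate refits the
two-component mixture, replicates are retained only if the fit converged
AND one component's mean strictly dominates in every modelled variable,
and every retained fit is evaluated at every original record.  Per-record
summaries (point estimate, quartiles, 95% percentile interval) are taken
across retained replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .mixture import (
    _batch_em,
    _high_component,
    _posterior_high_batch,
    _rank_split_resp,
)

__all__ = [
    "BootstrapConfig",
    "BootstrapSummary",
    "RetentionReport",
    "BootstrapPregnancyModel",
    "draw_bootstrap_sample",
    "run_bootstrap",
    "summarize_probabilities",
]


@dataclass
class BootstrapConfig:
    """Settings of the constrained bootstrap."""

    n_boot: int = 10_000
    forced_ids: tuple = ()
    seed: int | None = None
    point_rule: str = "median"  # "median" (univariate models) or "mean" (joint)
    weighting_mode: str = "literal"
    dither: float | tuple | None = None
    resample_forced: bool = False
    tol: float = 1e-8
    max_iter: int = 5000
    var_floor: float = 1e-10
    max_restarts: int = 20

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


@dataclass
class BootstrapSummary:
    """Per-record pregnancy probability summary across retained replicates."""

    record_id: object
    point: float
    mean: float
    median: float
    lq: float
    uq: float
    ci_low: float
    ci_high: float
    n_retained: int


@dataclass
class RetentionReport:
    model_id: str
    n_boot: int
    n_retained: int

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_boot


def draw_bootstrap_sample(records, forced_mask, rng, n_draws: int | None = None):
    """Index vector of one bootstrap sample: forced records once each plus
    draws with replacement from the non-forced pool.  Sample size equals
    the dataset size unless ``n_draws`` overrides the resampled part."""
    records = np.asarray(records)
    forced_mask = np.asarray(forced_mask, dtype=bool)
    n = len(records)
    forced_idx = np.flatnonzero(forced_mask)
    free_idx = np.flatnonzero(~forced_mask)
    if n_draws is None:
        n_draws = n - forced_idx.size
    if free_idx.size == 0:
        drawn = np.empty(0, dtype=int)
    else:
        drawn = free_idx[rng.integers(0, free_idx.size, size=n_draws)]
    return np.concatenate([forced_idx, drawn])


class BootstrapPregnancyModel(BaseEstimator):
    """Pregnancy probabilities with bootstrap uncertainty, sklearn-style.

    ``fit(X, forced=...)`` runs the full constrained bootstrap on the
    records in ``X`` (shape ``(n,)`` or ``(n, d)``, ``d`` in {1, 2}) and
    evaluates every retained replicate's mixture at every original record.

    Parameters mirror :class:`BootstrapConfig`.  ``point_rule`` selects
    the reported point estimate: "median" (used for the univariate
    models) or "mean" (used for the joint fP4m+W50 model).

    Attributes
    ----------
    summaries_ : DataFrame with point, mean, median, lq, uq, ci_low,
        ci_high per original record.
    probabilities_ : (n_retained, n) matrix of per-replicate probabilities.
    retention_ : RetentionReport.
    n_retained_ : int.
    """

    def __init__(
        self,
        n_boot: int = 10_000,
        point_rule: str = "median",
        weighting_mode: str = "literal",
        dither=None,
        resample_forced: bool = False,
        tol: float = 1e-8,
        max_iter: int = 5000,
        var_floor: float = 1e-10,
        max_restarts: int = 20,
        random_state=None,
        model_id: str = "model",
    ):
        self.n_boot = n_boot
        self.point_rule = point_rule
        self.weighting_mode = weighting_mode
        self.dither = dither
        self.resample_forced = resample_forced
        self.tol = tol
        self.max_iter = max_iter
        self.var_floor = var_floor
        self.max_restarts = max_restarts
        self.random_state = random_state
        self.model_id = model_id

    def fit(self, X, y=None, forced=None, record_ids=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n, d = X.shape
        if self.point_rule not in ("median", "mean"):
            raise ValueError(f"unknown point_rule {self.point_rule!r}")
        if forced is None:
            forced = np.zeros(n, dtype=bool)
        forced = np.asarray(forced, dtype=bool)
        if forced.shape != (n,):
            raise ValueError("forced mask must align with the records")
        n_forced = int(forced.sum())
        if n < n_forced + 2:
            raise ValueError("need at least two non-forced records to resample")
        if record_ids is None:
            record_ids = np.arange(n)

        rng = np.random.default_rng(self.random_state)
        B = int(self.n_boot)
        forced_idx = np.flatnonzero(forced)
        free_idx = np.flatnonzero(~forced)
        if self.resample_forced:
            # alternative reading: resample from everyone, then union with PF
            pool = np.arange(n)
            drawn = pool[rng.integers(0, n, size=(B, n - n_forced))]
        else:
            drawn = free_idx[rng.integers(0, free_idx.size, size=(B, n - n_forced))]
        idx = np.concatenate([np.broadcast_to(forced_idx, (B, n_forced)), drawn], axis=1)
        Xb = X[idx]  # (B, n, d)
        if self.dither is not None:
            # smoothed bootstrap for values printed at finite resolution:
            # each resampled value is drawn uniformly from its rounding
            # interval (half-width = dither); evaluation stays at the
            # original values
            h = np.broadcast_to(np.asarray(self.dither, dtype=float), (d,))
            Xb = Xb + rng.uniform(-1.0, 1.0, size=Xb.shape) * h

        # one deterministic median-split init per replicate.  The mixture
        # likelihood is unbounded (spiky local optima at tight clumps), so
        # chasing the highest likelihood across many inits drifts toward
        # degenerate solutions; a single moderate init targets the
        # well-behaved two-component optimum.
        res = _batch_em(
            Xb,
            _rank_split_resp(Xb),
            tol=self.tol,
            max_iter=self.max_iter,
            var_floor=self.var_floor,
            max_restarts=self.max_restarts,
            rng=rng,
        )
        high, valid = _high_component(res["means"])
        retained = res["converged"] & valid
        n_ret = int(retained.sum())
        self.retention_ = RetentionReport(self.model_id, B, n_ret)
        self.n_retained_ = n_ret
        if n_ret == 0:
            raise RuntimeError(
                f"no bootstrap replicate of {self.model_id!r} passed the retention "
                f"rules ({int(res['converged'].sum())} converged of {B}); "
                "the data may be degenerate"
            )

        self._w_ret = res["weights"][retained]
        self._mu_ret = res["means"][retained]
        self._cov_ret = res["covariances"][retained]
        self._high_ret = high[retained]
        probs = _posterior_high_batch(
            X,
            self._w_ret,
            self._mu_ret,
            self._cov_ret,
            self._high_ret,
            weighting_mode=self.weighting_mode,
        )
        self.probabilities_ = probs
        self.sample_indices_ = idx
        self.retained_mask_ = retained
        self.record_ids_ = np.asarray(record_ids)
        self.n_features_in_ = d
        self.summaries_ = _summary_frame(probs, self.record_ids_, self.point_rule)
        return self

    def predict_proba(self, X=None) -> np.ndarray:
        """(n, 2) [P(not pregnant), P(pregnant)] point estimates.

        With no argument, returns the summaries for the fitted records;
        otherwise every retained replicate fit is re-evaluated at ``X``."""
        if X is None:
            p = self.summaries_["point"].to_numpy()
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            probs = _posterior_high_batch(
                X,
                self._w_ret,
                self._mu_ret,
                self._cov_ret,
                self._high_ret,
                weighting_mode=self.weighting_mode,
            )
            p = np.median(probs, axis=0) if self.point_rule == "median" else probs.mean(axis=0)
        return np.column_stack([1.0 - p, p])

    def predict(self, X=None, threshold: float = 0.75) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= threshold).astype(int)


def _percentile(a: np.ndarray, q: float) -> np.ndarray:
    # linear-interpolation quantile convention, stated explicitly because
    # quantile definitions differ across ecosystems
    return np.percentile(a, q, axis=0, method="linear")


def _summary_frame(probs: np.ndarray, record_ids, point_rule: str) -> pd.DataFrame:
    mean = probs.mean(axis=0)
    median = _percentile(probs, 50)
    point = mean if point_rule == "mean" else median
    df = pd.DataFrame(
        {
            "record_id": record_ids,
            "point": point,
            "mean": mean,
            "median": median,
            "lq": _percentile(probs, 25),
            "uq": _percentile(probs, 75),
            "ci_low": _percentile(probs, 2.5),
            "ci_high": _percentile(probs, 97.5),
            "n_retained": probs.shape[0],
        }
    )
    return df


def summarize_probabilities(probs, record_id=None, point_rule: str = "median") -> BootstrapSummary:
    """Summarize one record's retained-replicate probabilities."""
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise ValueError("need at least one retained probability")
    if point_rule not in ("median", "mean"):
        raise ValueError(f"unknown point_rule {point_rule!r}")
    mean = float(probs.mean())
    median = float(np.percentile(probs, 50, method="linear"))
    return BootstrapSummary(
        record_id=record_id,
        point=mean if point_rule == "mean" else median,
        mean=mean,
        median=median,
        lq=float(np.percentile(probs, 25, method="linear")),
        uq=float(np.percentile(probs, 75, method="linear")),
        ci_low=float(np.percentile(probs, 2.5, method="linear")),
        ci_high=float(np.percentile(probs, 97.5, method="linear")),
        n_retained=probs.size,
    )


def run_bootstrap(records, forced, config: BootstrapConfig, record_ids=None, model_id="model"):
    """Functional wrapper: run the constrained bootstrap, return
    (list of BootstrapSummary, RetentionReport)."""
    est = BootstrapPregnancyModel(
        n_boot=config.n_boot,
        point_rule=config.point_rule,
        weighting_mode=config.weighting_mode,
        dither=config.dither,
        resample_forced=config.resample_forced,
        tol=config.tol,
        max_iter=config.max_iter,
        var_floor=config.var_floor,
        max_restarts=config.max_restarts,
        random_state=config.seed,
        model_id=model_id,
    )
    est.fit(records, forced=forced, record_ids=record_ids)
    summaries = [
        summarize_probabilities(est.probabilities_[:, j], rid, config.point_rule)
        for j, rid in enumerate(est.record_ids_)
    ]
    return summaries, est.retention_
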