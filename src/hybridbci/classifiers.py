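"""Shrinkage LDA, per-trial supervised adaptation, meta-combination and
threshold gating.

The binary discriminant is ``w^T x + b`` with

    w = ((1 - gamma) * Sigma + gamma * nu * I)^{-1} (mu2 - mu1)
    b = -w^T (mu1 + mu2) / 2,        nu = trace(Sigma) / d

where ``Sigma`` is the pooled within-class covariance and ``gamma`` the
analytic (Ledoit-Wolf) shrinkage coefficient.  Positive scores vote for
class 2.  During the labeled CopyTask phase the class means and pooled
covariance are re-estimated after every trial with an exponential moving
average at the adaptation rate (default 0.03); recomputing ``b`` from the
updated means is the implicit bias correction.  No adaptation happens in
FreeMode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.covariance import ledoit_wolf_shrinkage

__all__ = [
    "LDAModel",
    "AdaptationState",
    "MetaClassifier",
    "DecisionPolicy",
    "ShrinkageLDA",
    "train_shrinkage_lda",
    "lda_score",
    "adapt",
    "combine",
    "decide",
    "NO_DECISION",
]

#: Sentinel decision for trials whose accumulated output stays in the gate.
NO_DECISION = "noDecision"


def _solve_w_b(mu1, mu2, sigma, gamma):
    d = sigma.shape[0]
    nu = np.trace(sigma) / d
    shrunk = (1.0 - gamma) * sigma + gamma * nu * np.eye(d)
    w = np.linalg.solve(shrunk, mu2 - mu1)
    b = -float(w @ (mu1 + mu2) / 2.0)
    return w, b


@dataclass
class LDAModel:
    """Moments plus the derived discriminant of a shrinkage LDA."""

    mu1: np.ndarray
    mu2: np.ndarray
    sigma: np.ndarray
    gamma: float
    w: np.ndarray = field(default=None)  # type: ignore[assignment]
    b: float = 0.0

    def __post_init__(self) -> None:
        self.mu1 = np.asarray(self.mu1, dtype=np.float64)
        self.mu2 = np.asarray(self.mu2, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.w is None:
            self.w, self.b = _solve_w_b(self.mu1, self.mu2, self.sigma, self.gamma)
        else:
            self.w = np.asarray(self.w, dtype=np.float64)

    @property
    def dim(self) -> int:
        return self.mu1.size

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {
            "mu1": self.mu1.tolist(), "mu2": self.mu2.tolist(),
            "sigma": self.sigma.tolist(), "gamma": self.gamma,
            "w": self.w.tolist(), "b": self.b,
        }
        if path is not None:
            Path(path).write_text(json.dumps(d))
        return d

    @classmethod
    def from_json(cls, src: dict | str | Path) -> "LDAModel":
        if not isinstance(src, dict):
            src = json.loads(Path(src).read_text())
        return cls(
            mu1=np.asarray(src["mu1"]), mu2=np.asarray(src["mu2"]),
            sigma=np.asarray(src["sigma"]), gamma=float(src["gamma"]),
            w=np.asarray(src["w"]), b=float(src["b"]),
        )


@dataclass
class AdaptationState:
    """Supervised adaptation bookkeeping (rate is the EMA coefficient)."""

    rate: float = 0.03
    n_updates: int = 0
    enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"adaptation rate must be in [0, 1], got {self.rate}")


def train_shrinkage_lda(
    X: np.ndarray, y: np.ndarray, gamma: float | str = "auto"
) -> LDAModel:
    """Fit a shrinkage LDA on features *X* (n, d) and labels in {1, 2}.

    ``gamma="auto"`` uses the analytic Ledoit-Wolf shrinkage estimate on
    the class-centered pooled data; a float in [0, 1] forces the value.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    if set(np.unique(y)) != {1, 2}:
        raise ValueError("both classes {1, 2} must be present")
    X1, X2 = X[y == 1], X[y == 2]
    if len(X1) < 2 or len(X2) < 2:
        raise ValueError("need >= 2 samples per class")
    mu1, mu2 = X1.mean(axis=0), X2.mean(axis=0)
    centered = np.vstack([X1 - mu1, X2 - mu2])
    n = len(centered)
    sigma = centered.T @ centered / n
    if gamma == "auto":
        gamma_val = float(ledoit_wolf_shrinkage(centered, assume_centered=True))
    else:
        gamma_val = float(gamma)
    return LDAModel(mu1=mu1, mu2=mu2, sigma=sigma, gamma=gamma_val)


def lda_score(m: LDAModel, x: np.ndarray) -> float | np.ndarray:
    """Signed discriminant ``w^T x + b``; positive votes for class 2.

    Accepts a single feature vector or an (n, d) array.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != m.dim:
        raise ValueError(f"feature dim {x.shape[-1]} != model dim {m.dim}")
    s = x @ m.w + m.b
    return float(s) if s.ndim == 0 else s


def adapt(
    m: LDAModel, st: AdaptationState, x: np.ndarray, y_true: int
) -> LDAModel:
    """One supervised EMA update of the moments; returns a new model.

    mu_y <- (1-eta) mu_y + eta x; Sigma <- (1-eta) Sigma +
    eta (x - mu_pool)(x - mu_pool)^T with mu_pool the post-update mean of
    the two class means.  gamma stays frozen; w and b are recomputed, so
    the bias correction is implicit in b.
    """
    if not st.enabled:
        raise RuntimeError("adaptation is disabled (FreeMode performs none)")
    if y_true not in (1, 2):
        raise ValueError(f"y_true must be 1 or 2, got {y_true}")
    x = np.asarray(x, dtype=np.float64)
    if x.shape != m.mu1.shape:
        raise ValueError("feature dimension mismatch")
    eta = st.rate
    mu1, mu2 = m.mu1.copy(), m.mu2.copy()
    if y_true == 1:
        mu1 = (1 - eta) * mu1 + eta * x
    else:
        mu2 = (1 - eta) * mu2 + eta * x
    mu_pool = (mu1 + mu2) / 2.0
    dev = x - mu_pool
    sigma = (1 - eta) * m.sigma + eta * np.outer(dev, dev)
    st.n_updates += 1
    return LDAModel(mu1=mu1, mu2=mu2, sigma=sigma, gamma=m.gamma)


class ShrinkageLDA(ClassifierMixin, BaseEstimator):
    """sklearn-style front end over :class:`LDAModel`.

    Parameters
    ----------
    gamma : "auto" or float in [0, 1]
        Shrinkage coefficient; "auto" = analytic Ledoit-Wolf.
    adaptation_rate : float
        EMA rate used by :meth:`adapt_one` (labeled online updates).
    """

    def __init__(self, gamma: float | str = "auto", adaptation_rate: float = 0.03):
        self.gamma = gamma
        self.adaptation_rate = adaptation_rate

    def fit(self, X, y):
        self.model_ = train_shrinkage_lda(X, y, gamma=self.gamma)
        self.adaptation_ = AdaptationState(rate=self.adaptation_rate)
        self.classes_ = np.array([1, 2])
        # training-score scale, used to make branch outputs commensurate
        s = lda_score(self.model_, np.asarray(X, dtype=np.float64))
        self.score_scale_ = float(np.std(s)) or 1.0
        return self

    def decision_function(self, X):
        return lda_score(self.model_, X)

    def predict(self, X):
        s = np.atleast_1d(self.decision_function(X))
        return np.where(s > 0, 2, 1)

    def adapt_one(self, x, y_true) -> "ShrinkageLDA":
        """Labeled per-trial update (CopyTask); modifies the model in place."""
        self.model_ = adapt(self.model_, self.adaptation_, x, y_true)
        return self


@dataclass
class MetaClassifier:
    """Weighted sum of the two branch outputs.

    Each member score is divided by its training-set score scale before
    weighting, so the weights compare like with like.  ``active_output``
    selects which signal drives the application: "oscillatory", "slow" or
    "combined".
    """

    weights: tuple[float, float]  # (w_osc, w_slow), nonnegative, sum 1
    scales: tuple[float, float] = (1.0, 1.0)
    active_output: str = "combined"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        self.weights = tuple(w / w.sum())
        if self.active_output not in ("oscillatory", "slow", "combined"):
            raise ValueError(f"invalid active_output {self.active_output!r}")

    @classmethod
    def from_cv_accuracies(
        cls, acc_osc: float, acc_slow: float, scales=(1.0, 1.0),
        active_output: str = "combined",
    ) -> "MetaClassifier":
        """Weights proportional to max(0, CV accuracy - 0.5) per member."""
        w = np.maximum([acc_osc - 0.5, acc_slow - 0.5], 0.0)
        if w.sum() == 0:  # neither branch beats chance: fall back to equal
            w = np.array([0.5, 0.5])
        return cls(weights=tuple(w), scales=tuple(scales),
                   active_output=active_output)


def combine(meta: MetaClassifier, s_osc: float, s_slow: float) -> float:
    """The application-facing control signal for one frame or trial."""
    z_osc = s_osc / meta.scales[0]
    z_slow = s_slow / meta.scales[1]
    if meta.active_output == "oscillatory":
        return float(z_osc)
    if meta.active_output == "slow":
        return float(z_slow)
    w_osc, w_slow = meta.weights
    return float(w_osc * z_osc + w_slow * z_slow)


@dataclass
class DecisionPolicy:
    """Threshold gate on the accumulated output.

    Scores below ``-theta`` map to ``action_negative``, above ``+theta``
    to ``action_positive``; the closed interval ``[-theta, theta]``
    (boundary included) yields :data:`NO_DECISION`.
    """

    theta: float = 0.0
    action_negative: str = "select_next_column"
    action_positive: str = "place_coin"

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be nonnegative")


def decide(policy: DecisionPolicy, accumulated: float) -> str:
    if accumulated < -policy.theta:
        return policy.action_negative
    if accumulated > policy.theta:
        return policy.action_positive
    return NO_DECISION


def calibrate_theta(
    accumulated: np.ndarray, labels: np.ndarray,
    target_precision: float = 0.8,
) -> float:
    """Smallest theta reaching *target_precision* on decided trials.

    Candidate thresholds are the observed |accumulated| values; a trial is
    decided when |accumulated| > theta and counted correct when the sign
    matches the label (negative = class 1).  Returns 0.0 if the target is
    already met ungated, and the largest candidate if it is never met.
    """
    accumulated = np.asarray(accumulated, dtype=np.float64)
    labels = np.asarray(labels)
    signs = np.where(labels == 2, 1.0, -1.0)
    candidates = np.r_[0.0, np.sort(np.abs(accumulated))]
    for theta in candidates:
        decided = np.abs(accumulated) > theta
        if not decided.any():
            break
        precision = np.mean(np.sign(accumulated[decided]) == signs[decided])
        if precision >= target_precision:
            return float(theta)
    return float(candidates[-1])
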