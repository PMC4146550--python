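"""Feature extraction: the two branches of the hybrid pipeline.

Oscillatory branch: Common Spatial Patterns on the band-passed epochs,
log-variance of the projected signal as the per-trial feature.

Slow-potential branch: per-channel mean amplitude of the 0.2-4 Hz filtered,
baseline-corrected epochs over a class-discriminative interval (the
lateralized readiness potential, LRP).

Discriminability screening uses ssAUC, a signed and scaled area under the
ROC curve: ``2*(AUC - 0.5)`` in [-1, 1], positive where class-2 values are
larger.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg, stats
from sklearn.base import BaseEstimator, TransformerMixin

from .eeg import EpochSet

__all__ = [
    "SpatialFilterBank",
    "CSP",
    "fit_csp",
    "csp_logvar",
    "lrp_features",
    "ssauc",
    "ssauc_map",
]


@dataclass
class SpatialFilterBank:
    """Fitted CSP filters with their visualizable scalp patterns.

    ``filters`` is components x channels (rows project the signal);
    ``patterns`` is channels x components (columns are scalp patterns);
    ``eigenvalues`` is the class-1 variance ratio per component in [0, 1],
    sorted descending.  ``selected`` indexes the retained components, an
    even count taken half from each end of the spectrum.
    """

    filters: np.ndarray
    patterns: np.ndarray
    eigenvalues: np.ndarray
    selected: np.ndarray
    channel_labels: list[str] = field(default_factory=list)
    interval: tuple[float, float] | None = None

    @property
    def selected_filters(self) -> np.ndarray:
        return self.filters[self.selected]

    @property
    def selected_patterns(self) -> np.ndarray:
        return self.patterns[:, self.selected]

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {
            "filters": self.filters.tolist(),
            "patterns": self.patterns.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "selected": self.selected.tolist(),
            "channel_labels": self.channel_labels,
            "interval": list(self.interval) if self.interval else None,
        }
        if path is not None:
            Path(path).write_text(json.dumps(d))
        return d

    @classmethod
    def from_json(cls, src: dict | str | Path) -> "SpatialFilterBank":
        if not isinstance(src, dict):
            src = json.loads(Path(src).read_text())
        return cls(
            filters=np.asarray(src["filters"]),
            patterns=np.asarray(src["patterns"]),
            eigenvalues=np.asarray(src["eigenvalues"]),
            selected=np.asarray(src["selected"], dtype=int),
            channel_labels=list(src.get("channel_labels", [])),
            interval=tuple(src["interval"]) if src.get("interval") else None,
        )


def _class_covariances(X: np.ndarray, y: np.ndarray, reg: float):
    """Trace-normalized per-trial covariances averaged within class."""
    covs = {}
    for c in (1, 2):
        trials = X[y == c]
        if len(trials) < 2:
            raise ValueError(f"need >= 2 trials of class {c}, got {len(trials)}")
        acc = np.zeros((X.shape[1], X.shape[1]))
        for tr in trials:
            C = tr @ tr.T
            t = np.trace(C)
            if t <= 0:
                raise ValueError("zero-variance trial; cannot normalize covariance")
            acc += C / t
        C = acc / len(trials)
        covs[c] = C + reg * np.trace(C) * np.eye(C.shape[0])
    return covs[1], covs[2]


class CSP(TransformerMixin, BaseEstimator):
    """Common Spatial Patterns with log-variance features.

    fit(X, y) expects ``X`` of shape (trials, channels, samples) with
    binary labels in {1, 2}; transform returns (trials, n_components)
    log-variance features of the projected signal.

    The decomposition solves the generalized eigenproblem
    ``C1 v = lambda (C1 + C2) v`` on trace-normalized, class-averaged
    spatial covariances, so each eigenvalue is the fraction of (whitened)
    variance carried by class 1 and eigenvalues of the two classes sum to
    one per component.  Components are kept half from each end of the
    sorted spectrum, where class contrast is largest.
    """

    def __init__(self, n_components: int = 6, reg: float = 1e-8):
        self.n_components = n_components
        self.reg = reg

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be (trials, channels, samples)")
        classes = np.unique(y)
        if set(classes) != {1, 2}:
            raise ValueError(f"need both classes {{1, 2}}, got {classes}")
        if self.n_components % 2 or self.n_components < 2:
            raise ValueError("n_components must be even and >= 2")
        n_ch = X.shape[1]
        if self.n_components > n_ch:
            raise ValueError("n_components exceeds the channel count")

        C1, C2 = _class_covariances(X, y, self.reg)
        evals, evecs = linalg.eigh(C1, C1 + C2)
        evals = np.clip(evals, 0.0, 1.0)
        # descending eigenvalue; ties broken by the dominant-channel index
        dominant = np.argmax(np.abs(evecs), axis=0)
        order = np.lexsort((dominant, -np.round(evals, 12)))
        evals, evecs = evals[order], evecs[:, order]

        filters = evecs.T  # components x channels
        patterns = linalg.pinv(filters)  # channels x components
        # sign convention: largest-magnitude pattern coefficient positive
        for i in range(n_ch):
            j = np.argmax(np.abs(patterns[:, i]))
            if patterns[j, i] < 0:
                patterns[:, i] *= -1
                filters[i] *= -1

        half = self.n_components // 2
        selected = np.r_[np.arange(half), np.arange(n_ch - half, n_ch)]
        self.bank_ = SpatialFilterBank(
            filters=filters, patterns=patterns, eigenvalues=evals,
            selected=selected,
        )
        self.filters_ = filters
        self.patterns_ = patterns
        self.eigenvalues_ = evals
        self.classes_ = np.array([1, 2])
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        return logvar_features(X, self.bank_)


def logvar_features(X: np.ndarray, bank: SpatialFilterBank) -> np.ndarray:
    """Log of per-component variance after spatial filtering.

    Zero-variance components are floored at machine epsilon (with a
    warning) rather than producing -inf.
    """
    W = bank.selected_filters
    if W.shape[1] != X.shape[1]:
        raise ValueError(
            f"bank fitted on {W.shape[1]} channels, data has {X.shape[1]}"
        )
    proj = np.einsum("kc,tcs->tks", W, X)
    var = proj.var(axis=2)
    eps = np.finfo(np.float64).eps
    if np.any(var < eps):
        warnings.warn("zero-variance component; flooring at machine epsilon",
                      stacklevel=2)
        var = np.maximum(var, eps)
    return np.log(var)


# ---------------------------------------------------------------------------
# Functional wrappers over the estimator
# ---------------------------------------------------------------------------

def fit_csp(
    ep: EpochSet, interval: tuple[float, float], n_components: int = 6,
    reg: float = 1e-8,
) -> SpatialFilterBank:
    """Fit CSP on the epoch samples inside *interval* (ms, half-open)."""
    mask = ep.time_mask(interval)
    est = CSP(n_components=n_components, reg=reg)
    est.fit(ep.data[:, :, mask], ep.labels)
    bank = est.bank_
    bank.channel_labels = list(ep.channel_labels)
    bank.interval = tuple(interval)
    return bank


def csp_logvar(
    ep: EpochSet, bank: SpatialFilterBank, interval: tuple[float, float]
) -> np.ndarray:
    """Per-trial log-variance features over *interval*; (trials, selected)."""
    mask = ep.time_mask(interval)
    return logvar_features(ep.data[:, :, mask], bank)


def lrp_features(ep: EpochSet, interval: tuple[float, float]) -> np.ndarray:
    """Per-trial, per-channel mean amplitude over *interval*; (trials, ch).

    Expects epochs already filtered to the slow band (0.2-4 Hz) and
    baseline-corrected.
    """
    mask = ep.time_mask(interval)
    return ep.data[:, :, mask].mean(axis=2)


# ---------------------------------------------------------------------------
# ssAUC discriminability
# ---------------------------------------------------------------------------

def ssauc(values: np.ndarray, labels: np.ndarray) -> float:
    """Signed, scaled AUC of one scalar feature: 2*(AUC - 0.5) in [-1, 1].

    AUC is the rank-sum (Mann-Whitney) probability that a class-2 value
    exceeds a class-1 value; ties count half.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    v1, v2 = values[labels == 1], values[labels == 2]
    if len(v1) < 1 or len(v2) < 1:
        raise ValueError("both classes need at least one sample")
    ranks = stats.rankdata(np.r_[v1, v2])
    r2 = ranks[len(v1):].sum()
    auc = (r2 - len(v2) * (len(v2) + 1) / 2) / (len(v1) * len(v2))
    return float(2.0 * (auc - 0.5))


def ssauc_map(ep: EpochSet) -> np.ndarray:
    """Channel x time map of ssAUC discriminability for an EpochSet."""
    n_t, n_ch, n_s = ep.data.shape
    flat = ep.data.reshape(n_t, n_ch * n_s)
    y = ep.labels
    if not ((y == 1).any() and (y == 2).any()):
        raise ValueError("both classes must be present")
    n1, n2 = int((y == 1).sum()), int((y == 2).sum())
    ranks = stats.rankdata(flat, axis=0)
    r2 = ranks[y == 2].sum(axis=0)
    auc = (r2 - n2 * (n2 + 1) / 2) / (n1 * n2)
    return (2.0 * (auc - 0.5)).reshape(n_ch, n_s)
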