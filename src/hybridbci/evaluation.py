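"""The measurement stack: accuracy, significance, ITR, cross-validation,
spectral screening.

Binary accuracy has a 50% chance level (two balanced classes).
Significance against chance uses the exact one-sided binomial tail as the
primary test, with a Pearson chi-squared (1 df) cross-check.  Information
transfer rate follows Wolpaw's bits-per-selection, multiplied by the
decided-selection rate over *all* elapsed session time -- pauses and
noDecision trials included, so hesitating costs bitrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sig
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .classifiers import NO_DECISION, lda_score, train_shrinkage_lda
from .eeg import EpochSet, Recording
from .features import CSP
from .online import SessionLog

__all__ = [
    "SessionResult",
    "CrossValResult",
    "binary_accuracy",
    "chance_test",
    "chance_test_chi2",
    "wolpaw_bits",
    "itr_with_pauses",
    "crossval_accuracy",
    "spectral_screening",
    "ScreeningResult",
]

ALPHA_BAND = (8.0, 12.0)


@dataclass
class SessionResult:
    """Aggregated per-session performance."""

    n_trials: int
    n_correct: int
    n_nodecision: int
    accuracy: float
    p_value: float
    p_value_chi2: float
    significant: bool
    itr_bits_per_min: float
    block_accuracies: list[float] = field(default_factory=list)


def _labeled(log: SessionLog):
    return [o for o in log.outcomes if o.correct is not None]


def binary_accuracy(log: SessionLog, block_size: int = 20) -> SessionResult:
    """Fraction of correct trials, with >=*block_size*-trial block accuracies.

    CopyTask correctness is sign-based over all trials; in FreeMode only
    decided trials with known intent enter the accuracy, while noDecision
    trials still count toward session time (and hence ITR).
    """
    labeled = _labeled(log)
    n_trials = len(log.outcomes)
    n_nodecision = sum(o.decision == NO_DECISION for o in log.outcomes)
    if not labeled:
        raise ValueError("no labeled (evaluable) trials in this session")
    n_correct = sum(o.correct for o in labeled)
    accuracy = n_correct / len(labeled)
    p = chance_test(n_correct, len(labeled))
    p_chi2 = chance_test_chi2(n_correct, len(labeled))

    flags = np.array([o.correct for o in labeled], dtype=float)
    blocks = []
    n_blocks = max(1, len(flags) // block_size)
    bounds = np.linspace(0, len(flags), n_blocks + 1).astype(int)
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b > a:
            blocks.append(float(flags[a:b].mean()))

    return SessionResult(
        n_trials=n_trials,
        n_correct=int(n_correct),
        n_nodecision=int(n_nodecision),
        accuracy=float(accuracy),
        p_value=p,
        p_value_chi2=p_chi2,
        significant=bool(p < 0.05),
        itr_bits_per_min=itr_with_pauses(log),
        block_accuracies=blocks,
    )


def chance_test(n_correct: int, n_total: int) -> float:
    """Exact one-sided binomial tail P(X >= n_correct | n_total, 0.5)."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if n_correct > n_total:
        raise ValueError("n_correct cannot exceed n_total")
    return float(stats.binomtest(n_correct, n_total, 0.5,
                                 alternative="greater").pvalue)


def chance_test_chi2(n_correct: int, n_total: int) -> float:
    """Pearson chi-squared (1 df) test of the 50/50 split, as cross-check."""
    if n_correct > n_total:
        raise ValueError("n_correct cannot exceed n_total")
    expected = n_total / 2.0
    chi2 = (n_correct - expected) ** 2 / expected * 2.0
    return float(stats.chi2.sf(chi2, df=1))


def wolpaw_bits(P: float, N: int = 2) -> float:
    """Wolpaw bits per selection at accuracy *P* among *N* classes."""
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must be in [0, 1]")
    if N < 2:
        raise ValueError("N must be >= 2")
    bits = np.log2(N)
    if P > 0:
        bits += P * np.log2(P)
    if P < 1:
        bits += (1 - P) * np.log2((1 - P) / (N - 1))
    return float(bits)


def itr_with_pauses(log: SessionLog, N: int = 2) -> float:
    """Bits/min: Wolpaw bits over decided trials, time includes everything.

    Accuracy is computed over decided, labeled trials; the denominator is
    the full session span (pauses and noDecision trials included).
    """
    elapsed_min = log.elapsed / 60.0
    if elapsed_min <= 0:
        raise ValueError("session has zero elapsed time")
    decided = [
        o for o in log.outcomes
        if o.decision != NO_DECISION and o.correct is not None
    ]
    if not decided:
        return 0.0
    acc = float(np.mean([o.correct for o in decided]))
    return wolpaw_bits(acc, N) * len(decided) / elapsed_min


# ---------------------------------------------------------------------------
# Offline cross-validated accuracy
# ---------------------------------------------------------------------------

@dataclass
class CrossValResult:
    fold_accuracies: np.ndarray
    mean_accuracy: float
    std_accuracy: float


def crossval_accuracy(
    X, y=None, *, interval=None, n_folds: int = 5, n_csp: int = 6,
    seed: int = 0,
) -> CrossValResult:
    """k-fold accuracy with all supervised steps inside the training fold.

    *X* may be an :class:`EpochSet` (optionally restricted to *interval*
    ms), a 3-D array (trials x channels x samples: CSP is fitted per
    training fold, then shrinkage LDA), or a 2-D feature array (shrinkage
    LDA only).  Stratified folds; the fold count is reduced with a warning
    when a class has fewer trials than folds.
    """
    if isinstance(X, EpochSet):
        data = X.data if interval is None else X.data[:, :, X.time_mask(interval)]
        y = X.labels
    else:
        data = np.asarray(X, dtype=np.float64)
        if y is None:
            raise ValueError("y is required when X is an array")
        y = np.asarray(y)

    min_class = min(int((y == c).sum()) for c in (1, 2))
    if min_class < 2:
        raise ValueError("need >= 2 trials per class")
    folds = min(n_folds, min_class)
    if folds < n_folds:
        import warnings

        warnings.warn(f"reducing folds from {n_folds} to {folds}", stacklevel=2)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(np.zeros(len(y)), y):
        if data.ndim == 3:
            k = min(n_csp, data.shape[1])
            csp = CSP(n_components=max(2, k - k % 2))
            csp.fit(data[train], y[train])
            Xtr, Xte = csp.transform(data[train]), csp.transform(data[test])
        else:
            Xtr, Xte = data[train], data[test]
        model = train_shrinkage_lda(Xtr, y[train])
        pred = np.where(np.atleast_1d(lda_score(model, Xte)) > 0, 2, 1)
        accs.append(float(np.mean(pred == y[test])))
    accs = np.asarray(accs)
    return CrossValResult(
        fold_accuracies=accs,
        mean_accuracy=float(accs.mean()),
        std_accuracy=float(accs.std()),
    )


# ---------------------------------------------------------------------------
# Spectral screening (eyes-open / eyes-closed)
# ---------------------------------------------------------------------------

@dataclass
class ScreeningResult:
    freqs: np.ndarray
    spectra: dict  # condition -> (channels x freqs) power density
    alpha_power: dict  # condition -> (channels,) 8-12 Hz band power
    channel_labels: list[str]


def spectral_screening(
    rec: Recording,
    segments: dict,
    nperseg: int = 256,
) -> ScreeningResult:
    """Welch spectra per channel and condition, plus alpha-band topography.

    *segments* maps a condition name (e.g. "eyes-open") to a (start, stop)
    sample range or a list of such ranges.
    """
    spectra = {}
    alpha = {}
    freqs = None
    for cond, ranges in segments.items():
        if isinstance(ranges, tuple):
            ranges = [ranges]
        psds = []
        for a, b in ranges:
            if b - a < nperseg:
                raise ValueError(
                    f"segment {cond} ({b - a} samples) shorter than one "
                    f"Welch window ({nperseg})"
                )
            f, p = sig.welch(rec.signal[:, a:b], fs=rec.fs, nperseg=nperseg,
                             axis=-1)
            psds.append(p)
            freqs = f
        spectra[cond] = np.mean(psds, axis=0)
        band = (freqs >= ALPHA_BAND[0]) & (freqs <= ALPHA_BAND[1])
        alpha[cond] = np.trapezoid(spectra[cond][:, band], freqs[band], axis=-1)
    return ScreeningResult(
        freqs=freqs, spectra=spectra, alpha_power=alpha,
        channel_labels=list(rec.channel_labels),
    )
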