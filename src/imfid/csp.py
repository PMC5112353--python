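"""Band-pass preprocessing and common spatial patterns (CSP).

CSP finds spatial filters u maximizing the variance ratio
u^T C1 u / u^T C2 u between two classes of multichannel trials; the filters
are the generalized eigenvectors of C1 u = zeta C2 u.  Features of a trial
are normalized log-variances of the first and last m filtered components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.signal import butter, sosfiltfilt

from .signals import MultichannelSignal

__all__ = ["TrialSet", "CSPModel", "bandpass_8_30", "csp_fit", "csp_transform"]


@dataclass
class TrialSet:
    """Labelled multichannel trials: (T, n_channels, L) array plus class
    labels in {1, 2} and the sampling rate."""

    trials: np.ndarray
    labels: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.trials.ndim != 3:
            raise ValueError("trials must be a (T, channels, samples) array")
        if len(self.labels) != self.trials.shape[0]:
            raise ValueError("one label per trial required")

    def class_trials(self, label: int) -> np.ndarray:
        return self.trials[self.labels == label]


@dataclass
class CSPModel:
    """Spatial filters (columns of U, unit-norm) ordered by descending
    generalized eigenvalue."""

    U: np.ndarray
    eigenvalues: np.ndarray


def bandpass_8_30(signal: MultichannelSignal, order: int = 5) -> MultichannelSignal:
    """Zero-phase Butterworth band-pass, 8-30 Hz passband.

    Forward-backward filtering doubles the effective order but leaves the
    phase untouched, which matters for the later variance features.
    """
    if signal.fs <= 60:
        raise ValueError("sampling rate too low for an 8-30 Hz band-pass")
    sos = butter(order, [8.0, 30.0], btype="bandpass", fs=signal.fs, output="sos")
    return MultichannelSignal(sosfiltfilt(sos, signal.data, axis=1), fs=signal.fs,
                              channel_names=signal.channel_names,
                              noise_rows=list(signal.noise_rows))


def _class_covariance(trials: np.ndarray, trace_norm: bool) -> np.ndarray:
    covs = []
    for E in trials:
        C = E @ E.T
        if trace_norm:
            C = C / np.trace(C)
        covs.append(C)
    return np.mean(covs, axis=0)


def csp_fit(train: TrialSet, trace_norm: bool = True) -> CSPModel:
    """Fit CSP filters from a two-class trial set.

    Per class, spatial covariances E E^T are averaged over trials
    (trace-normalized per trial by default, for robustness to amplitude
    differences; pass ``trace_norm=False`` for plain covariance averages)
    and the generalized eigenproblem C1 u = zeta C2 u is solved.  Columns of
    U are unit-normalized and sorted by descending eigenvalue.
    """
    classes = np.unique(train.labels)
    if len(classes) != 2:
        raise ValueError("CSP requires exactly two classes in the training set")
    C1 = _class_covariance(train.class_trials(classes[0]), trace_norm)
    C2 = _class_covariance(train.class_trials(classes[1]), trace_norm)
    if np.linalg.cond(C2) > 1e12:
        C2 = C2 + 1e-8 * np.trace(C2) / C2.shape[0] * np.eye(C2.shape[0])
    zeta, U = scipy.linalg.eigh(C1, C2)
    order = np.argsort(zeta)[::-1]
    zeta, U = zeta[order], U[:, order]
    U = U / np.linalg.norm(U, axis=0, keepdims=True)
    return CSPModel(U=U, eigenvalues=zeta)


def csp_transform(trial: np.ndarray, model: CSPModel, m: int = 3) -> np.ndarray:
    """Normalized log-variance features of the m first and m last spatially
    filtered components:

        f_j = log( var(s_j) / sum_i var(s_i) ),  j over the 2m kept rows,

    so that sum_j exp(f_j) = 1.  Scale-invariant in the trial amplitude.
    """
    trial = np.asarray(trial, dtype=float)
    n = model.U.shape[1]
    if 2 * m > n:
        raise ValueError(f"2m={2*m} filters requested but only {n} channels")
    S = model.U.T @ trial
    keep = np.r_[0:m, n - m:n]
    v = np.var(S[keep], axis=1)
    return np.log(v / v.sum())
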