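"""Predictive-performance machinery: C-index, CVPL and pre-validation.

The concordance index is Harrell's estimator: over all usable pairs (a pair
is usable iff the member with the earlier observed time had the event), the
fraction in which the subject with the shorter time has the larger risk
score, ties in the score counting 1/2.

The cross-validated partial likelihood is

    CVPL = sum_k [ pl(beta_(-k)) - pl_(-k)(beta_(-k)) ]

where ``beta_(-k)`` is fitted without fold k, ``pl`` is evaluated on all
subjects and ``pl_(-k)`` on the training subjects only; the difference
measures how the left-out death times rank within the full risk sets.

Pre-validation refits the model K times, each time predicting the held-out
fold, so that every subject's prognostic index comes from a model that
never saw that subject's outcome; the resulting (t, d, eta-hat) triplets
form an honest evaluation set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sksurv.exceptions import NoComparablePairException
from sksurv.metrics import concordance_index_censored

from .survival import SurvivalOutcome, as_survival_outcome, partial_loglik

__all__ = ["CVResult", "c_index", "cvpl", "prevalidate", "stratified_folds"]


@dataclass
class CVResult:
    """Out-of-fold prognostic indices and derived measures.

    ``eta`` has one row per replicate; every entry was predicted by a model
    fitted without that subject's fold.
    """

    eta: np.ndarray                 # (reps, n) pre-validated prognostic indices
    c_index: np.ndarray             # (reps,)
    cvpl: np.ndarray                # (reps,) fold-sum CVPL
    prevalidated_pl: np.ndarray     # (reps,) pl of the pooled pre-validated eta
    n_nonzero: np.ndarray           # (reps, K) per-fold nonzero counts
    fold_assignment: np.ndarray     # (reps, n) fold label per subject
    seed: int

    def summary(self) -> dict:
        return {
            "cvpl_mean": float(self.cvpl.mean()),
            "cvpl_sd": float(self.cvpl.std(ddof=1)) if self.cvpl.size > 1 else 0.0,
            "c_index_mean": float(self.c_index.mean()),
            "c_index_sd": float(self.c_index.std(ddof=1)) if self.c_index.size > 1 else 0.0,
            "prevalidated_pl_mean": float(self.prevalidated_pl.mean()),
            "n_nonzero_mean": float(self.n_nonzero.mean()),
        }


def c_index(y, eta) -> float:
    """Harrell's concordance index of a risk score (higher = shorter survival)."""
    y = as_survival_outcome(y)
    eta = np.asarray(eta, dtype=float)
    if eta.shape != y.time.shape:
        raise ValueError("eta length does not match the outcome")
    try:
        ci = concordance_index_censored(y.status.astype(bool), y.time, eta)[0]
    except NoComparablePairException as err:
        raise ValueError("no usable (comparable) pairs for the C-index") from err
    return float(ci)


def stratified_folds(status, K: int, seed: int):
    """K folds balanced on the event indicator; returns index arrays.

    Events and censored subjects are shuffled separately and dealt round-
    robin, so every fold holds events whenever K <= number of events.
    """
    status = np.asarray(status)
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(K)]
    offset = 0
    for val in (1, 0):
        idx = np.flatnonzero(status == val)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[(i + offset) % K].append(j)
        offset += idx.size
    return [np.sort(np.asarray(f, dtype=np.intp)) for f in folds if len(f)]


def _fit_coef(fitter, X, y):
    """Run a fitter (callable or sklearn-style estimator) -> raw-scale coef."""
    if hasattr(fitter, "get_params") and hasattr(fitter, "fit"):
        from sklearn.base import clone

        est = clone(fitter).fit(X, y)
        return est.coef_raw_
    coef = fitter(X, y)
    return np.asarray(coef, dtype=float)


def cvpl(fitter, X, y, K: int = 10, seed: int = 0, ties: str = "breslow") -> float:
    """Cross-validated partial likelihood of a fitting procedure.

    ``fitter(X_train, y_train)`` must return a coefficient vector applicable
    to the raw predictor matrix.  Folds are stratified by event status.
    """
    X = np.asarray(X, dtype=float)
    y = as_survival_outcome(y)
    total = 0.0
    for test_idx in stratified_folds(y.status, K, seed):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        yt = SurvivalOutcome(y.time[train_idx], y.status[train_idx])
        coef = _fit_coef(fitter, X[train_idx], yt)
        eta = X @ coef
        total += partial_loglik(eta, y, ties) - partial_loglik(eta[train_idx], yt, ties)
    return float(total)


def prevalidate(fitter, X, y, K: int = 10, reps: int = 10, seed: int = 0,
                ties: str = "breslow") -> CVResult:
    """K-fold pre-validation repeated ``reps`` times.

    Each subject's prognostic index is computed from a fit excluding that
    subject's fold; the C-index is then evaluated on the pre-validated
    (t, d, eta-hat) data, and the CVPL accumulated per replicate.
    """
    X = np.asarray(X, dtype=float)
    y = as_survival_outcome(y)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n = len(y)
    eta = np.zeros((reps, n))
    ci = np.zeros(reps)
    cv = np.zeros(reps)
    ppl = np.zeros(reps)
    nnz = []
    assign = np.full((reps, n), -1, dtype=int)
    for r in range(reps):
        folds = stratified_folds(y.status, K, seed + r)
        row_nnz = []
        for k, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            yt = SurvivalOutcome(y.time[train_idx], y.status[train_idx])
            coef = _fit_coef(fitter, X[train_idx], yt)
            e = X @ coef
            eta[r, test_idx] = e[test_idx]
            assign[r, test_idx] = k
            cv[r] += partial_loglik(e, y, ties) - partial_loglik(e[train_idx], yt, ties)
            row_nnz.append(int(np.count_nonzero(coef)))
        nnz.append(row_nnz)
        ci[r] = c_index(y, eta[r])
        ppl[r] = partial_loglik(eta[r], y, ties)
    return CVResult(eta=eta, c_index=ci, cvpl=cv, prevalidated_pl=ppl,
                    n_nonzero=np.asarray(nnz), fold_assignment=assign, seed=seed)
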