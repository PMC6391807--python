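"""Right-censored survival outcomes and the Cox partial log-likelihood.

The Cox proportional-hazards model specifies the hazard of subject *i* as
``h(t | x_i) = h0(t) * exp(eta_i)`` with linear predictor (prognostic index)
``eta_i = x_i' beta``.  The baseline hazard ``h0`` is left unspecified and
``beta`` is estimated by maximizing the partial log-likelihood

    pl(beta) = sum_{i: d_i = 1} [ eta_i - log sum_{k in R(t_i)} exp(eta_k) ]

where ``R(t)`` is the set of subjects still at risk at time ``t`` (observed
time >= t).  Tied event times are handled with either the Breslow or the
Efron approximation.

This module also provides the diagonal quadratic (IRLS) approximation of the
negative partial log-likelihood used by the penalized coordinate-descent
solver: per-subject working weights (negative diagonal second derivatives)
and working responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalOutcome",
    "as_survival_outcome",
    "read_survival",
    "partial_loglik",
    "deviance",
    "partial_loglik_gradient",
    "quadratic_approx",
]

#: floor for IRLS weights of zero-information subjects
WEIGHT_FLOOR = 1e-8

_TIES = ("breslow", "efron")


@dataclass(frozen=True)
class SurvivalOutcome:
    """Right-censored survival data: observed times and event indicators.

    Attributes
    ----------
    time : ndarray of shape (n,)
        Strictly positive observed times ``t_i = min(T_i, C_i)``.
    status : ndarray of shape (n,)
        Event indicators ``d_i``; 1 if the event was observed, 0 if censored.
    """

    time: np.ndarray
    status: np.ndarray
    # sort-by-time permutation, computed once; original order is preserved in
    # `time`/`status` and all public results are mapped back to it.
    _order: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        status = np.asarray(self.status, dtype=float)
        if time.ndim != 1 or status.ndim != 1 or time.shape != status.shape:
            raise ValueError("time and status must be 1-d arrays of equal length")
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("all survival times must be finite and strictly positive")
        if not np.all(np.isin(status, (0.0, 1.0))):
            raise ValueError("status must contain only 0 (censored) and 1 (event)")
        if status.sum() < 1:
            raise ValueError("at least one event is required")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "status", status)
        object.__setattr__(self, "_order", np.argsort(time, kind="stable"))

    def __len__(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())


def as_survival_outcome(y) -> SurvivalOutcome:
    """Coerce `y` into a :class:`SurvivalOutcome`.

    Accepts a SurvivalOutcome, a numpy structured array with event/time
    fields (the scikit-survival convention), a ``(time, status)`` pair of
    sequences, or a DataFrame with ``time`` and ``status`` columns.
    """
    if isinstance(y, SurvivalOutcome):
        return y
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = y.dtype.names
        ev = next((n for n in names if y[n].dtype == bool or n.lower() in ("event", "status", "d")), None)
        tm = next((n for n in names if n != ev), None)
        if ev is None or tm is None:
            raise ValueError("cannot identify event/time fields in structured array")
        return SurvivalOutcome(np.asarray(y[tm], float), np.asarray(y[ev], float))
    if isinstance(y, pd.DataFrame):
        return SurvivalOutcome(y["time"].to_numpy(float), y["status"].to_numpy(float))
    y = np.asarray(y)
    if y.ndim == 2 and y.shape[1] == 2:
        return SurvivalOutcome(y[:, 0].astype(float), y[:, 1].astype(float))
    if isinstance(y, np.ndarray) and y.ndim == 1 and y.dtype == object:
        # (time, status) tuple stored as object array
        y = tuple(y)
    if isinstance(y, (tuple, list)) and len(y) == 2:
        return SurvivalOutcome(np.asarray(y[0], float), np.asarray(y[1], float))
    raise ValueError("unsupported survival outcome representation")


def read_survival(path) -> SurvivalOutcome:
    """Read a TSV/CSV with columns ``time`` and ``status`` (header required)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"time", "status"} - set(df.columns)
    if missing:
        raise ValueError(f"survival file {path!s} lacks required columns: {sorted(missing)}")
    return SurvivalOutcome(df["time"].to_numpy(float), df["status"].to_numpy(float))


def _check_eta(eta, y: SurvivalOutcome) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    if eta.shape != y.time.shape:
        raise ValueError("eta length does not match the number of subjects")
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    return eta


def _risk_structure(y: SurvivalOutcome):
    """Sorted views plus unique-event-time bookkeeping (cached per outcome).

    Returns (order, t_sorted, d_sorted, event_times, event_start, event_count)
    where event_start[k] is the first sorted index with time == event_times[k].
    """
    cached = getattr(y, "_risk_cache", None)
    if cached is not None:
        return cached
    order = y._order
    t = y.time[order]
    d = y.status[order]
    ev_t = np.unique(t[d == 1])
    start = np.searchsorted(t, ev_t, side="left")
    count = np.searchsorted(t, ev_t, side="right") - start
    out = (order, t, d, ev_t, start, count)
    object.__setattr__(y, "_risk_cache", out)
    return out


def partial_loglik(eta, y: SurvivalOutcome, ties: str = "breslow") -> float:
    """Cox partial log-likelihood of a linear predictor.

    Invariant under adding a constant to ``eta``; Breslow and Efron agree
    exactly when all event times are distinct.
    """
    if ties not in _TIES:
        raise ValueError(f"ties must be one of {_TIES}")
    eta = _check_eta(eta, y)
    order, t, d, ev_t, start, _ = _risk_structure(y)
    e = eta[order]
    # centre for numerical stability; pl is location invariant
    e = e - e.max()
    w = np.exp(e)
    # risk-set sums at each unique event time: sum of w over sorted idx >= start
    rc = np.concatenate((np.cumsum(w[::-1])[::-1], [0.0]))
    risk = rc[start]
    pl = float(e[d == 1].sum())
    D = count_events(t, d, ev_t)
    if ties == "breslow":
        # every tied event uses the full risk-set denominator
        pl -= float((D * np.log(risk)).sum())
    else:
        pl -= float(np.log(risk[D == 1]).sum())
        for k in np.flatnonzero(D > 1):
            tie_ev = (t == ev_t[k]) & (d == 1)
            Dk = int(D[k])
            E = float(w[tie_ev].sum())
            frac = np.arange(Dk) / Dk
            pl -= float(np.log(risk[k] - frac * E).sum())
    return pl


def deviance(eta, y: SurvivalOutcome, ties: str = "breslow") -> float:
    """Model deviance ``-2 * pl(eta)``, the EM convergence diagnostic."""
    return -2.0 * partial_loglik(eta, y, ties)


def _grad_hess_sorted(e, t, d, ev_t, start, count, ties):
    """Gradient and diagonal negative Hessian of pl w.r.t. eta, sorted order."""
    w = np.exp(e)
    rc = np.concatenate((np.cumsum(w[::-1])[::-1], [0.0]))
    risk = rc[start]
    D = count_events(t, d, ev_t)
    # Breslow terms, fully vectorized:
    # A_i = sum over event times tau <= t_i of D_tau / R_tau
    h1 = D / risk
    h2 = D / risk ** 2
    pos = np.searchsorted(ev_t, t, side="right")
    A = np.concatenate(([0.0], np.cumsum(h1)))[pos]
    B = np.concatenate(([0.0], np.cumsum(h2)))[pos]
    if ties == "efron":
        # correct tied groups only; for D == 1 Efron coincides with Breslow
        for k in np.flatnonzero(D > 1):
            tau = ev_t[k]
            tie_ev = (t == tau) & (d == 1)
            Dk = int(D[k])
            E = float(w[tie_ev].sum())
            frac = np.arange(Dk) / Dk
            denom = risk[k] - frac * E
            s1 = float((1.0 / denom).sum())
            s2 = float((1.0 / denom ** 2).sum())
            at_risk = t >= tau
            A[at_risk] += s1 - h1[k]
            B[at_risk] += s2 - h2[k]
            # an event in the tie enters denominator l with weight 1 - l/D:
            # grad_i = 1 - w_i * sum_l (1 - f_l)/denom_l
            # -d2pl/deta_i^2 = w_i*(s1 - g1) - w_i^2 * sum_l (1 - f_l)^2/denom_l^2
            g1 = float((frac / denom).sum())
            g2 = float((frac / denom ** 2).sum())
            q2 = float((frac ** 2 / denom ** 2).sum())
            A[tie_ev] -= g1
            B[tie_ev] += -2.0 * g2 + q2
    grad = d - w * A
    wdiag = w * A - w ** 2 * B
    return grad, wdiag


def count_events(t, d, ev_t):
    """Number of events at each unique event time (sorted inputs)."""
    left = np.searchsorted(t[d == 1], ev_t, side="left")
    right = np.searchsorted(t[d == 1], ev_t, side="right")
    return (right - left).astype(float)


def partial_loglik_gradient(eta, y: SurvivalOutcome, ties: str = "breslow") -> np.ndarray:
    """Per-subject gradient of the partial log-likelihood w.r.t. eta."""
    if ties not in _TIES:
        raise ValueError(f"ties must be one of {_TIES}")
    eta = _check_eta(eta, y)
    order, t, d, ev_t, start, count = _risk_structure(y)
    e = eta[order]
    e = e - e.max()
    grad_s, _ = _grad_hess_sorted(e, t, d, ev_t, start, count, ties)
    grad = np.empty_like(grad_s)
    grad[order] = grad_s
    return grad


def quadratic_approx(eta, y: SurvivalOutcome, ties: str = "breslow"):
    """Diagonal second-order (IRLS) approximation of -pl at ``eta``.

    Returns ``(weights, working_response)`` where ``weights`` are the
    negative diagonal second derivatives of pl w.r.t. each ``eta_i`` and the
    working response is ``z_i = eta_i + grad_i / w_i``.  Weights are floored
    at :data:`WEIGHT_FLOOR` so subjects carrying no information (censored
    before every event time) get weight ~0 and ``z_i = eta_i``.
    """
    if ties not in _TIES:
        raise ValueError(f"ties must be one of {_TIES}")
    eta = _check_eta(eta, y)
    order, t, d, ev_t, start, count = _risk_structure(y)
    e = eta[order]
    shift = e.max()
    grad_s, w_s = _grad_hess_sorted(e - shift, t, d, ev_t, start, count, ties)
    w_s = np.maximum(w_s, WEIGHT_FLOOR)
    grad = np.empty_like(grad_s)
    wdiag = np.empty_like(w_s)
    grad[order] = grad_s
    wdiag[order] = w_s
    z = eta + grad / wdiag
    return wdiag, z
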