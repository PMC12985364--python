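"""Discrete-time survival modeling on slide-level features.

The continuous time axis is cut at the quartiles of the *uncensored*
subjects' survival times into R intervals; a linear (or MLP) head maps the
slide-level feature vector to R sigmoid hazards

    f_hazard(r | h) = P(T = r | T >= r, h),
    f_surv(r | h)   = prod_{u=1..r} (1 - f_hazard(u | h)),  f_surv(0) = 1.

Training minimizes the censored negative log likelihood

    L = -c log f_surv(Y) - (1-c) log f_surv(Y-1) - (1-c) log f_hazard(Y)

blended with an uncensored-only term, L_surv = (1-beta) L + beta L_unc.
Interval labels r in {0..R-1} map to 1-based hazard indices u = r + 1.

Also here: Harrell-style concordance index, slide-level pooling of spot
predictions, Kaplan-Meier risk stratification, and integrated-gradients
attribution of feature (cell-type) contributions to predicted risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from ._tensor import Tensor
from .nn import Adam, Linear, MLP, SGD, Module
from .synthetic import SurvivalCohort

__all__ = [
    "discretize_times", "survival_from_hazard", "survival_loss",
    "HazardModel", "DiscreteTimeSurvival", "fit_hazard_model",
    "concordance_index", "pool_slide", "km_curve", "km_stratify",
    "integrated_gradients",
]

_EPS = 1e-7


def discretize_times(times, censor, n_intervals: int = 4
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Cut points = quartiles (linear-interpolation quantiles) of uncensored
    times; every subject is labeled by the interval containing its time,
    times beyond the last cut falling in the last interval."""
    times = np.asarray(times, dtype=np.float64)
    censor = np.asarray(censor, dtype=int)
    uncensored = times[censor == 0]
    if len(uncensored) < n_intervals:
        raise ValueError(
            f"need >= {n_intervals} uncensored subjects, got {len(uncensored)}")
    qs = np.linspace(0, 1, n_intervals + 1)[1:-1]
    cuts = np.quantile(uncensored, qs)          # type-7 linear interpolation
    if len(np.unique(cuts)) != len(cuts):
        raise ValueError("degenerate cut points (tied quantiles)")
    labels = np.searchsorted(cuts, times, side="right")
    return cuts, labels.astype(int)


def survival_from_hazard(hazards: np.ndarray) -> np.ndarray:
    """(R,) hazards in (0,1) -> (R+1,) survival curve with f_surv(0) = 1."""
    h = np.asarray(hazards, dtype=np.float64)
    if ((h <= 0) | (h >= 1)).any():
        raise ValueError("hazards must lie strictly in (0, 1)")
    return np.concatenate([[1.0], np.cumprod(1.0 - h)])


def survival_loss(hazards, y: int, c: int, beta: float) -> float:
    """Per-subject discrete survival loss (numpy scalar path).

    ``hazards`` indexed 1-based through u = r + 1; log arguments are clamped
    at 1e-7 with a warning.
    """
    h = np.asarray(hazards, dtype=np.float64)
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    surv = np.concatenate([[1.0], np.cumprod(1.0 - h)])

    def safe_log(v):
        if v < _EPS:
            warnings.warn("clamping log argument at epsilon")
            v = _EPS
        return np.log(v)

    # labels are 0-based; hazard index u = y + 1; f_surv(Y) uses the 1-based
    # survival grid, f_surv(Y-1) the previous point (f_surv(0) = 1 at y = 0)
    log_surv_y = safe_log(surv[y + 1])
    log_surv_prev = safe_log(surv[y])
    log_haz_y = safe_log(h[y])
    loss_full = -c * log_surv_y - (1 - c) * log_surv_prev - (1 - c) * log_haz_y
    loss_unc = -(1 - c) * (log_surv_prev + log_haz_y)
    return float((1.0 - beta) * loss_full + beta * loss_unc)


def _loss_tensor(hazards: Tensor, labels: np.ndarray, censor: np.ndarray,
                 beta: float) -> Tensor:
    """Batched differentiable mean L_surv; hazards (n, R) in (0,1)."""
    n, r = hazards.shape
    one_minus = (1.0 - hazards).clip_min(_EPS)
    log_1mh = one_minus.log()                      # (n, R)
    # differentiable cumulative log-survival via lower-triangular matmul
    tri = np.tril(np.ones((r, r)))
    log_surv = log_1mh @ Tensor(tri.T)             # column u = sum_{v<=u}
    rows = np.arange(n)
    c = censor.astype(np.float64)
    log_surv_y = log_surv.take_flat(rows * r + labels)          # f_surv(Y)
    # f_surv(Y-1): 0 for label 0 (log 1), else column y-1
    prev_idx = np.maximum(labels - 1, 0)
    log_surv_prev_raw = log_surv.take_flat(rows * r + prev_idx)
    prev_mask = (labels > 0).astype(np.float64)
    log_surv_prev = log_surv_prev_raw * Tensor(prev_mask)
    log_haz_y = hazards.clip_min(_EPS).log().take_flat(rows * r + labels)
    cc, uu = Tensor(c), Tensor(1.0 - c)
    loss_full = -(cc * log_surv_y) - uu * log_surv_prev - uu * log_haz_y
    loss_unc = -(uu * (log_surv_prev + log_haz_y))
    return ((1.0 - beta) * loss_full + beta * loss_unc).mean()


@dataclass
class HazardModel:
    """Fitted discrete-hazard head: feature -> R interval hazards."""
    net: Module
    cuts: np.ndarray
    beta: float
    n_intervals: int

    def hazards(self, x: np.ndarray) -> np.ndarray:
        return self.net(Tensor(np.atleast_2d(np.asarray(x, float)))).sigmoid().data

    def risk_score(self, x: np.ndarray) -> np.ndarray:
        """Higher = higher risk: negative expected discrete survival,
        -sum_r f_surv(r)."""
        h = self.hazards(x)
        surv = np.cumprod(1.0 - h, axis=1)
        return -(1.0 + surv.sum(axis=1))

    def weight_matrix(self) -> np.ndarray:
        """(n_features, R) first-layer weights of a linear head."""
        first = self.net.layers[0] if isinstance(self.net, MLP) else self.net
        return first.W.data


class DiscreteTimeSurvival(BaseEstimator):
    """Discrete-time hazard model as an sklearn-style estimator.

    ``fit(X, y)`` takes features (n, k) and ``y`` as a (times, censor)
    tuple or structured array; fitted state: ``model_`` (a
    :class:`HazardModel`), ``cuts_``, ``loss_trace_``.
    """

    def __init__(self, n_intervals: int = 4, beta: float = 0.5,
                 hidden: int = 0, epochs: int = 300,
                 learning_rate: float = 0.05, optimizer: str = "adam",
                 seed: int = 0):
        self.n_intervals = n_intervals
        self.beta = beta
        self.hidden = hidden
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.seed = seed

    @staticmethod
    def _unpack_y(y):
        if isinstance(y, tuple):
            times, censor = y
        else:
            arr = np.asarray(y)
            times, censor = arr[:, 0], arr[:, 1]
        return (np.asarray(times, float), np.asarray(censor, int))

    def fit(self, X, y):
        x = np.asarray(X, dtype=np.float64)
        times, censor = self._unpack_y(y)
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        cuts, labels = discretize_times(times, censor, self.n_intervals)
        rng = np.random.default_rng(self.seed)
        if self.hidden > 0:
            net = MLP([x.shape[1], self.hidden, self.n_intervals], rng)
        else:
            net = Linear(x.shape[1], self.n_intervals, rng)
        opt = (Adam if self.optimizer == "adam" else SGD)(
            net.parameters(), lr=self.learning_rate)
        xt = Tensor(x)
        trace = []
        for _ in range(self.epochs):
            hazards = net(xt).sigmoid()
            loss = _loss_tensor(hazards, labels, censor, self.beta)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged (loss trace: {trace[-5:]})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            trace.append(float(loss.data))
        self.model_ = HazardModel(net, cuts, self.beta, self.n_intervals)
        self.cuts_ = cuts
        self.labels_ = labels
        self.loss_trace_ = trace
        return self

    def predict(self, X):
        """Risk scores (higher = shorter predicted survival)."""
        return self.model_.risk_score(np.asarray(X, float))

    def predict_hazard(self, X):
        return self.model_.hazards(np.asarray(X, float))


def fit_hazard_model(cohort: SurvivalCohort, n_intervals: int = 4,
                     beta: float = 0.5, epochs: int = 300,
                     learning_rate: float = 0.05, seed: int = 0,
                     hidden: int = 0) -> tuple[HazardModel, list[float]]:
    est = DiscreteTimeSurvival(n_intervals=n_intervals, beta=beta,
                               hidden=hidden, epochs=epochs,
                               learning_rate=learning_rate, seed=seed)
    est.fit(cohort.features, (cohort.times, cohort.censor))
    return est.model_, est.loss_trace_


def concordance_index(scores, times, censor) -> float:
    """Censored concordance over admissible pairs (the earlier time is an
    observed event), with score ties counting 1/2.

    ``scores`` are survival-time-like: higher score = longer predicted
    survival.  Negate risk scores before calling.
    """
    s = np.asarray(scores, dtype=np.float64)
    t = np.asarray(times, dtype=np.float64)
    c = np.asarray(censor, dtype=int)
    if not (len(s) == len(t) == len(c)):
        raise ValueError("scores, times, censor must share length")
    # pair (i, j) admissible iff t_i < t_j and subject i had an event
    ti, tj = t[:, None], t[None, :]
    admissible = (ti < tj) & (c[:, None] == 0)
    n_adm = admissible.sum()
    if n_adm == 0:
        raise ValueError("no admissible pairs")
    si, sj = s[:, None], s[None, :]
    concordant = (si < sj) & admissible
    tied = (si == sj) & admissible
    return float((concordant.sum() + 0.5 * tied.sum()) / n_adm)


def pool_slide(spot_values: np.ndarray, mode: str = "average",
               gate: np.ndarray | None = None) -> np.ndarray:
    """Slide-level feature vector from per-spot predictions.

    ``average``: column means.  ``attention``: softmax-weighted mean with a
    gating vector (zero gate = uniform weights = average pooling).
    """
    v = np.asarray(spot_values, dtype=np.float64)
    if v.ndim != 2 or v.shape[0] < 1:
        raise ValueError("need a non-empty (spots x features) matrix")
    if mode == "average":
        return v.mean(axis=0)
    if mode == "attention":
        if gate is None:
            gate = np.zeros(v.shape[1])
        scores = v @ np.asarray(gate, float)
        scores = scores - scores.max()
        w = np.exp(scores)
        w = w / w.sum()
        return w @ v
    raise ValueError(f"unknown pooling mode {mode!r}")


def km_curve(times, censor) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate: (event_times, S(t)) step curve."""
    t = np.asarray(times, dtype=np.float64)
    c = np.asarray(censor, dtype=int)
    order = np.argsort(t, kind="stable")
    t, c = t[order], c[order]
    uniq = np.unique(t[c == 0])
    surv, s = [], 1.0
    for u in uniq:
        at_risk = (t >= u).sum()
        deaths = ((t == u) & (c == 0)).sum()
        s *= 1.0 - deaths / at_risk
        surv.append(s)
    return uniq, np.asarray(surv)


def km_stratify(scores, times, censor, split: str = "median") -> dict:
    """Median split on risk scores into high/low groups with KM curves."""
    if split != "median":
        raise ValueError("only median split is supported")
    s = np.asarray(scores, dtype=np.float64)
    if s.std() == 0:
        raise ValueError("constant scores cannot stratify")
    med = np.median(s)
    high = s > med
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    t = np.asarray(times, float)
    c = np.asarray(censor, int)
    return {
        "group": np.where(high, "high", "low"),
        "high": km_curve(t[high], c[high]),
        "low": km_curve(t[~high], c[~high]),
    }


def integrated_gradients(fn, x, baseline, steps: int = 64) -> np.ndarray:
    """Right-Riemann integrated gradients of a scalar differentiable
    function ``fn(Tensor (k,)) -> Tensor scalar``:

        IG_k = (x_k - x0_k) / steps * sum_{s=1..steps}
               dF/dx_k at x0 + (s/steps)(x - x0)

    Satisfies completeness (sum IG ~= F(x) - F(x0)) as steps grows; exact
    for linear F at any step count.
    """
    x = np.asarray(x, dtype=np.float64)
    x0 = np.asarray(baseline, dtype=np.float64)
    if x.shape != x0.shape:
        raise ValueError("baseline shape must match input")
    if steps < 2:
        raise ValueError("steps must be >= 2")
    total = np.zeros_like(x)
    for s in range(1, steps + 1):
        pt = Tensor(x0 + (s / steps) * (x - x0), requires_grad=True)
        out = fn(pt)
        out.backward()
        total += pt.grad
    return (x - x0) * total / steps
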