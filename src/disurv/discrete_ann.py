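"""Discrete-time individual survival prediction with a neural network.

The follow-up axis is cut into G intervals holding equal numbers of events
(so intervals are short where events are dense).  Each subject is encoded as
a length-G hazard-target vector: zeros through the interval containing the
subject's observed time, then ones for a subject who died, or the cohort
discrete hazards m_t/n_t for a censored subject.  A single-hidden-layer
network with logistic activations maps the covariates to the G per-interval
hazards; the hidden-layer size is chosen by a 10-fold cross-validation in
which each iteration uses one fold for testing, the next for validation and
the remaining eight for training.  Predicted hazards h_t are turned into a
survival curve by the product-limit formula S(t) = prod_{i < t} (1 - h_i),
and model quality is scored by the interval-distance accuracy

    ACC = sum_i (G - |T_surv,i - T'_surv,i|) / (G * N).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NumericalError, ValidationError
from .io_model import SurvivalDataset

__all__ = [
    "IntervalScheme",
    "AnnSurvivalModel",
    "SurvivalPrediction",
    "discretize",
    "interval_index",
    "cohort_interval_hazards",
    "encode_targets",
    "train_ann",
    "accuracy",
    "predict_survival",
]

DEFAULT_HIDDEN_GRID = (2, 4, 8, 12, 16, 20, 24, 32)


# ---------------------------------------------------------------------------
# interval scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntervalScheme:
    """Partition of [0, T] into G intervals with (near-)equal event counts.

    ``boundaries`` has G+1 strictly increasing entries, the first 0 and the
    last T (the maximum follow-up time).  Interval t (1-based) is
    (boundaries[t-1], boundaries[t]], except interval 1 which also contains
    time 0.
    """

    G: int
    boundaries: tuple[float, ...]
    events_per_interval: tuple[int, ...]

    def __post_init__(self):
        b = np.asarray(self.boundaries)
        if len(b) != self.G + 1 or np.any(np.diff(b) <= 0):
            raise ValidationError("boundaries must be G+1 strictly increasing times")

    def index_of(self, times) -> np.ndarray:
        return interval_index(times, self)


def interval_index(times, scheme: IntervalScheme) -> np.ndarray:
    """1-based interval index of each time under the scheme's boundaries."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    b = np.asarray(scheme.boundaries)
    if np.any(times < b[0]) or np.any(times > b[-1]):
        raise ValidationError("a time lies outside [0, T]")
    idx = np.searchsorted(b, times, side="left")  # interval (b[i-1], b[i]]
    idx[times == b[0]] = 1
    return idx


def discretize(ds: SurvivalDataset, G: int) -> IntervalScheme:
    """Cut [0, T] at event-time quantiles so each interval holds the same
    number of events (+-1, remainder spread over the earliest intervals).

    Tied event times are never split across a boundary: when the nominal
    cut falls inside a tie the boundary moves past the tie and a warning
    reports the uneven counts.
    """
    if G < 2:
        raise ConfigurationError("interval count G must be >= 2")
    etimes = np.sort(ds.time[ds.status == 1])
    D = len(etimes)
    if D < G:
        raise ValidationError(f"only {D} events for {G} intervals")
    T = float(np.max(ds.time))

    base, rem = divmod(D, G)
    target = np.full(G, base)
    target[:rem] += 1          # remainder to the earliest intervals
    cum = np.cumsum(target)

    # cut candidates: distinct event times strictly inside (0, T); a cut at
    # a tied time keeps the whole tie in the earlier interval
    distinct = np.unique(etimes)
    cum_at = np.searchsorted(etimes, distinct, side="right")
    keep = (distinct > 0.0) & (distinct < T)
    candidates, cum_at = distinct[keep], cum_at[keep]
    if len(candidates) < G - 1:
        raise ValidationError(
            "tied event times make a partition into G non-empty intervals "
            "impossible; reduce G"
        )
    boundaries = [0.0]
    prev = -1
    for j in range(G - 1):
        lo = prev + 1
        hi = len(candidates) - (G - 1 - j)   # leave room for later cuts
        window = cum_at[lo:hi + 1]
        best = lo + int(np.argmin(np.abs(window - cum[j])))
        boundaries.append(float(candidates[best]))
        prev = best
    boundaries.append(T)
    # realised events per interval, intervals (b_{t-1}, b_t] with 0 in the first
    pos = np.searchsorted(boundaries, etimes, side="left")
    pos[etimes == 0.0] = 1
    scheme_counts = np.bincount(pos, minlength=G + 1)[1:]
    if np.any(np.abs(scheme_counts - target) > 1):
        warnings.warn(
            "tied event times prevent exactly equal interval counts; "
            f"realised counts {scheme_counts.tolist()}"
        )
    return IntervalScheme(G=G, boundaries=tuple(boundaries),
                          events_per_interval=tuple(int(c) for c in scheme_counts))


# ---------------------------------------------------------------------------
# hazard-target encoding
# ---------------------------------------------------------------------------

def cohort_interval_hazards(ds: SurvivalDataset, scheme: IntervalScheme):
    """Empirical discrete hazards m_t/n_t on the interval-index scale.

    n_t counts subjects whose observed interval is >= t (still at risk at
    the start of interval t); m_t counts deaths in interval t.
    """
    idx = interval_index(ds.time, scheme)
    G = scheme.G
    m = np.zeros(G)
    n = np.zeros(G)
    for t in range(1, G + 1):
        at_risk = idx >= t
        n[t - 1] = at_risk.sum()
        m[t - 1] = np.sum(at_risk & (idx == t) & (ds.status == 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(n > 0, m / n, 0.0)
    return h, m, n


def encode_targets(ds: SurvivalDataset, scheme: IntervalScheme,
                   hazard_at_event: bool = False,
                   cohort_hazards: np.ndarray | None = None) -> np.ndarray:
    """Per-subject hazard-target vectors of length G.

    With the default (literal) encoding the entries are 0 for every interval
    up to and including the subject's interval, then 1 for an uncensored
    subject and the cohort hazard m_t/n_t for a censored one.

    ``hazard_at_event=True`` switches the encoding of uncensored subjects to
    the estimation-consistent variant: 1 at the event interval itself and
    the cohort hazard in the intervals after it (where the subject is no
    longer at risk).  Under squared-error training the conditional mean of
    that target is the discrete hazard, so the product-limit reconstruction
    of the network outputs estimates the survival curve; it also keeps a
    death in the last interval distinguishable from a survivor.  Censored
    subjects are encoded identically under both variants.

    ``cohort_hazards`` lets a caller supply hazards estimated on a training
    subset instead of on ``ds`` itself.
    """
    if cohort_hazards is None:
        cohort_hazards, _, _ = cohort_interval_hazards(ds, scheme)
    cohort_hazards = np.asarray(cohort_hazards, dtype=float)
    G = scheme.G
    if cohort_hazards.shape != (G,):
        raise ConfigurationError(f"cohort hazards must have length {G}")
    idx = interval_index(ds.time, scheme)
    status = ds.status
    cols = np.arange(1, G + 1)[None, :]
    after = cols > idx[:, None]
    if not hazard_at_event:
        targets = np.where(after,
                           np.where(status[:, None] == 1, 1.0,
                                    cohort_hazards[None, :]),
                           0.0)
    else:
        targets = np.where(after, cohort_hazards[None, :], 0.0)
        targets[(status == 1)[:, None] & (cols == idx[:, None])] = 1.0
    return targets


def accuracy(estimated, actual, G: int) -> float:
    """Interval-distance accuracy: sum (G - |T - T'|) / (G N)."""
    est = np.asarray(estimated, dtype=int)
    act = np.asarray(actual, dtype=int)
    if est.shape != act.shape:
        raise ValidationError("estimated and actual must have equal length")
    for arr, name in ((est, "estimated"), (act, "actual")):
        if np.any((arr < 1) | (arr > G)):
            raise ValidationError(f"{name} interval index outside 1..{G}")
    return float(np.sum(G - np.abs(est - act)) / (G * len(est)))


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


class _Mlp:
    """Single-hidden-layer network, logistic at both layers.

    Trained by full-batch Adam on the mean sum-of-squares loss with an L2
    weight penalty; optional early stopping on a validation set.
    """

    def __init__(self, n_in, n_hidden, n_out, rng, decay=1e-4):
        scale = 1.0 / np.sqrt(max(n_in, 1))
        self.W1 = rng.normal(0.0, scale, size=(n_in, n_hidden))
        self.b1 = np.zeros(n_hidden)
        self.W2 = rng.normal(0.0, 1.0 / np.sqrt(n_hidden), size=(n_hidden, n_out))
        self.b2 = np.zeros(n_out)
        self.decay = decay

    def forward(self, X):
        hidden = _sigmoid(X @ self.W1 + self.b1)
        return _sigmoid(hidden @ self.W2 + self.b2), hidden

    def loss(self, X, Y):
        out, _ = self.forward(X)
        penalty = self.decay * (np.sum(self.W1 ** 2) + np.sum(self.W2 ** 2))
        return float(np.mean(np.sum((out - Y) ** 2, axis=1)) + penalty)

    def _params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def train(self, X, Y, X_val=None, Y_val=None, epochs=500, patience=20,
              lr=0.05):
        n = len(X)
        moments = [(np.zeros_like(p), np.zeros_like(p)) for p in self._params()]
        best_val = np.inf
        best_state = [p.copy() for p in self._params()]
        stall = 0
        for epoch in range(1, epochs + 1):
            out, hidden = self.forward(X)
            err = 2.0 * (out - Y) / n
            d_out = err * out * (1.0 - out)
            gW2 = hidden.T @ d_out + 2.0 * self.decay * self.W2
            gb2 = d_out.sum(axis=0)
            d_hidden = (d_out @ self.W2.T) * hidden * (1.0 - hidden)
            gW1 = X.T @ d_hidden + 2.0 * self.decay * self.W1
            gb1 = d_hidden.sum(axis=0)
            grads = [gW1, gb1, gW2, gb2]
            if not all(np.all(np.isfinite(g)) for g in grads):
                raise NumericalError(
                    f"non-finite gradient at epoch {epoch}; "
                    "check covariate scaling"
                )
            for p, g, (m, v) in zip(self._params(), grads, moments):
                m *= 0.9
                m += 0.1 * g
                v *= 0.999
                v += 0.001 * g ** 2
                mh = m / (1.0 - 0.9 ** epoch)
                vh = v / (1.0 - 0.999 ** epoch)
                p -= lr * mh / (np.sqrt(vh) + 1e-8)
            if X_val is not None:
                val = self.loss(X_val, Y_val)
                if val < best_val - 1e-9:
                    best_val = val
                    best_state = [p.copy() for p in self._params()]
                    stall = 0
                else:
                    stall += 1
                    if stall >= patience:
                        break
        if X_val is not None:
            self.W1, self.b1, self.W2, self.b2 = best_state
        return self


# ---------------------------------------------------------------------------
# model container, training with CV model selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnSurvivalModel:
    scheme: IntervalScheme
    hidden_size: int
    covariate_names: tuple[str, ...]
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    cv_accuracy: float
    seed: int
    hazard_at_event: bool = False
    selection_table: tuple = field(default=(), repr=False)

    def predict_hazards(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != len(self.covariate_names):
            raise ValidationError(
                f"expected {len(self.covariate_names)} covariates, got {x.shape[1]}"
            )
        z = (x - self.x_mean) / self.x_scale
        hidden = _sigmoid(z @ self.W1 + self.b1)
        return _sigmoid(hidden @ self.W2 + self.b2)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "format": "disurv-ann/1",
            "scheme": {"G": self.scheme.G,
                       "boundaries": list(self.scheme.boundaries),
                       "events_per_interval": list(self.scheme.events_per_interval)},
            "hidden_size": self.hidden_size,
            "covariate_names": list(self.covariate_names),
            "weights": {k: getattr(self, k).tolist()
                        for k in ("W1", "b1", "W2", "b2")},
            "standardization": {"mean": self.x_mean.tolist(),
                                "scale": self.x_scale.tolist()},
            "cv_accuracy": self.cv_accuracy,
            "seed": self.seed,
            "hazard_at_event": self.hazard_at_event,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AnnSurvivalModel":
        payload = json.loads(text)
        if payload.get("format") != "disurv-ann/1":
            raise ConfigurationError("not a disurv ANN model file")
        sch = payload["scheme"]
        scheme = IntervalScheme(G=sch["G"], boundaries=tuple(sch["boundaries"]),
                                events_per_interval=tuple(sch["events_per_interval"]))
        wt = payload["weights"]
        std = payload["standardization"]
        return cls(
            scheme=scheme,
            hidden_size=payload["hidden_size"],
            covariate_names=tuple(payload["covariate_names"]),
            W1=np.asarray(wt["W1"]), b1=np.asarray(wt["b1"]),
            W2=np.asarray(wt["W2"]), b2=np.asarray(wt["b2"]),
            x_mean=np.asarray(std["mean"]), x_scale=np.asarray(std["scale"]),
            cv_accuracy=payload["cv_accuracy"],
            seed=payload["seed"],
            hazard_at_event=payload.get("hazard_at_event", False),
        )


@dataclass(frozen=True)
class SurvivalPrediction:
    hazards: np.ndarray            # length G
    survival: np.ndarray           # length G, S at the start of each interval
    estimated_interval: int


def _numeric_covariates(ds: SurvivalDataset) -> pd.DataFrame:
    cov = ds.covariates
    bad = [c for c in cov.columns
           if not pd.api.types.is_numeric_dtype(cov[c])]
    if bad:
        raise ValidationError(
            f"covariates {bad} are not numeric; expand categoricals first"
        )
    return cov.astype(float)


def train_ann(
    ds: SurvivalDataset,
    scheme: IntervalScheme,
    hidden_grid=DEFAULT_HIDDEN_GRID,
    seed: int = 0,
    hazard_at_event: bool = False,
    epochs: int = 500,
    patience: int = 20,
    decay: float = 1e-4,
    lr: float = 0.05,
) -> AnnSurvivalModel:
    """Select the hidden-layer size by 10-fold CV and fit the final network.

    The cohort is shuffled once under ``seed`` and cut into 10 folds of
    equal size (+-1).  In CV iteration i, fold i is the test set, fold
    i+1 (mod 10) the validation set and the remaining eight folds the
    training set.  For every candidate H a network is trained on the
    training folds (covariates standardised on those folds, hazard targets
    encoded from their own risk sets) with early stopping on the validation
    loss; the H with the best mean validation-fold interval accuracy wins.
    The reported ``cv_accuracy`` is the mean test-fold accuracy of the
    winning H, and the returned network is retrained on the full cohort.
    """
    hidden_grid = list(hidden_grid)
    if not hidden_grid:
        raise ConfigurationError("hidden_grid must be non-empty")
    if ds.n < 10:
        raise ValidationError("at least 10 subjects are needed for 10-fold CV")
    cov = _numeric_covariates(ds)
    X_all = cov.to_numpy(dtype=float)
    G = scheme.G
    actual_all = interval_index(ds.time, scheme)

    rng = np.random.default_rng(seed)
    order = rng.permutation(ds.n)
    folds = [order[k::10] for k in range(10)]

    def run_fold(i, H, collect_test):
        test_idx = folds[i]
        val_idx = folds[(i + 1) % 10]
        train_idx = np.concatenate([folds[k] for k in range(10)
                                    if k not in (i, (i + 1) % 10)])
        sub = ds.with_frame(ds.frame.iloc[train_idx].reset_index(drop=True))
        h_train, _, _ = cohort_interval_hazards(sub, scheme)
        Y_train = encode_targets(sub, scheme, hazard_at_event, h_train)
        mean = X_all[train_idx].mean(axis=0)
        scale = X_all[train_idx].std(axis=0)
        scale[scale == 0] = 1.0
        Z = (X_all - mean) / scale
        val_ds = ds.with_frame(ds.frame.iloc[val_idx].reset_index(drop=True))
        Y_val = encode_targets(val_ds, scheme, hazard_at_event, h_train)
        net = _Mlp(X_all.shape[1], H, G, np.random.default_rng(
            rng_seeds[i, hidden_grid.index(H)]), decay)
        net.train(Z[train_idx], Y_train, Z[val_idx], Y_val,
                  epochs=epochs, patience=patience, lr=lr)

        def fold_acc(idx):
            haz = _sigmoid(_sigmoid(Z[idx] @ net.W1 + net.b1) @ net.W2 + net.b2)
            est = _estimated_intervals(haz)
            return accuracy(est, actual_all[idx], G)

        return fold_acc(val_idx), (fold_acc(test_idx) if collect_test else None)

    rng_seeds = rng.integers(0, 2 ** 31 - 1, size=(10, len(hidden_grid)))
    mean_val_acc = {}
    for H in hidden_grid:
        accs = [run_fold(i, H, False)[0] for i in range(10)]
        mean_val_acc[H] = float(np.mean(accs))
    best_H = max(hidden_grid, key=lambda H: (mean_val_acc[H], -H))
    test_accs = [run_fold(i, best_H, True)[1] for i in range(10)]
    cv_accuracy = float(np.mean(test_accs))

    # final network: retrain on the full cohort at the selected size
    mean = X_all.mean(axis=0)
    scale = X_all.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X_all - mean) / scale
    h_full, _, _ = cohort_interval_hazards(ds, scheme)
    Y_full = encode_targets(ds, scheme, hazard_at_event, h_full)
    final_rng = np.random.default_rng(int(rng.integers(0, 2 ** 31 - 1)))
    net = _Mlp(X_all.shape[1], best_H, G, final_rng, decay)
    net.train(Z, Y_full, epochs=epochs, lr=lr)

    return AnnSurvivalModel(
        scheme=scheme,
        hidden_size=best_H,
        covariate_names=tuple(cov.columns),
        W1=net.W1, b1=net.b1, W2=net.W2, b2=net.b2,
        x_mean=mean, x_scale=scale,
        cv_accuracy=cv_accuracy,
        seed=seed,
        hazard_at_event=hazard_at_event,
        selection_table=tuple(sorted(mean_val_acc.items())),
    )


def _estimated_intervals(hazards: np.ndarray) -> np.ndarray:
    """First interval whose end-of-interval survival drops below 0.5, else G."""
    surv_end = np.cumprod(1.0 - hazards, axis=1)
    below = surv_end < 0.5
    est = np.where(below.any(axis=1), below.argmax(axis=1) + 1, hazards.shape[1])
    return est


def predict_survival(model: AnnSurvivalModel, covariates) -> SurvivalPrediction:
    """Forward pass for one subject; survival by the product-limit formula.

    ``survival[t-1]`` is S at the start of interval t, the product of
    (1 - h_i) over the strictly earlier intervals, so it starts at 1.
    ``estimated_interval`` is the first interval whose end-of-interval
    survival falls below 0.5 (G if it never does).
    """
    hazards = model.predict_hazards(covariates)[0]
    survival = np.concatenate([[1.0], np.cumprod(1.0 - hazards)])[:-1]
    est = int(_estimated_intervals(hazards[None, :])[0])
    return SurvivalPrediction(hazards=hazards, survival=survival,
                              estimated_interval=est)
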