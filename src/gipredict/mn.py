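"""Interpretable multinomial (softmax) regression for knockout viability.

The model has one linear equation per non-reference output class, each
giving the log odds of that class against a fixed reference class
(normal growth for single-gene fitness, neutral for genetic-interaction
models):

    log(p_x / p_ref) = b0_x + b_x . features

which is the softmax parameterisation with the reference-class score
pinned at zero.  Coefficients exponentiate to odds factors: exp(b)
is the multiplicative change in class-vs-reference odds per unit
increase of the feature, which is what makes these models open-box.

Training minimises class-weighted categorical cross-entropy (plus an
optional L2 penalty on non-intercept weights) by mini-batch stochastic
gradient descent with a 1/(1 + decay*epoch) step-size schedule and
tail (Polyak) averaging of the iterates, which removes most of the SGD
endpoint noise without giving up the simple first-order optimiser.

Features may be standardised internally for conditioning; coefficients
are always reported back on the original feature scale so odds factors
stay interpretable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class DegenerateClassError(ValueError):
    """A class required by the weighting scheme or fit has no examples."""


class DivergenceError(RuntimeError):
    """Training loss became non-finite (step size too large)."""


@dataclass
class TrainingConfig:
    """Hyperparameters for stochastic-gradient training.

    ``class_weight_scheme`` is ``"inverse_frequency"`` (default; class c
    gets weight N/(K*N_c), mean weight one per example), ``"uniform"``,
    or an explicit ``{class: weight}`` table.  ``lr_decay`` sets the
    schedule lr_t = lr / (1 + lr_decay * epoch); ``average_tail``
    is the fraction of final epochs whose end-of-epoch iterates are
    averaged into the returned coefficients (0 disables averaging).
    """

    learning_rate: float = 0.05
    n_epochs: int = 200
    batch_size: int = 128
    l2_penalty: float = 1e-4
    seed: int = 0
    class_weight_scheme: object = "inverse_frequency"
    standardize_features: bool = True
    lr_decay: float = 0.02
    average_tail: float = 0.25

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be at least 1")


def class_weights(label_counts: dict, scheme) -> dict:
    """Per-class loss weights.

    inverse_frequency: w_c = N_total / (K * N_c) (mean weight per
    example is one); uniform: all ones; a dict is passed through.
    """
    classes = list(label_counts)
    if isinstance(scheme, dict):
        return {c: float(scheme[c]) for c in classes}
    if scheme == "uniform":
        return {c: 1.0 for c in classes}
    if scheme == "inverse_frequency":
        total = sum(label_counts.values())
        k = len(classes)
        for c, n_c in label_counts.items():
            if n_c == 0:
                raise DegenerateClassError(
                    f"class {c!r} has no examples; inverse-frequency "
                    "weights are undefined")
        return {c: total / (k * n_c) for c, n_c in label_counts.items()}
    raise ValueError(f"unknown class-weight scheme {scheme!r}")


def weighted_cross_entropy(probs: np.ndarray, y_index: np.ndarray,
                           weights: np.ndarray, eps: float = 1e-12) -> float:
    """Mean over examples of -w_y * log p_y, with p clipped at ``eps``."""
    p_y = probs[np.arange(len(y_index)), y_index]
    n_clipped = int(np.sum(p_y < eps))
    if n_clipped:
        logger.debug("clipped %d probabilities at %.0e in the loss",
                     n_clipped, eps)
    return float(np.mean(-weights[y_index] * np.log(np.clip(p_y, eps, None))))


def odds_factor(coefficient: float) -> float:
    """exp(coefficient): multiplicative change in class-vs-reference odds
    per unit increase of the corresponding feature."""
    return float(np.exp(coefficient))


@dataclass
class MNModel:
    """A fitted (or ground-truth) multinomial regression model.

    ``coefficients`` has one row per non-reference class, in the order
    the non-reference classes appear in ``classes``; columns are
    ``[intercept, features...]`` following ``feature_names``.  The
    reference-class row is implicitly all zero.
    """

    classes: tuple[str, ...]
    reference_class: str
    coefficients: np.ndarray
    feature_names: tuple[str, ...]
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.classes = tuple(self.classes)
        self.feature_names = tuple(self.feature_names)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.reference_class not in self.classes:
            raise ValueError("reference_class must be one of classes")
        expected = (len(self.classes) - 1, 1 + len(self.feature_names))
        if self.coefficients.shape != expected:
            raise ValueError(
                f"coefficient matrix shape {self.coefficients.shape} != "
                f"expected {expected}")

    # -- structure -------------------------------------------------------
    @property
    def nonref_classes(self) -> tuple[str, ...]:
        return tuple(c for c in self.classes if c != self.reference_class)

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class linear scores (reference column fixed at zero)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature length {X.shape[1]} != layout "
                f"{len(self.feature_names)}")
        if not np.isfinite(X).all():
            raise ValueError("features must be finite")
        s_nonref = X @ self.coefficients[:, 1:].T + self.coefficients[:, 0]
        scores = np.zeros((X.shape[0], len(self.classes)))
        for j, c in enumerate(self.nonref_classes):
            scores[:, self.classes.index(c)] = s_nonref[:, j]
        return scores

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Softmax class probabilities; rows sum to one."""
        s = self.scores(X)
        s -= s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        p = self.predict_proba(X)
        return np.asarray(self.classes)[p.argmax(axis=1)]

    def odds_factors(self) -> pd.DataFrame:
        """exp(coefficients) as a tidy table (rows: intercept+features,
        columns: non-reference classes)."""
        return pd.DataFrame(
            np.exp(self.coefficients).T,
            index=["intercept"] + list(self.feature_names),
            columns=list(self.nonref_classes))

    # -- serialization ---------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "classes": list(self.classes),
            "reference_class": self.reference_class,
            "feature_names": list(self.feature_names),
            "coefficients": self.coefficients.tolist(),
            "training_meta": self.training_meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MNModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(tuple(d["classes"]), d["reference_class"],
                   np.array(d["coefficients"]), tuple(d["feature_names"]),
                   d.get("training_meta", {}))


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    sd_safe = np.where(keep, sd, 1.0)
    mu_safe = np.where(keep, mu, 0.0)  # constant columns left untouched
    return (X - mu_safe) / sd_safe, mu_safe, sd_safe


def fit_mn(X: np.ndarray, y, *, classes=None, reference_class=None,
           feature_names=None, config: TrainingConfig | None = None,
           loss_history: bool = False) -> MNModel:
    """Fit a multinomial model by mini-batch SGD on weighted cross-entropy.

    Parameters
    ----------
    X, y:
        Feature matrix (n, p) and label sequence of length n.
    classes:
        Output class order; defaults to sorted unique labels.
    reference_class:
        The class whose score is pinned at zero; defaults to the last
        entry of ``classes``.
    loss_history:
        If true, store the full-dataset loss per epoch in
        ``training_meta["loss_history"]``.
    """
    config = config or TrainingConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if classes is None:
        classes = tuple(sorted(set(y.tolist())))
    classes = tuple(classes)
    if len(set(y.tolist())) < 2:
        raise DegenerateClassError("need at least two classes in the data")
    if reference_class is None:
        reference_class = classes[-1]
    if feature_names is None:
        feature_names = tuple(f"x{j}" for j in range(X.shape[1]))

    class_index = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_index[lab] for lab in y])
    counts = {c: int(np.sum(y_idx == i)) for c, i in class_index.items()}
    w_table = class_weights(counts, config.class_weight_scheme)
    w = np.array([w_table[c] for c in classes])

    Z, mu, sd = (X, np.zeros(X.shape[1]), np.ones(X.shape[1]))
    if config.standardize_features:
        Z, mu, sd = _standardize(X)

    n, p = Z.shape
    nonref = [i for i, c in enumerate(classes) if c != reference_class]
    K1 = len(classes) - 1
    B = np.zeros((K1, p + 1))  # [intercept | weights] per non-ref class
    rng = np.random.default_rng(config.seed)
    Y = np.zeros((n, len(classes)))
    Y[np.arange(n), y_idx] = 1.0

    def forward(Zb):
        s = Zb @ B[:, 1:].T + B[:, 0]
        full = np.zeros((Zb.shape[0], len(classes)))
        full[:, nonref] = s
        full -= full.max(axis=1, keepdims=True)
        e = np.exp(full)
        return e / e.sum(axis=1, keepdims=True)

    history = []
    tail_start = config.n_epochs - max(1, int(round(
        config.average_tail * config.n_epochs)))
    B_avg = np.zeros_like(B)
    n_avg = 0
    for epoch in range(config.n_epochs):
        lr = config.learning_rate / (1.0 + config.lr_decay * epoch)
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            Zb, Yb = Z[idx], Y[idx]
            P = forward(Zb)
            G = (P - Yb) * w[y_idx[idx]][:, None] / len(idx)
            grad = np.empty_like(B)
            grad[:, 0] = G[:, nonref].sum(axis=0)
            grad[:, 1:] = G[:, nonref].T @ Zb
            grad[:, 1:] += 2.0 * config.l2_penalty * B[:, 1:]
            B -= lr * grad
        if not np.isfinite(B).all():
            raise DivergenceError(
                "training diverged (non-finite coefficients); reduce the "
                "learning rate or standardize features")
        if loss_history:
            history.append(weighted_cross_entropy(forward(Z), y_idx, w))
        if config.average_tail > 0 and epoch >= tail_start:
            B_avg += B
            n_avg += 1
    if n_avg:
        B = B_avg / n_avg

    # map back to the original feature scale
    coef = np.empty_like(B)
    coef[:, 1:] = B[:, 1:] / sd
    coef[:, 0] = B[:, 0] - (B[:, 1:] * (mu / sd)).sum(axis=1)

    meta = {"config": {k: (v if not isinstance(v, dict) else dict(v))
                       for k, v in asdict(config).items()},
            "n_examples": int(n), "class_counts": counts}
    if loss_history:
        meta["loss_history"] = history
    return MNModel(classes, reference_class, coef, feature_names, meta)


def canonicalize_gauge(model: MNModel, combo_names) -> MNModel:
    """Resolve the intercept/one-hot aliasing of fitness-combo blocks.

    A full combination one-hot sums to one, so adding a constant to all
    combo coefficients while subtracting it from the intercept leaves
    every prediction unchanged.  This fixes the gauge by zeroing the
    last-listed combo coefficient per class row, making coefficient sets
    from different fits (or a ground truth) directly comparable.
    """
    names = list(model.feature_names)
    cols = [1 + names.index(c) for c in combo_names]
    ref_col = cols[-1]
    coef = model.coefficients.copy()
    shift = coef[:, ref_col].copy()
    coef[:, cols] -= shift[:, None]
    coef[:, 0] += shift
    return MNModel(model.classes, model.reference_class, coef,
                   model.feature_names, dict(model.training_meta))


def predictions_to_tsv(path, tuples, model: MNModel, X: np.ndarray) -> None:
    """Write per-tuple class probabilities and the argmax class as TSV."""
    probs = model.predict_proba(X)
    arity = len(tuples[0]) if not isinstance(tuples[0], str) else 1
    if arity == 1:
        df = pd.DataFrame({"gene_a": list(tuples)})
    else:
        df = pd.DataFrame(list(tuples),
                          columns=[f"gene_{chr(97 + i)}" for i in range(arity)])
    for j, c in enumerate(model.classes):
        df[f"p_{c}"] = probs[:, j]
    df["predicted"] = np.asarray(model.classes)[probs.argmax(axis=1)]
    df.to_csv(path, sep="\t", index=False)
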