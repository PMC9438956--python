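"""Black-box neural counterparts of the multinomial viability models.

Two small numpy networks with hand-written backpropagation:

* :class:`FeedForwardClassifier` — a plain multilayer perceptron for
  single-gene fitness prediction.
* :class:`SiameseClassifier` — weight-shared per-gene towers plus a
  pairwise-feature sub-network for gene pairs (and, with three towers,
  triplets).  The tower embeddings are combined by summation, so the
  prediction is exactly invariant to any permutation of the input genes
  for every weight setting, not merely after training.

Both are trained on class-weighted categorical cross-entropy with Adam
and are deterministic under a fixed seed.  They exist as performance
yardsticks: the scientific claim under test is that the interpretable
multinomial models match them on linearly generated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mn import class_weights, weighted_cross_entropy

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda a: 1.0 - a ** 2),
    "relu": (lambda x: np.maximum(x, 0.0), lambda a: (a > 0).astype(float)),
}


@dataclass
class NNConfig:
    """Architecture and training hyperparameters for the numpy networks."""

    hidden_sizes: tuple[int, ...] = (32,)
    activation: str = "tanh"
    learning_rate: float = 1e-3
    n_epochs: int = 100
    batch_size: int = 128
    seed: int = 0
    class_weight_scheme: object = "inverse_frequency"
    l2_penalty: float = 0.0

    def __post_init__(self):
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g ** 2
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _init(rng, n_in, n_out):
    # Glorot-style scaling keeps tanh activations in range at init
    s = np.sqrt(2.0 / (n_in + n_out))
    return rng.normal(0.0, s, size=(n_in, n_out))


def _softmax(s):
    s = s - s.max(axis=1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=1, keepdims=True)


def _standardize_fit(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


class FeedForwardClassifier:
    """MLP probabilistic K-class classifier trained with weighted CE."""

    def __init__(self, config: NNConfig | None = None):
        self.config = config or NNConfig()
        self.classes: tuple[str, ...] | None = None

    def fit(self, X: np.ndarray, y, classes=None) -> "FeedForwardClassifier":
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes = tuple(classes) if classes is not None \
            else tuple(sorted(set(y.tolist())))
        cindex = {c: i for i, c in enumerate(self.classes)}
        y_idx = np.array([cindex[lab] for lab in y])
        counts = {c: int(np.sum(y_idx == i)) for c, i in cindex.items()}
        w_tab = class_weights(counts, cfg.class_weight_scheme)
        self._w = np.array([w_tab[c] for c in self.classes])
        self._mu, self._sd = _standardize_fit(X)
        Z = (X - self._mu) / self._sd

        rng = np.random.default_rng(cfg.seed)
        act, dact = _ACTIVATIONS[cfg.activation]
        sizes = [Z.shape[1], *cfg.hidden_sizes, len(self.classes)]
        self._W = [_init(rng, a, b) for a, b in zip(sizes[:-1], sizes[1:])]
        self._b = [np.zeros(b) for b in sizes[1:]]
        opt = _Adam(self._W + self._b, cfg.learning_rate)
        n = Z.shape[0]
        Y = np.zeros((n, len(self.classes)))
        Y[np.arange(n), y_idx] = 1.0

        for _ in range(cfg.n_epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                a_list = [Z[idx]]
                for W, b in zip(self._W[:-1], self._b[:-1]):
                    a_list.append(act(a_list[-1] @ W + b))
                logits = a_list[-1] @ self._W[-1] + self._b[-1]
                P = _softmax(logits)
                delta = (P - Y[idx]) * self._w[y_idx[idx]][:, None] / len(idx)
                gW, gb = [], []
                for layer in range(len(self._W) - 1, -1, -1):
                    gW.insert(0, a_list[layer].T @ delta
                              + 2 * cfg.l2_penalty * self._W[layer])
                    gb.insert(0, delta.sum(axis=0))
                    if layer > 0:
                        delta = (delta @ self._W[layer].T) * dact(a_list[layer])
                opt.step(self._W + self._b, gW + gb)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        act, _ = _ACTIVATIONS[self.config.activation]
        a = (np.asarray(X, dtype=float) - self._mu) / self._sd
        for W, b in zip(self._W[:-1], self._b[:-1]):
            a = act(a @ W + b)
        return _softmax(a @ self._W[-1] + self._b[-1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        p = self.predict_proba(X)
        return np.asarray(self.classes)[p.argmax(axis=1)]


class SiameseClassifier:
    """Weight-shared gene towers + pairwise sub-network, symmetric by sum.

    Input is ``(G, P)``: ``G`` of shape (n, arity, d_gene) holds each
    gene's feature block (all genes pass through the *same* tower), and
    ``P`` of shape (n, d_pair) the joint pairwise block (e.g. shortest
    path length).  Tower outputs are summed — a symmetric aggregation —
    concatenated with the pairwise embedding, passed through a combiner
    hidden layer (so non-additive fitness-combination effects are
    representable) and read out with softmax.
    """

    def __init__(self, config: NNConfig | None = None,
                 combiner_size: int | None = None):
        self.config = config or NNConfig()
        self.combiner_size = combiner_size or self.config.hidden_sizes[0]
        self.classes: tuple[str, ...] | None = None

    def _init_weights(self, rng, d_gene, d_pair, k_out):
        h = self.config.hidden_sizes[0]
        hc = self.combiner_size
        self._Wt = _init(rng, d_gene, h)     # shared tower
        self._bt = np.zeros(h)
        self._Wp = _init(rng, d_pair, h)     # pairwise sub-network
        self._bp = np.zeros(h)
        self._Wc = _init(rng, 2 * h, hc)     # combiner
        self._bc = np.zeros(hc)
        self._Wo = _init(rng, hc, k_out)
        self._bo = np.zeros(k_out)

    def _params(self):
        return [self._Wt, self._bt, self._Wp, self._bp,
                self._Wc, self._bc, self._Wo, self._bo]

    def _forward(self, G, P):
        act, _ = _ACTIVATIONS[self.config.activation]
        towers = act(G @ self._Wt + self._bt)      # (n, arity, h)
        # symmetric aggregation; sorting first fixes the floating-point
        # summation order, making predictions bitwise permutation-invariant
        e = np.sort(towers, axis=1).sum(axis=1)
        q = act(P @ self._Wp + self._bp)
        cat = np.concatenate([e, q], axis=1)
        z = act(cat @ self._Wc + self._bc)
        logits = z @ self._Wo + self._bo
        return towers, e, q, cat, z, _softmax(logits)

    def fit(self, data, y, classes=None) -> "SiameseClassifier":
        cfg = self.config
        G, P = data
        G = np.asarray(G, dtype=float)
        P = np.asarray(P, dtype=float)
        if G.ndim != 3:
            raise ValueError("gene block must have shape (n, arity, d_gene)")
        y = np.asarray(y)
        self.classes = tuple(classes) if classes is not None \
            else tuple(sorted(set(y.tolist())))
        cindex = {c: i for i, c in enumerate(self.classes)}
        y_idx = np.array([cindex[lab] for lab in y])
        counts = {c: int(np.sum(y_idx == i)) for c, i in cindex.items()}
        w_tab = class_weights(counts, cfg.class_weight_scheme)
        self._w = np.array([w_tab[c] for c in self.classes])

        # standardize per-gene and pairwise blocks (shared gene scaling
        # preserves tower weight sharing and hence exact symmetry)
        flat = G.reshape(-1, G.shape[2])
        self._mu_g, self._sd_g = _standardize_fit(flat)
        self._mu_p, self._sd_p = _standardize_fit(P)
        Gz = (G - self._mu_g) / self._sd_g
        Pz = (P - self._mu_p) / self._sd_p

        rng = np.random.default_rng(cfg.seed)
        self._init_weights(rng, G.shape[2], P.shape[1], len(self.classes))
        opt = _Adam(self._params(), cfg.learning_rate)
        act, dact = _ACTIVATIONS[cfg.activation]
        n = G.shape[0]
        Y = np.zeros((n, len(self.classes)))
        Y[np.arange(n), y_idx] = 1.0

        for _ in range(cfg.n_epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                Gb, Pb, Yb = Gz[idx], Pz[idx], Y[idx]
                towers, e, q, cat, z, Pr = self._forward(Gb, Pb)
                m = len(idx)
                dlog = (Pr - Yb) * self._w[y_idx[idx]][:, None] / m
                gWo = z.T @ dlog
                gbo = dlog.sum(axis=0)
                dz = (dlog @ self._Wo.T) * dact(z)
                gWc = cat.T @ dz
                gbc = dz.sum(axis=0)
                dcat = dz @ self._Wc.T
                h = towers.shape[2]
                de, dq = dcat[:, :h], dcat[:, h:]
                dq = dq * dact(q)
                gWp = Pb.T @ dq
                gbp = dq.sum(axis=0)
                # tower gradient: summed over the (shared) gene slots
                dt = de[:, None, :] * dact(towers)      # (m, arity, h)
                gWt = np.einsum("maf,mah->fh", Gb, dt)
                gbt = dt.sum(axis=(0, 1))
                opt.step(self._params(),
                         [gWt, gbt, gWp, gbp, gWc, gbc, gWo, gbo])
        return self

    def predict_proba(self, data) -> np.ndarray:
        G, P = data
        Gz = (np.asarray(G, dtype=float) - self._mu_g) / self._sd_g
        Pz = (np.asarray(P, dtype=float) - self._mu_p) / self._sd_p
        return self._forward(Gz, Pz)[-1]

    def predict(self, data) -> np.ndarray:
        p = self.predict_proba(data)
        return np.asarray(self.classes)[p.argmax(axis=1)]

    # -- portable serialization -----------------------------------------
    def save(self, path) -> None:
        import json
        payload = {"config": self.config.__dict__ | {
                       "hidden_sizes": list(self.config.hidden_sizes)},
                   "combiner_size": self.combiner_size,
                   "classes": list(self.classes),
                   "weights": [p.tolist() for p in self._params()],
                   "scaling": [self._mu_g.tolist(), self._sd_g.tolist(),
                               self._mu_p.tolist(), self._sd_p.tolist()]}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "SiameseClassifier":
        import json
        with open(path) as fh:
            d = json.load(fh)
        cfgd = d["config"]
        cfgd["hidden_sizes"] = tuple(cfgd["hidden_sizes"])
        obj = cls(NNConfig(**cfgd), combiner_size=d["combiner_size"])
        obj.classes = tuple(d["classes"])
        (obj._Wt, obj._bt, obj._Wp, obj._bp, obj._Wc, obj._bc,
         obj._Wo, obj._bo) = [np.array(p) for p in d["weights"]]
        obj._mu_g, obj._sd_g, obj._mu_p, obj._sd_p = \
            [np.array(a) for a in d["scaling"]]
        return obj


def fit_feedforward(X, y, config: NNConfig | None = None,
                    classes=None) -> FeedForwardClassifier:
    """Convenience wrapper: construct and fit a feed-forward classifier."""
    return FeedForwardClassifier(config).fit(X, y, classes=classes)


def fit_siamese(data, y, config: NNConfig | None = None,
                classes=None) -> SiameseClassifier:
    """Convenience wrapper: construct and fit a Siamese classifier on
    ``(gene_blocks, pairwise_block)`` data."""
    return SiameseClassifier(config).fit(data, y, classes=classes)
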