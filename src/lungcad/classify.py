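"""Two-stage classification: per-descriptor stacked autoencoders and fusion.

Stage 1 trains, per descriptor, a stack of three autoencoder layers whose
widths shrink by one third each (``ceil(2 d / 3)``, floor width 2), greedily
pretrained on the reconstruction objective and then fine-tuned end-to-end with
a 2-class softmax head.  The softmax output is the preliminary malignancy
probability for that descriptor.  Stage 2 concatenates the per-descriptor
probabilities and feeds them through a single hidden autoencoder layer (width
4) plus softmax for the final diagnosis.

Training details (fixed for reproducibility, they are conventional rather than
prescribed): plain non-denoising autoencoders, sigmoid activations, linear
decoders, MSE reconstruction loss, full-batch Adam, 200 pretraining epochs per
layer and 200 fine-tuning epochs, features z-scored per column.  Everything is
deterministic given (data, config, seed).

Evaluation reports accuracy / sensitivity / specificity / precision (percent)
from the 0.5-threshold confusion matrix plus the trapezoidal ROC AUC.
Malignant is the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

__all__ = [
    "StackedSAEConfig",
    "build_stacked_sae",
    "stacked_layer_dims",
    "StackedAutoencoderClassifier",
    "FusionClassifier",
    "train_descriptor_classifier",
    "fuse",
    "EvalReport",
    "evaluate",
    "split_train_test",
]

POSITIVE_LABEL = "malignant"


def stacked_layer_dims(input_dim: int, n_layers: int = 3, rule: str = "two_thirds",
                       min_width: int = 2) -> tuple:
    """Hidden widths obtained by shrinking the input by one third per layer.

    ``rule="two_thirds"`` keeps 2/3 of the previous width (reduce *by* a
    third, the default reading); ``rule="one_third"`` keeps 1/3 (reduce *to* a
    third).  Widths are ceil-rounded and floored at ``min_width``.
    """
    if rule not in ("two_thirds", "one_third"):
        raise ValueError(f"unknown reduction rule {rule!r}")
    frac = 2.0 / 3.0 if rule == "two_thirds" else 1.0 / 3.0
    dims = []
    d = input_dim
    for _ in range(n_layers):
        d = max(int(np.ceil(d * frac)), min_width)
        dims.append(d)
    return tuple(dims)


@dataclass
class StackedSAEConfig:
    """Architecture + training hyper-parameters of one stacked autoencoder."""

    input_dim: int
    layer_dims: tuple
    pretrain_epochs: int = 200
    finetune_epochs: int = 200
    learning_rate: float = 0.005
    seed: int = 0


def build_stacked_sae(input_dim: int, seed: int = 0, rule: str = "two_thirds",
                      pretrain_epochs: int = 200, finetune_epochs: int = 200,
                      learning_rate: float = 0.005) -> StackedSAEConfig:
    """Three-hidden-layer architecture for a descriptor of ``input_dim`` features."""
    if input_dim < 3:
        raise ValueError(f"input_dim must be >= 3, got {input_dim}")
    return StackedSAEConfig(
        input_dim=input_dim,
        layer_dims=stacked_layer_dims(input_dim, rule=rule),
        pretrain_epochs=pretrain_epochs,
        finetune_epochs=finetune_epochs,
        learning_rate=learning_rate,
        seed=seed,
    )


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _Adam:
    def __init__(self, params, lr):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + eps)


def _glorot(rng, d_in, d_out):
    lim = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-lim, lim, size=(d_in, d_out)).astype(np.float32)


def _pretrain_layer(h, d_out, epochs, lr, rng):
    """Train one sigmoid-encoder / linear-decoder autoencoder; return encoder."""
    d_in = h.shape[1]
    w1 = _glorot(rng, d_in, d_out)
    b1 = np.zeros(d_out, dtype=np.float32)
    w2 = _glorot(rng, d_out, d_in)
    b2 = np.zeros(d_in, dtype=np.float32)
    opt = _Adam([w1, b1, w2, b2], lr)
    n = len(h)
    for _ in range(epochs):
        z = _sigmoid(h @ w1 + b1)
        rec = z @ w2 + b2
        err = (rec - h) * (2.0 / (n * d_in))
        gw2 = z.T @ err
        gb2 = err.sum(axis=0)
        dz = (err @ w2.T) * z * (1 - z)
        gw1 = h.T @ dz
        gb1 = dz.sum(axis=0)
        opt.step([gw1, gb1, gw2, gb2])
    return w1, b1


class StackedAutoencoderClassifier(BaseEstimator, ClassifierMixin):
    """Greedy-pretrained stacked autoencoder with a softmax head.

    Parameters
    ----------
    hidden_dims : tuple or None
        Explicit hidden widths; when None they follow the one-third reduction
        rule (three layers of ``ceil(2 d / 3)`` each).
    rule : {"two_thirds", "one_third"}
        Which reading of "reduces the dimensionality by one third" to apply
        when ``hidden_dims`` is None.
    """

    def __init__(self, hidden_dims=None, n_layers: int = 3, rule: str = "two_thirds",
                 pretrain_epochs: int = 200, finetune_epochs: int = 200,
                 learning_rate: float = 0.005, random_state: int = 0):
        self.hidden_dims = hidden_dims
        self.n_layers = n_layers
        self.rule = rule
        self.pretrain_epochs = pretrain_epochs
        self.finetune_epochs = finetune_epochs
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _standardize(self, X, fit=False):
        if fit:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        return ((X - self.mean_) / self.scale_).astype(np.float32)

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training requires samples from both classes")
        counts = np.bincount(y_idx)
        if counts.min() < 2:
            raise ValueError("training requires at least 2 samples per class")
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        h = self._standardize(X, fit=True)
        dims = tuple(self.hidden_dims) if self.hidden_dims is not None else stacked_layer_dims(
            X.shape[1], n_layers=self.n_layers, rule=self.rule)
        # greedy layer-wise pretraining on the reconstruction objective
        self.weights_ = []
        for d_out in dims:
            w, b = _pretrain_layer(h, d_out, self.pretrain_epochs, self.learning_rate, rng)
            self.weights_.append([w, b])
            h = _sigmoid(h @ w + b)
        # softmax head + supervised fine-tuning through the whole stack
        n_classes = len(self.classes_)
        w_out = _glorot(rng, dims[-1], n_classes)
        b_out = np.zeros(n_classes, dtype=np.float32)
        params = [p for wb in self.weights_ for p in wb] + [w_out, b_out]
        opt = _Adam(params, self.learning_rate)
        t = np.zeros((len(y_idx), n_classes), dtype=np.float32)
        t[np.arange(len(y_idx)), y_idx] = 1.0
        x0 = self._standardize(X)
        n = len(x0)
        for _ in range(self.finetune_epochs):
            acts = [x0]
            for w, b in self.weights_:
                acts.append(_sigmoid(acts[-1] @ w + b))
            logits = acts[-1] @ w_out + b_out
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            p = e / e.sum(axis=1, keepdims=True)
            delta = (p - t) / n
            grads = []
            g_wout = acts[-1].T @ delta
            g_bout = delta.sum(axis=0)
            back = delta @ w_out.T
            for (w, b), a_in, a_out in zip(reversed(self.weights_), reversed(acts[:-1]),
                                           reversed(acts[1:])):
                dz = back * a_out * (1 - a_out)
                grads.append([a_in.T @ dz, dz.sum(axis=0)])
                back = dz @ w.T
            flat = [g for wb in reversed(grads) for g in wb] + [g_wout, g_bout]
            opt.step(flat)
        self.head_ = [w_out, b_out]
        self.layer_dims_ = dims
        return self

    def _forward(self, X):
        h = self._standardize(np.asarray(X, dtype=np.float64))
        for w, b in self.weights_:
            h = _sigmoid(h @ w + b)
        logits = h @ self.head_[0] + self.head_[1]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, X):
        return self._forward(X).astype(np.float64)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def malignancy_probability(self, X) -> np.ndarray:
        """P(malignant) per sample (the positive-class softmax output)."""
        p = self.predict_proba(X)
        col = int(np.where(self.classes_ == POSITIVE_LABEL)[0][0]) if POSITIVE_LABEL in self.classes_ else 1
        return p[:, col]


class FusionClassifier(StackedAutoencoderClassifier):
    """Stage-2 network: one hidden autoencoder layer (width 4) + softmax.

    ``n_expected_inputs`` guards the input dimension (six stage-1
    probabilities by default; configurable when descriptors are disabled).
    """

    def __init__(self, hidden_width: int = 4, n_expected_inputs: int | None = 6,
                 pretrain_epochs: int = 200, finetune_epochs: int = 200,
                 learning_rate: float = 0.01, random_state: int = 0):
        super().__init__(hidden_dims=(hidden_width,), pretrain_epochs=pretrain_epochs,
                         finetune_epochs=finetune_epochs, learning_rate=learning_rate,
                         random_state=random_state)
        self.hidden_width = hidden_width
        self.n_expected_inputs = n_expected_inputs

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        if self.n_expected_inputs is not None and X.shape[1] != self.n_expected_inputs:
            raise ValueError(
                f"fusion expects {self.n_expected_inputs} probabilities, got {X.shape[1]}"
            )
        self.hidden_dims = (self.hidden_width,)
        return super().fit(X, y)


def train_descriptor_classifier(features: np.ndarray, labels, config: StackedSAEConfig | None = None):
    """Train one stage-1 classifier; returns (model, P(malignant) on ``features``)."""
    features = np.asarray(features, dtype=np.float64)
    if config is None:
        config = build_stacked_sae(features.shape[1])
    model = StackedAutoencoderClassifier(
        hidden_dims=config.layer_dims, pretrain_epochs=config.pretrain_epochs,
        finetune_epochs=config.finetune_epochs, learning_rate=config.learning_rate,
        random_state=config.seed,
    ).fit(features, labels)
    return model, model.malignancy_probability(features)


def fuse(probabilities: np.ndarray, labels, seed: int = 0, n_expected_inputs: int | None = 6,
         **kw):
    """Train the fusion network on stage-1 probabilities.

    Returns ``(final_probabilities, model)`` with probabilities for the
    training samples.
    """
    model = FusionClassifier(n_expected_inputs=n_expected_inputs, random_state=seed, **kw)
    model.fit(np.asarray(probabilities, dtype=np.float64), labels)
    return model.malignancy_probability(probabilities), model


@dataclass
class EvalReport:
    """Confusion counts at the decision threshold plus derived metrics."""

    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float      # percent
    sensitivity: float   # percent
    specificity: float   # percent
    precision: float     # percent
    auc: float           # [0, 1]

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision, "auc": self.auc,
        }


def evaluate(probabilities, labels, threshold: float = 0.5) -> EvalReport:
    """AC/SN/SP/PR (percent) at ``threshold`` and trapezoidal ROC AUC.

    ``labels`` may be strings ("malignant" positive) or 0/1 integers.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels)
    y = (labels == POSITIVE_LABEL).astype(int) if labels.dtype.kind in "UO" else labels.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("evaluation requires both classes")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    sn = 100.0 * tp / (tp + fn)
    sp = 100.0 * tn / (tn + fp)
    ac = 100.0 * (tp + tn) / len(y)
    pr = 100.0 * tp / (tp + fp) if tp + fp > 0 else 0.0
    auc = float(roc_auc_score(y, p))
    return EvalReport(tp=tp, fn=fn, tn=tn, fp=fp, accuracy=ac, sensitivity=sn,
                      specificity=sp, precision=pr, auc=auc)


def split_train_test(records: list, train_frac: float = 0.70, seed: int = 0,
                     labels=None):
    """Stratified random split of records (default 70% training)."""
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    y = labels if labels is not None else [getattr(r, "label", None) for r in records]
    idx_train, idx_test = train_test_split(
        np.arange(len(records)), train_size=train_frac, random_state=seed, stratify=y
    )
    return [records[i] for i in idx_train], [records[i] for i in idx_test]
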