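"""Scikit-learn style estimators: the patch classifier used for tumour vs
non-tumour (and, retrained on infiltrate labels, for lymphocytic
infiltrate vs other tissue).

The same `PatchCNNClassifier` serves both roles; only the labels differ.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .cnn import ConvLayerSpec, NetworkSpec, PatchCNN

__all__ = ["PatchCNNClassifier"]


class PatchCNNClassifier(BaseEstimator, ClassifierMixin):
    """Four-layer convolutional classifier for 64x64 RGB tissue patches.

    Trained with plain stochastic gradient descent with momentum on the
    softmax cross-entropy, for a fixed number of epochs (no schedule, no
    early stopping). Inputs are 8-bit RGB patches; they are scaled to
    [0, 1] and mean-normalised per channel with means estimated on the
    training set and stored on the fitted model.

    Parameters
    ----------
    conv_filters : (int, int)
        Filter counts of the two convolution layers.
    kernel_size : int
        Square kernel size of both convolutions (valid, stride 1).
    fc_sizes : (int, int)
        Widths of the two fully connected layers.
    dropout_rate : float
        Dropout after the second FC layer, active only during training.
    learning_rate, momentum, epochs, batch_size :
        SGD hyper-parameters. Defaults: 0.001, 0.9, 15, 25.
    random_state : int
        Seeds weight initialisation, batch shuffling and dropout.

    Attributes
    ----------
    classes_ : ndarray of the (two) class labels, sorted.
    channel_means_ : per-channel means on the [0, 1] scale.
    history_ : DataFrame with per-epoch mean loss and training accuracy.
    n_parameters_ : total trainable parameter count.
    """

    def __init__(
        self,
        conv_filters=(32, 64),
        kernel_size=5,
        fc_sizes=(1024, 512),
        dropout_rate=0.5,
        learning_rate=0.001,
        momentum=0.9,
        epochs=15,
        batch_size=25,
        patch_size=64,
        random_state=0,
    ):
        self.conv_filters = conv_filters
        self.kernel_size = kernel_size
        self.fc_sizes = fc_sizes
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.epochs = epochs
        self.batch_size = batch_size
        self.patch_size = patch_size
        self.random_state = random_state

    # ------------------------------------------------------------------ #

    def _make_spec(self, n_classes: int) -> NetworkSpec:
        return NetworkSpec(
            input_size=self.patch_size,
            in_channels=3,
            conv1=ConvLayerSpec(self.conv_filters[0], self.kernel_size),
            conv2=ConvLayerSpec(self.conv_filters[1], self.kernel_size),
            fc_sizes=tuple(self.fc_sizes),
            n_classes=n_classes,
            dropout_rate=self.dropout_rate,
        )

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 3:
            X = X[None]
        s = self.patch_size
        if X.ndim != 4 or X.shape[1:] != (s, s, 3):
            raise ValueError(
                f"expected patches of shape (n, {s}, {s}, 3), got {X.shape}"
            )
        return X

    def _normalise(self, X: np.ndarray) -> np.ndarray:
        Xf = X.astype(np.float32) / 255.0
        return Xf - self.channel_means_.astype(np.float32)

    def fit(self, X, y):
        """Train on patches X (n, S, S, 3) with labels y."""
        X = self._check_X(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        if len(X) == 0:
            raise ValueError("empty training set")
        if int(self.epochs) < 1:
            raise ValueError("epochs must be >= 1")
        if int(self.batch_size) < 1:
            raise ValueError("batch_size must be >= 1")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training set must contain at least 2 classes")

        ss = np.random.SeedSequence(self.random_state)
        init_seed, shuffle_seed, drop_seed = [
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
        ]
        self.channel_means_ = X.mean(axis=(0, 1, 2), dtype=np.float64) / 255.0
        Xn = self._normalise(X)
        spec = self._make_spec(len(self.classes_))
        self.n_parameters_ = spec.n_parameters()
        net = PatchCNN(spec, seed=init_seed)
        shuffle_rng = np.random.default_rng(shuffle_seed)
        drop_rng = np.random.default_rng(drop_seed)

        n = len(Xn)
        bs = int(self.batch_size)
        log = []
        for epoch in range(int(self.epochs)):
            order = shuffle_rng.permutation(n)
            losses, correct = [], 0
            for k in range(0, n, bs):
                idx = order[k : k + bs]
                xb = np.ascontiguousarray(Xn[idx])
                yb = y_idx[idx]
                loss = net.train_step(
                    xb, yb, float(self.learning_rate), float(self.momentum), drop_rng
                )
                losses.append(loss)
                correct += int((net._probs.argmax(1) == yb).sum())
            log.append(
                {
                    "epoch": epoch + 1,
                    "loss": float(np.mean(losses)),
                    "accuracy": correct / n,
                }
            )
        self.history_ = pd.DataFrame(log)
        net.release_training_state()
        self.network_ = net
        return self

    # ------------------------------------------------------------------ #

    def predict_proba(self, X, batch_size: int = 25) -> np.ndarray:
        """Class probabilities; deterministic (dropout disabled)."""
        check_is_fitted(self, "network_")
        X = self._check_X(X)
        Xn = self._normalise(X)
        out = np.empty((len(Xn), len(self.classes_)))
        for k in range(0, len(Xn), batch_size):
            xb = np.ascontiguousarray(Xn[k : k + batch_size])
            out[k : k + len(xb)] = self.network_.forward(xb, training=False)
        return out

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    # ------------------------------------------------------------------ #

    def save(self, path) -> None:
        """Serialise spec, normalisation means and weights to one .npz."""
        check_is_fitted(self, "network_")
        state = self.network_.state_dict()
        np.savez(
            path,
            classes=self.classes_,
            channel_means=self.channel_means_,
            params=np.array(
                [
                    self.learning_rate,
                    self.momentum,
                    self.epochs,
                    self.batch_size,
                    self.patch_size,
                ]
            ),
            history=self.history_.to_numpy(),
            **state,
        )

    @classmethod
    def load(cls, path) -> "PatchCNNClassifier":
        d = np.load(path, allow_pickle=False)
        net = PatchCNN.from_state_dict(d)
        spec = net.spec
        est = cls(
            conv_filters=(spec.conv1.num_kernels, spec.conv2.num_kernels),
            kernel_size=spec.conv1.kernel_size,
            fc_sizes=spec.fc_sizes,
            dropout_rate=spec.dropout_rate,
            learning_rate=float(d["params"][0]),
            momentum=float(d["params"][1]),
            epochs=int(d["params"][2]),
            batch_size=int(d["params"][3]),
            patch_size=int(d["params"][4]),
        )
        est.classes_ = d["classes"]
        est.channel_means_ = d["channel_means"]
        est.history_ = pd.DataFrame(
            d["history"], columns=["epoch", "loss", "accuracy"]
        )
        est.n_parameters_ = spec.n_parameters()
        est.network_ = net
        return est
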