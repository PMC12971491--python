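"""Minimal multilayer perceptron with multitask readouts, in numpy.

Two uses in this package:

* an *untrained* random feature map (linear + nonlinearity stacks) that turns
  Gaussian latents into non-Gaussian "neural" responses — the hidden-manifold
  construction;
* a *trained* three-hidden-layer network (linear–batchnorm–nonlinearity
  blocks with one linear readout per task from the shared penultimate layer)
  optimized by Adam on the multitask binary labels.

Batch-normalization statistics are frozen (running estimates) whenever
representations are extracted, so every representation is a deterministic
function of its input.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["MultitaskMLP", "TrainingDiverged"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def _act(a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(a, 0.0)
    if kind == "tanh":
        return np.tanh(a)
    raise ValueError(f"unknown nonlinearity {kind!r}")


def _act_grad(a: np.ndarray, out: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (a > 0.0).astype(a.dtype)
    return 1.0 - out * out  # tanh


class MultitaskMLP:
    """Feed-forward net: hidden blocks + per-task linear readouts.

    Parameters
    ----------
    d_in : input (latent) dimension
    hidden : widths of the hidden layers
    n_tasks : number of binary readout heads (0 for a pure feature map)
    nonlinearity : "relu" or "tanh"
    batchnorm : insert a batch-norm stage between each linear map and its
        nonlinearity (used for the trained network, not the random one)
    rng : numpy Generator used for the 1/sqrt(fan-in) Gaussian initialization
    """

    def __init__(
        self,
        d_in: int,
        hidden: list[int],
        n_tasks: int,
        rng: np.random.Generator,
        nonlinearity: str = "relu",
        batchnorm: bool = False,
    ):
        if nonlinearity not in ("relu", "tanh"):
            raise ValueError(f"unknown nonlinearity {nonlinearity!r}")
        self.nonlinearity = nonlinearity
        self.batchnorm = batchnorm
        self.hidden = list(hidden)
        self.n_tasks = int(n_tasks)
        self.W, self.b = [], []
        self.gamma, self.beta = [], []
        self.run_mean, self.run_var = [], []
        fan_in = d_in
        for width in hidden:
            self.W.append(rng.standard_normal((fan_in, width)) / np.sqrt(fan_in))
            self.b.append(np.zeros(width))
            self.gamma.append(np.ones(width))
            self.beta.append(np.zeros(width))
            self.run_mean.append(np.zeros(width))
            self.run_var.append(np.ones(width))
            fan_in = width
        if n_tasks > 0:
            self.W_out = rng.standard_normal((fan_in, n_tasks)) / np.sqrt(fan_in)
            self.b_out = np.zeros(n_tasks)
        else:
            self.W_out = None
            self.b_out = None

    # --------------------------------------------------------------- forward
    def _forward(self, Z: np.ndarray, training: bool):
        """Run the hidden blocks; returns (activations h, cache, stages)."""
        h = np.asarray(Z, dtype=float)
        cache = []
        stages = [("input", h)]
        for i in range(len(self.hidden)):
            a = h @ self.W[i] + self.b[i]
            layer = {"h_in": h, "a": a}
            if self.batchnorm:
                if training:
                    mu = a.mean(axis=0)
                    var = a.var(axis=0)
                    self.run_mean[i] = (1 - _BN_MOMENTUM) * self.run_mean[i] \
                        + _BN_MOMENTUM * mu
                    self.run_var[i] = (1 - _BN_MOMENTUM) * self.run_var[i] \
                        + _BN_MOMENTUM * var
                else:
                    mu, var = self.run_mean[i], self.run_var[i]
                a_hat = (a - mu) / np.sqrt(var + _BN_EPS)
                a_bn = self.gamma[i] * a_hat + self.beta[i]
                layer.update(a_hat=a_hat, var=var, a_bn=a_bn)
                pre = a_bn
            else:
                pre = a
            stages.append((f"linear{i + 1}", pre))
            h = _act(pre, self.nonlinearity)
            layer["h_out"] = h
            cache.append(layer)
            stages.append((f"{self.nonlinearity}{i + 1}", h))
        return h, cache, stages

    def representations(self, Z: np.ndarray) -> list[tuple[str, np.ndarray]]:
        """Per-stage representations (input, each linear stage, each
        nonlinearity stage), with batch-norm in frozen/eval mode."""
        _, _, stages = self._forward(Z, training=False)
        return stages

    def logits(self, Z: np.ndarray, training: bool = False) -> np.ndarray:
        if self.W_out is None:
            raise RuntimeError("network has no readout heads")
        h, _, _ = self._forward(Z, training=training)
        return h @ self.W_out + self.b_out

    def predict_labels(self, Z: np.ndarray) -> np.ndarray:
        """Per-task label predictions in {-1, +1}."""
        return np.where(self.logits(Z) >= 0.0, 1.0, -1.0)

    # -------------------------------------------------------------- training
    def _params(self):
        ps = self.W + self.b
        if self.batchnorm:
            ps += self.gamma + self.beta
        ps += [self.W_out, self.b_out]
        return ps

    def train_epochs(
        self,
        Z: np.ndarray,
        Y: np.ndarray,
        rng: np.random.Generator,
        epochs: int = 1,
        batch_size: int = 128,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> np.ndarray:
        """Adam on the multitask logistic loss for labels Y in {-1, +1}.

        Returns the per-minibatch loss trace. Raises
        :class:`TrainingDiverged` if the loss becomes non-finite.
        """
        if self.W_out is None:
            raise RuntimeError("cannot train a network without readout heads")
        Z = np.asarray(Z, dtype=float)
        Y = np.asarray(Y, dtype=float)
        n = Z.shape[0]
        m_state = [np.zeros_like(p) for p in self._params()]
        v_state = [np.zeros_like(p) for p in self._params()]
        step = 0
        losses = []
        b1, b2 = betas
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                zb, yb = Z[idx], Y[idx]
                loss, grads = self._loss_and_grads(zb, yb)
                if not np.isfinite(loss):
                    raise TrainingDiverged(f"loss became {loss} at step {step}")
                losses.append(loss)
                step += 1
                params = self._params()
                for j, (p, g) in enumerate(zip(params, grads)):
                    m_state[j] = b1 * m_state[j] + (1 - b1) * g
                    v_state[j] = b2 * v_state[j] + (1 - b2) * g * g
                    m_hat = m_state[j] / (1 - b1**step)
                    v_hat = v_state[j] / (1 - b2**step)
                    p -= lr * m_hat / (np.sqrt(v_hat) + eps)
        return np.asarray(losses)

    def _loss_and_grads(self, Z: np.ndarray, Y: np.ndarray):
        h, cache, _ = self._forward(Z, training=True)
        logits = h @ self.W_out + self.b_out
        # logistic loss on +-1 labels: mean log(1 + exp(-y * logit))
        margin = Y * logits
        loss = float(np.mean(np.logaddexp(0.0, -margin)))
        # d loss / d logit = -y * sigmoid(-y * logit), averaged over entries
        dlogits = -Y * expit(-margin) / margin.size
        dW_out = cache[-1]["h_out"].T @ dlogits if cache else Z.T @ dlogits
        db_out = dlogits.sum(axis=0)
        dh = dlogits @ self.W_out.T
        dW, db = [None] * len(self.W), [None] * len(self.W)
        dgamma, dbeta = [None] * len(self.W), [None] * len(self.W)
        for i in reversed(range(len(self.W))):
            layer = cache[i]
            pre = layer["a_bn"] if self.batchnorm else layer["a"]
            da_pre = dh * _act_grad(pre, layer["h_out"], self.nonlinearity)
            if self.batchnorm:
                a_hat, var = layer["a_hat"], layer["var"]
                dgamma[i] = np.sum(da_pre * a_hat, axis=0)
                dbeta[i] = np.sum(da_pre, axis=0)
                # backprop through batch statistics
                inv_std = 1.0 / np.sqrt(var + _BN_EPS)
                da_hat = da_pre * self.gamma[i]
                mb = a_hat.shape[0]
                da = inv_std / mb * (
                    mb * da_hat
                    - da_hat.sum(axis=0)
                    - a_hat * np.sum(da_hat * a_hat, axis=0)
                )
            else:
                da = da_pre
            dW[i] = layer["h_in"].T @ da
            db[i] = da.sum(axis=0)
            dh = da @ self.W[i].T
        grads = dW + db
        if self.batchnorm:
            grads += dgamma + dbeta
        grads += [dW_out, db_out]
        return loss, grads
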