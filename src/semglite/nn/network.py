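"""Sequential container and the softmax cross-entropy head."""

from __future__ import annotations

import numpy as np

from .layers import Layer, Param, flush_denormals

F32 = np.float32


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits.

    ``y`` holds 0-based integer class indices.
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(n), y] + eps))
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), (dlogits / n).astype(F32)


class Network:
    """An ordered stack of layers trained with mini-batch backprop."""

    def __init__(self, layers: list[Layer], seed: int = 0) -> None:
        self.layers = layers
        self.rng = np.random.default_rng(seed)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def n_params(self) -> int:
        """The engine's own trainable-parameter count."""
        return sum(p.size for p in self.params())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.ascontiguousarray(x, dtype=F32)
        for layer in self.layers:
            out = layer.forward(out, train, self.rng)
        return out

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
            if dout.nbytes < (1 << 27):
                flush_denormals(dout)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def train_step(self, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """One forward/backward pass; returns (loss, batch accuracy)."""
        logits = self.forward(x, train=True)
        loss, dlogits = softmax_cross_entropy(logits, y)
        self.zero_grad()
        self.backward(dlogits)
        acc = float(np.mean(np.argmax(logits, axis=1) == y))
        return loss, acc

    def evaluate(self, x: np.ndarray, y: np.ndarray, batch: int = 256) -> tuple[float, float]:
        """Loss and accuracy without dropout, batched to bound memory."""
        losses, correct, n = [], 0, len(y)
        for lo in range(0, n, batch):
            logits = self.forward(x[lo : lo + batch], train=False)
            loss, _ = softmax_cross_entropy(logits, y[lo : lo + batch])
            losses.append(loss * len(y[lo : lo + batch]))
            correct += int(np.sum(np.argmax(logits, axis=1) == y[lo : lo + batch]))
        return float(np.sum(losses) / n), correct / n

    def predict(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        """0-based predicted class indices."""
        out = []
        for lo in range(0, len(x), batch):
            logits = self.forward(x[lo : lo + batch], train=False)
            out.append(np.argmax(logits, axis=1))
        return np.concatenate(out) if out else np.empty(0, dtype=int)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for idx, layer in enumerate(self.layers):
            for p in layer.params():
                state[f"{idx}:{p.name}"] = p.value
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for idx, layer in enumerate(self.layers):
            for p in layer.params():
                key = f"{idx}:{p.name}"
                if key not in state:
                    raise KeyError(f"missing parameter {key}")
                if state[key].shape != p.value.shape:
                    raise ValueError(
                        f"shape mismatch for {key}: {state[key].shape} vs {p.value.shape}"
                    )
                p.value[...] = state[key]
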