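"""Layers and optimizer built on the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv2d, embedding


class Module:
    """Base class with recursive parameter discovery by attribute name."""

    def named_parameters(self, prefix: str = ""):
        # Yields frozen tensors too; optimizers filter on requires_grad.
        for name, value in vars(self).items():
            if isinstance(value, Tensor):
                yield prefix + name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{p.data.shape} vs {state[k].shape}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Tensor(_glorot(rng, n_in, n_out, (n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    """'Same'-padded NHWC convolution with optional stride."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, stride: tuple[int, int] = (1, 1)):
        fan_in = kernel * kernel * c_in
        self.w = Tensor(_glorot(rng, fan_in, c_out,
                                (kernel, kernel, c_in, c_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride)


class Embedding(Module):
    def __init__(self, n_vocab: int, dim: int, rng: np.random.Generator):
        self.w = Tensor(rng.normal(scale=0.1, size=(n_vocab, dim)),
                        requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return embedding(self.w, idx)


class LSTMCell(Module):
    """Standard LSTM cell; forget-gate bias initialized to 1."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.w = Tensor(_glorot(rng, n_in + n_hidden, 4 * n_hidden,
                                (n_in + n_hidden, 4 * n_hidden)),
                        requires_grad=True)
        bias = np.zeros(4 * n_hidden)
        bias[n_hidden:2 * n_hidden] = 1.0
        self.b = Tensor(bias, requires_grad=True)

    def init_state(self, batch: int) -> tuple[Tensor, Tensor]:
        z = np.zeros((batch, self.n_hidden))
        return Tensor(z), Tensor(z.copy())

    def __call__(self, x: Tensor, state: tuple[Tensor, Tensor]
                 ) -> tuple[Tensor, Tensor]:
        h_prev, c_prev = state
        gates = concat([x, h_prev], axis=-1) @ self.w + self.b
        nh = self.n_hidden
        i = gates[:, :nh].sigmoid()
        f = gates[:, nh:2 * nh].sigmoid()
        g = gates[:, 2 * nh:3 * nh].tanh()
        o = gates[:, 3 * nh:].sigmoid()
        c = f * c_prev + i * g
        h = o * c.tanh()
        return h, c


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m[:] = b1 * m + (1 - b1) * p.grad
            v[:] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
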