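"""Neural-network layers and the Adam optimizer over the autodiff engine.

Layers follow the conventional Module pattern: parameters are `Tensor`s
with `requires_grad=True`, `parameters()` walks the module tree, and
`train()` / `eval()` toggle batch-norm statistics and dropout.  Weight
initialisation draws from a caller-supplied numpy Generator so model
construction is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv1d, maxpool1d


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
                isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for name, m in self._modules.items():
            out.extend(m.named_parameters(prefix + name + "."))
        return out

    def buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = [(prefix + n, b) for n, b in getattr(self, "_buffers", {}).items()]
        for name, m in self._modules.items():
            out.extend(m.buffers(prefix + name + "."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # checkpointing -------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {f"param:{n}": p.data.copy() for n, p in self.named_parameters()}
        d.update({f"buffer:{n}": b.copy() for n, b in self.buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for n, p in self.named_parameters():
            p.data = d[f"param:{n}"].copy().astype(p.data.dtype)
        for path, mod, key in self._buffer_owners():
            mod._buffers[key] = d[f"buffer:{path}"].copy()

    def _buffer_owners(self, prefix: str = ""):
        out = [(prefix + key, self, key)
               for key in getattr(self, "_buffers", {})]
        for name, m in self._modules.items():
            out.extend(m._buffer_owners(prefix + name + "."))
        return out


def _param(rng: np.random.Generator, shape, fan_in: int,
           dtype=np.float32) -> Tensor:
    scale = np.sqrt(2.0 / max(fan_in, 1))
    return Tensor(rng.normal(0.0, scale, shape).astype(dtype),
                  requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.w = _param(rng, (n_in, n_out), n_in, dtype)
        self.b = Tensor(np.zeros(n_out, dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, dilation: int = 1,
                 padding: str | int = "same", dtype=np.float32):
        super().__init__()
        self.w = _param(rng, (c_out, c_in, kernel), c_in * kernel, dtype)
        self.b = Tensor(np.zeros(c_out, dtype), requires_grad=True)
        self.stride = stride
        self.dilation = dilation
        if padding == "same":
            padding = ((kernel - 1) * dilation) // 2
        self.padding = int(padding)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, stride=self.stride,
                      dilation=self.dilation, padding=self.padding)


class BatchNorm(Module):
    """Batch normalisation for (N, C, L) inputs (axis=(0, 2)) or (N, F)
    inputs (axis=0), with running statistics for eval mode."""

    def __init__(self, n_features: int, axis=(0, 2), momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = Tensor(np.ones(n_features, dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features, dtype), requires_grad=True)
        self.axis = axis if isinstance(axis, tuple) else (axis,)
        self.momentum = momentum
        self.eps = eps
        self._buffers = {"running_mean": np.zeros(n_features, dtype),
                         "running_var": np.ones(n_features, dtype)}

    def _shaped(self, v, ndim):
        # reshape per-channel vectors for broadcasting
        shape = [1] * ndim
        ch_axis = 1 if ndim == 3 else -1
        shape[ch_axis] = -1
        return v.reshape(shape)

    def __call__(self, x: Tensor) -> Tensor:
        ndim = x.data.ndim
        axis = self.axis if ndim == 3 else (0,)
        if self.training:
            mu = x.mean(axis=axis, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axis, keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"]
                + m * mu.data.reshape(-1))
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"]
                + m * var.data.reshape(-1))
            inv = (var + self.eps).pow(-0.5)
            xn = xc * inv
        else:
            rm = self._shaped(self._buffers["running_mean"], ndim)
            rv = self._shaped(self._buffers["running_var"], ndim)
            xn = (x - Tensor(rm)) * Tensor(1.0 / np.sqrt(rv + self.eps))
        g = self._shaped(self.gamma.data, ndim)
        gamma = self.gamma.reshape(g.shape)
        beta = self.beta.reshape(g.shape)
        return xn * gamma + beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.data.shape) < keep) / keep
        return x * Tensor(mask.astype(x.data.dtype))


class LSTM(Module):
    """A single LSTM layer processing (N, T, F) input, returning the per-step
    hidden states as a list plus the final hidden state."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.n_hidden = n_hidden
        self.w_ih = _param(rng, (n_in, 4 * n_hidden), n_in, dtype)
        self.w_hh = _param(rng, (n_hidden, 4 * n_hidden), n_hidden, dtype)
        b = np.zeros(4 * n_hidden, dtype)
        b[n_hidden:2 * n_hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, xs: list[Tensor]) -> tuple[list[Tensor], Tensor]:
        n = xs[0].data.shape[0]
        H = self.n_hidden
        dtype = xs[0].data.dtype
        h = Tensor(np.zeros((n, H), dtype))
        c = Tensor(np.zeros((n, H), dtype))
        hs = []
        for x_t in xs:
            gates = x_t @ self.w_ih + h @ self.w_hh + self.b
            i = gates[:, :H].sigmoid()
            f = gates[:, H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            hs.append(h)
        return hs, h


class BiLSTM(Module):
    """Bidirectional LSTM; concatenates forward and backward hidden states."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.fwd = LSTM(n_in, n_hidden, rng, dtype)
        self.bwd = LSTM(n_in, n_hidden, rng, dtype)

    def __call__(self, xs: list[Tensor]) -> tuple[list[Tensor], Tensor]:
        hs_f, last_f = self.fwd(xs)
        hs_b, last_b = self.bwd(xs[::-1])
        hs_b = hs_b[::-1]
        steps = [concat([f, b], axis=1) for f, b in zip(hs_f, hs_b)]
        return steps, concat([last_f, last_b], axis=1)


class Adam:
    """Adam optimizer (Kingma & Ba defaults for the moment decay rates)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
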