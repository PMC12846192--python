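"""Network building blocks: linear layers, batch normalisation, Adam.

Layers operate on :class:`magwire.autodiff.Tensor` values and support
arbitrary leading batch dimensions (the feature axis is always last).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, leaky_relu

__all__ = ["Parameter", "Linear", "BatchNorm", "MLP", "Adam", "leaky_relu"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def parameters(self) -> list[Parameter]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def set_training(self, flag: bool) -> None:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.set_training(flag)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(flag)
        if hasattr(self, "training"):
            self.training = flag

    # -- flat serialisation (order matches parameters()) ----------------------

    def state_arrays(self) -> list[np.ndarray]:
        arrs = [p.data.copy() for p in self.parameters()]
        arrs.extend(a.copy() for a in self._buffers())
        return arrs

    def load_state_arrays(self, arrs: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, a in zip(params, arrs):
            p.data = np.array(a, dtype=np.float64)
        bufs = self._buffers()
        for b, a in zip(bufs, arrs[len(params):]):
            b[...] = a

    def _buffers(self) -> list[np.ndarray]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v._buffers())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item._buffers())
        out.extend(getattr(self, "_local_buffers", lambda: [])())
        return out


class Linear(Module):
    """Affine map on the last axis: ``y = x @ W + b``."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        bound = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, bound, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm(Module):
    """Batch normalisation over all leading axes (features on the last axis).

    Training mode uses batch statistics and updates running estimates;
    evaluation mode uses the running estimates, so inference is
    deterministic and batch-size independent.
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.training = True

    def _local_buffers(self):
        return [self.running_mean, self.running_var]

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var[...] = (1 - m) * self.running_var + m * var.data.reshape(-1)
            xn = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            xn = (x - self.running_mean) * ((self.running_var + self.eps) ** -0.5)
        return xn * self.gamma + self.beta


class MLP(Module):
    """Stack of linear layers, each optionally followed by batch norm and
    leaky-ReLU; the final layer is linear only (regression head convention).
    """

    def __init__(
        self,
        widths: list[int],
        rng: np.random.Generator,
        batch_norm: bool = False,
        negative_slope: float = 0.01,
        final_activation: bool = False,
    ):
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]
        self.norms = (
            [BatchNorm(w) for w in widths[1:]] if batch_norm else []
        )
        self.negative_slope = negative_slope
        self.final_activation = final_activation

    def __call__(self, x: Tensor) -> Tensor:
        last = len(self.layers) - 1
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < last or self.final_activation:
                if self.norms:
                    x = self.norms[i](x)
                x = leaky_relu(x, self.negative_slope)
        return x


class Adam:
    """Adam optimiser with optional decoupled weight decay."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m, v = self.m[i], self.v[i]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * np.square(g)
            denom = np.sqrt(v / b2t)
            denom += self.eps
            upd = m / denom
            upd *= self.lr / b1t
            p.data -= upd
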