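"""Network building blocks on top of the autograd engine.

Layers hold :class:`~tractdistill.autograd.Tensor` parameters in float32.
Initialization is Glorot-uniform from an explicit ``numpy`` Generator, so
construction is fully determined by a seed.  Freezing a parameter clears
``requires_grad``; the optimizer then never touches it, which keeps frozen
weights bit-identical through training.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Module", "Linear", "MLP", "GRUCell", "Conv3dEncoder", "Adam"]

DTYPE = np.float32


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Module:
    """Base class: named parameter traversal, freezing, state I/O."""

    def named_parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, attr in vars(self).items():
            if isinstance(attr, Tensor):
                out[name] = attr
            elif isinstance(attr, Module):
                for sub, t in attr.named_parameters().items():
                    out[f"{name}.{sub}"] = t
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        for sub, t in item.named_parameters().items():
                            out[f"{name}.{i}.{sub}"] = t
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def trainable_parameters(self) -> list[Tensor]:
        return [p for p in self.parameters() if p.requires_grad]

    def freeze(self) -> None:
        for p in self.parameters():
            p.requires_grad = False

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        if set(state) != set(params):
            raise ValueError("state dict keys do not match module parameters")
        for k, v in state.items():
            if params[k].data.shape != v.shape:
                raise ValueError(f"shape mismatch for {k}")
            params[k].data = np.asarray(v, dtype=params[k].data.dtype).copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Tensor(_glorot(rng, n_in, n_out, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MLP(Module):
    """Fully connected stack with tanh on hidden layers, linear output."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        if len(sizes) < 2:
            raise ValueError("MLP needs at least input and output sizes")
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self.sizes = list(sizes)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).tanh()
        return self.layers[-1](x)


class GRUCell(Module):
    """Gated recurrent unit, one step.

    ``h' = (1 - z) * n + z * h`` with update gate z, reset gate r and
    candidate ``n = tanh(x W_n + b_n + r * (h U_n))``.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_in, self.n_hidden = n_in, n_hidden
        self.w_z = Tensor(_glorot(rng, n_in, n_hidden, (n_in, n_hidden)), requires_grad=True)
        self.w_r = Tensor(_glorot(rng, n_in, n_hidden, (n_in, n_hidden)), requires_grad=True)
        self.w_n = Tensor(_glorot(rng, n_in, n_hidden, (n_in, n_hidden)), requires_grad=True)
        self.u_z = Tensor(_glorot(rng, n_hidden, n_hidden, (n_hidden, n_hidden)), requires_grad=True)
        self.u_r = Tensor(_glorot(rng, n_hidden, n_hidden, (n_hidden, n_hidden)), requires_grad=True)
        self.u_n = Tensor(_glorot(rng, n_hidden, n_hidden, (n_hidden, n_hidden)), requires_grad=True)
        self.b_z = Tensor(np.zeros(n_hidden, dtype=DTYPE), requires_grad=True)
        self.b_r = Tensor(np.zeros(n_hidden, dtype=DTYPE), requires_grad=True)
        self.b_n = Tensor(np.zeros(n_hidden, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        z = (x @ self.w_z + h @ self.u_z + self.b_z).sigmoid()
        r = (x @ self.w_r + h @ self.u_r + self.b_r).sigmoid()
        n = (x @ self.w_n + r * (h @ self.u_n) + self.b_n).tanh()
        return (1.0 - z) * n + z * h

    def zero_state(self, batch: int) -> Tensor:
        return Tensor(np.zeros((batch, self.n_hidden), dtype=DTYPE))


class Conv3dEncoder(Module):
    """Stack of 3x3x3 same-padded convolutions with tanh activations.

    Operates on a channels-last volume of fixed grid shape; convolution is
    an im2col row-gather (through a zero sentinel row for padding) followed
    by a dense matmul, so gradients flow through the autograd tape.  The
    per-shape patch-index table is cached.
    """

    def __init__(self, in_channels: int, channels: tuple[int, ...], rng: np.random.Generator):
        self.in_channels = int(in_channels)
        self.channels = tuple(int(c) for c in channels)
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        prev = in_channels
        for c in self.channels:
            fan_in = 27 * prev
            self.weights.append(
                Tensor(_glorot(rng, fan_in, c, (fan_in, c)), requires_grad=True)
            )
            self.biases.append(Tensor(np.zeros(c, dtype=DTYPE), requires_grad=True))
            prev = c
        self._idx_cache: dict[tuple[int, int, int], np.ndarray] = {}

    def named_parameters(self) -> dict[str, Tensor]:
        out = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"conv{i}.weight"] = w
            out[f"conv{i}.bias"] = b
        return out

    def _patch_indices(self, shape: tuple[int, int, int]) -> np.ndarray:
        """(n_voxels, 27) flat row indices into the voxel table; out-of-bounds
        neighbors point at the sentinel row ``n_voxels``."""
        if shape in self._idx_cache:
            return self._idx_cache[shape]
        nx, ny, nz = shape
        n = nx * ny * nz
        grid = np.stack(
            np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        offs = np.stack(
            np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        nb = grid[:, None, :] + offs[None, :, :]  # (n, 27, 3)
        oob = np.any((nb < 0) | (nb >= np.array(shape)), axis=-1)
        flat = (nb[:, :, 0] * ny + nb[:, :, 1]) * nz + nb[:, :, 2]
        flat[oob] = n
        self._idx_cache[shape] = flat
        return flat

    def __call__(self, volume: np.ndarray) -> Tensor:
        """Encode a (nx, ny, nz, in_channels) numpy volume.

        Returns the feature table as a (n_voxels, channels[-1]) tensor;
        callers sample it at points via ``weighted_gather``.
        """
        if volume.ndim != 4 or volume.shape[3] != self.in_channels:
            raise ValueError(
                f"expected channels-last volume with {self.in_channels} channels"
            )
        shape = volume.shape[:3]
        idx = self._patch_indices(shape)
        n = idx.shape[0]
        x = Tensor(volume.reshape(n, self.in_channels).astype(DTYPE))
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            c_in = x.data.shape[1]
            padded = Tensor._make(
                np.concatenate([x.data, np.zeros((1, c_in), dtype=DTYPE)], axis=0),
                (x,),
                (lambda g, xx=x: xx._accumulate(g[:-1])),
            )
            patches = padded.gather_rows(idx).reshape(n, 27 * c_in)
            x = (patches @ w + b).tanh()
        return x


class Adam:
    """Adam optimizer over a list of trainable tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params_list = [p for p in params if p.requires_grad]
        self.lr, self.betas, self.eps = lr, betas, eps
        self._m = [np.zeros_like(p.data) for p in self.params_list]
        self._v = [np.zeros_like(p.data) for p in self.params_list]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params_list:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self._t
        bc2 = 1.0 - b2**self._t
        for p, m, v in zip(self.params_list, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
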