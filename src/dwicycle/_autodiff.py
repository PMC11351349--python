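"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tensor engine sufficient for the networks in this
package: broadcasting elementwise arithmetic, (batched) matmul, 2D
convolution and transposed convolution via im2col/col2im, reductions,
shape ops, the activations used by the generator and discriminator, and
an Adam optimizer.  Everything is computed in float64 on the CPU so that
losses are reproducible bit-for-bit across runs and directly comparable
with independently coded reference formulas.

Gradients flow only into tensors whose ``requires_grad`` flag is set
(directly or through a parent), which is what lets the training engine
freeze the discriminators during a generator update and vice versa.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "Module",
    "Linear",
    "Conv2d",
    "ConvTranspose2d",
    "InstanceNorm2d",
    "LayerNorm",
    "Adam",
    "set_requires_grad",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size 1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        live = tuple(p for p in parents if p.requires_grad)
        if live:
            out.requires_grad = True
            out._parents = live
            out._backward = backward
        return out

    # -- basic properties ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs here can be thousands of nodes
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free non-leaf grads/graph? kept: training loop zeroes explicitly.

    def _accum(self, grad: np.ndarray):
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** (-1.0)
        return self * (1.0 / other)

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** (-1.0)

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._from_op(out_data, (self,), backward)

    def abs(self):
        out_data = np.abs(self.data)
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * sign)

        return Tensor._from_op(out_data, (self,), backward)

    # -- transcendental / activations -----------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._from_op(out_data, (self,), backward)

    def sqrt(self):
        return self**0.5

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._from_op(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._from_op(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out_data = np.where(mask, self.data, slope * self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * np.where(mask, 1.0, slope))

        return Tensor._from_op(out_data, (self,), backward)

    def softplus(self):
        # numerically stable log(1 + exp(x))
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * sig)

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along a single axis; gradient routed to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis)

        def backward(g):
            if not self.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            grad = np.zeros_like(self.data)
            np.put_along_axis(grad, np.expand_dims(idx, axis), gg, axis)
            self._accum(grad)

        return Tensor._from_op(out_data, (self,), backward)

    # -- shape ops ---------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._from_op(out_data, (self,), backward)

    def transpose(self, axes):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        out_data = np.matmul(a, b)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
                self._accum(ga)
            if other.requires_grad:
                if b.ndim == 2 and a.ndim > 2:
                    gb = np.matmul(
                        a.reshape(-1, a.shape[-1]).T, g.reshape(-1, g.shape[-1])
                    )
                else:
                    gb = np.matmul(np.swapaxes(a, -1, -2), g)
                other._accum(gb)

        return Tensor._from_op(out_data, (self, other), backward)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._from_op(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# convolution primitives (NCHW layout)
# ---------------------------------------------------------------------------


def _out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*kh*kw, OH*OW)."""
    n, c, h, w = x.shape
    oh, ow = _out_size(h, kh, stride, pad), _out_size(w, kw, stride, pad)
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]  # (N,C,OH,OW,kh,kw)
    cols = view.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, oh * ow)
    return np.ascontiguousarray(cols)


def _col2im(
    cols: np.ndarray, xshape: tuple, kh: int, kw: int, stride: int, pad: int
) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = xshape
    oh, ow = _out_size(h, kh, stride, pad), _out_size(w, kw, stride, pad)
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    out = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += (
                cols[:, :, i, j]
            )
    if pad:
        out = out[:, :, pad : pad + h, pad : pad + w]
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """2D convolution (cross-correlation). x (N,Cin,H,W), w (Cout,Cin,kh,kw)."""
    n, cin, h, wd = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input has {cin}, weight expects {cin_w}")
    oh, ow = _out_size(h, kh, stride, padding), _out_size(wd, kw, stride, padding)
    cols = _im2col(x.data, kh, kw, stride, padding)  # (N,K,L)
    w2 = w.data.reshape(cout, -1)  # (Cout,K)
    out_data = np.matmul(w2, cols).reshape(n, cout, oh, ow)
    del cols  # recomputed in backward; keeping it alive would dominate memory
    if b is not None:
        out_data = out_data + b.data.reshape(1, cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gflat = g.reshape(n, cout, -1)  # (N,Cout,L)
        if w.requires_grad:
            cols_b = _im2col(x.data, kh, kw, stride, padding)
            gw = np.einsum("nol,nkl->ok", gflat, cols_b).reshape(w.data.shape)
            del cols_b
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(w2.T, gflat)  # (N,K,L)
            x._accum(_col2im(dcols, x.data.shape, kh, kw, stride, padding))

    return Tensor._from_op(out_data, parents, backward)


def conv_transpose2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    output_padding: int = 0,
) -> Tensor:
    """Transposed 2D convolution. x (N,Cin,H,W), w (Cin,Cout,kh,kw)."""
    n, cin, h, wd = x.data.shape
    cin_w, cout, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv_transpose2d channel mismatch: input has {cin}, weight expects {cin_w}")
    oh = (h - 1) * stride - 2 * padding + kh + output_padding
    ow = (wd - 1) * stride - 2 * padding + kw + output_padding
    # forward = adjoint of conv2d with this geometry
    w2 = w.data.reshape(cin, cout * kh * kw)
    xflat = x.data.reshape(n, cin, -1)  # (N,Cin,L) with L=H*W
    gcols = np.matmul(w2.T, xflat)  # (N, Cout*kh*kw, L)
    out_data = _col2im(gcols, (n, cout, oh, ow), kh, kw, stride, padding)
    if b is not None:
        out_data = out_data + b.data.reshape(1, cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        cols_g = _im2col(g, kh, kw, stride, padding)  # (N, Cout*kh*kw, L)
        if x.requires_grad:
            dx = np.matmul(w2, cols_g).reshape(x.data.shape)
            x._accum(dx)
        if w.requires_grad:
            gw = np.einsum("ncl,nkl->ck", xflat, cols_g).reshape(w.data.shape)
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    return Tensor._from_op(out_data, parents, backward)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Module:
    """Container with recursive parameter discovery (attribute scan)."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out.append((full, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(full + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def set_requires_grad(module: Module, flag: bool):
    for p in module.parameters():
        p.requires_grad = flag


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, bias: bool = True):
        scale = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-scale, scale, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng: np.random.Generator, stride=1, padding=0, bias=True, init_std=0.02):
        self.weight = Parameter(rng.normal(0.0, init_std, size=(cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    def __init__(self, cin, cout, k, rng: np.random.Generator, stride=1, padding=0, output_padding=0, bias=True, init_std=0.02):
        self.weight = Parameter(rng.normal(0.0, init_std, size=(cin, cout, k, k)))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.stride, self.padding, self.output_padding = stride, padding, output_padding

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(
            x, self.weight, self.bias,
            stride=self.stride, padding=self.padding, output_padding=self.output_padding,
        )


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, channels: int, affine: bool = True, eps: float = 1e-5):
        self.eps = eps
        self.weight = Parameter(np.ones(channels)) if affine else None
        self.bias = Parameter(np.zeros(channels)) if affine else None

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        out = xc * (var + self.eps) ** -0.5
        if self.weight is not None:
            c = x.shape[1]
            out = out * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)
        return out


class LayerNorm(Module):
    """Normalization over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.weight + self.bias


def softmax_last(x: Tensor) -> Tensor:
    # subtracting the detached rowwise max leaves value and gradient unchanged
    shift = Tensor(np.max(x.data, axis=-1, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        self.m = [np.asarray(m, dtype=np.float64) for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float64) for v in state["v"]]
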