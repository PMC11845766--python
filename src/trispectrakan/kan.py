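"""Kolmogorov-Arnold network layers with B-spline edge activations.

A KAN layer replaces the scalar weights of a dense layer with learnable
univariate functions phi_{i,j} living on the edges.  Each edge function is
parametrized as

    phi_{i,j}(x) = w_base[i,j] * silu(x) + w_s[i,j] * sum_m c[i,j,m] B_m(x)

where the B_m are the G + k degree-k B-splines supported on a uniform grid
of G intervals over ``grid_range``, extended by k knots on each side.  A
network is the composition of such layers (widths ``[n_1, ..., n_{L+1}]``);
the classical superposition theorem corresponds to the shape [n, 2n+1, 1].

Everything is differentiable; the backward pass is analytic (the derivative
of a degree-k spline is a combination of degree-(k-1) splines).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._nn import Layer, Param, Sequential, silu, silu_grad, softmax

__all__ = [
    "SplineSpec",
    "extend_grid",
    "bspline_basis",
    "bspline_basis_and_deriv",
    "KANLayer",
    "KANNetwork",
    "kan_param_count",
]


@dataclass(frozen=True)
class SplineSpec:
    """Geometry of the per-edge spline family.

    order_k
        Polynomial degree of the B-splines (>= 1).  Degree 3 (cubic) is
        the default.
    grid_size
        Number G of uniform intervals spanning ``grid_range``; the basis
        then has G + order_k members.
    grid_range
        Closed interval [a, b] the grid covers.  Inputs outside it are
        evaluated through the extended knots rather than clamped.
    """

    order_k: int = 3
    grid_size: int = 5
    grid_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if self.order_k < 1:
            raise ValueError("spline order must be >= 1")
        if self.grid_size < 1:
            raise ValueError("grid size must be >= 1")
        a, b = self.grid_range
        if not (np.isfinite(a) and np.isfinite(b) and a < b):
            raise ValueError("grid_range must be a finite interval a < b")

    @property
    def n_basis(self) -> int:
        return self.grid_size + self.order_k


def extend_grid(spec: SplineSpec) -> np.ndarray:
    """Uniform knots over [a, b] with k extra knots each side.

    Returns G + 2k + 1 strictly increasing knots with spacing (b - a) / G.
    """
    a, b = spec.grid_range
    g, k = spec.grid_size, spec.order_k
    h = (b - a) / g
    return a + h * np.arange(-k, g + k + 1)


def _basis_all_degrees(x: np.ndarray, knots: np.ndarray, k: int) -> list[np.ndarray]:
    """Cox-de Boor recursion; returns basis arrays for degrees 0..k.

    Degree-d entry has trailing dimension ``len(knots) - d - 1``.
    """
    xs = x[..., None]
    out = [((xs >= knots[:-1]) & (xs < knots[1:])).astype(x.dtype)]
    for d in range(1, k + 1):
        b = out[-1]
        left = (xs - knots[:-(d + 1)]) / (knots[d:-1] - knots[:-(d + 1)]) * b[..., :-1]
        right = (knots[d + 1:] - xs) / (knots[d + 1:] - knots[1:-d]) * b[..., 1:]
        out.append(left + right)
    return out


def bspline_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the G+k degree-k basis functions at x (any array shape).

    Inside [a, b] the values form a partition of unity; far outside the
    extended support all values are zero.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("spline basis requires finite inputs")
    return _basis_all_degrees(x, extend_grid(spec), spec.order_k)[-1]


def bspline_basis_and_deriv(x, spec: SplineSpec):
    """Basis values and their first derivatives, shape (..., G+k) each."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("spline basis requires finite inputs")
    knots = extend_grid(spec)
    k = spec.order_k
    all_deg = _basis_all_degrees(x, knots, k)
    b = all_deg[-1]
    if k == 0:
        return b, np.zeros_like(b)
    bm1 = all_deg[-2]  # degree k-1, one extra member
    denom_l = knots[k:-1] - knots[:-(k + 1)]
    denom_r = knots[k + 1:] - knots[1:-k]
    db = k * (bm1[..., :-1] / denom_l - bm1[..., 1:] / denom_r)
    return b, db


def kan_param_count(n_in: int, n_out: int, spec: SplineSpec) -> int:
    """Learnable scalars of one KAN layer.

    Per edge: G + k spline coefficients, one base weight, one spline
    scaler; no bias terms.
    """
    if n_in <= 0 or n_out <= 0:
        raise ValueError("layer widths must be positive")
    return n_in * n_out * (spec.n_basis + 2)


class KANLayer(Layer):
    """One spline-edge layer mapping (N, n_in) -> (N, n_out)."""

    def __init__(self, n_in: int, n_out: int, spec: SplineSpec,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        if n_in <= 0 or n_out <= 0:
            raise ValueError("layer widths must be positive")
        self.n_in, self.n_out, self.spec = n_in, n_out, spec
        m = spec.n_basis
        limit = np.sqrt(6.0 / n_in)
        self.base_weight = Param(
            rng.uniform(-limit, limit, (n_in, n_out)).astype(dtype), "kan.base")
        self.spline_coeff = Param(
            (0.1 * rng.standard_normal((n_in, n_out, m)) / np.sqrt(n_in)).astype(dtype),
            "kan.coeff")
        self.spline_scale = Param(np.ones((n_in, n_out), dtype=dtype), "kan.scale")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.base_weight, self.spline_coeff, self.spline_scale]

    def _combined(self) -> np.ndarray:
        # (n_in * m, n_out) matrix of scaler-weighted coefficients
        c = self.spline_scale.value[:, :, None] * self.spline_coeff.value
        return np.ascontiguousarray(c.transpose(0, 2, 1)).reshape(-1, self.n_out)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.n_in:
            raise ValueError(f"KANLayer expected (N, {self.n_in}), got {x.shape}")
        b, db = bspline_basis_and_deriv(x, self.spec)
        b = b.astype(x.dtype)
        sx = silu(x)
        n = x.shape[0]
        cmat = self._combined()
        bflat = b.reshape(n, -1)
        y = sx @ self.base_weight.value + bflat @ cmat
        self._cache = (x, sx, bflat, db.astype(x.dtype), cmat)
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, sx, bflat, db, cmat = self._cache
        n = x.shape[0]
        m = self.spec.n_basis
        self.base_weight.grad += sx.T @ grad_out
        # dC[i, m, j] accumulated as one GEMM, then split into coeff/scale parts
        dcmat = (bflat.T @ grad_out).reshape(self.n_in, m, self.n_out)
        dc = dcmat.transpose(0, 2, 1)  # (n_in, n_out, m)
        self.spline_coeff.grad += self.spline_scale.value[:, :, None] * dc
        self.spline_scale.grad += np.einsum("ijm,ijm->ij", self.spline_coeff.value, dc)
        # input gradient: base path + spline path
        gx = (grad_out @ self.base_weight.value.T) * silu_grad(x)
        gc = (grad_out @ cmat.T).reshape(n, self.n_in, m)
        gx += np.einsum("nim,nim->ni", gc, db)
        return gx


class KANNetwork(Sequential):
    """Composition of KAN layers along a width chain [n_1, ..., n_{L+1}]."""

    def __init__(self, shape: list[int], spec: SplineSpec,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        if len(shape) < 2 or any(n <= 0 for n in shape):
            raise ValueError("shape must list >= 2 positive widths")
        self.shape = list(shape)
        self.spec = spec
        super().__init__([
            KANLayer(shape[i], shape[i + 1], spec, rng, dtype=dtype)
            for i in range(len(shape) - 1)
        ])

    def param_count(self) -> int:
        return sum(p.size for p in self.params())

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Forward pass followed by softmax over the final outputs."""
        return softmax(self.forward(x, train=False))


def save_kan(net: KANNetwork, path) -> None:
    """Flat binary checkpoint with a JSON header (shape + spline spec)."""
    header = json.dumps({
        "shape": net.shape,
        "order_k": net.spec.order_k,
        "grid_size": net.spec.grid_size,
        "grid_range": list(net.spec.grid_range),
    })
    arrays = {f"p{i}": p.value for i, p in enumerate(net.params())}
    np.savez(path, header=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def load_kan(path) -> KANNetwork:
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        spec = SplineSpec(header["order_k"], header["grid_size"],
                          tuple(header["grid_range"]))
        net = KANNetwork(header["shape"], spec, np.random.default_rng(0))
        for i, p in enumerate(net.params()):
            p.value[...] = data[f"p{i}"]
    return net
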