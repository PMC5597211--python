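"""Lagrange shape functions and Gauss quadrature for hexahedral elements.

The displacement field lives on 27-node (triquadratic) hexahedra and the
pressure field on their 8 corner nodes (trilinear), a Taylor-Hood-type
pairing that mitigates volumetric locking.  Element-local node ordering is
lexicographic over the tensor grid (i fastest along the first parent axis),
with parent coordinates in [-1, 1]^3.
"""

from __future__ import annotations

import numpy as np

# corner positions of the lexicographic 3x3x3 grid (i + 3j + 9k)
HEX27_CORNERS = np.array([0, 2, 6, 8, 18, 20, 24, 26])

# local faces of a hex, as (axis, side) -> the four corner ids (of the 8-node
# corner numbering 0..7 in lexicographic order i + 2j + 4k), ordered so that
# (t1 x t2) points outward.
HEX8_FACES = {
    ("x", 0): (0, 4, 6, 2),
    ("x", 1): (1, 3, 7, 5),
    ("y", 0): (0, 1, 5, 4),
    ("y", 1): (2, 6, 7, 3),
    ("z", 0): (0, 2, 3, 1),
    ("z", 1): (4, 5, 7, 6),
}


def _lagrange_quadratic(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1D quadratic Lagrange basis on nodes (-1, 0, 1): values and derivatives."""
    x = np.asarray(x, dtype=float)
    vals = np.stack([0.5 * x * (x - 1.0), 1.0 - x * x, 0.5 * x * (x + 1.0)], axis=-1)
    ders = np.stack([x - 0.5, -2.0 * x, x + 0.5], axis=-1)
    return vals, ders


def _lagrange_linear(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    vals = np.stack([0.5 * (1.0 - x), 0.5 * (1.0 + x)], axis=-1)
    ders = np.stack([np.full_like(x, -0.5), np.full_like(x, 0.5)], axis=-1)
    return vals, ders


def hex27_shape(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Triquadratic shape functions at parent points (n, 3).

    Returns (N, dN) with N of shape (n, 27) and dN of shape (n, 27, 3).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    lx, dlx = _lagrange_quadratic(pts[:, 0])
    ly, dly = _lagrange_quadratic(pts[:, 1])
    lz, dlz = _lagrange_quadratic(pts[:, 2])
    n = pts.shape[0]
    N = np.empty((n, 27))
    dN = np.empty((n, 27, 3))
    for k in range(3):
        for j in range(3):
            for i in range(3):
                a = i + 3 * j + 9 * k
                N[:, a] = lx[:, i] * ly[:, j] * lz[:, k]
                dN[:, a, 0] = dlx[:, i] * ly[:, j] * lz[:, k]
                dN[:, a, 1] = lx[:, i] * dly[:, j] * lz[:, k]
                dN[:, a, 2] = lx[:, i] * ly[:, j] * dlz[:, k]
    return N, dN


def hex8_shape(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear shape functions at parent points (n, 3): (n, 8) and (n, 8, 3)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    lx, dlx = _lagrange_linear(pts[:, 0])
    ly, dly = _lagrange_linear(pts[:, 1])
    lz, dlz = _lagrange_linear(pts[:, 2])
    n = pts.shape[0]
    N = np.empty((n, 8))
    dN = np.empty((n, 8, 3))
    for k in range(2):
        for j in range(2):
            for i in range(2):
                a = i + 2 * j + 4 * k
                N[:, a] = lx[:, i] * ly[:, j] * lz[:, k]
                dN[:, a, 0] = dlx[:, i] * ly[:, j] * lz[:, k]
                dN[:, a, 1] = lx[:, i] * dly[:, j] * lz[:, k]
                dN[:, a, 2] = lx[:, i] * ly[:, j] * dlz[:, k]
    return N, dN


def gauss_points(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product Gauss-Legendre rule of `order` points per direction."""
    x, w = np.polynomial.legendre.leggauss(order)
    pts = np.array([[xi, yj, zk] for zk in x for yj in x for xi in x])
    wts = np.array([wi * wj * wk for wk in w for wj in w for wi in w])
    return pts, wts
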