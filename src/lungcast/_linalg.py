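"""Batched small-matrix exponential.

The year-by-year solver exponentiates one small (7x7) generator per age cell
per year.  Looping over ``scipy.linalg.expm`` dominates runtime for grids with
~100 ages, so we batch the standard scaling-and-squaring construction with a
truncated Taylor series over the leading axis.  For the generators that arise
here (entries of order 1 or less) a single scaling level is typical and the
result agrees with scipy to machine precision (checked in the test suite).
"""

from __future__ import annotations

import numpy as np

# With the scaled norm held below 0.25, 13 Taylor terms leave a truncation
# error below 0.25**14/14! ~ 7e-20, i.e. under double-precision round-off.
_TAYLOR_DEGREE = 13
_NORM_TARGET = 0.25


def expm_batch(mats: np.ndarray) -> np.ndarray:
    """Exponentiate a stack of square matrices.

    Parameters
    ----------
    mats : ndarray, shape (..., n, n)
        Stack of real square matrices.

    Returns
    -------
    ndarray of the same shape holding ``expm`` of each matrix.
    """
    a = np.asarray(mats, dtype=float)
    if a.ndim < 2 or a.shape[-1] != a.shape[-2]:
        raise ValueError(f"expected a stack of square matrices, got shape {a.shape}")
    n = a.shape[-1]
    # 1-norm (max absolute column sum) per matrix, shared scaling level.
    norm = np.abs(a).sum(axis=-2).max(axis=-1)
    max_norm = float(norm.max(initial=0.0))
    if not np.isfinite(max_norm):
        raise ValueError("non-finite entries in matrix stack")
    s = 0
    if max_norm > _NORM_TARGET:
        s = int(np.ceil(np.log2(max_norm / _NORM_TARGET)))
    b = a / (2.0**s)
    eye = np.broadcast_to(np.eye(n), a.shape)
    # Horner evaluation of sum_{k<=d} B^k / k!.
    out = eye + b / _TAYLOR_DEGREE
    for k in range(_TAYLOR_DEGREE - 1, 0, -1):
        out = eye + (b @ out) / k
    for _ in range(s):
        out = out @ out
    return out
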