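"""Shared low-level helpers: errors, seed derivation, fast Pearson correlation."""

from __future__ import annotations

import hashlib

import numpy as np

#: Targets the pipeline knows how to decode.
TARGETS = ("rt", "confidence")


class RoidecodeError(Exception):
    """Base class for all package errors."""


class FormatError(RoidecodeError):
    """A file does not conform to the expected tabular schema."""


class ValidationError(RoidecodeError):
    """Data are well-formed but violate a domain invariant."""


def derive_seed(master_seed: int, *parts) -> int:
    """Derive a stable 31-bit seed from a master seed and a tuple of labels.

    Hash-based so that per-cell streams do not depend on scheduling order:
    the same (master seed, subject, ROI, target, stage) tuple always yields
    the same stream regardless of how many other cells ran before it.
    """
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for p in parts:
        h.update(b"\x1f")
        h.update(str(p).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r of two 1-D arrays; NaN if either side has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = xc @ xc
    syy = yc @ yc
    if sxx <= 0.0 or syy <= 0.0 or n < 2:
        return float("nan")
    return float((xc @ yc) / np.sqrt(sxx * syy))


def pearson_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r between matching rows of two (k, n) arrays.

    Rows with zero variance on either side yield NaN.  Used on the hot
    permutation-null path where per-call overhead matters.
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", Xc, Xc)
    syy = np.einsum("ij,ij->i", Yc, Yc)
    sxy = np.einsum("ij,ij->i", Xc, Yc)
    denom = np.sqrt(sxx * syy)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0.0, sxy / denom, np.nan)
    return r
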