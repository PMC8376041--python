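"""2D singular spectrum analysis (SSA) of embryo images.

2D SSA decomposes an image into additive components of decreasing scale by
(1) embedding: every Lx-by-Ly sliding window of the image becomes one
column of the trajectory matrix, which then has Hankel-block-Hankel
structure; (2) SVD of the trajectory matrix into eigentriples (singular
value, left factor, right factor); (3) grouping eigentriples into
interpretable parts — in this pipeline F1 (the leading eigentriple,
capturing the smooth expression trend), F2-F4 (mid-frequency structure:
local inhomogeneities of the cortical cytoplasm) and the residual noise;
(4) reconstruction of each group back to image space by averaging every
patch placement covering a pixel (the 2D analogue of diagonal averaging /
hankelization).

*Shaped* 2D SSA restricts the window placements to those lying entirely
inside an arbitrary pixel mask, so a decomposition can be confined to, say,
the cortical cytoplasm of a sagittal section.  Pixels covered by no
placement are reported as NaN, never zero-filled.  On a full rectangular
mask the shaped variant reduces exactly to plain 2D SSA.

Useful identities (exercised by the test-suite): the squared singular
values sum to the squared Frobenius norm of the trajectory matrix;
retaining every eigentriple reconstructs the input exactly; and an image
separable as exp(a*r + b*c) has a rank-1 trajectory matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "SSAConfig",
    "SSADecomposition",
    "embed",
    "decompose",
    "ssa2d",
    "shaped_ssa2d",
    "reconstruct",
    "split_signal_noise",
    "wcorrelation",
]

log = logging.getLogger(__name__)


@dataclass
class SSAConfig:
    """Configuration for the signal/noise split.

    ``window`` defaults (when None) to roughly a quarter of the image
    extent per axis.  ``groups`` maps component names to 1-based eigentriple
    index tuples; the default follows the trend / mid-frequency convention
    F1 = {1}, F2-F4 = {2, 3, 4}.
    """

    window: tuple[int, int] | None = None
    max_rank: int = 16
    groups: dict[str, tuple[int, ...]] | None = None

    def resolved_window(self, shape: tuple[int, int]) -> tuple[int, int]:
        if self.window is not None:
            return self.window
        return max(shape[0] // 4, 2), max(shape[1] // 4, 2)

    def resolved_groups(self) -> dict[str, tuple[int, ...]]:
        return self.groups or {"F1": (1,), "F2-F4": (2, 3, 4)}


def _placements_full(shape, window):
    kx, ky = shape[0] - window[0] + 1, shape[1] - window[1] + 1
    gx, gy = np.meshgrid(np.arange(kx), np.arange(ky), indexing="ij")
    return gx.ravel(), gy.ravel()


def embed(image: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Hankel-block-Hankel trajectory matrix of an image region.

    Columns are the vectorized Lx-by-Ly sliding patches in row-major
    placement order; shape is (Lx*Ly, (Nx-Lx+1)*(Ny-Ly+1)).
    """
    image = np.asarray(image, dtype=float)
    lx, ly = window
    if not (1 <= lx <= image.shape[0] and 1 <= ly <= image.shape[1]):
        raise ValueError(
            f"window {window} does not fit in image of shape {image.shape}"
        )
    patches = sliding_window_view(image, (lx, ly))  # (Kx, Ky, Lx, Ly)
    kx, ky = patches.shape[:2]
    return patches.reshape(kx * ky, lx * ly).T


def decompose(trajectory: np.ndarray, max_rank: int | None = None):
    """Truncated SVD of a trajectory matrix.

    Returns ``(s, U, Vt)`` with singular values in non-increasing order.
    Small matrices use a dense SVD; large ones an iterative truncated SVD.
    """
    m, n = trajectory.shape
    full = min(m, n)
    r = full if max_rank is None else min(max_rank, full)
    if r < full and min(m, n) > 256 and r < min(m, n) - 1:
        from scipy.sparse.linalg import svds

        u, s, vt = svds(trajectory, k=r)
        order = np.argsort(s)[::-1]
        return s[order], u[:, order], vt[order]
    u, s, vt = np.linalg.svd(trajectory, full_matrices=False)
    return s[:r], u[:, :r], vt[:r]


@dataclass
class SSADecomposition:
    """Eigentriples of a (possibly shaped) 2D SSA decomposition."""

    singular_values: np.ndarray
    u: np.ndarray  # (Lx*Ly, r) left factors
    vt: np.ndarray  # (r, n_placements) right factors
    window: tuple[int, int]
    shape: tuple[int, int]
    placements: tuple[np.ndarray, np.ndarray]  # top-left (rows, cols)
    mask: np.ndarray | None = None  # analysis mask (None = full frame)

    @property
    def rank(self) -> int:
        return self.singular_values.size

    def coverage(self) -> np.ndarray:
        """Number of patch placements covering each pixel."""
        lx, ly = self.window
        px, py = self.placements
        cov = np.zeros(self.shape)
        ones = np.ones(px.size)
        for i in range(lx):
            for j in range(ly):
                np.add.at(cov, (px + i, py + j), ones)
        return cov

    def reconstruct(self, group) -> np.ndarray:
        return reconstruct(self, group)


def _fold(dec: SSADecomposition, patch_matrix: np.ndarray) -> np.ndarray:
    """Average patch placements back to image space (diagonal averaging)."""
    lx, ly = dec.window
    px, py = dec.placements
    out = np.zeros(dec.shape)
    cov = np.zeros(dec.shape)
    ones = np.ones(px.size)
    for i in range(lx):
        for j in range(ly):
            row = patch_matrix[i * ly + j]
            np.add.at(out, (px + i, py + j), row)
            np.add.at(cov, (px + i, py + j), ones)
    with np.errstate(invalid="ignore"):
        out = np.where(cov > 0, out / np.maximum(cov, 1), np.nan)
    return out


def reconstruct(dec: SSADecomposition, group) -> np.ndarray:
    """Reconstruct the image component for a group of eigentriples.

    ``group`` contains 1-based eigentriple indices; an empty group yields a
    zero image (on the covered region).  Pixels covered by no placement are
    NaN.
    """
    idx = np.asarray(sorted(set(int(g) for g in group)), dtype=int)
    if idx.size and (idx.min() < 1 or idx.max() > dec.rank):
        raise ValueError(f"group indices must lie in 1..{dec.rank}")
    if idx.size == 0:
        patch = np.zeros((dec.u.shape[0], dec.vt.shape[1]))
    else:
        i0 = idx - 1
        patch = (dec.u[:, i0] * dec.singular_values[i0]) @ dec.vt[i0]
    return _fold(dec, patch)


def ssa2d(
    image: np.ndarray, window: tuple[int, int], max_rank: int | None = None
) -> SSADecomposition:
    """Plain 2D SSA of a full rectangular image."""
    image = np.asarray(image, dtype=float)
    traj = embed(image, window)
    s, u, vt = decompose(traj, max_rank)
    return SSADecomposition(
        singular_values=s,
        u=u,
        vt=vt,
        window=tuple(window),
        shape=image.shape,
        placements=_placements_full(image.shape, window),
        mask=None,
    )


def shaped_ssa2d(
    image: np.ndarray,
    mask: np.ndarray,
    window: tuple[int, int],
    max_rank: int | None = None,
) -> SSADecomposition:
    """Shaped 2D SSA: window placements restricted to lie inside ``mask``.

    Raises ``ValueError`` when no placement of the window fits in the mask.
    With a full (all-True) mask this is identical to :func:`ssa2d`.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask must match the image shape")
    lx, ly = window
    if not (1 <= lx <= image.shape[0] and 1 <= ly <= image.shape[1]):
        raise ValueError(f"window {window} does not fit in image {image.shape}")

    # a placement is admissible iff every pixel of the window is in the mask
    counts = sliding_window_view(mask.astype(np.int64), (lx, ly)).sum(axis=(2, 3))
    ok = counts == lx * ly
    px, py = np.nonzero(ok)
    if px.size == 0:
        raise ValueError("no placement of the window fits inside the mask")

    patches = sliding_window_view(image, (lx, ly))
    traj = patches[px, py].reshape(px.size, lx * ly).T
    s, u, vt = decompose(traj, max_rank)
    return SSADecomposition(
        singular_values=s,
        u=u,
        vt=vt,
        window=tuple(window),
        shape=image.shape,
        placements=(px, py),
        mask=mask,
    )


def wcorrelation(dec: SSADecomposition, k: int | None = None) -> np.ndarray:
    """Weighted-correlation matrix between elementary reconstructions.

    The weight of a pixel is the number of window placements covering it.
    Well-separated components have w-correlation near 0; values near 1
    suggest the eigentriples belong in one group.  Used as a grouping
    diagnostic.
    """
    k = dec.rank if k is None else min(k, dec.rank)
    comps = [np.nan_to_num(reconstruct(dec, [i + 1])) for i in range(k)]
    w = dec.coverage()
    mat = np.eye(k)
    norms = [np.sqrt(np.sum(w * f * f)) for f in comps]
    for i in range(k):
        for j in range(i + 1, k):
            denom = norms[i] * norms[j]
            mat[i, j] = mat[j, i] = (
                np.sum(w * comps[i] * comps[j]) / denom if denom > 0 else 0.0
            )
    return mat


def split_signal_noise(
    image: np.ndarray,
    config: SSAConfig = SSAConfig(),
    mask: np.ndarray | None = None,
):
    """Split an image into trend (F1), mid-frequency (F2-F4) and residual.

    Returns ``(f1, f24, residual)``; on the analyzed region the three sum
    exactly to the input image, since the residual is defined as the
    difference.  When fewer than four eigentriples are available the
    mid-frequency group is truncated accordingly (logged).
    """
    image = np.asarray(image, dtype=float)
    window = config.resolved_window(image.shape)
    if mask is None:
        dec = ssa2d(image, window, config.max_rank)
    else:
        dec = shaped_ssa2d(image, mask, window, config.max_rank)
    groups = config.resolved_groups()
    g1 = tuple(i for i in groups.get("F1", (1,)) if i <= dec.rank)
    g24 = tuple(i for i in groups.get("F2-F4", (2, 3, 4)) if i <= dec.rank)
    if len(g24) < len(groups.get("F2-F4", (2, 3, 4))):
        log.info("rank %d < 4: mid-frequency group truncated to %s", dec.rank, g24)
    f1 = reconstruct(dec, g1)
    f24 = reconstruct(dec, g24)
    covered = ~np.isnan(f1)
    residual = np.where(covered, image - f1 - f24, np.nan)
    return f1, f24, residual
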