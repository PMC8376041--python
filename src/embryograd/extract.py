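"""Extraction of apical/basal AP intensity profiles from sagittal images.

Profiles are acquired the way they are from real confocal sections: a chain
of circular regions of interest (ROIs) is moved along a contour offset a
fixed depth below the embryo surface (shallow for the apical layer, deeper
for the basal layer), and the mean intensity inside each disc becomes one
profile sample.  Sample positions are reported as percent egg length by
projecting each ROI center onto the AP chord of the embryo mask (the
anterior-most to posterior-most mask points), so apical and basal profiles
share one coordinate system; for custom contours (e.g. ventral -> anterior
pole -> dorsal sweeps) the arc-length fraction is reported instead.

Pixel convention: 0-based (row, col) with pixel centers at integer
coordinates; a pixel belongs to a disc when its center lies within the
radius.  ROIs entirely outside the embryo mask yield NaN (missing) samples,
never zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage import measure

from .profiles import AxisProfile

__all__ = [
    "ROIChain",
    "offset_contour",
    "build_roi_chain",
    "extract_profile",
    "threshold_mask",
    "ap_chord",
]


@dataclass
class ROIChain:
    """A chain of equal-radius circular ROIs along a contour."""

    centers: np.ndarray  # (n, 2) float, (row, col)
    radius: float
    layer: str = "custom"

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        if self.centers.shape[0] < 1:
            raise ValueError("chain needs at least one center")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        gaps = np.linalg.norm(np.diff(self.centers, axis=0), axis=1)
        if gaps.size and gaps.max() > 2 * self.radius + 1e-9:
            warnings.warn(
                "consecutive ROI spacing exceeds the disc diameter; "
                "the chain leaves gaps along the contour",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return self.centers.shape[0]


def threshold_mask(image: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Simple embryo mask: threshold (default Otsu) + largest component."""
    from skimage.filters import threshold_otsu

    if threshold is None:
        threshold = threshold_otsu(image)
    binary = image > threshold
    labels = measure.label(binary)
    if labels.max() == 0:
        raise ValueError("thresholding produced an empty mask")
    counts = np.bincount(labels.ravel())[1:]
    return labels == (1 + int(np.argmax(counts)))


def ap_chord(mask: np.ndarray) -> tuple[float, float]:
    """Column extent (anterior-most, posterior-most) of the embryo mask."""
    cols = np.where(mask.any(axis=0))[0]
    if cols.size == 0:
        raise ValueError("empty mask")
    return float(cols[0]), float(cols[-1])


def _single_region(mask: np.ndarray) -> None:
    labels = measure.label(mask)
    if labels.max() != 1:
        raise ValueError(f"mask must be a single connected region, got {labels.max()}")


def offset_contour(
    mask: np.ndarray, depth: float, side: str = "dorsal"
) -> np.ndarray:
    """Contour offset ``depth`` px inside the mask boundary, ordered from
    the anterior pole posteriorly.

    ``side`` selects the dorsal (upper) or ventral (lower) branch, or
    ``"full"`` for the whole closed contour opened at the posterior pole and
    ordered ventral -> anterior pole -> dorsal.

    Returns an (n, 2) float array of (row, col) points.  Raises
    ``ValueError`` if the requested depth erodes the mask away entirely.
    """
    if side not in ("dorsal", "ventral", "full"):
        raise ValueError("side must be dorsal, ventral or full")
    _single_region(mask)
    dist = distance_transform_edt(mask)
    level = max(float(depth), 0.5)  # boundary pixels sit at EDT value 1
    if dist.max() <= level:
        raise ValueError(f"depth {depth} erodes the mask to nothing")
    contours = measure.find_contours(dist, level)
    if not contours:
        raise ValueError(f"no contour at depth {depth}")
    contour = max(contours, key=lambda c: c.shape[0])
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]

    n = contour.shape[0]
    i_ant = int(np.argmin(contour[:, 1]))
    rolled = np.roll(contour, -i_ant, axis=0)
    i_post = int(np.argmax(rolled[:, 1]))

    # split the closed contour at the anterior and posterior poles into two
    # branches, both ordered anterior -> posterior, and name them by height
    branch_a = rolled[: i_post + 1]
    branch_b = np.concatenate([rolled[:1], rolled[i_post:][::-1]], axis=0)
    if np.mean(branch_a[:, 0]) <= np.mean(branch_b[:, 0]):
        dorsal, ventral = branch_a, branch_b
    else:
        dorsal, ventral = branch_b, branch_a
    if side == "dorsal":
        return dorsal
    if side == "ventral":
        return ventral
    # full: posterior -> ventral -> anterior pole -> dorsal -> posterior
    return np.concatenate([ventral[::-1], dorsal[1:]], axis=0)


def _arc_length(contour: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(contour, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def build_roi_chain(
    contour: np.ndarray, radius: float, spacing: float, layer: str = "custom"
) -> ROIChain:
    """Place ROI centers at uniform arc-length spacing along a contour.

    On a closed contour (identical endpoints) the wrap point is not
    duplicated.  ``spacing > 2*radius`` triggers a gap-coverage warning but
    proceeds; a contour shorter than ``spacing`` is rejected.
    """
    if spacing <= 0 or radius <= 0:
        raise ValueError("spacing and radius must be positive")
    contour = np.asarray(contour, dtype=float).reshape(-1, 2)
    s = _arc_length(contour)
    total = s[-1]
    if total < spacing:
        raise ValueError("contour shorter than the requested spacing")
    closed = bool(np.allclose(contour[0], contour[-1]))
    if closed:
        targets = np.arange(0.0, total, spacing)
    else:
        targets = np.arange(0.0, total + spacing * 1e-9, spacing)
    centers = np.column_stack(
        [np.interp(targets, s, contour[:, 0]), np.interp(targets, s, contour[:, 1])]
    )
    return ROIChain(centers=centers, radius=radius, layer=layer)


def extract_profile(
    image: np.ndarray,
    chain: ROIChain,
    mask: np.ndarray | None = None,
    coordinate: str = "ap_pct",
    channel: str = "",
    embryo_id: str = "",
) -> AxisProfile:
    """Mean-intensity profile along an ROI chain.

    Each sample is the mean of image pixels inside the disc intersected
    with the embryo mask (the whole frame when ``mask`` is None).  With
    ``coordinate="ap_pct"`` positions are the AP-chord projection of the
    centers in %EL; with ``"arc_fraction"`` they are the cumulative
    arc-length percentage along the chain.  ROIs without any valid pixel
    are flagged missing (NaN).
    """
    rows, cols = image.shape
    valid = np.ones(image.shape, dtype=bool) if mask is None else mask.astype(bool)

    rad = chain.radius
    intensities = np.empty(len(chain))
    for i, (cr, cc) in enumerate(chain.centers):
        r0, r1 = int(np.floor(cr - rad)), int(np.ceil(cr + rad))
        c0, c1 = int(np.floor(cc - rad)), int(np.ceil(cc + rad))
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, rows - 1), min(c1, cols - 1)
        if r0 > r1 or c0 > c1:
            intensities[i] = np.nan
            continue
        rr = np.arange(r0, r1 + 1)[:, None]
        cc_ = np.arange(c0, c1 + 1)[None, :]
        disc = ((rr - cr) ** 2 + (cc_ - cc) ** 2 <= rad**2) & valid[
            r0 : r1 + 1, c0 : c1 + 1
        ]
        if not disc.any():
            intensities[i] = np.nan
        else:
            intensities[i] = float(image[r0 : r1 + 1, c0 : c1 + 1][disc].mean())

    if coordinate == "ap_pct":
        if mask is None:
            lo, hi = 0.0, float(cols - 1)
        else:
            lo, hi = ap_chord(valid)
        positions = (chain.centers[:, 1] - lo) / (hi - lo) * 100.0
    elif coordinate == "arc_fraction":
        s = _arc_length(chain.centers)
        positions = s / s[-1] * 100.0 if s[-1] > 0 else s
    else:
        raise ValueError("coordinate must be 'ap_pct' or 'arc_fraction'")

    order = np.argsort(positions, kind="stable")
    positions, intensities = positions[order], intensities[order]
    keep = np.concatenate([[True], np.diff(positions) > 1e-9])
    return AxisProfile(
        positions=positions[keep],
        intensities=np.clip(intensities[keep], 0, None),
        layer=chain.layer,
        channel=channel,
        embryo_id=embryo_id,
        coordinate=coordinate,
    )
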