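"""Core containers for 1D axis profiles and embryo records.

An :class:`AxisProfile` holds intensity samples along the anterior-posterior
(AP) axis of one embryo, for one cortical layer (apical or basal) and one
channel (*bcd* mRNA or Staufen protein).  Positions are expressed in percent
egg length (%EL): 0 at the anterior pole, 100 at the posterior pole.  For
profiles taken along arbitrary contours the position is instead an arc-length
fraction in [0, 100]; the ``coordinate`` field records which convention is in
use.  Missing samples (e.g. an ROI falling outside the embryo) are stored as
NaN and must be skipped, never imputed, by downstream fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "AxisProfile",
    "EmbryoRecord",
    "profiles_to_frame",
    "frame_to_profiles",
    "read_profiles_csv",
    "write_profiles_csv",
]


@dataclass
class AxisProfile:
    """Ordered (position, intensity) samples for one embryo/layer/channel.

    Parameters
    ----------
    positions
        Strictly increasing positions in %EL (or arc-length percent for
        custom contours), within [0, 100].
    intensities
        Fluorescence intensities in arbitrary units, >= 0.  NaN marks a
        missing sample.
    layer
        ``"apical"``, ``"basal"`` or ``"custom"``.
    channel
        ``"bcd"`` or ``"stau"`` (free-form for synthetic data).
    embryo_id
        Identifier used in tabular output.
    coordinate
        ``"ap_pct"`` for AP-chord %EL, ``"arc_fraction"`` for arc-length
        percent along a custom contour.
    truth
        Optional noiseless model values at ``positions`` (set by the
        synthetic generator; None for real data).
    """

    positions: np.ndarray
    intensities: np.ndarray
    layer: str = "apical"
    channel: str = "bcd"
    embryo_id: str = ""
    coordinate: str = "ap_pct"
    truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.ndim != 1 or self.positions.size == 0:
            raise ValueError("positions must be a non-empty 1D array")
        if self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must have equal length")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        finite = self.intensities[np.isfinite(self.intensities)]
        if finite.size and finite.min() < 0:
            raise ValueError("intensities must be non-negative (NaN = missing)")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=float)
            if self.truth.shape != self.positions.shape:
                raise ValueError("truth must match positions in length")

    def __len__(self) -> int:
        return self.positions.size

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-missing samples."""
        return np.isfinite(self.intensities)

    def window(self, lo: float, hi: float) -> "AxisProfile":
        """Restrict to positions in [lo, hi] (missing samples kept as NaN)."""
        if not lo < hi:
            raise ValueError("window lo must be < hi")
        sel = (self.positions >= lo) & (self.positions <= hi)
        if not sel.any():
            raise ValueError(f"no samples inside window ({lo}, {hi})")
        return replace(
            self,
            positions=self.positions[sel],
            intensities=self.intensities[sel],
            truth=None if self.truth is None else self.truth[sel],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "embryo_id": self.embryo_id,
                "channel": self.channel,
                "layer": self.layer,
                "position_pct_el": self.positions,
                "intensity": self.intensities,
            }
        )


@dataclass
class EmbryoRecord:
    """Paired apical and basal profiles for one embryo.

    ``stage`` is one of the three main stages (``cleavage``, ``syncytial``,
    ``cc14``); ``subgroup`` optionally refines it to one of the nine age
    sub-groups.  ``true_params`` carries the generating parameters for
    synthetic embryos (per-layer dicts), and ``image`` an optional source
    image.
    """

    embryo_id: str
    apical: AxisProfile
    basal: AxisProfile
    channel: str = "bcd"
    stage: str | None = None
    subgroup: str | None = None
    true_params: dict | None = None
    image: object | None = None

    def profile(self, layer: str) -> AxisProfile:
        if layer == "apical":
            return self.apical
        if layer == "basal":
            return self.basal
        raise KeyError(f"unknown layer {layer!r}")


def profiles_to_frame(profiles: Iterable[AxisProfile]) -> pd.DataFrame:
    """Concatenate profiles into long-format table."""
    frames = [p.to_frame() for p in profiles]
    if not frames:
        return pd.DataFrame(
            columns=["embryo_id", "channel", "layer", "position_pct_el", "intensity"]
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_profiles(df: pd.DataFrame) -> list[AxisProfile]:
    """Split a long-format table back into AxisProfile objects."""
    out = []
    for (eid, channel, layer), grp in df.groupby(
        ["embryo_id", "channel", "layer"], sort=False
    ):
        grp = grp.sort_values("position_pct_el")
        out.append(
            AxisProfile(
                positions=grp["position_pct_el"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                layer=str(layer),
                channel=str(channel),
                embryo_id=str(eid),
            )
        )
    return out


def write_profiles_csv(path, profiles: Iterable[AxisProfile]) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles_csv(path) -> list[AxisProfile]:
    return frame_to_profiles(pd.read_csv(path))
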