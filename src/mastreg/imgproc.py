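"""Projection and temporal color-coding transforms.

Two transforms precede all analysis:

* **Maximum Z-projection** collapses each (z, y, x) volume to a single
  plane by taking the per-pixel maximum over z, merging cells that sit in
  different focal planes (dermal mast cells, infiltrating Tregs,
  epidermal Langerhans cells) onto one micrograph.

* **RGB triad encoding** overlays three consecutive time points of one
  channel as blue (t−1), green (t), red (t+1).  Immobile structures get
  equal contributions in all three planes and appear white/gray; pixels a
  cell is about to occupy are red-dominant (forward movement, sprouting),
  pixels it has vacated are blue-dominant (retraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stackio import ImageStack, StackMeta

__all__ = ["ProjectedStack", "RgbFrame", "max_z_project", "rgb_triad_encode", "rgb_triad_video"]


@dataclass
class ProjectedStack:
    """A (t, c, y, x) stack of maximum Z-projections with its calibration."""

    meta: StackMeta
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"projected data must be 4-D (t, c, y, x), got {self.data.ndim}-D")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channel(self, role: str) -> np.ndarray:
        """The (t, y, x) projected movie for one channel role."""
        return self.data[:, self.meta.channel_index(role)]

    def frame(self, t: int, role: str) -> np.ndarray:
        return self.data[t, self.meta.channel_index(role)]


@dataclass
class RgbFrame:
    """Three equal-shape intensity planes, each in [0, 1]."""

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        if not (self.r.shape == self.g.shape == self.b.shape):
            raise ValueError("r, g, b planes must share a shape")
        for plane in (self.r, self.g, self.b):
            if plane.min() < 0 or plane.max() > 1:
                raise ValueError("RGB planes must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        """(y, x, 3) float array, channel-last."""
        return np.stack([self.r, self.g, self.b], axis=-1)

    def as_uint8(self) -> np.ndarray:
        """(y, x, 3) 8-bit array for TIFF export."""
        return np.round(self.as_array() * 255).astype(np.uint8)


def max_z_project(stack: ImageStack) -> ProjectedStack:
    """Per-pixel maximum over the axial dimension; metadata preserved."""
    if stack.data.shape[1] < 1:
        raise ValueError("stack has no z slices")
    return ProjectedStack(meta=stack.meta, data=stack.data.max(axis=1))


def rgb_triad_encode(prev: np.ndarray, curr: np.ndarray, next: np.ndarray) -> RgbFrame:
    """Encode a triad of frames as blue = t−1, green = t, red = t+1.

    All three planes are normalized by the joint maximum over the triad
    (left as zeros if the triad is identically zero), so that intensity
    changes — not only displacement — produce color, and a static scene is
    exactly achromatic.
    """
    prev = np.asarray(prev, dtype=float)
    curr = np.asarray(curr, dtype=float)
    next = np.asarray(next, dtype=float)
    if not (prev.shape == curr.shape == next.shape):
        raise ValueError("triad planes must share a shape")
    peak = max(prev.max(initial=0.0), curr.max(initial=0.0), next.max(initial=0.0))
    if peak <= 0:
        zero = np.zeros_like(curr)
        return RgbFrame(r=zero, g=zero.copy(), b=zero.copy())
    return RgbFrame(r=next / peak, g=curr / peak, b=prev / peak)


def rgb_triad_video(frames) -> list[RgbFrame]:
    """Apply the triad encoding to every interior frame of a movie.

    Output frame k (1 ≤ k ≤ n−2) encodes frames (k−1, k, k+1); the two
    boundary frames are dropped rather than padded, since padding would
    fabricate motion at the sequence ends.  Length is n−2.
    """
    frames = [np.asarray(f) for f in frames]
    if len(frames) < 3:
        raise ValueError(f"triad video needs >= 3 frames, got {len(frames)}")
    return [
        rgb_triad_encode(frames[k - 1], frames[k], frames[k + 1])
        for k in range(1, len(frames) - 1)
    ]
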