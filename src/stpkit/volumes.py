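"""Synthetic multi-channel mFISH image volumes with known ground truth.

Volumes emulate the two signal classes of thick-tissue HCR imaging of human
cortex: amplified mRNA spots, bright in exactly one channel, and lipofuscin
autofluorescence granules, bright in *all* channels.  A Gaussian background
(truncated at zero) stands in for optical and detector noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Blob:
    """Spherical structure: ``center`` (z, y, x) voxels, ``radius`` voxels,
    ``intensity`` added above background.  ``channel=None`` renders in all
    channels (lipofuscin); an integer renders in that channel only (mRNA)."""

    center: tuple[float, float, float]
    radius: float
    intensity: float
    channel: int | None = None


@dataclass
class SyntheticVolumeSpec:
    shape: tuple[int, int, int] = (16, 64, 64)  # (z, y, x)
    n_channels: int = 3
    background_mean: float = 100.0
    background_sd: float = 10.0
    lipofuscin_blobs: list[Blob] = field(default_factory=list)
    spots: list[Blob] = field(default_factory=list)
    cell_masks: list[np.ndarray] = field(default_factory=list)  # boolean volumes

    def __post_init__(self) -> None:
        for b in self.lipofuscin_blobs + self.spots:
            if b.intensity <= self.background_mean:
                raise ValueError("blob/spot intensity must exceed background mean")
        for m in self.cell_masks:
            if m.shape != tuple(self.shape):
                raise ValueError("cell masks must match volume shape")


def _ball_mask(shape: tuple[int, int, int], blob: Blob) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = blob.center
    return (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= blob.radius**2


@dataclass
class VolumeGroundTruth:
    lipofuscin_mask: np.ndarray  # bool (z, y, x)
    spot_masks: list[np.ndarray]  # bool per spot
    cell_expression: list[np.ndarray]  # (n_cells, n_channels) injected mean intensity


def simulate_mfish_volume(
    spec: SyntheticVolumeSpec, seed: int = 0
) -> tuple[np.ndarray, VolumeGroundTruth]:
    """Render the volume → ``(stack, truth)``.

    ``stack`` has shape (n_channels, z, y, x).  Background is
    Normal(mean, sd) truncated at 0; lipofuscin blobs add their intensity to
    every channel, spots only to their own channel.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(spec.shape)
    stack = rng.normal(
        spec.background_mean, spec.background_sd, size=(spec.n_channels, *shape)
    )
    np.clip(stack, 0.0, None, out=stack)

    lipo = np.zeros(shape, dtype=bool)
    for blob in spec.lipofuscin_blobs:
        m = _ball_mask(shape, blob)
        lipo |= m
        stack[:, m] += blob.intensity - spec.background_mean

    spot_masks = []
    for spot in spec.spots:
        if spot.channel is None or not 0 <= spot.channel < spec.n_channels:
            raise ValueError("spots must name a valid channel")
        m = _ball_mask(shape, spot)
        spot_masks.append(m)
        if (m & lipo).any():
            warnings.warn("spot overlaps a lipofuscin blob", stacklevel=2)
        stack[spot.channel][m] += spot.intensity - spec.background_mean

    expression = []
    for cell in spec.cell_masks:
        per_chan = np.array(
            [stack[c][cell].mean() if cell.any() else 0.0 for c in range(spec.n_channels)]
        )
        expression.append(per_chan)

    truth = VolumeGroundTruth(
        lipofuscin_mask=lipo, spot_masks=spot_masks, cell_expression=expression
    )
    return stack, truth
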