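"""3-D image stacks with physical voxel spacing."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageStack:
    """A single-channel 3-D intensity grid.

    ``data`` is indexed ``(z, y, x)``; ``spacing`` gives the per-axis voxel
    size in um in the same order.  ``origin`` is the physical coordinate
    (x, y, z order NOT used here: stored as (z, y, x) to match the data) of
    voxel ``(0, 0, 0)``, so voxel ``(i, j, k)`` sits at
    ``origin + (i, j, k) * spacing``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    channel: str = ""
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axes_um(self):
        """Physical coordinate arrays along (z, y, x)."""
        return tuple(
            self.origin[i] + np.arange(self.data.shape[i]) * self.spacing[i]
            for i in range(3)
        )

    def index_of(self, point_zyx) -> np.ndarray:
        """Fractional voxel index of a physical (z, y, x) point."""
        return (np.asarray(point_zyx, float) - self.origin) / np.asarray(self.spacing)

    def point_of(self, index_zyx) -> np.ndarray:
        """Physical (z, y, x) coordinate of a fractional voxel index."""
        return self.origin + np.asarray(index_zyx, float) * np.asarray(self.spacing)
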