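"""CT volume container.

Array convention used throughout the package: axes are (z, y, x) with
0-based voxel indices, superior = decreasing z index and patient-left =
increasing x index.  Bounding boxes are half-open ``[min, max)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CTVolume:
    """A 3D scalar field in Hounsfield units with per-axis voxel spacing.

    Parameters
    ----------
    values
        Intensity array of shape (z, y, x), Hounsfield units.
    spacing_mm
        Voxel spacing per axis (z, y, x), millimetres.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"CTVolume expects a 3D array, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"invalid spacing {self.spacing_mm!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]

    def copy(self) -> "CTVolume":
        return CTVolume(self.values.copy(), self.spacing_mm, dict(self.meta))
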