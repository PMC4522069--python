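"""In-memory container for a multi-echo magnitude image stack."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """2D magnitude image per echo time.

    ``data`` has shape (rows, cols, n_echoes) — echo dimension last,
    matching the on-disk NIfTI layout.  ``pixel_spacing_mm`` is the
    in-plane (row, col) spacing; the protocols here use 2 x 2 mm.
    ``affine`` carries the NIfTI spatial metadata through a read/write
    round trip; it is never interpreted beyond that.
    """

    data: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (2.0, 2.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"stack must be (rows, cols, n_echoes), got shape {self.data.shape}"
            )
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be >= 0")
        if self.affine is None:
            sr, sc = self.pixel_spacing_mm
            self.affine = np.diag([sr, sc, 1.0, 1.0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[2]
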