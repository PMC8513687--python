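"""Acquisition geometry of the multimodal sensing array.

The default geometry is a 32 x 32 grid of multimodal pixels at 58 um pitch
(1024 electrode sites) with four photodiode sites per pixel (4096 optical
sites) spanning a 1.85 mm x 1.85 mm field of view.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, model_validator


class ArrayGeometry(BaseModel):
    """Grid layout of the sensing array.

    Parameters
    ----------
    rows, cols : int
        Pixel grid dimensions.
    pitch_um : float
        Centre-to-centre pixel spacing in micrometres.
    photodiode_sites_per_pixel : int
        Optical sub-sites per pixel, laid out on a 2 x 2 subgrid.
    fov_mm : float
        Side length of the field of view in millimetres.  Defaults to
        ``rows * pitch_um / 1000`` and must agree with it within 2 %.
    """

    model_config = {"frozen": True, "extra": "forbid"}

    rows: int = 32
    cols: int = 32
    pitch_um: float = 58.0
    photodiode_sites_per_pixel: int = 4
    fov_mm: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "ArrayGeometry":
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")
        if self.photodiode_sites_per_pixel != 4:
            raise ValueError("only 4 photodiode sites per pixel are supported")
        if self.fov_mm is None:
            object.__setattr__(self, "fov_mm", self.rows * self.pitch_um / 1000.0)
        implied = self.rows * self.pitch_um / 1000.0
        if abs(implied - self.fov_mm) > 0.02 * self.fov_mm:
            raise ValueError(
                f"fov_mm={self.fov_mm} inconsistent with rows*pitch={implied:.4f} mm"
            )
        return self

    @property
    def n_pixels(self) -> int:
        return self.rows * self.cols

    @property
    def n_optical_sites(self) -> int:
        return self.n_pixels * self.photodiode_sites_per_pixel

    def pixel_rc(self, pixel_id: int) -> tuple[int, int]:
        """Row/column of a flat (row-major) pixel id."""
        if not 0 <= pixel_id < self.n_pixels:
            raise ValueError(f"pixel_id {pixel_id} outside grid")
        return divmod(pixel_id, self.cols)

    def pixel_id(self, row: int, col: int) -> int:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise ValueError(f"pixel ({row}, {col}) outside grid")
        return row * self.cols + col

    def pixel_centres_um(self) -> np.ndarray:
        """(n_pixels, 2) array of pixel-centre (x, y) positions in um."""
        r, c = np.divmod(np.arange(self.n_pixels), self.cols)
        return np.column_stack([c * self.pitch_um, r * self.pitch_um]).astype(float)

    def radial_distance_um(self, pixel_ids=None) -> np.ndarray:
        """Distance of each pixel centre from the array centre, in um.

        The array centre is the mean of all pixel centres.
        """
        centres = self.pixel_centres_um()
        centre = centres.mean(axis=0)
        d = np.hypot(*(centres - centre).T)
        if pixel_ids is None:
            return d
        return d[np.asarray(pixel_ids, dtype=int)]


DEFAULT_GEOMETRY = ArrayGeometry()
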