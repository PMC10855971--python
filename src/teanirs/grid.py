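"""Wavelength grid for diffuse-reflectance NIR spectra.

The instrument records log(1/R) every 2 nm; the working range used for
chemometrics is 1100-2498 nm, i.e. 700 spectral variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WavelengthGrid", "DEFAULT_GRID"]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nanometres.

    Parameters
    ----------
    start_nm, end_nm : float
        First and last wavelength, inclusive.
    step_nm : float
        Spacing between consecutive points.
    """

    start_nm: float = 1100.0
    end_nm: float = 2498.0
    step_nm: float = 2.0

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        if self.end_nm <= self.start_nm:
            raise ValueError("end_nm must exceed start_nm")
        n = (self.end_nm - self.start_nm) / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise ValueError("grid span must be an integer number of steps")

    @property
    def n_points(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    def __len__(self) -> int:
        return self.n_points


#: The instrument grid: 1100-2498 nm at 2 nm -> 700 variables.
DEFAULT_GRID = WavelengthGrid()
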