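"""Coded spectral pretreatments.

Scatter corrections (SNV, MSC, detrend, SNV-DT) combined with the classic
four-digit derivative code ``(d, g, s1, s2)``: *d* is the derivative order,
*g* the gap in grid points over which each difference is taken, *s1* the
width of a running-average smoothing applied before differencing and *s2*
a second smoothing applied after. ``Detrend (2,4,4,1)`` therefore means:
polynomial de-trending, then a 4-point boxcar, then a second-order
gap-4 difference, then no further smoothing.

Scatter correction is applied first, then the derivative/smoothing math
treatment; edge points consumed by the stencils are trimmed and the
effective wavelength grid is returned alongside the values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .dataset import SampleTable

__all__ = [
    "PretreatmentCode",
    "parse_treatment_code",
    "snv",
    "msc_fit_reference",
    "msc",
    "detrend",
    "derivative_gap_segment",
    "apply_pretreatment",
]

_SCATTER_NAMES = {
    "none": "none",
    "snv": "SNV",
    "msc": "MSC",
    "dt": "DT",
    "detrend": "DT",
    "snv-dt": "SNV_DT",
    "snv_dt": "SNV_DT",
    "snvdt": "SNV_DT",
}

_DISPLAY = {"none": "none", "SNV": "SNV", "MSC": "MSC", "DT": "Detrend", "SNV_DT": "SNV-DT"}


@dataclass(frozen=True)
class PretreatmentCode:
    """A scatter-correction choice plus the four-digit math treatment."""

    scatter: str = "none"
    derivative_order: int = 0
    gap: int = 1
    smooth1: int = 1
    smooth2: int = 1

    def __post_init__(self) -> None:
        if self.scatter not in _DISPLAY:
            raise ValueError(f"unknown scatter correction {self.scatter!r}")
        if self.derivative_order not in (0, 1, 2, 3):
            raise ValueError("derivative order must be 0-3")
        min_gap = 0 if self.derivative_order == 0 else 1
        if self.gap < min_gap:
            raise ValueError("gap must be >= 1 when a derivative is taken")
        if self.smooth1 < 1 or self.smooth2 < 1:
            raise ValueError("smoothing widths must be >= 1 point")

    def __str__(self) -> str:
        return (f"{_DISPLAY[self.scatter]} ({self.derivative_order},{self.gap},"
                f"{self.smooth1},{self.smooth2})")

    @property
    def trim(self) -> int:
        """Grid points consumed by the smoothing/derivative stencils."""
        return (self.smooth1 - 1) + self.derivative_order * self.gap + (self.smooth2 - 1)


_CODE_RE = re.compile(
    r"^\s*(?:(?P<name>[A-Za-z][\w-]*)\s*)?"
    r"\(\s*(?P<d>\d+)\s*,\s*(?P<g>\d+)\s*,\s*(?P<s1>\d+)\s*,\s*(?P<s2>\d+)\s*\)\s*$"
)


def parse_treatment_code(text: str) -> PretreatmentCode:
    """Parse e.g. ``"Detrend (2,4,4,1)"`` or a bare ``"(0,0,1,1)"``."""
    m = _CODE_RE.match(text)
    if m is None:
        raise ValueError(f"malformed pretreatment code: {text!r}")
    name = (m.group("name") or "none").lower()
    if name not in _SCATTER_NAMES:
        raise ValueError(f"unknown scatter correction {m.group('name')!r}")
    return PretreatmentCode(
        scatter=_SCATTER_NAMES[name],
        derivative_order=int(m.group("d")),
        gap=int(m.group("g")),
        smooth1=int(m.group("s1")),
        smooth2=int(m.group("s2")),
    )


def _as_matrix(values: np.ndarray) -> tuple[np.ndarray, bool]:
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        return values[None, :], True
    return values, False


def snv(values: np.ndarray, ids=None) -> np.ndarray:
    """Standard normal variate: per-spectrum mean 0, sample SD 1 (n-1)."""
    x, squeeze = _as_matrix(values)
    sd = x.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        which = ids[bad[0]] if ids is not None else f"row {bad[0]}"
        raise ValueError(f"constant spectrum (SD = 0) for sample {which}")
    out = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return out[0] if squeeze else out


def msc_fit_reference(values: np.ndarray) -> np.ndarray:
    """MSC reference spectrum: the mean of the (calibration) set."""
    x, _ = _as_matrix(values)
    if x.shape[0] < 2:
        raise ValueError("MSC with reference='mean' needs at least 2 spectra")
    return x.mean(axis=0)


def msc(values: np.ndarray, reference: np.ndarray, ids=None) -> np.ndarray:
    """Multiplicative scatter correction against ``reference``.

    Each spectrum x is regressed x ~ a + b*reference by least squares and
    corrected to (x - a)/b, so a spectrum that is an affine distortion of
    the reference is restored exactly.
    """
    x, squeeze = _as_matrix(values)
    ref = np.asarray(reference, dtype=float)
    refc = ref - ref.mean()
    denom = float(refc @ refc)
    if denom <= 0:
        raise ValueError("MSC reference spectrum is constant")
    b = (x - x.mean(axis=1, keepdims=True)) @ refc / denom
    bad = np.flatnonzero(np.abs(b) < 1e-8)
    if bad.size:
        which = ids[bad[0]] if ids is not None else f"row {bad[0]}"
        raise ValueError(f"degenerate MSC slope (b ~ 0) for sample {which}")
    a = x.mean(axis=1) - b * ref.mean()
    out = (x - a[:, None]) / b[:, None]
    return out[0] if squeeze else out


def detrend(values: np.ndarray, wavelengths: np.ndarray, degree: int = 2) -> np.ndarray:
    """Subtract a least-squares polynomial in wavelength from each spectrum."""
    x, squeeze = _as_matrix(values)
    wl = np.asarray(wavelengths, dtype=float)
    if degree >= wl.size - 1:
        raise ValueError("detrend degree must be < n_points - 1")
    # Center/scale the wavelength axis for numerical conditioning.
    span = np.ptp(wl)
    z = (wl - wl.mean()) / (span / 2 if span > 0 else 1.0)
    V = np.vander(z, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(V, x.T, rcond=None)
    out = x - (V @ coef).T
    return out[0] if squeeze else out


def _boxcar(x: np.ndarray, wl: np.ndarray, width: int) -> tuple[np.ndarray, np.ndarray]:
    if width == 1:
        return x, wl
    if width > x.shape[1]:
        raise ValueError("smoothing window wider than the spectrum")
    kernel = np.ones(width) / width
    out = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, x)
    wl_out = np.convolve(wl, kernel, mode="valid")
    return out, wl_out


def _gap_difference(x: np.ndarray, wl: np.ndarray, gap: int) -> tuple[np.ndarray, np.ndarray]:
    if gap >= x.shape[1]:
        raise ValueError("derivative gap wider than the spectrum")
    return x[:, gap:] - x[:, :-gap], 0.5 * (wl[gap:] + wl[:-gap])


def derivative_gap_segment(
    values: np.ndarray, wavelengths: np.ndarray, code: PretreatmentCode
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the four-digit math treatment; returns (values, effective grid).

    Pipeline order: boxcar of width ``smooth1``, then the forward gap
    difference x(i+g) - x(i) applied ``derivative_order`` times, then a
    boxcar of width ``smooth2``. Width-1 smoothing and order-0 derivative
    are no-ops; edges are trimmed, never padded.
    """
    x, squeeze = _as_matrix(values)
    wl = np.asarray(wavelengths, dtype=float)
    if code.trim >= wl.size:
        raise ValueError("pretreatment stencil wider than the spectrum")
    x, wl = _boxcar(x, wl, code.smooth1)
    for _ in range(code.derivative_order):
        x, wl = _gap_difference(x, wl, code.gap)
    x, wl = _boxcar(x, wl, code.smooth2)
    return (x[0] if squeeze else x), wl


def apply_pretreatment(
    table: SampleTable, code: PretreatmentCode | str, fitted_state: dict | None = None
) -> tuple[SampleTable, dict]:
    """Scatter correction followed by the math treatment, on a whole table.

    Any state estimated from the data (the MSC reference spectrum) is
    returned so validation spectra receive the identical transform; pass the
    returned ``fitted_state`` back in to reuse it.
    """
    if isinstance(code, str):
        code = parse_treatment_code(code)
    state = dict(fitted_state or {})
    x = table.spectra
    wl = table.wavelengths
    ids = table.ids
    if code.scatter == "SNV":
        x = snv(x, ids)
    elif code.scatter == "DT":
        x = detrend(x, wl)
    elif code.scatter == "SNV_DT":
        x = detrend(snv(x, ids), wl)
    elif code.scatter == "MSC":
        if "msc_reference" not in state:
            state["msc_reference"] = msc_fit_reference(x)
        x = msc(x, state["msc_reference"], ids)
    x, wl_eff = derivative_gap_segment(x, wl, code)
    state["code"] = str(code)
    return table.with_spectra(x, wl_eff), state
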