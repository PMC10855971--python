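"""Seeded synthetic tea NIR library.

Emulates the study design every downstream stage expects: 26 pure teas
(7 black, 11 green, 8 red) with class-specific heavy-metal levels, plus
binary blends of two tea types whose dominant fraction ranges from 50% to
99%, for a default library of 322 samples.

Spectral model (log(1/R), 1100-2498 nm at 2 nm):

* a class baseline plus Gaussian absorption bands at the positions where
  tea spectra absorb (water at 1440/1950 nm, C-H overtones at 1220/1670/
  1740 nm, amide bands at 2150/2170 nm, phenolic combination bands above
  2200 nm, amino-acid bands at 1330/1400 nm), with amplitudes ordered so
  mean absorbance is black > red > green and the red-green gap is largest
  around 1940-1950 nm;
* narrow metal-signature bands, linear in concentration, at the wavelength
  pairs where the calibration beta coefficients peak (Al 1282/1290,
  Pb 1164/1984, As 1264/1580, Hg 1244/1252, Cu 1310/1614 nm) -- the
  "association with organic complexes" that makes metals NIR-visible;
* per-sample multiplicative/additive scatter and white measurement noise.

Blends mix linearly: spectra as convex combinations of the two parent
samples' spectra (Beer-Lambert additivity) plus fresh measurement noise,
and metal contents as the exact mixture-weighted combination of the parent
concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import METAL_COLUMNS, METALS, TEA_TYPES, SampleTable, split_sets
from .grid import DEFAULT_GRID, WavelengthGrid

__all__ = [
    "PURE_TEA_METAL_STATS",
    "METAL_SIGNATURES",
    "GeneratorConfig",
    "generate_pure_samples",
    "blend_chemistry",
    "generate_blends",
    "generate_library",
    "split_sets",
    "write_jcamp",
]

#: Per-class metal concentration mean/SD (Al in g/kg, others mg/kg).
PURE_TEA_METAL_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "black": {"Al": (2.04, 0.23), "Pb": (0.56, 0.28), "As": (0.04, 0.01),
              "Hg": (0.00, 0.00), "Cu": (17.31, 2.60)},
    "red":   {"Al": (2.36, 0.25), "Pb": (1.21, 0.36), "As": (0.19, 0.09),
              "Hg": (0.00, 0.00), "Cu": (19.87, 2.78)},
    "green": {"Al": (2.52, 0.29), "Pb": (0.98, 0.40), "As": (0.09, 0.02),
              "Hg": (0.01, 0.01), "Cu": (12.19, 2.40)},
}

#: Metal -> (signature wavelength pair in nm, absorbance per unit concentration).
METAL_SIGNATURES: dict[str, tuple[tuple[float, float], float]] = {
    "Al": ((1282.0, 1290.0), 0.006),
    "Pb": ((1164.0, 1984.0), 0.006),
    "As": ((1264.0, 1580.0), 0.030),
    "Hg": ((1244.0, 1252.0), 0.350),
    "Cu": ((1310.0, 1614.0), 0.0006),
}

#: Width (nm) of the narrow metal-signature Gaussians.
SIGNATURE_SIGMA_NM = 3.0

# Shared absorption-band positions (nm), widths (nm) and base amplitudes.
BAND_CENTERS = np.array(
    [1220.0, 1330.0, 1400.0, 1440.0, 1670.0, 1740.0,
     1885.0, 1950.0, 2150.0, 2170.0, 2280.0, 2350.0])
BAND_SIGMAS = np.array(
    [12.0, 10.0, 14.0, 22.0, 12.0, 10.0, 14.0, 24.0, 9.0, 9.0, 16.0, 18.0])
BAND_BASE_AMPLITUDES = np.array(
    [0.25, 0.12, 0.20, 0.55, 0.25, 0.18, 0.15, 0.75, 0.20, 0.20, 0.25, 0.22])

# Per-band amplitude multipliers per class. The patterns are deliberately
# non-collinear -- black is rich in the water and amide/caffeine bands,
# green in the catechin-related C-H bands, red has its own profile -- so no
# tea type is a mixture of the other two, while every multiplier stays close
# enough to 1 that the baseline offsets keep mean absorbance ordered
# black > red > green across the grid. The 1950 nm water band carries the
# largest red > green contrast.
_CLASS_BAND_MULTIPLIERS = {
    #         1220  1330  1400  1440  1670  1740  1885  1950  2150  2170  2280  2350
    "black": [1.30, 1.25, 1.35, 1.45, 1.20, 1.25, 1.30, 1.50, 1.40, 1.40, 1.25, 1.30],
    "red":   [1.15, 0.95, 1.05, 1.10, 0.95, 1.00, 1.35, 1.17, 1.05, 0.95, 1.10, 1.20],
    "green": [0.80, 0.90, 0.75, 0.70, 1.00, 0.95, 0.70, 0.67, 0.75, 0.85, 1.00, 0.90],
}
_BASELINE = {"black": 0.70, "red": 0.60, "green": 0.52}
# Fermentation state shifts band positions slightly between tea types; the
# per-band shift patterns (nm) contribute class contrast that survives
# derivative pretreatments and, like the amplitude patterns, are
# non-collinear across the three types.
_CLASS_BAND_SHIFT_NM = {
    #        1220 1330 1400 1440 1670 1740 1885 1950 2150 2170 2280 2350
    "black": [3.0, 2.0, 4.0, 5.0, 2.0, 2.0, 3.0, 5.0, 4.0, 4.0, 2.0, 3.0],
    "red":   [1.0, -4.0, 2.0, 2.0, -5.0, -4.0, 7.0, 2.0, -4.0, -1.0, 6.0, 7.0],
    "green": [-3.0, -2.0, -4.0, -5.0, -2.0, -1.0, -3.0, -5.0, -3.0, -4.0, -2.0, -2.0],
}


def default_band_amplitudes() -> dict[str, np.ndarray]:
    """Per-class amplitudes of the shared absorption bands."""
    return {cls: BAND_BASE_AMPLITUDES * np.asarray(mult)
            for cls, mult in _CLASS_BAND_MULTIPLIERS.items()}


@dataclass
class GeneratorConfig:
    """Settings of the synthetic library generator.

    Attributes
    ----------
    seed : int
        Master seed; the whole library is a deterministic function of it.
    n_black, n_green, n_red : int
        Pure-tea sample counts per class.
    n_total : int
        Library size including blends.
    noise_sd : float
        White measurement noise SD in absorbance units.
    scatter_offset_sd, scatter_slope_sd : float
        Additive offset / multiplicative factor SDs of per-sample scatter.
    amplitude_jitter : float
        Relative per-sample SD of the class band amplitudes (brand-to-brand
        variability of commercial teas of the same type).
    class_band_amplitudes : dict or None
        Override of the per-class band amplitude vectors.
    metal_signatures : dict
        Metal -> ((wavelength pair), amplitude per concentration unit).
    """

    seed: int = 0
    n_black: int = 7
    n_green: int = 11
    n_red: int = 8
    n_total: int = 322
    noise_sd: float = 0.001
    scatter_offset_sd: float = 0.01
    scatter_slope_sd: float = 0.005
    amplitude_jitter: float = 0.005
    baseline: dict = field(default_factory=lambda: dict(_BASELINE))
    class_band_shifts: dict = field(default_factory=lambda: dict(_CLASS_BAND_SHIFT_NM))
    class_band_amplitudes: dict | None = None
    metal_signatures: dict = field(default_factory=lambda: dict(METAL_SIGNATURES))
    grid: WavelengthGrid = field(default_factory=lambda: DEFAULT_GRID)

    def __post_init__(self) -> None:
        for name in ("n_black", "n_green", "n_red"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.scatter_offset_sd < 0 or self.scatter_slope_sd < 0:
            raise ValueError("scatter SDs must be nonnegative")

    @property
    def n_pure(self) -> int:
        return self.n_black + self.n_green + self.n_red

    def band_amplitudes(self) -> dict[str, np.ndarray]:
        if self.class_band_amplitudes is not None:
            return {c: np.asarray(a, dtype=float)
                    for c, a in self.class_band_amplitudes.items()}
        return default_band_amplitudes()


def _gaussian(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def _draw_concentration(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Nonnegative draw with the exact target mean and SD.

    Moment-matched gamma: shape (mean/sd)^2, scale sd^2/mean. Degenerates to
    the constant mean when sd == 0 and to exactly 0 when mean == 0; several
    trace metals have mean within 1-3 SD of zero, where a zero-truncated
    normal would bias the mean upward.
    """
    if mean <= 0.0:
        return 0.0
    if sd <= 0.0:
        return mean
    shape = (mean / sd) ** 2
    return float(rng.gamma(shape, sd * sd / mean))


def _metal_signal(wl: np.ndarray, metals: dict[str, float],
                  signatures: dict) -> np.ndarray:
    signal = np.zeros_like(wl)
    for m, (centers, amp) in signatures.items():
        c = metals.get(m, 0.0)
        if c == 0.0:
            continue
        for ctr in centers:
            signal += c * amp * _gaussian(wl, ctr, SIGNATURE_SIGMA_NM)
    return signal


def generate_pure_samples(config: GeneratorConfig) -> SampleTable:
    """Generate the pure black/green/red tea endmembers."""
    rng = np.random.default_rng([config.seed, 0])
    wl = config.grid.wavelengths
    amps = config.band_amplitudes()
    rows, spectra = [], []
    counts = {"black": config.n_black, "green": config.n_green, "red": config.n_red}
    for cls in TEA_TYPES:
        stats = PURE_TEA_METAL_STATS[cls]
        for i in range(counts[cls]):
            metals = {m: _draw_concentration(rng, *stats[m]) for m in METALS}
            jitter = 1.0 + config.amplitude_jitter * rng.standard_normal(len(BAND_CENTERS))
            shifts = np.broadcast_to(
                np.asarray(config.class_band_shifts.get(cls, 0.0), dtype=float),
                BAND_CENTERS.shape,
            )
            signal = np.full_like(wl, config.baseline[cls])
            for a, j, ctr, sh, sig in zip(amps[cls], jitter, BAND_CENTERS, shifts,
                                          BAND_SIGMAS):
                signal += a * j * _gaussian(wl, ctr + sh, sig)
            signal += _metal_signal(wl, metals, config.metal_signatures)
            slope = 1.0 + config.scatter_slope_sd * rng.standard_normal()
            offset = config.scatter_offset_sd * rng.standard_normal()
            noise = config.noise_sd * rng.standard_normal(wl.size)
            spectra.append(slope * signal + offset + noise)
            row = {"id": f"{cls}_{i + 1:02d}", "class": cls}
            for t in TEA_TYPES:
                row[f"fraction_{t}"] = 1.0 if t == cls else 0.0
            for m in METALS:
                row[METAL_COLUMNS[m]] = metals[m]
            rows.append(row)
    table = SampleTable(pd.DataFrame(rows), np.array(spectra), wl)
    table.validate()
    return table


def blend_chemistry(fractions: dict[str, float],
                    pure_metals: dict[str, dict[str, float]]) -> dict[str, float]:
    """Mixture-weighted metal contents of a blend.

    Each concentration is the exact convex combination
    ``sum_t fractions[t] * pure_metals[t][metal]`` in the source units.
    """
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {total}")
    for t, f in fractions.items():
        if f > 0 and t not in pure_metals:
            raise ValueError(f"missing metal map for constituent {t!r}")
    out: dict[str, float] = {}
    metals = next(iter(pure_metals.values())).keys()
    for m in metals:
        out[m] = sum(f * pure_metals[t][m] for t, f in fractions.items() if f > 0)
    return out


_BLEND_PAIRS = (("black", "green"), ("black", "red"), ("green", "red"))


def generate_blends(pures: SampleTable, config: GeneratorConfig) -> SampleTable:
    """Generate the binary blends completing the library to ``n_total``.

    Each blend picks one of the three tea-type pairs, a dominant side, a
    dominant fraction from {0.50, 0.51, ..., 0.99} and one parent sample per
    constituent; the blend spectrum is the convex combination of the parent
    spectra plus fresh measurement noise, and its metal contents follow
    :func:`blend_chemistry` exactly.
    """
    n_blends = config.n_total - len(pures)
    if n_blends < 0:
        raise ValueError("n_total is smaller than the number of pure samples")
    rng = np.random.default_rng([config.seed, 1])
    wl = pures.wavelengths
    by_class = {cls: np.flatnonzero(pures.classes == cls) for cls in TEA_TYPES}
    for cls, idx in by_class.items():
        if idx.size == 0:
            raise ValueError(f"no pure samples of class {cls!r} to blend")
    rows, spectra = [], []
    for i in range(n_blends):
        pair = _BLEND_PAIRS[rng.integers(len(_BLEND_PAIRS))]
        if rng.integers(2):
            pair = pair[::-1]
        dom, sub = pair
        f = 0.50 + 0.01 * float(rng.integers(50))  # {0.50 ... 0.99}
        ia = rng.integers(by_class[dom].size)
        ib = rng.integers(by_class[sub].size)
        a = pures.take([by_class[dom][ia]])
        b = pures.take([by_class[sub][ib]])
        spec = f * a.spectra[0] + (1.0 - f) * b.spectra[0]
        spec = spec + config.noise_sd * rng.standard_normal(wl.size)
        metals = blend_chemistry(
            {dom: f, sub: 1.0 - f},
            {dom: {m: a.metal(m)[0] for m in METALS},
             sub: {m: b.metal(m)[0] for m in METALS}},
        )
        row = {"id": f"blend_{i + 1:04d}", "class": "blend"}
        for t in TEA_TYPES:
            row[f"fraction_{t}"] = f if t == dom else (1.0 - f if t == sub else 0.0)
        for m in METALS:
            row[METAL_COLUMNS[m]] = metals[m]
        rows.append(row)
        spectra.append(spec)
    table = SampleTable(pd.DataFrame(rows), np.array(spectra), wl)
    table.validate()
    return table


def generate_library(config: GeneratorConfig | None = None, **kwargs) -> SampleTable:
    """Pure samples plus blends: the full synthetic library (default 322)."""
    if config is None:
        config = GeneratorConfig(**kwargs)
    elif kwargs:
        config = replace(config, **kwargs)
    pures = generate_pure_samples(config)
    blends = generate_blends(pures, config)
    table = SampleTable.concat([pures, blends])
    table.validate()
    return table


def write_jcamp(path, wavelengths: np.ndarray, values: np.ndarray,
                title: str = "spectrum") -> None:
    """Minimal JCAMP-DX (XYPOINTS) export of a single spectrum."""
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NEAR INFRARED SPECTRUM",
        "##XUNITS=NANOMETERS",
        "##YUNITS=ABSORBANCE",
        f"##FIRSTX={wavelengths[0]:.1f}",
        f"##LASTX={wavelengths[-1]:.1f}",
        f"##NPOINTS={len(wavelengths)}",
        "##XYPOINTS=(XY..XY)",
    ]
    lines += [f"{w:.1f}, {v:.6f}" for w, v in zip(wavelengths, values)]
    lines.append("##END=")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
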