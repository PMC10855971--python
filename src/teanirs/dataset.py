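"""Sample tables: spectra plus blend composition and metal reference values.

A :class:`SampleTable` couples a matrix of log(1/R) spectra on a common
wavelength grid with per-sample metadata: an id, a class label (a pure tea
type or ``blend``), the binary-blend fractions of the three tea types, and
the five reference heavy-metal concentrations (Al in g/kg; Pb, As, Hg, Cu
in mg/kg).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "METALS",
    "METAL_COLUMNS",
    "TEA_TYPES",
    "SampleTable",
    "split_sets",
]

#: Analyte -> reporting unit.
METALS = {"Al": "g/kg", "Pb": "mg/kg", "As": "mg/kg", "Hg": "mg/kg", "Cu": "mg/kg"}

#: CSV column name per analyte.
METAL_COLUMNS = {m: f"{m}_{u.replace('/', '_')}" for m, u in METALS.items()}

TEA_TYPES = ("black", "green", "red")

_FRACTION_COLUMNS = [f"fraction_{t}" for t in TEA_TYPES]


class SampleTable:
    """An ordered collection of samples sharing one wavelength grid.

    Parameters
    ----------
    meta : pandas.DataFrame
        One row per sample with columns ``id``, ``class``,
        ``fraction_black/green/red`` and the five metal columns
        (``Al_g_kg``, ``Pb_mg_kg``, ...).
    spectra : ndarray, shape (n_samples, n_wavelengths)
        log(1/R) absorbance values.
    wavelengths : ndarray, shape (n_wavelengths,)
        Wavelengths in nm, strictly increasing.
    role : {"calibration", "validation", "unsplit"}
    """

    def __init__(
        self,
        meta: pd.DataFrame,
        spectra: np.ndarray,
        wavelengths: np.ndarray,
        role: str = "unsplit",
    ) -> None:
        spectra = np.asarray(spectra, dtype=float)
        wavelengths = np.asarray(wavelengths, dtype=float)
        if spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D matrix")
        if spectra.shape[0] != len(meta):
            raise ValueError("meta and spectra disagree on the sample count")
        if spectra.shape[1] != wavelengths.size:
            raise ValueError("spectra and wavelengths disagree on the grid size")
        if role not in ("calibration", "validation", "unsplit"):
            raise ValueError(f"unknown role {role!r}")
        self.meta = meta.reset_index(drop=True)
        self.spectra = spectra
        self.wavelengths = wavelengths
        self.role = role

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.meta)

    @property
    def ids(self) -> np.ndarray:
        return self.meta["id"].to_numpy()

    @property
    def classes(self) -> np.ndarray:
        return self.meta["class"].to_numpy()

    @property
    def fractions(self) -> np.ndarray:
        """(n, 3) blend fractions in the order black, green, red."""
        return self.meta[_FRACTION_COLUMNS].to_numpy(dtype=float)

    def metal(self, analyte: str) -> np.ndarray:
        return self.meta[METAL_COLUMNS[analyte]].to_numpy(dtype=float)

    @property
    def metals_frame(self) -> pd.DataFrame:
        """Metal concentrations as a (n, 5) DataFrame keyed by analyte."""
        out = self.meta[[METAL_COLUMNS[m] for m in METALS]].copy()
        out.columns = list(METALS)
        return out

    def dominant(self) -> tuple[np.ndarray, np.ndarray]:
        """Dominant tea type and its fraction per sample.

        A 50/50 blend is attributed to the first nonzero type in the fixed
        order black, green, red (deterministic tie-break).
        """
        fr = self.fractions
        idx = np.argmax(fr, axis=1)  # argmax takes the first maximum
        types = np.asarray(TEA_TYPES)[idx]
        return types, fr[np.arange(len(fr)), idx]

    # -- subsetting --------------------------------------------------------

    def take(self, indices: Sequence[int] | np.ndarray, role: str | None = None) -> "SampleTable":
        indices = np.asarray(indices, dtype=int)
        return SampleTable(
            self.meta.iloc[indices],
            self.spectra[indices],
            self.wavelengths,
            role=role or self.role,
        )

    def drop_ids(self, ids: Iterable) -> "SampleTable":
        bad = set(ids)
        keep = np.array([i for i, s in enumerate(self.ids) if s not in bad])
        return self.take(keep)

    def with_spectra(self, spectra: np.ndarray, wavelengths: np.ndarray) -> "SampleTable":
        """Same metadata, new (e.g. pretreated) spectra on a new grid."""
        return SampleTable(self.meta, spectra, wavelengths, role=self.role)

    @staticmethod
    def concat(tables: Sequence["SampleTable"], role: str = "unsplit") -> "SampleTable":
        if not tables:
            raise ValueError("nothing to concatenate")
        wl = tables[0].wavelengths
        for t in tables[1:]:
            if not np.array_equal(t.wavelengths, wl):
                raise ValueError("tables are on different wavelength grids")
        meta = pd.concat([t.meta for t in tables], ignore_index=True)
        spectra = np.vstack([t.spectra for t in tables])
        return SampleTable(meta, spectra, wl, role=role)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        ids = self.ids
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids are not unique")
        fr = self.fractions
        if np.any(np.abs(fr.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("blend fractions must sum to 1")
        if np.any((fr > 0).sum(axis=1) > 2):
            raise ValueError("only binary blends are allowed")
        if np.any(fr.max(axis=1) < 0.5 - 1e-12):
            raise ValueError("dominant fraction must be >= 0.50")
        metals = self.metals_frame.to_numpy()
        if np.any(metals < 0):
            raise ValueError("metal concentrations must be nonnegative")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra contain non-finite values")

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Wide one-row-per-sample frame with wl_<nm> spectral columns."""
        spec_cols = [f"wl_{int(round(w))}" for w in self.wavelengths]
        spec = pd.DataFrame(self.spectra, columns=spec_cols)
        return pd.concat([self.meta.reset_index(drop=True), spec], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, role: str = "unsplit") -> "SampleTable":
        spec_cols = [c for c in frame.columns if c.startswith("wl_")]
        if not spec_cols:
            raise ValueError("no wl_<nm> spectral columns found")
        wavelengths = np.array([float(c[3:]) for c in spec_cols])
        order = np.argsort(wavelengths)
        spec_cols = [spec_cols[i] for i in order]
        wavelengths = wavelengths[order]
        meta_cols = [c for c in frame.columns if not c.startswith("wl_")]
        return cls(
            frame[meta_cols].copy(),
            frame[spec_cols].to_numpy(dtype=float),
            wavelengths,
            role=role,
        )

    @classmethod
    def from_csv(cls, path, role: str = "unsplit") -> "SampleTable":
        return cls.from_frame(pd.read_csv(path), role=role)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<SampleTable n={len(self)} grid={self.wavelengths[0]:.0f}-"
            f"{self.wavelengths[-1]:.0f} nm x{len(self.wavelengths)} role={self.role}>"
        )


def split_sets(
    table: SampleTable, cal_fraction: float = 0.8, seed: int = 0
) -> tuple[SampleTable, SampleTable]:
    """Random calibration/validation partition.

    The calibration set receives ``floor(cal_fraction * n)`` samples and the
    validation set the remainder, so 322 samples at 0.8 give 257/65. The two
    sets are disjoint and exhaustive; the same seed reproduces the same split.
    """
    if len(table) == 0:
        raise ValueError("cannot split an empty table")
    if not 0.0 < cal_fraction < 1.0:
        raise ValueError("cal_fraction must lie strictly between 0 and 1")
    n = len(table)
    n_cal = int(np.floor(cal_fraction * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cal = table.take(np.sort(perm[:n_cal]), role="calibration")
    val = table.take(np.sort(perm[n_cal:]), role="validation")
    return cal, val
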