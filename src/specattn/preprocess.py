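"""Hyperspectral preprocessing: reflectance calibration, grid-ROI mean
spectra, and standard normal variate (SNV) normalization.

Also hosts the core data types shared across the package: wavelength grids,
hypercubes, spectra and labelled spectra datasets, with CSV / NPZ round-trip
I/O for the tabular forms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "WavelengthGrid",
    "HyperCube",
    "Spectrum",
    "SpectraDataset",
    "DegenerateSpectrumError",
    "correct_reflectance",
    "grid_roi_mean_spectra",
    "snv",
    "snv_dataset",
]

CUBE_KINDS = ("raw", "white", "dark", "reflectance")


class DegenerateSpectrumError(ValueError):
    """Raised when SNV is asked to normalize a constant (zero-variance) spectrum."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band-center wavelengths in nanometres."""

    wavelengths: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("a wavelength grid needs at least 2 bands")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __eq__(self, other) -> bool:
        return isinstance(other, WavelengthGrid) and np.array_equal(
            self.wavelengths, other.wavelengths)

    def __hash__(self):
        return hash((self.wavelengths.size, float(self.wavelengths[0]),
                     float(self.wavelengths[-1])))


@dataclass
class HyperCube:
    """rows x cols x bands raster with its wavelength grid."""

    data: np.ndarray
    grid: WavelengthGrid
    kind: str = "raw"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube must be 3-D rows x cols x bands (got ndim {self.data.ndim})")
        if self.data.shape[2] != len(self.grid):
            raise ValueError(
                f"cube has {self.data.shape[2]} bands but grid has {len(self.grid)}")
        if self.kind not in CUBE_KINDS:
            raise ValueError(f"kind must be one of {CUBE_KINDS}")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class Spectrum:
    """A single band-indexed reflectance (or SNV-unit) vector."""

    values: np.ndarray
    grid: WavelengthGrid
    label: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != len(self.grid):
            raise ValueError(
                f"spectrum has {self.values.size} values but grid has {len(self.grid)} bands")


@dataclass
class SpectraDataset:
    """Labelled collection of spectra sharing one wavelength grid.

    Stored internally as a dense ``(n_samples, n_bands)`` matrix ``X`` with an
    integer label vector ``y``; :attr:`spectra` iterates Spectrum views.
    """

    X: np.ndarray
    y: np.ndarray
    grid: WavelengthGrid
    class_names: list[str] = field(default_factory=list)
    lens: str = "SWIR"
    provenance: str = ""

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.grid):
            raise ValueError("X must be (n_samples, n_bands) matching the grid")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y must be one label per row of X")
        if not self.class_names:
            n = int(self.y.max()) + 1 if self.y.size else 0
            self.class_names = [f"class{i}" for i in range(n)]
        if self.y.size and (self.y.min() < 0 or self.y.max() >= len(self.class_names)):
            raise ValueError("labels must lie in [0, n_classes)")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def spectra(self) -> Iterator[Spectrum]:
        for i in range(len(self)):
            yield Spectrum(self.X[i], self.grid, int(self.y[i]))

    def subset(self, indices) -> "SpectraDataset":
        idx = np.asarray(indices)
        return SpectraDataset(self.X[idx].copy(), self.y[idx].copy(), self.grid,
                              list(self.class_names), self.lens, self.provenance)

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path) -> None:
        cols = [f"{w:.6g}" for w in self.grid.wavelengths]
        df = pd.DataFrame(self.X, columns=cols)
        df["label"] = self.y
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, class_names: Sequence[str] | None = None,
                 lens: str = "SWIR") -> "SpectraDataset":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError(f"{path}: expected a 'label' column")
        y = df.pop("label").to_numpy(dtype=int)
        wl = np.array([float(c) for c in df.columns])
        return cls(df.to_numpy(dtype=float), y, WavelengthGrid(wl),
                   list(class_names) if class_names else [], lens, f"loaded from {path}")

    def to_npz(self, path) -> None:
        np.savez(path, X=self.X, y=self.y, wavelengths=self.grid.wavelengths,
                 class_names=np.array(self.class_names, dtype=object),
                 lens=np.array(self.lens), provenance=np.array(self.provenance))

    @classmethod
    def from_npz(cls, path) -> "SpectraDataset":
        with np.load(path, allow_pickle=True) as z:
            return cls(z["X"], z["y"], WavelengthGrid(z["wavelengths"]),
                       [str(c) for c in z["class_names"]], str(z["lens"]),
                       str(z["provenance"]))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def correct_reflectance(raw: HyperCube, white: HyperCube, dark: HyperCube,
                        max_bad_fraction: float = 0.01,
                        clip: bool = False) -> HyperCube:
    """Relative reflectance ``(raw - dark) / (white - dark)``, pixelwise.

    References may be full-frame (same shape as ``raw``) or per-column
    line-scan frames with a single row, broadcast down the scan axis.  Pixels
    where the white and dark references coincide are set to NaN, counted, and
    logged; if they exceed ``max_bad_fraction`` of the cube the call fails.
    Values outside [0, 1] are kept (and logged) unless ``clip=True``.
    """
    refs = {}
    for name, cube in (("white", white), ("dark", dark)):
        data = cube.data
        if data.shape != raw.data.shape:
            if data.shape == (1,) + raw.data.shape[1:]:      # line-scan reference
                data = np.broadcast_to(data, raw.data.shape)
            else:
                raise ValueError(
                    f"{name} reference shape {cube.data.shape} != raw {raw.data.shape} "
                    "(full-frame or single-row line-scan references supported)")
        if cube.grid != raw.grid:
            raise ValueError(f"{name} reference wavelength grid differs from raw")
        refs[name] = data
    white_d, dark_d = refs["white"], refs["dark"]
    denom = white_d - dark_d
    bad = denom == 0
    n_bad = int(bad.sum())
    if n_bad:
        frac = n_bad / denom.size
        log.warning("correct_reflectance: %d pixels (%.3g%%) with white == dark set to NaN",
                    n_bad, 100 * frac)
        if frac > max_bad_fraction:
            raise ValueError(
                f"{n_bad} pixels ({100 * frac:.2f}%) have white == dark, "
                f"exceeding the allowed {100 * max_bad_fraction:.2f}%")
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = np.where(bad, np.nan, (raw.data - dark_d) / np.where(bad, 1.0, denom))
    out_of_range = int(np.sum((refl < 0) | (refl > 1)))
    if out_of_range:
        log.info("correct_reflectance: %d reflectance values outside [0, 1]%s",
                 out_of_range, " (clipped)" if clip else " (kept)")
        if clip:
            refl = np.clip(refl, 0.0, 1.0)
    return HyperCube(refl, raw.grid, kind="reflectance")


def grid_roi_mean_spectra(cube: HyperCube, cell_rows: int, cell_cols: int,
                          labels_per_cell, class_names: Sequence[str] | None = None,
                          lens: str = "SWIR") -> SpectraDataset:
    """Tile the cube into ``cell_rows x cell_cols``-pixel ROIs and average.

    Cells are axis-aligned, non-overlapping, row-major, 0-based, half-open;
    only full cells within the cube extent are used.  Each cell yields one
    mean spectrum (NaN-ignoring); ``labels_per_cell`` supplies one class id
    per cell, row-major.
    """
    if cube.kind != "reflectance":
        raise ValueError(f"expected a reflectance cube, got kind={cube.kind!r}")
    if cell_rows < 1 or cell_cols < 1:
        raise ValueError("cell size must be >= 1 pixel in both directions")
    rows, cols, bands = cube.data.shape
    n_r, n_c = rows // cell_rows, cols // cell_cols
    if n_r < 1 or n_c < 1:
        raise ValueError(f"cell {cell_rows}x{cell_cols} does not fit in cube {rows}x{cols}")
    labels = np.asarray(labels_per_cell, dtype=int).reshape(-1)
    if labels.size != n_r * n_c:
        raise ValueError(f"expected {n_r * n_c} cell labels, got {labels.size}")
    trimmed = cube.data[:n_r * cell_rows, :n_c * cell_cols, :]
    blocks = trimmed.reshape(n_r, cell_rows, n_c, cell_cols, bands)
    all_nan = np.isnan(blocks).all(axis=(1, 3))
    if all_nan.any():
        r, c = np.argwhere(all_nan)[0][:2]
        raise ValueError(f"grid cell ({r}, {c}) is entirely NaN at some band; cannot average")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(blocks, axis=(1, 3))            # (n_r, n_c, bands)
    X = means.reshape(n_r * n_c, bands)
    return SpectraDataset(X, labels, cube.grid,
                          list(class_names) if class_names else [], lens,
                          f"grid ROI means, {n_r}x{n_c} cells of {cell_rows}x{cell_cols} px")


def snv(spectrum: Spectrum, ddof: int = 1) -> Spectrum:
    """Standard normal variate: centre and scale one spectrum to mean 0, SD 1.

    ``ddof=1`` (sample SD) by default; set ``ddof=0`` for the population
    convention.  A constant spectrum has no scale and raises
    :class:`DegenerateSpectrumError`.
    """
    v = spectrum.values
    if v.size < 2:
        raise ValueError("SNV needs at least 2 bands")
    sd = v.std(ddof=ddof)
    # relative guard: a numerically constant spectrum has no usable scale
    if sd < 1e-12 * max(1.0, float(np.abs(v).max())) or not np.isfinite(sd):
        label = "unlabelled" if spectrum.label is None else f"label {spectrum.label}"
        raise DegenerateSpectrumError(
            f"constant spectrum ({label}): standard deviation is zero, SNV undefined")
    return Spectrum((v - v.mean()) / sd, spectrum.grid, spectrum.label)


def snv_dataset(ds: SpectraDataset, ddof: int = 1) -> SpectraDataset:
    """Apply SNV independently to every sample (never across the dataset)."""
    out = np.empty_like(ds.X)
    for i in range(len(ds)):
        try:
            out[i] = snv(Spectrum(ds.X[i], ds.grid, int(ds.y[i])), ddof=ddof).values
        except DegenerateSpectrumError as e:
            raise DegenerateSpectrumError(f"sample {i}: {e}") from e
    return SpectraDataset(out, ds.y.copy(), ds.grid, list(ds.class_names), ds.lens,
                          ds.provenance + " | SNV")
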