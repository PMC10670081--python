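"""Synthetic labelled reflectance spectra and toy calibration hypercubes.

The generator emulates the structure of multi-species bulb reflectance data:
all classes share an overall waveform (a fixed set of Gaussian bumps) but
differ in peak/valley amplitudes, except for one "outlier" class built from
an independent peak set.  Samples add multiplicative scatter, a linear
baseline drift, and i.i.d. band noise — exactly the distortions SNV and the
attention network are meant to handle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import HyperCube, SpectraDataset, Spectrum, WavelengthGrid

__all__ = [
    "SyntheticConfig",
    "HypercubeBundle",
    "make_wavelength_grid",
    "class_template",
    "generate_dataset",
    "generate_hypercube",
    "vnir_config",
    "swir_config",
    "VNIR_RANGE_NM",
    "SWIR_RANGE_NM",
    "VNIR_BANDS",
    "SWIR_BANDS",
    "CLASS_NAMES",
]

# lens band ranges and counts
VNIR_RANGE_NM = (410.42, 990.10)
SWIR_RANGE_NM = (948.72, 2512.97)
VNIR_BANDS = 108
SWIR_BANDS = 288

# Eight classes; the outlier-shaped class (an unrelated genus) is placed last.
CLASS_NAMES = ["FTB", "FPB", "FUB", "FHB", "SongBei", "QingBei", "LuBei", "BSR"]

# Desk-scale per-class counts (full survey counts scaled down 10x), ordered as
# CLASS_NAMES.  Full-scale counts available via ``full_scale=True``.
_FULL_COUNTS = {
    "VNIR": [4041, 4344, 4497, 3919, 6355, 4556, 6423, 4696],
    "SWIR": [4105, 4317, 4399, 3887, 6235, 4271, 5643, 4571],
}

# shared waveform: (center, width, amplitude) as fractions of the band span
_SHARED_PEAK_FRACS = [
    (0.12, 0.045, 0.32),
    (0.28, 0.050, 0.50),
    (0.42, 0.040, 0.28),
    (0.55, 0.055, 0.46),
    (0.68, 0.042, 0.36),
    (0.82, 0.050, 0.42),
    (0.93, 0.038, 0.26),
]
# independent peak set for the outlier class
_OUTLIER_PEAK_FRACS = [
    (0.20, 0.080, 0.62),
    (0.50, 0.060, 0.20),
    (0.76, 0.090, 0.55),
]


def _default_offsets(n_classes: int, n_peaks: int,
                     scale: float = 0.05) -> list[list[float]]:
    """Per-class amplitude offsets with uniform pairwise separation.

    For up to 8 classes, rows of a Hadamard matrix (+-1 entries, equal
    pairwise Hamming distance) keep every class pair equally distinguishable;
    larger class counts fall back to fixed pseudo-random offsets.
    """
    if n_classes <= 8:
        h = np.array([[1]])
        while h.shape[0] < 8:
            h = np.block([[h, h], [h, -h]])
        pattern = h[:n_classes, 1:]                    # drop the constant column
        cols = [pattern[:, k % 7] for k in range(n_peaks)]
        return (scale * np.column_stack(cols)).tolist()
    rng = np.random.default_rng(20231109)
    return [list(rng.uniform(-scale, scale, size=n_peaks))
            for _ in range(n_classes)]


def make_wavelength_grid(start_nm: float, end_nm: float, n_bands: int) -> WavelengthGrid:
    """Evenly spaced band centres from ``start_nm`` to ``end_nm`` inclusive."""
    if n_bands < 2:
        raise ValueError(f"need at least 2 bands, got {n_bands}")
    if end_nm <= start_nm:
        raise ValueError(f"end wavelength {end_nm} must exceed start {start_nm}")
    return WavelengthGrid(np.linspace(start_nm, end_nm, n_bands))


@dataclass
class SyntheticConfig:
    n_classes: int = 8
    bands: int = SWIR_BANDS
    wavelength_start_nm: float = SWIR_RANGE_NM[0]
    wavelength_end_nm: float = SWIR_RANGE_NM[1]
    n_per_class: list[int] = field(default_factory=lambda: [100] * 8)
    shared_peaks: list[tuple[float, float, float]] = field(default_factory=list)
    class_amplitude_offsets: list[list[float]] = field(default_factory=list)
    outlier_class_index: int | None = 7
    outlier_peaks: list[tuple[float, float, float]] = field(default_factory=list)
    multiplicative_scatter_sd: float = 0.05
    additive_noise_sd: float = 0.01
    baseline_slope_sd: float = 2e-5
    seed: int = 0
    class_names: list[str] = field(default_factory=list)
    lens: str = "SWIR"

    def __post_init__(self):
        if self.bands < 2:
            raise ValueError("bands must be >= 2")
        if self.wavelength_end_nm <= self.wavelength_start_nm:
            raise ValueError("wavelength_end_nm must exceed wavelength_start_nm")
        if len(self.n_per_class) != self.n_classes:
            raise ValueError("n_per_class must have one count per class")
        if any(n < 1 for n in self.n_per_class):
            raise ValueError("all per-class counts must be >= 1")
        if self.multiplicative_scatter_sd < 0 or self.additive_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        span = self.wavelength_end_nm - self.wavelength_start_nm
        if not self.shared_peaks:
            self.shared_peaks = [(self.wavelength_start_nm + f * span, w * span, a)
                                 for f, w, a in _SHARED_PEAK_FRACS]
        if any(w <= 0 for _, w, _ in self.shared_peaks):
            raise ValueError("all peak widths must be > 0")
        if not self.class_amplitude_offsets:
            self.class_amplitude_offsets = _default_offsets(
                self.n_classes, len(self.shared_peaks))
        if len(self.class_amplitude_offsets) != self.n_classes:
            raise ValueError("class_amplitude_offsets must have one row per class")
        if not self.outlier_peaks:
            self.outlier_peaks = [(self.wavelength_start_nm + f * span, w * span, a)
                                  for f, w, a in _OUTLIER_PEAK_FRACS]
        if self.outlier_class_index is not None and not (
                0 <= self.outlier_class_index < self.n_classes):
            raise ValueError("outlier_class_index out of range")
        if not self.class_names:
            if self.n_classes == 8:
                self.class_names = list(CLASS_NAMES)
            else:
                self.class_names = [f"class{i}" for i in range(self.n_classes)]

    @property
    def grid(self) -> WavelengthGrid:
        return make_wavelength_grid(self.wavelength_start_nm, self.wavelength_end_nm,
                                    self.bands)


def _lens_config(lens: str, per_class: int | None, full_scale: bool,
                 seed: int, **overrides) -> SyntheticConfig:
    lens = lens.upper()
    if lens == "VNIR":
        bands, (lo, hi) = VNIR_BANDS, VNIR_RANGE_NM
    elif lens == "SWIR":
        bands, (lo, hi) = SWIR_BANDS, SWIR_RANGE_NM
    else:
        raise ValueError(f"lens must be 'vnir' or 'swir', got {lens!r}")
    if per_class is not None:
        counts = [int(per_class)] * 8
    elif full_scale:
        counts = list(_FULL_COUNTS[lens])
    else:
        counts = [max(1, n // 10) for n in _FULL_COUNTS[lens]]
    return SyntheticConfig(n_classes=8, bands=bands, wavelength_start_nm=lo,
                           wavelength_end_nm=hi, n_per_class=counts, seed=seed,
                           lens=lens, **overrides)


def vnir_config(per_class: int | None = None, full_scale: bool = False,
                seed: int = 0, **overrides) -> SyntheticConfig:
    """Default 8-class VNIR configuration (108 bands)."""
    return _lens_config("VNIR", per_class, full_scale, seed, **overrides)


def swir_config(per_class: int | None = None, full_scale: bool = False,
                seed: int = 0, **overrides) -> SyntheticConfig:
    """Default 8-class SWIR configuration (288 bands)."""
    return _lens_config("SWIR", per_class, full_scale, seed, **overrides)


def _gauss_sum(wl: np.ndarray, peaks, amps=None) -> np.ndarray:
    out = np.zeros_like(wl)
    for k, (center, width, amp) in enumerate(peaks):
        a = amp if amps is None else amps[k]
        out += a * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return out


def class_template(class_idx: int, grid: WavelengthGrid,
                   config: SyntheticConfig) -> Spectrum:
    """Noise-free class-mean curve: a Gaussian-bump mixture clipped to [0, 1]."""
    if not 0 <= class_idx < config.n_classes:
        raise IndexError(f"class index {class_idx} out of range [0, {config.n_classes})")
    wl = grid.wavelengths
    if class_idx == config.outlier_class_index:
        curve = _gauss_sum(wl, config.outlier_peaks)
    else:
        offsets = config.class_amplitude_offsets[class_idx]
        amps = [a + offsets[k] for k, (_, _, a) in enumerate(config.shared_peaks)]
        curve = _gauss_sum(wl, config.shared_peaks, amps)
    return Spectrum(np.clip(curve, 0.0, 1.0), grid, class_idx)


def _sample_rng(seed: int, class_idx: int, sample_idx: int) -> np.random.Generator:
    # counter-based stream split: per-class counts can change without
    # reshuffling other classes
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(class_idx, sample_idx)))


def generate_dataset(config: SyntheticConfig) -> SpectraDataset:
    """Draw ``sum(n_per_class)`` labelled spectra, reproducible from the seed.

    Each sample is ``m * template(class) + baseline + eps`` with
    ``m ~ 1 + N(0, multiplicative_scatter_sd)``, a random linear baseline
    drift, and i.i.d. band noise ``eps ~ N(0, additive_noise_sd)``.
    """
    grid = config.grid
    wl = grid.wavelengths
    wl_centered = wl - wl.mean()
    total = sum(config.n_per_class)
    X = np.empty((total, config.bands))
    y = np.empty(total, dtype=int)
    row = 0
    for c in range(config.n_classes):
        template = class_template(c, grid, config).values
        for i in range(config.n_per_class[c]):
            rng = _sample_rng(config.seed, c, i)
            m = 1.0 + rng.normal(0.0, config.multiplicative_scatter_sd)
            slope = rng.normal(0.0, config.baseline_slope_sd)
            eps = rng.normal(0.0, config.additive_noise_sd, size=config.bands)
            X[row] = m * template + slope * wl_centered + eps
            y[row] = c
            row += 1
    return SpectraDataset(X, y, grid, list(config.class_names), config.lens,
                          f"synthetic (seed={config.seed})")


@dataclass
class HypercubeBundle:
    """Raw/white/dark calibration trio plus the planted truth."""

    raw: HyperCube
    white: HyperCube
    dark: HyperCube
    roi_labels: np.ndarray              # (cell_rows, cell_cols) class ids
    reflectance: HyperCube              # planted ground truth
    cell_px: tuple[int, int]            # pixel extent of each labelled cell


def generate_hypercube(config: SyntheticConfig, n_cell_rows: int | None = None,
                       n_cell_cols: int = 4, cell_px: int = 4) -> HypercubeBundle:
    """Build a small raw/white/dark cube trio with a labelled ROI grid.

    Reflectance in each grid cell is the cell class's template; the raw cube
    is ``dark + reflectance * (white - dark)`` pixelwise, so reflectance
    correction recovers the planted cube exactly (up to float error).
    """
    if n_cell_rows is None:
        n_cell_rows = config.n_classes
    rows, cols = n_cell_rows * cell_px, n_cell_cols * cell_px
    if rows > 64 or cols > 64:
        raise ValueError(f"cube extent {rows}x{cols} exceeds the 64x64 toy limit")
    grid = config.grid
    labels = (np.arange(n_cell_rows * n_cell_cols) % config.n_classes).reshape(
        n_cell_rows, n_cell_cols)
    templates = np.stack([class_template(c, grid, config).values
                          for c in range(config.n_classes)])
    refl = np.empty((rows, cols, config.bands))
    for r in range(n_cell_rows):
        for c in range(n_cell_cols):
            refl[r * cell_px:(r + 1) * cell_px, c * cell_px:(c + 1) * cell_px, :] = \
                templates[labels[r, c]]
    # smooth, band-dependent reference frames (line-scan style illumination)
    band_profile = 0.8 + 0.2 * np.linspace(0.0, 1.0, config.bands)
    white = np.broadcast_to(1000.0 * band_profile, refl.shape).copy()
    dark = np.broadcast_to(50.0 + 10.0 * band_profile[::-1], refl.shape).copy()
    raw = dark + refl * (white - dark)
    return HypercubeBundle(
        raw=HyperCube(raw, grid, kind="raw"),
        white=HyperCube(white, grid, kind="white"),
        dark=HyperCube(dark, grid, kind="dark"),
        roi_labels=labels,
        reflectance=HyperCube(refl, grid, kind="reflectance"),
        cell_px=(cell_px, cell_px),
    )
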