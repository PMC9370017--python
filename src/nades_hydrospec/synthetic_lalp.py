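"""Synthetic Levulinic Acid / L-Proline (LALP) NADES spectra.

Emulates a standard-addition water-quantification study on a 2:1 (mol/mol)
Levulinic Acid : L-Proline natural deep eutectic solvent: 5 independently
prepared replicate sets, 9 added-water levels (0 to ~28.6 %w/w added), and
9 replicate spectra per sample (3 deposits/repositionings x 3 scans), for
four instrument profiles (ATR-IR, benchtop NIR, handheld NIR, macro-Raman).

The clean signal model is a two-endmember mixture: at total water mass
fraction ``f`` the spectrum is ``f * S_water + (1 - f) * S_NADES``, each
endmember a sum of Gaussian/Lorentzian bands on the instrument grid. Bands
may shift linearly and broaden with water fraction (observed for several
Raman bands of Levulinic Acid), making water contributions rise while
constituent contributions fall — the anticorrelation that the regression
ultimately exploits. Measurement effects layered on top: per-set intrinsic
water (Karl Fischer mean 1.07 +/- 0.08 %w/w), per-sample weighing error,
per-deposit multiplicative gain and baseline realization, per-scan additive
noise, and a hard absorbance ceiling for NIR detectors.

Metadata labels always carry the NOMINAL added %w/w (standard-addition
convention); the noisy realized composition only drives the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre

from .spectra_io import SpectralDataset, SpectrumMeta

_LN16 = 4.0 * np.log(2.0)

SPECIES = ("water", "levulinic_acid", "l_proline")


@dataclass(frozen=True)
class Band:
    """One vibrational band: peak position, FWHM, relative peak amplitude.

    ``shift_per_fraction`` displaces the center linearly with water mass
    fraction (cm^-1 per unit fraction); ``broaden_per_fraction`` scales the
    FWHM by ``1 + broaden_per_fraction * f``.
    """

    center: float
    width: float
    amplitude: float
    species: str
    shape: str = "gaussian"
    shift_per_fraction: float = 0.0
    broaden_per_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"band width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ValueError(f"band amplitude must be >= 0, got {self.amplitude}")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")

    def evaluate(self, grid: np.ndarray, fraction: float = 0.0) -> np.ndarray:
        """Band profile on ``grid`` at water mass fraction ``fraction``."""
        center = self.center + self.shift_per_fraction * fraction
        width = self.width * (1.0 + self.broaden_per_fraction * fraction)
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-_LN16 * ((grid - center) / width) ** 2)
        half = width / 2.0
        return self.amplitude * half**2 / ((grid - center) ** 2 + half**2)


@dataclass(frozen=True)
class SampleDesign:
    """The standard-addition design: sets x levels x replicates.

    ``added_mass_ratios`` are grams of water added per 100 g NADES; the
    nominal label is 100*r/(100+r) %w/w. The default nine ratios reproduce
    the printed level series C1 (0%) .. C9 (~28.57%) to printed precision.
    """

    n_sets: int = 5
    added_mass_ratios: tuple[float, ...] = (0.0, 1.0, 2.5, 5.0, 7.5, 10.0, 20.0, 30.0, 40.0)
    n_deposits: int = 3
    n_scans_per_deposit: int = 3
    intrinsic_water_mean: float = 1.07
    intrinsic_water_sd: float = 0.08
    weighing_error_sd: float = 0.002

    def __post_init__(self) -> None:
        if self.n_sets < 1 or self.n_deposits < 1 or self.n_scans_per_deposit < 1:
            raise ValueError("set/deposit/scan counts must be >= 1")
        if any(r < 0 for r in self.added_mass_ratios):
            raise ValueError("added mass ratios must be >= 0")
        if self.intrinsic_water_sd < 0 or self.weighing_error_sd < 0:
            raise ValueError("standard deviations must be >= 0")

    @property
    def n_levels(self) -> int:
        return len(self.added_mass_ratios)

    @property
    def n_spectra(self) -> int:
        return self.n_sets * self.n_levels * self.n_deposits * self.n_scans_per_deposit

    def set_ids(self) -> list[str]:
        return [f"SET_{i:02d}" for i in range(1, self.n_sets + 1)]

    def level_ids(self) -> list[str]:
        return [f"C{i}" for i in range(1, self.n_levels + 1)]


@dataclass(frozen=True)
class ModalityProfile:
    """Instrument model: grid, band library, baseline/noise/saturation.

    ``additive_noise_sd`` is in absolute intensity units (absorbance or
    normalized counts); band amplitudes are scaled so the clean signal is of
    order 1. ``deposit_gain_sd`` is the log-sd of the per-deposit
    multiplicative gain; ``baseline_scale`` the sd of random Legendre
    baseline coefficients; ``saturation_cap`` an absorbance ceiling or None.
    """

    name: str
    grid: np.ndarray
    bands: tuple[Band, ...]
    baseline_order: int = 1
    baseline_scale: float = 0.0
    baseline_kind: str = "legendre"
    additive_noise_sd: float = 0.001
    deposit_gain_sd: float = 0.002
    saturation_cap: float | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 1 or grid.size < 3 or not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be a 1-D strictly ascending axis with >= 3 points")
        object.__setattr__(self, "grid", grid)
        if self.baseline_order < 0:
            raise ValueError("baseline_order must be >= 0")
        if self.baseline_kind not in ("legendre", "fluorescence"):
            raise ValueError(f"unknown baseline_kind {self.baseline_kind!r}")

    def species_spectrum(self, species: tuple[str, ...], fraction: float = 0.0) -> np.ndarray:
        out = np.zeros_like(self.grid)
        for band in self.bands:
            if band.species in species:
                out += band.evaluate(self.grid, fraction)
        return out


def added_fraction_from_ratio(r: float) -> float:
    """Nominal added-water label (%w/w) for r grams of water per 100 g NADES."""
    if r < 0:
        raise ValueError(f"mass ratio must be >= 0, got {r}")
    return 100.0 * r / (100.0 + r)


def total_water_percent(added_percent: float, intrinsic_percent: float) -> float:
    """Total water %w/w given added %w/w and the NADES intrinsic water %w/w.

    The intrinsic water is a fraction of the NADES portion only, so its
    contribution is diluted as water is added:
    total = added + intrinsic * (1 - added/100).
    """
    return added_percent + intrinsic_percent * (1.0 - added_percent / 100.0)


def clean_mixture_spectrum(profile: ModalityProfile, total_water_fraction: float) -> np.ndarray:
    """Deterministic noise-free spectrum at total water mass fraction f.

    ``f * S_water + (1 - f) * S_NADES`` with band shifts/broadening evaluated
    at f. At f = 0 the water bands contribute exactly nothing.
    """
    f = float(total_water_fraction)
    if f < 0:
        raise ValueError(f"water fraction must be >= 0, got {f}")
    if f >= 1:
        raise ValueError(f"water fraction must be < 1, got {f}")
    s_water = profile.species_spectrum(("water",), f)
    s_nades = profile.species_spectrum(("levulinic_acid", "l_proline"), f)
    return f * s_water + (1.0 - f) * s_nades


def _legendre_baseline(grid: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    u = 2.0 * (grid - grid[0]) / (grid[-1] - grid[0]) - 1.0
    return legendre.legval(u, coeffs)


def _draw_baseline(
    profile: ModalityProfile, rng: np.random.Generator
) -> np.ndarray:
    """One per-deposit baseline realization.

    ``legendre``: random polynomial of the profile's order with coefficients
    N(0, scale) — a smooth drift model (instrument/background wander).

    ``fluorescence``: a positive, convex, decaying exponential
    ``amp * exp(-k u)`` with a random amplitude (lognormal around ``scale``)
    and random decay constant k per deposit — the shape of a Raman
    fluorescence background. Because k varies, the family is not confined to
    a low-dimensional linear subspace, so a linear regression cannot simply
    project it out, whereas the rubberband's convex-hull baseline removes it
    almost exactly in band-free regions.
    """
    grid = profile.grid
    if profile.baseline_kind == "legendre":
        coeffs = rng.normal(0.0, 1.0, profile.baseline_order + 1) * profile.baseline_scale
        return _legendre_baseline(grid, coeffs)
    amp = profile.baseline_scale * rng.lognormal(0.0, 0.5)
    decay = rng.uniform(1.0, 6.0)
    u = (grid - grid[0]) / (grid[-1] - grid[0])
    return amp * np.exp(-decay * u)


def generate_dataset(
    design: SampleDesign, profile: ModalityProfile, seed: int
) -> SpectralDataset:
    """Generate the full replicate-set dataset; a pure function of its inputs.

    Randomness uses independent named substreams off one master seed
    (intrinsic water, weighing error, deposit gains, baselines, scan noise),
    so switching one noise source off never reshuffles the others. The draw
    order is fixed: draws are made even when the corresponding sd is zero.
    """
    ss = np.random.SeedSequence(seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("intrinsic", "weighing", "gain", "baseline", "noise"), ss.spawn(5)
        )
    }

    set_ids = design.set_ids()
    level_ids = design.level_ids()
    n_channels = profile.grid.size
    intensities = np.empty((design.n_spectra, n_channels))
    meta: list[SpectrumMeta] = []

    row = 0
    for set_id in set_ids:
        intrinsic = streams["intrinsic"].normal(
            design.intrinsic_water_mean, design.intrinsic_water_sd
        )
        for level_id, ratio in zip(level_ids, design.added_mass_ratios):
            nominal = added_fraction_from_ratio(ratio)
            realized = nominal + streams["weighing"].normal(0.0, design.weighing_error_sd)
            f_total = total_water_percent(realized, intrinsic) / 100.0
            clean = clean_mixture_spectrum(profile, f_total)
            for deposit in range(1, design.n_deposits + 1):
                gain = streams["gain"].lognormal(0.0, profile.deposit_gain_sd)
                baseline = _draw_baseline(profile, streams["baseline"])
                for scan in range(1, design.n_scans_per_deposit + 1):
                    noise = streams["noise"].normal(0.0, profile.additive_noise_sd, n_channels)
                    spectrum = gain * clean + baseline + noise
                    if profile.saturation_cap is not None:
                        spectrum = np.minimum(spectrum, profile.saturation_cap)
                    intensities[row] = spectrum
                    meta.append(
                        SpectrumMeta(
                            spectrum_id=f"{set_id}_{level_id}_D{deposit}_S{scan}",
                            set_id=set_id,
                            level_id=level_id,
                            added_water=nominal,
                            deposit_index=deposit,
                            scan_index=scan,
                        )
                    )
                    row += 1
    return SpectralDataset(
        wavenumbers=profile.grid.copy(),
        intensities=intensities,
        meta=meta,
        modality=profile.name,
    )


# --- default instrument profiles --------------------------------------------
#
# Band positions follow the study's assignments; relative amplitudes and
# widths are not reported anywhere and are chosen so the clean spectra
# reproduce the described qualitative balance (water and constituents both
# strong in ATR-IR; water dominating NIR with a saturating 5200 cm^-1 band;
# constituents dominating the Raman fingerprint). All values live in the
# band tables below and are plain data, editable without touching code.

_W = "water"
_LA = "levulinic_acid"
_LP = "l_proline"

_ATR_BANDS = (
    # water: broad OH stretch + scissoring bend
    Band(3350.0, 420.0, 1.00, _W),
    Band(1640.0, 90.0, 0.35, _W),
    # Levulinic Acid
    Band(2940.0, 90.0, 0.25, _LA),
    Band(1713.0, 35.0, 1.00, _LA),
    Band(1393.0, 25.0, 0.40, _LA),
    Band(1360.0, 25.0, 0.35, _LA),
    Band(1235.0, 30.0, 0.45, _LA),
    Band(1204.0, 25.0, 0.35, _LA),
    Band(1157.0, 30.0, 0.50, _LA),
    Band(985.0, 25.0, 0.25, _LA),
    Band(800.0, 25.0, 0.20, _LA),
    Band(769.0, 20.0, 0.20, _LA),
    Band(614.0, 30.0, 0.15, _LA),
    Band(570.0, 30.0, 0.12, _LA),
    Band(489.0, 30.0, 0.10, _LA),
    # L-Proline
    Band(1609.0, 40.0, 0.45, _LP),
    Band(1558.0, 30.0, 0.40, _LP),
    Band(1542.0, 30.0, 0.38, _LP),
    Band(1375.0, 25.0, 0.30, _LP),
    Band(1325.0, 25.0, 0.20, _LP),
    Band(1289.0, 25.0, 0.25, _LP),
)

_NIR_BANDS = (
    # water overtone/combination bands; the 5200 cm^-1 combination band is
    # strong enough that high-water samples exceed the detector ceiling
    Band(5200.0, 300.0, 14.0, _W),
    Band(7000.0, 350.0, 0.90, _W),
    Band(8500.0, 400.0, 0.25, _W),
    # constituent first-overtone C-H stretches
    Band(5764.0, 60.0, 0.55, _LA),
    Band(5800.0, 60.0, 0.60, _LA),
    Band(5896.0, 60.0, 0.50, _LP),
    Band(5956.0, 60.0, 0.45, _LP),
)

_RAMAN_BANDS = (
    # water: two-lobed OH stretch, weak scissoring bend
    Band(3200.0, 300.0, 0.35, _W),
    Band(3400.0, 260.0, 0.40, _W),
    Band(1633.0, 80.0, 0.06, _W),
    # Levulinic Acid; CH and C=O and C-C bands shift/broaden with water
    Band(2929.0, 50.0, 1.00, _LA, shift_per_fraction=7.0),
    Band(1714.0, 40.0, 0.85, _LA, shift_per_fraction=-17.5, broaden_per_fraction=0.9),
    Band(1411.0, 25.0, 0.35, _LA),
    Band(772.0, 20.0, 0.40, _LA, shift_per_fraction=21.0),
    Band(617.0, 20.0, 0.25, _LA),
    # L-Proline
    Band(1624.0, 30.0, 0.30, _LP),
    Band(1480.0, 40.0, 0.50, _LP),
    Band(1450.0, 30.0, 0.55, _LP),
    Band(1166.0, 25.0, 0.20, _LP),
    Band(833.0, 25.0, 0.25, _LP),
)


def _nirh_grid() -> np.ndarray:
    """228 points linear in wavelength 900-1700 nm, converted to cm^-1."""
    wavelengths_nm = np.linspace(900.0, 1700.0, 228)
    return np.sort(1e7 / wavelengths_nm)


def default_profiles() -> dict[str, ModalityProfile]:
    """The four default instrument profiles keyed by modality name."""
    return {
        "ATR-IR": ModalityProfile(
            name="ATR-IR",
            grid=np.arange(400.0, 4000.0 + 1.0, 4.0),
            bands=_ATR_BANDS,
            baseline_order=1,
            baseline_scale=0.0,
            additive_noise_sd=0.001,
            deposit_gain_sd=0.002,
            saturation_cap=None,
        ),
        "NIR-B": ModalityProfile(
            name="NIR-B",
            grid=np.arange(4000.0, 12800.0 + 1.0, 8.0),
            bands=_NIR_BANDS,
            baseline_order=1,
            baseline_scale=0.0,
            additive_noise_sd=0.001,
            deposit_gain_sd=0.01,
            saturation_cap=3.0,
        ),
        "NIR-H": ModalityProfile(
            name="NIR-H",
            grid=_nirh_grid(),
            bands=_NIR_BANDS,
            baseline_order=1,
            baseline_scale=0.0,
            additive_noise_sd=0.003,
            deposit_gain_sd=0.01,
            saturation_cap=3.0,
        ),
        "Raman-B": ModalityProfile(
            name="Raman-B",
            grid=np.arange(150.0, 4000.0 + 1.0, 2.5),
            bands=_RAMAN_BANDS,
            baseline_order=3,
            baseline_scale=0.3,
            baseline_kind="fluorescence",
            additive_noise_sd=0.002,
            deposit_gain_sd=0.05,
            saturation_cap=None,
        ),
    }
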