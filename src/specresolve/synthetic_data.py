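"""Synthetic quaternary-mixture data: design matrices and Beer-Lambert spectra.

The experimental system is a severely overlapped four-component UV-Vis mixture
(paracetamol PARA, ascorbic acid ASC, caffeine CAF, chlorpheniramine maleate
CPM) measured over 200–400 nm. This module supplies everything the calibration
engines need without any instrument: the five-level, four-factor calibration
design (the printed 25 + 5 mixture table ships as a fixture, a cyclic
generator builds new designs), sum-of-Gaussian pure-component spectra with the
qualitative band overlap of the real system, additive Beer-Lambert mixing with
homoscedastic absorbance noise, and a simulated dosage form at the challenging
80:1:10:60 PARA:CPM:CAF:ASC ratio with CPM spiking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ANALYTES",
    "DEFAULT_LEVEL_GRIDS",
    "CYCLIC_LEVEL_SEQUENCE",
    "AnalyteSpec",
    "DesignMatrix",
    "SpectraSet",
    "PureSpectra",
    "table1_design",
    "generate_design",
    "default_pure_spectra",
    "simulate_spectra",
    "simulate_dosage_form",
]

#: Canonical analyte order used by every matrix in the package (design columns,
#: pure-spectrum rows, prediction columns). This is the printed design-table
#: order.
ANALYTES: tuple[str, ...] = ("PARA", "ASC", "CAF", "CPM")

#: Five ascending calibration levels per analyte (µg/mL).
DEFAULT_LEVEL_GRIDS: dict[str, tuple[float, ...]] = {
    "PARA": (4.00, 8.00, 12.00, 16.00, 20.00),
    "ASC": (3.00, 6.00, 9.00, 12.00, 15.00),
    "CAF": (2.50, 5.00, 7.50, 10.00, 12.50),
    "CPM": (1.00, 3.00, 5.00, 7.00, 9.00),
}

#: Coded-level sequence (runs 2–25 of the first factor) driving the cyclic
#: five-level generator. Subsequent factors are cyclic lags of this sequence.
CYCLIC_LEVEL_SEQUENCE: tuple[int, ...] = (
    0, -1, -2, -1, 2, 2, 0, -2, 2, -2, 1, 0,
    2, 1, 2, -1, -1, 0, 1, -1, 1, -2, -2, 0,
)

_WL_FMT = "{:.1f}"


def _data_path(name: str):
    return resources.files("specresolve.data").joinpath(name)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalyteSpec:
    """One analyte: its Gaussian band table and five-level concentration grid.

    ``bands`` holds ``(center_nm, width_nm, height)`` triples with height in
    AU·mL/µg at 1 cm path; ``level_grid`` the five ascending calibration
    concentrations in µg/mL.
    """

    name: str
    bands: tuple[tuple[float, float, float], ...]
    level_grid: tuple[float, ...]

    def __post_init__(self) -> None:
        grid = np.asarray(self.level_grid, dtype=float)
        if grid.shape != (5,) or not np.all(np.diff(grid) > 0):
            raise ValueError(
                f"{self.name}: level_grid must hold 5 strictly increasing values"
            )
        for center, width, height in self.bands:
            if width <= 0 or height <= 0:
                raise ValueError(f"{self.name}: band widths and heights must be > 0")
            if not 200.0 <= center <= 400.0:
                raise ValueError(f"{self.name}: band center {center} outside 200–400 nm")

    def absorptivity(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Unit absorptivity spectrum (AU per µg/mL) on the given grid."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        out = np.zeros_like(wl)
        for center, width, height in self.bands:
            out += height * np.exp(-0.5 * ((wl - center) / width) ** 2)
        return out


@dataclass
class DesignMatrix:
    """Sample × analyte nominal concentrations with coded levels and roles.

    ``coded`` stores the design level in {−2…+2} as floats; entries whose
    nominal concentration does not sit on the analyte's level grid (possible
    for hold-out mixtures) are NaN.
    """

    sample_ids: list[str]
    nominal: np.ndarray
    coded: np.ndarray
    role: np.ndarray
    analytes: tuple[str, ...] = ANALYTES

    def __post_init__(self) -> None:
        self.nominal = np.atleast_2d(np.asarray(self.nominal, dtype=float))
        self.coded = np.atleast_2d(np.asarray(self.coded, dtype=float))
        self.role = np.asarray(self.role, dtype=object)
        n, k = self.nominal.shape
        if k != len(self.analytes):
            raise ValueError("nominal column count must match analytes")
        if self.coded.shape != (n, k) or len(self.sample_ids) != n or self.role.shape != (n,):
            raise ValueError("inconsistent design dimensions")
        bad = set(self.role) - {"calibration", "validation"}
        if bad:
            raise ValueError(f"unknown roles: {bad}")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_nominal(
        cls,
        nominal: np.ndarray,
        role,
        sample_ids=None,
        level_grids: dict[str, tuple[float, ...]] | None = None,
        analytes: tuple[str, ...] = ANALYTES,
    ) -> "DesignMatrix":
        nominal = np.atleast_2d(np.asarray(nominal, dtype=float))
        n = nominal.shape[0]
        grids = level_grids or DEFAULT_LEVEL_GRIDS
        coded = np.full_like(nominal, np.nan)
        for j, name in enumerate(analytes):
            grid = np.asarray(grids[name], dtype=float)
            for i in range(n):
                hit = np.nonzero(np.isclose(grid, nominal[i, j], atol=1e-9))[0]
                if hit.size:
                    coded[i, j] = hit[0] - 2
        if sample_ids is None:
            sample_ids = [f"mix{i + 1:02d}" for i in range(n)]
        if isinstance(role, str):
            role = [role] * n
        return cls(list(sample_ids), nominal, coded, np.asarray(role, dtype=object), analytes)

    # -- views --------------------------------------------------------------

    def subset(self, mask: np.ndarray) -> "DesignMatrix":
        idx = np.nonzero(mask)[0]
        return DesignMatrix(
            [self.sample_ids[i] for i in idx],
            self.nominal[idx],
            self.coded[idx],
            self.role[idx],
            self.analytes,
        )

    @property
    def calibration(self) -> "DesignMatrix":
        return self.subset(self.role == "calibration")

    @property
    def validation(self) -> "DesignMatrix":
        return self.subset(self.role == "validation")

    def __len__(self) -> int:
        return self.nominal.shape[0]

    # -- I/O ----------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.nominal, columns=list(self.analytes))
        df.insert(0, "sample_id", self.sample_ids)
        df["role"] = self.role
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.4f")

    @classmethod
    def from_csv(cls, path, level_grids=None) -> "DesignMatrix":
        df = pd.read_csv(path)
        analytes = tuple(c for c in df.columns if c not in ("sample_id", "role"))
        return cls.from_nominal(
            df[list(analytes)].to_numpy(float),
            df["role"].tolist(),
            sample_ids=df["sample_id"].astype(str).tolist(),
            level_grids=level_grids,
            analytes=analytes,
        )


@dataclass
class SpectraSet:
    """Sample × wavelength absorbance matrix with its wavelength axis (nm/AU)."""

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        steps = np.diff(self.wavelengths_nm)
        if self.wavelengths_nm.size > 1 and (
            np.any(steps <= 0) or not np.allclose(steps, steps[0], atol=1e-9)
        ):
            raise ValueError("wavelength grid must be strictly ascending and uniform")
        if self.absorbance.shape != (len(self.sample_ids), self.wavelengths_nm.size):
            raise ValueError("absorbance shape inconsistent with ids/wavelengths")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")

    def __len__(self) -> int:
        return self.absorbance.shape[0]

    def subset(self, indices) -> "SpectraSet":
        idx = np.atleast_1d(np.asarray(indices, dtype=int))
        return SpectraSet(
            self.wavelengths_nm,
            self.absorbance[idx],
            [self.sample_ids[i] for i in idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.absorbance,
            columns=[_WL_FMT.format(w) for w in self.wavelengths_nm],
        )
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path) -> "SpectraSet":
        df = pd.read_csv(path)
        wl_cols = [c for c in df.columns if c != "sample_id"]
        return cls(
            np.array([float(c) for c in wl_cols]),
            df[wl_cols].to_numpy(float),
            df["sample_id"].astype(str).tolist(),
        )


@dataclass
class PureSpectra:
    """Unit-absorptivity spectra of the pure analytes (AU per µg/mL, 1 cm)."""

    wavelengths_nm: np.ndarray
    unit_absorptivity: np.ndarray
    analytes: tuple[str, ...] = ANALYTES

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.unit_absorptivity = np.atleast_2d(
            np.asarray(self.unit_absorptivity, dtype=float)
        )
        if self.unit_absorptivity.shape != (len(self.analytes), self.wavelengths_nm.size):
            raise ValueError("unit_absorptivity must be n_analytes × n_wavelengths")
        if np.any(self.unit_absorptivity < 0):
            raise ValueError("absorptivities must be non-negative")


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def _load_table1() -> pd.DataFrame:
    with resources.as_file(_data_path("table1_design.csv")) as p:
        return pd.read_csv(p)


def table1_design() -> DesignMatrix:
    """The printed 25-mixture calibration + 5-mixture validation design."""
    df = _load_table1()
    return DesignMatrix.from_nominal(
        df[list(ANALYTES)].to_numpy(float),
        df["role"].tolist(),
        sample_ids=df["sample_id"].tolist(),
    )


def generate_design(
    level_grids: dict[str, tuple[float, ...]] | None = None,
    seed: int = 0,
    source: str = "table1",
) -> DesignMatrix:
    """Build the five-level, four-factor calibration design (25 + 5 mixtures).

    Parameters
    ----------
    level_grids
        Mapping analyte → five ascending concentrations (µg/mL). Defaults to
        the study grids.
    seed
        Accepted for interface uniformity; the construction is deterministic.
    source
        ``"table1"`` (default) returns the printed design verbatim — the row
        order of the published table is taken as ground truth. ``"cyclic"``
        rebuilds the 25 calibration rows from the cyclic generator: run 1 has
        every factor at the centre level, runs 2–25 take factor 1 levels from
        :data:`CYCLIC_LEVEL_SEQUENCE` and factor ``j+1`` at run ``i`` equals
        factor ``j`` at run ``i+1`` (cyclic over runs 2–25). The five
        validation mixtures always come from the printed hold-out block.
    """
    grids = dict(DEFAULT_LEVEL_GRIDS if level_grids is None else level_grids)
    for name in ANALYTES:
        g = np.asarray(grids[name], dtype=float)
        if g.shape != (5,):
            raise ValueError(f"{name}: level grid must have exactly 5 entries")
        if not np.all(np.diff(g) > 0) or np.any(g <= 0):
            raise ValueError(f"{name}: level grid must be strictly increasing and > 0")

    if source == "table1":
        design = table1_design()
        if level_grids is not None:
            design = DesignMatrix.from_nominal(
                design.nominal, design.role, design.sample_ids, grids
            )
        return design
    if source != "cyclic":
        raise ValueError("source must be 'table1' or 'cyclic'")

    seq = np.array(CYCLIC_LEVEL_SEQUENCE, dtype=int)
    coded = np.zeros((25, 4), dtype=int)
    for j in range(4):
        coded[1:, j] = np.roll(seq, -j)
    nominal = np.empty((25, 4))
    for j, name in enumerate(ANALYTES):
        grid = np.asarray(grids[name], dtype=float)
        nominal[:, j] = grid[coded[:, j] + 2]

    val = table1_design().validation
    all_nominal = np.vstack([nominal, val.nominal])
    roles = ["calibration"] * 25 + ["validation"] * 5
    ids = [f"mix{i + 1:02d}" for i in range(30)]
    return DesignMatrix.from_nominal(all_nominal, roles, ids, grids)


# ---------------------------------------------------------------------------
# Spectra simulation
# ---------------------------------------------------------------------------


def load_band_table(path=None) -> list[AnalyteSpec]:
    """Read an analyte band table (YAML); defaults to the packaged one."""
    if path is None:
        with resources.as_file(_data_path("pure_bands.yaml")) as p:
            raw = yaml.safe_load(Path(p).read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    specs = []
    for entry in raw["analytes"]:
        specs.append(
            AnalyteSpec(
                name=entry["name"],
                bands=tuple(
                    (b["center_nm"], b["width_nm"], b["height"]) for b in entry["bands"]
                ),
                level_grid=tuple(entry["level_grid"]),
            )
        )
    return specs


def default_pure_spectra(
    grid_step_nm: float = 1.0, band_table=None
) -> PureSpectra:
    """Sum-of-Gaussian pure spectra on the 200–400 nm grid.

    The defaults place all four absorption maxima inside 220–300 nm with heavy
    mutual overlap; they are a qualitative stand-in for the real band shapes,
    deterministic for a fixed band table.
    """
    span = 400.0 - 200.0
    n_steps = span / grid_step_nm
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("grid_step_nm must divide the 200–400 nm span")
    wl = 200.0 + grid_step_nm * np.arange(int(round(n_steps)) + 1)
    specs = band_table if band_table is not None else load_band_table()
    U = np.vstack([spec.absorptivity(wl) for spec in specs])
    return PureSpectra(wl, U, tuple(spec.name for spec in specs))


def simulate_spectra(
    design: DesignMatrix,
    pure: PureSpectra,
    noise_sd: float = 0.002,
    seed: int = 0,
) -> SpectraSet:
    """Beer-Lambert mixture spectra: ``A = C · U + N(0, noise_sd)``.

    Noise is i.i.d. homoscedastic Gaussian on absorbance (AU), the standard
    photometric-noise picture for a bench UV-Vis instrument; reproducible for
    a fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if design.nominal.shape[1] != pure.unit_absorptivity.shape[0]:
        raise ValueError("design and pure spectra disagree on analyte count")
    A = design.nominal @ pure.unit_absorptivity
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        A = A + rng.normal(0.0, noise_sd, size=A.shape)
    return SpectraSet(pure.wavelengths_nm, A, list(design.sample_ids))


def simulate_dosage_form(
    pure: PureSpectra,
    spike_cpm: float = 0.75,
    noise_sd: float = 0.002,
    seed: int = 0,
    n_replicates: int = 3,
    baseline: np.ndarray | None = None,
) -> tuple[SpectraSet, DesignMatrix]:
    """Simulated capsule assay at the 80:1:10:60 PARA:CPM:CAF:ASC ratio.

    The capsule dilution puts PARA at 20.00, ASC at 15.00, CAF at 2.50 and CPM
    at 0.25 µg/mL; CPM is then spiked (default 0.75 µg/mL) to lift it to 1.00,
    inside its calibrated range. Returns replicate spectra plus the post-spike
    nominals that serve as the recovery reference. ``baseline`` optionally adds
    a fixed matrix/excipient absorbance spectrum to every replicate.
    """
    if spike_cpm < 0:
        raise ValueError("spike_cpm must be >= 0")
    nominal = np.tile(
        np.array([20.00, 15.00, 2.50, 0.25 + spike_cpm]), (n_replicates, 1)
    )
    ids = [f"capsule{r + 1}" for r in range(n_replicates)]
    design = DesignMatrix.from_nominal(nominal, "validation", ids)
    spectra = simulate_spectra(design, pure, noise_sd=noise_sd, seed=seed)
    if baseline is not None:
        spectra = replace(
            spectra, absorbance=spectra.absorbance + np.asarray(baseline, dtype=float)
        )
    return spectra, design
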