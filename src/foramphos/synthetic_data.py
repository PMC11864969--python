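"""Ground-truth-known synthetic inputs for every pipeline stage.

Each generator emulates the statistical structure of one class of field
data — specimen morphometry, autoanalyser extractions, living-assemblage
tables, EDS count phantoms — and returns its latent truth alongside the
observables, so every downstream stage has an exact recovery target.

Noise models follow field conventions: multiplicative Gaussian error for
autoanalyser concentrations (small positive signals with roughly
proportional error), lognormal abundances (ecological convention for
count data spanning orders of magnitude), Poisson counts for EDS X-ray
detection. A single master seed is split into independent per-generator
streams via ``numpy.random.SeedSequence`` so each table can be
regenerated on its own; identical seeds and parameters give identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import biovolume, stock_budget
from .biovolume import ShapeKind, ValidationError
from .eds_maps import ElementCountMaps
from .phosphate_quant import DEFAULT_EXTRACT_VOLUME_L

_STREAMS = ("specimens", "extractions", "assemblage", "eds")


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one named sub-stream of a master seed."""
    if stream not in _STREAMS:
        raise ValidationError(f"unknown stream {stream!r}")
    ss = np.random.SeedSequence(seed, spawn_key=(_STREAMS.index(stream),))
    return np.random.default_rng(ss)


# --- specimens ------------------------------------------------------------

@dataclass(frozen=True)
class SpecimenParams:
    """Lognormal axis distributions for one synthetic species.

    ``axis_medians`` maps each required axis of ``shape_kind`` to its
    median length (µm); ``sigma`` is the common lognormal shape
    parameter (σ = 0 collapses to identical specimens).
    """

    species: str
    shape_kind: ShapeKind
    axis_medians: dict[str, float]
    sigma: float = 0.2
    n: int = 20

    def __post_init__(self) -> None:
        required = biovolume.SHAPE_AXES[self.shape_kind]
        if set(self.axis_medians) != set(required):
            raise ValidationError(
                f"{self.species}: shape {self.shape_kind.value} needs axes "
                f"{required}, got {tuple(self.axis_medians)}"
            )
        if self.sigma < 0 or any(m <= 0 for m in self.axis_medians.values()):
            raise ValidationError("scale parameters must be positive, sigma ≥ 0")


def gen_specimens(params: list[SpecimenParams], seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic measurement table plus the true volumes.

    Returns (measurements, truth): measurements has specimen_id, species
    and axis columns in µm; truth stores the volumes computed from the
    same closed-form shapes, so the biovolume stage must recover them
    exactly.
    """
    rng = rng_for(seed, "specimens")
    meas_rows, truth_rows = [], []
    for p in params:
        for i in range(p.n):
            axes = {
                name: med * np.exp(rng.normal(0.0, p.sigma))
                for name, med in p.axis_medians.items()
            }
            sid = f"{p.species.replace(' ', '_')}_{i:03d}"
            height = axes.get("height")
            m = biovolume.SpecimenMeasurement(
                sid, p.species, {k: v for k, v in axes.items() if k != "height"}, height
            )
            tv = biovolume.compute_test_volume(biovolume.ShapeSpec(p.shape_kind), m)
            meas_rows.append({"specimen_id": sid, "species": p.species, **axes})
            truth_rows.append(
                {
                    "specimen_id": sid,
                    "species": p.species,
                    "true_test_volume_l": tv,
                    "true_cell_volume_l": biovolume.cell_volume(tv),
                }
            )
    return pd.DataFrame(meas_rows), pd.DataFrame(truth_rows)


# --- extractions ----------------------------------------------------------

def gen_extractions(
    true_content: float,
    n_samples: int,
    n_individuals: int,
    noise_sd: float,
    seed: int,
    species: str = "Synthetica exempli",
    extract_volume: float = DEFAULT_EXTRACT_VOLUME_L,
) -> pd.DataFrame:
    """Synthetic autoanalyser extraction table for one species.

    The measured concentration is the noiseless inversion of the
    per-individual content relation, times (1 + Gaussian error):
    conc = content × n / (V × 10⁶) × (1 + ε),  ε ~ N(0, noise_sd).
    The latent truth is stored in ``true_content_pmol``.
    """
    if noise_sd < 0:
        raise ValidationError("noise sd must be ≥ 0")
    if true_content < 0 or n_individuals < 1 or extract_volume <= 0:
        raise ValidationError("content ≥ 0, n_individuals ≥ 1, volume > 0 required")
    rng = rng_for(seed, "extractions")
    base_conc = true_content * n_individuals / (extract_volume * 1e6)
    eps = rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else np.zeros(n_samples)
    conc = np.clip(base_conc * (1.0 + eps), 0.0, None)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n_samples)],
            "species": species,
            "region": "synthetic",
            "n_individuals": n_individuals,
            "extract_volume_l": extract_volume,
            "conc_umol_per_l": conc,
            "true_content_pmol": true_content,
        }
    )


# --- assemblages ----------------------------------------------------------

@dataclass(frozen=True)
class AssemblageParams:
    """A synthetic region of stations with a structured species pool.

    The pool mixes three classes: species with measured contents,
    unmeasured congeners of measured genera (recoverable by genus-mean
    imputation), and species from unknown genera (excluded). Abundances
    are lognormal(µ, σ) in ind m⁻². Defaults give a 135-station region
    — the station count of the densest real survey this emulates — with
    contents spanning the measured range.
    """

    n_stations: int = 135
    measured_contents: dict[str, float] = field(
        default_factory=lambda: {
            "Ammonia confertitesta": 412.0,
            "Haynesina germanica": 165.0,
            "Elphidium bartletti": 478.0,
            "Bolivina seminuda": 69.0,
            "Stainforthia fusiformis": 9.0,
        }
    )
    n_unmeasured_congeners: int = 2
    n_unknown_genus: int = 1
    mu_log_abundance: float = np.log(2.0e4)  # median 2×10⁴ ind m⁻²
    sigma_log_abundance: float = 1.0
    lat_range: tuple[float, float] = (51.0, 55.0)
    lon_range: tuple[float, float] = (2.0, 10.0)

    def __post_init__(self) -> None:
        if self.n_stations < 1 or self.sigma_log_abundance < 0:
            raise ValidationError("need ≥1 station and σ ≥ 0")
        if any(c < 0 for c in self.measured_contents.values()):
            raise ValidationError("contents must be ≥ 0")


@dataclass
class AssemblageTruth:
    station_stocks_g_m2: pd.Series  # exact per-station stocks
    regional_mean_g_m2: float  # analytic expectation of a station stock
    regional_se_g_m2: float  # exact sampling s.e. of the regional mean
    contents: dict[str, float]  # effective content per species (0 = excluded)
    library: "stock_budget.ContentLibrary"


def gen_assemblage(params: AssemblageParams, seed: int) -> tuple[pd.DataFrame, AssemblageTruth]:
    """Synthetic living-assemblage table plus its exact truth.

    Unmeasured congeners carry the genus-mean content in truth, so that
    imputation from the accompanying library is exact; unknown-genus
    species carry content 0 (they are excluded from stocks). The
    analytic regional mean uses E[lognormal] = exp(µ + σ²/2); the exact
    sampling standard error of the regional mean follows from the
    lognormal variance, Var[A] = (e^{σ²} − 1)·e^{2µ+σ²}, summed over the
    (independent) species abundances and divided by the station count.
    """
    rng = rng_for(seed, "assemblage")
    contents = dict(params.measured_contents)
    genera = sorted({stock_budget.genus_of(s) for s in contents})
    # unmeasured congeners of measured genera → imputable
    for i in range(params.n_unmeasured_congeners):
        genus = genera[i % len(genera)]
        donors = [c for s, c in params.measured_contents.items() if stock_budget.genus_of(s) == genus]
        contents[f"{genus} incognita{i}"] = float(np.mean(donors))
    for i in range(params.n_unknown_genus):
        contents[f"Ignotum mysteriosum{i}"] = 0.0

    species = sorted(contents)
    mu, sg = params.mu_log_abundance, params.sigma_log_abundance
    rows = []
    lat = rng.uniform(*params.lat_range, size=params.n_stations)
    lon = rng.uniform(*params.lon_range, size=params.n_stations)
    for k in range(params.n_stations):
        for sp in species:
            rows.append(
                {
                    "station_id": f"ST{k:03d}",
                    "latitude": lat[k],
                    "longitude": lon[k],
                    "species": sp,
                    "abundance": float(rng.lognormal(mu, sg)),
                    "abundance_units": "ind_per_m2",
                }
            )
    table = pd.DataFrame(rows)

    molar = stock_budget.DEFAULT_MOLAR_MASS
    per_station = (
        table.assign(part=lambda d: d["abundance"] * d["species"].map(contents) * 1e-9)
        .groupby("station_id")["part"]
        .sum()
        * 1e-3
        * molar
    )
    scale = 1e-9 * 1e-3 * molar
    mean_ab = float(np.exp(mu + sg**2 / 2.0))
    var_ab = float((np.exp(sg**2) - 1.0) * np.exp(2.0 * mu + sg**2))
    regional_mean = sum(contents.values()) * mean_ab * scale
    var_station = sum(c**2 for c in contents.values()) * var_ab * scale**2
    regional_se = float(np.sqrt(var_station / params.n_stations))
    library = stock_budget.ContentLibrary.from_mapping(params.measured_contents)
    return table, AssemblageTruth(
        station_stocks_g_m2=per_station,
        regional_mean_g_m2=regional_mean,
        regional_se_g_m2=regional_se,
        contents=contents,
        library=library,
    )


# --- EDS phantoms ---------------------------------------------------------

@dataclass(frozen=True)
class Disc:
    """A localized enrichment: centre (row, col), radius px, contrast
    k = S_i / B_i, the signal-to-background ratio at the element's peak."""

    center: tuple[float, float]
    radius: float
    element: str
    contrast: float

    def __post_init__(self) -> None:
        if self.contrast <= 0 or self.radius <= 0:
            raise ValidationError("contrast and radius must be positive")


@dataclass(frozen=True)
class PhantomParams:
    """EDS phantom: smooth positive background with fixed per-channel
    spectral shape, plus enrichment discs and optional Poisson noise.

    ``background_level`` sets the mean total background counts per
    pixel; the spatial field is a broad Gaussian bump (peak/edge ratio
    about 2) so the background varies with position while its spectral
    split over channels stays fixed: channel i receives the fraction
    ``peak_fractions[i]`` and the out-of-peak continuum the remainder.
    Defaults image a P enrichment over a Ca/P/Mg-style three-channel
    stack at counts typical of short cryo-EDS dwell times.
    """

    shape: tuple[int, int] = (64, 64)
    elements: tuple[str, ...] = ("P", "Ca", "Mg")
    peak_fractions: tuple[float, ...] = (0.1, 0.1, 0.1)
    background_level: float = 200.0
    discs: tuple[Disc, ...] = (Disc((32.0, 32.0), 10.0, "P", 4.0),)
    poisson: bool = True

    def __post_init__(self) -> None:
        if len(self.peak_fractions) != len(self.elements):
            raise ValidationError("one peak fraction per element required")
        if any(f <= 0 for f in self.peak_fractions) or sum(self.peak_fractions) >= 1:
            raise ValidationError("peak fractions must be positive and sum below 1")
        if self.background_level <= 0:
            raise ValidationError("background level must be positive")
        for d in self.discs:
            if d.element not in self.elements:
                raise ValidationError(f"disc element {d.element!r} not in stack")


@dataclass
class PhantomTruth:
    signal: dict[str, np.ndarray]  # latent S_i per element
    background: dict[str, np.ndarray]  # latent B_i per element (under-peak)
    background_out: np.ndarray  # out-of-peak continuum B̄ (the Eq-denominator truth)
    expected_ratio: dict[str, np.ndarray]  # noiseless R per element


def _background_field(shape: tuple[int, int]) -> np.ndarray:
    """Smooth positive spatial modulation, mean ≈ 1."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    r2 = ((rows - shape[0] / 2) / shape[0]) ** 2 + ((cols - shape[1] / 2) / shape[1]) ** 2
    f = 0.6 + np.exp(-r2 / 0.08)
    return f / f.mean()


def gen_eds_phantom(params: PhantomParams, seed: int) -> tuple[ElementCountMaps, PhantomTruth]:
    """Poisson-count EDS phantom with latent signal and background maps.

    CPS is generated as the full-spectrum total Σ_i I_i + B̄, with the
    out-of-peak continuum B̄ = (1 − Σ f_i) × B(m,n) — exactly the
    quantity the ratio-map denominator CPS − Σ_i I_i estimates. The
    noiseless expected ratio R = (S_i + B_i)/B̄ is returned per element.
    """
    field2d = _background_field(params.shape) * params.background_level
    fractions = dict(zip(params.elements, params.peak_fractions))
    f_out = 1.0 - sum(params.peak_fractions)
    background = {el: fractions[el] * field2d for el in params.elements}
    background_out = f_out * field2d

    rows, cols = np.mgrid[0 : params.shape[0], 0 : params.shape[1]]
    signal = {el: np.zeros(params.shape) for el in params.elements}
    for d in params.discs:
        inside = (rows - d.center[0]) ** 2 + (cols - d.center[1]) ** 2 <= d.radius**2
        signal[d.element] += np.where(inside, d.contrast * background[d.element], 0.0)

    rng = rng_for(seed, "eds")
    counts, expected_ratio = {}, {}
    for el in params.elements:
        lam = signal[el] + background[el]
        counts[el] = rng.poisson(lam).astype(float) if params.poisson else lam
        expected_ratio[el] = lam / background_out
    bout = rng.poisson(background_out).astype(float) if params.poisson else background_out
    cps = np.sum(list(counts.values()), axis=0) + bout
    maps = ElementCountMaps(counts=counts, cps=cps)
    return maps, PhantomTruth(
        signal=signal,
        background=background,
        background_out=background_out,
        expected_ratio=expected_ratio,
    )


# --- scenario writer ------------------------------------------------------

def write_scenario(out_dir, seed: int = 0) -> None:
    """Write a complete default synthetic scenario to ``out_dir``.

    Produces the same CSV/TIFF dialects the pipeline readers consume,
    with latent truth tables in a parallel ``truth/`` tree.
    """
    import pathlib

    import tifffile

    out = pathlib.Path(out_dir)
    truth_dir = out / "truth"
    truth_dir.mkdir(parents=True, exist_ok=True)

    specs = [
        SpecimenParams(
            "Ammonia confertitesta", ShapeKind.OBLATE_SPHEROID,
            {"diameter": 300.0, "height": 150.0}, sigma=0.15, n=30,
        ),
        SpecimenParams(
            "Bolivina spissa", ShapeKind.ELLIPTIC_CONE,
            {"length": 250.0, "width": 120.0, "height": 133.0}, sigma=0.15, n=30,
        ),
    ]
    meas, vol_truth = gen_specimens(specs, seed)
    meas.to_csv(out / "specimens.csv", index=False)
    vol_truth.to_csv(truth_dir / "specimen_volumes.csv", index=False)

    extr = gen_extractions(412.0, 30, 10, 0.05, seed, species="Ammonia confertitesta")
    extr.drop(columns="true_content_pmol").to_csv(out / "extractions.csv", index=False)
    extr.to_csv(truth_dir / "extractions.csv", index=False)

    table, truth = gen_assemblage(AssemblageParams(), seed)
    table.to_csv(out / "assemblage.csv", index=False)
    truth.station_stocks_g_m2.rename("true_stock_g_m2").to_csv(truth_dir / "station_stocks.csv")
    truth.library.entries.to_csv(out / "content_library.csv", index=False)

    maps, ptruth = gen_eds_phantom(PhantomParams(), seed)
    for el, arr in maps.counts.items():
        tifffile.imwrite(str(out / f"eds_{el}.tif"), arr.astype(np.float32))
    tifffile.imwrite(str(out / "eds_cps.tif"), maps.cps.astype(np.float32))
    for el, arr in ptruth.expected_ratio.items():
        tifffile.imwrite(str(truth_dir / f"eds_R_{el}.tif"), arr.astype(np.float32))
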