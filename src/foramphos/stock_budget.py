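"""Assemblage-based phosphate stocks and riverine-runoff buffer budgets.

The standing stock of dissolved inorganic phosphate held inside living
benthic foraminifera on the seafloor is obtained by weighting each
species' living abundance with its mean per-individual content:

    DIP_sed [mmol m⁻²] = Σ_n  A_n [ind m⁻²] × content_n [pmol ind⁻¹] × 10⁻⁹

and converting to mass with the molar mass of phosphate (≈95 g mol⁻¹).
Species never measured for phosphate are imputed from the mean of their
congeners when any exist; otherwise they are excluded and their
abundance share reported so the unaccounted stock can be bounded.

Station stocks are summarised to a regional mean ± standard error,
scaled to a regional area (tonnes), and expressed as "buffer days": the
number of days of riverine phosphorus runoff the standing stock is
equivalent to, total/runoff × 365.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biovolume import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MOLAR_MASS = 95.0  # g mol⁻¹, molar mass of phosphate (HPO4²⁻ ≈ 96, H2PO4⁻ ≈ 97)

DAYS_PER_YEAR = 365.0


class _Excluded:
    """Sentinel: species without measured or imputable content."""

    def __repr__(self) -> str:  # pragma: no cover
        return "EXCLUDED"


EXCLUDED = _Excluded()


def genus_of(species: str) -> str:
    """First whitespace-delimited token of the binomial name."""
    parts = str(species).split()
    if not parts or not parts[0]:
        raise ValidationError(f"malformed species name {species!r}")
    return parts[0]


class ContentLibrary:
    """species → mean per-individual phosphate content (pmol ind⁻¹).

    Entries carry a provenance label and an exclusion flag. Excluded
    entries (e.g. culture-only measurements) are skipped both for direct
    lookups and as genus-imputation donors. Lookups are logged.
    """

    def __init__(self, entries: pd.DataFrame):
        required = {"species", "content_pmol"}
        if not required.issubset(entries.columns):
            raise ValidationError(f"library needs columns {sorted(required)}")
        df = entries.copy()
        if "excluded" not in df.columns:
            df["excluded"] = False
        if "provenance" not in df.columns:
            df["provenance"] = ""
        df["excluded"] = df["excluded"].astype(bool)
        if (df["content_pmol"] < 0).any():
            raise ValidationError("contents must be ≥ 0")
        self.entries = df
        self.lookup_log: list[tuple[str, str]] = []

    @classmethod
    def from_mapping(cls, contents: dict, excluded: set[str] | None = None) -> "ContentLibrary":
        excluded = excluded or set()
        return cls(
            pd.DataFrame(
                {
                    "species": list(contents),
                    "content_pmol": [contents[s] for s in contents],
                    "excluded": [s in excluded for s in contents],
                }
            )
        )

    @classmethod
    def from_csv(cls, path) -> "ContentLibrary":
        return cls(pd.read_csv(path))

    def lookup(self, species: str):
        """Content for ``species``: direct, genus-mean, or EXCLUDED."""
        genus = genus_of(species)  # validates the name
        hit = self.entries[
            (self.entries["species"] == species) & ~self.entries["excluded"]
        ]
        if len(hit):
            self.lookup_log.append((species, "direct"))
            return float(hit["content_pmol"].mean())
        congeners = self.entries[
            (self.entries["species"].map(genus_of) == genus) & ~self.entries["excluded"]
        ]
        if len(congeners):
            self.lookup_log.append((species, "genus_mean"))
            logger.info("imputed %s from %d congener(s)", species, len(congeners))
            return float(congeners["content_pmol"].mean())
        self.lookup_log.append((species, "excluded"))
        return EXCLUDED


def lookup_content(species: str, library: ContentLibrary):
    """Functional wrapper around :meth:`ContentLibrary.lookup`."""
    return library.lookup(species)


#: Measured mean per-individual contents (pmol ind⁻¹) by species and
#: sampling context. *A. veneta* is excluded by default: it is the only
#: species measured from laboratory culture rather than environmental
#: samples, so its values do not enter assemblage stocks.
MEASURED_CONTENTS = [
    ("Ammonia confertitesta", 412.0, False, "Friedrichskoog"),
    ("Ammonia veneta", 20.0, True, "culture, oxic"),
    ("Ammonia veneta", 10.0, True, "culture, anoxic"),
    ("Bolivina costata", 334.0, False, "Peru OMZ"),
    ("Bolivina interjuncta", 321.0, False, "Peru OMZ"),
    ("Bolivina seminuda", 69.0, False, "Peru OMZ"),
    ("Bolivina spissa", 83.0, False, "Sagami Bay"),
    ("Cassidulina limbata", 290.0, False, "Peru OMZ"),
    ("Cibiscides mundulus", 2.0, False, "Rainbow Vent Field"),
    ("Cibicidoides wuellerstorfi", 3.0, False, "Rainbow Vent Field"),
    ("Eggerella advena", 31.0, False, "Bedford Basin"),
    ("Elphidium bartletti", 478.0, False, "Bedford Basin"),
    ("Globobulimina affinis", 1078.0, False, "Sagami Bay"),
    ("Globobulimina affinis", 600.0, False, "Bedford Basin"),
    ("Haynesina germanica", 165.0, False, "Friedrichskoog"),
    ("Hoeglundina elegans", 88.0, False, "Rainbow Vent Field"),
    ("Labrospira crassimarga", 56.0, False, "Bedford Basin"),
    ("Rhizammina algaeformis", 108.0, False, "Rainbow Vent Field"),
    ("Spiroplectammina biformis", 19.0, False, "Bedford Basin"),
    ("Stainforthia fusiformis", 9.0, False, "Bedford Basin"),
    ("Uvigerina akitaensis", 203.0, False, "Sagami Bay"),
    ("Valvulineria inflata", 2603.0, False, "Peru OMZ"),
]


def default_library() -> ContentLibrary:
    """The measured-content library with the culture-only species excluded."""
    return ContentLibrary(
        pd.DataFrame(
            MEASURED_CONTENTS,
            columns=["species", "content_pmol", "excluded", "provenance"],
        )
    )


# --- abundance dialects ---------------------------------------------------

ABUNDANCE_CONVERSIONS = {
    "ind_per_m2": lambda a, depth_cm: a,
    "ind_per_cm2": lambda a, depth_cm: a * 1e4,
    "ind_per_10cm3": lambda a, depth_cm: a / 10.0 * depth_cm * 1e4,
    "ind_per_cm3": lambda a, depth_cm: a * depth_cm * 1e4,
}


def to_ind_per_m2(abundance: float, units: str, layer_depth_cm: float = 1.0) -> float:
    """Convert an abundance dialect to ind m⁻² (logged, explicit)."""
    if units not in ABUNDANCE_CONVERSIONS:
        raise ValidationError(
            f"unknown abundance units {units!r}; known: {sorted(ABUNDANCE_CONVERSIONS)}"
        )
    out = ABUNDANCE_CONVERSIONS[units](abundance, layer_depth_cm)
    logger.info("abundance %.4g %s → %.4g ind m⁻²", abundance, units, out)
    return out


# --- station and regional stocks -----------------------------------------

@dataclass
class StationStock:
    station_id: str
    stock_mmol_m2: float
    stock_g_m2: float
    total_abundance: float  # ind m⁻²
    excluded_abundance: float  # ind m⁻² with no usable content
    n_species: int

    @property
    def excluded_share(self) -> float:
        return self.excluded_abundance / self.total_abundance if self.total_abundance else 0.0


def station_stock(
    rows: pd.DataFrame,
    library: ContentLibrary,
    molar_mass: float = DEFAULT_MOLAR_MASS,
    station_id: str = "",
) -> StationStock:
    """Foraminiferal phosphate stock for one station.

    ``rows``: columns species, abundance (ind m⁻²). Excluded species
    contribute zero but are tallied in ``excluded_abundance``.
    """
    if "abundance" not in rows.columns or "species" not in rows.columns:
        raise ValidationError("assemblage rows need species and abundance columns")
    if (rows["abundance"] < 0).any():
        raise ValidationError("abundances must be ≥ 0")
    mmol = 0.0
    total_ab = 0.0
    excluded_ab = 0.0
    for row in rows.itertuples(index=False):
        a = float(row.abundance)
        total_ab += a
        content = library.lookup(str(row.species))
        if content is EXCLUDED:
            excluded_ab += a
            continue
        mmol += a * content * 1e-9
    g = mmol * 1e-3 * molar_mass
    return StationStock(
        station_id=station_id,
        stock_mmol_m2=mmol,
        stock_g_m2=g,
        total_abundance=total_ab,
        excluded_abundance=excluded_ab,
        n_species=rows["species"].nunique(),
    )


def station_stocks_table(
    assemblage: pd.DataFrame,
    library: ContentLibrary,
    molar_mass: float = DEFAULT_MOLAR_MASS,
) -> pd.DataFrame:
    """Per-station stocks for a full assemblage table.

    ``assemblage``: station_id, species, abundance (ind m⁻²), optional
    latitude/longitude carried through. Each distinct species is looked
    up once; excluded species contribute zero and are tallied into
    ``excluded_share``.
    """
    if (assemblage["abundance"] < 0).any():
        raise ValidationError("abundances must be ≥ 0")
    resolved = {}
    for sp in assemblage["species"].unique():
        c = library.lookup(str(sp))
        resolved[sp] = (float("nan") if c is EXCLUDED else float(c))
    content = assemblage["species"].map(resolved)
    work = assemblage.assign(
        _part=assemblage["abundance"] * content.fillna(0.0) * 1e-9,
        _excl_ab=assemblage["abundance"].where(content.isna(), 0.0),
    )
    g = work.groupby("station_id", sort=False)
    out = pd.DataFrame(
        {
            "station_id": [str(s) for s in g.size().index],
            "stock_mmol_m2": g["_part"].sum().to_numpy(),
            "excluded_abundance": g["_excl_ab"].sum().to_numpy(),
            "total_abundance": g["abundance"].sum().to_numpy(),
            "n_species": g["species"].nunique().to_numpy(),
        }
    )
    out["stock_g_m2"] = out["stock_mmol_m2"] * 1e-3 * molar_mass
    out["excluded_share"] = np.where(
        out["total_abundance"] > 0, out["excluded_abundance"] / out["total_abundance"], 0.0
    )
    for coord in ("latitude", "longitude"):
        if coord in assemblage.columns:
            out[coord] = g[coord].first().to_numpy()
    return out.drop(columns=["excluded_abundance", "total_abundance"])


def regional_summary(stocks, weights=None) -> tuple[float, float]:
    """Weighted mean and standard error of station stocks (g m⁻²).

    Equal weights by default: mean and sd/√n. With weights w the mean is
    Σwx/Σw and the s.e. is the weighted analogue
    sqrt(Σw(x−x̄)² / (Σw·(n−1))), which reduces to sd/√n for equal w.
    Single-station input returns s.e. = NaN.
    """
    x = np.asarray(stocks, dtype=float)
    if x.size == 0:
        raise ValidationError("no station stocks")
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape:
            raise ValidationError("weights must match stocks")
        if (w < 0).any():
            raise ValidationError("weights must be ≥ 0")
    if w.sum() == 0:
        raise ValidationError("all-zero weights")
    mean = float(np.sum(w * x) / np.sum(w))
    if x.size < 2:
        return mean, float("nan")
    se = float(np.sqrt(np.sum(w * (x - mean) ** 2) / (np.sum(w) * (x.size - 1))))
    return mean, se


@dataclass(frozen=True)
class RegionBudget:
    mean_stock: float  # g m⁻²
    se_stock: float  # g m⁻²
    area: float  # m²
    total_stock: float  # tonnes
    runoff: float  # t yr⁻¹
    buffer_days: float


def buffer_budget(
    mean_stock: float,
    area: float,
    runoff: float,
    se_stock: float = float("nan"),
) -> RegionBudget:
    """Regional stock in tonnes and the runoff-equivalent buffer days.

    total [t] = mean_stock [g m⁻²] × area [m²] × 10⁻⁶;
    buffer_days = total / runoff [t yr⁻¹] × 365.
    """
    if mean_stock < 0 or area <= 0:
        raise ValidationError("mean stock must be ≥ 0 and area positive")
    if runoff <= 0:
        raise ValidationError("runoff must be positive")
    total = mean_stock * area * 1e-6
    return RegionBudget(
        mean_stock=mean_stock,
        se_stock=se_stock,
        area=area,
        total_stock=total,
        runoff=runoff,
        buffer_days=total / runoff * DAYS_PER_YEAR,
    )


def areal_extrapolation(
    density: float,
    depth: float,
    content: float,
    area: float,
    molar_mass: float = DEFAULT_MOLAR_MASS,
) -> float:
    """Tonnes of phosphate in one species over a region, from a single
    population-density sample.

    density [ind cm⁻³] over the top ``depth`` cm gives density × depth ×
    10⁴ ind m⁻²; with per-individual content [pmol ind⁻¹] and molar mass
    [g mol⁻¹] over area [m²], mass = ind m⁻² × content×10⁻¹² × M × area
    × 10⁻⁶ tonnes.
    """
    if density < 0 or depth <= 0 or content < 0 or area <= 0 or molar_mass <= 0:
        raise ValidationError("inputs must be positive (density/content may be 0)")
    if area < 1.0:
        warnings.warn("area below 1 m² — check units (expected m²)", stacklevel=2)
    ind_per_m2 = density * depth * 1e4
    grams = ind_per_m2 * content * 1e-12 * molar_mass * area
    return grams * 1e-6


@dataclass(frozen=True)
class DensitySample:
    """A Rose-Bengal-stained, split sediment count."""

    counted: int
    split_fraction: float
    sediment_volume: float  # cm³
    sampled_area: float = float("nan")  # cm²
    depth: float = 1.0  # cm

    def __post_init__(self) -> None:
        if self.counted < 0:
            raise ValidationError("count must be ≥ 0")
        if not 0 < self.split_fraction <= 1:
            raise ValidationError("split fraction must lie in (0, 1]")
        if self.sediment_volume <= 0:
            raise ValidationError("sediment volume must be positive")


def population_density(sample: DensitySample) -> tuple[float, float]:
    """(ind cm⁻³, ind cm⁻²) from a split count.

    Volumetric density scales the split count back to the whole sample;
    areal density integrates it over the sampled layer depth.
    """
    per_cm3 = sample.counted / sample.split_fraction / sample.sediment_volume
    return per_cm3, per_cm3 * sample.depth


# --- region pipeline ------------------------------------------------------

@dataclass(frozen=True)
class RegionSpec:
    """Region configuration: area, runoff, optional bounding box."""

    name: str
    area_m2: float
    runoff_t_per_yr: float
    molar_mass: float = DEFAULT_MOLAR_MASS
    bbox: tuple[float, float, float, float] | None = None  # lon0, lon1, lat0, lat1


def plot_station_stocks(stocks: pd.DataFrame, path, title: str = "") -> None:
    """Simple gridded map of station stocks (PNG): lon/lat scatter
    coloured by g m⁻². Requires latitude/longitude columns."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not {"latitude", "longitude"}.issubset(stocks.columns):
        raise ValidationError("station table has no coordinates to map")
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(
        stocks["longitude"], stocks["latitude"], c=stocks["stock_g_m2"],
        cmap="viridis", s=30, edgecolors="k", linewidths=0.3,
    )
    fig.colorbar(sc, ax=ax, label="foraminiferal phosphate stock (g m⁻²)")
    ax.set_xlabel("longitude (°E)")
    ax.set_ylabel("latitude (°N)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def region_budget(
    assemblage: pd.DataFrame,
    library: ContentLibrary,
    region: RegionSpec,
    weights=None,
) -> tuple[pd.DataFrame, RegionBudget]:
    """Per-station stocks plus the full regional budget for one region."""
    stocks = station_stocks_table(assemblage, library, region.molar_mass)
    mean, se = regional_summary(stocks["stock_g_m2"].to_numpy(), weights)
    budget = buffer_budget(mean, region.area_m2, region.runoff_t_per_yr, se_stock=se)
    return stocks, budget
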