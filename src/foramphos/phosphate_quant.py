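"""Per-individual phosphate content and intracellular concentration.

Pooled batches of living specimens (1–75 individuals, depending on body
size) are lysed by repeated freeze–thaw in a small volume of reverse
osmosis water (3 ml by default) and the extract is analysed for total
dissolved phosphate on a segmented flow-injection autoanalyser. From the
measured concentration (µmol l⁻¹) this module derives:

* per-individual content,  content = conc × V_extract × 10⁶ / n  (pmol ind⁻¹)
* intracellular concentration,  C = content × 10⁻⁹ / V_cell  (mM)

where V_cell is the mean cytoplasm volume from :mod:`foramphos.biovolume`.

Species summaries are means of PER-SAMPLE values (mean of ratios), with
sample standard deviations (n−1); single-sample species carry no sd.
Procedural blank correction is available but off by default: in the
source protocol the blanks served the nitrate channel, not phosphate.
Values below the autoanalyser detection limit (0.004 µmol l⁻¹) are
flagged, never censored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biovolume import ValidationError

DEFAULT_EXTRACT_VOLUME_L = 0.003
DEFAULT_DETECTION_LIMIT = 0.004  # µmol l⁻¹


@dataclass(frozen=True)
class ExtractionSample:
    """One pooled freeze–thaw extraction."""

    sample_id: str
    species: str
    n_individuals: int
    measured_conc: float  # µmol l⁻¹
    extract_volume: float = DEFAULT_EXTRACT_VOLUME_L  # litres
    region: str = ""

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be ≥ 1")
        if self.extract_volume <= 0:
            raise ValidationError("extract volume must be positive")
        if self.measured_conc < 0:
            raise ValidationError("measured concentration must be ≥ 0")


@dataclass(frozen=True)
class BlankSet:
    """Procedural blank concentrations and the instrument detection limit."""

    blank_concs: tuple[float, ...] = ()
    detection_limit: float = DEFAULT_DETECTION_LIMIT

    def __post_init__(self) -> None:
        if any(b < 0 for b in self.blank_concs):
            raise ValidationError("blank concentrations must be ≥ 0")

    @property
    def mean(self) -> float:
        if not self.blank_concs:
            raise ValidationError("blank set is empty")
        return float(np.mean(self.blank_concs))


@dataclass(frozen=True)
class CorrectedConcentration:
    value: float  # µmol l⁻¹
    below_detection: bool


@dataclass(frozen=True)
class SpeciesSummary:
    species: str
    mean_content: float  # pmol ind⁻¹
    mean_conc: float  # mM
    n_samples: int
    sd_content: float | None = None
    sd_conc: float | None = None


def blank_correct(measured: float, blanks: BlankSet, enabled: bool = True) -> CorrectedConcentration:
    """Subtract the mean procedural blank, flooring at zero.

    Disabled correction is the identity. The below-detection flag compares
    the (corrected) value against the detection limit.
    """
    if measured < 0:
        raise ValidationError("measured concentration must be ≥ 0")
    corrected = max(measured - blanks.mean, 0.0) if enabled else measured
    return CorrectedConcentration(corrected, corrected < blanks.detection_limit)


def individual_content(sample: ExtractionSample, conc: float | None = None) -> float:
    """Phosphate content per individual in pmol ind⁻¹.

    ``conc`` overrides the sample's measured concentration (e.g. after
    blank correction). µmol l⁻¹ × l gives µmol; ×10⁶ converts to pmol.
    """
    c = sample.measured_conc if conc is None else conc
    if c < 0:
        raise ValidationError("concentration must be ≥ 0")
    return c * sample.extract_volume * 1e6 / sample.n_individuals


def intracellular_concentration(content: float, cell_volume: float) -> float:
    """Intracellular phosphate concentration in mM.

    content (pmol) × 10⁻¹² mol / V (l) = mol l⁻¹; ×10³ → mM, i.e. ×10⁻⁹.
    """
    if cell_volume <= 0:
        raise ValidationError("cell volume must be positive")
    if content < 0:
        raise ValidationError("content must be ≥ 0")
    return content * 1e-9 / cell_volume


def summarize_species(
    species: str, contents: "list[float]", concentrations: "list[float]"
) -> SpeciesSummary:
    """Mean ± sd over per-sample contents and concentrations.

    Means of per-sample ratios, never ratios of pooled means; sd uses the
    n−1 denominator and is omitted for a single sample.
    """
    if len(contents) == 0 or len(contents) != len(concentrations):
        raise ValidationError("need ≥1 sample and matching content/concentration lists")
    n = len(contents)
    mean_content = float(np.mean(contents))
    mean_conc = float(np.mean(concentrations))
    if n == 1:
        return SpeciesSummary(species, mean_content, mean_conc, 1)
    return SpeciesSummary(
        species,
        mean_content,
        mean_conc,
        n,
        sd_content=float(np.std(contents, ddof=1)),
        sd_conc=float(np.std(concentrations, ddof=1)),
    )


# --- table pipeline -------------------------------------------------------

def quantify_samples(
    samples: pd.DataFrame,
    cell_volumes: pd.DataFrame | dict,
    blanks: BlankSet | None = None,
    blank_correction: bool = False,
) -> pd.DataFrame:
    """Per-sample contents and intracellular concentrations.

    ``samples`` columns: sample_id, species, n_individuals,
    conc_umol_per_l, optional extract_volume_l and region.
    ``cell_volumes`` maps species → mean cell volume (l), or is a frame
    with columns species, mean_cell_volume_l.
    """
    if isinstance(cell_volumes, pd.DataFrame):
        vol_map = dict(zip(cell_volumes["species"], cell_volumes["mean_cell_volume_l"]))
    else:
        vol_map = dict(cell_volumes)
    if blank_correction and blanks is None:
        raise ValidationError("blank correction enabled but no blanks supplied")

    rows = []
    for row in samples.itertuples(index=False):
        extract_volume = float(getattr(row, "extract_volume_l", DEFAULT_EXTRACT_VOLUME_L))
        s = ExtractionSample(
            sample_id=str(row.sample_id),
            species=str(row.species),
            n_individuals=int(row.n_individuals),
            measured_conc=float(row.conc_umol_per_l),
            extract_volume=extract_volume,
            region=str(getattr(row, "region", "")),
        )
        if blank_correction:
            corr = blank_correct(s.measured_conc, blanks)
        elif blanks is not None:
            corr = blank_correct(s.measured_conc, blanks, enabled=False)
        else:
            corr = CorrectedConcentration(s.measured_conc, s.measured_conc < DEFAULT_DETECTION_LIMIT)
        content = individual_content(s, corr.value)
        conc_mm = (
            intracellular_concentration(content, vol_map[s.species])
            if s.species in vol_map
            else math.nan
        )
        rows.append(
            {
                "sample_id": s.sample_id,
                "species": s.species,
                "region": s.region,
                "n_individuals": s.n_individuals,
                "conc_umol_per_l": corr.value,
                "below_detection": corr.below_detection,
                "content_pmol_per_ind": content,
                "conc_mM": conc_mm,
            }
        )
    return pd.DataFrame(rows)


def species_table(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Species summary in the layout of the study's content table.

    Display rounding: contents to whole pmol, concentrations to 0.1 mM.
    """
    rows = []
    for (species, region), grp in per_sample.groupby(["species", "region"], dropna=False):
        summ = summarize_species(
            species, grp["content_pmol_per_ind"].tolist(), grp["conc_mM"].tolist()
        )
        rows.append(
            {
                "species": species,
                "region": region,
                "n_samples": summ.n_samples,
                "content_pmol_per_ind": round(summ.mean_content),
                "sd_content": None if summ.sd_content is None else round(summ.sd_content),
                "conc_mM": None if math.isnan(summ.mean_conc) else round(summ.mean_conc, 1),
                "sd_conc": None if summ.sd_conc is None else round(summ.sd_conc, 1),
                "mean_content_raw": summ.mean_content,
                "mean_conc_raw": summ.mean_conc,
            }
        )
    return pd.DataFrame(rows)
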