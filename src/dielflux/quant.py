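"""MS feature quantification: response factors, ECN calibration for TAGs,
internal-standard correction, carbon conversion, and transcript normalization.

Concentrations are derived from peak areas through external response factors
(area per pmol).  Triacylglycerols are calibrated against their equivalent
carbon number (ECN = acyl carbons − 2 × double bonds), which predicts the
chromatographic/ionization response of a TAG species; classes without their
own standard are quantified through a designated surrogate (betaine lipids
DGTA and DGCC through the DGTS standard).  A single internal-standard spike
per sample (DNP-PE by convention) corrects for extraction and injection
losses.  Transcript counts are converted to abundances per liter of seawater
through the recovery of internal mRNA standards.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ecn",
    "EcnResponseModel",
    "fit_ecn_response",
    "response_factor_from_curve",
    "CalibrationModel",
    "quantify",
    "tag_carbon_fraction",
    "membrane_ratio",
    "transcripts_per_liter",
    "clade_relative_abundance",
    "DEFAULT_SURROGATES",
]

_MASS_C = 12.011
_MASS_H = 1.008
_MASS_O = 15.999

#: classes lacking their own standard, quantified through a surrogate class
DEFAULT_SURROGATES: dict[str, str] = {"DGTA": "DGTS", "DGCC": "DGTS"}


def ecn(nc: int, ndb: int) -> int:
    """Equivalent carbon number of a TAG: total acyl carbons − 2 × double bonds."""
    if nc <= 0 or ndb < 0 or nc <= 2 * ndb:
        raise ValueError(f"invalid TAG composition nc={nc}, ndb={ndb}")
    return nc - 2 * ndb


@dataclass(frozen=True)
class EcnResponseModel:
    """Linear response-factor model over ECN, clamped to the calibrated range.

    Predictions outside ``[ecn_min − margin, ecn_max + margin]`` are clamped
    to the nearer bound with an extrapolation warning; the linear form is the
    simplest monotone model consistent with single-class calibrant series.
    """

    slope: float
    intercept: float
    ecn_min: float
    ecn_max: float
    margin: float = 4.0

    def predict(self, e: float | np.ndarray) -> float | np.ndarray:
        e = np.asarray(e, dtype=float)
        lo, hi = self.ecn_min - self.margin, self.ecn_max + self.margin
        if np.any((e < lo) | (e > hi)):
            warnings.warn(
                f"ECN outside calibrated range [{lo:g}, {hi:g}]; prediction clamped",
                stacklevel=2,
            )
        clamped = np.clip(e, lo, hi)
        out = self.intercept + self.slope * clamped
        return float(out) if out.ndim == 0 else out


def fit_ecn_response(standards: Sequence[tuple[float, float]]) -> EcnResponseModel:
    """Least-squares line of response factor versus ECN from calibrant pairs."""
    pts = np.asarray(standards, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or len(np.unique(pts[:, 0])) < 2:
        raise ValueError("need >=2 standards at distinct ECNs")
    res = sps.linregress(pts[:, 0], pts[:, 1])
    return EcnResponseModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        ecn_min=float(pts[:, 0].min()),
        ecn_max=float(pts[:, 0].max()),
    )


def response_factor_from_curve(amounts_pmol: Sequence[float], areas: Sequence[float]) -> float:
    """Response factor (area per pmol) as the through-origin slope of a standard curve."""
    a = np.asarray(amounts_pmol, float)
    y = np.asarray(areas, float)
    if a.size < 1 or np.all(a == 0):
        raise ValueError("standard curve needs nonzero amounts")
    return float((a @ y) / (a @ a))


@dataclass
class CalibrationModel:
    """Response factors per lipid class plus the ECN model for TAGs.

    ``response_factors`` maps class name → area per pmol; ``ecn_model``
    covers TAG species; ``internal_standard`` is ``(class_or_species_name,
    added_amount_pmol)`` and its response factor must be present in
    ``response_factors``.
    """

    response_factors: dict[str, float]
    ecn_model: EcnResponseModel | None = None
    internal_standard: tuple[str, float] = ("DNP-PE", 0.0)
    surrogates: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SURROGATES))

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.response_factors.items() if v <= 0}
        if bad:
            raise ValueError(f"response factors must be positive: {bad}")

    def response_factor(self, lipid_class: str, nc: int | None = None, ndb: int | None = None) -> float:
        if lipid_class == "TAG":
            if self.ecn_model is None:
                raise ValueError("no ECN model configured for TAG quantification")
            if nc is None or ndb is None:
                raise ValueError("TAG species need nc and ndb for ECN lookup")
            return float(self.ecn_model.predict(ecn(nc, ndb)))
        if lipid_class in self.response_factors:
            return self.response_factors[lipid_class]
        surrogate = self.surrogates.get(lipid_class)
        if surrogate is None or surrogate not in self.response_factors:
            raise ValueError(
                f"no response factor or surrogate standard for class '{lipid_class}'"
            )
        return self.response_factors[surrogate]


_SPECIES_RE = re.compile(r"(\d+):(\d+)")


def _parse_species(species: str) -> tuple[int, int]:
    m = _SPECIES_RE.search(species)
    if not m:
        raise ValueError(f"cannot parse NC:NDB from species label '{species}'")
    return int(m.group(1)), int(m.group(2))


def quantify(
    features: pd.DataFrame,
    model: CalibrationModel,
    internal_std_area: float,
    sample_volume_l: float,
) -> pd.DataFrame:
    """Convert a feature table (peak areas) to concentrations in pmol/L.

    ``features`` columns: ``species, lipid_class, nc, ndb, peak_area`` (and
    optionally ``sample_id``).  The internal-standard correction is a single
    sample-level factor: added amount over recovered amount, the latter
    inferred from the internal-standard peak area and its response factor.
    Concentration = (area / RF) × (added/recovered) / volume, linear in peak
    area and inversely linear in recovery.
    """
    if internal_std_area <= 0:
        raise ValueError("internal standard area must be positive")
    if sample_volume_l <= 0:
        raise ValueError("sample volume must be positive")
    is_name, is_added = model.internal_standard
    if is_added <= 0:
        raise ValueError("internal standard added amount must be positive")
    rf_is = model.response_factors.get(is_name)
    if rf_is is None:
        raise ValueError(f"no response factor for internal standard '{is_name}'")
    recovered = internal_std_area / rf_is
    correction = is_added / recovered

    out = features.copy()
    for col in ("nc", "ndb"):
        if col not in out.columns:
            out[col] = np.nan
    concs = []
    for row in out.itertuples(index=False):
        nc = int(row.nc) if not pd.isna(row.nc) else None
        ndb = int(row.ndb) if not pd.isna(row.ndb) else None
        rf = model.response_factor(row.lipid_class, nc, ndb)
        concs.append((row.peak_area / rf) * correction / sample_volume_l)
    out["concentration_pmol_l"] = concs
    return out


def tag_carbon_fraction(nc: int, ndb: int) -> float:
    """Mass fraction of carbon in a TAG with ``nc`` acyl carbons, ``ndb`` double bonds.

    Glyceryl tri-ester formula C(nc+3) H(2(nc+3)−4−2·ndb) O6: three ester
    bonds each remove two hydrogens relative to the free components, each
    C=C double bond two more.  Natural TAGs fall in (0.7, 0.8).
    """
    if nc <= 0 or ndb < 0 or nc <= 2 * ndb:
        raise ValueError(f"invalid TAG composition nc={nc}, ndb={ndb}")
    n_c = nc + 3
    n_h = 2 * n_c - 4 - 2 * ndb
    mw = n_c * _MASS_C + n_h * _MASS_H + 6 * _MASS_O
    return n_c * _MASS_C / mw


def membrane_ratio(
    class_concs: Mapping[str, float],
    numerator_classes: Sequence[str] = ("SQDG", "BL"),
    denominator_classes: Sequence[str] = ("PG", "PE", "PC"),
) -> float:
    """Ratio of summed numerator classes to summed denominator classes.

    ``BL`` (betaine lipids) expands to DGCC + DGTS + DGTA when not supplied
    directly.  Ratios of non-phosphorus membrane lipids to phospholipids
    index phosphorus stress; dilution-invariant by construction.
    """
    def total(names: Sequence[str]) -> float:
        s = 0.0
        for n in names:
            if n == "BL" and "BL" not in class_concs:
                s += sum(class_concs.get(b, 0.0) for b in ("DGCC", "DGTS", "DGTA"))
            else:
                s += class_concs.get(n, 0.0)
        return s

    denom = total(denominator_classes)
    if denom <= 0:
        raise ValueError("denominator classes sum to zero")
    return total(numerator_classes) / denom


def transcripts_per_liter(
    counts: float | np.ndarray | pd.Series,
    standards_added: float,
    standards_recovered: float,
    volume_l: float,
) -> float | np.ndarray | pd.Series:
    """Recovery-normalised transcript abundance per liter of seawater."""
    if standards_recovered <= 0:
        raise ValueError("standard recovery must be positive")
    if volume_l <= 0:
        raise ValueError("sample volume must be positive")
    return counts * (standards_added / standards_recovered) / volume_l


def clade_relative_abundance(
    normalized_counts: Mapping[str, float] | pd.Series,
) -> pd.Series:
    """Percent share of each clade; sums to 100 over clades."""
    s = pd.Series(normalized_counts, dtype=float)
    if (s < 0).any():
        raise ValueError("counts must be non-negative")
    total = s.sum()
    if total <= 0:
        raise ValueError("total counts must be positive")
    return 100.0 * s / total
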