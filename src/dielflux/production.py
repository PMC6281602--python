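"""Model-based primary production and size-class production from particle
size distributions.

Depth-resolved production follows the light-limited quantum-yield model
P(z) = 12000 × PAR(z) × chl(z) × a* × Φc, with a* the chlorophyll-specific
absorption coefficient (m² (mg chl a)⁻¹) and Φc the quantum yield of
photosynthesis (mol C per mol quanta); the 12000 converts mol C to mg C.
Particle biovolume converts to carbon through the non-diatom protist
allometry C = a · V^b (pg C, V in µm³), and the production of the 2–20 µm
size class is the amplitude of its daytime carbon rise, exactly as the
storage-lipid production rate is a daily concentration difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PPModelConstants",
    "AllometryParams",
    "MENDEN_DEUER_LESSARD_PROTIST",
    "pp_profile",
    "par_profile",
    "biovolume_to_carbon",
    "psd_carbon_series",
    "size_class_production",
    "dissolved_blank_correct",
]

#: theoretical maximum quantum yield of photosynthesis (mol C per mol quanta)
_PHI_C_MAX = 0.125


@dataclass(frozen=True)
class PPModelConstants:
    """Constants of the light-limited production model.

    ``a_star`` defaults to 0.026 m² (mg chl a)⁻¹ (summer HPLC-based value
    for the study region); ``phi_c`` has no universal default in nature —
    0.03 mol C (mol quanta)⁻¹ is a mid-range placeholder meant to be
    overridden with a value fitted from photosynthesis–irradiance curves.
    ``kd`` is the PAR attenuation coefficient used by the exponential
    profile helper.
    """

    mgc_per_mol: float = 12_000.0
    a_star: float = 0.026
    phi_c: float = 0.03
    kd: float = 0.04

    def __post_init__(self) -> None:
        if min(self.mgc_per_mol, self.a_star, self.phi_c, self.kd) <= 0:
            raise ValueError("all model constants must be positive")
        if self.phi_c > _PHI_C_MAX:
            warnings.warn(
                f"phi_c={self.phi_c} exceeds the theoretical maximum quantum "
                f"yield {_PHI_C_MAX}"
            )


@dataclass(frozen=True)
class AllometryParams:
    """Biovolume→carbon power law C = a · V^b (pg C per cell, V in µm³)."""

    a: float = 0.216
    b: float = 0.939
    group: str = "non-diatom protist"

    def __post_init__(self) -> None:
        if self.a <= 0 or not 0 < self.b <= 1.1:
            raise ValueError("require a > 0 and 0 < b <= 1.1")


#: non-diatom protistan plankton coefficients (log10 C = −0.665 + 0.939 log10 V)
MENDEN_DEUER_LESSARD_PROTIST = AllometryParams()


def pp_profile(
    par_z: np.ndarray,
    chl_z: np.ndarray,
    constants: PPModelConstants = PPModelConstants(),
) -> np.ndarray:
    """P(z) = 12000 × PAR(z) × chl(z) × a* × Φc, elementwise over a depth grid.

    ``par_z`` in mol quanta m⁻² d⁻¹ and ``chl_z`` in mg m⁻³ must share the
    grid; the result is in mg C m⁻³ d⁻¹, linear in every factor.
    """
    par = np.asarray(par_z, dtype=float)
    chl = np.asarray(chl_z, dtype=float)
    if par.shape != chl.shape:
        raise ValueError(f"depth grids differ: PAR {par.shape} vs chl {chl.shape}")
    if np.any(par < 0) or np.any(chl < 0):
        raise ValueError("PAR and chlorophyll must be non-negative")
    return constants.mgc_per_mol * par * chl * constants.a_star * constants.phi_c


def par_profile(par_0: float, depths: np.ndarray, kd: float | None = None,
                constants: PPModelConstants = PPModelConstants()) -> np.ndarray:
    """Exponential stand-in PAR profile PAR₀·exp(−kd·z) for unmeasured light."""
    k = constants.kd if kd is None else kd
    z = np.asarray(depths, dtype=float)
    if np.any(z < 0):
        raise ValueError("depths must be non-negative")
    return par_0 * np.exp(-k * z)


def biovolume_to_carbon(
    volume_um3, params: AllometryParams = MENDEN_DEUER_LESSARD_PROTIST
):
    """Per-cell carbon (pg) from cell biovolume (µm³) via C = a · V^b."""
    v = np.asarray(volume_um3, dtype=float)
    if np.any(v <= 0):
        raise ValueError("biovolume must be positive")
    out = params.a * v**params.b
    return float(out) if out.ndim == 0 else out


def psd_carbon_series(
    psd: pd.DataFrame,
    params: AllometryParams = MENDEN_DEUER_LESSARD_PROTIST,
    size_class_um: tuple[float, float] = (2.0, 20.0),
) -> pd.DataFrame:
    """Total carbon of a particle size class over time, in mg C m⁻³.

    ``psd`` columns: ``time, bin_lower_um, bin_upper_um, volume_ppm`` with
    volume in parts per million (µL per L).  Each bin's total volume is
    split into cells of the bin-center volume (geometric-mean diameter,
    spheres), converted per cell through the allometry, and summed over the
    bins falling inside the size class.
    """
    lo, hi = size_class_um
    sub = psd[(psd["bin_lower_um"] >= lo) & (psd["bin_upper_um"] <= hi)].copy()
    if sub.empty:
        raise ValueError(f"no PSD bins inside the {lo}-{hi} um size class")
    d_center = np.sqrt(sub["bin_lower_um"] * sub["bin_upper_um"])
    v_cell = np.pi / 6.0 * d_center**3  # µm³ per particle
    # ppm volume = µL/L = 1e9 µm³/L; pg/L × 1e-6 = mg/m³
    total_um3_per_l = sub["volume_ppm"].to_numpy() * 1.0e9
    n_cells = total_um3_per_l / v_cell.to_numpy()
    carbon_pg_l = n_cells * biovolume_to_carbon(v_cell.to_numpy(), params)
    sub["carbon_mg_m3"] = carbon_pg_l * 1.0e-6
    out = sub.groupby("time", as_index=False)["carbon_mg_m3"].sum()
    return out


def size_class_production(
    carbon_series: pd.DataFrame | tuple,
    photoperiod_h: float = 12.0,
    dawn_hour: float = 6.0,
    dusk_hour: float = 18.0,
    value_col: str = "carbon_mg_m3",
    time_col: str = "time",
) -> pd.DataFrame:
    """Daily production of a size class from its daytime carbon rise.

    Per day, the amplitude is max − min of the carbon series between dawn
    and dusk; the daily rate equals this amplitude (dawn/dusk differences
    are inherently per day), and the amplitude divided by the photoperiod is
    additionally reported as an hourly rate.  Returns ``day, amplitude,
    rate_per_day, rate_per_hour``.
    """
    if not 0 < photoperiod_h <= 24:
        raise ValueError("photoperiod must lie in (0, 24] hours")
    if isinstance(carbon_series, pd.DataFrame):
        ts = pd.to_datetime(carbon_series[time_col])
        start = ts.min().normalize()
        hours = (ts - start).dt.total_seconds().to_numpy() / 3600.0
        values = carbon_series[value_col].to_numpy(dtype=float)
    else:
        hours, values = carbon_series
        hours = np.asarray(hours, dtype=float)
        values = np.asarray(values, dtype=float)

    tod = np.mod(hours, 24.0)
    day = np.floor(hours / 24.0).astype(int)
    daytime = (tod >= dawn_hour) & (tod <= dusk_hour)
    rows = []
    for d in np.unique(day):
        sel = (day == d) & daytime
        if np.count_nonzero(sel) < 2:
            continue
        amp = float(values[sel].max() - values[sel].min())
        rows.append((int(d), amp, amp, amp / photoperiod_h))
    if not rows:
        raise ValueError("no complete day of daytime observations")
    return pd.DataFrame(rows, columns=["day", "amplitude", "rate_per_day", "rate_per_hour"])


def dissolved_blank_correct(
    whole_water: pd.DataFrame,
    blanks: pd.DataFrame,
    value_col: str = "signal",
    time_col: str = "time",
) -> pd.DataFrame:
    """Subtract the nearest preceding dissolved blank from whole-water signals.

    Emulates the hourly filtered-interval blank convention of flow-through
    particle sizing: each whole-water sample is corrected with the most
    recent blank at or before its timestamp (floored at 0).  Samples before
    the first blank fall back to the earliest blank, with a warning.
    """
    ww = whole_water.sort_values(time_col).copy()
    bl = blanks.sort_values(time_col)
    merged = pd.merge_asof(
        ww,
        bl.rename(columns={value_col: "_blank"}),
        on=time_col,
        direction="backward",
    )
    missing = merged["_blank"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} sample(s) precede the first blank; "
            "using the earliest blank"
        )
        merged.loc[missing, "_blank"] = bl[value_col].iloc[0]
    merged[value_col] = np.maximum(merged[value_col] - merged["_blank"], 0.0)
    return merged.drop(columns="_blank")
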