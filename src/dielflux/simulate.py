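"""Campaign-like synthetic data: diel lipid series, depth profiles, particle
size distributions, and primary-production incubation tables.

The generator emulates an oligotrophic subtropical-gyre sampling campaign:
triplicate lipid samples every 4 h over 8 day/night cycles at 15 m, a storage
lipid (TAG) cycling ~2.3-fold with a dusk peak, a membrane-lipid biomass proxy
(DGCC) nearly flat (~1.27-fold), and a respiratory quinone (UQ) in antiphase
with a pre-dawn maximum.  Diel amplitude attenuates with depth and vanishes
below the photic zone.  Particle carbon in the 2–20 µm size class rises from
a dawn minimum to a dusk maximum.

Waveform: a cosine in log-concentration with the peak at ``peak_hour`` and
the trough 12 h later, so the noiseless peak:trough ratio equals the
configured fold amplitude exactly.  Noise is multiplicative lognormal with a
configurable coefficient of variation, unit mean, independent across
replicates and timepoints.  A single integer seed expands into independent
per-table substreams by stable hashing of the table name, so generating one
table never perturbs another.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClassSpec",
    "GeneratorConfig",
    "DEFAULT_CLASSES",
    "amplitude_at_depth",
    "generate_diel_series",
    "generate_depth_profiles",
    "generate_psd_series",
    "generate_pp_tables",
]

_EPOCH = pd.Timestamp("2015-07-26 00:00")


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-table RNG derived from (seed, hash(label))."""
    h = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big")
    return np.random.default_rng([int(seed), h])


@dataclass(frozen=True)
class ClassSpec:
    """One lipid class in the simulated community.

    ``base_conc`` is the trough (dawn-side) concentration in arbitrary but
    internally consistent units; ``fold_amplitude`` the surface peak:trough
    ratio (≥ 1); ``peak_hour`` the local clock hour of the peak;
    ``depth_efolding`` the depth scale (m) over which the excess amplitude
    ``fold_amplitude − 1`` decays (``None`` → photic depth / 3, which keeps
    the residual amplitude below 5% of the surface excess at the base of the
    photic zone).
    """

    name: str
    base_conc: float = 1.0
    fold_amplitude: float = 1.0
    peak_hour: float = 18.0
    depth_efolding: float | None = None

    def __post_init__(self) -> None:
        if self.fold_amplitude < 1.0:
            raise ValueError(
                f"fold_amplitude must be >= 1 (got {self.fold_amplitude}); "
                "model antiphase classes with a shifted peak_hour instead"
            )
        if self.base_conc <= 0:
            raise ValueError("base_conc must be positive")


#: default community: storage lipid, near-flat membrane-lipid biomass proxy,
#: and an antiphase respiratory quinone (pre-dawn maximum).
DEFAULT_CLASSES: tuple[ClassSpec, ...] = (
    ClassSpec("TAG", base_conc=1.0, fold_amplitude=2.3, peak_hour=18.0),
    ClassSpec("DGCC", base_conc=2.0, fold_amplitude=1.27, peak_hour=18.0),
    ClassSpec("UQ", base_conc=0.05, fold_amplitude=3.3, peak_hour=4.0),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling design and noise level of the synthetic campaign."""

    n_days: int = 8
    samples_per_day: int = 6
    replicates: int = 3
    classes: tuple[ClassSpec, ...] = DEFAULT_CLASSES
    depths: tuple[float, ...] = (15.0,)
    photic_depth: float = 100.0
    dawn_hour: float = 6.0
    dusk_hour: float = 18.0
    noise_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 <= self.noise_cv < 1:
            raise ValueError("noise_cv must lie in [0, 1)")
        if not self.dawn_hour < self.dusk_hour:
            raise ValueError("dawn_hour must precede dusk_hour")
        if len(self.classes) == 0:
            raise ValueError("at least one lipid class is required")
        if any(d < 0 for d in self.depths):
            raise ValueError("depths must be non-negative")

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def _efolding(spec: ClassSpec, config: GeneratorConfig) -> float:
    return spec.depth_efolding if spec.depth_efolding is not None else config.photic_depth / 3.0


def amplitude_at_depth(spec: ClassSpec, depth: float, config: GeneratorConfig) -> float:
    """Effective peak:trough ratio at depth z: 1 + (F − 1)·exp(−z/λ)."""
    if depth < 0:
        raise ValueError("depth must be non-negative")
    lam = _efolding(spec, config)
    return 1.0 + (spec.fold_amplitude - 1.0) * math.exp(-depth / lam)


def _waveform(hour: np.ndarray | float, peak_hour: float) -> np.ndarray | float:
    """Position on the log-concentration cosine: 1 at the peak, 0 at the trough."""
    return 0.5 * (np.cos(2 * np.pi * (np.asarray(hour) - peak_hour) / 24.0) + 1.0)


def _concentration(spec: ClassSpec, hour, depth: float, config: GeneratorConfig):
    f_z = amplitude_at_depth(spec, depth, config)
    return spec.base_conc * f_z ** _waveform(hour, spec.peak_hour)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


# ---------------------------------------------------------------------------
# lipid time series
# ---------------------------------------------------------------------------

def generate_diel_series(config: GeneratorConfig) -> pd.DataFrame:
    """Long-format lipid concentration time series.

    Columns: ``sample_id, datetime_local, depth_m, replicate, lipid_class,
    species, concentration``.  Sampling starts at dawn on day 0 and proceeds
    every ``24 / samples_per_day`` hours for ``n_days`` days.

    The configured fold amplitude is expressed at the campaign's reference
    (shallowest) sampling depth — a time-series station samples where the
    signal it characterises lives — and attenuates over ``depth_efolding``
    below it; absolute-depth attenuation from the surface is the business of
    :func:`generate_depth_profiles`.
    """
    rng = _substream(config.seed, "diel_series")
    step = 24.0 / config.samples_per_day
    n_tp = config.n_days * config.samples_per_day
    hours = config.dawn_hour + step * np.arange(n_tp)
    z_ref = min(config.depths)

    rows = []
    for spec in config.classes:
        for depth in config.depths:
            clean = _concentration(spec, hours, depth - z_ref, config)
            noise = _lognormal_noise(rng, config.noise_cv, (n_tp, config.replicates))
            for i, h in enumerate(hours):
                ts = _EPOCH + pd.Timedelta(hours=float(h))
                for r in range(config.replicates):
                    rows.append(
                        (
                            f"S{i:03d}_{depth:g}m_r{r + 1}",
                            ts,
                            depth,
                            r + 1,
                            spec.name,
                            spec.name,
                            clean[i] * noise[i, r],
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "datetime_local",
            "depth_m",
            "replicate",
            "lipid_class",
            "species",
            "concentration",
        ],
    )


# ---------------------------------------------------------------------------
# depth profiles
# ---------------------------------------------------------------------------

def generate_depth_profiles(
    config: GeneratorConfig,
    depths: Sequence[float] | None = None,
    n_cycles: int = 4,
) -> pd.DataFrame:
    """Dawn and dusk concentration profiles over ``n_cycles`` day/night cycles.

    Columns: ``day, phase (dawn|dusk), depth_m, replicate, lipid_class,
    concentration``.  The dusk:dawn ratio at depth z follows
    ``1 + (F − 1)·exp(−z/λ)`` and the profiles converge below the photic
    depth.  Depths must be sorted ascending and non-negative.
    """
    z = np.asarray(config.depths if depths is None else depths, dtype=float)
    if np.any(z < 0):
        raise ValueError("depths must be non-negative")
    if np.any(np.diff(z) < 0):
        raise ValueError("depths must be sorted ascending")
    rng = _substream(config.seed, "depth_profiles")
    rows = []
    for spec in config.classes:
        for day in range(n_cycles):
            for phase, hour in (("dawn", config.dawn_hour), ("dusk", config.dusk_hour)):
                for depth in z:
                    c = _concentration(spec, hour, float(depth), config)
                    noise = _lognormal_noise(rng, config.noise_cv, config.replicates)
                    for r in range(config.replicates):
                        rows.append(
                            (day, phase, float(depth), r + 1, spec.name, c * noise[r])
                        )
    return pd.DataFrame(
        rows, columns=["day", "phase", "depth_m", "replicate", "lipid_class", "concentration"]
    )


# ---------------------------------------------------------------------------
# particle size distributions
# ---------------------------------------------------------------------------

def generate_psd_series(
    config: GeneratorConfig,
    base_biovolume_ppm: float = 0.07,
    daily_amplitude_ppm: float = 0.025,
    n_bins: int = 32,
    bin_range_um: tuple[float, float] = (1.25, 250.0),
    samples_per_hour: int = 1,
) -> pd.DataFrame:
    """Hourly particle-volume concentrations in log-spaced size bins.

    The total 2–20 µm biovolume follows a triangular diel cycle: linear rise
    from ``base_biovolume_ppm`` at dawn to ``base + daily_amplitude_ppm`` at
    dusk, then a linear fall back to the base by the next dawn, so that the
    noiseless dusk − dawn difference equals the amplitude exactly.  Volume is
    distributed over the 2–20 µm bins with fixed weights; bins outside the
    size class carry a static background.  Columns: ``time, bin_lower_um,
    bin_upper_um, volume_ppm``.
    """
    if daily_amplitude_ppm < 0 or base_biovolume_ppm <= 0:
        raise ValueError("biovolume levels must be positive (amplitude >= 0)")
    if bin_range_um[0] <= 0:
        raise ValueError("bin edges must be positive")
    rng = _substream(config.seed, "psd_series")
    edges = np.geomspace(bin_range_um[0], bin_range_um[1], n_bins + 1)
    lower, upper = edges[:-1], edges[1:]
    in_class = (lower >= 2.0) & (upper <= 20.0)
    if not np.any(in_class):
        raise ValueError("no bins fall inside the 2-20 um size class")

    # fixed within-class weights peaking mid-class (log-space triangular)
    centers = np.sqrt(lower * upper)
    w = np.zeros(n_bins)
    lc = np.log(centers[in_class])
    w_in = 1.0 - np.abs(lc - lc.mean()) / (np.ptp(lc) / 2 + 1e-12)
    w[in_class] = np.clip(w_in, 0.05, None)
    w[in_class] /= w[in_class].sum()
    background = 0.01 * base_biovolume_ppm  # per out-of-class bin

    hours = np.arange(0, config.n_days * 24, 1.0 / samples_per_hour)
    day_frac = np.mod(hours, 24.0)
    rise = (day_frac - config.dawn_hour) / (config.dusk_hour - config.dawn_hour)
    fall = 1.0 - (day_frac - config.dusk_hour) / (24.0 - (config.dusk_hour - config.dawn_hour))
    pre_dawn = (day_frac + 24.0 - config.dusk_hour) / (24.0 - (config.dusk_hour - config.dawn_hour))
    shape = np.where(
        (day_frac >= config.dawn_hour) & (day_frac <= config.dusk_hour),
        np.clip(rise, 0, 1),
        np.where(day_frac > config.dusk_hour, np.clip(fall, 0, 1), np.clip(1.0 - pre_dawn, 0, 1)),
    )
    total = base_biovolume_ppm + daily_amplitude_ppm * shape

    rows = []
    for h, tot in zip(hours, total):
        ts = _EPOCH + pd.Timedelta(hours=float(h))
        noise = _lognormal_noise(rng, config.noise_cv, n_bins)
        vols = np.where(in_class, tot * w, background) * noise
        for b in range(n_bins):
            rows.append((ts, lower[b], upper[b], vols[b]))
    return pd.DataFrame(rows, columns=["time", "bin_lower_um", "bin_upper_um", "volume_ppm"])


# ---------------------------------------------------------------------------
# primary production incubations and transcript tables
# ---------------------------------------------------------------------------

#: Table-1-like clade mix used for synthetic transcript tables (fractions).
DEFAULT_CLADE_MIX: dict[str, float] = {
    "Dinophyceae": 0.425,
    "Haptophytes": 0.253,
    "Heterokonts": 0.121,
    "Opisthokonts_glaucophytes_cryptophytes": 0.064,
    "Alveolates": 0.044,
    "Bacillariophyta": 0.032,
    "Viridiplantae": 0.014,
    "Other": 0.047,
}


def generate_pp_tables(
    config: GeneratorConfig,
    light_pp_mean: float = 16.0,
    light_pp_sd: float = 1.5,
    dark_fraction_mean: float = 0.04,
    dark_fraction_sd: float = 0.01,
    night_respiration_fraction: float = 0.4,
    night_respiration_sd: float = 0.05,
    transcript_total_per_l: float = 6.4e5,
    clade_mix: dict[str, float] | None = None,
    sample_volume_l: float = 2.0,
) -> dict[str, pd.DataFrame]:
    """Synthetic ¹⁴C incubation results and transcript count tables.

    Returns ``{"incubations": ..., "transcripts": ...}``.  Per day and
    replicate, the light-bottle dawn→dusk activity is drawn around
    ``light_pp_mean`` (mg C m⁻³ d⁻¹); the parallel dark bottle measures
    ``dark_fraction`` of the light rate; the 24-h light+dark activity equals
    the 12-h activity minus the injected night respiration, so the
    light−dark difference recovers the respiration and is never negative.
    Transcript counts come with internal-standard added/recovered amounts so
    that recovery-normalised counts per liter can be reconstructed.
    """
    rng = _substream(config.seed, "pp_tables")
    mix = DEFAULT_CLADE_MIX if clade_mix is None else clade_mix
    inc_rows = []
    for day in range(config.n_days):
        for r in range(config.replicates):
            light = max(rng.normal(light_pp_mean, light_pp_sd), 0.1)
            dark_frac = float(np.clip(rng.normal(dark_fraction_mean, dark_fraction_sd), 0.0, 0.5))
            resp_frac = float(
                np.clip(rng.normal(night_respiration_fraction, night_respiration_sd), 0.0, 1.0)
            )
            respiration = resp_frac * light
            inc_rows.append(
                (
                    day,
                    float(config.depths[0]),
                    r + 1,
                    light,
                    dark_frac * light,
                    light - respiration,  # 24-h activity <= 12-h activity
                )
            )
    incubations = pd.DataFrame(
        inc_rows,
        columns=["day", "depth_m", "replicate", "light_12h", "dark_12h", "light_dark_24h"],
    )

    tr_rows = []
    for day in range(config.n_days):
        recovery = float(rng.uniform(0.2, 0.6))
        added = 1.0e5
        for clade, frac in mix.items():
            true_per_l = transcript_total_per_l * frac
            observed = rng.poisson(true_per_l * sample_volume_l * recovery)
            tr_rows.append((day, clade, int(observed), added, added * recovery, sample_volume_l))
    transcripts = pd.DataFrame(
        tr_rows,
        columns=["day", "clade", "counts", "standards_added", "standards_recovered", "volume_l"],
    )
    return {"incubations": incubations, "transcripts": transcripts}
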