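"""Synthetic copepodamide datasets with the structure the analysis assumes.

Emulates the study design — six freshwater and four marine sites, each
contributing one bulk zooplankton extract (precursor-ion scan) and a set of
individually extracted copepods (targeted MRM areas plus taxon, site and
prosome-length metadata) — together with a calibration-standard record and a
ground-truth ledger kept separate from the observables.

The generative model:

* Each habitat has a compound profile (relative abundances over library
  species). Freshwater profiles are dominated by dhCA scaffolds (CA fraction
  at most a couple of percent by default); marine profiles mix CA and dhCA
  roughly 40/60.
* Bulk scans place peaks at theoretical precursor m/z plus Gaussian m/z
  error, with lognormal multiplicative intensity noise, plus uniform
  background peaks over the scan window that avoid library masses.
* Each individual has a taxon, a prosome length drawn from the taxon's
  length distribution, a dry mass from a power-law length-weight model, a
  total copepodamide content from an ln-ln allometry with lognormal scatter,
  compound amounts splitting the total by the habitat profile blended with a
  taxon-consistent perturbation, and observed MRM areas equal to amount x
  response factor x lognormal noise.

All randomness flows from one seed through deterministically derived
per-site/per-individual substreams, so regeneration is reproducible and
partial regeneration stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import SCAFFOLDS, FattyAcyl, LipidSpecies, enumerate_library

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "default_config",
    "simulate_bulk_scan",
    "simulate_individuals",
    "simulate_dataset",
    "FRESHWATER_PROFILE",
    "MARINE_PROFILE",
]


def _species(name: str) -> LipidSpecies:
    acyl, scaffold = name.split(" ")
    return LipidSpecies(SCAFFOLDS[scaffold], FattyAcyl.from_label(acyl))


#: Default freshwater profile: almost exclusively dhCA (1% CA), variable
#: saturation, some odd-chain acyls.
FRESHWATER_PROFILE: Mapping[str, float] = {
    "18:4 dhCA": 0.18,
    "18:3 dhCA": 0.14,
    "18:2 dhCA": 0.10,
    "18:5 dhCA": 0.08,
    "16:0 dhCA": 0.12,
    "14:0 dhCA": 0.08,
    "17:0 dhCA": 0.06,
    "15:0 dhCA": 0.05,
    "20:5 dhCA": 0.07,
    "22:6 dhCA": 0.07,
    "20:4 dhCA": 0.04,
    "22:6 CA": 0.005,
    "20:5 CA": 0.005,
}

#: Default marine profile: CA/dhCA mixed ~40/60, dominated by long-chain
#: polyunsaturated omega-3 acyls.
MARINE_PROFILE: Mapping[str, float] = {
    "22:6 dhCA": 0.16,
    "20:5 dhCA": 0.14,
    "18:4 dhCA": 0.10,
    "16:0 dhCA": 0.06,
    "14:0 dhCA": 0.08,
    "18:1 dhCA": 0.06,
    "22:6 CA": 0.12,
    "20:5 CA": 0.10,
    "18:4 CA": 0.07,
    "16:0 CA": 0.05,
    "18:0 CA": 0.06,
}

#: Taxon pools per habitat: (taxon, sampling weight, prosome length mean um,
#: length sd um). Length scales are typical for adult cyclopoid/calanoid
#: copepods.
FRESHWATER_TAXA: Sequence[tuple[str, float, float, float]] = (
    ("Cyclops strenuus", 0.50, 1400.0, 250.0),
    ("Cyclopoida sp.", 0.25, 800.0, 150.0),
    ("Eudiaptomus graciloides", 0.15, 1100.0, 180.0),
    ("Macrocyclops albidus", 0.10, 1900.0, 300.0),
)
MARINE_TAXA: Sequence[tuple[str, float, float, float]] = (
    ("Temora longicornis", 0.40, 1000.0, 180.0),
    ("Centropages hamatus", 0.20, 1300.0, 220.0),
    ("Calanus sp.", 0.25, 2500.0, 350.0),
    ("Acartia sp.", 0.15, 750.0, 120.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator. Seeds fully determine the output."""

    seed: int = 0
    n_freshwater_sites: int = 6
    n_marine_sites: int = 4
    n_individuals_per_site: int = 12
    freshwater_profile: Mapping[str, float] = field(default_factory=lambda: dict(FRESHWATER_PROFILE))
    marine_profile: Mapping[str, float] = field(default_factory=lambda: dict(MARINE_PROFILE))
    taxon_effect: float = 0.5  # strength of taxon-specific profile perturbation
    mz_error_sd: float = 0.02  # Gaussian m/z error, Da
    intensity_sigma: float = 0.3  # lognormal sigma for peak intensities
    area_sigma: float = 0.2  # lognormal sigma for MRM areas
    background_rate: float = 2.0  # background peaks per 100 Da of scan window
    scan_window: tuple[float, float] = (600.0, 1000.0)
    mz_tolerance: float = 0.3  # screening tolerance; background avoids 2x this
    allometry_slope: float = 0.3  # ln(total pmol) per ln(dry mass ug)
    allometry_intercept: float = 0.25
    allometry_sigma: float = 0.5  # lognormal scatter of total content
    lw_a: float = 30.0  # length-weight W = a * (L/1000)^b, ug
    lw_b: float = 2.5
    response_factor: float = 500.0  # area units per pmol
    standard_pmol: float = 10.0
    bulk_total_intensity: float = 1e6

    def noiseless(self) -> "SimulationConfig":
        """Copy with every stochastic nuisance switched off (for end-to-end
        ground-truth identity checks)."""
        return replace(
            self, mz_error_sd=0.0, intensity_sigma=0.0, area_sigma=0.0,
            background_rate=0.0, allometry_sigma=0.0,
        )

    def validate(self, library: Sequence[LipidSpecies]) -> None:
        names = {sp.name for sp in library}
        for label, profile in (("freshwater", self.freshwater_profile),
                               ("marine", self.marine_profile)):
            if not profile:
                raise ValueError(f"{label} profile is empty")
            values = np.array(list(profile.values()), dtype=float)
            if (values < 0).any():
                raise ValueError(f"{label} profile has negative weights")
            if abs(values.sum() - 1.0) > 1e-6:
                raise ValueError(f"{label} profile must sum to 1")
            missing = set(profile) - names
            if missing:
                raise ValueError(
                    f"{label} profile references compounds outside the "
                    f"library: {sorted(missing)}"
                )


def default_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(seed=seed)


@dataclass
class SyntheticDataset:
    """Observables plus a separate ground-truth ledger."""

    config: SimulationConfig
    sites: pd.DataFrame  # site, habitat
    bulk_scans: dict[str, pd.DataFrame]  # site -> peak table (mz, intensity, channel)
    mrm: pd.DataFrame  # individual_id, compound, area
    metadata: pd.DataFrame  # individual_id, taxon, site, habitat, prosome_length_um
    standard_area: float
    truth: dict  # ground-truth ledger


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *key]))


def _habitat_profile(config: SimulationConfig, habitat: str) -> dict[str, float]:
    return dict(
        config.freshwater_profile if habitat == "freshwater" else config.marine_profile
    )


def _taxon_perturbation(config: SimulationConfig, taxon: str,
                        compounds: Sequence[str]) -> np.ndarray:
    """Stable per-taxon lognormal reweighting of the habitat profile.

    Seeded from the dataset seed and a hash of the taxon name only, so the
    same taxon carries the same signature at every site and time point.
    """
    taxon_key = int.from_bytes(taxon.encode()[:4].ljust(4, b"\0"), "big")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1000003, taxon_key]))
    return rng.normal(size=len(compounds))


def _blend(profile: np.ndarray, z: np.ndarray, effect: float) -> np.ndarray:
    w = profile * np.exp(effect * z)
    return w / w.sum()


def site_table(config: SimulationConfig) -> pd.DataFrame:
    sites = [
        {"site": f"F{i + 1}", "habitat": "freshwater"}
        for i in range(config.n_freshwater_sites)
    ] + [
        {"site": f"M{i + 1}", "habitat": "marine"}
        for i in range(config.n_marine_sites)
    ]
    return pd.DataFrame(sites)


def simulate_bulk_scan(
    config: SimulationConfig,
    site_index: int,
    habitat: str,
    library: Sequence[LipidSpecies] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """One bulk precursor-ion scan for a site.

    Returns (peak table, true compound intensity shares). Peaks carry the
    diagnostic product channel of their scaffold; background peaks avoid
    library precursor masses by 2x the screening tolerance and are assigned
    a random channel.
    """
    if library is None:
        library = enumerate_library()
    config.validate(library)
    by_name = {sp.name: sp for sp in library}
    profile = _habitat_profile(config, habitat)
    rng = _rng(config, 1, site_index)

    names = list(profile)
    weights = np.array([profile[n] for n in names], dtype=float)
    noise = (
        rng.lognormal(mean=0.0, sigma=config.intensity_sigma, size=len(names))
        if config.intensity_sigma > 0
        else np.ones(len(names))
    )
    intensities = config.bulk_total_intensity * weights * noise
    rows = []
    for name, intensity in zip(names, intensities):
        sp = by_name[name]
        mz = sp.precursor_mz + (
            rng.normal(scale=config.mz_error_sd) if config.mz_error_sd > 0 else 0.0
        )
        rows.append({"mz": mz, "intensity": intensity, "channel": sp.scaffold.channel})

    lo, hi = config.scan_window
    n_background = rng.poisson(config.background_rate * (hi - lo) / 100.0)
    exclusion = 2.0 * config.mz_tolerance
    library_mz = np.array([sp.precursor_mz for sp in library])
    placed = 0
    while placed < n_background:
        mz = rng.uniform(lo, hi)
        if np.abs(library_mz - mz).min() <= exclusion:
            continue
        channel = rng.choice([SCAFFOLDS["CA"].channel, SCAFFOLDS["dhCA"].channel])
        intensity = config.bulk_total_intensity * 0.01 * rng.lognormal(sigma=1.0)
        rows.append({"mz": mz, "intensity": intensity, "channel": channel})
        placed += 1

    peaks = pd.DataFrame(rows, columns=["mz", "intensity", "channel"])
    peaks = peaks.sort_values("mz", kind="stable").reset_index(drop=True)
    shares = dict(zip(names, intensities / intensities.sum()))
    return peaks, shares


def simulate_individuals(
    config: SimulationConfig,
    site_index: int,
    site: str,
    habitat: str,
    library: Sequence[LipidSpecies] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-individual MRM tables and metadata for one site.

    Returns (mrm table, metadata table, truth dict keyed by individual id
    with true_dry_mass_ug, true_total_pmol, true_amounts_pmol, taxon).
    """
    if library is None:
        library = enumerate_library()
    config.validate(library)
    profile = _habitat_profile(config, habitat)
    names = list(profile)
    base = np.array([profile[n] for n in names], dtype=float)
    base = base / base.sum()
    taxa = FRESHWATER_TAXA if habitat == "freshwater" else MARINE_TAXA
    taxon_weights = np.array([t[1] for t in taxa])
    taxon_weights = taxon_weights / taxon_weights.sum()
    rng = _rng(config, 2, site_index)

    mrm_rows, meta_rows = [], []
    truth: dict[str, dict] = {}
    for i in range(config.n_individuals_per_site):
        ind_id = f"{site}-{i + 1:03d}"
        t_idx = rng.choice(len(taxa), p=taxon_weights)
        taxon, _, length_mean, length_sd = taxa[t_idx]
        length = float(np.clip(rng.normal(length_mean, length_sd), 200.0, None))
        mass = config.lw_a * (length / 1000.0) ** config.lw_b
        ln_total = (
            config.allometry_intercept
            + config.allometry_slope * np.log(mass)
            + (rng.normal(scale=config.allometry_sigma)
               if config.allometry_sigma > 0 else 0.0)
        )
        total_pmol = float(np.exp(ln_total))
        z = _taxon_perturbation(config, taxon, names)
        shares = _blend(base, z, config.taxon_effect)
        amounts = total_pmol * shares  # sums to total before measurement noise
        area_noise = (
            rng.lognormal(sigma=config.area_sigma, size=len(names))
            if config.area_sigma > 0
            else np.ones(len(names))
        )
        areas = amounts * config.response_factor * area_noise

        for name, area in zip(names, areas):
            mrm_rows.append({"individual_id": ind_id, "compound": name, "area": area})
        meta_rows.append(
            {
                "individual_id": ind_id,
                "taxon": taxon,
                "site": site,
                "habitat": habitat,
                "prosome_length_um": length,
            }
        )
        truth[ind_id] = {
            "taxon": taxon,
            "true_dry_mass_ug": mass,
            "true_total_pmol": total_pmol,
            "true_amounts_pmol": dict(zip(names, amounts.tolist())),
        }
    mrm_df = pd.DataFrame(mrm_rows, columns=["individual_id", "compound", "area"])
    meta_df = pd.DataFrame(
        meta_rows,
        columns=["individual_id", "taxon", "site", "habitat", "prosome_length_um"],
    )
    return mrm_df, meta_df, truth


def simulate_dataset(
    config: SimulationConfig, library: Sequence[LipidSpecies] | None = None
) -> SyntheticDataset:
    """The full synthetic study: bulk scans, individuals, calibration."""
    if library is None:
        library = enumerate_library()
    config.validate(library)
    sites = site_table(config)

    bulk_scans: dict[str, pd.DataFrame] = {}
    truth: dict = {"bulk_shares": {}, "individuals": {}, "profiles": {
        "freshwater": dict(config.freshwater_profile),
        "marine": dict(config.marine_profile),
    }}
    mrm_parts, meta_parts = [], []
    for idx, row in enumerate(sites.itertuples(index=False)):
        peaks, shares = simulate_bulk_scan(config, idx, row.habitat, library)
        bulk_scans[row.site] = peaks
        truth["bulk_shares"][row.site] = shares
        mrm, meta, ind_truth = simulate_individuals(
            config, idx, row.site, row.habitat, library
        )
        mrm_parts.append(mrm)
        meta_parts.append(meta)
        truth["individuals"].update(ind_truth)

    std_rng = _rng(config, 3)
    area_noise = (
        std_rng.lognormal(sigma=config.area_sigma) if config.area_sigma > 0 else 1.0
    )
    standard_area = config.standard_pmol * config.response_factor * area_noise
    truth["response_factor"] = config.response_factor

    return SyntheticDataset(
        config=config,
        sites=sites,
        bulk_scans=bulk_scans,
        mrm=pd.concat(mrm_parts, ignore_index=True) if mrm_parts else pd.DataFrame(columns=["individual_id", "compound", "area"]),
        metadata=pd.concat(meta_parts, ignore_index=True) if meta_parts else pd.DataFrame(columns=["individual_id", "taxon", "site", "habitat", "prosome_length_um"]),
        standard_area=float(standard_area),
        truth=truth,
    )
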