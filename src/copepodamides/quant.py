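"""Quantification of copepodamides in individually extracted copepods.

Peak areas from targeted MRM runs are converted to amounts by single-point
external calibration against an authentic copepodamide standard, applying the
same response factor to every compound (equal ionisation efficiency
assumption). Individual dry mass is estimated from prosome length through
taxon-specific power-law length-weight regressions, and content is summarised
as total pmol, total ng, and mass fraction in parts per thousand (ppt) of dry
mass. An ln-ln ordinary least squares regression relates total content to
body mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import PROTON_MASS, LipidSpecies

__all__ = [
    "CalibrationStandard",
    "LengthWeightModel",
    "DEFAULT_LENGTH_WEIGHT",
    "CopepodRecord",
    "quantify",
    "pmol_to_ng",
    "dry_mass",
    "content_metrics",
    "allometric_regression",
    "quantify_individuals",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationStandard:
    """Authentic-standard calibration point: known amount and measured area.

    The derived response factor (area per pmol) is applied uniformly to all
    compounds. Single-point calibration through the origin.
    """

    amount_pmol: float
    area: float

    def __post_init__(self) -> None:
        if self.amount_pmol <= 0:
            raise ValueError("standard amount must be positive")

    @property
    def response_factor(self) -> float:
        return self.area / self.amount_pmol


@dataclass(frozen=True)
class LengthWeightModel:
    """Power-law length-weight regression W = a * L^b, W in ug dry mass and
    L the prosome length in mm.

    ``source`` records provenance; the packaged default coefficients are a
    synthetic placeholder on the right order of magnitude for adult copepods,
    not a literature regression — real analyses must supply collated
    coefficients per taxon.
    """

    taxon: str
    a: float
    b: float
    source: str = "user"

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("length-weight coefficients must be positive")


DEFAULT_LENGTH_WEIGHT = LengthWeightModel(
    "default", a=30.0, b=2.5, source="synthetic placeholder (non-authoritative)"
)


def quantify(area: float, standard: CalibrationStandard) -> float:
    """Peak area -> amount in pmol via the standard's response factor."""
    if area < 0:
        raise ValueError("area must be non-negative")
    rf = standard.response_factor
    if rf <= 0:
        raise ValueError("response factor must be positive")
    return area / rf


def pmol_to_ng(amount_pmol: float, species: LipidSpecies) -> float:
    """Convert pmol to ng using the neutral monoisotopic mass of the species.

    ng = pmol * M(g/mol) * 1e-3, with M = precursor cation mass - proton.
    Monoisotopic rather than average mass; the difference is < 0.1% for
    these species.
    """
    if amount_pmol < 0:
        raise ValueError("amount must be non-negative")
    return amount_pmol * (species.precursor_mz - PROTON_MASS) * 1e-3


def dry_mass(
    length_um: float,
    model: LengthWeightModel | Mapping[str, LengthWeightModel],
    taxon: str | None = None,
) -> float:
    """Estimate dry mass (ug) from prosome length (um).

    The length is converted to mm before applying W = a * L^b. When a
    mapping of per-taxon models is given, the taxon's model is used, falling
    back to the entry named "default"; a missing model is an error naming
    the taxon.
    """
    if length_um <= 0:
        raise ValueError("prosome length must be positive")
    if isinstance(model, LengthWeightModel):
        chosen = model
    else:
        chosen = model.get(taxon) or model.get("default")
        if chosen is None:
            raise KeyError(
                f"no length-weight model for taxon {taxon!r} and no default"
            )
    return chosen.a * (length_um / 1000.0) ** chosen.b


@dataclass
class CopepodRecord:
    """One individually extracted copepod with its derived content metrics."""

    individual_id: str
    taxon: str
    site: str
    habitat: str  # freshwater | marine
    prosome_length_um: float
    dry_mass_ug: float
    amounts_pmol: dict[str, float] = field(default_factory=dict)
    lw_source: str = "user"

    @property
    def total_pmol(self) -> float:
        return float(sum(self.amounts_pmol.values()))


def content_metrics(
    amounts_pmol: Mapping[str, float],
    species_by_name: Mapping[str, LipidSpecies],
    dry_mass_ug: float,
) -> tuple[float, float, float]:
    """Total content as (pmol, ng, ppt of dry mass).

    ppt = total ng / (dry mass in ug * 1000 ng/ug) * 1000 — the mass
    fraction in parts per thousand, numerically total_ng / dry_mass_ug.
    """
    if dry_mass_ug <= 0:
        raise ValueError("dry mass must be positive")
    total_pmol = float(sum(amounts_pmol.values()))
    total_ng = float(
        sum(
            pmol_to_ng(amount, species_by_name[name])
            for name, amount in amounts_pmol.items()
        )
    )
    ppt = total_ng / (dry_mass_ug * 1000.0) * 1000.0
    return total_pmol, total_ng, ppt


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    n_dropped: int = 0
    covariate_slope: float | None = None
    covariate_p: float | None = None


def allometric_regression(
    total_pmol: Sequence[float],
    dry_mass_ug: Sequence[float],
    covariate: Sequence[float] | None = None,
) -> RegressionResult:
    """OLS of ln(total pmol) on ln(dry mass ug), optionally with an extra
    linear covariate (e.g. handling time from sampling to extraction).

    Records with non-positive content or mass cannot be log-transformed and
    are dropped with a logged count.
    """
    import statsmodels.api as sm

    y = np.asarray(total_pmol, dtype=float)
    x = np.asarray(dry_mass_ug, dtype=float)
    cov = None if covariate is None else np.asarray(covariate, dtype=float)
    keep = (y > 0) & (x > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("allometric_regression: dropped %d non-positive records",
                       n_dropped)
    y, x = np.log(y[keep]), np.log(x[keep])
    if cov is not None:
        cov = cov[keep]
    if y.size < 3:
        raise ValueError("need at least 3 records with positive values")

    if np.ptp(y) == 0:  # constant response: flat line, no variance explained
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0,
            n=int(y.size), n_dropped=n_dropped,
        )

    X = x[:, None] if cov is None else np.column_stack([x, cov])
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=int(y.size),
        n_dropped=n_dropped,
        covariate_slope=float(model.params[2]) if cov is not None else None,
        covariate_p=float(model.pvalues[2]) if cov is not None else None,
    )


def quantify_individuals(
    mrm: pd.DataFrame,
    metadata: pd.DataFrame,
    standard: CalibrationStandard,
    species_by_name: Mapping[str, LipidSpecies],
    lw_models: Mapping[str, LengthWeightModel] | LengthWeightModel = DEFAULT_LENGTH_WEIGHT,
) -> pd.DataFrame:
    """Full per-individual quantification table.

    ``mrm`` has columns individual_id, compound, area; ``metadata`` has
    individual_id, taxon, site, habitat, prosome_length_um. Returns one row
    per individual with per-compound pmol columns plus dry_mass_ug,
    total_pmol, total_ng and ppt_dry_mass.
    """
    amounts = mrm.copy()
    amounts["pmol"] = [quantify(a, standard) for a in amounts["area"]]
    wide = amounts.pivot_table(
        index="individual_id", columns="compound", values="pmol",
        aggfunc="sum", fill_value=0.0,
    )

    rows = []
    for row in metadata.itertuples(index=False):
        mass = dry_mass(row.prosome_length_um, lw_models, getattr(row, "taxon", None))
        per_compound = (
            wide.loc[row.individual_id].to_dict()
            if row.individual_id in wide.index
            else {}
        )
        total_pmol, total_ng, ppt = (
            content_metrics(per_compound, species_by_name, mass)
            if per_compound
            else (0.0, 0.0, 0.0)
        )
        rows.append(
            {
                "individual_id": row.individual_id,
                "taxon": row.taxon,
                "site": row.site,
                "habitat": row.habitat,
                "prosome_length_um": row.prosome_length_um,
                "dry_mass_ug": mass,
                **{f"pmol {k}": v for k, v in per_compound.items()},
                "total_pmol": total_pmol,
                "total_ng": total_ng,
                "ppt_dry_mass": ppt,
            }
        )
    return pd.DataFrame(rows)
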