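"""Packaged reference list of reported copepodamides.

The reference table collates the 35 copepodamides reported from bulk
zooplankton screening of six freshwater and four marine sites: scaffold,
putative fatty acyl, reported precursor m/z, prior attribution
(``Grebner2019`` for previously described species, ``ThisStudy`` for the 10
newly reported ones), and habitat occurrence class (``F`` freshwater-only,
``M`` marine-only, ``B`` both). ``single_sample`` flags the one compound seen
in a single sample; it is carried as information only, no filter uses it.

Reported m/z are stored as printed (measured, unit-resolution values);
``validate_reference`` compares them with the formula-derived theoretical
masses. The default 0.2 Da bound accommodates the unit-resolution rounding of
the printed values (the largest observed deviation is 0.198 Da for 22:6 CA).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .chem import SCAFFOLDS, FattyAcyl, LipidSpecies

__all__ = ["load_reference", "validate_reference", "reference_species"]

#: Validation bound for |reported - theoretical| precursor m/z, in Da.
REPORTED_MZ_TOLERANCE = 0.2


def load_reference() -> pd.DataFrame:
    """Load the packaged reference compound table.

    Returns a DataFrame with columns scaffold, acyl, reported_mz,
    described_in, present_in, single_sample, plus derived columns name and
    theoretical_mz.
    """
    with resources.files("copepodamides.data").joinpath(
        "reference_compounds.csv"
    ).open() as fh:
        df = pd.read_csv(fh, dtype={"acyl": str})
    species = [
        LipidSpecies(SCAFFOLDS[s], FattyAcyl.from_label(a))
        for s, a in zip(df["scaffold"], df["acyl"])
    ]
    df["name"] = [sp.name for sp in species]
    df["theoretical_mz"] = [sp.precursor_mz for sp in species]
    return df


def validate_reference(
    df: pd.DataFrame | None = None, tolerance: float = REPORTED_MZ_TOLERANCE
) -> pd.DataFrame:
    """Check reported m/z against formula-derived theory.

    Returns the table with a ``mz_delta`` column (reported - theoretical);
    raises ``ValueError`` if any |delta| exceeds ``tolerance``.
    """
    if df is None:
        df = load_reference()
    df = df.copy()
    df["mz_delta"] = df["reported_mz"] - df["theoretical_mz"]
    bad = df[df["mz_delta"].abs() > tolerance]
    if not bad.empty:
        names = ", ".join(bad["name"])
        raise ValueError(
            f"reported m/z deviates from theory by > {tolerance} Da for: {names}"
        )
    return df


def reference_species(df: pd.DataFrame | None = None) -> list[LipidSpecies]:
    """The reference table as LipidSpecies objects (the known-compound list
    merged into MRM target selection)."""
    if df is None:
        df = load_reference()
    return [
        LipidSpecies(SCAFFOLDS[s], FattyAcyl.from_label(a))
        for s, a in zip(df["scaffold"], df["acyl"])
    ]
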