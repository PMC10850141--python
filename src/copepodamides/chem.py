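"""Chemistry core for copepodamide homologs.

Copepodamides are taurine-conjugated lipids produced by copepods. They share a
common scaffold that fragments, under collision-induced dissociation, into a
charged diagnostic ion — C22H40NO5S (m/z ~430.3) for the copepodamide (CA)
scaffold, C22H42NO5S (m/z ~432.3) for the dihydro-copepodamide (dhCA)
scaffold, the two differing by two hydrogens at C3 — while the variable fatty
acyl esterified at C5 departs as a neutral free fatty acid. The [M+H]+
precursor m/z of a species is therefore the scaffold fragment cation mass plus
the neutral fatty-acid mass, and the neutral loss in an MS/MS experiment
identifies the acyl group.

This module provides monoisotopic formula arithmetic, homolog enumeration over
chain length x unsaturation, precursor/product m/z computation, neutral-loss
acyl assignment, and MRM transition construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ELEMENT_MASSES",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "Formula",
    "FattyAcyl",
    "Scaffold",
    "LipidSpecies",
    "Transition",
    "CA",
    "DHCA",
    "SCAFFOLDS",
    "TAURINE_FRAGMENT_MZ",
    "SULFONATE_FRAGMENT_MZ",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "fatty_acid_formula",
    "fatty_acid_mass",
    "precursor_mz",
    "neutral_mass",
    "enumerate_library",
    "assign_acyl",
    "build_transitions",
    "transitions_to_frame",
]

#: Monoisotopic atomic masses in Da (CODATA / AME2020 values).
ELEMENT_MASSES: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
}

ELECTRON_MASS: float = 0.000548579909  # Da
PROTON_MASS: float = ELEMENT_MASSES["H"] - ELECTRON_MASS  # Da

#: A molecular formula is a plain mapping of element symbol -> count.
Formula = Mapping[str, int]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownElementError(KeyError):
    """Raised when a formula references an element without a tabulated mass."""


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-style formula string ("C22H42NO5S") into a count map."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"unparseable formula {text!r} at position {pos}")
        pos = match.end()
        symbol, digits = match.groups()
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
    if pos != len(text):
        raise ValueError(f"unparseable formula {text!r} at position {pos}")
    return counts


def format_formula(formula: Formula) -> str:
    """Format a count map in Hill order (C, H, then alphabetical)."""
    symbols = sorted(formula, key=lambda s: (s != "C", s != "H", s))
    parts = []
    for sym in symbols:
        n = formula[sym]
        if n == 0:
            continue
        parts.append(sym if n == 1 else f"{sym}{n}")
    return "".join(parts)


def monoisotopic_mass(formula: Formula | str, charge_mode: str = "neutral") -> float:
    """Monoisotopic mass of a formula in Da.

    ``charge_mode="cation"`` subtracts one electron mass: the printed
    diagnostic fragment compositions (C22H42NO5S -> 432, C22H40NO5S -> 430)
    are the *charged* fragment compositions, so their m/z is the summed
    atomic mass minus one electron, not a protonated neutral.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    total = 0.0
    for symbol, count in formula.items():
        if count < 0:
            raise ValueError(f"negative count for element {symbol}")
        try:
            total += count * ELEMENT_MASSES[symbol]
        except KeyError:
            raise UnknownElementError(symbol) from None
    if charge_mode == "cation":
        total -= ELECTRON_MASS
    elif charge_mode != "neutral":
        raise ValueError(f"unknown charge_mode {charge_mode!r}")
    return total


@dataclass(frozen=True, order=True)
class FattyAcyl:
    """A fatty acyl chain: ``carbons`` carbons with ``double_bonds`` C=C bonds.

    Labelled "C:D" in lipid shorthand, e.g. 22:6 for docosahexaenoyl.
    """

    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"acyl needs >= 2 carbons, got {self.carbons}")
        max_db = (self.carbons - 2) // 2
        if not 0 <= self.double_bonds <= max_db:
            raise ValueError(
                f"double bonds must be in [0, {max_db}] for {self.carbons} "
                f"carbons, got {self.double_bonds}"
            )

    @property
    def label(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"

    @classmethod
    def from_label(cls, label: str) -> "FattyAcyl":
        c, _, d = label.partition(":")
        return cls(int(c), int(d))


def fatty_acid_formula(acyl: FattyAcyl) -> dict[str, int]:
    """Formula of the neutral free fatty acid: C_n H_(2n-2d) O2."""
    return {"C": acyl.carbons, "H": 2 * acyl.carbons - 2 * acyl.double_bonds, "O": 2}


def fatty_acid_mass(acyl: FattyAcyl) -> float:
    """Neutral monoisotopic mass of the free fatty acid in Da."""
    return monoisotopic_mass(fatty_acid_formula(acyl))


@dataclass(frozen=True)
class Scaffold:
    """A copepodamide scaffold with its charged diagnostic fragment.

    ``diagnostic_product_mz`` is the exact fragment cation m/z; ``channel``
    is the unit-resolution product-ion channel the instrument monitors
    (430.3 for CA, 432.3 for dhCA).
    """

    name: str
    fragment_formula: Mapping[str, int] = field(hash=False)
    channel: float = 0.0

    @property
    def diagnostic_product_mz(self) -> float:
        return monoisotopic_mass(self.fragment_formula, "cation")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


CA = Scaffold("CA", parse_formula("C22H40NO5S"), channel=430.3)
DHCA = Scaffold("dhCA", parse_formula("C22H42NO5S"), channel=432.3)
SCAFFOLDS: Mapping[str, Scaffold] = {"CA": CA, "dhCA": DHCA}

TAURINE_FRAGMENT_MZ = monoisotopic_mass("C2H6NO3S", "cation")  # ~124.006
SULFONATE_FRAGMENT_MZ = monoisotopic_mass("SO3", "cation")  # ~79.957


def precursor_mz(scaffold: Scaffold, acyl: FattyAcyl) -> float:
    """[M+H]+ precursor m/z: fragment cation mass + neutral fatty-acid mass.

    Equivalent to protonating the intact species whose collision-induced
    neutral loss is the free fatty acid.
    """
    return scaffold.diagnostic_product_mz + fatty_acid_mass(acyl)


@dataclass(frozen=True)
class LipidSpecies:
    """One copepodamide: scaffold x acyl, named "22:6 dhCA" style."""

    scaffold: Scaffold
    acyl: FattyAcyl

    @property
    def precursor_mz(self) -> float:
        return precursor_mz(self.scaffold, self.acyl)

    @property
    def name(self) -> str:
        return f"{self.acyl.label} {self.scaffold.name}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def neutral_mass(species: LipidSpecies) -> float:
    """Neutral monoisotopic mass of the intact species (precursor - proton)."""
    return species.precursor_mz - PROTON_MASS


def enumerate_library(
    chain_range: tuple[int, int] = (12, 24),
    unsat_range: tuple[int, int] = (0, 6),
    scaffolds: Iterable[Scaffold] = (CA, DHCA),
) -> list[LipidSpecies]:
    """All valid scaffold x acyl combinations within the given bounds.

    Defaults (chains 12-24, 0-6 double bonds) cover every reported
    copepodamide acyl with margin; odd chains and polyunsaturated acyls are
    enumerated uniformly with no plausibility filter. Sorted by
    (scaffold name, carbons, double_bonds), deduplicated.
    """
    c_lo, c_hi = chain_range
    d_lo, d_hi = unsat_range
    seen: set[tuple[str, int, int]] = set()
    out: list[LipidSpecies] = []
    for scaffold in scaffolds:
        for c in range(max(c_lo, 2), c_hi + 1):
            for d in range(max(d_lo, 0), min(d_hi, (c - 2) // 2) + 1):
                key = (scaffold.name, c, d)
                if key in seen:
                    continue
                seen.add(key)
                out.append(LipidSpecies(scaffold, FattyAcyl(c, d)))
    out.sort(key=lambda sp: (sp.scaffold.name, sp.acyl.carbons, sp.acyl.double_bonds))
    return out


@dataclass(frozen=True)
class Assignment:
    """Result of neutral-loss acyl assignment for one observed peak.

    ``status`` is "ok" when candidates exist, "no_scaffold" when the product
    ion matches neither diagnostic fragment, and "no_acyl" when the neutral
    loss matches no fatty acid in the library. Multiple candidates within
    tolerance (a collision) are all reported, sorted by absolute mass error.
    """

    status: str
    candidates: tuple[tuple[LipidSpecies, float], ...] = ()

    @property
    def best(self) -> LipidSpecies | None:
        return self.candidates[0][0] if self.candidates else None

    @property
    def best_error(self) -> float | None:
        return self.candidates[0][1] if self.candidates else None


def assign_acyl(
    observed_precursor: float,
    observed_product: float,
    tolerance: float = 0.3,
    library: Sequence[LipidSpecies] | None = None,
) -> Assignment:
    """Annotate an observed precursor/product pair by neutral loss.

    The product ion is matched to a scaffold diagnostic fragment within
    ``tolerance``; the neutral loss (precursor - product) is then matched
    against the free-fatty-acid masses of the library species on that
    scaffold. The default 0.3 Da tolerance suits unit-resolution
    triple-quadrupole data.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if library is None:
        library = enumerate_library()

    scaffold = None
    for cand in SCAFFOLDS.values():
        if abs(observed_product - cand.diagnostic_product_mz) <= tolerance:
            scaffold = cand
            break
    if scaffold is None:
        return Assignment("no_scaffold")

    loss = observed_precursor - observed_product
    if loss <= 0:
        raise ValueError(
            f"neutral loss must be positive (precursor {observed_precursor}, "
            f"product {observed_product})"
        )

    candidates = []
    for species in library:
        if species.scaffold.name != scaffold.name:
            continue
        error = loss - fatty_acid_mass(species.acyl)
        if abs(error) <= tolerance:
            candidates.append((species, error))
    if not candidates:
        return Assignment("no_acyl")
    candidates.sort(key=lambda pair: abs(pair[1]))
    return Assignment("ok", tuple(candidates))


@dataclass(frozen=True)
class Transition:
    """An MRM precursor -> product transition for one species.

    ``kind`` distinguishes the quantifier (scaffold fragment) from the
    confirmatory taurine (m/z ~124.0) and sulfonate (m/z ~80) transitions.
    """

    species: LipidSpecies
    product_mz: float
    kind: str  # scaffold | taurine | sulfonate

    @property
    def precursor_mz(self) -> float:
        return self.species.precursor_mz

    def __post_init__(self) -> None:
        if self.product_mz >= self.species.precursor_mz:
            raise ValueError("product m/z must be below precursor m/z")


def build_transitions(
    species: Sequence[LipidSpecies], include_confirmatory: bool = False
) -> list[Transition]:
    """One scaffold-fragment transition per species; optionally add the
    taurine and sulfonate confirmatory transitions."""
    out: list[Transition] = []
    for sp in species:
        out.append(Transition(sp, sp.scaffold.diagnostic_product_mz, "scaffold"))
        if include_confirmatory:
            out.append(Transition(sp, TAURINE_FRAGMENT_MZ, "taurine"))
            out.append(Transition(sp, SULFONATE_FRAGMENT_MZ, "sulfonate"))
    return out


def transitions_to_frame(transitions: Sequence[Transition]):
    """Vendor-neutral transition table (pandas DataFrame).

    Columns: compound_name, scaffold, acyl, precursor_mz, product_mz, kind.
    m/z values are carried at 4 decimals; coarser display rounding belongs to
    the caller's I/O layer.
    """
    import pandas as pd

    rows = [
        {
            "compound_name": t.species.name,
            "scaffold": t.species.scaffold.name,
            "acyl": t.species.acyl.label,
            "precursor_mz": round(t.precursor_mz, 4),
            "product_mz": round(t.product_mz, 4),
            "kind": t.kind,
        }
        for t in transitions
    ]
    return pd.DataFrame(rows, columns=["compound_name", "scaffold", "acyl", "precursor_mz", "product_mz", "kind"])
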