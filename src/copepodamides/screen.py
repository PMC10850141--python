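"""Screening of bulk precursor-ion scans for copepodamides.

Bulk zooplankton extracts are scanned over 600-1000 m/z for precursors that
yield the CA (430.3) or dhCA (432.3) diagnostic product ion. Each in-window
peak is annotated by neutral loss against the homolog library; the most
abundant annotated transitions, cumulatively making up at least 80% of the
annotated ion counts, are selected as MRM targets and merged with the
previously known copepodamides. Detections across samples feed a
presence/absence table classified by habitat occurrence (freshwater-only,
marine-only, or both).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem import LipidSpecies, assign_acyl, enumerate_library

__all__ = [
    "ScreenHit",
    "PresenceTable",
    "screen_sample",
    "select_transitions",
    "classify_presence",
    "count_novel",
    "presence_from_reference",
    "hits_to_frame",
]

#: Default precursor-ion scan window, half-open [low, high) in m/z.
DEFAULT_WINDOW = (600.0, 1000.0)


@dataclass(frozen=True)
class ScreenHit:
    """One peak from a precursor-ion scan, annotated where possible.

    ``species`` is None for peaks whose precursor/product pair matched no
    library compound; such peaks are retained for QC, never silently dropped.
    ``mass_error`` is the neutral-loss error in Da for annotated hits.
    """

    sample_id: str
    mz: float
    channel: float
    intensity: float
    species: LipidSpecies | None = None
    mass_error: float | None = None

    @property
    def annotated(self) -> bool:
        return self.species is not None


def screen_sample(
    spectrum: pd.DataFrame,
    library: Sequence[LipidSpecies] | None = None,
    sample_id: str = "sample",
    window: tuple[float, float] = DEFAULT_WINDOW,
    tolerance: float = 0.3,
) -> list[ScreenHit]:
    """Annotate one bulk precursor-ion scan.

    ``spectrum`` needs columns ``mz``, ``intensity`` and ``channel`` (the
    diagnostic product channel each peak produced, 430.3 or 432.3). Peaks
    outside the half-open window are dropped; each remaining peak is matched
    by scaffold channel and neutral loss. The window is applied to the
    observed peak m/z.
    """
    if library is None:
        library = enumerate_library()
    lo, hi = window
    hits: list[ScreenHit] = []
    for row in spectrum.itertuples(index=False):
        if not lo <= row.mz < hi:
            continue
        result = assign_acyl(row.mz, row.channel, tolerance, library)
        if result.status == "ok":
            hits.append(
                ScreenHit(sample_id, row.mz, row.channel, row.intensity,
                          result.best, result.best_error)
            )
        else:
            hits.append(ScreenHit(sample_id, row.mz, row.channel, row.intensity))
    return hits


def select_transitions(
    hits: Sequence[ScreenHit],
    threshold: float = 0.8,
    known: Sequence[LipidSpecies] = (),
) -> list[LipidSpecies]:
    """Select MRM targets by the cumulative-abundance rule.

    Annotated hits are ranked by intensity (ties broken by precursor m/z
    ascending); the minimal prefix whose cumulative intensity reaches
    ``threshold`` of the total annotated intensity is selected and unioned
    with the ``known`` reference species. "Total ion counts" here means the
    summed intensity of annotated, in-window hits.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    annotated = [h for h in hits if h.annotated]
    if not annotated:
        raise ValueError("no annotated hits to select from")
    total = sum(h.intensity for h in annotated)
    if total <= 0:
        raise ValueError("total annotated intensity is zero")

    # Aggregate duplicate annotations (several peaks matching one species).
    by_species: dict[str, tuple[LipidSpecies, float]] = {}
    for h in annotated:
        name = h.species.name
        prev = by_species.get(name)
        by_species[name] = (h.species, (prev[1] if prev else 0.0) + h.intensity)
    ranked = sorted(
        by_species.values(), key=lambda sv: (-sv[1], sv[0].precursor_mz)
    )

    selected: list[LipidSpecies] = []
    cumulative = 0.0
    for species, intensity in ranked:
        if cumulative >= threshold * total:
            break
        selected.append(species)
        cumulative += intensity

    names = {sp.name for sp in selected}
    for sp in known:
        if sp.name not in names:
            names.add(sp.name)
            selected.append(sp)
    return selected


@dataclass
class PresenceTable:
    """Compound x sample detection matrix with habitat occurrence classes.

    ``detections`` is a boolean DataFrame (compounds as rows, samples as
    columns); ``habitat_class`` maps each compound to F, M or B;
    ``n_samples_detected`` counts detections per compound.
    """

    detections: pd.DataFrame
    habitat_class: pd.Series
    n_samples_detected: pd.Series

    @property
    def counts(self) -> dict[str, int]:
        vc = self.habitat_class.value_counts()
        return {
            "total": int(len(self.habitat_class)),
            "F": int(vc.get("F", 0)),
            "M": int(vc.get("M", 0)),
            "B": int(vc.get("B", 0)),
        }


def classify_presence(
    hits: Iterable[ScreenHit], habitats: Mapping[str, str]
) -> PresenceTable:
    """Build the presence table from annotated hits across samples.

    ``habitats`` maps sample id -> "freshwater" | "marine". Detection means
    at least one annotated hit in at least one sample; compounds detected
    nowhere do not appear. A compound seen only in freshwater samples is
    classed F, only in marine M, in both B — so F + M + B = total always.
    """
    records = [
        (h.species.name, h.sample_id) for h in hits if h.annotated
    ]
    samples = list(habitats)
    for _, sid in records:
        if sid not in habitats:
            raise KeyError(f"sample {sid!r} has no habitat label")
    if not records:
        empty = pd.DataFrame(columns=samples, dtype=bool)
        return PresenceTable(empty, pd.Series(dtype=object), pd.Series(dtype=int))

    df = pd.DataFrame(records, columns=["compound", "sample"])
    detections = (
        pd.crosstab(df["compound"], df["sample"]).astype(bool)
        .reindex(columns=samples, fill_value=False)
    )
    fresh = [s for s in samples if habitats[s] == "freshwater"]
    marine = [s for s in samples if habitats[s] == "marine"]
    in_fresh = detections[fresh].any(axis=1)
    in_marine = detections[marine].any(axis=1)
    habitat_class = pd.Series("B", index=detections.index, dtype=object)
    habitat_class[in_fresh & ~in_marine] = "F"
    habitat_class[~in_fresh & in_marine] = "M"
    return PresenceTable(detections, habitat_class, detections.sum(axis=1))


def count_novel(reference: pd.DataFrame) -> tuple[int, int]:
    """Count newly described compounds and those also freshwater-only.

    Expects the packaged reference table columns ``described_in`` (values
    Grebner2019 / ThisStudy) and ``present_in`` (F / M / B).
    """
    new = reference["described_in"] == "ThisStudy"
    return int(new.sum()), int((new & (reference["present_in"] == "F")).sum())


def presence_from_reference(reference: pd.DataFrame) -> PresenceTable:
    """Reconstruct a presence table from the reference occurrence classes.

    Expands each compound's F/M/B class into detections in one synthetic
    freshwater and one synthetic marine sample, then reclassifies — a
    round-trip that recovers the published occurrence counts from the
    packaged table.
    """
    hits = []
    for row in reference.itertuples(index=False):
        from .chem import SCAFFOLDS, FattyAcyl

        sp = LipidSpecies(SCAFFOLDS[row.scaffold], FattyAcyl.from_label(row.acyl))
        if row.present_in in ("F", "B"):
            hits.append(ScreenHit("freshwater_pool", sp.precursor_mz,
                                  sp.scaffold.channel, 1.0, sp, 0.0))
        if row.present_in in ("M", "B"):
            hits.append(ScreenHit("marine_pool", sp.precursor_mz,
                                  sp.scaffold.channel, 1.0, sp, 0.0))
    return classify_presence(
        hits, {"freshwater_pool": "freshwater", "marine_pool": "marine"}
    )


def hits_to_frame(hits: Sequence[ScreenHit]) -> pd.DataFrame:
    """Hits as a flat table for CSV export (annotation may be empty)."""
    return pd.DataFrame(
        {
            "sample_id": [h.sample_id for h in hits],
            "mz": [round(h.mz, 4) for h in hits],
            "channel": [h.channel for h in hits],
            "intensity": [h.intensity for h in hits],
            "compound": [h.species.name if h.annotated else "" for h in hits],
            "mass_error": [
                round(h.mass_error, 4) if h.mass_error is not None else None
                for h in hits
            ],
        }
    )
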