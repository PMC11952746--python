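"""Reading, validating, and filtering per-animal cell-count tables.

Each animal contributes a tidy table of detected projection-neuron nuclei,
one row per (hemisphere, cortical area, layer), plus injection metadata.
Three exclusion rules are enforced:

1. Injection QC: the animal is excluded if more than 30% of the viral bolus
   lies outside the target area, or if white-matter transduction reaches
   0.1% of the bolus volume.
2. Minimum cell count: an area in a given hemisphere carrying fewer than 10
   cells (summed over layers) has all its counts set to zero.
3. Cohort inclusion: an (hemisphere, area) enters group analyses only if at
   least three animals carry >= 10 cells there, in that same hemisphere.

Hemisphere labels are injection-relative (``ipsi``/``contra``); raw
left/right tables are flipped according to the injection hemisphere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .atlas import (
    ANALYSIS_LAYERS,
    CONTRA,
    HEMISPHERES,
    IPSI,
    AtlasOntology,
    UnknownAreaError,
    load_atlas,
)

#: Fraction of the injection bolus allowed outside the target area.
MAX_BOLUS_OUTSIDE_TARGET = 0.30
#: White-matter transduction must stay strictly below this fraction.
MAX_WHITEMATTER_BOLUS = 0.001
#: Minimum cells for an area-hemisphere to count as labeled (exclusion rule 2/3).
MIN_CELLS = 10
#: Minimum number of qualifying animals for cohort inclusion (exclusion rule 3).
MIN_ANIMALS = 3

COUNT_COLUMNS = ("hemisphere", "area", "layer", "count")


class ValidationError(ValueError):
    """Raised when a count table or metadata record violates its contract."""


@dataclass(frozen=True)
class InjectionQC:
    """Injection metadata and bolus quality-control fractions."""

    target_area: str
    injection_hemisphere: str  # "left" | "right"
    frac_bolus_outside_target: float = 0.0
    frac_whitematter_bolus: float = 0.0

    def __post_init__(self):
        for name in ("frac_bolus_outside_target", "frac_whitematter_bolus"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reasons: tuple[str, ...]


def qc_injection(
    qc: InjectionQC,
    max_outside: float = MAX_BOLUS_OUTSIDE_TARGET,
    max_whitematter: float = MAX_WHITEMATTER_BOLUS,
) -> QCResult:
    """Apply the injection-level exclusion rules.

    Fails iff more than ``max_outside`` of the bolus is outside the target
    area, or the white-matter fraction is at or above ``max_whitematter``
    (inclusion requires white matter strictly below the limit).
    """
    reasons = []
    if qc.frac_bolus_outside_target > max_outside:
        reasons.append(
            f"bolus outside target: {qc.frac_bolus_outside_target:.3f} > {max_outside:.2f}"
        )
    if qc.frac_whitematter_bolus >= max_whitematter:
        reasons.append(
            f"white-matter bolus: {qc.frac_whitematter_bolus:.4f} >= {max_whitematter:.4f}"
        )
    return QCResult(passed=not reasons, reasons=tuple(reasons))


def _complete_grid(atlas: AtlasOntology) -> pd.DataFrame:
    """Full (hemisphere, area, layer) grid; agranular areas carry no L4 row."""
    rows = []
    for hemi in HEMISPHERES:
        for area in atlas.areas:
            for layer in atlas.layers_of(area.acronym):
                rows.append((hemi, area.acronym, layer))
    return pd.DataFrame(rows, columns=["hemisphere", "area", "layer"])


def _validate_counts(df: pd.DataFrame, atlas: AtlasOntology) -> pd.DataFrame:
    """Validate a tidy ipsi/contra count table and complete it with zeros."""
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"count table missing columns: {sorted(missing)}")
    df = df.loc[:, list(COUNT_COLUMNS)].copy()

    bad_hemi = set(df["hemisphere"]) - set(HEMISPHERES)
    if bad_hemi:
        raise ValidationError(f"unknown hemisphere labels: {sorted(bad_hemi)}")

    for i, row in enumerate(df.to_dict("records")):
        area, layer, count = row["area"], row["layer"], row["count"]
        if area not in atlas:
            raise UnknownAreaError(f"row {i}: unknown cortical area acronym {area!r}")
        if layer == "L1":
            if count != 0:
                raise ValidationError(f"row {i}: L1 carries no counts (got {count})")
            continue
        if layer not in ANALYSIS_LAYERS:
            raise ValidationError(f"row {i}: unknown layer {layer!r}")
        if layer == "L4" and not atlas.has_L4(area):
            if count != 0:
                raise ValidationError(
                    f"row {i}: area {area} is agranular and cannot carry L4 counts"
                )
            continue
        fcount = float(count)
        if fcount < 0 or fcount != int(fcount):
            raise ValidationError(
                f"row {i}: count must be a non-negative integer, got {count!r}"
            )

    df = df[(df["layer"] != "L1")]
    df = df[~((df["layer"] == "L4") & (~df["area"].map(atlas.has_L4)))]
    df["count"] = df["count"].astype(np.int64)

    dup = df.duplicated(subset=["hemisphere", "area", "layer"])
    if dup.any():
        df = df.groupby(["hemisphere", "area", "layer"], as_index=False)["count"].sum()

    grid = _complete_grid(atlas)
    out = grid.merge(df, on=["hemisphere", "area", "layer"], how="left")
    out["count"] = out["count"].fillna(0).astype(np.int64)
    return out


@dataclass(frozen=True)
class AnimalCounts:
    """One animal's validated (hemisphere, area, layer) nucleus counts."""

    animal_id: str
    qc: InjectionQC
    counts: pd.DataFrame  # complete tidy grid, injection-relative hemispheres
    atlas: AtlasOntology

    @classmethod
    def from_tidy(
        cls,
        animal_id: str,
        qc: InjectionQC,
        counts: pd.DataFrame,
        atlas: AtlasOntology | None = None,
    ) -> "AnimalCounts":
        atlas = atlas if atlas is not None else load_atlas()
        if qc.target_area not in atlas:
            raise UnknownAreaError(f"unknown target area: {qc.target_area!r}")
        return cls(animal_id, qc, _validate_counts(counts, atlas), atlas)

    # -- aggregation helpers -------------------------------------------------

    def total(self) -> int:
        return int(self.counts["count"].sum())

    def hemisphere_totals(self) -> pd.Series:
        return self.counts.groupby("hemisphere")["count"].sum()

    def area_totals(self, hemisphere: str) -> pd.Series:
        """Per-area summed counts in one hemisphere, indexed by acronym."""
        sub = self.counts[self.counts["hemisphere"] == hemisphere]
        return sub.groupby("area")["count"].sum()

    def layer_counts(self, hemisphere: str, area: str) -> pd.Series:
        sub = self.counts[
            (self.counts["hemisphere"] == hemisphere) & (self.counts["area"] == area)
        ]
        return sub.set_index("layer")["count"]

    def with_counts(self, counts: pd.DataFrame) -> "AnimalCounts":
        return replace(self, counts=counts)


@dataclass(frozen=True)
class CohortData:
    """All animals injected in the same target area."""

    target_area: str
    animals: tuple[AnimalCounts, ...]

    def __post_init__(self):
        for a in self.animals:
            if a.qc.target_area != self.target_area:
                raise ValidationError(
                    f"animal {a.animal_id} targets {a.qc.target_area}, "
                    f"cohort targets {self.target_area}"
                )

    @property
    def atlas(self) -> AtlasOntology:
        return self.animals[0].atlas

    def passing_qc(self) -> "CohortData":
        kept = tuple(a for a in self.animals if qc_injection(a.qc).passed)
        return CohortData(self.target_area, kept)


def flip_to_injection_frame(
    counts: pd.DataFrame, injection_hemisphere: str
) -> pd.DataFrame:
    """Relabel left/right hemispheres as ipsi/contra relative to the injection.

    Tables already in the ipsi/contra frame pass through unchanged, so the
    operation is idempotent.  Counts are never altered, only relabelled.
    """
    labels = set(counts["hemisphere"])
    if labels <= set(HEMISPHERES):
        return counts.copy()
    if not labels <= {"left", "right"}:
        raise ValidationError(f"mixed or unknown hemisphere labels: {sorted(labels)}")
    if injection_hemisphere not in ("left", "right"):
        raise ValidationError(
            f"injection_hemisphere must be 'left' or 'right', got {injection_hemisphere!r}"
        )
    out = counts.copy()
    out["hemisphere"] = np.where(
        out["hemisphere"] == injection_hemisphere, IPSI, CONTRA
    )
    return out


def read_count_table(
    file: str | Path,
    atlas: AtlasOntology | None = None,
    metadata: dict | str | Path | None = None,
) -> AnimalCounts:
    """Read one animal's CSV count table plus its JSON metadata sidecar.

    The CSV has columns ``animal_id,hemisphere,area,layer,count`` with
    hemisphere labels either ``left/right`` (flipped here using the
    injection hemisphere) or already ``ipsi/contra``.  Metadata is a dict or
    a JSON file (default: the CSV path with a ``.json`` suffix) with keys
    ``target_area``, ``injection_hemisphere``, and optional QC fractions
    ``frac_bolus_outside_target`` / ``frac_whitematter_bolus``.

    Missing (hemisphere, area, layer) combinations are imputed as zero.
    """
    file = Path(file)
    atlas = atlas if atlas is not None else load_atlas()

    if metadata is None:
        metadata = file.with_suffix(".json")
    if isinstance(metadata, (str, Path)):
        meta_path = Path(metadata)
        if not meta_path.exists():
            raise ValidationError(f"metadata sidecar not found: {meta_path}")
        metadata = json.loads(meta_path.read_text())
    try:
        qc = InjectionQC(
            target_area=metadata["target_area"],
            injection_hemisphere=metadata["injection_hemisphere"],
            frac_bolus_outside_target=float(
                metadata.get("frac_bolus_outside_target", 0.0)
            ),
            frac_whitematter_bolus=float(metadata.get("frac_whitematter_bolus", 0.0)),
        )
    except KeyError as exc:
        raise ValidationError(f"metadata missing required key: {exc}") from None

    df = pd.read_csv(file)
    required = {"animal_id", "hemisphere", "area", "layer", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{file}: missing columns {sorted(missing)}")
    ids = df["animal_id"].unique()
    if len(ids) != 1:
        raise ValidationError(f"{file}: expected exactly one animal_id, got {list(ids)}")

    counts = flip_to_injection_frame(
        df[["hemisphere", "area", "layer", "count"]], qc.injection_hemisphere
    )
    return AnimalCounts.from_tidy(str(ids[0]), qc, counts, atlas)


def write_count_table(animal: AnimalCounts, file: str | Path) -> None:
    """Round-trip an AnimalCounts back to the ingest CSV schema + sidecar."""
    file = Path(file)
    out = animal.counts.copy()
    out.insert(0, "animal_id", animal.animal_id)
    out.to_csv(file, index=False)
    meta = {
        "target_area": animal.qc.target_area,
        "injection_hemisphere": animal.qc.injection_hemisphere,
        "frac_bolus_outside_target": animal.qc.frac_bolus_outside_target,
        "frac_whitematter_bolus": animal.qc.frac_whitematter_bolus,
    }
    file.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def apply_min_cell_filter(animal: AnimalCounts, threshold: int = MIN_CELLS) -> AnimalCounts:
    """Zero out any (hemisphere, area) whose total across layers is < threshold.

    The rule acts on the per-area sum, not per layer; re-application is
    idempotent and counts never increase.
    """
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    counts = animal.counts.copy()
    totals = counts.groupby(["hemisphere", "area"])["count"].transform("sum")
    counts["count"] = np.where(totals < threshold, 0, counts["count"])
    return animal.with_counts(counts)


def area_inclusion_mask(
    cohort: CohortData | Sequence[AnimalCounts],
    min_cells: int = MIN_CELLS,
    min_animals: int = MIN_ANIMALS,
) -> set[tuple[str, str]]:
    """(hemisphere, area) pairs qualifying for cohort-level analyses.

    A pair is included iff at least ``min_animals`` distinct animals carry
    ``>= min_cells`` cells in that area, counted within the same hemisphere.
    The per-animal minimum-cell zeroing is applied first.
    """
    animals = cohort.animals if isinstance(cohort, CohortData) else tuple(cohort)
    qualifying: dict[tuple[str, str], int] = {}
    for animal in animals:
        filtered = apply_min_cell_filter(animal, min_cells)
        totals = filtered.counts.groupby(["hemisphere", "area"])["count"].sum()
        for (hemi, area), total in totals.items():
            if total >= min_cells:
                qualifying[(hemi, area)] = qualifying.get((hemi, area), 0) + 1
    return {key for key, n in qualifying.items() if n >= min_animals}


def filter_cohort(cohort: CohortData, threshold: int = MIN_CELLS) -> CohortData:
    """Apply the per-animal minimum-cell filter to every animal."""
    return CohortData(
        cohort.target_area,
        tuple(apply_min_cell_filter(a, threshold) for a in cohort.animals),
    )
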