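"""Normalized projection weights: hemispheric, areal, laminar, and modular.

All quantities are fractions of labeled cells.  The fractional count of an
area is its cell count divided by the total count of its hemisphere, after
the analysis-specific exclusions; laminar profiles normalize an area's
per-layer counts to the area total over a stated layer universe.  Undefined
results (zero denominators) propagate as NaN, never as zero.

Exclusion presets vary by analysis: the ipsilateral injection target is
always excluded (it holds the injection bolus); the contralateral homotopic
area is excluded for areal/module weight maps but retained when it is
itself the quantity of interest (homotopic share) or a valid contralateral
input (fILN tables).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .atlas import CONTRA, FILN_LAYERS, IPSI, AtlasOntology
from .ingest import AnimalCounts, CohortData


@dataclass(frozen=True)
class Exclusions:
    """Which injection-related entries are dropped before normalizing."""

    exclude_target_ipsi: bool = True
    exclude_homotopic_contra: bool = False


#: Areal/module weight maps: drop the injection site and its mirror area.
WEIGHT_MAP_EXCLUSIONS = Exclusions(exclude_target_ipsi=True, exclude_homotopic_contra=True)
#: Analyses where the homotopic area is a legitimate contralateral input.
KEEP_HOMOTOPIC_EXCLUSIONS = Exclusions(exclude_target_ipsi=True, exclude_homotopic_contra=False)


def _excluded(hemisphere: str, area: str, target: str, exclusions: Exclusions) -> bool:
    if hemisphere == IPSI:
        return exclusions.exclude_target_ipsi and area == target
    return exclusions.exclude_homotopic_contra and area == target


def hemisphere_share(animal: AnimalCounts) -> dict[str, float]:
    """Fraction of labeled cells per hemisphere (ipsi + contra = 1).

    Computed over all areas except the ipsilateral injection target; the
    contralateral homotopic area is retained.  NaN if no cells remain.
    """
    target = animal.qc.target_area
    df = animal.counts
    keep = ~((df["hemisphere"] == IPSI) & (df["area"] == target))
    totals = df[keep].groupby("hemisphere")["count"].sum()
    grand = float(totals.sum())
    if grand == 0:
        return {IPSI: float("nan"), CONTRA: float("nan")}
    return {
        IPSI: float(totals.get(IPSI, 0)) / grand,
        CONTRA: float(totals.get(CONTRA, 0)) / grand,
    }


def areal_fraction(
    animal: AnimalCounts,
    hemisphere: str,
    exclusions: Exclusions = WEIGHT_MAP_EXCLUSIONS,
) -> pd.Series:
    """Per-area fractional count within one hemisphere.

    Each included area's cells divided by the hemisphere total after
    exclusions; sums to 1 when any cells remain, all-NaN otherwise.
    Excluded areas are absent from the result.
    """
    target = animal.qc.target_area
    totals = animal.area_totals(hemisphere)
    keep = [a for a in totals.index if not _excluded(hemisphere, a, target, exclusions)]
    totals = totals.loc[keep]
    grand = float(totals.sum())
    if grand == 0:
        return pd.Series(np.nan, index=totals.index, name="fraction")
    return (totals / grand).rename("fraction")


def count_labeled_areas(animal: AnimalCounts, hemisphere: str) -> int:
    """Number of areas with labeled neurons in one hemisphere.

    Expects minimum-cell-filtered counts, so "labeled" means the area
    survived the >=10-cell rule.  The ipsilateral injection target is not
    counted; the contralateral homotopic area is.
    """
    target = animal.qc.target_area
    totals = animal.area_totals(hemisphere)
    if hemisphere == IPSI:
        totals = totals.drop(index=target, errors="ignore")
    return int((totals > 0).sum())


def homotopic_share(animal: AnimalCounts) -> float:
    """Fraction of contralateral cells located in the homotopic target area."""
    totals = animal.area_totals(CONTRA)
    grand = float(totals.sum())
    if grand == 0:
        return float("nan")
    return float(totals.get(animal.qc.target_area, 0)) / grand


def laminar_fraction(
    animal: AnimalCounts,
    hemisphere: str,
    area: str,
    layer_universe: Sequence[str] = FILN_LAYERS,
) -> dict[str, float] | None:
    """Per-layer fractions of one area's cells over a stated layer universe.

    Returns None (undefined) when the area holds no cells in the universe.
    """
    layers = animal.layer_counts(hemisphere, area)
    universe = [l for l in layer_universe if l in layers.index]
    total = float(layers.loc[universe].sum())
    if total == 0:
        return None
    return {l: float(layers.get(l, 0)) / total for l in layer_universe}


def laminar_profile_table(
    cohort: CohortData,
    layer_universe: Sequence[str] = FILN_LAYERS,
    inclusion: Iterable[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Tidy per-(animal, hemisphere, area, layer) laminar fractions.

    Rows for undefined profiles (or excluded (hemisphere, area) pairs when
    an inclusion mask is given) carry NaN fractions.
    """
    inclusion = set(inclusion) if inclusion is not None else None
    rows = []
    for animal in cohort.animals:
        for hemi in (IPSI, CONTRA):
            for area in animal.atlas.acronyms:
                included = inclusion is None or (hemi, area) in inclusion
                profile = (
                    laminar_fraction(animal, hemi, area, layer_universe)
                    if included
                    else None
                )
                for layer in layer_universe:
                    rows.append(
                        {
                            "animal_id": animal.animal_id,
                            "hemisphere": hemi,
                            "area": area,
                            "layer": layer,
                            "fraction": np.nan if profile is None else profile[layer],
                        }
                    )
    return pd.DataFrame(rows)


def module_fraction(
    fractions: pd.Series, atlas: AtlasOntology
) -> pd.Series:
    """Aggregate an areal-fraction vector into per-module fractions.

    The module fraction is the plain sum of its member areas' fractions, so
    the six modules sum to 1 whenever the areal fractions do.
    """
    modules = pd.Index([atlas.module_of(a) for a in fractions.index], name="module")
    return fractions.groupby(modules).sum().rename("fraction")


def module_fraction_table(
    cohort: CohortData,
    exclusions: Exclusions = WEIGHT_MAP_EXCLUSIONS,
) -> pd.DataFrame:
    """Tidy per-(animal, hemisphere, module) fractional counts."""
    rows = []
    for animal in cohort.animals:
        for hemi in (IPSI, CONTRA):
            frac = areal_fraction(animal, hemi, exclusions)
            mod = module_fraction(frac, animal.atlas)
            for module, value in mod.items():
                rows.append(
                    {
                        "animal_id": animal.animal_id,
                        "hemisphere": hemi,
                        "module": module,
                        "fraction": value,
                    }
                )
    return pd.DataFrame(rows)


def interhemispheric_correlation(
    cohort: CohortData,
    method: str = "pearson-R2-linfit",
    exclusions: Exclusions = WEIGHT_MAP_EXCLUSIONS,
    inclusion: Iterable[tuple[str, str]] | None = None,
):
    """Per-animal correlation of ipsi vs contra areal fractional counts.

    For each animal, areas defined in both hemispheres (after exclusions
    and the optional inclusion mask) are correlated; results aggregate as
    mean +- SEM across animals.
    """
    from .stats import correlate_by_animal

    inclusion = set(inclusion) if inclusion is not None else None
    pairs = []
    for animal in cohort.animals:
        fi = areal_fraction(animal, IPSI, exclusions)
        fc = areal_fraction(animal, CONTRA, exclusions)
        areas = [
            a
            for a in fi.index.intersection(fc.index)
            if inclusion is None
            or ((IPSI, a) in inclusion and (CONTRA, a) in inclusion)
        ]
        x = fi.loc[areas].values
        y = fc.loc[areas].values
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() >= 3:
            pairs.append((x[ok], y[ok]))
    return correlate_by_animal(pairs, method)


def area_symmetry_tests(
    cohort: CohortData,
    exclusions: Exclusions = WEIGHT_MAP_EXCLUSIONS,
    inclusion: Iterable[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-area test of hemispheric symmetry of fractional counts.

    For each area included in both hemispheres, a one-sample t-test on the
    per-animal contra - ipsi fraction differences, Bonferroni-corrected
    over the number of areas tested.  ``bias`` is "contra"/"ipsi" for
    significant asymmetries, "none" otherwise.
    """
    from .stats import bonferroni, compare

    inclusion = set(inclusion) if inclusion is not None else None
    per_area: dict[str, list[float]] = {}
    for animal in cohort.animals:
        fi = areal_fraction(animal, IPSI, exclusions)
        fc = areal_fraction(animal, CONTRA, exclusions)
        for area in fi.index.intersection(fc.index):
            if inclusion is not None and (
                (IPSI, area) not in inclusion or (CONTRA, area) not in inclusion
            ):
                continue
            d = fc.get(area, np.nan) - fi.get(area, np.nan)
            if np.isfinite(d):
                per_area.setdefault(area, []).append(float(d))

    rows = []
    for area, diffs in sorted(per_area.items()):
        if len(diffs) < 2:
            continue
        res = compare(diffs, paired=False, sidedness="two", test="one-sample-t")
        rows.append(
            {
                "area": area,
                "mean_diff": float(np.mean(diffs)),
                "p": res.p,
                "n": len(diffs),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_adjusted"] = bonferroni(out["p"].tolist(), m=len(out))
    out["m"] = len(out)
    sig = out["p_adjusted"] < alpha
    out["bias"] = "none"
    out.loc[sig & (out["mean_diff"] > 0), "bias"] = "contra"
    out.loc[sig & (out["mean_diff"] < 0), "bias"] = "ipsi"
    return out


def areal_fraction_table(
    cohort: CohortData,
    exclusions: Exclusions = WEIGHT_MAP_EXCLUSIONS,
    inclusion: Iterable[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Tidy per-(animal, hemisphere, area) fractional counts.

    With an inclusion mask, excluded (hemisphere, area) pairs carry NaN.
    """
    inclusion = set(inclusion) if inclusion is not None else None
    rows = []
    for animal in cohort.animals:
        for hemi in (IPSI, CONTRA):
            frac = areal_fraction(animal, hemi, exclusions)
            for area, value in frac.items():
                if inclusion is not None and (hemi, area) not in inclusion:
                    value = np.nan
                rows.append(
                    {
                        "animal_id": animal.animal_id,
                        "hemisphere": hemi,
                        "area": area,
                        "fraction": value,
                    }
                )
    return pd.DataFrame(rows)
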