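"""The fILN anatomical-hierarchy statistic and its derived analyses.

The fraction of infragranular labeled neurons,

    fILN = (L5 + L6) / (L2/3 + L5 + L6),

summarizes where an area's projection neurons sit relative to layer 4:
values near 0 indicate supragranular (feedforward-like) input, values near
1 infragranular (feedback-like) input.  L6 means L6a by default (L4 and L6b
carry too few projection neurons and are excluded); a switch folds L6b in.

Layer-ablation variants drop L5 or L6 from both numerator and denominator,
quantifying how much each infragranular layer contributes to the hierarchy
signal:

    excl_L5: L6 / (L2/3 + L6)        excl_L6: L5 / (L2/3 + L5)

Both are bounded above by the default fILN for any profile.

Derived analyses: per-area and per-hemisphere-pooled fILN tables, laminar
dominance labels, hierarchy rankings, interhemispheric differences, module
and module-group means, and per-layer interhemispheric fractional changes
with paired significance testing.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import CONTRA, IPSI, AtlasOntology, MODULE_GROUPINGS
from .fractions import laminar_fraction
from .ingest import CohortData, area_inclusion_mask, filter_cohort
from .stats import bonferroni, compare

VARIANTS = ("default", "excl_L5", "excl_L6")

#: Dominance considers the three layer classes that carry projection
#: neurons; L6 pools L6a and L6b.
DOMINANCE_LAYERS = ("L2/3", "L5", "L6")


def filn(profile: Mapping[str, float], variant: str = "default") -> float:
    """fILN of one laminar profile, or an ablation variant of it.

    ``profile`` maps layer names to non-negative fractions or counts over
    {L2/3, L5, L6} (the key ``L6a`` is accepted for ``L6``); normalization
    is irrelevant since fILN is a ratio.  Returns NaN when the denominator
    is empty.
    """
    l23 = float(profile.get("L2/3", 0.0))
    l5 = float(profile.get("L5", 0.0))
    l6 = float(profile.get("L6", profile.get("L6a", 0.0)))
    for name, v in (("L2/3", l23), ("L5", l5), ("L6", l6)):
        if v < 0:
            raise ValueError(f"negative {name} fraction: {v}")
    if variant == "default":
        num, den = l5 + l6, l23 + l5 + l6
    elif variant == "excl_L5":
        num, den = l6, l23 + l6
    elif variant == "excl_L6":
        num, den = l5, l23 + l5
    else:
        raise ValueError(f"unknown fILN variant: {variant!r} (expected one of {VARIANTS})")
    if den == 0:
        return float("nan")
    return num / den


def _filn_universe(include_l6b: bool) -> tuple[str, ...]:
    return ("L2/3", "L5", "L6a", "L6b") if include_l6b else ("L2/3", "L5", "L6a")


def _profile_for_filn(
    animal, hemisphere: str, area: str, include_l6b: bool
) -> dict[str, float] | None:
    universe = _filn_universe(include_l6b)
    prof = laminar_fraction(animal, hemisphere, area, universe)
    if prof is None:
        return None
    l6 = prof.get("L6a", 0.0) + (prof.get("L6b", 0.0) if include_l6b else 0.0)
    return {"L2/3": prof.get("L2/3", 0.0), "L5": prof.get("L5", 0.0), "L6": l6}


def filn_table(
    cohort: CohortData,
    variant: str = "default",
    include_l6b: bool = False,
    min_cells: int = 10,
    min_animals: int = 3,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Per-(animal, hemisphere, area) fILN values for a cohort.

    The minimum-cell filter and the cohort inclusion mask are applied
    first; excluded or undefined entries are NaN.  The ipsilateral
    injection target is always NaN; the contralateral homotopic area is
    retained (it is a valid contralateral input).
    """
    if not prefiltered:
        cohort = filter_cohort(cohort, min_cells)
    mask = area_inclusion_mask(cohort, min_cells, min_animals)
    target = cohort.target_area
    rows = []
    for animal in cohort.animals:
        for hemi in (IPSI, CONTRA):
            for area in animal.atlas.acronyms:
                value = np.nan
                excluded = (hemi == IPSI and area == target) or (hemi, area) not in mask
                if not excluded:
                    prof = _profile_for_filn(animal, hemi, area, include_l6b)
                    if prof is not None:
                        value = filn(prof, variant)
                rows.append(
                    {
                        "animal_id": animal.animal_id,
                        "hemisphere": hemi,
                        "area": area,
                        "filn": value,
                        "variant": variant,
                    }
                )
    return pd.DataFrame(rows)


def pooled_filn(
    cohort: CohortData,
    variant: str = "default",
    include_l6b: bool = False,
    min_cells: int = 10,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Hemisphere-pooled fILN per animal, blind to individual areas.

    Sums counts over all areas of a hemisphere (excluding the ipsilateral
    injection target) and evaluates fILN on the summed laminar counts, so
    the value is cell-weighted rather than area-averaged.
    """
    if not prefiltered:
        cohort = filter_cohort(cohort, min_cells)
    target = cohort.target_area
    universe = _filn_universe(include_l6b)
    rows = []
    for animal in cohort.animals:
        df = animal.counts
        keep = ~((df["hemisphere"] == IPSI) & (df["area"] == target))
        sums = df[keep].groupby(["hemisphere", "layer"])["count"].sum()
        for hemi in (IPSI, CONTRA):
            counts = {l: float(sums.get((hemi, l), 0)) for l in universe}
            l6 = counts.get("L6a", 0.0) + (counts.get("L6b", 0.0) if include_l6b else 0.0)
            value = filn({"L2/3": counts.get("L2/3", 0.0), "L5": counts.get("L5", 0.0), "L6": l6}, variant)
            rows.append(
                {
                    "animal_id": animal.animal_id,
                    "hemisphere": hemi,
                    "filn": value,
                    "variant": variant,
                }
            )
    return pd.DataFrame(rows)


# -- laminar dominance -------------------------------------------------------


def dominance(fractions: Mapping[str, float]) -> str | None:
    """Label of the dominant layer class among {L2/3, L5, L6}.

    ``L6`` pools L6a and L6b if given separately.  Ties break toward the
    deeper layer (L6 > L5 > L2/3) for determinism.  Returns None for an
    undefined (empty) profile.
    """
    l6 = fractions.get("L6")
    if l6 is None:
        l6 = fractions.get("L6a", 0.0) + fractions.get("L6b", 0.0)
    values = {
        "L2/3": float(fractions.get("L2/3", 0.0)),
        "L5": float(fractions.get("L5", 0.0)),
        "L6": float(l6),
    }
    if any(np.isnan(v) for v in values.values()) or sum(values.values()) == 0:
        return None
    # deeper-first order makes max() break ties toward the deeper layer
    order = ("L6", "L5", "L2/3")
    return max(order, key=lambda k: values[k])


def dominance_table(
    cohort: CohortData,
    basis: str = "per_animal",
    include_l4_l6b: bool = True,
    min_cells: int = 10,
    min_animals: int = 3,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Dominance labels per area.

    ``basis="per_animal"`` labels each (animal, hemisphere, area);
    ``basis="cohort_average"`` labels the across-animal mean profile per
    (hemisphere, area).  Dominance always compares {L2/3, L5, L6 = L6a+L6b};
    ``include_l4_l6b`` controls whether L4/L6b cells enter the profile
    normalization (they never compete for dominance themselves).
    """
    if basis not in ("per_animal", "cohort_average"):
        raise ValueError(f"unknown basis: {basis!r}")
    if not prefiltered:
        cohort = filter_cohort(cohort, min_cells)
    mask = area_inclusion_mask(cohort, min_cells, min_animals)
    target = cohort.target_area
    universe = ("L2/3", "L4", "L5", "L6a", "L6b") if include_l4_l6b else ("L2/3", "L5", "L6a", "L6b")

    records = []
    for animal in cohort.animals:
        for hemi in (IPSI, CONTRA):
            for area in animal.atlas.acronyms:
                if (hemi == IPSI and area == target) or (hemi, area) not in mask:
                    continue
                prof = laminar_fraction(animal, hemi, area, universe)
                records.append(
                    {
                        "animal_id": animal.animal_id,
                        "hemisphere": hemi,
                        "area": area,
                        **{l: (np.nan if prof is None else prof.get(l, 0.0)) for l in universe},
                    }
                )
    prof_df = pd.DataFrame(records)
    if prof_df.empty:
        return pd.DataFrame(columns=["animal_id", "hemisphere", "area", "label"])

    if basis == "per_animal":
        out = prof_df[["animal_id", "hemisphere", "area"]].copy()
        labels = []
        for row in prof_df.to_dict("records"):
            vals = {l: row[l] for l in universe}
            undefined = any(np.isnan(v) for v in vals.values())
            labels.append(None if undefined else dominance(vals))
        out["label"] = labels
    else:
        mean_prof = prof_df.groupby(["hemisphere", "area"])[list(universe)].mean()
        out = mean_prof.reset_index()[["hemisphere", "area"]]
        out["label"] = [
            dominance(dict(row.dropna())) for _, row in mean_prof.iterrows()
        ]
    out["basis"] = basis
    return out


def dominance_tally(dominance_df: pd.DataFrame) -> pd.DataFrame:
    """Percentage of areas dominated by each layer class.

    For per-animal labels the tally is per (animal, hemisphere) and can be
    averaged across animals downstream; for cohort-average labels it is per
    hemisphere.
    """
    df = dominance_df.dropna(subset=["label"])
    group_cols = (
        ["animal_id", "hemisphere"] if "animal_id" in df.columns else ["hemisphere"]
    )
    rows = []
    for key, sub in df.groupby(group_cols):
        key = key if isinstance(key, tuple) else (key,)
        n = len(sub)
        for layer in DOMINANCE_LAYERS:
            rows.append(
                {
                    **dict(zip(group_cols, key)),
                    "label": layer,
                    "percent": 100.0 * (sub["label"] == layer).sum() / n,
                    "n_areas": n,
                }
            )
    return pd.DataFrame(rows)


# -- rankings, deltas, module means ------------------------------------------


def rank_areas(
    filn_df: pd.DataFrame, hemisphere: str, atlas: AtlasOntology
) -> pd.DataFrame:
    """Rank areas by their NaN-aware mean fILN, ascending.

    ``filn_df`` may pool several cohorts (targets); each animal-area entry
    that is NaN simply does not contribute, so the per-area n varies.
    Areas with no defined values are dropped with a warning.  Ties break by
    area index.
    """
    sub = filn_df[filn_df["hemisphere"] == hemisphere]
    grouped = sub.groupby("area")["filn"]
    summary = pd.DataFrame(
        {
            "mean_filn": grouped.mean(),
            "sem_filn": grouped.sem(),
            "n": grouped.count(),
        }
    ).reset_index()
    empty = summary[summary["n"] == 0]["area"].tolist()
    if empty:
        warnings.warn(f"areas with no defined fILN dropped from ranking: {empty}")
    summary = summary[summary["n"] > 0].copy()
    summary["area_index"] = summary["area"].map(atlas.index_of)
    summary = summary.sort_values(["mean_filn", "area_index"]).reset_index(drop=True)
    summary["rank"] = np.arange(1, len(summary) + 1)
    return summary[["rank", "area", "area_index", "mean_filn", "sem_filn", "n"]]


def interhemispheric_delta(filn_df: pd.DataFrame) -> pd.DataFrame:
    """Per (animal, area) contra - ipsi fILN difference; NaN propagates."""
    wide = filn_df.pivot_table(
        index=["animal_id", "area"],
        columns="hemisphere",
        values="filn",
        dropna=False,
    )
    for hemi in (IPSI, CONTRA):
        if hemi not in wide.columns:
            wide[hemi] = np.nan
    out = wide.reset_index()
    out["delta"] = out[CONTRA] - out[IPSI]
    return out[["animal_id", "area", IPSI, CONTRA, "delta"]]


def module_filn(
    filn_df: pd.DataFrame, atlas: AtlasOntology, grouping: str = "modules"
) -> pd.DataFrame:
    """NaN-aware mean fILN per (animal, hemisphere, module or group).

    Areas are weighted equally (each defined area contributes one value);
    the two-group level averages member-area values directly rather than
    averaging module means.
    """
    df = filn_df.copy()
    if grouping == "modules":
        df["unit"] = df["area"].map(atlas.module_of)
    elif grouping == "groups":
        module_to_group = {
            m: g for g, members in MODULE_GROUPINGS.items() for m in members
        }
        df["unit"] = df["area"].map(lambda a: module_to_group[atlas.module_of(a)])
    else:
        raise ValueError(f"unknown grouping: {grouping!r}")
    out = (
        df.groupby(["animal_id", "hemisphere", "unit"])["filn"]
        .agg(mean_filn="mean", n="count")
        .reset_index()
    )
    out.loc[out["n"] == 0, "mean_filn"] = np.nan
    return out


# -- interhemispheric laminar change (sensory-motor areas) -------------------


def laminar_change(
    cohort: CohortData,
    layers: Sequence[str] = ("L2/3", "L5", "L6a"),
    alpha: float = 0.05,
    test: str = "paired-t",
    min_cells: int = 10,
    min_animals: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contra - ipsi laminar fractional changes for sensory-motor areas.

    For every v-a-sm area included in both hemispheres (the homotopic
    injection target is excluded), computes the per-animal laminar
    fractions over ``layers`` in each hemisphere, their mean change, and a
    per-(area, layer) paired comparison with Bonferroni correction over the
    areas tested within each layer.

    Returns ``(changes, tallies)``: the per-area table with adjusted
    p-values and change direction, and per-layer percentages of areas that
    significantly decrease or increase.  Areas missing in one hemisphere
    are excluded and reported with NaN change.
    """
    cohort = filter_cohort(cohort, min_cells)
    mask = area_inclusion_mask(cohort, min_cells, min_animals)
    atlas = cohort.atlas
    target = cohort.target_area
    vasm = [a for a in atlas.areas_in_group("v-a-sm") if a != target]

    rows = []
    for area in vasm:
        both = (IPSI, area) in mask and (CONTRA, area) in mask
        for layer in layers:
            if not both:
                rows.append(
                    {
                        "area": area,
                        "layer": layer,
                        "mean_change": np.nan,
                        "p": np.nan,
                        "p_adjusted": np.nan,
                        "significant": False,
                        "direction": "excluded",
                        "n": 0,
                    }
                )
                continue
            ipsi_vals, contra_vals = [], []
            for animal in cohort.animals:
                pi = laminar_fraction(animal, IPSI, area, layers)
                pc = laminar_fraction(animal, CONTRA, area, layers)
                if pi is None or pc is None:
                    continue
                ipsi_vals.append(pi[layer])
                contra_vals.append(pc[layer])
            if len(ipsi_vals) < 2:
                rows.append(
                    {
                        "area": area,
                        "layer": layer,
                        "mean_change": np.nan,
                        "p": np.nan,
                        "p_adjusted": np.nan,
                        "significant": False,
                        "direction": "excluded",
                        "n": len(ipsi_vals),
                    }
                )
                continue
            contra_arr = np.asarray(contra_vals)
            ipsi_arr = np.asarray(ipsi_vals)
            change = float(np.mean(contra_arr - ipsi_arr))
            res = compare(contra_arr, ipsi_arr, paired=True, sidedness="two", test=test)
            rows.append(
                {
                    "area": area,
                    "layer": layer,
                    "mean_change": change,
                    "p": res.p,
                    "p_adjusted": np.nan,
                    "significant": False,
                    "direction": "none",
                    "n": len(ipsi_vals),
                }
            )
    changes = pd.DataFrame(rows)

    for layer in layers:
        tested = changes[(changes["layer"] == layer) & changes["p"].notna()]
        if tested.empty:
            continue
        adj = bonferroni(tested["p"].tolist(), m=len(tested))
        changes.loc[tested.index, "p_adjusted"] = adj
    sig = changes["p_adjusted"] < alpha
    changes.loc[sig & (changes["mean_change"] > 0), "direction"] = "increase"
    changes.loc[sig & (changes["mean_change"] < 0), "direction"] = "decrease"
    changes.loc[sig, "significant"] = True

    tally_rows = []
    for layer in layers:
        tested = changes[(changes["layer"] == layer) & changes["p"].notna()]
        n = len(tested)
        if n == 0:
            continue
        for direction in ("decrease", "increase"):
            tally_rows.append(
                {
                    "layer": layer,
                    "direction": direction,
                    "percent_of_areas": 100.0 * (tested["direction"] == direction).sum() / n,
                    "n_areas_tested": n,
                }
            )
    return changes, pd.DataFrame(tally_rows)


# -- per-animal fILN correlations (hemispheric symmetry of hierarchy) --------


def filn_correlations(filn_df: pd.DataFrame, method: str = "spearman"):
    """Per-animal correlations of ipsi fILN with contra fILN and with delta.

    Returns ``(ipsi_vs_contra, ipsi_vs_delta)`` as CorrelationResults
    aggregated mean +- SEM across animals, matching the convention of
    reporting average per-animal correlation values.
    """
    from .stats import correlate_by_animal

    delta = interhemispheric_delta(filn_df)
    pairs_contra, pairs_delta = [], []
    for _, sub in delta.groupby("animal_id"):
        ok = sub[[IPSI, CONTRA]].notna().all(axis=1)
        sub = sub[ok]
        if len(sub) >= 3:
            pairs_contra.append((sub[IPSI].values, sub[CONTRA].values))
            pairs_delta.append((sub[IPSI].values, sub["delta"].values))
    return (
        correlate_by_animal(pairs_contra, method),
        correlate_by_animal(pairs_delta, method),
    )
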