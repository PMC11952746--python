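"""Synthetic retrograde-tracing cohorts with known ground truth.

The generator emulates the structure of cellfinder-style per-area laminar
count tables for a cohort of mice injected in one target area:

* ~80% of labeled cells ipsilateral, 20% contralateral;
* area weights dominated by the target's home module (visual for VISp,
  somatomotor for SSp-bfd and MOp), with a geometric within-module decay
  and the contralateral homotopic area carrying the largest contralateral
  weight;
* laminar profiles anchored per target, with the contralateral hemisphere
  shifting mass from L2/3 to L6a (the interhemispheric feedback shift);
  sensory-motor areas differ from frontal/medial/lateral areas, which sit
  high in the hierarchy in both hemispheres;
* animal-to-animal variability via concentration-weighted (Dirichlet/Beta)
  perturbations of the hemisphere split, area weights, and laminar
  profiles, all governed by one overdispersion parameter.

Each simulated animal is emitted both as an aggregated
:class:`~projectome.ingest.AnimalCounts` and as the raw per-cell event
list, which serves as the substrate for brute-force oracle checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ANALYSIS_LAYERS, CONTRA, HEMISPHERES, IPSI, AtlasOntology, load_atlas
from .fractions import WEIGHT_MAP_EXCLUSIONS, hemisphere_share
from .ingest import AnimalCounts, CohortData, InjectionQC, filter_cohort

DEFAULT_TARGETS = ("VISp", "SSp-bfd", "MOp")

#: Module-level fractional-count anchors per target and hemisphere.
_MODULE_WEIGHTS = {
    "VISp": {
        IPSI: {"visual": 0.42, "lateral": 0.19, "somatomotor": 0.12, "medial": 0.12, "auditory": 0.09, "prefrontal": 0.06},
        CONTRA: {"visual": 0.42, "lateral": 0.22, "somatomotor": 0.11, "medial": 0.10, "auditory": 0.09, "prefrontal": 0.06},
    },
    "SSp-bfd": {
        IPSI: {"somatomotor": 0.62, "visual": 0.16, "lateral": 0.10, "medial": 0.05, "auditory": 0.04, "prefrontal": 0.03},
        CONTRA: {"somatomotor": 0.53, "lateral": 0.24, "visual": 0.10, "medial": 0.05, "auditory": 0.04, "prefrontal": 0.04},
    },
    "MOp": {
        IPSI: {"somatomotor": 0.83, "lateral": 0.08, "prefrontal": 0.07, "visual": 0.01, "auditory": 0.005, "medial": 0.005},
        CONTRA: {"somatomotor": 0.71, "lateral": 0.14, "prefrontal": 0.125, "visual": 0.01, "auditory": 0.0075, "medial": 0.0075},
    },
}

#: (L2/3, L5, L6a) anchors for sensory-motor areas, per target and
#: hemisphere: the contralateral side loses L2/3 mass and gains L6a.
_VASM_LAMINAR = {
    "VISp": {IPSI: (0.25, 0.19, 0.38), CONTRA: (0.15, 0.21, 0.42)},
    "SSp-bfd": {IPSI: (0.36, 0.27, 0.24), CONTRA: (0.22, 0.28, 0.40)},
    "MOp": {IPSI: (0.23, 0.13, 0.45), CONTRA: (0.12, 0.12, 0.50)},
}
#: Frontal/medial/lateral areas sit high in the hierarchy in both
#: hemispheres, with only a mild contralateral shift.
_PFML_LAMINAR = {IPSI: (0.18, 0.30, 0.52), CONTRA: (0.14, 0.30, 0.56)}

_L4_SHARE = 0.08  # of an area's cells, when the area has L4
_L6B_SHARE = 0.02
_WITHIN_MODULE_DECAY = 0.85
_HOMOTOPIC_BOOST = 1.5  # contra homotopic weight vs largest other area
_AREA_TILT = 0.04  # deterministic per-area L2/3<->L6a tilt amplitude


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters of a synthetic projectome cohort."""

    target: str
    ipsi_share: float
    area_weights: pd.Series  # index (hemisphere, area), sums to 1 per hemisphere
    laminar_profiles: pd.DataFrame  # index (hemisphere, area), columns ANALYSIS_LAYERS
    overdispersion: float
    cells_per_animal: int
    n_animals: int
    seed: int
    atlas: AtlasOntology

    def __post_init__(self):
        if not (0.0 < self.ipsi_share < 1.0):
            raise ValueError(f"ipsi_share must lie in (0, 1), got {self.ipsi_share}")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")
        for hemi in HEMISPHERES:
            s = float(self.area_weights.loc[hemi].sum())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"{hemi} area weights sum to {s}, expected 1")
        w = self.area_weights
        lam = self.laminar_profiles
        for (hemi, area), weight in w.items():
            if weight < 0:
                raise ValueError(f"negative weight for ({hemi}, {area})")
            if weight == 0:
                continue
            row = lam.loc[(hemi, area)]
            if abs(float(row.sum()) - 1.0) > 1e-9:
                raise ValueError(f"laminar profile of ({hemi}, {area}) does not sum to 1")
            if not self.atlas.has_L4(area) and float(row.get("L4", 0.0)) != 0.0:
                raise ValueError(f"agranular area {area} has nonzero L4 mass")

    def filn_truth(self) -> pd.Series:
        """Generative per-(hemisphere, area) fILN over {L2/3, L5, L6a}."""
        lam = self.laminar_profiles
        num = lam["L5"] + lam["L6a"]
        den = lam["L2/3"] + lam["L5"] + lam["L6a"]
        out = num / den
        out[self.area_weights == 0] = np.nan
        return out.rename("filn")

    def areal_fraction_truth(self, hemisphere: str, exclude_homotopic: bool = True) -> pd.Series:
        """Generative areal fractions under the standard exclusions."""
        w = self.area_weights.loc[hemisphere].copy()
        if hemisphere == IPSI or exclude_homotopic:
            w = w.drop(index=self.target, errors="ignore")
        return w / w.sum()

    # -- serialization -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "target": self.target,
            "ipsi_share": self.ipsi_share,
            "overdispersion": self.overdispersion,
            "cells_per_animal": self.cells_per_animal,
            "n_animals": self.n_animals,
            "seed": self.seed,
            "area_weights": {
                f"{h}|{a}": float(v) for (h, a), v in self.area_weights.items()
            },
            "laminar_profiles": {
                f"{h}|{a}": {l: float(row[l]) for l in ANALYSIS_LAYERS}
                for (h, a), row in self.laminar_profiles.iterrows()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path, atlas: AtlasOntology | None = None) -> "GroundTruth":
        atlas = atlas if atlas is not None else load_atlas()
        payload = json.loads(Path(path).read_text())
        idx = pd.MultiIndex.from_tuples(
            [tuple(k.split("|")) for k in payload["area_weights"]],
            names=["hemisphere", "area"],
        )
        weights = pd.Series(list(payload["area_weights"].values()), index=idx).sort_index()
        lam_idx = pd.MultiIndex.from_tuples(
            [tuple(k.split("|")) for k in payload["laminar_profiles"]],
            names=["hemisphere", "area"],
        )
        lam = pd.DataFrame(
            list(payload["laminar_profiles"].values()), index=lam_idx
        )[list(ANALYSIS_LAYERS)].sort_index()
        return cls(
            target=payload["target"],
            ipsi_share=payload["ipsi_share"],
            area_weights=weights,
            laminar_profiles=lam,
            overdispersion=payload["overdispersion"],
            cells_per_animal=payload["cells_per_animal"],
            n_animals=payload["n_animals"],
            seed=payload["seed"],
            atlas=atlas,
        )


def _area_weight_vector(
    atlas: AtlasOntology, target: str, hemisphere: str, module_weights: dict[str, float]
) -> pd.Series:
    """Within-module geometric decay, homotopic boost, hemisphere-normalized."""
    w = pd.Series(0.0, index=pd.Index(atlas.acronyms, name="area"))
    for module, mw in module_weights.items():
        members = [
            a
            for a in atlas.areas_in_module(module)
            if not (hemisphere == IPSI and a == target)
        ]
        if not members:
            continue
        decay = np.array([_WITHIN_MODULE_DECAY**k for k in range(len(members))])
        w.loc[members] = mw * decay / decay.sum()
    if hemisphere == CONTRA:
        others = w.drop(index=target)
        w.loc[target] = _HOMOTOPIC_BOOST * others.max()
    return w / w.sum()


def _laminar_row(
    atlas: AtlasOntology, area: str, anchor: tuple[float, float, float]
) -> dict[str, float]:
    l23, l5, l6a = anchor
    # deterministic per-area tilt so areas occupy distinct hierarchy ranks
    tilt = _AREA_TILT * np.sin(2.7 * atlas.index_of(area))
    base = np.array([l23 + tilt, l5, l6a - tilt], dtype=float)
    base = np.clip(base, 0.02, None)
    base = base / base.sum()
    l4 = _L4_SHARE if atlas.has_L4(area) else 0.0
    main = 1.0 - l4 - _L6B_SHARE
    return {
        "L2/3": base[0] * main,
        "L4": l4,
        "L5": base[1] * main,
        "L6a": base[2] * main,
        "L6b": _L6B_SHARE,
    }


def default_profile(
    target: str = "VISp",
    ipsi_share: float = 0.8,
    overdispersion: float = 500.0,
    cells_per_animal: int = 200_000,
    n_animals: int = 6,
    seed: int = 0,
    atlas: AtlasOntology | None = None,
) -> GroundTruth:
    """Study-calibrated ground truth for one of the three injection targets."""
    if target not in DEFAULT_TARGETS:
        raise ValueError(f"target must be one of {DEFAULT_TARGETS}, got {target!r}")
    atlas = atlas if atlas is not None else load_atlas()

    weights = {}
    lam_rows = {}
    vasm = set(atlas.areas_in_group("v-a-sm"))
    for hemi in HEMISPHERES:
        weights[hemi] = _area_weight_vector(atlas, target, hemi, _MODULE_WEIGHTS[target][hemi])
        for area in atlas.acronyms:
            anchor = _VASM_LAMINAR[target][hemi] if area in vasm else _PFML_LAMINAR[hemi]
            lam_rows[(hemi, area)] = _laminar_row(atlas, area, anchor)

    area_weights = pd.concat(weights, names=["hemisphere"])
    lam = pd.DataFrame.from_dict(lam_rows, orient="index")[list(ANALYSIS_LAYERS)]
    lam.index = pd.MultiIndex.from_tuples(lam.index, names=["hemisphere", "area"])
    return GroundTruth(
        target=target,
        ipsi_share=ipsi_share,
        area_weights=area_weights.sort_index(),
        laminar_profiles=lam.sort_index(),
        overdispersion=overdispersion,
        cells_per_animal=cells_per_animal,
        n_animals=n_animals,
        seed=seed,
        atlas=atlas,
    )


def toy_profile(seed: int = 0, atlas: AtlasOntology | None = None) -> GroundTruth:
    """Tiny preset (3 source areas, 2 animals, 100 cells) for fast examples."""
    atlas = atlas if atlas is not None else load_atlas()
    target = "VISp"
    ipsi_w = {"VISl": 0.5, "VISal": 0.3, "ACAd": 0.2}
    contra_w = {"VISp": 0.4, "VISl": 0.3, "VISal": 0.2, "ACAd": 0.1}

    rows = {}
    weights = {}
    for hemi, wmap in ((IPSI, ipsi_w), (CONTRA, contra_w)):
        w = pd.Series(0.0, index=pd.Index(atlas.acronyms, name="area"))
        for a, v in wmap.items():
            w.loc[a] = v
        weights[hemi] = w
        vasm = set(atlas.areas_in_group("v-a-sm"))
        for area in atlas.acronyms:
            anchor = _VASM_LAMINAR[target][hemi] if area in vasm else _PFML_LAMINAR[hemi]
            rows[(hemi, area)] = _laminar_row(atlas, area, anchor)

    area_weights = pd.concat(weights, names=["hemisphere"])
    lam = pd.DataFrame.from_dict(rows, orient="index")[list(ANALYSIS_LAYERS)]
    lam.index = pd.MultiIndex.from_tuples(lam.index, names=["hemisphere", "area"])
    return GroundTruth(
        target=target,
        ipsi_share=0.8,
        area_weights=area_weights.sort_index(),
        laminar_profiles=lam.sort_index(),
        overdispersion=50.0,
        cells_per_animal=100,
        n_animals=2,
        seed=seed,
        atlas=atlas,
    )


def simulate_cohort(
    gt: GroundTruth, seed: int | None = None
) -> tuple[CohortData, pd.DataFrame]:
    """Draw a cohort of animals from a ground truth.

    Per animal: the ipsilateral share, per-hemisphere area weights, and
    per-area laminar profiles are each perturbed around the truth with a
    Beta/Dirichlet draw of concentration ``gt.overdispersion``; the
    animal's cells are then one multinomial draw from the composed
    (hemisphere, area, layer) probability vector.  Fully reproducible from
    the seed.

    Returns the aggregated cohort and the per-cell event list (columns
    ``animal_id, hemisphere, area, layer``), the substrate for brute-force
    oracle recomputation.
    """
    rng = np.random.default_rng(gt.seed if seed is None else seed)
    atlas = gt.atlas
    kappa = gt.overdispersion

    # support: (hemi, area, layer) cells can land in
    support = []
    base_p = []
    for hemi in HEMISPHERES:
        hemi_p = gt.ipsi_share if hemi == IPSI else 1.0 - gt.ipsi_share
        for area in atlas.acronyms:
            w = float(gt.area_weights.loc[(hemi, area)])
            if w == 0:
                continue
            lam = gt.laminar_profiles.loc[(hemi, area)]
            for layer in ANALYSIS_LAYERS:
                p = float(lam[layer])
                if p > 0:
                    support.append((hemi, area, layer))
                    base_p.append(hemi_p * w * p)
    support_df = pd.DataFrame(support, columns=["hemisphere", "area", "layer"])

    animals = []
    event_frames = []
    for i in range(gt.n_animals):
        animal_id = f"{gt.target}-{i + 1:02d}"

        share = rng.beta(kappa * gt.ipsi_share, kappa * (1.0 - gt.ipsi_share))
        hemi_p = {IPSI: share, CONTRA: 1.0 - share}

        area_p: dict[tuple[str, str], float] = {}
        for hemi in HEMISPHERES:
            w = gt.area_weights.loc[hemi]
            idx = w[w > 0].index
            draw = rng.dirichlet(kappa * w.loc[idx].values)
            for area, p in zip(idx, draw):
                area_p[(hemi, area)] = float(p)

        lam_p: dict[tuple[str, str, str], float] = {}
        for (hemi, area), _ in area_p.items():
            lam = gt.laminar_profiles.loc[(hemi, area)]
            layers = [l for l in ANALYSIS_LAYERS if lam[l] > 0]
            draw = rng.dirichlet(kappa * lam[layers].values)
            for layer, p in zip(layers, draw):
                lam_p[(hemi, area, layer)] = float(p)

        q = np.array(
            [
                hemi_p[h] * area_p[(h, a)] * lam_p[(h, a, l)]
                for h, a, l in support
            ]
        )
        q = q / q.sum()
        counts = rng.multinomial(gt.cells_per_animal, q)

        cell_rows = np.repeat(np.arange(len(support)), counts)
        rng.shuffle(cell_rows)
        events = support_df.iloc[cell_rows].reset_index(drop=True)
        events.insert(0, "animal_id", animal_id)
        event_frames.append(events)

        tidy = events.groupby(["hemisphere", "area", "layer"], as_index=False).size()
        tidy = tidy.rename(columns={"size": "count"})
        qc = InjectionQC(target_area=gt.target, injection_hemisphere="left")
        animals.append(AnimalCounts.from_tidy(animal_id, qc, tidy, atlas))

    cohort = CohortData(gt.target, tuple(animals))
    return cohort, pd.concat(event_frames, ignore_index=True)


def recovery_report(gt: GroundTruth, cohort: CohortData) -> pd.DataFrame:
    """Generative truth vs pipeline estimate for the key quantities.

    Rows cover the ipsilateral share, per-area areal fractions (both
    hemispheres, weight-map exclusions), per-area fILN, and the two
    module-group fILN means; columns: quantity, hemisphere, area, truth,
    estimate, abs_error.
    """
    from .hierarchy import filn_table, module_filn

    filtered = filter_cohort(cohort)
    rows = []

    shares = [hemisphere_share(a)[IPSI] for a in filtered.animals]
    est = float(np.nanmean(shares))
    rows.append(
        {
            "quantity": "ipsi_share",
            "hemisphere": "",
            "area": "",
            "truth": gt.ipsi_share,
            "estimate": est,
            "abs_error": abs(est - gt.ipsi_share),
        }
    )

    from .fractions import areal_fraction

    for hemi in HEMISPHERES:
        truth = gt.areal_fraction_truth(hemi, exclude_homotopic=True)
        per_animal = pd.DataFrame(
            [areal_fraction(a, hemi, WEIGHT_MAP_EXCLUSIONS) for a in filtered.animals]
        )
        est_frac = per_animal.mean(axis=0)
        for area in truth.index:
            e = float(est_frac.get(area, np.nan))
            rows.append(
                {
                    "quantity": "areal_fraction",
                    "hemisphere": hemi,
                    "area": area,
                    "truth": float(truth[area]),
                    "estimate": e,
                    "abs_error": abs(e - float(truth[area])),
                }
            )

    ftab = filn_table(cohort, "default")
    filn_est = ftab.groupby(["hemisphere", "area"])["filn"].mean()
    truth_filn = gt.filn_truth()
    for (hemi, area), t in truth_filn.items():
        if np.isnan(t):
            continue
        e = float(filn_est.get((hemi, area), np.nan))
        rows.append(
            {
                "quantity": "filn",
                "hemisphere": hemi,
                "area": area,
                "truth": float(t),
                "estimate": e,
                "abs_error": abs(e - float(t)) if np.isfinite(e) else np.nan,
            }
        )

    groups = module_filn(ftab, gt.atlas, grouping="groups")
    group_est = groups.groupby(["hemisphere", "unit"])["mean_filn"].mean()
    defined = ftab.dropna(subset=["filn"])
    for (hemi, unit), e in group_est.items():
        member_areas = set(gt.atlas.areas_in_group(unit))
        used = sorted(
            set(defined[defined["hemisphere"] == hemi]["area"]) & member_areas
        )
        if not used:
            continue
        t = float(truth_filn.loc[[(hemi, a) for a in used]].mean())
        rows.append(
            {
                "quantity": "group_filn",
                "hemisphere": hemi,
                "area": unit,
                "truth": t,
                "estimate": float(e),
                "abs_error": abs(float(e) - t),
            }
        )

    return pd.DataFrame(rows)
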