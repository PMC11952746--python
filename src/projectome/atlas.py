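"""Cortical parcellation, module membership, and layer definitions.

The analysis operates on the 45 cortical areas of the Allen Mouse Brain
Common Coordinate Framework (CCFv3) summary-structure parcellation of the
isocortex, plus lateral and medial entorhinal cortex.  Each area belongs to
exactly one of six connectivity-defined cortical modules (prefrontal,
lateral, somatomotor, visual, medial, auditory), and two coarser groupings
are used throughout: the sensory-motor group ``v-a-sm`` (visual + auditory +
somatomotor, 24 areas) and the frontal/associative group ``pf-m-l``
(prefrontal + medial + lateral, 21 areas).

The packaged area table is a reconstruction from the CCFv3 ontology and the
published module assignment; it can be overridden with a user CSV of the
same schema (columns ``acronym,index,module,has_L4``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

# -- layer and hemisphere vocabulary ----------------------------------------

#: All CCFv3 cortical layers.  L1 contains essentially no projection-neuron
#: somata and never carries counts in any table.
LAYERS: tuple[str, ...] = ("L1", "L2/3", "L4", "L5", "L6a", "L6b")

#: Layers that carry counts in analysis tables.
ANALYSIS_LAYERS: tuple[str, ...] = ("L2/3", "L4", "L5", "L6a", "L6b")

#: Default layer universe for the fILN hierarchy statistic (L6 := L6a).
FILN_LAYERS: tuple[str, ...] = ("L2/3", "L5", "L6a")

MODULES: tuple[str, ...] = (
    "prefrontal",
    "lateral",
    "somatomotor",
    "visual",
    "medial",
    "auditory",
)

#: The two module groupings compared across hemispheres.
MODULE_GROUPINGS: Mapping[str, frozenset[str]] = {
    "v-a-sm": frozenset({"visual", "auditory", "somatomotor"}),
    "pf-m-l": frozenset({"prefrontal", "medial", "lateral"}),
}

IPSI = "ipsi"
CONTRA = "contra"
HEMISPHERES: tuple[str, str] = (IPSI, CONTRA)

_BUILTIN_TABLE = "atlas_ccfv3_45.csv"


class AtlasSchemaError(ValueError):
    """Raised when an atlas table violates the documented schema."""


class UnknownAreaError(KeyError):
    """Raised when an area acronym is not part of the loaded parcellation."""


@dataclass(frozen=True)
class CorticalArea:
    """One summary-structure cortical area.

    ``has_L4`` is False for agranular areas (e.g. motor, prefrontal,
    retrosplenial, entorhinal cortex); such areas never carry L4 counts.
    """

    acronym: str
    index: int
    module: str
    has_L4: bool


class AtlasOntology:
    """Immutable lookup structure over the cortical parcellation."""

    def __init__(self, areas: Iterable[CorticalArea]):
        areas = tuple(areas)
        self._validate(areas)
        self.areas: tuple[CorticalArea, ...] = areas
        self._by_acronym = {a.acronym: a for a in areas}

    @staticmethod
    def _validate(areas: tuple[CorticalArea, ...]) -> None:
        if not areas:
            raise AtlasSchemaError("atlas table contains no areas")
        acronyms = [a.acronym for a in areas]
        dupes = {a for a in acronyms if acronyms.count(a) > 1}
        if dupes:
            raise AtlasSchemaError(f"duplicate acronyms in atlas table: {sorted(dupes)}")
        indices = [a.index for a in areas]
        if len(set(indices)) != len(indices):
            raise AtlasSchemaError("area indices are not unique")
        bad = [a.acronym for a in areas if a.module not in MODULES]
        if bad:
            raise AtlasSchemaError(f"unknown module for areas: {bad}")

    # -- lookups -------------------------------------------------------------

    def __contains__(self, acronym: str) -> bool:
        return acronym in self._by_acronym

    def __len__(self) -> int:
        return len(self.areas)

    def area(self, acronym: str) -> CorticalArea:
        try:
            return self._by_acronym[acronym]
        except KeyError:
            raise UnknownAreaError(f"unknown cortical area acronym: {acronym!r}") from None

    @property
    def acronyms(self) -> tuple[str, ...]:
        return tuple(a.acronym for a in self.areas)

    def module_of(self, acronym: str) -> str:
        return self.area(acronym).module

    def has_L4(self, acronym: str) -> bool:
        return self.area(acronym).has_L4

    def index_of(self, acronym: str) -> int:
        return self.area(acronym).index

    def areas_in_module(self, module: str) -> tuple[str, ...]:
        if module not in MODULES:
            raise KeyError(f"unknown module: {module!r}")
        return tuple(a.acronym for a in self.areas if a.module == module)

    def areas_in_group(self, group: str) -> tuple[str, ...]:
        try:
            members = MODULE_GROUPINGS[group]
        except KeyError:
            raise KeyError(f"unknown module grouping: {group!r}") from None
        return tuple(a.acronym for a in self.areas if a.module in members)

    def layers_of(self, acronym: str) -> tuple[str, ...]:
        """Analysis layers an area can carry counts in (drops L4 if agranular)."""
        if self.has_L4(acronym):
            return ANALYSIS_LAYERS
        return tuple(l for l in ANALYSIS_LAYERS if l != "L4")

    @property
    def module_groupings(self) -> Mapping[str, frozenset[str]]:
        return MODULE_GROUPINGS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "acronym": [a.acronym for a in self.areas],
                "index": [a.index for a in self.areas],
                "module": [a.module for a in self.areas],
                "has_L4": [a.has_L4 for a in self.areas],
            }
        )


def _parse_bool(value, row: int):
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise AtlasSchemaError(f"row {row}: has_L4 value {value!r} is not boolean")


def load_atlas(source: str | Path | None = None) -> AtlasOntology:
    """Load the packaged 45-area parcellation, or a user override table.

    Parameters
    ----------
    source:
        ``None`` for the packaged table, else a path to a CSV with columns
        ``acronym,index,module,has_L4``.

    Raises
    ------
    AtlasSchemaError
        If the table is malformed (missing columns, duplicate acronyms,
        unknown modules, non-integer indices), naming the offending row
        where possible.
    """
    if source is None:
        with resources.files("projectome.data").joinpath(_BUILTIN_TABLE).open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(source)

    required = {"acronym", "index", "module", "has_L4"}
    missing = required - set(table.columns)
    if missing:
        raise AtlasSchemaError(f"atlas table missing columns: {sorted(missing)}")

    areas = []
    for i, row in enumerate(table.to_dict("records")):
        try:
            idx = int(row["index"])
        except (TypeError, ValueError):
            raise AtlasSchemaError(f"row {i}: index {row['index']!r} is not an integer") from None
        areas.append(
            CorticalArea(
                acronym=str(row["acronym"]),
                index=idx,
                module=str(row["module"]),
                has_L4=_parse_bool(row["has_L4"], i),
            )
        )
    return AtlasOntology(areas)


def module_of(acronym: str, atlas: AtlasOntology) -> str:
    """Module an area belongs to (total function over the parcellation)."""
    return atlas.module_of(acronym)


def homotopic_of(acronym: str, hemisphere: str) -> tuple[str, str]:
    """Mirror-image counterpart: same area, opposite hemisphere.

    An involution: applying it twice is the identity.
    """
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"hemisphere must be one of {HEMISPHERES}, got {hemisphere!r}")
    other = CONTRA if hemisphere == IPSI else IPSI
    return acronym, other
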