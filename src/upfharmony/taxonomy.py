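"""Food-processing classification systems and the item-level allocation table.

Four taxonomies are encoded: NOVA (extent and purpose of industrial
processing, groups 1-4), IARC/EPIC (level of physical processing, groups
1-3), IFIC (complexity of processing and formulation, groups 1-5) and UNC
(extent of physicochemical change, groups 1, 2, 3.1, 3.2, 4.1, 4.2).  The
ultra-processed-food (UPF) group of each system is: NOVA {4}, IARC {3},
IFIC {4, 5}, UNC {4.1, 4.2}.

Group codes are strings throughout so that dotted UNC subcodes and plain
integer codes are handled uniformly.

The packaged default table (``data/taxonomy_synthetic.tsv``) is a synthetic
reconstruction of a 143-item Spanish semi-quantitative FFQ allocation: the
item-by-item published allocation is not openly redistributable, so the
packaged table reproduces its published structure instead -- 136 records of
which 135 are allocated in every system, per-system UPF item counts of
82 (IARC), 37 (NOVA) and 42 (IFIC and UNC), NOVA's UPF set nested inside
IARC's, and the documented single-item assumptions (UHT milk, industrially
produced custard and ice-cream, canned white asparagus, salted pistachios,
freshly baked bread, ...) recorded as notes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import (
    FormatError,
    IntegrityError,
    InsufficientDataError,
    UnknownSystemError,
    ValidationError,
)

__all__ = [
    "ClassificationSystem",
    "FoodItemRecord",
    "TaxonomyTable",
    "SYSTEMS",
    "SYSTEM_NAMES",
    "get_system",
    "load_taxonomy",
    "default_taxonomy",
    "is_upf",
    "upf_item_fraction",
]

TAXONOMY_COLUMNS = ("item_id", "label", "nova", "iarc", "ific", "unc", "note")


@dataclass(frozen=True)
class ClassificationSystem:
    """A food-processing taxonomy with an ordered set of group codes."""

    name: str
    group_codes: tuple[str, ...]
    upf_groups: frozenset[str]

    def __post_init__(self) -> None:
        if len(set(self.group_codes)) != len(self.group_codes):
            raise ValidationError(f"{self.name}: duplicate group codes")
        if not self.upf_groups:
            raise ValidationError(f"{self.name}: empty UPF group set")
        if not self.upf_groups < set(self.group_codes):
            raise ValidationError(
                f"{self.name}: UPF groups must be a strict subset of the "
                f"group codes"
            )


SYSTEMS: dict[str, ClassificationSystem] = {
    "NOVA": ClassificationSystem("NOVA", ("1", "2", "3", "4"),
                                 frozenset({"4"})),
    "IARC": ClassificationSystem("IARC", ("1", "2", "3"), frozenset({"3"})),
    "IFIC": ClassificationSystem("IFIC", ("1", "2", "3", "4", "5"),
                                 frozenset({"4", "5"})),
    "UNC": ClassificationSystem(
        "UNC", ("1", "2", "3.1", "3.2", "4.1", "4.2"),
        frozenset({"4.1", "4.2"})),
}
SYSTEM_NAMES = tuple(SYSTEMS)


def get_system(system: str | ClassificationSystem) -> ClassificationSystem:
    """Resolve a system given by name or instance; raise if unknown."""
    if isinstance(system, ClassificationSystem):
        if system.name not in SYSTEMS:
            raise UnknownSystemError(system.name)
        return system
    try:
        return SYSTEMS[str(system).upper()]
    except KeyError:
        raise UnknownSystemError(
            f"unknown classification system {system!r}; expected one of "
            f"{', '.join(SYSTEM_NAMES)}"
        ) from None


@dataclass(frozen=True)
class FoodItemRecord:
    """One FFQ food item and its processing group in each system.

    ``group_by_system`` maps each of the four system names to a group code,
    or to ``None`` for an item left unallocated in that system.
    """

    item_id: str
    label: str
    group_by_system: Mapping[str, str | None]
    note: str = ""

    def __post_init__(self) -> None:
        if set(self.group_by_system) != set(SYSTEM_NAMES):
            raise ValidationError(
                f"{self.item_id}: group_by_system must have exactly the "
                f"four system keys {SYSTEM_NAMES}"
            )
        for name, code in self.group_by_system.items():
            if code is not None and code not in SYSTEMS[name].group_codes:
                raise ValidationError(
                    f"{self.item_id}: invalid {name} group code {code!r} "
                    f"(valid: {', '.join(SYSTEMS[name].group_codes)})"
                )

    def code(self, system: str | ClassificationSystem) -> str | None:
        return self.group_by_system[get_system(system).name]

    def is_allocated(self, system: str | ClassificationSystem) -> bool:
        return self.code(system) is not None


def is_upf(record: FoodItemRecord,
           system: str | ClassificationSystem) -> bool:
    """True iff the record's group in ``system`` is one of its UPF groups."""
    sys_ = get_system(system)
    code = record.code(sys_)
    if code is None:
        raise ValidationError(
            f"{record.item_id} is not allocated under {sys_.name}"
        )
    return code in sys_.upf_groups


@dataclass(frozen=True)
class TaxonomyTable:
    """A validated collection of food-item allocation records."""

    records: tuple[FoodItemRecord, ...]
    version: str = "unversioned"
    _by_id: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = [r.item_id for r in self.records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise IntegrityError(f"duplicate item_id(s): {', '.join(dupes)}")
        object.__setattr__(self, "_by_id",
                           {r.item_id: r for r in self.records})

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, item_id: str) -> FoodItemRecord:
        return self._by_id[item_id]

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._by_id

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(r.item_id for r in self.records)

    def allocated_ids(
            self, system: str | ClassificationSystem) -> tuple[str, ...]:
        """Items that carry a group code in the given system."""
        sys_ = get_system(system)
        return tuple(r.item_id for r in self.records if r.is_allocated(sys_))

    def upf_ids(self, system: str | ClassificationSystem) -> tuple[str, ...]:
        """Items whose group in the given system is a UPF group."""
        sys_ = get_system(system)
        return tuple(r.item_id for r in self.records
                     if r.is_allocated(sys_) and is_upf(r, sys_))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "item_id": r.item_id,
                "label": r.label,
                "nova": r.group_by_system["NOVA"] or "",
                "iarc": r.group_by_system["IARC"] or "",
                "ific": r.group_by_system["IFIC"] or "",
                "unc": r.group_by_system["UNC"] or "",
                "note": r.note,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(TAXONOMY_COLUMNS))

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _records_from_frame(frame: pd.DataFrame) -> tuple[FoodItemRecord, ...]:
    records = []
    bad_rows: list[str] = []
    for _, row in frame.iterrows():
        groups = {}
        for name, col in (("NOVA", "nova"), ("IARC", "iarc"),
                          ("IFIC", "ific"), ("UNC", "unc")):
            raw = row[col]
            raw = "" if pd.isna(raw) else str(raw).strip()
            groups[name] = raw or None
        try:
            records.append(
                FoodItemRecord(
                    item_id=str(row["item_id"]).strip(),
                    label=str(row["label"]),
                    group_by_system=groups,
                    note="" if pd.isna(row["note"]) else str(row["note"]),
                )
            )
        except ValidationError as exc:
            bad_rows.append(str(exc))
    if bad_rows:
        raise ValidationError(
            "invalid group code(s):\n  " + "\n  ".join(bad_rows)
        )
    return tuple(records)


def load_taxonomy(path: str | Path, version: str | None = None
                  ) -> TaxonomyTable:
    """Read and validate a tab-separated allocation table.

    The file must be UTF-8 TSV with header columns
    ``item_id  label  nova  iarc  ific  unc  note``; empty group cells mean
    the item is unallocated in that system.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                        na_values=[])
    missing = [c for c in TAXONOMY_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s) {', '.join(missing)}"
        )
    return TaxonomyTable(_records_from_frame(frame),
                         version=version or path.stem)


@lru_cache(maxsize=1)
def default_taxonomy() -> TaxonomyTable:
    """The packaged synthetic 136-record allocation table."""
    with resources.as_file(
        resources.files("upfharmony.data") / "taxonomy_synthetic.tsv"
    ) as path:
        return load_taxonomy(path, version="synthetic-1")


def upf_item_fraction(table: TaxonomyTable,
                      system: str | ClassificationSystem) -> float:
    """Percentage of allocated items that fall in the UPF group.

    The denominator is the number of records allocated in the given system
    (135 in the packaged table); the result is reported to one decimal.
    """
    if len(table) == 0:
        raise InsufficientDataError("empty taxonomy table")
    sys_ = get_system(system)
    allocated = [r for r in table if r.is_allocated(sys_)]
    if not allocated:
        raise InsufficientDataError(
            f"no items allocated under {sys_.name}"
        )
    n_upf = sum(is_upf(r, sys_) for r in allocated)
    return round(100.0 * n_upf / len(allocated), 1)
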