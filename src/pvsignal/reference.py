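"""Reference tables: PT -> SOC mapping and the ATC N03A substance catalogue.

Both tables are plain delimited text. A default catalogue (the N03A
antiepileptics with their chemical subgroup and old/new market-era label)
and a small demonstration PT -> SOC map are bundled with the package;
users supply their own licensed terminology map for real analyses.
"""
from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .model import ChemicalSubgroup, DrugExposure, Era, NOT_SPECIFIED_SOC

_WS = re.compile(r"\s+")


def normalize_substance(name: str) -> str:
    """Casefold, trim and collapse whitespace for substance-name matching."""
    return _WS.sub(" ", name.strip()).casefold()


def _open_data(name: str) -> io.TextIOWrapper:
    return resources.files("pvsignal.data").joinpath(name).open("r", encoding="utf-8")


class MedDRAMap:
    """Single primary SOC per preferred term; lookups never fail.

    Unmapped PTs resolve to ``"Not Specified"`` and are counted on the
    instance (``n_unmapped``) so callers can report them.
    """

    def __init__(self, entries: Optional[dict] = None):
        self._entries = {normalize_substance(pt): soc for pt, soc in (entries or {}).items()}
        self.n_unmapped = 0

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, pt: str) -> bool:
        return normalize_substance(pt) in self._entries

    def get(self, pt: str) -> str:
        soc = self._entries.get(normalize_substance(pt))
        if soc is None:
            self.n_unmapped += 1
            return NOT_SPECIFIED_SOC
        return soc

    @classmethod
    def from_csv(cls, path_or_handle, delimiter: str = ",") -> "MedDRAMap":
        if hasattr(path_or_handle, "read"):
            reader = csv.DictReader(path_or_handle, delimiter=delimiter)
            return cls({row["pt"]: row["soc"] for row in reader})
        with open(path_or_handle, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter=delimiter)
            return cls({row["pt"]: row["soc"] for row in reader})

    @classmethod
    def load_demo(cls) -> "MedDRAMap":
        with _open_data("pt_soc_demo.csv") as fh:
            return cls.from_csv(fh)


@dataclass
class CatalogueEntry:
    substance: str  # canonical display name
    atc_code: str
    subgroup: ChemicalSubgroup
    era: Era


class ATCCatalogue:
    """Substance -> (ATC code, chemical subgroup, era) lookup.

    Matching is case-insensitive and folds salt/ester synonyms onto one
    canonical substance (e.g. valproic acid and its sodium salt are a
    single entry). Unknown substances resolve to era ``unclassified``.
    """

    def __init__(self, entries: list, synonyms: Optional[dict] = None):
        self._entries = {normalize_substance(e.substance): e for e in entries}
        self._synonyms = {
            normalize_substance(a): normalize_substance(c) for a, c in (synonyms or {}).items()
        }

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def substances(self) -> list:
        return [e.substance for e in self._entries.values()]

    def canonical(self, name: str) -> str:
        key = normalize_substance(name)
        key = self._synonyms.get(key, key)
        entry = self._entries.get(key)
        return entry.substance if entry else name.strip()

    def lookup(self, name: str) -> DrugExposure:
        key = normalize_substance(name)
        key = self._synonyms.get(key, key)
        entry = self._entries.get(key)
        if entry is None:
            return DrugExposure(substance=name.strip(), era=Era.UNCLASSIFIED)
        return DrugExposure(
            substance=entry.substance,
            atc_code=entry.atc_code,
            subgroup=entry.subgroup,
            era=entry.era,
        )

    @classmethod
    def from_csv(cls, path_or_handle, synonyms: Optional[dict] = None,
                 delimiter: str = ",") -> "ATCCatalogue":
        def _read(fh):
            entries = []
            for row in csv.DictReader(fh, delimiter=delimiter):
                entries.append(
                    CatalogueEntry(
                        substance=row["substance"],
                        atc_code=row["atc_code"],
                        subgroup=ChemicalSubgroup(row["chemical_subgroup"]),
                        era=Era(row["era"]),
                    )
                )
            return entries

        if hasattr(path_or_handle, "read"):
            return cls(_read(path_or_handle), synonyms)
        with open(path_or_handle, newline="", encoding="utf-8") as fh:
            return cls(_read(fh), synonyms)

    @classmethod
    def load_default(cls) -> "ATCCatalogue":
        with _open_data("synonyms.csv") as fh:
            synonyms = {row["alias"]: row["canonical"] for row in csv.DictReader(fh)}
        with _open_data("atc_n03a.csv") as fh:
            return cls.from_csv(fh, synonyms=synonyms)
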