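"""Association scans over a normalized report set.

All scans share the same machinery: flatten the reports into a PT-level
frame (one row per attributed drug-reaction pair), pick an exposure
grouping (old vs new era, one chemical subgroup vs the rest, one substance
vs the rest), pick an event axis (SOC, seriousness criterion, outcome
level, or a single PT), build the 2x2 table per event level and run the
full disproportionality computation on it.

Counting unit: demographics use report counts; association scans default
to PT-occurrence counts (``unit="pt"``). With the default
``attribution="all_suspected"`` every reaction is credited to every
suspected drug on its report, mirroring per-drug line-listing exports.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .model import (
    ChemicalSubgroup,
    Era,
    OUTCOME_LEVELS,
    SERIOUSNESS_CRITERIA,
    Seriousness,
    Sex,
)
from .stats import ContingencyTable, DisproResult, chi_square_rxc, compute

DEFAULT_SUDEP_TERMS = ("Sudden unexplained death in epilepsy",)

_SER_COLS = {s: f"ser_{s.value}" for s in Seriousness}

RESULT_COLUMNS = [
    "exposure", "event", "a", "b", "c", "d",
    "ror", "ror_l", "ror_u", "prr", "prr_l", "prr_u",
    "chi2", "dof", "p", "n_cases", "countable",
    "sdr_ci_rule", "sdr_chi2_rule",
]


class Dataset:
    """Normalized report set plus its flattened PT-level frame.

    ``attribution`` controls multi-drug reports: ``all_suspected`` credits
    each reaction to every suspected drug (default), ``first_listed`` only
    to the first drug on the report.
    """

    def __init__(self, reports: list, attribution: str = "all_suspected"):
        if attribution not in ("all_suspected", "first_listed"):
            raise ValueError(f"unknown attribution {attribution!r}")
        self.reports = reports
        self.attribution = attribution
        self._pt_frame: Optional[pd.DataFrame] = None
        self._report_frame: Optional[pd.DataFrame] = None

    def __len__(self) -> int:
        return len(self.reports)

    @property
    def pt_frame(self) -> pd.DataFrame:
        if self._pt_frame is None:
            self._pt_frame = _build_pt_frame(self.reports, self.attribution)
        return self._pt_frame

    @property
    def report_frame(self) -> pd.DataFrame:
        if self._report_frame is None:
            self._report_frame = _build_report_frame(self.reports)
        return self._report_frame

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for rep in self.reports:
            h.update(rep.report_id.encode())
            h.update(str(rep.receipt_year).encode())
            h.update(str(len(rep.reactions)).encode())
        h.update(self.attribution.encode())
        return h.hexdigest()[:16]


def _build_pt_frame(reports: list, attribution: str) -> pd.DataFrame:
    cols: dict = {name: [] for name in (
        "report_id", "year", "sex", "age_group", "reporter", "region",
        "substance", "subgroup", "era", "pt", "soc", "outcome")}
    ser_flags: dict = {c: [] for c in _SER_COLS.values()}
    append = {k: v.append for k, v in cols.items()}
    for rep in reports:
        drugs = rep.drugs if attribution == "all_suspected" else rep.drugs[:1]
        for drug in drugs:
            for rec in rep.reactions:
                append["report_id"](rep.report_id)
                append["year"](rep.receipt_year)
                append["sex"](rep.sex.value)
                append["age_group"](rep.age_group.value)
                append["reporter"](rep.reporter.value)
                append["region"](rep.region.value)
                append["substance"](drug.substance)
                append["subgroup"](drug.subgroup.value if drug.subgroup else "")
                append["era"](drug.era.value)
                append["pt"](rec.pt)
                append["soc"](rec.soc)
                append["outcome"](rec.outcome.value)
                for s in Seriousness:
                    ser_flags[_SER_COLS[s]].append(s in rec.seriousness)
    frame = pd.DataFrame(cols)
    for name in ("sex", "age_group", "reporter", "region", "substance",
                 "subgroup", "era", "pt", "soc", "outcome"):
        frame[name] = frame[name].astype("category")
    for name, values in ser_flags.items():
        frame[name] = np.asarray(values, dtype=bool)
    return frame


def _build_report_frame(reports: list) -> pd.DataFrame:
    rows = []
    for rep in reports:
        rows.append({
            "report_id": rep.report_id,
            "year": rep.receipt_year,
            "sex": rep.sex.value,
            "age_group": rep.age_group.value,
            "reporter": rep.reporter.value,
            "region": rep.region.value,
            "n_drugs": len(rep.drugs),
            "n_reactions": len(rep.reactions),
            "has_sudep": any(r.pt in DEFAULT_SUDEP_TERMS for r in rep.reactions),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Strata filters
# ---------------------------------------------------------------------------

_STRATA_KEYS = {"sex", "age", "year", "reporter"}


def parse_strata(text: str) -> dict:
    """Parse the ``sex=female,age=18-64,year=2012:2021`` mini-language."""
    strata: dict = {}
    if not text:
        return strata
    for part in text.split(","):
        if "=" not in part:
            raise ValueError(f"bad stratum {part!r}, expected key=value")
        key, _, value = part.partition("=")
        key = key.strip()
        value = value.strip()
        if key not in _STRATA_KEYS:
            raise ValueError(f"unknown stratum key {key!r} (use {sorted(_STRATA_KEYS)})")
        if key == "year":
            if ":" in value:
                lo, _, hi = value.partition(":")
                strata["year"] = (int(lo), int(hi))
            else:
                strata["year"] = (int(value), int(value))
        else:
            strata[key] = value
    return strata


def apply_strata(frame: pd.DataFrame, strata: Optional[dict]) -> pd.DataFrame:
    if not strata:
        return frame
    mask = pd.Series(True, index=frame.index)
    if "sex" in strata:
        mask &= frame["sex"].astype(str) == strata["sex"]
    if "age" in strata:
        mask &= frame["age_group"].astype(str) == strata["age"]
    if "reporter" in strata:
        mask &= frame["reporter"].astype(str) == strata["reporter"]
    if "year" in strata:
        lo, hi = strata["year"]
        mask &= (frame["year"] >= lo) & (frame["year"] <= hi)
    return frame[mask]


# ---------------------------------------------------------------------------
# Scan result container
# ---------------------------------------------------------------------------

@dataclass
class ScanResultTable:
    frame: pd.DataFrame                       # RESULT_COLUMNS
    spec: dict = field(default_factory=dict)  # scan descriptor
    dataset_hash: str = ""
    timestamp: str = ""

    def to_delimited(self, path, sep: str = ",") -> None:
        self.frame.to_csv(path, sep=sep, index=False)

    def sidecar(self) -> dict:
        return {"spec": self.spec, "dataset_hash": self.dataset_hash,
                "timestamp": self.timestamp}

    def write(self, table_path, meta_path, sep: str = ",") -> None:
        self.to_delimited(table_path, sep=sep)
        with open(meta_path, "w", encoding="utf-8") as fh:
            json.dump(self.sidecar(), fh, indent=2, sort_keys=True)

    def row(self, exposure: str, event: str) -> pd.Series:
        f = self.frame
        hits = f[(f["exposure"] == exposure) & (f["event"] == event)]
        if hits.empty:
            raise KeyError((exposure, event))
        return hits.iloc[0]


def _result_row(exposure: str, event: str, res: DisproResult) -> dict:
    t = res.table
    return {
        "exposure": exposure, "event": event,
        "a": t.a, "b": t.b, "c": t.c, "d": t.d,
        "ror": res.ror, "ror_l": res.ror_ci[0], "ror_u": res.ror_ci[1],
        "prr": res.prr, "prr_l": res.prr_ci[0], "prr_u": res.prr_ci[1],
        "chi2": res.chi2, "dof": res.dof, "p": res.p,
        "n_cases": res.n_cases, "countable": res.countable,
        "sdr_ci_rule": res.sdr.ci_rule, "sdr_chi2_rule": res.sdr.chi2_rule,
    }


def _finish(rows: list, spec: dict, dataset: Dataset) -> ScanResultTable:
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    frame = frame.sort_values(["exposure", "event"], kind="mergesort").reset_index(drop=True)
    return ScanResultTable(
        frame=frame, spec=spec, dataset_hash=dataset.content_hash(),
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )


# ---------------------------------------------------------------------------
# Exposure groupings
# ---------------------------------------------------------------------------

def _exposure_pairs(frame: pd.DataFrame, grouping: str):
    """Yield (exposure label, exposed mask, comparator mask) per grouping.

    Era grouping contrasts old vs new and drops unclassified-era rows from
    both arms; subgroup/substance groupings contrast one level against all
    the rest of the frame.
    """
    if grouping in ("era", "era_old_vs_new"):
        era = frame["era"].astype(str)
        old = (era == Era.OLD.value).to_numpy()
        new = (era == Era.NEW.value).to_numpy()
        yield Era.OLD.value, old, new
        yield Era.NEW.value, new, old
    elif grouping in ("subgroup", "subgroup_vs_rest"):
        sub = frame["subgroup"].astype(str)
        for g in ChemicalSubgroup:
            exposed = (sub == g.value).to_numpy()
            yield g.value, exposed, ~exposed
    elif grouping in ("substance", "substance_vs_rest"):
        sub = frame["substance"].astype(str)
        for name in sorted(sub.unique()):
            exposed = (sub == name).to_numpy()
            yield name, exposed, ~exposed
    else:
        raise ValueError(f"unknown grouping {grouping!r}")


def build_table(frame: pd.DataFrame, exposed_mask, event_mask,
                exposure_label: str = "exposed", event_label: str = "event",
                unit: str = "pt") -> ContingencyTable:
    """Assemble a 2x2 table from boolean masks over the PT-level frame."""
    exposed_mask = np.asarray(exposed_mask, dtype=bool)
    event_mask = np.asarray(event_mask, dtype=bool)
    a = int((exposed_mask & event_mask).sum())
    b = int(exposed_mask.sum()) - a
    c = int((~exposed_mask & event_mask).sum())
    d = int((~exposed_mask).sum()) - c
    return ContingencyTable(a, b, c, d, exposure_label=exposure_label,
                            event_label=event_label, unit=unit)


def _scan(dataset: Dataset, grouping: str, event_levels, event_mask_fn,
          event_axis: str, strata: Optional[dict] = None,
          restrict_classified: bool = True) -> ScanResultTable:
    frame = apply_strata(dataset.pt_frame, strata)
    if restrict_classified and grouping in ("era", "era_old_vs_new"):
        frame = frame[frame["era"].astype(str) != Era.UNCLASSIFIED.value]
    rows = []
    for exposure, exposed, comparator in _exposure_pairs(frame, grouping):
        for level in event_levels:
            event = np.asarray(event_mask_fn(frame, level), dtype=bool)
            a = int((exposed & event).sum())
            b = int(exposed.sum()) - a
            c = int((comparator & event).sum())
            d = int(comparator.sum()) - c
            table = ContingencyTable(a, b, c, d, exposure_label=exposure,
                                     event_label=str(level), unit="pt")
            rows.append(_result_row(exposure, str(level), compute(table)))
    spec = {"grouping": grouping, "event_axis": event_axis,
            "strata": strata or {}, "unit": "pt",
            "attribution": dataset.attribution}
    return _finish(rows, spec, dataset)


# ---------------------------------------------------------------------------
# The scans
# ---------------------------------------------------------------------------

def soc_scan(dataset: Dataset, grouping: str = "era",
             strata: Optional[dict] = None) -> ScanResultTable:
    """One row per SOC present in the dataset (including "Not Specified")."""
    frame = apply_strata(dataset.pt_frame, strata)
    levels = sorted(frame["soc"].astype(str).unique())
    return _scan(dataset, grouping, levels,
                 lambda f, s: (f["soc"].astype(str) == s).to_numpy(),
                 "soc", strata)


def seriousness_scan(dataset: Dataset, grouping: str = "era",
                     strata: Optional[dict] = None) -> ScanResultTable:
    """One row per seriousness criterion; multi-label, so a reaction
    carrying k criteria contributes to k rows. Reactions with wholly
    unspecified seriousness stay in the b/d cells."""
    levels = [s.value for s in SERIOUSNESS_CRITERIA]
    return _scan(dataset, grouping, levels,
                 lambda f, s: f[f"ser_{s}"].to_numpy(),
                 "seriousness_criterion", strata)


def outcome_scan(dataset: Dataset, grouping: str = "era",
                 strata: Optional[dict] = None) -> ScanResultTable:
    """One row per known outcome level; the rows partition the reactions
    with a known outcome (unspecified stays in the b/d cells)."""
    levels = [o.value for o in OUTCOME_LEVELS]
    return _scan(dataset, grouping, levels,
                 lambda f, o: (f["outcome"].astype(str) == o).to_numpy(),
                 "outcome", strata)


def sudep_scan(dataset: Dataset, grouping: str = "era",
               strata: Optional[dict] = None,
               sudep_terms: Iterable[str] = DEFAULT_SUDEP_TERMS) -> ScanResultTable:
    """Single-event scan: the event is membership in the configured SUDEP
    PT list (exact name match)."""
    terms = list(sudep_terms)
    return _scan(dataset, grouping, ["SUDEP"],
                 lambda f, _lvl: f["pt"].astype(str).isin(terms).to_numpy(),
                 "single_pt", strata)


def top_pt_table(dataset: Dataset, n: int = 10,
                 strata: Optional[dict] = None) -> pd.DataFrame:
    """Top-n PTs by occurrence count; percent of the total PT count at two
    decimals (round-half-up); ties broken alphabetically."""
    from .stats import round_half_up

    frame = apply_strata(dataset.pt_frame, strata)
    total = len(frame)
    counts = frame["pt"].astype(str).value_counts()
    table = counts.rename_axis("pt").reset_index(name="count")
    table = table.sort_values(["count", "pt"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    table = table.head(max(int(n), 0))
    table["percent"] = [
        round_half_up(100.0 * c / total, 2) if total else 0.0 for c in table["count"]
    ]
    return table


def yearly_soc_series(dataset: Dataset,
                      strata: Optional[dict] = None) -> pd.DataFrame:
    """Complete year x SOC count grid (zero-filled)."""
    frame = apply_strata(dataset.pt_frame, strata)
    if frame.empty:
        return pd.DataFrame(columns=["year", "soc", "count"])
    years = range(int(frame["year"].min()), int(frame["year"].max()) + 1)
    socs = sorted(frame["soc"].astype(str).unique())
    counts = frame.groupby(["year", frame["soc"].astype(str)], observed=True).size()
    rows = [
        {"year": y, "soc": s, "count": int(counts.get((y, s), 0))}
        for y in years for s in socs
    ]
    return pd.DataFrame(rows, columns=["year", "soc", "count"])


def demographic_tests(dataset: Dataset) -> list:
    """The dependence tests reported alongside the scans.

    * era x sex on PT counts (2x3, not-specified sex column included);
    * SUDEP x sex on report counts (2x2, not-specified sex excluded).

    Returns a list of dicts; a test with a zero margin is returned with
    ``skipped`` set and a reason instead of statistics.
    """
    results = []

    pts = dataset.pt_frame
    pts = pts[pts["era"].astype(str) != Era.UNCLASSIFIED.value]
    sex_order = [Sex.MALE.value, Sex.FEMALE.value, Sex.UNSPECIFIED.value]
    cells = [
        [int(((pts["era"].astype(str) == era) & (pts["sex"].astype(str) == sx)).sum())
         for sx in sex_order]
        for era in (Era.OLD.value, Era.NEW.value)
    ]
    n = int(np.sum(cells))
    obs = np.asarray(cells)
    if n == 0 or obs.sum(axis=1).min() == 0 or obs.sum(axis=0).min() == 0:
        results.append({"test": "era_by_sex_pt", "skipped": True,
                        "reason": "zero margin"})
    else:
        chi2, dof, p = chi_square_rxc(cells)
        results.append({"test": "era_by_sex_pt", "chi2": chi2, "dof": dof,
                        "p": p, "n": n, "skipped": False})

    reps = dataset.report_frame
    if reps.empty:
        results.append({"test": "sudep_by_sex_report", "skipped": True,
                        "reason": "empty dataset"})
        return results
    known = reps[reps["sex"] != Sex.UNSPECIFIED.value]
    cells2 = []
    for sx in (Sex.MALE.value, Sex.FEMALE.value):
        grp = known[known["sex"] == sx]
        sudep = int(grp["has_sudep"].sum())
        cells2.append([sudep, len(grp) - sudep])
    obs2 = np.asarray(cells2)
    if obs2.sum() == 0 or obs2.sum(axis=1).min() == 0 or obs2.sum(axis=0).min() == 0:
        results.append({"test": "sudep_by_sex_report", "skipped": True,
                        "reason": "zero margin"})
    else:
        chi2, dof, p = chi_square_rxc(cells2)
        results.append({"test": "sudep_by_sex_report", "chi2": chi2, "dof": dof,
                        "p": p, "n": int(obs2.sum()), "skipped": False})
    return results
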