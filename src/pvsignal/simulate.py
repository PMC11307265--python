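"""Synthetic ICSR generation.

Two generators live here:

* :func:`generate_dataset` — a seeded sampler producing reports with the
  statistical structure the scans assume (demographics, 1..k drugs and
  1..m reaction PTs per report, multi-label seriousness, single-label
  outcome) and *planted* drug-event odds ratios whose recovery the test
  suite checks.
* :func:`margin_replicator` — a deterministic allocator that emits a
  dataset whose PT-level cell counts equal requested margins exactly, for
  fixtures that must reproduce published contingency cells.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from .model import (
    AgeGroup,
    CaseReport,
    DrugExposure,
    Era,
    NOT_SPECIFIED_SOC,
    Outcome,
    ReactionRecord,
    Region,
    Reporter,
    Seriousness,
    SERIOUSNESS_CRITERIA,
    Sex,
)
from .reference import ATCCatalogue, MedDRAMap


class SimConfigError(ValueError):
    """Invalid generator configuration (raised before any sampling)."""


class MarginError(ValueError):
    """Internally inconsistent target margins."""


def solve_event_prob(base_prob: float, target_or: float) -> float:
    """Per-draw event probability p in the exposed arm such that the
    draw-level odds ratio against base probability q equals ``target_or``:
    p/(1-p) = target_or * q/(1-q)."""
    q, rho = base_prob, target_or
    if not 0.0 < q < 1.0:
        raise SimConfigError(f"base probability must be in (0, 1), got {q}")
    if rho <= 0:
        raise SimConfigError(f"target odds ratio must be positive, got {rho}")
    odds = rho * q / (1.0 - q)
    p = odds / (1.0 + odds)
    if p >= 1.0:
        raise SimConfigError("implied exposed probability >= 1")
    return p


@dataclass(frozen=True)
class PlantedSignal:
    """A drug-event association baked into the generator."""

    event_pt: str
    exposure_kind: str   # "era" | "subgroup" | "substance"
    exposure_value: str
    target_or: float


_DEFAULT_PT_WEIGHTS = {
    "Seizure": 9.0, "Drug ineffective": 6.3, "Somnolence": 3.4, "Dizziness": 3.3,
    "Off label use": 2.9, "Rash": 2.7, "Pain": 2.5, "Fatigue": 2.5,
    "Toxicity to various agents": 2.4, "Drug interaction": 2.4, "Headache": 2.2,
    "Nausea": 2.1, "Tremor": 1.8, "Epilepsy": 1.6, "Pyrexia": 1.5,
    "Insomnia": 1.5, "Depression": 1.4, "Vomiting": 1.4, "Aggression": 1.2,
    "Weight increased": 1.2, "Status epilepticus": 1.0, "Diarrhoea": 1.0,
    "Pruritus": 0.9, "Overdose": 0.9, "Alopecia": 0.8, "Anaemia": 0.8,
    "Blood pressure increased": 0.7, "Thrombocytopenia": 0.6, "Hepatitis": 0.5,
    "Liver function test increased": 0.5, "Bradycardia": 0.4, "Hepatic failure": 0.3,
    "Completed suicide": 0.3, "Cardiac arrest": 0.3, "Agranulocytosis": 0.2,
    "Foetal anticonvulsant syndrome": 0.2, "Foetal valproate syndrome": 0.1,
    "Sudden unexplained death in epilepsy": 0.05,
}

_DEFAULT_SUBSTANCES = {
    "old": {"Valproic acid and Sodium Valproate": 0.35, "Carbamazepine": 0.25,
            "Clonazepam": 0.15, "Phenytoin": 0.10, "Phenobarbital": 0.05,
            "Primidone": 0.04, "Ethosuximide": 0.03, "Trimethadione": 0.03},
    "new": {"Pregabalin": 0.30, "Levetiracetam": 0.16, "Lamotrigine": 0.12,
            "Gabapentin": 0.10, "Topiramate": 0.07,
            "Lacosamide": 0.06, "Oxcarbazepine": 0.04, "Clobazam": 0.03,
            "Zonisamide": 0.02, "Vigabatrin": 0.02, "Brivaracetam": 0.02,
            "Perampanel": 0.02, "Eslicarbazepine": 0.01, "Tiagabine": 0.01,
            "Felbamate": 0.01, "Fosphenytoin": 0.01, "Rufinamide": 0.01,
            "Stiripentol": 0.005, "Cenobamate": 0.005},
}


def _normalize(weights: dict, what: str) -> dict:
    total = float(sum(weights.values()))
    if total <= 0:
        raise SimConfigError(f"{what}: weights must sum to a positive value")
    if any(v < 0 for v in weights.values()):
        raise SimConfigError(f"{what}: negative weight")
    return {k: v / total for k, v in weights.items()}


@dataclass
class SimConfig:
    """Generator parameters. Weight dicts are normalized on validation;
    normalized vectors must sum to 1 within 1e-9."""

    n_reports: int = 1000
    seed: int = 0
    era_probs: dict = field(default_factory=lambda: {"old": 0.35, "new": 0.65})
    substance_weights: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_SUBSTANCES.items()})
    sex_probs: dict = field(
        default_factory=lambda: {"male": 0.39, "female": 0.54, "unspecified": 0.07})
    age_probs: dict = field(
        default_factory=lambda: {"0-2": 0.03, "3-17": 0.09, "18-64": 0.48,
                                 "65plus": 0.18, "unspecified": 0.22})
    reporter_probs: dict = field(
        default_factory=lambda: {"healthcare_professional": 0.72,
                                 "non_healthcare_professional": 0.23,
                                 "unspecified": 0.05})
    region_probs: dict = field(
        default_factory=lambda: {"EEA": 0.36, "non_EEA": 0.64, "unspecified": 0.0})
    year_range: tuple = (2012, 2021)
    year_weights: Optional[dict] = None          # default: uniform over range
    pts_per_report_mean: float = 3.8             # shifted Poisson: 1 + Poisson(mean-1)
    multi_drug_prob: float = 0.1                 # chance of a second same-era drug
    pt_weights: dict = field(default_factory=lambda: dict(_DEFAULT_PT_WEIGHTS))
    pt_soc: Optional[dict] = None                # default: bundled demo map
    planted_signals: list = field(default_factory=list)
    seriousness_probs: dict = field(
        default_factory=lambda: {"other_medically_important": 0.45,
                                 "hospitalisation": 0.25, "congenital_anomaly": 0.02,
                                 "disabling": 0.03, "life_threatening": 0.04,
                                 "death": 0.04})
    outcome_probs: dict = field(
        default_factory=lambda: {"fatal": 0.04, "not_recovered": 0.13,
                                 "recovered": 0.21, "recovered_with_sequelae": 0.005,
                                 "recovering": 0.08, "unspecified": 0.535})

    def validate(self) -> "SimConfig":
        if self.n_reports < 1:
            raise SimConfigError("n_reports must be >= 1")
        if self.pts_per_report_mean <= 0:
            raise SimConfigError("pts_per_report_mean must be > 0")
        if not 0.0 <= self.multi_drug_prob <= 1.0:
            raise SimConfigError("multi_drug_prob must be in [0, 1]")
        self.era_probs = _normalize(self.era_probs, "era_probs")
        self.sex_probs = _normalize(self.sex_probs, "sex_probs")
        self.age_probs = _normalize(self.age_probs, "age_probs")
        self.reporter_probs = _normalize(self.reporter_probs, "reporter_probs")
        self.region_probs = _normalize(self.region_probs, "region_probs")
        self.pt_weights = _normalize(self.pt_weights, "pt_weights")
        for era in self.era_probs:
            if era not in self.substance_weights:
                raise SimConfigError(f"no substance weights for era {era!r}")
            self.substance_weights[era] = _normalize(
                {k: v for k, v in self.substance_weights[era].items() if v > 0},
                f"substance_weights[{era}]")
        years = range(self.year_range[0], self.year_range[1] + 1)
        if self.year_weights is None:
            self.year_weights = {y: 1.0 for y in years}
        self.year_weights = _normalize(self.year_weights, "year_weights")
        for probs in (self.era_probs, self.sex_probs, self.age_probs,
                      self.reporter_probs, self.region_probs, self.pt_weights,
                      self.year_weights):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise SimConfigError("probability vector does not sum to 1")
        if not 0.0 <= min(self.seriousness_probs.values()) <= max(
                self.seriousness_probs.values()) <= 1.0:
            raise SimConfigError("seriousness probabilities must be in [0, 1]")
        self.outcome_probs = _normalize(self.outcome_probs, "outcome_probs")
        signals = []
        for sig in self.planted_signals:
            if isinstance(sig, dict):
                sig = PlantedSignal(**sig)
            if sig.event_pt not in self.pt_weights:
                raise SimConfigError(f"planted signal PT {sig.event_pt!r} "
                                     "not in pt_weights")
            if sig.exposure_kind not in ("era", "subgroup", "substance"):
                raise SimConfigError(f"bad exposure_kind {sig.exposure_kind!r}")
            solve_event_prob(self.pt_weights[sig.event_pt], sig.target_or)
            signals.append(sig)
        self.planted_signals = signals
        return self

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "year_range" in raw:
            raw["year_range"] = tuple(raw["year_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["year_range"] = list(self.year_range)
        d["planted_signals"] = [asdict(s) for s in self.planted_signals]
        return d


class _Categorical:
    """Cumulative-probability sampler (faster than Generator.choice)."""

    def __init__(self, items: dict):
        self.values = list(items.keys())
        self.cum = np.cumsum(np.fromiter(items.values(), dtype=float))
        self.cum[-1] = 1.0  # guard against rounding

    def draw(self, rng: np.random.Generator):
        return self.values[int(np.searchsorted(self.cum, rng.random(), side="right"))]

    def draw_many(self, rng: np.random.Generator, size: int) -> list:
        idx = np.searchsorted(self.cum, rng.random(size), side="right")
        return [self.values[i] for i in idx]


def _adjusted_pt_sampler(base: dict, active: tuple) -> _Categorical:
    """Per-draw PT distribution with each active signal PT moved to its
    solved exposed probability; non-signal mass rescaled proportionally."""
    if not active:
        return _Categorical(base)
    targets = {pt: solve_event_prob(base[pt], rho) for pt, rho in active}
    q_sum = sum(base[pt] for pt in targets)
    p_sum = sum(targets.values())
    if p_sum >= 1.0:
        raise SimConfigError("planted signals demand total probability >= 1")
    scale = (1.0 - p_sum) / (1.0 - q_sum)
    adjusted = {pt: (targets[pt] if pt in targets else w * scale)
                for pt, w in base.items()}
    return _Categorical(adjusted)


def generate_dataset(config: SimConfig,
                     catalogue: Optional[ATCCatalogue] = None) -> list:
    """Sample a fully seeded, reproducible report list.

    Per-report RNG streams are derived from ``(seed, report index)`` so
    generation order cannot change the output. PT draws within a report
    are with replacement then deduplicated (a report lists a PT once),
    which slightly shrinks realized event odds at a large PT count; the
    recovery tests' tolerances account for that.
    """
    config.validate()
    catalogue = catalogue or ATCCatalogue.load_default()
    pt_soc = config.pt_soc
    if pt_soc is None:
        demo = MedDRAMap.load_demo()
        pt_soc = {pt: demo.get(pt) for pt in config.pt_weights}

    era_cat = _Categorical(config.era_probs)
    sub_cats = {era: _Categorical(w) for era, w in config.substance_weights.items()}
    sex_cat = _Categorical(config.sex_probs)
    age_cat = _Categorical(config.age_probs)
    rep_cat = _Categorical(config.reporter_probs)
    reg_cat = _Categorical(config.region_probs)
    year_cat = _Categorical(config.year_weights)
    out_cat = _Categorical(config.outcome_probs)
    ser_items = [(Seriousness(k), p) for k, p in config.seriousness_probs.items()]

    exposures = {name: catalogue.lookup(name)
                 for weights in config.substance_weights.values() for name in weights}

    # signal lookup: which signals are active given a report's drug set
    def active_signals(drugs: list) -> tuple:
        active = []
        for sig in config.planted_signals:
            for drug in drugs:
                key = {"era": drug.era.value,
                       "subgroup": drug.subgroup.value if drug.subgroup else "",
                       "substance": drug.substance}[sig.exposure_kind]
                if key == sig.exposure_value:
                    active.append((sig.event_pt, sig.target_or))
                    break
        return tuple(sorted(active))

    sampler_cache: dict = {(): _Categorical(config.pt_weights)}
    lam = max(config.pts_per_report_mean - 1.0, 1e-12)

    reports = []
    for i in range(config.n_reports):
        rng = np.random.default_rng((config.seed, i))
        era = era_cat.draw(rng)
        primary = exposures[sub_cats[era].draw(rng)]
        drugs = [primary]
        if config.multi_drug_prob and rng.random() < config.multi_drug_prob:
            extra = exposures[sub_cats[era].draw(rng)]  # same era: keeps era-level
            if extra.substance != primary.substance:    # signals undiluted
                drugs.append(extra)
        key = active_signals(drugs)
        sampler = sampler_cache.get(key)
        if sampler is None:
            sampler = _adjusted_pt_sampler(config.pt_weights, key)
            sampler_cache[key] = sampler
        n_pts = 1 + int(rng.poisson(lam))
        pts: list = []
        for pt in sampler.draw_many(rng, n_pts):
            if pt not in pts:  # dedupe, keep draw order
                pts.append(pt)
        reactions = []
        for pt in pts:
            criteria = frozenset(
                s for (s, prob) in ser_items if rng.random() < prob)
            if not criteria:
                criteria = frozenset({Seriousness.UNSPECIFIED})
            reactions.append(ReactionRecord(
                pt=pt,
                soc=pt_soc.get(pt, NOT_SPECIFIED_SOC),
                seriousness=criteria,
                outcome=Outcome(out_cat.draw(rng)),
            ))
        reports.append(CaseReport(
            report_id=f"SIM-{i:08d}",
            receipt_year=int(year_cat.draw(rng)),
            sex=Sex(sex_cat.draw(rng)),
            age_group=AgeGroup(age_cat.draw(rng)),
            reporter=Reporter(rep_cat.draw(rng)),
            region=Region(reg_cat.draw(rng)),
            drugs=drugs,
            reactions=reactions,
        ))
    return reports


def truth_sidecar(config: SimConfig) -> dict:
    """Planted-truth record written next to simulated listings."""
    return {
        "seed": config.seed,
        "n_reports": config.n_reports,
        "planted_signals": [asdict(s) for s in config.planted_signals],
    }


# ---------------------------------------------------------------------------
# Deterministic margin replication
# ---------------------------------------------------------------------------

_ERA_REPRESENTATIVES = {"old": "Phenobarbital", "new": "Levetiracetam"}


@dataclass
class MarginSpec:
    """Exact PT-level margins to replicate.

    ``totals`` maps an exposure label (``old``/``new`` or a substance
    name) to its total PT count; ``cells`` maps exposure -> event -> count.
    Any slack between the cell sum and the total is filled with
    ``filler_event``. ``event_axis``: ``soc`` (synthetic PTs carrying the
    event as their SOC) or ``pt`` (event labels are the PT names).
    """

    totals: dict
    cells: dict
    event_axis: str = "soc"
    filler_event: str = "Other events"


def margin_replicator(spec: MarginSpec, chunk_size: int = 1000,
                      catalogue: Optional[ATCCatalogue] = None) -> list:
    """Emit a dataset whose PT-level counts equal the requested cells
    exactly. Deterministic allocation, no sampling."""
    catalogue = catalogue or ATCCatalogue.load_default()
    if spec.event_axis not in ("soc", "pt"):
        raise MarginError(f"unknown event_axis {spec.event_axis!r}")
    reports = []
    years = list(range(2012, 2022))
    for exposure in spec.totals:
        total = spec.totals[exposure]
        if total <= 0:
            raise MarginError(f"exposure {exposure!r}: total must be positive, "
                              f"got {total}")
        cells = dict(spec.cells.get(exposure, {}))
        if any(v < 0 for v in cells.values()):
            raise MarginError(f"exposure {exposure!r}: negative cell count")
        cell_sum = sum(cells.values())
        if cell_sum > total:
            raise MarginError(
                f"exposure {exposure!r}: cells sum to {cell_sum} "
                f"> total {total}")
        if cell_sum < total:
            cells[spec.filler_event] = cells.get(spec.filler_event, 0) + (total - cell_sum)

        substance = _ERA_REPRESENTATIVES.get(exposure, exposure)
        drug = catalogue.lookup(substance)
        idx = 0
        for event in sorted(cells):
            remaining = cells[event]
            if spec.event_axis == "soc":
                record = ReactionRecord(pt=f"{event} reaction", soc=event)
            else:
                record = ReactionRecord(pt=event)
            while remaining > 0:
                size = min(chunk_size, remaining)
                remaining -= size
                reports.append(CaseReport(
                    report_id=f"{exposure}-{idx:07d}",
                    receipt_year=years[idx % len(years)],
                    drugs=[drug],
                    reactions=[record] * size,   # shared records: counts only
                ))
                idx += 1
    return reports
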