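"""Core record types for spontaneous adverse-event (ICSR) line listings.

One :class:`CaseReport` corresponds to one individual case safety report:
demographics, one or more suspected drug exposures, and one or more reported
reactions (MedDRA preferred terms with seriousness and outcome).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

NOT_SPECIFIED_SOC = "Not Specified"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNSPECIFIED = "unspecified"


class AgeGroup(str, enum.Enum):
    A0_2 = "0-2"
    A3_17 = "3-17"
    A18_64 = "18-64"
    A65_PLUS = "65plus"
    UNSPECIFIED = "unspecified"


class Reporter(str, enum.Enum):
    HEALTHCARE_PROFESSIONAL = "healthcare_professional"
    NON_HEALTHCARE_PROFESSIONAL = "non_healthcare_professional"
    UNSPECIFIED = "unspecified"


class Region(str, enum.Enum):
    EEA = "EEA"
    NON_EEA = "non_EEA"
    UNSPECIFIED = "unspecified"


class Era(str, enum.Enum):
    OLD = "old"
    NEW = "new"
    UNCLASSIFIED = "unclassified"


class ChemicalSubgroup(str, enum.Enum):
    BARBITURATES = "barbiturates"
    BENZODIAZEPINES = "benzodiazepines"
    CARBOXAMIDES = "carboxamides"
    FATTY_ACID_DERIVATIVES = "fatty_acid_derivatives"
    HYDANTOINS = "hydantoins"
    OTHER_ANTIEPILEPTICS = "other_antiepileptics"
    OXAZOLIDINES = "oxazolidines"
    SUCCINIMIDES = "succinimides"


class Seriousness(str, enum.Enum):
    """Regulatory seriousness criteria; a reaction may carry several."""

    OTHER_MEDICALLY_IMPORTANT = "other_medically_important"
    HOSPITALISATION = "hospitalisation"
    CONGENITAL_ANOMALY = "congenital_anomaly"
    DISABLING = "disabling"
    LIFE_THREATENING = "life_threatening"
    DEATH = "death"
    UNSPECIFIED = "unspecified"


#: Seriousness values that are actual criteria (excludes the unspecified bucket).
SERIOUSNESS_CRITERIA = tuple(s for s in Seriousness if s is not Seriousness.UNSPECIFIED)


class Outcome(str, enum.Enum):
    """Resolution status of one reaction; single-valued per reaction."""

    FATAL = "fatal"
    NOT_RECOVERED = "not_recovered"
    RECOVERED = "recovered"
    RECOVERED_WITH_SEQUELAE = "recovered_with_sequelae"
    RECOVERING = "recovering"
    UNSPECIFIED = "unspecified"


#: Outcome levels excluding the unspecified bucket.
OUTCOME_LEVELS = tuple(o for o in Outcome if o is not Outcome.UNSPECIFIED)


@dataclass
class DrugExposure:
    """One suspected drug on a report, resolved against the ATC catalogue."""

    substance: str
    atc_code: str = ""
    subgroup: Optional[ChemicalSubgroup] = None
    era: Era = Era.UNCLASSIFIED


@dataclass
class ReactionRecord:
    """One preferred-term occurrence with its SOC, seriousness set and outcome.

    ``seriousness`` is a *set*: a single reaction may fulfil several
    regulatory criteria at once. ``outcome`` is single-valued.
    """

    pt: str
    soc: str = NOT_SPECIFIED_SOC
    seriousness: frozenset = frozenset({Seriousness.UNSPECIFIED})
    outcome: Outcome = Outcome.UNSPECIFIED
    duration: Optional[str] = None
    malformed: bool = False
    raw: Optional[str] = None


@dataclass
class CaseReport:
    report_id: str
    receipt_year: int
    sex: Sex = Sex.UNSPECIFIED
    age_group: AgeGroup = AgeGroup.UNSPECIFIED
    reporter: Reporter = Reporter.UNSPECIFIED
    region: Region = Region.UNSPECIFIED
    drugs: list = field(default_factory=list)
    reactions: list = field(default_factory=list)
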