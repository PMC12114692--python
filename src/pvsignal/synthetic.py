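"""Seeded synthetic ICSR cohorts with known ground truth.

Two generators live here:

* :func:`generate_cohort` draws random cohorts from a
  :class:`SyntheticCohortConfig` — per-drug reaction-probability profiles,
  demographic mixtures, seriousness/reporter/region/death rates and injected
  near-duplicates — so every pipeline stage and statistical property can be
  tested against a configured truth (e.g. the odds ratio implied by two
  reaction probabilities).

* :func:`reference_study` constructs, combinatorially and without
  randomness, a fixed three-drug study (esketamine 751 raw reports of which
  265 serious, fluoxetine 1066 serious, venlafaxine 2019 serious) whose
  per-PT, per-SOC, per-sex and per-age margins equal a reference
  EudraVigilance serious-report extraction (EEA + UK, 2019-2024).  Joint
  cells the reference does not pin down are free dimensions filled
  deterministically; the construction self-verifies and raises
  :class:`PresetConstructionError` naming any conflicting margin.
"""

from __future__ import annotations

import datetime as dt
import itertools
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .icsr import (
    AgeGroup,
    CohortCriteria,
    ICSRecord,
    MedDRAMap,
    Region,
    ReporterQualification,
    Seriousness,
    SeriousCriterion,
    Sex,
    normalize_drug_name,
)

__all__ = [
    "SyntheticCohortConfig",
    "CohortGroundTruth",
    "generate_cohort",
    "implied_odds_ratio",
    "ReferenceStudy",
    "PresetConstructionError",
    "reference_study",
    "reference_meddra_map",
    "reference_criteria",
    "PANEL_SOCS",
    "SUICIDALITY_PTS",
]

_DATE_START = dt.date(2019, 1, 1)
_DATE_END = dt.date(2024, 12, 31)
_WINDOW_DAYS = (_DATE_END - _DATE_START).days + 1


# --------------------------------------------------------------------------
# Random generator
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Generative parameters for a random multi-drug ICSR cohort.

    ``pt_profiles`` gives, per drug, the independent per-case occurrence
    probability of each PT.  Cases whose independent draws produce no
    reaction at all are redrawn, so realized marginal frequencies sit
    slightly above the configured probabilities for very sparse profiles.
    ``duplicate_rate`` is the fraction of cases copied into a near-duplicate
    row differing only in receipt date.
    """

    drugs: tuple[tuple[str, int], ...]
    pt_profiles: dict[str, dict[str, float]]
    soc_map: MedDRAMap = field(default_factory=MedDRAMap)
    sex_mix: float = 0.4
    unknown_sex_rate: float = 0.0
    age_mix: dict[AgeGroup, float] = field(
        default_factory=lambda: {AgeGroup.Y18_64: 0.8, AgeGroup.Y65_85: 0.2}
    )
    serious_rate: float = 1.0
    hcp_rate: float = 1.0
    eea_rate: float = 1.0
    death_rate: float = 0.0
    duplicate_rate: float = 0.0
    distinguish_collisions: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name, size in self.drugs:
            if size < 1:
                raise ValueError(f"cohort size for {name!r} must be >= 1")
            if name not in self.pt_profiles:
                raise ValueError(f"drug {name!r} has no PT profile")
            for pt, p in self.pt_profiles[name].items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability of {pt!r} for {name!r} outside [0, 1]")
                if self.distinguish_collisions and pt in _COMPANION_POOL:
                    raise ValueError(
                        f"profile PT {pt!r} clashes with the background vocabulary "
                        "reserved for collision distinguishing; rename it or set "
                        "distinguish_collisions=False"
                    )
        for label, p in (
            ("sex_mix", self.sex_mix),
            ("unknown_sex_rate", self.unknown_sex_rate),
            ("serious_rate", self.serious_rate),
            ("hcp_rate", self.hcp_rate),
            ("eea_rate", self.eea_rate),
            ("death_rate", self.death_rate),
            ("duplicate_rate", self.duplicate_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{label} must be in [0, 1]")
        total = sum(self.age_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"age_mix must sum to 1, got {total}")


@dataclass(frozen=True)
class CohortGroundTruth:
    """Labels recorded while generating a random cohort.

    ``duplicate_row_pairs`` lists (source index, duplicate index) into the
    returned record list; ``event_indicators`` maps drug -> PT -> boolean
    vector over that drug's non-duplicate cases, in generation order.
    """

    duplicate_row_pairs: tuple[tuple[int, int], ...]
    event_indicators: dict[str, dict[str, np.ndarray]]


def implied_odds_ratio(
    config: SyntheticCohortConfig, event: str, drug_a: str, drug_b: str
) -> float:
    """Odds ratio implied by the configured per-case probabilities."""
    try:
        p_a = config.pt_profiles[drug_a][event]
        p_b = config.pt_profiles[drug_b][event]
    except KeyError as exc:
        raise ValueError(f"event {event!r} missing from a profile") from exc
    if not (0.0 < p_a < 1.0 and 0.0 < p_b < 1.0):
        raise ValueError("implied odds undefined for probabilities 0 or 1")
    return (p_a / (1.0 - p_a)) / (p_b / (1.0 - p_b))


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[ICSRecord], CohortGroundTruth]:
    """Draw a random cohort; a pure function of ``config`` (incl. seed).

    With ``distinguish_collisions`` (default), base cases that coincide by
    chance on sex, age, drug and reaction set receive an extra companion PT
    from a fixed background vocabulary, the way real spontaneous reports are
    never carbon copies; injected duplicates then remain the only records
    the field-similarity duplicate rule can link.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ICSRecord] = []
    indicators: dict[str, dict[str, np.ndarray]] = {}
    dup_pairs: list[tuple[int, int]] = []
    age_groups = list(config.age_mix)
    age_probs = np.array([config.age_mix[g] for g in age_groups])

    for drug, size in config.drugs:
        profile = config.pt_profiles[drug]
        pts = list(profile)
        probs = np.array([profile[pt] for pt in pts])
        draws = rng.random((size, len(pts))) < probs
        # redraw empty rows: every case reports at least one reaction
        empty = np.flatnonzero(~draws.any(axis=1))
        while empty.size:
            draws[empty] = rng.random((empty.size, len(pts))) < probs
            empty = empty[~draws[empty].any(axis=1)]
        sex_u = rng.random(size)
        unknown_sex = rng.random(size) < config.unknown_sex_rate
        ages = rng.choice(len(age_groups), size=size, p=age_probs)
        serious = rng.random(size) < config.serious_rate
        fatal = rng.random(size) < config.death_rate
        serious |= fatal
        hcp = rng.random(size) < config.hcp_rate
        eea = rng.random(size) < config.eea_rate
        days = rng.integers(0, _WINDOW_DAYS, size=size)
        dup_flags = rng.random(size) < config.duplicate_rate

        indicators[drug] = {pt: draws[:, j].copy() for j, pt in enumerate(pts)}
        base: list[ICSRecord] = []
        for i in range(size):
            criteria: set[SeriousCriterion] = set()
            if fatal[i]:
                criteria.add(SeriousCriterion.DEATH)
            elif serious[i]:
                criteria.add(SeriousCriterion.HOSPITALIZATION)
            base.append(
                ICSRecord(
                    local_report_id=f"SYN-{drug[:3].upper()}-{i:06d}",
                    receipt_date=_DATE_START + dt.timedelta(days=int(days[i])),
                    origin_region=Region.EEA if eea[i] else Region.NON_EEA,
                    seriousness=Seriousness.SERIOUS if serious[i] else Seriousness.NON_SERIOUS,
                    serious_criteria=frozenset(criteria),
                    outcome_death=bool(fatal[i]),
                    reporter_qualification=(
                        ReporterQualification.HEALTHCARE_PROFESSIONAL
                        if hcp[i]
                        else ReporterQualification.NON_HEALTHCARE_PROFESSIONAL
                    ),
                    sex=(
                        Sex.UNKNOWN
                        if unknown_sex[i]
                        else (Sex.MALE if sex_u[i] < config.sex_mix else Sex.FEMALE)
                    ),
                    age_group=age_groups[int(ages[i])],
                    suspect_drugs=frozenset({normalize_drug_name(drug)}),
                    reactions=tuple(pt for j, pt in enumerate(pts) if draws[i, j]),
                )
            )
        if config.distinguish_collisions:
            _distinguish_records(base)
        for i, rec in enumerate(base):
            records.append(rec)
            if dup_flags[i]:
                delta = dt.timedelta(days=1 if rec.receipt_date < _DATE_END else -1)
                records.append(
                    ICSRecord(**{**rec.__dict__, "receipt_date": rec.receipt_date + delta})
                )
                dup_pairs.append((len(records) - 2, len(records) - 1))
    return records, CohortGroundTruth(
        duplicate_row_pairs=tuple(dup_pairs), event_indicators=indicators
    )


def _distinguish_records(base: list[ICSRecord]) -> None:
    """Append a distinct background PT to chance-colliding base cases."""
    groups: dict[tuple, list[int]] = defaultdict(list)
    for i, rec in enumerate(base):
        key = (
            rec.sex,
            rec.age_group,
            rec.suspect_drugs,
            frozenset(pt.casefold() for pt in rec.reactions),
        )
        groups[key].append(i)
    cyc = itertools.cycle(_COMPANION_POOL)
    for members in groups.values():
        if len(members) < 2:
            continue
        for i, extra in zip(members[1:], _companion_subsets(len(members) - 1, cyc)):
            base[i] = base[i].with_reactions(base[i].reactions + extra)


# --------------------------------------------------------------------------
# Deterministic reference study
# --------------------------------------------------------------------------


class PresetConstructionError(RuntimeError):
    """The combinatorial preset could not satisfy its target margins."""


# SOC labels
SOC_PSY = "Psychiatric disorders"
SOC_NRV = "Nervous system disorders"
SOC_VAS = "Vascular disorders"
SOC_INV = "Investigations"
SOC_RSP = "Respiratory, thoracic and mediastinal disorders"
SOC_GEN = "General disorders and administration site conditions"
SOC_CAR = "Cardiac disorders"
SOC_IMM = "Immune system disorders"
SOC_GI = "Gastrointestinal disorders"
SOC_EYE = "Eye disorders"
SOC_HEP = "Hepatobiliary disorders"
SOC_INF = "Infections and infestations"

#: the nine SOCs of the comparative panel
PANEL_SOCS = (
    SOC_PSY,
    SOC_NRV,
    SOC_VAS,
    SOC_INV,
    SOC_RSP,
    SOC_GEN,
    SOC_CAR,
    SOC_IMM,
    SOC_GI,
)

PT_DISSOCIATION = "Dissociation/dissociative disorder"
PT_SUICIDAL_IDEATION = "Suicidal ideation"
PT_SUICIDE_ATTEMPT = "Suicide attempt"
PT_COMPLETED_SUICIDE = "Completed suicide"
PT_INCREASED_BP = "Increased blood pressure"
PT_DRUG_INEFFECTIVE = "Drug ineffective"

#: the three suicidality PTs of the PT-level comparative panel
SUICIDALITY_PTS = (PT_SUICIDAL_IDEATION, PT_SUICIDE_ATTEMPT, PT_COMPLETED_SUICIDE)

# Increased blood pressure and Drug ineffective are deliberately absent from
# the PT->SOC slice: their reference case counts (43, 17) exceed every
# compatible SOC's case-level total in the comparative panel, so they
# aggregate under the unmapped bucket (see docs/methods.md).
_PT_TO_SOC = {
    PT_DISSOCIATION: SOC_PSY,
    PT_SUICIDAL_IDEATION: SOC_PSY,
    "Anxiety": SOC_PSY,
    PT_COMPLETED_SUICIDE: SOC_PSY,
    PT_SUICIDE_ATTEMPT: SOC_PSY,
    "Hallucination": SOC_PSY,
    "Aggression": SOC_PSY,
    "Depression": SOC_PSY,
    "Insomnia": SOC_PSY,
    "Agitation": SOC_PSY,
    "Confusional state": SOC_PSY,
    "Dizziness": SOC_NRV,
    "Loss of consciousness": SOC_NRV,
    "Generalized tonic-clonic seizure": SOC_NRV,
    "Headache": SOC_NRV,
    "Somnolence": SOC_NRV,
    "Tremor": SOC_NRV,
    "Paraesthesia": SOC_NRV,
    "Hypertension": SOC_VAS,
    "Hypotension": SOC_VAS,
    "Orthostatic hypotension": SOC_VAS,
    "Circulatory collapse": SOC_VAS,
    "Flushing": SOC_VAS,
    "Peripheral coldness": SOC_VAS,
    "Pulmonary embolism": SOC_VAS,
    "Weight increased": SOC_INV,
    "Heart rate increased": SOC_INV,
    "Hepatic enzyme increased": SOC_INV,
    "Electrocardiogram QT prolonged": SOC_INV,
    "Blood cortisol increased": SOC_INV,
    "Dyspnoea": SOC_RSP,
    "Respiratory depression": SOC_RSP,
    "Apnoea": SOC_RSP,
    "Hypoventilation": SOC_RSP,
    "Respiratory failure": SOC_RSP,
    "Fatigue": SOC_GEN,
    "Malaise": SOC_GEN,
    "Asthenia": SOC_GEN,
    "Gait disturbance": SOC_GEN,
    "Sudden death": SOC_GEN,
    "Multiple organ dysfunction syndrome": SOC_GEN,
    "Bradycardia": SOC_CAR,
    "Myocardial infarction": SOC_CAR,
    "Cardiac arrest": SOC_CAR,
    "Atrial fibrillation": SOC_CAR,
    "Tachycardia": SOC_CAR,
    "Palpitations": SOC_CAR,
    "Anaphylactic reaction": SOC_IMM,
    "Hypersensitivity": SOC_IMM,
    "Drug hypersensitivity": SOC_IMM,
    "Nausea": SOC_GI,
    "Vomiting": SOC_GI,
    "Diarrhoea": SOC_GI,
    "Dry mouth": SOC_GI,
    "Diplopia": SOC_EYE,
    "Hepatic failure": SOC_HEP,
    "Pneumonia": SOC_INF,
}

# editable synonym slice: two dissociation-related PTs merge onto one term
_SYNONYM_MERGE = {
    "Dissociation": PT_DISSOCIATION,
    "Dissociative disorder": PT_DISSOCIATION,
}

# low-frequency companion PTs, deliberately outside the SOC slice: they
# distinguish otherwise-identical reports (spontaneous reports are never
# carbon copies) without moving any SOC or descriptive-table margin
_COMPANION_POOL = (
    "Irritability",
    "Nightmare",
    "Restlessness",
    "Vertigo",
    "Tinnitus",
    "Hyperhidrosis",
    "Rash",
    "Pruritus",
    "Urticaria",
    "Alopecia",
    "Arthralgia",
    "Myalgia",
    "Back pain",
    "Muscle spasms",
    "Constipation",
    "Dyspepsia",
    "Abdominal pain",
    "Decreased appetite",
    "Weight decreased",
    "Dysgeusia",
    "Hypoaesthesia",
    "Sedation",
    "Memory impairment",
    "Disturbance in attention",
    "Dysarthria",
    "Migraine",
    "Epistaxis",
    "Cough",
    "Oropharyngeal pain",
    "Nasal congestion",
    "Vision blurred",
    "Eye pain",
    "Mydriasis",
    "Dry eye",
    "Polyuria",
    "Urinary retention",
    "Dysuria",
    "Chest discomfort",
    "Chills",
    "Pyrexia",
    "Oedema peripheral",
    "Pain",
    "Influenza like illness",
    "Fall",
    "Contusion",
    "Abdominal discomfort",
    "Flatulence",
    "Gastrooesophageal reflux disease",
    "Toothache",
    "Neck pain",
    "Pain in extremity",
    "Musculoskeletal stiffness",
    "Bone pain",
    "Joint swelling",
    "Dry skin",
    "Erythema",
    "Eczema",
    "Photosensitivity reaction",
    "Night sweats",
    "Cold sweat",
    "Feeling hot",
    "Feeling cold",
    "Thirst",
    "Ear pain",
    "Hypoacusis",
    "Eye irritation",
    "Lacrimation increased",
    "Photophobia",
    "Nasopharyngitis",
    "Sinusitis",
    "Rhinorrhoea",
    "Sneezing",
    "Dysphonia",
    "Yawning",
)


def _companion_subsets(n: int, cyc: "itertools.cycle") -> list[tuple[str, ...]]:
    """``n`` pairwise-distinct companion-PT subsets.

    Singles come off the shared rotating cycle (spreading per-term usage
    thin); larger demands fall back to distinct pairs, then triples.  Since
    the pool is disjoint from every substantive PT, augmenting identical
    reports with distinct subsets always yields distinct reaction sets.
    """
    subsets: list[tuple[str, ...]] = []
    used: set[str] = set()
    while len(subsets) < min(n, len(_COMPANION_POOL)):
        companion = next(cyc)
        if companion not in used:
            used.add(companion)
            subsets.append((companion,))
    for size in (2, 3):
        if len(subsets) >= n:
            break
        for combo in itertools.combinations(_COMPANION_POOL, size):
            if len(subsets) >= n:
                break
            subsets.append(combo)
    if len(subsets) < n:
        raise PresetConstructionError(f"companion pool exhausted for a group of {n + 1}")
    return subsets


def reference_meddra_map() -> MedDRAMap:
    """PT->SOC and synonym-merge slice used by the reference study."""
    return MedDRAMap(pt_to_soc=dict(_PT_TO_SOC), synonym_merge=dict(_SYNONYM_MERGE))


def reference_criteria(drug: str) -> CohortCriteria:
    """Serious + HCP + EEA/UK + 2019-2024 window, for one suspect drug."""
    return CohortCriteria(
        require_serious=True,
        require_hcp_reporter=True,
        allowed_regions=frozenset({Region.EEA, Region.UK}),
        date_window=(_DATE_START, _DATE_END),
        drug_of_interest=drug,
    )


# (sex, age) cells used by the constructive assignment
_MA = (Sex.MALE, AgeGroup.Y18_64)
_ME = (Sex.MALE, AgeGroup.Y65_85)
_MU = (Sex.MALE, AgeGroup.UNKNOWN)
_FA = (Sex.FEMALE, AgeGroup.Y18_64)
_FE = (Sex.FEMALE, AgeGroup.Y65_85)
_FU = (Sex.FEMALE, AgeGroup.UNKNOWN)

Cell = tuple[Sex, AgeGroup]


def _nw_cells(total: int, male: int, adult: int, elderly: int, unknown: int = 0) -> dict[Cell, int]:
    """Northwest-corner split of a PT's (sex x age) cell counts.

    Male cases fill the adult stratum first, then elderly, then unknown;
    female cells absorb the column remainders.
    """
    female = total - male
    if female < 0 or adult + elderly + unknown != total:
        raise PresetConstructionError(
            f"inconsistent margins: total={total} male={male} "
            f"adult={adult} elderly={elderly} unknown={unknown}"
        )
    m_a = min(male, adult)
    m_e = min(male - m_a, elderly)
    m_u = male - m_a - m_e
    if m_u > unknown:
        raise PresetConstructionError("male margin exceeds age margins")
    return {
        _MA: m_a,
        _ME: m_e,
        _MU: m_u,
        _FA: adult - m_a,
        _FE: elderly - m_e,
        _FU: unknown - m_u,
    }


def _pack_cell(slots: dict[str, int], n_records: int) -> list[list[str]]:
    """Pack PT slot counts into ``n_records`` PT lists, no repeats per list."""
    recs: list[list[str]] = [[] for _ in range(n_records)]
    have: list[set[str]] = [set() for _ in range(n_records)]
    for pt, count in sorted(slots.items(), key=lambda kv: (-kv[1], kv[0])):
        if count > n_records:
            raise PresetConstructionError(
                f"PT {pt!r} needs {count} records but cell has only {n_records}"
            )
        order = sorted(range(n_records), key=lambda i: (len(recs[i]), i))
        chosen = [i for i in order if pt not in have[i]][:count]
        if len(chosen) < count:
            raise PresetConstructionError(f"cannot place PT {pt!r} without repeats")
        for i in chosen:
            recs[i].append(pt)
            have[i].add(pt)
    if any(not r for r in recs):
        raise PresetConstructionError("packing left an empty record")
    return recs


@dataclass
class _Stub:
    cell: Cell
    reactions: list[str]
    death: bool = False
    serious: bool = True


def _group_stubs(
    pt_cells: dict[str, dict[Cell, int]], records_per_cell: dict[Cell, int]
) -> list[_Stub]:
    """Build record stubs for one SOC group from per-cell record budgets."""
    stubs: list[_Stub] = []
    for cell, n in records_per_cell.items():
        if n == 0:
            continue
        slots = {pt: c[cell] for pt, c in pt_cells.items() if c.get(cell, 0) > 0}
        if sum(slots.values()) < n:
            raise PresetConstructionError(f"cell {cell} has fewer slots than records")
        for pts in _pack_cell(slots, n):
            stubs.append(_Stub(cell=cell, reactions=pts))
    return stubs


# reference esketamine margins: PT -> (total, male, adult, elderly, unknown-age)
_ESK_PT_MARGINS: dict[str, tuple[int, int, int, int, int]] = {
    PT_INCREASED_BP: (43, 23, 26, 17, 0),
    PT_DISSOCIATION: (42, 14, 37, 5, 0),
    PT_SUICIDAL_IDEATION: (26, 9, 23, 3, 0),
    "Anxiety": (23, 5, 20, 3, 0),
    "Dizziness": (18, 2, 12, 6, 0),
    PT_COMPLETED_SUICIDE: (17, 12, 16, 1, 0),
    PT_DRUG_INEFFECTIVE: (17, 5, 11, 6, 0),
    PT_SUICIDE_ATTEMPT: (14, 3, 12, 2, 0),
    "Loss of consciousness": (13, 6, 10, 3, 0),
    "Hallucination": (12, 4, 11, 0, 1),
    "Generalized tonic-clonic seizure": (8, 4, 5, 2, 1),
    "Diplopia": (7, 2, 6, 1, 0),
    "Aggression": (5, 0, 4, 1, 0),
    "Bradycardia": (5, 4, 4, 1, 0),
}

#: esketamine case-level SOC targets of the comparative panel
_ESK_SOC_TARGETS = {
    SOC_PSY: 117,
    SOC_NRV: 26,
    SOC_VAS: 23,
    SOC_INV: 18,
    SOC_RSP: 14,
    SOC_GEN: 14,
    SOC_CAR: 9,
    SOC_IMM: 9,
    SOC_GI: 7,
}

# comparator margins: SOC case counts and suicidality PT counts
_FLX_SOC = {
    SOC_PSY: 318,
    SOC_NRV: 371,
    SOC_VAS: 66,
    SOC_INV: 119,
    SOC_RSP: 76,
    SOC_GEN: 240,
    SOC_CAR: 96,
    SOC_IMM: 15,
    SOC_GI: 147,
}
_FLX_SUICIDALITY = {PT_SUICIDAL_IDEATION: 38, PT_SUICIDE_ATTEMPT: 70, PT_COMPLETED_SUICIDE: 9}
_VEN_SOC = {
    SOC_PSY: 573,
    SOC_NRV: 793,
    SOC_VAS: 156,
    SOC_INV: 246,
    SOC_RSP: 197,
    SOC_GEN: 492,
    SOC_CAR: 258,
    SOC_IMM: 11,
    SOC_GI: 261,
}
_VEN_SUICIDALITY = {PT_SUICIDAL_IDEATION: 41, PT_SUICIDE_ATTEMPT: 102, PT_COMPLETED_SUICIDE: 13}


def _esketamine_serious_stubs() -> list[_Stub]:
    cells = {pt: _nw_cells(*m) for pt, m in _ESK_PT_MARGINS.items()}

    # psychiatric group: 117 cases holding 139 PT slots (22 two-PT records)
    psy_pts = {
        pt: cells[pt]
        for pt in (
            PT_DISSOCIATION,
            PT_SUICIDAL_IDEATION,
            "Anxiety",
            PT_COMPLETED_SUICIDE,
            PT_SUICIDE_ATTEMPT,
            "Hallucination",
            "Aggression",
        )
    }
    psy = _group_stubs(psy_pts, {_MA: 30, _FA: 71, _FE: 15, _FU: 1})

    # nervous group: 26 cases holding 39 PT slots
    nrv_pts = {
        pt: cells[pt]
        for pt in ("Dizziness", "Loss of consciousness", "Generalized tonic-clonic seizure")
    }
    nrv = _group_stubs(nrv_pts, {_MA: 6, _FA: 10, _FE: 9, _FU: 1})

    # bradycardia keeps its reference cells; remaining cardiac cases come
    # from fatal diagnoses and fillers
    brady = _group_stubs({"Bradycardia": cells["Bradycardia"]}, {_MA: 4, _FE: 1})

    # ten non-suicide deaths (8 adults, 1 elderly, 1 age unknown; 6 M / 4 F)
    deaths = [
        _Stub(_MA, ["Sudden death"], death=True),
        _Stub(_MA, ["Sudden death"], death=True),
        _Stub(_FA, ["Sudden death"], death=True),
        _Stub(_MA, ["Respiratory failure"], death=True),
        _Stub(_FA, ["Pulmonary embolism"], death=True),
        _Stub(_ME, ["Myocardial infarction"], death=True),
        _Stub(_MA, ["Cardiac arrest"], death=True),
        _Stub(_MA, ["Multiple organ dysfunction syndrome"], death=True),
        _Stub(_FA, ["Hepatic failure"], death=True),
        _Stub(_FU, ["Pneumonia"], death=True),
    ]

    # single-PT fillers completing the SOC panel targets; every count stays
    # below the descriptive-table row thresholds
    fillers: list[tuple[str, int]] = [
        ("Hypertension", 4),
        ("Hypotension", 4),
        ("Orthostatic hypotension", 4),
        ("Circulatory collapse", 4),
        ("Flushing", 3),
        ("Peripheral coldness", 3),  # vascular: 22 (+1 fatal embolism)
        ("Weight increased", 4),
        ("Heart rate increased", 4),
        ("Hepatic enzyme increased", 4),
        ("Electrocardiogram QT prolonged", 4),
        ("Blood cortisol increased", 2),  # investigations: 18
        ("Dyspnoea", 4),
        ("Respiratory depression", 4),
        ("Apnoea", 3),
        ("Hypoventilation", 2),  # respiratory: 13 (+1 fatal)
        ("Fatigue", 4),
        ("Malaise", 4),
        ("Gait disturbance", 2),  # general: 10 (+4 fatal)
        ("Atrial fibrillation", 2),  # cardiac: with bradycardia + 2 fatal -> 9
        ("Anaphylactic reaction", 4),
        ("Hypersensitivity", 4),
        ("Drug hypersensitivity", 1),  # immune: 9
        ("Nausea", 4),
        ("Vomiting", 3),  # gastrointestinal: 7
    ]
    filler_cells = [_MA] * 20 + [_ME] * 10 + [_FA] * 35 + [_FE] * 14 + [_FU] * 2
    filler_stubs: list[_Stub] = []
    it = iter(filler_cells)
    for pt, count in fillers:
        for _ in range(count):
            filler_stubs.append(_Stub(next(it), [pt]))
    leftover = sum(1 for _ in it)
    if leftover:
        raise PresetConstructionError(f"{leftover} filler cells unused")

    stubs = psy + nrv + brady + deaths + filler_stubs

    # overlay the SOC-unmapped and eye-disorder PTs onto existing records,
    # then emit the remainder as standalone reports
    def overlay(pt: str, cell: Cell, count: int) -> int:
        placed = 0
        for stub in stubs:
            if placed == count:
                break
            if stub.cell == cell and pt not in stub.reactions:
                stub.reactions.append(pt)
                placed += 1
        return placed

    overlay_plan = [
        # (PT, cell, overlay count, standalone remainder)
        (PT_INCREASED_BP, _FE, 17, 0),
        (PT_INCREASED_BP, _MA, 8, 15),
        (PT_INCREASED_BP, _FA, 3, 0),
        (PT_DRUG_INEFFECTIVE, _FE, 6, 0),
        (PT_DRUG_INEFFECTIVE, _MA, 0, 5),
        (PT_DRUG_INEFFECTIVE, _FA, 0, 6),
        ("Diplopia", _MA, 2, 0),
        ("Diplopia", _FA, 4, 0),
        ("Diplopia", _FE, 1, 0),
    ]
    standalone: list[_Stub] = []
    for pt, cell, n_overlay, n_standalone in overlay_plan:
        placed = overlay(pt, cell, n_overlay)
        if placed != n_overlay:
            raise PresetConstructionError(
                f"only {placed}/{n_overlay} overlay hosts for {pt!r} in cell {cell}"
            )
        standalone.extend(_Stub(cell, [pt]) for _ in range(n_standalone))
    stubs.extend(standalone)

    for stub in stubs:
        if PT_COMPLETED_SUICIDE in stub.reactions:
            stub.death = True

    # the line listing carries the raw dissociation PT variants; the synonym
    # table re-merges them downstream
    variants = itertools.cycle(["Dissociation", "Dissociative disorder"])
    for stub in stubs:
        stub.reactions = [
            next(variants) if pt == PT_DISSOCIATION else pt for pt in stub.reactions
        ]

    if len(stubs) != 265:
        raise PresetConstructionError(f"esketamine serious cohort has {len(stubs)} != 265 records")
    return stubs


def _esketamine_nonserious_stubs() -> list[_Stub]:
    """486 non-serious reports: 306 female, 168 male, 12 unknown sex."""
    variants = itertools.cycle(
        [
            ["Headache"],
            ["Nausea"],
            ["Dizziness"],
            ["Fatigue"],
            ["Insomnia"],
            ["Somnolence"],
            ["Anxiety"],
            ["Tremor"],
            ["Vomiting"],
            ["Malaise"],
            ["Paraesthesia"],
            ["Dry mouth"],
        ]
    )
    ages = itertools.cycle([AgeGroup.Y18_64, AgeGroup.Y18_64, AgeGroup.Y65_85])
    stubs = []
    for sex, n in ((Sex.FEMALE, 306), (Sex.MALE, 168), (Sex.UNKNOWN, 12)):
        for _ in range(n):
            stubs.append(_Stub((sex, next(ages)), list(next(variants)), serious=False))
    return stubs


#: marker PTs cycled per SOC for the comparator cohorts
_MARKERS: dict[str, tuple[str, ...]] = {
    SOC_PSY: ("Depression", "Insomnia", "Agitation", "Confusional state"),
    SOC_NRV: ("Headache", "Somnolence", "Tremor", "Paraesthesia"),
    SOC_VAS: ("Hypertension", "Hypotension", "Flushing", "Circulatory collapse"),
    SOC_INV: ("Weight increased", "Heart rate increased", "Electrocardiogram QT prolonged"),
    SOC_RSP: ("Dyspnoea", "Apnoea", "Respiratory depression"),
    SOC_GEN: ("Fatigue", "Malaise", "Asthenia"),
    SOC_CAR: ("Palpitations", "Atrial fibrillation", "Tachycardia"),
    SOC_IMM: ("Hypersensitivity", "Drug hypersensitivity", "Anaphylactic reaction"),
    SOC_GI: ("Nausea", "Vomiting", "Diarrhoea", "Dry mouth"),
}

_FLX_PLAN = [
    (SOC_PSY, SOC_NRV, 318),
    (SOC_NRV, SOC_GEN, 53),
    (SOC_GEN, SOC_INV, 11),
    (SOC_GEN, None, 176),
    (SOC_INV, None, 108),
    (SOC_VAS, None, 66),
    (SOC_RSP, None, 76),
    (SOC_CAR, None, 96),
    (SOC_IMM, None, 15),
    (SOC_GI, None, 147),
]
_VEN_PLAN = [
    (SOC_PSY, SOC_NRV, 573),
    (SOC_NRV, SOC_GEN, 220),
    (SOC_GEN, SOC_GI, 175),
    (SOC_GEN, None, 97),
    (SOC_GI, None, 86),
    (SOC_VAS, None, 156),
    (SOC_INV, None, 246),
    (SOC_RSP, None, 197),
    (SOC_CAR, None, 258),
    (SOC_IMM, None, 11),
]


def _comparator_stubs(
    soc_targets: dict[str, int],
    suicidality: dict[str, int],
    total: int,
    pair_plan: list[tuple[str, str | None, int]],
) -> list[_Stub]:
    """Comparator cohort: each record carries one or two SOC marker PTs.

    ``pair_plan`` lists (SOC, second SOC or None, record count); the three
    suicidality PTs are overlaid on the psychiatric records.  Demographics
    are free dimensions, cycled deterministically.
    """
    stubs: list[_Stub] = []
    for soc_a, soc_b, count in pair_plan:
        ma, mb = _MARKERS[soc_a], (_MARKERS[soc_b] if soc_b else ())
        for i in range(count):
            pts = [ma[i % len(ma)]]
            if soc_b is not None:
                pts.append(mb[(i // len(ma)) % len(mb)])
            stubs.append(_Stub(_MA, pts))
    if len(stubs) != total:
        raise PresetConstructionError(f"comparator plan yields {len(stubs)} != {total} records")
    realized: dict[str, int] = {s: 0 for s in soc_targets}
    for stub in stubs:
        for soc in {_PT_TO_SOC[pt] for pt in stub.reactions}:
            realized[soc] += 1
    if realized != soc_targets:
        raise PresetConstructionError(f"comparator SOC counts {realized} != {soc_targets}")
    psy_stubs = [s for s in stubs if any(_PT_TO_SOC[pt] == SOC_PSY for pt in s.reactions)]
    offset = 0
    for pt, count in suicidality.items():
        if offset + count > len(psy_stubs):
            raise PresetConstructionError(f"not enough psychiatric records to host {pt!r}")
        for stub in psy_stubs[offset : offset + count]:
            stub.reactions.append(pt)
            if pt == PT_COMPLETED_SUICIDE:
                stub.death = True
        offset += count
    sexes = itertools.cycle([Sex.FEMALE, Sex.MALE, Sex.FEMALE])
    age_cycle = itertools.cycle([AgeGroup.Y18_64] * 4 + [AgeGroup.Y65_85])
    for stub in stubs:
        stub.cell = (next(sexes), next(age_cycle))
    return stubs


def _diversify(stubs: list[_Stub]) -> None:
    """Append a distinct companion PT to otherwise-identical reports.

    Reports sharing (sex, age, reaction set) within a drug would otherwise
    be indistinguishable from true duplicates; companion PTs are outside the
    SOC slice, so no aggregate margin moves.
    """
    groups: dict[tuple[Cell, frozenset[str]], list[_Stub]] = defaultdict(list)
    for stub in stubs:
        groups[(stub.cell, frozenset(stub.reactions))].append(stub)
    cyc = itertools.cycle(_COMPANION_POOL)
    for members in groups.values():
        if len(members) < 2:
            continue
        for stub, extra in zip(members[1:], _companion_subsets(len(members) - 1, cyc)):
            stub.reactions.extend(extra)


def _materialize(stubs: list[_Stub], drug: str, prefix: str) -> list[ICSRecord]:
    records = []
    for i, stub in enumerate(stubs):
        sex, age = stub.cell
        criteria: set[SeriousCriterion] = set()
        if stub.death:
            criteria.add(SeriousCriterion.DEATH)
        elif stub.serious:
            criteria.add(SeriousCriterion.HOSPITALIZATION)
        records.append(
            ICSRecord(
                local_report_id=f"{prefix}-{i + 1:05d}",
                receipt_date=_DATE_START + dt.timedelta(days=(i * 37) % _WINDOW_DAYS),
                origin_region=Region.UK if i % 20 == 0 else Region.EEA,
                seriousness=Seriousness.SERIOUS if stub.serious else Seriousness.NON_SERIOUS,
                serious_criteria=frozenset(criteria),
                outcome_death=stub.death,
                reporter_qualification=ReporterQualification.HEALTHCARE_PROFESSIONAL,
                sex=sex,
                age_group=age,
                suspect_drugs=frozenset({drug}),
                reactions=tuple(stub.reactions),
            )
        )
    return records


@dataclass(frozen=True)
class ReferenceStudy:
    """Fixed reference cohorts plus the mapping and criteria to analyse them.

    ``raw_records`` holds the unfiltered line listings per drug (the
    esketamine listing includes its 486 non-serious reports); pushing each
    through criteria -> dedup -> synonym normalization reproduces the
    reference margins.
    """

    raw_records: dict[str, list[ICSRecord]]
    meddra: MedDRAMap

    def criteria(self, drug: str) -> CohortCriteria:
        return reference_criteria(drug)

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(self.raw_records)


def reference_study() -> ReferenceStudy:
    """Construct and verify the deterministic three-drug reference study."""
    esk_serious = _esketamine_serious_stubs()
    esk_nonserious = _esketamine_nonserious_stubs()
    flx_stubs = _comparator_stubs(_FLX_SOC, _FLX_SUICIDALITY, 1066, _FLX_PLAN)
    ven_stubs = _comparator_stubs(_VEN_SOC, _VEN_SUICIDALITY, 2019, _VEN_PLAN)
    # deduplication runs on the filtered (serious) cohort, so each
    # seriousness class only needs to be collision-free within itself
    for stubs in (esk_serious, esk_nonserious, flx_stubs, ven_stubs):
        _diversify(stubs)
    esk_stubs = esk_serious + esk_nonserious
    study = ReferenceStudy(
        raw_records={
            "esketamine": _materialize(esk_stubs, "esketamine", "EV-ESK"),
            "fluoxetine": _materialize(flx_stubs, "fluoxetine", "EV-FLX"),
            "venlafaxine": _materialize(ven_stubs, "venlafaxine", "EV-VEN"),
        },
        meddra=reference_meddra_map(),
    )
    _verify_reference(study)
    return study


def _verify_reference(study: ReferenceStudy) -> None:
    """Assert every reference margin; raise naming the first conflict."""
    from . import processing  # local import to avoid a cycle at module load

    meddra = study.meddra
    cohorts: dict[str, list[ICSRecord]] = {}
    for drug, raw in study.raw_records.items():
        filtered = processing.apply_cohort_criteria(raw, reference_criteria(drug))
        groups = processing.find_duplicates(filtered)
        if groups:
            raise PresetConstructionError(
                f"{drug}: {len(groups)} unintended duplicate group(s) in the preset"
            )
        cohorts[drug] = processing.normalize_reactions(filtered, meddra)

    def check(label: str, got, want) -> None:
        if got != want:
            raise PresetConstructionError(f"{label}: got {got}, expected {want}")

    esk = cohorts["esketamine"]
    check("esketamine raw size", len(study.raw_records["esketamine"]), 751)
    check("esketamine serious size", len(esk), 265)
    check("fluoxetine size", len(cohorts["fluoxetine"]), 1066)
    check("venlafaxine size", len(cohorts["venlafaxine"]), 2019)

    check("male margin", sum(r.sex is Sex.MALE for r in esk), 96)
    check("female margin", sum(r.sex is Sex.FEMALE for r in esk), 169)
    check("adult margin", sum(r.age_group is AgeGroup.Y18_64 for r in esk), 210)
    check("elderly margin", sum(r.age_group is AgeGroup.Y65_85 for r in esk), 50)

    for pt, (total, male, adult, elderly, _unknown) in _ESK_PT_MARGINS.items():
        with_pt = [r for r in esk if r.has_reaction(pt)]
        check(f"{pt}: count", len(with_pt), total)
        check(f"{pt}: male", sum(r.sex is Sex.MALE for r in with_pt), male)
        check(f"{pt}: adult", sum(r.age_group is AgeGroup.Y18_64 for r in with_pt), adult)
        check(f"{pt}: elderly", sum(r.age_group is AgeGroup.Y65_85 for r in with_pt), elderly)

    # no unlisted PT may cross a descriptive-table row threshold
    counts: dict[str, int] = {}
    for rec in esk:
        for pt in rec.reactions:
            counts[pt] = counts.get(pt, 0) + 1
    for pt, count in counts.items():
        if pt not in _ESK_PT_MARGINS and count > 4:
            raise PresetConstructionError(f"filler PT {pt!r} reached count {count}")

    soc_counts = processing.aggregate_to_soc(esk, meddra)
    for soc, want in _ESK_SOC_TARGETS.items():
        check(f"esketamine SOC {soc}", soc_counts.get(soc, 0), want)
    for drug, targets in (("fluoxetine", _FLX_SOC), ("venlafaxine", _VEN_SOC)):
        got = processing.aggregate_to_soc(cohorts[drug], meddra)
        for soc, want in targets.items():
            check(f"{drug} SOC {soc}", got.get(soc, 0), want)
    for drug, targets in (("fluoxetine", _FLX_SUICIDALITY), ("venlafaxine", _VEN_SUICIDALITY)):
        for pt, want in targets.items():
            check(f"{drug} {pt}", sum(r.has_reaction(pt) for r in cohorts[drug]), want)

    deaths = [r for r in esk if r.outcome_death]
    check("esketamine deaths", len(deaths), 27)
    check("male deaths", sum(r.sex is Sex.MALE for r in deaths), 18)
    suicides = [r for r in deaths if r.has_reaction(PT_COMPLETED_SUICIDE)]
    check("suicide deaths", len(suicides), 17)
    check("male suicide deaths", sum(r.sex is Sex.MALE for r in suicides), 12)
    other = [r for r in deaths if not r.has_reaction(PT_COMPLETED_SUICIDE)]
    check("non-suicide deaths", len(other), 10)
    check("non-suicide adult deaths", sum(r.age_group is AgeGroup.Y18_64 for r in other), 8)
    check("non-suicide elderly deaths", sum(r.age_group is AgeGroup.Y65_85 for r in other), 1)
    check("non-suicide male deaths", sum(r.sex is Sex.MALE for r in other), 6)
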