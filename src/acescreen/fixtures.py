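"""Synthetic inputs: compact ontology, scenario scripts, directories, logs.

Everything the screening assistant consumes can be generated here with no
external download: a compact ACEs/SDoH ontology (concepts, hierarchy,
causal axioms with provenance, entity lexicon, the ten-category ACE
question pool, score strata), four scripted intake scenarios with their
expected detections, a geocoded community-resource directory and zip
centroid table, a neighborhood-metrics table, the evidence table standing
in for literature lookup, and seeded simulated session logs for the
analytics layer. All generation is deterministic given a seed; resource
coordinates and names are plausible synthetic points, not real facilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dialog import Intent, IntentRegistry, SlotSpec
from .ontology import Ontology, ontology_from_dict
from .surveillance import EVIDENCE_COLUMNS


# ---------------------------------------------------------------------- #
# ontology

def _c(cid: str, label: str, cat: str) -> dict:
    return {"id": cid, "label": label, "category": cat}


def _ax(s: str, rel: str, o: str, prov: str) -> dict:
    return {"subject": s, "relation": rel, "object": o, "provenance": prov}


def aceso_lite_dict() -> dict:
    """The compact screening ontology as a plain JSON-able dict."""
    concepts = [
        _c("ace", "adverse childhood experience", "ACE"),
        _c("sdoh", "social determinant of health", "SDoH"),
        _c("symptom", "symptom", "symptom"),
        _c("outcome", "health outcome", "outcome"),
        # SDoH branch
        _c("housing_circumstance", "housing circumstance", "SDoH"),
        _c("mold", "mold", "SDoH"),
        _c("lead_based_paint", "lead-based paint", "SDoH"),
        _c("inadequate_heating", "inadequate heating", "SDoH"),
        _c("food_issue", "food issue", "SDoH"),
        _c("food_insecurity", "food insecurity", "SDoH"),
        _c("transportation_issue", "transportation issue", "SDoH"),
        _c("education_issue", "education issue", "SDoH"),
        _c("legal_issue", "legal issue", "SDoH"),
        _c("employment_issue", "employment issue", "SDoH"),
        _c("neighborhood", "neighborhood", "SDoH"),
        _c("physical_characteristic", "neighborhood physical characteristic", "SDoH"),
        _c("blight", "blight prevalence", "SDoH"),
        _c("walkability", "walkability score", "SDoH"),
        _c("crime", "crime index", "SDoH"),
        _c("poverty", "poverty rate", "SDoH"),
        # intermediates
        _c("toxicant", "toxicant", "other"),
        _c("toxicant_exposure", "exposure to toxicants", "other"),
        # ACE branch: the ten classic categories
        _c("physical_abuse", "physical abuse", "ACE"),
        _c("emotional_abuse", "emotional abuse", "ACE"),
        _c("sexual_abuse", "sexual abuse", "ACE"),
        _c("physical_neglect", "physical neglect", "ACE"),
        _c("emotional_neglect", "emotional neglect", "ACE"),
        _c("household_substance_abuse", "household substance abuse", "ACE"),
        _c("household_mental_illness", "household mental illness", "ACE"),
        _c("household_violence", "witnessing household violence", "ACE"),
        _c("incarcerated_household_member", "incarcerated household member", "ACE"),
        _c("parental_separation", "parental separation or divorce", "ACE"),
        # symptoms
        _c("night_terror", "night terror", "symptom"),
        _c("behavioral_issue", "behavioral issue", "symptom"),
        _c("developmental_delay", "developmental delay", "symptom"),
        # outcomes
        _c("asthma", "asthma", "outcome"),
        _c("diabetes", "diabetes", "outcome"),
        _c("obesity", "obesity", "outcome"),
        _c("stress", "stress", "outcome"),
        # demographics
        _c("zip_code", "zip code", "demographic"),
        _c("age", "age", "demographic"),
        _c("child_age", "child age", "demographic"),
        _c("school_age", "school age", "demographic"),
        _c("ethnicity", "ethnicity", "demographic"),
        _c("gender", "gender", "demographic"),
        _c("city", "city", "demographic"),
        _c("preferred_language", "preferred language", "demographic"),
    ]
    isa = [
        ("housing_circumstance", "sdoh"), ("food_issue", "sdoh"),
        ("transportation_issue", "sdoh"), ("education_issue", "sdoh"),
        ("legal_issue", "sdoh"), ("employment_issue", "sdoh"),
        ("neighborhood", "sdoh"),
        ("physical_characteristic", "neighborhood"),
        ("blight", "physical_characteristic"),
        ("walkability", "physical_characteristic"),
        ("crime", "physical_characteristic"),
        ("poverty", "physical_characteristic"),
        ("mold", "housing_circumstance"),
        ("lead_based_paint", "housing_circumstance"),
        ("lead_based_paint", "toxicant"),
        ("inadequate_heating", "housing_circumstance"),
        ("food_insecurity", "food_issue"),
        ("physical_abuse", "ace"), ("emotional_abuse", "ace"),
        ("sexual_abuse", "ace"), ("physical_neglect", "ace"),
        ("emotional_neglect", "ace"), ("household_substance_abuse", "ace"),
        ("household_mental_illness", "ace"), ("household_violence", "ace"),
        ("incarcerated_household_member", "ace"), ("parental_separation", "ace"),
        ("night_terror", "symptom"), ("behavioral_issue", "symptom"),
        ("developmental_delay", "symptom"),
        ("asthma", "outcome"), ("diabetes", "outcome"),
        ("obesity", "outcome"), ("stress", "outcome"),
        ("child_age", "age"), ("school_age", "age"),
    ]
    axioms = [_ax(s, "is_a", o, "onto") for s, o in isa] + [
        _ax("blight", "causes", "toxicant_exposure", "onto"),
        _ax("toxicant_exposure", "leads_to", "asthma", "onto"),
        _ax("toxicant", "risk_factor_of", "asthma", "onto"),
        _ax("stress", "risk_factor_of", "asthma", "onto"),
        _ax("obesity", "risk_factor_of", "diabetes", "onto"),
        _ax("emotional_neglect", "causes", "night_terror", "ace_lit"),
    ]
    lexicon = {
        "mold": ("housing_circumstance", "mold"),
        "lead-based paint": ("housing_circumstance", "lead_based_paint"),
        "lead based paint": ("housing_circumstance", "lead_based_paint"),
        "inadequate heating": ("housing_circumstance", "inadequate_heating"),
        "housing issues": ("housing_circumstance", "housing_circumstance"),
        "housing": ("housing_circumstance", "housing_circumstance"),
        "night terror": ("symptom", "night_terror"),
        "night terrors": ("symptom", "night_terror"),
        "developmentally delayed": ("symptom", "developmental_delay"),
        "developmental delay": ("symptom", "developmental_delay"),
        "hard to soothe": ("symptom", "behavioral_issue"),
        "calm him down": ("symptom", "behavioral_issue"),
        "calm her down": ("symptom", "behavioral_issue"),
        "bounces back quickly": ("symptom", "behavioral_issue"),
        "food insecurities": ("food_issue", "food_insecurity"),
        "food insecurity": ("food_issue", "food_insecurity"),
        "food": ("food_issue", "food_insecurity"),
        "legal issues": ("legal_issue", "legal_issue"),
        "legal": ("legal_issue", "legal_issue"),
        "education": ("education_issue", "education_issue"),
        "school": ("education_issue", "education_issue"),
        "job": ("employment_issue", "employment_issue"),
        "unemployed": ("employment_issue", "employment_issue"),
        "alcoholic": ("household_substance_abuse", "household_substance_abuse"),
        "substance abuse": ("household_substance_abuse", "household_substance_abuse"),
        "jail": ("incarcerated_household_member", "incarcerated_household_member"),
        "prison": ("incarcerated_household_member", "incarcerated_household_member"),
        "separated": ("parental_separation", "parental_separation"),
        "separation": ("parental_separation", "parental_separation"),
        "divorce": ("parental_separation", "parental_separation"),
        "divorced": ("parental_separation", "parental_separation"),
        "a lot of pressure": ("stress", "stress"),
        "stress": ("stress", "stress"),
        "stressed": ("stress", "stress"),
        "transportation": ("transportation_issue", "transportation_issue"),
        "african american": ("ethnicity", "african american"),
        "hispanic": ("ethnicity", "hispanic"),
        "latino": ("ethnicity", "hispanic"),
        "latina": ("ethnicity", "hispanic"),
        "female": ("gender", "female"),
        "male": ("gender", "male"),
        "memphis": ("city", "memphis"),
        "spanish": ("preferred_language", "spanish"),
        "english": ("preferred_language", "english"),
    }
    patterns = [
        {
            "entity_type": "child_age",
            "regex": r"\b(\d{1,2})[-\s]year[-\s]old\s+(?:child|son|daughter|boy|girl|baby\s+boy|baby\s+girl|baby)\b",
            "value_group": 1,
        },
        {"entity_type": "age", "regex": r"\b(\d{1,2})[-\s]year[-\s]old\b", "value_group": 1},
        {"entity_type": "zip_code", "regex": r"\b(\d{5})\b", "value_group": 1},
    ]
    questions = [
        ("q_physical_abuse", "physical_abuse",
         "Did a parent or other adult in the household often push, grab, slap, or throw something at the child?"),
        ("q_emotional_abuse", "emotional_abuse",
         "Did a parent or other adult in the household often swear at, insult, or humiliate the child?"),
        ("q_sexual_abuse", "sexual_abuse",
         "Did an adult or person at least 5 years older ever touch the child in a sexual way?"),
        ("q_physical_neglect", "physical_neglect",
         "Did the child often go without enough to eat or have to wear dirty clothes?"),
        ("q_emotional_neglect", "emotional_neglect",
         "Did the child often feel that no one in the family loved them or thought they were important?"),
        ("q_household_substance_abuse", "household_substance_abuse",
         "Did the child live with anyone who was a problem drinker, alcoholic, or used street drugs?"),
        ("q_household_mental_illness", "household_mental_illness",
         "Was a household member depressed or mentally ill, or did a household member attempt suicide?"),
        ("q_household_violence", "household_violence",
         "Did the child ever see or hear a household member being pushed, slapped, or otherwise hurt?"),
        ("q_incarcerated_household_member", "incarcerated_household_member",
         "Did a household member ever go to prison or jail?"),
        ("q_parental_separation", "parental_separation",
         "Were the child's parents ever separated or divorced?"),
    ]
    return {
        "schema_version": "1.0",
        "name": "aceso-lite",
        "ace_root": "ace",
        "sdoh_root": "sdoh",
        "sources": [
            {"id": "onto", "kind": "ontology",
             "citation": "Compact ACEs/SDoH screening ontology (bundled synthetic edition)."},
            {"id": "ace_lit", "kind": "literature",
             "citation": "Adversity-cohort literature linking ACE burden with negative health outcomes."},
            {"id": "nbhd", "kind": "neighborhood_repository",
             "citation": "Neighborhood-level indicator repository keyed by zip code (synthetic)."},
            {"id": "pool", "kind": "questionnaire",
             "citation": "Ten-category ACE screening questionnaire."},
        ],
        "concepts": concepts,
        "axioms": axioms,
        "lexicon": {k: list(v) for k, v in lexicon.items()},
        "patterns": patterns,
        "ace_questions": [
            {"id": qid, "text": text, "concept": concept, "mandatory": True}
            for qid, concept, text in questions
        ],
        "score_rules": [[0, "no reported ACEs"], [1, "moderate"], [4, "high risk"]],
    }


def build_aceso_lite() -> Ontology:
    """The compact screening ontology, validated and ready to query."""
    return ontology_from_dict(aceso_lite_dict(), origin="aceso-lite")


# ---------------------------------------------------------------------- #
# intent registry

def default_intent_registry() -> IntentRegistry:
    """Intent configuration for the family-resilience intake assistant."""
    assessment = Intent(
        name="FRI_Assessment",
        training_phrases=[
            "I am an African American female and I have housing issues",
            "I have several issues",
            "I need help with food and transportation",
            "My husband is an alcoholic and my son is hard to soothe",
            "I am concerned about legal issues and education",
            "My child experiences night terror and I have recently separated",
            "I have food insecurities and I am mostly concerned about food",
        ],
        required_params=[
            SlotSpec(name="zip_code", entity_type="zip_code",
                     prompt="What is your residential zip code?", order=0),
        ],
        fulfillment="recommendation",
    )
    sdoh = Intent(
        name="SDoH_Surveillance",
        parent="FRI_Assessment",
        training_phrases=[
            "There is mold and lead-based paint in the apartment",
            "We have inadequate heating and other housing issues",
            "We rely on food banks because of food insecurity",
        ],
        fulfillment="sdoh_surveillance",
    )
    aces = Intent(
        name="ACEs_Surveillance",
        parent="FRI_Assessment",
        training_phrases=[
            "A household member has been in jail",
            "My husband is an alcoholic",
            "The parents are divorced",
        ],
        fulfillment="aces_surveillance",
    )
    followup = Intent(
        name="FRI_followup_activity",
        training_phrases=["I would like to schedule an appointment"],
        events=["schedule an appointment"],
        required_params=[
            SlotSpec(name="date", entity_type="date", prompt="What date works for you?", order=0),
            SlotSpec(name="duration", entity_type="duration", prompt="How long should the appointment be?", order=1),
            SlotSpec(name="time", entity_type="time", prompt="What time of day suits you?", order=2),
            SlotSpec(name="appointment_type", entity_type="appointment_type",
                     prompt="What type of appointment do you need?", order=3),
        ],
        fulfillment="appointment",
    )
    return IntentRegistry([assessment, sdoh, aces, followup])


# ---------------------------------------------------------------------- #
# scenario scripts

@dataclass
class ScenarioScript:
    """A scripted intake conversation and its expected detections."""

    scenario_id: int
    opening: str
    turns: list[str]
    expected: dict
    notes: str = ""


def scenario_scripts() -> list[ScenarioScript]:
    """The four bundled walkthrough scenarios.

    Scenario 4 reaches an ACE score of 4 through: parental separation
    (provided), emotional neglect (inferred from night terror via axiom),
    and two scripted "yes" questionnaire answers (household mental illness,
    witnessing household violence). The last two items are synthetic
    choices fixed by this fixture so the walkthrough has a fully
    determined questionnaire.
    """
    s1_open = (
        "I am currently residing in a safe place, but I'm concerned about my "
        "household income as I am currently unemployed due to legal issues. "
        "I have some college and I am interested in furthering my education, "
        "but would prefer a job first."
    )
    s2_open = (
        "My husband is an alcoholic and he had served time in jail and right "
        "now it is hard to soothe my 4-year-old baby boy or calm him down. "
        "He also bounces back quickly when things do not go his way. This "
        "just puts a lot of pressure on me."
    )
    s3_open = (
        "I have a couple of issues. My 7-year-old son is developmentally "
        "delayed, and we have food insecurities that we hope we could "
        "resolve before the holidays. But I am mostly concerned about food."
    )
    s4_open = (
        "I am a Hispanic 21-year-old female living in Memphis. My 6-year-old "
        "child experiences night terror. I have recently separated from my "
        "husband."
    )
    no8 = ["no"] * 8
    s2_answers = list(no8)  # remaining pool questions, all negative
    # S4 remaining pool order: physical_abuse, emotional_abuse, sexual_abuse,
    # physical_neglect, household_substance_abuse, household_mental_illness,
    # household_violence, incarcerated_household_member
    s4_answers = ["no", "no", "no", "no", "no", "yes", "yes", "no"]
    return [
        ScenarioScript(
            scenario_id=1,
            opening=s1_open,
            turns=[s1_open, "38104"],
            expected={
                "symptoms": [],
                "risk_factors": {
                    "provided": ["employment_issue", "legal_issue", "education_issue"],
                    "inferred": [],
                    "neighborhood": [],
                },
                "outcomes": {"provided": [], "inferred": []},
                "interventions": [
                    "job search assistance",
                    "legal follow-up",
                    "school information",
                ],
            },
            notes="SDoH needs; the job preference cue promotes employment.",
        ),
        ScenarioScript(
            scenario_id=2,
            opening=s2_open,
            turns=[s2_open, "38105"] + s2_answers,
            expected={
                "symptoms": ["behavioral_issue"],
                "risk_factors": {
                    "provided": ["household_substance_abuse", "incarcerated_household_member"],
                    "inferred": [],
                    "neighborhood": [],
                },
                "outcomes": {"provided": ["stress"], "inferred": ["asthma"]},
                "interventions": ["schedule psychologist appointment"],
            },
            notes="ACE issues; asthma inferred from provided stress via axiom.",
        ),
        ScenarioScript(
            scenario_id=3,
            opening=s3_open,
            turns=[s3_open, "38106"],
            expected={
                "symptoms": ["developmental_delay"],
                "risk_factors": {
                    "provided": ["food_insecurity"],
                    "inferred": [],
                    "neighborhood": [],
                },
                "outcomes": {"provided": [], "inferred": []},
                "interventions": [
                    "food pantry information",
                    "schedule psychologist appointment",
                ],
            },
            notes="Mixed ACE/SDoH; the concern cue puts food first.",
        ),
        ScenarioScript(
            scenario_id=4,
            opening=s4_open,
            turns=[s4_open, "38103"] + s4_answers,
            expected={
                "symptoms": ["night_terror"],
                "risk_factors": {
                    "provided": ["parental_separation"],
                    "inferred": ["emotional_neglect"],
                    "neighborhood": ["blight"],
                },
                "outcomes": {"provided": [], "inferred": ["asthma"]},
                "interventions": ["schedule medical appointment"],
            },
            notes=(
                "Early-diagnosis walkthrough; ACE score 4 = separation "
                "(provided) + emotional neglect (inferred) + two scripted "
                "positives (synthetic choice)."
            ),
        ),
    ]


def write_scenario_scripts(out_dir: str | Path) -> list[Path]:
    """Write each scenario as a JSONL utterance script plus expectations."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    meta = {}
    for script in scenario_scripts():
        p = out_dir / f"scenario{script.scenario_id}.jsonl"
        with open(p, "w") as fh:
            for turn in script.turns:
                fh.write(json.dumps({"utterance": turn}) + "\n")
        meta[str(script.scenario_id)] = {
            "expected": script.expected,
            "notes": script.notes,
        }
        paths.append(p)
    (out_dir / "scenario_expectations.json").write_text(
        json.dumps(meta, indent=1, sort_keys=True)
    )
    return paths


# ---------------------------------------------------------------------- #
# geocoded directories and neighborhood table

ZIP_CENTROIDS = {
    "38103": (35.1490, -90.0490),
    "38104": (35.1326, -90.0040),
    "38105": (35.1495, -90.0330),
    "38106": (35.1020, -90.0332),
    "38107": (35.1670, -90.0251),
    "38002": (35.2720, -89.7290),
}

_RESOURCE_KINDS = [
    ("food_pantry", "food_insecurity", "Community Food Pantry"),
    ("school", "education_issue", "Neighborhood Learning Center"),
    ("legal_aid", "legal_issue", "Legal Aid Office"),
    ("employment_center", "employment_issue", "Workforce Development Center"),
]


def resource_directory(seed: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded synthetic resource directory plus the zip-centroid table.

    Guarantees a Spanish-speaking pediatric asthma clinic at the 38103
    centroid and one of each everyday resource kind near every core zip;
    a far-away English-only asthma clinic exercises the radius and
    language filters.
    """
    rng = np.random.default_rng(seed)
    rows = []
    lat0, lon0 = ZIP_CENTROIDS["38103"]
    rows.append(
        dict(id="r001", kind="clinic", name="Downtown Pediatric Asthma Clinic",
             zip="38103", lat=lat0, lon=lon0, languages="english;spanish",
             specialty="asthma")
    )
    rows.append(
        dict(id="r002", kind="clinic", name="Riverside Child Behavioral Health",
             zip="38103", lat=lat0 + 0.01, lon=lon0 - 0.01,
             languages="english;spanish", specialty="behavioral_issue")
    )
    far_lat, far_lon = ZIP_CENTROIDS["38002"]
    rows.append(
        dict(id="r003", kind="clinic", name="Suburban Asthma and Allergy Clinic",
             zip="38002", lat=far_lat, lon=far_lon, languages="english",
             specialty="asthma")
    )
    i = 4
    core_zips = ["38103", "38104", "38105", "38106", "38107"]
    for z in core_zips:
        zlat, zlon = ZIP_CENTROIDS[z]
        for kind, specialty, base_name in _RESOURCE_KINDS:
            jlat = zlat + float(rng.uniform(-0.02, 0.02))
            jlon = zlon + float(rng.uniform(-0.02, 0.02))
            langs = "english;spanish" if rng.random() < 0.5 else "english"
            rows.append(
                dict(id=f"r{i:03d}", kind=kind, name=f"{base_name} {z}",
                     zip=z, lat=round(jlat, 5), lon=round(jlon, 5),
                     languages=langs, specialty=specialty)
            )
            i += 1
    directory = pd.DataFrame(rows)
    centroids = pd.DataFrame(
        [{"zip": z, "lat": lat, "lon": lon} for z, (lat, lon) in sorted(ZIP_CENTROIDS.items())]
    )
    return directory, centroids


def neighborhood_table() -> pd.DataFrame:
    """Fixed neighborhood metrics; 38103 has blight = 80 as strict maximum."""
    rows = [
        {"zip": "38103", "blight": 80, "walkability": 55, "crime": 40, "poverty": 30},
        {"zip": "38104", "blight": 20, "walkability": 70, "crime": 30, "poverty": 25},
        {"zip": "38105", "blight": 0, "walkability": 0, "crime": 0, "poverty": 0},
        {"zip": "38106", "blight": 10, "walkability": 30, "crime": 45, "poverty": 20},
        {"zip": "38107", "blight": 35, "walkability": 35, "crime": 10, "poverty": 5},
    ]
    return pd.DataFrame(rows)


def evidence_table() -> pd.DataFrame:
    """External-knowledge table: (stratum, symptom) -> outcome + citation."""
    rows = [
        {"stratum": "high risk", "symptom": "night_terror", "outcome": "asthma",
         "source": "ace_lit",
         "citation": "High adversity burden with sleep disturbance: screen early for pediatric asthma."},
        {"stratum": "high risk", "symptom": "behavioral_issue", "outcome": "stress",
         "source": "ace_lit",
         "citation": "Behavioral dysregulation under high adversity indicates toxic stress."},
        {"stratum": "moderate", "symptom": "behavioral_issue", "outcome": "stress",
         "source": "ace_lit",
         "citation": "Behavioral symptoms with moderate adversity warrant stress screening."},
    ]
    return pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)


# ---------------------------------------------------------------------- #
# simulated session logs

AGE_GROUPS = ["18-25", "26-40", "41-65"]
ETHNICITY_GROUPS = ["hispanic", "non-hispanic"]
_TEMPLATES = [
    ["FRI_Assessment", "SDoH_Surveillance", "FRI_followup_activity"],
    ["FRI_Assessment", "ACEs_Surveillance", "FRI_followup_activity"],
    ["FRI_Assessment", "SDoH_Surveillance", "ACEs_Surveillance", "FRI_followup_activity"],
    ["FRI_Assessment"],
]
# route preference per (age group, ethnicity group): weights over templates,
# peaked so cohorts show recognizable conversational routes
_TEMPLATE_WEIGHTS = {
    ("18-25", "hispanic"): [0.1, 0.7, 0.1, 0.1],
    ("18-25", "non-hispanic"): [0.7, 0.1, 0.1, 0.1],
    ("26-40", "hispanic"): [0.1, 0.1, 0.7, 0.1],
    ("26-40", "non-hispanic"): [0.25, 0.25, 0.25, 0.25],
    ("41-65", "hispanic"): [0.4, 0.4, 0.1, 0.1],
    ("41-65", "non-hispanic"): [0.1, 0.1, 0.2, 0.6],
}
DEFAULT_MISMATCH_RATE = 0.1


def simulate_sessions(
    n: int,
    seed: int = 1,
    mismatch_rate: float = DEFAULT_MISMATCH_RATE,
    start_time: float = 1_700_000_000.0,
) -> list[dict]:
    """Simulate ``n`` session logs as flat per-turn records.

    Each session draws a user profile, follows a profile-weighted intent
    route, jitters latencies, and independently flips each turn to a
    mismatch with probability ``mismatch_rate``. Fully reproducible per
    seed.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    records: list[dict] = []
    t = start_time
    zips = sorted(ZIP_CENTROIDS)
    for s in range(n):
        sid = f"sim-{s:04d}"
        age_group = AGE_GROUPS[int(rng.integers(len(AGE_GROUPS)))]
        eth = ETHNICITY_GROUPS[int(rng.integers(len(ETHNICITY_GROUPS)))]
        zipc = zips[int(rng.integers(len(zips)))]
        weights = _TEMPLATE_WEIGHTS[(age_group, eth)]
        template = _TEMPLATES[int(rng.choice(len(_TEMPLATES), p=weights))]
        for intent in template:
            latency = float(rng.gamma(2.0, 0.15))
            mismatch = bool(rng.random() < mismatch_rate)
            records.append(
                {
                    "session_id": sid,
                    "age_group": age_group,
                    "ethnicity_group": eth,
                    "zip": zipc,
                    "ts": round(t, 3),
                    "utterance": "(simulated turn)" if not mismatch else "(simulated gibberish)",
                    "intent": None if mismatch else intent,
                    "response": "(simulated response)",
                    "latency": round(latency, 4),
                    "mismatch": mismatch,
                }
            )
            t += 30.0 + latency
        t += 300.0
    return records


def write_jsonl(records: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


# ---------------------------------------------------------------------- #
# one-shot generation

def generate_all(out_dir: str | Path, seed: int = 1, n_sessions: int = 100) -> dict[str, Path]:
    """Write every fixture the assistant needs into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ont = build_aceso_lite()
    paths["ontology"] = out_dir / "ontology.json"
    ont.to_json(paths["ontology"])

    registry = default_intent_registry()
    paths["intents"] = out_dir / "intents.yaml"
    registry.to_yaml(paths["intents"])

    write_scenario_scripts(out_dir)
    for script in scenario_scripts():
        paths[f"scenario{script.scenario_id}"] = out_dir / f"scenario{script.scenario_id}.jsonl"
    paths["expectations"] = out_dir / "scenario_expectations.json"

    directory, centroids = resource_directory(seed)
    paths["resources"] = out_dir / "resources.csv"
    directory.to_csv(paths["resources"], index=False)
    paths["centroids"] = out_dir / "zip_centroids.csv"
    centroids.to_csv(paths["centroids"], index=False)

    paths["neighborhood"] = out_dir / "neighborhood.csv"
    neighborhood_table().to_csv(paths["neighborhood"], index=False)

    paths["evidence"] = out_dir / "evidence.csv"
    evidence_table().to_csv(paths["evidence"], index=False)

    paths["sessions"] = out_dir / "sessions.jsonl"
    write_jsonl(simulate_sessions(n_sessions, seed=seed), paths["sessions"])
    return paths
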