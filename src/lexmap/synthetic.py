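"""Synthetic common data models emulating multi-cohort naming conventions.

Real cohort dictionaries rename the same concept in wildly different ways:
"Years of Education" appears as "Eduy", "education", "EDUC"; imaging
pipelines emit left/right near-duplicates ("Lhippo_FS_adj" vs
"Rhippo_FS_adj"); many cohorts ship no descriptions at all. This module
generates CDMs with exactly those pathologies from a built-in vocabulary of
dementia-research concept phrases (demographics, cognitive scores, CSF
markers, MRI volumes, PET measures, genetics), so the whole
train/retrieve/rerank pipeline can be exercised and scored offline.

Everything is deterministic under the spec seed. Generated CDMs always pass
:meth:`lexmap.cdm.CDM.validate`, and every generated variant carries its
true term_id so accuracy can be scored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .cdm import CDM, CohortVariable, ReferenceTerm

__all__ = [
    "VariantRule",
    "SyntheticSpec",
    "generate_reference_terms",
    "generate_cohort_variants",
    "generate_unseen_cohort",
    "make_benchmark",
]

# (name, description, modality); lateralizable MRI structures are listed
# separately so left/right hard-negative pairs can be synthesized.
_VOCABULARY: list[tuple[str, str, str]] = [
    ("Age", "Age of the participant in years at the time of assessment", "Demographics"),
    ("Sex", "Biological sex of the participant", "Demographics"),
    ("Years of Education", "Total years of formal schooling completed", "Demographics"),
    ("Marital Status", "Current marital status of the participant", "Demographics"),
    ("Handedness", "Dominant hand of the participant", "Demographics"),
    ("Ethnicity", "Self-reported ethnicity of the participant", "Demographics"),
    ("Body Mass Index", "Weight in kilograms divided by height in meters squared", "Demographics"),
    ("Smoking History", "Lifetime tobacco smoking history of the participant", "Demographics"),
    ("Mini-Mental State Examination (MMSE)", "Total score on the mini mental state examination screening test", "Clinical"),
    ("Clinical Dementia Rating Scale Sum of Boxes (CDRSB)", "Sum of boxes score of the clinical dementia rating scale", "Clinical"),
    ("Alzheimer Disease Assessment Scale Cognitive (ADAS-Cog)", "Total score of the cognitive subscale of the Alzheimer disease assessment scale", "Clinical"),
    ("Montreal Cognitive Assessment (MoCA)", "Total score on the Montreal cognitive assessment", "Clinical"),
    ("Geriatric Depression Scale (GDS)", "Total score on the geriatric depression scale", "Clinical"),
    ("Functional Activities Questionnaire (FAQ)", "Total score of the functional activities questionnaire", "Clinical"),
    ("Neuropsychiatric Inventory (NPI)", "Total severity score of the neuropsychiatric inventory", "Clinical"),
    ("Trail Making Test Part A", "Time in seconds to complete part A of the trail making test", "Clinical"),
    ("Trail Making Test Part B", "Time in seconds to complete part B of the trail making test", "Clinical"),
    ("Boston Naming Test", "Total correct responses on the Boston naming test", "Clinical"),
    ("Category Fluency Animals", "Number of animals named in sixty seconds", "Clinical"),
    ("Digit Span Forward", "Longest digit sequence repeated in presented order", "Clinical"),
    ("Digit Span Backward", "Longest digit sequence repeated in reverse order", "Clinical"),
    ("Logical Memory Delayed Recall", "Delayed recall score of the logical memory story", "Clinical"),
    ("Rey Auditory Verbal Learning Test", "Total learning score over the five immediate recall trials", "Clinical"),
    ("Clock Drawing Test", "Score on the clock drawing screening task", "Clinical"),
    ("Global Clinical Dementia Rating", "Global rating of dementia severity", "Clinical"),
    ("Diagnosis", "Clinical diagnostic group at the visit", "Clinical"),
    ("CSF Amyloid Beta 42", "Concentration of amyloid beta 1-42 peptide in cerebrospinal fluid", "CSF"),
    ("CSF Amyloid Beta 40", "Concentration of amyloid beta 1-40 peptide in cerebrospinal fluid", "CSF"),
    ("CSF Total Tau", "Concentration of total tau protein in cerebrospinal fluid", "CSF"),
    ("CSF Phosphorylated Tau 181", "Concentration of tau phosphorylated at threonine 181 in cerebrospinal fluid", "CSF"),
    ("CSF Neurofilament Light", "Concentration of neurofilament light chain in cerebrospinal fluid", "CSF"),
    ("CSF Neurogranin", "Concentration of neurogranin in cerebrospinal fluid", "CSF"),
    ("CSF Chitinase 3 Like 1", "Concentration of chitinase 3 like protein 1 in cerebrospinal fluid", "CSF"),
    ("CSF Alpha Synuclein", "Concentration of alpha synuclein in cerebrospinal fluid", "CSF"),
    ("Plasma Neurofilament Light", "Concentration of neurofilament light chain in blood plasma", "CSF"),
    ("Plasma Phosphorylated Tau 217", "Concentration of tau phosphorylated at threonine 217 in blood plasma", "CSF"),
    ("Whole Brain Volume", "Total brain volume from structural magnetic resonance imaging", "MRI"),
    ("Intracranial Volume", "Estimated total intracranial volume from structural imaging", "MRI"),
    ("White Matter Hyperintensity Volume", "Total volume of white matter hyperintensities", "MRI"),
    ("Total Gray Matter Volume", "Total gray matter volume from structural imaging", "MRI"),
    ("Mean Cortical Thickness", "Mean thickness of the cerebral cortex across both hemispheres", "MRI"),
    ("Ventricular Volume", "Total volume of the cerebral ventricles", "MRI"),
    ("Amyloid PET Global SUVR", "Global standardized uptake value ratio of the amyloid tracer", "PET"),
    ("FDG PET Composite SUVR", "Composite standardized uptake value ratio of fluorodeoxyglucose uptake", "PET"),
    ("Tau PET Temporal Meta ROI SUVR", "Standardized uptake value ratio of the tau tracer in the temporal meta region", "PET"),
    ("Amyloid PET Centiloid", "Amyloid tracer uptake expressed on the centiloid scale", "PET"),
    ("Amyloid PET Status", "Dichotomized amyloid positivity from the tracer scan", "PET"),
    ("PET Tracer", "Radiotracer compound used for the positron emission tomography scan", "PET"),
    ("APOE Genotype", "Apolipoprotein E genotype combining both alleles", "Genetics"),
    ("APOE e4 Carrier Status", "Whether the participant carries at least one apolipoprotein E epsilon 4 allele", "Genetics"),
    ("APOE e4 Allele Count", "Number of apolipoprotein E epsilon 4 alleles carried", "Genetics"),
    ("Polygenic Risk Score", "Genome wide polygenic risk score for Alzheimer disease", "Genetics"),
    ("Family History of Dementia", "Reported dementia diagnosis in a first degree relative", "Genetics"),
]

# lateralizable structures -> (measure phrase, description template)
_LATERAL_BASES: list[tuple[str, str]] = [
    ("hippocampus volume", "Volume of the {side} hippocampus from structural imaging"),
    ("entorhinal cortex thickness", "Thickness of the {side} entorhinal cortex"),
    ("amygdala volume", "Volume of the {side} amygdala from structural imaging"),
    ("lateral ventricle volume", "Volume of the {side} lateral ventricle"),
    ("fusiform gyrus volume", "Volume of the {side} fusiform gyrus"),
    ("middle temporal gyrus volume", "Volume of the {side} middle temporal gyrus"),
    ("precuneus thickness", "Thickness of the {side} precuneus cortex"),
    ("posterior cingulate thickness", "Thickness of the {side} posterior cingulate cortex"),
    ("parahippocampal gyrus volume", "Volume of the {side} parahippocampal gyrus"),
    ("inferior parietal thickness", "Thickness of the {side} inferior parietal cortex"),
    ("caudate volume", "Volume of the {side} caudate nucleus"),
    ("thalamus volume", "Volume of the {side} thalamus from structural imaging"),
]

_VISITS = ["", "at baseline", "at month 12", "at month 24", "at month 36", "at year 5"]

_SYNONYMS = {
    "volume": "vol",
    "examination": "exam",
    "assessment": "assess",
    "education": "schooling",
    "status": "stat",
    "score": "scr",
    "test": "tst",
    "total": "tot",
    "global": "glob",
    "years": "yrs",
    "memory": "mem",
    "delayed": "del",
    "recall": "recl",
    "thickness": "thick",
    "baseline": "bl",
    "month": "m",
    "cognitive": "cog",
    "composite": "comp",
    "temporal": "temp",
}

_SUFFIXES = ["_bl", "_adj", "_v1", "_tot", "_raw"]

DEFAULT_RULES: tuple = None  # populated after VariantRule is defined


@dataclass(frozen=True)
class VariantRule:
    """One naming-convention perturbation with an application probability."""

    kind: str
    probability: float

    _KINDS = {
        "abbreviate_initials",
        "truncate",
        "case_change",
        "underscore_style",
        "cohort_suffix",
        "vowel_drop",
        "synonym_swap",
        "drop_description",
    }

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown variant rule {self.kind!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("rule probability must be in [0, 1]")


DEFAULT_RULES = (
    VariantRule("synonym_swap", 0.30),
    VariantRule("abbreviate_initials", 0.15),
    VariantRule("truncate", 0.15),
    VariantRule("underscore_style", 0.50),
    VariantRule("case_change", 0.50),
    VariantRule("cohort_suffix", 0.20),
    VariantRule("vowel_drop", 0.15),
    VariantRule("drop_description", 0.30),
)


@dataclass
class SyntheticSpec:
    """Size, structure and noise model of one synthetic CDM."""

    n_terms: int = 50
    n_cohorts: int = 3
    modalities: list[str] = field(
        default_factory=lambda: ["Demographics", "Clinical", "CSF", "MRI", "PET", "Genetics"]
    )
    lateralized_fraction: float = 0.2
    rules: tuple[VariantRule, ...] = DEFAULT_RULES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 2:
            raise ValueError("n_terms must be >= 2")
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be >= 1")
        if not 0.0 <= self.lateralized_fraction <= 1.0:
            raise ValueError("lateralized_fraction must be in [0, 1]")
        if not self.rules:
            raise ValueError("at least one variant rule must be active")

    def rule(self, kind: str) -> float:
        for r in self.rules:
            if r.kind == kind:
                return r.probability
        return 0.0


# -- reference terms -------------------------------------------------------


def generate_reference_terms(spec: SyntheticSpec) -> list[ReferenceTerm]:
    """Draw ``n_terms`` reference terms from the built-in vocabulary.

    A ``lateralized_fraction`` of terms (rounded down to an even count) is
    emitted as left/right pairs whose names differ by a single character
    ("L hippocampus volume" / "R hippocampus volume") — the hard-negative
    structure imaging modalities exhibit. Concepts keep their natural
    modality; vocabulary exhaustion is handled by visit-qualified
    composites ("... at month 12").
    """
    rng = np.random.default_rng(spec.seed)
    n_lat = int(spec.n_terms * spec.lateralized_fraction) // 2 * 2
    n_plain = spec.n_terms - n_lat

    lat_pool = [
        (base, desc, visit)
        for visit in _VISITS
        for base, desc in _LATERAL_BASES
        if "MRI" in spec.modalities
    ]
    plain_pool = [
        (name, desc, mod, visit)
        for visit in _VISITS
        for name, desc, mod in _VOCABULARY
        if mod in spec.modalities
    ]
    if n_lat // 2 > len(lat_pool) or n_plain > len(plain_pool):
        raise ValueError("n_terms exceeds the built-in vocabulary capacity")

    # shuffle within each visit block so base visits are used first
    def _blocked_shuffle(pool, block):
        out = []
        for i in range(0, len(pool), block):
            chunk = pool[i : i + block]
            out += [chunk[j] for j in rng.permutation(len(chunk))]
        return out

    lat_pool = _blocked_shuffle(lat_pool, len(_LATERAL_BASES))
    plain_pool = _blocked_shuffle(plain_pool, sum(m in spec.modalities for *_, m in _VOCABULARY))

    terms: list[ReferenceTerm] = []

    def _add(name: str, desc: str, mod: str) -> None:
        terms.append(
            ReferenceTerm(
                term_id=f"T{len(terms):04d}",
                name=name,
                description=desc,
                ontology_id=f"SYN:{len(terms):07d}",
                modality=mod,
            )
        )

    for base, desc, visit in lat_pool[: n_lat // 2]:
        qual = f" {visit}" if visit else ""
        _add(f"L {base}{qual}", desc.format(side="left") + (f" {visit}" if visit else ""), "MRI")
        _add(f"R {base}{qual}", desc.format(side="right") + (f" {visit}" if visit else ""), "MRI")
    for name, desc, mod, visit in plain_pool[:n_plain]:
        qual = f" {visit}" if visit else ""
        _add(f"{name}{qual}", desc + (f" measured {visit}" if visit else ""), mod)
    return terms


# -- cohort variants -------------------------------------------------------


def _strip_parenthetical(name: str) -> tuple[str, str | None]:
    m = re.search(r"\(([^)]+)\)", name)
    if m:
        return re.sub(r"\s*\([^)]+\)", "", name).strip(), m.group(1)
    return name, None


def _abbreviate(name: str, acronym: str | None) -> str:
    if acronym:
        return acronym
    words = re.findall(r"[A-Za-z0-9]+", name)
    return "".join(w[0].upper() for w in words)


def _vowel_drop(name: str) -> str:
    out = "".join(c for c in name if c not in "aeiou")
    return out if len(out) >= 2 else name


def _variant_name(full_name: str, spec: SyntheticSpec, rng: np.random.Generator) -> str:
    """Apply the sampled naming-convention rules to one term name."""
    base, acronym = _strip_parenthetical(full_name)
    name = base if (acronym and rng.random() < 0.5) else full_name

    if rng.random() < spec.rule("synonym_swap"):
        words = name.split(" ")
        name = " ".join(_SYNONYMS.get(w.lower(), w) for w in words)

    r = rng.random()
    if r < spec.rule("abbreviate_initials"):
        name = _abbreviate(name, acronym)
    elif r < spec.rule("abbreviate_initials") + spec.rule("truncate"):
        squashed = re.sub(r"[^A-Za-z0-9]", "", name)
        keep = int(rng.integers(5, 9))
        name = squashed[:keep] if len(squashed) > keep else squashed

    if rng.random() < spec.rule("underscore_style"):
        name = re.sub(r"[\s\-]+", "_", name.strip())

    if rng.random() < spec.rule("case_change"):
        name = [str.lower, str.upper, str.title][rng.integers(3)](name)

    if rng.random() < spec.rule("cohort_suffix"):
        name = name + _SUFFIXES[rng.integers(len(_SUFFIXES))]

    if rng.random() < spec.rule("vowel_drop"):
        name = _vowel_drop(name)

    return name or full_name


def _variant_description(desc: str, spec: SyntheticSpec, rng: np.random.Generator) -> str:
    if not desc or rng.random() < spec.rule("drop_description"):
        return ""
    words = desc.split(" ")
    kept = [w for w in words if rng.random() > 0.25]
    if len(kept) < 2:
        kept = words[:3]
    return " ".join(kept)


def _draw_variant(
    term: ReferenceTerm,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    taken: set[str],
    tag: str,
) -> tuple[str, str]:
    """A variant (name, description) whose name avoids ``taken``; bounded
    retries, then a deterministic disambiguating suffix."""
    name = _variant_name(term.name, spec, rng)
    for _ in range(100):
        if name.lower() not in taken:
            break
        name = _variant_name(term.name, spec, rng)
    else:
        i = 2
        while f"{name}_{tag}{i}".lower() in taken:
            i += 1
        name = f"{name}_{tag}{i}"
    return name, _variant_description(term.description, spec, rng)


def generate_cohort_variants(terms: list[ReferenceTerm], spec: SyntheticSpec) -> CDM:
    """Build a CDM: every cohort renames every term by its own sampled
    conventions. Variant names are unique within each cohort."""
    if not terms:
        raise ValueError("terms must be non-empty")
    rng = np.random.default_rng([spec.seed, 1])
    cdm = CDM()
    for t in terms:
        cdm.add_term(t)
    for c in range(spec.n_cohorts):
        source = f"COHORT{c + 1}"
        taken: set[str] = set()
        for t in terms:
            name, desc = _draw_variant(t, spec, rng, taken, "v")
            taken.add(name.lower())
            cdm.add_variable(
                CohortVariable(name=name, description=desc, source_id=source, modality=t.modality),
                t.term_id,
            )
    cdm.validate()
    return cdm


def generate_unseen_cohort(
    terms: list[ReferenceTerm], spec: SyntheticSpec, exclude: CDM, cohort_index: int = 0
) -> list[tuple[str, str, str]]:
    """A labeled evaluation cohort: one fresh variant per term whose name
    collides with nothing in ``exclude``. Returns (name, description,
    true term_id) rows; truth is used only for scoring."""
    exclude.validate()
    rng = np.random.default_rng([spec.seed, 2, cohort_index])
    taken = {name.lower() for name, _ in exclude.variables}
    taken |= {t.name.lower() for t in exclude.terms.values()}
    rows: list[tuple[str, str, str]] = []
    for t in terms:
        name, desc = _draw_variant(t, spec, rng, taken, "u")
        taken.add(name.lower())
        rows.append((name, desc, t.term_id))
    return rows


def make_benchmark(
    n_terms: int = 150,
    n_cohorts: int = 4,
    n_unseen: int = 2,
    lateralized_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[CDM, list[list[tuple[str, str, str]]]]:
    """One-call benchmark fixture: a training CDM plus labeled unseen
    cohorts, mirroring the evaluate-on-held-out-cohorts protocol."""
    spec = SyntheticSpec(
        n_terms=n_terms,
        n_cohorts=n_cohorts,
        lateralized_fraction=lateralized_fraction,
        seed=seed,
    )
    terms = generate_reference_terms(spec)
    cdm = generate_cohort_variants(terms, spec)
    unseen = [generate_unseen_cohort(terms, spec, cdm, i) for i in range(n_unseen)]
    return cdm, unseen
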