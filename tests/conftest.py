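import pytest

from lexmap import (
    CDM,
    CohortVariable,
    HarmonizationConfig,
    Harmonizer,
    ReferenceTerm,
)
from lexmap.synthetic import SyntheticSpec, generate_cohort_variants, generate_reference_terms


@pytest.fixture
def age_cdm() -> CDM:
    """One reference term 'Age' with the four classic cohort spellings."""
    cdm = CDM()
    cdm.add_term(
        ReferenceTerm(
            term_id="AGE",
            name="Age",
            description="Age of the participant in years",
            modality="Demographics",
        )
    )
    for name, source in [
        ("age", "cohortA"),
        ("PTAGE", "cohortA"),
        ("samplingAge", "cohortB"),
        ("age_at_visit", "cohortC"),
    ]:
        cdm.add_variable(
            CohortVariable(name=name, description="", source_id=source, modality="Demographics"),
            "AGE",
        )
    return cdm


@pytest.fixture
def toy_cdm() -> CDM:
    """Small multi-modality CDM with lateralized MRI hard negatives and a
    CDRSB-style alias cluster."""
    cdm = CDM()
    terms = [
        ("AGE", "Age", "Age of the participant in years", "Demographics"),
        ("EDU", "Years of Education", "Total years of formal schooling", "Demographics"),
        ("MMSE", "Mini-Mental State Examination (MMSE)", "Mini mental state exam total", "Clinical"),
        ("CDRSB", "Clinical Dementia Rating Scale Sum of Boxes (CDRSB)",
         "Sum of boxes of the clinical dementia rating", "Clinical"),
        ("LHIPPO", "L hippocampus volume", "Volume of the left hippocampus", "MRI"),
        ("RHIPPO", "R hippocampus volume", "Volume of the right hippocampus", "MRI"),
    ]
    for tid, name, desc, mod in terms:
        cdm.add_term(ReferenceTerm(term_id=tid, name=name, description=desc, modality=mod))
    variables = [
        ("age", "", "ADNI", "AGE"),
        ("PTAGE", "Age at baseline", "ADNI", "AGE"),
        ("age_at_visit", "", "EPAD", "AGE"),
        ("EDUC", "Years of education", "ADNI", "EDU"),
        ("eduy", "", "EPAD", "EDU"),
        ("MMSCORE", "Mini mental state examination score", "ADNI", "MMSE"),
        ("mmse_total", "", "EPAD", "MMSE"),
        ("CDRSB", "CDR sum of boxes", "ADNI", "CDRSB"),
        ("CDR_SOB", "", "AIBL", "CDRSB"),
        ("cdr_sb", "sum of boxes", "EPAD", "CDRSB"),
        ("Lhippo_FS_adj", "Left hippocampus volume adjusted", "ADNI", "LHIPPO"),
        ("lhc_vol", "", "EPAD", "LHIPPO"),
        ("Rhippo_FS_adj", "Right hippocampus volume adjusted", "ADNI", "RHIPPO"),
        ("rhc_vol", "", "EPAD", "RHIPPO"),
    ]
    for name, desc, source, tid in variables:
        mod = cdm.terms[tid].modality
        cdm.add_variable(
            CohortVariable(name=name, description=desc, source_id=source, modality=mod), tid
        )
    return cdm


@pytest.fixture(scope="session")
def synthetic_cdm() -> CDM:
    """50 terms x 4 cohorts, the pair-generation benchmark shape."""
    spec = SyntheticSpec(n_terms=50, n_cohorts=4, lateralized_fraction=0.2, seed=11)
    return generate_cohort_variants(generate_reference_terms(spec), spec)


@pytest.fixture(scope="session")
def fitted_harmonizer(synthetic_cdm) -> Harmonizer:
    """A trained pipeline shared across inference tests (64-dim for speed)."""
    cfg = HarmonizationConfig(seed=11, embedding_dim=64, threshold=0.5)
    return Harmonizer(config=cfg).fit(synthetic_cdm)
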