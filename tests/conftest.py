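import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None)
settings.load_profile("ci")

from concord.concordance import profile_patient
from concord.io import records_from_frame
from concord.panels import Alteration, AlterationKind, Assay, load_panel_definitions
from concord.pipeline import harmonize_cohort
from concord.simulate import generate_cohort, preset_paperlike
from concord.stats import build_cohort_frame


def make_alt(
    gene,
    locus="",
    kind=AlterationKind.POINT_MUTATION,
    assay=Assay.TISSUE,
    patient_id="P1",
    vaf=None,
    characterized=True,
):
    return Alteration(
        patient_id=patient_id,
        gene=gene,
        kind=kind,
        locus=locus,
        assay=assay,
        vaf_percent=vaf,
        characterized=characterized,
    )


@pytest.fixture(scope="session")
def panels():
    return load_panel_definitions()


def cohort_frame_for(seed, n=433, **overrides):
    """Run the full in-memory chain on a preset cohort; return (frame, cohort)."""
    cohort = generate_cohort(preset_paperlike(n_patients=n, seed=seed, **overrides))
    panels_ = load_panel_definitions()
    harmonized, _ = harmonize_cohort(records_from_frame(cohort.alterations), panels_)
    for pid in cohort.clinical.patient_id:
        harmonized.setdefault(pid, ([], []))
    profiles = {p: profile_patient(t, c) for p, (t, c) in harmonized.items()}
    gene_counts = {
        p: (len({a.gene for a in t}), len({a.gene for a in c}))
        for p, (t, c) in harmonized.items()
    }
    frame = build_cohort_frame(cohort.clinical, profiles, gene_counts)
    frame = frame.merge(cohort.survival, on="patient_id")
    return frame, cohort


@pytest.fixture(scope="session")
def preset_frame():
    """One medium preset cohort run through the full chain (shared, read-only)."""
    return cohort_frame_for(seed=42, n=800)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
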