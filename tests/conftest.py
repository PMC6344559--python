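"""Shared fixtures: episode factories and a default synthetic cohort."""

from __future__ import annotations

from datetime import datetime
from pathlib import Path

import pytest

from sepsitree.cohort import (
    BiomarkerPanel,
    Cohort,
    DeteriorationEvents,
    Episode,
    ImmunoCriteria,
    cohort_to_frame,
)
from sepsitree.synth import default_paper_config, generate_cohort

EXAMPLES = Path(__file__).resolve().parent.parent / "examples"

T0 = datetime(2016, 7, 1, 12, 0)


def make_events(**kw) -> DeteriorationEvents:
    defaults = dict(weight_kg=20.0, crystalloid_ml_24h=0.0)
    defaults.update(kw)
    return DeteriorationEvents(**defaults)


def make_episode(**kw) -> Episode:
    defaults = dict(
        subject_id="S0001",
        episode_id="E1",
        age_years=7.8,
        sex="F",
        location="ward",
        platelet_k_mcl=80.0,
        immuno=ImmunoCriteria(anc=0.3),
        culture_time=T0,
        sample_time=T0,
        biomarkers=BiomarkerPanel(il8=250.0, ccl3=30.0, hspa1b=2000.0,
                                  gzmb=20.0, mmp8=3000.0),
        events=make_events(),
        bacterially_infected=False,
        death_28d=False,
    )
    defaults.update(kw)
    return Episode(**defaults)


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    return generate_cohort(default_paper_config(seed=1))


@pytest.fixture(scope="session")
def default_frame(default_cohort):
    return cohort_to_frame(default_cohort)


@pytest.fixture(scope="session")
def examples_dir() -> Path:
    return EXAMPLES
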