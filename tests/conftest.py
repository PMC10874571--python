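import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import mspanel as mp
from mspanel.preprocess import AnalyteProvenance, StandardizedPanel

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_like_cohort():
    cohort, truth = mp.generate_cohort(mp.SimConfig.paper_like(seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def recovery_cohort():
    cohort, truth = mp.generate_cohort(mp.SimConfig.recovery_scenario(seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def standardized(paper_like_cohort):
    cohort, _ = paper_like_cohort
    processed, panel = mp.standardize_cohort(cohort)
    return processed, panel


def make_subjects(labels, ages=None, sexes=None, rng=None):
    """Minimal subject list from 0/1 MS labels (for panel-model tests)."""
    rng = rng or np.random.default_rng(0)
    n = len(labels)
    ages = ages if ages is not None else rng.uniform(25, 55, n)
    sexes = sexes if sexes is not None else rng.choice(["F", "M"], n)
    return [
        mp.Subject(subject_id=f"P{i:05d}", group=mp.MS if labels[i] else mp.CONTROL,
                   age_at_sampling=float(ages[i]), sex=str(sexes[i]))
        for i in range(n)
    ]


def make_panel(columns: dict, subject_ids) -> StandardizedPanel:
    """StandardizedPanel from raw arrays keyed by (analyte, compartment)."""
    frame = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()},
                         index=list(subject_ids))
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["analyte", "compartment"])
    prov = {k: AnalyteProvenance(0.0, 1.0, int(frame[k].notna().sum()), 0)
            for k in frame.columns}
    return StandardizedPanel(features=frame, provenance=prov)
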