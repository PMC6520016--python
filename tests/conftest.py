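import math

import numpy as np
import pandas as pd
import pytest

from care_index.data_model import BiomarkerSpec, CohortTable
from care_index.event_models import EventModel, EventModelSet


@pytest.fixture
def toy_panel():
    return [
        BiomarkerSpec("up", "increase"),
        BiomarkerSpec("down", "decrease"),
        BiomarkerSpec("up2", "increase"),
    ]


@pytest.fixture
def toy_models(toy_panel):
    """Hand-specified event models: unit scales, event means displaced by 2."""
    models = {}
    for spec in toy_panel:
        sign = 1.0 if spec.direction == "increase" else -1.0
        models[spec.name] = EventModel(
            biomarker=spec.name,
            direction=spec.direction,
            mu_nonevent=0.0,
            sigma_nonevent=1.0,
            mu_event=sign * 2.0,
            sigma_event=1.0,
            w=0.5,
        )
    return EventModelSet(models)


def make_table(panel, values, groups=None, cohort_id="T"):
    """CohortTable from a list of per-subject biomarker value lists."""
    n = len(values)
    groups = groups if groups is not None else ["N-MCI"] * n
    data = pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "group": groups,
            "cohort": cohort_id,
        }
    )
    for j, spec in enumerate(panel):
        data[spec.name] = [row[j] for row in values]
    return CohortTable(cohort_id=cohort_id, data=data, panel=list(panel))


def enum_subject_likelihood(values, models, seq):
    """Brute-force event-based subject likelihood: average over all stages
    of the product of conditional densities (missing value -> factor 1)."""
    N = len(seq.events)
    total = 0.0
    for k in range(N + 1):
        prod = 1.0
        for pos, name in enumerate(seq.events, start=1):
            x = values.get(name)
            if x is None or (isinstance(x, float) and math.isnan(x)):
                continue
            m = models[name]
            prod *= m.density_event(x) if pos <= k else m.density_nonevent(x)
        total += prod
    return total / (N + 1)


def enum_stage_posterior(values, models, seq):
    """Brute-force stage posterior L(k)/sum(L) with missing factors = 1."""
    N = len(seq.events)
    L = np.zeros(N + 1)
    for k in range(N + 1):
        prod = 1.0
        for pos, name in enumerate(seq.events, start=1):
            x = values.get(name)
            if x is None or (isinstance(x, float) and math.isnan(x)):
                continue
            m = models[name]
            prod *= m.density_event(x) if pos <= k else m.density_nonevent(x)
        L[k] = prod
    return L / L.sum()
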