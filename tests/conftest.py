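"""Shared fixtures: simulated datasets with known ground truth.

Session-scoped so the heavier simulations (a few thousand events through
the full Bayes-factor calling path) run once and are shared by the unit,
property and acceptance tests.
"""

import pytest
from hypothesis import settings

from spliceswitch import (
    DISEASE_CONDITIONS,
    TREATMENT_CONDITIONS,
    CategoryBias,
    generate_event_catalog,
    run_contrast,
    simulate_counts,
    simulate_truth,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def _contrasts(catalog, counts, disease=True):
    treatment = run_contrast(
        catalog, counts, *TREATMENT_CONDITIONS, contrast_label="treatment"
    )
    out = {"treatment": treatment}
    if disease:
        out["disease"] = run_contrast(
            catalog, counts, *DISEASE_CONDITIONS, contrast_label="disease"
        )
    return out


@pytest.fixture(scope="session")
def sim_main():
    """Default study conditions: 3920 events (~2000 genes), 20% differential
    per contrast, |dpsi| in [0.25, 0.6], NB coverage mean 100, 3 replicates."""
    catalog = generate_event_catalog(560, seed=101)
    truth = simulate_truth(catalog, seed=102)
    counts = simulate_counts(truth, catalog, seed=103)
    data = {
        "catalog": catalog,
        "truth": truth,
        "truth_by_id": {t.event_id: t for t in truth},
        "counts": counts,
        "gene_by_event": {e.event_id: e.gene_id for e in catalog},
    }
    data.update(_contrasts(catalog, counts))
    return data


@pytest.fixture(scope="session")
def sim_switch():
    """High joint-differential rate so >= 1000 events are differential in
    both contrasts, for switch-fraction recovery."""
    catalog = generate_event_catalog(430, seed=201)
    truth = simulate_truth(catalog, frac_differential=0.65, frac_switch=0.6, seed=202)
    counts = simulate_counts(truth, catalog, seed=203)
    data = {
        "catalog": catalog,
        "truth": truth,
        "truth_by_id": {t.event_id: t for t in truth},
        "counts": counts,
    }
    data.update(_contrasts(catalog, counts))
    return data


@pytest.fixture(scope="session")
def sim_null():
    """Null simulation: no differential events in either contrast, 2002
    events, coverage 100, 3 replicates — for Bayes-factor calibration."""
    catalog = generate_event_catalog(286, seed=301)
    truth = simulate_truth(catalog, frac_differential=0.0, seed=302)
    counts = simulate_counts(truth, catalog, seed=303)
    data = {"catalog": catalog, "truth": truth, "counts": counts}
    data.update(_contrasts(catalog, counts, disease=False))
    return data


@pytest.fixture(scope="session")
def sim_ri_bias():
    """Planted excess of excluded, over-represented RI events in the
    treatment contrast, for composition-test recovery."""
    catalog = generate_event_catalog(200, seed=401)
    truth = simulate_truth(
        catalog,
        category_bias={"RI": CategoryBias(differential_odds=5.0, prob_excluded=0.95)},
        seed=402,
    )
    counts = simulate_counts(truth, catalog, seed=403)
    data = {"catalog": catalog, "truth": truth, "counts": counts}
    data.update(_contrasts(catalog, counts, disease=False))
    return data
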