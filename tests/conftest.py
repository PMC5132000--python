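import math

import numpy as np
import pytest

import exosurv as es


@pytest.fixture(scope="session")
def protocol():
    return es.StimulusProtocol.default()


@pytest.fixture(scope="session")
def table2_truth():
    """Reference frailty parameters for human beta-cells (healthy vs
    diabetic donors)."""
    return es.FrailtyParams(alpha1=math.log(0.00117), alpha2=math.log(0.00014),
                            beta2=1.43, eta=499.5, pi0=0.026, pi1=0.010)


@pytest.fixture(scope="session")
def small_dataset(table2_truth):
    """19 cells (11 healthy + 8 diabetic) x 80 granules, no cell
    heterogeneity."""
    design = es.SimulationDesign(11, 8, 80, truth=table2_truth,
                                 cell_heterogeneity_variance=0.0, seed=42)
    return es.simulate_dataset(design)


@pytest.fixture(scope="session")
def medium_dataset(table2_truth):
    """60 cells x 100 granules at the reference truth, v=0."""
    design = es.SimulationDesign(30, 30, 100, truth=table2_truth,
                                 cell_heterogeneity_variance=0.0, seed=7)
    return es.simulate_dataset(design)


@pytest.fixture(scope="session")
def medium_fit(medium_dataset):
    return es.fit_frailty(medium_dataset)


@pytest.fixture(scope="session")
def medium_adjusted(medium_fit):
    sw, adj = es.adjusted_inference(medium_fit)
    return sw, adj


def piecewise_survival_loglik(dataset, params):
    """Survival-form log-likelihood sum d log mu(t) - M(t), evaluated
    independently of the Poisson episode-split path (oracle)."""
    total = 0.0
    end = dataset.protocol.observation_end
    for row in dataset.table.itertuples():
        X = row.diabetic
        m = es.cumulative_baseline_hazard(row.time, params, X, dataset.protocol)
        total -= m
        if row.event:
            t_ev = min(row.time, np.nextafter(end, 0.0))
            total += np.log(es.hazard_at(t_ev, params, X, 1.0, dataset.protocol))
    return total
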