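import numpy as np
import pytest

from skewsample import ExperimentDesign, PopulationParams, TrialRecord, simulate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def build_trial(
    pid="p001",
    condition="negative",
    counts=(0, 1, 1, 3, 5),
    estimate_norm=None,
    trial_index=1,
    multiplier=60.0,
    values_by_bin=None,
):
    """Hand-crafted trial: draw values sit at bin midpoints unless given."""
    counts = np.asarray(counts, dtype=int)
    budget = int(counts.sum())
    edges = np.linspace(0.0, 1.0, 6)
    bins, values = [], []
    for k, c in enumerate(counts, start=1):
        for j in range(int(c)):
            bins.append(k)
            if values_by_bin and k in values_by_bin:
                values.append(values_by_bin[k][j])
            else:
                values.append(0.5 * (edges[k - 1] + edges[k]))
    values = np.asarray(values)
    if estimate_norm is None:
        estimate_norm = float(values.mean()) if len(values) else 0.5
    return TrialRecord(
        participant_id=pid,
        condition=condition,
        budget=budget,
        counts=counts,
        draw_bins=np.asarray(bins, dtype=int),
        draw_values=values,
        multiplier=multiplier,
        estimate_raw=estimate_norm * multiplier,
        trial_index=trial_index,
    )


@pytest.fixture(scope="session")
def small_experiment():
    """A 30-participant synthetic experiment shared across read-only tests."""
    design = ExperimentDesign(n_participants=30, seed=42)
    return simulate_experiment(design, PopulationParams(0.5, 0.2))
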