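import numpy as np
import pytest

import hubdisrupt as hd

# Replicated simulation at reduced scale (20 regions, 4 hubs, 20 + 20
# subjects, 200 time points) shared by the recovery, power and type-I
# tests so the cohorts are generated once per session.
REPLICATE_SCALE = dict(n_nc=20, n_emci=20, n_regions=20, n_timepoints=200,
                       n_hubs=4, hub_strength=0.55, base_strength=0.15,
                       subject_noise_sd=0.04)
N_REPLICATES = 20
DELTAS = (0.0, 0.4, 0.8)
SPARSITY = 0.3


def _one_replicate(delta: float, seed: int) -> dict:
    spec = hd.CohortSpec(disruption=delta, seed=seed, **REPLICATE_SCALE)
    cohort = hd.generate_cohort(spec)
    results = hd.analyze_cohort(cohort, (SPARSITY,))
    nc_k, em_k, _, _ = hd.cohort_hdi_values(results, SPARSITY)
    nc_nodal = [r.nodal_metrics[SPARSITY] for r in results if r.group == "NC"]
    em_nodal = [r.nodal_metrics[SPARSITY] for r in results if r.group == "EMCI"]
    diffs = hd.abnormal_regions(nc_nodal, em_nodal, "degree", top_k=4)
    top_reduced = {d.region_label for d in diffs if d.top_reduced}
    hubs = {cohort.region_labels[i] for i in spec.hub_indices}
    return {
        "nc_k": nc_k, "em_k": em_k,
        "top_reduced_degree": top_reduced, "hub_labels": hubs,
        "n_regions": spec.n_regions,
    }


@pytest.fixture(scope="session")
def replicates():
    """delta -> list of per-seed replicate summaries (k values, rankings)."""
    return {delta: [_one_replicate(delta, seed) for seed in range(N_REPLICATES)]
            for delta in DELTAS}


@pytest.fixture(scope="session")
def small_cohort():
    """One small disrupted cohort for structural/pipeline tests."""
    spec = hd.CohortSpec(n_nc=10, n_emci=10, n_regions=20, n_timepoints=150,
                         n_hubs=4, disruption=0.8, seed=11)
    return spec, hd.generate_cohort(spec)
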