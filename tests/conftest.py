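import numpy as np
import pandas as pd
import pytest

import lineagescore as ls


def brute_force_pcls(values, weights):
    """Independent O(n^2) double-summation oracle for the deviation statistic.

    Pure-Python re-derivation from the definition: explicit partial sums
    at every rank, no shared code with the streaming implementation.
    """
    n = len(values)
    m = [abs(v) for v in values]
    fg_tot = sum(weights[j] * m[j] for j in range(n))
    bg_tot = sum((1 - weights[j]) * m[j] for j in range(n))
    assert fg_tot > 0 and bg_tot > 0
    d = []
    for i in range(n):
        f_i = sum(weights[j] * m[j] for j in range(i + 1)) / fg_tot
        b_i = sum((1 - weights[j]) * m[j] for j in range(i + 1)) / bg_tot
        d.append(f_i - b_i)
    plus = max(max(d), 0.0)
    minus = min(min(d), 0.0)
    return plus if plus >= -minus else minus


@pytest.fixture(scope="session")
def tiny_panel():
    """Small synthetic reference panel with known marker structure."""
    panel, truth = ls.generate_reference(
        n_lineages=4, n_genes=400, markers_per_lineage=20, effect=3.0,
        n_replicates=3, noise_sd=0.3, seed=101,
    )
    return panel, truth


@pytest.fixture(scope="session")
def tiny_profiles(tiny_panel):
    panel, _ = tiny_panel
    return ls.build_weight_profiles(panel)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_panel):
    """40-sample tumour cohort mixed from the tiny panel's archetypes."""
    panel, truth = tiny_panel
    tumours, truth = ls.generate_tumours(
        truth, n_samples=40, tumour_intrinsic_sd=0.3, seed=202
    )
    return tumours, truth
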