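"""Synthetic reference panels, tumour cohorts and survival outcomes.

The generator emulates the structure the scoring method assumes: each
cell lineage carries a disjoint set of marker genes upregulated by a
fixed log2 effect over a shared baseline; a bulk tumour sample is a
convex mixture of lineage archetype *intensities* (mixing happens on the
linear scale, then the composite is logged, matching how bulk expression
composites cell signals) plus tumour-intrinsic gene noise; survival
times are exponential with hazard proportional to
``exp(sum_k beta_k * activity_k)`` where the activity is the
standardized true mixing fraction.

Known ground truth (marker assignment, mixing fractions, betas) is kept
alongside the data so every pipeline stage can be tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import ReferencePanel

#: Dirichlet concentration for mixing fractions; 0.5 gives sparse
#: infiltrates, i.e. most samples dominated by a few lineages.
DEFAULT_DIRICHLET_ALPHA = 0.5
#: Baseline log2 intensity distribution of non-marker genes (microarray-like).
BASELINE_MEAN = 6.0
BASELINE_SD = 1.0


@dataclass
class SimulationTruth:
    """Ground truth of a simulated cohort."""

    marker_assignment: dict[str, str]  # gene -> lineage
    effect: float                      # marker up-shift, log2 units
    noise_sd: float                    # replicate noise sd, log2 units
    baseline: pd.Series | None = None  # per-gene baseline log2 mean
    archetypes: pd.DataFrame | None = None  # genes x lineages log2 means
    mixing: pd.DataFrame | None = None  # samples x lineages simplex rows
    betas: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def generate_reference(
    n_lineages: int = 10,
    n_genes: int = 5000,
    markers_per_lineage: int = 50,
    effect: float = 3.0,
    n_replicates: int = 3,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ReferencePanel, SimulationTruth]:
    """Simulate a reference panel with lineage-specific marker genes.

    Each lineage gets ``markers_per_lineage`` disjoint marker genes whose
    mean log2 intensity is shifted up by ``effect`` in that lineage only;
    every replicate adds independent N(0, noise_sd) noise.
    """
    if markers_per_lineage * n_lineages > n_genes:
        raise ValueError("marker allocation infeasible: too few genes")
    if min(n_lineages, n_genes, markers_per_lineage, n_replicates) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    lineages = [f"LIN{k:02d}" for k in range(n_lineages)]
    baseline = pd.Series(
        rng.normal(BASELINE_MEAN, BASELINE_SD, n_genes), index=genes, name="baseline"
    )
    marker_genes = rng.choice(n_genes, markers_per_lineage * n_lineages, replace=False)
    assignment: dict[str, str] = {}
    archetypes = pd.DataFrame(
        np.tile(baseline.to_numpy()[:, None], (1, n_lineages)),
        index=genes, columns=lineages,
    )
    for k, lineage in enumerate(lineages):
        idx = marker_genes[k * markers_per_lineage : (k + 1) * markers_per_lineage]
        for gi in idx:
            assignment[genes[gi]] = lineage
        archetypes.iloc[idx, k] += effect

    columns, data, replicate_map = [], [], {}
    for k, lineage in enumerate(lineages):
        for r in range(n_replicates):
            rep = f"{lineage}_rep{r}"
            columns.append(rep)
            replicate_map[rep] = lineage
            data.append(
                archetypes.iloc[:, k].to_numpy() + rng.normal(0, noise_sd, n_genes)
            )
    expression = pd.DataFrame(
        np.column_stack(data), index=pd.Index(genes, name="gene"), columns=columns
    )
    meta = pd.DataFrame(
        {"group": ["none"] * n_lineages, "subtype": lineages},
        index=pd.Index(lineages, name="lineage"),
    )
    panel = ReferencePanel(expression=expression, replicate_map=replicate_map,
                           lineage_meta=meta)
    truth = SimulationTruth(
        marker_assignment=assignment, effect=effect, noise_sd=noise_sd,
        baseline=baseline, archetypes=archetypes, seed=seed,
    )
    return panel, truth


def generate_tumours(
    truth: SimulationTruth,
    n_samples: int = 200,
    tumour_intrinsic_sd: float = 0.3,
    dirichlet_alpha: float = DEFAULT_DIRICHLET_ALPHA,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate bulk tumour profiles as noisy mixtures of lineage archetypes.

    Mixing fractions are Dirichlet(alpha * 1) rows; mixing is done on the
    intensity scale (2**log2) and the composite logged, then
    N(0, tumour_intrinsic_sd) gene noise is added. The mixing matrix is
    stored in the returned truth.
    """
    if truth.archetypes is None:
        raise ValueError("truth lacks archetypes; run generate_reference first")
    rng = np.random.default_rng(seed)
    lineages = list(truth.archetypes.columns)
    genes = truth.archetypes.index
    fractions = rng.dirichlet([dirichlet_alpha] * len(lineages), size=n_samples)
    intensities = np.power(2.0, truth.archetypes.to_numpy())  # genes x lineages
    bulk = intensities @ fractions.T  # genes x samples
    log_bulk = np.log2(bulk) + rng.normal(0, tumour_intrinsic_sd, bulk.shape)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    expr = pd.DataFrame(log_bulk, index=genes, columns=samples)
    truth.mixing = pd.DataFrame(
        fractions, index=pd.Index(samples, name="sample"),
        columns=pd.Index(lineages, name="lineage"),
    )
    return expr, truth


def generate_survival(
    truth: SimulationTruth,
    activities: pd.DataFrame | None = None,
    baseline_hazard: float = 0.05,
    censor_rate: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate survival outcomes driven by lineage activities.

    Event times are exponential with hazard
    ``baseline_hazard * exp(sum_k beta_k * z(activity_k))`` where
    activities default to the true mixing fractions, standardized across
    samples so betas are per-sd effects. Censoring is an independent
    exponential clock with rate ``censor_rate``.
    """
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must lie in [0, 1)")
    if not truth.betas:
        raise ValueError("truth.betas is empty; set lineage effects first")
    if activities is None:
        if truth.mixing is None:
            raise ValueError("no activities given and truth has no mixing matrix")
        activities = truth.mixing
    rng = np.random.default_rng(seed)
    z = (activities - activities.mean()) / activities.std(ddof=0)
    lp = np.zeros(len(activities))
    for lineage, beta in truth.betas.items():
        if lineage not in z.columns:
            raise ValueError(f"beta refers to unknown lineage {lineage!r}")
        lp = lp + beta * z[lineage].to_numpy()
    hazard = baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, size=len(hazard))
    else:
        censor_time = np.full(len(hazard), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame(
        {"time": time, "event": event},
        index=pd.Index(activities.index, name="sample_id"),
    )


#: Named presets: moderate problem sizes with full signal, used by the
#: examples and the end-to-end recovery checks.
PRESETS = {
    "recovery-small": dict(
        n_lineages=10, n_genes=5000, markers_per_lineage=50, effect=3.0,
        n_replicates=3, noise_sd=0.3, n_samples=200,
        tumour_intrinsic_sd=0.3, n_perm=200,
    ),
    "tiny": dict(
        n_lineages=4, n_genes=400, markers_per_lineage=20, effect=3.0,
        n_replicates=3, noise_sd=0.3, n_samples=40,
        tumour_intrinsic_sd=0.3, n_perm=50,
    ),
}


def generate_preset(name: str, seed: int = 0):
    """Generate (panel, tumours, clinical, truth) for a named preset.

    Survival betas are +0.8 on the first lineage (deleterious) and -0.8
    on the second (protective), zero elsewhere.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    p = PRESETS[name]
    panel, truth = generate_reference(
        n_lineages=p["n_lineages"], n_genes=p["n_genes"],
        markers_per_lineage=p["markers_per_lineage"], effect=p["effect"],
        n_replicates=p["n_replicates"], noise_sd=p["noise_sd"], seed=seed,
    )
    tumours, truth = generate_tumours(
        truth, n_samples=p["n_samples"],
        tumour_intrinsic_sd=p["tumour_intrinsic_sd"], seed=seed + 1,
    )
    lineages = list(truth.mixing.columns)
    truth.betas = {lineages[0]: 0.8, lineages[1]: -0.8}
    clinical = generate_survival(truth, seed=seed + 2)
    return panel, tumours, clinical, truth
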