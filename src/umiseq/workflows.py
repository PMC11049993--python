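"""End-to-end study workflows assembled from the pipeline stages.

These mirror the cohort-level analyses: threshold training on a synthetic
training bundle followed by held-out specificity measurement, and the
low-AF mutation-level discrimination benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import (
    MutationPool,
    TrainingResult,
    in_silico_negatives,
    prepare_scans,
    train_threshold,
)
from .error_model import build_error_model
from .scoring import umiseq_score
from .synthetic import (
    simulate_background,
    simulate_catalog,
    simulate_panel,
    simulate_plasma,
    simulate_pon,
)
from .model import SyntheticCohortSpec


@dataclass
class SpecificityStudy:
    alpha: float
    training: TrainingResult
    heldout_specificity: float  # fraction of held-out negatives called negative
    n_heldout: int
    positive_scores: np.ndarray
    heldout_scores: np.ndarray


def specificity_study(
    seed: int,
    panel_size: int = 3_000,
    n_pon: int = 46,
    n_patients: int = 126,
    n_train_controls: int = 37,
    n_val_controls: int = 24,
    n_heldout: int = 2_500,
    depth: float = 9_086.0,
    caf_range: tuple[float, float] = (1e-4, 1e-2),
    K: int = 10_000,
    n_sims: int = 25,
    target_fpr: float = 0.05,
) -> SpecificityStudy:
    """Train the threshold on one synthetic bundle, validate on another.

    Simulates a PON, patient plasma samples at log-uniform cAFs and healthy
    training controls; runs the Monte-Carlo threshold training; then applies
    the trained threshold to fresh in-silico negatives built on independent
    healthy controls and reports the held-out specificity.
    """
    rng = np.random.default_rng(seed)
    panel = simulate_panel(panel_size, rng)
    pon, truth = simulate_pon(panel, rng, n_samples=n_pon, depth_median=depth)
    model = build_error_model(pon, panel)

    size_dist = SyntheticCohortSpec(seed=0).catalog_size_dist
    catalogs, pos_scores = [], []
    lo, hi = caf_range
    for i in range(n_patients):
        catalog = simulate_catalog(
            panel, rng, size_dist=size_dist, patient_id=f"patient{i:03d}"
        )
        caf = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        plasma = simulate_plasma(catalog, caf, depth, truth, panel, rng)
        pos_scores.append(umiseq_score(plasma, catalog, model, rng, K=K).S)
        catalogs.append(catalog)
    pos_scores = np.asarray(pos_scores)

    pool = MutationPool.from_catalogs(catalogs)
    sizes = [len(c) for c in catalogs]
    emp_size_dist = {s: sizes.count(s) / len(sizes) for s in sorted(set(sizes))}

    train_controls = [
        simulate_background(panel, truth, depth, rng) for _ in range(n_train_controls)
    ]
    training = train_threshold(
        pos_scores,
        prepare_scans(train_controls, model),
        pool,
        emp_size_dist,
        rng,
        n_sims=n_sims,
        target_fpr=target_fpr,
        K=K,
    )

    val_controls = [
        simulate_background(panel, truth, depth, rng) for _ in range(n_val_controls)
    ]
    heldout = in_silico_negatives(
        prepare_scans(val_controls, model), pool, emp_size_dist, n_heldout, rng, K=K
    )
    return SpecificityStudy(
        alpha=training.alpha,
        training=training,
        heldout_specificity=float((heldout <= training.alpha).mean()),
        n_heldout=n_heldout,
        positive_scores=pos_scores,
        heldout_scores=heldout,
    )
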