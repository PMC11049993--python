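"""Monte-Carlo training of the call threshold and specificity validation.

The threshold alpha is trained at a fixed false-positive rate: in each of 25
Monte-Carlo simulations, rank scores of real (or simulated) patient samples
serve as positive labels, while negative labels come from in-silico
catalogs — mutation sets drawn from the pooled cohort catalog with
frequency weights and evaluated on healthy-control counts.  The per-
simulation threshold is the negative-score order statistic whose held-out
specificity has expectation (1 - FPR) exactly (rank k = ceil((n+1)(1-FPR)),
an exchangeability argument that needs no distributional assumption), and
alpha is the mean over simulations.  An independent healthy cohort then
validates that the specificity at alpha transfers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .model import DEFAULT_K, CountTable, MutationCatalog, MutationRecord
from .error_model import ErrorModel
from .scoring import PanelScan, integrated_score, random_catalogs, rank_score

#: threshold trained on the original patient cohort; kept as a reference
#: constant — it is a property of that cohort's data and is not
#: recomputable from synthetic inputs.
REFERENCE_ALPHA = 0.9797


def sample_catalog_size(
    size_dist: dict[int, float], rng: np.random.Generator
) -> int:
    """Draw a catalog size from an empirical size distribution."""
    if not size_dist:
        raise ValueError("empty size distribution")
    sizes = np.array(sorted(size_dist))
    probs = np.array([size_dist[s] for s in sizes], dtype=float)
    probs = probs / probs.sum()
    return int(rng.choice(sizes, p=probs))


@dataclass
class MutationPool:
    """Pooled cohort catalog with per-mutation relative frequencies."""

    mutations: list[MutationRecord]
    weights: np.ndarray

    @classmethod
    def from_catalogs(cls, catalogs: list[MutationCatalog]) -> "MutationPool":
        seen: dict[tuple[str, int, str], tuple[MutationRecord, int]] = {}
        for cat in catalogs:
            for m in cat:
                rec, c = seen.get(m.key, (m, 0))
                seen[m.key] = (rec, c + 1)
        muts = [rec for rec, _ in seen.values()]
        counts = np.array([c for _, c in seen.values()], dtype=float)
        return cls(mutations=muts, weights=counts / counts.sum())

    def __len__(self) -> int:
        return len(self.mutations)

    def draw(self, n: int, rng: np.random.Generator) -> MutationCatalog:
        """n mutations without replacement, frequency-weighted."""
        if n > len(self.mutations):
            raise ValueError(
                f"requested {n} mutations from a pool of {len(self.mutations)}"
            )
        idx = rng.choice(
            len(self.mutations), size=n, replace=False, p=self.weights
        )
        return MutationCatalog(
            patient_id="insilico",
            mutations=[self.mutations[i] for i in idx],
        )


def prepare_scans(
    samples: list[CountTable], error_model: ErrorModel
) -> list[PanelScan]:
    """Panel-wide Bayes-factor scans, one per healthy sample (the expensive
    step; reuse them across all in-silico draws on the same sample)."""
    return [PanelScan(t, error_model) for t in samples]


def in_silico_negatives(
    scans: list[PanelScan],
    pool: MutationPool,
    size_dist: dict[int, float],
    n_draws: int,
    rng: np.random.Generator,
    K: int = DEFAULT_K,
) -> np.ndarray:
    """Rank scores of in-silico catalogs on randomly chosen healthy samples.

    Each draw pairs a healthy control (uniformly) with a frequency-weighted
    catalog whose size follows the cohort size distribution, and computes S.
    """
    out = np.empty(n_draws)
    for i in range(n_draws):
        scan = scans[int(rng.integers(len(scans)))]
        n = sample_catalog_size(size_dist, rng)
        catalog = pool.draw(n, rng)
        s = integrated_score(scan.catalog_log_m(catalog))
        idx = random_catalogs(scan.pool_size, len(catalog), K, rng)
        _, S = rank_score(s, scan.log_m[idx].sum(axis=1), K)
        out[i] = S
    return out


def fpr_threshold(neg_scores: np.ndarray, target_fpr: float) -> float:
    """Score threshold at a target false-positive rate.

    Returns the k-th smallest negative score with k = ceil((n+1)(1-fpr)),
    capped at n.  A fresh negative exceeds this order statistic with
    probability <= fpr in expectation (equality at k = (n+1)(1-fpr)), making
    the held-out specificity unbiased at 1 - fpr.
    """
    neg = np.sort(np.asarray(neg_scores, dtype=float))
    n = len(neg)
    if n == 0:
        raise ValueError("no negative scores")
    k = min(math.ceil((n + 1) * (1.0 - target_fpr)), n)
    return float(neg[k - 1])


def roc_stats(scores: np.ndarray, labels: np.ndarray) -> dict:
    """ROC AUC and curve points (midrank tie handling, trapezoid area)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_stats needs both classes present")
    fpr, tpr, thr = roc_curve(labels, scores)
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "fpr": fpr,
        "tpr": tpr,
        "thresholds": thr,
    }


@dataclass
class TrainingResult:
    alpha: float
    per_sim_threshold: np.ndarray
    per_sim_auc: np.ndarray
    per_sim_specificity: np.ndarray  # training negatives <= alpha, per sim
    negative_scores: list[np.ndarray]
    positive_scores: list[np.ndarray]


def train_threshold(
    positive_scores: np.ndarray,
    healthy_scans: list[PanelScan],
    pool: MutationPool,
    size_dist: dict[int, float],
    rng: np.random.Generator,
    n_sims: int = 25,
    n_pos: int = 100,
    n_neg: int = 100,
    target_fpr: float = 0.05,
    K: int = DEFAULT_K,
) -> TrainingResult:
    """Monte-Carlo threshold training at a fixed FPR.

    Per simulation: ``n_pos`` patient scores (sampled without replacement,
    or with replacement and a warning when fewer are available) and
    ``n_neg`` in-silico negatives; the per-simulation threshold is the FPR
    quantile of the negatives and alpha is the mean across simulations.
    """
    positive_scores = np.asarray(positive_scores, dtype=float)
    if len(healthy_scans) == 0:
        raise ValueError("need >= 1 healthy sample")
    replace = len(positive_scores) < n_pos
    if replace:
        import warnings

        warnings.warn(
            f"only {len(positive_scores)} positives for n_pos={n_pos}; "
            "sampling with replacement",
            stacklevel=2,
        )
    thresholds = np.empty(n_sims)
    aucs = np.empty(n_sims)
    negs, poss = [], []
    for k in range(n_sims):
        pos = rng.choice(positive_scores, size=n_pos, replace=replace)
        neg = in_silico_negatives(
            healthy_scans, pool, size_dist, n_neg, rng, K=K
        )
        thresholds[k] = fpr_threshold(neg, target_fpr)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
        aucs[k] = roc_stats(scores, labels)["auc"]
        negs.append(neg)
        poss.append(pos)
    alpha = float(thresholds.mean())
    per_sim_spec = np.array([(n <= alpha).mean() for n in negs])
    return TrainingResult(
        alpha=alpha,
        per_sim_threshold=thresholds,
        per_sim_auc=aucs,
        per_sim_specificity=per_sim_spec,
        negative_scores=negs,
        positive_scores=poss,
    )


@dataclass
class SpecificityValidation:
    mean_specificity: float
    per_rep_specificity: np.ndarray
    t_statistic: float
    p_value: float


def validate_specificity(
    validation_scans: list[PanelScan],
    pool: MutationPool,
    size_dist: dict[int, float],
    alpha: float,
    training_specificities: np.ndarray,
    rng: np.random.Generator,
    n_reps: int = 25,
    n_per_rep: int = 100,
    K: int = DEFAULT_K,
) -> SpecificityValidation:
    """Specificity of the fixed threshold on independent healthy controls.

    Per repetition, ``n_per_rep`` in-silico negative scores are generated on
    the validation controls; specificity is the fraction called negative
    (S <= alpha).  A Welch t-test compares the repetition means against the
    per-simulation training specificities.
    """
    spec = np.empty(n_reps)
    for k in range(n_reps):
        S = in_silico_negatives(
            validation_scans, pool, size_dist, n_per_rep, rng, K=K
        )
        spec[k] = (S <= alpha).mean()
    t, p = stats.ttest_ind(
        spec, np.asarray(training_specificities), equal_var=False
    )
    return SpecificityValidation(
        mean_specificity=float(spec.mean()),
        per_rep_specificity=spec,
        t_statistic=float(t),
        p_value=float(p),
    )
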