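"""The statistical core of the caller.

Per mutation, a Bayes factor ``m`` contrasts pure sequencing noise (at the
panel-of-normals rate) against noise plus a variant fraction shared by both
strands.  The product of Bayes factors over a patient's catalog gives the
integrated score ``s`` (a sum in log space).  Because a sample's noise
structure can deviate from the PON, ``s`` is not thresholded directly:
instead it is ranked against K scores of random same-size catalogs drawn
from the panel and evaluated on the *same* sample's counts, giving the
empirical rank score

    S = 1 - (r + 1) / (K + 1),

where r counts random scores strictly greater than s.  S near 1 means the
tumor catalog stands out from the panel background; the sample is called
ctDNA-positive when S exceeds a trained threshold alpha.
"""

from __future__ import annotations

import numpy as np

from ._betabinom import (
    GRID_SIZE,
    SCAN_GRID_SIZE,
    log_bayes_factor,
    log_bayes_factor_rows,
)
from .model import (
    DEFAULT_K,
    CountTable,
    CountVector,
    MutationCatalog,
    MutationRecord,
    SampleScore,
    UncallablePatientError,
)
from .error_model import ErrorModel


def mutation_score(
    counts: CountVector,
    mu_fwd: float,
    mu_rev: float,
    rho: float,
    grid_size: int = GRID_SIZE,
    model: str = "and",
) -> float:
    """Log Bayes factor m for one mutation; larger = more variant evidence."""
    return log_bayes_factor(
        counts.alt_fwd,
        counts.alt_rev,
        counts.depth_fwd,
        counts.depth_rev,
        mu_fwd,
        mu_rev,
        rho,
        grid_size=grid_size,
        model=model,
    )


def catalog_log_m(
    sample: CountTable,
    catalog: MutationCatalog,
    error_model: ErrorModel,
    grid_size: int = GRID_SIZE,
) -> np.ndarray:
    """Per-mutation log m over the retained (non-flagged) catalog."""
    out = []
    for record in catalog.retained():
        mu_f, mu_r, rho = error_model.params_for(record)
        out.append(
            mutation_score(
                sample.mutation_counts(record), mu_f, mu_r, rho, grid_size=grid_size
            )
        )
    return np.asarray(out)


def integrated_score(log_m: np.ndarray) -> float:
    """log s = sum of per-mutation log Bayes factors (product in real space)."""
    log_m = np.asarray(log_m, dtype=float)
    if log_m.size == 0:
        raise UncallablePatientError("empty retained catalog")
    return float(log_m.sum())


class PanelScan:
    """Precomputed log m for every modelable panel substitution of one sample.

    Computing the scan once per sample makes the K random catalogs cheap:
    each is just a sum of precomputed terms.  ``pool`` holds the flat
    (position, substitution) pairs eligible for random catalogs.
    """

    def __init__(
        self,
        sample: CountTable,
        error_model: ErrorModel,
        grid_size: int = SCAN_GRID_SIZE,
    ) -> None:
        panel = error_model.panel
        L = panel.size
        modelable = error_model.modelable
        pos_idx, col_idx = np.meshgrid(
            np.flatnonzero(modelable), np.arange(3), indexing="ij"
        )
        pos_idx = pos_idx.ravel()
        col_idx = col_idx.ravel()
        self.log_m = log_bayes_factor_rows(
            sample.alt_fwd[pos_idx, col_idx],
            sample.alt_rev[pos_idx, col_idx],
            sample.depth_fwd[pos_idx],
            sample.depth_rev[pos_idx],
            error_model.mu_fwd[pos_idx, col_idx],
            error_model.mu_rev[pos_idx, col_idx],
            error_model.rho[pos_idx, col_idx],
            grid_size=grid_size,
        )
        self.pos_idx = pos_idx
        self.col_idx = col_idx
        self.sample = sample
        self.error_model = error_model
        self.grid_size = grid_size
        self._lookup = {
            (int(p), int(c)): i for i, (p, c) in enumerate(zip(pos_idx, col_idx))
        }

    @property
    def pool_size(self) -> int:
        return len(self.log_m)

    def catalog_log_m(self, catalog: MutationCatalog) -> np.ndarray:
        """Per-mutation log m for the retained catalog, reusing the scan for
        SNVs and falling back to the scalar path for other classes."""
        panel = self.error_model.panel
        out = []
        for record in catalog.retained():
            if record.variant_class == "SNV" and record.key not in self.sample.extra:
                i = panel.locus_index(record.chrom, record.pos)
                col = panel.allele_column(i, record)
                hit = self._lookup.get((i, col))
                if hit is not None:
                    out.append(self.log_m[hit])
                    continue
            mu_f, mu_r, rho = self.error_model.params_for(record)
            out.append(
                mutation_score(
                    self.sample.mutation_counts(record),
                    mu_f,
                    mu_r,
                    rho,
                    grid_size=self.grid_size,
                )
            )
        return np.asarray(out)


def random_catalogs(
    pool_size: int, n: int, K: int, rng: np.random.Generator
) -> np.ndarray:
    """K random catalogs of size n: uniform without replacement over the pool.

    Returns an integer array of shape (K, n).  For pools much larger than n
    the rows are drawn iid and the (rare) rows containing duplicates are
    redrawn exactly; small pools fall back to per-row permutation sampling.
    """
    if n < 1:
        raise ValueError("catalog size must be >= 1")
    if n > pool_size:
        raise ValueError(f"catalog size {n} exceeds pool size {pool_size}")
    if n == pool_size:
        return np.tile(np.arange(pool_size), (K, 1))
    if pool_size < 4 * n:
        return np.stack([rng.permutation(pool_size)[:n] for _ in range(K)])
    idx = rng.integers(0, pool_size, size=(K, n))
    if n > 1:
        srt = np.sort(idx, axis=1)
        bad = np.flatnonzero((srt[:, 1:] == srt[:, :-1]).any(axis=1))
        for row in bad:
            idx[row] = rng.choice(pool_size, size=n, replace=False)
    return idx


def rank_score(observed_s: float, random_s: np.ndarray, K: int) -> tuple[int, float]:
    """(r, S) from the observed integrated score and K random scores.

    Ties count as not larger (strict inequality), keeping S conservative.
    """
    r = int((random_s > observed_s).sum())
    return r, 1.0 - (r + 1) / (K + 1)


def compute_caf(sample: CountTable, catalog: MutationCatalog) -> float:
    """Circulating allele frequency over the retained catalog.

    Sum of variant-supporting reads divided by the summed depth across the
    mutated loci.
    """
    retained = catalog.retained()
    if not retained:
        raise UncallablePatientError("empty retained catalog")
    vecs = [sample.mutation_counts(m) for m in retained]
    total_depth = sum(v.depth for v in vecs)
    if total_depth <= 0:
        raise ValueError("zero total depth across catalog loci")
    return sum(v.alt for v in vecs) / total_depth


def umiseq_score(
    sample: CountTable,
    catalog: MutationCatalog,
    error_model: ErrorModel,
    rng: np.random.Generator,
    K: int = DEFAULT_K,
    alpha: float = 0.9797,
    scan: PanelScan | None = None,
) -> SampleScore:
    """Score one plasma sample against its tumor catalog.

    ``scan`` may carry a precomputed :class:`PanelScan` for this sample
    (reused when many catalogs are evaluated on the same counts, e.g. during
    threshold training); otherwise it is computed here.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if scan is None:
        scan = PanelScan(sample, error_model)
    log_m = scan.catalog_log_m(catalog)
    s = integrated_score(log_m)
    n = len(log_m)
    idx = random_catalogs(scan.pool_size, n, K, rng)
    random_s = scan.log_m[idx].sum(axis=1)
    r, _ = rank_score(s, random_s, K)
    return SampleScore(
        m_scores=log_m,
        s=s,
        r=r,
        K=K,
        alpha=alpha,
        caf=compute_caf(sample, catalog),
    )


def call_sample(S: float, alpha: float) -> bool:
    """ctDNA-positive iff S strictly exceeds alpha."""
    if not 0 <= alpha < 1:
        raise ValueError("alpha must lie in [0, 1)")
    return S > alpha
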