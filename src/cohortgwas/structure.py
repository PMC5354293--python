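"""LD pruning and principal-component analysis for structure covariates.

PCA follows the EIGENSTRAT convention: genotypes are mean-centred per
marker and scaled by sqrt(2 p (1 - p)) with p the observed alt-allele
frequency; missing calls are imputed to the marker mean before scaling.
One member of each flagged related pair is excluded from the
decomposition and projected back onto the computed axes afterwards, so
every sample still receives covariate values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.utils.extmath import randomized_svd

from .gio import CohortDataset


@dataclass
class PCAResult:
    """Scores for the top K components plus bookkeeping.

    ``scores`` has one row per sample of the input dataset (projected
    relatives included); ``eigenvalues`` are non-increasing variances along
    each axis; ``excluded`` lists samples left out of the decomposition.
    """

    scores: pd.DataFrame                 # sample_id, PC1..PCK
    eigenvalues: np.ndarray
    excluded: list = field(default_factory=list)
    outlier_flags: pd.Series | None = None

    @property
    def k(self) -> int:
        return self.eigenvalues.size

    def score_matrix(self) -> np.ndarray:
        return self.scores[[f"PC{i + 1}" for i in range(self.k)]].to_numpy()


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def ld_prune(dataset: CohortDataset, r2_max: float = 0.2,
             window_size: int = 50, step: int = 5) -> np.ndarray:
    """Greedy windowed LD pruning; returns retained marker column indices.

    Within each window of ``window_size`` markers (advanced by ``step``),
    any pair of retained markers with squared genotype correlation above
    ``r2_max`` loses its higher-index member.  Deterministic by
    construction.  Missing calls are mean-imputed for the correlation.
    """
    if not (0.0 < r2_max < 1.0):
        raise ValueError("r2_max must lie in (0, 1)")
    if window_size < 2 or step < 1:
        raise ValueError("window_size >= 2 and step >= 1 required")
    m = dataset.n_markers
    x = _standardized(dataset, np.arange(m))
    keep = np.ones(m, dtype=bool)
    for start in range(0, max(m - 1, 1), step):
        idx = np.arange(start, min(start + window_size, m))
        idx = idx[keep[idx]]
        if idx.size < 2:
            continue
        sub = x[:, idx]
        norms = np.linalg.norm(sub, axis=0)
        norms[norms == 0] = 1.0
        r = (sub.T @ sub) / np.outer(norms, norms)
        r2 = r**2
        for a in range(idx.size):
            if not keep[idx[a]]:
                continue
            over = r2[a, a + 1:] > r2_max
            keep[idx[a + 1:][over]] = False
        if start + window_size >= m:
            break
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def _standardized(dataset: CohortDataset, cols: np.ndarray) -> np.ndarray:
    """EIGENSTRAT-standardized genotype block (samples x markers)."""
    g = dataset.genotypes[:, cols].astype(np.float32)
    miss = dataset.missing_mask()[:, cols]
    g[miss] = np.nan
    mean = np.nanmean(g, axis=0)
    p = mean / 2.0
    scale = np.sqrt(np.maximum(2.0 * p * (1.0 - p), 1e-12)).astype(np.float32)
    g = np.where(np.isnan(g), mean, g)
    return (g - mean) / scale


def pca(dataset: CohortDataset, pruned_markers: np.ndarray,
        related_exclusions: list | None = None, k: int = 10,
        random_state: int = 0) -> PCAResult:
    """EIGENSTRAT-style PCA on pruned markers.

    ``related_exclusions`` are sample ids (one member per related pair)
    left out of the eigen-decomposition and projected onto the axes
    afterwards.  ``k`` components are computed (default 10; the top 4 are
    the association covariates downstream).
    """
    excl = set(related_exclusions or [])
    ids = dataset.sample_ids
    core = np.array([i for i, s in enumerate(ids) if s not in excl])
    if core.size < k + 1:
        raise ValueError("need at least k + 1 samples after exclusions")
    x = _standardized(dataset, np.asarray(pruned_markers))
    xc = x[core]
    col_mean = xc.mean(axis=0)
    xc = xc - col_mean
    if not np.any(np.abs(xc) > 1e-8):
        raise ValueError("degenerate (zero-variance) genotype input")
    if xc.size <= 5_000_000:
        # exact decomposition: cheap at this size and permutation-stable
        u, s, vt = np.linalg.svd(xc.astype(np.float64), full_matrices=False)
        u, s, vt = u[:, :k], s[:k], vt[:k]
    else:
        u, s, vt = randomized_svd(xc, n_components=k, n_iter=7,
                                  random_state=random_state)
    # deterministic sign: largest-|loading| coordinate positive
    for c in range(k):
        jmax = np.argmax(np.abs(vt[c]))
        if vt[c, jmax] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0
    eigenvalues = (s**2) / max(core.size - 1, 1)
    scores = np.empty((len(ids), k), dtype=np.float64)
    scores[core] = u * s
    rest = np.array([i for i in range(len(ids)) if ids[i] in excl], dtype=int)
    if rest.size:
        scores[rest] = (x[rest] - col_mean) @ vt.T
    frame = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(k)])
    frame.insert(0, "sample_id", ids)
    return PCAResult(scores=frame, eigenvalues=eigenvalues,
                     excluded=sorted(excl))


def detect_outliers(result: PCAResult, sd_multiple: float = 6.0,
                    top_k: int = 4) -> pd.Series:
    """Flag samples more than ``sd_multiple`` SDs from the mean on any of
    the top ``top_k`` components (automated stand-in for a manual check).
    """
    if sd_multiple <= 0:
        raise ValueError("sd_multiple must be > 0")
    mat = result.score_matrix()[:, :top_k]
    sd = mat.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    dev = np.abs(mat - mat.mean(axis=0)) / sd
    flags = pd.Series((dev > sd_multiple).any(axis=1),
                      index=result.scores["sample_id"], name="outlier")
    result.outlier_flags = flags
    return flags
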