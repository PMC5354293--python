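"""Pairwise IBD estimation, relationship classification and duplicate removal.

The estimator is a PLINK-style method of moments on identity-by-state (IBS)
counts.  For a pair of individuals, count the markers on which they share
0, 1 or 2 alleles IBS and compare with the allele-frequency-dependent
expectations under each latent IBD state k (the probability the pair shares
k alleles identical by descent):

* IBS0 arises only under IBD0, so ``Z0 = N_IBS0 / E[IBS0 | IBD0]``;
* ``Z2`` solves the IBS2 moment equation after substituting
  ``Z1 = 1 - Z0 - Z2``;
* ``Z1 = 1 - Z0 - Z2`` exactly, by construction.

The individual Zk are **not clamped** to [0, 1]: the published duplicate
window (0.9 <= Z2 <= 1.1) only makes sense for a raw moment estimate that
can exceed 1.  Classification applies the printed closed windows verbatim,
in the order duplicate -> full sibling -> half sibling/avuncular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gio import MISSING, CohortDataset, RunConfig

MIN_JOINT_MARKERS = 100


@dataclass
class RelatednessEstimate:
    id_i: str
    id_j: str
    z0: float
    z1: float
    z2: float
    concordance: float
    n_markers_used: int


# ---------------------------------------------------------------------------
# expectations under each IBD state
# ---------------------------------------------------------------------------


def _ibs_expectations(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker P(IBS0 | IBD0), P(IBS2 | IBD0), P(IBS2 | IBD1).

    With alt frequency p (q = 1 - p), two independent genotypes give
    P(IBS0) = 2 p^2 q^2 and P(IBS2) = p^4 + q^4 + 4 p^2 q^2; a pair
    sharing one allele IBD gives P(IBS2) = p^2 + q^2 (the two free alleles
    coincide).  IBD2 pairs are always IBS2 (no genotyping error model).
    """
    p = np.asarray(freqs, dtype=np.float64)
    q = 1.0 - p
    e0_ibd0 = 2.0 * p**2 * q**2
    e2_ibd0 = p**4 + q**4 + 4.0 * p**2 * q**2
    e2_ibd1 = p**2 + q**2
    return e0_ibd0, e2_ibd0, e2_ibd1


def _zs_from_moments(n0: float, n2: float, m: float, e0: float,
                     e2_0: float, e2_1: float) -> tuple[float, float, float]:
    z0 = n0 / e0
    z2 = (n2 - z0 * e2_0 - (1.0 - z0) * e2_1) / (m - e2_1)
    z1 = 1.0 - z0 - z2
    return float(z0), float(z1), float(z2)


# ---------------------------------------------------------------------------
# per-pair operations
# ---------------------------------------------------------------------------


def estimate_ibd(genotypes_i: np.ndarray, genotypes_j: np.ndarray,
                 allele_freqs: np.ndarray, id_i: str = "i",
                 id_j: str = "j") -> RelatednessEstimate:
    """Method-of-moments (Z0, Z1, Z2) for one pair.

    Uses jointly non-missing markers only; requires at least
    ``MIN_JOINT_MARKERS`` of them and at least one polymorphic marker.
    ``allele_freqs`` are dataset-wide alt-allele frequency estimates.
    """
    gi = np.asarray(genotypes_i)
    gj = np.asarray(genotypes_j)
    p = np.asarray(allele_freqs, dtype=np.float64)
    ok = (gi != MISSING) & (gj != MISSING) & (p > 0.0) & (p < 1.0)
    m = int(ok.sum())
    if m < MIN_JOINT_MARKERS:
        raise ValueError(f"only {m} jointly non-missing markers (< {MIN_JOINT_MARKERS})")
    if not np.any((p[ok] > 0) & (p[ok] < 1)):
        raise ValueError("no polymorphic markers available")
    diff = np.abs(gi[ok].astype(np.int16) - gj[ok].astype(np.int16))
    n0 = int(np.sum(diff == 2))
    n2 = int(np.sum(diff == 0))
    e0v, e2_0v, e2_1v = _ibs_expectations(p[ok])
    z0, z1, z2 = _zs_from_moments(n0, n2, m, e0v.sum(), e2_0v.sum(), e2_1v.sum())
    return RelatednessEstimate(id_i, id_j, z0, z1, z2,
                               concordance=n2 / m, n_markers_used=m)


def concordance(genotypes_i: np.ndarray, genotypes_j: np.ndarray) -> float:
    """Fraction of identical calls over jointly non-missing markers."""
    gi = np.asarray(genotypes_i)
    gj = np.asarray(genotypes_j)
    ok = (gi != MISSING) & (gj != MISSING)
    m = int(ok.sum())
    if m == 0:
        raise ValueError("no jointly non-missing markers")
    return float(np.mean(gi[ok] == gj[ok]))


def classify_pair(z0: float, z1: float, z2: float,
                  config: RunConfig | None = None) -> str:
    """Apply the published Z windows, in order.

    duplicate:            0 <= Z0 <= 0.1, 0 <= Z1 <= 0.1, 0.9 <= Z2 <= 1.1
    full_sibling:         0.17 <= Z0 <= 0.33, 0.4 <= Z1 <= 0.6, 0.17 <= Z2 <= 0.33
    half_sib_or_avuncular: 0.4 <= Z1 <= 0.6, 0 <= Z2 <= 0.1
    otherwise Z0 >= 0.85 -> unrelated, else unclassified.
    """
    cfg = config or RunConfig()
    for v in (z0, z1, z2):
        if not np.isfinite(v):
            raise ValueError("Z values must be finite")

    def within(v, lohi):
        return lohi[0] <= v <= lohi[1]

    if within(z0, cfg.dup_z0) and within(z1, cfg.dup_z1) and within(z2, cfg.dup_z2):
        return "duplicate"
    if within(z0, cfg.sib_z0) and within(z1, cfg.sib_z1) and within(z2, cfg.sib_z2):
        return "full_sibling"
    if within(z1, cfg.half_z1) and within(z2, cfg.half_z2):
        return "half_sib_or_avuncular"
    return "unrelated" if z0 >= 0.85 else "unclassified"


# ---------------------------------------------------------------------------
# genome-wide screening
# ---------------------------------------------------------------------------


def screen_pairs(dataset: CohortDataset, config: RunConfig | None = None,
                 exhaustive_max_samples: int = 2000,
                 prefilter_markers: int = 512,
                 prefilter_concordance: float = 0.95,
                 seed: int = 0) -> pd.DataFrame:
    """Screen all sample pairs; return a table of non-unrelated pairs.

    For modest cohorts (n <= ``exhaustive_max_samples``) IBS counts for all
    pairs are computed exactly with blocked one-hot matrix products, and
    every pair is classified.  For larger cohorts an O(n^2) screen over all
    markers is not tractable on a single workstation, so a concordance
    pre-filter on ``prefilter_markers`` randomly sampled markers shortlists
    candidate duplicates (sampled concordance > ``prefilter_concordance``;
    a true concordance-0.99 pair fails this with probability < 1e-10), and
    the final Z estimates for shortlisted pairs always use all markers.

    Output columns: id_i, id_j, z0, z1, z2, concordance, n_markers, label,
    expected (same subject identifiers).
    """
    cfg = config or RunConfig()
    n = dataset.n_samples
    freqs = dataset.allele_freqs()
    poly = np.flatnonzero((freqs > 0) & (freqs < 1))
    ids = dataset.sample_ids
    subj = (dataset.samples["subject_id"].to_numpy()
            if "subject_id" in dataset.samples.columns else np.array(ids))

    if n <= exhaustive_max_samples:
        cand = _all_pairs_ibs(dataset, poly, freqs)
    else:
        cand = _prefiltered_pairs(dataset, poly, freqs, prefilter_markers,
                                  prefilter_concordance, seed)

    rows = []
    for i, j, z0, z1, z2, conc, m in cand:
        label = classify_pair(z0, z1, z2, cfg)
        if label == "unrelated":
            continue
        rows.append({
            "id_i": ids[i], "id_j": ids[j], "z0": z0, "z1": z1, "z2": z2,
            "concordance": conc, "n_markers": m, "label": label,
            "expected": bool(subj[i] == subj[j]),
        })
    return pd.DataFrame(rows, columns=["id_i", "id_j", "z0", "z1", "z2",
                                       "concordance", "n_markers", "label",
                                       "expected"])


def _all_pairs_ibs(dataset: CohortDataset, poly: np.ndarray,
                   freqs: np.ndarray, block: int = 2048):
    """Exact IBS0/IBS2 counts and expectation sums for all pairs."""
    g = dataset.genotypes[:, poly]
    n, m = g.shape
    e0v, e2_0v, e2_1v = _ibs_expectations(freqs[poly])
    valid = (g != MISSING)
    n0 = np.zeros((n, n), dtype=np.float32)
    n2 = np.zeros((n, n), dtype=np.float32)
    mj = np.zeros((n, n), dtype=np.float32)
    e0 = np.zeros((n, n), dtype=np.float32)
    e2_0 = np.zeros((n, n), dtype=np.float32)
    e2_1 = np.zeros((n, n), dtype=np.float32)
    for start in range(0, m, block):
        sl = slice(start, min(start + block, m))
        gb = g[:, sl]
        vb = valid[:, sl].astype(np.float32)
        m0 = ((gb == 0) & (gb != MISSING)).astype(np.float32)
        m1 = (gb == 1).astype(np.float32)
        m2 = (gb == 2).astype(np.float32)
        n0 += m0 @ m2.T + m2 @ m0.T
        n2 += m0 @ m0.T + m1 @ m1.T + m2 @ m2.T
        mj += vb @ vb.T
        e0 += (vb * e0v[sl]) @ vb.T
        e2_0 += (vb * e2_0v[sl]) @ vb.T
        e2_1 += (vb * e2_1v[sl]) @ vb.T
    iu, ju = np.triu_indices(n, k=1)
    mij = mj[iu, ju].astype(np.float64)
    ok = mij >= MIN_JOINT_MARKERS
    n0v = n0[iu, ju].astype(np.float64)
    n2v = n2[iu, ju].astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        z0v = n0v / e0[iu, ju]
        z2v = (n2v - z0v * e2_0[iu, ju]
               - (1.0 - z0v) * e2_1[iu, ju]) / (mij - e2_1[iu, ju])
        z1v = 1.0 - z0v - z2v
        concv = n2v / mij
    # any pair with Z0 >= 0.85 is unrelated under every window (duplicates
    # need Z0 <= 0.1, sibs <= 0.33, half sibs imply Z0 <= 0.6), so only the
    # rest needs per-pair classification
    cand = ok & (z0v < 0.85)
    out = []
    for t in np.flatnonzero(cand):
        out.append((int(iu[t]), int(ju[t]), float(z0v[t]), float(z1v[t]),
                    float(z2v[t]), float(concv[t]), int(mij[t])))
    return out


def _prefiltered_pairs(dataset: CohortDataset, poly: np.ndarray,
                       freqs: np.ndarray, n_sub: int, conc_min: float,
                       seed: int):
    rng = np.random.default_rng(seed)
    sub = rng.choice(poly, size=min(n_sub, poly.size), replace=False)
    g = dataset.genotypes[:, sub]
    valid = (g != MISSING).astype(np.float32)
    match = np.zeros((g.shape[0],) * 2, dtype=np.float32)
    for v in (0, 1, 2):
        mv = (g == v).astype(np.float32)
        match += mv @ mv.T
    joint = valid @ valid.T
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = np.where(joint > 0, match / joint, 0.0)
    iu, ju = np.triu_indices(g.shape[0], k=1)
    hits = conc[iu, ju] > conc_min
    out = []
    for i, j in zip(iu[hits], ju[hits]):
        est = estimate_ibd(dataset.genotypes[i], dataset.genotypes[j], freqs,
                           id_i=str(i), id_j=str(j))
        out.append((int(i), int(j), est.z0, est.z1, est.z2,
                    est.concordance, est.n_markers_used))
    return out


# ---------------------------------------------------------------------------
# removal policy
# ---------------------------------------------------------------------------


def apply_removal_policy(pairs: pd.DataFrame, seed: int = 0,
                         concordance_cutoff: float = 0.999):
    """Published duplicate-removal policy.

    * expected duplicate (same subject identifiers): one member removed,
      chosen at random (seeded, reproducible);
    * unexpected duplicate with concordance > 0.999: both removed;
      duplicate-window pairs below the concordance cutoff are treated the
      same (conservative: an unexplained near-duplicate is dropped);
    * relatives (full siblings, half sibs/avunculars): retained, but
      recorded so PCA can exclude one member per pair.

    Returns ``(removal_ids, retained_relative_pairs)``.
    """
    rng = np.random.default_rng(seed)
    removals: list[str] = []
    relatives: list[tuple[str, str]] = []
    for _, row in pairs.iterrows():
        if row["label"] == "duplicate":
            if row["expected"]:
                pick = row["id_i"] if rng.random() < 0.5 else row["id_j"]
                removals.append(pick)
            else:
                removals.extend([row["id_i"], row["id_j"]])
        elif row["label"] in ("full_sibling", "half_sib_or_avuncular"):
            relatives.append((row["id_i"], row["id_j"]))
    # de-duplicate while preserving order
    seen = set()
    removals = [r for r in removals if not (r in seen or seen.add(r))]
    return removals, relatives
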