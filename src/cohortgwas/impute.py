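"""Windowed haplotype-copying imputation with dosage quality scores.

Each chromosome's marker list is tiled into overlapping chunks; within a
chunk the dataset is phased and each phased haplotype is imputed against
the reference panel with a haploid Li–Stephens hidden Markov model:

* hidden state = which panel haplotype is being copied;
* transition over an inter-marker gap of d bp: stay with probability
  ``exp(-rho_eff * d)`` plus a uniform switch mass
  ``(1 - exp(-rho_eff * d)) / H`` to every haplotype (the stay target
  included), with ``rho_eff = rho * 4N / H`` (rho = 4e-8 /bp, N = 1e4 by
  default — the standard population-scaled switch rate divided among the
  H panel haplotypes);
* emission: ``1 - eps`` on an allele match, ``eps`` on a mismatch
  (eps = 1e-3); sites missing from the target emit uniformly.

The forward-backward posterior over copied haplotypes gives a per-site
alt-allele posterior per target haplotype; an individual's dosage is the
sum of its two haplotype posteriors.  Quality is the MACH-style RSQR_HAT:
the ratio of the empirical dosage variance to the binomial variance
2 p (1 - p) expected if genotypes were observed, capped into [0, 1].
Genotyped markers pass through as hard calls with rsq = 1 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gio import MISSING, CohortDataset
from .simcohort import HaplotypePanel


@dataclass
class CopyingModel:
    """Li–Stephens parameters.

    ``rho`` is the per-bp, per-generation-scale switch intensity; the
    effective per-bp intensity against an H-haplotype panel is
    ``rho * four_ne / H``.  ``eps`` is the allele-mismatch (error)
    probability.
    """

    rho: float = 4e-8
    eps: float = 1e-3
    four_ne: float = 4e4

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if not (0.0 < self.eps < 0.5):
            raise ValueError("eps must lie in (0, 0.5)")

    def stay_probs(self, positions: np.ndarray, n_hap: int) -> np.ndarray:
        """Per-interval stay probability (length m-1)."""
        gaps = np.diff(np.asarray(positions, dtype=np.float64))
        rho_eff = self.rho * self.four_ne / max(n_hap, 1)
        return np.exp(-rho_eff * gaps)


@dataclass
class Chunk:
    chrom: str
    start: int          # half-open marker-index range including flanks
    stop: int
    core_start: int     # half-open core (ownership) range
    core_stop: int


@dataclass
class ImputedMarkers:
    """Analysis-ready imputation output for one dataset."""

    dosages: np.ndarray            # (n_samples, n_markers) float32 in [0, 2]
    info: pd.DataFrame             # marker_id, chrom, pos, ref, alt, freq, rsq, genotyped
    sample_ids: list

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def subset(self, index: np.ndarray) -> "ImputedMarkers":
        return ImputedMarkers(self.dosages[:, index].copy(),
                              self.info.iloc[index].reset_index(drop=True),
                              list(self.sample_ids))


# ---------------------------------------------------------------------------
# chunking
# ---------------------------------------------------------------------------


def chunk_genome(marker_table: pd.DataFrame, chunk_size: int,
                 overlap: int) -> list[Chunk]:
    """Tile each chromosome's markers into chunks with flanking overlap.

    Chunk *cores* partition the markers; each chunk extends ``overlap``
    markers into its neighbours on both sides.  Requires
    ``chunk_size > 2 * overlap``.
    """
    if chunk_size <= 2 * overlap or chunk_size < 1 or overlap < 0:
        raise ValueError("need chunk_size > 2 * overlap >= 0")
    chunks = []
    step = chunk_size - overlap
    for chrom in pd.unique(marker_table["chrom"]):
        idx = np.flatnonzero((marker_table["chrom"] == chrom).to_numpy())
        lo, hi = int(idx[0]), int(idx[-1]) + 1
        m = hi - lo
        if m <= chunk_size:
            chunks.append(Chunk(str(chrom), lo, hi, lo, hi))
            continue
        start = 0
        while start < m:
            stop = min(start + chunk_size, m)
            core_start = 0 if start == 0 else start + overlap // 2
            core_stop = m if stop == m else stop - (overlap - overlap // 2)
            chunks.append(Chunk(str(chrom), lo + start, lo + stop,
                                lo + core_start, lo + core_stop))
            if stop == m:
                break
            start += step
    return chunks


def stitch_chunks(chunks: list[Chunk], outputs: list[np.ndarray],
                  n_markers: int) -> np.ndarray:
    """Assemble per-chunk (samples x chunk-markers) outputs genome-wide.

    Each marker's value is taken from the chunk owning it (the chunk whose
    core contains it); overlap flanks are discarded.  Order-independent.
    Raises if any marker is covered by no core.
    """
    if not outputs:
        raise ValueError("no chunk outputs")
    n = outputs[0].shape[0]
    out = np.full((n, n_markers), np.nan, dtype=np.float64)
    owned = np.zeros(n_markers, dtype=bool)
    for chunk, block in zip(chunks, outputs):
        sl = slice(chunk.core_start - chunk.start, chunk.core_stop - chunk.start)
        out[:, chunk.core_start:chunk.core_stop] = block[:, sl]
        owned[chunk.core_start:chunk.core_stop] = True
    if not owned.all():
        raise ValueError(f"{(~owned).sum()} markers covered by no chunk core")
    return out


# ---------------------------------------------------------------------------
# Li–Stephens forward-backward
# ---------------------------------------------------------------------------


def ls_forward_backward(target: np.ndarray, panel_haps: np.ndarray,
                        positions: np.ndarray,
                        model: CopyingModel | None = None):
    """Haploid Li–Stephens posterior decoding of one target haplotype.

    Parameters
    ----------
    target
        Length-m array over panel sites: 0/1 observed alleles, ``-1``
        (missing) at sites to impute.
    panel_haps
        (H, m) binary reference haplotypes.
    positions
        bp positions of the m sites (strictly increasing).

    Returns
    -------
    (copy_posteriors, alt_posteriors)
        ``copy_posteriors`` is (m, H), rows summing to 1;
        ``alt_posteriors`` is the per-site posterior alt-allele
        probability ``sum_h P(copy h) * allele_h``.
    """
    mdl = model or CopyingModel()
    hap = np.asarray(panel_haps, dtype=np.float64)
    if hap.size == 0:
        raise ValueError("empty reference panel")
    H, m = hap.shape
    t = np.asarray(target)
    stay = mdl.stay_probs(positions, H)

    def emission(j: int) -> np.ndarray:
        if t[j] == MISSING:
            return np.ones(H)
        match = hap[:, j] == t[j]
        return np.where(match, 1.0 - mdl.eps, mdl.eps)

    fwd = np.empty((m, H))
    scale = np.empty(m)
    f = emission(0) / H
    scale[0] = f.sum()
    fwd[0] = f / scale[0]
    for j in range(1, m):
        a = stay[j - 1]
        f = emission(j) * (a * fwd[j - 1] + (1.0 - a) / H)
        scale[j] = f.sum()
        fwd[j] = f / scale[j]
    bwd = np.empty((m, H))
    bwd[m - 1] = 1.0
    for j in range(m - 2, -1, -1):
        a = stay[j]
        eb = emission(j + 1) * bwd[j + 1]
        bwd[j] = (a * eb + (1.0 - a) * eb.mean()) / scale[j + 1]
    post = fwd * bwd
    post /= post.sum(axis=1, keepdims=True)
    alt = np.einsum("jh,hj->j", post, hap)
    return post, alt


def _ls_loo_alt(target: np.ndarray, panel_haps: np.ndarray,
                positions: np.ndarray, model: CopyingModel) -> np.ndarray:
    """Leave-one-out alt posteriors: at each site, the posterior excluding
    that site's own emission (prediction from flanking data only).

    Used by the phaser to re-assess a heterozygous site without the
    circularity of conditioning on its current assignment.
    """
    hap = np.asarray(panel_haps, dtype=np.float64)
    H, m = hap.shape
    t = np.asarray(target)
    stay = model.stay_probs(positions, H)
    eps = model.eps

    def emission(j: int) -> np.ndarray:
        if t[j] == MISSING:
            return np.ones(H)
        return np.where(hap[:, j] == t[j], 1.0 - eps, eps)

    pred = np.empty((m, H))     # forward prediction before seeing site j
    fwd = np.empty((m, H))
    scale = np.empty(m)
    pred[0] = 1.0 / H
    f = emission(0) * pred[0]
    scale[0] = f.sum()
    fwd[0] = f / scale[0]
    for j in range(1, m):
        a = stay[j - 1]
        pred[j] = a * fwd[j - 1] + (1.0 - a) / H
        f = emission(j) * pred[j]
        scale[j] = f.sum()
        fwd[j] = f / scale[j]
    bwd = np.empty((m, H))
    bwd[m - 1] = 1.0
    for j in range(m - 2, -1, -1):
        a = stay[j]
        eb = emission(j + 1) * bwd[j + 1]
        bwd[j] = (a * eb + (1.0 - a) * eb.mean()) / scale[j + 1]
    loo = pred * bwd
    loo /= loo.sum(axis=1, keepdims=True)
    return np.einsum("jh,hj->j", loo, hap)


def _ls_alt_posterior_batch(targets: np.ndarray, panel_haps: np.ndarray,
                            positions: np.ndarray,
                            model: CopyingModel) -> np.ndarray:
    """Vectorized alt posteriors for many target haplotypes at once.

    Same model as :func:`ls_forward_backward`, with the scaled recursions
    run across all targets simultaneously (targets x H matrices per site).
    """
    hap = np.asarray(panel_haps, dtype=np.float64)
    H, m = hap.shape
    T = targets.shape[0]
    stay = model.stay_probs(positions, H)
    eps = model.eps

    def emission(j: int) -> np.ndarray:
        e = np.ones((T, H))
        obs = targets[:, j] != MISSING
        if obs.any():
            match = targets[obs, j][:, None] == hap[None, :, j]
            e[obs] = np.where(match, 1.0 - eps, eps)
        return e

    fwd = np.empty((m, T, H))
    scale = np.empty((m, T))
    f = emission(0) / H
    scale[0] = f.sum(axis=1)
    fwd[0] = f / scale[0][:, None]
    for j in range(1, m):
        a = stay[j - 1]
        f = emission(j) * (a * fwd[j - 1] + (1.0 - a) / H)
        scale[j] = f.sum(axis=1)
        fwd[j] = f / scale[j][:, None]
    alt = np.empty((T, m))
    b = np.ones((T, H))
    post = fwd[m - 1] * b
    post /= post.sum(axis=1, keepdims=True)
    alt[:, m - 1] = post @ hap[:, m - 1]
    for j in range(m - 2, -1, -1):
        a = stay[j]
        eb = emission(j + 1) * b
        b = (a * eb + (1.0 - a) * eb.mean(axis=1, keepdims=True)) / scale[j + 1][:, None]
        post = fwd[j] * b
        post /= post.sum(axis=1, keepdims=True)
        alt[:, j] = post @ hap[:, j]
    return alt


# ---------------------------------------------------------------------------
# phasing
# ---------------------------------------------------------------------------


def phase_dataset(dataset: CohortDataset, panel: HaplotypePanel,
                  model: CopyingModel | None = None, mode: str = "statistical",
                  n_iter: int = 3, seed: int = 0,
                  site_index: np.ndarray | None = None) -> np.ndarray:
    """Phase a dataset's genotypes against the panel.

    Returns (n_samples, 2, m) haplotypes over the dataset's typed sites
    (``-1`` where the genotype is missing).  ``mode='oracle'`` passes the
    simulator's true phases through (testing aid, requires
    ``dataset.true_haplotypes``); ``mode='statistical'`` starts from a
    random phase and then, for ``n_iter`` sweeps, re-phases each
    individual's heterozygous sites one at a time to the maximum-posterior
    configuration implied by Li–Stephens alt posteriors of its two current
    haplotypes (each site treated as unobserved when assessed).

    The phase of each individual is canonicalized: the first heterozygous
    site carries its alt allele on haplotype 0.
    """
    mdl = model or CopyingModel()
    idx = (np.asarray(site_index) if site_index is not None
           else np.arange(dataset.n_markers))
    if mode == "oracle":
        haps = getattr(dataset, "true_haplotypes", None)
        if haps is None:
            raise ValueError("oracle mode requires simulator truth phases")
        panel_idx = dataset.panel_marker_index[idx]
        out = haps[:, :, panel_idx].astype(np.int8)
        miss = dataset.genotypes[:, idx] == MISSING
        out[np.repeat(miss[:, None, :], 2, axis=1)] = MISSING
        return _canonicalize_phase(out, dataset.genotypes[:, idx])
    if mode != "statistical":
        raise ValueError(f"unknown phasing mode {mode!r}")

    g = dataset.genotypes[:, idx]
    pos = dataset.markers["pos"].to_numpy()[idx]
    panel_cols = _match_panel_columns(dataset, panel, idx)
    ref = panel.haplotypes[:, panel_cols]
    n, m = g.shape
    het = g == 1
    miss = g == MISSING
    haps = _greedy_phase_init(g, ref, pos, mdl)
    for c in (0, 1):
        haps[:, c, :][miss] = MISSING

    for _ in range(n_iter):
        for i in range(n):
            het_sites = np.flatnonzero(het[i])
            if het_sites.size == 0:
                continue
            a0 = _ls_loo_alt(haps[i, 0], ref, pos, mdl)
            a1 = _ls_loo_alt(haps[i, 1], ref, pos, mdl)
            # maximum-posterior assignment per het site given the flanks:
            # alt on hap0 has likelihood a0 * (1 - a1); alt on hap1 the reverse
            alt_on_0 = a0[het_sites] * (1.0 - a1[het_sites]) >= \
                (1.0 - a0[het_sites]) * a1[het_sites]
            haps[i, 0, het_sites] = np.where(alt_on_0, 1, 0)
            haps[i, 1, het_sites] = np.where(alt_on_0, 0, 1)
    return _canonicalize_phase(haps, g)


def _greedy_phase_init(g: np.ndarray, ref: np.ndarray, pos: np.ndarray,
                       mdl: CopyingModel) -> np.ndarray:
    """Sequential forward decoding of phase for all individuals at once.

    Runs two coupled Li–Stephens forward passes (one per haplotype).  At a
    heterozygous site the alt allele is assigned to the haplotype whose
    one-step predictive distribution favours it; homozygous sites emit
    their fixed allele and missing sites emit uniformly.  Left-context
    only — the leave-one-out sweeps afterwards add right context.
    """
    H, m = ref.shape
    n = g.shape[0]
    stay = mdl.stay_probs(pos, H) if m > 1 else np.empty(0)
    eps = mdl.eps
    haps = np.empty((n, 2, m), dtype=np.int8)
    f = np.full((n, 2, H), 1.0 / H)
    for j in range(m):
        if j > 0:
            a = stay[j - 1]
            f = a * f + (1.0 - a) / H   # rows already sum to 1
        allele_alt = ref[:, j].astype(np.float64)        # (H,)
        p_alt = f @ allele_alt                            # (n, 2)
        gj = g[:, j]
        het = gj == 1
        hom = (gj == 0) | (gj == 2)
        # heterozygous: alt goes to the haplotype that predicts it better
        alt_on_0 = p_alt[:, 0] * (1 - p_alt[:, 1]) >= \
            (1 - p_alt[:, 0]) * p_alt[:, 1]
        col = np.zeros((n, 2), dtype=np.int8)
        col[het & alt_on_0, 0] = 1
        col[het & ~alt_on_0, 1] = 1
        col[hom] = (gj[hom] // 2)[:, None]
        col[gj == MISSING] = MISSING
        haps[:, :, j] = col
        # emission update per haplotype
        for c in (0, 1):
            obs = col[:, c]
            e = np.ones((n, H))
            known = obs != MISSING
            match = ref[None, :, j] == obs[known, None]
            e[known] = np.where(match, 1.0 - eps, eps)
            f[:, c, :] = f[:, c, :] * e
        norm = f.sum(axis=2, keepdims=True)
        f /= np.maximum(norm, 1e-300)
    return haps


def _canonicalize_phase(haps: np.ndarray, genotypes: np.ndarray) -> np.ndarray:
    """Swap each individual's haplotypes so the first het site has alt on 0."""
    out = haps.copy()
    het = genotypes == 1
    for i in range(haps.shape[0]):
        sites = np.flatnonzero(het[i])
        if sites.size and out[i, 0, sites[0]] != 1:
            out[i] = out[i, ::-1]
    return out


def _match_panel_columns(dataset: CohortDataset, panel: HaplotypePanel,
                         idx: np.ndarray) -> np.ndarray:
    pos = {m: j for j, m in enumerate(panel.marker_ids)}
    ids = dataset.markers["marker_id"].to_numpy()[idx]
    missing = [m for m in ids if m not in pos]
    if missing:
        raise ValueError(f"dataset markers absent from panel: {missing[:5]}...")
    return np.array([pos[m] for m in ids])


# ---------------------------------------------------------------------------
# dosage + quality
# ---------------------------------------------------------------------------


def dose_and_quality(alt_post_h1: np.ndarray, alt_post_h2: np.ndarray,
                     marker_table: pd.DataFrame,
                     genotyped: np.ndarray | None = None) -> ImputedMarkers:
    """Combine per-haplotype alt posteriors into dosages and rsq.

    dosage_i = posterior_h1_i + posterior_h2_i;  p-hat = mean(dosage)/2;
    rsq = Var(dosage) / (2 p-hat (1 - p-hat)), capped into [0, 1] and set
    to 0 where p-hat is 0 or 1.  ``genotyped`` marks pass-through markers
    (hard-call dosages, rsq = 1 by convention).
    """
    dose = np.asarray(alt_post_h1, dtype=np.float64) + np.asarray(
        alt_post_h2, dtype=np.float64)
    p_hat = dose.mean(axis=0) / 2.0
    var = dose.var(axis=0)
    denom = 2.0 * p_hat * (1.0 - p_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsq = np.where(denom > 0, var / denom, 0.0)
    rsq = np.clip(rsq, 0.0, 1.0)
    if genotyped is None:
        genotyped = np.zeros(dose.shape[1], dtype=bool)
    rsq[genotyped] = 1.0
    info = marker_table[["marker_id", "chrom", "pos", "ref", "alt"]].copy()
    info["freq"] = p_hat
    info["rsq"] = rsq
    info["genotyped"] = np.asarray(genotyped, dtype=bool)
    return ImputedMarkers(dose.astype(np.float32), info.reset_index(drop=True),
                          sample_ids=[])


def filter_markers(imputed: ImputedMarkers, maf_min: float = 0.01,
                   rsq_min: float = 0.3) -> ImputedMarkers:
    """Published analysis filters: exclude markers with MAF strictly below
    ``maf_min`` or rsq strictly below ``rsq_min`` (boundary values are
    retained).  Genotyped markers carry rsq = 1 and are never
    quality-filtered.
    """
    if not (0.0 < maf_min < 1.0) or not (0.0 < rsq_min < 1.0):
        raise ValueError("thresholds must lie in (0, 1)")
    maf = np.minimum(imputed.info["freq"].to_numpy(),
                     1.0 - imputed.info["freq"].to_numpy())
    rsq = imputed.info["rsq"].to_numpy()
    keep = np.flatnonzero((maf >= maf_min) & (rsq >= rsq_min))
    return imputed.subset(keep)


# ---------------------------------------------------------------------------
# end-to-end imputation of one dataset
# ---------------------------------------------------------------------------


def impute_dataset(dataset: CohortDataset, panel: HaplotypePanel,
                   model: CopyingModel | None = None,
                   phasing_mode: str = "statistical",
                   chunk_size: int = 300, overlap: int = 30,
                   seed: int = 0) -> ImputedMarkers:
    """Phase and impute one merged dataset to every panel site.

    Output covers all panel markers (on the dataset's chromosomes):
    genotyped sites keep their hard calls (missing hard calls receive
    their imputed dosage), untyped sites get Li–Stephens dosages.
    """
    mdl = model or CopyingModel()
    panel_tab = panel.marker_table()
    typed_cols = _match_panel_columns(dataset, panel,
                                      np.arange(dataset.n_markers))
    typed_mask = np.zeros(panel.n_markers, dtype=bool)
    typed_mask[typed_cols] = True

    chunks = chunk_genome(panel_tab, chunk_size, overlap)
    n = dataset.n_samples
    outputs = []
    for chunk in chunks:
        cols = np.arange(chunk.start, chunk.stop)
        in_chunk = typed_mask[cols]
        typed_in_chunk = cols[in_chunk]
        col_to_ds = {int(c): k for k, c in enumerate(typed_cols)}
        ds_idx = np.array([col_to_ds[int(c)] for c in typed_in_chunk], dtype=int)
        sub = dataset.subset_markers(ds_idx)
        sub.true_haplotypes = getattr(dataset, "true_haplotypes", None)
        sub.panel_marker_index = typed_cols[ds_idx]
        phased = phase_dataset(sub, panel, mdl, mode=phasing_mode,
                               seed=seed + chunk.start)
        # lift phased alleles onto the chunk's full site grid
        targets = np.full((2 * n, cols.size), MISSING, dtype=np.int8)
        local = np.flatnonzero(in_chunk)
        targets[0::2, local] = phased[:, 0, :]
        targets[1::2, local] = phased[:, 1, :]
        alt = _ls_alt_posterior_batch(targets,
                                      panel.haplotypes[:, cols],
                                      panel.positions[cols], mdl)
        outputs.append((alt[0::2] + alt[1::2]))
    dose = stitch_chunks(chunks, outputs, panel.n_markers)

    # genotyped sites: hard calls pass through where observed
    g = dataset.genotypes
    hard = np.where(g == MISSING, np.nan, g.astype(np.float64))
    obs = ~np.isnan(hard)
    block = dose[:, typed_cols]
    block[obs] = hard[obs]
    dose[:, typed_cols] = block

    out = dose_and_quality(dose / 2.0, dose / 2.0, panel_tab,
                           genotyped=typed_mask)
    out.dosages = dose.astype(np.float32)
    # recompute freq/var on the final dosage matrix
    p_hat = dose.mean(axis=0) / 2.0
    var = dose.var(axis=0)
    denom = 2.0 * p_hat * (1.0 - p_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsq = np.where(denom > 0, np.clip(var / denom, 0.0, 1.0), 0.0)
    rsq[typed_mask] = 1.0
    out.info["freq"] = p_hat
    out.info["rsq"] = rsq
    out.sample_ids = dataset.sample_ids
    return out
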