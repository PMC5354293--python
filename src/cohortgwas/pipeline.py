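"""End-to-end pipeline drivers and simulation scenarios.

These helpers wire the stages together in the published order — merge by
platform family, duplicate/relative screening and removal, PCA, artifact
scan, (optionally) imputation, platform-stratified association and
fixed-effects meta-analysis — on simulated multi-platform cohorts.  They
exist so the command-line layer, the test suite and reproduction scripts
share one code path.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import assoc_meta, harmonize, relatedness, simcohort, structure
from .gio import CohortDataset, RunConfig

log = logging.getLogger("cohortgwas")


@dataclass
class PlatformSim:
    """One simulated platform family plus its planted truth."""

    studies: list                      # list of CohortDataset
    panel: simcohort.HaplotypePanel
    ledger: simcohort.TruthLedger
    pheno: pd.DataFrame | None = None


def simulate_platform(panel: simcohort.HaplotypePanel,
                      manifest: simcohort.PlatformManifest | None,
                      study_specs: list[dict],
                      seed: int,
                      dup_fraction: float = 0.0,
                      ledger: simcohort.TruthLedger | None = None,
                      mosaic_switch_rate: float = 1e-5) -> PlatformSim:
    """Simulate the studies of one platform family.

    ``study_specs`` are dicts accepted by :class:`simcohort.StudyDesign`.
    ``dup_fraction`` plants expected cross-study duplicates: that fraction
    of the first study's samples is re-genotyped (same subject identifier,
    fresh sample id) in the following study, emulating subjects selected
    into multiple GWAS.
    """
    rng = np.random.default_rng(seed)
    led = ledger if ledger is not None else simcohort.TruthLedger()
    studies = []
    for k, spec in enumerate(study_specs):
        design = simcohort.StudyDesign(**spec)
        ds = simcohort.sample_cohort(panel, design,
                                     seed=int(rng.integers(2**31)),
                                     manifest=manifest,
                                     mosaic_switch_rate=mosaic_switch_rate)
        studies.append(ds)
    if dup_fraction > 0 and len(studies) >= 2:
        src = studies[0]
        n_dup = int(round(dup_fraction * sum(s.n_samples for s in studies)))
        pick = rng.choice(src.n_samples, size=min(n_dup, src.n_samples),
                          replace=False)
        target = studies[1]
        for i in pick:
            target = simcohort.copy_duplicate_to_study(
                src, src.sample_ids[int(i)], target,
                seed=int(rng.integers(2**31)), ledger=led)
        studies[1] = target
    return PlatformSim(studies=studies, panel=panel, ledger=led)


@dataclass
class QCResult:
    merged: CohortDataset
    merge_report: harmonize.MergeReport
    pairs: pd.DataFrame
    removed: list
    relatives: list
    pca: structure.PCAResult | None


def run_qc(studies: list[CohortDataset], config: RunConfig | None = None,
           seed: int = 0, remove_duplicates: bool = True,
           n_prune_candidates: int = 12000, n_pcs: int = 10) -> QCResult:
    """Merge one platform family and run the sample/marker QC stages.

    Steps: merge (call-rate, strand, intersection) -> pairwise
    duplicate/relative screen -> removal policy (skipped when
    ``remove_duplicates`` is false, mirroring the published
    with/without-duplicates comparison) -> LD pruning on a candidate
    subset of about ``n_prune_candidates`` common markers -> PCA with one
    member per related pair excluded and projected back.
    """
    cfg = config or RunConfig()
    t0 = time.time()
    merged, report = harmonize.merge_studies(studies, cfg)
    log.info("merge: %d markers, %d samples (%.1fs)", merged.n_markers,
             merged.n_samples, time.time() - t0)

    removed: list = []
    relatives: list = []
    pairs = pd.DataFrame()
    if remove_duplicates:
        pairs = relatedness.screen_pairs(merged, cfg, seed=seed)
        removed, relatives = relatedness.apply_removal_policy(
            pairs, seed=seed, concordance_cutoff=cfg.concordance_cutoff)
        if removed:
            merged = merged.drop_samples(removed)

    rng = np.random.default_rng(seed)
    freqs = merged.allele_freqs()
    common = np.flatnonzero(np.minimum(freqs, 1 - freqs) >= 0.05)
    if common.size > n_prune_candidates:
        common = np.sort(rng.choice(common, size=n_prune_candidates,
                                    replace=False))
    sub = merged.subset_markers(common)
    kept_local = structure.ld_prune(sub, cfg.ld_r2_max, cfg.ld_window,
                                    cfg.ld_step)
    pruned = common[kept_local]
    pca_excl = [b for _, b in relatives]
    n_pcs_eff = min(n_pcs, max(merged.n_samples - 2, 1))
    pca_res = structure.pca(merged, pruned, related_exclusions=pca_excl,
                            k=n_pcs_eff)
    log.info("qc: %d removed, %d relative pairs, %d pruned markers (%.1fs)",
             len(removed), len(relatives), pruned.size, time.time() - t0)
    return QCResult(merged=merged, merge_report=report, pairs=pairs,
                    removed=removed, relatives=relatives, pca=pca_res)


def quantitative_scan(qc: QCResult, pheno: pd.DataFrame,
                      config: RunConfig | None = None,
                      dosages: np.ndarray | None = None,
                      marker_ids=None) -> pd.DataFrame:
    """Platform association scan of the quantitative trait.

    Uses hard-call genotypes (mean-imputing missing calls per marker) or
    provided imputed dosages; covariates are study indicators, age and the
    top PCs, per the published quantitative-trait model.
    """
    cfg = config or RunConfig()
    merged = qc.merged
    ph = pheno.set_index("sample_id").loc[merged.sample_ids].reset_index()
    pcs = qc.pca.score_matrix() if qc.pca is not None else None
    cov = assoc_meta.build_covariates(ph, pcs=pcs, include_age=True,
                                     n_pcs=cfg.n_pcs)
    y = ph["trait_quant"].to_numpy(dtype=np.float64)
    if dosages is None:
        g = merged.genotypes   # hard calls; linear_scan mean-imputes blockwise
        ids = merged.marker_ids
    else:
        g = dosages
        ids = marker_ids
    return assoc_meta.linear_scan(g, y, cov, marker_ids=ids,
                                  platform=merged.platform)


def platform_lambda(scan: pd.DataFrame) -> float:
    return assoc_meta.genomic_lambda(scan).lam


def meta_lambda(scans: list[pd.DataFrame]) -> tuple[pd.DataFrame, float]:
    meta = assoc_meta.meta_analyze_scans(scans)
    return meta, assoc_meta.genomic_lambda(meta).lam


# ---------------------------------------------------------------------------
# canned scenarios (shared by tests and reproduction scripts)
# ---------------------------------------------------------------------------


def duplicate_inflation_run(seed: int, n_per_platform: int = 4000,
                            n_markers: int = 50_000, n_hap: int = 200,
                            dup_fraction: float = 0.05,
                            n_prune_candidates: int = 12000) -> dict:
    """Run the three-platform pipeline twice — with and without
    duplicate removal — and compare meta-analysis inflation factors.

    Returns a dict with ``lambda_with_duplicates``,
    ``lambda_without_duplicates`` (i.e. after removal), per-platform
    lambdas, and the number of duplicates planted/removed.
    """
    sims, panel, ledger, pheno = three_platform_scenario(
        seed=seed, n_per_platform=n_per_platform, n_markers=n_markers,
        n_hap=n_hap, dup_fraction=dup_fraction)
    out: dict = {"n_planted_duplicates": len(ledger.pairs)}
    scans_removed, scans_kept = [], []
    lam_platform = {}
    n_removed = 0
    for k, (pf, studies) in enumerate(sims.items()):
        qc = run_qc(studies, seed=seed + k,
                    n_prune_candidates=n_prune_candidates)
        n_removed += len(qc.removed)
        scan = quantitative_scan(qc, pheno)
        lam_platform[pf] = platform_lambda(scan)
        scans_removed.append(scan)
        del qc
        qc_dup = run_qc(studies, seed=seed + k, remove_duplicates=False,
                        n_prune_candidates=n_prune_candidates)
        scans_kept.append(quantitative_scan(qc_dup, pheno))
        del qc_dup
    _, lam_dedup = meta_lambda(scans_removed)
    _, lam_dup = meta_lambda(scans_kept)
    out.update({
        "lambda_without_duplicates": lam_dedup,
        "lambda_with_duplicates": lam_dup,
        "lambda_per_platform": lam_platform,
        "n_removed": n_removed,
        "n_samples": 3 * n_per_platform,
        "n_markers": n_markers,
    })
    return out


def artifact_free_scan_scenario(seed: int, n_per_study: int = 1500,
                                n_markers: int = 50_000, n_hap: int = 200):
    """One artifact-free platform family with four cohort-specific control
    sets: the artifact-scan specificity test bed.  Returns the merged
    dataset (samples carry the rotation-defining labels)."""
    from . import harmonize
    rng = np.random.default_rng(seed)
    panel = simcohort.generate_reference_panel(
        n_hap=n_hap, n_markers=n_markers, seed=int(rng.integers(2**31)))
    strata = [("CohortA", "gout"), ("CohortC", "gout"), ("CohortA", "colon"),
              ("CohortC", "colon")]
    studies = []
    for k, (cohort, outcome) in enumerate(strata):
        design = simcohort.StudyDesign(
            study_id=f"S{k + 1}", cohort=cohort, primary_outcome=outcome,
            platform="OmniExpress", n_cases=n_per_study // 5,
            n_controls=n_per_study - n_per_study // 5, missing_rate=0.002)
        studies.append(simcohort.sample_cohort(
            panel, design, seed=int(rng.integers(2**31))))
    for ds in studies:
        ds.true_haplotypes = None
    merged, _ = harmonize.merge_studies(studies)
    return merged


def single_platform_scenario(seed: int, n_samples: int = 6000,
                             n_markers: int = 50_000, n_causal: int = 10,
                             beta: float = 0.10, dup_fraction: float = 0.01,
                             n_hap: int = 200):
    """One platform family, two studies, planted causal markers and a few
    expected cross-study duplicates: the null-inflation test bed.

    Returns ``(studies, panel, ledger, pheno, trait_model)``.
    """
    rng = np.random.default_rng(seed)
    panel = simcohort.generate_reference_panel(
        n_hap=n_hap, n_markers=n_markers, seed=int(rng.integers(2**31)))
    causal = [str(m) for m in rng.choice(panel.marker_ids, size=n_causal,
                                         replace=False)]
    n1 = n_samples // 2
    specs = [
        dict(study_id="S1", cohort="CohortA", primary_outcome="t2d",
             platform="HumanHap", n_cases=n1 // 2, n_controls=n1 - n1 // 2,
             missing_rate=0.002),
        dict(study_id="S2", cohort="CohortC", primary_outcome="chd",
             platform="HumanHap", n_cases=(n_samples - n1) // 2,
             n_controls=(n_samples - n1) - (n_samples - n1) // 2,
             missing_rate=0.002),
    ]
    sim = simulate_platform(panel, None, specs, seed=int(rng.integers(2**31)),
                            dup_fraction=dup_fraction)
    for ds in sim.studies:   # cache causal genotypes, free the phase truth
        simcohort.extract_true_genotypes(ds, panel, causal)
        ds.true_haplotypes = None
    effects = {m: beta * (1 if i % 2 == 0 else -1)
               for i, m in enumerate(causal)}
    trait = simcohort.TraitModel(effects=effects, sigma=1.0,
                                 age_effect=0.01)
    pheno = simcohort.simulate_traits(sim.studies, trait, panel,
                                      seed=int(rng.integers(2**31)),
                                      ledger=sim.ledger)
    return sim.studies, panel, sim.ledger, pheno, trait


def three_platform_scenario(seed: int, n_per_platform: int = 4000,
                            n_markers: int = 50_000, n_causal: int = 10,
                            beta: float = 0.10, dup_fraction: float = 0.05,
                            n_hap: int = 200):
    """Three platform families over a shared panel with ~5% planted
    expected duplicates per family: the meta-analysis inflation test bed.

    Returns ``(platform_sims, panel, ledger, pheno)`` where
    ``platform_sims`` maps platform name -> list of studies.
    """
    rng = np.random.default_rng(seed)
    panel = simcohort.generate_reference_panel(
        n_hap=n_hap, n_markers=n_markers, seed=int(rng.integers(2**31)))
    causal = [str(m) for m in rng.choice(panel.marker_ids, size=n_causal,
                                         replace=False)]
    ledger = simcohort.TruthLedger()
    cohorts = {"HumanHap": ("CohortA", "CohortB"), "OmniExpress": ("CohortA", "CohortC"),
               "Affymetrix": ("CohortC", "CohortA")}
    outcomes = {"HumanHap": ("breast", "kidney"),
                "OmniExpress": ("gout", "colon"),
                "Affymetrix": ("t2d", "chd")}
    sims = {}
    all_studies = []
    for pf in ("HumanHap", "OmniExpress", "Affymetrix"):
        half = n_per_platform // 2
        specs = []
        for k in range(2):
            n_k = half if k == 0 else n_per_platform - half
            specs.append(dict(
                study_id=f"{pf}_S{k + 1}", cohort=cohorts[pf][k],
                primary_outcome=outcomes[pf][k], platform=pf,
                n_cases=n_k // 2, n_controls=n_k - n_k // 2,
                missing_rate=0.002))
        sim = simulate_platform(panel, None, specs,
                                seed=int(rng.integers(2**31)),
                                dup_fraction=dup_fraction, ledger=ledger)
        for ds in sim.studies:   # cache causal genotypes, free phase truth
            simcohort.extract_true_genotypes(ds, panel, causal)
            ds.true_haplotypes = None
        sims[pf] = sim.studies
        all_studies.extend(sim.studies)
    effects = {m: beta * (1 if i % 2 == 0 else -1)
               for i, m in enumerate(causal)}
    trait = simcohort.TraitModel(effects=effects, sigma=1.0, age_effect=0.01)
    pheno = simcohort.simulate_traits(all_studies, trait, panel,
                                      seed=int(rng.integers(2**31)),
                                      ledger=ledger)
    return sims, panel, ledger, pheno
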