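"""Rotating control-vs-control "null GWAS" for platform-artifact markers.

Within a merged platform-family dataset, every (cohort x primary-GWAS)
control set in turn is treated as pseudo-cases against all remaining
controls (primary-GWAS cases are excluded throughout).  A marker whose
genotype predicts this arbitrary partition at genome-wide significance in
any rotation is a platform/batch artifact and is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gio import CohortDataset
from .assoc_meta import genomic_lambda, logistic_scan_2param


@dataclass
class Rotation:
    name: str                   # "<cohort>:<primary outcome>"
    case_index: np.ndarray      # row indices of pseudo-cases
    control_index: np.ndarray   # row indices of pseudo-controls


@dataclass
class ScanResult:
    per_rotation: dict          # rotation name -> results DataFrame
    min_p: pd.DataFrame         # marker_id, min_p across rotations
    flagged: list               # marker ids with any rotation p < threshold
    lambdas: dict               # rotation name -> genomic inflation factor
    n_nonconverged: int = 0


def build_rotations(sample_table: pd.DataFrame) -> list[Rotation]:
    """One rotation per (cohort x primary-GWAS) control set.

    ``sample_table`` needs columns ``cohort``, ``primary_outcome`` and
    ``is_control_in_primary_gwas``.  Primary-GWAS cases never appear on
    either side.  Requires >= 2 control sets.
    """
    ctrl = sample_table["is_control_in_primary_gwas"].to_numpy(dtype=bool)
    strata = (sample_table["cohort"].astype(str) + ":" +
              sample_table["primary_outcome"].astype(str)).to_numpy()
    ctrl_idx = np.flatnonzero(ctrl)
    groups = sorted(pd.unique(strata[ctrl_idx]))
    if len(groups) < 2:
        raise ValueError("need at least two cohort-specific control sets")
    rotations = []
    for gname in groups:
        is_case = ctrl & (strata == gname)
        is_ctrl = ctrl & (strata != gname)
        rotations.append(Rotation(gname, np.flatnonzero(is_case),
                                  np.flatnonzero(is_ctrl)))
    return rotations


def run_scan(dataset: CohortDataset, rotations: list[Rotation],
             p_threshold: float = 1e-8) -> ScanResult:
    """Per-rotation logistic scan of pseudo-case status on each marker.

    Covariates default to none, matching the published QC regressions.
    Non-convergent fits are excluded from flagging (their p is NaN) and
    counted.  A marker is flagged when any rotation gives p < threshold.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must lie in (0, 1)")
    per_rotation = {}
    lambdas = {}
    min_p = np.full(dataset.n_markers, np.nan)
    n_bad = 0
    for rot in rotations:
        rows = np.concatenate([rot.case_index, rot.control_index])
        status = np.zeros(rows.size)
        status[: rot.case_index.size] = 1.0
        res = logistic_scan_2param(dataset.genotypes[rows], status,
                                   marker_ids=dataset.marker_ids)
        per_rotation[rot.name] = res
        n_bad += int((~res["converged"]).sum())
        z = res["z"].to_numpy()
        finite = np.isfinite(z)
        if finite.sum() >= 100:
            lambdas[rot.name] = genomic_lambda(z[finite]).lam
        p = res["p"].to_numpy()
        min_p = np.fmin(min_p, p)
    flagged_mask = np.nan_to_num(min_p, nan=1.0) < p_threshold
    flagged = [dataset.marker_ids[j] for j in np.flatnonzero(flagged_mask)]
    return ScanResult(
        per_rotation=per_rotation,
        min_p=pd.DataFrame({"marker_id": dataset.marker_ids, "min_p": min_p}),
        flagged=flagged, lambdas=lambdas, n_nonconverged=n_bad)


def remove_flagged(dataset: CohortDataset, flags: list) -> CohortDataset:
    """Drop flagged markers; idempotent, logs nothing for empty flags."""
    if not flags:
        return dataset
    bad = set(flags)
    keep = [j for j, m in enumerate(dataset.marker_ids) if m not in bad]
    return dataset.subset_markers(keep)


def qq_table(results: pd.DataFrame) -> pd.DataFrame:
    """Observed vs expected -log10 p for QQ plotting, exported as TSV."""
    p = np.sort(results["p"].dropna().to_numpy())
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({"expected_neglog10": -np.log10(expected),
                         "observed_neglog10": -np.log10(np.maximum(p, 1e-300))})
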