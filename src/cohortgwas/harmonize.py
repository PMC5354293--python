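"""Merging per-study datasets into platform-family datasets.

The merge rule is strict: within one platform family a marker survives only
if it is present in every study, passes the per-study missing-call-rate
filter (> 5% missing drops it), is not strand-ambiguous (A/T, C/G), and has
alleles consistent with the designated reference study after strand
flipping and allele-order recoding.  Samples are concatenated; study labels
are preserved.  Every input marker is accounted for exactly once in the
:class:`MergeReport` (retained, or one drop reason).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .gio import MISSING, CohortDataset, RunConfig

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = {frozenset("AT"), frozenset("CG")}


# ---------------------------------------------------------------------------
# overlap accounting
# ---------------------------------------------------------------------------


def platform_overlap(manifests: dict) -> pd.DataFrame:
    """Exact set-algebra overlap counts for a collection of marker manifests.

    Parameters
    ----------
    manifests
        Mapping of platform/study name -> set of marker ids (>= 1 entry).

    Returns a table with one row per non-empty subset of manifests:
    ``members`` (sorted ``+``-joined names), ``k`` (subset size) and
    ``n_intersection``.
    """
    if not manifests:
        raise ValueError("at least one manifest required")
    names = sorted(manifests)
    rows = []
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inter = set.intersection(*(set(manifests[c]) for c in combo))
            rows.append({"members": "+".join(combo), "k": k,
                         "n_intersection": len(inter)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-marker QC
# ---------------------------------------------------------------------------


def filter_call_rate(dataset: CohortDataset, max_missing: float = 0.05):
    """Drop markers with missing-call fraction strictly greater than the cut.

    Returns ``(filtered_dataset, dropped_marker_ids)``.
    """
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing outside [0, 1]")
    miss = dataset.missing_mask().mean(axis=0)
    keep = np.flatnonzero(miss <= max_missing)
    dropped = [dataset.marker_ids[j] for j in np.flatnonzero(miss > max_missing)]
    return dataset.subset_markers(keep), dropped


def marker_qc(dataset: CohortDataset) -> pd.DataFrame:
    """Per-marker call rate, MAF and HWE exact-test p-value."""
    g = dataset.genotypes
    miss = dataset.missing_mask()
    call_rate = 1.0 - miss.mean(axis=0)
    freqs = dataset.allele_freqs()
    maf = np.minimum(freqs, 1.0 - freqs)
    pvals = np.empty(dataset.n_markers)
    for j in range(dataset.n_markers):
        col = g[:, j][~miss[:, j]]
        n_aa = int(np.sum(col == 0))
        n_ab = int(np.sum(col == 1))
        n_bb = int(np.sum(col == 2))
        pvals[j] = 1.0 if (n_aa + n_ab + n_bb) == 0 else hwe_exact_test(n_aa, n_ab, n_bb)
    return pd.DataFrame({"marker_id": dataset.marker_ids, "call_rate": call_rate,
                         "maf": maf, "hwe_p": pvals})


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided Hardy–Weinberg exact test (probability-ordering convention).

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed configuration.

    Returns 1.0 for monomorphic input.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts zero")
    n_a = 2 * n_aa + n_Aa  # minor... either allele works by symmetry
    n_a = min(n_a, 2 * n - n_a)
    if n_a == 0:
        return 1.0
    # heterozygote counts share the parity of the rarer allele count
    het_values = np.arange(n_a % 2, n_a + 1, 2)
    probs = np.zeros(het_values.size)
    # recurrence on P(het) with fixed allele counts (Wigginton et al. form):
    # P(h-2)/P(h) = h*(h-1) / (4*(hom_r+1)*(hom_c+1)) with hom counts at h-2
    mid_i = het_values.size // 2
    probs[mid_i] = 1.0
    for i in range(mid_i, 0, -1):
        h = het_values[i]
        hom_r = (n_a - h) // 2          # rare homozygotes at h
        hom_c = n - h - hom_r           # common homozygotes at h
        probs[i - 1] = probs[i] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
    for i in range(mid_i, het_values.size - 1):
        h = het_values[i]
        hom_r = (n_a - h) // 2
        hom_c = n - h - hom_r
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((h + 1) * (h + 2))
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(het_values == n_Aa)[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# strand resolution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrandResolution:
    """Outcome of comparing a study's allele pair with the reference pair.

    ``action`` is one of ``keep``, ``flip``, ``drop_ambiguous``,
    ``mismatch``; ``recode`` marks an allele-order swap (genotypes must be
    recoded g -> 2 - g and the pair reported in reference orientation).
    """

    action: str
    recode: bool = False


def resolve_strand(study_pair: tuple[str, str],
                   reference_pair: tuple[str, str]) -> StrandResolution:
    """Classify a study/reference allele-pair comparison.

    A/T and C/G pairs are dropped unconditionally (strand unresolvable from
    alleles alone).  Otherwise: exact (ref, alt) match -> keep; swapped
    (alt, ref) match -> keep with recode; reverse-complement match -> flip
    (with recode if additionally swapped); anything else -> mismatch.
    """
    s_ref, s_alt = (a.upper() for a in study_pair)
    r_ref, r_alt = (a.upper() for a in reference_pair)
    for a in (s_ref, s_alt, r_ref, r_alt):
        if a not in _COMPLEMENT:
            raise ValueError(f"non-nucleotide allele {a!r}")
    if frozenset((s_ref, s_alt)) in _AMBIGUOUS or frozenset((r_ref, r_alt)) in _AMBIGUOUS:
        return StrandResolution("drop_ambiguous")
    if (s_ref, s_alt) == (r_ref, r_alt):
        return StrandResolution("keep")
    if (s_alt, s_ref) == (r_ref, r_alt):
        return StrandResolution("keep", recode=True)
    c_ref, c_alt = _COMPLEMENT[s_ref], _COMPLEMENT[s_alt]
    if (c_ref, c_alt) == (r_ref, r_alt):
        return StrandResolution("flip")
    if (c_alt, c_ref) == (r_ref, r_alt):
        return StrandResolution("flip", recode=True)
    return StrandResolution("mismatch")


# ---------------------------------------------------------------------------
# merge
# ---------------------------------------------------------------------------


@dataclass
class MergeReport:
    """Accounting for one platform-family merge."""

    platform: str = ""
    study_inputs: dict = field(default_factory=dict)   # study -> (n_samples, n_markers)
    dropped: dict = field(default_factory=dict)        # reason -> list of marker ids
    n_flipped: int = 0
    n_recoded: int = 0
    n_markers_out: int = 0
    n_samples_out: int = 0
    merged_call_rate_drops: list = field(default_factory=list)

    def drop_counts(self) -> dict:
        return {reason: len(ids) for reason, ids in self.dropped.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stage": f"input:{s}", "n_samples": ns, "n_markers": nm}
                for s, (ns, nm) in self.study_inputs.items()]
        for reason, ids in self.dropped.items():
            rows.append({"stage": f"dropped:{reason}", "n_samples": "",
                         "n_markers": len(ids)})
        rows.append({"stage": "merged", "n_samples": self.n_samples_out,
                     "n_markers": self.n_markers_out})
        return pd.DataFrame(rows)


def merge_studies(datasets: list[CohortDataset],
                  config: RunConfig | None = None) -> tuple[CohortDataset, MergeReport]:
    """Merge >= 2 same-platform studies into one dataset.

    The first study defines the reference allele orientation.  Markers kept
    are the intersection of all studies' post-call-rate marker sets, minus
    strand-ambiguous and allele-mismatch markers.  Duplicate sample ids
    across studies are an error (duplicate *subjects* are expected and are
    handled downstream by the relatedness stage).
    """
    cfg = config or RunConfig()
    if len(datasets) < 2:
        raise ValueError("need at least two studies to merge")
    report = MergeReport(platform=datasets[0].platform)

    all_ids: list[str] = []
    for ds in datasets:
        all_ids.extend(ds.sample_ids)
        report.study_inputs[ds.study_id or "?"] = (ds.n_samples, ds.n_markers)
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("duplicate sample ids across studies; resolve upstream")

    filtered, dropped_cr = [], set()
    per_study_markers = []
    for ds in datasets:
        f, dropped = filter_call_rate(ds, cfg.max_missing)
        filtered.append(f)
        dropped_cr.update(dropped)
        per_study_markers.append(set(f.marker_ids))

    union_markers = set().union(*(set(ds.marker_ids) for ds in datasets))
    shared = set.intersection(*per_study_markers)
    report.dropped["call_rate"] = sorted(dropped_cr)
    report.dropped["not_shared"] = sorted(
        union_markers - shared - dropped_cr)

    # order by the reference (first) study's marker order
    ref = filtered[0]
    ref_order = [m for m in ref.marker_ids if m in shared]
    ref_alleles = {m: (r, a) for m, r, a in zip(
        ref.markers["marker_id"], ref.markers["ref"], ref.markers["alt"])}

    ambiguous, mismatch = [], []
    actions_per_study: list[dict] = []
    for ds in filtered:
        acts = {}
        pairs = {m: (r, a) for m, r, a in zip(
            ds.markers["marker_id"], ds.markers["ref"], ds.markers["alt"])}
        for m in ref_order:
            res = resolve_strand(pairs[m], ref_alleles[m])
            acts[m] = res
            if res.action == "drop_ambiguous":
                ambiguous.append(m)
            elif res.action == "mismatch":
                mismatch.append(m)
        actions_per_study.append(acts)
    bad = set(ambiguous) | set(mismatch)
    kept = [m for m in ref_order if m not in bad]
    report.dropped["ambiguous"] = sorted(set(ambiguous))
    report.dropped["allele_mismatch"] = sorted(set(mismatch) - set(ambiguous))
    if not kept:
        raise ValueError("no markers survive the merge")

    blocks = []
    for ds, acts in zip(filtered, actions_per_study):
        col = {m: j for j, m in enumerate(ds.marker_ids)}
        idx = np.array([col[m] for m in kept])
        g = ds.genotypes[:, idx].copy()
        recode = np.array([acts[m].recode for m in kept])
        if recode.any():
            sub = g[:, recode]
            miss = sub == MISSING
            sub = 2 - sub
            sub[miss] = MISSING
            g[:, recode] = sub
            report.n_recoded += int(recode.sum())
        report.n_flipped += sum(acts[m].action == "flip" for m in kept)
        blocks.append(g)

    ref_col = {m: j for j, m in enumerate(ref.marker_ids)}
    markers = ref.markers.iloc[[ref_col[m] for m in kept]].reset_index(drop=True)
    samples = pd.concat([ds.samples for ds in filtered], ignore_index=True)
    merged = CohortDataset(np.vstack(blocks), markers, samples,
                           platform=datasets[0].platform, study_id=None)

    # re-check call rate on the merged matrix (logged, not re-filtered here)
    miss = merged.missing_mask().mean(axis=0)
    report.merged_call_rate_drops = [
        merged.marker_ids[j] for j in np.flatnonzero(miss > cfg.max_missing)]
    report.n_markers_out = merged.n_markers
    report.n_samples_out = merged.n_samples
    return merged, report
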