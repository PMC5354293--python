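"""Synthetic multi-study, multi-platform GWAS cohorts with planted truths.

The generator emulates the structure of a pooled cohort-GWAS resource:
several studies per genotyping-platform family, each typing an
overlapping-but-distinct SNP manifest, with planted duplicate/related
sample pairs, study-specific genotype-calling artifacts, and quantitative
(BMI-like) and rare binary (VTE-like) secondary traits driven by a handful
of causal variants.

Haplotypes come from a founder-mosaic reference panel: a small set of
founder haplotypes is generated with per-marker allele frequencies, and
every panel haplotype is a mosaic that switches founders along the
chromosome.  Cohort individuals are in turn mosaics of panel haplotypes,
so the population carries block-wise linkage disequilibrium without a full
coalescent simulation.  Genotypes are alt-allele counts 0/1/2 (``-1``
missing); the true phase of every individual is retained internally so the
imputation stage can be tested against ground truth.

Every planted truth (pairs, artifact markers, causal effects) is recorded
in a :class:`TruthLedger`; downstream recovery tests read only the ledger.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gio import MISSING, MARKER_COLUMNS, CohortDataset, write_matrix, write_pheno, write_vcf

_NUCS = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePanel:
    """Phased binary reference haplotypes (rows) over ordered markers."""

    haplotypes: np.ndarray          # (n_hap, n_markers) uint8 in {0,1}
    positions: np.ndarray           # bp, strictly increasing per chromosome
    alleles: np.ndarray             # (n_markers, 2) ref/alt nucleotides
    chromosomes: np.ndarray         # chromosome label per marker
    marker_ids: np.ndarray          # unique identifiers

    def __post_init__(self) -> None:
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        for chrom in pd.unique(self.chromosomes):
            pos = self.positions[self.chromosomes == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def allele_freqs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def marker_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker_id": self.marker_ids,
            "chrom": self.chromosomes,
            "pos": self.positions,
            "ref": self.alleles[:, 0],
            "alt": self.alleles[:, 1],
        })


@dataclass
class PlatformManifest:
    """The marker set typed by one platform family."""

    name: str
    marker_ids: set

    def __len__(self) -> int:
        return len(self.marker_ids)


@dataclass
class PairSpec:
    """A planted duplicate/relative pair anchored on an existing sample."""

    kind: str                       # duplicate | full_sib | half_sib
    source_id: str                  # existing individual to pair with
    expected: bool = True           # same subject identifiers across studies?
    discordance: float = 0.0        # duplicate-only per-genotype flip rate
    new_id: str | None = None


@dataclass
class StudyDesign:
    """One study: who was genotyped, on what platform, with what defects."""

    study_id: str
    cohort: str
    primary_outcome: str
    platform: str
    n_cases: int
    n_controls: int
    missing_rate: float = 0.0
    artifact_markers: Sequence[str] = field(default_factory=list)
    artifact_rate: float = 0.0
    pair_specs: Sequence[PairSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("n_cases and n_controls must be >= 0")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate outside [0, 1]")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise ValueError("artifact_rate outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class TraitModel:
    """Genetic architecture of the simulated secondary traits.

    ``effects`` maps causal marker id -> per-allele effect: trait units for
    the quantitative trait, log-odds for the binary trait.  The binary
    intercept is solved so the population prevalence hits ``prevalence``.
    """

    effects: dict
    sigma: float = 1.0              # residual SD of the quantitative trait
    prevalence: float = 0.072       # target binary-trait case fraction
    age_effect: float = 0.0
    study_effects: dict = field(default_factory=dict)
    binary_effects: dict | None = None   # defaults to `effects`

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")


@dataclass
class TruthLedger:
    """Every planted truth, recorded at plant time."""

    pairs: list = field(default_factory=list)       # dicts per planted pair
    artifacts: list = field(default_factory=list)   # dicts per corrupted marker
    causal: list = field(default_factory=list)      # dicts per causal marker

    def pairs_frame(self) -> pd.DataFrame:
        cols = ["id_i", "id_j", "kind", "expected", "study_i", "study_j",
                "true_z0", "true_z1", "true_z2"]
        return pd.DataFrame(self.pairs, columns=cols)

    def artifacts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.artifacts,
                            columns=["marker_id", "study_id", "corruption_rate"])

    def causal_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.causal,
                            columns=["marker_id", "trait", "effect"])

    def write(self, outdir: str | os.PathLike) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.pairs_frame().to_csv(os.path.join(outdir, "pairs.truth.tsv"),
                                  sep="\t", index=False)
        self.artifacts_frame().to_csv(os.path.join(outdir, "artifacts.truth.tsv"),
                                      sep="\t", index=False)
        self.causal_frame().to_csv(os.path.join(outdir, "causal.truth.tsv"),
                                   sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------


def generate_reference_panel(n_hap: int, n_markers: int,
                             mosaic_switch_rate: float = 1e-5,
                             seed: int = 0, n_founders: int = 8,
                             mean_gap_bp: float = 3000.0,
                             n_chromosomes: int = 1) -> HaplotypePanel:
    """Generate a founder-mosaic haplotype reference panel.

    ``n_founders`` haplotypes are drawn site-wise from per-marker allele
    frequencies ~ Uniform(0.05, 0.95); each of the ``n_hap`` panel
    haplotypes then copies a founder, switching to a random founder between
    adjacent markers with probability ``1 - exp(-rate * gap_bp)``.  Columns
    that come out monomorphic or singleton (alt count < 2 or > n_hap - 2)
    have their founder alleles redrawn, so the emitted panel contains no
    monomorphic or singleton sites.

    Parameters
    ----------
    n_hap : even number of panel haplotypes, >= 4.
    n_markers : number of sites, >= 2.
    mosaic_switch_rate : founder-switch intensity per base pair.
    mean_gap_bp : mean inter-marker spacing (exponential gaps).
    n_chromosomes : markers are split evenly across this many chromosomes;
        mosaic copying and meiosis restart independently on each.
    """
    if n_hap < 4 or n_hap % 2:
        raise ValueError("n_hap must be even and >= 4")
    if n_markers < 2:
        raise ValueError("n_markers must be >= 2")
    if mosaic_switch_rate < 0:
        raise ValueError("mosaic_switch_rate must be >= 0")
    if n_chromosomes < 1 or n_chromosomes > n_markers:
        raise ValueError("n_chromosomes must lie in [1, n_markers]")
    rng = np.random.default_rng(seed)

    gaps = np.maximum(1, rng.exponential(mean_gap_bp, size=n_markers)).astype(np.int64)
    positions = np.cumsum(gaps)
    chrom_of = np.minimum(np.arange(n_markers) * n_chromosomes // n_markers,
                          n_chromosomes - 1)
    chromosomes = np.array([str(c + 1) for c in chrom_of], dtype=object)
    # restart coordinates at each chromosome
    for c in range(n_chromosomes):
        sel = chrom_of == c
        offset = positions[sel][0] - gaps[sel][0]
        positions[sel] -= offset
    # avoid strand-ambiguous (complementary) pairs: with A,C,G,T coded
    # 0..3 the complement of r is 3 - r, so draw alt from the other two
    ref_idx = rng.integers(0, 4, size=n_markers)
    others = np.array([[b for b in range(4) if b != a and b != 3 - a]
                       for a in range(4)])
    alt_idx = others[ref_idx, rng.integers(0, 2, size=n_markers)]
    alleles = np.column_stack([_NUCS[ref_idx], _NUCS[alt_idx]])

    freqs = rng.uniform(0.05, 0.95, size=n_markers)
    founders = (rng.random((n_founders, n_markers)) < freqs).astype(np.uint8)

    breaks = _chromosome_breaks(chromosomes)
    paths = _mosaic_paths(rng, n_hap, positions, n_founders,
                          mosaic_switch_rate, breaks)
    hap = founders[paths, np.arange(n_markers)[None, :]]

    # redraw founder alleles at degenerate columns (paths kept fixed)
    for _ in range(200):
        counts = hap.sum(axis=0)
        bad = np.flatnonzero((counts < 2) | (counts > n_hap - 2))
        if bad.size == 0:
            break
        founders[:, bad] = rng.random((n_founders, bad.size)) < freqs[bad]
        hap[:, bad] = founders[np.ix_(range(n_founders), bad)][
            paths[:, bad], np.arange(bad.size)[None, :]]
    counts = hap.sum(axis=0)
    keep = np.flatnonzero((counts >= 2) & (counts <= n_hap - 2))
    marker_ids = np.array([f"rs{c}_{p}" for c, p in zip(chromosomes, positions)])
    return HaplotypePanel(
        haplotypes=np.ascontiguousarray(hap[:, keep]),
        positions=positions[keep],
        alleles=alleles[keep],
        chromosomes=chromosomes[keep],
        marker_ids=marker_ids[keep],
    )


def _chromosome_breaks(chromosomes: np.ndarray) -> np.ndarray:
    """Boolean mask: True at the first marker of each chromosome."""
    breaks = np.zeros(len(chromosomes), dtype=bool)
    breaks[0] = True
    breaks[1:] = chromosomes[1:] != chromosomes[:-1]
    return breaks


def _mosaic_paths(rng: np.random.Generator, n: int, positions: np.ndarray,
                  n_sources: int, rate: float,
                  breaks: np.ndarray | None = None) -> np.ndarray:
    """(n, m) matrix of source indices forming Markov mosaics along markers.

    ``breaks`` marks chromosome starts, where the source is redrawn
    unconditionally (chromosomes are independent).
    """
    m = positions.size
    choices = rng.integers(0, n_sources, size=(n, m), dtype=np.int32)
    gaps = np.diff(positions).astype(np.float64)
    p_switch = 1.0 - np.exp(-rate * np.maximum(gaps, 0.0))
    if breaks is not None:
        p_switch = np.where(breaks[1:], 1.0, p_switch)
    switch = np.empty((n, m), dtype=bool)
    switch[:, 0] = True
    switch[:, 1:] = rng.random((n, m - 1)) < p_switch[None, :]
    # forward-fill the founder chosen at the most recent switch point
    key = np.where(switch, np.arange(m, dtype=np.int32)[None, :], np.int32(0))
    last = np.maximum.accumulate(key, axis=1)
    return choices[np.arange(n)[:, None], last]


def default_manifests(panel: HaplotypePanel, seed: int = 0,
                      fractions: tuple[float, float, float] = (0.55, 0.6, 0.65),
                      names: tuple[str, str, str] = ("HumanHap", "OmniExpress",
                                                     "Affymetrix")) -> list[PlatformManifest]:
    """Three platform manifests with pairwise overlap but a small three-way core.

    Each platform types an independent random subset of the panel, so the
    three-way intersection (~f1*f2*f3 of the panel) is much smaller than any
    single manifest — the qualitative overlap structure of real array
    families.
    """
    rng = np.random.default_rng(seed)
    out = []
    for name, f in zip(names, fractions):
        mask = rng.random(panel.n_markers) < f
        out.append(PlatformManifest(name, set(panel.marker_ids[mask])))
    return out


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------


def sample_cohort(panel: HaplotypePanel, design: StudyDesign, seed: int = 0,
                  manifest: PlatformManifest | None = None,
                  mosaic_switch_rate: float = 1e-5) -> CohortDataset:
    """Draw one study's genotypes from the panel.

    Each individual is the sum of two haplotypes, each a mosaic of panel
    haplotypes (switch probability ``1 - exp(-rate * gap)`` per interval).
    Only manifest markers are retained in the visible genotype matrix;
    missing calls are injected at ``design.missing_rate``.  The full-panel
    true haplotypes and the case/control split are kept on the returned
    dataset (``dataset.true_haplotypes``, shape ``(n, 2, panel.n_markers)``)
    for trait simulation and imputation truth.
    """
    rng = np.random.default_rng(seed)
    n = design.n_samples
    if manifest is None:
        idx = np.arange(panel.n_markers)
    else:
        ids = set(manifest.marker_ids)
        missing = ids - set(panel.marker_ids)
        if missing:
            raise ValueError(f"manifest markers absent from panel: "
                             f"{sorted(missing)[:5]}...")
        idx = np.flatnonzero(np.isin(panel.marker_ids, list(ids)))

    # blocked over individuals: path matrices are int32 and would otherwise
    # dominate memory at biobank-ish sizes
    m_panel = panel.n_markers
    breaks = _chromosome_breaks(panel.chromosomes)
    haps = np.empty((n, 2, m_panel), dtype=np.uint8)
    cols = np.arange(m_panel)[None, :]
    block = max(1, int(2e7 // max(m_panel, 1)))
    for start in range(0, n, block):
        stop = min(start + block, n)
        paths = _mosaic_paths(rng, 2 * (stop - start), panel.positions,
                              panel.n_haplotypes, mosaic_switch_rate, breaks)
        haps[start:stop] = panel.haplotypes[paths, cols].reshape(
            stop - start, 2, m_panel)
    geno_full = (haps[:, 0, :] + haps[:, 1, :]).astype(np.int8)

    geno = geno_full[:, idx].copy()
    del geno_full
    if design.missing_rate > 0:
        mask = rng.random(geno.shape) < design.missing_rate
        geno[mask] = MISSING

    sample_ids = [f"{design.study_id}_s{i:05d}" for i in range(n)]
    subject_ids = [f"{design.cohort}_subj_{design.study_id}_{i:05d}" for i in range(n)]
    is_case = np.zeros(n, dtype=bool)
    is_case[: design.n_cases] = True
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "subject_id": subject_ids,
        "study_id": design.study_id,
        "cohort": design.cohort,
        "primary_outcome": design.primary_outcome,
        "is_control_in_primary_gwas": ~is_case,
    })
    markers = panel.marker_table().iloc[idx].reset_index(drop=True)
    ds = CohortDataset(geno, markers, samples, platform=design.platform,
                       study_id=design.study_id)
    ds.true_haplotypes = haps          # (n, 2, panel markers)
    ds.panel_marker_index = idx        # manifest -> panel column map
    return ds


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------


def plant_relatives(dataset: CohortDataset, pair_specs: Sequence[PairSpec],
                    panel: HaplotypePanel, seed: int = 0,
                    ledger: TruthLedger | None = None,
                    mosaic_switch_rate: float = 1e-5,
                    recomb_rate: float = 1e-8) -> CohortDataset:
    """Append planted duplicates / full sibs / half sibs to a study.

    * duplicate — the source's genotype vector copied, with an optional
      per-genotype discordance rate (random re-draw of the call).
    * full_sib — the source's two gametes are treated as one haplotype from
      each of two parents; a fresh mosaic haplotype completes each parent,
      and the sib receives one recombinant gamete per parent (crossovers at
      rate ``recomb_rate``/bp).  Per-marker transmission is tracked, so the
      ledger stores the realised (Z0, Z1, Z2) of each planted pair.
    * half_sib — one shared parent only; the other gamete is a fresh
      population mosaic.

    Returns a new dataset with the extra individuals appended.  Truth rows
    are appended to ``ledger`` if given.
    """
    rng = np.random.default_rng(seed)
    ids = dataset.sample_ids
    id_to_row = {s: i for i, s in enumerate(ids)}
    geno_rows, hap_rows, sample_rows = [], [], []
    idx = dataset.panel_marker_index
    m_panel = panel.n_markers
    breaks = _chromosome_breaks(panel.chromosomes)

    for k, spec in enumerate(pair_specs):
        if spec.source_id not in id_to_row:
            raise ValueError(f"unknown individual id {spec.source_id!r}")
        src = id_to_row[spec.source_id]
        new_id = spec.new_id or f"{dataset.study_id}_{spec.kind}{k:03d}"
        src_haps = dataset.true_haplotypes[src]       # (2, m_panel)

        if spec.kind == "duplicate":
            hap = src_haps.copy()
            g = dataset.genotypes[src].copy()
            if spec.discordance > 0:
                flip = np.flatnonzero(rng.random(g.size) < spec.discordance)
                for j in flip:
                    if g[j] == MISSING:
                        continue
                    alts = [v for v in (0, 1, 2) if v != g[j]]
                    g[j] = alts[rng.integers(len(alts))]
            tz = (0.0, 0.0, 1.0)
        elif spec.kind in ("full_sib", "half_sib"):
            n_shared = 2 if spec.kind == "full_sib" else 1
            gametes = np.empty((2, m_panel), dtype=np.uint8)
            ibd = np.zeros(m_panel, dtype=np.int8)
            for parent in range(2):
                if parent < n_shared:
                    other = _mosaic_paths(rng, 1, panel.positions,
                                          panel.n_haplotypes,
                                          mosaic_switch_rate, breaks)[0]
                    other_hap = panel.haplotypes[other, np.arange(m_panel)]
                    parent_haps = np.stack([src_haps[parent], other_hap])
                    trans = _meiosis_pattern(rng, panel.positions,
                                             recomb_rate, breaks)
                    gametes[parent] = parent_haps[trans, np.arange(m_panel)]
                    ibd += (trans == 0)
                else:
                    path = _mosaic_paths(rng, 1, panel.positions,
                                         panel.n_haplotypes,
                                         mosaic_switch_rate, breaks)[0]
                    gametes[parent] = panel.haplotypes[path, np.arange(m_panel)]
            hap = gametes
            g = hap.sum(axis=0).astype(np.int8)[idx]
            if dataset.missing_mask()[src].any():
                pass  # planted relatives carry complete calls by design
            tz = (float(np.mean(ibd == 0)), float(np.mean(ibd == 1)),
                  float(np.mean(ibd == 2)))
        else:
            raise ValueError(f"unknown pair kind {spec.kind!r}")

        geno_rows.append(g)
        hap_rows.append(hap)
        src_row = dataset.samples.iloc[src]
        subject = (src_row["subject_id"] if spec.expected and spec.kind == "duplicate"
                   else f"{src_row['cohort']}_subj_{new_id}")
        sample_rows.append({
            "sample_id": new_id,
            "subject_id": subject,
            "study_id": dataset.study_id,
            "cohort": src_row["cohort"],
            "primary_outcome": src_row["primary_outcome"],
            "is_control_in_primary_gwas": bool(src_row["is_control_in_primary_gwas"]),
        })
        if ledger is not None:
            ledger.pairs.append({
                "id_i": spec.source_id, "id_j": new_id, "kind": spec.kind,
                "expected": bool(spec.expected and spec.kind == "duplicate"),
                "study_i": dataset.study_id, "study_j": dataset.study_id,
                "true_z0": tz[0], "true_z1": tz[1], "true_z2": tz[2],
            })

    if not geno_rows:
        return dataset
    out = CohortDataset(
        genotypes=np.vstack([dataset.genotypes, np.array(geno_rows, dtype=np.int8)]),
        markers=dataset.markers.copy(),
        samples=pd.concat([dataset.samples, pd.DataFrame(sample_rows)],
                          ignore_index=True),
        platform=dataset.platform,
        study_id=dataset.study_id,
    )
    out.true_haplotypes = np.concatenate(
        [dataset.true_haplotypes, np.stack(hap_rows)], axis=0)
    out.panel_marker_index = idx
    return out


def _meiosis_pattern(rng: np.random.Generator, positions: np.ndarray,
                     recomb_rate: float,
                     breaks: np.ndarray | None = None) -> np.ndarray:
    """Per-marker transmitted-haplotype indicator (0/1) with crossovers.

    Haldane model; chromosomes (marked by ``breaks``) segregate
    independently (recombination fraction 0.5 at a boundary).
    """
    m = positions.size
    gaps = np.diff(positions).astype(np.float64)
    p_rec = 0.5 * (1.0 - np.exp(-2.0 * recomb_rate * np.maximum(gaps, 0.0)))
    if breaks is not None:
        p_rec = np.where(breaks[1:], 0.5, p_rec)
    cross = rng.random(m - 1) < p_rec
    start = rng.integers(2)
    pattern = np.empty(m, dtype=np.int8)
    pattern[0] = start
    pattern[1:] = start + np.cumsum(cross)
    return pattern % 2


def copy_duplicate_to_study(source: CohortDataset, source_id: str,
                            target: CohortDataset, seed: int = 0,
                            discordance: float = 0.0,
                            ledger: TruthLedger | None = None,
                            new_id: str | None = None) -> CohortDataset:
    """Plant the same subject into a *different* study (an expected
    cross-dataset duplicate: same subject identifier, new sample id).

    The subject's true haplotypes are re-projected onto the target study's
    manifest, so the two records agree wherever the manifests overlap.
    """
    rng = np.random.default_rng(seed)
    row = source.sample_ids.index(source_id)
    haps = source.true_haplotypes[row]
    g = haps.sum(axis=0).astype(np.int8)[target.panel_marker_index].copy()
    if discordance > 0:
        flip = np.flatnonzero(rng.random(g.size) < discordance)
        for j in flip:
            alts = [v for v in (0, 1, 2) if v != g[j]]
            g[j] = alts[rng.integers(len(alts))]
    new_id = new_id or f"{target.study_id}_dupof_{source_id}"
    src_row = source.samples.iloc[row]
    sample = {
        "sample_id": new_id,
        "subject_id": src_row["subject_id"],
        "study_id": target.study_id,
        "cohort": src_row["cohort"],
        "primary_outcome": target.samples["primary_outcome"].iloc[0],
        "is_control_in_primary_gwas": True,
    }
    out = CohortDataset(
        genotypes=np.vstack([target.genotypes, g[None, :]]),
        markers=target.markers.copy(),
        samples=pd.concat([target.samples, pd.DataFrame([sample])],
                          ignore_index=True),
        platform=target.platform,
        study_id=target.study_id,
    )
    out.true_haplotypes = np.concatenate(
        [target.true_haplotypes, haps[None, :, :]], axis=0)
    out.panel_marker_index = target.panel_marker_index
    if ledger is not None:
        ledger.pairs.append({
            "id_i": source_id, "id_j": new_id, "kind": "duplicate",
            "expected": True, "study_i": source.study_id,
            "study_j": target.study_id, "true_z0": 0.0, "true_z1": 0.0,
            "true_z2": 1.0,
        })
    return out


def plant_artifacts(dataset: CohortDataset, marker_ids: Sequence[str],
                    corruption_rate: float, seed: int = 0,
                    ledger: TruthLedger | None = None) -> CohortDataset:
    """Corrupt named markers toward the alternate homozygote in one study.

    With probability ``corruption_rate`` each non-missing genotype at a
    named marker is set to 2 — a directional platform-calling bias that
    shifts the study's allele frequency upward by ``rate * (1 - p)`` per
    allele in expectation.
    """
    if not (0.0 <= corruption_rate <= 1.0):
        raise ValueError("corruption_rate outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = dataset.copy()
    mk = list(dataset.marker_ids)
    col = {m: j for j, m in enumerate(mk)}
    for marker in marker_ids:
        if marker not in col:
            raise ValueError(f"marker {marker!r} not in study manifest")
        j = col[marker]
        g = out.genotypes[:, j]
        hit = (rng.random(g.size) < corruption_rate) & (g != MISSING)
        g[hit] = 2
        if ledger is not None:
            ledger.artifacts.append({
                "marker_id": marker, "study_id": dataset.study_id,
                "corruption_rate": corruption_rate,
            })
    out.true_haplotypes = getattr(dataset, "true_haplotypes", None)
    out.panel_marker_index = getattr(dataset, "panel_marker_index", None)
    return out


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def extract_true_genotypes(dataset: CohortDataset, panel: HaplotypePanel,
                           marker_ids: Sequence[str]) -> None:
    """Cache true genotypes at the named panel markers on the dataset
    (``dataset.causal_store``) so the phase truth can be released before
    trait simulation on large cohorts."""
    pos = {m: j for j, m in enumerate(panel.marker_ids)}
    cols = [pos[m] for m in marker_ids]
    g = dataset.true_haplotypes[:, :, cols].sum(axis=1).astype(np.float64)
    dataset.causal_store = dict(zip(marker_ids, g.T))


def _true_genotypes_at(datasets: Sequence[CohortDataset], panel: HaplotypePanel,
                       marker_ids: Sequence[str]) -> np.ndarray:
    """True (uncorrupted, unmissing) genotypes at panel markers, stacked
    over all datasets in order.  Causal markers need not be on any manifest.

    Uses the phase truth when present, else the cached ``causal_store``."""
    pos = {m: j for j, m in enumerate(panel.marker_ids)}
    cols = []
    for m in marker_ids:
        if m not in pos:
            raise ValueError(f"causal marker {m!r} absent from panel")
        cols.append(pos[m])
    if not cols:
        return np.zeros((sum(len(ds.samples) for ds in datasets), 0))
    mats = []
    for ds in datasets:
        haps = getattr(ds, "true_haplotypes", None)
        if haps is not None:
            mats.append(haps[:, :, cols].sum(axis=1).astype(np.float64))
        else:
            store = getattr(ds, "causal_store", None)
            if store is None:
                raise ValueError("dataset lacks phase truth and causal cache")
            missing = [m for m in marker_ids if m not in store]
            if missing:
                raise ValueError(f"causal cache lacks markers {missing[:3]}")
            mats.append(np.column_stack([store[m] for m in marker_ids]))
    return np.vstack(mats)


def simulate_traits(datasets: Sequence[CohortDataset], trait: TraitModel,
                    panel: HaplotypePanel, seed: int = 0,
                    ledger: TruthLedger | None = None,
                    age_mean: dict | float = 58.0, age_sd: float = 8.0) -> pd.DataFrame:
    """Simulate quantitative and binary secondary traits for all samples.

    Quantitative: ``y = sum_j beta_j g_j + study effect + age_effect * age
    + Normal(0, sigma^2)``.  Binary: logistic in the same genetic score
    (``binary_effects`` if given, else ``effects``) with the intercept
    solved by bisection so the population mean equals ``prevalence``.
    Duplicated subjects (same ``subject_id``) receive identical trait and
    age values — they are the same person observed twice.

    Returns the phenotype table (one row per sample, all datasets stacked).
    """
    rng = np.random.default_rng(seed)
    q_ids = list(trait.effects)
    q_beta = np.array([trait.effects[m] for m in q_ids])
    b_effects = trait.binary_effects if trait.binary_effects is not None else trait.effects
    b_ids = list(b_effects)
    b_beta = np.array([b_effects[m] for m in b_ids])

    all_ids = sorted(set(q_ids) | set(b_ids))
    G = _true_genotypes_at(datasets, panel, all_ids)
    col = {m: j for j, m in enumerate(all_ids)}
    score_q = G[:, [col[m] for m in q_ids]] @ q_beta if q_ids else np.zeros(len(G))
    score_b = G[:, [col[m] for m in b_ids]] @ b_beta if b_ids else np.zeros(len(G))

    samples = pd.concat([ds.samples for ds in datasets], ignore_index=True)
    n = len(samples)

    # per-subject randomness: duplicates of one subject share age and traits
    subjects = samples["subject_id"].to_numpy()
    uniq, first_idx, inverse = np.unique(subjects, return_index=True,
                                         return_inverse=True)

    if isinstance(age_mean, dict):
        means = samples["cohort"].map(age_mean).to_numpy(dtype=np.float64)
    else:
        means = np.full(n, float(age_mean))
    age_u = rng.normal(0.0, age_sd, size=uniq.size)
    age = means + age_u[inverse]

    study_eff = samples["study_id"].map(
        lambda s: trait.study_effects.get(s, 0.0)).to_numpy(dtype=np.float64)

    noise_u = rng.normal(0.0, trait.sigma, size=uniq.size)
    y = score_q + study_eff + trait.age_effect * (age - np.mean(means)) + noise_u[inverse]

    # binary intercept by bisection on the population mean of the logistic
    eta_u = score_b[first_idx]
    alpha = _solve_prevalence_intercept(eta_u, trait.prevalence)
    p_case = 1.0 / (1.0 + np.exp(-(alpha + score_b)))
    case_u = rng.random(uniq.size)
    y_bin = (case_u[inverse] < p_case).astype(int)

    pheno = pd.DataFrame({
        "sample_id": samples["sample_id"],
        "study_id": samples["study_id"],
        "cohort": samples["cohort"],
        "primary_outcome": samples["primary_outcome"],
        "age": np.round(age, 2),
        "trait_quant": y,
        "trait_binary": y_bin,
        "is_control_in_primary_gwas": samples["is_control_in_primary_gwas"],
    })
    if ledger is not None:
        for m, b in trait.effects.items():
            ledger.causal.append({"marker_id": m, "trait": "trait_quant", "effect": b})
        for m, b in b_effects.items():
            ledger.causal.append({"marker_id": m, "trait": "trait_binary", "effect": b})
    return pheno


def _solve_prevalence_intercept(eta: np.ndarray, prevalence: float,
                                tol: float = 1e-10) -> float:
    """Bisection for alpha with mean(expit(alpha + eta)) = prevalence."""
    lo, hi = -50.0, 50.0
    def mean_p(a: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(a + eta)))))
    if not (mean_p(lo) <= prevalence <= mean_p(hi)):
        raise ValueError("target prevalence unreachable given effects")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < prevalence:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_study(dataset: CohortDataset, outdir: str | os.PathLike) -> None:
    """Write one study as VCF + genotype-matrix text."""
    os.makedirs(outdir, exist_ok=True)
    stem = os.path.join(outdir, dataset.study_id or "study")
    write_vcf(dataset, stem + ".vcf")
    write_matrix(dataset, stem + ".geno.txt")


def panel_to_dataset(panel: HaplotypePanel) -> CohortDataset:
    """View the panel's haplotype pairs as diploid genotypes (2k -> k samples)."""
    k = panel.n_haplotypes // 2
    geno = (panel.haplotypes[0::2][:k] + panel.haplotypes[1::2][:k]).astype(np.int8)
    samples = pd.DataFrame({"sample_id": [f"panel{i:04d}" for i in range(k)]})
    return CohortDataset(geno, panel.marker_table(), samples, platform="panel")
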