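"""Readers, writers, containers and run configuration.

The pipeline moves genotype data around in three representations:

* :class:`CohortDataset` — the in-memory container: an ``n_samples x
  n_markers`` matrix of alt-allele counts (``int8``; ``-1`` = missing, or
  ``float`` dosages in ``[0, 2]``), a marker table and a sample table.
* VCF 4.2 with ``GT`` (hard calls) and/or ``DS`` (dosage) FORMAT fields.
* A plain-text genotype-matrix dialect (markers as rows) that round-trips
  bit-exactly and diffs cleanly, used for fixtures and intermediate files.

Coordinates are 1-based (VCF convention) throughout.  The text sentinel for
a missing genotype is ``NA``; in VCF it is ``./.``.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("cohortgwas")

MISSING = -1  # int8 sentinel for a missing hard call

MARKER_COLUMNS = ["marker_id", "chrom", "pos", "ref", "alt"]

#: phenotype/covariate table columns emitted by the simulator and expected
#: by the association stages
PHENO_COLUMNS = [
    "sample_id",
    "study_id",
    "cohort",
    "primary_outcome",
    "age",
    "trait_quant",
    "trait_binary",
    "is_control_in_primary_gwas",
]


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


class ConfigError(ValueError):
    """Out-of-domain or unknown configuration value."""


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------


@dataclass
class CohortDataset:
    """Genotypes plus sample and marker metadata for one study or one merge.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_markers)`` array.  ``int8`` alt-allele counts with
        ``-1`` for missing (genotype mode), or floats in ``[0, 2]``
        (dosage mode; ``NaN`` for missing).
    markers
        DataFrame with columns ``marker_id, chrom, pos, ref, alt``.
    samples
        DataFrame with at least ``sample_id``; the simulator and the
        association stages add ``study_id, cohort, subject_id,
        primary_outcome, is_control_in_primary_gwas``.
    platform
        Platform-family label (e.g. ``"HumanHap"``).
    study_id
        Study label for single-study datasets; ``None`` after merging.
    """

    genotypes: np.ndarray
    markers: pd.DataFrame
    samples: pd.DataFrame
    platform: str = ""
    study_id: str | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x markers)")
        n, m = self.genotypes.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample rows for {n} genotype rows")
        if len(self.markers) != m:
            raise ValueError(f"{len(self.markers)} marker rows for {m} genotype cols")
        missing = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing:
            raise ValueError(f"marker table lacks columns {missing}")
        self.markers = self.markers.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    # -- basic properties ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def is_dosage(self) -> bool:
        return np.issubdtype(self.genotypes.dtype, np.floating)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers["marker_id"])

    def missing_mask(self) -> np.ndarray:
        """Boolean (samples x markers) mask of missing calls."""
        if self.is_dosage:
            return np.isnan(self.genotypes)
        return self.genotypes == MISSING

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return 1.0 - self.missing_mask().mean(axis=0)

    def allele_freqs(self) -> np.ndarray:
        """Per-marker alt-allele frequency over non-missing calls.

        Markers with no non-missing call get ``NaN``.  Computed blockwise
        in integer arithmetic to avoid a float copy of the whole matrix.
        """
        g = self.genotypes
        m = g.shape[1]
        if self.is_dosage:
            with np.errstate(invalid="ignore"):
                return np.nanmean(g, axis=0) / 2.0
        freqs = np.empty(m)
        block = 16384
        for start in range(0, m, block):
            sl = slice(start, min(start + block, m))
            gb = g[:, sl]
            valid = gb != MISSING
            counts = valid.sum(axis=0)
            sums = np.where(valid, gb, 0).sum(axis=0, dtype=np.int64)
            with np.errstate(divide="ignore", invalid="ignore"):
                freqs[sl] = np.where(counts > 0, sums / (2.0 * counts), np.nan)
        return freqs

    # -- subsetting ---------------------------------------------------------

    def subset_markers(self, index: Sequence[int] | np.ndarray) -> "CohortDataset":
        index = np.asarray(index)
        return CohortDataset(
            genotypes=self.genotypes[:, index].copy(),
            markers=self.markers.iloc[index].reset_index(drop=True),
            samples=self.samples.copy(),
            platform=self.platform,
            study_id=self.study_id,
        )

    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "CohortDataset":
        index = np.asarray(index)
        return CohortDataset(
            genotypes=self.genotypes[index, :].copy(),
            markers=self.markers.copy(),
            samples=self.samples.iloc[index].reset_index(drop=True),
            platform=self.platform,
            study_id=self.study_id,
        )

    def drop_samples(self, sample_ids: Sequence[str]) -> "CohortDataset":
        drop = set(sample_ids)
        keep = [i for i, s in enumerate(self.samples["sample_id"]) if s not in drop]
        return self.subset_samples(keep)

    def copy(self) -> "CohortDataset":
        return CohortDataset(
            genotypes=self.genotypes.copy(),
            markers=self.markers.copy(),
            samples=self.samples.copy(),
            platform=self.platform,
            study_id=self.study_id,
        )


# ---------------------------------------------------------------------------
# genotype-matrix text dialect
# ---------------------------------------------------------------------------
# header: "#sample_ids<TAB>id1<TAB>id2..."  then one row per marker:
# marker_id  chrom  pos  ref  alt  g1 g2 ... (0/1/2/NA or %.4f dosage)


def write_matrix(dataset: CohortDataset, path: str | os.PathLike) -> None:
    """Write a dataset in the genotype-matrix text dialect.

    Hard calls are written as ``0/1/2/NA``; dosage datasets are written with
    4 decimal places.
    """
    g = dataset.genotypes
    dosage = dataset.is_dosage
    with open(path, "w") as fh:
        header_cells = ["#sample_ids"] + [str(s) for s in dataset.sample_ids]
        fh.write("\t".join(header_cells) + "\n")
        mk = dataset.markers
        for j in range(dataset.n_markers):
            row = mk.iloc[j]
            fields = [str(row.marker_id), str(row.chrom), str(int(row.pos)),
                      str(row.ref), str(row.alt)]
            col = g[:, j]
            if dosage:
                fields += ["NA" if np.isnan(v) else f"{v:.4f}" for v in col]
            else:
                fields += ["NA" if v == MISSING else str(int(v)) for v in col]
            fh.write("\t".join(fields) + "\n")


def read_matrix(path: str | os.PathLike, platform: str = "",
                study_id: str | None = None) -> CohortDataset:
    """Read the genotype-matrix text dialect written by :func:`write_matrix`.

    Raises
    ------
    ParseError
        On a ragged row, a bad header, a non-integer position, or positions
        not strictly increasing within a chromosome.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#sample_ids"):
            raise ParseError(f"{path}: line 1: expected '#sample_ids' header")
        parts = header.split("\t")
        sample_ids = parts[1:]
        n = len(sample_ids)
        marker_rows = []
        columns: list[np.ndarray] = []
        dosage_mode = False
        last_pos: dict[str, int] = {}
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5 + n:
                raise ParseError(
                    f"{path}: line {lineno}: expected {5 + n} fields, got {len(fields)}")
            mid, chrom, pos_s, ref, alt = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer position {pos_s!r}")
            if chrom in last_pos and pos <= last_pos[chrom]:
                raise ParseError(
                    f"{path}: line {lineno}: positions not strictly increasing on {chrom}")
            last_pos[chrom] = pos
            marker_rows.append((mid, chrom, pos, ref, alt))
            raw = fields[5:]
            if not dosage_mode and any("." in v for v in raw if v != "NA"):
                dosage_mode = True
            columns.append(np.array(raw, dtype=object))
    markers = pd.DataFrame(marker_rows, columns=MARKER_COLUMNS)
    m = len(columns)
    if dosage_mode:
        geno = np.full((n, m), np.nan)
        for j, raw in enumerate(columns):
            ok = raw != "NA"
            try:
                geno[ok, j] = raw[ok].astype(np.float64)
            except ValueError as e:
                raise ParseError(f"{path}: bad dosage in marker row {j + 1}: {e}")
        if geno[~np.isnan(geno)].size and (
                np.nanmin(geno) < 0 or np.nanmax(geno) > 2):
            raise ParseError(f"{path}: dosage outside [0, 2]")
    else:
        geno = np.full((n, m), MISSING, dtype=np.int8)
        for j, raw in enumerate(columns):
            ok = raw != "NA"
            try:
                vals = raw[ok].astype(np.int64)
            except ValueError as e:
                raise ParseError(f"{path}: bad genotype in marker row {j + 1}: {e}")
            if vals.size and (vals.min() < 0 or vals.max() > 2):
                raise ParseError(f"{path}: genotype outside {{0,1,2}} in row {j + 1}")
            geno[ok, j] = vals.astype(np.int8)
    return CohortDataset(geno, markers, pd.DataFrame({"sample_id": sample_ids}),
                         platform=platform, study_id=study_id)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=cohortgwas
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alt-allele dosage">
"""


def write_vcf(dataset: CohortDataset, path: str | os.PathLike,
              dosages: np.ndarray | None = None) -> None:
    """Write a VCF 4.2 file with GT and, optionally, DS fields.

    ``dosages`` (samples x markers) adds a DS field alongside the hard
    calls; a dosage-mode dataset is written as DS only with GT ``./.``.
    """
    g = dataset.genotypes
    dosage_only = dataset.is_dosage
    fmt = "GT:DS" if (dosages is not None or dosage_only) else "GT"
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, dataset.sample_ids)) + "\n")
        mk = dataset.markers
        for j in range(dataset.n_markers):
            row = mk.iloc[j]
            fields = [str(row.chrom), str(int(row.pos)), str(row.marker_id),
                      str(row.ref), str(row.alt), ".", "PASS", ".", fmt]
            cells = []
            for i in range(dataset.n_samples):
                if dosage_only:
                    d = g[i, j]
                    cells.append("./.:." if np.isnan(d) else f"./.:{d:.4f}")
                elif dosages is not None:
                    d = dosages[i, j]
                    ds = "." if np.isnan(d) else f"{d:.4f}"
                    cells.append(f"{gt_str[int(g[i, j])]}:{ds}")
                else:
                    cells.append(gt_str[int(g[i, j])])
            fh.write("\t".join(fields + cells) + "\n")


def read_vcf(path: str | os.PathLike, platform: str = "",
             study_id: str | None = None,
             prefer_dosage: bool = False) -> CohortDataset:
    """Read a VCF 4.2 file into a :class:`CohortDataset` via cyvcf2.

    GT is parsed to alt-allele counts 0/1/2 (missing -> ``-1``); with
    ``prefer_dosage`` and a DS FORMAT field present, dosages are returned
    instead.  Multi-allelic records raise a :class:`ParseError`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    marker_rows = []
    gt_cols: list[np.ndarray] = []
    ds_cols: list[np.ndarray] = []
    has_ds = True
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ParseError(
                f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS} unsupported")
        marker_rows.append((rec.ID or f"{rec.CHROM}:{rec.POS}", rec.CHROM,
                            rec.POS, rec.REF, rec.ALT[0]))
        gt = np.asarray(rec.gt_types, dtype=np.int8)  # 0,1,2 alt count; 3 = missing
        gt[gt == 3] = MISSING
        gt_cols.append(gt)
        if has_ds:
            try:
                ds = rec.format("DS")
            except KeyError:
                ds = None
            if ds is None:
                has_ds = False
            else:
                ds_cols.append(np.asarray(ds, dtype=np.float64).ravel())
    vcf.close()
    markers = pd.DataFrame(marker_rows, columns=MARKER_COLUMNS)
    samples = pd.DataFrame({"sample_id": sample_ids})
    if prefer_dosage and has_ds and ds_cols:
        geno = np.column_stack(ds_cols)
    elif gt_cols:
        geno = np.column_stack(gt_cols)
    else:
        geno = np.zeros((len(sample_ids), 0), dtype=np.int8)
    return CohortDataset(geno, markers, samples, platform=platform, study_id=study_id)


# ---------------------------------------------------------------------------
# phenotype / generic TSV
# ---------------------------------------------------------------------------


def write_pheno(pheno: pd.DataFrame, path: str | os.PathLike) -> None:
    pheno.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pheno(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: phenotype table lacks columns {missing}")
    return df


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Pipeline thresholds.  Defaults are the published operating points.

    ``max_missing`` — drop markers with missing-call fraction strictly above
    this (0.05).  ``scan_p`` — genome-wide flagging threshold for the
    control-vs-control artifact scan (1e-8).  ``rsq_min``/``maf_min`` —
    post-imputation analysis filters (0.3 / 0.01; markers strictly below are
    excluded).  ``n_pcs`` — principal components used as covariates (4).
    The duplicate/sibling Z windows and the 0.999 concordance cutoff are the
    printed classification rules.
    """

    max_missing: float = 0.05
    scan_p: float = 1e-8
    rsq_min: float = 0.3
    maf_min: float = 0.01
    n_pcs: int = 4
    concordance_cutoff: float = 0.999
    dup_z0: tuple[float, float] = (0.0, 0.1)
    dup_z1: tuple[float, float] = (0.0, 0.1)
    dup_z2: tuple[float, float] = (0.9, 1.1)
    sib_z0: tuple[float, float] = (0.17, 0.33)
    sib_z1: tuple[float, float] = (0.4, 0.6)
    sib_z2: tuple[float, float] = (0.17, 0.33)
    half_z1: tuple[float, float] = (0.4, 0.6)
    half_z2: tuple[float, float] = (0.0, 0.1)
    ld_r2_max: float = 0.2
    ld_window: int = 50
    ld_step: int = 5
    outlier_sd: float = 6.0
    min_expected_mac: float = 10.0
    mac_diploid: bool = False
    seed: int = 0

    _UNIT = {"max_missing", "scan_p", "rsq_min", "maf_min", "ld_r2_max",
             "concordance_cutoff"}
    _POSITIVE = {"n_pcs", "ld_window", "ld_step", "outlier_sd",
                 "min_expected_mac"}

    def validate(self) -> "RunConfig":
        for key in self._UNIT:
            v = getattr(self, key)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{key}={v} outside [0, 1]")
        for key in self._POSITIVE:
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be positive")
        for key in ("dup_z0", "dup_z1", "dup_z2", "sib_z0", "sib_z1",
                    "sib_z2", "half_z1", "half_z2"):
            lo, hi = getattr(self, key)
            if lo > hi:
                raise ConfigError(f"{key}: lower bound {lo} exceeds upper {hi}")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def load_config(path_or_stream) -> RunConfig:
    """Load a YAML config; missing keys take defaults, all values validated.

    Raises :class:`ConfigError` naming the offending key for out-of-domain
    values and for unknown keys.
    """
    if isinstance(path_or_stream, (str, os.PathLike)):
        with open(path_or_stream) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(path_or_stream)
    raw = raw or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in raw.items():
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    try:
        cfg = RunConfig(**kwargs)
    except TypeError as e:
        raise ConfigError(str(e))
    return cfg.validate()


def dump_config(cfg: RunConfig, path: str | os.PathLike | None = None) -> str:
    text = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
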