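"""Association testing, genomic control, and fixed-effects meta-analysis.

Per-marker models follow the published analysis plan: the imputed
alt-allele dosage (0–2) enters as a covariate in OLS (quantitative trait)
or logistic regression (binary trait), with study-indicator, age and
principal-component covariates.  Platform-family results are pooled by
inverse-variance fixed-effects meta-analysis with Cochran's Q for
heterogeneity, and the genomic inflation factor lambda is the median Wald
chi-square over its null median 0.45494.

Genome-wide linear scans use exact Frisch–Waugh–Lovell residualization
(numerically identical to full OLS, verified against a normal-equations
oracle in the test suite); logistic fits use iteratively reweighted least
squares with a separation guard (|beta| > 15 or 25 iterations marks the
fit non-convergent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CHI2_1_MEDIAN = 0.45494  # median of the chi-square(1) distribution

MAX_IRLS_ITER = 25
SEPARATION_BETA = 15.0


class CollinearityError(ValueError):
    """Design matrix is rank deficient; message names the column."""


@dataclass
class AssocResult:
    marker_id: str
    beta: float
    se: float
    z: float
    p: float
    n: int
    n_cases: int | None = None
    platform: str = ""
    freq: float = np.nan
    converged: bool = True


@dataclass
class MetaResult:
    marker_id: str
    beta: float
    se: float
    z: float
    p: float
    q: float
    df: int
    p_het: float
    direction: str
    k: int


@dataclass
class InflationStat:
    lam: float
    n_markers: int


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------


def build_covariates(pheno: pd.DataFrame, pcs: np.ndarray | None = None,
                     include_age: bool = True, n_pcs: int = 4) -> np.ndarray:
    """Intercept + study-stratum indicators (+ age) (+ top PCs).

    Study strata are (cohort x primary outcome) combinations; the first
    stratum alphabetically is the reference level.
    """
    n = len(pheno)
    cols: list[np.ndarray] = [np.ones(n)]
    strata = (pheno["cohort"].astype(str) + ":" +
              pheno["primary_outcome"].astype(str))
    levels = sorted(strata.unique())
    for lev in levels[1:]:
        cols.append((strata == lev).to_numpy(dtype=np.float64))
    if include_age:
        cols.append(pheno["age"].to_numpy(dtype=np.float64))
    x = np.column_stack(cols)
    if pcs is not None and n_pcs > 0:
        x = np.column_stack([x, np.asarray(pcs, dtype=np.float64)[:, :n_pcs]])
    return x


def _check_rank(x: np.ndarray, names: list[str] | None = None) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the first column whose removal restores full column rank
        for j in range(x.shape[1]):
            sub = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                name = names[j] if names else f"column {j}"
                raise CollinearityError(f"design is rank deficient at {name}")
        raise CollinearityError("design is rank deficient")


# ---------------------------------------------------------------------------
# linear association
# ---------------------------------------------------------------------------


def linear_assoc(dosages: np.ndarray, y: np.ndarray,
                 covariates: np.ndarray | None = None,
                 marker_id: str = "", platform: str = "") -> AssocResult:
    """OLS of y on dosage with an intercept and optional covariates;
    Wald test on the dosage coefficient (two-sided normal tail).
    """
    g = np.asarray(dosages, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if np.isnan(y).any():
        raise ValueError("y contains missing values")
    n = y.size
    c = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]) if not _has_intercept(covariates) else np.asarray(
        covariates, dtype=np.float64)
    x = np.column_stack([c, g])
    names = [f"covariate_{j}" for j in range(c.shape[1])] + ["dosage"]
    names[0] = "intercept"
    _check_rank(x, names)
    xtx = x.T @ x
    beta_all = np.linalg.solve(xtx, x.T @ y)
    resid = y - x @ beta_all
    df = n - x.shape[1]
    sigma2 = float(resid @ resid) / max(df, 1)
    cov = sigma2 * np.linalg.inv(xtx)
    beta = float(beta_all[-1])
    se = float(np.sqrt(cov[-1, -1]))
    z = beta / se if se > 0 else np.inf * np.sign(beta)
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return AssocResult(marker_id, beta, se, z, p, n, platform=platform,
                       freq=float(np.mean(g) / 2.0))


def _has_intercept(c: np.ndarray) -> bool:
    c = np.asarray(c)
    if c.ndim == 1:
        return False
    return any(np.allclose(c[:, j], c[0, j]) and c[0, j] != 0 for j in range(c.shape[1]))


def linear_scan(dosage_matrix: np.ndarray, y: np.ndarray,
                covariates: np.ndarray, marker_ids=None,
                platform: str = "", block: int = 4096,
                missing_value: float = -1) -> pd.DataFrame:
    """Genome-wide per-marker OLS via exact FWL residualization.

    ``covariates`` must include the intercept column.  Monomorphic markers
    (zero residual variance after projection) get NaN statistics.  Integer
    hard-call input may contain ``missing_value`` codes, which are
    mean-imputed per marker (blockwise, so the full matrix is never copied
    to float); float dosage input must be complete.
    """
    y = np.asarray(y, dtype=np.float64)
    c = np.asarray(covariates, dtype=np.float64)
    _check_rank(c)
    q, _ = np.linalg.qr(c)
    y_r = y - q @ (q.T @ y)
    yty = float(y_r @ y_r)
    n, p = c.shape
    df = n - p - 1
    m = dosage_matrix.shape[1]
    hard_calls = np.issubdtype(np.asarray(dosage_matrix).dtype, np.integer)
    beta = np.empty(m)
    se = np.empty(m)
    freq = np.empty(m)
    for start in range(0, m, block):
        sl = slice(start, min(start + block, m))
        g = np.asarray(dosage_matrix[:, sl], dtype=np.float64)
        if hard_calls:
            miss = g == missing_value
            if miss.any():
                g[miss] = np.nan
                col_mean = np.nanmean(g, axis=0)
                ii, jj = np.nonzero(miss)
                g[ii, jj] = col_mean[jj]
        freq[sl] = g.mean(axis=0) / 2.0
        g_r = g - q @ (q.T @ g)
        gg = np.einsum("ij,ij->j", g_r, g_r)
        gy = g_r.T @ y_r
        with np.errstate(divide="ignore", invalid="ignore"):
            b = gy / gg
            rss = yty - b * gy
            s2 = rss / df
            se_b = np.sqrt(s2 / gg)
        bad = gg <= 1e-10
        b[bad] = np.nan
        se_b[bad] = np.nan
        beta[sl] = b
        se[sl] = se_b
    with np.errstate(invalid="ignore"):
        z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    ids = marker_ids if marker_ids is not None else [f"m{j}" for j in range(m)]
    return pd.DataFrame({"marker_id": ids, "beta": beta, "se": se, "z": z,
                         "p": pvals, "n": n, "freq": freq,
                         "platform": platform})


# ---------------------------------------------------------------------------
# logistic association
# ---------------------------------------------------------------------------


def _irls(x: np.ndarray, y: np.ndarray):
    """Logistic IRLS with separation guard.

    Returns (beta, cov, converged).
    """
    n, p = x.shape
    beta = np.zeros(p)
    converged = False
    xtwx = None
    for _ in range(MAX_IRLS_ITER):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        xtwx = x.T @ (x * w[:, None])
        score = x.T @ (y - mu)
        try:
            step = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError:
            break
        beta_new = beta + step
        if np.max(np.abs(beta_new)) > SEPARATION_BETA:
            beta = beta_new
            break
        if np.max(np.abs(step)) < 1e-8:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    if xtwx is None:
        raise np.linalg.LinAlgError("IRLS failed at initialization")
    eta = x @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    xtwx = x.T @ (x * w[:, None])
    cov = np.linalg.inv(xtwx)
    if np.max(np.abs(beta)) > SEPARATION_BETA:
        converged = False
    return beta, cov, converged


def logistic_assoc(dosages: np.ndarray, case_status: np.ndarray,
                   covariates: np.ndarray | None = None,
                   marker_id: str = "", platform: str = "") -> AssocResult:
    """Logistic regression of case status on dosage; Wald test on the
    dosage coefficient.  Raises if only one outcome class is present;
    non-convergent (separated) fits are returned flagged.
    """
    g = np.asarray(dosages, dtype=np.float64)
    y = np.asarray(case_status, dtype=np.float64)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("case_status has a single class")
    n = y.size
    if covariates is None:
        c = np.ones((n, 1))
    elif _has_intercept(covariates):
        c = np.asarray(covariates, dtype=np.float64)
    else:
        c = np.column_stack([np.ones(n), covariates])
    x = np.column_stack([c, g])
    _check_rank(x)
    beta_all, cov, converged = _irls(x, y)
    beta = float(beta_all[-1])
    se = float(np.sqrt(cov[-1, -1]))
    z = beta / se if se > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return AssocResult(marker_id, beta, se, z, p, n,
                       n_cases=int(y.sum()), platform=platform,
                       freq=float(np.mean(g) / 2.0), converged=converged)


def logistic_scan_2param(genotypes: np.ndarray, case_status: np.ndarray,
                         marker_ids=None, block: int = 8192,
                         missing_value: int = -1) -> pd.DataFrame:
    """Intercept+genotype logistic regression across many hard-call markers.

    Used by the control-vs-control artifact scan (no covariates, per the
    published QC regressions).  Because the predictor takes only the
    values {0, 1, 2}, the per-marker 2x3 case/control-by-genotype table is
    a sufficient statistic; the IRLS iterations run on cell counts, which
    is exact and orders of magnitude faster than per-sample fits.  Missing
    genotypes are complete-cased per marker.  Separation guard as in
    :func:`_irls`; non-convergent and monomorphic markers get NaN p.
    """
    g_all = np.asarray(genotypes)
    if not np.issubdtype(g_all.dtype, np.integer):
        raise ValueError("batch logistic scan requires hard-call genotypes")
    y = np.asarray(case_status, dtype=np.float64)
    m = g_all.shape[1]
    n1 = np.empty((3, m))   # case counts per genotype value
    nt = np.empty((3, m))   # total non-missing counts per genotype value
    for start in range(0, m, block):
        sl = slice(start, min(start + block, m))
        gb = g_all[:, sl]
        for v in (0, 1, 2):
            mask = (gb == v)
            nt[v, sl] = mask.sum(axis=0)
            n1[v, sl] = y @ mask
    gvals = np.array([0.0, 1.0, 2.0])[:, None]

    counts_ok = nt.sum(axis=0) > 0
    present = nt > 0
    mono = present.sum(axis=0) < 2
    b0 = np.zeros(m)
    b1 = np.zeros(m)
    conv = np.zeros(m, dtype=bool)
    active = counts_ok & ~mono
    for _ in range(MAX_IRLS_ITER):
        if not active.any():
            break
        eta = b0[None, :] + gvals * b1[None, :]
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = nt * mu * (1.0 - mu)
        r = n1 - nt * mu
        s00 = w.sum(axis=0)
        s01 = (w * gvals).sum(axis=0)
        s11 = (w * gvals**2).sum(axis=0)
        u0 = r.sum(axis=0)
        u1 = (r * gvals).sum(axis=0)
        det = s00 * s11 - s01 * s01
        ok = active & (det > 1e-12)
        safe = np.where(det > 1e-12, det, 1.0)
        step0 = np.where(ok, (s11 * u0 - s01 * u1) / safe, 0.0)
        step1 = np.where(ok, (s00 * u1 - s01 * u0) / safe, 0.0)
        b0 += step0
        b1 += step1
        sep = (np.abs(b0) > SEPARATION_BETA) | (np.abs(b1) > SEPARATION_BETA)
        done = ok & (np.maximum(np.abs(step0), np.abs(step1)) < 1e-8)
        conv |= done & ~sep
        active &= ~done & ~sep & ok
    # Wald SE from the information matrix at the solution
    eta = b0[None, :] + gvals * b1[None, :]
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = nt * mu * (1.0 - mu)
    s00 = w.sum(axis=0)
    s01 = (w * gvals).sum(axis=0)
    s11 = (w * gvals**2).sum(axis=0)
    det = s00 * s11 - s01 * s01
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(np.where(det > 0, s00 / det, np.nan))
    conv &= ~((np.abs(b0) > SEPARATION_BETA) | (np.abs(b1) > SEPARATION_BETA))
    with np.errstate(invalid="ignore"):
        z = b1 / se1
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals[~conv] = np.nan
    z = np.where(conv, z, np.nan)
    ids = marker_ids if marker_ids is not None else [f"m{j}" for j in range(m)]
    return pd.DataFrame({"marker_id": ids, "beta": b1, "se": se1, "z": z,
                         "p": pvals, "converged": conv})


# ---------------------------------------------------------------------------
# screens and diagnostics
# ---------------------------------------------------------------------------


def min_case_screen(n_cases: int, maf: float,
                    min_expected_mac: float = 10.0,
                    diploid: bool = False) -> bool:
    """Expected-case-minor-allele-count screen for rare binary traits.

    The expected MAC is ``n_cases * maf`` (per-genotype convention, which
    reproduces the published boundary: 200 cases at MAF 0.05 -> 10 ->
    pass); set ``diploid`` for the 2-alleles-per-genotype convention.
    Passes when the expected count reaches the threshold.
    """
    if not (0.0 < maf <= 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    if min_expected_mac <= 0:
        raise ValueError("min_expected_mac must be > 0")
    mult = 2.0 if diploid else 1.0
    return bool(n_cases * maf * mult >= min_expected_mac)


def genomic_lambda(z_or_results) -> InflationStat:
    """Genomic inflation factor: median Wald chi-square / 0.45494.

    Accepts an array of Wald z statistics or a results DataFrame with a
    ``z`` column; NaNs (unfit markers) are ignored.  Requires >= 100
    usable markers.
    """
    if isinstance(z_or_results, pd.DataFrame):
        z = z_or_results["z"].to_numpy()
    else:
        z = np.asarray(z_or_results, dtype=np.float64)
    z = z[np.isfinite(z)]
    if z.size < 100:
        raise ValueError(f"need >= 100 markers for lambda, got {z.size}")
    lam = float(np.median(z**2) / CHI2_1_MEDIAN)
    return InflationStat(lam=lam, n_markers=z.size)


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------


def _direction(betas: np.ndarray) -> str:
    return "".join("?" if not np.isfinite(b) else ("+" if b > 0 else "-")
                   for b in betas)


def fixed_effects_meta(results: list[AssocResult] | pd.DataFrame,
                       marker_id: str = "") -> MetaResult:
    """Inverse-variance fixed-effects pooling of one marker's results.

    ``w_i = 1/se_i^2``; pooled beta is the weighted mean, pooled
    ``se = (sum w)^(-1/2)``.  All inputs must be on the same alt-allele
    orientation (enforced upstream by the merge).
    """
    if isinstance(results, pd.DataFrame):
        betas = results["beta"].to_numpy(dtype=np.float64)
        ses = results["se"].to_numpy(dtype=np.float64)
    else:
        betas = np.array([r.beta for r in results], dtype=np.float64)
        ses = np.array([r.se for r in results], dtype=np.float64)
        if not marker_id and results:
            marker_id = results[0].marker_id
    if betas.size < 1:
        raise ValueError("need at least one study")
    if np.any(ses <= 0) or np.any(~np.isfinite(ses)):
        raise ValueError("standard errors must be positive and finite")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    if betas.size >= 2:
        q, df, p_het = cochran_q_from_arrays(betas, ses)
    else:
        q, df, p_het = 0.0, 0, 1.0
    return MetaResult(marker_id, beta, se, z, p, q, df, p_het,
                      _direction(betas), k=betas.size)


def cochran_q_from_arrays(betas: np.ndarray, ses: np.ndarray):
    w = 1.0 / np.asarray(ses, dtype=np.float64)**2
    betas = np.asarray(betas, dtype=np.float64)
    pooled = np.sum(w * betas) / np.sum(w)
    q = float(np.sum(w * (betas - pooled)**2))
    df = betas.size - 1
    p_het = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    return q, df, p_het


def cochran_q(results: list[AssocResult] | pd.DataFrame):
    """Cochran's Q heterogeneity statistic; requires k >= 2 studies."""
    if isinstance(results, pd.DataFrame):
        betas = results["beta"].to_numpy(dtype=np.float64)
        ses = results["se"].to_numpy(dtype=np.float64)
    else:
        betas = np.array([r.beta for r in results], dtype=np.float64)
        ses = np.array([r.se for r in results], dtype=np.float64)
    if betas.size < 2:
        raise ValueError("Cochran's Q needs at least two studies")
    return cochran_q_from_arrays(betas, ses)


def meta_analyze_scans(scans: list[pd.DataFrame]) -> pd.DataFrame:
    """Meta-analyze per-platform scan tables marker-by-marker.

    Markers present (with finite beta and se) in at least one platform are
    pooled; the direction string covers the platforms in input order with
    ``?`` for a platform missing that marker.
    """
    betas, ses = [], []
    for scan in scans:
        betas.append(scan.set_index("marker_id")["beta"])
        ses.append(scan.set_index("marker_id")["se"])
    b = pd.concat(betas, axis=1, keys=range(len(scans)))
    s = pd.concat(ses, axis=1, keys=range(len(scans)))
    bv = b.to_numpy(dtype=np.float64)
    sv = s.to_numpy(dtype=np.float64)
    ok = np.isfinite(bv) & np.isfinite(sv) & (sv > 0)
    w = np.where(ok, 1.0 / np.where(ok, sv, 1.0)**2, 0.0)
    wsum = w.sum(axis=1)
    usable = wsum > 0
    pooled = np.where(usable, (w * np.where(ok, bv, 0.0)).sum(axis=1)
                      / np.where(usable, wsum, 1.0), np.nan)
    se = np.where(usable, 1.0 / np.sqrt(np.where(usable, wsum, 1.0)), np.nan)
    with np.errstate(invalid="ignore"):
        z = pooled / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    dev = np.where(ok, (bv - pooled[:, None])**2 * w, 0.0)
    q = dev.sum(axis=1)
    k = ok.sum(axis=1)
    df = np.maximum(k - 1, 0)
    p_het = np.where(df > 0, stats.chi2.sf(q, np.maximum(df, 1)), 1.0)
    direction = ["".join("?" if not o else ("+" if v > 0 else "-")
                         for o, v in zip(okr, bvr))
                 for okr, bvr in zip(ok, bv)]
    out = pd.DataFrame({
        "marker_id": b.index, "beta": pooled, "se": se, "z": z, "p": p,
        "q": q, "df": df, "p_het": p_het, "k": k, "direction": direction,
    })
    return out[usable].reset_index(drop=True)


# ---------------------------------------------------------------------------
# replication lookup
# ---------------------------------------------------------------------------


def replication_lookup(meta: pd.DataFrame, known: pd.DataFrame,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Check known loci against meta-analysis results.

    ``known`` columns: ``marker_id``, ``published_direction`` ('+'/'-').
    Output per locus: found flag, p < alpha flag, direction concordance.
    Markers absent from the results are reported found=False, not errors.
    """
    idx = meta.set_index("marker_id")
    rows = []
    for _, rec in known.iterrows():
        m = rec["marker_id"]
        if m in idx.index:
            r = idx.loc[m]
            concordant = (np.sign(r["beta"]) > 0) == (rec["published_direction"] == "+")
            rows.append({"marker_id": m, "found": True, "p": r["p"],
                         "significant": bool(r["p"] < alpha),
                         "direction_concordant": bool(concordant)})
        else:
            rows.append({"marker_id": m, "found": False, "p": np.nan,
                         "significant": False, "direction_concordant": False})
    return pd.DataFrame(rows, columns=["marker_id", "found", "p",
                                       "significant", "direction_concordant"])


def replication_summary(table: pd.DataFrame) -> dict:
    return {
        "n_known": int(len(table)),
        "n_found": int(table["found"].sum()),
        "n_significant": int(table["significant"].sum()),
        "n_concordant": int(table["direction_concordant"].sum()),
    }
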