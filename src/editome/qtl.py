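"""Trait association and editing-QTL mapping with permutation FDR.

Editing ratios are linked to clinical traits and to genotype dosages by
covariate-adjusted ordinary least squares, MatrixEQTL-style: the
response and the tested variable are residualized against the covariate
design once, and the slope, t statistic and p-value follow from the
partial regression. Significance is adjusted by permutations that
scramble the sample labels of the editing matrix jointly across sites,
breaking the link between samples and measurements while preserving
inter-site correlation. Rank-based inverse-normal transformation, with
ties broken randomly by a seeded generator, puts traits and ratios on a
standard-normal scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import EditingMatrix


def rank_normal(
    values: Sequence[float] | np.ndarray, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Rank-based inverse-normal transform with random tie-breaking.

    Non-missing entries are replaced by Phi^-1((rank - 0.5) / n) where
    ranks are 1..n; tied values receive distinct ranks in an order drawn
    from the seeded generator. Missing (NaN) entries stay missing.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    arr = np.asarray(values, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = np.isfinite(arr)
    vals = arr[mask]
    n = vals.size
    if n < 3:
        raise ValueError("rank_normal needs at least 3 non-missing values")
    if np.unique(vals).size == 1:
        import warnings

        warnings.warn("all values identical; ranks are purely random", stacklevel=2)
    tie_break = rng.permutation(n)
    order = np.lexsort((tie_break, vals))
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    out[mask] = stats.norm.ppf((ranks - 0.5) / n)
    return out


@dataclass
class OLSResult:
    beta: float
    t_statistic: float
    p_value: float
    r_squared: float
    n_used: int


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), covariates])


def _check_full_rank(D: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(D, pivoting=True)
        bad = sorted(names[i] for i in piv[rank:])
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")


def _batch_ols(
    Y: np.ndarray, x: np.ndarray, covariates: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of each column of Y on [1, covariates, x].

    Returns (beta, t, p, r_squared) arrays over Y's columns. Y must be
    free of NaN; r_squared is the full-model coefficient of
    determination.
    """
    n = x.size
    D = _design(n, covariates)
    k = D.shape[1]
    Q, _ = np.linalg.qr(D)
    rx = x - Q @ (Q.T @ x)
    bxx = float(rx @ rx)
    if bxx <= 1e-12 * n:
        raise ValueError("tested variable has no variance after adjustment")
    Y2 = Y if Y.ndim == 2 else Y[:, None]
    RY = Y2 - Q @ (Q.T @ Y2)
    beta = (rx @ RY) / bxx
    rss = (RY**2).sum(axis=0) - beta**2 * bxx
    df = n - k - 1
    if df <= 0:
        raise ValueError("not enough samples for the number of predictors")
    sigma2 = np.maximum(rss, 0.0) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(sigma2 / bxx)
    t = np.where(sigma2 <= 0, np.inf * np.sign(beta), t)
    p = 2 * stats.t.sf(np.abs(t), df)
    tss = ((Y2 - Y2.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1 - np.maximum(rss, 0.0) / tss, np.nan)
    return beta, t, p, r2


def ols_association(
    y: Sequence[float],
    x: Sequence[float],
    covariates: pd.DataFrame | np.ndarray | None = None,
    covariate_names: Sequence[str] | None = None,
) -> OLSResult:
    """OLS of y on [intercept, x, covariates] with a two-sided t test.

    Missing values (NaN in y or x) are dropped pairwise. Raises on a
    rank-deficient design, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        covariate_names = list(covariates.columns)
        covariates = covariates.to_numpy(dtype=float)
    mask = np.isfinite(y) & np.isfinite(x)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != y.size:
            covariates = covariates.T
        mask &= np.isfinite(covariates).all(axis=1)
        covariates = covariates[mask]
    yv, xv = y[mask], x[mask]
    n = int(mask.sum())
    names = ["intercept", "x"] + list(
        covariate_names
        or ([] if covariates is None else [f"cov{i}" for i in range(covariates.shape[1])])
    )
    D_full = np.column_stack(
        [np.ones(n), xv] + ([covariates] if covariates is not None else [])
    )
    if n <= D_full.shape[1]:
        raise ValueError("need n > number of predictors + 1")
    _check_full_rank(D_full, names)
    beta, t, p, r2 = _batch_ols(yv[:, None], xv, covariates)
    return OLSResult(
        beta=float(beta[0]),
        t_statistic=float(t[0]),
        p_value=float(p[0]),
        r_squared=float(r2[0]),
        n_used=n,
    )


def _pair_stats(
    y: np.ndarray, x: np.ndarray, C: np.ndarray | None
) -> tuple[float, float, float, float, int]:
    """Masked single-pair OLS used when NaN patterns differ per site."""
    mask = np.isfinite(y) & np.isfinite(x)
    if C is not None:
        mask &= np.isfinite(C).all(axis=1)
    n = int(mask.sum())
    Cm = C[mask] if C is not None else None
    beta, t, p, r2 = _batch_ols(y[mask][:, None], x[mask], Cm)
    return float(beta[0]), float(t[0]), float(p[0]), float(r2[0]), n


def encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design columns from a covariate table.

    Numeric columns pass through; object/categorical columns (sex,
    laboratory, batch) are one-hot encoded dropping the first level so
    the design stays full rank alongside the intercept.
    """
    numeric = covariates.select_dtypes(include=[np.number])
    categorical = covariates.drop(columns=numeric.columns)
    if categorical.shape[1]:
        dummies = pd.get_dummies(
            categorical.astype(str), drop_first=True, dtype=float
        )
        return pd.concat([numeric.astype(float), dummies], axis=1)
    return numeric.astype(float)


def _perm_adjusted(obs_p: float, perm_ps: np.ndarray) -> float:
    """Permutation-adjusted p with the +1 correction: (1+b)/(1+N)."""
    return (1 + int((perm_ps <= obs_p).sum())) / (1 + perm_ps.size)


@dataclass
class ClinicalScanResult:
    results: pd.DataFrame  # site, trait, beta, t, p, r_squared, adjusted_p, ...
    skipped: list[tuple[str, str, str]]  # (site, trait, reason)


def clinical_association_scan(
    matrix: EditingMatrix,
    traits: pd.DataFrame,
    covariates: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    site_genes: Mapping[str, Sequence[str]] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    min_samples: int = 50,
    r2_threshold: float = 0.4,
    expression_p_gate: float = 0.05,
    adjust: str = "maxT",
) -> ClinicalScanResult:
    """Scan (site, trait) pairs for association of editing with traits.

    Traits are rank-normal transformed; the site's editing ratio is
    regressed on the transformed trait plus covariates. Only sites with
    non-zero ratios in strictly more than ``min_samples`` samples are
    tested. The permutation null scrambles the editing matrix's sample
    labels; ``adjust='maxT'`` compares each observed p to the per-trait
    distribution of the minimum p across sites (family-wise, the
    stricter reading), ``adjust='pooled'`` compares to the same pair's
    own permutation p-values. A pair is flagged significant when (i)
    adjusted p < 0.05, (ii) full-model R-squared > ``r2_threshold``, and
    (iii) no overlapping gene's expression correlates with the trait at
    nominal p <= ``expression_p_gate``.
    """
    if adjust not in {"maxT", "pooled"}:
        raise ValueError("adjust must be 'maxT' or 'pooled'")
    rng = np.random.default_rng(seed)
    samples = [
        s
        for s in matrix.ratios.columns
        if s in traits.index and s in covariates.index
    ]
    det = matrix.detected()[samples]
    sites = [s for s in matrix.ratios.index if det.loc[s].sum() > min_samples]
    C = encode_covariates(covariates.loc[samples]).to_numpy(dtype=float)
    Y = matrix.ratios.loc[sites, samples].to_numpy(dtype=float).T  # n x m
    n = len(samples)
    perms = [rng.permutation(n) for _ in range(n_perm)]

    rows = []
    skipped: list[tuple[str, str, str]] = []
    for trait in traits.columns:
        x_raw = traits.loc[samples, trait].to_numpy(dtype=float)
        if np.isfinite(x_raw).sum() < 3:
            skipped.append(("*", trait, "too few non-missing trait values"))
            continue
        x = rank_normal(x_raw, rng)
        obs = np.full((len(sites), 4), np.nan)
        for j, site in enumerate(sites):
            try:
                b, t, p, r2, nu = _pair_stats(Y[:, j], x, C)
            except ValueError as exc:
                skipped.append((site, trait, str(exc)))
                continue
            obs[j] = (b, t, p, r2)
        tested = np.isfinite(obs[:, 2])
        # permutation null: scramble editing-sample labels jointly
        perm_p = np.full((n_perm, len(sites)), np.nan)
        for pi, perm in enumerate(perms):
            Yp = Y[perm]
            for j in np.flatnonzero(tested):
                try:
                    perm_p[pi, j] = _pair_stats(Yp[:, j], x, C)[2]
                except ValueError:
                    perm_p[pi, j] = 1.0
        null_min = np.nanmin(perm_p, axis=1) if tested.any() else np.array([])
        for j in np.flatnonzero(tested):
            b, t, p, r2 = obs[j]
            if adjust == "maxT":
                adj = _perm_adjusted(p, null_min)
            else:
                adj = _perm_adjusted(p, perm_p[:, j][np.isfinite(perm_p[:, j])])
            gate_ok = True
            if expression is not None and site_genes is not None:
                for gid in site_genes.get(sites[j], []):
                    if gid not in expression.columns:
                        continue
                    gp = ols_association(
                        expression.loc[samples, gid].to_numpy(dtype=float), x, C
                    ).p_value
                    if gp <= expression_p_gate:
                        gate_ok = False
            rows.append(
                {
                    "site": sites[j],
                    "trait": trait,
                    "beta": b,
                    "t_statistic": t,
                    "p_value": p,
                    "r_squared": r2,
                    "adjusted_p": adj,
                    "n_used": int(np.isfinite(Y[:, j] + x).sum()),
                    "expression_gate_ok": gate_ok,
                    "significant": bool(
                        adj < 0.05 and r2 > r2_threshold and gate_ok
                    ),
                }
            )
    return ClinicalScanResult(results=pd.DataFrame(rows), skipped=skipped)


@dataclass
class EdqtlScanResult:
    results: pd.DataFrame
    skipped: list[tuple[str, str, str]]


def _maf(dosages: np.ndarray) -> float:
    m = np.isfinite(dosages)
    if not m.any():
        return 0.0
    f = float(dosages[m].mean()) / 2.0
    return min(f, 1 - f)


def edqtl_scan(
    matrix: EditingMatrix,
    genotypes: pd.DataFrame,
    snp_meta: pd.DataFrame,
    covariates: pd.DataFrame,
    n_perm: int = 1_000,
    seed: int = 0,
    min_detected: int = 40,
    min_support_reads: int = 5,
    maf_min: float = 0.05,
    min_group_n: int = 20,
    min_groups: int = 2,
    adj_threshold: float = 0.20,
    sex_chroms: Iterable[str] = ("chrX", "chrY", "X", "Y"),
) -> EdqtlScanResult:
    """Map editing-ratio QTLs over all (site, SNP) pairs.

    Sites must be detected in strictly more than ``min_detected`` samples
    and lie on autosomes; cells supported by fewer than
    ``min_support_reads`` edited reads are masked, then each site's
    ratios are rank-normal transformed. SNPs need MAF > ``maf_min``.
    Each pair additionally requires at least ``min_group_n`` subjects in
    at least ``min_groups`` dosage groups. All pairs are tested
    regardless of genomic distance; cis means same chromosome. The
    permutation FDR scrambles sample labels of the editing matrix
    (``n_perm`` relabelings, one per permutation, shared across sites);
    adjusted p = (1 + #{perm p <= observed p}) / (1 + n_perm), and a pair
    is significant below ``adj_threshold``. The minimum-p association
    per site is flagged as the index edQTL.
    """
    rng = np.random.default_rng(seed)
    sex = set(sex_chroms)
    samples = [
        s
        for s in matrix.ratios.columns
        if s in genotypes.index and s in covariates.index
    ]
    det = matrix.detected()[samples]
    sites = [
        s
        for s in matrix.ratios.index
        if matrix.site_meta.loc[s, "chrom"] not in sex
        and det.loc[s].sum() > min_detected
    ]
    ratios = matrix.ratios.loc[sites, samples].copy()
    ratios[matrix.support.loc[sites, samples] < min_support_reads] = np.nan
    Y = np.full((len(samples), len(sites)), np.nan)
    for j, site in enumerate(sites):
        vals = ratios.loc[site].to_numpy(dtype=float)
        if np.isfinite(vals).sum() >= 3:
            Y[:, j] = rank_normal(vals, rng)
    C = encode_covariates(covariates.loc[samples]).to_numpy(dtype=float)
    snps = [s for s in genotypes.columns if _maf(
        genotypes.loc[samples, s].to_numpy(dtype=float)) > maf_min]

    perms = [rng.permutation(len(samples)) for _ in range(n_perm)]
    no_missing = np.isfinite(Y).all()

    rows = []
    skipped: list[tuple[str, str, str]] = []
    site_chrom = matrix.site_meta["chrom"]
    for snp in snps:
        x = genotypes.loc[samples, snp].to_numpy(dtype=float)
        snp_chrom = str(snp_meta.loc[snp, "chrom"]) if snp in snp_meta.index else ""
        for j, site in enumerate(sites):
            y = Y[:, j]
            mask = np.isfinite(y) & np.isfinite(x)
            groups = pd.Series(x[mask]).value_counts()
            if (groups >= min_group_n).sum() < min_groups:
                skipped.append((site, snp, "genotype-group condition unmet"))
                continue
            try:
                b, t, p, r2, nu = _pair_stats(y, x, C)
            except ValueError as exc:
                skipped.append((site, snp, str(exc)))
                continue
            rows.append(
                {
                    "site": site,
                    "snp": snp,
                    "beta": b,
                    "t_statistic": t,
                    "p_value": p,
                    "r_squared": r2,
                    "n_used": nu,
                    "_j": j,
                    "cis_trans": "cis"
                    if snp_chrom and snp_chrom == site_chrom.loc[site]
                    else "trans",
                }
            )
    res = pd.DataFrame(rows)
    if res.empty:
        return EdqtlScanResult(results=res, skipped=skipped)

    # permutation p-values, one joint relabeling per permutation
    perm_counts = np.zeros(len(res), dtype=int)
    obs_p = res["p_value"].to_numpy()
    by_snp = res.groupby("snp", sort=False).indices
    xcache = {
        snp: genotypes.loc[samples, snp].to_numpy(dtype=float) for snp in by_snp
    }
    for perm in perms:
        Yp = Y[perm]
        for snp, idx in by_snp.items():
            x = xcache[snp]
            js = res["_j"].to_numpy()[idx]
            if no_missing and np.isfinite(x).all():
                pp = _batch_ols(Yp[:, js], x, C)[2]
            else:
                pp = np.array(
                    [_pair_stats(Yp[:, j], x, C)[2] for j in js]
                )
            perm_counts[idx] += pp <= obs_p[idx]
    res["adjusted_p"] = (1 + perm_counts) / (1 + n_perm)
    res["significant"] = res["adjusted_p"] < adj_threshold
    res["index_edqtl"] = False
    idxmin = res.groupby("site")["p_value"].idxmin()
    res.loc[idxmin, "index_edqtl"] = True
    return EdqtlScanResult(
        results=res.drop(columns="_j").reset_index(drop=True), skipped=skipped
    )


def eqtl_overlap(
    edqtl_results: pd.DataFrame,
    expression: pd.DataFrame,
    genotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    site_genes: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag edQTLs whose SNP is also an eQTL for a gene overlapping the site.

    For each edQTL the same SNP is tested against each overlapping
    gene's expression by covariate-adjusted OLS; p-values are adjusted
    across all such tests with Benjamini-Hochberg, and the flag is set
    when any overlapping gene reaches adjusted p < alpha. edQTLs whose
    site overlaps no gene get a missing (NA) flag.
    """
    samples = [
        s
        for s in expression.index
        if s in genotypes.index and s in covariates.index
    ]
    C = encode_covariates(covariates.loc[samples])
    tests = []
    for i, row in edqtl_results.iterrows():
        genes = [
            g for g in site_genes.get(row["site"], []) if g in expression.columns
        ]
        for gid in genes:
            r = ols_association(
                expression.loc[samples, gid].to_numpy(dtype=float),
                genotypes.loc[samples, row["snp"]].to_numpy(dtype=float),
                C,
            )
            tests.append(
                {"row": i, "site": row["site"], "snp": row["snp"], "gene": gid,
                 "p_value": r.p_value, "beta": r.beta}
            )
    out = edqtl_results.copy()
    out["eqtl"] = pd.NA
    if not tests:
        return out
    tdf = pd.DataFrame(tests)
    tdf["adjusted_p"] = multipletests(tdf["p_value"], method="fdr_bh")[1]
    flag = tdf.groupby("row")["adjusted_p"].min() < alpha
    out.loc[flag.index, "eqtl"] = flag
    return out


def gwas_intersect(
    ed_snps: Iterable[str],
    catalog: pd.DataFrame,
    p_threshold: float = 1e-8,
    snp_col: str = "snp",
    trait_col: str = "trait",
    p_col: str = "p_value",
) -> pd.DataFrame:
    """Intersect significant edQTL regulatory SNPs with a GWAS catalog.

    Keeps catalog rows with p strictly below ``p_threshold`` whose SNP id
    is an edSNP; duplicate (SNP, trait) rows collapse to the smallest p.
    """
    edset = set(ed_snps)
    hits = catalog[(catalog[p_col] < p_threshold) & catalog[snp_col].isin(edset)]
    if hits.empty:
        return hits.copy()
    return (
        hits.sort_values(p_col)
        .drop_duplicates(subset=[snp_col, trait_col])
        .sort_values([snp_col, trait_col])
        .reset_index(drop=True)
    )


def ld_prune(
    snps: Sequence[str],
    genotypes: pd.DataFrame,
    positions: pd.DataFrame,
    window_bp: int = 400_000,
    step: int = 1,
    r2_threshold: float = 0.6,
) -> list[str]:
    """Greedy LD pruning of SNPs within a sliding genomic window.

    SNPs are scanned left to right per chromosome (position-sorted). A
    SNP is removed when its dosage vector has squared Pearson
    correlation above ``r2_threshold`` with any retained SNP lying at
    most ``window_bp`` upstream; the later SNP of a linked pair is
    always the one removed. The defaults mirror PLINK's
    --indep-pairwise 400 kb / step 1 / 0.6. Pruning is idempotent.
    """
    missing = [s for s in snps if s not in genotypes.columns]
    if missing:
        raise KeyError(f"SNPs absent from genotype matrix: {missing}")
    if step < 1:
        raise ValueError("step must be >= 1")
    order = sorted(
        snps, key=lambda s: (str(positions.loc[s, "chrom"]), int(positions.loc[s, "pos"]))
    )
    kept: list[str] = []
    kept_meta: list[tuple[str, int]] = []
    for snp in order:
        chrom = str(positions.loc[snp, "chrom"])
        pos = int(positions.loc[snp, "pos"])
        x = genotypes[snp].to_numpy(dtype=float)
        linked = False
        for prev, (pchrom, ppos) in zip(kept, kept_meta):
            if pchrom != chrom or pos - ppos > window_bp:
                continue
            y = genotypes[prev].to_numpy(dtype=float)
            m = np.isfinite(x) & np.isfinite(y)
            if m.sum() < 3 or np.std(x[m]) == 0 or np.std(y[m]) == 0:
                continue
            r = np.corrcoef(x[m], y[m])[0, 1]
            if r * r > r2_threshold:
                linked = True
                break
        if not linked:
            kept.append(snp)
            kept_meta.append((chrom, pos))
    return kept
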