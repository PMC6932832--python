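"""Association contrasts, ancestry adjustment and multiple-testing support.

Five primary analyses: logistic regressions of all mothers, MI mothers and
MII mothers against fathers, MI against MII mothers, and a transmission
disequilibrium test (TDT) over complete trios.  The logistic model is
``logit(p) = SNP + PC1 + PC2 + PC3`` with the SNP coded additively and the
first three principal components of ancestry computed with the Patterson
normalisation.  Candidate-gene windows use the Li & Ji effective number of
independent tests for a per-locus Bonferroni threshold; suggestive
genome-wide hits (p < 1e-5) are cross-referenced across analyses within
20 kb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MISSING, Cohort

CONTRAST_NAMES = (
    "all_mothers_vs_fathers",
    "mi_vs_fathers",
    "mii_vs_fathers",
    "mi_vs_mii",
    "tdt",
)

#: null median of a 1-df chi-square
_CHI2_NULL_MEDIAN = stats.chi2.ppf(0.5, 1)


@dataclass(frozen=True)
class ContrastSpec:
    name: str
    case_ids: tuple = ()
    control_ids: tuple = ()

    def __post_init__(self):
        if self.name not in CONTRAST_NAMES:
            raise ValueError(f"unknown contrast {self.name!r}")
        overlap = set(self.case_ids) & set(self.control_ids)
        if overlap:
            raise ValueError(f"case and control groups overlap: {sorted(overlap)[:5]}")


def make_contrasts(groups: dict) -> list:
    """The four logistic contrasts from phenotype groups (TDT is separate)."""
    g = groups
    return [
        ContrastSpec("all_mothers_vs_fathers", tuple(g["mothers_all"]), tuple(g["fathers"])),
        ContrastSpec("mi_vs_fathers", tuple(g["mothers_mi"]), tuple(g["fathers"])),
        ContrastSpec("mii_vs_fathers", tuple(g["mothers_mii"]), tuple(g["fathers"])),
        ContrastSpec("mi_vs_mii", tuple(g["mothers_mi"]), tuple(g["mothers_mii"])),
    ]


@dataclass
class AncestryPCs:
    coords: pd.DataFrame        # samples x PC1..PC3
    eigenvalues: np.ndarray
    snp_ids: tuple

    def for_samples(self, sample_ids) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.coords.index]
        if missing:
            raise KeyError(f"samples without PC coordinates: {missing[:5]}")
        return self.coords.loc[list(sample_ids)].to_numpy()


# --------------------------------------------------------------- PCA support

def _in_regions(chrom: np.ndarray, pos: np.ndarray, regions) -> np.ndarray:
    hit = np.zeros(chrom.shape, dtype=bool)
    for rchrom, start, end in regions or ():
        hit |= (chrom == str(rchrom)) & (pos >= start) & (pos <= end)
    return hit


def select_pca_snps(
    cohort: Cohort,
    sample_ids=None,
    missing_max: float = 0.05,
    maf_min: float = 0.05,
    ld_r2_max: float = 0.1,
    window: int = 50,
    step: int = 5,
    exclusion_regions=None,
) -> list:
    """SNP pre-selection for ancestry PCA.

    Screens non-chr21 autosomal SNPs on missingness and MAF, removes
    configured exclusion regions (high-LD loci such as LCT/2q21, HLA, 8p23
    and 17q21.31 in real data — supplied as (chrom, start, end) pinned to a
    genome build), then LD-prunes greedily over sliding index windows.
    """
    if sample_ids is None:
        sample_ids = cohort.sample_ids("mother") + cohort.sample_ids("father")
    G = cohort.genotype_matrix(sample_ids).astype(float)
    G[G == MISSING] = np.nan
    v = cohort.variants
    chrom = v["chrom"].to_numpy(dtype=str)
    pos = v["pos_bp"].to_numpy()
    miss = np.isnan(G).mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(G, axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    ok = (
        (chrom != cohort.genetic_map.chromosome)
        & (miss < missing_max)
        & (np.nan_to_num(maf) > maf_min)
        & ~_in_regions(chrom, pos, exclusion_regions)
    )
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise ValueError("no SNPs pass the PCA screens")
    # mean-impute for correlation
    X = G[:, idx]
    mu = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu, inds[1])
    keep = np.ones(idx.size, dtype=bool)
    for start in range(0, idx.size, step):
        stop = min(start + window, idx.size)
        w = np.flatnonzero(keep[start:stop]) + start
        if w.size < 2:
            continue
        sub = X[:, w]
        sd = sub.std(axis=0)
        sd[sd == 0] = np.nan
        r = np.corrcoef(sub, rowvar=False)
        r2 = np.nan_to_num(r) ** 2
        for a in range(w.size):
            if not keep[w[a]]:
                continue
            for b in range(a + 1, w.size):
                if keep[w[b]] and r2[a, b] > ld_r2_max:
                    keep[w[b]] = False
        if stop == idx.size:
            break
    ids = v["id"].to_numpy()
    return list(ids[idx[keep]])


def pca_patterson(G: np.ndarray, n_pcs: int = 3):
    """Patterson-normalised PCA on a (samples x SNPs) dosage matrix.

    Columns are centered at 2p and scaled by sqrt(p(1-p)); missing values
    are mean-imputed (zero after centering).  Returns (coords, eigenvalues),
    with each PC's sign fixed so its largest-magnitude coordinate is
    positive.
    """
    X = np.asarray(G, dtype=float).copy()
    X[X == MISSING] = np.nan
    n, m = X.shape
    if n < 4 or m < n_pcs:
        raise ValueError("need at least 4 samples and n_pcs SNPs")
    p = np.nanmean(X, axis=0) / 2.0
    with np.errstate(invalid="ignore"):
        var_ok = (p > 0) & (p < 1) & (np.nanstd(X, axis=0) > 0)
    if not var_ok.any():
        raise ValueError("zero-variance SNP panel")
    X = X[:, var_ok]
    p = p[var_ok]
    X = (X - 2 * p) / np.sqrt(p * (1 - p))
    X[np.isnan(X)] = 0.0
    cov = X @ X.T / X.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:n_pcs]
    coords = vecs[:, order]
    vals = vals[order]
    for k in range(coords.shape[1]):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords, vals


def compute_ancestry_pcs(cohort: Cohort, snp_list, sample_ids=None, n_pcs: int = 3) -> AncestryPCs:
    if sample_ids is None:
        sample_ids = cohort.sample_ids("mother") + cohort.sample_ids("father")
    if len(snp_list) < n_pcs:
        raise ValueError("need at least n_pcs SNPs")
    idx = cohort.variant_index(snp_list)
    G = cohort.genotype_matrix(sample_ids)[:, idx]
    coords, vals = pca_patterson(G, n_pcs)
    df = pd.DataFrame(coords, index=list(sample_ids),
                      columns=[f"PC{k + 1}" for k in range(n_pcs)])
    return AncestryPCs(coords=df, eigenvalues=vals, snp_ids=tuple(snp_list))


# --------------------------------------------------- batched logistic scans

def _batched_logit(y, G, C, tol=1e-8, max_iter=50, chunk=512):
    """Newton maximum-likelihood logistic fit of y ~ C + g for every column
    g of G, complete-case per column.  Returns beta, se, converged, n_used,
    n_case_used, monomorphic flags."""
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    p0 = C.shape[1]
    beta_out = np.full(m, np.nan)
    se_out = np.full(m, np.nan)
    conv = np.zeros(m, dtype=bool)
    mono = np.zeros(m, dtype=bool)
    n_used = np.zeros(m, dtype=int)
    n_case = np.zeros(m, dtype=int)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        g = np.asarray(G[:, lo:hi], dtype=float)
        obs = ~np.isnan(g)
        g0 = np.where(obs, g, 0.0)
        k = hi - lo
        n_used[lo:hi] = obs.sum(axis=0)
        n_case[lo:hi] = (obs * (y[:, None] == 1)).sum(axis=0)
        # monomorphic among used samples
        with np.errstate(invalid="ignore"):
            gm = np.where(obs, g, np.nan)
            mono[lo:hi] = np.nanstd(gm, axis=0) == 0
        active = ~mono[lo:hi] & (n_used[lo:hi] > p0 + 1)
        B = np.zeros((k, p0 + 1))
        done = ~active
        for _ in range(max_iter):
            if done.all():
                break
            eta = C @ B[:, :p0].T + g0 * B[:, p0]
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1 - mu) * obs
            resid = (y[:, None] - mu) * obs
            sC = C.T @ resid                      # (p0, k)
            sg = (g0 * resid).sum(axis=0)         # (k,)
            H = np.empty((k, p0 + 1, p0 + 1))
            H[:, :p0, :p0] = np.einsum("np,nk,nq->kpq", C, w, C)
            Hg = np.einsum("np,nk->kp", C, w * g0)
            H[:, :p0, p0] = Hg
            H[:, p0, :p0] = Hg
            H[:, p0, p0] = (w * g0 * g0).sum(axis=0)
            rhs = np.concatenate([sC.T, sg[:, None]], axis=1)
            idx = np.flatnonzero(~done)
            try:
                delta = np.linalg.solve(
                    H[idx] + 1e-10 * np.eye(p0 + 1), rhs[idx, :, None]
                )[:, :, 0]
            except np.linalg.LinAlgError:
                break
            B[idx] += delta
            step_done = np.abs(delta).max(axis=1) < tol
            newly = idx[step_done]
            conv[lo + newly] = True
            done[idx[step_done]] = True
        # standard errors from the final observed information
        eta = C @ B[:, :p0].T + g0 * B[:, p0]
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu) * obs
        H = np.empty((k, p0 + 1, p0 + 1))
        H[:, :p0, :p0] = np.einsum("np,nk,nq->kpq", C, w, C)
        Hg = np.einsum("np,nk->kp", C, w * g0)
        H[:, :p0, p0] = Hg
        H[:, p0, :p0] = Hg
        H[:, p0, p0] = (w * g0 * g0).sum(axis=0)
        for j in range(k):
            if mono[lo + j] or not conv[lo + j]:
                continue
            try:
                cov = np.linalg.inv(H[j])
                se = np.sqrt(cov[p0, p0])
            except np.linalg.LinAlgError:
                conv[lo + j] = False
                continue
            if not np.isfinite(se) or abs(B[j, p0]) > 15:
                conv[lo + j] = False   # separation / degenerate fit
                continue
            beta_out[lo + j] = B[j, p0]
            se_out[lo + j] = se
    return beta_out, se_out, conv, n_used, n_case, mono


def logistic_scan_matrix(
    G: np.ndarray,
    y: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    variants: Optional[pd.DataFrame] = None,
    analysis: str = "scan",
) -> pd.DataFrame:
    """Per-variant additive logistic scan on a (samples x variants) dosage
    matrix; missing dosages (-1 or NaN) are dropped per variant."""
    G = np.asarray(G, dtype=float).copy()
    G[G == MISSING] = np.nan
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    n = G.shape[0]
    if covariates is None:
        C = np.ones((n, 1))
    else:
        cov = np.asarray(covariates, dtype=float)
        C = np.column_stack([np.ones(n), cov])
    beta, se, conv, n_used, n_case, mono = _batched_logit(y, G, C)
    with np.errstate(invalid="ignore"):
        z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    flag = np.where(mono, "monomorphic", np.where(conv, "", "not_converged"))
    out = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "OR": np.exp(beta),
            "p": pvals,
            "n_case": n_case,
            "n_control": n_used - n_case,
            "flag": flag,
            "analysis": analysis,
        }
    )
    if variants is not None:
        out.insert(0, "variant_id", variants["id"].to_numpy())
        out.insert(1, "chrom", variants["chrom"].to_numpy())
        out.insert(2, "pos_bp", variants["pos_bp"].to_numpy())
    return out


def logistic_snp_scan(
    cohort: Cohort, contrast: ContrastSpec, pcs: Optional[AncestryPCs] = None
) -> pd.DataFrame:
    """One of the four case-control contrasts with PC ancestry adjustment."""
    cases = list(contrast.case_ids)
    controls = list(contrast.control_ids)
    if not cases or not controls:
        raise ValueError(f"{contrast.name}: empty case or control group")
    samples = cases + controls
    G = cohort.genotype_matrix(samples)
    y = np.concatenate([np.ones(len(cases)), np.zeros(len(controls))])
    cov = pcs.for_samples(samples) if pcs is not None else None
    return logistic_scan_matrix(G, y, cov, cohort.variants, analysis=contrast.name)


# ---------------------------------------------------------------------- TDT

def tdt_counts(cohort: Cohort, family_ids=None):
    """Per-variant transmission counts (b, c) of the B allele from
    heterozygous parents in complete trios; chr21 is excluded (the child is
    trisomic there and the disomic TDT does not apply)."""
    by_family = {t.family_id: t for t in cohort.trios}
    if family_ids is None:
        family_ids = [t.family_id for t in cohort.trios if t.availability == "complete"]
    non21 = ~cohort.chr21_mask
    b = np.zeros(cohort.n_variants)
    c_nt = np.zeros(cohort.n_variants)
    n_trios = 0
    for fam in family_ids:
        t = by_family[fam]
        if not (t.has_mother and t.has_father):
            continue
        n_trios += 1
        m, f, ch = t.mother_geno, t.father_geno, t.child_geno
        usable = (m != MISSING) & (f != MISSING) & (ch != MISSING) & non21
        n_het = (m == 1).astype(int) + (f == 1).astype(int)
        forced = (m == 2).astype(int) + (f == 2).astype(int)
        trans = ch - forced
        valid = usable & (n_het > 0) & (trans >= 0) & (trans <= n_het)
        b[valid] += trans[valid]
        c_nt[valid] += (n_het - trans)[valid]
    if n_trios == 0:
        raise ValueError("no complete trios for the TDT")
    return b, c_nt


def tdt_scan(cohort: Cohort, family_ids=None) -> pd.DataFrame:
    """McNemar-style TDT: (b - c)^2 / (b + c) against chi-square(1)."""
    b, c = tdt_counts(cohort, family_ids)
    total = b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(total > 0, (b - c) ** 2 / np.where(total > 0, total, 1), np.nan)
    pvals = np.where(total > 0, stats.chi2.sf(stat, 1), np.nan)
    v = cohort.variants
    out = pd.DataFrame(
        {
            "variant_id": v["id"].to_numpy(),
            "chrom": v["chrom"].to_numpy(),
            "pos_bp": v["pos_bp"].to_numpy(),
            "b": b,
            "c": c,
            "stat": stat,
            "p": pvals,
            "analysis": "tdt",
        }
    )
    return out[~cohort.chr21_mask].reset_index(drop=True)


# ------------------------------------------------------- inflation & Li--Ji

def genomic_lambda(p_values) -> float:
    """Genomic inflation factor: median observed 1-df chi-square over the
    null median (0.4549)."""
    p = np.asarray(pd.to_numeric(pd.Series(p_values), errors="coerce"), dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 1:
        raise ValueError("no finite p-values")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / _CHI2_NULL_MEDIAN)


def li_ji_meff(corr: np.ndarray) -> float:
    """Li & Ji effective number of independent tests from the eigenvalues of
    the absolute-value correlation matrix: Meff = sum 1{lam>=1} + (lam - floor(lam))."""
    r = np.asarray(corr, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(r, r.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(r), 1.0, atol=1e-6):
        raise ValueError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(np.abs(r))
    if lam.min() < -1e-6 * r.shape[0]:
        raise ValueError("matrix is not positive semi-definite within tolerance")
    lam = np.clip(lam, 0.0, None)
    lam[lam < 1e-9] = 0.0
    # guard the fractional part against eigenvalues an epsilon below an integer
    floor = np.floor(lam + 1e-9)
    frac = np.clip(lam - floor, 0.0, None)
    meff = float(np.sum((lam >= 1 - 1e-9).astype(float) + frac))
    return meff


def _window_corr(cohort: Cohort, sample_ids, var_idx: np.ndarray) -> np.ndarray:
    G = cohort.genotype_matrix(sample_ids)[:, var_idx].astype(float)
    G[G == MISSING] = np.nan
    mu = np.nanmean(G, axis=0)
    inds = np.where(np.isnan(G))
    G[inds] = np.take(mu, inds[1])
    sd = G.std(axis=0)
    keepable = sd > 0
    r = np.eye(var_idx.size)
    if keepable.sum() >= 2:
        sub = np.corrcoef(G[:, keepable], rowvar=False)
        r[np.ix_(keepable, keepable)] = sub
    return r


def candidate_gene_analysis(
    results: dict,
    loci: pd.DataFrame,
    cohort: Cohort,
    control_ids,
    window_bp: int = 60_000,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-locus minimum p with a Li-Ji Bonferroni threshold.

    ``loci`` columns: name, chrom, start_bp, end_bp (start == end for a SNP
    locus); the window extends ``window_bp`` on each side.  Meff is computed
    on control-group genotype correlations within the window.
    """
    v = cohort.variants
    chrom = v["chrom"].to_numpy(dtype=str)
    pos = v["pos_bp"].to_numpy()
    rows = []
    for _, locus in loci.iterrows():
        lo = int(locus["start_bp"]) - window_bp
        hi = int(locus["end_bp"]) + window_bp
        in_win = (chrom == str(locus["chrom"])) & (pos >= lo) & (pos <= hi)
        var_idx = np.flatnonzero(in_win)
        if var_idx.size == 0:
            raise ValueError(f"locus {locus['name']}: window contains no SNPs")
        meff = li_ji_meff(_window_corr(cohort, control_ids, var_idx))
        meff = max(meff, 1.0)
        threshold = alpha / meff
        win_ids = set(v["id"].to_numpy()[var_idx])
        for analysis, res in results.items():
            sub = res[res["variant_id"].isin(win_ids) & res["p"].notna()]
            if len(sub):
                k = sub["p"].idxmin()
                min_p = float(sub.loc[k, "p"])
                min_var = sub.loc[k, "variant_id"]
            else:
                min_p, min_var = np.nan, None
            rows.append(
                {
                    "locus": locus["name"],
                    "chrom": locus["chrom"],
                    "window_start": lo,
                    "window_end": hi,
                    "m_snps": int(var_idx.size),
                    "meff": meff,
                    "threshold": threshold,
                    "analysis": analysis,
                    "variant_id": min_var,
                    "min_p": min_p,
                    "significant": bool(min_p < threshold) if np.isfinite(min_p) else False,
                }
            )
    return pd.DataFrame(rows)


def top_hits_cross_lookup(
    results: dict, p_threshold: float = 1e-5, window_bp: int = 20_000
) -> dict:
    """Suggestive hits per analysis with the minimum p within +-window_bp in
    each of the other analyses (NaN when no variant lies in range)."""
    missing = [c for c in results if "p" not in results[c].columns]
    if missing:
        raise ValueError(f"results without p column: {missing}")
    out = {}
    for analysis, res in results.items():
        hits = res[res["p"].notna() & (res["p"] < p_threshold)].sort_values("p")
        rows = []
        for _, hit in hits.iterrows():
            row = {
                "variant_id": hit["variant_id"],
                "chrom": hit["chrom"],
                "pos_bp": hit["pos_bp"],
                f"p_{analysis}": hit["p"],
            }
            for other, ores in results.items():
                if other == analysis:
                    continue
                near = ores[
                    (ores["chrom"].astype(str) == str(hit["chrom"]))
                    & (np.abs(ores["pos_bp"] - hit["pos_bp"]) <= window_bp)
                    & ores["p"].notna()
                ]
                row[f"p_{other}"] = float(near["p"].min()) if len(near) else np.nan
            rows.append(row)
        out[analysis] = pd.DataFrame(rows)
    return out


def negative_control_scan(
    G: np.ndarray,
    sex: np.ndarray,
    variants: Optional[pd.DataFrame] = None,
    n_pcs: int = 3,
):
    """Female-vs-male scan on an unselected cohort as an artifact screen.

    Runs the identical logistic pipeline with sex as the outcome (with
    ancestry PCs computed from the same panel) and returns (results,
    genomic lambda).
    """
    sex = np.asarray(sex, dtype=float)
    coords, _ = pca_patterson(G, n_pcs)
    res = logistic_scan_matrix(G, sex, coords, variants, analysis="negative_control")
    lam = genomic_lambda(res["p"])
    return res, lam
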