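"""Kinship-corrected association scan on father-line dosages.

The hybrids are testcrosses of genotyped homozygous father lines to two
common maternal testers; only the fathers segregate, so a hybrid's marker
genotype is its father's dosage and the testers enter the model as a fixed
"mother" effect.  Each marker is tested sequentially in the mixed model
y = X beta + m u + Z g + e with g ~ N(0, G sigma2_g).

Two scan methods are provided.  The default, ``method="exact"``, re-fits
the variance ratio lambda = sigma2_g / sigma2_e for every marker by
profiled REML over a single eigendecomposition of the genetic covariance
(the rotation trick of the FaST-LMM family), so each Wald p-value comes
from the marker's own REML fit.  ``method="p3d"`` is the cheaper
EMMAX-style two-step that holds lambda at the null-model estimate and only
re-estimates the residual scale per marker; it is mildly conservative in
small panels because each trait's lambda error shifts that trait's whole
scan.  Both collapse to the ordinary regression t-test when sigma2_g is
estimated at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .reml import ModelSpec, RandomTerm, dummy_design, fit_reml

log = logging.getLogger(__name__)


@dataclass
class GRM:
    """VanRaden genomic relationship matrix.

    G = M M' / (2 sum p_i (1 - p_i)) with M the dosage matrix centered by
    twice the B-allele frequency of each marker.  Monomorphic markers
    contribute nothing to numerator or denominator and are excluded.
    """

    matrix: pd.DataFrame
    freqs: pd.Series
    denominator: float
    excluded_monomorphic: list = field(default_factory=list)


def vanraden_grm(dosages: pd.DataFrame) -> GRM:
    """Compute the GRM from an imputed (no missing) dosage DataFrame."""
    arr = dosages.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("dosages contain missing values; impute first")
    p = arr.mean(axis=0) / 2.0
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        log.warning("GRM: excluding %d monomorphic markers", int(mono.sum()))
    keep = ~mono
    M = arr[:, keep] - 2.0 * p[keep]
    denom = float(2.0 * np.sum(p[keep] * (1.0 - p[keep])))
    if denom <= 0:
        raise ValueError("all markers monomorphic; GRM undefined")
    G = M @ M.T / denom
    ids = dosages.index
    return GRM(
        matrix=pd.DataFrame(G, index=ids, columns=ids),
        freqs=pd.Series(p, index=dosages.columns),
        denominator=denom,
        excluded_monomorphic=list(dosages.columns[mono]),
    )


def compute_grm(dosages: pd.DataFrame) -> GRM:
    """Alias for :func:`vanraden_grm` (pipeline-facing name)."""
    return vanraden_grm(dosages)


def marker_pca(dosages: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Scores of individuals on the top-k PCs of the centered dosage matrix.

    Sign convention: within each component the loading with the largest
    magnitude is made positive, so scores do not flip between runs.
    """
    n = dosages.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of individuals ({n})")
    if k == 0:
        return pd.DataFrame(index=dosages.index)
    arr = dosages.to_numpy(dtype=float)
    arr = arr - arr.mean(axis=0)
    U, S, Vt = np.linalg.svd(arr, full_matrices=False)
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            U[:, j] = -U[:, j]
            Vt[j] = -Vt[j]
    scores = U[:, :k] * S[:k]
    return pd.DataFrame(scores, index=dosages.index,
                        columns=[f"PC{j + 1}" for j in range(k)])


@dataclass
class GWASResult:
    """Long-format association table plus per-trait bookkeeping."""

    table: pd.DataFrame        # trait, marker, chromosome, pos, effect, se, p, neg_log10_p, significant, degenerate
    null_vc: dict              # trait -> {'genetic': .., 'residual': ..}
    skipped_traits: list       # (trait, H^2) pairs below the gate
    threshold: float

    def trait_table(self, trait: str) -> pd.DataFrame:
        return self.table[self.table["trait"] == trait].reset_index(drop=True)


def _hybrid_frame(index, hybrids: pd.DataFrame) -> pd.DataFrame:
    unknown = index.difference(hybrids.index)
    if len(unknown):
        raise ValueError(f"hybrids table lacks entries for {list(unknown)[:5]}...")
    df = hybrids.loc[index, ["father", "mother"]].copy()
    if df.isna().any().any():
        raise ValueError("hybrids table has missing father/mother labels")
    return df


_LAMBDA_GRID = np.concatenate([[0.0], np.geomspace(1e-3, 1e3, 70)])


def _scan_exact(y, Xf, M, H, grid=_LAMBDA_GRID):
    """Per-marker REML scan: for every marker, profile the variance ratio
    lambda over ``grid`` in the rotated basis and take the Wald test at the
    marker's own REML optimum."""
    n = y.size
    d, U = linalg.eigh(H)
    d = np.maximum(d, 0.0)
    yt = U.T @ y
    Xt = U.T @ Xf
    Mt = U.T @ M
    p_fix = Xf.shape[1] + 1
    df_resid = n - p_fix
    nm = M.shape[1]

    best_ll = np.full(nm, -np.inf)
    best_u = np.zeros(nm)
    best_rss = np.full(nm, np.nan)
    best_mm = np.full(nm, np.nan)
    degenerate = np.zeros(nm, dtype=bool)
    for lam in grid:
        sw = 1.0 / np.sqrt(lam * d + 1.0)
        Xw = Xt * sw[:, None]
        yw = yt * sw
        Mw = Mt * sw[:, None]
        Q, R = np.linalg.qr(Xw)
        yr = yw - Q @ (Q.T @ yw)
        Mr = Mw - Q @ (Q.T @ Mw)
        mm = np.einsum("ij,ij->j", Mr, Mr)
        deg = mm <= 1e-10 * np.maximum(np.einsum("ij,ij->j", Mw, Mw), 1.0)
        degenerate |= deg
        mm_safe = np.where(deg, 1.0, mm)
        my = Mr.T @ yr
        u = my / mm_safe
        rss = np.maximum(float(yr @ yr) - u * my, 1e-300)
        # REML log-likelihood profiled over beta and the residual scale
        logdet_X = 2.0 * np.sum(np.log(np.abs(np.diag(R))))
        ll = -0.5 * (np.sum(np.log(lam * d + 1.0)) + df_resid * np.log(rss / df_resid)
                     + logdet_X + np.log(mm_safe))
        upd = (ll > best_ll) & ~deg
        best_ll[upd] = ll[upd]
        best_u[upd] = u[upd]
        best_rss[upd] = rss[upd]
        best_mm[upd] = mm[upd]

    s2 = best_rss / df_resid
    se = np.sqrt(s2 / best_mm)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = best_u / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df_resid)
    best_u[degenerate] = 0.0
    se[degenerate] = np.nan
    pval[degenerate] = 1.0
    return best_u, se, pval, degenerate


def _scan_one_trait(y, Xf, M, lam, H):
    """Rotated weighted least squares for every marker column of M.

    V = lam * H + I up to the residual scale; the eigendecomposition of H
    turns the GLS into an ordinary weighted regression in the rotated basis.
    """
    n = y.size
    d, U = linalg.eigh(H)
    w = 1.0 / np.sqrt(np.maximum(lam * d + 1.0, 1e-12))
    yt = (U.T @ y) * w
    Xt = (U.T @ Xf) * w[:, None]
    Mt = (U.T @ M) * w[:, None]

    Q, _ = np.linalg.qr(Xt)
    yr = yt - Q @ (Q.T @ yt)
    Mr = Mt - Q @ (Q.T @ Mt)
    mm = np.einsum("ij,ij->j", Mr, Mr)
    p_fixed = Xt.shape[1]
    df_resid = n - p_fixed - 1

    degenerate = mm <= 1e-10 * np.maximum(np.einsum("ij,ij->j", Mt, Mt), 1.0)
    mm_safe = np.where(degenerate, 1.0, mm)
    u = (Mr.T @ yr) / mm_safe
    rss = float(yr @ yr) - u**2 * mm_safe
    s2 = np.maximum(rss, 0.0) / df_resid
    se = np.sqrt(s2 / mm_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = u / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df_resid)
    u[degenerate] = 0.0
    se[degenerate] = np.nan
    pval[degenerate] = 1.0
    return u, se, pval, degenerate


def naive_gls_scan(y, Xf, M, lam, H):
    """Reference per-marker GLS with an explicit V inverse (test oracle
    for the eigendecomposition-accelerated path)."""
    n = y.size
    V = lam * H + np.eye(n)
    Vinv = np.linalg.inv(V)
    p_fixed = Xf.shape[1]
    df_resid = n - p_fixed - 1
    out = []
    for j in range(M.shape[1]):
        W = np.column_stack([Xf, M[:, j]])
        A = W.T @ Vinv @ W
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            out.append((0.0, np.nan, 1.0, True))
            continue
        if np.linalg.cond(A) > 1e10:
            out.append((0.0, np.nan, 1.0, True))
            continue
        b = Ainv @ (W.T @ Vinv @ y)
        r = y - W @ b
        s2 = float(r @ Vinv @ r) / df_resid
        se = np.sqrt(s2 * Ainv[-1, -1])
        tval = b[-1] / se
        pval = 2.0 * stats.t.sf(abs(tval), df_resid)
        out.append((b[-1], se, pval, False))
    u, se, pval, deg = map(np.array, zip(*out))
    return u, se, pval, deg.astype(bool)


def gwas_scan(
    means: pd.DataFrame,
    hybrids: pd.DataFrame,
    geno_dosages: pd.DataFrame,
    grm: GRM,
    pcs: pd.DataFrame | None = None,
    marker_map: pd.DataFrame | None = None,
    h2: pd.Series | None = None,
    threshold: float = 1e-3,
    gate_h2: float = 0.1,
    method: str = "exact",
) -> GWASResult:
    """Per-marker mixed-model association scan for every gated trait.

    Parameters
    ----------
    means : adjusted means, indexed by hybrid id, one column per trait.
    hybrids : hybrid id -> (father, mother) mapping.
    geno_dosages : imputed father-line dosages (fathers x markers).
    grm : VanRaden GRM over the father lines.
    pcs : father-line PC scores used as stratification covariates.
    h2 : per-trait heritability; traits with h2 < ``gate_h2`` are skipped.
    method : ``"exact"`` (per-marker REML, default) or ``"p3d"``
        (variance ratio held at the null-model estimate).
    """
    if method not in ("exact", "p3d"):
        raise ValueError(f"unknown scan method {method!r}")
    markers = list(geno_dosages.columns)
    results = []
    null_vc = {}
    skipped = []

    for trait in means.columns:
        if h2 is not None and trait in h2.index and h2[trait] < gate_h2:
            skipped.append((trait, float(h2[trait])))
            continue
        y_all = means[trait].dropna()
        hf = _hybrid_frame(y_all.index, hybrids)
        fathers = hf["father"]
        known = fathers.isin(geno_dosages.index)
        if not known.all():
            log.warning("trait %s: %d hybrids with unknown father dropped", trait, int((~known).sum()))
        y = y_all[known].to_numpy(dtype=float)
        hf = hf[known]
        fathers = fathers[known]
        n = y.size
        if n < 3:
            raise ValueError(f"trait {trait!r}: too few hybrids with data")

        cov_frame = hf.copy()
        covariates = []
        if pcs is not None and pcs.shape[1] > 0:
            for c in pcs.columns:
                cov_frame[c] = fathers.map(pcs[c]).to_numpy()
                covariates.append(c)
        factors = ["mother"] if cov_frame["mother"].nunique() > 1 else []
        Xf, names, _ = dummy_design(cov_frame, factors, covariates)

        # hybrid-level genetic covariance: H = Z G Z' via father lookups
        fidx = grm.matrix.index.get_indexer(fathers)
        Gf = grm.matrix.to_numpy()
        H = Gf[np.ix_(fidx, fidx)]
        eigmin = float(np.min(np.linalg.eigvalsh(Gf)))
        if eigmin < -1e-6 * max(1.0, float(np.max(np.diag(Gf)))):
            raise ValueError(f"GRM is not positive semidefinite (min eigenvalue {eigmin:.3g})")

        Zf = np.zeros((n, Gf.shape[0]))
        Zf[np.arange(n), fidx] = 1.0
        spec = ModelSpec(y=y, X=Xf, fixed_names=names,
                         random_terms=[RandomTerm("genetic", Zf, Gf)])
        fit = fit_reml(spec)
        s2g, s2e = fit.vc["genetic"], fit.vc["residual"]
        null_vc[trait] = {"genetic": s2g, "residual": s2e,
                          "converged": fit.converged, "loglik": fit.reml_loglik}
        lam = s2g / s2e if s2e > 0 else 0.0

        M = geno_dosages.loc[fathers].to_numpy(dtype=float)
        if method == "exact":
            u, se, pval, deg = _scan_exact(y, Xf, M, H)
        else:
            u, se, pval, deg = _scan_one_trait(y, Xf, M, lam, H)
        tab = pd.DataFrame({
            "trait": trait,
            "marker": markers,
            "effect": u,
            "se": se,
            "p": pval,
            "degenerate": deg,
        })
        results.append(tab)

    if results:
        table = pd.concat(results, ignore_index=True)
    else:
        table = pd.DataFrame(columns=["trait", "marker", "effect", "se", "p", "degenerate"])
    with np.errstate(divide="ignore"):
        table["neg_log10_p"] = -np.log10(table["p"].astype(float))
    table["significant"] = table["p"] <= threshold
    if marker_map is not None and len(table):
        table.insert(2, "chromosome", table["marker"].map(marker_map["chromosome"]))
        table.insert(3, "pos", table["marker"].map(marker_map["pos"]))
    return GWASResult(table=table, null_vc=null_vc, skipped_traits=skipped, threshold=threshold)
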