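"""Genotype-environment association scans and consensus candidate sets.

Three complementary decision rules are implemented natively:

* ``logistic_scan`` -- per genotype class, a univariate logistic regression
  of class membership on the individual's site climate value; a locus is
  significant if the likelihood-ratio (G) or Wald test passes a Bonferroni
  correction at family level alpha over all (locus, variable, class) tests.
* ``latent_scan`` -- per locus, linear regression of centred dosage on the
  climate variable plus k latent factors estimated from the genotype matrix;
  z-scores are recalibrated by genomic inflation, the median over several
  randomized runs is thresholded at |z| > 4 and p < 1e-5, with
  Benjamini-Hochberg q-values reported.
* ``bayes_scan`` -- population allele frequencies standardized and compared
  against a multivariate-normal null whose covariance is estimated from
  widely spaced loci; evidence is a Bayes factor averaged over a symmetric
  grid of slopes, and over runs, thresholded at mean log10(BF) > 1.5.

Candidate sets are the union (significant in >= 1 model) and the core
(significant in >= 2 models) over loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from ._rng import substream
from .containers import MISSING, GenotypeMatrix

__all__ = [
    "logistic_scan",
    "latent_scan",
    "bayes_scan",
    "combine_records",
    "consensus_sets",
    "ConsensusSets",
]

log = logging.getLogger(__name__)

# genotype classes with fewer members than this in either outcome group are
# not tested (chi-square tails are unreliable for tiny classes)
MIN_CLASS_COUNT = 10

# |beta| beyond this flags (quasi-)complete separation: the Wald statistic
# is unreliable and only the G test decides significance
SEPARATION_BETA = 15.0


def _climate_matrix(gm: GenotypeMatrix, sites: pd.DataFrame,
                    variables: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Per-individual climate values (n_individuals x n_vars)."""
    if variables is None:
        variables = [c for c in sites.columns if c.startswith("bio")]
    if not variables:
        raise ValueError("no climate variables found in site table")
    tab = sites.set_index("site_id")
    missing_sites = set(gm.site_ids) - set(tab.index)
    if missing_sites:
        raise ValueError(f"sites absent from climate table: {sorted(missing_sites)[:5]}")
    x = tab.loc[gm.site_ids, variables].to_numpy(dtype=float)
    for j, v in enumerate(variables):
        if np.std(x[:, j]) == 0:
            raise ValueError(f"climate variable {v!r} is constant")
    return x, list(variables)


# ---------------------------------------------------------------------------
# logistic scan
# ---------------------------------------------------------------------------

def _batched_logistic(x: np.ndarray, Y: np.ndarray, W: np.ndarray,
                      max_iter: int = 30, tol: float = 1e-8):
    """Newton fits of M univariate logistic regressions sharing predictor x.

    x: (n,), Y: (n, M) binary outcomes, W: (n, M) 0/1 observation weights.
    Returns (G, wald, beta1, converged) arrays of length M.
    """
    M = Y.shape[1]
    n_obs = W.sum(axis=0)
    n_pos = (W * Y).sum(axis=0)
    ybar = np.clip(n_pos / np.maximum(n_obs, 1), 1e-12, 1 - 1e-12)
    b0 = logit(ybar)
    b1 = np.zeros_like(b0)
    X = x[:, None]
    h00 = np.empty(M)
    det = np.ones(M)
    last_step = np.full(M, np.inf)
    active = np.arange(M)
    for _ in range(max_iter):
        Xa = X
        eta = b0[None, active] + Xa * b1[None, active]
        p = expit(eta)
        Wa, Ya = W[:, active], Y[:, active]
        resid = Wa * (Ya - p)
        g0 = resid.sum(axis=0)
        g1 = (resid * Xa).sum(axis=0)
        s = Wa * p * (1.0 - p)
        a00 = s.sum(axis=0)
        a01 = (s * Xa).sum(axis=0)
        a11 = (s * Xa * Xa).sum(axis=0)
        adet = np.maximum(a00 * a11 - a01 * a01, 1e-300)
        db0 = (a11 * g0 - a01 * g1) / adet
        db1 = (a00 * g1 - a01 * g0) / adet
        # damp steps so separated problems drift rather than explode
        db0 = np.clip(db0, -4.0, 4.0)
        db1 = np.clip(db1, -4.0, 4.0)
        b0[active] += db0
        b1[active] += db1
        h00[active] = a00
        det[active] = adet
        step = np.maximum(np.abs(db0), np.abs(db1))
        last_step[active] = step
        active = active[step >= tol]
        if active.size == 0:
            break
    converged = last_step < 1e-4
    eta = b0[None, :] + X * b1[None, :]
    p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    ll1 = (W * (Y * np.log(p) + (1 - Y) * np.log1p(-p))).sum(axis=0)
    ll0 = n_pos * np.log(ybar) + (n_obs - n_pos) * np.log1p(-ybar)
    G = np.maximum(2.0 * (ll1 - ll0), 0.0)
    se1 = np.sqrt(np.maximum(h00 / det, 1e-300))
    wald = (b1 / se1) ** 2
    return G, wald, b1, converged


def logistic_scan(gm: GenotypeMatrix, sites: pd.DataFrame,
                  alpha: float = 0.01,
                  variables: list[str] | None = None,
                  min_class_count: int = MIN_CLASS_COUNT) -> pd.DataFrame:
    """Presence/absence logistic scan over loci x climate variables.

    For every observed genotype class at a locus, class membership is
    regressed on the climate value; the per-(locus, variable) statistics are
    the maxima over classes and significance requires the G- or Wald-based
    chi-square(1) p-value to pass Bonferroni at family level ``alpha`` over
    all class tests.  Under separation only the G test decides.
    """
    xmat, variables = _climate_matrix(gm, sites, variables)
    obs = gm.calls != MISSING
    # enumerate testable (locus, class) problems once; shared across variables
    probs_locus: list[int] = []
    Y_cols: list[np.ndarray] = []
    W_cols: list[np.ndarray] = []
    for c in (0, 1, 2):
        is_c = (gm.calls == c) & obs
        n_c = is_c.sum(axis=0)
        n_not = obs.sum(axis=0) - n_c
        ok = (n_c >= min_class_count) & (n_not >= min_class_count)
        for j in np.nonzero(ok)[0]:
            probs_locus.append(j)
            Y_cols.append(is_c[:, j])
            W_cols.append(obs[:, j])
    if not probs_locus:
        return pd.DataFrame(columns=["locus_id", "variable", "G_score", "wald",
                                     "sig_logistic", "wald_reliable"])
    Y = np.array(Y_cols, dtype=float).T
    W = np.array(W_cols, dtype=float).T
    locus_idx = np.asarray(probs_locus)
    n_tests = Y.shape[1] * len(variables)
    thr = alpha / n_tests
    nL, nV = gm.n_loci, len(variables)
    G_out = np.full((nL, nV), np.nan)
    wald_out = np.full((nL, nV), np.nan)
    sig_out = np.zeros((nL, nV), dtype=bool)
    rel_out = np.ones((nL, nV), dtype=bool)
    for v in range(nV):
        x = xmat[:, v]
        xz = (x - x.mean()) / x.std()
        G, wald, b1, conv = _batched_logistic(xz, Y, W)
        reliable = conv & (np.abs(b1) < SEPARATION_BETA)
        p_g = stats.chi2.sf(G, 1)
        p_w = np.where(reliable, stats.chi2.sf(wald, 1), 1.0)
        sig = (p_g < thr) | (p_w < thr)
        col = np.full(nL, -np.inf)
        np.maximum.at(col, locus_idx, G)
        G_out[:, v] = np.where(np.isfinite(col), col, np.nan)
        col = np.full(nL, -np.inf)
        np.maximum.at(col, locus_idx, np.where(reliable, wald, -np.inf))
        wald_out[:, v] = np.where(np.isfinite(col), col, np.nan)
        np.logical_or.at(sig_out[:, v], locus_idx, sig)
        np.logical_and.at(rel_out[:, v], locus_idx, reliable)
    out = pd.DataFrame({
        "locus_id": np.tile(gm.locus_ids, nV),
        "variable": np.repeat(variables, nL),
        "G_score": G_out.T.ravel(),
        "wald": wald_out.T.ravel(),
        "sig_logistic": sig_out.T.ravel(),
        "wald_reliable": rel_out.T.ravel(),
    })
    log.info("logistic_scan: %d class tests x %d variables, Bonferroni %g",
             Y.shape[1], len(variables), thr)
    return out


# ---------------------------------------------------------------------------
# latent-factor scan
# ---------------------------------------------------------------------------

def _imputed_centered(gm: GenotypeMatrix) -> np.ndarray:
    X = gm.calls.astype(float)
    X[gm.calls == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    idx = np.where(np.isnan(X))
    X[idx] = mu[idx[1]]
    return X - X.mean(axis=0)


def latent_scan(gm: GenotypeMatrix, sites: pd.DataFrame, k: int,
                runs: int = 5, seed: int = 0,
                variables: list[str] | None = None,
                subsample: float = 0.9,
                run_seeds: list[int] | None = None) -> pd.DataFrame:
    """Latent-factor association scan with genomic-inflation recalibration.

    Per run, ``k`` factors are the top left-singular vectors of the centred
    genotype matrix computed on a random ``subsample`` of loci; every locus
    is then regressed on (climate variable + factors).  z-scores are divided
    by sqrt(lambda) with lambda = median(z^2)/0.456, the median over runs is
    taken, p-values come from the standard normal and q-values from
    Benjamini-Hochberg per variable.  Significance requires |z| > 4 and
    p < 1e-5.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= min(gm.n_individuals, gm.n_loci):
        raise ValueError("k must be smaller than both matrix dimensions")
    if runs < 1:
        raise ValueError("runs must be >= 1")
    xmat, variables = _climate_matrix(gm, sites, variables)
    Xc = _imputed_centered(gm)
    n, L = Xc.shape
    if run_seeds is None:
        run_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                     for s in substream(seed, "latent").spawn(runs)]
    elif len(run_seeds) != runs:
        raise ValueError("run_seeds length must equal runs")
    z_runs = np.empty((runs, L, len(variables)))
    for r, rs in enumerate(run_seeds):
        rng = np.random.default_rng(rs)
        m = max(k + 1, int(round(subsample * L)))
        cols = rng.choice(L, size=min(m, L), replace=False)
        u, _, _ = np.linalg.svd(Xc[:, cols], full_matrices=False)
        F = u[:, :k]
        for v in range(len(variables)):
            x = xmat[:, v]
            xz = (x - x.mean()) / x.std()
            D = np.column_stack([np.ones(n), xz, F])
            DtD = D.T @ D
            DtD_inv = np.linalg.pinv(DtD)
            coef = DtD_inv @ (D.T @ Xc)
            resid = Xc - D @ coef
            dof = n - D.shape[1]
            sigma2 = (resid ** 2).sum(axis=0) / max(dof, 1)
            se = np.sqrt(np.maximum(sigma2 * DtD_inv[1, 1], 1e-300))
            z = coef[1] / se
            lam = np.median(z ** 2) / 0.456
            z_runs[r, :, v] = z / np.sqrt(max(lam, 1e-12))
    z_med = np.median(z_runs, axis=0)
    p = 2.0 * stats.norm.sf(np.abs(z_med))
    q = np.empty_like(p)
    for v in range(p.shape[1]):
        q[:, v] = stats.false_discovery_control(p[:, v])
    sig = (np.abs(z_med) > 4.0) & (p < 1e-5)
    rows = []
    for v, var in enumerate(variables):
        for j in range(L):
            rows.append((gm.locus_ids[j], var, z_med[j, v], p[j, v],
                         q[j, v], bool(sig[j, v])))
    return pd.DataFrame(rows, columns=["locus_id", "variable", "z_median",
                                       "p_z", "q_z", "sig_latent"])


# ---------------------------------------------------------------------------
# Bayes-factor scan
# ---------------------------------------------------------------------------

def _standardized_freqs(gm: GenotypeMatrix):
    p, n, _, site_ids = gm.site_allele_stats()
    if p.shape[0] < 2:
        raise ValueError("bayes_scan needs >= 2 populations")
    # impute empty site/locus cells at the cross-population mean
    pbar_impute = np.nanmean(p, axis=0)
    idx = np.where(np.isnan(p))
    p[idx] = pbar_impute[idx[1]]
    pbar = p.mean(axis=0)
    denom = np.sqrt(np.maximum(pbar * (1 - pbar), 1e-12))
    X = (p - pbar[None, :]) / denom[None, :]
    polymorphic = (pbar > 0) & (pbar < 1)
    return X, polymorphic, site_ids


def bayes_scan(gm: GenotypeMatrix, sites: pd.DataFrame,
               null_stride: int = 200, runs: int = 5,
               bf_threshold: float = 1.5, seed: int = 0,
               variables: list[str] | None = None,
               n_grid: int = 21, ridge: float = 1e-6) -> pd.DataFrame:
    """Covariance-null Bayes-factor scan.

    Per run, the population covariance Omega is estimated from every
    ``null_stride``-th locus (random offset per run) of the standardized
    allele-frequency matrix, ridge-regularized by ``ridge * trace / P``.
    For each locus and variable the Bayes factor compares a linear climate
    effect (slope averaged over a 21-point symmetric grid spanning +/- 5
    empirical-regression standard deviations) against the zero-slope null.
    """
    X, poly, site_ids = _standardized_freqs(gm)
    S, L = X.shape
    tab = sites.set_index("site_id")
    if variables is None:
        variables = [c for c in sites.columns if c.startswith("bio")]
    env = tab.loc[site_ids, variables].to_numpy(dtype=float)
    for j, v in enumerate(variables):
        if np.std(env[:, j]) == 0:
            raise ValueError(f"climate variable {v!r} is constant")
    env = (env - env.mean(axis=0)) / env.std(axis=0)
    rng_master = substream(seed, "bayes").spawn(runs)
    log10bf_runs = np.zeros((runs, L, len(variables)))
    # the stride spaces covariance loci for LD independence, but the
    # subsample must stay large enough to estimate an S x S covariance:
    # cap it so at least ~3 loci per population remain
    stride = max(1, min(null_stride, L // max(3 * S, 30)))
    if stride < null_stride:
        log.info("bayes_scan: stride reduced %d -> %d to keep the covariance "
                 "subsample well-conditioned", null_stride, stride)
    for r, ss in enumerate(rng_master):
        rng = np.random.default_rng(ss)
        if L > stride:
            offset = int(rng.integers(0, stride))
            null_idx = np.arange(offset, L, stride)
        else:
            null_idx = np.arange(L)
        Xn = X[:, null_idx]
        omega = Xn @ Xn.T / max(Xn.shape[1], 1)
        omega = omega + (ridge * np.trace(omega) / S) * np.eye(S)
        try:
            chol = np.linalg.cholesky(omega)
        except np.linalg.LinAlgError:
            log.warning("bayes_scan: singular covariance; increasing ridge")
            omega = omega + (1e-3 * np.trace(omega) / S) * np.eye(S)
            chol = np.linalg.cholesky(omega)
        del chol
        Oinv_X = np.linalg.solve(omega, X)          # (S, L)
        for v in range(len(variables)):
            e = env[:, v]
            q2 = float(e @ np.linalg.solve(omega, e))
            q1 = e @ Oinv_X                          # (L,)
            beta_hat = q1 / q2
            sigma = float(np.std(beta_hat[poly])) or 1.0
            # midpoint grid over +/- 5 sigma: the plain mean is then a
            # proper quadrature of the uniform slope prior
            h = 10.0 * sigma / n_grid
            betas = -5.0 * sigma + (np.arange(n_grid) + 0.5) * h
            # log N(x; b e, O) - log N(x; 0, O) = b*q1 - b^2*q2/2,
            # averaged over the grid in a numerically safe way
            log_ratio = betas[:, None] * q1[None, :] \
                - 0.5 * (betas ** 2)[:, None] * q2
            m = log_ratio.max(axis=0)
            mean_bf = np.exp(log_ratio - m[None, :]).mean(axis=0)
            log10bf_runs[r, :, v] = (m + np.log(mean_bf)) / np.log(10.0)
    log10bf = log10bf_runs.mean(axis=0)
    rows = []
    for v, var in enumerate(variables):
        for j in range(L):
            rows.append((gm.locus_ids[j], var, log10bf[j, v],
                         bool(log10bf[j, v] > bf_threshold)))
    return pd.DataFrame(rows, columns=["locus_id", "variable",
                                       "log10_bf_mean", "sig_bayes"])


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def combine_records(logistic: pd.DataFrame, latent: pd.DataFrame,
                    bayes: pd.DataFrame) -> pd.DataFrame:
    """Merge the three per-(locus, variable) scan outputs into one table."""
    keys = ["locus_id", "variable"]
    out = logistic.merge(latent, on=keys, how="outer").merge(bayes, on=keys, how="outer")
    for flag in ("sig_logistic", "sig_latent", "sig_bayes"):
        if flag in out:
            out[flag] = out[flag].fillna(False).astype(bool)
    return out


@dataclass
class ConsensusSets:
    """Per-model significant locus sets with union (>=1) and core (>=2)."""

    per_model: dict
    union_set: set
    core_set: set

    def __post_init__(self) -> None:
        if not self.core_set <= self.union_set:
            raise ValueError("core set must be a subset of the union set")


def consensus_sets(records: pd.DataFrame) -> ConsensusSets:
    """A locus enters a model's set if significant for >= 1 variable there."""
    flags = {"logistic": "sig_logistic", "latent": "sig_latent", "bayes": "sig_bayes"}
    for col in flags.values():
        if col not in records.columns:
            raise ValueError(f"records missing flag column {col!r}")
    per_model = {}
    for name, col in flags.items():
        hit = records.loc[records[col].astype(bool), "locus_id"]
        per_model[name] = set(hit)
    all_loci = set(records["locus_id"])
    counts = {lid: sum(lid in s for s in per_model.values()) for lid in all_loci}
    union = {lid for lid, c in counts.items() if c >= 1}
    core = {lid for lid, c in counts.items() if c >= 2}
    return ConsensusSets(per_model=per_model, union_set=union, core_set=core)
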