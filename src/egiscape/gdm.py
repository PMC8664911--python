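"""Generalized dissimilarity modelling of genetic turnover.

Pairwise Weir-Cockerham (1984) FST among populations is regressed on
monotone I-spline transforms of between-site climate differences (and,
optionally, raw geographic distance) through the 1 - exp(-eta) link, with
nonnegative coefficients fitted by iteratively reweighted nonnegative least
squares on a binomial-type deviance.  The fitted spline maxima give
predictor importances; two screening rules (geographic-distance rank and a
reference-group deviance floor) separate climate-driven loci from
isolation-by-distance signal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.decomposition import PCA

from .containers import DissimMatrix, GenotypeMatrix

__all__ = [
    "pairwise_fst",
    "prune_predictors",
    "ispline_basis",
    "GDMFit",
    "fit_gdm",
    "rank_importance",
    "screen_snps",
    "per_locus_gdm_fits",
    "transform_pca_rgb",
    "GEO_PREDICTOR",
]

log = logging.getLogger(__name__)

GEO_PREDICTOR = "geo_distance"

_EPS = 1e-10


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def _wc_components(n1, p1, h1, n2, p2, h2):
    """WC84 per-locus variance components a, b, c for one population pair.

    Inputs are per-locus arrays: diploid sample sizes, alt-allele
    frequencies and observed heterozygote proportions.
    """
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
                           / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
    valid = (n1 >= 2) & (n2 >= 2) & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a, b, c, valid


def pairwise_fst(gm: GenotypeMatrix, loci=None, min_n: int = 5,
                 rescale: bool = True) -> DissimMatrix:
    """Multi-locus Weir-Cockerham theta for every pair of populations.

    Only populations with >= ``min_n`` individuals enter.  The per-pair
    estimate is sum(a) / sum(a+b+c) over loci; negative estimates are
    clamped to 0 and, when ``rescale``, the matrix is affinely mapped so the
    smallest pair is 0 and the largest 1.
    """
    if loci is not None:
        gm = gm.subset_loci(np.asarray(list(loci)))
    counts = gm.individual_table.groupby("site_id", sort=False).size()
    eligible = counts[counts >= min_n].index.tolist()
    if len(eligible) < 2:
        raise ValueError("need >= 2 populations with sufficient sample size")
    keep_ind = gm.individual_table["site_id"].isin(eligible).to_numpy()
    sub = GenotypeMatrix(gm.calls[keep_ind],
                         gm.locus_table,
                         gm.individual_table.loc[keep_ind].reset_index(drop=True))
    p, n, h, site_ids = sub.site_allele_stats()
    order = [site_ids.index(s) for s in eligible]
    p, n, h = p[order], n[order], h[order]
    S = len(eligible)
    theta = np.zeros((S, S))
    raw = np.zeros((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            a, b, c, valid = _wc_components(n[i], p[i], h[i], n[j], p[j], h[j])
            num = np.where(valid, a, 0.0).sum()
            den = np.where(valid, a + b + c, 0.0).sum()
            t = num / den if den > 0 else 0.0
            raw[i, j] = raw[j, i] = max(t, 0.0)
    if rescale:
        off = raw[np.triu_indices(S, k=1)]
        lo, hi = off.min(), off.max()
        if hi > lo:
            theta = (raw - lo) / (hi - lo)
        else:
            theta = np.zeros_like(raw)
        np.fill_diagonal(theta, 0.0)
    else:
        theta = raw.copy()
    ns = counts.loc[eligible].to_numpy()
    return DissimMatrix(ids=eligible, values=theta, n=ns, raw=raw)


# ---------------------------------------------------------------------------
# predictor pruning
# ---------------------------------------------------------------------------

def prune_predictors(sites: pd.DataFrame, r_threshold: float = 0.8,
                     scores: dict | None = None,
                     variables: list[str] | None = None) -> list[str]:
    """Greedy removal of collinear climate variables until all retained
    pairwise |Pearson r| < ``r_threshold``.

    When two variables collide, the one with the lower score (default: the
    higher variable index, so lower-indexed variables win ties) is dropped.
    ``scores`` may carry, e.g., single-predictor GDM explained deviances.
    Constant variables are removed with a warning.
    """
    if variables is None:
        variables = [c for c in sites.columns if c.startswith("bio")]
    if len(variables) < 2:
        raise ValueError("need at least two variables to prune")
    x = sites[variables].to_numpy(dtype=float)
    keep = list(variables)
    const = [v for v in keep if np.std(sites[v].to_numpy(dtype=float)) == 0]
    for v in const:
        warnings.warn(f"constant climate variable {v!r} removed")
        keep.remove(v)

    def score(v: str) -> tuple:
        s = scores.get(v, 0.0) if scores else 0.0
        return (s, -variables.index(v))  # higher deviance, then lower index

    while True:
        if len(keep) < 2:
            break
        sub = sites[keep].to_numpy(dtype=float)
        r = np.corrcoef(sub, rowvar=False)
        np.fill_diagonal(r, 0.0)
        amax = np.unravel_index(np.argmax(np.abs(r)), r.shape)
        if abs(r[amax]) < r_threshold:
            break
        vi, vj = keep[amax[0]], keep[amax[1]]
        drop = vj if score(vi) >= score(vj) else vi
        keep.remove(drop)
    del x
    return keep


# ---------------------------------------------------------------------------
# I-splines
# ---------------------------------------------------------------------------

def ispline_basis(x: np.ndarray, knots) -> np.ndarray:
    """Order-2 monotone I-spline basis with three functions.

    ``knots`` are three strictly increasing positions covering the data
    range; each basis function rises from 0 at the minimum knot to 1 at the
    maximum knot.  Values outside the knot range are clamped with a warning.
    """
    q1, q2, q3 = (float(k) for k in knots)
    if not (q1 < q2 < q3):
        raise ValueError("knots must be strictly increasing")
    x = np.asarray(x, dtype=float)
    if (x < q1 - 1e-12).any() or (x > q3 + 1e-12).any():
        warnings.warn("x outside knot range; clamping")
    x = np.clip(x, q1, q3)
    b = np.zeros(x.shape + (3,))
    left = x <= q2
    # I1: integral of the decreasing triangle on [q1, q2]
    b[..., 0] = np.where(left, 1.0 - (q2 - x) ** 2 / (q2 - q1) ** 2, 1.0)
    # I2: rises over the whole range, quadratic on each side of q2
    b[..., 1] = np.where(
        left,
        (x - q1) ** 2 / ((q3 - q1) * (q2 - q1)),
        1.0 - (q3 - x) ** 2 / ((q3 - q1) * (q3 - q2)),
    )
    # I3: integral of the increasing triangle on [q2, q3]
    b[..., 2] = np.where(left, 0.0, (x - q2) ** 2 / (q3 - q2) ** 2)
    return b


def _default_knots(values: np.ndarray) -> np.ndarray:
    """Knots at the 0/50/100 percentiles, nudged apart if degenerate."""
    q = np.percentile(values, [0, 50, 100]).astype(float)
    span = max(q[2] - q[0], 1e-9)
    if q[1] <= q[0]:
        q[1] = q[0] + 0.5 * span
    if q[2] <= q[1]:
        q[2] = q[1] + 1e-9
    return q


# ---------------------------------------------------------------------------
# GDM fit
# ---------------------------------------------------------------------------

@dataclass
class GDMFit:
    """Fitted generalized dissimilarity model.

    ``coefs[p]`` are the three nonnegative I-spline coefficients of
    predictor ``p`` over ``knots[p]``; the fitted transform is
    f_p(x) = sum_k coefs[p][k] * I_k(x) and predicted dissimilarity between
    environments is 1 - exp(-(intercept + sum_p |f_p(x_i) - f_p(x_j)|)).
    """

    predictors: list
    knots: dict
    coefs: dict
    intercept: float
    null_deviance: float
    residual_deviance: float
    converged: bool = True
    use_geo: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def explained_deviance(self) -> float:
        """Percent of null deviance explained (can be negative)."""
        if self.null_deviance <= 0:
            return 0.0
        return 100.0 * (1.0 - self.residual_deviance / self.null_deviance)

    def transform(self, predictor: str, x: np.ndarray) -> np.ndarray:
        """f_p(x): the fitted monotone transform of one predictor."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            basis = ispline_basis(np.asarray(x, dtype=float), self.knots[predictor])
        return basis @ np.asarray(self.coefs[predictor], dtype=float)

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "knots": {p: list(map(float, k)) for p, k in self.knots.items()},
            "coefs": {p: list(map(float, c)) for p, c in self.coefs.items()},
            "intercept": float(self.intercept),
            "null_deviance": float(self.null_deviance),
            "residual_deviance": float(self.residual_deviance),
            "converged": bool(self.converged),
            "use_geo": bool(self.use_geo),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GDMFit":
        return cls(
            predictors=list(d["predictors"]),
            knots={p: np.asarray(k, dtype=float) for p, k in d["knots"].items()},
            coefs={p: np.asarray(c, dtype=float) for p, c in d["coefs"].items()},
            intercept=float(d["intercept"]),
            null_deviance=float(d["null_deviance"]),
            residual_deviance=float(d["residual_deviance"]),
            converged=bool(d.get("converged", True)),
            use_geo=bool(d.get("use_geo", False)),
        )


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Binomial-type deviance for responses in [0, 1] with unit weights."""
    mu = np.clip(mu, _EPS, 1 - _EPS)
    yc = np.clip(y, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(yc > 0, yc * np.log(yc / mu), 0.0)
        t2 = np.where(yc < 1, (1 - yc) * np.log((1 - yc) / (1 - mu)), 0.0)
    return float(2.0 * np.sum(t1 + t2))


def _design(d: DissimMatrix, sites: pd.DataFrame, predictors: list[str],
            use_geo: bool):
    """Pairwise response and I-spline difference design.

    Returns (y, Z, columns, knots) where Z columns are, per predictor, the
    three |I_k(x_i) - I_k(x_j)| spline differences (raw spline values of
    pairwise Euclidean distance for the geographic predictor).
    """
    tab = sites.set_index("site_id")
    missing = set(d.ids) - set(tab.index)
    if missing:
        raise ValueError(f"populations absent from site table: {sorted(missing)[:5]}")
    ii, jj, y = d.pair_values()
    cols, names, knots = [], [], {}
    for p in predictors:
        v = tab.loc[d.ids, p].to_numpy(dtype=float)
        k = _default_knots(v)
        basis = ispline_basis(v, k)
        cols.append(np.abs(basis[ii] - basis[jj]))
        names.append(p)
        knots[p] = k
    if use_geo:
        xy = tab.loc[d.ids, ["lon", "lat"]].to_numpy(dtype=float)
        dist = np.sqrt(((xy[ii] - xy[jj]) ** 2).sum(axis=1))
        k = _default_knots(dist)
        knots[GEO_PREDICTOR] = k
        cols.append(ispline_basis(dist, k))
        names.append(GEO_PREDICTOR)
    Z = np.concatenate(cols, axis=1)
    return y, Z, names, knots


def _irls_nnls(y: np.ndarray, Z: np.ndarray, max_iter: int = 100,
               tol: float = 1e-9):
    """Fit eta = a0 + Z a (all coefficients >= 0) under the 1-exp(-eta)
    link by IRLS with an NNLS inner solve.  Returns (a0, a, deviance,
    converged)."""
    n = len(y)
    A = np.column_stack([np.ones(n), Z])
    mu = np.clip(y.mean(), 1e-3, 1 - 1e-3) * np.ones(n)
    eta = -np.log1p(-mu)
    coef = np.zeros(A.shape[1])
    dev = _binomial_deviance(y, mu)
    converged = False
    for _ in range(max_iter):
        mu = np.clip(1.0 - np.exp(-eta), _EPS, 1 - _EPS)
        dmu = 1.0 - mu  # d mu / d eta
        w = dmu * dmu / (mu * (1.0 - mu))
        z = eta + (y - mu) / dmu
        sw = np.sqrt(w)
        coef_new, _ = nnls(A * sw[:, None], z * sw)
        eta_new = A @ coef_new
        dev_new = _binomial_deviance(y, 1.0 - np.exp(-eta_new))
        if not np.isfinite(dev_new):
            break
        if dev_new > dev + 1e-12:
            # step-halve toward the previous coefficients
            improved = False
            for _ in range(12):
                coef_try = 0.5 * (coef_new + coef)
                eta_try = A @ coef_try
                dev_try = _binomial_deviance(y, 1.0 - np.exp(-eta_try))
                if dev_try <= dev:
                    coef_new, eta_new, dev_new, improved = coef_try, eta_try, dev_try, True
                    break
                coef_new = coef_try
            if not improved:
                break
        delta = abs(dev - dev_new)
        coef, eta, dev = coef_new, eta_new, dev_new
        if delta < tol * (dev + 0.1):
            converged = True
            break
    return coef[0], coef[1:], dev, converged


def fit_gdm(d: DissimMatrix, sites: pd.DataFrame, predictors: list[str],
            use_geo: bool = False, max_iter: int = 100) -> GDMFit:
    """Fit a GDM of the dissimilarity matrix on I-spline climate transforms.

    Geographic Euclidean distance on (lon, lat) enters as an extra splined
    predictor when ``use_geo``.  The null deviance comes from an
    intercept-only fit of the same family.
    """
    y, Z, names, knots = _design(d, sites, predictors, use_geo)
    a0, a, dev, converged = _irls_nnls(y, Z, max_iter=max_iter)
    # intercept-only null
    null0, _, null_dev, _ = _irls_nnls(y, np.zeros((len(y), 0)), max_iter=max_iter)
    coefs = {p: a[3 * i: 3 * i + 3] for i, p in enumerate(names)}
    if not converged:
        log.warning("fit_gdm: IRLS did not converge; returning best iterate")
    return GDMFit(predictors=names, knots=knots, coefs=coefs, intercept=float(a0),
                  null_deviance=float(null_dev), residual_deviance=float(dev),
                  converged=converged, use_geo=use_geo)


def rank_importance(fit: GDMFit) -> pd.DataFrame:
    """Predictor importances: fitted I-spline maxima (coefficient sums)
    rescaled so the largest is 1, sorted descending with index tie-break."""
    sums = {p: float(np.sum(fit.coefs[p])) for p in fit.predictors}
    top = max(sums.values()) if sums else 0.0
    rows = []
    for i, p in enumerate(fit.predictors):
        imp = sums[p] / top if top > 0 else 0.0
        rows.append((p, sums[p], imp, i))
    df = pd.DataFrame(rows, columns=["predictor", "coef_sum", "importance", "order"])
    df = df.sort_values(["importance", "order"], ascending=[False, True])
    df["rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="order").reset_index(drop=True)


# ---------------------------------------------------------------------------
# SNP screening
# ---------------------------------------------------------------------------

def per_locus_gdm_fits(gm: GenotypeMatrix, loci, sites: pd.DataFrame,
                       predictors: list[str], min_n: int = 5) -> dict:
    """Single-SNP GDM fits (climate + geographic distance) per locus."""
    fits = {}
    for lid in loci:
        d = pairwise_fst(gm, loci=[lid], min_n=min_n)
        fits[lid] = fit_gdm(d, sites, predictors, use_geo=True)
    return fits


def screen_snps(per_snp_fits: dict, reference_fit: GDMFit,
                geo_rank_cut: int = 3) -> set:
    """Apply the two screening rules to single-SNP GDM fits.

    Drops loci where geographic distance ranks within the top
    ``geo_rank_cut`` predictors, then drops loci whose explained deviance
    falls below the reference group's combined-model explained deviance.
    """
    if reference_fit is None:
        raise ValueError("reference fit required")
    floor = reference_fit.explained_deviance
    retained = set()
    for lid, fit in per_snp_fits.items():
        ranks = rank_importance(fit)
        geo_rows = ranks.loc[ranks["predictor"] == GEO_PREDICTOR, "rank"]
        geo_rank = int(geo_rows.iloc[0]) if len(geo_rows) else len(ranks) + 1
        if geo_rank <= geo_rank_cut:
            continue
        if fit.explained_deviance < floor:
            continue
        retained.add(lid)
    log.info("screen_snps: retained %d / %d loci (floor %.2f%%, geo cut %d)",
             len(retained), len(per_snp_fits), floor, geo_rank_cut)
    return retained


def screen_candidates(gm: GenotypeMatrix, candidate_loci, all_loci,
                      sites: pd.DataFrame, predictors: list[str],
                      n_reference: int = 200, seed: int = 0,
                      min_n: int = 5, geo_rank_cut: int = 3) -> tuple[set, GDMFit]:
    """End-to-end screening: per-SNP fits plus a random reference group.

    The reference group is sampled from ``all_loci`` and its combined-model
    explained deviance sets the floor.  Returns (retained set, reference fit).
    """
    all_loci = list(all_loci)
    if not all_loci:
        raise ValueError("reference pool is empty")
    rng = np.random.default_rng(seed)
    size = min(n_reference, len(all_loci))
    ref = list(rng.choice(np.asarray(all_loci, dtype=object), size=size, replace=False))
    d_ref = pairwise_fst(gm, loci=ref, min_n=min_n)
    ref_fit = fit_gdm(d_ref, sites, predictors, use_geo=True)
    fits = per_locus_gdm_fits(gm, candidate_loci, sites, predictors, min_n=min_n)
    return screen_snps(fits, ref_fit, geo_rank_cut=geo_rank_cut), ref_fit


# ---------------------------------------------------------------------------
# transformed-climate visualization
# ---------------------------------------------------------------------------

def transform_pca_rgb(fit: GDMFit, grid: pd.DataFrame) -> pd.DataFrame:
    """Transform grid climate through the fitted splines and colour by PCA.

    Each climate predictor's current value is mapped through f_p, a PCA is
    run on the transformed matrix, and the first three components are each
    affinely rescaled to [0, 1] as R, G, B.  Degenerate components become a
    flat 0.5 channel.
    """
    preds = [p for p in fit.predictors if p != GEO_PREDICTOR]
    T = np.column_stack([
        fit.transform(p, grid[f"{p}_cur"].to_numpy(dtype=float)) for p in preds
    ])
    out = pd.DataFrame({"cell_id": grid["cell_id"]})
    for i, p in enumerate(preds):
        out[f"f_{p}"] = T[:, i]
    n_comp = min(3, T.shape[1], max(len(T) - 1, 1))
    channels = np.full((len(T), 3), 0.5)
    if n_comp >= 1 and len(T) > 1:
        pca = PCA(n_components=n_comp)
        scores = pca.fit_transform(T)
        for c in range(min(3, scores.shape[1])):
            col = scores[:, c]
            span = col.max() - col.min()
            if span > 1e-12:
                channels[:, c] = (col - col.min()) / span
            else:
                warnings.warn(f"degenerate principal component {c + 1}; flat channel")
    else:
        warnings.warn("fewer than 3 non-degenerate components; padding with 0.5")
    out["R"], out["G"], out["B"] = channels.T
    return out
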