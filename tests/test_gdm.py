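"""Dissimilarity modelling: FST estimator, I-splines, fitting, screening."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import spearmanr

from egiscape import (fit_gdm, ispline_basis, pairwise_fst, prune_predictors,
                      rank_importance, screen_snps, transform_pca_rgb)
from egiscape.containers import MISSING, DissimMatrix
from egiscape.gdm import GDMFit, GEO_PREDICTOR, _default_knots, per_locus_gdm_fits

from conftest import build_gm


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def _wc_theta_naive(calls, site_of_ind, pops):
    """Independent variance-components implementation: explicit loops over
    loci following the two-population estimator definitions."""
    sum_a = sum_abc = 0.0
    for j in range(calls.shape[1]):
        stats = []
        for pop in pops:
            rows = [calls[i, j] for i in range(calls.shape[0])
                    if site_of_ind[i] == pop and calls[i, j] != MISSING]
            n = len(rows)
            if n < 2:
                stats = None
                break
            p = sum(rows) / (2.0 * n)
            h = sum(1 for c in rows if c == 1) / n
            stats.append((n, p, h))
        if stats is None:
            continue
        (n1, p1, h1), (n2, p2, h2) = stats
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc if sum_abc > 0 else 0.0


def test_wc_fst_matches_naive_variance_components():
    rng = np.random.default_rng(0)
    calls = rng.integers(0, 3, size=(24, 6)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.1] = MISSING
    site_of = ["A"] * 8 + ["B"] * 8 + ["C"] * 8
    gm = build_gm(calls, site_of_ind=site_of)
    d = pairwise_fst(gm, min_n=5, rescale=False)
    for i, j in ((0, 1), (0, 2), (1, 2)):
        pi, pj = d.ids[i], d.ids[j]
        naive = max(_wc_theta_naive(calls, site_of, [pi, pj]), 0.0)
        assert d.raw[i, j] == pytest.approx(naive, abs=1e-10)


def test_wc_fst_fixed_difference_is_one():
    calls = np.array([[0], [0], [0], [0], [0], [2], [2], [2], [2], [2]])
    gm = build_gm(calls, site_of_ind=["A"] * 5 + ["B"] * 5)
    d = pairwise_fst(gm, min_n=5, rescale=False)
    assert d.raw[0, 1] == pytest.approx(1.0)


def test_wc_fst_identical_frequencies_clamped_to_zero():
    # both populations at p = 0.5 with all homozygotes: raw estimate <= 0
    calls = np.array([[0], [2], [0], [2], [0], [0], [2], [0], [2], [2]])
    gm = build_gm(calls, site_of_ind=["A"] * 5 + ["B"] * 5)
    d = pairwise_fst(gm, min_n=5, rescale=False)
    assert d.raw[0, 1] == 0.0


def test_pairwise_fst_requires_two_populations():
    calls = np.zeros((6, 3), dtype=np.int8)
    gm = build_gm(calls, site_of_ind=["A"] * 5 + ["B"])
    with pytest.raises(ValueError):
        pairwise_fst(gm, min_n=5)


def test_pairwise_fst_rescaled_range(make_landscape):
    gm, *_ = make_landscape(seed=13, n_sites=8, n_neutral_loci=100)
    d = pairwise_fst(gm, min_n=5)
    off = d.values[np.triu_indices(d.n_pops, 1)]
    assert off.min() == 0.0 and off.max() == 1.0
    assert np.allclose(np.diag(d.values), 0.0)


# ---------------------------------------------------------------------------
# predictor pruning
# ---------------------------------------------------------------------------

def _sites_from(arrs):
    df = pd.DataFrame({f"bio{i + 1:02d}": a for i, a in enumerate(arrs)})
    df.insert(0, "site_id", [f"S{i}" for i in range(len(df))])
    df.insert(1, "lon", 0.0)
    df.insert(2, "lat", 0.0)
    return df


def test_prune_duplicated_variable_keeps_one():
    rng = np.random.default_rng(1)
    a = rng.normal(size=40)
    sites = _sites_from([a, a.copy(), rng.normal(size=40)])
    kept = prune_predictors(sites)
    assert len(kept) == 2 and "bio03" in kept


def test_prune_independent_noise_keeps_all():
    rng = np.random.default_rng(2)
    sites = _sites_from([rng.normal(size=60) for _ in range(5)])
    assert len(prune_predictors(sites)) == 5


def test_prune_chain_leaves_no_high_correlation():
    rng = np.random.default_rng(3)
    z = rng.normal(size=500)
    v1 = z + 0.45 * rng.normal(size=500)
    v2 = z + 0.12 * rng.normal(size=500)
    v3 = z + 0.45 * rng.normal(size=500)
    sites = _sites_from([v1, v2, v3])
    kept = prune_predictors(sites, r_threshold=0.8)
    r = np.corrcoef(sites[kept].to_numpy(), rowvar=False)
    if len(kept) > 1:
        np.fill_diagonal(r, 0.0)
        assert np.abs(r).max() < 0.8
    # exhaustive check: no larger valid subset exists among all subsets
    from itertools import combinations
    best = 0
    vs = ["bio01", "bio02", "bio03"]
    full = np.corrcoef(sites[vs].to_numpy(), rowvar=False)
    for k in (3, 2, 1):
        for sub in combinations(range(3), k):
            ok = all(abs(full[i, j]) < 0.8 for i in sub for j in sub if i < j)
            if ok:
                best = max(best, k)
        if best:
            break
    assert len(kept) == best


def test_prune_constant_variable_warned_and_removed():
    rng = np.random.default_rng(4)
    sites = _sites_from([rng.normal(size=30), np.full(30, 2.0)])
    with pytest.warns(UserWarning, match="constant"):
        kept = prune_predictors(sites)
    assert kept == ["bio01"]


# ---------------------------------------------------------------------------
# I-splines
# ---------------------------------------------------------------------------

def _msplines(knots):
    """Order-2 M-spline densities for the three-function basis (oracle)."""
    q1, q2, q3 = knots

    def m1(x):
        return 2 * (q2 - x) / (q2 - q1) ** 2 if q1 <= x <= q2 else 0.0

    def m2(x):
        if q1 <= x <= q2:
            return 2 * (x - q1) / ((q3 - q1) * (q2 - q1))
        if q2 < x <= q3:
            return 2 * (q3 - x) / ((q3 - q1) * (q3 - q2))
        return 0.0

    def m3(x):
        return 2 * (x - q2) / (q3 - q2) ** 2 if q2 <= x <= q3 else 0.0

    return m1, m2, m3


def test_ispline_endpoints():
    knots = (0.0, 3.0, 10.0)
    assert np.allclose(ispline_basis(np.array([0.0]), knots), [[0, 0, 0]])
    assert np.allclose(ispline_basis(np.array([10.0]), knots), [[1, 1, 1]])


def test_ispline_matches_msplines_integrals():
    knots = (1.0, 4.0, 9.0)
    ms = _msplines(knots)
    xs = np.linspace(1.0, 9.0, 17)
    basis = ispline_basis(xs, knots)
    for k, m in enumerate(ms):
        for xi, got in zip(xs, basis[:, k]):
            expected = quad(m, knots[0], xi, points=list(knots))[0]
            assert got == pytest.approx(expected, abs=1e-8)


def test_ispline_monotone_nondecreasing():
    knots = (0.0, 1.0, 5.0)
    xs = np.linspace(0, 5, 200)
    basis = ispline_basis(xs, knots)
    assert (np.diff(basis, axis=0) >= -1e-12).all()


def test_ispline_clamps_out_of_range_with_warning():
    with pytest.warns(UserWarning, match="clamp"):
        b = ispline_basis(np.array([-5.0, 50.0]), (0.0, 1.0, 2.0))
    assert np.allclose(b[0], [0, 0, 0]) and np.allclose(b[1], [1, 1, 1])


# ---------------------------------------------------------------------------
# GDM fitting
# ---------------------------------------------------------------------------

def _noise_free_problem(n=40, coef=(0.5, 0.8, 0.3), intercept=0.1, seed=0,
                        noise=0.0):
    rng = np.random.default_rng(seed)
    sites = _sites_from([rng.uniform(0, 10, n), rng.uniform(0, 10, n)])
    sites["lon"] = rng.uniform(-10, 10, n)
    sites["lat"] = rng.uniform(-10, 10, n)
    x = sites["bio01"].to_numpy()
    knots = _default_knots(x)
    f = ispline_basis(x, knots) @ np.asarray(coef)
    ii, jj = np.triu_indices(n, 1)
    eta = intercept + np.abs(f[ii] - f[jj])
    y = 1 - np.exp(-eta)
    if noise:
        y = np.clip(y + rng.normal(0, noise, len(y)), 1e-4, 1 - 1e-4)
    D = np.zeros((n, n))
    D[ii, jj] = D[jj, ii] = y
    d = DissimMatrix(ids=sites["site_id"].tolist(), values=D, n=np.full(n, 5))
    return d, sites, f


def test_gdm_recovers_noise_free_transform():
    d, sites, _ = _noise_free_problem()
    fit = fit_gdm(d, sites, ["bio01", "bio02"])
    assert fit.explained_deviance >= 99.0
    assert rank_importance(fit)["predictor"].iloc[0] == "bio01"
    assert np.allclose(fit.coefs["bio02"], 0.0, atol=1e-6)


def test_gdm_recovery_under_small_noise():
    d, sites, f_true = _noise_free_problem(noise=0.02, seed=5)
    fit = fit_gdm(d, sites, ["bio01", "bio02"])
    xs = np.linspace(sites["bio01"].min(), sites["bio01"].max(), 100)
    knots = _default_knots(sites["bio01"].to_numpy())
    f_ref = ispline_basis(xs, knots) @ np.array([0.5, 0.8, 0.3])
    rho = spearmanr(f_ref, fit.transform("bio01", xs)).statistic
    assert rho >= 0.95


def test_gdm_constant_response_intercept_only():
    n = 15
    rng = np.random.default_rng(6)
    sites = _sites_from([rng.uniform(0, 10, n)])
    D = np.full((n, n), 0.3)
    np.fill_diagonal(D, 0.0)
    d = DissimMatrix(ids=sites["site_id"].tolist(), values=D, n=np.full(n, 5))
    fit = fit_gdm(d, sites, ["bio01"])
    assert np.allclose(fit.coefs["bio01"], 0.0, atol=1e-8)
    assert 1 - np.exp(-fit.intercept) == pytest.approx(0.3, abs=1e-6)


def test_gdm_invariant_to_population_permutation():
    d, sites, _ = _noise_free_problem(n=20)
    fit1 = fit_gdm(d, sites, ["bio01", "bio02"])
    perm = np.random.default_rng(7).permutation(20)
    d2 = DissimMatrix(ids=[d.ids[i] for i in perm],
                      values=d.values[np.ix_(perm, perm)], n=d.n[perm])
    fit2 = fit_gdm(d2, sites, ["bio01", "bio02"])
    for p in fit1.predictors:
        np.testing.assert_allclose(fit1.coefs[p], fit2.coefs[p], atol=1e-6)
    assert fit1.intercept == pytest.approx(fit2.intercept, abs=1e-6)


def test_gdm_coefficients_nonnegative_and_predictions_bounded(make_landscape):
    gm, sites, _, _ = make_landscape(seed=15, n_sites=15, n_neutral_loci=150)
    d = pairwise_fst(gm, min_n=5)
    fit = fit_gdm(d, sites, ["bio01", "bio03", "bio12"], use_geo=True)
    for p in fit.predictors:
        assert (fit.coefs[p] >= 0).all()
    assert fit.intercept >= 0
    # monotonicity: larger single-predictor difference never lowers d-hat
    xs = np.linspace(sites["bio01"].min(), sites["bio01"].max(), 50)
    f = fit.transform("bio01", xs)
    assert (np.diff(f) >= -1e-12).all()


def test_gdm_serialization_roundtrip():
    d, sites, _ = _noise_free_problem(n=15)
    fit = fit_gdm(d, sites, ["bio01"], use_geo=True)
    clone = GDMFit.from_dict(fit.to_dict())
    assert clone.explained_deviance == pytest.approx(fit.explained_deviance)
    xs = np.linspace(0, 10, 9)
    np.testing.assert_allclose(clone.transform("bio01", xs),
                               fit.transform("bio01", xs))


# ---------------------------------------------------------------------------
# importance and screening
# ---------------------------------------------------------------------------

def _fit_with(coef_map, expl=50.0):
    knots = {p: np.array([0.0, 1.0, 2.0]) for p in coef_map}
    return GDMFit(predictors=list(coef_map), knots=knots,
                  coefs={p: np.asarray(c, dtype=float) for p, c in coef_map.items()},
                  intercept=0.1, null_deviance=100.0,
                  residual_deviance=100.0 - expl)


def test_rank_importance_rescaling_and_ties():
    fit = _fit_with({"a": [0.3, 0.2, 0.1], "b": [0.1, 0.1, 0.1], "c": [0, 0, 0]})
    ranks = rank_importance(fit)
    assert ranks["predictor"].tolist() == ["a", "b", "c"]
    assert ranks["importance"].tolist() == pytest.approx([1.0, 0.5, 0.0])


def test_screen_snps_rules():
    geo_first = _fit_with({GEO_PREDICTOR: [1.0, 0, 0], "bio01": [0.1, 0, 0]},
                          expl=60.0)
    weak = _fit_with({"bio01": [0.5, 0, 0], GEO_PREDICTOR: [0.0, 0, 0]}, expl=5.0)
    good = _fit_with({"bio01": [0.5, 0, 0], "bio02": [0.3, 0, 0],
                      "bio03": [0.2, 0, 0], GEO_PREDICTOR: [0.01, 0, 0]},
                     expl=60.0)
    reference = _fit_with({"bio01": [0.1, 0, 0]}, expl=11.2)
    kept = screen_snps({"geo": geo_first, "weak": weak, "good": good},
                       reference, geo_rank_cut=3)
    assert kept == {"good"}
    with pytest.raises(ValueError):
        screen_snps({"x": good}, None)


def test_per_locus_fits_screen_positive_control(make_landscape):
    gm, sites, _, truth = make_landscape(
        n_sites=20, n_neutral_loci=60, n_adaptive_loci=4,
        cline_strength=3.0, seed=17)
    loci = sorted(truth.adaptive_locus_ids)
    fits = per_locus_gdm_fits(gm, loci, sites, ["bio01", "bio03"], min_n=5)
    assert set(fits) == set(loci)
    for f in fits.values():
        assert GEO_PREDICTOR in f.predictors


# ---------------------------------------------------------------------------
# transformed-climate RGB
# ---------------------------------------------------------------------------

def _grid_from(fit, values):
    g = pd.DataFrame({"cell_id": [f"C{i}" for i in range(len(values))]})
    for p in fit.predictors:
        if p == GEO_PREDICTOR:
            continue
        g[f"{p}_cur"] = values
    return g


def test_rgb_identical_cells_flat_channels():
    fit = _fit_with({"bio01": [0.5, 0.2, 0.1], "bio02": [0.4, 0, 0]})
    grid = _grid_from(fit, np.full(10, 1.0))
    with pytest.warns(UserWarning):
        out = transform_pca_rgb(fit, grid)
    assert (out[["R", "G", "B"]].to_numpy() == 0.5).all()


def test_rgb_channels_bounded_and_zero_coef_predictor_ignored():
    fit = _fit_with({"bio01": [0.5, 0.2, 0.1], "bio02": [0.0, 0.0, 0.0]})
    rng = np.random.default_rng(0)
    grid = _grid_from(fit, rng.uniform(0, 2, 30))
    grid["bio02_cur"] = rng.uniform(0, 2, 30)  # differs but f is constant
    out = transform_pca_rgb(fit, grid)
    rgb = out[["R", "G", "B"]].to_numpy()
    assert (rgb >= 0).all() and (rgb <= 1).all()
    # two cells equal in bio01 but different in the zero-coef bio02
    grid2 = grid.copy()
    grid2.loc[1, "bio01_cur"] = grid2.loc[0, "bio01_cur"]
    out2 = transform_pca_rgb(fit, grid2)
    np.testing.assert_allclose(out2.loc[0, ["R", "G", "B"]].astype(float),
                               out2.loc[1, ["R", "G", "B"]].astype(float),
                               atol=1e-9)
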