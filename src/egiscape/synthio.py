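"""Seeded synthetic landscapes for the climate-adaptation pipeline.

The generator emulates the statistical structure the analysis assumes: sites
on a latitudinal gradient with correlated bioclimatic variables, neutral loci
drifting under a Balding–Nichols model, a minority of adaptive loci whose
site allele frequencies follow logistic clines along one climate variable,
per-genotype missingness, a future climate shift, and smooth habitat
suitability (EI) surfaces with both increasing and decreasing regions.
Ground truth (which loci are adaptive, driven by what, how strongly) is
returned for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._rng import substream
from .containers import MISSING, GenotypeMatrix

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "generate_landscape",
    "generate_ei_surfaces",
    "write_vcf",
    "write_sites_csv",
    "write_grid_csv",
    "write_truth_json",
]

# Suitability response used for the EI surfaces: a scaled Gaussian bump in
# the first (temperature-like) variable.  Fixed constants, not per-cell.
EI_OPTIMUM_C = 15.0
EI_WIDTH_C = 12.0

# Temperature-like variables get deg-C-ish location/scale, precipitation-like
# variables mm-ish; the analysis itself is unit-agnostic.
_TEMP_MU, _TEMP_SIGMA = 15.0, 6.0
_PREC_MU, _PREC_SIGMA = 1000.0, 300.0


def _default_corr_pairs() -> list[tuple[int, int, float]]:
    # mirrors the strongly collinear bioclim pairs seen in global data:
    # annual vs coldest-quarter temperature, warmest-month vs warmest-quarter
    # temperature, driest-month vs driest-quarter precipitation
    return [(0, 10, 0.92), (4, 9, 0.94), (13, 16, 0.99)]


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic landscape.

    Defaults mirror the sampling design the analysis targets: ~75 sites of
    ~5 individuals, moderate neutral differentiation (FST 0.1), clines of
    slope 2 per standardized climate unit on a minority of loci, 19
    correlated bioclimatic variables, light missingness, and a warming
    future shift.
    """

    n_sites: int = 75
    inds_per_site: int = 5
    n_neutral_loci: int = 450
    n_adaptive_loci: int = 50
    fst_neutral: float = 0.1
    cline_strength: float = 2.0
    missing_rate: float = 0.02
    n_climate_vars: int = 19
    climate_corr_pairs: list = field(default_factory=_default_corr_pairs)
    future_shift: np.ndarray | None = None
    grid_cells: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "inds_per_site", "n_neutral_loci",
                     "n_climate_vars", "grid_cells"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_adaptive_loci < 0:
            raise ValueError("n_adaptive_loci must be >= 0")
        if self.n_adaptive_loci > 0 and self.n_climate_vars == 0:
            raise ValueError("adaptive loci require at least one climate variable")
        if not (0.0 < self.fst_neutral < 1.0):
            raise ValueError("fst_neutral must lie in (0, 1)")
        if not (0.0 <= self.missing_rate < 0.5):
            raise ValueError("missing_rate must lie in [0, 0.5)")
        if self.cline_strength < 0:
            raise ValueError("cline_strength must be >= 0")
        if self.future_shift is None:
            self.future_shift = default_future_shift(self.n_climate_vars)
        self.future_shift = np.asarray(self.future_shift, dtype=float)
        if self.future_shift.shape != (self.n_climate_vars,):
            raise ValueError("future_shift must have one delta per climate variable")

    @property
    def n_loci(self) -> int:
        return self.n_neutral_loci + self.n_adaptive_loci

    @property
    def var_names(self) -> list[str]:
        return [f"bio{i + 1:02d}" for i in range(self.n_climate_vars)]


def default_future_shift(n_vars: int) -> np.ndarray:
    """Warming-dominated 2050-style shift: +2 units on temperature-like
    variables, -60 on precipitation-like ones (-0.2 of their scale)."""
    shift = np.full(n_vars, -60.0)
    shift[: min(11, n_vars)] = 2.0
    return shift


@dataclass
class TruthRecord:
    """Ground truth of the planted clines for recovery tests."""

    adaptive_locus_ids: set
    driving_variable: dict
    effect_size: dict
    seed: int

    def __post_init__(self) -> None:
        for lid in self.adaptive_locus_ids:
            if self.effect_size.get(lid, 0.0) == 0.0:
                raise ValueError("adaptive loci must have non-zero effect size")


# ---------------------------------------------------------------------------
# climate model: one latitudinal factor + correlated residuals
# ---------------------------------------------------------------------------

def _loadings(config: SyntheticConfig) -> np.ndarray:
    """Latitude-factor loadings, shrunk where a requested pairwise
    correlation would otherwise be infeasible under the factor model."""
    P = config.n_climate_vars
    lam = np.full(P, 0.4)
    lam[: min(11, P)] = 0.6
    lam[0] = 0.9  # the temperature-like variable tracks latitude strongly
    for i, j, r in config.climate_corr_pairs:
        if i >= P or j >= P:
            continue
        for _ in range(12):
            denom = np.sqrt((1 - lam[i] ** 2) * (1 - lam[j] ** 2))
            if abs(r - lam[i] * lam[j]) <= 0.95 * denom:
                break
            lam[i] *= 0.8
            lam[j] *= 0.8
    return lam


def _residual_root(config: SyntheticConfig) -> np.ndarray:
    """Square root of the residual correlation matrix implied by the
    requested pairwise correlations under the latitude factor model."""
    P = config.n_climate_vars
    lam = _loadings(config)
    R = np.eye(P)
    for i, j, r in config.climate_corr_pairs:
        if i >= P or j >= P:
            continue
        denom = np.sqrt((1 - lam[i] ** 2) * (1 - lam[j] ** 2))
        rij = np.clip((r - lam[i] * lam[j]) / denom, -0.999, 0.999)
        R[i, j] = R[j, i] = rij
    w, V = np.linalg.eigh(R)
    w = np.clip(w, 1e-9, None)
    R = (V * w) @ V.T
    scale = np.sqrt(np.diag(R))
    R = R / np.outer(scale, scale)
    w, V = np.linalg.eigh(R)
    w = np.clip(w, 1e-9, None)
    return V * np.sqrt(w)


def _climate_field(lat: np.ndarray, config: SyntheticConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Bioclim values at the given latitudes: latitude factor + correlated
    noise, mapped onto per-variable units."""
    P = config.n_climate_vars
    lam = _loadings(config)
    lat_z = -np.abs(lat) / np.std(np.abs(lat)) if np.std(lat) > 0 else np.zeros_like(lat)
    lat_z = (lat_z - lat_z.mean()) / (lat_z.std() or 1.0)
    root = _residual_root(config)
    eps = rng.standard_normal((len(lat), P)) @ root.T
    z = lat_z[:, None] * lam[None, :] + eps * np.sqrt(1 - lam[None, :] ** 2)
    mu = np.where(np.arange(P) < min(11, P), _TEMP_MU, _PREC_MU)
    sig = np.where(np.arange(P) < min(11, P), _TEMP_SIGMA, _PREC_SIGMA)
    return pd.DataFrame(mu + sig * z, columns=config.var_names)


# ---------------------------------------------------------------------------
# main generators
# ---------------------------------------------------------------------------

def generate_landscape(config: SyntheticConfig):
    """Generate (GenotypeMatrix, site table, climate grid, TruthRecord).

    Identical config and seed give bit-identical output.
    """
    ss = substream(config.seed, "synthio")
    r_sites, r_climate, r_loci, r_geno, r_miss, r_grid = (
        np.random.default_rng(c) for c in ss.spawn(6)
    )

    # sites on a latitudinal gradient
    S = config.n_sites
    lat = np.linspace(-50.0, 50.0, S) + r_sites.uniform(-1.0, 1.0, S)
    lon = r_sites.uniform(-180.0, 180.0, S)
    sites = pd.DataFrame({
        "site_id": [f"S{i + 1:03d}" for i in range(S)],
        "lon": lon,
        "lat": lat,
    })
    clim = _climate_field(lat, config, r_climate)
    sites = pd.concat([sites, clim], axis=1)

    # loci: one chromosome, positions without replacement from a range dense
    # enough that some pairs land inside a 25 bp window
    L = config.n_loci
    positions = np.sort(r_loci.choice(np.arange(1, 60 * L + 1), size=L, replace=False))
    bases = np.array(list("ACGT"))
    ref_idx = r_loci.integers(0, 4, L)
    alt_idx = (ref_idx + r_loci.integers(1, 4, L)) % 4
    locus_ids = [f"L{i + 1:06d}" for i in range(L)]
    locus_table = pd.DataFrame({
        "locus_id": locus_ids,
        "chrom": "1",
        "pos": positions,
        "ref": bases[ref_idx],
        "alt": bases[alt_idx],
        "n_alt": 1,
    })

    adaptive_idx = np.sort(
        r_loci.choice(L, size=config.n_adaptive_loci, replace=False)
    ) if config.n_adaptive_loci else np.array([], dtype=int)
    is_adaptive = np.zeros(L, dtype=bool)
    is_adaptive[adaptive_idx] = True

    # per-site allele frequencies
    F = config.fst_neutral
    p_site = np.empty((S, L))
    p_anc = r_geno.uniform(0.1, 0.9, L)
    shape = (1.0 - F) / F
    neutral = ~is_adaptive
    p_site[:, neutral] = r_geno.beta(
        p_anc[neutral] * shape, (1.0 - p_anc[neutral]) * shape, size=(S, neutral.sum())
    )

    driving: dict = {}
    effect: dict = {}
    if config.n_adaptive_loci:
        z_clim = clim.to_numpy()
        z_clim = (z_clim - z_clim.mean(axis=0)) / z_clim.std(axis=0)
        drive_idx = r_geno.integers(0, config.n_climate_vars, config.n_adaptive_loci)
        signs = r_geno.choice([-1.0, 1.0], config.n_adaptive_loci)
        base = logit(r_geno.uniform(0.2, 0.8, config.n_adaptive_loci))
        for k, li in enumerate(adaptive_idx):
            beta = signs[k] * config.cline_strength
            p_site[:, li] = expit(base[k] + beta * z_clim[:, drive_idx[k]])
            driving[locus_ids[li]] = config.var_names[drive_idx[k]]
            effect[locus_ids[li]] = float(beta)

    # genotypes and missingness
    n_ind = S * config.inds_per_site
    site_of_ind = np.repeat(np.arange(S), config.inds_per_site)
    calls = r_geno.binomial(2, p_site[site_of_ind, :]).astype(np.int8)
    if config.missing_rate > 0:
        miss = r_miss.random((n_ind, L)) < config.missing_rate
        calls[miss] = MISSING
    individual_table = pd.DataFrame({
        "individual_id": [f"I{i + 1:04d}" for i in range(n_ind)],
        "site_id": sites["site_id"].to_numpy()[site_of_ind],
    })
    gm = GenotypeMatrix(calls, locus_table, individual_table)

    # climate grid: same field evaluated at grid latitudes, plus the shift
    G = config.grid_cells
    glat = np.linspace(-55.0, 55.0, G) + r_grid.uniform(-0.5, 0.5, G)
    glon = r_grid.uniform(-180.0, 180.0, G)
    gclim = _climate_field(glat, config, r_grid)
    grid = pd.DataFrame({
        "cell_id": [f"C{i + 1:05d}" for i in range(G)],
        "lon": glon,
        "lat": glat,
    })
    for j, v in enumerate(config.var_names):
        grid[f"{v}_cur"] = gclim[v]
        grid[f"{v}_fut"] = gclim[v] + config.future_shift[j]

    truth = TruthRecord(
        adaptive_locus_ids={locus_ids[i] for i in adaptive_idx},
        driving_variable=driving,
        effect_size=effect,
        seed=config.seed,
    )
    return gm, sites, grid, truth


def ei_curve(temperature: np.ndarray) -> np.ndarray:
    """Habitat suitability (0-100) as a Gaussian bump in temperature."""
    t = np.asarray(temperature, dtype=float)
    ei = 100.0 * np.exp(-0.5 * ((t - EI_OPTIMUM_C) / EI_WIDTH_C) ** 2)
    return np.clip(ei, 0.0, 100.0)


def generate_ei_surfaces(grid: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Attach EI_C / EI_F columns computed from the temperature-like variable.

    The same fixed unimodal suitability curve is evaluated at current and
    future temperature, so a zero shift gives DEI = 0 everywhere and a
    warming shift depresses EI wherever cells sit above the optimum.
    """
    tvar = config.var_names[0]
    cur, fut = f"{tvar}_cur", f"{tvar}_fut"
    if fut not in grid.columns:
        raise ValueError("grid lacks future climate columns; cannot build EI_F")
    out = grid.copy()
    out["EI_C"] = ei_curve(out[cur].to_numpy())
    out["EI_F"] = ei_curve(out[fut].to_numpy())
    return out


# ---------------------------------------------------------------------------
# writers (plain-text interchange formats)
# ---------------------------------------------------------------------------

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write genotypes as a minimal VCF v4.2 (GT only, 1-based positions)."""
    path = Path(path)
    lt = gm.locus_table
    inds = gm.individual_table["individual_id"].tolist()
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(lt["chrom"]):
            ln = int(lt.loc[lt["chrom"] == chrom, "pos"].max()) + 1000
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(inds) + "\n")
        for j in range(gm.n_loci):
            row = lt.iloc[j]
            gts = "\t".join(_GT_CODE[int(c)] for c in gm.calls[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.locus_id}\t{row.ref}\t"
                     f"{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def write_sites_csv(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, index=False)


def write_grid_csv(grid: pd.DataFrame, path) -> None:
    grid.to_csv(path, index=False)


def write_truth_json(truth: TruthRecord, path) -> None:
    payload = {
        "adaptive_locus_ids": sorted(truth.adaptive_locus_ids),
        "driving_variable": truth.driving_variable,
        "effect_size": truth.effect_size,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
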