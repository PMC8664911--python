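"""Core in-memory containers shared across the pipeline.

Genotypes are held as an individuals x loci matrix of alt-allele dosages
(0, 1, 2) with ``MISSING`` (-1) for uncalled genotypes, alongside pandas
tables describing loci and individuals.  Site/climate tables and climate
grids are plain DataFrames with documented column conventions:

* site table    -- ``site_id``, ``lon``, ``lat``, ``bio01`` .. ``bioNN``
* climate grid  -- ``cell_id``, ``lon``, ``lat``, ``bio01_cur`` ..,
                   ``bio01_fut`` .., optionally ``EI_C``/``EI_F``
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MISSING", "GenotypeMatrix", "DissimMatrix", "climate_columns"]

MISSING: int = -1


def climate_columns(df: pd.DataFrame, suffix: str = "") -> list[str]:
    """Names of bioclimatic columns (``bioNN`` + suffix) in column order."""
    out = []
    for c in df.columns:
        if c.startswith("bio") and c.endswith(suffix):
            core = c[3 : len(c) - len(suffix)] if suffix else c[3:]
            if core.isdigit():
                out.append(c)
    return out


@dataclass
class GenotypeMatrix:
    """Bi-allelic genotype calls with locus and individual metadata.

    Attributes
    ----------
    calls
        ``int8`` array of shape (n_individuals, n_loci); entries in
        {0, 1, 2} are alt-allele dosages, ``MISSING`` marks no-calls.
    locus_table
        One row per locus: ``locus_id``, ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt`` (comma-joined), ``n_alt`` (alt allele count;
        >1 flags a multi-allelic record for downstream removal).
    individual_table
        One row per individual: ``individual_id``, ``site_id``.
    """

    calls: np.ndarray
    locus_table: pd.DataFrame
    individual_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x loci)")
        n_ind, n_loc = self.calls.shape
        if len(self.individual_table) != n_ind:
            raise ValueError("individual_table length does not match calls")
        if len(self.locus_table) != n_loc:
            raise ValueError("locus_table length does not match calls")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes outside {0,1,2,missing}")
        for tab, col in ((self.locus_table, "locus_id"),
                         (self.individual_table, "individual_id")):
            if tab[col].duplicated().any():
                raise ValueError(f"duplicated {col}")
        # positions strictly increasing within each chromosome
        lt = self.locus_table
        for _, grp in lt.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValueError("positions not strictly increasing within chromosome")

    # -- shapes -----------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def locus_ids(self) -> np.ndarray:
        return self.locus_table["locus_id"].to_numpy()

    @property
    def site_ids(self) -> np.ndarray:
        return self.individual_table["site_id"].to_numpy()

    # -- summaries --------------------------------------------------------
    def missing_fraction(self) -> np.ndarray:
        """Per-locus fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=0)

    def pooled_maf(self) -> np.ndarray:
        """Minor-allele frequency pooled over all individuals.

        Computed on non-missing calls only; loci with no calls get MAF 0.
        """
        obs = self.calls != MISSING
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        n = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
        return np.minimum(f, 1.0 - f)

    def site_allele_stats(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
        """Per-site alt-allele frequency, sample size, and het fraction.

        Returns (p, n, h, site_ids): arrays of shape (n_sites, n_loci) with
        ``p`` the alt frequency among non-missing calls, ``n`` the number of
        non-missing individuals and ``h`` the observed heterozygote
        proportion; entries with n == 0 are NaN (p, h) / 0 (n).
        """
        sites = pd.unique(self.individual_table["site_id"])
        P, N, H = [], [], []
        site_arr = self.site_ids
        for s in sites:
            rows = self.calls[site_arr == s]
            obs = rows != MISSING
            n = obs.sum(axis=0)
            alt = np.where(obs, rows, 0).sum(axis=0)
            with np.errstate(invalid="ignore"):
                p = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
                h = np.where(n > 0, (rows == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
            P.append(p)
            N.append(n)
            H.append(h)
        return np.array(P), np.array(N), np.array(H), list(sites)

    # -- subsetting -------------------------------------------------------
    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to loci selected by boolean mask or ids."""
        keep = np.asarray(keep)
        if keep.dtype != bool:
            keep = np.isin(self.locus_ids, keep)
        return GenotypeMatrix(
            calls=self.calls[:, keep],
            locus_table=self.locus_table.loc[keep].reset_index(drop=True),
            individual_table=self.individual_table.copy(),
        )


@dataclass
class DissimMatrix:
    """Symmetric pairwise dissimilarity matrix among populations.

    ``values`` holds the [0, 1]-rescaled dissimilarities used downstream;
    ``raw`` keeps the unscaled (clamped) estimates for inspection.
    """

    ids: list
    values: np.ndarray
    n: np.ndarray
    raw: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match population ids")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        self.values = v

    @property
    def n_pops(self) -> int:
        return len(self.ids)

    def pair_values(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Upper-triangle (i, j, value) arrays, i < j."""
        iu = np.triu_indices(self.n_pops, k=1)
        return iu[0], iu[1], self.values[iu]
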