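"""VCF loading and SNP quality control.

Filters follow the standard landscape-genomics recipe: keep bi-allelic SNPs
with pooled minor-allele frequency >= 5% and per-locus missing rate <= 10%,
then thin to at most one SNP per 25 bp window so retained loci are roughly
independent of local linkage disequilibrium.  All positional logic is
1-based and windows are fixed tiles anchored at position 1.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import MISSING, GenotypeMatrix

__all__ = ["VCFParseError", "load_genotypes", "attach_sites", "qc_filter",
           "window_thin"]

log = logging.getLogger(__name__)


class VCFParseError(ValueError):
    """Raised for records that cannot be interpreted as diploid bi-/multi-allelic SNP calls."""


def load_genotypes(vcf_path, site_of=None) -> GenotypeMatrix:
    """Parse a VCF with GT fields into a GenotypeMatrix.

    Diploid GT values are converted to alt-allele dosage (count of non-ref
    alleles); any call containing ``.`` becomes missing.  Multi-allelic
    records are kept but flagged (``n_alt > 1``) for removal by
    :func:`qc_filter`.  Haploid calls raise :class:`VCFParseError`.

    Parameters
    ----------
    site_of
        Optional mapping individual_id -> site_id.  Without it the site
        assignment is left empty and must be attached before association
        scans (`attach_sites`).
    """
    vcf_path = str(vcf_path)
    try:
        vcf = VCF(vcf_path, gts012=False)
    except Exception as exc:  # htslib raises plain OSError/ValueError
        raise VCFParseError(f"cannot open VCF {vcf_path!r}: {exc}") from exc
    samples = list(vcf.samples)
    rows = []
    calls_cols = []
    for rec_no, var in enumerate(vcf, start=1):
        genos = var.genotypes
        dos = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(genos):
            if len(g) != 3:  # [allele, phased] -> haploid
                raise VCFParseError(
                    f"record {rec_no} ({var.CHROM}:{var.POS}): haploid GT for "
                    f"sample {samples[i]!r}; diploid calls required"
                )
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                dos[i] = MISSING
            else:
                dos[i] = int(a > 0) + int(b > 0)
        alts = [a for a in var.ALT if a != "."]
        rows.append({
            "locus_id": var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}",
            "chrom": var.CHROM,
            "pos": int(var.POS),
            "ref": var.REF,
            "alt": ",".join(alts) if alts else ".",
            "n_alt": len(alts),
        })
        calls_cols.append(dos)
    if not rows:
        raise VCFParseError(f"no variant records in {vcf_path!r}")
    calls = np.stack(calls_cols, axis=1)
    locus_table = pd.DataFrame(rows)
    individual_table = pd.DataFrame({
        "individual_id": samples,
        "site_id": [site_of.get(s, "") for s in samples] if site_of else "",
    })
    return GenotypeMatrix(calls, locus_table, individual_table)


def attach_sites(gm: GenotypeMatrix, sites_csv) -> GenotypeMatrix:
    """Fill the site assignment from a CSV with individual_id,site_id columns
    or infer `site_of` from a sites table written by the synthetic module."""
    mapping = pd.read_csv(sites_csv)
    if not {"individual_id", "site_id"} <= set(mapping.columns):
        raise ValueError("mapping CSV needs individual_id and site_id columns")
    m = dict(zip(mapping["individual_id"], mapping["site_id"]))
    ind = gm.individual_table.copy()
    ind["site_id"] = [m.get(i, "") for i in ind["individual_id"]]
    if (ind["site_id"] == "").any():
        missing = ind.loc[ind["site_id"] == "", "individual_id"].tolist()
        raise ValueError(f"individuals without site assignment: {missing[:5]} ...")
    return GenotypeMatrix(gm.calls, gm.locus_table, ind)


def qc_filter(gm: GenotypeMatrix, maf_min: float = 0.05,
              miss_max: float = 0.10) -> GenotypeMatrix:
    """Drop multi-allelic loci, loci with MAF < maf_min (strict), and loci
    with missing fraction > miss_max (strict).

    MAF is pooled over all individuals on non-missing calls; a fully missing
    locus falls to the missingness rule.  Counts removed per rule are logged
    and attached to the result as ``filter_report``.
    """
    multi = gm.locus_table["n_alt"].to_numpy() > 1
    miss = gm.missing_fraction() > miss_max
    maf = gm.pooled_maf() < maf_min
    # report each locus under the first rule that catches it
    removed_multi = multi
    removed_miss = ~multi & miss
    removed_maf = ~multi & ~miss & maf
    keep = ~(multi | miss | maf)
    report = {
        "input_loci": gm.n_loci,
        "removed_multiallelic": int(removed_multi.sum()),
        "removed_missingness": int(removed_miss.sum()),
        "removed_maf": int(removed_maf.sum()),
        "retained": int(keep.sum()),
    }
    log.info("qc_filter: %s", report)
    out = gm.subset_loci(keep)
    out.filter_report = report  # type: ignore[attr-defined]
    return out


def window_thin(gm: GenotypeMatrix, window_bp: int = 25) -> GenotypeMatrix:
    """Keep at most one locus per non-overlapping window of ``window_bp``
    bases tiled from position 1.

    Within a tile the locus with the highest pooled MAF is kept (most
    informative), ties broken by lowest position.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    if gm.n_loci == 0:
        return gm
    lt = gm.locus_table
    tile = (lt["pos"].to_numpy() - 1) // window_bp
    maf = gm.pooled_maf()
    df = pd.DataFrame({
        "idx": np.arange(gm.n_loci),
        "chrom": lt["chrom"].to_numpy(),
        "tile": tile,
        "maf": maf,
        "pos": lt["pos"].to_numpy(),
    })
    df = df.sort_values(["chrom", "tile", "maf", "pos"],
                        ascending=[True, True, False, True])
    winners = df.groupby(["chrom", "tile"], sort=False).head(1)["idx"].to_numpy()
    keep = np.zeros(gm.n_loci, dtype=bool)
    keep[winners] = True
    log.info("window_thin: %d -> %d loci (window %d bp)",
             gm.n_loci, keep.sum(), window_bp)
    return gm.subset_loci(keep)
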