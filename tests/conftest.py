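"""Shared fixtures: small seeded landscapes and hand-built VCF helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from egiscape import SyntheticConfig, generate_landscape
from egiscape.containers import GenotypeMatrix


@pytest.fixture
def make_landscape():
    """Factory for seeded synthetic landscapes with overridable settings."""

    def _make(**kw):
        defaults = dict(n_sites=20, inds_per_site=5, n_neutral_loci=120,
                        n_adaptive_loci=8, seed=0)
        defaults.update(kw)
        return generate_landscape(SyntheticConfig(**defaults))

    return _make


@pytest.fixture
def write_toy_vcf(tmp_path):
    """Write a VCF from explicit per-locus GT strings.

    records: list of (chrom, pos, ref, alt, [gt strings per individual]).
    """

    def _write(records, n_ind=None, name="toy.vcf"):
        n_ind = n_ind or len(records[0][4])
        inds = [f"I{i:02d}" for i in range(n_ind)]
        lines = ["##fileformat=VCFv4.2",
                 '##contig=<ID=1,length=1000000>',
                 '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
                 "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(inds)]
        for i, (chrom, pos, ref, alt, gts) in enumerate(records):
            lines.append(f"{chrom}\t{pos}\tv{i}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                         + "\t".join(gts))
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


def build_gm(calls, positions=None, site_of_ind=None, chrom="1"):
    """Construct a GenotypeMatrix directly from a call matrix."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_loc = calls.shape
    if positions is None:
        positions = np.arange(1, n_loc + 1) * 100
    if site_of_ind is None:
        site_of_ind = [f"P{i % 2}" for i in range(n_ind)]
    locus_table = pd.DataFrame({
        "locus_id": [f"L{j}" for j in range(n_loc)],
        "chrom": chrom, "pos": positions,
        "ref": "A", "alt": "T", "n_alt": 1,
    })
    individual_table = pd.DataFrame({
        "individual_id": [f"I{i}" for i in range(n_ind)],
        "site_id": site_of_ind,
    })
    return GenotypeMatrix(calls, locus_table, individual_table)
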