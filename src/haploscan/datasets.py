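"""Packaged reference data.

``canchim_significant_snps()`` returns the 48 genome-wide-significant SNPs
reported by a published iHS selection scan of Canchim composite beef
cattle (39 on BTA5, 9 on BTA14; UMD3.1 coordinates): SNP id, chromosome,
position, printed iHS and piHS (2 decimals), the study's window label,
the nearest gene with its boundary distance, and the genic/intergenic
label. The underlying genotypes were never released; this table is the
published end point of the scan and is used to validate the piHS
transform, the significance rule and the region arithmetic against
printed values.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

__all__ = ["canchim_significant_snps"]


def canchim_significant_snps() -> pd.DataFrame:
    path = files("haploscan.data").joinpath("canchim_significant_snps.tsv")
    with path.open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    assert len(df) == 48
    return df
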