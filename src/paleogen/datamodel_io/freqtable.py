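"""TSV frequency tables: population derived/total chromosome counts per SNP.

Layout: columns ``snp chrom pos ref alt anc`` followed by one
``<pop>_der <pop>_tot`` pair per population.  Lines starting with '#' before
the header are metadata and are ignored on read.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from ..errors import FormatError, ValidationError
from .types import FrequencyPanel, SNPRecord

__all__ = ["read_frequency_table", "write_frequency_table"]

_META_COLS = ["snp", "chrom", "pos", "ref", "alt", "anc"]


def write_frequency_table(
    panel: FrequencyPanel, path: str | os.PathLike, header_lines: list[str] | None = None
) -> None:
    rows = {
        "snp": [s.id for s in panel.snps],
        "chrom": [s.chromosome for s in panel.snps],
        "pos": [s.position for s in panel.snps],
        "ref": [s.ref_allele for s in panel.snps],
        "alt": [s.alt_allele for s in panel.snps],
        "anc": [s.ancestral_allele or "." for s in panel.snps],
    }
    for i, pop in enumerate(panel.populations):
        rows[f"{pop}_der"] = panel.derived_count[i]
        rows[f"{pop}_tot"] = panel.total_count[i]
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_frequency_table(path: str | os.PathLike) -> FrequencyPanel:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    pops = []
    for col in df.columns:
        if col.endswith("_der"):
            pop = col[:-4]
            if f"{pop}_tot" not in df.columns:
                raise FormatError(f"{path}: column {col} lacks matching {pop}_tot")
            pops.append(pop)
    snps = [
        SNPRecord(
            str(r.snp), str(r.chrom), int(r.pos), str(r.ref), str(r.alt),
            ancestral_allele=None if str(r.anc) == "." else str(r.anc),
        )
        for r in df.itertuples()
    ]
    derived = np.array([df[f"{p}_der"].to_numpy(dtype=np.int64) for p in pops])
    total = np.array([df[f"{p}_tot"].to_numpy(dtype=np.int64) for p in pops])
    if derived.size == 0:
        derived = derived.reshape(len(pops), len(snps))
        total = total.reshape(len(pops), len(snps))
    try:
        return FrequencyPanel(snps, pops, derived, total)
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from e
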