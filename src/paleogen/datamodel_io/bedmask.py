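"""BED-style interval masks (accessibility, repeats, ancestry tracts).

BED intervals are 0-based half-open; SNP positions are 1-based.  The
conversion happens here, at the reader/mask boundary, and nowhere else:
a SNP at 1-based position p is covered by interval (start, end) iff
start <= p-1 < end.
"""

from __future__ import annotations

import os
from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np

from ..errors import FormatError, ValidationError
from .types import GenotypePanel, SNPRecord

__all__ = ["read_bed", "snp_covered", "apply_region_mask"]

Intervals = Mapping[str, Sequence[tuple[int, int]]]


def read_bed(path: str | os.PathLike) -> dict[str, list[tuple[int, int]]]:
    intervals: dict[str, list[tuple[int, int]]] = defaultdict(list)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: malformed interval start {start} >= end {end}"
                )
            intervals[chrom].append((start, end))
    return dict(intervals)


def _validate(intervals: Intervals) -> None:
    for chrom, ivs in intervals.items():
        for start, end in ivs:
            if start >= end:
                raise ValidationError(
                    f"malformed interval {chrom}:{start}-{end} (start >= end)"
                )


def snp_covered(snps: Sequence[SNPRecord], intervals: Intervals) -> np.ndarray:
    """Boolean vector: SNP falls inside at least one interval."""
    _validate(intervals)
    starts_ends: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in intervals.items():
        ivs = sorted(ivs)
        # merge overlapping so searchsorted gives a clean containment test
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts_ends[chrom] = (
            np.array([m[0] for m in merged]),
            np.array([m[1] for m in merged]),
        )
    out = np.zeros(len(snps), dtype=bool)
    for i, s in enumerate(snps):
        if s.chromosome not in starts_ends:
            continue
        starts, ends = starts_ends[s.chromosome]
        p0 = s.position - 1  # to 0-based
        j = np.searchsorted(starts, p0, side="right") - 1
        out[i] = j >= 0 and p0 < ends[j]
    return out


def apply_region_mask(
    panel: GenotypePanel, intervals: Intervals, mode: str = "keep"
) -> GenotypePanel:
    """Subset panel SNPs to those inside (keep) or outside (drop) the intervals."""
    if mode not in ("keep", "drop"):
        raise ValidationError(f"mode must be 'keep' or 'drop', got {mode!r}")
    covered = snp_covered(panel.snps, intervals)
    keep = covered if mode == "keep" else ~covered
    return panel.subset_snps(keep)
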