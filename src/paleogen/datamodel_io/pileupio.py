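"""samtools-style text pileup reader/writer.

Accepted dialect (one site per line, tab-separated):

    chrom  pos  ref  depth  bases  base_quals  map_quals  [gap_dist  in_repeat]

``bases`` follows samtools mpileup conventions: '.'/',' for the reference
base, ACGTacgt for mismatches; read-start markers '^' (plus the following
mapping-quality character), read-end '$' and deletion placeholders '*' are
tolerated and stripped.  ``map_quals`` is the extended per-read mapping
quality column (mpileup -s); both quality columns are Phred+33 encoded.
The two optional trailing columns carry the gap-distance and repeat
annotations consumed by the diploid filters; they default to "far from any
gap" and "not in repeat".
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from ..errors import FormatError
from .types import PileupSite

__all__ = ["read_pileup", "write_pileup"]


def _parse_bases(bases: str, ref: str) -> list[str]:
    out = []
    i = 0
    while i < len(bases):
        c = bases[i]
        if c == "^":
            i += 2  # skip the mapping-quality char after a read start
            continue
        if c in "$*<>":
            i += 1
            continue
        if c in ".,":
            out.append(ref.upper())
        elif c.upper() in "ACGTN":
            out.append(c.upper())
        else:
            raise FormatError(f"unparseable pileup base character {c!r}")
        i += 1
    return out


def read_pileup(path: str | os.PathLike) -> Iterator[PileupSite]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise FormatError(f"{path}:{lineno}: expected >= 7 columns")
            chrom, pos, ref, depth, bases, bqs, mqs = fields[:7]
            base_list = _parse_bases(bases, ref)
            bq = [ord(c) - 33 for c in bqs]
            mq = [ord(c) - 33 for c in mqs]
            if not (len(base_list) == len(bq) == len(mq) == int(depth)):
                raise FormatError(
                    f"{path}:{lineno}: depth {depth} inconsistent with "
                    f"{len(base_list)} bases / {len(bq)} BQs / {len(mq)} MQs"
                )
            gap = int(fields[7]) if len(fields) > 7 else 10**9
            rep = fields[8] == "1" if len(fields) > 8 else False
            yield PileupSite(
                chrom, int(pos), ref.upper(),
                list(zip(base_list, bq, mq)),
                gap_distance=gap, in_repeat=rep,
            )


def write_pileup(sites: Iterable[PileupSite], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in sites:
            bases = "".join(b for b, _, _ in s.reads)
            bqs = "".join(chr(min(q, 60) + 33) for _, q, _ in s.reads)
            mqs = "".join(chr(min(q, 60) + 33) for _, _, q in s.reads)
            fh.write(
                f"{s.chromosome}\t{s.position}\t{s.ref}\t{s.depth}\t"
                f"{bases}\t{bqs}\t{mqs}\t{s.gap_distance}\t{int(s.in_repeat)}\n"
            )
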