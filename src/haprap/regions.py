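"""Region chunking for genome-scale runs.

The estimator is meant for moderately small marker sets, so larger regions
are split into contiguous chunks (at most 20 SNPs by default) fine-mapped
independently.  Users may supply split positions (e.g. recombination
hotspots); otherwise chunks are fixed-size.
"""

from __future__ import annotations

from .errors import OrderingError
from .panel import SnpMeta

DEFAULT_CHUNK_SIZE = 20


def chunk_region(
    snps: list[SnpMeta],
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    boundaries: list[int] | None = None,
) -> list[list[SnpMeta]]:
    """Partition position-sorted SNPs into contiguous chunks.

    ``boundaries`` are base-pair positions: a SNP with pos <= boundary falls
    left of the cut.  Within each segment, greedy fixed-size chunks of at
    most ``chunk_size``.  The concatenated chunks always reproduce the input
    list (a true partition).
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be at least 1")
    positions = [s.pos for s in snps]
    if positions != sorted(positions):
        raise OrderingError("SNPs must be sorted by position before chunking")
    segments: list[list[SnpMeta]] = []
    if boundaries:
        cuts = sorted(boundaries)
        current: list[SnpMeta] = []
        ci = 0
        for s in snps:
            while ci < len(cuts) and s.pos > cuts[ci]:
                if current:
                    segments.append(current)
                    current = []
                ci += 1
            current.append(s)
        if current:
            segments.append(current)
    else:
        segments = [list(snps)] if snps else []
    chunks: list[list[SnpMeta]] = []
    for seg in segments:
        for i in range(0, len(seg), chunk_size):
            chunks.append(seg[i : i + chunk_size])
    return chunks
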