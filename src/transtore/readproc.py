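"""Read processing and retrieval filters.

Turns sequencing reads into compressed strands and applies the retrieval
filters: flank trimming, run-length compression, in-silico size selection of
raw strands, the two-step filter (designed length + terminal C, then most
abundant variant), and top-strand selection for the reconstruction decoder.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
from Bio import SeqIO

from .channel import CompressedStrand, RawStrand

logger = logging.getLogger(__name__)

__all__ = [
    "TrimSpec",
    "StrandPool",
    "RetrievalFailure",
    "trim_read",
    "run_length_compress",
    "size_select",
    "two_step_filter",
    "select_top_strands",
    "read_fastx",
    "pool_from_reads",
]


class RetrievalFailure(ValueError):
    """No strand survives a retrieval filter."""


@dataclass(frozen=True)
class TrimSpec:
    """Flanks to locate and remove: the 3' end of the initiator oligo and the
    5' end of the ligated adapter. ``max_error_fraction`` is the edit-distance
    tolerance as a fraction of the flank length (0.10 for Illumina-style
    reads, 0.25 for nanopore-style)."""

    initiator_suffix: str
    adapter_prefix: str
    max_error_fraction: float = 0.10

    def __post_init__(self):
        if not self.initiator_suffix or not self.adapter_prefix:
            raise ValueError("both flanks must be non-empty")
        if not 0.0 <= self.max_error_fraction <= 1.0:
            raise ValueError("max_error_fraction outside [0, 1]")


def _best_infix(
    flank: str, read: str, max_errors: int, prefer: str = "left"
) -> tuple[int, int] | None:
    """(start, end) of the best occurrence of ``flank`` in ``read`` with at
    most ``max_errors`` edits, or None.

    Among co-optimal locations, ``prefer="right"`` takes the one extending
    furthest right (used for the upstream initiator flank, so none of the
    flank bleeds into the interior) and ``prefer="left"`` the leftmost.
    """
    res = edlib.align(flank, read, mode="HW", task="locations", k=max_errors)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    locs = [(s if s is not None else 0, e) for s, e in res["locations"]]
    if prefer == "right":
        start, end = max(locs, key=lambda x: (x[1], x[0]))
    else:
        start, end = min(locs)
    return start, end + 1  # half-open


def trim_read(read: str, spec: TrimSpec) -> str | None:
    """Interior of ``read`` between its two flanks, or None (rejection).

    Each flank must occur with edit distance at most
    ``floor(max_error_fraction * len(flank))``; the adapter is searched only
    downstream of the initiator match.
    """
    read = read.upper()
    k_init = int(spec.max_error_fraction * len(spec.initiator_suffix))
    loc = _best_infix(spec.initiator_suffix.upper(), read, k_init, prefer="right")
    if loc is None:
        return None
    interior_start = loc[1]
    k_adap = int(spec.max_error_fraction * len(spec.adapter_prefix))
    tail = read[interior_start:]
    loc2 = _best_infix(spec.adapter_prefix.upper(), tail, k_adap)
    if loc2 is None:
        return None
    return tail[: loc2[0]]


def run_length_compress(seq: str) -> CompressedStrand:
    """Merge homopolymer runs; record run lengths. Idempotent."""
    bases = []
    runs: list[int] = []
    for b in seq:
        if bases and bases[-1] == b:
            runs[-1] += 1
        else:
            bases.append(b)
            runs.append(1)
    return CompressedStrand(bases="".join(bases), run_lengths=tuple(runs))


def size_select(
    pool: Sequence[RawStrand | str], min_len: int, max_len: int
) -> list[RawStrand | str]:
    """Keep strands whose raw length lies in the closed interval [min_len, max_len]."""
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    return [s for s in pool if min_len <= len(s) <= max_len]


@dataclass
class StrandPool:
    """Multiset of compressed-strand variants with read counts."""

    entries: Counter = field(default_factory=Counter)
    template_label: str = ""

    @property
    def total_reads(self) -> int:
        return int(sum(self.entries.values()))

    @property
    def n_variants(self) -> int:
        return len(self.entries)

    def add(self, bases: str, count: int = 1) -> None:
        if count < 1:
            raise ValueError("counts must be >= 1")
        self.entries[bases] += count

    def subsample(self, n_reads: int, rng: np.random.Generator) -> "StrandPool":
        """Uniform subsample of ``n_reads`` reads without replacement."""
        variants = sorted(self.entries)
        counts = np.array([self.entries[v] for v in variants], dtype=np.int64)
        total = int(counts.sum())
        if n_reads >= total:
            return StrandPool(Counter(self.entries), self.template_label)
        picked = rng.multivariate_hypergeometric(counts, n_reads)
        sub = Counter(
            {v: int(c) for v, c in zip(variants, picked) if c > 0}
        )
        return StrandPool(sub, self.template_label)


def pool_from_reads(
    reads: Iterable[str], template_label: str = "", trim: TrimSpec | None = None
) -> StrandPool:
    """Run-length-compress reads (optionally trimming flanks first) into a pool."""
    pool = StrandPool(template_label=template_label)
    for read in reads:
        if trim is not None:
            trimmed = trim_read(read, trim)
            if trimmed is None:
                continue
            read = trimmed
        if read:
            pool.add(run_length_compress(read).bases)
    return pool


def two_step_filter(pool: StrandPool, expected_length: int) -> CompressedStrand:
    """The two-step retrieval filter: keep strands of exactly the designed
    compressed length that end in the terminal ligation C, then return the
    most abundant surviving variant (ties broken lexicographically)."""
    survivors = {
        v: c
        for v, c in pool.entries.items()
        if len(v) == expected_length and v.endswith("C")
    }
    if not survivors:
        raise RetrievalFailure(
            f"no strand of length {expected_length} ending in C "
            f"(pool of {pool.total_reads} reads)"
        )
    best_count = max(survivors.values())
    winners = sorted(v for v, c in survivors.items() if c == best_count)
    if len(winners) > 1:
        warnings.warn(
            f"abundance tie among {len(winners)} variants; returning the "
            "lexicographically smallest",
            stacklevel=2,
        )
    return CompressedStrand(bases=winners[0], origin_template=pool.template_label)


# target-read brackets -> read-count cap used to exclude aberrant over-amplified
# variants; the cap grows with the sampling depth
DEFAULT_COUNT_CAPS: tuple[tuple[int, int], ...] = (
    (100, 1),
    (200, 2),
    (300, 3),
    (500, 4),
    (10**9, 5),
)


def _cap_for(target_reads: int, caps=DEFAULT_COUNT_CAPS) -> int:
    for bound, cap in caps:
        if target_reads <= bound:
            return cap
    return caps[-1][1]


def select_top_strands(
    pool: StrandPool,
    target_reads: int,
    rng: np.random.Generator,
    keep: int = 10,
    count_cap: int | None = None,
) -> list[CompressedStrand]:
    """Select the strands handed to the reconstruction decoder.

    Randomly subsample ``target_reads`` reads, drop variants whose read count
    exceeds ``count_cap`` (aberrant, typically chimeric or over-amplified
    species), rank the rest by compressed length descending, and keep the top
    ``keep`` variants.
    """
    if keep < 1:
        raise ValueError("keep must be >= 1")
    if count_cap is None:
        count_cap = _cap_for(target_reads)
    sub = pool.subsample(target_reads, rng)
    kept = [v for v, c in sub.entries.items() if c <= count_cap]
    kept.sort(key=lambda v: (-len(v), v))
    if len(kept) < keep:
        logger.warning(
            "only %d variants survive filtering (requested %d)", len(kept), keep
        )
    return [
        CompressedStrand(bases=v, origin_template=pool.template_label)
        for v in kept[:keep]
    ]


def read_fastx(path: str | Path) -> list[str]:
    """Sequences from a FASTA/FASTQ file (format inferred from the extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [str(rec.seq) for rec in SeqIO.parse(str(path), fmt)]
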