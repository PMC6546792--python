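"""Stochastic model of enzymatic synthesis and sequencing.

Two levels of simulation are provided:

* the *raw* level (:func:`simulate_raw_strand`): every synthesis cycle either
  fails (probability ``p_miss``, a missing nucleotide) or appends a
  homopolymeric run whose length follows a shifted geometric law with a
  per-transition mean (distributive TdT kinetics under apyrase limitation);
  sequencing substitutions/insertions are layered on by
  :func:`inject_sequencing_errors`;
* the *compressed* level (:func:`simulate_strand_c`): the Markov error model
  acting directly on the transition sequence — each template nucleotide is
  independently deleted or substituted and single-base insertions occur after
  each position — used for large-scale codec simulations. Its generative
  process is exactly the one integrated by the decoder's likelihood.

All randomness flows through an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .codec import NUCLEOTIDES, TemplateSequence

__all__ = [
    "ChannelModel",
    "RawStrand",
    "CompressedStrand",
    "simulate_raw_strand",
    "inject_sequencing_errors",
    "simulate_strand_c",
    "simulate_read_set",
    "write_fastq",
]

_IDX = {b: i for i, b in enumerate(NUCLEOTIDES)}


@dataclass(frozen=True)
class ChannelModel:
    """Error probabilities and extension-length law of the synthesis channel.

    Defaults are calibrated to the observed per-strand error fractions of the
    bead-synthesis experiments: ``p_miss = 0.113`` makes ~66% of 9-cycle
    syntheses lose at least one nucleotide, and ``p_mismatch``/``p_insert``
    are set analogously to the ~9.5%/~10.7% per-strand rates. They are
    configuration values, not measurements.

    ``extension_mean`` is either a scalar or a 4x4 matrix indexed by
    (previous base, added base); entries are mean run lengths (>= 1).
    """

    p_miss: float = 0.113
    p_mismatch: float = 0.011
    p_insert: float = 0.012
    extension_mean: float | np.ndarray = 2.5

    def __post_init__(self):
        for name in ("p_miss", "p_mismatch", "p_insert"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_miss + self.p_mismatch > 1.0 + 1e-12:
            raise ValueError("p_miss + p_mismatch must not exceed 1")
        mat = self.extension_matrix()
        if np.any(mat < 1.0):
            raise ValueError("extension means must be >= 1")

    def extension_matrix(self) -> np.ndarray:
        if np.isscalar(self.extension_mean):
            return np.full((4, 4), float(self.extension_mean))
        mat = np.asarray(self.extension_mean, dtype=float)
        if mat.shape != (4, 4):
            raise ValueError("extension_mean matrix must be 4x4")
        return mat


@dataclass(frozen=True)
class RawStrand:
    """A synthesized strand as sequenced, homopolymer runs included."""

    bases: str
    origin_template: str = ""

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class CompressedStrand:
    """A strand after run-length compression: no two adjacent bases identical."""

    bases: str
    run_lengths: tuple[int, ...] | None = None
    origin_template: str = ""

    def __post_init__(self):
        for a, b in zip(self.bases, self.bases[1:]):
            if a == b:
                raise ValueError("compressed strand contains a self-transition")
        if self.run_lengths is not None:
            if len(self.run_lengths) != len(self.bases):
                raise ValueError("one run length per base required")
            if any(r < 1 for r in self.run_lengths):
                raise ValueError("run lengths must be >= 1")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def raw_length(self) -> int:
        if self.run_lengths is None:
            return len(self.bases)
        return int(sum(self.run_lengths))


def _merge_runs(bases: str) -> str:
    out = []
    for b in bases:
        if not out or out[-1] != b:
            out.append(b)
    return "".join(out)


def simulate_raw_strand(
    template: TemplateSequence, model: ChannelModel, rng: np.random.Generator
) -> RawStrand:
    """Synthesize one raw strand: per cycle, zero extension with ``p_miss``,
    otherwise a shifted-geometric run with the transition's mean length.

    The ligation tail (when the template carries one) is a guaranteed final
    extension — the tail is added in bulk after the last cycle, not rationed
    by the cycle chemistry.
    """
    means = model.extension_matrix()
    runs = []
    prev = template.initiator_terminal
    for base in template.bases:
        if rng.random() >= model.p_miss:
            mu = means[_IDX[prev], _IDX[base]]
            n = int(rng.geometric(1.0 / mu)) if mu > 1.0 else 1
            runs.append(base * n)
        prev = base
    for base in template.ligation_tail:
        mu = means[_IDX[prev], _IDX[base]]
        n = int(rng.geometric(1.0 / mu)) if mu > 1.0 else 1
        runs.append(base * n)
        prev = base
    return RawStrand(bases="".join(runs), origin_template=template.label)


def inject_sequencing_errors(
    raw: RawStrand, model: ChannelModel, rng: np.random.Generator
) -> RawStrand:
    """Independent per-base substitutions and per-gap single-base insertions."""
    out = []
    for b in raw.bases:
        if model.p_mismatch > 0 and rng.random() < model.p_mismatch:
            b = NUCLEOTIDES[(_IDX[b] + 1 + rng.integers(3)) % 4]
        out.append(b)
        if model.p_insert > 0 and rng.random() < model.p_insert:
            out.append(NUCLEOTIDES[rng.integers(4)])
    return RawStrand(bases="".join(out), origin_template=raw.origin_template)


def simulate_strand_c(
    template: TemplateSequence, model: ChannelModel, rng: np.random.Generator
) -> CompressedStrand:
    """Markov compressed-level channel: per template nucleotide an independent
    deletion or substitution, a single-base insertion after each position,
    then re-compression of any adjacent duplicates the errors created."""
    out = []
    for base in template.bases:
        u = rng.random()
        if u < model.p_miss:
            pass  # missing nucleotide
        else:
            if u < model.p_miss + (1.0 - model.p_miss) * model.p_mismatch:
                base = NUCLEOTIDES[(_IDX[base] + 1 + rng.integers(3)) % 4]
            out.append(base)
        if model.p_insert > 0 and rng.random() < model.p_insert:
            out.append(NUCLEOTIDES[rng.integers(4)])
    # ligation tail: a guaranteed final extension, outside the error model
    out.append(template.ligation_tail)
    return CompressedStrand(bases=_merge_runs("".join(out)), origin_template=template.label)


def simulate_read_set(
    template: TemplateSequence,
    model: ChannelModel,
    n_reads: int,
    run_duration: float,
    rng: np.random.Generator,
) -> list[tuple[RawStrand, float]]:
    """Raw strands with sequencing errors and uniform arrival timestamps."""
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    times = np.sort(rng.uniform(0.0, run_duration, size=n_reads))
    reads = []
    for t in times:
        raw = simulate_raw_strand(template, model, rng)
        raw = inject_sequencing_errors(raw, model, rng)
        reads.append((raw, float(t)))
    return reads


def write_fastq(
    reads: Iterable[tuple[RawStrand, float]] | Iterable[RawStrand],
    path: str | Path,
    quality_char: str = "I",
) -> int:
    """Write reads as FASTQ with dummy qualities; arrival time and origin
    template recorded in the description. Returns the number of records."""
    path = Path(path)
    n = 0
    with path.open("w") as fh:
        for item in reads:
            if isinstance(item, tuple):
                read, t = item
                desc = f"template={read.origin_template or 'NA'} time={t:.4f}"
            else:
                read = item
                desc = f"template={read.origin_template or 'NA'}"
            fh.write(f"@read{n:06d} {desc}\n{read.bases}\n+\n{quality_char * len(read.bases)}\n")
            n += 1
    return n
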