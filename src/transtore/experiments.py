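"""Reproducible experiment harness.

Decoding-accuracy trials (random payload -> encode -> simulate a strand
population -> MAP reconstruction -> consensus -> demodulate -> ECC ->
bit-exact comparison), parameter sweeps, the streaming-retrieval simulation
for real-time sequencing, storage-efficiency reports, and the synthetic
fixture generator. Every stochastic experiment takes an integer seed and is
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import codec as _codec
from .bch import BCHDecodeFailure
from .channel import (
    ChannelModel,
    simulate_read_set,
    simulate_strand_c,
    write_fastq,
)
from .codec import (
    LOG2_3,
    CodecProfile,
    TemplateSequence,
    TransitionTable,
    build_scaffold,
    builtin_profile,
    encode_message,
)
from .decoder import consensus, map_decode

__all__ = [
    "TrialReport",
    "StreamingReport",
    "run_decoding_trials",
    "sweep",
    "streaming_retrieval_sim",
    "efficiency_report",
    "generate_fixtures",
    "E0_TEMPLATE",
]

# 16-nt error-analysis template covering all 12 transition types within its
# first 12 transitions (Eulerian walk from the initiator terminal G), then
# four repeated transitions; used by the E0-like synthetic fixture.
E0_TEMPLATE = TemplateSequence(bases="ACAGCGTATCTGACGT", initiator_terminal="G", label="E0")


@dataclass(frozen=True)
class TrialReport:
    profile: str
    p_miss: float
    p_mismatch: float
    p_insert: float
    n_strands: int
    n_trials: int
    n_success: int
    seed: int

    @property
    def accuracy(self) -> float:
        return self.n_success / self.n_trials

    def to_dict(self) -> dict:
        d = asdict(self)
        d["accuracy"] = self.accuracy
        return d


@dataclass(frozen=True)
class StreamingReport:
    increments: tuple[float, ...]  # fraction of run per increment
    success_prob: tuple[float, ...]
    robust_fraction: float  # earliest fraction with prob >= threshold
    threshold: float
    increment: float
    n_resamples: int
    never_robust: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def _random_info_bits(profile: CodecProfile, rng: np.random.Generator) -> str:
    return "".join("1" if b else "0" for b in rng.integers(0, 2, size=profile.omega))


def _template_from_info(
    info_bits: str, profile: CodecProfile, table: TransitionTable
) -> TemplateSequence:
    rec = _codec.AddressedPayload(
        address=int(info_bits[: profile.address_bits], 2) if profile.address_bits else 0,
        data_bits=info_bits[profile.address_bits :],
    )
    trits = _codec._record_to_trits(rec, profile)
    return _codec._assemble_template(trits, profile, table)


def decode_strand_population(
    strands, profile: CodecProfile, model: ChannelModel, table: TransitionTable
) -> str | None:
    """Full decode of one template's strand population down to Omega info
    bits; None when the block is uncorrectable or demodulation overflows."""
    result = map_decode(strands, profile, model)
    seq = consensus(
        result.posterior,
        build_scaffold(profile),
        initiator_terminal=profile.initiator_terminal,
    )
    try:
        trits = _codec._info_trits_from_template(seq.bases, profile, table)
        rec, _ = _codec._trits_to_record(trits, profile)
    except (ValueError, BCHDecodeFailure):
        return None
    addr = (
        format(rec.address, f"0{profile.address_bits}b") if profile.address_bits else ""
    )
    return addr + rec.data_bits


def run_decoding_trials(
    profile: CodecProfile | str,
    model: ChannelModel,
    n_strands: int,
    n_trials: int,
    seed: int,
) -> TrialReport:
    """Fraction of trials with bit-exact recovery of a random Omega-bit
    information word from ``n_strands`` simulated compressed strands."""
    if isinstance(profile, str):
        profile = builtin_profile(profile)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    table = TransitionTable()
    rng = np.random.default_rng(seed)
    n_success = 0
    for _ in range(n_trials):
        info = _random_info_bits(profile, rng)
        template = _template_from_info(info, profile, table)
        strands = [simulate_strand_c(template, model, rng) for _ in range(n_strands)]
        decoded = decode_strand_population(strands, profile, model, table)
        if decoded == info:
            n_success += 1
    return TrialReport(
        profile=profile.name,
        p_miss=model.p_miss,
        p_mismatch=model.p_mismatch,
        p_insert=model.p_insert,
        n_strands=n_strands,
        n_trials=n_trials,
        n_success=n_success,
        seed=seed,
    )


def sweep(
    profile: CodecProfile | str,
    models: Sequence[ChannelModel],
    strand_counts: Sequence[int],
    n_trials: int,
    seed: int,
) -> pd.DataFrame:
    """Grid of decoding trials: one row per (channel model, strand count)."""
    if not models or not strand_counts:
        raise ValueError("model grid and strand counts must be non-empty")
    rows = []
    trial_seed = seed
    for model in models:
        for n_strands in strand_counts:
            rep = run_decoding_trials(profile, model, n_strands, n_trials, trial_seed)
            rows.append(rep.to_dict())
            trial_seed += 1
    return pd.DataFrame(rows)


def streaming_retrieval_sim(
    reads: Sequence[tuple[object, float]],
    retrieve: Callable[[list], bool],
    run_duration: float,
    increment: float,
    n_resamples: int,
    seed: int,
    threshold: float = 0.9999,
) -> StreamingReport:
    """Earliest fraction of a sequencing run at which retrieval is robust.

    Mirrors the real-time nanopore analysis: for each time increment the read
    timestamps are shuffled and the number of reads proportional to the
    elapsed fraction is resampled ``n_resamples`` times; ``retrieve`` is a
    predicate on a read subset (e.g. filter + compare against the truth).
    Robust retrieval means success probability >= ``threshold``.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if increment <= 0 or increment > run_duration:
        raise ValueError("increment must be in (0, run_duration]")
    rng = np.random.default_rng(seed)
    items = [r for r, _ in reads]
    n_total = len(items)
    n_steps = int(round(run_duration / increment))
    fractions = [(i + 1) / n_steps for i in range(n_steps)]
    probs = []
    robust_at = None
    for frac in fractions:
        n_sub = int(round(frac * n_total))
        hits = 0
        for _ in range(n_resamples):
            idx = rng.choice(n_total, size=n_sub, replace=False) if n_sub < n_total else np.arange(n_total)
            if retrieve([items[i] for i in idx]):
                hits += 1
        prob = hits / n_resamples
        probs.append(prob)
        if robust_at is None and prob >= threshold:
            robust_at = frac
    never = robust_at is None
    return StreamingReport(
        increments=tuple(fractions),
        success_prob=tuple(probs),
        robust_fraction=1.0 if never else robust_at,
        threshold=threshold,
        increment=increment,
        n_resamples=n_resamples,
        never_robust=never,
    )


def efficiency_report(profiles: Iterable[CodecProfile | str]) -> pd.DataFrame:
    """Storage-efficiency table: bits per template nucleotide, sync and ECC
    overheads; asserts that no profile beats the log2(3) transition ceiling."""
    rows = []
    for p in profiles:
        if isinstance(p, str):
            p = builtin_profile(p)
        bits_per_transition = p.B / p.n_info
        assert bits_per_transition <= LOG2_3 + 1e-12, p.name
        rows.append(
            {
                "profile": p.name,
                "K": p.K,
                "B": p.B,
                "omega": p.omega,
                "address_bits": p.address_bits,
                "n_info": p.n_info,
                "n_sync": p.n_sync,
                "bits_per_nt": p.omega / p.K,
                "bits_per_transition": bits_per_transition,
                "sync_overhead": p.n_sync / p.K,
                "ecc_overhead": (p.B - p.omega) / p.B if p.B else 0.0,
                "ceiling_bits_per_transition": round(LOG2_3, 2),
            }
        )
    return pd.DataFrame(rows)


def generate_fixtures(outdir: str | Path, seed: int, reads_per_template: int = 60) -> dict:
    """Write synthetic FASTQ read sets with ground truth for three scenarios:
    hello-world-like (8-nt templates, polyC tail), Eureka-like (16-nt
    scaffolded templates) and an E0-like single-template error-analysis set.
    Returns the manifest (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    table = TransitionTable()
    model = ChannelModel()
    manifest: dict = {"seed": seed, "channel": {
        "p_miss": model.p_miss, "p_mismatch": model.p_mismatch,
        "p_insert": model.p_insert}, "sets": {}}

    for name, payload in [("hello_world", b"hello world!"), ("eureka", b"Eureka!")]:
        profile = builtin_profile(name)
        templates = encode_message(payload, profile, table)
        reads = []
        for tpl in templates:
            reads.extend(
                simulate_read_set(tpl, model, reads_per_template, 48.0, rng)
            )
        fq = outdir / f"{name}.fastq"
        write_fastq(reads, fq)
        manifest["sets"][name] = {
            "fastq": fq.name,
            "payload": payload.decode(),
            "profile": profile.to_dict(),
            "templates": {t.label: t.bases for t in templates},
            "n_reads": len(reads),
        }

    reads = simulate_read_set(E0_TEMPLATE, model, reads_per_template * 4, 48.0, rng)
    fq = outdir / "e0.fastq"
    write_fastq(reads, fq)
    manifest["sets"]["e0"] = {
        "fastq": fq.name,
        "template": E0_TEMPLATE.bases,
        "n_reads": len(reads),
    }
    (outdir / "truth.json").write_text(json.dumps(manifest, indent=2))
    return manifest
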