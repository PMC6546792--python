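"""Template reconstruction from populations of imperfect compressed strands.

The synthesis channel is an insertion/deletion/substitution edit channel
acting position-by-position on the template: each template nucleotide is
deleted with probability ``p_miss``, otherwise emitted correctly with
probability ``1 - p_mismatch`` or substituted uniformly among the other
three bases; after every template position a single uniform base is inserted
with probability ``p_insert``. Observed strands are run-length compressed,
so the likelihood marginalizes raw edit histories grouped by their
compressed image: re-emitting (or re-inserting) the base of the current run
is absorbed and consumes no observed symbol.
:func:`strand_log_likelihood` integrates over all such histories with a
forward dynamic program (scaled linear space with per-row log offsets).

Reconstruction maximizes the product of strand likelihoods over
transition-valid, scaffold-consistent templates of the designed length K.
The search is factorized along the synchronization scaffold:

1. a left-to-right beam over per-segment transition-valid candidates (a
   segment is a group of information nucleotides plus its trailing
   synchronization nucleotide), where each strand's anchoring ambiguity is
   marginalized exactly by its forward vector and pruning combines forward
   mass with a binomial suffix-consumption heuristic calibrated from the
   observed strand lengths;
2. coordinate-wise refinement: each segment (then each adjacent segment
   pair, which resolves shift errors spanning a synchronization nucleotide)
   is re-optimized under the exact joint likelihood with the rest of the
   template fixed, using precomputed backward vectors, sweeping to a fixed
   point. No refinement step can decrease the joint likelihood.

The final sweep's per-segment conditional candidate weights give the
per-position posterior; the fixed point is the MAP sequence. For small K,
:func:`exhaustive_map_decode` scores every consistent template and serves as
the ground-truth reference for the factorized search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .channel import ChannelModel, CompressedStrand
from .codec import (
    NUCLEOTIDES,
    CodecProfile,
    Scaffold,
    TemplateSequence,
    build_scaffold,
)

__all__ = [
    "ReconstructionPosterior",
    "DecodeResult",
    "strand_log_likelihood",
    "enumerate_consistent",
    "map_decode",
    "exhaustive_map_decode",
    "consensus",
]

_IDX = {b: i for i, b in enumerate(NUCLEOTIDES)}
_NEG_INF = -np.inf


@dataclass(frozen=True)
class ReconstructionPosterior:
    """Per-position nucleotide probabilities, columns ordered A, C, G, T."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("posterior must be K x 4")
        if np.any(p < -1e-12):
            raise ValueError("posterior entries must be non-negative")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("posterior rows must sum to 1")
        object.__setattr__(self, "probs", p)

    def __len__(self) -> int:
        return self.probs.shape[0]

    def argmax_bases(self) -> str:
        return "".join(NUCLEOTIDES[i] for i in np.argmax(self.probs, axis=1))


@dataclass(frozen=True)
class DecodeResult:
    map_sequence: TemplateSequence
    posterior: ReconstructionPosterior
    log_score: float
    n_strands_used: int
    low_confidence: bool = False


# ---------------------------------------------------------------------------
# channel forward/backward DP (scaled linear space)


class _ChannelProbs:
    """Per-position move probabilities of the compressed-strand channel."""

    def __init__(self, model: ChannelModel | None):
        if model is None:
            # a guaranteed extension (the ligation tail): always emitted,
            # never substituted, no insertion gap
            pm = ps = pi = 0.0
        else:
            pm, ps, pi = model.p_miss, model.p_mismatch, model.p_insert
        self.miss = pm
        self.emit_match = (1.0 - pm) * (1.0 - ps)
        self.emit_mis = (1.0 - pm) * ps / 3.0
        self.noins = 1.0 - pi
        self.ins = pi / 4.0
        # the insertion gap keeps the state when nothing is inserted or when
        # the inserted base equals the current run's base (absorbed by
        # run-length compression)
        self.stay_absorb = 1.0 - 0.75 * pi
        self.has_ins = pi > 0.0


_TAIL_PROBS = _ChannelProbs(None)


class _Forward:
    """Scaled forward mass: ``lin`` (C, S, L+1) with per-(C, S) log offsets.

    ``lin[c, s, j] * exp(off[c, s])`` is the probability that strand ``s``'s
    first ``j`` observed symbols were produced by the template prefix of
    candidate ``c``.
    """

    __slots__ = ("lin", "off")

    def __init__(self, lin: np.ndarray, off: np.ndarray):
        self.lin = lin
        self.off = off

    @classmethod
    def initial(cls, C: int, S: int, L: int) -> "_Forward":
        lin = np.zeros((C, S, L + 1))
        lin[:, :, 0] = 1.0
        return cls(lin, np.zeros((C, S)))

    def broadcast(self, C: int) -> "_Forward":
        return _Forward(
            np.broadcast_to(self.lin, (C,) + self.lin.shape[1:]).copy(),
            np.broadcast_to(self.off, (C,) + self.off.shape[1:]).copy(),
        )


def _emission(bases, strands, in_range, probs) -> np.ndarray:
    E = np.where(
        strands[None, :, :] == bases[:, None, None], probs.emit_match, probs.emit_mis
    )
    E *= in_range[None, :, :]
    return E


def _renorm(lin: np.ndarray, off: np.ndarray) -> None:
    m = lin.max(axis=2)
    nz = m > 0.0
    with np.errstate(divide="ignore"):
        off += np.where(nz, np.log(np.where(nz, m, 1.0)), _NEG_INF)
    lin /= np.where(nz, m, 1.0)[:, :, None]


def _fwd_step(F: _Forward, bases, strands, in_range, probs) -> _Forward:
    """Advance the forward mass by one template position."""
    E = _emission(bases, strands, in_range, probs)
    A = F.lin
    B = A * probs.miss
    B[:, :, 1:] += A[:, :, :-1] * E  # emit a new observed symbol
    B[:, :, 1:] += A[:, :, 1:] * E  # extend the current run (absorbed)
    if probs.has_ins:
        ins_term = B[:, :, :-1] * probs.ins * in_range[None]
        B[:, :, 0] *= probs.noins
        B[:, :, 1:] *= probs.stay_absorb
        B[:, :, 1:] += ins_term
    off = F.off.copy()
    _renorm(B, off)
    return _Forward(B, off)


def _bwd_step(G: _Forward, bases, strands, in_range, probs) -> _Forward:
    """Transpose of :func:`_fwd_step`: backward suffix mass."""
    E = _emission(bases, strands, in_range, probs)
    beta = G.lin
    if probs.has_ins:
        g = beta.copy()
        g[:, :, 0] *= probs.noins
        g[:, :, 1:] *= probs.stay_absorb
        g[:, :, :-1] += beta[:, :, 1:] * probs.ins * in_range[None]
    else:
        g = beta
    out = g * probs.miss
    out[:, :, :-1] += g[:, :, 1:] * E
    out[:, :, 1:] += g[:, :, 1:] * E
    off = G.off.copy()
    _renorm(out, off)
    return _Forward(out, off)


def _combine(F: _Forward, G: _Forward) -> np.ndarray:
    """Per-candidate joint log-likelihood: sum_s log sum_j forward*backward."""
    dot = np.einsum("csj,csj->cs", F.lin, G.lin)
    with np.errstate(divide="ignore"):
        ll = np.where(dot > 0.0, np.log(np.where(dot > 0.0, dot, 1.0)), _NEG_INF)
    return (ll + F.off + G.off).sum(axis=1)


def _pack_strands(strands) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    seqs = [s.bases if isinstance(s, CompressedStrand) else str(s) for s in strands]
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    L = int(lengths.max()) if len(seqs) else 0
    arr = np.full((len(seqs), L), -1, dtype=np.int8)
    for i, s in enumerate(seqs):
        arr[i, : len(s)] = [_IDX[b] for b in s]
    in_range = (np.arange(L)[None, :] < lengths[:, None]).astype(float)
    return arr, lengths, in_range


def strand_log_likelihood(
    candidate: TemplateSequence | str,
    strand: CompressedStrand | str,
    model: ChannelModel,
) -> float:
    """log P(strand | candidate template) under the edit channel.

    The total probability over all possible observed (compressed) strands is
    1 for any candidate and model, so likelihoods of different candidates
    are directly comparable.
    """
    if isinstance(candidate, TemplateSequence):
        bases, tail = candidate.bases, candidate.ligation_tail
    else:
        bases, tail = str(candidate), ""
    arr, lengths, in_range = _pack_strands([strand])
    probs = _ChannelProbs(model)
    F = _Forward.initial(1, 1, arr.shape[1])
    for b in bases:
        F = _fwd_step(F, np.array([_IDX[b]], dtype=np.int8), arr, in_range, probs)
    for b in tail:  # guaranteed ligation extension
        F = _fwd_step(F, np.array([_IDX[b]], dtype=np.int8), arr, in_range, _TAIL_PROBS)
    v = F.lin[0, 0, lengths[0]]
    return float(np.log(v) + F.off[0, 0]) if v > 0 else _NEG_INF


# ---------------------------------------------------------------------------
# candidate enumeration


def _is_subsequence(s: str, t: str) -> bool:
    it = iter(t)
    return all(c in it for c in s)


def enumerate_consistent(
    strands,
    length: int,
    scaffold: Scaffold | None = None,
    initiator_terminal: str | None = None,
    max_length: int = 12,
) -> list[str]:
    """All transition-valid sequences of ``length`` containing every strand
    as a subsequence, optionally restricted to scaffold-consistent sequences.

    Exhaustive over the 4 * 3^(length-1) transition-valid strings; refuses
    lengths beyond ``max_length`` (use :func:`map_decode` instead).
    """
    if length > max_length:
        raise ValueError(
            f"exhaustive enumeration refused for length {length} > {max_length}"
        )
    seqs = [s.bases if isinstance(s, CompressedStrand) else str(s) for s in strands]
    sync = set(scaffold.positions) if scaffold is not None else set()
    out = []

    def extend(prefix: str):
        pos = len(prefix)
        if pos == length:
            if all(_is_subsequence(s, prefix) for s in seqs):
                out.append(prefix)
            return
        prev = prefix[-1] if prefix else initiator_terminal
        if pos in sync and prev is not None:
            try:
                choices = [scaffold.identity(pos, prev)]
            except ValueError:
                return  # fixed identity collides with prev: branch infeasible
        else:
            choices = [b for b in NUCLEOTIDES if b != prev]
        for b in choices:
            extend(prefix + b)

    extend("")
    return out


# ---------------------------------------------------------------------------
# segment-factorized MAP: beam + coordinate refinement


def _segments(profile: CodecProfile) -> list[list[tuple[int, bool]]]:
    """Partition template positions into segments ending at sync positions."""
    scaffold = build_scaffold(profile)
    sync = set(scaffold.positions)
    segs: list[list[tuple[int, bool]]] = []
    cur: list[tuple[int, bool]] = []
    for pos in range(profile.K):
        cur.append((pos, pos in sync))
        if pos in sync or (not sync and len(cur) == 3):
            segs.append(cur)
            cur = []
    if cur:
        segs.append(cur)
    return segs


def _segment_candidates(
    seg: list[tuple[int, bool]], prev_base: int, scaffold: Scaffold
) -> np.ndarray:
    """(n_cand, len(seg)) int8 matrix of transition-valid segment fillings."""
    cands: list[list[int]] = [[]]
    prev_list = [prev_base]
    for pos, is_sync in seg:
        new_cands = []
        new_prev = []
        for cand, prev in zip(cands, prev_list):
            if is_sync:
                b = _IDX[scaffold.identity(pos, NUCLEOTIDES[prev])]
                new_cands.append(cand + [b])
                new_prev.append(b)
            else:
                for b in range(4):
                    if b != prev:
                        new_cands.append(cand + [b])
                        new_prev.append(b)
        cands, prev_list = new_cands, new_prev
    return np.array(cands, dtype=np.int8)


def _binom_logpmf_grid(K_rem: int, p_emit: float, lengths: np.ndarray, L: int) -> np.ndarray:
    """h[s, j] = log Binom(K_rem, p_emit) pmf at (L_s - j); -inf when out of
    range. Suffix-consumption heuristic used only for beam pruning."""
    j = np.arange(L + 1)[None, :]
    x = lengths[:, None] - j
    valid = (x >= 0) & (x <= K_rem)
    xs = np.clip(x, 0, K_rem).astype(float)
    if p_emit <= 0.0:
        lp = np.where(xs == 0, 0.0, _NEG_INF)
    elif p_emit >= 1.0:
        lp = np.where(xs == K_rem, 0.0, _NEG_INF)
    else:
        lp = (
            gammaln(K_rem + 1)
            - gammaln(xs + 1)
            - gammaln(K_rem - xs + 1)
            + xs * math.log(p_emit)
            + (K_rem - xs) * math.log1p(-p_emit)
        )
    return np.where(valid, lp, _NEG_INF)


@dataclass
class _Hypothesis:
    bases: tuple[int, ...]
    F: _Forward


def _beam_pass(
    segs, arr, in_range, lengths, probs, scaffold, init, K, p_emit, beam_width,
    tail_idx=(),
) -> list[_Hypothesis]:
    S, L = arr.shape
    hyps = [_Hypothesis(bases=(), F=_Forward.initial(1, S, L))]
    done = 0
    for seg_no, seg in enumerate(segs):
        done += len(seg)
        # remaining consumption includes any ligation-tail symbol still ahead
        tail_rem = len(tail_idx) if seg_no < len(segs) - 1 else 0
        h_grid = _binom_logpmf_grid(K - done + tail_rem, p_emit, lengths, L)
        h_lin = _Forward(
            np.exp(np.where(np.isfinite(h_grid), h_grid, -745.0))[None],
            np.zeros((1, S)),
        )
        all_bases: list[np.ndarray] = []
        all_prefix: list[tuple[int, ...]] = []
        lin_blocks, off_blocks = [], []
        for hyp in hyps:
            prev = hyp.bases[-1] if hyp.bases else init
            cands = _segment_candidates(seg, prev, scaffold)
            all_bases.append(cands)
            all_prefix.extend([hyp.bases] * cands.shape[0])
            lin_blocks.append(np.broadcast_to(hyp.F.lin, (cands.shape[0], S, L + 1)))
            off_blocks.append(np.broadcast_to(hyp.F.off, (cands.shape[0], S)))
        cands = np.concatenate(all_bases, axis=0)
        F = _Forward(
            np.concatenate(lin_blocks, axis=0).copy(),
            np.concatenate(off_blocks, axis=0).copy(),
        )
        for t in range(cands.shape[1]):
            F = _fwd_step(F, cands[:, t], arr, in_range, probs)
        if seg_no == len(segs) - 1:
            for b in tail_idx:  # guaranteed ligation extension
                F = _fwd_step(
                    F, np.repeat(np.int8(b), cands.shape[0]), arr, in_range, _TAIL_PROBS
                )
        scores = _combine(F, h_lin)
        order = sorted(
            range(cands.shape[0]),
            key=lambda c: (-scores[c], all_prefix[c] + tuple(cands[c])),
        )
        hyps = [
            _Hypothesis(
                bases=all_prefix[c] + tuple(cands[c]),
                F=_Forward(F.lin[c : c + 1].copy(), F.off[c : c + 1].copy()),
            )
            for c in order[:beam_width]
        ]
    return hyps


def map_decode(
    strands,
    profile: CodecProfile,
    model: ChannelModel,
    beam_width: int = 32,
    max_sweeps: int = 6,
) -> DecodeResult:
    """Reconstruct a template of length ``profile.K`` from a strand
    population (see the module docstring for the algorithm)."""
    strands = list(strands)
    if not strands:
        raise ValueError("at least one strand is required")
    arr, lengths, in_range = _pack_strands(strands)
    S, L = arr.shape
    probs = _ChannelProbs(model)
    scaffold = build_scaffold(profile)
    segs = _segments(profile)
    init = _IDX[profile.initiator_terminal]
    sidx = np.arange(S)

    tail_idx = [_IDX["C"]] if profile.terminal_c_tail else []
    # per-position observed-symbol yield estimated from the strands
    # themselves: accounts for deletions, insertions, and run merging
    p_emit = float(
        np.clip(lengths.mean() / max(profile.K + len(tail_idx), 1), 0.05, 0.95)
    )
    hyps = _beam_pass(
        segs, arr, in_range, lengths, probs, scaffold, init,
        profile.K, p_emit, beam_width, tail_idx=tail_idx,
    )

    def final_ll(h: _Hypothesis) -> float:
        # hypothesis forward vectors already include the tail step
        v = h.F.lin[0, sidx, lengths]
        with np.errstate(divide="ignore"):
            return float(np.where(v > 0, np.log(np.where(v > 0, v, 1.0)), _NEG_INF).sum()
                         + h.F.off[0].sum())

    best = min(hyps, key=lambda h: (-final_ll(h), h.bases))
    template = list(best.bases)

    bounds = []
    start = 0
    for seg in segs:
        bounds.append((start, start + len(seg)))
        start += len(seg)
    n_seg = len(segs)

    tail = "C" if profile.terminal_c_tail else ""

    def betas_at_bounds() -> list[_Forward]:
        beta = _Forward(np.zeros((1, S, L + 1)), np.zeros((1, S)))
        beta.lin[0, sidx, lengths] = 1.0
        for b in reversed(tail):  # guaranteed ligation extension
            beta = _bwd_step(beta, np.array([_IDX[b]], dtype=np.int8), arr, in_range, _TAIL_PROBS)
        out: list[_Forward | None] = [None] * (n_seg + 1)
        out[n_seg] = beta
        for g in range(n_seg - 1, -1, -1):
            lo, hi = bounds[g]
            for pos in range(hi - 1, lo - 1, -1):
                beta = _bwd_step(
                    beta, np.array([template[pos]], dtype=np.int8), arr, in_range, probs
                )
            out[g] = beta
        return out

    def rescore_span(F_prefix: _Forward, g_lo, g_hi, betas, collect=None) -> bool:
        """Re-optimize segments g_lo..g_hi-1 jointly, rest fixed."""
        lo = bounds[g_lo][0]
        hi = bounds[g_hi - 1][1]
        prev = template[lo - 1] if lo > 0 else init
        span = [p for g in range(g_lo, g_hi) for p in segs[g]]
        cands = _segment_candidates(span, prev, scaffold)
        if hi < profile.K:
            cands = cands[cands[:, -1] != template[hi]]
        F = F_prefix.broadcast(cands.shape[0])
        for t in range(cands.shape[1]):
            F = _fwd_step(F, cands[:, t], arr, in_range, probs)
        ll = _combine(F, betas[g_hi])
        c_best = min(range(cands.shape[0]), key=lambda c: (-ll[c], tuple(cands[c])))
        if collect is not None:
            collect.append((cands, ll))
        if list(cands[c_best]) != template[lo:hi]:
            template[lo:hi] = list(cands[c_best])
            return True
        return False

    def advance(F_prefix: _Forward, g) -> _Forward:
        lo, hi = bounds[g]
        for pos in range(lo, hi):
            F_prefix = _fwd_step(
                F_prefix, np.array([template[pos]], dtype=np.int8), arr, in_range, probs
            )
        return F_prefix

    F0 = _Forward.initial(1, S, L)
    for sweep in range(max_sweeps):
        betas = betas_at_bounds()
        changed = False
        F_prefix = F0
        for g in range(n_seg):
            changed |= rescore_span(F_prefix, g, g + 1, betas)
            F_prefix = advance(F_prefix, g)
        if not changed and n_seg > 1:
            # single-segment fixed point: joint moves on adjacent pairs
            # resolve shift errors spanning a synchronization nucleotide
            betas = betas_at_bounds()
            F_prefix = F0
            for g in range(n_seg - 1):
                changed |= rescore_span(F_prefix, g, g + 2, betas)
                F_prefix = advance(F_prefix, g)
        if not changed:
            break

    # final conditional scoring pass for the posterior (template now fixed)
    betas = betas_at_bounds()
    F_prefix = F0
    seg_weights: list[tuple[np.ndarray, np.ndarray]] = []
    for g in range(n_seg):
        rescore_span(F_prefix, g, g + 1, betas, collect=seg_weights)
        F_prefix = advance(F_prefix, g)

    map_str = "".join(NUCLEOTIDES[b] for b in template)
    map_seq = TemplateSequence(
        bases=map_str, initiator_terminal=profile.initiator_terminal, ligation_tail=tail
    )
    log_score = sum(strand_log_likelihood(map_seq, s, model) for s in strands)
    low_confidence = not np.isfinite(log_score)

    probs_mat = np.zeros((profile.K, 4))
    if low_confidence:
        probs_mat[:] = 0.25
    else:
        for (cands, ll), (lo, hi) in zip(seg_weights, bounds):
            finite = np.isfinite(ll)
            if not finite.any():
                probs_mat[lo:hi] = 0.25
                continue
            w = np.exp(ll - ll[finite].max())
            w = np.where(finite, w, 0.0)
            w /= w.sum()
            for weight, cand in zip(w, cands):
                for off, b in enumerate(cand):
                    probs_mat[lo + off, b] += weight
        probs_mat /= probs_mat.sum(axis=1, keepdims=True)

    return DecodeResult(
        map_sequence=map_seq,
        posterior=ReconstructionPosterior(probs=probs_mat),
        log_score=float(log_score),
        n_strands_used=S,
        low_confidence=bool(low_confidence),
    )


def exhaustive_map_decode(
    strands, profile: CodecProfile, model: ChannelModel, max_K: int = 10
) -> tuple[str, float]:
    """Ground-truth joint MAP by scoring every transition-valid,
    scaffold-consistent template of length K. Exponential in K; refuses
    K > ``max_K``."""
    if profile.K > max_K:
        raise ValueError(f"exhaustive decode refused for K={profile.K} > {max_K}")
    scaffold = build_scaffold(profile)
    sync = set(scaffold.positions)
    init = profile.initiator_terminal

    candidates: list[str] = []

    def extend(prefix: str):
        pos = len(prefix)
        if pos == profile.K:
            candidates.append(prefix)
            return
        prev = prefix[-1] if prefix else init
        if pos in sync:
            choices = [scaffold.identity(pos, prev)]
        else:
            choices = [b for b in NUCLEOTIDES if b != prev]
        for b in choices:
            extend(prefix + b)

    extend("")
    arr, lengths, in_range = _pack_strands(strands)
    S, L = arr.shape
    probs = _ChannelProbs(model)
    cand_arr = np.array([[_IDX[b] for b in c] for c in candidates], dtype=np.int8)
    C = cand_arr.shape[0]
    F = _Forward.initial(C, S, L)
    for t in range(profile.K):
        F = _fwd_step(F, cand_arr[:, t], arr, in_range, probs)
    v = F.lin[:, np.arange(S), lengths]
    with np.errstate(divide="ignore"):
        ll = (np.where(v > 0, np.log(np.where(v > 0, v, 1.0)), _NEG_INF) + F.off).sum(axis=1)
    best = min(range(C), key=lambda i: (-ll[i], candidates[i]))
    return candidates[best], float(ll[best])


# ---------------------------------------------------------------------------
# consensus


def consensus(
    posterior: ReconstructionPosterior,
    scaffold: Scaffold | None = None,
    initiator_terminal: str = "G",
    repair: bool = True,
) -> TemplateSequence:
    """Most probable nucleotide per position, with transition-validity repair.

    Synchronization positions are forced to their scaffold identities. When
    the per-position argmax creates a self-transition and ``repair`` is on,
    the offending adjacent pair is replaced by the transition-valid joint
    two-position argmax (respecting both flanking neighbours).
    """
    p = posterior.probs
    K = len(posterior)
    sync = set(scaffold.positions) if scaffold is not None else set()
    bases: list[str] = []
    prev = initiator_terminal
    for pos in range(K):
        if pos in sync:
            b = scaffold.identity(pos, prev)
        else:
            b = NUCLEOTIDES[int(np.argmax(p[pos]))]
        bases.append(b)
        prev = b

    if repair:
        i = 0
        while i < K:
            left = bases[i - 1] if i > 0 else initiator_terminal
            if bases[i] != left:
                i += 1
                continue
            right = bases[i + 1] if i + 1 < K else None
            if i == 0 or (i - 1) in sync:
                # left base immovable: repick position i only
                x = bases[i - 1] if i > 0 else initiator_terminal
                if i in sync:
                    y = scaffold.identity(i, x)
                else:
                    ys = [b for b in NUCLEOTIDES if b != x and b != right]
                    y = max(ys, key=lambda b: (p[i][_IDX[b]], -_IDX[b]))
                bases[i] = y
            else:
                outer = bases[i - 2] if i - 1 > 0 else initiator_terminal
                best = None
                for x in NUCLEOTIDES:
                    if x == outer:
                        continue
                    y_choices = (
                        [scaffold.identity(i, x)] if i in sync else NUCLEOTIDES
                    )
                    for y in y_choices:
                        if y == x or (right is not None and y == right):
                            continue
                        score = p[i - 1][_IDX[x]] + p[i][_IDX[y]]
                        key = (score, -_IDX[x], -_IDX[y])
                        if best is None or key > best[0]:
                            best = (key, x, y)
                _, bases[i - 1], bases[i] = best
            i += 1
    return TemplateSequence(bases="".join(bases), initiator_terminal=initiator_terminal)
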