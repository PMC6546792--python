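"""Synthesis-error quantification.

Global Needleman–Wunsch alignment of compressed strands against their
template (match +2, mismatch -3, gap open/extend -5, i.e. a linear gap
penalty), tabulation of mismatches / insertions / missing nucleotides from
the alignment, Levenshtein distances, and per-length diversity profiles of a
strand pool.

Alignment convention: the strand is the query, the template the reference.
A gap in the *strand* row means a template nucleotide was never synthesized
(missing); a gap in the *template* row means the strand carries an extra
nucleotide (insertion). Among co-optimal alignments the traceback prefers
gaps in the strand over mismatches over gaps in the template, placing gaps
leftmost; when several optimal alignments exist the tabulation is flagged
ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .channel import CompressedStrand
from .codec import TemplateSequence
from .readproc import StrandPool

__all__ = [
    "AlignmentScoring",
    "Alignment",
    "ErrorTabulation",
    "needleman_wunsch",
    "tabulate_errors",
    "levenshtein",
    "diversity_profile",
    "pooled_error_summary",
]


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -5.0

    def __post_init__(self):
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.gap_open != self.gap_extend:
            raise NotImplementedError(
                "only the linear gap model (gap_open == gap_extend) is supported"
            )


@dataclass(frozen=True)
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float
    n_optimal: int  # co-optimal alignment count, saturated at 2**30


@dataclass(frozen=True)
class ErrorTabulation:
    n_mismatch: int
    n_insertion: int
    n_missing: int
    alignment: Alignment
    ambiguous: bool

    @property
    def total_errors(self) -> int:
        return self.n_mismatch + self.n_insertion + self.n_missing


_GAP = "-"
_COUNT_CAP = 1 << 30


def needleman_wunsch(
    a: str, b: str, scoring: AlignmentScoring | None = None
) -> Alignment:
    """Optimal global alignment of ``a`` (strand) against ``b`` (template).

    End gaps are penalized (true global alignment). Deterministic traceback:
    prefer the gap-in-``a`` move, then the diagonal, then the gap-in-``b``
    move, which places missing-nucleotide gaps before mismatches and keeps
    co-optimal gaps leftmost in the strand.
    """
    if scoring is None:
        scoring = AlignmentScoring()
    la, lb = len(a), len(b)
    gap = scoring.gap_extend
    S = np.empty((la + 1, lb + 1))
    C = np.zeros((la + 1, lb + 1), dtype=np.int64)  # co-optimal path counts
    S[0, :] = gap * np.arange(lb + 1)
    S[:, 0] = gap * np.arange(la + 1)
    C[0, :] = 1
    C[:, 0] = 1
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            diag = S[i - 1, j - 1] + (scoring.match if ai == b[j - 1] else scoring.mismatch)
            up = S[i - 1, j] + gap  # gap in template: insertion in strand
            left = S[i, j - 1] + gap  # gap in strand: missing template base
            best = max(diag, up, left)
            S[i, j] = best
            c = 0
            if diag == best:
                c += C[i - 1, j - 1]
            if up == best:
                c += C[i - 1, j]
            if left == best:
                c += C[i, j - 1]
            C[i, j] = min(c, _COUNT_CAP)
    # traceback
    out_a, out_b = [], []
    i, j = la, lb
    while i > 0 or j > 0:
        best = S[i, j]
        if j > 0 and S[i, j - 1] + gap == best:
            out_a.append(_GAP)
            out_b.append(b[j - 1])
            j -= 1
        elif (
            i > 0
            and j > 0
            and S[i - 1, j - 1] + (scoring.match if a[i - 1] == b[j - 1] else scoring.mismatch)
            == best
        ):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        else:
            out_a.append(a[i - 1])
            out_b.append(_GAP)
            i -= 1
    return Alignment(
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=float(S[la, lb]),
        n_optimal=int(C[la, lb]),
    )


def tabulate_errors(
    strand: CompressedStrand | str,
    template: TemplateSequence | str,
    scoring: AlignmentScoring | None = None,
) -> ErrorTabulation:
    """Count mismatches, insertions and missing nucleotides from one optimal
    alignment of the strand to its template; flag alignment ambiguity."""
    s = strand.bases if isinstance(strand, CompressedStrand) else str(strand)
    t = template.bases if isinstance(template, TemplateSequence) else str(template)
    aln = needleman_wunsch(s, t, scoring)
    n_mis = n_ins = n_del = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca == _GAP:
            n_del += 1
        elif cb == _GAP:
            n_ins += 1
        elif ca != cb:
            n_mis += 1
    return ErrorTabulation(
        n_mismatch=n_mis,
        n_insertion=n_ins,
        n_missing=n_del,
        alignment=aln,
        ambiguous=aln.n_optimal > 1,
    )


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance."""
    if not a or not b:
        return max(len(a), len(b))
    return int(edlib.align(a, b, mode="NW", task="distance")["editDistance"])


def diversity_profile(
    pool: StrandPool, template: TemplateSequence | str
) -> pd.DataFrame:
    """Per-strand-length diversity table.

    One row per observed compressed-strand length with the number of reads,
    unique variants, perfect strands, and summary statistics of the
    Levenshtein distance to the template.
    """
    t = template.bases if isinstance(template, TemplateSequence) else str(template)
    rows: dict[int, dict] = {}
    for variant, count in pool.entries.items():
        d = levenshtein(variant, t)
        r = rows.setdefault(
            len(variant),
            {"n_reads": 0, "n_variants": 0, "n_perfect": 0, "distances": []},
        )
        r["n_reads"] += count
        r["n_variants"] += 1
        if variant == t:
            r["n_perfect"] += count
        r["distances"].extend([d] * count)
    records = []
    for length in sorted(rows):
        r = rows[length]
        dist = np.array(r["distances"])
        records.append(
            {
                "length": length,
                "n_reads": r["n_reads"],
                "n_variants": r["n_variants"],
                "n_perfect": r["n_perfect"],
                "edit_distance_median": float(np.median(dist)),
                "edit_distance_min": int(dist.min()),
                "edit_distance_max": int(dist.max()),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "length",
            "n_reads",
            "n_variants",
            "n_perfect",
            "edit_distance_median",
            "edit_distance_min",
            "edit_distance_max",
        ],
    )


def pooled_error_summary(
    pool: StrandPool,
    template: TemplateSequence | str,
    scoring: AlignmentScoring | None = None,
) -> pd.DataFrame:
    """Per-variant error tabulation plus per-strand indicator fractions.

    Emits both the per-read mean error counts and the fraction of strands
    carrying at least one error of each type (the two summaries one can form
    when alignments are ambiguous).
    """
    records = []
    for variant, count in sorted(pool.entries.items()):
        tab = tabulate_errors(variant, template, scoring)
        records.append(
            {
                "variant": variant,
                "count": count,
                "length": len(variant),
                "n_mismatch": tab.n_mismatch,
                "n_insertion": tab.n_insertion,
                "n_missing": tab.n_missing,
                "ambiguous": tab.ambiguous,
                "score": tab.alignment.score,
            }
        )
    df = pd.DataFrame.from_records(records)
    if len(df):
        total = df["count"].sum()
        df.attrs["frac_with_mismatch"] = float(
            df.loc[df.n_mismatch > 0, "count"].sum() / total
        )
        df.attrs["frac_with_insertion"] = float(
            df.loc[df.n_insertion > 0, "count"].sum() / total
        )
        df.attrs["frac_with_missing"] = float(
            df.loc[df.n_missing > 0, "count"].sum() / total
        )
    return df
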