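"""Circularity / terminal-redundancy detection and trimming.

A contig that recovers a complete circular genome (or runs into a terminal
repeat) carries the same sequence at both ends. Detection splits the contig
into a terminal probe window G_a = [L_s - 2*L_r, L_s - L_r) and the body
G_b = [0, L_s - 2*L_r), where L_s is the contig length and L_r the read
length, and looks for a high-identity match of G_a inside G_b.

The aligner is an internal seed-and-extend: exact k-mer seeds of G_a in G_b
propose candidate periods (shifts); each shift is scored by the ungapped
self-overlap of the contig at that shift. A shift qualifies when identity
(matches / alignment columns) is >= ``identity_threshold`` over an alignment
that covers >= ``aln_len_threshold`` of G_a. The maximal repeat pair is the
longest qualifying window along the winning shift; the downstream copy is
the one removed by trimming, keeping genome-start coordinates stable.

Only the forward strand is tested: a circularly permuted assembly cannot
present reverse-complemented terminal redundancy without misassembly.
Inverted terminal repeats are reported in the result note but never trimmed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import Contig, EditEvent, Region, revcomp
from .kmers import encode, kmer_codes

logger = logging.getLogger(__name__)

# beyond this many mismatching columns the window refinement is skipped and
# the shift judged on full-overlap identity alone (keeps worst case O(K^2) small)
_MAX_REFINE_MISMATCHES = 512


@dataclass(frozen=True)
class CircularityParams:
    identity_threshold: float = 0.95
    aln_len_threshold: float = 0.95  # fraction of G_a that must be covered
    seed_k: int = 21


@dataclass
class CircularityResult:
    is_circular: bool
    match_in_gb: Optional[Region] = None
    maximal_repeat: Optional[tuple[Region, Region]] = None
    identity: float = 0.0
    period: Optional[int] = None  # shift between the two copies
    note: str = ""

    def to_json(self) -> dict:
        return {
            "is_circular": self.is_circular,
            "identity": round(self.identity, 4),
            "identity_definition": "matches/alignment_columns",
            "repeat_length": len(self.maximal_repeat[0]) if self.maximal_repeat else 0,
            "copies": [
                [r.start, r.end] for r in self.maximal_repeat
            ] if self.maximal_repeat else None,
            "note": self.note,
        }


def _candidate_shifts(seq: str, read_length: int, k: int) -> list[int]:
    L = len(seq)
    ga_start, ga_end = L - 2 * read_length, L - read_length
    enc = encode(seq)
    gb_codes = kmer_codes(enc[:ga_start], k)
    ga_codes = kmer_codes(enc[ga_start:ga_end], k)
    valid_b = np.flatnonzero(gb_codes >= 0)
    if len(valid_b) == 0 or len(ga_codes) == 0:
        return []
    order = np.argsort(gb_codes[valid_b], kind="stable")
    sorted_codes = gb_codes[valid_b][order]
    sorted_pos = valid_b[order]
    valid_a = np.flatnonzero(ga_codes >= 0)
    q = ga_codes[valid_a]
    lo = np.searchsorted(sorted_codes, q, "left")
    hi = np.searchsorted(sorted_codes, q, "right")
    cnt = hi - lo
    total = int(cnt.sum())
    if total == 0:
        return []
    qrep = np.repeat(np.arange(len(q)), cnt)
    within = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
    pb = sorted_pos[lo[qrep] + within]
    pa = ga_start + valid_a[qrep]
    shifts = np.unique(pa - pb)
    return shifts[shifts > 0].tolist()


def _longest_window(
    mism_pos: np.ndarray,
    n_cols: int,
    max_rate: float,
    ga_cols: tuple[int, int],
    min_ga_cover: float,
) -> Optional[tuple[int, int, int]]:
    """Longest window [a, b) with mismatch rate <= max_rate covering enough of G_a.

    Returns (a, b, n_mismatch_in_window) or None. Optimal windows have their
    endpoints adjacent to mismatch positions or the overlap bounds, so only
    those O(K^2) combinations are enumerated.
    """
    starts = np.concatenate(([0], mism_pos + 1))
    ends = np.concatenate((mism_pos, [n_cols]))
    csum = np.concatenate(([0], np.cumsum(np.bincount(mism_pos, minlength=n_cols))))
    ga_lo, ga_hi = ga_cols
    need = min_ga_cover * (ga_hi - ga_lo)
    best = None
    for a in starts.tolist():
        for b in ends.tolist()[::-1]:
            if b <= a:
                break
            mm = int(csum[b] - csum[a])
            if mm > max_rate * (b - a):
                continue
            covered = min(b, ga_hi) - max(a, ga_lo)
            if covered < need:
                continue
            if best is None or b - a > best[1] - best[0]:
                best = (a, b, mm)
            break  # longer b for this a already tried; move on
    return best


def check_circularity(
    contig: Contig,
    read_length: int,
    params: CircularityParams | None = None,
) -> CircularityResult:
    """Test the G_a-in-G_b self-match and locate the maximal terminal repeat."""
    params = params or CircularityParams()
    seq, L, L_r = contig.seq, len(contig), read_length
    if L <= 3 * L_r:
        logger.warning("%s: length %d <= 3 * read length, circularity untestable", contig.id, L)
        return CircularityResult(False, note="contig shorter than 3 * read_length")

    ga_lo_seq, ga_hi_seq = L - 2 * L_r, L - L_r
    enc = encode(seq)
    best = None  # (window_len, -shift, a, b, mm, shift)
    for s in _candidate_shifts(seq, L_r, params.seed_k):
        n_cols = L - s
        # the overlap covers suffix positions [s, L); G_a must be coverable
        ga_lo = max(ga_lo_seq - s, 0)
        ga_hi = ga_hi_seq - s
        if ga_hi - ga_lo < params.aln_len_threshold * L_r:
            continue
        x, y = enc[s:], enc[: L - s]
        mism_pos = np.flatnonzero(x != y)
        max_mm = (1.0 - params.identity_threshold) * n_cols
        if len(mism_pos) <= max_mm:
            win = (0, n_cols, len(mism_pos))
        elif len(mism_pos) <= _MAX_REFINE_MISMATCHES:
            win = _longest_window(
                mism_pos, n_cols, 1.0 - params.identity_threshold,
                (ga_lo, ga_hi), params.aln_len_threshold,
            )
        else:
            win = None
        if win is None:
            continue
        a, b, mm = win
        cand = (b - a, -s, a, b, mm, s)
        if best is None or cand > best:
            best = cand

    note = ""
    if _has_inverted_repeat(seq, L_r, params.seed_k):
        note = "inverted terminal repeat detected (reported only, not trimmed)"

    if best is None:
        return CircularityResult(False, note=note)
    _, _, a, b, mm, s = best
    identity = 1.0 - mm / (b - a)
    upstream = Region(contig.id, a, b, "repeat")
    downstream = Region(contig.id, s + a, s + b, "repeat")
    ga_on_gb = Region(
        contig.id, max(ga_lo_seq - s, a), min(ga_hi_seq - s, b), "ga_match"
    )
    return CircularityResult(
        True,
        match_in_gb=ga_on_gb,
        maximal_repeat=(upstream, downstream),
        identity=identity,
        period=s,
        note=note,
    )


def _has_inverted_repeat(seq: str, read_length: int, k: int, min_hits: int = 5) -> bool:
    L = len(seq)
    ga = encode(seq[L - 2 * read_length : L - read_length])
    gb_rc = encode(revcomp(seq[: L - 2 * read_length]))
    a = kmer_codes(ga, k)
    b = kmer_codes(gb_rc, k)
    a, b = a[a >= 0], b[b >= 0]
    if len(a) == 0 or len(b) == 0:
        return False
    return int(np.isin(a, b).sum()) >= min_hits


def trim_circular_redundancy(
    contig: Contig, result: CircularityResult, iteration: int = 0
) -> Contig:
    """Remove the downstream (rightmost) copy of the maximal repeat."""
    if not result.is_circular or result.maximal_repeat is None:
        raise ValueError("trim_circular_redundancy requires a circular result")
    _, down = result.maximal_repeat
    seq = contig.seq[: down.start] + contig.seq[down.end :]
    event = EditEvent(
        kind="circular_trim",
        interval=down,
        delta_bp=-len(down),
        iteration=iteration,
        detail={"identity": result.identity, "period": result.period},
    )
    return contig.with_edit(seq, event)
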