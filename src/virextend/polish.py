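"""Pileup-majority consensus polishing of a contig.

Reads are placed on the contig with the same k-mer seeding machinery used
for coverage and extension. Reads that seed a diagonal but fail ungapped
verification are rescued by a banded gapped alignment (edlib, infix mode)
so that small insertions and deletions show up in the pileup. At every
column with depth >= ``min_depth`` whose plurality symbol (A/C/G/T or gap)
differs from the contig base and reaches frequency >= ``min_majority``, the
contig is corrected; short insertions supported by >= ``min_majority`` of
spanning reads are inserted. Unlike Pilon, counts are unweighted (no
mapping-quality or proper-pair weighting) and discordant-pair regions are
not reassembled — a deliberate simplification.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import edlib
import numpy as np

from .core import Contig, EditEvent, ReadSet, apply_event, revcomp
from .mapping import ReadMapper

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
_BASES = "ACGT"
# margin (bp) a placement must extend past an insertion point to count as spanning
_SPAN_MARGIN = 4


@dataclass(frozen=True)
class PolishParams:
    min_depth: int = 5
    min_majority: float = 0.7
    max_indel_len: int = 10
    map_max_mismatch_rate: float = 0.05
    min_overlap: int = 30

    def __post_init__(self) -> None:
        if not (0.5 < self.min_majority <= 1.0):
            raise ValueError("min_majority must be in (0.5, 1.0]")
        if self.min_depth < 1 or self.max_indel_len < 1:
            raise ValueError("min_depth and max_indel_len must be >= 1")


def _gapped_events(
    read_seq: str, contig_seq: str, diag: int, params: PolishParams
):
    """Align a seeded-but-unverified read with gaps; yield pileup events.

    Returns (cols, ins_events, span) or None.
    cols: list of (contig_pos, symbol_code 0..3) match/mismatch columns
    ins_events: list of (contig_pos, inserted_seq)
    dels are reported as symbol code 4 in cols.
    """
    L = len(contig_seq)
    rl = len(read_seq)
    pad = params.max_indel_len + 5
    w_lo = max(diag - pad, 0)
    w_hi = min(diag + rl + pad, L)
    if w_hi - w_lo < params.min_overlap:
        return None
    window = contig_seq[w_lo:w_hi]
    res = edlib.align(read_seq, window, mode="HW", task="path")
    max_ed = params.max_indel_len + int(round(params.map_max_mismatch_rate * rl)) + 1
    if res["editDistance"] < 0 or res["editDistance"] > max_ed or not res["cigar"]:
        return None
    t_pos = w_lo + res["locations"][0][0]
    q_pos = 0
    cols: list[tuple[int, int]] = []
    ins_events: list[tuple[int, str]] = []
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        if op in "=XM":
            for j in range(n):
                code = _BASES.find(read_seq[q_pos + j])
                if code >= 0:  # skip N
                    cols.append((t_pos + j, code))
            t_pos += n
            q_pos += n
        elif op == "I":  # bases in the read absent from the contig
            ins_events.append((t_pos, read_seq[q_pos : q_pos + n]))
            q_pos += n
        elif op == "D":  # contig bases unsupported by the read
            for j in range(n):
                cols.append((t_pos + j, 4))
            t_pos += n
    start = w_lo + res["locations"][0][0]
    return cols, ins_events, (start, t_pos)


def polish(
    contig: Contig,
    reads: ReadSet,
    params: PolishParams | None = None,
    mapper: Optional[ReadMapper] = None,
    iteration: int = 0,
) -> Contig:
    """Correct substitutions and short indels by pileup plurality."""
    params = params or PolishParams()
    if len(reads) == 0:
        return contig
    mapper = mapper or ReadMapper(reads)
    placements, failed = mapper.map_to(
        contig.seq,
        max_mismatch_rate=params.map_max_mismatch_rate,
        min_overlap=params.min_overlap,
    )
    L = len(contig)
    counts = np.zeros((5, L), dtype=np.int64)  # A C G T del
    span_delta = np.zeros(L + 1, dtype=np.int64)
    ins_votes: dict[tuple[int, str], int] = {}

    # ungapped placements: vote base columns over the aligned interval
    for i in range(len(placements)):
        ridx = int(placements.read_idx[i])
        strand = int(placements.strand[i])
        d = int(placements.diag[i])
        cs, ce = int(placements.start[i]), int(placements.end[i])
        renc = mapper.enc[strand][ridx][cs - d : ce - d]
        pos = np.arange(cs, ce)
        ok = renc < 4  # skip N
        np.add.at(counts, (renc[ok].astype(np.int64), pos[ok]), 1)
        a, b = cs + _SPAN_MARGIN, ce - _SPAN_MARGIN
        if b > a:
            span_delta[a] += 1
            span_delta[b] -= 1

    # gapped rescue of seeded-but-unverified reads
    for ridx, strand, d in zip(
        failed.read_idx.tolist(), failed.strand.tolist(), failed.diag.tolist()
    ):
        seq = reads.seqs[ridx] if strand == 0 else revcomp(reads.seqs[ridx])
        got = _gapped_events(seq, contig.seq, d, params)
        if got is None:
            continue
        cols, ins_events, (s, e) = got
        for pos, code in cols:
            if 0 <= pos < L and code < 5:
                counts[code, pos] += 1
        for pos, ins in ins_events:
            if 0 < pos < L:
                ins_votes[(pos, ins)] = ins_votes.get((pos, ins), 0) + 1
        a, b = s + _SPAN_MARGIN, e - _SPAN_MARGIN
        if b > a:
            span_delta[a] += 1
            span_delta[b] -= 1

    if counts.sum() == 0:
        return contig

    span_depth = np.cumsum(span_delta[:-1])
    contig_enc = np.frombuffer(contig.seq.encode(), dtype=np.uint8)
    contig_codes = np.full(L, 4, dtype=np.int64)
    for c, b in enumerate(_BASES):
        contig_codes[contig_enc == ord(b)] = c

    col_depth = counts.sum(axis=0)
    winner = counts.argmax(axis=0)
    win_count = counts.max(axis=0)
    eligible = (
        (col_depth >= params.min_depth)
        & (winner != contig_codes)
        & (win_count >= params.min_majority * col_depth)
        # strict plurality: the winner must beat the contig's own symbol
        & (win_count > counts[contig_codes, np.arange(L)])
    )

    ops: list[dict] = []
    sub_pos = np.flatnonzero(eligible & (winner != 4))
    for p in sub_pos.tolist():
        ops.append(
            {
                "op": "sub",
                "pos": p,
                "ref": contig.seq[p],
                "new": _BASES[winner[p]],
                "depth": int(col_depth[p]),
                "majority": round(float(win_count[p] / col_depth[p]), 3),
            }
        )
    # deletion columns: group consecutive runs, skip runs longer than max_indel_len
    del_pos = np.flatnonzero(eligible & (winner == 4))
    if len(del_pos):
        breaks = np.flatnonzero(np.diff(del_pos) > 1)
        runs = np.split(del_pos, breaks + 1)
        for run in runs:
            if len(run) > params.max_indel_len:
                continue
            p = int(run[0])
            ops.append(
                {
                    "op": "del",
                    "pos": p,
                    "ref": contig.seq[p : p + len(run)],
                    "len": int(len(run)),
                    "depth": int(col_depth[p]),
                    "majority": round(float(win_count[p] / col_depth[p]), 3),
                }
            )
    for (pos, ins), c in sorted(ins_votes.items()):
        sd = int(span_depth[pos])
        if (
            len(ins) <= params.max_indel_len
            and sd >= params.min_depth
            and c >= params.min_majority * sd
        ):
            ops.append(
                {
                    "op": "ins",
                    "pos": pos,
                    "new": ins,
                    "depth": sd,
                    "majority": round(c / sd, 3),
                }
            )

    if not ops:
        return contig
    # apply right-to-left so earlier positions stay valid; at equal positions
    # apply insertions after substitutions/deletions (i.e., earlier in the
    # right-to-left order they must come first)
    order = {"ins": 0, "del": 1, "sub": 2}
    ops.sort(key=lambda o: (-o["pos"], order[o["op"]]))
    event = EditEvent(
        kind="base_correction",
        interval=None,
        delta_bp=sum(
            len(o["new"]) if o["op"] == "ins" else (-o["len"] if o["op"] == "del" else 0)
            for o in ops
        ),
        iteration=iteration,
        detail={"ops": ops},
    )
    new_seq = apply_event(contig.seq, event)
    return contig.with_edit(new_seq, event)
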