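"""Edge-local contig extension: extract edges, recruit reads, greedy overlap
assembly, merge growth back, and the trim-and-retry fallback.

Local assembly is a greedy suffix-prefix overlap walk seeded on the edge
sequence: at each step the recruited read (either strand) with the longest
verified overlap against the growing tip is appended, extending strictly
outward. Branching ties (equal-length overlaps that disagree on the next
base) stop that side's extension for the round, and a tip k-mer revisit
guard stops runaway extension through tandem repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import Contig, EditEvent, ReadSet, Region, revcomp
from .kmers import encode
from .mapping import ReadMapper

_MAX_ASSEMBLY_STEPS = 500


@dataclass(frozen=True)
class ExtensionParams:
    edge_factor: float = 1.5
    trim_schedule: tuple[int, ...] = (300, 500, 1000, 1500, 2000)
    recruit_k: int = 21
    min_shared_kmers: int = 3
    min_overlap: int = 30
    max_mismatch_rate: float = 0.02
    anchor_min_identity: float = 0.98

    def __post_init__(self) -> None:
        if self.edge_factor <= 0:
            raise ValueError("edge_factor must be positive")
        if list(self.trim_schedule) != sorted(set(self.trim_schedule)):
            raise ValueError("trim_schedule must be strictly increasing")
        if self.trim_schedule and max(self.trim_schedule) > 2000:
            raise ValueError("trim_schedule values must be <= 2000")


@dataclass
class ExtensionOutcome:
    grew: bool
    left_added_bp: int = 0
    right_added_bp: int = 0
    trimmed_bp_applied: int = 0


def edge_length(read_length: int, params: ExtensionParams) -> int:
    return round(read_length * params.edge_factor)


def extract_edges(
    contig: Contig, read_length: int, params: ExtensionParams | None = None
) -> tuple[Region, Region]:
    """Left and right edge regions of length round(read_length * edge_factor).

    Short contigs are split into two non-overlapping halves.
    """
    params = params or ExtensionParams()
    L = len(contig)
    e = edge_length(read_length, params)
    if L < 2 * e:
        half = L // 2
        return (
            Region(contig.id, 0, half, "left_edge"),
            Region(contig.id, half, L, "right_edge"),
        )
    return (
        Region(contig.id, 0, e, "left_edge"),
        Region(contig.id, L - e, L, "right_edge"),
    )


def recruit_reads(
    reads: ReadSet,
    edges: tuple[Region, Region],
    contig: Contig,
    params: ExtensionParams | None = None,
    mapper: Optional[ReadMapper] = None,
) -> ReadSet:
    """Reads (plus mates) sharing >= min_shared_kmers k-mers with either edge."""
    params = params or ExtensionParams()
    if len(reads) == 0:
        return reads
    mapper = mapper or ReadMapper(reads, k=params.recruit_k)
    left, right = edges
    idx = mapper.recruit(
        [contig.seq[left.start : left.end], contig.seq[right.start : right.end]],
        min_shared=params.min_shared_kmers,
    )
    return reads.subset(idx)


def local_assemble(
    edge_seq: str, recruited: ReadSet, params: ExtensionParams | None = None
) -> list[str]:
    """Greedily extend ``edge_seq`` rightward (outward) using recruited reads.

    Returns a single-element list with the extended sequence (the original
    edge is always its prefix, verbatim). Callers extend a left edge by
    passing the reverse complement and reverse-complementing the result.
    """
    params = params or ExtensionParams()
    if not edge_seq:
        raise ValueError("empty edge sequence")
    if len(recruited) == 0:
        return [edge_seq]

    sub_mapper = ReadMapper(recruited, k=params.recruit_k)
    max_rl = max(len(s) for s in recruited.seqs)
    grow = edge_seq
    k = params.recruit_k
    seen_tips: set[str] = set()
    for _ in range(_MAX_ASSEMBLY_STEPS):
        W = min(len(grow), max_rl + k)
        tip = grow[-W:]
        placements, _ = sub_mapper.map_to(
            tip,
            max_mismatch_rate=params.max_mismatch_rate,
            min_overlap=params.min_overlap,
        )
        # candidates: reads whose placement runs off the right end of the tip
        best_ov = 0
        best: list[tuple[str, str]] = []  # (read_id, overhang)
        for i in range(len(placements)):
            d = int(placements.diag[i])
            ridx = int(placements.read_idx[i])
            strand = int(placements.strand[i])
            rl = len(recruited.seqs[ridx])
            overhang_len = d + rl - W
            if overhang_len <= 0 or d < 0:
                continue
            ov = W - d  # suffix-prefix overlap length
            if ov < params.min_overlap:
                continue
            seq = recruited.seqs[ridx] if strand == 0 else revcomp(recruited.seqs[ridx])
            cand = (recruited.ids[ridx], seq[ov:])
            if ov > best_ov:
                best_ov, best = ov, [cand]
            elif ov == best_ov:
                best.append(cand)
        if not best:
            break
        if len(best) > 1:
            first_bases = {o[0] for _, o in best}
            if len(first_bases) > 1:
                break  # branching overlap: stop this side for the round
            best.sort(key=lambda c: c[0])
        overhang = best[0][1]
        grow += overhang
        tip_sig = grow[-k:]
        if tip_sig in seen_tips:
            break  # cycle guard: re-acquired a previous tip k-mer
        seen_tips.add(tip_sig)
    return [grow]


def _anchor_overhang(
    ext: str, anchor: str, side: str, min_identity: float
) -> Optional[str]:
    """Overhang of ``ext`` past its anchored edge, or None if the anchor fails.

    For side "left" the anchor must be a suffix of ext; for "right" a prefix.
    """
    m = len(anchor)
    if len(ext) < m:
        return None
    part = ext[-m:] if side == "left" else ext[:m]
    mm = int(np.count_nonzero(encode(part) != encode(anchor)))
    if mm > (1.0 - min_identity) * m:
        return None
    return ext[:-m] if side == "left" else ext[m:]


def merge_extension(
    contig: Contig,
    left_ext: str,
    right_ext: str,
    read_length: int,
    params: ExtensionParams | None = None,
    iteration: int = 0,
) -> tuple[Contig, ExtensionOutcome]:
    """Splice edge-assembly products back onto the contig.

    ``left_ext``/``right_ext`` are the assembled edge sequences in contig
    orientation; each must still contain its original edge (verified at
    >= ``anchor_min_identity``), otherwise that side is discarded.
    """
    params = params or ExtensionParams()
    left_r, right_r = extract_edges(contig, read_length, params)
    left_over = _anchor_overhang(
        left_ext, contig.seq[left_r.start : left_r.end], "left", params.anchor_min_identity
    )
    right_over = _anchor_overhang(
        right_ext, contig.seq[right_r.start : right_r.end], "right", params.anchor_min_identity
    )
    left_over = left_over or ""
    right_over = right_over or ""
    if not left_over and not right_over:
        return contig, ExtensionOutcome(grew=False)
    seq = left_over + contig.seq + right_over
    event = EditEvent(
        kind="extension",
        interval=None,
        delta_bp=len(left_over) + len(right_over),
        iteration=iteration,
        detail={"left": left_over, "right": right_over},
    )
    out = ExtensionOutcome(
        grew=True, left_added_bp=len(left_over), right_added_bp=len(right_over)
    )
    return contig.with_edit(seq, event), out


def extend_once(
    contig: Contig,
    reads: ReadSet,
    read_length: int,
    params: ExtensionParams | None = None,
    mapper: Optional[ReadMapper] = None,
    iteration: int = 0,
) -> tuple[Contig, ExtensionOutcome]:
    """One extract-recruit-assemble-merge round on both edges."""
    params = params or ExtensionParams()
    edges = extract_edges(contig, read_length, params)
    recruited = recruit_reads(reads, edges, contig, params, mapper=mapper)
    left_r, right_r = edges
    left_seq = contig.seq[left_r.start : left_r.end]
    right_seq = contig.seq[right_r.start : right_r.end]
    if len(recruited) == 0:
        return contig, ExtensionOutcome(grew=False)
    left_ext = revcomp(local_assemble(revcomp(left_seq), recruited, params)[0])
    right_ext = local_assemble(right_seq, recruited, params)[0]
    return merge_extension(contig, left_ext, right_ext, read_length, params, iteration)


def trim_and_retry(
    contig: Contig,
    reads: ReadSet,
    read_length: int,
    params: ExtensionParams | None = None,
    mapper: Optional[ReadMapper] = None,
    iteration: int = 0,
) -> tuple[Contig, ExtensionOutcome]:
    """Symmetric end-trim fallback when plain extension stalls.

    For each trim value t in the schedule, t bp are removed from both ends
    and one extension round attempted; the first t whose merged contig is
    strictly longer than the pre-trim contig is accepted (the extension must
    more than repay 2t). If none succeeds the original contig is returned.
    """
    params = params or ExtensionParams()
    L0 = len(contig)
    e = edge_length(read_length, params)
    for t in params.trim_schedule:
        if L0 <= 2 * t + 2 * e:
            break
        trimmed = contig.with_edit(
            contig.seq[t : L0 - t],
            EditEvent(
                kind="end_trim",
                interval=None,
                delta_bp=-2 * t,
                iteration=iteration,
                detail={"trim_bp": t},
            ),
        )
        extended, out = extend_once(
            trimmed, reads, read_length, params, mapper=mapper, iteration=iteration
        )
        if out.grew and len(extended) > L0:
            out.trimmed_bp_applied = t
            return extended, out
    return contig, ExtensionOutcome(grew=False)
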