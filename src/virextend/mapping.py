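"""Vectorized k-mer read placement and recruitment.

A :class:`ReadMapper` indexes the k-mers of every read (both strands) once,
then supports two queries against arbitrary contig sequence:

* ``map_to`` — semiglobal ungapped placement of every read on a contig
  (seed k-mers vote for a diagonal; the best diagonal is verified by direct
  comparison). Reads may be soft-clipped at the contig boundaries only.
* ``recruit`` — ids of reads sharing at least ``min_shared`` k-mers with a
  query sequence (an edge region), on either strand, with paired mates
  pulled in regardless of their own match.

Contig k-mers occurring more than ``max_kmer_hits`` times are masked out of
the seeding step (repeat masking), so reads from high-copy tandem repeats do
not pile onto arbitrary copies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ReadSet, revcomp
from .kmers import encode, kmer_codes

_DIAG_OFF = 1 << 30


@dataclass
class Placements:
    """Ungapped read placements on one contig (parallel arrays)."""

    read_idx: np.ndarray
    strand: np.ndarray  # 0 forward, 1 reverse
    start: np.ndarray  # clipped alignment start on the contig
    end: np.ndarray  # clipped alignment end
    n_mismatch: np.ndarray
    diag: np.ndarray  # unclipped alignment start (may be <0 or >L-read_len)

    def __len__(self) -> int:
        return len(self.read_idx)

    def intervals(self) -> list[tuple[int, int]]:
        return list(zip(self.start.tolist(), self.end.tolist()))


@dataclass
class SeedCandidates:
    """Seeded but unverified (or failed) diagonals, for gapped rescue."""

    read_idx: np.ndarray
    strand: np.ndarray
    diag: np.ndarray


class ReadMapper:
    def __init__(self, reads: ReadSet, k: int = 21, max_kmer_hits: int = 16):
        self.reads = reads
        self.k = k
        self.max_kmer_hits = max_kmer_hits
        self.id_to_idx = {rid: i for i, rid in enumerate(reads.ids)}

        self.enc = [[], []]  # [strand][read] -> uint8 array
        codes_parts, meta_parts = [], []
        for i, seq in enumerate(reads.seqs):
            for strand, s in enumerate((seq, revcomp(seq))):
                e = encode(s)
                self.enc[strand].append(e)
                c = kmer_codes(e, k)
                valid = np.flatnonzero(c >= 0)
                if len(valid):
                    codes_parts.append(c[valid])
                    m = np.empty((len(valid), 3), dtype=np.int64)
                    m[:, 0] = i
                    m[:, 1] = strand
                    m[:, 2] = valid  # k-mer offset within the oriented read
                    meta_parts.append(m)
        if codes_parts:
            codes = np.concatenate(codes_parts)
            meta = np.concatenate(meta_parts)
        else:
            codes = np.empty(0, dtype=np.int64)
            meta = np.empty((0, 3), dtype=np.int64)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._meta = meta[order]

    # -- contig-side index ------------------------------------------------

    def _contig_index(self, contig_seq: str):
        enc = encode(contig_seq)
        codes = kmer_codes(enc, self.k)
        valid = np.flatnonzero(codes >= 0)
        codes, pos = codes[valid], valid
        order = np.argsort(codes, kind="stable")
        return enc, codes[order], pos[order]

    def map_to(
        self,
        contig_seq: str,
        max_mismatch_rate: float = 0.05,
        min_overlap: int = 30,
        min_seed: int = 3,
    ) -> tuple[Placements, SeedCandidates]:
        """Place every read on the contig; returns (placements, failed seeds)."""
        enc_c, c_codes, c_pos = self._contig_index(contig_seq)
        L = len(enc_c)
        empty_p = Placements(*(np.empty(0, dtype=np.int64) for _ in range(6)))
        empty_s = SeedCandidates(*(np.empty(0, dtype=np.int64) for _ in range(3)))
        if len(c_codes) == 0 or len(self._codes) == 0:
            return empty_p, empty_s

        lo = np.searchsorted(c_codes, self._codes, side="left")
        hi = np.searchsorted(c_codes, self._codes, side="right")
        cnt = hi - lo
        cnt[cnt > self.max_kmer_hits] = 0  # repeat masking
        total = int(cnt.sum())
        if total == 0:
            return empty_p, empty_s
        qrep = np.repeat(np.arange(len(cnt)), cnt)
        within = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
        hit_pos = c_pos[lo[qrep] + within]
        meta = self._meta[qrep]
        diag = hit_pos - meta[:, 2]

        key = ((meta[:, 0] * 2 + meta[:, 1]) << 32) + (diag + _DIAG_OFF)
        ukey, votes = np.unique(key, return_counts=True)
        keep = votes >= min_seed
        ukey, votes = ukey[keep], votes[keep]
        if len(ukey) == 0:
            return empty_p, empty_s
        rs = ukey >> 32
        diags = (ukey & 0xFFFFFFFF) - _DIAG_OFF
        # best diagonal per (read, strand): most votes, ties -> leftmost diag.
        # ukey is sorted, so within an rs block diags ascend; stable sort by
        # descending votes keeps the leftmost among equals first.
        order = np.lexsort((diags, -votes, rs))
        rs_s, diag_s = rs[order], diags[order]
        first = np.ones(len(rs_s), dtype=bool)
        first[1:] = rs_s[1:] != rs_s[:-1]
        rs_b, diag_b = rs_s[first], diag_s[first]

        # verify candidates; keep the better strand per read
        best: dict[int, tuple] = {}
        failed_r, failed_s, failed_d = [], [], []
        for r_s, d in zip(rs_b.tolist(), diag_b.tolist()):
            ridx, strand = divmod(r_s, 2)
            renc = self.enc[strand][ridx]
            rl = len(renc)
            cs, ce = max(d, 0), min(d + rl, L)
            ov = ce - cs
            ok = False
            if ov >= min_overlap:
                mm = int(np.count_nonzero(enc_c[cs:ce] != renc[cs - d : ce - d]))
                if mm <= max_mismatch_rate * ov:
                    ok = True
            if not ok:
                failed_r.append(ridx)
                failed_s.append(strand)
                failed_d.append(d)
                continue
            cand = (mm / ov, strand, cs, ce, mm, d)
            if ridx not in best or cand < best[ridx]:
                best[ridx] = cand
        if best:
            items = sorted(best.items())
            ridx = np.array([i for i, _ in items], dtype=np.int64)
            placements = Placements(
                read_idx=ridx,
                strand=np.array([c[1] for _, c in items], dtype=np.int64),
                start=np.array([c[2] for _, c in items], dtype=np.int64),
                end=np.array([c[3] for _, c in items], dtype=np.int64),
                n_mismatch=np.array([c[4] for _, c in items], dtype=np.int64),
                diag=np.array([c[5] for _, c in items], dtype=np.int64),
            )
        else:
            placements = empty_p
        seeds = SeedCandidates(
            np.array(failed_r, dtype=np.int64),
            np.array(failed_s, dtype=np.int64),
            np.array(failed_d, dtype=np.int64),
        )
        return placements, seeds

    # -- recruitment -------------------------------------------------------

    def shared_kmer_counts(self, query_seq: str) -> np.ndarray:
        """Per-read max-over-strands count of k-mers shared with ``query_seq``."""
        q = kmer_codes(encode(query_seq), self.k)
        q = q[q >= 0]
        counts = np.zeros((len(self.reads), 2), dtype=np.int64)
        if len(q) == 0 or len(self._codes) == 0:
            return counts.max(axis=1)
        lo = np.searchsorted(self._codes, q, side="left")
        hi = np.searchsorted(self._codes, q, side="right")
        cnt = hi - lo
        total = int(cnt.sum())
        if total:
            qrep = np.repeat(np.arange(len(q)), cnt)
            within = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
            meta = self._meta[lo[qrep] + within]
            np.add.at(counts, (meta[:, 0], meta[:, 1]), 1)
        return counts.max(axis=1)

    def recruit(self, query_seqs: list[str], min_shared: int = 3) -> list[int]:
        """Indices of reads sharing >= min_shared k-mers with any query, plus mates."""
        hit = np.zeros(len(self.reads), dtype=bool)
        for q in query_seqs:
            hit |= self.shared_kmer_counts(q) >= min_shared
        idx = set(np.flatnonzero(hit).tolist())
        for i in list(idx):
            mate = self.reads.mates.get(self.reads.ids[i])
            if mate is not None:
                idx.add(self.id_to_idx[mate])
        return sorted(idx)
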