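"""Domain types and file I/O shared by all pipeline stages.

Coordinates are 0-based, half-open everywhere internally; 1-based inclusive
coordinates appear only in human-readable reports. Sequences are upper-cased
on input and restricted to the alphabet {A, C, G, T, N}.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains symbols outside {A,C,G,T,N}."""


def _validate_seq(seq: str, name: str) -> str:
    seq = seq.upper()
    if not seq:
        raise SequenceAlphabetError(f"{name}: empty sequence")
    bad = set(seq) - ALPHABET
    if bad:
        raise SequenceAlphabetError(f"{name}: invalid symbols {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class Region:
    """A contiguous interval on a contig, 0-based half-open."""

    contig_id: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def to_1based(self) -> tuple[int, int]:
        """(start, end) in 1-based inclusive convention, for reports."""
        return self.start + 1, self.end


@dataclass(frozen=True)
class EditEvent:
    """One recorded modification of a contig.

    ``detail`` carries whatever is needed to replay the event: removed or
    inserted sequence, trim sizes, correction ops. ``delta_bp`` is the signed
    length change length(after) - length(before).
    """

    kind: str  # circular_trim | suspicious_split | end_trim | extension | base_correction
    interval: Optional[Region]
    delta_bp: int
    iteration: int
    detail: dict = field(default_factory=dict)

    KINDS = frozenset(
        {"circular_trim", "suspicious_split", "end_trim", "extension", "base_correction"}
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown edit kind {self.kind!r}")


@dataclass
class Contig:
    """A named nucleotide sequence with provenance of edits."""

    id: str
    seq: str
    history: list[EditEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = _validate_seq(self.seq, self.id)

    def __len__(self) -> int:
        return len(self.seq)

    def with_edit(self, seq: str, event: EditEvent) -> "Contig":
        """New contig with ``seq`` and ``event`` appended to the history."""
        if event.delta_bp != len(seq) - len(self.seq):
            raise ValueError(
                f"delta_bp {event.delta_bp} does not match length change "
                f"{len(seq) - len(self.seq)}"
            )
        return Contig(self.id, seq, [*self.history, event])


def apply_event(seq: str, event: EditEvent) -> str:
    """Replay a single edit event on ``seq``."""
    kind, d = event.kind, event.detail
    if kind == "circular_trim":
        iv = event.interval
        return seq[: iv.start] + seq[iv.end :]
    if kind == "suspicious_split":
        iv = event.interval
        return seq[iv.start : iv.end]
    if kind == "end_trim":
        t = d["trim_bp"]
        return seq[t : len(seq) - t]
    if kind == "extension":
        return d.get("left", "") + seq + d.get("right", "")
    if kind == "base_correction":
        out = seq
        # ops pre-sorted right-to-left so positions stay valid
        for op in d["ops"]:
            pos = op["pos"]
            if op["op"] == "sub":
                out = out[:pos] + op["new"] + out[pos + 1 :]
            elif op["op"] == "ins":
                out = out[:pos] + op["new"] + out[pos:]
            elif op["op"] == "del":
                out = out[:pos] + out[pos + op["len"] :]
        return out
    raise ValueError(kind)


def replay_history(original: str, history: Sequence[EditEvent]) -> str:
    """Replay an edit history from the original sequence."""
    seq = original
    for ev in history:
        seq = apply_event(seq, ev)
    return seq


@dataclass
class ReadSet:
    """Collection of (possibly paired) short reads.

    ``read_length`` is the representative (modal) read length of the set.
    ``mates`` maps a read id to its partner's id, symmetrically.
    """

    ids: list[str]
    seqs: list[str]
    quals: list[Optional[str]]
    mates: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("read ids are not unique")
        for rid, seq, q in zip(self.ids, self.seqs, self.quals):
            if q is not None and len(q) != len(seq):
                raise ValueError(f"{rid}: quality length != sequence length")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def read_length(self) -> int:
        if not self.seqs:
            raise ValueError("empty read set has no representative length")
        counts = Counter(len(s) for s in self.seqs)
        top = max(counts.values())
        # deterministic tie-break: longest among the modal lengths
        return max(l for l, c in counts.items() if c == top)

    def subset(self, indices: Iterable[int]) -> "ReadSet":
        idx = sorted(set(indices))
        ids = [self.ids[i] for i in idx]
        keep = set(ids)
        mates = {a: b for a, b in self.mates.items() if a in keep and b in keep}
        return ReadSet(
            ids,
            [self.seqs[i] for i in idx],
            [self.quals[i] for i in idx],
            mates,
        )

    def iter_reads(self) -> Iterator[tuple[str, str, Optional[str]]]:
        yield from zip(self.ids, self.seqs, self.quals)


# ---------------------------------------------------------------------------
# File I/O


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a FASTA file into a list of contigs (sequences upper-cased)."""
    contigs = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            contigs.append(Contig(rec.id, str(rec.seq)))
    return contigs


def write_fasta(path: str | Path, contigs: Iterable[Contig]) -> None:
    records = [SeqRecord(Seq(c.seq), id=c.id, description="") for c in contigs]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path, path2: Optional[str | Path] = None) -> ReadSet:
    """Read single or paired FASTQ file(s) into a ReadSet.

    With ``path2``, records pair positionally; ids are suffixed /1 and /2
    when the two files reuse the same id.
    """
    def _load(p):
        out = []
        with _open_text(p) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
                out.append((rec.id, str(rec.seq).upper(), qual))
        return out

    first = _load(path)
    if path2 is None:
        ids = [r[0] for r in first]
        # interleaved pairing by the conventional /1 and /2 id suffixes
        present = set(ids)
        mates = {}
        for rid in ids:
            if rid.endswith("/1") and rid[:-1] + "2" in present:
                mates[rid] = rid[:-1] + "2"
                mates[rid[:-1] + "2"] = rid
        return ReadSet(ids, [r[1] for r in first], [r[2] for r in first], mates)

    second = _load(path2)
    if len(first) != len(second):
        raise ValueError(
            f"paired FASTQ record count mismatch: {len(first)} vs {len(second)}"
        )
    ids, seqs, quals, mates = [], [], [], {}
    for (i1, s1, q1), (i2, s2, q2) in zip(first, second):
        if i1 == i2:
            i1, i2 = i1 + "/1", i2 + "/2"
        ids += [i1, i2]
        seqs += [s1, s2]
        quals += [q1, q2]
        mates[i1], mates[i2] = i2, i1
    return ReadSet(ids, seqs, quals, mates)


def write_fastq(path: str | Path, reads: ReadSet) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in reads.iter_reads():
            fh.write(f"@{rid}\n{seq}\n+\n{qual or 'I' * len(seq)}\n")


def placements_from_sam(path: str | Path, contig_id: str) -> list[tuple[int, int]]:
    """Extract (start, end) reference intervals for reads mapped to a contig.

    Accepts SAM or BAM; unmapped and secondary records are skipped.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.reference_name != contig_id:
                continue
            out.append((aln.reference_start, aln.reference_end))
    return out


def write_bed(path: str | Path, regions: Iterable[Region]) -> None:
    """Write regions as BED (0-based half-open) with a track header."""
    with open(path, "w") as fh:
        fh.write('track name="virextend_regions" description="flagged regions"\n')
        for r in regions:
            fh.write(f"{r.contig_id}\t{r.start}\t{r.end}\t{r.label}\n")


def write_outputs(contig: Contig, regions: Sequence[Region], log, outdir: str | Path) -> dict:
    """Write final FASTA, BED of flagged regions and the JSON provenance log.

    Returns a dict of output paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{contig.id}.final.fasta"
    bed = outdir / f"{contig.id}.regions.bed"
    logp = outdir / f"{contig.id}.log.json"
    write_fasta(fasta, [contig])
    write_bed(bed, regions)
    with open(logp, "w") as fh:
        json.dump(log.to_json() if hasattr(log, "to_json") else log, fh, indent=2)
    return {"fasta": fasta, "bed": bed, "log": logp}
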