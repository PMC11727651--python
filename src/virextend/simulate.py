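"""Synthetic genomes, misassemblies and Illumina-like read sets.

The generator produces the data regimes the pipeline assumes: circular or
linear viral genomes (optionally with a terminal repeat), chimeric inserts
with independent truth coordinates, and uniformly sampled single or paired
150 bp reads with substitution errors. Fragment starts are uniform (no GC
bias) and the error model is substitution-only with constant quality
strings: the pipeline's logic is coverage- and identity-driven, so indel
sequencing errors would add noise without exercising additional code paths.
Everything is fully reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import Contig, ReadSet, Region, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    genome_length: int
    circular: bool = False
    terminal_repeat_len: int = 0
    read_length: int = 150
    coverage: float = 30.0
    error_rate: float = 0.01
    paired: bool = True
    insert_mean: float = 450.0
    insert_sd: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1 or self.read_length < 1:
            raise ValueError("lengths must be positive")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.circular and self.terminal_repeat_len:
            raise ValueError("terminal repeats apply to linear genomes only")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def make_genome(config: SimConfig, contig_id: str | None = None) -> Contig:
    """I.i.d. uniform genome; linear genomes may carry a terminal repeat."""
    rng = _rng(config, 0)
    arr = _BASES[rng.integers(0, 4, size=config.genome_length)]
    seq = arr.tobytes().decode()
    if not config.circular and config.terminal_repeat_len > 0:
        seq = seq + seq[: config.terminal_repeat_len]
    cid = contig_id or f"sim_{'circ' if config.circular else 'lin'}_{config.genome_length}_{config.seed}"
    return Contig(cid, seq)


def make_chimera(
    host: Contig, insert: "Contig | str", position: int
) -> tuple[Contig, Region | None]:
    """Inject ``insert`` into ``host`` at ``position`` (a misassembly).

    ``insert`` may be a contig or a bare sequence string (possibly empty).
    Returns the chimeric contig and the truth coordinates of the insert
    (None when the insert is empty).
    """
    if not (0 <= position <= len(host)):
        raise ValueError("position outside host")
    ins_seq = insert.seq if isinstance(insert, Contig) else insert
    ins_id = insert.id if isinstance(insert, Contig) else "ins"
    seq = host.seq[:position] + ins_seq + host.seq[position:]
    cid = f"{host.id}+{ins_id}"
    region = (
        Region(cid, position, position + len(ins_seq), "insert") if ins_seq else None
    )
    return Contig(cid, seq), region


def mutate(seq: str, n_subs: int, seed: int) -> str:
    """Place exactly ``n_subs`` substitutions at distinct random positions."""
    if n_subs == 0:
        return seq
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    pos = rng.choice(len(arr), size=n_subs, replace=False)
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


def _apply_errors(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return arr
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for p in hit:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return arr


def simulate_reads(genome: Contig, config: SimConfig) -> ReadSet:
    """Uniform shotgun reads from the genome (wrapping the origin if circular).

    Read count follows round(coverage * genome_length / (read_length * 2))
    fragments when paired (two reads each), or that many single reads
    otherwise.
    """
    G = len(genome)
    L = config.read_length
    if G <= L:
        raise ValueError("genome must be longer than the read length")
    rng = _rng(config, 1)
    n = int(round(config.coverage * G / (L * (2 if config.paired else 1))))
    garr = np.frombuffer(genome.seq.encode(), dtype=np.uint8)

    ids, seqs, quals, mates = [], [], [], {}
    qual = "I" * L

    def fragment(start: int, length: int) -> np.ndarray:
        idx = np.arange(start, start + length)
        if config.circular:
            idx %= G
        return garr[idx]

    for i in range(n):
        if config.paired:
            F = int(np.clip(round(rng.normal(config.insert_mean, config.insert_sd)), L, G))
            start = int(rng.integers(0, G if config.circular else G - F + 1))
            frag = fragment(start, F)
            r1 = _apply_errors(frag[:L].copy(), config.error_rate, rng)
            r2arr = _apply_errors(frag[-L:].copy(), config.error_rate, rng)
            r2 = revcomp(r2arr.tobytes().decode())
            i1, i2 = f"r{i:07d}/1", f"r{i:07d}/2"
            ids += [i1, i2]
            seqs += [r1.tobytes().decode(), r2]
            quals += [qual, qual]
            mates[i1], mates[i2] = i2, i1
        else:
            start = int(rng.integers(0, G if config.circular else G - L + 1))
            r = _apply_errors(fragment(start, L).copy(), config.error_rate, rng)
            ids.append(f"r{i:07d}")
            seqs.append(r.tobytes().decode())
            quals.append(qual)
    return ReadSet(ids, seqs, quals, mates)


def write_truth(path: str | Path, truth: dict) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
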