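"""The full correct-and-extend loop.

Each iteration: (1) check circularity — a circular contig is trimmed of its
redundant terminal copy and the loop exits; (2) re-map the reads genome-wide,
compute the depth profile and cut the contig down to its longest
non-suspicious region if the audit flags anything; (3) attempt edge
extension, falling back to trim-and-retry; if nothing grows the loop exits.
The loop is capped at ``max_iterations``. Afterwards circularity is checked
once more (extension may have closed the genome on the final round), the
redundant copy trimmed, and the contig polished by pileup consensus.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Optional

from .circularity import CircularityParams, check_circularity, trim_circular_redundancy
from .core import Contig, EditEvent, ReadSet, Region
from .coverage import (
    AuditParams,
    WholeContigSuspiciousError,
    compute_depth,
    flag_suspicious,
    longest_non_suspicious,
)
from .extension import ExtensionParams, extend_once, trim_and_retry
from .mapping import ReadMapper
from .polish import PolishParams, polish

logger = logging.getLogger(__name__)

STOP_REASONS = frozenset(
    {"circular", "no_growth_after_trim", "max_iterations", "whole_contig_suspicious"}
)


@dataclass(frozen=True)
class PipelineConfig:
    audit: AuditParams = field(default_factory=AuditParams)
    extension: ExtensionParams = field(default_factory=ExtensionParams)
    polish: PolishParams = field(default_factory=PolishParams)
    circularity: CircularityParams = field(default_factory=CircularityParams)
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            audit=AuditParams(**d.get("audit", {})),
            extension=ExtensionParams(**d.get("extension", {})),
            polish=PolishParams(**d.get("polish", {})),
            circularity=CircularityParams(**d.get("circularity", {})),
            max_iterations=d.get("max_iterations", 100),
        )


@dataclass
class Round:
    index: int
    action: str
    length_before: int
    length_after: int
    stop_reason: Optional[str] = None
    details: dict = field(default_factory=dict)


@dataclass
class IterationLog:
    rounds: list[Round] = field(default_factory=list)
    post: dict = field(default_factory=dict)

    def append(self, rnd: Round) -> None:
        if self.rounds and rnd.index <= self.rounds[-1].index:
            raise ValueError("iteration indices must be strictly increasing")
        self.rounds.append(rnd)

    @property
    def stop_reason(self) -> Optional[str]:
        for r in self.rounds:
            if r.stop_reason:
                return r.stop_reason
        return None

    def to_json(self) -> dict:
        return {
            "schema": 1,
            "rounds": [asdict(r) for r in self.rounds],
            "post": self.post,
        }


@dataclass
class PipelineResult:
    contig: Contig
    regions: list[Region]
    log: IterationLog


def run_pipeline(
    contig: Contig, reads: ReadSet, config: PipelineConfig | None = None
) -> PipelineResult:
    """Run error correction, iterative extension and polishing on one contig."""
    config = config or PipelineConfig()
    if len(reads) == 0:
        raise ValueError("empty read set")
    mapper = ReadMapper(reads, k=config.extension.recruit_k)
    L_r = reads.read_length
    map_kwargs = dict(
        max_mismatch_rate=config.polish.map_max_mismatch_rate,
        min_overlap=config.extension.min_overlap,
    )
    log = IterationLog()
    cur = contig
    stop: Optional[str] = None

    for it in range(1, config.max_iterations + 1):
        len0 = len(cur)
        details: dict = {}
        actions: list[str] = []

        circ = check_circularity(cur, L_r, config.circularity)
        details["circularity"] = circ.to_json()
        if circ.is_circular:
            cur = trim_circular_redundancy(cur, circ, it)
            log.append(Round(it, "circular_trim", len0, len(cur), "circular", details))
            stop = "circular"
            break

        placements, _ = mapper.map_to(cur.seq, **map_kwargs)
        profile = compute_depth(cur, placements.intervals(), config.audit)
        suspicious = flag_suspicious(profile, config.audit)
        details["suspicious_regions"] = [[r.start, r.end] for r in suspicious]
        if suspicious:
            try:
                keep = longest_non_suspicious(profile, suspicious)
            except WholeContigSuspiciousError:
                log.append(
                    Round(it, "halt", len0, len0, "whole_contig_suspicious", details)
                )
                logger.warning("%s: whole contig suspicious, halting", contig.id)
                return PipelineResult(contig, suspicious, log)
            if (keep.start, keep.end) != (0, len(cur)):
                cur = cur.with_edit(
                    cur.seq[keep.start : keep.end],
                    EditEvent(
                        kind="suspicious_split",
                        interval=keep,
                        delta_bp=len(keep) - len(cur),
                        iteration=it,
                        detail={"kept": [keep.start, keep.end]},
                    ),
                )
                actions.append("suspicious_split")
                details["kept_region"] = [keep.start, keep.end]

        extended, outcome = extend_once(
            cur, reads, L_r, config.extension, mapper=mapper, iteration=it
        )
        if outcome.grew:
            cur = extended
            actions.append("extend")
            details["added_bp"] = [outcome.left_added_bp, outcome.right_added_bp]
            log.append(Round(it, "+".join(actions), len0, len(cur), None, details))
            continue
        retried, outcome = trim_and_retry(
            cur, reads, L_r, config.extension, mapper=mapper, iteration=it
        )
        if outcome.grew:
            cur = retried
            actions.append("trim_extend")
            details["trim_applied"] = outcome.trimmed_bp_applied
            details["added_bp"] = [outcome.left_added_bp, outcome.right_added_bp]
            log.append(Round(it, "+".join(actions), len0, len(cur), None, details))
            continue
        actions.append("no_growth")
        log.append(
            Round(it, "+".join(actions), len0, len(cur), "no_growth_after_trim", details)
        )
        stop = "no_growth_after_trim"
        break
    else:
        # cap reached: mark the last round as terminal
        last = log.rounds[-1]
        log.rounds[-1] = Round(
            last.index, last.action, last.length_before, last.length_after,
            "max_iterations", last.details,
        )
        stop = "max_iterations"

    # final circularity re-check (extension may have closed the genome)
    final_circ = check_circularity(cur, L_r, config.circularity)
    if final_circ.is_circular:
        cur = trim_circular_redundancy(cur, final_circ, log.rounds[-1].index + 1)
    log.post["final_circularity"] = final_circ.to_json()

    polished = polish(cur, reads, config.polish, mapper=mapper, iteration=log.rounds[-1].index + 1)
    n_corr = (
        len(polished.history[-1].detail["ops"])
        if len(polished.history) > len(cur.history)
        else 0
    )
    log.post["polish_corrections"] = n_corr
    if n_corr:
        log.post["corrections"] = polished.history[-1].detail["ops"]
    cur = polished

    placements, _ = mapper.map_to(cur.seq, **map_kwargs)
    profile = compute_depth(cur, placements.intervals(), config.audit)
    regions = flag_suspicious(profile, config.audit)
    log.post["final_length"] = len(cur)
    log.post["stop_reason"] = stop
    return PipelineResult(cur, regions, log)
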