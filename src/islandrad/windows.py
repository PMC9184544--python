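"""Planning and extraction of homologous fixed-length genome segments.

Segments of length ``L`` are tiled along each contig with a fixed gap ``G``
between them, starting from a random point drawn uniformly between site
100,000 and 1,000,000 (to avoid starting too close to a potential
telomere).  Because all individuals carry sequences in the same reference
coordinates, a coordinate slice is automatically an alignment and no
re-alignment is needed.

Coordinates are 0-based half-open internally; 1-based only at VCF
boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from islandrad.qc import WindowedAlignment, encode_sequence

TELOMERE_BUFFER = 100_000  # minimum distance of any segment from the contig start
START_UPPER_BOUND = 1_000_000  # sampled start never exceeds this


@dataclass(frozen=True)
class SegmentCoordinates:
    """One segment: contig id plus a 0-based half-open interval."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentPlan:
    """Deterministic tiling of segments across contigs."""

    length: int
    gap: int
    starts: dict[str, int | None]  # sampled start per contig (None: contig too short)
    segments: list[SegmentCoordinates] = field(default_factory=list)
    seed: int = 0


def tile_from_start(start: int, contig_length: int, length: int, gap: int, contig: str = "contig") -> list[SegmentCoordinates]:
    """Tile fixed-length segments from ``start``: extract ``length``, skip
    ``gap``, repeat; a final partial segment is discarded."""
    out = []
    pos = start
    while pos + length <= contig_length:
        out.append(SegmentCoordinates(contig, pos, pos + length))
        pos += length + gap
    return out


def plan_segments(
    contig_lengths: Mapping[str, int],
    length: int,
    gap: int,
    seed: int,
) -> SegmentPlan:
    """Plan fixed-length segments with fixed gaps on every contig.

    Per contig the first start is drawn uniformly from the integers
    ``[100000, min(1000000, contig_length - length)]``; successive starts
    differ by exactly ``length + gap``; a final partial segment is
    discarded.  Contigs too short for the minimum start contribute no
    segments.  Deterministic under ``seed``.
    """
    if length <= 0:
        raise ValueError("segment length must be positive")
    if gap < 0:
        raise ValueError("gap must be nonnegative")
    rng = np.random.default_rng(seed)
    starts: dict[str, int | None] = {}
    segments: list[SegmentCoordinates] = []
    for contig in contig_lengths:  # insertion order: deterministic
        clen = int(contig_lengths[contig])
        hi = min(START_UPPER_BOUND, clen - length)
        if hi < TELOMERE_BUFFER:
            starts[contig] = None
            continue
        start = int(rng.integers(TELOMERE_BUFFER, hi + 1))
        starts[contig] = start
        segments.extend(tile_from_start(start, clen, length, gap, contig=contig))
    return SegmentPlan(length=length, gap=gap, starts=starts, segments=segments, seed=seed)


def extract_alignments(
    sequences: Mapping[str, Mapping[str, str]],
    plan: SegmentPlan,
    taxon_order: list[str] | None = None,
) -> list[WindowedAlignment]:
    """Slice every planned segment out of every individual's sequence.

    ``sequences`` maps individual -> contig -> sequence string.  Every
    individual must carry every planned contig.  Row order is fixed to
    ``taxon_order`` (default: sorted individual ids) and recorded on each
    alignment.
    """
    taxa = taxon_order if taxon_order is not None else sorted(sequences)
    planned_contigs = {seg.contig for seg in plan.segments}
    encoded: dict[str, dict[str, np.ndarray]] = {}
    for ind in taxa:
        encoded[ind] = {}
        for contig in planned_contigs:
            if contig not in sequences[ind]:
                raise KeyError(f"individual {ind!r} has no sequence for contig {contig!r}")
            encoded[ind][contig] = encode_sequence(sequences[ind][contig])
    alignments = []
    for seg in plan.segments:
        data = np.vstack([encoded[ind][seg.contig][seg.start : seg.end] for ind in taxa])
        alignments.append(WindowedAlignment(taxa=list(taxa), data=data, coords=seg))
    return alignments


def write_plan_bed(plan: SegmentPlan, bed_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Serialize a plan as BED (0-based half-open) plus a JSON sidecar."""
    bed_path = Path(bed_path)
    with open(bed_path, "w") as fh:
        for seg in plan.segments:
            fh.write(f"{seg.contig}\t{seg.start}\t{seg.end}\n")
    if sidecar_path is None:
        sidecar_path = bed_path.with_suffix(".json")
    meta = {
        "length": plan.length,
        "gap": plan.gap,
        "seed": plan.seed,
        "starts": plan.starts,
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=2) + "\n")


def read_plan_bed(bed_path: str | Path, sidecar_path: str | Path | None = None) -> SegmentPlan:
    """Load a plan written by :func:`write_plan_bed`."""
    bed_path = Path(bed_path)
    if sidecar_path is None:
        sidecar_path = bed_path.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    segments = []
    for line in bed_path.read_text().splitlines():
        if not line.strip():
            continue
        contig, start, end = line.split("\t")
        segments.append(SegmentCoordinates(contig, int(start), int(end)))
    return SegmentPlan(
        length=meta["length"],
        gap=meta["gap"],
        starts={k: (None if v is None else int(v)) for k, v in meta["starts"].items()},
        segments=segments,
        seed=meta["seed"],
    )
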