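"""Per-alignment quality statistics and the retention filter.

Each windowed alignment is summarised by three statistics -- the number of
parsimony-informative sites, the fraction of missing (``N``) cells, and the
GC fraction of the non-missing cells -- and retained only if it has more
than 5 parsimony-informative sites, less than 10% missing data, and a GC
content strictly between 30% and 70%.  All three thresholds are strict
inequalities and all are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from islandrad.windows import SegmentCoordinates

# Base encoding used throughout the package: A C G T N -> 0 1 2 3 4.
ALPHABET = "ACGTN"
N_CODE = 4

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET.encode()):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase
_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/N string as a uint8 code array (A=0 .. N=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[raw]
    if np.any(codes == 255):
        bad = int(np.argmax(codes == 255))
        raise ValueError(f"invalid base {seq[bad]!r} at offset {bad}")
    return codes


def decode_sequence(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an A/C/G/T/N string."""
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass
class WindowedAlignment:
    """Homologous fixed-length multi-taxon segment in reference coordinates.

    Rows are stored as a (taxa x sites) uint8 code matrix over A/C/G/T/N.
    Because every row is the same coordinate slice of a different
    individual, rows are positionally homologous and gap-free.
    """

    taxa: list[str]
    data: np.ndarray  # shape (n_taxa, length), dtype uint8, values 0..4
    coords: "SegmentCoordinates | None" = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise ValueError("alignment data must be a 2-D matrix (ragged rows?)")
        if self.data.shape[0] != len(self.taxa):
            raise ValueError("row count does not match taxon count")
        if self.data.size and self.data.max() > N_CODE:
            raise ValueError("alignment contains codes outside A/C/G/T/N")

    @classmethod
    def from_strings(
        cls,
        taxa: Sequence[str],
        rows: Sequence[str],
        coords: "SegmentCoordinates | None" = None,
    ) -> "WindowedAlignment":
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValueError("ragged rows: all rows must have equal length")
        data = np.vstack([encode_sequence(r) for r in rows]) if rows else np.empty((0, 0), np.uint8)
        return cls(taxa=list(taxa), data=data, coords=coords)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def length(self) -> int:
        return self.data.shape[1]

    def row(self, i: int) -> str:
        return decode_sequence(self.data[i])


@dataclass(frozen=True)
class QCThresholds:
    """Retention thresholds; defaults follow the AMAS-style filter."""

    min_pi: int = 5  # strict: PI must exceed this
    max_missing: float = 0.10  # strict: missing fraction must be below this
    gc_low: float = 0.30  # strict bounds
    gc_high: float = 0.70


@dataclass
class QCReport:
    alignment_id: str
    pi_sites: int
    missing_frac: float
    gc_frac: float  # nan when every cell is N
    passed: bool = field(default=False)


def count_parsimony_informative(aln: WindowedAlignment) -> int:
    """Number of columns with >= 2 distinct non-N states each in >= 2 rows.

    ``N`` is never counted as a state, so a column like (N, A, C, C) has C
    twice but A only once and is not informative.
    """
    if aln.n_taxa == 0 or aln.length == 0:
        raise ValueError("empty alignment")
    counts = np.stack([(aln.data == s).sum(axis=0) for s in range(4)])  # (4, L)
    return int((((counts >= 2).sum(axis=0)) >= 2).sum())


def missing_fraction(aln: WindowedAlignment) -> float:
    """Fraction of cells that are N."""
    if aln.data.size == 0:
        raise ValueError("empty alignment")
    return float((aln.data == N_CODE).mean())


def gc_content(aln: WindowedAlignment) -> float:
    """(G + C cells) / (non-N cells).  Undefined for an all-N alignment."""
    non_n = int((aln.data != N_CODE).sum())
    if non_n == 0:
        raise ValueError("gc_content undefined: alignment is entirely N")
    gc = int(((aln.data == 1) | (aln.data == 2)).sum())
    return gc / non_n


def qc_report(aln: WindowedAlignment, thresholds: QCThresholds = QCThresholds(),
              alignment_id: str = "") -> QCReport:
    """Compute the three statistics and the pass flag for one alignment."""
    pi = count_parsimony_informative(aln)
    miss = missing_fraction(aln)
    try:
        gc = gc_content(aln)
    except ValueError:
        # all-N alignment: GC undefined, automatically fails the filter
        return QCReport(alignment_id, pi, miss, float("nan"), False)
    passed = (
        pi > thresholds.min_pi
        and miss < thresholds.max_missing
        and thresholds.gc_low < gc < thresholds.gc_high
    )
    return QCReport(alignment_id, pi, miss, gc, passed)


def apply_filters(
    alignments: Sequence[WindowedAlignment],
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[list[WindowedAlignment], list[QCReport]]:
    """Filter alignments, preserving input order.

    Returns the retained alignments and one :class:`QCReport` per input.
    The pass flag is a pure function of the report, so re-running yields
    identical retention.
    """
    reports = []
    retained = []
    for i, aln in enumerate(alignments):
        ident = f"{aln.coords.contig}:{aln.coords.start}-{aln.coords.end}" if aln.coords else str(i)
        rep = qc_report(aln, thresholds, alignment_id=ident)
        reports.append(rep)
        if rep.passed:
            retained.append(aln)
    return retained, reports
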