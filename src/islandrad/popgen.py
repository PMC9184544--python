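"""Heterozygosity, heterozygosity-normalized genetic distance, and
lineage assignment.

Pairwise genetic distance between two individuals is higher when the
individuals come from more diverse populations, so the raw segment-mean
distance is normalized by the individuals' average genome-wide
heterozygosity:

    distance = ( (1/n) * sum_i a_i / S_i ) / ( (h1 + h2) / 2 )

where n is the number of genomic segments, a_i the pairwise difference
count in segment i, S_i the number of sites with no missing base (N) for
the pair in segment i, and h1, h2 the per-base-pair genome-wide observed
heterozygosities of the two individuals.  Under this scaling two
individuals drawn from the same panmictic population sit near 1, so the
distance of a focal individual can be read directly against the
within-species distribution.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from islandrad.qc import N_CODE, encode_sequence
from islandrad.structure import GenotypeMatrix
from islandrad.windows import SegmentCoordinates, SegmentPlan

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------


@dataclass
class HeterozygosityEstimate:
    """Observed per-bp heterozygosity of one individual."""

    individual: str
    het_sites: int
    callable_sites: int

    def __post_init__(self) -> None:
        if self.callable_sites <= 0:
            raise ValueError("heterozygosity undefined: zero callable sites")

    @property
    def h(self) -> float:
        return self.het_sites / self.callable_sites


def estimate_heterozygosity(
    genotypes: GenotypeMatrix,
    individual: str,
    min_depth: int = 6,
    min_gq: int = 18,
    invariant_callable: int = 0,
) -> HeterozygosityEstimate:
    """Observed heterozygosity from genotype calls with DP/GQ filters.

    Only genotype calls with depth >= ``min_depth`` and genotype quality
    >= ``min_gq`` (i.e. GQ strictly greater than 17 at the defaults) are
    counted as callable.  ``invariant_callable`` adds the number of
    callable invariant sites, which a variants-only VCF cannot carry, so
    the denominator covers variant plus invariant callable sites; leave it
    at 0 to restrict to variant sites only.
    """
    try:
        col = genotypes.samples.index(individual)
    except ValueError:
        raise KeyError(f"unknown individual {individual!r}") from None
    dos = genotypes.dosage[:, col]
    ok = dos >= 0
    if genotypes.dp is not None and min_depth is not None:
        ok &= genotypes.dp[:, col] >= min_depth
    if genotypes.gq is not None and min_gq is not None:
        ok &= genotypes.gq[:, col] >= min_gq
    het = int(((dos == 1) & ok).sum())
    callable_sites = int(ok.sum()) + int(invariant_callable)
    return HeterozygosityEstimate(individual, het, callable_sites)


# ---------------------------------------------------------------------------
# segment differences and Eq.-style normalized distance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentDiff:
    """Per-segment pairwise difference count a_i over overlap S_i."""

    segment_id: str
    a: int  # pairwise differences
    s: int  # mutually non-N sites

    def __post_init__(self) -> None:
        if not (0 <= self.a <= self.s):
            raise ValueError("need 0 <= a <= S")


def segment_diff(seq_a: str, seq_b: str, coords: SegmentCoordinates) -> SegmentDiff:
    """Count differences and mutual non-N overlap on one segment slice.

    ``seq_a`` and ``seq_b`` are full contig sequences in reference
    coordinates; the slice is taken here so both individuals are cut at
    identical positions.
    """
    a = encode_sequence(seq_a[coords.start : coords.end])
    b = encode_sequence(seq_b[coords.start : coords.end])
    if a.size != b.size:
        raise ValueError("length mismatch between the two slices")
    both = (a != N_CODE) & (b != N_CODE)
    s = int(both.sum())
    diff = int(((a != b) & both).sum())
    return SegmentDiff(f"{coords.contig}:{coords.start}-{coords.end}", diff, s)


@dataclass
class NormalizedDistance:
    """Heterozygosity-normalized genetic distance between two individuals."""

    pair: tuple[str, str]
    n_segments: int
    raw: float  # mean of a_i / S_i
    value: float  # raw / mean heterozygosity

    def __post_init__(self) -> None:
        self.pair = tuple(sorted(self.pair))  # symmetric in the pair


def normalized_distance(
    diffs: Sequence[SegmentDiff],
    h_a: float,
    h_b: float,
    pair: tuple[str, str] = ("a", "b"),
) -> NormalizedDistance:
    """Average of per-segment difference ratios over the average
    heterozygosity of the pair.

    The mean of ratios is taken (not the ratio of sums): each segment
    contributes a_i / S_i with equal weight.  Segments with S_i = 0 carry
    no information for the pair and are skipped (and logged).
    """
    usable = [d for d in diffs if d.s > 0]
    skipped = len(diffs) - len(usable)
    if skipped:
        log.info("normalized_distance %s: skipped %d zero-overlap segments", pair, skipped)
    if not usable:
        raise ValueError("no usable segments (all have zero overlap)")
    mean_h = (h_a + h_b) / 2.0
    if mean_h <= 0:
        raise ValueError("normalization undefined: both heterozygosities are zero")
    raw = float(np.mean([d.a / d.s for d in usable]))
    return NormalizedDistance(pair=pair, n_segments=len(usable), raw=raw, value=raw / mean_h)


def pairwise_distances(
    sequences: Mapping[str, Mapping[str, str]],
    plan: SegmentPlan,
    het: Mapping[str, float],
) -> list[NormalizedDistance]:
    """All pairwise normalized distances over a segment plan.

    ``sequences`` maps individual -> contig -> pseudo-haploid sequence;
    ``het`` maps individual -> genome-wide heterozygosity.
    """
    inds = sorted(sequences)
    # encode once; segment_diff on strings would re-encode per pair
    enc = {
        ind: {c: encode_sequence(s) for c, s in sequences[ind].items()} for ind in inds
    }
    out = []
    for a, b in itertools.combinations(inds, 2):
        diffs = []
        for seg in plan.segments:
            xa = enc[a][seg.contig][seg.start : seg.end]
            xb = enc[b][seg.contig][seg.start : seg.end]
            both = (xa != N_CODE) & (xb != N_CODE)
            diffs.append(
                SegmentDiff(
                    f"{seg.contig}:{seg.start}-{seg.end}",
                    int(((xa != xb) & both).sum()),
                    int(both.sum()),
                )
            )
        out.append(normalized_distance(diffs, het[a], het[b], pair=(a, b)))
    return out


# ---------------------------------------------------------------------------
# distance hierarchy and assignment
# ---------------------------------------------------------------------------


@dataclass
class DistanceHierarchy:
    """Distances partitioned into focal-vs-each / within- / between-species."""

    focal_vs_each: list[NormalizedDistance]
    within_species: list[NormalizedDistance]
    between_species: list[NormalizedDistance]
    species: dict[str, str]
    focal_ids: list[str]

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for name, stratum in (
            ("focal_vs_each", self.focal_vs_each),
            ("within_species", self.within_species),
            ("between_species", self.between_species),
        ):
            vals = [d.value for d in stratum]
            out[name] = {
                "n": len(vals),
                "min": float(min(vals)) if vals else math.nan,
                "median": float(np.median(vals)) if vals else math.nan,
                "max": float(max(vals)) if vals else math.nan,
            }
        return out


def build_hierarchy(
    pairs: Sequence[NormalizedDistance],
    species: Mapping[str, str],
    focal_ids: Sequence[str] = (),
) -> DistanceHierarchy:
    """Partition computed pairs into disjoint, exhaustive strata.

    A pair touching any focal individual goes to the focal stratum; the
    remaining pairs split into within- and between-species by label.
    """
    focal = set(focal_ids)
    for d in pairs:
        for ind in d.pair:
            if ind not in species:
                raise KeyError(f"individual {ind!r} has no species label")
    f, w, b = [], [], []
    for d in pairs:
        a, bnd = d.pair
        if a in focal or bnd in focal:
            f.append(d)
        elif species[a] == species[bnd]:
            w.append(d)
        else:
            b.append(d)
    hierarchy = DistanceHierarchy(f, w, b, dict(species), list(focal_ids))
    log.info("distance hierarchy: %s", hierarchy.summary())
    return hierarchy


@dataclass
class Assignment:
    """Lineage-assignment decision for a focal individual.

    The decision is a pure function of the recorded criterion values:
    same-lineage when the focal's minimum distance is within the
    ``q``-quantile of the within-species reference distribution; novel
    when it exceeds every within-species value and the margin to the
    second-nearest lineage is positive; ambiguous otherwise.
    """

    focal: str
    nearest_lineage: str
    decision: str  # same-lineage | novel | ambiguous
    min_distance: float
    reference_quantile: float
    reference_max: float
    q: float
    lineage_means: dict[str, float] = field(default_factory=dict)


def classify_focal(focal: str, hierarchy: DistanceHierarchy, q: float = 0.95) -> Assignment:
    """Assign a focal individual to its nearest lineage, or call it novel."""
    focal_pairs = [d for d in hierarchy.focal_vs_each if focal in d.pair]
    if not focal_pairs:
        raise ValueError(f"hierarchy has no distances for focal {focal!r}")
    reference = [d.value for d in hierarchy.within_species]
    if not reference:
        raise ValueError("empty within-species reference distribution")
    by_lineage: dict[str, list[float]] = {}
    for d in focal_pairs:
        other = d.pair[0] if d.pair[1] == focal else d.pair[1]
        by_lineage.setdefault(hierarchy.species[other], []).append(d.value)
    means = {sp: float(np.mean(v)) for sp, v in by_lineage.items()}
    nearest = min(means, key=lambda sp: (means[sp], sp))
    min_distance = min(d.value for d in focal_pairs)
    ref_q = float(np.quantile(reference, q))
    ref_max = float(max(reference))
    if min_distance <= ref_q:
        decision = "same-lineage"
    elif min_distance > ref_max and _positive_margin(means, nearest):
        decision = "novel"
    else:
        decision = "ambiguous"
    return Assignment(
        focal=focal,
        nearest_lineage=nearest,
        decision=decision,
        min_distance=min_distance,
        reference_quantile=ref_q,
        reference_max=ref_max,
        q=q,
        lineage_means=means,
    )


def _positive_margin(means: Mapping[str, float], nearest: str) -> bool:
    others = [v for sp, v in means.items() if sp != nearest]
    return (not others) or min(others) > means[nearest]


def plot_hierarchy(hierarchy: DistanceHierarchy, path=None):
    """Optional strip plot of the three distance strata."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    strata = [
        ("focal vs each", [d.value for d in hierarchy.focal_vs_each]),
        ("within species", [d.value for d in hierarchy.within_species]),
        ("between species", [d.value for d in hierarchy.between_species]),
    ]
    rng = np.random.default_rng(0)
    for x, (label, vals) in enumerate(strata):
        jitter = rng.uniform(-0.08, 0.08, size=len(vals))
        ax.scatter(np.full(len(vals), x) + jitter, vals, s=14, alpha=0.7)
    ax.set_xticks(range(len(strata)), [s[0] for s in strata])
    ax.set_ylabel("normalized genetic distance")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
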