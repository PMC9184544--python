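"""Genotype-matrix site filtering, LD pruning, and PCA.

The path mirrors a standard population-structure workflow: keep biallelic
SNVs with a minimum minor-allele count, no missing genotypes, and a mean
depth within one standard deviation of the across-site mean; prune linked
variants with a 50 kb sliding window, a step of 5 loci and an r^2 ceiling
of 0.5; then run PCA on dosages standardized by sqrt(2 p (1 - p)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantRecord:
    """Biallelic SNV in internal coordinates (0-based position)."""

    contig: str
    pos0: int
    ref: str
    alt: str


@dataclass
class GenotypeMatrix:
    """Dosage matrix (variants x samples) with per-genotype DP and GQ.

    Dosage counts alternate-allele copies (0/1/2); -1 marks a missing
    genotype.  Positions are strictly increasing within each contig.
    """

    samples: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray  # int8, shape (n_variants, n_samples), -1 missing
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.variants), len(self.samples)):
            raise ValueError("dosage shape must be (n_variants, n_samples)")
        if self.dosage.size and (self.dosage.max() > 2 or self.dosage.min() < -1):
            raise ValueError("dosages must be in {-1, 0, 1, 2}")
        last: dict[str, int] = {}
        for v in self.variants:
            if v.contig in last and v.pos0 <= last[v.contig]:
                raise ValueError("positions must be strictly increasing within contig")
            last[v.contig] = v.pos0

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, rows: np.ndarray) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        idx = np.flatnonzero(rows) if rows.dtype == bool else rows
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[int(i)] for i in idx],
            dosage=self.dosage[idx],
            dp=None if self.dp is None else self.dp[idx],
            gq=None if self.gq is None else self.gq[idx],
        )


def minor_allele_counts(dosage: np.ndarray) -> np.ndarray:
    """Per-site minor allele count over non-missing genotypes."""
    valid = dosage >= 0
    alt = np.where(valid, dosage, 0).sum(axis=1)
    total = 2 * valid.sum(axis=1)
    return np.minimum(alt, total - alt)


def site_filter(
    gm: GenotypeMatrix,
    min_mac: int = 1,
    max_missing: int = 0,
    depth_band: float = 1.0,
) -> GenotypeMatrix:
    """Keep sites with MAC >= min_mac, at most ``max_missing`` missing
    genotypes (default none), and mean depth within ``depth_band``
    standard deviations of the across-site mean depth.

    The depth band is computed over all input sites before any other
    criterion is applied.  An empty result is returned (with a warning)
    rather than raised.
    """
    if gm.n_variants == 0:
        return gm
    missing = (gm.dosage == -1).sum(axis=1)
    keep = missing <= max_missing
    keep &= minor_allele_counts(gm.dosage) >= min_mac
    if gm.dp is not None and depth_band is not None:
        site_depth = gm.dp.mean(axis=1)
        mu, sd = site_depth.mean(), site_depth.std()
        keep &= np.abs(site_depth - mu) <= depth_band * sd
    out = gm.subset(keep)
    log.info("site_filter: retained %d of %d sites", out.n_variants, gm.n_variants)
    if out.n_variants == 0:
        warnings.warn("site_filter retained no sites", stacklevel=2)
    return out


def _imputed(dosage: np.ndarray) -> np.ndarray:
    """Float dosage with missing genotypes mean-imputed per variant."""
    X = dosage.astype(float)
    miss = dosage < 0
    if miss.any():
        with np.errstate(invalid="ignore"):
            means = np.where(
                (~miss).sum(axis=1) > 0,
                np.where(miss, 0, X).sum(axis=1) / np.maximum((~miss).sum(axis=1), 1),
                0.0,
            )
        X[miss] = np.broadcast_to(means[:, None], X.shape)[miss]
    return X


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation; 0 when either vector is constant."""
    xc = x - x.mean()
    yc = y - y.mean()
    denom = (xc @ xc) * (yc @ yc)
    if denom == 0:
        return 0.0
    return float((xc @ yc) ** 2 / denom)


def ld_prune(
    gm: GenotypeMatrix,
    window_bp: int = 50_000,
    step_variants: int = 5,
    r2_max: float = 0.5,
) -> list[int]:
    """Greedy sliding-window LD pruning; returns kept variant row indices.

    Within each window (all kept variants within ``window_bp`` of the
    window's first variant, per contig), while any pair of dosage vectors
    has r^2 > ``r2_max`` the member with the lower minor-allele frequency
    is removed (tie: the higher position).  Pairs are examined in
    position order; because r^2 between two fixed vectors never changes,
    pairs already found compliant are not re-examined after a removal,
    which yields the same result as restarting the scan.  The window
    start slides by ``step_variants`` kept variants and whole sweeps
    repeat until no window removes anything.  The outcome depends only on
    positions and dosages, never on sample order.
    """
    X = _imputed(gm.dosage)
    # standardize rows to unit vectors so r^2 = (z_i . z_j)^2
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    Z = np.divide(Xc, norms[:, None], out=np.zeros_like(Xc), where=norms[:, None] > 0)
    mac = minor_allele_counts(gm.dosage)
    pos = np.array([v.pos0 for v in gm.variants])
    contigs = np.array([v.contig for v in gm.variants])
    kept = np.ones(gm.n_variants, dtype=bool)

    def prune_window(idx: np.ndarray) -> bool:
        w = len(idx)
        high = (Z[idx] @ Z[idx].T) ** 2 > r2_max
        np.fill_diagonal(high, False)
        alive = np.ones(w, dtype=bool)
        removed_any = False
        for a in range(w):
            if not alive[a]:
                continue
            while alive[a]:
                cand = np.flatnonzero(high[a] & alive)
                cand = cand[cand > a]
                if cand.size == 0:
                    break
                b = int(cand[0])
                i, j = int(idx[a]), int(idx[b])
                # drop the lower-MAF member; tie -> higher position
                drop = a if (mac[i] < mac[j] or (mac[i] == mac[j] and pos[i] > pos[j])) else b
                alive[drop] = False
                kept[idx[drop]] = False
                removed_any = True
        return removed_any

    stable = False
    while not stable:
        stable = True
        for contig in dict.fromkeys(contigs):  # preserve input order
            in_contig = contigs == contig
            start = 0
            while True:
                rows_alive = np.flatnonzero(in_contig & kept)
                if start >= len(rows_alive):
                    break
                w0 = pos[rows_alive[start]]
                sel = (pos[rows_alive] >= w0) & (pos[rows_alive] < w0 + window_bp)
                window = rows_alive[sel]
                if len(window) > 1 and prune_window(window):
                    stable = False
                start += step_variants
    kept_idx = [int(i) for i in np.flatnonzero(kept)]
    log.info("ld_prune: kept %d of %d variants", len(kept_idx), gm.n_variants)
    return kept_idx


@dataclass
class PCAResult:
    """Sample coordinates, eigenvalues and variance explained."""

    samples: list[str]
    coordinates: np.ndarray  # (n_samples, k)
    eigenvalues: np.ndarray  # all nonzero axes
    variance_explained: np.ndarray  # percentages, all axes, sums to 100
    loadings: np.ndarray | None = None  # (n_variants, k)


def pca(gm: GenotypeMatrix, k: int = 10, scale: str = "binom") -> PCAResult:
    """PCA of the standardized dosage matrix.

    Each variant is mean-centered and, with ``scale="binom"``, divided by
    sqrt(2 p (1 - p)) with p the observed alternate-allele frequency
    (standard genotype-PCA practice); ``scale="unit"`` divides by the
    sample standard deviation instead.  Axes are ordered by decreasing
    eigenvalue; each axis' sign is fixed so its largest-magnitude variant
    loading is positive.  ``k`` beyond the matrix rank is truncated with a
    warning.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if gm.n_variants < 1:
        raise ValueError("need at least 1 variant")
    X = _imputed(gm.dosage)  # (m, n)
    p_hat = X.mean(axis=1) / 2.0
    if scale == "binom":
        denom = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    elif scale == "unit":
        denom = X.std(axis=1)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    informative = denom > 0
    Z = (X[informative] - 2.0 * p_hat[informative, None]) / denom[informative, None]
    # samples x variants, columns centered by construction
    Zt = Z.T
    U, S, Vt = np.linalg.svd(Zt, full_matrices=False)
    tol = S.max(initial=0.0) * max(Zt.shape) * np.finfo(float).eps
    rank = int((S > tol).sum())
    if k > rank:
        warnings.warn(f"k={k} exceeds rank {rank}; truncating", stacklevel=2)
        k = rank
    eigenvalues = S[:rank] ** 2 / Z.shape[0]
    var_exp = 100.0 * (S[:rank] ** 2) / (S**2).sum()
    coords = U[:, :k] * S[:k]
    load = Vt[:k].T
    # sign convention: largest-magnitude loading positive per axis
    for axis in range(k):
        j = int(np.argmax(np.abs(load[:, axis])))
        if load[j, axis] < 0:
            load[:, axis] *= -1
            coords[:, axis] *= -1
    return PCAResult(
        samples=list(gm.samples),
        coordinates=coords,
        eigenvalues=eigenvalues,
        variance_explained=var_exp,
        loadings=load,
    )


def plot_pca(result: PCAResult, species: dict[str, str] | None = None, path=None, axes=(0, 1)):
    """Optional scatter of two PCA axes, colored by species label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    i, j = axes
    if species:
        for sp in sorted(set(species.values())):
            rows = [r for r, s in enumerate(result.samples) if species[s] == sp]
            ax.scatter(result.coordinates[rows, i], result.coordinates[rows, j], label=sp, s=30)
        ax.legend(fontsize=7)
    else:
        ax.scatter(result.coordinates[:, i], result.coordinates[:, j], s=30)
    ax.set_xlabel(f"PC{i+1} ({result.variance_explained[i]:.1f}%)")
    ax.set_ylabel(f"PC{j+1} ({result.variance_explained[j]:.1f}%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
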