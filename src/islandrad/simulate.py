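"""Synthetic island-radiation generator.

The generator produces the statistical structure the downstream analysis
assumes, without any external data: a recent multi-species radiation with
short internal branches, per-species heterozygosity, incomplete lineage
sorting (ILS), pseudo-random allele selection at heterozygous sites, contig
structure, and runs of missing bases typical of a degraded museum specimen.

Model, in full:

* an ancestral sequence is drawn per contig from the configured base
  composition and evolved down the rooted species tree under JC69 with the
  given branch lengths (expected substitutions per site);
* ILS is emulated block-wise: each contig is tiled into fixed-length
  recombination blocks and, independently per block with probability
  ``p_ils``, the species topology is replaced by one random
  nearest-neighbor interchange of a uniformly chosen internal edge before
  that block is evolved;
* within each species, each individual's two haplotypes differ
  independently per site with probability ``theta`` (expected per-site
  heterozygosity);
* missing data are laid down as geometric-length runs of uncallable sites
  with a configurable stationary rate, mimicking patchy coverage of a
  degraded specimen.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from islandrad.qc import decode_sequence, encode_sequence
from islandrad.structure import GenotypeMatrix, VariantRecord


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------


class _Node:
    """Rooted tree node used for sequence evolution."""

    __slots__ = ("name", "length", "children")

    def __init__(self, name: str | None, length: float, children: list["_Node"]):
        self.name = name
        self.length = length
        self.children = children

    def copy(self) -> "_Node":
        return _Node(self.name, self.length, [c.copy() for c in self.children])

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:g}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:g}"


def _parse_rooted(newick: str) -> _Node:
    dt = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)

    def conv(node) -> _Node:
        length = float(node.edge.length) if node.edge.length is not None else 0.0
        if node.is_leaf():
            return _Node(node.taxon.label, length, [])
        return _Node(None, length, [conv(c) for c in node.child_nodes()])

    return conv(dt.seed_node)


@dataclass
class SpeciesTreeSpec:
    """Rooted binary species tree plus per-species diversity and sampling.

    ``newick`` carries branch lengths in expected substitutions per site;
    ``theta`` is the expected per-site heterozygosity of each species and
    ``n_individuals`` how many diploid individuals to sample from it.
    """

    newick: str
    theta: Mapping[str, float]
    n_individuals: Mapping[str, int]

    def __post_init__(self) -> None:
        root = _parse_rooted(self.newick)
        leaves = root.leaves()
        if len(set(leaves)) != len(leaves):
            raise ConfigurationError("species labels must be unique")
        if set(leaves) != set(self.theta) or set(leaves) != set(self.n_individuals):
            raise ConfigurationError("theta and n_individuals must cover exactly the tree's species")
        for sp, th in self.theta.items():
            if not (0.0 <= th < 0.75):
                raise ConfigurationError(f"theta for {sp} must be in [0, 0.75)")
        for sp, n in self.n_individuals.items():
            if n < 1:
                raise ConfigurationError(f"n_individuals for {sp} must be >= 1")
        stack = [root]
        while stack:
            node = stack.pop()
            if node.length < 0:
                raise ConfigurationError("branch lengths must be nonnegative")
            stack.extend(node.children)

    @property
    def species(self) -> list[str]:
        return _parse_rooted(self.newick).leaves()

    def root(self) -> _Node:
        return _parse_rooted(self.newick)


@dataclass
class SimulationConfig:
    """Full description of one synthetic radiation."""

    tree: SpeciesTreeSpec
    contig_lengths: Mapping[str, int]
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    p_ils: float = 0.0
    ils_block_bp: int = 50_000
    missing_rate: float = 0.0
    missing_run_mean: float = 500.0
    depth_mean: float = 20.0
    gq_mean: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.base_composition), 1.0, abs_tol=1e-9):
            raise ConfigurationError("base composition must sum to 1")
        if any(p < 0 for p in self.base_composition):
            raise ConfigurationError("base composition probabilities must be nonnegative")
        if not (0.0 <= self.p_ils <= 1.0):
            raise ConfigurationError("p_ils must be in [0, 1]")
        if any(int(v) <= 0 for v in self.contig_lengths.values()):
            raise ConfigurationError("contig lengths must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing rate must be in [0, 1)")
        if self.ils_block_bp <= 0:
            raise ConfigurationError("ils_block_bp must be positive")


@dataclass
class DiploidGenomeSet:
    """Two haplotypes plus a callability mask per individual and contig.

    Haplotypes are uint8 code arrays (A=0..T=3) in reference coordinates;
    ``reference`` holds the ancestral root sequence of each contig, which
    plays the role of the reference assembly.
    """

    individuals: list[str]
    species: dict[str, str]  # individual -> species label
    contigs: dict[str, int]  # contig -> length
    reference: dict[str, np.ndarray]
    haplotypes: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]
    mask: dict[str, dict[str, np.ndarray]]  # True = callable

    def realized_heterozygosity(self, individual: str) -> float:
        """Fraction of sites (all sites) where the two haplotypes differ."""
        het = total = 0
        for contig in self.contigs:
            h1, h2 = self.haplotypes[individual][contig]
            het += int((h1 != h2).sum())
            total += h1.size
        return het / total


@dataclass
class TruthRecord:
    """Ground truth of one simulation, serializable and re-loadable."""

    species_newick: str
    theta: dict[str, float]
    true_heterozygosity: dict[str, float]  # realized per individual
    expected_divergence: dict[tuple[str, str], float]  # species pair -> expected mismatch
    block_topologies: dict[str, list[tuple[int, int, str]]]  # contig -> (start, end, newick)

    def discordant_fraction(self, species_newick_of_block: str) -> bool:
        return species_newick_of_block != self.species_newick


# ---------------------------------------------------------------------------
# core simulation
# ---------------------------------------------------------------------------


def _jc69_mutate(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """One JC69 branch: each site changes with prob (3/4)(1 - e^{-4t/3}),
    to a uniformly chosen different base."""
    out = seq.copy()
    if t <= 0:
        return out
    p = 0.75 * -math.expm1(-4.0 * t / 3.0)
    hit = rng.random(seq.size) < p
    k = int(hit.sum())
    if k:
        out[hit] = (out[hit] + rng.integers(1, 4, size=k)) % 4
    return out


def _rooted_nni(root: _Node, rng: np.random.Generator) -> _Node:
    """One NNI at a uniformly chosen internal edge of a copy of ``root``.

    An internal edge connects an internal non-root node to its parent; the
    move swaps one of the node's children with the node's sibling.
    """
    root = root.copy()
    edges: list[tuple[_Node, int]] = []  # (parent, child index) with internal child
    stack = [root]
    while stack:
        node = stack.pop()
        for i, child in enumerate(node.children):
            if child.children:
                edges.append((node, i))
            stack.append(child)
    if not edges:
        return root
    parent, ci = edges[int(rng.integers(len(edges)))]
    child = parent.children[ci]
    si = 1 - ci if len(parent.children) == 2 else int(rng.integers(len(parent.children)))
    while si == ci:
        si = int(rng.integers(len(parent.children)))
    gi = int(rng.integers(len(child.children)))
    parent.children[si], child.children[gi] = child.children[gi], parent.children[si]
    return root


def _evolve_block(anc: np.ndarray, root: _Node, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Evolve an ancestral block down a rooted tree; returns tip sequences."""
    tips: dict[str, np.ndarray] = {}

    def descend(node: _Node, seq: np.ndarray) -> None:
        seq = _jc69_mutate(seq, node.length, rng)
        if not node.children:
            tips[node.name] = seq
        else:
            for child in node.children:
                descend(child, seq)

    descend(root, anc)
    return tips


def _run_mask(length: int, rate: float, run_mean: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean array, True = missing, from an alternating renewal process.

    Missing runs are Geometric on {1, 2, ...} with mean ``run_mean``;
    callable gaps are Geometric on {0, 1, ...} with mean
    ``run_mean * (1 - rate) / rate`` (a zero-length gap merges adjacent
    runs), so the stationary missing fraction is exactly ``rate`` and the
    degenerate case ``run_mean = 1`` reduces to independent Bernoulli
    missingness.
    """
    if rate <= 0:
        return np.zeros(length, dtype=bool)
    gap_mean = run_mean * (1.0 - rate) / rate
    p_run = min(1.0, 1.0 / run_mean)
    p_gap = 1.0 / (gap_mean + 1.0)
    miss = np.zeros(length, dtype=bool)
    pos = 0
    in_run = bool(rng.random() < rate)
    while pos < length:
        if in_run:
            ln = int(rng.geometric(p_run))
            miss[pos : pos + ln] = True
            pos += ln
        else:
            pos += int(rng.geometric(p_gap)) - 1  # support {0, 1, ...}
        in_run = not in_run
    return miss


def simulate(config: SimulationConfig) -> tuple[DiploidGenomeSet, TruthRecord]:
    """Run the generator; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    root = config.tree.root()
    species = root.leaves()
    individuals = [
        f"{sp}_{k}" for sp in species for k in range(1, config.tree.n_individuals[sp] + 1)
    ]
    species_of = {ind: ind.rsplit("_", 1)[0] for ind in individuals}
    contigs = {c: int(v) for c, v in config.contig_lengths.items()}
    base_p = np.asarray(config.base_composition, dtype=float)
    base_p = base_p / base_p.sum()

    reference: dict[str, np.ndarray] = {}
    haplotypes: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {ind: {} for ind in individuals}
    mask: dict[str, dict[str, np.ndarray]] = {ind: {} for ind in individuals}
    block_topologies: dict[str, list[tuple[int, int, str]]] = {}
    species_newick = root.newick() + ";"

    for contig, clen in contigs.items():
        anc = rng.choice(4, size=clen, p=base_p).astype(np.uint8)
        reference[contig] = anc
        tips = {sp: np.empty(clen, dtype=np.uint8) for sp in species}
        blocks: list[tuple[int, int, str]] = []
        for start in range(0, clen, config.ils_block_bp):
            end = min(start + config.ils_block_bp, clen)
            topo = root
            if config.p_ils > 0 and rng.random() < config.p_ils:
                topo = _rooted_nni(root, rng)
            blocks.append((start, end, topo.newick() + ";"))
            block_tips = _evolve_block(anc[start:end], topo, rng)
            for sp in species:
                tips[sp][start:end] = block_tips[sp]
        block_topologies[contig] = blocks
        for ind in individuals:
            sp = species_of[ind]
            theta = config.tree.theta[sp]
            h1 = tips[sp].copy()
            h2 = h1.copy()
            if theta > 0:
                hit = rng.random(clen) < theta
                k = int(hit.sum())
                if k:
                    h2[hit] = (h2[hit] + rng.integers(1, 4, size=k)) % 4
            haplotypes[ind][contig] = (h1, h2)
            mask[ind][contig] = ~_run_mask(clen, config.missing_rate, config.missing_run_mean, rng)

    genomes = DiploidGenomeSet(
        individuals=individuals,
        species=species_of,
        contigs=contigs,
        reference=reference,
        haplotypes=haplotypes,
        mask=mask,
    )
    truth = TruthRecord(
        species_newick=species_newick,
        theta=dict(config.tree.theta),
        true_heterozygosity={ind: genomes.realized_heterozygosity(ind) for ind in individuals},
        expected_divergence=_expected_divergences(root),
        block_topologies=block_topologies,
    )
    return genomes, truth


def _expected_divergences(root: _Node) -> dict[tuple[str, str], float]:
    """JC69 expected mismatch per species pair from tree path lengths."""
    depths: dict[str, float] = {}
    paths: dict[tuple[str, str], float] = {}

    def collect(node: _Node, depth: float) -> list[tuple[str, float]]:
        depth += node.length
        if not node.children:
            depths[node.name] = depth
            return [(node.name, depth)]
        groups = [collect(c, depth) for c in node.children]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                for a, da in groups[i]:
                    for b, db in groups[j]:
                        key = tuple(sorted((a, b)))
                        path = (da - depth) + (db - depth)
                        paths[key] = 0.75 * -math.expm1(-4.0 * path / 3.0)
        return [x for g in groups for x in g]

    collect(root, -root.length)  # root edge does not separate any pair
    return paths


# ---------------------------------------------------------------------------
# pseudo-haploidization and missingness
# ---------------------------------------------------------------------------


def pseudo_haploidize(genomes: DiploidGenomeSet, seed: int) -> dict[str, dict[str, str]]:
    """One sequence per individual per contig from the diploid genotypes.

    Homozygous sites emit the shared base; heterozygous sites emit one of
    the two alleles by a seeded fair coin (modelling the read-count tie of
    a majority-read rule at a balanced heterozygous site); uncallable sites
    emit N.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, str]] = {}
    for ind in genomes.individuals:
        out[ind] = {}
        for contig in genomes.contigs:
            h1, h2 = genomes.haplotypes[ind][contig]
            coin = rng.random(h1.size) < 0.5
            seq = np.where(coin, h1, h2)
            seq = np.where(genomes.mask[ind][contig], seq, np.uint8(4))
            out[ind][contig] = decode_sequence(seq.astype(np.uint8))
    return out


def apply_missingness(
    sequences: Mapping[str, Mapping[str, str]],
    rate: float,
    run_length: float,
    seed: int,
) -> dict[str, dict[str, str]]:
    """Overlay geometric-length runs of N at stationary fraction ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, str]] = {}
    for ind in sorted(sequences):
        out[ind] = {}
        for contig in sequences[ind]:
            seq = sequences[ind][contig]
            if rate == 0:
                out[ind][contig] = seq
                continue
            codes = encode_sequence(seq)
            miss = _run_mask(codes.size, rate, run_length, rng)
            codes[miss] = 4
            out[ind][contig] = decode_sequence(codes)
    return out


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def genotype_matrix(
    genomes: DiploidGenomeSet,
    depth_mean: float = 20.0,
    gq_mean: float = 45.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Diploid genotype calls at every biallelic variant site.

    A site is variant when any callable haplotype differs from the
    reference (ancestral) base.  Sites with more than one alternate allele
    among callable haplotypes are skipped (the VCF dialect is biallelic
    SNVs only).  Per-genotype depth and genotype quality are drawn from
    Poisson distributions with the given means so downstream DP/GQ filters
    are exercisable; uncallable genotypes are missing with DP = GQ = 0.
    """
    rng = np.random.default_rng(seed)
    inds = genomes.individuals
    n = len(inds)
    variants: list[VariantRecord] = []
    dosage_cols: list[np.ndarray] = []
    bases = "ACGT"
    for contig in genomes.contigs:
        ref = genomes.reference[contig]
        H = np.vstack(
            [genomes.haplotypes[ind][contig][h] for ind in inds for h in (0, 1)]
        )  # (2n, L)
        M = np.vstack([genomes.mask[ind][contig] for ind in inds])  # (n, L)
        M2 = np.repeat(M, 2, axis=0)
        diff = (H != ref[None, :]) & M2
        cols = np.flatnonzero(diff.any(axis=0))
        if cols.size == 0:
            continue
        Hc = H[:, cols]
        Mc = M2[:, cols]
        refc = ref[cols]
        vals = np.where(Mc & (Hc != refc[None, :]), Hc.astype(np.int16), np.int16(-1))
        alt = vals.max(axis=0)
        multi = ((vals != -1) & (vals != alt[None, :])).any(axis=0)
        keep = ~multi
        cols, Hc, refc, alt = cols[keep], Hc[:, keep], refc[keep], alt[keep]
        Mk = M[:, np.flatnonzero(diff.any(axis=0))][:, keep]
        h1 = Hc[0::2]
        h2 = Hc[1::2]
        dos = (h1 == alt[None, :]).astype(np.int8) + (h2 == alt[None, :]).astype(np.int8)
        dos[~Mk] = -1
        for k, c in enumerate(cols):
            variants.append(VariantRecord(contig, int(c), bases[refc[k]], bases[alt[k]]))
            dosage_cols.append(dos[:, k])
    if variants:
        dosage = np.vstack(dosage_cols)  # (n_variants, n_samples)
    else:
        dosage = np.empty((0, n), dtype=np.int8)
    dp = rng.poisson(depth_mean, size=dosage.shape).astype(np.int32)
    gq = np.minimum(rng.poisson(gq_mean, size=dosage.shape), 99).astype(np.int32)
    missing = dosage == -1
    dp[missing] = 0
    gq[missing] = 0
    return GenotypeMatrix(samples=list(inds), variants=variants, dosage=dosage, dp=dp, gq=gq)


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------


def export(
    genomes: DiploidGenomeSet,
    truth: TruthRecord,
    outdir: str | Path,
    seed: int = 0,
    depth_mean: float = 20.0,
    gq_mean: float = 45.0,
) -> dict[str, Path]:
    """Write the dataset as plain-text files; re-importable round trip.

    Emits one pseudo-haploid FASTA per individual, a VCF of biallelic
    variant sites with GT:DP:GQ, a species-label TSV, the truth species
    tree (Newick) and truth tables (TSV).
    """
    from islandrad import ioutils  # local import: ioutils imports structure only

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    pseudo = pseudo_haploidize(genomes, seed)
    for ind in genomes.individuals:
        p = outdir / f"{ind}.fa"
        ioutils.write_fasta(pseudo[ind], p)
        paths[f"fasta:{ind}"] = p
    gm = genotype_matrix(genomes, depth_mean=depth_mean, gq_mean=gq_mean, seed=seed + 1)
    paths["vcf"] = outdir / "variants.vcf"
    ioutils.write_vcf(gm, paths["vcf"], contig_lengths=genomes.contigs)
    paths["labels"] = outdir / "labels.tsv"
    with open(paths["labels"], "w") as fh:
        fh.write("individual\tspecies\n")
        for ind in genomes.individuals:
            fh.write(f"{ind}\t{genomes.species[ind]}\n")
    paths["truth_tree"] = outdir / "truth_species_tree.nwk"
    paths["truth_tree"].write_text(truth.species_newick + "\n")
    paths["truth_het"] = outdir / "truth_heterozygosity.tsv"
    with open(paths["truth_het"], "w") as fh:
        fh.write("individual\ttheta\ttrue_heterozygosity\n")
        for ind in genomes.individuals:
            th = truth.theta[genomes.species[ind]]
            fh.write(f"{ind}\t{th:.10g}\t{truth.true_heterozygosity[ind]:.10g}\n")
    paths["truth_divergence"] = outdir / "truth_divergence.tsv"
    with open(paths["truth_divergence"], "w") as fh:
        fh.write("species_a\tspecies_b\texpected_mismatch\n")
        for (a, b), p in sorted(truth.expected_divergence.items()):
            fh.write(f"{a}\t{b}\t{p:.10g}\n")
    paths["truth_blocks"] = outdir / "truth_blocks.tsv"
    with open(paths["truth_blocks"], "w") as fh:
        fh.write("contig\tstart\tend\ttopology\n")
        for contig, blocks in truth.block_topologies.items():
            for start, end, nwk in blocks:
                fh.write(f"{contig}\t{start}\t{end}\t{nwk}\n")
    return paths


@dataclass
class ImportedDataset:
    """Round-trip view of an exported dataset."""

    sequences: dict[str, dict[str, str]]  # pseudo-haploid
    genotypes: GenotypeMatrix
    labels: dict[str, str]
    truth_newick: str
    truth_het: dict[str, tuple[float, float]]  # individual -> (theta, realized)
    truth_divergence: dict[tuple[str, str], float]
    truth_blocks: dict[str, list[tuple[int, int, str]]]


def import_dataset(outdir: str | Path) -> ImportedDataset:
    """Load everything written by :func:`export`."""
    from islandrad import ioutils

    outdir = Path(outdir)
    labels: dict[str, str] = {}
    for line in (outdir / "labels.tsv").read_text().splitlines()[1:]:
        ind, sp = line.split("\t")
        labels[ind] = sp
    sequences = {ind: ioutils.read_fasta(outdir / f"{ind}.fa") for ind in labels}
    gm = ioutils.read_vcf(outdir / "variants.vcf")
    truth_newick = (outdir / "truth_species_tree.nwk").read_text().strip()
    truth_het = {}
    for line in (outdir / "truth_heterozygosity.tsv").read_text().splitlines()[1:]:
        ind, th, realized = line.split("\t")
        truth_het[ind] = (float(th), float(realized))
    truth_divergence = {}
    for line in (outdir / "truth_divergence.tsv").read_text().splitlines()[1:]:
        a, b, p = line.split("\t")
        truth_divergence[(a, b)] = float(p)
    truth_blocks: dict[str, list[tuple[int, int, str]]] = {}
    for line in (outdir / "truth_blocks.tsv").read_text().splitlines()[1:]:
        contig, start, end, nwk = line.split("\t")
        truth_blocks.setdefault(contig, []).append((int(start), int(end), nwk))
    return ImportedDataset(
        sequences=sequences,
        genotypes=gm,
        labels=labels,
        truth_newick=truth_newick,
        truth_het=truth_het,
        truth_divergence=truth_divergence,
        truth_blocks=truth_blocks,
    )
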