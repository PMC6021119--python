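"""SNP genotype matrices, identity-by-state distances and UPGMA clustering.

Genotypes are diploid biallelic dosages (count of alternate alleles, 0/1/2;
-1 marks a missing call). Filtering is site-wise complete-case: a site with
any missing call among the retained samples is dropped, then monomorphic
sites are removed. Two pairwise distances are offered:

* identity-by-state distance GD = 1 - IBS, with per-site allele sharing
  IBS = 1 - |d_a - d_b| / 2;
* Hamming (bitwise) distance, the mean per-site fraction of differing
  allele copies |d_a - d_b| / 2.

For dosage data these coincide; both are kept because published pipelines
report GD from one tool and cluster on the other. Clustering is UPGMA
(average linkage) with node height equal to half the between-cluster
average distance, deterministic lexicographic tie-breaking, and optional
bootstrap supports from resampling loci with replacement.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from skbio.tree import TreeNode

MISSING = -1


@dataclass
class SnpMatrix:
    """Samples x sites matrix of alternate-allele dosages."""

    samples: tuple[str, ...]
    sites: pd.DataFrame  # columns chrom, pos, ref, alt
    dosages: np.ndarray  # (n_samples, n_sites) int8; -1 = missing
    skipped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.samples = tuple(self.samples)
        if self.dosages.shape != (len(self.samples), len(self.sites)):
            raise ValueError("dosage matrix shape inconsistent with samples/sites")
        if (self.sites["pos"] <= 0).any():
            raise ValueError("site positions must be 1-based positive")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset_samples(self, ids: list[str]) -> "SnpMatrix":
        missing = [s for s in ids if s not in self.samples]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}; available: {list(self.samples)}")
        rows = [self.samples.index(s) for s in ids]
        return SnpMatrix(tuple(ids), self.sites.copy(), self.dosages[rows], dict(self.skipped))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal."""

    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        self.ids = tuple(self.ids)
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        np.fill_diagonal(m, 0.0)
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.ids), columns=list(self.ids))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))


def read_vcf(path, samples: list[str] | None = None) -> SnpMatrix:
    """Load biallelic SNP dosages for a sample subset from a VCF.

    Multi-allelic records and non-SNP variants (indels, symbolic alleles)
    are skipped and counted in ``skipped``. Genotypes map to dosage via the
    number of alternate alleles; any unresolvable call is missing.
    """
    vcf = VCF(str(path))
    available = list(vcf.samples)
    if samples is not None:
        absent = [s for s in samples if s not in available]
        if absent:
            raise KeyError(f"samples not in VCF: {absent}; available: {available}")
        vcf = VCF(str(path), samples=samples)
        order = list(vcf.samples)
    else:
        order = available

    rows = []
    dosage_cols = []
    skipped = {"multiallelic": 0, "non_snp": 0, "malformed": 0}
    for var in vcf:
        if len(var.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if not var.is_snp:
            skipped["non_snp"] += 1
            continue
        try:
            gts = var.genotypes  # [[a0, a1, phased], ...]
            col = np.full(len(order), MISSING, dtype=np.int8)
            for k, gt in enumerate(gts):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    continue
                col[k] = sum(1 for a in alleles if a > 0)
        except Exception:
            skipped["malformed"] += 1
            continue
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        dosage_cols.append(col)

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosages = (
        np.stack(dosage_cols, axis=1) if dosage_cols else np.zeros((len(order), 0), np.int8)
    )
    return SnpMatrix(tuple(order), sites, dosages, skipped)


def filter_sites(m: SnpMatrix) -> SnpMatrix:
    """Complete-case polymorphic filtering, preserving site order.

    Drops every site with at least one missing call among the retained
    samples, then every site at which all samples share the same dosage.
    """
    if m.n_sites == 0:
        raise ValueError("empty SNP matrix")
    complete = (m.dosages != MISSING).all(axis=0)
    d = m.dosages[:, complete]
    polymorphic = (d != d[0]).any(axis=0)
    keep = np.flatnonzero(complete)[polymorphic]
    if keep.size == 0:
        raise ValueError("no sites survive missing-data and polymorphism filters")
    filt = SnpMatrix(
        m.samples,
        m.sites.iloc[keep].reset_index(drop=True),
        m.dosages[:, keep],
        dict(m.skipped),
    )
    filt.skipped["missing_call"] = int((~complete).sum())
    filt.skipped["monomorphic"] = int((~polymorphic).sum())
    return filt


def _pairwise_mean_allele_diff(dosages: np.ndarray) -> np.ndarray:
    d = dosages.astype(float)
    if (d < 0).any():
        raise ValueError("missing calls present; run filter_sites first")
    diff = np.abs(d[:, None, :] - d[None, :, :]) / 2.0
    return diff.mean(axis=2)


def ibs_distance(m: SnpMatrix) -> DistanceMatrix:
    """GD = 1 - IBS with per-site allele sharing IBS = 1 - |d_a - d_b|/2."""
    if m.n_sites == 0:
        raise ValueError("no sites")
    ibs = 1.0 - np.abs(
        m.dosages.astype(float)[:, None, :] - m.dosages.astype(float)[None, :, :]
    ) / 2.0
    if (m.dosages < 0).any():
        raise ValueError("missing calls present; run filter_sites first")
    return DistanceMatrix(m.samples, 1.0 - ibs.mean(axis=2))


def hamming_distance(m: SnpMatrix) -> DistanceMatrix:
    """Mean per-site fraction of differing allele copies |d_a - d_b|/2."""
    if m.n_sites == 0:
        raise ValueError("no sites")
    return DistanceMatrix(m.samples, _pairwise_mean_allele_diff(m.dosages))


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class UpgmaTree:
    """Rooted ultrametric tree with node heights and optional supports."""

    root: TreeNode
    heights: dict[int, float]  # id(node) -> height above leaves
    supports: dict[frozenset, float] | None = None  # clade leafset -> percent

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.root.tips()]

    def height_of(self, node: TreeNode) -> float:
        return self.heights[id(node)]

    def clades(self) -> set[frozenset]:
        """Leaf-name sets of all internal nodes (root included)."""
        out = set()
        for node in self.root.non_tips(include_self=True):
            out.add(frozenset(t.name for t in node.tips()))
        return out

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        root_h = self.height_of(self.root)
        for tip in self.root.tips():
            depth = 0.0
            node = tip
            while node is not self.root:
                depth += node.length
                node = node.parent
            if abs(depth - root_h) > tol:
                return False
        return True


def upgma(d: DistanceMatrix) -> UpgmaTree:
    """Average-linkage agglomeration into an ultrametric rooted tree.

    The pair with the smallest between-cluster average distance merges at a
    node of height d/2; among exactly tied pairs the one whose combined,
    sorted member-id tuple is lexicographically smallest is merged, making
    the tree deterministic.
    """
    n = len(d.ids)
    if n < 2:
        raise ValueError("need at least 2 samples")
    # cluster state: key -> (sorted member names, size, TreeNode, height)
    clusters: dict[int, tuple[tuple[str, ...], int, TreeNode, float]] = {
        k: ((name,), 1, TreeNode(name=name), 0.0) for k, name in enumerate(d.ids)
    }
    dist: dict[frozenset, float] = {
        frozenset((a, b)): float(d.matrix[a, b])
        for a in range(n)
        for b in range(a + 1, n)
    }
    heights: dict[int, float] = {id(node): 0.0 for _, _, node, _ in clusters.values()}
    next_key = n
    while len(clusters) > 1:
        best = None
        for pair, dd in dist.items():
            a, b = sorted(pair)
            tiekey = tuple(sorted(clusters[a][0] + clusters[b][0]))
            cand = (dd, tiekey, a, b)
            if best is None or cand < best:
                best = cand
        dd, _, a, b = best
        mem_a, na, node_a, _ = clusters[a]
        mem_b, nb, node_b, _ = clusters[b]
        h = dd / 2.0
        node_a.length = h - heights[id(node_a)]
        node_b.length = h - heights[id(node_b)]
        if mem_b < mem_a:  # canonical child order: lexicographic member tuples
            node_a, node_b = node_b, node_a
        parent = TreeNode(children=[node_a, node_b])
        heights[id(parent)] = h
        merged = (tuple(sorted(mem_a + mem_b)), na + nb, parent, h)
        del clusters[a], clusters[b]
        new_dist: dict[frozenset, float] = {}
        for pair, val in dist.items():
            if a in pair or b in pair:
                continue
            new_dist[pair] = val
        for k in clusters:
            da = dist[frozenset((a, k))]
            db = dist[frozenset((b, k))]
            new_dist[frozenset((next_key, k))] = (na * da + nb * db) / (na + nb)
        clusters[next_key] = merged
        dist = new_dist
        next_key += 1
    (_, _, root, _) = next(iter(clusters.values()))
    root.length = None
    return UpgmaTree(root=root, heights=heights)


def bootstrap_support(
    m: SnpMatrix,
    b_replicates: int = 1000,
    seed: int | None = None,
    distance: str = "hamming",
) -> UpgmaTree:
    """UPGMA tree with clade supports from resampling loci with replacement.

    Each replicate draws ``n_sites`` site indices with replacement,
    recomputes the distance matrix and its UPGMA tree; the support of an
    internal node of the original tree is the percentage of replicates whose
    tree contains the same leaf set as a clade.
    """
    if b_replicates < 1:
        raise ValueError("need at least 1 bootstrap replicate")
    dist_fn = {"hamming": hamming_distance, "ibs": ibs_distance}[distance]
    tree = upgma(dist_fn(m))
    target = {c: 0 for c in tree.clades()}
    rng = np.random.default_rng(seed)
    for _ in range(b_replicates):
        idx = rng.integers(0, m.n_sites, size=m.n_sites)
        rep = SnpMatrix(m.samples, m.sites.iloc[idx].reset_index(drop=True), m.dosages[:, idx])
        rep_clades = upgma(dist_fn(rep)).clades()
        for c in target:
            if c in rep_clades:
                target[c] += 1
    supports = {c: 100.0 * k / b_replicates for c, k in target.items()}
    # annotate internal node names with integer supports (root left blank)
    for node in tree.root.non_tips(include_self=False):
        leafset = frozenset(t.name for t in node.tips())
        node.name = str(int(round(supports[leafset])))
    tree.supports = supports
    return tree


def write_newick(tree: UpgmaTree, path) -> None:
    """Serialize with branch lengths; supports become internal node labels."""
    tree.root.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    """Parse a Newick file back into a tree (for round-trips and plotting)."""
    return TreeNode.read(str(path), format="newick")


def to_newick_string(tree: UpgmaTree) -> str:
    buf = io.StringIO()
    tree.root.write(buf, format="newick")
    return buf.getvalue().strip()
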