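"""Synthetic half-diallel phenotypes and SNP panels with known ground truth.

The phenotype generator inverts the fixed-effects combining-ability model:
it draws GCA effects g_i ~ N(0, s2_gca), symmetric SCA effects
s_ij ~ N(0, s2_sca) (selfs s_ii from the same distribution), block effects
and residuals, and emits plot observations

    y_ijk = mu + g_i + g_j + s_ij + beta_k + e_ijk     (selfs: mu + 2 g_i + ...)

so every estimator downstream can be checked against the drawn truth. The
SNP generator produces cluster-structured diploid dosage panels: an
ancestral haplotype is perturbed per cluster (between-cluster divergence)
and per sample (within-cluster divergence), with optional residual
heterozygosity and missing calls. Phenotypes and genotypes are simulated
independently, matching an analysis that treats them as separate inputs.

Defaults emulate the study conditions this package targets: a 10-parent,
3-block half-diallel (55 genotypes, 45 hybrids) and a 10-sample panel of
7,335 SNP sites split into one divergent singleton plus a main cluster of
nine, with pairwise distances spanning roughly 0.01-0.04.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genodist import SnpMatrix
from .phenio import DiallelPhenotypeTable, ParentSet, from_dataframe


@dataclass(frozen=True)
class DiallelSimConfig:
    p: int = 10
    b: int = 3
    mu: float = 100.0
    sigma2_gca: float = 4.0
    sigma2_sca: float = 1.0
    sigma2_block: float = 0.5
    sigma2_error: float = 1.0
    traits: tuple[str, ...] = ("sim_trait",)
    # optional per-trait overrides of mu / variances
    trait_overrides: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if self.p < 3:
            raise ValueError("need p >= 3 parents")
        if self.b < 2:
            raise ValueError("need b >= 2 blocks")
        for name in ("sigma2_gca", "sigma2_sca", "sigma2_block", "sigma2_error"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_trait_arrays(
    p: int,
    b: int,
    mu: float,
    sigma2_gca: float,
    sigma2_sca: float,
    sigma2_block: float,
    sigma2_error: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Draw one trait and return the (n_genotypes, b) plot array plus truth.

    Genotypes are ordered canonically (i <= j, row-major over the upper
    triangle), matching the table-level pipeline. Draw order: g, then the
    upper triangle of s (selfs included), then block effects, then
    residuals.
    """
    g = rng.normal(0.0, np.sqrt(sigma2_gca), size=p)
    s = np.zeros((p, p))
    iu = np.triu_indices(p)
    s[iu] = rng.normal(0.0, np.sqrt(sigma2_sca), size=len(iu[0]))
    s = np.triu(s) + np.triu(s, 1).T
    beta = rng.normal(0.0, np.sqrt(sigma2_block), size=b)
    cell = mu + g[:, None] + g[None, :] + s
    geno = cell[iu]  # (n_genotypes,) expected plot means
    eps = rng.normal(0.0, np.sqrt(sigma2_error), size=(len(geno), b))
    y = geno[:, None] + beta[None, :] + eps
    truth = {"mu": mu, "g": g, "s": s, "beta": beta}
    return y, truth


def simulate_diallel(cfg: DiallelSimConfig) -> tuple[DiallelPhenotypeTable, dict]:
    """Simulate a complete half-diallel phenotype table with known effects.

    A single seeded RNG stream drives all draws (trait by trait, in the
    order listed in the config), so equal seeds give identical tables.
    Returns the table and a truth record holding every drawn effect.
    """
    rng = np.random.default_rng(cfg.seed)
    parents = ParentSet(ids=tuple(f"P{k + 1:02d}" for k in range(cfg.p)))
    iu = np.triu_indices(cfg.p)
    frames = []
    truth: dict = {"config": asdict(cfg), "traits": {}}
    for trait in cfg.traits:
        over = cfg.trait_overrides.get(trait, {})
        y, tr = simulate_trait_arrays(
            cfg.p,
            cfg.b,
            over.get("mu", cfg.mu),
            over.get("sigma2_gca", cfg.sigma2_gca),
            over.get("sigma2_sca", cfg.sigma2_sca),
            over.get("sigma2_block", cfg.sigma2_block),
            over.get("sigma2_error", cfg.sigma2_error),
            rng,
        )
        truth["traits"][trait] = tr
        for col, block in enumerate(y.T, start=1):
            frames.append(
                pd.DataFrame(
                    {
                        "parent_a": [parents.ids[i] for i in iu[0]],
                        "parent_b": [parents.ids[j] for j in iu[1]],
                        "block": col,
                        "trait": trait,
                        "value": block,
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    return from_dataframe(df, parents), truth


def write_phenotypes(table: DiallelPhenotypeTable, path) -> None:
    """Write a table back to the long CSV dialect the reader accepts."""
    ids = table.parents.ids
    out = table.data.copy()
    out["parent_a"] = [ids[i] for i in out["i"]]
    out["parent_b"] = [ids[j] for j in out["j"]]
    out[["parent_a", "parent_b", "block", "trait", "value"]].to_csv(path, index=False)


def truth_to_json(truth: dict, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=default)


# ---------------------------------------------------------------------------
# SNP panels


@dataclass(frozen=True)
class SnpSimConfig:
    n_samples: int = 10
    n_sites: int = 7335
    n_clusters: int = 2
    cluster_sizes: tuple[int, ...] | None = (9, 1)
    between_rate: float = 0.015  # per-site flip probability per cluster lineage
    within_rate: float = 0.005  # per-site flip probability per sample
    het_rate: float = 0.01  # residual heterozygous calls
    missing_rate: float = 0.02
    seed: int | None = None

    def __post_init__(self):
        for name in ("between_rate", "within_rate", "het_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_clusters > self.n_samples:
            raise ValueError("more clusters than samples")
        if self.cluster_sizes is not None:
            if len(self.cluster_sizes) != self.n_clusters:
                raise ValueError("cluster_sizes length must equal n_clusters")
            if sum(self.cluster_sizes) != self.n_samples:
                raise ValueError("cluster_sizes must sum to n_samples")

    def sizes(self) -> tuple[int, ...]:
        if self.cluster_sizes is not None:
            return self.cluster_sizes
        base, extra = divmod(self.n_samples, self.n_clusters)
        return tuple(base + (1 if k < extra else 0) for k in range(self.n_clusters))


def simulate_snps(cfg: SnpSimConfig) -> SnpMatrix:
    """Cluster-structured homozygous-dominated diploid dosage panel.

    An ancestral dosage vector (0 or 2 per site) is flipped per cluster at
    ``between_rate`` and per sample at ``within_rate``; ``het_rate`` of
    calls become heterozygous (dosage 1) and ``missing_rate`` become
    missing. Sample ids encode their cluster (``C<k>S<n>``) so truth is
    recoverable from names alone.
    """
    rng = np.random.default_rng(cfg.seed)
    ancestor = rng.choice(np.array([0, 2], dtype=np.int8), size=cfg.n_sites)
    names = []
    rows = []
    for c, size in enumerate(cfg.sizes(), start=1):
        flip_c = rng.random(cfg.n_sites) < cfg.between_rate
        base = np.where(flip_c, 2 - ancestor, ancestor).astype(np.int8)
        for k in range(size):
            flip_s = rng.random(cfg.n_sites) < cfg.within_rate
            dos = np.where(flip_s, 2 - base, base).astype(np.int8)
            het = rng.random(cfg.n_sites) < cfg.het_rate
            dos[het] = 1
            miss = rng.random(cfg.n_sites) < cfg.missing_rate
            dos[miss] = -1
            names.append(f"C{c}S{k + 1:02d}")
            rows.append(dos)
    sites = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, cfg.n_sites + 1) * 100,
            "ref": "A",
            "alt": "G",
        }
    )
    return SnpMatrix(tuple(names), sites, np.stack(rows))


_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(m: SnpMatrix, path) -> None:
    """Emit the matrix as a minimal plain-text VCF v4.2 with GT calls."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(m.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(m.samples) + "\n")
        for col, site in enumerate(m.sites.itertuples(index=False)):
            gts = "\t".join(_GT[int(d)] for d in m.dosages[:, col])
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )
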