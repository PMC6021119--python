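"""Fixed-effects half-diallel analysis: Griffing Method 2, Model 1.

The design crosses ``p`` parents in all unordered pairs including selfs
(one set of F1s, no reciprocals) and grows the ``p(p+1)/2`` genotypes in a
randomized complete block design with ``b`` blocks. The model for the cell
mean of cross i x j is

    x_ij = mu + g_i + g_j + s_ij        (parents: x_ii = mu + 2 g_i + s_ii)

with general combining abilities (GCA) g_i constrained to sum to zero and
specific combining abilities (SCA) s_ij the saturated remainder. All effects
are fixed (Model 1); GCA, SCA, genotype and block mean squares are each
tested against the RCBD error.

Conventions. The row margin ``x_i.`` sums the full symmetric row of the cell
mean matrix with the diagonal counted once, so ``x_i. + x_ii`` counts the
self twice — this is the margin Griffing's Method 2 formulas expect and what
makes SS_GCA + SS_SCA = SS_genotypes an exact identity.

Two layers are provided: array-level functions on the p x p cell-mean matrix
(fast, used by simulations) and table-level wrappers on
:class:`~diallelkit.phenio.DiallelPhenotypeTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phenio import DiallelPhenotypeTable, IncompleteDesignError, ParentSet

__all__ = [
    "GenotypeCellMeans",
    "AnovaRow",
    "DiallelAnova",
    "CombiningAbilities",
    "VarianceComponents",
    "cell_means",
    "rcbd_anova",
    "griffing_partition",
    "estimate_effects",
    "diallel_anova",
    "variance_components",
    "components_from_ms",
    "heritabilities",
    "sca_percent",
    "heterosis",
    "rcbd_ss",
    "griffing_ss",
    "effects_from_means",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeCellMeans:
    """Symmetric p x p matrix of genotype means over blocks for one trait."""

    trait: str
    parents: ParentSet
    matrix: np.ndarray  # (p, p) symmetric
    b: int  # number of blocks averaged over

    @property
    def p(self) -> int:
        return self.matrix.shape[0]

    @property
    def row_margins(self) -> np.ndarray:
        """x_i. — full symmetric row sums, diagonal counted once."""
        return self.matrix.sum(axis=1)

    @property
    def grand_total(self) -> float:
        """x.. — total over the upper triangle including the diagonal."""
        return float(np.triu(self.matrix).sum())


@dataclass(frozen=True)
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: float
    f: float | None = None
    p_value: float | None = None


@dataclass
class DiallelAnova:
    """Per-trait ANOVA with Blocks, Genotypes, GCA, SCA and Error strata."""

    trait: str
    rows: dict[str, AnovaRow]

    def __getitem__(self, source: str) -> AnovaRow:
        return self.rows[source]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows.values()])


@dataclass
class CombiningAbilities:
    """Estimated mu, per-parent GCA and per-pair SCA for one trait."""

    trait: str
    parents: ParentSet
    mu: float
    gca: np.ndarray  # (p,)
    sca: np.ndarray  # (p, p) symmetric, diagonal = s_ii

    def fitted(self) -> np.ndarray:
        """Reconstructed cell means mu + g_i + g_j + s_ij (selfs mu + 2g_i + s_ii)."""
        g = self.gca
        return self.mu + g[:, None] + g[None, :] + self.sca

    def gca_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parent": self.parents.ids, "gca": self.gca})

    def sca_frame(self, *, hybrids_only: bool = True) -> pd.DataFrame:
        ids = self.parents.ids
        rows = []
        for i in range(len(ids)):
            for j in range(i if not hybrids_only else i + 1, len(ids)):
                rows.append({"parent_a": ids[i], "parent_b": ids[j], "sca": self.sca[i, j]})
        return pd.DataFrame(rows)


@dataclass
class VarianceComponents:
    """Griffing Model 1 quasi-variance components and derived ratios.

    Components come from the expected mean squares on the plot basis with
    ``b`` blocks: sigma2_gca = (MS_GCA - MS_error)/(b (p + 2)),
    sigma2_sca = (MS_SCA - MS_error)/b, sigma2_error = MS_error. The 1/b
    factor makes the components commensurate with sigma2_error and with the
    generative per-genotype variances (and is what published diallel h2/H2
    columns computed from plot-basis ANOVA imply); it cancels in
    ``ratio_component`` (sigma2_gca / sigma2_sca), the ratio such tables
    print, and in Baker's ratio 2 sigma2_gca / (2 sigma2_gca + sigma2_sca).
    Negative components are reported as estimated and only clamped to zero
    inside heritabilities.
    """

    trait: str
    p: int
    sigma2_gca: float
    sigma2_sca: float
    sigma2_error: float
    ratio_component: float | None
    ratio_baker: float | None
    h2: float | None
    H2: float | None
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# array-level core


def rcbd_ss(y: np.ndarray) -> dict[str, tuple[int, float]]:
    """Randomized-complete-block decomposition of an (n_genotypes, b) array.

    Returns ``{source: (df, ss)}`` for block, genotype, error and total.
    """
    y = np.asarray(y, dtype=float)
    n_g, b = y.shape
    if b < 2:
        raise ValueError("RCBD analysis needs at least 2 blocks")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_block = float(n_g * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_geno = float(b * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_error = ss_total - ss_block - ss_geno
    return {
        "block": (b - 1, ss_block),
        "genotype": (n_g - 1, ss_geno),
        "error": ((n_g - 1) * (b - 1), max(ss_error, 0.0)),
        "total": (n_g * b - 1, ss_total),
    }


def griffing_ss(m: np.ndarray, b: int) -> tuple[float, float]:
    """GCA and SCA sums of squares on the plot basis.

    On the genotype-mean basis:

        SS'_GCA = (1/(p+2)) * sum_i (x_i. + x_ii)^2 - (4/(p(p+2))) * x..^2
        SS'_SCA = sum_{i<=j} x_ij^2 - (1/(p+2)) * sum_i (x_i. + x_ii)^2
                  + (2/((p+1)(p+2))) * x..^2

    both multiplied by ``b`` to sit on the plot basis shared with the RCBD
    error stratum. Their sum equals the genotype SS exactly.
    """
    m = np.asarray(m, dtype=float)
    p = m.shape[0]
    if p < 3:
        raise ValueError("Griffing partition needs p >= 3 parents")
    margins = m.sum(axis=1) + np.diag(m)  # x_i. + x_ii, self counted twice
    total = np.triu(m).sum()
    ss_gca = margins @ margins / (p + 2) - 4.0 * total**2 / (p * (p + 2))
    ss_sca = (
        float(np.triu(m**2).sum())
        - margins @ margins / (p + 2)
        + 2.0 * total**2 / ((p + 1) * (p + 2))
    )
    return float(b * ss_gca), float(b * ss_sca)


def effects_from_means(m: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Griffing Method 2 estimates (mu, g, s) from a symmetric cell-mean matrix.

    mu = 2 x.. / (p(p+1));  g_i = (x_i. + x_ii - 2 x.. / p) / (p + 2);
    s is the exact residual x_ij - mu - g_i - g_j (selfs: x_ii - mu - 2 g_i),
    so the model is saturated and reproduces every cell mean.
    """
    m = np.asarray(m, dtype=float)
    p = m.shape[0]
    total = np.triu(m).sum()
    mu = 2.0 * total / (p * (p + 1))
    g = (m.sum(axis=1) + np.diag(m) - 2.0 * total / p) / (p + 2)
    s = m - mu - g[:, None] - g[None, :]
    return float(mu), g, s


def _f_row(source: str, df: int, ss: float, ms_error: float, df_error: int) -> AnovaRow:
    ms = ss / df
    if ms_error <= 0:
        return AnovaRow(source, df, ss, ms, None, None)
    f = ms / ms_error
    return AnovaRow(source, df, ss, ms, f, float(stats.f.sf(f, df, df_error)))


# ---------------------------------------------------------------------------
# table-level API


def cell_means(table: DiallelPhenotypeTable, trait: str) -> GenotypeCellMeans:
    """Genotype means over blocks as a symmetric p x p matrix.

    Raises :class:`IncompleteDesignError` if any genotype x block cell for
    the trait is absent.
    """
    missing = table.missing_cells(trait)
    if missing:
        raise IncompleteDesignError(missing)
    p = table.parents.p
    means = table.genotype_means(trait)
    m = np.zeros((p, p))
    for (i, j), v in means.items():
        m[i, j] = m[j, i] = v
    return GenotypeCellMeans(trait=trait, parents=table.parents, matrix=m, b=table.n_blocks)


def _plot_matrix(table: DiallelPhenotypeTable, trait: str) -> np.ndarray:
    """(n_genotypes, b) array of plot values, genotypes in canonical order."""
    missing = table.missing_cells(trait)
    if missing:
        raise IncompleteDesignError(missing)
    sub = table.trait_data(trait)
    wide = sub.pivot_table(index=["i", "j"], columns="block", values="value")
    wide = wide.sort_index()
    return wide.to_numpy()


def rcbd_anova(table: DiallelPhenotypeTable, trait: str) -> dict[str, AnovaRow]:
    """Block / genotype / error decomposition for one trait (no F tests)."""
    y = _plot_matrix(table, trait)
    parts = rcbd_ss(y)
    return {
        src: AnovaRow(src, df, ss, ss / df if df else float("nan"))
        for src, (df, ss) in parts.items()
    }


def griffing_partition(means: GenotypeCellMeans, b: int | None = None) -> tuple[float, float]:
    """(SS_GCA, SS_SCA) on the plot basis; see :func:`griffing_ss`."""
    return griffing_ss(means.matrix, means.b if b is None else b)


def estimate_effects(means: GenotypeCellMeans) -> CombiningAbilities:
    """Estimate mu, GCA and SCA effects from complete cell means."""
    mu, g, s = effects_from_means(means.matrix)
    return CombiningAbilities(
        trait=means.trait, parents=means.parents, mu=mu, gca=g, sca=s
    )


def diallel_anova(table: DiallelPhenotypeTable, trait: str) -> DiallelAnova:
    """Full Model 1 ANOVA: Blocks, Genotypes, GCA, SCA, Error.

    GCA and SCA sums of squares partition the genotype stratum; every mean
    square is tested against the RCBD error (fixed effects, single error
    line).
    """
    y = _plot_matrix(table, trait)
    parts = rcbd_ss(y)
    p = table.parents.p
    means = cell_means(table, trait)
    ss_gca, ss_sca = griffing_ss(means.matrix, means.b)
    df_e, ss_e = parts["error"]
    ms_e = ss_e / df_e
    rows = {
        "blocks": _f_row("blocks", *parts["block"], ms_e, df_e),
        "genotypes": _f_row("genotypes", *parts["genotype"], ms_e, df_e),
        "gca": _f_row("gca", p - 1, ss_gca, ms_e, df_e),
        "sca": _f_row("sca", p * (p - 1) // 2, ss_sca, ms_e, df_e),
        "error": AnovaRow("error", df_e, ss_e, ms_e),
    }
    return DiallelAnova(trait=trait, rows=rows)


def components_from_ms(
    ms_gca: float,
    ms_sca: float,
    ms_error: float,
    p: int,
    *,
    b: int = 1,
    trait: str = "",
    h2_variant: str = "default",
    ms_genotypes: float | None = None,
) -> VarianceComponents:
    """Variance components and ratios from (possibly published) mean squares.

    ``b`` is the number of blocks behind the plot-basis mean squares; leave
    it at 1 when the mean squares are already per genotype mean (both
    GCA/SCA ratios are unaffected either way). ``h2_variant='genotypic'``
    replaces H2 with the genotype-MS form
    ((MS_gen - MS_e)/b) / ((MS_gen - MS_e)/b + MS_e), which then requires
    ``ms_genotypes``.
    """
    flags: list[str] = []
    s2g = (ms_gca - ms_error) / (b * (p + 2))
    s2s = (ms_sca - ms_error) / b
    s2e = ms_error
    if s2g < 0:
        flags.append("negative sigma2_gca")
    if s2s < 0:
        flags.append("negative sigma2_sca")

    ratio_component = None
    if s2s > 0:
        ratio_component = s2g / s2s
    else:
        flags.append("ratio_component undefined (sigma2_sca <= 0)")
    denom_baker = 2 * s2g + s2s
    ratio_baker = 2 * s2g / denom_baker if denom_baker > 0 else None
    if ratio_baker is None:
        flags.append("ratio_baker undefined")

    # heritabilities on clamped components
    cg, cs, ce = max(s2g, 0.0), max(s2s, 0.0), max(s2e, 0.0)
    if (cg, cs) != (s2g, s2s):
        flags.append("components clamped to 0 for heritability")
    tot = 2 * cg + cs + ce
    if tot <= 0:
        h2 = H2 = None
        flags.append("heritabilities undefined (all components 0)")
    else:
        h2 = 2 * cg / tot
        if h2_variant == "genotypic":
            if ms_genotypes is None:
                raise ValueError("genotypic H2 needs ms_genotypes")
            s2_gen = (ms_genotypes - ms_error) / b
            s2_gen = max(s2_gen, 0.0)
            H2 = s2_gen / (s2_gen + ms_error) if (s2_gen + ms_error) > 0 else None
        else:
            H2 = (2 * cg + cs) / tot
    return VarianceComponents(
        trait=trait,
        p=p,
        sigma2_gca=s2g,
        sigma2_sca=s2s,
        sigma2_error=s2e,
        ratio_component=ratio_component,
        ratio_baker=ratio_baker,
        h2=h2,
        H2=H2,
        flags=flags,
    )


def variance_components(
    anova: DiallelAnova, p: int, b: int, *, h2_variant: str = "default"
) -> VarianceComponents:
    """Components, GCA/SCA ratios and heritabilities from a fitted ANOVA.

    ``b`` is the block count of the design the ANOVA was fitted on (its
    mean squares are on the plot basis).
    """
    return components_from_ms(
        anova["gca"].ms,
        anova["sca"].ms,
        anova["error"].ms,
        p,
        b=b,
        trait=anova.trait,
        h2_variant=h2_variant,
        ms_genotypes=anova["genotypes"].ms,
    )


def heritabilities(vc: VarianceComponents) -> tuple[float | None, float | None]:
    """Narrow- and broad-sense heritabilities already held by the components.

    h2 = 2 sigma2_gca / (2 sigma2_gca + sigma2_sca + sigma2_error);
    H2 = (2 sigma2_gca + sigma2_sca) / (same denominator).
    """
    return vc.h2, vc.H2


def sca_percent(
    ca: CombiningAbilities, table: DiallelPhenotypeTable, trait: str
) -> pd.DataFrame:
    """SCA of each hybrid as a percentage of the mean of all hybrid means."""
    means = table.genotype_means(trait)
    is_self = means.index.get_level_values("i") == means.index.get_level_values("j")
    hybrid_mean = float(means[~is_self].mean())
    frame = ca.sca_frame(hybrids_only=True)
    if hybrid_mean == 0:
        frame["sca_percent"] = np.nan
        frame["flag"] = "hybrid mean is 0; percentage undefined"
        return frame
    frame["sca_percent"] = 100.0 * frame["sca"] / hybrid_mean
    return frame


def heterosis(table: DiallelPhenotypeTable, trait: str) -> pd.DataFrame:
    """Mid-parent heterosis Het = 100 (F1 - MP) / MP per hybrid.

    F1 is the hybrid genotype mean, MP the average of the two parental
    genotype means. MP = 0 yields NaN with an explanatory flag.
    """
    means = table.genotype_means(trait)
    ids = table.parents.ids
    rows = []
    for (i, j), f1 in means.items():
        if i == j:
            continue
        try:
            mp = (means[(i, i)] + means[(j, j)]) / 2.0
        except KeyError as exc:
            raise IncompleteDesignError([(ids[i], ids[j], "parent self", trait)]) from exc
        if mp == 0:
            het, flag = np.nan, "MP = 0; heterosis undefined"
        else:
            het, flag = 100.0 * (f1 - mp) / mp, ""
        rows.append(
            {
                "parent_a": ids[i],
                "parent_b": ids[j],
                "f1": float(f1),
                "mid_parent": float(mp),
                "heterosis": het,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)
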