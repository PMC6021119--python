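"""Half-diallel phenotype input, validation and group summaries.

A half-diallel crosses ``p`` parents in all unordered pairs, including the
selfed parents, giving ``p(p+1)/2`` genotypes grown in ``b`` complete blocks.
This module reads the long-format phenotype table, canonicalizes cross keys
(the cross A x B and B x A are the same genotype), checks design
completeness, and compares the parent and hybrid groups per trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("parent_a", "parent_b", "block", "trait", "value")


class PhenotypeFormatError(ValueError):
    """The input file does not conform to the expected CSV dialect."""


class PhenotypeValidationError(ValueError):
    """The file parses but its content violates a design constraint."""


class IncompleteDesignError(ValueError):
    """A genotype x block cell required by the analysis is missing."""

    def __init__(self, missing: list[tuple]):
        self.missing = missing
        preview = ", ".join(map(str, missing[:10]))
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        super().__init__(f"incomplete diallel design; missing cells: {preview}{more}")


@dataclass(frozen=True)
class ParentSet:
    """Ordered parent identifiers, optionally tagged with group labels.

    The order given here is the canonical index used by every downstream
    matrix (cell means, GCA vectors, SCA matrices, distance matrices).
    """

    ids: tuple[str, ...]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        if len(set(self.ids)) != len(self.ids):
            raise PhenotypeValidationError("parent ids must be unique")
        unknown = set(self.labels) - set(self.ids)
        if unknown:
            raise PhenotypeValidationError(f"labels for unknown parents: {sorted(unknown)}")

    @property
    def p(self) -> int:
        return len(self.ids)

    def index(self, parent_id: str) -> int:
        return self.ids.index(parent_id)

    def subset_with_label(self, label: str) -> tuple[str, ...]:
        return tuple(i for i in self.ids if self.labels.get(i) == label)


@dataclass
class DiallelPhenotypeTable:
    """Plot-level half-diallel observations keyed by unordered parent pair.

    ``data`` holds columns ``i``, ``j`` (canonical parent indices, i <= j),
    ``block``, ``trait``, ``value``.
    """

    parents: ParentSet
    data: pd.DataFrame

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    @property
    def blocks(self) -> list[int]:
        return sorted(self.data["block"].unique())

    @property
    def n_blocks(self) -> int:
        return self.data["block"].nunique()

    def trait_data(self, trait: str) -> pd.DataFrame:
        sub = self.data[self.data["trait"] == trait]
        if sub.empty:
            raise PhenotypeValidationError(f"trait {trait!r} not present")
        return sub

    def genotype_means(self, trait: str) -> pd.Series:
        """Mean over blocks per genotype, indexed by (i, j) with i <= j."""
        sub = self.trait_data(trait)
        return sub.groupby(["i", "j"])["value"].mean()

    def missing_cells(self, trait: str | None = None) -> list[tuple]:
        """Genotype x block x trait cells absent from a complete design."""
        p = self.parents.p
        blocks = self.blocks
        traits = [trait] if trait is not None else self.traits
        expected = {
            (i, j, b, t)
            for i in range(p)
            for j in range(i, p)
            for b in blocks
            for t in traits
        }
        sub = self.data if trait is None else self.data[self.data["trait"] == trait]
        present = set(map(tuple, sub[["i", "j", "block", "trait"]].itertuples(index=False)))
        missing = sorted(expected - present)
        ids = self.parents.ids
        return [(ids[i], ids[j], b, t) for (i, j, b, t) in missing]


def canonical_pair(a: str, b: str, parents: ParentSet) -> tuple[int, int]:
    """Map an (a, b) cross to its unordered canonical index pair (i <= j)."""
    ia, ib = parents.index(a), parents.index(b)
    return (ia, ib) if ia <= ib else (ib, ia)


def from_dataframe(df: pd.DataFrame, parents: ParentSet) -> DiallelPhenotypeTable:
    """Validate a raw long-format frame and canonicalize its cross keys."""
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PhenotypeFormatError(f"missing required columns: {missing_cols}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()

    known = set(parents.ids)
    for col in ("parent_a", "parent_b"):
        df[col] = df[col].astype(str)
        bad = sorted(set(df[col]) - known)
        if bad:
            raise PhenotypeValidationError(f"unknown parent ids in {col!r}: {bad}")

    values = pd.to_numeric(df["value"], errors="coerce")
    nonnum = df.index[values.isna()]
    if len(nonnum):
        row = nonnum[0]
        raise PhenotypeValidationError(
            f"non-numeric or missing value at row {row}: {df.loc[row].to_dict()}"
        )
    if not np.isfinite(values).all():
        raise PhenotypeValidationError("non-finite phenotype values present")
    df["value"] = values.astype(float)

    blocks = pd.to_numeric(df["block"], errors="coerce")
    if blocks.isna().any() or (blocks < 1).any() or (blocks != blocks.round()).any():
        raise PhenotypeValidationError("block must be an integer >= 1")
    df["block"] = blocks.astype(int)
    df["trait"] = df["trait"].astype(str)

    idx = {pid: k for k, pid in enumerate(parents.ids)}
    ia = df["parent_a"].map(idx).to_numpy()
    ib = df["parent_b"].map(idx).to_numpy()
    df["i"] = np.minimum(ia, ib)
    df["j"] = np.maximum(ia, ib)

    dup = df.duplicated(subset=["i", "j", "block", "trait"], keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        raise PhenotypeValidationError(
            f"duplicate observation for cross ({first['parent_a']},{first['parent_b']}) "
            f"block {first['block']} trait {first['trait']!r}"
        )
    out = df[["i", "j", "block", "trait", "value"]].reset_index(drop=True)
    return DiallelPhenotypeTable(parents=parents, data=out)


def read_phenotypes(path, parents: ParentSet) -> DiallelPhenotypeTable:
    """Read a UTF-8 CSV with header ``parent_a,parent_b,block,trait,value``."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise PhenotypeFormatError(f"cannot parse {path}: {exc}") from exc
    return from_dataframe(df, parents)


@dataclass(frozen=True)
class DesignCounts:
    p: int
    n_hybrids: int
    n_genotypes: int
    b: int
    incomplete_cells: tuple = ()


def design_counts(table: DiallelPhenotypeTable) -> DesignCounts:
    """Report design dimensions; incomplete cells are flagged, not fatal."""
    if table.data.empty:
        raise PhenotypeValidationError("empty phenotype table")
    p = table.parents.p
    return DesignCounts(
        p=p,
        n_hybrids=p * (p - 1) // 2,
        n_genotypes=p * (p + 1) // 2,
        b=table.n_blocks,
        incomplete_cells=tuple(table.missing_cells()),
    )


@dataclass(frozen=True)
class GroupSummary:
    """Parent-group vs hybrid-group comparison for one trait."""

    trait: str
    parent_mean: float
    parent_range: tuple[float, float]
    hybrid_mean: float
    hybrid_range: tuple[float, float]
    t_statistic: float
    p_value: float
    degenerate: bool = False


def group_compare(
    table: DiallelPhenotypeTable, trait: str, *, pooled: bool = False
) -> GroupSummary:
    """Two-sided t-test of parent vs hybrid genotype means for one trait.

    Welch's unequal-variance test by default; ``pooled=True`` selects the
    classical equal-variance test. Both groups constant yields a degenerate
    result with t = 0, p = 1.
    """
    means = table.genotype_means(trait)
    is_self = means.index.get_level_values("i") == means.index.get_level_values("j")
    par = means[is_self].to_numpy()
    hyb = means[~is_self].to_numpy()
    if len(par) < 2 or len(hyb) < 2:
        raise PhenotypeValidationError("need >= 2 parents and >= 2 hybrids with data")
    if np.ptp(par) == 0 and np.ptp(hyb) == 0:
        return GroupSummary(
            trait=trait,
            parent_mean=float(par.mean()),
            parent_range=(float(par.min()), float(par.max())),
            hybrid_mean=float(hyb.mean()),
            hybrid_range=(float(hyb.min()), float(hyb.max())),
            t_statistic=0.0,
            p_value=1.0,
            degenerate=True,
        )
    t, p = stats.ttest_ind(par, hyb, equal_var=pooled)
    return GroupSummary(
        trait=trait,
        parent_mean=float(par.mean()),
        parent_range=(float(par.min()), float(par.max())),
        hybrid_mean=float(hyb.mean()),
        hybrid_range=(float(hyb.min()), float(hyb.max())),
        t_statistic=float(t),
        p_value=float(p),
    )


def group_summary_table(table: DiallelPhenotypeTable, *, pooled: bool = False) -> pd.DataFrame:
    """Parent/hybrid summary rows for every trait (one row per trait)."""
    rows = []
    for trait in table.traits:
        s = group_compare(table, trait, pooled=pooled)
        rows.append(
            {
                "trait": s.trait,
                "parent_mean": s.parent_mean,
                "parent_min": s.parent_range[0],
                "parent_max": s.parent_range[1],
                "hybrid_mean": s.hybrid_mean,
                "hybrid_min": s.hybrid_range[0],
                "hybrid_max": s.hybrid_range[1],
                "t": s.t_statistic,
                "p_value": s.p_value,
                "degenerate": s.degenerate,
            }
        )
    return pd.DataFrame(rows)
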