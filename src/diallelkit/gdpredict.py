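"""Parental genetic distance as a predictor of hybrid performance.

For every hybrid i x j the parental genetic distance GD(i, j) is paired with
three responses per trait: the hybrid genotype mean, its mid-parent
heterosis, and its specific combining ability. Pearson correlations with
two-sided p-values (n - 2 df) quantify how well GD predicts each response,
for the full parent set and for labeled subsets (e.g. excluding a wild
parent whose large distances could dominate the signal). Significance stars
are per-cell and unadjusted.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import griffing
from .genodist import DistanceMatrix
from .griffing import CombiningAbilities
from .phenio import DiallelPhenotypeTable

RESPONSES = ("value", "heterosis", "sca")


def assemble_hybrid_records(
    gd: DistanceMatrix,
    table: DiallelPhenotypeTable,
    ca_by_trait: dict[str, CombiningAbilities],
    het_by_trait: dict[str, pd.DataFrame],
    subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One row per hybrid x trait: GD, hybrid mean, heterosis, SCA.

    ``subset`` restricts to hybrids whose *both* parents are in the subset;
    None keeps every parent. A hybrid absent from any source is an error.
    """
    ids = table.parents.ids
    keep = set(ids if subset is None else subset)
    unknown = keep - set(ids)
    if unknown:
        raise KeyError(f"subset parents not in phenotype table: {sorted(unknown)}")
    if not keep:
        raise ValueError("empty parent subset")
    missing_gd = keep - set(gd.ids)
    if missing_gd:
        raise KeyError(f"subset parents not in distance matrix: {sorted(missing_gd)}")

    rows = []
    for trait, ca in ca_by_trait.items():
        means = table.genotype_means(trait)
        het = het_by_trait[trait].set_index(["parent_a", "parent_b"])
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                if a not in keep or b not in keep:
                    continue
                if (i, j) not in means.index:
                    raise KeyError(f"hybrid {a} x {b} missing phenotype for {trait!r}")
                if (a, b) not in het.index:
                    raise KeyError(f"hybrid {a} x {b} missing heterosis for {trait!r}")
                rows.append(
                    {
                        "parent_a": a,
                        "parent_b": b,
                        "trait": trait,
                        "gd": gd.get(a, b),
                        "value": float(means[(i, j)]),
                        "heterosis": float(het.loc[(a, b), "heterosis"]),
                        "sca": float(ca.sca[i, j]),
                    }
                )
    return pd.DataFrame(rows)


def _stars(p: float, levels: Sequence[float]) -> str:
    return "*" * sum(p < a for a in sorted(levels, reverse=True))


def gd_correlations(
    records: pd.DataFrame,
    alphas: Sequence[float] = (0.05, 0.01, 0.001),
    subset_name: str = "all",
) -> pd.DataFrame:
    """Pearson r of GD against each response per trait, with stars.

    Zero-variance responses (or GD constant across hybrids) yield NaN with a
    flag rather than an error.
    """
    if records.empty:
        raise ValueError("no hybrid records")
    out = []
    for trait, sub in records.groupby("trait", sort=True):
        n = len(sub)
        for response in RESPONSES:
            x = sub["gd"].to_numpy()
            y = sub[response].to_numpy()
            flag = ""
            if n < 3:
                r = p = np.nan
                flag = "fewer than 3 hybrids"
            elif np.ptp(x) == 0 or np.ptp(y) == 0:
                r = p = np.nan
                flag = "zero variance"
            else:
                res = stats.pearsonr(x, y)
                r, p = float(res.statistic), float(res.pvalue)
            out.append(
                {
                    "trait": trait,
                    "response": response,
                    "subset": subset_name,
                    "n": n,
                    "r": r,
                    "p_value": p,
                    "stars": "" if np.isnan(p) else _stars(p, alphas),
                    "flag": flag,
                }
            )
    return pd.DataFrame(out)


def gd_association_report(
    table: DiallelPhenotypeTable,
    gd: DistanceMatrix,
    subsets: dict[str, Sequence[str] | None] | None = None,
    alphas: Sequence[float] = (0.05, 0.01, 0.001),
) -> pd.DataFrame:
    """End-to-end report: fit combining abilities per trait, then correlate.

    ``subsets`` maps a report label to a parent-id list (None = all
    parents); default is the full set only.
    """
    ca_by_trait: dict[str, CombiningAbilities] = {}
    het_by_trait: dict[str, pd.DataFrame] = {}
    for trait in table.traits:
        means = griffing.cell_means(table, trait)
        ca_by_trait[trait] = griffing.estimate_effects(means)
        het_by_trait[trait] = griffing.heterosis(table, trait)
    if subsets is None:
        subsets = {"all": None}
    reports = []
    for name, subset in subsets.items():
        records = assemble_hybrid_records(gd, table, ca_by_trait, het_by_trait, subset)
        reports.append(gd_correlations(records, alphas, subset_name=name))
    return pd.concat(reports, ignore_index=True)


def report_to_wide(report: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long report into a trait x (subset, response) table of r."""
    wide = report.pivot_table(
        index="trait", columns=["subset", "response"], values="r", sort=False
    )
    return wide
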