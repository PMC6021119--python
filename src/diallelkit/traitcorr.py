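"""Pairwise Pearson trait correlations with Bonferroni screening.

Correlations are computed across genotypes (parents and hybrids together) on
genotype means over blocks, so the sample size for a complete half-diallel
is n = p(p+1)/2. With t traits there are m = t(t-1)/2 unique pairs; instead
of adjusting each p-value, the family-wise alpha is converted into a single
critical |r| via the Student-t transform, the decision rule being identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phenio import DiallelPhenotypeTable


def count_pairs(t: int) -> int:
    """Number of unique unordered trait pairs, m = t(t-1)/2."""
    if t < 2:
        raise ValueError("need at least 2 traits")
    return t * (t - 1) // 2


def bonferroni_critical_r(n: int, m: int, alpha: float = 0.05) -> float:
    """Critical |r| for m simultaneous two-sided tests at family level alpha.

    t* is the upper alpha/(2m) quantile of Student's t with n - 2 df and
    the threshold is t* / sqrt(t*^2 + n - 2): a pair is significant iff
    |r| >= this value.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    if m < 1:
        raise ValueError("need m >= 1")
    tstar = stats.t.ppf(1.0 - alpha / (2.0 * m), n - 2)
    return float(tstar / np.sqrt(tstar**2 + n - 2))


@dataclass
class CorrelationMatrix:
    """Trait x trait Pearson r with Bonferroni significance flags."""

    r: pd.DataFrame  # t x t, NaN where undefined
    n: int
    m: int
    alpha: float
    critical_r: float
    significant: pd.DataFrame  # boolean, |r| >= critical_r

    @property
    def traits(self) -> list[str]:
        return list(self.r.columns)

    def to_long(self) -> pd.DataFrame:
        """(trait_a, trait_b, r, significant) for each unique pair."""
        traits = self.traits
        rows = []
        for a in range(len(traits)):
            for b in range(a + 1, len(traits)):
                rows.append(
                    {
                        "trait_a": traits[a],
                        "trait_b": traits[b],
                        "r": self.r.iloc[a, b],
                        "significant": bool(self.significant.iloc[a, b]),
                    }
                )
        return pd.DataFrame(rows)


def genotype_trait_matrix(table: DiallelPhenotypeTable) -> pd.DataFrame:
    """Genotypes x traits matrix of means over blocks."""
    wide = table.data.pivot_table(
        index=["i", "j"], columns="trait", values="value", aggfunc="mean"
    )
    return wide.sort_index()


def pearson_matrix(genotype_means: pd.DataFrame, alpha: float = 0.05) -> CorrelationMatrix:
    """All-pairs Pearson r over genotypes with a Bonferroni critical r.

    Genotypes with a missing value in either trait of a pair are dropped
    pairwise (pandas' default). Zero-variance traits yield NaN against every
    other trait and are never flagged significant.
    """
    if genotype_means.shape[0] < 3:
        raise ValueError("need at least 3 genotypes")
    if genotype_means.shape[1] < 2:
        raise ValueError("need at least 2 traits")
    r = genotype_means.corr(method="pearson")
    np.fill_diagonal(r.values, 1.0)
    n = genotype_means.shape[0]
    m = count_pairs(genotype_means.shape[1])
    crit = bonferroni_critical_r(n, m, alpha)
    significant = r.abs().ge(crit) & r.notna()
    np.fill_diagonal(significant.values, False)
    return CorrelationMatrix(
        r=r, n=n, m=m, alpha=alpha, critical_r=crit, significant=significant
    )
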