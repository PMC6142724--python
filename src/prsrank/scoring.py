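"""Weighted additive polygenic scores, percentile ranks and z-scores.

The score of individual *i* is the raw weighted allele count

    S_i = sum_j g_ij * beta_j        (mm of height)

where g_ij in {0,1,2} counts effect-allele copies and beta_j is the
per-allele effect in mm. Scores are deliberately NOT centered or
allele-frequency normalized (no -2*p̄*beta term): the genotype-class
decomposition of a score into its homozygous/heterozygous components only
sums back to the total under the raw convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import ValidationError
from .io import EffectTable, GenotypeMatrix


class PercentileRank(NamedTuple):
    """Mid-rank percentile of a focal score within a comparison cohort.

    ``is_highest`` marks the focal score strictly above every comparison
    score — the distribution's top rank, displayed as "*" in tables.
    """

    percentile: float
    is_highest: bool


@dataclass
class CohortScoreStats:
    mean: float
    sd: float
    n: int


class PolygenicScorer(BaseEstimator, TransformerMixin):
    """Linear scoring transformer: dosage matrix -> additive score per row.

    Parameters
    ----------
    effect_table : EffectTable
        Supplies the per-SNP weights (beta, mm/allele). At ``fit`` the
        panel columns are intersected with the table and weights aligned
        in table order.

    Attributes
    ----------
    snp_ids_ : SNPs actually scored (table order)
    beta_ : aligned weights
    """

    def __init__(self, effect_table: EffectTable = None):
        self.effect_table = effect_table

    def fit(self, X, y=None, snp_ids=None):
        if self.effect_table is None:
            raise ValidationError("PolygenicScorer requires an effect_table")
        ids = list(X.snp_ids) if isinstance(X, GenotypeMatrix) else list(
            snp_ids if snp_ids is not None else self.effect_table.snp_ids
        )
        present = set(ids)
        sub = self.effect_table.df[self.effect_table.df["snp_id"].isin(present)]
        if sub.empty:
            raise ValidationError("no overlap between genotype panel and effect table")
        self.snp_ids_ = list(sub["snp_id"])
        self.beta_ = sub["beta"].to_numpy(dtype=float)
        self._col_idx = np.array([ids.index(s) for s in self.snp_ids_])
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "beta_")
        if isinstance(X, GenotypeMatrix):
            D = X.imputed_dosage()
        else:
            D = check_array(X, dtype=float)
        return D[:, self._col_idx] @ self.beta_


def compute_scores(geno: GenotypeMatrix, table: EffectTable) -> pd.Series:
    """Additive polygenic score in mm for every individual.

    SNPs are the intersection of the panel and the table, summed in table
    order for reproducible results; missing genotypes are mean-imputed by
    the panel (see ``GenotypeMatrix.imputed_dosage``).
    """
    scorer = PolygenicScorer(table).fit(geno)
    values = scorer.transform(geno)
    return pd.Series(values, index=pd.Index(geno.individual_ids, name="individual_id"),
                     name="score_mm")


def cohort_stats(scores: pd.Series) -> CohortScoreStats:
    """Mean and SD (ddof=1) of a cohort's scores."""
    n = len(scores)
    if n < 2:
        raise ValidationError("need >= 2 scores for a standard deviation")
    return CohortScoreStats(float(scores.mean()), float(scores.std(ddof=1)), n)


def rank_percentile(scores, focal) -> PercentileRank:
    """Mid-rank percentile of a focal individual against comparison scores.

    percentile = 100 * (#strictly below + 0.5 * #tied) / N over the N
    comparison scores. ``focal`` may be an individual id present in
    ``scores`` (then excluded from the comparison set) or an external
    score value.
    """
    scores = pd.Series(scores) if not isinstance(scores, pd.Series) else scores
    if isinstance(focal, str):
        if focal not in scores.index:
            raise ValidationError(f"focal individual {focal!r} not in scores")
        focal_score = float(scores.loc[focal])
        comparison = scores.drop(index=focal).to_numpy(dtype=float)
    else:
        focal_score = float(focal)
        comparison = scores.to_numpy(dtype=float)
    if comparison.size == 0:
        raise ValidationError("need at least one comparison score")
    below = int((comparison < focal_score).sum())
    ties = int((comparison == focal_score).sum())
    pct = 100.0 * (below + 0.5 * ties) / comparison.size
    return PercentileRank(pct, below == comparison.size)


def zscore(x: float, mean: float, sd: float) -> float:
    """Standard score (x - mean) / sd."""
    if sd <= 0:
        raise ValidationError(f"sd must be positive, got {sd}")
    return (x - mean) / sd
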