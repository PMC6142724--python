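"""Genotype-class decomposition of a score, goodness-of-fit, and
score-phenotype correlation.

A score S = Σ g_j β_j can be split by (sign of β) x (genotype class):
homozygous for the effect allele (g=2), heterozygous (g=1), homozygous for
the non-effect allele (g=0). The two homozygous-noneffect cells contribute
nothing to the score, so the four remaining cell sums reconstruct S
exactly; an extreme individual typically shows an excess of positive-effect
homozygotes over negative-effect homozygotes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import EffectTable, PhenotypeTable

SIGNS = ("positive", "negative")
CLASSES = ("hom_effect", "het", "hom_noneffect")


@dataclass
class ScoreDecomposition:
    """2x3 genotype-class counts and the 4 scoring-cell contributions.

    ``counts``: rows (positive beta, negative beta) x columns
    (hom_effect, het, hom_noneffect); beta = 0 SNPs are excluded from the
    sign cells and counted in ``n_zero_beta``. ``contributions`` (mm) has
    the same layout with the hom_noneffect column structurally zero.
    """

    counts: pd.DataFrame
    contributions: pd.DataFrame
    n_zero_beta: int = 0

    @property
    def total(self) -> float:
        """The individual's score: sum of the four scoring cells."""
        return float(self.contributions.to_numpy().sum())

    def to_tsv(self, path) -> None:
        out = self.counts.astype(str).copy()
        for s in SIGNS:
            for c in ("hom_effect", "het"):
                out.loc[s, c] += f" ({self.contributions.loc[s, c]:.2f})"
            out.loc[s, "hom_noneffect"] += " (NA)"
        out.index.name = "effect_sign"
        out.to_csv(path, sep="\t")


@dataclass
class GofResult:
    chi2: float
    df: int
    p: float
    expected_counts: np.ndarray


def decompose(dosages, table: EffectTable) -> ScoreDecomposition:
    """Assign each SNP of one individual to a (sign, genotype-class) cell.

    ``dosages`` must be complete (mean-imputed dosages are rounded to the
    nearest genotype for counting but contribute their raw value to the
    cell sums only when integral; pass integer dosages for exact tables).
    """
    d = np.asarray(dosages, dtype=float)
    beta = table.betas
    if d.shape != beta.shape:
        raise ValidationError(f"dosage length {d.shape} != table length {beta.shape}")
    g = np.rint(d).astype(int)
    if np.any((g < 0) | (g > 2)):
        raise ValidationError("dosages outside {0,1,2}")
    sign_masks = {"positive": beta > 0, "negative": beta < 0}
    class_masks = {"hom_effect": g == 2, "het": g == 1, "hom_noneffect": g == 0}
    prod = d * beta
    counts = pd.DataFrame(
        {c: [int((sign_masks[s] & class_masks[c]).sum()) for s in SIGNS] for c in CLASSES},
        index=list(SIGNS),
    )
    contrib = pd.DataFrame(
        {c: [float(prod[sign_masks[s] & class_masks[c]].sum()) for s in SIGNS] for c in CLASSES},
        index=list(SIGNS),
    )
    return ScoreDecomposition(counts, contrib, int((beta == 0).sum()))


def excess_homozygotes(d: ScoreDecomposition) -> int:
    """Positive-effect homozygote count minus negative-effect homozygote count."""
    return int(d.counts.loc["positive", "hom_effect"] - d.counts.loc["negative", "hom_effect"])


def average_decomposition(geno, table: EffectTable) -> ScoreDecomposition:
    """Cohort-average decomposition (cell means over individuals, rounded).

    Serves as the expected composition when testing one individual's
    genotype distribution against the cohort's.
    """
    beta = table.betas
    D = np.asarray(geno.dosage, dtype=np.int8)
    n = geno.n_individuals
    sign_masks = {"positive": beta > 0, "negative": beta < 0}
    counts = pd.DataFrame(0, index=list(SIGNS), columns=list(CLASSES))
    contrib = pd.DataFrame(0.0, index=list(SIGNS), columns=list(CLASSES))
    for g, cls in ((2, "hom_effect"), (1, "het"), (0, "hom_noneffect")):
        per_snp = (D == g).sum(axis=0)  # genotype-class tally per SNP
        for s in SIGNS:
            counts.loc[s, cls] = int(round(per_snp[sign_masks[s]].sum() / n))
            contrib.loc[s, cls] = float(
                (per_snp[sign_masks[s]] * g * beta[sign_masks[s]]).sum() / n
            )
    return ScoreDecomposition(counts, contrib, int((beta == 0).sum()))


def gof_test(observed, expected_proportions) -> GofResult:
    """Pearson chi-square goodness of fit of counts against proportions.

    Expected counts are proportion x total observed; df = cells - 1;
    upper-tail p from the chi-square distribution. Proportions off unit
    sum by more than 1e-9 are renormalized with a warning.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    prop = np.asarray(expected_proportions, dtype=float).ravel()
    if obs.shape != prop.shape:
        raise ValidationError("observed and expected shapes differ")
    if obs.sum() < 1:
        raise ValidationError("observed total must be >= 1")
    if abs(prop.sum() - 1.0) > 1e-9:
        warnings.warn(f"expected proportions sum to {prop.sum():.6g}; renormalizing")
    prop = prop / prop.sum()
    expected = prop * obs.sum()
    if np.any((expected == 0) & (obs > 0)):
        raise ValidationError("expected count 0 with observed count > 0")
    keep = expected > 0
    chi2, p = stats.chisquare(obs[keep], expected[keep])
    df = int(obs.size - 1)
    # scipy's df assumes all kept cells; recompute p for declared df
    p = float(stats.chi2.sf(chi2, df))
    return GofResult(float(chi2), df, p, expected)


def pearson_correlation(scores: pd.Series, pheno: PhenotypeTable) -> dict:
    """Pearson r between scores and heights on the id intersection.

    Two-sided p from the exact t transform t = r*sqrt((n-2)/(1-r²)) on
    n-2 degrees of freedom (scipy.stats.pearsonr).
    """
    h = pheno.df.set_index("individual_id")["height_cm"]
    common = scores.index.intersection(h.index)
    if len(common) < 3:
        raise ValidationError("need >= 3 paired observations")
    x = scores.loc[common].to_numpy(dtype=float)
    y = h.loc[common].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in scores or heights")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(len(common))}
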