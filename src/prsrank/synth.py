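"""Synthetic cohorts with LD-block structure, effect sizes, phenotypes and
a constructed extreme individual.

The generator emulates the study conditions the pipeline was built for —
roughly a thousand individuals typed at a few thousand height-associated
SNPs whose per-allele effects span about -0.14 to 0.19 mm — without any
access to restricted genotypes:

* allele frequencies ~ Uniform(0.05, 0.95): common SNPs only;
* genotypes in Hardy-Weinberg equilibrium, dosage ~ Binomial(2, p);
* LD blocks: within a block every SNP copies a founder column, each
  individual's genotype independently redrawn from HWE with a flip
  probability f = 1 - sqrt(target r²), so the expected pairwise dosage
  correlation is r = 1 - f and r² hits the target analytically;
* betas from a Normal(0, sigma_beta) clipped to the observed effect range;
* phenotypes: height = mu + genetic deviation + Gaussian noise, the noise
  variance set so the score explains a configurable fraction of the
  phenotypic variance;
* one "extreme" individual whose genotype at each SNP is pushed toward the
  height-increasing homozygote with a configurable enrichment probability
  — a generative stand-in for a rare combination of common alleles, not a
  model of any real person.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import EffectTable, GenotypeMatrix, PhenotypeTable
from .scoring import compute_scores

#: mm of score per cm of height
MM_PER_CM = 10.0

#: unambiguous allele pairs (no A/T or C/G) used for synthetic SNPs
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


@dataclass
class SynthConfig:
    """Study-condition defaults: ~1020 individuals x 2910 common SNPs,
    effects clipped to [-0.14, 0.19] mm/allele, scores explaining 20% of
    phenotypic variance around a 176.8 cm mean."""

    n_individuals: int = 1020
    n_snps: int = 2910
    freq_low: float = 0.05
    freq_high: float = 0.95
    beta_sigma: float = 0.05
    beta_low: float = -0.14
    beta_high: float = 0.19
    n_blocks: int | None = None  # default: ~5 SNPs per block
    within_block_r2: float = 0.95
    imputed_fraction: float = 0.144  # matches a 419-of-2910 imputed panel
    genetic_var_fraction: float = 0.20
    extreme_enrichment: float = 0.3
    mean_height_cm: float = 176.8
    n_chromosomes: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.genetic_var_fraction < 1:
            raise ValidationError("genetic_var_fraction must lie in (0, 1)")
        if not 0 <= self.extreme_enrichment <= 1:
            raise ValidationError("extreme_enrichment must lie in [0, 1]")
        if self.n_blocks is None:
            self.n_blocks = max(1, self.n_snps // 5)
        if self.n_blocks > self.n_snps:
            raise ValidationError("n_blocks exceeds n_snps")
        if not 0 < self.within_block_r2 <= 1:
            raise ValidationError("within_block_r2 must lie in (0, 1]")


def _block_sizes(rng: np.random.Generator, n_snps: int, n_blocks: int) -> np.ndarray:
    """Random block sizes >= 1 summing to n_snps (uniform cut points)."""
    if n_blocks == 1:
        return np.array([n_snps])
    cuts = rng.choice(np.arange(1, n_snps), size=n_blocks - 1, replace=False)
    cuts.sort()
    return np.diff(np.concatenate(([0], cuts, [n_snps])))


def generate_panel(cfg: SynthConfig) -> tuple[EffectTable, GenotypeMatrix]:
    """Effect table plus HWE genotypes with LD-block structure.

    Deterministic under ``cfg.seed``. Blocks never span chromosomes;
    block b is placed on chromosome 1 + (b * n_chromosomes) // n_blocks
    with positions spaced 5 kb apart.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    sizes = _block_sizes(rng, cfg.n_snps, cfg.n_blocks)
    flip = 1.0 - np.sqrt(cfg.within_block_r2)

    n = cfg.n_individuals
    dosage = np.empty((n, cfg.n_snps), dtype=np.int8)
    freqs = np.empty(cfg.n_snps)
    chroms = np.empty(cfg.n_snps, dtype=object)
    pos = np.empty(cfg.n_snps, dtype=int)
    block_of = np.empty(cfg.n_snps, dtype=int)
    j = 0
    pos_counter: dict[str, int] = {}
    for b, size in enumerate(sizes):
        p = rng.uniform(cfg.freq_low, cfg.freq_high)
        chrom = str(1 + (b * cfg.n_chromosomes) // cfg.n_blocks)
        founder = rng.binomial(2, p, size=n).astype(np.int8)
        for k in range(size):
            if k == 0:
                col = founder
            else:
                redraw = rng.random(n) < flip
                col = np.where(redraw, rng.binomial(2, p, size=n), founder).astype(np.int8)
            dosage[:, j] = col
            freqs[j] = p
            chroms[j] = chrom
            pos_counter[chrom] = pos_counter.get(chrom, 0) + 1
            pos[j] = pos_counter[chrom] * 5000
            block_of[j] = b
            j += 1

    beta = np.clip(rng.normal(0.0, cfg.beta_sigma, cfg.n_snps), cfg.beta_low, cfg.beta_high)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), cfg.n_snps)
    swap = rng.random(cfg.n_snps) < 0.5
    effect = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    other = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)
    effect[swap], other[swap] = other[swap].copy(), effect[swap].copy()
    imputed = rng.random(cfg.n_snps) < cfg.imputed_fraction
    info = np.where(imputed, rng.uniform(0.4, 1.0, cfg.n_snps), np.nan)

    table = EffectTable(
        pd.DataFrame(
            {
                "snp_id": [f"snp{b:05d}_{k}" for b, k in zip(block_of, _within_index(block_of))],
                "chrom": chroms,
                "pos": pos,
                "effect_allele": effect,
                "other_allele": other,
                "beta": beta,
                "origin": np.where(imputed, "imputed", "genotyped"),
                "info": info,
            }
        )
    )
    ids = [f"I{i:05d}" for i in range(n)]
    geno = GenotypeMatrix(ids, table.snp_ids, dosage)
    # stash frequencies for downstream HWE sampling
    geno.allele_freqs = freqs
    return table, geno


def _within_index(block_of: np.ndarray) -> np.ndarray:
    out = np.zeros_like(block_of)
    seen: dict[int, int] = {}
    for i, b in enumerate(block_of):
        out[i] = seen.get(b, 0)
        seen[b] = out[i] + 1
    return out


def generate_phenotypes(
    geno: GenotypeMatrix, table: EffectTable, cfg: SynthConfig
) -> PhenotypeTable:
    """Heights (cm) = mean + centered genetic deviation + Gaussian noise.

    Scores are in mm and heights in cm; the genetic deviation is converted
    with an explicit factor of 10 mm/cm. The environmental variance is set
    from the realized score variance so that
    Var(genetic) / Var(height) = cfg.genetic_var_fraction.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    scores = compute_scores(geno, table)
    g_cm = (scores - scores.mean()).to_numpy() / MM_PER_CM
    var_g = g_cm.var(ddof=1)
    if var_g == 0:
        raise ValidationError("zero score variance; cannot scale phenotype noise")
    v = cfg.genetic_var_fraction
    sigma_e = np.sqrt(var_g * (1.0 - v) / v)
    height = cfg.mean_height_cm + g_cm + rng.normal(0.0, sigma_e, len(g_cm))
    return PhenotypeTable(
        pd.DataFrame({"individual_id": scores.index, "height_cm": height})
    )


def make_extreme_individual(
    table: EffectTable,
    freqs,
    extreme_enrichment: float,
    seed: int = 0,
) -> np.ndarray:
    """Dosage row enriched for height-increasing homozygotes.

    At each SNP, with probability ``extreme_enrichment`` the genotype is
    set to the height-increasing homozygote (dosage 2 if beta > 0, 0 if
    beta < 0); otherwise it is drawn from HWE at the SNP's frequency.
    Enrichment 1 yields the maximum possible panel score; enrichment 0 is
    distributionally an ordinary cohort member.
    """
    if not 0 <= extreme_enrichment <= 1:
        raise ValidationError("enrichment must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    beta = table.betas
    p = np.asarray(freqs, dtype=float)
    base = rng.binomial(2, p).astype(np.int8)
    push = rng.random(len(beta)) < extreme_enrichment
    target = np.where(beta > 0, 2, np.where(beta < 0, 0, base)).astype(np.int8)
    return np.where(push & (beta != 0), target, base).astype(np.int8)


def generate_cohort(cfg: SynthConfig, extreme_id: str = "EXTREME"):
    """Panel + phenotypes + appended extreme individual, all from cfg.seed.

    Returns (EffectTable, GenotypeMatrix incl. extreme, PhenotypeTable of
    the ordinary cohort, extreme_id).
    """
    table, geno = generate_panel(cfg)
    pheno = generate_phenotypes(geno, table, cfg)
    extreme = make_extreme_individual(
        table, geno.allele_freqs, cfg.extreme_enrichment, seed=np.random.default_rng([cfg.seed, 2]).integers(2**31)
    )
    full = GenotypeMatrix(
        geno.individual_ids + [extreme_id],
        list(geno.snp_ids),
        np.vstack([geno.dosage, extreme[None, :]]),
    )
    full.allele_freqs = geno.allele_freqs
    return table, full, pheno, extreme_id
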