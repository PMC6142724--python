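"""Null distribution of polygenic scores from simulated genotypes.

Simulated individuals draw a genotype independently at every SNP and are
scored with the real betas; because individuals never need to be kept, the
score distribution is summarized in a single pass (streaming count, mean,
variance via chunk-merged Welford updates, exact min and max), so the
replicate count is limited by time only, not memory.

Two genotype models:

* ``uniform`` — each dosage in {0, 1, 2} with probability 1/3, i.e. the
  "no evolutionary constraints" null in which every genotype is equally
  likely regardless of allele frequency.
* ``hwe`` — dosage ~ Binomial(2, p_j) at the supplied effect-allele
  frequencies; a random-mating cohort rather than an unconstrained one.

Closed-form moments for both models make the simulator self-checking:
uniform gives E[S] = Σβ_j and Var[S] = (2/3)Σβ_j² (per-SNP dosage mean 1,
variance 2/3); HWE gives E[S] = Σ2p_jβ_j and Var[S] = Σ2p_j(1-p_j)β_j².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import EffectTable

MODELS = ("uniform", "hwe")


@dataclass
class NullSimSummary:
    n_sim: int
    mean: float
    variance: float  # sample variance, ddof=1
    min: float
    max: float
    seed: int
    model: str


def closed_form_moments(table: EffectTable, model: str = "uniform", freqs=None) -> dict:
    """Exact population mean and variance of the simulated score."""
    beta = table.betas
    if model == "uniform":
        return {"mean": float(beta.sum()), "variance": float((2.0 / 3.0) * (beta ** 2).sum())}
    if model == "hwe":
        p = _check_freqs(freqs, len(beta))
        return {
            "mean": float((2.0 * p * beta).sum()),
            "variance": float((2.0 * p * (1.0 - p) * beta ** 2).sum()),
        }
    raise ValidationError(f"unknown model {model!r}")


def _check_freqs(freqs, n: int) -> np.ndarray:
    if freqs is None:
        raise ValidationError("hwe model requires effect-allele frequencies")
    p = np.asarray(freqs, dtype=float)
    if p.shape != (n,):
        raise ValidationError(f"need one frequency per SNP ({n}), got shape {p.shape}")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValidationError("hwe frequencies must lie strictly in (0, 1)")
    return p


def simulate_null(
    table: EffectTable,
    n_sim: int = 1_000_000,
    model: str = "uniform",
    freqs=None,
    seed: int = 0,
    chunk_size: int = 4096,
    return_scores: bool = False,
):
    """Streaming summary of ``n_sim`` simulated null scores.

    Genotypes are drawn chunk by chunk in a fixed row-major order, so the
    simulated scores depend only on ``seed`` and ``n_sim``, not on
    ``chunk_size``. With ``return_scores`` the raw scores are also
    returned (intended for small n_sim: plotting and cross-checks).
    """
    if n_sim < 1:
        raise ValidationError("n_sim must be >= 1")
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}")
    beta = table.betas
    p_freq = _check_freqs(freqs, len(beta)) if model == "hwe" else None

    rng = np.random.default_rng(seed)
    n_done = 0
    mean = 0.0
    m2 = 0.0
    lo = np.inf
    hi = -np.inf
    kept: list[np.ndarray] = []
    while n_done < n_sim:
        k = min(chunk_size, n_sim - n_done)
        if model == "uniform":
            g = rng.integers(0, 3, size=(k, len(beta)))
        else:
            g = rng.binomial(2, p_freq, size=(k, len(beta)))
        scores = g.astype(float) @ beta
        if return_scores:
            kept.append(scores)
        # Chan et al. pairwise merge of (count, mean, M2)
        c_mean = float(scores.mean())
        c_m2 = float(((scores - c_mean) ** 2).sum())
        delta = c_mean - mean
        tot = n_done + k
        mean += delta * k / tot
        m2 += c_m2 + delta ** 2 * n_done * k / tot
        lo = min(lo, float(scores.min()))
        hi = max(hi, float(scores.max()))
        n_done = tot

    variance = m2 / (n_sim - 1) if n_sim > 1 else 0.0
    summary = NullSimSummary(n_sim, mean, variance, lo, hi, seed, model)
    if return_scores:
        return summary, np.concatenate(kept)
    return summary
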