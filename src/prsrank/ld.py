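"""Pairwise LD (r²) from genotype dosages and greedy tag-SNP selection.

Linkage disequilibrium is quantified as the squared Pearson correlation of
effect-allele dosage vectors across individuals — the composite (phase-free)
estimator, computable directly from unphased genotypes. One representative
"tag" SNP is then chosen per LD block by a deterministic greedy set cover:
a tag covers every SNP correlated with it at r² >= threshold, so each block
contributes a single association signal to downstream scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import ValidationError
from .io import EffectTable, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Symmetric r² matrix for one chromosome (or one undivided panel)."""

    snp_ids: list[str]
    r2: np.ndarray
    pos: np.ndarray = None  # 1-based positions, used for tag tie-breaking
    monomorphic: np.ndarray = field(default=None)  # zero-variance SNP flags

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        p = len(self.snp_ids)
        if self.r2.shape != (p, p):
            raise ValidationError("r2 matrix shape mismatch")
        if self.pos is None:
            self.pos = np.arange(1, p + 1)
        self.pos = np.asarray(self.pos)
        if self.monomorphic is None:
            self.monomorphic = np.zeros(p, dtype=bool)
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValidationError("r2 matrix not symmetric")
        if np.any(self.r2 < -1e-12) or np.any(self.r2 > 1 + 1e-12):
            raise ValidationError("r2 entries outside [0, 1]")


@dataclass
class TagSet:
    """Tags plus the map from each covered non-tag SNP to its covering tag."""

    tag_ids: list[str]
    cover_map: dict[str, str]

    def __len__(self) -> int:
        return len(self.tag_ids)


def _pairwise_r2(dosage: np.ndarray, missing: np.ndarray | None = None) -> np.ndarray:
    """Squared Pearson correlation between dosage columns.

    With missing data, each pair uses the individuals observed at both SNPs
    (pairwise-complete), assembled from O(p²) matrix products rather than a
    per-pair loop. Zero-variance (monomorphic) SNPs get r² = 0 off-diagonal.
    """
    X = np.asarray(dosage, dtype=float)
    n, p = X.shape
    if missing is None or not missing.any():
        sd = X.std(axis=0)
        ok = sd > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(X, rowvar=False)
        if p == 1:
            c = np.array([[1.0]])
        r2 = np.where(np.outer(ok, ok), np.nan_to_num(c, nan=0.0) ** 2, 0.0)
    else:
        M = (~missing).astype(float)
        X0 = np.where(missing, 0.0, X)
        n_ij = M.T @ M
        sx = X0.T @ M  # sum of x over rows complete in both
        sxx = (X0 ** 2).T @ M
        sxy = X0.T @ X0
        cov = n_ij * sxy - sx * sx.T
        var_x = n_ij * sxx - sx ** 2
        denom = var_x * var_x.T
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where((denom > 0) & (n_ij >= 2), cov ** 2 / np.where(denom > 0, denom, 1), 0.0)
        few = (n_ij < 2) & ~np.eye(p, dtype=bool)
        if few.any():
            logger.info("%d SNP pairs with <2 complete observations; r2 set to 0", int(few.sum() // 2))
    np.fill_diagonal(r2, 1.0)
    return np.clip(r2, 0.0, 1.0)


def compute_r2(
    geno: GenotypeMatrix,
    table: EffectTable | None = None,
    chrom_partition: bool = True,
) -> dict[str, LDMatrix]:
    """Per-chromosome composite r² matrices for a genotype panel.

    Chromosome and position come from ``table``; with no table (or with
    ``chrom_partition=False``) the whole panel is treated as one block keyed
    ``"all"``. Pairs on different chromosomes are never computed.
    """
    p = geno.n_snps
    if table is not None:
        sub = table.subset(geno.snp_ids).df.set_index("snp_id").loc[geno.snp_ids]
        chroms = sub["chrom"].to_numpy()
        pos = sub["pos"].to_numpy()
    else:
        chroms = np.array(["all"] * p)
        pos = np.arange(1, p + 1)
    if not chrom_partition:
        chroms = np.array(["all"] * p)

    mono = geno.dosage.std(axis=0) == 0
    if mono.any():
        logger.info("%d monomorphic SNPs flagged (r2 = 0)", int(mono.sum()))

    out: dict[str, LDMatrix] = {}
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        r2 = _pairwise_r2(geno.dosage[:, idx], geno.missing_mask[:, idx])
        out[chrom] = LDMatrix(
            [geno.snp_ids[i] for i in idx], r2, pos[idx], mono[idx]
        )
    return out


def greedy_tag(ld: LDMatrix | dict[str, LDMatrix], threshold: float = 0.8) -> TagSet:
    """Greedy maximum-coverage tag selection at an r² threshold.

    Repeatedly selects the SNP covering (r² >= threshold) the largest
    number of currently uncovered SNPs, breaking ties by lowest position
    then lexicographic id, until every SNP is covered. Each covered SNP is
    assigned to the first tag that covered it.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError(f"r2 threshold {threshold} outside (0, 1]")
    if isinstance(ld, dict):
        tags: list[str] = []
        cover: dict[str, str] = {}
        for mat in ld.values():
            ts = greedy_tag(mat, threshold)
            tags.extend(ts.tag_ids)
            cover.update(ts.cover_map)
        return TagSet(tags, cover)

    p = len(ld.snp_ids)
    adj = ld.r2 >= threshold
    np.fill_diagonal(adj, True)  # a SNP always covers itself
    uncovered = np.ones(p, dtype=bool)
    covered_by = np.full(p, -1, dtype=int)
    tag_idx: list[int] = []
    ids = np.array(ld.snp_ids)
    while uncovered.any():
        counts = adj[:, uncovered].sum(axis=1)
        best = counts.max()
        cand = np.flatnonzero(counts == best)
        # deterministic tie-break: lowest position, then lexicographic id
        order = np.lexsort((ids[cand], ld.pos[cand]))
        t = int(cand[order[0]])
        tag_idx.append(t)
        newly = adj[t] & uncovered
        covered_by[newly] = t
        uncovered &= ~newly
    tag_ids = [ld.snp_ids[t] for t in tag_idx]
    tag_set = set(tag_idx)
    cover_map = {
        ld.snp_ids[j]: ld.snp_ids[covered_by[j]]
        for j in range(p)
        if j not in tag_set
    }
    return TagSet(tag_ids, cover_map)


class LDTagger(BaseEstimator, TransformerMixin):
    """LD-pruning feature selector: keeps one tag SNP per LD block.

    Parameters
    ----------
    r2_threshold : float, default 0.8
        Pairwise r² at or above which two SNPs are considered one signal.
    chrom_partition : bool, default True
        Compute r² within chromosomes only (requires ``effect_table``).
    effect_table : EffectTable, optional
        Supplies chromosome and position metadata for the columns of X.

    Attributes
    ----------
    ld_ : dict of LDMatrix per chromosome
    tags_ : TagSet
    support_ : bool array marking tag columns of the input
    """

    def __init__(self, r2_threshold: float = 0.8, chrom_partition: bool = True,
                 effect_table: EffectTable | None = None):
        self.r2_threshold = r2_threshold
        self.chrom_partition = chrom_partition
        self.effect_table = effect_table

    def fit(self, X, y=None, snp_ids=None):
        geno = self._as_matrix(X, snp_ids)
        self.ld_ = compute_r2(geno, self.effect_table, self.chrom_partition)
        self.tags_ = greedy_tag(self.ld_, self.r2_threshold)
        tag_set = set(self.tags_.tag_ids)
        self.snp_ids_ = list(geno.snp_ids)
        self.support_ = np.array([s in tag_set for s in geno.snp_ids])
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, GenotypeMatrix):
            return X.subset_snps([s for s, k in zip(X.snp_ids, self.support_) if k])
        X = check_array(X)
        return X[:, self.support_]

    def _as_matrix(self, X, snp_ids) -> GenotypeMatrix:
        if isinstance(X, GenotypeMatrix):
            return X
        X = check_array(X)
        n, p = X.shape
        ids = list(snp_ids) if snp_ids is not None else [f"snp{j}" for j in range(p)]
        return GenotypeMatrix([f"i{i}" for i in range(n)], ids, X.astype(np.int8))


def write_tags(tags: TagSet, path) -> None:
    """Two-column TSV: snp_id, covering tag (tags cover themselves)."""
    with open(path, "w") as fh:
        fh.write("snp_id\ttag_id\n")
        for t in tags.tag_ids:
            fh.write(f"{t}\t{t}\n")
        for s, t in tags.cover_map.items():
            fh.write(f"{s}\t{t}\n")
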