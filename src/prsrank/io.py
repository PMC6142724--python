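"""Readers, writers and harmonization for effect tables, genotypes and phenotypes.

The central convention of the whole package is fixed here: genotypes are
stored as *effect-allele dosages* — the number of copies (0, 1 or 2) of the
allele whose count is multiplied by the per-allele effect size beta
(mm of height per allele). A VCF record whose REF/ALT orientation is
swapped relative to the effect table has its allele count flipped
(``2 - alt_count``) so that downstream code never needs to know how the
variant was represented on disk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: canonical effect-table column names; a "dialect" maps these to the
#: column names actually present in a file (e.g. GIANT's ``Allele1``).
EFFECT_COLUMNS = ("snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta")
OPTIONAL_EFFECT_COLUMNS = ("origin", "info")

ORIGINS = ("genotyped", "imputed", "unknown")

#: alleles whose complement equals the partner allele; ambiguous under
#: strand flips.
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class EffectTable:
    """Per-SNP effect sizes and alleles, in stable input order.

    ``df`` columns: snp_id, chrom, pos (1-based), effect_allele,
    other_allele, beta (mm per effect allele), origin
    (genotyped/imputed/unknown), info (imputation info score in [0,1],
    NaN when absent).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        for col in ("origin",):
            if col not in df.columns:
                df[col] = "unknown"
        if "info" not in df.columns:
            df["info"] = np.nan
        if "chrom" not in df.columns:
            df["chrom"] = "0"
        if "pos" not in df.columns:
            df["pos"] = np.arange(1, len(df) + 1)
        df["chrom"] = df["chrom"].astype(str)
        self.df = df
        self._validate()

    def _validate(self) -> None:
        df = self.df
        dup = df["snp_id"][df["snp_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate snp_id: {sorted(set(dup))}")
        if not np.all(np.isfinite(df["beta"].to_numpy(dtype=float))):
            raise ValidationError("non-finite beta")
        same = df["effect_allele"] == df["other_allele"]
        if same.any():
            raise ValidationError(
                f"effect_allele == other_allele for {list(df.loc[same, 'snp_id'])}"
            )
        bad_origin = ~df["origin"].isin(ORIGINS)
        if bad_origin.any():
            raise ValidationError(f"unknown origin value: {set(df.loc[bad_origin, 'origin'])}")
        info = df["info"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            out_of_range = (info < 0) | (info > 1)
        if np.any(out_of_range & ~np.isnan(info)):
            raise ValidationError("info score outside [0, 1]")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df["snp_id"])

    @property
    def betas(self) -> np.ndarray:
        return self.df["beta"].to_numpy(dtype=float)

    def subset(self, snp_ids) -> "EffectTable":
        """Rows for ``snp_ids``, keeping this table's order."""
        keep = self.df["snp_id"].isin(set(snp_ids))
        return EffectTable(self.df.loc[keep].reset_index(drop=True))

    def is_ambiguous(self) -> np.ndarray:
        """Strand-ambiguous (A/T or C/G) SNP mask."""
        ea = self.df["effect_allele"].str.upper()
        oa = self.df["other_allele"].str.upper()
        return (ea.map(_COMPLEMENT) == oa).fillna(False).to_numpy()

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs effect-allele dosages with a missingness mask."""

    individual_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray  # int8, (n_individuals, n_snps); 0 where missing
    missing_mask: np.ndarray = field(default=None)  # bool, same shape

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.missing_mask is None:
            self.missing_mask = np.zeros_like(self.dosage, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.dosage.shape
        if len(self.individual_ids) != n or len(self.snp_ids) != p:
            raise ValidationError("GenotypeMatrix dimensions inconsistent with id lists")
        if self.missing_mask.shape != (n, p):
            raise ValidationError("missing_mask shape mismatch")
        observed = self.dosage[~self.missing_mask]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValidationError("dosage outside {0,1,2}")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def row(self, individual_id: str) -> np.ndarray:
        i = self.individual_ids.index(individual_id)
        return self.dosage[i]

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return GenotypeMatrix(
            list(self.individual_ids),
            [self.snp_ids[i] for i in idx],
            self.dosage[:, idx].copy(),
            self.missing_mask[:, idx].copy(),
        )

    def imputed_dosage(self) -> np.ndarray:
        """Float dosage with missing cells mean-imputed per SNP.

        The cohort mean dosage of each SNP over its observed genotypes is
        substituted, the standard PRS convention that keeps scores
        comparable across individuals with different missingness.
        """
        d = self.dosage.astype(float)
        if not self.missing_mask.any():
            return d
        obs = ~self.missing_mask
        with np.errstate(invalid="ignore"):
            col_mean = np.where(
                obs.sum(axis=0) > 0,
                (d * obs).sum(axis=0) / np.maximum(obs.sum(axis=0), 1),
                0.0,
            )
        n_imputed = int(self.missing_mask.sum())
        if n_imputed:
            logger.info("mean-imputed %d missing genotype cells", n_imputed)
        return np.where(self.missing_mask, col_mean[None, :], d)


@dataclass
class PhenotypeTable:
    """Individual heights in cm."""

    df: pd.DataFrame  # columns: individual_id, height_cm

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        if df["individual_id"].duplicated().any():
            raise ValidationError("duplicate individual_id in phenotype table")
        if (df["height_cm"] <= 0).any():
            raise ValidationError("non-positive height")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_effect_table(path, dialect: dict | None = None) -> EffectTable:
    """Read a tab-separated effect-size table.

    Parameters
    ----------
    path
        TSV with a header row. Required columns (after dialect mapping):
        snp_id, effect_allele, other_allele, beta. Optional: chrom, pos,
        origin, info.
    dialect
        Mapping from canonical column name to the name used in the file,
        e.g. ``{"snp_id": "MarkerName", "beta": "b"}``.
    """
    dialect = dialect or {}
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    rename = {v: k for k, v in dialect.items()}
    raw = raw.rename(columns=rename)
    required = ("snp_id", "effect_allele", "other_allele", "beta")
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    beta = pd.to_numeric(raw["beta"], errors="coerce")
    bad = beta.isna() & raw["beta"].notna() | raw["beta"].isna()
    if bad.any():
        rows = [i + 2 for i in raw.index[bad]]  # 1-based incl. header
        raise FormatError(f"{path}: unparseable beta at row(s) {rows}")
    raw["beta"] = beta.astype(float)
    if "pos" in raw.columns:
        raw["pos"] = pd.to_numeric(raw["pos"]).astype(int)
    if "info" in raw.columns:
        raw["info"] = pd.to_numeric(raw["info"], errors="coerce")
    if "origin" in raw.columns:
        raw["origin"] = raw["origin"].fillna("unknown")
    return EffectTable(raw)


def filter_info(table: EffectTable, threshold: float = 0.4) -> EffectTable:
    """Drop imputed SNPs with imputation info score strictly below threshold.

    Only SNPs flagged ``imputed`` are candidates; directly genotyped SNPs
    and SNPs without an info score are always retained. Order is preserved
    and the operation is idempotent.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"info threshold {threshold} outside [0, 1]")
    df = table.df
    info = df["info"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        low = (df["origin"] == "imputed").to_numpy() & (info < threshold) & ~np.isnan(info)
    removed = int(low.sum())
    if removed:
        logger.info("info filter (<%g) removed %d imputed SNPs", threshold, removed)
    return EffectTable(df.loc[~low].reset_index(drop=True))


def _dosage_from_gt(gt: list) -> tuple[int, bool]:
    """(alt-allele count, missing) from a cyvcf2 genotype entry [a1, a2, phased]."""
    alleles = gt[:-1]
    if any(a < 0 for a in alleles):
        return 0, True
    return sum(1 for a in alleles if a == 1), False


def read_genotypes(path, table: EffectTable, drop_ambiguous: bool = False) -> GenotypeMatrix:
    """Extract effect-allele dosages for the table's SNPs from a VCF.

    Records are matched on chrom + pos + unordered allele pair (snp ids in
    VCFs drift across builds; they are used only for reporting). When the
    VCF's REF is the effect allele the raw ALT count is flipped to
    ``2 - count``. Multiallelic records and records whose allele pair
    matches neither orientation are skipped with a warning; table SNPs not
    found in the VCF are dropped with a logged count. Strand-ambiguous
    (A/T, C/G) SNPs are retained with a warning unless ``drop_ambiguous``.
    """
    from cyvcf2 import VCF

    ambiguous = dict(zip(table.snp_ids, table.is_ambiguous()))
    lookup: dict[tuple, tuple[str, str]] = {}
    pos_set: set[tuple] = set()
    for row in table.df.itertuples(index=False):
        key = (str(row.chrom), int(row.pos), frozenset((row.effect_allele, row.other_allele)))
        lookup[key] = (row.snp_id, row.effect_allele)
        pos_set.add(key[:2])

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for variant in vcf:
        if len(variant.ALT) != 1:
            if (str(variant.CHROM), int(variant.POS)) in pos_set:
                warnings.warn(
                    f"skipping multiallelic record at {variant.CHROM}:{variant.POS}"
                )
            continue
        ref, alt = variant.REF, variant.ALT[0]
        key = (str(variant.CHROM), int(variant.POS), frozenset((ref, alt)))
        if key not in lookup:
            if key[:2] in pos_set:
                warnings.warn(
                    f"allele pair {ref}/{alt} at {variant.CHROM}:{variant.POS} "
                    "matches neither orientation of the effect table; skipped"
                )
            continue
        snp_id, effect_allele = lookup[key]
        raw = np.empty(len(samples), dtype=np.int8)
        miss = np.zeros(len(samples), dtype=bool)
        for i, gt in enumerate(variant.genotypes):
            raw[i], miss[i] = _dosage_from_gt(gt)
        if effect_allele == ref:
            raw = np.where(miss, 0, 2 - raw).astype(np.int8)
        if ambiguous.get(snp_id, False):
            if drop_ambiguous:
                logger.info("dropping strand-ambiguous SNP %s", snp_id)
                continue
            warnings.warn(f"strand-ambiguous SNP {snp_id} retained")
        cols[snp_id] = (raw, miss)

    found = [s for s in table.snp_ids if s in cols]
    n_dropped = len(table) - len(found)
    if n_dropped:
        logger.info("%d table SNPs absent from %s; dropped", n_dropped, path)
    if not found:
        raise ValidationError(f"no effect-table SNPs found in {path}")
    dosage = np.column_stack([cols[s][0] for s in found])
    missing = np.column_stack([cols[s][1] for s in found])
    return GenotypeMatrix(samples, found, dosage, missing)


def read_phenotypes(path, dialect: dict | None = None) -> PhenotypeTable:
    """Read a two-column TSV of individual id and height in cm."""
    dialect = dialect or {}
    raw = pd.read_csv(path, sep="\t", dtype=str).rename(
        columns={v: k for k, v in dialect.items()}
    )
    missing = [c for c in ("individual_id", "height_cm") if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    raw["height_cm"] = pd.to_numeric(raw["height_cm"], errors="raise")
    return PhenotypeTable(raw[["individual_id", "height_cm"]])


def write_scores(scores: pd.Series, path) -> None:
    scores.rename("score_mm").rename_axis("individual_id").to_csv(path, sep="\t")


def write_vcf(geno: GenotypeMatrix, table: EffectTable, path, ref_is_effect=None) -> None:
    """Write dosages as a minimal VCF v4.2 with GT genotypes.

    ``ref_is_effect`` (bool array per SNP) controls whether REF is the
    effect allele; default False (ALT = effect allele, dosage = ALT count).
    Used for synthetic fixtures and round-trip tests.
    """
    sub = table.subset(geno.snp_ids)
    order = {s: i for i, s in enumerate(geno.snp_ids)}
    rows = sorted(sub.df.itertuples(index=False), key=lambda r: (r.chrom, r.pos))
    if ref_is_effect is None:
        ref_is_effect = np.zeros(geno.n_snps, dtype=bool)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(r.chrom for r in rows):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.individual_ids)
            + "\n"
        )
        for r in rows:
            j = order[r.snp_id]
            if ref_is_effect[j]:
                ref, alt = r.effect_allele, r.other_allele
                alt_count = 2 - geno.dosage[:, j]
            else:
                ref, alt = r.other_allele, r.effect_allele
                alt_count = geno.dosage[:, j]
            gts = []
            for i in range(geno.n_individuals):
                if geno.missing_mask[i, j]:
                    gts.append("./.")
                else:
                    c = int(alt_count[i])
                    gts.append(("0/0", "0/1", "1/1")[c])
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.snp_id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
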