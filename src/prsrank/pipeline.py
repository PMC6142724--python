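"""End-to-end orchestration: filter -> genotypes -> LD tagging -> scoring ->
ranking -> composition -> bootstrap -> null simulation -> correlation.

Every random stage carries an explicit seed so two runs with the same
configuration produce byte-identical numeric artifacts. Per-stage SNP
counts are written to a structured key=value log.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import bootstrap as bt
from . import composition as cs
from . import io as pio
from . import nullsim as ns
from . import scoring as sc
from .errors import ValidationError
from .ld import LDTagger, write_tags
from .synth import SynthConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and seeds for a full pipeline run."""

    out_dir: str = "prsrank_run"
    effect_table: str | None = None
    vcf: str | None = None
    phenotypes: str | None = None
    focal: str | None = None
    info_threshold: float = 0.4
    r2_threshold: float = 0.8
    bootstrap_sizes: tuple = bt.DEFAULT_SIZES
    bootstrap_reps: int = 10_000
    null_n_sim: int = 1_000_000
    null_model: str = "uniform"
    seed: int = 0
    synth: dict = field(default_factory=dict)  # non-empty -> synthesize inputs

    def __post_init__(self) -> None:
        if not 0 <= self.info_threshold <= 1:
            raise ValidationError("info_threshold outside [0, 1]")
        if not 0 < self.r2_threshold <= 1:
            raise ValidationError("r2_threshold outside (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _log_line(fh, **kv) -> None:
    stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    fh.write(stamp + " " + " ".join(f"{k}={v}" for k, v in kv.items()) + "\n")
    fh.flush()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages, writing artifacts into ``cfg.out_dir``.

    Returns the run directory. Any stage failure raises with the stage
    name in the message.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = open(out / "run.log", "w")
    stage = "setup"
    try:
        if cfg.synth:
            stage = "synth"
            scfg = SynthConfig(**{**cfg.synth, "seed": cfg.synth.get("seed", cfg.seed)})
            table, geno, pheno, focal = generate_cohort(scfg)
            freqs = geno.allele_freqs
            _log_line(log, stage=stage, n_snps=len(table), n_individuals=geno.n_individuals)
        else:
            if not (cfg.effect_table and cfg.vcf and cfg.focal):
                raise ValidationError("need effect_table, vcf and focal (or a synth block)")
            stage = "read_effect_table"
            table = pio.read_effect_table(cfg.effect_table)
            _log_line(log, stage=stage, n_snps=len(table))
            focal = cfg.focal
            pheno = pio.read_phenotypes(cfg.phenotypes) if cfg.phenotypes else None
            freqs = None

        stage = "filter_info"
        table = pio.filter_info(table, cfg.info_threshold)
        _log_line(log, stage=stage, n_snps=len(table))
        table.to_tsv(out / "effect_table.filtered.tsv")

        if not cfg.synth:
            stage = "read_genotypes"
            geno = pio.read_genotypes(cfg.vcf, table)
            _log_line(log, stage=stage, n_snps=geno.n_snps, n_individuals=geno.n_individuals)

        stage = "ld_tagging"
        tagger = LDTagger(cfg.r2_threshold, effect_table=table).fit(geno)
        geno_tagged = tagger.transform(geno)
        table_tagged = table.subset(geno_tagged.snp_ids)
        write_tags(tagger.tags_, out / "tags.tsv")
        _log_line(log, stage=stage, n_tags=len(tagger.tags_), n_snps_in=geno.n_snps)

        stage = "scoring"
        scores = sc.compute_scores(geno_tagged, table_tagged)
        pio.write_scores(scores, out / "scores.tsv")
        stats = sc.cohort_stats(scores.drop(index=focal))
        rank = sc.rank_percentile(scores, focal)
        zs = sc.zscore(float(scores.loc[focal]), stats.mean, stats.sd)
        with open(out / "rank.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "focal": focal,
                    "score_mm": float(scores.loc[focal]),
                    "percentile": rank.percentile,
                    "is_highest": bool(rank.is_highest),
                    "cohort_mean": stats.mean,
                    "cohort_sd": stats.sd,
                    "zscore": zs,
                    "n_comparison": stats.n,
                },
                fh,
            )
        _log_line(log, stage=stage, n_scored=len(scores), focal_percentile=rank.percentile)

        stage = "composition"
        dec = cs.decompose(geno_tagged.row(focal), table_tagged)
        dec.to_tsv(out / "decomposition.tsv")
        avg = cs.average_decomposition(geno_tagged, table_tagged)
        expected = avg.counts.to_numpy().ravel().astype(float)
        gof = cs.gof_test(dec.counts.to_numpy().ravel(), expected / expected.sum())
        with open(out / "gof.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "chi2": gof.chi2,
                    "df": gof.df,
                    "p": gof.p,
                    "excess_homozygotes": cs.excess_homozygotes(dec),
                },
                fh,
            )
        _log_line(log, stage=stage, chi2=f"{gof.chi2:.4g}", p=f"{gof.p:.4g}")

        stage = "bootstrap"
        sizes = [m for m in cfg.bootstrap_sizes if m <= geno_tagged.n_snps]
        if not sizes:
            raise ValidationError(
                f"bootstrap sizes {list(cfg.bootstrap_sizes)} all exceed panel of "
                f"{geno_tagged.n_snps} SNPs"
            )
        if len(sizes) < len(cfg.bootstrap_sizes):
            logger.warning("dropped bootstrap sizes exceeding the panel")
        ranks = bt.bootstrap_rank(
            geno_tagged, table_tagged, focal, sizes, cfg.bootstrap_reps, seed=cfg.seed
        )
        ranks.to_tsv(out / "bootstrap_percentiles.tsv")
        _log_line(log, stage=stage, sizes=",".join(map(str, sizes)), reps=cfg.bootstrap_reps)

        stage = "null_simulation"
        model = cfg.null_model
        null_freqs = freqs if model == "hwe" else None
        if model == "hwe" and null_freqs is None:
            null_freqs = np.clip(geno_tagged.imputed_dosage().mean(axis=0) / 2, 1e-6, 1 - 1e-6)
        summ = ns.simulate_null(
            table_tagged, cfg.null_n_sim, model, freqs=null_freqs, seed=cfg.seed
        )
        with open(out / "null_simulation.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "n_sim": summ.n_sim,
                    "model": summ.model,
                    "mean": summ.mean,
                    "variance": summ.variance,
                    "min": summ.min,
                    "max": summ.max,
                    "observed_mean": stats.mean,
                    "observed_minus_simulated_mean": stats.mean - summ.mean,
                    "focal_minus_simulated_max": float(scores.loc[focal]) - summ.max,
                },
                fh,
            )
        _log_line(log, stage=stage, n_sim=summ.n_sim, sim_mean=f"{summ.mean:.4g}")

        if pheno is not None:
            stage = "correlation"
            corr = cs.pearson_correlation(scores.drop(index=focal, errors="ignore"), pheno)
            with open(out / "correlation.yaml", "w") as fh:
                yaml.safe_dump(corr, fh)
            _log_line(log, stage=stage, r=f"{corr['r']:.4f}", p=f"{corr['p']:.4g}")

        cfg_dict = dataclasses.asdict(cfg)
        cfg_dict["bootstrap_sizes"] = list(cfg_dict["bootstrap_sizes"])
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg_dict, fh)
        _log_line(log, stage="done", out_dir=str(out))
        return out
    except Exception as exc:
        _log_line(log, stage=stage, error=repr(exc))
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    finally:
        log.close()
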