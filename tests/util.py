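"""Shared builders for small in-memory fixtures."""

from __future__ import annotations

import numpy as np
import pandas as pd

from prsrank import EffectTable, GenotypeMatrix

ALLELE_CYCLE = [("A", "G"), ("T", "C"), ("A", "C"), ("T", "G")]


def make_table(betas, origins=None, infos=None, chroms=None, pos=None) -> EffectTable:
    n = len(betas)
    return EffectTable(
        pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(n)],
                "chrom": chroms if chroms is not None else ["1"] * n,
                "pos": pos if pos is not None else np.arange(1, n + 1) * 1000,
                "effect_allele": [ALLELE_CYCLE[i % 4][0] for i in range(n)],
                "other_allele": [ALLELE_CYCLE[i % 4][1] for i in range(n)],
                "beta": list(betas),
                "origin": origins if origins is not None else ["genotyped"] * n,
                "info": infos if infos is not None else [np.nan] * n,
            }
        )
    )


def make_geno(dosage, missing=None, snp_ids=None) -> GenotypeMatrix:
    dosage = np.asarray(dosage, dtype=np.int8)
    n, p = dosage.shape
    return GenotypeMatrix(
        [f"ind{i}" for i in range(n)],
        snp_ids if snp_ids is not None else [f"rs{j}" for j in range(p)],
        dosage,
        missing,
    )
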