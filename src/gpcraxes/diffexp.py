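"""Tumor-vs-normal differential expression.

The pipeline's primary path is importing DE tables computed by any
engine (gene, lfc, pvalue, padj).  The internal stage implemented here
is a deliberately simple, fully documented procedure: median-of-ratios
size-factor normalization, log2 transform with pseudocount 1, a Welch
two-sample t-test per gene, and Benjamini-Hochberg adjustment per
contrast.  It exists so the whole pipeline is exercisable without an
external engine, not to replace negative-binomial modeling; dispersion
or fold-change shrinkage is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from gpcraxes.errors import DegenerateInputError, SchemaError

PSEUDOCOUNT = 1.0

#: printed significance thresholds used pipeline-wide
LFC_CUT = 1.0
PADJ_CUT = 0.01


@dataclass
class CountMatrix:
    """Gene x sample raw count matrix with per-sample metadata.

    ``counts`` is indexed by gene symbol with sample-id columns;
    ``sample_meta`` is indexed by sample id and carries at least
    ``cohort`` (tumor/normal), ``tissue`` and ``subtype`` columns.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise SchemaError("counts must be nonnegative")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise SchemaError(f"samples without metadata: {sorted(missing)[:5]}")
        for col in ("cohort", "tissue"):
            if col not in self.sample_meta.columns:
                raise SchemaError(f"sample_meta missing column {col!r}")
        bad = set(self.sample_meta["cohort"]) - {"tumor", "normal"}
        if bad:
            raise SchemaError(f"unknown cohort labels {sorted(bad)}")

    def subset(self, tissue: str | None = None, subtype: str | None = None) -> "CountMatrix":
        meta = self.sample_meta.loc[self.counts.columns]
        mask = pd.Series(True, index=meta.index)
        if tissue is not None:
            mask &= meta["tissue"] == tissue
        if subtype is not None and subtype != "all":
            mask &= meta["subtype"] == subtype
        samples = meta.index[mask]
        return CountMatrix(self.counts[samples], self.sample_meta.loc[samples])

    @classmethod
    def from_tsv(cls, counts_path: str | Path, meta_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", comment="#", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", comment="#", index_col=0, dtype=str)
        return cls(counts, meta)

    def to_tsv(self, counts_path: str | Path, meta_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene")
        self.sample_meta.loc[self.counts.columns].to_csv(meta_path, sep="\t", index_label="sample")


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with a nonzero count in every sample; the
    per-sample factor is the median over reference genes of
    count / geometric-mean(count across samples).
    """
    counts = cm.counts.to_numpy(dtype=float)
    reference = (counts > 0).all(axis=1)
    if not reference.any():
        raise DegenerateInputError(
            "no gene has nonzero counts in all samples; consider a pseudocount mode"
        )
    ref = counts[reference]
    geomean = np.exp(np.log(ref).mean(axis=1, keepdims=True))
    factors = np.median(ref / geomean, axis=0)
    return pd.Series(factors, index=cm.counts.columns, name="size_factor")


def normalized_counts(cm: CountMatrix) -> pd.DataFrame:
    return cm.counts / size_factors(cm)


def adjust_pvalues(pvalues: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Missing values are ignored (returned as NaN, not counted in m);
    adjusted values are capped at 1.  Raises on values outside [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def differential_expression(
    cm: CountMatrix,
    tissue: str | None = None,
    subtype: str | None = None,
) -> pd.DataFrame:
    """Per-gene tumor-vs-normal DE table for one contrast.

    Returns a DataFrame with columns gene, lfc, pvalue, padj.  lfc is
    the difference of group means of log2(normalized + 1), tumor minus
    normal; pvalue is a Welch t-test on the same values; padj is BH over
    all genes tested within the contrast.  Genes with zero counts in
    every sample get NaN lfc and are excluded from adjustment.
    """
    sub = cm.subset(tissue=tissue, subtype=subtype)
    cohorts = sub.sample_meta.loc[sub.counts.columns, "cohort"]
    n_tumor = int((cohorts == "tumor").sum())
    n_normal = int((cohorts == "normal").sum())
    if n_tumor < 2 or n_normal < 2:
        group = "tumor" if n_tumor < 2 else "normal"
        raise DegenerateInputError(
            f"need >=2 samples per group; group {group!r} has too few "
            f"(tumor={n_tumor}, normal={n_normal})"
        )

    log_norm = np.log2(normalized_counts(sub) + PSEUDOCOUNT)
    tumor = log_norm.loc[:, cohorts == "tumor"].to_numpy()
    normal = log_norm.loc[:, cohorts == "normal"].to_numpy()

    lfc = tumor.mean(axis=1) - normal.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvalue = stats.ttest_ind(tumor, normal, axis=1, equal_var=False)

    all_zero = (sub.counts.to_numpy() == 0).all(axis=1)
    lfc = np.where(all_zero, np.nan, lfc)
    pvalue = np.where(all_zero, np.nan, pvalue)

    return pd.DataFrame(
        {
            "gene": sub.counts.index,
            "lfc": lfc,
            "pvalue": pvalue,
            "padj": adjust_pvalues(pvalue),
        }
    )


def significant_genes(
    de: pd.DataFrame, lfc_cut: float = LFC_CUT, padj_cut: float = PADJ_CUT
) -> tuple[set[str], set[str]]:
    """Partition genes into (up, down) at the strict |lfc| and padj cuts."""
    ok = de["padj"] < padj_cut
    up = set(de.loc[ok & (de["lfc"] > lfc_cut), "gene"])
    down = set(de.loc[ok & (de["lfc"] < -lfc_cut), "gene"])
    return up, down


def read_de_table(path: str | Path) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("gene", "lfc", "pvalue", "padj") if c not in de.columns]
    if missing:
        raise SchemaError(f"DE table {path}: missing columns {missing}")
    return de


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index=False, float_format="%.10g")
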