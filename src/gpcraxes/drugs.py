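"""Growth-inhibitory GPCR drug calling from pooled viability screens.

A drug's response profile is its log2 fold change in cell counts across
cell lines (negative = growth inhibition).  A drug is called *active*
when its replicate-replicate Pearson correlation exceeds 0.2 and the
bimodality coefficient of its LFC profile exceeds 0.35 — a bimodal
profile separates sensitive from insensitive lines, while a reproducible
unimodal profile is consistent with uniform (in)activity.

The bimodality coefficient is Sarle's sample-adjusted statistic

    b = (g1^2 + 1) / (g2 + 3(n-1)^2 / ((n-2)(n-3)))

with g1 the bias-corrected sample skewness and g2 the bias-corrected
excess kurtosis; b is near 1/3 for a normal sample, 5/9 for a uniform
one, and approaches 1 for a balanced two-point mixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from gpcraxes.errors import DegenerateInputError, SchemaError

logger = logging.getLogger(__name__)

CORR_THRESHOLD = 0.2
BC_THRESHOLD = 0.35
TOP_K = 10
MIN_CELL_LINES = 4


@dataclass
class DrugResponsePanel:
    """Drug x cell-line viability LFC matrix with replicates and metadata.

    ``lfc`` is the consolidated (replicate-averaged) matrix indexed by
    drug with cell-line columns; ``replicates`` holds the >=2 per-
    replicate matrices with the same shape.  ``drug_meta`` is indexed by
    drug with columns targets (set of gene symbols), moa, action;
    ``cell_meta`` is indexed by cell line with a tissue column.
    """

    lfc: pd.DataFrame
    replicates: list[pd.DataFrame] = field(default_factory=list)
    drug_meta: pd.DataFrame = None
    cell_meta: pd.DataFrame = None

    def __post_init__(self) -> None:
        if self.drug_meta is None or self.cell_meta is None:
            raise SchemaError("drug_meta and cell_meta are required")
        missing = set(self.lfc.index) - set(self.drug_meta.index)
        if missing:
            raise SchemaError(f"drugs without metadata: {sorted(missing)[:5]}")
        missing = set(self.lfc.columns) - set(self.cell_meta.index)
        if missing:
            raise SchemaError(f"cell lines without tissue label: {sorted(missing)[:5]}")
        for rep in self.replicates:
            if rep.shape != self.lfc.shape:
                raise SchemaError("replicate matrices must match the consolidated shape")


def bimodality_coefficient(values: Iterable[float]) -> float:
    """Sarle's sample bimodality coefficient.

    Requires n >= 4 non-missing values with positive variance; invariant
    to affine transforms of the data.
    """
    x = np.asarray([v for v in np.asarray(list(values), dtype=float) if not np.isnan(v)])
    n = len(x)
    if n < 4:
        raise DegenerateInputError(f"bimodality coefficient needs n >= 4, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero variance")
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, fisher=True, bias=False)
    return float((g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def activity_calls(
    panel: DrugResponsePanel,
    corr_threshold: float = CORR_THRESHOLD,
    bc_threshold: float = BC_THRESHOLD,
) -> pd.DataFrame:
    """Per-drug activity calls from replicate correlation and bimodality.

    Correlation is the Pearson r between the first two replicate LFC
    vectors across cell lines (pairwise-complete); bimodality is
    computed on the consolidated LFC vector with missing entries
    dropped.  Active iff correlation > threshold AND bimodality >
    threshold (both strict).  Drugs with fewer than four scored cell
    lines are flagged missing.
    """
    if len(panel.replicates) < 2:
        raise SchemaError("activity calls need >=2 replicate matrices")
    rep1, rep2 = panel.replicates[0], panel.replicates[1]
    records = []
    for drug in panel.lfc.index:
        vals = panel.lfc.loc[drug].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        r1 = rep1.loc[drug].to_numpy(dtype=float)
        r2 = rep2.loc[drug].to_numpy(dtype=float)
        both = ~np.isnan(r1) & ~np.isnan(r2)
        if ok.sum() < MIN_CELL_LINES or both.sum() < MIN_CELL_LINES:
            records.append(
                {"drug": drug, "correlation": np.nan, "bimodality": np.nan, "active": pd.NA}
            )
            continue
        try:
            bc = bimodality_coefficient(vals[ok])
        except DegenerateInputError:
            records.append(
                {"drug": drug, "correlation": np.nan, "bimodality": np.nan, "active": pd.NA}
            )
            continue
        corr = float(stats.pearsonr(r1[both], r2[both])[0])
        records.append(
            {
                "drug": drug,
                "correlation": corr,
                "bimodality": bc,
                "active": bool(corr > corr_threshold and bc > bc_threshold),
            }
        )
    return pd.DataFrame(records).set_index("drug")


def top_inhibitors(
    panel: DrugResponsePanel, k: int = TOP_K
) -> tuple[dict[str, list[str]], pd.DataFrame, pd.DataFrame]:
    """Top growth-inhibiting drugs per cell line and tissue summaries.

    Per cell line, drugs are ranked by ascending LFC (most negative =
    strongest inhibition; ties break on drug id) and the first ``k``
    kept.  The tissue summaries count, for each (tissue, moa) and
    (tissue, target), in how many of the tissue's cell lines that
    mechanism/target appears among the top-k drugs; the target table
    also carries the count normalized by the tissue's total cell
    line-drug pairs.
    """
    per_line: dict[str, list[str]] = {}
    for cl in panel.lfc.columns:
        col = panel.lfc[cl].dropna()
        ranked = sorted(col.items(), key=lambda kv: (kv[1], kv[0]))
        per_line[cl] = [d for d, _ in ranked[:k]]

    moa_rows: list[dict] = []
    target_rows: list[dict] = []
    tissue_of = panel.cell_meta["tissue"].to_dict()
    moa_counts: dict[tuple[str, str], int] = {}
    target_counts: dict[tuple[str, str], int] = {}
    pairs_per_tissue: dict[str, int] = {}
    for cl, drugs_k in per_line.items():
        tissue = tissue_of[cl]
        pairs_per_tissue[tissue] = pairs_per_tissue.get(tissue, 0) + len(drugs_k)
        moas = {panel.drug_meta.loc[d, "moa"] for d in drugs_k}
        targets = set()
        for d in drugs_k:
            targets |= set(panel.drug_meta.loc[d, "targets"])
        for m in moas:
            moa_counts[(tissue, m)] = moa_counts.get((tissue, m), 0) + 1
        for t in targets:
            target_counts[(tissue, t)] = target_counts.get((tissue, t), 0) + 1

    moa_df = pd.DataFrame(
        [{"tissue": t, "moa": m, "n_cell_lines": c} for (t, m), c in sorted(moa_counts.items())]
    )
    target_df = pd.DataFrame(
        [
            {
                "tissue": t,
                "target": g,
                "n_cell_lines": c,
                "normalized": c / pairs_per_tissue[t],
            }
            for (t, g), c in sorted(target_counts.items())
        ]
    )
    return per_line, moa_df, target_df


def survival_target_overlap(
    calls: pd.DataFrame,
    drug_meta: pd.DataFrame,
    survival_receptors: set[str],
) -> dict:
    """Intersect active drugs' targets with survival-associated receptors.

    Returns per-drug overlapping target sets for active drugs plus the
    Venn partition sizes of (all active-drug targets) vs the pooled
    survival receptor set.
    """
    if not survival_receptors:
        raise ValueError("survival_receptors must be non-empty")
    active_drugs = [
        d for d in calls.index if not pd.isna(calls.loc[d, "active"]) and bool(calls.loc[d, "active"])
    ]
    per_drug = {
        d: sorted(set(drug_meta.loc[d, "targets"]) & survival_receptors) for d in active_drugs
    }
    all_targets: set[str] = set()
    for d in active_drugs:
        all_targets |= set(drug_meta.loc[d, "targets"])
    return {
        "per_drug": per_drug,
        "n_active": len(active_drugs),
        "n_active_overlapping": sum(1 for d in active_drugs if per_drug[d]),
        "targets_only": len(all_targets - survival_receptors),
        "survival_only": len(survival_receptors - all_targets),
        "intersection": len(all_targets & survival_receptors),
    }


# ---------------------------------------------------------------------------
# TSV input/output


def load_panel(panel_path, drug_meta_path, cell_meta_path) -> DrugResponsePanel:
    """Read the long-format panel table (drug, cell_line, lfc, replicate)
    plus drug and cell-line metadata tables."""
    long = pd.read_csv(panel_path, sep="\t", comment="#")
    meta = pd.read_csv(drug_meta_path, sep="\t", comment="#", index_col="drug")
    meta["targets"] = meta["targets"].fillna("").map(
        lambda s: frozenset(t for t in str(s).split(";") if t)
    )
    cell_meta = pd.read_csv(cell_meta_path, sep="\t", comment="#", index_col="cell_line")
    reps = []
    for r, block in sorted(long.groupby("replicate")):
        reps.append(block.pivot(index="drug", columns="cell_line", values="lfc"))
    lfc = sum(reps) / len(reps)
    return DrugResponsePanel(lfc=lfc, replicates=reps, drug_meta=meta, cell_meta=cell_meta)


def write_panel(panel: DrugResponsePanel, panel_path, drug_meta_path, cell_meta_path) -> None:
    rows = []
    for i, rep in enumerate(panel.replicates, start=1):
        melted = rep.reset_index().melt(id_vars="drug", var_name="cell_line", value_name="lfc")
        melted["replicate"] = i
        rows.append(melted)
    pd.concat(rows).to_csv(panel_path, sep="\t", index=False, float_format="%.10g")
    meta = panel.drug_meta.copy()
    meta["targets"] = meta["targets"].map(lambda s: ";".join(sorted(s)))
    meta.to_csv(drug_meta_path, sep="\t", index_label="drug")
    panel.cell_meta.to_csv(cell_meta_path, sep="\t", index_label="cell_line")
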