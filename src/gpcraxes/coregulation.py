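"""Co-differential regulation of axis partners across cancer subtypes.

Each (receptor, partner) axis gets an integer score per subtype:

* +2 / -2 — both genes pass |LFC| > 1 in the same direction and both
  are significant (adjusted p < 0.01);
* +1 / -1 — both pass the fold-change cut in the same direction but
  only one is significant;
* 0 — anti-regulation, sub-threshold fold change, or neither gene
  significant.

The resulting pair x subtype matrix is filtered for recurrence, Ward-
clustered, summarized per receptor (ligand-wise / tissue-wise profile
similarity), tested for expression correlation against a random-pair
background, and intersected with subtype mutation signatures.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from gpcraxes.diffexp import LFC_CUT, PADJ_CUT, adjust_pvalues
from gpcraxes.errors import DegenerateInputError

logger = logging.getLogger(__name__)

RECURRENCE_FRACTION = 0.25

AxisPair = tuple[str, str, str]  # (receptor, partner, partner_kind)


def code_score(
    de_r: tuple[float, float],
    de_p: tuple[float, float],
    lfc_cut: float = LFC_CUT,
    padj_cut: float = PADJ_CUT,
) -> int:
    """Five-level co-differential-expression score for one axis in one
    subtype.  Arguments are (lfc, padj) for the receptor and partner;
    missing values score 0.  Symmetric in its two arguments and odd
    under a joint sign flip of both fold changes."""
    lfc_r, padj_r = de_r
    lfc_p, padj_p = de_p
    if any(x is None or (isinstance(x, float) and math.isnan(x)) for x in (lfc_r, padj_r, lfc_p, padj_p)):
        return 0
    if abs(lfc_r) <= lfc_cut or abs(lfc_p) <= lfc_cut:
        return 0
    if lfc_r * lfc_p < 0:
        return 0
    sign = 1 if lfc_r > 0 else -1
    n_sig = int(padj_r < padj_cut) + int(padj_p < padj_cut)
    if n_sig == 2:
        return 2 * sign
    if n_sig == 1:
        return sign
    return 0


def build_code_matrix(
    de_tables: Mapping[str, pd.DataFrame],
    pairs: Sequence[AxisPair],
    recurrence_fraction: float = RECURRENCE_FRACTION,
    lfc_cut: float = LFC_CUT,
    padj_cut: float = PADJ_CUT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every axis in every subtype.

    Returns ``(full, filtered)`` DataFrames indexed by
    (receptor, partner, partner_kind) with one integer column per
    subtype.  ``filtered`` keeps the "affected" axes: nonzero score in
    at least ``recurrence_fraction`` of subtypes (inclusive boundary).
    Genes absent from a subtype's DE table score 0 there.
    """
    if not de_tables:
        raise ValueError("need at least one subtype DE table")
    subtypes = list(de_tables)
    lookups = {
        s: de.set_index("gene")[["lfc", "padj"]].to_dict("index") for s, de in de_tables.items()
    }
    rows = []
    for receptor, partner, kind in pairs:
        row = []
        for s in subtypes:
            lut = lookups[s]
            rec, par = lut.get(receptor), lut.get(partner)
            if rec is None or par is None:
                logger.debug("pair (%s, %s) missing from DE table %s; scored 0", receptor, partner, s)
                row.append(0)
                continue
            row.append(
                code_score(
                    (rec["lfc"], rec["padj"]), (par["lfc"], par["padj"]), lfc_cut, padj_cut
                )
            )
        rows.append(row)
    index = pd.MultiIndex.from_tuples(pairs, names=["receptor", "partner", "partner_kind"])
    full = pd.DataFrame(rows, index=index, columns=subtypes, dtype=int)
    affected = (full != 0).sum(axis=1) / len(subtypes) >= recurrence_fraction
    return full, full.loc[affected]


def cluster_pairs(matrix: pd.DataFrame, n_clusters: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Ward hierarchical clustering of score rows (Euclidean metric).

    Returns integer cluster labels (1..n_clusters, deterministic for a
    given row order) and the linkage matrix with merge heights.
    """
    if len(matrix) < n_clusters:
        raise DegenerateInputError(
            f"cannot form {n_clusters} clusters from {len(matrix)} pairs"
        )
    Z = linkage(matrix.to_numpy(dtype=float), method="ward")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return labels, Z


def similarity_profiles(
    matrix: pd.DataFrame,
    subtype_tissue: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Receptor-centric summary of co-DE profile diversity.

    Per receptor: ``ligand_wise`` is the mean pairwise Euclidean
    distance between its partners' score vectors across subtypes
    (0 when it has a single partner); ``tissue_wise`` applies the same
    metric horizontally after averaging subtype columns within each
    tissue (distances between per-tissue vectors across partners);
    ``updown_balance`` is the mean, over partners, of the count of +2
    entries minus the count of -2 entries.
    """
    records = []
    for receptor, block in matrix.groupby(level="receptor", sort=True):
        rows = block.to_numpy(dtype=float)
        n_lig = rows.shape[0]
        if n_lig >= 2:
            dists = [
                float(np.linalg.norm(rows[i] - rows[j])) for i, j in combinations(range(n_lig), 2)
            ]
            ligand_wise = float(np.mean(dists))
        else:
            ligand_wise = 0.0

        tissue_wise = 0.0
        if subtype_tissue is not None:
            tissues = sorted({subtype_tissue[s] for s in matrix.columns})
            cols = np.column_stack(
                [
                    block[[s for s in matrix.columns if subtype_tissue[s] == t]]
                    .mean(axis=1)
                    .to_numpy()
                    for t in tissues
                ]
            )
            if len(tissues) >= 2:
                tissue_wise = float(
                    np.mean(
                        [
                            np.linalg.norm(cols[:, i] - cols[:, j])
                            for i, j in combinations(range(len(tissues)), 2)
                        ]
                    )
                )
        updown = float(np.mean(((rows == 2).sum(axis=1) - (rows == -2).sum(axis=1))))
        records.append(
            {
                "receptor": receptor,
                "tissue_wise": tissue_wise,
                "ligand_wise": ligand_wise,
                "n_ligands": n_lig,
                "updown_balance": updown,
            }
        )
    return pd.DataFrame(records).set_index("receptor")


def correlation_calls(
    expr: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    n_background: int = 1000,
    seed: int = 0,
    q_cut: float = 0.05,
    r_cut: float = 0.25,
) -> pd.DataFrame:
    """Pairwise expression correlation vs a random-pair background.

    ``expr`` is a normalized gene x sample matrix for one subtype.  For
    each tested pair the Pearson r across samples is compared to the r
    distribution of ``n_background`` gene pairs sampled uniformly
    without replacement (excluding the tested pairs); one shared
    background is drawn per matrix.  t_p is the two-sided tail
    probability of drawing a background correlation at least as far
    from the background mean as r (a t-score against the background
    standard deviation, not the standard error of its mean — the test
    asks whether r is an outlier with respect to the background
    population).  A pair is called correlated when the BH-adjusted p is
    below ``q_cut`` and |r| exceeds ``r_cut``.  Pairs containing a
    zero-variance gene are flagged missing.
    """
    if expr.shape[1] < 3:
        raise DegenerateInputError("need >=3 samples for correlation analysis")
    rng = np.random.default_rng(seed)
    genes = list(expr.index)
    values = expr.to_numpy(dtype=float)
    var = values.var(axis=1)
    idx = {g: i for i, g in enumerate(genes)}

    tested = {frozenset(p) for p in pairs}
    candidates = [i for i in range(len(genes)) if var[i] > 0]
    background: list[float] = []
    seen: set[frozenset[int]] = set()
    max_draws = 100 * n_background
    draws = 0
    while len(background) < n_background and draws < max_draws:
        draws += 1
        i, j = rng.choice(len(candidates), size=2, replace=False)
        gi, gj = candidates[i], candidates[j]
        key = frozenset((genes[gi], genes[gj]))
        ikey = frozenset((gi, gj))
        if key in tested or ikey in seen:
            continue
        seen.add(ikey)
        background.append(float(stats.pearsonr(values[gi], values[gj])[0]))
    background_arr = np.asarray(background)

    bg_mean = float(background_arr.mean())
    bg_sd = float(background_arr.std(ddof=1))
    df = len(background_arr) - 1

    records = []
    for a, b in pairs:
        if a not in idx or b not in idx or var[idx[a]] == 0 or var[idx[b]] == 0:
            records.append({"gene_a": a, "gene_b": b, "r": np.nan, "t_p": np.nan})
            continue
        r = float(stats.pearsonr(values[idx[a]], values[idx[b]])[0])
        t_p = float(2.0 * stats.t.sf(abs(r - bg_mean) / bg_sd, df=df))
        records.append({"gene_a": a, "gene_b": b, "r": r, "t_p": t_p})
    out = pd.DataFrame(records)
    out["q"] = adjust_pvalues(out["t_p"].to_numpy())
    out["correlated"] = pd.array(
        (out["q"] < q_cut) & (out["r"].abs() > r_cut), dtype="boolean"
    )
    out.loc[out["r"].isna(), "correlated"] = pd.NA
    return out


def concordance_prevalence(
    de_tables: Mapping[str, pd.DataFrame],
    pairs: Sequence[AxisPair],
    lfc_cut: float = LFC_CUT,
) -> pd.DataFrame:
    """Concordant vs discordant fold-change direction per subtype.

    Among axes where both genes pass |lfc| > cut, concordant pairs share
    the fold-change sign and discordant pairs oppose it; the prevalence
    flag records whether concordant pairs outnumber discordant ones.
    """
    records = []
    for subtype, de in de_tables.items():
        lut = de.set_index("gene")["lfc"].to_dict()
        n_con = n_dis = 0
        for receptor, partner, _ in pairs:
            lr, lp = lut.get(receptor, np.nan), lut.get(partner, np.nan)
            if np.isnan(lr) or np.isnan(lp):
                continue
            if abs(lr) > lfc_cut and abs(lp) > lfc_cut:
                if lr * lp > 0:
                    n_con += 1
                else:
                    n_dis += 1
        records.append(
            {
                "subtype": subtype,
                "n_concordant": n_con,
                "n_discordant": n_dis,
                "prevalence_flag": n_con > n_dis,
            }
        )
    return pd.DataFrame(records).set_index("subtype")


def mutation_axis_association(
    mutations: pd.DataFrame,
    cancer_genes: Mapping[str, str],
    matrix: pd.DataFrame,
    subtype_samples: Mapping[str, int] | None = None,
    top_k: int = 5,
) -> pd.DataFrame:
    """Associate recurrently mutated cancer genes with axis co-regulation.

    ``mutations`` has columns (gene, sample, subtype); ``cancer_genes``
    maps gene -> role (oncogene/TSG/both) and restricts the candidates.
    Per subtype, mutation frequency is the fraction of samples carrying
    at least one mutation in the gene (a sample counts once); the top
    ``top_k`` genes per subtype are retained, keeping all ties at rank
    k.  Each retained gene is then scored as the mean, over the subtypes
    where it ranked, of the number of axes with |score| = 2 in that
    subtype.  Output is sorted by descending average count.
    """
    coreg_counts = (matrix.abs() == 2).sum(axis=0)

    mut = mutations[mutations["gene"].isin(cancer_genes)]
    per_gene_subtypes: dict[str, list[str]] = {}
    for subtype, block in mut.groupby("subtype"):
        if subtype not in matrix.columns:
            logger.info("subtype %s absent from co-DE matrix; skipped", subtype)
            continue
        n_samples = (
            subtype_samples[subtype]
            if subtype_samples is not None
            else block["sample"].nunique()
        )
        freq = block.groupby("gene")["sample"].nunique() / n_samples
        freq = freq.sort_values(ascending=False)
        if len(freq) > top_k:
            cutoff = freq.iloc[top_k - 1]
            freq = freq[freq >= cutoff]  # ties at rank k all included
        for gene in freq.index:
            per_gene_subtypes.setdefault(gene, []).append(subtype)

    records = [
        {
            "gene": gene,
            "role": cancer_genes[gene],
            "n_subtypes": len(subs),
            "avg_coregulated_axes": float(np.mean([coreg_counts[s] for s in subs])),
        }
        for gene, subs in per_gene_subtypes.items()
    ]
    out = pd.DataFrame(records, columns=["gene", "role", "n_subtypes", "avg_coregulated_axes"])
    return out.sort_values(
        ["avg_coregulated_axes", "gene"], ascending=[False, True]
    ).reset_index(drop=True)


def read_code_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index(["receptor", "partner", "partner_kind"])


def write_code_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.reset_index().to_csv(path, sep="\t", index=False)
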