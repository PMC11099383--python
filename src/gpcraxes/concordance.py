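"""Transcript-metabolite pathway concordance.

The Pathway Abundance Score (PAS) is a sign-balance statistic over a
pathway's differentially regulated members: PAS = (I - D) / S where I
is the number of members with LFC > 0, D the number with LFC < 0 and
S = I + D (S = 1 when I + D = 0, so an unregulated pathway scores 0).
A pathway's metabolite-level PAS is compared in sign with a transcript-
level gene-set enrichment score (ES, consumed as an input table, never
computed here): concordance +1 means both positive (co-enrichment in
cancer), -1 both negative (co-enrichment in normal), 0 otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ES_PADJ_CUT = 0.01


@dataclass(frozen=True)
class PASRecord:
    pathway: str
    I: int
    D: int
    S: int
    pas: float


def pas(member_lfcs: Iterable[float], pathway: str = "") -> PASRecord:
    """Pathway Abundance Score over member log2 fold changes.

    Missing entries are ignored; exact zeros count toward neither I nor
    D.  The score is sign-only: invariant to member order and to LFC
    magnitude, and odd under negation of all members.
    """
    vals = [v for v in member_lfcs if v is not None and not math.isnan(v)]
    I = sum(1 for v in vals if v > 0)
    D = sum(1 for v in vals if v < 0)
    S = I + D if I + D > 0 else 1
    return PASRecord(pathway=pathway, I=I, D=D, S=S, pas=(I - D) / S)


def concordance(
    es: float, es_padj: float, pas_value: float, padj_cut: float = ES_PADJ_CUT
) -> tuple[int, bool]:
    """Sign concordance of enrichment score and PAS.

    Returns (code, significant): code +1 iff both positive, -1 iff both
    negative, else 0; the significance flag records es_padj < cut and is
    reported alongside without gating the sign.
    """
    if es > 0 and pas_value > 0:
        code = 1
    elif es < 0 and pas_value < 0:
        code = -1
    else:
        code = 0
    return code, bool(es_padj < padj_cut)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line as name<TAB>description<TAB>members."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = [m for m in fields[2:] if m]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def pathway_concordance_table(
    de: pd.DataFrame,
    metabolite_lfcs: pd.DataFrame,
    gene_sets: Mapping[str, list[str]],
    metabolite_sets: Mapping[str, list[str]],
    es_table: pd.DataFrame,
    padj_cut: float = ES_PADJ_CUT,
) -> pd.DataFrame:
    """Per-pathway concordance records for one cancer type.

    ``de`` is a gene-level DE table (gene, lfc, ...); ``metabolite_lfcs``
    has columns (metabolite, lfc); ``es_table`` has columns
    (pathway, es, es_padj).  The metabolite-level PAS drives the
    concordance code; a companion gene-level PAS column is reported.
    Pathway members missing from the tables are ignored (logged);
    pathways absent from the es_table get missing es and concordance.
    """
    gene_lfc = de.set_index("gene")["lfc"].to_dict()
    met_lfc = metabolite_lfcs.set_index("metabolite")["lfc"].to_dict()
    es_lut = es_table.set_index("pathway")[["es", "es_padj"]].to_dict("index")

    records = []
    for pathway in sorted(set(gene_sets) | set(metabolite_sets)):
        mets = metabolite_sets.get(pathway, [])
        missing_mets = [m for m in mets if m not in met_lfc]
        if missing_mets:
            logger.debug("pathway %s: %d unmapped metabolites", pathway, len(missing_mets))
        met_rec = pas((met_lfc[m] for m in mets if m in met_lfc), pathway)

        genes = gene_sets.get(pathway, [])
        gene_rec = pas((gene_lfc[g] for g in genes if g in gene_lfc), pathway)

        row = {
            "pathway": pathway,
            "I": met_rec.I,
            "D": met_rec.D,
            "S": met_rec.S,
            "pas": met_rec.pas,
            "pas_genes": gene_rec.pas,
        }
        hit = es_lut.get(pathway)
        if hit is None:
            row.update({"es": np.nan, "es_padj": np.nan, "concord": pd.NA, "es_significant": pd.NA})
        else:
            code, sig = concordance(hit["es"], hit["es_padj"], met_rec.pas, padj_cut)
            row.update(
                {"es": hit["es"], "es_padj": hit["es_padj"], "concord": code, "es_significant": sig}
            )
        records.append(row)
    return pd.DataFrame(records)
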