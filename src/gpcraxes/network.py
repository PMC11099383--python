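"""GPCR-ligand-enzyme axis network.

The network holds three component classes and three typed edge kinds:

* ``ligand_receptor`` — an endogenous ligand activating (or blocking) a
  receptor, annotated with the action mode;
* ``enzyme_ligand`` — a biosynthetic enzyme producing (LR), consuming
  (RL) or reversibly handling (UN) a ligand;
* ``receptor_enzyme`` — a derived, ligand-mediated edge between a
  receptor and an enzyme synthesizing one of its ligands, kept only when
  a functional-interaction confidence score clears a threshold.

An *axis* is a receptor paired with either a peptide-ligand precursor
(via a ``ligand_receptor`` edge) or a biosynthetic enzyme (via a
``receptor_enzyme`` edge); axes are the unit every downstream analysis
operates on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from gpcraxes.errors import SchemaError

logger = logging.getLogger(__name__)

EDGE_KINDS = frozenset({"ligand_receptor", "enzyme_ligand", "receptor_enzyme"})
ACTIONS = frozenset({"agonist", "antagonist", "mixed", "unknown"})
DIRECTIONS = frozenset({"LR", "RL", "UN"})
LIGAND_TYPES = frozenset(
    {"peptide", "metabolite", "synthetic organic", "inorganic", "natural product"}
)
COUPLINGS = frozenset({"Gs", "Gi/o", "Gq/11", "G12/13"})

#: default STRING-style confidence cutoff for derived receptor-enzyme edges
MIN_CONFIDENCE = 150


@dataclass(frozen=True)
class Receptor:
    id: str
    family: str = ""
    coupling: frozenset[str] = frozenset()
    orphan: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise SchemaError("receptor id must be non-empty")
        if not self.coupling and not self.orphan:
            raise SchemaError(f"receptor {self.id!r}: empty coupling requires orphan=True")
        bad = set(self.coupling) - COUPLINGS
        if bad:
            raise SchemaError(f"receptor {self.id!r}: unknown coupling {sorted(bad)}")


@dataclass(frozen=True)
class Ligand:
    id: str
    name: str = ""
    ligand_type: str = "peptide"
    external_refs: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise SchemaError("ligand id must be non-empty")
        if self.ligand_type not in LIGAND_TYPES:
            raise SchemaError(
                f"ligand {self.id!r}: ligand_type {self.ligand_type!r} not in "
                f"{sorted(LIGAND_TYPES)}"
            )


@dataclass(frozen=True)
class Enzyme:
    id: str
    cc_terms: frozenset[str] = frozenset()
    class_terms: frozenset[str] = frozenset()
    literature_count: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SchemaError("enzyme id must be non-empty")
        if self.literature_count is not None and self.literature_count < 0:
            raise SchemaError(f"enzyme {self.id!r}: negative literature_count")


@dataclass(frozen=True)
class Edge:
    """A typed edge; kind-specific attributes are present exactly when
    applicable (action on ligand_receptor, direction on enzyme_ligand,
    confidence on receptor_enzyme)."""

    source: str
    target: str
    edge_kind: str
    action: str | None = None
    direction: str | None = None
    confidence: int | None = None

    def __post_init__(self) -> None:
        if self.edge_kind not in EDGE_KINDS:
            raise SchemaError(f"unknown edge_kind {self.edge_kind!r}")
        if self.source == self.target:
            raise SchemaError(f"self-edge on {self.source!r}")
        if self.edge_kind == "ligand_receptor":
            if self.action is not None and self.action not in ACTIONS:
                raise SchemaError(f"bad action {self.action!r}")
            if self.direction is not None or self.confidence is not None:
                raise SchemaError("ligand_receptor edge carries only 'action'")
        elif self.edge_kind == "enzyme_ligand":
            if self.direction is not None and self.direction not in DIRECTIONS:
                raise SchemaError(f"bad direction {self.direction!r}")
            if self.action is not None or self.confidence is not None:
                raise SchemaError("enzyme_ligand edge carries only 'direction'")
        else:  # receptor_enzyme
            if self.action is not None or self.direction is not None:
                raise SchemaError("receptor_enzyme edge carries only 'confidence'")
            if self.confidence is not None and self.confidence < 0:
                raise SchemaError("confidence must be nonnegative")


@dataclass
class AxisNetwork:
    receptors: dict[str, Receptor]
    ligands: dict[str, Ligand]
    enzymes: dict[str, Enzyme]
    edges: list[Edge]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for edge in self.edges:
            if edge.edge_kind == "ligand_receptor":
                ok = edge.source in self.ligands and edge.target in self.receptors
            elif edge.edge_kind == "enzyme_ligand":
                ok = edge.source in self.enzymes and edge.target in self.ligands
            else:
                ok = edge.source in self.receptors and edge.target in self.enzymes
            if not ok:
                raise SchemaError(
                    f"dangling {edge.edge_kind} edge "
                    f"{edge.source!r} -> {edge.target!r}: endpoint not declared"
                )

    def edges_of_kind(self, kind: str) -> list[Edge]:
        return [e for e in self.edges if e.edge_kind == kind]

    def axis_pairs(self) -> list[tuple[str, str, str]]:
        """All (receptor, partner, partner_kind) axes in the network.

        Receptor-ligand axes come from ligand_receptor edges and
        receptor-enzyme axes from the derived receptor_enzyme edges.
        """
        pairs: list[tuple[str, str, str]] = []
        seen: set[tuple[str, str, str]] = set()
        for e in self.edges:
            if e.edge_kind == "ligand_receptor":
                key = (e.target, e.source, "ligand")
            elif e.edge_kind == "receptor_enzyme":
                key = (e.source, e.target, "enzyme")
            else:
                continue
            if key not in seen:
                seen.add(key)
                pairs.append(key)
        return pairs


# ---------------------------------------------------------------------------
# TSV input/output


def _split(cell: object, sep: str = ";") -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return frozenset()
    return frozenset(s.strip() for s in str(cell).split(sep) if s.strip())


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


def load_network(directory: str | Path) -> AxisNetwork:
    """Load and validate a network from a directory of component tables.

    Expects ``receptors.tsv``, ``ligands.tsv``, ``enzymes.tsv`` and
    ``edges.tsv`` in the directory.  Raises :class:`SchemaError` naming
    the offending row on duplicate ids or dangling edge endpoints.
    """
    directory = Path(directory)
    rec_df = _read_tsv(directory / "receptors.tsv")
    lig_df = _read_tsv(directory / "ligands.tsv")
    enz_df = _read_tsv(directory / "enzymes.tsv")
    edge_df = _read_tsv(directory / "edges.tsv")

    _require_columns(rec_df, ["id", "family", "coupling", "orphan"], "receptors.tsv")
    _require_columns(lig_df, ["id", "name", "ligand_type"], "ligands.tsv")
    _require_columns(enz_df, ["id", "cc_terms", "class_terms"], "enzymes.tsv")
    _require_columns(edge_df, ["source", "target", "edge_kind"], "edges.tsv")

    receptors: dict[str, Receptor] = {}
    for row in rec_df.itertuples(index=False):
        if row.id in receptors:
            raise SchemaError(f"receptors.tsv: duplicate id {row.id!r}")
        receptors[row.id] = Receptor(
            id=row.id,
            family=row.family,
            coupling=_split(row.coupling),
            orphan=str(row.orphan) in {"1", "True", "true"},
        )

    ligands: dict[str, Ligand] = {}
    for row in lig_df.itertuples(index=False):
        if row.id in ligands:
            raise SchemaError(f"ligands.tsv: duplicate id {row.id!r}")
        refs = {}
        raw = getattr(row, "external_refs", "")
        for item in _split(raw):
            if ":" in item:
                k, v = item.split(":", 1)
                refs[k] = v
        ligands[row.id] = Ligand(
            id=row.id, name=row.name, ligand_type=row.ligand_type, external_refs=refs
        )

    enzymes: dict[str, Enzyme] = {}
    for row in enz_df.itertuples(index=False):
        if row.id in enzymes:
            raise SchemaError(f"enzymes.tsv: duplicate id {row.id!r}")
        raw_count = getattr(row, "literature_count", "")
        enzymes[row.id] = Enzyme(
            id=row.id,
            cc_terms=_split(row.cc_terms),
            class_terms=_split(row.class_terms),
            literature_count=int(raw_count) if raw_count != "" else None,
        )

    edges: list[Edge] = []
    for row in edge_df.itertuples(index=False):
        action = getattr(row, "action", "") or None
        direction = getattr(row, "direction", "") or None
        conf_raw = getattr(row, "confidence", "")
        confidence = int(float(conf_raw)) if conf_raw != "" else None
        edges.append(
            Edge(
                source=row.source,
                target=row.target,
                edge_kind=row.edge_kind,
                action=action,
                direction=direction,
                confidence=confidence,
            )
        )

    return AxisNetwork(receptors=receptors, ligands=ligands, enzymes=enzymes, edges=edges)


def write_network(net: AxisNetwork, directory: str | Path) -> None:
    """Write a network back to the four-table TSV layout read by
    :func:`load_network` (round-trip identity on valid networks)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "id": r.id,
                "family": r.family,
                "coupling": ";".join(sorted(r.coupling)),
                "orphan": int(r.orphan),
            }
            for r in net.receptors.values()
        ]
    ).to_csv(directory / "receptors.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "id": l.id,
                "name": l.name,
                "ligand_type": l.ligand_type,
                "external_refs": ";".join(f"{k}:{v}" for k, v in sorted(l.external_refs.items())),
            }
            for l in net.ligands.values()
        ]
    ).to_csv(directory / "ligands.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "id": e.id,
                "cc_terms": ";".join(sorted(e.cc_terms)),
                "class_terms": ";".join(sorted(e.class_terms)),
                "literature_count": "" if e.literature_count is None else e.literature_count,
            }
            for e in net.enzymes.values()
        ]
    ).to_csv(directory / "enzymes.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "source": e.source,
                "target": e.target,
                "edge_kind": e.edge_kind,
                "action": e.action or "",
                "direction": e.direction or "",
                "confidence": "" if e.confidence is None else e.confidence,
            }
            for e in net.edges
        ],
        columns=["source", "target", "edge_kind", "action", "direction", "confidence"],
    ).to_csv(directory / "edges.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filters


def filter_enzymes(
    enzymes: Iterable[Enzyme],
    keep_cc_terms: set[str],
    exclude_class_terms: set[str],
) -> list[Enzyme]:
    """Keep enzymes plausibly acting in the extracellular/membrane
    compartment and drop excluded functional classes.

    An enzyme survives iff (a) at least one of its cellular-component
    annotations is in ``keep_cc_terms`` and (b) none of its class/domain/
    name annotations contains any exclude term as a case-insensitive
    substring (the exclude list names plain-language classes such as
    kinases, channels, transporters, cytochromes).  Input order is
    preserved; the filter is idempotent.
    """
    if not keep_cc_terms or not exclude_class_terms:
        raise ValueError("keep_cc_terms and exclude_class_terms must be non-empty")
    excludes = [t.lower() for t in exclude_class_terms]
    kept = []
    for enz in enzymes:
        if not (enz.cc_terms & keep_cc_terms):
            continue
        annots = [t.lower() for t in enz.class_terms]
        if any(x in a for a in annots for x in excludes):
            continue
        kept.append(enz)
    return kept


def derive_receptor_enzyme_edges(
    net: AxisNetwork,
    confidence_scores: Mapping[tuple[str, str], int],
    min_confidence: int = MIN_CONFIDENCE,
) -> list[Edge]:
    """Derive ligand-mediated receptor-enzyme edges.

    A receptor R and enzyme E are connected when at least one ligand L
    has both an ``enzyme_ligand`` edge E->L and a ``ligand_receptor``
    edge L->R, and the pair's functional-interaction confidence is at
    least ``min_confidence`` (inclusive).  One edge per pair regardless
    of how many ligands mediate it; pairs missing from
    ``confidence_scores`` are skipped with a log message.
    """
    ligand_to_receptors: dict[str, set[str]] = {}
    for e in net.edges_of_kind("ligand_receptor"):
        ligand_to_receptors.setdefault(e.source, set()).add(e.target)

    pairs: set[tuple[str, str]] = set()
    for e in net.edges_of_kind("enzyme_ligand"):
        for receptor in ligand_to_receptors.get(e.target, ()):
            pairs.add((receptor, e.source))

    edges: list[Edge] = []
    for receptor, enzyme in sorted(pairs):
        conf = confidence_scores.get((receptor, enzyme))
        if conf is None:
            logger.info("no confidence score for pair (%s, %s); excluded", receptor, enzyme)
            continue
        if conf >= min_confidence:
            edges.append(
                Edge(source=receptor, target=enzyme, edge_kind="receptor_enzyme", confidence=conf)
            )
    return edges


def select_rate_limiting(
    pathway_enzymes: Mapping[str, set[str]],
    literature_counts: Mapping[str, int],
) -> dict[str, str]:
    """Pick the rate-limiting enzyme of each metabolic pathway.

    The designated enzyme is the pathway member with the largest
    literature evidence count (number of publications mentioning it as
    rate limiting / a bottleneck); ties break to the lexicographically
    smallest gene symbol so the choice is deterministic.
    """
    out: dict[str, str] = {}
    for pathway, members in pathway_enzymes.items():
        counted = sorted(m for m in members if m in literature_counts)
        if not counted:
            raise ValueError(f"pathway {pathway!r} has no enzyme with a literature count")
        out[pathway] = min(counted, key=lambda m: (-literature_counts[m], m))
    return out
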