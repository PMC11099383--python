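"""Synthetic cohort and screen generator with planted ground truth.

Every pipeline input — network component tables, negative-binomial
count matrices, clinical survival tables, metabolite/enrichment tables,
mutation tables and drug-response panels — can be generated from one
:class:`SimulationConfig` with a mandatory seed.  Each generator emits
a machine-readable truth table describing the planted structure, so
every downstream stage has a ground-truth surface to be tested against.

Counts are negative binomial with mean mu per gene drawn log-uniformly
over ``nb_mean_log_range`` and variance mu + dispersion * mu^2; planted
axis genes are shifted by their configured log2 fold change in tumor
samples of every subtype.  Survival times are exponential (proportional
hazards hold exactly) with per-patient hazard
baseline * prod_a multiplier_a^(both-high indicator for axis a);
censoring is independent exponential with its rate solved numerically
to hit the configured censoring fraction.  Drug panels mix a bimodal
two-component response for planted active drugs with unimodal nulls,
plus independent replicate noise.

All generators are pure functions of the config: a fixed seed produces
byte-identical tables.  Each generator draws from its own stream seeded
by (config.seed, generator offset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from gpcraxes.diffexp import CountMatrix
from gpcraxes.network import AxisNetwork, Edge, Enzyme, Ligand, Receptor

# per-generator stream offsets (combined with config.seed via SeedSequence)
_NETWORK, _COUNTS, _SURVIVAL, _PATHWAYS, _DRUGS, _MUTATIONS = range(1, 7)


@dataclass
class PlantedAxis:
    receptor: str
    partner: str
    kind: str  # ligand | enzyme
    lfc_r: float
    lfc_p: float
    hazard_multiplier: float = 1.0


@dataclass
class SurvivalSettings:
    baseline_hazard: float = 0.1
    censoring_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")


@dataclass
class DrugSettings:
    n_drugs: int = 200
    n_cell_lines: int = 100
    active_fraction: float = 0.25
    bimodal_separation: float = 3.0
    replicate_noise_sd: float = 0.1


@dataclass
class PathwaySettings:
    n_pathways: int = 20
    members_per_pathway: int = 10
    concordant_fraction: float = 0.5


@dataclass
class SimulationConfig:
    seed: int
    n_genes: int = 2000
    n_samples_tumor: int = 400
    n_samples_normal: int = 100
    n_subtypes: int = 8
    n_tissues: int = 4
    nb_mean_log_range: tuple[float, float] = (3.0, 8.0)  # natural log of NB mean
    nb_dispersion: float = 0.1
    n_planted_axes: int = 10
    n_decoy_axes: int = 90
    planted_lfc: float = 2.0
    planted_hazard_multiplier: float = 3.0
    planted_axes: list[PlantedAxis] | None = None
    survival: SurvivalSettings = field(default_factory=SurvivalSettings)
    drug: DrugSettings = field(default_factory=DrugSettings)
    pathways: PathwaySettings = field(default_factory=PathwaySettings)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        # allow plain mappings (e.g. parsed YAML) for the nested settings
        if isinstance(self.survival, dict):
            self.survival = SurvivalSettings(**self.survival)
        if isinstance(self.drug, dict):
            self.drug = DrugSettings(**self.drug)
        if isinstance(self.pathways, dict):
            self.pathways = PathwaySettings(**self.pathways)
        if self.planted_axes is not None:
            self.planted_axes = [
                PlantedAxis(**a) if isinstance(a, dict) else a for a in self.planted_axes
            ]
        if isinstance(self.nb_mean_log_range, list):
            self.nb_mean_log_range = tuple(self.nb_mean_log_range)
        for name in ("n_genes", "n_samples_tumor", "n_samples_normal", "n_subtypes", "n_tissues"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        axes = self.resolved_axes()
        pairs = [(a.receptor, a.partner) for a in axes]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate planted axis pair")
        if any(a.hazard_multiplier <= 0 for a in axes):
            raise ValueError("hazard multipliers must be positive")

    def resolved_axes(self) -> list[PlantedAxis]:
        """Planted plus decoy axes.

        If ``planted_axes`` is not given explicitly, ``n_planted_axes``
        axes carry the configured expression LFC and hazard multiplier;
        ``n_decoy_axes`` further axes are null (lfc 0, multiplier 1).
        Axis kinds alternate between ligand and enzyme partners.
        """
        if self.planted_axes is not None:
            return list(self.planted_axes)
        axes = []
        for i in range(self.n_planted_axes + self.n_decoy_axes):
            planted = i < self.n_planted_axes
            kind = "ligand" if i % 2 == 0 else "enzyme"
            partner = (f"LIG{i:03d}" if kind == "ligand" else f"ENZ{i:03d}")
            axes.append(
                PlantedAxis(
                    receptor=f"GPR{i:03d}",
                    partner=partner,
                    kind=kind,
                    lfc_r=self.planted_lfc if planted else 0.0,
                    lfc_p=self.planted_lfc if planted else 0.0,
                    hazard_multiplier=self.planted_hazard_multiplier if planted else 1.0,
                )
            )
        return axes

    def subtype_names(self) -> list[str]:
        per_tissue = max(1, self.n_subtypes // self.n_tissues)
        return [
            f"T{(i // per_tissue) % self.n_tissues + 1}.S{i + 1}" for i in range(self.n_subtypes)
        ]

    def subtype_tissue(self) -> dict[str, str]:
        return {s: s.split(".")[0] for s in self.subtype_names()}

    def _rng(self, offset: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), offset]))


# ---------------------------------------------------------------------------
# network


def generate_network_fixture(config: SimulationConfig) -> AxisNetwork:
    """Component and edge tables containing every planted axis plus the
    decoys, schema-valid for :func:`gpcraxes.network.load_network`."""
    axes = config.resolved_axes()
    receptors: dict[str, Receptor] = {}
    ligands: dict[str, Ligand] = {}
    enzymes: dict[str, Enzyme] = {}
    edges: list[Edge] = []
    couplings = ["Gi/o", "Gq/11", "Gs", "G12/13"]
    for i, axis in enumerate(axes):
        if axis.receptor not in receptors:
            receptors[axis.receptor] = Receptor(
                id=axis.receptor,
                family="ClassA",
                coupling=frozenset({couplings[i % 4]}),
            )
        if axis.kind == "ligand":
            ligands.setdefault(
                axis.partner, Ligand(id=axis.partner, name=axis.partner, ligand_type="peptide")
            )
            edges.append(
                Edge(source=axis.partner, target=axis.receptor,
                     edge_kind="ligand_receptor", action="agonist")
            )
        else:
            mediator = f"MET{i:03d}"
            ligands.setdefault(
                mediator, Ligand(id=mediator, name=mediator, ligand_type="metabolite")
            )
            enzymes.setdefault(
                axis.partner,
                Enzyme(
                    id=axis.partner,
                    cc_terms=frozenset({"plasma membrane"}),
                    class_terms=frozenset({"transferase"}),
                    literature_count=10,
                ),
            )
            edges.append(
                Edge(source=axis.partner, target=mediator,
                     edge_kind="enzyme_ligand", direction="LR")
            )
            edges.append(
                Edge(source=mediator, target=axis.receptor,
                     edge_kind="ligand_receptor", action="agonist")
            )
            edges.append(
                Edge(source=axis.receptor, target=axis.partner,
                     edge_kind="receptor_enzyme", confidence=400)
            )
    return AxisNetwork(receptors=receptors, ligands=ligands, enzymes=enzymes, edges=edges)


# ---------------------------------------------------------------------------
# counts


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def generate_counts(
    config: SimulationConfig,
) -> tuple[dict[str, CountMatrix], pd.DataFrame]:
    """Per-subtype count matrices plus the truth table of true LFCs.

    Axis genes carry their configured fold change in tumor samples of
    every subtype; pathway-member genes (used by the concordance stage)
    carry a per-pathway direction with |LFC| = 2; remaining filler genes
    are null.  Truth rows record every nonzero (gene, subtype, true_lfc)
    plus the pathway block assignments.
    """
    rng = config._rng(_COUNTS)
    axes = config.resolved_axes()
    axis_genes: dict[str, float] = {}
    for a in axes:
        axis_genes[a.receptor] = a.lfc_r
        axis_genes[a.partner] = a.lfc_p

    pw = config.pathways
    pathway_genes: dict[str, tuple[str, float]] = {}
    directions = {}
    for p in range(pw.n_pathways):
        name = f"PW{p:03d}"
        directions[name] = 1.0 if p % 2 == 0 else -1.0
        for m in range(pw.members_per_pathway):
            pathway_genes[f"PWG{p:03d}_{m:02d}"] = (name, directions[name] * 2.0)

    genes = list(axis_genes) + list(pathway_genes)
    n_filler = max(0, config.n_genes - len(genes))
    genes += [f"G{i:05d}" for i in range(n_filler)]

    lfc_by_gene = np.zeros(len(genes))
    for i, g in enumerate(genes):
        if g in axis_genes:
            lfc_by_gene[i] = axis_genes[g]
        elif g in pathway_genes:
            lfc_by_gene[i] = pathway_genes[g][1]

    lo, hi = config.nb_mean_log_range
    base_mu = np.exp(rng.uniform(lo, hi, size=len(genes)))

    counts_by_subtype: dict[str, CountMatrix] = {}
    truth_rows = []
    tissue_of = config.subtype_tissue()
    for subtype in config.subtype_names():
        nt, nn = config.n_samples_tumor, config.n_samples_normal
        tumor_mu = base_mu[:, None] * (2.0 ** lfc_by_gene)[:, None]
        tumor = _nb_sample(rng, np.broadcast_to(tumor_mu, (len(genes), nt)), config.nb_dispersion)
        normal = _nb_sample(
            rng, np.broadcast_to(base_mu[:, None], (len(genes), nn)), config.nb_dispersion
        )
        samples = [f"{subtype}.TU{i:03d}" for i in range(nt)] + [
            f"{subtype}.NO{i:03d}" for i in range(nn)
        ]
        counts = pd.DataFrame(np.hstack([tumor, normal]), index=genes, columns=samples)
        meta = pd.DataFrame(
            {
                "cohort": ["tumor"] * nt + ["normal"] * nn,
                "tissue": tissue_of[subtype],
                "subtype": subtype,
            },
            index=samples,
        )
        counts_by_subtype[subtype] = CountMatrix(counts, meta)
        for i, g in enumerate(genes):
            if lfc_by_gene[i] != 0:
                truth_rows.append(
                    {
                        "gene": g,
                        "subtype": subtype,
                        "true_lfc": lfc_by_gene[i],
                        "pathway": pathway_genes[g][0] if g in pathway_genes else "",
                    }
                )
    truth = pd.DataFrame(truth_rows, columns=["gene", "subtype", "true_lfc", "pathway"])
    return counts_by_subtype, truth


# ---------------------------------------------------------------------------
# survival


def _solve_censoring_rate(hazards: np.ndarray, fraction: float) -> float:
    """Exponential censoring rate c with mean_i c/(h_i + c) = fraction."""
    if fraction == 0:
        return 0.0
    lo, hi = 1e-9, float(hazards.max()) * 1e4
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if float(np.mean(mid / (hazards + mid))) < fraction:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def generate_survival(
    config: SimulationConfig,
    counts_by_subtype: dict[str, CountMatrix],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clinical tables with expression-linked hazards, one cohort per
    subtype, using that cohort's tumor samples as patients.

    Per-patient hazard is baseline * prod_a m_a^(I_a) where I_a
    indicates the patient is above the cohort median for both genes of
    planted axis a.  Censoring times are independent exponential with
    the rate solved so the expected censored fraction matches the
    configuration.  Returns (clinical, truth).
    """
    rng = config._rng(_SURVIVAL)
    axes = [a for a in config.resolved_axes() if a.hazard_multiplier != 1.0]
    clin_rows = []
    truth_rows = []
    for subtype, cm in counts_by_subtype.items():
        tumor_samples = cm.sample_meta.index[cm.sample_meta["cohort"] == "tumor"]
        expr = np.log2(cm.counts[tumor_samples] + 1.0)
        n = len(tumor_samples)
        hazard = np.full(n, config.survival.baseline_hazard)
        for a in axes:
            if a.receptor not in expr.index or a.partner not in expr.index:
                continue
            er = expr.loc[a.receptor].to_numpy()
            ep = expr.loc[a.partner].to_numpy()
            both_high = (er > np.median(er)) & (ep > np.median(ep))
            hazard *= np.where(both_high, a.hazard_multiplier, 1.0)
            truth_rows.append(
                {
                    "subtype": subtype,
                    "receptor": a.receptor,
                    "partner": a.partner,
                    "kind": a.kind,
                    "hazard_multiplier": a.hazard_multiplier,
                    "n_both_high": int(both_high.sum()),
                }
            )
        event_time = rng.exponential(1.0 / hazard)
        c_rate = _solve_censoring_rate(hazard, config.survival.censoring_fraction)
        if c_rate > 0:
            censor_time = rng.exponential(1.0 / c_rate, size=n)
        else:
            censor_time = np.full(n, np.inf)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
        for i, patient in enumerate(tumor_samples):
            clin_rows.append(
                {
                    "patient": patient,
                    "time": float(time[i]),
                    "event": int(event[i]),
                    "cohort": subtype,
                }
            )
    clinical = pd.DataFrame(clin_rows)
    truth = pd.DataFrame(
        truth_rows,
        columns=["subtype", "receptor", "partner", "kind", "hazard_multiplier", "n_both_high"],
    )
    return clinical, truth


# ---------------------------------------------------------------------------
# pathways / metabolites / enrichment scores


def generate_metabolites_and_es(
    config: SimulationConfig, counts_truth: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, list[str]], dict[str, list[str]], pd.DataFrame, pd.DataFrame]:
    """Metabolite LFC table, gene/metabolite GMT sets, enrichment-score
    table and the truth table of intended concordance codes.

    Concordant pathways get metabolite fold-change signs and an ES sign
    matching their planted gene direction; discordant pathways get
    metabolite signs opposing the ES, so their intended concordance
    code is 0.
    """
    rng = config._rng(_PATHWAYS)
    pw = config.pathways
    gene_dir = (
        counts_truth[counts_truth["pathway"] != ""]
        .groupby("pathway")["true_lfc"]
        .mean()
        .apply(np.sign)
    )
    gene_sets: dict[str, list[str]] = {}
    met_sets: dict[str, list[str]] = {}
    met_rows, es_rows, truth_rows = [], [], []
    pathways = sorted(gene_dir.index)
    n_concordant = int(round(pw.concordant_fraction * len(pathways)))
    for i, pathway in enumerate(pathways):
        direction = float(gene_dir[pathway])
        members = sorted(
            counts_truth.loc[counts_truth["pathway"] == pathway, "gene"].unique()
        )
        gene_sets[pathway] = members
        mets = [f"{pathway}.M{m:02d}" for m in range(pw.members_per_pathway)]
        met_sets[pathway] = mets
        concordant = i < n_concordant
        met_sign = direction if concordant else -direction
        for m in mets:
            met_rows.append({"metabolite": m, "lfc": met_sign * float(rng.uniform(0.5, 2.0))})
        es = direction * float(rng.uniform(1.0, 2.5))
        es_rows.append({"pathway": pathway, "es": es, "es_padj": 0.001})
        truth_rows.append(
            {
                "pathway": pathway,
                "direction": direction,
                "concordant": concordant,
                "intended_code": int(direction) if concordant else 0,
            }
        )
    return (
        pd.DataFrame(met_rows),
        gene_sets,
        met_sets,
        pd.DataFrame(es_rows),
        pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# mutations


def generate_mutations(
    config: SimulationConfig,
    counts_by_subtype: dict[str, CountMatrix],
    n_cancer_genes: int = 10,
    planted_frequency: float = 0.6,
    background_frequency: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Mutation table (gene, sample, subtype), cancer-gene role table,
    and a truth table of planted per-subtype top mutated genes.

    Each subtype gets two planted cancer genes mutated in
    ``planted_frequency`` of its tumor samples; all cancer genes also
    mutate at a low background rate everywhere.
    """
    rng = config._rng(_MUTATIONS)
    cancer_genes = [f"CG{i:02d}" for i in range(n_cancer_genes)]
    roles = pd.DataFrame(
        {"gene": cancer_genes, "role": ["oncogene" if i % 2 == 0 else "TSG" for i in range(n_cancer_genes)]}
    )
    rows, truth_rows = [], []
    for si, (subtype, cm) in enumerate(counts_by_subtype.items()):
        samples = list(cm.sample_meta.index[cm.sample_meta["cohort"] == "tumor"])
        planted = [cancer_genes[(2 * si) % n_cancer_genes], cancer_genes[(2 * si + 1) % n_cancer_genes]]
        for gene in cancer_genes:
            freq = planted_frequency if gene in planted else background_frequency
            hit = rng.random(len(samples)) < freq
            for s, h in zip(samples, hit):
                if h:
                    rows.append({"gene": gene, "sample": s, "subtype": subtype})
        truth_rows.append({"subtype": subtype, "planted_genes": ";".join(planted)})
    return (
        pd.DataFrame(rows, columns=["gene", "sample", "subtype"]),
        roles,
        pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# drug panel


def generate_drug_panel(
    config: SimulationConfig, survival_receptors: Sequence[str] = ()
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Long-format drug panel with two replicates, drug metadata,
    cell-line metadata, and the truth table of planted active flags.

    Active drugs draw their true per-cell-line LFC from a balanced
    two-component mixture centered at 0 (insensitive lines, sd 0.2) and
    at -``bimodal_separation`` (sensitive lines, sd 0.2); inactive
    drugs have no systematic cell-line effect, so their observed
    profile is replicate noise alone and is irreproducible across
    replicates.  Observed replicates add independent noise of sd
    ``replicate_noise_sd``.  Active drugs target planted survival
    receptors when provided.
    """
    rng = config._rng(_DRUGS)
    dc = config.drug
    n_active = int(round(dc.active_fraction * dc.n_drugs))
    cell_lines = [f"CL{i:03d}" for i in range(dc.n_cell_lines)]
    tissues = [f"TIS{i % 5}" for i in range(dc.n_cell_lines)]
    panel_rows, meta_rows, truth_rows = [], [], []
    receptors = list(survival_receptors)
    for d in range(dc.n_drugs):
        drug = f"DRUG{d:03d}"
        active = d < n_active
        if active:
            component = rng.random(dc.n_cell_lines) < 0.5
            true_lfc = np.where(
                component,
                rng.normal(-dc.bimodal_separation, 0.2, dc.n_cell_lines),
                rng.normal(0.0, 0.2, dc.n_cell_lines),
            )
        else:
            true_lfc = np.zeros(dc.n_cell_lines)
        for rep in (1, 2):
            noisy = true_lfc + rng.normal(0.0, dc.replicate_noise_sd, dc.n_cell_lines)
            for cl, v in zip(cell_lines, noisy):
                panel_rows.append(
                    {"drug": drug, "cell_line": cl, "lfc": float(v), "replicate": rep}
                )
        if active and receptors:
            targets = {receptors[d % len(receptors)]}
        else:
            targets = {f"DECOY{d:03d}"}
        meta_rows.append(
            {
                "drug": drug,
                "targets": ";".join(sorted(targets)),
                "moa": "receptor antagonist" if d % 4 else "receptor agonist",
                "action": "antagonist" if d % 4 else "agonist",
            }
        )
        truth_rows.append({"drug": drug, "active": active})
    panel = pd.DataFrame(panel_rows)
    drug_meta = pd.DataFrame(meta_rows)
    cell_meta = pd.DataFrame({"cell_line": cell_lines, "tissue": tissues})
    truth = pd.DataFrame(truth_rows)
    return panel, drug_meta, cell_meta, truth
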