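"""End-to-end pipeline orchestration.

Stages run in dependency order: simulate (optional input generation)
-> network -> de -> coregulation / concordance -> survival -> drugs.
Every stage reads and writes plain TSV tables under the output
directory (a leading ``#`` comment line documents the columns), logs
record counts in and out of every filter, and a run manifest records
the configuration hash, package version, seed and per-stage outputs.
Identical configuration and inputs produce byte-identical outputs;
reruns can resume from completed stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import gpcraxes
from gpcraxes import concordance as conc
from gpcraxes import coregulation as coreg
from gpcraxes import diffexp, drugs, network, simulate
from gpcraxes import survival as surv
from gpcraxes.errors import GpcrAxesError

logger = logging.getLogger(__name__)

STAGES = ["network", "de", "coregulation", "concordance", "survival", "drugs"]


class PipelineError(GpcrAxesError):
    pass


@dataclass
class Thresholds:
    lfc_cut: float = 1.0
    padj_cut: float = 0.01
    recurrence: float = 0.25
    logrank_alpha: float = 0.05
    fdr_cut: float = 0.1
    corr_threshold: float = 0.2
    bc_threshold: float = 0.35
    min_confidence: int = 150
    top_k: int = 10
    top_mut: int = 5


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    resume: bool = True
    simulation: dict | None = None  # SimulationConfig kwargs; None = inputs pre-exist
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir", None)  # run identity is independent of location
        payload.pop("resume", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, comment: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(f"missing {path.name}; run stage {producer!r} first")
    return path


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages; returns the output directory.

    The directory layout is ``inputs/`` (generated or user-supplied),
    ``truth/`` (planted ground truth, when simulated) and one TSV per
    stage product at the top level, plus ``manifest.json``.
    """
    out = Path(config.out_dir)
    inputs = out / "inputs"
    truth_dir = out / "truth"
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "package_version": gpcraxes.__version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
    }

    def done(stage: str) -> Path:
        return out / f".{stage}.done"

    def finish(stage: str, **counts) -> None:
        entry = {"stage": stage, **counts}
        done(stage).write_text(json.dumps(entry, sort_keys=True) + "\n")
        logger.info("stage %s: %s", stage, counts)

    # ----- simulate ---------------------------------------------------
    if config.simulation is not None and not (config.resume and done("simulate").exists()):
        inputs.mkdir(exist_ok=True)
        truth_dir.mkdir(exist_ok=True)
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        sim = simulate.SimulationConfig(**sim_kwargs)

        net = simulate.generate_network_fixture(sim)
        network.write_network(net, inputs)

        counts_by_subtype, counts_truth = simulate.generate_counts(sim)
        for subtype, cm in counts_by_subtype.items():
            cm.to_tsv(inputs / f"counts_{subtype}.tsv", inputs / f"samples_{subtype}.tsv")
        _write(counts_truth, truth_dir / "counts_truth.tsv", "gene subtype true_lfc pathway")

        clinical, surv_truth = simulate.generate_survival(sim, counts_by_subtype)
        clinical.to_csv(inputs / "clinical.tsv", sep="\t", index=False, float_format="%.10g")
        _write(surv_truth, truth_dir / "survival_truth.tsv", "planted hazard multipliers")

        mets, gene_sets, met_sets, es, conc_truth = simulate.generate_metabolites_and_es(
            sim, counts_truth
        )
        mets.to_csv(inputs / "metabolite_lfcs.tsv", sep="\t", index=False, float_format="%.10g")
        conc.write_gmt(gene_sets, inputs / "pathways_genes.gmt")
        conc.write_gmt(met_sets, inputs / "pathways_metabolites.gmt")
        es.to_csv(inputs / "es_table.tsv", sep="\t", index=False, float_format="%.10g")
        _write(conc_truth, truth_dir / "concordance_truth.tsv", "intended concordance codes")

        mutations, roles, mut_truth = simulate.generate_mutations(sim, counts_by_subtype)
        mutations.to_csv(inputs / "mutations.tsv", sep="\t", index=False)
        roles.to_csv(inputs / "cancer_genes.tsv", sep="\t", index=False)
        _write(mut_truth, truth_dir / "mutation_truth.tsv", "planted top mutated genes")

        planted_receptors = sorted(
            {a.receptor for a in sim.resolved_axes() if a.hazard_multiplier != 1.0}
        )
        panel, drug_meta, cell_meta, drug_truth = simulate.generate_drug_panel(
            sim, planted_receptors
        )
        panel.to_csv(inputs / "panel.tsv", sep="\t", index=False, float_format="%.10g")
        drug_meta.to_csv(inputs / "drug_meta.tsv", sep="\t", index=False)
        cell_meta.to_csv(inputs / "cell_meta.tsv", sep="\t", index=False)
        _write(drug_truth, truth_dir / "drug_truth.tsv", "planted active flags")
        finish(
            "simulate",
            n_subtypes=len(counts_by_subtype),
            n_genes=sim.n_genes,
            n_axes=len(sim.resolved_axes()),
        )

    thr = config.thresholds

    def subtypes_present() -> list[str]:
        return sorted(p.stem.removeprefix("counts_") for p in inputs.glob("counts_*.tsv"))

    # ----- network ----------------------------------------------------
    if "network" in config.stages and not (config.resume and done("network").exists()):
        net = network.load_network(_require(inputs, "simulate"))
        pairs = net.axis_pairs()
        _write(
            pd.DataFrame(pairs, columns=["receptor", "partner", "partner_kind"]),
            out / "axis_pairs.tsv",
            "receptor-partner axes from ligand_receptor and receptor_enzyme edges",
        )
        finish(
            "network",
            n_receptors=len(net.receptors),
            n_ligands=len(net.ligands),
            n_enzymes=len(net.enzymes),
            n_edges=len(net.edges),
            n_axes=len(pairs),
        )

    # ----- de ---------------------------------------------------------
    if "de" in config.stages and not (config.resume and done("de").exists()):
        n_sig = 0
        for subtype in subtypes_present():
            cm = diffexp.CountMatrix.from_tsv(
                inputs / f"counts_{subtype}.tsv", inputs / f"samples_{subtype}.tsv"
            )
            de = diffexp.differential_expression(cm)
            up, down = diffexp.significant_genes(de, thr.lfc_cut, thr.padj_cut)
            n_sig += len(up) + len(down)
            _write(de, out / f"de_{subtype}.tsv", f"tumor-vs-normal DE for subtype {subtype}")
        finish("de", n_subtypes=len(subtypes_present()), n_significant_genes=n_sig)

    # ----- coregulation -----------------------------------------------
    if "coregulation" in config.stages and not (config.resume and done("coregulation").exists()):
        pairs_df = pd.read_csv(_require(out / "axis_pairs.tsv", "network"), sep="\t", comment="#")
        pairs = [tuple(r) for r in pairs_df.itertuples(index=False)]
        de_tables = {
            s: pd.read_csv(_require(out / f"de_{s}.tsv", "de"), sep="\t", comment="#")
            for s in subtypes_present()
        }
        full, filtered = coreg.build_code_matrix(de_tables, pairs, thr.recurrence)
        coreg.write_code_matrix(full, out / "code_matrix_full.tsv")
        coreg.write_code_matrix(filtered, out / "code_matrix.tsv")
        if len(filtered) >= 2:
            labels, _ = coreg.cluster_pairs(filtered, n_clusters=2)
            clustered = filtered.reset_index()[["receptor", "partner", "partner_kind"]]
            clustered["cluster"] = labels
            _write(clustered, out / "pair_clusters.tsv", "Ward cluster label per retained axis")
        meta = pd.read_csv(
            inputs / f"samples_{subtypes_present()[0]}.tsv", sep="\t", comment="#"
        )
        subtype_tissue = {
            s: pd.read_csv(inputs / f"samples_{s}.tsv", sep="\t", comment="#")["tissue"].iloc[0]
            for s in subtypes_present()
        }
        _write(
            coreg.similarity_profiles(full, subtype_tissue),
            out / "similarity.tsv",
            "tissue-wise / ligand-wise similarity per receptor",
            index=True,
        )
        _write(
            coreg.concordance_prevalence(de_tables, pairs, thr.lfc_cut),
            out / "prevalence.tsv",
            "concordant vs discordant axis direction per subtype",
            index=True,
        )
        # expression-correlation calls per subtype (tumor samples, normalized)
        corr_frames = []
        for subtype in subtypes_present():
            cm = diffexp.CountMatrix.from_tsv(
                inputs / f"counts_{subtype}.tsv", inputs / f"samples_{subtype}.tsv"
            )
            tumor = cm.sample_meta.index[cm.sample_meta["cohort"] == "tumor"]
            expr = np.log2(diffexp.normalized_counts(cm)[tumor] + 1.0)
            calls = coreg.correlation_calls(
                expr, [(r, p) for r, p, _ in pairs],
                n_background=min(1000, len(expr) * (len(expr) - 1) // 4),
                seed=config.seed,
            )
            calls.insert(0, "subtype", subtype)
            corr_frames.append(calls)
        _write(
            pd.concat(corr_frames, ignore_index=True),
            out / "correlation_calls.tsv",
            "axis expression correlation vs random-pair background, per subtype",
        )
        mut_path = inputs / "mutations.tsv"
        if mut_path.exists():
            mutations = pd.read_csv(mut_path, sep="\t", comment="#")
            roles = pd.read_csv(inputs / "cancer_genes.tsv", sep="\t", comment="#")
            n_tumor = {
                s: int(
                    (
                        pd.read_csv(inputs / f"samples_{s}.tsv", sep="\t", comment="#")["cohort"]
                        == "tumor"
                    ).sum()
                )
                for s in subtypes_present()
            }
            assoc = coreg.mutation_axis_association(
                mutations,
                roles.set_index("gene")["role"].to_dict(),
                filtered,
                subtype_samples=n_tumor,
                top_k=thr.top_mut,
            )
            _write(assoc, out / "mutation_association.tsv", "top mutated genes vs co-regulated axis counts")
        finish("coregulation", n_pairs=len(full), n_retained=len(filtered))

    # ----- concordance ------------------------------------------------
    if "concordance" in config.stages and not (config.resume and done("concordance").exists()):
        gene_sets = conc.read_gmt(_require(inputs / "pathways_genes.gmt", "simulate"))
        met_sets = conc.read_gmt(inputs / "pathways_metabolites.gmt")
        mets = pd.read_csv(inputs / "metabolite_lfcs.tsv", sep="\t", comment="#")
        es = pd.read_csv(inputs / "es_table.tsv", sep="\t", comment="#")
        n_conc = 0
        for subtype in subtypes_present():
            de = pd.read_csv(_require(out / f"de_{subtype}.tsv", "de"), sep="\t", comment="#")
            table = conc.pathway_concordance_table(de, mets, gene_sets, met_sets, es, thr.padj_cut)
            n_conc += int((table["concord"].fillna(0) != 0).sum())
            _write(table, out / f"concordance_{subtype}.tsv", f"pathway PAS/ES concordance for {subtype}")
        finish("concordance", n_subtypes=len(subtypes_present()), n_concordant_calls=n_conc)

    # ----- survival ---------------------------------------------------
    if "survival" in config.stages and not (config.resume and done("survival").exists()):
        pairs_df = pd.read_csv(_require(out / "axis_pairs.tsv", "network"), sep="\t", comment="#")
        axes = [tuple(r) for r in pairs_df.itertuples(index=False)]
        clinical = pd.read_csv(_require(inputs / "clinical.tsv", "simulate"), sep="\t", comment="#")
        screens = []
        for subtype in subtypes_present():
            cm = diffexp.CountMatrix.from_tsv(
                inputs / f"counts_{subtype}.tsv", inputs / f"samples_{subtype}.tsv"
            )
            expr = np.log2(cm.counts + 1.0)
            ds = surv.load_survival_dataset(clinical, expr, cohort=subtype)
            if len(ds.time) < 4:
                continue
            screen = surv.axis_screen(
                ds, axes, fdr_cut=thr.fdr_cut, alpha=thr.logrank_alpha
            )
            screen.insert(0, "cohort", subtype)
            screens.append(screen)
        all_screens = pd.concat(screens, ignore_index=True)
        _write(all_screens, out / "axis_screen.tsv", "axis survival screen, one row per axis per cohort")
        finish(
            "survival",
            n_cohorts=len(screens),
            n_tested=int((~all_screens["missing"]).sum()),
            n_passing=int(all_screens["passes_filter"].sum()),
        )

    # ----- drugs ------------------------------------------------------
    if "drugs" in config.stages and not (config.resume and done("drugs").exists()):
        panel = drugs.load_panel(
            _require(inputs / "panel.tsv", "simulate"),
            inputs / "drug_meta.tsv",
            inputs / "cell_meta.tsv",
        )
        calls = drugs.activity_calls(panel, thr.corr_threshold, thr.bc_threshold)
        _write(calls, out / "drug_calls.tsv", "per-drug activity calls", index=True)
        per_line, moa_df, target_df = drugs.top_inhibitors(panel, thr.top_k)
        _write(moa_df, out / "top_moa.tsv", "per-tissue MOA counts among top-k inhibitors")
        _write(target_df, out / "top_targets.tsv", "per-tissue target counts among top-k inhibitors")
        screen_path = out / "axis_screen.tsv"
        if screen_path.exists():
            screen = pd.read_csv(screen_path, sep="\t", comment="#")
            survivors = set(screen.loc[screen["passes_filter"], "receptor"])
            if survivors:
                overlap = drugs.survival_target_overlap(calls, panel.drug_meta, survivors)
                (out / "target_overlap.json").write_text(
                    json.dumps(overlap, indent=2, sort_keys=True) + "\n"
                )
        n_active = int(calls["active"].fillna(False).astype(bool).sum())
        finish("drugs", n_drugs=len(calls), n_active=n_active)

    manifest["stages"] = [
        json.loads(done(s).read_text()) for s in ["simulate", *STAGES] if done(s).exists()
    ]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
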