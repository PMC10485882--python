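"""End-to-end orchestration of the off-target analysis stages.

Each stage writes its result tables plus a machine-readable manifest
recording the inputs, parameters and seed that produced them.  Outputs
contain no timestamps, so re-running with the same configuration yields
byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import __version__, io_formats
from .annotation import (
    GeneIndex,
    ReferenceMismatchError,
    assign_region,
    coding_effect,
    tally_regions,
)
from .association import (
    AssociationConfig,
    associate_features,
    associated_de_summary,
    association_frame,
)
from .editing import classify_editing, summarize_distribution
from .expression import call_de_sets, de_results_frame, de_test, normalize
from .models import RNA_CLASSES
from .network import build_network, chord_matrix, edge_frame, enrich, enrichment_frame, tally_graph
from .synthetic import GroundTruth, SimulationConfig, generate_all

log = logging.getLogger(__name__)

_BIOTYPE_TO_RNA = {"coding": "mRNA", "lncRNA": "lncRNA", "miRNA": "miRNA"}

DEFAULT_INPUT_NAMES = {
    "fasta": "genome.fa",
    "gtf": "annotation.gtf",
    "circ": "circ_models.tsv",
    "vcf": "variants.vcf",
    "sample_sheet": "samples.tsv",
    "gmt": "gene_sets.gmt",
    "truth": "ground_truth.json",
    **{f"counts_{c}": f"counts_{c}.tsv" for c in RNA_CLASSES},
}


class PipelineError(RuntimeError):
    pass


def resolve_input(config: dict, key: str, required: bool = True) -> Optional[Path]:
    inputs = config.get("inputs", {})
    if key in inputs:
        path = Path(inputs[key])
    else:
        data_dir = Path(config.get("outdir", ".")) / "data"
        path = data_dir / DEFAULT_INPUT_NAMES[key]
    if not path.exists():
        if required:
            raise PipelineError(f"missing input file for {key!r}: {path}")
        return None
    return path


def _relative_to_outdir(path, outdir: Path) -> str:
    # manifests must be byte-stable across reruns in different locations
    try:
        return str(Path(path).resolve().relative_to(outdir.resolve()))
    except ValueError:
        return str(path)


def _write_manifest(outdir: Path, stage: str, config: dict, parameters: dict, inputs: dict) -> None:
    io_formats.write_json(
        {
            "stage": stage,
            "package": "editscape",
            "version": __version__,
            "seed": config.get("seed", 0),
            "inputs": {k: _relative_to_outdir(v, outdir) for k, v in inputs.items()},
            "parameters": parameters,
        },
        outdir / f"manifest_{stage}.json",
    )


class PipelineState:
    """Lazily loaded shared state across stages of one run."""

    def __init__(self, config: dict):
        self.config = config
        self.outdir = Path(config.get("outdir", "editscape_out"))
        self.outdir.mkdir(parents=True, exist_ok=True)
        self._cache: dict[str, Any] = {}
        # every explicitly referenced input must exist before a stage runs
        for key, path in config.get("inputs", {}).items():
            if not Path(path).exists():
                raise PipelineError(f"missing input file for {key!r}: {path}")

    def _load(self, key: str, loader):
        if key not in self._cache:
            self._cache[key] = loader()
        return self._cache[key]

    @property
    def genome(self):
        return self._load("genome", lambda: io_formats.read_fasta(resolve_input(self.config, "fasta")))

    @property
    def genes(self):
        return self._load("genes", lambda: io_formats.read_gtf(resolve_input(self.config, "gtf")))

    @property
    def circs(self):
        path = resolve_input(self.config, "circ", required=False)
        return self._load("circs", lambda: io_formats.read_circ_models(path) if path else [])

    @property
    def vcf(self):
        return self._load("vcf", lambda: io_formats.read_vcf(resolve_input(self.config, "vcf")))

    @property
    def sample_sheet(self):
        return self._load(
            "sheet", lambda: io_formats.read_sample_sheet(resolve_input(self.config, "sample_sheet"))
        )

    @property
    def matrices(self):
        def loader():
            out = {}
            for rna_class in RNA_CLASSES:
                path = resolve_input(self.config, f"counts_{rna_class}")
                out[rna_class] = normalize(
                    io_formats.read_counts(path, self.sample_sheet, rna_class)
                )
            return out

        return self._load("matrices", loader)

    @property
    def truth(self) -> Optional[GroundTruth]:
        path = resolve_input(self.config, "truth", required=False)
        return self._load(
            "truth", lambda: GroundTruth.from_dict(io_formats.read_json(path)) if path else None
        )

    @property
    def contrast(self) -> dict:
        groups = sorted(set(self.sample_sheet["group"]))
        default_controls = [g for g in groups if g in ("eGFP", "WT")]
        contrast = self.config.get("contrast", {})
        treated = contrast.get(
            "treated_groups", [g for g in groups if g not in default_controls]
        )
        controls = contrast.get("control_groups", default_controls or groups[-1:])
        return {"treated_groups": list(treated), "control_groups": list(controls)}

    @property
    def events(self):
        def loader():
            window = self.association_config.window_bp
            index = GeneIndex(self.genes, window)
            return [classify_editing(v, index, window) for v in self.vcf.records]

        return self._load("events", loader)

    @property
    def association_config(self) -> AssociationConfig:
        raw = dict(self.config.get("association", {}))
        if "control_groups" in raw:
            raw["control_groups"] = tuple(raw["control_groups"])
        return AssociationConfig(**raw)

    @property
    def de_results(self):
        def loader():
            contrast = self.contrast
            return {
                rna_class: de_test(m, contrast["treated_groups"], contrast["control_groups"])
                for rna_class, m in self.matrices.items()
            }

        return self._load("de_results", loader)

    @property
    def de_sets(self):
        return self._load("de_sets", lambda: call_de_sets(self.de_results))

    @property
    def association_results(self):
        def loader():
            cfg = self.association_config
            treated = self.contrast["treated_groups"]
            model_sets = {
                "mRNA": [g for g in self.genes if g.biotype == "coding"],
                "circRNA": self.circs,
                "lncRNA": [g for g in self.genes if g.biotype == "lncRNA"],
                "miRNA": [g for g in self.genes if g.biotype == "miRNA"],
            }
            out = {}
            for editing_class in ("A_to_I", "C_to_U"):
                for rna_class, models in model_sets.items():
                    out[(editing_class, rna_class)] = associate_features(
                        self.events,
                        self.matrices[rna_class],
                        models,
                        self.de_sets.all(rna_class),
                        treated,
                        cfg,
                        editing_class,
                    )
            return out

        return self._load("assoc", loader)


# ---------------------------------------------------------------------------
# Stages

def stage_simulate(config: dict) -> dict[str, Path]:
    outdir = Path(config.get("outdir", "editscape_out"))
    sim_raw = dict(config.get("simulate", {}))
    sim_raw.setdefault("seed", config.get("seed", 0))
    for key in ("groups",):
        if key in sim_raw:
            sim_raw[key] = tuple((g, int(n)) for g, n in sim_raw[key])
    if "control_groups" in sim_raw:
        sim_raw["control_groups"] = tuple(sim_raw["control_groups"])
    if "freq_beta_params" in sim_raw:
        sim_raw["freq_beta_params"] = tuple(sim_raw["freq_beta_params"])
    sim = SimulationConfig(**sim_raw)
    paths = generate_all(sim, outdir / "data")
    params = asdict(sim)
    params["groups"] = [list(g) for g in sim.groups]
    _write_manifest(outdir, "simulate", config, params, {})
    return paths


def stage_classify(state: PipelineState) -> None:
    events = state.events
    samples = state.vcf.samples
    rows = []
    for ev in events:
        row = {
            "chrom": ev.variant.chrom,
            "pos": ev.variant.pos,
            "ref": ev.variant.ref,
            "alt": ev.variant.alt,
            "editing_class": ev.editing_class,
            "strand": ev.resolved_strand,
            "host_gene": ev.host_gene_id or "",
            "region": ev.region or "",
            "multi_gene": ev.multi_gene,
        }
        for s in samples:
            f = ev.variant.frequency(s)
            row[f"freq_{s}"] = "" if f is None else round(f, 6)
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(["chrom", "pos", "alt"], kind="stable")
    df.to_csv(state.outdir / "events.tsv", sep="\t", index=False)
    chrom_lengths = {c: len(s) for c, s in state.genome.items()}
    treated = [
        s
        for s in samples
        if state.sample_sheet.set_index("sample")["group"][s] in state.contrast["treated_groups"]
    ]
    for editing_class in ("A_to_I", "C_to_U", "other", "ambiguous"):
        summary = summarize_distribution(events, editing_class, chrom_lengths, treated)
        io_formats.write_json(
            {
                "editing_class": editing_class,
                "total": summary.total,
                "counts": summary.counts,
                "chi2": summary.chi2,
                "chi2_pvalue": summary.chi2_pvalue,
                "per_chromosome": {
                    c: [[p, round(f, 6)] for p, f in sites]
                    for c, sites in sorted(summary.per_chromosome.items())
                },
                "strand_convention": "hostless variants classified on the + strand",
            },
            state.outdir / f"distribution_{editing_class}.json",
        )
    _write_manifest(
        state.outdir,
        "classify",
        state.config,
        {"window_bp": state.association_config.window_bp, "n_skipped_non_snv": state.vcf.n_skipped_non_snv},
        {"vcf": resolve_input(state.config, "vcf"), "gtf": resolve_input(state.config, "gtf")},
    )


def stage_annotate(state: PipelineState) -> None:
    gene_index = {g.gene_id: g for g in state.genes}
    rows = []
    tally_inputs_by_class: dict[str, list[tuple[str, str]]] = {c: [] for c in RNA_CLASSES}
    effect_counts: dict[str, dict[str, int]] = {}
    for ev in state.events:
        if ev.editing_class not in ("A_to_I", "C_to_U") or ev.host_gene_id is None:
            continue
        gene = gene_index[ev.host_gene_id]
        rna_class = _BIOTYPE_TO_RNA[gene.biotype]
        entry = {
            "variant_id": ev.variant.variant_id,
            "feature_id": gene.gene_id,
            "rna_class": rna_class,
            "editing_class": ev.editing_class,
            "region": ev.region,
            "effect": "",
            "codon_before": "",
            "codon_after": "",
            "aa_before": "",
            "aa_after": "",
        }
        if gene.biotype == "coding" and ev.region == "exon" and any(
            s <= ev.variant.pos <= e for s, e in gene.cds
        ):
            try:
                ce = coding_effect(ev.variant, gene, state.genome)
            except ReferenceMismatchError as exc:
                raise PipelineError(str(exc)) from exc
            entry.update(
                effect=ce.effect,
                codon_before=ce.codon_before,
                codon_after=ce.codon_after,
                aa_before=ce.aa_before,
                aa_after=ce.aa_after,
            )
            effect_counts.setdefault(ev.editing_class, {}).setdefault(ce.effect, 0)
            effect_counts[ev.editing_class][ce.effect] += 1
        rows.append(entry)
        tally_inputs_by_class[rna_class].append((ev.editing_class, ev.region))
        for circ in state.circs:
            call = assign_region(ev.variant, circ, state.association_config.window_bp)
            if call is not None:
                rows.append(
                    {
                        "variant_id": ev.variant.variant_id,
                        "feature_id": circ.circ_id,
                        "rna_class": "circRNA",
                        "editing_class": ev.editing_class,
                        "region": call.region,
                        "effect": "",
                        "codon_before": "",
                        "codon_after": "",
                        "aa_before": "",
                        "aa_after": "",
                    }
                )
                tally_inputs_by_class["circRNA"].append((ev.editing_class, call.region))
    pd.DataFrame(rows).sort_values(["variant_id", "feature_id"], kind="stable").to_csv(
        state.outdir / "annotation.tsv", sep="\t", index=False
    )
    tallies = []
    for rna_class, pairs in tally_inputs_by_class.items():
        t = tally_regions(pairs)
        if len(t):
            t.insert(0, "rna_class", rna_class)
            tallies.append(t)
    tally_df = (
        pd.concat(tallies, ignore_index=True)
        if tallies
        else pd.DataFrame(columns=["rna_class", "editing_class", "region", "count", "fraction"])
    )
    tally_df.to_csv(state.outdir / "region_tallies.tsv", sep="\t", index=False)
    fractions = {}
    for editing_class, counts in sorted(effect_counts.items()):
        total = sum(counts.values())
        fractions[editing_class] = {
            "counts": dict(sorted(counts.items())),
            "fractions": {k: v / total for k, v in sorted(counts.items())},
            "total": total,
        }
    io_formats.write_json(fractions, state.outdir / "effect_fractions.json")
    _write_manifest(
        state.outdir,
        "annotate",
        state.config,
        {"window_bp": state.association_config.window_bp},
        {"vcf": resolve_input(state.config, "vcf"), "gtf": resolve_input(state.config, "gtf"),
         "fasta": resolve_input(state.config, "fasta")},
    )


def stage_de(state: PipelineState) -> None:
    for rna_class, results in state.de_results.items():
        de_results_frame(results).sort_values("feature_id", kind="stable").to_csv(
            state.outdir / f"de_{rna_class}.tsv", sep="\t", index=False
        )
    io_formats.write_json(
        {"contrast": state.contrast, "summary": state.de_sets.summary()},
        state.outdir / "de_summary.json",
    )
    inputs = {f"counts_{c}": resolve_input(state.config, f"counts_{c}") for c in RNA_CLASSES}
    _write_manifest(
        state.outdir,
        "de",
        state.config,
        {"test": "welch_t_log2", "pseudocount": 0.5, "log2fc_threshold": 1.0, "q_threshold": 0.05,
         "contrast": state.contrast},
        inputs,
    )


def stage_associate(state: PipelineState) -> None:
    summary: dict[str, dict] = {}
    for (editing_class, rna_class), results in state.association_results.items():
        association_frame(results).sort_values("feature_id", kind="stable").to_csv(
            state.outdir / f"assoc_{editing_class}_{rna_class}.tsv", sep="\t", index=False
        )
        summary.setdefault(editing_class, {})[rna_class] = associated_de_summary(
            results,
            state.de_sets.up.get(rna_class, set()),
            state.de_sets.down.get(rna_class, set()),
        )
    io_formats.write_json(summary, state.outdir / "assoc_summary.json")
    cfg = state.association_config
    if cfg.fdr_threshold > 0.1:
        log.warning("association FDR threshold %.2f is permissive", cfg.fdr_threshold)
    _write_manifest(
        state.outdir,
        "associate",
        state.config,
        {**asdict(cfg), "control_groups": list(cfg.control_groups),
         "treated_groups": state.contrast["treated_groups"],
         "aggregation": "within-feature Bonferroni over window variants"},
        {"vcf": resolve_input(state.config, "vcf")},
    )


def stage_network(state: PipelineState) -> None:
    net_cfg = state.config.get("network", {})
    r_threshold = float(net_cfg.get("r_threshold", 0.9))
    p_threshold = float(net_cfg.get("p_threshold", 0.05))
    node_features = {c: set() for c in RNA_CLASSES}
    for (editing_class, rna_class), results in state.association_results.items():
        node_features[rna_class] |= {r.feature_id for r in results if r.associated_de}
    expression = {c: state.matrices[c].log2_normalized() for c in RNA_CLASSES}
    graph = build_network(
        {c: sorted(v) for c, v in node_features.items()}, expression, r_threshold, p_threshold
    )
    edge_frame(graph).to_csv(state.outdir / "network_edges.tsv", sep="\t", index=False)
    tallies = tally_graph(graph)
    io_formats.write_json(
        {
            "tallies": tallies,
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "edge_rule": (
                "co-expression: |Pearson r| >= "
                f"{r_threshold} and p < {p_threshold} on log2 normalized expression; "
                "this package's own edge definition"
            ),
        },
        state.outdir / "network_tallies.json",
    )
    chord_matrix(graph).to_csv(state.outdir / "chord_matrix.csv")
    _write_manifest(
        state.outdir, "network", state.config,
        {"r_threshold": r_threshold, "p_threshold": p_threshold}, {},
    )


def stage_enrich(state: PipelineState) -> None:
    gmt_path = resolve_input(state.config, "gmt", required=False)
    if gmt_path is None:
        log.info("no GMT provided; skipping enrichment")
        return
    gene_sets = io_formats.read_gmt(gmt_path)
    universe = set(state.matrices["mRNA"].features)
    study = state.de_sets.all("mRNA") & universe
    results = enrich(study, gene_sets, universe)
    enrichment_frame(results).to_csv(state.outdir / "enrichment.tsv", sep="\t", index=False)
    _write_manifest(
        state.outdir, "enrich", state.config,
        {"study_size": len(study), "universe_size": len(universe)}, {"gmt": gmt_path},
    )


def _recovery_report(state: PipelineState) -> None:
    truth = state.truth
    if truth is None:
        return
    report: dict[str, Any] = {}
    planted_class = {
        pv.variant_id: pv.editing_class for pv in truth.planted_variants
    }
    matched = sum(
        1
        for ev in state.events
        if planted_class.get(ev.variant.variant_id) == ev.editing_class
    )
    report["classification"] = {
        "n_planted": len(planted_class),
        "n_matching": matched,
        "agreement": matched / len(planted_class) if planted_class else 1.0,
    }
    de_recovery = {}
    for rna_class, planted in truth.planted_de.items():
        planted_ids = {d["feature_id"] for d in planted}
        called = state.de_sets.all(rna_class)
        tp = len(planted_ids & called)
        de_recovery[rna_class] = {
            "n_planted": len(planted_ids),
            "n_called": len(called),
            "sensitivity": tp / len(planted_ids) if planted_ids else None,
            "precision": tp / len(called) if called else None,
        }
    report["differential_expression"] = de_recovery
    coupled = {c["gene_id"] for c in truth.planted_couplings}
    sig = set()
    for (editing_class, rna_class), results in state.association_results.items():
        if rna_class == "mRNA":
            sig |= {r.feature_id for r in results if r.significant}
    report["association"] = {
        "n_planted_couplings": len(coupled),
        "n_recovered": len(coupled & sig),
        "sensitivity": len(coupled & sig) / len(coupled) if coupled else None,
    }
    io_formats.write_json(report, state.outdir / "recovery.json")


STAGES = {
    "classify": stage_classify,
    "annotate": stage_annotate,
    "de": stage_de,
    "associate": stage_associate,
    "network": stage_network,
    "enrich": stage_enrich,
}


def run_stage(name: str, config: dict) -> PipelineState:
    state = PipelineState(config)
    STAGES[name](state)
    return state


def run_all(config: dict) -> PipelineState:
    state = PipelineState(config)
    for name in ("classify", "annotate", "de", "associate", "network", "enrich"):
        STAGES[name](state)
    _recovery_report(state)
    _write_manifest(state.outdir, "run_all", config, {"stages": list(STAGES)}, {})
    return state
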