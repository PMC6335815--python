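"""End-to-end orchestration of the synthetic-data pipeline.

Stages run in dependency order: simulate -> orthology -> seq_evol ->
branch_rates, with go_sets and heat_response as independent arms.  Every
run emits its tables plus a manifest (seed, parameter hash, per-file
checksums) so that a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import branch_rates as br
from . import go_sets as gs
from . import heat
from . import io as cio
from . import orthology as orth
from . import seqevol as se
from .simulate import (
    SimulationConfig,
    simulate_codon_sequences,
    simulate_expression,
    simulate_gene_families,
    simulate_go_annotations,
)
from .tree import REPLETA_SPECIES

STAGES = ("simulate", "orthology", "seq_evol", "branch_rates", "go_sets", "heat_response")

STAGE_DEPS = {
    "orthology": ("simulate",),
    "seq_evol": ("simulate",),
    "branch_rates": ("orthology", "seq_evol"),
    "go_sets": ("simulate",),
    "heat_response": ("simulate",),
}


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    synteny_window: int = 5
    fcm_clusters: int | None = 8       # None -> choose by partition coefficient
    fcm_restarts: int = 5
    make_plots: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for stage in self.stages:
            missing = [d for d in STAGE_DEPS.get(stage, ()) if d not in self.stages]
            if missing:
                raise ValueError(
                    f"stage {stage!r} requires disabled stage(s) {missing}"
                )


def _param_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    payload = dataclasses.asdict(config)
    payload.pop("outdir", None)  # hash covers scientific parameters only
    blob = json.dumps(payload, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns the manifest dictionary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "seed": config.seed,
        "parameter_hash": _param_hash(config),
        "stages": list(config.stages),
        "files": {},
    }

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["files"][name] = cio.sha256_of(path)

    artifacts: dict = {}

    if "simulate" in config.stages:
        gene_tables, truth = simulate_gene_families(sim, rng)
        sequences = simulate_codon_sequences(truth, sim, rng)
        artifacts["truth"] = truth
        artifacts["sequences"] = sequences
        tree = sim.tree()
        artifacts["tree"] = tree
        emit("species_tree.nwk", lambda p: cio.write_tree(tree, p))
        for sp, table in gene_tables.items():
            emit(
                f"genes_{sp}.tsv",
                lambda p, t=table: cio.write_tsv(
                    t[["gene_id", "species", "scaffold", "order_index", "strand"]], p
                ),
            )
            sp_seqs = {
                g: s
                for fam in sequences.values()
                for g, s in fam.items()
                if g.startswith(sp + "|")
            }
            if sp_seqs:
                emit(f"cds_{sp}.fasta", lambda p, s=sp_seqs: cio.write_fasta(s, p))
        emit("selection_flags.tsv", lambda p: cio.write_tsv(truth.selection, p))
        emit("truth_genes.tsv", lambda p: cio.write_tsv(truth.genes, p))

    if "orthology" in config.stages:
        truth = artifacts["truth"]
        sequences = artifacts["sequences"]
        tree = artifacts["tree"]
        sim_edges = [
            orth.similarity_from_sequences(fam_seqs)
            for fam_seqs in sequences.values()
            if len(fam_seqs) > 1
        ]
        similarity = (
            pd.concat(sim_edges, ignore_index=True)
            if sim_edges
            else pd.DataFrame(columns=cio.SIMILARITY_COLUMNS)
        )
        omap = orth.classify_orthology(
            truth.genes, similarity, tree, synteny_window=config.synteny_window
        )
        artifacts["orthology"] = omap
        species_of = dict(zip(truth.genes["gene_id"], truth.genes["species"]))
        emit("orthology_map.tsv", lambda p: cio.write_tsv(omap.to_frame(species_of), p))
        emit(
            "orthology_summary.tsv",
            lambda p: cio.write_tsv(omap.counts_by_species(species_of), p, index=True),
        )

    if "seq_evol" in config.stages:
        sequences = artifacts["sequences"]
        tree = artifacts["tree"]
        truth = artifacts["truth"]
        # silent branch lengths from families spanning every species
        all_sp = set(tree.species)
        spanning = {
            fam: {g.split("|")[0]: s for g, s in seqs.items() if "|d" not in g}
            for fam, seqs in sequences.items()
        }
        spanning = {
            fam: by_sp for fam, by_sp in spanning.items() if set(by_sp) == all_sp
        }
        if spanning:
            concat = {
                sp: "".join(spanning[fam][sp] for fam in sorted(spanning))
                for sp in sorted(all_sp)
            }
            aln = se.CodonAlignment(concat)
            dist = se.jc_silent_distance(aln)
            lengths, resid = se.ls_branch_lengths(tree, dist)
            artifacts["branch_lengths"] = lengths
            emit(
                "silent_branch_lengths.tsv",
                lambda p: cio.write_tsv(
                    pd.DataFrame(
                        sorted(lengths.items()), columns=["branch", "silent_length"]
                    ),
                    p,
                ),
            )
        else:
            artifacts["branch_lengths"] = tree.branch_lengths

    if "branch_rates" in config.stages:
        truth = artifacts["truth"]
        omap = artifacts["orthology"]
        tree = artifacts["tree"].with_branch_lengths(artifacts["branch_lengths"])
        table = br.tabulate_branch_events(omap, truth.selection, tree)
        sel_branches = sorted(set(truth.selection["branch"]))
        table = br.expected_and_excess(
            table, restrict={"selected_genes": sel_branches}
        )
        artifacts["branch_events"] = table
        emit("branch_events.tsv", lambda p: cio.write_tsv(table, p, index=True))

        genes = truth.genes
        in_group = genes["species"].isin(REPLETA_SPECIES)
        fams_dup = genes[genes["is_inparalogue"]].groupby("species")["family_id"].agg(set)
        sel = truth.selection[truth.selection["branch"].isin(REPLETA_SPECIES)]
        sel_genes = set(sel.loc[sel["selected"] == 1, "gene_id"])
        sub = genes[in_group & ~genes["is_inparalogue"]]
        flags = pd.DataFrame(
            {
                "gene_id": sub["gene_id"],
                "species": sub["species"],
                "has_inparalogue": [
                    f in fams_dup.get(sp, set())
                    for sp, f in zip(sub["species"], sub["family_id"])
                ],
                "is_selected": sub["gene_id"].isin(sel_genes),
            }
        )
        assoc = br.association_table(flags)
        artifacts["association"] = assoc
        emit("duplication_selection.tsv", lambda p: cio.write_tsv(assoc, p))

    if "go_sets" in config.stages:
        obo_text, annotations, go_truth = simulate_go_annotations(sim, rng)
        emit("ontology.obo", lambda p: Path(p).write_text(obo_text))
        emit("annotations.tsv", lambda p: cio.write_tsv(annotations, p))
        import io as _stdio

        graph = cio.read_obo(_stdio.StringIO(obo_text))
        ggraph = gs.GoGraph.from_obonet(
            graph, annotations.groupby("gene_id")["go_id"].agg(set).to_dict()
        )
        weighted = gs.edge_weights(ggraph)
        partition = gs.louvain_partition(weighted, seed=config.seed)
        partition = gs.label_partition(partition, ggraph)
        partition.validate(weighted.nodes)
        enrich = gs.enrich_sets(
            go_truth["study_genes"], list(ggraph.annotations), partition, ggraph
        )
        artifacts["go_partition"] = partition
        artifacts["go_enrichment"] = enrich
        artifacts["go_truth"] = go_truth
        emit("go_partition.tsv", lambda p: cio.write_tsv(partition.to_frame(), p))
        emit("go_enrichment.tsv", lambda p: cio.write_tsv(enrich, p))

    if "heat_response" in config.stages:
        counts, expr_truth = simulate_expression(sim, rng)
        artifacts["expression_truth"] = expr_truth
        profiles = {}
        de_results = {}
        for sp, mat in counts.items():
            emit(f"counts_{sp}.tsv", lambda p, m=mat: cio.write_tsv(m, p, index=True))
            kept = heat.filter_low_expression(mat)
            res = heat.de_call(kept)
            de_results[sp] = res
            means = heat.timepoint_means(res.expr.loc[res.de[res.de].index])
            if len(means):
                profiles[sp] = heat.standardize_profiles(means)
        artifacts["de"] = de_results
        pooled = pd.concat(
            [p.set_index(pd.Index([f"{sp}|{g}" for g in p.index])) for sp, p in profiles.items()]
        )
        if len(pooled) > 2:
            c = config.fcm_clusters
            if c is None:
                c, _ = heat.select_c(pooled, seed=config.seed, restarts=config.fcm_restarts)
            memberships, centroids = heat.fuzzy_cmeans(
                pooled, c=min(c, len(pooled) - 1), seed=config.seed,
                restarts=config.fcm_restarts,
            )
            gene_species = pd.Series(
                {g: g.split("|")[0] for g in pooled.index}, name="species"
            )
            # same gene id in both species = 1:1 orthologue in the toy universe
            pairs = {}
            sps = sorted(profiles)
            if len(sps) == 2:
                a, b = sps
                for g in pooled.index:
                    sp, raw = g.split("|", 1)
                    pairs[g] = f"{b if sp == a else a}|{raw}"
            summary, tops, unclustered = heat.cluster_report(
                memberships, gene_species, pairs
            )
            artifacts["memberships"] = memberships
            artifacts["cluster_summary"] = summary
            emit("memberships.tsv", lambda p: cio.write_tsv(memberships, p, index=True))
            emit("cluster_report.tsv", lambda p: cio.write_tsv(summary, p))
            if config.make_plots:
                emit(
                    "cluster_trajectories.png",
                    lambda p: heat.plot_cluster_trajectories(
                        pooled, memberships, centroids, p
                    ),
                )
        de_summary = pd.DataFrame(
            [{"species": sp, "n_de": r.n_de()} for sp, r in de_results.items()]
        )
        emit("de_summary.tsv", lambda p: cio.write_tsv(de_summary, p))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = manifest
    return artifacts
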