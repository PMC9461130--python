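"""End-to-end orchestration: simulate -> assoc -> qtl -> annotate -> grn -> network.

The demo cohort reproduces, at desk scale, the statistical structure the
analysis assumes: 398 RILs from orthogonal/reciprocal crosses on a 5 x 100 cM
genome, three oil-related traits measured in two environments, a replicated
metabolome/lipidome (20 metabolites + 30 lipids, two biological replicates)
riding on a sparse precision matrix, and a regulatory layer (genes, one TF,
miRNAs, promoters, expression, PPI) planted so that five trait--compound--gene
(--miRNA) relations are recoverable as 3D/4D circulating sub-networks.  The
ground-truth ledger written next to the inputs lists every planted relation,
so the run report can score recovery instead of merely counting edges.

``run_pipeline`` executes the stages in order, writes per-stage TSV outputs
plus a manifest (config hash, seed, package version, per-stage record counts)
and returns the run directory.  All randomness derives from the single
configured seed; reruns with an identical config produce byte-identical
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotate, assoc, grn, io, network, qtl
from . import simulate as sim

TRAITS = ["oil_content", "oleic_acid", "linolenic_acid"]
ENVIRONMENTS = ["E1", "E2"]


@dataclass
class PipelineConfig:
    """Thresholds, seeds and stage toggles for one pipeline run."""

    seed: int = 1
    # simulated cohort
    n_lines: int = 398
    n_oc: int = 171
    n_metabolites: int = 20
    n_lipids: int = 30
    marker_spacing_cM: float = 2.0
    trait_h2: float = 0.55
    # thresholds (published cutoffs)
    lod_im: float = 2.5
    lod_mls: float = 3.0
    lod_qei: float = 5.0
    flank_kb: float = 200.0
    r_min: float = 0.8
    ppi_min: float = 0.40
    fimo_p: float = 1.0e-4
    alpha: float = 0.05
    ggm_alpha: float = 0.05
    mcc_top: float = 0.10
    # association selection
    n_folds: int = 10
    n_lambda: int = 100
    # circuits
    min_cycle: int = 3
    max_cycle: int = 5
    # stage toggles
    stages: tuple = ("simulate", "assoc", "qtl", "annotate", "grn", "network")
    # optional external input directory (defaults to <run>/simulate)
    input_dir: str | None = None

    def __post_init__(self):
        checks = [
            (0 < self.r_min <= 1, "r_min"), (0 < self.alpha < 1, "alpha"),
            (0 < self.ggm_alpha < 1, "ggm_alpha"), (0 < self.mcc_top <= 1, "mcc_top"),
            (self.flank_kb >= 0, "flank_kb"), (0 < self.fimo_p <= 1, "fimo_p"),
            (self.lod_im > 0, "lod_im"), (self.lod_mls > 0, "lod_mls"),
            (self.lod_qei > 0, "lod_qei"),
        ]
        for ok, name in checks:
            if not ok:
                raise ValueError(f"config field {name} outside its documented range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# demo cohort with planted tri-layer relations
# ---------------------------------------------------------------------------

DEMO_PWM_PROBS = 0.94


def demo_pwm() -> grn.PWM:
    """An 8-bp informative motif (consensus TGACGTCA, bZIP-like)."""
    consensus = "TGACGTCA"
    mat = np.full((4, len(consensus)), (1 - DEMO_PWM_PROBS) / 3)
    for j, b in enumerate(consensus):
        mat["ACGT".index(b), j] = DEMO_PWM_PROBS
    return grn.PWM("bZIP_demo", mat)


def build_demo_cohort(cfg: PipelineConfig, out_dir: Path) -> dict:
    """Generate genotypes, phenotypes, omics and regulatory truth; write files.

    Five relations are planted, one per chromosome at 50 cM: a trait QTL and a
    compound mQTL at the same position, a causal gene at the locus midpoint
    (seed-specific, DEG, 55-DAF-high, TF-bound), and a miRNA 50 kb away that
    targets the gene.  A crossover QEI for linolenic acid sits at chr1:20 cM.
    """
    out_dir.mkdir(parents=True, exist_ok=True)
    rng_seed = cfg.seed
    map_spec = sim.MapSpec.uniform(5, 100.0, cfg.marker_spacing_cM)
    geno = sim.simulate_ril_population(map_spec, cfg.n_lines, cfg.n_oc, seed=rng_seed)

    metabolites = [f"M{i + 1:02d}" for i in range(cfg.n_metabolites)]
    lipids = [f"L{i + 1:02d}" for i in range(cfg.n_lipids)]
    compounds = metabolites + lipids
    categories = {m: "metabolite" for m in metabolites}
    categories.update({l: "lipid" for l in lipids})
    # compound classes for mQTL-cluster merging
    class_names = ["carbohydrate", "amino acid", "organic acid", "fatty acid"]
    lipid_classes = ["glycerolipid", "glycerophospholipid", "sphingolipid"]
    class_map = {m: class_names[i % len(class_names)] for i, m in enumerate(metabolites)}
    class_map.update({l: lipid_classes[i % len(lipid_classes)] for i, l in enumerate(lipids)})

    relations = [
        {"trait": "oil_content", "compound": "M01", "chrom": "chr1"},
        {"trait": "oil_content", "compound": "M02", "chrom": "chr2"},
        {"trait": "oleic_acid", "compound": "L01", "chrom": "chr3"},
        {"trait": "oleic_acid", "compound": "M03", "chrom": "chr4"},
        {"trait": "linolenic_acid", "compound": "L02", "chrom": "chr5"},
    ]
    pos_cM = 50.0
    trait_qtls = [
        sim.QtlSpec(rel["trait"], rel["chrom"], pos_cM, 1.0) for rel in relations
    ]
    trait_qtls.append(
        sim.QtlSpec("linolenic_acid", "chr1", 20.0, 0.0, env_effects=(0.6, -0.6))
    )
    traits_table = sim.simulate_trait_phenotypes(
        geno, trait_qtls, cfg.trait_h2, ENVIRONMENTS, seed=rng_seed + 1
    )

    omega = np.eye(len(compounds))
    # planted GGM backbone among non-QTL compounds
    ggm_pairs = [("M05", "M06"), ("M07", "M08"), ("L05", "L06"), ("L07", "L08")]
    for a, b in ggm_pairs:
        i, j = compounds.index(a), compounds.index(b)
        omega[i, j] = omega[j, i] = -0.35
    prec = sim.PrecisionSpec(tuple(compounds), omega, class_map)
    mqtls = [
        sim.QtlSpec(rel["compound"], rel["chrom"], pos_cM, 1.2,
                    category=categories[rel["compound"]])
        for rel in relations
    ]
    metabolome = sim.simulate_metabolome(
        prec, geno, mqtls, n_reps=2, seed=rng_seed + 2, rep_noise_sd=0.5
    )

    pwm = demo_pwm()
    bp_mid = int(pos_cM * map_spec.bp_per_cM)
    loci = [
        {
            "id": f"locus_{rel['chrom']}",
            "chrom": rel["chrom"],
            "start_bp": bp_mid - 100_000,
            "end_bp": bp_mid + 100_000,
            "gene": True,
            "mirna": True,
            "decoy": True,
        }
        for rel in relations
    ]
    reg = sim.simulate_regulatory_truth(map_spec, loci, pwm, seed=rng_seed + 3)
    for rel, locus in zip(relations, loci):
        rel["gene"] = reg.ledger["locus_genes"][locus["id"]][0]
        rel["mirna"] = reg.ledger["locus_mirnas"][locus["id"]][0]
    reg.ledger["relations"] = relations
    reg.ledger["qei"] = [{"trait": "linolenic_acid", "chrom": "chr1", "pos_cM": 20.0}]

    io.write_genotypes(geno.geno, out_dir / "genotypes.csv")
    io.write_genetic_map(geno.gmap, out_dir / "map.tsv")
    geno.cross.to_frame().to_csv(out_dir / "cross.tsv", sep="\t", index_label="line")
    io.write_phenotypes(traits_table, out_dir / "traits.tsv")
    io.write_phenotypes(metabolome, out_dir / "metabolome.tsv")
    io.write_gff3(reg.features, out_dir / "features.gff3")
    io.write_fasta(reg.promoters, out_dir / "promoters.fasta")
    io.write_fasta(reg.transcripts, out_dir / "transcripts.fasta")
    io.write_fasta(reg.mirna_seqs, out_dir / "mirnas.fasta")
    io.write_expression(reg.atlas_expr, out_dir / "atlas_fpkm.tsv")
    io.write_expression(reg.stage_expr, out_dir / "stage_fpkm.tsv")
    reg.deg_counts.to_csv(out_dir / "deg_counts.tsv", sep="\t", index_label="gene")
    reg.lfc.to_csv(out_dir / "lfc.tsv", sep="\t", index_label="node")
    io.write_ppi(reg.ppi, out_dir / "ppi.tsv")
    grn.write_meme([pwm], out_dir / "motifs.meme")
    io.write_json(
        {"categories": categories, "class_map": class_map, "traits": TRAITS},
        out_dir / "variables.json",
    )
    io.write_json(reg.ledger, out_dir / "ledger.json")
    return {
        "geno": geno, "traits_table": traits_table, "metabolome": metabolome,
        "reg": reg, "pwm": pwm, "categories": categories, "class_map": class_map,
        "ledger": reg.ledger, "map_spec": map_spec,
    }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _load_inputs(in_dir: Path) -> dict:
    geno = sim.GenotypeData(
        io.read_genotypes(in_dir / "genotypes.csv"),
        io.read_genetic_map(in_dir / "map.tsv"),
        pd.read_csv(in_dir / "cross.tsv", sep="\t", index_col="line")["cross"],
    )
    variables = io.read_json(in_dir / "variables.json")
    reg_lfc = pd.read_csv(in_dir / "lfc.tsv", sep="\t", index_col="node")
    return {
        "geno": geno,
        "traits_table": io.read_phenotypes(in_dir / "traits.tsv"),
        "metabolome": io.read_phenotypes(in_dir / "metabolome.tsv"),
        "features": io.read_gff3(in_dir / "features.gff3"),
        "promoters": io.read_fasta(in_dir / "promoters.fasta"),
        "transcripts": io.read_fasta(in_dir / "transcripts.fasta"),
        "mirna_seqs": io.read_fasta(in_dir / "mirnas.fasta"),
        "atlas": io.read_expression(in_dir / "atlas_fpkm.tsv"),
        "stage_expr": io.read_expression(in_dir / "stage_fpkm.tsv"),
        "deg_counts": pd.read_csv(in_dir / "deg_counts.tsv", sep="\t", index_col="gene"),
        "lfc": reg_lfc,
        "ppi": io.read_ppi(in_dir / "ppi.tsv"),
        "pwms": grn.read_meme(in_dir / "motifs.meme"),
        "categories": variables["categories"],
        "class_map": variables["class_map"],
        "traits": variables["traits"],
        "ledger": io.read_json(in_dir / "ledger.json")
        if (in_dir / "ledger.json").exists() else None,
    }


def stage_assoc(state: dict, cfg: PipelineConfig, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    blup = assoc.compute_blup(state["traits_table"])
    blup.to_csv(out / "trait_blup.tsv", sep="\t", na_rep="NA")
    omics_log = assoc.log2_transform(state["metabolome"])
    categories = state["categories"]
    reps = sorted(omics_log["environment"].unique())
    edges = []
    for trait in blup.columns:
        per_rep = []
        for rep in reps:
            wide = io.pivot_phenotypes(
                omics_log.loc[omics_log["environment"] == rep]
            )
            found = assoc.select_trait_associations(
                blup[trait], wide, categories, n_folds=cfg.n_folds,
                seed=cfg.seed + 10, alpha=cfg.alpha,
            )
            per_rep.append({e.node_b for e in found})
            if rep == reps[0]:
                rep_edges = {e.node_b: e for e in found}
        stable_vars = set.intersection(*per_rep) if per_rep else set()
        edges.extend(rep_edges[v] for v in sorted(stable_vars))
    omics_mean = io.pivot_phenotypes(omics_log, aggregate="mean")
    ggm = assoc.ggm_edges(omics_mean, alpha_family=cfg.ggm_alpha,
                          categories=categories)
    all_edges = edges + ggm.edges
    assoc.edges_to_frame(all_edges).to_csv(out / "assoc_edges.tsv", sep="\t",
                                           index=False)
    node_types = {t: "trait" for t in blup.columns}
    node_types.update(categories)
    cliques = assoc.trait_cliques(all_edges, node_types)
    pd.DataFrame(
        [{"members": ",".join(c["members"]), "types": ",".join(c["types"])}
         for c in cliques]
    ).to_csv(out / "trait_cliques.tsv", sep="\t", index=False)
    return {"assoc_edges": all_edges, "trait_assoc_edges": edges,
            "ggm": ggm, "blup": blup, "omics_log": omics_log}


def stage_qtl(state: dict, cfg: PipelineConfig, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    geno: sim.GenotypeData = state["geno"]
    cov = geno.covariate()
    cache: dict = {}
    blup: pd.DataFrame = state["blup"]
    traits_table = state["traits_table"]
    trait_records = []
    for trait in blup.columns:
        series = {"BLUP": blup[trait]}
        for env in sorted(traits_table["environment"].unique()):
            sub = traits_table.query("variable == @trait and environment == @env")
            series[env] = sub.set_index("line")["value"].rename(trait)
        for env, y in series.items():
            trait_records += qtl.interval_mapping(
                geno, y, cov, lod_min=cfg.lod_im, environment=env, _cache=cache
            )
            trait_records += qtl.multilocus_scan(
                geno, y, cov, lod_min=cfg.lod_mls, environment=env
            )
    qei_records = []
    for trait in blup.columns:
        qei_records += qtl.detect_qei(
            geno, traits_table, cov, lod_min=cfg.lod_qei, variable=trait
        )
    stable = qtl.call_stable(trait_records)
    omics_log = state["omics_log"]
    mqtl_records = []
    for rep in sorted(omics_log["environment"].unique()):
        wide = io.pivot_phenotypes(omics_log.loc[omics_log["environment"] == rep])
        for var in wide.columns:
            y = wide[var]
            mqtl_records += qtl.interval_mapping(
                geno, y, cov, lod_min=cfg.lod_im, environment=rep, _cache=cache
            )
            mqtl_records += qtl.multilocus_scan(
                geno, y, cov, lod_min=cfg.lod_mls, environment=rep
            )
    clusters = qtl.merge_mqtl_clusters(mqtl_records, state["class_map"])
    pairs = qtl.colocate(stable, clusters, window_kb=cfg.flank_kb)
    qtl.records_to_frame(trait_records).to_csv(out / "trait_qtls.tsv", sep="\t",
                                               index=False)
    qtl.records_to_frame(qei_records).to_csv(out / "qei.tsv", sep="\t", index=False)
    qtl.records_to_frame(mqtl_records).to_csv(out / "mqtls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"variable": s.variable, "chrom": s.chrom, "peak_cM": s.peak_cM,
          "left_bp": s.left_bp, "right_bp": s.right_bp,
          "methods": "+".join(sorted(s.methods)),
          "environments": "+".join(sorted(s.environments))}
         for s in stable]
    ).to_csv(out / "stable_trait_qtls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"category": c.category, "chrom": c.chrom, "left_bp": c.merged_left_bp,
          "right_bp": c.merged_right_bp, "variables": "+".join(sorted(c.variables)),
          "methods": "+".join(sorted(c.methods))}
         for c in clusters]
    ).to_csv(out / "mqtl_clusters.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"trait": t.variable, "trait_chrom": t.chrom, "trait_peak_cM": t.peak_cM,
          "cluster_category": c.category, "cluster_left_bp": c.merged_left_bp,
          "cluster_right_bp": c.merged_right_bp,
          "cluster_variables": "+".join(sorted(c.variables))}
         for t, c in pairs]
    ).to_csv(out / "colocated.tsv", sep="\t", index=False)
    return {"trait_records": trait_records, "qei_records": qei_records,
            "stable": stable, "mqtl_records": mqtl_records, "clusters": clusters,
            "colocated": pairs}


def stage_annotate(state: dict, cfg: PipelineConfig, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    features = state["features"]
    expressed = annotate.filter_expressed(state["atlas"])
    seed_set = annotate.seed_specific(state["atlas"])
    high55 = annotate.high_expression_55daf(state["stage_expr"])
    deg = annotate.deg_high_low_oil(
        state["deg_counts"]["high_oil"], state["deg_counts"]["low_oil"],
        alpha=cfg.alpha,
    )
    trait_calls, trait_mirnas = [], []
    for s in state["stable"]:
        locus = annotate.Locus(f"{s.variable}:{s.chrom}:{s.peak_cM:g}",
                               s.chrom, s.left_bp, s.right_bp, s.variable)
        trait_calls += annotate.candidate_genes(
            locus, features, seed_set, deg, high55, expressed,
            mode="trait", flank_kb=cfg.flank_kb,
        )
        trait_mirnas += [
            (s.variable, m.id)
            for m in annotate.mirnas_in_window(locus, features, cfg.flank_kb)
        ]
    metab_calls, metab_mirnas = [], []
    for c in state["clusters"]:
        locus = annotate.Locus(
            f"cluster:{c.chrom}:{c.category}", c.chrom,
            c.merged_left_bp, c.merged_right_bp,
        )
        calls = annotate.candidate_genes(
            locus, features, seed_set, deg, high55, expressed,
            mode="metabolite", flank_kb=cfg.flank_kb,
        )
        for var in sorted(c.variables):
            metab_calls += [(var, call) for call in calls]
            metab_mirnas += [
                (var, m.id)
                for m in annotate.mirnas_in_window(locus, features, cfg.flank_kb)
            ]
    trait_links = sorted(
        {(call.locus.split(":")[0], call.gene.id) for call in trait_calls}
        | set(trait_mirnas)
    )
    metab_links = sorted(
        {(var, call.gene.id) for var, call in metab_calls} | set(metab_mirnas)
    )
    pd.DataFrame(
        [{"locus": call.locus, "gene": call.gene.id,
          "evidence": "+".join(sorted(call.evidence)), "mode": "trait"}
         for call in trait_calls]
        + [{"locus": var, "gene": call.gene.id,
            "evidence": "+".join(sorted(call.evidence)), "mode": "metabolite"}
           for var, call in metab_calls]
    ).to_csv(out / "candidates.tsv", sep="\t", index=False)
    pd.DataFrame(trait_links + metab_links, columns=["variable", "feature"]).to_csv(
        out / "qtl_links.tsv", sep="\t", index=False
    )
    candidate_ids = {c.gene.id for c in trait_calls} | {
        call.gene.id for _, call in metab_calls
    }
    return {"trait_links": trait_links, "metab_links": metab_links,
            "candidate_ids": candidate_ids}


def stage_grn(state: dict, cfg: PipelineConfig, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    features = state["features"]
    tf_ids = {f.id for f in features if f.biotype == "TF"}
    mirna_ids = set(state["mirna_seqs"])
    candidates = set(state["candidate_ids"]) | tf_ids
    pwm = state["pwms"][0]
    motif_pairs, motif_rows = [], []
    for gene in sorted(candidates - tf_ids):
        seq = state["promoters"].get(gene)
        if seq is None:
            continue
        hits = grn.pwm_scan(seq, pwm, gene=gene, p_max=cfg.fimo_p)
        for h in hits:
            motif_rows.append({"motif": h.motif, "gene": gene, "position": h.position,
                               "strand": h.strand, "score_bits": h.score,
                               "p": h.p_value})
        for tf in sorted(tf_ids):
            motif_pairs += [(tf, gene)] if hits else []
    target_pairs, target_rows = [], []
    for mir in sorted(mirna_ids):
        for gene in sorted(candidates - tf_ids):
            tx = state["transcripts"].get(gene)
            if tx is None:
                continue
            hits = grn.mirna_target_score(
                state["mirna_seqs"][mir], tx, mirna_id=mir, gene=gene
            )
            if hits:
                target_pairs.append((mir, gene))
                for h in hits:
                    target_rows.append({"mirna": mir, "gene": gene,
                                        "position": h.position,
                                        "expectation": h.expectation,
                                        "alignment": h.alignment})
    g = grn.assemble_grn(
        candidates, tf_ids, mirna_ids, motif_pairs, target_pairs,
        state["ppi"], state["stage_expr"], r_min=cfg.r_min, ppi_min=cfg.ppi_min,
    )
    pd.DataFrame(motif_rows).to_csv(out / "motif_hits.tsv", sep="\t", index=False)
    pd.DataFrame(target_rows).to_csv(out / "target_hits.tsv", sep="\t", index=False)
    network.export_network(g, out / "grn.graphml", "GraphML")
    return {"grn_net": g}


def stage_network(state: dict, cfg: PipelineConfig, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    node_types = {t: "trait" for t in state["traits"]}
    node_types.update(state["categories"])
    for f in state["features"]:
        node_types.setdefault(f.id, f.biotype if f.biotype in ("TF", "miRNA") else "gene")
    net, report = network.assemble_mdgn(
        state["assoc_edges"], state["trait_links"], state["metab_links"],
        state["grn_net"], node_types,
    )
    cycles = network.enumerate_circuits(net, cfg.min_cycle, cfg.max_cycle)
    subs = network.classify_subnetworks(cycles, net)
    scores = network.mcc_scores(net)
    hub_nodes = network.hubs(net, cfg.mcc_top)
    sub_df = network.subnetwork_report(subs, net)
    sub_df.to_csv(out / "subnetworks.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(scores.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["node", "mcc"],
    ).assign(hub=lambda d: d["node"].isin(hub_nodes)).to_csv(
        out / "hubs.tsv", sep="\t", index=False
    )
    network.export_network(net, out / "mdgn.graphml", "GraphML")
    network.export_network(net, out / "mdgn.sif", "SIF")
    report["n_3d"] = sum(s.dimension == "3D" for s in subs)
    report["n_4d"] = sum(s.dimension == "4D" for s in subs)
    report["n_cycles"] = len(subs)
    report["hubs"] = hub_nodes
    if state.get("ledger"):
        report["recovery"] = evaluate_ledger_recovery(subs, state["ledger"])
    io.write_json(report, out / "network_report.json")
    return {"net": net, "subnetworks": subs, "report": report}


def evaluate_ledger_recovery(subs: list, ledger: dict) -> dict:
    """Fraction of planted tri-layer relations visible as 3D/4D sub-networks."""
    triples_3d = [set(s.cycle) for s in subs if s.dimension == "3D"]
    quads_4d = [set(s.cycle) for s in subs if s.dimension == "4D"]
    n3 = n4 = n4_total = 0
    relations = ledger.get("relations", [])
    for rel in relations:
        core = {rel["trait"], rel["compound"], rel["gene"]}
        if any(core <= cyc for cyc in triples_3d):
            n3 += 1
        if rel.get("mirna"):
            n4_total += 1
            quad = core | {rel["mirna"]}
            if any(quad <= cyc for cyc in quads_4d):
                n4 += 1
    total = len(relations)
    return {
        "relations": total,
        "recovered_3d": n3,
        "recovered_4d": n4,
        "recall_3d": n3 / total if total else float("nan"),
        "recall_4d": n4 / n4_total if n4_total else float("nan"),
    }


STAGES = ["simulate", "assoc", "qtl", "annotate", "grn", "network"]


def run_pipeline(cfg: PipelineConfig, out_dir) -> Path:
    """Execute the configured stages and write a manifest; returns the run dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    counts: dict = {}
    sim_dir = Path(cfg.input_dir) if cfg.input_dir else out_dir / "simulate"
    if "simulate" in cfg.stages:
        build_demo_cohort(cfg, sim_dir)
    state.update(_load_inputs(sim_dir))
    stage_fns = {
        "assoc": stage_assoc, "qtl": stage_qtl, "annotate": stage_annotate,
        "grn": stage_grn, "network": stage_network,
    }
    for name in STAGES[1:]:
        if name not in cfg.stages:
            continue
        try:
            result = stage_fns[name](state, cfg, out_dir / name)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        state.update(result)
        counts[name] = {
            k: (len(v) if hasattr(v, "__len__") else 1) for k, v in result.items()
        }
    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": cfg.digest(),
        "package_version": __version__,
        "seed": cfg.seed,
        "stage_record_counts": counts,
    }
    io.write_json(manifest, out_dir / "manifest.json")
    return out_dir
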