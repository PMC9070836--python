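"""End-to-end orchestration of the lignin-resistance analysis stages.

One declarative configuration drives all stages with the published
default parameters (blur sigma 2.0; DGE FDR 0.1 and log2FC 1; t-SNE
perplexity 20, 250 early-exaggeration iterations, size cutoff 20, seed
2; network quantile 0.997; 5-kb promoter window; W-box TTGACY;
extinction 17.2).  In synthetic mode every input is generated with known
ground truth.  Stages run in dependency order (dge -> clustering ->
networks; imaging, variants and chemistry are independent); every output
file is recorded in a manifest with a content hash, and rerunning with
the same configuration reproduces the hashes of the deterministic
stages (imaging, dge, variants, chemistry).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemistry, cluster, dge, imaging, network, variants
from .simulate.expression import ClusterPlan, ExprSimSpec, ModulePlan, simulate_counts
from .simulate.sections import SectionSpec, render_section
from .simulate.variants import VariantSimSpec, simulate_variants, write_variant_files

log = logging.getLogger("dodderlign")

STAGES = ("imaging", "dge", "cluster", "network", "variants", "chemistry")
HASH_STABLE_STAGES = ("imaging", "dge", "variants", "chemistry")


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the published values."""

    output_dir: str = "dodderlign_out"
    synthetic: bool = True
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # imaging
    sigma: float = 2.0
    n_sections: int = 3
    stain_fractions: tuple[float, ...] = (0.05, 0.3, 0.6)
    # dge
    fdr: float = 0.1
    log2fc: float = 1.0
    contrast: tuple[str, str] = ("H9553", "H9775")
    # clustering
    perplexity: float = 20.0
    lying: int = 250
    cutoff: int = 20
    tsne_seed: int = 2
    # network
    q: float = 0.997
    network_mode: str = "normal"
    # variants
    promoter_window: int = 5000
    motif: str = "TTGACY"
    # chemistry
    extinction: float = 17.2
    path_cm: float = 1.0

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["stain_fractions"] = list(self.stain_fractions)
        d["contrast"] = list(self.contrast)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["stain_fractions"] = tuple(d.get("stain_fractions", cls.stain_fractions))
        d["contrast"] = tuple(d.get("contrast", cls.contrast))
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _record(manifest: dict, stage: str, *paths: Path) -> None:
    root = Path(manifest["output_dir"])
    entry = manifest["outputs"].setdefault(stage, [])
    for p in paths:
        entry.append(
            {"path": str(p.relative_to(root)), "sha256": _sha256(p)}
        )


# ---------------------------------------------------------------------------
# stages (synthetic mode)


def _stage_imaging(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    d = out / "imaging"
    d.mkdir(parents=True, exist_ok=True)
    params = imaging.ImagingParams(sigma=cfg.sigma)
    rows = []
    for i, frac in enumerate(cfg.stain_fractions):
        spec = SectionSpec(cortex_stain_fraction=frac, seed=cfg.seed + i)
        section = render_section(spec)
        smoothed = imaging.gaussian_smooth(section.image, params)
        mask = imaging.lignin_mask(imaging.rgb_to_lab8(smoothed), params.histogram_bins)
        quant = imaging.quantify_cortex_lignin(mask, section.rois)
        truth_pct = (
            100.0
            * (section.lignin_mask & section.rois.cortex_mask).sum()
            / section.rois.cortex_mask.sum()
        )
        img_path = d / f"section{i}.png"
        overlay_path = d / f"section{i}_overlay.png"
        imaging.write_image(section.image, str(img_path))
        imaging.write_overlay(section.image, mask, str(overlay_path))
        rows.append(
            {
                "section": f"section{i}",
                "stain_fraction": frac,
                "total_lignin_px": quant.total_lignin_px,
                "xylem_lignin_px": quant.xylem_lignin_px,
                "cortex_lignin_px": quant.cortex_lignin_px,
                "cortex_area_px": quant.cortex_area_px,
                "cortex_lignin_pct": round(quant.cortex_lignin_pct, 4),
                "truth_cortex_lignin_pct": round(truth_pct, 4),
            }
        )
        log.info(
            "imaging: section%d cortex lignin %.2f%% (truth %.2f%%)",
            i, quant.cortex_lignin_pct, truth_pct,
        )
    tsv = d / "lignin_quant.tsv"
    pd.DataFrame(rows).to_csv(tsv, sep="\t", index=False)
    _record(manifest, "imaging", tsv, *sorted(d.glob("*.png")))


def _demo_expression_spec(cfg: PipelineConfig) -> ExprSimSpec:
    """The synthetic demonstration design: four cultivars, two conditions,
    three planted response clusters and two infestation-specific modules."""
    resistant = [("H9492", "infested"), ("H9553", "infested")]
    susceptible = [("H1706", "infested"), ("H9775", "infested")]
    everyone = resistant + susceptible
    return ExprSimSpec(
        n_genes=600,
        strata=[
            (g, c, 8)
            for g in ("H1706", "H9775", "H9492", "H9553")
            for c in ("uninfested", "infested")
        ],
        cluster_plan=[
            ClusterPlan(60, {s: 4.0 for s in resistant}),
            ClusterPlan(60, {s: 4.0 for s in everyone}),
            ClusterPlan(60, {s: -4.0 for s in susceptible}),
        ],
        module_plan=[
            ModulePlan(
                25, 0.7, hub=True, strata=resistant,
                shifts={s: 3.0 for s in resistant},
            ),
            ModulePlan(
                25, 0.7, strata=everyone,
                shifts={s: -3.0 for s in everyone},
            ),
        ],
        background_pattern_sd=0.5,
        seed=cfg.seed + 100,
    )


def _stage_dge(cfg: PipelineConfig, out: Path, manifest: dict, state: dict) -> None:
    d = out / "dge"
    d.mkdir(parents=True, exist_ok=True)
    cm, truth = simulate_counts(_demo_expression_spec(cfg))
    state["counts"] = cm
    state["expr_truth"] = truth
    thresholds = dge.DGEThresholds(fdr_max=cfg.fdr, log2fc_min=cfg.log2fc)
    inter = dge.interaction_dge(cm, thresholds, contrast=cfg.contrast)
    anova = dge.twofactor_anova_dge(cm, thresholds)
    state["anova"] = anova
    counts_tsv = d / "counts.tsv"
    cm.counts.to_csv(counts_tsv, sep="\t")
    meta_tsv = d / "samples.tsv"
    cm.samples.to_csv(meta_tsv, sep="\t")
    inter_tsv = d / "interaction_dge.tsv"
    inter.to_csv(inter_tsv, sep="\t")
    anova_tsv = d / "anova_dge.tsv"
    anova.to_csv(anova_tsv, sep="\t")
    log.info(
        "dge: %d interaction DEGs, %d ANOVA DEGs (FDR<%g, |log2FC|>%g)",
        int(inter["passes"].sum()), int(anova["passes"].sum()), cfg.fdr, cfg.log2fc,
    )
    _record(manifest, "dge", counts_tsv, meta_tsv, inter_tsv, anova_tsv)


def _stage_cluster(cfg: PipelineConfig, out: Path, manifest: dict, state: dict) -> None:
    d = out / "cluster"
    d.mkdir(parents=True, exist_ok=True)
    cm: dge.CountMatrix = state["counts"]
    degs = state["anova"].index[state["anova"]["passes"]]
    z, _ = cluster.zscore_rows(dge.log2_cpm(cm).loc[degs])
    params = cluster.TsneParams(
        perplexity=cfg.perplexity,
        early_exaggeration_iters=cfg.lying,
        seed=cfg.tsne_seed,
    )
    assignment, coords = cluster.cluster_genes(z, params, cutoff=cfg.cutoff)
    state["assignment"] = assignment
    emb = pd.DataFrame(
        {"x": coords[:, 0], "y": coords[:, 1], "cluster": assignment.labels},
        index=z.index,
    )
    emb_tsv = d / "embedding.tsv"
    emb.to_csv(emb_tsv, sep="\t", index_label="gene")
    summary_tsv = d / "cluster_profiles.tsv"
    cluster.cluster_summary(assignment, z).to_csv(summary_tsv, sep="\t")
    genes_tsv = d / "clustered_genes.tsv"
    clustered = assignment.labels[assignment.labels != cluster.NOISE_LABEL]
    clustered.rename("cluster").to_csv(genes_tsv, sep="\t", index_label="gene")
    n_noise = int((assignment.labels == cluster.NOISE_LABEL).sum())
    log.info(
        "cluster: %d genes in %d clusters, %d in the noise group",
        len(clustered), assignment.n_clusters, n_noise,
    )
    _record(manifest, "cluster", emb_tsv, summary_tsv, genes_tsv)


def _stage_network(cfg: PipelineConfig, out: Path, manifest: dict, state: dict) -> None:
    d = out / "network"
    d.mkdir(parents=True, exist_ok=True)
    cm: dge.CountMatrix = state["counts"]
    assignment: cluster.ClusterAssignment = state["assignment"]
    gene_list = sorted(
        assignment.labels.index[assignment.labels != cluster.NOISE_LABEL]
    )
    gcns = network.build_stratified_gcns(
        cm, gene_list, q=cfg.q, mode=cfg.network_mode
    )
    paths = []
    hub_rows = []
    for (genotype, condition), res in sorted(gcns.items()):
        tag = f"{genotype}_{condition}"
        edge_tsv = d / f"gcn_{tag}_edges.tsv"
        graphml = d / f"gcn_{tag}.graphml"
        network.write_graph(res["graph"], str(edge_tsv), str(graphml))
        module_tsv = d / f"gcn_{tag}_modules.tsv"
        pd.DataFrame(
            {"module": res["modules"], "degree": res["hubs"].degrees}
        ).to_csv(module_tsv, sep="\t", index_label="gene")
        top = res["hubs"].degrees
        hub_rows.append(
            {
                "genotype": genotype,
                "condition": condition,
                "top_gene": top.index[0] if len(top) else "",
                "top_degree": int(top.iloc[0]) if len(top) else 0,
                "n_edges": res["graph"].number_of_edges(),
                "n_isolated": len(res["hubs"].isolated),
                "modularity": round(res["modularity"], 4),
            }
        )
        paths += [edge_tsv, graphml, module_tsv]
    hubs_tsv = d / "hub_summary.tsv"
    pd.DataFrame(hub_rows).to_csv(hubs_tsv, sep="\t", index=False)
    log.info("network: %d strata analyzed over %d genes", len(gcns), len(gene_list))
    _record(manifest, "network", hubs_tsv, *paths)


def _stage_variants(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    d = out / "variants"
    d.mkdir(parents=True, exist_ok=True)
    spec = VariantSimSpec(
        promoter_window=cfg.promoter_window, seed=cfg.seed + 200
    )
    sim = simulate_variants(spec)
    vcf, fasta, gff = d / "genotypes.vcf", d / "reference.fa", d / "genes.gff3"
    write_variant_files(sim, str(vcf), str(fasta), str(gff))

    table = variants.read_vcf(str(vcf))
    filtered, skipped = variants.resistance_specific_snps(table)
    genes = variants.read_gff3_genes(str(gff))
    ref = variants.read_fasta(str(fasta))
    chrom_lengths = {c: len(s) for c, s in ref.items()}
    promoters = variants.promoter_windows(genes, cfg.promoter_window, chrom_lengths)
    hits = variants.scan_promoters(ref, promoters, pattern=cfg.motif)
    overlap = variants.snp_motif_overlap(filtered, hits, promoters, pattern=cfg.motif)

    filt_tsv = d / "resistance_specific_snps.tsv"
    filtered.to_csv(filt_tsv, sep="\t", index=False)
    bed = d / "promoters.bed"
    variants.write_bed(promoters, str(bed))
    hits_tsv = d / "wbox_hits.tsv"
    hits.to_csv(hits_tsv, sep="\t", index=False)
    overlap_tsv = d / "snp_motif_overlap.tsv"
    overlap.to_csv(overlap_tsv, sep="\t", index=False)
    log.info(
        "variants: %d/%d resistance-specific SNPs (%d skipped), %d W-box hits "
        "in promoters, %d SNP-in-motif overlaps",
        len(filtered), len(table), skipped, len(hits), len(overlap),
    )
    _record(
        manifest, "variants", vcf, fasta, gff, filt_tsv, bed, hits_tsv, overlap_tsv
    )


def _stage_chemistry(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    d = out / "chemistry"
    d.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 300)
    # absorbance table: resistant cultivars show elevated lignin on infestation
    rows = []
    for genotype, base in (("H9553", 0.30), ("H9492", 0.27), ("H9775", 0.18)):
        for condition, bump in (("uninfested", 0.0), ("infested", 0.10 if genotype != "H9775" else 0.01)):
            for rep in range(1, 4):
                rec = chemistry.AbsorbanceRecord(
                    absorbance=float(base + bump + rng.normal(0, 0.01)),
                    biomass_mg=2.0,
                    volume_mL=1.0,
                    path_cm=cfg.path_cm,
                    extinction=cfg.extinction,
                )
                rows.append(
                    {
                        "genotype": genotype,
                        "condition": condition,
                        "replicate": rep,
                        "absorbance": round(rec.absorbance, 4),
                        "absl_pct": round(chemistry.absl_percent(rec), 4),
                    }
                )
    absl_tsv = d / "absl.tsv"
    pd.DataFrame(rows).to_csv(absl_tsv, sep="\t", index=False)

    compounds = [
        ("phenol", "H", 4.0), ("4-vinylphenol", "H", 6.0),
        ("guaiacol", "G", 14.0), ("4-vinylguaiacol", "G", 18.0),
        ("vanillin", "G", 6.0), ("syringol", "S", 9.0),
        ("4-allylsyringol", "S", 5.0), ("p-coumaric acid", "p-coumarate", 3.0),
        ("unassigned", "other", 2.0),
    ]
    pyro = pd.DataFrame(
        [
            {
                "compound": name,
                "class": cls,
                "area": float(max(area + rng.normal(0, area * 0.1), 0.01)),
            }
            for name, cls, area in compounds
        ]
    )
    fracs, class_sums = chemistry.normalize_pyrogram(pyro)
    pyro_tsv = d / "pyrogram_fractions.tsv"
    fracs.to_csv(pyro_tsv, sep="\t", index=False)
    class_tsv = d / "monolignol_classes.tsv"
    class_sums.rename("fraction").to_csv(class_tsv, sep="\t", index_label="class")
    log.info(
        "chemistry: mean %%ABSL %.3f; H/G/S fractions %.3f/%.3f/%.3f",
        pd.DataFrame(rows)["absl_pct"].mean(),
        class_sums["H"], class_sums["G"], class_sums["S"],
    )
    _record(manifest, "chemistry", absl_tsv, pyro_tsv, class_tsv)


# ---------------------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; returns the manifest."""
    unknown = set(cfg.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    if not cfg.synthetic:
        raise NotImplementedError(
            "only synthetic mode is orchestrated end-to-end; apply the stage "
            "functions directly to external data"
        )
    needs = {"cluster": "dge", "network": "cluster"}
    for stage, dep in needs.items():
        if stage in cfg.stages and dep not in cfg.stages:
            raise ValueError(f"stage {stage!r} requires stage {dep!r}")

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {
        "output_dir": str(out),
        "config": json.loads(json.dumps(asdict(cfg), default=list)),
        "hash_stable_stages": [s for s in cfg.stages if s in HASH_STABLE_STAGES],
        "outputs": {},
    }
    state: dict = {}
    try:
        for stage in STAGES:
            if stage not in cfg.stages:
                continue
            log.info("running stage %s", stage)
            if stage == "imaging":
                _stage_imaging(cfg, out, manifest)
            elif stage == "dge":
                _stage_dge(cfg, out, manifest, state)
            elif stage == "cluster":
                _stage_cluster(cfg, out, manifest, state)
            elif stage == "network":
                _stage_network(cfg, out, manifest, state)
            elif stage == "variants":
                _stage_variants(cfg, out, manifest)
            elif stage == "chemistry":
                _stage_chemistry(cfg, out, manifest)
    finally:
        log.removeHandler(handler)
        handler.close()
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def write_report(manifest: dict, path: str | Path | None = None) -> str:
    """Human-readable run summary built only from files in the manifest."""
    root = Path(manifest["output_dir"])
    files = {
        Path(entry["path"]).name: root / entry["path"]
        for entries in manifest["outputs"].values()
        for entry in entries
    }
    lines = ["dodderlign run report", "=" * 21, ""]

    if "lignin_quant.tsv" in files:
        t = pd.read_csv(files["lignin_quant.tsv"], sep="\t")
        lines.append("Cortex lignin per section:")
        for _, r in t.iterrows():
            lines.append(
                f"  {r['section']}: {r['cortex_lignin_pct']:.2f}% of cortex "
                f"(truth {r['truth_cortex_lignin_pct']:.2f}%)"
            )
        lines.append("")
    if "interaction_dge.tsv" in files:
        inter = pd.read_csv(files["interaction_dge.tsv"], sep="\t", index_col=0)
        anova = pd.read_csv(files["anova_dge.tsv"], sep="\t", index_col=0)
        lines.append(
            f"DEGs: {int(inter['passes'].sum())} interaction, "
            f"{int(anova['passes'].sum())} ANOVA"
        )
        lines.append("")
    if "embedding.tsv" in files:
        emb = pd.read_csv(files["embedding.tsv"], sep="\t", index_col=0)
        sizes = emb["cluster"].value_counts().sort_index()
        clustered = sizes[sizes.index != -1]
        lines.append(
            f"Clusters: {len(clustered)} groups "
            f"({int(clustered.sum())} genes), noise {int(sizes.get(-1, 0))}"
        )
        for label, size in clustered.items():
            lines.append(f"  cluster {label}: {size} genes")
        lines.append("")
    if "hub_summary.tsv" in files:
        hubs = pd.read_csv(files["hub_summary.tsv"], sep="\t")
        lines.append("Co-expression networks per stratum:")
        for _, r in hubs.iterrows():
            lines.append(
                f"  {r['genotype']} {r['condition']}: top hub {r['top_gene']} "
                f"(degree {r['top_degree']}), {r['n_edges']} edges, "
                f"{r['n_isolated']} isolated"
            )
        lines.append("")
    if "resistance_specific_snps.tsv" in files:
        snps = pd.read_csv(files["resistance_specific_snps.tsv"], sep="\t")
        lines.append(f"Resistance-specific SNPs: {len(snps)}")
        if "snp_motif_overlap.tsv" in files:
            ov = pd.read_csv(files["snp_motif_overlap.tsv"], sep="\t")
            lines.append(f"SNPs inside promoter W-boxes: {len(ov)}")
            for _, r in ov.iterrows():
                lines.append(
                    f"  {r['chrom']}:{r['pos']} {r['ref']}>{r['alt']} in "
                    f"{r['gene_id']} promoter W-box at {r['motif_start']} "
                    f"({'breaks' if r['breaks_motif'] else 'retains'} the motif)"
                )
        lines.append("")
    if "absl.tsv" in files:
        absl = pd.read_csv(files["absl.tsv"], sep="\t")
        by = absl.groupby(["genotype", "condition"])["absl_pct"].mean()
        lines.append("Mean %ABSL by genotype and condition:")
        for (genotype, condition), v in by.items():
            lines.append(f"  {genotype} {condition}: {v:.2f}%")
        if "monolignol_classes.tsv" in files:
            cls = pd.read_csv(files["monolignol_classes.tsv"], sep="\t", index_col=0)
            lines.append(
                "Monolignol class fractions: "
                + ", ".join(f"{k}={v:.3f}" for k, v in cls["fraction"].items())
            )
        lines.append("")

    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text
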