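"""End-to-end orchestration: simulate → assoc → loci → hotspots → cna →
tfbs → report, driven by a single YAML config with one global seed.

The global seed is fanned out to per-stage sub-seeds through
``numpy.random.SeedSequence(seed).generate_state`` so each stage is
individually reproducible; the run manifest records the seed, the
sub-seeds, and a checksum of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cna as cna_mod
from . import hotspots as hotspots_mod
from . import intervals as intervals_mod
from . import io_formats as io
from . import signature_assoc as assoc_mod
from . import synthetic_data as synth
from . import tfbs as tfbs_mod

logger = logging.getLogger(__name__)

STAGES = ("simulate", "assoc", "loci", "hotspots", "cna", "tfbs", "report")


@dataclass
class RunConfig:
    """Validated run configuration (see the annotated example YAML)."""

    outdir: Path
    seed: int = 0
    stages: dict[str, dict[str, Any] | None] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(
            outdir=Path(raw["outdir"]),
            seed=int(raw.get("seed", 0)),
            stages={k: (v or {}) for k, v in (raw.get("stages") or {}).items()},
            inputs={k: str(v) for k, v in (raw.get("inputs") or {}).items()},
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages in config: {sorted(unknown)}")
        for key, path in self.inputs.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"input {key!r}: {path} not found")
        # stages needing inputs must get them from simulate or from `inputs`
        if "simulate" not in self.stages:
            needs = {
                "assoc": ["expression", "activities"],
                "hotspots": ["snvs"],
                "cna": ["seg"],
                "loci": ["loci"],
            }
            for stage, keys in needs.items():
                if stage in self.stages:
                    for key in keys:
                        if key not in self.inputs:
                            raise ValueError(
                                f"stage {stage!r} enabled without the "
                                f"simulate stage, but input {key!r} missing"
                            )

    def enabled(self, stage: str) -> bool:
        return stage in self.stages

    def stage_opts(self, stage: str) -> dict[str, Any]:
        return dict(self.stages.get(stage) or {})


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage sub-seeds derived from the global seed."""
    state = np.random.SeedSequence(seed).generate_state(len(STAGES))
    return {stage: int(s % (2 ** 31)) for stage, s in zip(STAGES, state)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Demo scenario defaults
# ---------------------------------------------------------------------------

#: Signatures carried by the demo scenario: the recurrently active
#: ovarian-tumor signatures with known etiologies.
DEMO_SIGNATURES = [
    "SBS1", "SBS2", "SBS3", "SBS5", "SBS13", "SBS18", "SBS26", "SBS35",
    "SBS40", "DBS2", "DBS4", "DBS5", "DBS7", "DBS11", "ID1", "ID2",
    "ID4", "ID5", "ID6", "ID8",
]

DEMO_DEFAULTS: dict[str, Any] = {
    "n_chroms": 2,
    "chrom_size_bp": 500_000,
    "n_expr_samples": 89,     # RNA-seq cohort size
    "n_snv_samples": 40,
    "n_cna_samples": 60,
    "n_genes": 300,
    "n_planted_assoc": 10,
    "assoc_slope": 1.0,
    "assoc_noise_sd": 0.3,
    "annotation_classes": ["coding", "enhancer", "promoter", "H3K27ac"],
    "n_per_class": 60,
    "mean_element_len": 500,
    "background_rate": 2e-5,  # mutations / bp / sample
    "n_hotspots": 2,
    "hotspot_multiplier": 25.0,
    "n_tfs": 5,
    "motif_len": 8,
    "n_sites": 4,
    "n_loci": 4,
}


def _simulate(cfg: RunConfig, seed: int, outdir: Path) -> dict[str, Path]:
    """Generate every pipeline input and write it under outdir/inputs."""
    opts = {**DEMO_DEFAULTS, **cfg.stage_opts("simulate")}
    rng = np.random.default_rng(seed)
    indir = outdir / "inputs"
    indir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genome = synth.gen_genome(opts["n_chroms"], opts["chrom_size_bp"],
                              seed=seed)
    genome_df = pd.DataFrame({
        "chrom": genome.chrom_names,
        "size": [genome.chrom_sizes[c] for c in genome.chrom_names],
    })
    paths["genome"] = indir / "genome.tsv"
    genome_df.to_csv(paths["genome"], sep="\t", index=False)

    # expression + activities with planted gene-signature couplings
    genes = [f"G{i:04d}" for i in range(opts["n_genes"])]
    planted_genes = list(rng.choice(genes, size=opts["n_planted_assoc"],
                                    replace=False))
    planted_sigs = list(rng.choice(DEMO_SIGNATURES,
                                   size=opts["n_planted_assoc"],
                                   replace=False))
    planted = [
        synth.PlantedAssociation(g, s, opts["assoc_slope"],
                                 opts["assoc_noise_sd"])
        for g, s in zip(planted_genes, planted_sigs)
    ]
    expr, act = synth.gen_signature_expression(
        opts["n_expr_samples"], genes, DEMO_SIGNATURES, planted,
        seed=int(rng.integers(2 ** 31)))
    paths["expression"] = indir / "expression.tsv"
    paths["activities"] = indir / "activities.tsv"
    io.write_matrix(expr, paths["expression"])
    io.write_matrix(act, paths["activities"])

    # three candidate gene lists; the last one contains the planted genes
    pool = [g for g in genes if g not in planted_genes]
    lists = {
        "multixcan": list(rng.choice(pool, size=25, replace=False)),
        "magma": list(rng.choice(pool, size=20, replace=False)),
        "chrommagma": planted_genes
        + list(rng.choice(pool, size=30, replace=False)),
    }
    for name, gl in lists.items():
        p = indir / f"genes_{name}.txt"
        p.write_text("\n".join(gl) + "\n")
        paths[f"genes_{name}"] = p

    # annotation tracks + SNVs with planted hotspots
    tracks = synth.gen_annotation_tracks(
        genome, opts["annotation_classes"], opts["n_per_class"],
        opts["mean_element_len"], seed=int(rng.integers(2 ** 31)))
    hotspot_pool = tracks[opts["annotation_classes"][1]]
    chosen = rng.choice(len(hotspot_pool), size=opts["n_hotspots"],
                        replace=False)
    hotspots = [synth.PlantedHotspot(hotspot_pool[i],
                                     opts["hotspot_multiplier"])
                for i in chosen]
    for cls, ivs in tracks.items():
        p = indir / f"track_{cls}.bed"
        io.write_bed(ivs, p)
        paths[f"track_{cls}"] = p
    snvs = synth.gen_snvs(genome, opts["n_snv_samples"],
                          opts["background_rate"], hotspots,
                          seed=int(rng.integers(2 ** 31)))
    paths["snvs"] = indir / "snvs.tsv"
    io.write_variants_tsv(snvs, paths["snvs"])
    truth_hs = [h.interval for h in hotspots]
    paths["hotspot_truth"] = indir / "hotspot_truth.bed"
    io.write_bed(truth_hs, paths["hotspot_truth"])

    # risk loci
    loci_rows = []
    for i in range(opts["n_loci"]):
        chrom = genome.chrom_names[i % len(genome.chrom_names)]
        size = genome.chrom_sizes[chrom]
        pos = int(rng.integers(size // 10, size - size // 10)) + 1
        loci_rows.append({"locus_id": f"L{i + 1}", "chrom": chrom,
                          "pos": pos, "histotype": "HGSOC"})
    loci_df = pd.DataFrame(loci_rows)
    paths["loci"] = indir / "risk_loci.tsv"
    loci_df.to_csv(paths["loci"], sep="\t", index=False)

    # CNA segments with one planted amplification and one deletion
    c0 = genome.chrom_names[0]
    size0 = genome.chrom_sizes[c0]
    amp = synth.RecurrentCNASpec(
        io.GenomicInterval(c0, size0 // 4, size0 // 4 + 50_000), "amp", 0.7)
    dele = synth.RecurrentCNASpec(
        io.GenomicInterval(c0, 3 * size0 // 5, 3 * size0 // 5 + 40_000),
        "del", 0.5)
    segments = synth.gen_cna_segments(genome, opts["n_cna_samples"],
                                      [amp, dele],
                                      seed=int(rng.integers(2 ** 31)))
    paths["seg"] = indir / "segments.seg"
    io.write_seg(segments, paths["seg"])

    # chromatin-state tracks for two cell types
    state_names = sorted(cna_mod.ALLOWED_STATES)
    for cell_type in ("HGSOC", "FT"):
        st = synth.gen_annotation_tracks(genome, state_names, 40, 800,
                                         seed=int(rng.integers(2 ** 31)))
        for state, ivs in st.items():
            p = indir / f"states_{cell_type}_{state}.bed"
            io.write_bed(ivs, p)
            paths[f"states_{cell_type}_{state}"] = p

    # PWMs, sequence, and germline credible variants with planted effects
    scenario = synth.gen_pwms_and_variants(
        opts["n_tfs"], opts["motif_len"], genome, opts["n_sites"],
        seed=int(rng.integers(2 ** 31)))
    paths["pwms"] = indir / "motifs.jaspar"
    io.write_jaspar_counts(scenario.counts_by_tf, paths["pwms"])
    paths["fasta"] = indir / "sequence.fa"
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{scenario.chrom}\n")
        for i in range(0, len(scenario.sequence), 80):
            fh.write(scenario.sequence[i:i + 80] + "\n")
    paths["germline_variants"] = indir / "credible_variants.tsv"
    gv = scenario.variants[["chrom", "pos", "ref", "alt"]]
    gv.to_csv(paths["germline_variants"], sep="\t", index=False)
    paths["variant_truth"] = indir / "variant_truth.tsv"
    scenario.variants.to_csv(paths["variant_truth"], sep="\t", index=False)

    # provenance block
    prov = {
        "seed": seed,
        "options": {k: (list(v) if isinstance(v, (list, tuple)) else v)
                    for k, v in opts.items()},
        "planted_associations": [
            {"gene": str(p.gene), "signature": str(p.signature),
             "slope": p.slope, "noise_sd": p.noise_sd} for p in planted
        ],
        "planted_hotspots": [
            {"chrom": h.interval.chrom, "start": h.interval.start,
             "end": h.interval.end,
             "rate_multiplier": h.rate_multiplier} for h in hotspots
        ],
    }
    with open(indir / "scenario.yaml", "w") as fh:
        yaml.safe_dump(prov, fh, sort_keys=True)
    paths["scenario"] = indir / "scenario.yaml"
    return paths


def _resolve_inputs(cfg: RunConfig, sim_paths: dict[str, Path]) -> dict:
    paths = dict(sim_paths)
    for key, p in cfg.inputs.items():
        paths[key] = Path(p)
    return paths


def _run_assoc(cfg, seed, outdir, paths):
    opts = cfg.stage_opts("assoc")
    alpha = float(opts.get("alpha", 0.05))
    n_perm = int(opts.get("n_permutations", 1000))
    expr = io.read_matrix(paths["expression"])
    act = io.read_matrix(paths["activities"])
    d = outdir / "assoc"
    d.mkdir(parents=True, exist_ok=True)
    gene_lists = {
        key.removeprefix("genes_"): [
            g for g in Path(paths[key]).read_text().split() if g
        ]
        for key in sorted(paths) if key.startswith("genes_")
    }
    all_results, all_counts, perm_rows = [], [], []
    for i, (name, gl) in enumerate(sorted(gene_lists.items())):
        results, counts = assoc_mod.scan(expr, act, gl, alpha=alpha,
                                         list_name=name)
        results.insert(0, "gene_list_name", name)
        all_results.append(results)
        counts["etiology"] = counts["signature"].map(assoc_mod.map_etiology)
        all_counts.append(counts)
        perm = assoc_mod.permutation_test(expr, act, gl, n_iter=n_perm,
                                          alpha=alpha, seed=seed + i,
                                          list_name=name)
        perm_rows.append({
            "gene_list_name": name, "n_iter": perm.n_iter,
            "observed": perm.observed, "n_exceed": perm.n_exceed,
            "p_value": perm.p_value,
            "null_mean": float(np.mean(perm.null_counts)),
        })
    pd.concat(all_results).to_csv(d / "associations.tsv", sep="\t",
                                  index=False)
    pd.concat(all_counts).to_csv(d / "signature_counts.tsv", sep="\t",
                                 index=False)
    pd.DataFrame(perm_rows).to_csv(d / "permutation.tsv", sep="\t",
                                   index=False)
    return d


def _read_genome_sizes(paths) -> dict[str, int]:
    df = pd.read_csv(paths["genome"], sep="\t")
    return dict(zip(df["chrom"], df["size"]))


def _run_loci(cfg, outdir, paths) -> list[intervals_mod.RiskLocus]:
    sizes = _read_genome_sizes(paths)
    df = pd.read_csv(paths["loci"], sep="\t")
    loci = [
        intervals_mod.build_risk_locus(str(r.locus_id), str(r.chrom),
                                       int(r.pos), str(r.histotype), sizes)
        for r in df.itertuples(index=False)
    ]
    d = outdir / "loci"
    d.mkdir(parents=True, exist_ok=True)
    io.write_bed([lc.region for lc in loci], d / "risk_loci.bed")
    return loci


def _run_hotspots(cfg, outdir, paths, loci):
    opts = cfg.stage_opts("hotspots")
    fdr = float(opts.get("fdr", 0.05))
    snvs = io.read_variants(paths["snvs"], format="tsv")
    d = outdir / "hotspots"
    d.mkdir(parents=True, exist_ok=True)
    tally = hotspots_mod.tally_recurrence(snvs)
    pd.DataFrame(
        sorted(tally.histogram.items()),
        columns=["samples_sharing_position", "n_positions"],
    ).to_csv(d / "recurrence_tally.tsv", sep="\t", index=False)
    (d / "recurrence_totals.tsv").write_text(
        "total_snvs\tunique_positions\n"
        f"{tally.total_snvs}\t{tally.unique_positions}\n"
    )
    all_results = []
    rows = []
    for key in sorted(paths):
        if not key.startswith("track_"):
            continue
        cls = key.removeprefix("track_")
        track = io.read_bed(paths[key])
        results = hotspots_mod.scan_track(track, snvs, fdr=fdr,
                                          annotation=cls)
        all_results.extend(results)
        for r in results:
            rows.append({
                "annotation": r.annotation, "chrom": r.element.chrom,
                "start": r.element.start, "end": r.element.end,
                "observed": r.observed, "expected": r.expected,
                "p_value": r.p_value, "q_value": r.q_value,
                "significant": r.significant,
            })
    pd.DataFrame(rows).to_csv(d / "elements.tsv", sep="\t", index=False)
    frames = [hotspots_mod.enrich(all_results, "genome"),
              hotspots_mod.enrich(all_results, "chromosome")]
    if loci:
        frames.append(hotspots_mod.enrich(all_results, "loci", loci=loci))
    pd.concat(frames).to_csv(d / "enrichment.tsv", sep="\t", index=False)
    sig = [r.element for r in all_results if r.significant]
    io.write_bed(sig, d / "significant_elements.bed")
    return d, all_results


def _run_cna(cfg, seed, outdir, paths, loci):
    opts = cfg.stage_opts("cna")
    segments = io.read_seg(paths["seg"])
    regions = cna_mod.call_recurrent(
        segments,
        t_amp=float(opts.get("t_amp", 0.3)),
        t_del=float(opts.get("t_del", -0.3)),
        bin_bp=int(opts.get("bin_bp", 10_000)),
        n_perm=int(opts.get("n_perm", 500)),
        fdr=float(opts.get("fdr", 0.25)),
        seed=seed,
    )
    d = outdir / "cna"
    d.mkdir(parents=True, exist_ok=True)
    io.write_bed(
        [io.GenomicInterval(r.region.chrom, r.region.start, r.region.end,
                            name=r.direction, value=r.frequency)
         for r in regions],
        d / "recurrent_regions.bed",
    )
    state_tracks: dict[str, dict[str, list]] = {}
    for key in sorted(paths):
        if key.startswith("states_"):
            _, cell_type, state = key.split("_", 2)
            state_tracks.setdefault(cell_type, {})[state] = \
                io.read_bed(paths[key])
    if state_tracks:
        cov = cna_mod.annotate_cna(regions, state_tracks)
        cov.to_csv(d / "state_coverage.tsv", sep="\t", index=False)
    if loci:
        table, summary = cna_mod.intersect_with_loci(regions, loci)
        table.to_csv(d / "loci_cna.tsv", sep="\t", index=False)
        with open(d / "loci_cna_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return d


def _read_fasta(path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def _run_tfbs(cfg, outdir, paths, hotspot_results):
    opts = cfg.stage_opts("tfbs")
    strong = float(opts.get("strong_site_threshold", 0.85))
    delta = float(opts.get("delta_threshold", 0.10))
    min_mut = int(opts.get("min_mutations", 3))
    pwms = io.read_jaspar(paths["pwms"])
    sequences = _read_fasta(paths["fasta"])
    variants = io.read_variants(paths["germline_variants"], format="tsv")
    snvs = io.read_variants(paths["snvs"], format="tsv") \
        if "snvs" in paths else []
    d = outdir / "tfbs"
    d.mkdir(parents=True, exist_ok=True)
    # regulatory elements: frequently mutated elements when available,
    # otherwise the whole sequenced chromosome
    elements = [r.element for r in (hotspot_results or [])
                if r.significant
                and io.normalize_chrom(r.element.chrom) in
                {io.normalize_chrom(c) for c in sequences}
                and r.element.end <= len(
                    sequences[r.element.chrom]
                    if r.element.chrom in sequences else
                    sequences[io.normalize_chrom(r.element.chrom)])]
    germ_counts, calls = tfbs_mod.germline_disrupted_tfs(
        variants, pwms, sequences, elements=None,
        strong_site_threshold=strong, delta_threshold=delta)
    germ_counts.to_csv(d / "germline_disrupted_tfs.tsv", sep="\t",
                       index=False)
    pd.DataFrame([
        {"chrom": c.variant.chrom, "pos": c.variant.pos,
         "ref": c.variant.ref, "alt": c.variant.alt, "tf": c.tf_name,
         "ref_score": round(c.ref_score, 6),
         "alt_score": round(c.alt_score, 6),
         "delta": round(c.delta, 6), "disrupting": c.disrupting}
        for c in calls
    ]).to_csv(d / "disruption_calls.tsv", sep="\t", index=False)
    burden_elements = elements
    if not burden_elements:
        chrom = next(iter(sequences))
        burden_elements = [io.GenomicInterval(chrom, 0,
                                              len(sequences[chrom]))]
    burden = tfbs_mod.somatic_tf_burden(burden_elements, snvs, pwms,
                                        sequences, site_threshold=strong,
                                        min_mutations=min_mut)
    pd.DataFrame([
        {"tf_name": b.tf_name, "chrom": b.element.chrom,
         "start": b.element.start, "end": b.element.end,
         "n_mutations": b.n_mutations, "passes_filter": b.passes_filter}
        for b in burden
    ]).to_csv(d / "somatic_tf_burden.tsv", sep="\t", index=False)
    germ_tfs = list(germ_counts["tf_name"])
    som_tfs = sorted({b.tf_name for b in burden if b.passes_filter})
    common = tfbs_mod.intersect_tf_lists(germ_tfs, som_tfs)
    (d / "common_tfs.txt").write_text(
        ("\n".join(common) + "\n") if common else "")
    return d


def _write_report(outdir: Path) -> Path:
    """Collate stage outputs into one human-readable summary."""
    lines = ["germsoma run summary", "=" * 22, ""]
    sections = [
        ("Signature associations (per-signature significant gene counts)",
         outdir / "assoc" / "signature_counts.tsv"),
        ("Permutation test", outdir / "assoc" / "permutation.tsv"),
        ("Hotspot enrichment (annotation x stratum)",
         outdir / "hotspots" / "enrichment.tsv"),
        ("CNA state coverage", outdir / "cna" / "state_coverage.tsv"),
        ("Germline-disrupted TFs",
         outdir / "tfbs" / "germline_disrupted_tfs.tsv"),
    ]
    for title, path in sections:
        if not path.exists():
            continue
        lines.append(title)
        lines.append("-" * len(title))
        df = pd.read_csv(path, sep="\t")
        lines.append(df.to_string(index=False, max_rows=40))
        lines.append("")
    common = outdir / "tfbs" / "common_tfs.txt"
    if common.exists():
        names = [x for x in common.read_text().split() if x]
        lines.append(f"TFs disrupted by both germline and somatic "
                     f"mutations: {', '.join(names) if names else '(none)'}")
        lines.append("")
    report = outdir / "summary.txt"
    report.write_text("\n".join(lines))
    return report


def run(config: RunConfig) -> dict:
    """Execute all enabled stages in order and write a run manifest."""
    config.validate()
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    sim_paths: dict[str, Path] = {}
    if config.enabled("simulate"):
        logger.info("stage simulate")
        sim_paths = _simulate(config, seeds["simulate"], outdir)
    paths = _resolve_inputs(config, sim_paths)
    loci = None
    hotspot_results = None
    if config.enabled("loci"):
        logger.info("stage loci")
        loci = _run_loci(config, outdir, paths)
    if config.enabled("assoc"):
        logger.info("stage assoc")
        _run_assoc(config, seeds["assoc"], outdir, paths)
    if config.enabled("hotspots"):
        logger.info("stage hotspots")
        _, hotspot_results = _run_hotspots(config, outdir, paths, loci)
    if config.enabled("cna"):
        logger.info("stage cna")
        _run_cna(config, seeds["cna"], outdir, paths, loci)
    if config.enabled("tfbs"):
        logger.info("stage tfbs")
        _run_tfbs(config, outdir, paths, hotspot_results)
    if config.enabled("report"):
        logger.info("stage report")
        _write_report(outdir)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": sorted(config.stages),
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def demo_config(outdir: str | Path, seed: int = 0,
                **stage_overrides) -> RunConfig:
    """A fully synthetic end-to-end configuration (all stages enabled)."""
    stages: dict[str, dict] = {s: {} for s in STAGES}
    stages["assoc"] = {"n_permutations": 500}
    stages["cna"] = {"n_perm": 300}
    for stage, opts in stage_overrides.items():
        stages[stage] = opts
    return RunConfig(outdir=Path(outdir), seed=seed, stages=stages)
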