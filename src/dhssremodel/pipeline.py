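"""End-to-end orchestration: from tag files to figure-level summary tables.

``run_all`` runs the DHSS caller, CAGE clustering and all downstream
annotation/enrichment analyses on one input bundle and writes eleven
plain-TSV/BED tables into the output directory.  Missing optional inputs
(enhancers, Foxa2 peaks, qPCR panel, motifs, FASTA) skip the dependent
tables with a logged warning; the run still succeeds.  All randomness is
driven by the single config seed, and no timestamps are written, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .annotate import (
    GeneAnnotator,
    IntervalIndex,
    assign_repeat,
    any_overlap_class,
    distance_bins,
    distance_ks_vs_random,
    enhancer_binomial,
    overlap_fisher,
)
from .cage import (
    TssActivityModel,
    exon1_ratio,
    promoter_overlap,
    read_cage_bed,
    tss_profile,
)
from .caller import DhssAccessibilityModel, ScanGeometry
from .intervals import (
    MappabilityTrack,
    TagLibrary,
    read_bed,
    read_bed12_genes,
    read_chrom_sizes,
    read_repeats,
)
from .motif import compare_groups, pfm_to_pwm, read_jaspar
from .stats import delta_ct, read_qpcr_tsv, welch_t_two_tailed

log = logging.getLogger("dhssremodel")


@dataclass
class PipelineConfig:
    """Input paths, thresholds and the seed for one full run."""

    dhss_veh: str
    dhss_vpa: str
    chrom_sizes: str
    cage_veh: str | None = None
    cage_vpa: str | None = None
    genes: str | None = None
    repeats: str | None = None
    enhancers: str | None = None
    foxa2: str | None = None
    genome: str | None = None
    motifs: str | None = None
    mappability: str | None = None
    qpcr: str | None = None
    fdr: float = 0.05
    min_tpm: float = 10.0
    motif_threshold: float = 0.8
    proximal_max: int = 1_000
    distal_min: int = 1_000_000
    profile_flank: int = 5_000
    seed: int = 0
    geometry: ScanGeometry = field(default_factory=ScanGeometry)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        geo = data.pop("geometry", None)
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        if geo:
            cfg.geometry = ScanGeometry(**geo)
        return cfg


def _write_tsv(path: Path, header: list[str], rows: list[list],
               provenance: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {provenance}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(
                f"{v:.6g}" if isinstance(v, float) else str(v)
                for v in row) + "\n")


def run_all(config: PipelineConfig, outdir) -> dict[str, Path]:
    """Run every stage; returns the map of table name -> written path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    prov = f"dhssremodel {__version__} seed={config.seed} fdr={config.fdr}"
    written: dict[str, Path] = {}

    def emit(name: str, header, rows):
        path = out / name
        _write_tsv(path, header, rows, prov)
        written[name] = path

    log.info("loading tag libraries")
    veh = TagLibrary.from_bed(config.dhss_veh, "Veh")
    vpa = TagLibrary.from_bed(config.dhss_vpa, "VPA")
    chrom_sizes = read_chrom_sizes(config.chrom_sizes)
    mappability = (MappabilityTrack.from_bed(config.mappability)
                   if config.mappability else None)

    log.info("calling DHSS clusters")
    model = DhssAccessibilityModel(veh, vpa, chrom_sizes, mappability,
                                   config.geometry)
    dhss = model.fit(seed=config.seed, target_fdr=config.fdr,
                     alpha=config.fdr)
    dhss.to_bed(out / "dhss_clusters.bed")
    written["dhss_clusters.bed"] = out / "dhss_clusters.bed"
    counts = dhss.status_counts()
    emit("dhss_venn.tsv", ["status", "n_clusters"],
         [[k, v] for k, v in counts.items()])

    genes = read_bed12_genes(config.genes) if config.genes else None
    induced_ivs = [c.interval for c in dhss.induced]
    non_induced_ivs = [c.interval for c in dhss.non_induced]

    # ----- CAGE ---------------------------------------------------------
    tss_res = None
    if config.cage_veh and config.cage_vpa:
        log.info("clustering CAGE tags")
        tags = (read_cage_bed(config.cage_veh, "Veh")
                + read_cage_bed(config.cage_vpa, "VPA"))
        totals = {"Veh": sum(1 for t in tags if t.condition == "Veh"),
                  "VPA": sum(1 for t in tags if t.condition == "VPA")}
        tss_res = TssActivityModel(tags, totals).fit(config.min_tpm, config.fdr)
        tss_res.to_bed(out / "tss_clusters.bed")
        written["tss_clusters.bed"] = out / "tss_clusters.bed"

        if genes:
            fractions, _ = promoter_overlap(tss_res.clusters, genes)
            grp = {s: [c for c in tss_res.clusters if c.status == s]
                   for s in ("induced", "downregulated", "non_induced")}
            rows = [[s, len(grp[s]), f] for s, f in fractions.items()]
            # induced vs non-induced promoter-mapping Fisher test
            _, flags = promoter_overlap(tss_res.clusters, genes)
            ind = [f for c, f in zip(tss_res.clusters, flags)
                   if c.status == "induced"]
            non = [f for c, f in zip(tss_res.clusters, flags)
                   if c.status != "induced"]
            if ind and non:
                _, p = overlap_fisher(sum(ind), len(ind), sum(non), len(non))
                rows.append(["induced_vs_rest_fisher_p", "", p])
            emit("tss_promoter_overlap.tsv",
                 ["group", "n", "fraction_or_p"], rows)

            ratios = exon1_ratio(genes, tags, min_tags=10)
            rows = [[cond, i, r] for cond in sorted(ratios)
                    for i, r in enumerate(ratios[cond])]
            emit("exon1_ratios.tsv", ["condition", "gene_index", "ratio"], rows)

        tss_ivs = {"induced": [c.interval for c in tss_res.clusters
                               if c.status == "induced"],
                   "non_induced": [c.interval for c in tss_res.clusters
                                   if c.status != "induced"]}
        rows = []
        for tss_grp, qs in tss_ivs.items():
            for dhss_grp, targets in (("induced_dhss", induced_ivs),
                                      ("non_induced_dhss", non_induced_ivs)):
                if not qs or not targets:
                    continue
                b = distance_bins(qs, targets, config.proximal_max,
                                  config.distal_min)
                rows.append([tss_grp, dhss_grp, b.proximal, b.semi_distal,
                             b.distal, b.no_target])
        emit("distance_bins.tsv",
             ["tss_group", "dhss_group", "proximal", "semi_distal",
              "distal", "no_target"], rows)
    else:
        log.warning("CAGE inputs missing; skipping TSS tables")

    # ----- repeats ------------------------------------------------------
    sine_induced: list = []
    sine_other: list = []
    if config.repeats:
        repeats = read_repeats(config.repeats)
        rep_index = IntervalIndex(repeats)
        annot = GeneAnnotator(genes) if genes else None
        rows = []
        groups = {"vpa_induced": induced_ivs, "non_induced": non_induced_ivs}
        for gname, ivs in groups.items():
            from collections import Counter
            longest = Counter()
            any_sine = 0
            for iv in ivs:
                hit = assign_repeat(iv, rep_index)
                longest[hit[0] if hit else "none"] += 1
                if any_overlap_class(iv, rep_index, "SINE"):
                    any_sine += 1
                    (sine_induced if gname == "vpa_induced"
                     else sine_other).append(iv)
            for cls, n in sorted(longest.items()):
                rows.append(["longest_overlap", gname, cls, n])
            rows.append(["any_overlap", gname, "SINE", any_sine])
        if annot is not None:
            sines = [r.interval for r in repeats if r.repeat_class == "SINE"]
            for gname, ivs in (("induced_sine_dhss", sine_induced),
                               ("non_induced_sine_dhss", sine_other),
                               ("all_sines", sines)):
                from collections import Counter
                cats = Counter(annot.category(iv) for iv in ivs)
                for cat in ("promoter", "gene_body", "intergenic"):
                    rows.append(["sine_distribution", gname, cat,
                                 cats.get(cat, 0)])
        emit("repeat_assignment.tsv",
             ["section", "group", "key", "value"], rows)
    else:
        log.warning("repeat annotation missing; skipping repeat tables")

    # ----- motifs -------------------------------------------------------
    if config.motifs and config.genome and sine_induced:
        import pyfaidx
        genome = pyfaidx.Fasta(config.genome)
        motifs = [pfm_to_pwm(p, threshold_rel=config.motif_threshold)
                  for p in read_jaspar(config.motifs)]
        other = [iv for iv in induced_ivs + non_induced_ivs
                 if iv not in set(sine_induced)]
        results = compare_groups(sine_induced, other, genome, motifs)
        rows = [[r["motif_id"], r["name"], len(r["counts_a"]),
                 len(r["counts_b"]), float(np.mean(r["counts_a"])),
                 float(np.mean(r["counts_b"])), r["p_value"]]
                for r in results]
        emit("motif_comparison.tsv",
             ["motif_id", "name", "n_induced_sine", "n_other",
              "mean_hits_induced_sine", "mean_hits_other", "wilcoxon_p"],
             rows)
    else:
        log.warning("motif inputs missing; skipping motif comparison")

    # ----- overlap tests ------------------------------------------------
    rows = []
    all_ivs = induced_ivs + non_induced_ivs
    if config.enhancers and all_ivs:
        enhancers = read_bed(config.enhancers)
        p_binom = enhancer_binomial(all_ivs, enhancers, chrom_sizes)
        d, p_ks = distance_ks_vs_random(all_ivs, enhancers, chrom_sizes,
                                        seed=config.seed)
        rows.append(["enhancer_binomial", len(all_ivs), "", p_binom])
        rows.append(["enhancer_ks", len(all_ivs), f"{d:.6g}", p_ks])
    else:
        log.warning("enhancer input missing; skipping enhancer tests")
    if config.foxa2 and sine_induced:
        foxa2 = read_bed(config.foxa2)
        fox_index = IntervalIndex(foxa2)
        hits = sum(1 for iv in sine_induced if fox_index.overlapping(iv))
        bg = sine_other
        bg_hits = sum(1 for iv in bg if fox_index.overlapping(iv))
        if bg:
            odds, p = overlap_fisher(hits, len(sine_induced), bg_hits, len(bg))
            rows.append(["foxa2_fisher", len(sine_induced), f"{odds:.6g}", p])
    emit("overlap_tests.tsv", ["test", "n", "statistic", "p_value"], rows)

    # ----- TSS profile --------------------------------------------------
    if genes:
        profile = tss_profile(veh, genes, flank=config.profile_flank)
        profile_vpa = tss_profile(vpa, genes, flank=config.profile_flank)
        rows = [[int(o), float(mv), float(ma)]
                for o, mv, ma in zip(profile.bin_offsets, profile.mean_tpm,
                                     profile_vpa.mean_tpm)]
        emit("tss_profile.tsv", ["bin_offset", "mean_tpm_veh",
                                 "mean_tpm_vpa"], rows)
    else:
        log.warning("gene models missing; skipping TSS profile")

    # ----- qPCR ---------------------------------------------------------
    if config.qpcr:
        ms = read_qpcr_tsv(config.qpcr)
        groups: dict[str, dict[str, list[float]]] = {}
        for m in ms:
            grp = m.primer_id.rsplit("_", 1)[0]
            groups.setdefault(grp, {}).setdefault(m.condition, []).append(
                delta_ct(m))
        rows = []
        for grp in sorted(groups):
            conds = groups[grp]
            veh_d = conds.get("Veh", [])
            vpa_d = conds.get("VPA", [])
            if len(veh_d) >= 2 and len(vpa_d) >= 2:
                p = welch_t_two_tailed(vpa_d, veh_d)
                rows.append([grp, len(veh_d), len(vpa_d),
                             float(np.mean(veh_d)), float(np.mean(vpa_d)), p])
        emit("qpcr_stats.tsv",
             ["group", "n_veh", "n_vpa", "mean_dct_veh", "mean_dct_vpa",
              "welch_p"], rows)
    else:
        log.warning("qPCR input missing; skipping qPCR table")

    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"dhssremodel {__version__}\n")
        fh.write(f"seed {config.seed}\nfdr {config.fdr}\n")
        fh.write(f"min_tpm {config.min_tpm}\n")
        fh.write(f"geometry {config.geometry}\n")
        fh.write("tables " + " ".join(sorted(written)) + "\n")
    return written
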