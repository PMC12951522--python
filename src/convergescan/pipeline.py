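"""Config-driven orchestration of the full convergence scan.

Stages run in dependency order: filter -> allele frequencies -> {score,
windows, fixed differences, MK} -> enrichment. Every output file is listed
in a JSON manifest with the parameters that produced it, so two runs with
the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .convergence import (classify_sites, convergence_score,
                          excess_binomial_test, partition_genes_by_sign)
from .enrichment import ora, read_gmt, significant_terms
from .filters import FilterConfig, apply_site_filters
from .fixation import (morph_candidate_genes, morph_overlap_permutation,
                       sites_to_genes, species_fixed_sites)
from .frequencies import allele_frequencies
from .panel import Pairing, load_panel
from .selection import compare_ni_between_groups, mk_counts, ni_tg, selection_table
from .variants import read_variants
from .windows import (da_outlier_windows, make_windows, window_divergence,
                      window_diversity)

log = logging.getLogger(__name__)

DEFAULT_STAGES = ("filter", "afreq", "score", "windows", "fixed", "mk", "enrich")


@dataclass
class RunConfig:
    vcf: str
    panel: str
    annotation: str | None = None
    terms: str | None = None
    outdir: str = "convergescan_out"
    stages: tuple[str, ...] = DEFAULT_STAGES
    seed: int = 0
    threshold: float = 0.25
    window_size: int = 20_000
    window_step: int = 10_000
    da_quantile: float = 0.95
    n_perm: int = 199
    n_boot: int = 1000
    alpha: float = 0.05
    min_fixed_copies: int = 8
    pairing: tuple[str, ...] | None = None  # slenderA, stoutA, slenderB, stoutB
    filter: FilterConfig = field(default_factory=FilterConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        fcfg = FilterConfig(**raw.pop("filter", {}))
        stages = tuple(raw.pop("stages", DEFAULT_STAGES))
        return cls(filter=fcfg, stages=stages, **raw)

    def validate(self) -> None:
        for p in (self.vcf, self.panel, self.annotation, self.terms):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages; returns the manifest (also written to disk)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "stages": list(cfg.stages), "outputs": {}, "summary": {}}

    def register(stage: str, name: str, path: Path) -> None:
        manifest["outputs"].setdefault(stage, {})[name] = path.name

    panel = load_panel(
        cfg.panel, Pairing(*cfg.pairing) if cfg.pairing else None
    )
    vt, gt = read_variants(cfg.vcf, panel)
    if cfg.annotation:
        vt = vt.join_annotation(cfg.annotation)

    if "filter" in cfg.stages:
        keep, gt, report = apply_site_filters(gt, cfg.filter)
        vt, gt = vt.subset(keep), gt.subset(keep)
        path = outdir / "filter_report.json"
        path.write_text(json.dumps(report.as_dict(), indent=1))
        register("filter", "report", path)
        sites = outdir / "filtered_sites.tsv"
        vt.df[["chrom", "pos", "ref", "alt", "vtype"]].to_csv(
            sites, sep="\t", index=False
        )
        register("filter", "sites", sites)
        manifest["summary"]["n_sites"] = len(vt)

    af = allele_frequencies(gt, panel)
    if "afreq" in cfg.stages:
        path = outdir / "allele_frequencies.tsv"
        af.to_dataframe(vt).to_csv(path, sep="\t", index=False, float_format="%.6g")
        register("afreq", "table", path)

    track = None
    if "score" in cfg.stages:
        track = convergence_score(af, panel.require_pairing())
        outliers = classify_sites(track, cfg.threshold)
        path = outdir / "convergence_scores.tsv"
        df = vt.df[["chrom", "pos"]].copy()
        df["score"] = track.score
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        register("score", "scores", path)
        bed = outdir / "outliers.bed"
        with open(bed, "w") as fh:
            for i in np.sort(np.concatenate([outliers.positive, outliers.negative])):
                row = vt.df.iloc[int(i)]
                fh.write(f"{row.chrom}\t{row.pos - 1}\t{row.pos}\t"
                         f"{track.score[int(i)]:.6g}\n")
        register("score", "outlier_bed", bed)
        nz_pos = int((track.score[track.defined] > 0).sum())
        nz_neg = int((track.score[track.defined] < 0).sum())
        excess = excess_binomial_test(nz_pos, nz_neg) if nz_pos + nz_neg else None
        out_excess = (
            excess_binomial_test(len(outliers.positive), len(outliers.negative))
            if len(outliers.positive) + len(outliers.negative)
            else None
        )
        pos_only, neg_only, both = partition_genes_by_sign(outliers, vt)
        rep = {
            "n_nonzero_convergent": nz_pos, "n_nonzero_divergent": nz_neg,
            "excess_p": excess.p_value if excess else None,
            "n_outlier_positive": len(outliers.positive),
            "n_outlier_negative": len(outliers.negative),
            "outlier_excess_p": out_excess.p_value if out_excess else None,
            "n_genes_positive_only": len(pos_only),
            "n_genes_negative_only": len(neg_only),
            "n_genes_both": len(both),
        }
        path = outdir / "excess_test.json"
        path.write_text(json.dumps(rep, indent=1))
        register("score", "excess_report", path)
        manifest["summary"]["score"] = rep
        manifest["summary"]["gene_sets"] = {
            "positive_only": sorted(pos_only), "negative_only": sorted(neg_only)
        }

    if "windows" in cfg.stages:
        contig_lengths = {
            c: int(vt.df.loc[vt.df["chrom"] == c, "pos"].max())
            for c in vt.df["chrom"].unique()
        }
        wins = make_windows(contig_lengths, cfg.window_size, cfg.window_step)
        pi = window_diversity(gt, vt, panel, wins)
        pairing = panel.require_pairing()
        table = pi.copy()
        for pair in (
            (pairing.slender_a, pairing.stout_a),
            (pairing.slender_b, pairing.stout_b),
        ):
            div = window_divergence(af, vt, wins, pair, pi)
            tag = f"{pair[0]}_{pair[1]}"
            table[f"dxy_{tag}"] = div["dxy"]
            table[f"da_{tag}"] = div["da"]
        path = outdir / "windows.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        register("windows", "table", path)
        out_a = da_outlier_windows(
            table[f"da_{pairing.slender_a}_{pairing.stout_a}"].to_numpy(),
            cfg.da_quantile,
        )
        out_b = da_outlier_windows(
            table[f"da_{pairing.slender_b}_{pairing.stout_b}"].to_numpy(),
            cfg.da_quantile,
        )
        bed = outdir / "da_outliers.bed"
        with open(bed, "w") as fh:
            for k in sorted(set(out_a) | set(out_b)):
                r = table.iloc[int(k)]
                fh.write(f"{r.chrom}\t{int(r.start)}\t{int(r.end)}\n")
        register("windows", "outlier_bed", bed)
        manifest["summary"]["windows"] = {
            "n_windows": len(table),
            "n_outliers_pairA": len(out_a), "n_outliers_pairB": len(out_b),
            "n_shared": len(set(out_a) & set(out_b)),
        }

    if "fixed" in cfg.stages:
        fixed = species_fixed_sites(af, min_copies=cfg.min_fixed_copies)
        cand = morph_candidate_genes(fixed, vt, panel.require_pairing())
        gene_sets = {sp: sites_to_genes(s, vt) for sp, s in fixed.sets.items()}
        obs, p_perm, _ = morph_overlap_permutation(gene_sets, panel.require_pairing())
        path = outdir / "fixed_candidates.tsv"
        with open(path, "w") as fh:
            fh.write("gene\tmorph\n")
            for g in sorted(cand.fixed_slender):
                fh.write(f"{g}\tslender\n")
            for g in sorted(cand.fixed_stout):
                fh.write(f"{g}\tstout\n")
        register("fixed", "candidates", path)
        rep = {
            "n_fixed_sites": {sp: len(s) for sp, s in fixed.sets.items()},
            "n_genes_slender": len(cand.fixed_slender),
            "n_genes_stout": len(cand.fixed_stout),
            "overlap_statistic": obs, "permutation_p": p_perm,
        }
        path = outdir / "fixed_report.json"
        path.write_text(json.dumps(rep, indent=1))
        register("fixed", "report", path)
        manifest["summary"]["fixed"] = rep
        manifest["summary"]["gene_sets_fixed"] = {
            "slender": sorted(cand.fixed_slender), "stout": sorted(cand.fixed_stout)
        }

    if "mk" in cfg.stages:
        species = panel.species()
        mk_summary = {}
        ni_by_pair = {}
        for i, a in enumerate(species):
            for b in species[i + 1:]:
                genes = mk_counts(vt, af, a, b)
                if not genes or not any(g.ps + g.ds > 0 for g in genes):
                    continue
                tab = selection_table(genes, cfg.alpha)
                tag = f"{a}_{b}"
                path = outdir / f"mk_{tag}.tsv"
                tab.to_csv(path, sep="\t", index=False, float_format="%.6g")
                register("mk", tag, path)
                point, ci, p = ni_tg(genes, cfg.n_boot, rng)
                ni_by_pair[tag] = (a, b, point)
                mk_summary[tag] = {
                    "ni_tg": point, "ci": list(ci), "p_vs_1": p,
                    "n_genes": len(genes),
                    "n_positively_selected": int(tab["positively_selected"].sum()),
                }
        morphs = panel.morph_of
        cross, within = [], []
        for a, b, v in ni_by_pair.values():
            if not np.isfinite(v):
                continue
            (cross if morphs[a] != morphs[b] else within).append(v)
        if len(cross) >= 1 and len(within) >= 1:
            mk_summary["cross_vs_within_p"] = compare_ni_between_groups(
                cross, within
            )
        path = outdir / "mk_report.json"
        path.write_text(json.dumps(mk_summary, indent=1))
        register("mk", "report", path)
        manifest["summary"]["mk"] = mk_summary

    if "enrich" in cfg.stages and cfg.terms:
        terms = read_gmt(cfg.terms)
        background = {
            g for g in vt.df["gene"] if isinstance(g, str)
        }
        queries = {}
        gs = manifest["summary"].get("gene_sets", {})
        if gs:
            queries["score_positive"] = set(gs["positive_only"]) & background
            queries["score_negative"] = set(gs["negative_only"]) & background
        gsf = manifest["summary"].get("gene_sets_fixed", {})
        if gsf:
            queries["fixed_union"] = (
                set(gsf["slender"]) | set(gsf["stout"])
            ) & background
        enrich_summary = {}
        for name, query in queries.items():
            res = ora(query, background, terms, cfg.alpha)
            path = outdir / f"enrichment_{name}.tsv"
            res.to_csv(path, sep="\t", index=False, float_format="%.6g")
            register("enrich", name, path)
            enrich_summary[name] = {
                "n_tested": len(res),
                "n_significant": len(significant_terms(res)),
            }
        manifest["summary"]["enrichment"] = enrich_summary

    for key in ("gene_sets", "gene_sets_fixed"):
        manifest["summary"].pop(key, None)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
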