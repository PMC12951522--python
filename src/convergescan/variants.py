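"""Variant tables, diploid genotype matrices, and VCF input/output.

Genotypes are stored as alt-allele dosage (0, 1, 2) with -1 for missing, in a
variants × samples int8 array. Coordinates stay 1-based as in the VCF; window
arithmetic downstream converts to 0-based half-open internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import SpeciesPanel

log = logging.getLogger(__name__)

MISSING = -1

#: SnpEff-style effect classes recognised in annotation tables.
EFFECT_CLASSES = ("synonymous", "nonsynonymous", "noncoding")


@dataclass
class VariantTable:
    """Per-variant metadata: position, alleles, type, gene and effect class."""

    df: pd.DataFrame  # chrom, pos, ref, alt, vtype, gene, effect

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "ref", "alt"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"variant table needs columns {sorted(required)}")
        if "vtype" not in self.df.columns:
            ref = self.df["ref"].str.len()
            alt = self.df["alt"].str.len()
            self.df["vtype"] = np.where((ref == 1) & (alt == 1), "SNP", "indel")
        for col in ("gene", "effect"):
            if col not in self.df.columns:
                self.df[col] = None
        key = self.df[["chrom", "pos", "alt"]]
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, pos, alt) records")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    @property
    def is_snp(self) -> np.ndarray:
        return (self.df["vtype"] == "SNP").to_numpy()

    def join_annotation(self, path) -> "VariantTable":
        """Join a SnpEff-like TSV (chrom, pos, ref, alt, gene, effect) by site."""
        ann = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": np.int64})
        bad = set(ann["effect"].dropna()) - set(EFFECT_CLASSES)
        if bad:
            raise ValueError(f"unknown effect classes: {sorted(bad)}")
        merged = self.df.drop(columns=["gene", "effect"]).merge(
            ann[["chrom", "pos", "ref", "alt", "gene", "effect"]],
            on=["chrom", "pos", "ref", "alt"],
            how="left",
        )
        return VariantTable(merged)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(self.df.loc[mask].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Diploid alt-allele dosages with optional per-call depth evidence.

    calls : (n_variants, n_samples) int8, values {0, 1, 2, -1=missing}
    depth : optional (n_variants, n_samples) total read depth
    ad    : optional (n_variants, n_samples, 2) ref/alt read depths
    """

    calls: np.ndarray
    depth: np.ndarray | None = None
    ad: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (variants x samples)")
        if not np.isin(self.calls, [-1, 0, 1, 2]).all():
            raise ValueError("genotype dosages must be in {-1, 0, 1, 2}")
        for arr, nd in ((self.depth, 2), (self.ad, 3)):
            if arr is not None and arr.shape[:2] != self.calls.shape:
                raise ValueError("depth/ad dimensions do not match calls")

    @property
    def n_variants(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    def missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls[mask],
            None if self.depth is None else self.depth[mask],
            None if self.ad is None else self.ad[mask],
        )


def read_variants(
    vcf_path, panel: SpeciesPanel, biallelic_only: bool = True
) -> tuple[VariantTable, GenotypeMatrix]:
    """Read a VCF into a variant table and dosage matrix for the panel samples.

    Multiallelic records are excluded (with a log entry) when
    ``biallelic_only`` is set. Raises if a panel sample is absent from the
    VCF header.
    """
    vcf = VCF(str(vcf_path))
    header_samples = list(vcf.samples)
    absent = [s for s in panel.samples if s not in header_samples]
    if absent:
        raise ValueError(f"panel samples absent from VCF: {absent}")
    order = [header_samples.index(s) for s in panel.samples]

    rows = []
    calls_rows, depth_rows, ad_rows = [], [], []
    have_dp = have_ad = True
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            if biallelic_only:
                continue
        alt = rec.ALT[0] if rec.ALT else "."
        rows.append((rec.CHROM, rec.POS, rec.REF, alt))
        gts = rec.genotype.array()[:, :2]  # alleles; -1 missing
        dosage = np.where((gts < 0).any(axis=1), MISSING, gts.clip(0).sum(axis=1))
        calls_rows.append(dosage[order])
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        if dp is None:
            have_dp = False
        else:
            depth_rows.append(dp[:, 0][order])
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is None or ad.shape[1] < 2:
            have_ad = False
        else:
            ad_rows.append(ad[order, :2])
    if n_multi:
        log.info("excluded %d multiallelic record(s)", n_multi)
    if not rows:
        raise ValueError("VCF contains no usable records")
    vt = VariantTable(pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]))
    gt = GenotypeMatrix(
        np.asarray(calls_rows, dtype=np.int8),
        np.asarray(depth_rows) if have_dp and depth_rows else None,
        np.asarray(ad_rows) if have_ad and ad_rows else None,
    )
    return vt, gt


def write_vcf(vt: VariantTable, gt: GenotypeMatrix, panel: SpeciesPanel, path) -> None:
    """Write a minimal valid VCF v4.2 with GT (and DP/AD when present).

    Missing genotypes are serialised as ``./.`` so a round-trip through
    :func:`read_variants` preserves dosage counts exactly.
    """
    if len(vt) != gt.n_variants or len(panel.samples) != gt.n_samples:
        raise ValueError("variant table, genotypes and panel are inconsistent")
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    fmt = "GT"
    if gt.depth is not None:
        fmt += ":DP"
    if gt.ad is not None:
        fmt += ":AD"
    contigs = list(dict.fromkeys(vt.df["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            end = int(vt.df.loc[vt.df["chrom"] == c, "pos"].max()) + 1000
            fh.write(f"##contig=<ID={c},length={end}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gt.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        if gt.ad is not None:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        for i, row in enumerate(vt.df.itertuples(index=False)):
            cells = []
            for j in range(gt.n_samples):
                parts = [gt_strings[int(gt.calls[i, j])]]
                if gt.depth is not None:
                    parts.append(str(int(gt.depth[i, j])))
                if gt.ad is not None:
                    parts.append(f"{int(gt.ad[i, j, 0])},{int(gt.ad[i, j, 1])}")
                cells.append(":".join(parts))
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\t"
                f"{fmt}\t" + "\t".join(cells) + "\n"
            )
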