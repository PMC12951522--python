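"""Synthetic multi-species radiation generator with planted convergent loci.

The generator emulates the study design the pipeline assumes: five species
(two slender, three stout) of 10–13 diploid individuals each, biallelic SNPs
and indels whose per-species allele frequencies drift along a species tree
(Balding–Nichols beta perturbation, variance F·p(1−p) per branch with
branch-specific F), one optional introgression edge mixing a recipient's
frequencies toward a donor, and a configurable number of convergent loci
where a new allele (absent elsewhere) is pushed to frequency δ in both
slender species after drift — mimicking independent selection on shared
standing variation. Genotypes are binomial draws from the species
frequencies, with missingness and synthetic read-depth evidence; genes are
fixed-length tiles so gene/window bookkeeping is exactly computable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from Bio import Phylo

from .enrichment import TermMap
from .frequencies import AlleleFrequencyTable
from .panel import Pairing, SpeciesPanel
from .variants import MISSING, GenotypeMatrix, VariantTable
from .convergence import OutlierSets

#: Species tree mirroring the study radiation: slenderA basal, then slenderB,
#: then stoutB, with (stoutC, stoutA) as the youngest split. Branch lengths
#: are the per-branch drift parameters F, sized for a radiation old enough
#: to carry species-private fixed differences (several Myr of divergence).
DEFAULT_TREE = (
    "(slenderA:0.3,(slenderB:0.25,(stoutB:0.2,"
    "(stoutC:0.1,stoutA:0.1):0.1):0.1):0.1);"
)

DEFAULT_MORPHS = {
    "slenderA": "slender",
    "stoutA": "stout",
    "slenderB": "slender",
    "stoutB": "stout",
    "stoutC": "stout",
}


@dataclass
class SimConfig:
    """Study-scale defaults: 5 species x 11-13 diploids (58 total), drifted
    biallelic SNPs/indels, one introgression edge at 38.3%, planted
    convergent loci at frequency shift delta in the slender species."""

    n_per_species: dict[str, int] = field(
        default_factory=lambda: {
            "slenderA": 12, "stoutA": 11, "slenderB": 12,
            "stoutB": 11, "stoutC": 12,
        }
    )
    morph_of: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MORPHS))
    contigs: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    n_sites: int = 20_000
    tree: str = DEFAULT_TREE
    # (donor tip, recipient tips, proportion); mirrors gene flow from the
    # basal slender lineage into the youngest stout ancestor.
    admixture: tuple[str, tuple[str, ...], float] | None = (
        "slenderA", ("stoutC", "stoutA"), 0.383
    )
    convergent_loci: int = 50
    delta: float = 0.9
    effect_mix: dict[str, float] = field(
        default_factory=lambda: {
            "synonymous": 0.10, "nonsynonymous": 0.15, "noncoding": 0.75
        }
    )
    indel_fraction: float = 0.14
    missing_rate: float = 0.02
    depth_mean: float = 20.0
    gene_size: int = 5_000
    gene_spacing: int = 15_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.delta <= 1.0:
            raise ValueError("delta must be in (0, 1]")
        if abs(sum(self.effect_mix.values()) - 1.0) > 1e-9:
            raise ValueError("effect_mix fractions must sum to 1")
        for sp, n in self.n_per_species.items():
            if sp not in self.morph_of:
                raise ValueError(f"species {sp!r} lacks a morphotype")
            if n < 2:
                raise ValueError("need at least 2 individuals per species")

    @property
    def species(self) -> list[str]:
        return list(self.n_per_species)

    def pairing(self) -> Pairing:
        slender = [s for s in self.species if self.morph_of[s] == "slender"]
        stout = [s for s in self.species if self.morph_of[s] == "stout"]
        return Pairing(slender[0], stout[0], slender[1], stout[1])


@dataclass
class TruthTable:
    """Ground truth per simulated site."""

    df: pd.DataFrame  # chrom, pos, is_convergent, delta, gene, effect

    def __post_init__(self) -> None:
        n_flagged = int(self.df["is_convergent"].sum())
        self._n_convergent = n_flagged

    @property
    def convergent_indices(self) -> np.ndarray:
        return np.flatnonzero(self.df["is_convergent"].to_numpy())


@dataclass
class SimResult:
    panel: SpeciesPanel
    variants: VariantTable
    genotypes: GenotypeMatrix
    truth: TruthTable
    terms: TermMap
    species_freqs: np.ndarray  # (n_sites, n_species) true tip frequencies

    def allele_frequency_table(self) -> AlleleFrequencyTable:
        """True (not sampled) per-species frequencies, for diagnostics."""
        n = np.full_like(self.species_freqs, 2, dtype=np.int64)
        return AlleleFrequencyTable(self.species_freqs, n, self.panel.species())


def _drift_tip_freqs(
    tree_newick: str, species: list[str], p_anc: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Propagate ancestral frequencies down the tree with Balding–Nichols
    beta perturbations (variance F p(1-p), F = branch length)."""
    tree = Phylo.read(StringIO(tree_newick), "newick")

    def perturb(p: np.ndarray, f: float) -> np.ndarray:
        if f <= 0:
            return p.copy()
        out = p.copy()
        interior = (p > 0) & (p < 1)
        a = p[interior] * (1 - f) / f
        b = (1 - p[interior]) * (1 - f) / f
        out[interior] = rng.beta(a, b)
        return out

    tips: dict[str, np.ndarray] = {}

    def walk(clade, p):
        for child in clade.clades:
            f = child.branch_length or 0.0
            q = perturb(p, f)
            if child.is_terminal():
                tips[child.name] = q
            else:
                walk(child, q)

    walk(tree.root, p_anc)
    missing = set(species) - set(tips)
    if missing:
        raise ValueError(f"tree lacks tips for species: {sorted(missing)}")
    return tips


_BASES = np.array(list("ACGT"))


def simulate_radiation(cfg: SimConfig) -> SimResult:
    """Generate the full synthetic data set for one seed.

    Deterministic given ``cfg.seed``: site placement, frequencies, genotypes,
    missingness and annotations all derive from one generator stream.
    """
    rng = np.random.default_rng(cfg.seed)
    species = cfg.species
    total_len = sum(cfg.contigs.values())

    # --- site placement, proportional to contig length
    chroms, positions = [], []
    remaining = cfg.n_sites
    names = list(cfg.contigs)
    for i, (chrom, length) in enumerate(cfg.contigs.items()):
        k = remaining if i == len(names) - 1 else int(
            round(cfg.n_sites * length / total_len)
        )
        k = min(k, remaining)
        remaining -= k
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=k, replace=False))
        chroms.extend([chrom] * k)
        positions.extend(pos.tolist())
    chrom_arr = np.array(chroms)
    pos_arr = np.array(positions, dtype=np.int64)
    n_sites = len(pos_arr)

    # --- ancestral frequencies from a neutral-SFS-like density (~1/p),
    # rare-variant-heavy so lineage-private fixation can arise under drift
    u = rng.random(n_sites)
    lo, hi = 0.01, 0.99
    p_anc = lo * (hi / lo) ** u

    # --- planted convergent loci: a new allele absent elsewhere
    conv_idx = rng.choice(n_sites, size=cfg.convergent_loci, replace=False)
    conv_idx.sort()
    is_conv = np.zeros(n_sites, dtype=bool)
    is_conv[conv_idx] = True
    p_anc[is_conv] = 0.0

    # --- drift along the tree, then admixture, then the convergent shift
    tips = _drift_tip_freqs(cfg.tree, species, p_anc, rng)
    if cfg.admixture is not None:
        donor, recipients, prop = cfg.admixture
        for r in recipients:
            tips[r] = (1 - prop) * tips[r] + prop * tips[donor]
    slender_species = [s for s in species if cfg.morph_of[s] == "slender"]
    clipped = 0
    for s in slender_species:
        shifted = tips[s].copy()
        shifted[is_conv] += cfg.delta
        clipped += int((shifted[is_conv] > 1).sum())
        tips[s] = np.clip(shifted, 0.0, 1.0)
    freqs = np.column_stack([tips[s] for s in species])

    # --- genes as fixed tiles; effects only inside genes
    period = cfg.gene_size + cfg.gene_spacing
    tile = (pos_arr - 1) // period
    in_gene = (pos_arr - 1) % period < cfg.gene_size
    gene_ids = np.array(
        [f"g_{c}_{t:04d}" if g else None
         for c, t, g in zip(chrom_arr, tile, in_gene)],
        dtype=object,
    )
    effect_names = list(cfg.effect_mix)
    effect_p = np.array([cfg.effect_mix[e] for e in effect_names])
    eff_draw = rng.choice(len(effect_names), size=n_sites, p=effect_p)
    effects = np.where(
        in_gene, np.array(effect_names, dtype=object)[eff_draw], "noncoding"
    )

    # --- alleles and variant types
    is_indel = rng.random(n_sites) < cfg.indel_fraction
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    ref = _BASES[ref_idx].astype(object)
    alt = _BASES[alt_idx].astype(object)
    ins = rng.random(n_sites) < 0.5
    for i in np.flatnonzero(is_indel):
        if ins[i]:
            alt[i] = str(ref[i]) + str(_BASES[alt_idx[i]])
        else:
            ref[i] = str(ref[i]) + str(_BASES[alt_idx[i]])
            alt[i] = str(ref[i])[0]
    # indels are noncoding in the synthetic annotation (frame bookkeeping is
    # out of scope for the generator)
    effects = np.where(is_indel, "noncoding", effects)

    vt = VariantTable(
        pd.DataFrame(
            {
                "chrom": chrom_arr, "pos": pos_arr,
                "ref": ref.astype(str), "alt": alt.astype(str),
                "vtype": np.where(is_indel, "indel", "SNP"),
                "gene": gene_ids, "effect": effects,
            }
        )
    )

    # --- panel and genotypes
    samples, species_of = [], {}
    for sp in species:
        for i in range(cfg.n_per_species[sp]):
            name = f"{sp}_{i + 1:02d}"
            samples.append(name)
            species_of[name] = sp
    panel = SpeciesPanel(samples, species_of, dict(cfg.morph_of), cfg.pairing())

    n_samp = len(samples)
    calls = np.empty((n_sites, n_samp), dtype=np.int8)
    col = 0
    for j, sp in enumerate(species):
        k = cfg.n_per_species[sp]
        calls[:, col:col + k] = rng.binomial(
            2, freqs[:, [j]], size=(n_sites, k)
        ).astype(np.int8)
        col += k
    miss = rng.random(calls.shape) < cfg.missing_rate
    calls[miss] = MISSING

    depth = rng.poisson(cfg.depth_mean, size=calls.shape).astype(np.int32)
    alt_reads = np.zeros_like(depth)
    het = calls == 1
    alt_reads[het] = rng.binomial(depth[het], 0.5)
    hom_alt = calls == 2
    alt_reads[hom_alt] = depth[hom_alt]
    ad = np.stack([depth - alt_reads, alt_reads], axis=-1)
    gt = GenotypeMatrix(calls, depth, ad)

    truth = TruthTable(
        pd.DataFrame(
            {
                "chrom": chrom_arr, "pos": pos_arr, "is_convergent": is_conv,
                "delta": np.where(is_conv, cfg.delta, 0.0),
                "gene": gene_ids, "effect": effects,
            }
        )
    )

    # --- term-map fixture: consecutive genes chunked into terms of 10
    genes_sorted = sorted({g for g in gene_ids if isinstance(g, str)})
    terms = {
        f"T{t:03d}": set(genes_sorted[t * 10:(t + 1) * 10])
        for t in range((len(genes_sorted) + 9) // 10)
    }
    term_map = TermMap({t: g for t, g in terms.items() if g})

    return SimResult(panel, vt, gt, truth, term_map, freqs)


def evaluate_recovery(
    outliers: OutlierSets, truth: TruthTable
) -> tuple[float, float]:
    """Precision and recall of positive outliers against planted convergent loci.

    Precision is NaN when no positive outlier was called.
    """
    called = set(int(i) for i in outliers.positive)
    true_set = set(int(i) for i in truth.convergent_indices)
    if not true_set:
        raise ValueError("truth table contains no convergent loci")
    tp = len(called & true_set)
    precision = tp / len(called) if called else float("nan")
    recall = tp / len(true_set)
    return precision, recall


def write_panel_tsv(panel: SpeciesPanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tspecies\tmorphotype\n")
        for s in panel.samples:
            sp = panel.species_of[s]
            fh.write(f"{s}\t{sp}\t{panel.morph_of[sp]}\n")


def write_annotation_tsv(vt: VariantTable, path) -> None:
    out = vt.df[["chrom", "pos", "ref", "alt", "gene", "effect"]]
    out.to_csv(path, sep="\t", index=False)


def write_truth_tsv(truth: TruthTable, path) -> None:
    truth.df.to_csv(path, sep="\t", index=False)
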