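"""Synthetic genotype + phenotype panels with known ground truth.

Population structure follows the Balding-Nichols model: per-population
allele frequencies are Beta draws around a shared ancestral frequency with
variance set by the target Fst.  Individuals carry Dirichlet admixture
proportions biased toward their labelled population; genotypes are binomial
draws from the admixed individual frequency.  Traits are cluster means plus
correlated Gaussian noise.  Everything is reproducible bit-for-bit under a
fixed seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .datatypes import GenomeLayout, GenotypeMatrix, TRAITS, new_variant_table
from .genotype_io import write_vcf

#: Default population codes (7 sub-regional populations).
DEFAULT_POP_CODES = ("DDB", "DDN", "DX", "DXB", "DXN", "DZ", "YJZY")

#: Trait baseline means and coefficients of variation shaping the defaults.
_TRAIT_MEANS = {"BNMS": 6.8, "NNMS": 19.1, "SD": 9.8, "PH": 151.3}
_TRAIT_CVS = {"BNMS": 0.21, "NNMS": 0.10, "SD": 0.085, "PH": 0.081}


def _default_pop_sizes(n: int, codes: Tuple[str, ...]) -> Dict[str, int]:
    base, extra = divmod(n, len(codes))
    return {c: base + (1 if i < extra else 0) for i, c in enumerate(codes)}


@dataclass
class SimulationConfig:
    n_accessions: int = 313
    pop_sizes: Optional[Dict[str, int]] = None
    n_snps: int = 5000
    n_chromosomes: int = 8
    chrom_lengths: Optional[Dict[str, int]] = None
    fst: float = 0.05
    admixture_alpha: float = 0.1
    missing_rate: float = 0.02
    n_trait_clusters: int = 4
    trait_cluster_spread: float = 1.5
    trait_correlation: float = 0.3
    #: fraction of sites planted to fail each hard-filter rule
    fail_fractions: Dict[str, float] = field(default_factory=dict)
    seed: int = 313

    def __post_init__(self) -> None:
        if self.pop_sizes is None:
            self.pop_sizes = _default_pop_sizes(self.n_accessions, DEFAULT_POP_CODES)
        if sum(self.pop_sizes.values()) != self.n_accessions:
            raise ValueError("population sizes must sum to n_accessions")
        if not (0.0 < self.fst < 0.5):
            raise ValueError("fst must be in (0, 0.5)")
        if not (0.0 <= self.missing_rate < 0.5):
            raise ValueError("missing_rate must be in [0, 0.5)")
        if self.chrom_lengths is None:
            per = -(-self.n_snps // self.n_chromosomes)
            self.chrom_lengths = {
                f"chr{i+1}": (per + 1) * 1000 for i in range(self.n_chromosomes)
            }


@dataclass
class SimulationTruth:
    ancestral_freqs: np.ndarray
    pop_freqs: np.ndarray  # (k_pops, n_snps)
    admixture: np.ndarray  # (n, k_pops) rows sum to 1
    pop_labels: List[str]
    trait_clusters: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "ancestral_freqs": self.ancestral_freqs.round(6).tolist(),
                "pop_freqs": self.pop_freqs.round(6).tolist(),
                "admixture": self.admixture.round(6).tolist(),
                "pop_labels": self.pop_labels,
                "trait_clusters": self.trait_clusters.tolist(),
            },
            sort_keys=True,
        )


def simulate_frequencies(
    n_snps: int, k_pops: int, fst: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Ancestral Uniform(0.05, 0.95) frequencies and Balding-Nichols
    per-population Beta(p(1-F)/F, (1-p)(1-F)/F) draws."""
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    ratio = (1.0 - fst) / fst
    pop = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio, size=(k_pops, n_snps))
    return p_anc, np.clip(pop, 1e-6, 1 - 1e-6)


@dataclass
class SimPanel:
    genotypes: GenotypeMatrix
    layout: GenomeLayout
    phenotypes: pd.DataFrame
    popmap: pd.Series
    truth: SimulationTruth


_PURINE_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _draw_alleles(n: int, rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """REF/ALT pairs with a ~68% transition share (realistic Ts/Tv)."""
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=n)]
    is_ts = rng.random(n) < 0.68
    alt = np.empty(n, dtype="<U1")
    for i in range(n):
        if is_ts[i]:
            alt[i] = _PURINE_PARTNER[ref[i]]
        else:
            alt[i] = _TRANSVERSIONS[ref[i]][rng.integers(0, 2)]
    return ref, alt


_FAIL_VALUES = {
    "QUAL": ("qual", 10.0),
    "QD": ("QD", 1.5),
    "MQ": ("MQ", 30.0),
    "FS": ("FS", 70.0),
    "SOR": ("SOR", 5.0),
    "MQRankSum": ("MQRankSum", -13.0),
    "ReadPosRankSum": ("ReadPosRankSum", -9.0),
}


def simulate_panel(config: SimulationConfig) -> SimPanel:
    """Draw a full synthetic panel from a configuration (deterministic)."""
    rng = np.random.default_rng(config.seed)
    codes = list(config.pop_sizes)
    k = len(codes)
    m = config.n_snps
    p_anc, pop_freqs = simulate_frequencies(m, k, config.fst, rng)

    labels: List[str] = []
    for code in codes:
        labels.extend([code] * config.pop_sizes[code])
    n = len(labels)
    accessions = [f"ACC{i+1:03d}" for i in range(n)]

    conc = np.full((n, k), config.admixture_alpha)
    for i, lab in enumerate(labels):
        conc[i, codes.index(lab)] += 1.0
    Q = np.vstack([rng.dirichlet(conc[i]) for i in range(n)])

    indiv_freq = Q @ pop_freqs
    dosages = rng.binomial(2, indiv_freq).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    # site coordinates: contiguous chromosome blocks, evenly spaced
    chrom_names = list(config.chrom_lengths)
    per = -(-m // len(chrom_names))
    chroms, positions = [], []
    for ci, cname in enumerate(chrom_names):
        count = min(per, m - ci * per)
        if count <= 0:
            break
        chroms.extend([cname] * count)
        positions.extend((np.arange(count) + 1) * 1000)
    ref, alt = _draw_alleles(m, rng)

    sites = new_variant_table(
        pd.DataFrame(
            {
                "chrom": chroms,
                "pos": positions,
                "ref": ref,
                "alt": alt,
                "qual": rng.uniform(30, 100, m).round(2),
                "QD": rng.uniform(5, 30, m).round(2),
                "MQ": rng.uniform(50, 60, m).round(2),
                "FS": rng.uniform(0, 10, m).round(2),
                "SOR": rng.uniform(0.5, 2.0, m).round(2),
                "MQRankSum": rng.normal(0, 1, m).round(2),
                "ReadPosRankSum": rng.normal(0, 1, m).round(2),
            }
        )
    )
    for rule, frac in config.fail_fractions.items():
        col, bad_value = _FAIL_VALUES[rule]
        hit = rng.random(m) < frac
        sites.loc[hit, col] = bad_value

    geno = GenotypeMatrix(accessions, dosages, sites)
    layout = GenomeLayout(dict(config.chrom_lengths))

    # traits: population-derived cluster means + correlated Gaussian noise
    clusters = np.array([codes.index(lab) % config.n_trait_clusters for lab in labels])
    t = len(TRAITS)
    corr = np.full((t, t), config.trait_correlation)
    np.fill_diagonal(corr, 1.0)
    sds = np.array([_TRAIT_MEANS[tr] * _TRAIT_CVS[tr] for tr in TRAITS])
    cov = corr * np.outer(sds, sds)
    offsets = rng.normal(0.0, config.trait_cluster_spread, size=(config.n_trait_clusters, t))
    base = np.array([_TRAIT_MEANS[tr] for tr in TRAITS])
    means = base[None, :] * (1.0 + 0.1 * offsets)
    noise = rng.multivariate_normal(np.zeros(t), cov, size=n, method="cholesky")
    values = np.maximum(means[clusters] + noise, 0.1 * base[None, :])
    pheno = pd.DataFrame(values.round(2), index=accessions, columns=list(TRAITS))
    pheno.index.name = "accession"

    popmap = pd.Series(labels, index=accessions, name="population")
    popmap.index.name = "accession"
    truth = SimulationTruth(p_anc, pop_freqs, Q, labels, clusters)
    return SimPanel(geno, layout, pheno, popmap, truth)


def write_panel(panel: SimPanel, outdir: str) -> Dict[str, str]:
    """Write a panel in the plain-text formats the readers consume."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "panel.vcf"),
        "pheno": os.path.join(outdir, "pheno.csv"),
        "popmap": os.path.join(outdir, "popmap.csv"),
        "layout": os.path.join(outdir, "layout.json"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_vcf(paths["vcf"], panel.genotypes, panel.layout)
    panel.phenotypes.to_csv(paths["pheno"])
    panel.popmap.to_frame().to_csv(paths["popmap"])
    with open(paths["layout"], "w") as fh:
        json.dump(panel.layout.to_dict(), fh, sort_keys=True, indent=1)
    with open(paths["truth"], "w") as fh:
        fh.write(panel.truth.to_json())
    return paths


def fixture_suite(outdir: str, seed: int = 313) -> Dict[str, str]:
    """Small deterministic test panel with planted, detectable features.

    24 accessions x 600 SNPs on 2 chromosomes with: two exact duplicate
    accession pairs, two extreme phenotype outliers, one site failing each
    hard-filter rule, one duplicated (r^2 = 1) site column and a handful of
    low-MAF sites.  Re-running with the same seed is byte-identical.
    """
    config = SimulationConfig(
        n_accessions=24,
        pop_sizes={"DDB": 6, "DDN": 6, "DXB": 6, "YJZY": 6},
        n_snps=600,
        n_chromosomes=2,
        chrom_lengths={"chr1": 300_000, "chr2": 300_000},
        fst=0.08,
        admixture_alpha=0.05,
        missing_rate=0.02,
        n_trait_clusters=4,
        seed=seed,
    )
    panel = simulate_panel(config)
    dos = panel.genotypes.dosages
    # duplicate accession pairs: rows 1:=0 and 13:=12
    dos[1] = dos[0]
    dos[13] = dos[12]
    panel.phenotypes.iloc[1] = panel.phenotypes.iloc[0]
    panel.phenotypes.iloc[13] = panel.phenotypes.iloc[12]
    # phenotype outliers: scaled extremes on the last two accessions
    panel.phenotypes.iloc[-1] = (panel.phenotypes.max(axis=0) * 1.5).round(2)
    panel.phenotypes.iloc[-2] = (panel.phenotypes.min(axis=0) * 0.5).round(2)
    # one site failing each hard-filter rule, at sites 10..16
    for offset, (col, bad_value) in enumerate(_FAIL_VALUES.values()):
        panel.genotypes.sites.loc[10 + offset, col] = bad_value
    # a perfect-LD pair: site 31 duplicates site 30
    dos[:, 31] = dos[:, 30]
    # low-MAF sites below the default 0.1 cutoff: one ALT allele at sites 40-44
    # (carried by accession 5, clear of the duplicate pairs at 0/1 and 12/13)
    for j in range(40, 45):
        dos[:, j] = 0.0
        dos[5, j] = 1.0
    return write_panel(panel, outdir)
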