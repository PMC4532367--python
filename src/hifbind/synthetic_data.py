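"""Synthetic fixtures with the statistical structure the analysis assumes.

Every stage of the pipeline can be exercised without any external download:
two partially overlapping binding-site sets with an enforced fold gap,
co-factor signal with tunable coupling, motif planting whose rate varies
with co-factor rank, negative-binomial expression coupled to binding, and a
patient cohort whose expression and survival share a latent prognostic
factor.  All outputs are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GENE_CLASSES,
    GeneRecord,
    GenomicInterval,
    write_bed,
    write_fasta,
    write_gene_table,
)
from .peak_quant import SignalMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "SimulatedBinding",
    "simulate_annotation",
    "simulate_binding",
    "simulate_counts",
    "simulate_cohort",
    "write_simulation",
]

CONDITIONS = ("H1A", "H2A", "H1B_ctrl", "H1B_exp")
LABEL_ISOFORM1 = "isoform1_specific"
LABEL_ISOFORM2 = "isoform2_specific"
LABEL_SHARED = "shared"

AP1_CONSENSUS = "TGACTCA"
HRE_CORES = ("ACGTG", "GCGTG")  # RCGTG

SITE_HALF_WIDTH = 150  # summit flank scanned for motifs


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 300
    class_proportions: dict = field(
        default_factory=lambda: {
            "protein_coding": 0.68, "lncRNA": 0.17, "antisense": 0.10, "other": 0.05,
        }
    )
    n_sites_isoform1: int = 60
    n_sites_isoform2: int = 60
    n_sites_shared: int = 30
    signal_lognormal_params: dict = field(
        default_factory=lambda: {
            "H1A": (2.5, 0.8), "H2A": (2.5, 0.8),
            "H1B_ctrl": (1.5, 0.6), "H1B_exp": (2.5, 1.0),
        }
    )
    hif1b_coupling: float = 0.8
    motif_plant_rate: tuple = (0.1, 0.8)  # (base rate, slope over rank range)
    n_patients: int = 200
    latent_effect: float = 1.0
    censoring_rate: float = 0.3
    de_fraction: float = 0.8
    de_lfc_scale: float = 1.0
    chrom: str = "chrV"
    chrom_length: int = 3_000_000

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_proportions sum to {total}, expected 1")
        unknown = set(self.class_proportions) - set(GENE_CLASSES)
        if unknown:
            raise ConfigError(f"unknown gene class(es) {unknown}")
        for name in ("n_genes", "n_patients"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("n_sites_isoform1", "n_sites_isoform2", "n_sites_shared"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ConfigError(f"censoring_rate must be in [0,1), got {self.censoring_rate}")
        if not 0.0 <= self.hif1b_coupling <= 1.0:
            raise ConfigError(f"hif1b_coupling must be in [0,1], got {self.hif1b_coupling}")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError(f"de_fraction must be in [0,1], got {self.de_fraction}")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "motif_plant_rate" in raw:
            raw["motif_plant_rate"] = tuple(raw["motif_plant_rate"])
        if "signal_lognormal_params" in raw:
            raw["signal_lognormal_params"] = {
                k: tuple(v) for k, v in raw["signal_lognormal_params"].items()
            }
        return cls(**raw)


@dataclass
class SimulatedBinding:
    peaks_caller_a: list
    peaks_caller_b: list
    signal: SignalMatrix
    sequences: dict
    truth: pd.DataFrame  # site name, label, H1B rank, planted motifs


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # separate stream per stage so stages stay deterministic independently
    return np.random.default_rng([config.seed, stage])


def simulate_annotation(config: SimulationConfig) -> list[GeneRecord]:
    """Genes with non-overlapping TSS on one virtual chromosome."""
    rng = _rng(config, 1)
    # spacing chosen so summit-anchored sites (+/-260 bp offsets, +/-150 bp
    # flanks, <=60 bp caller jitter) can never overlap between genes
    spacing = 1200
    grid = np.arange(5_000, config.chrom_length - 5_000, spacing)
    if config.n_genes > grid.size:
        raise ConfigError(
            f"n_genes={config.n_genes} exceeds {grid.size} available TSS positions"
        )
    positions = np.sort(rng.choice(grid, size=config.n_genes, replace=False))
    classes = list(config.class_proportions)
    probs = np.asarray([config.class_proportions[c] for c in classes])
    labels = rng.choice(classes, size=config.n_genes, p=probs)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    width = len(str(config.n_genes))
    return [
        GeneRecord(f"gene_{i:0{width}d}", int(pos), str(strand), config.chrom, str(cls))
        for i, (pos, cls, strand) in enumerate(zip(positions, labels, strands))
    ]


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


_IDX2BASE = np.array(list("ACGT"))


def _plant(seq: np.ndarray, motif: str, rng: np.random.Generator) -> int:
    """Plant a motif (random strand) at a random offset; returns the offset."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if rng.random() < 0.5:
        motif = "".join(comp[b] for b in reversed(motif))
    offset = int(rng.integers(0, seq.size - len(motif) + 1))
    for i, b in enumerate(motif):
        seq[offset + i] = "ACGT".index(b)
    return offset


def simulate_binding(
    config: SimulationConfig, annotation: Sequence[GeneRecord]
) -> SimulatedBinding:
    """Two jittered caller outputs, a signal matrix over the four conditions,
    and peak sequences with rank-dependent motif planting.

    Isoform-specific sites carry an enforced pseudocounted fold gap
    (strictly > 3) between the two isoform conditions; shared sites stay
    strictly within 3-fold.  Co-factor (H1B_exp) signal at isoform-1 sites
    is coupled to the isoform-1 signal on the log scale with correlation
    ``hif1b_coupling``.  The RCGTG core is planted with probability
    increasing with H1B rank, the AP-1 consensus (isoform-2 sites only) with
    probability increasing as H1B rank falls.
    """
    if not annotation:
        raise ConfigError("annotation is empty")
    rng = _rng(config, 2)
    n1, n2, ns = config.n_sites_isoform1, config.n_sites_isoform2, config.n_sites_shared
    n_sites = n1 + n2 + ns
    if n_sites == 0:
        empty = SignalMatrix([], list(CONDITIONS), np.zeros((0, len(CONDITIONS))))
        return SimulatedBinding([], [], empty, {}, pd.DataFrame(
            columns=["site", "label", "h1b_rank", "hre_planted", "ap1_planted"]))
    if n_sites > len(annotation):
        raise ConfigError(f"{n_sites} sites but only {len(annotation)} genes to anchor them")

    labels = [LABEL_ISOFORM1] * n1 + [LABEL_ISOFORM2] * n2 + [LABEL_SHARED] * ns
    anchor_idx = rng.choice(len(annotation), size=n_sites, replace=False)
    width = 2 * SITE_HALF_WIDTH + 1

    mu1, sig1 = config.signal_lognormal_params["H1A"]
    mu2, sig2 = config.signal_lognormal_params["H2A"]
    mub_c, sigb_c = config.signal_lognormal_params["H1B_ctrl"]
    mub_e, sigb_e = config.signal_lognormal_params["H1B_exp"]

    v1 = np.empty(n_sites)
    v2 = np.empty(n_sites)
    h1a_z = np.empty(n_sites)  # latent normal driving the dominant signal
    for i, label in enumerate(labels):
        z = rng.standard_normal()
        if label == LABEL_ISOFORM1:
            weak = float(rng.lognormal(mu2 - 1.5, sig2))
            gap = 3.2 + rng.exponential(2.0)
            v2[i] = weak
            v1[i] = (weak + 1.0) * gap - 1.0
            h1a_z[i] = z  # reused below for co-factor coupling
        elif label == LABEL_ISOFORM2:
            weak = float(rng.lognormal(mu1 - 1.5, sig1))
            gap = 3.2 + rng.exponential(2.0)
            v1[i] = weak
            v2[i] = (weak + 1.0) * gap - 1.0
            h1a_z[i] = z
        else:
            base = float(rng.lognormal(mu1, sig1))
            ratio = float(np.exp(rng.uniform(np.log(1 / 2.7), np.log(2.7))))
            v1[i] = base
            v2[i] = max((base + 1.0) / ratio - 1.0, 0.0)
            h1a_z[i] = z

    # co-factor signal: coupled to isoform-1 signal (log1p scale) at
    # isoform-1 sites, independent elsewhere
    rho = config.hif1b_coupling
    h1b_exp = np.empty(n_sites)
    is1 = np.asarray([lab == LABEL_ISOFORM1 for lab in labels])
    if is1.any():
        log_v1 = np.log1p(v1[is1])
        spread = log_v1.std()
        zhat = (log_v1 - log_v1.mean()) / (spread if spread > 0 else 1.0)
        noise = rng.standard_normal(int(is1.sum()))
        h1b_exp[is1] = np.exp(
            mub_e + sigb_e * (rho * zhat + np.sqrt(max(0.0, 1 - rho**2)) * noise)
        )
    other = ~is1
    h1b_exp[other] = rng.lognormal(mub_e - 1.0, sigb_e, size=int(other.sum()))
    h1b_ctrl = rng.lognormal(mub_c, sigb_c, size=n_sites)

    # site coordinates anchored near their gene's TSS, non-overlapping
    sites: list[GenomicInterval] = []
    name_width = len(str(n_sites))
    for i in range(n_sites):
        gene = annotation[int(anchor_idx[i])]
        offset = int(rng.integers(150, 260)) * int(rng.choice([-1, 1]))
        summit = max(SITE_HALF_WIDTH, gene.tss + offset)
        sites.append(
            GenomicInterval(
                config.chrom,
                summit - SITE_HALF_WIDTH,
                summit + SITE_HALF_WIDTH + 1,
                ".",
                SITE_HALF_WIDTH,
                f"site_{i:0{name_width}d}",
            )
        )

    # motif planting driven by H1B rank (rank 0 = strongest co-factor)
    order = np.argsort(-h1b_exp, kind="stable")
    rank = np.empty(n_sites, dtype=int)
    rank[order] = np.arange(n_sites)
    rank_frac = rank / max(1, n_sites - 1)
    base_rate, slope = config.motif_plant_rate
    p_hre = np.clip(base_rate + slope * (1.0 - rank_frac), 0.0, 1.0)
    p_ap1 = np.clip(base_rate + slope * rank_frac, 0.0, 1.0)

    sequences: dict[str, str] = {}
    hre_planted = np.zeros(n_sites, dtype=bool)
    ap1_planted = np.zeros(n_sites, dtype=bool)
    for i, site in enumerate(sites):
        seq = _random_sequence(rng, width)
        if rng.random() < p_hre[i]:
            core = HRE_CORES[int(rng.integers(0, len(HRE_CORES)))]
            _plant(seq, core, rng)
            hre_planted[i] = True
        if labels[i] == LABEL_ISOFORM2 and rng.random() < p_ap1[i]:
            _plant(seq, AP1_CONSENSUS, rng)
            ap1_planted[i] = True
        sequences[site.name] = "".join(_IDX2BASE[seq])

    # two callers emit overlapping but jittered intervals around each site
    peaks_a, peaks_b = [], []
    for site in sites:
        ja0, ja1 = rng.integers(0, 60, size=2)
        jb0, jb1 = rng.integers(0, 60, size=2)
        start_a = max(0, site.start - int(ja0))
        peaks_a.append(
            GenomicInterval(
                site.chrom, start_a, site.end + int(ja1), ".",
                site.summit_position - start_a, site.name,
            )
        )
        peaks_b.append(
            GenomicInterval(
                site.chrom, max(0, site.start - int(jb0)), site.end + int(jb1),
                ".", None, site.name,
            )
        )

    values = np.column_stack([v1, v2, h1b_ctrl, h1b_exp])
    signal = SignalMatrix(list(sites), list(CONDITIONS), values)
    truth = pd.DataFrame(
        {
            "site": [s.name for s in sites],
            "gene": [annotation[int(j)].id for j in anchor_idx],
            "label": labels,
            "h1b_rank": rank,
            "hre_planted": hre_planted,
            "ap1_planted": ap1_planted,
        }
    )
    return SimulatedBinding(peaks_a, peaks_b, signal, sequences, truth)


def simulate_counts(
    config: SimulationConfig,
    annotation: Sequence[GeneRecord],
    bound_genes: Sequence[str],
    n_replicates: int = 3,
    depth: float = 1e6,
) -> tuple[pd.DataFrame, list[str], pd.DataFrame]:
    """Two-condition negative-binomial count matrix with binding-coupled DE.

    Genes in ``bound_genes`` receive a positive log2 fold-change (condition 2
    over condition 1) with probability ``de_fraction``; effect sizes scale
    with ``de_lfc_scale``.  Returns (counts genes x samples, group labels,
    per-gene truth).
    """
    if not annotation:
        raise ConfigError("annotation is empty")
    rng = _rng(config, 3)
    genes = [g.id for g in annotation]
    n = len(genes)
    bound = set(bound_genes)
    base_mean = rng.lognormal(4.0, 1.2, size=n)
    base_mean *= depth / 1e6
    dispersion = rng.lognormal(np.log(0.1), 0.3, size=n)
    lfc = np.zeros(n)
    for i, g in enumerate(genes):
        if g in bound and config.de_lfc_scale > 0 and rng.random() < config.de_fraction:
            lfc[i] = config.de_lfc_scale * (0.5 + rng.exponential(0.5))
    groups = ["ctrl"] * n_replicates + ["expt"] * n_replicates
    mu = np.column_stack(
        [np.repeat(base_mean[:, None], n_replicates, axis=1),
         np.repeat((base_mean * 2.0**lfc)[:, None], n_replicates, axis=1)]
    )
    r = 1.0 / dispersion[:, None]
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    samples = [f"{g}_{i+1}" for g in ("ctrl", "expt") for i in range(n_replicates)]
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    truth = pd.DataFrame({"gene": genes, "lfc": lfc, "dispersion": dispersion,
                          "base_mean": base_mean})
    return counts_df, groups, truth


def simulate_cohort(
    config: SimulationConfig, predictor_genes: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cohort whose expression and survival share one latent factor.

    Each listed gene's expression is loading * z + noise for a per-patient
    latent factor z ~ N(0,1); survival is exponential with hazard
    proportional to exp(latent_effect * z); censoring is independent with
    the configured rate; the clinical fields are drawn so the 0-4 risk score
    correlates with z.  Returns (expression patients x genes, clinical
    table, gene truth with loadings).
    """
    genes = list(predictor_genes)
    if not genes:
        raise ConfigError("predictor gene list is empty")
    if config.n_patients < 3:
        raise ConfigError(f"n_patients must be >= 3, got {config.n_patients}")
    rng = _rng(config, 4)
    n = config.n_patients
    z = rng.standard_normal(n)
    loadings = rng.uniform(0.5, 1.0, size=len(genes)) * rng.choice([-1.0, 1.0],
                                                                   size=len(genes))
    noise = rng.standard_normal((n, len(genes))) * 0.6
    expr = z[:, None] * loadings[None, :] + noise
    expr_df = pd.DataFrame(expr, columns=genes,
                           index=[f"pt_{i:04d}" for i in range(n)])

    baseline_hazard = np.log(2) / 1000.0  # median survival ~1000 days at z=0
    hazard = baseline_hazard * np.exp(config.latent_effect * z)
    survival = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < config.censoring_rate
    time = np.where(censored, survival * rng.uniform(0.1, 1.0, size=n), survival)
    time = np.maximum(time, 1e-3)
    event = ~censored

    sigmoid = lambda v: 1.0 / (1.0 + np.exp(-v))
    age = np.clip(60 + 8 * z + rng.normal(0, 8, size=n), 30, 95)
    stage = 1 + rng.binomial(3, sigmoid(0.8 * z))
    metastasis = rng.random(n) < sigmoid(z - 1.0)
    deceased = event  # registry snapshot: death observed within follow-up

    clinical = pd.DataFrame(
        {
            "id": expr_df.index,
            "age": age,
            "stage": stage,
            "metastasis": metastasis,
            "deceased": deceased,
            "time": time,
            "event": event,
            "latent": z,
        }
    )
    truth = pd.DataFrame({"gene": genes, "loading": loadings})
    return expr_df, clinical, truth


def write_simulation(config: SimulationConfig, outdir: str | Path) -> dict:
    """Run every stage and write plain-text outputs plus a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = simulate_annotation(config)
    binding = simulate_binding(config, annotation)
    bound_genes = binding.truth.loc[
        binding.truth["label"] == LABEL_ISOFORM1, "gene"
    ].tolist()
    counts, groups, counts_truth = simulate_counts(config, annotation, bound_genes)
    expr, clinical, cohort_truth = simulate_cohort(
        config, bound_genes or [g.id for g in annotation[:20]]
    )

    write_gene_table(outdir / "genes.tsv", annotation)
    write_bed(outdir / "peaks_caller_a.bed", binding.peaks_caller_a)
    write_bed(outdir / "peaks_caller_b.bed", binding.peaks_caller_b)
    binding.signal.to_tsv(outdir / "signal.tsv")
    write_fasta(outdir / "peaks.fa", binding.sequences)
    binding.truth.to_csv(outdir / "binding_truth.tsv", sep="\t", index=False)
    counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene")
    pd.DataFrame({"sample": counts.columns, "group": groups}).to_csv(
        outdir / "groups.tsv", sep="\t", index=False
    )
    expr.to_csv(outdir / "expression.tsv", sep="\t", index_label="id")
    clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)

    manifest = {
        "config": _config_to_jsonable(config),
        "files": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
        "n_genes": len(annotation),
        "n_sites": len(binding.signal.regions),
        "n_patients": config.n_patients,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _config_to_jsonable(config: SimulationConfig) -> dict:
    raw = asdict(config)
    raw["motif_plant_rate"] = list(raw["motif_plant_rate"])
    raw["signal_lognormal_params"] = {
        k: list(v) for k, v in raw["signal_lognormal_params"].items()
    }
    return raw
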