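"""Synthetic tumor/normal expression studies with planted ground truth.

Emulates the data regime the cross-talk pipeline targets — RNA-seq style
negative-binomial counts for mRNAs and miRNAs, a GMT pathway collection,
and binary phenotype labels — while planting a recoverable signal at every
stage:

* a set of DE genes whose tumor/normal mean ratio is ``2**planted_logfc``;
* enriched pathways that draw roughly half their members from the DE set;
* cross-talk pathway pairs whose member genes are coherently co-shifted in
  tumor samples, separating the pair's Discriminating Score distribution
  between classes without making every member gene DE on its own;
* miRNA regulators whose profiles depend on their targets through a
  Gaussian copula (anti-correlated by default) mapped to NB marginals.

Counts use the mean-dispersion NB parameterization (variance =
mu + phi mu^2) with a single common dispersion, the regime the common-
dispersion exact test assumes; baseline means are log-normal to emulate
sequencing dynamic range.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import nbinom, norm, poisson

from .pea import PathwayCollection

#: fraction of an enriched pathway's members drawn from the planted DE genes
_DE_MEMBER_FRACTION = 0.6


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study generator.

    ``crosstalk_shift`` is the additive log2 shift planted on the
    non-overlap member genes of one pathway of each cross-talk pair in
    tumor samples; the default 0.8 sits below the DE logFC cut of 1 so the
    pair signal is carried by the pathway mean, not by new DE genes.
    """

    n_tumor: int = 30
    n_normal: int = 30
    n_genes: int = 1000
    n_mirnas: int = 30
    n_pathways: int = 10
    pathway_size_range: tuple[int, int] = (10, 25)
    overlap_fraction: float = 0.2
    n_de_genes: int = 100
    planted_logfc: float = 2.0
    nb_dispersion: float = 0.1
    n_crosstalk_pairs: int = 2
    regulon_size: int = 10
    regulon_strength: float = 0.8
    regulon_sign: int = -1
    crosstalk_shift: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.pathway_size_range
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValueError("need at least 2 samples per class")
        if not 0 <= self.n_de_genes <= self.n_genes:
            raise ValueError("n_de_genes must be in [0, n_genes]")
        if lo < 2 or lo > hi:
            raise ValueError("pathway_size_range must satisfy 2 <= lo <= hi")
        if hi > self.n_genes:
            raise ValueError("pathway sizes exceed gene count")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not 0.0 < self.regulon_strength < 1.0:
            raise ValueError("regulon_strength must be in (0, 1)")
        if self.regulon_sign not in (-1, 1):
            raise ValueError("regulon_sign must be -1 or +1")
        if 2 * self.n_crosstalk_pairs > self.n_pathways:
            raise ValueError("need 2 pathways per cross-talk pair")
        if self.n_crosstalk_pairs > self.n_mirnas:
            raise ValueError("need one miRNA per cross-talk pair")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be nonnegative")
        if self.regulon_size < 1:
            raise ValueError("regulon_size must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Planted signal of a synthetic study, for downstream recovery checks."""

    de_genes: frozenset[str]
    de_mirnas: frozenset[str]
    enriched_pathways: frozenset[str]
    crosstalk_pairs: frozenset[tuple[str, str]]
    regulons: dict[str, frozenset[str]]

    def to_dict(self) -> dict:
        return {
            "de_genes": sorted(self.de_genes),
            "de_mirnas": sorted(self.de_mirnas),
            "enriched_pathways": sorted(self.enriched_pathways),
            "crosstalk_pairs": sorted(list(p) for p in self.crosstalk_pairs),
            "regulons": {m: sorted(g) for m, g in sorted(self.regulons.items())},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            de_genes=frozenset(d["de_genes"]),
            de_mirnas=frozenset(d["de_mirnas"]),
            enriched_pathways=frozenset(d["enriched_pathways"]),
            crosstalk_pairs=frozenset(tuple(sorted(p)) for p in d["crosstalk_pairs"]),
            regulons={m: frozenset(g) for m, g in d["regulons"].items()},
        )


@dataclass
class Study:
    """One synthetic study: matrices, labels, pathways and planted truth."""

    mrna: pd.DataFrame
    mirna: pd.DataFrame
    labels: pd.Series
    pathways: PathwayCollection
    truth: GroundTruth
    config: SimulationConfig


def _nb_counts(mean: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    """NB(mean, dispersion) draws via the gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def _nb_ppf(u: np.ndarray, mean: np.ndarray, phi: float) -> np.ndarray:
    """Quantile map to NB marginals (Poisson when phi -> 0)."""
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    if phi <= 0:
        return poisson.ppf(u, mean).astype(np.int64)
    r = 1.0 / phi
    p = r / (r + mean)
    return nbinom.ppf(u, r, p).astype(np.int64)


def _build_pathways(cfg: SimulationConfig, genes: np.ndarray,
                    de_genes: list[str], rng: np.random.Generator):
    """Member lists for enriched (paired) and background pathways."""
    lo, hi = cfg.pathway_size_range
    non_de = [g for g in genes if g not in set(de_genes)]
    members: list[list[str]] = []
    pair_index: list[tuple[int, int]] = []

    def _mixed_sample(size: int, exclude: set[str]) -> list[str]:
        n_de = min(max(2, round(_DE_MEMBER_FRACTION * size)), len(de_genes), size)
        pool_de = [g for g in de_genes if g not in exclude]
        pool_bg = [g for g in non_de if g not in exclude]
        n_de = min(n_de, len(pool_de))
        chosen = list(rng.choice(pool_de, size=n_de, replace=False)) if n_de else []
        n_bg = min(size - n_de, len(pool_bg))
        chosen += list(rng.choice(pool_bg, size=n_bg, replace=False))
        return chosen

    for i in range(cfg.n_crosstalk_pairs):
        size_a = int(rng.integers(lo, hi + 1))
        size_b = int(rng.integers(lo, hi + 1))
        set_a = _mixed_sample(size_a, exclude=set())
        n_overlap = int(round(cfg.overlap_fraction * min(size_a, size_b)))
        n_overlap = min(n_overlap, size_b - 2, len(set_a))
        overlap = (list(rng.choice(set_a, size=n_overlap, replace=False))
                   if n_overlap > 0 else [])
        set_b = overlap + _mixed_sample(size_b - len(overlap), exclude=set(set_a))
        pair_index.append((len(members), len(members) + 1))
        members.append(set_a)
        members.append(set_b)

    for _ in range(cfg.n_pathways - 2 * cfg.n_crosstalk_pairs):
        size = int(rng.integers(lo, hi + 1))
        members.append(list(rng.choice(genes, size=size, replace=False)))
    return members, pair_index


def generate_study(config: SimulationConfig) -> Study:
    """Generate a full synthetic study; identical seeds give identical output."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    genes = np.array([f"G{i + 1:05d}" for i in range(cfg.n_genes)])
    mirnas = np.array([f"mir{i + 1:04d}" for i in range(cfg.n_mirnas)])
    samples = ([f"T{i + 1:03d}" for i in range(cfg.n_tumor)]
               + [f"N{i + 1:03d}" for i in range(cfg.n_normal)])
    labels = pd.Series(["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal,
                       index=samples, name="phenotype")

    # gene means: log-normal baseline; DE genes shifted in tumor, alternating sign
    base = rng.lognormal(mean=math.log(100.0), sigma=1.0, size=cfg.n_genes)
    de_idx = rng.choice(cfg.n_genes, size=cfg.n_de_genes, replace=False)
    de_genes = [genes[i] for i in sorted(de_idx)]
    tumor_mean = base.copy()
    for rank, i in enumerate(sorted(de_idx)):
        sign = 1.0 if rank % 2 == 0 else -1.0
        tumor_mean[i] = base[i] * 2.0 ** (sign * cfg.planted_logfc)

    members, pair_index = _build_pathways(cfg, genes, de_genes, rng)

    # cross-talk planting: coherent sub-DE up-shift of the first pathway's
    # non-overlap genes in tumor samples
    gene_pos = {g: i for i, g in enumerate(genes)}
    shifted: set[str] = set()
    for a_idx, b_idx in pair_index:
        non_overlap = [g for g in members[a_idx] if g not in set(members[b_idx])]
        for g in non_overlap:
            if g not in shifted:
                tumor_mean[gene_pos[g]] *= 2.0 ** cfg.crosstalk_shift
                shifted.add(g)

    # pathway names assigned in a shuffled order so plantedness is not positional
    order = rng.permutation(len(members))
    names = [""] * len(members)
    for pos, orig in enumerate(order):
        names[orig] = f"PW{pos + 1:03d}"
    pathway_sets = {names[i]: frozenset(members[i]) for i in range(len(members))}
    enriched = frozenset(names[i] for pair in pair_index for i in pair)
    crosstalk_pairs = frozenset(tuple(sorted((names[a], names[b])))
                                for a, b in pair_index)

    mrna = np.empty((cfg.n_genes, len(samples)), dtype=np.int64)
    mrna[:, :cfg.n_tumor] = np.column_stack([
        _nb_counts(tumor_mean, cfg.nb_dispersion, rng) for _ in range(cfg.n_tumor)])
    mrna[:, cfg.n_tumor:] = np.column_stack([
        _nb_counts(base, cfg.nb_dispersion, rng) for _ in range(cfg.n_normal)])
    mrna_df = pd.DataFrame(mrna, index=genes, columns=samples)
    mrna_df.index.name = "gene_id"

    # miRNAs: planted regulators are DE (up in tumor) and tied to their
    # targets through a Gaussian copula on a shared latent factor.  Target
    # genes load +sqrt(strength) on the factor and the miRNA loads
    # regulon_sign*sqrt(strength), so every miRNA-target pair has latent
    # correlation of magnitude regulon_strength; latent values are mapped
    # to the genes' and miRNA's own NB marginals (class means preserved).
    # Narrower dynamic range than mRNA: with total-count normalization a
    # single very abundant planted miRNA would otherwise distort libraries.
    mir_base = rng.lognormal(mean=math.log(50.0), sigma=0.7, size=cfg.n_mirnas)
    regulator_ids = [str(m) for m in mirnas[:cfg.n_crosstalk_pairs]]
    regulons: dict[str, frozenset[str]] = {}
    mirna_mat = np.empty((cfg.n_mirnas, len(samples)), dtype=np.int64)
    n_samp = len(samples)
    is_tumor = np.arange(n_samp) < cfg.n_tumor
    load = math.sqrt(cfg.regulon_strength)
    resid = math.sqrt(1.0 - cfg.regulon_strength)

    for j in range(cfg.n_mirnas):
        mu_t = mu_n = mir_base[j]
        if j < cfg.n_crosstalk_pairs:
            mu_t = mir_base[j] * 2.0 ** cfg.planted_logfc
            a_idx, b_idx = pair_index[j]
            half = (cfg.regulon_size + 1) // 2
            pool_a = list(members[a_idx])
            pool_b = [g for g in members[b_idx] if g not in set(members[a_idx])]
            t_a = list(rng.choice(pool_a, size=min(half, len(pool_a)), replace=False))
            n_b = min(cfg.regulon_size - len(t_a), len(pool_b))
            t_b = list(rng.choice(pool_b, size=n_b, replace=False))
            targets = t_a + t_b
            regulons[regulator_ids[j]] = frozenset(targets)

            h = rng.standard_normal(n_samp)
            for g in targets:
                gi = gene_pos[g]
                zg = load * h + resid * rng.standard_normal(n_samp)
                mu_g = np.where(is_tumor, tumor_mean[gi], base[gi])
                mrna_df.iloc[gi] = _nb_ppf(norm.cdf(zg), mu_g, cfg.nb_dispersion)
            zm = (cfg.regulon_sign * load * h
                  + resid * rng.standard_normal(n_samp))
            mu = np.where(is_tumor, mu_t, mu_n)
            mirna_mat[j] = _nb_ppf(norm.cdf(zm), mu, cfg.nb_dispersion)
        else:
            mirna_mat[j] = _nb_counts(np.full(n_samp, mu_n), cfg.nb_dispersion, rng)
    mirna_df = pd.DataFrame(mirna_mat, index=mirnas, columns=samples)
    mirna_df.index.name = "mirna_id"

    planted_de = cfg.planted_logfc != 0
    truth = GroundTruth(
        de_genes=frozenset(de_genes) if planted_de else frozenset(),
        de_mirnas=frozenset(regulator_ids) if planted_de else frozenset(),
        enriched_pathways=enriched,
        crosstalk_pairs=crosstalk_pairs,
        regulons=regulons,
    )
    collection = PathwayCollection(sets=pathway_sets)
    return Study(mrna=mrna_df, mirna=mirna_df, labels=labels,
                 pathways=collection, truth=truth, config=cfg)


def write_fixtures(study: Study, outdir) -> dict[str, Path]:
    """Write a study to disk as TSV/GMT/JSON fixtures; returns the paths."""
    from . import io as cio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mrna": outdir / "mrna.tsv",
        "mirna": outdir / "mirna.tsv",
        "labels": outdir / "labels.tsv",
        "gmt": outdir / "pathways.gmt",
        "truth": outdir / "ground_truth.json",
        "config": outdir / "sim_config.json",
    }
    try:
        cio.write_expression(study.mrna, paths["mrna"])
        cio.write_expression(study.mirna, paths["mirna"])
        cio.write_labels(study.labels, paths["labels"])
        cio.write_gmt(study.pathways, paths["gmt"])
        paths["truth"].write_text(
            json.dumps(study.truth.to_dict(), indent=1) + "\n")
        cfg = asdict(study.config)
        cfg["pathway_size_range"] = list(cfg["pathway_size_range"])
        paths["config"].write_text(json.dumps(cfg, indent=1) + "\n")
    except OSError as exc:
        raise OSError(f"writing fixtures under {outdir}: {exc}") from exc
    return paths
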