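"""End-to-end orchestration: DEA -> PEA -> DS -> selection -> regulons.

Every randomized stage draws from explicit seeds carried in the
configuration, all intermediate artifacts are written to the output
directory, and a manifest records parameters, seeds, per-stage counts and
the SHA-256 of every file, so a rerun with the same configuration and seed
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .crosstalk import ds_matrix, euclidean_crosstalk, pathway_activity
from .dea import call_de, nb_exact_test, quantile_filter
from .pea import enrich_all
from .regulon import (build_regulon, delta_table, mi_matrix, mra_pair,
                      permutation_null)
from .selection import run_mccv

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and stage parameters of one pipeline run.

    Defaults follow the published protocol: quantile filter q=0.25, DE at
    |logFC| > 1 and FDR < 0.01, enrichment at FDR < 0.01, 50 bootstraps of
    60/40 MCCV, 10-fold CV, 500 trees, KSG k=3.
    """

    mrna_path: str
    labels_path: str
    gmt_path: str
    out_dir: str
    mirna_path: str | None = None
    q: float = 0.25
    logfc_cut: float = 1.0
    fdr_cut: float = 0.01
    alpha_pea: float = 0.01
    min_pathway_size: int = 5
    metric: str = "ds"
    n_bootstraps: int = 50
    train_frac: float = 0.6
    k_folds: int = 10
    ntree: int = 500
    top_n: int = 10
    full_per_bootstrap: bool = True
    mi_k: int = 3
    regulon_rule: str = "permutation_fdr"
    regulon_alpha: float = 0.05
    regulon_top_k: int | None = None
    n_permutations: int = 5
    mra_alpha: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        for attr in ("mrna_path", "labels_path", "gmt_path"):
            p = getattr(self, attr)
            if not Path(p).is_file():
                raise ValueError(f"config: {attr} does not exist: {p}")
        if self.mirna_path is not None and not Path(self.mirna_path).is_file():
            raise ValueError(f"config: mirna_path does not exist: {self.mirna_path}")
        if not 0 < self.q < 1:
            raise ValueError("config: q must be in (0, 1)")
        if not 0 < self.train_frac < 1:
            raise ValueError("config: train_frac must be in (0, 1)")
        if self.metric not in ("ds", "euclidean"):
            raise ValueError("config: metric must be 'ds' or 'euclidean'")
        for attr in ("n_bootstraps", "k_folds", "ntree", "top_n", "mi_k"):
            if getattr(self, attr) < 1:
                raise ValueError(f"config: {attr} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _equalize_to(counts: pd.DataFrame, target: float) -> pd.DataFrame:
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    return counts * (target / lib)


def _geomean_libsize(counts: pd.DataFrame) -> float:
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    return math.exp(float(np.mean(np.log(lib))))


def _ds_features(expr_norm: pd.DataFrame, collection, metric: str) -> pd.DataFrame:
    activity = pathway_activity(expr_norm, collection)
    return ds_matrix(activity) if metric == "ds" else euclidean_crosstalk(activity)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages, write artifacts and the manifest; return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
    }

    def _save(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def _stage(name: str):
        logger.info("=== stage %s ===", name)
        return name

    # ---- load inputs -----------------------------------------------------
    stage = _stage("load")
    try:
        mrna = cio.read_expression(config.mrna_path)
        labels = cio.read_labels(config.labels_path)
        collection = cio.read_gmt(config.gmt_path)
        mirna = (cio.read_expression(config.mirna_path)
                 if config.mirna_path else None)
        labels = labels.loc[[s for s in mrna.columns if s in labels.index]]
        if len(labels) != mrna.shape[1]:
            raise ValueError("labels missing for some mRNA samples")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"][stage] = {
        "n_genes": int(mrna.shape[0]), "n_samples": int(mrna.shape[1]),
        "n_pathways": len(collection),
        "n_mirnas": int(mirna.shape[0]) if mirna is not None else 0,
    }

    # ---- step 1: DEA -----------------------------------------------------
    stage = _stage("dea")
    try:
        mrna_f = quantile_filter(mrna, config.q)
        dea_mrna = nb_exact_test(mrna_f, labels)
        degs = call_de(dea_mrna, config.logfc_cut, config.fdr_cut)
        dea_mrna.to_csv(out / "dea_mrna.tsv", sep="\t")
        _save("dea_mrna", out / "dea_mrna.tsv")
        dea_mirna, de_mirnas = None, set()
        if mirna is not None:
            mirna_labels = labels.loc[[s for s in mirna.columns
                                       if s in labels.index]]
            mirna_f = quantile_filter(mirna[mirna_labels.index], config.q)
            dea_mirna = nb_exact_test(mirna_f, mirna_labels)
            de_mirnas = call_de(dea_mirna, config.logfc_cut, config.fdr_cut)
            dea_mirna.to_csv(out / "dea_mirna.tsv", sep="\t")
            _save("dea_mirna", out / "dea_mirna.tsv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"][stage] = {
        "n_genes_filtered": int(mrna_f.shape[0]), "n_degs": len(degs),
        "n_de_mirnas": len(de_mirnas),
    }

    # ---- step 2: PEA -----------------------------------------------------
    stage = _stage("pea")
    try:
        universe = frozenset(mrna_f.index)
        restricted = collection.restrict(universe, config.min_pathway_size)
        enr = enrich_all(degs, restricted, alpha=config.alpha_pea)
        enr.to_csv(out / "pea.tsv", sep="\t", index=False)
        _save("pea", out / "pea.tsv")
        significant = list(enr.loc[enr["significant"], "pathway"])
        if len(significant) < 2:
            raise ValueError(
                f"only {len(significant)} enriched pathways; need >=2 for pairs")
        enriched = restricted.__class__(
            sets={n: restricted.sets[n] for n in significant},
            universe=restricted.universe)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"][stage] = {
        "n_pathways_restricted": len(restricted),
        "n_enriched": len(significant),
    }

    # ---- steps 3-4: DS matrix -------------------------------------------
    stage = _stage("ds")
    try:
        target = _geomean_libsize(mrna_f)
        mrna_norm = _equalize_to(mrna_f, target)
        ds = _ds_features(mrna_norm, enriched, config.metric)
        cio.write_ds_matrix(ds, out / "ds.tsv")
        _save("ds", out / "ds.tsv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"][stage] = {"n_pairs": int(ds.shape[1])}

    # ---- step 5: MCCV selection -----------------------------------------
    stage = _stage("selection")
    try:
        builder = None
        if config.full_per_bootstrap:
            def builder(train, test, seed):  # noqa: F811 - intentional closure
                sub = mrna[train]
                sub_f = quantile_filter(sub, config.q)
                res = nb_exact_test(sub_f, labels.loc[train])
                b_degs = call_de(res, config.logfc_cut, config.fdr_cut)
                b_restricted = collection.restrict(frozenset(sub_f.index),
                                                   config.min_pathway_size)
                b_enr = enrich_all(b_degs, b_restricted, alpha=config.alpha_pea)
                names = list(b_enr.loc[b_enr["significant"], "pathway"])
                if len(names) < 2:
                    # too little training signal: fall back to the two
                    # best-ranked pathways so the bootstrap stays comparable
                    logger.warning("bootstrap: <2 enriched pathways, using "
                                   "the 2 best-ranked")
                    names = list(b_enr["pathway"][:2])
                b_sets = b_restricted.__class__(
                    sets={n: b_restricted.sets[n] for n in names},
                    universe=b_restricted.universe)
                b_target = _geomean_libsize(sub_f)
                norm_all = _equalize_to(mrna.loc[sub_f.index], b_target)
                feats = _ds_features(norm_all, b_sets, config.metric)
                return feats.loc[train], feats.loc[test]

        boots, agg = run_mccv(
            ds, labels, n_bootstraps=config.n_bootstraps,
            train_frac=config.train_frac, k=config.k_folds, ntree=config.ntree,
            top_n=config.top_n, seed=config.seed, feature_builder=builder,
            samples=list(ds.index))
        agg.to_csv(out / "aggregate_ranking.tsv", sep="\t", index=False)
        _save("aggregate_ranking", out / "aggregate_ranking.tsv")
        boot_dump = [{
            "bootstrap_id": b.bootstrap_id,
            "train_samples": b.train_samples, "test_samples": b.test_samples,
            "train_auc": b.train_auc, "top10": b.top10, "test_auc": b.test_auc,
        } for b in boots]
        (out / "bootstraps.json").write_text(
            json.dumps(boot_dump, indent=1, sort_keys=True) + "\n")
        _save("bootstraps", out / "bootstraps.json")
        # binary membership matrix: pair in top10 of bootstrap b
        pairs = sorted({p for b in boots for p in b.top10})
        member = pd.DataFrame(
            [[int(p in b.top10) for b in boots] for p in pairs],
            index=pairs, columns=[f"b{b.bootstrap_id}" for b in boots])
        member.to_csv(out / "top10_membership.tsv", sep="\t", index_label="pair")
        _save("top10_membership", out / "top10_membership.tsv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"][stage] = {
        "n_bootstraps": len(boots),
        "n_pairs_selected": int(len(agg)),
    }

    # ---- step 6: regulons and MRA ---------------------------------------
    stage = _stage("regulon")
    if mirna is not None and len(agg):
        try:
            top_pairs = [tuple(p.split("|")) for p in agg["pair"][:config.top_n]]
            pair_genes = sorted({g for a, b in top_pairs
                                 for g in (enriched.sets.get(a, frozenset())
                                           | enriched.sets.get(b, frozenset()))})
            common = [s for s in mirna_f.columns if s in mrna_norm.columns]
            gene_expr = mrna_norm.loc[[g for g in pair_genes
                                       if g in mrna_norm.index], common]
            mir_expr = mirna_f[common]
            mi = mi_matrix(mir_expr, gene_expr, k=config.mi_k, seed=config.seed)
            mi.to_csv(out / "mi.tsv", sep="\t", index_label="mirna_id")
            _save("mi", out / "mi.tsv")
            null = None
            if config.regulon_rule == "permutation_fdr":
                null = permutation_null(mir_expr, gene_expr, k=config.mi_k,
                                        n_permutations=config.n_permutations,
                                        seed=config.seed + 1)
            regs = build_regulon(mi, rule=config.regulon_rule, null=null,
                                 alpha=config.regulon_alpha,
                                 top_k=config.regulon_top_k)
            (out / "regulons.json").write_text(json.dumps(
                {m: sorted(r.targets) for m, r in sorted(regs.items())},
                indent=1) + "\n")
            _save("regulons", out / "regulons.json")
            mra_frames = []
            for a, b in top_pairs:
                if a in enriched.sets and b in enriched.sets:
                    mra_frames.append(mra_pair(regs, (a, b), enriched,
                                               de_mirnas, alpha=config.mra_alpha))
            mra = (pd.concat(mra_frames, ignore_index=True) if mra_frames
                   else pd.DataFrame())
            mra.to_csv(out / "mra.tsv", sep="\t", index=False)
            _save("mra", out / "mra.tsv")
            delta = delta_table(dea_mirna, sorted(de_mirnas))
            delta.to_csv(out / "delta.tsv", sep="\t", index=False)
            _save("delta", out / "delta.tsv")
            manifest["stages"][stage] = {
                "n_regulon_mirnas": len(regs),
                "n_master_regulators": (int(mra["is_mr"].sum())
                                        if "is_mr" in mra else 0),
            }
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
    else:
        manifest["stages"][stage] = {"skipped": mirna is None}

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    logger.info("pipeline complete: %s", manifest_path)
    return manifest
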