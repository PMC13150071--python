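"""End-to-end orchestration: data -> preprocessing -> differential ->
attention dual filter -> consensus -> diagnostic panel -> evaluation ->
enrichment, with every intermediate written to disk and a JSON manifest
recording the feature funnel, seeds, and timings.

Stages communicate via files (TSV/JSON) so any stage can be re-run
independently; a rerun with the same config reproduces byte-identical
numeric outputs (timings aside).
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attention, consensus, diagnostic, differential, enrich, preprocess, synthdata
from .containers import OmicsMatrix, read_labels_tsv, write_labels_tsv

DEFAULT_SYNTH = {
    "metabolome": dict(n_per_group=40, n_features=500, n_planted=20, effect_shift_sd=1.5),
    "transcriptome": dict(n_per_group=30, n_features=2000, n_planted=30, effect_log2fc=2.0),
}


@dataclasses.dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    split_frac: float = 0.7
    consensus_k: int = 10
    panel_size: int = 5
    modalities: dict = dataclasses.field(default_factory=dict)
    gmt: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def default_synthetic(self) -> "RunConfig":
        if not self.modalities:
            self.modalities = {k: {"synth": dict(v)} for k, v in DEFAULT_SYNTH.items()}
        return self


def _load_or_generate(modality: str, spec: dict, seed: int):
    """Returns (matrix, truth-or-None)."""
    if "matrix" in spec:
        labels = read_labels_tsv(spec["labels"])
        m = OmicsMatrix.from_tsv(spec["matrix"], modality, labels=labels)
        return m, None
    synth_kwargs = dict(DEFAULT_SYNTH[modality])
    synth_kwargs.update(spec.get("synth", {}))
    synth_kwargs.setdefault("seed", seed)
    params = synthdata.SynthOmicsParams(**synth_kwargs)
    if modality == "metabolome":
        return synthdata.generate_metabolome(params)
    return synthdata.generate_transcriptome(params)


def _attention_config(modality: str, spec: dict, seed: int):
    cfg = attention.default_config(modality, seed=seed)
    overrides = spec.get("attention", {})
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}, "funnel": {}, "timings": {}, "notes": []}

    for modality, spec in config.modalities.items():
        t0 = time.time()
        mdir = out / modality
        mdir.mkdir(exist_ok=True)
        fun: dict = {}
        try:
            matrix, truth = _load_or_generate(modality, spec, config.seed)
            fun["input_features"] = matrix.n_features
            fun["n_samples"] = matrix.n_samples
            matrix.to_tsv(mdir / "raw_matrix.tsv")
            write_labels_tsv(matrix.group_labels, mdir / "labels.tsv")
            if truth is not None:
                (mdir / "ground_truth.json").write_text(
                    json.dumps(truth.to_json_dict(), indent=1, sort_keys=True))

            # --- preprocessing -------------------------------------------
            if modality == "metabolome":
                proc, plog = preprocess.preprocess_metabolome(matrix)
                size_factors = None
            else:
                proc, size_factors, plog = preprocess.preprocess_transcriptome(matrix)
            proc.to_tsv(mdir / "preprocessed.tsv")
            (mdir / "preprocess_log.json").write_text(json.dumps(plog, indent=1))
            fun["preprocessed_features"] = proc.n_features

            # --- classical differential ----------------------------------
            dtre = spec.get("differential", {})
            if modality == "metabolome":
                diff = differential.metabolome_differential(
                    proc, vip_min=dtre.get("vip_min", 1.0), p_max=dtre.get("p_max", 0.05))
            else:
                diff = differential.nb_wald_de(
                    proc, size_factors=size_factors,
                    fdr_max=dtre.get("fdr_max", 0.01), fc_min=dtre.get("fc_min", 2.0))
            diff.drop(columns=["feature_id"]).to_csv(mdir / "differential.tsv", sep="\t")
            diff_set = set(diff.index[diff["significant"]])
            fun["differential"] = len(diff_set)

            # --- attention stage ------------------------------------------
            acfg = _attention_config(modality, spec, config.seed)
            report = attention.cross_validate(proc, config=acfg)
            imp = report.feature_importance.sort_values(ascending=False)
            imp_tsv = pd.DataFrame({
                "feature_id": imp.index, "importance": imp.values,
                "rank": np.arange(1, len(imp) + 1),
                "selected": [f in set(report.selected) for f in imp.index],
            })
            imp_tsv.to_csv(mdir / "attention_importance.tsv", sep="\t", index=False)
            report.fold_metrics.to_csv(mdir / "attention_cv_metrics.tsv", sep="\t")
            pd.DataFrame([
                {"fold": i, "epoch": e, "train_loss": h["train_loss"][e],
                 "val_loss": h["val_loss"][e]}
                for i, h in enumerate(report.histories)
                for e in range(len(h["train_loss"]))
            ]).to_csv(mdir / "training_history.csv", index=False)
            fun["attention_top_fraction"] = len(report.selected)

            # --- dual filter ----------------------------------------------
            panel_candidates = attention.dual_filter(
                diff_set, report.selected, universe=proc.feature_ids)
            ordered_candidates = [f for f in imp.index if f in panel_candidates]
            fun["dual_filter"] = len(panel_candidates)
            (mdir / "dual_filter.txt").write_text("\n".join(ordered_candidates) + "\n")

            # --- consensus -------------------------------------------------
            if len(panel_candidates) == 0:
                manifest["notes"].append(f"{modality}: empty dual-filter intersection; "
                                         "consensus and diagnostic stages skipped")
                fun["consensus"] = 0
            else:
                cand = proc.with_values(proc.values.loc[:, ordered_candidates])
                panel = consensus.consensus_panel(cand, k=config.consensus_k, seed=config.seed)
                for name, lst in panel["rankings"].items():
                    (mdir / f"ranking_{name}.txt").write_text("\n".join(lst) + "\n")
                (mdir / "consensus.txt").write_text("\n".join(panel["intersection"]) + "\n")
                fun["consensus"] = len(panel["intersection"])
                bench = consensus.benchmark_models(cand, seed=config.seed)
                bench.to_csv(mdir / "model_benchmark.tsv", sep="\t")

                # --- diagnostic panel -------------------------------------
                final_panel = panel["intersection"][:config.panel_size]
                if final_panel:
                    model, train_ma, test_ma = diagnostic.build_diagnostic(
                        proc, final_panel, train_frac=config.split_frac, seed=config.seed)
                    (mdir / "panel_model.json").write_text(
                        json.dumps(model.to_json_dict(), indent=1, sort_keys=True))
                    metrics = pd.DataFrame({
                        "train": train_ma.to_dict(), "test": test_ma.to_dict()}).T
                    metrics.to_csv(mdir / "panel_metrics.tsv", sep="\t")
                    fun["panel"] = len(final_panel)
                    fun["panel_train_auc"] = round(train_ma.auc, 6)
                    fun["panel_test_auc"] = round(test_ma.auc, 6)
                else:
                    manifest["notes"].append(f"{modality}: empty consensus; diagnostic skipped")

                # --- enrichment -------------------------------------------
                if config.gmt:
                    sets = enrich.read_gmt(config.gmt)
                    sel = panel["intersection"] or ordered_candidates
                    if sel:
                        ora = enrich.hypergeom_ora(set(sel), sets,
                                                   universe=set(proc.feature_ids) | sets.universe)
                        ora.to_csv(mdir / "enrichment.tsv", sep="\t", index=False)
        except Exception as exc:  # persist what we have, then abort
            manifest["stages"][modality] = "failed"
            manifest["funnel"][modality] = fun
            (out / "manifest.json").write_text(_manifest_json(manifest))
            raise RuntimeError(f"stage '{modality}' failed: {exc}") from exc

        manifest["stages"][modality] = "ok"
        manifest["funnel"][modality] = fun
        manifest["timings"][modality] = round(time.time() - t0, 3)

    (out / "manifest.json").write_text(_manifest_json(manifest))
    return manifest


def _manifest_json(manifest: dict) -> str:
    return json.dumps(manifest, indent=1, sort_keys=True, default=str)


def leak_check(m: OmicsMatrix, config=None, n_perm: int = 10,
               threshold: float = 0.6) -> dict:
    """Permuted-label null of the confined CV.

    Permutes the labels ``n_perm`` times (seeded), runs the confined
    cross-validation, and fails if the mean AUC exceeds ``threshold``.
    """
    if config is None:
        config = attention.default_config(m.modality)
    rng = np.random.default_rng(config.seed)
    y = m.binary_labels()
    aucs = []
    for i in range(n_perm):
        yp = rng.permutation(y)
        perm = pd.Series(np.where(yp == 1, "RA_ane", "RA"), index=m.values.index)
        mm = OmicsMatrix(values=m.values, modality=m.modality, group_labels=perm)
        cfg = dataclasses.replace(config, seed=config.seed + 7919 * (i + 1))
        report = attention.cross_validate(mm, config=cfg)
        aucs.append(float(report.fold_metrics["auc"].mean()))
    mean_auc = float(np.mean(aucs))
    return {"per_permutation_auc": aucs, "mean_auc": mean_auc,
            "passed": mean_auc <= threshold}
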