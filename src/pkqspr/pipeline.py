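"""End-to-end workflow orchestration.

Runs the full modeling sequence on a compound set (ingested from SDF/CSV or
synthesized): descriptor conditioning -> PCA chemical-space calibration with
boundary rules and Hotelling outlier removal -> cluster-stratified split ->
PLS2 fit with cross-validated component selection and VIP variable reduction
-> balanced forest with out-of-bag statistics -> applicability domain ->
external validation -> Y-randomization.  Every exclusion and random decision
is logged to an audit trail; re-running with the same configuration
reproduces every number.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from pkqspr import (
    ClassScheme,
    GeneratorConfig,
    assign_joint_class,
    assign_vss_class,
    cross_validate_q2,
    fit_balanced_forest,
    fit_pca,
    fit_pls2,
    generate_qspr_dataset,
    hotelling_outliers,
    impute_missing_fu,
    oob_predictions,
    reduce_variables,
    selection_frequency_importance,
    split_cluster_stratified,
)
from pkqspr.dataset import CompoundSet, attach_descriptors, read_descriptor_table, read_sdf_dataset
from pkqspr.latent import select_n_components
from pkqspr.preprocess import (
    apply_boundary_filter,
    apply_scaler,
    builtin_rules,
    drop_duplicate_descriptors,
    fit_scaler,
    select_log_transform,
)
from pkqspr.validation import (
    ValidationReport,
    confusion_matrix,
    class_sensitivity,
    class_specificity,
    external_q2,
    fold_errors,
    hand_till_auc,
    y_randomization,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run; all randomness derives from ``seed``."""

    sdf_path: str | None = None
    descriptor_csv: str | None = None
    id_column: str = "compound_id"
    vss_field: str = "Vss"
    fu_field: str = "fu"
    boundary_rules: str | None = None  # model1/model2/model3 or None
    test_fraction: float = 0.3
    pca_components: int = 2
    pls_max_components: int = 10
    vip_cutoff: float = 0.8
    n_trees: int = 10
    min_leaf: int = 5
    ad_z: float = 0.7
    fingerprint_bits: int = 1024
    class_scheme_upper_inclusive: bool = False
    n_permutations: int = 20
    synthetic: GeneratorConfig | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None and not isinstance(d["synthetic"], GeneratorConfig):
            d["synthetic"] = GeneratorConfig(**d["synthetic"])
        return cls(**d)


def _load_dataset(cfg: PipelineConfig) -> CompoundSet:
    if cfg.synthetic is not None:
        syn_cfg = cfg.synthetic
        cset, _ = generate_qspr_dataset(syn_cfg)
        return cset
    if cfg.sdf_path is None:
        raise ValueError("either synthetic config or sdf_path is required")
    cset = read_sdf_dataset(cfg.sdf_path, vss_field=cfg.vss_field, fu_field=cfg.fu_field)
    if cfg.descriptor_csv:
        table = read_descriptor_table(cfg.descriptor_csv, id_column=cfg.id_column)
        cset = attach_descriptors(cset, table)
    return cset


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full workflow; writes models/reports under ``out_dir``.

    Returns the report dictionary (also written as ``report.json``).
    """
    cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seeds = np.random.SeedSequence(cfg.seed).generate_state(8) % (2**31)
    audit: list[dict] = []
    current = {"name": "ingest"}

    def stage(name):
        current["name"] = name
        logger.info("stage: %s", name)

    try:
        stage("ingest")
        cset = _load_dataset(cfg)
        audit.append({"stage": "ingest", "n": len(cset)})

        stage("conditioning")
        cset, removed = drop_duplicate_descriptors(cset)
        audit.append({"stage": "duplicates", "removed": removed})
        if cfg.boundary_rules:
            rules = builtin_rules(cfg.boundary_rules)
            cset, excluded = apply_boundary_filter(cset, rules)
            audit.append(
                {"stage": "boundary_filter", "rule_set": rules.name,
                 "excluded": [{"id": cid, "violated": v} for cid, v in excluded]}
            )
        log_flags = select_log_transform(cset)
        scaler = fit_scaler(cset, log_flags=log_flags)
        Xs = apply_scaler(scaler, cset.descriptors)

        stage("pca_calibration")
        n_pca = min(cfg.pca_components, len(cset) - 1, Xs.shape[1])
        pca = fit_pca(Xs, n_pca)
        out_ids = hotelling_outliers(pca, alpha=0.05, ids=cset.ids)
        audit.append({"stage": "pca", "r2x_cum": float(pca.r2x_cum[-1]), "hotelling_outliers": list(out_ids)})
        keep = [i for i, cid in enumerate(cset.ids) if cid not in set(out_ids)]
        cset = cset.subset(keep)

        stage("impute_and_split")
        cset = impute_missing_fu(cset)
        train, test = split_cluster_stratified(cset, cfg.test_fraction, seed=int(rng_seeds[0]))
        audit.append({"stage": "split", "n_train": len(train), "n_test": len(test)})

        stage("pls")
        scaler = fit_scaler(train, log_flags=select_log_transform(train))
        Xtr = apply_scaler(scaler, train.descriptors)
        Xte = apply_scaler(scaler, test.descriptors)
        fu_tr, fu_te = train.fu, test.fu
        obs_tr = ~train.fu_missing_mask
        imputed_ids = set(cset.meta.get("fu_imputed_ids", []))
        obs_tr &= np.array([cid not in imputed_ids for cid in train.ids])
        Y_raw = np.column_stack([train.log_vss, fu_tr])[obs_tr]
        y_mean, y_sd = Y_raw.mean(axis=0), Y_raw.std(axis=0, ddof=1)
        Ytr = (Y_raw - y_mean) / y_sd
        Xpls = Xtr[obs_tr]
        n_comp = select_n_components(Xpls, Ytr, max_components=cfg.pls_max_components, seed=int(rng_seeds[1]))
        selected, pls, trail = reduce_variables(
            Xpls, Ytr, variable_names=train.descriptor_names,
            vip_cutoff=cfg.vip_cutoff, n_components=n_comp, seed=int(rng_seeds[1]),
        )
        audit.append({"stage": "pls", "n_components": pls.n_components, "q2": pls.q2,
                      "selected_variables": selected, "reduction_trail": trail})
        pls.to_json(out / "pls_model.json")

        stage("forest")
        scheme = ClassScheme(vss_upper_inclusive=cfg.class_scheme_upper_inclusive)
        ytr_class = assign_vss_class(train.vss, scheme)
        forest = fit_balanced_forest(
            train.descriptors, ytr_class, n_trees=cfg.n_trees, seed=int(rng_seeds[2]),
            min_leaf=cfg.min_leaf, variable_names=train.descriptor_names,
        )
        oob = oob_predictions(forest, train.descriptors, ytr_class)
        importance = selection_frequency_importance(forest)
        importance.to_csv(out / "forest_importance.csv", index=False)
        forest.to_json(out / "forest_model.json")
        classes = forest.classes
        covered_labels = np.asarray(ytr_class)[oob["covered"]]
        if all(np.any(covered_labels == c) for c in classes):
            oob_auc = hand_till_auc(covered_labels, oob["proba"][oob["covered"]], classes)
        else:
            oob_auc = float("nan")
        audit.append({"stage": "forest", "oob_accuracy": oob.get("accuracy"), "oob_auc": oob_auc})

        stage("validation")
        sel_idx = [train.descriptor_names.index(v) for v in selected]
        pred_scaled = Xte[:, sel_idx] @ pls.coef
        pred = pred_scaled * y_sd + y_mean
        report = ValidationReport()
        report.qe2["logVss"] = external_q2(test.log_vss, pred[:, 0])
        fe = fold_errors(test.vss, np.power(10.0, pred[:, 0]))
        report.mfe["logVss"] = fe["mfe"]
        report.pct_within["logVss"] = fe["pct_within"]
        obs_te = ~test.fu_missing_mask & np.array([cid not in imputed_ids for cid in test.ids])
        if obs_te.sum() >= 3 and np.ptp(fu_te[obs_te]) > 0:
            report.qe2["fu"] = external_q2(fu_te[obs_te], pred[obs_te, 1])
            pred_fu = np.clip(pred[obs_te, 1], 1e-4, None)
            fe_fu = fold_errors(fu_te[obs_te], pred_fu)
            report.mfe["fu"] = fe_fu["mfe"]
            report.pct_within["fu"] = fe_fu["pct_within"]
        yte_class = assign_vss_class(test.vss, scheme)
        pred_class = forest.predict(test.descriptors)
        report.confusion = confusion_matrix(yte_class, pred_class, classes)
        for cls in classes:
            if report.confusion.loc[cls].sum() > 0:
                report.sensitivity[str(cls)] = class_sensitivity(report.confusion, cls)
                report.specificity[str(cls)] = class_specificity(report.confusion, cls)
        if all(np.any(yte_class == c) for c in classes):
            report.auc = hand_till_auc(yte_class, forest.predict_proba(test.descriptors), classes)
        report.confusion.to_csv(out / "confusion_test.csv")

        stage("applicability_domain")
        ad_info = None
        if all(r.structure_ref is not None for r in train.records):
            from pkqspr.domain import ad_threshold, compute_fingerprints, in_domain

            fps_train = compute_fingerprints(train, n_bits=cfg.fingerprint_bits)
            ad = ad_threshold(fps_train, z=cfg.ad_z)
            fps_test = compute_fingerprints(test, n_bits=cfg.fingerprint_bits)
            flags, _ = in_domain(ad, fps_test)
            ad.to_json(out / "ad_model.json")
            ad_info = {"threshold": ad.threshold, "z": cfg.ad_z,
                       "test_coverage_pct": float(100.0 * flags.mean())}
            audit.append({"stage": "applicability_domain", **ad_info})
        else:
            audit.append({"stage": "applicability_domain", "skipped": "no structures in dataset"})

        stage("y_randomization")
        def builder(X, Y):
            a = min(pls.n_components, X.shape[1], X.shape[0] - 1)
            mdl = fit_pls2(X, Y, a)
            q2 = cross_validate_q2(X, Y, a, seed=int(rng_seeds[3]))["pooled"]
            return mdl.r2y, q2
        yrand = y_randomization(
            Xpls[:, sel_idx], Ytr, builder, n_permutations=cfg.n_permutations, seed=int(rng_seeds[4])
        )
        audit.append({"stage": "y_randomization",
                      "r2_intercept": yrand["r2_intercept"], "q2_intercept": yrand["q2_intercept"],
                      "r2_pass": yrand["r2_pass"], "q2_pass": yrand["q2_pass"]})

        result = {
            "seed": cfg.seed,
            "n_compounds": len(cset),
            "pls": {"n_components": pls.n_components, "r2y": pls.r2y, "q2": pls.q2,
                    "selected_variables": selected},
            "forest": {"oob_accuracy": oob.get("accuracy"), "oob_auc": oob_auc},
            "applicability_domain": ad_info,
            "validation": report.to_dict(),
            "y_randomization": {k: yrand[k] for k in ("r2_intercept", "q2_intercept", "r2_pass", "q2_pass")},
            "audit": audit,
        }
        (out / "report.json").write_text(json.dumps(result, indent=1, default=str))
        (out / "report.txt").write_text(report.summary() + "\n")
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {current['name']}: {exc}") from exc
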