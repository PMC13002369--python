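"""End-to-end orchestration: synthesize (or load) cohorts, harmonize,
test differential expression, intersect with compound targets, run the
model zoo, stack, rank and explain — all from one seeded config.

Every stage writes plain-text artifacts plus a manifest entry recording its
parameters, seed and output hashes, so a rerun with an identical config
reproduces identical rankings and tampering is detectable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seeds import child_seed
from . import compounds as compounds_mod
from .diffexpr import fit_gene_models, select_degs
from .harmonize import combat_adjust, estimate_surrogates, pca_embed
from .io import write_gmt, write_target_table
from .overlap import enrich, enrichment_frame, intersect_targets
from .rank import rank_targets
from .shapley import (
    kernel_shap,
    kernel_shap_table,
    mean_abs_shap,
    shap_interactions,
    single_gene_auc,
    EXACT_LIMIT,
    INTERACTION_LIMIT,
)
from .stack import (
    base_probability_matrix,
    build_meta_features,
    compare_ensembles,
    fit_meta,
    stacked_predict_function,
)
from .study import ExpressionStudy
from .synth import SyntheticConfig, generate_cohorts, generate_target_fixture
from .zoo import enumerate_models, external_feature_matrix, manifest_text, run_cv, FAMILIES

log = logging.getLogger("flavotarget")


class PipelineConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All stage parameters of the target-prioritization pipeline.

    Defaults mirror the reference study conditions: three training cohorts
    of 30 disease / 30 control samples, 2,000 genes with 5 informative at a
    log2 effect of 2, 5-fold stratified CV, stacking gate 0.945 and
    redundancy threshold rho 0.85.
    """

    seed: int = 0
    outdir: str = "flavotarget_out"

    # synthetic cohorts (ignored when expression/metadata paths are given)
    n_cohorts: int = 3
    samples_per_cohort: tuple = ((30, 30), (30, 30), (30, 30))
    n_genes: int = 2000
    n_informative: int = 5
    effect_size: float = 2.0
    batch_shift_sd: float = 1.0
    batch_scale_sd: float = 0.25
    noise_sd: float = 1.0
    n_validation_cohorts: int = 2
    validation_samples: tuple = (20, 20)
    n_compounds: int = 10
    hit_fraction: float = 0.5
    genes_per_compound: int = 10

    # optional external inputs (disable the synth stage)
    expression_tsv: str | None = None
    metadata_tsv: str | None = None
    targets_csv: str | None = None

    # harmonization
    sva_permutations: int = 20
    sva_alpha: float = 0.05
    use_eb: bool = True

    # differential expression
    moderated: bool = True
    lfc_thresh: float = 1.0
    q_thresh: float = 0.05

    # model zoo
    classifiers: tuple = FAMILIES
    selectors: tuple = ("lasso",)
    include_standalone: bool = True
    k_folds: int = 5

    # stacking / ranking / explanation
    gate: float = 0.945
    meta_l2: float = 1e-4
    rho: float = 0.85
    shap_background: int = 32
    shap_enabled: bool = True
    run_compounds: bool = True

    def __post_init__(self) -> None:
        self.samples_per_cohort = tuple(
            tuple(int(v) for v in pair) for pair in self.samples_per_cohort
        )
        self.validation_samples = tuple(int(v) for v in self.validation_samples)
        self.classifiers = tuple(self.classifiers)
        self.selectors = tuple(self.selectors)

    # -- validation / serialization ---------------------------------------

    def validate(self) -> None:
        if self.seed is None:
            raise PipelineConfigError("seed is required")
        external = [self.expression_tsv, self.metadata_tsv]
        if any(external) and not all(external):
            raise PipelineConfigError(
                "expression_tsv and metadata_tsv must be given together"
            )
        for path in (self.expression_tsv, self.metadata_tsv, self.targets_csv):
            if path is not None and not Path(path).exists():
                raise PipelineConfigError(f"input path does not exist: {path}")
        if self.synth_enabled:
            # instantiating checks the generator invariants
            self.synthetic_config()
        if not 0 < self.rho < 1:
            raise PipelineConfigError("rho must lie in (0, 1)")
        if not 0 <= self.gate <= 1:
            raise PipelineConfigError("gate must lie in [0, 1]")
        if self.k_folds < 2:
            raise PipelineConfigError("k_folds must be >= 2")

    @property
    def synth_enabled(self) -> bool:
        return self.expression_tsv is None

    def synthetic_config(self) -> SyntheticConfig:
        n_total = self.n_cohorts + (self.n_validation_cohorts if self.synth_enabled else 0)
        pairs = list(self.samples_per_cohort) + [
            tuple(self.validation_samples)
        ] * self.n_validation_cohorts
        return SyntheticConfig(
            n_cohorts=n_total,
            samples_per_cohort=tuple(pairs),
            n_genes=self.n_genes,
            n_informative=self.n_informative,
            effect_size=self.effect_size,
            batch_shift_sd=self.batch_shift_sd,
            batch_scale_sd=self.batch_scale_sd,
            noise_sd=self.noise_sd,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class PipelineResult:
    config: PipelineConfig
    outdir: Path
    study: ExpressionStudy
    corrected: ExpressionStudy
    truth: object | None
    sva_k: int
    silhouette_before: float
    silhouette_after: float
    de_table: pd.DataFrame
    degs: list
    panel: object
    records: list
    ensemble: object
    comparison: pd.DataFrame
    report: object
    shap_mean_abs: pd.Series | None
    shap_phi: pd.DataFrame | None
    single_auc: pd.Series | None
    interactions: pd.DataFrame | None
    validation_metrics: dict
    manifest: list = field(default_factory=list)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _split_by_cohorts(study: ExpressionStudy, cohorts: list[str]) -> ExpressionStudy:
    keep = [s for s in study.samples if study.cohort[s] in set(cohorts)]
    idx = [study.samples.index(s) for s in keep]
    return ExpressionStudy(
        list(study.genes), keep, study.values[:, idx],
        {s: study.cohort[s] for s in keep},
        {s: study.condition[s] for s in keep},
    )


def _silhouette(study: ExpressionStudy) -> float:
    from sklearn.metrics import silhouette_score

    table, _ = pca_embed(study, k=2)
    labels = table["cohort"].to_numpy()
    if len(set(labels)) < 2:
        return float("nan")
    return float(silhouette_score(table[["PC1", "PC2"]].to_numpy(), labels))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every enabled stage; returns in-memory results and writes
    artifacts plus a manifest under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: list[dict] = []

    def finish_stage(stage: str, params: dict, outputs: list[Path], seed=None) -> None:
        manifest.append(
            {
                "stage": stage,
                "params": params,
                "seed": seed,
                "outputs": {p.name: _sha256(p) for p in outputs},
            }
        )

    try:
        t0 = time.time()
        # ---- synth / load -------------------------------------------------
        stage = "synth"
        if config.synth_enabled:
            full_study, truth = generate_cohorts(config.synthetic_config())
            train_cohorts = full_study.cohort_ids[: config.n_cohorts]
            val_cohorts = full_study.cohort_ids[config.n_cohorts:]
            study = _split_by_cohorts(full_study, train_cohorts)
            validation = {
                c: _split_by_cohorts(full_study, [c]) for c in val_cohorts
            }
            target_table = generate_target_fixture(
                truth, study.genes,
                n_compounds=config.n_compounds,
                hit_fraction=config.hit_fraction,
                genes_per_compound=config.genes_per_compound,
                seed=config.seed,
            )
            study.to_tsv(outdir / "expression.tsv", outdir / "samples.tsv")
            write_target_table(target_table, outdir / "targets.csv")
            truth.to_json(outdir / "truth.json")
            outputs = [outdir / n for n in
                       ("expression.tsv", "samples.tsv", "targets.csv", "truth.json")]
        else:
            truth = None
            validation = {}
            study = ExpressionStudy.from_tsv(config.expression_tsv, config.metadata_tsv)
            if config.targets_csv is None:
                raise PipelineConfigError("targets_csv required with external inputs")
            from .io import read_target_table

            target_table = read_target_table(config.targets_csv)
            outputs = []
        log.info(
            "synth: %d genes x %d training samples, %d validation cohorts",
            study.n_genes, study.n_samples, len(validation),
        )
        finish_stage(stage, {"synth_enabled": config.synth_enabled}, outputs,
                     seed=config.seed)

        # ---- harmonize ----------------------------------------------------
        stage = "harmonize"
        svs = estimate_surrogates(
            study, n_permutations=config.sva_permutations,
            alpha=config.sva_alpha, seed=config.seed,
        )
        sil_before = _silhouette(study)
        corrected, _model = combat_adjust(study, use_eb=config.use_eb)
        sil_after = _silhouette(corrected)
        corrected.to_tsv(outdir / "corrected.tsv", outdir / "samples.tsv")
        pca_table, frac = pca_embed(corrected, k=min(2, corrected.n_samples))
        pca_table.to_csv(outdir / "pca.tsv", sep="\t", lineterminator="\n")
        log.info(
            "harmonize: k_sv=%d silhouette %.3f -> %.3f (PC1+2 var %.2f)",
            svs.k, sil_before, sil_after, float(np.sum(frac)),
        )
        finish_stage(stage, {"use_eb": config.use_eb, "sva_k": svs.k},
                     [outdir / "corrected.tsv", outdir / "pca.tsv"],
                     seed=config.seed)

        # ---- differential expression -------------------------------------
        stage = "diffexpr"
        de_table = fit_gene_models(
            corrected, moderated=config.moderated,
            lfc_thresh=config.lfc_thresh, q_thresh=config.q_thresh,
        )
        degs = select_degs(de_table, config.lfc_thresh, config.q_thresh)
        de_table.to_csv(outdir / "differential.tsv", sep="\t", lineterminator="\n")
        log.info("diffexpr: %d DEGs at |logFC|>=%s, q<%s",
                 len(degs), config.lfc_thresh, config.q_thresh)
        finish_stage(stage, {"lfc": config.lfc_thresh, "q": config.q_thresh,
                             "n_deg": len(degs)},
                     [outdir / "differential.tsv"])

        # ---- overlap ------------------------------------------------------
        stage = "overlap"
        panel = intersect_targets(degs, target_table)
        if len(panel.genes) < 2:
            raise RuntimeError(
                f"candidate panel has {len(panel.genes)} genes; need >= 2 "
                "(relax thresholds or enlarge the target table)"
            )
        pd.DataFrame({"gene": panel.genes}).to_csv(
            outdir / "panel.tsv", sep="\t", index=False, lineterminator="\n"
        )
        (outdir / "panel_provenance.json").write_text(
            json.dumps({g: sorted(c) for g, c in panel.provenance.items()}, indent=2)
        )
        enr_outputs = [outdir / "panel.tsv", outdir / "panel_provenance.json"]
        if truth is not None:
            rng = np.random.default_rng(child_seed(config.seed, "overlap.collection"))
            collection = {"PLANTED_SIGNAL": set(truth.informative_genes)}
            for i in range(3):
                collection[f"RANDOM_SET_{i + 1}"] = set(
                    rng.choice(study.genes, size=25, replace=False)
                )
            write_gmt(collection, outdir / "collection.gmt")
            rows = enrich(panel.genes, collection, study.genes)
            enrichment_frame(rows).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False, lineterminator="\n"
            )
            enr_outputs += [outdir / "collection.gmt", outdir / "enrichment.tsv"]
        log.info("overlap: panel of %d genes (deg=%d, target=%d)",
                 panel.sizes[2], panel.sizes[0], panel.sizes[1])
        finish_stage(stage, {"sizes": list(panel.sizes)}, enr_outputs)

        # ---- model zoo ----------------------------------------------------
        stage = "zoo"
        specs = enumerate_models(
            classifiers=config.classifiers,
            selectors=config.selectors,
            include_standalone=config.include_standalone,
        )
        (outdir / "zoo_manifest.txt").write_text(manifest_text(specs))
        features = corrected.feature_frame(panel.genes)
        y = corrected.labels
        cohorts = corrected.cohort_labels
        records = []
        for spec in specs:
            rec = run_cv(spec, features, y, k_folds=config.k_folds,
                         seed=config.seed, cohorts=cohorts)
            records.append(rec)
        with (outdir / "zoo_metrics.jsonl").open("w") as fh:
            for rec in records:
                fh.write(json.dumps({
                    "spec": rec.spec.spec_id,
                    "tuned": rec.tuned_params,
                    "metrics": rec.metrics,
                    "selected": sorted(rec.selected),
                }) + "\n")
        log.info("zoo: %d specs fitted; best OOF AUC %.3f",
                 len(records), max(r.train_auc for r in records))
        finish_stage(stage, {"n_specs": len(specs), "k_folds": config.k_folds},
                     [outdir / "zoo_manifest.txt", outdir / "zoo_metrics.jsonl"],
                     seed=config.seed)

        # ---- stacking -----------------------------------------------------
        stage = "stack"
        meta, retained = build_meta_features(records, gate=config.gate)
        ensemble = fit_meta(meta, y, l2=config.meta_l2, gate=config.gate)
        train_means = features.mean(axis=0)
        validation_sets = {}
        validation_metrics: dict[str, dict] = {}
        for cname, vstudy in validation.items():
            Xv, coverage = external_feature_matrix(vstudy, panel.genes, train_means)
            vmeta = base_probability_matrix(records, retained, Xv)
            validation_sets[cname] = (vmeta, vstudy.labels)
            from .metrics import binary_metrics

            validation_metrics[cname] = {
                **binary_metrics(vstudy.labels, ensemble.predict_from_meta(vmeta)),
                "coverage": coverage,
            }
        comparison = compare_ensembles(ensemble, records, y, validation_sets)
        ensemble.to_json(outdir / "ensemble.json")
        comparison.to_csv(outdir / "comparison.tsv", sep="\t", index=False,
                          lineterminator="\n")
        log.info("stack: retained %d/%d models (gate %.3f); train OOF AUC %.3f",
                 len(retained), len(records), config.gate, ensemble.train_oof_auc)
        finish_stage(stage, {"gate": config.gate, "retained": retained},
                     [outdir / "ensemble.json", outdir / "comparison.tsv"])

        # ---- redundancy-weighted ranking ---------------------------------
        stage = "rank"
        report = rank_targets(records, rho=config.rho)
        report.ranking_frame().to_csv(
            outdir / "ranking.tsv", sep="\t", index=False, lineterminator="\n"
        )
        (outdir / "redundancy.json").write_text(json.dumps({
            "rho": report.rho,
            "clusters": report.clusters,
            "weights": report.weights,
            "wsf": {g: report.wsf[g] for g in report.ranking},
        }, indent=2))
        log.info("rank: %d clusters over %d models; top gene %s",
                 len(report.clusters), len(records),
                 report.ranking[0] if report.ranking else "-")
        finish_stage(stage, {"rho": config.rho},
                     [outdir / "ranking.tsv", outdir / "redundancy.json"])

        # ---- SHAP explanation --------------------------------------------
        stage = "shap"
        shap_ranking = None
        phi_table = None
        single_auc = None
        interactions = None
        if config.shap_enabled:
            predict = stacked_predict_function(records, ensemble, panel.genes)
            Xmat = features.to_numpy(dtype=float)
            rng = np.random.default_rng(child_seed(config.seed, "shap.background"))
            if len(Xmat) > config.shap_background:
                bg_idx = np.sort(rng.choice(len(Xmat), size=config.shap_background,
                                            replace=False))
            else:
                bg_idx = np.arange(len(Xmat))
            background = Xmat[bg_idx]
            if len(panel.genes) <= EXACT_LIMIT:
                phi_table, base = kernel_shap_table(predict, background, features)
            else:
                rows = []
                for i, sample in enumerate(features.index):
                    exp = kernel_shap(
                        predict, background, Xmat[i],
                        n_coalitions=min(512, 2 ** len(panel.genes) - 2),
                        seed=child_seed(config.seed, f"shap.{sample}"),
                    )
                    rows.append(exp.phi)
                    base = exp.base_value
                phi_table = pd.DataFrame(rows, index=features.index,
                                         columns=panel.genes)
            phi_table.to_csv(outdir / "shap_phi.tsv", sep="\t", lineterminator="\n")
            shap_ranking = mean_abs_shap(phi_table)
            shap_ranking.rename("mean_abs_shap").to_csv(
                outdir / "shap_ranking.tsv", sep="\t", lineterminator="\n"
            )
            top = list(shap_ranking.index[:5])
            single_auc = single_gene_auc(corrected, top)
            single_auc.to_csv(outdir / "single_gene_auc.tsv", sep="\t",
                              lineterminator="\n")
            if len(panel.genes) <= INTERACTION_LIMIT:
                probe = features.iloc[int(np.argmax(predict(Xmat)))].to_numpy()
                inter = shap_interactions(predict, background, probe)
                interactions = pd.DataFrame(inter, index=panel.genes,
                                            columns=panel.genes)
                interactions.to_csv(outdir / "shap_interactions.tsv", sep="\t",
                                    lineterminator="\n")
            log.info("shap: base=%.3f top genes %s", base,
                     ",".join(shap_ranking.index[:5]))
            finish_stage(stage, {"background": int(len(background))},
                         [outdir / "shap_ranking.tsv"], seed=config.seed)

        # ---- compound screening ------------------------------------------
        stage = "compounds"
        if config.run_compounds:
            recs = compounds_mod.flavonoid_records()
            # evaluate only rules whose descriptors every record carries
            available = set.intersection(
                *(set(r.descriptors) for r in recs)
            ) if recs else set()
            rules = {
                name: rule
                for name, rule in compounds_mod.DEFAULT_RULES.items()
                if rule[0] == "mw" or rule[0] in available
            }
            compounds_mod.screen(recs, rules)
            compounds_mod.screening_frame(recs).to_csv(
                outdir / "screening.tsv", sep="\t", index=False, lineterminator="\n"
            )
            log.info("compounds: %d records screened, %d leads",
                     len(recs), sum(bool(r.lead) for r in recs))
            finish_stage(stage, {"rules": "default"}, [outdir / "screening.tsv"])

        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.info("pipeline complete in %.1f s", time.time() - t0)
        return PipelineResult(
            config=config, outdir=outdir, study=study, corrected=corrected,
            truth=truth, sva_k=svs.k, silhouette_before=sil_before,
            silhouette_after=sil_after, de_table=de_table, degs=degs,
            panel=panel, records=records, ensemble=ensemble,
            comparison=comparison, report=report, shap_mean_abs=shap_ranking,
            shap_phi=phi_table, single_auc=single_auc,
            interactions=interactions, validation_metrics=validation_metrics,
            manifest=manifest,
        )
    except (PipelineConfigError,):
        raise
    except Exception as exc:  # noqa: BLE001 - stage failures carry context
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc
    finally:
        log.removeHandler(handler)
        handler.close()


def verify_manifest(outdir: str | Path) -> list[str]:
    """Recompute output hashes against the manifest; returns the names of
    files that were altered or removed since the run."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    tampered = []
    for entry in manifest:
        for name, digest in entry["outputs"].items():
            path = outdir / name
            if not path.exists() or _sha256(path) != digest:
                tampered.append(name)
    return tampered
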