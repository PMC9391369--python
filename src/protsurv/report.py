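"""Pipeline orchestration and paper-shaped outputs.

``run_pipeline`` wires the stages together: clinical imputation and
association tables -> expression normalization/filtering/averaging and
diagnostics -> per-marker MCCV survival prediction under the configured
scheme -> bootstrap differential signature -> gene set enrichment. Every
output is a plain-text TSV/JSON artifact plus a manifest recording the
configuration, seeds and versions, sufficient to replay the run
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import impute_table, binarize_characteristics, table_one
from .proteomics import (
    channel_sum_normalize,
    filter_proteins,
    average_replicates,
    replicate_correlation_audit,
    distribution_diagnostics,
)
from .mccv import MCCVConfig, PredictionScheme, evaluate_marker
from .signature import bootstrap_rank_statistic, ranked_list, write_rnk
from .enrichment import read_gmt, phenotype_gsea, enrichment_table, write_leading_edges

__all__ = ["RunConfig", "run_pipeline", "summarize_markers"]


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Either ``synthetic`` carries generator parameter overrides (synthetic
    cohort mode) or the input paths must point at existing TSV/GMT files.
    ``markers`` limits the screening set ('all', an integer count of
    proteins, or an explicit name list).
    """

    output_dir: str = "protsurv_run"
    seed: int = 0
    synthetic: dict | None = None
    clinical_path: str | None = None
    matrix_path: str | None = None
    meta_path: str | None = None
    annotation_path: str | None = None
    gmt_path: str | None = None
    scheme: dict = field(default_factory=dict)
    mccv: dict = field(default_factory=dict)
    markers: object = "all"
    signature: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    run_enrichment: bool = True
    run_signature: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.synthetic is None:
            for name in ("clinical_path", "matrix_path", "meta_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"input path {name} missing: {p!r}")
        if self.run_enrichment and self.synthetic is None:
            if self.gmt_path is None or not Path(self.gmt_path).exists():
                raise ValueError(f"gmt_path missing: {self.gmt_path!r}")
        PredictionScheme(**self.scheme)  # raises on bad scheme
        MCCVConfig(master_seed=self.seed, **self.mccv)


def summarize_markers(results) -> pd.DataFrame:
    """Marker table sorted by median beta descending, three-decimal formatting.

    Column order follows the significant-markers report: AUROC 2.5% / median /
    97.5%, then beta 2.5% / median / 97.5%, p-values and the significance
    flag.
    """
    rows = [asdict(r) for r in results]
    cols = ["marker", "auroc_q2_5", "auroc_median", "auroc_q97_5",
            "beta_q2_5", "beta_median", "beta_q97_5",
            "p_raw", "p_adjusted", "significant"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)[cols]
    df = df.sort_values("beta_median", ascending=False, kind="mergesort")
    num = [c for c in cols if c.startswith(("auroc", "beta"))]
    df[num] = df[num].round(3)
    return df.reset_index(drop=True)


def _scheme_covariates(scheme: PredictionScheme, clinical, patient_ids):
    cols = []
    names = []
    df = clinical.df.loc[patient_ids]
    if "site_of_origin" in scheme.covariates:
        dummies = pd.get_dummies(df["site"], prefix="site", drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(c)
    if "pgd" in scheme.covariates:
        cols.append(pd.to_numeric(df["pgd"]).to_numpy(dtype=float))
        names.append("pgd")
    if not cols:
        return None, []
    return np.column_stack(cols), names


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a manifest dict of artifacts."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write_df(df, name, **kw):
        path = outdir / name
        df.to_csv(path, sep="\t", **kw)
        written.append(path)
        return path

    def _write_json(obj, name):
        path = outdir / name
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True, default=str)
        written.append(path)
        return path

    stage = "setup"
    try:
        # ---- inputs -----------------------------------------------------
        stage = "inputs"
        if config.synthetic is not None:
            from .synthetic import GeneratorParams, generate_cohort, generate_genesets

            params = GeneratorParams(**{**config.synthetic, "seed": config.seed})
            cohort = generate_cohort(params)
            clinical_raw, expression = cohort.clinical, cohort.expression
            _write_json(cohort.truth, "truth.json")
            planted = cohort.truth["planted_geneset"]
            gene_sets, _ = generate_genesets(
                [p for p in expression.values.index], n_sets=20,
                set_size_range=(5, 25), planted_set=planted,
                seed=config.seed + 1,
            )
        else:
            from .clinical import ClinicalTable
            from .proteomics import read_expression

            clinical_raw = ClinicalTable.from_tsv(config.clinical_path)
            expression = read_expression(
                config.matrix_path, config.meta_path, config.annotation_path
            )
            gene_sets = read_gmt(config.gmt_path) if config.run_enrichment else []

        # ---- clinical ---------------------------------------------------
        stage = "clinical"
        clinical = impute_table(clinical_raw)
        _write_df(table_one(clinical), "table_one.tsv", index=False)
        binarized = binarize_characteristics(clinical)
        _write_df(binarized, "clinical_binarized.tsv")

        # ---- proteomics -------------------------------------------------
        stage = "proteomics"
        normalized = channel_sum_normalize(expression)
        pred_matrix, pred_report = filter_proteins(
            normalized, include_immunoglobulins=False)
        sig_matrix, sig_report = filter_proteins(
            normalized, include_immunoglobulins=True)
        audit = replicate_correlation_audit(pred_matrix)
        diagnostics = distribution_diagnostics(sig_matrix)
        pred_patients = average_replicates(pred_matrix)
        sig_patients = average_replicates(sig_matrix)
        _write_json({
            "prediction_filter": asdict(pred_report),
            "signature_filter": asdict(sig_report),
            "replicate_audit": audit,
            "diagnostics": diagnostics,
        }, "proteomics_diagnostics.json")

        # ---- prediction -------------------------------------------------
        stage = "prediction"
        scheme = PredictionScheme(**config.scheme)
        patient_ids = list(pred_patients.values.columns)
        clin = clinical.df.loc[patient_ids]
        labels = scheme.labels(clin["survived"].to_numpy(dtype=int),
                               pd.to_numeric(clin["followup_years"]).to_numpy())
        covariates, cov_names = _scheme_covariates(scheme, clinical, patient_ids)

        protein_features = pred_patients.values.T  # patients x proteins
        clinical_features = binarized.loc[patient_ids]
        all_markers = pd.concat([protein_features, clinical_features], axis=1)
        if config.markers == "all":
            screen = list(all_markers.columns)
        elif isinstance(config.markers, int):
            screen = list(all_markers.columns[: config.markers])
        else:
            missing = [m for m in config.markers if m not in all_markers.columns]
            if missing:
                raise ValueError(f"unknown markers requested: {missing}")
            screen = list(config.markers)
        mccv_cfg = MCCVConfig(master_seed=config.seed,
                              bonferroni_m=len(all_markers.columns),
                              **config.mccv)
        results = [
            evaluate_marker(all_markers[m].to_numpy(dtype=float), covariates,
                            labels, mccv_cfg, marker_name=m)
            for m in screen
        ]
        marker_table = summarize_markers(results)
        _write_df(marker_table, "marker_table.tsv", index=False)
        _write_df(marker_table[marker_table["significant"]],
                  "significant_markers.tsv", index=False)
        _write_curves(results, all_markers, labels, screen, outdir, written)

        # ---- signature ---------------------------------------------------
        stage = "signature"
        rank_stat = None
        if config.run_signature:
            sig_ids = list(sig_patients.values.columns)
            sig_labels = scheme.labels(
                clinical.df.loc[sig_ids, "survived"].to_numpy(dtype=int),
                pd.to_numeric(clinical.df.loc[sig_ids, "followup_years"]).to_numpy())
            sites = clinical.df.loc[sig_ids, "site"]
            rank_stat = bootstrap_rank_statistic(
                sig_patients.values, sig_labels, sites,
                seed=config.seed + 2, **config.signature)
            write_rnk(rank_stat, outdir / "signature.rnk")
            written.append(outdir / "signature.rnk")
            _write_df(rank_stat.table, "signature_intervals.tsv")

        # ---- enrichment ---------------------------------------------------
        stage = "enrichment"
        if config.run_enrichment and config.run_signature:
            results_enr = phenotype_gsea(
                sig_patients.values, sig_labels, sites, gene_sets,
                seed=config.seed + 3, **config.enrichment)
            _write_df(enrichment_table(results_enr), "enrichment_table.tsv",
                      index=False)
            write_leading_edges(results_enr, outdir / "leading_edges.json")
            written.append(outdir / "leading_edges.json")

        # ---- manifest ------------------------------------------------------
        stage = "manifest"
        manifest = {
            "config": asdict(config),
            "seed": config.seed,
            "versions": {
                "protsurv": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "design": {
                "scaling": mccv_cfg.scaling,
                "penalty_grid": list(mccv_cfg.penalty_grid),
                "bonferroni_m": mccv_cfg.bonferroni_m,
                "stratified_splits": True,
                "separate_block_scaling": True,
                "markers_screened": screen,
            },
            "outputs": [str(p) for p in written],
        }
        _write_json(manifest, "manifest.json")
        return manifest
    except Exception as err:
        for p in written:
            Path(p).unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err


def _write_curves(results, markers, labels, screen, outdir, written):
    """ROC and precision-recall curve coordinates plus a per-group max-min
    normalized expression export for the significant markers."""
    from sklearn.metrics import roc_curve, precision_recall_curve

    rows_roc, rows_pr, rows_expr = [], [], []
    for r in results:
        if not r.significant:
            continue
        x = markers[r.marker].to_numpy(dtype=float)
        span = np.ptp(x)
        x_norm = (x - x.min()) / span if span > 0 else np.zeros_like(x)
        fpr, tpr, _ = roc_curve(labels, x_norm)
        prec, rec, _ = precision_recall_curve(labels, x_norm)
        rows_roc.extend({"marker": r.marker, "fpr": f, "tpr": t}
                        for f, t in zip(fpr, tpr))
        rows_pr.extend({"marker": r.marker, "recall": rc, "precision": pr}
                       for rc, pr in zip(rec, prec))
        rows_expr.extend({"marker": r.marker, "group": "survived" if l else "died",
                          "value": v} for l, v in zip(labels, x_norm))
    for rows, name in ((rows_roc, "roc_curves.tsv"),
                       (rows_pr, "pr_curves.tsv"),
                       (rows_expr, "marker_expression_by_group.tsv")):
        path = outdir / name
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written.append(path)
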