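"""Protein expression matrix handling: I/O, channel-sum normalization,
presence/annotation filters, replicate averaging, and distributional
diagnostics.

The matrix is proteins x samples of nonnegative signal-to-noise intensities
(TMT channel quantifications), with per-sample metadata (patient, site,
replicate index) and per-protein annotation (gene symbol, immunoglobulin
flag). Two filter modes mirror the two downstream uses: prediction mode
excludes immunoglobulins; signature mode keeps them (differential-expression
ranking), while proteins lacking a gene annotation are dropped in both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "FilterReport",
    "read_expression",
    "channel_sum_normalize",
    "filter_proteins",
    "average_replicates",
    "replicate_correlation_audit",
    "distribution_diagnostics",
]

IG_PREFIXES = ("IGH", "IGK", "IGL")


@dataclass
class ExpressionMatrix:
    """Proteins x samples intensity matrix with sample metadata and annotation.

    values : DataFrame, index=protein names, columns=sample ids, >= 0
    meta : DataFrame indexed by sample_id with patient_id, site, replicate_index
    annotation : DataFrame indexed by protein with gene (str) and is_ig (bool)
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValueError("duplicate protein ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.values.columns if s not in self.meta.index]
        if missing:
            raise ValueError(f"samples absent from metadata: {missing}")
        vals = self.values.to_numpy()
        if np.isfinite(vals).all() and (vals < 0).any():
            raise ValueError("negative intensities")
        unknown = [p for p in self.values.index if p not in self.annotation.index]
        if unknown:
            raise ValueError(f"proteins absent from annotation: {unknown}")

    @property
    def proteins(self):
        return list(self.values.index)

    @property
    def samples(self):
        return list(self.values.columns)

    def subset_proteins(self, keep) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[keep],
            meta=self.meta,
            annotation=self.annotation.loc[keep],
        )


@dataclass
class FilterReport:
    n_input: int
    n_present_in_all: int
    n_final: int
    excluded: dict = field(default_factory=dict)
    mode: str = "prediction"

    def __post_init__(self):
        if not (self.n_input >= self.n_present_in_all >= self.n_final):
            raise ValueError("filter counts must be non-increasing")


def read_expression(matrix_tsv, meta_tsv, annotation_tsv=None,
                    ig_prefixes=IG_PREFIXES) -> ExpressionMatrix:
    """Load matrix + metadata (+ optional annotation) TSVs.

    Without an annotation file, genes default to the protein names and the
    immunoglobulin flag is inferred from the configured gene-symbol prefixes.
    """
    values = pd.read_csv(matrix_tsv, sep="\t", index_col=0)
    bad = values.map(lambda v: not isinstance(v, (int, float, np.number)))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at protein {values.index[r]!r}, "
            f"sample {values.columns[c]!r}"
        )
    meta = pd.read_csv(meta_tsv, sep="\t", index_col=0)
    if annotation_tsv is not None:
        annotation = pd.read_csv(annotation_tsv, sep="\t", index_col=0)
        annotation["gene"] = annotation["gene"].fillna("")
        if "is_ig" not in annotation.columns:
            annotation["is_ig"] = annotation["gene"].str.startswith(
                tuple(ig_prefixes))
        annotation["is_ig"] = annotation["is_ig"].astype(bool)
    else:
        genes = pd.Series(values.index, index=values.index)
        annotation = pd.DataFrame({
            "gene": genes,
            "is_ig": genes.str.startswith(tuple(ig_prefixes)),
        })
        annotation.index.name = "protein"
    return ExpressionMatrix(values=values, meta=meta, annotation=annotation)


def channel_sum_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample so all column sums equal the grand mean column sum.

    Emulates equal-protein-loading normalization of TMT channel
    signal-to-noise values; within-sample protein ratios are preserved.
    """
    sums = matrix.values.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    target = sums.mean()
    values = matrix.values * (target / sums)
    return ExpressionMatrix(values=values, meta=matrix.meta,
                            annotation=matrix.annotation)


def filter_proteins(matrix: ExpressionMatrix, include_immunoglobulins=False,
                    require_nonzero=True):
    """Keep proteins quantified in every sample, then apply annotation filters.

    Presence means nonmissing (and, by default, nonzero) in every sample.
    Proteins without a gene annotation are always dropped; immunoglobulin
    proteins are dropped in prediction mode (include_immunoglobulins=False)
    and retained in signature mode. Returns (matrix, FilterReport).
    """
    vals = matrix.values
    present = vals.notna().all(axis=1)
    if require_nonzero:
        present &= (vals.fillna(0) > 0).all(axis=1)
    excluded = {"not_present_in_all": sorted(vals.index[~present])}
    kept = vals.index[present]
    n_present = len(kept)

    ann = matrix.annotation.loc[kept]
    no_gene = ann["gene"].astype(str).str.len() == 0
    excluded["no_gene_annotation"] = sorted(kept[no_gene])
    kept = kept[~no_gene]
    ann = ann[~no_gene]
    if not include_immunoglobulins:
        ig = ann["is_ig"].to_numpy()
        excluded["immunoglobulin"] = sorted(kept[ig])
        kept = kept[~ig]
    else:
        excluded["immunoglobulin"] = []
    if len(kept) == 0:
        raise ValueError("no proteins survive filtering")
    report = FilterReport(
        n_input=len(vals.index), n_present_in_all=n_present,
        n_final=len(kept), excluded=excluded,
        mode="signature" if include_immunoglobulins else "prediction",
    )
    return matrix.subset_proteins(list(kept)), report


def average_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse replicate samples to one column per patient (arithmetic mean).

    Metadata collapses to (patient_id, site); a patient whose samples span
    multiple sites is a metadata error.
    """
    meta = matrix.meta.loc[matrix.values.columns]
    sites = meta.groupby("patient_id")["site"].nunique()
    bad = sites[sites > 1]
    if len(bad):
        raise ValueError(f"patients with samples from multiple sites: {list(bad.index)}")
    patient_of = meta["patient_id"]
    avg = matrix.values.T.groupby(patient_of).mean().T
    new_meta = (
        meta.groupby("patient_id")["site"].first().to_frame()
        .loc[avg.columns]
    )
    new_meta.index.name = "sample_id"
    new_meta["patient_id"] = new_meta.index
    new_meta["replicate_index"] = 1
    return ExpressionMatrix(values=avg, meta=new_meta,
                            annotation=matrix.annotation)


def replicate_correlation_audit(matrix: ExpressionMatrix, threshold=0.5) -> dict:
    """Spearman correlation over proteins for every unordered sample pair.

    Reports C(n,2) total pairs, how many exceed the threshold, and how many
    exceeders are technical-replicate pairs (same patient). Pairs involving a
    constant sample vector have undefined correlation and are recorded.
    """
    vals = matrix.values.to_numpy(dtype=float)
    n_prot, n_samp = vals.shape
    if n_samp < 2 or n_prot < 3:
        raise ValueError("need >= 2 samples and >= 3 proteins")
    # Spearman = Pearson on within-sample ranks (average ties)
    ranks = np.apply_along_axis(stats.rankdata, 0, vals)
    sd = ranks.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks.T)
    iu = np.triu_indices(n_samp, k=1)
    pair_corr = corr[iu]
    patient = matrix.meta.loc[matrix.values.columns, "patient_id"].to_numpy()
    same_patient = patient[iu[0]] == patient[iu[1]]
    defined = ~(constant[iu[0]] | constant[iu[1]])
    above = defined & (pair_corr > threshold)
    return {
        "n_samples": n_samp,
        "n_pairs": len(pair_corr),
        "n_undefined": int((~defined).sum()),
        "n_above_threshold": int(above.sum()),
        "fraction_above_threshold": float(above.sum() / len(pair_corr)),
        "n_above_replicate_pairs": int((above & same_patient).sum()),
        "threshold": threshold,
    }


def distribution_diagnostics(matrix: ExpressionMatrix, alpha=0.05,
                             min_group=8) -> dict:
    """Per-site normality, pairwise site KS tests, and Ig vs non-Ig comparison.

    Normality is D'Agostino-Pearson's omnibus test on pooled within-site
    intensities; site differences use the two-sample Kolmogorov-Smirnov test;
    immunoglobulin vs non-immunoglobulin mean expression uses Mann-Whitney U.
    Sites with fewer than ``min_group`` values are skipped with a notice.
    """
    meta = matrix.meta.loc[matrix.values.columns]
    out = {"normality": {}, "site_ks": {}, "skipped": [], "alpha": alpha}
    pooled = {}
    for site, cols in meta.groupby("site").groups.items():
        x = matrix.values[list(cols)].to_numpy(dtype=float).ravel()
        x = x[np.isfinite(x)]
        pooled[site] = x
        if x.size < min_group:
            out["skipped"].append(site)
            continue
        stat, p = stats.normaltest(x)
        out["normality"][site] = {
            "statistic": float(stat), "p_value": float(p),
            "normal_rejected": bool(p < alpha),
        }
    sites = sorted(pooled)
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            a, b = pooled[sites[i]], pooled[sites[j]]
            if a.size < min_group or b.size < min_group:
                continue
            res = stats.ks_2samp(a, b)
            out["site_ks"][f"{sites[i]} vs {sites[j]}"] = {
                "statistic": float(res.statistic), "p_value": float(res.pvalue),
            }
    ann = matrix.annotation.loc[matrix.values.index]
    mean_expr = matrix.values.mean(axis=1)
    ig = mean_expr[ann["is_ig"].to_numpy()]
    non_ig = mean_expr[~ann["is_ig"].to_numpy()]
    if len(ig) and len(non_ig):
        res = stats.mannwhitneyu(ig, non_ig, alternative="two-sided")
        out["ig_vs_non_ig"] = {
            "statistic": float(res.statistic), "p_value": float(res.pvalue),
        }
    return out
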