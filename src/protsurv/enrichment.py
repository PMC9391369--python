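"""Gene set enrichment from a ranked protein list, implemented from scratch.

The enrichment score (ES) is the signed extremum of a weighted running sum
over the ranked universe: genes in the set add |score|^p normalized by the
sum over hits, genes outside subtract 1/(N - Nh). The null distribution comes
from phenotype permutation: outcome labels are shuffled, the bootstrap
differential rank statistic is recomputed (with a reduced bootstrap count for
tractability), the list re-ranked and every set rescored. NES divides ES by
the mean same-sign null ES of the same set; the nominal p is the same-sign
null exceedance fraction; the FDR q compares pooled null NES against observed
NES separately by sign, per the standard GSEA estimator. The leading edge is
the subset of hits at or before the running-sum maximum (at or after the
minimum for negative ES).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signature import bootstrap_rank_statistic, ranked_list

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "enrichment_score",
    "leading_edge",
    "phenotype_permutation_null",
    "nes_p_fdr",
    "phenotype_gsea",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple

    def __post_init__(self):
        if len(self.members) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p_value: float
    fdr_q: float
    leading_edge: tuple
    n_overlap: int
    n_perm: int = 0
    flagged: str = ""

    def __post_init__(self):
        if np.isfinite(self.nes) and self.es * self.nes < 0:
            raise ValueError("NES and ES must share sign")
        for v in (self.p_value, self.fdr_q):
            if np.isfinite(v) and not 0.0 <= v <= 1.0:
                raise ValueError("p and q must lie in [0, 1]")


def read_gmt(source) -> list:
    """Parse a GMT file (name, description, members...) into GeneSets.

    Duplicate members within a line are deduplicated with a warning; a line
    with fewer than 3 tab-separated fields is a parse error.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    sets = []
    for ln, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {ln}: expected >= 3 tab-separated fields")
        name, desc, *members = fields
        members = [m for m in members if m]
        uniq = list(dict.fromkeys(members))
        if len(uniq) != len(members):
            warnings.warn(f"GMT line {ln} ({name}): duplicate members removed")
        sets.append(GeneSet(name=name, description=desc, members=tuple(uniq)))
    return sets


def write_gmt(sets, dest) -> None:
    """Write GeneSets as GMT text (round-trips through read_gmt)."""
    def _write(fh):
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")

    if hasattr(dest, "write"):
        _write(dest)
    else:
        with open(dest, "w") as fh:
            _write(fh)


def enrichment_score(ranked: pd.Series, gene_set: GeneSet, weight_p=1.0,
                     min_size=2):
    """Weighted running-sum enrichment score of one set on a ranked list.

    ranked: Series of scores indexed by gene, already sorted descending.
    Returns (ES, running sum array, hit index array) or None if the overlap
    with the universe is below min_size (set skipped with a notice).
    """
    genes = np.asarray(ranked.index)
    scores = ranked.to_numpy(dtype=float)
    members = set(gene_set.members)
    hits = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))
    nh = int(hits.sum())
    if nh < min_size:
        warnings.warn(f"set {gene_set.name!r}: overlap {nh} < min_size, skipped")
        return None
    n = len(genes)
    weights = np.abs(scores) ** weight_p
    hit_w = np.where(hits, weights, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = hits.astype(float)
        denom = hit_w.sum()
    inc = hit_w / denom
    if n > nh:
        inc = inc - np.where(hits, 0.0, 1.0 / (n - nh))
    running = np.cumsum(inc)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    return es, running, np.flatnonzero(hits)


def leading_edge(running, hit_indices, ranked: pd.Series):
    """Hit genes driving the extremum of the running sum.

    Positive ES: hits at or before the running-sum maximum; negative ES:
    hits at or after the minimum.
    """
    running = np.asarray(running, dtype=float)
    i_ext = int(np.argmax(np.abs(running)))
    genes = np.asarray(ranked.index)
    if running[i_ext] >= 0:
        keep = hit_indices[hit_indices <= i_ext]
    else:
        keep = hit_indices[hit_indices >= i_ext]
    return [str(g) for g in genes[keep]]


def _score_sets(ranked, sets, weight_p, min_size):
    """ES per set on one ranked list; NaN marks skipped sets."""
    out = np.full(len(sets), np.nan)
    for k, s in enumerate(sets):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = enrichment_score(ranked, s, weight_p, min_size)
        if res is not None:
            out[k] = res[0]
    return out


def phenotype_permutation_null(expression, labels, sites, sets, n_perm=200,
                               n_boot=20, weight_p=1.0, min_size=2,
                               inverse_penalty=1.0, seed=0) -> np.ndarray:
    """Null ES matrix by full recomputation under label permutation.

    Each permutation shuffles the outcome labels (class balance preserved),
    recomputes the bootstrap rank statistic with n_boot resamples, re-ranks,
    and rescores every set. Returns (n_perm, n_sets) null ES values.
    """
    if n_perm < 10:
        raise ValueError("n_perm < 10: FDR estimate would be meaningless")
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(sets)))
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        stat = bootstrap_rank_statistic(
            expression, y_perm, sites, n_boot=n_boot,
            inverse_penalty=inverse_penalty,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ranked = ranked_list(stat)
        null[i] = _score_sets(ranked, sets, weight_p, min_size)
    return null


def nes_p_fdr(observed_es, null_es):
    """Normalize ES, assign nominal p and GSEA-style FDR q per set.

    observed_es : (n_sets,) observed ES (NaN = skipped set)
    null_es : (n_perm, n_sets) phenotype-permutation null ES

    NES = ES / mean(|same-sign null ES of the same set|); nominal
    p = same-sign null exceedance fraction; FDR q = [fraction of pooled
    same-sign null NES at least as extreme] / [fraction of observed same-sign
    NES at least as extreme], clipped to [0, 1], separately by sign.
    """
    es = np.asarray(observed_es, dtype=float)
    null = np.asarray(null_es, dtype=float)
    if null.size == 0:
        raise ValueError("empty null matrix")
    n_perm, n_sets = null.shape
    if es.shape[0] != n_sets:
        raise ValueError("observed/null set count mismatch")

    nes = np.full(n_sets, np.nan)
    pvals = np.full(n_sets, np.nan)
    null_nes = np.full_like(null, np.nan)
    flags = [""] * n_sets
    for k in range(n_sets):
        if not np.isfinite(es[k]):
            flags[k] = "skipped"
            continue
        col = null[:, k]
        col = col[np.isfinite(col)]
        same = col[col * es[k] > 0] if es[k] != 0 else col
        if same.size == 0:
            flags[k] = "no same-sign null values"
            continue
        mean_mag = np.abs(same).mean()
        nes[k] = es[k] / mean_mag
        pvals[k] = float((np.abs(same) >= abs(es[k])).sum() / same.size)
        # normalize this set's null column by sign for the pooled FDR null
        pos = col[col >= 0]
        neg = col[col < 0]
        pos_mean = pos.mean() if pos.size else np.nan
        neg_mean = np.abs(neg).mean() if neg.size else np.nan
        normed = np.where(col >= 0, col / pos_mean, col / neg_mean)
        null_nes[: len(normed), k] = normed

    pool = null_nes[np.isfinite(null_nes)]
    obs = nes[np.isfinite(nes)]
    qvals = np.full(n_sets, np.nan)
    for k in range(n_sets):
        v = nes[k]
        if not np.isfinite(v):
            continue
        if v >= 0:
            num_pool = pool[pool >= 0]
            num = (num_pool >= v).mean() if num_pool.size else 0.0
            den_obs = obs[obs >= 0]
            den = (den_obs >= v).mean() if den_obs.size else 0.0
        else:
            num_pool = pool[pool < 0]
            num = (num_pool <= v).mean() if num_pool.size else 0.0
            den_obs = obs[obs < 0]
            den = (den_obs <= v).mean() if den_obs.size else 0.0
        if den == 0:
            qvals[k] = 0.0 if num == 0 else 1.0
        else:
            qvals[k] = min(1.0, num / den)
    return nes, pvals, qvals, flags


def phenotype_gsea(expression, labels, sites, sets, n_boot_observed=200,
                   n_perm=200, n_boot_null=20, weight_p=1.0, min_size=2,
                   max_size=500, inverse_penalty=1.0, seed=0):
    """End-to-end enrichment: observed rank statistic, permutation null,
    NES/p/FDR and leading edges. Returns a list of EnrichmentResult sorted
    by FDR ascending."""
    sets = [s for s in sets if min_size <= len(s.members) <= max_size]
    if not sets:
        raise ValueError("no gene sets within size limits")
    stat = bootstrap_rank_statistic(
        expression, labels, sites, n_boot=n_boot_observed,
        inverse_penalty=inverse_penalty, seed=seed,
    )
    ranked = ranked_list(stat)
    observed = []
    ledges = []
    overlaps = []
    for s in sets:
        res = enrichment_score(ranked, s, weight_p, min_size)
        if res is None:
            observed.append(np.nan)
            ledges.append(())
            overlaps.append(0)
        else:
            es, running, hit_idx = res
            observed.append(es)
            ledges.append(tuple(leading_edge(running, hit_idx, ranked)))
            overlaps.append(len(hit_idx))
    null = phenotype_permutation_null(
        expression, labels, sites, sets, n_perm=n_perm, n_boot=n_boot_null,
        weight_p=weight_p, min_size=min_size,
        inverse_penalty=inverse_penalty, seed=seed + 1,
    )
    nes, pvals, qvals, flags = nes_p_fdr(np.asarray(observed), null)
    results = []
    for k, s in enumerate(sets):
        results.append(EnrichmentResult(
            name=s.name, es=float(np.nan_to_num(observed[k], nan=np.nan)),
            nes=float(nes[k]), p_value=float(pvals[k]), fdr_q=float(qvals[k]),
            leading_edge=ledges[k], n_overlap=overlaps[k], n_perm=n_perm,
            flagged=flags[k],
        ))
    results.sort(key=lambda r: (np.isnan(r.fdr_q), r.fdr_q, r.name))
    return results


def enrichment_table(results) -> pd.DataFrame:
    """Pathway-table export: set, NES, FDR, sorted by FDR ascending."""
    return pd.DataFrame([
        {"gene_set": r.name, "es": r.es, "nes": r.nes, "p_value": r.p_value,
         "fdr_q": r.fdr_q, "n_overlap": r.n_overlap,
         "leading_edge": ",".join(r.leading_edge)}
        for r in results
    ])


def write_leading_edges(results, path) -> None:
    with open(path, "w") as fh:
        json.dump({r.name: list(r.leading_edge) for r in results}, fh, indent=1)
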