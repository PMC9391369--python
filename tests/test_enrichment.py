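"""GSEA machinery against brute-force hand computation on toy instances."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from protsurv.enrichment import (
    GeneSet,
    read_gmt,
    write_gmt,
    enrichment_score,
    leading_edge,
    phenotype_permutation_null,
    nes_p_fdr,
)


def _ranked(scores: dict) -> pd.Series:
    s = pd.Series(scores, dtype=float)
    return s.sort_values(ascending=False)


def _es_oracle(genes, scores, members, p):
    """Straight-from-definition running sum, one explicit loop."""
    nh = sum(g in members for g in genes)
    n = len(genes)
    denom = sum(abs(s) ** p for g, s in zip(genes, scores) if g in members)
    run, acc = [], 0.0
    for g, s in zip(genes, scores):
        if g in members:
            acc += (abs(s) ** p) / denom
        else:
            acc -= 1.0 / (n - nh)
        run.append(acc)
    i = int(np.argmax(np.abs(run)))
    return run[i], run


class TestGMT:
    def test_parse_line(self):
        sets = read_gmt(io.StringIO("S1\tdesc\tA\tB\n"))
        assert sets == [GeneSet("S1", "desc", ("A", "B"))]

    def test_roundtrip(self, tmp_path):
        sets = [GeneSet("S1", "d1", ("A", "B")),
                GeneSet("S2", "d2", ("C", "D", "E"))]
        path = tmp_path / "x.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets

    def test_two_field_line_rejected(self):
        with pytest.raises(ValueError, match="line 1"):
            read_gmt(io.StringIO("S1\tdesc_only\n"))

    def test_duplicates_deduplicated_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            sets = read_gmt(io.StringIO("S\td\tA\tB\tA\n"))
        assert sets[0].members == ("A", "B")


class TestEnrichmentScore:
    def test_top_hits_unweighted(self):
        ranked = _ranked({"g1": 4, "g2": 3, "g3": 2, "g4": 1})
        es, run, hits = enrichment_score(ranked, GeneSet("s", "", ("g1", "g2")),
                                         weight_p=0)
        assert es == pytest.approx(1.0)
        assert np.allclose(run, [0.5, 1.0, 0.5, 0.0])
        assert hits.tolist() == [0, 1]

    def test_whole_universe_set(self):
        ranked = _ranked({"a": 3, "b": 2, "c": 1})
        es, _, _ = enrichment_score(ranked, GeneSet("s", "", ("a", "b", "c")),
                                    weight_p=1)
        assert es == pytest.approx(1.0)

    def test_weighted_matches_hand_oracle(self):
        scores = {"a": 3.0, "b": 2.5, "c": -0.5, "d": -1.0, "e": -2.0,
                  "f": -4.0}
        ranked = _ranked(scores)
        members = ("a", "c", "f")
        es, run, _ = enrichment_score(ranked, GeneSet("s", "", members),
                                      weight_p=1)
        es_o, run_o = _es_oracle(list(ranked.index), list(ranked.values),
                                 set(members), 1)
        assert es == pytest.approx(es_o, abs=1e-15)
        assert np.allclose(run, run_o)

    def test_small_overlap_skipped(self):
        ranked = _ranked({"a": 2, "b": 1})
        with pytest.warns(UserWarning, match="skipped"):
            assert enrichment_score(ranked, GeneSet("s", "", ("a", "zz")),
                                    min_size=2) is None

    @given(st.integers(0, 10**9))
    def test_es_bounded_and_reversal_negates(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = rng.normal(size=n)
        genes = [f"g{i}" for i in range(n)]
        k = int(rng.integers(2, n))
        members = tuple(rng.choice(genes, size=k, replace=False))
        ranked = pd.Series(scores, index=genes).sort_values(ascending=False)
        es, _, _ = enrichment_score(ranked, GeneSet("s", "", members),
                                    weight_p=0)
        assert -1.0 <= es <= 1.0
        if k < n:
            run = enrichment_score(ranked, GeneSet("s", "", members),
                                   weight_p=0)[1]
            # with unweighted (rational) increments the max and min of the
            # running sum can tie in magnitude, making the ES sign a
            # tie-break; the reversal identity is only asserted off ties
            unique_extremum = abs(run.max() + run.min()) > 1e-12
            reversed_ranked = ranked.iloc[::-1]
            es_r, _, _ = enrichment_score(reversed_ranked,
                                          GeneSet("s", "", members),
                                          weight_p=0)
            assert abs(es_r) == pytest.approx(abs(es), abs=1e-12)
            if unique_extremum:
                assert es_r == pytest.approx(-es, abs=1e-12)


class TestLeadingEdge:
    def test_all_hits_before_peak(self):
        ranked = _ranked({"g1": 4, "g2": 3, "g3": 2, "g4": 1})
        es, run, hits = enrichment_score(ranked, GeneSet("s", "", ("g1", "g2")),
                                         weight_p=0)
        assert leading_edge(run, hits, ranked) == ["g1", "g2"]

    def test_single_hit(self):
        ranked = _ranked({"g1": 4, "g2": 3, "g3": 2})
        es, run, hits = enrichment_score(ranked, GeneSet("s", "", ("g2",)),
                                         weight_p=0, min_size=1)
        assert leading_edge(run, hits, ranked) == ["g2"]

    def test_negative_es_tail_by_enumeration(self):
        # hits at the bottom -> negative ES; ledge = hits at/after the minimum
        ranked = _ranked({"a": 5, "b": 4, "c": 3, "d": 2, "e": 1, "f": 0.5})
        members = ("e", "f")
        es, run, hits = enrichment_score(ranked, GeneSet("s", "", members),
                                         weight_p=0)
        assert es < 0
        i_min = int(np.argmin(run))
        expected = [g for i, g in enumerate(ranked.index)
                    if g in members and i >= i_min]
        assert leading_edge(run, hits, ranked) == expected


class TestNesPFdr:
    def test_observed_equal_to_all_nulls(self):
        null = np.full((10, 1), 0.5)
        nes, p, q, flags = nes_p_fdr(np.array([0.5]), null)
        assert nes[0] == pytest.approx(1.0)
        assert p[0] == pytest.approx(1.0)

    def test_observed_exceeding_all_nulls(self):
        rng = np.random.default_rng(0)
        null = rng.uniform(0.05, 0.4, size=(1000, 1))
        nes, p, q, flags = nes_p_fdr(np.array([0.9]), null)
        assert p[0] == 0.0  # empirical bound: below 1/1000
        assert q[0] == 0.0

    def test_toy_three_set_oracle(self):
        """q values equal the pooled-ratio hand computation."""
        rng = np.random.default_rng(1)
        observed = np.array([0.8, 0.3, -0.6])
        null = np.column_stack([
            rng.uniform(0.1, 0.7, 10),
            rng.uniform(0.1, 0.7, 10),
            rng.uniform(-0.7, -0.1, 10),
        ])
        nes, p, q, _ = nes_p_fdr(observed, null)
        # oracle: explicit per-definition computation
        nes_o = np.empty(3)
        null_nes_cols = []
        for k in range(3):
            col = null[:, k]
            same = col[col * observed[k] > 0]
            nes_o[k] = observed[k] / np.abs(same).mean()
            pos, neg = col[col >= 0], col[col < 0]
            normed = np.concatenate([
                pos / pos.mean() if pos.size else pos,
                neg / np.abs(neg).mean() if neg.size else neg,
            ])
            null_nes_cols.append(normed)
            assert p[k] == pytest.approx(
                (np.abs(same) >= abs(observed[k])).mean())
        assert np.allclose(nes, nes_o)
        pool = np.concatenate(null_nes_cols)
        obs = nes_o
        for k in range(3):
            v = nes_o[k]
            if v >= 0:
                num = (pool[pool >= 0] >= v).mean()
                den = (obs[obs >= 0] >= v).mean()
            else:
                num = (pool[pool < 0] <= v).mean()
                den = (obs[obs < 0] <= v).mean()
            expected_q = min(1.0, num / den) if den else (0.0 if num == 0 else 1.0)
            assert q[k] == pytest.approx(expected_q)

    def test_no_same_sign_nulls_flagged(self):
        null = np.full((10, 1), 0.4)
        nes, p, q, flags = nes_p_fdr(np.array([-0.5]), null)
        assert flags[0] == "no same-sign null values"
        assert np.isnan(nes[0])


class TestPhenotypeNull:
    def _inputs(self, rng, n=30, n_prot=8):
        y = np.array([0] * (n // 3) + [1] * (n - n // 3))
        expr = pd.DataFrame(rng.normal(size=(n_prot, n)),
                            index=[f"g{i}" for i in range(n_prot)],
                            columns=[f"pt{i}" for i in range(n)])
        sites = ["site_A" if i % 2 else "site_B" for i in range(n)]
        sets = [GeneSet("s1", "", ("g0", "g1", "g2")),
                GeneSet("s2", "", ("g3", "g4"))]
        return expr, y, sites, sets

    def test_dimensions_and_determinism(self, rng):
        expr, y, sites, sets = self._inputs(rng)
        a = phenotype_permutation_null(expr, y, sites, sets, n_perm=12,
                                       n_boot=5, seed=3)
        b = phenotype_permutation_null(expr, y, sites, sets, n_perm=12,
                                       n_boot=5, seed=3)
        assert a.shape == (12, 2)
        assert np.array_equal(a, b)

    def test_too_few_permutations_refused(self, rng):
        expr, y, sites, sets = self._inputs(rng)
        with pytest.raises(ValueError, match="n_perm"):
            phenotype_permutation_null(expr, y, sites, sets, n_perm=5)

    def test_random_labels_within_null_band(self, rng):
        """With no signal, observed ES sits inside the null 95% band for most
        random sets."""
        from protsurv.signature import bootstrap_rank_statistic, ranked_list
        from protsurv.enrichment import _score_sets

        expr, y, sites, sets = self._inputs(rng, n=40, n_prot=12)
        y = rng.permutation(y)
        sets = [GeneSet(f"s{k}", "", tuple(f"g{i}" for i in
                        rng.choice(12, size=4, replace=False)))
                for k in range(8)]
        stat = bootstrap_rank_statistic(expr, y, sites, n_boot=20, seed=9)
        observed = _score_sets(ranked_list(stat), sets, 1.0, 2)
        null = phenotype_permutation_null(expr, y, sites, sets, n_perm=60,
                                          n_boot=10, seed=10)
        lo, hi = np.percentile(null, [2.5, 97.5], axis=0)
        inside = np.mean((observed >= lo) & (observed <= hi))
        assert inside >= 0.7
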