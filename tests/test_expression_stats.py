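"""Phred scores, read filters, RPKM, BH adjustment, DEG calls, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpersim import (
    CountTable,
    DomainError,
    ReadRecord,
    StructuralError,
    bh_adjust,
    call_degs,
    filter_reads,
    hypergeom_enrichment,
    phred_q,
    rpkm,
)
from gpersim.expression_stats import read_gmt
from gpersim.synthetic_data import planted_enrichment, synthetic_counts


def naive_bh(pvalues):
    """Independent O(n^2) step-up oracle."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        candidate = p[i] * m / rank_from_top
        running_min = min(running_min, candidate)
        q[i] = min(running_min, 1.0)
    return q


class TestPhredQ:
    def test_certain_error_scores_zero(self):
        assert phred_q(1.0) == 0.0
        assert phred_q(1.0, log_base=2) == 0.0

    def test_standard_base10_q20(self):
        assert phred_q(0.01) == pytest.approx(20.0)

    def test_base2_form(self):
        assert phred_q(0.25, log_base=2) == pytest.approx(20.0)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            phred_q(bad)


class TestFilterReads:
    @staticmethod
    def read(rid, q=40, n=30, frac_n=0.0, adapter=False):
        return ReadRecord(rid, [q] * n, fraction_N=frac_n, has_adapter=adapter)

    def test_pristine_read_kept(self):
        out = filter_reads([self.read("ok")])
        assert [r.id for r in out.kept] == ["ok"]

    def test_n_fraction_rule(self):
        out = filter_reads([self.read("bad", frac_n=0.25)])
        assert out.kept == [] and out.discarded_n_fraction == 1

    def test_hand_enumerated_batch(self):
        """Ten constructed reads; keep/discard worked out by hand per rule."""
        reads = [
            self.read("r0"),                                  # keep
            self.read("r1", adapter=True),                    # adapter
            self.read("r2", frac_n=0.30),                     # N rule
            self.read("r3", frac_n=0.20),                     # boundary: keep
            self.read("r4", q=10),                            # all bases low-Q
            ReadRecord("r5", [10] * 6 + [40] * 4),            # 60% low-Q
            ReadRecord("r6", [10] * 5 + [40] * 5),            # 50%: boundary keep
            self.read("r7", q=19),                            # Q just below 20
            self.read("r8", q=20),                            # Q at threshold: keep
            ReadRecord("r9", [40] * 4, fraction_N=0.21),      # just over N rule
        ]
        out = filter_reads(reads)
        assert [r.id for r in out.kept] == ["r0", "r3", "r6", "r8"]
        assert out.discarded_adapter == 1
        assert out.discarded_n_fraction == 2
        assert out.discarded_low_quality == 3
        assert out.n_input == 10


class TestRpkm:
    @staticmethod
    def table(counts, lengths, mapped):
        return CountTable(
            gene_ids=[f"g{i}" for i in range(len(lengths))],
            length_kb=lengths,
            counts=counts,
            mapped_millions=mapped,
        )

    def test_printed_formula_example(self):
        # 100 reads / (10 million mapped * 2 kb) = 5.0
        t = self.table(np.array([[100.0]]), [2.0], [10.0])
        assert rpkm(t).iloc[0, 0] == pytest.approx(5.0)

    def test_zero_counts_give_zero(self):
        t = self.table(np.array([[0.0]]), [1.5], [3.0])
        assert rpkm(t).iloc[0, 0] == 0.0

    def test_linearity_and_library_size_scaling(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 500, size=(20, 4)).astype(float)
        lengths = rng.uniform(0.3, 8.0, size=20)
        mapped = rng.uniform(5.0, 40.0, size=4)
        base = rpkm(self.table(counts, lengths, mapped)).to_numpy()
        doubled_counts = rpkm(self.table(2 * counts, lengths, mapped)).to_numpy()
        doubled_library = rpkm(self.table(counts, lengths, 2 * mapped)).to_numpy()
        np.testing.assert_allclose(doubled_counts, 2 * base)
        np.testing.assert_allclose(doubled_library, base / 2)

    def test_invalid_tables_rejected(self):
        with pytest.raises(DomainError):
            self.table(np.array([[1.0]]), [0.0], [1.0])
        with pytest.raises(DomainError):
            self.table(np.array([[1.0]]), [1.0], [0.0])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_uniform_spacing_all_tie(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_order_preserved(self):
        p = [0.9, 0.001, 0.5]
        q = bh_adjust(p)
        assert q[1] < q[2] < q[0]

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.0, 1.0, size=rng.integers(1, 60))
        if seed % 3 == 0:  # exercise ties
            p = np.round(p, 1)
        np.testing.assert_allclose(bh_adjust(p), naive_bh(p), rtol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(42)
        p = rng.uniform(size=200)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_properties_hold_on_arbitrary_inputs(self, p):
        q = bh_adjust(p)
        assert np.all((q >= 0) & (q <= 1))
        assert np.all(q >= np.asarray(p) - 1e-12)  # step-up never shrinks p
        np.testing.assert_allclose(q, naive_bh(p), rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.2])


class TestCallDegs:
    def test_no_evidence_no_degs(self):
        calls = call_degs({f"g{i}": (2.0, 1.0) for i in range(50)})
        assert all(c.direction == "none" for c in calls)

    def test_zero_threshold_calls_nothing(self):
        calls = call_degs({"g0": (3.0, 1e-30)}, q_threshold=0.0)
        assert calls[0].direction == "none"

    def test_duplicate_genes_rejected(self):
        df = pd.DataFrame(
            {"log2_fold_change": [1.0, 1.0], "p_value": [0.5, 0.5]},
            index=["g0", "g0"],
        )
        with pytest.raises(StructuralError):
            call_degs(df)

    def test_planted_up_genes_recovered(self):
        """Large planted effects at 10 replicates/group: >=90% recovered."""
        _, frame, truth = synthetic_counts(
            n_genes=1000,
            n_samples_per_group=10,
            n_up=50,
            n_down=0,
            effect_log2fc=3.0,
            dispersion=0.05,
            seed=11,
        )
        calls = {c.gene_id: c for c in call_degs(frame, q_threshold=0.01)}
        planted = truth.payload["up_genes"]
        hits = [g for g in planted if calls[g].direction == "up"]
        assert len(hits) >= 0.9 * len(planted)
        wrong_direction = [g for g in planted if calls[g].direction == "down"]
        assert not wrong_direction

    def test_null_false_positive_control(self):
        """At q<0.01 on null tables the FDP stays within 0.01 + 3·SE."""
        n_genes, n_seeds = 1000, 20
        fps = []
        for seed in range(n_seeds):
            _, frame, _ = synthetic_counts(
                n_genes=n_genes, n_samples_per_group=10, seed=seed
            )
            calls = call_degs(frame, q_threshold=0.01)
            fps.append(sum(c.direction != "none" for c in calls) / n_genes)
        mean_fp = float(np.mean(fps))
        se = float(np.std(fps, ddof=1) / math.sqrt(n_seeds))
        assert mean_fp <= 0.01 + 3 * se + 1e-12


class TestHypergeomEnrichment:
    def test_forced_complete_overlap_is_degenerate(self):
        genes = [f"g{i}" for i in range(10)]
        (res,) = hypergeom_enrichment(genes, {"T": genes}, genes)
        assert res.p_value == pytest.approx(1.0)
        assert res.k == res.K == res.n == res.N == 10

    def test_matches_exhaustive_enumeration(self):
        """p(X >= k) equals counting over all C(20, 8) draws."""
        N, K, n, k_obs = 20, 5, 8, 4
        background = list(range(N))
        term = set(range(K))
        total = hits = 0
        for draw in itertools.combinations(background, n):
            total += 1
            if len(term & set(draw)) >= k_obs:
                hits += 1
        expected = hits / total
        gene_list = [f"g{i}" for i in list(range(k_obs)) + list(range(K, K + n - k_obs))]
        bg = [f"g{i}" for i in range(N)]
        (res,) = hypergeom_enrichment(gene_list, {"T": [f"g{i}" for i in range(K)]}, bg)
        assert res.p_value == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_small_instances_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(8, 21))
        K = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        bg = [f"g{i}" for i in range(N)]
        term = list(rng.choice(bg, size=K, replace=False))
        lst = list(rng.choice(bg, size=n, replace=False))
        (res,) = hypergeom_enrichment(lst, {"T": term}, bg)
        k_obs = len(set(term) & set(lst))
        total = hits = 0
        for draw in itertools.combinations(range(N), n):
            total += 1
            if len({bg[i] for i in draw} & set(term)) >= k_obs:
                hits += 1
        assert res.p_value == pytest.approx(hits / total, rel=1e-10)

    def test_planted_term_ranks_first(self):
        bg, sets, lst, truth = planted_enrichment(
            n_background=5000, n_terms=50, term_size=50, list_size=100,
            enrich_factor=5.0, seed=2,
        )
        results = hypergeom_enrichment(lst, sets, bg)
        assert results[0].term_id == truth.payload["enriched_term"]

    def test_list_gene_outside_background_rejected(self):
        with pytest.raises(StructuralError):
            hypergeom_enrichment(["x"], {"T": ["a"]}, ["a", "b"])


def test_gmt_round_trip(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("T1\tdesc\tg1\tg2\nT2\tdesc\tg3\n", encoding="utf-8")
    assert read_gmt(path) == {"T1": ["g1", "g2"], "T2": ["g3"]}
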