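"""The four master-TF nomination analyses: exact rank-sum p-values,
JSD specificity scoring against an entropy oracle, ROSE stitching and
elbow calling, motif scanning, clique enumeration against exhaustive
subset search, and the consensus rule."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rcc_regulome import master_tf as mtf
from rcc_regulome.core_genomics import GenomicInterval, Peak, PeakSet, TssAnnotation
from rcc_regulome.stats import rank_sum_one_sided


def entropy_oracle(p, base=2):
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return -(p * np.log(p) / np.log(base)).sum()


def jsd_oracle(p, q):
    p = np.asarray(p, float) / np.sum(p)
    q = np.asarray(q, float) / np.sum(q)
    m = (p + q) / 2
    return entropy_oracle(m) - 0.5 * entropy_oracle(p) - 0.5 * entropy_oracle(q)


class TestRankSumExact:
    def test_complete_separation_3v3_is_one_twentieth(self):
        # all C(6,3)=20 rank splits; only one puts all query values on top
        p = rank_sum_one_sided([30, 40, 50], [1, 2, 3], alternative="greater")
        assert p == pytest.approx(1 / 20)

    def test_matches_enumeration_oracle(self, rng):
        q = rng.normal(size=4)
        r = rng.normal(size=4)
        pooled = np.concatenate([q, r])
        ranks = pd.Series(pooled).rank().to_numpy()
        obs = ranks[:4].sum()
        count = sum(
            1 for c in combinations(range(8), 4) if ranks[list(c)].sum() >= obs
        )
        expected = count / len(list(combinations(range(8), 4)))
        assert rank_sum_one_sided(q, r) == pytest.approx(expected)

    def test_identical_constant_data_p_one(self):
        assert rank_sum_one_sided([5, 5, 5], [5, 5, 5]) == 1.0


class TestDifferentialTfExpression:
    def test_separated_tf_detected_and_low_fpkm_excluded(self):
        samples = [f"s{i}" for i in range(6)]
        df = pd.DataFrame({"high": [30, 40, 50, 1, 2, 3], "dim": [8, 8, 8, 1, 1, 1]}).T
        df.columns = samples
        labels = pd.Series(["q"] * 3 + ["r"] * 3, index=samples)
        res = mtf.differential_tf_expression(df, labels, "q")
        assert res.loc["high", "pvalue"] == pytest.approx(0.05)
        assert not res.loc["dim", "tested"]  # max histotype mean 8 < 10 FPKM
        assert np.isnan(res.loc["dim", "pvalue"])

    def test_identical_distributions_fail(self):
        samples = [f"s{i}" for i in range(6)]
        df = pd.DataFrame({"flat": [20, 21, 22, 20, 21, 22]}).T
        df.columns = samples
        labels = pd.Series(["q"] * 3 + ["r"] * 3, index=samples)
        res = mtf.differential_tf_expression(df, labels, "q")
        assert not res.loc["flat", "de_pass"]
        assert res.loc["flat", "pvalue"] > 0.3

    def test_small_group_error(self):
        df = pd.DataFrame({"t": [1, 2, 3]}).T
        df.columns = ["a", "b", "c"]
        labels = pd.Series(["q", "r", "r"], index=df.columns)
        with pytest.raises(ValueError):
            mtf.differential_tf_expression(df, labels, "q")


class TestCactsScores:
    def test_one_hot_tf_scores_one(self):
        m = pd.DataFrame({"q": [10.0, 5.0], "b1": [0.0, 5.0], "b2": [0.0, 5.0]},
                         index=["spec", "flat"])
        res = mtf.cacts_scores(m, "q")
        assert res.loc["spec", "jsd_divergence"] == pytest.approx(0.0, abs=1e-6)
        assert res.loc["spec", "specificity_score"] == pytest.approx(1.0, abs=1e-3)

    def test_disjoint_support_scores_zero(self):
        m = pd.DataFrame({"q": [0.0], "b1": [10.0]}, index=["anti"])
        res = mtf.cacts_scores(m, "q")
        assert res.loc["anti", "jsd_divergence"] == pytest.approx(1.0, abs=1e-6)
        assert res.loc["anti", "specificity_score"] == pytest.approx(0.0, abs=1e-3)

    def test_half_half_closed_form(self):
        # observed [0.5, 0.5] vs ideal [1, 0]: jsd = H([.75,.25]) - 0.5
        m = pd.DataFrame({"q": [5.0], "b1": [5.0]}, index=["tf"])
        res = mtf.cacts_scores(m, "q")
        expected_jsd = entropy_oracle([0.75, 0.25]) - 0.5
        assert res.loc["tf", "jsd_divergence"] == pytest.approx(expected_jsd, abs=1e-9)
        assert res.loc["tf", "specificity_score"] == pytest.approx(1 - np.sqrt(expected_jsd), abs=1e-9)
        assert res.loc["tf", "jsd_divergence"] == pytest.approx(0.3113, abs=1e-4)
        assert res.loc["tf", "specificity_score"] == pytest.approx(0.4421, abs=1e-4)

    def test_jsd_matches_entropy_oracle_on_random_profiles(self, rng):
        types = list("abcde")
        m = pd.DataFrame(rng.gamma(2.0, 5.0, size=(30, 5)), columns=types)
        res = mtf.cacts_scores(m, "c")
        shifted = m - m.min().min()
        prof = shifted.where(shifted > 0, 1e-17)
        prof = prof.div(prof.sum(axis=1), axis=0)
        ideal = np.array([0, 0, 1, 0, 0], dtype=float)
        for i in range(30):
            assert res["jsd_divergence"].iloc[i] == pytest.approx(
                jsd_oracle(prof.iloc[i].to_numpy(), ideal), abs=1e-9
            )
        assert (res["jsd_divergence"].between(0, 1)).all()

    def test_candidate_requires_both_top_quantiles(self, rng):
        n = 100
        m = pd.DataFrame(
            {"q": np.ones(n) * 10, "b1": np.ones(n) * 10, "b2": np.ones(n) * 10},
            index=[f"tf{i}" for i in range(n)],
        )
        # one specific-and-high TF, one specific-but-dim TF
        m.loc["tf0"] = [100.0, 0.0, 0.0]
        m.loc["tf1"] = [0.001, 0.0, 0.0]
        res = mtf.cacts_scores(m, "q")
        assert res.loc["tf0", "cacts_candidate"]
        assert not res.loc["tf1", "cacts_candidate"]  # high specificity, low mean


class TestStitchAndRose:
    def make_peaks(self, coords_scores):
        return PeakSet(
            Peak(GenomicInterval("chr1", s, e), score=sc) for s, e, sc in coords_scores
        )

    def test_gap_rule(self):
        regions = mtf.stitch_peaks(
            self.make_peaks([(100, 200, 1.0), (300, 400, 1.0), (20000, 20100, 1.0)])
        )
        spans = [(r.interval.start, r.interval.end) for r in regions]
        assert spans == [(100, 400), (20000, 20100)]
        assert regions[0].total_signal == pytest.approx(2.0)

    def test_stitch_zero_merges_only_bookended(self):
        regions = mtf.stitch_peaks(
            self.make_peaks([(0, 100, 1.0), (100, 200, 1.0), (201, 300, 1.0)]),
            stitch_bp=0,
        )
        assert [(r.interval.start, r.interval.end) for r in regions] == [(0, 200), (201, 300)]

    def test_all_within_one_window_single_region(self):
        regions = mtf.stitch_peaks(self.make_peaks([(0, 100, 1.0), (5000, 5100, 1.0), (10000, 10100, 1.0)]))
        assert len(regions) == 1

    def test_elbow_isolates_outlier(self):
        regions = [
            mtf.StitchedRegion(GenomicInterval("chr1", i * 1000, i * 1000 + 100), s, 1)
            for i, s in enumerate([100.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        ]
        out = mtf.call_superenhancers(regions)
        supers = [r.total_signal for r in out if r.is_super]
        assert supers == [100.0]
        assert [r.rank for r in out] == [1, 2, 3, 4, 5, 6]

    def test_constant_signal_no_superenhancers(self):
        regions = [
            mtf.StitchedRegion(GenomicInterval("chr1", i * 1000, i * 1000 + 100), 7.0, 1)
            for i in range(5)
        ]
        with pytest.warns(UserWarning):
            out = mtf.call_superenhancers(regions)
        assert not any(r.is_super for r in out)

    def test_adding_sub_cutoff_region_never_promotes(self, rng):
        base = sorted(rng.lognormal(1.0, 1.0, size=30))
        regions = [
            mtf.StitchedRegion(GenomicInterval("chr1", i * 1000, i * 1000 + 100), float(s), 1)
            for i, s in enumerate(base)
        ]
        out = mtf.call_superenhancers(list(regions))
        cutoff = min(r.total_signal for r in out if r.is_super)
        before = {r.interval.start for r in out if r.is_super}
        regions2 = regions + [
            mtf.StitchedRegion(GenomicInterval("chr1", 999_000, 999_100), cutoff * 0.5, 1)
        ]
        out2 = mtf.call_superenhancers(regions2)
        after = {r.interval.start for r in out2 if r.is_super and r.interval.start != 999_000}
        assert before <= after or before == after
        assert not any(r.is_super for r in out2 if r.interval.start == 999_000)


class TestSeGeneAssignment:
    def tss(self, entries):
        return [TssAnnotation(g, GenomicInterval("chr1", p, p + 1)) for g, p in entries]

    def test_nearest_tie_and_exact(self):
        regions = [mtf.StitchedRegion(GenomicInterval("chr1", 1000, 2000), 1.0, 1)]
        out = mtf.assign_se_to_gene(regions, self.tss([("geneA", 1400), ("geneB", 5000)]))
        assert out[0].assigned_gene == "geneA"
        out = mtf.assign_se_to_gene(regions, self.tss([("geneA", 1400), ("geneB", 1600)]))
        assert out[0].assigned_gene == "geneA"  # equidistant from midpoint 1500
        out = mtf.assign_se_to_gene(regions, self.tss([("geneC", 1500)]))
        assert out[0].assigned_gene == "geneC"

    def test_missing_chromosome_warns(self):
        regions = [mtf.StitchedRegion(GenomicInterval("chr9", 0, 10), 1.0, 1)]
        with pytest.warns(UserWarning):
            out = mtf.assign_se_to_gene(regions, self.tss([("geneA", 0)]))
        assert out[0].assigned_gene is None


class TestSeRankMatrix:
    def region(self, gene, rank, is_super=True):
        r = mtf.StitchedRegion(GenomicInterval("chr1", 0, 10), 1.0, 1, rank=rank, is_super=is_super)
        r.assigned_gene = gene
        return r

    def test_minimum_rule_and_fill(self):
        per_sample = {
            "s1": [self.region("tfA", 7), self.region("tfA", 30), self.region("x", 1477)],
            "s2": [self.region("tfB", 1)],
        }
        mat, fill = mtf.tf_se_rank_matrix(per_sample, ["tfA", "tfB"])
        assert fill == 1477
        assert mat.loc["tfA", "s1"] == 7
        assert mat.loc["tfA", "s2"] == 1477
        assert mat.loc["tfB", "s2"] == 1

    def test_differential_rank_exact_and_exclusion(self):
        cols = [f"q{i}" for i in range(3)] + [f"r{i}" for i in range(3)]
        mat = pd.DataFrame(
            {c: {"good": v, "bad": 1200} for c, v in zip(cols, [1, 2, 3, 1477, 1476, 1475])}
        )
        labels = pd.Series(["h"] * 3 + ["o"] * 3, index=cols)
        res = mtf.differential_se_rank(mat, labels, "h")
        assert res.loc["good", "pvalue"] == pytest.approx(0.05)
        assert not res.loc["bad", "tested"]  # mean rank 1200 > 1000


class TestMotifScan:
    def test_consensus_hit_and_reverse_complement(self):
        pwm = np.array([[0.97, 0.01, 0.01, 0.01],
                        [0.01, 0.97, 0.01, 0.01],
                        [0.01, 0.01, 0.97, 0.01],
                        [0.01, 0.01, 0.01, 0.97]])  # consensus ACGT
        thr = 0.8 * mtf.pwm_log_odds(pwm).max(axis=1).sum()
        assert mtf.scan_sequence(pwm, "TTTTACGTTTTT", thr)
        assert mtf.scan_sequence(pwm, "AAAAACGTAAAA"[::-1].translate(str.maketrans("ACGT", "TGCA")), thr)
        assert not mtf.scan_sequence(pwm, "AAAAAAAAAAAA", thr)

    def test_threshold_above_max_never_hits(self):
        pwm = np.full((4, 4), 0.25)
        assert not mtf.scan_sequence(pwm, "ACGTACGTACGT", threshold=1.0)

    def test_non_acgt_windows_skipped_with_warning(self):
        pwm = np.array([[0.97, 0.01, 0.01, 0.01]] * 2)
        with pytest.warns(UserWarning):
            assert mtf.scan_sequence(pwm, "NNAANN", threshold=1.0)


def exhaustive_maximal_cliques(g):
    nodes = list(g.nodes)
    cliques = []
    for r in range(2, len(nodes) + 1):
        for sub in combinations(nodes, r):
            if all(g.has_edge(a, b) for a, b in combinations(sub, 2)):
                cliques.append(frozenset(sub))
    return {c for c in cliques if not any(c < d for d in cliques)}


class TestCliques:
    def graph(self, edges, nodes=()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        return g

    def test_triangle_single_clique(self):
        cl = mtf.enumerate_cliques(self.graph([("A", "B"), ("B", "C"), ("A", "C")]))
        assert set(cl) == {frozenset("ABC")}

    def test_path_two_cliques(self):
        cl = mtf.enumerate_cliques(self.graph([("A", "B"), ("B", "C")]))
        assert set(cl) == {frozenset("AB"), frozenset("BC")}

    def test_no_edges_no_cliques(self):
        assert mtf.enumerate_cliques(self.graph([], nodes="ABC")) == []

    def test_matches_exhaustive_enumeration_on_random_graphs(self, rng):
        for n in range(2, 7):
            for _ in range(20):
                g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
                assert set(mtf.enumerate_cliques(g)) == exhaustive_maximal_cliques(g)

    def test_build_graph_requires_mutuality_and_self_regulation(self):
        se_of = {"A": "rA", "B": "rB", "C": "rC"}
        hits = {("A", "rA"), ("B", "rB"),  # both self-regulate
                ("A", "rB"), ("B", "rA"),  # mutual A-B
                ("C", "rA")}  # C not self-regulating, one-way
        g = mtf.build_clique_graph(hits, se_of, expressed_tfs={"A", "B", "C"})
        assert set(g.nodes) == {"A", "B"}
        assert set(map(frozenset, g.edges)) == {frozenset("AB")}


class TestCes:
    def test_fraction_of_cliques(self):
        cl = [frozenset("AB"), frozenset("BC")]
        scores = mtf.ces(cl, ["A", "B", "C", "D"])
        assert scores["B"] == 1.0
        assert scores["A"] == scores["C"] == 0.5
        assert scores["D"] == 0.0

    def test_no_cliques_all_zero(self):
        assert (mtf.ces([], ["A", "B"]) == 0).all()

    def test_differential_ces_exclusion_and_pass(self):
        cols = [f"q{i}" for i in range(3)] + [f"r{i}" for i in range(3)]
        mat = pd.DataFrame(
            {c: {"strong": v, "dim": v / 15} for c, v in zip(cols, [0.4, 0.5, 0.6, 0.0, 0.0, 0.0])}
        )
        labels = pd.Series(["h"] * 3 + ["o"] * 3, index=cols)
        res = mtf.differential_ces(mat, labels, "h")
        assert res.loc["strong", "pvalue"] == pytest.approx(0.05)
        assert not res.loc["dim", "tested"]  # mean query CES 0.033 < 0.05


class TestConsensusRule:
    def table(self, de, cacts, se, ces_):
        idx = ["tf"]
        return (
            pd.DataFrame({"de_pass": [de]}, index=idx),
            pd.DataFrame({"cacts_candidate": [cacts]}, index=idx),
            pd.DataFrame({"se_pass": [se]}, index=idx),
            pd.DataFrame({"ces_pass": [ces_]}, index=idx),
        )

    @pytest.mark.parametrize(
        "de,cacts,se,ces_,master,evidence",
        [
            (True, True, False, False, True, 2),
            (False, True, True, False, False, 2),  # no DE -> never master
            (True, True, True, True, True, 4),
            (True, False, False, False, False, 1),
        ],
    )
    def test_rule(self, de, cacts, se, ces_, master, evidence):
        out = mtf.nominate_master_tfs(*self.table(de, cacts, se, ces_))
        assert bool(out.loc["tf", "consensus_master"]) is master
        assert out.loc["tf", "evidence_count"] == evidence

    def test_planted_masters_recovered(self, bundle, master_tf_output):
        from rcc_regulome.pipeline import master_tf_recovery

        rec = master_tf_recovery(master_tf_output, bundle.truth.master_tf_labels)
        assert rec["sensitivity"] >= 0.9
        assert rec["false_nomination_rate"] <= 0.1
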