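"""Consensus calling, individual matching, error rates, probability of identity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtscr.genotypes import (
    allele_frequencies_from_consensus,
    build_consensus,
    consensus_panel,
    error_rates,
    match_individuals,
    pid_random_subsets,
    probability_of_identity,
    sampling_summary,
)
from rtscr.simulate import simulate_genotype_panel


def _replicates(sample_id, locus_calls):
    """Long-form replicate table from {locus: [(a1, a2) or None per replicate]}."""
    rows = []
    for locus, calls in locus_calls.items():
        for rep, call in enumerate(calls, start=1):
            a1, a2 = call if call else (None, None)
            rows.append((sample_id, rep, locus, a1, a2))
    return pd.DataFrame(rows, columns=["sample_id", "replicate", "locus", "allele1", "allele2"])


class TestConsensusRules:
    @pytest.mark.parametrize(
        "calls, expected",
        [
            # heterozygote confirmed in two independent PCRs
            ([("A", "B"), ("A", "B"), ("A", "A"), None], ("A", "B")),
            # homozygote needs three replicates; two is not enough
            ([("A", "A"), ("A", "A"), None, None], None),
            ([("A", "A"), ("A", "A"), ("A", "A"), None], ("A", "A")),
            # a single heterozygous observation is not a call
            ([("A", "B"), ("A", "C"), ("B", "C"), None], None),
            # two distinct heterozygotes seen twice each: ambiguous, no call
            ([("A", "B"), ("A", "B"), ("A", "C"), ("A", "C")], None),
            # allele order within a pair is irrelevant
            ([("B", "A"), ("A", "B"), None, None], ("A", "B")),
        ],
    )
    def test_per_locus_rules(self, calls, expected):
        table = _replicates("s1", {"L01": calls})
        cons = build_consensus(table, min_called=1)
        assert cons.call("L01") == expected

    def test_acceptance_threshold_is_more_than_14_loci(self):
        good = {f"L{k:02d}": [("A", "B"), ("A", "B"), None, None] for k in range(15)}
        assert build_consensus(_replicates("s", good)).accepted
        assert build_consensus(_replicates("s", good)).n_called == 15
        onefewer = dict(itertools.islice(good.items(), 14))
        cons14 = build_consensus(_replicates("s", onefewer))
        assert cons14.n_called == 14 and not cons14.accepted

    def test_replicate_order_invariance(self):
        calls = {
            "L01": [("A", "B"), ("A", "A"), ("A", "B"), ("A", "A")],
            "L02": [("C", "C"), ("C", "C"), ("C", "C"), ("C", "D")],
        }
        t = _replicates("s", calls)
        a = build_consensus(t, min_called=1)
        b = build_consensus(t.sample(frac=1.0, random_state=7), min_called=1)
        assert a.calls == b.calls

    def test_sex_marker_rule(self):
        calls = {"LutSRY": [("Y", "Y"), ("Y", "Y"), None, None],
                 "L01": [("A", "B"), ("A", "B"), None, None]}
        cons = build_consensus(_replicates("s", calls), min_called=1, male_marker="LutSRY")
        assert cons.sex == "M"
        calls["LutSRY"] = [("Y", "Y"), None, None, None]
        cons = build_consensus(_replicates("s", calls), min_called=1, male_marker="LutSRY")
        assert cons.sex == "F"


class TestMatching:
    def _panel(self, genos):
        frames = [
            _replicates(sid, {loc: [pair, pair, None, None] for loc, pair in g.items()})
            for sid, g in genos.items()
        ]
        return pd.concat(frames, ignore_index=True)

    def test_identical_genotypes_merge(self):
        g = {f"L{k:02d}": ("A", "B") for k in range(20)}
        table = self._panel({"s1": g, "s2": g})
        assign = match_individuals(consensus_panel(table))
        assert assign["individual_id"].nunique() == 1

    def test_single_locus_mismatch_splits_at_zero_tolerance(self):
        g1 = {f"L{k:02d}": ("A", "B") for k in range(20)}
        g2 = dict(g1)
        g2["L00"] = ("A", "C")
        assign = match_individuals(consensus_panel(self._panel({"s1": g1, "s2": g2})))
        assert assign["individual_id"].nunique() == 2
        relaxed = match_individuals(
            consensus_panel(self._panel({"s1": g1, "s2": g2})), mismatch_tolerance=1
        )
        assert relaxed["individual_id"].nunique() == 1

    def test_empty_input(self):
        assert len(match_individuals([])) == 0

    def test_simulated_panel_recovers_13_individuals(self):
        table, truth, _ = simulate_genotype_panel(
            n_individuals=13, n_samples=120, dropout=0.2, missing=0.08, seed=4
        )
        cons = consensus_panel(table)
        # with four replicates a rare false homozygous consensus call can
        # survive, so near-matches are relinked at one-locus tolerance
        assign = match_individuals(cons, mismatch_tolerance=1)
        # the accepted samples must partition exactly into the 13 source otters
        merged = assign.merge(truth.rename("truth"), left_on="sample_id", right_index=True)
        pairs = merged.groupby("individual_id")["truth"].nunique()
        assert (pairs == 1).all()                      # no wrong merges
        assert merged["truth"].nunique() == assign["individual_id"].nunique() == 13


class TestErrorRates:
    def test_perfect_replicates_have_zero_rates(self):
        g = {f"L{k:02d}": ("A", "B") for k in range(16)}
        table = pd.concat(
            [_replicates("s1", {loc: [pair] * 4 for loc, pair in g.items()})],
            ignore_index=True,
        )
        er = error_rates(table, consensus_panel(table))
        assert er.mean_dropout == 0.0
        assert er.mean_false_allele == 0.0

    def test_half_dropout_at_one_locus(self):
        calls = {"L01": [("A", "B"), ("A", "B"), ("A", "A"), ("B", "B")]}
        table = _replicates("s1", calls)
        er = error_rates(table, [build_consensus(table, min_called=1)])
        assert er.dropout_per_locus["L01"] == pytest.approx(0.5)

    def test_dropout_unidentifiable_without_heterozygous_consensus(self):
        calls = {"L01": [("A", "A")] * 4}
        table = _replicates("s1", calls)
        er = error_rates(table, [build_consensus(table, min_called=1)])
        assert np.isnan(er.dropout_per_locus["L01"])

    @staticmethod
    def _expected_consensus_conditioned_dropout(d, miss, nrep=4):
        """Exact E[homozygous fraction | locus consensus-called heterozygous].

        The estimator references the consensus, which requires >= 2 identical
        heterozygous replicates, so it conditions away high-dropout outcomes.
        Enumerate every replicate pattern (missing / het / hom-a / hom-b) of a
        true heterozygote and average the homozygous fraction over patterns
        that yield a heterozygous consensus call.
        """
        import itertools as it

        probs = {"x": miss, "h": (1 - miss) * (1 - d),
                 "a": (1 - miss) * d / 2, "b": (1 - miss) * d / 2}
        num = den = 0.0
        for pat in it.product("xhab", repeat=nrep):
            p = np.prod([probs[c] for c in pat])
            nh = pat.count("h")
            na, nb = pat.count("a"), pat.count("b")
            if nh < 2 or na >= 3 or nb >= 3:     # no het consensus call
                continue
            nobs = nh + na + nb
            num += p * (na + nb)
            den += p * nobs
        return num / den

    def test_simulated_dropout_rate_recovered(self):
        d, miss = 0.35, 0.05
        table, _, _ = simulate_genotype_panel(
            n_individuals=10, n_samples=60, dropout=d, missing=miss,
            false_allele=0.0, seed=11,
        )
        cons = consensus_panel(table)
        er = error_rates(table, cons)
        expected = self._expected_consensus_conditioned_dropout(d, miss)
        assert er.mean_dropout == pytest.approx(expected, abs=0.05)


class TestProbabilityOfIdentity:
    def test_biallelic_half_half_locus(self):
        # brute force over the 3 genotypes: PID = 0.25^2 + 0.5^2 + 0.25^2 = 0.375
        stats = probability_of_identity({"L": {"a": 0.5, "b": 0.5}})
        assert stats.pid == pytest.approx(0.375)

    def test_monomorphic_locus(self):
        stats = probability_of_identity({"L": {"a": 1.0}})
        assert stats.pid == 1.0 and stats.pidsibs == 1.0

    def test_unnormalized_frequencies_rejected(self):
        with pytest.raises(ValueError):
            probability_of_identity({"L": {"a": 0.5, "b": 0.4}})

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0.05, 10.0), min_size=2, max_size=8))
    def test_formulas_match_brute_force_and_ordering(self, raw):
        p = np.array(raw) / np.sum(raw)
        freqs = {"L": {f"a{i}": float(v) for i, v in enumerate(p)}}
        stats = probability_of_identity(freqs)
        # brute force: sum over genotype probabilities squared
        brute = 0.0
        for i in range(len(p)):
            for k in range(i, len(p)):
                g = p[i] ** 2 if i == k else 2 * p[i] * p[k]
                brute += g**2
        assert stats.pid == pytest.approx(brute, rel=1e-9)
        assert 0.0 <= stats.pid <= stats.pidsibs <= 1.0

    def test_adding_loci_never_increases_pid(self):
        f1 = {"L1": {"a": 0.5, "b": 0.5}}
        f2 = {**f1, "L2": {"a": 0.3, "b": 0.3, "c": 0.4}}
        assert probability_of_identity(f2).pid <= probability_of_identity(f1).pid

    def test_random_subsets_deterministic_and_sized(self):
        _, _, freqs = simulate_genotype_panel(seed=2)
        sub = pid_random_subsets(freqs, subset_size=14, n_subsets=10, seed=3)
        assert len(sub) == 10
        assert all(len(s.split(",")) == 14 for s in sub["loci"])
        again = pid_random_subsets(freqs, subset_size=14, n_subsets=10, seed=3)
        pd.testing.assert_frame_equal(sub, again)
        full = probability_of_identity(freqs)
        assert (sub["pid"] >= full.pid - 1e-15).all()   # fewer loci, weaker power

    def test_empirical_frequencies_sum_to_one(self):
        table, _, _ = simulate_genotype_panel(n_samples=40, seed=9)
        freqs = allele_frequencies_from_consensus(consensus_panel(table))
        for loc, f in freqs.items():
            assert sum(f.values()) == pytest.approx(1.0)


class TestSurveySummary:
    def test_study_scale_summary_arithmetic(self):
        # 120 collected samples, 71 accepted genotypes, 13 individuals, 8 M : 5 F
        sizes = [23, 12, 7, 5, 3, 3, 3, 3, 3, 3, 2, 2, 2]
        rows, k = [], 0
        for i, ns in enumerate(sizes):
            sex = "M" if i < 8 else "F"
            for _ in range(ns):
                rows.append((f"s{k}", f"ID{i:02d}", 18, sex))
                k += 1
        assign = pd.DataFrame(rows, columns=["sample_id", "individual_id", "n_called", "sex"])
        s = sampling_summary(120, assign)
        assert s["success_rate"] == pytest.approx(71 / 120)
        assert round(100 * s["success_rate"], 1) == 59.2
        assert s["mean_recaptures"] == pytest.approx(5.46, abs=0.005)
        assert s["males"] == 8 and s["females"] == 5
        assert s["sex_ratio"] == pytest.approx(1.6)
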