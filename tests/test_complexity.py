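import math

import numpy as np
import pytest
from scipy import stats

from ehrmtl.complexity import (
    build_histogram,
    complexity_report,
    entropy,
    fnv1a64,
    kl_divergence,
)
from ehrmtl.errors import ConfigurationError, InsufficientDataError
from ehrmtl.rules import make_complexity_controlled_rule, satisfying_signatures
from ehrmtl.synthetic import PatientRecord


def _record(i, codes, hidden=True):
    return PatientRecord(
        patient_id=f"p{i}",
        codes=frozenset(codes),
        age=50,
        sex="M",
        race="other",
        ethnicity="non_hispanic",
        latent_flags=frozenset(),
        hidden_flag=hidden,
    )


def _cohort_from_signatures(signatures, oracle_codes):
    """Materialize records whose oracle signature is exactly the given string."""
    records = []
    for i, sig in enumerate(signatures):
        codes = {oracle_codes[j] for j, bit in enumerate(sig) if bit == "1"}
        records.append(_record(i, codes))
    return records


class TestHistogram:
    def test_single_combination_occupies_one_bucket(self):
        hist = build_histogram(["101"] * 40, ["000"] * 60)
        assert (hist.counts_pos > 0).sum() == 1
        assert hist.counts_pos.sum() == 40

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        pos = ["".join(rng.choice(["0", "1"], 6)) for _ in range(1000)]
        neg = ["".join(rng.choice(["0", "1"], 6)) for _ in range(1000)]
        hist = build_histogram(pos, neg, n_buckets=16)
        assert hist.counts_pos.sum() == 1000
        assert hist.counts_neg.sum() == 1000

    def test_direct_indexing_never_collides(self):
        sigs = [format(i, "05b") for i in range(32)]
        hist = build_histogram(sigs, sigs, n_buckets=32, hash_name="direct")
        assert np.array_equal(hist.counts_pos, np.ones(32, dtype=int))

    def test_direct_indexing_requires_enough_buckets(self):
        with pytest.raises(ConfigurationError):
            build_histogram(["000000"], ["000001"], n_buckets=32, hash_name="direct")

    def test_empty_side_rejected(self):
        with pytest.raises(InsufficientDataError):
            build_histogram([], ["0"])

    def test_hash_matches_published_fnv1a_vectors(self):
        # FNV-1a 64-bit reference vectors; also pins cross-run stability
        assert fnv1a64("") == 0xCBF29CE484222325
        assert fnv1a64("a") == 0xAF63DC4C8601EC8C
        assert fnv1a64("foobar") == 0x85944171F73967E8


class TestEntropy:
    def test_point_mass_is_zero(self):
        assert entropy([0, 10, 0]) == 0.0

    def test_uniform_is_log_buckets(self):
        assert entropy(np.ones(32)) == pytest.approx(math.log(32))

    def test_three_one_split(self):
        assert entropy([3, 1]) == pytest.approx(0.5623, abs=1e-4)

    def test_base_two(self):
        assert entropy([1, 1], base=2) == pytest.approx(1.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=32)
        counts[0] = 1  # guarantee nonzero
        assert entropy(counts) == pytest.approx(stats.entropy(counts))

    def test_all_zero_rejected(self):
        with pytest.raises(InsufficientDataError):
            entropy([0, 0, 0])

    def test_range_invariant(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            counts = rng.integers(0, 100, size=32)
            if counts.sum() == 0:
                continue
            h = entropy(counts)
            assert 0.0 <= h <= math.log(32) + 1e-12


class TestKlDivergence:
    def test_identical_histograms_give_zero(self):
        assert kl_divergence([3, 1, 5], [3, 1, 5], smoothing_alpha=0.5) == 0.0
        assert kl_divergence([2, 2], [4, 4], smoothing_alpha=0.0) == 0.0

    def test_hand_computed_two_bucket_case(self):
        # P+=[0.75,0.25], P-=[0.5,0.5]
        assert kl_divergence([3, 1], [2, 2], smoothing_alpha=0.0) == pytest.approx(
            0.1308, abs=1e-4
        )

    def test_disjoint_support(self):
        smoothed = kl_divergence([4, 0], [0, 4], smoothing_alpha=0.5)
        assert np.isfinite(smoothed) and smoothed > 0
        # hand evaluation: P+=[0.9,0.1], P-=[0.1,0.9]
        expected = 0.9 * math.log(9) + 0.1 * math.log(1 / 9)
        assert smoothed == pytest.approx(expected)
        with pytest.warns(RuntimeWarning, match="infinite"):
            assert kl_divergence([4, 0], [0, 4], smoothing_alpha=0.0) == math.inf

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        p = rng.integers(1, 50, size=16)
        q = rng.integers(1, 50, size=16)
        assert kl_divergence(p, q, smoothing_alpha=0.0) == pytest.approx(
            stats.entropy(p, q)
        )

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            p = rng.integers(0, 30, size=32)
            q = rng.integers(0, 30, size=32)
            if p.sum() == 0 or q.sum() == 0:
                continue
            assert kl_divergence(p, q, smoothing_alpha=0.5) >= 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence([1, 2], [1, 2, 3])


class TestComplexityReport:
    def test_single_combination_rule_has_zero_entropy(self):
        rule = make_complexity_controlled_rule(5, 1, seed=0)
        sig = next(iter(satisfying_signatures(rule)))
        cases = _cohort_from_signatures([sig] * 50, rule.oracle_codes)
        controls = _cohort_from_signatures(["0" * 5] * 200, rule.oracle_codes)
        if sig == "00000":  # ensure controls differ from the case signature
            controls = _cohort_from_signatures(["11111"] * 200, rule.oracle_codes)
        records = cases + controls
        labels = np.array([1] * 50 + [0] * 200)
        report = complexity_report(rule, records, labels)
        assert report.entropy_pos == 0.0
        assert report.histogram.hash_name == "direct"

    @pytest.mark.parametrize("n_satisfying", [1, 4, 16])
    def test_uniform_satisfying_sets_recover_log_support(self, n_satisfying):
        """Cases drawn uniformly over k satisfying combinations have entropy
        close to log(k) once the sample is large."""
        rule = make_complexity_controlled_rule(5, n_satisfying, seed=1)
        sats = sorted(satisfying_signatures(rule))
        rng = np.random.default_rng(5)
        case_sigs = [sats[i] for i in rng.integers(0, len(sats), size=2500)]
        non_sats = sorted(set(format(i, "05b") for i in range(32)) - set(sats))
        if not non_sats:
            non_sats = ["00000"]
        ctrl_sigs = [non_sats[i] for i in rng.integers(0, len(non_sats), size=2500)]
        records = _cohort_from_signatures(case_sigs + ctrl_sigs, rule.oracle_codes)
        labels = np.array([1] * 2500 + [0] * 2500)
        report = complexity_report(rule, records, labels)
        assert report.entropy_pos == pytest.approx(math.log(n_satisfying), abs=0.1)

    def test_common_source_distributions_have_small_kl(self):
        rng = np.random.default_rng(6)
        sigs = [format(i, "05b") for i in range(32)]
        probs = rng.dirichlet(np.ones(32))
        draw = lambda: [sigs[i] for i in rng.choice(32, size=5000, p=probs)]
        records = _cohort_from_signatures(draw() + draw(), tuple(range(5)))
        labels = np.array([1] * 5000 + [0] * 5000)
        rule = make_complexity_controlled_rule(5, 3, seed=2)
        report = complexity_report(rule, records, labels)
        assert report.kl_pos_vs_neg < 0.05

    def test_hashing_fewer_buckets_never_increases_entropy(self):
        rng = np.random.default_rng(7)
        sigs = ["".join(rng.choice(["0", "1"], 10)) for _ in range(3000)]
        entropies = []
        for n_buckets in (32, 16, 8):
            hist = build_histogram(sigs, sigs, n_buckets=n_buckets, hash_name="fnv1a")
            entropies.append(entropy(hist.counts_pos))
        assert entropies[0] >= entropies[1] >= entropies[2]
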