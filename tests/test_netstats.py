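"""Prevalence curves, size classes, enrichment and co-occurrence statistics."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from viranet import netstats as ns
from viranet.dataset_io import GenomeRecord


def _genomes(lengths, morphology="unknown"):
    return [
        GenomeRecord(f"g{i}", 100 + i, L, "dsDNA", "bacteria", morphology)
        for i, L in enumerate(lengths)
    ]


class TestPrevalenceCurve:
    def test_counting_example(self):
        genomes = _genomes([10_000, 50_000, 120_000, 200_000])
        curve = ns.prevalence_curve(genomes, {"g2", "g3"}, [0, 100_000])
        at = curve.set_index("threshold")
        assert at.loc[0.0, "fraction"] == pytest.approx(0.5)
        assert at.loc[100_000.0, "fraction"] == pytest.approx(1.0)
        assert at.loc[100_000.0, "n_genomes"] == 2

    def test_all_positive_gives_unit_fraction(self):
        genomes = _genomes([10_000, 50_000])
        curve = ns.prevalence_curve(genomes, {"g0", "g1"}, [0, 20_000])
        assert (curve["fraction"] == 1.0).all()

    def test_empty_stratum_point_omitted(self):
        genomes = _genomes([10_000])
        curve = ns.prevalence_curve(genomes, set(), [0, 1_000_000])
        assert curve["threshold"].tolist() == [0.0]

    def test_counts_non_increasing_in_threshold(self, rng):
        genomes = _genomes(rng.integers(2_000, 400_000, size=50).tolist())
        curve = ns.prevalence_curve(genomes, set(), np.linspace(0, 3e5, 20))
        assert (np.diff(curve["n_genomes"]) <= 0).all()


class TestClassPrevalence:
    def test_gap_between_classes_is_unclassed(self):
        table = ns.class_prevalence(_genomes([30_000]), set())
        row = table.set_index("size_class").loc["unclassed"]
        assert row["n_genomes"] == 1

    def test_fractions_per_class(self):
        genomes = _genomes([10_000, 20_000, 120_000, 200_000, 250_000])
        table = ns.class_prevalence(genomes, {"g2", "g3"}).set_index("size_class")
        assert table.loc["small", "fraction"] == pytest.approx(0.0)
        assert table.loc["medium", "fraction"] == pytest.approx(1.0)
        assert table.loc["jumbo", "fraction"] == pytest.approx(0.5)

    def test_empty_class_reports_nan_not_zero(self):
        table = ns.class_prevalence(_genomes([10_000]), set()).set_index("size_class")
        assert math.isnan(table.loc["jumbo", "fraction"])

    def test_overlapping_classes_rejected(self):
        with pytest.raises(ValueError):
            ns.SizeClassConfig(classes=(("a", 0, 50_000), ("b", 40_000, 90_000)))


class TestPer1000:
    def test_rate_arithmetic(self):
        genomes = _genomes([10_000] * 150, morphology="myovirus")
        pos = {f"g{i}" for i in range(30)}
        table = ns.per_1000(genomes, pos).set_index("morphology")
        assert table.loc["myovirus", "per_1000"] == pytest.approx(200.0)

    def test_zero_positives(self):
        table = ns.per_1000(_genomes([10_000] * 5, "podovirus"), set())
        assert table["per_1000"].tolist() == [0.0]

    def test_round_trip_through_tsv(self, tmp_path):
        import pandas as pd

        genomes = _genomes([10_000] * 9, "siphovirus")
        table = ns.per_1000(genomes, {"g0", "g5"})
        path = tmp_path / "per1000.tsv"
        table.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t")
        assert back["per_1000"].tolist() == table["per_1000"].tolist()


def _pearson_chi2_oracle(table):
    obs = np.asarray(table, dtype=float)
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    return ((obs - expected) ** 2 / expected).sum()


class TestEnrichment:
    def test_two_by_two_closed_form(self):
        res = ns.enrichment_test([[12, 8], [5, 15]])
        assert res.chi2 == pytest.approx(5.013, abs=0.001)
        assert res.df == 1

    def test_independent_table_gives_zero(self):
        res = ns.enrichment_test([[10, 20], [20, 40]])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_formula_on_random_tables(self, rng):
        for _ in range(20):
            table = rng.integers(5, 60, size=(int(rng.integers(2, 4)), int(rng.integers(2, 4))))
            res = ns.enrichment_test(table)
            assert res.chi2 == pytest.approx(_pearson_chi2_oracle(table), abs=1e-9)
            assert res.df == (table.shape[0] - 1) * (table.shape[1] - 1)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            ns.enrichment_test([[0, 0], [3, 4]])

    def test_low_expected_warns_and_adds_fisher(self):
        with pytest.warns(UserWarning):
            res = ns.enrichment_test([[1, 9], [2, 8]])
        assert res.low_expected and res.fisher_p is not None


def _hypergeom_enumeration(N, na, nb, both):
    """P[X >= both] by direct enumeration of the hypergeometric pmf."""
    total = 0.0
    for k in range(both, min(na, nb) + 1):
        total += (
            math.comb(na, k) * math.comb(N - na, nb - k) / math.comb(N, nb)
        )
    return total


class TestCooccurrence:
    def _carriage(self, N, a_ids, b_ids):
        return {
            f"g{i}": frozenset(
                (["A"] if i in a_ids else []) + (["B"] if i in b_ids else [])
            )
            for i in range(N)
        }

    def test_enrichment_p_matches_enumeration(self):
        carriage = self._carriage(10, set(range(5)), {0, 1, 2, 3})
        res = ns.cooccurrence(carriage, ["A", "B"])[0]
        assert res.n_both == 4
        assert res.p_enrich == pytest.approx(5.0 / 210.0, abs=1e-12)
        assert res.p_enrich == pytest.approx(_hypergeom_enumeration(10, 5, 4, 4), abs=1e-12)

    def test_one_sided_tails_overlap_at_observed(self):
        carriage = self._carriage(12, set(range(6)), set(range(3, 9)))
        res = ns.cooccurrence(carriage, ["A", "B"])[0]
        assert res.p_enrich + res.p_deplete >= 1.0

    def test_enumeration_agreement_randomized_small_n(self, rng):
        for _ in range(15):
            N = int(rng.integers(6, 30))
            a = set(rng.choice(N, size=int(rng.integers(1, N)), replace=False).tolist())
            b = set(rng.choice(N, size=int(rng.integers(1, N)), replace=False).tolist())
            res = ns.cooccurrence(self._carriage(N, a, b), ["A", "B"])[0]
            assert res.p_enrich == pytest.approx(
                _hypergeom_enumeration(N, len(a), len(b), len(a & b)), abs=1e-12
            )

    def test_absent_family_skipped(self):
        carriage = self._carriage(6, {0, 1}, set())
        assert ns.cooccurrence(carriage, ["A", "B"]) == []

    def test_bh_qvalues_bound_pvalues(self, rng):
        carriage = {
            f"g{i}": frozenset(
                f for f in "ABCD" if rng.random() < 0.4
            )
            for i in range(40)
        }
        results = ns.cooccurrence(carriage, list("ABCD"))
        for r in results:
            assert r.q_enrich >= r.p_enrich - 1e-12
            assert r.q_deplete >= r.p_deplete - 1e-12
        # BH never exceeds 1 and is monotone in p-rank
        ranked = sorted(results, key=lambda r: r.p_enrich)
        qs = [r.q_enrich for r in ranked]
        assert all(q <= 1.0 for q in qs)


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
@settings(deadline=None, max_examples=60, derandomize=True)
def test_bh_adjustment_invariants(pvals):
    p = np.array(pvals)
    q = ns._bh(p)
    assert (q >= p - 1e-12).all() and (q <= 1.0 + 1e-12).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()  # monotone in p-rank


def _planted_cooccurrence_q(seed, rho):
    from viranet import synthetic_genomes as sg

    cfg = sg.GeneratorConfig(
        n_genomes=1000,
        seed=seed,
        class_mix=((("dsDNA", "bacteria"), 1.0),),
        length_model={"dsDNA": ("uniform", 40_000, 120_000)},
        family_params={
            "Macro": sg.FamilyParams(const_prob=0.3),
            "NADAR": sg.FamilyParams(const_prob=0.3),
        },
        context_params=(),
        cooccur_group=("Macro", "NADAR"),
        cooccur_rho=rho,
        emit_proteins=False,
    )
    _, truth = sg.generate_collection(cfg)
    carriage = {g: set(f) for g, f in truth.genome_truth.items()}
    res = ns.cooccurrence(carriage, ["Macro", "NADAR"])[0]
    return res.p_enrich, res.q_enrich


def test_planted_cooccurrence_detected_and_null_calibrated():
    detected = sum(_planted_cooccurrence_q(s, 0.4)[1] < 0.05 for s in range(20))
    assert detected >= 19
    null_rej = np.mean([_planted_cooccurrence_q(100 + s, 0.0)[0] < 0.05 for s in range(100)])
    assert null_rej <= 0.1  # one-sided test at nominal level under independence


class TestEuler:
    def test_exclusive_counts_sum_to_carriers(self, rng):
        fams = ["A", "B", "C", "D"]
        carriage = {
            f"g{i}": frozenset(f for f in fams if rng.random() < 0.3) for i in range(60)
        }
        counts = ns.euler_counts(carriage, fams)
        n_carriers = sum(1 for v in carriage.values() if v)
        assert sum(counts.values()) == n_carriers
        # each genome contributes to exactly its own exact subset
        for combo, n in counts.items():
            assert n == sum(
                1 for v in carriage.values() if tuple(f for f in fams if f in v) == combo
            )

    def test_family_count_limits(self):
        with pytest.raises(ValueError):
            ns.euler_counts({}, ["A", "B", "C", "D", "E"])
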