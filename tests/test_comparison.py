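import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foodmine.comparison import (DatabaseSnapshot, SnapshotRow, agreement,
                                 coverage, merge_variants, paper_frequency)
from foodmine.fixtures import FixtureSpec, gen_records_and_snapshots
from foodmine.records import (CompoundEntry, CompoundKey, MeasurementRecord,
                              aggregate, attach_keys)


def key(name, cid=None):
    return CompoundKey(cid=cid, canonical_name=name)


def entry(name, cid=None, mean=1.0, food="garlic", descriptors=()):
    return CompoundEntry(
        key=key(name, cid), food=food,
        mean_mg_per_100g=mean, min_mg_per_100g=mean, max_mg_per_100g=mean,
        variance=0.0 if mean is not None else None,
        n_records=1, n_papers=1, descriptors=tuple(descriptors))


def unquantified(name, cid=None):
    return CompoundEntry(key=key(name, cid), food="garlic",
                         mean_mg_per_100g=None, min_mg_per_100g=None,
                         max_mg_per_100g=None, variance=None,
                         n_records=1, n_papers=1)


def snap(source, rows):
    return DatabaseSnapshot(
        source=source, food_variants=sorted({v for v, _, _ in rows}),
        rows=[SnapshotRow(food_variant=v, key=key(n, c_q[0]),
                          quantity_mg_per_100g=c_q[1])
              for v, n, c_q in rows])


class TestMergeVariants:
    def test_disjoint_variants_union(self):
        s = snap("FooDB", [("Garlic", "a", (1, 1.0)),
                           ("Soft-necked Garlic", "b", (2, 2.0))])
        m = merge_variants(s)
        assert {r.key.canonical_name for r in m.rows} == {"a", "b"}

    def test_quantified_in_any_variant_wins(self):
        s = snap("FooDB", [("Garlic", "a", (1, None)),
                           ("Soft-necked Garlic", "a", (1, 3.0))])
        [r] = merge_variants(s).rows
        assert r.quantity_mg_per_100g == 3.0

    def test_quantities_averaged_across_variants(self):
        s = snap("USDA", [("Garlic", "a", (1, 10.0)),
                          ("Soft-necked Garlic", "a", (1, 30.0))])
        [r] = merge_variants(s).rows
        assert r.quantity_mg_per_100g == 20.0

    def test_empty_is_identity(self):
        m = merge_variants(DatabaseSnapshot(source="USDA"))
        assert m.rows == []


class TestCoverage:
    def test_set_arithmetic_example(self):
        entries = [entry("a", 1), entry("b", 2), entry("c", 3)]
        refs = [snap("USDA", [("G", "a", (1, 5.0))]),
                snap("FooDB", [("G", "b", (2, None))])]
        report = coverage(entries, refs)
        assert report.novel_quantified == 1
        assert [k.canonical_name for k in report.novel_list] == ["c"]
        assert report.shared_quantified == 1
        assert report.shared_unquantified == 1

    def test_empty_foodmine_all_zero(self):
        report = coverage([], [snap("USDA", [("G", "a", (1, 5.0))])])
        assert report.foodmine_quantified == 0
        assert report.novel_quantified == 0

    def test_novelty_against_union_not_each_source(self):
        # present unquantified in FooDB only -> shared, not novel
        entries = [entry("a", 1)]
        refs = [snap("USDA", [("G", "zzz", (99, 1.0))]),
                snap("FooDB", [("G", "a", (1, None))])]
        assert coverage(entries, refs).novel_quantified == 0

    def test_duplicate_keys_after_merge_integrity_error(self):
        s = DatabaseSnapshot(source="USDA", food_variants=["G"], rows=[
            SnapshotRow("G", key("a", 1), 1.0),
            SnapshotRow("G", key("a", 1), 2.0)], merged=True)
        with pytest.raises(ValueError, match="duplicate"):
            coverage([entry("a", 1)], [s])

    def test_counts_partition_foodmine_quantified(self, bundle):
        entries = aggregate(attach_keys(bundle.records, bundle.resolver()))
        report = coverage(entries, bundle.snapshots)
        assert (report.shared_quantified + report.shared_unquantified +
                report.novel_quantified) == report.foodmine_quantified

    def test_invariant_to_splitting_a_snapshot(self):
        entries = [entry("a", 1), entry("b", 2), entry("c", 3)]
        whole = [snap("USDA", [("G", "a", (1, 5.0)), ("G", "b", (2, 1.0))])]
        split = [snap("USDA", [("G", "a", (1, 5.0))]),
                 snap("X", [("G", "b", (2, 1.0))])]
        assert coverage(entries, whole).novel_quantified == \
            coverage(entries, split).novel_quantified

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(q=st.integers(0, 10), u=st.integers(0, 8), v=st.integers(0, 10),
           seed=st.integers(0, 10_000))
    def test_planted_overlap_recovered_exactly(self, q, u, v, seed):
        spec = FixtureSpec(seed=seed, n_relevant=5, n_irrelevant=5,
                           n_compounds=q + u + v + 3,
                           planted_overlap=(q, u, v), n_ref_only=2)
        bundle = gen_records_and_snapshots(spec)
        entries = aggregate(attach_keys(bundle.records, bundle.resolver()))
        report = coverage(entries, bundle.snapshots)
        assert (report.shared_quantified, report.shared_unquantified,
                report.novel_quantified) == (q, u, v)


class TestPaperFrequency:
    def mk_records(self, plan, resolver):
        records = []
        i = 0
        for name, papers in plan.items():
            for p in papers:
                records.append(MeasurementRecord(
                    record_id=f"r{i}", entry_id=p, food="garlic",
                    compound_name_raw=name, value=1.0, unit_raw="mg/100 g",
                    quantified=True))
                i += 1
        return attach_keys(records, resolver)

    def test_descending_paper_counts(self, resolver):
        records = self.mk_records(
            {"caffeine": ["p1", "p2", "p3"], "allicin": ["p1"]}, resolver)
        ranked = paper_frequency(records, top_k=10)
        assert [(k.canonical_name, n) for k, n in ranked] == \
            [("caffeine", 3), ("allicin", 1)]

    def test_same_paper_counted_once(self, resolver):
        records = self.mk_records({"caffeine": ["p1", "p1"]}, resolver)
        [(k, n)] = paper_frequency(records, top_k=5)
        assert n == 1

    def test_tie_break_on_name(self, resolver):
        records = self.mk_records(
            {"glycine": ["p1"], "alanine": ["p2"]}, resolver)
        ranked = paper_frequency(records, top_k=2)
        assert [k.canonical_name for k, _ in ranked] == ["alanine", "glycine"]

    def test_planted_frequencies_recovered(self, bundle):
        records = attach_keys(bundle.records, bundle.resolver())
        truth = bundle.ground_truth["n_papers"]
        ranked = paper_frequency(records, top_k=len(truth))
        assert {k.canonical_name: n for k, n in ranked} == truth

    def test_top_k_must_be_positive(self, resolver):
        with pytest.raises(ValueError):
            paper_frequency([], top_k=0)


class TestAgreement:
    def gold(self, values):
        return snap("USDA", [("G", n, (cid, v))
                             for n, cid, v in values])

    def test_perfect_match_r2_one(self):
        vals = [("c%d" % i, i + 1, float(10 ** (i % 5))) for i in range(10)]
        entries = [entry(n, c, v) for n, c, v in vals]
        res = agreement(entries, self.gold(vals))
        assert res.r2_log == pytest.approx(1.0)
        assert res.n_pairs == 10

    def test_zero_gold_value_excluded(self):
        vals = [("a", 1, 1.0), ("b", 2, 2.0), ("c", 3, 4.0), ("z", 4, 0.0)]
        entries = [entry(n, c, max(v, 0.5)) for n, c, v in vals]
        res = agreement(entries, self.gold(vals))
        assert [k.canonical_name for k in res.excluded_zero] == ["z"]
        assert res.n_pairs == 3

    def test_descriptor_exclusion_drops_fully_tagged_entries(self):
        vals = [("a", 1, 1.0), ("b", 2, 2.0), ("c", 3, 4.0), ("r", 4, 8.0)]
        entries = [entry(n, c, v) for n, c, v in vals[:3]]
        entries.append(entry("r", 4, 800.0, descriptors=("roasted",)))
        full = agreement(entries, self.gold(vals))
        filtered = agreement(entries, self.gold(vals),
                             exclude_descriptors=["roasted"])
        assert full.n_pairs == 4
        assert filtered.n_pairs == 3
        assert [k.canonical_name for k in filtered.excluded_descriptor] == ["r"]
        # partially tagged entries stay: "a" gains a second descriptor and
        # must survive the filter while fully-tagged "r" is still dropped
        entries[0] = entry("a", 1, 1.0, descriptors=("roasted", "fresh"))
        partial = agreement(entries, self.gold(vals),
                            exclude_descriptors=["roasted"])
        assert "a" in {k.canonical_name for k, _f, _g in partial.matched_pairs}
        assert partial.n_pairs == 3

    def test_r2_matches_independent_least_squares(self):
        rng = np.random.default_rng(0)
        x = 10 ** rng.uniform(-1, 2, size=20)
        y = x * 10 ** rng.normal(0, 0.3, size=20)
        vals = [("c%d" % i, i + 1, float(g)) for i, g in enumerate(x)]
        entries = [entry(n, c, float(y[i])) for i, (n, c, _g) in enumerate(vals)]
        res = agreement(entries, self.gold(vals))
        lx, ly = np.log10(x), np.log10(y)
        X = np.column_stack([np.ones(20), lx])
        beta, *_ = np.linalg.lstsq(X, ly, rcond=None)
        resid = ly - X @ beta
        r2 = 1 - resid @ resid / ((ly - ly.mean()) @ (ly - ly.mean()))
        assert res.r2_log == pytest.approx(r2, abs=1e-12)

    def test_scale_invariance_of_r2(self):
        rng = np.random.default_rng(1)
        x = 10 ** rng.uniform(-1, 2, size=12)
        y = x * 10 ** rng.normal(0, 0.2, size=12)
        vals = [("c%d" % i, i + 1, float(g)) for i, g in enumerate(x)]
        e1 = [entry(n, c, float(y[i])) for i, (n, c, _g) in enumerate(vals)]
        scaled = [("c%d" % i, i + 1, float(g * 137.0))
                  for i, g in enumerate(x)]
        e2 = [entry(n, c, float(y[i] * 137.0))
              for i, (n, c, _g) in enumerate(scaled)]
        assert agreement(e1, self.gold(vals)).r2_log == pytest.approx(
            agreement(e2, self.gold(scaled)).r2_log, abs=1e-12)

    def test_too_few_pairs_insufficient_data(self):
        vals = [("a", 1, 1.0), ("b", 2, 2.0)]
        entries = [entry(n, c, v) for n, c, v in vals]
        with pytest.raises(ValueError, match="at least 3"):
            agreement(entries, self.gold(vals))

    def test_noise_free_fixture_reaches_r2_one(self):
        spec = FixtureSpec(seed=21, noise_sigma_log=0.0)
        bundle = gen_records_and_snapshots(spec)
        entries = aggregate(attach_keys(bundle.records, bundle.resolver()))
        gold = next(s for s in bundle.snapshots if s.source == "USDA")
        res = agreement(entries, gold)
        assert res.r2_log == pytest.approx(1.0, abs=1e-9)
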