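"""Responder detection, inhibition testing and guild classification."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_metadata
from necrosip.io import AnalysisConfig, CountTable, ValidationError
from necrosip.responders import (
    ContrastPair,
    ResponderModel,
    build_inhibition_contrasts,
    build_substrate_contrasts,
    classify_guilds,
    compare_rates,
    relative_abundance,
)
from necrosip.responders import test_enrichment as run_enrichment
from necrosip.responders import test_inhibition as run_inhibition


def spirulina_design():
    """Four treatment/control library pairs: 2 days x DNA/RNA."""
    rows = []
    for day in (20, 32):
        for molecule in ("DNA", "RNA"):
            rows.append(
                dict(sample_id=f"spir-d{day}-{molecule}", day=day,
                     substrate="spirulina", isotope="13C", dose="HD",
                     molecule=molecule)
            )
            rows.append(
                dict(sample_id=f"none-d{day}-{molecule}", day=day,
                     molecule=molecule)
            )
    return make_metadata(rows)


def make_table(meta, counts_by_phylotype, depth=4000, n_filler=50):
    """Table with explicit counts for named phylotypes plus filler rows that
    absorb the remaining depth evenly."""
    samples = meta.sample_ids
    data = {}
    for sid in samples:
        named = [counts_by_phylotype[p][sid] for p in counts_by_phylotype]
        remaining = depth - sum(named)
        filler = np.full(n_filler, remaining // n_filler)
        filler[: remaining % n_filler] += 1
        data[sid] = named + filler.tolist()
    index = list(counts_by_phylotype) + [f"fill{i}" for i in range(n_filler)]
    return CountTable(pd.DataFrame(data, index=pd.Index(index, name="phylotype_id")))


class TestRelativeAbundance:
    def test_simple_column(self):
        df = pd.DataFrame({"s1": [3, 1]}, index=["a", "b"])
        rel = relative_abundance(CountTable(df))
        np.testing.assert_allclose(rel["s1"], [0.75, 0.25])

    def test_columns_sum_to_one(self, small_counts):
        rel = relative_abundance(small_counts)
        np.testing.assert_allclose(rel.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_sum_column_names_sample(self):
        df = pd.DataFrame({"good": [3, 1], "empty": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValidationError, match="empty"):
            relative_abundance(CountTable(df))


class TestEnrichment:
    def test_strong_enrichment_in_two_pairs_is_responsive(self):
        meta = spirulina_design()
        pairs = build_substrate_contrasts(meta, "spirulina")
        assert len(pairs) == 4
        # enriched (200 vs 20) in the two day-20 pairs only
        counts = {
            "hit": {s: 200 if ("spir-d20" in s) else 20 for s in meta.sample_ids},
            "flat": {s: 20 for s in meta.sample_ids},
        }
        table = make_table(meta, counts)
        records, calls = run_enrichment(table, meta, pairs)
        calls = calls.set_index("phylotype_id")
        assert bool(calls.loc["hit", "responsive"])
        assert calls.loc["hit", "response_mode"] == "growth"
        assert not bool(calls.loc["flat", "responsive"])
        assert calls.loc["flat", "response_mode"] == "none"

    def test_rna_only_enrichment_is_activity(self):
        meta = spirulina_design()
        pairs = build_substrate_contrasts(meta, "spirulina")
        counts = {
            "rna_hit": {
                s: 200 if ("spir" in s and s.endswith("RNA")) else 20
                for s in meta.sample_ids
            },
        }
        table = make_table(meta, counts)
        _, calls = run_enrichment(table, meta, pairs)
        row = calls.set_index("phylotype_id").loc["rna_hit"]
        assert bool(row["responsive"])
        assert row["n_enriched_dna"] == 0
        assert row["n_enriched_rna"] == 2
        assert row["response_mode"] == "activity"

    def test_single_pair_enrichment_not_responsive(self):
        meta = spirulina_design()
        pairs = build_substrate_contrasts(meta, "spirulina")
        counts = {
            "once": {s: 200 if s == "spir-d20-DNA" else 20 for s in meta.sample_ids},
        }
        _, calls = run_enrichment(make_table(meta, counts), meta, pairs)
        row = calls.set_index("phylotype_id").loc["once"]
        assert int(row["n_enriched_dna"]) == 1
        assert not bool(row["responsive"])

    def test_all_zero_phylotype_gets_p1_without_failure(self):
        meta = spirulina_design()
        pairs = build_substrate_contrasts(meta, "spirulina")
        counts = {"ghost": {s: 0 for s in meta.sample_ids}}
        records, calls = run_enrichment(make_table(meta, counts), meta, pairs)
        ghost = records[records["phylotype_id"] == "ghost"]
        assert (ghost["raw_p"] == 1.0).all()
        assert not bool(calls.set_index("phylotype_id").loc["ghost", "responsive"])

    def test_too_few_pairs_is_a_configuration_error(self):
        meta = spirulina_design()
        pairs = build_substrate_contrasts(meta, "spirulina")[:1]
        table = make_table(meta, {"x": {s: 10 for s in meta.sample_ids}})
        with pytest.raises(ValidationError, match="min_libraries"):
            run_enrichment(table, meta, pairs)

    def test_without_bh_calls_are_per_phylotype_independent(self):
        """Dropping an untested (all-zero) row must not move any other
        phylotype's p-values or flags once the BH family is out of the
        picture; rows with reads enter every test through the library depth,
        so only a zero row is 'non-tested' in the strict sense."""
        meta = spirulina_design()
        pairs = build_substrate_contrasts(meta, "spirulina")
        counts = {
            "hit": {s: 200 if "spir-d20" in s else 20 for s in meta.sample_ids},
            "bystander": {s: 0 for s in meta.sample_ids},
        }
        full = make_table(meta, counts, n_filler=30)
        records_full, _ = run_enrichment(full, meta, pairs, adjust=False)
        reduced = CountTable(full.counts.drop(index="bystander"))
        records_red, _ = run_enrichment(reduced, meta, pairs, adjust=False)
        merged = records_full[records_full["phylotype_id"] != "bystander"]
        pd.testing.assert_frame_equal(
            merged.reset_index(drop=True)[["phylotype_id", "raw_p", "enriched"]],
            records_red.reset_index(drop=True)[["phylotype_id", "raw_p", "enriched"]],
        )


class TestInhibition:
    def design(self):
        rows = []
        for substrate in ("spirulina", "acetate"):
            for day in (20, 32):
                for molecule in ("DNA", "RNA"):
                    for inhibitor in ("none", "molybdate"):
                        tag = "mo-" if inhibitor == "molybdate" else ""
                        rows.append(
                            dict(
                                sample_id=f"{substrate[:4]}-{tag}d{day}-{molecule}",
                                day=day, substrate=substrate, isotope="13C",
                                dose="HD", inhibitor=inhibitor, molecule=molecule,
                            )
                        )
        return make_metadata(rows)

    def test_suppressed_under_molybdate_is_srm(self):
        meta = self.design()
        pairs = build_inhibition_contrasts(meta)
        assert len(pairs) == 8
        counts = {
            "srm": {s: 20 if "-mo-" in s else 200 for s in meta.sample_ids},
            "flat": {s: 50 for s in meta.sample_ids},
        }
        _, srm = run_inhibition(make_table(meta, counts), meta, pairs)
        assert bool(srm["srm"])
        assert not bool(srm["flat"])

    def test_all_zero_phylotype_is_not_srm(self):
        meta = self.design()
        pairs = build_inhibition_contrasts(meta)
        counts = {"ghost": {s: 0 for s in meta.sample_ids}}
        _, srm = run_inhibition(make_table(meta, counts), meta, pairs)
        assert not bool(srm["ghost"])


class TestGuilds:
    TABLE = {
        (True, False, False): "hydrolyser_fermenter",
        (True, True, True): "acetate_utilizing_srm",
        (False, True, True): "acetate_utilizing_srm",
        (False, False, True): "srm_other_donor",
        (True, True, False): "vfa_utilizer_non_srm",
        (False, True, False): "vfa_utilizer_non_srm",
        (True, False, True): "unclassified",
        (False, False, False): "unclassified",
    }

    def test_decision_table_total_on_all_combinations(self):
        combos = list(itertools.product([False, True], repeat=3))
        idx = pd.Index([f"p{i}" for i in range(8)], name="phylotype_id")
        s = pd.Series([c[0] for c in combos], index=idx)
        a = pd.Series([c[1] for c in combos], index=idx)
        m = pd.Series([c[2] for c in combos], index=idx)
        guilds = classify_guilds(s, a, m).set_index("phylotype_id")
        for i, combo in enumerate(combos):
            assert guilds.loc[f"p{i}", "guild"] == self.TABLE[combo], combo

    def test_invariant_to_phylotype_ordering(self):
        idx = pd.Index(["b", "a", "c"], name="phylotype_id")
        s = pd.Series([True, False, True], index=idx)
        a = pd.Series([False, True, True], index=idx)
        m = pd.Series([False, False, True], index=idx)
        forward = classify_guilds(s, a, m).set_index("phylotype_id")["guild"]
        rev = classify_guilds(s[::-1], a[::-1], m[::-1]).set_index("phylotype_id")["guild"]
        pd.testing.assert_series_equal(forward.sort_index(), rev.sort_index())

    def test_mismatched_indexes_rejected(self):
        s = pd.Series([True], index=["a"])
        a = pd.Series([True], index=["b"])
        with pytest.raises(ValidationError):
            classify_guilds(s, a, s)


class TestCompareRates:
    def test_identical_rate_vectors(self):
        assert compare_rates([1.0, 2, 3], [1.0, 2, 3]).p_value >= 0.99

    def test_fully_separated_rates_exact_p(self):
        res = compare_rates([10.0, 11, 12, 13], [1.0, 2, 3, 4])
        assert res.p_value == pytest.approx(2 / 70)

    def test_single_element_vectors_have_no_power(self):
        assert compare_rates([5.0], [1.0]).p_value == pytest.approx(1.0)


class TestResponderModel:
    def test_fit_recovers_planted_structure_small(self):
        from necrosip.simulate import default_community_config, simulate_counts

        config = default_community_config(11, n_phylotypes=400)
        table, meta, truth = simulate_counts(config)
        results = ResponderModel(table, meta).fit()
        planted = set(truth.loc[truth["kind"] == "responder", "phylotype_id"])
        called = set(results.responsive_phylotypes("spirulina")) | set(
            results.responsive_phylotypes("acetate")
        )
        assert len(called & planted) >= 8  # high sensitivity at 8x fold
        assert len(called - planted) <= 1
        assert "Responder detection summary" in results.summary()

    def test_report_round_trips_through_json(self, tmp_path):
        from necrosip.io import read_report, write_report
        from necrosip.simulate import default_community_config, simulate_counts

        table, meta, _ = simulate_counts(
            default_community_config(5, n_phylotypes=150)
        )
        report = ResponderModel(table, meta).fit().to_report()
        write_report(report, tmp_path / "r.json")
        back = read_report(tmp_path / "r.json")
        assert back["srm_phylotypes"] == report["srm_phylotypes"]
        assert set(back["substrates"]) == set(report["substrates"])
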