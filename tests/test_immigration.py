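import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from manglift import (
    CommunityTable,
    intersection_counts,
    pathway_groups,
    simulate,
    turnover,
    turnover_chain,
)

from conftest import small_sim_config

sets_strategy = st.sets(st.integers(0, 30), max_size=15)


class TestTurnover:
    def test_worked_example(self):
        rec = turnover({"a", "b", "c"}, {"b", "c", "d"})
        assert (rec.Simm, rec.Sext, rec.Stot) == (1, 1, 4)
        assert rec.SERr == 0.5 and rec.SImR == 0.25 and rec.SExR == 0.25

    def test_identical_sets(self):
        rec = turnover({"a", "b"}, {"a", "b"})
        assert rec.SERr == 0 and rec.Stot == 2

    def test_disjoint_sets(self):
        a, b = {"a", "b", "c"}, {"x", "y"}
        rec = turnover(a, b)
        assert rec.SERr == 1
        assert rec.SImR == len(b) / 5 and rec.SExR == len(a) / 5

    def test_empty_union_is_error(self):
        with pytest.raises(ValueError):
            turnover(set(), set())

    def test_literal_convention_swaps_labels(self):
        eco = turnover({"a", "b", "c"}, {"c", "d"})
        lit = turnover({"a", "b", "c"}, {"c", "d"}, convention="literal")
        assert (lit.SImR, lit.SExR) == (eco.SExR, eco.SImR)
        assert lit.SERr == eco.SERr

    @given(sets_strategy, sets_strategy)
    @settings(max_examples=200, deadline=None)
    def test_ratio_identities(self, a, b):
        if not (a | b):
            return
        rec = turnover(a, b)
        assert rec.SImR + rec.SExR == rec.SERr  # exact: same denominator
        assert 0 <= rec.SImR <= 1 and 0 <= rec.SExR <= 1 and 0 <= rec.SERr <= 1
        assert rec.Stot >= max(rec.Simm, rec.Sext)
        assert (rec.SERr == 0) == (a == b)
        back = turnover(b, a)
        assert rec.Simm == back.Sext and rec.Sext == back.Simm


class TestTurnoverChain:
    def test_matches_set_level_brute_force(self, small_dataset):
        table, samples, *_ = small_dataset
        rec = turnover_chain(table, samples)
        meta = samples.frame
        for _, row in rec.iterrows():
            src = table.presence_set(row["source_sample"])
            dst = table.presence_set(row["recipient_sample"])
            # brute-force double loop over ASVs
            simm = sum(1 for a in table.asv_ids if a in dst and a not in src)
            sext = sum(1 for a in table.asv_ids if a in src and a not in dst)
            stot = sum(1 for a in table.asv_ids if a in src or a in dst)
            assert (row["Simm"], row["Sext"], row["Stot"]) == (simm, sext, stot)
        assert len(rec) == meta.groupby(["site", "plot"]).ngroups * 3

    def test_site_pooling_unions_plots(self, small_dataset):
        table, samples, *_ = small_dataset
        rec = turnover_chain(table, samples, pairing="site")
        assert len(rec) == samples.frame["site"].nunique() * 3
        # pooled source richness >= any single plot's
        plot_rec = turnover_chain(table, samples)
        assert rec["Stot"].max() >= plot_rec["Stot"].max()


class TestPathwayGroups:
    def _table(self, sets):
        asvs = sorted(set().union(*sets.values()))
        counts = [[1 if a in sets[c] else 0 for a in asvs] for c in ("NS", "RS", "RE", "LE")]
        return CommunityTable([f"X_P1_{c}" for c in ("NS", "RS", "RE", "LE")], asvs, counts)

    def test_fully_nested_plot(self, toy_samples):
        sets = {
            "NS": {"a", "b", "c", "d"},
            "RS": {"a", "b", "c"},
            "RE": {"a", "b"},
            "LE": {"a"},
        }
        table = self._table(sets)
        sub = toy_samples.frame[toy_samples.frame["plot"] == "P1"]
        from manglift import SampleFrame

        grp = pathway_groups(table, SampleFrame(sub.reset_index(drop=True)), scope="global")
        assert grp.group_IV == {"a"} == grp.group_III
        assert grp.group_III <= grp.group_II <= grp.group_I

    def test_brute_force_set_algebra(self, toy_samples):
        rng = np.random.default_rng(2)
        asvs = [f"a{i}" for i in range(20)]
        counts = (rng.random((8, 20)) < 0.4).astype(int)
        table = CommunityTable(toy_samples.sample_ids, asvs, counts)
        grp = pathway_groups(table, toy_samples, scope="global")
        sets = {}
        for comp in ("NS", "RS", "RE", "LE"):
            ids = [s for s in toy_samples.sample_ids if s.endswith(comp)]
            sets[comp] = set().union(*(table.presence_set(s) for s in ids))
        assert grp.group_I == sets["NS"] & sets["RS"]
        assert grp.group_II == sets["NS"] & sets["RS"] & sets["RE"]
        assert grp.group_III == sets["NS"] & sets["RS"] & sets["RE"] & sets["LE"]
        assert grp.group_IV == sets["NS"] & sets["LE"]
        assert grp.group_IV_external_only == (sets["NS"] & sets["LE"]) - (sets["RS"] | sets["RE"])

    def test_monotone_nesting_invariant(self, small_dataset):
        table, samples, *_ = small_dataset
        grp = pathway_groups(table, samples, scope="global")
        assert grp.group_III <= grp.group_II <= grp.group_I
        assert grp.group_III <= grp.group_IV

    def test_external_recovery_with_truth_labels(self):
        cfg = small_sim_config(
            seed=11, external_rate=0.1,
            gain={t: 0.0 for t in ("NS_RS", "RS_RE", "RE_LE")},
        )
        table, samples, _, _, truth = simulate(cfg)
        tp = fp = fn = 0
        for (site, plot), _ in samples.frame.groupby(["site", "plot"]):
            grp = pathway_groups(table, samples, scope="plot", site=site, plot=plot)
            truth_ext = {
                a for a, lab in truth.labels_for(site, plot).items() if lab == "external"
            }
            detected = grp.group_IV_external_only
            tp += len(detected & truth_ext)
            fp += len(detected - truth_ext)
            fn += len(truth_ext - detected)
        assert tp > 0
        recall = tp / (tp + fn)
        precision = tp / (tp + fp)
        assert recall >= 0.9
        assert precision >= 0.9


class TestIntersectionCounts:
    def test_identical_sets(self, toy_samples):
        asvs = ["a", "b", "c"]
        counts = np.ones((8, 3))
        table = CommunityTable(toy_samples.sample_ids, asvs, counts)
        df = intersection_counts(table, toy_samples)
        full = df[df["degree"] == 4]
        assert full["exclusive_size"].iloc[0] == 3
        assert df[df["degree"] < 4]["exclusive_size"].sum() == 0

    def test_regions_partition_union(self, small_dataset):
        table, samples, *_ = small_dataset
        df = intersection_counts(table, samples)
        union = set()
        for comp in ("NS", "RS", "RE", "LE"):
            for sid in samples.samples_where(compartment=comp):
                union |= table.presence_set(sid)
        assert df["exclusive_size"].sum() == len(union)

    def test_matches_membership_pattern_tally(self, toy_samples):
        rng = np.random.default_rng(9)
        asvs = [f"a{i}" for i in range(25)]
        counts = (rng.random((8, 25)) < 0.5).astype(int)
        table = CommunityTable(toy_samples.sample_ids, asvs, counts)
        df = intersection_counts(table, toy_samples).set_index("compartments")
        comps = ("NS", "RS", "RE", "LE")
        sets = {
            c: set().union(
                *(table.presence_set(s) for s in toy_samples.sample_ids if s.endswith(c))
            )
            for c in comps
        }
        # exhaustive membership-pattern tally
        tally: dict[tuple, int] = {}
        for a in asvs:
            pattern = tuple(c for c in comps if a in sets[c])
            if pattern:
                tally[pattern] = tally.get(pattern, 0) + 1
        for pattern, n in tally.items():
            assert df.loc["&".join(pattern), "exclusive_size"] == n
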