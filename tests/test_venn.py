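import numpy as np
import pytest

from foldchron.venn import (
    ALL_GROUPS,
    DEFAULT_MARKERS,
    PhaseCountTable,
    PhaseTimeline,
    VennError,
    VennGroup,
    accumulation_curves,
    category_of,
    delimit_phases,
    first_appearances,
    phase_count_table,
    presence_grid,
    quantile_timeline,
    shared_percentage,
    specificity_summary,
    venn_group,
)
from foldchron.census import to_occurrence
from tests.conftest import make_census

# Table 1 per-phase counts (phases 0..V)
T1 = {
    ("viruses", "prototypes"): [128, 196, 495, 629, 879, 535],
    ("viruses", "domains"): [20, 47, 162, 368, 670, 259],
    ("cells", "prototypes"): [0, 40, 378, 656, 1146, 303],
    ("cells", "domains"): [0, 12, 161, 450, 1445, 298],
}


class TestVennGroup:
    def test_canonical_names(self):
        assert VennGroup(frozenset("VAB")).name == "ABV"
        assert VennGroup.from_name("BEV").members == frozenset("BEV")
        assert len(ALL_GROUPS) == 15

    def test_from_occurrence(self):
        census = make_census(
            [[1, 1, 1, 1], [0, 0, 0, 2], [0, 1, 1, 1]],
            codes=["A", "B", "E", "V"],
        )
        occ = to_occurrence(census)
        assert venn_group(occ, "f0").name == "ABEV"
        assert venn_group(occ, "f1").name == "V"
        assert venn_group(occ, "f2").name == "BEV"

    def test_orphan_errors(self):
        census = make_census([[0, 0], [1, 1]], codes=["A", "B"])
        with pytest.raises(VennError, match="orphan"):
            venn_group(to_occurrence(census), "f0")

    def test_invalid_members(self):
        with pytest.raises(VennError):
            VennGroup(frozenset())
        with pytest.raises(VennError):
            VennGroup(frozenset("AX"))


class TestCategory:
    @pytest.mark.parametrize(
        "name,cat",
        [("ABEV", "viruses"), ("ABE", "cells"), ("V", "viruses"), ("BE", "cells")],
    )
    def test_examples(self, name, cat):
        assert category_of(VennGroup.from_name(name)) == cat

    def test_partition_8_7(self):
        cats = [category_of(VennGroup.from_name(g)) for g in ALL_GROUPS]
        assert cats.count("viruses") == 8
        assert cats.count("cells") == 7


class TestFirstAppearances:
    def test_single(self):
        fa = first_appearances({"f": 0.0}, {"f": VennGroup.from_name("ABEV")})
        assert fa == {"ABEV": 0.0}

    def test_minima(self):
        nd = {"a": 0.0, "b": 0.2, "c": 0.15}
        vg = {
            "a": VennGroup.from_name("ABEV"),
            "b": VennGroup.from_name("ABEV"),
            "c": VennGroup.from_name("BEV"),
        }
        assert first_appearances(nd, vg) == {"ABEV": 0.0, "BEV": 0.15}

    def test_fixture_ground_truth_order(self, paper_fixture):
        _, truth = paper_fixture
        order = truth.appearance_order
        assert order[:4] == ["ABEV", "ABE", "BEV", "BE"]


class TestDelimitPhases:
    def make_first(self):
        return {
            "ABEV": 0.0,
            "ABE": 0.1,
            "BEV": 0.2,
            "BE": 0.25,
            "B": 0.3,
            "V": 0.47,
            "E": 0.8,
        }

    def test_construction(self):
        tl = delimit_phases(self.make_first())
        assert tl.boundaries == [0.1, 0.2, 0.3, 0.47, 0.8]

    def test_half_open_assignment(self):
        tl = delimit_phases(self.make_first())
        assert tl.phase_name(0.1) == "I"  # boundary goes to the later phase
        assert tl.phase_name(0.0999) == "0"
        assert tl.phase_name(1.0) == "V"

    def test_v_marker_in_paper_window(self, paper_fixture):
        # fixture tuned so the V boundary (truth chronology) is in 0.47-0.53
        _, truth = paper_fixture
        fa = first_appearances(truth.birth, truth.venn)
        tl = delimit_phases(fa)
        assert 0.47 <= tl.boundaries[3] <= 0.53

    def test_missing_marker(self):
        first = {"ABEV": 0.0, "ABE": 0.1}
        with pytest.raises(VennError, match="missing marker"):
            delimit_phases(first)

    def test_non_increasing_rejected(self):
        first = self.make_first()
        first["V"] = 0.05
        with pytest.raises(VennError):
            delimit_phases(first)

    def test_quantile_fallback_valid(self):
        rng = np.random.default_rng(0)
        tl = quantile_timeline(rng.uniform(0, 1, size=40))
        b = tl.boundaries
        assert all(b[i] < b[i + 1] for i in range(4))


class TestPhaseCountTable:
    def test_table1_ratios(self):
        t = PhaseCountTable.from_counts(T1)
        assert t.ratio("viruses", 0) == 6.40
        assert t.ratio("cells", 0) == "–"
        assert t.ratios("viruses") == [6.40, 4.17, 3.06, 1.71, 1.31, 2.07]
        assert t.ratios("cells") == ["–", 3.33, 2.35, 1.46, 0.79, 1.02]

    def test_empty(self):
        t = PhaseCountTable.from_features(
            [], PhaseTimeline([0.1, 0.2, 0.3, 0.4, 0.5])
        )
        assert all(sum(v) == 0 for v in t.counts.values())

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        tl = PhaseTimeline([0.1, 0.3, 0.5, 0.7, 0.9])
        feats = [
            (float(rng.uniform(0, 1)), VennGroup.from_name("ABEV"), "domains")
            for _ in range(57)
        ]
        t = PhaseCountTable.from_features(feats, tl)
        assert t.category_total("viruses", "domains") == 57

    def test_cumulative_matches_text(self):
        t = PhaseCountTable.from_counts(T1)
        assert t.cumulative("viruses", "domains", "II") == 229
        assert t.cumulative("viruses", "domains", "III") == 597
        assert t.cumulative("cells", "domains", "III") == 623

    def test_category_totals_match_text(self):
        t = PhaseCountTable.from_counts(T1)
        assert t.category_total("viruses", "domains") == 1526
        assert t.category_total("cells", "domains") == 2366


class TestAccumulation:
    def test_conservation_at_end(self):
        tl = PhaseTimeline([0.1, 0.3, 0.5, 0.7, 0.9])
        nd = {"a": 0.05, "b": 0.4, "c": 0.95}
        vg = {k: VennGroup.from_name(g) for k, g in
              [("a", "ABEV"), ("b", "V"), ("c", "ABE")]}
        df = accumulation_curves(nd, vg, tl)
        last = df.iloc[-1]
        assert last["viruses"] == 2 and last["cells"] == 1


class TestSpecificity:
    def test_v_only_percentage(self):
        vgs = [VennGroup.from_name("V")] * 95 + [VennGroup.from_name("ABEV")] * (
            3892 - 95
        )
        out = specificity_summary(vgs)
        assert out["singletons"]["V"] == 2.44

    def test_all_shared(self):
        out = specificity_summary([VennGroup.from_name("ABEV")] * 10)
        assert all(v == 0.0 for v in out["singletons"].values())
        assert out["shared"] == 100.0

    def test_all_singletons(self):
        out = specificity_summary(
            [VennGroup.from_name(c) for c in "ABEV" for _ in range(5)]
        )
        assert out["shared"] == 0.0

    def test_shared_percentage_paper_values(self):
        assert shared_percentage([0.85, 2.44, 8.32, 11.51]) == 76.9
        assert shared_percentage([0.29, 1.32, 4.02, 4.29]) == 90.1


class TestPresenceGrid:
    def test_single_phase_row(self):
        tl = PhaseTimeline([0.1, 0.3, 0.5, 0.7, 0.9])
        nd = {"x": 0.75}
        vg = {"x": VennGroup.from_name("EV")}
        grid = presence_grid(nd, vg, tl)
        assert grid.loc["EV"].tolist() == [False, False, False, False, True, False]

    def test_empty_phase_all_false_column(self):
        tl = PhaseTimeline([0.1, 0.3, 0.5, 0.7, 0.9])
        grid = presence_grid({}, {}, tl)
        assert not grid.any().any()

    def test_microbial_groups_absent_in_phase_v(self):
        # generator configured so microbial-specific features stop before b5
        from foldchron.simulate import Cohort, SimulationConfig, simulate_census

        cohorts = [
            Cohort("ABEV", 6, 0.0, (0.0, 0.95)),
            Cohort("ABE", 4, 0.05, (0.05, 0.95)),
            Cohort("BEV", 4, 0.1, (0.1, 0.95)),
            Cohort("BE", 4, 0.15, (0.15, 0.95)),
            Cohort("AB", 2, 0.2, (0.2, 0.6)),
            Cohort("AV", 2, 0.22, (0.22, 0.6)),
            Cohort("ABV", 2, 0.24, (0.24, 0.6)),
            Cohort("B", 2, 0.3, (0.3, 0.6)),
            Cohort("A", 2, 0.32, (0.32, 0.6)),
            Cohort("BV", 2, 0.34, (0.34, 0.6)),
            Cohort("V", 3, 0.48, (0.48, 0.53)),
            Cohort("AEV", 2, 0.62, (0.62, 0.95)),
            Cohort("EV", 2, 0.64, (0.64, 0.95)),
            Cohort("AE", 2, 0.66, (0.66, 0.95)),
            Cohort("E", 2, 0.68, (0.68, 0.95)),
        ]
        cfg = SimulationConfig(
            n_families=sum(c.n for c in cohorts), cohorts=cohorts, seed=3,
            occupancy_noise=0.0, hgt_rate=0.0,
        )
        census, truth = simulate_census(cfg)
        fa = first_appearances(truth.birth, truth.venn)
        tl = delimit_phases(fa)
        grid = presence_grid(truth.birth, truth.venn, tl)
        for g in ("AV", "BV", "ABV", "V", "AB", "B", "A"):
            assert not grid.loc[g, "V"], f"{g} should be absent in Phase V"
        for g in ("AEV", "EV", "AE", "E"):
            assert grid.loc[g].any()
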