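"""Barcode sharing, diagnosability, and stratified summaries."""

import numpy as np
import pytest

from barcode_audit.errors import DataError
from barcode_audit.sharing import (
    shared_haplotype_pairs, diagnosability, regional_sharing_summary,
    group_sharing_summary, chi_square_independence, spearman_genus_correlation,
)
from conftest import CLEAN_BASE, make_record, mutate


class TestSharedHaplotypePairs:
    def test_identical_sequence_across_species_flagged(self):
        records = [
            make_record("a1", species="A"),
            make_record("b1", species="B"),
            make_record("c1", species="C", sequence=mutate(CLEAN_BASE, 5, "G")),
        ]
        report = shared_haplotype_pairs(records)
        assert report.flags == {"A": True, "B": True, "C": False}
        assert report.pairs == [("A", "B", 1)]

    def test_distinct_species_no_sharing(self):
        records = [
            make_record("a1", species="A"),
            make_record("b1", species="B", sequence=mutate(CLEAN_BASE, 5, "G")),
        ]
        report = shared_haplotype_pairs(records)
        assert not any(report.flags.values()) and report.pairs == []

    def test_conspecific_identity_is_not_sharing(self):
        records = [make_record("a1", species="A"), make_record("a2", species="A")]
        assert shared_haplotype_pairs(records).pairs == []

    def test_flags_consistent_with_pair_list(self, rng):
        records = []
        for s in range(6):
            seq = CLEAN_BASE
            for p in rng.choice(658, size=3, replace=False):
                seq = mutate(seq, int(p) + 1, "ACGT"[int(rng.integers(4))])
            records.append(make_record(f"s{s}", species=f"sp{s}", sequence=seq))
        # inject one introgression: sp5 adopts sp0's barcode
        records.append(make_record("s5b", species="sp5", sequence=records[0].sequence))
        report = shared_haplotype_pairs(records)
        in_pairs = {sp for a, b, _ in report.pairs for sp in (a, b)}
        assert in_pairs == set(report.sharing_species)
        assert ("sp0", "sp5") in {(a, b) for a, b, _ in report.pairs}


class TestDiagnosability:
    def test_fixed_state_site_is_diagnostic(self):
        records = [
            make_record("a1", species="A", sequence=mutate(CLEAN_BASE, 100, "G")),
            make_record("a2", species="A", sequence=mutate(CLEAN_BASE, 100, "G")),
            make_record("b1", species="B"),
            make_record("c1", species="C"),
        ]
        result = diagnosability(records, "A")
        assert (100, "G") in result.diagnostic_positions
        assert result.diagnosable

    def test_shared_only_haplotype_not_diagnosable(self):
        records = [
            make_record("a1", species="A"),
            make_record("b1", species="B"),
        ]
        result = diagnosability(records, "A")
        assert result.diagnostic_positions == [] and not result.diagnosable

    def test_diagnostic_species_never_in_sharing_pairs(self):
        records = [
            make_record("a1", species="A", sequence=mutate(CLEAN_BASE, 100, "G")),
            make_record("b1", species="B"),
            make_record("c1", species="C"),
        ]
        result = diagnosability(records, "A")
        report = shared_haplotype_pairs(records)
        assert result.diagnostic_positions and "A" not in report.sharing_species

    def test_positions_match_per_site_oracle(self, rng):
        records = []
        for s in range(4):
            for k in range(3):
                seq = CLEAN_BASE
                for p in rng.choice(658, size=rng.integers(1, 6), replace=False):
                    seq = mutate(seq, int(p) + 1, "ACGT"[int(rng.integers(4))])
                records.append(make_record(f"s{s}_{k}", species=f"sp{s}", sequence=seq))
        result = diagnosability(records, "sp0")
        members = [r.sequence for r in records if r.species == "sp0"]
        others = [r.sequence for r in records if r.species != "sp0"]
        expected = []
        for p in range(658):
            states = {s[p] for s in members if s[p] in "ACGT"}
            if len(states) != 1:
                continue
            (state,) = states
            if all(o[p] != state for o in others):
                expected.append((p + 1, state))
        assert result.diagnostic_positions == expected


class TestRegionalSummary:
    def test_simple_proportions(self):
        flags = {"A": True, "B": False, "C": True, "D": False}
        regions = {"A": "north_alpine", "B": "north_alpine",
                   "C": "south", "D": "south"}
        table = regional_sharing_summary(flags, regions).set_index("region")
        assert table.loc["north_alpine", "proportion"] == 0.5
        assert table.loc["south", "proportion"] == 0.5

    def test_empty_region_reports_zero_over_zero(self):
        flags = {"A": True}
        table = regional_sharing_summary(flags, {"A": "south"}).set_index("region")
        assert table.loc["mid_latitude", "total"] == 0
        assert np.isnan(table.loc["mid_latitude", "proportion"])

    def test_invalid_region_is_validation_error(self):
        with pytest.raises(DataError, match="arctic"):
            regional_sharing_summary({"A": True}, {"A": "arctic"})

    def test_weighted_regional_proportions_reproduce_overall(self, rng):
        flags = {f"sp{i}": bool(rng.random() < 0.3) for i in range(30)}
        regions = {
            sp: ("north_alpine", "mid_latitude", "south")[i % 3]
            for i, sp in enumerate(flags)
        }
        table = regional_sharing_summary(flags, regions)
        overall = sum(flags.values()) / len(flags)
        assert table["sharing"].sum() / table["total"].sum() == pytest.approx(overall)


def test_family_by_region_cells_formatted():
    from barcode_audit.sharing import family_by_region_table

    flags = {"A": True, "B": False, "C": True}
    families = {"A": "F1", "B": "F1", "C": "F2"}
    regions = {"A": "north_alpine", "B": "south", "C": "south"}
    table = family_by_region_table(flags, families, regions).set_index("family")
    assert table.loc["F1", "north_alpine"] == "1/1 (100.0%)"
    assert table.loc["F1", "south"] == "0/1 (0.0%)"
    assert table.loc["Total", "Total"] == "2/3 (66.7%)"


class TestGroupTests:
    def test_balanced_table_statistic_zero(self):
        import pandas as pd

        table = pd.DataFrame(
            {"group": ["F1", "F2"], "sharing": [10, 10], "total": [20, 20]}
        )
        stat, df, p = chi_square_independence(table)
        assert stat == pytest.approx(0.0) and df == 1

    def test_hand_computed_pearson_value(self):
        import pandas as pd

        # 2x2 table (30,10 / 10,30): expected 20 everywhere -> sum 4*100/20
        table = pd.DataFrame(
            {"group": ["F1", "F2"], "sharing": [30, 10], "total": [40, 40]}
        )
        stat, df, p = chi_square_independence(table)
        assert stat == pytest.approx(20.0, abs=1e-12)

    def test_statistic_equals_cellwise_oracle(self, rng):
        import pandas as pd

        sharing = rng.integers(1, 15, size=4)
        totals = sharing + rng.integers(1, 15, size=4)
        table = pd.DataFrame(
            {"group": [f"F{i}" for i in range(4)], "sharing": sharing, "total": totals}
        )
        stat, df, _ = chi_square_independence(table)
        obs = np.column_stack([sharing, totals - sharing]).astype(float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        oracle = ((obs - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(oracle, rel=1e-12)
        assert df == 3

    def test_spearman_monotone_and_tied_cases(self, rng):
        import pandas as pd
        from scipy import stats

        up = pd.DataFrame({"group": list("abcd"), "sharing": [1, 2, 3, 4],
                           "total": [2, 4, 6, 8]})
        rho, rho2, p = spearman_genus_correlation(up)
        assert rho == pytest.approx(1.0)
        down = up.assign(sharing=[4, 3, 2, 1])
        assert spearman_genus_correlation(down)[0] == pytest.approx(-1.0)
        # ties: average-rank Pearson oracle
        tied = pd.DataFrame({"group": list("abcde"), "sharing": [1, 1, 2, 3, 3],
                             "total": [3, 5, 5, 7, 9]})
        rho, rho2, _ = spearman_genus_correlation(tied)
        rx = stats.rankdata(tied["total"])
        ry = stats.rankdata(tied["sharing"])
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, rel=1e-12)
        assert rho2 == pytest.approx(rho * rho)

    def test_constant_vector_undefined(self):
        import pandas as pd

        table = pd.DataFrame({"group": list("abc"), "sharing": [2, 2, 2],
                              "total": [4, 6, 8]})
        rho, rho2, p = spearman_genus_correlation(table)
        assert np.isnan(rho) and np.isnan(p)
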