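"""Ecological risk factors, RI bands, and the Site Ranking Index."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sedrisk.ecological_risk import (
    ecological_risk_factor,
    potential_ecological_risk,
    site_ranking_index,
    sri_categories,
    sri_from_ranks,
)
from sedrisk.reference_data import ReferenceDataError


class TestRiskFactor:
    def test_cadmium_worked_value(self, toxicity):
        # T(Cd) = 30 applied to the 4-fold downstream enrichment
        assert ecological_risk_factor(toxicity, 4.0, "Cd") == pytest.approx(120.0)

    def test_zero_cf_gives_zero(self, toxicity):
        assert ecological_risk_factor(toxicity, 0.0, "As") == 0.0

    @given(cf=st.floats(min_value=0, max_value=1e6))
    def test_linearity(self, toxicity, cf):
        one = ecological_risk_factor(toxicity, cf, "Pb")
        two = ecological_risk_factor(toxicity, 2 * cf, "Pb")
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_missing_factor_raises(self, toxicity):
        with pytest.raises(ReferenceDataError, match="Fe"):
            ecological_risk_factor(toxicity, 1.0, "Fe")


class TestPotentialEcologicalRisk:
    def test_sum_and_low_band(self):
        ri, cat = potential_ecological_risk({"As": 0.0, "Cd": 0.0})
        assert ri == 0.0 and cat == "low"

    @pytest.mark.parametrize(
        "ri, category",
        [
            (95.0, "low"), (95.01, "moderate"), (190.0, "moderate"),
            (190.01, "considerable"), (380.0, "considerable"),
            (380.01, "very high"), (400.0, "very high"),
        ],
    )
    def test_band_edges_follow_printed_inequalities(self, ri, category):
        got = potential_ecological_risk({"X": ri})  # 'X' placeholder key unused
        assert got == (ri, category)

    @given(
        er=st.dictionaries(
            st.sampled_from(["As", "Cd", "Cr", "Cu", "Pb", "Zn"]),
            st.floats(min_value=0, max_value=500),
            min_size=2,
            max_size=6,
        )
    )
    def test_additive_over_element_partitions(self, er):
        elements = sorted(er)
        left = {e: er[e] for e in elements[: len(elements) // 2]}
        right = {e: er[e] for e in elements[len(elements) // 2:]}
        total, _ = potential_ecological_risk(er)
        if left and right:
            assert total == pytest.approx(
                potential_ecological_risk(left)[0]
                + potential_ecological_risk(right)[0]
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            potential_ecological_risk({})


# ---------------------------------------------------------------------------
# SRI: brute-force oracle built from first principles (pairwise comparison
# counts instead of library ranking), kept independent of the implementation.


def _oracle_ranks(values):
    out = []
    for v in values:
        below = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        out.append(1 + below + (equal - 1) / 2.0)
    return out


def _oracle_sri(cf_by_site, igeo_by_site):
    keys = [(s, e) for s, vals in cf_by_site.items() for e in vals]
    cf_ranks = _oracle_ranks([cf_by_site[s][e] for s, e in keys])
    ig_ranks = _oracle_ranks([igeo_by_site[s][e] for s, e in keys])
    n = {k: (a + b) / 2.0 for k, a, b in zip(keys, cf_ranks, ig_ranks)}
    out = {}
    for site, vals in cf_by_site.items():
        s = len(vals)
        w = sum(n[(site, e)] for e in vals) / (s * (s + 1) / 2.0)
        out[site] = w / s * 100.0
    return out


class TestSiteRankingIndex:
    def test_identity_ranking_gives_100_over_s(self):
        # a site whose contaminants occupy exactly positions 1..10: W = 1
        assert sri_from_ranks(range(1, 11)) == pytest.approx(10.0)

    def test_fewer_than_two_contaminants_rejected(self):
        with pytest.raises(ValueError):
            sri_from_ranks([1.0])

    @given(
        data=st.lists(
            st.lists(
                st.integers(min_value=0, max_value=8), min_size=2, max_size=5
            ),
            min_size=1,
            max_size=4,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_matches_brute_force_oracle(self, data):
        # integer-valued draws force plenty of ties
        elements = [f"E{j}" for j in range(len(data[0]))]
        cf = {
            f"site{i}": dict(zip(elements, (float(v) for v in row)))
            for i, row in enumerate(data)
        }
        igeo = {
            site: {e: math.log2(max(v, 0.25) / 1.5) for e, v in vals.items()}
            for site, vals in cf.items()
        }
        got = site_ranking_index(cf, igeo)
        expected = _oracle_sri(cf, igeo)
        for site in cf:
            assert got[site] == pytest.approx(expected[site], rel=1e-12)

    def test_invariant_under_contaminant_relabeling(self):
        cf = {"A": {"As": 3.0, "Cd": 1.0, "Zn": 2.0}, "B": {"As": 0.5, "Cd": 4.0, "Zn": 1.0}}
        igeo = {s: {e: math.log2(v / 1.5) for e, v in vals.items()} for s, vals in cf.items()}
        renamed_cf = {s: {e + "x": v for e, v in vals.items()} for s, vals in cf.items()}
        renamed_igeo = {s: {e + "x": v for e, v in vals.items()} for s, vals in igeo.items()}
        base = site_ranking_index(cf, igeo)
        renamed = site_ranking_index(renamed_cf, renamed_igeo)
        assert base == pytest.approx(renamed)

    def test_category_partition_is_scale_free(self):
        sri = {"A": 10.0, "B": 20.0, "C": 30.0, "D": 80.0}
        scaled = {k: 7.5 * v for k, v in sri.items()}
        assert sri_categories(sri) == sri_categories(scaled)

    def test_identical_sites_collapse_to_median_rule(self):
        sri = {"A": 25.0, "B": 25.0, "C": 25.0}
        assert set(sri_categories(sri).values()) == {"high"}

    def test_category_bands(self):
        # median 20, sample SD ~15.6: one site in each band
        sri = {"low": 2.0, "mod": 18.0, "high": 22.0, "severe": 40.0}
        values = np.array(list(sri.values()))
        med, sd = np.median(values), values.std(ddof=1)
        cats = sri_categories(sri)
        assert cats["low"] == "low" and sri["low"] < med - sd
        assert cats["mod"] == "moderate"
        assert cats["high"] == "high"
        assert cats["severe"] == "severe" and sri["severe"] > med + sd
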