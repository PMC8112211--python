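"""CR, DR, OS scoring; candidate ranking; TCS correlation clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from combiscreen.orthogonality import (
    AS_PRINTED,
    NORMALIZED,
    concordance_ratio,
    discordance_ratio,
    orthogonality_score,
    rank_candidates,
    score_compound,
    tcs_correlation_network,
)
from combiscreen.signatures import SignedSignature, compute_tcs

from conftest import make_panel, make_signature


def brute_force_ratios(z_dir, d_dir, r_dir, mode):
    """Independent sign-product counter over a common gene list."""
    n_same = sum(1 for zi, ri in zip(z_dir, r_dir) if zi * ri > 0)
    n_opp = sum(1 for zi, ri in zip(z_dir, r_dir) if zi * ri < 0)
    n_disc = sum(
        1 for zi, di, ri in zip(z_dir, d_dir, r_dir) if ri == 0 and zi * di < 0
    )
    n_conc = sum(
        1 for zi, di, ri in zip(z_dir, d_dir, r_dir) if ri == 0 and zi * di > 0
    )

    def ratio(hit, miss):
        if hit + miss == 0:
            return math.nan
        if mode == NORMALIZED:
            return hit / (hit + miss)
        return math.inf if miss == 0 else hit / miss

    return ratio(n_same, n_opp), ratio(n_disc, n_conc)


class TestConcordance:
    def test_identical_signatures_cr_one(self):
        z = make_signature({"a": 1, "b": -1, "c": 1})
        cr, _ = concordance_ratio(z, z)
        assert cr == 1.0

    def test_opposite_signatures_cr_zero(self):
        z = make_signature({"a": 1, "b": -1})
        r = make_signature({"a": -1, "b": 1})
        cr, _ = concordance_ratio(z, r)
        assert cr == 0.0

    def test_hand_enumeration_example(self):
        # z=(+2,-1,+3,0), r=(+1,+1,-1,+1): products (+,-,-,.)
        z = SignedSignature.from_arrays(
            list("abcd"), [1, -1, 1, 0], [2.0, -1.0, 3.0, 0.0], [1, 1, 1, 0], "z"
        )
        r = make_signature({"a": 1, "b": 1, "c": -1, "d": 1}, "r")
        cr, counts = concordance_ratio(z, r, NORMALIZED)
        assert cr == pytest.approx(1 / 3)
        assert counts["n_concordant"] == 1 and counts["n_discordant"] == 2
        cr_printed, _ = concordance_ratio(z, r, AS_PRINTED)
        assert cr_printed == pytest.approx(0.5)

    def test_no_overlap_flagged(self):
        z = make_signature({"a": 0, "b": 0, "c": 1})
        r = make_signature({"a": 1, "b": 1, "c": 0})
        cr, counts = concordance_ratio(z, r)
        assert math.isnan(cr) and counts["flagged"]

    def test_as_printed_zero_denominator_flagged_inf(self):
        z = make_signature({"a": 1})
        r = make_signature({"a": 1})
        cr, counts = concordance_ratio(z, r, AS_PRINTED)
        assert math.isinf(cr) and counts["flagged"]


class TestDiscordance:
    def test_full_reversal(self):
        d = make_signature({"a": 1, "b": 1, "c": -1}, "d")
        r = make_signature({"a": 0, "b": 1, "c": 0}, "r")
        z = make_signature({"a": -1, "b": 1, "c": 1}, "z")
        dr, counts = discordance_ratio(z, d, r)
        assert dr == 1.0
        assert counts["n_disease_only_discordant"] == 2

    def test_mimic_gives_zero(self):
        d = make_signature({"a": 1, "b": -1}, "d")
        r = make_signature({"a": 0, "b": 0}, "r")
        dr, _ = discordance_ratio(d, d, r)
        assert dr == 0.0

    def test_reference_covering_everything_flags(self):
        d = make_signature({"a": 1}, "d")
        r = make_signature({"a": 1}, "r")
        z = make_signature({"a": -1}, "z")
        dr, counts = discordance_ratio(z, d, r)
        assert math.isnan(dr) and counts["flagged"]


class TestOrthogonalityScore:
    @pytest.mark.parametrize(
        "cr, dr, expected",
        [(1, 0, 0.0), (0, 1, math.sqrt(2)), (0.25, 0.5, math.sqrt(0.8125))],
    )
    def test_closed_forms(self, cr, dr, expected):
        assert orthogonality_score(cr, dr) == pytest.approx(expected, abs=1e-12)

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            orthogonality_score(math.inf, 0.5)

    @settings(derandomize=True, max_examples=60)
    @given(
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
    )
    def test_bounded_and_pairwise_monotone(self, cr1, cr2, dr):
        lo, hi = sorted([cr1, cr2])
        assert 0.0 <= orthogonality_score(hi, dr) <= math.sqrt(2) + 1e-12
        assert orthogonality_score(hi, dr) <= orthogonality_score(lo, dr) + 1e-12

    def test_monotone_in_cr_and_dr(self):
        crs = np.linspace(0, 1, 21)
        os_vals = [orthogonality_score(c, 0.4) for c in crs]
        assert all(a >= b - 1e-15 for a, b in zip(os_vals, os_vals[1:]))
        drs = np.linspace(0, 1.5, 21)
        os_vals = [orthogonality_score(0.4, d) for d in drs]
        assert all(a <= b + 1e-15 for a, b in zip(os_vals, os_vals[1:]))


class TestSignProperties:
    def _random_triple(self, rng, n_genes):
        genes = [f"g{i}" for i in range(n_genes)]
        dirs = lambda: rng.choice([-1, 0, 1], size=n_genes)  # noqa: E731
        return (
            make_signature(dict(zip(genes, dirs())), "z"),
            make_signature(dict(zip(genes, dirs())), "d"),
            make_signature(dict(zip(genes, dirs())), "r"),
        )

    def test_scale_invariance_of_normalized_ratios(self):
        rng = np.random.default_rng(17)
        z, d, r = self._random_triple(rng, 30)
        scaled = SignedSignature(
            z.frame.assign(magnitude=z.frame["magnitude"] * 7.5), name="z"
        )
        assert concordance_ratio(z, r)[0] == concordance_ratio(scaled, r)[0]
        assert discordance_ratio(z, d, r)[0] == discordance_ratio(scaled, d, r)[0]

    def test_negating_z_complements_ratios(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            z, d, r = self._random_triple(rng, 25)
            neg = SignedSignature(
                z.frame.assign(
                    direction=-z.frame["direction"], magnitude=-z.frame["magnitude"]
                ),
                name="negz",
            )
            cr, ci = concordance_ratio(z, r)
            ncr, _ = concordance_ratio(neg, r)
            if not ci["flagged"]:
                assert ncr == pytest.approx(1 - cr)
            dr, di = discordance_ratio(z, d, r)
            ndr, _ = discordance_ratio(neg, d, r)
            if not di["flagged"]:
                assert ndr == pytest.approx(1 - dr)

    def test_counts_bounded_by_joint_active_set(self):
        rng = np.random.default_rng(29)
        z, d, r = self._random_triple(rng, 40)
        _, counts = concordance_ratio(z, r)
        joint = len(set(z.active_genes()) & set(r.active_genes()))
        assert counts["n_concordant"] + counts["n_discordant"] <= joint


class TestRanking:
    genes = ["g1", "g2", "g3", "g4"]

    def _panel(self):
        # ref up on g1,g2; mirror matches ref and the disease; anti opposes both
        rows = [
            ("ref", "CL0", "e0", [2, 2, 0, 0]),
            ("mirror", "CL0", "e0", [2, 2, 2, 2]),
            ("anti", "CL0", "e0", [-2, -2, -2, -2]),
        ]
        return make_panel(rows, self.genes)

    def test_identical_compound_scores_zero(self):
        panel = self._panel()
        disease = make_signature({"g1": 0, "g2": 0, "g3": 1, "g4": 1}, "d")
        result = rank_candidates(panel, "ref", disease, top_k=2)
        mirror = result.table.set_index("compound").loc["mirror"]
        assert mirror["cr"] == 1.0 and mirror["dr"] == 0.0 and mirror["os"] == 0.0
        anti = result.table.set_index("compound").loc["anti"]
        assert anti["os"] == pytest.approx(math.sqrt(2))
        assert result.top_compounds == ["anti", "mirror"]

    def test_tie_broken_by_dr_then_compound_id(self):
        rows = [
            ("ref", "CL0", "e0", [2, 2, 0, 0]),
            ("beta", "CL0", "e0", [-2, -2, -2, -2]),
            ("alpha", "CL0", "e0", [-2, -2, -2, -2]),
        ]
        panel = make_panel(rows, self.genes)
        disease = make_signature({"g3": 1, "g4": 1}, "d")
        result = rank_candidates(panel, "ref", disease, top_k=3)
        assert result.top_compounds == ["alpha", "beta"]

    def test_rerun_is_bit_identical_and_a_permutation(self):
        panel = self._panel()
        disease = make_signature({"g3": 1, "g4": 1}, "d")
        r1 = rank_candidates(panel, "ref", disease, top_k=2)
        r2 = rank_candidates(panel, "ref", disease, top_k=2)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert sorted(r1.table["compound"]) == ["anti", "mirror"]

    def test_top_k_larger_than_valid_warns(self):
        panel = self._panel()
        disease = make_signature({"g3": 1, "g4": 1}, "d")
        with pytest.warns(UserWarning, match="top_k"):
            rank_candidates(panel, "ref", disease, top_k=10)


class TestCorrelationNetwork:
    def _tcs(self, directions, name):
        return make_signature(directions, name)

    def test_duplicates_share_edge_and_cluster(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(500)]
        v = rng.choice([-1, 0, 1], size=500)
        other = rng.choice([-1, 0, 1], size=500)
        tcs = {
            "dup1": make_signature(dict(zip(genes, v)), "dup1"),
            "dup2": make_signature(dict(zip(genes, v)), "dup2"),
            "indep": make_signature(dict(zip(genes, other)), "indep"),
        }
        net = tcs_correlation_network(tcs, threshold=0.7)
        assert net.graph.number_of_edges() == 1
        assert net.graph.has_edge("dup1", "dup2")
        assert net.clusters["dup1"] == net.clusters["dup2"]
        # oracle: direct correlation computation
        direct = np.corrcoef(
            np.array(v, dtype=float), np.array(other, dtype=float)
        )[0, 1]
        assert net.correlations.loc["dup1", "indep"] == pytest.approx(direct)
        assert net.correlations.loc["dup1", "dup2"] == pytest.approx(1.0)

    def test_anticorrelated_pair_has_no_edge(self):
        genes = [f"g{i}" for i in range(50)]
        v = np.resize([1, -1, 0], 50)
        tcs = {
            "z": make_signature(dict(zip(genes, v)), "z"),
            "negz": make_signature(dict(zip(genes, -v)), "negz"),
        }
        net = tcs_correlation_network(tcs)
        assert net.correlations.loc["z", "negz"] == pytest.approx(-1.0)
        assert net.graph.number_of_edges() == 0

    def test_zero_variance_excluded_with_warning(self):
        genes = ["a", "b"]
        tcs = {
            "flat": make_signature({"a": 0, "b": 0}, "flat"),
            "x": make_signature({"a": 1, "b": -1}, "x"),
            "y": make_signature({"a": 1, "b": -1}, "y"),
        }
        with pytest.warns(UserWarning, match="zero-variance"):
            net = tcs_correlation_network(tcs)
        assert net.excluded == ["flat"]


class TestBruteForceOracle:
    def test_ratios_match_sign_product_counter(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = int(rng.integers(3, 21))
            genes = [f"g{i}" for i in range(n)]
            zd = rng.choice([-1, 0, 1], size=n)
            dd = rng.choice([-1, 0, 1], size=n)
            rd = rng.choice([-1, 0, 1], size=n)
            z = make_signature(dict(zip(genes, zd)), "z")
            d = make_signature(dict(zip(genes, dd)), "d")
            r = make_signature(dict(zip(genes, rd)), "r")
            if (rd != 0).sum() == 0 or (dd != 0).sum() == 0:
                continue
            for mode in (NORMALIZED, AS_PRINTED):
                exp_cr, exp_dr = brute_force_ratios(zd, dd, rd, mode)
                cr, _ = concordance_ratio(z, r, mode)
                dr, _ = discordance_ratio(z, d, r, mode)
                for got, want in ((cr, exp_cr), (dr, exp_dr)):
                    if math.isnan(want):
                        assert math.isnan(got)
                    else:
                        assert got == want
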