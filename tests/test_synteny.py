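"""Plurality voting, map anchor joins and inversion detection."""
import numpy as np
import pandas as pd
import pytest

from bacatlas import synteny as syn
from bacatlas.errors import DataError


def hits_frame(rows):
    return pd.DataFrame(rows, columns=["query_id", "subject_chrom", "subject_pos", "evalue"])


class TestVoteBac:
    def test_single_hit_places(self):
        v = syn.vote_bac(hits_frame([("b", "Os1", 5_000_000, 1e-30)]))
        assert (v.status, v.chrom, v.position) == ("placed", "Os1", 5_000_000.0)

    def test_tie_gives_no_placement(self):
        rows = [("b", "Os1", i, 1e-30) for i in range(3)] + [("b", "Os5", i, 1e-30) for i in range(3)]
        v = syn.vote_bac(hits_frame(rows))
        assert v.status == "tied" and v.chrom is None

    def test_mean_position_over_winning_chromosome_only(self):
        rows = [("b", "Os2", 1.0, 1e-30), ("b", "Os2", 2.0, 1e-30),
                ("b", "Os2", 6.0, 1e-30), ("b", "Os7", 9.0, 1e-30)]
        v = syn.vote_bac(hits_frame(rows))
        assert v.chrom == "Os2" and v.position == pytest.approx(3.0)

    def test_weak_evalue_hits_ignored(self):
        rows = [("b", "Os1", 1.0, 1e-30), ("b", "Os2", 2.0, 1e-19), ("b", "Os2", 3.0, 1e-10)]
        v = syn.vote_bac(hits_frame(rows))
        assert v.chrom == "Os1"
        rows_all_weak = [("b", "Os2", 2.0, 1e-19)]
        assert syn.vote_bac(hits_frame(rows_all_weak)).status == "no_hits"

    def test_order_invariance_and_winner_monotonicity(self):
        rows = [("b", "Os2", 1.0, 1e-30), ("b", "Os2", 2.0, 1e-30), ("b", "Os7", 9.0, 1e-30)]
        v1 = syn.vote_bac(hits_frame(rows))
        v2 = syn.vote_bac(hits_frame(list(reversed(rows))))
        assert (v1.chrom, v1.position, v1.votes) == (v2.chrom, v2.position, v2.votes)
        # adding a hit on the winner never unseats it
        v3 = syn.vote_bac(hits_frame(rows + [("b", "Os2", 5.0, 1e-30)]))
        assert v3.chrom == "Os2"


class TestVoteContig:
    def mk(self, chrom, pos):
        return syn.SyntenyVote(bac_id="x", status="placed", chrom=chrom, position=pos)

    def test_mean_of_members(self):
        v = syn.vote_contig([self.mk("Os3", 10), self.mk("Os3", 20), self.mk("Os3", 30)])
        assert v.chrom == "Os3" and v.position == pytest.approx(20.0)

    def test_minority_member_excluded_from_mean(self):
        v = syn.vote_contig([self.mk("Os3", 10), self.mk("Os3", 30), self.mk("Os8", 99)])
        assert v.chrom == "Os3" and v.position == pytest.approx(20.0)

    def test_single_member_equals_member_vote(self):
        m = self.mk("Os5", 42.0)
        v = syn.vote_contig([m])
        assert (v.chrom, v.position) == (m.chrom, m.position)

    def test_no_placed_members(self):
        v = syn.vote_contig([syn.SyntenyVote(bac_id="x", status="no_hits")])
        assert v.status == "no_hits"
        with pytest.raises(DataError):
            syn.vote_contig([])


class TestAnchorJoin:
    def test_single_chain(self):
        pairs = syn.anchor_join(
            pd.DataFrame([{"marker_id": "m", "group": "1D", "cm": 10.0}]),
            pd.DataFrame([{"marker_id": "m", "bac_id": "bacX"}]),
            pd.DataFrame([{"bac_id": "bacX", "group": "1H", "cm": 12.0}]),
            [("1D", "1H")],
        )
        assert len(pairs) == 1
        assert pairs.iloc[0]["cm_a"] == 10.0 and pairs.iloc[0]["cm_b"] == 12.0

    def test_non_orthologous_chain_dropped(self):
        pairs = syn.anchor_join(
            pd.DataFrame([{"marker_id": "m", "group": "1D", "cm": 10.0}]),
            pd.DataFrame([{"marker_id": "m", "bac_id": "bacX"}]),
            pd.DataFrame([{"bac_id": "bacX", "group": "5H", "cm": 12.0}]),
            [("1D", "1H")],
        )
        assert pairs.empty

    def test_twenty_marker_join_size_matches_hand_count(self):
        # 20 markers: 12 chain to orthologous groups, 5 to non-orthologous,
        # 3 have no BAC link; one chain is duplicated and must collapse
        map_a = pd.DataFrame(
            [{"marker_id": f"m{i}", "group": "1D", "cm": float(i)} for i in range(20)]
        )
        links = pd.DataFrame(
            [{"marker_id": f"m{i}", "bac_id": f"bac{i}"} for i in range(17)]
            + [{"marker_id": "m0", "bac_id": "bac0"}]  # duplicate chain
        )
        map_b = pd.DataFrame(
            [{"bac_id": f"bac{i}", "group": "1H" if i < 12 else "3H", "cm": float(i)} for i in range(17)]
        )
        pairs = syn.anchor_join(map_a, links, map_b, [("1D", "1H")])
        assert len(pairs) == 12

    def test_marker_on_two_groups_raises(self):
        map_a = pd.DataFrame(
            [
                {"marker_id": "m", "group": "1D", "cm": 1.0},
                {"marker_id": "m", "group": "2D", "cm": 2.0},
            ]
        )
        with pytest.raises(DataError, match="more than one linkage group"):
            syn.anchor_join(map_a, pd.DataFrame(columns=["marker_id", "bac_id"]),
                            pd.DataFrame(columns=["bac_id", "group", "cm"]), [])

    def test_join_monotone_under_orthology_restriction(self):
        map_a = pd.DataFrame(
            [{"marker_id": f"m{i}", "group": "1D" if i % 2 else "2D", "cm": float(i)} for i in range(10)]
        )
        links = pd.DataFrame([{"marker_id": f"m{i}", "bac_id": f"b{i}"} for i in range(10)])
        map_b = pd.DataFrame(
            [{"bac_id": f"b{i}", "group": "1H" if i % 2 else "2H", "cm": float(i)} for i in range(10)]
        )
        full = syn.anchor_join(map_a, links, map_b, [("1D", "1H"), ("2D", "2H")])
        restricted = syn.anchor_join(map_a, links, map_b, [("1D", "1H")])
        assert len(restricted) <= len(full)


class TestInversions:
    def collinear(self, n=60):
        cm = np.linspace(0, 100, n)
        return pd.DataFrame({"cm_a": cm, "cm_b": cm * 0.8 + 1})

    def test_collinear_pairs_give_no_inversions(self):
        assert syn.detect_inversions(self.collinear()).empty

    def test_reversed_block_reported_once_covering_block(self):
        pairs = self.collinear(60)
        block = slice(25, 40)  # 15 reversed markers
        vals = pairs.loc[block.start : block.stop - 1, "cm_b"].to_numpy()
        pairs.loc[block.start : block.stop - 1, "cm_b"] = vals[::-1]
        inv = syn.detect_inversions(pairs, window_size=10, min_run=2)
        assert len(inv) == 1
        cm_a = pairs["cm_a"].to_numpy()
        assert inv.iloc[0]["cm_a_start"] <= cm_a[block.start]
        assert inv.iloc[0]["cm_a_end"] >= cm_a[block.stop - 1]

    def test_global_reversal_flips_every_window(self):
        pairs = self.collinear(40)
        flipped = pairs.assign(cm_b=-pairs["cm_b"])
        inv = syn.detect_inversions(flipped, window_size=10, min_run=2)
        assert len(inv) == 1
        assert inv.iloc[0]["n_windows"] == 40 - 10 + 1

    def test_too_few_pairs_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="window_size"):
            out = syn.detect_inversions(self.collinear(5), window_size=10)
        assert out.empty


def test_noise_free_voting_recovers_origin_and_order(clean_genome):
    """On collinear ortholog layouts every placed BAC lands on the true
    chromosome and voted positions track true positions."""
    from scipy import stats as sps

    from bacatlas.synthetic import simulate_bac_library, simulate_hit_table

    lib = simulate_bac_library(clean_genome, n_clones=80, insert_mean=40_000,
                               insert_sd=4_000, node_split=2, seed=21)
    hits = simulate_hit_table(lib, clean_genome, noise=0.0, seed=22)
    votes = syn.vote_table(hits)
    placed = votes[votes["status"] == "placed"]
    idx = {c: f"Os{i + 1}" for i, c in enumerate(clean_genome.chrom_names)}
    truth = lib.truth.set_index("bac_id")
    assert (placed["chrom"] == [idx[truth.loc[b, "chrom"]] for b in placed["bac_id"]]).all()
    mids = [(truth.loc[b, "start"] + truth.loc[b, "end"]) / 2 for b in placed["bac_id"]]
    rho = sps.spearmanr(placed["position"], mids).statistic
    assert rho >= 0.99
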