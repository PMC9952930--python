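"""Profile-HMM marker search, best hits, class demarcation, profile building."""

import numpy as np
import pytest

from maveritax.genome_io import ProteinRecord
from maveritax.marker_detection import (
    InsufficientReferencesError,
    MarkerHit,
    MarkerTable,
    ProfileSet,
    assign_class,
    best_hits,
    build_marker_profiles,
    filter_by_profile_coverage,
    search_markers,
)
from maveritax.synthetic import mutate_protein, random_protein


def make_hit(genome="g1", marker="MCP", profile="MCP_1", protein="g1_1",
             score=100.0, evalue=1e-30, cov=0.9):
    return MarkerHit(genome, marker, profile, protein, score, evalue, cov)


class TestSearchMarkers:
    def test_profile_consensus_scores_high(self, small_profiles):
        name = sorted(p for p in small_profiles.profiles if p.startswith("MCP"))[0]
        consensus = str(small_profiles.profiles[name].consensus).upper()
        hits = search_markers([ProteinRecord(id="q_1", sequence=consensus)], small_profiles)
        mcp = [h for h in hits if h.marker == "MCP"]
        assert mcp and max(h.bit_score for h in mcp) >= 100

    def test_shuffled_protein_of_same_composition_misses(self, small_profiles, rng):
        name = sorted(p for p in small_profiles.profiles if p.startswith("MCP"))[0]
        consensus = str(small_profiles.profiles[name].consensus).upper()
        shuffled = "".join(rng.permutation(list(consensus)))
        hits = search_markers([ProteinRecord(id="q_1", sequence=shuffled)], small_profiles)
        assert hits == []

    def test_empty_protein_set(self, small_profiles):
        assert search_markers([], small_profiles) == []

    def test_repeated_runs_identical(self, small_set, small_profiles):
        gid = small_set.query_ids[0]
        prots = [
            ProteinRecord(id=f"{gid}_{i+1}", sequence=seq)
            for i, (pid, seq) in enumerate(sorted(small_set.marker_proteins["MCP"].items()))
            if pid.startswith(gid)
        ]
        first = search_markers(prots, small_profiles)
        second = search_markers(prots, small_profiles)
        assert first == second

    def test_member_markers_detected_with_coverage(self, small_set, small_profiles):
        gid = small_set.query_ids[0]
        prots = [
            ProteinRecord(id=f"{gid}_{k+1}", sequence=small_set.marker_proteins[m][f"{gid}.{m}"])
            for k, m in enumerate(["MCP", "Penton", "ATPase", "PRO"])
        ]
        tables = best_hits(search_markers(prots, small_profiles))
        assert tables[gid].n_markers_detected == 4
        for hit in tables[gid].best.values():
            assert 0 < hit.profile_coverage <= 1
            assert hit.profile_coverage > 0.9  # full-length plants


class TestBestHits:
    def test_keeps_highest_score(self):
        t = best_hits([make_hit(score=80.0), make_hit(score=120.0, profile="MCP_2")])
        assert t["g1"].best["MCP"].bit_score == 120.0

    def test_tie_breaks_by_evalue_then_profile(self):
        hits = [
            make_hit(score=90.0, evalue=1e-20, profile="MCP_2"),
            make_hit(score=90.0, evalue=1e-25, profile="MCP_3"),
            make_hit(score=90.0, evalue=1e-25, profile="MCP_1"),
        ]
        assert best_hits(hits)["g1"].best["MCP"].profile_id == "MCP_1"

    def test_marker_counts(self):
        four = [make_hit(marker=m, profile=f"{m}_1") for m in ("MCP", "Penton", "ATPase", "PRO")]
        assert best_hits(four)["g1"].n_markers_detected == 4
        assert best_hits(four[:1])["g1"].n_markers_detected == 1

    def test_plv_hit_tracked_separately(self):
        t = best_hits([make_hit(marker="PLV_ATPase", profile="PLV_ATPase_1", score=70.0)])
        assert t["g1"].n_markers_detected == 0
        assert t["g1"].plv_hit.bit_score == 70.0


class TestAssignClass:
    def test_strong_mcp_assigns(self):
        t = best_hits([make_hit(score=120.0)])["g1"]
        assert assign_class(t).in_maveriviricetes

    def test_class_call_flips_exactly_at_threshold(self):
        below = best_hits([make_hit(score=49.999)])["g1"]
        at = best_hits([make_hit(score=50.0)])["g1"]
        assert not assign_class(below).in_maveriviricetes
        assert assign_class(at).in_maveriviricetes

    def test_candidate_flag_for_three_markers_without_mcp(self):
        hits = [make_hit(marker=m, profile=f"{m}_1", score=90.0) for m in ("Penton", "ATPase", "PRO")]
        a = assign_class(best_hits(hits)["g1"])
        assert not a.in_maveriviricetes and a.candidate_flag

    def test_weak_mcp_with_strong_others_is_candidate(self):
        hits = [make_hit(score=49.0)] + [
            make_hit(marker=m, profile=f"{m}_1", score=200.0) for m in ("Penton", "ATPase", "PRO")
        ]
        a = assign_class(best_hits(hits)["g1"])
        assert not a.in_maveriviricetes and a.candidate_flag

    def test_plv_flag_only_outside_class(self):
        plv = make_hit(marker="PLV_ATPase", profile="PLV_ATPase_1", score=60.0)
        alone = assign_class(best_hits([plv])["g1"])
        assert alone.possible_plv
        with_mcp = assign_class(best_hits([plv, make_hit(score=120.0)])["g1"])
        assert with_mcp.in_maveriviricetes and not with_mcp.possible_plv

    def test_monotone_in_mcp_score(self):
        for lo in (50.0, 80.0, 300.0):
            t = best_hits([make_hit(score=lo)])["g1"]
            assert assign_class(t).in_maveriviricetes
        # raising the score never flips an assigned genome to unassigned
        assert assign_class(best_hits([make_hit(score=1e4)])["g1"]).in_maveriviricetes

    def test_no_markers_at_all(self):
        a = assign_class(MarkerTable(genome_id="g1"))
        assert not (a.in_maveriviricetes or a.candidate_flag or a.possible_plv)


class TestCoverageFilter:
    @pytest.mark.parametrize("cov,kept", [(0.59, False), (0.60, True), (0.61, True)])
    def test_flips_at_threshold(self, cov, kept):
        out = filter_by_profile_coverage([make_hit(cov=cov)])
        assert bool(out) == kept

    def test_empty_input(self):
        assert filter_by_profile_coverage([]) == []


class TestBuildMarkerProfiles:
    def test_two_divergent_groups_give_two_profiles(self, rng):
        a = random_protein(rng, 300)
        b = random_protein(rng, 300)
        refs = {
            "MCP": {
                **{f"a{i}": mutate_protein(rng, a, 0.9) for i in range(15)},
                **{f"b{i}": mutate_protein(rng, b, 0.9) for i in range(15)},
            }
        }
        ps = build_marker_profiles(refs, min_group=10)
        assert sorted(ps.marker_of.values()) == ["MCP", "MCP"]

    def test_near_identical_set_gives_one_profile(self, rng):
        a = random_protein(rng, 250)
        refs = {"PRO": {f"s{i}": mutate_protein(rng, a, 0.97) for i in range(30)}}
        ps = build_marker_profiles(refs, min_group=10)
        assert list(ps.marker_of.values()) == ["PRO"]

    def test_too_few_references_raise(self, rng):
        refs = {"MCP": {f"s{i}": random_protein(rng, 200) for i in range(9)}}
        with pytest.raises(InsufficientReferencesError, match="insufficient references"):
            build_marker_profiles(refs, min_group=10)

    def test_fixture_profiles_cover_all_markers(self, small_profiles):
        markers = set(small_profiles.marker_of.values())
        assert markers == {"MCP", "Penton", "ATPase", "PRO", "PLV_ATPase"}

    def test_roundtrip_through_hmm_file(self, small_profiles, tmp_path):
        path = tmp_path / "profiles.hmm"
        small_profiles.write(path)
        loaded = ProfileSet.from_files([path])
        assert set(loaded.profiles) == set(small_profiles.profiles)
        assert loaded.marker_of == small_profiles.marker_of

    def test_unreadable_profile_file_raises(self, tmp_path):
        bad = tmp_path / "bad.hmm"
        bad.write_text("this is not a profile\n")
        with pytest.raises(ValueError, match="bad.hmm"):
            ProfileSet.from_files([bad])
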