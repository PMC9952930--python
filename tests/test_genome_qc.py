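"""Terminal repeats, trimming, integration screening, completeness calls."""

import numpy as np
import pytest

from maveritax import genome_io, genome_qc
from maveritax.genome_io import GenomeRecord, call_orfs, revcomp
from maveritax.genome_qc import (
    TerminalRepeat,
    call_completeness,
    detect_terminal_repeats,
    gc_profile,
    screen_integration,
    trim_dtr,
    trim_host_region,
)
from maveritax.synthetic import FixtureSpec, _suppress_orfs, generate_fixture_set, random_dna


def repeat_oracle(seq, min_len=10, max_len=5000):
    """Exhaustive scan over all candidate lengths, collecting every match and
    choosing by (length, direct-over-inverted)."""
    L = len(seq)
    found = []
    for n in range(min_len, min(max_len, L // 2) + 1):
        if seq[:n] == seq[-n:]:
            found.append((n, 0, "direct"))
        if seq[:n] == revcomp(seq[-n:]):
            found.append((n, 1, "inverted"))
    if not found:
        return None
    n, _, kind = max(found, key=lambda t: (t[0], -t[1]))
    return kind, n


class TestDetectTerminalRepeats:
    def test_planted_direct_repeat(self, rng):
        R = random_dna(rng, 15, 0.5)
        X = random_dna(rng, 1000, 0.5)
        rep = detect_terminal_repeats(R + X + R)
        assert (rep.kind, rep.length, rep.repeat_seq) == ("direct", 15, R)

    def test_planted_inverted_repeat(self, rng):
        R = random_dna(rng, 15, 0.5)
        X = random_dna(rng, 1000, 0.5)
        rep = detect_terminal_repeats(R + X + revcomp(R))
        assert (rep.kind, rep.length) == ("inverted", 15)

    def test_detection_flips_at_minimum_length(self, rng):
        X = random_dna(rng, 800, 0.5)
        for n, expected in [(9, None), (10, "direct")]:
            while True:  # make sure no accidental longer repeat exists
                R = random_dna(rng, n, 0.5)
                seq = R + X + R
                if n == 9 and seq[:10] == seq[-10:]:
                    continue
                break
            rep = detect_terminal_repeats(seq)
            if expected is None:
                assert rep is None or rep.length < 10 if rep else rep is None
                assert rep is None
            else:
                assert rep is not None and rep.kind == expected and rep.length >= 10

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, int(rng.integers(200, 2000)), float(rng.uniform(0.3, 0.7)))
        if seed % 2:  # plant a repeat in half the cases
            R = random_dna(rng, int(rng.integers(10, 40)), 0.5)
            seq = R + seq + (R if seed % 4 == 1 else revcomp(R))
        got = detect_terminal_repeats(seq)
        want = repeat_oracle(seq)
        if want is None:
            assert got is None
        else:
            assert (got.kind, got.length) == want

    def test_short_sequence_raises(self):
        with pytest.raises(ValueError, match="too short"):
            detect_terminal_repeats("ACGTACGTACGTACGTACGT")


class TestTrimDtr:
    def test_length_arithmetic(self, rng):
        core = random_dna(rng, 20000, 0.45)
        genome = GenomeRecord(id="g", sequence=core + core[:15])
        rep = detect_terminal_repeats(genome.sequence)
        trimmed, report = trim_dtr(genome, rep)
        assert len(genome.sequence) == 20015
        assert report.trimmed_length == 20000
        assert trimmed.topology == "dtr_trimmed"

    def test_idempotent_on_planted_fixture(self):
        spec = FixtureSpec(
            seed=9, n_families=1, genomes_per_family=1,
            genome_length_range=(15000, 18000), dtr_length=20,
            n_plv_genomes=0, n_decoys=0, dupes_per_family=0,
        )
        g = generate_fixture_set(spec).genomes[0]
        rep = detect_terminal_repeats(g.sequence)
        assert (rep.kind, rep.length) == ("direct", 20)
        trimmed, _ = trim_dtr(g, rep)
        assert detect_terminal_repeats(trimmed.sequence) is None

    def test_itr_refused(self):
        rep = TerminalRepeat("inverted", 12, "ACGTACGTACGT")
        with pytest.raises(ValueError, match="ITRs are not trimmed"):
            trim_dtr(GenomeRecord(id="g", sequence="A" * 100), rep)

    def test_junction_spanning_gene_rotated_to_intergenic_gap(self, rng):
        # tiny circular genome whose only >=50 aa ORF is the planted gene
        from _fixtures import clean_gene_circle

        circle, protein = clean_gene_circle(rng)
        L = len(circle)
        # locate the gene on the circle, then reopen it mid-gene + DTR copy
        doubled = GenomeRecord(id="d", sequence=circle + circle)
        gene = next(
            c for c in call_orfs(doubled) if c.protein == protein and c.start <= L
        )
        cut = (gene.start + gene.end) // 2  # 1-based position inside the gene
        reopened = circle[cut:] + circle[:cut]
        genome = GenomeRecord(id="g", sequence=reopened + reopened[:15])
        rep = detect_terminal_repeats(genome.sequence)
        trimmed, report = trim_dtr(genome, rep)
        # the gene must be contiguous in the rotated output
        assert any(c.protein == protein for c in call_orfs(trimmed))
        # oracle: smallest rotation that yields the full gene on the linear seq
        want = next(
            s
            for s in range(L)
            if any(
                c.protein == protein
                for c in call_orfs(
                    GenomeRecord(id="r", sequence=reopened[s:] + reopened[:s])
                )
            )
        )
        assert report.start_shift == want


class TestGcProfile:
    def test_single_window_equals_whole_sequence_gc(self, rng):
        seq = random_dna(rng, 100, 0.6)
        prof = gc_profile(seq, window=100)
        assert len(prof) == 1
        want = (seq.count("G") + seq.count("C")) / 100
        assert prof[0] == pytest.approx(want)

    def test_window_count_and_range(self, rng):
        seq = random_dna(rng, 1050, 0.4)
        prof = gc_profile(seq, window=100)
        assert len(prof) == 11  # ten full windows plus the 50-nt tail
        assert np.all((prof >= 0) & (prof <= 1))


class TestScreenIntegration:
    def test_uniform_genomes_mostly_clean(self):
        # the GC rule (|diff| >= 0.05 between 2-kb means) sits at ~3 sigma on
        # random sequence, so demand a low false-positive rate, not zero
        clean = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            g = GenomeRecord(id=f"g{seed}", sequence=random_dna(rng, 12000, 0.45))
            screen = screen_integration(g, call_orfs(g))
            assert screen.long_intergenic_regions == []
            clean += not screen.candidate_boundaries
        assert clean >= 4

    def test_planted_intergenic_gap_listed(self, rng):
        left = random_dna(rng, 3000, 0.45)
        gap = _suppress_orfs(random_dna(rng, 1200, 0.45), rng)
        right = random_dna(rng, 3000, 0.45)
        g = GenomeRecord(id="g", sequence=left + gap + right)
        screen = screen_integration(g, call_orfs(g))
        assert any(
            s <= 3001 <= e or (s >= 3001 - 100 and e - s + 1 >= 1000)
            for s, e in screen.long_intergenic_regions
        )

    def test_gc_shift_boundary_recovered_near_true_junction(self):
        spec = FixtureSpec(
            seed=11, n_families=1, genomes_per_family=1,
            genome_length_range=(16000, 20000), host_flank_length=5000,
            gc_element=0.35, gc_host=0.60,
            n_plv_genomes=0, n_decoys=0, dupes_per_family=0,
        )
        fs = generate_fixture_set(spec)
        g = fs.genomes[0]
        truth = fs.truth_genomes.iloc[0]
        screen = screen_integration(g, call_orfs(g))
        assert any(abs(b - truth.element_start) <= 500 for b in screen.candidate_boundaries)
        assert any(abs(b - truth.element_end) <= 500 for b in screen.candidate_boundaries)


class TestTrimHostRegion:
    def test_slice_and_provenance(self, rng):
        seq = random_dna(rng, 40000, 0.5)
        g = GenomeRecord(id="g", sequence=seq)
        element, report = trim_host_region(g, (10001, 30000))
        assert len(element.sequence) == 20000
        assert report.start_shift == 10000
        # round-trip: element coordinates map back into the original contig
        assert seq[report.start_shift : report.start_shift + 20000] == element.sequence

    def test_whole_contig_is_identity(self, rng):
        seq = random_dna(rng, 5000, 0.5)
        g = GenomeRecord(id="g", sequence=seq)
        element, report = trim_host_region(g, (1, 5000))
        assert element.sequence == seq and report.start_shift == 0

    def test_out_of_bounds_raises(self, rng):
        g = GenomeRecord(id="g", sequence=random_dna(rng, 1000, 0.5))
        with pytest.raises(ValueError, match="outside sequence"):
            trim_host_region(g, (500, 2000))


class TestCallCompleteness:
    @pytest.mark.parametrize(
        "length,checkv,repeat,flanks,isolate,expected",
        [
            (26000, None, None, None, False, "large_linear"),
            (25000, None, None, None, False, "large_linear"),
            (24999, None, None, None, False, "partial"),
            (20000, 91.0, None, None, False, "checkv_high"),
            (20000, 89.9, None, None, False, "partial"),
            (20000, None, ("direct", 15), None, False, "dtr"),
            (20000, None, ("inverted", 15), None, False, "itr"),
            (20000, None, None, (2000, 2000), False, "integrated_flanked"),
            (20000, None, None, (1999, 2000), False, "partial"),
            (20000, None, None, None, True, "isolate_reference"),
            (30000, 95.0, ("direct", 15), (3000, 3000), True, "isolate_reference"),
        ],
    )
    def test_precedence_and_boundaries(self, rng, length, checkv, repeat, flanks, isolate, expected):
        g = GenomeRecord(id="g", sequence=random_dna(rng, length, 0.5))
        rep = TerminalRepeat(repeat[0], repeat[1], "A" * repeat[1]) if repeat else None
        call = call_completeness(
            g,
            repeat=rep,
            host_flanks=flanks,
            checkv_estimate=checkv,
            is_isolate_reference=isolate,
        )
        assert call.category == expected
        assert call.complete_or_near == (expected != "partial")

    def test_every_genome_gets_exactly_one_category(self, rng):
        cats = set()
        for length in (10000, 26000):
            g = GenomeRecord(id="g", sequence=random_dna(rng, length, 0.5))
            call = call_completeness(g)
            assert call.category in genome_qc.CATEGORIES
            cats.add(call.category)
        assert cats == {"partial", "large_linear"}
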