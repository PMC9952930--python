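"""Genome QC: terminal repeats, integrated-element screening, completeness.

Complete or near-complete virophage genomes are recognised from several
lines of evidence, in a fixed precedence order: isolate reference status,
integration with host flanks on both sides (>= 2 kb), a direct or inverted
terminal repeat, an external completeness estimate >= 90%, or sheer length
(linear contigs >= 25 kb). Everything else is called partial.

Direct terminal repeats (DTRs) indicate a complete, presumably circular
genome assembled with its origin duplicated; the duplicated 3' copy is
trimmed so one genome unit remains. Inverted terminal repeats (ITRs) are
recorded but never trimmed. Integrated elements are screened via long
intergenic regions (>= 1 kb, unusual for a virus annotated with a
prokaryotic-style gene caller) and sustained GC-content shifts; the
automated GC rule here (>= 0.05 absolute difference between >= 2 kb means on
each side of a boundary) is a reproducible stand-in for the expert
inspection such regions normally receive, and both parameters are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome_io import GeneCall, GenomeRecord, call_orfs, revcomp

# completeness categories, in precedence order
CATEGORIES = (
    "isolate_reference",
    "integrated_flanked",
    "dtr",
    "itr",
    "checkv_high",
    "large_linear",
    "partial",
)


@dataclass
class TerminalRepeat:
    kind: str  # 'direct' or 'inverted'
    length: int
    repeat_seq: str

    def __post_init__(self) -> None:
        if self.kind not in ("direct", "inverted"):
            raise ValueError(f"invalid repeat kind {self.kind!r}")
        if self.length < 1 or len(self.repeat_seq) != self.length:
            raise ValueError("repeat length inconsistent with repeat_seq")


@dataclass
class TrimReport:
    genome_id: str
    original_length: int
    trimmed_length: int
    repeat: TerminalRepeat | None = None
    start_shift: int = 0


@dataclass
class IntegrationScreen:
    genome_id: str
    long_intergenic_regions: list[tuple[int, int]] = field(default_factory=list)
    gc_profile: np.ndarray = field(default_factory=lambda: np.empty(0))
    candidate_boundaries: list[int] = field(default_factory=list)
    host_like_segments: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class CompletenessCall:
    genome_id: str
    category: str
    complete_or_near: bool
    checkv_estimate: float | None = None


def detect_terminal_repeats(
    seq: str, min_len: int = 10, max_len: int = 5000
) -> TerminalRepeat | None:
    """Longest exact terminal repeat of length in [min_len, max_len].

    Direct: the 5' prefix equals the 3' suffix. Inverted: the 5' prefix
    equals the reverse complement of the 3' suffix. The longest match wins;
    at equal length, direct is preferred. Matches are exact (the repeat
    definition is "identical sequences"); the cap guards against
    pathological self-similar inputs. Returns None when nothing qualifies.
    """
    seq = seq.upper()
    L = len(seq)
    if L <= 2 * min_len:
        raise ValueError(f"sequence too short ({L} nt) for terminal-repeat search")
    upper = min(max_len, L // 2)
    rc = revcomp(seq)
    for n in range(upper, min_len - 1, -1):
        if seq[:n] == seq[L - n :]:
            return TerminalRepeat("direct", n, seq[:n])
        # suffix reverse complement equals rc prefix
        if seq[:n] == rc[:n]:
            return TerminalRepeat("inverted", n, seq[:n])
    return None


def _circular_cut_ok(cut: int, genes: Sequence[tuple[int, int]], L: int) -> bool:
    """True if cutting between positions cut and cut+1 (circular, 1-based)
    splits no gene. `genes` intervals may wrap past L."""
    for start, end in genes:
        if end <= L:
            if start <= cut < end:
                return False
        else:  # wraps: occupies [start, L] and [1, end - L]
            if cut >= start or cut < end - L:
                return False
    return True


def trim_dtr(
    genome: GenomeRecord,
    repeat: TerminalRepeat,
    min_aa: int = 50,
    genetic_code: int = 11,
) -> tuple[GenomeRecord, TrimReport]:
    """Remove the duplicated 3' copy of a direct terminal repeat.

    After trimming the genome is one circular unit. If an ORF would span the
    new junction (detected on the doubled sequence), the sequence is rotated
    by the smallest start shift that places the junction in an intergenic
    gap, so downstream gene prediction does not truncate a gene at the ends.
    """
    if repeat.kind != "direct":
        raise ValueError("ITRs are not trimmed")
    L0 = len(genome.sequence)
    trimmed = genome.sequence[: L0 - repeat.length]
    L = len(trimmed)

    # genes of the circular unit, from the doubled sequence
    doubled = GenomeRecord(id=genome.id, sequence=trimmed + trimmed, source=genome.source)
    circ_calls = [
        c
        for c in call_orfs(doubled, min_aa=min_aa, genetic_code=genetic_code)
        if c.start <= L and (c.end - c.start + 1) < L
    ]
    # dedupe genes that appear in both copies
    genes = sorted({((c.start - 1) % L + 1, c.end - ((c.start - 1) // L) * L) for c in circ_calls})
    genes = [(s, e) for s, e in genes if e - s + 1 < L]

    shift = 0
    if not _circular_cut_ok(0, genes, L):
        for s in range(1, L):
            if _circular_cut_ok(s, genes, L):
                shift = s
                break
        else:
            shift = 0  # fully coding circle: keep original frame
    rotated = trimmed[shift:] + trimmed[:shift]
    out = GenomeRecord(
        id=genome.id,
        sequence=rotated,
        topology="dtr_trimmed",
        source=genome.source,
    )
    report = TrimReport(
        genome_id=genome.id,
        original_length=L0,
        trimmed_length=L,
        repeat=repeat,
        start_shift=shift,
    )
    return out, report


def gc_profile(seq: str, window: int = 100) -> np.ndarray:
    """Per-window GC fraction (non-overlapping windows; trailing partial
    window included). Ns are excluded from the denominator."""
    seq = seq.upper()
    vals = []
    for i in range(0, len(seq), window):
        win = seq[i : i + window]
        acgt = sum(win.count(b) for b in "ACGT")
        gc = win.count("G") + win.count("C")
        vals.append(gc / acgt if acgt else 0.0)
    return np.asarray(vals)


def _intergenic_regions(gene_calls: Sequence[GeneCall], L: int) -> list[tuple[int, int]]:
    """Gaps (1-based inclusive) not covered by any gene, including termini."""
    if not gene_calls:
        return [(1, L)] if L >= 1 else []
    ivs = sorted((c.start, c.end) for c in gene_calls)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    gaps = []
    prev_end = 0
    for s, e in merged:
        if s > prev_end + 1:
            gaps.append((prev_end + 1, s - 1))
        prev_end = max(prev_end, e)
    if prev_end < L:
        gaps.append((prev_end + 1, L))
    return gaps


def screen_integration(
    genome: GenomeRecord,
    gene_calls: Sequence[GeneCall],
    reference_proteins: dict[str, str] | None = None,
    min_intergenic: int = 1000,
    window: int = 100,
    gc_delta: float = 0.05,
    flank: int = 2000,
    min_ref_bitscore: float = 30.0,
) -> IntegrationScreen:
    """Screen a contig for evidence of an integrated (provirus-like) element.

    Reports intergenic regions >= `min_intergenic`, the non-overlapping
    GC-content profile, and candidate integration boundaries: positions
    where the mean GC over `flank` nt on one side differs from the other
    side by >= `gc_delta` (a run of qualifying positions is collapsed to its
    strongest point). If reference virophage proteins are supplied,
    boundary-delimited segments whose genes show no hit at
    >= `min_ref_bitscore` bits are flagged host-like.
    """
    L = len(genome.sequence)
    seq = genome.sequence
    gaps = [
        (s, e) for s, e in _intergenic_regions(gene_calls, L) if e - s + 1 >= min_intergenic
    ]
    profile = gc_profile(seq, window=window)

    # cumulative GC/ACGT counts for O(1) window means
    is_gc = np.frombuffer(seq.encode(), dtype=np.uint8)
    gc_mask = (is_gc == ord("G")) | (is_gc == ord("C"))
    acgt_mask = gc_mask | (is_gc == ord("A")) | (is_gc == ord("T"))
    cum_gc = np.concatenate([[0], np.cumsum(gc_mask)])
    cum_acgt = np.concatenate([[0], np.cumsum(acgt_mask)])

    def mean_gc(a: int, b: int) -> float:  # 0-based half-open
        n = cum_acgt[b] - cum_acgt[a]
        return (cum_gc[b] - cum_gc[a]) / n if n else 0.0

    candidates: list[int] = []
    diffs: list[float] = []
    for p in range(flank, L - flank + 1, window):
        d = abs(mean_gc(p - flank, p) - mean_gc(p, p + flank))
        if d >= gc_delta:
            candidates.append(p)
            diffs.append(d)
    # collapse runs of adjacent qualifying positions to the strongest one
    boundaries: list[int] = []
    i = 0
    while i < len(candidates):
        j = i
        while j + 1 < len(candidates) and candidates[j + 1] - candidates[j] == window:
            j += 1
        best = max(range(i, j + 1), key=lambda k: diffs[k])
        boundaries.append(candidates[best])
        i = j + 1

    host_like: list[tuple[int, int]] = []
    if reference_proteins and boundaries:
        from .protein_search import blastp

        cuts = [0] + boundaries + [L]
        segments = [(cuts[k] + 1, cuts[k + 1]) for k in range(len(cuts) - 1)]
        prots = {c.protein_id: c.protein for c in gene_calls}
        hits = blastp(prots, reference_proteins, evalue=1e-3)
        hit_ids = set(hits.loc[hits.bitscore >= min_ref_bitscore, "qseqid"])
        seg_has_hit = []
        for s, e in segments:
            seg_genes = [c for c in gene_calls if c.start >= s and c.end <= e]
            seg_has_hit.append(any(c.protein_id in hit_ids for c in seg_genes))
        if any(seg_has_hit):
            for (s, e), has in zip(segments, seg_has_hit):
                if not has:
                    host_like.append((s, e))

    return IntegrationScreen(
        genome_id=genome.id,
        long_intergenic_regions=gaps,
        gc_profile=profile,
        candidate_boundaries=boundaries,
        host_like_segments=host_like,
    )


def trim_host_region(
    genome: GenomeRecord, boundaries: tuple[int, int]
) -> tuple[GenomeRecord, TrimReport]:
    """Extract the element between `boundaries` (1-based inclusive), dropping
    flanking host sequence. Provenance: position p of the element maps to
    p + start_shift in the original contig."""
    start, end = boundaries
    L = len(genome.sequence)
    if not (1 <= start <= end <= L):
        raise ValueError(f"boundaries {boundaries} outside sequence of length {L}")
    element = GenomeRecord(
        id=genome.id,
        sequence=genome.sequence[start - 1 : end],
        topology=genome.topology,
        source=f"{genome.source};host_trimmed[{start}:{end}]",
    )
    report = TrimReport(
        genome_id=genome.id,
        original_length=L,
        trimmed_length=end - start + 1,
        repeat=None,
        start_shift=start - 1,
    )
    return element, report


def host_flank_lengths(
    integration: IntegrationScreen, L: int
) -> tuple[int, int]:
    """Lengths of host-like sequence touching the 5' and 3' contig ends."""
    up = down = 0
    for s, e in integration.host_like_segments:
        if s == 1:
            up = max(up, e - s + 1)
        if e == L:
            down = max(down, e - s + 1)
    return up, down


def call_completeness(
    genome: GenomeRecord,
    trim_report: TrimReport | None = None,
    integration: IntegrationScreen | None = None,
    checkv_estimate: float | None = None,
    is_isolate_reference: bool = False,
    repeat: TerminalRepeat | None = None,
    host_flanks: tuple[int, int] | None = None,
    min_flank: int = 2000,
    min_checkv: float = 90.0,
    min_linear: int = 25000,
) -> CompletenessCall:
    """Assign a completeness category by first match in precedence order.

    isolate_reference > integrated_flanked (host regions >= `min_flank` on
    both sides) > dtr > itr > checkv_high (estimate >= `min_checkv`) >
    large_linear (>= `min_linear` nt) > partial. Exactly one category is
    assigned; everything except partial counts as complete-or-near-complete.
    """
    rep = repeat
    if rep is None and trim_report is not None:
        rep = trim_report.repeat
    flanks = host_flanks
    if flanks is None and integration is not None:
        flanks = host_flank_lengths(integration, len(genome.sequence))

    if is_isolate_reference:
        category = "isolate_reference"
    elif flanks is not None and min(flanks) >= min_flank:
        category = "integrated_flanked"
    elif genome.topology == "dtr_trimmed" or (rep is not None and rep.kind == "direct"):
        category = "dtr"
    elif rep is not None and rep.kind == "inverted":
        category = "itr"
    elif checkv_estimate is not None and checkv_estimate >= min_checkv:
        category = "checkv_high"
    elif len(genome.sequence) >= min_linear:
        category = "large_linear"
    else:
        category = "partial"
    return CompletenessCall(
        genome_id=genome.id,
        category=category,
        complete_or_near=category != "partial",
        checkv_estimate=checkv_estimate,
    )
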