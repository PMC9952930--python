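"""Detection of the conserved virophage morphogenesis genes with profile HMMs.

Virophages (class *Maveriviricetes*) share a four-gene morphogenesis module:
the major capsid protein (MCP, double jelly-roll hexon), the penton (minor
capsid) protein, the FtsK-HerA family genome-packaging ATPase, and a
maturation cysteine protease (PRO). Proteins are searched against a set of
profile HMMs covering these markers (plus one profile for the analogous but
non-homologous ATPase of polinton-like viruses, PLVs), keeping hits with
E-value <= 0.01 and full-sequence bit score >= 40, then reduced to the best
hit per marker per genome. A genome is automatically assigned to the class
when its best MCP hit scores >= 50 bits; genomes with at least three of the
four markers but no qualifying MCP are flagged as candidates for manual
review, and sequences outside the class with a PLV-profile hit >= 50 bits
are flagged as possible PLVs.

Profiles can be rebuilt from labeled reference proteins: an all-vs-all
protein search is clustered with MCL (inflation 5), and every cluster of at
least ten sequences is aligned (MAFFT) and turned into one HMM profile.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pyhmmer

from .clustering import markov_cluster
from .genome_io import ProteinRecord, protein_genome_id
from .protein_search import best_hsp_per_pair, blastp_all_vs_all

MARKERS = ("MCP", "Penton", "ATPase", "PRO")
PLV_MARKER = "PLV_ATPase"

_AMINO = pyhmmer.easel.Alphabet.amino()


class InsufficientReferencesError(ValueError):
    pass


@dataclass
class ProfileSet:
    """Profile HMMs plus the marker each profile detects."""

    profiles: dict[str, pyhmmer.plan7.HMM]
    marker_of: dict[str, str]

    def __post_init__(self) -> None:
        for pid in self.profiles:
            marker = self.marker_of.get(pid)
            if marker not in MARKERS + (PLV_MARKER,):
                raise ValueError(f"profile {pid!r} mapped to unknown marker {marker!r}")

    @classmethod
    def from_files(
        cls, hmm_paths: Iterable[str | Path], marker_of: Mapping[str, str] | None = None
    ) -> "ProfileSet":
        """Load HMMER3 text-format profiles.

        Without an explicit mapping, the marker is inferred from the profile
        name's prefix before the last underscore (e.g. ``MCP_3`` -> MCP).
        """
        profiles: dict[str, pyhmmer.plan7.HMM] = {}
        mapping: dict[str, str] = {}
        for path in hmm_paths:
            try:
                with pyhmmer.plan7.HMMFile(str(path)) as fh:
                    for hmm in fh:
                        name = str(hmm.name)
                        profiles[name] = hmm
                        if marker_of is not None:
                            mapping[name] = marker_of[name]
                        else:
                            mapping[name] = name.rsplit("_", 1)[0]
            except (OSError, ValueError) as exc:
                raise ValueError(f"unreadable profile file {path}: {exc}") from exc
        return cls(profiles=profiles, marker_of=mapping)

    def write(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            for name in sorted(self.profiles):
                self.profiles[name].write(fh)


@dataclass
class MarkerHit:
    genome_id: str
    marker: str
    profile_id: str
    protein_id: str
    bit_score: float
    e_value: float
    profile_coverage: float


@dataclass
class MarkerTable:
    """Per-genome demarcation evidence: best hit per marker."""

    genome_id: str
    best: dict[str, MarkerHit] = field(default_factory=dict)  # marker -> hit
    plv_hit: MarkerHit | None = None

    @property
    def n_markers_detected(self) -> int:
        return sum(1 for m in MARKERS if m in self.best)

    def score(self, marker: str) -> float | None:
        hit = self.best.get(marker)
        return hit.bit_score if hit else None


@dataclass
class ClassAssignment:
    genome_id: str
    in_maveriviricetes: bool
    evidence: MarkerTable
    candidate_flag: bool
    possible_plv: bool


def search_markers(
    proteins: Sequence[ProteinRecord],
    profile_set: ProfileSet,
    min_score: float = 40.0,
    max_evalue: float = 0.01,
) -> list[MarkerHit]:
    """hmmsearch of proteins against all profiles; hits passing score and
    E-value thresholds, sorted deterministically.

    Bit score is the full-sequence score. Profile coverage is the aligned
    profile span of the best domain divided by profile length.
    """
    if not proteins:
        return []
    seqs = [
        pyhmmer.easel.TextSequence(name=p.id, sequence=p.sequence).digitize(_AMINO)
        for p in proteins
    ]
    hmms = [profile_set.profiles[name] for name in sorted(profile_set.profiles)]
    out: list[MarkerHit] = []
    for top_hits in pyhmmer.hmmer.hmmsearch(hmms, seqs, cpus=1, E=max_evalue):
        profile_id = str(top_hits.query.name)
        M = top_hits.query.M
        for hit in top_hits:
            if hit.score < min_score or hit.evalue > max_evalue:
                continue
            dom = hit.best_domain
            aln = dom.alignment
            cov = (aln.hmm_to - aln.hmm_from + 1) / M
            pid = str(hit.name)
            out.append(
                MarkerHit(
                    genome_id=protein_genome_id(pid),
                    marker=profile_set.marker_of[profile_id],
                    profile_id=profile_id,
                    protein_id=pid,
                    bit_score=float(hit.score),
                    e_value=float(hit.evalue),
                    profile_coverage=float(cov),
                )
            )
    out.sort(key=lambda h: (h.genome_id, h.marker, -h.bit_score, h.e_value, h.profile_id))
    return out


def best_hits(hits: Iterable[MarkerHit]) -> dict[str, MarkerTable]:
    """Reduce raw hits to the best hit per marker per genome.

    Ties on bit score break by lower E-value, then lexicographic profile id.
    The PLV profile is tracked separately and never counts toward
    n_markers_detected.
    """
    tables: dict[str, MarkerTable] = {}
    for h in sorted(
        hits, key=lambda h: (h.genome_id, h.marker, -h.bit_score, h.e_value, h.profile_id)
    ):
        table = tables.setdefault(h.genome_id, MarkerTable(genome_id=h.genome_id))
        if h.marker == PLV_MARKER:
            if table.plv_hit is None:
                table.plv_hit = h
        elif h.marker not in table.best:
            table.best[h.marker] = h
    return tables


def assign_class(
    table: MarkerTable, mcp_min: float = 50.0, plv_min: float = 50.0
) -> ClassAssignment:
    """Class demarcation from a genome's marker evidence.

    In the class iff the best MCP hit scores >= `mcp_min` bits. Genomes not
    assigned but showing >= 3 of the 4 markers are flagged candidates.
    The PLV flag is only raised for genomes outside the class (class
    members may legitimately carry a weak PLV-profile cross-hit).
    """
    mcp = table.score("MCP")
    in_class = mcp is not None and mcp >= mcp_min
    candidate = (not in_class) and table.n_markers_detected >= 3
    plv = (
        not in_class
        and table.plv_hit is not None
        and table.plv_hit.bit_score >= plv_min
    )
    return ClassAssignment(
        genome_id=table.genome_id,
        in_maveriviricetes=in_class,
        evidence=table,
        candidate_flag=candidate,
        possible_plv=plv,
    )


def filter_by_profile_coverage(
    hits: Iterable[MarkerHit], min_cov: float = 0.60
) -> list[MarkerHit]:
    """Drop hits covering < `min_cov` of the profile (removes partial gene
    predictions before exporting markers for alignment or classification)."""
    return [h for h in hits if h.profile_coverage >= min_cov]


def _mafft_align(seqs: Mapping[str, str]) -> pyhmmer.easel.DigitalMSA:
    mafft = shutil.which("mafft")
    if mafft is None:
        raise RuntimeError("mafft not found on PATH (required to build profiles)")
    with tempfile.TemporaryDirectory(prefix="maveritax_msa_") as tmp:
        inp = Path(tmp) / "in.faa"
        with open(inp, "w") as fh:
            for sid, seq in sorted(seqs.items()):
                fh.write(f">{sid}\n{seq}\n")
        res = subprocess.run(
            [mafft, "--auto", "--quiet", "--anysymbol", str(inp)],
            check=True,
            capture_output=True,
        )
        out = Path(tmp) / "out.afa"
        out.write_bytes(res.stdout)
        with pyhmmer.easel.MSAFile(str(out), digital=True, alphabet=_AMINO) as fh:
            return fh.read()


def build_marker_profiles(
    reference_proteins_by_marker: Mapping[str, Mapping[str, str]],
    inflation: float = 5.0,
    min_group: int = 10,
    seed: int = 42,
) -> ProfileSet:
    """Build one HMM profile per well-populated cluster of marker proteins.

    For each marker, reference proteins are compared all-vs-all, the
    bit-score-weighted graph is clustered with MCL at the given inflation,
    and every cluster with >= `min_group` members is aligned and compiled
    into a profile named ``<marker>_<k>``. Raises
    :class:`InsufficientReferencesError` when a marker yields no qualifying
    cluster.
    """
    profiles: dict[str, pyhmmer.plan7.HMM] = {}
    marker_of: dict[str, str] = {}
    background = pyhmmer.plan7.Background(_AMINO)
    for marker, seqs in sorted(reference_proteins_by_marker.items()):
        if marker not in MARKERS + (PLV_MARKER,):
            raise ValueError(f"unknown marker {marker!r}")
        groups: list[list[str]]
        if len(seqs) < min_group:
            groups = []
        else:
            hits = best_hsp_per_pair(blastp_all_vs_all(dict(seqs)))
            edges = [
                (q, s, b)
                for q, s, b in zip(hits.qseqid, hits.sseqid, hits.bitscore)
                if q != s
            ]
            groups = [
                g
                for g in markov_cluster(edges, inflation=inflation, nodes=sorted(seqs))
                if len(g) >= min_group
            ]
        if not groups:
            raise InsufficientReferencesError(
                f"insufficient references: no cluster of >= {min_group} sequences "
                f"for marker {marker}"
            )
        for i, group in enumerate(groups, start=1):
            name = f"{marker}_{i}"
            msa = _mafft_align({sid: seqs[sid] for sid in group})
            msa.name = name
            builder = pyhmmer.plan7.Builder(_AMINO, seed=seed)
            hmm, _, _ = builder.build_msa(msa, background)
            profiles[name] = hmm
            marker_of[name] = marker
    return ProfileSet(profiles=profiles, marker_of=marker_of)


def marker_table_rows(
    tables: Mapping[str, MarkerTable],
    assignments: Mapping[str, ClassAssignment] | None = None,
) -> list[dict]:
    """Flatten marker tables (one row per best hit) for TSV export."""
    rows = []
    for gid in sorted(tables):
        t = tables[gid]
        a = assignments.get(gid) if assignments else None
        hits = [t.best[m] for m in MARKERS if m in t.best]
        if t.plv_hit is not None:
            hits.append(t.plv_hit)
        for h in hits:
            rows.append(
                {
                    "genome_id": gid,
                    "marker": h.marker,
                    "profile_id": h.profile_id,
                    "protein_id": h.protein_id,
                    "bit_score": h.bit_score,
                    "e_value": h.e_value,
                    "profile_coverage": round(h.profile_coverage, 4),
                    "n_markers_detected": t.n_markers_detected,
                    "class_call": bool(a.in_maveriviricetes) if a else None,
                    "plv_flag": bool(a.possible_plv) if a else None,
                }
            )
    return rows
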