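"""Family-level assignment of class members by best hit against labeled MCPs.

Within *Maveriviricetes*, seven family-level groups are recognised
(Ruviroviridae, Maviroviridae, Sputniviroviridae, Dishuiviroviridae,
Omnilimnoviroviridae, Gulliviroviridae, Burtonviroviridae). A query MCP is
affiliated with the family of its best-scoring reference hit, provided the
bit score strictly exceeds that family's cutoff. Cutoffs are derived from
the reference set itself: for each family, the highest bit score any
out-of-group sequence achieves against an in-group reference (self-hits
ignored) — a score a query must beat to be distinguishable from the best
impostor. Families with no cross-family hit at all fall back to a
configurable floor (50 bits) so assignment never rides on spurious weak
hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import genome_qc
from .genome_io import GeneCall, GenomeRecord, ProteinRecord, call_orfs, proteins_of
from .marker_detection import (
    MARKERS,
    ClassAssignment,
    MarkerTable,
    ProfileSet,
    assign_class,
    best_hits,
    filter_by_profile_coverage,
    search_markers,
)
from .protein_search import best_hsp_per_pair, blastp

FAMILIES = (
    "Ruviroviridae",
    "Maviroviridae",
    "Sputniviroviridae",
    "Dishuiviroviridae",
    "Omnilimnoviroviridae",
    "Gulliviroviridae",
    "Burtonviroviridae",
)

UNCLASSIFIED = "unclassified_within_class"

REPORT_COLUMNS = [
    "genome_id",
    "length",
    "n_genes",
    "class_call",
    "candidate_flag",
    "possible_plv",
    "n_markers_detected",
    "family",
    "family_best_subject",
    "family_best_score",
    "completeness_category",
    "complete_or_near",
    "phylogenetic_label",
    "error",
    "mcp_score",
    "penton_score",
    "atpase_score",
    "pro_score",
    "plv_atpase_score",
]


@dataclass
class FamilyReferenceDB:
    """Labeled reference MCPs: id -> (sequence, family)."""

    sequences: dict[str, str]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.sequences) ^ set(self.labels)
        if missing:
            raise ValueError(f"reference db sequence/label mismatch for {sorted(missing)}")
        if not self.sequences:
            raise ValueError("empty reference db")

    @property
    def families(self) -> list[str]:
        return sorted(set(self.labels.values()))

    @classmethod
    def from_files(cls, fasta: str | Path, labels_tsv: str | Path) -> "FamilyReferenceDB":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
        labels = {}
        with open(labels_tsv) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                pid, fam = line.split("\t")[:2]
                if pid == "id":
                    continue
                labels[pid] = fam
        return cls(sequences=seqs, labels=labels)

    def write(self, fasta: str | Path, labels_tsv: str | Path) -> None:
        with open(fasta, "w") as fh:
            for pid in sorted(self.sequences):
                fh.write(f">{pid}\n{self.sequences[pid]}\n")
        with open(labels_tsv, "w") as fh:
            fh.write("id\tfamily\n")
            for pid in sorted(self.labels):
                fh.write(f"{pid}\t{self.labels[pid]}\n")


@dataclass
class FamilyCutoffs:
    cutoffs: dict[str, float]
    provenance: dict[str, tuple[str, str]] = field(default_factory=dict)
    floor: float = 50.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fam in sorted(self.cutoffs):
            q, s = self.provenance.get(fam, ("", ""))
            rows.append(
                {"family": fam, "min_bitscore": self.cutoffs[fam], "query": q, "subject": s}
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_tsv(cls, path: str | Path, floor: float = 50.0) -> "FamilyCutoffs":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            cutoffs=dict(zip(df.family, df.min_bitscore)),
            provenance={
                r.family: (str(r.query), str(r.subject))
                for r in df.itertuples()
                if getattr(r, "query", "")
            },
            floor=floor,
        )


@dataclass
class FamilyAssignment:
    genome_id: str
    family: str
    best_subject: str | None
    best_score: float
    passed_cutoff: bool


def derive_cutoffs(db: FamilyReferenceDB, floor: float = 50.0) -> FamilyCutoffs:
    """Per-family minimum bit score from the highest out-of-group hit.

    All-vs-all search of the reference MCPs, self-hits omitted; for each
    family F the cutoff is the maximum bit score over (query not in F,
    subject in F) pairs, or `floor` when no such hit exists.
    """
    if len(db.families) < 2:
        raise ValueError("cannot derive out-of-group cutoffs from a single-family db")
    hits = best_hsp_per_pair(blastp(db.sequences, db.sequences))
    cutoffs: dict[str, float] = {}
    provenance: dict[str, tuple[str, str]] = {}
    for fam in db.families:
        best_score, best_pair = 0.0, None
        for r in hits.itertuples():
            if r.qseqid == r.sseqid:
                continue
            if db.labels[r.sseqid] == fam and db.labels[r.qseqid] != fam:
                if r.bitscore > best_score:
                    best_score, best_pair = float(r.bitscore), (r.qseqid, r.sseqid)
        if best_pair is None:
            cutoffs[fam] = floor
        else:
            cutoffs[fam] = best_score
            provenance[fam] = best_pair
    return FamilyCutoffs(cutoffs=cutoffs, provenance=provenance, floor=floor)


def _assign_from_hits(
    genome_id: str, hits: pd.DataFrame, db: FamilyReferenceDB, cutoffs: FamilyCutoffs
) -> FamilyAssignment:
    if hits.empty:
        return FamilyAssignment(genome_id, UNCLASSIFIED, None, 0.0, False)
    # best hit: bit score, then percent identity, then lexicographic subject
    hits = hits.sort_values(
        ["bitscore", "pident", "sseqid"], ascending=[False, False, True], kind="mergesort"
    )
    top = hits.iloc[0]
    fam = db.labels[top.sseqid]
    cutoff = cutoffs.cutoffs.get(fam, cutoffs.floor)
    passed = float(top.bitscore) > cutoff
    return FamilyAssignment(
        genome_id=genome_id,
        family=fam if passed else UNCLASSIFIED,
        best_subject=str(top.sseqid),
        best_score=float(top.bitscore),
        passed_cutoff=passed,
    )


def assign_family(
    query_mcp: ProteinRecord,
    db: FamilyReferenceDB,
    cutoffs: FamilyCutoffs,
    max_evalue: float = 1e-3,
    exclude_self: bool = True,
) -> FamilyAssignment:
    """Affiliate one MCP with a family by best reference hit above cutoff.

    The comparison against the cutoff is strict (>): the cutoff IS the best
    score an out-of-group sequence achieved, so merely equaling it cannot
    separate in-group from out-group. When the query id is itself in the
    reference db, its self-hit is ignored.
    """
    hits = best_hsp_per_pair(
        blastp({query_mcp.id: query_mcp.sequence}, db.sequences, evalue=max_evalue)
    )
    if exclude_self and not hits.empty:
        hits = hits[hits.sseqid != query_mcp.id]
    return _assign_from_hits(query_mcp.genome_id, hits, db, cutoffs)


def classify_batch(
    genomes: Sequence[GenomeRecord],
    profiles: ProfileSet,
    db: FamilyReferenceDB | None = None,
    cutoffs: FamilyCutoffs | None = None,
    gene_calls: Mapping[str, Sequence[GeneCall]] | None = None,
    checkv: Mapping[str, float] | None = None,
    isolate_ids: set[str] | None = None,
    mcp_min: float = 50.0,
    plv_min: float = 50.0,
    marker_min_score: float = 40.0,
    marker_max_evalue: float = 0.01,
    min_profile_cov: float = 0.60,
) -> pd.DataFrame:
    """Run the full identification + assignment workflow on a batch.

    Per genome: gene calls (supplied, or the built-in ORF fallback), marker
    search, class call, family assignment of the best coverage-qualified MCP
    (class members only, when a reference db is supplied), PLV flag, and a
    completeness call from the evidence at hand. One row per input genome,
    input order preserved; a failing genome yields an ``error`` row and
    never aborts the batch.
    """
    rows: list[dict] = []
    per_genome: dict[str, dict] = {}
    all_proteins: list[ProteinRecord] = []
    calls_by_genome: dict[str, Sequence[GeneCall]] = {}

    for g in genomes:
        try:
            calls = (
                gene_calls.get(g.id) if gene_calls is not None else None
            ) or call_orfs(g)
            calls_by_genome[g.id] = calls
            prots = proteins_of(calls)
            all_proteins.extend(prots)
            per_genome[g.id] = {"n_genes": len(calls), "error": ""}
        except Exception as exc:  # keep the batch alive
            per_genome[g.id] = {"n_genes": 0, "error": str(exc)}

    hits = search_markers(
        all_proteins, profiles, min_score=marker_min_score, max_evalue=marker_max_evalue
    )
    tables = best_hits(hits)
    mcp_queries: dict[str, ProteinRecord] = {}
    prot_seq = {p.id: p.sequence for p in all_proteins}

    for g in genomes:
        info = per_genome[g.id]
        if info["error"]:
            continue
        table = tables.get(g.id, MarkerTable(genome_id=g.id))
        assignment = assign_class(table, mcp_min=mcp_min, plv_min=plv_min)
        info["table"] = table
        info["assignment"] = assignment
        if assignment.in_maveriviricetes and db is not None:
            mcp_hits = [h for h in hits if h.genome_id == g.id and h.marker == "MCP"]
            qualified = filter_by_profile_coverage(mcp_hits, min_cov=min_profile_cov)
            if qualified:
                best = max(qualified, key=lambda h: (h.bit_score, h.protein_id))
                mcp_queries[g.id] = ProteinRecord(
                    id=best.protein_id, sequence=prot_seq[best.protein_id]
                )

    fam_assignments: dict[str, FamilyAssignment] = {}
    if db is not None and mcp_queries:
        if cutoffs is None:
            cutoffs = derive_cutoffs(db)
        qseqs = {p.id: p.sequence for p in mcp_queries.values()}
        bhits = best_hsp_per_pair(blastp(qseqs, db.sequences, evalue=1e-3))
        for gid, prot in mcp_queries.items():
            sub = bhits[(bhits.qseqid == prot.id) & (bhits.sseqid != prot.id)]
            fam_assignments[gid] = _assign_from_hits(gid, sub, db, cutoffs)

    for g in genomes:
        info = per_genome[g.id]
        if info["error"]:
            rows.append(_error_row(g.id, info["error"]))
            continue
        table: MarkerTable = info["table"]
        assignment: ClassAssignment = info["assignment"]
        fam = fam_assignments.get(g.id)
        completeness = genome_qc.call_completeness(
            g,
            checkv_estimate=(checkv or {}).get(g.id),
            is_isolate_reference=g.id in (isolate_ids or set()),
        )
        row = {
            "genome_id": g.id,
            "length": len(g.sequence),
            "n_genes": info["n_genes"],
            "class_call": assignment.in_maveriviricetes,
            "candidate_flag": assignment.candidate_flag,
            "possible_plv": assignment.possible_plv,
            "n_markers_detected": table.n_markers_detected,
            "family": fam.family if fam else ("" if not assignment.in_maveriviricetes else UNCLASSIFIED),
            "family_best_subject": fam.best_subject if fam else "",
            "family_best_score": fam.best_score if fam else 0.0,
            "completeness_category": completeness.category,
            "complete_or_near": completeness.complete_or_near,
            "phylogenetic_label": "",
            "error": "",
        }
        for marker in MARKERS + ("PLV_ATPase",):
            hit = table.plv_hit if marker == "PLV_ATPase" else table.best.get(marker)
            row[f"{marker.lower()}_score"] = hit.bit_score if hit else 0.0
        rows.append(row)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def _error_row(genome_id: str, message: str) -> dict:
    row = {
        "genome_id": genome_id,
        "length": 0,
        "n_genes": 0,
        "class_call": False,
        "candidate_flag": False,
        "possible_plv": False,
        "n_markers_detected": 0,
        "family": "",
        "family_best_subject": "",
        "family_best_score": 0.0,
        "completeness_category": "",
        "complete_or_near": False,
        "phylogenetic_label": "",
        "error": message,
    }
    for marker in MARKERS + ("PLV_ATPase",):
        row[f"{marker.lower()}_score"] = 0.0
    return row
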