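"""Sequence I/O, gene calls, and coordinate bookkeeping.

Coordinates are 1-based inclusive everywhere in this package, matching the
header dialect of common prokaryotic gene callers (``id # start # end #
strand``). Conversions to other conventions happen only at I/O boundaries.

The built-in ORF caller is a deliberate simplification: it enumerates
maximal stop-to-stop open reading frames on all six frames under a chosen
genetic code. It approximates, but does not reproduce, dedicated gene
callers such as prodigal; pipelines that need to match an external caller's
gene models should ingest its protein FASTA via
:func:`load_external_gene_calls` instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

_VALID = set("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GenomeRecord:
    """A nucleotide genome or contig.

    ``topology`` is ``"linear"`` for raw contigs and ``"dtr_trimmed"`` once a
    direct terminal repeat has been collapsed (the sequence then represents
    one unit of a presumed-circular genome).
    """

    id: str
    sequence: str
    topology: str = "linear"
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: sequence length must be >= 1")
        seq = self.sequence.upper()
        if not set(seq) <= _VALID:
            # non-ACGTN IUPAC characters are treated as N
            seq = re.sub(r"[^ACGTN]", "N", seq)
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneCall:
    """A protein-coding gene on a genome. start/end are 1-based inclusive."""

    genome_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    protein: str
    gene_index: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene call {self.genome_id}:{self.gene_index}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.protein:
            raise ValueError("protein length must be >= 1")

    @property
    def protein_id(self) -> str:
        return f"{self.genome_id}_{self.gene_index}"


@dataclass
class ProteinRecord:
    """A predicted protein; ``id`` is ``<genome_id>_<gene_index>``."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().rstrip("*")
        if "*" in seq:
            raise ValueError(f"protein {self.id!r}: internal stop codon")
        self.sequence = seq

    @property
    def genome_id(self) -> str:
        return protein_genome_id(self.id)


def protein_genome_id(protein_id: str) -> str:
    """Genome id of a ``<genome_id>_<gene_index>`` protein id.

    Ids without a trailing numeric index are returned unchanged.
    """
    stem, _, idx = protein_id.rpartition("_")
    return stem if stem and idx.isdigit() else protein_id


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read nucleotide FASTA into GenomeRecords.

    The header token before the first whitespace becomes the record id.
    Raises on an empty file and on duplicate ids.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeRecord(id=rec.id, sequence=str(rec.seq), source=str(path)))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_protein_fasta(calls: Iterable[GeneCall], path: str | Path, width: int = 70) -> None:
    """Write gene calls as protein FASTA in the ``# start # end # strand`` dialect."""
    with open(path, "w") as fh:
        for c in calls:
            strand = "1" if c.strand == "+" else "-1"
            fh.write(f">{c.protein_id} # {c.start} # {c.end} # {strand}\n")
            for i in range(0, len(c.protein), width):
                fh.write(c.protein[i : i + width] + "\n")


def translate(nt: str, table: int = 11) -> str:
    """Translate a nucleotide string; codons containing N become X."""
    return str(Seq(nt).translate(table=table))


def _forward_orfs(seq: str, genome_id: str, min_aa: int, table: int, strand: str, L: int):
    """Maximal stop-to-stop ORFs on the three frames of `seq` (already oriented)."""
    codon_table = CodonTable.unambiguous_dna_by_id[table]
    stops = set(codon_table.stop_codons)
    out = []
    for frame in range(3):
        n_codons = (len(seq) - frame) // 3
        if n_codons == 0:
            continue
        seg_start = 0  # codon index where current ORF segment starts
        for ci in range(n_codons + 1):
            codon = seq[frame + 3 * ci : frame + 3 * ci + 3] if ci < n_codons else None
            if codon is None or codon in stops:
                # segment [seg_start, ci) ends; contig ends count as stops
                n_seg = ci - seg_start
                if n_seg >= min_aa:
                    nt_start = frame + 3 * seg_start  # 0-based
                    nt_end = frame + 3 * ci  # exclusive
                    sub = seq[nt_start:nt_end]
                    prot = str(Seq(sub).translate(table=table))
                    if strand == "+":
                        start, end = nt_start + 1, nt_end
                    else:
                        # map back from the reverse-complemented coordinates
                        start, end = L - nt_end + 1, L - nt_start
                    out.append((start, end, strand, prot))
                seg_start = ci + 1
    return out


def call_orfs(genome: GenomeRecord, min_aa: int = 50, genetic_code: int = 11) -> list[GeneCall]:
    """All maximal stop-to-stop ORFs of >= min_aa codons on all six frames.

    Contig ends are treated as stops, so terminal partial ORFs are reported.
    Ns translate to X and do not interrupt an ORF. Output is sorted by start
    position and deterministic.
    """
    L = len(genome.sequence)
    raw = _forward_orfs(genome.sequence, genome.id, min_aa, genetic_code, "+", L)
    raw += _forward_orfs(revcomp(genome.sequence), genome.id, min_aa, genetic_code, "-", L)
    raw.sort(key=lambda t: (t[0], t[1], t[2]))
    return [
        GeneCall(genome.id, start, end, strand, prot, i + 1)
        for i, (start, end, strand, prot) in enumerate(raw)
    ]


_HEADER_RE = re.compile(
    r"^(?P<id>\S+)\s*#\s*(?P<start>\d+)\s*#\s*(?P<end>\d+)\s*#\s*(?P<strand>-?1)(\s*#.*)?$"
)


def load_external_gene_calls(protein_fasta_path: str | Path) -> list[GeneCall]:
    """Load gene calls from a protein FASTA with coordinate-bearing headers.

    Expects the gene-caller dialect ``>id # start # end # strand [# attrs]``
    with 1-based inclusive coordinates and strand 1/-1.
    """
    calls: list[GeneCall] = []
    per_genome_counter: dict[str, int] = {}
    for rec in SeqIO.parse(str(protein_fasta_path), "fasta"):
        m = _HEADER_RE.match(rec.description)
        if not m:
            raise ValueError(
                f"unparseable gene-call header in {protein_fasta_path}: {rec.description!r}"
            )
        pid = m.group("id")
        genome_id = protein_genome_id(pid)
        stem, _, idx = pid.rpartition("_")
        if stem and idx.isdigit():
            gene_index = int(idx)
        else:
            gene_index = per_genome_counter.get(genome_id, 0) + 1
        per_genome_counter[genome_id] = gene_index
        calls.append(
            GeneCall(
                genome_id=genome_id,
                start=int(m.group("start")),
                end=int(m.group("end")),
                strand="+" if m.group("strand") == "1" else "-",
                protein=str(rec.seq).rstrip("*"),
                gene_index=gene_index,
            )
        )
    return calls


def proteins_of(calls: Iterable[GeneCall]) -> list[ProteinRecord]:
    return [ProteinRecord(id=c.protein_id, sequence=c.protein) for c in calls]


def gene_calls_to_tsv(calls: Iterable[GeneCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tgene_index\tstart\tend\tstrand\tlength_aa\n")
        for c in calls:
            fh.write(
                f"{c.genome_id}\t{c.gene_index}\t{c.start}\t{c.end}\t{c.strand}\t{len(c.protein)}\n"
            )
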