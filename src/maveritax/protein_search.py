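"""Thin wrapper around NCBI BLAST+ (blastp/makeblastdb) for protein searches.

All protein-vs-protein comparisons in the package (family cutoff derivation,
best-hit family assignment, genome-wide AAI, and the all-vs-all graph behind
profile construction) run through :func:`blastp`, so bit scores are
comparable across steps. Results come back as a pandas DataFrame with one
row per HSP.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Mapping

import pandas as pd

_OUTFMT_COLS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "evalue",
    "bitscore",
    "qstart",
    "qend",
    "sstart",
    "send",
    "qlen",
    "slen",
]


class BlastNotFoundError(RuntimeError):
    pass


def _require(tool: str) -> str:
    path = shutil.which(tool)
    if path is None:
        raise BlastNotFoundError(f"required executable {tool!r} not found on PATH")
    return path


def _write_fasta(seqs: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n{seq}\n")


def blastp(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    evalue: float = 1e-3,
    max_target_seqs: int = 10000,
    threads: int = 1,
) -> pd.DataFrame:
    """Run blastp of `queries` against a database built from `subjects`.

    Returns the tabular (outfmt 6) hits with query/subject lengths. Rows are
    sorted by (qseqid, descending bitscore, sseqid) for determinism.
    """
    if not queries or not subjects:
        return pd.DataFrame(columns=_OUTFMT_COLS)
    makeblastdb = _require("makeblastdb")
    blastp_bin = _require("blastp")
    with tempfile.TemporaryDirectory(prefix="maveritax_blast_") as tmp:
        tmpdir = Path(tmp)
        qpath, dbpath = tmpdir / "query.faa", tmpdir / "db.faa"
        _write_fasta(queries, qpath)
        _write_fasta(subjects, dbpath)
        subprocess.run(
            [makeblastdb, "-in", str(dbpath), "-dbtype", "prot"],
            check=True,
            capture_output=True,
        )
        out = tmpdir / "hits.tsv"
        subprocess.run(
            [
                blastp_bin,
                "-query", str(qpath),
                "-db", str(dbpath),
                "-out", str(out),
                "-outfmt", "6 " + " ".join(_OUTFMT_COLS),
                "-evalue", str(evalue),
                "-max_target_seqs", str(max_target_seqs),
                "-num_threads", str(threads),
            ],
            check=True,
            capture_output=True,
        )
        hits = pd.read_csv(out, sep="\t", names=_OUTFMT_COLS)
    hits = hits.sort_values(
        ["qseqid", "bitscore", "pident", "sseqid"],
        ascending=[True, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return hits


def blastp_all_vs_all(
    seqs: Mapping[str, str], evalue: float = 1e-3, max_target_seqs: int = 10000
) -> pd.DataFrame:
    return blastp(seqs, seqs, evalue=evalue, max_target_seqs=max_target_seqs)


def best_hsp_per_pair(hits: pd.DataFrame) -> pd.DataFrame:
    """Keep the highest-scoring HSP for every (query, subject) pair."""
    if hits.empty:
        return hits
    return hits.drop_duplicates(subset=["qseqid", "sseqid"], keep="first").reset_index(
        drop=True
    )
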