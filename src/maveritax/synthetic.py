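"""Synthetic genomes with known truth for every stage of the pipeline.

The generator emulates the structure of a family-resolved virophage
dataset: for each simulated family an ancestral protein is drawn per marker
(MCP, Penton, ATPase, PRO), descendants are mutated to a target identity,
back-translated with GC-biased codon choice, and embedded in genomes with
random intergenic spacers and decoy genes. Optional features plant the QC
signals the pipeline looks for: direct terminal repeats, host flanks with a
distinct GC content and gene-free (>= 1 kb intergenic) junctions, and
near-identical genome copies forming known vOTUs. A polinton-like-virus
(PLV) pseudo-family carries only the PLV-type packaging ATPase, and fully
random decoy genomes carry no marker at all.

Synthetic markers are random proteins — intentionally NOT homologous to any
published profile — so tests build their profiles from the synthetic
references themselves and stay hermetic. The generator is deterministic:
the same spec yields byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .genome_io import GenomeRecord, revcomp
from .taxonomy import FAMILIES

AA = "ACDEFGHIKLMNPQRSTVWY"

MARKER_LENGTHS = {"MCP": 600, "Penton": 350, "ATPase": 300, "PRO": 200}
PLV_ATPASE_LENGTH = 320

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_SYN: dict[str, list[str]] = {}
for codon, aa in _TABLE11.forward_table.items():
    _SYN.setdefault(aa, []).append(codon)
for aa in _SYN:
    _SYN[aa].sort()
_STOPS = sorted(_TABLE11.stop_codons)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Defaults describe the standard test conditions: seven families of ten
    genomes, markers at 70% identity to their family ancestor, genome
    lengths 15-45 kb, one near-identical duplicate per family (planted
    vOTUs), two PLV-like and two random decoy genomes.
    """

    seed: int = 42
    n_families: int = 7
    genomes_per_family: int = 10
    marker_identity_target: float = 0.70
    genome_length_range: tuple[int, int] = (15000, 45000)
    gc_element: float = 0.40
    gc_host: float = 0.60
    dtr_length: int | None = None
    host_flank_length: int | None = None
    n_decoys: int = 2
    n_plv_genomes: int = 2
    n_decoy_genes: int = 8
    dupes_per_family: int = 1
    dupe_divergence: float = 0.01
    max_cross_family_identity: float = 0.35

    def __post_init__(self) -> None:
        for frac in (self.marker_identity_target, self.gc_element, self.gc_host):
            if not 0 < frac < 1:
                raise ValueError("fractions must be in (0, 1)")

    def family_names(self) -> list[str]:
        if self.n_families <= len(FAMILIES):
            return list(FAMILIES[: self.n_families])
        return list(FAMILIES) + [
            f"Synthviroviridae{i}" for i in range(1, self.n_families - len(FAMILIES) + 1)
        ]


def aa_identity(a: str, b: str) -> float:
    """Global identity between two proteins (matches / alignment columns)."""
    res = edlib.align(a, b, mode="NW", task="distance")
    cols = max(len(a), len(b))
    return 1.0 - res["editDistance"] / cols


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def mutate_protein(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Substitute positions independently so the result has ~`identity`
    expected identity to `seq` (substitutions only, no indels)."""
    chars = np.array(list(seq))
    mask = rng.random(len(chars)) < (1.0 - identity)
    for i in np.nonzero(mask)[0]:
        choices = [c for c in AA if c != chars[i]]
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def mutate_nucleotide(rng: np.random.Generator, seq: str, divergence: float) -> str:
    chars = np.array(list(seq))
    mask = rng.random(len(chars)) < divergence
    for i in np.nonzero(mask)[0]:
        choices = [c for c in "ACGT" if c != chars[i]]
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ATGC"), size=length, p=[probs[0], probs[3], probs[1], probs[2]]))


def back_translate(rng: np.random.Generator, protein: str, gc: float) -> str:
    """Encode a protein with synonymous codons weighted toward GC `gc`."""
    weights: dict[str, np.ndarray] = {}
    for aa, codons in _SYN.items():
        w = np.array(
            [
                np.prod([gc / 2 if b in "GC" else (1 - gc) / 2 for b in codon])
                for codon in codons
            ]
        )
        weights[aa] = w / w.sum()
    out = []
    for aa in protein:
        codons = _SYN.get(aa, _SYN["A"])  # X or unknown falls back to Ala codons
        out.append(codons[rng.choice(len(codons), p=weights.get(aa, weights["A"]))])
    return "".join(out)


def _suppress_orfs(seq: str, rng: np.random.Generator, max_run: int = 40) -> str:
    """Break every stop-free run of > `max_run` codons on all six frames by
    planting a stop codon, yielding host-like 'non-coding' sequence."""
    seq = list(seq)
    for _ in range(6):  # a few passes are enough in practice
        changed = False
        for strand in ("+", "-"):
            s = "".join(seq) if strand == "+" else revcomp("".join(seq))
            L = len(s)
            for frame in range(3):
                run = 0
                ci = frame
                while ci + 3 <= L:
                    codon = s[ci : ci + 3]
                    if codon in _STOPS:
                        run = 0
                    else:
                        run += 1
                        if run > max_run:
                            stop = _STOPS[rng.integers(len(_STOPS))]
                            if strand == "+":
                                seq[ci : ci + 3] = list(stop)
                            else:
                                a = L - (ci + 3)
                                seq[a : a + 3] = list(revcomp(stop))
                            run = 0
                            changed = True
                    ci += 3
        if not changed:
            break
    return "".join(seq)


@dataclass
class MarkerFamilies:
    """Ancestral and descendant marker proteins per family."""

    ancestors: dict[str, dict[str, str]]  # family -> marker -> protein
    members: dict[str, dict[str, list[str]]]  # family -> marker -> descendants
    plv_ancestor: str = ""
    plv_members: list[str] = field(default_factory=list)


def generate_marker_families(spec: FixtureSpec, rng: np.random.Generator | None = None) -> MarkerFamilies:
    """Draw per-family ancestral markers and mutate descendants to the
    identity target; cross-family ancestor identity is forced below the
    configured ceiling by rejection sampling."""
    if spec.n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    families = spec.family_names()
    ancestors: dict[str, dict[str, str]] = {}
    for fam in families:
        for _attempt in range(50):
            cand = {m: random_protein(rng, n) for m, n in MARKER_LENGTHS.items()}
            if spec.n_families == 1 or all(
                aa_identity(cand[m], ancestors[other][m]) <= spec.max_cross_family_identity
                for other in ancestors
                for m in MARKER_LENGTHS
            ):
                ancestors[fam] = cand
                break
        else:
            raise ValueError("cannot satisfy cross-family identity ceiling")
    members = {
        fam: {
            m: [
                mutate_protein(rng, ancestors[fam][m], spec.marker_identity_target)
                for _ in range(spec.genomes_per_family)
            ]
            for m in MARKER_LENGTHS
        }
        for fam in families
    }
    plv_ancestor = random_protein(rng, PLV_ATPASE_LENGTH)
    n_plv_refs = max(10, spec.n_plv_genomes)
    plv_members = [
        mutate_protein(rng, plv_ancestor, spec.marker_identity_target)
        for _ in range(n_plv_refs)
    ]
    return MarkerFamilies(
        ancestors=ancestors,
        members=members,
        plv_ancestor=plv_ancestor,
        plv_members=plv_members,
    )


def generate_genome(
    family_markers: dict[str, str],
    spec: FixtureSpec,
    rng: np.random.Generator,
    genome_id: str,
    family: str = "",
) -> tuple[GenomeRecord, dict, pd.DataFrame]:
    """Assemble one genome around the given marker proteins.

    Genes (markers plus decoys) are back-translated at the element GC, each
    wrapped in in-frame stop codons, and separated by random spacers whose
    composition is adjusted so the whole element lands on the GC target.
    Optionally a direct terminal repeat is appended and/or host flanks of
    distinct GC with gene-free (>= 1 kb) junction regions are added.

    Returns the record, a truth dict for the genome, and a truth frame of
    marker coordinates (1-based inclusive, protein-coding span only).
    """
    target_len = int(rng.integers(spec.genome_length_range[0], spec.genome_length_range[1] + 1))
    genes: list[tuple[str, str]] = [(m, family_markers[m]) for m in sorted(family_markers)]
    for d in range(spec.n_decoy_genes):
        genes.append((f"decoy{d+1}", random_protein(rng, int(rng.integers(80, 250)))))

    cds = {name: back_translate(rng, prot, spec.gc_element) for name, prot in genes}
    stop = lambda: _STOPS[rng.integers(len(_STOPS))]
    wrapped = {name: stop() + seq + stop() for name, seq in cds.items()}
    content_len = sum(len(s) for s in wrapped.values())

    n_slots = len(genes) + 1
    min_spacer = 250
    budget = target_len - content_len
    if spec.dtr_length:
        budget -= spec.dtr_length
    if budget < n_slots * min_spacer:
        raise ValueError(
            f"genome length {target_len} infeasible for {len(genes)} genes"
        )
    extra = budget - n_slots * min_spacer
    props = rng.dirichlet(np.ones(n_slots))
    spacer_lens = [min_spacer + int(extra * p) for p in props]
    spacer_lens[0] += budget - sum(spacer_lens)  # absorb rounding

    # balance spacers so overall element GC hits the target
    coding_gc = sum(s.count("G") + s.count("C") for s in wrapped.values())
    spacer_total = sum(spacer_lens)
    want_gc = spec.gc_element * (content_len + spacer_total)
    spacer_gc = float(np.clip((want_gc - coding_gc) / spacer_total, 0.1, 0.9))

    parts: list[str] = []
    marker_rows = []
    pos = 0
    order = list(range(len(genes)))
    for slot, gi in enumerate(order):
        spacer = random_dna(rng, spacer_lens[slot], spacer_gc)
        parts.append(spacer)
        pos += len(spacer)
        name, prot = genes[gi]
        parts.append(wrapped[name])
        gene_start = pos + 4  # skip the leading stop codon (3 nt)
        gene_end = pos + len(wrapped[name]) - 3
        if name in MARKER_LENGTHS or name == "PLV_ATPase":
            marker_rows.append(
                {
                    "genome_id": genome_id,
                    "marker": name,
                    "start": gene_start,
                    "end": gene_end,
                    "strand": "+",
                    "length_aa": len(prot),
                }
            )
        pos += len(wrapped[name])
    parts.append(random_dna(rng, spacer_lens[-1], spacer_gc))
    core = "".join(parts)

    truth = {
        "genome_id": genome_id,
        "family": family,
        "dtr_length": 0,
        "host_flank_up": 0,
        "host_flank_down": 0,
        "element_start": 1,
        "element_end": len(core),
    }

    if spec.host_flank_length:
        fl = spec.host_flank_length
        up = _suppress_orfs(random_dna(rng, fl, spec.gc_host), rng)
        down = _suppress_orfs(random_dna(rng, fl, spec.gc_host), rng)
        # gene-free junction margins inside the element as well
        head = _suppress_orfs(core[: spacer_lens[0]], rng)
        tail = _suppress_orfs(core[len(core) - spacer_lens[-1] :], rng)
        core_mid = core[spacer_lens[0] : len(core) - spacer_lens[-1]]
        core = head + core_mid + tail
        offset = fl
        for row in marker_rows:
            row["start"] += offset
            row["end"] += offset
        truth.update(
            host_flank_up=fl,
            host_flank_down=fl,
            element_start=fl + 1,
            element_end=fl + len(core),
        )
        core = up + core + down

    if spec.dtr_length:
        dtr = spec.dtr_length
        core = core + core[:dtr]
        truth["dtr_length"] = dtr

    truth["length"] = len(core)
    record = GenomeRecord(id=genome_id, sequence=core, source="synthetic")
    return record, truth, pd.DataFrame(marker_rows)


@dataclass
class FixtureSet:
    spec: FixtureSpec
    genomes: list[GenomeRecord]
    truth_genomes: pd.DataFrame
    truth_markers: pd.DataFrame
    marker_proteins: dict[str, dict[str, str]]  # marker -> protein_id -> seq
    reference_mcp: dict[str, str]  # protein_id -> seq (reference half)
    reference_labels: dict[str, str]  # protein_id -> family
    query_ids: list[str]

    def genome(self, gid: str) -> GenomeRecord:
        return next(g for g in self.genomes if g.id == gid)


def generate_fixture_set(spec: FixtureSpec) -> FixtureSet:
    """Generate the full dataset: family genomes, planted vOTU duplicates,
    PLV-like genomes, random decoys, marker reference sets, and the
    reference/query split of the family MCPs."""
    rng = np.random.default_rng(spec.seed)
    fams = generate_marker_families(spec, rng)
    families = spec.family_names()

    genomes: list[GenomeRecord] = []
    g_rows: list[dict] = []
    m_frames: list[pd.DataFrame] = []
    marker_proteins: dict[str, dict[str, str]] = {m: {} for m in MARKER_LENGTHS}
    marker_proteins["PLV_ATPase"] = {}
    reference_mcp: dict[str, str] = {}
    reference_labels: dict[str, str] = {}
    query_ids: list[str] = []

    for fi, fam in enumerate(families):
        n_ref = spec.genomes_per_family // 2
        for gi in range(spec.genomes_per_family):
            gid = f"F{fi+1:02d}G{gi+1:02d}"
            this_markers = {m: fams.members[fam][m][gi] for m in MARKER_LENGTHS}
            rec, truth, markers = generate_genome(this_markers, spec, rng, gid, family=fam)
            truth["votu_id"] = gid
            truth["aai_group"] = fam
            truth["kind"] = "virophage"
            genomes.append(rec)
            g_rows.append(truth)
            m_frames.append(markers)
            for m in MARKER_LENGTHS:
                marker_proteins[m][f"{gid}.{m}"] = this_markers[m]
            if gi < n_ref:
                reference_mcp[f"{gid}.MCP"] = this_markers["MCP"]
                reference_labels[f"{gid}.MCP"] = fam
            else:
                query_ids.append(gid)
            if gi == 0:
                for di in range(spec.dupes_per_family):
                    dup_id = f"{gid}d{di+1}"
                    dup_seq = mutate_nucleotide(rng, rec.sequence, spec.dupe_divergence)
                    genomes.append(
                        GenomeRecord(id=dup_id, sequence=dup_seq, source="synthetic")
                    )
                    g_rows.append(
                        {
                            "genome_id": dup_id,
                            "family": fam,
                            "length": len(dup_seq),
                            "dtr_length": 0,
                            "host_flank_up": 0,
                            "host_flank_down": 0,
                            "element_start": 1,
                            "element_end": len(dup_seq),
                            "votu_id": gid,
                            "aai_group": fam,
                            "kind": "duplicate",
                        }
                    )

    for pi in range(spec.n_plv_genomes):
        gid = f"PLV{pi+1:02d}"
        rec, truth, markers = generate_genome(
            {"PLV_ATPase": fams.plv_members[pi]}, spec, rng, gid, family="PLV"
        )
        truth.update(votu_id=gid, aai_group="PLV", kind="plv")
        genomes.append(rec)
        g_rows.append(truth)
        m_frames.append(markers)
    for i, seq in enumerate(fams.plv_members):
        marker_proteins["PLV_ATPase"][f"PLVref{i+1:02d}.PLV_ATPase"] = seq

    for di in range(spec.n_decoys):
        gid = f"RAND{di+1:02d}"
        length = int(rng.integers(*spec.genome_length_range))
        seq = random_dna(rng, length, spec.gc_element)
        genomes.append(GenomeRecord(id=gid, sequence=seq, source="synthetic"))
        g_rows.append(
            {
                "genome_id": gid,
                "family": "",
                "length": length,
                "dtr_length": 0,
                "host_flank_up": 0,
                "host_flank_down": 0,
                "element_start": 1,
                "element_end": length,
                "votu_id": gid,
                "aai_group": "",
                "kind": "random",
            }
        )

    truth_genomes = pd.DataFrame(g_rows)
    truth_markers = (
        pd.concat(m_frames, ignore_index=True) if m_frames else pd.DataFrame()
    )
    return FixtureSet(
        spec=spec,
        genomes=genomes,
        truth_genomes=truth_genomes,
        truth_markers=truth_markers,
        marker_proteins=marker_proteins,
        reference_mcp=reference_mcp,
        reference_labels=reference_labels,
        query_ids=query_ids,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def emit_fixture_set(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Write a fixture set to disk and return the manifest (also written as
    manifest.json): genome FASTA, truth tables, per-marker reference protein
    FASTAs, the labeled reference MCP db, the query list, and checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fs = generate_fixture_set(spec)

    from .genome_io import write_fasta

    write_fasta(fs.genomes, outdir / "genomes.fna")
    fs.truth_genomes.to_csv(outdir / "truth_genomes.tsv", sep="\t", index=False)
    fs.truth_markers.to_csv(outdir / "truth_markers.tsv", sep="\t", index=False)
    for marker, seqs in fs.marker_proteins.items():
        with open(outdir / f"markers_{marker}.faa", "w") as fh:
            for pid in sorted(seqs):
                fh.write(f">{pid}\n{seqs[pid]}\n")
    with open(outdir / "reference_mcp.faa", "w") as fh:
        for pid in sorted(fs.reference_mcp):
            fh.write(f">{pid}\n{fs.reference_mcp[pid]}\n")
    with open(outdir / "reference_labels.tsv", "w") as fh:
        fh.write("id\tfamily\n")
        for pid in sorted(fs.reference_labels):
            fh.write(f"{pid}\t{fs.reference_labels[pid]}\n")
    (outdir / "queries.txt").write_text("\n".join(fs.query_ids) + "\n")

    files = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(spec).items()},
        "checksums": {name: _sha256(outdir / name) for name in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
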