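"""Genome dereplication (vOTUs) and genome-wide AAI grouping.

Two complementary clusterings operate here:

* vOTUs — viral operational taxonomic units: genomes sharing >= 95% average
  nucleotide identity (ANI) over >= 85% of the shorter genome (aligned
  fraction, AF), the standard dereplication cutoff for dsDNA viruses.
  Clustering is greedy longest-first against representatives.
* gwAAI groups — genome-wide average amino-acid identity between the shared
  proteins of two genomes, edges kept when the normalized cumulative bit
  score is >= 0.05, partitioned with Markov clustering (MCL) at a shallow
  inflation of 1.1. These groups underpin family-level taxa.

The MCL implementation is in-house (dense, numpy): expansion by matrix
squaring, inflation by elementwise power with column renormalization,
pruning of tiny entries, attractor-based cluster extraction. The built-in
ANI backend is a k-mer seeded block aligner (exact 13-mer anchors grouped
into diagonal bands, each band aligned globally with edlib); a parser for
external whole-genome-aligner coordinate files can stand in where
bit-compatibility with published pipelines matters.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .genome_io import GenomeRecord, ProteinRecord, revcomp
from .protein_search import best_hsp_per_pair, blastp_all_vs_all


@dataclass
class ANIResult:
    query_id: str
    subject_id: str
    ani: float  # percent identity over aligned blocks
    af_shorter: float  # aligned fraction of the shorter genome, 0-1


@dataclass
class VOTUSet:
    clusters: list[tuple[str, list[str]]]  # (representative, members)

    def membership(self) -> dict[str, str]:
        return {m: rep for rep, members in self.clusters for m in members}

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"votu_id": f"vOTU_{i+1:04d}", "representative": rep, "member": m}
            for i, (rep, members) in enumerate(self.clusters)
            for m in members
        ]
        return pd.DataFrame(rows, columns=["votu_id", "representative", "member"])


@dataclass
class AAIEdge:
    genome_a: str
    genome_b: str
    aai: float  # mean percent aa identity over reciprocal best-hit pairs
    n_shared: int
    norm_cum_bitscore: float


@dataclass
class AAIGroupSet:
    groups: list[list[str]]
    inflation: float

    def membership(self) -> dict[str, int]:
        return {m: i for i, grp in enumerate(self.groups) for m in grp}


# ---------------------------------------------------------------------------
# Markov clustering


def markov_cluster(
    edges: Iterable[tuple[Hashable, Hashable, float]],
    inflation: float = 1.1,
    expansion: int = 2,
    max_iter: int = 200,
    prune: float = 1e-6,
    nodes: Sequence[Hashable] | None = None,
) -> list[list[Hashable]]:
    """Markov clustering of a weighted undirected graph.

    Self-loops are added at each node's maximum incident weight before
    normalization. The column-stochastic flow matrix is alternately expanded
    (matrix power `expansion`) and inflated (elementwise power `inflation`,
    then renormalized), with entries below `prune` zeroed, until the matrix
    changes by < 1e-8 or `max_iter` rounds. Clusters are read from attractor
    rows (positive diagonal); a node attracted by several attractors goes to
    the one with the largest flow, ties to the lexicographically smallest.
    """
    node_set = set(nodes or [])
    edge_list = []
    for a, b, w in edges:
        node_set.update((a, b))
        if a != b and w > 0:
            edge_list.append((a, b, float(w)))
    if not node_set:
        return []
    order = sorted(node_set, key=str)
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)
    W = np.zeros((n, n))
    for a, b, w in edge_list:
        i, j = idx[a], idx[b]
        W[i, j] = max(W[i, j], w)
        W[j, i] = max(W[j, i], w)
    # self-loops at max incident weight (1.0 for isolated nodes)
    diag = W.max(axis=1)
    diag[diag == 0] = 1.0
    np.fill_diagonal(W, diag)

    def _colnorm(A: np.ndarray) -> np.ndarray:
        colsum = A.sum(axis=0, keepdims=True)
        dead = colsum[0] == 0
        if dead.any():  # resurrect emptied columns as self-flows
            A[np.where(dead)[0], dead] = 1.0
            colsum = A.sum(axis=0, keepdims=True)
        return A / colsum

    M = _colnorm(W.copy())
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        # inflation, then pruning relative to the renormalized column (pruning
        # raw inflated values would wipe out near-uniform columns wholesale)
        M = _colnorm(np.power(M, inflation))
        M[M < prune] = 0.0
        M = _colnorm(M)
        if np.abs(M - prev).max() < 1e-8:
            break

    attractors = [i for i in range(n) if M[i, i] > prune]
    if not attractors:
        attractors = list(range(n))
    assign: dict[int, int] = {}
    arr = M[attractors, :]
    for j in range(n):
        col = arr[:, j]
        best = col.max()
        if best <= 0:
            assign[j] = j
            continue
        tied = [attractors[k] for k in range(len(attractors)) if col[k] >= best - 1e-12]
        assign[j] = min(tied, key=lambda i: str(order[i]))
    clusters: dict[int, list[Hashable]] = defaultdict(list)
    for j in range(n):
        clusters[assign[j]].append(order[j])
    return [sorted(clusters[a], key=str) for a in sorted(clusters, key=lambda i: str(order[i]))]


def mcl_cluster(
    edges: Iterable[AAIEdge] | Iterable[tuple[str, str, float]],
    inflation: float = 1.1,
    expansion: int = 2,
    max_iter: int = 200,
    prune: float = 1e-6,
    nodes: Sequence[str] | None = None,
) -> AAIGroupSet:
    """Partition genomes by MCL on an AAI (or generic weighted) edge list."""
    triples = []
    for e in edges:
        if isinstance(e, AAIEdge):
            triples.append((e.genome_a, e.genome_b, e.aai))
        else:
            triples.append(e)
    groups = markov_cluster(
        triples,
        inflation=inflation,
        expansion=expansion,
        max_iter=max_iter,
        prune=prune,
        nodes=nodes,
    )
    return AAIGroupSet(groups=[list(map(str, g)) for g in groups], inflation=inflation)


# ---------------------------------------------------------------------------
# ANI


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(alignment columns, edit ops) from an edlib cigar (M/I/D ops)."""
    cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            cols += int(num)
            num = ""
    return cols, 0  # edit ops come from editDistance, not the cigar


def _aligned_blocks(
    query: str, target: str, index: dict[str, list[int]], k: int, band_merge: int, max_occ: int
) -> list[tuple[int, int, int, int, int, int]]:
    """Anchor-seeded alignment blocks between query and an indexed target.

    Returns (q_start, q_end, t_start, t_end, matches, columns) per block,
    half-open 0-based coordinates.
    """
    anchors: list[tuple[int, int]] = []  # (diag, qpos)
    for i in range(len(query) - k + 1):
        hits = index.get(query[i : i + k])
        if hits and len(hits) <= max_occ:
            for j in hits:
                anchors.append((i - j, i))
    if not anchors:
        return []
    # diagonal bands: consecutive diagonals within band_merge of each other
    anchors.sort()
    bands: list[list[tuple[int, int]]] = []
    group: list[tuple[int, int]] = [anchors[0]]
    for d, i in anchors[1:]:
        if d - group[-1][0] <= band_merge:
            group.append((d, i))
        else:
            bands.append(group)
            group = [(d, i)]
    bands.append(group)

    max_gap = 500  # split runs on query-position gaps (spurious anchors are sparse)
    min_anchors = 3
    min_block = 100  # nt; shorter runs carry no reliable identity signal
    out = []
    for band in bands:
        # chained spurious anchors can stretch a band across many diagonals;
        # keep only anchors near the band's dominant (median) diagonal
        diags = sorted(d for d, _ in band)
        med = diags[len(diags) // 2]
        kept = sorted(
            ((d, i) for d, i in band if abs(d - med) <= band_merge),
            key=lambda t: t[1],
        )
        runs: list[list[tuple[int, int]]] = []
        cur = [kept[0]]
        for d, i in kept[1:]:
            if i - cur[-1][1] <= max_gap:
                cur.append((d, i))
            else:
                runs.append(cur)
                cur = [(d, i)]
        runs.append(cur)
        for run in runs:
            qs = min(i for _, i in run)
            qe = max(i for _, i in run) + k
            if len(run) < min_anchors or qe - qs < min_block:
                continue
            ts = max(min(i - d for d, i in run), 0)
            te = min(max(i - d for d, i in run) + k, len(target))
            qsub, tsub = query[qs:qe], target[ts:te]
            if not qsub or not tsub:
                continue
            res = edlib.align(qsub, tsub, mode="NW", task="path")
            cols, _ = _cigar_stats(res["cigar"])
            matches = cols - res["editDistance"]
            if matches <= 0:
                continue
            out.append((qs, qe, ts, te, matches, cols))
    return out


def _merge_intervals(ivs: list[tuple[int, int]]) -> int:
    if not ivs:
        return 0
    ivs = sorted(ivs)
    total = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    return total + (cur_e - cur_s)


def pairwise_ani(
    a: GenomeRecord | str,
    b: GenomeRecord | str,
    k: int = 13,
    band_merge: int = 100,
    max_kmer_occ: int = 10,
) -> ANIResult:
    """ANI and aligned fraction between two genomes (built-in backend).

    Exact `k`-mer anchors between the query and each strand of the target
    are grouped into diagonal bands; each band's spans are globally aligned
    with edlib. ANI is the column-weighted mean identity over all blocks of
    the better-scoring strand orientation; AF is the merged aligned length
    on the shorter genome divided by its length.
    """
    aid = a.id if isinstance(a, GenomeRecord) else "query"
    bid = b.id if isinstance(b, GenomeRecord) else "subject"
    aseq = a.sequence if isinstance(a, GenomeRecord) else a.upper()
    bseq = b.sequence if isinstance(b, GenomeRecord) else b.upper()
    if not aseq or not bseq:
        raise ValueError("empty sequence")
    if len(aseq) < 100 or len(bseq) < 100:
        raise ValueError("sequences must be >= 100 nt")

    return _ani_indexed(aid, bid, aseq, _kmer_index(aseq, k), bseq, k, band_merge, max_kmer_occ)


def _ani_indexed(
    aid: str,
    bid: str,
    aseq: str,
    index: dict[str, list[int]],
    bseq: str,
    k: int,
    band_merge: int,
    max_kmer_occ: int,
) -> ANIResult:
    short_len = min(len(aseq), len(bseq))
    best = (0.0, 0.0)  # (ani, af)
    for orient in ("+", "-"):
        query = bseq if orient == "+" else revcomp(bseq)
        blocks = _aligned_blocks(query, aseq, index, k, band_merge, max_kmer_occ)
        if not blocks:
            continue
        matches = sum(m for *_, m, _ in blocks)
        cols = sum(c for *_, c in blocks)
        ani = 100.0 * matches / cols
        if len(bseq) <= len(aseq):
            ivs = [(qs, qe) for qs, qe, *_ in blocks]
        else:
            ivs = [(ts, te) for _, _, ts, te, _, _ in blocks]
        af = min(_merge_intervals(ivs) / short_len, 1.0)
        if af > best[1] or (af == best[1] and ani > best[0]):
            best = (ani, af)
    return ANIResult(query_id=aid, subject_id=bid, ani=best[0], af_shorter=best[1])


def load_external_ani(coords_tsv: str) -> list[ANIResult]:
    """Ingest precomputed pairwise ANI from a 4-column TSV
    (query_id, subject_id, ani, af_shorter), e.g. derived from an external
    whole-genome aligner's coordinate output."""
    df = pd.read_csv(coords_tsv, sep="\t")
    need = {"query_id", "subject_id", "ani", "af_shorter"}
    if not need <= set(df.columns):
        raise ValueError(f"ANI table must have columns {sorted(need)}")
    return [
        ANIResult(r.query_id, r.subject_id, float(r.ani), float(r.af_shorter))
        for r in df.itertuples()
    ]


def cluster_votus(
    genomes: Sequence[GenomeRecord],
    min_ani: float = 95.0,
    min_af: float = 0.85,
    overrides: set[str] | None = None,
    precomputed: Mapping[tuple[str, str], ANIResult] | None = None,
) -> VOTUSet:
    """Greedy dereplication of genomes into vOTUs.

    Genomes are processed longest first (ties broken by id); each joins the
    first existing representative it matches at >= `min_ani` ANI and
    >= `min_af` aligned fraction, otherwise it founds a new vOTU. The longest
    member is the representative, unless a cluster contains an id from
    `overrides` (isolate/reference genomes manually chosen as
    representatives), which is then promoted.
    """
    k, band_merge, max_occ = 13, 100, 10
    order = sorted(genomes, key=lambda g: (-len(g.sequence), g.id))
    reps: list[GenomeRecord] = []
    rep_index: dict[str, dict[str, list[int]]] = {}
    members: dict[str, list[str]] = {}
    for g in order:
        placed = False
        for rep in reps:
            if precomputed is not None:
                res = precomputed.get((g.id, rep.id)) or precomputed.get((rep.id, g.id))
                if res is None:
                    continue
            else:
                res = _ani_indexed(
                    rep.id, g.id, rep.sequence, rep_index[rep.id], g.sequence,
                    k, band_merge, max_occ,
                )
            if res.ani >= min_ani and res.af_shorter >= min_af:
                members[rep.id].append(g.id)
                placed = True
                break
        if not placed:
            reps.append(g)
            if precomputed is None:
                rep_index[g.id] = _kmer_index(g.sequence, k)
            members[g.id] = [g.id]
    clusters = []
    for rep in reps:
        mem = members[rep.id]
        rep_id = rep.id
        if overrides:
            hit = sorted(set(mem) & overrides)
            if hit:
                rep_id = hit[0]
        clusters.append((rep_id, mem))
    return VOTUSet(clusters=clusters)


# ---------------------------------------------------------------------------
# genome-wide AAI


def compute_aai_edges(
    proteins_by_genome: Mapping[str, Sequence[ProteinRecord]],
    min_cov: float = 0.50,
    max_evalue: float = 1e-5,
    min_norm_score: float = 0.05,
    keep_all: bool = False,
) -> list[AAIEdge]:
    """Genome-wide AAI for every genome pair from one all-vs-all search.

    Protein hits qualify with E <= `max_evalue` and >= `min_cov` alignment
    coverage of BOTH query and subject. For each genome pair, reciprocal
    best-hit protein pairs are collected; AAI is the mean percent identity
    over those pairs (both directions averaged) and the cumulative bit score
    is normalized by the smaller of the two genomes' summed protein
    self-scores, a bounded symmetric quantity. Edges below `min_norm_score`
    are dropped unless `keep_all`.
    """
    seqs: dict[str, str] = {}
    genome_of: dict[str, str] = {}
    for gid, prots in proteins_by_genome.items():
        for p in prots:
            key = f"{gid}@{p.id}"
            seqs[key] = p.sequence
            genome_of[key] = gid
    if not seqs:
        return []
    hits = best_hsp_per_pair(blastp_all_vs_all(seqs, evalue=max_evalue))
    if hits.empty:
        return []
    hits = hits.assign(
        qgenome=hits.qseqid.map(genome_of),
        sgenome=hits.sseqid.map(genome_of),
        qcov=(hits.qend - hits.qstart + 1) / hits.qlen,
        scov=(hits.send - hits.sstart + 1) / hits.slen,
    )
    self_scores = (
        hits.loc[hits.qseqid == hits.sseqid].set_index("qseqid")["bitscore"].to_dict()
    )
    self_sum: dict[str, float] = defaultdict(float)
    for pid, score in self_scores.items():
        self_sum[genome_of[pid]] += score

    qual = hits[
        (hits.qgenome != hits.sgenome)
        & (hits.evalue <= max_evalue)
        & (hits.qcov >= min_cov)
        & (hits.scov >= min_cov)
    ]
    # best hit of each protein into each other genome (hits pre-sorted by score)
    best = qual.drop_duplicates(subset=["qseqid", "sgenome"], keep="first")
    best_map = {
        (r.qseqid, r.sgenome): (r.sseqid, r.bitscore, r.pident) for r in best.itertuples()
    }

    pair_data: dict[tuple[str, str], list[tuple[float, float]]] = defaultdict(list)
    for (q, sg), (s, bits_qs, pid_qs) in best_map.items():
        qg = genome_of[q]
        if qg >= sg:
            continue  # handle each unordered pair once, from the A->B side
        back = best_map.get((s, qg))
        if back is not None and back[0] == q:  # reciprocal best pair
            _, bits_sq, pid_sq = back
            pair_data[(qg, sg)].append(
                ((pid_qs + pid_sq) / 2.0, (bits_qs + bits_sq) / 2.0)
            )

    edges = []
    for (ga, gb), rows in sorted(pair_data.items()):
        aai = float(np.mean([p for p, _ in rows]))
        cum = float(sum(b for _, b in rows))
        denom = min(self_sum.get(ga, 0.0), self_sum.get(gb, 0.0))
        norm = cum / denom if denom > 0 else 0.0
        edge = AAIEdge(ga, gb, aai=aai, n_shared=len(rows), norm_cum_bitscore=norm)
        if keep_all or norm >= min_norm_score:
            edges.append(edge)
    return edges


def pairwise_aai(
    proteins_a: Sequence[ProteinRecord],
    proteins_b: Sequence[ProteinRecord],
    min_cov: float = 0.50,
    max_evalue: float = 1e-5,
) -> AAIEdge:
    """AAI between two genomes' protein sets (see :func:`compute_aai_edges`)."""
    if not proteins_a or not proteins_b:
        raise ValueError("both genomes must have at least one protein")
    edges = compute_aai_edges(
        {"A": proteins_a, "B": proteins_b},
        min_cov=min_cov,
        max_evalue=max_evalue,
        keep_all=True,
    )
    if not edges:
        return AAIEdge("A", "B", aai=0.0, n_shared=0, norm_cum_bitscore=0.0)
    return edges[0]


def aai_groups(
    proteins_by_genome: Mapping[str, Sequence[ProteinRecord]],
    inflation: float = 1.1,
    min_cov: float = 0.50,
    max_evalue: float = 1e-5,
    min_norm_score: float = 0.05,
) -> tuple[list[AAIEdge], AAIGroupSet]:
    """Full gwAAI pipeline: AAI edges, score filter, MCL partition."""
    edges = compute_aai_edges(
        proteins_by_genome,
        min_cov=min_cov,
        max_evalue=max_evalue,
        min_norm_score=min_norm_score,
    )
    groups = mcl_cluster(
        edges, inflation=inflation, nodes=sorted(proteins_by_genome)
    )
    return edges, groups
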