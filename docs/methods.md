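# Methods

## Scope and model

`maveritax` operationalizes a marker-gene framework for recognising
virophages (class *Maveriviricetes*) and placing them in seven family-level
groups. The underlying model is that virophages — and no related element —
carry a recognisable four-gene morphogenesis module (MCP/hexon, penton,
FtsK-HerA packaging ATPase, maturation protease), detectable with profile
HMMs, and that family membership is decided by similarity to labeled
reference MCPs with per-family score cutoffs calibrated on the references
themselves. Polinton-like viruses (PLVs) carry an analogous but
non-homologous packaging ATPase and are screened with a separate profile so
they are reported, not silently discarded.

## Thresholds and defaults

All operating points live in `maveritax.config.RunConfig` and are echoed in
every report header.

| parameter | default | meaning |
|---|---|---|
| `marker_min_score` / `marker_max_evalue` | 40 bits / 0.01 | hmmsearch acceptance for any marker hit |
| `class_mcp_min_score` | 50 bits | MCP score required for the class call |
| `plv_min_score` | 50 bits | PLV-ATPase score for the `possible_plv` flag |
| `min_profile_coverage` | 0.60 | profile fraction a hit must span before its protein is used downstream |
| `dtr_min_len` | 10 nt | shortest terminal repeat reported |
| `min_intergenic` | 1000 nt | intergenic region flagged in integration screen |
| `gc_window` / `gc_delta` / `gc_flank` | 100 nt / 0.05 / 2000 nt | GC-shift boundary rule |
| `min_host_flank` | 2000 nt | host flank needed for `integrated_flanked` |
| `min_checkv` | 90% | external completeness estimate for `checkv_high` |
| `min_linear_complete` | 25000 nt | `large_linear` length threshold |
| `family_floor_bitscore` | 50 bits | family cutoff when no out-of-group hit exists |
| `votu_min_ani` / `votu_min_af` | 95% / 0.85 | vOTU membership |
| `aai_min_cov` / `aai_max_evalue` / `aai_min_norm_score` | 0.50 / 1e-5 / 0.05 | gwAAI edge qualification |
| `mcl_inflation` / `profile_mcl_inflation` | 1.1 / 5 | MCL granularity for gwAAI groups / profile building |

Bit scores are full-sequence scores throughout; domain scores are not used.
Profile coverage is the best domain's aligned profile span divided by
profile length — the conventional reading where no canonical definition
exists.

## Design choices where the design was open

* **Class call keys on the MCP alone.** The demarcation literature states
  both "MCP + ATPase + protease required for a complete genome" and an
  automated MCP-only classifier. The automated rule is implemented for
  assignment; `n_markers_detected` is always reported so the stricter
  criterion can be applied to complete genomes downstream.
* **Family cutoffs are strict (`>`).** The cutoff *is* the best score an
  out-of-group sequence achieved, so a query merely equaling it is not
  distinguishable from the best impostor. Cutoffs are computed per family
  (max over all out-of-group queries), with provenance (which cross pair
  set each cutoff) stored.
* **GC-shift boundaries.** Published integrated-element curation relied on
  expert inspection of GC profiles. The automated stand-in — a boundary
  wherever the mean GC of ≥ 2 kb on one side differs from the other side by
  ≥ 0.05 (absolute) — is reproducible but sits near 3σ of random
  fluctuation for 2-kb windows, so isolated false boundaries on uniform
  sequence occur at the few-percent level per genome. Both parameters are
  configurable; boundary runs are collapsed to their strongest position.
* **ITRs are recorded, never trimmed**; only direct terminal repeats are
  collapsed. Repeat matching is exact ("identical sequences"), longest
  match wins, capped at 5 kb to avoid pathological self-similar inputs.
  Whether to prefer direct or inverted at equal length is arbitrary; direct
  wins.
* **DTR trimming rotation.** If an ORF would span the junction of the
  trimmed (circular) unit — detected on the doubled sequence — the sequence
  is rotated by the smallest shift that places the junction in an
  intergenic gap. Fully coding circles keep their original frame.
* **AAI normalization.** The "normalized cumulative bit score" is not
  defined in the sources it descends from; here it is the summed scores of
  reciprocal best-hit pairs divided by the smaller of the two genomes'
  summed self-scores — bounded by ~1 and symmetric. Raw sums travel with
  each edge so alternative normalizations can be recomputed.
* **MCL numerics.** Only the inflation parameter is externally prescribed.
  Expansion 2, pruning at 1e-6 *after* column renormalization (pruning raw
  inflated values annihilates near-uniform columns), convergence at 1e-8 or
  200 iterations, self-loops at each node's maximum incident weight,
  attractor-based cluster extraction with largest-flow assignment and
  lexicographic tie-breaks. The implementation is validated against an
  independently written dense reference on every binary graph of ≤ 5 nodes.
* **ANI backend.** A k-mer seeded block aligner: exact 13-mer anchors are
  grouped into diagonal bands, anchors far from a band's median diagonal
  are discarded, runs are split at > 500 nt query gaps, and blocks need ≥ 3
  anchors over ≥ 100 nt before global alignment with edlib. Both strands
  are searched; the orientation with the larger aligned fraction wins. The
  support thresholds exist because low-complexity (AT-rich) sequence throws
  spurious anchors that would otherwise fabricate aligned blocks between
  unrelated genomes. Precomputed ANI from an external whole-genome aligner
  can be ingested instead where bit-compatibility with published pipelines
  matters.
* **Fallback gene caller.** The built-in caller enumerates maximal
  stop-to-stop ORFs ≥ 50 aa on six frames (translation table 11, contig
  ends treated as stops, N → X without splitting). It is *not* a trained
  gene finder: it over-calls overlapping junk ORFs and under-calls genes
  whose true start matters. Pipelines aiming to match an external caller's
  gene models should supply that caller's protein FASTA
  (`id # start # end # strand` headers).
* **Multiple MCPs in one genome** are resolved by classifying on the
  highest-scoring coverage-qualified MCP.

## Synthetic data: what it emulates and what it does not

The generator (`maveritax.synthetic`) draws one random ancestral protein
per marker per family, mutates descendants to a target identity
(substitutions only; identity is measured against the ancestor, so pairwise
within-family identity is roughly the square of the target), back-translates
with GC-biased codon choice, and embeds genes among random spacers whose
composition is balanced so the element lands on its GC target. Planted
features with recorded truth: direct terminal repeats, host flanks of
distinct GC with gene-free ≥ 1 kb junctions (host "non-coding" sequence is
made by breaking all long ORFs), near-identical genome copies (vOTU truth),
a PLV pseudo-family, and markerless random decoys. Same spec ⇒
byte-identical outputs.

Default study conditions: seed 42, seven families × ten genomes, marker
identity 0.70, genome lengths 15–45 kb, one 1%-diverged duplicate per
family, two PLV-like and two random genomes. The gwAAI benchmark uses three
families of six genomes at identity 0.90 (within-group AAI ≥ 60 on
average) and 15–20 kb genomes to keep the all-vs-all search quick. These
sizes keep the full test suite and the acceptance script within a few
minutes on one CPU.

What passing these benchmarks shows: the thresholds, tie-breaks and
clustering recover planted structure exactly when signal and noise are
separated as designed. What it does not show: robustness to real
evolutionary processes — indels, rate heterogeneity, domain shuffling,
compositional bias, diverged-beyond-recognition penton proteins (known in
rumen virophages), or chimeric assemblies. Synthetic markers are random
proteins, deliberately non-homologous to any published profile, so
fixture-mode results say nothing about the published profiles' sensitivity;
runs against real data should use the published profile set, which loads
directly (`ProfileSet.from_files`, HMMER3 text format, with an explicit
profile→marker mapping when names do not carry it).

## Degenerate inputs and numerical corner cases

Empty FASTA inputs produce empty reports (exit 0) rather than errors; a
corrupt record inside a batch yields an error row without aborting the
batch. Sequences shorter than twice the minimum repeat length refuse the
terminal-repeat search; ANI requires ≥ 100 nt. GC windows with no
unambiguous base report 0. A single-family reference database cannot yield
out-of-group cutoffs and is rejected. Ties everywhere (best hits, cluster
attractors, representatives) break deterministically: score, then E-value
or identity, then lexicographic id — repeated runs are byte-identical, and
results are independent of the `--threads` setting (searches run
single-threaded).

## Known limitations

* CheckV is not run; its completeness estimate is an optional input column.
* Greedy vOTU clustering tests membership against representatives only
  (standard for the 95/85 protocol), so borderline chains can depend on
  genome length order — mitigated by the deterministic longest-first sort.
* The integration screen's host-likeness call needs reference virophage
  proteins to be meaningful; without them only intergenic regions and GC
  boundaries are reported.
* Profile construction from fewer than ten reference sequences per cluster
  is refused rather than degraded.
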