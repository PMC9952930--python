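# maveritax

Identification, quality control, taxonomic assignment and dereplication of
**virophage** genomes — the small dsDNA viruses (class *Maveriviricetes*)
that replicate only during co-infection of a protist host with a giant
virus.

## Who this is for

Metagenome and virome analysts who assemble contigs and want to know: is
this a virophage, how complete is it, which family does it belong to, and
is it redundant with what I already have? The package implements the
marker-gene demarcation and BLAST-based family assignment framework used to
delineate the class, as a reusable library plus a `maveritax` command-line
tool.

## The method

Virophages share a conserved four-gene **morphogenesis module**: the major
capsid protein (MCP, double jelly-roll hexon), the penton (minor capsid)
protein, an FtsK-HerA family genome-packaging ATPase, and a maturation
cysteine protease (PRO). The workflow:

1. **Marker detection** — predicted proteins (external gene calls, or a
   built-in six-frame stop-to-stop ORF caller) are searched against profile
   HMMs for the four markers with `hmmsearch` semantics (pyhmmer): hits kept
   at E ≤ 0.01 and bit score ≥ 40, reduced to the best hit per marker per
   genome.
2. **Class call** — a genome is assigned to *Maveriviricetes* iff its best
   MCP hit scores ≥ 50 bits. Genomes with ≥ 3 of the 4 markers but no
   qualifying MCP are flagged candidates; non-class genomes hitting the
   distinct polinton-like-virus (PLV) ATPase profile at ≥ 50 bits are
   flagged `possible_plv`.
3. **Family assignment** — the best coverage-qualified MCP (≥ 60% of the
   profile) is compared by blastp to labeled reference MCPs of the seven
   families (*Ruviroviridae*, *Maviroviridae*, *Sputniviroviridae*,
   *Dishuiviroviridae*, *Omnilimnoviroviridae*, *Gulliviroviridae*,
   *Burtonviroviridae*). The best hit assigns its family when the bit score
   strictly exceeds that family's cutoff, which is derived from the
   reference set as the highest score any out-of-group sequence achieves
   (self-hits ignored), with a 50-bit floor.
4. **Genome QC** — direct terminal repeats (identical 5'/3' sequences
   ≥ 10 nt) are detected and the duplicated 3' copy trimmed (with rotation
   if a gene would span the new junction); integrated elements are screened
   via intergenic regions ≥ 1 kb and sustained GC shifts; completeness is
   called in precedence order: isolate reference → integrated with ≥ 2 kb
   host flanks → DTR → ITR → external completeness estimate ≥ 90% → linear
   ≥ 25 kb → partial.
5. **Dereplication & grouping** — genomes are clustered into vOTUs at 95%
   ANI over ≥ 85% aligned fraction of the shorter sequence (greedy,
   longest-first); genome-wide AAI between shared proteins (both-way
   coverage ≥ 50%, E ≤ 1e-5), filtered at normalized cumulative bit score
   ≥ 0.05, is partitioned with an in-house Markov clustering (MCL)
   implementation at inflation 1.1.

Profiles can also be rebuilt from reference proteins (all-vs-all blastp →
MCL at inflation 5 → MAFFT alignment and `hmmbuild` per cluster of ≥ 10).

## Worked example

The package ships a synthetic-data generator that emits family-structured
genomes with planted markers and a truth table, so the whole workflow can
be exercised without downloads:

```bash
maveritax simulate --outdir fx --seed 42 --n-families 3 --genomes-per-family 10
maveritax build-profiles --markers-dir fx --out fx/profiles.hmm
maveritax derive-cutoffs --reference-db fx/reference_mcp.faa \
    --reference-labels fx/reference_labels.tsv --out fx/cutoffs.tsv
maveritax classify fx/genomes.fna --profiles fx/profiles.hmm \
    --reference-db fx/reference_mcp.faa --reference-labels fx/reference_labels.tsv \
    --cutoffs fx/cutoffs.tsv --out report.tsv --summary summary.json
```

`summary.json` from this exact run:

```json
{
  "n_candidate": 0,
  "n_class": 33,
  "n_genomes": 37,
  "n_plv": 2,
  "per_family": {
    "Maviroviridae": 11,
    "Ruviroviridae": 10,
    "Sputniviroviridae": 11,
    "unclassified_within_class": 1
  }
}
```

All 30 simulated virophages plus their 3 planted near-duplicate copies are
class members (`n_class: 33`); the 2 PLV-like genomes are flagged, the 2
random decoys are rejected. One duplicate ends up
`unclassified_within_class`: its 1%-mutated MCP gained an internal stop, the
fragment covers < 60% of the profile, and the coverage rule excludes
truncated genes from family assignment — exactly the intended behavior for
partial gene models. The per-row report (`report.tsv`) carries marker
scores, family, PLV flag and completeness per genome:

```
genome_id  length  n_genes  class_call  n_markers_detected  family         completeness_category
F01G01     20017   111      True        4                   Ruviroviridae  partial
F01G02     35961   177      True        4                   Ruviroviridae  large_linear
PLV02      37004   163      False       0                                  large_linear
```

The same operations are available as library functions
(`maveritax.taxonomy.classify_batch`, `maveritax.clustering.cluster_votus`,
…) returning dataclasses and pandas DataFrames.

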