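"""Hand-built micro-fixtures shared by QC tests."""

from __future__ import annotations

import numpy as np

from maveritax.genome_io import GenomeRecord, call_orfs
from maveritax.synthetic import _STOPS, _suppress_orfs, random_dna

_NON_STOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def clean_gene_circle(rng: np.random.Generator, n_codons: int = 100):
    """A small circular genome whose only ORF of >= 50 aa is one planted
    gene, so rotation validity is decided by that gene alone.

    Returns (circle_sequence, gene_protein).
    """
    for _ in range(100):
        spacer1 = _suppress_orfs(random_dna(rng, 700, 0.45), rng, max_run=20)
        spacer2 = _suppress_orfs(random_dna(rng, 700, 0.45), rng, max_run=20)
        body = "".join(rng.choice(_NON_STOP, size=n_codons))
        circle = spacer1 + "TAA" + body + "TAA" + spacer2
        L = len(circle)
        doubled = GenomeRecord(id="d", sequence=circle + circle)
        circ_orfs = [
            c for c in call_orfs(doubled) if c.start <= L and (c.end - c.start + 1) < L
        ]
        proteins = {c.protein for c in circ_orfs}
        if len(proteins) == 1:
            return circle, proteins.pop()
    raise AssertionError("could not construct a single-gene circle")
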