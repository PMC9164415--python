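"""Seeded generation of random coding sequences.

A random CDS is a string of i.i.d. codons drawn uniformly from the 61 sense
codons of the active table (codon-level, not base-level, uniformity), so the
native frame never contains a stop codon while the shifted frames contain
stops at the rate induced by the codon pool.  Default length is 500 codons;
sets of three CDSs per record group mirror the layout used for the
independent-sequence similarity baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .genetic_code import CodonTable, standard_code


@dataclass(frozen=True, eq=False)
class SimulationSpec:
    """Parameters of one simulated CDS-set collection."""

    n_sets: int
    cds_per_set: int = 3
    codons_per_cds: int = 500
    seed: int = 0
    table: CodonTable = field(default_factory=standard_code)

    def __post_init__(self) -> None:
        if self.codons_per_cds < 2:
            raise ValueError("codons_per_cds must be >= 2")
        if self.n_sets < 1 or self.cds_per_set < 1:
            raise ValueError("n_sets and cds_per_set must be >= 1")


def _codon_pool(table: CodonTable) -> np.ndarray:
    return np.array(table.sense_codons)


def random_cds(
    n_codons: int,
    rng: np.random.Generator | int,
    table: CodonTable | None = None,
) -> str:
    """One CDS of ``n_codons`` uniform sense codons."""
    if n_codons < 2:
        raise ValueError("n_codons must be >= 2")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    table = table or standard_code()
    pool = _codon_pool(table)
    return "".join(pool[rng.integers(0, pool.size, n_codons)])


def random_cds_batch(
    n_cds: int,
    n_codons: int,
    rng: np.random.Generator | int,
    table: CodonTable | None = None,
) -> list[str]:
    """``n_cds`` independent random CDSs from one generator state."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    table = table or standard_code()
    pool = _codon_pool(table)
    draws = rng.integers(0, pool.size, (n_cds, n_codons))
    return ["".join(row) for row in pool[draws]]


def iter_sets(spec: SimulationSpec) -> Iterator[tuple[str, str]]:
    """Yield ``(record_id, sequence)`` pairs, deterministically from the seed.

    Ids encode the set and the index within the set: ``set00001_cds1`` etc.
    """
    rng = np.random.default_rng(spec.seed)
    pool = _codon_pool(spec.table)
    width = max(5, len(str(spec.n_sets)))
    for s in range(1, spec.n_sets + 1):
        for j in range(1, spec.cds_per_set + 1):
            seq = "".join(pool[rng.integers(0, pool.size, spec.codons_per_cds)])
            yield f"set{s:0{width}d}_cds{j}", seq


def generate_sets(spec: SimulationSpec, path) -> int:
    """Write the simulated CDS sets as multi-FASTA; returns records written."""
    n = 0
    with open(path, "w") as fh:
        for rid, seq in iter_sets(spec):
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
            n += 1
    return n
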