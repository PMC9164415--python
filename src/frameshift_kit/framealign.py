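"""Fixed-gap alignment of frame translations and the shiftability statistic.

The three translations of a CDS (WT, FF, RF) are aligned pairwise with a
fixed gap scheme — no gap search is involved, because the frame relationship
between the sequences is known exactly:

* WT vs FF: one gap appended to the end of FF (alignment length ``n``);
* WT vs RF: one gap prepended to the beginning of RF (length ``n``);
* FF vs RF: no gaps (length ``n - 1``).

Pairwise similarity is the fraction of alignment columns whose residue pair
is conserved (substitution score >= 0; gap columns never conserved).  The
shiftability of the CDS is

    delta = (delta12 + delta13 + delta23) / 3

where delta12 = sim(WT, FF), delta13 = sim(WT, RF), delta23 = sim(FF, RF).
Shiftability quantifies how much of the protein survives a +-1 frameshift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genetic_code import (
    ALPHABET,
    GAP,
    CodonTable,
    FrameTranslations,
    ReadthroughRules,
    _cached_lookup,
    _codon_indices,
    encode_bases,
    frame_translations,
    standard_code,
)
from .scoring import ScoringMatrix, load_matrix

PAIRS = ("WT-FF", "WT-RF", "FF-RF")

_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}


@dataclass(frozen=True)
class FrameAlignment:
    """One fixed-gap pairwise alignment between two frame translations."""

    pair: str
    seq_a: str
    seq_b: str
    gap_count: int

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")


@dataclass(frozen=True)
class ShiftabilityResult:
    """Pairwise frame similarities and their mean (shiftability delta)."""

    delta12: float
    delta13: float
    delta23: float
    delta: float
    n: int
    gap_total: int = 2


def framealign_pair(ft: FrameTranslations, pair: str) -> FrameAlignment:
    """Align one pair of frame translations with the fixed gap placement."""
    if pair == "WT-FF":
        return FrameAlignment(pair, ft.wt, ft.ff + GAP, gap_count=1)
    if pair == "WT-RF":
        return FrameAlignment(pair, ft.wt, GAP + ft.rf, gap_count=1)
    if pair == "FF-RF":
        return FrameAlignment(pair, ft.ff, ft.rf, gap_count=0)
    raise ValueError(f"pair must be one of {PAIRS}, got {pair!r}")


def pairwise_similarity(aln: FrameAlignment, m: ScoringMatrix) -> float:
    """Fraction of conserved columns; gap columns count in the denominator."""
    if not aln.seq_a:
        raise ValueError("cannot compute similarity of a zero-length alignment")
    cons = m.conserved_table
    conserved = 0
    for a, b in zip(aln.seq_a, aln.seq_b):
        if a != GAP and b != GAP and cons[_AA_INDEX[a], _AA_INDEX[b]]:
            conserved += 1
    return conserved / len(aln.seq_a)


def _deltas_from_arrays(
    a0: np.ndarray, a1: np.ndarray, a2: np.ndarray, cons: np.ndarray
) -> tuple[float, float, float]:
    """Pairwise similarities from residue-index arrays (wt, ff, rf)."""
    n = a0.size
    d12 = cons[a0[:-1], a1].sum() / n        # last column: WT residue vs gap
    d13 = cons[a0[1:], a2].sum() / n         # first column: WT residue vs gap
    d23 = cons[a1, a2].mean()
    return float(d12), float(d13), float(d23)


def shiftability(
    cds: str,
    table: CodonTable | None = None,
    matrix: ScoringMatrix | str = "GON250",
    readthrough: ReadthroughRules | None | str = "default",
) -> ShiftabilityResult:
    """Shiftability of one CDS.

    ``readthrough="default"`` applies the suppressor-tRNA rules
    (TAG->S, TAA->K, TGA->W) to every stop codon before scoring; pass
    ``None`` to keep stops as '*' and score them via the matrix stop policy.
    """
    table = table or standard_code()
    if isinstance(matrix, str):
        matrix = load_matrix(matrix)
    if readthrough == "default":
        readthrough = ReadthroughRules.default()
    bases = encode_bases(cds)
    if bases.size % 3 != 0:
        raise ValueError(f"CDS length {bases.size} is not a multiple of 3")
    if bases.size < 6:
        raise ValueError("CDS must contain at least two codons")
    lut = _cached_lookup(table, readthrough)
    cons = matrix.conserved_table
    a0 = lut[_codon_indices(bases, 0)]
    a1 = lut[_codon_indices(bases, 1)]
    a2 = lut[_codon_indices(bases, 2)]
    d12, d13, d23 = _deltas_from_arrays(a0, a1, a2, cons)
    return ShiftabilityResult(
        delta12=d12, delta13=d13, delta23=d23,
        delta=(d12 + d13 + d23) / 3, n=int(bases.size // 3),
    )


def native_similarity(
    cds_triple: Sequence[str],
    table: CodonTable | None = None,
    matrix: ScoringMatrix | str = "GON250",
    readthrough: ReadthroughRules | None | str = None,
) -> float:
    """Mean pairwise similarity of the native translations of three CDSs.

    The baseline for mutually independent sequences: translations are
    compared columnwise with no gaps, truncated to the shortest length.
    """
    if len(cds_triple) != 3:
        raise ValueError("expected exactly three CDSs")
    table = table or standard_code()
    if isinstance(matrix, str):
        matrix = load_matrix(matrix)
    if readthrough == "default":
        readthrough = ReadthroughRules.default()
    lut = _cached_lookup(table, readthrough)
    cons = matrix.conserved_table
    arrays = []
    for cds in cds_triple:
        bases = encode_bases(cds)
        if bases.size % 3 != 0:
            raise ValueError(f"CDS length {bases.size} is not a multiple of 3")
        arrays.append(lut[_codon_indices(bases, 0)])
    m = min(a.size for a in arrays)
    a, b, c = (x[:m] for x in arrays)
    sims = (cons[a, b].mean(), cons[a, c].mean(), cons[b, c].mean())
    return float(np.mean(sims))


def batch_shiftability(
    records: Iterable[tuple[str, str] | object],
    table: CodonTable | None = None,
    matrix: ScoringMatrix | str = "GON250",
    readthrough: ReadthroughRules | None | str = "default",
) -> tuple[pd.DataFrame, dict]:
    """Shiftability for a batch of CDS records, with QC skipping.

    ``records`` yields ``(id, sequence)`` pairs or objects with ``id`` /
    ``sequence`` attributes.  Records whose length is not a multiple of 3,
    that contain non-ACGT characters, or that are shorter than two codons
    are skipped and counted.

    Returns a per-record DataFrame (id, n_codons, delta12, delta13, delta23,
    delta) and a summary dict (count, mean, sd, max, min, n_skipped,
    skip_reasons).
    """
    table = table or standard_code()
    if isinstance(matrix, str):
        matrix = load_matrix(matrix)
    if readthrough == "default":
        readthrough = ReadthroughRules.default()

    rows = []
    skip_reasons: dict[str, int] = {}
    n_seen = 0
    for rec in records:
        rid, seq = (rec if isinstance(rec, tuple) else (rec.id, rec.sequence))
        n_seen += 1
        try:
            res = shiftability(seq, table=table, matrix=matrix, readthrough=readthrough)
        except ValueError as exc:
            reason = ("length_not_multiple_of_3" if "multiple of 3" in str(exc)
                      else "too_short" if "two codons" in str(exc)
                      else "ambiguous_bases")
            skip_reasons[reason] = skip_reasons.get(reason, 0) + 1
            continue
        rows.append((rid, res.n, res.delta12, res.delta13, res.delta23, res.delta))
    if n_seen == 0:
        raise ValueError("empty input: no CDS records")
    df = pd.DataFrame(
        rows, columns=["id", "n_codons", "delta12", "delta13", "delta23", "delta"]
    )
    deltas = df["delta"].to_numpy()
    summary = {
        "count": len(df),
        "mean": float(deltas.mean()) if len(df) else float("nan"),
        "sd": float(deltas.std(ddof=1)) if len(df) > 1 else float("nan"),
        "max": float(deltas.max()) if len(df) else float("nan"),
        "min": float(deltas.min()) if len(df) else float("nan"),
        "n_skipped": n_seen - len(df),
        "skip_reasons": skip_reasons,
    }
    return df, summary


def expected_native_similarity(
    table: CodonTable | None = None,
    matrix: ScoringMatrix | str = "GON250",
) -> float:
    """Analytic mean similarity of independent uniform sense-codon draws.

    With residues drawn from the amino-acid frequency p induced by uniform
    draws over the sense codons, the probability that one aligned column is
    conserved is  sum_a sum_b p(a) p(b) [score(a,b) >= 0].
    """
    table = table or standard_code()
    if isinstance(matrix, str):
        matrix = load_matrix(matrix)
    cons = matrix.conserved_table
    p = np.zeros(len(ALPHABET))
    for aa, codons in table.synonym_classes.items():
        p[_AA_INDEX[aa]] = len(codons)
    p /= p.sum()
    return float(p @ cons @ p)
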