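"""Codon-pair frameshift substitutions (CPFSs) and their scores.

Write a codon pair as the six bases B1..B6.  A +-1 frameshift across the
pair, together with one flanking base, replaces the encoded amino-acid pair:

* forward (incoming 5' base B0):  (B0 B1 B2, B3 B4 B5)
* reverse (incoming 3' base B7):  (B2 B3 B4, B5 B6 B7)

Each of the 4,096 codon pairs has four forward and four reverse CPFSs, 4096
x 8 = 32,768 in total.  The pair's frameshift substitution score is the sum
of the two residue substitution scores (optionally their mean).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .genetic_code import BASES, CODONS, CodonTable, standard_code
from .scoring import ScoringMatrix, load_matrix

DIRECTIONS = ("FF", "RF")


@dataclass(frozen=True)
class CodonPairSubstitution:
    """One frameshift substitution of an adjacent codon pair."""

    pair: tuple[str, str]
    direction: str
    flank_base: str
    shifted_pair: tuple[str, str]
    score: float


def shift_codon_pair(
    pair: tuple[str, str], direction: str, flank_base: str
) -> tuple[str, str]:
    """The two shifted codons produced by a +-1 frameshift over a pair."""
    s = pair[0] + pair[1]
    if len(s) != 6:
        raise ValueError("a codon pair must consist of two triplets")
    if direction == "FF":
        return (flank_base + s[0] + s[1], s[2] + s[3] + s[4])
    if direction == "RF":
        return (s[1] + s[2] + s[3], s[4] + s[5] + flank_base)
    raise ValueError(f"direction must be 'FF' or 'RF', got {direction!r}")


def cpfs_score(
    sub: CodonPairSubstitution | tuple,
    table: CodonTable | None = None,
    matrix: ScoringMatrix | str = "GON250",
    combine: str = "sum",
) -> float:
    """Score of one CPFS: combine the two residue substitution scores.

    ``combine="sum"`` (default) adds the two scores, keeping the value
    additive with single-codon FSSs; ``"mean"`` averages them.
    """
    table = table or standard_code()
    if isinstance(matrix, str):
        matrix = load_matrix(matrix)
    if isinstance(sub, CodonPairSubstitution):
        pair, shifted = sub.pair, sub.shifted_pair
    else:
        pair, direction, flank = sub
        shifted = shift_codon_pair(pair, direction, flank)
    s1 = matrix.score(table.assignment[pair[0]], table.assignment[shifted[0]])
    s2 = matrix.score(table.assignment[pair[1]], table.assignment[shifted[1]])
    if combine == "sum":
        return s1 + s2
    if combine == "mean":
        return (s1 + s2) / 2
    raise ValueError(f"combine must be 'sum' or 'mean', got {combine!r}")


def iter_cpfs(
    table: CodonTable | None = None,
    matrix: ScoringMatrix | str = "GON250",
    combine: str = "sum",
) -> Iterator[CodonPairSubstitution]:
    """Yield all 32,768 CPFSs of a code (4 forward + 4 reverse per pair)."""
    table = table or standard_code()
    if isinstance(matrix, str):
        matrix = load_matrix(matrix)
    for c1 in CODONS:
        for c2 in CODONS:
            pair = (c1, c2)
            for direction in DIRECTIONS:
                for b in BASES:
                    shifted = shift_codon_pair(pair, direction, b)
                    sub = CodonPairSubstitution(
                        pair=pair, direction=direction, flank_base=b,
                        shifted_pair=shifted,
                        score=cpfs_score((pair, direction, b), table, matrix,
                                         combine=combine),
                    )
                    yield sub


def enumerate_cpfs(
    table: CodonTable | None = None,
    matrix: ScoringMatrix | str = "GON250",
    combine: str = "sum",
) -> list[CodonPairSubstitution]:
    return list(iter_cpfs(table, matrix, combine))


def codon_fss_means(
    table: CodonTable | None = None,
    matrix: ScoringMatrix | str = "GON250",
) -> np.ndarray:
    """(64,) mean FSS per codon over its 8 frameshift substitutions.

    Flank bases are weighted equally.  Indexed by base-4 codon order.
    """
    from .code_optimality import _fcs_pairs, _score_table

    table = table or standard_code()
    if isinstance(matrix, str):
        matrix = load_matrix(matrix)
    frm, to, _ = _fcs_pairs()
    lut = table.aa_indices
    scores = _score_table(matrix)[lut[frm], lut[to]]
    return scores.reshape(64, 8).mean(axis=1)


def pair_fss_means(
    table: CodonTable | None = None,
    matrix: ScoringMatrix | str = "GON250",
    combine: str = "sum",
) -> np.ndarray:
    """(4096,) mean FSS per codon pair over its 8 CPFSs.

    Indexed by 64 * index(codon1) + index(codon2); flank bases weighted
    equally.  Vectorized over the full enumeration.
    """
    from .code_optimality import _score_table

    table = table or standard_code()
    if isinstance(matrix, str):
        matrix = load_matrix(matrix)
    S = _score_table(matrix)
    lut = table.aa_indices

    # base-4 digits of the 4096 pairs: B1..B6
    idx = np.arange(4096)
    c1, c2 = idx // 64, idx % 64
    b1, b2, b3 = c1 // 16, (c1 // 4) % 4, c1 % 4
    b4, b5, b6 = c2 // 16, (c2 // 4) % 4, c2 % 4

    totals = np.zeros(4096)
    for b in range(4):  # flank base
        # forward: (B0 B1 B2, B3 B4 B5)
        f1 = 16 * b + 4 * b1 + b2
        f2 = 16 * b3 + 4 * b4 + b5
        s_f = S[lut[c1], lut[f1]] + S[lut[c2], lut[f2]]
        # reverse: (B2 B3 B4, B5 B6 B7)
        r1 = 16 * b2 + 4 * b3 + b4
        r2 = 16 * b5 + 4 * b6 + b
        s_r = S[lut[c1], lut[r1]] + S[lut[c2], lut[r2]]
        totals += s_f + s_r
    means = totals / 8
    if combine == "mean":
        means /= 2
    elif combine != "sum":
        raise ValueError(f"combine must be 'sum' or 'mean', got {combine!r}")
    return means
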