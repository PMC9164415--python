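"""Codon substitution classes, frameshift substitution scores, and the
ranking of the standard genetic code among alternatives.

Three families of single-codon substitutions are enumerated exhaustively:

* RCS — random substitutions, any codon to any codon (64 x 64 = 4096);
* ICS — interchangeable substitutions, third position only (64 x 4 = 256);
* FCS — frameshift substitutions: each codon has four forward shifts
  (drop the first base, append an incoming base) and four reverse shifts
  (prepend an incoming base, drop the last), 64 x 8 = 512 in total.

The amino-acid substitution score of an FCS is its frameshift substitution
score (FSS); summed over all 512 FCSs it measures the frameshift tolerance of
a genetic code.  Alternative codes come from two constructions: *random*
codes permute the 20 amino acids over the standard code's synonym classes
(degeneracy and stops preserved), and *compatible* codes permute the
nucleotide alphabet independently at each codon position (24^3 = 13,824, or
24 x 24 x 2 = 1,152 under the wobble constraint at position 3).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np
from scipy import stats

from .genetic_code import BASES, CODONS, STOP, CodonTable, standard_code
from .scoring import ScoringMatrix, load_matrix

KINDS = ("RCS", "ICS", "FCS", "FCS_FF", "FCS_RF")


@dataclass(frozen=True)
class SubstitutionRecord:
    """One codon substitution with its classification and score.

    ``cls`` is SYN when both codons encode the same product (stop counts as
    its own class, so SYN includes all unchanged codons), POS when the
    products differ with a positive substitution score, NEG otherwise.
    """

    from_codon: str
    to_codon: str
    kind: str
    unchanged: bool
    cls: str
    score: float


@dataclass(frozen=True)
class CodeFssSummary:
    code_id: str
    sum_fss: float
    matrix: str


@lru_cache(maxsize=1)
def _fcs_pairs() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Codon-index pairs of the 512 FCSs: (from, to, is_forward).

    Table-independent: a forward shift of codon (b1 b2 b3) with incoming base
    b is (b2 b3 b); a reverse shift with incoming base b is (b b1 b2).
    """
    frm, to, fwd = [], [], []
    for i in range(64):
        b1, b2, b3 = i // 16, (i // 4) % 4, i % 4
        for b in range(4):
            frm.append(i)
            to.append(16 * b2 + 4 * b3 + b)
            fwd.append(True)
        for b in range(4):
            frm.append(i)
            to.append(16 * b + 4 * b1 + b2)
            fwd.append(False)
    return np.array(frm), np.array(to), np.array(fwd)


def _iter_pairs(kind: str) -> Iterator[tuple[int, int, str]]:
    if kind == "RCS":
        for i in range(64):
            for j in range(64):
                yield i, j, "RCS"
    elif kind == "ICS":
        for i in range(64):
            for b in range(4):
                yield i, (i // 4) * 4 + b, "ICS"
    elif kind in ("FCS", "FCS_FF", "FCS_RF"):
        frm, to, fwd = _fcs_pairs()
        for i, j, f in zip(frm, to, fwd):
            k = "FCS_FF" if f else "FCS_RF"
            if kind == "FCS" or kind == k:
                yield int(i), int(j), k
    else:
        raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")


def enumerate_substitutions(
    kind: str,
    table: CodonTable | None = None,
    matrix: ScoringMatrix | str = "GON250",
) -> list[SubstitutionRecord]:
    """Exhaustively enumerate one kind of codon substitution."""
    table = table or standard_code()
    if isinstance(matrix, str):
        matrix = load_matrix(matrix)
    records = []
    for i, j, k in _iter_pairs(kind):
        cf, ct = CODONS[i], CODONS[j]
        af, at = table.assignment[cf], table.assignment[ct]
        score = matrix.score(af, at)
        cls = "SYN" if af == at else ("POS" if score > 0 else "NEG")
        records.append(
            SubstitutionRecord(
                from_codon=cf, to_codon=ct, kind=k,
                unchanged=(cf == ct), cls=cls, score=score,
            )
        )
    return records


def substitution_stats(
    kind: str,
    table: CodonTable | None = None,
    matrix: ScoringMatrix | str = "GON250",
) -> dict:
    """Class counts and mean score for one substitution kind.

    The counts partition the enumeration: SYN + POS + NEG = total, and SYN
    includes the unchanged (identical-codon) cases.
    """
    records = enumerate_substitutions(kind, table, matrix)
    scores = np.array([r.score for r in records])
    return {
        "kind": kind,
        "total": len(records),
        "unchanged": sum(r.unchanged for r in records),
        "SYN": sum(r.cls == "SYN" for r in records),
        "POS": sum(r.cls == "POS" for r in records),
        "NEG": sum(r.cls == "NEG" for r in records),
        "mean_score": float(scores.mean()),
    }


def _score_table(matrix: ScoringMatrix) -> np.ndarray:
    """Dense (21, 21) score array (errors if the matrix is partial)."""
    if not matrix.covers_standard_aas():
        raise ValueError(f"matrix {matrix.name!r} does not cover all residues")
    return matrix._arr


def sum_fss(
    table: CodonTable | None = None,
    matrix: ScoringMatrix | str = "GON250",
) -> CodeFssSummary:
    """Sum of the scores of a code's 512 frameshift substitutions."""
    table = table or standard_code()
    if isinstance(matrix, str):
        matrix = load_matrix(matrix)
    frm, to, _ = _fcs_pairs()
    lut = table.aa_indices
    total = _score_table(matrix)[lut[frm], lut[to]].sum()
    return CodeFssSummary(code_id=table.name, sum_fss=float(total), matrix=matrix.name)


def fss_vs_rss_test(
    table: CodonTable | None = None,
    matrix: ScoringMatrix | str = "GON250",
) -> tuple[float, float]:
    """Welch two-sample t statistic and P-value, FSS vs RSS distributions."""
    fss = [r.score for r in enumerate_substitutions("FCS", table, matrix)]
    rss = [r.score for r in enumerate_substitutions("RCS", table, matrix)]
    t, p = stats.ttest_ind(fss, rss, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Alternative genetic codes
# ---------------------------------------------------------------------------

def _assignment_from_class_relabel(
    base: CodonTable, new_aas: Sequence[str]
) -> dict[str, str]:
    classes = base.synonym_classes  # sorted by amino acid, deterministic
    assignment = {c: STOP for c in base.stop_codons}
    for aa_new, (_aa_old, codons) in zip(new_aas, classes.items()):
        for c in codons:
            assignment[c] = aa_new
    return assignment


def random_codes(
    count: int,
    seed: int,
    method: str = "uniform_permutation",
    table: CodonTable | None = None,
    n_swaps: int = 100,
) -> Iterator[CodonTable]:
    """Stream of degeneracy-preserving random genetic codes.

    Each emitted code reassigns the 20 amino acids over the standard code's
    synonym classes, keeping every degenerate codon synonymous and the stop
    codons fixed.  ``uniform_permutation`` (default) draws uniformly from the
    20! possible relabelings; ``proportional_swap`` applies ``n_swaps``
    transpositions in which an amino acid's chance of being swapped is
    proportional to its number of codons in the table.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    table = table or standard_code()
    rng = np.random.default_rng(seed)
    aas = list(table.synonym_classes)
    sizes = np.array([len(v) for v in table.synonym_classes.values()], dtype=float)
    weights = sizes / sizes.sum()
    for i in range(count):
        if method == "uniform_permutation":
            perm = rng.permutation(len(aas))
            new_aas = [aas[k] for k in perm]
        elif method == "proportional_swap":
            order = list(range(len(aas)))
            for _ in range(n_swaps):
                a, b = rng.choice(len(aas), size=2, replace=False, p=weights)
                order[a], order[b] = order[b], order[a]
            new_aas = [aas[k] for k in order]
        else:
            raise ValueError(f"unknown sampling method {method!r}")
        yield CodonTable(
            name=f"random_{method}_{seed}_{i}",
            assignment=_assignment_from_class_relabel(table, new_aas),
        )


def compatible_codes(
    wobble_constrained: bool = False,
    table: CodonTable | None = None,
) -> list[CodonTable]:
    """All codes reachable by permuting the base alphabet per codon position.

    The code assigned to permutations (p1, p2, p3) translates codon
    b1 b2 b3 as the original code translates p1(b1) p2(b2) p3(b3); stop
    codons move with the permutation, and each code keeps the standard
    code's per-amino-acid codon counts.  With ``wobble_constrained`` only
    the identity and the A<->G swap are allowed at position 3 (purine
    pairing at the wobble position), leaving 24 x 24 x 2 = 1,152 codes.
    """
    table = table or standard_code()
    perms = ["".join(p) for p in itertools.permutations(BASES)]
    third = ["ACGT", "GCAT"] if wobble_constrained else perms
    codes = []
    for p1 in perms:
        m1 = dict(zip(BASES, p1))
        for p2 in perms:
            m2 = dict(zip(BASES, p2))
            for p3 in third:
                m3 = dict(zip(BASES, p3))
                assignment = {
                    c: table.assignment[m1[c[0]] + m2[c[1]] + m3[c[2]]]
                    for c in CODONS
                }
                codes.append(
                    CodonTable(name=f"compatible_{p1}_{p2}_{p3}", assignment=assignment)
                )
    return codes


def pool_sum_fss(
    pool: Sequence[CodonTable],
    matrix: ScoringMatrix | str = "GON250",
) -> np.ndarray:
    """Vectorized sum-FSS for every code in a pool."""
    if isinstance(matrix, str):
        matrix = load_matrix(matrix)
    frm, to, _ = _fcs_pairs()
    S = _score_table(matrix)
    out = np.empty(len(pool))
    for k, code in enumerate(pool):
        lut = code.aa_indices
        out[k] = S[lut[frm], lut[to]].sum()
    return out


def rank_code(
    target: CodonTable,
    pool: Sequence[CodonTable],
    matrix: ScoringMatrix | str = "GON250",
) -> tuple[int, float]:
    """Rank of ``target`` by sum FSS within ``pool`` (higher sum is better).

    rank = 1 + number of pool codes with strictly greater sum FSS;
    percentile = rank / len(pool) (a fraction; small is near the top).
    """
    if not len(pool):
        raise ValueError("pool must be non-empty")
    if isinstance(matrix, str):
        matrix = load_matrix(matrix)
    target_sum = sum_fss(target, matrix).sum_fss
    sums = pool_sum_fss(pool, matrix)
    rank = 1 + int((sums > target_sum).sum())
    return rank, rank / len(pool)
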