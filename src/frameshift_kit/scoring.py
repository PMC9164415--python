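"""Amino-acid substitution matrices and the conserved-site predicate.

Three "deep" matrices are bundled: BLOSUM62, PAM250 and GON250 (Gonnet's
PAM250-distance matrix in the conventional x10 integer scaling).  A pair of
aligned residues is *conserved* when neither is a gap and their substitution
score is >= 0; gap columns and negative scores count as different.

Stops are treated as a 21st residue class.  How a stop scores against an
amino acid is not defined by the matrices themselves, so it is governed by a
``stop_policy``:

``min_score`` (default)
    score('*','*') = +1 (synonymous-equivalent), score('*', aa) = the matrix
    minimum over the 20x20 block (always negative for the bundled matrices).
``matrix_star_row``
    use the '*' row shipped in the matrix file (BLOSUM62/PAM250 have one;
    an error is raised for matrices without it).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .genetic_code import ALPHABET, GAP, STOP

BUNDLED = ("BLOSUM62", "PAM250", "GON250")
_AMBIGUITY = set("BZX")  # accepted in files, ignored for the 21-letter core


class ScoringMatrix:
    """Symmetric residue substitution matrix over the 21-letter alphabet.

    Parameters
    ----------
    name:
        Label ("BLOSUM62", "PAM250", "GON250" or a file path).
    scores:
        Mapping ``(aa1, aa2) -> score`` covering at least one residue pair;
        must be symmetric.
    stop_policy:
        How '*' pairs are scored when the source does not define them
        (see module docstring).
    """

    def __init__(self, name: str, scores: dict[tuple[str, str], float],
                 stop_policy: str = "min_score"):
        if stop_policy not in ("min_score", "matrix_star_row"):
            raise ValueError(f"unknown stop_policy {stop_policy!r}")
        self.name = name
        self.stop_policy = stop_policy

        arr = np.full((21, 21), np.nan)
        for (a, b), s in scores.items():
            ia, ib = ALPHABET.index(a), ALPHABET.index(b)
            if not np.isnan(arr[ia, ib]) and arr[ia, ib] != s:
                raise ValueError(f"conflicting scores for pair ({a},{b})")
            arr[ia, ib] = arr[ib, ia] = s

        core = arr[:20, :20]
        self._min_core = float(np.nanmin(core)) if not np.all(np.isnan(core)) else np.nan
        istar = ALPHABET.index(STOP)
        if stop_policy == "min_score":
            arr[istar, :] = self._min_core
            arr[:, istar] = self._min_core
            arr[istar, istar] = 1.0
        elif np.isnan(arr[istar, istar]):
            raise ValueError(
                f"matrix {name!r} has no '*' row; stop_policy='matrix_star_row' "
                "is unavailable"
            )
        self._arr = arr

    # -- access -----------------------------------------------------------
    def score(self, a: str, b: str) -> float:
        s = self._arr[ALPHABET.index(a), ALPHABET.index(b)]
        if np.isnan(s):
            raise KeyError(f"matrix {self.name!r} defines no score for ({a},{b})")
        return float(s)

    @property
    def min_score(self) -> float:
        """Minimum score over the defined 20x20 amino-acid block."""
        return self._min_core

    def covers_standard_aas(self) -> bool:
        return not np.isnan(self._arr[:20, :20]).any()

    @property
    def conserved_table(self) -> np.ndarray:
        """(21, 21) boolean array: score >= 0, indexed by ALPHABET position."""
        if not self.covers_standard_aas():
            raise ValueError(
                f"matrix {self.name!r} does not cover the 20 standard amino acids"
            )
        return self._arr >= 0

    def to_dict(self) -> dict[tuple[str, str], float]:
        out = {}
        for i, a in enumerate(ALPHABET):
            for j, b in enumerate(ALPHABET[i:], start=i):
                if not np.isnan(self._arr[i, j]):
                    out[(a, ALPHABET[j])] = float(self._arr[i, j])
        return out

    def write(self, path) -> None:
        """Serialize in the standard square matrix text layout."""
        letters = [a for i, a in enumerate(ALPHABET)
                   if not np.isnan(self._arr[i, i])]
        with open(path, "w") as fh:
            fh.write("   " + "  ".join(letters) + "\n")
            for a in letters:
                row = " ".join(_fmt(self.score(a, b)) for b in letters)
                fh.write(f"{a}  {row}\n")

    def __repr__(self) -> str:
        return f"ScoringMatrix({self.name!r}, stop_policy={self.stop_policy!r})"


def _fmt(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else f"{x:g}"


def _from_bio_array(name: str, bio_arr, stop_policy: str,
                    scale: float = 1.0) -> ScoringMatrix:
    letters = list(bio_arr.alphabet)
    unknown = [c for c in letters if c not in ALPHABET and c not in _AMBIGUITY]
    if unknown:
        raise ValueError(f"matrix {name!r} contains unknown residue letters: {unknown}")
    scores: dict[tuple[str, str], float] = {}
    for a in letters:
        for b in letters:
            if a in ALPHABET and b in ALPHABET:
                va, vb = bio_arr[a, b], bio_arr[b, a]
                if va != vb:
                    raise ValueError(
                        f"matrix {name!r} is asymmetric at ({a},{b}): {va} vs {vb}"
                    )
                scores[(a, b)] = float(va) * scale
    # partial (toy) matrices are permitted; bundled ones cover all 20 residues
    return ScoringMatrix(name, scores, stop_policy=stop_policy)


@lru_cache(maxsize=16)
def load_matrix(source: str, stop_policy: str = "min_score") -> ScoringMatrix:
    """Load a bundled matrix by name or any NCBI-format matrix file by path.

    Bundled names (case-insensitive): BLOSUM62, PAM250, GON250.  GON250 is
    Gonnet's 250-PAM matrix in x10 integer scaling.
    """
    key = source.upper()
    if key in ("BLOSUM62", "BLOSSUM62"):
        return _from_bio_array("BLOSUM62", substitution_matrices.load("BLOSUM62"),
                               stop_policy)
    if key == "PAM250":
        return _from_bio_array("PAM250", substitution_matrices.load("PAM250"),
                               stop_policy)
    if key in ("GON250", "GONNET250", "GONNET"):
        return _from_bio_array("GON250", substitution_matrices.load("GONNET1992"),
                               stop_policy, scale=10.0)
    try:
        bio_arr = substitution_matrices.read(source)
    except FileNotFoundError:
        raise FileNotFoundError(
            f"{source!r} is neither a bundled matrix name {BUNDLED} nor a file"
        ) from None
    m = _from_bio_array(source, bio_arr, stop_policy)
    _check_complete(m, source)
    return m


def _check_complete(m: ScoringMatrix, source: str) -> None:
    # every residue present in the file must score against every other
    letters = [a for i, a in enumerate(ALPHABET[:20]) if not np.isnan(m._arr[i, i])]
    sub = m._arr[np.ix_([ALPHABET.index(a) for a in letters],
                        [ALPHABET.index(a) for a in letters])]
    if np.isnan(sub).any():
        raise ValueError(f"matrix file {source!r} has missing cells")


def is_conserved(a: str, b: str, m: ScoringMatrix) -> bool:
    """True iff neither symbol is a gap and score(a, b) >= 0.

    Gap columns are never conserved; stops score via the matrix's stop policy.
    """
    if a == GAP or b == GAP:
        return False
    return m.score(a, b) >= 0
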