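"""Codon tables, frame translation, and stop-codon readthrough.

A coding sequence (CDS) of ``n`` codons has three translations on its sense
strand: the wild-type protein WT (frame offset 0), the forward frameshift FF
(offset 1, ``n - 1`` complete codons) and the reverse frameshift RF (offset 2,
``n - 1`` complete codons).  The trailing incomplete codon of FF/RF is
discarded.  Stop codons may optionally be read through into amino acids using
rules modelled on natural suppressor tRNAs (supD/supE/supF for TAG, supG for
TAA, supU for TGA).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import cached_property, lru_cache
from typing import Iterator, Mapping

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

BASES = "ACGT"
#: The 20 standard amino acids, alphabetical one-letter order.
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"
#: Residue alphabet used for array-indexed computations; stop is index 20.
ALPHABET = AA_LETTERS + STOP
GAP = "-"

#: All 64 codons in base-4 index order (AAA, AAC, ..., TTT).
CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(BASES, repeat=3)
)
_CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i
# RNA notation is accepted and normalized to DNA.
_BASE_CODE[ord("U")] = _BASE_CODE[ord("T")]
_BASE_CODE[ord("u")] = _BASE_CODE[ord("T")]

_AA_BYTES = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


def codon_index(codon: str) -> int:
    """Base-4 index of a codon (AAA=0 ... TTT=63)."""
    return _CODON_INDEX[codon.upper().replace("U", "T")]


def encode_bases(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (A=0, C=1, G=2, T=3).

    U/u are treated as T.  Any other character raises ``ValueError`` naming
    the first offending 1-based position.
    """
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    arr = _BASE_CODE[raw]
    bad = np.nonzero(arr == 255)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"invalid nucleotide {seq[pos]!r} at position {pos + 1} "
            "(expected A/C/G/T/U)"
        )
    return arr


def _codon_indices(bases: np.ndarray, offset: int) -> np.ndarray:
    """Indices of the complete in-frame codons starting at ``offset``."""
    m = (bases.size - offset) // 3
    end = offset + 3 * m
    return (
        16 * bases[offset:end:3]
        + 4 * bases[offset + 1 : end : 3]
        + bases[offset + 2 : end : 3]
    )


# eq=False: identity-based hashing (the mapping field itself is unhashable);
# tables are compared explicitly via .assignment where needed.
@dataclass(frozen=True, eq=False)
class CodonTable:
    """Assignment of the 64 DNA triplets to amino acids / the stop symbol."""

    name: str
    assignment: Mapping[str, str]

    def __post_init__(self) -> None:
        keys = set(self.assignment)
        if keys != set(CODONS):
            missing = sorted(set(CODONS) - keys)[:3]
            extra = sorted(keys - set(CODONS))[:3]
            raise ValueError(
                f"codon table {self.name!r} must cover the 64 ACGT triplets "
                f"exactly (missing e.g. {missing}, unexpected e.g. {extra})"
            )
        bad = {v for v in self.assignment.values() if v not in ALPHABET}
        if bad:
            raise ValueError(f"invalid amino-acid symbols: {sorted(bad)}")

    @cached_property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.assignment[c] == STOP)

    @cached_property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.assignment[c] != STOP)

    @cached_property
    def synonym_classes(self) -> dict[str, tuple[str, ...]]:
        """Sense codons grouped by encoded amino acid (stops excluded)."""
        classes: dict[str, list[str]] = {}
        for c in self.sense_codons:
            classes.setdefault(self.assignment[c], []).append(c)
        return {aa: tuple(cs) for aa, cs in sorted(classes.items())}

    @cached_property
    def aa_indices(self) -> np.ndarray:
        """(64,) uint8 array mapping codon index to residue index in ALPHABET."""
        lut = np.empty(64, dtype=np.uint8)
        for i, c in enumerate(CODONS):
            lut[i] = ALPHABET.index(self.assignment[c])
        lut.setflags(write=False)
        return lut

    def __getitem__(self, codon: str) -> str:
        return self.assignment[codon.upper().replace("U", "T")]

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "CodonTable":
        """Read a two-column ``codon<TAB>amino-acid`` text table."""
        assignment: dict[str, str] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"{path}:{ln}: expected 'codon aa', got {line!r}")
                codon, aa = parts
                codon = codon.upper().replace("U", "T")
                if codon in assignment:
                    raise ValueError(f"{path}:{ln}: duplicate codon {codon}")
                assignment[codon] = aa.upper()
        return cls(name or str(path), assignment)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for c in CODONS:
                fh.write(f"{c}\t{self.assignment[c]}\n")


@lru_cache(maxsize=1)
def standard_code() -> CodonTable:
    """The standard genetic code (NCBI translation table 1)."""
    ncbi = unambiguous_dna_by_id[1]
    assignment = dict(ncbi.forward_table)
    for c in ncbi.stop_codons:
        assignment[c] = STOP
    return CodonTable("standard", assignment)


#: Suppressor-tRNA readthrough rules: locus -> (stop codon, amino acid).
SUPPRESSOR_TRNAS: dict[str, tuple[str, str]] = {
    "supD": ("TAG", "S"),
    "supE": ("TAG", "Q"),
    "supF": ("TAG", "Y"),
    "supG": ("TAA", "K"),
    "supU": ("TGA", "W"),
}


@dataclass(frozen=True, eq=False)
class ReadthroughRules:
    """Stop-codon -> amino-acid replacements applied during translation."""

    mapping: Mapping[str, str] = field(
        default_factory=lambda: {"TAG": "S", "TAA": "K", "TGA": "W"}
    )

    def __post_init__(self) -> None:
        for codon, aa in self.mapping.items():
            if codon not in ("TAA", "TAG", "TGA"):
                raise ValueError(f"{codon!r} is not a standard stop codon")
            if aa not in AA_LETTERS:
                raise ValueError(f"{aa!r} is not a standard amino acid")

    @classmethod
    def default(cls, tag: str = "S") -> "ReadthroughRules":
        """Default rule set covering all three stops.

        ``tag`` selects the amber suppressor: 'S' (supD), 'Q' (supE) or
        'Y' (supF).  TAA -> K (supG) and TGA -> W (supU) are fixed.
        """
        if tag not in ("S", "Q", "Y"):
            raise ValueError("TAG suppressor must be one of 'S', 'Q', 'Y'")
        return cls({"TAG": tag, "TAA": "K", "TGA": "W"})

    def get(self, codon: str) -> str | None:
        return self.mapping.get(codon)


@dataclass(frozen=True)
class FrameTranslations:
    """The triple (WT, FF, RF) of protein translations of one CDS."""

    wt: str
    ff: str
    rf: str
    n: int

    def __post_init__(self) -> None:
        if len(self.wt) != self.n or len(self.ff) != self.n - 1 or len(self.rf) != self.n - 1:
            raise ValueError(
                "frame translation lengths must be (n, n-1, n-1); got "
                f"({len(self.wt)}, {len(self.ff)}, {len(self.rf)}) for n={self.n}"
            )


def _aa_lookup(table: CodonTable, readthrough: ReadthroughRules | None) -> np.ndarray:
    lut = table.aa_indices.copy()
    if readthrough is not None:
        for codon in table.stop_codons:
            aa = readthrough.get(codon)
            if aa is not None:
                lut[_CODON_INDEX[codon]] = ALPHABET.index(aa)
    lut.setflags(write=False)
    return lut


@lru_cache(maxsize=64)
def _cached_lookup(table: CodonTable, readthrough: ReadthroughRules | None) -> np.ndarray:
    # keyed by object identity; rebuilding on a cache miss is cheap (64 lookups)
    return _aa_lookup(table, readthrough)


def _decode_aa(indices: np.ndarray) -> str:
    return _AA_BYTES[indices].tobytes().decode()


def translate(
    cds: str,
    frame_offset: int = 0,
    table: CodonTable | None = None,
    readthrough: ReadthroughRules | None = None,
) -> str:
    """Translate complete triplets of ``cds`` starting at ``frame_offset``.

    Trailing 1-2 bases are discarded.  Stop codons render as ``'*'`` unless
    ``readthrough`` rules replace them with an amino acid.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    table = table or standard_code()
    bases = encode_bases(cds)
    if bases.size < frame_offset + 3:
        raise ValueError(
            f"sequence of length {bases.size} has no complete codon at "
            f"frame offset {frame_offset}"
        )
    lut = _cached_lookup(table, readthrough)
    return _decode_aa(lut[_codon_indices(bases, frame_offset)])


def frame_translations(
    cds: str,
    table: CodonTable | None = None,
    readthrough: ReadthroughRules | None = None,
) -> FrameTranslations:
    """Build the (WT, FF, RF) translation triple of a CDS.

    The CDS length must be a multiple of 3 (no silent trimming; QC happens
    upstream) and at least two codons long.
    """
    table = table or standard_code()
    bases = encode_bases(cds)
    if bases.size % 3 != 0:
        raise ValueError(
            f"CDS length {bases.size} is not a multiple of 3; "
            "run QC/trimming explicitly before translation"
        )
    if bases.size < 6:
        raise ValueError("CDS must contain at least two codons")
    lut = _cached_lookup(table, readthrough)
    n = bases.size // 3
    wt = _decode_aa(lut[_codon_indices(bases, 0)])
    ff = _decode_aa(lut[_codon_indices(bases, 1)])
    rf = _decode_aa(lut[_codon_indices(bases, 2)])
    return FrameTranslations(wt=wt, ff=ff, rf=rf, n=n)


def iter_codons(cds: str) -> Iterator[str]:
    """Yield the in-frame codons of a CDS (length must be a multiple of 3)."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length is not a multiple of 3")
    s = cds.upper().replace("U", "T")
    for i in range(0, len(s), 3):
        yield s[i : i + 3]
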