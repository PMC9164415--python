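"""Codon and codon-pair usage census, over/under-representation, and
usage-weighted frameshift substitution scores.

Observed counts come from in-frame codons (and adjacent in-frame codon
pairs, never crossing record boundaries).  Expected counts follow the
independence construction of Gutman & Hatfield:

* codon pairs: E(a,b) = N_a N_b / N^2 * P, the product of the codon
  marginal frequencies scaled so that sum(E) = sum(O) (= P, the number of
  observed pairs);
* single codons: amino-acid-conditional uniform synonym usage,
  E(c) = N_aa(c) / k_aa(c), where k is the synonym-class size.

Each unit gets chi2 = (O - E)^2 / E and an over (O > E) / under (O < E) /
absent (O = 0) status; weighted mean FSS averages a per-unit FSS with the
observed frequencies as weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .codon_pairs import codon_fss_means, pair_fss_means
from .genetic_code import CODONS, CodonTable, encode_bases, standard_code
from .scoring import ScoringMatrix

PAIR_UNITS: tuple[str, ...] = tuple(f"{a}-{b}" for a in CODONS for b in CODONS)


@dataclass(frozen=True)
class UsageRecord:
    """Observed/expected usage of one codon or codon pair."""

    unit: str
    observed: int
    expected: float
    chi2: float
    status: str  # over | under | absent | equal
    frequency: float


@dataclass(frozen=True)
class WeightedFss:
    scope: str    # codons | codon_pairs
    subset: str   # over | under | all
    value: float


def _status(observed: int, expected: float) -> str:
    if observed == 0:
        return "absent"
    if observed > expected:
        return "over"
    if observed < expected:
        return "under"
    return "equal"


def _observed_counts(cds_set: Iterable[str], unit: str) -> np.ndarray:
    n_units = 64 if unit == "codon" else 4096
    counts = np.zeros(n_units, dtype=np.int64)
    n_records = 0
    for seq in cds_set:
        n_records += 1
        bases = encode_bases(seq)
        if bases.size % 3 != 0:
            raise ValueError(f"CDS length {bases.size} is not a multiple of 3")
        m = bases.size // 3
        b = bases.astype(np.int64)  # uint8 would overflow in the pair index
        cod = 16 * b[0::3] + 4 * b[1::3] + b[2::3]
        if unit == "codon":
            np.add.at(counts, cod, 1)
        else:
            if m >= 2:
                np.add.at(counts, 64 * cod[:-1] + cod[1:], 1)
    if n_records == 0:
        raise ValueError("empty input: no CDS records")
    return counts


def count_usage(cds_set: Iterable[str], unit: str = "codon") -> list[UsageRecord]:
    """Usage records for a CDS set: observed counts, expectations and chi2.

    ``unit`` is ``"codon"`` (64 records) or ``"codon_pair"`` (4,096 records,
    adjacent in-frame pairs within each record).
    """
    if unit not in ("codon", "codon_pair"):
        raise ValueError(f"unit must be 'codon' or 'codon_pair', got {unit!r}")
    seqs = list(cds_set)
    if unit == "codon":
        observed = _observed_counts(seqs, "codon")
        names = CODONS
    else:
        observed = _observed_counts(seqs, "codon_pair")
        names = PAIR_UNITS
    total = int(observed.sum())
    if total == 0:
        raise ValueError("no complete units counted")
    records = [
        UsageRecord(unit=names[i], observed=int(observed[i]), expected=np.nan,
                    chi2=np.nan, status=_status(int(observed[i]), np.nan),
                    frequency=observed[i] / total)
        for i in range(len(names))
    ]
    expectations = expected_counts(records, unit=unit, cds_set=seqs)
    return apply_expectations(records, expectations)


def expected_counts(
    records: Sequence[UsageRecord],
    unit: str = "codon_pair",
    table: CodonTable | None = None,
    cds_set: Sequence[str] | None = None,
) -> np.ndarray:
    """Gutman-Hatfield expected counts matching the observed records.

    For codon pairs the expectation is the codon-marginal independence
    model; ``records`` may be the pair records themselves (marginals are
    then derived from them) or, with ``cds_set`` given, marginals come from
    an in-frame codon count of the set.  For single codons the expectation
    distributes each amino acid's observed total uniformly over its
    synonymous codons.  In both cases sum(E) = sum(O).
    """
    table = table or standard_code()
    observed = np.array([r.observed for r in records], dtype=float)
    if unit == "codon":
        if observed.size != 64:
            raise ValueError("codon expectations need 64 records")
        expected = np.zeros(64)
        classes = dict(table.synonym_classes)
        classes["*"] = table.stop_codons
        index = {c: i for i, c in enumerate(CODONS)}
        for codons in classes.values():
            ids = [index[c] for c in codons]
            expected[ids] = observed[ids].sum() / len(ids)
        return expected
    if unit == "codon_pair":
        if observed.size != 4096:
            raise ValueError("codon-pair expectations need 4096 records")
        n_pairs = observed.sum()
        if n_pairs == 0:
            raise ValueError("zero total pair count")
        if cds_set is not None:
            marg = _observed_counts(cds_set, "codon").astype(float)
        else:
            # derive marginals from the pair counts themselves
            pairs = observed.reshape(64, 64)
            marg = pairs.sum(axis=1) + pairs.sum(axis=0)
        p = marg / marg.sum()
        return np.outer(p, p).ravel() * n_pairs
    raise ValueError(f"unit must be 'codon' or 'codon_pair', got {unit!r}")


def apply_expectations(
    records: Sequence[UsageRecord], expectations: np.ndarray
) -> list[UsageRecord]:
    out = []
    for rec, e in zip(records, expectations):
        chi2 = (rec.observed - e) ** 2 / e if e > 0 else np.nan
        out.append(replace(rec, expected=float(e), chi2=float(chi2),
                           status=_status(rec.observed, e)))
    return out


def weighted_mean_fss(
    usage: Sequence[UsageRecord],
    fss_per_unit: np.ndarray | Sequence[float],
    subset: str = "all",
) -> WeightedFss:
    """Usage-weighted mean FSS over a subset of units.

    Weights are the observed frequencies; absent units carry zero weight.
    ``subset`` restricts to over- or under-represented units.
    """
    if subset not in ("all", "over", "under"):
        raise ValueError(f"subset must be all/over/under, got {subset!r}")
    fss = np.asarray(fss_per_unit, dtype=float)
    if fss.size != len(usage):
        raise ValueError("usage and FSS tables must cover the same units")
    w = np.array([
        r.frequency if (subset == "all" or r.status == subset) else 0.0
        for r in usage
    ])
    if w.sum() == 0:
        raise ValueError(f"no usage weight in subset {subset!r}")
    scope = "codons" if len(usage) == 64 else "codon_pairs"
    return WeightedFss(scope=scope, subset=subset,
                       value=float((w * fss).sum() / w.sum()))


def usage_table(
    cds_set: Iterable[str],
    unit: str = "codon",
    table: CodonTable | None = None,
    matrix: ScoringMatrix | str = "GON250",
) -> pd.DataFrame:
    """Full usage report: unit, O, E, chi2, status, freq, mean FSS per unit."""
    records = count_usage(cds_set, unit=unit)
    fss = (codon_fss_means(table, matrix) if unit == "codon"
           else pair_fss_means(table, matrix))
    return pd.DataFrame({
        "unit": [r.unit for r in records],
        "observed": [r.observed for r in records],
        "expected": [r.expected for r in records],
        "chi2": [r.chi2 for r in records],
        "status": [r.status for r in records],
        "frequency": [r.frequency for r in records],
        "fss": fss,
    })
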