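"""FASTA CDS ingestion with QC flags, and run configuration."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .genetic_code import ReadthroughRules, iter_codons, standard_code

QC_FLAGS = (
    "length_not_multiple_of_3",
    "ambiguous_bases",
    "internal_stop",
    "too_short",
)


@dataclass(frozen=True)
class CdsRecord:
    """One CDS record with its QC flags (empty set = clean)."""

    id: str
    sequence: str
    qc_flags: frozenset[str] = frozenset()

    @property
    def clean(self) -> bool:
        return not self.qc_flags


def _qc(seq: str) -> frozenset[str]:
    flags = set()
    if len(seq) % 3 != 0:
        flags.add("length_not_multiple_of_3")
    if len(seq) < 6:
        flags.add("too_short")
    if any(b not in "ACGT" for b in seq):
        flags.add("ambiguous_bases")
    elif len(seq) % 3 == 0 and len(seq) >= 6:
        table = standard_code()
        stops = set(table.stop_codons)
        codons = list(iter_codons(seq))
        if any(c in stops for c in codons[:-1]):
            flags.add("internal_stop")
    return frozenset(flags)


def read_cds_fasta(path) -> list[CdsRecord]:
    """Parse a FASTA file of CDSs, attaching QC flags to each record.

    U is normalized to T and case to upper before QC.  Raises on an empty
    file or a file that does not start with a FASTA header.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise ValueError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise ValueError(f"{path}:1: malformed FASTA (expected '>' header)")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(CdsRecord(id=rec.id, sequence=seq, qc_flags=_qc(seq)))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def qc_summary(records: list[CdsRecord]) -> dict[str, int]:
    summary = {"total": len(records), "clean": sum(r.clean for r in records)}
    for flag in QC_FLAGS:
        summary[flag] = sum(flag in r.qc_flags for r in records)
    return summary


@dataclass(frozen=True, eq=False)
class RunConfig:
    """Serializable configuration of one analysis run.

    Echoed as ``# key=value`` comment lines at the top of every output TSV
    so a result file records how it was produced.
    """

    matrix: str = "GON250"
    readthrough_on: bool = True
    readthrough: dict = field(
        default_factory=lambda: {"TAG": "S", "TAA": "K", "TGA": "W"}
    )
    stop_policy: str = "min_score"
    seed: int = 0
    keep_internal_stop: bool = True

    def rules(self) -> ReadthroughRules | None:
        return ReadthroughRules(self.readthrough) if self.readthrough_on else None

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix,
            "readthrough_on": self.readthrough_on,
            **{f"readthrough.{k}": v for k, v in sorted(self.readthrough.items())},
            "stop_policy": self.stop_policy,
            "seed": self.seed,
            "keep_internal_stop": self.keep_internal_stop,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a flat ``key=value`` config file.

        Recognized keys: matrix, readthrough (on/off), readthrough.TAG,
        readthrough.TAA, readthrough.TGA, stop_policy, seed,
        keep_internal_stop.
        """
        values: dict[str, str] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{ln}: expected key=value, got {line!r}")
                k, v = line.split("=", 1)
                values[k.strip()] = v.strip()
        rt = {"TAG": "S", "TAA": "K", "TGA": "W"}
        for stop in list(rt):
            if f"readthrough.{stop}" in values:
                rt[stop] = values[f"readthrough.{stop}"].upper()
        return cls(
            matrix=values.get("matrix", "GON250"),
            readthrough_on=values.get("readthrough", "on").lower()
            in ("on", "true", "1", "yes"),
            readthrough=rt,
            stop_policy=values.get("stop_policy", "min_score"),
            seed=int(values.get("seed", "0")),
            keep_internal_stop=values.get("keep_internal_stop", "true").lower()
            in ("on", "true", "1", "yes"),
        )
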