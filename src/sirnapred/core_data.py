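"""Domain types and I/O for siRNA activity datasets.

A record is a 21-nt guide (antisense) strand written 5'->3' over the RNA
alphabet {A, C, G, U}, optionally carrying a measured RNAi activity
(normalized target knockdown in [0, 1]) and the mRNA context it targets.
Guides of any other length are rejected rather than trimmed, because every
positional feature downstream assumes exactly 21 positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

from Bio import SeqIO

__all__ = [
    "GUIDE_LENGTH",
    "POTENCY_THRESHOLD",
    "ValidationError",
    "SiRNARecord",
    "Dataset",
    "PotencyLabel",
    "normalize_sequence",
    "read_dataset",
    "write_dataset",
    "label_potency",
    "reverse_complement",
]

GUIDE_LENGTH = 21

#: Activity cut separating potent from nonpotent siRNAs (>70% knockdown).
POTENCY_THRESHOLD = 0.7

_RNA_BASES = frozenset("ACGU")
_ALLOWED_RAW = frozenset("ACGUTacgut")


class ValidationError(ValueError):
    """Raised when a sequence or record violates a domain invariant."""


def normalize_sequence(raw: str) -> str:
    """Uppercase an RNA/DNA sequence and convert T to U.

    Parameters
    ----------
    raw : str
        Nonempty sequence over {A, C, G, U, T}, case-insensitive.

    Returns
    -------
    str
        The sequence over {A, C, G, U}.

    Raises
    ------
    ValidationError
        If the sequence is empty or contains a character outside the
        alphabet; the message names the offending 1-based position.
    """
    if not raw:
        raise ValidationError("empty sequence")
    for i, ch in enumerate(raw):
        if ch not in _ALLOWED_RAW:
            raise ValidationError(
                f"invalid character {ch!r} at position {i + 1} "
                f"(expected one of A/C/G/U/T, any case)"
            )
    return raw.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA sequence (A<->U, G<->C)."""
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    try:
        return "".join(comp[b] for b in reversed(seq))
    except KeyError as exc:  # pragma: no cover - guarded by normalization
        raise ValidationError(f"invalid base {exc.args[0]!r}") from exc


@dataclass
class SiRNARecord:
    """One siRNA: guide strand plus optional activity and mRNA context.

    Positions 1..21 index the guide strand 5'->3'. ``activity`` is the
    normalized knockdown fraction in [0, 1]; ``mrna_context`` is the
    (sense-strand) mRNA region the guide targets, at least 21 nt long.
    """

    id: str
    guide: str
    activity: float | None = None
    mrna_context: str | None = None

    def __post_init__(self) -> None:
        self.guide = normalize_sequence(self.guide)
        if len(self.guide) != GUIDE_LENGTH:
            raise ValidationError(
                f"record {self.id!r}: guide must be exactly {GUIDE_LENGTH} nt, "
                f"got {len(self.guide)}"
            )
        if self.activity is not None:
            self.activity = float(self.activity)
            if math.isnan(self.activity) or not 0.0 <= self.activity <= 1.0:
                raise ValidationError(
                    f"record {self.id!r}: activity {self.activity} outside [0, 1]"
                )
        if self.mrna_context is not None:
            self.mrna_context = normalize_sequence(self.mrna_context)
            if len(self.mrna_context) < GUIDE_LENGTH:
                raise ValidationError(
                    f"record {self.id!r}: mRNA context shorter than "
                    f"{GUIDE_LENGTH} nt"
                )


@dataclass
class Dataset:
    """Ordered collection of :class:`SiRNARecord` with unique ids."""

    records: list[SiRNARecord] = field(default_factory=list)
    name: str = "dataset"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValidationError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SiRNARecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SiRNARecord:
        return self.records[i]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclass(frozen=True)
class PotencyLabel:
    """Binary potency call for one record at a given activity threshold.

    A record is potent when its activity exceeds the threshold. Activity
    exactly at the threshold is classed nonpotent (inclusive upper bound
    on the nonpotent side).
    """

    record_id: str
    label: Literal["potent", "nonpotent"]
    threshold: float = POTENCY_THRESHOLD

    @property
    def is_potent(self) -> bool:
        return self.label == "potent"


def label_potency(
    dataset: Dataset, threshold: float = POTENCY_THRESHOLD
) -> list[PotencyLabel]:
    """Label every record potent (activity > threshold) or nonpotent.

    Raises
    ------
    ValidationError
        If any record lacks an activity, naming that record.
    """
    labels: list[PotencyLabel] = []
    for rec in dataset:
        if rec.activity is None:
            raise ValidationError(f"record {rec.id!r} has no activity")
        lab = "potent" if rec.activity > threshold else "nonpotent"
        labels.append(PotencyLabel(rec.id, lab, threshold))
    return labels


_TSV_COLUMNS = ("id", "guide", "activity", "mrna_context")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".fa", ".fasta", ".fna"}:
        return "fasta"
    return "tsv"


def read_dataset(
    path: str | Path, format: str | None = None, name: str | None = None
) -> Dataset:
    """Read a dataset from FASTA (sequences only) or TSV (full records).

    The TSV layout is ``id<TAB>guide<TAB>activity<TAB>mrna_context`` with a
    header line; activity and mrna_context may be empty. Sequences are
    normalized (T->U, uppercase) on read.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if name is None:
        name = path.stem
    if fmt == "fasta":
        records = [
            SiRNARecord(id=sr.id, guide=str(sr.seq))
            for sr in SeqIO.parse(str(path), "fasta")
        ]
        return Dataset(records=records, name=name)
    if fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r} (expected 'fasta' or 'tsv')")

    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_TSV_COLUMNS)] != list(_TSV_COLUMNS):
            raise ValidationError(
                f"line 1: expected header {'	'.join(_TSV_COLUMNS)!r}, got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"line {lineno}: expected at least id and guide")
            parts += [""] * (len(_TSV_COLUMNS) - len(parts))
            rid, guide, activity, context = parts[:4]
            try:
                records.append(
                    SiRNARecord(
                        id=rid,
                        guide=guide,
                        activity=float(activity) if activity else None,
                        mrna_context=context or None,
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"line {lineno}: {exc}") from exc
    return Dataset(records=records, name=name)


def write_dataset(dataset: Dataset, path: str | Path, format: str = "tsv") -> None:
    """Write a dataset as TSV (full records) or FASTA (sequences only)."""
    path = Path(path)
    if format == "fasta":
        with open(path, "w") as fh:
            for rec in dataset:
                fh.write(f">{rec.id}\n{rec.guide}\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for rec in dataset:
            activity = "" if rec.activity is None else format_activity(rec.activity)
            context = rec.mrna_context or ""
            fh.write(f"{rec.id}\t{rec.guide}\t{activity}\t{context}\n")


def format_activity(a: float) -> str:
    """Canonical text form of an activity value (shortest round-trip repr)."""
    return repr(float(a))
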