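"""Feature extraction: the 230-dimensional mixed descriptor of an siRNA.

The vector concatenates, in fixed order:

* 39 positional categorical codes — one integer per dinucleotide window
  (positions 1..20) and trinucleotide window (positions 1..19) of the guide.
  A base is mapped to a digit (A=1, U=2, G=3, C=4) and a window of digits
  (f, s[, t]) to the mixed-radix code (f-1)*4 + s, resp.
  (f-1)*16 + (s-1)*4 + t, a bijection onto {1..16} / {1..64}.
* 2 thermodynamic stabilities of the guide paired with its perfect
  complement: the whole-duplex nearest-neighbor free energy (sum over the
  20 dinucleotide steps, Xia et al. 1998 parameters at 37 C, no initiation
  or terminal corrections) and the 5'-minus-3' difference of the terminal
  five-nucleotide windows (4 steps each). A positive difference means the
  5' end of the guide is the less stable end.
* 21 positional nucleotide representations, A/U/G/C digitized as
  0.1/0.2/0.3/0.4.
* 168 overlapping k-mer composition fractions (k = 1..3; 4 + 16 + 64 = 84
  motifs) of the guide and of the mRNA context, denominated by the window
  count L - k + 1 so each k-block sums to 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    GUIDE_LENGTH,
    Dataset,
    SiRNARecord,
    ValidationError,
    normalize_sequence,
    reverse_complement,
)

__all__ = [
    "BASE_DIGIT",
    "BASE_REPRESENTATION",
    "NearestNeighborTable",
    "FeatureVector",
    "encode_dinucleotide",
    "encode_trinucleotide",
    "decode_dinucleotide",
    "decode_trinucleotide",
    "extract_2_3NT",
    "delta_g_duplex",
    "delta_delta_g",
    "extract_representation",
    "extract_compositions",
    "build_feature_vector",
    "feature_matrix",
    "feature_names",
    "kmer_motifs",
    "N_FEATURES",
]

#: Digit assigned to each base in the categorical window codes.
BASE_DIGIT: Mapping[str, int] = {"A": 1, "U": 2, "G": 3, "C": 4}

#: Numeric representation of each base for the positional features.
BASE_REPRESENTATION: Mapping[str, float] = {"A": 0.1, "U": 0.2, "G": 0.3, "C": 0.4}

_TERMINAL_WINDOW_NT = 5  # five terminal nucleotides -> 4 nearest-neighbor steps

N_FEATURES = 230


class ConfigurationError(ValueError):
    """Raised when a lookup table or configuration is incomplete."""


def _digit(base: str) -> int:
    try:
        return BASE_DIGIT[base]
    except KeyError:
        raise ValidationError(f"invalid base {base!r} (expected A, C, G or U)")


def encode_dinucleotide(a: str, b: str) -> int:
    """Categorical code of an ordered base pair: (f-1)*4 + s, in {1..16}."""
    return (_digit(a) - 1) * 4 + _digit(b)


def encode_trinucleotide(a: str, b: str, c: str) -> int:
    """Categorical code of an ordered base triple: (f-1)*16 + (s-1)*4 + t."""
    return (_digit(a) - 1) * 16 + (_digit(b) - 1) * 4 + _digit(c)


_DIGIT_BASE = {v: k for k, v in BASE_DIGIT.items()}


def decode_dinucleotide(code: int) -> tuple[str, str]:
    """Inverse of :func:`encode_dinucleotide`."""
    if not 1 <= code <= 16:
        raise ValueError(f"dinucleotide code {code} outside 1..16")
    f, s = divmod(code - 1, 4)
    return _DIGIT_BASE[f + 1], _DIGIT_BASE[s + 1]


def decode_trinucleotide(code: int) -> tuple[str, str, str]:
    """Inverse of :func:`encode_trinucleotide`."""
    if not 1 <= code <= 64:
        raise ValueError(f"trinucleotide code {code} outside 1..64")
    f, rest = divmod(code - 1, 16)
    s, t = divmod(rest, 4)
    return _DIGIT_BASE[f + 1], _DIGIT_BASE[s + 1], _DIGIT_BASE[t + 1]


@dataclass(frozen=True)
class NearestNeighborTable:
    """Free-energy increment (kcal/mol, 37 C) for each RNA dinucleotide step.

    Keys are guide-strand steps 5'->3'; the guide is assumed paired with its
    perfect Watson-Crick complement, so all 16 ordered steps are present.
    """

    increments: Mapping[str, float]
    version: str = "custom"

    def __post_init__(self) -> None:
        missing = [
            a + b
            for a in BASE_DIGIT
            for b in BASE_DIGIT
            if a + b not in self.increments
        ]
        if missing:
            raise ConfigurationError(
                f"nearest-neighbor table {self.version!r} is missing steps: "
                + ", ".join(sorted(missing))
            )

    def __getitem__(self, step: str) -> float:
        return self.increments[step]

    @classmethod
    def from_tsv(cls, path: str | Path, version: str | None = None) -> "NearestNeighborTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        mapping = dict(zip(df["step"], df["dG37"].astype(float)))
        return cls(increments=mapping, version=version or Path(path).stem)

    @classmethod
    def default(cls) -> "NearestNeighborTable":
        """The Xia et al. (1998) Watson-Crick stacking parameters at 37 C."""
        ref = resources.files("sirnapred.data") / "xia1998_wc_stacking_dG37.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path, version="xia1998-v1")


def _check_guide(guide: str) -> str:
    guide = normalize_sequence(guide)
    if len(guide) != GUIDE_LENGTH:
        raise ValidationError(
            f"guide must be {GUIDE_LENGTH} nt, got {len(guide)}"
        )
    return guide


def extract_2_3NT(guide: str) -> dict[str, int]:
    """The 39 positional window codes: NT2_pos1..20 then NT3_pos1..19."""
    guide = _check_guide(guide)
    feats: dict[str, int] = {}
    for p in range(GUIDE_LENGTH - 1):
        feats[f"NT2_pos{p + 1}"] = encode_dinucleotide(guide[p], guide[p + 1])
    for p in range(GUIDE_LENGTH - 2):
        feats[f"NT3_pos{p + 1}"] = encode_trinucleotide(
            guide[p], guide[p + 1], guide[p + 2]
        )
    return feats


def delta_g_duplex(guide: str, table: NearestNeighborTable) -> float:
    """Whole-duplex stability: sum of the 20 nearest-neighbor step increments.

    The duplex is the guide paired with its perfect reverse complement; no
    helix-initiation, terminal-AU or self-complementarity corrections are
    applied — only the per-step stacking sum.
    """
    guide = _check_guide(guide)
    return _window_dg(guide, 0, GUIDE_LENGTH - 1, table)


def _window_dg(guide: str, start: int, n_steps: int, table: NearestNeighborTable) -> float:
    total = 0.0
    for i in range(start, start + n_steps):
        step = guide[i : i + 2]
        try:
            total += table[step]
        except KeyError:
            raise ConfigurationError(
                f"nearest-neighbor table has no entry for step {step!r}"
            )
    return total


def delta_delta_g(guide: str, table: NearestNeighborTable) -> float:
    """Terminal-asymmetry energy: dG(5' five-nt window) - dG(3' five-nt window).

    Each terminal window of five nucleotides spans four nearest-neighbor
    steps. Positive values mean the 5' end of the guide forms the less
    stable duplex terminus.
    """
    guide = _check_guide(guide)
    n_steps = _TERMINAL_WINDOW_NT - 1
    dg5 = _window_dg(guide, 0, n_steps, table)
    dg3 = _window_dg(guide, GUIDE_LENGTH - _TERMINAL_WINDOW_NT, n_steps, table)
    return dg5 - dg3


def extract_representation(guide: str) -> dict[str, float]:
    """Positional digitization POS1..POS21 (A=0.1, U=0.2, G=0.3, C=0.4)."""
    guide = _check_guide(guide)
    return {
        f"POS{i + 1}": BASE_REPRESENTATION[b] for i, b in enumerate(guide)
    }


def kmer_motifs(k: int) -> list[str]:
    """All 4**k RNA k-mers in lexicographic (A, C, G, U) order."""
    return ["".join(p) for p in itertools.product("ACGU", repeat=k)]


def extract_compositions(seq: str, kmax: int = 3, prefix: str = "") -> dict[str, float]:
    """Overlapping k-mer fractions for k = 1..kmax (84 features for kmax=3).

    Each motif's fraction is its window count divided by L - k + 1, so every
    k-block sums to exactly 1. Sequences shorter than kmax are rejected.
    """
    seq = normalize_sequence(seq)
    if len(seq) < kmax:
        raise ValidationError(
            f"sequence of length {len(seq)} too short for {kmax}-mer compositions"
        )
    feats: dict[str, float] = {}
    for k in range(1, kmax + 1):
        n_windows = len(seq) - k + 1
        counts = {m: 0 for m in kmer_motifs(k)}
        for i in range(n_windows):
            counts[seq[i : i + k]] += 1
        for motif, c in counts.items():
            feats[f"{prefix}{motif}"] = c / n_windows
    return feats


@dataclass(frozen=True)
class FeatureVector:
    """Named, ordered feature vector for one siRNA record."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names and values disagree in length")

    def __len__(self) -> int:
        return len(self.names)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def feature_names(include_mrna: bool = True) -> list[str]:
    """The fixed feature-name order the extractor emits."""
    names = [f"NT2_pos{p}" for p in range(1, GUIDE_LENGTH)]
    names += [f"NT3_pos{p}" for p in range(1, GUIDE_LENGTH - 1)]
    names += ["dG_duplex", "ddG"]
    names += [f"POS{i}" for i in range(1, GUIDE_LENGTH + 1)]
    names += [f"sirna_{m}" for k in (1, 2, 3) for m in kmer_motifs(k)]
    if include_mrna:
        names += [f"mrna_{m}" for k in (1, 2, 3) for m in kmer_motifs(k)]
    return names


def _window_context(rec: SiRNARecord, window: int) -> str:
    """Clip the mRNA context to +/- ``window`` nt around the target site.

    The target site is the first exact occurrence of the reverse complement
    of the guide in the context.
    """
    site = reverse_complement(rec.guide)
    assert rec.mrna_context is not None
    pos = rec.mrna_context.find(site)
    if pos < 0:
        raise ValidationError(
            f"record {rec.id!r}: target site not found in mRNA context; "
            "cannot window the context"
        )
    lo = max(0, pos - window)
    hi = min(len(rec.mrna_context), pos + len(site) + window)
    return rec.mrna_context[lo:hi]


def build_feature_vector(
    rec: SiRNARecord,
    table: NearestNeighborTable | None = None,
    *,
    include_mrna: bool = True,
    context_window: int | None = None,
) -> FeatureVector:
    """Assemble the full mixed feature vector for one record.

    Order: 39 window codes, 2 thermodynamic stabilities, 21 positional
    representations, 84 guide compositions, then (by default) 84 mRNA-context
    compositions — 230 features in total. With ``include_mrna=False`` the
    context block is dropped (146 features). ``context_window`` optionally
    restricts the context to that many nucleotides on each side of the
    target site before computing its compositions.
    """
    if table is None:
        table = NearestNeighborTable.default()
    feats: dict[str, float] = {}
    feats.update(extract_2_3NT(rec.guide))
    feats["dG_duplex"] = delta_g_duplex(rec.guide, table)
    feats["ddG"] = delta_delta_g(rec.guide, table)
    feats.update(extract_representation(rec.guide))
    feats.update(extract_compositions(rec.guide, prefix="sirna_"))
    if include_mrna:
        if rec.mrna_context is None:
            raise ValidationError(
                f"record {rec.id!r} has no mRNA context; pass include_mrna=False "
                "to build the guide-only vector"
            )
        context = (
            _window_context(rec, context_window)
            if context_window is not None
            else rec.mrna_context
        )
        feats.update(extract_compositions(context, prefix="mrna_"))
    names = tuple(feature_names(include_mrna=include_mrna))
    values = np.array([feats[n] for n in names], dtype=float)
    if include_mrna and len(names) != N_FEATURES:  # pragma: no cover
        raise AssertionError("feature layout drifted from 230 dimensions")
    return FeatureVector(names=names, values=values)


def feature_matrix(
    dataset: Dataset,
    table: NearestNeighborTable | None = None,
    *,
    include_mrna: bool = True,
    context_window: int | None = None,
) -> pd.DataFrame:
    """Feature vectors for a whole dataset as a DataFrame indexed by id."""
    if table is None:
        table = NearestNeighborTable.default()
    names = feature_names(include_mrna=include_mrna)
    rows = np.empty((len(dataset), len(names)), dtype=float)
    for i, rec in enumerate(dataset):
        rows[i] = build_feature_vector(
            rec, table, include_mrna=include_mrna, context_window=context_window
        ).values
    return pd.DataFrame(rows, index=dataset.ids(), columns=names)
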