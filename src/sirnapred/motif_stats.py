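"""Positional di-/trinucleotide enrichment between potent and nonpotent siRNAs.

For every guide position and every k-mer (k = 2 or 3), compare how often the
window at that position equals the motif in the potent versus the nonpotent
class. Significance is a two-sample Student's t-test on the per-record binary
occurrence indicator (pooled variance by default; Welch behind a flag), which
on binary data is algebraically the classic two-proportion pooled test with a
t rather than z reference distribution. Raw p-values are reported; an
optional Bonferroni correction is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import GUIDE_LENGTH, Dataset, PotencyLabel, ValidationError
from .features import kmer_motifs

__all__ = [
    "MotifEnrichmentRow",
    "positional_motif_counts",
    "motif_t_test",
    "enrichment_table",
    "enrichment_frame",
]


@dataclass(frozen=True)
class MotifEnrichmentRow:
    """One minimal-p motif at one position, in Table-style shape."""

    position: int
    motif: str
    count_potent: int
    n_potent: int
    count_nonpotent: int
    n_nonpotent: int
    corr_type: Literal["Positive", "Negative"]
    p_value: float


def positional_motif_counts(
    dataset: Dataset, labels: list[PotencyLabel], k: int
) -> pd.DataFrame:
    """Occurrence counts of every k-mer at every window position, per class.

    Returns a DataFrame with columns position (1-based), motif,
    count_potent, count_nonpotent. At each position the class counts sum to
    the class size (each record shows exactly one motif per window).
    """
    if k not in (2, 3):
        raise ValueError("window size k must be 2 or 3")
    if len(labels) != len(dataset):
        raise ValidationError("labels do not align with dataset records")
    motifs = kmer_motifs(k)
    motif_idx = {m: i for i, m in enumerate(motifs)}
    n_pos = GUIDE_LENGTH - k + 1
    counts = np.zeros((n_pos, len(motifs), 2), dtype=int)  # [pos, motif, class]
    for rec, lab in zip(dataset, labels):
        cls = 0 if lab.is_potent else 1
        for p in range(n_pos):
            counts[p, motif_idx[rec.guide[p : p + k]], cls] += 1
    rows = [
        (p + 1, m, counts[p, j, 0], counts[p, j, 1])
        for p in range(n_pos)
        for j, m in enumerate(motifs)
    ]
    return pd.DataFrame(
        rows, columns=["position", "motif", "count_potent", "count_nonpotent"]
    )


def motif_t_test(
    count_p: int,
    n_p: int,
    count_n: int,
    n_n: int,
    *,
    welch: bool = False,
) -> tuple[float, Literal["Positive", "Negative"] | None, bool]:
    """Student's t-test on per-record motif-occurrence indicators.

    Each record contributes a 0/1 indicator (its window equals the motif or
    not); the two classes of indicators are compared with a two-sided
    two-sample t-test, pooled-variance by default. Returns
    ``(p_value, corr_type, degenerate)`` where corr_type is "Positive" when
    the potent-class frequency is the larger one (None on an exact tie) and
    ``degenerate`` flags the zero-variance-in-both-groups case, for which
    the p-value is reported as 1.
    """
    if n_p < 2 or n_n < 2:
        raise ValueError("each class needs at least 2 records")
    if not (0 <= count_p <= n_p and 0 <= count_n <= n_n):
        raise ValueError("counts exceed class sizes")
    p1, p2 = count_p / n_p, count_n / n_n
    corr: Literal["Positive", "Negative"] | None
    corr = "Positive" if p1 > p2 else "Negative" if p1 < p2 else None
    # sum of squared deviations of a binary vector: n * p * (1 - p)
    ss1 = n_p * p1 * (1.0 - p1)
    ss2 = n_n * p2 * (1.0 - p2)
    if ss1 == 0.0 and ss2 == 0.0:
        if p1 == p2:
            return 1.0, corr, True
        return 0.0, corr, True  # disjoint constant groups: infinite t
    if welch:
        v1, v2 = ss1 / (n_p - 1) / n_p, ss2 / (n_n - 1) / n_n
        t = (p1 - p2) / math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (
            (v1**2 / (n_p - 1) if v1 else 0.0)
            + (v2**2 / (n_n - 1) if v2 else 0.0)
        )
    else:
        sp2 = (ss1 + ss2) / (n_p + n_n - 2)
        t = (p1 - p2) / math.sqrt(sp2 * (1.0 / n_p + 1.0 / n_n))
        df = n_p + n_n - 2
    p_value = 2.0 * stats.t.sf(abs(t), df)
    return min(p_value, 1.0), corr, False


def enrichment_table(
    dataset: Dataset,
    labels: list[PotencyLabel],
    k: int,
    alpha: float = 0.05,
    *,
    welch: bool = False,
    bonferroni: bool = False,
) -> list[MotifEnrichmentRow]:
    """Minimal-p positively and negatively enriched motif per position.

    For each window position, report the motif with the smallest p-value
    among those more frequent in potent records (corr_type Positive) and
    likewise for the nonpotent direction, keeping only p < alpha. Either
    row may be absent at a position. Ties on p are broken lexicographically
    by motif; rows are sorted by position, Positive before Negative.
    """
    counts = positional_motif_counts(dataset, labels, k)
    n_p = sum(1 for lab in labels if lab.is_potent)
    n_n = len(labels) - n_p
    n_tests = counts.shape[0] if bonferroni else 1
    rows: list[MotifEnrichmentRow] = []
    for position, grp in counts.groupby("position", sort=True):
        best: dict[str, MotifEnrichmentRow] = {}
        for _, r in grp.sort_values("motif").iterrows():
            p_val, corr, _ = motif_t_test(
                int(r.count_potent), n_p, int(r.count_nonpotent), n_n, welch=welch
            )
            if bonferroni:
                p_val = min(1.0, p_val * n_tests)
            if corr is None or p_val >= alpha:
                continue
            if corr not in best or p_val < best[corr].p_value:
                best[corr] = MotifEnrichmentRow(
                    position=int(position),
                    motif=str(r.motif),
                    count_potent=int(r.count_potent),
                    n_potent=n_p,
                    count_nonpotent=int(r.count_nonpotent),
                    n_nonpotent=n_n,
                    corr_type=corr,
                    p_value=p_val,
                )
        for corr in ("Positive", "Negative"):
            if corr in best:
                rows.append(best[corr])
    return rows


def enrichment_frame(rows: list[MotifEnrichmentRow]) -> pd.DataFrame:
    """Tabular form of an enrichment table, with count/classsize strings."""
    return pd.DataFrame(
        {
            "position": [r.position for r in rows],
            "motif": [r.motif for r in rows],
            "freq_potent": [f"{r.count_potent}/{r.n_potent}" for r in rows],
            "freq_nonpotent": [f"{r.count_nonpotent}/{r.n_nonpotent}" for r in rows],
            "count_potent": [r.count_potent for r in rows],
            "count_nonpotent": [r.count_nonpotent for r in rows],
            "corr_type": [r.corr_type for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )
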