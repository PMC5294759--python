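"""Synthetic siRNA datasets with known structure, for testing every stage.

Guides are drawn uniformly over {A, C, G, U}^21, each embedded (as its
reverse complement) in a longer random mRNA context so that guide and
context compositions are correlated but not identical. Activities follow a
logistic link: a linear predictor over a chosen set of (standardized)
feature columns plus Gaussian noise, squashed to (0, 1). Two optional
class-structured mechanisms support enrichment tests: a latent
potent/nonpotent class that shifts the linear predictor by
+/- ``class_separation``, and motif plants that overwrite a window of the
guide with a fixed motif, with some excess probability, in records of one
latent class only.

The default specification emulates the study conditions the predictor
assumes: ~500 records, ten informative features (thermodynamic, positional
and composition columns) with effect weight 0.8 on the standardized scale,
observation noise of 0.5 on the logit scale — strong but noisy sequence
determinants whose activities straddle the 0.7 potency cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_data import (
    GUIDE_LENGTH,
    Dataset,
    SiRNARecord,
    ValidationError,
    reverse_complement,
)
from .features import NearestNeighborTable, feature_matrix

__all__ = ["SimulationSpec", "simulate_dataset", "DEFAULT_PLANTED_FEATURES"]

_BASES = np.array(list("ACGU"))

#: Ten informative feature columns and their weights on the standardized scale.
DEFAULT_PLANTED_FEATURES: tuple[tuple[str, float], ...] = (
    ("dG_duplex", -0.8),
    ("ddG", 0.8),
    ("POS1", 0.8),
    ("POS10", -0.8),
    ("POS19", 0.8),
    ("sirna_UU", 0.8),
    ("sirna_GC", -0.8),
    ("sirna_AGA", 0.8),
    ("mrna_CUG", 0.8),
    ("mrna_GGG", -0.8),
)


@dataclass(frozen=True)
class SimulationSpec:
    """Recipe for one synthetic dataset.

    n_records : number of siRNA records.
    seed : root seed; the dataset is a pure function of the spec.
    planted_features : (feature name, weight) pairs entering the linear
        predictor; feature columns are standardized over the dataset first.
    noise_sd : Gaussian noise s.d. on the logit scale.
    motif_plants : (position, motif, class, excess_probability) tuples; in
        records of the named latent class ("potent"/"nonpotent"), the guide
        window at the 1-based position is overwritten with the motif with
        the given probability.
    context_length : length of the mRNA context embedding the target site.
    class_separation : logit shift of +/- this amount for the latent class
        (potent +, nonpotent -); a latent class is drawn Bernoulli(1/2) per
        record whenever this is nonzero or motif plants are present.
    """

    n_records: int = 500
    seed: int = 0
    planted_features: tuple[tuple[str, float], ...] = DEFAULT_PLANTED_FEATURES
    noise_sd: float = 0.5
    motif_plants: tuple[tuple[int, str, str, float], ...] = ()
    context_length: int = 60
    class_separation: float = 0.0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.context_length < GUIDE_LENGTH:
            raise ValueError(f"context_length must be >= {GUIDE_LENGTH}")
        for name, w in self.planted_features:
            if not np.isfinite(w):
                raise ValueError(f"non-finite weight for planted feature {name!r}")
        for pos, motif, cls, excess in self.motif_plants:
            if cls not in ("potent", "nonpotent"):
                raise ValueError(f"unknown plant class {cls!r}")
            if not 0.0 <= excess <= 1.0:
                raise ValueError(f"plant probability {excess} outside [0, 1]")
            if not 1 <= pos <= GUIDE_LENGTH - len(motif) + 1:
                raise ValueError(
                    f"plant {motif!r} at position {pos} does not fit a "
                    f"{GUIDE_LENGTH}-nt guide"
                )


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_dataset(
    spec: SimulationSpec, table: NearestNeighborTable | None = None
) -> Dataset:
    """Generate a dataset per the spec; byte-identical for equal specs."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records

    latent_potent = (
        rng.random(n) < 0.5
        if (spec.motif_plants or spec.class_separation != 0.0)
        else np.zeros(n, dtype=bool)
    )

    guides = rng.choice(_BASES, size=(n, GUIDE_LENGTH))
    for pos, motif, cls, excess in spec.motif_plants:
        in_class = latent_potent if cls == "potent" else ~latent_potent
        hit = in_class & (rng.random(n) < excess)
        for offset, base in enumerate(motif):
            guides[hit, pos - 1 + offset] = base
    guide_strs = ["".join(row) for row in guides]

    # Embed the perfect target site (reverse complement of the guide) at a
    # random offset inside a random context.
    flank_total = spec.context_length - GUIDE_LENGTH
    offsets = rng.integers(0, flank_total + 1, size=n)
    contexts = []
    for i, g in enumerate(guide_strs):
        flanks = "".join(rng.choice(_BASES, size=flank_total))
        off = int(offsets[i])
        contexts.append(flanks[:off] + reverse_complement(g) + flanks[off:])

    records = [
        SiRNARecord(id=f"SIM{i + 1:06d}", guide=g, mrna_context=c)
        for i, (g, c) in enumerate(zip(guide_strs, contexts))
    ]
    dataset = Dataset(records=records, name=spec.name)

    eta = np.zeros(n)
    if spec.planted_features:
        X = feature_matrix(dataset, table)
        for fname, w in spec.planted_features:
            if fname not in X.columns:
                raise ValidationError(f"unknown planted feature {fname!r}")
            col = X[fname].to_numpy()
            sd = col.std()
            if sd > 0:
                eta += w * (col - col.mean()) / sd
    if spec.class_separation != 0.0:
        eta += np.where(latent_potent, spec.class_separation, -spec.class_separation)
    if spec.noise_sd > 0:
        eta += rng.normal(0.0, spec.noise_sd, size=n)

    activities = np.clip(_logistic(eta), 0.0, 1.0)
    for rec, a in zip(records, activities):
        rec.activity = float(a)
    return dataset
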