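"""Deterministic synthetic-MSA generator with planted column classes.

The generator emulates the structure a subfamily analysis must recover —
not real evolution.  Sequences belong to ``n_subfamilies`` planted
subfamilies; each column is one of four classes:

- ``conserved``: one residue in every sequence,
- ``subfamily_specific``: one residue per subfamily, drawn without
  replacement so subfamilies are maximally discriminative,
- ``random``: i.i.d. uniform over the 20 residues,
- ``gappy``: like random, but each cell becomes a gap with
  ``gap_probability``.

Independent per-cell substitution noise (uniform over the 19 other
residues) is applied afterwards.  Everything is drawn from one seeded
generator, so the same spec yields byte-identical FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._alphabet import STANDARD_RESIDUES
from .msa_io import Alignment

__all__ = ["FixtureSpec", "generate_msa", "default_spec"]

CLASSES = ("conserved", "subfamily_specific", "random", "gappy")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic alignment."""

    n_subfamilies: int = 4
    sequences_per_subfamily: int = 8
    column_classes: tuple[str, ...] = ()
    substitution_noise: float = 0.0
    gap_probability: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subfamilies * self.sequences_per_subfamily < 2:
            raise ValueError("need at least 2 sequences in total")
        bad = [c for c in self.column_classes if c not in CLASSES]
        if bad:
            raise ValueError(f"unknown column classes: {sorted(set(bad))}")
        if not 0 <= self.substitution_noise <= 1:
            raise ValueError("substitution_noise must be in [0, 1]")
        if not 0 <= self.gap_probability <= 1:
            raise ValueError("gap_probability must be in [0, 1]")

    @property
    def n_sequences(self) -> int:
        return self.n_subfamilies * self.sequences_per_subfamily

    @property
    def n_columns(self) -> int:
        return len(self.column_classes)


def default_spec(seed: int = 0, noise: float = 0.0) -> FixtureSpec:
    """The standard validation design: 4 subfamilies x 8 sequences,
    100 columns (10 conserved, 10 subfamily-specific, 80 random)."""
    return FixtureSpec(
        n_subfamilies=4,
        sequences_per_subfamily=8,
        column_classes=("conserved",) * 10
        + ("subfamily_specific",) * 10
        + ("random",) * 80,
        substitution_noise=noise,
        seed=seed,
    )


def generate_msa(spec: FixtureSpec) -> tuple[Alignment, pd.DataFrame]:
    """Generate the alignment and its ground-truth table.

    The ground truth records, per column (1-based), its class and the
    planted residues ("" for random/gappy columns; per-subfamily
    comma-joined for specific columns).
    """
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_sequences, spec.n_columns
    if L == 0:
        raise ValueError("column_classes must not be empty")
    subfamily = np.repeat(np.arange(spec.n_subfamilies), spec.sequences_per_subfamily)
    codes = np.zeros((n, L), dtype=np.int8)
    truth_rows = []
    for c, cls in enumerate(spec.column_classes):
        if cls == "conserved":
            aa = int(rng.integers(20))
            codes[:, c] = aa
            planted = STANDARD_RESIDUES[aa]
        elif cls == "subfamily_specific":
            if spec.n_subfamilies > 20:
                raise ValueError("subfamily_specific needs n_subfamilies <= 20")
            aas = rng.choice(20, size=spec.n_subfamilies, replace=False)
            codes[:, c] = aas[subfamily]
            planted = ",".join(STANDARD_RESIDUES[a] for a in aas)
        else:  # random / gappy
            codes[:, c] = rng.integers(20, size=n)
            planted = ""
        truth_rows.append({"column": c + 1, "class": cls, "planted": planted})

    if spec.substitution_noise > 0:
        hit = rng.random((n, L)) < spec.substitution_noise
        # substitute with a uniformly drawn *different* residue
        shift = rng.integers(1, 20, size=(n, L))
        codes = np.where(hit, (codes + shift) % 20, codes).astype(np.int8)

    gap_cols = [c for c, cls in enumerate(spec.column_classes) if cls == "gappy"]
    gap_mask = np.zeros((n, L), dtype=bool)
    if gap_cols:
        gap_mask[:, gap_cols] = rng.random((n, len(gap_cols))) < spec.gap_probability

    seqs = []
    for i in range(n):
        chars = [STANDARD_RESIDUES[c] for c in codes[i]]
        for c in np.nonzero(gap_mask[i])[0]:
            chars[c] = "-"
        seqs.append("".join(chars))
    ids = tuple(
        f"SF{subfamily[i] + 1}_seq{i % spec.sequences_per_subfamily + 1}"
        for i in range(n)
    )
    truth = pd.DataFrame(truth_rows)
    aln = Alignment(ids=ids, sequences=tuple(seqs))
    return aln, truth
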