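"""Shannon-entropy profiles: global, per-partition-level, and the TEA-O average.

Two-Entropies Analysis contrasts, for every alignment column, the entropy of
the pooled residue distribution (H_global) with the entropy left *within*
subfamilies.  The objective ("-O") variant removes the user's choice of
subfamilies by averaging the within-subgroup entropy over every partition
level cut from the UPGMA tree:

    H_level[k][c] = sum_g (n_g / N) * H(column c restricted to subgroup g)
    H_avg[c]      = mean over k = 1..N of H_level[k][c]

Size-weighted within-level averaging makes H_level (and hence H_avg) never
exceed H_global — a concavity property of Shannon entropy — so the gap
H_global - H_avg is the entropy the subgrouping explains.  The scores are

    conservation[c] = 1 - H_global[c] / log2(20)
    specificity[c]  = (H_global[c] - H_avg[c]) / (H_global[c] + h0)

with smoothing h0 = 0.5 bits by default.  The specificity score is the
*fraction* of the column's entropy explained by subgrouping rather than the
raw normalised difference: raw differences rank uniformly variable columns
(large H_global, moderate H_avg) above genuinely subfamily-specific ones
(H_global capped at log2 of the subfamily count, H_avg near zero).  The
plain fraction, in turn, is unstable for near-conserved columns whose tiny
entropy is trivially "explained"; the h0 pseudo-entropy in the denominator
damps columns carrying less variation than a single 50/50 substitution.

Columns conserved within subfamilies but different between them ("specificity
determining") have high H_global and low H_avg.  Entropies are in bits; gaps
and ambiguity codes are excluded from the distributions (``gap_as_symbol``
switches gaps into the alphabet for comparison).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._alphabet import AMBIGUOUS_CODE, GAP_CODE
from .msa_io import Alignment, PositionMap, ResidueCounts
from .tree import PartitionSet

__all__ = [
    "EntropyProfile",
    "MAX_ENTROPY",
    "shannon_entropy",
    "global_profile",
    "level_average_profile",
    "teao_profile",
    "profile_table",
]

MAX_ENTROPY: float = float(np.log2(20.0))


@dataclass(frozen=True)
class EntropyProfile:
    """Per-column entropy results for one alignment.

    All arrays have length ``n_columns`` except ``H_level`` which is
    (n_levels, n_columns), row k-1 holding the level-k subgroup-averaged
    entropy.  ``low_support`` flags columns where at most one residue
    contributed to the global distribution (entropy fixed at 0 there).
    """

    n_columns: int
    H_global: np.ndarray
    H_level: np.ndarray
    H_avg: np.ndarray
    conservation: np.ndarray
    specificity: np.ndarray
    gap_fraction: np.ndarray
    n_distinct: np.ndarray
    low_support: np.ndarray


def _column_count_matrix(codes: np.ndarray, gap_as_symbol: bool) -> np.ndarray:
    """(n_columns, n_symbols) residue counts for a block of sequences."""
    n_sym = 21 if gap_as_symbol else 20
    L = codes.shape[1]
    counts = np.zeros((L, n_sym), dtype=np.int64)
    mask = codes < n_sym  # codes are 0..19 residues, 20 gap, 21 ambiguity
    cidx = np.broadcast_to(np.arange(L), codes.shape)[mask]
    np.add.at(counts, (cidx, codes[mask].astype(np.int64)), 1)
    return counts


def _entropy_from_counts(counts: np.ndarray) -> np.ndarray:
    """Shannon entropy (bits) of each row of a count matrix; rows with
    total <= 1 give 0."""
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / np.maximum(totals, 1)
        terms = np.where(counts > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    h = terms.sum(axis=1)
    h[totals[:, 0] <= 1] = 0.0
    return h


def shannon_entropy(counts: ResidueCounts | dict[str, int]) -> float:
    """Shannon entropy in bits of one column's residue distribution.

    H = -sum_a p_a log2 p_a over residues with count > 0, where p_a is the
    count fraction among standard residues (gaps/ambiguity excluded).
    Returns 0.0 when one or zero residues are observed.
    """
    mapping = counts.counts if isinstance(counts, ResidueCounts) else counts
    vec = np.array([v for v in mapping.values() if v > 0], dtype=float)
    total = vec.sum()
    if total <= 1:
        return 0.0
    p = vec / total
    return float(-(p * np.log2(p)).sum())


def global_profile(aln: Alignment, gap_as_symbol: bool = False) -> np.ndarray:
    """Per-column Shannon entropy (bits) over the whole alignment."""
    return _entropy_from_counts(_column_count_matrix(aln.codes, gap_as_symbol))


def level_average_profile(
    aln: Alignment, partition: dict[str, int], gap_as_symbol: bool = False
) -> np.ndarray:
    """Size-weighted mean of within-subgroup entropies at one level.

    ``partition`` maps every alignment identifier to its subgroup index.
    """
    if set(partition) != set(aln.ids):
        missing = set(aln.ids) ^ set(partition)
        raise ValueError(
            f"partition and alignment identifiers differ: {sorted(missing)[:5]}"
        )
    n = aln.n_sequences
    out = np.zeros(aln.n_columns)
    for g in sorted(set(partition.values())):
        rows = [i for i, ident in enumerate(aln.ids) if partition[ident] == g]
        counts = _column_count_matrix(aln.codes[rows], gap_as_symbol)
        out += (len(rows) / n) * _entropy_from_counts(counts)
    return out


def teao_profile(
    aln: Alignment,
    partitions: PartitionSet,
    gap_as_symbol: bool = False,
    levels: str = "all",
    specificity_smoothing: float = 0.5,
) -> EntropyProfile:
    """Full TEA-O profile: H_global, per-level averages, H_avg and scores.

    Parameters
    ----------
    levels : {"all", "inner"}
        "all" averages over k = 1..N; "inner" over k = 2..N-1 (drops the
        trivial single-group and singleton partitions) for comparison with
        implementations that cut only between merges.
    specificity_smoothing : float
        Pseudo-entropy h0 (bits) in the specificity denominator
        ``(H_global - H_avg) / (H_global + h0)``; damps low-entropy
        columns.  Must be > 0.
    """
    if specificity_smoothing <= 0:
        raise ValueError("specificity_smoothing must be > 0")
    if tuple(sorted(partitions.labels)) != tuple(sorted(aln.ids)):
        raise ValueError("partition set was built on a different alignment")
    n = aln.n_sequences
    L = aln.n_columns
    label_to_row = {ident: i for i, ident in enumerate(aln.ids)}

    # Along the refinement chain the same subgroup recurs at consecutive
    # levels, so each of the (at most 2N-1) distinct subgroups is scored
    # once and cached.
    level_h = np.zeros((n, L))
    group_cache: dict[frozenset[int], np.ndarray] = {}

    def group_entropy(rows: frozenset[int]) -> np.ndarray:
        cached = group_cache.get(rows)
        if cached is not None:
            return cached
        counts = _column_count_matrix(aln.codes[sorted(rows)], gap_as_symbol)
        h = _entropy_from_counts(counts)
        group_cache[rows] = h
        return h

    for k in range(1, n + 1):
        assignment = partitions.levels[k]
        groups: dict[int, set[int]] = {}
        for ident, g in assignment.items():
            groups.setdefault(g, set()).add(label_to_row[ident])
        total = np.zeros(L)
        for rows in groups.values():
            fs = frozenset(rows)
            total += (len(fs) / n) * group_entropy(fs)
        level_h[k - 1] = total

    H_global = level_h[0].copy()
    if levels == "inner" and n > 2:
        H_avg = level_h[1 : n - 1].mean(axis=0)
    else:
        H_avg = level_h.mean(axis=0)

    counts_all = _column_count_matrix(aln.codes, gap_as_symbol=False)
    n_distinct = (counts_all > 0).sum(axis=1)
    totals = counts_all.sum(axis=1)
    gap_fraction = np.array(
        [np.mean(aln.codes[:, c] == GAP_CODE) for c in range(L)]
    )
    return EntropyProfile(
        n_columns=L,
        H_global=H_global,
        H_level=level_h,
        H_avg=H_avg,
        conservation=1.0 - H_global / MAX_ENTROPY,
        specificity=(H_global - H_avg) / (H_global + specificity_smoothing),
        gap_fraction=gap_fraction,
        n_distinct=n_distinct,
        low_support=totals <= 1,
    )


def profile_table(
    profile: EntropyProfile,
    position_map: PositionMap | None = None,
) -> pd.DataFrame:
    """One row per alignment column: positions, entropies, scores, flags."""
    cols = np.arange(1, profile.n_columns + 1)
    ref = (
        position_map.column_to_residue
        if position_map is not None
        else np.zeros(profile.n_columns, dtype=int)
    )
    df = pd.DataFrame(
        {
            "column": cols,
            "reference_residue": [int(r) if r else pd.NA for r in ref],
            "H_global": profile.H_global,
            "H_avg": profile.H_avg,
            "conservation": profile.conservation,
            "specificity": profile.specificity,
            "gap_fraction": profile.gap_fraction,
            "n_distinct": profile.n_distinct,
            "low_support": profile.low_support.astype(int),
        }
    )
    return df
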