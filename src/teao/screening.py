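"""Screen alignment positions for candidate specificity / rheostat residues.

A rheostat position tolerates many different substitutions, each nudging
function up or down rather than switching it off; in an MSA such positions
show high entropy and a wide repertoire of residues.  The screen keeps
reference-mapped columns that (i) carry at least ``min_distinct_residues``
distinct standard residues, (ii) exceed an entropy threshold (absolute bits
or a quantile of the profile), (iii) sit away from the alignment termini,
and (iv) are not on a user-supplied exclusion list (catalytic or
substrate-binding residues are domain knowledge, not computed).  Failing
rows are kept with their failure reasons so the table is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .entropy import EntropyProfile
from .msa_io import Alignment, PositionMap, column_composition
from .property_scores import PropertyProfile

__all__ = ["ScreenConfig", "screen_positions", "read_exclusion_list"]


@dataclass(frozen=True)
class ScreenConfig:
    """Screening criteria.

    entropy_threshold: float bits when ``threshold_is_quantile`` is False,
    else a quantile in [0, 1] of the chosen metric over reference-mapped
    columns (default: top quartile of H_global).
    """

    min_distinct_residues: int = 10
    entropy_metric: str = "global"  # "global" or "specificity"
    entropy_threshold: float = 0.75
    threshold_is_quantile: bool = True
    terminal_exclusion: int = 10
    exclusion_positions: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 1 <= self.min_distinct_residues <= 20:
            raise ValueError("min_distinct_residues must be in 1..20")
        if self.terminal_exclusion < 0:
            raise ValueError("terminal_exclusion must be >= 0")
        if self.entropy_metric not in ("global", "specificity"):
            raise ValueError("entropy_metric must be 'global' or 'specificity'")


def read_exclusion_list(path: str | Path) -> tuple[int, ...]:
    """Plain-text reference residue numbers, one per line or ranges "a-b"."""
    out: list[int] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#")[0].strip()
        if not line:
            continue
        if "-" in line:
            a, b = line.split("-", 1)
            out.extend(range(int(a), int(b) + 1))
        else:
            out.append(int(line))
    return tuple(out)


def screen_positions(
    aln: Alignment,
    profile: EntropyProfile,
    position_map: PositionMap,
    cfg: ScreenConfig = ScreenConfig(),
    property_profile: PropertyProfile | None = None,
) -> pd.DataFrame:
    """Build the candidate table over reference-mapped columns.

    Returns one row per mapped column with scores, criterion pass flags,
    an overall ``passed`` flag and a ``fail_reasons`` string; sorted by the
    chosen entropy metric descending, ties by reference position ascending.
    """
    n_ref = position_map.n_mapped
    bad = [p for p in cfg.exclusion_positions if not 1 <= p <= max(n_ref, 1)]
    if bad:
        raise IndexError(
            f"exclusion positions outside reference range 1..{n_ref}: {bad}"
        )
    metric = profile.H_global if cfg.entropy_metric == "global" else profile.specificity
    mapped_cols = position_map.residue_to_column  # 1-based
    if cfg.threshold_is_quantile:
        threshold = float(np.quantile(metric[mapped_cols - 1], cfg.entropy_threshold))
    else:
        threshold = cfg.entropy_threshold

    excl = set(cfg.exclusion_positions)
    rows = []
    for res in range(1, n_ref + 1):
        col = position_map.column_of(res)
        comp = column_composition(aln, col)
        m = float(metric[col - 1])
        ok_distinct = comp.n_distinct >= cfg.min_distinct_residues
        ok_entropy = m >= threshold
        ok_terminal = (
            cfg.terminal_exclusion < res <= n_ref - cfg.terminal_exclusion
        )
        ok_excl = res not in excl
        reasons = []
        if not ok_distinct:
            reasons.append("too_few_distinct")
        if not ok_entropy:
            reasons.append("low_entropy")
        if not ok_terminal:
            reasons.append("terminal")
        if not ok_excl:
            reasons.append("excluded")
        row = {
            "reference_residue": res,
            "column": col,
            "H_global": float(profile.H_global[col - 1]),
            "H_avg": float(profile.H_avg[col - 1]),
            "specificity": float(profile.specificity[col - 1]),
            "n_distinct": comp.n_distinct,
            "residues": ",".join(
                f"{aa}:{c}" for aa, c in sorted(comp.counts.items())
            ),
            "pass_distinct": ok_distinct,
            "pass_entropy": ok_entropy,
            "pass_terminal": ok_terminal,
            "pass_exclusion": ok_excl,
            "passed": ok_distinct and ok_entropy and ok_terminal and ok_excl,
            "fail_reasons": ";".join(reasons),
        }
        if property_profile is not None:
            for d, nm in enumerate(property_profile.descriptor_names):
                row[f"sd_{nm}"] = float(property_profile.sd[col - 1, d])
        rows.append(row)
    df = pd.DataFrame(rows)
    sort_key = "H_global" if cfg.entropy_metric == "global" else "specificity"
    df = df.sort_values(
        [sort_key, "reference_residue"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df
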