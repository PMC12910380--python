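"""Physicochemical variability profiles from per-residue descriptor tables.

Shannon entropy treats residues as interchangeable symbols; a column where
I/L/V alternate scores the same as one mixing D/K/W.  Z-scales — principal
components of a large panel of experimental amino-acid properties — restore
that information: z1 tracks lipophilicity, z2 steric bulk/polarizability,
z3 polarity/charge.  For every alignment column we report the standard
deviation of each descriptor over the residues actually observed there
(one contribution per sequence), so columns whose variants differ in kind,
not just in identity, stand out.

Custom descriptor tables (any number of numeric columns, one row per
residue) plug into the same profile machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ._alphabet import GAP_CODE, STANDARD_RESIDUES
from .msa_io import Alignment

__all__ = [
    "PropertyTable",
    "PropertyProfile",
    "builtin_zscales",
    "property_sd_profile",
    "load_custom_table",
    "write_table",
]


@dataclass(frozen=True)
class PropertyTable:
    """Descriptor values for each of the 20 standard residues.

    ``values[residue]`` is a length-D vector aligned with
    ``descriptor_names``.
    """

    name: str
    values: dict[str, np.ndarray]
    descriptor_names: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = sorted(set(STANDARD_RESIDUES) - set(self.values))
        extra = sorted(set(self.values) - set(STANDARD_RESIDUES))
        if missing:
            raise ValueError(f"table {self.name!r} missing residues: {missing}")
        if extra:
            raise ValueError(f"table {self.name!r} has non-standard rows: {extra}")
        d = len(self.descriptor_names)
        for res, vec in self.values.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (d,):
                raise ValueError(f"residue {res}: expected {d} values, got {vec.shape}")
            if not np.isfinite(vec).all():
                raise ValueError(f"residue {res}: non-finite descriptor value")

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def as_matrix(self) -> np.ndarray:
        """(20, D) matrix in standard residue (alphabetical) order."""
        return np.vstack([self.values[aa] for aa in STANDARD_RESIDUES])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.as_matrix(),
            index=pd.Index(list(STANDARD_RESIDUES), name="residue"),
            columns=list(self.descriptor_names),
        )


@dataclass(frozen=True)
class PropertyProfile:
    """Per-column descriptor standard deviations.

    ``sd`` has shape (n_columns, D); columns with fewer than two scored
    residues carry 0 and are flagged in ``low_support``.
    """

    descriptor_names: tuple[str, ...]
    sd: np.ndarray
    low_support: np.ndarray


def builtin_zscales() -> PropertyTable:
    """The packaged 3-component z-scale table (z1-z3; scales 4-5 omitted
    as low-variance and hard to interpret)."""
    with resources.files("teao.data").joinpath("zscales.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return PropertyTable(
        name="zscales-1998-z1z2z3",
        values={row.residue: np.array([row.z1, row.z2, row.z3]) for row in df.itertuples()},
        descriptor_names=("z1", "z2", "z3"),
    )


def load_custom_table(path: str | Path, name: str | None = None) -> PropertyTable:
    """Read a user descriptor table (TSV or CSV, header row required).

    First column: residue one-letter codes, exactly the 20 standard amino
    acids; remaining columns: numeric descriptors.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a residue column plus >=1 descriptor column")
    residues = df.iloc[:, 0].astype(str).str.strip().str.upper()
    dup = residues[residues.duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate residue rows: {dup}")
    desc = df.columns[1:].tolist()
    numeric = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-numeric value at row {r + 2}, column {desc[c]!r}"
        )
    values = {
        res: numeric.iloc[i].to_numpy(dtype=float) for i, res in enumerate(residues)
    }
    return PropertyTable(
        name=name or path.stem, values=values, descriptor_names=tuple(desc)
    )


def write_table(table: PropertyTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t")


def property_sd_profile(
    aln: Alignment,
    table: PropertyTable | None = None,
    weighted: bool = True,
    ddof: int = 0,
) -> PropertyProfile:
    """Per-column, per-descriptor standard deviation of property values.

    Parameters
    ----------
    weighted : bool
        True (default): every sequence's residue contributes one
        observation (occurrence-weighted).  False: each distinct residue
        present contributes once, regardless of frequency.
    ddof : int
        0 (default) for the population SD — the column's residues are the
        whole population of interest — or 1 for the sample SD.

    Gaps and ambiguity codes contribute nothing; columns with fewer than
    two scored observations get SD 0 and a low-support flag.
    """
    if table is None:
        table = builtin_zscales()
    codes = aln.codes
    L = aln.n_columns
    D = table.n_descriptors
    values = table.as_matrix()  # (20, D), standard residue order
    sd = np.zeros((L, D))
    low = np.zeros(L, dtype=bool)
    for c in range(L):
        col = codes[:, c]
        obs = col[col < GAP_CODE]
        if not weighted:
            obs = np.unique(obs)
        if obs.size < 2:
            low[c] = True
            continue
        v = values[obs]
        sd[c] = v.std(axis=0, ddof=ddof)
        sd[c, v.max(axis=0) == v.min(axis=0)] = 0.0  # exact 0 when constant
    return PropertyProfile(
        descriptor_names=table.descriptor_names, sd=sd, low_support=low
    )
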