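"""Taxonomic annotation and filtering from local NCBI-style dump files.

Reads the three standard dump dialects — a tab-separated
``accession2taxid`` table, and the ``"\\t|\\t"``-delimited ``nodes.dmp`` /
``names.dmp`` — entirely offline, reconstructs root-to-leaf lineages, and
filters an alignment to (or away from) a clade.  Accessions are pulled out
of FASTA identifiers with a configurable extractor; the default understands
UniProt-style ``db|ACC|name`` headers and bare accessions, with trailing
version suffixes (".1") stripped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .msa_io import Alignment

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonomyStore",
    "LineageAnnotation",
    "load_store",
    "annotate",
    "filter_by_taxon",
    "default_accession_extractor",
]

MAX_LINEAGE_DEPTH = 100


class TaxonomyCycleError(ValueError):
    """Parent walk failed to reach the root within the depth bound."""


class TaxonomyFormatError(ValueError):
    """Too many malformed lines in a dump file."""


@dataclass(frozen=True)
class TaxonomyStore:
    """In-memory slice of the NCBI taxonomy."""

    accession_to_taxid: dict[str, int]
    parent: dict[int, int]
    rank: dict[int, str]
    name: dict[int, str]

    def lineage(self, taxid: int) -> list[tuple[int, str, str]]:
        """Root-to-leaf chain of (taxid, rank, name); cycle-guarded."""
        chain: list[int] = []
        t = taxid
        for _ in range(MAX_LINEAGE_DEPTH):
            chain.append(t)
            p = self.parent.get(t)
            if p is None:
                raise KeyError(f"taxid {t} has no parent entry")
            if p == t:  # root convention: parent of root is itself
                break
            t = p
        else:
            raise TaxonomyCycleError(
                f"lineage of taxid {taxid} did not reach the root within "
                f"{MAX_LINEAGE_DEPTH} steps (cycle?)"
            )
        chain.reverse()
        return [
            (t, self.rank.get(t, "no rank"), self.name.get(t, str(t))) for t in chain
        ]

    def resolve(self, taxon: int | str) -> int:
        """Accept a taxid or a scientific name; return the taxid."""
        if isinstance(taxon, int) or (isinstance(taxon, str) and taxon.isdigit()):
            t = int(taxon)
            if t not in self.parent:
                raise KeyError(f"taxid {t} not in store")
            return t
        matches = [t for t, nm in self.name.items() if nm == taxon]
        if not matches:
            raise KeyError(f"taxon name {taxon!r} not in store")
        if len(matches) > 1:
            raise KeyError(f"taxon name {taxon!r} is ambiguous: taxids {matches}")
        return matches[0]


@dataclass(frozen=True)
class LineageAnnotation:
    """Per-identifier lineage; identifiers that could not be mapped are
    listed, never dropped."""

    lineages: dict[str, tuple[int, list[tuple[int, str, str]]]]
    unmapped: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ident, (taxid, lin) in self.lineages.items():
            rows.append(
                {
                    "identifier": ident,
                    "taxid": taxid,
                    "lineage": ";".join(nm for _, _, nm in lin),
                }
            )
        for ident in self.unmapped:
            rows.append({"identifier": ident, "taxid": pd.NA, "lineage": pd.NA})
        return pd.DataFrame(rows, columns=["identifier", "taxid", "lineage"])


def _strip_version(acc: str) -> str:
    return re.sub(r"\.\d+$", "", acc)


def default_accession_extractor(identifier: str) -> str:
    """UniProt-style ``db|ACC|name`` middle field, else the identifier
    itself; version suffix stripped either way."""
    parts = identifier.split("|")
    acc = parts[1] if len(parts) >= 3 and parts[1] else identifier
    return _strip_version(acc)


def load_store(
    accession2taxid_path: str | Path,
    nodes_path: str | Path,
    names_path: str | Path,
    max_malformed_fraction: float = 0.1,
) -> TaxonomyStore:
    """Parse the three NCBI dump files into a :class:`TaxonomyStore`.

    Malformed lines are counted and logged; parsing fails only when more
    than ``max_malformed_fraction`` of a file's lines are bad.
    """
    acc2tax: dict[str, int] = {}
    bad = 0
    lines = Path(accession2taxid_path).read_text().splitlines()
    for i, line in enumerate(lines):
        fields = line.rstrip("\n").split("\t")
        if i == 0 and fields and fields[0].lower().startswith("accession"):
            continue  # header
        # dialect: accession, accession.version, taxid, gi  (>=3 cols used)
        if len(fields) >= 3 and fields[2].strip().isdigit():
            acc2tax[_strip_version(fields[0].strip())] = int(fields[2])
            if fields[1].strip():
                acc2tax.setdefault(_strip_version(fields[1].strip()), int(fields[2]))
        elif len(fields) == 2 and fields[1].strip().isdigit():
            acc2tax[_strip_version(fields[0].strip())] = int(fields[1])
        elif line.strip():
            bad += 1
    _check_malformed(bad, len(lines), accession2taxid_path, max_malformed_fraction)

    parent: dict[int, int] = {}
    rank: dict[int, str] = {}
    bad = 0
    lines = Path(nodes_path).read_text().splitlines()
    for line in lines:
        fields = [f.strip() for f in line.rstrip("|\n").split("\t|\t")]
        if len(fields) >= 3 and fields[0].isdigit() and fields[1].isdigit():
            t = int(fields[0])
            parent[t] = int(fields[1])
            rank[t] = fields[2].rstrip("\t|").strip()
        elif line.strip():
            bad += 1
    _check_malformed(bad, len(lines), nodes_path, max_malformed_fraction)

    name: dict[int, str] = {}
    bad = 0
    lines = Path(names_path).read_text().splitlines()
    for line in lines:
        fields = [f.strip().rstrip("\t|").strip() for f in line.split("\t|\t")]
        if len(fields) >= 4 and fields[0].isdigit():
            if fields[3] == "scientific name":
                name[int(fields[0])] = fields[1]
        elif line.strip():
            bad += 1
    _check_malformed(bad, len(lines), names_path, max_malformed_fraction)

    store = TaxonomyStore(
        accession_to_taxid=acc2tax, parent=parent, rank=rank, name=name
    )
    # validate lineage walks up-front so cycles fail fast
    for t in parent:
        store.lineage(t)
    return store


def _check_malformed(bad: int, total: int, path, threshold: float) -> None:
    if total and bad / total > threshold:
        raise TaxonomyFormatError(
            f"{path}: {bad}/{total} malformed lines exceeds threshold {threshold}"
        )
    if bad:
        logger.warning("%s: skipped %d malformed line(s)", path, bad)


def annotate(
    aln: Alignment,
    store: TaxonomyStore,
    accession_extractor=default_accession_extractor,
) -> LineageAnnotation:
    """Attach a taxonomic lineage to every alignment identifier possible."""
    lineages: dict[str, tuple[int, list[tuple[int, str, str]]]] = {}
    unmapped: list[str] = []
    for ident in aln.ids:
        acc = accession_extractor(ident)
        taxid = store.accession_to_taxid.get(acc)
        if taxid is None or taxid not in store.parent:
            unmapped.append(ident)
            continue
        lineages[ident] = (taxid, store.lineage(taxid))
    if unmapped:
        logger.info("%d identifier(s) had no taxonomy mapping", len(unmapped))
    return LineageAnnotation(lineages=lineages, unmapped=unmapped)


def filter_by_taxon(
    aln: Alignment,
    ann: LineageAnnotation,
    store: TaxonomyStore,
    include: int | str,
    exclude: int | str | None = None,
    keep_unmapped: bool = False,
) -> Alignment:
    """Keep sequences whose lineage passes through ``include`` (and not
    ``exclude``); original order preserved; at least 2 must survive."""
    include_id = store.resolve(include)
    exclude_id = store.resolve(exclude) if exclude is not None else None
    keep: list[str] = []
    for ident in aln.ids:
        entry = ann.lineages.get(ident)
        if entry is None:
            if keep_unmapped:
                keep.append(ident)
            continue
        taxids = {t for t, _, _ in entry[1]}
        if include_id in taxids and (exclude_id is None or exclude_id not in taxids):
            keep.append(ident)
    return aln.subset(keep)
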