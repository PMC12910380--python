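"""One-shot analysis run: MSA -> tree -> profiles -> screening -> figures.

:class:`RunConfig` holds every knob; :func:`run` executes the whole chain
deterministically (no step consumes randomness) and writes the full output
set — Newick tree, per-position profile TSV, candidate table, figure plus
sidecar data tables, the resolved config and a log — into one directory.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .entropy import profile_table, teao_profile
from .msa_io import map_reference_positions, read_msa, write_msa
from .property_scores import builtin_zscales, load_custom_table, property_sd_profile
from .screening import ScreenConfig, read_exclusion_list, screen_positions
from .taxonomy import annotate, filter_by_taxon, load_store
from .tree import pairwise_distance, tree_levels, upgma, write_newick
from .viz import DEFAULT_PANELS, FigureSpec, render_overview

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """Flat, file-round-trippable configuration of one pipeline run."""

    input: str = ""
    output_dir: str = "teao_out"
    reference_id: str | None = None
    gap_as_symbol: bool = False
    levels: str = "all"  # "all" (k=1..N) or "inner" (k=2..N-1)
    property_table: str = "builtin"  # "builtin" or a TSV/CSV path
    write_distance_matrix: bool = False
    # taxonomy (all optional; filtering only happens when include is set)
    accession2taxid: str | None = None
    nodes_dmp: str | None = None
    names_dmp: str | None = None
    include_taxon: str | None = None
    exclude_taxon: str | None = None
    keep_unmapped: bool = False
    # screening
    min_distinct_residues: int = 10
    entropy_metric: str = "global"
    entropy_threshold: float = 0.75
    threshold_is_quantile: bool = True
    terminal_exclusion: int = 10
    exclusion_file: str | None = None
    # figure
    panels: tuple[str, ...] = DEFAULT_PANELS
    output_format: str = "svg"
    dpi: int = 150
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["panels"] = list(data["panels"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "panels" in data:
            data["panels"] = tuple(data["panels"])
        return cls(**data)


def run(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns a name -> path map of outputs."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setLevel(cfg.log_level)
    logging.getLogger("teao").addHandler(fh)
    paths: dict[str, Path] = {}
    try:
        logger.info("teao %s", __version__)
        aln = read_msa(cfg.input)
        logger.info(
            "alignment: %d sequences x %d columns", aln.n_sequences, aln.n_columns
        )

        if cfg.include_taxon or cfg.exclude_taxon:
            if not (cfg.accession2taxid and cfg.nodes_dmp and cfg.names_dmp):
                raise ValueError(
                    "taxonomic filtering needs accession2taxid, nodes_dmp and "
                    "names_dmp"
                )
            store = load_store(cfg.accession2taxid, cfg.nodes_dmp, cfg.names_dmp)
            ann = annotate(aln, store)
            aln = filter_by_taxon(
                aln,
                ann,
                store,
                include=cfg.include_taxon or "root",
                exclude=cfg.exclude_taxon,
                keep_unmapped=cfg.keep_unmapped,
            )
            logger.info("after taxonomic filter: %d sequences", aln.n_sequences)
            write_msa(aln, out / "filtered.fasta")
            paths["filtered_msa"] = out / "filtered.fasta"
            ann.to_frame().to_csv(out / "taxonomy.tsv", sep="\t", index=False)
            paths["taxonomy"] = out / "taxonomy.tsv"

        dm = pairwise_distance(aln)
        if cfg.write_distance_matrix:
            dm.to_tsv(out / "distances.tsv")
            paths["distances"] = out / "distances.tsv"
        tree = upgma(dm)
        write_newick(tree, out / "tree.nwk")
        paths["tree"] = out / "tree.nwk"
        partitions = tree_levels(tree)

        profile = teao_profile(
            aln, partitions, gap_as_symbol=cfg.gap_as_symbol, levels=cfg.levels
        )
        pmap = map_reference_positions(aln, cfg.reference_id)
        table = profile_table(profile, pmap)

        if cfg.property_table == "builtin":
            ptable = builtin_zscales()
        else:
            ptable = load_custom_table(cfg.property_table)
        pprofile = property_sd_profile(aln, ptable)
        for d, nm in enumerate(pprofile.descriptor_names):
            table[f"sd_{nm}"] = pprofile.sd[:, d]
        table.to_csv(out / "profile.tsv", sep="\t", index=False)
        paths["profile"] = out / "profile.tsv"
        low = int(profile.low_support.sum())
        if low:
            logger.warning("%d low-support column(s) (entropy fixed at 0)", low)

        exclusions: tuple[int, ...] = ()
        if cfg.exclusion_file:
            exclusions = read_exclusion_list(cfg.exclusion_file)
        scfg = ScreenConfig(
            min_distinct_residues=cfg.min_distinct_residues,
            entropy_metric=cfg.entropy_metric,
            entropy_threshold=cfg.entropy_threshold,
            threshold_is_quantile=cfg.threshold_is_quantile,
            terminal_exclusion=cfg.terminal_exclusion,
            exclusion_positions=exclusions,
        )
        candidates = screen_positions(aln, profile, pmap, scfg, pprofile)
        candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
        paths["candidates"] = out / "candidates.tsv"
        logger.info(
            "screening: %d of %d reference positions pass",
            int(candidates["passed"].sum()),
            len(candidates),
        )

        ref_row = aln.sequences[aln.index_of(pmap.reference_id)]
        fig_spec = FigureSpec(
            panels=tuple(cfg.panels),
            output_format=cfg.output_format,
            dpi=cfg.dpi,
        )
        for p in render_overview(
            aln,
            profile,
            out,
            fig_spec,
            property_profile=pprofile,
            tree=tree,
            reference_sequence=ref_row,
        ):
            paths[p.name] = p

        cfg.to_yaml(out / "resolved_config.yaml")
        paths["config"] = out / "resolved_config.yaml"
        return paths
    finally:
        logging.getLogger("teao").removeHandler(fh)
        fh.close()
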