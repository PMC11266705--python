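"""Configuration-driven pipeline: lesion calling through asymmetry tables.

A run is described by a TOML config (paths, per-condition read pairs and gel
fractions, analysis parameters). Stages mirror the analysis order: lesion
maps -> composition QC -> TSS metaplot -> gene-body bins -> asymmetry ->
per-gene heatmaps. All outputs are TSV (or wig) with ``#`` header comments
carrying the config hash and package version; writes are atomic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core import ConfigError, GeneSet, LesionMap
from .io import (
    read_bed_reads,
    read_fasta_genome,
    read_gene_table,
    read_signal_track,
    write_lesion_track,
)
from .lesions import (
    OffsetConvention,
    dipyrimidine_composition,
    filter_dipyrimidine,
    infer_lesion_positions,
)
from .normalize import make_normalization
from .profiles import (
    asymmetry_score,
    binned_repair,
    heatmap_matrix,
    tss_profile,
    write_cdt,
)

log = logging.getLogger(__name__)

STAGES = ("lesions", "qc", "metaplot", "bins", "asymmetry", "heatmap")


@dataclass
class ConditionConfig:
    name: str
    reads_0h: Path
    reads_t: Path
    gel_fraction: float | None = None


@dataclass
class RunConfig:
    genome: Path
    genes: Path
    out_dir: Path
    conditions: list[ConditionConfig]
    dyads: Path | None = None
    offset: int = 0
    window: tuple[int, int] = (-200, 640)
    smooth: int = 11
    seed: int = 0
    exclude_overlaps: bool = False
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path: str | os.PathLike, **overrides) -> "RunConfig":
        try:
            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: invalid TOML: {exc}") from exc
        base = Path(path).parent
        raw.update({k: v for k, v in overrides.items() if v is not None})

        def _path(key: str, required: bool = True) -> Path | None:
            if key not in raw:
                if required:
                    raise ConfigError(f"{path}: missing required key {key!r}")
                return None
            p = Path(raw[key])
            return p if p.is_absolute() else base / p

        conditions = []
        for name, sub in raw.get("conditions", {}).items():
            for req in ("reads_0h", "reads_t"):
                if req not in sub:
                    raise ConfigError(
                        f"{path}: condition {name!r} missing {req!r} "
                        "(a repair stage needs both timepoints)"
                    )

            def _cpath(v: str) -> Path:
                p = Path(v)
                return p if p.is_absolute() else base / p

            conditions.append(
                ConditionConfig(
                    name=name,
                    reads_0h=_cpath(sub["reads_0h"]),
                    reads_t=_cpath(sub["reads_t"]),
                    gel_fraction=sub.get("gel_fraction"),
                )
            )
        if not conditions:
            raise ConfigError(f"{path}: no [conditions.*] defined")
        window = tuple(raw.get("window", (-200, 640)))
        cfg = cls(
            genome=_path("genome"),
            genes=_path("genes"),
            out_dir=Path(raw.get("out_dir", "out")),
            conditions=conditions,
            dyads=_path("dyads", required=False),
            offset=int(raw.get("offset", 0)),
            window=(int(window[0]), int(window[1])),
            smooth=int(raw.get("smooth", 11)),
            seed=int(raw.get("seed", 0)),
            exclude_overlaps=bool(raw.get("exclude_overlaps", False)),
            raw=raw,
        )
        if not cfg.out_dir.is_absolute():
            cfg.out_dir = base / cfg.out_dir
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in [self.genome, self.genes, self.dyads] + [
            q for c in self.conditions for q in (c.reads_0h, c.reads_t)
        ]:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"referenced file does not exist: {p}")

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _drop_overlapping(genes: GeneSet) -> GeneSet:
    """Remove genes whose transcribed spans overlap another gene's span."""
    spans = []
    for g in genes:
        if g.tes is None:
            lo = hi = g.tss
        else:
            lo, hi = min(g.tss, g.tes), max(g.tss, g.tes)
        spans.append((g.chrom, lo, hi, g))
    keep = []
    for chrom, lo, hi, g in spans:
        clash = any(
            c == chrom and o is not g and lo <= h2 and l2 <= hi
            for c, l2, h2, o in spans
        )
        if not clash:
            keep.append(g)
    return GeneSet(keep)


def _atomic_write(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        for ln in header_lines:
            fh.write(f"# {ln}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")
    os.replace(tmp, path)


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict[str, list[Path]]:
    """Execute the requested stages for every condition; return written paths."""
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    config.out_dir.mkdir(parents=True, exist_ok=True)
    genome = read_fasta_genome(config.genome)
    genes = read_gene_table(config.genes)
    genes, n_unplaced = genes.on_chroms(genome.lengths)
    if n_unplaced:
        log.warning("dropped %d genes on chromosomes absent from genome", n_unplaced)
    if config.exclude_overlaps:
        before = len(genes)
        genes = _drop_overlapping(genes)
        log.info("excluded %d overlapping genes", before - len(genes))
    dyads = (
        read_signal_track(config.dyads, genome.lengths)
        if config.dyads is not None
        else None
    )
    offset = OffsetConvention(delta=config.offset)
    stamp = [
        f"cpdseq {__version__}",
        f"config_hash={config.config_hash()}",
    ]
    needs_repair = any(s in stages for s in ("metaplot", "bins", "asymmetry", "heatmap"))
    written: dict[str, list[Path]] = {s: [] for s in stages}
    for cond in config.conditions:
        maps: dict[str, LesionMap] = {}
        for label, bed in (("0h", cond.reads_0h), ("t", cond.reads_t)):
            reads = read_bed_reads(bed)
            raw_map = infer_lesion_positions(reads, genome, offset)
            filtered = filter_dipyrimidine(raw_map, genome)
            maps[label] = filtered
            if "lesions" in stages:
                prefix = config.out_dir / f"{cond.name}_{label}"
                written["lesions"].extend(write_lesion_track(filtered, prefix))
            if "qc" in stages:
                comp = dipyrimidine_composition(raw_map, genome)
                qc = comp.rename_axis("dinucleotide").reset_index()
                qc_path = config.out_dir / f"{cond.name}_{label}_composition.tsv"
                _atomic_write(
                    qc,
                    qc_path,
                    stamp
                    + [
                        f"condition={cond.name} timepoint={label}",
                        f"total_reads={len(reads)} retained={filtered.total()} "
                        f"filter_losses={filtered.filter_losses} "
                        f"oob_drops={filtered.oob_drops}",
                    ],
                )
                written["qc"].append(qc_path)
        if not needs_repair:
            continue
        norm = make_normalization(maps["0h"], maps["t"], cond.gel_fraction)
        norm_meta = (
            f"gel_fraction={norm.gel_fraction} scale={norm.scale:.6g} "
            f"T0={norm.total_0h} Tt={norm.total_t} "
            f"mode={'gel' if cond.gel_fraction is not None else 'depth-only (G=1)'}"
        )
        if "metaplot" in stages:
            prof = tss_profile(
                maps["0h"], maps["t"], genes, norm,
                window=config.window, smooth_width=config.smooth,
                nucleosome_track=dyads,
            )
            p = config.out_dir / f"{cond.name}_tss_profile.tsv"
            _atomic_write(
                prof.table, p,
                stamp + [f"condition={cond.name} n_genes={prof.n_genes}", norm_meta],
            )
            written["metaplot"].append(p)
        if {"bins", "asymmetry", "heatmap"} & set(stages):
            binned = binned_repair(maps["0h"], maps["t"], genes, norm)
            if "bins" in stages:
                p = config.out_dir / f"{cond.name}_bins.tsv"
                _atomic_write(
                    binned.aggregate, p,
                    stamp
                    + [
                        f"condition={cond.name} n_genes={binned.n_genes} "
                        f"n_excluded={binned.n_excluded}",
                        norm_meta,
                    ],
                )
                written["bins"].append(p)
            if "asymmetry" in stages:
                result = asymmetry_score(binned, allow_undefined=True)
                p = config.out_dir / f"{cond.name}_asymmetry.tsv"
                table = result.per_bin.copy()
                _atomic_write(
                    table, p,
                    stamp
                    + [
                        f"condition={cond.name} n_genes={binned.n_genes}",
                        norm_meta,
                        f"average_log2_ts_nts={result.average:.6g} "
                        f"se={result.average_se:.3g} "
                        f"body_bins_defined={result.n_body_defined}",
                    ],
                )
                written["asymmetry"].append(p)
            if "heatmap" in stages:
                for sc, mat in heatmap_matrix(binned).items():
                    p = config.out_dir / f"{cond.name}_heatmap_{sc}.cdt"
                    tmp = p.with_suffix(p.suffix + ".tmp")
                    write_cdt(mat, tmp)
                    os.replace(tmp, p)
                    written["heatmap"].append(p)
    return written


class ExitCodes:
    OK = 0
    CONFIG = 2
    DATA = 3
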