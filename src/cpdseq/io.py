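"""Readers and writers for the formats the pipeline touches.

Coordinate dialects are fixed here and nowhere else: BED and bedGraph are
0-based half-open; wiggle (variableStep / fixedStep) is 1-based; everything
in memory is 0-based half-open.  Text wiggle has no reader among the usual
binary-format libraries, so the (small) dialect is implemented directly.
"""

from __future__ import annotations

import logging
import os
from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import (
    ConfigError,
    DataError,
    Genome,
    GeneRecord,
    GeneSet,
    LesionMap,
    SignalTrack,
)

log = logging.getLogger(__name__)

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
GENE_COLUMNS = ["id", "chrom", "strand", "tss", "tes", "txn_freq"]


def read_fasta_genome(path: str | os.PathLike) -> Genome:
    """Read a multi-record FASTA into a :class:`Genome` (sequences uppercased)."""
    records = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise DataError(f"{path}: duplicate chromosome name {rec.id!r}")
            records[rec.id] = str(rec.seq)
    except FileNotFoundError:
        raise
    except DataError:
        raise
    except Exception as exc:  # Biopython raises ValueError on syntax problems
        raise DataError(f"{path}: FASTA parse error: {exc}") from exc
    if not records:
        raise DataError(f"{path}: no records")
    return Genome(records)


def write_fasta_genome(genome: Genome, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed_reads(path: str | os.PathLike) -> pd.DataFrame:
    """Read aligned reads from a 6-column BED file.

    Returns a DataFrame with columns chrom/start/end/name/score/strand plus a
    derived ``five_prime`` column (the read's 5' end: ``start`` on "+" and
    ``end - 1`` on "-"). Only the 5' end carries lesion information.
    """
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            comment="#",
            dtype=str,
            engine="python",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=BED_COLUMNS)
    if df.empty:
        out = pd.DataFrame(columns=BED_COLUMNS + ["five_prime"])
        return out.astype({"start": int, "end": int, "five_prime": int}, errors="ignore")
    if df.shape[1] < 6:
        raise DataError(f"{path}: BED6 requires >= 6 columns, found {df.shape[1]}")
    df = df.iloc[:, :6].copy()
    df.columns = BED_COLUMNS
    df["start"] = pd.to_numeric(df["start"], errors="raise").astype(np.int64)
    df["end"] = pd.to_numeric(df["end"], errors="raise").astype(np.int64)
    bad_order = df["start"] >= df["end"]
    if bad_order.any():
        line = int(np.flatnonzero(bad_order.to_numpy())[0]) + 1
        raise DataError(f"{path}: start >= end at line {line}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        n = int(bad_strand.sum())
        log.warning("%s: rejected %d reads with strand not in {+,-}", path, n)
        df = df[~bad_strand].reset_index(drop=True)
    df["five_prime"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df


def write_bed_reads(reads: pd.DataFrame, path: str | os.PathLike) -> None:
    reads[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_gene_table(path: str | os.PathLike) -> GeneSet:
    """Read a TSV gene table with header ``id chrom strand tss tes txn_freq``.

    ``txn_freq`` is optional (column or individual values); ``tes`` values may
    be empty for genes without a mapped polyadenylation site. Genes violating
    the strand/coordinate invariants are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "id": str})
    mandatory = ["id", "chrom", "strand", "tss", "tes"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: gene table missing mandatory columns {missing}")
    has_txn = "txn_freq" in df.columns
    genes: list[GeneRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        tes = getattr(row, "tes")
        tes = None if pd.isna(tes) else int(tes)
        txn = getattr(row, "txn_freq", None) if has_txn else None
        txn = None if txn is None or pd.isna(txn) else float(txn)
        try:
            genes.append(
                GeneRecord(
                    id=str(row.id),
                    chrom=str(row.chrom),
                    strand=str(row.strand),
                    tss=int(row.tss),
                    tes=tes,
                    txn_freq=txn,
                )
            )
        except DataError as exc:
            dropped += 1
            log.warning("%s: dropping gene: %s", path, exc)
    if dropped:
        log.warning("%s: dropped %d/%d genes failing invariants", path, dropped, len(df))
    gs = GeneSet(genes)
    gs.n_dropped = dropped
    return gs


def write_gene_table(genes: GeneSet, path: str | os.PathLike) -> None:
    rows = [
        {
            "id": g.id,
            "chrom": g.chrom,
            "strand": g.strand,
            "tss": g.tss,
            "tes": "" if g.tes is None else g.tes,
            "txn_freq": "" if g.txn_freq is None else g.txn_freq,
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def _is_wig(first_line: str) -> bool:
    head = first_line.strip()
    return head.startswith(("track", "variableStep", "fixedStep"))


def read_signal_track(
    path: str | os.PathLike, lengths: Mapping[str, int] | None = None
) -> SignalTrack:
    """Read a wiggle (variableStep/fixedStep) or bedGraph file into dense vectors.

    Wiggle coordinates are 1-based; bedGraph is 0-based half-open. Unspecified
    positions are 0. With ``lengths`` given, vectors are allocated at
    chromosome length and out-of-range records raise; otherwise vectors grow
    to the maximum observed coordinate.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    content = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not content:
        return SignalTrack() if lengths is None else SignalTrack.zeros(lengths)
    if _is_wig(content[0]) or any(
        ln.startswith(("variableStep", "fixedStep")) for ln in content
    ):
        values = _read_wig(content, path)
    else:
        values = _read_bedgraph(content, path)
    return _densify(values, lengths, path)


def _read_wig(lines: list[str], path) -> dict[str, list[tuple[int, int, float]]]:
    """Parse wig into per-chrom (start0, end0, value) interval lists."""
    out: dict[str, list[tuple[int, int, float]]] = {}
    mode = None  # ("variable"|"fixed", chrom, span, [start, step, cursor])
    for i, ln in enumerate(lines, start=1):
        if ln.startswith("track"):
            continue
        if ln.startswith("variableStep") or ln.startswith("fixedStep"):
            fields = dict(
                kv.split("=", 1) for kv in ln.split()[1:] if "=" in kv
            )
            if "chrom" not in fields:
                raise DataError(f"{path}:{i}: wig declaration without chrom=")
            span = int(fields.get("span", 1))
            if ln.startswith("variableStep"):
                mode = ("variable", fields["chrom"], span, None)
            else:
                start = int(fields["start"])  # 1-based
                step = int(fields.get("step", 1))
                mode = ("fixed", fields["chrom"], span, [start, step, 0])
            out.setdefault(fields["chrom"], [])
            continue
        if mode is None:
            raise DataError(f"{path}:{i}: wig data before any step declaration")
        kind, chrom, span, fixed = mode
        parts = ln.split()
        try:
            if kind == "variable":
                pos1, val = int(parts[0]), float(parts[1])
            else:
                val = float(parts[0])
                pos1 = fixed[0] + fixed[2] * fixed[1]
                fixed[2] += 1
        except (ValueError, IndexError) as exc:
            raise DataError(f"{path}:{i}: malformed wig data line {ln!r}") from exc
        out[chrom].append((pos1 - 1, pos1 - 1 + span, val))
    return out


def _read_bedgraph(lines: list[str], path) -> dict[str, list[tuple[int, int, float]]]:
    out: dict[str, list[tuple[int, int, float]]] = {}
    for i, ln in enumerate(lines, start=1):
        parts = ln.split()
        if len(parts) < 4:
            raise DataError(f"{path}:{i}: bedGraph needs 4 columns")
        chrom, start, end, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        if start >= end:
            raise DataError(f"{path}:{i}: bedGraph start >= end")
        out.setdefault(chrom, []).append((start, end, val))
    # ambiguity check: overlapping intervals
    for chrom, ivals in out.items():
        ivals.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise DataError(
                    f"{path}: overlapping bedGraph intervals on {chrom} at {s2}"
                )
    return out


def _densify(
    values: dict[str, list[tuple[int, int, float]]],
    lengths: Mapping[str, int] | None,
    path,
) -> SignalTrack:
    track = SignalTrack()
    if lengths is not None:
        for c, n in lengths.items():
            track[c] = np.zeros(n, dtype=float)
    for chrom, ivals in values.items():
        if lengths is not None:
            if chrom not in lengths:
                raise DataError(f"{path}: unknown chromosome {chrom!r} in track")
            vec = track[chrom]
        else:
            size = max((e for _, e, _ in ivals), default=0)
            vec = np.zeros(size, dtype=float)
            track[chrom] = vec
        for s, e, v in ivals:
            if s < 0 or e > len(vec):
                raise DataError(
                    f"{path}: interval [{s},{e}) outside chromosome {chrom!r}"
                )
            vec[s:e] = v
    return track


def write_signal_track_wig(
    track: Mapping[str, np.ndarray], path: str | os.PathLike, *, name: str = "signal"
) -> None:
    """Write a dense track as 1-based variableStep wig, omitting zeros."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for chrom in sorted(track):
            fh.write(f"variableStep chrom={chrom} span=1\n")
            vec = np.asarray(track[chrom])
            for pos in np.flatnonzero(vec):
                v = vec[pos]
                v_repr = int(v) if float(v).is_integer() else float(v)
                fh.write(f"{pos + 1}\t{v_repr}\n")


def write_lesion_track(lmap: LesionMap, path_prefix: str | os.PathLike) -> tuple[Path, Path]:
    """Write a LesionMap as two variableStep wig files (one per damaged strand)."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = (
        prefix.with_name(prefix.name + ".plus.wig"),
        prefix.with_name(prefix.name + ".minus.wig"),
    )
    for strand, p in zip(("+", "-"), paths):
        write_signal_track_wig(
            {c: lmap.counts[c][strand] for c in lmap.counts},
            p,
            name=f"CPD lesions ({strand})",
        )
    return paths


def read_lesion_track(
    path_prefix: str | os.PathLike, lengths: Mapping[str, int]
) -> LesionMap:
    """Inverse of :func:`write_lesion_track`."""
    prefix = Path(path_prefix)
    lmap = LesionMap(lengths)
    for strand, suffix in (("+", ".plus.wig"), ("-", ".minus.wig")):
        track = read_signal_track(prefix.with_name(prefix.name + suffix), lengths)
        for chrom, vec in track.items():
            if not np.allclose(vec, np.round(vec)):
                raise DataError(f"{path_prefix}{suffix}: non-integer lesion counts")
            lmap.counts[chrom][strand] = np.round(vec).astype(np.int64)
    return lmap
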