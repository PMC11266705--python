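"""TSS metaplots, gene-body bin profiles, repair asymmetry, heatmaps.

All aggregation is strand-aware. A lesion is classified against each gene:
it lies on the non-transcribed strand (NTS) when its damaged strand equals
the gene's annotated (coding) strand, and on the transcribed / template
strand (TS) otherwise. TC-NER acts only on the TS, so the log2 ratio of TS
to NTS fractions remaining isolates TC-NER activity from global repair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DataError, GeneRecord, GeneSet, LesionMap, SignalTrack
from .normalize import NormalizationFactor, fraction_remaining

log = logging.getLogger(__name__)

STRAND_CLASSES = ("TS", "NTS")

N_BODY = 6
N_FLANK = 3
FLANK_SIZE = 167


def classify_strand(lesion_strand: str, gene_strand: str) -> str:
    """NTS iff the damaged strand equals the gene's coding strand."""
    if lesion_strand not in "+-" or gene_strand not in "+-":
        raise DataError("strands must be '+' or '-'")
    return "NTS" if lesion_strand == gene_strand else "TS"


# ---------------------------------------------------------------------------
# TSS metaplot
# ---------------------------------------------------------------------------

@dataclass
class RepairProfile:
    """Single-nucleotide fraction-remaining profile around the TSS.

    ``table`` columns: offset, strand_class, counts_0, counts_t, fraction,
    fraction_smoothed (NaN when smoothing disabled), nucleosome (optional
    mean dyad coverage). Offsets run in transcription direction.
    """

    window: tuple[int, int]
    table: pd.DataFrame
    n_genes: int
    norm: NormalizationFactor
    smooth_width: int | None = None

    def fractions(self, strand_class: str) -> pd.Series:
        sub = self.table[self.table["strand_class"] == strand_class]
        return sub.set_index("offset")["fraction"]


def _offset_positions(gene: GeneRecord, offsets: np.ndarray, chrom_len: int):
    """Genomic positions for transcription-direction offsets; mask of valid."""
    if gene.strand == "+":
        pos = gene.tss + offsets
    else:
        pos = gene.tss - offsets
    valid = (pos >= 0) & (pos < chrom_len)
    return pos, valid


def moving_average(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average ignoring NaNs; width clipped at the edges."""
    if width <= 1:
        return values.copy()
    half = width // 2
    out = np.full_like(values, np.nan, dtype=float)
    finite = np.isfinite(values)
    vals = np.where(finite, values, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    cnum = np.concatenate([[0], np.cumsum(finite.astype(int))])
    n = len(values)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        k = cnum[hi] - cnum[lo]
        if k:
            out[i] = (csum[hi] - csum[lo]) / k
    return out


def tss_profile(
    lesions_0h: LesionMap,
    lesions_t: LesionMap,
    genes: GeneSet,
    norm: NormalizationFactor,
    window: tuple[int, int] = (-200, 640),
    smooth_width: int | None = 11,
    nucleosome_track: SignalTrack | None = None,
) -> RepairProfile:
    """Aggregate per-offset TS/NTS fractions remaining around the TSS.

    Counts at each transcription-direction offset are summed over genes per
    strand class and converted through :func:`fraction_remaining`; smoothing
    (centered moving average) touches only the ``fraction_smoothed`` column.
    """
    usable, n_off = genes.on_chroms(lesions_0h.lengths)
    if len(usable) == 0:
        raise DataError("empty gene set for TSS profile")
    if n_off:
        log.warning("tss_profile: dropped %d genes on unknown chromosomes", n_off)
    offsets = np.arange(window[0], window[1])
    w = len(offsets)
    sums = {sc: {"0": np.zeros(w), "t": np.zeros(w)} for sc in STRAND_CLASSES}
    for gene in usable:
        chrom_len = lesions_0h.lengths[gene.chrom]
        pos, valid = _offset_positions(gene, offsets, chrom_len)
        pv = pos[valid]
        for lesion_strand in "+-":
            sc = classify_strand(lesion_strand, gene.strand)
            sums[sc]["0"][valid] += lesions_0h.counts[gene.chrom][lesion_strand][pv]
            sums[sc]["t"][valid] += lesions_t.counts[gene.chrom][lesion_strand][pv]
    overlay = (
        nucleosome_overlay(nucleosome_track, usable, window)
        if nucleosome_track is not None
        else None
    )
    frames = []
    for sc in STRAND_CLASSES:
        frac = fraction_remaining(sums[sc]["t"], sums[sc]["0"], norm)
        smoothed = (
            moving_average(frac, smooth_width)
            if smooth_width and smooth_width > 1
            else np.full(w, np.nan)
        )
        df = pd.DataFrame(
            {
                "offset": offsets,
                "strand_class": sc,
                "counts_0": sums[sc]["0"].astype(np.int64),
                "counts_t": sums[sc]["t"].astype(np.int64),
                "fraction": frac,
                "fraction_smoothed": smoothed,
            }
        )
        if overlay is not None:
            df["nucleosome"] = overlay
        frames.append(df)
    return RepairProfile(
        window=window,
        table=pd.concat(frames, ignore_index=True),
        n_genes=len(usable),
        norm=norm,
        smooth_width=smooth_width,
    )


def nucleosome_overlay(
    track: SignalTrack, genes: GeneSet, window: tuple[int, int] = (-200, 640)
) -> np.ndarray:
    """Mean (not summed) track value per transcription-direction offset."""
    offsets = np.arange(window[0], window[1])
    total = np.zeros(len(offsets))
    count = np.zeros(len(offsets), dtype=int)
    for gene in genes:
        if gene.chrom not in track:
            continue
        vec = track[gene.chrom]
        pos, valid = _offset_positions(gene, offsets, len(vec))
        total[valid] += vec[pos[valid]]
        count[valid] += 1
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)


# ---------------------------------------------------------------------------
# Gene-body bins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bin:
    """One profile bin of a gene, in transcription order.

    ``index`` runs 0..11: three upstream flank bins, six body bins, three
    downstream flank bins. ``start``/``end`` are genomic half-open and may be
    clipped at chromosome ends (``clipped`` is then True).
    """

    index: int
    kind: str  # "upstream" | "body" | "downstream"
    start: int
    end: int
    clipped: bool = False

    @property
    def size(self) -> int:
        return self.end - self.start


def gene_bins(
    gene: GeneRecord,
    n_body: int = N_BODY,
    n_flank: int = N_FLANK,
    flank_size: int = FLANK_SIZE,
    chrom_length: int | None = None,
) -> list[Bin]:
    """Partition a gene into flank + body + flank bins.

    The body partition is *defined* by the per-base rule: the base at
    transcription-direction offset ``o`` in a gene of length ``L`` belongs to
    body bin ``floor(n_body * o / L)``; the half-open intervals are derived
    from that rule (boundaries at ``ceil(k * L / n_body)``), which pins down
    every boundary case. Flank bins are exactly ``flank_size`` bp, adjacent,
    outside the transcribed span.
    """
    if gene.tes is None:
        raise DataError(f"gene {gene.id}: no TES, cannot bin")
    length = gene.length
    if length < n_body:
        raise DataError(f"gene {gene.id}: length {length} < {n_body} bins")
    # transcription-direction half-open offset intervals, in order
    offset_bounds: list[tuple[int, int, str]] = []
    for k in range(n_flank, 0, -1):
        offset_bounds.append((-k * flank_size, -(k - 1) * flank_size, "upstream"))
    body_edges = [-(-k * length // n_body) for k in range(n_body + 1)]  # ceil
    for k in range(n_body):
        offset_bounds.append((body_edges[k], body_edges[k + 1], "body"))
    for k in range(n_flank):
        offset_bounds.append(
            (length + k * flank_size, length + (k + 1) * flank_size, "downstream")
        )
    bins: list[Bin] = []
    for idx, (o0, o1, kind) in enumerate(offset_bounds):
        if gene.strand == "+":
            start, end = gene.tss + o0, gene.tss + o1
        else:
            start, end = gene.tss - o1 + 1, gene.tss - o0 + 1
        clipped = False
        if chrom_length is not None:
            c0, c1 = max(0, start), min(chrom_length, end)
            clipped = (c0, c1) != (start, end)
            start, end = c0, max(c0, c1)
        bins.append(Bin(index=idx, kind=kind, start=start, end=end, clipped=clipped))
    return bins


@dataclass
class BinnedRepair:
    """Per-gene and aggregate bin counts/fractions, per strand class.

    ``per_gene`` columns: gene, bin, kind, strand_class, counts_0, counts_t.
    ``aggregate`` columns: bin, kind, strand_class, counts_0, counts_t,
    fraction.
    """

    per_gene: pd.DataFrame
    aggregate: pd.DataFrame
    norm: NormalizationFactor
    n_genes: int
    n_excluded: int = 0  # too short, no TES, or unknown chromosome
    genes: GeneSet = field(default_factory=GeneSet)


def binned_repair(
    lesions_0h: LesionMap,
    lesions_t: LesionMap,
    genes: GeneSet,
    norm: NormalizationFactor,
    n_body: int = N_BODY,
    n_flank: int = N_FLANK,
    flank_size: int = FLANK_SIZE,
) -> BinnedRepair:
    """Count lesions per gene bin and convert to aggregate fractions."""
    qualifying, n_unknown = genes.with_tes().on_chroms(lesions_0h.lengths)
    n_excluded = (len(genes) - len(genes.with_tes())) + n_unknown
    rows = []
    used = []
    for gene in qualifying:
        chrom_len = lesions_0h.lengths[gene.chrom]
        try:
            bins = gene_bins(gene, n_body, n_flank, flank_size, chrom_length=chrom_len)
        except DataError:
            n_excluded += 1
            continue
        used.append(gene)
        for b in bins:
            for lesion_strand in "+-":
                sc = classify_strand(lesion_strand, gene.strand)
                c0 = int(
                    lesions_0h.counts[gene.chrom][lesion_strand][b.start : b.end].sum()
                )
                ct = int(
                    lesions_t.counts[gene.chrom][lesion_strand][b.start : b.end].sum()
                )
                rows.append(
                    {
                        "gene": gene.id,
                        "bin": b.index,
                        "kind": b.kind,
                        "strand_class": sc,
                        "counts_0": c0,
                        "counts_t": ct,
                    }
                )
    if not used:
        raise DataError("no qualifying genes for bin analysis")
    per_gene = pd.DataFrame(rows)
    agg = (
        per_gene.groupby(["bin", "kind", "strand_class"], as_index=False)[
            ["counts_0", "counts_t"]
        ]
        .sum()
        .sort_values(["bin", "strand_class"], ignore_index=True)
    )
    agg["fraction"] = fraction_remaining(
        agg["counts_t"].to_numpy(), agg["counts_0"].to_numpy(), norm
    )
    if n_excluded:
        log.info("binned_repair: excluded %d genes (no TES / too short / unknown chrom)", n_excluded)
    return BinnedRepair(
        per_gene=per_gene,
        aggregate=agg,
        norm=norm,
        n_genes=len(used),
        n_excluded=n_excluded,
        genes=GeneSet(used),
    )


# ---------------------------------------------------------------------------
# Repair asymmetry
# ---------------------------------------------------------------------------

@dataclass
class AsymmetryResult:
    """Per-bin log2(TS/NTS) fractions remaining and the six-body-bin average.

    Negative values mean faster repair of the transcribed strand, the
    signature of TC-NER. ``average`` uses exactly the body bins; flank bins
    are reported but never averaged. ``average_se`` is a delta-method
    (Poisson-count) standard error, an approximation useful for judging
    Monte-Carlo convergence of simulated data.
    """

    per_bin: pd.DataFrame  # bin, kind, f_ts, f_nts, log2_ratio, se
    average: float
    average_se: float
    n_body_defined: int
    allow_undefined: bool = False

    def summary(self) -> str:
        lines = [
            "Repair asymmetry: log2(TS fraction remaining / NTS fraction remaining)",
            f"  six-body-bin average: {self.average:.4f} (se {self.average_se:.4f})",
            f"  body bins defined: {self.n_body_defined}/{N_BODY}",
            "",
            self.per_bin.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


def asymmetry_score(binned: BinnedRepair, allow_undefined: bool = False) -> AsymmetryResult:
    """Per-bin log2(f_TS / f_NTS) on aggregate fractions plus the body average.

    A bin is undefined when either strand class has zero 0 h counts or a zero
    fraction. By default an undefined body bin makes the average undefined
    (NaN); ``allow_undefined=True`` averages the defined body bins instead.
    """
    agg = binned.aggregate
    piv = agg.pivot_table(
        index=["bin", "kind"],
        columns="strand_class",
        values=["fraction", "counts_0", "counts_t"],
        aggfunc="first",
    )
    rows = []
    for (b, kind), r in piv.iterrows():
        f_ts, f_nts = r[("fraction", "TS")], r[("fraction", "NTS")]
        defined = (
            np.isfinite(f_ts) and np.isfinite(f_nts) and f_ts > 0 and f_nts > 0
        )
        if defined:
            ratio = math.log2(f_ts / f_nts)
            # delta method, treating the four aggregate counts as Poisson
            invs = sum(
                1.0 / r[(c, sc)]
                for c in ("counts_0", "counts_t")
                for sc in STRAND_CLASSES
                if r[(c, sc)] > 0
            )
            se = math.sqrt(invs) / math.log(2)
        else:
            ratio, se = np.nan, np.nan
        rows.append(
            {
                "bin": b,
                "kind": kind,
                "f_ts": f_ts,
                "f_nts": f_nts,
                "log2_ratio": ratio,
                "se": se,
            }
        )
    per_bin = pd.DataFrame(rows).sort_values("bin", ignore_index=True)
    body = per_bin[per_bin["kind"] == "body"]
    defined = body["log2_ratio"].notna()
    n_def = int(defined.sum())
    if n_def == 0:
        raise DataError("all body bins undefined: no asymmetry average")
    if n_def < len(body) and not allow_undefined:
        average, average_se = float("nan"), float("nan")
    else:
        sub = body[defined]
        average = float(sub["log2_ratio"].mean())
        average_se = float(np.sqrt((sub["se"] ** 2).sum()) / len(sub))
    return AsymmetryResult(
        per_bin=per_bin,
        average=average,
        average_se=average_se,
        n_body_defined=n_def,
        allow_undefined=allow_undefined,
    )


# ---------------------------------------------------------------------------
# Per-gene heatmap matrices
# ---------------------------------------------------------------------------

def heatmap_matrix(binned: BinnedRepair) -> dict[str, pd.DataFrame]:
    """Per-gene fraction-remaining matrices (gene x bin) per strand class.

    Rows are ordered by descending transcription frequency, ties broken by
    gene id; genes lacking a frequency sink to the bottom. Per-gene fractions
    use the condition's normalization scale; bins with zero 0 h counts are
    NaN.
    """
    freq = {g.id: g.txn_freq for g in binned.genes}
    out: dict[str, pd.DataFrame] = {}
    scale = binned.norm.scale
    pg = binned.per_gene
    for sc in STRAND_CLASSES:
        sub = pg[pg["strand_class"] == sc]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(
                sub["counts_0"] > 0,
                scale * sub["counts_t"] / sub["counts_0"].replace(0, 1),
                np.nan,
            )
        mat = (
            sub.assign(fraction=frac)
            .pivot(index="gene", columns="bin", values="fraction")
            .sort_index()
        )
        order = sorted(
            mat.index,
            key=lambda g: (
                0 if freq.get(g) is not None else 1,
                -(freq.get(g) or 0.0),
                g,
            ),
        )
        out[sc] = mat.loc[order]
    return out


def write_cdt(matrix: pd.DataFrame, path) -> None:
    """Write a gene x bin matrix as a CDT-style tab-delimited file."""
    df = matrix.copy()
    df.insert(0, "NAME", df.index)
    df.insert(0, "UID", df.index)
    df.to_csv(path, sep="\t", index=False)


def read_cdt(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("UID").drop(columns=["NAME"])
    df.columns = [int(c) for c in df.columns]
    return df
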