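"""Synthetic UV-damage / repair experiments with analytic ground truth.

The generator produces everything the pipeline consumes — genome FASTA, gene
table, nucleosome dyad track, and stranded BED reads for a 0 h and a t-hour
timepoint — from an explicit generative model:

* **Damage.** CPDs form only at dipyrimidine anchors; the per-anchor damage
  probability ``q_i`` is proportional to a class weight (TT heaviest, then
  TC = CT, then CC), emulating the observed enrichment order.
* **Repair.** Per-anchor survival over ``t`` hours is exponential,
  ``S_i = exp(-t * [m_rad16 * k_gg * (1 - a * occ_i)
                    + 1{i on TS of gene g} * m_elf1ctd * m_rad26 * k_tc
                      * tau_g * d(o_i)])``,
  combining global repair (GG-NER, both strands, suppressed near nucleosome
  dyads by amplitude ``a``) with transcribed-strand-only repair (TC-NER,
  scaled by the gene's relative transcription frequency ``tau_g`` and a
  positional profile ``d`` over the gene body). Genotype multipliers
  attenuate the pathways to emulate elf1-CTD-truncation, rad26 and rad16
  mutants.
* **Sequencing.** Both timepoints are multinomial draws at a requested depth
  (plus an optional uniform noise fraction); reads are emitted by the exact
  inverse of the read-to-lesion geometry, so a noise-free experiment
  round-trips bit-exactly through lesion calling.

Because ``q_i`` and ``S_i`` are known, every downstream quantity — bulk
fraction remaining ``G* = sum(q S) / sum(q)``, per-bin TS/NTS fractions, the
average log2 TS/NTS asymmetry — has an exact expectation computed by direct
summation (:func:`truth_report`), never by sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import ConfigError, DataError, Genome, GeneRecord, GeneSet, LesionMap, SignalTrack, revcomp
from .lesions import OffsetConvention, dinucleotide_class_codes
from .profiles import N_BODY, N_FLANK, FLANK_SIZE, classify_strand, gene_bins

_GAP_MIN = 510  # bp between genes: keeps 3 x 167 bp flanks off neighbours
_EDGE = 520  # bp clear of chromosome ends for gene placement


@dataclass(frozen=True)
class SimParams:
    """Parameters of one synthetic CPD-seq experiment.

    Defaults describe a compact but structurally faithful experiment: a
    two-chromosome 50 kb genome, 16 non-overlapping genes, yeast-like
    AT-rich base composition, nucleosomes phased from the TSS (+1 dyad at
    +60, 165 bp repeat), and kinetics whose wild-type-like expected
    asymmetry sits at the magnitude reported for repair-proficient yeast
    (about -0.7 over two hours).
    """

    # genome
    n_chroms: int = 2
    chrom_length: int = 25_000
    base_probs: tuple[float, float, float, float] = (0.31, 0.19, 0.19, 0.31)  # A C G T
    # genes
    n_genes: int = 16
    gene_length: tuple[int, int] = (600, 1800)
    txn_sigma: float = 0.8  # lognormal spread of relative transcription frequency
    # nucleosomes
    nuc_plus1_offset: int = 60
    nuc_spacing: int = 165
    nuc_kernel_sd: float = 30.0
    # damage class weights (TT >= TC = CT >= CC > 0)
    w_tt: float = 8.0
    w_tc: float = 3.0
    w_ct: float = 3.0
    w_cc: float = 1.0
    # repair kinetics (per hour)
    k_gg: float = 0.35
    k_tc: float = 0.30
    suppression: float = 0.6  # nucleosome suppression amplitude a in [0, 1]
    decay: str = "uniform"  # TC-NER positional profile d(o): "uniform" | "exp"
    decay_length: float = 500.0
    m_elf1ctd: float = 1.0
    m_rad26: float = 1.0
    m_rad16: float = 1.0
    t: float = 2.0  # repair duration, hours
    # sequencing
    depth_0: int = 200_000
    depth_t: int = 200_000
    noise_frac: float = 0.0
    read_length: tuple[int, int] = (20, 40)
    offset_delta: int = 0
    seed: int = 0
    edge_margin: int = 5  # anchors this close to a chromosome end carry no damage

    def validate(self) -> None:
        if not (self.w_tt >= self.w_tc == self.w_ct >= self.w_cc > 0):
            raise ConfigError("damage weights must satisfy w_TT >= w_TC = w_CT >= w_CC > 0")
        if self.k_gg < 0 or self.k_tc < 0:
            raise ConfigError("repair rates must be >= 0")
        if not 0 <= self.suppression <= 1:
            raise ConfigError("nucleosome suppression amplitude must be in [0, 1]")
        if not 0 <= self.noise_frac < 1:
            raise ConfigError("noise_frac must be in [0, 1)")
        if self.depth_0 <= 0 or self.depth_t <= 0:
            raise ConfigError("sequencing depths must be > 0")
        for m in (self.m_elf1ctd, self.m_rad26, self.m_rad16):
            if not 0 <= m <= 1:
                raise ConfigError("genotype multipliers must be in [0, 1]")
        if self.decay not in ("uniform", "exp"):
            raise ConfigError(f"unknown TC-NER decay profile {self.decay!r}")
        if not abs(np.sum(self.base_probs) - 1) < 1e-9:
            raise ConfigError("base_probs must sum to 1")

    def with_(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)


StrandArrays = dict[str, dict[str, np.ndarray]]  # chrom -> strand -> per-base array


@dataclass
class SimExperiment:
    """A fully realized synthetic experiment plus its generative truth."""

    params: SimParams
    genome: Genome
    genes: GeneSet
    dyads: SignalTrack
    q: StrandArrays  # per-anchor damage probability (sums to 1)
    survival: StrandArrays  # per-anchor survival S in (0, 1]
    lesions_0h: LesionMap
    lesions_t: LesionMap
    g_star: float  # true bulk fraction remaining


# ---------------------------------------------------------------------------
# genome / genes / nucleosomes
# ---------------------------------------------------------------------------

def simulate_genome(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[Genome, GeneSet, SignalTrack]:
    """Random genome, non-overlapping genes, and a phased dyad track."""
    params.validate()
    rng = rng or np.random.default_rng(params.seed)
    seqs = {}
    for c in range(params.n_chroms):
        bases = rng.choice(list("ACGT"), size=params.chrom_length, p=params.base_probs)
        seqs[f"chr{c + 1}"] = "".join(bases)
    genome = Genome(seqs)

    per_chrom = [params.n_genes // params.n_chroms] * params.n_chroms
    for i in range(params.n_genes % params.n_chroms):
        per_chrom[i] += 1
    genes: list[GeneRecord] = []
    gid = 0
    for ci, k in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        if k == 0:
            continue
        lengths = rng.integers(params.gene_length[0], params.gene_length[1] + 1, size=k)
        required = int(lengths.sum()) + (k - 1) * _GAP_MIN + 2 * _EDGE
        if required > params.chrom_length:
            raise ConfigError(
                f"cannot pack {k} genes of total {lengths.sum()} bp into "
                f"{params.chrom_length} bp chromosome {chrom}"
            )
        slack = params.chrom_length - required
        extras = rng.multinomial(slack, [1 / (k + 1)] * (k + 1))
        cursor = _EDGE + int(extras[0])
        for j in range(k):
            length = int(lengths[j])
            start, end = cursor, cursor + length
            strand = "+" if rng.random() < 0.5 else "-"
            tau = float(rng.lognormal(mean=-params.txn_sigma**2 / 2, sigma=params.txn_sigma))
            gid += 1
            if strand == "+":
                genes.append(GeneRecord(f"g{gid:03d}", chrom, "+", start, end, tau))
            else:
                genes.append(GeneRecord(f"g{gid:03d}", chrom, "-", end - 1, start - 1, tau))
            cursor = end + _GAP_MIN + int(extras[j + 1])
    gene_set = GeneSet(genes)

    dyads = SignalTrack.zeros(genome.lengths)
    sd = params.nuc_kernel_sd
    reach = int(3 * sd)
    for g in gene_set:
        vec = dyads[g.chrom]
        length = g.length or 0
        o = params.nuc_plus1_offset
        while o < length:
            center = g.tss + o if g.strand == "+" else g.tss - o
            lo, hi = max(0, center - reach), min(len(vec), center + reach + 1)
            x = np.arange(lo, hi)
            vec[lo:hi] += np.exp(-((x - center) ** 2) / (2 * sd**2))
            o += params.nuc_spacing
    return genome, gene_set, dyads


# ---------------------------------------------------------------------------
# damage and repair fields
# ---------------------------------------------------------------------------

def damage_probabilities(genome: Genome, params: SimParams) -> StrandArrays:
    """Per-anchor damage probability q (dipyrimidine-weighted, normalized)."""
    weights = np.array([params.w_tt, params.w_tc, params.w_ct, params.w_cc, 0.0])
    q: StrandArrays = {}
    total = 0.0
    m = params.edge_margin
    for chrom in sorted(genome):
        codes = dinucleotide_class_codes(genome, chrom)
        q[chrom] = {}
        for strand in ("+", "-"):
            w = weights[codes[strand]]
            if m > 0:
                w[:m] = 0.0
                w[-m:] = 0.0
            q[chrom][strand] = w
            total += w.sum()
    if total == 0:
        raise DataError("genome contains no dipyrimidine anchors")
    for chrom in q:
        for strand in ("+", "-"):
            q[chrom][strand] = q[chrom][strand] / total
    return q


def _positional_profile(offsets: np.ndarray, params: SimParams) -> np.ndarray:
    if params.decay == "uniform":
        return np.ones_like(offsets, dtype=float)
    return np.exp(-offsets / params.decay_length)


def survival_field(
    genome: Genome, genes: GeneSet, dyads: SignalTrack, params: SimParams
) -> StrandArrays:
    """Per-anchor survival S_i combining GG-NER and TS-restricted TC-NER."""
    occ_max = max((float(v.max()) for v in dyads.values()), default=0.0)
    survival: StrandArrays = {}
    for chrom in sorted(genome):
        occ = dyads[chrom] / occ_max if occ_max > 0 else np.zeros(genome.lengths[chrom])
        gg_rate = params.m_rad16 * params.k_gg * (1 - params.suppression * occ)
        base = np.exp(-params.t * gg_rate)
        survival[chrom] = {"+": base.copy(), "-": base.copy()}
    for g in genes:
        length = g.length
        if length is None:
            continue
        offsets = np.arange(length)
        pos = g.tss + offsets if g.strand == "+" else g.tss - offsets
        d = _positional_profile(offsets, params)
        tau = g.txn_freq if g.txn_freq is not None else 1.0
        rate = params.m_elf1ctd * params.m_rad26 * params.k_tc * tau * d
        survival[g.chrom][g.template_strand][pos] *= np.exp(-params.t * rate)
    return survival


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _flatten(arrays: StrandArrays) -> tuple[np.ndarray, list[tuple[str, str, int, int]]]:
    chunks, index = [], []
    pos = 0
    for chrom in sorted(arrays):
        for strand in ("+", "-"):
            a = arrays[chrom][strand]
            chunks.append(a)
            index.append((chrom, strand, pos, pos + len(a)))
            pos += len(a)
    return np.concatenate(chunks), index


def _sample_map(
    p: np.ndarray,
    index: list[tuple[str, str, int, int]],
    lengths: dict[str, int],
    depth: int,
    noise_frac: float,
    noise_support: np.ndarray,
    rng: np.random.Generator,
) -> LesionMap:
    lmap = LesionMap(lengths)
    n_noise = int(round(depth * noise_frac))
    n_signal = depth - n_noise
    counts = rng.multinomial(n_signal, p / p.sum())
    if n_noise:
        counts = counts + rng.multinomial(n_noise, noise_support / noise_support.sum())
    for chrom, strand, lo, hi in index:
        lmap.counts[chrom][strand] += counts[lo:hi].astype(np.int64)
    return lmap


def simulate_damage(
    genome: Genome, params: SimParams, rng: np.random.Generator | None = None
) -> tuple[StrandArrays, LesionMap]:
    """Damage field q plus a sampled 0 h lesion map at ``depth_0``."""
    rng = rng or np.random.default_rng(params.seed)
    q = damage_probabilities(genome, params)
    flat_q, index = _flatten(q)
    noise = _noise_support(genome, params)
    lmap = _sample_map(
        flat_q, index, genome.lengths, params.depth_0, params.noise_frac, noise, rng
    )
    return q, lmap


def _noise_support(genome: Genome, params: SimParams) -> np.ndarray:
    """Uniform support for noise lesions (any anchor clear of the edge margin)."""
    chunks = []
    m = params.edge_margin
    for chrom in sorted(genome):
        n = genome.lengths[chrom]
        vec = np.ones(n)
        if m > 0:
            vec[:m] = 0.0
            vec[-m:] = 0.0
        chunks.extend([vec, vec])
    return np.concatenate(chunks)


def simulate_repair(
    q: StrandArrays,
    survival: StrandArrays,
    genome: Genome,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> tuple[LesionMap, float]:
    """Sampled t-hour lesion map at ``depth_t`` plus the exact bulk G*."""
    rng = rng or np.random.default_rng(params.seed + 1)
    qs = {
        c: {s: q[c][s] * survival[c][s] for s in ("+", "-")} for c in q
    }
    flat_qs, index = _flatten(qs)
    flat_q, _ = _flatten(q)
    g_star = float(flat_qs.sum() / flat_q.sum())
    noise = _noise_support(genome, params)
    lmap = _sample_map(
        flat_qs, index, genome.lengths, params.depth_t, params.noise_frac, noise, rng
    )
    return lmap, g_star


def simulate_experiment(params: SimParams) -> SimExperiment:
    """Run the full generator deterministically from ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    genome, genes, dyads = simulate_genome(params, rng)
    q, lesions_0h = simulate_damage(genome, params, rng)
    survival = survival_field(genome, genes, dyads, params)
    lesions_t, g_star = simulate_repair(q, survival, genome, params, rng)
    return SimExperiment(
        params=params,
        genome=genome,
        genes=genes,
        dyads=dyads,
        q=q,
        survival=survival,
        lesions_0h=lesions_0h,
        lesions_t=lesions_t,
        g_star=g_star,
    )


# ---------------------------------------------------------------------------
# read emission (inverse of lesion inference)
# ---------------------------------------------------------------------------

def emit_reads(
    lmap: LesionMap,
    offset: OffsetConvention = OffsetConvention(),
    read_length: tuple[int, int] = (20, 40),
    rng: np.random.Generator | None = None,
    name_prefix: str = "r",
) -> tuple[pd.DataFrame, int]:
    """One BED read per lesion count, placed by the inverse read geometry.

    Returns ``(reads, n_unrepresentable)``: lesions whose read 5' end would
    fall off the chromosome cannot be emitted and are counted. Reads that
    would extend past a chromosome end are truncated (the 5' end, the only
    semantically meaningful coordinate, is preserved).
    """
    if offset.polarity != "opposite":
        raise DataError("emit_reads models the standard opposite-strand chemistry")
    rng = rng or np.random.default_rng(0)
    rows = []
    dropped = 0
    rid = 0
    for chrom, strand, anchor, count in lmap.nonzero():
        n = lmap.lengths[chrom]
        if strand == "+":
            p = anchor - 1 - offset.delta  # read on "-", 5' end at p
            if p < 0 or p > n - 1:
                dropped += count
                continue
            lens = rng.integers(read_length[0], read_length[1] + 1, size=count)
            for ln in lens:
                rid += 1
                start = max(0, p - int(ln) + 1)
                rows.append((chrom, start, p + 1, f"{name_prefix}{rid}", 0, "-"))
        else:
            p = anchor + 1 + offset.delta  # read on "+", 5' end at p
            if p < 0 or p > n - 1:
                dropped += count
                continue
            lens = rng.integers(read_length[0], read_length[1] + 1, size=count)
            for ln in lens:
                rid += 1
                end = min(n, p + int(ln))
                rows.append((chrom, p, end, f"{name_prefix}{rid}", 0, "+"))
    reads = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    if len(reads):
        reads["five_prime"] = np.where(
            reads["strand"] == "+", reads["start"], reads["end"] - 1
        )
    else:
        reads["five_prime"] = pd.Series([], dtype=np.int64)
    return reads, dropped


# ---------------------------------------------------------------------------
# analytic truth
# ---------------------------------------------------------------------------

@dataclass
class TruthReport:
    """Exact expectations implied by (q, S): no sampling anywhere."""

    per_bin: pd.DataFrame  # bin, kind, strand_class, expected fraction
    expected_average: float  # average log2(TS/NTS) over the six body bins
    g_star: float


def truth_report(
    exp: SimExperiment,
    n_body: int = N_BODY,
    n_flank: int = N_FLANK,
    flank_size: int = FLANK_SIZE,
) -> TruthReport:
    """Expected per-bin fractions remaining and asymmetry, by exact summation.

    For a bin B restricted to one strand class, the pipeline's normalized
    fraction-remaining estimator converges (with the gel scalar set to the
    true bulk G*) to ``sum_{i in B} q_i S_i / sum_{i in B} q_i``; the expected
    asymmetry average follows directly.
    """
    rows = []
    sums: dict[tuple[int, str, str], list[float]] = {}
    kinds: dict[int, str] = {}
    for gene in exp.genes.with_tes():
        chrom_len = exp.genome.lengths[gene.chrom]
        bins = gene_bins(gene, n_body, n_flank, flank_size, chrom_length=chrom_len)
        for b in bins:
            kinds[b.index] = b.kind
            for strand in ("+", "-"):
                sc = classify_strand(strand, gene.strand)
                qv = exp.q[gene.chrom][strand][b.start : b.end]
                sv = exp.survival[gene.chrom][strand][b.start : b.end]
                acc = sums.setdefault((b.index, b.kind, sc), [0.0, 0.0])
                acc[0] += float((qv * sv).sum())
                acc[1] += float(qv.sum())
    for (idx, kind, sc), (num, den) in sorted(sums.items()):
        rows.append(
            {
                "bin": idx,
                "kind": kind,
                "strand_class": sc,
                "expected_fraction": num / den if den > 0 else np.nan,
            }
        )
    per_bin = pd.DataFrame(rows)
    body = per_bin[per_bin["kind"] == "body"].pivot(
        index="bin", columns="strand_class", values="expected_fraction"
    )
    ratios = np.log2(body["TS"] / body["NTS"])
    expected_average = float(ratios.mean())
    return TruthReport(per_bin=per_bin, expected_average=expected_average, g_star=exp.g_star)


# ---------------------------------------------------------------------------
# strand-mirror transform (symmetry oracle)
# ---------------------------------------------------------------------------

def mirror_genome(genome: Genome) -> Genome:
    return Genome({c: revcomp(genome[c]) for c in genome})


def mirror_genes(genes: GeneSet, lengths: dict[str, int]) -> GeneSet:
    out = []
    for g in genes:
        n = lengths[g.chrom]
        out.append(
            GeneRecord(
                id=g.id,
                chrom=g.chrom,
                strand="-" if g.strand == "+" else "+",
                tss=n - 1 - g.tss,
                tes=None if g.tes is None else n - 1 - g.tes,
                txn_freq=g.txn_freq,
            )
        )
    return GeneSet(out)


def mirror_track(track: SignalTrack) -> SignalTrack:
    return SignalTrack({c: np.asarray(v)[::-1].copy() for c, v in track.items()})


def mirror_lesions(lmap: LesionMap) -> LesionMap:
    """Reverse-complement a lesion map: strands swap and coordinates flip.

    A plus-strand dimer {a, a+1} becomes a minus-strand dimer at the mirrored
    coordinates, whose 5'-in-strand anchor is ``L - 1 - a`` — so each strand
    vector is simply the other strand's vector reversed.
    """
    out = LesionMap(lmap.lengths, filtered=lmap.filtered)
    for chrom in lmap.counts:
        out.counts[chrom]["+"] = lmap.counts[chrom]["-"][::-1].copy()
        out.counts[chrom]["-"] = lmap.counts[chrom]["+"][::-1].copy()
    out.filter_losses = lmap.filter_losses
    out.oob_drops = lmap.oob_drops
    return out


def mirror_experiment(exp: SimExperiment) -> SimExperiment:
    """The reverse-complemented experiment; every profile must be invariant."""
    lengths = exp.genome.lengths
    return SimExperiment(
        params=exp.params,
        genome=mirror_genome(exp.genome),
        genes=mirror_genes(exp.genes, lengths),
        dyads=mirror_track(exp.dyads),
        q={
            c: {"+": exp.q[c]["-"][::-1].copy(), "-": exp.q[c]["+"][::-1].copy()}
            for c in exp.q
        },
        survival={
            c: {
                "+": exp.survival[c]["-"][::-1].copy(),
                "-": exp.survival[c]["+"][::-1].copy(),
            }
            for c in exp.survival
        },
        lesions_0h=mirror_lesions(exp.lesions_0h),
        lesions_t=mirror_lesions(exp.lesions_t),
        g_star=exp.g_star,
    )
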