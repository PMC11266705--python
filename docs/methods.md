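# Methods

## Coordinate and strand conventions

All internal coordinates are 0-based, half-open, genomic; BED input and
bedGraph share that dialect, wiggle output is 1-based. A gene is anchored by
its TSS and a TES derived from the polyadenylation site; the transcribed
span is `[tss, tes)` for plus-strand genes and `(tes, tss]` for minus-strand
genes, i.e. the TSS base is transcribed and the TES base is not, in both
orientations. A lesion is on the non-transcribed strand (NTS) of a gene
when its damaged strand equals the gene's annotated strand, and on the
transcribed/template strand (TS) otherwise.

Lesion maps index the 5' base of the dimer in damaged-strand orientation
(the "anchor"): a plus-strand anchor `a` covers genomic `{a, a+1}`, a
minus-strand anchor `a` covers `{a-1, a}` read 5'→3' as `(a, a-1)`.

## Read-to-lesion geometry

The assay's enzymatic digestion exposes a 3'-OH immediately upstream of the
dimer, so the ligated read begins one base 3' of the lesion on the strand
opposite the damage. Default geometry: a read 5' end at `p` on "+" places a
lesion at anchor `p-1` on "-"; a 5' end at `p` on "-" places one at `p+1`
on "+". Read length and 3' end carry no information and are ignored. The
exact published offset convention is protocol-defined rather than visible
in the data, so `calibrate_offset` scans shifts δ ∈ [−3, 3] in both strand
polarities and picks the one maximizing the dipyrimidine fraction of the
inferred anchors; under the correct geometry a UV sample is essentially
100 % dipyrimidine-anchored, so the score landscape is far from flat (a
flat one triggers an explicit "no offset signal" warning). Duplicate reads
are kept: the protocol gives no deduplication step, and collapsing by
(chrom, 5' end, strand) is available as an explicit option upstream of the
library if desired.

Anchors whose dimer does not fit on the chromosome are dropped and tallied,
so `reads = retained + filter losses + out-of-range drops` holds exactly.

## Fraction of CPDs remaining

All repair quantities are ratios of *aggregate* counts over identical
position sets, `f = scale · Σc_t / Σc_0`, never means of per-site ratios —
per-site 0 h counts are almost all 0 or 1 at realistic depth, where per-site
ratios are undefined or wildly unstable. The scale `G·T0/Tt` makes the
genome-wide fraction equal the bulk gel measurement `G` identically (this
is an algebraic identity, tested to 1e−12). Each condition carries its own
gel scalar; without one, `G = 1` (pure depth matching) is used and recorded
in the output metadata. Fractions above 1 are sampling noise and are never
clipped; a zero 0 h aggregate makes the fraction undefined (NaN), which
propagates as undefined rather than as 0 or infinity.

## Binning

Gene bodies are divided into six bins by the per-base rule: the base at
transcription-direction offset `o` of a gene of length `L` belongs to bin
`⌊6·o/L⌋`. The half-open intervals are *derived* from that rule (boundaries
at `⌈k·L/6⌉`), which fixes every boundary case unambiguously and makes the
partition testable base-by-base; bin sizes differ by at most 1 and cover
the span exactly. Three 167-bp flank bins extend upstream of the TSS and
downstream of the TES. Genes shorter than six bases, or without a TES, are
excluded from bin analyses (but TES-less genes still contribute to TSS
metaplots, mirroring the two different gene universes the two analyses
use). Overlapping genes are used as annotated; `--exclude-overlaps` removes
genes whose transcribed spans intersect, for sensitivity analysis. Flank
bins are not masked against neighbouring genes.

## Asymmetry statistic

Per bin, `log2(f_TS / f_NTS)` on aggregate fractions; the summary is the
mean over the six body bins. Undefined bins propagate: by default one
undefined body bin makes the average undefined, `allow_undefined=True`
averages the defined bins and reports how many. No pseudocounts are used
anywhere. A delta-method standard error accompanies each ratio and the
average, treating the four aggregate counts of a bin as independent Poisson
variables — an approximation (the counts are multinomial cells) that is
accurate for judging Monte-Carlo convergence, which is its only use here.

TSS metaplots default to a (−200, +640) window around the TSS; an optional
centered moving average (default width 11 nt) is applied only to a separate
smoothed column — unsmoothed values are always emitted and authoritative.
Nucleosome dyad coverage overlays are per-offset *means* over genes.

## Synthetic experiments

The generator emulates the statistical structure the analysis relies on,
with every expectation available in closed form:

* **Genome** — `n_chroms × chrom_length` (default 2 × 25 kb) i.i.d. bases,
  AT-rich (A = T = 0.31, C = G = 0.19) as in yeast. Genes (default 16, 0.6–1.8 kb,
  random strand) are packed without overlap, ≥ 510 bp apart so flank bins
  stay off neighbours; relative transcription frequencies τ_g are lognormal
  with unit mean (σ = 0.8). Nucleosome dyads phase from each TSS (+1 dyad
  at +60, 165 bp spacing, Gaussian occupancy kernel, σ = 30 bp).
* **Damage** — CPDs form only at dipyrimidine anchors with class weights
  TT : TC : CT : CC = 8 : 3 : 3 : 1, reproducing the observed enrichment
  order; `q_i ∝ w_class(i)`, normalized. Anchors within 5 bp of a chromosome
  end carry no damage, so the inverse read geometry can represent every
  sampled lesion — required for the bit-exact round-trip property and
  negligible (< 0.05 %) otherwise.
* **Repair** — exponential survival over `t` hours (default 2), the
  simplest kinetics with monotone fraction remaining:
  `S_i = exp(−t·[m_rad16·k_gg·(1 − a·occ_i) + 1{TS}·m_elf1ctd·m_rad26·k_tc·τ_g·d(o_i)])`.
  GG-NER (`k_gg = 0.35 /h`) acts on both strands and is suppressed near
  dyads with amplitude `a = 0.6`; TC-NER (`k_tc`) acts only on gene-body TS
  anchors, scaled by τ_g and a positional profile `d` (uniform over the
  body by default; an exponential decay option emulates a TSS-proximal
  signature). Genotype multipliers in [0, 1] attenuate the pathways
  independently — a deliberate simplification of the real epistasis —
  emulating CTD-truncation (`m_elf1ctd`), rad26-null (`m_rad26`) and
  rad16-null (`m_rad16`) conditions. The default `k_tc = 0.30 /h` was
  chosen so that the wild-type-like expected asymmetry averages ≈ −0.7
  across genome realizations, the magnitude reported for repair-proficient
  yeast; it is a calibration of the toy model, not a biological claim.
* **Sequencing** — both timepoints are single multinomial draws at the
  requested depth (totals are exact); t-hour probabilities ∝ `q_i·S_i`.
  An optional noise fraction places lesions uniformly over all anchors,
  emulating non-UV background. Reads are emitted by the exact inverse of
  the lesion geometry with uniform lengths (20–40 bp), truncated at
  chromosome ends with the 5' end preserved.

`truth_report` computes expectations by exact summation: the bulk fraction
`G* = Σq_iS_i / Σq_i`, and per bin/strand class
`E[f] = Σ_{i∈bin} q_iS_i / Σ_{i∈bin} q_i` — what the pipeline's estimator
converges to when normalized with `G*`. With TC-NER off the expected
asymmetry is not exactly 0 but a small composition term (TS and NTS anchor
sets sample the dyad-modulated GG survival differently), typically |·| < 0.01
at default geometry.

What the generator does **not** emulate: sequence-context photochemistry
beyond class weights, 6-4 photoproducts, mappability structure, replication
bias, gene overlap, and the richer rad26/elf1 epistasis. Passing tests
therefore demonstrate correctness of the coordinate logic, estimators and
invariances, not fidelity to any particular organism's repair kinetics.

## Problem sizes and determinism

Tests and the acceptance script use 50 kb genomes with 16 genes and depths
from 2×10⁵ (null and QC checks) to 2×10⁶ total (rate-grid convergence
checks, judged against exact expectations at 5 delta-method SE). A single
integer seed fixes the entire experiment; reruns are byte-identical, and
pipeline outputs carry a config hash and version instead of timestamps.

## Known limitations

* The text-wiggle reader supports variableStep/fixedStep with span, but not
  bigWig (out of scope; convert upstream if needed).
* Per-gene heatmap fractions are noisy at desk-scale depth (many NaN bins);
  they are intended for ordering/visualization, not inference.
* The delta-method SE ignores multinomial correlations between bins; it is
  a convergence diagnostic, not a published-quality uncertainty.
* Statistical comparison between conditions (e.g. testing two repair
  curves) is out of scope; outputs are descriptive.
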