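# Methods

## Problem and model

ADAR enzymes deaminate adenosine to inosine (read as guanosine by reverse
transcriptase and sequencer) in double-stranded RNA; APOBEC-family enzymes
deaminate cytidine to uridine. In mature miRNAs these edits appear in small
RNA-seq reads as A→G (sense strand) and C→U mismatches against the pre-miRNA
reference. Edits in the seed (mature positions 2–8) change which 3′UTRs the
miRNA can pair with, so distinguishing true editing from sequencing error,
and from germline variation, is the central inference problem.

`miredit` implements that inference as a pipeline of small, separately
testable stages over a precursor-space reference (1-based, sense-orientation
coordinates throughout):

1. **Preprocess** — 3′ adapter removal and a 15–28 nt length filter. An
   adapter hit is the leftmost position where a prefix of the adapter
   (≥ `min_overlap` = 8 bases, exact match) runs to the read end (or a full
   adapter occurs internally). Reads without a hit are retained and flagged:
   they may be adapter-free full-length inserts, and dropping them would bias
   against 28-nt matures.
2. **Map** — exhaustive ungapped placement of each read at every offset of
   every precursor, keeping the best mismatch stratum with a budget of one
   substitution. Reads with more than one equally good placement are
   discarded, not fractionally assigned: cross-mapping between paralogous
   precursors is the canonical artifact in miRNA-editing detection and a
   conservative policy makes site counts interpretable. Mapping directly to
   the precursor set (rather than genome-then-precursor) changes no
   site-level count for reads lying wholly within precursors and removes a
   genome-scale dependency. Identical read sequences are collapsed before
   alignment and re-expanded as pileup weights.
3. **Call** — at every covered position inside an expressed mature, the count
   k of each specific non-reference base among n covering reads is tested
   against Binomial(n, ε/3): per-base error rate ε (default 0.001, the
   typical Illumina substitution rate) spread uniformly over the three
   alternatives. The one-sided upper tail P(X ≥ k) is Bonferroni-corrected
   and calls require corrected p < α = 0.05.
4. **Filter** — any called site whose (precursor, position, ref, alt)
   matches a DNA-level variant (dbSNP-style or matched exome VCF) is moved to
   a removed list, labelled with the variant source. Matching is
   allele-aware: a variant with a different alternate allele does not veto a
   site.
5. **Annotate** — seed membership (in_seed ⇔ 2 ≤ mature position ≤ 8, with a
   seed-relative coordinate 1–7 = mature position − 1), the ±10 nt sequence
   window (truncated at precursor ends, never padded, so position-frequency
   columns stay interpretable), the immediate-neighbour UAG context (5′ U,
   3′ G around an edited A — the context most permissive for ADAR), and
   sliding trinucleotide counts over the precursor set.
6. **Structure** — MFE folding of the unedited and edited precursor
   (ViennaRNA, Turner parameters, 37 °C) and ΔΔG = ΔG_edited − ΔG_unedited;
   negative values mean the edit stabilizes the hairpin and ΔΔG ≤ −6.0
   kcal/mol is flagged as strong stabilization. The base "facing" the edited
   position is classified on the **unedited** structure (the substrate the
   enzyme sees): paired positions report their partner; an unpaired position
   reports `mismatch:<base>` only inside a symmetric internal loop, where the
   opposite position interpolates unambiguously as j − (pos − i) for
   innermost enclosing pair (i, j); bulges, asymmetric loops, multiloop
   interiors and terminal loops report `bulge/ambiguous`. The engine name and
   version are recorded in every structure table because MFE values are
   parameter-set dependent.
7. **Statistics** — per-sample percentage editing (edited matures /
   expressed matures × 100, per edit type, a mature with several sites
   counting once); per-event presence and median summaries across samples;
   the differential (hypo)editing screen; cluster enrichment; and 7-mer seed
   target scanning.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| ε (error_rate) | 0.001 | per-base substitution probability; per-alternative null uses ε/3. Optionally self-calibrated from non-canonical mismatches (below). |
| α | 0.05 | family-wise level after Bonferroni |
| min_depth | 10 reads | a mature with ≥ 10 overlapping reads counts as expressed; only expressed matures are tested and enter the percentage denominator |
| read length window | 15–28 nt | retained insert lengths after trimming |
| mismatch budget | 1 | ungapped alignment substitutions |
| min_overlap | 8 | adapter prefix length required for trimming |
| strong ΔΔG | −6.0 kcal/mol | strong-stabilization flag |
| min_presence | 3 | control samples in which an event must be called to enter the differential screen |
| min_samples_for_median | 3 | expressed samples needed before a group median is reported (otherwise "−") |

**Bonferroni family.** The family is every covered (position × alternative
base) hypothesis inside an expressed mature — 3 tests per covered position —
whether or not a mismatch was observed. Conditioning the family on observed
k ≥ 1 shrinks the correction by almost exactly the factor that inflates the
family-wise error above α (measured ≈ 0.08 on error-only simulations versus
≈ 0.005 for the full family); the full family is the definition under which
the filter actually delivers the error rate it promises.

**ε self-calibration.** Without per-base qualities, ε can be estimated from
mismatch classes that canonical editing cannot produce: all alternatives
except A→G at A positions and C→U at C positions. Each reference base
contributes a known number of counted error channels (2 of 3 for A and C,
3 of 3 for G and U), so the pooled count divided by channel-weighted depth is
an unbiased estimate of the full per-base rate.

**Expression threshold.** "Minimum read count 10" is applied per mature
miRNA (reads overlapping the mature interval), not per site; site depth is
reported alongside. Sites in a mature expressed in a sample but not called
there contribute level 0 to that sample's event median — without this
convention, fold-reduction contrasts against groups where editing collapses
to zero would be incomputable.

**Wilcoxon screen.** Events called in ≥ 3 samples of each control group are
tested control-vs-tumor with a two-tailed rank-sum test; direction (hypo vs
hyper) comes from group medians. When both groups have ≤ 8 values the exact
permutation null of the midrank statistic is enumerated over all group
assignments — correct under ties (ties are routine here because
expressed-but-uncalled samples contribute zeros) and identical to the
classical exact test without ties; larger designs use the normal
approximation with tie and continuity corrections. No multiple-testing
correction is applied across events; raw p-values are reported with a 0.05
flag.

**Proportion and enrichment tests.** Seed-fraction contrasts use the pooled
two-proportion z test with Yates continuity correction (on by default; the
correction is what reproduces the reference value 6.66 × 10⁻⁹ for the
44/60-vs-10/56 contrast — uncorrected gives ≈ 2 × 10⁻⁹). Cluster enrichment
(e.g. the chr14 miR-379/miR-656 cluster, C14MC) is the hypergeometric upper
tail of edited-within-cluster given the expressed miRnome; the cluster is
just a labelled id set from a two-column TSV, nothing is hard-coded.

**Seed targets.** The 7-mer at mature positions 2–8 (optionally with the
edited base substituted) is reverse-complemented to DNA and matched as an
exact substring against user-supplied 3′UTRs; membership, not site counts.
The before/after-editing overlap is 100·|before ∩ after| / |before|.

## Synthetic data

The generator plants known truth so every stage is testable without any
external download:

* reads are full-length mature sequences (no isomiR 5′/3′ heterogeneity —
  out of scope by design) with the TruSeq small RNA 3′ adapter appended and
  the result truncated to the 50-base instrument read length;
* per-mature depth is log-uniform over [10, 10⁴] by default (the dynamic
  range of expressed miRNAs), fixable to a constant for calibration designs;
* planted editing: each read covering a planted site carries the edited base
  independently with the configured per-group fraction; fractions span the
  sub-1 % to ~31 % range seen for real A-to-I events;
* sequencing error: uniform per-base rate (default 0.001), uniform over the
  three alternatives — exactly the caller's null, so calibration runs measure
  the caller, not a model mismatch;
* germline SNPs are homozygous (every read carries the alternate: a variant
  masquerading as 100 % "editing") and are emitted as a precursor-space
  VCF 4.2 for the DNA filter;
* constant 'I' qualities (Phred 40): the caller is quality-agnostic.

Everything is deterministic given (seed, sample id).

What the generator does **not** emulate: isomiR length variants, ligation and
PCR bias, position-dependent error profiles, cross-mapping families of
near-identical paralogs (random-sequence precursors are almost always
unique), RNA structure coupled to editing level, and heterozygous variants.
Passing tests therefore demonstrate the statistical machinery under the
model's own assumptions, not robustness to those real-data artifacts.

The standard cohort design (`simulate.hypoediting_cohort`) is 6 control + 5
tumor samples over 30 precursors: ten A>G sites planted at seed adenosines
with control fractions 0.05–0.30, a constant hypoediting factor 0.2 (a
5-fold reduction, e.g. 28 % → 5.6 %) in the tumor group, and two homozygous
SNPs on unedited precursors. Depth is fixed at 1000 reads per mature in this
design so that group comparisons measure the statistics rather than coverage
dropout; calibration of the caller itself (family-wise error at depth 100,
recovery at depth 150) runs on direct pileup-count simulation, since the
caller's operating characteristics depend only on the count table. Note that
with fixed depth 1000 even 5-fold-reduced tumor sites remain detectable, so
the binary percent-edited-miRNAs metric barely moves between groups; the
hypoediting signal lives in the editing *levels*, which is what the Wilcoxon
screen tests.

## Numerical choices and degenerate inputs

* Binomial tails via `scipy.stats.binom.sf` (exact survival function);
  verified in tests against term-by-term rational enumeration.
* ΔΔG of an identity edit is exactly 0 (the edited sequence is not re-folded).
* Stability categories use a 10⁻⁶ tolerance around 0; energies are rounded
  to 0.01 kcal/mol (the engine's printed precision).
* Zero expressed matures make percentage editing undefined: reported as
  absent, never as 0.
* Events untestable in the differential screen (fewer than 2 expressed
  samples in a side) are flagged, never silently dropped.
* Empty pileups, empty batches and header-only VCFs all produce empty —
  not missing — outputs.
* Aligner ties are never broken arbitrarily: ambiguity means discard.

## Limitations

* The fixed-ε binomial null ignores per-base quality scores; a
  quality-aware null would gain power at low depth.
* Ungapped alignment cannot place reads over indels (none are simulated).
* The facing-base rule answers "what is opposite this base" only where the
  geometry is unambiguous; asymmetric internal loops are reported as
  ambiguous rather than guessed.
* The recovery guarantee (sensitivity ≥ 0.9 for fractions ≥ 5 %) holds from
  depth ≈ 150 under the full-family Bonferroni correction; at depth exactly
  100 a 5 % site produces the required k ≥ 3 edited reads only ~88 % of the
  time, an information-theoretic limit of the design rather than an
  implementation artifact.
* Differential expression of miRNAs, genome-space variant calling, partition
  functions/base-pair probabilities, and 3D structure are out of scope.
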