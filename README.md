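# miredit

Detection and analysis of A-to-I (and C-to-U) editing in mature microRNAs
from small RNA sequencing reads.

ADAR enzymes deaminate adenosines to inosine in the double-stranded hairpin
of precursor miRNAs; inosine pairs like guanosine, so edited positions show
up in reads as A→G mismatches against the sense precursor. Edits inside the
seed (mature positions 2–8) redirect the miRNA's target repertoire, and loss
of editing (hypoediting) is a signature of ADAR2-poor tissue such as
glioblastoma. Separating genuine editing from sequencing error and from
germline variation — and then quantifying its sequence context, structural
consequences and group differences — is what this package does.

## The statistical core

For each covered position of an expressed mature miRNA (≥ 10 overlapping
reads), the count *k* of a specific non-reference base among *n* covering
reads is tested against the sequencing-error null

&nbsp;&nbsp;&nbsp;&nbsp;*k* ~ Binomial(*n*, ε/3),&nbsp;&nbsp;p = P(X ≥ k),

with per-base error ε (default 0.001) spread uniformly over the three
alternative bases. p-values are Bonferroni-corrected over every covered
(position × alternative base) hypothesis in the sample, and calls require
corrected p < 0.05. Called sites are filtered against DNA-level variants
(dbSNP-style and matched exome VCFs, allele-aware), annotated with seed
position and ±10 nt context, scored for hairpin stability change
ΔΔG = ΔG(edited) − ΔG(unedited) under a Turner-model MFE fold, and screened
for differential editing between sample groups with a two-tailed Wilcoxon
rank-sum test (exact permutation null for small groups). A synthetic-data
module plants known editing fractions, depths and SNPs so that every stage
is testable against ground truth without any external download.

## Worked example

```python
from miredit.data import load_mir411_reference
from miredit.structure import delta_delta_g
from miredit.stats import two_proportion_test

refset = load_mir411_reference()
result = delta_delta_g(refset, "hsa-mir-411", 20, "A>G")
print(result.dg_unedited, result.dg_edited, result.ddg, result.facing)
# -24.4 -31.0 -6.6 mismatch:C

z, p = two_proportion_test(44, 60, 10, 56)
print(round(z, 4), p)
# 5.7994 6.654565357832182e-09
```

The first block folds the hsa-mir-411 precursor with and without the known
seed edit at precursor position 20 (mature miR-411-5p position 5): the A sits
opposite an unpaired C in the hairpin stem, and the A→G edit closes that
mismatch into a G–C pair, stabilizing the hairpin by 6.6 kcal/mol — the
archetype of the A–C-mismatch mechanism by which editing promotes precursor
processing. The second block is the seed-enrichment contrast: 44/60 A-to-I
events in seed versus 10/56 for C-to-U gives p ≈ 6.7 × 10⁻⁹ under the
continuity-corrected two-proportion z test.

A full simulated study lives under `analysis/` (run the scripts in order
from that directory):

```bash
cd analysis
python 01_simulate_cohort.py     # 6 control + 5 tumor samples, planted truth
python 02_call_editing.py        # trim -> align -> call -> DNA-filter
python 03_annotate_and_structure.py
python 04_differential_editing.py
python 05_printed_examples.py
```

`04` prints, for the default seed:

```
tested (presence >= 3 in controls): 10
significant hypoediting (p < 0.05): 10
planted hypoedited events recovered: 10/10 (100%)
direction errors among significant calls: 0
```

Tables land under `results/`; FASTQs under `scratch/` (regenerated
deterministically on demand).

There is also a CLI mirroring the stages
(`miredit simulate / preprocess / map / call / annotate / structure / run /
report / targets`), driven by a YAML config for end-to-end runs; see
`miredit --help`.

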