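"""Shared setup for the numbered analysis scripts.

The study design is a simulated two-group brain cohort: 6 control and 5 tumor
small RNA-seq samples over 30 precursors, ten A-to-I sites planted at seed
adenosines with control editing fractions 5-30% and a 5-fold (factor 0.2)
hypoediting in the tumor group, plus two homozygous germline A>G SNPs on
unedited precursors. FASTQs land in scratch/ (regenerated deterministically
from COHORT_SEED on demand); tables land in results/.
"""

from pathlib import Path

from miredit.refset import load_variants
from miredit.simulate import hypoediting_cohort, simulate_cohort

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
COHORT_SEED = 1


def get_cohort():
    """(refset, sim config, fastq paths, truth, variant table); simulates on
    first use, reuses the deterministic on-disk FASTQs afterwards."""
    refset, sim = hypoediting_cohort(seed=COHORT_SEED)
    RESULTS.mkdir(exist_ok=True)
    fastqs = [SCRATCH / f"{sid}.fastq" for sid, _ in sim.samples]
    vcf = SCRATCH / "planted_snps.vcf"
    if not all(p.exists() for p in fastqs) or not vcf.exists():
        fastqs, truth, vcf = simulate_cohort(refset, sim, SCRATCH)
        truth.write_tsv(RESULTS / "truth_sites.tsv")
    else:
        _, truth, _ = simulate_cohort(refset, sim, SCRATCH)  # deterministic rebuild
    variants = load_variants([vcf], ["exome"])
    return refset, sim, fastqs, truth, variants
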