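"""Simulate the study cohort: 6 control + 5 tumor small RNA-seq samples with
planted A-to-I editing truth and germline SNPs.

Writes scratch/cohort/*.fastq, scratch/cohort/planted_snps.vcf and
results/truth_sites.tsv, and prints the design summary.
"""

from common import RESULTS, get_cohort


def main() -> None:
    refset, sim, fastqs, truth, _ = get_cohort()
    truth.write_tsv(RESULTS / "truth_sites.tsv")
    n_reads = sum(truth.total_reads(sid) for sid, _ in sim.samples)
    print(f"reference: {len(refset)} precursors")
    print(f"samples: {len(sim.samples)} ({len(fastqs)} FASTQs, {n_reads} reads)")
    print(f"planted sites: {len(sim.planted_sites)} (A>G, control fractions "
          f"{min(s.fractions['control'] for s in sim.planted_sites):.2f}-"
          f"{max(s.fractions['control'] for s in sim.planted_sites):.2f}, "
          f"tumor factor 0.2)")
    print(f"planted SNPs: {len(sim.planted_snps)} (homozygous A>G)")
    print(f"truth table: {RESULTS / 'truth_sites.tsv'}")


if __name__ == "__main__":
    main()
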