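"""Annotate called sites (seed membership, UAG context, motif PFM,
trinucleotide background) and score hairpin stability for the worked
hsa-mir-411 example.

Reads results/sites.tsv (from 02); writes results/pfm.tsv,
results/trinucleotides.tsv, results/mir411_stability.tsv and prints the seed
and context summaries.
"""

import pandas as pd

from common import RESULTS, get_cohort
from miredit.annotate import build_pfm, motif_window, trinucleotide_counts
from miredit.data import load_mir411_reference
from miredit.structure import delta_delta_g, stability_table


def main() -> None:
    refset, _, _, _, _ = get_cohort()
    sites = pd.read_csv(RESULTS / "sites.tsv", sep="\t")
    kept = sites[~sites.dna_variant]
    distinct = kept.drop_duplicates(subset=["precursor", "position", "obs"])
    seed_fraction = distinct.in_seed.mean()
    print(f"distinct called events: {len(distinct)}")
    print(f"fraction in seed (planting targeted the seed): {seed_fraction:.2%}")

    contexts = [
        motif_window(refset, r.precursor, int(r.position))
        for r in distinct.itertuples()
    ]
    uag = sum(c.uag_flag for c in contexts)
    print(f"UAG context (5'-U [A] G-3'): {uag}/{len(contexts)} events")
    build_pfm(contexts).to_csv(RESULTS / "pfm.tsv", sep="\t")
    trinucleotide_counts(refset).to_csv(RESULTS / "trinucleotides.tsv", sep="\t")

    # worked stability example: the known miR-411-5p seed edit
    mir411 = load_mir411_reference()
    result = delta_delta_g(mir411, "hsa-mir-411", 20, "A>G")
    stability_table([result]).to_csv(
        RESULTS / "mir411_stability.tsv", sep="\t", index=False
    )
    print(
        f"\nhsa-mir-411 A>G at position 20: dG {result.dg_unedited} -> "
        f"{result.dg_edited} kcal/mol, ddG = {result.ddg} "
        f"({result.category}, strong={result.strong_flag}, facing {result.facing})"
    )


if __name__ == "__main__":
    main()
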