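"""Call editing sites in every cohort sample: trim, align (<=1 mismatch),
binomial error-model calling with Bonferroni control, DNA-variant filtering.

Writes results/sites.tsv (all surviving + removed sites, all samples) and
results/profiles.tsv (per-sample percentage editing).
"""

import pandas as pd

from common import RESULTS, get_cohort
from miredit.editcall import CallerConfig, sites_to_frame
from miredit.pipeline import process_fastq_sample


def main() -> None:
    refset, sim, fastqs, _, variants = get_cohort()
    caller = CallerConfig()
    frames, prof_rows = [], []
    for (sid, group), fq in zip(sim.samples, fastqs):
        sc, profile, _, removed = process_fastq_sample(
            fq, refset, caller, sid, group, variants=variants
        )
        frames.append(sites_to_frame(sc.sites + removed))
        pct = profile.percent_editing("A-to-I")
        prof_rows.append(
            {
                "sample": sid,
                "group": group,
                "expressed": profile.expressed,
                "edited_A_to_I": profile.edited_by_type.get("A-to-I", 0),
                "percent_A_to_I": round(pct, 2) if pct is not None else "",
            }
        )
        print(
            f"{sid:10s} {group:8s} expressed={profile.expressed:3d} "
            f"sites={len(sc.sites):3d} removed_as_DNA={len(removed)}"
        )
    pd.concat(frames, ignore_index=True).to_csv(
        RESULTS / "sites.tsv", sep="\t", index=False
    )
    profiles = pd.DataFrame(prof_rows)
    profiles.to_csv(RESULTS / "profiles.tsv", sep="\t", index=False)
    by_group = profiles.groupby("group")["percent_A_to_I"].mean()
    print("\nmean percent A-to-I editing by group:")
    print(by_group.round(2).to_string())


if __name__ == "__main__":
    main()
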