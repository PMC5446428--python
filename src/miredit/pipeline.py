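"""End-to-end orchestration: trim -> align -> pileup -> call -> filter ->
annotate -> summarise -> cohort statistics, driven by a single YAML config.

Every stage writes its table under the run directory, and a provenance record
(tool and folding-engine versions, parameters, input checksums) accompanies
the results so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_sites, build_pfm
from .editcall import (
    CallerConfig,
    estimate_error_rate,
    call_sites,
    filter_dna_variants,
    sites_to_frame,
    summarize_sample,
)
from .mapper import build_pileup, map_batch, mature_read_counts
from .preprocess import TRUSEQ_SMALL_RNA_ADAPTER, preprocess_fastq
from .refset import ReferenceSet, load_reference, load_variants
from .stats import (
    SampleCalls,
    differential_screen,
    differential_to_frame,
    events_to_frame,
    summarize_events,
)
from .structure import delta_delta_g, stability_table


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class SampleSpec:
    sample_id: str
    fastq: Path
    group: str


@dataclasses.dataclass
class RunConfig:
    precursor_fasta: Path
    mature_table: Path
    samples: list
    cluster_table: Optional[Path] = None
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    min_len: int = 15
    max_len: int = 28
    max_mismatch: int = 1
    caller: CallerConfig = dataclasses.field(default_factory=CallerConfig)
    estimate_epsilon: bool = False
    variant_vcfs: list = dataclasses.field(default_factory=list)
    variant_sources: Optional[list] = None
    out_dir: Path = Path("miredit_run")
    test_group: Optional[str] = None
    control_groups: list = dataclasses.field(default_factory=list)
    min_presence: int = 3
    diff_alpha: float = 0.05
    min_samples_for_median: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            ref = raw["reference"]
            samples = [
                SampleSpec(s["id"], Path(s["fastq"]), s["group"])
                for s in raw["samples"]
            ]
            caller_raw = raw.get("caller", {})
            config = cls(
                precursor_fasta=Path(ref["fasta"]),
                mature_table=Path(ref["matures"]),
                cluster_table=Path(ref["clusters"]) if "clusters" in ref else None,
                samples=samples,
                adapter=raw.get("adapter", TRUSEQ_SMALL_RNA_ADAPTER),
                min_len=raw.get("min_len", 15),
                max_len=raw.get("max_len", 28),
                max_mismatch=raw.get("max_mismatch", 1),
                caller=CallerConfig(
                    error_rate=caller_raw.get("error_rate", 0.001),
                    alpha=caller_raw.get("alpha", 0.05),
                    min_depth=caller_raw.get("min_depth", 10),
                ),
                estimate_epsilon=caller_raw.get("estimate_error_rate", False),
                variant_vcfs=[Path(p) for p in raw.get("variants", [])],
                variant_sources=raw.get("variant_sources"),
                out_dir=Path(raw.get("out_dir", "miredit_run")),
                test_group=raw.get("differential", {}).get("test_group"),
                control_groups=raw.get("differential", {}).get("control_groups", []),
                min_presence=raw.get("differential", {}).get("min_presence", 3),
                diff_alpha=raw.get("differential", {}).get("alpha", 0.05),
            )
        except KeyError as exc:
            raise ConfigError(f"missing config key: {exc}") from exc
        return config

    def validate(self) -> None:
        paths = [self.precursor_fasta, self.mature_table, *self.variant_vcfs]
        if self.cluster_table:
            paths.append(self.cluster_table)
        paths += [s.fastq for s in self.samples]
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise ConfigError(f"missing input files: {missing}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ConfigError("sample ids must be unique")


def _checksum(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _table_header(params: dict) -> str:
    fields = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# miredit {__version__} | coordinates 1-based inclusive | {fields}\n"


def _write_tsv(df: pd.DataFrame, path: Path, params: dict) -> None:
    with open(path, "w") as fh:
        fh.write(_table_header(params))
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage for every sample; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    refset = load_reference(
        config.precursor_fasta, config.mature_table, config.cluster_table
    )
    variants = (
        load_variants(config.variant_vcfs, config.variant_sources)
        if config.variant_vcfs
        else None
    )

    params = {
        "adapter": config.adapter,
        "min_len": config.min_len,
        "max_len": config.max_len,
        "max_mismatch": config.max_mismatch,
        "error_rate": config.caller.error_rate,
        "alpha": config.caller.alpha,
        "min_depth": config.caller.min_depth,
    }
    provenance = {
        "miredit_version": __version__,
        "parameters": dict(params),
        "inputs": {
            str(p): _checksum(Path(p))
            for p in [
                config.precursor_fasta,
                config.mature_table,
                *config.variant_vcfs,
                *[s.fastq for s in config.samples],
            ]
        },
        "samples": [
            {"id": s.sample_id, "group": s.group, "fastq": str(s.fastq)}
            for s in config.samples
        ],
        "stage_counts": {},
    }
    try:
        from .structure import engine_version

        provenance["folding_engine"] = engine_version()
    except RuntimeError:
        provenance["folding_engine"] = None

    sample_calls = []
    profiles = []
    for spec in config.samples:
        stage = "preprocess"
        try:
            batch = preprocess_fastq(
                spec.fastq, config.adapter, min_len=config.min_len,
                max_len=config.max_len,
            )
            stage = "map"
            mapped = map_batch(batch, refset, config.max_mismatch)
            pileups = build_pileup(mapped.hits, refset, mapped.weights)
            counts = mature_read_counts(mapped.hits, refset, mapped.weights)
            stage = "call"
            caller = config.caller
            if config.estimate_epsilon and not pileups.empty:
                caller = dataclasses.replace(
                    caller, error_rate=max(1e-5, min(0.049, estimate_error_rate(pileups)))
                )
            sites = call_sites(
                pileups, refset, caller, counts, sample_id=spec.sample_id
            )
            stage = "filter_dna_variants"
            removed = []
            if variants is not None:
                sites, removed = filter_dna_variants(sites, variants, refset)
            stage = "annotate"
            sites, _ = annotate_sites(sites, refset)
            profile = summarize_sample(
                sites, pileups, refset, caller, counts,
                sample_id=spec.sample_id, group=spec.group,
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage {stage} failed for sample {spec.sample_id}: {exc}"
            ) from exc
        provenance["stage_counts"][spec.sample_id] = {
            "reads_in": batch.total_seen(),
            "reads_kept": len(batch),
            "reads_untrimmed": batch.untrimmed,
            "reads_assigned": mapped.n_assigned,
            "reads_unmapped": mapped.n_unmapped,
            "reads_ambiguous": mapped.n_ambiguous,
            "sites_called": len(sites) + len(removed),
            "sites_removed_dna": len(removed),
        }
        _write_tsv(pileups, out / f"{spec.sample_id}.pileup.tsv", params)
        _write_tsv(
            sites_to_frame(sites + removed), out / f"{spec.sample_id}.sites.tsv", params
        )
        sample_calls.append(SampleCalls.from_profile(profile, sites))
        profiles.append(profile)

    prof_rows = []
    for p in profiles:
        row = {"sample": p.sample_id, "group": p.group, "expressed": p.expressed}
        for t in ("A-to-I", "C-to-U"):
            pct = p.percent_editing(t)
            row[f"edited_{t}"] = p.edited_by_type.get(t, 0)
            row[f"percent_{t}"] = round(pct, 4) if pct is not None else ""
        prof_rows.append(row)
    _write_tsv(pd.DataFrame(prof_rows), out / "profiles.tsv", params)

    groups = sorted({s.group for s in config.samples})
    summaries = summarize_events(
        sample_calls, groups, config.min_samples_for_median
    )
    _write_tsv(events_to_frame(summaries, groups), out / "events.tsv", params)

    if config.test_group and config.control_groups:
        records = differential_screen(
            summaries,
            config.test_group,
            config.control_groups,
            alpha=config.diff_alpha,
            min_presence=config.min_presence,
        )
        _write_tsv(differential_to_frame(records), out / "differential.tsv", params)

    # structure report for every distinct called event (skipped without engine)
    if provenance["folding_engine"]:
        seen = set()
        results = []
        for sc in sample_calls:
            for site in sc.sites:
                key = (site.precursor_id, site.position, site.ref_base, site.obs_base)
                if key in seen or site.edit_type == "other":
                    continue
                seen.add(key)
                results.append(
                    delta_delta_g(
                        refset,
                        site.precursor_id,
                        site.position,
                        f"{site.ref_base}>{site.obs_base}",
                    )
                )
        if results:
            _write_tsv(stability_table(results), out / "structure.tsv", params)

    # motif summary over distinct sites
    distinct = {}
    for sc in sample_calls:
        for site in sc.sites:
            distinct.setdefault(
                (site.precursor_id, site.position), site
            )
    if distinct:
        _, contexts = annotate_sites(distinct.values(), refset)
        pfm = build_pfm(contexts)
        with open(out / "pfm.tsv", "w") as fh:
            fh.write(_table_header(params))
            pfm.to_csv(fh, sep="\t")

    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return out


def report(run_dir: str | Path) -> dict:
    """Machine-readable summary of a completed run."""
    run_dir = Path(run_dir)
    prov_path = run_dir / "provenance.json"
    if not prov_path.exists():
        raise FileNotFoundError(f"{run_dir} has no provenance.json (incomplete run)")
    with open(prov_path) as fh:
        provenance = json.load(fh)
    summary = {
        "miredit_version": provenance["miredit_version"],
        "n_samples": len(provenance["samples"]),
        "samples": {},
        "n_sites": 0,
        "seed_fraction": None,
        "differential_significant": 0,
    }
    profiles = pd.read_csv(run_dir / "profiles.tsv", sep="\t", comment="#")
    for row in profiles.itertuples(index=False):
        pct = row[4]
        summary["samples"][row.sample] = {
            "group": row.group,
            "expressed": int(row.expressed),
            "percent_A_to_I": float(pct) if pd.notna(pct) else None,
        }
    n_sites = 0
    n_seed = 0
    for spec in provenance["samples"]:
        sites = pd.read_csv(
            run_dir / f"{spec['id']}.sites.tsv", sep="\t", comment="#"
        )
        if not sites.empty:
            kept = sites[~sites["dna_variant"]]
            n_sites += len(kept)
            n_seed += int(kept["in_seed"].sum())
    summary["n_sites"] = n_sites
    summary["seed_fraction"] = round(n_seed / n_sites, 4) if n_sites else None
    diff_path = run_dir / "differential.tsv"
    if diff_path.exists():
        diff = pd.read_csv(diff_path, sep="\t", comment="#")
        if not diff.empty:
            summary["differential_significant"] = int(diff["significant"].sum())
    struct_path = run_dir / "structure.tsv"
    if struct_path.exists():
        struct = pd.read_csv(struct_path, sep="\t", comment="#")
        summary["stability_classes"] = struct["category"].value_counts().to_dict()
    with open(run_dir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def process_fastq_sample(
    fastq: Path | str,
    refset: ReferenceSet,
    caller: CallerConfig,
    sample_id: str,
    group: str = "",
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER,
    variants=None,
    max_mismatch: int = 1,
):
    """Programmatic single-sample path: trim -> map -> pileup -> call ->
    DNA-filter -> seed-annotate. Returns (SampleCalls, profile, pileups,
    removed_sites)."""
    batch = preprocess_fastq(fastq, adapter)
    mapped = map_batch(batch, refset, max_mismatch)
    pileups = build_pileup(mapped.hits, refset, mapped.weights)
    counts = mature_read_counts(mapped.hits, refset, mapped.weights)
    sites = call_sites(pileups, refset, caller, counts, sample_id=sample_id)
    removed = []
    if variants is not None:
        sites, removed = filter_dna_variants(sites, variants, refset)
    sites, _ = annotate_sites(sites, refset)
    profile = summarize_sample(
        sites, pileups, refset, caller, counts, sample_id=sample_id, group=group
    )
    return SampleCalls.from_profile(profile, sites), profile, pileups, removed
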