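"""End-to-end orchestration: features, nulls, summaries and comparisons.

``analyze`` is the in-memory core (records in, tables out); ``run_pipeline``
wraps it with file I/O, producing a fixed set of TSV artifacts in the
output directory.  Every artifact is deterministic for a given config and
master seed (no timestamps, fixed float formatting), so reruns are
byte-identical.
"""
from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import Alignment, code_gaps_binary, variable_and_pi_sites, write_alignment_stats, write_indel_matrix
from .energy import EnergyModel, default_model, load_energy_model
from .features import FEATURE_COLUMNS, StructureFeatures, featurize
from .fold import fold_suboptimal
from .nulls import NullMode, derive_seed, generate_null_cohort, write_provenance
from .records import REGIONS, SequenceRecord
from .seqio import dedupe_identical, filter_terminal_missing, read_fasta, read_metadata, write_fasta, write_removal_report
from .stats import describe, kruskal_wallis, mann_whitney_u

SUMMARY_FEATURES = ["length", "les", "n_structures", "n_hairpins", "n_paired", "pct_paired"]
TWO_GROUP_FEATURES = ["les", "n_structures", "n_hairpins", "n_paired", "pct_paired"]
NULL_FEATURES = ["les", "n_structures"]
KRUSKAL_FEATURES = ["les", "n_structures", "n_hairpins"]


@dataclass
class RunConfig:
    fasta: dict[str, str] = field(default_factory=dict)  # region -> path
    metadata: Optional[str] = None
    aligned: list[dict] = field(default_factory=list)  # {path, group, region}
    energy_params: Optional[str] = None
    master_seed: int = 0
    percent_window: float = 10.0
    max_structures: int = 20
    min_pair_distance: int = 3
    null_mode: NullMode = "composition"
    out_dir: str = "itsfold_out"
    max_terminal: int = 10
    id_whitelist: Optional[list[str]] = None
    collapse_tu: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True,
        )


@dataclass
class PipelineResult:
    features: pd.DataFrame        # per-sequence rows, real + null
    summary: pd.DataFrame         # mean (SD) per group x region
    tests: pd.DataFrame
    scatter: pd.DataFrame
    hairpin_freq: pd.DataFrame
    warnings: list[str]


def _feature_frame(rows: Sequence[StructureFeatures], cls: dict[str, str]) -> pd.DataFrame:
    recs = []
    for r in rows:
        d = {k: getattr(r, k) for k in FEATURE_COLUMNS}
        d["class"] = cls.get(r.id, r.region)
        recs.append(d)
    return pd.DataFrame(recs, columns=FEATURE_COLUMNS + ["class"])


def analyze(
    records_by_region: dict[str, list[SequenceRecord]],
    master_seed: int = 0,
    percent_window: float = 10.0,
    max_structures: int = 20,
    min_pair_distance: int = 3,
    null_mode: NullMode = "composition",
    model: EnergyModel | None = None,
) -> PipelineResult:
    """Fold every real sequence and its matched null, then compare groups.

    ``records_by_region`` maps ``"ITS1"``/``"ITS2"`` to record lists; either
    region may be absent (affected comparisons are skipped with a logged
    warning, never silently).
    """
    model = model or default_model()
    warnings_log: list[str] = []
    regions = [r for r in REGIONS if records_by_region.get(r)]
    if not regions:
        raise ValueError("no records in any region")

    reals: list[SequenceRecord] = []
    for region in regions:
        reals.extend(records_by_region[region])
    nulls = generate_null_cohort(reals, master_seed, mode=null_mode)

    def fold_one(rec: SequenceRecord) -> StructureFeatures:
        fr = fold_suboptimal(
            rec.ungapped(), model=model, percent_window=percent_window,
            max_structures=max_structures,
            min_pair_distance_between_structures=min_pair_distance,
        )
        return featurize(fr, rec)

    feats_real = [fold_one(r) for r in reals]
    feats_null = [fold_one(r) for r in nulls]
    cls = {f.id: f.region for f in feats_real}
    cls.update({f.id: "random" for f in feats_null})
    features = pd.concat(
        [_feature_frame(feats_real, cls), _feature_frame(feats_null, cls)],
        ignore_index=True,
    )

    # ---- Table-2-style summary: per group and overall, per class ---------
    summary_rows = []
    real_df = features[features["class"] != "random"]
    null_df = features[features["class"] == "random"]
    for region in regions:
        sub = real_df[real_df["region"] == region]
        groups = sorted(sub["group"].unique())
        for label, gdf in [(g, sub[sub["group"] == g]) for g in groups] + [("all", sub)]:
            row = {"region": region, "group": label, "n": len(gdf)}
            for feat in SUMMARY_FEATURES:
                s = describe(gdf[feat].to_numpy(), label=feat)
                row[feat] = f"{s.mean:.1f} ({s.sd:.1f})"
            summary_rows.append(row)
    if len(null_df):
        row = {"region": "random", "group": "all", "n": len(null_df)}
        for feat in SUMMARY_FEATURES:
            s = describe(null_df[feat].to_numpy(), label=feat)
            row[feat] = f"{s.mean:.1f} ({s.sd:.1f})"
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows, columns=["region", "group", "n"] + SUMMARY_FEATURES)

    # ---- rank tests -------------------------------------------------------
    test_rows = []
    test_idx = 0

    import warnings as _warnings

    def add_mw(label: str, feature: str, x, y, nx_label: str, ny_label: str):
        nonlocal test_idx
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            res = mann_whitney_u(
                list(x), list(y), seed=derive_seed(master_seed, 10_000 + test_idx)
            )
        for w in caught:
            warnings_log.append(f"{label}/{feature}: {w.message}")
        test_idx += 1
        test_rows.append({
            "comparison": label, "feature": feature, "method": res.method,
            "statistic": f"{res.statistic:.4f}", "p_value": f"{res.p_value:.6g}",
            "n": f"{nx_label}={res.n_per_group[0]},{ny_label}={res.n_per_group[1]}",
            "p_method": res.p_method,
            "effect_size": f"{res.effect_size:.4f}" if res.effect_size is not None else "",
        })

    if len(regions) == 2:
        its1 = real_df[real_df["region"] == "ITS1"]
        its2 = real_df[real_df["region"] == "ITS2"]
        for feat in TWO_GROUP_FEATURES:
            add_mw("ITS1_vs_ITS2", feat, its1[feat], its2[feat], "ITS1", "ITS2")
    else:
        warnings_log.append(
            f"only region {regions[0]} present: ITS1 vs ITS2 comparisons skipped"
        )

    for feat in NULL_FEATURES:
        add_mw("ITS_vs_random", feat, real_df[feat], null_df[feat], "ITS", "random")
    for region in regions:
        sub = real_df[real_df["region"] == region]
        nsub = null_df[null_df["region"] == region]
        for feat in NULL_FEATURES:
            add_mw(f"{region}_vs_random", feat, sub[feat], nsub[feat], region, "random")

    for region in regions:
        sub = real_df[real_df["region"] == region]
        groups = sorted(sub["group"].unique())
        if len(groups) < 2:
            warnings_log.append(
                f"{region}: fewer than 2 groups, Kruskal-Wallis skipped"
            )
            continue
        for feat in KRUSKAL_FEATURES:
            with _warnings.catch_warnings(record=True) as caught:
                _warnings.simplefilter("always")
                res = kruskal_wallis([
                    sub[sub["group"] == g][feat].to_numpy() for g in groups
                ])
            for w in caught:
                warnings_log.append(f"{region}_groups/{feat}: {w.message}")
            test_rows.append({
                "comparison": f"{region}_groups", "feature": feat,
                "method": res.method, "statistic": f"{res.statistic:.4f}",
                "p_value": f"{res.p_value:.6g}",
                "n": ",".join(f"{g}={n}" for g, n in zip(groups, res.n_per_group)),
                "p_method": res.p_method, "effect_size": "",
            })
    tests = pd.DataFrame(
        test_rows,
        columns=["comparison", "feature", "method", "statistic", "p_value", "n",
                 "p_method", "effect_size"],
    )

    scatter = features[["id", "les", "n_structures", "class"]].copy()

    freq_rows = []
    for region in regions:
        sub = real_df[real_df["region"] == region]
        counts = sub["n_hairpins"].value_counts().sort_index()
        for value, count in counts.items():
            freq_rows.append({"region": region, "n_hairpins": int(value), "count": int(count)})
    hairpin_freq = pd.DataFrame(freq_rows, columns=["region", "n_hairpins", "count"])

    return PipelineResult(features, summary, tests, scatter, hairpin_freq, warnings_log)


def _load_region_records(config: RunConfig) -> dict[str, list[SequenceRecord]]:
    meta = read_metadata(config.metadata) if config.metadata else None
    out: dict[str, list[SequenceRecord]] = {}
    removed_all: list[tuple[str, str]] = []
    for region, path in sorted(config.fasta.items()):
        if region not in REGIONS:
            raise ValueError(f"config fasta key {region!r} must be one of {REGIONS}")
        records = read_fasta(path, region=region, group_map=meta)
        records, removed = filter_terminal_missing(records, config.max_terminal)
        removed_all.extend(removed)
        records = dedupe_identical(records, collapse_tu=config.collapse_tu)
        if config.id_whitelist is not None:
            allowed = set(config.id_whitelist)
            records = [r for r in records if r.id in allowed]
        out[region] = records
    out["_removed"] = removed_all  # type: ignore[assignment]
    return out


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns a name -> path map of the artifacts."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = load_energy_model(config.energy_params) if config.energy_params else default_model()

    loaded = _load_region_records(config)
    removed = loaded.pop("_removed")
    records_by_region = {k: v for k, v in loaded.items() if v}

    result = analyze(
        records_by_region,
        master_seed=config.master_seed,
        percent_window=config.percent_window,
        max_structures=config.max_structures,
        min_pair_distance=config.min_pair_distance,
        null_mode=config.null_mode,
        model=model,
    )

    reals = [r for region in REGIONS for r in records_by_region.get(region, [])]
    nulls = generate_null_cohort(reals, config.master_seed, mode=config.null_mode)

    paths: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, lineterminator="\n")
        paths[name] = p

    save("features", result.features)
    save("summary", result.summary)
    save("tests", result.tests)
    save("scatter", result.scatter)
    save("hairpin_freq", result.hairpin_freq)

    write_fasta(nulls, out_dir / "nulls.fasta")
    paths["nulls_fasta"] = out_dir / "nulls.fasta"
    write_provenance(reals, nulls, config.master_seed, out_dir / "null_provenance.tsv")
    paths["null_provenance"] = out_dir / "null_provenance.tsv"
    write_removal_report(removed, out_dir / "removed.tsv")
    paths["removed"] = out_dir / "removed.tsv"

    # ---- alignment-side artifacts (optional) ------------------------------
    if config.aligned:
        stat_rows = []
        for entry in config.aligned:
            records = read_fasta(entry["path"], region=entry.get("region"))
            aln = Alignment.from_records(records, group=entry.get("group", ""))
            n_species = len({r.species for r in records if r.species}) or None
            stat_rows.append(
                (aln.group, aln.region, variable_and_pi_sites(aln, n_species=n_species))
            )
            matrix = code_gaps_binary(aln)
            name = f"indels_{aln.group or 'group'}_{aln.region}"
            write_indel_matrix(matrix, out_dir / f"{name}.tsv")
            paths[name] = out_dir / f"{name}.tsv"
        write_alignment_stats(stat_rows, out_dir / "alignment_stats.tsv")
        paths["alignment_stats"] = out_dir / "alignment_stats.tsv"

    log_lines = [
        f"itsfold {__version__}",
        f"python {sys.version.split()[0]} numpy {np.__version__} pandas {pd.__version__}",
        f"energy parameters: {model.source}",
        f"master_seed: {config.master_seed}",
        "config:",
        *("  " + ln for ln in config.to_yaml().splitlines()),
        "warnings:",
        *("  " + w for w in (result.warnings or ["none"])),
    ]
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    paths["run_log"] = out_dir / "run_log.txt"
    return paths
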