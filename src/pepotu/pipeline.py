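"""End-to-end pipeline: configuration, runners and report writers.

``run_profile`` takes a set of technical-replicate identification CSVs, an
accession→taxid map and a taxonomy, and produces post-consensus taxon
profiles for both counting workflows at every configured rank, together with
an exact per-replicate filter ledger. ``run_compare`` adds the per-peptide
LCA profile and divergence reports. ``run_simulate`` writes a complete
synthetic input bundle. All outputs are plain TSV/JSON and deterministic for
identical inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import ecology, lca, mascot, profiling, simulate
from .errors import PepotuError, ProfileError
from .profiling import TaxonProfile
from .taxonomy import RANKS, TaxonomyTree, read_taxonomy_tsv

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = (
    "rank",
    "taxid",
    "name",
    "count",
    "relative_abundance",
    "workflow_tag",
    "sample_id",
)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline settings, defaulting to the reference analysis:
    ion-score threshold 10 (inclusive), OTUs kept only when seen in at least
    2 of 3 technical replicates, replicate means below one peptide removed,
    small taxa merged into ``other`` below 1% of the total."""

    score_threshold: float = 10.0
    ranks: tuple[str, ...] = ("phylum", "class", "order", "family", "genus", "species")
    consensus_min_replicates: int = 2
    mean_floor: float = 1.0
    other_fraction: float = 0.01
    counting_mode: str = "dedup"
    consensus_average: str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.score_threshold < 0 or self.mean_floor < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 <= self.other_fraction < 1:
            raise ValueError("other_fraction must lie in [0, 1)")
        for r in self.ranks:
            if r not in RANKS:
                raise ValueError(f"unknown rank '{r}' in config")
        if self.counting_mode not in profiling.COUNTING_MODES:
            raise ValueError("counting_mode must be 'dedup' or 'occurrence'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "ranks" in data:
            data["ranks"] = tuple(data["ranks"])
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ranks"] = list(self.ranks)
        return d


@dataclass
class ProfileResult:
    """Everything a profiling run produces, before/after consensus."""

    config: PipelineConfig
    sample_id: str
    tree: TaxonomyTree = field(repr=False)
    #: (rank, workflow_tag) → consensus TaxonProfile
    consensus: dict[tuple[str, str], TaxonProfile] = field(repr=False)
    #: (rank, workflow_tag) → per-replicate TaxonProfiles
    per_replicate: dict[tuple[str, str], list[TaxonProfile]] = field(repr=False)
    #: replicate_index → filter-ledger counts
    ledgers: dict[int, dict] = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frames = []
        for (rank, tag), profile in sorted(self.consensus.items()):
            frames.append(profile_to_frame(profile, self.tree))
        table = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=PROFILE_COLUMNS)
        )
        table.to_csv(out / "profiles.tsv", sep="\t", index=False)
        table.to_json(out / "profiles.json", orient="records", indent=2)
        manifest = {
            "config": self.config.to_dict(),
            "sample_id": self.sample_id,
            "inputs": self.input_checksums,
            "filter_ledgers": {str(k): v for k, v in sorted(self.ledgers.items())},
        }
        (out / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def profile_to_frame(profile: TaxonProfile, tree: TaxonomyTree) -> pd.DataFrame:
    """Tabular form of a profile (the documented TSV/JSON schema)."""
    total = profile.total()
    rows = []
    for taxon, count in profile.counts.items():
        name = profiling.OTHER if taxon == profiling.OTHER else tree.name(int(taxon))
        rows.append(
            {
                "rank": profile.rank,
                "taxid": taxon,
                "name": name,
                "count": count,
                "relative_abundance": count / total if total > 0 else 0.0,
                "workflow_tag": profile.workflow_tag,
                "sample_id": profile.sample_id,
            }
        )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_replicates(
    replicate_csvs: Sequence[str | Path],
    accession_map_path: str | Path,
    taxonomy_path: str | Path,
    sample_id: str,
) -> tuple[list[mascot.ReplicateRun], TaxonomyTree, dict[str, str]]:
    for p in list(replicate_csvs) + [accession_map_path, taxonomy_path]:
        if not Path(p).exists():
            raise FileNotFoundError(f"missing input file: {p}")
    if len(replicate_csvs) < 2:
        raise PepotuError("at least 2 technical replicates are required for consensus")
    checksums = {}
    tree = read_taxonomy_tsv(taxonomy_path)
    mapping = mascot.read_accession_map(accession_map_path)
    runs = []
    for i, path in enumerate(replicate_csvs, start=1):
        run = mascot.read_mascot_csv(path, sample_id=sample_id, replicate_index=i)
        runs.append(mascot.map_to_taxa(run, mapping))
        checksums[Path(path).name] = _sha256(Path(path))
    checksums[Path(accession_map_path).name] = _sha256(Path(accession_map_path))
    checksums[Path(taxonomy_path).name] = _sha256(Path(taxonomy_path))
    return runs, tree, checksums


def run_profile(
    config: PipelineConfig,
    replicate_csvs: Sequence[str | Path],
    accession_map_path: str | Path,
    taxonomy_path: str | Path,
    sample_id: str = "sample",
    out_dir: str | Path | None = None,
    workflows: tuple[str, ...] = ("all", "unique"),
    with_lca: bool = False,
) -> ProfileResult:
    """Run admission → assignment → counting → consensus for one sample.

    Produces consensus profiles for the requested workflows at every
    configured rank that exists in the taxonomy. Expects 3 replicates but
    proceeds (with a warning) on any number ≥ 2.
    """
    runs, tree, checksums = _load_replicates(
        replicate_csvs, accession_map_path, taxonomy_path, sample_id
    )
    if len(runs) != 3:
        logger.warning("expected 3 technical replicates, got %d; proceeding", len(runs))

    ledgers: dict[int, dict] = {}
    all_assignments = []
    for run in runs:
        admitted = profiling.admit_hits(run, config.score_threshold)
        assignments = profiling.collect_assignments(admitted, tree)
        all_assignments.append(assignments)
        ledgers[run.replicate_index] = dict(admitted.meta)

    ranks = [r for r in config.ranks if tree.taxids_at_rank(r)]
    skipped = set(config.ranks) - set(ranks)
    if skipped:
        logger.info("ranks absent from taxonomy, skipped: %s", sorted(skipped))

    per_replicate: dict[tuple[str, str], list[TaxonProfile]] = {}
    consensus: dict[tuple[str, str], TaxonProfile] = {}
    counters = {
        "all": profiling.count_all_taxa,
        "unique": profiling.count_unique_taxa,
    }
    for rank in ranks:
        for tag in workflows:
            profiles = [
                counters[tag](a, rank, sample_id, config.counting_mode)
                for a in all_assignments
            ]
            per_replicate[(rank, tag)] = profiles
            consensus[(rank, tag)] = profiling.replicate_consensus(
                profiles,
                min_replicates=config.consensus_min_replicates,
                mean_floor=config.mean_floor,
                average=config.consensus_average,
            )
        if with_lca:
            profiles = [
                lca.lca_profile(a, tree, rank, sample_id) for a in all_assignments
            ]
            per_replicate[(rank, "lca")] = profiles
            consensus[(rank, "lca")] = profiling.replicate_consensus(
                profiles,
                min_replicates=config.consensus_min_replicates,
                mean_floor=config.mean_floor,
                average=config.consensus_average,
            )

    result = ProfileResult(
        config=config,
        sample_id=sample_id,
        tree=tree,
        consensus=consensus,
        per_replicate=per_replicate,
        ledgers=ledgers,
        input_checksums=checksums,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


@dataclass
class CompareResult:
    """Profiles for both workflows plus LCA, with divergence reports."""

    profile_result: ProfileResult
    #: rank → {('all','lca') report, ('unique','lca') report}
    reports: dict[str, dict[tuple[str, str], lca.DivergenceReport]]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.profile_result.write(out)
        summary = []
        for rank, pair_reports in sorted(self.reports.items()):
            for (tag_p, tag_q), report in sorted(pair_reports.items()):
                report.table.assign(rank=rank, tag_p=tag_p, tag_q=tag_q).to_csv(
                    out / f"compare_{rank}_{tag_p}_vs_{tag_q}.tsv",
                    sep="\t",
                    index=False,
                )
                summary.append(
                    {
                        "rank": rank,
                        "tag_p": tag_p,
                        "tag_q": tag_q,
                        "bray_curtis": report.bray_curtis,
                        "only_in_p": sorted(map(str, report.only_in_p)),
                        "only_in_q": sorted(map(str, report.only_in_q)),
                    }
                )
        (out / "compare_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def run_compare(
    config: PipelineConfig,
    replicate_csvs: Sequence[str | Path],
    accession_map_path: str | Path,
    taxonomy_path: str | Path,
    sample_id: str = "sample",
    out_dir: str | Path | None = None,
) -> CompareResult:
    """Profile with both workflows and LCA, then report their divergence."""
    base = run_profile(
        config,
        replicate_csvs,
        accession_map_path,
        taxonomy_path,
        sample_id=sample_id,
        with_lca=True,
    )
    reports: dict[str, dict[tuple[str, str], lca.DivergenceReport]] = {}
    for (rank, tag) in sorted(base.consensus):
        if tag != "lca":
            continue
        lca_prof = base.consensus[(rank, "lca")]
        reports[rank] = {}
        for other in ("all", "unique"):
            reports[rank][(other, "lca")] = lca.compare_profiles(
                base.consensus[(rank, other)], lca_prof
            )
    result = CompareResult(profile_result=base, reports=reports)
    if out_dir is not None:
        result.write(out_dir)
    return result


def run_simulate(
    generator_config: simulate.GeneratorConfig, seed: int, out_dir: str | Path
) -> Path:
    """Write a synthetic bundle; returns the manifest path."""
    return simulate.write_bundle(generator_config, seed, out_dir)


# -- small report helpers used by the CLI -------------------------------------


def diversity_table(
    result: ProfileResult, workflow_tag: str = "unique"
) -> pd.DataFrame:
    """Per-rank richness and Shannon–Wiener H' of the consensus profiles."""
    rows = []
    for (rank, tag), profile in sorted(result.consensus.items()):
        if tag != workflow_tag or not profile.counts:
            continue
        av = ecology.shannon_wiener(profile)
        rows.append(
            {
                "sample_id": profile.sample_id,
                "rank": rank,
                "richness": av.richness,
                "h_prime": av.h_prime,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "rank", "richness", "h_prime"])


def venn_regions_from_profiles(
    profiles: Mapping[str, TaxonProfile]
) -> dict[str, list]:
    """Exclusive shared-OTU regions of named samples' profiles (JSON-ready)."""
    ranks = {p.rank for p in profiles.values()}
    if len(ranks) > 1:
        raise ProfileError(f"profiles must share a rank, got {sorted(ranks)}")
    groups = {name: set(p.nonzero()) for name, p in profiles.items()}
    return {
        label: sorted(members, key=lambda x: (isinstance(x, str), x))
        for label, members in ecology.shared_otus(groups).items()
    }
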