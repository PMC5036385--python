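"""Peptide-counting workflows and replicate-consensus filtering.

The core of the pipeline: admitted peptide-spectrum matches are turned into
per-peptide taxon assignments, which are counted into per-rank taxon profiles
under two strategies,

* **all-matches counting** (:func:`count_all_taxa`): every peptide contributes
  one count to *every* taxon it matches at the requested rank — an inclusive
  picture that over-counts homologous branches but reflects overall evidence;
* **unique-taxon counting** (:func:`count_unique_taxa`): only peptides whose
  rank-level taxon set is a singleton contribute — a conservative picture that
  under-counts homology-rich taxa but avoids phantom identifications.

Hit admission applies the ion-score threshold first (default 10, inclusive),
then requires each hit to retain at least one bold-red peptide. Consensus
across technical replicates removes taxa seen in fewer than two replicates,
averages counts over all replicates (absences as zero) and removes taxa whose
mean falls below a floor of one peptide.

Every filter records row counts in ``run.meta`` so that the exact ledger

    input rows = retained + score-dropped + no-bold-red-dropped + unmapped-dropped

holds for each replicate.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .errors import ProfileError, UnknownRankError
from .mascot import ProteinHit, ReplicateRun
from .taxonomy import RANKS, TaxonomyTree

logger = logging.getLogger(__name__)

#: Reserved key for the merged low-abundance bucket.
OTHER = "other"

#: Recognised per-peptide counting modes. ``dedup`` counts each distinct
#: (sequence, taxon) pair once per replicate; ``occurrence`` counts it once
#: per admitted hit containing the sequence and supporting the taxon.
COUNTING_MODES = ("dedup", "occurrence")


@dataclass(frozen=True)
class PeptideTaxonAssignment:
    """One distinct peptide sequence and the taxa its proteins belong to.

    ``taxid_set`` is the union over every admitted hit (primary and same-set
    accessions) containing the sequence; ``rank_sets`` projects it to each
    canonical rank (taxa whose lineage lacks a rank are omitted from that
    rank's set); ``hit_rank_sets`` keeps each containing hit's own projection,
    used only by occurrence-mode counting.
    """

    sequence: str
    taxid_set: frozenset[int]
    rank_sets: Mapping[str, frozenset[int]]
    hit_rank_sets: tuple[Mapping[str, frozenset[int]], ...]


@dataclass(frozen=True)
class TaxonProfile:
    """Per-rank taxon → count map, tagged with the workflow that produced it."""

    rank: str
    counts: Mapping[int | str, float]
    workflow_tag: str
    sample_id: str

    def total(self) -> float:
        return float(sum(self.counts.values()))

    def taxa(self) -> set[int | str]:
        return set(self.counts)

    def get(self, taxon: int | str) -> float:
        return float(self.counts.get(taxon, 0.0))

    def nonzero(self) -> dict[int | str, float]:
        return {t: c for t, c in self.counts.items() if c > 0}


def _check_rank(rank: str) -> None:
    if rank not in RANKS:
        raise UnknownRankError(f"unknown rank '{rank}'; expected one of {RANKS}")


def _check_mode(mode: str) -> None:
    if mode not in COUNTING_MODES:
        raise ValueError(f"counting_mode must be one of {COUNTING_MODES}")


def _sorted_counts(counts: Mapping[int | str, float]) -> dict[int | str, float]:
    # deterministic ordering: integer taxids first, then the "other" bucket
    return {t: counts[t] for t in sorted(counts, key=lambda x: (isinstance(x, str), x))}


# -- hit admission ------------------------------------------------------------


def admit_hits(run: ReplicateRun, score_threshold: float = 10.0) -> ReplicateRun:
    """Apply the ion-score threshold, then the bold-red admission rule.

    Peptide matches with score below the threshold (inclusive retention:
    ``score >= threshold`` is kept) are removed; hits left without a single
    bold-red peptide after score filtering are removed entirely. Filter counts
    are recorded in ``meta``: ``input_rows``, ``score_dropped``,
    ``no_boldred_dropped`` and ``retained_rows``.
    """
    if score_threshold < 0:
        raise ValueError("score_threshold must be non-negative")
    input_rows = run.n_peptide_rows()
    score_dropped = 0
    no_boldred_dropped = 0
    new_hits: list[ProteinHit] = []
    for hit in run.hits:
        surviving = tuple(p for p in hit.peptides if p.score >= score_threshold)
        score_dropped += len(hit.peptides) - len(surviving)
        if not surviving:
            continue
        if not any(p.is_bold_red for p in surviving):
            no_boldred_dropped += len(surviving)
            continue
        new_hits.append(replace(hit, peptides=surviving))
    retained = sum(len(h.peptides) for h in new_hits)
    meta = dict(run.meta)
    meta.update(
        input_rows=input_rows,
        score_dropped=score_dropped,
        no_boldred_dropped=no_boldred_dropped,
        retained_rows=retained,
    )
    logger.info(
        "%s rep %d admission: %d rows -> %d retained (%d below score, %d no bold-red)",
        run.sample_id,
        run.replicate_index,
        input_rows,
        retained,
        score_dropped,
        no_boldred_dropped,
    )
    return replace(run, hits=tuple(new_hits), meta=meta)


# -- assignment collection ----------------------------------------------------


def _project(taxa: frozenset[int], tree: TaxonomyTree) -> dict[str, frozenset[int]]:
    return {
        rank: frozenset(
            a for a in (tree.ancestor_at_rank(t, rank) for t in taxa) if a is not None
        )
        for rank in RANKS
    }


def collect_assignments(
    run: ReplicateRun, tree: TaxonomyTree
) -> list[PeptideTaxonAssignment]:
    """Collect one taxon assignment per distinct peptide sequence in a run.

    The run must already be taxid-annotated (:func:`pepotu.mascot.map_to_taxa`)
    and admitted. A peptide's taxon set is the union of the taxid sets of all
    admitted hits containing it. Peptides whose every containing hit is fully
    unmapped are dropped; the count of their rows goes to
    ``run.meta['unmapped_dropped']`` and the ledger's final retained count to
    ``run.meta['retained_final']``.
    """
    per_seq_hits: dict[str, list[frozenset[int]]] = defaultdict(list)
    per_seq_rows: Counter = Counter()
    for hit in run.hits:
        hit_taxa = hit.taxid_set
        seen_in_hit: set[str] = set()
        for pep in hit.peptides:
            per_seq_rows[pep.sequence] += 1
            if pep.sequence not in seen_in_hit:
                per_seq_hits[pep.sequence].append(hit_taxa)
                seen_in_hit.add(pep.sequence)

    assignments: list[PeptideTaxonAssignment] = []
    unmapped_rows = 0
    for seq in sorted(per_seq_hits):
        hit_sets = tuple(s for s in per_seq_hits[seq] if s)
        union = frozenset().union(*hit_sets) if hit_sets else frozenset()
        if not union:
            unmapped_rows += per_seq_rows[seq]
            continue
        assignments.append(
            PeptideTaxonAssignment(
                sequence=seq,
                taxid_set=union,
                rank_sets=_project(union, tree),
                hit_rank_sets=tuple(_project(s, tree) for s in hit_sets),
            )
        )
    run.meta["unmapped_dropped"] = unmapped_rows
    run.meta["retained_final"] = run.meta.get("retained_rows", 0) - unmapped_rows
    if unmapped_rows:
        logger.info(
            "%s rep %d: %d peptide rows dropped (no mapped accession)",
            run.sample_id,
            run.replicate_index,
            unmapped_rows,
        )
    return assignments


# -- counting workflows -------------------------------------------------------


def count_all_taxa(
    assignments: Iterable[PeptideTaxonAssignment],
    rank: str,
    sample_id: str = "",
    counting_mode: str = "dedup",
) -> TaxonProfile:
    """All-matches counting: each peptide adds 1 to every taxon in its rank set.

    In ``dedup`` mode (default) a sequence contributes once per taxon; in
    ``occurrence`` mode it contributes once per admitted hit whose own taxa
    project onto that taxon.
    """
    _check_rank(rank)
    _check_mode(counting_mode)
    counts: Counter = Counter()
    for a in assignments:
        if counting_mode == "dedup":
            for t in a.rank_sets[rank]:
                counts[t] += 1
        else:
            for hit_proj in a.hit_rank_sets:
                for t in hit_proj[rank]:
                    counts[t] += 1
    return TaxonProfile(rank, _sorted_counts(counts), "all", sample_id)


def count_unique_taxa(
    assignments: Iterable[PeptideTaxonAssignment],
    rank: str,
    sample_id: str = "",
    counting_mode: str = "dedup",
) -> TaxonProfile:
    """Unique-taxon counting: only peptides with a singleton rank set count."""
    _check_rank(rank)
    _check_mode(counting_mode)
    counts: Counter = Counter()
    for a in assignments:
        rset = a.rank_sets[rank]
        if len(rset) != 1:
            continue
        (taxon,) = rset
        if counting_mode == "dedup":
            counts[taxon] += 1
        else:
            counts[taxon] += sum(
                1 for hit_proj in a.hit_rank_sets if taxon in hit_proj[rank]
            )
    return TaxonProfile(rank, _sorted_counts(counts), "unique", sample_id)


# -- replicate consensus and post-processing ----------------------------------


def replicate_consensus(
    profiles: Sequence[TaxonProfile],
    min_replicates: int = 2,
    mean_floor: float = 1.0,
    average: str = "all",
) -> TaxonProfile:
    """Consensus profile over technical replicates of one sample.

    Taxa present (count > 0) in fewer than ``min_replicates`` replicates are
    removed; the survivors' counts are averaged — over all R replicates with
    absences as zero when ``average='all'`` (default), or over the replicates
    where the taxon appears when ``average='nonzero'`` — and taxa whose mean
    falls below ``mean_floor`` are removed.
    """
    if len(profiles) < 2:
        raise ProfileError("consensus requires at least 2 replicate profiles")
    if average not in ("all", "nonzero"):
        raise ValueError("average must be 'all' or 'nonzero'")
    first = profiles[0]
    for p in profiles[1:]:
        if p.rank != first.rank or p.workflow_tag != first.workflow_tag:
            raise ProfileError(
                "replicate profiles must share rank and workflow tag; got "
                f"({p.rank},{p.workflow_tag}) vs ({first.rank},{first.workflow_tag})"
            )
        if p.sample_id != first.sample_id:
            raise ProfileError("replicate profiles must share sample_id")
    n_rep = len(profiles)
    taxa = sorted(
        set().union(*(p.taxa() for p in profiles)),
        key=lambda x: (isinstance(x, str), x),
    )
    counts: dict[int | str, float] = {}
    for taxon in taxa:
        values = [p.get(taxon) for p in profiles]
        presence = sum(1 for v in values if v > 0)
        if presence < min_replicates:
            continue
        denom = n_rep if average == "all" else presence
        mean = sum(values) / denom
        if mean < mean_floor:
            continue
        counts[taxon] = mean
    return TaxonProfile(first.rank, counts, first.workflow_tag, first.sample_id)


def to_relative(profile: TaxonProfile) -> TaxonProfile:
    """Normalise counts to relative abundances summing to one."""
    total = profile.total()
    if total <= 0:
        raise ProfileError("cannot normalise an empty or all-zero profile")
    counts = {t: c / total for t, c in profile.counts.items()}
    return replace(profile, counts=counts)


def group_other(profile: TaxonProfile, min_fraction: float = 0.01) -> TaxonProfile:
    """Merge taxa below ``min_fraction`` of the total into the ``other`` bucket.

    The total is conserved exactly; ``min_fraction`` of zero is the identity.
    """
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must lie in [0, 1)")
    total = profile.total()
    threshold = min_fraction * total
    kept: dict[int | str, float] = {}
    other = profile.get(OTHER)
    for taxon, count in profile.counts.items():
        if taxon == OTHER:
            continue
        if count < threshold:
            other += count
        else:
            kept[taxon] = count
    if other > 0 or OTHER in profile.counts:
        kept[OTHER] = other
    return replace(profile, counts=_sorted_counts(kept))
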