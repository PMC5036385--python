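"""Lowest-common-ancestor peptide assignment and profile divergence.

This is the comparator arm of the pipeline: the per-peptide LCA strategy used
by tools such as Unipept. Peptide sequences are canonicalised by equating
isoleucine and leucine (isobaric, indistinguishable by mass), deduplicated
(taxon sets of merged variants are unioned), and each peptide is assigned to
the lowest common ancestor of all taxa whose proteins contain it. At a given
rank, a peptide counts once toward its assigned taxon's rank-level ancestor;
peptides whose LCA is *shallower* than the rank are dropped from that rank's
profile (rank-level treemap semantics) rather than bucketed at an ancestor.

Because homologous peptides shared across genera of one family resolve only
to the family, genera in homology-rich branches lose counts under LCA that
all-matches counting retains — the divergence :func:`compare_profiles`
quantifies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import ProfileError
from .profiling import PeptideTaxonAssignment, TaxonProfile, _check_rank, _sorted_counts
from .taxonomy import TaxonomyTree


def equate_il(sequence: str) -> str:
    """Replace every L with I (idempotent); I/L are isobaric in MS."""
    return sequence.replace("L", "I")


@dataclass(frozen=True)
class LcaAssignment:
    """An I/L-equated peptide and the taxon its evidence resolves to."""

    canonical_sequence: str
    assigned_taxid: int


def lca_assignments(
    assignments: Iterable[PeptideTaxonAssignment], tree: TaxonomyTree
) -> list[LcaAssignment]:
    """Canonicalise, deduplicate and LCA-assign a replicate's peptides.

    I/L variants merge into one canonical sequence whose taxid set is the
    union of the variants' sets before the LCA is taken.
    """
    merged: dict[str, set[int]] = {}
    for a in assignments:
        canon = equate_il(a.sequence)
        merged.setdefault(canon, set()).update(a.taxid_set)
    return [
        LcaAssignment(seq, tree.lca(taxa))
        for seq, taxa in sorted(merged.items())
        if taxa
    ]


def lca_profile(
    assignments: Iterable[PeptideTaxonAssignment],
    tree: TaxonomyTree,
    rank: str,
    sample_id: str = "",
) -> TaxonProfile:
    """Per-peptide LCA profile at ``rank`` (workflow tag ``lca``).

    Each deduplicated peptide contributes 1 to the rank-level ancestor of its
    LCA, or is dropped when the LCA sits above the requested rank.
    """
    _check_rank(rank)
    counts: Counter = Counter()
    for la in lca_assignments(assignments, tree):
        taxon = tree.ancestor_at_rank(la.assigned_taxid, rank)
        if taxon is not None:
            counts[taxon] += 1
    return TaxonProfile(rank, _sorted_counts(counts), "lca", sample_id)


# -- divergence reporting -----------------------------------------------------


@dataclass(frozen=True)
class DivergenceReport:
    """Per-taxon differences between two same-rank profiles.

    ``bray_curtis`` is computed on the relative profiles (0 identical,
    1 disjoint) and is symmetric in the two inputs; the table covers the
    union of taxa.
    """

    rank: str
    tag_p: str
    tag_q: str
    table: pd.DataFrame = field(repr=False)
    bray_curtis: float
    only_in_p: frozenset[int | str]
    only_in_q: frozenset[int | str]


def bray_curtis(p: Mapping[int | str, float], q: Mapping[int | str, float]) -> float:
    """Bray–Curtis dissimilarity between two abundance maps.

    ``BC = Σ|p_i − q_i| / Σ(p_i + q_i)`` over the union of keys; two empty
    maps are identical (0).
    """
    taxa = set(p) | set(q)
    num = sum(abs(p.get(t, 0.0) - q.get(t, 0.0)) for t in taxa)
    den = sum(p.get(t, 0.0) + q.get(t, 0.0) for t in taxa)
    return num / den if den > 0 else 0.0


def compare_profiles(p: TaxonProfile, q: TaxonProfile) -> DivergenceReport:
    """Quantify the divergence between two same-rank profiles.

    Reports the per-taxon count difference (q − p) over the union of taxa,
    the Bray–Curtis dissimilarity of the *relative* profiles, and the taxa
    present in exactly one profile.
    """
    if p.rank != q.rank:
        raise ProfileError(f"profiles must share a rank: {p.rank} vs {q.rank}")
    taxa = sorted(p.taxa() | q.taxa(), key=lambda x: (isinstance(x, str), x))
    table = pd.DataFrame(
        {
            "taxon": taxa,
            "count_p": [p.get(t) for t in taxa],
            "count_q": [q.get(t) for t in taxa],
        }
    )
    table["delta"] = table["count_q"] - table["count_p"]
    tp, tq = p.total(), q.total()
    rel_p = {t: p.get(t) / tp for t in p.counts} if tp > 0 else {}
    rel_q = {t: q.get(t) / tq for t in q.counts} if tq > 0 else {}
    bc = bray_curtis(rel_p, rel_q)
    pn, qn = set(p.nonzero()), set(q.nonzero())
    return DivergenceReport(
        rank=p.rank,
        tag_p=p.workflow_tag,
        tag_q=q.workflow_tag,
        table=table,
        bray_curtis=bc,
        only_in_p=frozenset(pn - qn),
        only_in_q=frozenset(qn - pn),
    )
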