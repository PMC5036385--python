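"""Parsing of Mascot-style CSV identification exports.

Real Mascot exports vary by version, so the package defines one minimal
canonical dialect that the parser and the synthetic generator agree on
bit-exactly: UTF-8, comma-separated, RFC-4180 quoting, a header row with six
mandatory columns

    prot_hit_num, prot_acc, prot_sameset_accs, pep_seq, pep_score, pep_isbold

and optional preamble lines before the header (skipped). ``prot_sameset_accs``
is a semicolon-joined list of the co-listed proteins sharing the hit's peptide
set. ``pep_isbold`` is the per-row bold-red flag (top-ranking, first-occurrence
match); the hit-level admission rule ("at least one bold-red peptide") is
applied downstream in :mod:`pepotu.profiling`, not here — the parser is
policy-free. Modified-residue notation (e.g. ``M(ox)``) is stripped to the
bare residue string at parse time.

FDR control is assumed already applied upstream by the search engine; no
score-based filtering happens here.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, TextIO

from .errors import MascotFormatError

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = (
    "prot_hit_num",
    "prot_acc",
    "prot_sameset_accs",
    "pep_seq",
    "pep_score",
    "pep_isbold",
)

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

_MOD_RE = re.compile(r"[\(\[][^\)\]]*[\)\]]")
_NONALPHA_RE = re.compile(r"[^A-Za-z]")

_TRUE_TOKENS = {"1", "true", "t", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n", ""}


@dataclass(frozen=True)
class PeptideMatch:
    """One peptide-spectrum match row: bare sequence, ion score, bold-red flag."""

    sequence: str
    score: float
    is_bold_red: bool
    replicate_index: int


@dataclass(frozen=True)
class ProteinHit:
    """One ranked protein hit with its co-listed same-set proteins and peptides."""

    primary_accession: str
    sameset_accessions: tuple[str, ...]
    hit_rank: int
    peptides: tuple[PeptideMatch, ...]
    #: accession → taxid, filled by :func:`map_to_taxa` (mapped accessions only)
    accession_taxids: Mapping[str, int] = field(default_factory=dict)

    @property
    def accessions(self) -> tuple[str, ...]:
        return (self.primary_accession,) + self.sameset_accessions

    @property
    def taxid_set(self) -> frozenset[int]:
        """Taxa of this hit's mapped accessions (empty before map_to_taxa)."""
        return frozenset(self.accession_taxids.values())


@dataclass(frozen=True)
class ReplicateRun:
    """One technical replicate's parsed identification list."""

    sample_id: str
    replicate_index: int
    hits: tuple[ProteinHit, ...]
    unmapped_accessions: Counter = field(default_factory=Counter)
    #: bookkeeping: rejected row count at parse time, filter-ledger counts later
    meta: dict = field(default_factory=dict)

    def n_peptide_rows(self) -> int:
        return sum(len(h.peptides) for h in self.hits)


def clean_sequence(raw: str) -> str | None:
    """Strip modification tags and delimiters; return the bare residue string.

    Returns None if the result is empty or contains a non-canonical residue.
    """
    s = _MOD_RE.sub("", raw)
    s = _NONALPHA_RE.sub("", s).upper()
    if not s or any(c not in CANONICAL_RESIDUES for c in s):
        return None
    return s


def _parse_bool(token: str) -> bool | None:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    return None


def _as_text(source: str | Path | TextIO) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline=""), True
    return source, False


def read_mascot_csv(
    source: str | Path | TextIO, sample_id: str, replicate_index: int
) -> ReplicateRun:
    """Parse a canonical-dialect identification CSV into a :class:`ReplicateRun`.

    Preamble lines before the header are skipped. Rows with an unparsable
    score, flag or sequence are rejected with a logged warning (counted in
    ``run.meta['rejected_rows']``), never dropped silently. A header with no
    body yields an empty run; a missing header raises
    :class:`MascotFormatError` listing the absent columns.
    """
    if replicate_index < 1:
        raise ValueError("replicate_index must be >= 1")
    fh, own = _as_text(source)
    try:
        header: list[str] | None = None
        best_missing: set[str] = set(MANDATORY_COLUMNS)
        reader = csv.reader(fh)
        for row in reader:
            present = set(row) & set(MANDATORY_COLUMNS)
            if present:
                missing = set(MANDATORY_COLUMNS) - set(row)
                if not missing:
                    header = row
                    break
                if len(missing) < len(best_missing):
                    best_missing = missing
        if header is None:
            raise MascotFormatError(
                "no header row with the mandatory columns; missing: "
                + ", ".join(sorted(best_missing))
            )
        col = {name: header.index(name) for name in MANDATORY_COLUMNS}

        rejected = 0
        # hit number → (primary, sameset, [peptides]) in first-seen order
        groups: dict[int, tuple[str, tuple[str, ...], list[PeptideMatch]]] = {}
        for row in reader:
            if not any(f.strip() for f in row):
                continue
            try:
                hit_num = int(row[col["prot_hit_num"]])
                score = float(row[col["pep_score"]])
            except (ValueError, IndexError):
                logger.warning("rejecting unparsable row: %r", row)
                rejected += 1
                continue
            flag = _parse_bool(row[col["pep_isbold"]])
            seq = clean_sequence(row[col["pep_seq"]])
            if flag is None or seq is None or score < 0:
                logger.warning("rejecting unparsable row: %r", row)
                rejected += 1
                continue
            acc = row[col["prot_acc"]].strip()
            if not acc:
                logger.warning("rejecting row with empty accession: %r", row)
                rejected += 1
                continue
            sameset = tuple(
                a.strip()
                for a in row[col["prot_sameset_accs"]].split(";")
                if a.strip()
            )
            match = PeptideMatch(seq, score, flag, replicate_index)
            if hit_num not in groups:
                groups[hit_num] = (acc, sameset, [match])
            else:
                groups[hit_num][2].append(match)
        hits = tuple(
            ProteinHit(
                primary_accession=primary,
                sameset_accessions=sameset,
                hit_rank=hit_num,
                peptides=tuple(peps),
            )
            for hit_num, (primary, sameset, peps) in sorted(groups.items())
        )
        return ReplicateRun(
            sample_id=sample_id,
            replicate_index=replicate_index,
            hits=hits,
            meta={"rejected_rows": rejected},
        )
    finally:
        if own:
            fh.close()


def write_mascot_csv(run: ReplicateRun, dest: str | Path | TextIO) -> None:
    """Write a run back to the canonical dialect (structure round-trips)."""
    own = isinstance(dest, (str, Path))
    fh: TextIO = open(dest, "w", encoding="utf-8", newline="") if own else dest  # type: ignore[arg-type]
    try:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(MANDATORY_COLUMNS)
        for hit in run.hits:
            for pep in hit.peptides:
                writer.writerow(
                    [
                        hit.hit_rank,
                        hit.primary_accession,
                        ";".join(hit.sameset_accessions),
                        pep.sequence,
                        repr(pep.score),
                        int(pep.is_bold_red),
                    ]
                )
    finally:
        if own:
            fh.close()


# -- accession → taxid mapping ------------------------------------------------

#: accession → taxid map (accessions unique, taxids positive)
AccessionTaxidMap = dict[str, int]


def read_accession_map(source: str | Path | TextIO) -> dict[str, int]:
    """Read a 2-column (accession, taxid) TSV with a header row."""
    fh, own = _as_text(source)
    try:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise MascotFormatError("accession map must have 2 tab-separated columns")
        entries: dict[str, int] = {}
        for line in fh:
            if not line.strip():
                continue
            acc, taxid_s = line.rstrip("\n").split("\t")[:2]
            taxid = int(taxid_s)
            if taxid <= 0:
                raise MascotFormatError(f"taxid must be positive for {acc!r}")
            if acc in entries and entries[acc] != taxid:
                raise MascotFormatError(f"conflicting taxids for accession {acc!r}")
            entries[acc] = taxid
        return entries
    finally:
        if own:
            fh.close()


def write_accession_map(mapping: Mapping[str, int], dest: str | Path | TextIO) -> None:
    own = isinstance(dest, (str, Path))
    fh: TextIO = open(dest, "w", encoding="utf-8") if own else dest  # type: ignore[arg-type]
    try:
        fh.write("accession\ttaxid\n")
        for acc in sorted(mapping):
            fh.write(f"{acc}\t{mapping[acc]}\n")
    finally:
        if own:
            fh.close()


def map_to_taxa(run: ReplicateRun, mapping: Mapping[str, int]) -> ReplicateRun:
    """Annotate every hit's accessions with taxids (pure annotation).

    Sequences and scores are untouched. Accessions absent from the map are
    counted in ``unmapped_accessions`` and excluded from taxon sets; hits
    whose every accession is unmapped contribute no taxon evidence downstream.
    Never fatal.
    """
    unmapped: Counter = Counter()
    new_hits = []
    for hit in run.hits:
        taxids: dict[str, int] = {}
        for acc in hit.accessions:
            if acc in mapping:
                taxids[acc] = mapping[acc]
            else:
                unmapped[acc] += 1
        new_hits.append(replace(hit, accession_taxids=taxids))
    if unmapped:
        logger.info(
            "%d distinct accessions unmapped in %s rep %d",
            len(unmapped),
            run.sample_id,
            run.replicate_index,
        )
    return replace(run, hits=tuple(new_hits), unmapped_accessions=unmapped)
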