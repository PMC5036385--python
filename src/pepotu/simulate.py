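"""Synthetic communities, peptide universes and identification exports.

The generator is the test bed for the whole pipeline: it builds a balanced
toy taxonomy, a ground-truth community over its species, a catalog of
tryptic-like peptides per species with *controlled inter-taxon homology*, and
Mascot-style CSV exports with technical-replicate structure — everything the
real pipeline consumes, but with the true peptide→species map and true
abundances known.

Homology model: each peptide is, with probability ``homology``, copied into a
protein of a uniformly chosen sibling species — a sibling being another
species under the same family when the taxonomy has a family rank, otherwise
under the same genus. A second, independent probability
(``cross_family_homology``) shares peptides with species of other families in
the same phylum. Homology 0 makes every peptide species-unique, so all
counting strategies must agree; branch-local homology reproduces the
family-level peptide sharing that separates LCA assignment from all-matches
counting.

Sampling model: a replicate observes ``depth`` *distinct* peptide sequences.
Depth is split across species by a multinomial draw on the (dropout-adjusted)
abundances, then each species' quota is drawn without replacement from its
catalog. Identified-peptide counts therefore track abundances multinomially,
which is also how identification lists are usually summarised (numbers of
peptide sequences, not spectra). Repeat spectra of a peptide are emulated
separately by duplicate rows (never bold-red, per the first-occurrence rule).

Everything is deterministic given (config, seed): same seed → byte-identical
exports.
"""

from __future__ import annotations

import dataclasses
import io
import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .profiling import TaxonProfile, _check_rank, _sorted_counts
from .taxonomy import NO_RANK, TaxonNode, TaxonomyTree, write_taxonomy_tsv
from .mascot import MANDATORY_COLUMNS, write_accession_map

#: Residues allowed inside a tryptic peptide (the 20 canonical minus K/R).
_INTERNAL_RESIDUES = np.array(list("ACDEFGHILMNPQSTVWY"))


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape and noise parameters of the synthetic study.

    Defaults emulate a simple neonatal-gut-like community: a few phyla with a
    handful of genera and species, a few thousand identified peptide
    sequences per replicate, three technical replicates, ion scores with
    roughly a tenth of the draws below the admission threshold of 10, and
    occasional replicate dropout of rare taxa.
    """

    n_phyla: int = 2
    #: 0 disables the family level (root→phylum→genus→species tree).
    families_per_phylum: int = 0
    #: genera under each phylum, or under each family when families exist.
    genera_per_phylum: int = 2
    species_per_genus: int = 2
    proteins_per_species: int = 100
    peptides_per_protein: int = 25
    homology: float = 0.2
    cross_family_homology: float = 0.0
    depth: int = 5000
    n_replicates: int = 3
    #: log-normal ion-score parameters; defaults put ~10% of draws below 10.
    score_mu: float = 3.2
    score_sigma: float = 0.7
    #: per-replicate probability that a low-abundance species yields nothing.
    dropout: float = 0.1
    #: abundance below which a species is exposed to dropout.
    dropout_abundance: float = 0.05
    missed_cleavage_fraction: float = 0.1
    #: probability a peptide row is followed by a duplicate (non-bold) row.
    duplicate_row_fraction: float = 0.1
    #: Dirichlet concentration for random community abundances.
    abundance_alpha: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "n_phyla",
            "genera_per_phylum",
            "species_per_genus",
            "proteins_per_species",
            "peptides_per_protein",
            "n_replicates",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.families_per_phylum < 0:
            raise ValueError("families_per_phylum must be >= 0")
        if not 0 <= self.homology <= 1:
            raise ValueError("homology must lie in [0, 1]")
        if not 0 <= self.cross_family_homology <= 1:
            raise ValueError("cross_family_homology must lie in [0, 1]")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


def generate_taxonomy(config: GeneratorConfig, seed: int | None = None) -> TaxonomyTree:
    """Balanced toy taxonomy: root→phylum(→family)→genus→species.

    Taxid assignment is sequential in construction order and therefore fully
    deterministic for a given config (the seed does not enter).
    """
    del seed  # shape alone determines the tree
    nodes: dict[int, TaxonNode] = {1: TaxonNode(1, 1, NO_RANK, "root")}
    next_id = 2

    def add(parent: int, rank: str, name: str) -> int:
        nonlocal next_id
        taxid = next_id
        next_id += 1
        nodes[taxid] = TaxonNode(taxid, parent, rank, name)
        return taxid

    for p in range(1, config.n_phyla + 1):
        phy = add(1, "phylum", f"Phylum{p}")
        parents = (
            [add(phy, "family", f"Family{p}.{f}") for f in range(1, config.families_per_phylum + 1)]
            if config.families_per_phylum
            else [phy]
        )
        for parent in parents:
            for g in range(1, config.genera_per_phylum + 1):
                gen = add(parent, "genus", f"{nodes[parent].name}-Genus{g}")
                for s in range(1, config.species_per_genus + 1):
                    add(gen, "species", f"{nodes[gen].name}-sp{s}")
    return TaxonomyTree(nodes)


@dataclass(frozen=True)
class SyntheticCommunity:
    """Ground truth: a taxonomy, species abundances and homology parameters."""

    tree: TaxonomyTree
    abundances: dict[int, float]
    proteins_per_species: int = 100
    peptides_per_protein: int = 25
    homology: float = 0.2
    cross_family_homology: float = 0.0
    missed_cleavage_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1, got {total}")
        if not 0 <= self.homology <= 1:
            raise ValueError("homology must lie in [0, 1]")
        for taxid in self.abundances:
            if self.tree.rank(taxid) != "species":
                raise ValueError(f"abundance key {taxid} is not a species")

    @property
    def species(self) -> list[int]:
        return sorted(self.abundances)

    @classmethod
    def random(cls, config: GeneratorConfig, seed: int) -> "SyntheticCommunity":
        """Community with Dirichlet-distributed abundances over the species."""
        tree = generate_taxonomy(config)
        species = tree.taxids_at_rank("species")
        rng = np.random.default_rng(seed)
        ab = rng.dirichlet(np.full(len(species), config.abundance_alpha))
        # exact renormalisation so the invariant holds to 1e-9
        ab = ab / ab.sum()
        return cls(
            tree=tree,
            abundances=dict(zip(species, ab.tolist())),
            proteins_per_species=config.proteins_per_species,
            peptides_per_protein=config.peptides_per_protein,
            homology=config.homology,
            cross_family_homology=config.cross_family_homology,
            missed_cleavage_fraction=config.missed_cleavage_fraction,
            seed=seed,
        )


@dataclass
class PeptideUniverse:
    """Per-species protein/peptide catalog with the true sharing structure."""

    #: species taxid → its protein accessions (construction order)
    species_proteins: dict[int, list[str]]
    #: protein accession → peptide sequences it contains
    protein_peptides: dict[str, list[str]]
    #: protein accession → owning species taxid
    accession_taxid: dict[str, int]
    #: peptide sequence → accessions of every protein containing it
    peptide_proteins: dict[str, set[str]] = field(repr=False)
    #: peptide sequence → true species set (the sidecar truth)
    peptide_species: dict[str, set[int]] = field(repr=False)
    #: species taxid → sorted catalog of all peptides found in its proteins
    species_catalog: dict[int, list[str]] = field(repr=False)


def _random_peptides(rng: np.random.Generator, n: int, mcf: float, used: set[str]) -> list[str]:
    """Distinct random tryptic-like sequences: length 7–25, K/R terminus,
    no internal K/R except an ``mcf`` fraction with one missed cleavage."""
    out: list[str] = []
    kr = np.array(["K", "R"])
    while len(out) < n:
        batch = n - len(out)
        lengths = rng.integers(7, 26, size=batch)
        bodies = rng.integers(0, len(_INTERNAL_RESIDUES), size=int(lengths.sum()) - batch)
        chars = _INTERNAL_RESIDUES[bodies]
        terminal = kr[rng.integers(0, 2, size=batch)]
        miss = rng.random(batch) < mcf
        miss_char = kr[rng.integers(0, 2, size=batch)]
        miss_frac = rng.random(batch)
        offset = 0
        for i in range(batch):
            length = int(lengths[i])
            seq = "".join(chars[offset : offset + length - 1]) + terminal[i]
            offset += length - 1
            if miss[i] and length >= 9:
                pos = 1 + int(miss_frac[i] * (length - 4))
                seq = seq[:pos] + miss_char[i] + seq[pos + 1 :]
            if seq not in used:
                used.add(seq)
                out.append(seq)
    return out


def _sibling_pools(tree: TaxonomyTree, species: list[int]) -> dict[int, list[int]]:
    """Same-family siblings of each species (same-genus when no family rank)."""
    groups: dict[int, list[int]] = defaultdict(list)
    key_rank = "family" if tree.taxids_at_rank("family") else "genus"
    for s in species:
        anc = tree.ancestor_at_rank(s, key_rank)
        groups[anc if anc is not None else -1].append(s)
    return {
        s: [x for x in members if x != s]
        for members in groups.values()
        for s in members
    }


def _cross_family_pools(tree: TaxonomyTree, species: list[int]) -> dict[int, list[int]]:
    """Species of *other* families (or genera) within the same phylum."""
    sibs = _sibling_pools(tree, species)
    by_phylum: dict[int, list[int]] = defaultdict(list)
    for s in species:
        anc = tree.ancestor_at_rank(s, "phylum")
        by_phylum[anc if anc is not None else -1].append(s)
    pools: dict[int, list[int]] = {}
    for members in by_phylum.values():
        for s in members:
            near = set(sibs[s]) | {s}
            pools[s] = [x for x in members if x not in near]
    return pools


def generate_peptide_universe(community: SyntheticCommunity) -> PeptideUniverse:
    """Build every species' proteins and peptides, then apply homologous sharing.

    With probability ``homology`` a peptide is copied into a random protein of
    a uniformly chosen same-family sibling species (independently, with
    probability ``cross_family_homology``, into a same-phylum species of
    another family). The catalog records each peptide's true species set.
    """
    rng = np.random.default_rng([community.seed, 104729])
    tree = community.tree
    species = community.species
    used: set[str] = set()

    species_proteins: dict[int, list[str]] = {}
    protein_peptides: dict[str, list[str]] = {}
    accession_taxid: dict[str, int] = {}
    peptide_proteins: dict[str, set[str]] = {}
    peptide_species: dict[str, set[int]] = {}
    owner: dict[str, int] = {}

    for s in species:
        accs = [f"SP{s}P{j}" for j in range(1, community.proteins_per_species + 1)]
        species_proteins[s] = accs
        peptides = _random_peptides(
            rng,
            community.proteins_per_species * community.peptides_per_protein,
            community.missed_cleavage_fraction,
            used,
        )
        for j, acc in enumerate(accs):
            chunk = peptides[
                j * community.peptides_per_protein : (j + 1) * community.peptides_per_protein
            ]
            protein_peptides[acc] = list(chunk)
            accession_taxid[acc] = s
            for seq in chunk:
                peptide_proteins[seq] = {acc}
                peptide_species[seq] = {s}
                owner[seq] = s

    sib_pools = _sibling_pools(tree, species)
    cross_pools = _cross_family_pools(tree, species)

    def share(seq: str, target: int) -> None:
        accs = species_proteins[target]
        acc = accs[int(rng.integers(len(accs)))]
        if seq not in protein_peptides[acc]:
            protein_peptides[acc].append(seq)
        peptide_proteins[seq].add(acc)
        peptide_species[seq].add(target)

    for seq in sorted(owner):
        s = owner[seq]
        pool = sib_pools[s]
        if pool and rng.random() < community.homology:
            share(seq, pool[int(rng.integers(len(pool)))])
        cpool = cross_pools[s]
        if cpool and rng.random() < community.cross_family_homology:
            share(seq, cpool[int(rng.integers(len(cpool)))])

    species_catalog = {
        s: sorted({seq for acc in species_proteins[s] for seq in protein_peptides[acc]})
        for s in species
    }
    return PeptideUniverse(
        species_proteins=species_proteins,
        protein_peptides=protein_peptides,
        accession_taxid=accession_taxid,
        peptide_proteins=peptide_proteins,
        peptide_species=peptide_species,
        species_catalog=species_catalog,
    )


def generate_mascot_export(
    community: SyntheticCommunity,
    universe: PeptideUniverse,
    config: GeneratorConfig,
    replicate_index: int,
    sample_id: str = "synthetic",
) -> str:
    """One replicate's identification CSV in the canonical dialect.

    Observed peptides are drawn species-proportionally to (dropout-adjusted)
    abundances; observed peptides sharing the exact same containing-protein
    set are grouped into one protein hit whose extra proteins are listed as
    same-set accessions; ion scores are log-normal; the first occurrence of
    each sequence is flagged bold-red. Depth 0 yields a header-only export.
    Byte-identical for identical (community, config, replicate_index).
    """
    if replicate_index < 1:
        raise ValueError("replicate_index must be >= 1")
    rng = np.random.default_rng([community.seed, 15485863, replicate_index])
    species = community.species
    ab = np.array([community.abundances[s] for s in species])

    keep = np.ones(len(species), dtype=bool)
    for i, s in enumerate(species):
        if ab[i] < config.dropout_abundance and rng.random() < config.dropout:
            keep[i] = False
    if not keep.any():
        keep[:] = True
    ab_eff = np.where(keep, ab, 0.0)
    ab_eff = ab_eff / ab_eff.sum()

    counts = rng.multinomial(config.depth, ab_eff)
    observed: set[str] = set()
    for i, s in enumerate(species):
        n = int(counts[i])
        if n == 0:
            continue
        catalog = universe.species_catalog[s]
        take = min(n, len(catalog))
        idx = rng.choice(len(catalog), size=take, replace=False)
        observed.update(catalog[int(k)] for k in sorted(idx))

    # protein hits: group observed peptides by exact containing-protein set
    groups: dict[tuple[str, ...], list[str]] = defaultdict(list)
    for seq in sorted(observed):
        groups[tuple(sorted(universe.peptide_proteins[seq]))].append(seq)
    hits = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))

    buf = io.StringIO()
    buf.write("Synthetic identification export\n")
    buf.write(f"sample={sample_id};replicate={replicate_index}\n")
    buf.write(",".join(MANDATORY_COLUMNS) + "\n")
    seen: set[str] = set()
    for hit_num, (accs, peptides) in enumerate(hits, start=1):
        primary, sameset = accs[0], ";".join(accs[1:])
        for seq in peptides:
            bold = int(seq not in seen)
            seen.add(seq)
            score = rng.lognormal(config.score_mu, config.score_sigma)
            buf.write(f"{hit_num},{primary},{sameset},{seq},{score:.2f},{bold}\n")
            if rng.random() < config.duplicate_row_fraction:
                score2 = rng.lognormal(config.score_mu, config.score_sigma)
                buf.write(f"{hit_num},{primary},{sameset},{seq},{score2:.2f},0\n")
    return buf.getvalue()


def ground_truth_profile(community: SyntheticCommunity, rank: str) -> TaxonProfile:
    """True relative abundances aggregated to ``rank`` (sums to 1)."""
    _check_rank(rank)
    counts: dict[int | str, float] = defaultdict(float)
    for s in community.species:
        anc = community.tree.ancestor_at_rank(s, rank)
        if anc is not None:
            counts[anc] += community.abundances[s]
    return TaxonProfile(rank, _sorted_counts(dict(counts)), "truth", "truth")


# -- bundle writer ------------------------------------------------------------


def write_bundle(
    config: GeneratorConfig,
    seed: int,
    out_dir: str | Path,
    sample_id: str = "synthetic",
    community: SyntheticCommunity | None = None,
) -> Path:
    """Write a complete synthetic input bundle; returns the manifest path.

    Files: one identification CSV per replicate, the taxonomy TSV, the
    accession→taxid map, two ground-truth sidecars (peptide→species set and
    species abundances) and a JSON manifest echoing config and seed. An
    explicit ``community`` overrides the Dirichlet draw (the taxonomy inside
    it is then the one written).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if community is None:
        community = SyntheticCommunity.random(config, seed)
    universe = generate_peptide_universe(community)

    write_taxonomy_tsv(community.tree, out / "taxonomy.tsv")
    write_accession_map(universe.accession_taxid, out / "accession_map.tsv")
    replicate_files = []
    for r in range(1, config.n_replicates + 1):
        text = generate_mascot_export(community, universe, config, r, sample_id)
        path = out / f"replicate_{r}.csv"
        path.write_text(text, encoding="utf-8")
        replicate_files.append(path.name)

    with open(out / "truth_peptides.tsv", "w", encoding="utf-8") as fh:
        fh.write("peptide\tspecies_taxids\n")
        for seq in sorted(universe.peptide_species):
            taxa = ";".join(str(t) for t in sorted(universe.peptide_species[seq]))
            fh.write(f"{seq}\t{taxa}\n")
    with open(out / "truth_abundances.tsv", "w", encoding="utf-8") as fh:
        fh.write("taxid\tabundance\n")
        for s in community.species:
            fh.write(f"{s}\t{community.abundances[s]:.12g}\n")

    manifest = {
        "format": "pepotu-bundle-1",
        "sample_id": sample_id,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "files": {
            "taxonomy": "taxonomy.tsv",
            "accession_map": "accession_map.tsv",
            "replicates": replicate_files,
            "truth_peptides": "truth_peptides.tsv",
            "truth_abundances": "truth_abundances.tsv",
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest_path
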