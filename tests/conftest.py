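"""Shared fixtures: a hand-built gut-like taxonomy and replicate trio.

The hand fixture models a minimal neonatal-gut community (two Firmicutes
genera, one Proteobacteria genus) with scores, bold-red flags and an
unmapped accession chosen so every admission filter and both consensus
removal rules fire, and every dropped/retained count is known by hand.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pepotu import TaxonomyTree, tree_from_rows

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


GUT_TAXONOMY_ROWS = [
    (1, 1, "no_rank", "root"),
    (2, 1, "phylum", "Firmicutes"),
    (3, 1, "phylum", "Proteobacteria"),
    (4, 2, "genus", "Lactobacillus"),
    (5, 2, "genus", "Enterococcus"),
    (6, 3, "genus", "Escherichia"),
    (7, 4, "species", "Lactobacillus murinus"),
    (8, 4, "species", "Lactobacillus johnsonii"),
    (9, 5, "species", "Enterococcus faecalis"),
    (10, 6, "species", "Escherichia coli"),
]

GUT_ACCESSION_MAP = {"LM1": 7, "LJ1": 8, "EF1": 9, "EC1": 10}

_HEADER = "prot_hit_num,prot_acc,prot_sameset_accs,pep_seq,pep_score,pep_isbold\n"

# replicate 1: one peptide below score 10, one hit with no bold-red peptide,
# one unmapped accession — retained evidence: AAAAAAK → Lactobacillus.
GUT_REPLICATE_CSVS = [
    _HEADER
    + "1,LM1,,AAAAAAK,50,1\n"
    + "1,LM1,,CCCCCCK,8,1\n"
    + "2,EC1,,EEEEEEK,30,0\n"
    + "2,EC1,,FFFFFFK,12,0\n"
    + "3,XX1,,GGGGGGK,40,1\n",
    _HEADER
    + "1,LM1,,AAAAAAK,45,1\n"
    + "1,LM1,,HHHHHHK,20,1\n"
    + "2,EF1,,IIIIIIK,15,1\n"
    + "3,EC1,,MMMMMMK,25,1\n",
    _HEADER
    + "1,LM1,,AAAAAAK,60,1\n"
    + "1,LM1,,NNNNNNK,18,1\n"
    + "2,EF1,,PPPPPPK,22,1\n",
]

# hand-computed per-replicate filter ledgers at score threshold 10
GUT_EXPECTED_LEDGERS = {
    1: dict(input_rows=5, score_dropped=1, no_boldred_dropped=2,
            retained_rows=2, unmapped_dropped=1, retained_final=1),
    2: dict(input_rows=4, score_dropped=0, no_boldred_dropped=0,
            retained_rows=4, unmapped_dropped=0, retained_final=4),
    3: dict(input_rows=3, score_dropped=0, no_boldred_dropped=0,
            retained_rows=3, unmapped_dropped=0, retained_final=3),
}

# per-replicate genus counts: rep1 {Lacto:1}; rep2 {Lacto:2, Entero:1, Esch:1};
# rep3 {Lacto:2, Entero:1}. Consensus: Escherichia seen in one replicate →
# removed; Enterococcus mean 2/3 < 1 → removed; Lactobacillus mean 5/3 kept.
GUT_EXPECTED_GENUS_CONSENSUS = {4: 5.0 / 3.0}


@pytest.fixture(scope="session")
def gut_tree() -> TaxonomyTree:
    return tree_from_rows(GUT_TAXONOMY_ROWS)


@pytest.fixture(scope="session")
def gut_bundle_dir(tmp_path_factory):
    """The hand fixture written to disk in pipeline-ready form."""
    from pepotu import write_accession_map, write_taxonomy_tsv

    d = tmp_path_factory.mktemp("gut_bundle")
    write_taxonomy_tsv(tree_from_rows(GUT_TAXONOMY_ROWS), d / "taxonomy.tsv")
    write_accession_map(GUT_ACCESSION_MAP, d / "accession_map.tsv")
    for i, text in enumerate(GUT_REPLICATE_CSVS, start=1):
        (d / f"replicate_{i}.csv").write_text(text, encoding="utf-8")
    return d


def random_tree(rng: np.random.Generator, n_nodes: int) -> TaxonomyTree:
    """Random rooted tree (all no_rank): node i attaches to a random earlier node."""
    rows = [(1, 1, "no_rank", "root")]
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        rows.append((i, parent, "no_rank", f"n{i}"))
    return tree_from_rows(rows)


def brute_force_lca(tree: TaxonomyTree, taxids) -> int:
    """Oracle: deepest element common to every member's explicit root path."""
    paths = [[t for _, t in tree.lineage(x)] for x in taxids]
    common = set(paths[0]).intersection(*map(set, paths[1:]))
    return max(common, key=tree.depth)
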