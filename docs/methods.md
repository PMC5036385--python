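# Methods

## Problem and model

Shotgun metaproteomics identifies peptides from a mixed microbial community
by LC–MS/MS and a database search. Taxonomic profiling then has to turn a
ranked list of protein hits — each hit carrying peptide-spectrum matches and
a list of *same-set* proteins indistinguishable by their peptide evidence —
into rank-level OTU abundances. The central obstacle is homology: closely
related bacterial genomes share a large fraction of tryptic peptides, so a
peptide frequently matches proteins from several genera of one family and
cannot be attributed to a single taxon.

`pepotu` implements two complementary peptide-counting strategies plus the
standard per-peptide LCA assignment as a comparator:

* **All-matches counting** (tag `all`). Every admitted peptide adds one
  count to *every* taxon its proteins belong to, projected to the requested
  rank. Inclusive: homology-rich branches are over-counted and phantom
  sibling taxa can appear, but the overall abundance picture is retained.
* **Unique-taxon counting** (tag `unique`). Only peptides whose rank-level
  taxon set is a singleton count. Conservative: no phantom taxa, but
  homology-rich taxa are depleted because their taxon-specific peptide
  complement is small.
* **LCA** (tag `lca`). Sequences are I/L-equated (isobaric residues),
  deduplicated with taxon sets unioned, assigned to the lowest common
  ancestor of their full taxon set, and counted at a rank only when the LCA
  lies at or below that rank (peptides resolving above the rank are dropped,
  matching rank-level treemap semantics).

A direct consequence, verified by the acceptance tests: with no homology the
three strategies coincide exactly at species rank; for every taxon and rank
the unique count is bounded by the all-matches count; and the total of
unique-counting contributions is non-decreasing from species toward phylum.

A less obvious directional property: in a family whose genera share a large
peptide fraction, the *relative* abundance of the family's dominant genus is
lower under LCA than under all-matches counting **provided the community
also contains taxa outside the homologous branch**. Shared peptides of the
dominant genus are pushed up to the family level and vanish from the
genus-rank LCA profile, while a homology-free outgroup keeps all of its
counts; the dominant genus therefore loses share to the outgroup. Within a
single isolated family the effect reverses (symmetric sharing dilutes the
dominant genus under all-matches counting instead), which is why the test
construction pairs one homologous family with a homology-free outgroup.

## Admission and filtering

Upstream FDR control (search-engine level) is assumed done; the pipeline's
own filters are:

1. **Ion-score threshold** (default 10, *inclusive*: score ≥ 10 is kept).
   Applied per peptide row before anything else.
2. **Bold-red admission**: a protein hit is kept only if, after score
   filtering, it retains at least one bold-red peptide (a top-ranking,
   first-occurrence match). Ordering matters and is fixed: scores first,
   then the bold-red requirement on the survivors.
3. **Unmapped evidence**: peptides all of whose containing hits have no
   accession resolvable to a taxid contribute nothing and are counted.
4. **Replicate consensus** (default 3 technical replicates): OTUs present in
   fewer than 2 replicates are removed; surviving counts are averaged over
   *all* R replicates, absences as zero (an `average="nonzero"` variant
   divides by the number of replicates where the OTU appears); OTUs with a
   mean below 1.0 peptide are removed.

Each replicate's filter ledger is exact and machine-checked:
`input_rows = retained_final + score_dropped + no_boldred_dropped +
unmapped_dropped`.

Counting is over distinct (sequence, taxon) pairs per replicate by default
(`counting_mode="dedup"`); the `occurrence` mode instead counts one
contribution per admitted hit containing the sequence, for the reading in
which re-occurrence of a peptide across protein hits is itself evidence.
Deduplication is the default because it is insensitive to how the search
engine groups redundant hits. I/L equating is applied only on the LCA path;
the counting workflows use raw sequences.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `score_threshold` | 10 | minimum ion score, inclusive |
| `consensus_min_replicates` | 2 (of 3) | presence filter across technical replicates |
| `mean_floor` | 1.0 peptide | minimum replicate-mean count |
| `other_fraction` | 0.01 | taxa below this fraction merge into `other` (display only; totals conserved) |
| `counting_mode` | `dedup` | see above |
| `consensus_average` | `all` | divide means by R, absences as zero |

## Synthetic data generator

The generator emulates post-search, FDR-filtered identification exports with
known ground truth; it is the test bed for everything above.

* **Taxonomy**: balanced root→phylum(→family)→genus→species tree with
  deterministic sequential taxids. The family level is optional
  (`families_per_phylum`, default 0).
* **Community**: Dirichlet(1) species abundances (or explicit abundances for
  designed scenarios). Defaults: 2 phyla × 2 genera × 2 species = 8 species,
  a scale at which every rank keeps multiple taxa while per-species counts
  at the default depth remain precise.
* **Peptides**: random tryptic-like strings, length 7–25, K/R terminus, no
  internal K/R except a 10% missed-cleavage fraction; 100 proteins × 25
  peptides per species, so catalogs (2 500/species) comfortably exceed
  per-species sampling quotas at the default depth.
* **Homology**: each peptide is, with probability `homology` (default 0.2),
  copied into a protein of a uniformly chosen sibling species — same family
  when a family rank exists, else same genus; `cross_family_homology`
  (default 0) shares across families within a phylum. Sharing is
  branch-local because genomic homology is.
* **Sampling**: each replicate observes `depth` (default 5 000) *distinct*
  peptides: a multinomial split of depth across species followed by
  without-replacement draws from each species' catalog. Depth therefore
  counts peptide sequences — the unit identification lists are summarised
  in — and recovered counts are multinomial in the true abundances rather
  than saturating coupon-collector-style, which keeps abundance recovery
  unbiased.
* **Export**: observed peptides sharing the exact same containing-protein
  set form one protein hit whose additional proteins become same-set
  accessions; ion scores are log-normal (μ = 3.2, σ = 0.7, putting ≈ 10% of
  draws below the threshold of 10 so the score filter is exercised); the
  first occurrence of each sequence is flagged bold-red, and a 10% fraction
  of rows is followed by a duplicate non-bold row emulating repeat spectra.
* **Noise**: species with abundance < 0.05 drop out of a replicate with
  probability 0.1, emulating run-to-run irreproducibility of rare taxa.

What the generator does **not** emulate: spectrum-level noise, retention
time and m/z, decoy matches and FDR estimation, database incompleteness,
protein-inference parsimony, and non-uniform protein expression (all
proteins of a species are equally observable). Passing tests therefore
demonstrate the correctness of the counting, filtering and comparison logic
under controlled homology and sampling noise — not robustness to search
engine artifacts on real spectra.

## Numerical and design choices

* Threshold comparisons are inclusive (score 10 is retained) — the common
  search-engine convention for an integer threshold.
* Consensus means divide by R with absences as zero; the plain reading of
  "averaged among the replicates". The nonzero-divisor variant is available
  but not default.
* The `other` bucket merges taxa strictly below `min_fraction × total`; the
  total is conserved to the last bit by construction.
* Shannon–Wiener uses natural log (nats) with 0·ln 0 = 0; a `base` argument
  converts for comparison with bits-based tools. Richness counts taxa with
  positive abundance only.
* Bray–Curtis dissimilarity is computed on relative profiles
  (= ½ Σ|p_i − q_i|); two empty profiles have distance 0.
* LCA of a singleton is the member itself; LCA queries, lineage resolution
  and rank projection treat `no_rank` nodes as transparent.
* Degenerate inputs error loudly: empty profiles cannot be normalised or
  given a diversity index; taxonomies with zero/multiple roots, cycles,
  missing parents or repeated ranks on a path are rejected at load;
  unknown taxids and ranks raise rather than defaulting.
* Unparsable CSV rows (bad score, flag, or residue alphabet) are rejected
  with a logged warning and counted — never silently dropped.
* Merged/deleted taxid remapping is out of scope: synthetic and fixture
  taxonomies are closed worlds, and the taxonomy snapshot is an explicit
  input precisely because profiles depend on it.

## Problem sizes in the test-suite and acceptance runs

Oracle and property tests run at sizes where the independent oracle is
exact and fast: 200-node random trees with 1 000 LCA queries against a
path-intersection oracle; 100 seeded communities at depth 300 for the
dominance and monotonicity sweeps; depth 5 000 with 8 species for the
homology-free equivalence, multinomial-error and abundance-recovery checks
(20 seeds); depth 2 000 for the 20-seed homologous-family comparison. The
summary script (`scripts/acceptance.py`) runs the default 8-species,
depth-5 000, 3-replicate configuration end to end.

## Known limitations

* Protein-level inference (parsimony grouping) and spectral quantification
  are intentionally absent; counts are peptide-based.
* The bold-red flag is consumed per row as exported; whether same-set
  proteins inherit the primary hit's flags is not modelled beyond hit-level
  admission.
* With very deep sampling relative to catalog size, per-species quotas
  saturate at the catalog and compress high abundances; defaults keep a
  ≥ 1.6× headroom.
* Real taxonomies contain rank irregularities (subspecies, strain nodes,
  intermediate clades) exercised here only through `no_rank` transparency.
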