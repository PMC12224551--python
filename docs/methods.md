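# Methods

## Model and procedure

`bgcpan` treats BGC conservation as a property derived from gene-level
conservation, not from cluster-similarity scores. The unit of evidence is
the gene family of a pan-genome presence/absence matrix; the unit of
inference is the cluster region. The assumptions are:

- the presence/absence matrix is correct as given (no paralog splitting or
  re-clustering is attempted; an upstream pan-genome tool owns that);
- a BGC is a colocated run of genes inside one annotated region, so
  evidence for a cluster never aggregates across regions;
- two regions describe "the same cluster" when they share conserved gene
  content — identity of the biosynthetic genes, not genomic position,
  carries the signal.

The per-genus stage computes family prevalence over exactly the genomes of
one genus, thresholds it at `min_prevalence` (default 0.5, inclusive: a
family in exactly half the genomes is conserved), maps conserved families
into regions by locus tag, groups regions by shared conserved content, and
applies the double rule: a group is genus-conserved iff it occurs in
`min_genome_frac` (default 0.5, inclusive) of the genus's genomes and
carries `min_conserved_genes` (default 2) *distinct* conserved families.
Distinct families, not gene copies: paralogous copies of one family carry
no additional conservation evidence, so a region with two copies of a
single conserved gene does not satisfy the ≥2 rule.

Grouping is single linkage on "share ≥ `min_shared` (default 2) conserved
families", with connected components as the cluster families. Published
analyses of this kind typically match clusters across genomes by
similarity scores plus manual inspection; single linkage on shared content
is the simplest fully explicit substitute, and every threshold in it is a
parameter. A singleton region that itself carries ≥ `min_shared` conserved
families forms a one-member family (it is then usually removed by the
genome-fraction rule); regions with fewer conserved families form no
family at all. Hybrid regions (multiple product classes) are grouped like
any other region; their mapped families may mix pathway content.

The phylum stage picks one representative region per genus-conserved
family (the member whose genome mapped the most conserved families; ties
resolved lexicographically), links families whose representatives share
≥ `link_min_shared_genes` (default 2) best-bidirectional protein hits at
≥ 40 % identity and ≥ 60 % coverage, and calls a connected component
phylum-conserved when it spans ≥ `min_genera` genera. The default
`min_genera` is 7, matching a conventional "most of eleven analyzed
genera" design; it is a parameter, not a constant, and analyses with a
different genus count should scale it.

Screening a new genome asks, per conserved-cluster profile (≥ 2 reference
protein sequences), whether any single region contains
≥ `screen_min_matched_genes` (default 2) distinct CDS that are mutual-best
partners of distinct reference genes at ≥ 40 % identity / ≥ 60 % coverage.
The colocation requirement is deliberate: two reference genes found in two
different regions are evidence for the genes, not the cluster. The 2-gene
/ 40 % / 60 % defaults are operational stand-ins for a curator's
similarity judgment and are all overridable.

## Comparison machinery

Protein identity is computed from one optimal global alignment under an
affine scheme (match +1, mismatch −1, gap open −2, gap extend −1):
identity = identical columns / all columns, coverage = residue-vs-residue
columns / length of the shorter sequence. Where several optimal alignments
exist their identities can differ in the last few percent; the tests
account for this by checking membership in the optimal set.

Gene matching is mutual-best on identity with lexicographic tie-breaking,
so outputs are deterministic. Synteny is the fraction of adjacent matched
gene pairs (adjacency among matched genes, ranked within each region) that
are adjacent in both regions, orientation-insensitive: a fully inverted
but colinear cluster scores 1.0, because an inversion preserves the
organizational claim the score is meant to capture. With one match the
score is 1.0 only when both regions are single-gene; with none it is 0.

Fragment ANI follows the OrthoANI construction: both sequences are cut
into non-overlapping 1020-bp fragments (trailing remainder dropped),
reciprocal best fragment pairs with identity ≥ 0.3 and coverage ≥ 0.7 are
kept, and the ANI is 100 × their mean identity; with no qualifying pair
the ANI is undefined rather than zero. Fragment alignments use edlib's
bit-parallel unit-cost global aligner instead of the scored aligner used
for proteins: at the substitution-dominated divergences ANI measures, the
unit-cost optimum gives the same identity estimate, and it keeps a 50-kb ×
50-kb comparison (≈ 2,400 fragment pairs) around a second. Edit distances
drive best-pair selection; identity and coverage of kept pairs come from
the full alignment path. A note on degenerate input: on exactly periodic
sequences all fragments tie, reciprocity collapses to one pair, and the
ANI is still correct (identity of identical fragments), just averaged over
fewer pairs.

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical skeleton of a multi-genus
pan-genome study: universal core families, Bernoulli shell families
(presence probability 0.5) and cloud families (0.1) making the pan-genome
"open", planted colocated clusters with controlled per-genus prevalence,
and decoy clusters below the conservation threshold so false positives are
detectable. Sequences evolve on a two-level star phylogeny: one phylum
root per family, genus ancestors at `divergence_between_genera` (default
0.10 per site), genome copies at `divergence_within_genus` (default 0.02).
Substitutions are uniform to a different symbol; there are no indels, no
rearrangements, no rate heterogeneity, and no gene gain/loss dynamics
beyond the Bernoulli draws. HGT clusters draw their root from an
independent out-group and skip the genus-level divergence step, so their
copies are more alike across genera than vertically inherited genes — the
qualitative signature of a recent transfer, with no phylogenetics
implied.

Planted-cluster prevalence is realized *exactly*: round(prevalence × n)
carrier genomes are drawn without replacement. This is what makes the
expected conservation calls derivable from the parameters alone, so
recovery tests have a crisp ground truth. The cost is that planted
prevalence has no sampling noise; shell/cloud families keep their binomial
noise, and a fidelity test checks realized shell prevalence stays within
three binomial standard deviations.

The default design — 3 genera × 8 genomes, 200/300/300 core/shell/cloud
families, two conserved clusters (prevalence 0.75, 4 genes), three decoys
(prevalence 0.25), 2 % divergence — is sized so a full pipeline run takes
about a second; perfect recovery on it shows the machinery implements its
own rules exactly, not that the method is robust to real annotation noise,
fragmented assemblies, or tag-universe mismatches (the coordinate fallback
covers the latter and is tested separately). Back-translation uses one
fixed codon per amino acid, so synthetic nucleotide identity overstates
the protein identity of real sequences; ANI calibration therefore uses
directly mutated nucleotide sequences, not back-translated genes.

## Numerical and design choices

- All threshold comparisons are ≥ on exact fractions, never on rounded
  percentages (so 2/4 qualifies at 0.5; 5/11 does not).
- Pan-genome bins follow the conventional 99/95/15 boundaries; they are a
  reporting convenience and parameterized, not part of the inference.
- Greedy protein clustering (the internal stand-in for an external
  pan-genome tool on synthetic runs) processes proteins longest-first with
  deterministic tie-breaking, joining the first centroid at ≥ 70 %
  identity and ≥ 80 % bidirectional coverage. These defaults are looser
  than a typical pan-genome tool's blastp settings because the simulator
  controls divergence directly.
- Ties everywhere (best hits, representatives, grouping order) break
  lexicographically on tags/ids, making every report byte-reproducible;
  reports carry their fully resolved configuration as a YAML sidecar.
- Degenerate inputs: empty presence/absence cells are absence; a genome
  with zero regions screens as all-absent (a valid result); zero-CDS
  region files and out-of-range thresholds are errors.

## Known limitations

- The grouping rules (shared-content single linkage within a genus,
  representative-based linkage across genera) are stand-ins for curated
  cluster matching; chains of partially overlapping regions can merge
  families that a curator would split.
- MiBIG-style identity assignment is out of scope: known-cluster labels
  pass through from input annotations but are never computed.
- The simulator's noise model is substitution-only; conclusions about
  robustness to indels, assembly fragmentation, or annotation error cannot
  be drawn from it.
- Protein alignment is scored without a substitution matrix (a hook for
  one is left in `AlignmentParams`); identities between distantly related
  proteins are conservative.
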