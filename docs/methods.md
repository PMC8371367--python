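# Methods

## Scope and model

`cementome` compares the secreted protein repertoires ("adhesive
proteomes") of two barnacle species. The package starts where
mass-spectrometry protein inference ends: its inputs are per-species
protein FASTA files and an annotation table of boolean evidence flags
(intracellular annotation, predicted signal peptide, ER-retention motif,
outgroup homology) plus conserved-domain tags. Producing those flags —
peptide-spectrum matching, signal-peptide prediction, conserved-domain
search, homology search against outgroup databases — is upstream tooling
and out of scope; the package consumes their outputs and makes every
downstream decision reproducible.

## Contaminant exclusion and categories

A protein is excluded as presumed cellular contamination iff

    (intracellular AND NOT signal_peptide) OR (signal_peptide AND er_motif)

The ER-retention motif is the C-terminal tetrapeptide `[HK]DEL`; the
annotation flag is honoured when set, and recomputed from the sequence when
absent. KDEL is accepted alongside HDEL as the canonical variant of the
same retention signal.

Retained proteins receive exactly one category by an ordered decision
list: (1) no outgroup homologue → **bulk** (taxonomic uniqueness wins over
any domain tag — a barnacle-only protein with, say, a C-type lectin domain
is still bulk); (2) a pheromone domain tag (α-macroglobulin A2M-family
domains or the cupin domain of waterborne settlement pheromones) →
**pheromone**; (3) an enzyme or protease-inhibitor family tag →
**enzyme_or_inhibitor** (inhibitors counted with enzymes); (4) otherwise
**homologous**. Tag conflicts are resolved by that order and logged. The
domain catalog ships as `src/cementome/data/domain_catalog.yaml` and is
user-extensible; note that CLIP_1 (pfam18322) is catalogued under serine
proteases although annexin-family proteins can also carry it, and CBM_14
(pfam01607) under chitinases although chitin deacetylases share it — a
single mapping per tag is required, and the stated decision order plus the
other tags on a protein usually disambiguate.

## Alignment and similarity statistics

Pairwise similarity uses exact affine-gap Smith–Waterman (Gotoh) local
alignment — no heuristic seeding — computed by Biopython's C
`PairwiseAligner`; proteome sizes here make the O(mn) search affordable.
Defaults: BLOSUM62, gap open 11, gap extend 1 (a gap of length L costs
11 + L), and the unknown residue X scores 0 against everything. Percent
identity counts identical columns over all aligned columns with gap
columns in the denominator; query coverage is the aligned query span over
the query length. Equal-scoring optimal alignments are resolved by the
aligner's deterministic traceback order, so results are reproducible for
fixed inputs.

Significance uses Karlin–Altschul statistics with the published gapped
BLOSUM62/11/1 parameters λ = 0.267 and K = 0.041:

    E = K · m · n · exp(−λ S),   S' = (λS − ln K) / ln 2

with m, n the two sequence lengths. No effective-length (edge) correction
and no composition-based score adjustment are applied; at the proteome
sizes and the decision threshold used here the simpler statistic changes
no threshold decision of interest. Two proteins are *similar* when
E ≤ 1e-4 — the smaller-is-more-similar direction; source material that
writes the threshold as an E-value lower bound is read with this
conventional direction. A pair whose optimal local score is 0 has no
alignment and is reported as a no-hit rather than given an E-value.

Because composition-adjusted statistics are deliberately out of scope,
strongly composition-biased sequences (e.g. two unrelated glycine-rich
proteins) can reach E ≤ 1e-4 by shared bias alone, exactly as unfiltered
BLAST would without its composition corrections. This is a property of the
method, documented rather than patched; the synthetic fixtures used to
validate overlap and family recovery therefore use background-composition
sequences so that planted identity is the only similarity signal.

## Families, overlap and trees

Within-species families are single-linkage clusters: connected components
of the graph whose edges are pairs at E ≤ 1e-4 from the within-species
("self-BLAST") search. Named seed sets (historical cement-protein family
names) propagate onto any component containing a seed member; a component
that absorbs seeds with different names keeps both names joined
("CP52-1/CP52-2") and is flagged for manual splitting. De novo families
are numbered by their lexicographically smallest member, making naming
independent of input order.

Cross-species overlap is counted per protein (a protein is matched when it
has ≥ 1 passing hit in the other species' proteome); the two matched
counts may differ because one protein can align to several partners.
Percentages round half up to integers. Family reconciliation tables list,
for each member of each species-A family, the best species-B hit by
E-value (ties broken by raw score, then subject accession) with explicit
no-match rows.

Distance trees over protein sets use d = 1 − identity/100 from the
pairwise local alignments and UPGMA (average-linkage) agglomeration,
giving an ultrametric tree; leaves are pre-sorted lexicographically so tie
handling is deterministic. This is a pairwise-distance stand-in for a tree
built from a progressive multiple sequence alignment: branch lengths are
not comparable to MSA-based trees, but the qualitative grouping questions
it is used for — do α-macroglobulin-like pheromones cluster by family
while small cupin pheromones cluster by species? — are robust to the
substitution, which is what the tree fixtures test.

## Composition groups and PCA

Composition profiles are percentages of the 20 canonical residues over the
canonical-residue count (X excluded from numerator and denominator).
Clustering is agglomerative with complete linkage on Euclidean distances
over the residue-wise z-scored matrix (`scaling="none"` clusters raw
percentages; both are exposed because heatmap conventions differ), cut at
a user-chosen k — no automatic k selection.

Cluster labels follow an enrichment rule: residue r is enriched in a
cluster when the cluster mean exceeds the background mean by at least
1.5 background SD *and* by at least 2 percentage points. The background
mean is the leave-cluster-out mean (a large enriched class should not be
its own reference); the SD is the pooled within-cluster SD, an ANOVA-style
noise estimate that is not inflated by between-class spread. The absolute
2-point floor guards against compositional closure: percentages sum to
100, so a plain cluster compared against a heavily biased background looks
weakly "enriched" in every other residue. Base labels: C enriched → CrCP;
otherwise LrCP or GrCP by whichever of {L} or {G,A,S,T} dominates the
enrichment excess; no enrichment → minor, sub-labelled by the top residue.
Clusters sharing a base label are numbered by descending mean enrichment
(GrCP1 stronger than GrCP2).

PCA runs on the centered (not unit-scaled) composition matrix via SVD with
a deterministic sign convention; per-residue contributions are
100·loading²/Σloading² per component. Identical profiles (zero variance)
are a hard error. Composition is computed on the full sequence including
any signal peptide; at the sequence lengths involved the ≤ 16-residue
peptide shifts no group assignment.

## Glycosylation heuristics

N-sites are canonical sequons N-X-S/T with X ≠ P. O-sites are S/T
positions whose surrounding window (half-width 5) contains ≥ 40% S/T/P —
a mucin-context rule. Both are documented motif heuristics standing in for
trained predictors; their absolute counts are not comparable to any
machine-learned tool's output, and every serialized output says so in its
header. What they preserve — and what the tests assert — are the
qualitative contrasts: Ser/Thr-rich (GrCP-like) proteins collect several
times more predicted O-sites than Leu-rich proteins.

## Six-frame gene rescue

Contigs are translated in all six frames (standard genetic code; codons
containing N translate to X); stop-free segments of ≥ 30 residues (the
`min_len` default filters translation noise and is configurable, since the
true segment boundaries of a real locus depend on it) are aligned against
the query protein, hits at E ≤ 1e-4 are kept, and overlapping hits are
resolved by bit score — single best hit, no spliced chaining. Hit spans
are trimmed to the aligned codons and reported 1-based inclusive on the
forward strand; gap reports give the nucleotides strictly between
consecutive hits and the residues between their query spans, plus the
union query coverage. Two hits with a ~10²-nt gap jointly covering the
query are the signature of a split, unannotated coding sequence.

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical structure of a two-species adhesive
proteome comparison at desk scale. Defaults: 8 shared bulk families of
3 members per species; cross-species homologue pairs at 40% identity
(the typical between-suborder range) realised exactly by counted point
substitutions from a per-family ancestor; within-species relatives at 75%;
6 and 5 species-unique bulk proteins (2 per species flagged as matched
elsewhere in the other genome); composition classes mixed 45% GrCP-like /
35% LrCP-like / 10% CrCP-like / 10% unbiased; 3 intracellular contaminants
and 1 ER-retained (signal peptide + HDEL) protein per species; 2 + 2
shared pheromones (A2M-domain and cupin-tagged), 3 enzymes and
2 homologous proteins with their catalog tags; signal peptides
(Met + 12 hydrophobic residues + A-x-A) on 70% of secreted proteins;
lengths 150–400. Background residues follow average protein frequencies
(Robinson–Robinson-style), which keeps random-alignment score statistics
in the regime the fixed λ, K describe; signal-peptide cores are
Leu/Ala-dominated with Trp rare, as in real secretion signals. Split-CDS
contigs back-translate a query with random synonymous codons, cut it at a
codon boundary, and separate the exons with a gap (default 120 nt)
carrying a stop codon flush against each exon in its own frame plus a
12-nt block with stops in all six frames, so no reading frame can cross
the gap; the sizes used in tests and the acceptance script (≈ 40 proteins
per species, 200-residue rescue queries, 500-residue composition fixtures)
keep the full chain in seconds on one core.

The generator does **not** simulate mass spectra or peptide-level
evidence, indels (substitution-only mutation by default), realistic
signal-peptide physicochemistry, domain architecture within sequences, or
compositionally biased homology. Passing the planted-truth suites
therefore shows that the pipeline's logic is correct under its stated
model — exact recovery of categories, overlap counts, family structure,
composition labels and split-CDS coordinates when the planted signal is
the only signal — not that the heuristics would match any particular
external tool on real data. Checks that require real deposited sequences
(alignment metrics of published accession pairs, N-glycosite positions of
real pheromones) are out of desk scale and are not asserted offline.

## Determinism

All randomness flows through seeded `numpy` generators; identical seeds
and configs give byte-identical generator outputs and report bundles. The
pipeline run log records stages, input checksums and counts but no
wall-clock data, so reruns diff clean (the echoed config file differs
only when the output directory path itself differs).
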