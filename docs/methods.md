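# Methods

## The design problem

A designer TALE (dTALE) activates transcription from any promoter carrying
its effector-binding element (EBE). Used as a synthetic transcription
system inside a plant genome, a dTALE is only as clean as its EBE is
absent from that genome: every genomic window similar enough to the EBE is
a potential off-target promoter. `taledesign` implements the computational
half of that problem — propose candidate EBEs, quantify how badly each
candidate's nearest genomic neighbours could be bound, select the most
orthogonal candidate, and audit a chosen EBE against a genome and its gene
models.

## Model and assumptions

**TALE code.** Binding is modeled through the canonical one-repeat/one-base
code: HD→C, NN→G, NI→A, NG→T, with an invariant 5′ thymine (T0) that is
required for binding but coordinated by the protein's N-terminal region
rather than a canonical repeat. An EBE of length L therefore translates to
L−1 repeats. Position numbering is 1-based over the full EBE with T0 at
position 1: the position weight below must be finite at the first base,
and first-base mismatches occur in real off-target sites, so the scoring
coordinate cannot start at 0 even though the field names the thymine
"position 0". Non-canonical RVD chemistry, aberrant repeat lengths, and
protein structure are out of scope; the RVD set is extensible through the
preference-matrix file.

**Mismatch scoring.** Each (RVD, base) pair has a preference in [0, 1]
(1 = cognate). A mismatch at position p between the designed repeat and
the genomic base contributes

    S_M = (preference − 0.5) · (−2)      ∈ [−1, 1]
    F_P = 1 / √p

and a site's off-target score is the sum over its mismatch positions,

    S_OFF = Σ F_P · S_M .

Matched positions contribute nothing, so a perfect match scores 0, and a
site consisting only of strongly disfavored, T0-proximal mismatches scores
highest — high S_OFF means the mismatches are disruptive and the site is
*safe*. F_P encodes the observation that T0-proximal mismatches are less
tolerated than T0-distal ones. A mismatch at T0 itself has no repeat to
index the matrix with; it is scored with a fixed configurable preference,
default 0.0 (a non-T at T0 abolishes binding), giving the maximal
contribution S_M = 1 at F_P = 1. How that position should be scored is not
settled by the published description; the default is the conservative
choice and is exposed as a parameter.

**Preference matrix.** The matrix is position-independent; all position
dependence is carried by F_P. The built-in default is derived from the
canonical code alone — cognate 1.0, NN:A 0.6 (NN's documented weaker
second preference), all other entries 0.0 — and is deliberately a
structural stand-in: quantitative preference tables from binding or
activation studies can be dropped in as a TSV (`RVD<TAB>A<TAB>C<TAB>G<TAB>T`)
without code changes. Consequences of the stand-in: scores computed with
the default matrix are comparable *within* a run but are not calibrated
against published S_N magnitudes, and the package's guarantees about S_N
are property-based (monotonicity, permutation invariance, arithmetic
identities) rather than value-based.

**Candidate metric.** For each candidate, off-target scores are computed
for the n closest off-targets with at least 3 mismatches (n = 200 by
default; fewer are scored, and flagged, when the genome yields fewer).
"Closest" sorts by ascending mismatch count, then by descending summed
position factor over the mismatch positions (windows whose mismatches are
T0-proximal are the more informative near-neighbours), then by coordinate
for determinism. The mean of these scores is the neverword score S_N; the
ratio of the mean of the lowest half to the mean of the remaining half
(100/100 at n = 200, ⌊n/2⌋/⌈n/2⌉ otherwise) summarizes the score
distribution. A ratio near 1 means the off-target risk is spread evenly;
a small ratio flags a dangerous low-score tail that the mean hides. The
ratio is undefined (reported as NA/None) for fewer than two scores or a
zero upper-half mean.

**Selection.** "Highest S_N with the ratio closest to 1" is a
two-objective statement; it is resolved lexicographically: S_N dominates,
|ratio − 1| breaks ties within an absolute tolerance (default 1e−9), and
the lexicographically smaller sequence breaks exact ties. A weighted
composite would invent weights no published description states. An
alternative rule — restrict to the top-k by S_N, then minimize
|ratio − 1| — is available via `rank_candidates(top_k=...)`.

## Candidate generation

Candidates are length-19 sequences with a fixed leading T; positions 2..19
are drawn i.i.d. with composition weights A:C:G:T = 4:5:5:5 (rice-like GC),
configurable. Rejection sampling enforces a minimum pairwise Hamming
distance (default 2) under a seeded generator, erroring out after a
bounded number of attempts on infeasible requests. Candidates are then
filtered against the genome: any candidate whose closest window (either
strand) lies within the minimum genome distance (default 3 mismatches) is
discarded. The distance is ungapped Hamming, not edit distance: the
original selection aligned candidates with gap-free alignments, and the
downstream census is mismatch-count based, so gaps never enter the model.
A suffix-structure exact neverword algorithm is deliberately not
reimplemented; generate-then-filter produces equivalent candidates.

## Genome scan

`scan_genome` finds every window of the genome within a mismatch budget of
the query, on both strands by default (a functional EBE can face either
strand; the convention is a flag because published censuses do not state
theirs). The implementation is a pigeonhole seed filter: the query is
split into budget+1 contiguous near-equal blocks; any window with ≤ budget
mismatches must match at least one block exactly at its offset, so exact
block occurrences (located with C-level string search) anchor the only
windows that need full verification. The filter is exactly equivalent to
the sliding-window oracle `brute_force_scan`, and the test suite asserts
hit-set identity across randomized genomes, budgets 0–5, and all strand
modes. Soft-masked bases are uppercased; windows containing any non-ACGT
character are disqualified. Coordinates are 0-based half-open internally
and in BED output, 1-based in human-readable text. Hits are identified by
(chrom, start, strand), so overlapping opposite-strand self-hits are
distinct sites. The census defaults to a budget of 4 mismatches
(≈79% identity for a 19-mer; more diverged sites are not considered), and
the scoring stage scans to a ceiling of 6 so that candidates with no
3–4-mismatch neighbours still collect a scored off-target set.

## Gene context

Gene models come from GFF3 via `gffutils`; each gene is reduced to its
longest mRNA (one deterministic model per gene, matching per-gene
counting), introns are exon gaps, and UTRs are explicit features or
exonic-minus-CDS split by strand. A site is classified against every gene
within 5 kbp. Genic overlap resolves by precedence CDS > 5′UTR > 3′UTR >
intron at distance 0; otherwise the distance from the site midpoint to
the gene-span boundary (start/stop codon proxies) decides: within the
window on the 5′ side (strand-aware) of the site's *nearest* gene is
"upstream", the 3′ side "downstream", and any association to a farther
gene within the window is "intergenic". No gene within 5 kbp yields
"unassociated". **Interpretation flag:** published category tables never
define the boundary between "upstream/downstream" and "intergenic" — both
live inside the 5 kbp window. The nearest-gene rule used here is a
deterministic interpretation that reproduces the published labeling of
specific worked examples while leaving a populous residual intergenic
class; counts in those two categories are therefore convention-dependent.
The summary table counts each gene once under its highest-precedence
category by default (`mode="first"`); `mode="all"` counts a gene in every
category it collects, since published totals do not settle which
convention was used. Expressed/up/down gene-ID lists are accepted as
input and intersected; expression calling itself is out of scope.

## Synthetic fixtures

The fixture generator emulates only what the scanner and classifier need:
i.i.d. background at GC 0.435 (rice-like, configurable), planted EBE
variants mutated at exactly the requested positions on a requested strand
and locus, and simple non-overlapping gene models (1–4 exons, UTR stubs,
both strands) that round-trip through the GFF3 parser. After planting,
the finished genome is re-checked with the brute-force oracle; if the
random background happens to contain a window closer to a planted EBE
than that EBE's closest plant, the fixture is redrawn from a successor
seed (bounded retries). Background sites at or beyond the planted
distance remain possible and tests compare against the oracle, not the
plant list. The fixtures deliberately lack repeat structure, isochores,
paralogy and real gene architecture, so passing tests demonstrate
*algorithmic correctness* (scan equivalence, recovery, classification
logic) — not that any particular real genome yields a particular census.

## Numerical and determinism choices

All randomness flows from a single integer seed through
`numpy.random.default_rng`. Components seed domain-separated streams
(`default_rng([seed, tag])`) so that, e.g., a fixture genome and a
candidate set built from the same user seed do not replay the same base
draws — without this, candidates literally reappear in the synthetic
background. Ranking ties use an absolute S_N tolerance of 1e−9 and final
lexicographic tie-breaks, making ranked output byte-stable across runs.
Score arithmetic is plain double precision; the identities checked exactly
(S_OFF of constructed cases, S_N of constant lists) are exact in floating
point by construction.

## Problem sizes

The bundled tests and the acceptance script run on synthetic genomes of
5–20 kb with tens of candidates, sizes chosen so the brute-force oracle
can shadow every scan. The scan itself is intended for real plant
chromosomes: the pigeonhole filter's verification work scales with block
occurrence counts, not genome length times query length. Auditing a
19-mer against a ~380 Mb genome reproduces published census tables only
up to the stated strand/dedup conventions (`--strands`, and the
(chrom, start, strand) site identity), which are toggles precisely
because the original conventions are unstated.

## Known limitations

- The default preference matrix is structural, not quantitative; S_N
  values are run-internal rankings until a measured matrix is supplied.
- The upstream/intergenic boundary is an interpretation (above).
- One representative transcript per gene; isoform-aware annotation is out
  of scope.
- Hamming, not edit, distance throughout; indel-mediated off-targets are
  invisible to the model.
- T0-mismatch scoring is a documented assumption, configurable but not
  derivable from published material.
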