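# Methods

`satellome` rebuilds a satellitome — the catalogue of satellite-DNA (satDNA)
families of a genome, each represented by a consensus monomer — from an
assembly plus short- and long-read sets, and characterizes every family by
abundance, copy number, read-level clustering and chromosome specificity.
This note documents the models, the defaults and the reasoning behind the
choices that were genuinely open.

## Pipeline overview

1. **Preprocessing.** Soft-masked bases are unmasked; every non-ACGT
   character becomes N. Lengths are preserved exactly.
2. **Tandem detection** in three rounds with increasing monomer-period
   ranges — (10, 200), (150, 1000), (800, 3000) bp — hard-masking (N) each
   round's calls before the next, so short periods cannot shadow long ones
   and vice versa.
3. **Consensus building** per array call, with strand re-orientation and a
   k-mer-coverage quality floor (>= 0.5).
4. **Deduplication** at 80% rotation-invariant identity, applied twice
   (within assembly of origin, then across detectors/assemblies).
5. **Contaminant screens** in fixed order: protein-coding, transposable
   element, organelle/rDNA.
6. **Final clustering** of the candidate pool (plus any known published
   monomers) on a bitscore-weighted similarity graph with Markov
   clustering; one representative per cluster.
7. **Quantification**: short-read abundance and copy number per 2C,
   long-read hit-count copy number, cross-validation (CNCV), adjusted copy
   number (ACN).
8. **Clustering metrics** MCNPR / MTSPR / MCOPR over long reads, with the
   10 kb MTSPR threshold separating clustered from dispersed families.
9. **Chromosome specificity**: per-chromosome hit counts, correspondence
   analysis (CA) of ln(1+x) counts, Mahalanobis distance from the origin,
   peak-copy-number (PCN) chromosomes, strict 1-/2-chromosome calls and
   the fully-anchored fraction.
10. **Nomenclature**: `<prefix>Sat<rank>-<length>[-cen|-subtel]`, ranks by
    decreasing genomic abundance.

## Alignment engine

All similarity decisions run through one affine-gap Smith–Waterman/Gotoh
aligner (numba-jitted, full traceback) with seed-and-extend scanning for
monomer-vs-chromosome and monomer-vs-read searches.

* Scoring: match +1, mismatch −2, gap open 5, gap extend 2 (a gap of
  length L costs 5 + 2L). Low-complexity filtering is off.
* E-values use the ungapped Karlin–Altschul form K·m·n·exp(−λS) with
  λ = 1.28, K = 0.46 — the published constants for the +1/−2 nucleotide
  scheme. Only threshold behaviour (E ≤ 1e−5 etc.) is consumed downstream.
* Seeds are exact 11-mers. Seed matches are clustered into candidate loci;
  a locus must hold at least max(2, min(30, qlen/100)) matches — a genuine
  copy at the 70%-identity admission floor still shares ~0.7^11 ≈ 2% of
  its k-mers, so the floor discards chance clusters without costing
  sensitivity. Within a locus a cursor tiles successive alignments so each
  monomer copy of a tandem array yields one hit; when the best window
  alignment is not the leftmost copy, the skipped stretch is rescanned.
* Hits on the same strand overlapping by more than 50% of the shorter are
  collapsed, keeping the higher score. Reported coordinates are 1-based
  inclusive, subject coordinates always on the forward strand.
* Monomers are rotation-ambiguous, so monomer-vs-monomer comparisons align
  one sequence against the doubled other (`pairwise_identity_circular`).

The engine's scores are verified in the test suite against an independent
pure-Python exhaustive DP on short random pairs, and against biotite's
aligner during development.

## Tandem detection and consensus

Periodicity is the modal distance between successive occurrences of
repeated 13-mers in a sliding window (window = max(6 kb, 4× the round's
maximum period), half-window step). A period is accepted when its support
(distances within ±2% of the mode) is at least 5 and at least 3× the
support of the same statistic on a base-shuffled window. Support positions
are clustered (split at gaps > 2.5 periods) so two arrays inside one
window yield two calls; adjacent window calls with periods within 10%
merge.

Monomer units are cut at the detected period and phase-standardized by the
rotation minimizing Hamming distance to the first unit; strand is
standardized by shared-k-mer count against a running 7-mer profile
(ties — including perfect palindromes — break to the lexicographically
smaller sequence). The consensus is a per-column majority vote in the
coordinate frame of the medoid unit, with each unit contributing votes via
a local alignment against the doubled medoid: the alignment absorbs both
rotation offsets and the phase drift that indels accumulate along an
array, which a plain rotation vote does not (a single internal indel
otherwise scrambles every downstream column of that unit).

Candidate quality is scored by **k-mer coverage**: the fraction of all
7-mer occurrences across the units whose 7-mer also occurs in the
consensus. A homogeneous family scores ≈ (1 − substitution rate)^7;
mixtures of unrelated units score low because only one component can be
represented. Candidates below 0.5 are discarded. This operationalization
is declared, not derived from any external tool's internal score, and
nothing downstream compares it to such a score.

## Curation

Deduplication is greedy centroid clustering, longest-first: a candidate
joins the first retained representative with circular identity ≥ 80% and
coverage ≥ 80% of the shorter sequence. The coverage clause is ours: a
bare identity threshold would merge unrelated monomers on the strength of
a 20 bp chance match.

The similarity graph admits an edge only at E ≤ 1e−5, identity ≥ 80% and
coverage ≥ 80% of the shorter sequence, weighted by the alignment
bitscore ((λS − ln K)/ln 2). Markov clustering iterates expansion (matrix
squaring) and inflation (entrywise power 2.0, renormalization) on the
column-normalized weight matrix until the largest entry change is below
1e−9 (entries below 1e−6 pruned; failure to converge in 200 iterations is
an error). Self-loops are set to each node's maximum incident weight — the
mcl tool's default — without which a two-node cluster converges to the
identity matrix and never merges. Clusters are attractor-connected
components; each cluster's representative is the member with the highest
short-read abundance, ties to the longer sequence (length alone when
clustering precedes quantification). Known published monomers added to the
pool are never dropped: a cluster containing one records the original name
in the family's provenance, and an unmatched known entry survives as its
own family.

Coverage profiles (per-position read depth over a consensus) support
manual curation; a consensus is flagged as potentially chimeric when a
contiguous ≥ 20% stretch has depth below 10% of the median positive depth.

## Contaminant screens

Order is fixed and logged: coding → TE → organelle/rDNA; a candidate is
removed by the first matching screen only.

* **Coding**: all six reading frames of the *doubled* candidate (an ORF
  split across the arbitrary rotation junction stays intact) are aligned
  against each reference protein; removal at E ≤ 1e−5 with ≥ 50% of the
  protein covered. The 50% rule is ours — the search is a translated-
  similarity stand-in for spliced alignment, and gene content is what the
  screen targets, so coverage is measured on the protein.
* **TE**: plain nucleotide similarity, removal at E ≤ 1e−3 (stand-in for
  profile-HMM scanning).
* **Organelle/rDNA**: removal at E ≤ 0.01 when hits to a single reference
  jointly cover ≥ 80% of the candidate; coverage is the merged union of
  hit intervals because fragmented hits are the norm for tandem queries.

## Quantification

Short reads map to at most one family each: the best local alignment of
the read against the doubled consensus (strand chosen by seed vote), kept
at score ≥ 30. Abundance is the percentage of all reads mapped to the
family — read counts, not base counts — and converts to copies per
diploid genome as

    CN = 2C_size(bp) × abundance(%) / (monomer_length(bp) × 100).

Long-read copy number is the total threshold-passing hit count (E ≤ 1e−5,
identity ≥ 70%, query coverage ≥ 70%) of the consensus across all reads
≥ 10 kb. A raw hit count equals copies per 2C only when the read set
totals ~1× 2C coverage; the synthetic study samples long reads at 15×, so
the pipeline also reports the coverage-normalized value
hits × 2C / (total read bases) and uses it for CNCV and ACN.

CNCV flags a family when |log10(PacBio CN / Illumina CN)| > 1 — one order
of magnitude, our operationalization of a "significant discrepancy" — and
summarizes the rest as the squared Pearson correlation of log10 CNs
(log scale because CNs span several orders of magnitude; a raw-scale
correlation would be dominated by the single largest family). ACN is the
geometric mean exp((ln a + ln b)/2); the final genomic abundance is
ACN × monomer length / 2C × 100.

## Clustering metrics

Per read: copy number (non-redundant hit count), total span (length of
the union of hit intervals — overlapping hits are not double-counted) and
coverage fraction. Per family, MCNPR, MTSPR and MCOPR are the maxima over
reads, each taken independently (they may come from different reads).
A family is clustered when MTSPR strictly exceeds 10,000 bp; the boundary
itself does not qualify. MCOPR is stored as a percentage.

## Chromosome specificity

Hits are counted per chromosome-named scaffold ("chr" prefix); hits on any
other scaffold are tallied as unplaced and provably never enter the CA
input matrix. Counts are transformed ln(1+x) (the +1 admits zeros; the log
damps multiplicative copy-number differences between chromosomes), then
standard CA: P = X/ΣX, S = Dr^−1/2 (P − r cᵀ) Dc^−1/2, SVD of S, row
principal coordinates Dr^−1/2 U Σ, two dimensions retained, with the first
nonzero loading of each dimension forced positive so coordinates are
reproducible to 1e−9 across runs. All-zero rows are dropped with a
warning; a table of rank < 2 is an error.

The Mahalanobis distance of each family's coordinates from the origin —
the point a family matching the average chromosomal profile maps to — is
computed with the sample covariance of all row coordinates
(pseudo-inverse with a warning when singular). Larger distance = less
uniform distribution.

PCN chromosomes are those with counts ≥ 50% of the per-chromosome maximum
(a declared rule; raw counts are reported alongside so users can re-call).
Strict specificity requires positive counts on exactly 1 or 2 chromosomes
regardless of unplaced copies; anchoring (no unplaced copies at all) is
the separate `fully_anchored` flag, and the anchored fraction is reported
as an exact ratio.

## In-silico PCR

An amplicon is a plus-strand stretch reading `forward … revcomp(reverse)`
(or the symmetric arrangement with the primer roles swapped, which makes
the product multiset invariant under reverse complementation of the
template). Product length runs from one primer's 5′ site start to the
other's 5′ site end, inclusive — standard PCR sizing. Circular templates
(tandem monomers) are searched doubled, keeping products no longer than
the template. Primers must be ≥ 15 bp; mismatch tolerance defaults to 0.

## Synthetic data: what it emulates and what it does not

The generator plants known truth so every stage is scored against a
manifest: multi-chromosome genomes with tandem arrays (specified monomer
length, GC, per-chromosome copies, per-copy substitution and indel rates,
arrays on random strands), unplaced scaffolds carrying extra copies,
contaminant tandem arrays (organelle-, rDNA-, TE- and protein-coding-like)
with matching reference sets, uniform-coverage 150 bp short reads (1%
error) and lognormal-length long reads truncated at 10 kb (mean 25 kb,
log-sd 0.35, 0.2% error). The copy mutation model is i.i.d. substitutions
plus geometric-length indels — the simplest model producing the identity
spread the 70–80% thresholds are designed for. All generators are
bit-reproducible under a fixed seed.

The default study conditions are five families on a ~4.7 Mb, 8-chromosome
genome: 377 bp × 1230 copies on all chromosomes (subtelomeric-like, one
array per chromosome, some copies unplaced), 40 bp × 4900 (two arrays per
chromosome, some unplaced), 2500 bp × 80 confined to one chromosome,
183 bp × 400 confined to another, and a dispersed 741 bp × 96 family laid
out as four 3-copy arrays per chromosome — at most ~8.9 kb of monomer per
chromosome, so its ground truth stays below the 10 kb clustering threshold
by construction. Substitution rates are 2–5%. Short reads at 10×, long
reads at 15×. The 2C size of the synthetic species is the genome length,
so estimated copies per 2C are directly comparable to planted copies.

Real data differ in ways the generator does not model: HiFi error
profiles, diploid heterozygosity, higher-order repeat structure,
transposon nesting, GC-biased coverage and library artifacts. Passing the
synthetic suite therefore demonstrates the correctness of the algorithms
and their statistical behaviour under the stated noise model, not
performance on any particular real genome.

## Numerical choices and degenerate inputs

* DP ties resolve toward the earliest cell in fill order; alignment ties
  between strands keep the forward strand.
* `local_align` returns no hit when the best score is ≤ 0; empty
  sequences are input errors.
* CNCV requires ≥ 3 families with positive copy numbers on both
  platforms; fewer is an error.
* An empty satellitome makes the anchored fraction an error, not a NaN.
* An all-N scaffold reports GC 0 with a warning.
* MCL non-convergence raises with the last delta in the message.

## Known limitations

* The detector is a simplified periodicity scanner: it does not decompose
  higher-order repeats, and arrays shorter than two monomer copies are
  invisible to it.
* Copy numbers for families whose monomer is much longer than a short
  read rest on the read-share estimate, which conflates partial edge
  overlaps with full copies (a ≲ 2% effect at the default array sizes).
* The coding screen is translated similarity, not spliced alignment: an
  intron-riddled gene fragment diverged beyond direct similarity would
  pass.
* In-silico PCR reports all products of exact (or bounded-mismatch)
  primer sites; it does not model polymerase processivity or competing
  short products.
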