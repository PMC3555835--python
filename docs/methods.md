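# Methods

This note documents the models, algorithms and numerical choices behind
isomirkit, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Preprocessing

Reads are assigned to libraries by **exact** 5-nt MID prefix match — the
454-era barcodes carry no error-correction structure, and at desk scale a
false assignment is worse than losing a read, so no mismatch tolerance is
offered. The insert is the region between the MID and the first exact
occurrence of the 3' adapter (full remainder if the adapter is absent);
no partial-suffix adapter alignment is attempted because the targeted
libraries are gel-purified, fixed-structure constructs. Sequences are
canonicalised to uppercase DNA (U→T) before collapsing. Filters are
inclusive: length in [15, 29] and copy number CN ≥ 3, both configurable.
Unassignable or empty reads are logged with a reason, never silently
dropped, and the pipeline's accounting table proves read conservation
(assigned + discarded = input; annotated + unannotated + filtered =
assigned).

## End-tolerant annotation

A tag matches a mature reference when some ungapped offset alignment has
a 100% identical contiguous core covering at least (query length − 4)
query positions, with the total number of terminal variant nucleotides —
query extensions beyond the reference, query truncations relative to the
reference, and mismatching terminal positions, summed over both ends —
at most 4. The tolerance of 4 is read as a *total* over both ends rather
than 4 per end: that is the stricter of the two readings and still admits
the 1–2 nt end variants that dominate real isomiR tables. Internal
substitutions are not tolerated by default (the matching semantics are
exact-core); an `allow_internal_mismatch` knob admits up to N internal
mismatches for users who want edited isomiRs annotated rather than sent
to the novel-discovery pool.

The matcher enumerates every admissible (offset, 5'-trim, 3'-trim)
triple — the tolerance bounds the offset to a window of at most nine —
and minimises total terminal variants, breaking ties by longer core,
then smaller |offset|. When several references match at equal cost the
assignment priority is: porcine ("ssc"-prefixed) reference first, then
longer core, then lexicographic id, reflecting the convention of
annotating same-species miRNAs before orthologs. A brute-force oracle
that enumerates *all* offsets and trims column-by-column is kept in the
test suite and must agree on 10,000 random cases.

Clusters inherit the name of the reference their tags matched; the
member with maximal CN (ties broken lexicographically, for determinism)
is the predominant isomiR, and a divergence flag records when it differs
from the database sequence. Per-group predominance sums counts-per-
thousand (not raw counts) within the group so deep libraries cannot
dominate shallow ones. Profiles exclude clusters with CN < 3; the
percentage share uses all length-filtered reads as denominator.

## Novel discovery and folding

Candidates must map perfectly and uniquely to the genome (both strands
searched, minus-strand hits reported in plus coordinates), be 19–23 nt,
fall outside the annotation mask, and have CN > 2. These four filters
commute, so they are applied in a single pass. Clustering is
single-linkage over ≥ 1 nt same-strand overlap — the most inclusive
deterministic reading of "positioned in the same region". Each cluster's
max-CN member is its reference sequence; its locus ± 50 nt (clipped and
logged at chromosome ends, strand-oriented) is the putative precursor.
Coordinates are 0-based half-open internally and 1-based inclusive in
user-facing tables, named in the column header.

Folding is **base-pair maximisation** (Nussinov-style dynamic programme,
minimum hairpin loop 3 nt, Watson–Crick plus G·U wobble pairs), not
thermodynamic minimum free energy: the pass/fail decision below depends
on pairing topology, not energies, and a maximisation DP can be audited
against an exhaustive structure-enumeration oracle, which the test suite
does for every precursor in a fixed set. Because max-pair structures of
a 121-nt window are massively degenerate, the traceback breaks ties by
the number of stacked pairs, so a contiguous helix is reported when one
attains the optimum; the pair *count* — the audited quantity — is
unaffected by the tie-break.

A candidate passes when, in the computed structure, (i) at least 16
pairs connect the mature span to one side, arranged as a single helix
whose steps allow at most 1-nt bulges with at most two such
interruptions; (ii) the span pairs essentially in one direction (at most
two terminal bases grabbed the other way by the pair-maximising
objective); and (iii) no pair lies entirely inside the mature span (no
multiloop branching across it). The helix-contiguity requirement is what
separates real stems from the scattered pairing a maximisation objective
assigns to random sequence: across 60 simulated genomes, planted
hairpins always contained a ≥ 16-pair helix while random decoy loci never
exceeded 13. The 16-pair threshold follows the community guideline of
roughly 16 bp between a candidate mature and the opposite arm; all
thresholds are exposed as parameters.

One caveat is recorded rather than hidden: with G·U pairs enabled the
maximal pair count is *not* invariant under reverse complement (a G·U
pair maps to an unpairable A·C), so the strand-symmetry property holds —
and is tested — in Watson–Crick-only mode. Precursors are always folded
in their transcribed (strand-oriented) orientation, so the wobble
asymmetry does not affect pipeline results.

## Expression

cpt = raw / library_total × 1000, where the library total counts all
length-filtered reads — this denominator, with unweighted arithmetic
means across the libraries of a group, is the only combination that
reproduces the bundled survey's printed fold-change cells, and both
choices are therefore fixed. The signed fold change is +a/b when group a
is at least group b and −b/a otherwise, so |FC| ≥ 1 and FC(a,b) =
−FC(b,a) with +1/−1 identified at equality. DE requires |FC|
strictly > 1.5, or zero raw counts in every library of exactly one
group. No p-value is attached: with one pooled library per breed the
ratio is the statistic, and attaching a count-model test would
misrepresent the design. Printed fold changes are rounded to 2 dp and
compared at that precision, not bit-exactly.

## qPCR quantification

Quantities come from the standard curve (absolute-relative
quantification), not ΔΔCq, because the validation protocol being
modelled runs a dilution series in every assay. Efficiency is
10^(−1/slope) − 1 with QC pass at 90–110% and r² ≥ 0.99 (inclusive
bounds). geNorm stability is the single-pass M statistic — mean over
partner references of the SD (n−1 denominator) across samples of the
pairwise log2 ratio — with threshold exclusion at M < 1.5; the original
iterative worst-gene elimination is available behind `iterative=True`.
The normalisation factor is the per-sample geometric mean of retained
references; targets are divided by it and expressed relative to their
lowest per-sample mean, then log2-transformed. Downstream group testing
(e.g. a two-way analysis of variance on RT replicate and breed) is
deliberately delegated to standard routines; `analyze_cq_table` emits
the tidy long-format table they expect.

## Enrichment

Exact hypergeometric tails, p_over = P(X ≥ k) and p_under = P(X ≤ k),
computed from the survival and distribution functions; both tails are
reported for every category. Benjamini–Hochberg is applied to each tail
family separately by default because over- and under-representation are
distinct hypothesis families; a `joint_tails` flag pools them for users
who prefer a single family. The universe defaults to all genes appearing
in the category map, the least surprising background when none is given.
Target prediction is consumed as input (gene lists per miRNA); no
predictor is re-implemented.

## The synthetic-data generator

The generator emulates the *structure* of a pooled multiplexed 454-style
run: seven libraries whose default identities, breed groups and depths
(4,022–23,815 reads) follow the kidney survey design, a uniform-ACGT
background genome with planted hairpin loci, and reads of the form
MID + insert + adapter. Planted hairpins place the mature in a random
arm with a 6-nt loop; the opposite arm is the reverse complement with
three interior positions switched to G·U wobble partners, so each mature
maps to exactly one genomic site while the stem still pairs fully. Novel
hairpins are identical constructions absent from the mature reference
and annotation mask; decoys are bare sequences planted without hairpin
context, to exercise the folding screen's rejection path.

IsomiRs follow an explicit end-variability model: each end shifts
independently (default p = 0.30 at the 3' end, 0.10 at the 5' end,
reflecting the higher 3' variability real surveys observe), a shifted
end is truncated or template-extended equiprobably by 1–2 nt (the
published end differences are mostly 1–2 nt; the cap is configurable up
to the matcher tolerance of 4), and a single internal substitution
occurs with p = 0.02. Extensions are *templated* — read from the
precursor flanks — so simulated isomiRs remain genome-mappable, matching
the biological origin of end variants in imprecise Drosha/Dicer
cleavage. No survey quantifies these rates, so they are free parameters
of the config, not estimates of any dataset. Base expression weights are
log-normal (σ = 1, clipped to [0.35, 40]), giving the skewed profiles
with a dominant miRNA that real tissues show. Read counts per library
are exactly multinomial at the configured depth; FASTA is the native
output (quality strings, if FASTQ is requested, would be constant
placeholders — the pipeline never reads qualities). All randomness
derives from one integer seed via fixed offsets; identical seed and
config give byte-identical outputs.

What the generator does **not** emulate: 454 homopolymer errors, quality
degradation, RNA degradation, adapter ligation biases, cross-mapping
between paralogous miRNA families, or arm switching. Tests passing on
simulations therefore demonstrate algorithmic correctness (filters,
matching semantics, clustering, folding, normalisation arithmetic) — not
robustness to platform-specific artefacts.

### Parameter-recovery conditions

The recovery check plants a 2.0× expression effect and asks that the
estimated |FC| fall in [1.6, 2.5] for at least 90% of affected miRNAs
across five seeds. Ratio normalisation by library totals is unbiased
only when differentially expressed miRNAs are a minor share of the
miRNAome — the usual most-genes-not-DE assumption — so the check plants
4 affected miRNAs out of 40, balanced across groups (two up in EU, two
up in AS, so composition shifts cancel between numerator and
denominator groups), at a library depth of 16,000, which puts
multinomial sampling error well inside the acceptance window. An
unbalanced design at shallow depth visibly exhibits the composition
bias (estimates near 1.75 for a true 2.0) — that is a property of cpt
normalisation itself, faithfully reproduced, not an estimator defect.

## Problem sizes

The test suite and acceptance script run simulations of 12–40 miRNAs on
11–22 kb genomes at depths of 1,500–16,000 reads per library — small
enough to finish in minutes on one CPU while keeping every planted
structure and effect recoverable at the stated tolerances. The folding
oracle's fixed test set uses precursors up to 40 nt, the largest size at
which exhaustive structure enumeration stays tractable.

## Known limitations

* The matcher is ungapped; indels inside the core are never aligned.
* Base-pair maximisation over-pairs random sequence relative to MFE
  folding; the helix-contiguity criterion compensates, but the
  dot-bracket structures should be read as screening evidence, not
  predicted physical structures.
* The expression stage reproduces a ratio-based, replicate-free design;
  it intentionally offers no count-model inference.
* Cross-species reference sets are supported by the priority rule, but
  no family-level (seed-sequence) inference is attempted.
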