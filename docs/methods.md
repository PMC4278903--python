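# Methods

## Variant representation and identity

Coordinates are 0-based half-open throughout. An SNV spans `[p, p+1)`; an
insertion is a zero-length anchor `[p, p)` between reference bases; empty
alleles are empty strings (rendered `-` in tab-separated output). Variant
types are classified purely from the alleles: SNV (both length 1), insertion
(empty reference), deletion (empty alternate), substitution (everything else
with both alleles non-empty, including unequal-length block replacements —
the convention of Complete-Genomics-style var files, since no sharper
definition of "substitution" is in general use).

Two observations are *the same variant* iff their normalized keys
`(chrom, start, end, ref, alt)` are equal. Normalization trims shared
prefix/suffix bases and left-aligns pure indels (shift left while the
shifted representation spells the same alternate haplotype); it is
idempotent, and an independent haplotype-spelling oracle in the test suite
verifies equivalence on randomized indels in repeat contexts. Matching is
exact-key only — no positional fuzz windows — because exact keys make the
downstream set algebra reproducible and order-insensitive. How the original
vendor tooling matched variants between genomes is not documented publicly;
exact-key matching after normalization is this package's explicit stand-in,
and VCF anchor bases are trimmed on read precisely so that VCF and
tab-separated inputs produce identical keys. Input VCFs are assumed
left-aligned, as the format's convention requires; the full left-alignment
pass is applied wherever a reference window is available (the simulator
normalizes every call it emits).

## Triage

Germline subtraction removes from tumor (or node) every key *confidently
called* in the matched normal. A key coinciding with a normal *no-call*
survives but is tagged `low_confidence_somatic`: absence of evidence in the
normal is not a confident reference call, and the distinction is preserved
rather than silently collapsed. The tumor/node partition is then plain key
algebra — shared = intersection, private = differences — so
`|shared| + |tumor_private| + |node_private| = |union|` holds by
construction and is fuzz-tested.

The depth filter keeps calls with position read depth ≥ `min_depth`
(default 100, the threshold used to focus on well-measured truncal
variants). For shared keys the threshold must hold in **both** samples by
default (`either` is available); the choice matters only near the depth
floor and is logged. Known/novel judgment is membership in a user-pinned
catalog snapshot (no live database queries, for reproducibility); the
count grid reports total/known/novel per variant type for the tumor and
node somatic sets and their sample-unique subsets, with
total = known + novel in every cell group by construction.

## Annotation

Region assignment is strand-aware with fixed precedence
`splice > cds > utr > intron > upstream_tss > downstream > flank`.
"Upstream of the TSS" is promoter-proximal sequence in transcription
orientation: upstream of a minus-strand gene lies at larger coordinates.
The upstream window defaults to 2000 bp and the flank window to 2000 bp —
promoter-scale conventions, since no quantitative window is standard — and
both are configurable and echoed in the run log. Splice sites are the first
and last 2 bp of each intron (the canonical donor/acceptor dinucleotides);
the transcription-5′ intron edge is the donor. Insertions are placed by
their anchor point and count as inside an interval only when strictly
interior, a deterministic tie-break at exon boundaries. A call overlapping
several genes is annotated against all of them; panel restriction keeps a
call if *any* assignment hits a panel gene, avoiding an arbitrary
single-gene choice.

Functional impact: CDS SNVs are translated codon-by-codon (standard code,
reverse-complemented on the minus strand) into
missense/synonymous/nonsense; CDS indels and length-changing substitutions
are frameshift iff the net length change is not a multiple of 3, else
in-frame; length-preserving CDS substitutions are reported as
`coding_substitution`; splice-window hits are `splice_site`. A gene whose
total CDS length is not a multiple of 3 is kept with a warning and a
partial terminal codon is called conservatively as missense.

Gene-set enrichment is the hypergeometric upper tail (scipy) of the
observed term overlap given an explicit, user-supplied background, with
Benjamini–Hochberg adjustment (statsmodels) reported alongside raw values;
thresholds are applied to raw p-values by default. The operation requires
an explicit term→gene map; no ontology data ships with the package, so
published term-level p-values that depended on particular GO/GAD releases
and implicit backgrounds are out of reach by design.

## Clonality statistics

VAF = 100 × alt reads / depth, two decimals; depth 0 yields an undefined
marker excluded from summaries. Shared somatic keys are labeled truncal,
the rest by their private sample. Frequencies are always reported
per-sample (a shared variant carries both). VAF > 80% triggers a free-text
note that the observation is consistent with homozygosity or amplification;
the pipeline deliberately does not call genotypes or copy number. The
multi-clone flag fires when one gene carries ≥ 2 same-sample variants whose
VAFs differ by more than 30 percentage points (default): under the
expected-VAF model ρ·f/2 a spread that large cannot come from one clone at
plausible purity, while the 23.4% vs 92.9% worked pair flags and
equal-VAF pairs do not. The threshold is configurable and logged.

## The simulator

`ClonalArchitecture` describes the truth: variant counts per origin class,
subclone cell fractions, per-sample purity, depth model, variant-type mix,
catalog membership rate, caller threshold and seed. Defaults encode the
targeted study conditions: mean depth 100 with negative-binomial
overdispersion (variance = μ(1 + αμ), α = 0.02; α = 0 recovers Poisson —
whole-genome depth is overdispersed in practice), purity 0.9 in tumor and
node (microdissection to ~90% neoplastic cellularity), variant-type
probabilities 0.841/0.07/0.069/0.02 (the genome-wide SNV-dominated mix),
95% of germline variants present in the known catalog, subclone fractions
(0.6, 0.3), and a 3-alt-read caller floor. Problem sizes default to 300
germline / 80 truncal / 60 + 60 private variants over a 40-gene toy
chromosome — desk scale, chosen so every rate in the acceptance checks is
estimated on hundreds-to-thousands of variants while a full trio simulates
in well under a second.

Per variant and sample, depth ~ NB(μ, α) and alt reads ~ Binomial(depth,
expected VAF), with expected VAF = purity × fraction × 0.5 for heterozygous
somatic variants and 0.5 for germline. Somatic calls are emitted iff alt
reads ≥ the caller floor — an explicit, deliberately simple stand-in for a
production caller that reproduces the masking of low-fraction subclones at
finite depth (call rate is monotone in the subclone fraction). Germline
variants are emitted in all three samples unconditionally, reflecting that
a diploid caller genotypes a 50%-VAF het essentially always at these
depths; this also makes germline leakage through subtraction exactly zero,
so any observed leakage indicates a pipeline defect rather than simulator
noise. All randomness flows from the single architecture seed; identical
seeds give byte-identical outputs.

What the simulator does **not** model: sequencing error and mapping
artifacts, copy-number variation and loss of heterozygosity, homozygous or
amplified somatic states, multi-sample joint genotyping, and positional
clustering of mutations. Passing recovery tests therefore demonstrates the
*set algebra, filtering and labeling logic* under clean read-sampling
noise, not robustness to artifacts of real sequencing.

## Recovery evaluation

`evaluate_recovery` scores pipeline clonality labels against truth over
somatic keys; truth keys missing from the output count as misses against
recall. The recovery harness runs the pipeline with `min_depth = 0`: at a
mean depth of 100 the ≥ 100 filter removes roughly half of all calls *by
design*, which measures the filter, not the labeling; recovery is about
labeling. Germline leakage counts truth-germline keys surviving
subtraction (expected exactly 0, see above).

## Numerical and degenerate-input choices

* Empty sample sets propagate as empty partitions; empty catalogs/panels
  warn; an empty panel is rejected at restriction time.
* Depth-0 calls have undefined VAF and are excluded from frequency
  summaries; missing VCF depth tags are warned about and recorded as 0 so
  the depth filter removes them.
* Multi-allelic VCF records are split into biallelic calls; non-PASS
  records are retained as no-calls so that "absent" and "not assessable"
  stay distinguishable.
* Duplicate catalog keys keep the first ID with a warning.
* Type proportions and VAFs are rounded to two decimals at the reporting
  boundary only; internal arithmetic is unrounded.

## Limitations

Exact-key matching cannot pair calls that a caller represents
inconsistently beyond left-alignment (e.g. complex MNV decompositions).
Impact calls are single-transcript (one gene model per symbol), with no
isoform awareness or protein-domain context. The enrichment operation
reports over-representation only. Copy number, purity estimation and
formal subclonal deconvolution (VAF clustering into clone trees) are out
of scope; the multi-clone flag is a deliberately simple pairwise-spread
heuristic, not a mixture model.
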