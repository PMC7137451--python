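# Methods

## The measurement model

An smMIP panel captures single template molecules and tags each with a random
UMI, so after collapsing duplicate reads the per-probe count is a molecule
count, not a read count. Both analyses in this package treat that count as
the primary observable.

### UMI consensus

Reads are grouped by the exact (probe, UMI, strand) triple. Sequence payloads
are merged by per-position majority vote among reads of the group's modal
length; repeat-length payloads by the modal length. Both tie-breaks are
deterministic (lexicographically smallest base, smallest length), so collapse
is a pure function of the read multiset and invariant under read order.
No error-tolerant UMI clustering is attempted: with 8 bp tags and per-probe
molecule numbers in the hundreds, tag collisions and near-miss merges are
rare enough that exact matching keeps the contract simple; directional
clustering would be the natural extension if UMI error rates warranted it.
Strand stays part of the molecule key (the two strands of one fragment count
as two molecules), keeping strand-resolved counts available; callers consume
the strand-summed totals.

### Amplification calling

Normalization divides each probe count by the sample median over **all**
panel amplicons (every role, sex controls included; an exclusion list is
configurable). The median is the deliberate choice over the mean: a
high-level amplification inflates only its own ~10 probes, which shifts a
~350-probe median by a rank or two but drags the mean arbitrarily.

The per-gene value is the arithmetic **mean** of the gene's
amplification-role probes' normalized coverages. The aggregation over probes
was a genuinely open choice; the mean matches the baseline's per-gene mean
referencing and makes gene values linear in molecule counts (which the
mixture-linearity property test exploits); the median is available by
configuration. Zero-count probes are treated as technical dropouts and
excluded while at least 50% of the gene's probes remain evaluable; below
that the gene is reported not-evaluable rather than guessed.

The baseline stores, per gene, the mean and sample SD (ddof = 1) of the
gene value across ≥ 2 normal FFPE controls; controls failing the sample QC
gate are excluded with a warning. Relative coverage, z-score, the ×2 alleles
per genome equivalent, and the purity correction
`(2·RC − 2(1−p))/p` follow directly. The z-score is **informational only**:
its published pairing with the RC threshold (z > 6.4 at RC 3.0) is an
empirical property of one control series, so gating on it would silently
re-tune the assay whenever the baseline changes. With degenerate controls
(SD = 0) z is undefined, flagged, and calling proceeds on RC alone.

Boundary semantics are fixed by the validated rules: amplified at RC ≥ 3.0
(inclusive), potentially amplified in [2.0, 3.0), QC pass strictly above 25
molecules median coverage. With replicates, a gene is amplified only when
every replicate reaches the threshold; the reported RC is the replicate mean.

### MSI calling

Allele counting includes a repeat length iff its count **strictly** exceeds
5% of the modal count; at a modal tie the shared top count is the reference
and all tied lengths count as alleles. A locus is unstable iff its allele
count **strictly** exceeds the baseline mean + 2 SD. "Exceeds" is taken
literally in both rules; boundary cases are pinned by tests. No SD floor is
applied: with SD = 0 the threshold is the mean itself, so any excess allele
marks instability — accepted as the literal rule and flagged in the result.

Loci are evaluable at ≥ 30 unique molecules (configurable). A fixed depth
floor had to be chosen because real panels show "could not be analyzed" loci;
30 molecules mirrors the common mSINGS default and sits above the coverage
where the 5% rule becomes dominated by sampling noise. Loci evaluable in
fewer than two normals are unbuildable and excluded from scoring on both
sides of the fraction.

The score is unstable/evaluated loci. Classification: MSI-high at ≥ 30%,
MSS below 15% but only reportable at ≥ 30% tumor purity (below that a
negative score is indistinguishable from dilution), indeterminate between.
Score cutoffs are inclusive (≥) by default — the borderline duplicate
analyses around 20% motivated making the boundary configurable. Replicate
scores are reported individually; classification uses their mean.

## The synthetic-data generator

The generator's defaults are the study conditions of the validation
experiments, and every draw is a pure function of the spec seed.

* **Panel**: 13 amplification genes × 10 probes, 150 hotspot mutation probes
  over 33 genes, 55 microsatellite loci, AMELX/AMELY sex controls
  (337 probes). Probe capture efficiencies are log-normal (σ = 0.55, mean 1),
  fixed per probe id — so, as in a real pool, they are a panel property that
  cancels against the external baseline; σ = 0.55 puts ≈ 96% of probes within
  one order of magnitude of the median, matching observed panel uniformity.
* **Depth**: mean 300 unique molecules per probe (200 in the amplification
  re-enactment, mirroring a mid-output run), negative-binomial with
  `var = μ + 0.02·μ²` on top of the efficiency spread; dispersion 0 gives
  deterministic counts for degenerate-spec tests.
* **Amplification**: an amplified gene's expected depth scales by
  `(p·k + (1−p)·2)/2` — the generative counterpart of the purity correction,
  which is what makes parameter recovery a meaningful round trip. Positive
  controls use (k, p) pairs of (10, 0.7), (14, 0.5), (20, 0.4), (25, 0.6),
  (40, 0.9): high-, mid- and low-level amplifications whose expected RC all
  clear 3.0, as positive controls should.
* **Microsatellites**: stable loci emit a stutter ladder — lengths L₀−j,
  j = 0..3, with geometric decay q drawn per locus from [0.08, 0.20]. Tight
  loci yield two confident alleles; high-q loci hover near the 5% cut, which
  is precisely what gives the normal baseline a non-zero SD. Unstable loci
  mix in two shifted ladders (−4 and −7 repeats, weights 0.45/0.35/0.20 with
  the native ladder) in the tumor-derived fraction of molecules only, so
  detectability degrades with purity the way dilution series show. MSI
  cohorts destabilize 22–87% of loci (35–80% for the diagnostic-threshold
  re-enactment) at purities 0.5–0.9.
* **Reads**: 1 + geometric(0.25) PCR duplicates per molecule, 0.2% per-base
  substitution errors, uniform 8 bp UMIs. UMI/strand keys are uniquified
  within a probe, so consensus counts recover the truth manifest exactly —
  the idealization that a UMI is meant to be; real collisions at these depths
  would be ~1 per 10⁴ molecules.

What the generator does **not** emulate: FFPE deamination artifacts and any
sequence-level mutation signal (variant calling is out of scope), locus- or
GC-dependent capture bias beyond the static efficiency term, quality strings,
inter-run batch effects within one baseline, and real microsatellite motif
structure (lengths are abstract integers). Passing tests therefore
demonstrate the statistical machinery — normalization, referencing,
thresholding, purity arithmetic — under realistic noise, not robustness to
every wet-lab failure mode of real FFPE material.

## Numerical and degenerate-input choices

* Sample median of an all-zero column → explicit failure ("sample failed"),
  surfaced as a dropout in reports rather than a division by zero.
* Gene with zero evaluable probes, baseline mean ≤ 0, or locus missing from
  the baseline → not-evaluable, never a silent 0 or NaN.
* Purity unknown: the purity-corrected allele count and detection floor are
  withheld with an explicit error/None — no default purity is assumed; the
  MSS purity gate treats unknown purity as "too low to report MSS".
* Baselines serialize to JSON and round-trip exactly; all TSV dialects are
  bit-stable (read∘write = id), so fixtures are diffable.
* Reports embed a config snapshot (JSON-native) and are byte-identical under
  identical inputs.

## Problem sizes

The test suite and the validation re-enactments run on the cohort sizes of
the original experiments (10–20 controls, 13–33 samples per series) at
200–300 molecules mean depth on the 337-probe default panel; read-level
simulations use a trimmed panel (~100 probes) at depth 40–150. Recovery and
false-positive-rate properties average over 100–200 seeded simulations.

## Known limitations

* Deletions, subclonal amplifications and SNP-allele-frequency support are
  out of scope; calling is coverage-threshold-based by design.
* The per-gene aggregation (mean) and the sex-check thresholds
  (AMELY/AMELX ≥ 0.25 → male, < 0.05 → female) are package choices where the
  assay description is silent; both are configurable and flagged as such.
* Tumor purity estimates are themselves error-prone; the purity-corrected
  allele counts inherit that error linearly in 1/p, which is why the
  detection floor is reported next to every call.
* The MSI caller assumes the baseline and samples share one panel version;
  loci added later must be re-baselined before they contribute to scores.
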