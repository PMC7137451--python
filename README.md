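# mipscreen

Targeted-panel screening of FFPE tumor samples for **gene amplifications** and
**microsatellite instability (MSI)** from single-molecule molecular inversion
probe (smMIP) sequencing — the computational side of a combined diagnostic
workflow in which one small NGS panel answers several predictive questions at
once, without a paired normal sample.

It is written for molecular-diagnostics and bioinformatics engineers who have
UMI-tagged reads (or precomputed unique-coverage tables and repeat-length
histograms) from an smMIP panel and need reproducible, threshold-based calls
with explicit QC and detection-limit annotations.

## What it computes

**Unique-molecule coverage.** Reads sharing a (probe, UMI, strand) key are
collapsed into consensus molecules (`umi_consensus`); the per-probe molecule
count is the unit of all downstream analysis.

**Gene amplification** (`cnv_caller`). Per sample, probe counts are normalized
by the sample's median over all amplicons (robust to the very probes an
amplification inflates); per gene *g* the normalized coverage is referenced
against an external baseline of normal FFPE controls:

    RC_g = x̄_g / μ_g                    relative coverage (fold change)
    z_g  = (x̄_g − μ_g) / σ_g            z-score vs the control series
    alleles per genome equivalent = 2·RC_g
    tumor allele count = (2·RC_g − 2(1−p)) / p      for neoplastic fraction p

A gene is **amplified** at RC ≥ 3.0, **potentially amplified** in [2.0, 3.0),
and the sample fails QC unless its median unique coverage per amplicon
exceeds 25 molecules. The detection floor — the minimal tumor-cell allele
count reaching RC 3.0 at purity *p* — is reported alongside every call.

**MSI** (`msi_caller`). Per microsatellite locus, alleles are counted from the
repeat-length histogram (a length counts iff its read count strictly exceeds
5% of the modal count); a locus is **unstable** iff its allele count strictly
exceeds the normal-baseline mean + 2 SD. The sample score is the fraction of
evaluated loci that are unstable: ≥ 30% → MSI-high, < 15% → MSS (reportable
only at ≥ 30% tumor purity), 15–30% → indeterminate (orthogonal follow-up).
A legacy two-way rule at the 20% cutoff reproduces the original validation.

**Synthetic data** (`synthetic_data`). A seeded generator emulates FFPE runs —
log-normal probe efficiencies, negative-binomial depth noise, PCR duplicates
and base errors, stromal dilution of amplifications, and stutter-ladder
broadening at unstable microsatellites — with a full truth manifest, so the
whole pipeline is testable without sequencing data.

## Worked example

```bash
mipscreen simulate --seed 7 --n-normal 10 --n-mss 1 --n-msi 1 --n-amplified 1 --out fixtures
# -> 13 samples -> fixtures (panel.tsv, coverage.tsv, profiles.tsv, samples.tsv, truth.json)

mipscreen baseline-cnv --coverage fixtures/normals.tsv --design fixtures/panel.tsv --out cnv_baseline.json
# -> amplification baseline: 13 genes from 10 controls -> cnv_baseline.json
mipscreen baseline-msi --profiles fixtures/normal_profiles.tsv --out msi_baseline.json
# -> MSI baseline: 55 loci (0 unbuildable) from 10 normals -> msi_baseline.json

mipscreen cnv --coverage fixtures/coverage.tsv --design fixtures/panel.tsv \
    --baseline cnv_baseline.json --sample AMP_01 --purity 0.7 --out calls
# -> AMP_01: ALK=amplified
```

(`normals.tsv` / `normal_profiles.tsv` are the NORM_* columns of the simulated
run; in practice they are your normal-control samples.) The call table for
`AMP_01` — a simulated tumor carrying a true ALK copy number of 10 at 70%
purity — reads:

```
gene  relative_coverage  z_score  alleles_per_genome_equivalent  tumor_allele_count  detection_floor  status
ALK   3.479              47.59    6.958                          9.08                7.71             amplified
BRAF  0.950              -0.81    1.900                          1.86                7.71             not_amplified
```

RC 3.48 is the stroma-diluted fold change ((0.7·10 + 0.3·2)/2 = 3.8 expected);
inverting the purity correction recovers ≈ 9.1 of the true 10 alleles per
tumor cell, and the detection floor says that at 70% purity no amplification
below ≈ 7.7 tumor-cell alleles can reach the RC ≥ 3.0 threshold. The MSI
sample of the same run (22% of loci truly unstable, purity 0.58):

```bash
mipscreen msi --profiles fixtures/profiles.tsv --baseline msi_baseline.json \
    --sample MSI_01 --purity 0.8 --legacy-cutoff --out calls
# -> MSI_01: score=0.24 -> indeterminate
```

scores 24% unstable loci: positive under the legacy 20% validation cutoff but
*indeterminate* under the stricter diagnostic bands — exactly the borderline
zone the three-way rule routes to orthogonal confirmation.

`mipscreen report` combines both analyses with QC and an AMELX/AMELY sex
concordance check into one JSON report; `--help` on any subcommand lists the
options.

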