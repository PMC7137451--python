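"""Baseline-referenced gene amplification analysis.

The copy-number signal of a targeted smMIP panel is carried by unique-molecule
coverage. Per sample, each probe's unique count is normalized by the median
count over all amplicons of the sample (the median is robust to the very
probes an amplification inflates, unlike the mean). Per gene, the normalized
coverages of the gene's amplification-role probes are averaged, and that value
is referenced against an external baseline built from normal FFPE controls:

* relative coverage (fold change)  RC = sample gene value / control mean;
  2 * RC is the number of alleles per genome equivalent,
* z-score  z = (sample gene value - control mean) / control SD,
* purity-corrected tumor allele count
  (RC * 2 - (1 - p) * 2) / p  for neoplastic-cell fraction p, i.e. the number
  of alleles present per tumor cell after subtracting the diploid stromal
  contribution.

Calls are categorical: a gene is *amplified* at RC >= 3.0, *potentially
amplified* in the 2.0 <= RC < 3.0 band, and the whole sample fails QC when its
median unique coverage per amplicon is not strictly above 25 molecules. The
z-score is reported as an informational statistic, not used as a second gate:
its published correspondence (z > 6.4 at RC 3.0) is a property of one control
series, not a portable threshold.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError
from .panel_model import CoverageMatrix, PanelDesign

logger = logging.getLogger(__name__)

STATUS_AMPLIFIED = "amplified"
STATUS_POTENTIAL = "potentially_amplified"
STATUS_NOT_AMPLIFIED = "not_amplified"
STATUS_QC_FAIL = "qc_fail"
STATUS_NOT_EVALUABLE = "not_evaluable"

# monotone order of call severity for fixed QC state
_STATUS_RANK = {STATUS_NOT_AMPLIFIED: 0, STATUS_POTENTIAL: 1, STATUS_AMPLIFIED: 2}


@dataclass
class CnvConfig:
    """Thresholds of the amplification caller.

    Defaults are the validated diagnostic cut-offs: RC >= 3.0 calls an
    amplification, the [2.0, 3.0) band is flagged for follow-up, and a sample
    is only evaluable when its median unique coverage per amplicon exceeds 25
    gDNA molecules.
    """

    amplified_threshold: float = 3.0
    potential_low: float = 2.0
    min_median_unique_coverage: float = 25.0
    require_all_replicates: bool = True
    gene_aggregate: str = "mean"  # or "median"
    normalization_exclude: tuple[str, ...] = ()  # probe_ids excluded from the sample median
    min_evaluable_probe_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.potential_low < self.amplified_threshold:
            raise ValidationError("potential_low must be < amplified_threshold")
        if self.min_median_unique_coverage <= 0:
            raise ValidationError("min_median_unique_coverage must be > 0")
        if self.gene_aggregate not in ("mean", "median"):
            raise ValidationError("gene_aggregate must be 'mean' or 'median'")


@dataclass
class GeneBaseline:
    mean: float
    sd: float


@dataclass
class AmplificationBaseline:
    """Per-gene mean/SD of gene-level normalized coverage across normal controls."""

    genes: dict[str, GeneBaseline]
    n_controls: int
    control_ids: list[str] = field(default_factory=list)
    panel_version: str = ""

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": {g: {"mean": b.mean, "sd": b.sd} for g, b in sorted(self.genes.items())},
            "n_controls": self.n_controls,
            "control_ids": self.control_ids,
            "panel_version": self.panel_version,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AmplificationBaseline":
        payload = json.loads(Path(path).read_text())
        return cls(
            genes={g: GeneBaseline(**b) for g, b in payload["genes"].items()},
            n_controls=payload["n_controls"],
            control_ids=payload.get("control_ids", []),
            panel_version=payload.get("panel_version", ""),
        )


@dataclass
class GeneAmplificationResult:
    gene: str
    relative_coverage: Optional[float]
    z_score: Optional[float]  # None when the baseline SD is zero (flagged) or gene not evaluable
    alleles_per_genome_equivalent: Optional[float]
    tumor_allele_count: Optional[float]  # None when purity unknown
    detection_floor: Optional[float]
    status: str


def normalize_sample(counts: pd.Series, exclude: Sequence[str] = ()) -> pd.Series:
    """Divide each probe's unique count by the sample median over all amplicons.

    The median is taken over every panel probe (minus an optional exclusion
    list), so the output's median is 1. An all-zero column means the sample
    produced no usable library and is an error.
    """
    if (counts < 0).any():
        raise ValidationError("negative counts in coverage column")
    included = counts.drop(labels=[p for p in exclude if p in counts.index])
    median = float(included.median())
    if median <= 0:
        raise AnalysisError("sample failed: median unique coverage is zero")
    return counts / median


def gene_normalized_coverage(
    normalized: pd.Series, design: PanelDesign, config: Optional[CnvConfig] = None
) -> dict[str, Optional[float]]:
    """Aggregate probe-level normalized coverage to one value per amplification gene.

    Zero-coverage probes are treated as technical dropouts and excluded as long
    as at least half of the gene's probes remain evaluable; with fewer
    survivors the gene is not evaluable (None).
    """
    config = config or CnvConfig()
    agg = np.mean if config.gene_aggregate == "mean" else np.median
    out: dict[str, Optional[float]] = {}
    for gene in sorted(design.amplification_genes):
        probe_ids = [p.probe_id for p in design.probes_for_gene(gene)]
        values = normalized.reindex(probe_ids)
        present = values.dropna()
        evaluable = present[present > 0]
        if len(probe_ids) == 0 or len(evaluable) < config.min_evaluable_probe_fraction * len(probe_ids) or len(evaluable) == 0:
            out[gene] = None
        else:
            out[gene] = float(agg(evaluable.to_numpy()))
    return out


def build_baseline(
    controls: CoverageMatrix,
    design: PanelDesign,
    config: Optional[CnvConfig] = None,
    panel_version: str = "",
) -> AmplificationBaseline:
    """Build the external baseline from normal control samples.

    Controls failing the sample-level QC gate (median unique coverage not
    above the floor) are excluded with a warning; at least two survivors are
    required. Per gene, the mean and sample SD (ddof=1) of the gene-level
    normalized coverage across surviving controls are stored.
    """
    config = config or CnvConfig()
    surviving: dict[str, dict[str, Optional[float]]] = {}
    for sample in controls.sample_ids:
        column = controls.column(sample)
        if float(column.median()) <= config.min_median_unique_coverage:
            warnings.warn(
                f"control {sample!r} excluded from baseline: median unique coverage "
                f"{float(column.median()):.1f} <= {config.min_median_unique_coverage}",
                stacklevel=2,
            )
            continue
        normalized = normalize_sample(column, exclude=config.normalization_exclude)
        surviving[sample] = gene_normalized_coverage(normalized, design, config)
    if len(surviving) < 2:
        raise AnalysisError(
            f"only {len(surviving)} control(s) pass QC; >=2 required to build a baseline"
        )
    genes: dict[str, GeneBaseline] = {}
    for gene in sorted(design.amplification_genes):
        values = [v[gene] for v in surviving.values() if v[gene] is not None]
        if len(values) < 2:
            warnings.warn(f"gene {gene!r} evaluable in <2 controls; left out of baseline", stacklevel=2)
            continue
        arr = np.asarray(values, dtype=float)
        genes[gene] = GeneBaseline(mean=float(arr.mean()), sd=float(arr.std(ddof=1)))
    return AmplificationBaseline(
        genes=genes,
        n_controls=len(surviving),
        control_ids=sorted(surviving),
        panel_version=panel_version,
    )


def relative_coverage(sample_gene_value: float, baseline: AmplificationBaseline, gene: str) -> float:
    """Fold change of a gene versus the control series (2x this = alleles per
    genome equivalent)."""
    ref = baseline.genes.get(gene)
    if ref is None or ref.mean <= 0:
        raise AnalysisError(f"gene {gene!r} not evaluable: baseline mean missing or <= 0")
    return sample_gene_value / ref.mean


def z_score(sample_gene_value: float, baseline: AmplificationBaseline, gene: str) -> Optional[float]:
    """Significance of the coverage excess versus the control series.

    Returns None when the control SD is zero (degenerate controls); calling
    then proceeds on relative coverage alone.
    """
    ref = baseline.genes.get(gene)
    if ref is None:
        raise AnalysisError(f"gene {gene!r} missing from baseline")
    if ref.sd == 0:
        return None
    return (sample_gene_value - ref.mean) / ref.sd


def tumor_allele_count(relative_coverage: float, neoplastic_fraction: Optional[float]) -> float:
    """Alleles per tumor cell: (RC * 2 - (1 - p) * 2) / p.

    The stromal (non-neoplastic) compartment contributes two alleles per cell;
    subtracting it and rescaling by the neoplastic fraction p yields the allele
    count within the tumor compartment. RC = 1 gives 2 for every p.
    """
    if neoplastic_fraction is None:
        raise AnalysisError("purity required: neoplastic_fraction is unknown")
    if not 0.0 < neoplastic_fraction <= 1.0:
        raise AnalysisError(f"purity required: neoplastic_fraction {neoplastic_fraction} not in (0, 1]")
    p = neoplastic_fraction
    return (relative_coverage * 2.0 - (1.0 - p) * 2.0) / p


def detection_floor(neoplastic_fraction: Optional[float], threshold: float = 3.0) -> float:
    """Minimal tumor-cell allele count that can reach the calling threshold at
    the given purity — the sample-specific sensitivity limit quoted in reports."""
    return tumor_allele_count(threshold, neoplastic_fraction)


def simulate_dilution_curve(rc: float, dilution_factors: Sequence[float]) -> list[float]:
    """Ideal-mixing prediction for diluting a sample in normal gDNA:
    RC(d) = 1 + (RC - 1) / d."""
    if rc < 0:
        raise ValidationError("relative coverage must be >= 0")
    out = []
    for d in dilution_factors:
        if d < 1:
            raise ValidationError(f"dilution factor {d} < 1")
        out.append(1.0 + (rc - 1.0) / d)
    return out


def _classify_rc(rc: Optional[float], config: CnvConfig) -> str:
    if rc is None:
        return STATUS_NOT_EVALUABLE
    if rc >= config.amplified_threshold:
        return STATUS_AMPLIFIED
    if rc >= config.potential_low:
        return STATUS_POTENTIAL
    return STATUS_NOT_AMPLIFIED


def call_amplifications(
    counts: pd.Series,
    design: PanelDesign,
    baseline: AmplificationBaseline,
    config: Optional[CnvConfig] = None,
    neoplastic_fraction: Optional[float] = None,
    replicates: Optional[Sequence[pd.Series]] = None,
) -> list[GeneAmplificationResult]:
    """Produce one categorical amplification call per panel gene.

    The sample-level QC gate (median unique coverage per amplicon strictly
    above the floor) fails every gene at once. With replicate columns, a gene
    is amplified only if it reaches the threshold in every replicate; the
    reported RC is the mean across replicates.
    """
    config = config or CnvConfig()
    columns = [counts] + list(replicates or [])
    medians = [float(c.median()) for c in columns]
    qc_pass = all(m > config.min_median_unique_coverage for m in medians)
    logger.info("QC gate: medians=%s floor=%s pass=%s", medians, config.min_median_unique_coverage, qc_pass)

    floor_value: Optional[float] = None
    if neoplastic_fraction:
        floor_value = detection_floor(neoplastic_fraction, config.amplified_threshold)

    results = []
    if not qc_pass:
        for gene in sorted(design.amplification_genes):
            results.append(
                GeneAmplificationResult(
                    gene=gene, relative_coverage=None, z_score=None,
                    alleles_per_genome_equivalent=None, tumor_allele_count=None,
                    detection_floor=floor_value, status=STATUS_QC_FAIL,
                )
            )
        return results

    per_rep_values = []
    for column in columns:
        normalized = normalize_sample(column, exclude=config.normalization_exclude)
        per_rep_values.append(gene_normalized_coverage(normalized, design, config))

    for gene in sorted(design.amplification_genes):
        values = [v[gene] for v in per_rep_values]
        if any(v is None for v in values) or gene not in baseline.genes or baseline.genes[gene].mean <= 0:
            results.append(
                GeneAmplificationResult(
                    gene=gene, relative_coverage=None, z_score=None,
                    alleles_per_genome_equivalent=None, tumor_allele_count=None,
                    detection_floor=floor_value, status=STATUS_NOT_EVALUABLE,
                )
            )
            continue
        rcs = [relative_coverage(v, baseline, gene) for v in values]
        mean_rc = float(np.mean(rcs))
        statuses = [_classify_rc(rc, config) for rc in rcs]
        if config.require_all_replicates and len(statuses) > 1:
            # amplified only when every replicate reaches the threshold
            status = min(statuses, key=lambda s: _STATUS_RANK[s])
        else:
            status = _classify_rc(mean_rc, config)
        z = z_score(float(np.mean(values)), baseline, gene)
        tac = None
        if neoplastic_fraction:
            tac = tumor_allele_count(mean_rc, neoplastic_fraction)
        logger.info("gene %s: RC=%.3f z=%s status=%s", gene, mean_rc, z, status)
        results.append(
            GeneAmplificationResult(
                gene=gene,
                relative_coverage=mean_rc,
                z_score=z,
                alleles_per_genome_equivalent=2.0 * mean_rc,
                tumor_allele_count=tac,
                detection_floor=floor_value,
                status=status,
            )
        )
    return results


def results_to_frame(results: Sequence[GeneAmplificationResult]) -> pd.DataFrame:
    """Tabular view of per-gene calls (one row per gene)."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "relative_coverage": r.relative_coverage,
                "z_score": r.z_score,
                "alleles_per_genome_equivalent": r.alleles_per_genome_equivalent,
                "tumor_allele_count": r.tumor_allele_count,
                "detection_floor": r.detection_floor,
                "status": r.status,
            }
            for r in results
        ]
    )
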