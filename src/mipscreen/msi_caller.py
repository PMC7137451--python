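"""Tumor-only microsatellite instability (MSI) detection.

Each microsatellite locus yields a histogram of repeat lengths over unique
molecules. Per locus, the number of distinct alleles is counted: a repeat
length contributes an allele iff its count strictly exceeds 5% of the modal
(most frequent) allele's count. A baseline built from normal FFPE tissue
stores the mean and SD of that allele count per locus; in a tumor sample a
locus is scored *unstable* iff its allele count strictly exceeds
mean + 2 * SD. The sample-level score is the fraction of evaluated loci that
are unstable (loci under the depth floor, or unbuildable in the baseline, are
excluded from numerator and denominator alike).

Classification uses the diagnostic thresholds: score >= 30% is MSI-high;
score < 15% is MSS, but only reportable when the neoplastic-cell fraction is
at least 30% (below that, absence of instability cannot be distinguished from
signal dilution); the 15-30% band is indeterminate and triggers orthogonal
follow-up (MMR immunohistochemistry / pentaplex PCR). A legacy two-way
classifier at the 20% cutoff reproduces the original validation rule.

Both "exceeds 5%" and "exceeds mean + 2 SD" are strict inequalities; values
exactly at a cut do not pass. The boundary of the 20%/30% score cutoffs is
inclusive (>=) by default and configurable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError
from .panel_model import LocusAlleleProfile

logger = logging.getLogger(__name__)

LOCUS_STABLE = "stable"
LOCUS_UNSTABLE = "unstable"
LOCUS_NOT_EVALUABLE = "not_evaluable"

MSI_HIGH = "MSI_high"
MSS = "MSS"
INDETERMINATE = "indeterminate"
NOT_REPORTABLE = "not_reportable_low_purity"


@dataclass
class MsiConfig:
    """Thresholds of the MSI caller (defaults: validated diagnostic values)."""

    allele_fraction_threshold: float = 0.05
    sd_multiplier: float = 2.0
    msi_high_threshold: float = 0.30
    mss_threshold: float = 0.15
    min_purity_for_mss: float = 0.30
    min_locus_depth: int = 30
    validation_cutoff: float = 0.20  # legacy two-way rule
    inclusive_score_boundary: bool = True  # score == cutoff counts as reaching it

    def __post_init__(self) -> None:
        if not self.mss_threshold < self.msi_high_threshold:
            raise ValidationError("mss_threshold must be < msi_high_threshold")
        for name in ("allele_fraction_threshold", "msi_high_threshold", "mss_threshold",
                     "min_purity_for_mss", "validation_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")


@dataclass
class LocusBaseline:
    mean: float
    sd: float
    n_controls: int


@dataclass
class MsiBaseline:
    """Per-locus allele-count statistics from normal tissue samples.

    Loci evaluable in fewer than two normals are *unbuildable* and excluded
    from scoring.
    """

    loci: dict[str, LocusBaseline]
    unbuildable: list[str] = field(default_factory=list)
    n_controls: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "loci": {
                l: {"mean": b.mean, "sd": b.sd, "n_controls": b.n_controls}
                for l, b in sorted(self.loci.items())
            },
            "unbuildable": sorted(self.unbuildable),
            "n_controls": self.n_controls,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MsiBaseline":
        payload = json.loads(Path(path).read_text())
        return cls(
            loci={l: LocusBaseline(**b) for l, b in payload["loci"].items()},
            unbuildable=payload.get("unbuildable", []),
            n_controls=payload.get("n_controls", 0),
        )


@dataclass
class LocusCall:
    locus_id: str
    n_alleles: Optional[int]
    threshold: Optional[float]  # mean + sd_multiplier * sd
    status: str


@dataclass
class MsiResult:
    sample_id: str
    locus_calls: list[LocusCall]
    fraction_unstable: Optional[float]
    n_evaluated: int
    classification: str
    sd_zero_loci: list[str] = field(default_factory=list)  # degenerate baselines, flagged


def count_alleles(profile: LocusAlleleProfile, config: Optional[MsiConfig] = None) -> Optional[int]:
    """Count distinct alleles at a locus.

    A repeat length counts iff its read count strictly exceeds
    ``allele_fraction_threshold`` times the modal count (at a modal tie, the
    shared top count is the reference and every tied length counts). Returns
    None when total depth is below ``min_locus_depth`` (locus not evaluable).
    """
    config = config or MsiConfig()
    if not profile.histogram:
        raise ValidationError(
            f"locus {profile.locus_id!r}, sample {profile.sample_id!r}: empty histogram"
        )
    if profile.total_depth < config.min_locus_depth:
        return None
    modal = max(profile.histogram.values())
    cut = config.allele_fraction_threshold * modal
    return sum(1 for c in profile.histogram.values() if c > cut)


def build_msi_baseline(
    profiles: Iterable[LocusAlleleProfile], config: Optional[MsiConfig] = None
) -> MsiBaseline:
    """Per-locus mean/SD of allele counts across normal samples.

    Profiles under the depth floor are dropped first; loci left with fewer
    than two evaluable normals are marked unbuildable.
    """
    config = config or MsiConfig()
    counts: dict[str, list[int]] = {}
    samples: set[str] = set()
    for profile in profiles:
        samples.add(profile.sample_id)
        counts.setdefault(profile.locus_id, [])
        n = count_alleles(profile, config)
        if n is None:
            continue
        counts[profile.locus_id].append(n)
    loci: dict[str, LocusBaseline] = {}
    unbuildable: list[str] = []
    for locus in sorted(counts):
        values = counts[locus]
        if len(values) < 2:
            unbuildable.append(locus)
            continue
        arr = np.asarray(values, dtype=float)
        loci[locus] = LocusBaseline(
            mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n_controls=len(values)
        )
    return MsiBaseline(loci=loci, unbuildable=unbuildable, n_controls=len(samples))


def score_locus(
    profile: LocusAlleleProfile, baseline: MsiBaseline, config: Optional[MsiConfig] = None
) -> LocusCall:
    """Score one locus against the baseline: unstable iff the allele count
    strictly exceeds mean + sd_multiplier * SD."""
    config = config or MsiConfig()
    ref = baseline.loci.get(profile.locus_id)
    if ref is None:
        return LocusCall(profile.locus_id, None, None, LOCUS_NOT_EVALUABLE)
    n = count_alleles(profile, config)
    if n is None:
        return LocusCall(profile.locus_id, None, None, LOCUS_NOT_EVALUABLE)
    threshold = ref.mean + config.sd_multiplier * ref.sd
    status = LOCUS_UNSTABLE if n > threshold else LOCUS_STABLE
    logger.debug("locus %s: n_alleles=%d threshold=%.3f -> %s", profile.locus_id, n, threshold, status)
    return LocusCall(profile.locus_id, n, threshold, status)


def msi_score(locus_calls: Sequence[LocusCall]) -> float:
    """Fraction of evaluated loci scored unstable (not-evaluable loci are
    excluded from numerator and denominator)."""
    evaluated = [c for c in locus_calls if c.status != LOCUS_NOT_EVALUABLE]
    if not evaluated:
        raise AnalysisError("no evaluable locus: sample not reportable")
    unstable = sum(1 for c in evaluated if c.status == LOCUS_UNSTABLE)
    return unstable / len(evaluated)


def _reaches(score: float, cutoff: float, inclusive: bool) -> bool:
    return score >= cutoff if inclusive else score > cutoff


def classify(
    score: float, neoplastic_fraction: Optional[float], config: Optional[MsiConfig] = None
) -> str:
    """Three-way diagnostic classification with the low-purity MSS gate."""
    config = config or MsiConfig()
    if not 0.0 <= score <= 1.0:
        raise ValidationError(f"score {score} outside [0, 1]")
    if _reaches(score, config.msi_high_threshold, config.inclusive_score_boundary):
        return MSI_HIGH
    if score >= config.mss_threshold:
        return INDETERMINATE
    if neoplastic_fraction is None or neoplastic_fraction < config.min_purity_for_mss:
        return NOT_REPORTABLE
    return MSS


def legacy_validation_classify(score: float, config: Optional[MsiConfig] = None) -> str:
    """Two-way rule of the original validation experiment: positive iff the
    score reaches the 20% cutoff."""
    config = config or MsiConfig()
    return (
        "positive"
        if _reaches(score, config.validation_cutoff, config.inclusive_score_boundary)
        else "negative"
    )


def score_sample(
    profiles: Iterable[LocusAlleleProfile],
    baseline: MsiBaseline,
    neoplastic_fraction: Optional[float] = None,
    config: Optional[MsiConfig] = None,
) -> MsiResult:
    """Score every locus of one sample and classify it."""
    config = config or MsiConfig()
    profiles = list(profiles)
    if not profiles:
        raise AnalysisError("no MSI profiles supplied")
    sample_ids = {p.sample_id for p in profiles}
    if len(sample_ids) != 1:
        raise ValidationError(f"profiles from multiple samples: {sorted(sample_ids)}")
    calls = [score_locus(p, baseline, config) for p in profiles]
    score = msi_score(calls)
    sd_zero = sorted(
        c.locus_id
        for c in calls
        if c.status != LOCUS_NOT_EVALUABLE and baseline.loci[c.locus_id].sd == 0.0
    )
    return MsiResult(
        sample_id=sample_ids.pop(),
        locus_calls=calls,
        fraction_unstable=score,
        n_evaluated=sum(1 for c in calls if c.status != LOCUS_NOT_EVALUABLE),
        classification=classify(score, neoplastic_fraction, config),
        sd_zero_loci=sd_zero,
    )


def classify_replicates(
    scores: Sequence[float], neoplastic_fraction: Optional[float], config: Optional[MsiConfig] = None
) -> str:
    """Combine duplicate analyses: per-replicate scores are reported, the
    classification uses their mean."""
    if not scores:
        raise AnalysisError("no replicate scores")
    return classify(float(np.mean(scores)), neoplastic_fraction, config)


def locus_status_matrix(results: Sequence[MsiResult]) -> pd.DataFrame:
    """Loci x samples status table (heatmap-ready: unstable / stable /
    not_evaluable strings)."""
    loci = sorted({c.locus_id for r in results for c in r.locus_calls})
    data = {
        r.sample_id: {c.locus_id: c.status for c in r.locus_calls} for r in results
    }
    return pd.DataFrame(data, index=loci).fillna(LOCUS_NOT_EVALUABLE)


def calls_to_frame(result: MsiResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"locus_id": c.locus_id, "n_alleles": c.n_alleles,
             "threshold": c.threshold, "status": c.status}
            for c in result.locus_calls
        ]
    )
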