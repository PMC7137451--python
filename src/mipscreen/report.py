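"""Per-sample diagnostic report: QC, sex concordance, amplification and MSI
calls, and detection-limit annotations.

A report is a pure function of its inputs and configuration — identical
inputs produce byte-identical JSON — and embeds a snapshot of every threshold
used, so each call in it is traceable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .cnv_caller import (
    AmplificationBaseline,
    CnvConfig,
    GeneAmplificationResult,
    call_amplifications,
    detection_floor,
)
from .errors import AnalysisError
from .msi_caller import MsiBaseline, MsiConfig, MsiResult, score_sample
from .panel_model import LocusAlleleProfile, PanelDesign, SampleMeta

logger = logging.getLogger(__name__)

SEX_MALE = "M"
SEX_FEMALE = "F"
SEX_INDETERMINATE = "indeterminate"


@dataclass
class SexCheckConfig:
    """Thresholds of the AMELX/AMELY concordance check (plumbing defaults, not
    validated clinical rules): male iff the AMELY count reaches
    ``male_ratio`` x AMELX; female iff AMELY is below ``noise_floor`` x AMELX."""

    male_ratio: float = 0.25
    noise_floor: float = 0.05


def infer_sex(
    amelx_count: float, amely_count: float, config: Optional[SexCheckConfig] = None
) -> str:
    """Infer sample sex from the sex-control probe counts."""
    config = config or SexCheckConfig()
    if amelx_count <= 0:
        return SEX_INDETERMINATE
    ratio = amely_count / amelx_count
    if ratio >= config.male_ratio:
        return SEX_MALE
    if ratio < config.noise_floor:
        return SEX_FEMALE
    return SEX_INDETERMINATE


@dataclass
class SampleQc:
    median_unique_coverage: float
    qc_pass: bool
    dropout: bool


@dataclass
class SexCheck:
    amelx_count: int
    amely_count: int
    inferred: str
    concordant: Optional[bool]  # None when no sex was declared


@dataclass
class SampleReport:
    sample_id: str
    qc: SampleQc
    sex_check: Optional[SexCheck]
    amplification: list[GeneAmplificationResult]
    msi: Optional[MsiResult]
    msi_assessed: bool
    config: dict
    version: str = __version__

    def to_dict(self) -> dict:
        out = asdict(self)
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_dict(cls, payload: dict) -> "SampleReport":
        from .msi_caller import LocusCall

        qc = SampleQc(**payload["qc"])
        sex = SexCheck(**payload["sex_check"]) if payload["sex_check"] else None
        amp = [GeneAmplificationResult(**r) for r in payload["amplification"]]
        msi = None
        if payload["msi"]:
            m = dict(payload["msi"])
            m["locus_calls"] = [LocusCall(**c) for c in m["locus_calls"]]
            msi = MsiResult(**m)
        return cls(
            sample_id=payload["sample_id"], qc=qc, sex_check=sex, amplification=amp,
            msi=msi, msi_assessed=payload["msi_assessed"], config=payload["config"],
            version=payload["version"],
        )

    @classmethod
    def from_json(cls, text: str) -> "SampleReport":
        return cls.from_dict(json.loads(text))


def _config_snapshot(cnv: CnvConfig, msi: MsiConfig, sex: SexCheckConfig) -> dict:
    snapshot = {"cnv": asdict(cnv), "msi": asdict(msi), "sex_check": asdict(sex)}
    return json.loads(json.dumps(snapshot))  # JSON-native types, so reports round-trip


def run_sample(
    design: PanelDesign,
    counts: pd.Series,
    profiles: Optional[Sequence[LocusAlleleProfile]],
    meta: SampleMeta,
    cnv_baseline: Optional[AmplificationBaseline],
    msi_baseline: Optional[MsiBaseline],
    cnv_config: Optional[CnvConfig] = None,
    msi_config: Optional[MsiConfig] = None,
    sex_config: Optional[SexCheckConfig] = None,
    replicates: Optional[Sequence[pd.Series]] = None,
) -> SampleReport:
    """Assemble the combined diagnostic report for one sample.

    A sample with no usable coverage (median of zero) is marked as a dropout
    and gets no calls. The MSI block is "not assessed" when no profiles are
    supplied. Baselines are mandatory for the analyses they serve.
    """
    cnv_config = cnv_config or CnvConfig()
    msi_config = msi_config or MsiConfig()
    sex_config = sex_config or SexCheckConfig()

    median_cov = float(counts.median())
    dropout = median_cov <= 0
    qc_pass = median_cov > cnv_config.min_median_unique_coverage
    qc = SampleQc(median_unique_coverage=median_cov, qc_pass=qc_pass, dropout=dropout)
    logger.info("sample %s: median unique coverage %.1f (QC %s%s)",
                meta.sample_id, median_cov, "pass" if qc_pass else "fail",
                ", dropout" if dropout else "")

    sex_check: Optional[SexCheck] = None
    amelx = [p.probe_id for p in design.probes if p.role == "sex_control" and p.gene == "AMELX"]
    amely = [p.probe_id for p in design.probes if p.role == "sex_control" and p.gene == "AMELY"]
    if amelx and amely:
        x = int(counts.reindex(amelx).fillna(0).sum())
        y = int(counts.reindex(amely).fillna(0).sum())
        inferred = infer_sex(x, y, sex_config) if not dropout else SEX_INDETERMINATE
        concordant = None if meta.declared_sex is None else (inferred == meta.declared_sex)
        sex_check = SexCheck(amelx_count=x, amely_count=y, inferred=inferred, concordant=concordant)
    else:
        logger.warning("sample %s: AMELX/AMELY probes absent, sex check skipped", meta.sample_id)

    amplification: list[GeneAmplificationResult] = []
    if not dropout:
        if cnv_baseline is None:
            raise AnalysisError(
                "no amplification baseline supplied: build one first (baseline-cnv)"
            )
        amplification = call_amplifications(
            counts, design, cnv_baseline, cnv_config,
            neoplastic_fraction=meta.neoplastic_fraction, replicates=replicates,
        )

    msi_result: Optional[MsiResult] = None
    msi_assessed = False
    if profiles and not dropout:
        if msi_baseline is None:
            raise AnalysisError("no MSI baseline supplied: build one first (baseline-msi)")
        msi_result = score_sample(
            profiles, msi_baseline, neoplastic_fraction=meta.neoplastic_fraction,
            config=msi_config,
        )
        msi_assessed = True

    return SampleReport(
        sample_id=meta.sample_id,
        qc=qc,
        sex_check=sex_check,
        amplification=amplification,
        msi=msi_result,
        msi_assessed=msi_assessed,
        config=_config_snapshot(cnv_config, msi_config, sex_config),
    )
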