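"""Synthetic smMIP sequencing runs with known truth.

The generator emulates the statistical structure the callers assume, so every
pipeline stage can be exercised without sequencing data:

* **Unique-molecule depth** per probe is the product of the run's mean depth,
  a fixed per-probe capture efficiency (log-normal across probes — real smMIP
  pools show an order-of-magnitude spread between efficient and poor probes,
  which an external baseline cancels because efficiencies are a property of
  the panel, not the sample), and negative-binomial sampling noise
  (``variance = mu + dispersion * mu**2``) for FFPE-style overdispersion.
* **Amplifications** scale the expected depth of every probe of the amplified
  gene by the stromal-dilution mixture factor ``(p*k + (1-p)*2) / 2`` for true
  tumor copy number ``k`` at neoplastic fraction ``p`` — a tumor compartment
  with ``k`` alleles mixed with diploid stroma.
* **Microsatellites** emit repeat lengths from a stutter ladder: a geometric
  decay of unit deletions below the reference length. Unstable loci add, in
  the tumor-derived fraction of molecules only, shifted ladders at novel
  lengths, broadening the distribution the way replication slippage does in
  mismatch-repair-deficient tumors.
* **Reads** (optional, for UMI-collapse tests) expand each molecule into
  1 + geometric PCR duplicates, tag it with a random fixed-length UMI, and
  inject per-base substitution errors. With an 8 bp UMI and a few hundred
  molecules per probe, the birthday-collision probability per probe is
  ~ n^2 / (2 * 4^8) < 1e-3 and is neglected.

Everything is a pure function of the spec's seed: the same spec yields
byte-identical output.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .panel_model import (
    CoverageMatrix,
    LocusAlleleProfile,
    PanelDesign,
    SampleMeta,
    SmmipProbe,
    write_allele_profiles,
    write_coverage_matrix,
    write_panel_design,
    write_sample_meta,
)
from .umi_consensus import TaggedRead

BASES = np.array(list("ACGT"))

#: Genes with dedicated amplification tiling (>=10 probes each).
AMPLIFICATION_GENES = (
    "ALK", "BRAF", "EGFR", "ERBB2", "FGFR1", "FGFR2", "FGFR3",
    "KIT", "KRAS", "MDM2", "MET", "PDGFRA", "PIK3CA",
)

#: Genes covered for hotspot mutation analysis.
MUTATION_GENES = (
    "AKT1", "AKT2", "AKT3", "ALK", "ARAF", "BRAF", "DDR2", "EGFR", "ERBB2",
    "FGFR1", "FGFR2", "FGFR3", "GNA11", "GNAQ", "GNAS", "HRAS", "IDH1",
    "IDH2", "JAK2", "KIT", "KRAS", "MAP2K1", "MDM2", "MET", "MTOR", "NRAS",
    "PDGFRA", "PIK3CA", "POLE", "PTEN", "RAF1", "ROS1", "TP53",
)


def _hash32(text: str) -> int:
    return zlib.crc32(text.encode())


def _gene_chrom(gene: str) -> str:
    if gene == "AMELX":
        return "chrX"
    if gene == "AMELY":
        return "chrY"
    return f"chr{1 + _hash32(gene) % 22}"


def default_panel(
    probes_per_amp_gene: int = 10,
    n_mutation_probes: int = 150,
    n_msi_loci: int = 55,
) -> PanelDesign:
    """The default simulated panel: 13 amplification genes tiled with
    ``probes_per_amp_gene`` probes each, hotspot mutation probes across 33
    genes, ``n_msi_loci`` microsatellite loci, and AMELX/AMELY sex controls."""
    probes: list[SmmipProbe] = []
    for gi, gene in enumerate(AMPLIFICATION_GENES):
        base = 1_000_000 * (gi + 1)
        for i in range(probes_per_amp_gene):
            start = base + 5_000 * i
            probes.append(
                SmmipProbe(
                    probe_id=f"AMP_{gene}_{i + 1:02d}", gene=gene,
                    chrom=_gene_chrom(gene), target_start=start,
                    target_end=start + 120, strand="+" if i % 2 == 0 else "-",
                    role="amplification",
                )
            )
    for i in range(n_mutation_probes):
        gene = MUTATION_GENES[i % len(MUTATION_GENES)]
        start = 50_000_000 + 300 * i
        probes.append(
            SmmipProbe(
                probe_id=f"MUT_{i + 1:03d}_{gene}", gene=gene,
                chrom=_gene_chrom(gene), target_start=start,
                target_end=start + 120, strand="+" if i % 2 == 0 else "-",
                role="mutation",
            )
        )
    for i in range(n_msi_loci):
        locus = f"MSI_{i + 1:02d}"
        start = 80_000_000 + 1_000 * i
        probes.append(
            SmmipProbe(
                probe_id=f"MS_{locus}", gene="MS_PANEL",
                chrom=f"chr{1 + i % 22}", target_start=start,
                target_end=start + 100, strand="+", role="msi", msi_locus_id=locus,
            )
        )
    for gene, chrom in (("AMELX", "chrX"), ("AMELY", "chrY")):
        probes.append(
            SmmipProbe(
                probe_id=f"SEX_{gene}", gene=gene, chrom=chrom,
                target_start=10_000_000, target_end=10_000_120,
                strand="+", role="sex_control",
            )
        )
    return PanelDesign(probes)


@dataclass
class StutterModel:
    """Repeat-length emission model.

    Stable loci draw lengths ``L0 - j`` (j = 0..max_step) with probability
    proportional to ``q**j``; the decay ``q`` varies per locus within
    [decay_min, decay_max], so some loci are tight (2 confident alleles) and
    some hover near the 5% allele cut — which is what gives the normal
    baseline a non-zero SD. Unstable loci mix the native ladder with ladders
    shifted by ``unstable_shifts`` (tumor molecules only), with
    ``unstable_weights`` over (native, shift1, shift2, ...).
    """

    decay_min: float = 0.08
    decay_max: float = 0.20
    max_step: int = 3
    unstable_shifts: tuple[int, ...] = (-4, -7)
    unstable_weights: tuple[float, ...] = (0.45, 0.35, 0.20)

    def __post_init__(self) -> None:
        if len(self.unstable_weights) != len(self.unstable_shifts) + 1:
            raise ValidationError("unstable_weights must have one entry per ladder (native + shifts)")
        if abs(sum(self.unstable_weights) - 1.0) > 1e-9:
            raise ValidationError("unstable_weights must sum to 1")

    def locus_reference_length(self, locus_id: str) -> int:
        return 14 + _hash32(locus_id + "/len") % 16

    def locus_decay(self, locus_id: str) -> float:
        u = (_hash32(locus_id + "/q") % 10_000) / 9_999.0
        return self.decay_min + u * (self.decay_max - self.decay_min)

    def _ladder(self, origin: int, q: float) -> dict[int, float]:
        weights = np.array([q**j for j in range(self.max_step + 1)])
        weights /= weights.sum()
        return {origin - j: float(w) for j, w in enumerate(weights)}

    def stable_distribution(self, locus_id: str) -> dict[int, float]:
        return self._ladder(self.locus_reference_length(locus_id), self.locus_decay(locus_id))

    def unstable_distribution(self, locus_id: str) -> dict[int, float]:
        """Length distribution of tumor-derived molecules at an unstable locus."""
        origin = self.locus_reference_length(locus_id)
        q = self.locus_decay(locus_id)
        out: dict[int, float] = {}
        origins = (origin,) + tuple(origin + s for s in self.unstable_shifts)
        for o, w in zip(origins, self.unstable_weights):
            for length, p in self._ladder(o, q).items():
                out[length] = out.get(length, 0.0) + w * p
        return out


@dataclass
class SimulationSpec:
    """Full description of one simulated sample (seed determines everything)."""

    seed: int = 0
    panel: Optional[PanelDesign] = None  # default_panel() when omitted
    mean_depth: float = 300.0
    depth_dispersion: float = 0.02  # var = mu + dispersion * mu^2; 0 -> deterministic depth
    probe_efficiency_sigma: float = 0.55  # log-normal spread of per-probe capture efficiency
    efficiency_seed: int = 7
    pcr_duplicate_rate: float = 0.25
    base_error_rate: float = 0.002
    umi_length: int = 8
    amplified_genes: dict[str, float] = field(default_factory=dict)  # gene -> true tumor copy number k
    neoplastic_fraction: Optional[float] = None
    msi_unstable_loci: frozenset[str] = frozenset()
    stutter: StutterModel = field(default_factory=StutterModel)
    sex: str = "F"

    def __post_init__(self) -> None:
        for name in ("pcr_duplicate_rate", "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValidationError(f"{name} must be in [0, 1), got {v}")
        if self.depth_dispersion < 0:
            raise ValidationError("depth_dispersion must be >= 0")
        for gene, k in self.amplified_genes.items():
            if k < 2:
                raise ValidationError(f"amplified gene {gene!r}: copy number {k} < 2")
        if self.neoplastic_fraction is not None and not 0.0 <= self.neoplastic_fraction <= 1.0:
            raise ValidationError("neoplastic_fraction must be in [0, 1]")
        if self.sex not in ("M", "F"):
            raise ValidationError("sex must be 'M' or 'F'")
        if self.panel is None:
            self.panel = default_panel()
        self.msi_unstable_loci = frozenset(self.msi_unstable_loci)

    @property
    def is_tumor(self) -> bool:
        return bool(self.amplified_genes) or bool(self.msi_unstable_loci)


@dataclass
class SampleTruth:
    """Ground truth for one generated sample."""

    sample_id: str
    kind: str  # normal / mss_tumor / msi_tumor / amplified_tumor
    neoplastic_fraction: Optional[float]
    molecule_counts: pd.Series  # per probe_id
    locus_histograms: dict[str, dict[int, int]]  # molecule-level, per locus
    amplified_genes: dict[str, float]
    expected_relative_coverage: dict[str, float]
    unstable_loci: list[str]
    sex: str

    def to_jsonable(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "kind": self.kind,
            "neoplastic_fraction": self.neoplastic_fraction,
            "molecule_counts": {k: int(v) for k, v in self.molecule_counts.items()},
            "locus_histograms": {
                locus: {str(l): int(c) for l, c in sorted(hist.items())}
                for locus, hist in sorted(self.locus_histograms.items())
            },
            "amplified_genes": self.amplified_genes,
            "expected_relative_coverage": self.expected_relative_coverage,
            "unstable_loci": sorted(self.unstable_loci),
            "sex": self.sex,
        }


def probe_efficiency(spec: SimulationSpec, probe_id: str) -> float:
    """Fixed per-probe capture efficiency (mean 1 across the log-normal)."""
    if spec.probe_efficiency_sigma == 0:
        return 1.0
    rng = np.random.default_rng(_hash32(probe_id) ^ spec.efficiency_seed)
    z = rng.standard_normal()
    s = spec.probe_efficiency_sigma
    return float(np.exp(s * z - 0.5 * s * s))


def mixture_factor(k: float, p: float) -> float:
    """Expected fold change of an amplified gene at purity p: (p*k + (1-p)*2) / 2."""
    return (p * k + (1.0 - p) * 2.0) / 2.0


def _expected_depth(spec: SimulationSpec, probe: SmmipProbe) -> float:
    mu = spec.mean_depth * probe_efficiency(spec, probe.probe_id)
    if probe.role == "sex_control":
        if spec.sex == "M":
            return mu * 0.5
        return mu if probe.gene == "AMELX" else 0.0
    if probe.gene in spec.amplified_genes:
        p = spec.neoplastic_fraction if spec.neoplastic_fraction is not None else 1.0
        return mu * mixture_factor(spec.amplified_genes[probe.gene], p)
    return mu


def _draw_count(rng: np.random.Generator, mu: float, dispersion: float) -> int:
    if mu <= 0:
        return 0
    if dispersion == 0:
        return int(round(mu))
    size = 1.0 / dispersion  # NB size parameter: var = mu + mu^2 / size
    p = size / (size + mu)
    return int(rng.negative_binomial(size, p))


def _locus_distribution(spec: SimulationSpec, locus_id: str) -> dict[int, float]:
    stable = spec.stutter.stable_distribution(locus_id)
    if locus_id not in spec.msi_unstable_loci:
        return stable
    p = spec.neoplastic_fraction if spec.neoplastic_fraction is not None else 1.0
    tumor = spec.stutter.unstable_distribution(locus_id)
    out: dict[int, float] = {}
    for length, w in stable.items():
        out[length] = out.get(length, 0.0) + (1.0 - p) * w
    for length, w in tumor.items():
        out[length] = out.get(length, 0.0) + p * w
    return out


def sample_tables(
    spec: SimulationSpec, sample_id: str = "SAMPLE", kind: str = "normal"
) -> SampleTruth:
    """Draw one sample at the table level: per-probe molecule counts and
    per-locus repeat-length histograms (no read expansion)."""
    rng = np.random.default_rng(spec.seed)
    panel = spec.panel
    assert panel is not None
    counts = {}
    histograms: dict[str, dict[int, int]] = {}
    for probe in panel.probes:
        n = _draw_count(rng, _expected_depth(spec, probe), spec.depth_dispersion)
        counts[probe.probe_id] = n
        if probe.role == "msi":
            dist = _locus_distribution(spec, probe.msi_locus_id)  # type: ignore[arg-type]
            lengths = np.array(sorted(dist))
            probs = np.array([dist[l] for l in lengths])
            draws = rng.multinomial(n, probs / probs.sum())
            hist = {int(l): int(c) for l, c in zip(lengths, draws) if c > 0}
            histograms[probe.msi_locus_id] = hist  # type: ignore[index]
    expected_rc = {
        gene: mixture_factor(k, spec.neoplastic_fraction if spec.neoplastic_fraction is not None else 1.0)
        for gene, k in spec.amplified_genes.items()
    }
    return SampleTruth(
        sample_id=sample_id,
        kind=kind,
        neoplastic_fraction=spec.neoplastic_fraction,
        molecule_counts=pd.Series(counts, name=sample_id).reindex(panel.probe_ids),
        locus_histograms=histograms,
        amplified_genes=dict(spec.amplified_genes),
        expected_relative_coverage=expected_rc,
        unstable_loci=sorted(spec.msi_unstable_loci),
        sex=spec.sex,
    )


def _reference_sequence(probe_id: str, length: int = 24) -> str:
    rng = np.random.default_rng(_hash32(probe_id + "/ref"))
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _random_umi(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0:
        return seq
    arr = np.array(list(seq))
    mask = rng.random(arr.size) < rate
    if not mask.any():
        return seq
    for i in np.nonzero(mask)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _expand_reads(spec: SimulationSpec, truth: SampleTruth) -> list[TaggedRead]:
    rng = np.random.default_rng((spec.seed * 2 + 1) % 2**31)
    panel = spec.panel
    assert panel is not None
    reads: list[TaggedRead] = []
    for probe in panel.probes:
        n = int(truth.molecule_counts[probe.probe_id])
        if n == 0:
            continue
        if probe.role == "msi":
            hist = truth.locus_histograms.get(probe.msi_locus_id, {})  # type: ignore[arg-type]
            payload_pool: list = [l for l, c in sorted(hist.items()) for _ in range(c)]
        else:
            payload_pool = [_reference_sequence(probe.probe_id)] * n
        used_keys: set[tuple[str, str]] = set()
        for payload in payload_pool:
            # uniform draw, uniquified within the probe: two template molecules
            # never share a (UMI, strand) key, so consensus counts recover the
            # truth exactly. At fixture depths a redraw is a rare event.
            while True:
                umi = _random_umi(rng, spec.umi_length)
                strand = "+" if rng.random() < 0.5 else "-"
                if (umi, strand) not in used_keys:
                    used_keys.add((umi, strand))
                    break
            n_copies = (
                1 if spec.pcr_duplicate_rate == 0 else int(rng.geometric(1.0 - spec.pcr_duplicate_rate))
            )
            for _ in range(n_copies):
                if isinstance(payload, str):
                    reads.append(
                        TaggedRead(probe.probe_id, umi, strand, _mutate(rng, payload, spec.base_error_rate))
                    )
                else:
                    reads.append(TaggedRead(probe.probe_id, umi, strand, int(payload)))
    return reads


def gen_normal_sample(
    spec: SimulationSpec, sample_id: str = "NORMAL"
) -> tuple[list[TaggedRead], SampleTruth]:
    """Generate tagged reads + truth for a normal (non-tumor) sample; any
    tumor state on the spec is ignored."""
    clean = replace(
        spec, amplified_genes={}, msi_unstable_loci=frozenset(), neoplastic_fraction=None
    )
    truth = sample_tables(clean, sample_id=sample_id, kind="normal")
    return _expand_reads(clean, truth), truth


def gen_tumor_sample(
    spec: SimulationSpec, sample_id: str = "TUMOR"
) -> tuple[list[TaggedRead], SampleTruth]:
    """Generate tagged reads + truth for a tumor sample.

    Requires ``neoplastic_fraction`` whenever amplifications or unstable loci
    are set (the signal is meaningless without a mixture fraction).
    """
    if spec.is_tumor and spec.neoplastic_fraction is None:
        raise ValidationError(
            "neoplastic_fraction required when amplified_genes or msi_unstable_loci are set"
        )
    kind = "msi_tumor" if spec.msi_unstable_loci else ("amplified_tumor" if spec.amplified_genes else "mss_tumor")
    truth = sample_tables(spec, sample_id=sample_id, kind=kind)
    return _expand_reads(spec, truth), truth


#: (true copy number k, purity p) pairs used for amplification positive
#: controls; every pair gives an expected relative coverage of at least 3.0.
AMPLIFIED_CONTROL_PAIRS = ((10, 0.7), (14, 0.5), (20, 0.4), (25, 0.6), (40, 0.9))


@dataclass
class Cohort:
    """An in-memory synthetic cohort plus its truth manifest."""

    design: PanelDesign
    coverage: CoverageMatrix
    profiles: list[LocusAlleleProfile]
    meta: list[SampleMeta]
    truths: dict[str, SampleTruth]

    @property
    def manifest(self) -> dict:
        return {sid: t.to_jsonable() for sid, t in sorted(self.truths.items())}


def gen_cohort(
    n_normal: int,
    n_mss_tumor: int,
    n_msi_tumor: int,
    n_amplified: int = 0,
    template: Optional[SimulationSpec] = None,
    out_dir: Optional[str | Path] = None,
    msi_fraction_range: tuple[float, float] = (0.22, 0.87),
    msi_purity_range: tuple[float, float] = (0.5, 0.9),
    mss_purity_range: tuple[float, float] = (0.4, 0.9),
) -> Cohort:
    """Generate a cohort of table-level samples with a truth manifest.

    Normals are FFPE normal-tissue controls (no tumor content). MSI tumors
    destabilize fractions of the panel's loci spanning ``msi_fraction_range``
    (linearly spaced across the samples, the worst case first). Amplified
    tumors cycle through :data:`AMPLIFIED_CONTROL_PAIRS` and the panel's
    amplification genes. When ``out_dir`` is given, panel/coverage/profile/
    metadata TSVs and a ``truth.json`` manifest are written there; an empty
    cohort writes nothing.
    """
    template = template or SimulationSpec()
    panel = template.panel
    assert panel is not None
    loci = sorted(panel.msi_loci)
    total = n_normal + n_mss_tumor + n_msi_tumor + n_amplified
    child_seeds = [
        int(s) % 2**31
        for s in np.random.SeedSequence(template.seed).generate_state(max(total, 1) * 2)
    ]
    picker = np.random.default_rng(child_seeds[-1])

    specs: list[tuple[str, str, SimulationSpec]] = []
    idx = 0
    for i in range(n_normal):
        specs.append(
            (f"NORM_{i + 1:02d}", "normal",
             replace(template, seed=child_seeds[idx], amplified_genes={},
                     msi_unstable_loci=frozenset(), neoplastic_fraction=None))
        )
        idx += 1
    for i in range(n_mss_tumor):
        purity = float(picker.uniform(*mss_purity_range))
        specs.append(
            (f"MSS_{i + 1:02d}", "mss_tumor",
             replace(template, seed=child_seeds[idx], amplified_genes={},
                     msi_unstable_loci=frozenset(), neoplastic_fraction=round(purity, 2)))
        )
        idx += 1
    if n_msi_tumor > 0:
        fractions = np.linspace(*msi_fraction_range, n_msi_tumor)
        for i in range(n_msi_tumor):
            n_unstable = int(round(fractions[i] * len(loci)))
            unstable = frozenset(picker.choice(loci, size=n_unstable, replace=False))
            purity = float(picker.uniform(*msi_purity_range))
            specs.append(
                (f"MSI_{i + 1:02d}", "msi_tumor",
                 replace(template, seed=child_seeds[idx], amplified_genes={},
                         msi_unstable_loci=unstable, neoplastic_fraction=round(purity, 2)))
            )
            idx += 1
    amp_genes = sorted(panel.amplification_genes)
    for i in range(n_amplified):
        k, purity = AMPLIFIED_CONTROL_PAIRS[i % len(AMPLIFIED_CONTROL_PAIRS)]
        gene = amp_genes[i % len(amp_genes)]
        specs.append(
            (f"AMP_{i + 1:02d}", "amplified_tumor",
             replace(template, seed=child_seeds[idx], amplified_genes={gene: float(k)},
                     msi_unstable_loci=frozenset(), neoplastic_fraction=purity))
        )
        idx += 1

    truths: dict[str, SampleTruth] = {}
    columns: dict[str, pd.Series] = {}
    profiles: list[LocusAlleleProfile] = []
    metas: list[SampleMeta] = []
    for sample_id, kind, spec in specs:
        truth = sample_tables(spec, sample_id=sample_id, kind=kind)
        truths[sample_id] = truth
        columns[sample_id] = truth.molecule_counts
        for locus, hist in sorted(truth.locus_histograms.items()):
            profiles.append(LocusAlleleProfile(sample_id=sample_id, locus_id=locus, histogram=hist))
        metas.append(
            SampleMeta(
                sample_id=sample_id,
                neoplastic_fraction=spec.neoplastic_fraction,
                is_normal_control=(kind == "normal"),
                declared_sex=spec.sex,
            )
        )

    if total > 0:
        coverage = CoverageMatrix.from_columns(columns)
    else:
        coverage = CoverageMatrix(pd.DataFrame(index=pd.Index([], name="probe_id")))

    cohort = Cohort(design=panel, coverage=coverage, profiles=profiles, meta=metas, truths=truths)

    if out_dir is not None and total > 0:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_panel_design(panel, out / "panel.tsv")
        write_coverage_matrix(coverage, out / "coverage.tsv")
        write_allele_profiles(profiles, out / "profiles.tsv")
        write_sample_meta(metas, out / "samples.tsv")
        (out / "truth.json").write_text(json.dumps(cohort.manifest, indent=2, sort_keys=True) + "\n")
    return cohort
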