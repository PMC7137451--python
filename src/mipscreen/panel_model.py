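"""Domain types and file I/O for an smMIP screening panel.

A panel is a set of single-molecule molecular inversion probes (smMIPs), each
targeting one genomic region and serving one analytical role: ``mutation``
(hotspot sequencing), ``amplification`` (copy-number signal, at least ten
probes per gene spread across the gene), ``msi`` (a microsatellite locus whose
repeat-length distribution is scored for instability), or ``sex_control``
(AMELX/AMELY concordance probes).

Conventions
-----------
* Genomic coordinates are 0-based, half-open (BED convention).
* All tabular files are tab-separated UTF-8 with a required header row;
  lines starting with ``#`` are comments. Written files are bit-stable, so
  ``read(write(x)) == x``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import ValidationError

ROLES = ("mutation", "amplification", "msi", "sex_control")
SEX_CONTROL_GENES = ("AMELX", "AMELY")
MISSING = "."  # TSV placeholder for absent optional fields


@dataclass(frozen=True)
class SmmipProbe:
    """One smMIP probe record.

    ``msi_locus_id`` is required iff ``role == "msi"``; probes of other roles
    must leave it unset.
    """

    probe_id: str
    gene: str
    chrom: str
    target_start: int
    target_end: int
    strand: str
    role: str
    msi_locus_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.probe_id:
            raise ValidationError("probe_id must be non-empty")
        if self.target_end <= self.target_start:
            raise ValidationError(
                f"probe {self.probe_id!r}: target_end ({self.target_end}) must be "
                f"> target_start ({self.target_start})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"probe {self.probe_id!r}: strand must be '+' or '-'")
        if self.role not in ROLES:
            raise ValidationError(
                f"probe {self.probe_id!r}: unknown role {self.role!r}; expected one of {ROLES}"
            )
        if self.role == "msi" and not self.msi_locus_id:
            raise ValidationError(f"probe {self.probe_id!r}: role 'msi' requires msi_locus_id")
        if self.role != "msi" and self.msi_locus_id:
            raise ValidationError(
                f"probe {self.probe_id!r}: msi_locus_id only allowed for role 'msi'"
            )
        if self.role == "sex_control" and self.gene not in SEX_CONTROL_GENES:
            raise ValidationError(
                f"probe {self.probe_id!r}: role 'sex_control' only for genes "
                f"{SEX_CONTROL_GENES}, got {self.gene!r}"
            )


@dataclass
class PanelDesign:
    """A validated set of probes plus derived per-role views.

    With ``strict_panel_rules`` every amplification gene must carry at least
    ten amplification-role probes (the design rule for a stable per-gene
    coverage estimate); otherwise a warning is emitted.
    """

    probes: list[SmmipProbe]
    strict_panel_rules: bool = False

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.probes:
            if p.probe_id in seen:
                raise ValidationError(f"duplicate probe_id {p.probe_id!r} in panel")
            seen.add(p.probe_id)
        for gene in sorted(self.amplification_genes):
            n = sum(1 for p in self.probes if p.role == "amplification" and p.gene == gene)
            if n < 10:
                msg = f"amplification gene {gene!r} has only {n} amplification probes (<10)"
                if self.strict_panel_rules:
                    raise ValidationError(msg)
                warnings.warn(msg, stacklevel=2)

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    @property
    def amplification_genes(self) -> set[str]:
        return {p.gene for p in self.probes if p.role == "amplification"}

    @property
    def msi_loci(self) -> set[str]:
        return {p.msi_locus_id for p in self.probes if p.role == "msi"}  # type: ignore[misc]

    def probes_for_gene(self, gene: str, role: str = "amplification") -> list[SmmipProbe]:
        return [p for p in self.probes if p.gene == gene and p.role == role]

    def probe(self, probe_id: str) -> SmmipProbe:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)

    def __len__(self) -> int:
        return len(self.probes)


PANEL_COLUMNS = ["chrom", "start", "end", "probe_id", "gene", "strand", "role", "msi_locus_id"]


def read_panel_design(path: str | Path, strict_panel_rules: bool = False) -> PanelDesign:
    """Read a BED-like panel design TSV (columns: chrom, start, end, probe_id,
    gene, strand, role, msi_locus_id; '.' marks an absent locus id)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"panel design {path}: missing columns {missing}")
    probes = []
    for row in df.itertuples(index=False):
        locus = None if row.msi_locus_id in (MISSING, "", None) or pd.isna(row.msi_locus_id) else row.msi_locus_id
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"panel design {path}: non-integer coordinate for probe {row.probe_id!r}"
            ) from exc
        probes.append(
            SmmipProbe(
                probe_id=row.probe_id, gene=row.gene, chrom=row.chrom,
                target_start=start, target_end=end, strand=row.strand,
                role=row.role, msi_locus_id=locus,
            )
        )
    return PanelDesign(probes, strict_panel_rules=strict_panel_rules)


def write_panel_design(design: PanelDesign, path: str | Path) -> None:
    rows = [
        {
            "chrom": p.chrom, "start": p.target_start, "end": p.target_end,
            "probe_id": p.probe_id, "gene": p.gene, "strand": p.strand,
            "role": p.role, "msi_locus_id": p.msi_locus_id or MISSING,
        }
        for p in design.probes
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


@dataclass
class CoverageMatrix:
    """Samples x smMIPs table of unique-molecule counts.

    Stored as a probes-by-samples integer DataFrame. Counts are the number of
    distinct template molecules (post-UMI-collapse) per probe per sample.
    """

    counts: pd.DataFrame  # index: probe_id, columns: sample_id

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate probe_id {dup!r} in coverage matrix")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample_id {dup!r} in coverage matrix")
        for sample in self.counts.columns:
            col = self.counts[sample]
            if col.isna().any():
                probe = col.index[col.isna()][0]
                raise ValidationError(
                    f"missing count for sample {sample!r}, probe {probe!r}"
                )
            for probe, value in col.items():
                if float(value) != int(value):
                    raise ValidationError(
                        f"non-integer count {value!r} for sample {sample!r}, probe {probe!r}"
                    )
                if int(value) < 0:
                    raise ValidationError(
                        f"negative count {value!r} for sample {sample!r}, probe {probe!r}"
                    )
        self.counts = self.counts.astype("int64")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def column(self, sample_id: str) -> pd.Series:
        if sample_id not in self.counts.columns:
            raise KeyError(sample_id)
        return self.counts[sample_id]

    @classmethod
    def from_columns(cls, columns: Mapping[str, pd.Series]) -> "CoverageMatrix":
        """Assemble from per-sample columns (each a probe-indexed Series)."""
        return cls(pd.DataFrame(dict(columns)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageMatrix):
            return NotImplemented
        return self.counts.equals(other.counts)


def read_coverage_matrix(path: str | Path) -> CoverageMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.columns[0] != "probe_id":
        raise ValidationError(f"coverage matrix {path}: first column must be 'probe_id'")
    df = df.set_index("probe_id")
    numeric = pd.DataFrame(index=df.index)
    for sample in df.columns:
        raw = df[sample]
        if raw.isna().all():
            raise ValidationError(f"coverage matrix {path}: sample {sample!r} column is empty")
        values = []
        for probe, cell in raw.items():
            if pd.isna(cell):
                raise ValidationError(
                    f"coverage matrix {path}: missing count for sample {sample!r}, probe {probe!r}"
                )
            try:
                values.append(int(cell))
            except ValueError as exc:
                raise ValidationError(
                    f"coverage matrix {path}: non-integer count {cell!r} for "
                    f"sample {sample!r}, probe {probe!r}"
                ) from exc
        numeric[sample] = values
    return CoverageMatrix(numeric)


def write_coverage_matrix(matrix: CoverageMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


@dataclass
class SampleMeta:
    """Per-sample metadata.

    ``neoplastic_fraction`` (tumor purity) is the pathologist's estimate of
    the proportion of neoplastic cells; it dilutes both amplification and MSI
    signal and gates several downstream rules. ``None`` means unknown —
    operations that require purity must then fail explicitly.
    """

    sample_id: str
    neoplastic_fraction: Optional[float] = None
    replicate_group: Optional[str] = None
    is_normal_control: bool = False
    declared_sex: Optional[str] = None  # "M", "F" or None

    def __post_init__(self) -> None:
        if self.neoplastic_fraction is not None and not (0.0 <= self.neoplastic_fraction <= 1.0):
            raise ValidationError(
                f"sample {self.sample_id!r}: neoplastic_fraction "
                f"{self.neoplastic_fraction} outside [0, 1]"
            )
        if self.declared_sex not in (None, "M", "F"):
            raise ValidationError(f"sample {self.sample_id!r}: declared_sex must be M/F/unknown")


META_COLUMNS = ["sample_id", "neoplastic_fraction", "replicate_group", "is_normal_control", "declared_sex"]


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"sample metadata {path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        frac = None if row.neoplastic_fraction in (MISSING, "", None) or pd.isna(row.neoplastic_fraction) else float(row.neoplastic_fraction)
        group = None if row.replicate_group in (MISSING, "", None) or pd.isna(row.replicate_group) else row.replicate_group
        sex = None if row.declared_sex in (MISSING, "", None, "unknown") or pd.isna(row.declared_sex) else row.declared_sex
        out.append(
            SampleMeta(
                sample_id=row.sample_id,
                neoplastic_fraction=frac,
                replicate_group=group,
                is_normal_control=str(row.is_normal_control).lower() in ("1", "true", "yes"),
                declared_sex=sex,
            )
        )
    return out


def write_sample_meta(metas: Iterable[SampleMeta], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "neoplastic_fraction": MISSING if m.neoplastic_fraction is None else m.neoplastic_fraction,
            "replicate_group": m.replicate_group or MISSING,
            "is_normal_control": str(m.is_normal_control).lower(),
            "declared_sex": m.declared_sex or MISSING,
        }
        for m in metas
    ]
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, sep="\t", index=False)


@dataclass
class LocusAlleleProfile:
    """Repeat length (bp) -> unique-read count histogram for one microsatellite
    locus in one sample."""

    sample_id: str
    locus_id: str
    histogram: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for length, count in self.histogram.items():
            if int(length) != length:
                raise ValidationError(
                    f"locus {self.locus_id!r}, sample {self.sample_id!r}: "
                    f"non-integer repeat length {length!r}"
                )
            if count < 0:
                raise ValidationError(
                    f"locus {self.locus_id!r}, sample {self.sample_id!r}: "
                    f"negative count at length {length}"
                )

    @property
    def total_depth(self) -> int:
        return sum(self.histogram.values())


PROFILE_COLUMNS = ["sample_id", "locus_id", "repeat_length", "count"]


def read_allele_profiles(path: str | Path) -> list[LocusAlleleProfile]:
    """Read a long-format TSV (sample_id, locus_id, repeat_length, count) into
    one profile per (sample, locus)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"allele profiles {path}: missing columns {missing}")
    profiles: dict[tuple[str, str], dict[int, int]] = {}
    for row in df.itertuples(index=False):
        key = (row.sample_id, row.locus_id)
        try:
            length = int(row.repeat_length)
        except ValueError as exc:
            raise ValidationError(
                f"allele profiles {path}: malformed repeat_length {row.repeat_length!r} "
                f"for sample {row.sample_id!r}, locus {row.locus_id!r}"
            ) from exc
        try:
            count = int(row.count)
        except ValueError as exc:
            raise ValidationError(
                f"allele profiles {path}: malformed count {row.count!r} for "
                f"sample {row.sample_id!r}, locus {row.locus_id!r}"
            ) from exc
        hist = profiles.setdefault(key, {})
        if length in hist:
            raise ValidationError(
                f"allele profiles {path}: duplicate row for sample {row.sample_id!r}, "
                f"locus {row.locus_id!r}, repeat_length {length}"
            )
        hist[length] = count
    return [
        LocusAlleleProfile(sample_id=s, locus_id=l, histogram=h)
        for (s, l), h in profiles.items()
    ]


def write_allele_profiles(profiles: Iterable[LocusAlleleProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for length in sorted(p.histogram):
            rows.append(
                {"sample_id": p.sample_id, "locus_id": p.locus_id,
                 "repeat_length": length, "count": p.histogram[length]}
            )
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, sep="\t", index=False)


def merge_duplicate_targets(matrix: CoverageMatrix, design: PanelDesign) -> tuple[CoverageMatrix, PanelDesign]:
    """Sum the counts of probes sharing one (chrom, start, end, gene, role)
    target into a single row.

    Panels carry extra probes recognizing common SNP variant alleles under the
    probe arms; those interrogate the same template molecules as their primary
    probe, so their unique-molecule counts add before analysis. The first
    probe_id of each target group is kept.
    """
    groups: dict[tuple, list[SmmipProbe]] = {}
    for p in design.probes:
        key = (p.chrom, p.target_start, p.target_end, p.gene, p.role, p.msi_locus_id)
        groups.setdefault(key, []).append(p)
    keep_probes, rows = [], {}
    for members in groups.values():
        primary = members[0]
        keep_probes.append(primary)
        total = matrix.counts.loc[[m.probe_id for m in members]].sum(axis=0)
        rows[primary.probe_id] = total
    merged = pd.DataFrame(rows).T
    merged = merged.loc[[p.probe_id for p in keep_probes]]
    merged.index.name = "probe_id"
    return CoverageMatrix(merged), PanelDesign(keep_probes)
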