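"""UMI-based collapse of tagged reads into unique molecules.

Each smMIP captures a single template molecule and tags it with a random
unique molecular identifier (UMI). PCR amplification and sequencing then
produce multiple reads per molecule; grouping reads by the exact
(probe_id, UMI, strand) key and merging each group into one consensus
eliminates PCR/sequencing duplicates and most base-call artifacts. The number
of consensus molecules per probe is the "unique coverage" that downstream
amplification and MSI analyses consume.

Grouping is by exact UMI string match; no error-tolerant UMI clustering is
attempted. Strand is part of the molecule key, so the two strands of one
fragment count as distinct molecules (strand-aggregated totals can be obtained
by summing).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .errors import ValidationError
from .panel_model import LocusAlleleProfile, PanelDesign

Payload = Union[str, int]


@dataclass(frozen=True)
class TaggedRead:
    """One read assigned to a probe, carrying its UMI.

    ``payload`` is the read sequence for sequence-role probes, or an observed
    repeat length (bp, integer) for MSI-role probes.
    """

    probe_id: str
    umi: str
    strand: str
    payload: Payload

    def __post_init__(self) -> None:
        if not self.umi:
            raise ValidationError("UMI must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class ConsensusMolecule:
    """One unique template molecule: the consensus over its duplicate reads."""

    probe_id: str
    umi: str
    strand: str
    consensus_payload: Payload
    duplicate_count: int


def _modal_int(values: Sequence[int]) -> int:
    # ties resolve to the smallest value, deterministically
    counts = Counter(values)
    best = max(counts.values())
    return min(v for v, c in counts.items() if c == best)


def _sequence_consensus(seqs: Sequence[str]) -> str:
    lengths = [len(s) for s in seqs]
    target_len = _modal_int(lengths)
    voters = [s for s in seqs if len(s) == target_len]
    out = []
    for pos in range(target_len):
        column = Counter(s[pos] for s in voters)
        best = max(column.values())
        # per-position majority; ties resolve to the lexicographically smallest base
        out.append(min(b for b, c in column.items() if c == best))
    return "".join(out)


def collapse(reads: Iterable[TaggedRead]) -> list[ConsensusMolecule]:
    """Merge duplicate reads into consensus molecules.

    One molecule is emitted per distinct (probe_id, umi, strand) key. Sequence
    payloads are merged by per-position majority vote (among reads of the modal
    length); repeat-length payloads by modal length. The sum of
    ``duplicate_count`` over the output equals the number of input reads.
    Output order is deterministic (sorted by key) regardless of input order.
    """
    groups: dict[tuple[str, str, str], list[TaggedRead]] = defaultdict(list)
    kinds: dict[str, type] = {}
    for read in reads:
        kind = int if isinstance(read.payload, int) else str
        prev = kinds.setdefault(read.probe_id, kind)
        if prev is not kind:
            raise ValidationError(
                f"probe {read.probe_id!r}: mixed sequence and repeat-length payloads"
            )
        groups[(read.probe_id, read.umi, read.strand)].append(read)

    molecules = []
    for key in sorted(groups):
        probe_id, umi, strand = key
        members = groups[key]
        payloads = [r.payload for r in members]
        if kinds[probe_id] is int:
            consensus: Payload = _modal_int(payloads)  # type: ignore[arg-type]
        else:
            consensus = _sequence_consensus(payloads)  # type: ignore[arg-type]
        molecules.append(
            ConsensusMolecule(
                probe_id=probe_id, umi=umi, strand=strand,
                consensus_payload=consensus, duplicate_count=len(members),
            )
        )
    return molecules


def unique_coverage(molecules: Iterable[ConsensusMolecule], design: PanelDesign) -> pd.Series:
    """Count consensus molecules per probe for one sample.

    Returns an int Series over every probe of the panel (zero where no
    molecule was observed). A molecule on a probe absent from the panel is an
    error.
    """
    counts = Counter(m.probe_id for m in molecules)
    known = set(design.probe_ids)
    unknown = sorted(set(counts) - known)
    if unknown:
        raise ValidationError(f"molecules on probes not in panel: {unknown}")
    return pd.Series(
        [counts.get(pid, 0) for pid in design.probe_ids],
        index=pd.Index(design.probe_ids, name="probe_id"),
        dtype="int64",
    )


def profiles_from_molecules(
    molecules: Iterable[ConsensusMolecule], design: PanelDesign, sample_id: str
) -> list[LocusAlleleProfile]:
    """Build per-locus repeat-length histograms from MSI-probe molecules."""
    locus_of = {p.probe_id: p.msi_locus_id for p in design.probes if p.role == "msi"}
    hists: dict[str, Counter] = defaultdict(Counter)
    for m in molecules:
        locus = locus_of.get(m.probe_id)
        if locus is None:
            continue
        if not isinstance(m.consensus_payload, int):
            raise ValidationError(
                f"probe {m.probe_id!r} is MSI-role but its consensus is not a repeat length"
            )
        hists[locus][m.consensus_payload] += 1
    return [
        LocusAlleleProfile(sample_id=sample_id, locus_id=locus, histogram=dict(hists[locus]))
        for locus in sorted(hists)
    ]


def reset_duplicates(molecules: Iterable[ConsensusMolecule]) -> list[TaggedRead]:
    """Re-cast consensus molecules as single reads (for idempotence checks)."""
    return [
        TaggedRead(m.probe_id, m.umi, m.strand, m.consensus_payload) for m in molecules
    ]


READ_COLUMNS = ["probe_id", "umi", "strand", "payload"]


def read_tagged_reads(path: str | Path, design: Optional[PanelDesign] = None) -> list[TaggedRead]:
    """Read a tagged-read TSV (probe_id, umi, strand, payload).

    Payloads of MSI-role probes (when ``design`` is given) or all-digit
    payloads are parsed as repeat lengths; anything else is a sequence.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in READ_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"tagged reads {path}: missing columns {missing}")
    msi_probes = (
        {p.probe_id for p in design.probes if p.role == "msi"} if design is not None else None
    )
    out = []
    for row in df.itertuples(index=False):
        raw = row.payload
        is_length = raw.isdigit() if msi_probes is None else row.probe_id in msi_probes
        payload: Payload = int(raw) if is_length else raw
        out.append(TaggedRead(row.probe_id, row.umi, row.strand, payload))
    return out


def write_tagged_reads(reads: Iterable[TaggedRead], path: str | Path) -> None:
    rows = [
        {"probe_id": r.probe_id, "umi": r.umi, "strand": r.strand, "payload": r.payload}
        for r in reads
    ]
    pd.DataFrame(rows, columns=READ_COLUMNS).to_csv(path, sep="\t", index=False)


def reads_from_sam(path: str | Path, design: PanelDesign, umi_tag: str = "RX") -> list[TaggedRead]:
    """Adapter: extract tagged reads from a SAM/BAM file.

    Each mapped read carrying ``umi_tag`` is assigned to the panel probe whose
    target overlaps it most (same reference name); reads overlapping no target
    or lacking the tag are skipped. The payload is the query sequence, or — for
    MSI-role probes — the query length as a crude repeat-length proxy.
    """
    import pysam  # deferred: only needed for the alignment adapter

    by_chrom: dict[str, list] = defaultdict(list)
    for p in design.probes:
        by_chrom[p.chrom].append(p)

    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for aln in handle.fetch(until_eof=True):
            if aln.is_unmapped or not aln.has_tag(umi_tag):
                continue
            start, end = aln.reference_start, aln.reference_end or aln.reference_start + 1
            best, best_overlap = None, 0
            for p in by_chrom.get(aln.reference_name, []):
                overlap = min(end, p.target_end) - max(start, p.target_start)
                if overlap > best_overlap:
                    best, best_overlap = p, overlap
            if best is None:
                continue
            strand = "-" if aln.is_reverse else "+"
            payload: Payload = (
                len(aln.query_sequence) if best.role == "msi" else aln.query_sequence
            )
            reads.append(TaggedRead(best.probe_id, str(aln.get_tag(umi_tag)), strand, payload))
    return reads
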