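"""Readers and writers for every file the pipeline touches.

The central format is a flat, search-engine-agnostic PSM (peptide-spectrum
match) table: tab-separated, UTF-8, one row per PSM, with mass-shift
annotations in a compact ``offset:delta`` syntax and the eight iTRAQ 8-plex
reporter-channel intensities as columns.  Protein coordinates are 1-based
inclusive everywhere data crosses a module boundary; peptide-internal mod
offsets are 0-based, with ``-1`` denoting the peptide N-terminus.

Supporting formats: FASTA protein sequences (via biopython), a domain
annotation TSV (Interpro-style intervals), a plain-text EV-marker list, and a
clinical cohort CSV.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The iTRAQ 8-plex reporter channels, in ascending mass order.
CHANNELS: Tuple[str, ...] = ("113", "114", "115", "116", "117", "118", "119", "121")

#: Channel -> group assignment used in the study design this package models:
#: three normozoospermic (NZ) pools and five non-normozoospermic (nonNZ) pools.
DEFAULT_CHANNEL_TO_GROUP: Dict[str, str] = {
    "113": "NZ", "114": "NZ", "119": "NZ",
    "115": "nonNZ", "116": "nonNZ", "117": "nonNZ", "118": "nonNZ", "121": "nonNZ",
}

GROUPS: Tuple[str, str] = ("NZ", "nonNZ")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

PSM_COLUMNS: Tuple[str, ...] = (
    "spectrum_id", "peptide", "protein", "peptide_start", "mods", "q_value",
    "pool", "I113", "I114", "I115", "I116", "I117", "I118", "I119", "I121",
)

CLINICAL_COLUMNS: Tuple[str, ...] = (
    "subject_id", "group", "vitality", "morphology", "progressive_motility",
    "count", "age", "smoking", "alcohol", "toxicology",
)

DOMAIN_COLUMNS: Tuple[str, ...] = ("protein_accession", "domain_name", "start", "end")


class ParseError(ValueError):
    """Raised when an input file violates its format contract.

    ``line`` is the 1-based line number in the file (header included).
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match with its mass-shift and reporter data."""

    spectrum_id: str
    peptide: str
    protein_accession: str
    peptide_start: int  # 1-based position of the peptide's first residue
    mods: Tuple[Tuple[int, float], ...]  # (0-based offset or -1 for N-term, delta Da)
    q_value: float
    reporter_intensities: Mapping[str, float]
    pool_id: str

    def __post_init__(self):
        if not self.peptide:
            raise ValueError("empty peptide")
        bad = set(self.peptide) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-canonical residues in peptide: {sorted(bad)}")
        if self.peptide_start < 1:
            raise ValueError(f"peptide_start must be >= 1, got {self.peptide_start}")
        for off, delta in self.mods:
            if not -1 <= off <= len(self.peptide) - 1:
                raise ValueError(f"mod offset {off} outside [-1, {len(self.peptide) - 1}]")
            if not math.isfinite(delta):
                raise ValueError(f"non-finite delta mass {delta!r}")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value {self.q_value} outside [0, 1]")
        unknown = set(self.reporter_intensities) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown reporter channels: {sorted(unknown)}")
        for ch, v in self.reporter_intensities.items():
            if v < 0:
                raise ValueError(f"negative intensity in channel {ch}")

    def intensity(self, channels: Sequence[str] | None = None) -> float:
        """Summed reporter intensity over *channels* (default: all)."""
        if channels is None:
            channels = CHANNELS
        return float(sum(self.reporter_intensities.get(c, 0.0) for c in channels))


@dataclass(frozen=True)
class ReporterDesign:
    """The 8-channel iTRAQ design: which channel carries which pooled group."""

    channel_to_group: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_TO_GROUP))

    def __post_init__(self):
        if set(self.channel_to_group) != set(CHANNELS):
            raise ValueError(
                f"design must map exactly the 8 channels {CHANNELS}, "
                f"got {sorted(self.channel_to_group)}")

    @property
    def groups(self) -> Tuple[str, ...]:
        seen: List[str] = []
        for c in CHANNELS:
            g = self.channel_to_group[c]
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def channels_for(self, group: str) -> Tuple[str, ...]:
        return tuple(c for c in CHANNELS if self.channel_to_group[c] == group)

    @property
    def channel_to_pool(self) -> Dict[str, str]:
        """Channel -> pool label (``NZ1`` .. ``nonNZ5`` in channel order)."""
        counters: Dict[str, int] = {}
        out = {}
        for c in CHANNELS:
            g = self.channel_to_group[c]
            counters[g] = counters.get(g, 0) + 1
            out[c] = f"{g}{counters[g]}"
        return out

    @property
    def pool_to_channel(self) -> Dict[str, str]:
        return {p: c for c, p in self.channel_to_pool.items()}

    @property
    def pools(self) -> Tuple[str, ...]:
        return tuple(self.channel_to_pool[c] for c in CHANNELS)

    def pool_group(self, pool_id: str) -> str:
        try:
            return self.channel_to_group[self.pool_to_channel[pool_id]]
        except KeyError:
            raise KeyError(f"unknown pool id {pool_id!r}") from None


@dataclass(frozen=True)
class DomainAnnotation:
    """An Interpro-style domain interval on a protein, 1-based inclusive."""

    protein_accession: str
    domain_name: str
    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"require 1 <= start <= end, got [{self.start}, {self.end}]")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-subject sperm parameters, age and lifestyle flags.

    Missing numeric values are carried as NaN and removed pairwise by the
    statistics layer.
    """

    subject_id: str
    group: str  # "NZ" or "nonNZ"
    vitality: float  # %
    morphology: float  # %
    progressive_motility: float  # %
    count: float  # 10^6 / ml
    age: float  # years
    smoking: bool
    alcohol: bool
    toxicology: bool

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        for name in ("vitality", "morphology", "progressive_motility"):
            v = getattr(self, name)
            if not math.isnan(v) and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} {v} outside [0, 100]")
        if not math.isnan(self.count) and self.count < 0:
            raise ValueError(f"count {self.count} negative")
        if not math.isnan(self.age) and self.age <= 0:
            raise ValueError(f"age {self.age} must be positive")


# ---------------------------------------------------------------------------
# PSM table
# ---------------------------------------------------------------------------

def _parse_mods(text: str) -> Tuple[Tuple[int, float], ...]:
    if not text:
        return ()
    out = []
    for part in text.split(";"):
        try:
            off_s, delta_s = part.split(":")
            out.append((int(off_s), float(delta_s)))
        except ValueError:
            raise ValueError(f"malformed mod entry {part!r} (expected 'offset:delta')")
    return tuple(out)


def _format_mods(mods: Sequence[Tuple[int, float]]) -> str:
    return ";".join(f"{off}:{delta!r}" for off, delta in mods)


def read_psm_table(path: str | Path) -> List[PSMRecord]:
    """Read a PSM TSV table; every violation is reported with its line number."""
    path = Path(path)
    records: List[PSMRecord] = []
    n_missing_cells = 0
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty PSM table", line=1)
        if tuple(header) != PSM_COLUMNS:
            raise ParseError(
                f"bad header: expected {list(PSM_COLUMNS)}, got {header}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(PSM_COLUMNS):
                raise ParseError(
                    f"expected {len(PSM_COLUMNS)} fields, got {len(row)}", line=lineno)
            d = dict(zip(PSM_COLUMNS, row))
            try:
                intensities = {}
                for ch in CHANNELS:
                    cell = d[f"I{ch}"].strip()
                    if cell == "":
                        n_missing_cells += 1
                        intensities[ch] = 0.0
                    else:
                        intensities[ch] = float(cell)
                rec = PSMRecord(
                    spectrum_id=d["spectrum_id"],
                    peptide=d["peptide"],
                    protein_accession=d["protein"],
                    peptide_start=int(d["peptide_start"]),
                    mods=_parse_mods(d["mods"]),
                    q_value=float(d["q_value"]),
                    reporter_intensities=intensities,
                    pool_id=d["pool"],
                )
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            records.append(rec)
    if n_missing_cells:
        logger.warning("%s: %d missing reporter intensity cells read as 0",
                       path.name, n_missing_cells)
    return records


def write_psm_table(records: Sequence[PSMRecord], path: str | Path) -> None:
    """Write a PSM table in the dialect :func:`read_psm_table` accepts.

    Floats are written with ``repr`` so a write/read round trip reproduces the
    records field-for-field, and identical records always produce identical
    bytes.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PSM_COLUMNS)
        for r in records:
            writer.writerow([
                r.spectrum_id, r.peptide, r.protein_accession, r.peptide_start,
                _format_mods(r.mods), repr(r.q_value), r.pool_id,
                *(repr(float(r.reporter_intensities.get(c, 0.0))) for c in CHANNELS),
            ])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Dict[str, str]:
    """Map accession -> uppercased sequence; accession is the first header token."""
    path = Path(path)
    sequences: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        accession = record.id
        if accession in sequences:
            raise ParseError(f"duplicate accession {accession!r} in {path.name}")
        sequences[accession] = str(record.seq).upper()
    if not sequences:
        raise ParseError(f"no sequences found in {path.name}")
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for acc in sequences:
            fh.write(f">{acc}\n")
            seq = sequences[acc]
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# marker list
# ---------------------------------------------------------------------------

def read_marker_list(path: str | Path) -> List[str]:
    """One accession per line, ``#`` comments skipped, order-preserving dedup."""
    path = Path(path)
    seen = set()
    markers: List[str] = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            if token not in seen:
                seen.add(token)
                markers.append(token)
    if not markers:
        raise ParseError(f"no markers left after filtering in {path.name}")
    return markers


def write_marker_list(markers: Sequence[str], path: str | Path,
                      comment: str | None = None) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for m in markers:
            fh.write(m + "\n")


# ---------------------------------------------------------------------------
# domains
# ---------------------------------------------------------------------------

def read_domains(path: str | Path) -> List[DomainAnnotation]:
    path = Path(path)
    out: List[DomainAnnotation] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty domain table", line=1)
        if tuple(header) != DOMAIN_COLUMNS:
            raise ParseError(
                f"bad header: expected {list(DOMAIN_COLUMNS)}, got {header}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                out.append(DomainAnnotation(row[0], row[1], int(row[2]), int(row[3])))
            except (IndexError, ValueError) as exc:
                raise ParseError(str(exc), line=lineno) from exc
    return out


def write_domains(domains: Sequence[DomainAnnotation], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(DOMAIN_COLUMNS)
        for d in domains:
            writer.writerow([d.protein_accession, d.domain_name, d.start, d.end])


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

_BOOL = {"1": True, "0": False, "true": True, "false": False,
         "yes": True, "no": False}


def _parse_bool(text: str) -> bool:
    try:
        return _BOOL[text.strip().lower()]
    except KeyError:
        raise ValueError(f"bad boolean value {text!r}")


def _parse_float(text: str) -> float:
    text = text.strip()
    return math.nan if text == "" else float(text)


def read_clinical(path: str | Path) -> List[ClinicalRecord]:
    path = Path(path)
    out: List[ClinicalRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty clinical table", line=1)
        if tuple(header) != CLINICAL_COLUMNS:
            raise ParseError(
                f"bad header: expected {list(CLINICAL_COLUMNS)}, got {header}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            d = dict(zip(CLINICAL_COLUMNS, row))
            try:
                out.append(ClinicalRecord(
                    subject_id=d["subject_id"],
                    group=d["group"],
                    vitality=_parse_float(d["vitality"]),
                    morphology=_parse_float(d["morphology"]),
                    progressive_motility=_parse_float(d["progressive_motility"]),
                    count=_parse_float(d["count"]),
                    age=_parse_float(d["age"]),
                    smoking=_parse_bool(d["smoking"]),
                    alcohol=_parse_bool(d["alcohol"]),
                    toxicology=_parse_bool(d["toxicology"]),
                ))
            except (KeyError, ValueError) as exc:
                raise ParseError(str(exc), line=lineno) from exc
    return out


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    def fmt(v: float) -> str:
        return "" if math.isnan(v) else repr(float(v))

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CLINICAL_COLUMNS)
        for r in records:
            writer.writerow([
                r.subject_id, r.group, fmt(r.vitality), fmt(r.morphology),
                fmt(r.progressive_motility), fmt(r.count), fmt(r.age),
                int(r.smoking), int(r.alcohol), int(r.toxicology),
            ])
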