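"""Sequence and alignment data model plus plain-text readers/writers.

Coordinates are 0-based, half-open everywhere; conversion to 1-based happens
only when writing human-readable reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("retroburst")

DNA_ALPHABET = set("ACGTN")
GAP = "-"
ALIGNED_ALPHABET = DNA_ALPHABET | {GAP}

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")

REGION_LABELS = ("full", "LTR5", "LTR3", "Int", "RT")

# numeric encoding used by the statistics modules: A,C,G,T = 0..3, missing = -1
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N and gaps map to themselves)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named DNA sequence.

    ``seq`` is uppercase over {A,C,G,T,N}; aligned records may also contain
    ``-``. ``desc`` is free text carried through from the FASTA header.
    """

    id: str
    seq: str
    desc: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        self.seq = normalize_seq(self.seq)
        if not self.seq:
            raise ValueError(f"sequence for record {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


def normalize_seq(seq: str) -> str:
    """Uppercase, map U->T, and validate the alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - ALIGNED_ALPHABET
    if bad:
        raise ValueError(f"illegal sequence characters: {sorted(bad)!r}")
    return s


@dataclass
class Alignment:
    """An equal-length set of >=2 sequence rows with optional group labels."""

    records: list[SequenceRecord]
    region_label: str = "full"
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("alignment needs at least 2 records")
        L = len(self.records[0].seq)
        for rec in self.records:
            if len(rec.seq) != L:
                raise ValueError(
                    f"record {rec.id!r} has length {len(rec.seq)}, expected {L}"
                )
        if self.region_label not in REGION_LABELS:
            raise ValueError(
                f"region_label {self.region_label!r} not in {REGION_LABELS}"
            )
        ids = {r.id for r in self.records}
        if len(ids) != len(self.records):
            raise ValueError("duplicate record ids in alignment")
        if not self.groups:
            self.groups = {r.id: "ungrouped" for r in self.records}
        else:
            for rid in ids:
                self.groups.setdefault(rid, "ungrouped")
            for gid in list(self.groups):
                if gid not in ids:
                    logger.warning("group map id %r not present in alignment", gid)
                    del self.groups[gid]

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def encoded(self) -> np.ndarray:
        """(n, L) int8 matrix; A,C,G,T -> 0..3, gap/N -> -1."""
        arr = np.frombuffer(
            "".join(r.seq for r in self.records).encode("ascii"), dtype=np.uint8
        )
        return _ENCODE[arr].reshape(self.n, self.length)

    def group_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for rid in self.ids:
            out.setdefault(self.groups[rid], []).append(rid)
        return out

    def subset(self, ids: Sequence[str]) -> "Alignment":
        wanted = set(ids)
        recs = [r for r in self.records if r.id in wanted]
        return Alignment(
            records=recs,
            region_label=self.region_label,
            groups={r.id: self.groups[r.id] for r in recs},
        )

    def slice_columns(self, start: int, end: int) -> "Alignment":
        recs = [SequenceRecord(r.id, r.seq[start:end], r.desc) for r in self.records]
        return Alignment(records=recs, region_label=self.region_label,
                         groups=dict(self.groups))


@dataclass
class PipelineConfig:
    """Flat run configuration; every field can be overridden from the CLI."""

    seed: int = 0
    tsd_len: int = 4
    ltr_min_len: int = 100
    ltr_max_len: int = 1000
    ltr_min_identity: float = 0.8
    family_threshold: float = 0.70
    site_coverage: float = 0.90
    bootstrap_reps: int = 1000
    window: int = 300
    step: int = 50
    alpha: float = 0.05
    window_span: int = 15000
    min_contig_len: int = 10000
    termini_mismatch: int = 3

    def __post_init__(self) -> None:
        for name in ("ltr_min_identity", "family_threshold", "site_coverage", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if not self.window >= self.step >= 1:
            raise ValueError("require window >= step >= 1")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, allow_gaps: bool = False) -> list[SequenceRecord]:
    """Read FASTA, preserving order, uppercasing, and mapping U->T.

    Duplicate ids raise; unaligned files may not contain gap characters
    unless ``allow_gaps`` is set.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    rid: str | None = None
    desc = ""
    chunks: list[str] = []

    def flush() -> None:
        if rid is None:
            return
        rec = SequenceRecord(rid, "".join(chunks), desc)
        if not allow_gaps and GAP in rec.seq:
            raise ValueError(f"unaligned record {rid!r} contains gap characters")
        records.append(rec)

    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                head = line[1:].split(maxsplit=1)
                if not head:
                    raise ValueError(f"{path}: FASTA header with no id")
                rid = head[0]
                desc = head[1] if len(head) > 1 else ""
                if rid in seen:
                    raise ValueError(f"{path}: duplicate sequence id {rid!r}")
                seen.add(rid)
                chunks = []
            else:
                if rid is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line)
    flush()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}" + (f" {rec.desc}" if rec.desc else "")
            fh.write(head + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column (copy_id, group) TSV; a header line is optional."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
            if ln == 1 and parts[0].lower() in ("copy_id", "id", "copy"):
                continue
            groups[parts[0]] = parts[1]
    return groups


def read_alignment(path: str | Path, groups: str | Path | None = None,
                   region_label: str = "full") -> Alignment:
    """Ingest an aligned FASTA plus optional copy_id -> group TSV."""
    records = read_fasta(path, allow_gaps=True)
    gmap = read_groups_tsv(groups) if groups else {}
    aln = Alignment(records=records, region_label=region_label, groups=gmap)
    if region_label == "RT" and aln.length % 3 != 0:
        raise ValueError(
            f"RT alignment length {aln.length} is not divisible by 3"
        )
    return aln


def write_groups_tsv(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("copy_id\tgroup\n")
        for cid, g in groups.items():
            fh.write(f"{cid}\t{g}\n")


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

def write_tsv_report(rows: Sequence[Mapping], path: str | Path,
                     columns: Sequence[str] | None = None,
                     float_decimals: int = 4) -> None:
    """Write dict rows as a UTF-8 TSV with a header line.

    Floats are rendered with ``float_decimals`` decimals. An empty row list
    still produces the header (``columns`` must then be given).
    """
    if rows:
        df = pd.DataFrame(list(rows), columns=columns or list(rows[0].keys()))
    else:
        if columns is None:
            raise ValueError("columns required to write an empty report")
        df = pd.DataFrame(columns=list(columns))
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{float_decimals}f",
              encoding="utf-8")
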