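"""Readers and writers for every pipeline artifact.

Formats (all plain text, UTF-8, '.' decimal separator):

* FASTA — reference / sample / corrected reads (Biopython-backed, 80-column
  wrap, uppercase-normalized, ACGTN alphabet).
* flowgram TSV — the raw-signal stand-in: one row per flow with columns
  read_id, flow_index, nucleotide, read_position (1-based), voltage
  (6-decimal fixed precision).
* priors JSON — see :mod:`flowcall.priors`.
* ground-truth / variants / calls / evaluation TSVs.
* run config YAML/JSON for the CLI.

All writers use stable row ordering and fixed float formatting so a
fixed-seed pipeline is byte-reproducible end-to-end.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, InputError
from .priors import FLOWGRAM_COLUMNS, NUCLEOTIDES, ZONE_PROFILES, ZoneScheme

_VALID_SEQ = re.compile(r"^[ACGTN]*$")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into an ordered {id: sequence} dict.

    Sequences are uppercased; any character outside ACGTN raises an input
    error naming the offending record and position.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        m = _VALID_SEQ.match(seq)
        if m is None or m.end() != len(seq):
            bad = next(i for i, c in enumerate(seq) if c not in "ACGTN")
            raise InputError(
                f"record {rec.id!r}: invalid character {seq[bad]!r} at position {bad + 1}"
            )
        records[rec.id] = seq
    return records


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]],
                path: str | Path) -> None:
    """Write sequences as FASTA, 80-column wrapped, uppercase."""
    items = records.items() if isinstance(records, Mapping) else records
    seq_records = [SeqRecord(Seq(seq.upper()), id=name, description="") for name, seq in items]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


# ---------------------------------------------------------------------------
# Flowgram TSV
# ---------------------------------------------------------------------------

def read_flowgram_tsv(path: str | Path) -> pd.DataFrame:
    """Read a flowgram TSV, validating header and every row (with line numbers)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header != FLOWGRAM_COLUMNS:
        raise InputError(f"{path}: bad header {header}, expected {FLOWGRAM_COLUMNS}")
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str})
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.nucleotide not in NUCLEOTIDES:
            raise InputError(f"{path}:{i}: bad nucleotide {row.nucleotide!r}")
        if row.voltage < 0:
            raise InputError(f"{path}:{i}: negative voltage {row.voltage}")
        if row.read_position < 1:
            raise InputError(f"{path}:{i}: read_position must be >= 1")
    return df


def write_flowgram_tsv(rows: pd.DataFrame, path: str | Path) -> None:
    """Write flowgram rows with voltages at fixed 6-decimal precision."""
    missing = [c for c in FLOWGRAM_COLUMNS if c not in rows.columns]
    if missing:
        raise InputError(f"flowgram frame missing columns {missing}")
    out = rows[FLOWGRAM_COLUMNS].copy()
    out["voltage"] = out["voltage"].map(lambda v: f"{float(v):.6f}")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Generic TSV artifacts (ground truth, variants, calls, evaluation)
# ---------------------------------------------------------------------------

CALLS_COLUMNS = [
    "read_id", "flow_index", "nucleotide", "zone", "voltage",
    "ref_length", "method", "called_length", "posterior_max", "score_max",
]

_FLOAT_FMT = {"voltage": "{:.6f}", "posterior_max": "{:.6g}", "score_max": "{:.6g}"}


def write_table_tsv(df: pd.DataFrame, path: str | Path,
                    columns: Sequence[str] | None = None) -> None:
    """Deterministic TSV writer: fixed column order, fixed float formatting."""
    out = df.copy() if columns is None else df[list(columns)].copy()
    fmts = dict(_FLOAT_FMT)
    fmts.update({c: "{:.3f}" for c in out.columns if c.endswith("_error_pct")})
    for col, fmt in fmts.items():
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else fmt.format(float(v))
            )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"read_id": str})


def write_calls_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in CALLS_COLUMNS if c in calls.columns]
    write_table_tsv(calls, path, columns=cols)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated run settings for the CLI pipeline."""

    zone_profile: str = "torrent"
    length_range: tuple[int, int] = (2, 6)
    penalty_match: float = 0.0
    penalty_substitution: float = -1.0
    penalty_indel: float = -2.0
    weight: float | None = None
    grid_step: float = 0.02
    folds: int = 5
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.zone_profile not in (*ZONE_PROFILES, "custom"):
            raise FormatError(f"unknown zone profile {self.zone_profile!r}")
        lo, hi = self.length_range
        if not (0 <= lo <= hi):
            raise FormatError(f"bad length_range {self.length_range}")
        if self.weight is not None and not 0.0 <= self.weight <= 1.0:
            raise FormatError(f"weight must be in [0, 1], got {self.weight}")
        if not 0 < self.grid_step <= 1:
            raise FormatError("grid_step must be in (0, 1]")
        if self.folds < 2:
            raise FormatError("folds must be >= 2")

    def zone_scheme(self) -> ZoneScheme:
        return ZONE_PROFILES.get(self.zone_profile, ZONE_PROFILES["torrent"])

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if not isinstance(doc, dict):
            raise FormatError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        if "length_range" in doc:
            doc["length_range"] = tuple(doc["length_range"])
        return cls(**doc)
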