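"""Class-conditional Gaussian voltage model for homopolymer flow signals.

Semiconductor sequencers (Ion Torrent / Ion Proton) read a homopolymer of
length L as a single voltage pulse whose magnitude is ideally L times the
single-incorporation baseline.  In practice the measured voltage follows a
distribution that depends on the nucleotide, the homopolymer length, and the
position of the homopolymer within the read.  This module models that signal
as a Gaussian per (nucleotide, zone, length) cell, where a *zone* is a
position bin along the read (signal drifts toward the 3' end), and couples it
with an empirical length prior P(L).  The fitted table is the trained model
consumed by every caller.

Conventions: voltages are in incorporation units (single base ~ 1.0),
read positions are 1-based, zones are 1-based.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FitError, FormatError, InputError, ModelCoverageError

NUCLEOTIDES = ("A", "C", "G", "T")

PRIORS_SCHEMA_VERSION = 1

#: Voltage threshold (strict) above which a flow is a homopolymer candidate.
CANDIDATE_THRESHOLD = 1.5


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowCandidate:
    """One homopolymer observation: a single flow of one read.

    ``ref_length`` is the length of the homopolymer of the same nucleotide at
    the matching reference locus (supplied by the upstream anchoring step);
    ``true_length`` is the training/evaluation label.
    """

    read_id: str
    flow_index: int
    nucleotide: str
    read_position: int
    voltage: float
    ref_length: int | None = None
    true_length: int | None = None

    def __post_init__(self) -> None:
        if self.nucleotide not in NUCLEOTIDES:
            raise InputError(f"invalid nucleotide {self.nucleotide!r}")
        if self.read_position < 1:
            raise InputError(f"read_position must be >= 1, got {self.read_position}")
        if self.voltage < 0:
            raise InputError(f"voltage must be nonnegative, got {self.voltage}")
        for name in ("ref_length", "true_length"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InputError(f"{name} must be nonnegative, got {v}")


@dataclass(frozen=True)
class ZoneScheme:
    """Uniform position bins along the read; trailing positions clamp to the last zone."""

    zone_width: int
    n_zones: int

    def __post_init__(self) -> None:
        if self.zone_width < 1 or self.n_zones < 1:
            raise InputError("zone_width and n_zones must be positive")

    @property
    def max_position(self) -> int:
        return self.zone_width * self.n_zones


#: Ion Torrent profile: four 75-bp zones covering 300-bp reads.
TORRENT_ZONES = ZoneScheme(zone_width=75, n_zones=4)
#: Ion Proton profile: five 50-bp zones covering 250-bp reads.
PROTON_ZONES = ZoneScheme(zone_width=50, n_zones=5)

ZONE_PROFILES: dict[str, ZoneScheme] = {"torrent": TORRENT_ZONES, "proton": PROTON_ZONES}


@dataclass(frozen=True)
class GaussianParam:
    """Gaussian voltage parameters for one (nucleotide, zone, length) class."""

    mean: float
    stdev: float
    n_obs: int = 0
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.stdev <= 0:
            raise InputError(f"stdev must be positive, got {self.stdev}")
        if self.n_obs < 0:
            raise InputError("n_obs must be nonnegative")


Cell = tuple[str, int, int]  # (nucleotide, zone, length)


@dataclass
class SignalPriorSet:
    """The trained signal model: per-cell Gaussians plus the length prior P(L).

    The voltage marginal P(V) is never stored explicitly; posteriors normalize
    over lengths at fixed (nucleotide, zone), so P(V) is the implied constant
    sum_L P(V | N, Z, L) P(L).
    """

    params: dict[Cell, GaussianParam]
    length_prior: dict[int, float]
    length_range: tuple[int, int]
    zone_scheme: ZoneScheme = TORRENT_ZONES

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lo, hi = self.length_range
        if lo > hi:
            raise FormatError(f"empty length_range {self.length_range}")
        total = sum(self.length_prior.get(L, 0.0) for L in range(lo, hi + 1))
        if abs(total - 1.0) > 1e-9:
            raise FormatError(f"length_prior sums to {total}, expected 1")
        covered = {(n, z) for (n, z, _) in self.params}
        for n, z in covered:
            for L in range(lo, hi + 1):
                if (n, z, L) not in self.params:
                    raise FormatError(f"({n}, Z{z}) missing length {L}")

    @property
    def lengths(self) -> np.ndarray:
        lo, hi = self.length_range
        return np.arange(lo, hi + 1)

    def has_cell_group(self, nucleotide: str, zone: int) -> bool:
        lo = self.length_range[0]
        return (nucleotide, zone, lo) in self.params

    def cell_arrays(self, nucleotide: str, zone: int) -> tuple[np.ndarray, np.ndarray]:
        """Means and stdevs over the length range for one (nucleotide, zone)."""
        if not self.has_cell_group(nucleotide, zone):
            raise ModelCoverageError(
                f"no parameters for nucleotide {nucleotide!r} in zone {zone}"
            )
        cells = [self.params[(nucleotide, zone, L)] for L in self.lengths]
        return (
            np.array([c.mean for c in cells]),
            np.array([c.stdev for c in cells]),
        )

    def prior_array(self) -> np.ndarray:
        return np.array([self.length_prior[int(L)] for L in self.lengths])

    def __eq__(self, other: object) -> bool:  # field-for-field to 1e-12
        if not isinstance(other, SignalPriorSet):
            return NotImplemented
        if self.length_range != other.length_range or self.zone_scheme != other.zone_scheme:
            return False
        if set(self.params) != set(other.params):
            return False
        for key, a in self.params.items():
            b = other.params[key]
            if (
                abs(a.mean - b.mean) > 1e-12
                or abs(a.stdev - b.stdev) > 1e-12
                or a.n_obs != b.n_obs
                or a.imputed != b.imputed
            ):
                return False
        if set(self.length_prior) != set(other.length_prior):
            return False
        return all(
            abs(self.length_prior[L] - other.length_prior[L]) <= 1e-12
            for L in self.length_prior
        )


# ---------------------------------------------------------------------------
# Zone assignment and candidate detection
# ---------------------------------------------------------------------------

def assign_zone(read_position: int, scheme: ZoneScheme = TORRENT_ZONES) -> int:
    """Map a 1-based read position to its 1-based zone index.

    Positions past the last zone boundary clamp to the last zone.
    """
    if read_position < 1:
        raise InputError(f"read_position must be >= 1, got {read_position}")
    return min(math.ceil(read_position / scheme.zone_width), scheme.n_zones)


FLOWGRAM_COLUMNS = ["read_id", "flow_index", "nucleotide", "read_position", "voltage"]


def detect_candidates(
    rows: pd.DataFrame | Iterable[Mapping],
    threshold: float = CANDIDATE_THRESHOLD,
    scheme: ZoneScheme = TORRENT_ZONES,
) -> list[FlowCandidate]:
    """Select the flows whose voltage strictly exceeds ``threshold``.

    A single incorporation reads near 1.0, so flows above 1.5 units are the
    homopolymer candidates (length >= 2); length-0/1 flows are excluded by
    construction.  Zones are assigned on the way out.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows))
    if rows.empty:
        return []
    missing = [c for c in ("nucleotide", "read_position", "voltage") if c not in rows.columns]
    if missing:
        raise InputError(f"flowgram rows missing columns: {missing}")
    out: list[FlowCandidate] = []
    for idx, row in enumerate(rows.itertuples(index=False)):
        try:
            voltage = float(row.voltage)
            if voltage <= threshold:
                continue
            out.append(
                FlowCandidate(
                    read_id=str(getattr(row, "read_id", f"row{idx}")),
                    flow_index=int(getattr(row, "flow_index", idx)),
                    nucleotide=str(row.nucleotide),
                    read_position=int(row.read_position),
                    voltage=voltage,
                    ref_length=_opt_int(getattr(row, "ref_length", None)),
                    true_length=_opt_int(getattr(row, "true_length", None)),
                )
            )
        except (TypeError, ValueError, InputError) as exc:
            raise InputError(f"malformed flowgram row {idx}: {exc}") from exc
    return out


def _opt_int(v) -> int | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return int(v)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def candidates_to_frame(candidates: Iterable[FlowCandidate], scheme: ZoneScheme) -> pd.DataFrame:
    rows = [
        {
            "read_id": c.read_id,
            "flow_index": c.flow_index,
            "nucleotide": c.nucleotide,
            "read_position": c.read_position,
            "zone": assign_zone(c.read_position, scheme),
            "voltage": c.voltage,
            "ref_length": c.ref_length,
            "true_length": c.true_length,
        }
        for c in candidates
    ]
    return pd.DataFrame(rows)


def fit_priors(
    candidates: pd.DataFrame | Iterable[FlowCandidate],
    scheme: ZoneScheme = TORRENT_ZONES,
    length_range: tuple[int, int] = (2, 6),
) -> SignalPriorSet:
    """Fit per-cell Gaussians and the empirical length prior from labeled flows.

    Each (nucleotide, zone, length) cell with >= 2 observations gets the
    sample mean and the n-1 sample standard deviation.  Sparse cells (< 2
    observations) are imputed — mean from a per-base slope fitted across the
    populated cells of the same (nucleotide, zone), stdev from the nearest
    populated cell — and flagged.  The length prior is the empirical
    frequency of ``true_length`` over all candidates.

    Accepts either ``FlowCandidate`` objects or a DataFrame with columns
    nucleotide, voltage, true_length and either zone or read_position.
    """
    if isinstance(candidates, pd.DataFrame):
        df = candidates.copy()
        if "zone" not in df.columns:
            df["zone"] = df["read_position"].map(lambda p: assign_zone(int(p), scheme))
    else:
        df = candidates_to_frame(candidates, scheme)
    if df.empty or df.get("true_length") is None or df["true_length"].isna().all():
        raise FitError("no labeled candidates to fit from")
    df = df.dropna(subset=["true_length"])
    df["true_length"] = df["true_length"].astype(int)

    lo, hi = length_range
    bad = df[(df["true_length"] < lo) | (df["true_length"] > hi)]
    if not bad.empty:
        raise FitError(
            f"{len(bad)} candidates have true_length outside [{lo}, {hi}] "
            f"(e.g. {int(bad['true_length'].iloc[0])})"
        )

    counts = df["true_length"].value_counts()
    n_total = int(counts.sum())
    length_prior = {L: float(counts.get(L, 0)) / n_total for L in range(lo, hi + 1)}

    fitted: dict[Cell, GaussianParam] = {}
    obs_count: dict[Cell, int] = {}
    for (nuc, zone, L), grp in df.groupby(["nucleotide", "zone", "true_length"]):
        key = (str(nuc), int(zone), int(L))
        obs_count[key] = len(grp)
        if len(grp) >= 2:
            sd = float(grp["voltage"].std(ddof=1))
            if sd <= 0:  # degenerate constant cell: keep a tiny positive width
                sd = 1e-6
            fitted[key] = GaussianParam(
                mean=float(grp["voltage"].mean()), stdev=sd, n_obs=len(grp)
            )

    if not fitted:
        raise FitError("no (nucleotide, zone, length) cell has >= 2 observations")

    nucs = sorted(df["nucleotide"].unique())
    zones = range(1, scheme.n_zones + 1)
    params = impute_missing_cells(fitted, obs_count, nucs, zones, length_range)
    return SignalPriorSet(
        params=params,
        length_prior=length_prior,
        length_range=length_range,
        zone_scheme=scheme,
    )


def _slope_through_origin(cells: Mapping[Cell, GaussianParam]) -> float:
    """Per-base voltage slope: least squares of mean vs length through the origin."""
    ls = np.array([L for (_, _, L) in cells])
    ms = np.array([p.mean for p in cells.values()])
    return float((ls * ms).sum() / (ls * ls).sum())


def impute_missing_cells(
    fitted: Mapping[Cell, GaussianParam],
    obs_count: Mapping[Cell, int],
    nucleotides: Iterable[str],
    zones: Iterable[int],
    length_range: tuple[int, int],
) -> dict[Cell, GaussianParam]:
    """Fill every (nucleotide, zone, length) cell, flagging non-fitted ones.

    Imputation rule: mean = L x per-base slope fitted across that
    (nucleotide, zone)'s populated cells; stdev copied from the nearest
    populated cell (smallest |delta L|, ties toward the shorter length).  A
    (nucleotide, zone) with no populated cell borrows the populated cells of
    the nearest zone for the same nucleotide, then of any nucleotide.
    """
    lo, hi = length_range
    out: dict[Cell, GaussianParam] = dict(fitted)
    for nuc in nucleotides:
        for zone in zones:
            donors = {k: v for k, v in fitted.items() if k[0] == nuc and k[1] == zone}
            if not donors:
                same_nuc = [k for k in fitted if k[0] == nuc]
                if same_nuc:
                    nearest_zone = min({k[1] for k in same_nuc}, key=lambda z: (abs(z - zone), z))
                    donors = {
                        k: v for k, v in fitted.items() if k[0] == nuc and k[1] == nearest_zone
                    }
                else:
                    donors = dict(fitted)
            slope = _slope_through_origin(donors)
            donor_lengths = sorted({k[2] for k in donors})
            for L in range(lo, hi + 1):
                key = (nuc, zone, L)
                if key in out:
                    continue
                nearest_L = min(donor_lengths, key=lambda d: (abs(d - L), d))
                donor = next(v for k, v in donors.items() if k[2] == nearest_L)
                out[key] = GaussianParam(
                    mean=L * slope,
                    stdev=donor.stdev,
                    n_obs=obs_count.get(key, 0),
                    imputed=True,
                )
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_priors(priors: SignalPriorSet, path: str | Path,
                provenance: str | None = None) -> None:
    """Serialize a prior set to the documented JSON schema."""
    doc = {
        "schema_version": PRIORS_SCHEMA_VERSION,
        **({"provenance": provenance} if provenance else {}),
        "zone_scheme": {
            "zone_width": priors.zone_scheme.zone_width,
            "n_zones": priors.zone_scheme.n_zones,
        },
        "length_range": list(priors.length_range),
        "cells": [
            {
                "nucleotide": n,
                "zone": z,
                "length": L,
                "mean": p.mean,
                "stdev": p.stdev,
                "n_obs": p.n_obs,
                "imputed": p.imputed,
            }
            for (n, z, L), p in sorted(priors.params.items())
        ],
        "length_prior": {str(L): p for L, p in sorted(priors.length_prior.items())},
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def load_priors(path: str | Path) -> SignalPriorSet:
    """Load a prior set, validating schema version and required fields."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {path}") from exc
    return _priors_from_doc(doc, source=str(path))


def _priors_from_doc(doc: dict, source: str = "<memory>") -> SignalPriorSet:
    version = doc.get("schema_version")
    if version != PRIORS_SCHEMA_VERSION:
        raise FormatError(
            f"{source}: schema_version {version!r}, expected {PRIORS_SCHEMA_VERSION}"
        )
    for field_name in ("zone_scheme", "length_range", "cells", "length_prior"):
        if field_name not in doc:
            raise FormatError(f"{source}: missing field {field_name!r}")
    scheme = ZoneScheme(**doc["zone_scheme"])
    params = {
        (c["nucleotide"], int(c["zone"]), int(c["length"])): GaussianParam(
            mean=float(c["mean"]),
            stdev=float(c["stdev"]),
            n_obs=int(c["n_obs"]),
            imputed=bool(c["imputed"]),
        )
        for c in doc["cells"]
    }
    length_prior = {int(L): float(p) for L, p in doc["length_prior"].items()}
    return SignalPriorSet(
        params=params,
        length_prior=length_prior,
        length_range=tuple(doc["length_range"]),
        zone_scheme=scheme,
    )


# ---------------------------------------------------------------------------
# Default (built-in) parameter table
# ---------------------------------------------------------------------------

# Printed anchors, Ion Torrent run, reconstructed from published values:
#   A/Z1 lengths 2-6: means 1.85, 2.78, 3.68, 4.64, 5.57; stdev 0.14 -> 0.38
#   (linear in L).  C/Z1/L4: 3.74 +/- 0.30; G,T/Z1/L4: 3.68 +/- 0.24.
#   A/L4 per zone Z1-Z4: 3.68, 3.57, 3.54, 3.57 (stdev taken from Z1).
_A_Z1_MEANS = {2: 1.85, 3: 2.78, 4: 3.68, 5: 4.64, 6: 5.57}
_A_Z1_STDEVS = {L: 0.14 + (0.38 - 0.14) * (L - 2) / 4 for L in range(2, 7)}
_A_L4_ZONE_MEANS = {1: 3.68, 2: 3.57, 3: 3.54, 4: 3.57}

#: Geometric-decay default length prior over the calling range (ratio 0.5).
DEFAULT_LENGTH_PRIOR = {
    L: (0.5 ** (L - 2)) / sum(0.5 ** (k - 2) for k in range(2, 7)) for L in range(2, 7)
}


def build_default_priors(scheme: ZoneScheme = TORRENT_ZONES) -> SignalPriorSet:
    """Reconstruct the default parameter table from the published anchors.

    Anchors cover A/Z1 at all lengths, every nucleotide at Z1/L=4, and A/L=4
    across zones; all remaining cells are filled by the standard imputation
    rule and flagged.
    """
    anchors: dict[Cell, GaussianParam] = {}
    for L in range(2, 7):
        anchors[("A", 1, L)] = GaussianParam(_A_Z1_MEANS[L], _A_Z1_STDEVS[L])
    anchors[("C", 1, 4)] = GaussianParam(3.74, 0.30)
    anchors[("G", 1, 4)] = GaussianParam(3.68, 0.24)
    anchors[("T", 1, 4)] = GaussianParam(3.68, 0.24)
    for zone in range(2, scheme.n_zones + 1):
        mean = _A_L4_ZONE_MEANS.get(zone, _A_L4_ZONE_MEANS[max(_A_L4_ZONE_MEANS)])
        anchors[("A", zone, 4)] = GaussianParam(mean, _A_Z1_STDEVS[4])
    params = impute_missing_cells(
        anchors, {}, NUCLEOTIDES, range(1, scheme.n_zones + 1), (2, 6)
    )
    return SignalPriorSet(
        params=params,
        length_prior=dict(DEFAULT_LENGTH_PRIOR),
        length_range=(2, 6),
        zone_scheme=scheme,
    )


def default_priors() -> SignalPriorSet:
    """Load the shipped default table (reconstructed from printed values)."""
    with resources.files("flowcall.data").joinpath("default_priors.json").open() as fh:
        return _priors_from_doc(json.load(fh), source="flowcall/data/default_priors.json")


def extend_priors(priors: SignalPriorSet, length_range: tuple[int, int]) -> SignalPriorSet:
    """Widen a prior set's length range, imputing the new cells.

    Length 1 (the single-incorporation baseline) anchors at mean 1.0 with the
    narrowest fitted stdev; other new lengths follow the slope rule.  The
    length prior is re-normalized over the widened range with zero mass on new
    lengths (they are not calling candidates).
    """
    lo, hi = length_range
    fitted = {k: v for k, v in priors.params.items() if not v.imputed}
    nucs = sorted({k[0] for k in priors.params})
    zones = sorted({k[1] for k in priors.params})
    params = impute_missing_cells(fitted, {}, nucs, zones, length_range)
    for k, v in priors.params.items():
        params[k] = v  # keep existing (incl. previously imputed) cells verbatim
    if lo <= 1:
        narrow = min(
            min(p.stdev for p in priors.params.values()), 0.14
        )  # single incorporations are at least as tight as the tightest homopolymer
        for nuc in nucs:
            for zone in zones:
                params[(nuc, zone, 1)] = GaussianParam(1.0, narrow, imputed=True)
    prior = {L: priors.length_prior.get(L, 0.0) for L in range(lo, hi + 1)}
    total = sum(prior.values())
    prior = {L: p / total for L, p in prior.items()}
    return SignalPriorSet(
        params=params, length_prior=prior, length_range=length_range,
        zone_scheme=priors.zone_scheme,
    )
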