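"""Scoring callers against ground truth.

An identification error is a per-homopolymer event: the called length differs
from the true length.  Reports are stratified by (nucleotide, position zone),
mirroring the usual per-stratum accounting for flow-signal callers, with
error percentages to three decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .callers import (
    IntegratedConfig,
    log_posterior_matrix,
    optimize_weight,
    penalty_matrix,
    _argmax_matrix_with_ties,
)
from .errors import ConsistencyError, InputError, JoinError
from .priors import SignalPriorSet

JOIN_KEYS = ["read_id", "flow_index"]


@dataclass
class ErrorTableRow:
    """One (nucleotide, zone) stratum of the evaluation table."""

    nucleotide: str
    zone: int
    count: int
    error_percent: dict[str, float] = field(default_factory=dict)  # method -> %
    best_weight: float | None = None


def _join(calls: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    for col in JOIN_KEYS + ["called_length"]:
        if col not in calls.columns:
            raise InputError(f"calls frame missing column {col!r}")
    for col in JOIN_KEYS + ["true_length"]:
        if col not in truth.columns:
            raise InputError(f"truth frame missing column {col!r}")
    t = truth[JOIN_KEYS + ["true_length"] + [c for c in ("nucleotide", "zone") if c in truth.columns]]
    if t.duplicated(JOIN_KEYS).any():
        dupes = t[t.duplicated(JOIN_KEYS)][JOIN_KEYS].head(5).to_records(index=False).tolist()
        raise JoinError(f"duplicate ground-truth keys, e.g. {dupes}")
    # truth may cover every flow; calls cover candidates only, so join left.
    merged = calls.merge(t, on=JOIN_KEYS, how="left", indicator=True,
                         suffixes=("", "_truth"))
    bad = merged[merged["_merge"] != "both"]
    if not bad.empty:
        ids = bad[JOIN_KEYS].head(5).to_records(index=False).tolist()
        raise JoinError(f"{len(bad)} calls without a ground-truth record, e.g. {ids}")
    if "true_length_truth" in merged.columns:
        merged["true_length"] = merged["true_length_truth"]
    return merged.drop(columns=["_merge"])


def evaluate_calls(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    weights: Mapping[tuple[str, int], float] | None = None,
) -> tuple[list[ErrorTableRow], dict[str, float]]:
    """Per-(nucleotide, zone) and overall identification error rates.

    ``calls`` may mix methods (column ``method``); every call must join to
    exactly one ground-truth record on (read_id, flow_index).  Returns the
    stratified rows and the overall error percent per method, both rounded
    to three decimals.  ``weights`` optionally annotates rows with the
    per-stratum integrated weight.
    """
    merged = _join(calls, truth)
    merged["error"] = merged["called_length"].astype(int) != merged["true_length"].astype(int)
    if "method" not in merged.columns:
        merged["method"] = "calls"

    rows: dict[tuple[str, int], ErrorTableRow] = {}
    for (nuc, zone, method), grp in merged.groupby(["nucleotide", "zone", "method"]):
        key = (str(nuc), int(zone))
        row = rows.setdefault(
            key,
            ErrorTableRow(nucleotide=key[0], zone=key[1], count=0,
                          best_weight=(weights or {}).get(key)),
        )
        row.count = max(row.count, len(grp))
        row.error_percent[str(method)] = round(100.0 * grp["error"].mean(), 3)
    overall = {
        str(method): round(100.0 * grp["error"].mean(), 3)
        for method, grp in merged.groupby("method")
    }
    ordered = sorted(rows.values(), key=lambda r: (r.nucleotide, r.zone))
    return ordered, overall


def error_table_frame(rows: Sequence[ErrorTableRow]) -> pd.DataFrame:
    """Fixed-column report: No, Nt, Pos, Count, per-method error %, Weight."""
    methods: list[str] = []
    for r in rows:
        for m in r.error_percent:
            if m not in methods:
                methods.append(m)
    recs = []
    for i, r in enumerate(rows, start=1):
        rec = {"No": i, "Nt": r.nucleotide, "Pos": f"Z{r.zone}", "Count": r.count}
        for m in methods:
            rec[f"{m}_error_pct"] = r.error_percent.get(m, np.nan)
        rec["Weight"] = r.best_weight if r.best_weight is not None else np.nan
        recs.append(rec)
    return pd.DataFrame(recs)


def weight_sweep_report(
    cands: pd.DataFrame,
    priors: SignalPriorSet,
    grid: Sequence[float] | None = None,
    folds: int = 5,
    seed: int = 0,
    config: IntegratedConfig = IntegratedConfig(),
) -> tuple[pd.DataFrame, float]:
    """Descriptive weight sweep: total in-sample errors per grid value.

    Unlike :func:`optimize_weight` (cross-validated selection) this scores
    every grid value on the full candidate set — the shape of the error-vs-W
    curve — and returns it with the CV-selected best weight alongside, so the
    in-sample and held-out views can be compared.
    """
    best, _ = optimize_weight(cands, priors, grid=grid, folds=folds, seed=seed, config=config)
    grid_arr = (
        np.round(np.arange(0.0, 1.0 + 1e-9, 0.02), 2) if grid is None
        else np.asarray(sorted(grid), dtype=float)
    )
    cands = cands.reset_index(drop=True)
    logpost = log_posterior_matrix(cands, priors)
    post = np.exp(logpost)
    pen = penalty_matrix(cands["ref_length"].to_numpy(dtype=int), priors.lengths,
                         config.penalties)
    floored = np.maximum(logpost, np.log(config.log_floor))
    truth = cands["true_length"].to_numpy(dtype=int)
    counts = []
    for w in grid_arr:
        scores = w * floored + (1.0 - w) * pen
        called = _argmax_matrix_with_ties(scores, post, priors.lengths)
        counts.append(int((called != truth).sum()))
    curve = pd.DataFrame({"weight": grid_arr, "error_count": counts})
    return curve, best


# ---------------------------------------------------------------------------
# Read correction
# ---------------------------------------------------------------------------

def _runs_of(seq: str) -> list[tuple[str, int]]:
    runs: list[tuple[str, int]] = []
    for ch in seq:
        if runs and runs[-1][0] == ch:
            runs[-1] = (ch, runs[-1][1] + 1)
        else:
            runs.append((ch, 1))
    return runs


def correct_reads(
    reads: Mapping[str, str] | Iterable[tuple[str, str]],
    calls: pd.DataFrame,
) -> dict[str, str]:
    """Rewrite each called homopolymer run to its called length.

    ``calls`` is indexed by (read_id, flow_index) where flow_index is the
    0-based index of the run within the read (every run is one flow).  Runs
    without a call — including all single-base runs — pass through unchanged.
    """
    reads = dict(reads)
    by_read: dict[str, dict[int, int]] = {}
    for row in calls.itertuples(index=False):
        by_read.setdefault(str(row.read_id), {})[int(row.flow_index)] = int(row.called_length)
    out: dict[str, str] = {}
    for read_id, seq in reads.items():
        runs = _runs_of(seq)
        call_map = by_read.get(read_id, {})
        unknown = [fi for fi in call_map if fi >= len(runs)]
        if unknown:
            raise ConsistencyError(
                f"read {read_id!r} has {len(runs)} runs but calls for flows {unknown}"
            )
        pieces = []
        for fi, (nuc, run_len) in enumerate(runs):
            pieces.append(nuc * call_map.get(fi, run_len))
        out[read_id] = "".join(pieces)
    missing = set(by_read) - set(reads)
    if missing:
        raise ConsistencyError(f"calls reference unknown reads: {sorted(missing)[:5]}")
    return out
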