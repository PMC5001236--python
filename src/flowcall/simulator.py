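"""Synthetic flow-signal data with known ground truth.

Generates the full stack a training/evaluation run needs when matched
real datasets (a semiconductor-sequencing run plus an orthogonal
high-accuracy gold standard of the same individual) are unavailable:

1. a random reference genome with a controlled homopolymer length spectrum,
2. a sample genome carrying homopolymer variants at a configurable rate
   (default 1%, the rough per-nucleotide divergence between two human
   genomes),
3. reads and per-flow voltages drawn from the Gaussian class-conditional
   signal model (one flow per homopolymer run; flow-order phasing,
   carry-forward and droop are deliberately not modeled),
4. ground-truth records tying every flow to its true and reference lengths.

All outputs are deterministic functions of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError
from .priors import (
    NUCLEOTIDES,
    SignalPriorSet,
    TORRENT_ZONES,
    ZoneScheme,
    assign_zone,
    default_priors,
    extend_priors,
)

#: Default homopolymer length spectrum of the *reference*: mostly single
#: bases, with 10% of runs length >= 2 decaying geometrically (ratio 0.5).
DEFAULT_REFERENCE_SPECTRUM: dict[int, float] = {
    1: 0.90,
    **{L: 0.10 * (0.5 ** (L - 2)) / sum(0.5 ** (k - 2) for k in range(2, 7))
       for L in range(2, 7)},
}

#: Candidate-length spectrum (runs >= 2 only), used when sampling labeled
#: candidates directly; geometric decay matching the default length prior.
DEFAULT_CANDIDATE_SPECTRUM: dict[int, float] = {
    L: (0.5 ** (L - 2)) / sum(0.5 ** (k - 2) for k in range(2, 7)) for L in range(2, 7)
}

#: A/T-enriched nucleotide usage for simulated genomes.
DEFAULT_NUC_WEIGHTS: dict[str, float] = {"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3}


@dataclass
class SimConfig:
    """Knobs of the synthetic pipeline (defaults mirror the modeled study design)."""

    seed: int = 0
    n_reads: int = 1000
    read_length: int = 300
    variant_rate: float = 0.01
    indel_variant_fraction: float = 1.0
    homopolymer_length_spectrum: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_SPECTRUM)
    )
    nucleotide_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NUC_WEIGHTS)
    )
    parameter_table: SignalPriorSet | None = None
    zone_scheme: ZoneScheme = TORRENT_ZONES

    def __post_init__(self) -> None:
        if not 0.0 <= self.variant_rate <= 1.0:
            raise InputError("variant_rate must be in [0, 1]")
        if not 0.0 <= self.indel_variant_fraction <= 1.0:
            raise InputError("indel_variant_fraction must be in [0, 1]")
        total = sum(self.homopolymer_length_spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"length spectrum sums to {total}, expected 1")

    def priors(self) -> SignalPriorSet:
        return self.parameter_table if self.parameter_table is not None else default_priors()


GROUND_TRUTH_COLUMNS = [
    "read_id", "flow_index", "locus", "nucleotide", "true_length", "ref_length", "zone",
]


# ---------------------------------------------------------------------------
# Reference and variant simulation
# ---------------------------------------------------------------------------

def _normalize_spectrum(spectrum: Mapping[int, float]) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array(sorted(spectrum), dtype=int)
    probs = np.array([spectrum[int(L)] for L in lengths], dtype=float)
    if lengths.size == 0 or probs.sum() <= 0 or np.all(lengths <= 0):
        raise InputError("degenerate homopolymer length spectrum")
    if np.any(lengths < 1):
        raise InputError("spectrum lengths must be >= 1")
    return lengths, probs / probs.sum()


def simulate_reference(
    seed: int,
    length: int,
    spectrum: Mapping[int, float] | None = None,
    nucleotide_weights: Mapping[str, float] | None = None,
) -> tuple[str, pd.DataFrame]:
    """Simulate a reference sequence as a chain of homopolymer runs.

    Run lengths are drawn i.i.d. from ``spectrum``; each run's nucleotide is
    drawn from ``nucleotide_weights`` restricted to differ from the previous
    run, so adjacent runs never merge.  Returns the sequence and a locus
    table (run_index, start [0-based], nucleotide, length).
    """
    spectrum = DEFAULT_REFERENCE_SPECTRUM if spectrum is None else spectrum
    weights = DEFAULT_NUC_WEIGHTS if nucleotide_weights is None else dict(nucleotide_weights)
    lengths, probs = _normalize_spectrum(spectrum)
    rng = np.random.default_rng(seed)
    nucs = list(NUCLEOTIDES)
    w = np.array([weights.get(n, 0.0) for n in nucs], dtype=float)
    if w.sum() <= 0:
        raise InputError("nucleotide weights must have positive mass")
    w = w / w.sum()

    runs: list[tuple[int, str, int]] = []  # (start, nucleotide, run_length)
    pos = 0
    prev = None
    while pos < length:
        run_len = int(rng.choice(lengths, p=probs))
        run_len = min(run_len, length - pos)
        if prev is None:
            nuc = str(rng.choice(nucs, p=w))
        else:
            mask = np.array([n != prev for n in nucs], dtype=float) * w
            nuc = str(rng.choice(nucs, p=mask / mask.sum()))
        runs.append((pos, nuc, run_len))
        pos += run_len
        prev = nuc
    table = pd.DataFrame(
        {
            "run_index": np.arange(len(runs)),
            "start": [r[0] for r in runs],
            "nucleotide": [r[1] for r in runs],
            "length": [r[2] for r in runs],
        }
    )
    seq = "".join(n * l for _, n, l in runs)
    return seq, table


def inject_variants(
    ref_runs: pd.DataFrame,
    variant_rate: float,
    indel_variant_fraction: float = 1.0,
    seed: int = 0,
) -> tuple[str, pd.DataFrame, pd.DataFrame]:
    """Mutate homopolymer loci (runs of length >= 2) of a reference run table.

    Each homopolymer locus independently becomes a variant with probability
    ``variant_rate``; a variant is a length indel (+/-1 base, equal odds)
    with probability ``indel_variant_fraction`` and otherwise a substitution
    of the run's nucleotide (length preserved, nucleotide changed to one
    differing from both neighbors).  Returns the sample sequence, the sample
    run table (with ref_length / ref_nucleotide / variant_type columns), and
    the variant table.
    """
    if not 0.0 <= variant_rate <= 1.0 or not 0.0 <= indel_variant_fraction <= 1.0:
        raise InputError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(ref_runs)
    nucleotide = ref_runs["nucleotide"].to_numpy()
    ref_len = ref_runs["length"].to_numpy(dtype=int)
    new_len = ref_len.copy()
    new_nuc = nucleotide.copy()
    variant_type = np.full(n, "", dtype=object)

    is_hp = ref_len >= 2
    hit = is_hp & (rng.random(n) < variant_rate)
    for i in np.flatnonzero(hit):
        if rng.random() < indel_variant_fraction:
            delta = 1 if rng.random() < 0.5 else -1
            new_len[i] = ref_len[i] + delta
            variant_type[i] = "ins" if delta > 0 else "del"
        else:
            neighbors = set()
            if i > 0:
                neighbors.add(new_nuc[i - 1])
            if i + 1 < n:
                neighbors.add(nucleotide[i + 1])
            choices = [x for x in NUCLEOTIDES if x != nucleotide[i] and x not in neighbors]
            if not choices:
                continue
            new_nuc[i] = choices[rng.integers(len(choices))]
            variant_type[i] = "sub"

    starts = np.concatenate([[0], np.cumsum(new_len)[:-1]])
    sample_runs = pd.DataFrame(
        {
            "run_index": ref_runs["run_index"].to_numpy(),
            "start": starts,
            "nucleotide": new_nuc,
            "length": new_len,
            "ref_start": ref_runs["start"].to_numpy(),
            "ref_nucleotide": nucleotide,
            "ref_length": ref_len,
            "variant_type": variant_type,
        }
    )
    variants = sample_runs[sample_runs["variant_type"] != ""].reset_index(drop=True)
    seq = "".join(n * l for n, l in zip(new_nuc, new_len))
    return seq, sample_runs, variants


# ---------------------------------------------------------------------------
# Flowgram simulation
# ---------------------------------------------------------------------------

def _emission_table(priors: SignalPriorSet, max_length: int) -> SignalPriorSet:
    lo, hi = priors.length_range
    return extend_priors(priors, (min(lo, 1), max(hi, max_length)))


def _draw_voltage(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Truncated-at-zero Gaussian draw (resample on negative)."""
    v = rng.normal(mean, sd)
    while v < 0:
        v = rng.normal(mean, sd)
    return float(v)


def simulate_flowgrams(
    sample_runs: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Emit per-flow voltages for reads tiled over a sample run table.

    Reads are consecutive windows of whole runs, each holding as many runs as
    fit in ``read_length`` bases; ``n_reads`` reads are produced by cycling
    over the genome.  Every run in a read yields one flow with voltage drawn
    from the Gaussian for its (nucleotide, zone, true length); runs extending
    past the zone coverage clamp to the last zone.  Returns (flowgram rows,
    ground-truth records, read sequences), one flowgram/truth row per flow.
    """
    rng = np.random.default_rng(config.seed)
    priors = config.priors()
    max_len = int(sample_runs["length"].max())
    table = _emission_table(priors, max_len)
    scheme = config.zone_scheme

    nucs = sample_runs["nucleotide"].to_numpy()
    lens = sample_runs["length"].to_numpy(dtype=int)
    ref_lens = sample_runs["ref_length"].to_numpy(dtype=int)
    ref_starts = sample_runs["ref_start"].to_numpy(dtype=int)
    n_runs = len(sample_runs)
    if n_runs == 0:
        raise InputError("empty run table")

    flow_rows = []
    truth_rows = []
    reads: dict[str, str] = {}
    run_cursor = 0
    for r in range(config.n_reads):
        read_id = f"read{r:06d}"
        pos_in_read = 1  # 1-based
        flow_index = 0
        start_cursor = run_cursor
        pieces: list[str] = []
        while pos_in_read <= config.read_length:
            i = run_cursor % n_runs
            if i == 0 and run_cursor > start_cursor:
                break  # wrapped past the genome end; reads never span the wrap
            if lens[i] > config.read_length - pos_in_read + 1 and flow_index > 0:
                break
            zone = assign_zone(pos_in_read, scheme)
            cell = table.params[(str(nucs[i]), zone, int(lens[i]))]
            v = _draw_voltage(rng, cell.mean, cell.stdev)
            flow_rows.append((read_id, flow_index, str(nucs[i]), pos_in_read, round(v, 6)))
            truth_rows.append(
                (read_id, flow_index, int(ref_starts[i]), str(nucs[i]),
                 int(lens[i]), int(ref_lens[i]), zone)
            )
            pieces.append(str(nucs[i]) * int(lens[i]))
            pos_in_read += int(lens[i])
            flow_index += 1
            run_cursor += 1
            if run_cursor - start_cursor >= n_runs:
                break  # genome shorter than a read
        reads[read_id] = "".join(pieces)
    flowgram = pd.DataFrame(
        flow_rows, columns=["read_id", "flow_index", "nucleotide", "read_position", "voltage"]
    )
    truth = pd.DataFrame(truth_rows, columns=GROUND_TRUTH_COLUMNS)
    return flowgram, truth, reads


# ---------------------------------------------------------------------------
# Direct candidate sampling (homopolymer-level, no genome assembly)
# ---------------------------------------------------------------------------

def sample_candidates(
    n: int,
    priors: SignalPriorSet | None = None,
    variant_rate: float = 0.01,
    seed: int = 0,
    spectrum: Mapping[int, float] | None = None,
    nucleotide_weights: Mapping[str, float] | None = None,
    zone_scheme: ZoneScheme = TORRENT_ZONES,
    nucleotide: str | None = None,
    zone: int | None = None,
) -> pd.DataFrame:
    """Draw ``n`` labeled homopolymer candidates directly.

    Each candidate gets a true length from the candidate spectrum, a
    nucleotide and read position (hence zone), a voltage from the Gaussian
    for its (nucleotide, zone, true length), and a reference length equal to
    the true length except at variant loci (rate ``variant_rate``), where
    reference and sample differ by one base.  ``nucleotide``/``zone`` pin
    those strata (e.g. A/Z1-only experiments).

    This is the homopolymer-level shortcut for training and benchmarking
    callers; use the genome pipeline for end-to-end runs.
    """
    if n < 1:
        raise InputError("n must be positive")
    priors = default_priors() if priors is None else priors
    spectrum = DEFAULT_CANDIDATE_SPECTRUM if spectrum is None else spectrum
    weights = DEFAULT_NUC_WEIGHTS if nucleotide_weights is None else dict(nucleotide_weights)
    lengths, probs = _normalize_spectrum(spectrum)
    if np.any(lengths < 2):
        raise InputError("candidate spectrum must cover lengths >= 2 only")
    rng = np.random.default_rng(seed)

    if nucleotide is None:
        nucs_all = list(NUCLEOTIDES)
        w = np.array([weights.get(x, 0.0) for x in nucs_all], dtype=float)
        w = w / w.sum()
        nuc_col = rng.choice(nucs_all, size=n, p=w)
    else:
        nuc_col = np.full(n, nucleotide)

    max_pos = zone_scheme.max_position
    if zone is None:
        positions = rng.integers(1, max_pos + 1, size=n)
    else:
        lo_pos = (zone - 1) * zone_scheme.zone_width + 1
        positions = rng.integers(lo_pos, lo_pos + zone_scheme.zone_width, size=n)
    zones = np.minimum((positions - 1) // zone_scheme.zone_width + 1, zone_scheme.n_zones)

    true_len = rng.choice(lengths, size=n, p=probs).astype(int)
    is_variant = rng.random(n) < variant_rate
    delta = np.where(rng.random(n) < 0.5, 1, -1)
    ref_len = np.where(is_variant, true_len + delta, true_len)
    ref_len = np.maximum(ref_len, 1)  # a reference run is at least one base

    lo, hi = priors.length_range
    means = np.empty(n)
    sds = np.empty(n)
    frame = pd.DataFrame({"nucleotide": nuc_col, "zone": zones, "true_length": true_len})
    for (nuc, z, L), idx in frame.groupby(["nucleotide", "zone", "true_length"]).indices.items():
        cell = priors.params[(str(nuc), int(z), int(L))]
        means[idx] = cell.mean
        sds[idx] = cell.stdev
    volts = rng.normal(means, sds)
    neg = volts < 0
    while neg.any():
        volts[neg] = rng.normal(means[neg], sds[neg])
        neg = volts < 0

    return pd.DataFrame(
        {
            "read_id": [f"cand{i:07d}" for i in range(n)],
            "flow_index": np.zeros(n, dtype=int),
            "nucleotide": nuc_col,
            "read_position": positions,
            "zone": zones,
            "voltage": np.round(volts, 6),
            "ref_length": ref_len.astype(int),
            "true_length": true_len,
        }
    )
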