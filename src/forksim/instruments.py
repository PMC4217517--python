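"""Simulated measurement devices.

Each function turns an :class:`~forksim.engine.EnsembleRecord` into one of
the observables produced by the corresponding wet-lab technique:

- :func:`timing_profile` — per-bin expected replication time (the headline
  output, comparable to Repli-seq timing profiles).
- :func:`flow_sort` — partition S cells by replicated genome fraction, the
  in-silico analog of FACS-sorted Repli-seq fractions, with an S50-style
  derived timing.
- :func:`single_molecule_stats` — eye / hole / eye-to-eye length statistics
  as in DNA combing experiments.
- :func:`initiation_rate` — global initiation rate (events per unreplicated
  bin per sweep) as a function of replicated fraction.
- :func:`nascent_profile` — per-bin initiation-event counts, the analog of
  short-nascent-strand / bubble-seq origin enrichment.
- :func:`indices` — per-epoch S-phase fraction of the population and
  replication-factor engagement fraction.
- :func:`pearson_rmsd` — agreement between a predicted and an observed
  per-bin profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import EnsembleRecord

__all__ = [
    "TimingProfile",
    "FlowSortResult",
    "timing_profile",
    "flow_sort",
    "single_molecule_stats",
    "initiation_rate",
    "nascent_profile",
    "indices",
    "pearson_rmsd",
    "mask_runs",
]


@dataclass
class TimingProfile:
    """Per-bin expected replication time, in sweeps from S entry.

    ``normalized`` is the z-scored, sign-flipped profile (early = high),
    the form comparable to early/late-ratio replication-timing data.
    """

    mean_sweep: np.ndarray
    count: np.ndarray
    binsize: int

    @property
    def normalized(self) -> np.ndarray:
        m = self.mean_sweep
        sd = m.std()
        if sd == 0:
            return np.zeros_like(m)
        return -(m - m.mean()) / sd

    def to_bedgraph(self, path, chrom: str = "chrom",
                    which: str = "mean") -> None:
        """Write the profile as a 4-column bedgraph."""
        values = self.mean_sweep if which == "mean" else self.normalized
        n = values.size
        starts = np.arange(n) * self.binsize
        df = pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": starts + self.binsize,
            "value": values,
        })
        df.to_csv(path, sep="\t", header=False, index=False)


def timing_profile(record: EnsembleRecord) -> TimingProfile:
    """Arithmetic mean replication sweep per bin over observed cycles."""
    if record.n_cycles < 1:
        raise ValueError("no completed cycles recorded")
    count = np.full(record.n_bins, record.n_cycles, dtype=np.int64)
    return TimingProfile(
        mean_sweep=record.timing_sum / record.n_cycles,
        count=count,
        binsize=record.binsize,
    )


@dataclass
class FlowSortResult:
    """Replicated-bin counts per flow-sort fraction and genomic bin."""

    boundaries: np.ndarray       # (k+1,) fraction boundaries
    counts: np.ndarray           # (k, n_bins) cells with bin replicated
    cells_per_interval: np.ndarray   # (k,) sorted (snapshot, cell) pairs
    derived_timing: np.ndarray   # (n_bins,) weighted mean of midpoints

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.boundaries[:-1] + self.boundaries[1:])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in range(self.counts.shape[0]):
            for b in range(self.counts.shape[1]):
                rows.append((self.boundaries[k], self.boundaries[k + 1],
                             b, self.counts[k, b]))
        return pd.DataFrame(
            rows, columns=["frac_lo", "frac_hi", "bin", "count"]
        )


def flow_sort(record: EnsembleRecord, boundaries) -> FlowSortResult:
    """Sort snapshot S cells into replicated-fraction gates.

    Intervals are half-open ``[lo, hi)`` with the last interval closed;
    G cells are never sorted, and S cells outside the gated range are
    discarded.  ``derived_timing[b]`` is the count-weighted mean of interval
    midpoints — an S50-style timing where small values mean early
    replication.
    """
    bnd = np.asarray(boundaries, dtype=float)
    if bnd.ndim != 1 or bnd.size < 2:
        raise ValueError("need at least two boundaries")
    if np.any(np.diff(bnd) <= 0):
        raise ValueError("boundaries must be strictly increasing")
    if bnd[0] < 0 or bnd[-1] > 1:
        raise ValueError("boundaries must lie within [0, 1]")
    k = bnd.size - 1
    counts = np.zeros((k, record.n_bins), dtype=np.int64)
    cells_per = np.zeros(k, dtype=np.int64)
    for snap in record.snapshots:
        for i in np.flatnonzero(snap.in_s):
            f = snap.frac[i]
            if f < bnd[0] or f > bnd[-1]:
                continue
            # right-closed last interval, half-open otherwise
            g = min(np.searchsorted(bnd, f, side="right") - 1, k - 1)
            cells_per[g] += 1
            counts[g] += snap.masks[i]
    with np.errstate(invalid="ignore"):
        totals = counts.sum(axis=0).astype(float)
        mids = 0.5 * (bnd[:-1] + bnd[1:])
        derived = (mids @ counts) / totals
    return FlowSortResult(
        boundaries=bnd, counts=counts,
        cells_per_interval=cells_per, derived_timing=derived,
    )


def mask_runs(mask: np.ndarray) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Maximal runs of a boolean mask as half-open bin ranges.

    Returns ``(eyes, holes)`` where eyes are runs of True (replicated) and
    holes runs of False, each a ``(start, stop)`` pair of bin indices.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return [], []
    change = np.flatnonzero(np.diff(mask)) + 1
    edges = np.concatenate(([0], change, [mask.size]))
    eyes, holes = [], []
    for s, e in zip(edges[:-1], edges[1:]):
        (eyes if mask[s] else holes).append((int(s), int(e)))
    return eyes, holes


def _combing_one_mask(mask: np.ndarray, binsize: int):
    """Eye lengths, hole lengths (bp) and eye-to-eye distances (bp).

    Eye-to-eye is the center-to-center distance between adjacent eyes;
    eyes truncated by the chromosome ends count toward eye lengths but are
    excluded from eye-to-eye (their true centers are censored).
    """
    eyes, holes = mask_runs(mask)
    eye_bp = [(e - s) * binsize for s, e in eyes]
    hole_bp = [(e - s) * binsize for s, e in holes]
    n = mask.size
    interior = [(s, e) for s, e in eyes if s > 0 and e < n]
    centers = [0.5 * (s + e - 1) for s, e in interior]
    e2e_bp = [(c2 - c1) * binsize for c1, c2 in zip(centers, centers[1:])]
    return eye_bp, hole_bp, e2e_bp


def single_molecule_stats(record: EnsembleRecord, time_bins: int = 10) -> pd.DataFrame:
    """DNA-combing style eye/hole/eye-to-eye statistics by time in S.

    Each snapshot S cell contributes its maximal replicated runs (eyes),
    unreplicated runs (holes) and center-to-center distances of adjacent
    interior eyes, all in bp.  Statistics are averaged within ``time_bins``
    equal-width bins of time-in-S (sweeps; multiply by
    :func:`~forksim.engine.sweep_seconds` for seconds).
    """
    if time_bins < 1:
        raise ValueError("time_bins must be >= 1")
    if not record.snapshots:
        raise ValueError("record has no snapshots")
    times, eyes_all, holes_all, e2e_all = [], [], [], []
    for snap in record.snapshots:
        for i in np.flatnonzero(snap.in_s):
            e, h, d = _combing_one_mask(snap.masks[i], record.binsize)
            times.append(snap.time_in_s[i])
            eyes_all.append(e)
            holes_all.append(h)
            e2e_all.append(d)
    if not times:
        raise ValueError("no S-phase cells in any snapshot")
    times = np.asarray(times, dtype=float)
    t_max = times.max() + 1.0
    edges = np.linspace(0.0, t_max, time_bins + 1)
    which = np.minimum(
        np.searchsorted(edges, times, side="right") - 1, time_bins - 1
    )
    rows = []
    for k in range(time_bins):
        sel = np.flatnonzero(which == k)
        eyes = [x for i in sel for x in eyes_all[i]]
        holes = [x for i in sel for x in holes_all[i]]
        e2e = [x for i in sel for x in e2e_all[i]]
        rows.append({
            "t_lo": edges[k],
            "t_hi": edges[k + 1],
            "n_cells": sel.size,
            "mean_eye_bp": np.mean(eyes) if eyes else np.nan,
            "n_eyes": len(eyes),
            "mean_hole_bp": np.mean(holes) if holes else np.nan,
            "n_holes": len(holes),
            "mean_e2e_bp": np.mean(e2e) if e2e else np.nan,
            "n_e2e": len(e2e),
        })
    return pd.DataFrame(rows)


def initiation_rate(record: EnsembleRecord, fraction_bins: int = 10) -> pd.DataFrame:
    """Global initiation rate vs. replicated fraction of the genome.

    Rate = initiation events per unreplicated bin per sweep, within
    equal-width bins of replicated fraction.  Bins with zero exposure have
    an undefined rate, reported as NaN (never as zero).
    """
    if fraction_bins < 1:
        raise ValueError("fraction_bins must be >= 1")
    n = record.n_bins
    fracs = np.arange(n + 1) / n  # discrete fractions r / n_bins
    edges = np.linspace(0.0, 1.0, fraction_bins + 1)
    which = np.minimum(
        np.searchsorted(edges, fracs, side="right") - 1, fraction_bins - 1
    )
    rows = []
    for k in range(fraction_bins):
        sel = which == k
        events = int(record.events_by_count[sel].sum())
        exposure = float(record.exposure_by_count[sel].sum())
        rows.append({
            "frac_lo": edges[k],
            "frac_hi": edges[k + 1],
            "events": events,
            "exposure": exposure,
            "rate": events / exposure if exposure > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def nascent_profile(record: EnsembleRecord) -> np.ndarray:
    """Initiation events per genomic bin across observed cycles.

    The simulated analog of short-nascent-strand / replication-bubble
    enrichment at origins.
    """
    return record.init_counts.copy()


def indices(record: EnsembleRecord) -> pd.DataFrame:
    """Per-snapshot S-phase fraction and fork-engagement fraction.

    Engagement is engaged forks divided by ``nfork`` times the number of
    S cells (0 when no cell is in S).
    """
    if not record.snapshots:
        raise ValueError("record has no snapshots")
    rows = []
    for snap in record.snapshots:
        n_s = int(snap.in_s.sum())
        engaged = int(snap.engaged[snap.in_s].sum())
        rows.append({
            "global_sweep": snap.global_sweep,
            "s_fraction": n_s / record.ncells,
            "engagement": engaged / (record.nfork * n_s) if n_s else 0.0,
        })
    return pd.DataFrame(rows)


def pearson_rmsd(predicted, observed) -> tuple[float, float]:
    """Pearson correlation and RMSD between paired per-bin profiles.

    Pairs with a missing value (NaN) in either vector are deleted; at least
    three complete pairs and nonzero variance in both vectors are required.
    """
    a = np.asarray(predicted, dtype=float)
    b = np.asarray(observed, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("predicted and observed must be equal-length 1-D")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("fewer than 3 complete pairs")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(stats.pearsonr(a, b).statistic)
    rmsd = float(np.sqrt(np.mean((a - b) ** 2)))
    return r, rmsd
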