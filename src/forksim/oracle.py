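"""Independent reference computations for validating the engine.

Two oracles live here, both deliberately written without sharing any code
with :mod:`forksim.engine`:

- :func:`analytic_timing`: the closed-form timing profile for deterministic
  kinetics (fork-progress 1, no release) and point origins — a fork travels
  one bin per sweep, so a bin replicates ``min over origins of |b - o|``
  sweeps after all origins fire.
- :func:`reference_simulate`: a straightforward, clarity-over-speed Monte
  Carlo re-implementation of the sweep rules using plain Python lists,
  restricted to small chromosomes.  Its per-bin mean replication times are
  compared with the engine's within Monte Carlo error.
"""

from __future__ import annotations

import math

import numpy as np

from .landscape import Landscape

__all__ = ["analytic_timing", "reference_simulate", "ReferenceSummary"]

MAX_REF_BINS = 12
MAX_REF_FORKS = 4


def analytic_timing(origins, n_bins: int) -> np.ndarray:
    """Exact replication-sweep offsets for point origins, deterministic forks.

    ``offset[b] = min_o |b - o|``, in sweeps, relative to the sweep at which
    all origins fire.  Valid only for fork-progress 1 and release 0.
    """
    origins = sorted(int(o) for o in origins)
    if not origins:
        raise ValueError("need at least one origin")
    if origins[0] < 0 or origins[-1] >= n_bins:
        raise ValueError("origin out of range")
    b = np.arange(n_bins)
    return np.min(np.abs(b[:, None] - np.asarray(origins)[None, :]), axis=1)


class ReferenceSummary:
    """Per-bin mean/variance of replication sweep from the reference model."""

    def __init__(self, times: np.ndarray):
        self.times = times  # (n_cycles, n_bins)
        self.n_cycles = times.shape[0]
        self.mean = times.mean(axis=0)
        self.var = times.var(axis=0, ddof=1) if self.n_cycles > 1 else np.zeros(times.shape[1])

    @property
    def sem(self) -> np.ndarray:
        return np.sqrt(self.var / self.n_cycles)


def reference_simulate(
    landscape: Landscape,
    n_cycles: int,
    *,
    nfork: int = 2,
    pprogress: float = 1.0,
    prelease: float = 0.0,
    initiation_mode: str = "per_pair",
    seed: int = 12345,
) -> ReferenceSummary:
    """Plain-Python Monte Carlo of S phase, for cross-checking the engine.

    Each cycle starts a fresh cell in S and runs sweeps until the whole
    chromosome is replicated, recording the sweep at which each bin
    replicated.  Sweep order: engaged forks advance (lowest fork first,
    disengaging on boundary or on stepping into replicated DNA), engaged
    forks release, then one initiation attempt per free fork pair (or one
    per cell) at a uniformly random unreplicated bin.

    Restricted to ``n_bins <= 12`` and ``nfork <= 4`` — this implementation
    values transparency over speed.
    """
    n = landscape.n_bins
    if n > MAX_REF_BINS:
        raise ValueError(f"reference simulator limited to {MAX_REF_BINS} bins")
    if nfork > MAX_REF_FORKS:
        raise ValueError(f"reference simulator limited to {MAX_REF_FORKS} forks")
    if nfork < 2:
        raise ValueError("need at least one fork pair")
    if initiation_mode not in ("per_pair", "per_cell"):
        raise ValueError("bad initiation_mode")

    p_init = [float(x) for x in landscape.init_prob]
    p_prog = [float(x) for x in landscape.progress_array(pprogress)]
    p_rel = [float(x) for x in landscape.release_array(prelease)]
    rng = np.random.default_rng(seed)

    all_times = np.empty((n_cycles, n), dtype=float)
    for c in range(n_cycles):
        replicated = [False] * n
        rep_time = [math.nan] * n
        # forks: list of slots, each None (free) or [position, direction]
        forks: list[list[int] | None] = [None] * nfork
        t = 0
        while not all(replicated):
            # advance
            for i in range(nfork):
                f = forks[i]
                if f is None:
                    continue
                if rng.random() >= p_prog[f[0]]:
                    continue
                tgt = f[0] + f[1]
                if tgt < 0 or tgt >= n or replicated[tgt]:
                    forks[i] = None
                else:
                    f[0] = tgt
                    replicated[tgt] = True
                    rep_time[tgt] = t
            # release
            for i in range(nfork):
                f = forks[i]
                if f is not None and rng.random() < p_rel[f[0]]:
                    forks[i] = None
            # initiate
            free = [i for i in range(nfork) if forks[i] is None]
            attempts = len(free) // 2
            if initiation_mode == "per_cell":
                attempts = min(attempts, 1)
            for _ in range(attempts):
                unrep = [b for b in range(n) if not replicated[b]]
                if not unrep:
                    break
                b = unrep[int(rng.integers(len(unrep)))]
                if rng.random() < p_init[b]:
                    replicated[b] = True
                    rep_time[b] = t
                    left, right = free[0], free[1]
                    forks[left] = [b, -1]
                    forks[right] = [b, +1]
                    free = free[2:]
            t += 1
        all_times[c] = rep_time
    return ReferenceSummary(all_times)
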