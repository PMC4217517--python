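"""Discrete-time stochastic simulation of the replication cell cycle.

A population of independent virtual cells replicates a binned chromosome.
Each cell cycles between a resting G phase (duration drawn from a truncated
normal) and a synthesizing S phase.  During S, a fixed pool of ``nfork``
replication forks operates under three rules applied once per sweep:

1. *Advance* — every engaged fork attempts, with the fork-progress
   probability at its current bin, to step one bin in its direction.  A step
   into an already-replicated bin (a collision with another fork's territory)
   or off the chromosome end disengages the fork; otherwise the fork moves
   and marks the target bin replicated.
2. *Release* — every still-engaged fork disengages with the fork-release
   probability at its bin.
3. *Initiate* — for each pair of free forks (or once per cell, see
   ``initiation_mode``), a uniformly random unreplicated bin is drawn and
   fires with the landscape's initiation probability there; on firing the
   bin is marked replicated and two forks engage at it, moving left and
   right.  Replication is therefore bidirectional from every origin.

A sweep is the time in which a fork traverses one bin; with the canonical
50 bp/s fork velocity a sweep of a 500 bp landscape lasts 10 s
(:func:`sweep_seconds`).  When every bin is replicated the cell archives the
cycle and returns to G.  The population starts fully in G and is
desynchronized by a thermalization burn-in before observations begin.

Reproducibility: every cell owns a random stream spawned from the master
seed, so results are bit-identical for a given (config, landscape, seed)
and independent of iteration order or any thread count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import Landscape

__all__ = [
    "FORK_VELOCITY_BP_PER_S",
    "SimulationConfig",
    "CellState",
    "Snapshot",
    "EnsembleRecord",
    "sweep_seconds",
    "cell_sweep",
    "population_sweep",
    "run_simulation",
]

#: Constant fork velocity; one sweep advances a fork exactly one bin.
FORK_VELOCITY_BP_PER_S = 50.0

G_PHASE = "G"
S_PHASE = "S"


def sweep_seconds(binsize: int) -> float:
    """Duration of one sweep in seconds for the given bin width.

    A fork moves one bin per sweep at 50 bp/s, so a sweep lasts
    ``binsize / 50`` seconds (10 s at the standard 500 bp resolution).
    """
    if binsize <= 0:
        raise ValueError("binsize must be positive")
    return binsize / FORK_VELOCITY_BP_PER_S


@dataclass
class SimulationConfig:
    """Run parameters for :func:`run_simulation`.

    Defaults mirror the simulator's canonical command-line defaults.

    Parameters
    ----------
    ncells
        Population size (default 1000).
    nfork
        Replication forks per cell; initiation engages forks in pairs, so at
        least 2 are required (default 50).  A whole-genome sizing rule of
        thumb is one fork per 80 Mb of genome.
    ntherm
        Thermalization sweeps discarded before measuring (default 80000).
    nmeas, stepsize
        Number of measurement epochs and sweeps between them
        (defaults 2000 and 20000).
    pprogress, prelease
        Global fork-progress / fork-release probabilities per sweep
        (defaults 1 and 0); overridden bin-by-bin by landscape columns 3/4.
    g_mean, g_sd
        Mean / standard deviation (sweeps) of the normal G-phase duration,
        truncated at >= 1 sweep.  When ``g_mean`` is None a short pilot run
        estimates the landscape's mean S duration and uses that, with
        ``g_sd = 0.1 * g_mean`` — this yields a well-mixed asynchronous
        population, the G phase's only role.
    initiation_mode
        ``"per_pair"`` (default): one initiation attempt per free fork pair
        per sweep.  ``"per_cell"``: at most one attempt per cell per sweep.
    seed
        Master seed for the per-cell random streams.
    threads
        Accepted for interface compatibility; execution is serial and
        results never depend on it (per-cell streams).
    """

    ncells: int = 1000
    nfork: int = 50
    ntherm: int = 80000
    nmeas: int = 2000
    stepsize: int = 20000
    pprogress: float = 1.0
    prelease: float = 0.0
    g_mean: float | None = None
    g_sd: float | None = None
    initiation_mode: str = "per_pair"
    seed: int = 0
    threads: int = 1

    def validate(self) -> None:
        if self.ncells < 1:
            raise ValueError("ncells must be >= 1")
        if self.nfork < 2:
            raise ValueError("nfork must be >= 2 (forks engage in pairs)")
        if self.ntherm < 0 or self.nmeas < 1 or self.stepsize < 1:
            raise ValueError("ntherm >= 0, nmeas >= 1, stepsize >= 1 required")
        for name in ("pprogress", "prelease"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.g_mean is not None and self.g_mean <= 0:
            raise ValueError("g_mean must be positive")
        if self.g_sd is not None and self.g_sd < 0:
            raise ValueError("g_sd must be >= 0")
        if self.initiation_mode not in ("per_pair", "per_cell"):
            raise ValueError("initiation_mode must be 'per_pair' or 'per_cell'")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


class CellState:
    """One virtual cell: phase, replication mask, and its fork pool.

    ``phase_clock`` counts sweeps remaining in G, or sweeps elapsed in S.
    ``rep_sweep[b]`` holds the sweep (relative to S entry) at which bin ``b``
    was replicated, and is -1 while unreplicated.  ``init_log`` lists
    ``(sweep_in_s, bin)`` initiation events of the current cycle.
    """

    __slots__ = (
        "n_bins", "nfork", "phase", "phase_clock", "mask", "rep_sweep",
        "fork_engaged", "fork_pos", "fork_dir", "init_log", "entry_sweep",
        "_unrep_ids", "_unrep_pos", "n_unrep",
    )

    def __init__(self, n_bins: int, nfork: int, g_duration: int = 1):
        if g_duration < 1:
            raise ValueError("g_duration must be >= 1")
        self.n_bins = n_bins
        self.nfork = nfork
        self.phase = G_PHASE
        self.phase_clock = int(g_duration)
        self.mask = np.zeros(n_bins, dtype=bool)
        self.rep_sweep = np.full(n_bins, -1, dtype=np.int64)
        self.fork_engaged = np.zeros(nfork, dtype=bool)
        self.fork_pos = np.zeros(nfork, dtype=np.int64)
        self.fork_dir = np.zeros(nfork, dtype=np.int64)
        self.init_log: list[tuple[int, int]] = []
        self.entry_sweep = -1  # global sweep at which current S phase began
        # swap-remove structure for O(1) uniform sampling of unreplicated bins
        self._unrep_ids = np.arange(n_bins, dtype=np.int64)
        self._unrep_pos = np.arange(n_bins, dtype=np.int64)
        self.n_unrep = n_bins

    # -- phase transitions -------------------------------------------------

    def enter_s(self, global_sweep: int = 0) -> None:
        """Reset replication state and begin an S phase."""
        self.phase = S_PHASE
        self.phase_clock = 0
        self.entry_sweep = global_sweep
        self.mask[:] = False
        self.rep_sweep[:] = -1
        self.fork_engaged[:] = False
        self.init_log = []
        self._unrep_ids = np.arange(self.n_bins, dtype=np.int64)
        self._unrep_pos = np.arange(self.n_bins, dtype=np.int64)
        self.n_unrep = self.n_bins

    def enter_g(self, g_duration: int) -> None:
        self.phase = G_PHASE
        self.phase_clock = max(1, int(g_duration))
        self.fork_engaged[:] = False

    # -- replication bookkeeping -------------------------------------------

    def mark_replicated(self, b: int, sweep: int) -> None:
        """Mark bin ``b`` replicated at sweep ``sweep`` (in-S time)."""
        if self.mask[b]:
            raise RuntimeError(f"bin {b} replicated twice")
        self.mask[b] = True
        self.rep_sweep[b] = sweep
        # swap-remove b from the unreplicated pool
        j = self._unrep_pos[b]
        last = self.n_unrep - 1
        moved = self._unrep_ids[last]
        self._unrep_ids[j] = moved
        self._unrep_pos[moved] = j
        self.n_unrep = last

    def sample_unreplicated(self, rng: np.random.Generator) -> int:
        """Uniformly random unreplicated bin (requires n_unrep > 0)."""
        return int(self._unrep_ids[rng.integers(self.n_unrep)])

    def fire_origin(self, b: int, sweep: int) -> None:
        """Fire an origin at bin ``b``: mark it replicated and engage a
        bidirectional fork pair there.  Requires two free forks."""
        free = np.flatnonzero(~self.fork_engaged)
        if free.size < 2:
            raise RuntimeError("initiation requires two free forks")
        self.mark_replicated(b, sweep)
        self.init_log.append((sweep, b))
        for idx, direction in zip(free[:2], (-1, +1)):
            self.fork_engaged[idx] = True
            self.fork_pos[idx] = b
            self.fork_dir[idx] = direction

    @property
    def replicated_count(self) -> int:
        return self.n_bins - self.n_unrep

    @property
    def replicated_fraction(self) -> float:
        return self.replicated_count / self.n_bins

    @property
    def n_engaged(self) -> int:
        return int(self.fork_engaged.sum())


@dataclass
class Snapshot:
    """Population state captured at one measurement epoch."""

    global_sweep: int
    in_s: np.ndarray          # (ncells,) bool
    frac: np.ndarray          # (ncells,) replicated fraction (0 for G cells)
    engaged: np.ndarray       # (ncells,) engaged-fork count
    time_in_s: np.ndarray     # (ncells,) sweeps elapsed in S (-1 for G cells)
    masks: np.ndarray         # (ncells, n_bins) bool replication masks


@dataclass
class EnsembleRecord:
    """Accumulated observations of a simulated population.

    Per-bin replication-time statistics are summed over every S phase that
    began after thermalization; ``snapshots`` capture the population at each
    measurement epoch; initiation events and exposure (unreplicated-bin
    sweeps) are keyed by the cell's replicated-bin count at the sweep start,
    which makes initiation-rate estimates exact on the discrete fraction
    grid ``r / n_bins``.
    """

    n_bins: int
    binsize: int
    ncells: int
    nfork: int
    timing_sum: np.ndarray      # per-bin sum of rep_sweep over cycles
    timing_sumsq: np.ndarray    # per-bin sum of rep_sweep**2
    n_cycles: int               # completed, observed S phases
    init_counts: np.ndarray     # per-bin initiation events (observed cycles)
    events_by_count: np.ndarray     # (n_bins+1,) initiations keyed by r
    exposure_by_count: np.ndarray   # (n_bins+1,) unreplicated-bin sweeps
    s_durations: list[int] = field(default_factory=list)
    snapshots: list[Snapshot] = field(default_factory=list)

    @property
    def fork_velocity_bp_per_s(self) -> float:
        return FORK_VELOCITY_BP_PER_S

    @property
    def seconds_per_sweep(self) -> float:
        return sweep_seconds(self.binsize)


class _Recorder:
    """Accumulates engine events into an EnsembleRecord."""

    def __init__(self, n_bins: int, binsize: int, ncells: int, nfork: int):
        self.record = EnsembleRecord(
            n_bins=n_bins,
            binsize=binsize,
            ncells=ncells,
            nfork=nfork,
            timing_sum=np.zeros(n_bins, dtype=np.float64),
            timing_sumsq=np.zeros(n_bins, dtype=np.float64),
            n_cycles=0,
            init_counts=np.zeros(n_bins, dtype=np.int64),
            events_by_count=np.zeros(n_bins + 1, dtype=np.int64),
            exposure_by_count=np.zeros(n_bins + 1, dtype=np.float64),
        )
        self.observing = False

    def sweep_exposure(self, replicated_count: int, n_unrep: int) -> None:
        if self.observing:
            self.record.exposure_by_count[replicated_count] += n_unrep

    def initiation(self, replicated_count: int) -> None:
        if self.observing:
            self.record.events_by_count[replicated_count] += 1

    def cycle_complete(self, cell: CellState, ntherm: int) -> None:
        if cell.entry_sweep < ntherm:
            return  # cycle began during burn-in
        rec = self.record
        rs = cell.rep_sweep.astype(np.float64)
        rec.timing_sum += rs
        rec.timing_sumsq += rs * rs
        rec.n_cycles += 1
        for _, b in cell.init_log:
            rec.init_counts[b] += 1
        rec.s_durations.append(cell.phase_clock)


def _draw_g_duration(rng: np.random.Generator, g_mean: float, g_sd: float) -> int:
    return max(1, int(round(rng.normal(g_mean, g_sd))))


def cell_sweep(
    cell: CellState,
    landscape: Landscape,
    rng: np.random.Generator,
    *,
    pprogress: float = 1.0,
    prelease: float = 0.0,
    initiation_mode: str = "per_pair",
    g_mean: float = 1.0,
    g_sd: float = 0.0,
    recorder: _Recorder | None = None,
    ntherm: int = 0,
) -> CellState:
    """Apply one S-phase sweep to ``cell`` (advance, release, initiate).

    The cell must be in S phase.  If the sweep completes replication the
    cell transitions back to G with a freshly drawn duration.  One uniform
    variate is consumed per probability test regardless of its value, so
    the stream layout does not depend on the landscape.
    """
    if cell.phase != S_PHASE:
        raise RuntimeError("cell_sweep requires a cell in S phase")
    t = cell.phase_clock
    prog = landscape.progress_array(pprogress)
    rel = landscape.release_array(prelease)

    if recorder is not None:
        recorder.sweep_exposure(cell.replicated_count, cell.n_unrep)
    r0 = cell.replicated_count  # fraction key for this sweep's initiations

    # 1. advance engaged forks (pool-index order: the lower-index fork wins
    #    a bin two forks converge on in the same sweep)
    engaged = np.flatnonzero(cell.fork_engaged)
    for i in engaged:
        pos = cell.fork_pos[i]
        if rng.random() >= prog[pos]:
            continue  # no movement attempt this sweep
        target = pos + cell.fork_dir[i]
        if target < 0 or target >= cell.n_bins or cell.mask[target]:
            cell.fork_engaged[i] = False  # boundary or collision
        else:
            cell.fork_pos[i] = target
            cell.mark_replicated(int(target), t)

    # 2. stochastic release of still-engaged forks
    for i in engaged:
        if cell.fork_engaged[i] and rng.random() < rel[cell.fork_pos[i]]:
            cell.fork_engaged[i] = False

    # 3. initiation attempts from the free-fork pool
    n_free = cell.nfork - cell.n_engaged
    n_attempts = n_free // 2
    if initiation_mode == "per_cell":
        n_attempts = min(n_attempts, 1)
    for _ in range(n_attempts):
        if cell.n_unrep == 0:
            break
        b = cell.sample_unreplicated(rng)
        if rng.random() < landscape.init_prob[b]:
            cell.fire_origin(b, t)
            if recorder is not None:
                recorder.initiation(r0)

    # 4. completion check
    cell.phase_clock = t + 1
    if cell.n_unrep == 0:
        if recorder is not None:
            recorder.cycle_complete(cell, ntherm)
        cell.enter_g(_draw_g_duration(rng, g_mean, g_sd))
    return cell


def population_sweep(
    cells: list[CellState],
    landscape: Landscape,
    rngs,
    *,
    global_sweep: int = 0,
    recorder: _Recorder | None = None,
    **sweep_kwargs,
) -> list[CellState]:
    """Advance every cell by one sweep; cells are fully independent.

    G cells tick down their clock and, on reaching zero, enter S at the
    start of the sweep — a fresh S entrant may therefore initiate in this
    same sweep.
    """
    for cell, rng in zip(cells, rngs):
        if cell.phase == G_PHASE:
            cell.phase_clock -= 1
            if cell.phase_clock <= 0:
                cell.enter_s(global_sweep)
        if cell.phase == S_PHASE:
            cell_sweep(cell, landscape, rng, recorder=recorder, **sweep_kwargs)
    return cells


def estimate_s_duration(
    landscape: Landscape,
    config: SimulationConfig,
    n_pilot: int = 5,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean S-phase duration (sweeps) from a short single-cell pilot run."""
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(1)[0]
        )
    cell = CellState(landscape.n_bins, config.nfork)
    durations = []
    for _ in range(n_pilot):
        cell.enter_s(0)
        sweeps = 0
        while cell.phase == S_PHASE:
            cell_sweep(
                cell, landscape, rng,
                pprogress=config.pprogress, prelease=config.prelease,
                initiation_mode=config.initiation_mode,
            )
            sweeps += 1
        durations.append(sweeps)
    return float(np.mean(durations))


def run_simulation(config: SimulationConfig, landscape: Landscape) -> EnsembleRecord:
    """Simulate the full population and return its observation record.

    All cells start in G with independently drawn durations; ``ntherm``
    sweeps desynchronize the population before ``nmeas`` measurement epochs
    of ``stepsize`` sweeps each.  Per-bin replication times accumulate from
    every S phase that began after thermalization; a population snapshot is
    taken at the end of each epoch.
    """
    config.validate()
    if not np.any(landscape.init_prob > 0):
        raise ValueError("landscape has no positive initiation probability")

    master = np.random.SeedSequence(config.seed)
    pilot_ss, *cell_ss = master.spawn(config.ncells + 1)

    g_mean = config.g_mean
    g_sd = config.g_sd
    if g_mean is None:
        g_mean = estimate_s_duration(
            landscape, config, rng=np.random.default_rng(pilot_ss)
        )
    if g_sd is None:
        g_sd = 0.1 * g_mean

    rngs = [np.random.default_rng(ss) for ss in cell_ss]
    cells = []
    for rng in rngs:
        cells.append(
            CellState(
                landscape.n_bins, config.nfork,
                g_duration=_draw_g_duration(rng, g_mean, g_sd),
            )
        )

    recorder = _Recorder(
        landscape.n_bins, landscape.binsize, config.ncells, config.nfork
    )
    sweep_kwargs = dict(
        pprogress=config.pprogress,
        prelease=config.prelease,
        initiation_mode=config.initiation_mode,
        g_mean=g_mean,
        g_sd=g_sd,
        ntherm=config.ntherm,
    )

    total = config.ntherm + config.nmeas * config.stepsize
    for sweep in range(total):
        recorder.observing = sweep >= config.ntherm
        population_sweep(
            cells, landscape, rngs,
            global_sweep=sweep, recorder=recorder, **sweep_kwargs,
        )
        done = sweep + 1
        if done > config.ntherm and (done - config.ntherm) % config.stepsize == 0:
            recorder.record.snapshots.append(_take_snapshot(cells, sweep))
    return recorder.record


def _take_snapshot(cells: list[CellState], global_sweep: int) -> Snapshot:
    ncells = len(cells)
    n_bins = cells[0].n_bins
    in_s = np.zeros(ncells, dtype=bool)
    frac = np.zeros(ncells)
    engaged = np.zeros(ncells, dtype=np.int64)
    time_in_s = np.full(ncells, -1, dtype=np.int64)
    masks = np.zeros((ncells, n_bins), dtype=bool)
    for i, cell in enumerate(cells):
        if cell.phase == S_PHASE:
            in_s[i] = True
            frac[i] = cell.replicated_fraction
            engaged[i] = cell.n_engaged
            time_in_s[i] = cell.phase_clock
            masks[i] = cell.mask
    return Snapshot(
        global_sweep=global_sweep, in_s=in_s, frac=frac,
        engaged=engaged, time_in_s=time_in_s, masks=masks,
    )
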