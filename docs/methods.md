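# Model and methods

## The replication model

forksim simulates the temporal program of DNA replication in metazoan cells
with a stochastic, essentially parameter-free mechanism.  A chromosome is
discretized into fixed-width bins (500 bp by default).  The only genomic
input is the **initiation probability landscape (IPLS)**: for every bin, the
probability that a replication-initiation attempt there fires.  In practice
the IPLS is derived from an open-chromatin signal (e.g. DNase
hypersensitivity), on the premise that initiation sites are localized by
accessible chromatin and that the precise amplitude at each site matters
little for global timing.

Each virtual cell is independent and alternates between two phases:

- **G (rest)** — a duration drawn from a normal distribution, truncated at
  one sweep.  Its only purpose is to desynchronize the population.
- **S (synthesis)** — the cell owns a pool of `nfork` replication forks
  and applies, once per discrete time step ("sweep"), the rules:

  1. *Advance.*  Every engaged fork attempts, with the fork-progress
     probability of its current bin (global default 1), to step one bin in
     its direction.  Stepping into already-replicated territory (a
     collision) or off a chromosome end disengages the fork; otherwise it
     moves and marks the target bin replicated.
  2. *Release.*  Every still-engaged fork disengages with the fork-release
     probability of its bin (global default 0).
  3. *Initiate.*  For each free pair of forks, one attempt: a uniformly
     random unreplicated bin is drawn and fires with its IPLS probability.
     On firing, the bin is marked replicated and two forks engage there
     with directions −1 and +1 — replication is bidirectional.
  4. When every bin is replicated the cycle is archived and the cell
     returns to G.

A fork traverses exactly one bin per sweep at the model's one technical
constant, the **fork velocity of 50 bp/s**; a sweep therefore lasts
`binsize / 50` seconds (10 s at 500 bp).  The per-bin sweep at which each
bin replicated (relative to S entry) is the raw observable; its mean over
many cycles is the replication-timing profile.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `ncells` | 1000 | independent cells in the population |
| `nfork` | 50 | forks per cell (pairs; rule of thumb: one fork per 80 Mb of genome) |
| `ntherm` | 80000 | burn-in sweeps before observation |
| `nmeas` | 2000 | measurement epochs |
| `stepsize` | 20000 | sweeps between epochs |
| `pprogress` | 1 | global fork-progress probability (per-bin column 3 overrides) |
| `prelease` | 0 | global fork-release probability (per-bin column 4 overrides) |
| `g_mean`, `g_sd` | estimated | G-phase duration (sweeps), see below |
| `initiation_mode` | `per_pair` | initiation attempts per sweep (see below) |
| `seed` | 0 | master seed |

These defaults describe production-scale runs of a real chromosome.  The
test suite and the acceptance script use far smaller populations, bin
counts and epoch schedules (stated in each test/case file) — chosen so each
scenario still yields ≥ 10⁴ observed cycles where a stochastic comparison
is made.

## Design choices where the design was open

- **Initiation attempts per sweep.**  Two readings are defensible: one
  attempt per free fork pair, or one attempt per cell.  The default is
  per-pair (firing opportunity scales with available replication factors);
  `initiation_mode="per_cell"` selects the other reading.  Both modes are
  validated against correspondingly configured reference simulations.
- **G-phase duration.**  No canonical values exist.  When unset, `g_mean`
  is estimated as the landscape's mean S duration from a 5-cycle
  single-cell pilot run (seeded from the master seed), with
  `g_sd = 0.1·g_mean` and truncation at ≥ 1 sweep.  Any values yielding a
  well-mixed asynchronous population are equivalent for timing statistics,
  because cycles are independent and timing is measured relative to S entry.
- **Within-sweep ordering** is fixed as advance → release → initiate; a
  fresh S entrant is processed at sweep start and may initiate in its first
  sweep.  An initiation marks the chosen bin itself replicated at the
  firing sweep; forks extend from it starting the next sweep.
- **Collisions** release only the blocked fork; when two forks converge on
  the same unreplicated bin in one sweep, the lower pool index wins
  (deterministic tie-break) and the other disengages on its own attempt.
- **Randomness.**  Each cell owns a generator spawned from the master seed
  (`numpy` SeedSequence), so results are bit-reproducible and independent of
  iteration order or the `threads` flag (execution is serial; the flag is
  accepted for interface compatibility).  One uniform variate is consumed
  per probability test even for probabilities 0 or 1, keeping the stream
  layout independent of the landscape values.
- **Bedgraph → IPLS normalization.**  Bin signal is the coverage-weighted
  mean of overlapping interval values (uncovered bp contribute 0, so
  signal-free bins are passively replicable only).  Per-chromosome
  max-normalization maps the strongest bin to probability 1; only relative
  magnitudes shape timing, so a graded (rather than thresholded-binary)
  mapping is used.  Sum-normalization is available via
  `normalization="sum"`.
- **Thermalization accounting.**  Per-cycle timing statistics include only
  cycles that *began* at or after sweep `ntherm`.  Initiation-event and
  exposure tallies (used for rate estimates) include all sweeps from
  `ntherm` onward; the slight asymmetry only affects partially-burned-in
  cycles straddling the boundary and vanishes with longer burn-in.
- **Initiation-rate exposure** is keyed by the cell's replicated-bin count
  at sweep start, so rates are exact on the discrete fraction grid
  `r / n_bins`; re-binning to coarser fraction windows aggregates these
  exact tallies.  Windows with zero exposure report a missing (NaN) rate,
  never zero.
- **Flow sorting** gates S cells by replicated fraction into half-open
  `[lo, hi)` intervals with the last interval closed; G cells are never
  sorted.  Both raw per-gate counts and a gate-midpoint-weighted derived
  timing are produced, because sorted-fraction experiments are reported in
  both forms.
- **Combing statistics.**  Eyes/holes are maximal runs of the replication
  mask; eye-to-eye is center-to-center between adjacent eyes.  Eyes
  truncated by a chromosome end contribute to eye-length statistics but are
  excluded from eye-to-eye (their centers are censored).  Time-in-S bins
  are equal-width in sweeps; multiply by `sweep_seconds(binsize)` for
  wall-clock units.
- **Timing normalization.**  Besides raw mean sweeps, profiles expose a
  z-scored, sign-flipped form (early = positive) for comparison with
  early/late-ratio timing data.  Wavelet smoothing of empirical profiles is
  out of scope.

## What the synthetic landscapes emulate

`synthetic_landscape` produces delta / multi-delta (point origins), uniform,
and Gaussian-peak landscapes.  Peaks over a small baseline emulate the
salient feature of accessibility-derived landscapes — localized initiation
zones over a weakly permissive background.  Real landscapes additionally
carry measurement noise, mappability gaps, and broad domain structure;
passing tests on synthetic landscapes therefore validate the mechanism and
its statistics, not the quality of any particular empirical input.
Reproducing published genome-scale accuracy figures requires external
accessibility and timing datasets and is not attempted here; the
`pearson_rmsd` utility provided is the comparison statistic used for such
evaluations.

## Validation strategy

- **Closed forms.**  With fork-progress 1 and no release, a bin at distance
  `d` from the nearest origin fired at sweep `t₀` replicates exactly at
  `t₀ + d`.  Delta and multi-delta landscapes are checked against this
  minimum-distance profile with zero tolerance (up to 10⁴ bins).
- **Independent reference.**  `forksim.oracle.reference_simulate` is a
  deliberately plain re-implementation of the sweep rules (Python lists, no
  shared code) limited to ≤ 12 bins and ≤ 4 forks.  Engine and reference
  per-bin mean replication times must agree within 3 combined standard
  errors at ≥ 10⁴ cycles per side, across per-pair and per-cell modes and
  non-trivial kinetics.
- **Conservation properties** (each bin exactly once per S phase, fork-pool
  accounting, monotone replication) are property-tested over randomized
  landscapes and configurations.
- **Physical calibration.**  The per-fork velocity inferred from eye-length
  growth on a single-origin landscape equals 50 bp/s exactly — the
  discretization makes this an identity, so any deviation indicates a
  bookkeeping bug rather than noise.

## Numerical and degenerate-input notes

- Unreplicated-bin sampling uses a swap-remove pool, making sweeps O(nfork)
  regardless of chromosome size.
- An all-zero IPLS is rejected (S phase could never complete).  A landscape
  with per-bin fork-progress 0 and release 0 can deadlock a fork pair by
  construction; such inputs are accepted (they are locally meaningful) but
  long-running configurations should keep some progress or release mass.
- Snapshot storage is O(nmeas · ncells · n_bins) bits; at production scales
  reduce `nmeas` or thin snapshots if memory matters.
- `write_ipls`/`read_ipls` round-trip exactly (floats serialized via repr);
  a single-bin file has no spacing to infer, so its binsize reads back as
  the 500 bp default.

## Known limitations

- No inter-fork or inter-cell interactions, licensing dynamics, chromatin
  remodeling during S, or sequencing-read-level simulation.
- One chromosome per run; whole-genome studies fan out one process per
  chromosome.
- The nascent-strand instrument counts initiation events per bin; it does
  not model strand-length selection windows.
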