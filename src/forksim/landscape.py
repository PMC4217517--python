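"""Initiation probability landscapes.

A landscape assigns, to every fixed-width bin of one chromosome, the
probability that a replication-initiation attempt at that bin fires.  It may
optionally carry per-bin fork kinetics: a fork-progress probability (chance an
engaged fork advances one bin per sweep) and a fork-release probability
(chance an engaged fork is disengaged per sweep).  Landscapes are stored as
plain-text files with 2-4 whitespace-delimited columns::

    <bin start (bp)>  <init prob>  [<fork progress>  [<fork release>]]

One file describes one chromosome; coordinates are 0-based, half-open bins
``[p, p + binsize)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Landscape",
    "LandscapeError",
    "read_ipls",
    "write_ipls",
    "bedgraph_to_ipls",
    "synthetic_landscape",
]

DEFAULT_BINSIZE = 500


class LandscapeError(ValueError):
    """Raised for malformed or invalid landscape inputs."""


@dataclass
class Landscape:
    """Per-bin initiation probabilities (and optional fork kinetics).

    Parameters
    ----------
    init_prob
        Per-bin probability in [0, 1] that an initiation attempt at the bin
        fires.  At least one bin must be positive, otherwise S phase could
        never complete.
    binsize
        Bin width in bp (default 500).
    start
        Genomic coordinate of the first bin (bp).  Bin ``i`` covers
        ``[start + i*binsize, start + (i+1)*binsize)``.
    fork_progress, fork_release
        Optional per-bin kinetics overriding the global simulation settings.
    chrom_name
        Label used when writing genomic output (bedgraph).
    """

    init_prob: np.ndarray
    binsize: int = DEFAULT_BINSIZE
    start: int = 0
    fork_progress: np.ndarray | None = None
    fork_release: np.ndarray | None = None
    chrom_name: str = "chrom"

    def __post_init__(self) -> None:
        self.init_prob = np.asarray(self.init_prob, dtype=float)
        if self.init_prob.ndim != 1 or self.init_prob.size == 0:
            raise LandscapeError("init_prob must be a non-empty 1-D array")
        if np.any(~np.isfinite(self.init_prob)):
            raise LandscapeError("init_prob contains non-finite values")
        if np.any((self.init_prob < 0) | (self.init_prob > 1)):
            raise LandscapeError("init_prob values must lie in [0, 1]")
        if not np.any(self.init_prob > 0):
            raise LandscapeError(
                "all-zero landscape: S phase could never complete"
            )
        if self.binsize <= 0:
            raise LandscapeError("binsize must be positive")
        for name in ("fork_progress", "fork_release"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.init_prob.shape:
                raise LandscapeError(f"{name} must match init_prob length")
            if np.any(~np.isfinite(arr)) or np.any((arr < 0) | (arr > 1)):
                raise LandscapeError(f"{name} values must lie in [0, 1]")
            setattr(self, name, arr)

    @property
    def n_bins(self) -> int:
        return int(self.init_prob.size)

    @property
    def positions(self) -> np.ndarray:
        """Bin start coordinates in bp."""
        return self.start + self.binsize * np.arange(self.n_bins)

    def progress_array(self, default: float) -> np.ndarray:
        """Effective per-bin fork-progress probabilities."""
        if self.fork_progress is not None:
            return self.fork_progress
        return np.full(self.n_bins, float(default))

    def release_array(self, default: float) -> np.ndarray:
        """Effective per-bin fork-release probabilities."""
        if self.fork_release is not None:
            return self.fork_release
        return np.full(self.n_bins, float(default))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Landscape):
            return NotImplemented

        def _opt_eq(a, b):
            if a is None or b is None:
                return a is None and b is None
            return np.array_equal(a, b)

        return (
            self.binsize == other.binsize
            and self.start == other.start
            and np.array_equal(self.init_prob, other.init_prob)
            and _opt_eq(self.fork_progress, other.fork_progress)
            and _opt_eq(self.fork_release, other.fork_release)
        )


def read_ipls(path) -> Landscape:
    """Read a landscape from a 2-4 column whitespace-delimited text file.

    The bin size is inferred from the spacing of consecutive positions
    (a single-bin file defaults to 500 bp).  Columns 3 and 4, when present,
    populate ``fork_progress`` and ``fork_release``.
    """
    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) < 2 or len(fields) > 4:
                raise LandscapeError(
                    f"{path}:{lineno}: expected 2-4 columns, got {len(fields)}"
                )
            try:
                values = [float(x) for x in fields]
            except ValueError as exc:
                raise LandscapeError(f"{path}:{lineno}: {exc}") from None
            if width is None:
                width = len(fields)
            elif len(fields) != width:
                raise LandscapeError(
                    f"{path}:{lineno}: inconsistent column count"
                )
            rows.append(values)
    if not rows:
        raise LandscapeError(f"{path}: empty landscape file")

    data = np.asarray(rows, dtype=float)
    pos = data[:, 0]
    if data.shape[0] > 1:
        spacing = np.diff(pos)
        if np.any(spacing <= 0):
            raise LandscapeError(f"{path}: positions must be strictly increasing")
        if not np.all(spacing == spacing[0]):
            raise LandscapeError(f"{path}: non-uniform position spacing")
        binsize = int(spacing[0])
        if binsize != spacing[0]:
            raise LandscapeError(f"{path}: non-integer bin spacing")
    else:
        binsize = DEFAULT_BINSIZE
    return Landscape(
        init_prob=data[:, 1],
        binsize=binsize,
        start=int(pos[0]),
        fork_progress=data[:, 2] if data.shape[1] >= 3 else None,
        fork_release=data[:, 3] if data.shape[1] >= 4 else None,
    )


def _fmt(x: float) -> str:
    # repr round-trips float64 exactly; integers print without a trailing .0
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_ipls(landscape: Landscape, path) -> None:
    """Write a landscape so that :func:`read_ipls` reproduces it exactly."""
    cols = [landscape.positions.astype(float), landscape.init_prob]
    if landscape.fork_release is not None and landscape.fork_progress is None:
        # release without progress is unrepresentable in the column layout
        raise LandscapeError(
            "cannot write fork_release without fork_progress (column order)"
        )
    if landscape.fork_progress is not None:
        cols.append(landscape.fork_progress)
    if landscape.fork_release is not None:
        cols.append(landscape.fork_release)
    with open(path, "w") as fh:
        for row in zip(*cols):
            fh.write(" ".join(_fmt(v) for v in row) + "\n")


def bedgraph_to_ipls(
    path,
    binsize: int = DEFAULT_BINSIZE,
    chrom: str | None = None,
    normalization: str = "max",
) -> Landscape:
    """Convert a 4-column bedgraph signal into a landscape.

    Each bin's signal is the coverage-weighted mean of overlapping interval
    values, with uncovered base pairs contributing zero.  The signal is then
    normalized so probabilities lie in [0, 1]: ``normalization="max"``
    (default) divides by the maximum bin signal so the strongest bin gets
    probability 1; ``"sum"`` divides by the total (probabilities then sum
    to 1 and are typically tiny — relative magnitudes, which are what shape
    timing, are identical under either choice).

    Parameters
    ----------
    path
        Bedgraph file: ``chrom  start  end  value`` (0-based, half-open).
    binsize
        Output bin width in bp.
    chrom
        Chromosome to extract; may be omitted for a single-chromosome file.
    """
    if normalization not in ("max", "sum"):
        raise LandscapeError(f"unknown normalization {normalization!r}")
    try:
        bg = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64,
                   "value": float},
        )
    except ValueError as exc:
        raise LandscapeError(f"{path}: malformed bedgraph ({exc})") from None
    if bg.isna().any().any():
        raise LandscapeError(f"{path}: malformed bedgraph (missing fields)")
    if chrom is None:
        names = bg["chrom"].unique()
        if len(names) != 1:
            raise LandscapeError(
                f"{path}: multiple chromosomes present; specify chrom"
            )
        chrom = str(names[0])
    sub = bg[bg["chrom"] == chrom]
    if sub.empty:
        raise LandscapeError(f"{path}: no intervals for chromosome {chrom!r}")
    if (sub["value"] < 0).any():
        raise LandscapeError(f"{path}: negative bedgraph values")
    if (sub["end"] <= sub["start"]).any() or (sub["start"] < 0).any():
        raise LandscapeError(f"{path}: invalid interval coordinates")
    sub = sub.sort_values("start")
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    if np.any(starts[1:] < ends[:-1]):
        raise LandscapeError(f"{path}: overlapping bedgraph intervals")

    last = int(ends.max())
    n_bins = -(-last // binsize)  # ceil: bins span [0, last rounded up)
    signal = np.zeros(n_bins)
    values = sub["value"].to_numpy()
    for s, e, v in zip(starts, ends, values):
        b0, b1 = s // binsize, (e - 1) // binsize
        for b in range(b0, b1 + 1):
            lo = max(s, b * binsize)
            hi = min(e, (b + 1) * binsize)
            signal[b] += v * (hi - lo)
    signal /= binsize  # coverage-weighted mean (uncovered bp contribute 0)

    total = signal.max() if normalization == "max" else signal.sum()
    if total <= 0:
        raise LandscapeError(f"{path}: zero signal for chromosome {chrom!r}")
    return Landscape(init_prob=signal / total, binsize=binsize,
                     chrom_name=chrom)


def synthetic_landscape(
    kind: str,
    n_bins: int,
    binsize: int = DEFAULT_BINSIZE,
    *,
    origin: int | None = None,
    origins=None,
    p: float = 1.0,
    centers=None,
    widths=None,
    heights=None,
    baseline: float = 0.0,
) -> Landscape:
    """Build a synthetic landscape for testing and exploration.

    Kinds
    -----
    ``delta``
        Probability 1 at one ``origin`` bin, 0 elsewhere.
    ``multi_delta``
        Probability 1 at every bin in ``origins``.
    ``uniform``
        Constant probability ``p`` at every bin.
    ``peaks``
        Sum of Gaussian bumps (``centers``/``widths`` in bins, ``heights``
        as probabilities) over a flat ``baseline``, clipped to [0, 1].
    """
    if n_bins < 1:
        raise LandscapeError("n_bins must be >= 1")

    def _check(idx: int) -> int:
        idx = int(idx)
        if not 0 <= idx < n_bins:
            raise LandscapeError(f"origin index {idx} out of range [0, {n_bins})")
        return idx

    prob = np.zeros(n_bins)
    if kind == "delta":
        if origin is None:
            raise LandscapeError("delta landscape requires origin=")
        prob[_check(origin)] = 1.0
    elif kind == "multi_delta":
        if not origins:
            raise LandscapeError("multi_delta landscape requires origins=")
        for o in origins:
            prob[_check(o)] = 1.0
    elif kind == "uniform":
        if not 0 < p <= 1:
            raise LandscapeError("uniform landscape requires 0 < p <= 1")
        prob[:] = p
    elif kind == "peaks":
        if not centers:
            raise LandscapeError("peaks landscape requires centers=")
        widths = widths if widths is not None else [3.0] * len(centers)
        heights = heights if heights is not None else [1.0] * len(centers)
        if not (len(centers) == len(widths) == len(heights)):
            raise LandscapeError("centers/widths/heights lengths differ")
        x = np.arange(n_bins, dtype=float)
        prob[:] = baseline
        for c, w, h in zip(centers, widths, heights):
            _check(c)
            prob += h * np.exp(-0.5 * ((x - c) / float(w)) ** 2)
        prob = np.clip(prob, 0.0, 1.0)
    else:
        raise LandscapeError(f"unknown landscape kind {kind!r}")
    return Landscape(init_prob=prob, binsize=binsize)
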