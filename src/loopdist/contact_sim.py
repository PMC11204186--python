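"""Toy contact-map simulator and insulation-based domain caller.

Generates a symmetric binned contact matrix from a loop annotation:
power-law distance decay, within-loop contact enrichment, corner peaks at
the paired anchors of each loop, and optional Poisson sampling noise. The
domain caller computes a standard insulation profile (mean contact crossing
each bin within a window) and places domain boundaries at its prominent
local minima, recovering the annotated loop structure on noiseless input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.signal

from .coords import LoopAnnotation, assign_loop

__all__ = [
    "ContactMap",
    "InsulationProfile",
    "DomainCall",
    "simulate_contact_map",
    "insulation_profile",
    "call_domains",
    "read_contact_map",
    "write_contact_map",
    "plot_contact_map",
]

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 25_000
DEFAULT_WINDOW_BP = 200_000  # 8 bins at the default bin size


@dataclass(frozen=True)
class ContactMap:
    """Square symmetric matrix of non-negative contacts over uniform bins."""

    matrix: np.ndarray
    bin_size: int
    chrom: str
    start: int  # genomic position of the left edge of bin 0 (1-based)

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("contact matrix must be symmetric (tol 1e-9)")
        if np.any(np.diag(m) <= 0):
            raise ValueError("diagonal must be positive")
        if np.any(m < 0):
            raise ValueError("contacts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_of(self, position: int | float) -> int:
        return int((position - self.start) // self.bin_size)

    def bin_start(self, i: int) -> int:
        return self.start + i * self.bin_size


@dataclass(frozen=True)
class InsulationProfile:
    """Per-bin insulation scores; NaN where the window does not fit."""

    scores: np.ndarray
    window: int  # in bins

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.scores)


@dataclass(frozen=True)
class DomainCall:
    """Called domains as half-open bin ranges [start_bin, end_bin) with labels."""

    domains: tuple[tuple[int, int], ...]
    labels: tuple[str, ...]
    boundary_bins: tuple[int, ...]

    @property
    def n_domains(self) -> int:
        return len(self.domains)


def _bin_loop_labels(loops: LoopAnnotation, bin_size: int, n_bins: int) -> list[str | None]:
    b0 = loops.boundaries[0]
    return [
        assign_loop(b0 + (i + 0.5) * bin_size, loops) for i in range(n_bins)
    ]


def simulate_contact_map(
    loops: LoopAnnotation,
    bin_size: int = DEFAULT_BIN_SIZE,
    alpha: float = 1.0,
    enrich: float = 2.0,
    anchor_peak: float = 5.0,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> ContactMap:
    """Simulate a contact map over the annotated span.

    ``C_ij = decay * (1 + enrich * same_loop(i, j)) + anchor_peak * decay *
    corner(i, j)`` where ``decay = (|i - j| + 1) ** -alpha``, ``same_loop``
    marks bin pairs whose midpoints fall in the same loop, and ``corner``
    marks pairs within one bin of the two anchors of one loop (the loop's
    corner dot). ``anchor_peak`` is therefore a multiple of the background at
    that genomic distance. With ``noise_rate > 0`` each entry is replaced by
    ``Poisson(noise_rate * C) / noise_rate`` (sequencing-depth noise) and the
    matrix re-symmetrized. The last bin is padded when ``bin_size`` does not
    divide the span.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if enrich < 0 or anchor_peak < 0:
        raise ValueError("enrich and anchor_peak must be >= 0")
    b0, b3 = loops.span
    n = math.ceil((b3 - b0) / bin_size)
    idx = np.arange(n)
    decay = (np.abs(idx[:, None] - idx[None, :]) + 1.0) ** (-alpha)

    labels = _bin_loop_labels(loops, bin_size, n)
    lab_arr = np.array([l if l is not None else "" for l in labels])
    same_loop = (lab_arr[:, None] == lab_arr[None, :]) & (lab_arr[:, None] != "")

    corner = np.zeros((n, n), dtype=bool)
    for b_left, b_right in zip(loops.boundaries, loops.boundaries[1:]):
        a1 = min(int((b_left - b0) // bin_size), n - 1)
        a2 = min(int((b_right - b0) // bin_size), n - 1)
        i_near = np.abs(idx - a1) <= 1
        j_near = np.abs(idx - a2) <= 1
        corner |= i_near[:, None] & j_near[None, :]
        corner |= j_near[:, None] & i_near[None, :]

    c = decay * (1.0 + enrich * same_loop) + anchor_peak * decay * corner
    if noise_rate > 0:
        rng = np.random.default_rng(seed)
        c = rng.poisson(noise_rate * c).astype(float) / noise_rate
        c = 0.5 * (c + c.T)
        # Poisson can zero a diagonal entry at low rate; keep it positive
        np.fill_diagonal(c, np.maximum(np.diag(c), 1.0 / noise_rate))
    else:
        c = 0.5 * (c + c.T)
    return ContactMap(matrix=c, bin_size=bin_size, chrom=loops.chrom, start=b0)


def insulation_profile(
    cmap: ContactMap, w: int | None = None, window_bp: int = DEFAULT_WINDOW_BP
) -> InsulationProfile:
    """Insulation score per bin: mean contact in the w x w square crossing it.

    ``score(b)`` averages ``C[i, j]`` over ``i in (b - w, b]`` and
    ``j in (b, b + w]``; low scores mark bins that few contacts cross, i.e.
    domain boundaries. ``w`` defaults to ``window_bp / bin_size`` rounded
    (200 kb -> 8 bins at 25 kb bins).
    """
    n = cmap.n_bins
    if w is None:
        w = max(1, round(window_bp / cmap.bin_size))
    if not 1 <= w <= n // 4:
        raise ValueError(f"window w={w} out of range [1, n_bins/4 = {n // 4}]")
    m = cmap.matrix
    scores = np.full(n, np.nan)
    for b in range(w - 1, n - w):
        scores[b] = m[b - w + 1 : b + 1, b + 1 : b + w + 1].mean()
    return InsulationProfile(scores=scores, window=w)


def call_domains(
    profile: InsulationProfile,
    cmap: ContactMap,
    loops_span: tuple[int, int],
    min_prominence: float | None = None,
    loop_labels: tuple[str, ...] | None = None,
    smooth: int = 3,
) -> DomainCall:
    """Call domains between prominent insulation minima inside the span.

    The profile is first smoothed with a ``smooth``-bin moving average (the
    usual guard against single-bin noise dips; ``smooth=1`` disables it).
    Boundaries are then local minima with prominence at least
    ``min_prominence`` (default: 10% of the smoothed profile's range).
    Domains are the spans between consecutive elements of {span start,
    detected boundaries, span end}. If no minimum is found a single domain
    is returned and a warning logged.
    """
    scores = profile.scores.copy()
    valid = np.where(np.isfinite(scores))[0]
    if valid.size == 0:
        raise ValueError("insulation profile has no valid bins")
    if smooth > 1:
        scores[valid] = scipy.ndimage.uniform_filter1d(
            scores[valid], size=smooth, mode="nearest"
        )
    finite = scores[valid]
    if min_prominence is None:
        rng_ = float(finite.max() - finite.min())
        min_prominence = 0.1 * rng_
    filled = np.where(np.isfinite(scores), scores, finite.max())
    minima, _ = scipy.signal.find_peaks(-filled, prominence=min_prominence)

    lo = max(0, cmap.bin_of(loops_span[0]))
    hi = min(cmap.n_bins, math.ceil((loops_span[1] - cmap.start) / cmap.bin_size))
    minima = [int(b) for b in minima if lo < b < hi - 1]
    if not minima:
        logger.warning("no insulation minima found; returning a single domain")
    edges = [lo] + minima + [hi]
    domains = tuple((a, b) for a, b in zip(edges, edges[1:]))
    if loop_labels is not None and len(loop_labels) == len(domains):
        labels = tuple(loop_labels)
    else:
        labels = tuple(f"d{i + 1}" for i in range(len(domains)))
    return DomainCall(domains=domains, labels=labels, boundary_bins=tuple(minima))


# --- I/O and rendering -----------------------------------------------------


def write_contact_map(cmap: ContactMap, path, header_comments: list[str] | None = None) -> None:
    """Dense TSV with bin start coordinates as header row and first column."""
    coords = [cmap.bin_start(i) for i in range(cmap.n_bins)]
    df = pd.DataFrame(cmap.matrix, index=coords, columns=coords)
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        fh.write(f"# chrom={cmap.chrom} bin_size={cmap.bin_size}\n")
        df.to_csv(fh, sep="\t", index_label="bin_start")


def read_contact_map(path) -> ContactMap:
    chrom, bin_size = "unknown", None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if tok.startswith("chrom="):
                    chrom = tok.split("=", 1)[1]
                elif tok.startswith("bin_size="):
                    bin_size = int(tok.split("=", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    coords = df.index.to_numpy(dtype=int)
    if bin_size is None:
        bin_size = int(coords[1] - coords[0]) if len(coords) > 1 else 1
    return ContactMap(
        matrix=df.to_numpy(dtype=float), bin_size=bin_size, chrom=chrom, start=int(coords[0])
    )


def plot_contact_map(cmap: ContactMap, ax=None, log: bool = True):
    """Heat-map rendering for inspection (log scale by default)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    m = np.log10(cmap.matrix + 1e-6) if log else cmap.matrix
    extent_mb = (
        cmap.start / 1e6,
        (cmap.start + cmap.n_bins * cmap.bin_size) / 1e6,
    )
    ax.imshow(m, cmap="Reds", extent=(*extent_mb, extent_mb[1], extent_mb[0]))
    ax.set_xlabel(f"{cmap.chrom} (Mb)")
    ax.set_ylabel(f"{cmap.chrom} (Mb)")
    return ax
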