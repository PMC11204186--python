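"""Synthetic dual-color interphase FISH spot generator.

Emulates the measurement process behind inter-probe distance FISH: in each
nucleus a chromatin segment of true 3D length ``d`` connects the two
hybridized probes; the segment takes a uniformly random orientation inside a
spherical nucleus, the microscope records only the (x, y) projection, and
each spot position carries isotropic Gaussian localization error. Two
homologous copies of chromosome 15 are placed per nucleus, their segment
centers kept apart so the two spot pairs are unambiguous.

The condition means (probe pair x rs12913832 genotype) default to the
published interphase-FISH values for the 15q12-q13.1 panel; they are
generator calibration, not a mechanistic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GENOTYPES",
    "PAIRS",
    "DistanceModel",
    "NucleusConfig",
    "default_distance_model",
    "sample_orientation",
    "simulate_nucleus",
    "simulate_cohort",
    "projected_distance",
    "pair_distances",
    "read_spot_table",
    "write_spot_table",
]

GENOTYPES = ("AA", "AG", "GG")
#: Hybridized probe pairs, by panel number.
PAIRS = ((2, 3), (1, 4), (4, 5))

SPOT_COLUMNS = ["nucleus", "homolog", "probe", "x_um", "y_um", "z_um", "pair", "genotype"]


def pair_tag(pair: tuple[int, int]) -> str:
    return f"{pair[0]}-{pair[1]}"


def parse_pair(tag: str) -> tuple[int, int]:
    a, b = tag.replace("#", "").split("-")
    return int(a), int(b)


# Mean true 3D separations (um), calibrated to the published per-condition
# means. The overlapping pair #4-#5 is genotype-invariant by construction.
_DEFAULT_MU: dict[tuple[tuple[int, int], str], float] = {
    ((2, 3), "AA"): 2.2,
    ((2, 3), "AG"): 1.8,
    ((2, 3), "GG"): 0.9,
    ((1, 4), "AA"): 1.3,
    ((1, 4), "AG"): 1.4,
    ((1, 4), "GG"): 1.0,
    ((4, 5), "AA"): 0.7,
    ((4, 5), "AG"): 0.7,
    ((4, 5), "GG"): 0.7,
}


@dataclass(frozen=True)
class DistanceModel:
    """Condition -> true-separation calibration.

    Parameters
    ----------
    mu : mapping (pair, genotype) -> mean true 3D separation in um.
    tau : cell-to-cell SD of the true separation (um). 0 = rigid mode.
    sigma_loc : per-axis Gaussian localization SD (um). 0 = noiseless.
    """

    mu: Mapping[tuple[tuple[int, int], str], float] = field(
        default_factory=lambda: dict(_DEFAULT_MU)
    )
    tau: float = 0.0
    sigma_loc: float = 0.0

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.mu.values()):
            raise ValueError("all mean separations must be >= 0")
        if self.tau < 0 or self.sigma_loc < 0:
            raise ValueError("tau and sigma_loc must be >= 0")

    def mean_separation(self, pair: tuple[int, int], genotype: str) -> float:
        key = (tuple(pair), genotype)
        if key not in self.mu:
            raise KeyError(f"no calibration for pair {pair_tag(pair)}, genotype {genotype}")
        return self.mu[key]

    @property
    def max_mu(self) -> float:
        return max(self.mu.values())


def default_distance_model(tau: float = 0.0, sigma_loc: float = 0.0) -> DistanceModel:
    """Calibrated model; rigid (tau=0, sigma_loc=0) unless overridden."""
    return DistanceModel(tau=tau, sigma_loc=sigma_loc)


@dataclass(frozen=True)
class NucleusConfig:
    """Spherical-nucleus geometry.

    radius : nucleus radius in um (default 3.5, a typical lymphocyte).
    homolog_min_sep : minimum distance between the segment centers of the two
        chromosome-15 homologs (um), so spot-pair-to-homolog assignment by
        proximity is unambiguous.
    homologs_per_nucleus : how many homolog distances per nucleus enter the
        measurement list downstream (1 or 2); the spot table always carries
        both homologs.
    """

    radius: float = 3.5
    homolog_min_sep: float = 2.0
    homologs_per_nucleus: int = 1

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.homolog_min_sep < 0:
            raise ValueError("homolog_min_sep must be >= 0")
        if self.homologs_per_nucleus not in (1, 2):
            raise ValueError("homologs_per_nucleus must be 1 or 2")

    def check_feasible(self, model: DistanceModel) -> None:
        if self.homolog_min_sep + model.max_mu >= 2 * self.radius:
            raise ValueError(
                "infeasible geometry: homolog_min_sep + max separation "
                f"({self.homolog_min_sep} + {model.max_mu}) must be < 2*radius "
                f"({2 * self.radius})"
            )


def sample_orientation(rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Unit vector(s) uniform on the sphere (normalized isotropic Gaussians)."""
    n = 1 if size is None else size
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v[0] if size is None else v


def _uniform_in_sphere(rng: np.random.Generator, radius: float) -> np.ndarray:
    direction = sample_orientation(rng)
    r = radius * rng.random() ** (1.0 / 3.0)
    return r * direction


def simulate_nucleus(
    pair: tuple[int, int],
    genotype: str,
    model: DistanceModel,
    cfg: NucleusConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spot coordinates for one nucleus.

    Returns an array of shape (2 homologs, 2 probes, 3 axes) in um, nucleus
    center at the origin. Per homolog: the true separation is
    ``max(0, Normal(mu, tau))``; the segment center is uniform in the sphere
    of radius ``radius - d/2`` (so both endpoints stay inside the nucleus);
    endpoints are ``center +/- (d/2) * orientation`` with orientation uniform
    on the sphere; each endpoint is then perturbed by isotropic Gaussian
    localization noise. The two homolog centers are rejection-sampled to be
    at least ``homolog_min_sep`` apart.
    """
    cfg.check_feasible(model)
    mu = model.mean_separation(pair, genotype)

    d = np.empty(2)
    centers = np.empty((2, 3))
    for h in range(2):
        d[h] = max(0.0, rng.normal(mu, model.tau)) if model.tau > 0 else mu
    # rejection-sample both centers jointly until separated
    while True:
        for h in range(2):
            centers[h] = _uniform_in_sphere(rng, cfg.radius - d[h] / 2.0)
        if np.linalg.norm(centers[0] - centers[1]) >= cfg.homolog_min_sep:
            break

    spots = np.empty((2, 2, 3))
    for h in range(2):
        u = sample_orientation(rng)
        spots[h, 0] = centers[h] - (d[h] / 2.0) * u
        spots[h, 1] = centers[h] + (d[h] / 2.0) * u
        if model.sigma_loc > 0:
            spots[h] += rng.normal(0.0, model.sigma_loc, size=(2, 3))
    return spots


def simulate_cohort(
    pair: tuple[int, int],
    genotype: str,
    n_nuclei: int,
    model: DistanceModel | None = None,
    cfg: NucleusConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a cohort of nuclei for one (pair, genotype) condition.

    Returns a spot table with one row per spot: 2 homologs x 2 probes per
    nucleus. Reproducible for a given seed; each nucleus draws from its own
    deterministic substream so the table is independent of iteration order.
    """
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    model = model if model is not None else default_distance_model()
    cfg = cfg if cfg is not None else NucleusConfig()
    cfg.check_feasible(model)

    child_seeds = np.random.SeedSequence(seed).spawn(n_nuclei)
    rows: list[tuple] = []
    probes = tuple(pair)
    tag = pair_tag(pair)
    for i, ss in enumerate(child_seeds):
        spots = simulate_nucleus(pair, genotype, model, cfg, np.random.default_rng(ss))
        for h in range(2):
            for p in range(2):
                x, y, z = spots[h, p]
                rows.append((i, h + 1, probes[p], x, y, z, tag, genotype))
    return pd.DataFrame(rows, columns=SPOT_COLUMNS)


def projected_distance(spot_a: pd.Series, spot_b: pd.Series) -> float:
    """2D (microscope-plane) Euclidean distance between two spots in um.

    Both spots must come from the same nucleus and homolog; z is ignored,
    which is exactly why the projected distance underestimates the true 3D
    separation for out-of-plane segments.
    """
    if (spot_a["nucleus"], spot_a["homolog"]) != (spot_b["nucleus"], spot_b["homolog"]):
        raise ValueError("spots come from different (nucleus, homolog) — not a probe pair")
    return float(np.hypot(spot_a["x_um"] - spot_b["x_um"], spot_a["y_um"] - spot_b["y_um"]))


def pair_distances(
    table: pd.DataFrame,
    homologs_per_nucleus: int = 1,
    projected: bool = True,
) -> np.ndarray:
    """Per-homolog inter-probe distances from a spot table.

    ``homologs_per_nucleus=1`` records one measurement per nucleus (homolog 1);
    ``2`` pools both homolog distances. With ``projected=False`` the full 3D
    distance is returned (available only for synthetic data carrying z).
    """
    if homologs_per_nucleus not in (1, 2):
        raise ValueError("homologs_per_nucleus must be 1 or 2")
    sub = table if homologs_per_nucleus == 2 else table[table["homolog"] == 1]
    axes = ["x_um", "y_um"] + ([] if projected else ["z_um"])
    wide = sub.pivot_table(
        index=["nucleus", "homolog"], columns="probe", values=axes, sort=True
    )
    probes = sorted(sub["probe"].unique())
    if len(probes) != 2:
        raise ValueError(f"expected exactly 2 probes in the table, got {probes}")
    delta = np.column_stack(
        [wide[(ax, probes[0])] - wide[(ax, probes[1])] for ax in axes]
    )
    return np.linalg.norm(delta, axis=1)


def write_spot_table(table: pd.DataFrame, path, header_comments: list[str] | None = None) -> None:
    """Write a spot table as TSV, optionally with leading ``#`` comment lines."""
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_spot_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SPOT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"spot table missing columns: {sorted(missing)}")
    return table
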