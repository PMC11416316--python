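"""Point-pattern statistics of NPC positions in tomograms.

Per tomogram, all within-tomogram pair distances of the selected particle
class(es) are computed; the radial distribution function g(r) of each
tomogram is the observed pair count per distance shell divided by the count
expected for a homogeneous (CSR) process of the same intensity in the same
box.  The final curve is the unweighted mean over tomograms — per-tomogram
normalization first, then averaging, never pooled pairs.

The CSR expectation uses the exact distance distribution of two independent
uniform points in the tomogram's axis-aligned box (per-axis squared-
difference distributions combined by numerical convolution).  This is the
translational edge correction: no periodic wrap, no boundary bias.
Particles near the nuclear envelope form a quasi-2-D pattern embedded in
3-D; treating the box as fully 3-D is an approximation documented in the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

__all__ = ["ParticleTable", "pairwise_distances", "radial_distribution"]

DEFAULT_BIN_WIDTH_NM = 25.0


@dataclass
class ParticleTable:
    """Particle coordinates per tomogram with declared units.

    ``data`` needs columns ``tomogram, x, y, z`` and optionally ``label``
    (e.g. "single" / "double" nuclear-ring class).  ``boxes`` maps tomogram
    id to (Lx, Ly, Lz); coordinates must lie in [0, L] per axis.  ``units``
    must be declared ("nm" or "angstrom").
    """

    data: pd.DataFrame
    boxes: dict
    units: str

    def __post_init__(self):
        if self.units not in ("nm", "angstrom"):
            raise ValueError("units must be declared as 'nm' or 'angstrom'")
        missing = {"tomogram", "x", "y", "z"} - set(self.data.columns)
        if missing:
            raise ValueError(f"particle table lacks columns: {sorted(missing)}")
        for tomo, grp in self.data.groupby("tomogram"):
            if tomo not in self.boxes:
                raise ValueError(f"no bounding box for tomogram {tomo!r}")
            box = np.asarray(self.boxes[tomo], dtype=float)
            xyz = grp[["x", "y", "z"]].to_numpy(dtype=float)
            if np.any(xyz < -1e-9) or np.any(xyz > box + 1e-9):
                raise ValueError(f"coordinates outside the box in tomogram {tomo!r}")

    def filtered(self, classes=None) -> pd.DataFrame:
        if classes is None:
            return self.data
        if "label" not in self.data.columns:
            raise ValueError("table has no class labels to filter on")
        if isinstance(classes, str):
            classes = [classes]
        return self.data[self.data["label"].isin(classes)]


def pairwise_distances(table: ParticleTable, classes=None) -> dict:
    """Unordered within-tomogram pair distances per tomogram.

    Cross-tomogram pairs never appear.  Returns {tomogram: sorted distances}.
    """
    out = {}
    for tomo, grp in table.filtered(classes).groupby("tomogram"):
        xyz = grp[["x", "y", "z"]].to_numpy(dtype=float)
        out[tomo] = np.sort(pdist(xyz)) if len(xyz) >= 2 else np.empty(0)
    return out


def _axis_sq_mass(length: float, grid_edges: np.ndarray) -> np.ndarray:
    """P((x1-x2)^2 in [e_k, e_{k+1})) for x1, x2 ~ U(0, length).

    CDF of delta = |x1-x2| is F(d) = (2 L d - d^2) / L^2 on [0, L].
    """
    d = np.sqrt(np.minimum(grid_edges, length**2))
    cdf = (2.0 * length * d - d**2) / length**2
    return np.diff(cdf)


from functools import lru_cache


@lru_cache(maxsize=128)
def _csr_sq_distance_cum(box: tuple, umax: float, n_grid: int):
    edges = np.linspace(0.0, umax, n_grid + 1)
    conv = _axis_sq_mass(box[0], edges)
    for length in box[1:]:
        conv = np.convolve(conv, _axis_sq_mass(length, edges))[:n_grid]
    return edges, np.concatenate([[0.0], np.cumsum(conv)])


def _csr_distance_cdf(box: np.ndarray, r: np.ndarray, n_grid: int = 2048) -> np.ndarray:
    """P(|X - Y| <= r) for X, Y independent uniform in the box, via
    convolution of per-axis squared-difference histograms (cached per box)."""
    r = np.asarray(r, dtype=float)
    umax = float(np.max(r) ** 2) * (1.0 + 1e-12)
    if umax <= 0:
        return np.zeros_like(r)
    edges, cum = _csr_sq_distance_cum(tuple(float(v) for v in box), umax, n_grid)
    return np.interp(r**2, edges, cum)


def radial_distribution(
    table: ParticleTable,
    bin_width: float | None = None,
    r_max: float | None = None,
    classes=None,
):
    """Edge-corrected g(r), per tomogram and averaged.

    Defaults: bin width 25 nm (converted to the declared units), r_max half
    the shortest box edge over tomograms.  Tomograms with fewer than two
    particles of the selected class(es) are skipped.  Returns
    ``(bin_centers, g_mean, per_tomogram)`` where ``g_mean`` is the
    unweighted mean over tomogram curves (NaN-aware for empty shells).
    """
    df = table.filtered(classes)
    if len(df) == 0:
        raise ValueError("empty particle table")
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTH_NM * (10.0 if table.units == "angstrom" else 1.0)
    if r_max is None:
        r_max = min(min(b) for b in (np.asarray(table.boxes[t], float)
                                     for t in df["tomogram"].unique())) / 2.0
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    if len(edges) < 2:
        raise ValueError("r_max smaller than one bin")
    centers = 0.5 * (edges[:-1] + edges[1:])

    per_tomo = {}
    for tomo, grp in df.groupby("tomogram"):
        xyz = grp[["x", "y", "z"]].to_numpy(dtype=float)
        n = len(xyz)
        if n < 2:
            continue
        counts, _ = np.histogram(pdist(xyz), bins=edges)
        box = np.asarray(table.boxes[tomo], dtype=float)
        cdf = _csr_distance_cdf(box, edges)
        expected = (n * (n - 1) / 2.0) * np.diff(cdf)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(expected > 0, counts / expected, np.nan)
        per_tomo[tomo] = g
    if not per_tomo:
        raise ValueError("no tomogram has at least two particles of the "
                         "selected class(es)")
    stack = np.vstack(list(per_tomo.values()))
    with np.errstate(invalid="ignore"):
        g_mean = np.nanmean(stack, axis=0)
    return centers, g_mean, per_tomo
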