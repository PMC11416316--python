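"""Multiscale bead representation of one symmetry unit.

Subunit specifications (name, length, stoichiometry per symmetry unit,
segment annotations) are converted into strings of spherical beads.  Rigid
segments that come with source coordinates become rigid bodies and carry an
extra fine bead layer for residue-resolved restraints; everything else is a
flexible string of coarse beads.  FG-repeat ("excluded") segments produce no
beads at all.

Default multiscale schedule: coarse beads at 10 residues/bead everywhere;
rigid segments with source coordinates additionally at 1 residue/bead.
Bead radius is volume-proportional, r = R0_BEAD * n_res**(1/3) with
R0_BEAD = 3.0 A (roughly the volume of an average residue).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import AssemblyState, ChainInfo, RigidBody, rotation_about_z

__all__ = [
    "Segment",
    "SubunitSpec",
    "CoarseGrainPolicy",
    "bead_radius",
    "coarse_grain",
    "build_representation",
    "apply_symmetry",
    "yeast_subunit_specs",
    "mouse_subunit_specs",
]

R0_BEAD = 3.0  # A; radius of a 1-residue bead

SEGMENT_KINDS = ("rigid", "coiled-coil", "disordered", "excluded")


@dataclass(frozen=True)
class Segment:
    """Residue range annotation; ``start``/``end`` are 1-based inclusive."""

    start: int
    end: int
    kind: str = "disordered"

    def __post_init__(self):
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad segment range {self.start}..{self.end}")

    @property
    def n_res(self) -> int:
        return self.end - self.start + 1


@dataclass
class SubunitSpec:
    """One protein type: length, copies per symmetry unit, segments."""

    name: str
    length: int
    copies_per_unit: int = 1
    segments: list[Segment] = field(default_factory=list)
    # per-residue coordinates (length, 3) for rigid/coiled-coil segments;
    # segments with source coordinates become rigid bodies
    source_model: np.ndarray | None = None
    role: str = "component"

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"{self.name}: length must be >= 1")
        if self.copies_per_unit < 1:
            raise ValueError(f"{self.name}: copies_per_unit must be >= 1")
        if not self.segments:
            self.segments = [Segment(1, self.length, "disordered")]
        self._check_tiling()
        if self.source_model is not None:
            self.source_model = np.asarray(self.source_model, dtype=float)
            if self.source_model.shape != (self.length, 3):
                raise ValueError(f"{self.name}: source_model must be (length, 3)")

    def _check_tiling(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.start)
        pos = 1
        for s in segs:
            if s.start != pos:
                raise ValueError(
                    f"{self.name}: segments must tile 1..{self.length} "
                    f"(gap/overlap at residue {pos})"
                )
            pos = s.end + 1
        if pos != self.length + 1:
            raise ValueError(f"{self.name}: segments do not cover 1..{self.length}")
        self.segments = segs

    @property
    def represented_residues(self) -> int:
        return sum(s.n_res for s in self.segments if s.kind != "excluded")


@dataclass(frozen=True)
class CoarseGrainPolicy:
    """Residues-per-bead schedule of the multiscale representation."""

    coarse: int = 10          # residues/bead, all represented segments
    fine: int = 1             # residues/bead, rigid segments with coordinates
    spacing: float = 40.0     # A between default-layout chain baselines

    def __post_init__(self):
        if self.coarse < 1 or self.fine < 1:
            raise ValueError("beads must contain at least one residue")


def bead_radius(n_res: int | np.ndarray) -> np.ndarray:
    """Volume-equivalent sphere radius for a window of ``n_res`` residues."""
    return R0_BEAD * np.asarray(n_res, dtype=float) ** (1.0 / 3.0)


def _windows(start: int, end: int, per_bead: int) -> np.ndarray:
    """Split 1-based inclusive ``start..end`` into consecutive windows."""
    edges = list(range(start, end + 1, per_bead))
    out = []
    for lo in edges:
        hi = min(lo + per_bead - 1, end)
        out.append((lo, hi))
    return np.asarray(out, dtype=np.intp)


def coarse_grain(coords: np.ndarray, residues_per_bead: int, start_residue: int = 1):
    """Collapse ordered per-residue coordinates into beads.

    Returns ``(centers, radii, resranges)``: bead center is the centroid of
    its residue window, radius the volume-equivalent sphere for the window's
    residue count.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) == 0:
        raise ValueError("coords must be a nonempty (n, 3) array")
    if residues_per_bead < 1:
        raise ValueError("residues_per_bead must be >= 1")
    n = len(coords)
    ranges = _windows(start_residue, start_residue + n - 1, residues_per_bead)
    centers = np.array(
        [coords[lo - start_residue : hi - start_residue + 1].mean(axis=0) for lo, hi in ranges]
    )
    radii = bead_radius(ranges[:, 1] - ranges[:, 0] + 1)
    return centers, radii, ranges


def _default_layout(n_beads: int, radii: np.ndarray, baseline: float) -> np.ndarray:
    """Deterministic extended-chain layout for beads lacking coordinates."""
    x = np.concatenate([[0.0], np.cumsum((radii[:-1] + radii[1:]))]) if n_beads > 1 else np.zeros(1)
    out = np.zeros((n_beads, 3))
    out[:, 0] = x
    out[:, 1] = baseline
    return out


def build_representation(
    specs: list[SubunitSpec],
    policy: CoarseGrainPolicy | None = None,
) -> AssemblyState:
    """Instantiate all copies of all subunits as one symmetry unit.

    Excluded segments produce no beads.  Rigid/coiled-coil segments with a
    source model become rigid bodies (with a fine bead layer); all other
    segments are flexible coarse strings laid out deterministically (their
    placement is randomized later, before sampling).
    """
    policy = policy or CoarseGrainPolicy()
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate subunit names")

    chain_beads: list[dict] = []
    rigid_groups: list[tuple[list[int], bool]] = []
    offset = 0
    baseline = 0.0
    for spec in specs:
        for copy_idx in range(spec.copies_per_unit):
            coarse_centers, coarse_radii, coarse_ranges = [], [], []
            fine_centers, fine_radii, fine_ranges = [], [], []
            rigid_coarse_local: list[int] = []  # local coarse bead indices in rigid segs
            rigid_fine_local: list[int] = []
            for seg in spec.segments:
                if seg.kind == "excluded":
                    continue
                has_coords = spec.source_model is not None and seg.kind in ("rigid", "coiled-coil")
                ranges = _windows(seg.start, seg.end, policy.coarse)
                if has_coords:
                    seg_coords = spec.source_model[seg.start - 1 : seg.end]
                    c, r, rr = coarse_grain(seg_coords, policy.coarse, seg.start)
                    rigid_coarse_local.extend(
                        range(len(coarse_centers), len(coarse_centers) + len(c))
                    )
                    coarse_centers.extend(c)
                    coarse_radii.extend(r)
                    coarse_ranges.extend(rr)
                    if policy.fine < policy.coarse:
                        fc, fr, frr = coarse_grain(seg_coords, policy.fine, seg.start)
                        rigid_fine_local.extend(
                            range(len(fine_centers), len(fine_centers) + len(fc))
                        )
                        fine_centers.extend(fc)
                        fine_radii.extend(fr)
                        fine_ranges.extend(frr)
                else:
                    radii = bead_radius(ranges[:, 1] - ranges[:, 0] + 1)
                    coarse_centers.extend(np.full((len(ranges), 3), np.nan))
                    coarse_radii.extend(radii)
                    coarse_ranges.extend(ranges)
            if not coarse_centers:
                raise ValueError(f"{spec.name}: all segments excluded, nothing to represent")
            coarse_radii = np.asarray(coarse_radii)
            centers = np.asarray(coarse_centers, dtype=float)
            # fill placeholder coordinates with a deterministic extended layout
            missing = np.isnan(centers[:, 0])
            if missing.any():
                layout = _default_layout(len(centers), coarse_radii, baseline)
                centers[missing] = layout[missing]
            cb = {
                "subunit": spec.name,
                "copy_index": copy_idx,
                "role": spec.role,
                "centers": centers,
                "radii": coarse_radii,
                "resranges": np.asarray(coarse_ranges, dtype=np.intp),
            }
            n_coarse = len(centers)
            if fine_centers:
                cb["fine_centers"] = np.asarray(fine_centers)
                cb["fine_radii"] = np.asarray(fine_radii)
                cb["fine_resranges"] = np.asarray(fine_ranges, dtype=np.intp)
            chain_beads.append(cb)
            if rigid_coarse_local:
                idx = [offset + i for i in rigid_coarse_local] + [
                    offset + n_coarse + i for i in rigid_fine_local
                ]
                rigid_groups.append((idx, False))
            offset += n_coarse + len(fine_centers)
            baseline += policy.spacing
    return AssemblyState.from_chains(chain_beads, rigid_groups)


def apply_symmetry(state: AssemblyState, n: int) -> list[AssemblyState]:
    """Return the ``n`` rotational images of ``state`` about the z axis.

    Image ``k`` is rotated by 2*pi*k/n; image 0 is the identity.  The input
    state is not modified.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return [
        state.transformed(rotation_about_z(2.0 * np.pi * k / n), np.zeros(3))
        for k in range(n)
    ]


# ---------------------------------------------------------------------------
# Stoichiometry presets
# ---------------------------------------------------------------------------

# UniProt canonical lengths (rounded to the canonical isoform).
_YEAST_LENGTHS = {
    "Mlp1": 1875, "Nup1": 1076, "Nup2": 720, "Nup60": 539,
    "Nup84": 726, "Nup85": 744, "Nup120": 1037, "Nup133": 1157,
    "Nup145C": 712, "Sec13": 297, "Seh1": 349,
}
_MOUSE_LENGTHS = {
    "Tpr": 2363, "Nup50": 467, "Nup153": 1475,
    "Nup160": 1436, "Nup85": 656, "Nup96": 939, "Sec13": 322, "Seh1": 361,
    "Nup107": 926, "Nup133": 1156, "Nup43": 380, "Nup37": 326,
}

_Y_COMPLEX_YEAST = ("Nup84", "Nup85", "Nup120", "Nup133", "Nup145C", "Sec13", "Seh1")
_Y_COMPLEX_MOUSE = ("Nup160", "Nup85", "Nup96", "Sec13", "Seh1", "Nup107", "Nup133",
                    "Nup43", "Nup37")


def yeast_subunit_specs() -> list[SubunitSpec]:
    """Yeast basket stoichiometry for one symmetry unit.

    Two Mlp copies (the Mlp1/Mlp2 stoichiometry is ambiguous, so both are
    modeled with Mlp1's length but kept as distinct types), one Nup1, two
    each of Nup2 and Nup60, and two copies of the heptameric Nup84 (Y)
    complex forming the double nuclear ring: 21 subunits of 12 types.
    """
    specs = [
        SubunitSpec("Mlp1", _YEAST_LENGTHS["Mlp1"], 1, role="strut"),
        SubunitSpec("Mlp2", _YEAST_LENGTHS["Mlp1"], 1, role="strut"),
        SubunitSpec("Nup1", _YEAST_LENGTHS["Nup1"], 1, role="anchor"),
        SubunitSpec("Nup2", _YEAST_LENGTHS["Nup2"], 2, role="anchor"),
        SubunitSpec("Nup60", _YEAST_LENGTHS["Nup60"], 2, role="anchor"),
    ]
    specs += [
        SubunitSpec(name, _YEAST_LENGTHS[name], 2, role="scaffold")
        for name in _Y_COMPLEX_YEAST
    ]
    return specs


def mouse_subunit_specs() -> list[SubunitSpec]:
    """Mouse basket stoichiometry: 2 Tpr, 2 Nup50, 2 Nup153 and two copies of
    the nonameric Nup107 (Y) complex — 24 subunits of 12 types."""
    specs = [
        SubunitSpec("Tpr", _MOUSE_LENGTHS["Tpr"], 2, role="strut"),
        SubunitSpec("Nup50", _MOUSE_LENGTHS["Nup50"], 2, role="anchor"),
        SubunitSpec("Nup153", _MOUSE_LENGTHS["Nup153"], 2, role="anchor"),
    ]
    specs += [
        SubunitSpec(name, _MOUSE_LENGTHS[name], 2, role="scaffold")
        for name in _Y_COMPLEX_MOUSE
    ]
    return specs


def count_subunits(specs: list[SubunitSpec]) -> tuple[int, int]:
    """(total subunit instances, distinct types) for one symmetry unit."""
    return sum(s.copies_per_unit for s in specs), len({s.name for s in specs})
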