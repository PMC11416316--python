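"""Coarse-grained assembly state: bead pools, chains, rigid bodies.

One :class:`AssemblyState` holds a single symmetry unit of an assembly as a
flat pool of spherical beads (struct-of-arrays, for fast vectorized scoring)
plus chain and rigid-body bookkeeping.  Beads exist at one or two resolution
levels: every chain has a *coarse* bead string (used for connectivity,
excluded volume, density scoring, and RMSD) and rigid segments may carry an
additional *fine* bead layer (used for residue-resolved restraints such as
crosslinks).  Fine beads always belong to the rigid body of their segment and
move with it.

Coordinates are in Angstrom.  The frame convention is: origin at the center
of the fixed scaffold ring, z along the central (symmetry) axis pointing
cytoplasmic, so basket components extend toward negative z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChainInfo",
    "RigidBody",
    "AssemblyState",
    "rotation_about_z",
    "random_rotation_matrix",
]


def rotation_about_z(angle_rad: float) -> np.ndarray:
    """3x3 rotation matrix about the z (central) axis."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def random_rotation_matrix(rng: np.random.Generator, max_angle_rad: float | None = None) -> np.ndarray:
    """Random rotation: uniform axis, angle uniform in [0, max] (or [0, pi])."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, np.pi if max_angle_rad is None else max_angle_rad)
    if rng.uniform() < 0.5:
        angle = -angle
    k = np.array(
        [[0.0, -axis[2], axis[1]], [axis[2], 0.0, -axis[0]], [-axis[1], axis[0], 0.0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


@dataclass
class ChainInfo:
    """One polypeptide copy: ordered coarse beads plus optional fine beads."""

    subunit: str
    copy_index: int
    role: str = "component"  # "scaffold" | "strut" | "anchor" | "component"
    coarse: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    fine: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))


@dataclass
class RigidBody:
    """Beads (coarse and fine) that move as one unit; ``fixed`` bodies never move."""

    bead_idx: np.ndarray
    fixed: bool = False


class AssemblyState:
    """Bead pool + chains + rigid bodies for one symmetry unit."""

    def __init__(
        self,
        coords: np.ndarray,
        radii: np.ndarray,
        nres: np.ndarray,
        resrange: np.ndarray,
        is_coarse: np.ndarray,
        chains: list[ChainInfo],
        rigid_bodies: list[RigidBody] | None = None,
    ):
        self.coords = np.ascontiguousarray(coords, dtype=np.float64)
        self.radii = np.asarray(radii, dtype=np.float64)
        self.nres = np.asarray(nres, dtype=np.intp)
        self.resrange = np.asarray(resrange, dtype=np.intp)
        self.is_coarse = np.asarray(is_coarse, dtype=bool)
        self.chains = chains
        self.rigid_bodies = rigid_bodies or []
        self._validate()

    # -- construction ------------------------------------------------------

    def _validate(self) -> None:
        n = len(self.coords)
        if not (len(self.radii) == len(self.nres) == len(self.resrange) == len(self.is_coarse) == n):
            raise ValueError("bead array lengths disagree")
        if n and np.any(self.radii <= 0):
            raise ValueError("bead radii must be positive")
        seen = np.zeros(n, dtype=int)
        for ch in self.chains:
            for idx in (ch.coarse, ch.fine):
                seen[idx] += 1
        if np.any(seen != 1):
            raise ValueError("every bead must belong to exactly one chain")
        in_body = np.zeros(n, dtype=int)
        for rb in self.rigid_bodies:
            in_body[rb.bead_idx] += 1
        if np.any(in_body > 1):
            raise ValueError("a bead may belong to at most one rigid body")

    @classmethod
    def from_chains(
        cls,
        chain_beads: list[dict],
        rigid_groups: list[tuple[list[int], bool]] | None = None,
    ) -> "AssemblyState":
        """Assemble a state from per-chain bead dicts.

        Each dict has keys ``subunit, copy_index, role, centers, radii,
        resranges`` and optionally ``fine_centers, fine_radii, fine_resranges``.
        ``rigid_groups`` lists (global bead indices, fixed) pairs referring to
        the concatenated pool in chain order (coarse then fine per chain).
        """
        coords, radii, nres, rr, isc, chains = [], [], [], [], [], []
        offset = 0
        for cb in chain_beads:
            c = np.atleast_2d(np.asarray(cb["centers"], dtype=float))
            r = np.asarray(cb["radii"], dtype=float)
            ranges = np.asarray(cb["resranges"], dtype=np.intp).reshape(-1, 2)
            k = len(c)
            coarse_idx = np.arange(offset, offset + k, dtype=np.intp)
            offset += k
            fc = cb.get("fine_centers")
            if fc is not None and len(fc):
                fc = np.atleast_2d(np.asarray(fc, dtype=float))
                fr = np.asarray(cb["fine_radii"], dtype=float)
                franges = np.asarray(cb["fine_resranges"], dtype=np.intp).reshape(-1, 2)
                fine_idx = np.arange(offset, offset + len(fc), dtype=np.intp)
                offset += len(fc)
            else:
                fc = np.empty((0, 3))
                fr = np.empty(0)
                franges = np.empty((0, 2), dtype=np.intp)
                fine_idx = np.empty(0, dtype=np.intp)
            coords.append(c)
            coords.append(fc)
            radii.extend([r, fr])
            rr.extend([ranges, franges])
            nres.extend([ranges[:, 1] - ranges[:, 0] + 1, franges[:, 1] - franges[:, 0] + 1])
            isc.extend([np.ones(k, dtype=bool), np.zeros(len(fc), dtype=bool)])
            chains.append(
                ChainInfo(
                    subunit=cb["subunit"],
                    copy_index=int(cb.get("copy_index", 0)),
                    role=cb.get("role", "component"),
                    coarse=coarse_idx,
                    fine=fine_idx,
                )
            )
        bodies = [
            RigidBody(bead_idx=np.asarray(idx, dtype=np.intp), fixed=fixed)
            for idx, fixed in (rigid_groups or [])
        ]
        return cls(
            np.vstack(coords) if coords else np.empty((0, 3)),
            np.concatenate(radii) if radii else np.empty(0),
            np.concatenate(nres) if nres else np.empty(0, dtype=np.intp),
            np.vstack(rr) if rr else np.empty((0, 2), dtype=np.intp),
            np.concatenate(isc) if isc else np.empty(0, dtype=bool),
            chains,
            bodies,
        )

    # -- views -------------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def coarse_idx(self) -> np.ndarray:
        return np.flatnonzero(self.is_coarse)

    @property
    def coarse_coords(self) -> np.ndarray:
        return self.coords[self.is_coarse]

    def subunit_names(self) -> list[str]:
        return sorted({ch.subunit for ch in self.chains})

    def chains_of(self, subunit: str) -> list[ChainInfo]:
        return [ch for ch in self.chains if ch.subunit == subunit]

    def get_chain(self, subunit: str, copy_index: int) -> ChainInfo:
        for ch in self.chains:
            if ch.subunit == subunit and ch.copy_index == copy_index:
                return ch
        raise KeyError(f"no chain {subunit!r} copy {copy_index}")

    def total_residues(self) -> int:
        """Residues represented at the coarse level (the primary resolution)."""
        return int(self.nres[self.is_coarse].sum())

    def fixed_bead_idx(self) -> np.ndarray:
        idx = [rb.bead_idx for rb in self.rigid_bodies if rb.fixed]
        return np.concatenate(idx) if idx else np.empty(0, dtype=np.intp)

    def movable_bodies(self) -> list[RigidBody]:
        return [rb for rb in self.rigid_bodies if not rb.fixed]

    def flexible_idx(self) -> np.ndarray:
        """Coarse beads not claimed by any rigid body: moved individually."""
        in_body = np.zeros(self.n_beads, dtype=bool)
        for rb in self.rigid_bodies:
            in_body[rb.bead_idx] = True
        return np.flatnonzero(self.is_coarse & ~in_body)

    # -- residue mapping ---------------------------------------------------

    def residue_to_bead(self, chain: ChainInfo, residue: int) -> int:
        """Finest bead of ``chain`` whose residue range contains ``residue``."""
        for pool in (chain.fine, chain.coarse):
            if len(pool) == 0:
                continue
            lo = self.resrange[pool, 0]
            hi = self.resrange[pool, 1]
            hit = np.flatnonzero((lo <= residue) & (residue <= hi))
            if len(hit):
                return int(pool[hit[0]])
        raise KeyError(f"residue {residue} not represented in {chain.subunit} copy {chain.copy_index}")

    def residue_to_beads_all_copies(self, subunit: str, residue: int) -> list[int]:
        """Candidate beads for a residue over every copy of ``subunit``."""
        chains = self.chains_of(subunit)
        if not chains:
            raise KeyError(f"unknown subunit {subunit!r}")
        return [self.residue_to_bead(ch, residue) for ch in chains]

    # -- geometry ----------------------------------------------------------

    def copy(self) -> "AssemblyState":
        st = AssemblyState.__new__(AssemblyState)
        st.coords = self.coords.copy()
        st.radii = self.radii
        st.nres = self.nres
        st.resrange = self.resrange
        st.is_coarse = self.is_coarse
        st.chains = self.chains
        st.rigid_bodies = self.rigid_bodies
        return st

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AssemblyState":
        st = self.copy()
        st.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return st
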