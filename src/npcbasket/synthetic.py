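"""Synthetic basket-like ground truth and simulated restraint inputs.

The generator emulates, with a known ground truth, everything the modeling
pipeline consumes: a fixed two-tier scaffold ring segment (the double nuclear
ring of one C8 unit), straight coiled-coil-like strut rods tilted from the
central axis and terminating in a distal blob, flexible anchor chains near
the scaffold, DSS-style crosslinks (within-cutoff residue pairs plus an
exactly counted false-positive fraction), a noisy Gaussian-mixture density
of the truth, and terminal-domain localizations with Gaussian uncertainty.

Geometry presets follow the measured basket dimensions: yeast — struts
tilted 30 deg from the central axis, distal densities 540 A below the
scaffold ring, distal ring diameter ~760 A, struts ~100 A thick; mouse —
6 deg tilt, 630 A offset, ~1000 A distal diameter.  The scaffold ring
radius is derived from these (straight-rod geometry) unless overridden.

Strut beads take their radius from the strut thickness (the rod's physical
cross-section); scaffold and anchor beads use the volume-proportional policy
of the representation module.  Residue windows are assigned so simulated
crosslinks address residues, exactly like real CX-MS input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .assembly import AssemblyState, rotation_about_z
from .gmm import GaussianMixture, model_to_gmm
from .representation import bead_radius
from .restraints import CrosslinkRecord, PositionalSpec, DEFAULT_XL_CUTOFF

__all__ = [
    "GroundTruthParams",
    "GroundTruthBundle",
    "yeast_params",
    "mouse_params",
    "make_ground_truth",
    "simulate_crosslinks",
    "simulate_density",
    "simulate_terminal_localizations",
    "simulate_membrane_anchors",
    "make_bundle",
    "measure_geometry",
]


@dataclass(frozen=True)
class GroundTruthParams:
    """Geometry and size parameters of the synthetic basket truth."""

    n_symmetry: int = 8
    strut_tilt: float = 30.0            # deg from the central axis
    distal_offset: float = 540.0        # A below the scaffold ring plane
    distal_ring_diameter: float = 760.0  # A
    strut_thickness: float = 100.0      # A (bead diameter of the rod)
    strut_start_offset: float = 60.0    # A along the rod before the first bead
    strut_copy_azimuth: float = 8.5     # deg; copies sit at +/- this azimuth
    scaffold_ring_radius: float | None = None  # A; derived if None
    beads_per_strut: int = 12
    strut_copies: int = 2
    residues_per_strut_bead: int = 100
    distal_blob_residues: int = 200
    anchor_chain_lengths: tuple[int, ...] = (300, 250)  # residues
    anchor_residues_per_bead: int = 50
    scaffold_beads_per_tier: int = 6
    scaffold_tier_separation: float = 50.0  # A between the two ring tiers
    scaffold_bead_radius: float = 15.0
    scaffold_residues_per_bead: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_symmetry < 1:
            raise ValueError("n_symmetry must be >= 1")
        if not (0.0 <= self.strut_tilt < 90.0):
            raise ValueError("strut_tilt must be in [0, 90) degrees")
        for name in ("distal_offset", "distal_ring_diameter", "strut_thickness",
                     "scaffold_tier_separation", "scaffold_bead_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.scaffold_ring_radius is not None and self.scaffold_ring_radius <= 0:
            raise ValueError("scaffold_ring_radius must be positive")
        if self.beads_per_strut < 2:
            raise ValueError("beads_per_strut must be >= 2")

    @property
    def derived_scaffold_radius(self) -> float:
        if self.scaffold_ring_radius is not None:
            return self.scaffold_ring_radius
        return self.distal_ring_diameter / 2.0 + self.distal_offset * np.tan(
            np.deg2rad(self.strut_tilt)
        )


def yeast_params(seed: int = 0) -> GroundTruthParams:
    """Yeast basket geometry: 30 deg tilt, 540 A offset, 760 A distal ring."""
    return GroundTruthParams(seed=seed)


def mouse_params(seed: int = 0) -> GroundTruthParams:
    """Mouse basket geometry: 6 deg tilt, 630 A offset, ~1000 A distal ring."""
    return GroundTruthParams(
        strut_tilt=6.0, distal_offset=630.0, distal_ring_diameter=1000.0, seed=seed
    )


# ---------------------------------------------------------------------------
# Truth construction
# ---------------------------------------------------------------------------

def make_ground_truth(params: GroundTruthParams) -> AssemblyState:
    """Build one symmetry unit of the synthetic basket truth.

    Deterministic in ``params.seed``.  The unit contains a fixed two-tier
    scaffold arc (one rigid body), ``strut_copies`` straight strut rods (one
    rigid body each, including the distal blob bead), and flexible anchor
    chains random-walked near the scaffold.
    """
    rng = np.random.default_rng(params.seed)
    r0 = params.derived_scaffold_radius
    tilt = np.deg2rad(params.strut_tilt)
    chain_beads: list[dict] = []
    rigid_groups: list[tuple[list[int], bool]] = []
    offset = 0

    # scaffold: two tiers of an arc spanning one symmetry wedge
    wedge = 2.0 * np.pi / params.n_symmetry
    nb = params.scaffold_beads_per_tier
    phis = (np.arange(nb) + 0.5) / nb * wedge - wedge / 2.0
    scaffold_idx = []
    for tier, z in enumerate((0.0, params.scaffold_tier_separation)):
        centers = np.column_stack(
            [r0 * np.cos(phis), r0 * np.sin(phis), np.full(nb, z)]
        )
        ranges = np.column_stack(
            [np.arange(nb) * params.scaffold_residues_per_bead + 1,
             (np.arange(nb) + 1) * params.scaffold_residues_per_bead]
        )
        chain_beads.append(
            {"subunit": "ScaffoldRing", "copy_index": tier, "role": "scaffold",
             "centers": centers, "radii": np.full(nb, params.scaffold_bead_radius),
             "resranges": ranges}
        )
        scaffold_idx.extend(range(offset, offset + nb))
        offset += nb
    rigid_groups.append((scaffold_idx, True))

    # struts: straight rods in the r-z plane, ending in a distal blob bead.
    # The rod's topmost stretch (strut_start_offset) is left unrepresented so
    # the first bead clears the scaffold tier sterically.
    rod_len = params.distal_offset / np.cos(tilt)
    nb = params.beads_per_strut
    t = params.strut_start_offset + (np.arange(nb) + 0.5) / nb * (
        rod_len - params.strut_start_offset
    )
    if params.strut_copies > 1:
        azimuths = np.linspace(
            -params.strut_copy_azimuth, params.strut_copy_azimuth, params.strut_copies
        )
    else:
        azimuths = [0.0]
    for copy_idx, az in enumerate(azimuths):
        base = np.column_stack(
            [r0 - t * np.sin(tilt), np.zeros(nb), -t * np.cos(tilt)]
        )
        blob = np.array(
            [[r0 - rod_len * np.sin(tilt), 0.0, -params.distal_offset]]
        )
        rot = rotation_about_z(np.deg2rad(az))
        centers = np.vstack([base, blob]) @ rot.T
        rpb = params.residues_per_strut_bead
        ranges = np.column_stack(
            [np.arange(nb) * rpb + 1, (np.arange(nb) + 1) * rpb]
        )
        ranges = np.vstack(
            [ranges, [nb * rpb + 1, nb * rpb + params.distal_blob_residues]]
        )
        radii = np.full(nb + 1, params.strut_thickness / 2.0)
        radii[-1] *= 1.1  # globular distal blob
        chain_beads.append(
            {"subunit": "Strut", "copy_index": copy_idx, "role": "strut",
             "centers": centers, "radii": radii, "resranges": ranges}
        )
        rigid_groups.append((list(range(offset, offset + nb + 1)), False))
        offset += nb + 1

    # anchor chains: compact seeded random walks starting at scaffold beads,
    # with steric clearance against everything already placed (except the
    # walk's immediate predecessor, which is a bonded contact)
    placed_xyz = np.vstack([cb["centers"] for cb in chain_beads])
    placed_r = np.concatenate([cb["radii"] for cb in chain_beads])
    for a, n_res in enumerate(params.anchor_chain_lengths):
        rpb = params.anchor_residues_per_bead
        nb = int(np.ceil(n_res / rpb))
        ranges = np.column_stack(
            [np.arange(nb) * rpb + 1, np.minimum((np.arange(nb) + 1) * rpb, n_res)]
        )
        radii = bead_radius(ranges[:, 1] - ranges[:, 0] + 1)
        start_bead = 2 * a  # spread anchors along the tier-0 arc
        anchor_to = chain_beads[0]["centers"][start_bead % params.scaffold_beads_per_tier]
        # first bead sits just clear of its scaffold bead but inside DSS
        # range, so an anchor-scaffold residue pair is always crosslinkable
        start = anchor_to + np.array(
            [0.0, 0.0, -(params.scaffold_bead_radius + radii[0] + 5.0)]
        )
        centers = [start]
        for b in range(1, nb):
            step_len = radii[b - 1] + radii[b]
            best = None
            for _ in range(60):
                step = rng.normal(size=3)
                step *= step_len / np.linalg.norm(step)
                cand = centers[-1] + step
                cand[2] = np.clip(cand[2], -120.0, 30.0)
                clear_fixed = np.linalg.norm(placed_xyz - cand, axis=1) - (
                    placed_r + radii[b]
                )
                prev = np.asarray(centers[:-1])
                clear_own = (
                    np.linalg.norm(prev - cand, axis=1) - (radii[: b - 1] + radii[b])
                    if len(prev)
                    else np.array([np.inf])
                )
                worst = min(clear_fixed.min(), clear_own.min())
                if best is None or worst > best[0]:
                    best = (worst, cand)
                if worst >= 0:
                    break
            centers.append(best[1])
        centers = np.asarray(centers)
        chain_beads.append(
            {"subunit": f"Anchor{a + 1}", "copy_index": 0, "role": "anchor",
             "centers": centers, "radii": radii, "resranges": ranges}
        )
        placed_xyz = np.vstack([placed_xyz, centers])
        placed_r = np.concatenate([placed_r, radii])
        offset += nb

    return AssemblyState.from_chains(chain_beads, rigid_groups)


def measure_geometry(truth: AssemblyState) -> dict:
    """Measured strut tilt (deg), distal offset (A), and distal ring diameter
    (A) of a truth state, recovered from the bead coordinates alone."""
    tilts, offsets, ring_r = [], [], []
    for ch in truth.chains:
        if ch.role != "strut":
            continue
        xyz = truth.coords[ch.coarse]
        rod = xyz[:-1] if len(xyz) > 2 else xyz
        centered = rod - rod.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0] / np.linalg.norm(vt[0])
        tilts.append(np.rad2deg(np.arccos(abs(axis[2]))))
        offsets.append(-xyz[-1, 2])
        ring_r.append(np.linalg.norm(xyz[-1, :2]))
    if not tilts:
        raise ValueError("state has no strut chains")
    return {
        "strut_tilt": float(np.mean(tilts)),
        "distal_offset": float(np.mean(offsets)),
        "distal_ring_diameter": float(2.0 * np.mean(ring_r)),
    }


# ---------------------------------------------------------------------------
# Simulated inputs
# ---------------------------------------------------------------------------

def _residue_pair_pool(truth: AssemblyState):
    """All distinct-bead coarse pairs with chain/range bookkeeping."""
    coarse = truth.coarse_idx
    sub = {}
    for ch in truth.chains:
        for b in ch.coarse:
            sub[int(b)] = (ch.subunit, ch.copy_index)
    iu, ju = np.triu_indices(len(coarse), k=1)
    i, j = coarse[iu], coarse[ju]
    d = np.linalg.norm(truth.coords[i] - truth.coords[j], axis=1)
    return i, j, d, sub


def simulate_crosslinks(
    truth: AssemblyState,
    cutoff: float = DEFAULT_XL_CUTOFF,
    n_true: int = 60,
    fp_rate: float = 0.0,
    seed: int = 0,
) -> list[CrosslinkRecord]:
    """DSS-style crosslinks: residue pairs sampled from within-cutoff bead
    pairs, plus ``floor(n_true * fp_rate / (1 - fp_rate))`` false positives
    drawn exclusively from beyond-cutoff pairs (so violation counts are
    exact).  Deterministic in ``seed``.
    """
    if not 0.0 <= fp_rate < 1.0:
        raise ValueError("fp_rate must be in [0, 1)")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    i, j, d, sub = _residue_pair_pool(truth)
    good = np.flatnonzero(d <= cutoff)
    bad = np.flatnonzero(d > cutoff)
    if len(good) == 0:
        raise RuntimeError(
            f"no residue pairs within the {cutoff:.1f} A cutoff; "
            "cannot simulate crosslinks"
        )
    n_fp = int(np.floor(n_true * fp_rate / (1.0 - fp_rate)))
    if n_fp > 0 and len(bad) == 0:
        raise RuntimeError(f"no residue pairs beyond the {cutoff:.1f} A cutoff")
    rng = np.random.default_rng(seed)

    def draw(pool: np.ndarray, n: int) -> list[CrosslinkRecord]:
        picks = rng.choice(pool, size=n, replace=True)
        recs = []
        for p in picks:
            b1, b2 = int(i[p]), int(j[p])
            s1, s2 = sub[b1], sub[b2]
            r1 = int(rng.integers(truth.resrange[b1, 0], truth.resrange[b1, 1] + 1))
            r2 = int(rng.integers(truth.resrange[b2, 0], truth.resrange[b2, 1] + 1))
            recs.append(CrosslinkRecord(s1[0], r1, s2[0], r2, "DSS"))
        return recs

    return draw(good, n_true) + draw(bad, n_fp)


def simulate_density(
    truth: AssemblyState,
    sigma_scale: float = 1.0,
    jitter: float = 0.0,
    seed: int = 0,
) -> GaussianMixture:
    """Noisy mixture of the truth: one Gaussian per coarse bead with width
    sigma_scale * radius, means displaced by isotropic Gaussian jitter,
    weights proportional to bead residue counts."""
    if sigma_scale <= 0:
        raise ValueError("sigma_scale must be positive")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    base = model_to_gmm(truth, sigma_scale)
    rng = np.random.default_rng(seed)
    means = base.means + (rng.normal(size=base.means.shape) * jitter if jitter else 0.0)
    return GaussianMixture(base.weights, means, base.sigmas)


def simulate_membrane_anchors(
    truth: AssemblyState, z_range: tuple[float, float] = (-120.0, 30.0)
) -> list[PositionalSpec]:
    """Slab restraints keeping anchor-chain N-termini near the envelope.

    Emulates sequence-based predictions that the N-terminal segments of the
    FG-Nup anchors lie at the nuclear envelope: one z-slab spec per anchor
    chain, on its first bead's residue window.
    """
    z0, z1 = z_range
    specs = []
    for ch in truth.chains:
        if ch.role != "anchor":
            continue
        bead = ch.coarse[0]
        lo, hi = truth.resrange[bead]
        specs.append(
            PositionalSpec(
                kind="membrane-slab",
                subunit=ch.subunit,
                res_start=int(lo),
                res_end=int(hi),
                target=(float(z0), float(z1)),
                copy_index=ch.copy_index,
            )
        )
    return specs


def simulate_terminal_localizations(
    truth: AssemblyState, sigma: float = 20.0
) -> list[PositionalSpec]:
    """Immuno-EM-style point targets at the true N- and C-terminal bead
    positions of every strut chain, with stated uncertainty ``sigma``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    struts = [ch for ch in truth.chains if ch.role == "strut"]
    if not struts:
        raise ValueError("state has no chains annotated as struts")
    specs = []
    for ch in struts:
        for bead, which in ((ch.coarse[0], "N"), (ch.coarse[-1], "C")):
            lo, hi = truth.resrange[bead]
            specs.append(
                PositionalSpec(
                    kind="terminal-localization",
                    subunit=ch.subunit,
                    res_start=int(lo),
                    res_end=int(hi),
                    target=truth.coords[bead].copy(),
                    tolerance=float(sigma),
                    copy_index=ch.copy_index,
                )
            )
    return specs


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthBundle:
    """Truth state plus every simulated input, regenerable from params+seed."""

    truth_state: AssemblyState
    crosslinks: list[CrosslinkRecord]
    density: GaussianMixture
    terminal_localizations: list[PositionalSpec]
    params: GroundTruthParams
    seed: int
    membrane_anchors: list[PositionalSpec] = field(default_factory=list)
    xl_cutoff: float = DEFAULT_XL_CUTOFF
    em_sigma_scale: float = 1.0


def make_bundle(
    params: GroundTruthParams,
    n_true: int = 60,
    fp_rate: float = 0.0,
    xl_cutoff: float = DEFAULT_XL_CUTOFF,
    sigma_scale: float = 1.0,
    jitter: float = 0.0,
    localization_sigma: float = 20.0,
) -> GroundTruthBundle:
    """Generate the full synthetic study bundle (deterministic in params.seed)."""
    truth = make_ground_truth(params)
    ss = np.random.SeedSequence(params.seed)
    xl_seed, dens_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    return GroundTruthBundle(
        truth_state=truth,
        crosslinks=simulate_crosslinks(truth, xl_cutoff, n_true, fp_rate, xl_seed),
        density=simulate_density(truth, sigma_scale, jitter, dens_seed),
        terminal_localizations=simulate_terminal_localizations(truth, localization_sigma),
        params=params,
        seed=params.seed,
        membrane_anchors=simulate_membrane_anchors(truth),
        xl_cutoff=xl_cutoff,
        em_sigma_scale=sigma_scale,
    )
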