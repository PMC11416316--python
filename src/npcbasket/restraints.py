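"""Spatial restraints and their weighted sum.

Every data term is a one-sided harmonic: zero inside its bound, and
``0.5 * k * excess**2`` outside, with stiffness ``k`` in kT/A^2 (default 1).
Terms:

* crosslinks — upper bound (default 35 A, the usual DSS Calpha-Calpha
  convention) on the minimum bead-center distance over all copy assignments
  of the two crosslinked residues;
* density — ``w * (1 - CC)`` where CC is the Gaussian-mixture
  cross-correlation between the model and the map;
* positional — point targets with a tolerance (immuno-EM terminal-domain
  localizations) and z-slabs (membrane anchors);
* proximity — upper bound on the minimum distance between two domains
  (affinity co-purification contacts);
* connectivity — upper bound at ``c * (r_i + r_j)`` between consecutive
  beads of a chain (default c = 1.2);
* excluded volume — lower bound at ``r_i + r_j`` between non-bonded bead
  pairs at the coarse resolution, excluding pairs inside one rigid body;
* structural equivalence — superposition-free matching of intra-model
  pairwise distances across two assemblies through a residue alignment.

:class:`ScoringFunction` compiles a restraint bundle against a fixed topology
into vectorized index arrays for fast repeated evaluation during sampling;
the standalone ``score_*`` functions are the reference implementations and
the two are cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .assembly import AssemblyState, rotation_about_z
from .gmm import GaussianMixture, cross_correlation, gmm_overlap, model_to_gmm

__all__ = [
    "CrosslinkRecord",
    "PositionalSpec",
    "ProximityPair",
    "RestraintWeights",
    "RestraintBundle",
    "RestraintSetupError",
    "crosslink_candidates",
    "score_crosslinks",
    "score_em",
    "score_positional",
    "score_proximity",
    "score_connectivity",
    "score_excluded_volume",
    "score_equivalence",
    "total_score",
    "ScoringFunction",
]

DEFAULT_XL_CUTOFF = 35.0  # A, DSS Calpha-Calpha upper bound
CONNECTIVITY_SCALE = 1.2


class RestraintSetupError(ValueError):
    """A restraint datum cannot be mapped onto the representation."""


@dataclass(frozen=True)
class CrosslinkRecord:
    """One crosslinked residue pair; ambiguity over copies is implicit."""

    protein1: str
    residue1: int
    protein2: str
    residue2: int
    linker: str = "DSS"
    multiplicity: int = 1

    def __post_init__(self):
        if self.residue1 < 1 or self.residue2 < 1:
            raise ValueError("residue indices are 1-based and must be >= 1")

    def unordered_key(self) -> tuple:
        a = (self.protein1, self.residue1)
        b = (self.protein2, self.residue2)
        return (a, b, self.linker) if a <= b else (b, a, self.linker)


@dataclass
class PositionalSpec:
    """Point-target or z-slab positional restraint on a residue range."""

    kind: str  # "terminal-localization" | "membrane-slab"
    subunit: str
    res_start: int
    res_end: int
    target: tuple | np.ndarray  # xyz point, or (z_min, z_max) slab
    tolerance: float = 0.0
    copy_index: int | None = None  # None = ambiguous over copies (min rule)

    def __post_init__(self):
        if self.kind not in ("terminal-localization", "membrane-slab"):
            raise ValueError(f"unknown positional kind {self.kind!r}")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.kind == "membrane-slab":
            z0, z1 = self.target
            if not z0 < z1:
                raise ValueError("slab needs z_min < z_max")
        else:
            self.target = np.asarray(self.target, dtype=float).reshape(3)


@dataclass(frozen=True)
class ProximityPair:
    """Upper bound on the minimum distance between two domains.

    A domain is (subunit, res_start, res_end); copies are ambiguous.
    """

    domain_a: tuple
    domain_b: tuple
    max_distance: float


@dataclass
class RestraintWeights:
    """Per-term multipliers of the total score (all >= 0).

    The density weight multiplies (1 - CC) directly; because CC varies on a
    0..1 scale while the harmonic terms are in kT, it defaults much larger so
    the map term competes during sampling.
    """

    crosslink: float = 1.0
    em: float = 1000.0
    positional: float = 1.0
    proximity: float = 1.0
    connectivity: float = 1.0
    excluded_volume: float = 1.0
    equivalence: float = 1.0

    def __post_init__(self):
        if any(v < 0 for v in asdict(self).values()):
            raise ValueError("restraint weights must be >= 0")


@dataclass
class RestraintBundle:
    """All data terms for one scoring problem."""

    crosslinks: list[CrosslinkRecord] = field(default_factory=list)
    map_gmm: GaussianMixture | None = None
    positional: list[PositionalSpec] = field(default_factory=list)
    proximity: list[ProximityPair] = field(default_factory=list)
    reference: AssemblyState | None = None
    alignment: list[tuple] = field(default_factory=list)  # ((sub,copy,res),(sub,copy,res))
    xl_cutoff: float = DEFAULT_XL_CUTOFF
    stiffness: float = 1.0
    em_sigma_scale: float = 1.0
    connectivity_scale: float = CONNECTIVITY_SCALE


def _harmonic_upper(d: np.ndarray, bound: float | np.ndarray, k: float) -> np.ndarray:
    excess = np.maximum(0.0, d - bound)
    return 0.5 * k * excess**2


def _harmonic_lower(d: np.ndarray, bound: float | np.ndarray, k: float) -> np.ndarray:
    deficit = np.maximum(0.0, bound - d)
    return 0.5 * k * deficit**2


# ---------------------------------------------------------------------------
# Crosslinks
# ---------------------------------------------------------------------------

def crosslink_candidates(state: AssemblyState, rec: CrosslinkRecord) -> np.ndarray:
    """All (bead_i, bead_j) assignments of a record over subunit copies.

    Self-assignments (identical bead from the same copy of the same protein
    and residue) are dropped; a record with no valid assignment raises
    :class:`RestraintSetupError`.
    """
    try:
        beads1 = state.residue_to_beads_all_copies(rec.protein1, rec.residue1)
        beads2 = state.residue_to_beads_all_copies(rec.protein2, rec.residue2)
    except KeyError as exc:
        raise RestraintSetupError(f"cannot map crosslink {rec}: {exc}") from exc
    pairs = [(i, j) for i in beads1 for j in beads2 if i != j]
    if not pairs:
        raise RestraintSetupError(f"crosslink {rec} has no non-self assignment")
    return np.asarray(pairs, dtype=np.intp)


def score_crosslinks(
    state: AssemblyState,
    links: list[CrosslinkRecord],
    cutoff: float = DEFAULT_XL_CUTOFF,
    k: float = 1.0,
    n_symmetry: int | None = None,
):
    """Total crosslink penalty and per-link effective distances.

    The effective distance d* of a link is the minimum bead-center distance
    over all copy assignments; penalty = 0.5*k*(d* - cutoff)^2 when d* exceeds
    the cutoff.  With ``n_symmetry`` set, assignments additionally consider
    the rotational images of fixed-scaffold beads (contacts across the
    symmetry-unit interface).
    """
    details = []
    total = 0.0
    fixed = set(state.fixed_bead_idx().tolist())
    rots = None
    if n_symmetry and n_symmetry > 1:
        rots = [rotation_about_z(2 * np.pi * s / n_symmetry) for s in (1, n_symmetry - 1)]
    for rec in links:
        pairs = crosslink_candidates(state, rec)
        d = np.linalg.norm(state.coords[pairs[:, 0]] - state.coords[pairs[:, 1]], axis=1)
        dmin = d.min()
        if rots is not None:
            for i, j in pairs:
                for fix, mob in ((i, j), (j, i)):
                    if fix in fixed:
                        for rot in rots:
                            img = state.coords[fix] @ rot.T
                            dmin = min(dmin, float(np.linalg.norm(img - state.coords[mob])))
        pen = float(_harmonic_upper(np.array(dmin), cutoff, k))
        total += pen
        details.append(
            {"record": rec, "distance": float(dmin), "penalty": pen,
             "satisfied": bool(dmin <= cutoff)}
        )
    return total, details


# ---------------------------------------------------------------------------
# Density
# ---------------------------------------------------------------------------

def score_em(model_gmm: GaussianMixture, map_gmm: GaussianMixture, weight: float = 1.0):
    """(CC, weight * (1 - CC)) for two mixtures."""
    cc = cross_correlation(model_gmm, map_gmm)
    return cc, weight * (1.0 - cc)


# ---------------------------------------------------------------------------
# Positional
# ---------------------------------------------------------------------------

def _spec_beads(state: AssemblyState, spec: PositionalSpec) -> list[int]:
    mid = (spec.res_start + spec.res_end) // 2
    if spec.copy_index is not None:
        ch = state.get_chain(spec.subunit, spec.copy_index)
        return [state.residue_to_bead(ch, mid)]
    try:
        return state.residue_to_beads_all_copies(spec.subunit, mid)
    except KeyError as exc:
        raise RestraintSetupError(f"cannot map positional spec {spec}: {exc}") from exc


def score_positional(state: AssemblyState, specs: list[PositionalSpec], k: float = 1.0):
    """Harmonic penalties on point-target excess distance / slab excursion.

    Point kind: penalty on (distance - tolerance) when the representative
    bead of the residue range lies beyond the tolerance.  Slab kind: penalty
    on the z-excursion outside [z_min, z_max].  Copy-ambiguous specs take the
    best copy (minimum penalty).
    """
    total = 0.0
    per_spec = []
    for spec in specs:
        beads = _spec_beads(state, spec)
        if spec.kind == "terminal-localization":
            d = np.linalg.norm(state.coords[beads] - spec.target, axis=1)
            pens = _harmonic_upper(d, spec.tolerance, k)
        else:
            z0, z1 = spec.target
            z = state.coords[beads, 2]
            exc = np.maximum(0.0, np.maximum(z0 - z, z - z1))
            pens = 0.5 * k * exc**2
        best = float(pens.min())
        total += best
        per_spec.append({"spec": spec, "penalty": best})
    return total, per_spec


# ---------------------------------------------------------------------------
# Proximity
# ---------------------------------------------------------------------------

def _domain_beads(state: AssemblyState, domain: tuple) -> np.ndarray:
    sub, lo, hi = domain
    chains = state.chains_of(sub)
    if not chains:
        raise RestraintSetupError(f"unknown subunit {sub!r} in proximity domain")
    out = []
    for ch in chains:
        pool = ch.fine if len(ch.fine) else ch.coarse
        sel = pool[(state.resrange[pool, 0] <= hi) & (state.resrange[pool, 1] >= lo)]
        out.append(sel)
    idx = np.concatenate(out) if out else np.empty(0, dtype=np.intp)
    if len(idx) == 0:
        raise RestraintSetupError(f"proximity domain {domain} maps to no beads")
    return idx


def score_proximity(state: AssemblyState, pairs: list[ProximityPair], k: float = 1.0):
    """Harmonic upper bound on the minimum inter-domain bead distance."""
    total = 0.0
    per_pair = []
    for pr in pairs:
        a = _domain_beads(state, pr.domain_a)
        b = _domain_beads(state, pr.domain_b)
        d = cdist(state.coords[a], state.coords[b]).min()
        pen = float(_harmonic_upper(np.array(d), pr.max_distance, k))
        total += pen
        per_pair.append({"pair": pr, "distance": float(d), "penalty": pen})
    return total, per_pair


# ---------------------------------------------------------------------------
# Connectivity & excluded volume
# ---------------------------------------------------------------------------

def _body_id(state: AssemblyState) -> np.ndarray:
    body = -np.ones(state.n_beads, dtype=np.intp)
    for b, rb in enumerate(state.rigid_bodies):
        body[rb.bead_idx] = b
    return body


def _connectivity_pairs(state: AssemblyState, c: float):
    body = _body_id(state)
    i1, i2 = [], []
    for ch in state.chains:
        for a, b in zip(ch.coarse[:-1], ch.coarse[1:]):
            # pairs inside one rigid body are held by the rigidity itself
            if body[a] >= 0 and body[a] == body[b]:
                continue
            i1.append(a)
            i2.append(b)
    i1 = np.asarray(i1, dtype=np.intp)
    i2 = np.asarray(i2, dtype=np.intp)
    thresh = c * (state.radii[i1] + state.radii[i2]) if len(i1) else np.empty(0)
    return i1, i2, thresh


def score_connectivity(state: AssemblyState, c: float = CONNECTIVITY_SCALE, k: float = 1.0):
    """Chain connectivity: upper bound c*(r_i+r_j) between consecutive beads
    (pairs inside one rigid body are constant and skipped)."""
    i1, i2, thresh = _connectivity_pairs(state, c)
    if len(i1) == 0:
        return 0.0
    d = np.linalg.norm(state.coords[i1] - state.coords[i2], axis=1)
    return float(_harmonic_upper(d, thresh, k).sum())


def _ev_pairs(state: AssemblyState):
    """Non-bonded coarse bead pairs: excludes consecutive-in-chain pairs and
    pairs within one rigid body."""
    coarse = state.coarse_idx
    pos = -np.ones(state.n_beads, dtype=np.intp)
    pos[coarse] = np.arange(len(coarse))
    n = len(coarse)
    exclude = np.zeros((n, n), dtype=bool)
    for ch in state.chains:
        a, b = pos[ch.coarse[:-1]], pos[ch.coarse[1:]]
        exclude[a, b] = exclude[b, a] = True
    for rb in state.rigid_bodies:
        members = pos[rb.bead_idx]
        members = members[members >= 0]
        exclude[np.ix_(members, members)] = True
    iu, ju = np.triu_indices(n, k=1)
    keep = ~exclude[iu, ju]
    return coarse[iu[keep]], coarse[ju[keep]]


def score_excluded_volume(
    state: AssemblyState,
    k: float = 1.0,
    include_symmetry_images: bool = False,
    n_symmetry: int = 8,
):
    """Soft-sphere lower bound at r_i + r_j over non-bonded coarse pairs.

    With ``include_symmetry_images`` the unit is additionally scored against
    its two adjacent rotational images (the only ones a ring unit can touch).
    """
    i1, i2 = _ev_pairs(state)
    total = 0.0
    if len(i1):
        d = np.linalg.norm(state.coords[i1] - state.coords[i2], axis=1)
        total += float(_harmonic_lower(d, state.radii[i1] + state.radii[i2], k).sum())
    if include_symmetry_images and n_symmetry > 1:
        coarse = state.coarse_idx
        xyz = state.coords[coarse]
        radii = state.radii[coarse]
        bounds = radii[:, None] + radii[None, :]
        for s in {1, n_symmetry - 1}:
            rot = rotation_about_z(2 * np.pi * s / n_symmetry)
            d = cdist(xyz, xyz @ rot.T)
            total += 0.5 * float(_harmonic_lower(d, bounds, k).sum())
    return total


# ---------------------------------------------------------------------------
# Structural equivalence
# ---------------------------------------------------------------------------

def _aligned_beads(state: AssemblyState, entries: list[tuple]) -> np.ndarray:
    idx = []
    for sub, copy_idx, res in entries:
        ch = state.get_chain(sub, copy_idx)
        idx.append(state.residue_to_bead(ch, res))
    return np.asarray(idx, dtype=np.intp)


def score_equivalence(
    state: AssemblyState,
    reference: AssemblyState,
    alignment: list[tuple],
    k: float = 1.0,
):
    """Intra-model pairwise-distance matching across an alignment.

    ``alignment`` lists ((subunit, copy, residue), (subunit, copy, residue))
    correspondences between ``state`` and ``reference``.  For every pair of
    aligned positions the difference between the two intra-model distances is
    penalized harmonically — superposition-free, hence invariant under rigid
    motion of either model.
    """
    if not alignment:
        import warnings

        warnings.warn("empty alignment: equivalence score is 0", stacklevel=2)
        return 0.0
    a_idx = _aligned_beads(state, [a for a, _ in alignment])
    b_idx = _aligned_beads(reference, [b for _, b in alignment])
    da = pdist(state.coords[a_idx])
    db = pdist(reference.coords[b_idx])
    return float((0.5 * k * (da - db) ** 2).sum())


# ---------------------------------------------------------------------------
# Total
# ---------------------------------------------------------------------------

def total_score(
    state: AssemblyState,
    bundle: RestraintBundle,
    weights: RestraintWeights | None = None,
    include_symmetry_images: bool = False,
    n_symmetry: int = 8,
):
    """Weighted sum of all configured terms.

    Returns ``(total, breakdown, info)``; ``breakdown`` holds the weighted
    per-term contributions and sums to the total; ``info`` carries
    side-channel values (the density CC).
    """
    weights = weights or RestraintWeights()
    k = bundle.stiffness
    breakdown: dict[str, float] = {}
    info: dict[str, float] = {}
    if bundle.crosslinks:
        xl, _ = score_crosslinks(state, bundle.crosslinks, bundle.xl_cutoff, k)
        breakdown["crosslink"] = weights.crosslink * xl
    if bundle.map_gmm is not None:
        cc, pen = score_em(
            model_to_gmm(state, bundle.em_sigma_scale), bundle.map_gmm, weights.em
        )
        breakdown["em"] = pen
        info["em_cc"] = cc
    if bundle.positional:
        pos, _ = score_positional(state, bundle.positional, k)
        breakdown["positional"] = weights.positional * pos
    if bundle.proximity:
        prox, _ = score_proximity(state, bundle.proximity, k)
        breakdown["proximity"] = weights.proximity * prox
    breakdown["connectivity"] = weights.connectivity * score_connectivity(
        state, bundle.connectivity_scale, k
    )
    breakdown["excluded_volume"] = weights.excluded_volume * score_excluded_volume(
        state, k, include_symmetry_images, n_symmetry
    )
    if bundle.reference is not None and bundle.alignment:
        breakdown["equivalence"] = weights.equivalence * score_equivalence(
            state, bundle.reference, bundle.alignment, k
        )
    total = float(sum(breakdown.values()))
    return total, breakdown, info


# ---------------------------------------------------------------------------
# Compiled scorer for sampling
# ---------------------------------------------------------------------------

class ScoringFunction:
    """Restraint bundle compiled against one topology for fast evaluation.

    ``energy(coords)`` evaluates the weighted total on a full (n_beads, 3)
    coordinate array sharing the topology of the state the scorer was built
    from.  Matches :func:`total_score` to numerical precision (cross-checked
    in the tests).
    """

    def __init__(
        self,
        state: AssemblyState,
        bundle: RestraintBundle,
        weights: RestraintWeights | None = None,
    ):
        self.weights = weights or RestraintWeights()
        self.bundle = bundle
        k = bundle.stiffness
        self._k = k

        # crosslinks: flattened candidate pairs + per-link offsets
        self._xl = None
        if bundle.crosslinks:
            cand = [crosslink_candidates(state, rec) for rec in bundle.crosslinks]
            flat = np.vstack(cand)
            counts = np.array([len(c) for c in cand])
            self._xl = (
                flat[:, 0],
                flat[:, 1],
                np.concatenate([[0], np.cumsum(counts)[:-1]]),
                bundle.xl_cutoff,
            )

        # connectivity
        self._conn = _connectivity_pairs(state, bundle.connectivity_scale)

        # excluded volume
        e1, e2 = _ev_pairs(state)
        self._ev = (e1, e2, state.radii[e1] + state.radii[e2])

        # positional (point specs resolved to candidate bead lists)
        self._pos = []
        for spec in bundle.positional:
            beads = np.asarray(_spec_beads(state, spec), dtype=np.intp)
            self._pos.append((spec, beads))

        # proximity
        self._prox = [
            (_domain_beads(state, p.domain_a), _domain_beads(state, p.domain_b), p.max_distance)
            for p in bundle.proximity
        ]

        # density
        self._em = None
        if bundle.map_gmm is not None:
            idx = state.coarse_idx
            w = state.nres[idx].astype(float)
            sig2 = (bundle.em_sigma_scale * state.radii[idx]) ** 2
            m = bundle.map_gmm
            s2x = sig2[:, None] + m.sigmas[None, :] ** 2
            ax = (w[:, None] * m.weights[None, :]) * (2 * np.pi * s2x) ** -1.5
            s2s = sig2[:, None] + sig2[None, :]
            aself = (w[:, None] * w[None, :]) * (2 * np.pi * s2s) ** -1.5
            map_self = gmm_overlap(m, m)
            self._em = (idx, m.means, ax, 2.0 * s2x, aself, 2.0 * s2s, map_self)

        # equivalence
        self._equiv = None
        if bundle.reference is not None and bundle.alignment:
            a_idx = _aligned_beads(state, [a for a, _ in bundle.alignment])
            b_idx = _aligned_beads(bundle.reference, [b for _, b in bundle.alignment])
            dref = pdist(bundle.reference.coords[b_idx])
            self._equiv = (a_idx, dref)

    # -- evaluation --------------------------------------------------------

    def em_cc(self, coords: np.ndarray) -> float:
        idx, means, ax, s2x2, aself, s2s2, map_self = self._em
        x = coords[idx]
        d2 = cdist(x, means, "sqeuclidean")
        num = (ax * np.exp(-d2 / s2x2)).sum()
        d2s = cdist(x, x, "sqeuclidean")
        den = (aself * np.exp(-d2s / s2s2)).sum() * map_self
        return float(num / np.sqrt(den))

    def breakdown(self, coords: np.ndarray) -> tuple[float, dict, dict]:
        k, w = self._k, self.weights
        terms: dict[str, float] = {}
        info: dict[str, float] = {}
        if self._xl is not None:
            i1, i2, offsets, cutoff = self._xl
            d = np.linalg.norm(coords[i1] - coords[i2], axis=1)
            dmin = np.minimum.reduceat(d, offsets)
            terms["crosslink"] = w.crosslink * float(
                _harmonic_upper(dmin, cutoff, k).sum()
            )
        if self._em is not None:
            cc = self.em_cc(coords)
            terms["em"] = w.em * (1.0 - cc)
            info["em_cc"] = cc
        if self._pos:
            tot = 0.0
            for spec, beads in self._pos:
                if spec.kind == "terminal-localization":
                    d = np.linalg.norm(coords[beads] - spec.target, axis=1)
                    tot += float(_harmonic_upper(d, spec.tolerance, k).min())
                else:
                    z0, z1 = spec.target
                    z = coords[beads, 2]
                    exc = np.maximum(0.0, np.maximum(z0 - z, z - z1))
                    tot += float((0.5 * k * exc**2).min())
            terms["positional"] = w.positional * tot
        if self._prox:
            tot = 0.0
            for a, b, bound in self._prox:
                d = cdist(coords[a], coords[b]).min()
                tot += float(_harmonic_upper(np.array(d), bound, k))
            terms["proximity"] = w.proximity * tot
        i1, i2, thresh = self._conn
        if len(i1):
            d = np.linalg.norm(coords[i1] - coords[i2], axis=1)
            terms["connectivity"] = w.connectivity * float(
                _harmonic_upper(d, thresh, k).sum()
            )
        else:
            terms["connectivity"] = 0.0
        e1, e2, bounds = self._ev
        if len(e1):
            d = np.linalg.norm(coords[e1] - coords[e2], axis=1)
            terms["excluded_volume"] = w.excluded_volume * float(
                _harmonic_lower(d, bounds, k).sum()
            )
        else:
            terms["excluded_volume"] = 0.0
        if self._equiv is not None:
            a_idx, dref = self._equiv
            da = pdist(coords[a_idx])
            terms["equivalence"] = w.equivalence * float((0.5 * k * (da - dref) ** 2).sum())
        total = float(sum(terms.values()))
        return total, terms, info

    def energy(self, coords: np.ndarray) -> float:
        total, _, _ = self.breakdown(coords)
        if np.isnan(total):
            bad = [name for name, v in self.breakdown(coords)[1].items() if np.isnan(v)]
            raise FloatingPointError(f"NaN score in term(s): {bad}")
        return total
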