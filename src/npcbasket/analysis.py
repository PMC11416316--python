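"""Ensemble analysis and validation.

Selection of good-scoring models, RMSD in the fixed-scaffold frame (no
superposition, optional exact minimization over equivalent-copy
permutations), greedy threshold clustering, the three-test sampling-
exhaustiveness protocol (score-distribution similarity, cluster-population
chi-square / Cramer's V across a threshold grid, and the sampling precision
as the smallest passing threshold), model precision as average pairwise
RMSD, per-component localization probability densities, and restraint
satisfaction reporting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assembly import AssemblyState
from .restraints import (
    RestraintBundle,
    score_crosslinks,
    score_em,
    score_positional,
)
from .gmm import model_to_gmm
from .sampling import ModelEnsemble

__all__ = [
    "select_good_scoring",
    "rmsd",
    "pairwise_rmsd_matrix",
    "cluster",
    "ClusterResult",
    "model_precision",
    "sampling_precision",
    "SamplingPrecisionReport",
    "localization_density",
    "satisfaction_report",
]


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_good_scoring(
    ensemble: ModelEnsemble,
    percentile: float | None = None,
    per_term_thresholds: dict[str, float] | None = None,
):
    """Frames passing every criterion.

    ``percentile`` keeps the best-scoring fraction by total score (100 keeps
    everything); ``per_term_thresholds`` imposes absolute caps on weighted
    term scores.  Returns ``(subset, report)``; an empty selection is
    reported explicitly, never silently.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    keep = np.ones(len(ensemble), dtype=bool)
    criteria = {}
    if percentile is not None:
        cut = np.percentile(ensemble.scores, percentile)
        keep &= ensemble.scores <= cut
        criteria["total_score_percentile"] = percentile
        criteria["total_score_cutoff"] = float(cut)
    for term, cap in (per_term_thresholds or {}).items():
        if term not in ensemble.breakdowns.columns:
            raise KeyError(f"unknown score term {term!r}")
        keep &= ensemble.breakdowns[term].to_numpy() <= cap
        criteria[f"max_{term}"] = cap
    report = {
        "criteria": criteria,
        "n_input": len(ensemble),
        "n_selected": int(keep.sum()),
    }
    if report["n_selected"] == 0:
        import warnings

        warnings.warn("no good-scoring models under the given criteria", stacklevel=2)
    return ensemble.subset(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def _equivalent_copy_groups(state: AssemblyState):
    """Groups of coarse-index blocks for copies of the same subunit with
    identical bead counts (permutation-equivalent)."""
    by_sub: dict[str, list[np.ndarray]] = {}
    for ch in state.chains:
        by_sub.setdefault(ch.subunit, []).append(ch.coarse)
    groups = []
    for blocks in by_sub.values():
        if len(blocks) > 1 and len({len(b) for b in blocks}) == 1:
            groups.append(blocks)
    return groups


def rmsd(
    state_a: AssemblyState,
    state_b: AssemblyState,
    allow_copy_permutation: bool = False,
) -> float:
    """RMSD over coarse bead centers in the fixed-scaffold frame.

    No superposition is performed — both states live in the common frame set
    by the immobile scaffold.  With ``allow_copy_permutation`` the RMSD is
    minimized exactly over permutations of equivalent subunit copies
    (brute force per subunit type; types are independent, so the joint
    minimum is the sum of per-type minima).
    """
    ia, ib = state_a.coarse_idx, state_b.coarse_idx
    sig_a = [(ch.subunit, ch.copy_index, len(ch.coarse)) for ch in state_a.chains]
    sig_b = [(ch.subunit, ch.copy_index, len(ch.coarse)) for ch in state_b.chains]
    if (len(ia) != len(ib) or sig_a != sig_b
            or not np.array_equal(state_a.nres[ia], state_b.nres[ib])):
        raise ValueError("topology mismatch between states")
    xa, xb = state_a.coords[ia], state_b.coords[ib]
    pos = -np.ones(state_a.n_beads, dtype=np.intp)
    pos[ia] = np.arange(len(ia))
    sq = ((xa - xb) ** 2).sum()
    if allow_copy_permutation:
        for blocks in _equivalent_copy_groups(state_a):
            rows = [pos[b] for b in blocks]
            base = sum(((xa[r] - xb[r]) ** 2).sum() for r in rows)
            best = base
            for perm in itertools.permutations(range(len(rows))):
                trial = sum(
                    ((xa[rows[i]] - xb[rows[j]]) ** 2).sum()
                    for i, j in enumerate(perm)
                )
                best = min(best, trial)
            sq += best - base
    return float(np.sqrt(sq / len(ia)))


def pairwise_rmsd_matrix(frames: np.ndarray) -> np.ndarray:
    """All-vs-all RMSD of an (F, N, 3) coordinate stack (no permutation)."""
    f = np.asarray(frames, dtype=float)
    n = f.shape[1]
    flat = f.reshape(len(f), -1)
    sq = np.square(flat).sum(axis=1)
    g = flat @ flat.T
    d2 = np.maximum(0.0, (sq[:, None] + sq[None, :] - 2.0 * g) / n)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Partition of the selected frames by greedy threshold clustering."""

    clusters: list[np.ndarray]   # member indices, largest first
    centroids: list[int]         # seed frame index per cluster
    threshold: float

    @property
    def labels(self) -> np.ndarray:
        n = sum(len(c) for c in self.clusters)
        lab = np.empty(n, dtype=int)
        for k, members in enumerate(self.clusters):
            lab[members] = k
        return lab


def cluster(frames: np.ndarray, threshold: float, dmat: np.ndarray | None = None) -> ClusterResult:
    """Greedy centroid clustering at an RMSD threshold.

    The frame with the largest within-threshold neighborhood seeds the first
    cluster (itself plus all neighbors); the procedure repeats on the
    remainder until every frame is assigned.
    """
    if len(frames) == 0:
        raise ValueError("nothing to cluster")
    if dmat is None:
        dmat = pairwise_rmsd_matrix(frames)
    n = len(dmat)
    unassigned = np.ones(n, dtype=bool)
    within = dmat <= threshold
    clusters, centroids = [], []
    while unassigned.any():
        counts = (within & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        seed = int(np.argmax(counts))
        members = np.flatnonzero(within[seed] & unassigned)
        clusters.append(members)
        centroids.append(seed)
        unassigned[members] = False
    order = np.argsort([-len(c) for c in clusters], kind="stable")
    return ClusterResult(
        clusters=[clusters[i] for i in order],
        centroids=[centroids[i] for i in order],
        threshold=float(threshold),
    )


# ---------------------------------------------------------------------------
# Model precision
# ---------------------------------------------------------------------------

def model_precision(frames: np.ndarray, dmat: np.ndarray | None = None) -> dict:
    """Cluster spread: average pairwise RMSD (primary) and average RMSD to
    the centroid member (the member minimizing total RMSD to the rest)."""
    if len(frames) == 0:
        raise ValueError("empty cluster")
    if len(frames) == 1:
        return {"pairwise": 0.0, "to_centroid": 0.0, "n": 1,
                "note": "singleton cluster"}
    if dmat is None:
        dmat = pairwise_rmsd_matrix(frames)
    iu = np.triu_indices(len(dmat), k=1)
    centroid = int(np.argmin(dmat.sum(axis=1)))
    others = np.arange(len(dmat)) != centroid
    return {
        "pairwise": float(dmat[iu].mean()),
        "to_centroid": float(dmat[centroid, others].mean()),
        "centroid_index": centroid,
        "n": len(dmat),
    }


# ---------------------------------------------------------------------------
# Sampling precision (three-test exhaustiveness protocol)
# ---------------------------------------------------------------------------

@dataclass
class SamplingPrecisionReport:
    precision: float | None
    score_statistic: float
    score_pvalue: float
    table: pd.DataFrame  # per-threshold: pvalue, cramers_v, n_clusters, ...
    passed_thresholds: np.ndarray = field(default_factory=lambda: np.empty(0))


def _population_test(labels: np.ndarray, halves: np.ndarray,
                     min_cluster_size: int = 10):
    """Chi-square homogeneity of cluster populations between two halves.

    Clusters smaller than ``min_cluster_size`` are excluded: with near-empty
    rows the chi-square asymptotics break down and Cramér's V is inflated
    by sparseness rather than by genuine population imbalance.
    """
    k = labels.max() + 1
    table = np.zeros((k, 2))
    for lab, h in zip(labels, halves):
        table[lab, h] += 1
    table = table[table.sum(axis=1) >= max(1, min_cluster_size)]
    if len(table) < 2 or (table.sum(axis=0) == 0).any():
        return 1.0, 0.0
    chi2 = stats.chi2_contingency(table, correction=False).statistic
    n = table.sum()
    v = np.sqrt(chi2 / (n * (min(table.shape) - 1)))
    p = stats.chi2.sf(chi2, (table.shape[0] - 1) * (table.shape[1] - 1))
    return float(p), float(v)


def sampling_precision(
    frames: np.ndarray,
    halves: np.ndarray,
    threshold_grid: np.ndarray,
    scores: np.ndarray | None = None,
    p_cut: float = 0.05,
    v_cut: float = 0.10,
    min_clustered_fraction: float = 0.8,
) -> SamplingPrecisionReport:
    """Sampling-exhaustiveness protocol on two independent half-samples.

    ``halves`` assigns each frame to half 0 or 1 (split by independent run).
    Three tests: (a) a two-sample Kolmogorov-Smirnov test that the two
    halves' score distributions agree; (b) at each grid threshold, cluster
    the union and compare per-cluster populations between halves by
    chi-square and Cramer's V; (c) the sampling precision is the smallest
    threshold at which the populations are statistically indistinguishable
    (p > 0.05 and V < 0.10) and the clustering is non-trivial (at least
    ``min_clustered_fraction`` of frames in non-singleton clusters).
    """
    halves = np.asarray(halves)
    if set(np.unique(halves)) - {0, 1} or len(np.unique(halves)) < 2:
        raise ValueError("need two independent halves (values 0 and 1); "
                         "run at least two independent sampling runs")
    if scores is not None:
        ks = stats.ks_2samp(scores[halves == 0], scores[halves == 1])
        score_stat, score_p = float(ks.statistic), float(ks.pvalue)
    else:
        score_stat, score_p = np.nan, np.nan
    dmat = pairwise_rmsd_matrix(frames)
    rows = []
    for thr in np.sort(np.asarray(threshold_grid, dtype=float)):
        cr = cluster(frames, thr, dmat=dmat)
        labels = cr.labels
        p, v = _population_test(labels, halves)
        nonsingleton = sum(len(c) for c in cr.clusters if len(c) > 1) / len(frames)
        rows.append(
            {"threshold": thr, "pvalue": p, "cramers_v": v,
             "n_clusters": len(cr.clusters),
             "nonsingleton_fraction": nonsingleton,
             "passes": bool(p > p_cut and v < v_cut
                            and nonsingleton >= min_clustered_fraction)}
        )
    table = pd.DataFrame(rows)
    passed = table.loc[table.passes, "threshold"].to_numpy()
    return SamplingPrecisionReport(
        precision=float(passed[0]) if len(passed) else None,
        score_statistic=score_stat,
        score_pvalue=score_p,
        table=table,
        passed_thresholds=passed,
    )


# ---------------------------------------------------------------------------
# Localization density
# ---------------------------------------------------------------------------

def localization_density(
    members: list[AssemblyState],
    selector: str | tuple,
    voxel_size: float = 10.0,
    margin: float = 2.0,
):
    """Per-voxel probability of observing the selected component.

    ``selector`` is a subunit name or (subunit, copy_index).  Each member
    contributes an indicator envelope: voxels where the Gaussian-smoothed
    occupancy of the component's beads (sigma = bead radius) is at least
    exp(-1/2), i.e. within one radius of a bead center.  The map value is
    the fraction of members covering the voxel, in [0, 1].

    Returns ``(values, origin, voxel_size)`` for writing as MRC.
    """
    if not members:
        raise ValueError("empty cluster")

    def beads_of(state: AssemblyState):
        if isinstance(selector, str):
            chains = state.chains_of(selector)
        else:
            sub, cp = selector
            chains = [ch for ch in state.chains_of(sub) if ch.copy_index == cp]
        idx = np.concatenate([ch.coarse for ch in chains]) if chains else np.empty(0, np.intp)
        if len(idx) == 0:
            raise ValueError(f"selector {selector!r} matches no beads")
        return idx

    all_xyz, all_r = [], []
    for st in members:
        idx = beads_of(st)
        all_xyz.append(st.coords[idx])
        all_r.append(st.radii[idx])
    stack = np.vstack(all_xyz)
    rmax = max(r.max() for r in all_r)
    lo = stack.min(axis=0) - margin * rmax
    hi = stack.max(axis=0) + margin * rmax
    shape = np.maximum(1, np.ceil((hi - lo) / voxel_size).astype(int))
    grid_axes = [lo[d] + (np.arange(shape[d]) + 0.5) * voxel_size for d in range(3)]
    gx, gy, gz = np.meshgrid(*grid_axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    values = np.zeros(len(pts))
    for xyz, r in zip(all_xyz, all_r):
        d2 = ((pts[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=2)
        occ = np.exp(-0.5 * d2 / (r[None, :] ** 2)).max(axis=1)
        values += occ >= np.exp(-0.5)
    values /= len(members)
    return values.reshape(shape), lo, voxel_size


# ---------------------------------------------------------------------------
# Satisfaction report
# ---------------------------------------------------------------------------

def satisfaction_report(
    members: list[AssemblyState],
    bundle: RestraintBundle,
    cutoff: float | None = None,
) -> dict:
    """How well a cluster satisfies the input restraints.

    Per crosslink: the best (minimum over members) effective distance and an
    ensemble-level satisfied flag (distance <= cutoff in at least one
    member); summary percentages at ensemble level and averaged per model;
    density CC of the centroid member; positional violations of the
    centroid.
    """
    if not members:
        raise ValueError("empty cluster")
    cutoff = bundle.xl_cutoff if cutoff is None else cutoff
    frames = np.stack([m.coords for m in members])
    dmat = pairwise_rmsd_matrix(frames)
    centroid = members[int(np.argmin(dmat.sum(axis=1)))]

    report: dict = {"n_members": len(members)}
    if bundle.crosslinks:
        n_links = len(bundle.crosslinks)
        best = np.full(n_links, np.inf)
        per_model_rates = []
        for m in members:
            _, details = score_crosslinks(m, bundle.crosslinks, cutoff, bundle.stiffness)
            d = np.array([row["distance"] for row in details])
            best = np.minimum(best, d)
            per_model_rates.append(float((d <= cutoff).mean()))
        rows = [
            {"protein1": rec.protein1, "residue1": rec.residue1,
             "protein2": rec.protein2, "residue2": rec.residue2,
             "best_distance": float(best[i]), "satisfied": bool(best[i] <= cutoff)}
            for i, rec in enumerate(bundle.crosslinks)
        ]
        report["crosslinks"] = pd.DataFrame(rows)
        report["crosslink_satisfaction_ensemble"] = float((best <= cutoff).mean())
        report["crosslink_satisfaction_per_model"] = float(np.mean(per_model_rates))
    if bundle.map_gmm is not None:
        cc, _ = score_em(model_to_gmm(centroid, bundle.em_sigma_scale), bundle.map_gmm)
        report["centroid_em_cc"] = cc
    if bundle.positional:
        _, per_spec = score_positional(centroid, bundle.positional, bundle.stiffness)
        report["positional_violations"] = [
            row for row in per_spec if row["penalty"] > 0
        ]
    return report
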