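"""End-to-end pipelines tying the stages together.

The ground-truth recovery experiment is the package's integration
benchmark: generate a synthetic basket with known truth, simulate noiseless
restraints (dense crosslinks, sharp density, terminal localizations),
sample from randomized starts with replica-exchange MC, and measure how
well the top cluster recovers the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import (
    cluster,
    localization_density,
    model_precision,
    pairwise_rmsd_matrix,
    rmsd,
    sampling_precision,
    satisfaction_report,
    select_good_scoring,
)
from .restraints import RestraintBundle, RestraintWeights, ScoringFunction
from .sampling import ModelEnsemble, ReplicaConfig, run_sampling
from .synthetic import GroundTruthBundle, make_bundle, yeast_params

__all__ = ["RecoveryResult", "scoring_problem", "recovery_region",
           "ground_truth_recovery"]

DEFAULT_THRESHOLD_GRID = np.arange(5.0, 80.0, 5.0)


def scoring_problem(bundle: GroundTruthBundle, weights: RestraintWeights | None = None):
    """(template state, compiled scorer, restraint bundle) for a synthetic
    bundle: the sampled topology is the truth topology with coordinates to
    be randomized."""
    template = bundle.truth_state.copy()
    rb = RestraintBundle(
        crosslinks=bundle.crosslinks,
        map_gmm=bundle.density,
        positional=list(bundle.terminal_localizations) + list(bundle.membrane_anchors),
        xl_cutoff=bundle.xl_cutoff,
        em_sigma_scale=bundle.em_sigma_scale,
    )
    scorer = ScoringFunction(template, rb, weights or RestraintWeights())
    return template, scorer, rb


def recovery_region(bundle: GroundTruthBundle):
    """Sampling box enclosing the scaffold neighborhood and basket volume."""
    span = np.abs(bundle.truth_state.coords).max() + 150.0
    depth = bundle.params.distal_offset + 200.0
    return (np.array([-span, -span, -depth]), np.array([span, span, 150.0]))


@dataclass
class RecoveryResult:
    ensemble: ModelEnsemble
    selected: ModelEnsemble
    top_cluster_indices: np.ndarray
    centroid_rmsd_to_truth: float
    mean_bead_radius: float
    crosslink_satisfaction_ensemble: float
    crosslink_satisfaction_per_model: float
    centroid_em_cc: float
    strut_density_at_truth: float
    model_precision_pairwise: float
    model_precision_to_centroid: float
    sampling_precision: float | None
    report: dict


def ground_truth_recovery(
    seed: int = 1,
    n_steps: int = 20000,
    n_replicas: int = 4,
    n_runs: int = 2,
    n_true_crosslinks: int = 120,
    select_percentile: float = 20.0,
    cluster_threshold: float | None = None,
    max_members_analyzed: int = 60,
    params=None,
    weights: RestraintWeights | None = None,
) -> RecoveryResult:
    """Run the yeast-preset recovery experiment end to end.

    Noiseless study conditions: ``n_true_crosslinks`` true crosslinks
    (no false positives), a jitter-free density, terminal localizations at
    20 A uncertainty.  Sampling: ``n_replicas`` replicas x ``n_steps`` steps
    x ``n_runs`` independent runs.  Analysis selects the best
    ``select_percentile`` % of frames, estimates the sampling precision,
    clusters at that precision (or ``cluster_threshold``), and compares the
    top-cluster centroid against the ground truth.
    """
    params = params if params is not None else yeast_params(seed=seed)
    bundle = make_bundle(params, n_true=n_true_crosslinks, fp_rate=0.0,
                         sigma_scale=1.0, jitter=0.0)
    template, scorer, rb = scoring_problem(bundle, weights)
    config = ReplicaConfig(
        n_replicas=n_replicas, n_steps=n_steps, n_independent_runs=n_runs,
        seed=seed,
    )
    ensemble = run_sampling(template, scorer, config, region=recovery_region(bundle))

    selected, sel_report = select_good_scoring(ensemble, percentile=select_percentile)
    halves = (selected.provenance["run"].to_numpy() >= (n_runs // 2)).astype(int)
    coarse = template.coarse_idx
    sel_frames = selected.frames[:, coarse, :]
    sp = sampling_precision(sel_frames, halves, DEFAULT_THRESHOLD_GRID,
                            scores=selected.scores) if n_runs >= 2 else None

    thr = cluster_threshold
    if thr is None:
        thr = sp.precision if (sp is not None and sp.precision is not None) else 40.0
    cr = cluster(sel_frames, thr)
    top = cr.clusters[0]
    # cap the per-member analyses on an evenly strided subset
    stride = max(1, len(top) // max_members_analyzed)
    members_idx = top[::stride]
    members = [selected.state(int(i)) for i in members_idx]

    truth = bundle.truth_state
    dmat = pairwise_rmsd_matrix(selected.frames[members_idx][:, coarse, :])
    centroid_state = members[int(np.argmin(dmat.sum(axis=1)))]
    centroid_rmsd = rmsd(centroid_state, truth, allow_copy_permutation=True)
    mp = model_precision(selected.frames[members_idx][:, coarse, :], dmat=dmat)

    report = satisfaction_report(members, rb)

    values, origin, voxel = localization_density(members, "Strut", voxel_size=25.0)
    strut_idx = np.concatenate(
        [ch.coarse for ch in truth.chains if ch.subunit == "Strut"]
    )
    ijk = np.floor((truth.coords[strut_idx] - origin) / voxel).astype(int)
    ijk = np.clip(ijk, 0, np.array(values.shape) - 1)
    density_at_truth = float(values[ijk[:, 0], ijk[:, 1], ijk[:, 2]].mean())

    return RecoveryResult(
        ensemble=ensemble,
        selected=selected,
        top_cluster_indices=members_idx,
        centroid_rmsd_to_truth=float(centroid_rmsd),
        mean_bead_radius=float(truth.radii[coarse].mean()),
        crosslink_satisfaction_ensemble=float(
            report["crosslink_satisfaction_ensemble"]
        ),
        crosslink_satisfaction_per_model=float(
            report["crosslink_satisfaction_per_model"]
        ),
        centroid_em_cc=float(report["centroid_em_cc"]),
        strut_density_at_truth=density_at_truth,
        model_precision_pairwise=float(mp["pairwise"]),
        model_precision_to_centroid=float(mp["to_centroid"]),
        sampling_precision=None if sp is None else sp.precision,
        report={**sel_report, "threshold_used": float(thr)},
    )
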