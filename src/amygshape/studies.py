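"""Desk-scale simulation studies: calibration and parameter recovery.

These studies run the statistics stage of the pipeline over many
simulated cohorts generated directly on the shared surface sampling
(`synthetic.simulate_surface_cohort`), which keeps hundreds of cohorts
tractable while exercising exactly the displacement-metric, smoothing
and inference code the full mask route uses.  The voxel round trip is
validated separately by the end-to-end pipeline tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._heat import HeatSmoother
from . import metrics as met
from . import registration as reg
from . import stats as vstats
from . import synthetic


def _cohort_clusters(config: synthetic.CohortConfig, level: int, fwhm: float,
                     cluster_forming_p: float, metric: str = "direct",
                     n_perm: int = 0, perm_seed: int = 0):
    """One simulated cohort through template, metric, smoothing, GLM and
    cluster correction.  Returns (clusters, atlas, stack, scores, region)."""
    meshes, cov, region = synthetic.simulate_surface_cohort(config, level=level)
    atlas = reg.build_template(meshes, side=config.bump_side)
    registered = [reg.register_shrec(m, atlas)[0] for m in meshes]
    atlas = reg.build_template(registered, side=config.bump_side, iterations=2)
    smoother = HeatSmoother(atlas.mesh)
    fn = met.direct_displacement if metric == "direct" else met.normal_displacement
    maps = [met.smooth_map(fn(r, atlas), atlas, fwhm, smoother=smoother)
            for r in registered]
    stack = met.cohort_stack(maps)
    scores = cov.stai_t.to_numpy()
    statmap = vstats.fit_vertexwise_glm(stack, scores)
    clusters = vstats.rft_cluster_correction(statmap, atlas.mesh, fwhm,
                                             cluster_forming_p=cluster_forming_p)
    if n_perm:
        clusters = vstats.permutation_cluster_oracle(
            stack, scores, atlas.mesh, cluster_forming_p=cluster_forming_p,
            n_perm=n_perm, seed=perm_seed, clusters=clusters)
    return clusters, atlas, stack, cov, region


def null_fwer_study(n_cohorts: int = 200, level: int = 3, fwhm: float = 5.0,
                    cluster_forming_p: float = 0.001, alpha: float = 0.05,
                    n_perm: int = 500, seed: int = 0,
                    base_config: synthetic.CohortConfig | None = None) -> dict:
    """Family-wise error rate of RFT and permutation cluster inference
    under the null generator (bump_gain = 0).

    Also pools per-vertex uncorrected p-values at three well-separated
    probe vertices across cohorts (independent across cohorts) for a
    uniformity check.  Returns rates and the pooled p-values.
    """
    base = base_config or synthetic.CohortConfig()
    fp_rft = 0
    fp_perm = 0
    probe_p = []
    probes = None
    for k in range(n_cohorts):
        cfg = dataclasses.replace(base, bump_gain=0.0, seed=seed + 1000 + k)
        clusters, atlas, stack, cov, _ = _cohort_clusters(
            cfg, level, fwhm, cluster_forming_p, n_perm=n_perm,
            perm_seed=seed + 5000 + k)
        if any(c.p_rft <= alpha for c in clusters):
            fp_rft += 1
        if any((c.p_perm or 1.0) <= alpha for c in clusters):
            fp_perm += 1
        statmap = vstats.fit_vertexwise_glm(stack, cov.stai_t.to_numpy())
        if probes is None:
            n_v = stack.shape[1]
            probes = [0, n_v // 3, 2 * n_v // 3]
        probe_p.extend(statmap.p[probes])
    return {"n_cohorts": n_cohorts,
            "fwer_rft": fp_rft / n_cohorts,
            "fwer_perm": fp_perm / n_cohorts,
            "probe_pvalues": np.asarray(probe_p)}


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two index sets."""
    a, b = set(map(int, a)), set(map(int, b))
    if not a and not b:
        return 1.0
    return 2.0 * len(a & b) / (len(a) + len(b))


def bump_recovery_study(n_cohorts: int = 50, level: int = 3, fwhm: float = 5.0,
                        cluster_forming_p: float = 0.001, alpha: float = 0.05,
                        seed: int = 0, metric: str = "direct",
                        n_perm: int = 0,
                        base_config: synthetic.CohortConfig | None = None) -> dict:
    """Parameter recovery under the detectable-bump configuration.

    For each cohort: does a corrected-significant cluster exist, does
    its vertex set overlap the injected bump region (Dice), is the
    cluster-mean metric positively correlated with the trait score, and
    is any significant cluster far (beyond twice the bump radius) from
    the injected center?  When ``n_perm`` > 0 the permutation oracle is
    run as well and RFT/permutation decision agreement is recorded.
    """
    base = base_config or synthetic.CohortConfig()
    detected = 0
    dices = []
    pos_corr = 0
    far_cluster = 0
    agree = 0
    partials = []
    for k in range(n_cohorts):
        cfg = dataclasses.replace(base, seed=seed + 2000 + k)
        clusters, atlas, stack, cov, region = _cohort_clusters(
            cfg, level, fwhm, cluster_forming_p, metric=metric,
            n_perm=n_perm, perm_seed=seed + 7000 + k)
        sig = [c for c in clusters if c.p_rft <= alpha]
        if n_perm:
            rft_sig = len(sig) > 0
            perm_sig = any((c.p_perm or 1.0) <= alpha for c in clusters)
            agree += int(rft_sig == perm_sig)
        if not sig:
            continue
        region_idx = np.nonzero(region)[0]
        best = max(sig, key=lambda c: dice(c.vertices, region_idx))
        d = dice(best.vertices, region_idx)
        if d < 0.3:
            continue
        detected += 1
        dices.append(d)
        # cluster-mean metric vs score correlation (scatter-plot analogue)
        w = vstats.vertex_areas(atlas.mesh)[best.vertices]
        avg = stack[:, best.vertices] @ (w / w.sum())
        r = np.corrcoef(avg, cov.stai_t.to_numpy())[0, 1]
        if r > 0:
            pos_corr += 1
        r_p, _ = vstats.cluster_partial_correlation(
            stack, best, cov.stai_t.to_numpy(), cov.sds.to_numpy(), atlas.mesh)
        partials.append(r_p)
        # off-target check: any significant cluster entirely beyond 2x radius
        center = np.asarray(cfg.bump_center) * (
            np.array([-1.0, 1.0, 1.0]) if cfg.bump_side == "right" else 1.0)
        dirs = atlas.mesh.vertices - atlas.mesh.vertices.mean(axis=0)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        gamma = np.arccos(np.clip(dirs @ center, -1, 1))
        for c in sig:
            if (gamma[c.vertices] > 2 * cfg.bump_angular_radius).all():
                far_cluster += 1
                break
    out = {"n_cohorts": n_cohorts,
           "detection_rate": detected / n_cohorts,
           "mean_dice": float(np.mean(dices)) if dices else 0.0,
           "positive_correlation_fraction": (pos_corr / detected if detected
                                             else 0.0),
           "far_cluster_fraction": (far_cluster / detected if detected else 0.0),
           "mean_partial_r": float(np.mean(partials)) if partials else 0.0}
    if n_perm:
        out["rft_perm_agreement"] = agree / n_cohorts
    return out


def volumetry_calibration(n_subjects: int = 24, level: int = 3,
                          voxel_size: float = 1.0, seed: int = 0,
                          base_config: synthetic.CohortConfig | None = None) -> dict:
    """Cohort mask volumes per side via the voxel route, plus the
    volume-score and covariate correlations."""
    from . import volumetry
    from .synthetic import make_base_shape, voxelize

    base = base_config or synthetic.CohortConfig()
    cfg = dataclasses.replace(base, n_subjects=n_subjects, seed=seed)
    cov = synthetic.sample_covariates(cfg)
    rng = np.random.default_rng(seed + 17)
    out = {}
    for side, mean in (("left", cfg.volume_mean_left),
                       ("right", cfg.volume_mean_right)):
        vols = []
        for i in range(n_subjects):
            target = max(200.0, mean + cfg.volume_sd * rng.standard_normal())
            mesh = make_base_shape(side, target, seed=seed + 31 * i + (side == "right"),
                                   level=level)
            mask = voxelize(mesh, voxel_size)
            vols.append(volumetry.compute_volume(mask))
        vols = np.asarray(vols)
        r, p = volumetry.correlate_volume_with_score(vols, cov.stai_t.to_numpy())
        out[side] = {"mean": float(vols.mean()), "sd": float(vols.std(ddof=1)),
                     "stai_r": float(r), "stai_p": float(p)}
    r_cov = float(np.corrcoef(cov.stai_t, cov.sds)[0, 1])
    out["stai_mean"] = float(cov.stai_t.mean())
    out["stai_sd"] = float(cov.stai_t.std(ddof=1))
    out["sds_stai_corr"] = r_cov
    return out
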