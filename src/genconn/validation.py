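"""Simulation studies validating the inference machinery.

Two standard checks on the AUC permutation test:

* type-I error — replicate cohorts in which group labels are independent
  of the measure curves; the rejection rate at alpha must match alpha;
* power — replicate synthetic cohorts with the planted between-module
  coupling reduction for S-carriers, pushed through correlation,
  proportional thresholding, participation and AUC, then permutation
  tested.

The power study runs the covariance -> correlation -> threshold ->
participation -> AUC -> permutation chain at the full subject count with
a reduced ROI count (6 modules of 8) and the ground-truth partition, so
it measures the sensitivity of the statistics, not of community
detection (which has its own recovery checks).
"""

from __future__ import annotations

import numpy as np

from . import construction, inference, metrics, simulate

__all__ = [
    "end_to_end_recovery",
    "null_rejection_rate",
    "participation_group_power",
    "participation_auc_per_subject",
]


def null_rejection_rate(
    n_replicates: int = 1000,
    n_subjects: int = 111,
    n_risk: int = 80,
    n_densities: int = 30,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the permutation test under the null.

    Each replicate draws measure curves (a subject-level random intercept
    plus noise across the density grid) independent of the risk labels,
    whose group sizes mirror the S-carrier / L-homozygote split.
    """
    rng = np.random.default_rng(seed)
    densities = np.round(np.arange(1, n_densities + 1) / 100, 2)
    risk = np.zeros(n_subjects, dtype=bool)
    risk[:n_risk] = True
    rejections = 0
    for _ in range(n_replicates):
        intercept = rng.standard_normal(n_subjects)
        values = intercept[:, None] + 0.5 * rng.standard_normal((n_subjects, n_densities))
        labels = rng.permutation(risk)
        res = inference.permutation_test(
            values, labels, densities, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        rejections += res.p_value < alpha
    return rejections / n_replicates


def participation_auc_per_subject(
    cohort: simulate.SyntheticCohort,
    module: int,
    densities: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject AUC-ready participation curves for one module.

    Correlates each subject's raw time series (no artifact cleanup; the
    generator is run artifact-free here), thresholds across the density
    grid and averages the weighted participation coefficient over the
    module's nodes.  Returns (curves, densities, risk mask for the
    S-carrier contrast).
    """
    if densities is None:
        densities = construction.default_density_grid()
    labels = cohort.module_labels
    xyz = cohort.coords[["x", "y", "z"]].to_numpy()
    node_mask = labels == module
    curves = np.empty((len(cohort.subject_ids), len(densities)))
    for i, sid in enumerate(cohort.subject_ids):
        raw = construction.correlation_matrix(cohort.timeseries[sid], xyz)
        stack = construction.build_stack(raw, densities, check_nesting=False)
        for d in range(len(densities)):
            p = metrics.participation_coefficient(stack.weighted[d], labels, "weighted")
            curves[i, d] = p[node_mask].mean()
    risk = cohort.genotypes["httlpr"].map(
        lambda g: g is not None and "S" in g.split("/")
    ).to_numpy(dtype=bool)
    return curves, np.asarray(densities), risk


def participation_group_power(
    n_seeds: int = 50,
    n_subjects: int = 111,
    n_rois: int = 48,
    n_perm: int = 500,
    alpha: float = 0.05,
    effect_participation: float | None = None,
    seed: int = 0,
) -> float:
    """Detection rate of the planted S-carrier participation effect.

    Each seed generates an artifact-free cohort (nuisance and motion
    amplitudes zero) with the planted between-module coupling reduction,
    computes per-subject participation AUC curves for the first
    designated module using the ground-truth partition, and permutation
    tests the group difference.
    """
    rng = np.random.default_rng(seed)
    overrides = dict(
        n_subjects=n_subjects,
        n_rois=n_rois,
        global_amp=0.0,
        wm_amp=0.0,
        csf_amp=0.0,
        motion_amp=0.0,
        spike_rate=0.0,
    )
    if effect_participation is not None:
        overrides["effect_participation"] = effect_participation
    detections = 0
    for _ in range(n_seeds):
        cohort = simulate.simulate_cohort(seed=int(rng.integers(2**31)), **overrides)
        module = cohort.config.participation_modules[0]
        curves, densities, risk = participation_auc_per_subject(cohort, module)
        res = inference.permutation_test(
            curves, risk, densities, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        detections += (res.p_value < alpha) and (res.observed_auc < 0)
    return detections / n_seeds


def end_to_end_recovery(
    workdir,
    seed: int = 0,
    n_subjects: int = 40,
    n_rois: int = 48,
    n_perm: int = 500,
) -> dict:
    """Drive the full command-line chain on a seeded synthetic cohort.

    Runs simulate -> genotypes -> prep -> construct -> decompose ->
    measure -> infer (both polymorphisms) through the installed CLI and
    summarizes ground-truth recovery: the number of modules found at the
    selected density and the observed AUC statistics for the planted
    effects (S-carrier participation difference in the designated
    modules; COMT slope difference for the moderated modules), with
    module indices matched to the planted labels by majority overlap.
    """
    import json
    import subprocess
    import sys
    from pathlib import Path

    import pandas as pd

    work = Path(workdir)
    work.mkdir(parents=True, exist_ok=True)

    def cli(*args) -> None:
        subprocess.run(
            [sys.executable, "-m", "genconn", *map(str, args)],
            check=True,
            cwd=work,
            capture_output=True,
        )

    cli("simulate", "--out", "cohort", "--seed", seed,
        "--n-subjects", n_subjects, "--n-rois", n_rois)
    cli("genotypes", "--infile", "cohort/genotypes.tsv", "--out", "groups.tsv",
        "--hwe-report", "hwe.tsv")
    cli("prep", "--cohort", "cohort", "--out", "prep")
    cli("construct", "--prep", "prep", "--coords", "cohort/coords.tsv", "--out", "matrices")
    cli("decompose", "--matrices", "matrices", "--out", "partition.tsv")
    cli("measure", "--matrices", "matrices", "--partition", "partition.tsv",
        "--out", "measures.tsv")
    cli("infer", "--measures", "measures.tsv", "--pheno", "cohort/phenotypes.tsv",
        "--groups", "groups.tsv", "--polymorphism", "httlpr",
        "--nperm", n_perm, "--seed", seed, "--out", "results_httlpr.tsv")
    cli("infer", "--measures", "measures.tsv", "--pheno", "cohort/phenotypes.tsv",
        "--groups", "groups.tsv", "--polymorphism", "comt",
        "--nperm", n_perm, "--seed", seed + 1, "--out", "results_comt.tsv")

    truth = json.loads((work / "cohort" / "ground_truth.json").read_text())
    true_labels = np.array(truth["module_labels"])
    partition = pd.read_csv(work / "partition.tsv", sep="\t")
    found = partition["module"].to_numpy()

    def matched(true_module: int) -> int:
        values, counts = np.unique(found[true_labels == true_module], return_counts=True)
        return int(values[np.argmax(counts)])

    httlpr = pd.read_csv(work / "results_httlpr.tsv", sep="\t")
    comt = pd.read_csv(work / "results_comt.tsv", sep="\t")

    def auc_of(table, measure, modules, statistic):
        sel = table[
            (table["measure"] == measure)
            & table["module"].isin(modules)
            & (table["variant"] == "weighted")
            & (table["statistic"] == statistic)
        ]
        return sel["observed_auc"].to_numpy(), sel["p_value"].to_numpy()

    part_modules = [matched(m) for m in truth["participation_modules"]]
    slope_modules = [matched(m) for m in truth["slope_modules"]]
    part_aucs, part_ps = auc_of(httlpr, "participation", part_modules, "mean_difference")
    slope_aucs, slope_ps = auc_of(comt, "local_efficiency", slope_modules, "slope_difference")
    info = json.loads((work / "partition.json").read_text())
    return {
        "n_modules": int(found.max()) + 1,
        "selected_density": info["density"],
        "participation_auc_differences": part_aucs.tolist(),
        "participation_p_values": part_ps.tolist(),
        "slope_auc_differences": slope_aucs.tolist(),
        "slope_p_values": slope_ps.tolist(),
        "n_subjects": n_subjects,
        "n_rois": n_rois,
    }
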