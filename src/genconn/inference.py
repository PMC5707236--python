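"""Statistical engine: group-difference and slope-difference curves,
AUC summarization across the density grid, and label-permutation tests.

Per network measure the per-subject values form a curve across
densities.  Two statistics are supported:

* mean difference — mean(risk) - mean(non-risk), per density;
* slope difference — OLS slope of measure on neuroticism within the
  risk group minus the same within the non-risk group, per density.

Each statistic curve is summarized by its trapezoidal area under the
curve (AUC) over the density grid, which removes the dependence on any
single threshold.  Significance is assessed by permuting group labels
(group sizes preserved), recomputing the statistic's AUC for each
permutation, and ranking |observed AUC| against the |null AUCs|:

    p = (#{|null| >= |observed|} + 1) / (n_perm + 1)

a two-tailed test that is never exactly zero.  With a fixed seed the
entire result is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InferenceError",
    "PermutationResult",
    "auc",
    "group_difference_curve",
    "permutation_test",
    "run_inference",
    "slope_difference_curve",
]


class InferenceError(ValueError):
    """Invalid input to a statistical routine."""


def auc(curve: np.ndarray, densities: np.ndarray) -> float:
    """Trapezoidal integral of a measure curve over the density grid."""
    curve = np.asarray(curve, dtype=float)
    densities = np.asarray(densities, dtype=float)
    if curve.shape[-1] != densities.shape[0]:
        raise InferenceError("curve and density grid lengths differ")
    if densities.shape[0] < 2 or np.any(np.diff(densities) <= 0):
        raise InferenceError("need >= 2 strictly increasing densities")
    return np.trapezoid(curve, densities, axis=-1)


def _check_groups(risk: np.ndarray, n: int, min_per_group: int) -> np.ndarray:
    risk = np.asarray(risk, dtype=bool)
    if risk.shape[0] != n:
        raise InferenceError("group labels do not match subject count")
    if risk.sum() < min_per_group or (~risk).sum() < min_per_group:
        raise InferenceError(
            f"need at least {min_per_group} subjects per group "
            f"(got {int(risk.sum())} risk, {int((~risk).sum())} non-risk)"
        )
    return risk


def group_difference_curve(values: np.ndarray, risk: np.ndarray) -> np.ndarray:
    """Per-density mean(risk) - mean(non-risk).

    ``values`` is subjects x densities.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    risk = _check_groups(risk, values.shape[0], 2)
    return values[risk].mean(axis=0) - values[~risk].mean(axis=0)


def _group_slopes(values: np.ndarray, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    xg = x[mask]
    if xg.var() == 0:
        raise InferenceError("zero neuroticism variance within a group")
    xc = xg - xg.mean()
    return xc @ values[mask] / (xc @ xc)


def slope_difference_curve(
    values: np.ndarray, neuroticism: np.ndarray, risk: np.ndarray
) -> np.ndarray:
    """Per-density difference of within-group OLS slopes (risk - non-risk)
    of measure on neuroticism."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    x = np.asarray(neuroticism, dtype=float)
    if x.shape[0] != values.shape[0]:
        raise InferenceError("neuroticism vector does not match subject count")
    risk = _check_groups(risk, values.shape[0], 3)
    return _group_slopes(values, x, risk) - _group_slopes(values, x, ~risk)


@dataclass
class PermutationResult:
    """Observed AUC, its permutation null, and the two-tailed p-value."""

    statistic: str
    observed_auc: float
    null_aucs: np.ndarray = field(repr=False)
    p_value: float
    n_perm: int
    seed: int
    measure: str | None = None


def _permutation_masks(risk: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """n_perm shuffles of the label vector; group sizes are preserved."""
    n = risk.shape[0]
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    return risk[idx]


def _null_mean_difference(values: np.ndarray, masks: np.ndarray) -> np.ndarray:
    n_risk = masks.sum(axis=1, keepdims=True).astype(float)
    n_non = masks.shape[1] - n_risk
    total = values.sum(axis=0)
    sum_risk = masks @ values
    return sum_risk / n_risk - (total - sum_risk) / n_non


def _null_slope_difference(values: np.ndarray, x: np.ndarray, masks: np.ndarray) -> np.ndarray:
    out = np.empty((masks.shape[0], values.shape[1]))
    for g, sign in ((masks, 1.0), (~masks, -1.0)):
        n_g = g.sum(axis=1).astype(float)
        sx = g @ x
        sxx = g @ (x * x)
        sxy = (g * x) @ values
        sy = g @ values
        denom = n_g * sxx - sx**2
        slopes = (n_g[:, None] * sxy - sx[:, None] * sy) / denom[:, None]
        if sign > 0:
            out = slopes
        else:
            out = out - slopes
    return out


def permutation_test(
    values: np.ndarray,
    risk: np.ndarray,
    densities: np.ndarray,
    statistic: str = "mean_difference",
    neuroticism: np.ndarray | None = None,
    n_perm: int = 5000,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation test of a statistic's AUC across densities.

    ``values`` is subjects x densities.  ``statistic`` is
    ``"mean_difference"`` or ``"slope_difference"`` (the latter requires
    ``neuroticism``).  Group sizes are preserved under permutation and
    the test is two-tailed via |AUC| ranking.
    """
    if n_perm < 1:
        raise InferenceError("n_perm must be >= 1")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    densities = np.asarray(densities, dtype=float)
    if statistic == "mean_difference":
        observed_curve = group_difference_curve(values, risk)
    elif statistic == "slope_difference":
        if neuroticism is None:
            raise InferenceError("slope_difference requires neuroticism scores")
        observed_curve = slope_difference_curve(values, neuroticism, risk)
    else:
        raise InferenceError(f"unknown statistic {statistic!r}")
    observed = float(auc(observed_curve, densities))

    risk = np.asarray(risk, dtype=bool)
    rng = np.random.default_rng(seed)
    masks = _permutation_masks(risk, n_perm, rng)
    if statistic == "mean_difference":
        null_curves = _null_mean_difference(values, masks)
    else:
        x = np.asarray(neuroticism, dtype=float)
        null_curves = _null_slope_difference(values, x, masks)
    null_aucs = auc(null_curves, densities)
    p = (np.sum(np.abs(null_aucs) >= abs(observed)) + 1) / (n_perm + 1)
    return PermutationResult(
        statistic=statistic,
        observed_auc=observed,
        null_aucs=null_aucs,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
    )


def run_inference(
    measures: pd.DataFrame,
    groups: pd.Series,
    neuroticism: pd.Series | None = None,
    measure_list: list[tuple[str, object]] | None = None,
    variants: tuple[str, ...] = ("weighted", "binary"),
    statistics: tuple[str, ...] = ("mean_difference", "slope_difference"),
    n_perm: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation tests for every requested measure x variant x statistic.

    ``measures`` is the long table produced by the metrics stage with a
    ``subject_id`` column; ``groups`` maps subject_id -> True for risk.
    ``measure_list`` restricts testing to (measure, module) pairs —
    module ``None`` for whole-brain measures — mirroring the restriction
    of interaction analyses to measures of prior interest; by default
    every (measure, module) pair present is tested.  One child seed per
    test keeps results reproducible and independent.
    """
    if measure_list is None:
        pairs = (
            measures[["measure", "module"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        measure_list = list(pairs)
    subjects = sorted(groups.index)
    risk = groups.loc[subjects].to_numpy(dtype=bool)
    x = neuroticism.loc[subjects].to_numpy(dtype=float) if neuroticism is not None else None
    seeds = np.random.SeedSequence(seed).spawn(len(measure_list) * len(variants) * len(statistics))
    rows = []
    i = 0
    for measure, module in measure_list:
        sel = measures["measure"] == measure
        sel &= measures["module"].isna() if module is None else measures["module"] == module
        sub = measures[sel]
        for variant in variants:
            block = sub[sub["variant"] == variant]
            if block.empty:
                i += len(statistics)
                continue
            wide = block.pivot_table(index="subject_id", columns="density", values="value")
            wide = wide.loc[subjects]
            densities = wide.columns.to_numpy(dtype=float)
            values = wide.to_numpy()
            for statistic in statistics:
                child = int(seeds[i].generate_state(1)[0] % (2**31))
                i += 1
                if statistic == "slope_difference" and x is None:
                    continue
                res = permutation_test(
                    values, risk, densities,
                    statistic=statistic, neuroticism=x, n_perm=n_perm, seed=child,
                )
                rows.append(
                    {
                        "measure": measure,
                        "module": module,
                        "variant": variant,
                        "statistic": statistic,
                        "observed_auc": res.observed_auc,
                        "p_value": res.p_value,
                        "n_perm": n_perm,
                        "seed": child,
                    }
                )
    return pd.DataFrame(rows)
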