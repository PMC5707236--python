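"""Synthetic-cohort generator.

Emulates the statistical structure the analysis pipeline assumes, with
ground truth stored alongside every artifact so planted effects are
recoverable end to end:

* genotypes drawn under Hardy-Weinberg equilibrium at configurable
  allele frequencies (5-HTTLPR S = 0.50, rs4680 Met(A) = 0.53,
  rs165599 A = 0.69), with an optional linkage-disequilibrium term for
  the two COMT markers;
* neuroticism scores ~ Normal(135.5, 18.9), independent of genotype;
* per-subject ROI time series (default 259 ROIs, 300 volumes, TR 2 s)
  drawn from a 6-module block covariance, plus global / WM / CSF
  nuisance components and random-walk motion with occasional spikes;
* planted effects injected at the covariance level: S-carriers get
  reduced between-module coupling for two designated modules (a
  participation-coefficient group effect) and COMT-risk subjects get
  within-module correlation of two other designated modules shifted by
  -effect_slope * z(neuroticism) (a genotype-moderated slope effect).

Because effects live in the covariance, the whole pipeline — cleanup,
correlation, thresholding, decomposition, metrics, inference — is
exercised, not just single stages.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import parse_genotype_table

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "module_labels",
    "read_cohort",
    "roi_coordinates",
    "simulate_cohort",
    "simulate_genotypes",
    "simulate_phenotypes",
    "subject_covariance",
    "write_cohort",
]


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    The defaults mirror the emulated cohort: 111 analyzable subjects,
    259 ROIs, 300 volumes at TR 2 s, six functional modules, and the
    cohort's allele frequencies and neuroticism distribution.  Planted
    effect sizes are calibration parameters (the real effects' sizes are
    unknown); their defaults were calibrated once so the planted
    participation effect is detectable with high power at n = 111.
    """

    n_subjects: int = 111
    n_rois: int = 259
    n_volumes: int = 300
    tr_seconds: float = 2.0
    n_modules: int = 6
    # allele frequencies of the first allele of each marker
    httlpr_s_freq: float = 0.50
    rs4680_met_freq: float = 0.53
    rs165599_a_freq: float = 0.69
    comt_ld: float = 0.0  # D term between Met and A haplotype frequencies
    neuro_mean: float = 135.5
    neuro_sd: float = 18.9
    within_module_r: float = 0.5
    between_module_r: float = 0.1
    # planted effects (0 disables)
    effect_participation: float = 0.03
    effect_slope: float = 0.10
    participation_modules: tuple[int, int] = (2, 3)
    slope_modules: tuple[int, int] = (4, 5)
    # nuisance / artifact amplitudes (network signal has unit scale)
    global_amp: float = 0.5
    wm_amp: float = 0.3
    csf_amp: float = 0.3
    motion_amp: float = 0.4
    motion_step_mm: float = 0.01
    spike_rate: float = 0.01
    spike_mm: float = 0.8
    ar_coefficient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("httlpr_s_freq", "rs4680_met_freq", "rs165599_a_freq"):
            f = getattr(self, name)
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (-1.0 < self.between_module_r < self.within_module_r < 1.0):
            raise ValueError("need -1 < between_module_r < within_module_r < 1")
        if self.n_modules > self.n_rois:
            raise ValueError("n_modules cannot exceed n_rois")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("participation_modules", "slope_modules"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticCohort:
    """All generated tables plus ground truth."""

    config: SimConfig
    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    coords: pd.DataFrame
    module_labels: np.ndarray
    timeseries: dict[str, np.ndarray]
    motion: dict[str, np.ndarray]
    nuisance: dict[str, np.ndarray]

    @property
    def subject_ids(self) -> list[str]:
        return list(self.genotypes["subject_id"])


def _subject_ids(n: int) -> list[str]:
    return [f"sub-{i + 1:03d}" for i in range(n)]


def _draw_genotype(rng, freq: float, alleles: tuple[str, str], n: int) -> list[str]:
    doses = rng.binomial(2, freq, size=n)  # HWE: two independent draws
    lookup = {
        2: f"{alleles[0]}/{alleles[0]}",
        1: f"{alleles[0]}/{alleles[1]}",
        0: f"{alleles[1]}/{alleles[1]}",
    }
    return [lookup[d] for d in doses]


def simulate_genotypes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw genotypes under HWE at the configured allele frequencies.

    The two COMT markers are drawn jointly from a haplotype distribution
    with frequency f(Met,A) = p_Met * p_A + D (``comt_ld``); D = 0 gives
    independent markers.
    """
    n = config.n_subjects
    httlpr = _draw_genotype(rng, config.httlpr_s_freq, ("S", "L"), n)
    pm, pa, d = config.rs4680_met_freq, config.rs165599_a_freq, config.comt_ld
    hap_freqs = np.array(
        [
            pm * pa + d,              # Met-A
            pm * (1 - pa) - d,        # Met-G
            (1 - pm) * pa - d,        # Val-A
            (1 - pm) * (1 - pa) + d,  # Val-G
        ]
    )
    if np.any(hap_freqs < 0):
        raise ValueError("comt_ld incompatible with the allele frequencies")
    haps = rng.choice(4, size=(n, 2), p=hap_freqs)
    met_dose = (haps < 2).sum(axis=1)
    a_dose = ((haps == 0) | (haps == 2)).sum(axis=1)
    g4680 = {2: "Met/Met", 1: "Val/Met", 0: "Val/Val"}
    g165599 = {2: "A/A", 1: "A/G", 0: "G/G"}
    table = pd.DataFrame(
        {
            "subject_id": _subject_ids(n),
            "httlpr": httlpr,
            "rs4680": [g4680[d] for d in met_dose],
            "rs165599": [g165599[d] for d in a_dose],
        }
    )
    return parse_genotype_table(table)


def simulate_phenotypes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Neuroticism ~ Normal(mean, sd), independent of genotype."""
    scores = rng.normal(config.neuro_mean, config.neuro_sd, size=config.n_subjects)
    return pd.DataFrame({"subject_id": _subject_ids(config.n_subjects), "neuroticism": scores})


def module_labels(config: SimConfig) -> np.ndarray:
    """Contiguous near-equal module blocks over the ROIs."""
    sizes = np.full(config.n_modules, config.n_rois // config.n_modules)
    sizes[: config.n_rois % config.n_modules] += 1
    return np.repeat(np.arange(config.n_modules), sizes)


# fixed, well-separated cluster anchors inside an MNI-like bounding box (mm)
_CLUSTER_ANCHORS = np.array(
    [
        [-45.0, 30.0, 10.0],
        [45.0, 30.0, 10.0],
        [-40.0, -60.0, 40.0],
        [40.0, -60.0, 40.0],
        [0.0, -90.0, 0.0],
        [0.0, 10.0, 60.0],
    ]
)


def roi_coordinates(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """ROI centers on a clustered spatial layout.

    Each module's ROIs scatter around one anchor with 25 mm jitter, so a
    small fraction of pairs (on the order of a percent, as in real
    ROI sets) falls closer than 20 mm and the distance-exclusion rule is
    exercised without isolating nodes.
    """
    labels = module_labels(config)
    anchors = _CLUSTER_ANCHORS[
        np.resize(np.arange(len(_CLUSTER_ANCHORS)), config.n_modules)
    ]
    xyz = anchors[labels] + rng.normal(0.0, 25.0, size=(config.n_rois, 3))
    return pd.DataFrame(
        {
            "roi_id": [f"roi{i + 1:03d}" for i in range(config.n_rois)],
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
        }
    )


def subject_covariance(
    config: SimConfig,
    labels: np.ndarray,
    s_carrier: bool,
    comt_risk: bool,
    neuro_z: float,
) -> np.ndarray:
    """Block covariance for one subject with planted effects injected.

    S-carriers: between-module coupling of the designated participation
    modules reduced by ``effect_participation``.  COMT risk: within-
    module correlation of the designated slope modules shifted by
    ``-effect_slope * neuro_z``.  A non-positive-definite result is
    shrunk toward the identity with a warning.
    """
    n = labels.shape[0]
    same = labels[:, None] == labels[None, :]
    cov = np.where(same, config.within_module_r, config.between_module_r).astype(float)
    if s_carrier and config.effect_participation != 0.0:
        involved = np.isin(labels, config.participation_modules)
        cross = (involved[:, None] | involved[None, :]) & ~same
        cov[cross] -= config.effect_participation
    if comt_risk and config.effect_slope != 0.0:
        for m in config.slope_modules:
            in_m = labels == m
            block = in_m[:, None] & in_m[None, :] & same
            cov[block] -= config.effect_slope * neuro_z
    cov = np.clip(cov, -0.95, 0.95)
    np.fill_diagonal(cov, 1.0)
    lam = 0.0
    while np.linalg.eigvalsh(cov)[0] < 1e-8:
        lam += 0.05
        cov = (1 - lam) * cov + lam * np.eye(n)
        warnings.warn(f"covariance shrunk toward identity (lambda={lam:.2f})", stacklevel=2)
        if lam >= 1.0:
            break
    return cov


def _smooth_series(rng, t: int, width: int = 10) -> np.ndarray:
    x = rng.standard_normal(t + width)
    kernel = np.hanning(width)
    kernel /= kernel.sum()
    y = np.convolve(x, kernel, mode="same")[:t]
    return (y - y.mean()) / y.std()


def _simulate_motion(rng, config: SimConfig) -> np.ndarray:
    t = config.n_volumes
    steps = rng.normal(0.0, config.motion_step_mm, size=(t, 6))
    steps[:, 3:] /= 50.0  # rotations in radians; ~same FD scale as translations
    spikes = rng.random(t) < config.spike_rate
    spikes[0] = False
    steps[spikes, :3] += rng.choice([-1.0, 1.0], size=(int(spikes.sum()), 3)) * config.spike_mm
    motion = np.cumsum(steps, axis=0)
    return motion - motion[0]


def simulate_cohort(config: SimConfig | None = None, **overrides) -> SyntheticCohort:
    """Generate a full synthetic cohort with ground truth.

    All randomness flows from ``config.seed``.  Nuisance components
    (global, WM, CSF, motion-coupled) are added to the network signal so
    the cleanup stage has real work to do; setting the amplitudes to 0
    yields artifact-free data.
    """
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = SimConfig(**{**asdict(config), **overrides})
    rng = np.random.default_rng(config.seed)
    genotypes = simulate_genotypes(config, rng)
    phenotypes = simulate_phenotypes(config, rng)
    coords = roi_coordinates(config, rng)
    labels = module_labels(config)

    s_carrier = genotypes["httlpr"].map(lambda g: g is not None and "S" in g.split("/"))
    comt_risk = (genotypes["rs4680"] == "Val/Val") | (genotypes["rs165599"] == "A/A")
    neuro_z = (phenotypes["neuroticism"] - config.neuro_mean) / config.neuro_sd

    t, n = config.n_volumes, config.n_rois
    timeseries, motion_traces, nuisance = {}, {}, {}
    for i, sid in enumerate(genotypes["subject_id"]):
        cov = subject_covariance(
            config, labels, bool(s_carrier.iloc[i]), bool(comt_risk.iloc[i]), float(neuro_z.iloc[i])
        )
        chol = np.linalg.cholesky(cov)
        innov = rng.standard_normal((t, n))
        if config.ar_coefficient:
            phi = config.ar_coefficient
            for row in range(1, t):
                innov[row] += phi * innov[row - 1]
            innov *= np.sqrt(1 - phi**2)
        net = innov @ chol.T

        motion = _simulate_motion(rng, config)
        glob = _smooth_series(rng, t)
        wm = _smooth_series(rng, t)
        csf = _smooth_series(rng, t)
        fd_like = np.zeros(t)
        fd_like[1:] = np.abs(np.diff(motion[:, :3], axis=0)).sum(axis=1)
        fd_like = (fd_like - fd_like.mean()) / (fd_like.std() + 1e-12)
        data = (
            net
            + config.global_amp * glob[:, None]
            + config.wm_amp * wm[:, None]
            + config.csf_amp * csf[:, None]
            + config.motion_amp * fd_like[:, None]
        )
        timeseries[sid] = data
        motion_traces[sid] = motion
        nuisance[sid] = np.column_stack([glob, wm, csf])

    return SyntheticCohort(
        config=config,
        genotypes=genotypes,
        phenotypes=phenotypes,
        coords=coords,
        module_labels=labels,
        timeseries=timeseries,
        motion=motion_traces,
        nuisance=nuisance,
    )


# ---------------------------------------------------------------------------
# on-disk layout


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Write every table of the cohort as TSV plus ground_truth.json.

    Layout: genotypes.tsv, phenotypes.tsv, coords.tsv, ground_truth.json
    and subjects/<id>_{ts,motion,nuisance}.tsv.
    """
    outdir = Path(outdir)
    (outdir / "subjects").mkdir(parents=True, exist_ok=True)
    geno = cohort.genotypes.fillna("NA")
    geno.to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
    cohort.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    cohort.coords.to_csv(outdir / "coords.tsv", sep="\t", index=False)
    roi_ids = list(cohort.coords["roi_id"])
    for sid in cohort.subject_ids:
        pd.DataFrame(cohort.timeseries[sid], columns=roi_ids).to_csv(
            outdir / "subjects" / f"{sid}_ts.tsv", sep="\t", index=False, float_format="%.6f"
        )
        pd.DataFrame(cohort.motion[sid], columns=["x", "y", "z", "pitch", "roll", "yaw"]).to_csv(
            outdir / "subjects" / f"{sid}_motion.tsv", sep="\t", index=False, float_format="%.6f"
        )
        pd.DataFrame(cohort.nuisance[sid], columns=["global", "wm", "csf"]).to_csv(
            outdir / "subjects" / f"{sid}_nuisance.tsv", sep="\t", index=False, float_format="%.6f"
        )
    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cohort.config).items()
        },
        "module_labels": cohort.module_labels.tolist(),
        "participation_modules": list(cohort.config.participation_modules),
        "slope_modules": list(cohort.config.slope_modules),
        "effect_participation": cohort.config.effect_participation,
        "effect_slope": cohort.config.effect_slope,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return outdir


def read_cohort(indir) -> SyntheticCohort:
    """Read a cohort directory back through the pipeline's readers."""
    indir = Path(indir)
    with open(indir / "ground_truth.json") as fh:
        truth = json.load(fh)
    cfg_raw = truth["config"]
    for key in ("participation_modules", "slope_modules"):
        cfg_raw[key] = tuple(cfg_raw[key])
    config = SimConfig(**cfg_raw)
    from .genotypes import read_genotype_table

    genotypes = read_genotype_table(indir / "genotypes.tsv")
    phenotypes = pd.read_csv(indir / "phenotypes.tsv", sep="\t")
    coords = pd.read_csv(indir / "coords.tsv", sep="\t")
    timeseries, motion, nuisance = {}, {}, {}
    for sid in genotypes["subject_id"]:
        timeseries[sid] = pd.read_csv(indir / "subjects" / f"{sid}_ts.tsv", sep="\t").to_numpy()
        motion[sid] = pd.read_csv(indir / "subjects" / f"{sid}_motion.tsv", sep="\t").to_numpy()
        nuisance[sid] = pd.read_csv(indir / "subjects" / f"{sid}_nuisance.tsv", sep="\t").to_numpy()
    return SyntheticCohort(
        config=config,
        genotypes=genotypes,
        phenotypes=phenotypes,
        coords=coords,
        module_labels=np.array(truth["module_labels"]),
        timeseries=timeseries,
        motion=motion,
        nuisance=nuisance,
    )
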