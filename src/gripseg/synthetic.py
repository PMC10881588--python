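"""Synthetic cohorts with the statistical structure the pipeline assumes.

No public accession exists for the study cohort, so every pipeline stage
is exercised on simulated data that reproduces its statistical skeleton:

* per subject, a block-structured correlation matrix — within-network
  off-diagonals ``w_i``, between-network off-diagonals ``b_i`` — from which
  either multivariate-normal ROI time series are sampled or exact
  (noise-free) Fisher-z matrices are emitted;
* a latent, subject-level segregation on the Fisher-z scale,
  ``s_i = 1 - atanh(b_i)/atanh(w_i)``, which is what the closed-form block
  matrix yields for every network and globally;
* linear phenotype couplings: handgrip depends on ``s_i`` (slope alpha1,
  kg per segregation unit) plus demographic loadings; cognition depends on
  handgrip (slope beta1, T-units per kg) and optionally directly on ``s_i``
  (slope beta2), giving a tunable mediation structure;
* a demographic/covariate block (age, sex, education, intracranial and
  grey-matter volume, GDS, BMI, waist-hip ratio, scan interval) with
  distributions matched to the study sample's summary statistics.

Because ``(w_i, b_i)`` are homogeneous across networks, every network's
closed-form segregation equals the global one — the minimal structure
under which between-subject segregation-phenotype associations are
well-defined.  Defaults target the study scale: n = 148, 235 usable
volumes of an 8-min TR-2s scan, 142 regions over nine networks (the
salience/ventral-attention analogue has 22 regions, hence 231 intra-network
pairs), handgrip mean ~22.3 kg SD ~7 kg, and a handgrip-segregation
correlation of roughly 0.27.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, ROITimeSeries
from .phenotypes import DEFAULT_BATTERY, handgrip_score, write_battery_config
from .segregation import NetworkPartition, write_partition

#: nine-network partition analogue: 112 cortical + 30 subcortical = 142 regions,
#: with 22 salience/ventral-attention regions (231 intra-network pairs)
DEFAULT_NETWORK_SIZES: dict[str, int] = {
    "default": 24,
    "control": 14,
    "limbic": 10,
    "salience_ventral_attention": 22,
    "dorsal_attention": 12,
    "somatomotor": 16,
    "visual": 12,
    "temporoparietal": 2,
    "subcortical": 30,
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """All knobs of the generative model; ``seed`` is mandatory."""

    seed: int
    n_subjects: int = 148
    timepoints: int = 235
    network_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_NETWORK_SIZES))

    # subject-level connectivity heterogeneity (correlation scale)
    within_mean: float = 0.45
    within_sd: float = 0.08
    within_bounds: tuple[float, float] = (0.05, 0.85)
    between_mean: float = 0.12
    between_sd: float = 0.04
    between_floor: float = 0.0
    between_gap: float = 0.02   # enforce b <= w - gap

    # handgrip model: alpha0 + alpha1*s + demographic loadings + noise (kg)
    alpha0: float = 8.0
    alpha1: float = 19.0        # kg per segregation unit (corr(grip, s) ~ 0.27)
    age_grip: float = -0.20     # kg per year, age centred
    sex_grip: float = 8.0       # kg male-female gap, sex centred
    edu_grip: float = 0.15      # kg per education year, centred
    grip_noise_sd: float = 5.4
    trial_noise_sd: float = 0.8  # per-dynamometer-reading jitter (kg)

    # cognition model: beta0 + beta1*(grip - 22.3) + beta2*(s - s0) + loadings
    beta0: float = 50.0
    beta1: float = 0.25         # T-units per kg
    beta2: float = 0.0          # direct segregation path (mediation structure)
    age_cog: float = -0.35
    edu_cog: float = 0.50
    cog_noise_sd: float = 4.5
    test_noise_sd: float = 5.0
    grip_center: float = 22.3
    seg_center: float = 0.75

    # demographics (study-sample summary scale)
    age_mean: float = 72.8
    age_sd: float = 3.9
    p_male: float = 65.0 / 148.0
    edu_mean: float = 7.28
    edu_sd: float = 3.97
    ticv_mean: float = 1.45e6
    ticv_sd: float = 1.1e5
    ticv_sex_shift: float = 1.0e5
    gmv_frac: float = 0.42
    gmv_noise_sd: float = 2.5e4

    def __post_init__(self) -> None:
        lo, hi = self.within_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("within-correlation bounds must lie in (0, 1)")
        if self.between_floor < 0.0 or self.between_floor >= hi:
            raise ValueError("between-correlation floor must lie in [0, within)")
        if any(n < 2 for n in self.network_sizes.values()):
            raise ValueError("every network needs at least 2 regions")
        if self.timepoints < 3:
            raise ValueError("timepoints must be at least 3")

    @property
    def n_regions(self) -> int:
        return sum(self.network_sizes.values())

    def partition(self) -> NetworkPartition:
        assignment: dict[str, str] = {}
        idx = 1
        for net, size in self.network_sizes.items():
            for _ in range(size):
                assignment[f"R{idx:03d}"] = net
                idx += 1
        return NetworkPartition(assignment, tuple(self.network_sizes))


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Draw by rejection; bounds are narrow enough that this converges fast."""
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())
    raise RuntimeError("truncated-normal rejection sampling did not converge")


def _draw_correlations(spec: SyntheticCohortSpec, rng) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = spec.within_bounds
    w = _truncated_normal(rng, spec.within_mean, spec.within_sd, lo, hi,
                          spec.n_subjects)
    b = np.empty_like(w)
    for i, wi in enumerate(w):
        b[i] = _truncated_normal(rng, spec.between_mean, spec.between_sd,
                                 spec.between_floor, wi - spec.between_gap, 1)[0]
    return w, b


def latent_segregation(w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Closed-form segregation of the block model on the Fisher-z scale."""
    return 1.0 - np.arctanh(b) / np.arctanh(w)


def _block_correlation(spec: SyntheticCohortSpec, w: float, b: float) -> np.ndarray:
    labels = np.repeat(np.arange(len(spec.network_sizes)),
                       list(spec.network_sizes.values()))
    c = np.where(labels[:, None] == labels[None, :], w, b)
    np.fill_diagonal(c, 1.0)
    return c


def _block_fisher_z(spec: SyntheticCohortSpec, w: float, b: float) -> np.ndarray:
    z = _block_correlation(spec, w, b)
    np.fill_diagonal(z, 0.0)
    return np.arctanh(z)


def _phenotypes(spec: SyntheticCohortSpec, s: np.ndarray, rng) -> pd.DataFrame:
    n = spec.n_subjects
    age = rng.normal(spec.age_mean, spec.age_sd, n)
    sex = (rng.random(n) < spec.p_male).astype(int)  # 1 = male
    edu = np.clip(rng.normal(spec.edu_mean, spec.edu_sd, n), 0.0, None)
    ticv = rng.normal(spec.ticv_mean, spec.ticv_sd, n) \
        + spec.ticv_sex_shift * (sex - spec.p_male)
    gmv = spec.gmv_frac * ticv + rng.normal(0.0, spec.gmv_noise_sd, n)

    grip_true = (
        spec.alpha0 + spec.alpha1 * s
        + spec.age_grip * (age - spec.age_mean)
        + spec.sex_grip * (sex - spec.p_male)
        + spec.edu_grip * (edu - spec.edu_mean)
        + rng.normal(0.0, spec.grip_noise_sd, n)
    )
    grip_true = np.clip(grip_true, 1.0, None)
    trials = {
        f"grip_{hand}_{t}": np.round(
            np.clip(grip_true + rng.normal(0.0, spec.trial_noise_sd, n), 0.5, None), 1)
        for hand in ("left", "right") for t in (1, 2)
    }
    handgrip = np.array([
        handgrip_score(
            [trials["grip_left_1"][i], trials["grip_left_2"][i]],
            [trials["grip_right_1"][i], trials["grip_right_2"][i]])
        for i in range(n)
    ])

    cog = (
        spec.beta0 + spec.beta1 * (handgrip - spec.grip_center)
        + spec.beta2 * (s - spec.seg_center)
        + spec.age_cog * (age - spec.age_mean)
        + spec.edu_cog * (edu - spec.edu_mean)
        + rng.normal(0.0, spec.cog_noise_sd, n)
    )

    df = pd.DataFrame({
        "subject_id": [f"S{i + 1:04d}" for i in range(n)],
        "handgrip": handgrip,
        **trials,
        "age": age,
        "sex": sex,
        "education": edu,
        "ticv": ticv,
        "gmv": gmv,
        "gds": np.clip(rng.poisson(2.33, n), 0, 15),
        "bmi": rng.normal(23.0, 3.4, n),
        "whr": rng.normal(0.917, 0.068, n),
        "scan_interval": rng.normal(276.6, 156.6, n),
    })
    # raw cognitive test scores around the latent cognition; timed tests are
    # emitted on a "longer is worse" scale so the direction flag matters
    for test, (_, higher_is_better) in DEFAULT_BATTERY.items():
        noise = rng.normal(0.0, spec.test_noise_sd, n)
        raw = cog + noise
        df[test] = raw if higher_is_better else 200.0 - raw
    df["smmse"] = np.clip(np.round(26.4 + 0.2 * (cog - 50.0)
                                   + rng.normal(0.0, 2.0, n)), 10, 30)
    # latent truth for parameter-recovery checks
    df["latent_seg"] = s
    df["latent_cognition"] = cog
    return df


def generate_matrices(spec: SyntheticCohortSpec
                      ) -> tuple[list[ConnectivityMatrix], pd.DataFrame]:
    """Exact (noise-free) prepared Fisher-z block matrices plus phenotypes.

    The fast deterministic route: the empirical segregation of each matrix
    equals the latent ``s_i`` to machine precision, so estimation checks are
    not confounded by finite-scan sampling noise.
    """
    rng = np.random.default_rng(spec.seed)
    w, b = _draw_correlations(spec, rng)
    s = latent_segregation(w, b)
    pheno = _phenotypes(spec, s, rng)
    pheno["latent_w"] = w
    pheno["latent_b"] = b
    region_ids = tuple(spec.partition().assignment)
    mats = [
        ConnectivityMatrix(sid, _block_fisher_z(spec, wi, bi), region_ids,
                           prepared=True)
        for sid, wi, bi in zip(pheno["subject_id"], w, b)
    ]
    return mats, pheno


def generate_cohort(spec: SyntheticCohortSpec
                    ) -> tuple[list[ROITimeSeries], pd.DataFrame]:
    """Multivariate-normal ROI time series per subject plus the phenotype table.

    Each subject's T x R signal is sampled from N(0, C_i) with C_i the
    block correlation matrix built from (w_i, b_i); phenotypes are coupled
    to the latent segregation exactly as in :func:`generate_matrices`.
    """
    rng = np.random.default_rng(spec.seed)
    w, b = _draw_correlations(spec, rng)
    s = latent_segregation(w, b)
    pheno = _phenotypes(spec, s, rng)
    pheno["latent_w"] = w
    pheno["latent_b"] = b
    region_ids = tuple(spec.partition().assignment)
    series = []
    for sid, wi, bi in zip(pheno["subject_id"], w, b):
        c = _block_correlation(spec, wi, bi)
        try:
            chol = np.linalg.cholesky(c)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                f"non-positive-definite correlation for subject {sid} "
                f"(w={wi:.4f}, b={bi:.4f})") from err
        x = rng.standard_normal((spec.timepoints, spec.n_regions)) @ chol.T
        series.append(ROITimeSeries(sid, x, region_ids))
    return series, pheno


def write_cohort(spec: SyntheticCohortSpec, out_dir: str,
                 time_series: bool = True) -> dict[str, str]:
    """Write the full input layout: time-series (or matrix) files, partition
    TSV, phenotype CSV, truth CSV and battery config.  Returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    ts_dir = os.path.join(out_dir, "timeseries" if time_series else "matrices")
    os.makedirs(ts_dir, exist_ok=True)
    truth_cols = ["subject_id", "latent_w", "latent_b", "latent_seg",
                  "latent_cognition"]
    if time_series:
        series, pheno = generate_cohort(spec)
        for ts in series:
            pd.DataFrame(ts.values, columns=list(ts.region_ids)).to_csv(
                os.path.join(ts_dir, f"{ts.subject_id}.tsv"),
                sep="\t", index=False, float_format="%.17g")
    else:
        from .connectivity import write_matrix

        mats, pheno = generate_matrices(spec)
        for m in mats:
            write_matrix(m, os.path.join(ts_dir, f"{m.subject_id}.tsv"))
    paths = {
        "data_dir": ts_dir,
        "partition": os.path.join(out_dir, "partition.tsv"),
        "phenotypes": os.path.join(out_dir, "phenotypes.csv"),
        "truth": os.path.join(out_dir, "truth.csv"),
        "battery": os.path.join(out_dir, "battery.cfg"),
    }
    write_partition(spec.partition(), paths["partition"])
    pheno.drop(columns=truth_cols[1:]).to_csv(
        paths["phenotypes"], index=False, float_format="%.17g")
    pheno[truth_cols].to_csv(paths["truth"], index=False, float_format="%.17g")
    write_battery_config(DEFAULT_BATTERY, paths["battery"])
    return paths


def null_spec(seed: int, **overrides) -> SyntheticCohortSpec:
    """Spec with every segregation-phenotype coupling zeroed (type-I studies)."""
    return replace(SyntheticCohortSpec(seed=seed, alpha1=0.0, beta1=0.0,
                                       beta2=0.0), **overrides)
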