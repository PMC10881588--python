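"""End-to-end orchestration: fc -> segregate -> associate -> mediate.

The run mirrors the study's analysis flow on a directory of inputs:

1. per-subject connectivity (Pearson + Fisher-z) from ROI time-series
   files, or pre-computed matrices, then preparation (diagonal/negative
   zeroing);
2. segregation profiles (global, per-network, intra-/inter-network means)
   and the focal network's edge table;
3. association families with per-family BH-FDR:
   (a) handgrip -> five cognitive measures (age/sex/education),
   (b) handgrip -> nine network segregations, global reported alongside
       but excluded from the nine-member correction,
   (c) handgrip -> focal-network intra- plus eight inter-network means,
   (d) handgrip -> every intra-network edge of the focal network,
   (e) for each FC measure FDR-significant in (b)-(d): FC -> five
       cognitive measures; families (b)-(e) add intracranial volume as a
       covariate;
4. mediation (handgrip -> FC measure -> cognition) for measures
   significant with both handgrip and a cognitive outcome.

Validation covariate sets only alter the covariate lists (adding SM-MMSE,
GDS, BMI, waist-hip ratio or scan interval, or swapping intracranial for
grey-matter volume).  Outputs are fixed-order TSVs plus a JSON run log
with versions, seeds and row counts but no wall-clock data, so reruns
with an identical config are byte-identical.
"""

from __future__ import annotations

import glob
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .association import results_to_frame, run_family
from .connectivity import compute_fc, prepare_matrix, read_matrix, read_timeseries
from .mediation import mediate
from .phenotypes import DEFAULT_BATTERY, read_battery_config, score_battery
from .segregation import (NetworkPartition, edges_to_frame, profile_subject,
                          profiles_to_frame, read_partition)

COGNITIVE_OUTCOMES = ("global", "processing_speed", "attention",
                      "executive_function", "smmse")

COVARIATE_SETS = ("base", "+smmse", "+gds", "+bmi", "+whr", "+interval", "gmv-swap")


@dataclass(frozen=True)
class RunConfig:
    data_dir: str                 # per-subject time-series or matrix files
    partition_path: str
    phenotypes_path: str
    out_dir: str
    battery_path: str | None = None
    matrices_precomputed: bool = False  # data_dir holds prepared z matrices
    focal_network: str = "salience_ventral_attention"
    covariate_set: str = "base"
    seed: int = 0
    n_boot: int = 5000

    def __post_init__(self) -> None:
        if self.covariate_set not in COVARIATE_SETS:
            raise ValueError(f"covariate_set must be one of {COVARIATE_SETS}")
        for path in (self.data_dir, self.partition_path, self.phenotypes_path):
            if not os.path.exists(path):
                raise FileNotFoundError(path)


def covariate_lists(covariate_set: str) -> tuple[list[str], list[str]]:
    """(cognition-family covariates, FC-family covariates) for a selector."""
    cog = ["age", "sex", "education"]
    fc = ["age", "sex", "education", "ticv"]
    extra = {"+smmse": "smmse", "+gds": "gds", "+bmi": "bmi",
             "+whr": "whr", "+interval": "scan_interval"}
    if covariate_set in extra:
        cog = cog + [extra[covariate_set]]
        fc = fc + [extra[covariate_set]]
    elif covariate_set == "gmv-swap":
        fc = ["age", "sex", "education", "gmv"]
    return cog, fc


def load_matrices(config: RunConfig):
    files = sorted(glob.glob(os.path.join(config.data_dir, "*.tsv")))
    if not files:
        raise FileNotFoundError(f"no .tsv files in {config.data_dir}")
    mats = []
    for path in files:
        if config.matrices_precomputed:
            mats.append(read_matrix(path, prepared=True))
        else:
            mats.append(prepare_matrix(compute_fc(read_timeseries(path))))
    return mats


def measure_table(matrices, partition: NetworkPartition, focal: str) -> pd.DataFrame:
    """Wide per-subject table of every segregation/connectivity measure."""
    profiles = [profile_subject(m, partition) for m in matrices]
    rows = {}
    for pr in profiles:
        row = {"seg_global": pr.seg_global}
        for k in partition.networks:
            row[f"seg:{k}"] = pr.seg[k]
        row[f"intra:{focal}"] = pr.intra[focal]
        for (a, b), v in pr.inter.items():
            if focal in (a, b):
                other = b if a == focal else a
                row[f"inter:{focal}:{other}"] = v
        rows[pr.subject_id] = row
    wide = pd.DataFrame.from_dict(rows, orient="index")
    wide.index.name = "subject_id"
    edges = edges_to_frame(matrices, partition, focal)
    return wide.join(edges), profiles


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute all stages and write the result bundle under ``config.out_dir``."""
    os.makedirs(config.out_dir, exist_ok=True)
    partition = read_partition(config.partition_path)
    if config.focal_network not in partition.networks:
        raise ValueError(f"focal network {config.focal_network!r} not in partition")
    battery = (read_battery_config(config.battery_path)
               if config.battery_path else dict(DEFAULT_BATTERY))
    pheno = pd.read_csv(config.phenotypes_path).set_index("subject_id")

    matrices = load_matrices(config)
    mat_ids = [m.subject_id for m in matrices]
    missing = sorted(set(pheno.index) ^ set(mat_ids))
    if missing:
        raise ValueError(f"subject-id mismatch between phenotypes and "
                         f"connectivity inputs: {missing}")
    matrices = sorted(matrices, key=lambda m: m.subject_id)

    cog = score_battery(pheno, battery)
    measures, profiles = measure_table(matrices, partition, config.focal_network)
    data = pheno.join(cog[[c for c in cog.columns if c not in pheno.columns]],
                      how="inner").join(measures, how="inner")
    data = data.sort_index()

    cov_cog, cov_fc = covariate_lists(config.covariate_set)
    focal = config.focal_network
    seg_outcomes = [f"seg:{k}" for k in partition.networks]
    fc_outcomes = [f"intra:{focal}"] + [
        c for c in measures.columns if c.startswith(f"inter:{focal}:")]
    edge_outcomes = [c for c in measures.columns if c.startswith("edge:")]

    fam_a = run_family("grip_cognition", list(COGNITIVE_OUTCOMES), "handgrip",
                       cov_cog, data)
    fam_b = run_family("grip_segregation", ["seg_global"] + seg_outcomes,
                       "handgrip", cov_fc, data,
                       exclude_from_correction=["seg_global"])
    fam_c = run_family("grip_focal_fc", fc_outcomes, "handgrip", cov_fc, data)
    fam_d = run_family("grip_focal_edges", edge_outcomes, "handgrip", cov_fc, data)

    sig_measures = [r.spec.outcome for r in fam_b + fam_c + fam_d if r.significant]
    fam_e: list = []
    for meas in sig_measures:
        fam_e.extend(run_family(f"fc_cognition:{meas}", list(COGNITIVE_OUTCOMES),
                                meas, cov_fc, data))

    med_rows = []
    for meas in sig_measures:
        sig_cog = [r.spec.outcome for r in fam_e
                   if r.spec.family_id == f"fc_cognition:{meas}" and r.significant]
        for outcome in sig_cog:
            res = mediate(data["handgrip"], data[meas], data[outcome],
                          covariates=data[cov_fc].to_numpy(float),
                          n_boot=config.n_boot, seed=config.seed)
            med_rows.append({
                "mediator": meas, "outcome": outcome, "a": res.a, "b": res.b,
                "c": res.c, "c_prime": res.c_prime, "indirect": res.indirect,
                "proportion_mediated": res.proportion_mediated,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "p_boot": res.p_boot, "n_boot": res.n_boot, "seed": res.seed,
            })
    med_cols = ["mediator", "outcome", "a", "b", "c", "c_prime", "indirect",
                "proportion_mediated", "ci_low", "ci_high", "p_boot",
                "n_boot", "seed"]
    mediation_df = pd.DataFrame(med_rows, columns=med_cols)

    bundle = {
        "profiles": profiles_to_frame(profiles),
        "associations_grip_cognition": results_to_frame(fam_a),
        "associations_grip_segregation": results_to_frame(fam_b),
        "associations_grip_focal_fc": results_to_frame(fam_c),
        "associations_grip_focal_edges": results_to_frame(fam_d),
        "associations_fc_cognition": results_to_frame(fam_e) if fam_e
        else results_to_frame([]),
        "mediation": mediation_df,
        "cognitive_scores": cog.reset_index(),
    }
    for name, df in bundle.items():
        df.to_csv(os.path.join(config.out_dir, f"{name}.tsv"), sep="\t",
                  index=False, float_format="%.12g")

    log = {
        "gripseg_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "n_boot": config.n_boot,
        "covariate_set": config.covariate_set,
        "focal_network": config.focal_network,
        "n_subjects": int(len(data)),
        "n_matrices": len(matrices),
        "significant_fc_measures": sorted(sig_measures),
        "sex_encoding": "0=female, 1=male",
    }
    with open(os.path.join(config.out_dir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return bundle
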