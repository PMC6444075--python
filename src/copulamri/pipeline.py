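"""End-to-end pipeline: maps -> copula matrices -> features -> subtypes -> stats.

Stages mirror the study design: per-patient voxel pairs are copula-transformed
and discretized, second-order features feed complete-linkage clustering with
the validity-index vote choosing k, LOOCV consensus measures cluster
stability, and the resulting subtypes drive group comparisons and survival
models. Every stage consumes/emits CSV so stages are independently
scriptable; a run-metadata JSON echoes the configuration so a run can be
reproduced bit-exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    cluster_consensus_means,
    hierarchical_cluster,
    loocv_consensus,
    select_k,
)
from .config import RunConfig
from .copula import JointDistributionMatrix, patient_matrix
from .features import FEATURE_NAMES, cohort_feature_table
from .imaging_io import VoxelPairSample, load_cohort, read_manifest
from .stats import (
    adjust_family,
    compare_groups,
    cox_fit,
    kaplan_meier,
    logrank_test,
    subtype_indicators,
)

logger = logging.getLogger(__name__)

#: Clinical covariates used in the Cox models, in reporting order.
COX_COVARIATES = (
    "age",
    "sex_male",
    "extent_of_resection",
    "mgmt_methylated",
    "idh_mutant",
    "tumor_volume_cm3",
)


def matrices_from_samples(
    samples: list[VoxelPairSample], bins: int = 10
) -> list[tuple[str, JointDistributionMatrix]]:
    out = []
    for s in samples:
        logger.info("patient %s: %d voxels (%d dropped)", s.patient_id, s.n_voxels, s.n_dropped)
        out.append((s.patient_id, patient_matrix(s, bins=bins)))
    return out


def matrices_to_frame(
    matrices: list[tuple[str, JointDistributionMatrix]]
) -> pd.DataFrame:
    """Long-format CSV-friendly view: patient_id, row bin, column bin, count."""
    rows = []
    for pid, m in matrices:
        for i in range(m.bins):
            for j in range(m.bins):
                rows.append(
                    {"patient_id": pid, "adc_bin": i + 1, "rcbv_bin": j + 1,
                     "count": int(m.counts[i, j])}
                )
    return pd.DataFrame(rows)


def frame_to_matrices(df: pd.DataFrame) -> list[tuple[str, JointDistributionMatrix]]:
    out = []
    for pid, g in df.groupby("patient_id", sort=False):
        bins = int(g["adc_bin"].max())
        counts = np.zeros((bins, bins), dtype=np.int64)
        counts[g["adc_bin"] - 1, g["rcbv_bin"] - 1] = g["count"]
        out.append((str(pid), JointDistributionMatrix(counts=counts, n=int(counts.sum()))))
    return out


def reference_subtype(features: pd.DataFrame, labels: np.ndarray) -> int:
    """Pick the reference subtype for Cox indicator coding.

    Clusters are ordered by their mean copula-matrix correlation (the
    interdependence axis); with three or more clusters the middle-ranked
    cluster is the reference (the intermediate-interdependence group, which
    the survival models contrast the extremes against); with two, the one
    with lower mean correlation.
    """
    labels = np.asarray(labels)
    means = {
        int(c): features.loc[labels == c, "correlation"].mean()
        for c in np.unique(labels)
    }
    ordered = sorted(means, key=means.get)
    return ordered[len(ordered) // 2] if len(ordered) >= 3 else ordered[0]


def survival_analysis(
    clinical: pd.DataFrame,
    labels: pd.Series,
    features: pd.DataFrame,
    config: RunConfig,
    time_col: str = "time_days",
    event_col: str = "event",
) -> tuple[pd.DataFrame, dict]:
    """Log-rank + univariate and multivariate Cox for one endpoint.

    Returns the combined Cox table and a small summary dict (log-rank chi2/p,
    per-group KM medians, reference subtype).
    """
    df = clinical.set_index("patient_id").loc[labels.index].copy()
    ref = reference_subtype(features, labels.to_numpy())
    ind = subtype_indicators(labels, reference=ref)
    df = df.join(ind)
    chi2, p = logrank_test(df[time_col], df[event_col], labels)
    km = kaplan_meier(df[time_col], df[event_col], labels)
    covs = [c for c in COX_COVARIATES if c in df.columns] + list(ind.columns)
    constant = [c for c in covs if df[c].dropna().nunique() < 2]
    if constant:
        logger.warning("dropping constant covariate(s) from Cox models: %s", constant)
        covs = [c for c in covs if c not in constant]
    # univariate screen; a covariate with a monotone likelihood (e.g. a rare
    # marker with no events in one level) is excluded with a warning
    uni_parts, usable = [], []
    for c in covs:
        try:
            uni_parts.append(
                cox_fit(df, [c], time_col, event_col, config.cox_tie_method)
            )
            usable.append(c)
        except RuntimeError as exc:
            logger.warning("excluding covariate %r from Cox models: %s", c, exc)
    uni = pd.concat(uni_parts, ignore_index=True)
    uni["model_type"] = "univariate"
    multi = cox_fit(df, usable, time_col, event_col, config.cox_tie_method, "multivariate")
    table = pd.concat([uni, multi], ignore_index=True)
    summary = {
        "logrank_chi2": chi2,
        "logrank_p": p,
        "reference_subtype": ref,
        "km_median_by_subtype": {g: c.median for g, c in km.items()},
    }
    return table, summary


def group_comparisons(
    clinical: pd.DataFrame, labels: pd.Series, quantities: list[str]
) -> pd.DataFrame:
    """Kruskal-Wallis across subtypes for each quantity, BH-adjusted as a family."""
    df = clinical.set_index("patient_id").loc[labels.index]
    results = [
        compare_groups(df[q], labels, quantity=q) for q in quantities if q in df.columns
    ]
    adjust_family(results)
    rows = [
        {"quantity": r.quantity, "kruskal_h": r.statistic,
         "raw_p": r.raw_p, "adjusted_p": r.adjusted_p}
        for r in results
    ]
    return pd.DataFrame(rows)


def run_pipeline(
    manifest: str | Path | pd.DataFrame,
    clinical_table: str | Path | pd.DataFrame | None,
    config: RunConfig,
    out_dir: str | Path,
    samples: list[VoxelPairSample] | None = None,
) -> dict:
    """Run the full analysis and write all artifacts under ``out_dir``.

    ``samples`` may be passed directly (e.g. from the synthetic generator) to
    bypass image I/O; otherwise patients are loaded from the manifest. Returns
    a results dict with the feature table, labels, consensus matrix and the
    stage summaries, mirroring what is written to disk.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if samples is None:
        mdf = manifest if isinstance(manifest, pd.DataFrame) else read_manifest(manifest)
        samples = load_cohort(mdf)
    matrices = matrices_from_samples(samples, bins=config.bins)
    features = cohort_feature_table(
        matrices, config.homogeneity_variant, config.entropy_base
    )
    features.to_csv(out_dir / "features.csv")
    matrices_to_frame(matrices).to_csv(out_dir / "matrices.csv", index=False)

    k_best, votes = select_k(
        features, config.k_min, min(config.k_max, len(features) - 2),
        standardize=config.standardize,
    )
    assign = hierarchical_cluster(features, k_best, standardize=config.standardize)
    assign.vote_table = votes
    assign.to_frame().to_csv(out_dir / "labels.csv", index=False)
    pd.DataFrame(
        sorted(votes.items()), columns=["index", "voted_k"]
    ).to_csv(out_dir / "votes.csv", index=False)

    consensus = loocv_consensus(features, k_best, standardize=config.standardize)
    consensus.to_frame().to_csv(out_dir / "consensus.csv")
    cons_means = cluster_consensus_means(consensus, assign.labels)

    labels = pd.Series(assign.labels, index=features.index, name="subtype")
    results: dict = {
        "features": features,
        "assignment": assign,
        "consensus": consensus,
        "k_best": k_best,
        "votes": votes,
        "consensus_means": cons_means,
    }

    if clinical_table is not None:
        clinical = (
            clinical_table
            if isinstance(clinical_table, pd.DataFrame)
            else pd.read_csv(clinical_table, dtype={"patient_id": str})
        )
        numeric = [
            c for c in clinical.columns
            if c not in ("patient_id", "time_days", "event", "pfs_days",
                         "pfs_event", "subgroup_true")
            and pd.api.types.is_numeric_dtype(clinical[c])
        ]
        gstats = group_comparisons(clinical, labels, numeric)
        gstats.to_csv(out_dir / "group_stats.csv", index=False)
        results["group_stats"] = gstats
        surv_summaries = {}
        cox_os, os_summary = survival_analysis(
            clinical, labels, features, config, "time_days", "event"
        )
        cox_os.to_csv(out_dir / "cox_os.csv", index=False)
        results["cox_os"] = cox_os
        surv_summaries["os"] = os_summary
        if "pfs_days" in clinical.columns:
            cox_pfs, pfs_summary = survival_analysis(
                clinical, labels, features, config, "pfs_days", "pfs_event"
            )
            cox_pfs.to_csv(out_dir / "cox_pfs.csv", index=False)
            results["cox_pfs"] = cox_pfs
            surv_summaries["pfs"] = pfs_summary
        results["survival_summaries"] = surv_summaries

    meta = {
        "package_version": __version__,
        "config": config.to_dict(),
        "n_patients": len(features),
        "k_best": k_best,
        "votes": votes,
        "consensus_means": cons_means,
        "cluster_sizes": {
            int(c): int((assign.labels == c).sum()) for c in np.unique(assign.labels)
        },
    }
    if "survival_summaries" in results:
        meta["survival"] = results["survival_summaries"]
    (out_dir / "run_meta.json").write_text(json.dumps(meta, indent=2, default=float) + "\n")
    return results
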