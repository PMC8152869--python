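"""End-to-end orchestration: segment -> consensus -> NMI -> shape -> metrics -> classify.

`run_pipeline` executes the full analysis on an in-memory cohort and returns
a JSON-serializable summary.  Every stage draws its randomness from a
per-stage child of one global seed (numpy SeedSequence spawning), so reruns
with the same configuration are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import build_features, crossval_classify, pca_embed
from .fixels import extract_fixels_volume, fixel_fc, match_fixels
from .micro import (
    aggregate_metric,
    fdr_bh,
    group_permutation_test,
    partial_correlation,
    tensor_metrics,
)
from .morphometry import (
    covariate_adjusted_one_sample_test,
    jacobian_field,
    log_jacobian,
    nucleus_shape_stats,
    volume_ratio_from_logj,
)
from .parcellation import (
    ClusteringConfig,
    Parcellation,
    kmeans_segment,
    match_labels,
)
from .phantom import Cohort
from .shmath import FODImage, SHBasis
from .similarity import nmi, nmi_permutation_test

COVARIATES = ("age", "icv", "doc_duration")
GROUP_COVARIATES = ("age", "icv")  # DOC duration is zero for every control by
# convention, so between-group adjustment for it would absorb the group
# contrast itself; it is adjusted for only in patient-only analyses


@dataclass(frozen=True)
class PipelineConfig:
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    n_perm_metrics: int = 2000
    n_perm_nmi: int = 1000
    q: float = 0.05
    peak_threshold: float = 0.1
    max_fixels: int = 3
    fixel_match_angle: float = 45.0
    n_folds: int = 3
    n_repeats: int = 20
    seed: int = 0


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def subject_voxel_metrics(
    subject,
    basis: SHBasis,
    analysis_mask: np.ndarray,
    template_fixels: list,
    config: PipelineConfig,
) -> dict:
    """Per-voxel FD/FC/FDC fixel values (template-matched) and tensor maps."""
    coeffs = subject.fod.coeffs[analysis_mask]
    fixels = extract_fixels_volume(
        coeffs, basis, peak_threshold=config.peak_threshold, max_fixels=config.max_fixels
    )
    J = jacobian_field(subject.warp_field, subject.fod.voxel_size)[analysis_mask]
    fd, fc, fdc, voxel_of = [], [], [], []
    for v, (sub_fx, tmp_fx) in enumerate(zip(fixels, template_fixels)):
        matched = match_fixels(sub_fx, tmp_fx, max_angle_deg=config.fixel_match_angle)
        for f in matched:
            if f is None:
                continue
            f_fc = fixel_fc(f.direction, J[v])
            fd.append(f.fd)
            fc.append(f_fc)
            fdc.append(f.fd * f_fc)
            voxel_of.append(v)
    tensors = tensor_metrics(subject.tensor_eigs)
    return {
        "fixel_fd": np.asarray(fd),
        "fixel_fc": np.asarray(fc),
        "fixel_fdc": np.asarray(fdc),
        "fixel_voxel": np.asarray(voxel_of, dtype=int),
        "tensor": {m: tensors[m][analysis_mask] for m in ("FA", "MD", "AD", "RD")},
    }


def region_metric_row(voxel_metrics: dict, region_sel: np.ndarray, voxel_volume: float) -> dict:
    """Aggregate one subject's voxel metrics over one region (flat selection)."""
    sel_fix = region_sel[voxel_metrics["fixel_voxel"]]
    row = {}
    for name, key in (("FD", "fixel_fd"), ("FC", "fixel_fc"), ("FDC", "fixel_fdc")):
        vals = voxel_metrics[key][sel_fix]
        row[name] = float(vals.mean()) if vals.size else float("nan")
    for name in ("FA", "MD", "AD", "RD"):
        row[name] = aggregate_metric(voxel_metrics["tensor"][name], region_sel)
    row["volume"] = float(region_sel.sum()) * voxel_volume
    return row


def build_metric_table(
    region_labels_per_subject: dict[str, np.ndarray],
    voxel_metrics: dict[str, dict],
    region_names: dict[int, str],
    voxel_volume: float,
) -> pd.DataFrame:
    """Subjects x (region, metric) table from flat per-voxel metric bundles."""
    rows = {}
    for sid, labels in region_labels_per_subject.items():
        row = {}
        for lab, name in region_names.items():
            agg = region_metric_row(voxel_metrics[sid], labels == lab, voxel_volume)
            for m, v in agg.items():
                row[f"{name}|{m}"] = v
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def run_pipeline(
    cohort: Cohort,
    config: PipelineConfig | None = None,
    reference: Parcellation | None = None,
    progress: bool = False,
) -> dict:
    """Run the full analysis on a cohort; returns the summary dictionary."""
    config = config or PipelineConfig()
    basis = SHBasis(cohort.config.lmax)
    meta = cohort.metadata.set_index("id")
    ids = meta.index.tolist()
    groups = meta["group"].to_numpy()
    is_doc = np.isin(groups, ["MCS", "VS"])
    covs = meta.loc[:, list(COVARIATES)].to_numpy(dtype=float)
    covs_group = meta.loc[:, list(GROUP_COVARIATES)].to_numpy(dtype=float)
    voxel_volume = float(np.prod(cohort.config.voxel_size))
    k = cohort.config.k_nuclei

    # --- stage 1: template segmentation on the cohort-mean FOD -------------
    mean_coeffs = np.mean([s.fod.coeffs for s in cohort.subjects], axis=0)
    template_fod = FODImage(mean_coeffs, cohort.config.voxel_size, cohort.mask)
    template_parc = kmeans_segment(template_fod, config=config.clustering)
    if reference is not None:
        template_parc = match_labels(template_parc, reference)

    # --- stage 2: individual segmentations, label-matched to the template --
    individual: dict[str, Parcellation] = {}
    for sid, subject in zip(ids, cohort.subjects):
        parc = kmeans_segment(subject.fod, config=config.clustering)
        individual[sid] = match_labels(parc, template_parc)

    # --- stage 3: group consensus partitions and NMI permutation test ------
    hc_parcs = [individual[i] for i, d in zip(ids, is_doc) if not d]
    doc_parcs = [individual[i] for i, d in zip(ids, is_doc) if d]
    nmi_result = nmi_permutation_test(
        doc_parcs, hc_parcs, n_perm=config.n_perm_nmi, seed=_stage_seed(config.seed, 3), k=k
    )

    # --- stage 4: shape statistics (patients' warps) ------------------------
    logj = {
        sid: log_jacobian(s.warp_field, s.fod.voxel_size, mask=cohort.mask)
        for sid, s in zip(ids, cohort.subjects)
    }
    shape_means = np.array([nucleus_shape_stats(logj[sid], individual[sid]) for sid in ids])
    volume_ratios = np.array([volume_ratio_from_logj(logj[sid], individual[sid]) for sid in ids])
    doc_idx = np.flatnonzero(is_doc)
    shape_tests = []
    for nuc in range(k):
        t, p = covariate_adjusted_one_sample_test(shape_means[doc_idx, nuc], covs[doc_idx])
        shape_tests.append({"nucleus": nuc + 1, "t": t, "p": p})
    shape_q, shape_sig = fdr_bh(np.array([d["p"] for d in shape_tests]), q=config.q)
    for d, qv, sg in zip(shape_tests, shape_q, shape_sig):
        d["q"], d["significant"] = float(qv), bool(sg)

    # --- stage 5: microstructural metric tables and group statistics -------
    analysis_mask = cohort.mask | (cohort.pathways > 0)
    template_fixels = extract_fixels_volume(
        template_fod.coeffs[analysis_mask],
        basis,
        peak_threshold=config.peak_threshold,
        max_fixels=config.max_fixels,
    )
    voxel_metrics = {
        sid: subject_voxel_metrics(s, basis, analysis_mask, template_fixels, config)
        for sid, s in zip(ids, cohort.subjects)
    }
    flat_nuclei = {sid: _flat_labels(individual[sid].labels, analysis_mask) for sid in ids}
    flat_consensus = _flat_labels(template_parc.labels, analysis_mask)
    flat_pathways = _flat_labels(cohort.pathways, analysis_mask)

    nucleus_names = {n: f"nucleus{n}" for n in range(1, k + 1)}
    n_targets = int(np.ceil(cohort.pathways.max() / k)) if cohort.pathways.max() else 0
    pathway_names = {
        p: f"pathway{(p - 1) // n_targets + 1}t{(p - 1) % n_targets + 1}"
        for p in np.unique(cohort.pathways[cohort.pathways > 0])
    }

    table_individual = build_metric_table(flat_nuclei, voxel_metrics, nucleus_names, voxel_volume)
    table_consensus = build_metric_table(
        {sid: flat_consensus for sid in ids}, voxel_metrics, nucleus_names, voxel_volume
    )
    table_pathways = build_metric_table(
        {sid: flat_pathways for sid in ids}, voxel_metrics, pathway_names, voxel_volume
    )

    group2 = np.where(is_doc, "DOC", "HC")
    stats_nuclei = group_permutation_test(
        table_individual.loc[ids],
        group2,
        covariates=covs_group,
        n_perm=config.n_perm_metrics,
        q=config.q,
        seed=_stage_seed(config.seed, 5),
    )
    stats_pathways = group_permutation_test(
        table_pathways.loc[ids],
        group2,
        covariates=covs_group,
        n_perm=config.n_perm_metrics,
        q=config.q,
        seed=_stage_seed(config.seed, 6),
    )

    # partial correlations of CRS-R with structural markers, patients only
    crs = meta["crs_r_total"].to_numpy(dtype=float)[doc_idx]
    cov_doc = covs[doc_idx]
    def _corr(x, y, covariates):
        # drop covariates (never the CRS-R link itself) if patients are too few
        cov = covariates
        while cov is not None and x.size < cov.shape[1] + 3:
            cov = cov[:, :-1] if cov.shape[1] > 1 else None
        try:
            return partial_correlation(x, y, cov)
        except ValueError:
            return float("nan"), float("nan")

    correlations = []
    for nuc in range(k):
        fd_col = table_individual.loc[ids, f"nucleus{nuc + 1}|FD"].to_numpy()[doc_idx]
        entry = {"nucleus": nuc + 1}
        r, p = _corr(crs, volume_ratios[doc_idx, nuc], cov_doc)
        entry["volume_ratio_r"], entry["volume_ratio_p"] = r, p
        r, p = _corr(crs, fd_col, cov_doc)
        entry["fd_r"], entry["fd_p"] = r, p
        correlations.append(entry)

    # --- stage 6: classification -------------------------------------------
    tasks = {"doc_vs_hc": group2}
    if np.sum(groups == "MCS") >= config.n_folds and np.sum(groups == "VS") >= config.n_folds:
        tasks["mcs_vs_vs"] = groups
    classification = {}
    for task, lab in tasks.items():
        keep = np.ones(len(ids), bool) if task == "doc_vs_hc" else is_doc
        y = lab[keep]
        classification[task] = {}
        for mode, table in (
            ("individual", table_individual),
            ("consensus", table_consensus),
            ("whole", table_individual),
        ):
            feats = build_features(table.loc[ids].iloc[keep], mode=mode)
            cv = crossval_classify(
                feats, y, n_folds=config.n_folds, n_repeats=config.n_repeats,
                seed=_stage_seed(config.seed, 7),
            )
            classification[task][mode] = {
                "mean_accuracy": cv.mean,
                "std_accuracy": cv.std,
            }
        feats = build_features(table_individual.loc[ids].iloc[keep], mode="individual")
        coords, evr = pca_embed(feats, n_components=3)
        classification[task]["pca_explained_variance"] = [float(v) for v in evr]

    summary = {
        "config": {
            "k": k,
            "alpha": config.clustering.alpha,
            "beta": config.clustering.beta,
            "seed": config.seed,
            "n_perm_metrics": config.n_perm_metrics,
            "n_perm_nmi": config.n_perm_nmi,
            "q": config.q,
        },
        "n_subjects": {g: int(np.sum(groups == g)) for g in ("HC", "MCS", "VS")},
        "segmentation": {
            "template_labels": sorted(int(v) for v in np.unique(template_parc.masked_labels())),
            "mean_nmi_individual_vs_template": float(
                np.mean([nmi(individual[i], template_parc) for i in ids])
            ),
        },
        "nmi_test": {
            "observed": nmi_result.observed,
            "p": nmi_result.p_value,
            "null_lower": nmi_result.lower,
            "null_upper": nmi_result.upper,
            "significant": nmi_result.significant,
            "consensus_nmi_hc_vs_doc": nmi_result.observed,
        },
        "shape": {
            "per_nucleus_tests": shape_tests,
            "mean_logj_doc": [float(v) for v in np.nanmean(shape_means[doc_idx], axis=0)],
            "mean_volume_ratio_doc": [float(v) for v in np.nanmean(volume_ratios[doc_idx], axis=0)],
        },
        "metrics": {
            "nuclei": stats_nuclei.table.to_dict(orient="records"),
            "pathways_significant": stats_pathways.significant()[["region", "metric"]].to_dict(
                orient="records"
            ),
        },
        "correlations": correlations,
        "classification": classification,
    }
    summary["tables"] = {
        "individual": table_individual.round(10).to_dict(orient="index"),
    }
    return summary


def _flat_labels(labels: np.ndarray, analysis_mask: np.ndarray) -> np.ndarray:
    return labels[analysis_mask]
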