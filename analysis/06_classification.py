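"""Classify DOC vs HC and MCS vs VS from thalamic microstructure features.

Assembles the 7 metrics x nuclei feature matrices under three parcellation
modes (individualized, consensus template applied to all subjects, and
whole-thalamus means), runs the L1-logistic classifier with stratified
3-fold cross-validation repeated 20 times, and embeds subjects in the top-3
principal components.  Writes results/classification.json.
"""

import json
import sys
import warnings
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED, segment_cohort, study_cohort

from thalparc.features import build_features, crossval_classify, pca_embed
from thalparc.fixels import extract_fixels_volume
from thalparc.pipeline import PipelineConfig, build_metric_table, subject_voxel_metrics
from thalparc.shmath import SHBasis


def main():
    warnings.filterwarnings("ignore")
    cohort = study_cohort()
    cfg = PipelineConfig(seed=SEED)
    basis = SHBasis(cohort.config.lmax)
    template, individual = segment_cohort(cohort)
    meta = cohort.metadata.set_index("id")
    ids = meta.index.tolist()
    analysis_mask = cohort.mask | (cohort.pathways > 0)

    mean_coeffs = np.mean([s.fod.coeffs for s in cohort.subjects], axis=0)
    template_fixels = extract_fixels_volume(
        mean_coeffs[analysis_mask], basis, cfg.peak_threshold, cfg.max_fixels
    )
    voxel_metrics = {
        s.record["id"]: subject_voxel_metrics(s, basis, analysis_mask, template_fixels, cfg)
        for s in cohort.subjects
    }
    k = cohort.config.k_nuclei
    names = {n: f"nucleus{n}" for n in range(1, k + 1)}
    voxvol = float(np.prod(cohort.config.voxel_size))
    tables = {
        "individual": build_metric_table(
            {sid: individual[sid].labels[analysis_mask] for sid in ids},
            voxel_metrics, names, voxvol,
        ),
        "consensus": build_metric_table(
            {sid: template.labels[analysis_mask] for sid in ids},
            voxel_metrics, names, voxvol,
        ),
    }

    groups = meta["group"].to_numpy()
    tasks = {
        "doc_vs_hc": (np.ones(len(ids), bool), np.where(groups == "HC", "HC", "DOC")),
        "mcs_vs_vs": (groups != "HC", groups),
    }
    out = {}
    for task, (keep, labels) in tasks.items():
        out[task] = {}
        for mode in ("individual", "consensus", "whole"):
            table = tables["individual" if mode == "whole" else mode]
            feats = build_features(table.loc[ids].iloc[keep], mode=mode)
            cv = crossval_classify(feats, labels[keep], n_folds=3, n_repeats=20, seed=SEED)
            out[task][mode] = {"mean_accuracy": cv.mean, "std_accuracy": cv.std}
        feats = build_features(tables["individual"].loc[ids].iloc[keep], mode="individual")
        _, evr = pca_embed(feats, n_components=3)
        out[task]["pca_explained_variance"] = [float(v) for v in evr]

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "classification.json").write_text(json.dumps(out, indent=2, sort_keys=True))
    for task in out:
        accs = {m: round(out[task][m]["mean_accuracy"], 3)
                for m in ("individual", "consensus", "whole")}
        print(task, accs)


if __name__ == "__main__":
    main()
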