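"""Nucleus shape statistics from the subject deformation fields.

Computes the voxelwise log-Jacobian determinant of every patient's warp,
averages it over each nucleus of the individual parcellation, tests each
nucleus mean against zero with a covariate-adjusted one-sample t-test
(age, intracranial volume, DOC duration; BH-FDR over nuclei), and reports
the implied volumetric-ratio change relative to the healthy template.
Writes results/shape_stats.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, segment_cohort, study_cohort

from thalparc.micro import fdr_bh
from thalparc.morphometry import (
    covariate_adjusted_one_sample_test,
    log_jacobian,
    nucleus_shape_stats,
    volume_ratio_from_logj,
)


def main():
    cohort = study_cohort()
    _, individual = segment_cohort(cohort)
    meta = cohort.metadata.set_index("id")
    patients = meta.index[meta.group != "HC"]
    covs = meta.loc[patients, ["age", "icv", "doc_duration"]].to_numpy(float)

    means, ratios = [], []
    for sid in patients:
        s = next(x for x in cohort.subjects if x.record["id"] == sid)
        lj = log_jacobian(s.warp_field, s.fod.voxel_size, mask=cohort.mask)
        means.append(nucleus_shape_stats(lj, individual[sid]))
        ratios.append(volume_ratio_from_logj(lj, individual[sid]))
    means, ratios = np.array(means), np.array(ratios)

    rows = []
    for nuc in range(means.shape[1]):
        t, p = covariate_adjusted_one_sample_test(means[:, nuc], covs)
        rows.append(
            {
                "nucleus": nuc + 1,
                "mean_logj": means[:, nuc].mean(),
                "mean_volume_ratio": ratios[:, nuc].mean(),
                "t": t,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["q"], df["significant"] = fdr_bh(df["p"].to_numpy(), q=0.05)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "shape_stats.tsv", sep="\t", index=False, float_format="%.5f")
    print(df.round(4).to_string(index=False))
    exp = df.loc[df.mean_logj.idxmax()]
    shr = df.loc[df.mean_logj.idxmin()]
    print(f"\nlargest expansion: nucleus {int(exp.nucleus)} "
          f"(mean logJ {exp.mean_logj:.3f}, volume ratio {exp.mean_volume_ratio:.3f})")
    print(f"largest shrinkage: nucleus {int(shr.nucleus)} "
          f"(mean logJ {shr.mean_logj:.3f}, volume ratio {shr.mean_volume_ratio:.3f})")


if __name__ == "__main__":
    main()
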