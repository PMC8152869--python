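"""Shared study conditions for the analysis scripts.

One seeded synthetic cohort emulating the study design: 10 healthy controls,
5 MCS and 5 VS patients, one thalamic hemisphere per subject, planted
expansion of nucleus 6 / shrinkage of nucleus 1, FD reduction in nucleus 6
and its pathways, and CRS-R scores coupled to the planted severities.
"""

from pathlib import Path

from thalparc.parcellation import ClusteringConfig, Parcellation, kmeans_segment, match_labels
from thalparc.phantom import EffectConfig, PhantomConfig, make_cohort
from thalparc.shmath import FODImage

SEED = 42
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def study_cohort():
    return make_cohort(
        n_hc=10, n_mcs=5, n_vs=5,
        phantom=PhantomConfig(seed=SEED),
        effects=EffectConfig(),
        seed=SEED,
    )


def segment_cohort(cohort, clustering=None):
    """Template + label-matched individual parcellations for every subject."""
    import numpy as np

    clustering = clustering or ClusteringConfig()
    mean_coeffs = np.mean([s.fod.coeffs for s in cohort.subjects], axis=0)
    template_fod = FODImage(mean_coeffs, cohort.config.voxel_size, cohort.mask)
    template = kmeans_segment(template_fod, config=clustering)
    template = match_labels(template, Parcellation(cohort.labels, cohort.mask))
    individual = {
        s.record["id"]: match_labels(kmeans_segment(s.fod, config=clustering), template)
        for s in cohort.subjects
    }
    return template, individual
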