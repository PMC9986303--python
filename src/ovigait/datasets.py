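"""Bundled reference data.

``load_pca_cohort`` returns the published 20-animal post-stroke dataset
used for the principal component analysis: infarct volume on diffusion MRI,
total neurological score, and six gait measures (global velocity and
head-to-T1 position, left/right forelimb swing durations, left forelimb
stance duration and minimum fetlock angle in swing), exactly as printed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

PCA_COHORT_COLUMNS = {
    "infarct_volume": "cm^3",
    "total_neuroscore": "score (0-36)",
    "mean_velocity": "m/s",
    "mean_head_to_T1": "cm",
    "swing_duration_right": "s",
    "swing_duration_left": "s",
    "stance_duration_left": "s",
    "min_fetlock_swing_left": "deg",
}


def load_pca_cohort() -> pd.DataFrame:
    """The 20-animal PCA input table, indexed by animal id."""
    with resources.files("ovigait.data").joinpath("pca_cohort.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("animal")
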