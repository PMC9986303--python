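"""Correlation PCA of the bundled 20-animal post-stroke reference table.

Eight variables (infarct volume, total neuroscore, two global gait
measures, four forelimb measures) enter a correlation-matrix PCA after
adequacy checks: Bartlett's sphericity test and Kaiser-Meyer-Olkin
sampling adequacy.  Components with eigenvalue > 1 are retained; signs are
anchored so the total neuroscore loads positively on PC1.
"""

import ovigait as og
from ovigait.stats import pca_correlation

data = og.load_pca_cohort()
res = pca_correlation(data, sign_anchor="total_neuroscore")

print(res.summary())
print()
print("loadings (retained components):")
print(res.loadings.iloc[:, :res.n_components].round(2).to_string())
# PC1 groups slow, long-stance, high-neuroscore animals against fast ones
# with a high head carriage; PC2 is dominated by infarct volume.
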