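"""Phase 1: Gaussian profile-similarity kernel between patients.

For one omic layer with patient feature profiles :math:`p_i`, the
patient-patient similarity is

.. math:: A_{ij} = \\exp(-\\alpha\\,\\lVert p_i - p_j \\rVert^2),

the Gaussian interaction-profile kernel on Euclidean distances. ``alpha``
sets the kernel bandwidth: larger values make similarity decay faster with
distance. An unsquared-distance variant ``exp(-alpha * d)`` is available
for sensitivity analysis.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datatypes import OmicsMatrix, SimilarityMatrix

__all__ = ["pairwise_similarity"]


def pairwise_similarity(
    m: OmicsMatrix,
    alpha: float = 1.5,
    squared: bool = True,
) -> SimilarityMatrix:
    """Build the per-omic patient similarity matrix (role ``original``).

    Parameters
    ----------
    m
        Preprocessed omic layer; must contain no missing values.
    alpha
        Positive kernel bandwidth (default 1.5).
    squared
        Use the squared Euclidean distance in the exponent (default); if
        False, uses the plain distance.

    Returns
    -------
    SimilarityMatrix with unit diagonal, entries in (0, 1], symmetric.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if m.has_missing():
        raise ValueError(
            f"omic {m.omic_name!r} still contains missing values; run preprocessing first"
        )
    d = pdist(m.values, metric="sqeuclidean" if squared else "euclidean")
    sim = squareform(np.exp(-alpha * d))
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(
        sample_ids=list(m.sample_ids),
        values=sim,
        role="original",
        omic_name=m.omic_name,
    )
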