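"""scikit-learn style estimator for end-to-end network construction.

:class:`CoexpressionNetwork` wraps the similarity -> threshold-scan ->
adjacency chain behind a ``fit`` interface so it composes with sklearn
tooling; :class:`~gcnforge.comparison.NetworkPCA` and
:class:`~gcnforge.comparison.KMeansBIC` cover the comparison stage.
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator

from .comparison import KMeansBIC, NetworkPCA
from .similarity import similarity_matrix
from .thresholding import adjacency, select_threshold, threshold_curve

__all__ = ["CoexpressionNetwork", "NetworkPCA", "KMeansBIC"]


class CoexpressionNetwork(BaseEstimator):
    """Build a gene co-expression network from an expression matrix.

    Parameters
    ----------
    measure : {"apcc", "ncmi", "nmrs"}
        Pairwise similarity measure.
    bins : int or "auto"
        Histogram bins for the mutual-information measure.
    tau : float or "auto"
        Similarity threshold; ``"auto"`` selects it from the
        clustering-coefficient contrast curve.
    drop_isolated : bool
        Remove degree-0 genes from the fitted network.

    Attributes
    ----------
    similarity_ : SimilarityMatrix
    curve_ : DataFrame            (only when ``tau="auto"``)
    tau_star_ : float
    network_ : Network
    """

    def __init__(self, measure: str = "ncmi", bins="auto", tau="auto",
                 drop_isolated: bool = True):
        self.measure = measure
        self.bins = bins
        self.tau = tau
        self.drop_isolated = drop_isolated

    def fit(self, X: pd.DataFrame, y=None):
        kwargs = {"bins": self.bins} if self.measure == "ncmi" else {}
        self.similarity_ = similarity_matrix(X, measure=self.measure, **kwargs)
        if self.tau == "auto":
            self.curve_ = threshold_curve(self.similarity_)
            self.tau_star_ = select_threshold(self.curve_)
        else:
            self.tau_star_ = float(self.tau)
        net = adjacency(self.similarity_, self.tau_star_)
        if self.drop_isolated:
            net = net.subgraph(net.degrees() > 0)
        self.network_ = net
        return self
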