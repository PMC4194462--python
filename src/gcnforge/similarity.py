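"""Pairwise gene-similarity measures on the [0, 1] scale.

Three measures are provided:

``apcc``
    Absolute value of the Pearson correlation coefficient: detects linear
    co-expression regardless of sign.
``ncmi``
    Non-linear correlation coefficient based on mutual information.  The
    mutual information I(X;Y) is estimated in nats from an equal-width
    two-dimensional histogram (square-root bin rule by default), debiased with
    the Miller-Madow correction, and mapped onto [0, 1] through the global
    correlation coefficient lambda = sqrt(1 - exp(-2 I)).  Detects any
    statistical dependence, including non-monotone (e.g. quadratic)
    relations that Pearson correlation misses.
``nmrs``
    Normalized mean residue similarity: one minus the mean absolute residue
    between the two range-normalised profiles.  Invariant to additive shifts
    and positive scalings, so it detects shifted expression patterns.

Missing values are handled pairwise-complete throughout.  Degenerate inputs
(constant profiles, too few overlapping observations) yield similarity 0
with a warning instead of raising, so that full-matrix computation never
aborts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "apcc",
    "ncmi",
    "nmrs",
    "similarity_matrix",
    "compare_measures",
    "MEASURES",
    "MIN_OVERLAP",
]

#: Minimum number of pairwise-complete observations for any similarity.
MIN_OVERLAP = 3


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles differ in length")
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def _degenerate(reason: str) -> float:
    warnings.warn(f"similarity set to 0: {reason}", stacklevel=3)
    return 0.0


def apcc(x, y) -> float:
    """Absolute Pearson correlation over pairwise-complete observations."""
    xc, yc = _pairwise_complete(x, y)
    if xc.size < MIN_OVERLAP:
        return _degenerate(f"fewer than {MIN_OVERLAP} complete observations")
    if np.ptp(xc) == 0 or np.ptp(yc) == 0:
        return _degenerate("constant profile")
    r = np.corrcoef(xc, yc)[0, 1]
    return float(min(abs(r), 1.0))


def default_bins(n_obs: int) -> int:
    """Default bin count for the 2-D histogram: max(2, floor(sqrt(n / 5))).

    Chosen so the joint histogram keeps about five observations per cell,
    which keeps the plug-in mutual-information bias small; one-dimensional
    rules such as Sturges overbin a B x B joint histogram badly.
    """
    return max(2, int(np.floor(np.sqrt(n_obs / 5.0))))


def ncmi(x, y, bins: int | str = "auto") -> float:
    """Mutual-information similarity lambda = sqrt(1 - exp(-2 I(X;Y))).

    I is the plug-in histogram estimate (nats) with the Miller-Madow
    bias correction, floored at zero.  ``bins`` may be a positive integer or
    ``"auto"`` (square-root rule on the number of complete observations).  When
    fewer than ``2 * bins`` observations are available the bin count is
    reduced with a warning.
    """
    xc, yc = _pairwise_complete(x, y)
    n = xc.size
    if n < MIN_OVERLAP:
        return _degenerate(f"fewer than {MIN_OVERLAP} complete observations")
    if np.ptp(xc) == 0 or np.ptp(yc) == 0:
        return _degenerate("constant profile")
    b = default_bins(n) if bins == "auto" else int(bins)
    if b < 2:
        raise ValueError("bins must be >= 2")
    if n < 2 * b:
        b_new = max(2, n // 2)
        warnings.warn(f"only {n} observations for {b} bins; reducing to {b_new}",
                      stacklevel=2)
        b = b_new
    counts, _, _ = np.histogram2d(xc, yc, bins=b)
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))
    # Miller-Madow debiasing of the plug-in estimate
    kx = int((counts.sum(axis=1) > 0).sum())
    ky = int((counts.sum(axis=0) > 0).sum())
    kxy = int(nz.sum())
    mi -= (kxy - kx - ky + 1) / (2.0 * n)
    mi = max(mi, 0.0)
    lam = np.sqrt(1.0 - np.exp(-2.0 * mi))
    return float(np.clip(lam, 0.0, 1.0))


def nmrs(x, y) -> float:
    """Normalized mean residue similarity of two range-normalised profiles.

    Each profile is mapped onto [0, 1] by (v - min) / (max - min) over the
    pairwise-complete positions; the similarity is 1 minus the mean absolute
    difference of the normalised profiles.  Invariant to additive shift and
    positive scaling of either profile.
    """
    xc, yc = _pairwise_complete(x, y)
    if xc.size < MIN_OVERLAP:
        return _degenerate(f"fewer than {MIN_OVERLAP} complete observations")
    rx, ry = np.ptp(xc), np.ptp(yc)
    if rx == 0 or ry == 0:
        return _degenerate("zero-range profile")
    xn = (xc - xc.min()) / rx
    yn = (yc - yc.min()) / ry
    return float(1.0 - np.mean(np.abs(xn - yn)))


MEASURES = {"apcc": apcc, "ncmi": ncmi, "nmrs": nmrs}


@dataclass
class SimilarityMatrix:
    """Symmetric gene x gene similarity matrix with unit diagonal."""

    gene_ids: np.ndarray
    values: np.ndarray
    measure_name: str = ""

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match gene ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, measure_name: str = "") -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.index.to_numpy(), df.to_numpy(), measure_name)


def similarity_matrix(E: pd.DataFrame, measure: str = "ncmi",
                      min_overlap: int = MIN_OVERLAP, **kwargs) -> SimilarityMatrix:
    """Compute the full pairwise similarity matrix of an expression matrix.

    Pairs with fewer than ``min_overlap`` complete observations get
    similarity 0 (warned).  The diagonal is set to 1.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {sorted(MEASURES)}")
    if E.shape[0] < 2:
        raise ValueError("need at least two genes")
    fn = MEASURES[measure]
    X = E.to_numpy(dtype=float)
    n = X.shape[0]
    S = np.eye(n)
    any_nan = np.isnan(X).any()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if measure == "apcc" and not any_nan:
            # vectorised fast path
            sd = X.std(axis=1)
            ok = sd > 0
            S = np.zeros((n, n))
            if ok.any():
                R = np.corrcoef(X[ok])
                S[np.ix_(ok, ok)] = np.abs(np.clip(R, -1, 1))
            np.fill_diagonal(S, 1.0)
        else:
            for i in range(n):
                for j in range(i + 1, n):
                    xc, yc = _pairwise_complete(X[i], X[j])
                    s = fn(X[i], X[j], **kwargs) if xc.size >= min_overlap else 0.0
                    S[i, j] = S[j, i] = s
    return SimilarityMatrix(E.index.to_numpy(), S, measure)


def compare_measures(S_a: SimilarityMatrix, S_b: SimilarityMatrix,
                     tau: float) -> dict[str, int]:
    """Quadrant counts of off-diagonal pairs at threshold ``tau``.

    Returns counts of unordered gene pairs for which both measures reach
    ``tau``, only the first does, only the second does, or neither does.
    The four counts sum to n(n-1)/2.
    """
    if S_a.n_genes != S_b.n_genes or not np.array_equal(S_a.gene_ids, S_b.gene_ids):
        raise ValueError("mismatched gene sets")
    iu = np.triu_indices(S_a.n_genes, 1)
    a = S_a.values[iu] >= tau
    b = S_b.values[iu] >= tau
    return {
        "both": int(np.sum(a & b)),
        "only_a": int(np.sum(a & ~b)),
        "only_b": int(np.sum(~a & b)),
        "neither": int(np.sum(~a & ~b)),
    }
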