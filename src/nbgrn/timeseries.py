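"""Count time-series container, normalization, and design-matrix construction.

Data are a gene x sample matrix of RNA-Seq counts where each sample is one
(time point, replicate) pair.  Per-sample size factors correct for sequencing
depth and enter the model as a fixed offset ``log s`` on the linear
predictor.  The first-order Markov structure means each gene's counts at time
t are regressed on all other genes' (transformed) values at time t-1;
transitions never cross replicate boundaries.

Predictor transform: raw counts are a poor regressor inside ``exp(X beta)``
with coefficients of order 0.3, so the default transform is
``log(1 + count/s)`` per predictor followed by centering/scaling to unit
variance ("log-std").  Plain "log" and "raw" modes are available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import RegressionProblem

__all__ = [
    "CountTimeSeries",
    "size_factors",
    "transform_predictors",
    "build_problem",
    "TRANSFORMS",
]

TRANSFORMS = ("log-std", "log", "raw")


def size_factors(counts: pd.DataFrame, method: str = "median-ratio") -> pd.Series:
    """Per-sample size factors from a gene x sample count matrix.

    "median-ratio" is the median-of-ratios estimator: each gene's geometric
    mean across samples is the reference (genes with any zero excluded), and
    a sample's factor is the median of count/reference over genes.  "total"
    normalizes per-sample totals to mean one.  "none" returns all ones.
    """
    if method == "none":
        return pd.Series(1.0, index=counts.columns)
    if method == "total":
        totals = counts.sum(axis=0).astype(float)
        return totals / totals.mean()
    if method != "median-ratio":
        raise ValueError(f"unknown size-factor method {method!r}")
    mat = counts.to_numpy(dtype=float)
    nonzero = np.all(mat > 0, axis=1)
    if not np.any(nonzero):
        raise ValueError(
            "no gene has nonzero counts in every sample; use the total-count method"
        )
    ref = np.exp(np.mean(np.log(mat[nonzero]), axis=1))
    ratios = mat[nonzero] / ref[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.columns)


class CountTimeSeries:
    """Gene x sample count matrix with time/replicate structure.

    Parameters
    ----------
    counts : DataFrame, genes x samples, non-negative integers
    metadata : DataFrame indexed by sample with columns ``time`` and
        ``replicate``.  Time points follow metadata order of first
        appearance, not lexicographic label order.
    size_factors : Series per sample, optional; estimated by median-of-ratios
        when omitted (falling back to total-count if that fails).
    """

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame, size_factors_=None):
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        mat = counts.to_numpy()
        flt = counts.to_numpy(dtype=float)
        if not np.allclose(flt, np.round(flt)) or np.any(flt < 0):
            bad = np.argwhere(~np.isclose(flt, np.round(flt)) | (flt < 0))
            r, c = bad[0]
            raise ValueError(
                f"counts must be non-negative integers; offending entry at "
                f"gene {counts.index[r]!r}, sample {counts.columns[c]!r}"
            )
        missing = set(metadata.index) - set(counts.columns)
        extra = set(counts.columns) - set(metadata.index)
        if missing or extra:
            raise ValueError(
                f"sample sets differ between counts and metadata; "
                f"missing from counts: {sorted(missing)}, "
                f"missing from metadata: {sorted(extra)}"
            )
        pairs = list(zip(metadata["time"], metadata["replicate"]))
        if len(set(pairs)) != len(pairs):
            raise ValueError("(time, replicate) pairs must be unique")
        self.counts = counts.astype(np.int64)
        self.metadata = metadata
        # time order: order of first appearance in the metadata
        self.times = list(dict.fromkeys(metadata["time"]))
        self.replicates = sorted(set(metadata["replicate"]), key=str)
        for t in self.times:
            for r in self.replicates:
                if (t, r) not in pairs:
                    raise ValueError(f"missing sample for (time={t!r}, replicate={r!r})")
        if size_factors_ is None:
            try:
                size_factors_ = size_factors(self.counts, "median-ratio")
            except ValueError:
                size_factors_ = size_factors(self.counts, "total")
        self.size_factors = pd.Series(size_factors_, index=counts.columns, dtype=float)
        if np.any(self.size_factors <= 0):
            raise ValueError("size factors must be strictly positive")
        # sample name lookup by (time, replicate)
        self._sample_of = {
            (t, r): s for s, t, r in zip(metadata.index, metadata["time"], metadata["replicate"])
        }

    @property
    def genes(self) -> list:
        return list(self.counts.index)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def sample_name(self, time, replicate):
        return self._sample_of[(time, replicate)]

    def as_array(self) -> np.ndarray:
        """Counts as an (L, R, M) array in time/replicate/gene order."""
        L, R, M = self.n_times, self.n_replicates, self.n_genes
        out = np.empty((L, R, M), dtype=np.int64)
        for i, t in enumerate(self.times):
            for j, r in enumerate(self.replicates):
                out[i, j] = self.counts[self.sample_name(t, r)].to_numpy()
        return out

    def size_factor_array(self) -> np.ndarray:
        """Size factors as an (L, R) array aligned with :meth:`as_array`."""
        L, R = self.n_times, self.n_replicates
        out = np.empty((L, R))
        for i, t in enumerate(self.times):
            for j, r in enumerate(self.replicates):
                out[i, j] = self.size_factors[self.sample_name(t, r)]
        return out


def transform_predictors(
    counts: np.ndarray, s: np.ndarray, mode: str = "log-std"
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the predictor transform column-wise to a rows x genes matrix.

    Returns ``(transformed, degenerate_mask)``.  For "log-std", constant
    columns cannot be scaled; they become all-zero and are flagged.
    """
    if mode not in TRANSFORMS:
        raise ValueError(f"transform must be one of {TRANSFORMS}, got {mode!r}")
    vals = counts / s[:, None] if mode != "raw" else counts.astype(float)
    if mode != "raw":
        vals = np.log1p(vals)
    degenerate = np.zeros(vals.shape[1], dtype=bool)
    if mode == "log-std":
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0)
        degenerate = sd == 0
        sd = np.where(degenerate, 1.0, sd)
        vals = (vals - mean) / sd
        vals[:, degenerate] = 0.0
    return vals, degenerate


def build_problem(
    data: CountTimeSeries,
    gene,
    transform: str = "log-std",
    include_self: bool = False,
) -> RegressionProblem:
    """Assemble one gene's regression problem from the time series.

    The response stacks the gene's counts at times 2..L over replicates; each
    row's predictors are every other gene's transformed value at the
    preceding time in the same replicate, plus an intercept column.  Offsets
    are the log size factors of the response samples.
    """
    if gene not in data.counts.index:
        raise KeyError(f"gene {gene!r} not present in the count matrix")
    if data.n_times < 2:
        raise ValueError("need at least 2 time points to form transitions")
    arr = data.as_array()  # (L, R, M)
    sf = data.size_factor_array()
    L, R, M = arr.shape
    gi = data.genes.index(gene)
    pred_idx = [j for j in range(M) if include_self or j != gi]
    pred_names = [data.genes[j] for j in pred_idx]

    # predictor rows: times 1..L-1, per replicate; response: times 2..L
    pred_counts = arr[:-1].reshape((L - 1) * R, M)[:, pred_idx]
    pred_s = sf[:-1].reshape((L - 1) * R)
    Xp, _ = transform_predictors(pred_counts, pred_s, mode=transform)
    y = arr[1:, :, gi].reshape((L - 1) * R)
    off = np.log(sf[1:].reshape((L - 1) * R))
    X = np.column_stack([Xp, np.ones(y.size)])
    return RegressionProblem(y, X, offset=off, predictor_names=pred_names)
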