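"""Read-count matrices and log-CPM normalization.

RNA-seq read counts are normalized to log2 counts-per-million with the
standard pseudo-count convention

    log2( (count + 0.5) / (lib_size + 1) * 1e6 )

which is the log-transform step of limma's ``voom``.  Observation-level
precision weights from the voom mean–variance trend are available for
diagnostics, but the downstream correlation statistics operate on the
unweighted log-CPM values: Pearson correlation, not a weighted linear
model, is the unit of analysis here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples, with a two-group sample design."""

    counts: pd.DataFrame  # genes x samples, nonnegative integers
    groups: pd.Series  # sample id -> group label; exactly two labels

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.isfinite(vals)) or np.any(vals != np.floor(vals)):
                bad = np.argwhere(~np.isfinite(vals) | (vals != np.floor(vals)))
                g, s = bad[0]
                raise ValueError(
                    f"non-integer count at gene {self.counts.index[g]!r}, "
                    f"sample {self.counts.columns[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if np.any(vals < 0):
            g, s = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()][0]
            raise ValueError(f"sample {missing!r} has no group assignment")
        labels = self.group_labels
        if len(labels) != 2:
            raise ValueError(f"expected exactly 2 groups, found {len(labels)}: {labels}")
        for lab in labels:
            n = int((self.groups == lab).sum())
            if n < 3:
                raise ValueError(f"group {lab!r} has {n} samples; at least 3 required")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def group_labels(self) -> tuple[str, ...]:
        # descending sort puts "LA" before "HA", matching the analysis
        # orientation z_diff = z_first - z_second
        return tuple(sorted(self.groups.unique(), reverse=True))

    def samples_in_group(self, label: str) -> list[str]:
        return list(self.groups.index[self.groups == label])

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class ExpressionMatrix:
    """log2-scale expression values with the library sizes they came from."""

    values: pd.DataFrame  # genes x samples, finite reals
    lib_sizes: pd.Series

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def read_counts(path: str | Path, groups_path: str | Path) -> CountMatrix:
    """Read a counts TSV (gene_id + one column per sample) and a groups TSV
    (columns sample_id, group). Sample order follows the count-matrix header."""
    counts = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    gdf = pd.read_csv(groups_path, sep="\t", comment="#", dtype=str)
    for col in ("sample_id", "group"):
        if col not in gdf.columns:
            raise ValueError(f"groups file {groups_path} is missing column {col!r}")
    groups = pd.Series(gdf["group"].values, index=gdf["sample_id"].values, name="group")
    extra = set(groups.index) - set(counts.columns)
    if extra:
        raise ValueError(f"samples in groups file absent from counts: {sorted(extra)}")
    missing = set(counts.columns) - set(groups.index)
    if missing:
        raise ValueError(f"samples in counts missing from groups file: {sorted(missing)}")
    return CountMatrix(counts=counts, groups=groups)


def normalize_log_cpm(cm: CountMatrix) -> ExpressionMatrix:
    """log2 counts-per-million with voom's pseudo-count convention.

    value(g, s) = log2( (count(g,s) + 0.5) / (lib_size(s) + 1) * 1e6 ).
    Libraries are the column sums of the counts; a zero library is an error.
    """
    lib = cm.lib_sizes
    zero = lib.index[lib == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero library size")
    vals = np.log2(
        (cm.counts.to_numpy(dtype=float) + 0.5)
        / (lib.to_numpy(dtype=float) + 1.0)
        * 1e6
    )
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns),
        lib_sizes=lib.astype(float),
    )


def voom_weights(em: ExpressionMatrix, cm: CountMatrix, span: float = 0.5) -> pd.DataFrame:
    """Observation-level precision weights from the voom mean-variance trend.

    Fits a lowess trend of sqrt(per-gene residual standard deviation) against
    mean log2 count (residuals taken about the two group means), then sets
    each observation's weight to the trend value at its fitted log2 count,
    raised to the -4th power.  Provided for diagnostics; the correlation
    pipeline does not consume weights.
    """
    y = em.values.to_numpy()
    n_genes, n_samples = y.shape
    if n_genes < 10:
        raise ValueError("voom trend fit requires at least 10 genes")
    lib = em.lib_sizes.to_numpy(dtype=float)

    # residual sd about group means
    resid = np.empty_like(y)
    fitted = np.empty_like(y)
    for lab in cm.group_labels:
        cols = [em.samples.index(s) for s in cm.samples_in_group(lab)]
        mu = y[:, cols].mean(axis=1, keepdims=True)
        fitted[:, cols] = mu
        resid[:, cols] = y[:, cols] - mu
    df_resid = n_samples - 2
    sd = np.sqrt((resid**2).sum(axis=1) / df_resid)
    if np.all(sd == 0):
        raise ValueError("all genes are constant within groups; no trend to fit")

    # mean log2 count; the lib-size term converts log-CPM back to log-count scale
    mean_log_count = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sqrt_sd = np.sqrt(sd)
    trend = lowess(sqrt_sd, mean_log_count, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]

    # evaluate the trend at each observation's fitted log-count
    fitted_log_count = fitted + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    pred = np.interp(fitted_log_count, tx, ty)
    pred = np.clip(pred, a_min=max(1e-6, float(ty.min()) * 1e-3), a_max=None)
    w = pred**-4.0
    return pd.DataFrame(w, index=em.values.index, columns=em.values.columns)
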