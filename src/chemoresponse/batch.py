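"""Location/scale batch-effect correction.

Expression values (log2) are adjusted per feature and batch so that every
batch shares the pooled median and the pooled scale:

    g* = M_i + (g - M_ij) * s_i / s_ij

where ``M`` are medians and ``s`` the scale estimates (sample standard
deviation by default, or the consistency-scaled MAD).  Methylation beta
values, being bounded in [0, 1] and mildly bimodal, are instead rescaled
through a bounded piecewise-linear map that sends the batch median onto the
pooled median and fixes the endpoints 0 and 1:

    b* = b * M_i / M_ij                         if b <= M_ij
    b* = M_i + (b - M_ij) (1 - M_i) / (1 - M_ij)  otherwise

Copy-number ratios are never batch corrected: the comparative hybridisation
against normal DNA on the same array already absorbs processing effects.

Both correctors follow the sklearn fit/transform protocol on
(samples x features) input; batch labels are passed at fit time.  All
statistics are computed on observed (non-missing) entries only, and missing
entries stay missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

MAD_CONSTANT = 1.4826  # consistency with the sd on normal data

SMALL_BATCH_WARN = 25


@dataclass
class BatchAdjustmentReport:
    """Per (feature, batch) medians/scales before and after adjustment."""

    batches: list
    batch_sizes: dict
    pre_batch_median: pd.DataFrame   # batches x features
    post_batch_median: pd.DataFrame
    pre_batch_scale: pd.DataFrame | None
    post_batch_scale: pd.DataFrame | None
    global_median: pd.Series
    global_scale: pd.Series | None
    flags: list  # (feature, batch, reason)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.batches:
            df = pd.DataFrame({
                "feature_id": self.pre_batch_median.columns,
                "batch": b,
                "n": self.batch_sizes[b],
                "pre_median": self.pre_batch_median.loc[b].to_numpy(),
                "post_median": self.post_batch_median.loc[b].to_numpy(),
            })
            if self.pre_batch_scale is not None:
                df["pre_scale"] = self.pre_batch_scale.loc[b].to_numpy()
                df["post_scale"] = self.post_batch_scale.loc[b].to_numpy()
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def _nan_scale(x: np.ndarray, estimator: str, axis: int = 0) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if estimator == "sd":
            return np.nanstd(x, axis=axis, ddof=1)
        if estimator == "mad":
            med = np.nanmedian(x, axis=axis, keepdims=True)
            return MAD_CONSTANT * np.nanmedian(np.abs(x - med), axis=axis)
    raise ValueError(f"unknown scale estimator {estimator!r}")


def _check_batches(X: pd.DataFrame, batches) -> pd.Series:
    b = pd.Series(batches)
    if not b.index.equals(X.index):
        if len(b) != len(X):
            raise ValueError("batches must map every sample to a batch label")
        b.index = X.index
    if b.isna().any():
        raise ValueError("every sample needs a batch label")
    small = b.value_counts()
    small = small[small < SMALL_BATCH_WARN]
    if len(small):
        warnings.warn(
            f"batches with fewer than {SMALL_BATCH_WARN} samples: "
            f"{dict(small)} -- scale estimates may be unstable")
    return b


class LocationScaleBatchCorrector(BaseEstimator, TransformerMixin):
    """Median/scale alignment of log2 expression across batches.

    Parameters
    ----------
    scale_estimator : {"sd", "mad"}
        Within/across-batch scale estimate; ``mad`` is the robust variant
        (median absolute deviation times 1.4826).

    Attributes
    ----------
    global_median_, global_scale_ : pandas.Series per feature.
    batch_median_, batch_scale_ : pandas.DataFrame, batches x features.
    report_ : BatchAdjustmentReport
    """

    def __init__(self, scale_estimator: str = "sd"):
        self.scale_estimator = scale_estimator

    def fit(self, X: pd.DataFrame, y=None, *, batches):
        X = pd.DataFrame(X)
        b = _check_batches(X, batches)
        vals = X.to_numpy(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gm = np.nanmedian(vals, axis=0)
        gs = _nan_scale(vals, self.scale_estimator, axis=0)
        labels = sorted(b.unique().tolist())
        bm = np.empty((len(labels), X.shape[1]))
        bs = np.empty_like(bm)
        sizes = {}
        for i, lab in enumerate(labels):
            sub = vals[(b == lab).to_numpy()]
            sizes[lab] = sub.shape[0]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                bm[i] = np.nanmedian(sub, axis=0)
            bs[i] = _nan_scale(sub, self.scale_estimator, axis=0)
        self.batches_ = b
        self.batch_labels_ = labels
        self.batch_sizes_ = sizes
        self.global_median_ = pd.Series(gm, index=X.columns)
        self.global_scale_ = pd.Series(gs, index=X.columns)
        self.batch_median_ = pd.DataFrame(bm, index=labels, columns=X.columns)
        self.batch_scale_ = pd.DataFrame(bs, index=labels, columns=X.columns)
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X: pd.DataFrame, *, batches=None) -> pd.DataFrame:
        X = pd.DataFrame(X)
        b = self.batches_ if batches is None else _check_batches(X, batches)
        out = X.to_numpy(float).copy()
        flags = []
        gm = self.global_median_.to_numpy()
        gs = self.global_scale_.to_numpy()
        for lab in self.batch_labels_:
            rows = (b == lab).to_numpy()
            if not rows.any():
                continue
            if self.batch_sizes_[lab] < 2:
                warnings.warn(f"batch {lab!r} has a single sample; passed "
                              "through unadjusted")
                flags.append((None, lab, "singleton_batch"))
                continue
            bm = self.batch_median_.loc[lab].to_numpy()
            bs = self.batch_scale_.loc[lab].to_numpy()
            zero = bs == 0
            unstat = np.isnan(bs) | np.isnan(gs)  # <2 observed values
            bad = zero | unstat
            ratio = np.where(bad, 0.0, gs / np.where(bad, 1.0, bs))
            adj = gm + (out[rows] - bm) * ratio
            # zero within-batch scale: no spread to rescale -> pin to M_i
            adj[:, zero] = gm[zero]
            # too few observed values to estimate a scale: pass through
            adj[:, unstat] = out[rows][:, unstat]
            keep_nan = np.isnan(out[rows])
            adj[keep_nan] = np.nan
            out[rows] = adj
            for j in np.nonzero(zero)[0]:
                flags.append((X.columns[j], lab, "zero_batch_scale"))
        result = pd.DataFrame(out, index=X.index, columns=X.columns)
        post_m = {}
        post_s = {}
        for lab in self.batch_labels_:
            rows = (b == lab).to_numpy()
            sub = out[rows]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                post_m[lab] = np.nanmedian(sub, axis=0)
            post_s[lab] = _nan_scale(sub, self.scale_estimator, axis=0)
        self.report_ = BatchAdjustmentReport(
            batches=self.batch_labels_,
            batch_sizes=self.batch_sizes_,
            pre_batch_median=self.batch_median_.copy(),
            post_batch_median=pd.DataFrame(post_m, index=X.columns).T,
            pre_batch_scale=self.batch_scale_.copy(),
            post_batch_scale=pd.DataFrame(post_s, index=X.columns).T,
            global_median=self.global_median_,
            global_scale=self.global_scale_,
            flags=flags,
        )
        return result

    def fit_transform(self, X, y=None, *, batches):
        return self.fit(X, batches=batches).transform(X)


class BetaValueBatchCorrector(BaseEstimator, TransformerMixin):
    """Bounded piecewise-linear median alignment for methylation betas.

    The per-feature map is non-decreasing on [0, 1], fixes 0 and 1, and
    sends the batch median exactly onto the pooled median.
    """

    def fit(self, X: pd.DataFrame, y=None, *, batches):
        X = pd.DataFrame(X)
        vals = X.to_numpy(float)
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
        if not ok.all():
            raise ValueError("beta values must lie in [0, 1]")
        b = _check_batches(X, batches)
        labels = sorted(b.unique().tolist())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gm = np.nanmedian(vals, axis=0)
            bm = np.vstack([np.nanmedian(vals[(b == lab).to_numpy()], axis=0)
                            for lab in labels])
        self.batches_ = b
        self.batch_labels_ = labels
        self.batch_sizes_ = {lab: int((b == lab).sum()) for lab in labels}
        self.global_median_ = pd.Series(gm, index=X.columns)
        self.batch_median_ = pd.DataFrame(bm, index=labels, columns=X.columns)
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X: pd.DataFrame, *, batches=None) -> pd.DataFrame:
        X = pd.DataFrame(X)
        b = self.batches_ if batches is None else _check_batches(X, batches)
        out = X.to_numpy(float).copy()
        gm = self.global_median_.to_numpy()
        flags = []
        for lab in self.batch_labels_:
            rows = (b == lab).to_numpy()
            if not rows.any():
                continue
            bm = self.batch_median_.loc[lab].to_numpy()
            sub = out[rows]
            zero_med = bm == 0          # lower branch would divide by 0
            one_med = bm == 1           # upper branch would divide by 0
            lo_ratio = np.where(zero_med, 1.0, gm / np.where(zero_med, 1.0, bm))
            hi_ratio = np.where(one_med, 1.0,
                                (1.0 - gm) / np.where(one_med, 1.0, 1.0 - bm))
            lower = sub <= bm[None, :]
            adj = np.where(lower, sub * lo_ratio[None, :],
                           gm[None, :] + (sub - bm[None, :]) * hi_ratio[None, :])
            adj = np.clip(adj, 0.0, 1.0)
            adj[np.isnan(sub)] = np.nan
            out[rows] = adj
            for j in np.nonzero(zero_med)[0]:
                flags.append((X.columns[j], lab, "zero_batch_median"))
            for j in np.nonzero(one_med)[0]:
                flags.append((X.columns[j], lab, "unit_batch_median"))
        result = pd.DataFrame(out, index=X.index, columns=X.columns)
        post_m = {}
        for lab in self.batch_labels_:
            rows = (b == lab).to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                post_m[lab] = np.nanmedian(out[rows], axis=0)
        self.report_ = BatchAdjustmentReport(
            batches=self.batch_labels_,
            batch_sizes=self.batch_sizes_,
            pre_batch_median=self.batch_median_.copy(),
            post_batch_median=pd.DataFrame(post_m, index=X.columns).T,
            pre_batch_scale=None,
            post_batch_scale=None,
            global_median=self.global_median_,
            global_scale=None,
            flags=flags,
        )
        return result

    def fit_transform(self, X, y=None, *, batches):
        return self.fit(X, batches=batches).transform(X)


# ---------------------------------------------------------------------------
# OmicsMatrix-level wrappers


def correct_expression(matrix, batches, scale_estimator: str = "sd"):
    """Adjust a log2 expression OmicsMatrix; returns (matrix, report)."""
    from .io import OmicsMatrix

    if matrix.modality == "copy_number":
        raise ValueError("copy-number matrices are not batch corrected")
    est = LocationScaleBatchCorrector(scale_estimator=scale_estimator)
    adj = est.fit_transform(matrix.to_samples_by_features(), batches=batches)
    return (OmicsMatrix(adj.T, matrix.modality, matrix.annotations),
            est.report_)


def correct_methylation(matrix, batches):
    """Adjust a methylation OmicsMatrix; returns (matrix, report)."""
    from .io import OmicsMatrix

    if matrix.modality != "methylation":
        raise ValueError("correct_methylation expects a methylation matrix")
    est = BetaValueBatchCorrector()
    adj = est.fit_transform(matrix.to_samples_by_features(), batches=batches)
    return (OmicsMatrix(adj.T, matrix.modality, matrix.annotations),
            est.report_)
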