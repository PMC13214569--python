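"""Validation metrics: per-label Dice, test-retest ICC, volume-covariate rank
correlation."""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr


def dice_scores(seg_a: np.ndarray, seg_b: np.ndarray,
                cluster_map: dict[int, int] | None = None) -> pd.DataFrame:
    """Hard Dice per label: 2|A.B|/(|A|+|B|).

    ``cluster_map`` (many-to-one) is applied to ``seg_a`` *before* comparison
    so a fine-grained segmentation can be matched against a coarser protocol;
    labels absent from both volumes are excluded.
    """
    a = np.asarray(seg_a)
    b = np.asarray(seg_b)
    if a.shape != b.shape:
        raise ValueError("segmentations must be on the same grid")
    if cluster_map:
        lut = np.zeros(int(a.max()) + 1, dtype=np.int64)
        for src, dst in cluster_map.items():
            lut[src] = dst
        a = lut[a]
    labels = sorted((set(np.unique(a)) | set(np.unique(b))) - {0})
    rows = []
    for k in labels:
        na = int((a == k).sum())
        nb = int((b == k).sum())
        if na == 0 and nb == 0:
            continue
        inter = int(((a == k) & (b == k)).sum())
        rows.append({"label": k, "dice": 2.0 * inter / (na + nb),
                     "n_a": na, "n_b": nb})
    return pd.DataFrame(rows, columns=["label", "dice", "n_a", "n_b"])


def icc_2_1(test: np.ndarray, retest: np.ndarray) -> float:
    """Two-way random-effects, absolute-agreement, single-measurement ICC.

    Computed from the mean squares of the n-subject x 2-session table:
    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    """
    x = np.column_stack([np.asarray(test, float), np.asarray(retest, float)])
    n, k = x.shape
    if n < 5:
        raise ValueError("need at least 5 paired measurements")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-30:
        return 1.0 if abs(msr - mse) < 1e-30 else np.sign(msr - mse)
    return float((msr - mse) / denom)


def icc_volumes(test: pd.DataFrame, retest: pd.DataFrame) -> pd.DataFrame:
    """Per-ROI ICC(2,1) from paired volume tables.

    Both tables need columns ``subject``, ``label_id``, ``volume_mm3``; rows
    are paired on (subject, label_id).
    """
    merged = test.merge(retest, on=["subject", "label_id"], suffixes=("_t", "_r"))
    rows = []
    for lid, grp in merged.groupby("label_id"):
        rows.append({"label_id": lid,
                     "icc": icc_2_1(grp["volume_mm3_t"].to_numpy(),
                                    grp["volume_mm3_r"].to_numpy()),
                     "n_subjects": len(grp)})
    return pd.DataFrame(rows, columns=["label_id", "icc", "n_subjects"])


def volume_covariate_correlation(volumes: pd.DataFrame,
                                 covariate: pd.Series | dict) -> pd.DataFrame:
    """Spearman rank correlation of ROI volume against a subject covariate.

    ``volumes`` has columns ``subject``, ``label_id``, ``volume_mm3``;
    constant-volume ROIs get a missing (NaN) correlation.
    """
    cov = pd.Series(covariate)
    if cov.size < 10:
        raise ValueError("need at least 10 subjects")
    rows = []
    for lid, grp in volumes.groupby("label_id"):
        v = grp.set_index("subject")["volume_mm3"]
        common = v.index.intersection(cov.index)
        vv = v.loc[common].to_numpy(float)
        cc = cov.loc[common].to_numpy(float)
        if np.ptp(vv) == 0 or np.ptp(cc) == 0:
            rho = np.nan
        else:
            rho = float(spearmanr(vv, cc).statistic)
        rows.append({"label_id": lid, "rho": rho, "n_subjects": len(common)})
    return pd.DataFrame(rows, columns=["label_id", "rho", "n_subjects"])
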