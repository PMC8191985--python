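"""Gene-expression plumbing around the ASE analysis: dual-reference count
averaging, FPKM-based low-expression filtering, logCPM, PCA summary,
cross-dataset correlation, and a simple Welch-test differential-expression
stage.

The DE stage is a deliberately plain stand-in (per-gene Welch t-test on
logCPM with BH correction) that lets the pipeline run end-to-end; it makes
no claim to the efficiency of weighted linear-model approaches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust
from .types import ValidationError

logger = logging.getLogger(__name__)

#: Sample group labels: two parental lines and the two hybrid directions.
GROUPS = ("VV", "GG", "VG", "GV")


@dataclass
class CountsMatrix:
    """Gene x sample count matrix with per-sample group labels.

    Values may be non-integer: averaging two integer count matrices can
    give halves.
    """

    values: pd.DataFrame  # genes x samples
    groups: dict[str, str]  # sample -> group label

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValidationError("negative counts")
        for sample in self.values.columns:
            if sample not in self.groups:
                raise ValidationError(f"sample {sample!r} has no group label")


def average_dual_counts(
    counts_ref: CountsMatrix, counts_pseudo: CountsMatrix
) -> CountsMatrix:
    """Elementwise mean of the two single-reference count matrices."""
    a, b = counts_ref.values, counts_pseudo.values
    if set(a.index) != set(b.index) or set(a.columns) != set(b.columns):
        sym_genes = set(a.index) ^ set(b.index)
        sym_samples = set(a.columns) ^ set(b.columns)
        raise ValidationError(
            f"matrices differ: genes {sorted(sym_genes)[:10]}, "
            f"samples {sorted(sym_samples)[:10]}"
        )
    b = b.loc[a.index, a.columns]
    return CountsMatrix(values=(a + b) / 2.0, groups=dict(counts_ref.groups))


def fpkm(counts: CountsMatrix, lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads.

    FPKM[g, s] = count[g, s] * 1e9 / (length[g] * library_size[s]) with
    library size the column sum of counts.
    """
    missing = set(counts.values.index) - set(lengths.index)
    if missing:
        raise ValidationError(f"no length for genes {sorted(missing)[:10]}")
    lens = lengths.loc[counts.values.index].astype(float)
    if (lens < 1).any():
        raise ValidationError("gene lengths must be >= 1 bp")
    lib = counts.values.sum(axis=0)
    if (lib == 0).any():
        zero = list(lib.index[lib == 0])
        raise ValidationError(f"zero library size for samples {zero}")
    return counts.values.mul(1e9).div(lens, axis=0).div(lib, axis=1)


def filter_low_expression(
    counts: CountsMatrix, lengths: pd.Series, threshold: float = 0.5
) -> CountsMatrix:
    """Keep genes with mean FPKM >= threshold within at least one group."""
    fpkm_mat = fpkm(counts, lengths)
    group_of = pd.Series(counts.groups)
    keep = pd.Series(False, index=fpkm_mat.index)
    for group in sorted(set(group_of)):
        samples = group_of.index[group_of == group]
        samples = [s for s in samples if s in fpkm_mat.columns]
        if samples:
            keep |= fpkm_mat[samples].mean(axis=1) >= threshold
    kept = counts.values.loc[keep]
    logger.info("expression filter: kept %d of %d genes", len(kept),
                len(counts.values))
    return CountsMatrix(values=kept, groups=dict(counts.groups))


def log_cpm(counts: CountsMatrix, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts per million with a pseudo-count.

    logCPM[g, s] = log2((count + prior) / (library_size + 2*prior) * 1e6).
    """
    if prior <= 0:
        raise ValidationError("prior must be > 0")
    lib = counts.values.sum(axis=0)
    return np.log2((counts.values + prior).div(lib + 2 * prior, axis=1) * 1e6)


@dataclass
class PcaSummary:
    proportions: np.ndarray  # per-PC proportion of variance, sums to 1
    projections: pd.DataFrame  # samples x PCs


def pca_summary(logcpm: pd.DataFrame) -> PcaSummary:
    """Scaled and centred PCA of samples in gene space.

    Each gene is centred and unit-scaled across samples; zero-variance
    genes are dropped. Proportions of variance sum to 1.
    """
    if logcpm.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    x = logcpm.T.values.astype(float)  # samples x genes
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    z = (x[:, keep] - mu[keep]) / sd[keep]
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    var = s ** 2
    proportions = var / var.sum()
    proj = u * s
    cols = [f"PC{i + 1}" for i in range(proj.shape[1])]
    return PcaSummary(
        proportions=proportions,
        projections=pd.DataFrame(proj, index=logcpm.columns, columns=cols),
    )


def cross_dataset_correlation(
    mean_logcpm_a: pd.Series, mean_logcpm_b: pd.Series
) -> float:
    """Pearson correlation of per-gene mean logCPM on the shared gene set."""
    shared = mean_logcpm_a.index.intersection(mean_logcpm_b.index)
    if len(shared) == 0:
        raise ValidationError("no shared genes")
    a = mean_logcpm_a.loc[shared].astype(float)
    b = mean_logcpm_b.loc[shared].astype(float)
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    return float(sps.pearsonr(a, b)[0])


def simple_de_test(
    logcpm: pd.DataFrame,
    groups: dict[str, str],
    pair: tuple[str, str],
    q_threshold: float = 0.01,
    lfc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-gene Welch two-sample test between two groups on logCPM.

    Returns a DataFrame with log2FC (mean difference g1 - g2), p, q (BH
    within this comparison), and is_DE (q <= q_threshold and
    \\|log2FC\\| >= lfc_threshold, both inclusive).
    """
    g1, g2 = pair
    cols1 = [s for s in logcpm.columns if groups.get(s) == g1]
    cols2 = [s for s in logcpm.columns if groups.get(s) == g2]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValidationError(f"groups {pair} need >= 2 samples each")
    x1 = logcpm[cols1].values
    x2 = logcpm[cols2].values
    lfc = x1.mean(axis=1) - x2.mean(axis=1)
    t, p = sps.ttest_ind(x1, x2, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance genes: no evidence
    q = np.array(bh_adjust(list(p)))
    return pd.DataFrame(
        {
            "log2FC": lfc,
            "p": p,
            "q": q,
            "is_DE": (q <= q_threshold) & (np.abs(lfc) >= lfc_threshold),
        },
        index=logcpm.index,
    )
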