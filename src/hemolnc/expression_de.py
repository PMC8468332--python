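"""Negative-binomial differential expression of lncRNAs.

Expression is quantified as TPM; each stimulus is compared against the
unstimulated control with the exact negative-binomial test of Robinson
and Smyth: libraries are first scaled to a common size, a common
dispersion is estimated by conditional maximum likelihood (qCML), and
each feature's group sums are tested conditionally on their total.
Features pass the differential-expression gate when |fold change| > 2
and Benjamini-Hochberg FDR < 0.05. DE features are summarized by a
heat map ordering from centroid-linkage clustering of per-condition
mean TPM under the Pearson distance 1 - r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import nbinom, poisson
from statsmodels.stats.multitest import multipletests

_POISSON_PHI = 1e-8  # at or below this dispersion the NB is treated as Poisson


# ---------------------------------------------------------------------------
# Quantification and library handling
# ---------------------------------------------------------------------------

def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million per sample column.

    TPM_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j). An all-zero column
    yields an all-zero TPM column with a warning.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:5].tolist()
        raise ValueError(f"missing feature lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero_cols = denom[denom == 0].index.tolist()
    if zero_cols:
        warnings.warn(f"all-zero count columns: {zero_cols}", stacklevel=2)
        denom = denom.replace(0, 1.0)
    return rate.div(denom, axis=1) * 1e6


def equalize_libraries(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Scale every column to the geometric-mean library size.

    The exact test conditions on equal library sizes; counts are
    multiplied by per-column factors and rounded half-to-even so they
    stay integers. Returns (pseudo-counts, scale factors).
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    libsizes = counts.sum(axis=0).astype(float)
    if (libsizes == 0).any():
        raise ValueError("zero library size in columns "
                         f"{libsizes[libsizes == 0].index.tolist()}")
    target = float(np.exp(np.mean(np.log(libsizes))))
    factors = target / libsizes
    pseudo = counts.mul(factors, axis=1)
    # numpy's round is round-half-to-even
    pseudo = pd.DataFrame(
        np.round(pseudo.to_numpy()), index=counts.index, columns=counts.columns
    ).astype(np.int64)
    return pseudo, factors


# ---------------------------------------------------------------------------
# Dispersion (qCML) and the exact test
# ---------------------------------------------------------------------------

@dataclass
class DispersionEstimate:
    phi: float
    log_likelihood: float
    bracket: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.bracket
        if not (lo <= self.phi <= hi):
            raise ValueError("phi outside search bracket")
        if not np.isfinite(self.log_likelihood):
            raise ValueError("non-finite log-likelihood")


def _cond_log_lik(counts: np.ndarray, group_slices: list[np.ndarray], phi: float) -> float:
    """Summed conditional NB log-likelihood over features and groups.

    For a group of n replicates with counts y and total z, the NB
    likelihood conditional on z is
    prod_i C(y_i + r - 1, y_i) / C(z + n r - 1, z) with r = 1/phi,
    which depends on the mean only through z — the device that lets a
    common dispersion be estimated free of the per-feature means.
    """
    r = 1.0 / max(phi, 1e-12)
    total = 0.0
    for cols in group_slices:
        y = counts[:, cols]
        n = y.shape[1]
        z = y.sum(axis=1)
        total += float(
            np.sum(gammaln(y + r) - gammaln(r))
            - np.sum(gammaln(z + n * r) - gammaln(n * r))
            + np.sum(gammaln(z + 1) - gammaln(y + 1).sum(axis=1))
        )
    return total


def estimate_common_dispersion(
    counts: pd.DataFrame,
    groups: pd.Series,
    bracket: tuple[float, float] = (1e-6, 10.0),
    tol: float = 1e-6,
) -> DispersionEstimate:
    """qCML common-dispersion estimate by golden-section search.

    ``groups`` maps sample (column) names to group labels; every group
    must have at least 2 replicates.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.sum() == 0:
        raise ValueError("all counts are zero; dispersion is unidentifiable")
    labels = groups.reindex(counts.columns)
    if labels.isna().any():
        raise ValueError("every sample column needs a group label")
    slices = []
    for g in labels.unique():
        cols = np.flatnonzero((labels == g).to_numpy())
        if cols.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
        slices.append(cols)
    if len(slices) < 2:
        raise ValueError("need at least 2 groups")

    invphi = (np.sqrt(5) - 1) / 2
    a, b = bracket
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = (_cond_log_lik(mat, slices, x) for x in (c, d))
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _cond_log_lik(mat, slices, c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _cond_log_lik(mat, slices, d)
    phi = (a + b) / 2
    return DispersionEstimate(phi, _cond_log_lik(mat, slices, phi), bracket)


def _conditional_log_pmf(t: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """log P(A = x | A + B = t) for x = 0..t under the common-phi NB model."""
    x = np.arange(t + 1)
    if phi < _POISSON_PHI:
        # Poisson limit: conditional is Binomial(t, n_a / (n_a + n_b))
        la = poisson.logpmf(x, n_a)
        lb = poisson.logpmf(t - x, n_b)
    else:
        mu = t / (n_a + n_b)  # per-sample mean under the null
        p = 1.0 / (1.0 + phi * mu) if mu > 0 else 1.0 - 1e-12
        la = nbinom.logpmf(x, n_a / phi, p)
        lb = nbinom.logpmf(t - x, n_b / phi, p)
    joint = la + lb
    return joint - logsumexp(joint)


def exact_test(
    counts_a: np.ndarray, counts_b: np.ndarray, phi: float, tie_tol: float = 1e-12
) -> float:
    """Two-sided exact NB test p-value for two groups of equalized counts.

    Conditional on the total t = sum(A) + sum(B), the p-value is the sum
    of the probabilities of all splits no more likely than the observed
    one (probability-mass two-siding); masses within ``tie_tol``
    (relative) of the observed mass count as ties and are included.
    """
    a = int(np.sum(counts_a))
    b = int(np.sum(counts_b))
    t = a + b
    if t == 0:
        return 1.0
    logp = _conditional_log_pmf(t, len(counts_a), len(counts_b), phi)
    probs = np.exp(logp)
    obs = probs[a]
    p = float(probs[probs <= obs * (1.0 + tie_tol)].sum())
    return min(p, 1.0)


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Fold change and the per-stimulus DE driver
# ---------------------------------------------------------------------------

def signed_fold_change(mean_ctrl: float, mean_stim: float, pseudo: float = 1.0) -> float:
    """Signed FC on pseudo-shifted means: ratio >= 1 reported as-is,
    ratio < 1 reported as its negated reciprocal (so FC = -2 means
    halved in the stimulus)."""
    ratio = (mean_stim + pseudo) / (mean_ctrl + pseudo)
    return ratio if ratio >= 1 else -1.0 / ratio


@dataclass
class DEOptions:
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    pseudo_tpm: float = 1.0


def run_de(
    counts: pd.DataFrame,
    lengths: pd.Series,
    conditions: pd.Series,
    control: str = "control",
    options: DEOptions | None = None,
) -> dict[str, pd.DataFrame]:
    """Exact-test DE of every stimulus against the control.

    For each stimulus, the control+stimulus columns are equalized, a
    common dispersion is estimated over the two groups, each feature is
    tested exactly, and BH adjustment is applied within the contrast.
    Fold changes come from per-group mean TPM with a pseudo-TPM of 1.
    Returns one result frame per stimulus with columns
    [mean_tpm_ctrl, mean_tpm_stim, fc, p, fdr, de_flag, direction].
    """
    opt = options or DEOptions()
    conditions = conditions.reindex(counts.columns)
    if conditions.isna().any():
        raise ValueError("every sample needs a condition label")
    if control not in set(conditions):
        raise ValueError(f"control condition {control!r} missing")
    tpm = compute_tpm(counts, lengths)
    ctrl_cols = conditions.index[conditions == control]

    results: dict[str, pd.DataFrame] = {}
    for stim in [c for c in conditions.unique() if c != control]:
        stim_cols = conditions.index[conditions == stim]
        sub = counts[list(ctrl_cols) + list(stim_cols)]
        eq, _ = equalize_libraries(sub)
        grp = pd.Series(
            [control] * len(ctrl_cols) + [stim] * len(stim_cols), index=sub.columns
        )
        disp = estimate_common_dispersion(eq, grp)
        a = eq[list(ctrl_cols)].to_numpy()
        s = eq[list(stim_cols)].to_numpy()
        pvals = np.array(
            [exact_test(s[i], a[i], disp.phi) for i in range(eq.shape[0])]
        )
        fdr = bh_fdr(pvals)
        mean_ctrl = tpm[list(ctrl_cols)].mean(axis=1)
        mean_stim = tpm[list(stim_cols)].mean(axis=1)
        fc = np.array(
            [
                signed_fold_change(mc, ms, opt.pseudo_tpm)
                for mc, ms in zip(mean_ctrl, mean_stim)
            ]
        )
        de = (np.abs(fc) > opt.fc_threshold) & (fdr < opt.fdr_threshold)
        direction = np.where(~de, "ns", np.where(fc > 0, "up", "down"))
        results[stim] = pd.DataFrame(
            {
                "mean_tpm_ctrl": mean_ctrl,
                "mean_tpm_stim": mean_stim,
                "fc": fc,
                "p": pvals,
                "fdr": fdr,
                "de_flag": de,
                "direction": direction,
            },
            index=counts.index,
        )
    return results


def de_summary(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Up/down/total DE feature counts per stimulus."""
    rows = {}
    for stim, df in results.items():
        up = int((df["direction"] == "up").sum())
        down = int((df["direction"] == "down").sum())
        rows[stim] = {"up": up, "down": down, "total": up + down}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Centroid-linkage clustering under the Pearson distance
# ---------------------------------------------------------------------------

def pearson_distance_matrix(rows: np.ndarray) -> np.ndarray:
    """Pairwise d = 1 - r between rows; zero-variance rows sit at the
    maximum distance 2 from everything (with a warning)."""
    rows = np.asarray(rows, dtype=float)
    sd = rows.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance rows assigned max distance",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(rows)
    d = 1.0 - r
    d[degenerate, :] = 2.0
    d[:, degenerate] = 2.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def centroid_linkage(dist: np.ndarray) -> np.ndarray:
    """Agglomerative clustering with the Lance-Williams centroid update.

    Operates on squared dissimilarities; at each step the closest pair
    (ties: smallest creation-order index pair) merges. Returns a
    scipy-style (n-1, 4) linkage matrix with unsquared heights.
    """
    d2 = np.asarray(dist, dtype=float) ** 2
    n = d2.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to cluster")
    active = {i: (i, 1) for i in range(n)}  # slot -> (cluster id, size)
    D = d2.copy()
    np.fill_diagonal(D, np.inf)
    merges = []
    next_id = n
    slots = list(range(n))
    for _ in range(n - 1):
        best = None
        for ii in range(len(slots)):
            for jj in range(ii + 1, len(slots)):
                si, sj = slots[ii], slots[jj]
                key = (D[si, sj], active[si][0], active[sj][0])
                if best is None or key < best[0]:
                    best = (key, si, sj)
        si, sj = best[1], best[2]
        (id_i, n_i), (id_j, n_j) = active[si], active[sj]
        d_ij2 = D[si, sj]
        lo, hi = sorted((id_i, id_j))
        merges.append([lo, hi, np.sqrt(max(d_ij2, 0.0)), n_i + n_j])
        # Lance-Williams centroid update on squared dissimilarities
        for sk in slots:
            if sk in (si, sj):
                continue
            D[si, sk] = D[sk, si] = (
                (n_i * D[si, sk] + n_j * D[sj, sk]) / (n_i + n_j)
                - n_i * n_j * d_ij2 / (n_i + n_j) ** 2
            )
        active[si] = (next_id, n_i + n_j)
        next_id += 1
        slots.remove(sj)
        del active[sj]
    return np.array(merges, dtype=float)


def cluster_heatmap(
    tpm_condition_means: pd.DataFrame,
) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Cluster DE features on per-condition mean TPM profiles.

    Returns (linkage matrix, leaf-ordered feature ids, row-normalized
    matrix for plotting). Row normalization is (x - mean) / sd with
    zero-variance rows left at 0.
    """
    from scipy.cluster.hierarchy import leaves_list

    mat = tpm_condition_means.to_numpy(dtype=float)
    link = centroid_linkage(pearson_distance_matrix(mat))
    order = [tpm_condition_means.index[i] for i in leaves_list(link)]
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    norm = pd.DataFrame(
        (mat - mean) / sd,
        index=tpm_condition_means.index,
        columns=tpm_condition_means.columns,
    )
    return link, order, norm
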