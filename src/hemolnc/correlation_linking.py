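"""Expression correlation between DE lncRNAs and their DE neighbor genes.

Every qualifying (DE lncRNA, DE neighbor gene) pair is scored with both
Pearson's r and Spearman's rho across all samples, reproducing the
cis-regulation screen: a lncRNA whose expression tracks a gene within
10 kb of its locus is a cis-regulation candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

from .genome_context import NeighborLink


@dataclass
class CorrelationResult:
    lncrna_id: str
    gene_id: str
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n_samples: int
    defined: bool = True

    def __post_init__(self) -> None:
        if self.defined:
            if not (-1 <= self.pearson_r <= 1 and -1 <= self.spearman_rho <= 1):
                raise ValueError("correlation coefficient outside [-1, 1]")
            if self.n_samples < 3:
                raise ValueError("need at least 3 samples")


def _validate(x: np.ndarray, y: np.ndarray) -> None:
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation and its two-sided t-test p-value.

    Zero variance in either vector raises; callers wanting a flagged
    result use :func:`correlate_pair`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate(x, y)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    res = stats.pearsonr(x, y)
    return float(np.clip(res.statistic, -1.0, 1.0)), float(res.pvalue)


def spearman(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on midranks) with t-approx p.

    With ``exact=True`` and n <= 8 the p-value is computed by full
    permutation enumeration of one vector's ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate(x, y)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    rho, p = stats.spearmanr(x, y)
    rho = float(np.clip(rho, -1.0, 1.0))
    if exact:
        n = len(x)
        if n > 8:
            raise ValueError("exact permutation p limited to n <= 8")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = sum(
            abs(np.corrcoef(rx, np.array(perm))[0, 1]) >= obs - 1e-12
            for perm in permutations(ry)
        )
        p = count / factorial(n)
    return rho, float(p)


def correlate_pair(lnc_id: str, gene_id: str, x, y) -> CorrelationResult:
    """Both correlation statistics for one pair, degeneracy-flagged."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate(x, y)
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult(
            lnc_id, gene_id, np.nan, np.nan, np.nan, np.nan, len(x), defined=False
        )
    r, pr = pearson(x, y)
    rho, ps = spearman(x, y)
    return CorrelationResult(lnc_id, gene_id, r, pr, rho, ps, len(x))


def qualifying_pairs(
    links: list[NeighborLink],
    de_lncrnas: set[str],
    de_genes: set[str],
    gene_subset: set[str] | None = None,
) -> list[tuple[str, str]]:
    """(lncRNA, gene) pairs linked by proximity with both members DE.

    ``gene_subset`` optionally restricts genes to a family of interest.
    """
    pairs = sorted(
        {
            (l.lncrna_id, l.gene_id)
            for l in links
            if l.lncrna_id in de_lncrnas
            and l.gene_id in de_genes
            and (gene_subset is None or l.gene_id in gene_subset)
        }
    )
    return pairs


def correlate_links(
    tpm: pd.DataFrame,
    links: list[NeighborLink],
    de_lncrnas: set[str],
    de_genes: set[str],
    gene_subset: set[str] | None = None,
) -> tuple[list[CorrelationResult], pd.DataFrame]:
    """Correlate every qualifying pair across all sample columns.

    Returns the per-pair results and a row-normalized TPM matrix of the
    involved features (heat-map export). Empty pair lists warn.
    """
    pairs = qualifying_pairs(links, de_lncrnas, de_genes, gene_subset)
    if not pairs:
        warnings.warn("no qualifying DE lncRNA / DE neighbor-gene pairs", stacklevel=2)
        return [], pd.DataFrame(columns=tpm.columns)
    results = [
        correlate_pair(l, g, tpm.loc[l].to_numpy(), tpm.loc[g].to_numpy())
        for l, g in pairs
    ]
    involved = sorted({f for pair in pairs for f in pair})
    mat = tpm.loc[involved].to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    norm = pd.DataFrame((mat - mean) / sd, index=involved, columns=tpm.columns)
    return results, norm
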