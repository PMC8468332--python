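"""Coding-potential scoring of candidate lncRNAs.

Re-implements the classic alignment-free coding-potential assessment:
four sequence features (longest-ORF length, ORF coverage, Fickett
TESTCODE score, hexamer usage bias) feed a logistic regression whose
probability is thresholded to call a transcript coding or non-coding.

The Fickett lookup tables ship with the package as a JSON data file;
:func:`fickett_score` interprets them at run time so that an
independently coded table reader can serve as a cross-check.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import product
from math import log

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .orf import OrfCall, find_longest_orf, reverse_complement

BASES = "ACGT"
ALL_HEXAMERS = ["".join(p) for p in product(BASES, repeat=6)]


@dataclass(frozen=True)
class CodingPotentialFeatures:
    """Feature bundle for one transcript."""

    orf_length_bp: int
    orf_coverage: float
    fickett: float
    hexamer_bias: float
    score: float | None = None  # filled after classification

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.orf_length_bp, self.orf_coverage, self.fickett, self.hexamer_bias],
            dtype=float,
        )


# ---------------------------------------------------------------------------
# Fickett TESTCODE
# ---------------------------------------------------------------------------

def _load_fickett_tables() -> dict:
    text = resources.files("hemolnc.data").joinpath("fickett_tables.json").read_text()
    return json.loads(text)


_FICKETT = _load_fickett_tables()


def _lookup(value: float, thresholds: list[float], probs: list[float]) -> float:
    for t, p in zip(thresholds, probs):
        if value >= t:
            return p
    return probs[-1]


def fickett_score(sequence: str, tables: dict | None = None) -> float:
    """Fickett TESTCODE statistic of a nucleotide sequence.

    Combines, for each base, a positional-asymmetry parameter
    max(count in codon positions) / (min(count) + 1) and the base
    content fraction, each mapped through the published lookup bins and
    weighted. Case-insensitive; N counts toward neither statistic.
    Sequences shorter than 200 nt are rejected, mirroring the lncRNA
    length floor.
    """
    seq = sequence.upper()
    if len(seq) < 200:
        raise ValueError(f"sequence shorter than 200 nt ({len(seq)})")
    tbl = tables if tables is not None else _FICKETT

    pos_counts = {b: [0, 0, 0] for b in BASES}
    totals = dict.fromkeys(BASES, 0)
    for i, base in enumerate(seq):
        if base in pos_counts:
            pos_counts[base][i % 3] += 1
            totals[base] += 1
    n_acgt = sum(totals.values())

    score = 0.0
    for b in BASES:
        counts = pos_counts[b]
        position_param = max(counts) / (min(counts) + 1)
        content_param = totals[b] / n_acgt if n_acgt else 0.0
        score += tbl["position_weight"][b] * _lookup(
            position_param, tbl["position_para"], tbl["position_prob"][b]
        )
        score += tbl["content_weight"][b] * _lookup(
            content_param, tbl["content_para"], tbl["content_prob"][b]
        )
    return score


# ---------------------------------------------------------------------------
# Hexamer usage bias
# ---------------------------------------------------------------------------

def hexamer_frequencies(
    sequences: list[str], step: int = 3, pseudocount: float = 1.0
) -> dict[str, float]:
    """Smoothed hexamer frequency table trained from sequences.

    ``step=3`` counts in-frame (frame 0) hexamers, appropriate for
    ORF-derived coding training sequences; ``step=1`` counts every
    overlapping hexamer for unoriented non-coding sequences.
    """
    counts = dict.fromkeys(ALL_HEXAMERS, pseudocount)
    for seq in sequences:
        s = seq.upper()
        for i in range(0, len(s) - 5, step):
            h = s[i : i + 6]
            if h in counts:
                counts[h] += 1
    total = sum(counts.values())
    return {h: c / total for h, c in counts.items()}


def hexamer_bias(
    sequence: str,
    coding_freqs: dict[str, float],
    noncoding_freqs: dict[str, float],
    orf: OrfCall | None = None,
    _orf_computed: bool = False,
) -> float:
    """Mean in-frame log-ratio log(F_coding / F_noncoding) of hexamers.

    Hexamers are read at step 3 within the longest ORF (on the ORF's
    strand); when the transcript has no ORF the whole sequence in frame
    0 is used. Hexamers containing N are skipped; if every hexamer is
    skipped the score is 0 with a warning.
    """
    seq = sequence.upper()
    if not _orf_computed and orf is None:
        orf = find_longest_orf(seq)
    if orf is None:
        region = seq
    else:
        stranded = seq if orf.strand == "+" else reverse_complement(seq)
        region = stranded[orf.start : orf.end]

    ratios = []
    for i in range(0, len(region) - 5, 3):
        h = region[i : i + 6]
        if h not in coding_freqs:  # contains N or other ambiguity
            continue
        ratios.append(log(coding_freqs[h] / noncoding_freqs[h]))
    if not ratios:
        warnings.warn("no scoreable hexamers; hexamer bias set to 0", stacklevel=2)
        return 0.0
    return float(np.mean(ratios))


def compute_features(
    sequence: str,
    coding_freqs: dict[str, float],
    noncoding_freqs: dict[str, float],
) -> CodingPotentialFeatures:
    """All four coding-potential features of one transcript."""
    orf = find_longest_orf(sequence)
    orf_len = orf.length_bp if orf else 0
    return CodingPotentialFeatures(
        orf_length_bp=orf_len,
        orf_coverage=orf_len / len(sequence),
        fickett=fickett_score(sequence),
        hexamer_bias=hexamer_bias(
            sequence, coding_freqs, noncoding_freqs, orf=orf, _orf_computed=True
        ),
    )


# ---------------------------------------------------------------------------
# Logistic classifier
# ---------------------------------------------------------------------------

class CodingPotentialClassifier(BaseEstimator, ClassifierMixin):
    """Logistic-regression coding/non-coding classifier.

    Fit by iteratively reweighted least squares on internally
    standardized features; on (quasi-)perfect separation the fit falls
    back to an L2 ridge penalty with a warning. The decision cutoff
    defaults to 0.5 and can instead be chosen to maximise Youden's J on
    a held-out split.

    Parameters
    ----------
    cutoff : float
        Probability above which a transcript is called coding.
    tol, max_iter : IRLS convergence controls.
    ridge : L2 penalty used only in the separation fallback.
    """

    def __init__(
        self,
        cutoff: float = 0.5,
        tol: float = 1e-8,
        max_iter: int = 100,
        ridge: float = 1e-3,
    ):
        self.cutoff = cutoff
        self.tol = tol
        self.max_iter = max_iter
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("both classes (0 and 1) must be present")
        if min((y == 0).sum(), (y == 1).sum()) < 2:
            raise ValueError("need at least 2 examples per class")

        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        Z = np.column_stack([np.ones(len(X)), (X - self.mean_) / self.scale_])

        beta, converged = self._irls(Z, y, 0.0)
        if not converged or np.abs(beta).max() > 1e4:
            warnings.warn(
                "quasi-perfect separation detected; refitting with L2 ridge",
                stacklevel=2,
            )
            beta, _ = self._irls(Z, y, self.ridge)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.classes_ = np.array([0, 1])
        self.cutoff_ = float(self.cutoff)
        return self

    def _irls(self, Z, y, lam):
        beta = np.zeros(Z.shape[1])
        penalty = lam * np.eye(Z.shape[1])
        penalty[0, 0] = 0.0  # never penalize the intercept
        for _ in range(self.max_iter):
            eta = np.clip(Z @ beta, -30, 30)
            p = 1.0 / (1.0 + np.exp(-eta))
            w = np.clip(p * (1 - p), 1e-10, None)
            H = (Z * w[:, None]).T @ Z + penalty
            grad = Z.T @ (y - p) - penalty @ beta
            try:
                delta = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                return beta, False
            beta = beta + delta
            if np.abs(delta).max() < self.tol:
                return beta, True
        return beta, False

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        return self.intercept_ + Z @ self.coef_

    def predict_proba(self, X):
        p = 1.0 / (1.0 + np.exp(-np.clip(self.decision_function(X), -30, 30)))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= self.cutoff_).astype(int)

    def tune_cutoff_youden(self, X_val, y_val):
        """Set ``cutoff_`` to maximise Youden's J on validation data."""
        p = self.predict_proba(X_val)[:, 1]
        y_val = np.asarray(y_val)
        best_j, best_c = -np.inf, self.cutoff_
        for c in np.unique(np.round(p, 6)):
            pred = p >= c
            tpr = (pred & (y_val == 1)).sum() / max((y_val == 1).sum(), 1)
            fpr = (pred & (y_val == 0)).sum() / max((y_val == 0).sum(), 1)
            if tpr - fpr > best_j:
                best_j, best_c = tpr - fpr, c
        self.cutoff_ = float(best_c)
        return self


def train_coding_model(
    features: np.ndarray,
    labels: np.ndarray,
    cutoff: float = 0.5,
    youden_split: float | None = None,
    random_state: int | None = None,
) -> CodingPotentialClassifier:
    """Fit a :class:`CodingPotentialClassifier` on labeled feature rows.

    ``labels`` are 1 for coding, 0 for non-coding. When ``youden_split``
    is given (e.g. 0.25), that fraction is held out and the decision
    cutoff is tuned to maximise Youden's J on it.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    clf = CodingPotentialClassifier(cutoff=cutoff)
    if youden_split:
        rng = np.random.default_rng(random_state)
        idx = rng.permutation(len(X))
        n_val = max(int(round(youden_split * len(X))), 1)
        val, train = idx[:n_val], idx[n_val:]
        clf.fit(X[train], y[train])
        clf.tune_cutoff_youden(X[val], y[val])
    else:
        clf.fit(X, y)
    return clf
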