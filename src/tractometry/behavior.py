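"""2AFC scoring, the binomial blindsight criterion, and cross-validation.

A participant is "blindsight positive" when either their pooled
performance over all valid trials or their performance at 100% contrast
is significantly above chance under a one-sided cumulative binomial
test at p < 0.01. At 20 trials per contrast the 100%-contrast threshold
works out to 16/20 correct (tail p = 0.0059; 15/20 gives 0.0207).

Two label-free checks validate the criterion: leave-one-out k-nearest
neighbours over the all-contrast performance vectors (neighbour labels
come from the binomial criterion; ties break toward "negative"), and a
two-component Gaussian mixture fitted blind, with the higher-performance
centroid mapped to "positive". Both are sklearn estimators under the
hood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

from .errors import ConvergenceError, CriterionError, EmptyInputError

__all__ = [
    "PerformanceVector",
    "BlindsightLabel",
    "exclude_fixation_breaks",
    "score_performance",
    "binomial_exceedance",
    "classify_blindsight",
    "knn_crossval",
    "gmm_classify",
]

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class PerformanceVector:
    """Per-contrast and pooled 2AFC performance for one participant."""

    contrasts: np.ndarray        # ascending
    n_correct: np.ndarray
    n_valid: np.ndarray
    percent_correct: np.ndarray  # NaN where a contrast has no valid trials
    overall_n_correct: int
    overall_n_valid: int
    missing_contrasts: list[float]

    @property
    def overall_percent(self) -> float:
        return 100.0 * self.overall_n_correct / self.overall_n_valid


@dataclass
class BlindsightLabel:
    """Binomial-criterion outcome for one participant."""

    label: str                 # "positive" | "negative"
    p_overall: float
    p_at_100: float
    criterion_met: str         # "overall" | "at_100" | "both" | "none"


def exclude_fixation_breaks(trials: pd.DataFrame, limit: float = 1.0) -> pd.DataFrame:
    """Drop trials whose fixation deviation exceeded ``limit`` degrees.

    The comparison is strict ("exceeded"): a trial at exactly the limit
    is retained.
    """
    keep = trials["fixation_deg"] <= limit
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluded %d/%d trials for fixation breaks (> %g deg)",
                    n_dropped, len(trials), limit)
    return trials.loc[keep].reset_index(drop=True)


def score_performance(
    trials: pd.DataFrame, expected_contrasts=None
) -> PerformanceVector:
    """Percent correct per contrast and pooled over all valid trials.

    A trial is correct when the response matches the true interval. A
    contrast level with zero valid trials (e.g. all excluded as fixation
    breaks) is reported as missing (NaN percent), never imputed; pass
    ``expected_contrasts`` to flag levels absent from the table.
    """
    if trials.empty:
        raise EmptyInputError("no trials to score")
    if expected_contrasts is not None:
        contrasts = np.sort(np.unique(expected_contrasts))
    else:
        contrasts = np.sort(trials["contrast"].unique())
    correct = (trials["response"] == trials["true_interval"]).to_numpy()
    n_correct, n_valid = [], []
    for c in contrasts:
        sel = (trials["contrast"] == c).to_numpy()
        n_valid.append(int(sel.sum()))
        n_correct.append(int(correct[sel].sum()))
    n_correct = np.asarray(n_correct)
    n_valid = np.asarray(n_valid)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(n_valid > 0, 100.0 * n_correct / np.maximum(n_valid, 1), np.nan)
    missing = [float(c) for c, n in zip(contrasts, n_valid) if n == 0]
    if missing:
        logger.warning("contrasts with zero valid trials: %s", missing)
    return PerformanceVector(
        contrasts=contrasts,
        n_correct=n_correct,
        n_valid=n_valid,
        percent_correct=percent,
        overall_n_correct=int(correct.sum()),
        overall_n_valid=int(len(trials)),
        missing_contrasts=missing,
    )


def binomial_exceedance(n_correct: int, n_trials: int, p0: float = 0.5) -> float:
    """One-sided upper-tail probability P(X >= n_correct), X ~ Bin(n, p0)."""
    if not 0 <= n_correct <= n_trials:
        raise ValueError(f"n_correct={n_correct} outside [0, {n_trials}]")
    return float(binom.sf(n_correct - 1, n_trials, p0))


def classify_blindsight(perf: PerformanceVector, alpha: float = 0.01) -> BlindsightLabel:
    """Binomial criterion: positive if pooled OR 100%-contrast performance
    is above chance at ``alpha`` (one-sided exact binomial)."""
    at100 = np.isclose(perf.contrasts, 1.0)
    if not at100.any() or perf.n_valid[at100][0] == 0:
        raise CriterionError("100%-contrast cell is missing; criterion undefined")
    i = int(np.nonzero(at100)[0][0])
    p_at_100 = binomial_exceedance(int(perf.n_correct[i]), int(perf.n_valid[i]))
    p_overall = binomial_exceedance(perf.overall_n_correct, perf.overall_n_valid)
    met_overall = p_overall < alpha
    met_100 = p_at_100 < alpha
    criterion = {(True, True): "both", (True, False): "overall",
                 (False, True): "at_100", (False, False): "none"}[(met_overall, met_100)]
    return BlindsightLabel(
        label=POSITIVE if criterion != "none" else NEGATIVE,
        p_overall=p_overall,
        p_at_100=p_at_100,
        criterion_met=criterion,
    )


def knn_crossval(
    perf_matrix: np.ndarray,
    labels: list[str],
    k: int = 5,
) -> tuple[list[str], int]:
    """Leave-one-out k-NN validation of the binomial labels.

    Each participant is held out and relabelled by the majority label of
    their ``k`` nearest neighbours (Euclidean distance over all-contrast
    performance); ties break toward "negative". Returns the predictions
    and the number agreeing with the input labels.
    """
    X = np.asarray(perf_matrix, dtype=float)
    n = len(X)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} participants, got {n}")
    if len(labels) != n:
        raise ValueError("labels length does not match perf_matrix")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    labels_arr = np.asarray(labels)
    predictions = []
    for i in range(n):
        neighbours = [j for j in idx[i] if j != i][:k]
        votes = labels_arr[neighbours]
        n_pos = int((votes == POSITIVE).sum())
        predictions.append(POSITIVE if n_pos > len(votes) - n_pos else NEGATIVE)
    agreement = int(sum(p == l for p, l in zip(predictions, labels)))
    return predictions, agreement


def gmm_classify(
    perf_matrix: np.ndarray,
    rng_seed: int = 0,
    n_init: int = 10,
) -> tuple[list[str], np.ndarray]:
    """Blind two-component Gaussian mixture classification.

    The mixture is fitted by EM without labels (``n_init`` seeded
    restarts, best likelihood kept); participants are assigned to the
    nearest component and the higher-mean-performance centroid is
    called "positive". Returns labels and the (2, n_contrasts) centroid
    means. A degenerate cohort (all rows identical) raises
    :class:`ConvergenceError`.
    """
    X = np.asarray(perf_matrix, dtype=float)
    if len(X) < 3:
        raise ValueError(f"need >= 3 participants, got {len(X)}")
    if np.allclose(X, X[0]):
        raise ConvergenceError("all participants identical; mixture fit is degenerate")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_init,
        random_state=rng_seed,
        reg_covar=1e-4,
    ).fit(X)
    if not gm.converged_:
        raise ConvergenceError(
            f"EM did not converge in {gm.n_iter_} iterations "
            f"(lower bound {gm.lower_bound_:.4g})"
        )
    assign = gm.predict(X)
    positive_component = int(np.argmax(gm.means_.mean(axis=1)))
    labels = [POSITIVE if a == positive_component else NEGATIVE for a in assign]
    return labels, gm.means_
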