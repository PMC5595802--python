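"""Bayes classifier and Bayes error of the idealized tree-vote process.

Model the HARF classification step for two categories (coded here as class 0
and class 1) with T trees, each voting independently with per-class
accuracies

    P(vote 0 | Y=0) = b0,    P(vote 1 | Y=1) = b1,

and prior P(Y=0) = C. The number of 0-votes B then follows Binomial(T, b0)
under Y=0 and Binomial(T, 1-b1) under Y=1, and the Bayes rule "declare 0 iff
P(Y=0|B) > P(Y=1|B)" reduces to a vote-count threshold

    declare 0  iff  k > T_hat,
    T_hat = T log(beta1)/log(beta0) + log((1-C)/C)/log(beta0),
    beta0 = b0 b1 / ((1-b0)(1-b1)),   beta1 = b1 / (1-b0),

valid for beta0 > 1 (informative trees). For b0 = b1 and C = 1/2 this is the
familiar k > T/2 majority; unequal priors shift the optimal threshold away
from 50%, which motivates HARF's tunable vote threshold. The attainable
error of the thresholded vote is the pair of binomial tails

    eps_d = P(Y=1) P(B > T_hat | Y=1) + P(Y=0) P(B <= T_hat | Y=0),

summed over integer vote counts; a count exactly equal to an integer
threshold falls on the "declare 1" side (the <= branch of the Bayes rule),
which is the convention that generalizes the even-T sums to odd T and
non-integer thresholds.

The independence assumption is optimistic -- real trees share training data
and features, so eps_d is a lower bound that empirical misclassification
approaches but does not beat.

The mapping onto HARF models is category 1 -> class 0 and category 2 ->
class 1 (so b0 is the per-tree accuracy on category 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .heterogeneity import HarfModel, leaf_majority
from . import forest as rf

__all__ = [
    "VoteModel",
    "DegenerateClassifierError",
    "vote_threshold",
    "bayes_error",
    "estimate_tree_accuracies",
]


class DegenerateClassifierError(ValueError):
    """The vote count carries no information (log beta0 = 0)."""


@dataclass(frozen=True)
class VoteModel:
    b0: float          # P(vote 0 | Y=0)
    b1: float          # P(vote 1 | Y=1)
    prior_c0: float    # P(Y=0)
    T: int             # number of trees

    def __post_init__(self) -> None:
        for name in ("b0", "b1"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if not 0.0 < self.prior_c0 < 1.0:
            raise ValueError(f"prior_c0 must lie strictly in (0, 1), got {self.prior_c0}")
        if self.T < 1:
            raise ValueError("T must be >= 1")


def _betas(vm: VoteModel) -> tuple[float, float]:
    beta0 = vm.b0 * vm.b1 / ((1.0 - vm.b0) * (1.0 - vm.b1))
    beta1 = vm.b1 / (1.0 - vm.b0)
    return beta0, beta1


def vote_threshold(vm: VoteModel) -> float:
    """Vote-count threshold T_hat of the Bayes rule: declare class 0 iff
    the number of 0-votes k exceeds T_hat."""
    if vm.b0 == 1.0 or vm.b1 == 1.0:
        raise DegenerateClassifierError(
            "perfect per-tree accuracy: the threshold formula is not finite"
        )
    beta0, beta1 = _betas(vm)
    log_b0 = math.log(beta0)
    # b0 + b1 = 1 makes beta0 = 1 exactly; tolerate float round-off in the product
    if abs(log_b0) < 1e-9:
        raise DegenerateClassifierError(
            "beta0 = 1: the vote count does not discriminate between classes"
        )
    return (vm.T * math.log(beta1) + math.log((1.0 - vm.prior_c0) / vm.prior_c0)) / log_b0


def _class0_votes(vm: VoteModel) -> np.ndarray:
    """Integer vote counts k in 0..T for which the Bayes rule declares 0."""
    k = np.arange(vm.T + 1)
    if vm.b0 == 1.0 and vm.b1 == 1.0:
        # perfect trees: any threshold strictly between 0 and T separates
        return k == vm.T
    if vm.b0 == 1.0 or vm.b1 == 1.0:
        # one-sided certainty: compare posteriors directly (0^0 handled by numpy)
        logp0 = k * np.log(vm.b0) + (vm.T - k) * np.log1p(-vm.b0) \
            if vm.b0 < 1.0 else np.where(k == vm.T, 0.0, -np.inf)
        logp1 = k * np.log1p(-vm.b1) + (vm.T - k) * np.log(vm.b1) \
            if vm.b1 < 1.0 else np.where(k == 0, 0.0, -np.inf)
        return logp0 + math.log(vm.prior_c0) > logp1 + math.log(1.0 - vm.prior_c0)
    beta0, beta1 = _betas(vm)
    if abs(math.log(beta0)) < 1e-9:
        # k-free rule: declare 0 iff the class-0 posterior dominates everywhere
        lhs = vm.T * math.log(beta1) + math.log((1.0 - vm.prior_c0) / vm.prior_c0)
        return np.full(vm.T + 1, lhs < 0.0)
    t_hat = vote_threshold(vm)
    if beta0 > 1.0:
        return k > t_hat
    return k < t_hat           # anti-informative trees flip the direction


def bayes_error(vm: VoteModel) -> float:
    """Minimal misclassification probability of the thresholded tree vote."""
    k = np.arange(vm.T + 1)
    declare0 = _class0_votes(vm)
    p_b_given_y0 = binom.pmf(k, vm.T, vm.b0)          # 0-votes under Y=0
    p_b_given_y1 = binom.pmf(k, vm.T, 1.0 - vm.b1)    # 0-votes under Y=1
    err = (1.0 - vm.prior_c0) * p_b_given_y1[declare0].sum() \
        + vm.prior_c0 * p_b_given_y0[~declare0].sum()
    return float(min(max(err, 0.0), 1.0))


def estimate_tree_accuracies(model: HarfModel, out_of_bag: bool = False,
                             clip: bool = True) -> tuple[float, float]:
    """Estimate (b0, b1) from per-tree leaf-majority votes on training samples.

    b0 is the fraction of (tree, sample) pairs with true category 1 whose
    leaf majority is 1; b1 likewise for category 2. By default all training
    samples are used (in-bag); ``out_of_bag=True`` restricts each tree's
    pairs to samples absent from its bootstrap. Estimates are clipped into
    [1/(2TS), 1 - 1/(2TS)] so the resulting VoteModel stays non-degenerate.
    """
    if model.K != 2:
        raise ValueError("tree-accuracy estimation requires exactly two categories")
    X = model.forest.X_train
    labels = model.train_labels
    T = len(model.forest.trees)
    S = X.shape[0]
    hits = np.zeros(2)
    totals = np.zeros(2)
    for tree, boot in zip(model.forest.trees, model.forest.bootstrap_indices):
        if out_of_bag:
            in_bag = np.zeros(S, dtype=bool)
            in_bag[boot] = True
            sample_idx = np.flatnonzero(~in_bag)
        else:
            sample_idx = np.arange(S)
        for i in sample_idx:
            vote = leaf_majority(rf.tree_leaf(tree, X[i]))
            c = labels[i] - 1
            totals[c] += 1
            hits[c] += vote == labels[i]
    if (totals == 0).any():
        raise ValueError("no (tree, sample) pairs available for some category")
    b = hits / totals
    if clip:
        lo = 1.0 / (2.0 * T * S)
        b = np.clip(b, lo, 1.0 - lo)
    return float(b[0]), float(b[1])
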