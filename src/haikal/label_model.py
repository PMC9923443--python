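"""Aggregate LF votes into probabilistic correct/incorrect labels.

Two aggregators are provided: a majority-vote baseline and a generative
label model.  The generative model is a two-class, conditionally
independent Dawid-Skene model with abstention as an explicit outcome:
each decoy carries a latent binary label y with prior pi = P(y = correct),
and each labeling function j emits a vote v in {+1, 0, -1} from its own
class-conditional vote distribution

    theta_j[y, v] = P(v_ij = v | y_i = y),

a 2x3 row-stochastic confusion matrix.  Modeling the two classes
separately matters here: threshold LFs are typically asymmetric voters
(a wide correct region, a narrow incorrect region), and a single
symmetric accuracy parameter would mistake that bias for skill and drag
the estimated class prior toward the majority vote direction.

Parameters are estimated by EM from the vote matrix alone — no gold
labels — which is what lets the model mass-label decoys whose structural
quality was never assessed.  The row likelihood is

    P(v_i) = pi * prod_j theta_j[+1, v_ij] + (1-pi) * prod_j theta_j[-1, v_ij].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WeakLabeling",
    "LabelModel",
    "LabelModelResults",
    "majority_vote",
    "labeling_accuracy",
    "estimate_prevalence",
]

#: Accuracy clamp half-width: reported accuracies live in (0.5+DELTA, 1-DELTA).
DELTA = 0.01

#: Vote categories in the order used by the confusion matrices.
_VOTE_ORDER = (1, 0, -1)


@dataclass
class WeakLabeling:
    """Per-decoy weak labels.

    ``prob`` is the probability of being correct; ``label`` the hard label
    at the 0.5 cutoff (ties -> incorrect, conservative for downstream
    balanced sampling); ``covered`` flags decoys with at least one
    non-abstain vote.  Uncovered decoys receive the class prior as their
    probability and the prior's hard label, so every decoy is labeled.
    """

    prob: np.ndarray
    label: np.ndarray  # bool, True = correct
    covered: np.ndarray  # bool

    def to_frame(self) -> pd.DataFrame:
        from .core_data import CORRECT, INCORRECT

        return pd.DataFrame(
            {
                "weak_prob": self.prob,
                "weak_label": np.where(self.label, CORRECT, INCORRECT),
                "covered": self.covered,
            }
        )


def majority_vote(matrix: np.ndarray, prior: float = 0.5) -> WeakLabeling:
    """Baseline aggregator: fraction of +1 votes among non-abstain votes.

    Ties give probability 0.5 (hence hard label incorrect); all-abstain
    rows fall back to the class prior and are flagged uncovered.
    """
    m = np.asarray(matrix)
    if m.size == 0:
        raise ValueError("empty vote matrix")
    n_pos = (m == 1).sum(axis=1)
    n_vote = (m != 0).sum(axis=1)
    covered = n_vote > 0
    with np.errstate(invalid="ignore"):
        prob = np.where(covered, n_pos / np.maximum(n_vote, 1), prior)
    return WeakLabeling(prob=prob, label=prob > 0.5, covered=covered)


def _vote_indices(m: np.ndarray) -> np.ndarray:
    """Map votes {+1, 0, -1} to confusion-matrix column indices {0, 1, 2}."""
    return np.select([m == 1, m == 0], [0, 1], default=2)


class LabelModel:
    """Generative vote-aggregation model for a decoys x LFs vote matrix.

    Parameters
    ----------
    vote_matrix :
        Integer matrix with entries +1 (correct), -1 (incorrect),
        0 (abstain); one row per decoy, one column per labeling function.
    lf_names :
        Optional column names for reporting.
    """

    def __init__(self, vote_matrix, lf_names=None):
        m = np.asarray(vote_matrix, dtype=np.int8)
        if m.ndim != 2 or m.shape[1] < 2:
            raise ValueError("need a 2-D vote matrix with >= 2 LFs")
        if not np.isin(m, (-1, 0, 1)).all():
            raise ValueError("votes must be in {-1, 0, +1}")
        if not (m != 0).any(axis=1).any():
            raise ValueError("every row abstains; nothing to fit")
        self.votes = m
        self.lf_names = (
            list(lf_names)
            if lf_names is not None
            else [f"lf{j}" for j in range(m.shape[1])]
        )

    def fit(
        self,
        seed: int = 0,
        max_iter: int = 500,
        tol: float = 1e-6,
        class_prior: float | None = None,
        smoothing: float = 0.01,
    ) -> "LabelModelResults":
        """Fit the per-LF confusion matrices and the class prior by EM.

        ``class_prior`` fixes pi when the prevalence is known (e.g. 0.5 on
        a deliberately balanced training set); by default it is estimated.
        Initialization is deterministic given ``seed``: responsibilities
        start from the majority vote, softened, with a tiny seeded jitter
        to break exact symmetries.  ``smoothing`` is a small Dirichlet
        pseudo-count keeping vote probabilities off zero; the recorded
        log-likelihood trace is the corresponding penalised (MAP)
        objective, which EM makes non-decreasing.
        """
        m = self.votes
        n, k = m.shape
        rng = np.random.default_rng(seed)
        vidx = _vote_indices(m)

        mv = majority_vote(m)
        r = np.where(mv.covered, 0.25 + 0.5 * (mv.prob > 0.5), 0.5)
        r = np.clip(r + rng.uniform(-0.01, 0.01, size=n), 1e-3, 1 - 1e-3)
        prior = 0.5 if class_prior is None else float(class_prior)

        theta = np.empty((k, 2, 3))
        alpha = smoothing
        trace: list[float] = []
        converged = False
        for _ in range(max_iter):
            # M-step: class-conditional vote distributions from the
            # current responsibilities
            w = np.stack([r, 1.0 - r])  # (2, n)
            for j in range(k):
                for v in range(3):
                    sel = vidx[:, j] == v
                    theta[j, :, v] = w[:, sel].sum(axis=1) + alpha
            theta /= theta.sum(axis=2, keepdims=True)
            # E-step
            lik_pos = np.ones(n)
            lik_neg = np.ones(n)
            for j in range(k):
                lik_pos *= theta[j, 0, vidx[:, j]]
                lik_neg *= theta[j, 1, vidx[:, j]]
            mix = prior * lik_pos + (1.0 - prior) * lik_neg
            ll = float(np.log(mix).sum()) + alpha * float(np.log(theta).sum())
            trace.append(ll)
            r = prior * lik_pos / mix
            if class_prior is None:
                prior = float(np.clip(r.mean(), 1e-6, 1 - 1e-6))
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
                converged = True
                break
        if not converged:
            warnings.warn("label-model EM did not converge", stacklevel=2)

        return LabelModelResults(
            model=self,
            confusion=theta,
            prior=prior,
            loglik_trace=np.asarray(trace),
            converged=converged,
            n_iter=len(trace),
            seed=seed,
        )


@dataclass
class LabelModelResults:
    """Fitted label-model parameters and posterior prediction.

    ``confusion`` holds the per-LF class-conditional vote distributions,
    shape (n_lfs, 2, 3): axis 1 is the latent class (correct, incorrect),
    axis 2 the vote (+1, 0, -1).  ``accuracies`` and ``propensities``
    summarise it per LF: the prior-weighted probability of voting with
    the true class given a vote (clamped to (0.51, 0.99)), and the
    marginal probability of voting at all.
    """

    model: LabelModel
    confusion: np.ndarray
    prior: float
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    seed: int

    @property
    def accuracies(self) -> np.ndarray:
        t = self.confusion
        # P(vote agrees | voted, y) per class, then prior-weighted
        agree_pos = t[:, 0, 0] / (t[:, 0, 0] + t[:, 0, 2])
        agree_neg = t[:, 1, 2] / (t[:, 1, 2] + t[:, 1, 0])
        acc = self.prior * agree_pos + (1 - self.prior) * agree_neg
        return np.clip(acc, 0.5 + DELTA, 1 - DELTA)

    @property
    def propensities(self) -> np.ndarray:
        t = self.confusion
        voted = 1.0 - t[:, :, 1]  # per class
        return self.prior * voted[:, 0] + (1 - self.prior) * voted[:, 1]

    def adapted_prior(self, vote_matrix, max_iter: int = 100, tol: float = 1e-8):
        """Class prior re-estimated on a new vote population.

        The training split's prevalence (0.5 on a deliberately balanced
        set) does not transfer to an arbitrary decoy population.  This is
        the standard EM prior-shift correction: iterate posterior
        averaging with the fitted per-LF confusions held fixed, updating
        only pi, until the prior stabilises.
        """
        m = np.asarray(vote_matrix, dtype=np.int8)
        vidx = _vote_indices(m)
        lik_pos = np.ones(m.shape[0])
        lik_neg = np.ones(m.shape[0])
        for j in range(m.shape[1]):
            lik_pos *= self.confusion[j, 0, vidx[:, j]]
            lik_neg *= self.confusion[j, 1, vidx[:, j]]
        prior = self.prior
        for _ in range(max_iter):
            post = prior * lik_pos / (prior * lik_pos + (1 - prior) * lik_neg)
            new = float(np.clip(post.mean(), 1e-6, 1 - 1e-6))
            if abs(new - prior) < tol:
                break
            prior = new
        return prior

    def predict(self, vote_matrix=None, adapt_prior: bool = False) -> WeakLabeling:
        """Posterior probability of correctness per decoy.

        Hard label at the 0.5 cutoff with ties -> incorrect; all-abstain
        rows receive the class prior and are flagged uncovered.  With
        ``adapt_prior`` the class prior is first re-estimated on the given
        votes (see :meth:`adapted_prior`) — appropriate when the predicted
        population's prevalence differs from the training split's.
        """
        m = (
            self.model.votes
            if vote_matrix is None
            else np.asarray(vote_matrix, dtype=np.int8)
        )
        if m.ndim != 2 or m.shape[1] != self.confusion.shape[0]:
            raise ValueError("LF count mismatch with fitted parameters")
        prior = self.adapted_prior(m) if adapt_prior else self.prior
        vidx = _vote_indices(m)
        lik_pos = np.ones(m.shape[0])
        lik_neg = np.ones(m.shape[0])
        for j in range(m.shape[1]):
            lik_pos *= self.confusion[j, 0, vidx[:, j]]
            lik_neg *= self.confusion[j, 1, vidx[:, j]]
        mix = prior * lik_pos + (1 - prior) * lik_neg
        prob = prior * lik_pos / mix
        covered = (m != 0).any(axis=1)
        prob = np.where(covered, prob, prior)
        return WeakLabeling(prob=prob, label=prob > 0.5, covered=covered)

    def to_text(self) -> str:
        """Plain-text serialization: per LF the summary accuracy and
        propensity plus the six confusion entries; prior on the last line."""
        lines = []
        for name, a, q, t in zip(
            self.model.lf_names, self.accuracies, self.propensities, self.confusion
        ):
            flat = "\t".join(repr(float(x)) for x in t.ravel())
            lines.append(f"{name}\t{float(a)!r}\t{float(q)!r}\t{flat}")
        lines.append(f"__prior__\t{float(self.prior)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "LabelModelResults":
        names, thetas, prior = [], [], 0.5
        for line in text.splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if parts[0] == "__prior__":
                prior = float(parts[1])
            else:
                names.append(parts[0])
                thetas.append(np.array([float(x) for x in parts[3:]]).reshape(2, 3))
        theta = np.stack(thetas)
        model = LabelModel.__new__(LabelModel)
        model.votes = np.zeros((1, len(names)), dtype=np.int8)
        model.lf_names = names
        return cls(
            model=model,
            confusion=theta,
            prior=prior,
            loglik_trace=np.empty(0),
            converged=True,
            n_iter=0,
            seed=0,
        )

    def summary(self) -> str:
        """Human-readable parameter table, statsmodels-style."""
        width = max(len(n) for n in self.model.lf_names)
        head = (
            f"Label model: {self.confusion.shape[0]} LFs, "
            f"{self.model.votes.shape[0]} decoys\n"
            f"prior P(correct) = {self.prior:.4f}   "
            f"EM iterations = {self.n_iter}   converged = {self.converged}\n"
            f"{'LF'.ljust(width)}  accuracy  propensity\n"
        )
        rows = "".join(
            f"{name.ljust(width)}  {a:8.4f}  {q:10.4f}\n"
            for name, a, q in zip(
                self.model.lf_names, self.accuracies, self.propensities
            )
        )
        return head + rows


def estimate_prevalence(
    vote_matrix,
    tpr,
    fpr,
    min_separation: float = 0.1,
) -> float | None:
    """Adjusted-count quantification of the correct-class prevalence.

    For an LF with gold-measured correct-vote rates
    tpr = P(v=+1 | correct) and fpr = P(v=+1 | incorrect), the observed
    positive-vote rate on a new population is
    r = tpr * pi + fpr * (1 - pi); solving for pi corrects the raw count
    for the LF's known miss and false-alarm rates.  The estimate is the
    median over all LFs whose rates are separated by at least
    ``min_separation`` (near-chance LFs carry no prevalence signal);
    returns None when no LF qualifies.
    """
    m = np.asarray(vote_matrix)
    tpr = np.asarray(tpr, dtype=float)
    fpr = np.asarray(fpr, dtype=float)
    estimates = []
    for j in range(m.shape[1]):
        sep = tpr[j] - fpr[j]
        if abs(sep) < min_separation:
            continue
        r = (m[:, j] == 1).mean()
        estimates.append(float(np.clip((r - fpr[j]) / sep, 0.0, 1.0)))
    if not estimates:
        return None
    return float(np.median(estimates))


def labeling_accuracy(pred: WeakLabeling, gold) -> tuple[float, float]:
    """Fraction of decoys whose hard weak label matches gold.

    Returns ``(accuracy on covered rows, accuracy over all rows)`` — the
    latter under the all-abstain prior policy.
    """
    y = np.asarray(gold, dtype=bool)
    if len(y) != len(pred.label):
        raise ValueError("gold labels misaligned with predictions")
    if not pred.covered.any():
        raise ValueError("no covered rows to score")
    hits = pred.label == y
    return float(hits[pred.covered].mean()), float(hits.mean())
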