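"""Hybrid identification and genotype-frequency-class posteriors.

Two complementary classifiers for fully diagnostic markers:

* a threshold rule on an admixture proportion Q (externally estimated or
  proxied by the nuclear hybrid index): individuals with intermediate Q
  are hybrids, the rest pure parentals. The conventional printed cutoffs
  are (0.1, 0.9); a "formula" mode uses the midpoint construction
  ``lower = (0 + 1/(2L+1))/2``, ``upper = (1 + 2L/(2L+1))/2`` for L
  diploid diagnostic loci (L = 3 gives 1/14 and 13/14).
* a closed-form posterior over the six early-generation genotype
  frequency classes (two parentals, F1, F2, two backcrosses), multiplying
  each class's per-locus genotype probabilities across scored loci. This
  is exact for diagnostic loci and needs no MCMC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

CLASSES = ("pure_E", "pure_K", "F1", "F2", "BC_E", "BC_K")

#: P(K-copy count = 0, 1, 2) at one diagnostic diploid locus, per class
CLASS_GENOTYPE_PROBS = {
    "pure_E": np.array([1.0, 0.0, 0.0]),
    "pure_K": np.array([0.0, 0.0, 1.0]),
    "F1": np.array([0.0, 1.0, 0.0]),
    "F2": np.array([0.25, 0.5, 0.25]),
    "BC_E": np.array([0.5, 0.5, 0.0]),
    "BC_K": np.array([0.0, 0.5, 0.5]),
}


def q_thresholds(mode: str = "printed", n_diagnostic_loci: int = 3) -> tuple[float, float]:
    """Hybrid/parental Q cutoffs: conventional printed values or the midpoint formula."""
    if mode == "printed":
        return (0.1, 0.9)
    if mode == "formula":
        L = int(n_diagnostic_loci)
        if L < 1:
            raise ValueError("need at least one diagnostic locus")
        denom = 2 * L + 1
        return ((0 + 1 / denom) / 2, (1 + 2 * L / denom) / 2)
    raise ValueError("mode must be 'printed' or 'formula'")


@dataclass
class QClassification:
    label: str  # pure_E | hybrid | pure_K
    q: float
    thresholds: tuple[float, float]


def classify_by_q(
    q: float, n_diagnostic_loci: int = 3, mode: str = "printed"
) -> QClassification:
    """Threshold call from an admixture proportion q in [0, 1]."""
    q = float(q)
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    lo, hi = q_thresholds(mode, n_diagnostic_loci)
    label = "pure_E" if q < lo else ("pure_K" if q > hi else "hybrid")
    return QClassification(label=label, q=q, thresholds=(lo, hi))


@dataclass
class ClassPosterior:
    """Posterior over the six genotype-frequency classes."""

    probabilities: dict[str, float]
    loci_used: int

    def map_class(self) -> str:
        return max(self.probabilities, key=self.probabilities.get)


def genotype_class_posterior(
    nuclear_k_counts, prior=None
) -> ClassPosterior:
    """Closed-form class posterior from per-locus K-allele counts.

    ``nuclear_k_counts`` holds one entry per diploid diagnostic locus
    (0, 1, 2 or NaN for missing; missing loci are skipped). Classes whose
    likelihood is zero get posterior probability exactly 0.
    """
    k = np.asarray(nuclear_k_counts, dtype=float).ravel()
    scored = k[~np.isnan(k)]
    if scored.size == 0:
        raise ValueError("all loci missing: no posterior")
    if np.any((scored < 0) | (scored > 2) | (scored != np.round(scored))):
        raise ValueError("K-allele counts must be integers in {0, 1, 2}")
    if prior is None:
        prior = np.full(len(CLASSES), 1.0 / len(CLASSES))
    prior = np.asarray(prior, dtype=float).ravel()
    if prior.size != len(CLASSES) or abs(prior.sum() - 1.0) > 1e-9 or np.any(prior < 0):
        raise ValueError("prior must be a 6-vector of probabilities summing to 1")

    like = np.ones(len(CLASSES))
    for g in scored.astype(int):
        like *= np.array([CLASS_GENOTYPE_PROBS[c][g] for c in CLASSES])
    post = like * prior
    total = post.sum()
    if total == 0:
        raise ValueError("genotype impossible under every class")
    post /= total
    return ClassPosterior(
        probabilities={c: float(p) for c, p in zip(CLASSES, post)},
        loci_used=int(scored.size),
    )


class GenotypeClassClassifier(ClassifierMixin, BaseEstimator):
    """scikit-learn classifier over the six genotype-frequency classes.

    X is an (n_individuals, n_loci) matrix of per-locus K-allele counts
    (NaN = missing). Stateless apart from the prior: ``fit`` validates and
    records ``classes_``.
    """

    def __init__(self, prior=None):
        self.prior = prior

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (individuals x loci)")
        self.classes_ = np.array(CLASSES)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], len(CLASSES)))
        for i, row in enumerate(X):
            post = genotype_class_posterior(row, self.prior)
            out[i] = [post.probabilities[c] for c in CLASSES]
        return out

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]
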