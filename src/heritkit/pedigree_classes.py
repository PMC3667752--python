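"""Relationship-class heritability: correlation-based estimators per class.

For a class of relative pairs (siblings, first cousins, ...) the phenotypic
correlation across pairs, divided by the class's expected genome-wide IBD
fraction, estimates heritability: a first-cousin correlation is multiplied
by eight, a parent-offspring correlation by two.  No per-trait standard
error is attached — the pairs overlap through the wider pedigree — but
empirical means, standard deviations and confidence intervals can be taken
across traits, and classes compared by a Wald test on per-trait differences.

Comparing classes with equal expected IBD but different IBD2 or
cohabitation (e.g. half-siblings vs grandparent-grandchild) separates
additive genetics from dominance-like and shared-environment inflation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class RelationshipClass:
    name: str
    expected_ibd: float
    expected_ibd2: float

    def __post_init__(self):
        if not (0.0 <= self.expected_ibd2 <= self.expected_ibd <= 1.0):
            raise ValueError("need 0 <= expected_ibd2 <= expected_ibd <= 1")


SIBLING = RelationshipClass("sibling", 0.5, 0.25)
PARENT_OFFSPRING = RelationshipClass("parent-offspring", 0.5, 0.0)
HALF_SIBLING = RelationshipClass("half-sibling", 0.25, 0.0)
GRANDPARENT_GRANDCHILD = RelationshipClass("grandparent-grandchild", 0.25, 0.0)
AVUNCULAR = RelationshipClass("avuncular", 0.25, 0.0)
FIRST_COUSIN = RelationshipClass("first-cousin", 0.125, 0.0)
MZ_TWIN = RelationshipClass("MZ-twin", 1.0, 1.0)

CLASSES = {c.name: c for c in (SIBLING, PARENT_OFFSPRING, HALF_SIBLING,
                               GRANDPARENT_GRANDCHILD, AVUNCULAR,
                               FIRST_COUSIN, MZ_TWIN)}

# study-style minimum pair counts; violations warn, never fail
MIN_PAIRS_CONTINUOUS = 100
MIN_PAIRS_DICHOTOMOUS = 50


class UndefinedCorrelationError(ValueError):
    """Zero variance in one member position makes the correlation undefined."""


def class_h2(pairs, cls: RelationshipClass, min_pairs: int | None = None) -> float:
    """Heritability from the phenotypic correlation of one relative class.

    ``pairs`` is a sequence of (value_a, value_b) phenotype pairs, already
    residualized for covariates.  Each pair enters once in each order, so
    the Pearson correlation — and hence the estimate — is invariant to
    member labeling.  The estimate is the correlation divided by the class's
    expected IBD fraction; values above 1 are legal and flagged with a
    warning (dominance-like inflation, shared environment, or noise).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (a, b) phenotype pairs")
    if min_pairs is not None and arr.shape[0] < min_pairs:
        warnings.warn(f"only {arr.shape[0]} pairs for class {cls.name!r} "
                      f"(fewer than {min_pairs})", RuntimeWarning)
    a = np.concatenate([arr[:, 0], arr[:, 1]])  # symmetrized: both orders
    b = np.concatenate([arr[:, 1], arr[:, 0]])
    if a.std() == 0 or b.std() == 0:
        raise UndefinedCorrelationError(
            f"zero phenotype variance in class {cls.name!r}")
    r = float(np.corrcoef(a, b)[0, 1])
    est = r / cls.expected_ibd
    if est > 1.0:
        warnings.warn(f"class {cls.name!r} heritability estimate {est:.3f} "
                      "exceeds 1", RuntimeWarning)
    return est


def compare_classes(est_a: dict, est_b: dict) -> tuple[float, float, float]:
    """Wald test on per-trait differences between two classes' estimates.

    ``est_a`` and ``est_b`` map trait name -> class_h2 estimate and must
    cover the same traits.  Returns (mean difference, standard error =
    sd / sqrt(n_traits), two-sided normal p-value).
    """
    if set(est_a) != set(est_b):
        raise ValueError("trait sets differ between the two classes")
    traits = sorted(est_a)
    if len(traits) < 2:
        raise ValueError("need at least two traits to compare classes")
    d = np.array([est_a[t] - est_b[t] for t in traits])
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / np.sqrt(len(traits))
    if se == 0:
        if mean == 0:
            return 0.0, 0.0, 1.0
        warnings.warn("zero spread of differences; p-value at machine floor",
                      RuntimeWarning)
        return mean, 0.0, float(np.nextafter(0, 1))
    z = mean / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return mean, se, p


def class_average(estimates: dict) -> dict:
    """Cross-trait mean and normal-approximation 95% CI per class.

    ``estimates`` maps class name -> {trait -> estimate}; every class needs
    at least two traits.  Returns class name -> (mean, lo, hi).
    """
    out = {}
    for cls_name, per_trait in estimates.items():
        vals = np.array(list(per_trait.values()), dtype=float)
        if vals.size < 2:
            raise ValueError(f"class {cls_name!r} has fewer than two traits")
        mean = float(vals.mean())
        half = 1.959963984540054 * vals.std(ddof=1) / np.sqrt(vals.size)
        out[cls_name] = (mean, mean - half, mean + half)
    return out


def residualize(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of a linear fixed-effect fit (with intercept) of values on
    covariates; the covariate adjustment applied before pair correlations."""
    y = np.asarray(values, dtype=float)
    Z = np.column_stack([np.ones(y.size), np.atleast_2d(np.asarray(covariates, float).T).T])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return y - Z @ beta
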