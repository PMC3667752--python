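"""Named heritability estimators composed from kinship matrices and REML.

* Single-component estimates: narrow-sense h2 from an IBD matrix, or from a
  thresholded IBS matrix; SNP heritability h2_g from the full IBS matrix on
  data without close relatives.
* The joint two-component model: a close-relative matrix (thresholded IBS,
  or IBD directly) together with the full IBS matrix.  The parameter on the
  full IBS matrix is the heritability explained by genotyped SNPs; the sum
  of the two genetic proportions is the total narrow-sense heritability, so
  related individuals need not be removed.
* The ADE-style model: IBD plus IBD2 components.  The IBD2 parameter soaks
  up shared environment, dominance and epistasis collectively
  ("dominance-like"); a 1-df likelihood-ratio test against the IBD-only
  model assesses its significance.
* Observed-to-liability conversion for dichotomous traits, with the
  case-control ascertainment correction.

Dichotomous traits are fit as linear mixed models on their 0/1 values
(observed scale) and converted afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import PhenotypeTable, ValidationError
from .grm import KinshipMatrix, Kind, center_ibs
from .reml import MixedModelSpec, REMLFit, fit_reml, h2_from_fit, lrt

DEFAULT_THRESHOLD = 0.05  # conservative default for zeroing distant IBS entries


@dataclass
class HeritabilityReport:
    """Result of one heritability model fit."""

    model: str                       # IBD | IBS | IBS_THR | JOINT_THR_IBS | JOINT_IBD_IBS | ADE
    h2_total: float
    h2_total_se: float
    h2_g: float | None = None
    h2_g_se: float | None = None
    h2_dominance_like: float | None = None
    h2_dominance_like_se: float | None = None
    ratio_h2g_over_h2: float | None = None
    ratio_se: float | None = None
    scale: str = "observed"          # observed | liability
    liability_flag: str | None = None
    lrt_p: float | None = None
    fit: REMLFit | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "fit"}
        if self.fit is not None:
            d["sigma2"] = list(map(float, self.fit.sigma2))
            d["loglik_restricted"] = self.fit.loglik_restricted
            d["converged"] = self.fit.converged
            d["n_iter"] = self.fit.n_iter
        return d


# ---------------------------------------------------------------------------
# Design assembly
# ---------------------------------------------------------------------------


def build_design(pheno: PhenotypeTable, trait: str, covars: list[str],
                 ids: list[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Assemble (y, X, ids) aligned by identifier, dropping missing rows.

    Quantitative traits are standardized to mean 0, variance 1; dichotomous
    (only 0/1 values) traits are left on the observed 0/1 scale.  Numeric
    covariates enter directly, categorical ones are one-hot encoded against
    a first-level reference.  An intercept column is always included.
    """
    df = pheno.aligned(ids)
    cols = [trait] + list(covars)
    df = df[cols].dropna()
    kept = [str(i) for i in df.index]
    y = df[trait].to_numpy(dtype=float)
    uniq = np.unique(y)
    dichotomous = np.isin(uniq, (0.0, 1.0)).all()
    if not dichotomous:
        sd = y.std(ddof=1)
        if sd == 0:
            raise ValidationError(f"trait {trait!r} has zero variance")
        y = (y - y.mean()) / sd
    blocks = [np.ones((len(y), 1))]
    for c in covars:
        col = df[c]
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(col.to_numpy(dtype=float)[:, None])
        else:
            dummies = pd.get_dummies(col.astype("category"), drop_first=True)
            if dummies.shape[1]:
                blocks.append(dummies.to_numpy(dtype=float))
    X = np.hstack(blocks)
    return y, X, kept


def _prepare_ibs(K: KinshipMatrix, center: bool) -> KinshipMatrix:
    if center and K.kind in (Kind.IBS, Kind.IBS_THRESHOLDED) and not K.centered:
        return center_ibs(K)
    return K


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


def estimate_h2(pheno: PhenotypeTable, covars: list[str], K: KinshipMatrix,
                trait: str = "trait", constraint: bool = True,
                center: bool = True, tol: float = 1e-6,
                max_iter: int = 100) -> HeritabilityReport:
    """Single-component heritability: h2 from IBD or thresholded IBS, or the
    genotyped-SNP heritability h2_g from the full IBS matrix."""
    if K.kind not in (Kind.IBD, Kind.IBS, Kind.IBS_THRESHOLDED):
        raise ValidationError(f"unsupported matrix kind {K.kind.name}")
    y, X, ids = build_design(pheno, trait, covars, K.sample_ids)
    Ksub = _prepare_ibs(K.subset(ids), center)
    fit = fit_reml(MixedModelSpec(y, X, [Ksub], constraint=constraint),
                   tol=tol, max_iter=max_iter)
    (h2,), (se,) = h2_from_fit(fit)
    model = {"IBD": "IBD", "IBS": "IBS", "IBS_THRESHOLDED": "IBS_THR"}[K.kind.name]
    return HeritabilityReport(model=model, h2_total=float(h2),
                              h2_total_se=float(se), fit=fit)


def estimate_joint(pheno: PhenotypeTable, covars: list[str],
                   K_close: KinshipMatrix, K_ibs: KinshipMatrix,
                   trait: str = "trait", constraint: bool = True,
                   center: bool = True, tol: float = 1e-6,
                   max_iter: int = 100) -> HeritabilityReport:
    """Joint narrow-sense / SNP heritability from two components.

    ``K_close`` captures close relatives (thresholded IBS or IBD) and
    ``K_ibs`` is the full IBS matrix.  h2_g is the proportion on the full
    IBS component; the total narrow-sense heritability is the sum of both
    genetic proportions.
    """
    if K_close.kind not in (Kind.IBS_THRESHOLDED, Kind.IBD):
        raise ValidationError("close-relative component must be IBS_THRESHOLDED or IBD")
    if K_ibs.kind is not Kind.IBS:
        raise ValidationError("second component must be the full IBS matrix")
    if np.allclose(K_close.values, K_ibs.values):
        raise ValidationError("joint model components are identical (collinear)")
    y, X, ids = build_design(pheno, trait, covars, K_close.sample_ids)
    Kc = _prepare_ibs(K_close.subset(ids), center)
    Ki = _prepare_ibs(K_ibs.subset(ids), center)
    fit = fit_reml(MixedModelSpec(y, X, [Kc, Ki], constraint=constraint),
                   tol=tol, max_iter=max_iter)
    props, ses = h2_from_fit(fit)
    h2_g = float(props[1])
    h2_total = float(props.sum())
    # s.e. of the sum via the full proportion covariance (delta method)
    theta, S = fit.sigma2, float(fit.sigma2.sum())
    g = np.array([(S - theta[0] - theta[1]) / S ** 2,
                  (S - theta[0] - theta[1]) / S ** 2,
                  -(theta[0] + theta[1]) / S ** 2])
    se_total = float(np.sqrt(max(g @ fit.vc_cov @ g, 0.0)))
    ratio = h2_g / h2_total if h2_total > 0 else np.nan
    # delta method for the ratio theta1/(theta0+theta1)
    s12 = theta[0] + theta[1]
    if s12 > 0:
        gr = np.array([-theta[1] / s12 ** 2, theta[0] / s12 ** 2, 0.0])
        ratio_se = float(np.sqrt(max(gr @ fit.vc_cov @ gr, 0.0)))
    else:
        ratio_se = np.nan
    model = ("JOINT_IBD_IBS" if K_close.kind is Kind.IBD else "JOINT_THR_IBS")
    return HeritabilityReport(model=model, h2_total=h2_total,
                              h2_total_se=se_total, h2_g=h2_g,
                              h2_g_se=float(ses[1]),
                              ratio_h2g_over_h2=float(ratio),
                              ratio_se=ratio_se, fit=fit)


def fit_ade(pheno: PhenotypeTable, covars: list[str], K_ibd: KinshipMatrix,
            K_ibd2: KinshipMatrix, trait: str = "trait",
            constraint: bool = True, tol: float = 1e-6,
            max_iter: int = 100,
            boundary_mixture: bool = False) -> HeritabilityReport:
    """ADE-style fit: additive (IBD) plus dominance-like (IBD2) components.

    The dominance-like proportion aggregates shared environment, dominance
    and epistasis.  ``lrt_p`` is the 1-df likelihood-ratio p-value against
    the IBD-only model.
    """
    if K_ibd.kind is not Kind.IBD or K_ibd2.kind is not Kind.IBD2:
        raise ValidationError("components must be IBD and IBD2 matrices")
    y, X, ids = build_design(pheno, trait, covars, K_ibd.sample_ids)
    Ka = K_ibd.subset(ids)
    Kd = K_ibd2.subset(ids)
    if not (Kd.off_diagonal() > 0).any():
        warnings.warn("no pair shares IBD2 > 0; dominance-like component is "
                      "non-identifiable and pinned at 0", RuntimeWarning)
        null_rep = estimate_h2(pheno, covars, K_ibd, trait=trait,
                               constraint=constraint, tol=tol,
                               max_iter=max_iter)
        return HeritabilityReport(model="ADE", h2_total=null_rep.h2_total,
                                  h2_total_se=null_rep.h2_total_se,
                                  h2_dominance_like=0.0,
                                  h2_dominance_like_se=np.nan,
                                  lrt_p=1.0, fit=null_rep.fit)
    full = fit_reml(MixedModelSpec(y, X, [Ka, Kd], constraint=constraint),
                    tol=tol, max_iter=max_iter)
    null = fit_reml(MixedModelSpec(y, X, [Ka], constraint=constraint),
                    tol=tol, max_iter=max_iter)
    if full.loglik_restricted < null.loglik_restricted - 1e-8:
        # the full model can never sit below its nested null: warm-start a
        # refit from the null solution with a zeroed dominance-like term
        refit = fit_reml(MixedModelSpec(y, X, [Ka, Kd], constraint=constraint),
                         tol=tol, max_iter=max_iter,
                         init=np.array([null.sigma2[0], 0.0, null.sigma2[1]]))
        if refit.loglik_restricted > full.loglik_restricted:
            full = refit
    p = lrt(full, null, df=1, boundary_mixture=boundary_mixture)
    props, ses = h2_from_fit(full)
    return HeritabilityReport(model="ADE", h2_total=float(props[0]),
                              h2_total_se=float(ses[0]),
                              h2_dominance_like=float(props[1]),
                              h2_dominance_like_se=float(ses[1]),
                              lrt_p=p, fit=full)


# ---------------------------------------------------------------------------
# Liability scale
# ---------------------------------------------------------------------------


def observed_to_liability(h2_obs: float, prevalence: float,
                          case_fraction: float) -> float:
    """Convert an observed-scale (0/1) heritability to the liability scale.

    Under the normal threshold model with population prevalence K and
    in-sample case fraction P,

        h2_liab = h2_obs * [K(1-K)/z^2] * [K(1-K)/(P(1-P))],

    where z is the standard-normal density at the K-upper-tail threshold.
    The second factor is the case-control ascertainment correction; it is 1
    when P = K (random sampling).  Estimates from cohorts that ascertain
    affected relatives remain upper bounds: no correction exists for
    within-family ascertainment.
    """
    if not (0.0 < prevalence < 1.0 and 0.0 < case_fraction < 1.0):
        raise ValueError("prevalence and case_fraction must be in (0, 1)")
    if h2_obs < 0:
        warnings.warn("negative observed-scale h2 passed through the "
                      "liability conversion", RuntimeWarning)
    K, P = prevalence, case_fraction
    thresh = stats.norm.isf(K)
    z = stats.norm.pdf(thresh)
    return h2_obs * (K * (1 - K) / z ** 2) * (K * (1 - K) / (P * (1 - P)))


def estimate_prevalence(values) -> float:
    """Fraction of cases among non-missing 0/1 phenotype values."""
    v = pd.Series(values).dropna().to_numpy(dtype=float)
    if v.size == 0:
        raise ValueError("all phenotype values are missing")
    if not np.isin(np.unique(v), (0.0, 1.0)).all():
        raise ValueError("phenotype is not dichotomous 0/1")
    cases = int(v.sum())
    controls = v.size - cases
    if cases == 0 or controls == 0:
        raise ValueError("need at least one case and one control")
    return cases / v.size


def cohort_estimates(cohort, t: float = DEFAULT_THRESHOLD,
                     which: tuple = ("ibd", "ibs_thr", "ibs", "joint"),
                     prune_t: float = 0.025) -> dict:
    """All standard estimators on one simulated cohort.

    Builds the IBS matrix from the observed genotypes and the IBD matrix
    from the cohort's true pairwise table, then runs the requested
    single-component and joint fits.  ``pruned`` estimates SNP heritability
    the classical way: drop one member of every pair with IBS relatedness
    above ``prune_t`` and fit the full IBS matrix on the remainder.

    Returns a flat dict of heritability point estimates.
    """
    from .grm import build_ibd as _build_ibd
    from .grm import build_ibs as _build_ibs
    from .grm import threshold_ibs as _threshold

    out: dict[str, float] = {}
    pheno = cohort.phenotype
    need_ibs = {"ibs", "ibs_thr", "joint", "pruned"} & set(which)
    K_ibs = _build_ibs(cohort.observed) if need_ibs else None
    if "ibd" in which or "joint_ibd" in which:
        K_ibd = _build_ibd(cohort.true_ibd, cohort.sample_ids)
    if "ibd" in which:
        out["h2_ibd"] = estimate_h2(pheno, [], K_ibd).h2_total
    if "ibs" in which:
        out["h2_ibs"] = estimate_h2(pheno, [], K_ibs).h2_total
    if "ibs_thr" in which:
        K_thr = _threshold(K_ibs, t)
        out["h2_ibs_thr"] = estimate_h2(pheno, [], K_thr).h2_total
    if "joint" in which:
        K_thr = _threshold(K_ibs, t)
        rep = estimate_joint(pheno, [], K_thr, K_ibs)
        out["joint_h2"] = rep.h2_total
        out["joint_h2_g"] = rep.h2_g
        out["joint_ratio"] = rep.ratio_h2g_over_h2
    if "joint_ibd" in which:
        rep = estimate_joint(pheno, [], K_ibd, K_ibs)
        out["joint_ibd_h2"] = rep.h2_total
        out["joint_ibd_h2_g"] = rep.h2_g
    if "pruned" in which:
        # drop one member of every truly related pair (relatedness above
        # prune_t), then fit the full IBS matrix on the remainder — the
        # classical unrelated-only estimate of SNP heritability.  Pruning on
        # the measured IBS matrix instead is only meaningful when its
        # per-pair noise (sd ~ 1/sqrt(N_SNPs)) is well below the threshold.
        keep = set(cohort.sample_ids)
        for key, (ibd, _) in cohort.true_ibd.pairs.items():
            if ibd > prune_t:
                a, b = sorted(key)
                if a in keep and b in keep:
                    keep.discard(b)
        kept = [s for s in cohort.sample_ids if s in keep]
        sub = cohort.observed.subset_samples(kept)
        K_sub = _build_ibs(sub)  # frequencies recomputed after subsetting
        ptab = PhenotypeTable(pheno.data.loc[kept])
        out["pruned_h2_g"] = estimate_h2(ptab, [], K_sub).h2_total
        out["pruned_n"] = float(len(kept))
    return out


def report_on_liability(report: HeritabilityReport, prevalence: float,
                        case_fraction: float) -> HeritabilityReport:
    """Re-express a report's components on the liability scale.

    Only the SNP-heritability component receives the full case-control
    ascertainment correction; total-h2 figures from models leaning on close
    relatives are flagged as upper bounds, since family-based ascertainment
    cannot be corrected.
    """
    mult_full = observed_to_liability(1.0, prevalence, case_fraction)
    out = HeritabilityReport(**{k: v for k, v in report.__dict__.items()})
    out.scale = "liability"
    out.h2_total = report.h2_total * mult_full
    out.h2_total_se = report.h2_total_se * mult_full
    if report.h2_g is not None:
        out.h2_g = report.h2_g * mult_full
        out.h2_g_se = report.h2_g_se * mult_full
    if report.h2_dominance_like is not None:
        out.h2_dominance_like = report.h2_dominance_like * mult_full
        out.h2_dominance_like_se = report.h2_dominance_like_se * mult_full
    if report.model != "IBS":
        out.liability_flag = "upper bound (family ascertainment uncorrected)"
    return out
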