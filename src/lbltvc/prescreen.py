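"""Single-SNP logistic screen and 5-SNP block construction.

Each SNP is tested one at a time at the first examination with

    logit P(Y1 = 1) = b0 + b1*SNP + b2*SMOKE1 + b3*AGE1 + b4*SEX,

the SNP coded additively as 0/1/2 minor-allele copies, and a 1-df
likelihood-ratio chi-square comparing the model with and without the SNP
term.  The SNPs with the smallest p-values anchor 5-SNP haplotype blocks
(two flanking SNPs on each side, the window shifted inward at gene edges).
This is a computational screen to pick blocks for the main analysis, so no
multiplicity correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .data_io import Cohort, GenotypeTable


@dataclass
class PrescreenFit:
    snp_id: str
    coefficients: np.ndarray | None   # (5,) b0..b4 when fitted
    lrt: float
    df: int
    p_value: float
    skipped: bool = False
    separation: bool = False


@dataclass
class Block:
    anchor: str
    snp_ids: list[str]
    bp_span: tuple[int, int] | None = None

    def __post_init__(self):
        if len(self.snp_ids) != 5:
            raise ValueError("a block holds exactly 5 SNPs")


def additive_coding(genotypes: GenotypeTable, snp_id: str) -> np.ndarray:
    """0/1/2 minor-allele copies per individual (np.nan when missing)."""
    s = genotypes.snp_ids.index(snp_id)
    calls = [row[s] for row in genotypes.genotypes]
    alleles = [a for pair in calls for a in pair if a != "0"]
    if not alleles:
        return np.full(len(calls), np.nan)
    uniq, counts = np.unique(alleles, return_counts=True)
    minor = uniq[np.argmin(counts)] if len(uniq) > 1 else uniq[0]
    out = np.array([np.nan if a == "0" else (a == minor) + (b == minor)
                    for a, b in calls], dtype=float)
    return out


def first_exam_frame(cohort: Cohort) -> pd.DataFrame:
    df = cohort.phenotypes.df
    return df.loc[df.groupby("id")["exam"].idxmin()].set_index("id")


def _logit_loglik(X: np.ndarray, y: np.ndarray, ridge: float = 0.0
                  ) -> tuple[np.ndarray, float]:
    if ridge > 0:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
            alpha=ridge, L1_wt=0.0)
    else:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    return np.asarray(res.params), float(sm.Logit(y, X).loglike(res.params))


def fit_single_snp(cohort: Cohort, snp_id: str) -> PrescreenFit:
    """Additive logistic fit of one SNP at the first exam, LRT p-value."""
    snp = additive_coding(cohort.genotypes, snp_id)
    fe = first_exam_frame(cohort)
    order = {ind: i for i, ind in enumerate(cohort.genotypes.individual_ids)}
    fe = fe.loc[sorted(fe.index, key=order.get)]
    snp = snp[[order[i] for i in fe.index]]
    y = fe["y"].to_numpy(float)
    covars = np.column_stack([np.ones(len(fe)), snp,
                              fe["smoke"].to_numpy(float),
                              fe["age"].to_numpy(float),
                              fe["sex"].to_numpy(float)])
    ok = ~np.isnan(snp)
    covars, y = covars[ok], y[ok]
    if np.nanstd(covars[:, 1]) == 0:
        warnings.warn(f"SNP {snp_id} is monomorphic; screen skipped")
        return PrescreenFit(snp_id=snp_id, coefficients=None, lrt=0.0, df=1,
                            p_value=1.0, skipped=True)
    X_null = np.delete(covars, 1, axis=1)
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params, ll_full = _logit_loglik(covars, y)
            _, ll_null = _logit_loglik(X_null, y)
        if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 15:
            raise ValueError("separation suspected")
    except Exception:
        separation = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params, ll_full = _logit_loglik(covars, y, ridge=1e-3)
            _, ll_null = _logit_loglik(X_null, y, ridge=1e-3)
    lrt = max(2.0 * (ll_full - ll_null), 0.0)
    return PrescreenFit(snp_id=snp_id, coefficients=params, lrt=lrt, df=1,
                        p_value=float(chi2.sf(lrt, df=1)),
                        separation=separation)


def prescreen_all(cohort: Cohort) -> list[PrescreenFit]:
    return [fit_single_snp(cohort, s) for s in cohort.genotypes.snp_ids]


def select_anchors(fits: list[PrescreenFit], k: int,
                   positions: dict[str, int] | None = None) -> list[str]:
    """The k smallest-p SNPs; ties broken by smaller bp position."""
    if not fits:
        raise ValueError("no fits")
    if k > len(fits):
        raise ValueError(f"k={k} exceeds the {len(fits)} fitted SNPs")
    pos = positions or {f.snp_id: i for i, f in enumerate(fits)}
    ranked = sorted(fits, key=lambda f: (f.p_value, pos[f.snp_id]))
    return [f.snp_id for f in ranked[:k]]


def build_block(snp_list: list[str], anchor: str,
                positions: dict[str, int] | None = None) -> Block:
    """5 contiguous SNPs centered on the anchor; window shifts inward at edges."""
    if len(snp_list) < 5:
        raise ValueError("need at least 5 SNPs to form a block")
    if anchor not in snp_list:
        raise ValueError(f"anchor {anchor!r} not in the SNP list")
    i = snp_list.index(anchor)
    start = min(max(i - 2, 0), len(snp_list) - 5)
    ids = snp_list[start:start + 5]
    span = None
    if positions is not None:
        span = (positions[ids[0]], positions[ids[-1]])
    return Block(anchor=anchor, snp_ids=ids, bp_span=span)


def prescreen_table(fits: list[PrescreenFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"snp": f.snp_id,
          "beta": f.coefficients[1] if f.coefficients is not None else np.nan,
          "lrt": f.lrt, "p": f.p_value, "skipped": f.skipped,
          "separation": f.separation} for f in fits])
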