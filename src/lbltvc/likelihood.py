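"""Design construction and the complete-data prospective log-likelihood.

The per-record log-odds of affection is

    eta = beta0 + sum_h X_h[h] * (sum_l beta_hl B_l(t))
          + beta_E X_E(t) + sum_h beta_Eh[h] X_h[h] X_E(t) + beta_s X_s,

where X_h counts copies of each non-reference haplotype in the latent
diplotype Z, B_l is the age spline basis, X_E(t) is smoking status at the
exam and X_s is sex.  The complete-data log-likelihood over records (i, j)
given a diplotype assignment is

    sum_ij [ y_ij eta_ij - log(1 + exp(eta_ij)) ] + sum_i log P(Z_i | f, d).

The smoking- and sex-marginal factors of the full prospective likelihood
carry no shared parameters and are dropped as constants.  log(1 + exp) is
evaluated via logaddexp, stable for |eta| up to ~700.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .haplotypes import Diplotype, FrequencyModel, diplotype_probability
from .splines import SplineBasis


@dataclass
class ParameterState:
    """Full parameter collection for one posterior draw.

    ``spline_coeffs`` has one row of ``n_basis`` coefficients per
    non-reference haplotype (reference effects are absorbed by ``beta0``).
    """

    beta0: float
    spline_coeffs: np.ndarray          # (m-1, n_basis)
    beta_smoke: float
    beta_interaction: np.ndarray       # (m-1,)
    beta_sex: float
    freq_model: FrequencyModel
    intensity: float = 1.0             # shared Laplace rate

    def __post_init__(self):
        self.spline_coeffs = np.atleast_2d(np.asarray(self.spline_coeffs, float))
        self.beta_interaction = np.asarray(self.beta_interaction, float)
        m1 = self.freq_model.m - 1
        if self.spline_coeffs.shape[0] != m1 or self.beta_interaction.size != m1:
            raise ValueError("coefficient blocks inconsistent with the "
                             "number of non-reference haplotypes")

    @property
    def penalized_coefficients(self) -> np.ndarray:
        """All coefficients under the Laplace shrinkage prior (not beta0)."""
        return np.concatenate([self.spline_coeffs.ravel(),
                               [self.beta_smoke], self.beta_interaction,
                               [self.beta_sex]])


@dataclass
class DesignRow:
    """Covariates for one (individual, exam) record under one diplotype."""

    hap_copies: np.ndarray   # (m-1,) copies of each non-reference haplotype
    smoke: int
    sex: int
    age: float

    @property
    def interaction(self) -> np.ndarray:
        return self.hap_copies * self.smoke


def hap_copy_vector(dip: Diplotype, m: int, reference: int) -> np.ndarray:
    """Copies of each non-reference haplotype in a diplotype.

    Non-reference haplotypes keep their model order with the reference
    removed; a reference homozygote maps to the zero vector and total copies
    over all haplotypes (including the reference) always equal 2.
    """
    counts = np.zeros(m)
    counts[dip.k] += 1
    counts[dip.kp] += 1
    return np.delete(counts, reference)


def build_design_row(dip: Diplotype, exam: dict, freq_model: FrequencyModel,
                     reference: int) -> DesignRow:
    return DesignRow(
        hap_copies=hap_copy_vector(dip, freq_model.m, reference),
        smoke=int(exam["smoke"]), sex=int(exam["sex"]),
        age=float(exam["age"]))


def log_odds(params: ParameterState, row: DesignRow,
             basis: SplineBasis) -> float:
    """Per-record log-odds eta under one parameter state."""
    b = basis.evaluate(row.age)
    hap_effects = params.spline_coeffs @ b          # (m-1,)
    return float(params.beta0
                 + row.hap_copies @ hap_effects
                 + params.beta_smoke * row.smoke
                 + params.beta_interaction @ row.interaction
                 + params.beta_sex * row.sex)


def bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Stable per-record log P(y | eta) = y*eta - log(1 + e^eta)."""
    return y * eta - np.logaddexp(0.0, eta)


@dataclass
class ModelData:
    """Flattened per-record arrays plus the precomputed spline basis matrix.

    The basis matrix depends only on ages, so it is computed once; every
    likelihood evaluation during sampling is then pure linear algebra.
    """

    y: np.ndarray        # (N,)
    smoke: np.ndarray    # (N,)
    sex: np.ndarray      # (N,)
    age: np.ndarray      # (N,)
    indiv: np.ndarray    # (N,) individual index per record
    n_indiv: int
    basis: SplineBasis
    basis_matrix: np.ndarray = field(init=False)

    def __post_init__(self):
        self.basis_matrix = self.basis.evaluate(self.age)

    @classmethod
    def from_cohort(cls, cohort, basis: SplineBasis) -> "ModelData":
        df = cohort.phenotypes.df
        order = {ind: i for i, ind in enumerate(cohort.genotypes.individual_ids)}
        indiv = df["id"].map(order).to_numpy()
        return cls(y=df["y"].to_numpy(float), smoke=df["smoke"].to_numpy(float),
                   sex=df["sex"].to_numpy(float), age=df["age"].to_numpy(float),
                   indiv=indiv, n_indiv=len(order), basis=basis)


def linear_predictor(params: ParameterState, data: ModelData,
                     hap_counts: np.ndarray) -> np.ndarray:
    """Vectorized eta for all records; ``hap_counts`` is (n_indiv, m-1)."""
    hap_t = data.basis_matrix @ params.spline_coeffs.T      # (N, m-1)
    X = hap_counts[data.indiv]                              # (N, m-1)
    return (params.beta0
            + np.einsum("nh,nh->n", X, hap_t)
            + params.beta_smoke * data.smoke
            + (X @ params.beta_interaction) * data.smoke
            + params.beta_sex * data.sex)


def complete_data_loglik(params: ParameterState, data: ModelData,
                         assignment: list[Diplotype], reference: int,
                         supports: list[list[Diplotype]] | None = None,
                         ) -> float:
    """Phenotype log-likelihood plus the latent-diplotype log-probability.

    ``assignment`` gives one diplotype per individual; if ``supports`` is
    given, each assigned diplotype must belong to the individual's support.
    """
    if len(assignment) != data.n_indiv:
        raise ValueError("one diplotype per individual is required")
    if supports is not None:
        for i, (dip, sup) in enumerate(zip(assignment, supports)):
            if dip not in sup:
                raise ValueError(f"individual {i}: assigned diplotype not in support")
    m = params.freq_model.m
    hap_counts = np.stack([hap_copy_vector(d, m, reference) for d in assignment])
    eta = linear_predictor(params, data, hap_counts)
    ll = float(bernoulli_loglik(data.y, eta).sum())
    ll += sum(np.log(diplotype_probability(params.freq_model, d))
              for d in assignment)
    return ll
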