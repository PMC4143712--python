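"""Posterior sampling for the time-varying-coefficient haplotype model.

Every penalized regression coefficient (spline coefficients, smoking, sex,
haplotype-smoking interactions) carries a double-exponential (Laplace) prior
centered at 0 whose shared intensity has a Gamma(a, b) hyperprior — the
Bayesian-LASSO shrinkage that lets rare-haplotype effects survive while noise
coefficients collapse toward zero.  The intercept gets a diffuse normal
prior; haplotype frequencies a flat Dirichlet; the inbreeding coefficient a
flat prior over the range where every diplotype probability stays
nonnegative.

Latent diplotypes are the only Gibbs-updatable block: each individual's Z is
drawn from its exact full conditional over the (precomputed, finite) support.
All continuous blocks move by random-walk Metropolis-Hastings — Gaussian
walks for coefficient blocks, a stick-breaking-logit walk for the frequency
simplex, a reflected walk for the inbreeding coefficient, and a log-scale
walk for the Laplace intensity.  Proposal scales are adapted toward a target
acceptance rate during burn-in only, then frozen, preserving detailed
balance for the retained draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

from .config import MCMCSettings, PriorSpec
from .haplotypes import (Diplotype, DiplotypeSupport, FrequencyModel,
                         d_lower_bound, diplotype_log_probabilities)
from .likelihood import ModelData, ParameterState, bernoulli_loglik

D_EPS = 1e-8


def log_prior(prior: PriorSpec, params: ParameterState) -> float:
    """Joint log-prior density of a parameter state (intensity included)."""
    lam = params.intensity
    if lam <= 0:
        return -math.inf
    beta = params.penalized_coefficients
    lp = beta.size * math.log(lam / 2.0) - lam * np.abs(beta).sum()
    lp += (-0.5 * (params.beta0 / prior.beta0_sd) ** 2
           - math.log(prior.beta0_sd) - 0.5 * math.log(2 * math.pi))
    a, b = prior.gamma_shape, prior.gamma_rate
    lp += a * math.log(b) - gammaln(a) + (a - 1) * math.log(lam) - b * lam
    fm = params.freq_model
    # flat Dirichlet(1,...,1): just its normalizing constant
    lp += gammaln(fm.m)
    if not (d_lower_bound(fm.f) <= fm.d < 1.0):
        return -math.inf
    return float(lp)


def random_walk_metropolis(log_target, x0: float, scale: float, n: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Scalar Gaussian random-walk Metropolis chain for an arbitrary target."""
    x = float(x0)
    lp = log_target(x)
    out = np.empty(n)
    for i in range(n):
        prop = x + scale * rng.standard_normal()
        lp_prop = log_target(prop)
        if math.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
        out[i] = x
    return out


def _stick_to_simplex(v: np.ndarray) -> tuple[np.ndarray, float]:
    """Map unconstrained stick-breaking logits to the simplex; return (f, log|J|)."""
    z = expit(v)
    f = np.empty(v.size + 1)
    rest = 1.0
    logj = 0.0
    for i, zi in enumerate(z):
        f[i] = zi * rest
        logj += math.log(max(zi, 1e-300)) + math.log(max(1 - zi, 1e-300)) \
            + math.log(max(rest, 1e-300))
        rest *= (1 - zi)
    f[-1] = rest
    return f, logj


def _simplex_to_stick(f: np.ndarray) -> np.ndarray:
    v = np.empty(f.size - 1)
    rest = 1.0
    for i in range(f.size - 1):
        z = min(max(f[i] / rest, 1e-12), 1 - 1e-12)
        v[i] = math.log(z / (1 - z))
        rest *= (1 - z)
    return v


def _reflect(x: float, lo: float, hi: float) -> float:
    width = hi - lo
    if width <= 0:
        return lo
    y = (x - lo) % (2 * width)
    return lo + (y if y <= width else 2 * width - y)


@dataclass
class ChainOutput:
    """Post-burn-in draws plus bookkeeping for one chain."""

    haplotypes: list[str]
    reference: int
    n_basis: int
    beta0: np.ndarray                 # (S,)
    spline_coeffs: np.ndarray         # (S, m-1, n_basis)
    beta_smoke: np.ndarray            # (S,)
    beta_interaction: np.ndarray      # (S, m-1)
    beta_sex: np.ndarray              # (S,)
    f: np.ndarray                     # (S, m)
    d: np.ndarray                     # (S,)
    intensity: np.ndarray             # (S,)
    assignments: np.ndarray           # (S, n_indiv) candidate index
    acceptance_rates: dict[str, float]
    settings: MCMCSettings = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.beta0.size

    def nonreference_haplotypes(self) -> list[str]:
        return [h for i, h in enumerate(self.haplotypes) if i != self.reference]

    def to_dataframe(self):
        import pandas as pd
        cols = {"beta0": self.beta0, "beta_smoke": self.beta_smoke,
                "beta_sex": self.beta_sex, "d": self.d,
                "intensity": self.intensity}
        for hi, h in enumerate(self.nonreference_haplotypes()):
            for l in range(self.n_basis):
                cols[f"b[{h},{l}]"] = self.spline_coeffs[:, hi, l]
            cols[f"b_int[{h}]"] = self.beta_interaction[:, hi]
        for k, h in enumerate(self.haplotypes):
            cols[f"f[{h}]"] = self.f[:, k]
        return pd.DataFrame(cols)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via the initial positive sequence of autocorrelations."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1))
    acf /= acf[0]
    s = 0.0
    for k in range(1, n // 2):
        pair = acf[2 * k - 1] + acf[2 * k] if 2 * k < n else acf[2 * k - 1]
        if pair < 0:
            break
        s += pair
    return float(n / (1 + 2 * s))


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain means."""
    x = np.asarray(x, dtype=float)
    n = x.size
    a, b = x[: int(first * n)], x[int((1 - last) * n):]
    va = np.var(a) / max(effective_sample_size(a), 1.0)
    vb = np.var(b) / max(effective_sample_size(b), 1.0)
    denom = math.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


class Sampler:
    """MCMC sampler bound to one dataset, support structure and config."""

    def __init__(self, data: ModelData, support: DiplotypeSupport,
                 freq_start: FrequencyModel, settings: MCMCSettings,
                 prior: PriorSpec, reference: int | None = None):
        self.data = data
        self.support = support
        self.settings = settings
        self.prior = prior
        self.haplotypes = support.haplotypes
        self.m = len(self.haplotypes)
        if reference is None:
            reference = int(np.argmax(freq_start.f))
        self.reference = reference
        self.n_basis = data.basis.n_basis
        self.rng = np.random.default_rng(settings.seed)
        self._build_candidates()
        self._init_state(freq_start)
        self._init_blocks()

    # -- static candidate structures -------------------------------------
    def _build_candidates(self):
        sups = self.support.supports
        n = len(sups)
        sizes = [len(s) for s in sups]
        self.cand_offsets = np.concatenate([[0], np.cumsum(sizes)])
        self.cand_k = np.array([d.k for s in sups for d in s])
        self.cand_kp = np.array([d.kp for s in sups for d in s])
        self.cand_indiv = np.repeat(np.arange(n), sizes)
        K = self.cand_k.size
        counts = np.zeros((K, self.m))
        np.add.at(counts, (np.arange(K), self.cand_k), 1.0)
        np.add.at(counts, (np.arange(K), self.cand_kp), 1.0)
        self.cand_counts = np.delete(counts, self.reference, axis=1)  # (K, m-1)
        # expand candidates over their individuals' records
        rec_by_indiv = [np.flatnonzero(self.data.indiv == i) for i in range(n)]
        rc_rec, rc_cand = [], []
        for c in range(K):
            recs = rec_by_indiv[self.cand_indiv[c]]
            rc_rec.append(recs)
            rc_cand.append(np.full(recs.size, c))
        self.rc_rec = np.concatenate(rc_rec)
        self.rc_cand = np.concatenate(rc_cand)
        self.K = K

    def _init_state(self, freq_start: FrequencyModel):
        data, m1 = self.data, self.m - 1
        self.f = freq_start.f.copy()
        self.d = 0.0
        self.lam = (self.prior.gamma_shape / self.prior.gamma_rate
                    if self.settings.update_intensity
                    else self.settings.fixed_intensity)
        self.beta0 = 0.0
        if self.settings.likelihood_enabled and data.y.size:
            prev = min(max(float(data.y.mean()), 0.02), 0.98)
            self.beta0 = math.log(prev / (1 - prev))
        self.Bh = np.zeros((m1, self.n_basis))
        self.betaE = 0.0
        self.betaEh = np.zeros(m1)
        self.betaS = 0.0
        # start each individual at its most probable diplotype
        logp = diplotype_log_probabilities(self.f, self.d,
                                           self.cand_k, self.cand_kp)
        self.assign = np.array(
            [self.cand_offsets[i]
             + int(np.argmax(logp[self.cand_offsets[i]:self.cand_offsets[i + 1]]))
             for i in range(self.data.n_indiv)])
        self._refresh_caches()

    def _init_blocks(self):
        names = ["beta0"] + [f"spline_{h}" for h in range(self.m - 1)]
        names += ["beta_smoke", "beta_interaction", "beta_sex"]
        if self.settings.update_frequencies and self.m > 1:
            names.append("frequencies")
        if self.settings.update_inbreeding:
            names.append("inbreeding")
        if self.settings.update_intensity:
            names.append("intensity")
        self.block_names = names
        s0 = self.settings.initial_scale
        self.scales = {n: s0 for n in names}
        self.acc = {n: 0 for n in names}
        self.tries = {n: 0 for n in names}
        self.acc_window = {n: [0, 0] for n in names}

    # -- cached posterior pieces -----------------------------------------
    def _eta(self, beta0, Bh, betaE, betaEh, betaS) -> np.ndarray:
        X = self.cand_counts[self.assign][self.data.indiv]    # (N, m-1)
        hap_t = self.data.basis_matrix @ Bh.T                 # (N, m-1)
        return (beta0 + np.einsum("nh,nh->n", X, hap_t)
                + betaE * self.data.smoke
                + (X @ betaEh) * self.data.smoke
                + betaS * self.data.sex)

    def _pheno_ll(self, beta0=None, Bh=None, betaE=None, betaEh=None,
                  betaS=None) -> float:
        if not self.settings.likelihood_enabled:
            return 0.0
        eta = self._eta(self.beta0 if beta0 is None else beta0,
                        self.Bh if Bh is None else Bh,
                        self.betaE if betaE is None else betaE,
                        self.betaEh if betaEh is None else betaEh,
                        self.betaS if betaS is None else betaS)
        return float(bernoulli_loglik(self.data.y, eta).sum())

    def _z_logprob(self, f=None, d=None) -> float:
        f = self.f if f is None else f
        d = self.d if d is None else d
        lp = diplotype_log_probabilities(f, d, self.cand_k[self.assign],
                                         self.cand_kp[self.assign])
        return float(lp.sum())

    def _refresh_caches(self):
        self.ll_pheno = self._pheno_ll()
        self.ll_z = self._z_logprob()

    def _penalized(self) -> np.ndarray:
        return np.concatenate([self.Bh.ravel(), [self.betaE], self.betaEh,
                               [self.betaS]])

    # -- Gibbs update of latent diplotypes -------------------------------
    def gibbs_update_diplotypes(self) -> None:
        """Draw each individual's diplotype from its exact full conditional."""
        w = diplotype_log_probabilities(self.f, self.d, self.cand_k, self.cand_kp)
        if self.settings.likelihood_enabled:
            hap_t = self.data.basis_matrix @ self.Bh.T
            base = (self.beta0 + self.betaE * self.data.smoke
                    + self.betaS * self.data.sex)
            Xrc = self.cand_counts[self.rc_cand]
            eta_rc = (base[self.rc_rec]
                      + np.einsum("rh,rh->r", Xrc, hap_t[self.rc_rec])
                      + (Xrc @ self.betaEh) * self.data.smoke[self.rc_rec])
            ll_rc = bernoulli_loglik(self.data.y[self.rc_rec], eta_rc)
            w = w + np.bincount(self.rc_cand, ll_rc, minlength=self.K)
        gumbel = -np.log(-np.log(self.rng.random(self.K)))
        pert = w + gumbel
        seg_max = np.maximum.reduceat(pert, self.cand_offsets[:-1])
        hit = pert == seg_max[self.cand_indiv]
        idx = np.flatnonzero(hit)
        first = idx[np.unique(self.cand_indiv[idx], return_index=True)[1]]
        self.assign = first
        self._refresh_caches()

    def gibbs_full_conditionals(self) -> list[np.ndarray]:
        """Exact per-individual sampling probabilities (for verification)."""
        w = diplotype_log_probabilities(self.f, self.d, self.cand_k, self.cand_kp)
        if self.settings.likelihood_enabled:
            hap_t = self.data.basis_matrix @ self.Bh.T
            base = (self.beta0 + self.betaE * self.data.smoke
                    + self.betaS * self.data.sex)
            Xrc = self.cand_counts[self.rc_cand]
            eta_rc = (base[self.rc_rec]
                      + np.einsum("rh,rh->r", Xrc, hap_t[self.rc_rec])
                      + (Xrc @ self.betaEh) * self.data.smoke[self.rc_rec])
            ll_rc = bernoulli_loglik(self.data.y[self.rc_rec], eta_rc)
            w = w + np.bincount(self.rc_cand, ll_rc, minlength=self.K)
        out = []
        for i in range(self.data.n_indiv):
            wi = w[self.cand_offsets[i]:self.cand_offsets[i + 1]]
            wi = np.exp(wi - wi.max())
            out.append(wi / wi.sum())
        return out

    # -- MH block updates -------------------------------------------------
    def _accept(self, name: str, log_ratio: float) -> bool:
        self.tries[name] += 1
        self.acc_window[name][1] += 1
        ok = math.log(self.rng.random()) < log_ratio
        if ok:
            self.acc[name] += 1
            self.acc_window[name][0] += 1
        return ok

    def mh_update_block(self, name: str) -> bool:
        scale = self.scales[name]
        if name == "beta0":
            prop = self.beta0 + scale * self.rng.standard_normal()
            ll = self._pheno_ll(beta0=prop)
            sd = self.prior.beta0_sd
            dprior = -0.5 * (prop ** 2 - self.beta0 ** 2) / sd ** 2
            if self._accept(name, ll - self.ll_pheno + dprior):
                self.beta0, self.ll_pheno = prop, ll
                return True
            return False
        if name.startswith("spline_"):
            h = int(name.split("_")[1])
            Bh = self.Bh.copy()
            Bh[h] = Bh[h] + scale * self.rng.standard_normal(self.n_basis)
            ll = self._pheno_ll(Bh=Bh)
            dprior = -self.lam * (np.abs(Bh[h]).sum() - np.abs(self.Bh[h]).sum())
            if self._accept(name, ll - self.ll_pheno + dprior):
                self.Bh, self.ll_pheno = Bh, ll
                return True
            return False
        if name == "beta_smoke":
            prop = self.betaE + scale * self.rng.standard_normal()
            ll = self._pheno_ll(betaE=prop)
            dprior = -self.lam * (abs(prop) - abs(self.betaE))
            if self._accept(name, ll - self.ll_pheno + dprior):
                self.betaE, self.ll_pheno = prop, ll
                return True
            return False
        if name == "beta_interaction":
            prop = self.betaEh + scale * self.rng.standard_normal(self.m - 1)
            ll = self._pheno_ll(betaEh=prop)
            dprior = -self.lam * (np.abs(prop).sum() - np.abs(self.betaEh).sum())
            if self._accept(name, ll - self.ll_pheno + dprior):
                self.betaEh, self.ll_pheno = prop, ll
                return True
            return False
        if name == "beta_sex":
            prop = self.betaS + scale * self.rng.standard_normal()
            ll = self._pheno_ll(betaS=prop)
            dprior = -self.lam * (abs(prop) - abs(self.betaS))
            if self._accept(name, ll - self.ll_pheno + dprior):
                self.betaS, self.ll_pheno = prop, ll
                return True
            return False
        if name == "frequencies":
            v = _simplex_to_stick(self.f)
            _, logj_cur = _stick_to_simplex(v)
            v_prop = v + scale * self.rng.standard_normal(v.size)
            f_prop, logj_prop = _stick_to_simplex(v_prop)
            if np.any(f_prop <= 0) or not (
                    d_lower_bound(f_prop) + D_EPS <= self.d < 1.0 - D_EPS):
                self._accept(name, -math.inf)
                return False
            ll_z = self._z_logprob(f=f_prop)
            if self._accept(name, ll_z - self.ll_z + logj_prop - logj_cur):
                self.f, self.ll_z = f_prop, ll_z
                return True
            return False
        if name == "inbreeding":
            lo = d_lower_bound(self.f) + D_EPS
            hi = 1.0 - D_EPS
            prop = _reflect(self.d + scale * self.rng.standard_normal(), lo, hi)
            ll_z = self._z_logprob(d=prop)
            if self._accept(name, ll_z - self.ll_z):
                self.d, self.ll_z = prop, ll_z
                return True
            return False
        if name == "intensity":
            prop = self.lam * math.exp(scale * self.rng.standard_normal())
            beta_abs = np.abs(self._penalized()).sum()
            p = self._penalized().size
            a, b = self.prior.gamma_shape, self.prior.gamma_rate
            cur = (p * math.log(self.lam) - self.lam * beta_abs
                   + (a - 1) * math.log(self.lam) - b * self.lam)
            new = (p * math.log(prop) - prop * beta_abs
                   + (a - 1) * math.log(prop) - b * prop)
            # log-scale walk Jacobian
            if self._accept(name, new - cur + math.log(prop) - math.log(self.lam)):
                self.lam = prop
                return True
            return False
        raise KeyError(f"unknown block {name!r}")

    def _adapt(self):
        for name, (a, t) in self.acc_window.items():
            if t == 0:
                continue
            rate = a / t
            self.scales[name] *= math.exp(0.5 * (rate - self.settings.target_acceptance))
            self.scales[name] = min(max(self.scales[name], 1e-4), 50.0)
            self.acc_window[name] = [0, 0]

    def current_state(self) -> ParameterState:
        return ParameterState(
            beta0=self.beta0, spline_coeffs=self.Bh.copy(),
            beta_smoke=self.betaE, beta_interaction=self.betaEh.copy(),
            beta_sex=self.betaS,
            freq_model=FrequencyModel(list(self.haplotypes), self.f.copy(),
                                      self.d),
            intensity=self.lam)

    # -- main loop ---------------------------------------------------------
    def run(self) -> ChainOutput:
        s = self.settings
        n_keep = s.n_samples
        m1, L = self.m - 1, self.n_basis
        out_b0 = np.empty(n_keep)
        out_B = np.empty((n_keep, m1, L))
        out_bE = np.empty(n_keep)
        out_bEh = np.empty((n_keep, m1))
        out_bS = np.empty(n_keep)
        out_f = np.empty((n_keep, self.m))
        out_d = np.empty(n_keep)
        out_lam = np.empty(n_keep)
        out_assign = np.empty((n_keep, self.data.n_indiv), dtype=np.int32)
        kept = 0
        for it in range(s.iterations):
            self.gibbs_update_diplotypes()
            for name in self.block_names:
                self.mh_update_block(name)
            if it < s.burn_in:
                if (it + 1) % s.adapt_interval == 0:
                    self._adapt()
            elif (it - s.burn_in) % s.thinning == 0 and kept < n_keep:
                out_b0[kept] = self.beta0
                out_B[kept] = self.Bh
                out_bE[kept] = self.betaE
                out_bEh[kept] = self.betaEh
                out_bS[kept] = self.betaS
                out_f[kept] = self.f
                out_d[kept] = self.d
                out_lam[kept] = self.lam
                out_assign[kept] = self.assign - self.cand_offsets[:-1]
                kept += 1
        rates = {n: (self.acc[n] / self.tries[n] if self.tries[n] else 0.0)
                 for n in self.block_names}
        out = ChainOutput(
            haplotypes=list(self.haplotypes), reference=self.reference,
            n_basis=L, beta0=out_b0[:kept], spline_coeffs=out_B[:kept],
            beta_smoke=out_bE[:kept], beta_interaction=out_bEh[:kept],
            beta_sex=out_bS[:kept], f=out_f[:kept], d=out_d[:kept],
            intensity=out_lam[:kept], assignments=out_assign[:kept],
            acceptance_rates=rates, settings=s)
        out.diagnostics = {
            "ess_beta0": effective_sample_size(out.beta0),
            "geweke_beta0": geweke_z(out.beta0),
            "ess_intensity": effective_sample_size(out.intensity),
        }
        return out


def run_chain(data: ModelData, support: DiplotypeSupport,
              freq_start: FrequencyModel, settings: MCMCSettings,
              prior: PriorSpec, reference: int | None = None) -> ChainOutput:
    """Run one chain; fully reproducible from ``settings.seed``."""
    return Sampler(data, support, freq_start, settings, prior,
                   reference=reference).run()
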