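"""Synthetic cohorts for power and type-I-error studies.

The generator emulates a 5-SNP haplotype block with 5 common and 2 rare
haplotypes, one causal haplotype of each class, an age-varying per-copy
log-odds-ratio curve for each causal haplotype, a binary smoking process
evolving over up to 4 examinations as a 2-state Markov chain, and a
haplotype-by-smoking interaction with the common risk haplotype.  Diplotypes
are drawn under Hardy-Weinberg equilibrium (two independent haplotype draws)
and only the unphased genotypes are emitted — the analysis must recover
phase as a latent variable.  The default common-haplotype effect curve is a
cubic interpolant through a published real-data odds-ratio-by-age profile:
protective in young adulthood, crossing OR = 1 in the early fifties, peaking
near 2.5 at ages 65-70, and decaying toward 1 in old age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .data_io import Cohort, GenotypeTable, PhenotypeTable

# (age, odds ratio) anchors for the default effect profile
EFFECT_CURVE_ANCHORS = (
    (25, 0.13), (30, 0.10), (35, 0.14), (40, 0.26), (45, 0.51), (50, 0.93),
    (55, 1.53), (60, 2.15), (65, 2.52), (70, 2.52), (75, 2.26), (80, 1.88),
    (85, 1.53), (90, 1.27), (95, 1.12))

DEFAULT_HAPLOTYPES = ("AGTAC", "ACTAG", "GGTCC", "GCGAC", "AGGCG",
                      "GCTAC", "ACGCG")
DEFAULT_FREQUENCIES = (0.30, 0.25, 0.20, 0.13, 0.06, 0.035, 0.025)


def default_effect_curve():
    """Cubic interpolant through the default (age, log OR) anchors.

    Returns a callable mapping age (years) to per-copy log odds ratio; exact
    at every anchor age and smoothly extrapolated just beyond them (the
    simulated age range 20-90 slightly exceeds the anchor span).
    """
    ages = np.array([a for a, _ in EFFECT_CURVE_ANCHORS], dtype=float)
    log_or = np.log([r for _, r in EFFECT_CURVE_ANCHORS])
    return CubicSpline(ages, log_or, extrapolate=True)


def zero_curve():
    return lambda t: np.zeros_like(np.asarray(t, dtype=float))


@dataclass
class SimScenario:
    """Generating model for one simulated cohort."""

    n: int = 250
    n_exams: int = 4
    haplotypes: tuple[str, ...] = DEFAULT_HAPLOTYPES
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    causal_common: str = "GGTCC"
    causal_rare: str = "GCTAC"
    null_haplotype: str = "ACTAG"   # designated null for type-I accounting
    common_curve: object = None     # callable age -> log OR; None => default
    rare_curve: object = None       # None => same profile as common
    interaction_log_or: float = float(np.log(2.0))
    smoking_init: float = 0.3
    smoking_persistence: float = 0.8
    sex_prevalence: float = 0.5
    beta0: float = float(np.log(0.35 / 0.65))
    first_exam_age: tuple[float, float] = (22.0, 75.0)
    exam_gap: tuple[float, float] = (3.0, 6.0)
    max_age: float = 90.0

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        if len(self.haplotypes) != f.size:
            raise ValueError("haplotypes and frequencies differ in length")
        if np.any(f <= 0) or not np.isclose(f.sum(), 1.0):
            raise ValueError("frequencies must be positive and sum to 1")
        for h in (self.causal_common, self.causal_rare, self.null_haplotype):
            if h not in self.haplotypes:
                raise ValueError(f"haplotype {h!r} not in the scenario set")

    @classmethod
    def null(cls, **kw) -> "SimScenario":
        """All genetic and interaction effects zero."""
        kw.setdefault("common_curve", zero_curve())
        kw.setdefault("rare_curve", zero_curve())
        kw.setdefault("interaction_log_or", 0.0)
        return cls(**kw)

    def curves(self):
        common = self.common_curve if self.common_curve is not None \
            else default_effect_curve()
        rare = self.rare_curve if self.rare_curve is not None else common
        return common, rare


@dataclass
class TruthRecord:
    """Everything the generator used, for parameter-recovery checks."""

    scenario: SimScenario
    diplotypes: np.ndarray      # (n, 2) haplotype indices
    seed: int


def generate_dataset(scenario: SimScenario, seed: int
                     ) -> tuple[GenotypeTable, PhenotypeTable, TruthRecord]:
    """Simulate one cohort; deterministic given (scenario, seed)."""
    rng = np.random.default_rng(seed)
    sc = scenario
    haps = list(sc.haplotypes)
    f = np.asarray(sc.frequencies, dtype=float)
    n = sc.n
    # HWE (d = 0): two independent haplotype draws per individual
    dips = rng.choice(len(haps), size=(n, 2), p=f)
    common, rare = sc.curves()
    i_common = haps.index(sc.causal_common)
    i_rare = haps.index(sc.causal_rare)
    copies_common = (dips == i_common).sum(axis=1)
    copies_rare = (dips == i_rare).sum(axis=1)

    sex = (rng.random(n) < sc.sex_prevalence).astype(int)
    ids = [f"ind{i + 1:04d}" for i in range(n)]

    rows = []
    for i in range(n):
        age = rng.uniform(*sc.first_exam_age)
        smoke = int(rng.random() < sc.smoking_init)
        for j in range(sc.n_exams):
            if j > 0:
                age = min(age + rng.uniform(*sc.exam_gap), sc.max_age)
                stay = rng.random() < sc.smoking_persistence
                smoke = smoke if stay else 1 - smoke
            eta = (sc.beta0
                   + copies_common[i] * float(common(age))
                   + copies_rare[i] * float(rare(age))
                   + sc.interaction_log_or * copies_common[i] * smoke)
            y = int(rng.random() < 1.0 / (1.0 + np.exp(-eta)))
            rows.append({"id": ids[i], "exam": j + 1, "y": y, "smoke": smoke,
                         "age": round(age, 2), "sex": sex[i]})
    pheno = PhenotypeTable(df=pd.DataFrame(rows))

    # unphased genotypes: per-site allele pair with phase discarded
    n_snps = len(haps[0])
    snp_ids = [f"snp{s + 1}" for s in range(n_snps)]
    genotypes = []
    for i in range(n):
        h1, h2 = haps[dips[i, 0]], haps[dips[i, 1]]
        genotypes.append([tuple(sorted((h1[s], h2[s]))) for s in range(n_snps)])
    geno = GenotypeTable(individual_ids=ids, snp_ids=snp_ids,
                         genotypes=genotypes)
    return geno, pheno, TruthRecord(scenario=sc, diplotypes=dips, seed=seed)


@dataclass
class PowerResult:
    """Rejection proportions per target effect over replicates."""

    rejections: dict[str, int]
    n_replicates: int
    n_failures: int = 0
    per_replicate: list[dict] = field(default_factory=list)

    def proportion(self, effect: str) -> float:
        denom = self.n_replicates - self.n_failures
        return self.rejections[effect] / denom if denom else float("nan")

    def mcse(self, effect: str) -> float:
        denom = self.n_replicates - self.n_failures
        if denom == 0:
            return float("nan")
        p = self.proportion(effect)
        return float(np.sqrt(p * (1 - p) / denom))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"effect": e, "rejection_proportion": self.proportion(e),
              "mcse": self.mcse(e),
              "replicates": self.n_replicates - self.n_failures}
             for e in self.rejections])


def run_power_study(scenario: SimScenario, replicates: int, config,
                    seed: int, progress: bool = False) -> PowerResult:
    """Generate-fit-test loop estimating rejection rates per effect.

    For every replicate a cohort is generated, the full analysis (EM start,
    latent-phase MCMC, posterior odds-ratio curves) is run, and each target
    effect is scored significant when its 95% credible interval excludes 1 —
    for haplotype curves at at least one reporting-grid age inside the
    significance window (default 55-85), for the interaction as a scalar.
    Targets: the common causal haplotype, the rare causal haplotype, the
    smoking interaction with the common causal haplotype, and a designated
    null haplotype (whose rejection rate estimates the type-I error).
    """
    from .api import fit_block

    if replicates < 1:
        raise ValueError("need at least one replicate")
    effects = ("common_causal", "rare_causal", "interaction", "null_haplotype")
    rej = {e: 0 for e in effects}
    failures = 0
    per_rep = []
    root = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                 for s in root.spawn(replicates)]
    for r, s in enumerate(rep_seeds):
        geno, pheno, _ = generate_dataset(scenario, seed=s)
        try:
            result = fit_block(Cohort(geno, pheno), config, seed=s + 1)
        except Exception as exc:  # noqa: BLE001 - fit failure is recorded
            failures += 1
            per_rep.append({"replicate": r, "error": str(exc)})
            continue
        calls = {}
        sig = result.summary
        window_sig = {h: c.significant(sig.age_window)
                      for h, c in sig.curves.items()}
        calls["common_causal"] = window_sig.get(scenario.causal_common, False)
        calls["rare_causal"] = window_sig.get(scenario.causal_rare, False)
        inter = sig.scalars.get(f"interaction:{scenario.causal_common}")
        calls["interaction"] = bool(inter.significant) if inter else False
        calls["null_haplotype"] = window_sig.get(scenario.null_haplotype, False)
        for e in effects:
            rej[e] += int(calls[e])
        per_rep.append({"replicate": r, **calls})
        if progress:
            print(f"replicate {r + 1}/{replicates}: {calls}", flush=True)
    return PowerResult(rejections=rej, n_replicates=replicates,
                       n_failures=failures, per_replicate=per_rep)
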