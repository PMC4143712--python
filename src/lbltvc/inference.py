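"""Posterior summaries: odds-ratio curves over age, significance, reports.

For each non-reference haplotype h the per-copy odds ratio at age t is
OR(t) = exp(sum_l beta_hl B_l(t)); the chain's draws of the spline
coefficients induce draws of OR(t) at every grid age, summarized by the
posterior median and the 2.5/97.5 percentile band.  A haplotype is called
significant at age t when the 95% interval strictly excludes 1, and overall
when that happens at at least one grid age (optionally restricted to an age
window).  Scalar effects (smoking, sex, haplotype-smoking interactions) are
summarized the same way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .haplotypes import RARE_FREQUENCY_THRESHOLD
from .mcmc import ChainOutput
from .splines import SplineBasis


@dataclass
class CurveSummary:
    haplotype: str
    ages: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    mean: np.ndarray
    rare: bool = False

    def significant_at(self) -> np.ndarray:
        return (self.lower > 1.0) | (self.upper < 1.0)

    def significant(self, age_window: tuple[float, float] | None = None) -> bool:
        sig = self.significant_at()
        if age_window is not None:
            lo, hi = age_window
            sig = sig & (self.ages >= lo) & (self.ages <= hi)
        return bool(sig.any())


@dataclass
class ScalarSummary:
    name: str
    median: float
    lower: float
    upper: float
    mean: float

    @property
    def significant(self) -> bool:
        return self.lower > 1.0 or self.upper < 1.0


@dataclass
class PosteriorSummary:
    curves: dict[str, CurveSummary]
    scalars: dict[str, ScalarSummary]
    frequencies: pd.DataFrame = None
    age_window: tuple[float, float] | None = None

    def significant_haplotypes(self) -> list[str]:
        return [h for h, c in self.curves.items()
                if c.significant(self.age_window)]


def or_draws(chain: ChainOutput, haplotype: str, ages,
             basis: SplineBasis) -> np.ndarray:
    """Per-draw odds ratios OR(t) = exp(beta_h(t)) on an age grid; (S, T)."""
    nonref = chain.nonreference_haplotypes()
    if haplotype not in nonref:
        raise KeyError(f"haplotype {haplotype!r} not a non-reference haplotype")
    hi = nonref.index(haplotype)
    B = basis.evaluate(np.asarray(ages, dtype=float))          # (T, L)
    eff = chain.spline_coeffs[:, hi, :] @ B.T                  # (S, T)
    return np.exp(eff)


def or_curve(chain: ChainOutput, haplotype: str, ages,
             basis: SplineBasis, rare: bool = False) -> CurveSummary:
    draws = or_draws(chain, haplotype, ages, basis)
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5], axis=0)
    return CurveSummary(haplotype=haplotype, ages=np.asarray(ages, float),
                        median=med, lower=lo, upper=hi,
                        mean=draws.mean(axis=0), rare=rare)


def scalar_or_summary(name: str, coef_draws: np.ndarray) -> ScalarSummary:
    ors = np.exp(np.asarray(coef_draws, float))
    lo, med, hi = np.percentile(ors, [2.5, 50.0, 97.5])
    return ScalarSummary(name=name, median=float(med), lower=float(lo),
                         upper=float(hi), mean=float(ors.mean()))


def summarize_chain(chain: ChainOutput, basis: SplineBasis, ages,
                    age_window: tuple[float, float] | None = None
                    ) -> PosteriorSummary:
    fmean = chain.f.mean(axis=0)
    freq_df = pd.DataFrame({
        "haplotype": chain.haplotypes, "frequency": fmean,
        "rare": fmean < RARE_FREQUENCY_THRESHOLD,
        "reference": [i == chain.reference for i in range(len(chain.haplotypes))]})
    curves = {}
    for h in chain.nonreference_haplotypes():
        rare = bool(freq_df.loc[freq_df["haplotype"] == h, "rare"].iloc[0])
        curves[h] = or_curve(chain, h, ages, basis, rare=rare)
    scalars = {"smoking": scalar_or_summary("smoking", chain.beta_smoke),
               "sex": scalar_or_summary("sex", chain.beta_sex)}
    for hi, h in enumerate(chain.nonreference_haplotypes()):
        scalars[f"interaction:{h}"] = scalar_or_summary(
            f"interaction:{h}", chain.beta_interaction[:, hi])
    return PosteriorSummary(curves=curves, scalars=scalars,
                            frequencies=freq_df, age_window=age_window)


def call_significance(summary: PosteriorSummary) -> dict[str, bool]:
    """Overall significance flag per haplotype (strict exclusion of OR = 1)."""
    return {h: c.significant(summary.age_window)
            for h, c in summary.curves.items()}


def summary_table(summary: PosteriorSummary) -> pd.DataFrame:
    """Long-format table: haplotype x grid age x OR / L / U / significance."""
    rows = []
    for h, c in summary.curves.items():
        for j, age in enumerate(c.ages):
            rows.append({"haplotype": h, "age": age, "OR": c.median[j],
                         "L": c.lower[j], "U": c.upper[j],
                         "significant": bool(c.significant_at()[j]),
                         "rare": c.rare})
    return pd.DataFrame(rows)


def report_tables(summary: PosteriorSummary, out_dir,
                  manifest: dict | None = None, plots: bool = True) -> Path:
    """Write summary.tsv, per-haplotype curve CSVs, plots and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary_table(summary).to_csv(out / "summary.tsv", sep="\t", index=False)
    scal = pd.DataFrame([{"effect": s.name, "OR": s.median, "L": s.lower,
                          "U": s.upper, "mean": s.mean,
                          "significant": s.significant}
                         for s in summary.scalars.values()])
    scal.to_csv(out / "scalar_effects.tsv", sep="\t", index=False)
    if summary.frequencies is not None:
        summary.frequencies.to_csv(out / "frequencies.tsv", sep="\t", index=False)
    curve_dir = out / "curves"
    curve_dir.mkdir(exist_ok=True)
    for h, c in summary.curves.items():
        pd.DataFrame({"age": c.ages, "OR": c.median, "L": c.lower,
                      "U": c.upper, "mean": c.mean}).to_csv(
            curve_dir / f"{h}.csv", index=False)
    if plots:
        plot_dir = out / "plots"
        plot_dir.mkdir(exist_ok=True)
        for h in summary.significant_haplotypes():
            _plot_curve(summary.curves[h], plot_dir / f"{h}.png")
    if manifest is not None:
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return out


def read_summary_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _plot_curve(curve: CurveSummary, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.ages, curve.median, "k-", label="posterior median OR")
    ax.plot(curve.ages, curve.lower, "r:", label="95% credible bounds")
    ax.plot(curve.ages, curve.upper, "r:")
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("odds ratio")
    ax.set_title(f"haplotype {curve.haplotype}")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
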