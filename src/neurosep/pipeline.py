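"""End-to-end experiment driver: simulate -> analyze -> model-compare.

A run simulates ``n_cultures`` cultures under one stimulation condition,
computes per-electrode conditional statistics and KLD transients, fits the
population free-energy trajectory and the two plasticity models per
culture, writes the dataset-layout CSVs, and summarizes group-level changes
(trial 1 vs last) with the appropriate non-parametric tests.

Conditions
----------
``trn``   reference training (a, rho) = (3/4, 1/2)
``apv``   plasticity blocked (NMDA-antagonist analog)
``prt``   partial training: plastic trials 1-10 and 91-100 only
``alt1..alt4``  alternative (a, rho): (1/2, 1/2), (3/4, 1/4), (3/4, 3/4),
          (1, 1/2)
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import io as nio
from ._rng import culture_seeds
from .plasticity import estimate_alpha, estimate_beta, hebbian_statistics
from .population import EmptyGroupError, build_population, free_energy_trajectory
from .preprocess import EvokedCounts
from .response import clip_delta, conditional_stats, kld_transition
from .simulate import SimConfig, simulate_culture
from .stimulus import StimulusParams, StimulusSchedule, generate_schedule

__all__ = [
    "RunConfig",
    "RunReport",
    "CultureResult",
    "ALT_CONDITIONS",
    "run_experiment",
    "analyze_culture",
    "group_tests",
]

log = logging.getLogger("neurosep")

#: (a, rho) for the alternative stimulation conditions.
ALT_CONDITIONS: dict[str, tuple[float, float]] = {
    "alt1": (0.5, 0.5),
    "alt2": (0.75, 0.25),
    "alt3": (0.75, 0.75),
    "alt4": (1.0, 0.5),
}

CONDITIONS = ("trn", "apv", "prt", *ALT_CONDITIONS)


@dataclass
class RunConfig:
    condition: str = "trn"
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    sim: SimConfig = field(default_factory=SimConfig)
    n_cultures: int = 23
    outdir: str | None = None
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.condition in ALT_CONDITIONS:
            a, rho = ALT_CONDITIONS[self.condition]
            self.stimulus = dataclasses.replace(self.stimulus, a=a, rho=rho)
        if self.condition == "apv":
            self.sim = dataclasses.replace(self.sim, apv_mode=True)

    def plastic_trials(self) -> np.ndarray | None:
        if self.condition != "prt":
            return None
        mask = np.zeros(self.stimulus.n_trials, dtype=bool)
        mask[:10] = True
        mask[-10:] = True
        return mask

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location and
        verbosity excluded: they do not affect the results)."""
        plain = nio._to_plain(self)
        plain.pop("outdir", None)
        plain.pop("verbosity", None)
        return hashlib.sha256(
            yaml.safe_dump(plain, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class CultureResult:
    """Everything the analysis stages produce for one culture."""

    culture: int
    seed: int
    counts: EvokedCounts
    schedule: StimulusSchedule
    stats: object
    kld: object
    pop: object | None = None
    fep: pd.DataFrame | None = None
    alpha_fit: object | None = None
    beta_fit: object | None = None
    exclusion_reason: str | None = None


@dataclass
class RunReport:
    condition: str
    config_hash: str
    seed: int
    n_cultures: int
    n_excluded_cultures: int
    n_unavailable_electrodes: int
    tests: list[dict]
    summary: pd.DataFrame
    efficacy: pd.DataFrame

    def to_markdown(self) -> str:
        lines = [
            f"# neurosep run report: condition {self.condition}",
            "",
            f"- config hash: `{self.config_hash}`",
            f"- seed: {self.seed}",
            f"- cultures analyzed: {self.n_cultures} "
            f"({self.n_excluded_cultures} excluded from population summaries)",
            f"- unavailable electrodes: {self.n_unavailable_electrodes}",
            "",
            "## Group summary (per-culture means)",
            "",
            self.summary.to_markdown(),
            "",
            "## Efficacy fits",
            "",
            self.efficacy.to_markdown(index=False),
            "",
            "## Statistical tests",
            "",
        ]
        for t in self.tests:
            lines.append(
                f"- {t['name']}: {t['test']}, statistic={t['statistic']:.4g}, "
                f"p={t['p']:.3g}, n={t['n']}"
            )
        return "\n".join(lines) + "\n"


def group_tests(kind: str, x, y=None, alternative: str = "two-sided") -> dict:
    """Dispatch the study's non-parametric tests.

    ``kind`` is ``"paired"`` (Wilcoxon signed-rank on x - y, or on x if y is
    None), ``"unpaired"`` (Mann-Whitney U) or ``"correlation"`` (Spearman).
    All-tied paired data is reported as degenerate with p = 1.
    """
    x = np.asarray(x, dtype=float)
    if kind == "paired":
        d = x if y is None else x - np.asarray(y, dtype=float)
        d = d[~np.isnan(d)]
        if d.size < 2:
            raise ValueError("need >= 2 observations")
        if np.all(d == 0):
            return {"test": "wilcoxon", "statistic": np.nan, "p": 1.0,
                    "n": int(d.size), "degenerate": True}
        res = sps.wilcoxon(d, alternative=alternative)
        return {"test": "wilcoxon", "statistic": float(res.statistic),
                "p": float(res.pvalue), "n": int(d.size), "degenerate": False}
    if kind == "unpaired":
        res = sps.mannwhitneyu(x, np.asarray(y, dtype=float), alternative=alternative)
        return {"test": "mann-whitney", "statistic": float(res.statistic),
                "p": float(res.pvalue), "n": int(x.size + len(y)),
                "degenerate": False}
    if kind == "correlation":
        res = sps.spearmanr(x, np.asarray(y, dtype=float))
        return {"test": "spearman", "statistic": float(res.statistic),
                "p": float(res.pvalue), "n": int(x.size), "degenerate": False}
    raise ValueError(f"unknown test kind {kind!r}")


def analyze_culture(
    counts: EvokedCounts,
    schedule: StimulusSchedule,
    culture: int = 1,
    seed: int | None = None,
) -> CultureResult:
    """Run every analysis stage on one culture's counts.

    Cultures whose u1- or u2-preferring group is empty keep their
    electrode-level results but carry an exclusion reason instead of
    population-level fits.
    """
    stats = conditional_stats(counts, schedule.u)
    kld = kld_transition(stats)
    result = CultureResult(
        culture=culture,
        seed=seed if seed is not None else -1,
        counts=counts,
        schedule=schedule,
        stats=stats,
        kld=kld,
    )
    try:
        pop = build_population(counts, stats, schedule)
    except EmptyGroupError as err:
        result.exclusion_reason = str(err)
        log.info("culture %d excluded: %s", culture, err)
        return result
    result.pop = pop
    result.fep = free_energy_trajectory(pop)
    W_traj = result.fep[["W11", "W12", "W21", "W22"]].to_numpy().reshape(-1, 2, 2)
    hebb = hebbian_statistics(pop, W_traj)
    result.alpha_fit = estimate_alpha(hebb)
    result.beta_fit = estimate_beta(hebb)
    return result


def run_experiment(config: RunConfig) -> RunReport:
    """Simulate, analyze and report one condition; deterministic per seed."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    seeds = culture_seeds(config.seed, config.n_cultures)
    results: list[CultureResult] = []
    schedule = generate_schedule(config.stimulus, seed=config.seed)
    plastic = config.plastic_trials()

    for k, cs in enumerate(seeds, start=1):
        counts, _truth = simulate_culture(
            schedule, config.sim, seed=cs, plastic_trials=plastic
        )
        counts.condition = config.condition
        try:
            results.append(analyze_culture(counts, schedule, culture=k, seed=cs))
        except Exception as err:  # pragma: no cover - stage diagnostics
            raise RuntimeError(
                f"analysis stage failed for culture {k}: {err}"
            ) from err

    n_unavail = int(sum((~r.stats.available).sum() for r in results))
    kept = [r for r in results if r.fep is not None]
    log.info(
        "condition %s: %d/%d cultures usable, %d unavailable electrodes",
        config.condition, len(kept), len(results), n_unavail,
    )

    summary, tests = _summarize(config, results, kept)
    efficacy = pd.DataFrame(
        [
            {
                "culture": r.culture,
                "mu_alpha": r.alpha_fit.mu_alpha,
                "mu_beta1": r.beta_fit.mu_beta1,
                "mu_beta2": r.beta_fit.mu_beta2,
                "ratio": r.beta_fit.efficacy_ratio,
                "bic_alpha": r.alpha_fit.bic,
                "bic_beta": r.beta_fit.bic,
            }
            for r in kept
        ]
    )

    report = RunReport(
        condition=config.condition,
        config_hash=config.config_hash(),
        seed=config.seed,
        n_cultures=len(results),
        n_excluded_cultures=len(results) - len(kept),
        n_unavailable_electrodes=n_unavail,
        tests=tests,
        summary=summary,
        efficacy=efficacy,
    )

    if outdir:
        _write_outputs(outdir, config, results, kept, report)
    return report


def _summarize(config, results, kept):
    last = config.stimulus.n_trials - 1
    rows, tests = [], []

    kld_first = [np.nanmean(r.kld.d_kl[r.kld.available, 0]) for r in results]
    kld_last = [np.nanmean(clip_delta(r.kld)[r.kld.available, last])
                + np.nanmean(r.kld.d_kl[r.kld.available, 0]) for r in results]
    rows.append({"quantity": "mean KLD", "trial_1": np.nanmean(kld_first),
                 "trial_last": np.nanmean(kld_last)})
    tests.append({"name": "KLD change (trial 1 vs last)",
                  **group_tests("paired", kld_last, kld_first)})

    if kept:
        for col, name in (("U", "internal energy"), ("H", "entropy"),
                          ("F", "free energy")):
            a = [r.fep[col].iloc[0] for r in kept]
            b = [r.fep[col].iloc[-1] for r in kept]
            rows.append({"quantity": name, "trial_1": np.mean(a),
                         "trial_last": np.mean(b)})
            tests.append({"name": f"{name} change", **group_tests("paired", b, a)})
        diag_a = [r.fep[c].iloc[0] for r in kept for c in ("W11", "W22")]
        diag_b = [r.fep[c].iloc[-1] for r in kept for c in ("W11", "W22")]
        off_a = [r.fep[c].iloc[0] for r in kept for c in ("W12", "W21")]
        off_b = [r.fep[c].iloc[-1] for r in kept for c in ("W12", "W21")]
        rows.append({"quantity": "W11/W22", "trial_1": np.mean(diag_a),
                     "trial_last": np.mean(diag_b)})
        rows.append({"quantity": "W12/W21", "trial_1": np.mean(off_a),
                     "trial_last": np.mean(off_b)})
        tests.append({"name": "within-group connectivity change",
                      **group_tests("paired", diag_b, diag_a)})
        tests.append({"name": "between-group connectivity change",
                      **group_tests("paired", off_b, off_a)})
        ratios = [r.beta_fit.efficacy_ratio for r in kept]
        rows.append({"quantity": "beta2/beta1", "trial_1": np.nan,
                     "trial_last": np.mean(ratios)})
        if len(kept) >= 2:
            tests.append({"name": "BIC beta vs alpha",
                          **group_tests(
                              "paired",
                              [r.beta_fit.bic for r in kept],
                              [r.alpha_fit.bic for r in kept],
                          )})
    return pd.DataFrame(rows), tests


def _write_outputs(outdir: Path, config, results, kept, report) -> None:
    label = config.condition
    for r in results:
        nio.write_counts_csv(
            outdir / nio.counts_filename(label, r.culture), r.counts, r.schedule.u
        )
    nio.write_xu_csv(outdir / f"x_u_{label}.csv",
                     {r.culture: r.stats.x_u for r in results})
    nio.write_kld_csv(outdir / f"kld_{label}.csv",
                      {r.culture: r.kld.d_kl for r in results})
    if kept:
        fep = pd.concat(
            [r.fep.assign(culture=r.culture) for r in kept]
        ).reset_index()
        fep.to_csv(outdir / f"fep_{label}.csv", index=False)
    report.efficacy.to_csv(outdir / f"efficacy_{label}.csv", index=False)
    nio.save_config(outdir / "config.yaml", config)
    (outdir / f"report_{label}.md").write_text(report.to_markdown())
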