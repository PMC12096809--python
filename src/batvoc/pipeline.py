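"""End-to-end orchestration and population-level statistics.

``run_pipeline`` chains the stages — synthesize the 15-call library,
simulate (or accept) a unit population, compute response windows,
preference indices, confusion matrices and selectivity indices — and
aggregates per-unit results with the standard group comparisons
(two-sample t-test, Wilcoxon rank-sum, one-way ANOVA with Tukey HSD).
A run is a pure function of its :class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .calls import CATEGORIES, CallLibrary, InputError, make_call_library
from .patterns import ConfusionMatrix, confusion_matrix, selectivity_index
from .psth import NonResponsiveError
from .selectivity import PreferenceResult, preference_result
from .tuning import TuningSummary, summarize_unit
from .units import (
    TrialProtocol,
    UnitProfile,
    dac_template,
    faf_template,
    make_population,
    simulate_call_response,
    simulate_tone_grid,
)

log = logging.getLogger("batvoc")

ALPHA = 0.05  # population significance level


@dataclass
class RunConfig:
    """Declarative description of one full analysis run."""

    seed: int = 0
    n_faf: int = 5
    n_dac: int = 5
    n_trials: int = 20
    pre_stimulus_ms: float = 50.0
    post_stimulus_ms: float = 450.0
    integration_windows_ms: tuple[float, ...] = (2.0, 200.0)
    n_resamples: int = 2_000
    include_within_category: bool = False
    include_tuning: bool = False
    tone_levels_step_db: float = 5.0
    criterion_n_sd: float = 2.0
    out_dir: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["integration_windows_ms"] = list(d["integration_windows_ms"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["integration_windows_ms"] = tuple(d.get("integration_windows_ms", (2.0, 200.0)))
        return cls(**d)


@dataclass
class PopulationSummary:
    """Aggregated per-unit results and group-comparison table."""

    units: pd.DataFrame
    comparisons: pd.DataFrame
    confusions: dict[tuple[str, float], ConfusionMatrix] = field(default_factory=dict)
    preferences: dict[str, PreferenceResult] = field(default_factory=dict)
    tuning: dict[str, TuningSummary] = field(default_factory=dict)
    library: CallLibrary | None = None


def compare_groups(values_a, values_b, test: str = "t") -> tuple[float, float]:
    """Two-sample comparison via the named standard test.

    ``test`` is ``"t"`` (two-sided two-sample t-test) or ``"ranksum"``
    (two-sided Wilcoxon rank-sum).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise InputError("need at least 2 values per group")
    if test == "t":
        res = stats.ttest_ind(a, b)
    elif test == "ranksum":
        res = stats.ranksums(a, b)
    else:
        raise InputError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def compare_multi(groups: list[np.ndarray], labels: list[str] | None = None) -> pd.DataFrame:
    """One-way ANOVA followed by Tukey HSD pairwise adjusted p-values.

    Returns one row per group pair: group_a, group_b, mean_diff,
    p_adj, plus the overall ANOVA F and p repeated on each row.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 3:
        raise InputError("need at least 3 groups")
    if any(len(g) < 2 for g in groups):
        raise InputError("need at least 2 values per group")
    labels = labels or [f"g{i}" for i in range(len(groups))]
    f_stat, f_p = stats.f_oneway(*groups)
    values = np.concatenate(groups)
    codes = np.concatenate([[lab] * len(g) for lab, g in zip(labels, groups)])
    tk = pairwise_tukeyhsd(values, codes, alpha=ALPHA)
    rows = tk.summary().data[1:]
    out = pd.DataFrame(rows, columns=[str(c) for c in tk.summary().data[0]])
    out = out.rename(columns={"group1": "group_a", "group2": "group_b", "p-adj": "p_adj", "meandiff": "mean_diff"})
    out["anova_F"] = float(f_stat)
    out["anova_p"] = float(f_p)
    return out[["group_a", "group_b", "mean_diff", "p_adj", "anova_F", "anova_p"]]


def unit_selectivity(cm: ConfusionMatrix) -> tuple[float, float, str]:
    """(best-class probability, SI of the best row, best class label).

    The unit's best class is the one with the highest diagonal entry; the
    SI is computed on that row of the confusion matrix.
    """
    diag = cm.diagonal
    i = int(np.argmax(diag))
    si = selectivity_index(cm.probs[i], labels=cm.labels)
    return float(diag[i]), si.si, cm.labels[i]


def simulate_unit_call_responses(
    profile: UnitProfile, library: CallLibrary, protocol: TrialProtocol
):
    """Responses of one unit to every call in the library (dict by call id)."""
    return {
        call.call_id: simulate_call_response(profile, call, protocol) for call in library
    }


def run_pipeline(
    config: RunConfig,
    population: list[UnitProfile] | None = None,
    library: CallLibrary | None = None,
) -> PopulationSummary:
    """Execute the full analysis; deterministic under a fixed config.

    A failing stage for one unit (e.g. a unit whose activity never
    crosses the response criterion) is logged and flagged; the run
    continues with the remaining units.
    """
    if library is None:
        library = make_call_library(seed=config.seed)
    if population is None:
        population = make_population(
            [(faf_template(), config.n_faf), (dac_template(), config.n_dac)],
            seed=config.seed,
        )
    categories = {c.call_id: c.category for c in library}
    protocol = TrialProtocol(
        pre_stimulus_ms=config.pre_stimulus_ms,
        post_stimulus_ms=config.post_stimulus_ms,
        n_trials=config.n_trials,
        seed=config.seed,
    )

    rows = []
    confusions: dict[tuple[str, float], ConfusionMatrix] = {}
    preferences: dict[str, PreferenceResult] = {}
    tuning_results: dict[str, TuningSummary] = {}
    for profile in population:
        log.info("unit %s (%s): simulating call responses", profile.unit_id, profile.area)
        unit_data = simulate_unit_call_responses(profile, library, protocol)
        row: dict[str, object] = {"unit_id": profile.unit_id, "area": profile.area, "ok": True}
        try:
            pref = preference_result(unit_data, categories, pre_ms=config.pre_stimulus_ms)
            preferences[profile.unit_id] = pref
            row["pi_cat"] = pref.pi_cat
            for cat in CATEGORIES:
                row[f"pi_call_{cat}"] = pref.pi_call[cat]
            for w in config.integration_windows_ms:
                cm = confusion_matrix(
                    unit_data,
                    categories,
                    level="category",
                    integration_window_ms=w,
                    n_resamples=config.n_resamples,
                    seed=config.seed,
                    window=pref.window,
                )
                confusions[(profile.unit_id, w)] = cm
                best_p, si, best_label = unit_selectivity(cm)
                row[f"best_prob_{w:g}ms"] = best_p
                row[f"si_{w:g}ms"] = si
                row[f"best_category_{w:g}ms"] = best_label
                if config.include_within_category:
                    for cat in CATEGORIES:
                        wcm = confusion_matrix(
                            unit_data,
                            categories,
                            level=f"within:{cat}",
                            integration_window_ms=w,
                            n_resamples=config.n_resamples,
                            seed=config.seed,
                            window=pref.window,
                        )
                        confusions[(profile.unit_id, w, cat)] = wcm  # type: ignore[index]
                        wb, wsi, _ = unit_selectivity(wcm)
                        row[f"within_best_prob_{cat}_{w:g}ms"] = wb
                        row[f"within_si_{cat}_{w:g}ms"] = wsi
        except NonResponsiveError as exc:
            log.warning("unit %s: %s", profile.unit_id, exc)
            row["ok"] = False
        if config.include_tuning:
            grid = simulate_tone_grid(
                profile,
                protocol=TrialProtocol(
                    pre_stimulus_ms=50.0, post_stimulus_ms=300.0, n_trials=10, seed=config.seed
                ),
            )
            ts = summarize_unit(grid, unit_id=profile.unit_id)
            tuning_results[profile.unit_id] = ts
            row.update(
                bf_khz=ts.bf_khz,
                cf_khz=ts.cf_khz,
                q10=ts.q10,
                latency_ms=ts.latency_ms,
                response_duration_ms=ts.response_duration_ms,
            )
        rows.append(row)

    units = pd.DataFrame(rows)
    comparisons = _group_comparisons(units, config)
    summary = PopulationSummary(
        units=units,
        comparisons=comparisons,
        confusions=confusions,
        preferences=preferences,
        tuning=tuning_results,
        library=library,
    )
    if config.out_dir:
        _write_outputs(summary, config)
    return summary


def _group_comparisons(units: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """dAC vs FAF and 2-ms vs 200-ms comparisons on the unit table."""
    rows = []
    ok = units[units.get("ok", True) == True]  # noqa: E712
    faf = ok[ok["area"] == "FAF"]
    dac = ok[ok["area"] == "dAC"]

    def add(analysis, a_lab, b_lab, a, b, test):
        try:
            stat, p = compare_groups(a, b, test=test)
        except InputError:
            return
        rows.append(
            {
                "analysis": analysis,
                "group_a": a_lab,
                "group_b": b_lab,
                "test": test,
                "statistic": stat,
                "p": p,
                "significant": p < ALPHA,
                "mean_a": float(np.nanmean(a)) if len(a) else np.nan,
                "mean_b": float(np.nanmean(b)) if len(b) else np.nan,
            }
        )

    for w in config.integration_windows_ms:
        col_p, col_si = f"best_prob_{w:g}ms", f"si_{w:g}ms"
        if col_p in ok.columns and len(faf) and len(dac):
            add(f"best_prob_{w:g}ms dAC_vs_FAF", "dAC", "FAF", dac[col_p], faf[col_p], "t")
            add(f"si_{w:g}ms dAC_vs_FAF", "dAC", "FAF", dac[col_si], faf[col_si], "ranksum")
    if len(config.integration_windows_ms) >= 2:
        w1, w2 = config.integration_windows_ms[:2]
        for area, grp in (("FAF", faf), ("dAC", dac)):
            c1, c2 = f"best_prob_{w1:g}ms", f"best_prob_{w2:g}ms"
            if c1 in ok.columns and c2 in ok.columns and len(grp):
                add(f"best_prob {w1:g}ms_vs_{w2:g}ms {area}", f"{w1:g}ms", f"{w2:g}ms", grp[c1], grp[c2], "t")
    return pd.DataFrame(rows)


def _write_outputs(summary: PopulationSummary, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.units.to_csv(out / "units.csv", index=False)
    summary.comparisons.to_csv(out / "comparisons.csv", index=False)
    payload = {
        "_".join(str(k) for k in key): {
            "labels": cm.labels,
            "probs": cm.probs.tolist(),
            "n_resamples": cm.n_resamples,
        }
        for key, cm in summary.confusions.items()
    }
    (out / "confusion_matrices.json").write_text(json.dumps(payload, indent=1))
    config.to_yaml(out / "config.yaml")
    log.info("wrote outputs to %s", out)
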