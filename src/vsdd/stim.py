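"""Statistics for paired stimulation/control sessions.

Each site contributes one session in which stimulation (electrical, or
optogenetic facilitation of dopamine input) was applied on half of the
trials during the first-object presentation. The per-value effect is the
difference in choice rate between stimulation and non-stimulation trials
(delta choice rate); per-site significance uses a 2x2 chi-square without
continuity correction. Because sites shift choice in both directions, the
*net* population effect is summarized two ways: the mean absolute delta per
value (largest at the indifference-adjacent value 4, where decisions are
least deterministic), and the width of the delta distribution across sites
against a chance-level width obtained by shuffling the condition labels
within each site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .config import substream
from .exceptions import InsufficientDataError, ParameterError
from .io import VALUES, as_trial_frame

__all__ = [
    "StimEffect",
    "WidthTest",
    "delta_choice_rate",
    "site_chi_square",
    "abs_delta_profile",
    "width_shuffle_test",
    "latency_effect",
    "halves_consistency",
    "StimulationEffectAnalysis",
]


@dataclass
class StimEffect:
    """Per-site, per-value stimulation effect."""

    site_id: str
    value: int
    n_stim: int
    n_nostim: int
    rate_stim: float
    rate_nostim: float
    delta: float
    chi2: float
    p: float


@dataclass
class WidthTest:
    """Monte Carlo test of the delta distribution width at one value."""

    value: int
    width_obs: float
    exceed_count: int
    n_shuffle: int
    p: float
    significant: bool


def _value_table(df: pd.DataFrame, value: int):
    g = df[df["value1"] == value]
    stim = g[g["stim"] == 1]
    ctrl = g[g["stim"] == 0]
    return stim, ctrl


def delta_choice_rate(site_trials) -> dict[int, float]:
    """Per-value choice-rate difference (stimulation minus control).

    Values lacking trials in either condition are absent (with a warning).
    """
    df = as_trial_frame(site_trials)
    out: dict[int, float] = {}
    for v in VALUES:
        stim, ctrl = _value_table(df, v)
        if len(stim) == 0 or len(ctrl) == 0:
            warnings.warn(
                f"value {v}: missing trials in one condition; delta absent",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        out[v] = float(stim["chosen"].mean() - ctrl["chosen"].mean())
    return out


def site_chi_square(site_trials, value: int) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) at one value.

    Returns (nan, nan) when any margin of the 2x2 table is zero.
    """
    df = as_trial_frame(site_trials)
    stim, ctrl = _value_table(df, value)
    table = np.array(
        [
            [stim["chosen"].sum(), len(stim) - stim["chosen"].sum()],
            [ctrl["chosen"].sum(), len(ctrl) - ctrl["chosen"].sum()],
        ],
        float,
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return float("nan"), float("nan")
    if table[0, 0] / table[0].sum() == table[1, 0] / table[1].sum():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def site_effects(sites: dict[str, object]) -> list[StimEffect]:
    """Full per-site, per-value effect table."""
    effects = []
    for sid in sorted(sites):
        df = as_trial_frame(sites[sid])
        deltas = delta_choice_rate(df)
        for v, d in deltas.items():
            stim, ctrl = _value_table(df, v)
            chi2, p = site_chi_square(df, v)
            effects.append(
                StimEffect(
                    site_id=sid,
                    value=v,
                    n_stim=len(stim),
                    n_nostim=len(ctrl),
                    rate_stim=float(stim["chosen"].mean()),
                    rate_nostim=float(ctrl["chosen"].mean()),
                    delta=d,
                    chi2=chi2,
                    p=p,
                )
            )
    return effects


def abs_delta_profile(sites: dict[str, object]) -> dict:
    """Mean |delta| per value with a one-way F-test across values.

    Site is the unit of analysis. A post-hoc two-group contrast compares
    value 4 against the pooled other values (Welch t-test).
    """
    if len(sites) < 1:
        raise InsufficientDataError("no sites")
    per_value: dict[int, list[float]] = {v: [] for v in VALUES}
    for sid in sorted(sites):
        for v, d in delta_choice_rate(sites[sid]).items():
            per_value[v].append(abs(d))
    groups = {v: np.asarray(a) for v, a in per_value.items() if len(a)}
    out = {
        "mean_abs_delta": {v: float(np.mean(a)) for v, a in groups.items()},
        "sem_abs_delta": {
            v: float(stats.sem(a)) if len(a) > 1 else np.nan for v, a in groups.items()
        },
        "n_sites": {v: len(a) for v, a in groups.items()},
    }
    if len(sites) < 2 or len(groups) < 2:
        out["f_stat"] = np.nan
        out["f_p"] = np.nan
        out["value4_vs_rest_p"] = np.nan
        return out
    arrays = [groups[v] for v in sorted(groups)]
    if all(np.allclose(a, arrays[0].mean()) for a in arrays):
        out["f_stat"], out["f_p"] = 0.0, 1.0
    else:
        f = stats.f_oneway(*arrays)
        out["f_stat"], out["f_p"] = float(f.statistic), float(f.pvalue)
    if 4 in groups and len(groups) > 1:
        rest = np.concatenate([a for v, a in groups.items() if v != 4])
        if np.allclose(groups[4], rest.mean()) and np.allclose(rest, rest.mean()):
            out["value4_vs_rest_p"] = 1.0
        else:
            t = stats.ttest_ind(groups[4], rest, equal_var=False)
            out["value4_vs_rest_p"] = float(t.pvalue)
    else:
        out["value4_vs_rest_p"] = np.nan
    return out


def _site_arrays(sites: dict[str, object], value: int):
    """(n_stim, n_ctrl, chosen_total) per site at one value, sites with both conditions."""
    rows = []
    for sid in sorted(sites):
        df = as_trial_frame(sites[sid])
        stim, ctrl = _value_table(df, value)
        if len(stim) == 0 or len(ctrl) == 0:
            continue
        rows.append(
            (
                len(stim),
                len(ctrl),
                int(stim["chosen"].sum()),
                int(ctrl["chosen"].sum()),
            )
        )
    return rows


def width_shuffle_test(
    sites: dict[str, object],
    value: int = 4,
    n_shuffle: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> WidthTest:
    """Distribution-width Monte Carlo test at one value.

    Width is the sigma of a maximum-likelihood Gaussian fit to the site
    deltas after centering (the population SD). The chance-level width is
    obtained by shuffling the stimulation/no-stimulation labels within
    every site and recomputing the deltas; label shuffling is realized
    through its exact equivalent, drawing the number of chosen trials that
    land in the stimulated half from a hypergeometric law. Significant iff
    the observed width exceeds the null width in more than
    (1 - alpha/2) * n_shuffle repetitions (two-tailed convention).
    """
    if n_shuffle < 100:
        raise ParameterError("n_shuffle must be >= 100")
    rows = _site_arrays(sites, value)
    if len(rows) < 5:
        warnings.warn(
            f"only {len(rows)} usable sites: width estimate unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    if len(rows) == 0:
        raise InsufficientDataError(f"no usable sites at value {value}")
    n_stim = np.array([r[0] for r in rows])
    n_ctrl = np.array([r[1] for r in rows])
    k_stim = np.array([r[2] for r in rows])
    k_ctrl = np.array([r[3] for r in rows])
    obs_delta = k_stim / n_stim - k_ctrl / n_ctrl
    width_obs = float(np.std(obs_delta))  # ML sigma, centered

    rng = substream(seed, "width-shuffle", value)
    k_tot = k_stim + k_ctrl
    n_tot = n_stim + n_ctrl
    # X ~ Hypergeom(ngood=k_tot, nbad=n_tot-k_tot, nsample=n_stim) per shuffle
    X = rng.hypergeometric(
        k_tot[None, :].repeat(n_shuffle, axis=0),
        (n_tot - k_tot)[None, :].repeat(n_shuffle, axis=0),
        n_stim[None, :].repeat(n_shuffle, axis=0),
    )
    null_delta = X / n_stim[None, :] - (k_tot[None, :] - X) / n_ctrl[None, :]
    width_null = np.std(null_delta, axis=1)
    exceed = int(np.sum(width_obs > width_null))
    hi = (1.0 - alpha / 2.0) * n_shuffle
    # two-tailed Monte Carlo p from the exceedance count
    p = 2.0 * min(
        (1 + np.sum(width_null >= width_obs)) / (1 + n_shuffle),
        (1 + np.sum(width_null <= width_obs)) / (1 + n_shuffle),
    )
    return WidthTest(
        value=value,
        width_obs=width_obs,
        exceed_count=exceed,
        n_shuffle=n_shuffle,
        p=float(min(p, 1.0)),
        significant=exceed > hi,
    )


def latency_effect(sites: dict[str, object]) -> dict:
    """Release-latency effect of stimulation and its relation to choice effects.

    Per site: mean release latency (stim minus control, chosen trials).
    Population: two-sided Wilcoxon signed-rank of the per-site differences
    against zero, and the Pearson correlation between the latency
    difference and the choice-rate difference at value 4.
    """
    rows = []
    for sid in sorted(sites):
        df = as_trial_frame(sites[sid])
        rel = df[~df["latency_ms"].isna()]
        stim = rel[rel["stim"] == 1]["latency_ms"]
        ctrl = rel[rel["stim"] == 0]["latency_ms"]
        if len(stim) == 0 or len(ctrl) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            deltas = delta_choice_rate(df)
        rows.append(
            {
                "site_id": sid,
                "delta_latency_ms": float(stim.mean() - ctrl.mean()),
                "delta_choice_value4": deltas.get(4, np.nan),
            }
        )
    table = pd.DataFrame(rows)
    out: dict = {"per_site": table}
    d = table["delta_latency_ms"].to_numpy()
    if len(d) >= 2 and np.any(d != 0):
        out["wilcoxon_p"] = float(stats.wilcoxon(d, alternative="two-sided").pvalue)
    else:
        out["wilcoxon_p"] = 1.0 if len(d) else np.nan
    ok = ~table["delta_choice_value4"].isna()
    if ok.sum() >= 3 and np.ptp(d[ok]) > 0 and np.ptp(table["delta_choice_value4"][ok]) > 0:
        r, p = stats.pearsonr(d[ok], table["delta_choice_value4"][ok])
        out["corr_r"], out["corr_p"] = float(r), float(p)
    else:
        out["corr_r"], out["corr_p"] = np.nan, np.nan
    return out


def halves_consistency(sites: dict[str, object], value: int = 4) -> pd.DataFrame:
    """Sign agreement of the delta between early and late trial halves (descriptive)."""
    rows = []
    for sid in sorted(sites):
        df = as_trial_frame(sites[sid]).sort_values("trial_index")
        half = len(df) // 2
        halves = []
        for part in (df.iloc[:half], df.iloc[half:]):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                d = delta_choice_rate(part)
            halves.append(d.get(value, np.nan))
        rows.append(
            {
                "site_id": sid,
                "delta_early": halves[0],
                "delta_late": halves[1],
                "sign_agree": bool(np.sign(halves[0]) == np.sign(halves[1]))
                if np.isfinite(halves[0]) and np.isfinite(halves[1])
                else None,
            }
        )
    return pd.DataFrame(rows)


class StimulationEffectAnalysis(BaseEstimator):
    """Site-level stimulation-effect statistics.

    Fit on ``{site_id: trials}``; fitted attributes: ``effects_`` (per-site
    per-value table), ``abs_profile_``, ``width_tests_`` (dict value ->
    WidthTest), ``latency_`` and ``halves_``.
    """

    def __init__(self, n_shuffle: int = 1000, alpha: float = 0.05, seed: int = 0):
        self.n_shuffle = n_shuffle
        self.alpha = alpha
        self.seed = seed

    def fit(self, sites: dict[str, object], y=None):
        self.effects_ = pd.DataFrame([e.__dict__ for e in site_effects(sites)])
        self.abs_profile_ = abs_delta_profile(sites)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.width_tests_ = {
                v: width_shuffle_test(
                    sites, v, n_shuffle=self.n_shuffle, seed=self.seed, alpha=self.alpha
                )
                for v in VALUES
            }
            self.latency_ = latency_effect(sites)
            self.halves_ = halves_consistency(sites)
        return self
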