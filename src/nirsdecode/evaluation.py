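"""Classifier assessment: pairwise 4-fold CV, 7 repeats, topology search.

Rest/pinch trial pairs (never individual trials) are randomly split into 4
folds, so train and test sets always contain equal numbers of rest and
active observations.  Per fold, feature weights and both HMMs are fitted on
the training pairs only.  The fold metrics are averaged into one complete
cross-validation run; runs are repeated 7 times with fresh partitions; the
topology with the highest mean accuracy over the repeats is selected per
decoder mode.  Chance-level tests use an exact (Clopper-Pearson) binomial
confidence interval on the mean number of correctly classified trials, and
decoder modes are compared with paired two-tailed t-tests across the 7
run-level means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from . import features as feat
from .biosignals import assemble_biosignals
from .fnirs import preprocess_fnirs
from .hmm import EMConfig, Topology, classify, default_grid, train_dual_classifier
from .protocol import RawRecording

CHANCE_LEVEL = 50.0
USABILITY_BOUND = 70.0

METRICS = ("acc", "sens", "spec")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def compute_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) as fractions; NaN if undefined."""
    if counts.total == 0:
        raise ValueError("no test observations")
    acc = (counts.tp + counts.tn) / counts.total
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    sens = counts.tp / pos if pos > 0 else np.nan
    spec = counts.tn / neg if neg > 0 else np.nan
    return acc, sens, spec


def partition_pairs(pairs: list, k: int = 4,
                    seed: int | np.random.Generator = 0) -> list[list]:
    """Random split of trial pairs into k near-equal disjoint folds."""
    if len(pairs) < k:
        raise ValueError(f"need at least {k} pairs for {k}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    return [[pairs[i] for i in chunk] for chunk in np.array_split(order, k)]


def binomial_ci(mean_accuracy: float, n_trials: int,
                level: float = 0.95) -> tuple[float, float]:
    """Exact Clopper-Pearson CI of the accuracy, returned in percent.

    The mean number of successes over repeated cross-validation runs is in
    general fractional; it is used as-is in the beta-quantile form of the
    interval (the integer case reduces to the textbook Clopper-Pearson
    bounds).
    """
    if not 0.0 <= mean_accuracy <= 1.0:
        raise ValueError("mean accuracy must be within [0, 1]")
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    successes = mean_accuracy * n_trials
    lo, hi = proportion_confint(successes, n_trials, alpha=1.0 - level,
                                method="beta")
    lo = 0.0 if successes == 0 else lo
    hi = 1.0 if successes == n_trials else hi
    return 100.0 * lo, 100.0 * hi


@dataclass
class PerformanceReport:
    """Fold-level confusion counts and metrics for every evaluated cell."""

    records: pd.DataFrame           # mode, n_states, n_mixtures, repeat, fold,
                                    # tp, tn, fp, fn, acc, sens, spec
    n_trials: dict[str, int]        # included test trials per mode (all folds)
    modes: tuple[str, ...]
    seed: int
    notes: list[str] = field(default_factory=list)

    def run_level(self) -> pd.DataFrame:
        """Mean metrics over the 4 folds = one complete CV run."""
        g = self.records.groupby(["mode", "n_states", "n_mixtures", "repeat"])
        out = g[list(METRICS)].mean().reset_index()
        return out

    def topology_summary(self) -> pd.DataFrame:
        """Mean and SD over the repeats, per mode and topology."""
        runs = self.run_level()
        g = runs.groupby(["mode", "n_states", "n_mixtures"])
        out = g[list(METRICS)].agg(["mean", "std"])
        out.columns = [f"{m}_{s}" for m, s in out.columns]
        return out.reset_index()

    def selected_topology(self, mode: str) -> Topology:
        """Highest mean accuracy; ties break toward fewer states, mixtures."""
        summ = self.topology_summary()
        summ = summ[summ["mode"] == mode]
        if summ.empty:
            raise ValueError(f"no results for mode {mode!r}")
        summ = summ.sort_values(["acc_mean", "n_states", "n_mixtures"],
                                ascending=[False, True, True])
        row = summ.iloc[0]
        return Topology(int(row["n_states"]), int(row["n_mixtures"]))

    def selected_runs(self, mode: str) -> pd.DataFrame:
        topo = self.selected_topology(mode)
        runs = self.run_level()
        sel = runs[(runs["mode"] == mode)
                   & (runs["n_states"] == topo.n_states)
                   & (runs["n_mixtures"] == topo.n_mixtures)]
        return sel.sort_values("repeat").reset_index(drop=True)

    def summary(self, mode: str) -> dict:
        """Selected-topology performance in percent, with the accuracy CI."""
        topo = self.selected_topology(mode)
        runs = self.selected_runs(mode)
        out = {"mode": mode, "n_states": topo.n_states,
               "n_mixtures": topo.n_mixtures,
               "n_trials": self.n_trials[mode]}
        for m in METRICS:
            out[f"{m}_mean"] = 100.0 * runs[m].mean()
            out[f"{m}_sd"] = 100.0 * runs[m].std(ddof=1)
        out["acc_ci"] = binomial_ci(runs["acc"].mean(), self.n_trials[mode])
        return out

    def table(self) -> str:
        """Human-readable per-mode summary."""
        lines = []
        for mode in self.modes:
            s = self.summary(mode)
            lines.append(
                f"{mode:>10s}: Acc {s['acc_mean']:5.1f} ± {s['acc_sd']:4.1f} %  "
                f"Sens {s['sens_mean']:5.1f} ± {s['sens_sd']:4.1f} %  "
                f"Spec {s['spec_mean']:5.1f} ± {s['spec_sd']:4.1f} %  "
                f"(Ns={s['n_states']}, Nm={s['n_mixtures']}, "
                f"N={s['n_trials']}, CI [{s['acc_ci'][0]:.1f}, "
                f"{s['acc_ci'][1]:.1f}])")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"seed": self.seed, "modes": list(self.modes),
                "n_trials": self.n_trials, "notes": self.notes,
                "records": self.records.to_dict(orient="list")}


def _counts_from_predictions(pred_true: list[tuple[str, str]]) -> ConfusionCounts:
    tp = sum(p == "active" and t == "active" for p, t in pred_true)
    tn = sum(p == "rest" and t == "rest" for p, t in pred_true)
    fp = sum(p == "active" and t == "rest" for p, t in pred_true)
    fn = sum(p == "rest" and t == "active" for p, t in pred_true)
    return ConfusionCounts(tp, tn, fp, fn)


def run_experiment(recording: RawRecording,
                   modes: tuple[str, ...] = ("fnirs_only", "combined"),
                   grid: list[Topology] | None = None,
                   n_repeats: int = 7, n_folds: int = 4,
                   n_restarts: int = 10, seed: int = 0,
                   segment_spec: feat.SegmentSpec | None = None,
                   em_config: EMConfig | None = None) -> PerformanceReport:
    """Full assessment pipeline on one recording.

    Per mode, topology and repeat, a complete pairwise ``n_folds``-fold CV is
    run; partitions are shared across modes and topologies within a repeat so
    mode comparisons are paired.  Feature weights and HMMs see training folds
    only.  If biosignals are missing, the combined mode is dropped with a
    warning and the report is flagged.
    """
    grid = grid if grid is not None else default_grid()
    spec = segment_spec or feat.SegmentSpec()
    notes: list[str] = []

    processed = preprocess_fnirs(recording)
    ans = None
    if "combined" in modes:
        try:
            ans = assemble_biosignals(recording)
        except ValueError as exc:
            modes = tuple(m for m in modes if m != "combined")
            notes.append(f"combined mode unavailable: {exc}")
            warnings.warn(f"biosignals unavailable ({exc}); "
                          "reporting fNIRS-only results")
    if not modes:
        raise ValueError("no decoder mode can be evaluated")

    pairs = feat.extract_trial_pairs(recording.timeline, processed, spec)
    clean = [p for p in pairs if not p.ma_affected]
    n_excluded = len(pairs) - len(clean)
    if n_excluded:
        notes.append(f"{n_excluded} of {len(pairs)} pairs excluded "
                     "(motion artifacts)")

    rows = []
    for rep in range(n_repeats):
        folds = partition_pairs(
            clean, n_folds,
            np.random.default_rng(np.random.SeedSequence((seed, rep))))
        for mi, mode in enumerate(modes):
            for ti, topo in enumerate(grid):
                for fi in range(n_folds):
                    test_pairs = folds[fi]
                    train_pairs = [p for j, f in enumerate(folds) if j != fi
                                   for p in f]
                    fit_seed = np.random.SeedSequence(
                        (seed, rep, mi, ti, fi))
                    weights = feat.fit_feature_weights(
                        train_pairs, processed,
                        np.random.default_rng(fit_seed))
                    signals = feat.apply_weights(processed, weights)
                    train_obs = feat.build_observations(train_pairs, signals,
                                                        ans, mode)
                    test_obs = feat.build_observations(test_pairs, signals,
                                                       ans, mode)
                    clf = train_dual_classifier(
                        train_obs, topo, n_restarts=n_restarts,
                        seed=np.random.SeedSequence((seed, rep, mi, ti, fi, 1)),
                        em_config=em_config)
                    counts = _counts_from_predictions(
                        [(classify(clf, o), o.label) for o in test_obs])
                    acc, sens, spec_ = compute_metrics(counts)
                    rows.append({"mode": mode, "n_states": topo.n_states,
                                 "n_mixtures": topo.n_mixtures, "repeat": rep,
                                 "fold": fi, "tp": counts.tp, "tn": counts.tn,
                                 "fp": counts.fp, "fn": counts.fn, "acc": acc,
                                 "sens": sens, "spec": spec_})
    records = pd.DataFrame(rows)
    n_trials = {mode: 2 * len(clean) for mode in modes}
    return PerformanceReport(records=records, n_trials=n_trials, modes=modes,
                             seed=seed, notes=notes)


def compare_decoders(report: PerformanceReport) -> pd.DataFrame:
    """Per-metric paired t-test (run level) and relative gain of the modes."""
    if not {"fnirs_only", "combined"} <= set(report.modes):
        raise ValueError("comparison requires both decoder modes")
    runs_f = report.selected_runs("fnirs_only")
    runs_c = report.selected_runs("combined")
    if len(runs_f) != len(runs_c):
        raise ValueError("unequal numbers of cross-validation runs")
    rows = []
    for m in METRICS:
        a, b = runs_f[m].to_numpy(), runs_c[m].to_numpy()
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(b, a)
        gain = 100.0 * (b.mean() - a.mean()) / a.mean()
        rows.append({"metric": m, "fnirs_only": 100 * a.mean(),
                     "combined": 100 * b.mean(), "gain_pct": gain,
                     "t_stat": float(t), "p_value": float(p)})
    return pd.DataFrame(rows)


def relative_gain(fnirs_value: float, combined_value: float) -> float:
    """Percent change of the combined decoder relative to fNIRS-only."""
    return 100.0 * (combined_value - fnirs_value) / fnirs_value


def summarize_group(fnirs: pd.DataFrame, combined: pd.DataFrame) -> dict:
    """Group-level aggregation of per-subject metric means (in percent).

    Both frames are indexed by subject with columns acc/sens/spec; only
    subjects present in both (i.e. with data for both decoder modes) enter
    the averages, matching how multi-subject summaries exclude subjects
    lacking one mode.  Gains are means of the per-subject relative gains;
    p-values are paired two-tailed t-tests across subjects.
    """
    common = fnirs.index.intersection(combined.index)
    if len(common) < 2:
        raise ValueError("need at least two subjects with both modes")
    f, c = fnirs.loc[common], combined.loc[common]
    out = {"subjects": list(common)}
    for m in METRICS:
        gains = relative_gain(f[m].to_numpy(), c[m].to_numpy())
        t, p = stats.ttest_rel(c[m], f[m])
        out[m] = {
            "fnirs_mean": float(f[m].mean()), "fnirs_sd": float(f[m].std(ddof=1)),
            "combined_mean": float(c[m].mean()),
            "combined_sd": float(c[m].std(ddof=1)),
            "gain_mean": float(np.mean(gains)),
            "gain_sd": float(np.std(gains, ddof=1)),
            "per_subject_gain": {str(s): float(g)
                                 for s, g in zip(common, gains)},
            "t_stat": float(t), "p_value": float(p),
        }
    return out
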