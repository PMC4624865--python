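"""The evaluation protocol: split, train, decode, score, select, compare.

Trials are split 50/50 at random within each (subject, symbol) group.
Models are fitted per subject on the training half — either one model
pooling all symbols ("within-group") or one model per symbol
("per-symbol") — then each test trial is decoded from its EMG envelopes
with a zero start state and scored per coordinate with the
explained-energy ratio

    R^2 = sum_i (shat_i - sbar)^2 / sum_i (s_i - sbar)^2,

where sbar is the mean of the *actual* trace. Note this ratio is not
bounded by 1 and is not literally a squared correlation; a squared-Pearson
alternative is available via ``metric="pearson"``. Per-symbol results are
summarised across subjects with Student-t 95% confidence intervals.

Model order (K state lags, L measurement lags) is selected on a grid by
maximising g = mean(R^2)/sd(R^2) over trials — accuracy weighted by
stability. Decoder comparisons use the one-sided Wilcoxon matched-pair
test on per-trial scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateTestError,
    InvalidInputError,
    MissingDataError,
    UndefinedMetricError,
)
from .fit import fit_model, prepare_trial
from .kalman import kf_decode, wiener_decode
from .preprocess import attach_envelopes

__all__ = [
    "EvalMetrics",
    "SplitPlan",
    "GridSearchResult",
    "ComparisonResult",
    "r_squared",
    "split_trials",
    "run_design",
    "grid_search_order",
    "compare_filters",
    "run_comparison",
]


def r_squared(actual, predicted, metric: str = "energy") -> float:
    """Reconstruction accuracy of one coordinate sequence.

    ``metric="energy"`` (default) is the explained-energy ratio
    sum((pred - mean(actual))^2) / sum((actual - mean(actual))^2);
    ``metric="pearson"`` is the squared Pearson correlation.
    """
    actual = np.asarray(actual, float)
    predicted = np.asarray(predicted, float)
    if actual.shape != predicted.shape or actual.ndim != 1 or actual.size < 2:
        raise InvalidInputError(
            f"need equal-length 1-D sequences of >= 2 samples; "
            f"got {actual.shape} and {predicted.shape}"
        )
    centred = actual - actual.mean()
    sst = float(np.dot(centred, centred))
    if sst == 0.0:
        raise UndefinedMetricError("actual sequence is constant; R^2 undefined")
    if metric == "energy":
        dev = predicted - actual.mean()
        return float(np.dot(dev, dev)) / sst
    if metric == "pearson":
        pdev = predicted - predicted.mean()
        sp = float(np.dot(pdev, pdev))
        if sp == 0.0:
            return 0.0
        return float(np.dot(centred, pdev)) ** 2 / (sst * sp)
    raise InvalidInputError(f"unknown metric {metric!r}")


@dataclass(frozen=True)
class SplitPlan:
    """Deterministic trial-id -> {'train', 'test'} assignment."""

    assignment: dict
    seed: int

    @property
    def train_ids(self) -> set:
        return {k for k, v in self.assignment.items() if v == "train"}

    @property
    def test_ids(self) -> set:
        return {k for k, v in self.assignment.items() if v == "test"}


def split_trials(trials, seed: int) -> SplitPlan:
    """Stratified random 50/50 split within each (subject, symbol) group.

    Group sizes of n give ceil(n/2) training trials. Reproducible given
    ``seed``; every group must have at least 2 trials.
    """
    groups: dict[tuple, list] = {}
    for t in trials:
        groups.setdefault((t.subject_id, int(t.symbol)), []).append(t.trial_id)
    rng = np.random.default_rng(seed)
    assignment = {}
    for key in sorted(groups):
        ids = sorted(groups[key])
        if len(ids) < 2:
            raise MissingDataError(
                f"subject {key[0]} symbol {key[1]}: {len(ids)} trials (need >= 2)"
            )
        perm = rng.permutation(len(ids))
        n_train = (len(ids) + 1) // 2
        for rank, i in enumerate(perm):
            assignment[ids[i]] = "train" if rank < n_train else "test"
    return SplitPlan(assignment=assignment, seed=seed)


@dataclass
class EvalMetrics:
    """Per-trial scores plus symbol- and subject-level aggregates."""

    per_trial: pd.DataFrame  # trial_id, subject_id, symbol, r2_x, r2_y, r2_avg
    design: str
    decoder: str
    K: int
    L: int
    seed: int | None = None
    metric: str = "energy"

    @property
    def g(self) -> float:
        """Accuracy/stability ratio mean(R^2)/sd(R^2) over trials (inf if sd=0)."""
        vals = self.per_trial["r2_avg"].to_numpy()
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        if sd == 0.0:
            return math.inf
        return float(np.mean(vals)) / sd

    def per_subject(self) -> pd.DataFrame:
        """Mean scores per subject (over all of that subject's test trials)."""
        return self.per_trial.groupby("subject_id")[["r2_x", "r2_y", "r2_avg"]].mean()

    def per_symbol_table(self) -> pd.DataFrame:
        """Per-symbol summary across subjects, with an 'All' row.

        For each symbol, trial scores are first averaged within each
        subject; the table reports the across-subject mean together with
        three dispersion measures (sd, sem, and the half-width of the
        Student-t 95% CI on the subject means).
        """
        cols = ["r2_x", "r2_y", "r2_avg"]
        subj_sym = self.per_trial.groupby(["symbol", "subject_id"])[cols].mean()
        rows = []
        symbols = sorted(self.per_trial["symbol"].unique())
        for label, frame in [
            *[(str(s), subj_sym.loc[s]) for s in symbols],
            ("All", self.per_subject()),
        ]:
            row: dict = {"symbol": label}
            n = len(frame)
            for c in cols:
                vals = frame[c].to_numpy()
                mean = float(np.mean(vals))
                sd = float(np.std(vals, ddof=1)) if n > 1 else float("nan")
                sem = sd / math.sqrt(n) if n > 1 else float("nan")
                ci95 = stats.t.ppf(0.975, n - 1) * sem if n > 1 else float("nan")
                row |= {f"{c}_mean": mean, f"{c}_sd": sd, f"{c}_sem": sem,
                        f"{c}_ci95": ci95}
            row["n_subjects"] = n
            rows.append(row)
        return pd.DataFrame(rows).set_index("symbol")


def run_design(
    trials,
    K: int = 1,
    L: int = 2,
    design: str = "within-group",
    seed: int = 0,
    decoder: str = "kf",
    metric: str = "energy",
    fc: float = 2.0,
    filter_order: int = 2,
    sqrt: bool = True,
    split: SplitPlan | None = None,
    ridge: float = 0.0,
) -> EvalMetrics:
    """Full protocol for one design: split, fit per subject, decode, score.

    Models are fitted per subject on the training half; every test trial is
    decoded with a zero start state and scored per coordinate.
    """
    if decoder not in ("kf", "wf"):
        raise InvalidInputError(f"unknown decoder {decoder!r}")
    trials = attach_envelopes(list(trials), fc=fc, order=filter_order, sqrt=sqrt)
    if split is None:
        split = split_trials(trials, seed)
    by_subject: dict[str, list] = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t)

    records = []
    for subject in sorted(by_subject):
        subj_trials = by_subject[subject]
        train = [t for t in subj_trials if split.assignment[t.trial_id] == "train"]
        test = [t for t in subj_trials if split.assignment[t.trial_id] == "test"]
        fitted = fit_model(
            train, K=K, L=L, design=design, fc=fc, filter_order=filter_order,
            sqrt=sqrt, ridge=ridge,
        )
        for trial in test:
            if design == "per-symbol":
                try:
                    model = fitted[int(trial.symbol)]
                except KeyError:
                    raise MissingDataError(
                        f"no per-symbol model for symbol {trial.symbol} "
                        f"(subject {subject})"
                    )
            else:
                model = fitted
            try:
                states, obs = prepare_trial(
                    trial, K=K, L=L, fc=fc, filter_order=filter_order, sqrt=sqrt
                )
                trace = (
                    kf_decode(model, obs) if decoder == "kf"
                    else wiener_decode(model, obs)
                )
                r2_x = r_squared(states.coords[:, 0], trace.xy[:, 0], metric)
                r2_y = r_squared(states.coords[:, 1], trace.xy[:, 1], metric)
            except Exception as exc:
                exc.add_note(f"while scoring trial {trial.trial_id}")
                raise
            records.append(
                {
                    "trial_id": trial.trial_id,
                    "subject_id": subject,
                    "symbol": int(trial.symbol),
                    "r2_x": r2_x,
                    "r2_y": r2_y,
                    "r2_avg": 0.5 * (r2_x + r2_y),
                }
            )
    per_trial = pd.DataFrame.from_records(records)
    return EvalMetrics(
        per_trial=per_trial, design=design, decoder=decoder, K=K, L=L,
        seed=split.seed, metric=metric,
    )


@dataclass
class GridSearchResult:
    table: pd.DataFrame  # K, L, mean_r2, sd_r2, g
    best: tuple[int, int] | None

    def g_map(self) -> pd.DataFrame:
        return self.table.pivot(index="K", columns="L", values="g")

    def r2_map(self) -> pd.DataFrame:
        return self.table.pivot(index="K", columns="L", values="mean_r2")


def grid_search_order(
    trials,
    K_range,
    L_range,
    seed: int = 0,
    design: str = "within-group",
    **kwargs,
) -> GridSearchResult:
    """Model-order selection by the accuracy/stability ratio g.

    The outer 50/50 split reserves the test half untouched; the grid is
    evaluated on the training half with an internal sub-split (seed + 1).
    For each (K, L), g = mean(R^2)/sd(R^2) over the inner test trials; a
    zero sd is reported as +inf and excluded from the argmax.
    """
    K_range = list(K_range)
    L_range = list(L_range)
    if not K_range or not L_range:
        raise InvalidInputError("K_range and L_range must be nonempty")
    trials = attach_envelopes(
        list(trials),
        fc=kwargs.get("fc", 2.0),
        order=kwargs.get("filter_order", 2),
        sqrt=kwargs.get("sqrt", True),
    )
    outer = split_trials(trials, seed)
    train_trials = [t for t in trials if outer.assignment[t.trial_id] == "train"]
    inner = split_trials(train_trials, seed + 1)
    rows = []
    for K in K_range:
        for L in L_range:
            metrics = run_design(
                train_trials, K=K, L=L, design=design, split=inner, **kwargs
            )
            vals = metrics.per_trial["r2_avg"].to_numpy()
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            g = math.inf if sd == 0.0 else mean / sd
            rows.append({"K": K, "L": L, "mean_r2": mean, "sd_r2": sd, "g": g})
    table = pd.DataFrame(rows)
    finite = table[np.isfinite(table["g"])]
    if len(finite):
        i = finite["g"].idxmax()
    else:  # all-degenerate grid: fall back to accuracy alone
        i = table["mean_r2"].idxmax()
    best = (int(table.loc[i, "K"]), int(table.loc[i, "L"]))
    return GridSearchResult(table=table, best=best)


def compare_filters(
    kf_scores,
    wf_scores,
    alternative: str = "greater",
    symbols=None,
):
    """One-sided Wilcoxon matched-pair test on per-trial score differences.

    Pairs must be matched by trial. Zero differences are dropped; the exact
    null distribution is used for n < 25 remaining pairs, the normal
    approximation with continuity correction otherwise. Returns
    (statistic, p_value, per_symbol_breakdown) where the breakdown is a
    DataFrame (or None if ``symbols`` is not given).
    """
    kf_scores = np.asarray(kf_scores, float)
    wf_scores = np.asarray(wf_scores, float)
    if kf_scores.shape != wf_scores.shape or kf_scores.ndim != 1:
        raise InvalidInputError("scores must be equal-length 1-D arrays")
    if kf_scores.size < 5:
        raise InvalidInputError(f"need >= 5 pairs; got {kf_scores.size}")
    stat, p = _wilcoxon(kf_scores - wf_scores, alternative)
    breakdown = None
    if symbols is not None:
        symbols = np.asarray(symbols)
        if symbols.shape != kf_scores.shape:
            raise InvalidInputError("symbols must align with the score arrays")
        rows = []
        for sym in sorted(np.unique(symbols)):
            mask = symbols == sym
            d = kf_scores[mask] - wf_scores[mask]
            if mask.sum() >= 5 and np.any(d != 0):
                s_stat, s_p = _wilcoxon(d, alternative)
            else:
                s_stat, s_p = float("nan"), float("nan")
            rows.append(
                {"symbol": sym, "n": int(mask.sum()),
                 "mean_diff": float(np.mean(d)), "statistic": s_stat, "p": s_p}
            )
        breakdown = pd.DataFrame(rows).set_index("symbol")
    return stat, p, breakdown


def _wilcoxon(diffs: np.ndarray, alternative: str):
    diffs = diffs[diffs != 0.0]
    if diffs.size == 0:
        raise DegenerateTestError("all paired differences are zero")
    n = diffs.size
    method = "exact" if n < 25 else "approx"
    try:
        res = stats.wilcoxon(
            diffs, alternative=alternative, zero_method="wilcox",
            method=method, correction=(method == "approx"),
        )
    except ValueError:
        # exact null unavailable (e.g. ties in |d|): normal approximation
        res = stats.wilcoxon(
            diffs, alternative=alternative, zero_method="wilcox",
            method="approx", correction=True,
        )
    return float(res.statistic), float(res.pvalue)


@dataclass
class ComparisonResult:
    """KF-vs-WF comparison plus the within/between design contrast."""

    within_kf: EvalMetrics
    within_wf: EvalMetrics
    between_kf: EvalMetrics
    wilcoxon_statistic: float
    wilcoxon_p: float
    per_symbol: pd.DataFrame
    seed: int


def run_comparison(
    trials,
    K: int = 1,
    L: int = 2,
    seed: int = 0,
    metric: str = "pearson",
    fc: float = 2.0,
    filter_order: int = 2,
    sqrt: bool = True,
) -> ComparisonResult:
    """Decode the same test trials with the KF and the WF and compare.

    The envelope is computed once and shared, the split is shared, and the
    within-group model behind both decoders is fitted on the same training
    trials — the decoders differ only in whether the dynamical model is
    used. Also runs the per-symbol (between-group) design for the
    design-contrast ordering.

    The default metric here is the squared Pearson correlation rather than
    the explained-energy ratio: the energy ratio credits prediction noise
    as "explained" energy, which systematically favours the noisier
    static decoder and would invert the comparison's meaning. See
    :func:`r_squared` for both metrics.
    """
    trials = attach_envelopes(
        list(trials), fc=fc, order=filter_order, sqrt=sqrt, drop_raw=True
    )
    split = split_trials(trials, seed)
    common = dict(
        K=K, L=L, seed=seed, metric=metric, fc=fc,
        filter_order=filter_order, sqrt=sqrt, split=split,
    )
    within_kf = run_design(trials, design="within-group", decoder="kf", **common)
    within_wf = run_design(trials, design="within-group", decoder="wf", **common)
    between_kf = run_design(trials, design="per-symbol", decoder="kf", **common)
    kf = within_kf.per_trial.sort_values("trial_id").reset_index(drop=True)
    wf = within_wf.per_trial.sort_values("trial_id").reset_index(drop=True)
    assert (kf["trial_id"] == wf["trial_id"]).all()
    stat, p, breakdown = compare_filters(
        kf["r2_avg"].to_numpy(), wf["r2_avg"].to_numpy(),
        symbols=kf["symbol"].to_numpy(),
    )
    return ComparisonResult(
        within_kf=within_kf, within_wf=within_wf, between_kf=between_kf,
        wilcoxon_statistic=stat, wilcoxon_p=p, per_symbol=breakdown, seed=seed,
    )
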