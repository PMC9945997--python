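"""Ripple-rate tables, cross-area temporal relations, ripple-locked spiking,
reaction-time modeling, and the associated statistics.

Rates: for a given session, epoch, and condition cell (cue location x
attentional focus x stimulus size) the ripple rate is

    events / (n_trials * epoch_duration)          [events/s]

computed per electrode and then averaged across electrodes, so each session
contributes one value per cell. Sessions are the repeated-measures unit of
the three-way RM-ANOVA and of the paired signed-rank comparisons.

Cross-area timing: the correlogram of V4-minus-V1 ripple times over
same-trial pairs is corrected by a shuffle predictor (the mean correlogram
after randomly permuting trial identities of one area), which removes
stimulus-locked covariation. The area under the corrected correlogram on
either side of lag zero quantifies lead-lag asymmetry; positive-lag excess
means the first area's ripples tend to precede the second's.

Trial-level models: reaction times or firing rates are fit with a linear
mixed-effects model with the task factors as categorical fixed effects and
a random intercept per session (REML), followed by per-factor Wald tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .io import EpochDefinition, epoch_windows

logger = logging.getLogger(__name__)

__all__ = [
    "CrossCorrelogram",
    "ModelResult",
    "PSTH",
    "epoch_condition_rates",
    "compare_rates_paired",
    "rm_anova3",
    "posthoc_signrank_fdr",
    "layer_anova",
    "cross_area_correlogram",
    "cooccurrence_probability",
    "matched_control_times",
    "ripple_locked_spike_rate",
    "fit_mixed_model",
]

CONDITION_COLS = ("cue_location", "focus", "stim_size")


# --------------------------------------------------------------------------
# rates
# --------------------------------------------------------------------------

def _count_in_windows(t: np.ndarray, windows: pd.DataFrame) -> np.ndarray:
    """Boolean mask: which times fall inside any [t_start, t_end) window."""
    inside = np.zeros(len(t), bool)
    for s, e in windows[["t_start", "t_end"]].itertuples(index=False):
        inside |= (t >= s) & (t < e)
    return inside


def epoch_condition_rates(
    events: pd.DataFrame,
    trials: pd.DataFrame,
    epochs: dict[str, EpochDefinition],
    channels: list,
    session: str | None = None,
) -> pd.DataFrame:
    """Ripple rate per epoch x condition cell for one session.

    Per-electrode rates (``channels`` enumerates the electrodes, including
    those with zero events) are averaged across electrodes to yield one
    value per cell. Cells with zero trials are absent from the output
    (logged). Returns tidy rows ``session, epoch, cue_location, focus,
    stim_size, rate, n_trials, n_events``.
    """
    if session is None:
        session = str(events["session"].iloc[0]) if len(events) else "s0"
    rows = []
    for epoch_name, epoch in epochs.items():
        for keys, cell in trials.groupby(list(CONDITION_COLS), observed=True):
            if len(cell) == 0:
                continue
            win = epoch_windows(cell, epoch)
            if len(win) == 0:
                logger.info("cell %s has no usable trials in %s", keys, epoch_name)
                continue
            t = events["t_center"].to_numpy(float)
            inside = _count_in_windows(t, win)
            ev = events[inside]
            per_electrode = [
                (ev["channel"] == ch).sum() / (len(win) * epoch.duration)
                for ch in channels
            ]
            rows.append(
                {
                    "session": session,
                    "epoch": epoch_name,
                    "cue_location": keys[0],
                    "focus": keys[1],
                    "stim_size": keys[2],
                    "rate": float(np.mean(per_electrode)),
                    "n_trials": len(win),
                    "n_events": int(inside.sum()),
                }
            )
    return pd.DataFrame(rows)


def compare_rates_paired(
    table: pd.DataFrame, factor: str, value: str = "rate"
) -> tuple[float, float, int]:
    """Two-sided Wilcoxon signed-rank test on session-paired rate
    differences between the two levels of ``factor``.

    Rates are first averaged within session and factor level (collapsing
    the other factors). Zero differences are dropped (standard convention);
    the exact null distribution is used for n < 20 when possible. Returns
    ``(W, p, n_nonzero_pairs)``.
    """
    piv = table.pivot_table(index="session", columns=factor, values=value, aggfunc="mean")
    if piv.shape[1] != 2:
        raise ValueError(f"factor {factor!r} must have exactly two levels")
    piv = piv.dropna()
    a, b = piv.iloc[:, 0].to_numpy(), piv.iloc[:, 1].to_numpy()
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return 0.0, 1.0, 0
    method = "exact" if len(d) < 20 else "approx"
    try:
        res = sps.wilcoxon(d, method=method)
    except ValueError:
        res = sps.wilcoxon(d, method="approx")
    return float(res.statistic), float(res.pvalue), int(len(d))


def rm_anova3(table: pd.DataFrame, value: str = "rate") -> pd.DataFrame:
    """Three-factor repeated-measures ANOVA on one epoch's rate table.

    Factors are cue location, attentional focus, and stimulus size; the
    session is the repeated-measures unit. Sessions with incomplete 2x2x2
    cells are excluded listwise (logged). Returns a DataFrame indexed by
    effect (mains, two-way and three-way interactions) with columns
    ``F, num_df, den_df, p``. Effects with zero between-cell variance are
    reported as F=0, p=1.
    """
    counts = table.groupby("session", observed=True).size()
    complete = counts[counts >= 8].index
    dropped = set(counts.index) - set(complete)
    if dropped:
        logger.info("excluding %d session(s) with incomplete cells: %s", len(dropped), sorted(dropped))
    data = table[table["session"].isin(complete)]
    if data["session"].nunique() < 3:
        raise ValueError("need at least 3 complete sessions")
    effects = [
        "cue_location", "focus", "stim_size",
        "cue_location:focus", "cue_location:stim_size", "focus:stim_size",
        "cue_location:focus:stim_size",
    ]
    if np.ptp(data[value].to_numpy(float)) == 0:
        # constant table: no effect and no error variance anywhere
        n = data["session"].nunique()
        return pd.DataFrame(
            {"F": 0.0, "num_df": 1.0, "den_df": float(n - 1), "p": 1.0}, index=effects
        )
    res = AnovaRM(
        data,
        depvar=value,
        subject="session",
        within=list(CONDITION_COLS),
        aggregate_func="mean",
    ).fit()
    out = res.anova_table.rename(
        columns={"F Value": "F", "Num DF": "num_df", "Den DF": "den_df", "Pr > F": "p"}
    )
    degenerate = ~np.isfinite(out["F"])
    out.loc[degenerate, "F"] = 0.0
    out.loc[degenerate, "p"] = 1.0
    return out


def posthoc_signrank_fdr(
    contrasts: list[tuple[str, np.ndarray, np.ndarray]], alpha: float = 0.05
) -> pd.DataFrame:
    """Signed-rank tests on a pre-declared family of paired contrasts, with
    Benjamini-Hochberg adjustment within the family.

    Each contrast is ``(name, x, y)`` of paired session values. Returns a
    DataFrame with raw and adjusted p-values and the rejection flag.
    """
    names, stats_, praw = [], [], []
    for name, x, y in contrasts:
        d = np.asarray(x, float) - np.asarray(y, float)
        d = d[d != 0]
        if len(d) == 0:
            w, p = 0.0, 1.0
        else:
            try:
                r = sps.wilcoxon(d, method="exact" if len(d) < 20 else "approx")
            except ValueError:
                r = sps.wilcoxon(d, method="approx")
            w, p = float(r.statistic), float(r.pvalue)
        names.append(name)
        stats_.append(w)
        praw.append(p)
    rej, padj, _, _ = multipletests(praw, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {"contrast": names, "W": stats_, "p_raw": praw, "p_adj": padj, "significant": rej}
    )


def layer_anova(rates: pd.DataFrame, value: str = "rate_per_contact"):
    """One-way ANOVA of ripple rates across layers with Tukey post hoc.

    ``rates`` needs a ``layer`` column and one value per observation
    (e.g. per session x layer). Returns ``(F, p, tukey_summary_frame)``.
    """
    groups = [g[value].to_numpy(float) for _, g in rates.groupby("layer", observed=True)]
    if len(groups) < 2:
        raise ValueError("need at least two layers")
    f, p = sps.f_oneway(*groups)
    tk = pairwise_tukeyhsd(rates[value].to_numpy(float), rates["layer"].to_numpy())
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return float(f), float(p), tukey


# --------------------------------------------------------------------------
# cross-area timing
# --------------------------------------------------------------------------

@dataclass
class CrossCorrelogram:
    """Shuffle-predictor-corrected lag histogram of B-minus-A event times.

    Positive lags mean A's events precede B's. ``auc_lead``/``auc_lag`` are
    the summed corrected counts at positive/negative lags; ``auc_test`` is
    the Wilcoxon signed-rank (statistic, p) on per-channel-pair AUC
    asymmetries, or None when too few pairs exist.
    """

    lags_ms: np.ndarray  # bin centers
    raw: np.ndarray
    predictor: np.ndarray
    corrected: np.ndarray
    auc_lead: float
    auc_lag: float
    n_pairs: int
    auc_test: tuple[float, float] | None = None


def _relative_times(events: pd.DataFrame, trials: pd.DataFrame, anchor: str) -> pd.DataFrame:
    anchors = trials.set_index("trial_id")[anchor]
    ev = events.dropna(subset=["trial_id"]).copy()
    ev["t_rel"] = ev["t_center"].to_numpy(float) - anchors.reindex(ev["trial_id"]).to_numpy(float)
    return ev.dropna(subset=["t_rel"])


def cross_area_correlogram(
    events_a: pd.DataFrame,
    events_b: pd.DataFrame,
    trials: pd.DataFrame,
    bin_ms: float = 5.0,
    max_lag_ms: float = 200.0,
    n_shuffles: int = 100,
    seed: int = 0,
    anchor: str = "t_stim_on",
) -> CrossCorrelogram:
    """Cross-correlogram of two areas' ripple times with shuffle correction.

    Events must carry ``trial_id`` (see
    :func:`ripplepipe.detect.label_events_by_epoch`). Same-trial pairs
    contribute ``t_B - t_A`` to the raw histogram; the predictor is the
    mean histogram over ``n_shuffles`` random permutations of B's trial
    identities (times kept trial-relative to ``anchor``), and
    ``corrected = raw - predictor``.
    """
    rng = np.random.default_rng(seed)
    ids = trials["trial_id"].tolist()
    if len(ids) < 2:
        raise ValueError("shuffle predictor undefined with fewer than 2 trials")
    eva = _relative_times(events_a, trials, anchor)
    evb = _relative_times(events_b, trials, anchor)
    a_by_trial = {t: g["t_rel"].to_numpy() for t, g in eva.groupby("trial_id")}
    b_by_trial = {t: g["t_rel"].to_numpy() for t, g in evb.groupby("trial_id")}
    a_ch = {t: g["channel"].to_numpy() for t, g in eva.groupby("trial_id")} if "channel" in eva else {}
    b_ch = {t: g["channel"].to_numpy() for t, g in evb.groupby("trial_id")} if "channel" in evb else {}

    # odd bin count with a zero-centered middle bin: bin centers land on
    # multiples of bin_ms and no bin edge sits exactly at lag 0
    max_lag = max_lag_ms * 1e-3
    n_side = int(round(max_lag_ms / bin_ms))
    n_bins = 2 * n_side + 1
    edges = (np.arange(n_bins + 1) - n_side - 0.5) * bin_ms * 1e-3
    centers = (edges[:-1] + edges[1:]) / 2 * 1e3

    def hist_for(mapping: dict) -> np.ndarray:
        h = np.zeros(n_bins)
        for ta, tb in mapping.items():
            if ta in a_by_trial and tb in b_by_trial:
                d = (b_by_trial[tb][None, :] - a_by_trial[ta][:, None]).ravel()
                h += np.histogram(d, bins=edges)[0]
        return h

    raw = hist_for({t: t for t in ids})
    # each permutation is accumulated together with its inverse, which
    # symmetrizes the predictor (identical A and B then yield an exactly
    # symmetric corrected correlogram) without biasing it
    pred = np.zeros(n_bins)
    for _ in range(n_shuffles):
        perm = rng.permutation(len(ids))
        pred += hist_for({ids[i]: ids[perm[i]] for i in range(len(ids))})
        pred += hist_for({ids[perm[i]]: ids[i] for i in range(len(ids))})
    pred /= 2 * n_shuffles
    corrected = raw - pred

    # the zero-centered bin is split evenly so lead + lag = total AUC
    mid = float(corrected[centers == 0].sum())
    auc_lead = float(corrected[centers > 0].sum()) + mid / 2
    auc_lag = float(corrected[centers < 0].sum()) + mid / 2

    # per channel-pair asymmetry test
    auc_test = None
    if a_ch and b_ch:
        lead: dict = {}
        lag: dict = {}

        def accumulate(mapping, sign):
            for ta, tb in mapping.items():
                if ta in a_by_trial and tb in b_by_trial:
                    d = b_by_trial[tb][None, :] - a_by_trial[ta][:, None]
                    ca = np.broadcast_to(a_ch[ta][:, None], d.shape)
                    cb = np.broadcast_to(b_ch[tb][None, :], d.shape)
                    sel = np.abs(d) <= max_lag
                    for dd, pa, pb in zip(d[sel], ca[sel], cb[sel]):
                        key = (pa, pb)
                        tgt = lead if dd > 0 else lag if dd < 0 else None
                        if tgt is not None:
                            tgt[key] = tgt.get(key, 0.0) + sign
        accumulate({t: t for t in ids}, 1.0)
        for _ in range(n_shuffles):
            perm = rng.permutation(len(ids))
            accumulate({ids[i]: ids[perm[i]] for i in range(len(ids))}, -0.5 / n_shuffles)
            accumulate({ids[perm[i]]: ids[i] for i in range(len(ids))}, -0.5 / n_shuffles)
        pairs = sorted(set(lead) | set(lag))
        asym = np.array([lead.get(k, 0.0) - lag.get(k, 0.0) for k in pairs])
        asym = asym[asym != 0]
        if len(asym) >= 5:
            try:
                r = sps.wilcoxon(asym, method="exact" if len(asym) < 20 else "approx")
                auc_test = (float(r.statistic), float(r.pvalue))
            except ValueError:
                pass

    return CrossCorrelogram(
        lags_ms=centers,
        raw=raw,
        predictor=pred,
        corrected=corrected,
        auc_lead=auc_lead,
        auc_lag=auc_lag,
        n_pairs=int(raw.sum()),
        auc_test=auc_test,
    )


def cooccurrence_probability(
    events_a: pd.DataFrame,
    events_b: pd.DataFrame,
    trials: pd.DataFrame,
    epoch: EpochDefinition,
) -> float:
    """Fraction of trials containing an area-A ripple (any contact, within
    the epoch) that also contain an area-B ripple in the same epoch."""
    win = epoch_windows(trials, epoch)
    ta = events_a["t_center"].to_numpy(float)
    tb = events_b["t_center"].to_numpy(float)
    n_a = n_both = 0
    for s, e in win[["t_start", "t_end"]].itertuples(index=False):
        has_a = np.any((ta >= s) & (ta < e))
        if has_a:
            n_a += 1
            if np.any((tb >= s) & (tb < e)):
                n_both += 1
    return n_both / n_a if n_a else float("nan")


# --------------------------------------------------------------------------
# ripple-locked spiking
# --------------------------------------------------------------------------

def matched_control_times(
    events: pd.DataFrame,
    trials: pd.DataFrame,
    epoch: EpochDefinition,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Condition- and time-matched ripple-free control times.

    For each event, a trial with the same condition cell and no event in
    the epoch is drawn with replacement, and the event's within-trial
    offset is transplanted onto it. Events with no eligible matched trial
    are dropped (logged). Returns a frame with ``t_center`` (control time),
    ``channel`` and ``source_index`` (row index of the original event).
    """
    from .io import _ANCHOR_COLUMN  # single source of anchor naming

    anchor_col = _ANCHOR_COLUMN[epoch.anchor]
    win = epoch_windows(trials, epoch)
    t = events["t_center"].to_numpy(float)
    with_event = set()
    for tid, s, e in win[["trial_id", "t_start", "t_end"]].itertuples(index=False):
        if np.any((t >= s) & (t < e)):
            with_event.add(tid)
    anchors = trials.set_index("trial_id")[anchor_col]
    cond_of = trials.set_index("trial_id")[list(CONDITION_COLS)]
    free = trials[~trials["trial_id"].isin(with_event) & trials[anchor_col].notna()]
    pools = {
        cond: g[["trial_id", anchor_col]].to_numpy()
        for cond, g in free.groupby(list(CONDITION_COLS), observed=True)
    }
    rows, dropped = [], 0
    for idx, ev in events.iterrows():
        tid = ev.get("trial_id")
        if pd.isna(tid) or tid not in anchors.index:
            dropped += 1
            continue
        pool = pools.get(tuple(cond_of.loc[tid]))
        if pool is None or len(pool) == 0:
            dropped += 1
            continue
        pick_tid, pick_anchor = pool[rng.integers(len(pool))]
        offset = ev["t_center"] - anchors.loc[tid]
        rows.append(
            {
                "t_center": pick_anchor + offset,
                "channel": ev.get("channel"),
                "source_index": idx,
                "trial_id": pick_tid,
            }
        )
    if dropped:
        logger.info("control matching dropped %d event(s) with no eligible trial", dropped)
    return pd.DataFrame(rows)


@dataclass
class PSTH:
    lags_ms: np.ndarray
    ripple_rate: np.ndarray  # Hz, mean across events
    ripple_sem: np.ndarray
    control_rate: np.ndarray
    control_sem: np.ndarray
    n_events: int
    n_control: int


def _event_psth(spike_times: dict, centers, channels, edges_s: np.ndarray) -> np.ndarray:
    """Per-event binned firing rates [n_events, n_bins] (Hz)."""
    widths = np.diff(edges_s)
    rates = []
    for c, ch in zip(centers, channels):
        st = spike_times.get(ch)
        if st is None:
            continue
        counts = np.diff(np.searchsorted(st, c + edges_s))
        rates.append(counts / widths)
    return np.asarray(rates, float)


def ripple_locked_spike_rate(
    spikes: pd.DataFrame,
    events: pd.DataFrame,
    trials: pd.DataFrame,
    epoch: EpochDefinition,
    window_ms: float = 200.0,
    bin_ms: float = 10.0,
    n_control_reps: int = 10,
    seed: int = 0,
) -> PSTH:
    """Peri-ripple firing-rate histogram with a matched-trial control.

    Spikes of the unit(s) on each event's own contact are binned around the
    event center (window of ``window_ms`` total, i.e. +-window/2; use 50
    for the narrow within-ripple estimate or 200 for the +-100 ms view).
    The control PSTH uses ripple-free trials matched on condition and
    within-trial time, resampled with replacement ``n_control_reps`` times
    and averaged over repetitions.
    """
    rng = np.random.default_rng(seed)
    spike_times = {
        ch: np.sort(g["t"].to_numpy(float)) for ch, g in spikes.groupby("channel")
    }
    half = window_ms / 2 * 1e-3
    n_bins = max(int(round(window_ms / bin_ms)), 1)
    edges = np.linspace(-half, half, n_bins + 1)
    lags_ms = (edges[:-1] + edges[1:]) / 2 * 1e3

    centers = events["t_center"].to_numpy(float)
    chans = events["channel"].to_numpy()
    rip = _event_psth(spike_times, centers, chans, edges)
    if len(rip) == 0:
        raise ValueError("no events with spikes on their contact")

    ctrl_reps = []
    n_ctrl = 0
    for _ in range(n_control_reps):
        ctrl = matched_control_times(events, trials, epoch, rng)
        if len(ctrl) == 0:
            continue
        c = _event_psth(
            spike_times, ctrl["t_center"].to_numpy(float), ctrl["channel"].to_numpy(), edges
        )
        if len(c):
            ctrl_reps.append(c.mean(axis=0))
            n_ctrl = max(n_ctrl, len(c))
    if ctrl_reps:
        ctrl_stack = np.asarray(ctrl_reps)
        control_rate = ctrl_stack.mean(axis=0)
        control_sem = ctrl_stack.std(axis=0, ddof=1) / np.sqrt(len(ctrl_stack)) if len(ctrl_reps) > 1 else np.zeros(n_bins)
    else:
        control_rate = np.full(n_bins, np.nan)
        control_sem = np.full(n_bins, np.nan)

    return PSTH(
        lags_ms=lags_ms,
        ripple_rate=rip.mean(axis=0),
        ripple_sem=rip.std(axis=0, ddof=1) / np.sqrt(len(rip)),
        control_rate=control_rate,
        control_sem=control_sem,
        n_events=len(rip),
        n_control=n_ctrl,
    )


# --------------------------------------------------------------------------
# trial-level mixed model
# --------------------------------------------------------------------------

_REFERENCE = {
    "cue_location": "away",
    "ripple": "none",
    "focus": "narrow",
    "stim_size": "large",
}


@dataclass
class ModelResult:
    """Fitted trial-level model: fixed-effect coefficients with SEs,
    per-factor Wald ANOVA, and the random-intercept variance (0 when the
    model fell back to pooled OLS)."""

    params: pd.Series
    bse: pd.Series
    anova: pd.DataFrame
    random_intercept_var: float
    pooled: bool
    result: object


def _model_formula(df: pd.DataFrame, response: str) -> tuple[str, pd.DataFrame]:
    df = df.copy()
    terms = []
    for col, ref in _REFERENCE.items():
        if col not in df.columns:
            continue
        if df[col].dtype == bool:
            df[col] = np.where(df[col], "ripple", "none")
        df[col] = df[col].astype(str)
        ref_level = ref if ref in set(df[col]) else sorted(df[col].unique())[0]
        terms.append(f"C({col}, Treatment('{ref_level}'))")
    if not terms:
        raise ValueError("no task factors found in the table")
    return f"{response} ~ " + " + ".join(terms), df


def _wald_anova(result, design_info) -> pd.DataFrame:
    """Per-term Wald chi-square tests on the fixed effects."""
    rows = []
    params = np.asarray(result.fe_params if hasattr(result, "fe_params") else result.params)
    cov = np.asarray(result.cov_params())[: len(params), : len(params)]
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(len(params))[sl]
        b = params[idx]
        v = cov[np.ix_(idx, idx)]
        try:
            stat = float(b @ np.linalg.solve(v, b))
        except np.linalg.LinAlgError:
            stat = np.nan
        df_num = len(idx)
        p = float(sps.chi2.sf(stat, df_num)) if np.isfinite(stat) else np.nan
        rows.append({"term": term, "wald_chi2": stat, "df": df_num, "p": p})
    return pd.DataFrame(rows).set_index("term")


def fit_mixed_model(
    df: pd.DataFrame,
    response: str = "rt_ms",
    force_pooled: bool = False,
) -> ModelResult:
    """Random-intercept linear model of a trial-level response.

    ``df`` has one row per trial with a ``session`` column and any of the
    task factors ``cue_location`` (reference: away), ``ripple`` (reference:
    none; boolean or multi-level e.g. none/V1/V4/both), ``focus``
    (reference: narrow) and ``stim_size`` (reference: large). The model is
    fit by REML with a per-session random intercept; a singular
    random-effect variance triggers a warning and a pooled OLS fallback.
    """
    formula, data = _model_formula(df, response)
    data = data.dropna(subset=[response])
    if not force_pooled and data["session"].nunique() >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = smf.mixedlm(formula, data, groups=data["session"])
                res = model.fit(reml=True)
                re_var = float(np.asarray(res.cov_re)[0, 0])
                if np.isfinite(re_var) and re_var > 1e-10:
                    anova = _wald_anova(res, model.data.design_info)
                    return ModelResult(
                        params=res.fe_params,
                        bse=res.bse_fe,
                        anova=anova,
                        random_intercept_var=re_var,
                        pooled=False,
                        result=res,
                    )
                logger.warning("singular random-intercept variance; falling back to pooled OLS")
            except Exception as exc:  # convergence failure
                logger.warning("mixed-model fit failed (%s); falling back to pooled OLS", exc)
    model = smf.ols(formula, data)
    res = model.fit()
    anova = _wald_anova(res, model.data.design_info)
    return ModelResult(
        params=res.params,
        bse=res.bse,
        anova=anova,
        random_intercept_var=0.0,
        pooled=True,
        result=res,
    )
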