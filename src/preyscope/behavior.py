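"""Eye-trace analytics and the behavioral feature-compound response model.

Hunting initiation in larval zebrafish is marked by a convergent saccade:
a rapid nasal rotation of both eyes within 150 ms of one another.  This
module detects those events from binocular traces, measures their
kinematics, classifies them as visually evoked or spontaneous, and models
the probability of a hunting response as a logistic function of the four
binary stimulus features (direction, speed, size, contrast polarity),
including forward stepwise term selection scored by a cross-validated R^2
on per-stimulus response rates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .stimulus import (
    N_SPOT_STIMULI,
    StimulusEpoch,
    epoch_at,
    feature_code,
    spot_azimuth,
)
from .synthdata.eyes import EyeTrace

MAIN_EFFECTS = ("direction", "speed", "size", "polarity")

#: terms of the best behavioral model
BEST_MODEL_TERMS = ("size", "polarity", "speed:size:polarity")


class SeparationError(RuntimeError):
    """Raised when a logistic fit is degenerate (all 0s or all 1s)."""


# ---------------------------------------------------------------------------
# vergence and saccade detection
# ---------------------------------------------------------------------------

def compute_vergence(trace: EyeTrace) -> np.ndarray:
    """Vergence angle time series: sum of the nasal-positive channels."""
    if trace.left.shape != trace.right.shape:
        raise ValueError("left/right channels differ in length")
    return trace.left + trace.right


@dataclass
class DetectorParams:
    """Convergent-saccade detector configuration.

    The 150 ms onset-asynchrony pairing rule is the defining criterion;
    velocity and displacement gates reject tracker noise.  The displacement
    gate (3 deg/eye) sits just below the smallest physiological convergence
    the simulator produces, so the amplitude distribution is not censored.
    """

    smooth_window_s: float = 0.05
    velocity_threshold: float = 60.0        # deg/s, per-eye nasal velocity
    min_displacement_deg: float = 3.0       # per-eye nasal displacement
    max_asynchrony_s: float = 0.150
    refractory_s: float = 1.0
    pre_window: tuple[float, float] = (-0.25, -0.05)
    post_window: tuple[float, float] = (0.15, 0.35)
    peak_velocity_span_s: float = 0.4
    merge_gap_s: float = 0.120


@dataclass
class SaccadeEvent:
    """A detected (or annotated) convergent saccade with its kinematics."""

    onset_time: float
    pre_left: float = math.nan
    pre_right: float = math.nan
    post_left: float = math.nan
    post_right: float = math.nan
    delta_left: float = math.nan
    delta_right: float = math.nan
    peak_velocity_left: float = math.nan
    peak_velocity_right: float = math.nan
    evoked: bool = False
    epoch_index: Optional[int] = None
    spot_azimuth_at_event: Optional[float] = None

    @property
    def dvergence(self) -> float:
        return self.delta_left + self.delta_right

    def eye(self, side: str) -> dict:
        side = side.upper()
        if side not in ("L", "R"):
            raise ValueError("side must be 'L' or 'R'")
        sfx = "left" if side == "L" else "right"
        return {
            "post": getattr(self, f"post_{sfx}"),
            "delta": getattr(self, f"delta_{sfx}"),
            "peak_velocity": getattr(self, f"peak_velocity_{sfx}"),
        }


def _smooth(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    w = max(1, int(round(window_s * fs)))
    if w <= 1:
        return x.astype(float)
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def _candidate_onsets(chan: np.ndarray, fs: float, p: DetectorParams) -> np.ndarray:
    """Sample indices where nasal velocity first exceeds threshold.

    Velocity is a raw first difference (saccades last only a couple of
    samples at 60 Hz; smoothing here would hide small events).  Runs of
    suprathreshold samples closer than ``merge_gap_s`` collapse to one
    onset.
    """
    v = np.diff(chan) * fs
    above = np.flatnonzero(v > p.velocity_threshold)
    if above.size == 0:
        return above
    gap = max(1, int(round(p.merge_gap_s * fs)))
    keep = [above[0]]
    for i in above[1:]:
        if i - keep[-1] > gap:
            keep.append(i)
        else:
            keep[-1] = keep[-1]  # onset stays at the first crossing
    return np.asarray(keep)


def _window_mean(chan, fs, onset_idx, window):
    i0 = onset_idx + int(round(window[0] * fs))
    i1 = onset_idx + int(round(window[1] * fs))
    if i0 < 0 or i1 > chan.size or i1 <= i0:
        return None
    return float(np.mean(chan[i0:i1]))


def detect_convergent_saccades(
    trace: EyeTrace, params: Optional[DetectorParams] = None
) -> list[SaccadeEvent]:
    """Detect convergent saccades: paired nasal rotations of both eyes.

    Both eyes must show a suprathreshold nasal velocity with onsets within
    150 ms of one another and a confirmed nasal displacement (post-window
    mean minus pre-window mean) of at least ``min_displacement_deg``.
    The event onset is the earlier eye's threshold crossing.
    """
    if params is None:
        params = DetectorParams()
    fs = trace.fs
    if trace.n < max(2, int(round(params.smooth_window_s * fs)) + 1):
        raise ValueError("trace shorter than the smoothing window")

    on_l = _candidate_onsets(trace.left, fs, params)
    on_r = _candidate_onsets(trace.right, fs, params)
    if on_l.size == 0 or on_r.size == 0:
        return []

    max_async = int(round(params.max_asynchrony_s * fs))
    refractory = int(round(params.refractory_s * fs))

    events: list[SaccadeEvent] = []
    last_onset = -10 * refractory
    j = 0
    for i in on_l:
        # nearest right-eye candidate
        while j + 1 < on_r.size and abs(on_r[j + 1] - i) <= abs(on_r[j] - i):
            j += 1
        if abs(int(on_r[j]) - int(i)) > max_async:
            continue
        onset_idx = min(int(i), int(on_r[j]))
        if onset_idx - last_onset < refractory:
            continue
        dl = _displacement(trace.left, fs, onset_idx, params)
        dr = _displacement(trace.right, fs, onset_idx, params)
        if dl is None or dr is None:
            continue
        if dl < params.min_displacement_deg or dr < params.min_displacement_deg:
            continue
        ev = SaccadeEvent(onset_time=trace.t0 + onset_idx / fs)
        saccade_kinematics(ev, trace, params)
        events.append(ev)
        last_onset = onset_idx
    return events


def _displacement(chan, fs, onset_idx, params: DetectorParams):
    pre = _window_mean(chan, fs, onset_idx, params.pre_window)
    post = _window_mean(chan, fs, onset_idx, params.post_window)
    if pre is None or post is None:
        return None
    return post - pre


def saccade_kinematics(
    event: SaccadeEvent,
    trace: EyeTrace,
    params: Optional[DetectorParams] = None,
) -> SaccadeEvent:
    """Fill pre/post positions, displacement and peak nasal velocity.

    Pre/post positions are window means; peak velocity is the maximum of
    the smoothed nasal derivative within ``peak_velocity_span_s`` of onset.
    """
    if params is None:
        params = DetectorParams()
    fs = trace.fs
    onset_idx = int(round((event.onset_time - trace.t0) * fs))
    for side, chan in (("left", trace.left), ("right", trace.right)):
        pre = _window_mean(chan, fs, onset_idx, params.pre_window)
        post = _window_mean(chan, fs, onset_idx, params.post_window)
        if pre is None or post is None:
            raise ValueError("kinematics window exceeds trace bounds")
        sm_chan = _smooth(chan, fs, params.smooth_window_s)
        v = np.diff(sm_chan) * fs
        i1 = min(v.size, onset_idx + int(round(params.peak_velocity_span_s * fs)))
        i0 = max(0, onset_idx - 1)
        pv = float(np.max(v[i0:i1])) if i1 > i0 else math.nan
        setattr(event, f"pre_{side}", pre)
        setattr(event, f"post_{side}", post)
        setattr(event, f"delta_{side}", post - pre)
        setattr(event, f"peak_velocity_{side}", pv)
    return event


def classify_evoked(
    events: Sequence[SaccadeEvent], schedule: Sequence[StimulusEpoch]
) -> list[SaccadeEvent]:
    """Label events evoked iff they fall in a spot-presentation interval."""
    for ev in events:
        ep = epoch_at(schedule, ev.onset_time)
        ev.evoked = False
        ev.epoch_index = None
        ev.spot_azimuth_at_event = None
        if ep is None or ep.is_flash:
            continue
        if ep.spot_onset <= ev.onset_time <= ep.spot_offset:
            ev.evoked = True
            ev.epoch_index = ep.epoch_index
            ev.spot_azimuth_at_event = spot_azimuth(ep, ev.onset_time)
    return list(events)


# ---------------------------------------------------------------------------
# response statistics
# ---------------------------------------------------------------------------

def response_location_stats(
    events: Sequence[SaccadeEvent],
    schedule: Optional[Sequence[StimulusEpoch]] = None,
) -> dict:
    """Spot-location statistics at the moment of evoked convergences.

    Returns the median azimuth with a signed-rank test against 0, and
    Kolmogorov-Smirnov comparisons of the azimuth distributions for
    left-to-right vs right-to-left spots and (after mirroring right-to-left
    azimuths so all events read as left-to-right motion) slow vs fast spots.
    """
    evoked = [e for e in events if e.evoked and e.spot_azimuth_at_event is not None]
    if not evoked:
        raise ValueError("no evoked events")
    az = np.array([e.spot_azimuth_at_event for e in evoked])
    out: dict = {"n": az.size, "median_azimuth": float(np.median(az))}
    if np.any(az != 0):
        out["signed_rank_p"] = float(stats.wilcoxon(az)[1])
    else:
        out["signed_rank_p"] = 1.0

    if schedule is not None:
        codes = {}
        for e in evoked:
            ep = schedule[e.epoch_index]
            codes[id(e)] = ep.feature_code
        l2r = az[[codes[id(e)][0] == 1 for e in evoked]]
        r2l = az[[codes[id(e)][0] == 0 for e in evoked]]
        if l2r.size and r2l.size:
            out["direction_ks_p"] = float(stats.ks_2samp(l2r, r2l)[1])
        mirrored = np.array(
            [a if codes[id(e)][0] == 1 else -a for e, a in zip(evoked, az)]
        )
        slow = mirrored[[codes[id(e)][1] == 0 for e in evoked]]
        fast = mirrored[[codes[id(e)][1] == 1 for e in evoked]]
        if slow.size and fast.size:
            out["speed_ks_p"] = float(stats.ks_2samp(slow, fast)[1])
    return out


def response_rate_table(
    events: Sequence[SaccadeEvent], schedule: Sequence[StimulusEpoch]
) -> pd.DataFrame:
    """Response rate R per moving-spot stimulus.

    R(s) = (# epochs of stimulus s containing an evoked event) / (# epochs
    of s).  One row per stimulus id 0-15 with the 4-bit feature code.
    """
    if not schedule:
        raise ValueError("empty schedule")
    responded_epochs = {e.epoch_index for e in events if e.evoked}
    rows = []
    for sid in range(N_SPOT_STIMULI):
        eps = [ep for ep in schedule if ep.stimulus_id == sid]
        n = len(eps)
        k = sum(ep.epoch_index in responded_epochs for ep in eps)
        d, s, z, p = feature_code(sid)
        rows.append(
            {
                "stimulus_id": sid,
                "direction": d,
                "speed": s,
                "size": z,
                "polarity": p,
                "n_trials": n,
                "n_responses": k,
                "rate": k / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def trial_table(
    events: Sequence[SaccadeEvent], schedule: Sequence[StimulusEpoch]
) -> pd.DataFrame:
    """Per-trial table (one row per spot epoch): feature bits + responded."""
    responded_epochs = {e.epoch_index for e in events if e.evoked}
    rows = []
    for ep in schedule:
        if ep.is_flash:
            continue
        d, s, z, p = ep.feature_code
        rows.append(
            {
                "epoch_index": ep.epoch_index,
                "stimulus_id": ep.stimulus_id,
                "direction": d,
                "speed": s,
                "size": z,
                "polarity": p,
                "responded": int(ep.epoch_index in responded_epochs),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic feature-compound model
# ---------------------------------------------------------------------------

@dataclass
class BehaviorModel:
    """Fitted logistic model of hunting-response probability."""

    terms: tuple[str, ...]
    coefficients: dict[str, float]
    conf_int: dict[str, tuple[float, float]] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    cv_r2: Optional[float] = None
    separation_flag: bool = False

    @property
    def odds_ratios(self) -> dict[str, float]:
        return {k: math.exp(v) for k, v in self.coefficients.items()}

    def linear_predictor(self, code: Sequence[int]) -> float:
        bits = dict(zip(MAIN_EFFECTS, code))
        eta = self.coefficients.get("intercept", 0.0)
        for term in self.terms:
            x = 1.0
            for factor in term.split(":"):
                x *= bits[factor]
            eta += self.coefficients[term] * x
        return eta

    def predict(self, code: Sequence[int]) -> float:
        return 1.0 / (1.0 + math.exp(-self.linear_predictor(code)))


def predict_response_rate(model: BehaviorModel, code: Sequence[int]) -> float:
    """Inverse-logit of the model's linear predictor for a 4-bit code."""
    if len(code) != 4 or any(b not in (0, 1) for b in code):
        raise ValueError("feature code must be four binary values")
    return model.predict(code)


def _term_design(table: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(table))]
    for term in terms:
        x = np.ones(len(table))
        for factor in term.split(":"):
            if factor not in table.columns:
                raise KeyError(f"trial table lacks feature column '{factor}'")
            x = x * table[factor].to_numpy(dtype=float)
        cols.append(x)
    return np.column_stack(cols)


def _aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-trial table to per-stimulus success/failure counts."""
    grouped = table.groupby(list(MAIN_EFFECTS), as_index=False).agg(
        successes=("responded", "sum"), n=("responded", "size")
    )
    grouped["failures"] = grouped["n"] - grouped["successes"]
    return grouped


def fit_logistic_model(
    table: pd.DataFrame, terms: Sequence[str] = BEST_MODEL_TERMS
) -> BehaviorModel:
    """Maximum-likelihood logistic fit of `responded` on feature terms.

    The per-trial table is collapsed to per-stimulus binomial counts (an
    equivalent likelihood) before fitting; Wald 95% CIs and p values are
    reported per coefficient.
    """
    agg = _aggregate(table)
    total_succ = agg["successes"].sum()
    if total_succ == 0 or agg["failures"].sum() == 0:
        raise SeparationError("responses are all 0 or all 1; model is degenerate")
    X = _term_design(agg, terms)
    endog = agg[["successes", "failures"]].to_numpy(dtype=float)
    glm = sm.GLM(endog, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = glm.fit()
    names = ["intercept", *terms]
    coefs = dict(zip(names, map(float, res.params)))
    ci = res.conf_int()
    conf = {n: (float(ci[i][0]), float(ci[i][1])) for i, n in enumerate(names)}
    pvals = dict(zip(names, map(float, res.pvalues)))
    # quasi-separation shows up as exploding Wald SEs
    separated = bool(np.any(res.bse > 50))
    return BehaviorModel(
        terms=tuple(terms),
        coefficients=coefs,
        conf_int=conf,
        p_values=pvals,
        separation_flag=separated,
    )


def cross_validated_r2(
    table: pd.DataFrame,
    terms: Sequence[str],
    n_splits: int = 10,
    seed: int = 0,
) -> float:
    """cvR^2 of a term set on per-stimulus response rates.

    Trials are randomly halved (stratified by stimulus); the model is fitted
    on one half and its predicted per-stimulus rates are scored against the
    observed rates of the unseen half as an R^2, averaged over splits.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    rng = np.random.default_rng(seed)
    scores = []
    codes = table[list(MAIN_EFFECTS)].to_numpy(dtype=int)
    sid = codes @ np.array([8, 4, 2, 1])
    y = table["responded"].to_numpy(dtype=float)
    for _ in range(n_splits):
        mask = np.zeros(len(table), dtype=bool)
        for s in np.unique(sid):
            idx = np.flatnonzero(sid == s)
            half = rng.permutation(idx)[: idx.size // 2]
            mask[half] = True
        train = table[mask]
        try:
            model = fit_logistic_model(train, terms)
        except SeparationError:
            scores.append(0.0)
            continue
        obs, pred = [], []
        for s in np.unique(sid):
            test_idx = (~mask) & (sid == s)
            if not np.any(test_idx):
                continue
            obs.append(float(np.mean(y[test_idx])))
            code = codes[np.flatnonzero(sid == s)[0]]
            pred.append(model.predict(code))
        obs = np.asarray(obs)
        pred = np.asarray(pred)
        ss_tot = float(np.sum((obs - obs.mean()) ** 2))
        if ss_tot == 0:
            scores.append(0.0)
            continue
        scores.append(1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot)
    return float(np.mean(scores))


def candidate_terms(max_order: int = 4) -> list[str]:
    """All feature main effects and interactions up to ``max_order``."""
    from itertools import combinations

    terms = []
    for k in range(1, max_order + 1):
        for combo in combinations(MAIN_EFFECTS, k):
            terms.append(":".join(combo))
    return terms


def stepwise_select(
    table: pd.DataFrame,
    candidates: Optional[Sequence[str]] = None,
    n_splits: int = 10,
    seed: int = 0,
    min_improvement: float = 0.01,
) -> BehaviorModel:
    """Forward stepwise term selection scored by cross-validated R^2.

    Starting from the intercept-only model, the term whose addition most
    improves the mean cvR^2 is added while the improvement exceeds
    ``min_improvement``.  The returned model is refitted on all trials and
    carries the winning cvR^2.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if candidates is None:
        candidates = candidate_terms()
    remaining = list(candidates)
    chosen: list[str] = []
    best_score = 0.0  # intercept-only predicts a constant rate: R^2 = 0
    improved = True
    step_seed = seed
    while improved and remaining:
        improved = False
        trial_scores = {
            term: cross_validated_r2(table, [*chosen, term], n_splits, step_seed)
            for term in remaining
        }
        term, score = max(trial_scores.items(), key=lambda kv: kv[1])
        if score > best_score + min_improvement:
            chosen.append(term)
            remaining.remove(term)
            best_score = score
            improved = True
        step_seed += 1
    if not chosen:
        rate = float(table["responded"].mean())
        eps = 1e-9
        rate = min(max(rate, eps), 1 - eps)
        return BehaviorModel(
            terms=(),
            coefficients={"intercept": math.log(rate / (1 - rate))},
            cv_r2=0.0,
        )
    model = fit_logistic_model(table, chosen)
    model.cv_r2 = best_score
    return model


# ---------------------------------------------------------------------------
# angular geometry of natural prey
# ---------------------------------------------------------------------------

def angular_geometry(
    object_size_mm: float,
    distance_mm: float,
    speed_mm_s: Optional[float] = None,
) -> tuple[float, Optional[float]]:
    """Angular size and speed of an object at a viewing distance.

    Size subtends ``2*atan(size / (2*distance))``; tangential angular speed
    uses the small-angle rate ``speed / distance`` (rad/s) in deg/s.  E.g. a
    135 um Paramecium 0.5 mm away subtends ~15 deg.
    """
    if distance_mm <= 0:
        raise ValueError("distance must be positive")
    if object_size_mm < 0:
        raise ValueError("object size must be non-negative")
    angle = math.degrees(2.0 * math.atan(object_size_mm / (2.0 * distance_mm)))
    speed = None
    if speed_mm_s is not None:
        if speed_mm_s < 0:
            raise ValueError("speed must be non-negative")
        speed = math.degrees(speed_mm_s / distance_mm)
    return angle, speed
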