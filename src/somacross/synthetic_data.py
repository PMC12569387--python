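"""Seeded generators for every input of the crossover pipeline.

The study design is a randomized, sham-controlled, two-period crossover:
every participant receives both a 3 h repetitive somatosensory
stimulation (RSS) of the right index finger and a sham protocol, in
counterbalanced order, with the four tasks (2PDT, TMT, TDJT, TLT)
measured before (pre) and after (post) each intervention.

This module simulates

* the stimulation trains themselves (Poisson-process pulse trains with
  bounded inter-stimulus intervals; sham = six short blocks),
* the order randomization of the crossover,
* per-trial response tables for all four tasks from parametric
  observers with known ground truth, so that the downstream fitting and
  inference layers can be validated by parameter recovery.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "TWO_PDT_LEVELS",
    "TMT_LEVELS",
    "TDJT_DISTANCES",
    "TDJT_POSITIONS",
    "PHALANGES",
    "DesignSpec",
    "ObserverParams",
    "StimTrain",
    "generate_crossover_design",
    "generate_stim_train",
    "simulate_binary_task",
    "simulate_distance_task",
    "simulate_localization_task",
    "inject_missing_and_outliers",
    "simulate_pse_table",
    "sample_observer",
    "simulate_study",
]

# Stimulus sets fixed by the task designs.
TWO_PDT_LEVELS: tuple[float, ...] = (0.0, 0.7, 1.0, 1.3, 1.6, 1.9, 2.2, 2.5)
"""2PDT probe separations in mm; 0 encodes the single-tip probe."""

TMT_LEVELS: tuple[float, ...] = (-12.0, -9.0, -6.0, -3.0, 0.0, 3.0, 6.0, 9.0, 12.0)
"""TMT image area distortions in % relative to the real finger."""

TDJT_DISTANCES: tuple[float, ...] = (15.0, 30.0)
TDJT_POSITIONS: tuple[str, ...] = ("base", "tip")
PHALANGES: tuple[str, ...] = ("proximal", "middle", "distal")

INTERVENTIONS: tuple[str, ...] = ("sham", "RSS")
SESSIONS: tuple[str, ...] = ("pre", "post")

# RSS pulse-train constants: 10 ms pulses, ISIs bounded to [0.1 s, 3 s],
# mean rate 1 Hz; sham delivers six 2.5 min blocks (15 min active) over 3 h.
ISI_LOW_S = 0.1
ISI_HIGH_S = 3.0
ISI_MEAN_S = 1.0
PULSE_WIDTH_MS = 10.0
RSS_DURATION_S = 3 * 3600.0
SHAM_N_BLOCKS = 6
SHAM_BLOCK_S = 150.0


# ---------------------------------------------------------------------------
# design


@dataclass(frozen=True)
class DesignSpec:
    """Randomized order assignment of the 2x2 crossover."""

    n_participants: int
    order_assignment: tuple[str, ...]  # "RSS-first" | "sham-first" per participant
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": [f"P{i + 1:02d}" for i in range(self.n_participants)],
                "order": self.order_assignment,
            }
        )


def generate_crossover_design(n_participants: int, seed: int) -> DesignSpec:
    """Randomly assign intervention order, balanced to within one.

    Half of the participants receive RSS first and half sham first; for
    odd n the group sizes differ by one, the larger group being chosen
    at random.
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    rng = np.random.default_rng(seed)
    half = n_participants // 2
    labels = ["RSS-first"] * half + ["sham-first"] * half
    if n_participants % 2:
        labels.append(str(rng.choice(["RSS-first", "sham-first"])))
    rng.shuffle(labels)
    return DesignSpec(n_participants, tuple(labels), seed)


# ---------------------------------------------------------------------------
# stimulation trains


@dataclass(frozen=True)
class StimTrain:
    """A pulse train of one 3 h intervention."""

    protocol: str  # "RSS" | "sham"
    pulse_times: np.ndarray  # seconds from protocol start, strictly increasing
    duration: float  # seconds
    pulse_width: float = PULSE_WIDTH_MS  # ms
    blocks: tuple[tuple[float, float], ...] | None = None  # sham (start, stop)

    @property
    def mean_rate(self) -> float:
        """Pulses per second over the whole protocol."""
        return len(self.pulse_times) / self.duration

    @property
    def active_time(self) -> float:
        """Seconds during which pulses may occur (block time for sham)."""
        if self.blocks is None:
            return self.duration
        return float(sum(b - a for a, b in self.blocks))


@lru_cache(maxsize=None)
def _truncated_exp_rate(low: float, high: float, target_mean: float) -> float:
    """Rate of an exponential truncated to [low, high] whose mean is target_mean.

    The truncated mean is 1/lam + (low*e^{-lam*low} - high*e^{-lam*high})
    / (e^{-lam*low} - e^{-lam*high}); it decreases monotonically from
    (low+high)/2 at lam -> 0 to low as lam -> inf, so the root is unique.
    """
    if not (low < target_mean < (low + high) / 2):
        raise ValueError("target mean unreachable for truncation bounds")

    def mean_minus_target(lam: float) -> float:
        el, eh = math.exp(-lam * low), math.exp(-lam * high)
        return 1.0 / lam + (low * el - high * eh) / (el - eh) - target_mean

    return brentq(mean_minus_target, 1e-9, 100.0, xtol=1e-12, rtol=1e-14)


def _sample_truncated_exp_isis(
    rng: np.random.Generator, n: int, low: float = ISI_LOW_S, high: float = ISI_HIGH_S
) -> np.ndarray:
    """Inverse-CDF draws from the calibrated bounded-ISI distribution."""
    lam = _truncated_exp_rate(low, high, ISI_MEAN_S)
    u = rng.random(n)
    el, eh = math.exp(-lam * low), math.exp(-lam * high)
    return -np.log(el - u * (el - eh)) / lam


def _fill_with_pulses(rng: np.random.Generator, duration: float) -> np.ndarray:
    """Pulse times in [0, duration): start at 0, step by bounded ISIs."""
    n_guess = int(duration / ISI_MEAN_S * 1.2) + 16
    times = [0.0]
    t = 0.0
    while True:
        for isi in _sample_truncated_exp_isis(rng, n_guess):
            t += isi
            if t >= duration:
                return np.asarray(times)
            times.append(t)


def generate_stim_train(
    protocol: str, duration: float = RSS_DURATION_S, seed: int = 0
) -> StimTrain:
    """Simulate one intervention's pulse train.

    RSS: a Poisson-like train whose inter-stimulus intervals are drawn
    from an exponential distribution truncated to [100 ms, 3000 ms],
    with the rate calibrated numerically so the truncated mean is
    exactly 1 s (average stimulation frequency 1 Hz).

    Sham: six blocks of 2.5 min (15 min active time over the 3 h),
    placed at equal intervals across the protocol, with within-block
    pulses drawn exactly as in RSS.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    if protocol == "RSS":
        return StimTrain("RSS", _fill_with_pulses(rng, duration), duration)
    if protocol == "sham":
        segment = duration / SHAM_N_BLOCKS
        if segment < SHAM_BLOCK_S:
            raise ValueError("duration too short for six 2.5 min sham blocks")
        starts = [i * segment + (segment - SHAM_BLOCK_S) / 2 for i in range(SHAM_N_BLOCKS)]
        blocks = tuple((s, s + SHAM_BLOCK_S) for s in starts)
        times = np.concatenate(
            [s + _fill_with_pulses(rng, SHAM_BLOCK_S) for s, _ in blocks]
        )
        return StimTrain("sham", times, duration, blocks=blocks)
    raise ValueError(f"unknown protocol {protocol!r}; expected 'RSS' or 'sham'")


# ---------------------------------------------------------------------------
# observers


def _default_localization_bias() -> dict[str, np.ndarray]:
    # Signs follow the systematic localization pattern: proximo-ulnar
    # bias on distal and middle phalanges, radial bias on the proximal
    # phalanx (units: fraction of finger length).
    return {
        "proximal": np.array([0.02, 0.0]),
        "middle": np.array([-0.02, -0.05]),
        "distal": np.array([-0.02, -0.05]),
    }


def _default_localization_cov() -> dict[str, np.ndarray]:
    # Scatter grows from fingertip to base (smaller ellipses distally).
    return {
        "proximal": np.diag([0.065, 0.065]) ** 2,
        "middle": np.diag([0.06, 0.06]) ** 2,
        "distal": np.diag([0.04, 0.04]) ** 2,
    }


@dataclass
class ObserverParams:
    """Generative parameters of one simulated participant.

    Binary tasks respond "two"/"larger" with probability
    ``lapse/2 + (1-lapse) * logistic(slope * (x - pse))``; the distance
    judge maps true distance linearly with additive Gaussian noise; the
    localization observer displaces each touch by a phalanx-specific
    bias plus bivariate Gaussian noise, both in finger-length units.

    ``rss_effects`` holds additive shifts applied to the named
    parameters in the post-RSS cell only (the sham protocol shifts
    nothing); ``session_jitter`` holds a zero-mean cell-wise
    perturbation of the named parameters, emulating day-to-day state
    fluctuation of the underlying thresholds. A jitter entry is either
    a float (Gaussian SD) or a (scale, df) tuple for a scaled Student-t
    perturbation: heavy tails keep most cells well inside the stimulus
    range while still producing the occasional wild session that makes
    a cell unfittable, as observed in real threshold data.
    """

    pse_2pdt: float = 1.5  # mm
    slope_2pdt: float = 3.0  # logit per mm
    pse_tmt: float = 0.0  # % area distortion
    slope_tmt: float = 0.25  # logit per %
    lapse: float = 0.02
    distance_gain: float = 0.9
    distance_bias: float = 0.0  # mm
    distance_noise_sd: float = 4.0  # mm
    distance_position_effect: float = 0.0  # mm added at the fingertip
    localization_bias: dict[str, np.ndarray] = field(
        default_factory=_default_localization_bias
    )
    localization_cov: dict[str, np.ndarray] = field(
        default_factory=_default_localization_cov
    )
    rss_effects: dict[str, float] = field(default_factory=dict)
    session_jitter: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.slope_2pdt > 0 and self.slope_tmt > 0):
            raise ValueError("psychometric slopes must be positive")
        if not 0 <= self.lapse < 0.5:
            raise ValueError("lapse must lie in [0, 0.5)")
        if self.distance_noise_sd < 0:
            raise ValueError("distance_noise_sd must be non-negative")
        for ph, cov in self.localization_cov.items():
            cov = np.asarray(cov, dtype=float)
            if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
                raise ValueError(f"localization_cov[{ph!r}] must be symmetric 2x2")
            if np.linalg.eigvalsh(cov).min() < -1e-12:
                raise ValueError(f"localization_cov[{ph!r}] must be PSD")
            self.localization_cov[ph] = cov

    def for_cell(
        self, intervention: str, session: str, rng: np.random.Generator | None = None
    ) -> "ObserverParams":
        """Parameters effective in one design cell.

        Post-RSS applies ``rss_effects``; if an rng is given, the
        ``session_jitter`` perturbations are drawn for this cell.
        """
        out = replace(self, rss_effects=dict(self.rss_effects),
                      session_jitter=dict(self.session_jitter))
        if intervention == "RSS" and session == "post":
            for name, shift in self.rss_effects.items():
                setattr(out, name, getattr(out, name) + shift)
        if rng is not None:
            for name, jitter in self.session_jitter.items():
                if isinstance(jitter, tuple):
                    scale, df = jitter
                    shift = scale * rng.standard_t(df)
                else:
                    shift = rng.normal(0.0, jitter)
                setattr(out, name, getattr(out, name) + shift)
        return out


def sample_observer(
    rng: np.random.Generator, rss_effects: Mapping[str, float] | None = None
) -> ObserverParams:
    """Draw one participant's parameters from the population model.

    Population means and spreads are chosen to match the studied cohort:
    2PDT thresholds around 1.5 mm, unbiased finger-size perception with
    ~8% between-participant spread, mild tactile-distance underestimation,
    and the proximo-ulnar/radial localization bias pattern along the
    finger. Cell-to-cell PSE jitter SDs are set so the residual spread
    of PSE changes matches the reported effect sizes (Cohen's d ~ 0.7
    for a 7.4-point TMT shift).
    """
    bias = {
        "proximal": np.array([0.02, 0.0]) + rng.normal(0, 0.015, 2),
        "middle": np.array([-0.02, -0.05]) + rng.normal(0, 0.015, 2),
        "distal": np.array([-0.02, -0.05]) + rng.normal(0, 0.015, 2),
    }
    params = ObserverParams(
        pse_2pdt=float(np.clip(rng.normal(1.5, 0.3), 0.5, 2.4)),
        slope_2pdt=float(rng.lognormal(np.log(3.0), 0.25)),
        pse_tmt=float(rng.normal(0.0, 4.0)),
        slope_tmt=float(rng.lognormal(np.log(0.25), 0.25)),
        lapse=float(rng.uniform(0.0, 0.05)),
        distance_gain=float(rng.normal(0.9, 0.08)),
        distance_bias=float(rng.normal(0.0, 3.0)),
        distance_noise_sd=float(rng.lognormal(np.log(4.0), 0.2)),
        distance_position_effect=float(rng.normal(0.0, 1.0)),
        localization_bias=bias,
        session_jitter={"pse_tmt": (5.0, 3.0), "pse_2pdt": 0.2},
    )
    if rss_effects is not None:
        params.rss_effects = dict(rss_effects)
    return params


# ---------------------------------------------------------------------------
# task simulators


def _cell_columns(task: str, cell: Mapping[str, str], n: int) -> dict[str, list]:
    return {
        "task": [task] * n,
        "participant": [cell["participant"]] * n,
        "intervention": [cell["intervention"]] * n,
        "session": [cell["session"]] * n,
        "order": [cell.get("order", "")] * n,
    }


def simulate_binary_task(
    params: ObserverParams,
    task: str,
    cell: Mapping[str, str],
    n_reps: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate one session of a binary psychophysical task.

    2PDT: 8 probe separations (single tip encoded as 0 mm) x n_reps,
    response "one"/"two". TMT: 9 area distortions x n_reps, response
    "smaller"/"larger". Trial order is pseudo-randomized.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if task not in ("2PDT", "TMT"):
        raise ValueError(f"unknown binary task {task!r}")
    rng = np.random.default_rng(seed)
    eff = params.for_cell(cell["intervention"], cell["session"], rng)
    if task == "2PDT":
        levels, pse, slope = TWO_PDT_LEVELS, eff.pse_2pdt, eff.slope_2pdt
        stim_col, pos_label, neg_label = "separation", "two", "one"
    else:
        levels, pse, slope = TMT_LEVELS, eff.pse_tmt, eff.slope_tmt
        stim_col, pos_label, neg_label = "distortion", "larger", "smaller"
    x = np.repeat(levels, n_reps).astype(float)
    rng.shuffle(x)
    p = eff.lapse / 2 + (1 - eff.lapse) * expit(slope * (x - pse))
    resp = np.where(rng.random(x.size) < p, pos_label, neg_label)
    out = _cell_columns(task, cell, x.size)
    out[stim_col] = x
    out["response"] = resp
    return pd.DataFrame(out)


def simulate_distance_task(
    params: ObserverParams,
    cell: Mapping[str, str],
    seed: int,
    n_reps: int = 10,
) -> pd.DataFrame:
    """Simulate one TDJT session: 2 distances x 2 positions x n_reps trials.

    Judged length = gain * true + bias (+ position effect at the tip)
    + Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    eff = params.for_cell(cell["intervention"], cell["session"], rng)
    dist = np.repeat(TDJT_DISTANCES, len(TDJT_POSITIONS) * n_reps)
    pos = np.tile(np.repeat(TDJT_POSITIONS, n_reps), len(TDJT_DISTANCES))
    idx = rng.permutation(dist.size)
    dist, pos = dist[idx], pos[idx]
    judged = (
        eff.distance_gain * dist
        + eff.distance_bias
        + np.where(pos == "tip", eff.distance_position_effect, 0.0)
        + rng.normal(0.0, eff.distance_noise_sd, dist.size)
    )
    out = _cell_columns("TDJT", cell, dist.size)
    out["position"] = pos
    out["true_distance"] = dist
    out["judged_length"] = judged
    return pd.DataFrame(out)


def target_locations(
    finger_length: float, phalanx_lengths: Sequence[float] | None = None
) -> pd.DataFrame:
    """The nine touch targets along the finger midline.

    Three positions per phalanx at 1/4, 1/2 and 3/4 of the phalanx
    length; y runs proximal (0) to distal (finger_length), x = 0 on the
    midline. Phalanx lengths default to equal thirds.
    """
    if phalanx_lengths is None:
        phalanx_lengths = [finger_length / 3] * 3
    if len(phalanx_lengths) != 3 or not math.isclose(
        sum(phalanx_lengths), finger_length, rel_tol=1e-9
    ):
        raise ValueError("phalanx_lengths must be 3 values summing to finger_length")
    rows = []
    y0 = 0.0
    for ph, length in zip(PHALANGES, phalanx_lengths):
        for k, frac in enumerate((0.25, 0.5, 0.75), start=1):
            rows.append({"phalanx": ph, "position": k,
                         "real_x": 0.0, "real_y": y0 + frac * length})
        y0 += length
    return pd.DataFrame(rows)


def simulate_localization_task(
    params: ObserverParams,
    cell: Mapping[str, str],
    finger_length: float,
    seed: int,
    n_reps: int = 10,
    phalanx_lengths: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Simulate one TLT session: 9 locations x n_reps pointing trials.

    Judged location = real + finger_length * (phalanx bias + bivariate
    Gaussian noise); coordinates in mm, +y distal, +x radial.
    """
    if finger_length <= 0:
        raise ValueError("finger_length must be positive")
    rng = np.random.default_rng(seed)
    eff = params.for_cell(cell["intervention"], cell["session"], rng)
    targets = target_locations(finger_length, phalanx_lengths)
    reps = targets.loc[targets.index.repeat(n_reps)].reset_index(drop=True)
    reps = reps.iloc[rng.permutation(len(reps))].reset_index(drop=True)
    judged = np.empty((len(reps), 2))
    for ph in PHALANGES:
        mask = (reps["phalanx"] == ph).to_numpy()
        n = int(mask.sum())
        noise = rng.multivariate_normal(
            np.zeros(2), eff.localization_cov[ph], size=n, method="svd"
        )
        shift = finger_length * (eff.localization_bias[ph] + noise)
        judged[mask, 0] = reps.loc[mask, "real_x"].to_numpy() + shift[:, 0]
        judged[mask, 1] = reps.loc[mask, "real_y"].to_numpy() + shift[:, 1]
    out = _cell_columns("TLT", cell, len(reps))
    out.update(
        {
            "phalanx": reps["phalanx"].tolist(),
            "position": reps["position"].tolist(),
            "real_x": reps["real_x"].to_numpy(),
            "real_y": reps["real_y"].to_numpy(),
            "judged_x": judged[:, 0],
            "judged_y": judged[:, 1],
            "finger_length": [finger_length] * len(reps),
        }
    )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# missingness / outlier injection


_CONDITION_KEYS = {
    "TLT": ["participant", "intervention", "session", "phalanx", "position"],
    "TDJT": ["participant", "intervention", "session", "position", "true_distance"],
    "2PDT": ["participant", "intervention", "session", "separation"],
    "TMT": ["participant", "intervention", "session", "distortion"],
}


def inject_missing_and_outliers(
    table: pd.DataFrame,
    miss_rate: float = 0.0,
    outlier_spec: Mapping[str, object] | None = None,
    seed: int = 0,
    min_reps: int = 7,
) -> pd.DataFrame:
    """Remove random missed trials and optionally plant a group outlier.

    ``miss_rate`` is the per-trial missing probability; removal that
    would leave any single-trial condition with fewer than ``min_reps``
    trials (the 7-of-10 floor) raises. ``outlier_spec`` is a mapping
    {"participant", "column", "shift"} that displaces one participant's
    values by ``shift`` group standard deviations of that column,
    for testing the 3-SD group-level outlier rule.
    """
    if not 0 <= miss_rate < 0.3:
        raise ValueError("miss_rate must lie in [0, 0.3)")
    rng = np.random.default_rng(seed)
    out = table.copy()
    if miss_rate > 0:
        keep = rng.random(len(out)) >= miss_rate
        out = out[keep].reset_index(drop=True)
        task = str(table["task"].iloc[0])
        if task in ("TLT", "TDJT"):
            counts = out.groupby(_CONDITION_KEYS[task], observed=True).size()
            if (counts < min_reps).any():
                bad = counts[counts < min_reps].index[0]
                raise ValueError(
                    f"missingness left fewer than {min_reps} trials in condition {bad}"
                )
    if outlier_spec is not None:
        col = str(outlier_spec["column"])
        sd = float(out[col].std(ddof=1))
        mask = out["participant"] == outlier_spec["participant"]
        out.loc[mask, col] = out.loc[mask, col] + float(outlier_spec["shift"]) * sd
    return out


# ---------------------------------------------------------------------------
# measure-level and whole-study simulation


def simulate_pse_table(
    n_participants: int,
    interaction: float,
    seed: int,
    sd_participant: float = 8.0,
    sd_slope: float = 2.0,
    sd_resid: float = 10.1,
    grand_mean: float = 0.0,
) -> pd.DataFrame:
    """Simulate a participant x intervention x session table of PSEs.

    The generative model is the inference layer's own: a per-participant
    random intercept (SD ``sd_participant``), a random intervention
    slope (SD ``sd_slope``), an intervention x session interaction equal
    to ``interaction`` applied to the post-RSS cell only, and i.i.d.
    cell-level noise (SD ``sd_resid``, default matched to a Cohen's
    d ~ 0.73 for a 7.4-point shift). Used for calibration and coverage
    studies of the mixed-model layer.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        intercept = rng.normal(grand_mean, sd_participant)
        slope_int = rng.normal(0.0, sd_slope)
        for intervention in INTERVENTIONS:
            for session in SESSIONS:
                mu = intercept + (slope_int if intervention == "RSS" else 0.0)
                if intervention == "RSS" and session == "post":
                    mu += interaction
                rows.append(
                    {
                        "participant": f"P{i + 1:02d}",
                        "intervention": intervention,
                        "session": session,
                        "pse": mu + rng.normal(0.0, sd_resid),
                    }
                )
    return pd.DataFrame(rows)


DEFAULT_RSS_EFFECTS: dict[str, float] = {"pse_tmt": -7.4, "pse_2pdt": -0.3}
"""Post-RSS parameter shifts: the finger is perceived ~7.4 area-% smaller
and the two-point threshold drops; sham shifts nothing."""


@dataclass
class SimulatedStudy:
    """All tables of one synthetic crossover study plus its ground truth."""

    design: DesignSpec
    tables: dict[str, pd.DataFrame]  # task -> long trial table
    observers: dict[str, ObserverParams]
    finger_lengths: dict[str, float]
    seed: int


def simulate_study(
    n_participants: int = 33,
    seed: int = 0,
    rss_effects: Mapping[str, float] | None = None,
    n_reps_binary: Mapping[str, int] | None = None,
) -> SimulatedStudy:
    """Simulate the complete four-task crossover study.

    Defaults reproduce the study conditions: 33 participants, 64/108/
    40/90 trials per session for 2PDT/TMT/TDJT/TLT, counterbalanced
    order, and an RSS-only effect shifting the TMT PSE by -7.4 area-%
    and the 2PDT threshold downward.
    """
    if rss_effects is None:
        rss_effects = DEFAULT_RSS_EFFECTS
    reps = {"2PDT": 8, "TMT": 12}
    if n_reps_binary:
        reps.update(n_reps_binary)
    root = np.random.default_rng(seed)
    design = generate_crossover_design(n_participants, int(root.integers(2**31)))
    observers: dict[str, ObserverParams] = {}
    finger_lengths: dict[str, float] = {}
    frames: dict[str, list[pd.DataFrame]] = {t: [] for t in ("2PDT", "TMT", "TDJT", "TLT")}
    for pid, order in zip(design.as_frame()["participant"], design.order_assignment):
        prng = np.random.default_rng(root.integers(2**31))
        obs = sample_observer(prng, rss_effects)
        observers[pid] = obs
        finger_lengths[pid] = float(np.clip(prng.normal(75.0, 7.0), 55.0, 95.0))
        for intervention in INTERVENTIONS:
            for session in SESSIONS:
                cell = {
                    "participant": pid,
                    "intervention": intervention,
                    "session": session,
                    "order": order,
                }
                s2, st, sd_, sl = (int(prng.integers(2**31)) for _ in range(4))
                frames["2PDT"].append(
                    simulate_binary_task(obs, "2PDT", cell, reps["2PDT"], s2)
                )
                frames["TMT"].append(
                    simulate_binary_task(obs, "TMT", cell, reps["TMT"], st)
                )
                frames["TDJT"].append(simulate_distance_task(obs, cell, sd_))
                frames["TLT"].append(
                    simulate_localization_task(obs, cell, finger_lengths[pid], sl)
                )
    tables = {t: pd.concat(fs, ignore_index=True) for t, fs in frames.items()}
    return SimulatedStudy(design, tables, observers, finger_lengths, seed)
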