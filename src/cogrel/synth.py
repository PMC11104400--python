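"""Synthetic two-session study generator with known ground truth.

Emulates the study design: N subjects complete a 200-trial restless
four-armed bandit (win and loss probabilities drifting independently per
arm) and a two-phase gambling task (training: 50 mixed + 40 gain-only
offers on a fixed grid; calibrated: 64 mixed + 56 gain-only offers centred
on indifference points estimated from the training phase) in each of two
sessions. Subject-level parameters are drawn on the unbounded latent scale
from per-parameter bivariate normal distributions whose off-diagonal
correlation is the between-session reliability being studied, then mapped
to native bounds with the same probit transform the fitter uses — so every
reliability estimand downstream has a known generating value.

Default group-level values are chosen to produce behaviour in the range
reported for healthy adults on these tasks (moderate learning rates,
sensitivities around 6 points, rare lapses; risk aversion just below 1,
loss aversion around 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import transforms
from .tasks import BanditTrials, GambleTrials, PTParams, RLParams, pt_simulate, rl_simulate

__all__ = [
    "BanditEnvironment",
    "ParamSpec",
    "PopulationSpec",
    "CalibrationResult",
    "generate_bandit_environment",
    "generate_population",
    "training_offers",
    "calibrate_offers",
    "simulate_study",
    "default_bandit_population",
    "default_gamble_population",
]


@dataclass
class BanditEnvironment:
    """Per-trial win and loss probabilities for the four arms."""

    win_prob: np.ndarray
    loss_prob: np.ndarray

    def __post_init__(self):
        self.win_prob = np.asarray(self.win_prob, dtype=float)
        self.loss_prob = np.asarray(self.loss_prob, dtype=float)
        if self.win_prob.shape != self.loss_prob.shape or self.win_prob.ndim != 2:
            raise ValueError("win_prob and loss_prob must be equal-shape (T, arms)")
        for a in (self.win_prob, self.loss_prob):
            if a.min() < 0 or a.max() > 1:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_trials(self):
        return self.win_prob.shape[0]


@dataclass(frozen=True)
class ParamSpec:
    """Group-level description of one parameter on the latent scale."""

    name: str
    mean: float        # latent group mean
    sd: float          # latent group SD (between subjects)
    corr: float        # between-session latent correlation
    lo: float
    hi: float

    def __post_init__(self):
        if abs(self.corr) > 1:
            raise ValueError("between-session correlation must lie in [-1, 1]")
        if self.sd < 0:
            raise ValueError("group SD must be non-negative")


@dataclass
class PopulationSpec:
    """A task's population: one ParamSpec per model parameter, N subjects."""

    task: str  # "bandit" | "gamble"
    params: list
    n_subjects: int = 50

    @property
    def param_names(self):
        return [p.name for p in self.params]

    @property
    def bounds(self):
        return np.array([[p.lo, p.hi] for p in self.params])


def default_bandit_population(n_subjects=50, corr=None):
    """Bandit population defaults.

    Native-scale group means: a_rew 0.40, a_pun 0.30, sensitivities 6 (of a
    0-30 range), lapse 0.05 with deliberately small spread (lapse varies
    little between healthy subjects, which is what makes it hard to
    recover). Between-session correlations default to the good-to-excellent
    range observed for learning rates/sensitivities and zero for lapse.
    """
    corr = {} if corr is None else dict(corr)
    specs = [
        ParamSpec("a_rew", -0.25, 0.5, corr.get("a_rew", 0.71), 0.0, 1.0),
        ParamSpec("a_pun", -0.52, 0.5, corr.get("a_pun", 0.85), 0.0, 1.0),
        ParamSpec("r_sens", -0.84, 0.4, corr.get("r_sens", 0.68), 0.0, 30.0),
        ParamSpec("p_sens", -0.84, 0.4, corr.get("p_sens", 0.64), 0.0, 30.0),
        ParamSpec("xi", -1.64, 0.2, corr.get("xi", 0.0), 0.0, 1.0),
    ]
    return PopulationSpec("bandit", specs, n_subjects)


def default_gamble_population(n_subjects=50, corr=None):
    """Gambling-task population defaults.

    Native-scale group means: rho about 0.9 (mild risk aversion), lam about
    1.5 (losses weighted 1.5x gains), tau about 0.25 in point-utility units.
    Between-session correlations default to the excellent range observed
    for prospect-theory parameters.
    """
    corr = {} if corr is None else dict(corr)
    specs = [
        ParamSpec("rho", -0.13, 0.35, corr.get("rho", 0.90), 0.0, 2.0),
        ParamSpec("lam", -0.52, 0.40, corr.get("lam", 0.87), 0.0, 5.0),
        ParamSpec("tau", -2.40, 0.30, corr.get("tau", 0.91), 0.0, 30.0),
    ]
    return PopulationSpec("gamble", specs, n_subjects)


# ---------------------------------------------------------------------------
# Environment and population generators
# ---------------------------------------------------------------------------


def generate_bandit_environment(T=200, arms=4, walk_sd=0.03, bounds=(0.2, 0.8),
                                seed=None, rng=None) -> BanditEnvironment:
    """Reflecting Gaussian random walks for win and loss probabilities.

    Each of the 2*arms trajectories starts uniform within bounds and takes
    independent N(0, walk_sd) steps, reflecting at the bounds.
    """
    lo, hi = bounds
    if not (0 <= lo < hi <= 1):
        raise ValueError("bounds must satisfy 0 <= lo < hi <= 1")
    if walk_sd < 0:
        raise ValueError("walk_sd must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    start = rng.uniform(lo, hi, size=(1, 2 * arms))
    steps = rng.normal(0.0, walk_sd, size=(T - 1, 2 * arms)) if T > 1 else np.zeros((0, 2 * arms))
    raw = np.concatenate([start, steps]).cumsum(axis=0)
    traj = _reflect(raw, lo, hi)
    return BanditEnvironment(traj[:, :arms], traj[:, arms:])


def _reflect(x, lo, hi):
    """Fold an unconstrained walk into [lo, hi] by reflection at both ends."""
    width = hi - lo
    y = np.mod(x - lo, 2 * width)
    return lo + np.where(y <= width, y, 2 * width - y)


def generate_population(spec: PopulationSpec, seed=None, rng=None) -> pd.DataFrame:
    """Draw true per-subject, per-session parameters.

    For each parameter, subject latent pairs (z_s1, z_s2) are bivariate
    normal with the spec's mean/SD marginals and its between-session
    correlation, then mapped to native bounds. Returns a tidy frame with
    columns subject, session, param, latent, value.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for p in spec.params:
        cov = p.sd**2 * np.array([[1.0, p.corr], [p.corr, 1.0]])
        # svd method: tolerates the singular cov of corr = +/-1 or sd = 0
        z = rng.multivariate_normal([p.mean, p.mean], cov, size=spec.n_subjects,
                                    method="svd")
        x = transforms.to_native(z, p.lo, p.hi)
        for s in (1, 2):
            rows.append(pd.DataFrame({
                "subject": np.arange(1, spec.n_subjects + 1),
                "session": s,
                "param": p.name,
                "latent": z[:, s - 1],
                "value": x[:, s - 1],
            }))
    return pd.concat(rows, ignore_index=True)


def params_wide(truth: pd.DataFrame, session: int) -> pd.DataFrame:
    """Pivot a truth table to one row per subject for one session."""
    sub = truth[truth.session == session]
    return sub.pivot(index="subject", columns="param", values="value")


# ---------------------------------------------------------------------------
# Gambling-task offers and calibration
# ---------------------------------------------------------------------------

_TRAIN_GAINS = np.array([20.0, 30.0, 40.0, 50.0, 60.0])
_TRAIN_MIXED_RATIOS = np.geomspace(0.25, 4.0, 10)   # |loss| / gain
_TRAIN_GAIN_FRACS = np.linspace(0.1, 0.9, 8)        # sure / gain


def training_offers() -> GambleTrials:
    """Fixed phase-1 grid: 50 mixed and 40 gain-only offers."""
    g_m = np.repeat(_TRAIN_GAINS, len(_TRAIN_MIXED_RATIOS))
    r_m = np.tile(_TRAIN_MIXED_RATIOS, len(_TRAIN_GAINS))
    g_g = np.repeat(_TRAIN_GAINS, len(_TRAIN_GAIN_FRACS))
    f_g = np.tile(_TRAIN_GAIN_FRACS, len(_TRAIN_GAINS))
    trial_type = np.array(["mixed"] * len(g_m) + ["gain"] * len(g_g), dtype=object)
    sure = np.concatenate([np.zeros(len(g_m)), np.round(f_g * g_g, 1)])
    gain = np.concatenate([g_m, g_g])
    loss = np.concatenate([-np.round(r_m * g_m, 1), np.zeros(len(g_g))])
    return GambleTrials(trial_type, sure, gain, loss, np.zeros(len(trial_type)))


@dataclass
class CalibrationResult:
    """Indifference points and the phase-2 offer table built around them."""

    lambda_hat: float      # |loss|/gain ratio at mixed-trial indifference
    risk_hat: float        # sure/gain fraction at gain-trial indifference
    offers: GambleTrials   # 64 mixed + 56 gain-only phase-2 offers
    flagged: bool = False  # degenerate phase-1 responding, fallback used


def _pt_mle(trials: GambleTrials):
    """Maximum-likelihood (rho, lam, tau) for one subject's choices."""
    from .tasks import pt_loglik_batch

    def nll(u):
        rho = 2.0 / (1.0 + np.exp(-u[0]))
        lam = 5.0 / (1.0 + np.exp(-u[1]))
        tau = np.exp(u[2])
        p = np.array([[rho, lam, tau]])
        return -pt_loglik_batch(p, trials.sure_amount[None], trials.gamble_gain[None],
                                trials.gamble_loss[None], trials.gambled[None])[0]

    best = None
    for u0 in ([0.0, 0.0, -1.5], [-1.0, 1.0, -0.5], [1.0, -1.0, -2.5]):
        res = minimize(nll, np.asarray(u0), method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    u = best.x
    return 2.0 / (1.0 + np.exp(-u[0])), 5.0 / (1.0 + np.exp(-u[1])), np.exp(u[2])


def calibrate_offers(training: GambleTrials) -> CalibrationResult:
    """Estimate indifference points from phase-1 responses and build phase 2.

    The prospect-theory choice rule is fit by maximum likelihood to the
    training responses; the mixed indifference ratio is the |loss|/gain at
    which a 50-50 mixed gamble is utility-neutral (lam**(-1/rho)), inverted
    to the lam scale for reporting, and the gain-trial indifference is the
    sure/gain fraction 0.5**(1/rho). Degenerate all-gamble or all-sure
    responding within a trial type falls back to the grid midpoint and
    flags the subject. Phase 2 spans symmetric grids around the
    indifference points: 64 mixed and 56 gain-only offers.
    """
    mixed = training.trial_type == "mixed"
    gain = training.trial_type == "gain"
    flagged = False
    deg_mixed = len(set(training.gambled[mixed])) < 2
    deg_gain = len(set(training.gambled[gain])) < 2
    if deg_mixed and deg_gain:
        lam_hat, risk_hat = 1.0, 0.5
        flagged = True
    else:
        rho_hat, lam_mle, _ = _pt_mle(training)
        rho_hat = float(np.clip(rho_hat, 0.3, 1.9))
        lam_hat = float(np.clip(lam_mle, 0.3, 4.5))
        risk_hat = float(np.clip(0.5 ** (1.0 / rho_hat), 0.1, 0.9))
        if deg_mixed:
            lam_hat, flagged = 1.0, True
        if deg_gain:
            risk_hat, flagged = 0.5, True
    return CalibrationResult(lam_hat, risk_hat,
                             _phase2_offers(lam_hat, risk_hat), flagged)


def _phase2_offers(lam_hat, risk_hat) -> GambleTrials:
    # mixed: 8 gain levels x 8 loss ratios log-spaced around indifference
    gains_m = np.linspace(20.0, 62.0, 8)
    r_star = np.clip(1.0 / lam_hat, 0.2, 5.0)
    ratios = r_star * np.exp(np.linspace(-0.9, 0.9, 8))
    g_m = np.repeat(gains_m, 8)
    r_m = np.tile(ratios, 8)
    # gain-only: 7 gain levels x 8 sure fractions around indifference
    gains_g = np.linspace(20.0, 80.0, 7)
    fracs = np.clip(risk_hat + np.linspace(-0.25, 0.25, 8), 0.05, 0.95)
    g_g = np.repeat(gains_g, 8)
    f_g = np.tile(fracs, 7)
    trial_type = np.array(["mixed"] * 64 + ["gain"] * 56, dtype=object)
    sure = np.concatenate([np.zeros(64), np.round(f_g * g_g, 1)])
    gamble_gain = np.concatenate([g_m, g_g])
    gamble_loss = np.concatenate([-np.round(r_m * g_m, 1), np.zeros(56)])
    return GambleTrials(trial_type, sure, gamble_gain, gamble_loss, np.zeros(120))


# ---------------------------------------------------------------------------
# Full study simulation
# ---------------------------------------------------------------------------


@dataclass
class StudyData:
    """Simulated two-session study with ground truth."""

    bandit: pd.DataFrame
    gamble: pd.DataFrame
    truth: pd.DataFrame
    meta: dict = field(default_factory=dict)


def simulate_study(bandit_spec=None, gamble_spec=None, T=200, walk_sd=0.03,
                   walk_bounds=(0.2, 0.8), shared_environment=False,
                   seed=None) -> StudyData:
    """Simulate the full two-session study for both tasks.

    One independent bandit environment is drawn per subject-session unless
    ``shared_environment`` is set, in which case all subjects in a session
    face the same schedule. Gamble sessions run training on the fixed grid,
    calibrate, then run the calibrated phase. Either task can be disabled
    by passing an explicit None while the other spec is given.
    """
    if bandit_spec is None and gamble_spec is None:
        bandit_spec = default_bandit_population()
        gamble_spec = default_gamble_population()
    rng = np.random.default_rng(seed)
    bandit_rows, gamble_rows, truth_frames = [], [], []

    if bandit_spec is not None:
        truth_b = generate_population(bandit_spec, rng=rng)
        truth_b["task"] = "bandit"
        truth_frames.append(truth_b)
        shared_env = {s: generate_bandit_environment(T, 4, walk_sd, walk_bounds, rng=rng)
                      for s in (1, 2)} if shared_environment else None
        for session in (1, 2):
            wide = params_wide(truth_b, session)
            for subject in wide.index:
                env = (shared_env[session] if shared_environment else
                       generate_bandit_environment(T, 4, walk_sd, walk_bounds, rng=rng))
                params = RLParams(**{k: wide.loc[subject, k]
                                     for k in ("a_rew", "a_pun", "r_sens", "p_sens", "xi")})
                tr = rl_simulate(params, env, rng=rng)
                bandit_rows.append(pd.DataFrame({
                    "subject": subject, "session": session,
                    "trial": np.arange(1, T + 1),
                    "choice": tr.choice, "reward": tr.reward.astype(int),
                    "punishment": tr.punishment.astype(int),
                }))

    if gamble_spec is not None:
        truth_g = generate_population(gamble_spec, rng=rng)
        truth_g["task"] = "gamble"
        truth_frames.append(truth_g)
        train = training_offers()
        for session in (1, 2):
            wide = params_wide(truth_g, session)
            for subject in wide.index:
                params = PTParams(rho=wide.loc[subject, "rho"],
                                  lam=wide.loc[subject, "lam"],
                                  tau=wide.loc[subject, "tau"])
                phase1 = pt_simulate(params, train, rng=rng)
                calib = calibrate_offers(phase1)
                phase2 = pt_simulate(params, calib.offers, rng=rng)
                for phase, tr in (("training", phase1), ("calibrated", phase2)):
                    gamble_rows.append(pd.DataFrame({
                        "subject": subject, "session": session,
                        "trial": np.arange(1, len(tr) + 1), "phase": phase,
                        "trial_type": tr.trial_type,
                        "sure_amount": tr.sure_amount,
                        "gamble_gain": tr.gamble_gain,
                        "gamble_loss": tr.gamble_loss,
                        "gambled": tr.gambled.astype(int),
                    }))

    return StudyData(
        bandit=pd.concat(bandit_rows, ignore_index=True) if bandit_rows else pd.DataFrame(),
        gamble=pd.concat(gamble_rows, ignore_index=True) if gamble_rows else pd.DataFrame(),
        truth=pd.concat(truth_frames, ignore_index=True) if truth_frames else pd.DataFrame(),
        meta={"seed": seed, "T": T, "walk_sd": walk_sd, "walk_bounds": list(walk_bounds),
              "shared_environment": shared_environment},
    )
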