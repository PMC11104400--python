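"""Generative models for the two decision-making tasks.

Two tasks, two models:

* Restless four-armed bandit, modelled by Q-learning with separate reward
  and punishment learning rates (a_rew, a_pun), separate outcome
  sensitivities (r_sens, p_sens) and a lapse probability xi. On each trial
  the agent chooses among four arms via a softmax (temperature fixed at 1;
  the sensitivities scale the Q-values and so play the role of inverse
  temperature) mixed with a uniform lapse:

      p(a) = (1 - xi) * softmax(q_rew + q_pun)[a] + xi / 4

  After the choice, only the chosen arm's Q-values update:

      q_rew[c] += a_rew * (r_sens * reward     - q_rew[c])
      q_pun[c] += a_pun * (p_sens * punishment - q_pun[c])

  Rewards are coded {0, 1} and punishments {-1, 0}; a trial can deliver
  both, either, or neither. Q-values reset to zero at the start of each
  session.

* Calibrated gambling task, modelled by prospect theory with risk aversion
  rho, loss aversion lam and inverse temperature tau. Utility is
  u(x) = x**rho for gains and -lam * (-x)**rho for losses; the probability
  of accepting a 50-50 gamble over a sure amount is

      p(gamble) = logistic(tau * (0.5*u(gain) + 0.5*u(loss) - u(sure)))

This module provides likelihoods (total and per-trial) and forward
simulators for both models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit

from ._kernels import bandit_simulate_kernel, bandit_trial_logp

__all__ = [
    "RLParams",
    "RLState",
    "PTParams",
    "BanditTrials",
    "GambleTrials",
    "rl_choice_probs",
    "rl_step",
    "rl_loglik",
    "rl_simulate",
    "pt_utility",
    "pt_gamble_prob",
    "pt_loglik",
    "pt_simulate",
]


class DataError(ValueError):
    """Raised when trial data violate the task's coding conventions."""


# ---------------------------------------------------------------------------
# Parameter and data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RLParams:
    """Five-parameter bandit model: learning rates, sensitivities, lapse."""

    a_rew: float
    a_pun: float
    r_sens: float
    p_sens: float
    xi: float

    def __post_init__(self):
        if not (0.0 <= self.a_rew <= 1.0 and 0.0 <= self.a_pun <= 1.0):
            raise ValueError("learning rates must lie in [0, 1]")
        if not (0.0 <= self.xi <= 1.0):
            raise ValueError("lapse probability must lie in [0, 1]")
        if not (np.isfinite(self.r_sens) and np.isfinite(self.p_sens)):
            raise ValueError("sensitivities must be finite")
        if self.r_sens < 0 or self.p_sens < 0:
            raise ValueError("sensitivities must be non-negative")

    def to_array(self):
        return np.array([self.a_rew, self.a_pun, self.r_sens, self.p_sens, self.xi])


@dataclass
class RLState:
    """Reward and punishment Q-values for the four arms."""

    q_rew: np.ndarray = field(default_factory=lambda: np.zeros(4))
    q_pun: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def __post_init__(self):
        self.q_rew = np.asarray(self.q_rew, dtype=float)
        self.q_pun = np.asarray(self.q_pun, dtype=float)
        if self.q_rew.shape != (4,) or self.q_pun.shape != (4,):
            raise ValueError("Q-value vectors must have length 4")


@dataclass(frozen=True)
class PTParams:
    """Prospect-theory model: risk aversion, loss aversion, inverse temperature."""

    rho: float
    lam: float
    tau: float

    def __post_init__(self):
        if self.rho <= 0 or self.lam <= 0 or self.tau < 0:
            raise ValueError("rho and lam must be positive, tau non-negative")

    def to_array(self):
        return np.array([self.rho, self.lam, self.tau])


@dataclass
class BanditTrials:
    """One subject-session of bandit data.

    choice is 1-based (arms 1..4), reward in {0, 1}, punishment in {-1, 0}.
    """

    choice: np.ndarray
    reward: np.ndarray
    punishment: np.ndarray

    def __post_init__(self):
        self.choice = np.asarray(self.choice, dtype=np.int64)
        self.reward = np.asarray(self.reward, dtype=float)
        self.punishment = np.asarray(self.punishment, dtype=float)
        n = len(self.choice)
        if len(self.reward) != n or len(self.punishment) != n:
            raise DataError("choice, reward and punishment must have equal length")
        if n and (self.choice.min() < 1 or self.choice.max() > 4):
            raise DataError("choices must lie in 1..4")
        if not np.isin(self.reward, (0.0, 1.0)).all():
            raise DataError("rewards must be coded {0, 1}")
        if not np.isin(self.punishment, (-1.0, 0.0)).all():
            raise DataError("punishments must be coded {-1, 0}")

    def __len__(self):
        return len(self.choice)


@dataclass
class GambleTrials:
    """One subject-session of gamble offers and decisions.

    Mixed trials: gamble_loss < 0 and sure_amount == 0.
    Gain-only trials: gamble_loss == 0 and sure_amount > 0.
    """

    trial_type: np.ndarray  # "mixed" | "gain"
    sure_amount: np.ndarray
    gamble_gain: np.ndarray
    gamble_loss: np.ndarray
    gambled: np.ndarray

    def __post_init__(self):
        self.trial_type = np.asarray(self.trial_type, dtype=object)
        for name in ("sure_amount", "gamble_gain", "gamble_loss", "gambled"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.trial_type)
        for name in ("sure_amount", "gamble_gain", "gamble_loss", "gambled"):
            if len(getattr(self, name)) != n:
                raise DataError("all gamble columns must have equal length")
        mixed = self.trial_type == "mixed"
        gain = self.trial_type == "gain"
        if not (mixed | gain).all():
            raise DataError("trial_type must be 'mixed' or 'gain'")
        if n:
            if (self.gamble_loss[mixed] >= 0).any() or (self.sure_amount[mixed] != 0).any():
                raise DataError("mixed trials need gamble_loss < 0 and sure_amount == 0")
            if (self.gamble_loss[gain] != 0).any() or (self.sure_amount[gain] <= 0).any():
                raise DataError("gain trials need gamble_loss == 0 and sure_amount > 0")
        if not np.isin(self.gambled, (0.0, 1.0)).all():
            raise DataError("gambled must be coded {0, 1}")

    def __len__(self):
        return len(self.trial_type)


# ---------------------------------------------------------------------------
# Bandit operations
# ---------------------------------------------------------------------------


def rl_choice_probs(state: RLState, params: RLParams) -> np.ndarray:
    """Lapse-mixed softmax choice probabilities over the four arms."""
    q = state.q_rew + state.q_pun
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite Q-values")
    e = np.exp(q - q.max())
    return (1.0 - params.xi) * e / e.sum() + params.xi / 4.0


def rl_step(state: RLState, choice: int, reward: float, punishment: float,
            params: RLParams) -> RLState:
    """Apply one prediction-error update to the chosen arm (choice is 1-based)."""
    if not 1 <= choice <= 4:
        raise DataError("choice must lie in 1..4")
    if reward not in (0, 1):
        raise DataError("reward must be 0 or 1")
    if punishment not in (-1, 0):
        raise DataError("punishment must be -1 or 0")
    c = choice - 1
    q_rew = state.q_rew.copy()
    q_pun = state.q_pun.copy()
    q_rew[c] += params.a_rew * (params.r_sens * reward - q_rew[c])
    q_pun[c] += params.a_pun * (params.p_sens * punishment - q_pun[c])
    return RLState(q_rew, q_pun)


def rl_loglik(params: RLParams, trials: BanditTrials):
    """Total log-likelihood and per-trial probabilities of the observed choices.

    Q-values reset to zero at trial 1.
    """
    if len(trials) == 0:
        raise DataError("empty trial sequence")
    logp = bandit_trial_logp(trials.choice - 1, trials.reward,
                             trials.punishment, params.to_array())
    return float(logp.sum()), np.exp(logp)


def rl_simulate(params: RLParams, env, seed=None, rng=None) -> BanditTrials:
    """Simulate a session in a bandit environment.

    Outcomes are independent Bernoulli draws from the chosen arm's win and
    loss probabilities (both can occur on one trial).
    """
    from .synth import BanditEnvironment  # avoid import cycle

    if not isinstance(env, BanditEnvironment):
        env = BanditEnvironment(*env)
    if rng is None:
        rng = np.random.default_rng(seed)
    T = env.n_trials
    u = rng.random((3, T))
    choices, rewards, punishments = bandit_simulate_kernel(
        env.win_prob, env.loss_prob, params.to_array(), u[0], u[1], u[2])
    return BanditTrials(choices + 1, rewards, punishments)


# ---------------------------------------------------------------------------
# Gamble operations
# ---------------------------------------------------------------------------


def pt_utility(x, rho, lam):
    """Prospect-theory utility: x**rho for gains, -lam*(-x)**rho for losses."""
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, np.power(np.abs(x), rho),
                    -lam * np.power(np.abs(x), rho))


def pt_gamble_prob(params: PTParams, sure_amount, gamble_gain, gamble_loss):
    """Probability of accepting the 50-50 gamble over the sure amount."""
    eu_gamble = 0.5 * pt_utility(gamble_gain, params.rho, params.lam) \
        + 0.5 * pt_utility(gamble_loss, params.rho, params.lam)
    eu_sure = pt_utility(sure_amount, params.rho, params.lam)
    return expit(params.tau * (eu_gamble - eu_sure))


def pt_loglik(params: PTParams, trials: GambleTrials):
    """Total log-likelihood and per-trial probabilities of the observed decisions."""
    if len(trials) == 0:
        raise DataError("empty trial sequence")
    logp = _pt_trial_logp(params.to_array()[None, :],
                          trials.sure_amount[None, :],
                          trials.gamble_gain[None, :],
                          trials.gamble_loss[None, :],
                          trials.gambled[None, :])[0]
    return float(logp.sum()), np.exp(logp)


def pt_simulate(params: PTParams, offers: GambleTrials, seed=None, rng=None) -> GambleTrials:
    """Simulate gamble/sure decisions for a table of offers."""
    if rng is None:
        rng = np.random.default_rng(seed)
    p = pt_gamble_prob(params, offers.sure_amount, offers.gamble_gain,
                       offers.gamble_loss)
    gambled = (rng.random(len(offers)) < p).astype(float)
    return GambleTrials(offers.trial_type, offers.sure_amount,
                        offers.gamble_gain, offers.gamble_loss, gambled)


# ---------------------------------------------------------------------------
# Batched internals shared with the fitting module
# ---------------------------------------------------------------------------


def _pt_trial_logp(params, sure, gain, loss, gambled):
    """Vectorised per-trial log-probabilities.

    params : (N, 3) rows (rho, lam, tau); offer arrays broadcast to (N, T).
    """
    rho = params[:, 0:1]
    lam = params[:, 1:2]
    tau = params[:, 2:3]
    u_gain = np.power(np.abs(gain), rho)
    u_loss = -lam * np.power(np.abs(loss), rho)
    u_sure = np.sign(sure) * np.power(np.abs(sure), rho)
    dv = tau * (0.5 * u_gain + 0.5 * u_loss - u_sure)
    # log p(observed) = log_expit(dv) if gambled else log_expit(-dv)
    return log_expit(np.where(gambled > 0.5, dv, -dv))


def pt_loglik_batch(params, sure, gain, loss, gambled):
    """Total log-likelihood per row; offer arrays shaped (N, T)."""
    return _pt_trial_logp(params, sure, gain, loss, gambled).sum(axis=1)
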