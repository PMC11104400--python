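"""Numba kernels for the bandit Q-learning likelihood and simulator.

These inner loops dominate the cost of MCMC, so they are compiled. All
kernels take the canonical five-parameter vector
(a_rew, a_pun, r_sens, p_sens, xi); reduced model variants expand their
free parameters to this form before calling in.

Choices are 0-based inside the kernels (the public API is 1-based).
"""

import numpy as np
from numba import njit

LOG_QUARTER = np.log(0.25)


@njit(cache=True)
def bandit_trial_logp(choices, rewards, punishments, p5):
    """Per-trial log-probability of the observed choices for one session.

    Q-values start at zero. On each trial the choice probability is a
    lapse-mixed softmax over q_rew + q_pun, then the chosen arm's reward
    and punishment Q-values are updated with separate learning rates and
    sensitivities.
    """
    a_rew, a_pun, r_sens, p_sens, xi = p5[0], p5[1], p5[2], p5[3], p5[4]
    T = choices.shape[0]
    out = np.empty(T)
    q_rew = np.zeros(4)
    q_pun = np.zeros(4)
    for t in range(T):
        c = choices[t]
        # softmax over summed Q with lapse floor xi/4
        m = q_rew[0] + q_pun[0]
        for a in range(1, 4):
            s = q_rew[a] + q_pun[a]
            if s > m:
                m = s
        denom = 0.0
        ec = 0.0
        for a in range(4):
            e = np.exp(q_rew[a] + q_pun[a] - m)
            denom += e
            if a == c:
                ec = e
        p = (1.0 - xi) * ec / denom + xi * 0.25
        out[t] = np.log(p)
        q_rew[c] += a_rew * (r_sens * rewards[t] - q_rew[c])
        q_pun[c] += a_pun * (p_sens * punishments[t] - q_pun[c])
    return out


@njit(cache=True)
def bandit_loglik_batch(choices, rewards, punishments, params):
    """Total log-likelihood per row for a batch of (session, parameter) pairs.

    choices : int64 (N, T); rewards, punishments : float64 (N, T)
    params : float64 (N, 5) canonical parameter vectors
    """
    N = choices.shape[0]
    out = np.empty(N)
    for i in range(N):
        lp = bandit_trial_logp(choices[i], rewards[i], punishments[i], params[i])
        out[i] = lp.sum()
    return out


@njit(cache=True)
def bandit_simulate_kernel(win_prob, loss_prob, p5, u_choice, u_rew, u_pun):
    """Forward-simulate one session given pre-drawn uniforms.

    win_prob, loss_prob : (T, 4) outcome probabilities per trial and arm.
    u_choice, u_rew, u_pun : (T,) iid U(0,1) variates.
    Returns (choices 0-based, rewards {0,1}, punishments {-1,0}).
    """
    a_rew, a_pun, r_sens, p_sens, xi = p5[0], p5[1], p5[2], p5[3], p5[4]
    T = win_prob.shape[0]
    choices = np.empty(T, dtype=np.int64)
    rewards = np.empty(T)
    punishments = np.empty(T)
    q_rew = np.zeros(4)
    q_pun = np.zeros(4)
    probs = np.empty(4)
    for t in range(T):
        m = q_rew[0] + q_pun[0]
        for a in range(1, 4):
            s = q_rew[a] + q_pun[a]
            if s > m:
                m = s
        denom = 0.0
        for a in range(4):
            probs[a] = np.exp(q_rew[a] + q_pun[a] - m)
            denom += probs[a]
        cum = 0.0
        c = 3
        for a in range(4):
            cum += (1.0 - xi) * probs[a] / denom + xi * 0.25
            if u_choice[t] < cum:
                c = a
                break
        choices[t] = c
        r = 1.0 if u_rew[t] < win_prob[t, c] else 0.0
        p = -1.0 if u_pun[t] < loss_prob[t, c] else 0.0
        rewards[t] = r
        punishments[t] = p
        q_rew[c] += a_rew * (r_sens * r - q_rew[c])
        q_pun[c] += a_pun * (p_sens * p - q_pun[c])
    return choices, rewards, punishments
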