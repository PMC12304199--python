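"""Independent oracles used by the test suite only.

These deliberately avoid the package's own computational paths: the
prevalence oracle is an individual-level continuous-time simulation, the
Markov reward oracle is a fundamental-matrix closed form, and the
calibration oracle iterates the control-arm chain forward explicitly.
"""

import numpy as np


def simulate_screen_prevalence(n_people: int, incidence: float,
                               progression_rates: list[float],
                               diagnosis_rates: list[float],
                               stage4_death_rate: float,
                               sensitivity: list[float], coverage: float,
                               rng: np.random.Generator,
                               window: float = 80.0):
    """Individual-level simulation of screen-detectable prevalence.

    People acquire preclinical stage 1 disease as a Poisson process at a
    constant ``incidence`` per person-year over a long window before the
    screen.  Each episode then draws sequential exponential stage sojourns
    with competing exits (progression, symptomatic diagnosis, and cancer
    death in stage 4).  A person still undiagnosed in stage s at the screen
    is detected with probability sensitivity[s] * coverage.

    Returns (detected fraction, standard error, per-stage detected fractions).
    """
    # stationary occupancy equals the expected number of active (undiagnosed,
    # detected) episodes per person, so episodes are simulated directly: the
    # episode count is Poisson with mean incidence * window * n_people
    m = int(rng.poisson(incidence * window * n_people))
    remaining = rng.uniform(0.0, window, size=m)  # entry time before screen
    alive_undx = np.ones(m, dtype=bool)
    detected_by_stage = np.zeros(4)
    for s in range(4):
        lam = progression_rates[s] if s < 3 else 0.0
        delta = diagnosis_rates[s]
        mu = stage4_death_rate if s == 3 else 0.0
        exit_rate = lam + delta + mu
        if exit_rate <= 0:
            in_stage = alive_undx
            sojourn = np.full(m, np.inf)
        else:
            sojourn = rng.exponential(1.0 / exit_rate, size=m)
            in_stage = alive_undx & (sojourn > remaining)
        hits = rng.random(m) < sensitivity[s] * coverage
        detected_by_stage[s] = np.count_nonzero(in_stage & hits)
        # episodes whose sojourn ended before the screen: resolve the exit
        exited = alive_undx & ~in_stage
        if exit_rate > 0:
            progressed = exited & (rng.random(m) < lam / exit_rate)
            alive_undx = progressed
            remaining = remaining - sojourn
        else:
            alive_undx = np.zeros_like(alive_undx)
    n_detected = detected_by_stage.sum()
    p = n_detected / n_people
    se = np.sqrt(max(n_detected, 1.0)) / n_people
    return p, se, detected_by_stage / n_people


def discounted_reward_closed_form(M: np.ndarray, init: np.ndarray,
                                  reward: np.ndarray, discount_rate: float,
                                  n_cycles: int) -> float:
    """Finite-horizon trapezoidal discounted reward via the fundamental matrix.

    sum_{k=0}^{N-1} d^k * 0.5 * v (M^k + M^{k+1}) r
      = 0.5 * v (I + M) (I - dM)^{-1} (I - d^N M^N) r,  d = 1/(1+rate).
    """
    S = M.shape[0]
    d = 1.0 / (1.0 + discount_rate)
    eye = np.eye(S)
    MN = np.linalg.matrix_power(M, n_cycles)
    core = np.linalg.solve(eye - d * M, (eye - (d ** n_cycles) * MN) @ reward)
    return float(0.5 * init @ (eye + M) @ core)


def stage_at_diagnosis_forward(dwell: list[float], diag: list[float],
                               n_cycles: int = 20000) -> np.ndarray:
    """Iterate the undiagnosed control-arm chain forward and tally the stage
    at which symptomatic diagnosis absorbs each unit of cohort mass."""
    p = [1.0 - np.exp(-1.0 / d) for d in dwell]
    occ = np.array([1.0, 0.0, 0.0, 0.0])
    diagnosed = np.zeros(4)
    for _ in range(n_cycles):
        new = np.zeros(4)
        for s in range(4):
            d = diag[s]
            diagnosed[s] += occ[s] * d
            if s < 3:
                new[s + 1] += occ[s] * (1.0 - d) * p[s]
                new[s] += occ[s] * (1.0 - d) * (1.0 - p[s])
            else:
                new[s] += occ[s] * (1.0 - d)
        occ = new
        if occ.sum() < 1e-14:
            break
    return diagnosed / diagnosed.sum()
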