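"""Independent oracles: direct stochastic simulation of the unwinding chain.

Deliberately written from the process definition (per-step competing
exponentials, one step at a time) with no reference to the package's matrix
exponential or its grouped completion-time sampler.
"""

import numpy as np


def stochastic_unwinding_curve(scheme, times, n_molecules, rng):
    """Fraction unwound at each time from explicit molecule simulation.

    Every molecule: Bernoulli(baseline) competence, an Exp(k_act) activation
    wait, then for each step an Exp(k_U + k_D) holding time and a Bernoulli
    branch choice between stepping forward and dissociating.

    Returns (fractions, standard_errors).
    """
    times = np.asarray(times, dtype=float)
    competent = rng.random(n_molecules) < scheme.baseline_amplitude
    t_done = rng.exponential(1.0 / scheme.k_act, size=n_molecules)
    alive = competent.copy()
    for step in scheme.steps:
        exit_rate = step.k_U + step.k_D
        t_done = t_done + rng.exponential(1.0 / exit_rate, size=n_molecules)
        forward = rng.random(n_molecules) < (step.k_U / exit_rate)
        alive &= forward
    frac = np.array([(alive & (t_done <= t)).mean() for t in times])
    se = np.sqrt(np.maximum(frac * (1 - frac), 1e-12) / n_molecules)
    return frac, se


def brute_force_amplitude(scheme):
    """Asymptote by explicit per-step survival product (enumeration oracle)."""
    amp = scheme.baseline_amplitude
    for step in scheme.steps:
        amp = amp * (step.k_U / (step.k_U + step.k_D))
    return amp
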