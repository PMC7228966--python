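"""Fitting model parameters with the genetic algorithm.

Two worked fits: an exactly identifiable two-parameter exponential, and the
receiver dose-response curve where the Hill parameters (K_RFP, n_RFP) are
recovered from steady outputs over a range of clamped AHL levels.
"""

import numpy as np

from chamberlink import circuit as cir
from chamberlink import gafit

# --- 1. two-parameter exponential -----------------------------------------
t = np.linspace(0.0, 100.0, 51)
observed = 3.0 * np.exp(-t / 25.0)
bounds = gafit.ParameterBounds(lower={"A": 0.1, "tau": 1.0},
                               upper={"A": 10.0, "tau": 100.0},
                               scale={"A": "log", "tau": "log"})
res = gafit.fit(gafit.FitProblem(
    lambda p: p["A"] * np.exp(-t / p["tau"]), observed, bounds), rng_seed=101)
print("exponential fit (truth A=3, tau=25):")
print(f"  A   = {res.best_parameters['A']:.4f}")
print(f"  tau = {res.best_parameters['tau']:.4f}")
print(f"  objective {res.best_objective:.3e} after "
      f"{len(res.objective_trace)} generations "
      f"(converged={res.converged})")

# --- 2. receiver dose-response Hill parameters -----------------------------
true = cir.CircuitParameters()
levels = np.logspace(-1, 3, 25)
target = cir.dose_response(true, levels)


def simulate(p):
    trial = cir.CircuitParameters(K_RFP=p["K_RFP"], n_RFP=p["n_RFP"])
    return cir.dose_response(trial, levels)


b = gafit.ParameterBounds(lower={"K_RFP": 10.0, "n_RFP": 0.5},
                          upper={"K_RFP": 1000.0, "n_RFP": 4.0},
                          scale={"K_RFP": "log"})
res2 = gafit.fit(gafit.FitProblem(simulate, target, b), rng_seed=202)
print(f"\ndose-response fit (truth K_RFP={true.K_RFP}, n_RFP={true.n_RFP}):")
print(f"  K_RFP = {res2.best_parameters['K_RFP']:.2f}")
print(f"  n_RFP = {res2.best_parameters['n_RFP']:.3f}")
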