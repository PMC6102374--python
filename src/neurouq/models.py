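"""Built-in, dependency-free demonstration models.

Three model families are provided:

* ``coffee_cup`` — Newton's law of cooling, dT/dt = -kappa (T - T_env)
  with T(0) = 95 degC over 200 minutes, plus a deliberately
  over-parameterized variant dT/dt = -alpha * kappa_hat (T - T_env) whose
  two parameters are statistically dependent (alpha * kappa_hat must be
  distributed like kappa).
* ``hodgkin_huxley`` — the classical four-variable squid-axon model in
  its original convention (resting potential at 0 mV, depolarization
  positive), driven by a constant 140 uA/cm^2 current from t = 0 and
  reported over the 5-15 ms window.
* ``brunel_lif`` — a sparsely connected recurrent network of
  current-based leaky integrate-and-fire neurons with delta synapses
  (10,000 excitatory / 2,500 inhibitory, fixed in-degree 1,000/250),
  returning spike trains of 20 recorded excitatory units.

Each model exposes the black-box contract of the runner: a callable
returning (time, values, info).  The Hodgkin-Huxley model additionally
supports batched evaluation (all parameter sets integrated side by side
as numpy arrays), which the ensemble evaluator exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .distributions import (ConditionalJoint, ParameterSet, Parameter,
                            Uniform, uniform_pm)
from .features import SpikeTrainSet

__all__ = [
    "coffee_cup",
    "coffee_cup_model",
    "coffee_cup_parameters",
    "coffee_cup_dependent",
    "coffee_cup_dependent_model",
    "coffee_cup_dependent_parameters",
    "HH_DEFAULTS",
    "HH_PARAM_NAMES",
    "hodgkin_huxley",
    "hodgkin_huxley_batch",
    "hodgkin_huxley_model",
    "hodgkin_huxley_parameters",
    "BrunelParams",
    "brunel_lif",
    "brunel_model",
    "brunel_parameters",
]

# ---------------------------------------------------------------------------
# cooling coffee cup
# ---------------------------------------------------------------------------

COFFEE_T0 = 95.0          # degC, fixed initial temperature
COFFEE_SPAN = 200.0       # minutes
COFFEE_GRID_POINTS = 150


def coffee_cup(kappa: float, T_env: float):
    """Temperature of a cooling coffee cup over 200 minutes.

    Solves dT/dt = -kappa (T - T_env), T(0) = 95, with a stiff-capable
    adaptive integrator at tight tolerances, reported on a uniform
    150-point grid.  (The exact solution T_env + (95 - T_env) e^{-kappa t}
    is used in tests as the oracle, not here.)
    """
    t = np.linspace(0.0, COFFEE_SPAN, COFFEE_GRID_POINTS)
    sol = solve_ivp(lambda _t, T: -kappa * (T - T_env), (0.0, COFFEE_SPAN),
                    [COFFEE_T0], t_eval=t, method="LSODA",
                    rtol=1e-10, atol=1e-10)
    return t, sol.y[0], None


def coffee_cup_dependent(alpha: float, kappa_hat: float, T_env: float = 20.0):
    """Reparameterized coffee cup: dT/dt = -alpha kappa_hat (T - T_env).

    The trajectory is identical to ``coffee_cup`` with
    kappa = alpha * kappa_hat.
    """
    return coffee_cup(alpha * kappa_hat, T_env)


def coffee_cup_parameters() -> ParameterSet:
    """The independent case-study priors: kappa ~ U(0.025, 0.075) 1/min,
    T_env ~ U(15, 25) degC."""
    return ParameterSet({
        "kappa": Uniform(0.025, 0.075),
        "T_env": Uniform(15.0, 25.0),
    })


def coffee_cup_dependent_parameters(alpha_range=(0.5, 1.5)) -> ParameterSet:
    """Dependent priors for the reparameterized cup.

    alpha gets an (arbitrary, zero-free) uniform distribution; the
    conditional distribution of kappa_hat given alpha is the kappa prior
    scaled by 1/alpha, so that the product alpha * kappa_hat is
    distributed exactly like kappa.  T_env keeps its independent
    uniform prior.  The resulting joint is dependent and exercises the
    Rosenblatt machinery; the choice of the alpha distribution cannot
    affect the model output statistics.
    """
    a_lo, a_hi = alpha_range
    if a_lo <= 0 <= a_hi or a_lo == 0 or a_hi == 0:
        raise ValueError("the alpha range must not contain 0")

    def kappa_hat_given(prev):
        alpha = prev[0]
        lo, hi = 0.025 / alpha, 0.075 / alpha
        return Uniform(min(lo, hi), max(lo, hi))

    joint = ConditionalJoint([Uniform(a_lo, a_hi), kappa_hat_given,
                              Uniform(15.0, 25.0)])
    return ParameterSet(
        [Parameter("alpha", distribution=Uniform(a_lo, a_hi)),
         Parameter("kappa_hat", distribution=Uniform(0.025 / a_hi, 0.075 / a_lo)),
         Parameter("T_env", distribution=Uniform(15.0, 25.0))],
        distribution=joint)


# ---------------------------------------------------------------------------
# Hodgkin-Huxley
# ---------------------------------------------------------------------------

HH_PARAM_NAMES = ("V0", "Cm", "gbar_Na", "gbar_K", "gbar_L",
                  "E_Na", "E_K", "E_L", "n0", "m0", "h0")

#: Original 1952 parameter values, resting-potential-at-0 convention.
HH_DEFAULTS = {
    "V0": -10.0,        # mV, initial voltage
    "Cm": 1.0,          # uF/cm^2, membrane capacitance
    "gbar_Na": 120.0,   # mS/cm^2, max sodium conductance
    "gbar_K": 36.0,     # mS/cm^2, max potassium conductance
    "gbar_L": 0.3,      # mS/cm^2, max leak conductance
    "E_Na": 112.0,      # mV, sodium reversal potential
    "E_K": -12.0,       # mV, potassium reversal potential
    "E_L": 10.613,      # mV, leak reversal potential
    "n0": 0.0011,       # initial K activation gate
    "m0": 0.0003,       # initial Na activation gate
    "h0": 0.9998,       # initial Na inactivation gate
}

HH_STIMULUS = 140.0     # uA/cm^2, constant current from t = 0
HH_DT = 0.01            # ms, fixed RK4 step
HH_RECORD_EVERY = 5     # record every 5th step -> 0.05 ms output resolution
HH_T_END = 15.0         # ms
HH_WINDOW = (5.0, 15.0) # ms, reported analysis window


def _expm1_ratio(x):
    """x / (exp(x) - 1), continuous through x = 0."""
    x = np.asarray(x, float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-7
    out[small] = 1.0 - 0.5 * x[small]
    xs = x[~small]
    out[~small] = xs / np.expm1(xs)
    return out


def _hh_rates(V):
    """Gating rate functions of the original model (V in mV, rates in 1/ms).

    The voltage is the displacement from rest with depolarization
    positive, the sign convention that produces upward action potentials.
    """
    a_n = 0.1 * _expm1_ratio((10.0 - V) / 10.0)
    b_n = 0.125 * np.exp(-V / 80.0)
    a_m = _expm1_ratio((25.0 - V) / 10.0)
    b_m = 4.0 * np.exp(-V / 18.0)
    a_h = 0.07 * np.exp(-V / 20.0)
    b_h = 1.0 / (np.exp((30.0 - V) / 10.0) + 1.0)
    return a_n, b_n, a_m, b_m, a_h, b_h


def hodgkin_huxley_batch(params: np.ndarray, stimulus: float = HH_STIMULUS,
                         dt: float = HH_DT, t_end: float = HH_T_END,
                         record_every: int = HH_RECORD_EVERY):
    """Integrate many Hodgkin-Huxley parameter sets side by side.

    ``params`` has shape (M, 11) with columns ordered as
    ``HH_PARAM_NAMES``.  Fixed-step RK4; returns (time, V) with V of
    shape (M, n_recorded).  The full trace from t = 0 is returned; the
    5-15 ms analysis window is cut afterwards by the caller.
    """
    params = np.atleast_2d(np.asarray(params, float))
    (V0, Cm, gNa, gK, gL, ENa, EK, EL, n0, m0, h0) = params.T
    n_steps = int(round(t_end / dt))
    rec_idx = np.arange(0, n_steps + 1, record_every)
    time = rec_idx * dt
    M = params.shape[0]
    V = V0.copy()
    n = n0.copy()
    m = m0.copy()
    h = h0.copy()
    out = np.empty((M, rec_idx.size))
    out[:, 0] = V
    inv_Cm = 1.0 / Cm

    def deriv(V, n, m, h):
        a_n, b_n, a_m, b_m, a_h, b_h = _hh_rates(V)
        I_ion = (gNa * m**3 * h * (V - ENa) + gK * n**4 * (V - EK)
                 + gL * (V - EL))
        dV = (stimulus - I_ion) * inv_Cm
        dn = a_n * (1.0 - n) - b_n * n
        dm = a_m * (1.0 - m) - b_m * m
        dh = a_h * (1.0 - h) - b_h * h
        return dV, dn, dm, dh

    for step in range(1, n_steps + 1):
        k1 = deriv(V, n, m, h)
        k2 = deriv(V + 0.5 * dt * k1[0], n + 0.5 * dt * k1[1],
                   m + 0.5 * dt * k1[2], h + 0.5 * dt * k1[3])
        k3 = deriv(V + 0.5 * dt * k2[0], n + 0.5 * dt * k2[1],
                   m + 0.5 * dt * k2[2], h + 0.5 * dt * k2[3])
        k4 = deriv(V + dt * k3[0], n + dt * k3[1],
                   m + dt * k3[2], h + dt * k3[3])
        V = V + (dt / 6.0) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        n = n + (dt / 6.0) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        m = m + (dt / 6.0) * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        h = h + (dt / 6.0) * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        if step % record_every == 0:
            out[:, step // record_every] = V
    return time, out


def hodgkin_huxley(V0=HH_DEFAULTS["V0"], Cm=HH_DEFAULTS["Cm"],
                   gbar_Na=HH_DEFAULTS["gbar_Na"], gbar_K=HH_DEFAULTS["gbar_K"],
                   gbar_L=HH_DEFAULTS["gbar_L"], E_Na=HH_DEFAULTS["E_Na"],
                   E_K=HH_DEFAULTS["E_K"], E_L=HH_DEFAULTS["E_L"],
                   n0=HH_DEFAULTS["n0"], m0=HH_DEFAULTS["m0"],
                   h0=HH_DEFAULTS["h0"], stimulus: float = HH_STIMULUS,
                   dt: float = HH_DT):
    """Membrane potential of the original Hodgkin-Huxley model.

    Simulated from t = 0 with a constant external current of
    140 uA/cm^2; the returned trace is restricted to the 5-15 ms window
    (the first 5 ms are discarded as initial transient).
    """
    p = np.array([[V0, Cm, gbar_Na, gbar_K, gbar_L, E_Na, E_K, E_L,
                   n0, m0, h0]])
    time, V = hodgkin_huxley_batch(p, stimulus=stimulus, dt=dt)
    mask = (time >= HH_WINDOW[0]) & (time <= HH_WINDOW[1])
    if not np.all(np.isfinite(V)):
        return time[mask], None, {"stimulus_start": 0.0,
                                  "stimulus_end": HH_T_END}
    return time[mask], V[0, mask], {"stimulus_start": 0.0,
                                    "stimulus_end": HH_T_END}


def hodgkin_huxley_parameters(fraction: float = 0.1) -> ParameterSet:
    """All 11 original parameters, uniform within +/-``fraction`` of their
    nominal values."""
    return ParameterSet({name: uniform_pm(HH_DEFAULTS[name], fraction)
                         for name in HH_PARAM_NAMES})


# ---------------------------------------------------------------------------
# Brunel network
# ---------------------------------------------------------------------------

@dataclass
class BrunelParams:
    """Parameters of the sparsely connected recurrent LIF network.

    The three uncertain parameters of the case study are ``eta`` (external
    Poisson rate relative to the threshold rate), ``g`` (relative strength
    of inhibition) and ``delay`` (synaptic delay, ms).  The network itself
    is fixed: N_E excitatory and N_I inhibitory neurons with fixed
    in-degree C_E = eps*N_E excitatory and C_I = eps*N_I inhibitory
    connections per neuron, delta synapses of amplitude J (excitatory) and
    -g*J (inhibitory).  Membrane constants are the canonical ones of this
    network model: tau_m = 20 ms, threshold theta = 20 mV, reset
    V_r = 10 mV, refractory period 2 ms.
    """

    eta: float = 2.0
    g: float = 5.0
    delay: float = 1.5          # ms
    J: float = 0.1              # mV
    n_excitatory: int = 10000
    n_inhibitory: int = 2500
    epsilon: float = 0.1
    duration: float = 1000.0    # ms
    discard: float = 100.0      # ms of initial transient not recorded
    n_record: int = 20          # recorded excitatory units
    tau_m: float = 20.0         # ms
    theta: float = 20.0         # mV
    V_reset: float = 10.0       # mV
    tau_rp: float = 2.0         # ms
    dt: float = 0.1             # ms

    @property
    def C_E(self) -> int:
        return int(round(self.epsilon * self.n_excitatory))

    @property
    def C_I(self) -> int:
        return int(round(self.epsilon * self.n_inhibitory))

    @property
    def nu_threshold(self) -> float:
        """Threshold rate theta / (J C_E tau_m), spikes/ms per input."""
        return self.theta / (self.J * self.C_E * self.tau_m)


def brunel_lif(params: BrunelParams | None = None, seed: int = 0,
               **overrides) -> SpikeTrainSet:
    """Simulate the recurrent network and return recorded spike trains.

    Current-based LIF dynamics with delta synapses on a fixed 0.1 ms
    grid: between spikes the membrane decays exponentially with tau_m;
    each presynaptic spike arriving after the synaptic delay deflects the
    membrane by J (excitatory) or -g*J (inhibitory).  Every neuron
    additionally receives independent external Poisson drive of total
    rate eta * nu_thr * C_E.  Spikes reset the membrane to V_r and start
    a 2 ms refractory period.  Deterministic for a given seed.

    Returns the spike times of the first ``n_record`` excitatory units in
    the window [discard, duration] ms.
    """
    p = params or BrunelParams()
    if overrides:
        p = BrunelParams(**{**p.__dict__, **overrides})
    if p.delay < p.dt:
        raise ValueError("synaptic delay must be at least one time step")
    rng = np.random.default_rng(seed)
    N = p.n_excitatory + p.n_inhibitory
    n_steps = int(round(p.duration / p.dt))
    delay_steps = int(round(p.delay / p.dt))
    decay = math.exp(-p.dt / p.tau_m)
    ext_rate = p.eta * p.nu_threshold * p.C_E * p.dt  # expected spikes/step

    # fixed in-degree connectivity: each neuron draws C_E excitatory and
    # C_I inhibitory presynaptic partners without replacement (uniform
    # subsets via the smallest-uniforms trick), then the (pre, post)
    # pairs are inverted into flat out-target lists for push-style
    # propagation
    def fixed_indegree(n_pre, k, chunk=1024):
        pres = np.empty((N, k), dtype=np.int32)
        for start in range(0, N, chunk):
            stop = min(start + chunk, N)
            r = rng.random((stop - start, n_pre), dtype=np.float32)
            pres[start:stop] = np.argpartition(r, k - 1, axis=1)[:, :k]
        return pres

    pre_e = fixed_indegree(p.n_excitatory, p.C_E)
    pre_i = fixed_indegree(p.n_inhibitory, p.C_I) + p.n_excitatory
    posts = np.arange(N, dtype=np.int32)
    pre_all = np.concatenate([pre_e.ravel(), pre_i.ravel()])
    post_all = np.concatenate([np.repeat(posts, p.C_E),
                               np.repeat(posts, p.C_I)])
    del pre_e, pre_i
    order = np.argsort(pre_all, kind="stable")
    out_flat = post_all[order]
    out_counts = np.bincount(pre_all, minlength=N)
    out_offsets = np.zeros(N + 1, dtype=np.int64)
    out_offsets[1:] = np.cumsum(out_counts)
    del pre_all, post_all, order

    V = np.zeros(N)
    refractory_until = np.full(N, -1)
    buffer = np.zeros((delay_steps + 1, N))     # circular delayed-input buffer
    rec_spikes: list[list[float]] = [[] for _ in range(p.n_record)]
    weight = np.where(np.arange(N) < p.n_excitatory, p.J, -p.g * p.J)

    for step in range(n_steps):
        t = step * p.dt
        slot = step % (delay_steps + 1)
        active = refractory_until < step
        V[active] = (V[active] * decay + buffer[slot][active]
                     + rng.poisson(ext_rate, size=int(active.sum())) * p.J)
        buffer[slot] = 0.0
        spiking = np.flatnonzero(active & (V >= p.theta))
        if spiking.size:
            V[spiking] = p.V_reset
            refractory_until[spiking] = step + int(round(p.tau_rp / p.dt))
            dest_slot = (step + delay_steps) % (delay_steps + 1)
            cat = np.concatenate([out_flat[out_offsets[j]:out_offsets[j + 1]]
                                  for j in spiking])
            wts = np.repeat(weight[spiking], out_counts[spiking])
            buffer[dest_slot] += np.bincount(cat, weights=wts, minlength=N)
            if t >= p.discard:
                for j in spiking[spiking < p.n_record]:
                    rec_spikes[j].append(t)
    trains = [np.asarray(s) - p.discard for s in rec_spikes]
    return SpikeTrainSet(trains, end=p.duration - p.discard, resolution=p.dt)


def brunel_parameters(state: str = "AI") -> ParameterSet:
    """Uncertain-parameter priors of the two analyzed network states.

    SR (synchronous regular): g ~ U(1, 3); AI (asynchronous irregular):
    g ~ U(5, 8).  Both states share eta ~ U(1.5, 3.5) and
    delay ~ U(1.5, 3) ms.
    """
    g_range = {"SR": (1.0, 3.0), "AI": (5.0, 8.0)}.get(state.upper())
    if g_range is None:
        raise ValueError("state must be 'SR' or 'AI'")
    return ParameterSet({
        "eta": Uniform(1.5, 3.5),
        "g": Uniform(*g_range),
        "delay": Uniform(1.5, 3.0),
    })


# ---------------------------------------------------------------------------
# runner-facing model wrappers (built lazily to avoid an import cycle)
# ---------------------------------------------------------------------------

def coffee_cup_model():
    from .runner import Model
    return Model(run=coffee_cup, labels=("Time (min)", "Temperature (degC)"))


def coffee_cup_dependent_model():
    from .runner import Model
    return Model(run=coffee_cup_dependent,
                 labels=("Time (min)", "Temperature (degC)"))


def _hh_run_batch(param_dicts):
    matrix = np.array([[{**HH_DEFAULTS, **pd}[name] for name in HH_PARAM_NAMES]
                       for pd in param_dicts])
    time, V = hodgkin_huxley_batch(matrix)
    mask = (time >= HH_WINDOW[0]) & (time <= HH_WINDOW[1])
    info = {"stimulus_start": 0.0, "stimulus_end": HH_T_END}
    results = []
    for row in V:
        if np.all(np.isfinite(row)):
            results.append((time[mask], row[mask], info))
        else:
            results.append((time[mask], None, info))
    return results


def hodgkin_huxley_model():
    from .runner import Model
    return Model(run=hodgkin_huxley, run_batch=_hh_run_batch,
                 labels=("Time (ms)", "Membrane potential (mV)"))


def _brunel_run(eta, g, delay, seed=42, state_overrides=None):
    p = BrunelParams(eta=eta, g=g, delay=delay,
                     **(state_overrides or {}))
    trains = brunel_lif(p, seed=seed)
    return None, trains, {"end_time": trains.end}


def brunel_model(seed: int = 42, **overrides):
    """Network model wrapper; raw output is the SpikeTrainSet (ignored in
    UQ unless post-processed to binary trains)."""
    from .runner import Model

    def run(eta, g, delay):
        return _brunel_run(eta, g, delay, seed=seed, state_overrides=overrides)

    return Model(run=run, ignore=True,
                 labels=("Time (ms)", "Unit"))
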