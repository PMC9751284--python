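"""Division-structured stochastic model of a responding B-cell population.

Stimulated B lymphocytes regulate survival and division independently: cells
show broad (lognormal) variation in their time to first division, divide at a
roughly fixed interval thereafter, die with an exponential hazard, and
differentiate to antibody-secreting cells (ASC, CD138+) at a per-division
frequency that increases with generation number.  Differentiation is modelled
as an absorbing label: a daughter cell may acquire CD138 positivity at
division and passes it to all descendants, while its division and death
kinetics are unchanged (plasmablasts remain proliferative over the simulated
3-day window).  A compound perturbs the population through three
multiplicative axes: survival (death hazard), division rate and
differentiation probability.

Two views of the same process are provided:

* :func:`simulate_population` — an agent-based sampler (every cell draws its
  own first-division time and death time);
* :func:`expected_population` — the deterministic expectation of the agent
  process obtained by numerical integration over the first-division-time
  distribution, used as an oracle for the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

__all__ = [
    "CytonParams",
    "CompoundEffect",
    "PopulationState",
    "simulate_population",
    "expected_population",
]


@dataclass(frozen=True)
class CytonParams:
    """Kinetic parameters of an unperturbed responding population.

    Parameters
    ----------
    n0
        Number of founder cells placed in culture.
    t_first_div_meanlog, t_first_div_sdlog
        Parameters of the lognormal time-to-first-division distribution
        (hours); the broad variance of this distribution produces the
        asynchronous division peaks seen in dye-dilution profiles.
    t_div
        Fixed inter-division time for subsequent divisions (hours).
    death_hazard
        Per-hour exponential death hazard of undifferentiated live cells.
    p_diff0, p_diff_slope
        Differentiation probability applied to a daughter entering
        generation ``i`` is ``clamp(p_diff0 + p_diff_slope * i, 0, 1)``;
        differentiation frequency therefore increases with each generation.
    max_gen
        Highest generation index tracked; cells in ``max_gen`` no longer
        divide.
    """

    n0: int = 2000
    t_first_div_meanlog: float = float(np.log(40.0))
    t_first_div_sdlog: float = 0.2
    t_div: float = 10.0
    death_hazard: float = 0.01
    p_diff0: float = 0.0
    p_diff_slope: float = 0.05
    max_gen: int = 8

    def __post_init__(self) -> None:
        if self.n0 < 0:
            raise ValueError("n0 must be >= 0")
        if self.t_div < 0 or self.death_hazard < 0 or self.t_first_div_sdlog < 0:
            raise ValueError("times and hazards must be >= 0")
        if not 0.0 <= self.p_diff0 <= 1.0:
            raise ValueError("p_diff0 must lie in [0, 1]")
        if self.max_gen < 1:
            raise ValueError("max_gen must be >= 1")


@dataclass(frozen=True)
class CompoundEffect:
    """Multiplicative perturbation of the three phenotype axes.

    ``s_surv`` multiplies the death hazard, ``s_div`` the division rate
    (0 disables division entirely), ``s_diff`` the per-division
    differentiation probability.  The identity effect is (1, 1, 1).
    """

    compound_id: str = "control"
    dose: float = 1.0
    s_surv: float = 1.0
    s_div: float = 1.0
    s_diff: float = 1.0

    def __post_init__(self) -> None:
        for name in ("s_surv", "s_div", "s_diff"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")


@dataclass
class PopulationState:
    """Per-generation census of a population at one time point.

    ``live[i]`` counts undifferentiated live cells in generation ``i``,
    ``asc[i]`` differentiated (CD138+) cells, ``dead_cum`` is the cumulative
    number of deaths.  Counts are integers for the stochastic simulator and
    reals for the expectation.
    """

    time: float
    live: np.ndarray
    asc: np.ndarray
    dead_cum: float

    @property
    def max_gen(self) -> int:
        return len(self.live) - 1

    @property
    def total_live(self) -> float:
        """All live cells (undifferentiated + ASC)."""
        return float(self.live.sum() + self.asc.sum())

    def census(self) -> np.ndarray:
        """Per-generation live counts N_i = L_i + D_i."""
        return self.live + self.asc


def _p_diff(gen: int, params: CytonParams, effect: CompoundEffect) -> float:
    base = np.clip(params.p_diff0 + params.p_diff_slope * gen, 0.0, 1.0)
    return float(np.clip(base * effect.s_diff, 0.0, 1.0))


def _check_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending")
    return t


def simulate_population(
    params: CytonParams,
    effect: CompoundEffect,
    times,
    seed: int | np.random.Generator,
) -> list[PopulationState]:
    """Agent-based simulation of the perturbed population.

    Every founder draws a lognormal first-division time and an exponential
    death time; daughters inherit a fixed inter-division interval and draw
    fresh death times.  At each division a daughter entering generation ``i``
    acquires the absorbing CD138+ (ASC) label with probability
    ``clamp(clamp(p_diff0 + p_diff_slope*i, 0, 1) * s_diff, 0, 1)``; the
    label is inherited by all descendants and does not alter division or
    death kinetics (plasmablasts remain in cycle over the simulated window),
    which keeps the survival, proliferation and differentiation axes of a
    compound perturbation orthogonal.

    Returns one :class:`PopulationState` per requested time.  Bit-identical
    under a fixed seed.
    """
    t_req = _check_times(times)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_max = float(t_req[-1])
    G = params.max_gen
    lam = params.death_hazard * effect.s_surv

    live = np.zeros((len(t_req), G + 1))
    asc = np.zeros((len(t_req), G + 1))
    dead = np.zeros(len(t_req))

    # generation-0 wave
    n = int(params.n0)
    birth = np.zeros(n)
    is_asc = np.zeros(n, dtype=bool)  # undivided cells never carry the label
    if effect.s_div > 0 and n > 0:
        t1 = rng.lognormal(params.t_first_div_meanlog, params.t_first_div_sdlog, n)
        div_time = t1 / effect.s_div
    else:
        div_time = np.full(n, np.inf)
    gen = 0
    while n > 0:
        death_time = (
            birth + rng.exponential(1.0 / lam, n) if lam > 0 else np.full(n, np.inf)
        )
        if gen >= G:
            div_time = np.full(n, np.inf)
        exit_time = np.minimum(div_time, death_time)
        for k, t in enumerate(t_req):
            alive = (birth <= t) & (exit_time > t)
            live[k, gen] += np.count_nonzero(alive & ~is_asc)
            asc[k, gen] += np.count_nonzero(alive & is_asc)
            dead[k] += np.count_nonzero((death_time <= t) & (death_time < div_time))
        divides = (div_time < death_time) & (div_time <= t_max)
        n_div = int(np.count_nonzero(divides))
        if n_div == 0 or gen >= G:
            break
        d_birth = np.repeat(div_time[divides], 2)
        d_asc = np.repeat(is_asc[divides], 2)  # label is absorbing
        p = _p_diff(gen + 1, params, effect)
        d_asc |= rng.random(d_birth.size) < p
        birth, is_asc = d_birth, d_asc
        n = birth.size
        dt = params.t_div / effect.s_div if effect.s_div > 0 else np.inf
        div_time = birth + dt
        gen += 1

    return [
        PopulationState(time=float(t), live=live[k], asc=asc[k], dead_cum=float(dead[k]))
        for k, t in enumerate(t_req)
    ]


def expected_population(
    params: CytonParams,
    effect: CompoundEffect,
    times,
    grid_points: int = 4001,
) -> list[PopulationState]:
    """Deterministic expectation of :func:`simulate_population`.

    The flux of cells entering generation 1 is ``B_1(s) = 2 n0 f(s) e^{-λs}``
    with ``f`` the (rate-scaled) first-division-time density; live cells
    divide again exactly ``Δ = t_div / s_div`` later if they survive, so
    ``B_i(s) = B_1(s-(i-1)Δ) · 2^{i-1} e^{-λ(i-1)Δ}``.  Generation censuses
    ``N_i`` follow by integrating these fluxes against the exponential
    survival kernel on a fine trapezoid grid.  The CD138 label does not alter
    kinetics, so the ASC compartment is the deterministic split
    ``D_i = q_i N_i`` with ``q_i = 1 - Π_{j<=i}(1 - p_j)`` the probability of
    having differentiated at any division along the lineage.  Cumulative
    deaths come from the bookkeeping identity
    ``dead = n0 + #divisions − live − asc``.
    """
    t_req = _check_times(times)
    t_max = float(t_req[-1])
    G = params.max_gen
    lam = params.death_hazard * effect.s_surv
    n0 = float(params.n0)

    states = []
    if effect.s_div == 0 or n0 == 0:
        for t in t_req:
            live = np.zeros(G + 1)
            live[0] = n0 * np.exp(-lam * t)
            states.append(
                PopulationState(float(t), live, np.zeros(G + 1), n0 - live[0])
            )
        return states

    # first-division time scaled by the division-rate multiplier
    scale = np.exp(params.t_first_div_meanlog) / effect.s_div
    first_div = stats.lognorm(s=params.t_first_div_sdlog, scale=scale)
    delta = params.t_div / effect.s_div

    s = np.linspace(0.0, max(t_max, 1e-9), grid_points)
    f1 = first_div.pdf(s)
    p = np.array([_p_diff(i, params, effect) for i in range(G + 1)])

    # q_i: probability of having differentiated at any division 1..i
    q = np.zeros(G + 1)
    q[1:] = 1.0 - np.cumprod(1.0 - p[1:])

    # B_i on the grid, plus cumulative integrals of B_i and of B_i * e^{λs}
    cum_B = {}
    cum_G = {}
    for i in range(1, G + 1):
        shift = (i - 1) * delta
        fi = np.interp(s - shift, s, f1, left=0.0, right=0.0)
        Bi = 2.0**i * n0 * fi * np.exp(-lam * (s - shift)) * np.exp(-lam * shift)
        cum_B[i] = integrate.cumulative_trapezoid(Bi, s, initial=0.0)
        cum_G[i] = integrate.cumulative_trapezoid(Bi * np.exp(lam * s), s, initial=0.0)

    def interp(cum: np.ndarray, t: float) -> float:
        return float(np.interp(t, s, cum))

    for t in t_req:
        census = np.zeros(G + 1)
        census[0] = n0 * first_div.sf(t) * np.exp(-lam * t)
        n_div = 0.0
        for i in range(1, G + 1):
            lo = 0.0 if i == G else max(0.0, t - delta)
            census[i] = np.exp(-lam * t) * (
                interp(cum_G[i], t) - interp(cum_G[i], lo)
            )
            n_div += interp(cum_B[i], t) / 2.0
        live = (1.0 - q) * census
        asc = q * census
        dead = n0 + n_div - census.sum()
        states.append(PopulationState(float(t), live, asc, max(dead, 0.0)))
    return states
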