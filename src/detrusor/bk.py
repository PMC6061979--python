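"""Ten-state Markov model of the large-conductance Ca2+-activated K+ (BK) channel.

The channel is described by two tiers of five states: closed C0-C4 and open
O0-O4, the index counting bound Ca2+ ions.  Horizontal transitions within a
tier are sequential Ca2+ binding/unbinding with mass-action kinetics and
binding-site multiplicity (4, 3, 2, 1 forward; 1, 2, 3, 4 backward); open
states bind Ca2+ with higher affinity than closed states, which is what makes
the channel Ca2+-activated.  Vertical transitions C_i <-> O_i carry the
voltage dependence; the allosteric factor D = Kd_closed/Kd_open multiplies the
opening equilibrium once per bound Ca2+, as detailed balance around each
square of the scheme requires.  The C4 <-> O4 pair additionally carries a
Ca2+-saturating kinetic factor applied symmetrically to both directions, so
that this transition depends on both voltage and Ca2+ without disturbing the
equilibrium.

State ordering used everywhere: [C0 C1 C2 C3 C4 O0 O1 O2 O3 O4].

The conducting open probability is the sum over O1-O4; O0 is excluded by
default (``include_o0`` restores the convention in which every open state
conducts).

Units: mV, ms, mM, S/cm2, mA/cm2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .channels import TemperatureContext

__all__ = [
    "BKMarkovSpec",
    "BKOccupancy",
    "bk_transition_edges",
    "bk_transition_rates",
    "bk_rate_matrix",
    "bk_occupancy_step",
    "bk_stationary_occupancy",
    "bk_open_probability",
    "bk_current",
]

N_STATES = 10
#: index of the first open state (O0)
_O0 = 5
#: conducting states per the model's current equation (O1..O4)
CONDUCTING_STATES = (6, 7, 8, 9)


@dataclass(frozen=True)
class BKMarkovSpec:
    """Parameters of the 10-state scheme.

    kon          Ca2+ on-rate, per mM per ms (same for every binding step,
                 scaled by site multiplicity).
    kd_closed    Ca2+ dissociation constant of the closed tier, mM.
    kd_open      Ca2+ dissociation constant of the open tier, mM (< kd_closed).
    a0           base rate of the vertical (C<->O) transitions, per ms.
    l0           C0<->O0 open/closed equilibrium constant at 0 mV.
    forward_frac how the allosteric equilibrium factor l0*D**i splits between
                 opening (exponent forward_frac) and closing (forward_frac-1).
    za, zb       effective gating charges (e) of opening and closing.
    vslope       mV per unit charge in the exponential voltage factors.
    kc4          half-saturation (mM) of the extra Ca2+ factor on C4<->O4.
    include_o0   if true, O0 conducts as well.
    """

    gmax: float = 0.024
    erev: float = -75.0
    kon: float = 200.0
    kd_closed: float = 0.011
    kd_open: float = 0.0011
    a0: float = 0.3
    l0: float = 1e-3
    forward_frac: float = 0.7
    za: float = 0.8
    zb: float = 0.4
    vslope: float = 25.0
    kc4: float = 0.01
    include_o0: bool = False

    def __post_init__(self) -> None:
        if self.gmax < 0:
            raise ValueError("gmax must be nonnegative")
        for name in ("kon", "kd_closed", "kd_open", "a0", "l0", "vslope", "kc4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kd_open >= self.kd_closed:
            raise ValueError("open-tier Kd must be below closed-tier Kd")

    @property
    def allosteric_d(self) -> float:
        """Equilibrium gain in opening per bound Ca2+ (detailed balance)."""
        return self.kd_closed / self.kd_open


@dataclass
class BKOccupancy:
    """Probability vector over the ten states; sums to one."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape[0] != N_STATES:
            raise ValueError("occupancy must have 10 states")
        if np.any(self.p < -1e-9) or np.any(self.p > 1 + 1e-9):
            raise ValueError("occupancies must lie in [0, 1]")
        if not np.allclose(self.p.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("occupancy must sum to 1 within 1e-6")

    @classmethod
    def resting(cls) -> "BKOccupancy":
        p = np.zeros(N_STATES)
        p[0] = 1.0
        return cls(p)

    @property
    def open_total(self) -> float:
        return float(np.sum(self.p[_O0:], axis=0))


def bk_transition_edges() -> Tuple[np.ndarray, np.ndarray]:
    """The 26 directed edges (from-state, to-state) of the scheme topology.

    13 undirected pairs: 4 Ca-binding pairs in each tier plus the 5 vertical
    pairs; each contributes two directed edges.  Order matches the rate rows
    returned by :func:`bk_transition_rates`.
    """
    src, dst = [], []
    for i in range(4):  # closed tier binding / unbinding
        src += [i, i + 1]
        dst += [i + 1, i]
    for i in range(4):  # open tier
        src += [_O0 + i, _O0 + i + 1]
        dst += [_O0 + i + 1, _O0 + i]
    for i in range(5):  # vertical opening / closing
        src += [i, _O0 + i]
        dst += [_O0 + i, i]
    return np.array(src), np.array(dst)


_EDGE_SRC, _EDGE_DST = bk_transition_edges()


def bk_transition_rates(v, ca, spec: BKMarkovSpec, tadj: float = 1.0) -> np.ndarray:
    """Directed transition rates (per ms) on the edges of the scheme.

    ``v`` (mV) and ``ca`` (mM) may be scalars or arrays of a common shape;
    the result has shape (26,) + shape(v).  All rates are nonnegative; the
    Ca2+-binding (forward horizontal) rates vanish at ca = 0.
    """
    v = np.asarray(v, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("calcium concentration must be nonnegative")

    koff_c = spec.kon * spec.kd_closed
    koff_o = spec.kon * spec.kd_open
    d = spec.allosteric_d

    rates = np.empty((26,) + np.broadcast(v, ca).shape, dtype=float)
    k = 0
    for koff in (koff_c, koff_o):  # closed tier then open tier
        for i in range(4):
            rates[k] = (4 - i) * spec.kon * ca  # bind
            rates[k + 1] = (i + 1) * koff  # unbind
            k += 2
    ea = np.exp(spec.za * v / spec.vslope)
    eb = np.exp(-spec.zb * v / spec.vslope)
    f4 = 0.5 + 0.5 * ca / (ca + spec.kc4)  # symmetric kinetic factor on C4<->O4
    for i in range(5):
        allo = spec.l0 * d**i
        alpha = spec.a0 * allo**spec.forward_frac * ea
        beta = spec.a0 * allo ** (spec.forward_frac - 1.0) * eb
        if i == 4:
            alpha = alpha * f4
            beta = beta * f4
        rates[k] = alpha
        rates[k + 1] = beta
        k += 2
    return rates * tadj


def bk_rate_matrix(
    v: float, ca: float, spec: BKMarkovSpec, temp: TemperatureContext | None = None
) -> np.ndarray:
    """Dense 10x10 master-equation generator Q with d(occ)/dt = Q @ occ.

    Off-diagonal Q[j, i] is the i -> j rate on the 13 adjacent state pairs
    (zero elsewhere); the diagonal makes every column sum to zero, which is
    probability conservation.
    """
    tadj = temp.tadj if temp is not None else 1.0
    rates = bk_transition_rates(v, ca, spec, tadj)
    q = np.zeros((N_STATES, N_STATES))
    np.add.at(q, (_EDGE_DST, _EDGE_SRC), rates)
    q[np.diag_indices(N_STATES)] -= q.sum(axis=0)
    return q


def bk_occupancy_step(
    occ: BKOccupancy,
    v: float,
    ca: float,
    dt: float,
    spec: BKMarkovSpec,
    temp: TemperatureContext | None = None,
    max_substeps: int = 1_000_000,
) -> BKOccupancy:
    """Advance the master equation by ``dt`` with automatic sub-stepping.

    The Euler substep is chosen so no state's total exit probability per
    substep exceeds 0.1, which keeps every component nonnegative and the sum
    exactly conserved (the generator's columns sum to zero).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    q = bk_rate_matrix(v, ca, spec, temp)
    max_exit = float(np.max(-np.diag(q)))
    n_sub = max(1, int(np.ceil(max_exit * dt / 0.1)))
    if n_sub > max_substeps:
        raise ValueError(
            f"step size {dt} ms requires {n_sub} substeps; transition "
            "probability per step would exceed 1 - reduce dt"
        )
    p = occ.p.copy()
    h = dt / n_sub
    for _ in range(n_sub):
        p = p + h * (q @ p)
    return BKOccupancy(np.clip(p, 0.0, 1.0) / np.sum(np.clip(p, 0.0, 1.0)))


def bk_stationary_occupancy(
    v: float, ca: float, spec: BKMarkovSpec, temp: TemperatureContext | None = None
) -> BKOccupancy:
    """Equilibrium occupancy: the normalized null vector of the generator."""
    q = bk_rate_matrix(v, ca, spec, temp)
    # replace one balance equation by the normalization constraint
    a = np.vstack([q[:-1], np.ones(N_STATES)])
    b = np.zeros(N_STATES)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(a, b, rcond=None)
    p = np.clip(p, 0.0, 1.0)
    return BKOccupancy(p / p.sum())


def bk_open_probability(occ: BKOccupancy, spec: BKMarkovSpec) -> float:
    """Conducting open probability: O1+O2+O3+O4 (plus O0 if configured)."""
    idx = list(CONDUCTING_STATES) + ([_O0] if spec.include_o0 else [])
    return float(np.sum(occ.p[idx], axis=0))


def bk_current(occ: BKOccupancy, v: float, spec: BKMarkovSpec) -> float:
    """BK current density gmax * O * (V - EK), O the conducting open prob."""
    return spec.gmax * bk_open_probability(occ, spec) * (v - spec.erev)
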