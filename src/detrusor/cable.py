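"""1-D propagation: multicompartment cables and gap-junction coupled strands.

A long detrusor smooth muscle cell is discretized into isopotential
compartments joined by axial conductances computed from the cytoplasmic
resistivity and the cylinder cross-section,

    g_axial = (pi d^2 / 4) / (Ri * dx),

with sealed ends (no leak beyond the membrane itself).  Multicellular
strands place an ohmic gap junction of resistance r_j between the abutting
ends of adjacent cells; junctional current is simply dV / r_j.

The reference space constant (1.8 mm, from prior syncytium work) is carried
alongside the value implied by the passive parameters; the two are not
mutually consistent and both are reported by :func:`cable_diagnostics`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cell import SimulationTrace, StimulusProtocol, run_protocol
from .config import CellGeometry, ModelConfig, default_config
from .engine import CompartmentModel

__all__ = [
    "CableSpec",
    "GapJunction",
    "RecordingSite",
    "build_cable",
    "build_strand",
    "propagate",
    "cable_diagnostics",
    "foot_curvature",
]


@dataclass(frozen=True)
class CableSpec:
    """Geometry of the unicellular 1-D cable (22.2 mm, 111 compartments)."""

    total_length_mm: float = 22.2
    n_compartments: int = 111
    geometry: CellGeometry = field(default_factory=CellGeometry)
    lambda_ref_mm: float = 1.8

    def __post_init__(self) -> None:
        if self.n_compartments < 3:
            raise ValueError("a cable needs at least 3 compartments")
        if self.total_length_mm <= 0:
            raise ValueError("total length must be positive")

    @property
    def compartment_length_mm(self) -> float:
        return self.total_length_mm / self.n_compartments


@dataclass(frozen=True)
class GapJunction:
    """Ohmic intercellular coupling: resistance in MOhm between two
    (cell index, compartment index) endpoints."""

    resistance_mohm: float
    endpoints: Tuple[Tuple[int, int], Tuple[int, int]]

    def __post_init__(self) -> None:
        if self.resistance_mohm <= 0:
            raise ValueError("gap junction resistance must be positive")

    @property
    def conductance_uS(self) -> float:
        return 1.0 / self.resistance_mohm


@dataclass(frozen=True)
class RecordingSite:
    """A labelled recording position, in mm from the cable origin."""

    label: str
    position_mm: float

    def index(self, compartment_length_mm: float, n_comp: int) -> int:
        idx = int(round(self.position_mm / compartment_length_mm - 0.5))
        if not (0 <= idx < n_comp):
            raise ValueError(
                f"site {self.label} at {self.position_mm} mm lies outside the model"
            )
        return idx


def axial_conductance_uS(geometry: CellGeometry, dx_mm: float) -> float:
    """Axial coupling conductance between adjacent compartments, in uS."""
    d_cm = geometry.diameter * 1e-4
    area = math.pi * d_cm**2 / 4.0
    g_S = area / (geometry.ri * dx_mm * 0.1)
    return g_S * 1e6


def build_cable(
    spec: CableSpec, config: Optional[ModelConfig] = None
) -> CompartmentModel:
    """Compile the unicellular cable; every compartment carries the full
    channel complement and its own Ca2+ shell."""
    config = config or default_config()
    n = spec.n_compartments
    dx_mm = spec.compartment_length_mm
    lam = spec.geometry.space_constant_mm
    if dx_mm > lam / 3.0:
        warnings.warn(
            f"compartment length {dx_mm:.2f} mm exceeds lambda/3 "
            f"({lam / 3.0:.2f} mm); spatial discretization may be coarse",
            stacklevel=2,
        )
    g = axial_conductance_uS(spec.geometry, dx_mm)
    coupling = [(i, i + 1, g) for i in range(n - 1)]
    return CompartmentModel(
        config,
        n_comp=n,
        compartment_length_um=dx_mm * 1e3,
        coupling=coupling,
    )


def build_strand(
    n_cells: int = 3,
    rj_mohm: float = 30.0,
    per_cell_compartments: int = 51,
    config: Optional[ModelConfig] = None,
    compartment_length_mm: float = 0.2,
) -> CompartmentModel:
    """End-to-end cells joined by ohmic gap junctions (Cell 0, Cell 1, ...).

    ``rj_mohm`` may be ``inf`` to isolate the cells electrically.
    """
    if n_cells < 2:
        raise ValueError("a strand needs at least 2 cells")
    config = config or default_config()
    geom = config.geometry
    g_ax = axial_conductance_uS(geom, compartment_length_mm)
    g_gap = 0.0 if math.isinf(rj_mohm) else 1.0 / rj_mohm
    coupling: List[Tuple[int, int, float]] = []
    n_total = n_cells * per_cell_compartments
    for c in range(n_cells):
        base = c * per_cell_compartments
        coupling += [
            (base + i, base + i + 1, g_ax) for i in range(per_cell_compartments - 1)
        ]
        if c + 1 < n_cells and g_gap > 0.0:
            coupling.append((base + per_cell_compartments - 1,
                             base + per_cell_compartments, g_gap))
    return CompartmentModel(
        config,
        n_comp=n_total,
        compartment_length_um=compartment_length_mm * 1e3,
        coupling=coupling,
    )


def propagate(
    model: CompartmentModel,
    protocol: StimulusProtocol,
    sites: Sequence[RecordingSite],
    dt: Optional[float] = None,
    record_every: int = 5,
) -> Dict[str, SimulationTrace]:
    """Run a stimulus on the cable/strand and record at the named sites."""
    dx_mm = model.comp_length_um * 1e-3
    indices = [s.index(dx_mm, model.n_comp) for s in sites]
    labels = [s.label for s in sites]
    trace = run_protocol(
        protocol,
        model=model,
        dt=dt,
        record_every=record_every,
        record_comps=indices,
        site_labels=labels,
        record_currents=False,
    )
    out: Dict[str, SimulationTrace] = {}
    v = np.atleast_2d(trace.v.T).T
    ca = np.atleast_2d(trace.ca.T).T if trace.ca is not None else None
    for k, label in enumerate(labels):
        out[label] = SimulationTrace(
            time=trace.time,
            v=v[:, k],
            ca=ca[:, k] if ca is not None else None,
            sites=(label,),
            metadata=dict(trace.metadata, site=label, position_mm=sites[k].position_mm),
        )
    return out


def cable_synaptic_protocol(
    model: CompartmentModel,
    position_mm: Optional[float] = None,
    gmax_uS: float = 0.07,
    tau_rise: float = 15.0,
    tau_decay: float = 25.0,
    total: float = 600.0,
    settle: float = 150.0,
) -> StimulusProtocol:
    """Synaptic drive at a cable position (midpoint by default).

    The conductance default is larger than the single-cell value because a
    cable's input conductance is set by the axial spread of charge, not by
    the membrane of one compartment; 0.07 uS reliably evokes a propagating
    spike on the standard 22.2 mm cable.
    """
    import dataclasses as _dc

    from .cell import standard_synaptic_protocol

    dx_mm = model.comp_length_um * 1e-3
    if position_mm is None:
        comp = model.n_comp // 2
    else:
        comp = RecordingSite("stim", position_mm).index(dx_mm, model.n_comp)
    proto = standard_synaptic_protocol(
        gmax_uS=gmax_uS, tau_rise=tau_rise, tau_decay=tau_decay,
        total=total, settle=settle,
    )
    return _dc.replace(
        proto,
        synapses=tuple(_dc.replace(s, compartment=comp) for s in proto.synapses),
    )


def cable_diagnostics(spec: CableSpec) -> Dict[str, float]:
    """Space constants: the reference value and the one implied by the
    passive parameters (they are not mutually consistent; both reported)."""
    return {
        "lambda_ref_mm": spec.lambda_ref_mm,
        "lambda_from_geometry_mm": spec.geometry.space_constant_mm,
        "compartment_length_mm": spec.compartment_length_mm,
    }


def foot_curvature(
    trace: SimulationTrace, rmp: Optional[float] = None
) -> float:
    """Mean second difference of V over the spike foot (10%-50% of upstroke).

    Positive means a concave-upward foot (propagated AP, driven by local
    circuit currents); negative means convex-upward (the synaptically evoked
    AP at the stimulation site).
    """
    t = np.asarray(trace.time)
    v = np.asarray(trace.v)
    if rmp is None:
        rmp = float(v[0])
    i_peak = int(np.argmax(v))
    amp = v[i_peak] - rmp
    lo, hi = rmp + 0.1 * amp, rmp + 0.5 * amp
    upstroke = np.nonzero((v[:i_peak] >= lo) & (v[:i_peak] <= hi))[0]
    if upstroke.size < 5:
        raise ValueError("too few samples on the spike foot")
    # restrict to the contiguous run ending at the upstroke
    breaks = np.nonzero(np.diff(upstroke) > 1)[0]
    if breaks.size:
        upstroke = upstroke[breaks[-1] + 1 :]
    seg = v[upstroke]
    return float(np.mean(np.diff(seg, 2)))
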