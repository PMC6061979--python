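"""Model configuration: cell geometry, channel complement, solver settings.

The default configuration carries the full detrusor smooth muscle channel
complement: two voltage-gated Ca2+ channels (CaL, CaT), two voltage-gated K+
channels (Kv1, KCNQ), three Ca2+-activated K+ channels (BK as a 10-state
Markov scheme, IK and SK as Hill-gated HH conductances), the ATP-inhibited
KATP channel, the hyperpolarization-activated channel Ih, and an ohmic
background leak.  Maximal conductances and reversal potentials of the nine
active channels are the published whole-cell values; the gating parameters
(half-potentials, slopes, time constants, Markov rates) are calibrated so
that the model reproduces the published whole-cell readouts (resting
potential, spike shape, block responses), and each parameter carries a
provenance tag saying whether it is source-cited, calibrated, or a plain
default.

Configurations serialize losslessly to YAML; loading validates the schema
and rejects unknown keys.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, List

import yaml

from .bk import BKMarkovSpec
from .calcium import CalciumShellSpec
from .channels import CaHillSpec, GatingVariableSpec, HHChannelSpec, LigandSpec, TauSpec

__all__ = [
    "CellGeometry",
    "SolverSpec",
    "ModelConfig",
    "default_config",
    "young_config",
    "load_config",
    "E_SYN",
    "YOUNG_SYNAPSE",
    "save_config",
    "REQUIRED_CHANNELS",
]

#: the nine active conductances every valid configuration must define
REQUIRED_CHANNELS = ("CaT", "CaL", "Kv1", "KCNQ", "IK", "SK", "KATP", "Ih")


@dataclass(frozen=True)
class CellGeometry:
    """Cylindrical single-cell morphology and passive membrane constants.

    length/diameter in um, cm in uF/cm2, rm in kOhm cm2, ri in Ohm cm.
    Membrane area is the lateral cylinder surface; the ends are ignored.
    """

    length: float = 200.0
    diameter: float = 6.0
    cm: float = 1.0
    rm: float = 138.0
    ri: float = 183.0

    def __post_init__(self) -> None:
        for name in ("length", "diameter", "cm", "rm", "ri"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def area_cm2(self) -> float:
        return math.pi * self.diameter * self.length * 1e-8

    @property
    def space_constant_mm(self) -> float:
        """Passive space constant sqrt(rm * d / (4 ri)) from the geometry."""
        rm_ohm_cm2 = self.rm * 1e3
        d_cm = self.diameter * 1e-4
        return math.sqrt(rm_ohm_cm2 * d_cm / (4.0 * self.ri)) * 10.0


@dataclass(frozen=True)
class SolverSpec:
    """Fixed-step forward-Euler integration settings (dt in ms)."""

    dt: float = 0.02
    method: str = "euler"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.method != "euler":
            raise ValueError("only the fixed-step Euler method is supported")


@dataclass
class ModelConfig:
    """Everything needed to build and integrate the cell model."""

    geometry: CellGeometry = field(default_factory=CellGeometry)
    channels: List[HHChannelSpec] = field(default_factory=list)
    bk: BKMarkovSpec = field(default_factory=BKMarkovSpec)
    leak_gmax: float = 7.25e-6
    leak_erev: float = -20.0
    calcium: CalciumShellSpec = field(default_factory=CalciumShellSpec)
    temperature: float = 37.0
    atp: float = 1.0
    apamin: float = 0.0
    v_init: float = -50.0
    solver: SolverSpec = field(default_factory=SolverSpec)
    provenance: Dict[str, str] = field(default_factory=dict)

    def channel(self, name: str) -> HHChannelSpec:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise KeyError(f"no channel named {name!r}")

    def with_scaled_gmax(self, factors: Dict[str, float]) -> "ModelConfig":
        """Copy of the config with named maximal conductances scaled.

        Recognized names: the HH channels, 'BK' and 'Leak'.  Used by the
        block and sweep experiments.
        """
        cfg = dataclasses.replace(self)
        cfg.channels = list(self.channels)
        cfg.provenance = dict(self.provenance)
        for name, f in factors.items():
            if f < 0:
                raise ValueError("scale factor must be nonnegative")
            if name == "BK":
                cfg.bk = dataclasses.replace(self.bk, gmax=self.bk.gmax * f)
            elif name == "Leak":
                cfg.leak_gmax = self.leak_gmax * f
            else:
                ch = self.channel(name)
                cfg.channels = [
                    dataclasses.replace(c, gmax=c.gmax * f) if c.name == name else c
                    for c in cfg.channels
                ]
        return cfg

    def validate(self) -> None:
        names = [ch.name for ch in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names in configuration")
        missing = [n for n in REQUIRED_CHANNELS if n not in names]
        if missing:
            raise ValueError(f"configuration is missing required channels: {missing}")
        if self.leak_gmax < 0:
            raise ValueError("leak conductance must be nonnegative")
        if not (0.0 <= self.temperature <= 50.0):
            raise ValueError("temperature outside 0-50 degC")


def _tau(tau0, amp=0.0, vmid=0.0, sigma=10.0) -> TauSpec:
    return TauSpec(tau0=tau0, amp=amp, vmid=vmid, sigma=sigma)


def default_config() -> ModelConfig:
    """The calibrated mouse detrusor smooth muscle cell.

    Maximal conductances and reversal potentials of the nine active channels
    are the published whole-cell values (S/cm2 and mV).  Gating parameters
    are calibrated so the cell reproduces the published readouts: an
    emergent -50 mV rest with 150 nM shell Ca2+, the 0.1 nA / 10 ms spike
    (peak +9.6 mV, 35 ms width at -25 mV, 5 mV / 15 ms AHP, threshold near
    -30 mV), two spikes under 0.1 nA / 100 ms, and the conductance-block
    responses.  The division of labour: CaT is a steep low-threshold
    trigger with fast inactivation and slow subthreshold recovery; CaL
    carries the spike dome with slow inactivation; Kv1 is a high-threshold
    rectifier capping the peak; the BK Markov scheme accumulates open
    probability through the dome, terminates it, and its closing residual
    is the after-hyperpolarization; KCNQ operates on the shallow foot of
    its activation curve as a quasi-ohmic resting K+ conductance; IK and SK
    are Hill-gated by the large shell Ca2+ transient; KATP is an ohmic
    ATP-gated background; Ih is a hyperpolarization-activated restorer that
    terminates the AHP.
    """
    channels = [
        HHChannelSpec(
            name="CaT",
            gmax=2e-4,
            erev=51.0,
            activation=GatingVariableSpec(31.796527, -1.150307, _tau(0.506036)),
            inactivation=GatingVariableSpec(
                38.0, 8.0, _tau(5.136704, 12.171660, 45.0, 10.0)
            ),
            is_calcium_carrier=True,
        ),
        HHChannelSpec(
            name="CaL",
            gmax=4e-4,
            erev=51.0,
            activation=GatingVariableSpec(19.44, -2.0, _tau(2.080114)),
            inactivation=GatingVariableSpec(23.392257, 5.897555, _tau(70.0)),
            is_calcium_carrier=True,
        ),
        HHChannelSpec(
            name="Kv1",
            gmax=6e-3,
            erev=-75.0,
            activation=GatingVariableSpec(
                -31.771468, -4.361049, _tau(5.099912, 4.801678, 30.0, 15.648)
            ),
            inactivation=GatingVariableSpec(20.0, 6.0, _tau(3000.0)),
        ),
        HHChannelSpec(
            name="KCNQ",
            gmax=9e-3,
            erev=-75.0,
            activation=GatingVariableSpec(-250.379864, -57.002795, _tau(6.814508)),
        ),
        HHChannelSpec(
            name="IK",
            gmax=7e-3,
            erev=-75.0,
            activation=GatingVariableSpec(200.0, -20.0, _tau(30.0)),
            ca_dependence=CaHillSpec(kd=0.427514, n=2.0),
        ),
        HHChannelSpec(
            name="SK",
            gmax=1e-2,
            erev=-15.0,
            activation=GatingVariableSpec(200.0, -20.0, _tau(14.059271)),
            ca_dependence=CaHillSpec(kd=0.239021, n=2.0),
            ligand_dependence=LigandSpec("apamin_block", half=1e-7, n=1.0),
        ),
        HHChannelSpec(
            name="KATP",
            gmax=1e-3,
            erev=-21.0,
            activation=GatingVariableSpec(0.0, -1.0, _tau(1.0), exponent=0),
            ligand_dependence=LigandSpec("atp_inhibition", half=0.019950, n=1.0),
        ),
        HHChannelSpec(
            name="Ih",
            gmax=1e-4,
            erev=-40.0,
            activation=GatingVariableSpec(57.164262, 4.160753, _tau(30.856667)),
        ),
    ]
    bk = BKMarkovSpec(
        gmax=0.024,
        erev=-75.0,
        kon=134.528110,
        kd_closed=0.021357,
        kd_open=0.00928,
        a0=0.004022,
        l0=0.004202,
        forward_frac=0.7,
        za=0.323292,
        zb=0.228021,
        vslope=25.0,
        kc4=0.023203,
    )
    calcium = CalciumShellSpec(depth=0.1, baseline=150e-6, tau_removal=2.386060)
    provenance = {f"{ch.name}.gmax": "source-cited" for ch in channels}
    provenance.update({f"{ch.name}.erev": "source-cited" for ch in channels})
    provenance.update(
        {
            "BK.gmax": "source-cited",
            "BK.erev": "source-cited",
            "BK.rates": "calibrated",
            "geometry": "source-cited",
            "calcium.baseline": "source-cited",
            "calcium.depth": "source-cited",
            "calcium.tau_removal": "calibrated",
            "leak": "calibrated",
            "Kv1.inactivation.tau": "calibrated",
            "KATP.atp_half": "calibrated",
        }
    )
    provenance.update({f"{ch.name}.kinetics": "calibrated" for ch in channels})
    return ModelConfig(
        channels=channels,
        bk=bk,
        leak_gmax=7.25e-6,
        leak_erev=17.135717,
        calcium=calcium,
        atp=1.0,
        provenance=provenance,
    )


#: effective reversal potential (mV) of the purinergic synaptic conductance;
#: calibrated jointly with the channel kinetics (see docs/methods.md)
E_SYN = -16.136291

#: synaptic drive matched to the Young et al. 2008 spike (Table 3 row)
YOUNG_SYNAPSE = {"gmax_uS": 0.003600, "tau_rise": 2.026029, "tau_decay": 6.309117}


def young_config() -> ModelConfig:
    """Configuration matched to the Young et al. 2008 spike recording.

    The same cell with three conductances shifted within the +/-20%
    physiological envelope (CaL +20%, Kv1 -15%, BK -20%), a lower ambient
    ATP (larger KATP availability) so the emergent rest sits at -43 mV, and
    the synaptic drive of :data:`YOUNG_SYNAPSE`; the resulting spike
    reproduces the recorded amplitude and APD50 (see docs/methods.md).
    """
    cfg = default_config()
    cfg = cfg.with_scaled_gmax({"CaL": 1.2000, "Kv1": 0.8541, "BK": 0.8000})
    cfg.channels = [
        dataclasses.replace(
            ch,
            ligand_dependence=dataclasses.replace(
                ch.ligand_dependence, half=0.061984
            ),
        )
        if ch.name == "KATP"
        else ch
        for ch in cfg.channels
    ]
    cfg.v_init = -43.0
    cfg.provenance["KATP.atp_half"] = "calibrated (Young et al. rest)"
    return cfg


# ----------------------------------------------------------------------------
# serialization


def _spec_to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        out = {}
        for f in dataclasses.fields(obj):
            if not f.init:
                continue
            out[f.name] = _spec_to_dict(getattr(obj, f.name))
        return out
    if isinstance(obj, (list, tuple)):
        return [_spec_to_dict(x) for x in obj]
    return obj


def _dict_to_spec(cls, data):
    if data is None:
        return None
    if not dataclasses.is_dataclass(cls):
        return data
    names = {f.name: f for f in dataclasses.fields(cls) if f.init}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    sub = {
        "tau": TauSpec,
        "activation": GatingVariableSpec,
        "inactivation": GatingVariableSpec,
        "ca_dependence": CaHillSpec,
        "ligand_dependence": LigandSpec,
        "geometry": CellGeometry,
        "bk": BKMarkovSpec,
        "calcium": CalciumShellSpec,
        "solver": SolverSpec,
    }
    for key, value in data.items():
        if key == "channels":
            kwargs[key] = [_dict_to_spec(HHChannelSpec, ch) for ch in value]
        elif key in sub:
            kwargs[key] = _dict_to_spec(sub[key], value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def save_config(cfg: ModelConfig, path) -> None:
    """Write a configuration to YAML (lossless round trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_spec_to_dict(cfg), fh, sort_keys=False)


def load_config(path) -> ModelConfig:
    """Load and validate a YAML configuration; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    cfg = _dict_to_spec(ModelConfig, data)
    cfg.validate()
    return cfg
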