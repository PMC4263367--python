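"""Model parameter sets: variants, chambers, per-parameter scaling, serialization.

A :class:`ModelParameters` instance resolves, for every named parameter,
``value = baseline × variant factor × chamber factor × user scale``.  The
resolved values are packed into a flat float64 vector consumed by the
compiled integration kernels.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as c

VARIANTS = ("control", "cAF")
CHAMBERS = ("LA", "RA")
RYR_FORMULATIONS = ("original", "sato_bers")

#: every key accepted in a ``scales`` mapping
SCALABLE = tuple(c.TABLE1_BASELINE) + ("k_34",)


def _check_scales(scales):
    for name, s in scales.items():
        if name not in SCALABLE:
            hint = ""
            low = {k.lower(): k for k in SCALABLE}
            if name.lower() in low:
                hint = f"; did you mean {low[name.lower()]!r}?"
            raise KeyError(f"unknown parameter name {name!r}{hint}")
        if not np.isfinite(s) or s <= 0:
            raise ValueError(f"scale for {name!r} must be positive, got {s}")


@dataclass(frozen=True)
class ModelParameters:
    """Fully resolved parameter set of the GPVm atrial model.

    Attributes
    ----------
    variant, chamber : str
        ``control``/``cAF`` × ``LA``/``RA``.
    ryr_formulation : str
        ``original`` (luminal-Ca-regulated Markov RyR, single SR pool) or
        ``sato_bers`` (CSQN-regulated RyR, split JSR/NSR).
    scales : dict
        user scale factors, composed multiplicatively on top of the variant.
    fast_buffers : bool
        treat calsequestrin and the membrane Ca2+ buffers with the rapid-buffering
        approximation (default; required for stability at the 20 µs step);
        the explicit-buffer form is retained for verification.
    """

    variant: str = "control"
    chamber: str = "LA"
    ryr_formulation: str = "original"
    scales: dict = field(default_factory=dict)
    fast_buffers: bool = True
    stim_amplitude: float | None = None  # A/F; None -> resolved by the engine
    stim_duration: float = 2.0           # ms
    block_sarcolemmal_ca: bool = False   # closed-cell Ca2+ mode (diagnostics)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.chamber not in CHAMBERS:
            raise ValueError(f"chamber must be one of {CHAMBERS}")
        if self.ryr_formulation not in RYR_FORMULATIONS:
            raise ValueError(f"ryr_formulation must be one of {RYR_FORMULATIONS}")
        _check_scales(self.scales)
        object.__setattr__(self, "scales", dict(self.scales))

    # -- resolution --------------------------------------------------------
    def value(self, name: str) -> float:
        """Resolved value of a named Table-1/Table-2 parameter."""
        vec = self.vector()
        if name in c.TABLE1_BASELINE:
            return float(vec[c.TABLE1_BASELINE[name][0]])
        for tab in (c.TABLE2_ORIGINAL, c.TABLE2_SATOBERS):
            if name in tab:
                return float(vec[tab[name][0]])
        raise KeyError(name)

    def vector(self) -> np.ndarray:
        """Pack resolved values into the kernel parameter vector."""
        p = np.zeros(c.N_PARAM)
        sb = self.ryr_formulation == "sato_bers"
        for name, (slot, base) in c.TABLE1_BASELINE.items():
            v = base
            if self.variant == "cAF":
                v *= c.CAF_FACTORS.get(name, 1.0)
            else:
                v *= c.CONTROL_FACTORS.get(name, 1.0)
            if self.chamber == "RA":
                v *= c.RA_FACTORS.get(name, 1.0)
            v *= self.scales.get(name, 1.0)
            p[slot] = v
        for name, (slot, base) in {**c.TABLE2_ORIGINAL, **c.TABLE2_SATOBERS}.items():
            p[slot] = base
        p[c.P_K34] *= self.scales.get("k_34", 1.0)
        if sb:
            p[c.P_RYRFORM] = 1.0
            p[c.P_KS] = c.SATOBERS_KS * self.scales.get("k_s", 1.0)
            p[c.P_VMAXSRCAP] = c.SATOBERS_VMAXSRCAP * self.scales.get("V_maxSRCaP", 1.0)
            p[c.P_BMAX_CSQN] = c.SATOBERS_BMAX_CSQN
            p[c.P_KD_CSQN] = c.SATOBERS_KC
        p[c.P_FASTBUF] = 1.0 if self.fast_buffers else 0.0
        p[c.P_BLOCK_SLCA] = 1.0 if self.block_sarcolemmal_ca else 0.0
        return p

    def rescaled(self, scales: dict) -> "ModelParameters":
        """Compose additional multiplicative scale factors."""
        _check_scales(scales)
        new = dict(self.scales)
        for k, v in scales.items():
            new[k] = new.get(k, 1.0) * v
        return replace(self, scales=new)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "variant": self.variant,
            "chamber": self.chamber,
            "ryr_formulation": self.ryr_formulation,
            "fast_buffers": self.fast_buffers,
            "stim_amplitude": self.stim_amplitude,
            "stim_duration": self.stim_duration,
            "scales": {k: float(v) for k, v in sorted(self.scales.items())},
        }
        d["resolved"] = {name: self.value(name) for name in c.TABLE1_BASELINE}
        tab2 = c.TABLE2_SATOBERS if self.ryr_formulation == "sato_bers" \
            else c.TABLE2_ORIGINAL
        d["resolved"].update({name: self.value(name) for name in tab2})
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(
            variant=d.get("variant", "control"),
            chamber=d.get("chamber", "LA"),
            ryr_formulation=d.get("ryr_formulation", "original"),
            scales=d.get("scales", {}),
            fast_buffers=d.get("fast_buffers", True),
            stim_amplitude=d.get("stim_amplitude"),
            stim_duration=d.get("stim_duration", 2.0),
        )

    def digest(self) -> str:
        """Stable short hash of the resolved parameter vector (for manifests)."""
        h = hashlib.sha256(self.vector().tobytes())
        h.update(f"{self.stim_amplitude}/{self.stim_duration}".encode())
        return h.hexdigest()[:12]


def make_parameters(variant: str = "control", chamber: str = "LA",
                    scales: dict | None = None, *,
                    ryr_formulation: str = "original",
                    **kwargs) -> ModelParameters:
    """Build a resolved parameter set for a model variant.

    ``scales`` compose multiplicatively on top of the variant values, e.g.
    ``make_parameters("cAF", "LA", {"ki_Ca": 0.5})`` yields the cAF model with
    the RyR inactivation rate constant halved (the alternans-prone variant).
    """
    return ModelParameters(variant=variant, chamber=chamber,
                           scales=scales or {}, ryr_formulation=ryr_formulation,
                           **kwargs)
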