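"""Candidate network architectures for the emotional-face processing network.

Two message-passing architectures over a left-lateralized, four-region
ventral-stream network — early visual cortex (EV), fusiform cortex (Fusi),
amygdala (Amy) and inferior frontal gyrus (IFG):

* Model 1: a serial bottom-up hierarchy EV -> Fusi -> Amy -> IFG with
  reciprocal backward connections.
* Model 2: Model 1 plus a direct reciprocal EV <-> IFG pathway (a
  shortcut for fast magnocellular projections to frontal cortex).

A Gaussian "thalamic" input bump drives the spiny stellate cells of EV.
Face emotion (happy vs. the angry reference) modulates every
region-to-region connection through per-edge log-modulators B.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

__all__ = [
    "REGIONS",
    "MNI_COORDS",
    "NetworkSpec",
    "build_model",
    "input_bump",
    "condition_edge_gains",
    "CONDITIONS",
]

REGIONS = ("EV", "Fusi", "Amy", "IFG")

#: MNI coordinate labels of the four sources (mm).
MNI_COORDS = {
    "EV": (-8, -94, -8),
    "Fusi": (-52, -52, -22),
    "Amy": (-25, -3, -16),
    "IFG": (-48, -28, -2),
}

#: Condition labels; "angry" is the reference, "happy" the modulated condition.
CONDITIONS = ("angry", "happy")


@dataclass(frozen=True)
class NetworkSpec:
    """Region list plus directed forward/backward adjacency.

    ``backward_edges`` is always the exact reversal of ``forward_edges``;
    the thalamic input enters ``input_region`` only.
    """

    model_id: int
    regions: tuple[str, ...] = REGIONS
    forward_edges: tuple[tuple[str, str], ...] = ()
    backward_edges: tuple[tuple[str, str], ...] = ()
    input_region: str = "EV"
    mni: dict = field(default_factory=lambda: dict(MNI_COORDS))

    def __post_init__(self):
        declared = set(self.regions)
        for a, b in self.forward_edges + self.backward_edges:
            if a not in declared or b not in declared:
                raise ValueError(f"edge ({a}, {b}) references undeclared region")
        if tuple((b, a) for a, b in self.forward_edges) != self.backward_edges:
            raise ValueError("backward_edges must be the reversal of forward_edges")
        if self.input_region not in declared:
            raise ValueError(f"unknown input region {self.input_region!r}")

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        """All directed region-to-region edges (forward then backward)."""
        return self.forward_edges + self.backward_edges

    def region_index(self, name: str) -> int:
        return self.regions.index(name)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_id": self.model_id,
                "regions": [
                    {"name": r, "mni": list(self.mni[r])} for r in self.regions
                ],
                "forward_edges": [list(e) for e in self.forward_edges],
                "backward_edges": [list(e) for e in self.backward_edges],
                "input_region": self.input_region,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        return cls(
            model_id=d["model_id"],
            regions=tuple(r["name"] for r in d["regions"]),
            forward_edges=tuple(tuple(e) for e in d["forward_edges"]),
            backward_edges=tuple(tuple(e) for e in d["backward_edges"]),
            input_region=d["input_region"],
            mni={r["name"]: tuple(r["mni"]) for r in d["regions"]},
        )


_MODEL1_FORWARD = (("EV", "Fusi"), ("Fusi", "Amy"), ("Amy", "IFG"))
_MODEL2_FORWARD = _MODEL1_FORWARD + (("EV", "IFG"),)


def build_model(model_id: int) -> NetworkSpec:
    """Return the architecture for ``model_id`` 1 (serial) or 2 (+EV<->IFG)."""
    if model_id == 1:
        fwd = _MODEL1_FORWARD
    elif model_id == 2:
        fwd = _MODEL2_FORWARD
    else:
        raise ValueError(f"model_id must be 1 or 2, got {model_id!r}")
    bwd = tuple((b, a) for a, b in fwd)
    return NetworkSpec(model_id=model_id, forward_edges=fwd, backward_edges=bwd)


def input_bump(t, onset: float, width: float, amp: float):
    """Gaussian stimulus-bound input drive amp * exp(-(t-onset)^2 / (2 width^2)).

    ``t`` may be a scalar or array (ms). Symmetric about ``onset``.
    """
    if width <= 0:
        raise ValueError(f"input width must be > 0, got {width}")
    try:
        import numpy as np

        z = (np.asarray(t, dtype=float) - onset) / width
        out = amp * np.exp(-0.5 * z * z)
        return out if out.ndim else float(out)
    except TypeError:
        z = (t - onset) / width
        return amp * math.exp(-0.5 * z * z)


def condition_edge_gains(params, spec: NetworkSpec, condition: str) -> dict:
    """Effective extrinsic (AMPA, NMDA) gain per directed edge under a condition.

    Angry is the reference (modulator exp(0)); happy scales both receptor
    components of every region-to-region connection by exp(B_edge).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    out = {}
    for edge in spec.edges:
        a_ampa, a_nmda = params.extrinsic_gain(edge, spec)
        bname = f"B:{edge[0]}->{edge[1]}"
        if bname not in params.values:
            raise ValueError(f"missing emotion modulator for edge {edge}")
        mod = math.exp(params.values[bname]) if condition == "happy" else 1.0
        out[edge] = (a_ampa * mod, a_nmda * mod)
    return out
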