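"""Acquisition protocol description for diffusion-prepared pCASL.

The protocol fixes the labeling/readout constants of the two-PLD DP-pCASL
scheme: a 1.5 s pCASL labeling block, a short post-labeling delay (0.9 s)
acquired with b = 0 and 14 s/mm^2 for transit-time estimation (FEAST), and a
long delay (1.8 s) acquired with b = 0 and 50 s/mm^2 for water-exchange
estimation.  All times are in seconds here; quantities exposed to users of
the parameter maps use ms / min^-1 conventions (see :mod:`dpasl.kinetics`).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

__all__ = ["AcquisitionProtocol", "load_protocol", "save_protocol"]


@dataclasses.dataclass(frozen=True)
class AcquisitionProtocol:
    """Labeling and readout constants of a DP-pCASL acquisition.

    Parameters
    ----------
    label_dur : float
        pCASL labeling duration tau in seconds.
    plds : tuple of float
        Post-labeling delays in seconds, ascending.
    b_values_per_pld : tuple of tuple of float
        Diffusion weightings (s/mm^2) acquired at each PLD; within a pair the
        values must be nonnegative and strictly increasing.
    label_eff : float
        Labeling efficiency alpha in (0, 1]; the default 0.72 is the product
        of a pCASL inversion efficiency of 0.85 and a background-suppression
        efficiency of 0.85.
    t1_blood : float
        Longitudinal relaxation time of arterial blood (s).
    t1_tissue : float
        Longitudinal relaxation time of tissue water (s); may be overridden
        per voxel downstream.
    lambda_part : float
        Blood-brain partition coefficient (ml/g).
    att_floor : float
        Minimum resolvable arterial transit time (s); also the assumed
        earliest arrival of the uncrushed FEAST reference signal.
    """

    label_dur: float = 1.5
    plds: tuple[float, ...] = (0.9, 1.8)
    b_values_per_pld: tuple[tuple[float, ...], ...] = ((0.0, 14.0), (0.0, 50.0))
    label_eff: float = 0.72
    t1_blood: float = 1.65
    t1_tissue: float = 1.2
    lambda_part: float = 0.9
    att_floor: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "plds", tuple(float(p) for p in self.plds))
        object.__setattr__(
            self,
            "b_values_per_pld",
            tuple(tuple(float(b) for b in pair) for pair in self.b_values_per_pld),
        )
        if self.label_dur <= 0:
            raise ValueError("labeling duration must be positive")
        if not self.plds or any(p <= 0 for p in self.plds):
            raise ValueError("all PLDs must be positive")
        if not 0 < self.label_eff <= 1:
            raise ValueError("labeling efficiency must lie in (0, 1]")
        if self.t1_blood <= 0 or self.t1_tissue <= 0:
            raise ValueError("T1 values must be positive")
        if self.lambda_part <= 0:
            raise ValueError("partition coefficient must be positive")
        if self.att_floor <= 0:
            raise ValueError("att_floor must be positive")
        if len(self.b_values_per_pld) != len(self.plds):
            raise ValueError("need one b-value pair per PLD")
        for pair in self.b_values_per_pld:
            if any(b < 0 for b in pair):
                raise ValueError("b-values must be nonnegative")
            if list(pair) != sorted(set(pair)):
                raise ValueError("b-values must be strictly increasing within a pair")

    @property
    def pld_max(self) -> float:
        return max(self.plds)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "label_dur": self.label_dur,
            "plds": list(self.plds),
            "b_values": [list(p) for p in self.b_values_per_pld],
            "label_eff": self.label_eff,
            "t1_blood": self.t1_blood,
            "t1_tissue": self.t1_tissue,
            "lambda": self.lambda_part,
            "att_floor": self.att_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        return cls(
            label_dur=d["label_dur"],
            plds=tuple(d["plds"]),
            b_values_per_pld=tuple(tuple(p) for p in d["b_values"]),
            label_eff=d["label_eff"],
            t1_blood=d["t1_blood"],
            t1_tissue=d["t1_tissue"],
            lambda_part=d["lambda"],
            att_floor=d["att_floor"],
        )


def save_protocol(proto: AcquisitionProtocol, path: str | Path) -> None:
    """Write a protocol descriptor as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    d = proto.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_protocol(path: str | Path) -> AcquisitionProtocol:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return AcquisitionProtocol.from_dict(d)
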