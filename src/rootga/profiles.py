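"""Spatial concentration profiles and biosensor emission datasets.

CSV schemas (full double precision, schema-versioned header comment):
  profile:  x_um, ga12_nM, ga15_nM, ga24_nM, ga9_nM, ga4_nM
            (+ optional *_vac_nM / *_apo_nM columns)
  emission: x_um, ratio
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .params import METABOLITES, Metabolite

__all__ = ["SteadyProfile", "EmissionProfile"]

_MET_NAMES = ["ga12", "ga15", "ga24", "ga9", "ga4"]
SCHEMA_VERSION = "rootga-profile-v1"


@dataclass
class SteadyProfile:
    """Steady concentration fields on a strictly increasing grid (μm).

    ``cyt``/``vac``/``apo`` are (n, 5) arrays of nM in pathway order
    GA12, GA15, GA24, GA9, GA4.
    """

    x: np.ndarray
    cyt: np.ndarray
    vac: Optional[np.ndarray] = None
    apo: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.cyt = np.asarray(self.cyt, dtype=float)
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.cyt.shape != (self.x.size, len(METABOLITES)):
            raise ValueError("cyt must be (n, 5)")

    def field_for(self, met: Metabolite, compartment: str = "cyt") -> np.ndarray:
        arr = getattr(self, compartment)
        return arr[:, int(met)]

    def ga4(self) -> np.ndarray:
        return self.cyt[:, int(Metabolite.GA4)]

    def interp(self, xq, met: Metabolite = Metabolite.GA4, compartment: str = "cyt"):
        return np.interp(xq, self.x, self.field_for(met, compartment))

    def to_frame(self) -> pd.DataFrame:
        data = {"x_um": self.x}
        for k, name in enumerate(_MET_NAMES):
            data[f"{name}_nM"] = self.cyt[:, k]
        if self.vac is not None:
            for k, name in enumerate(_MET_NAMES):
                data[f"{name}_vac_nM"] = self.vac[:, k]
        if self.apo is not None:
            for k, name in enumerate(_MET_NAMES):
                data[f"{name}_apo_nM"] = self.apo[:, k]
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# schema={SCHEMA_VERSION}\n")
            self.to_frame().to_csv(fh, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SteadyProfile":
        df = pd.read_csv(path, comment="#")
        cyt = np.column_stack([df[f"{n}_nM"].to_numpy() for n in _MET_NAMES])
        vac = apo = None
        if f"{_MET_NAMES[0]}_vac_nM" in df:
            vac = np.column_stack([df[f"{n}_vac_nM"].to_numpy() for n in _MET_NAMES])
        if f"{_MET_NAMES[0]}_apo_nM" in df:
            apo = np.column_stack([df[f"{n}_apo_nM"].to_numpy() for n in _MET_NAMES])
        return cls(x=df["x_um"].to_numpy(), cyt=cyt, vac=vac, apo=apo)


@dataclass
class EmissionProfile:
    """Per-nucleus biosensor readings: position (μm from tip) and ratio."""

    x: np.ndarray
    ratio: np.ndarray
    sensor: str = "nlsGPS1"
    label: str = "wildtype"
    seed: Optional[int] = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.x.shape != self.ratio.shape:
            raise ValueError("x and ratio must have the same shape")

    def __len__(self) -> int:
        return self.x.size

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# schema={SCHEMA_VERSION}\n")
            pd.DataFrame({"x_um": self.x, "ratio": self.ratio}).to_csv(
                fh, index=False, float_format="%.17g"
            )

    def sidecar(self) -> dict:
        return {
            "sensor": self.sensor,
            "label": self.label,
            "seed": self.seed,
            "truth": self.truth,
        }

    def to_csv_with_sidecar(self, path: str | Path) -> None:
        path = Path(path)
        self.to_csv(path)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(self.sidecar(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_csv(cls, path: str | Path, **meta) -> "EmissionProfile":
        df = pd.read_csv(path, comment="#")
        if df.empty:
            raise ValueError(f"empty emission profile: {path}")
        side = Path(path).with_suffix(".json")
        if side.exists():
            info = json.loads(side.read_text())
            meta.setdefault("sensor", info.get("sensor", "nlsGPS1"))
            meta.setdefault("label", info.get("label", ""))
            meta.setdefault("seed", info.get("seed"))
            meta.setdefault("truth", info.get("truth", {}))
        return cls(x=df["x_um"].to_numpy(), ratio=df["ratio"].to_numpy(), **meta)
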