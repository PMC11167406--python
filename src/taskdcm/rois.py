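"""Network node template for the spatial-conflict (SRC) task network.

Nine regions form the task-evoked network: bilateral dorsolateral prefrontal
cortex (DLPFC), premotor cortex (PMC), intraparietal sulcus (IPS) and
anterior insula (AI), plus the anterior midcingulate cortex (AMCC).  Group
nodes are 10-mm spheres around fixed MNI peak coordinates; subject-level
nodes are 4-mm spheres around individual local maxima found inside them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NODE_NAMES = (
    "LDLPFC", "RDLPFC", "LPMC", "RPMC", "LIPS", "RIPS", "LAI", "RAI", "AMCC",
)

#: default MNI peak coordinates of the group-level network nodes (mm)
DEFAULT_CENTERS = {
    "LDLPFC": (-40.0, 22.0, 28.0),
    "RDLPFC": (36.0, 30.0, 28.0),
    "LPMC": (-24.0, -8.0, 48.0),
    "RPMC": (24.0, -8.0, 48.0),
    "LIPS": (-34.0, -46.0, 38.0),
    "RIPS": (36.0, -44.0, 40.0),
    "LAI": (-30.0, 18.0, -10.0),
    "RAI": (30.0, 20.0, -4.0),
    "AMCC": (-2.0, 8.0, 46.0),
}

DRIVING_NODES = ("LIPS", "RIPS")


@dataclass(frozen=True)
class ROITemplate:
    """Named node centers with group/individual sphere radii."""

    names: tuple[str, ...] = NODE_NAMES
    centers_mm: tuple[tuple[float, float, float], ...] = tuple(
        DEFAULT_CENTERS[n] for n in NODE_NAMES
    )
    group_radius_mm: float = 10.0
    individual_radius_mm: float = 4.0

    def __post_init__(self):
        if len(self.names) != len(self.centers_mm):
            raise ValueError("names and centers_mm must align")
        if self.group_radius_mm <= 0 or self.individual_radius_mm <= 0:
            raise ValueError("radii must be positive")

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    def center(self, name: str) -> np.ndarray:
        return np.asarray(self.centers_mm[self.names.index(name)], float)

    def centers(self) -> np.ndarray:
        return np.asarray(self.centers_mm, float)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "node": self.names,
                "x": [c[0] for c in self.centers_mm],
                "y": [c[1] for c in self.centers_mm],
                "z": [c[2] for c in self.centers_mm],
                "radius_mm": self.group_radius_mm,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, individual_radius_mm: float = 4.0) -> "ROITemplate":
        df = pd.read_csv(path, sep="\t")
        return cls(
            names=tuple(df["node"]),
            centers_mm=tuple(
                (float(r.x), float(r.y), float(r.z)) for r in df.itertuples()
            ),
            group_radius_mm=float(df["radius_mm"].iloc[0]),
            individual_radius_mm=individual_radius_mm,
        )


def default_template() -> ROITemplate:
    return ROITemplate()
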