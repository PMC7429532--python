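"""Delimited-text round trips for source spaces and leadfields.

* Source-space file: CSV with mandatory header ``x,y,z,region`` — one row
  per point, coordinates in mm, region from the 10-label lobar atlas.
* Leadfield file: CSV whose first column is the channel name and whose
  remaining columns are the dense gain matrix, one column per source
  moment component in point-major, component (x,y,z) minor order —
  the same layout as ``Leadfield.matrix``.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

from .atlas import AtlasLabels
from .headmodel import Leadfield, SourceSpace, SourceSpaceKind

__all__ = [
    "save_source_space",
    "load_source_space",
    "save_leadfield",
    "load_leadfield",
]


def save_source_space(
    space: SourceSpace, labels: AtlasLabels, path: str | pathlib.Path
) -> None:
    if len(labels) != space.n_points:
        raise ValueError("labels must cover every source point")
    frame = pd.DataFrame(
        {
            "x": space.points[:, 0],
            "y": space.points[:, 1],
            "z": space.points[:, 2],
            "region": list(labels.labels),
        }
    )
    frame.to_csv(path, index=False)


def load_source_space(
    path: str | pathlib.Path,
    kind: SourceSpaceKind | str = SourceSpaceKind.volume,
    spacing: float = 5.0,
    head_radius: float = 90.0,
) -> tuple[SourceSpace, AtlasLabels]:
    frame = pd.read_csv(path)
    required = {"x", "y", "z", "region"}
    if not required <= set(frame.columns):
        raise ValueError(f"source-space file must have columns {sorted(required)}")
    space = SourceSpace(
        points=frame[["x", "y", "z"]].to_numpy(dtype=float),
        kind=SourceSpaceKind(kind),
        spacing=spacing,
        head_radius=head_radius,
    )
    return space, AtlasLabels(labels=tuple(frame["region"]))


def save_leadfield(leadfield: Leadfield, path: str | pathlib.Path) -> None:
    frame = pd.DataFrame(leadfield.matrix)
    frame.insert(0, "channel", list(leadfield.channel_names))
    frame.to_csv(path, index=False)


def load_leadfield(path: str | pathlib.Path, space: SourceSpace) -> Leadfield:
    frame = pd.read_csv(path)
    names = tuple(frame["channel"])
    matrix = frame.drop(columns="channel").to_numpy(dtype=float)
    return Leadfield(matrix=matrix, channel_names=names, source_space=space)
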