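"""Electrode placement: mapping 10/20 channel names onto a 2D scalp grid.

The default layout places the 32-channel montage on a 9x9 grid (row 0 at the
frontal edge). Layouts are data, not code: they ship as JSON files under
``eegdcn/layouts`` and users can point at their own file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = ["ElectrodeMap", "build_electrode_map", "load_layout", "DEFAULT_LAYOUT", "DEAP_CHANNELS"]

DEFAULT_LAYOUT = "deap9x9"

#: channel order of the 32-electrode montage handled by the default layout
DEAP_CHANNELS = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7", "CP5", "CP1", "P3",
    "P7", "PO3", "O1", "Oz", "Pz", "Fp2", "AF4", "Fz", "F4", "F8", "FC6",
    "FC2", "Cz", "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

_LAYOUT_FILES = {"deap9x9": "deap_9x9.json"}


@dataclass(frozen=True)
class ElectrodeMap:
    """Injective channel-name -> (row, col) placement within an h x w grid."""

    placements: dict[str, tuple[int, int]]
    h: int = 9
    w: int = 9
    name: str = DEFAULT_LAYOUT
    version: int = 1

    def __post_init__(self):
        seen: dict[tuple[int, int], str] = {}
        for ch, (r, c) in self.placements.items():
            if not (0 <= r < self.h and 0 <= c < self.w):
                raise ValueError(f"channel {ch} placed at {(r, c)} outside {self.h}x{self.w} grid")
            if (r, c) in seen:
                raise ValueError(f"channels {seen[(r, c)]} and {ch} collide at cell {(r, c)}")
            seen[(r, c)] = ch

    def __len__(self) -> int:
        return len(self.placements)

    def __contains__(self, channel: str) -> bool:
        return channel in self.placements

    def __getitem__(self, channel: str) -> tuple[int, int]:
        return self.placements[channel]

    def occupancy(self):
        """Boolean h x w occupancy mask."""
        import numpy as np

        mask = np.zeros((self.h, self.w), dtype=bool)
        for r, c in self.placements.values():
            mask[r, c] = True
        return mask


def load_layout(source: str | Path = DEFAULT_LAYOUT) -> dict:
    """Load a layout definition from a packaged name or a JSON file path."""
    if isinstance(source, str) and source in _LAYOUT_FILES:
        text = resources.files("eegdcn.layouts").joinpath(_LAYOUT_FILES[source]).read_text()
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"unknown layout {source!r}; packaged layouts: {sorted(_LAYOUT_FILES)}")
        text = path.read_text()
    return json.loads(text)


def build_electrode_map(channel_names, layout: str | Path = DEFAULT_LAYOUT) -> ElectrodeMap:
    """Build the placement map for ``channel_names`` from a layout definition.

    Every name must be present in the layout (recognized 10/20 labels);
    duplicates and unknown names are rejected.
    """
    spec = load_layout(layout)
    known = {ch: tuple(rc) for ch, rc in spec["placements"].items()}
    placements: dict[str, tuple[int, int]] = {}
    for name in channel_names:
        if name in placements:
            raise ValueError(f"duplicate channel name: {name!r}")
        if name not in known:
            raise ValueError(f"unknown channel name: {name!r} (not in layout {spec['name']!r})")
        placements[name] = known[name]
    return ElectrodeMap(
        placements=placements,
        h=int(spec["rows"]),
        w=int(spec["cols"]),
        name=spec["name"],
        version=int(spec.get("version", 1)),
    )
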