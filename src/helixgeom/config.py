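"""Run configuration: helix definitions and pipeline tunables.

The groove helices of an MH class 1 molecule (G-ALPHA1, G-ALPHA2, both on
the heavy chain) or class 2 molecule (G-ALPHA on the alpha chain, G-BETA
on the beta chain) are defined by chain id and residue range.  The
shipped presets are editable approximations of the IMGT G-domain helix
delimitations — exact ranges vary per allele and should be adjusted per
structure; they are data, not code.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class HelixDef:
    label: str
    chain: str
    start: int
    end: int

    @property
    def residue_range(self) -> tuple[int, int]:
        return (self.start, self.end)


#: approximate G-domain helix ranges (IMGT-style numbering of the mature
#: chains); editable per allele
PRESETS: dict[str, list[HelixDef]] = {
    "MH1": [
        HelixDef("G-ALPHA1", "A", 50, 84),
        HelixDef("G-ALPHA2", "A", 138, 180),
    ],
    "MH2": [
        HelixDef("G-ALPHA", "A", 46, 77),
        HelixDef("G-BETA", "B", 52, 92),
    ],
}


@dataclass
class RunConfig:
    helix_class: str = "custom"  # MH1 | MH2 | custom
    helices: list[HelixDef] = field(default_factory=list)
    reference: str | None = None  # path of the superposition reference
    window: int = 4
    tail_exclusion: int = 3
    n_rulings: int | str = "auto"
    weighting: str = "none"  # none | inverse_b
    percentile_interpolation: str = "linear"
    torsal_epsilon: float = 1e-6
    trim_tail_windows: int = 0  # drop profile windows overlapping this many C-terminal residues
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.tail_exclusion < 0:
            raise ValueError("tail_exclusion must be >= 0")
        if self.weighting not in ("none", "inverse_b"):
            raise ValueError("weighting must be 'none' or 'inverse_b'")
        if self.helix_class in PRESETS and not self.helices:
            self.helices = list(PRESETS[self.helix_class])
        if len(self.helices) != 2:
            raise ValueError("exactly two helix definitions are required")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
        helices = [HelixDef(**h) for h in data.pop("helices", [])]
        return cls(helices=helices, **data)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["helices"] = [h.__dict__ for h in self.helices]
        return d

    def digest(self) -> str:
        """Stable hash of all config values, stamped into output headers."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
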