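"""Flat key=value run configuration with a content hash.

Stored flat (TOML-compatible scalars, one ``key = value`` per line) so runs
diff cleanly; the hash is stamped into every TSV output, and a rerun with an
unchanged hash reproduces outputs byte-identically.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Union

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    n_days: int = 3
    lights_on_offset_s: int = 0
    photoperiod_h: float = 12.0
    body_length_mm: float = 2.5
    max_gap_s: int = 5
    bin_width_min: int = 30
    mai_completeness: float = 0.95
    preset: str = "male"

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            else:
                lines.append(f"{f.name} = {v!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        for ln, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {ln}: expected key = value")
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key not in types:
                raise ValueError(f"line {ln}: unknown key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, str):
                kwargs[key] = raw.strip('"')
            elif isinstance(current, int):
                kwargs[key] = int(raw)
            else:
                kwargs[key] = float(raw)
        return cls(**kwargs)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RunConfig":
        return cls.from_text(Path(path).read_text(encoding="utf-8"))

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_text(), encoding="utf-8", newline="\n")

    def hash(self) -> str:
        canonical = repr(sorted(asdict(self).items()))
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
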