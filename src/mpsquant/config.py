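"""Run configuration: delineation/scoring parameters + seed, TOML round-trip."""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .delineation import DelineationParams
from .quantify import DEFAULT_SCORE_BINS


@dataclass
class RunConfig:
    delineation: DelineationParams = field(default_factory=DelineationParams)
    score_bins: tuple[float, float, float, float] = DEFAULT_SCORE_BINS
    seed: int = 0
    out_dir: str = "."
    verbose: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["score_bins"] = list(self.score_bins)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def to_toml(self, path) -> None:
        d = self.to_dict()
        lines = []
        for key in ("seed", "out_dir", "verbose", "score_bins"):
            lines.append(f"{key} = {_toml_value(d[key])}")
        lines.append("")
        lines.append("[delineation]")
        for key, val in d["delineation"].items():
            lines.append(f"{key} = {_toml_value(val)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        doc = tomllib.loads(Path(path).read_text())
        deli = doc.pop("delineation", {})
        valid = {f.name for f in fields(DelineationParams)}
        unknown = set(deli) - valid
        if unknown:
            raise ValueError(f"unknown delineation parameters: {sorted(unknown)}")
        cfg = cls(delineation=DelineationParams(**deli))
        if "score_bins" in doc:
            cfg.score_bins = tuple(doc.pop("score_bins"))
        for key in ("seed", "out_dir", "verbose"):
            if key in doc:
                setattr(cfg, key, doc.pop(key))
        if doc:
            raise ValueError(f"unknown config keys: {sorted(doc)}")
        return cfg


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    return repr(v)
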