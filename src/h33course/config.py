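"""Run configuration: thresholds with their study-anchored defaults.

Configs round-trip through a plain ``key=value`` text representation; the
manifest always records every effective value so default-vs-override is
auditable.  The hash of that canonical text stamps every output file.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .genome_io import ValidationError


@dataclass
class RunConfig:
    input_dir: str = ""
    output_dir: str = ""
    promoter_bp: int = 3000          # promoter: bases strictly upstream of the TSS
    fold: float = 2.0                # fold-over-input for a presence call
    min_density: float = 0.5         # normalized tags/kb floor; 0 disables
    pseudocount: float = 1.0
    fpkm_threshold: float = 1.0      # expression "on" gate
    lfc_min: float = 1.0             # |log2FC| gate for DE and cluster direction
    top_n: int = 250                 # size of the H3.3-loss ranking
    significance_score: float = 2.0  # -log10(adjusted p) cut for marker enrichment
    flank: int = 2000                # profile half-window (bp)
    n_bins: int = 40
    scale: float = 1e7               # library-normalization tag total
    sustained_expression: bool = False
    seed: int = 0

    def items(self):
        """Analysis parameters only: run locations are ephemeral context and
        do not enter the canonical text, the hash or the manifest."""
        d = asdict(self)
        d.pop("input_dir")
        d.pop("output_dir")
        return sorted(d.items())

    def to_text(self) -> str:
        return "".join(f"{k}={v}\n" for k, v in self.items())

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text(), encoding="utf-8")

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValidationError(f"config line {lineno}: expected key=value")
            k, v = (s.strip() for s in line.split("=", 1))
            if k not in known:
                raise ValidationError(f"config line {lineno}: unknown key {k!r}")
            kwargs[k] = v
        cfg = cls()
        for k, v in kwargs.items():
            cur = getattr(cfg, k)
            if isinstance(cur, bool):
                setattr(cfg, k, v.lower() in ("1", "true", "yes"))
            elif isinstance(cur, int):
                setattr(cfg, k, int(v))
            elif isinstance(cur, float):
                setattr(cfg, k, float(v))
            else:
                setattr(cfg, k, v)
        return cfg

    @classmethod
    def read(cls, path: str | Path) -> "RunConfig":
        return cls.from_text(Path(path).read_text(encoding="utf-8"))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_text().encode("utf-8")).hexdigest()[:16]
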