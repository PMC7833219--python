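"""Pipeline configuration.

Every analysis choice the method leaves open (resampling step, segment
count, Hurst estimator, separation-layer width, tie rules) is named here so
a published run is self-describing: serialising the config alongside the
results records exactly which defaults were in effect.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """End-to-end pipeline options.

    Attributes
    ----------
    dt : float
        Resampling step in seconds (default 30: the effective resolution
        a coarse-grained wearable recording is analysed at).
    k : int or None
        Segment count; if None it is derived from ``samples_per_segment``.
    samples_per_segment : int
        Target samples per segment when ``k`` is None (default 225; with
        dt = 30 s this makes a ~15 h recording come out at 8 segments).
    hurst_method : {"rs", "dfa"}
        Per-segment Hurst estimator.
    min_segment_samples : int
        Segments with fewer samples are flagged, not estimated.
    epsilon : float or None
        Separation-layer width; None → 1% of the diagonal of Ω.
    mesh : int
        Mesh points per axis of the domain triangulation (≥ 10).
    classifier : {"hull", "logistic"}
        Triangle-classification rule (geometric nearest-hull, or the
        logistic-regression cross-check).
    entropy_variant : {"global", "local"}
        Default behavioural-entropy variant reported in summaries.
    seed : int
        Seed for any randomized component (the pipeline itself is
        deterministic; the seed feeds synthetic-data generation only).
    """

    dt: float = 30.0
    k: int | None = None
    samples_per_segment: int = 225
    hurst_method: Literal["rs", "dfa"] = "rs"
    min_segment_samples: int = 32
    epsilon: float | None = None
    mesh: int = 60
    classifier: Literal["hull", "logistic"] = "hull"
    entropy_variant: Literal["global", "local"] = "global"
    seed: int = 0
    column_map: dict[str, str] | None = None
    time_column: str = "t"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.k is not None and self.k <= 1:
            raise ValueError("segment count k must exceed 1")
        if self.samples_per_segment <= 0:
            raise ValueError("samples_per_segment must be positive")
        if self.mesh < 10:
            raise ValueError("mesh must be >= 10")
        if self.min_segment_samples < 2:
            raise ValueError("min_segment_samples must be >= 2")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))
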