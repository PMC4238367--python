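"""Pipeline configuration.

All defaults follow the published parameterization of the method where one
exists (bin width 0.5 ms, heat time t = 25, propagation-velocity bound
400 mm/s, jitter half-width 5 ms, 100 dithering repetitions, p = 0.05);
the remaining knobs (Hough detector, kappa scaling, SC threshold) are
method-internal and documented in docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InputError


@dataclass
class HoughConfig:
    """Segment-detector settings applied per image patch.

    ``canny_sigma`` controls the edge map; ``threshold``, ``line_length``
    and ``line_gap`` are the probabilistic Hough transform parameters
    (votes, minimum accepted segment length and maximum bridged gap, all
    in pixels).
    """

    canny_sigma: float = 1.0
    threshold: int = 5
    line_length: int = 8
    line_gap: int = 3


@dataclass
class PipelineConfig:
    # electrode grid geometry
    n_rows: int = 64
    n_cols: int = 64
    pitch_um: float = 42.0
    sampling_rate_hz: float = 7000.0

    # image registration: pixel offset of patch (0, 0) and image scale
    offset_row_px: float = 0.0
    offset_col_px: float = 0.0
    px_per_um: float | None = None  # None -> inferred from image extent

    # structural prior
    hough: HoughConfig = field(default_factory=HoughConfig)
    kappa_scale: float = 10.0  # px; kappa = kappa_scale / (d + kappa_eps)
    kappa_eps: float = 1.0
    kappa_max: float = 1.0e4
    heat_time: float = 25.0
    sc_threshold: float = 0.05  # on the max-normalized heat map
    normalize_mode: str = "offdiag"  # or "full"

    # functional graph
    bin_ms: float = 0.5
    window_ms: float = 50.0
    v_max_mm_s: float = 400.0
    jitter_ms: float = 5.0
    null_reps: int = 100
    null_pairs: int = 500
    p_value: float = 0.05

    # classification
    svm_c: float = 1.0
    cv_folds: int = 10

    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_toml(self) -> str:
        lines = []
        d = self.to_dict()
        hough = d.pop("hough")
        for k, v in d.items():
            if v is None:  # TOML has no null; omitted keys keep their default
                continue
            lines.append(f"{k} = {json.dumps(v)}")
        lines.append("")
        lines.append("[hough]")
        for k, v in hough.items():
            lines.append(f"{k} = {json.dumps(v)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        hough = d.pop("hough", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(hough=HoughConfig(**hough), **d)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))
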