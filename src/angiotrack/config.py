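"""Run configuration shared by every pipeline stage.

All tunable constants of the tracker live here so that a run can be
reproduced from its serialized config alone.  Defaults target bright
vessels (diameters roughly 3--15 px) on a dark background in images
normalized to [0, 1]; use ``invert=True`` for dark-vessel angiograms.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path


def _default_scales() -> list[float]:
    # 14 log-spaced Hessian scales covering tube diameters ~3-15 px after
    # focal blur; the top scale reaches the ridge-response optimum of wide
    # blurred tubes.  Large scales merge closely parallel vessels into one
    # ridge, which the tracker's per-element axis recentering (on the raw
    # intensity profile) compensates.
    n = 14
    lo, hi = 0.9, 8.0
    r = (hi / lo) ** (1.0 / (n - 1))
    return [lo * r**i for i in range(n)]


def _default_diam_scales() -> list[float]:
    # 25 geometric scales for the diameter sweep; sigma_hat ~ w/2 for wide
    # tubes, saturating near sqrt(2)*psf for thin ones, so this spans
    # diameters ~2-20 px under typical focal blur.
    n = 25
    lo, hi = 0.8, 12.0
    r = (hi / lo) ** (1.0 / (n - 1))
    return [lo * r**i for i in range(n)]


@dataclass
class RunConfig:
    """Every tunable of the pipeline, serializable to/from JSON or TOML."""

    # --- vesselness ---
    scales: list[float] = field(default_factory=_default_scales)
    #: eigenvalue gate r_lambda = -rlambda_coeff / sigma_f  (negative threshold
    #: whose magnitude shrinks with scale, admitting faint large vessels)
    rlambda_coeff: float = 2.0 / math.pi
    binarize_threshold: float = 0.05
    degenerate_ratio: float = 0.98

    # --- tracking (PTO) ---
    stop_threshold: float = 0.05
    sigma_floor: float = 1e-3
    d_min: float = 3.0
    d_max: float = 15.0
    step_min: float = 1.0
    step_max: float = 7.0

    # --- diameter estimation ---
    diam_scales: list[float] = field(default_factory=_default_diam_scales)
    profile_half_length: int = 40
    #: measure diameters on the raw intensity ("image") or on the
    #: vesselness map ("feature_map")
    diameter_source: str = "image"
    #: std (px) of the acquisition point-spread function; an imaging-chain
    #: property used to build the sigma_hat -> diameter calibration and the
    #: along-track curvature correction
    psf_sigma: float = 3.2
    #: optional linear calibration diameter = k_cal * sigma_hat; None selects
    #: the monotone table calibration built at psf_sigma (more accurate)
    k_cal: float | None = None

    # --- structure pattern detector (SPD) ---
    alpha: float = 1.25
    #: the template radius is alpha*d/2 + spd_radius_margin*psf_sigma: the
    #: circle must clear the PSF-smeared junction core before the limbs of a
    #: bifurcation separate into distinct profile peaks
    spd_radius_margin: float = 3.0
    #: peaks whose co-vessel Gabor response falls below this are treated as
    #: noise/pseudo-edges and do not count toward the peak number
    gamma_gate: float = 0.15
    n_circle_samples: int = 150
    circle_deriv_sigma: float = 2.0
    fuzzy_sigma_z: float = 0.5
    fuzzy_sigma_gamma: float = 0.5
    fuzzy_sigma_m: float = 1.0
    gabor_on_feature_map: bool = False
    gabor_jitter: float = math.pi / 8

    #: raw log-response drop (relative to the local level) at the geometric
    #: end of a tube of diameter d: intercept - slope * d.  Calibrated once
    #: on the straight-bar phantom family (blur-independent over 3.2-4.0 px);
    #: used to prune blur fringe past terminations and refine endpoints.
    end_drop_intercept: float = 0.657
    end_drop_slope: float = 0.0258

    # --- evaluation ---
    tau_match: float = 2.0

    # --- misc ---
    invert: bool = False
    seed: int = 0
    verbose: bool = False

    def validate(self) -> None:
        if len(self.scales) < 2:
            raise ValueError("need at least 2 Hessian scales")
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")
        if sorted(self.scales) != list(self.scales):
            raise ValueError("scales must be strictly increasing")
        for name in ("fuzzy_sigma_z", "fuzzy_sigma_gamma", "fuzzy_sigma_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (1.0 <= self.alpha <= 1.5):
            raise ValueError("alpha must lie in [1, 1.5]")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".toml":
            import tomllib

            return cls.from_dict(tomllib.loads(text))
        return cls.from_dict(json.loads(text))

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
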