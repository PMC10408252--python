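"""Configuration for the synthetic population generator.

All randomness is driven by the mandatory ``seed`` field; there is no hidden
global random state anywhere in the package.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import yaml

#: canonical organ order used throughout the package
ORGANS = ("ovary", "hepatopancreas", "stomach", "body_rest")

#: limb slots, 1 = right claw, clockwise to 10 = left claw
LIMB_IDS = tuple(range(1, 11))

# Default per-limb power-law coefficients (a in g * mm^-b).  Claws (limbs 1
# and 10) are heavier than walking legs; left-side legs mirror the right.
_DEFAULT_LIMB_ALLOMETRY: Tuple[Tuple[float, float], ...] = (
    (2.5e-5, 2.9),  # 1  right claw
    (1.6e-5, 2.9),  # 2  walking leg
    (1.8e-5, 2.9),  # 3
    (1.7e-5, 2.9),  # 4
    (1.4e-5, 2.9),  # 5
    (1.4e-5, 2.9),  # 6
    (1.7e-5, 2.9),  # 7
    (1.8e-5, 2.9),  # 8
    (1.6e-5, 2.9),  # 9
    (2.5e-5, 2.9),  # 10 left claw
)

_DEFAULT_ORGAN_ALLOMETRY: Tuple[Tuple[float, float], ...] = (
    (2.0e-5, 2.8),  # ovary
    (3.0e-5, 2.8),  # hepatopancreas
    (1.0e-5, 2.7),  # stomach (with contents)
    (2.0e-4, 2.9),  # rest of body
)

# Organ-mass change per unit predictor: (per missing limb, per bud, per gram
# of regenerated limb mass), all in grams.
_DEFAULT_TRADEOFF_COEFFS: Tuple[Tuple[float, float, float], ...] = (
    (0.0, -0.004, -0.05311),    # ovary
    (-0.00488, -0.004, -0.07376),  # hepatopancreas
    (0.0, 0.002, -0.005),       # stomach
    (0.0, 0.03662, -1.24),      # body_rest
)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic crab population.

    Probabilities are per limb; ``p_bud_given_loss`` and
    ``p_partial_given_loss`` are conditional on a limb having been lost, and
    the remainder of lost limbs are completely absent (no bud, no regrowth).
    """

    n_crabs: int = 736
    seed: int = 0
    cw_range: Tuple[float, float] = (12.0, 32.0)
    julian_range: Tuple[int, int] = (61, 316)
    sites: Sequence[str] = ("ME", "NH", "CT", "NJ", "NC")
    limb_allometry: Tuple[Tuple[float, float], ...] = _DEFAULT_LIMB_ALLOMETRY
    limb_noise_sd: float = 0.1
    molt_stage_range: Tuple[float, float] = (0.9, 1.1)
    p_loss: float = 0.24
    p_loss_sd: float = 0.08
    p_bud_given_loss: float = 0.29
    p_partial_given_loss: float = 0.59
    regen_fraction_range: Tuple[float, float] = (0.10, 0.70)
    bud_mass_fraction_range: Tuple[float, float] = (0.005, 0.05)
    organ_allometry: Tuple[Tuple[float, float], ...] = _DEFAULT_ORGAN_ALLOMETRY
    season_amplitude: float = 0.2
    season_peak_day: float = 196.0
    tradeoff_coeffs: Tuple[Tuple[float, float, float], ...] = _DEFAULT_TRADEOFF_COEFFS
    organ_noise_sd: float = 0.1
    # 'lognormal': multiplicative exp(N(0, sd)); 'gaussian': additive
    # N(0, sd * organ mass at the midpoint carapace width), homoskedastic
    # within each organ.
    organ_noise_model: str = "lognormal"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_crabs < 1:
            raise ValueError("n_crabs must be >= 1")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer (and is mandatory)")
        lo, hi = self.cw_range
        if not (0 < lo < hi):
            raise ValueError("cw_range must satisfy 0 < min < max")
        jlo, jhi = self.julian_range
        if not (1 <= jlo <= jhi <= 366):
            raise ValueError("julian_range must lie within [1, 366]")
        for name in ("p_loss", "p_bud_given_loss", "p_partial_given_loss"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.p_loss_sd < 0:
            raise ValueError("p_loss_sd must be non-negative")
        if self.p_loss_sd > 0:
            if not (0 < self.p_loss < 1):
                raise ValueError("p_loss_sd > 0 requires 0 < p_loss < 1")
            if self.p_loss_sd**2 >= self.p_loss * (1 - self.p_loss):
                raise ValueError("p_loss_sd too large for a Beta distribution")
        if self.p_bud_given_loss + self.p_partial_given_loss > 1.0 + 1e-12:
            raise ValueError(
                "p_bud_given_loss + p_partial_given_loss must not exceed 1"
            )
        fmin, fmax = self.regen_fraction_range
        if not (0.0 <= fmin < fmax < 1.0):
            raise ValueError("regen_fraction_range must satisfy 0 <= min < max < 1")
        if len(self.limb_allometry) != 10:
            raise ValueError("limb_allometry must supply coefficients for 10 limbs")
        for a, b in self.limb_allometry:
            if a <= 0:
                raise ValueError("limb allometry coefficient a must be positive")
        if len(self.organ_allometry) != len(ORGANS):
            raise ValueError(f"organ_allometry must supply {len(ORGANS)} pairs")
        if len(self.tradeoff_coeffs) != len(ORGANS):
            raise ValueError(f"tradeoff_coeffs must supply {len(ORGANS)} triples")
        if self.limb_noise_sd < 0 or self.organ_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.organ_noise_model not in ("lognormal", "gaussian"):
            raise ValueError("organ_noise_model must be 'lognormal' or 'gaussian'")
        mlo, mhi = self.molt_stage_range
        if not (0 < mlo <= mhi):
            raise ValueError("molt_stage_range must satisfy 0 < lo <= hi")
        if not (0.0 <= self.season_amplitude < 1.0):
            raise ValueError("season_amplitude must be in [0, 1)")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sites"] = list(self.sites)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if isinstance(v, list):
                v = _tuplify(v)
            kwargs[f.name] = v
        return cls(**kwargs)

    def digest(self) -> str:
        """Stable hash of the full configuration (used in run manifests)."""
        payload = json.dumps(_listify(self.to_dict()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _listify(obj):
    if isinstance(obj, tuple):
        return [_listify(x) for x in obj]
    if isinstance(obj, list):
        return [_listify(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    return obj


def _tuplify(obj):
    if isinstance(obj, list):
        return tuple(_tuplify(x) for x in obj)
    return obj
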