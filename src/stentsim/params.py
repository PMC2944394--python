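"""Run parameters and artery geometry.

The baseline values are the published parameter set for a human coronary
artery: lattice spacing ``dl`` = 0.01825 mm (one smooth muscle cell per
site, maximum density dl**-3 ~ 1.64e5 cells/mm^3), injury threshold 35 kPa
compressive minimum principal stress, migration speed 0.24 mm/day,
SMC mitosis rate 0.24/day, endothelial attempt rate 2/cell/day, matrix
degradation rate 0.05/day (damaged tissue resorbed in 20 days) and matrix
production rate 0.20/day.

Two thresholds the model needs but for which no measured value exists are
exposed with documented defaults: ``g_crit`` (growth stimulus consumed per
division, default 1) and ``c_smc_crit`` (local occupancy above which an SMC
stays synthetic, default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


class ConfigurationError(ValueError):
    """A parameter or geometry value is invalid or inconsistent."""


@dataclass(frozen=True)
class Geometry:
    """Idealised hollow-cylinder artery, axis along z.

    Lengths in mm. ``stent_z`` is the axial extent [z_lo, z_hi] of the
    stent: the endothelium is denuded there and the synthetic stress
    pattern is confined to it.
    """

    length: float = 14.0
    r_inner: float = 1.25
    r_outer: float = 1.875
    stent_z: tuple[float, float] = (3.0, 11.0)

    def validate(self) -> None:
        if self.length <= 0:
            raise ConfigurationError(f"artery length must be > 0, got {self.length}")
        if self.r_inner < 0 or self.r_outer < self.r_inner:
            raise ConfigurationError(
                f"need 0 <= r_inner <= r_outer, got {self.r_inner}, {self.r_outer}"
            )
        z_lo, z_hi = self.stent_z
        if not (0.0 <= z_lo <= z_hi <= self.length):
            raise ConfigurationError(
                f"stent extent {self.stent_z} must lie within [0, {self.length}]"
            )


@dataclass
class Params:
    """All model parameters (units in field comments)."""

    dl: float = 0.01825            # lattice spacing, mm
    sigma_crit: float = 35.0       # injury threshold, kPa compressive magnitude
    c_smc_init: float = 3.16e4     # initial SMC concentration, cells/mm^3
    c_max: float | None = None     # max density, cells/mm^3; None -> dl**-3
    v_smc: float = 0.24            # sSMC migration speed, mm/day
    p_smc: float = 0.24            # sSMC mitosis rate, 1/day
    p_ec: float = 2.0              # EC proliferation attempts, 1/cell/day
    mdf_init: float = 1.0          # matrix-degrading factor at injured sites
    c_deg: float = 0.05            # ECM/MDF degradation rate, 1/day
    c_ecm: float = 0.20            # ECM production rate, 1/day
    g_init: float = 3.0            # growth stimulus at injured sites
    g_crit: float = 1.0            # stimulus consumed per division (default, see docs)
    c_smc_crit: float = 0.5        # occupancy threshold for contractile phenotype
    stencil: int = 26              # neighbourhood connectivity: 6, 18 or 26
    ec_placement: str = "rejection"  # EC daughter siting: "rejection" or "valid"
    ec_scheduling: str = "same_day"  # EC daughter turns: "same_day", "rounds", "next_day"
    days_max: int = 320            # simulated duration, days
    rng_seed: int = 0
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        if self.dl <= 0:
            raise ConfigurationError(f"dl must be > 0, got {self.dl}")
        if self.c_max is None:
            self.c_max = self.dl ** -3
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def seed_fraction(self) -> float:
        """Per-site probability of carrying a cSMC at t = 0."""
        return self.c_smc_init / self.c_max

    @property
    def migration_attempts_per_day(self) -> float:
        """Mean migration attempts/day: steps of length dl at v_smc mm/day."""
        return self.v_smc / self.dl

    def validate(self) -> None:
        if self.dl <= 0:
            raise ConfigurationError(f"dl must be > 0, got {self.dl}")
        for name in ("sigma_crit", "c_smc_init", "v_smc", "p_smc", "p_ec",
                     "mdf_init", "c_deg", "c_ecm", "g_init", "g_crit",
                     "c_smc_crit"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")
        if self.c_max <= 0:
            raise ConfigurationError(f"c_max must be > 0, got {self.c_max}")
        if abs(self.c_max - self.dl ** -3) > 0.01 * self.dl ** -3:
            raise ConfigurationError(
                f"c_max={self.c_max:g} inconsistent with dl^-3={self.dl**-3:g} "
                "(one cell per lattice site)"
            )
        if self.c_smc_init > self.c_max * (1 + 1e-12):
            raise ConfigurationError(
                f"c_smc_init={self.c_smc_init:g} exceeds c_max={self.c_max:g}"
            )
        if self.stencil not in (6, 18, 26):
            raise ConfigurationError(f"stencil must be 6, 18 or 26, got {self.stencil}")
        if self.ec_placement not in ("valid", "rejection"):
            raise ConfigurationError(
                f"ec_placement must be 'valid' or 'rejection', got {self.ec_placement!r}"
            )
        if self.ec_scheduling not in ("rounds", "same_day", "next_day"):
            raise ConfigurationError(
                f"ec_scheduling must be 'rounds', 'same_day' or 'next_day', "
                f"got {self.ec_scheduling!r}"
            )
        if self.g_crit <= 0:
            raise ConfigurationError(
                f"g_crit must be > 0 (each division consumes it), got {self.g_crit}"
            )
        if self.days_max < 0:
            raise ConfigurationError("days_max must be >= 0")
        self.geometry.validate()

    # -- serialisation ------------------------------------------------------

    def replace(self, **kw) -> "Params":
        geo = kw.pop("geometry", self.geometry)
        d = asdict(self)
        d.pop("geometry")
        if "dl" in kw and "c_max" not in kw:
            d["c_max"] = None  # re-derive from the new spacing
        d.update(kw)
        return Params(geometry=geo if isinstance(geo, Geometry) else Geometry(**geo), **d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"]["stent_z"] = list(self.geometry.stent_z)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Params":
        d = dict(d)
        geo = d.pop("geometry", {})
        if geo and not isinstance(geo, Geometry):
            geo = dict(geo)
            if "stent_z" in geo:
                geo["stent_z"] = tuple(float(v) for v in geo["stent_z"])
            geo = Geometry(**{k: float(v) if k != "stent_z" else v
                              for k, v in geo.items()})
        # YAML 1.1 reads exponent literals like 3.16e4 as strings; coerce
        for k, v in list(d.items()):
            if isinstance(v, str) and k not in ("ec_placement", "ec_scheduling"):
                d[k] = float(v)
        for k in ("stencil", "days_max", "rng_seed"):
            if k in d and d[k] is not None:
                d[k] = int(d[k])
        return cls(geometry=geo or Geometry(), **d)

    @classmethod
    def from_yaml(cls, path) -> "Params":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc.get("params", doc))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"params": self.to_dict()}, fh, sort_keys=False)
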