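"""Model parameters for the pore/slab translocation system.

All quantities are dimensionless: energies in units of k_B*T, lengths in
units of the maximum bond extension, time in Monte Carlo steps (MCS).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["SimParams", "load_config", "save_config"]


@dataclass(frozen=True)
class SimParams:
    """All model constants and run-control knobs for one parameter point.

    The defaults reproduce the reference coarse-grained model: a chain of
    ``n_bonds + 1`` monomers with FENE bonds (spring constant ``k_spring``,
    preferred length ``l0``, hard limits ``lmin``/``lmax``), Morse excluded
    volume (``alpha_morse``, ``rmin_morse``, ``eps_morse``), an angle
    potential kappa*(1 + cos theta), purely repulsive membranes separated
    by ``r_sep``, and a pore of length ``l_pore`` and diameter ``d_pore``
    carrying a uniform electric field ``e_field`` along -z.

    Parameters
    ----------
    n_bonds
        Chain length N; the chain has N + 1 monomers.
    kappa
        Bending stiffness in k_B*T.
    e_field
        Electric field strength inside the pore; the driving force per
        monomer is q*E.
    r_sep
        Separation R between the two membranes bounding the trans slab.
    """

    n_bonds: int = 150
    kappa: float = 40.0
    e_field: float = 5.0
    r_sep: float = 5.0

    # pore / membrane geometry
    l_pore: float = 2.0
    d_pore: float = 1.2

    # interactions
    q_charge: float = 1.0
    k_spring: float = 20.0
    l0: float = 0.7
    lmin: float = 0.4
    lmax: float = 1.0
    r0: float = 0.3
    alpha_morse: float = 24.0
    rmin_morse: float = 0.8
    eps_morse: float = 1.0
    r_cut: float = 1.5
    # Wall Morse potential is evaluated at (surface gap + wall_offset):
    # the immobile wall monomers have diameter sigma = rmin_morse, so their
    # centers sit sigma/2 inside the material surface.
    wall_offset: float = 0.4

    # Monte Carlo kernel
    step_max: float = 0.25
    kbt: float = 1.0

    # run control
    n_samples: int = 5000
    base_seed: int = 0
    relax_mcs: int = 1000
    max_mcs: int = 100_000_000
    relax_window: int = 500
    relax_tol: float = 0.01
    relax_max_mcs: int = 50_000
    # Axial parking position of the held head monomer during relaxation:
    # just inside the pore mouth (half a bond deep), so the chain is engaged
    # with the pore when released at t = 0.
    z_park: float = -0.35

    def __post_init__(self) -> None:
        if self.n_bonds < 1:
            raise ValueError(f"n_bonds must be >= 1, got {self.n_bonds}")
        if not (self.lmin < self.l0 < self.lmax):
            raise ValueError(
                f"bond limits must satisfy lmin < l0 < lmax, got "
                f"{self.lmin} / {self.l0} / {self.lmax}"
            )
        if abs((self.lmax - self.l0) - self.r0) > 1e-12 or abs(
            (self.l0 - self.lmin) - self.r0
        ) > 1e-12:
            raise ValueError(
                "FENE range must satisfy r0 = lmax - l0 = l0 - lmin "
                f"(got r0={self.r0}, lmax-l0={self.lmax - self.l0}, "
                f"l0-lmin={self.l0 - self.lmin})"
            )
        for name in ("r_sep", "l_pore", "d_pore", "k_spring", "eps_morse",
                     "alpha_morse", "rmin_morse", "step_max", "kbt", "r_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.kappa < 0 or self.e_field < 0:
            raise ValueError("kappa and e_field must be >= 0")
        if self.wall_offset < 0:
            raise ValueError("wall_offset must be >= 0")
        if self.n_samples < 1 or self.max_mcs < 1:
            raise ValueError("n_samples and max_mcs must be >= 1")
        if not (-self.l_pore < self.z_park < self.l0):
            raise ValueError(
                "z_park must lie within the pore mouth region "
                f"(-l_pore, l0), got {self.z_park}")

    @property
    def n_monomers(self) -> int:
        return self.n_bonds + 1

    @property
    def pore_radius(self) -> float:
        return self.d_pore / 2.0

    def replace(self, **changes) -> "SimParams":
        """Return a copy with the given fields changed."""
        return dataclasses.replace(self, **changes)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            want = int if f.type in ("int",) else float
            if isinstance(v, bool) or not isinstance(v, (int, float)):
                raise TypeError(f"config key {f.name!r}: expected a number, got {v!r}")
            if want is int and float(v) != int(v):
                raise TypeError(f"config key {f.name!r}: expected an integer, got {v!r}")
            kwargs[f.name] = want(v)
        return cls(**kwargs)


def load_config(path: str | Path) -> SimParams:
    """Load a SimParams from a YAML or JSON file.

    Missing keys take the model defaults, so an empty file reproduces the
    reference parameter set. Unknown keys and constraint violations raise.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(data).__name__}")
    return SimParams.from_dict(data)


def save_config(params: SimParams, path: str | Path) -> None:
    """Write a SimParams to YAML or JSON (by extension)."""
    path = Path(path)
    d = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
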