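"""Radionuclides, emission spectra and decay chains.

Radiations are carried as discrete lines: each line is a radiation type
(photon or electron), a mean energy in MeV and a yield per nuclear
transformation.  Beta emitters are represented by their mean beta energies
with the corresponding branch yields, not by full beta spectra; this is the
line representation used throughout the dosimetry engine.

Packaged defaults cover the cerium ingestion problem: 141Ce (a single-member
chain, its only radioactive progeny being ignored as stable) and the
144Ce -> {144mPr, 144Pr} -> 144Nd chain, 144Nd being treated as stable
because of its extremely long half-life.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "EmissionLine",
    "Radionuclide",
    "DecayChain",
    "ValidationError",
    "decay_constant",
    "builtin_nuclides",
    "load_nuclide_file",
    "write_nuclide_file",
    "load_chain_file",
]

#: 1 MeV in joule; applied only in the S-value engine.
MEV_TO_J = 1.602176634e-13

LN2 = math.log(2.0)


class ValidationError(ValueError):
    """Raised when domain invariants are violated."""


def decay_constant(half_life: float) -> float:
    """Physical decay constant ``lambda_p = ln 2 / T_half`` in d^-1.

    Parameters
    ----------
    half_life
        Physical half-life in days; must be positive.
    """
    if not half_life > 0:
        raise ValidationError(f"half-life must be positive, got {half_life!r}")
    return LN2 / half_life


@dataclass(frozen=True)
class EmissionLine:
    """One discrete emission: type, mean energy (MeV), yield per transformation."""

    radiation_type: str  # "photon" | "electron"
    mean_energy: float  # MeV
    yield_per_nt: float  # emissions per nuclear transformation

    def __post_init__(self) -> None:
        if self.radiation_type not in ("photon", "electron"):
            raise ValidationError(
                f"unknown radiation type {self.radiation_type!r}"
            )
        if not self.mean_energy > 0:
            raise ValidationError(
                f"mean energy must be positive, got {self.mean_energy!r}"
            )
        if self.yield_per_nt < 0:
            raise ValidationError(
                f"yield must be non-negative, got {self.yield_per_nt!r}"
            )


@dataclass(frozen=True)
class Radionuclide:
    """A radionuclide with its emission lines and direct progeny.

    ``progeny`` lists ``(nuclide name, branching fraction)`` pairs; fractions
    must sum to at most 1 (the remainder decays to a stable species).
    """

    name: str
    half_life: float  # days
    emissions: tuple[EmissionLine, ...] = ()
    progeny: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.half_life > 0:
            raise ValidationError(
                f"{self.name}: half-life must be positive, got {self.half_life!r}"
            )
        total = 0.0
        for child, frac in self.progeny:
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(
                    f"{self.name}: branching fraction to {child} out of [0,1]: {frac}"
                )
            total += frac
        if total > 1.0 + 1e-12:
            raise ValidationError(
                f"{self.name}: branching fractions sum to {total} > 1"
            )
        object.__setattr__(self, "emissions", tuple(self.emissions))
        object.__setattr__(
            self, "progeny", tuple((str(c), float(f)) for c, f in self.progeny)
        )

    @property
    def decay_constant(self) -> float:
        """lambda_p in d^-1."""
        return decay_constant(self.half_life)

    def total_emitted_energy(self) -> float:
        """Sum of E_i * Y_i over all lines, in MeV per transformation."""
        return sum(l.mean_energy * l.yield_per_nt for l in self.emissions)

    def lines(self, radiation_type: str) -> tuple[EmissionLine, ...]:
        return tuple(
            l for l in self.emissions if l.radiation_type == radiation_type
        )


@dataclass(frozen=True)
class DecayChain:
    """Topologically ordered radioactive decay chain.

    Every progeny reference of a member must resolve to a *later* member of
    the chain or be absent (meaning the branch ends in a stable species).
    """

    members: tuple[Radionuclide, ...]
    terminal_stable: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        names = [m.name for m in self.members]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate chain members: {names}")
        for idx, member in enumerate(self.members):
            for child, _ in member.progeny:
                if child in names and names.index(child) <= idx:
                    raise ValidationError(
                        f"progeny {child} of {member.name} does not occur "
                        "later in the chain (cycle or bad ordering)"
                    )

    @property
    def parent(self) -> Radionuclide:
        return self.members[0]

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def member(self, name: str) -> Radionuclide:
        for m in self.members:
            if m.name == name:
                return m
        raise KeyError(name)

    @classmethod
    def single(cls, nuclide: Radionuclide) -> "DecayChain":
        """A one-member chain (all branches end in stable species)."""
        radioactive = [c for c, f in nuclide.progeny if f > 0]
        if radioactive:
            raise ValidationError(
                f"{nuclide.name} has radioactive progeny {radioactive}; "
                "build the full chain instead"
            )
        return cls(members=(nuclide,))


# ---------------------------------------------------------------------------
# File round-trip (structured-text nuclide files)
# ---------------------------------------------------------------------------

def _line_to_dict(line: EmissionLine) -> dict:
    return {
        "type": line.radiation_type,
        "energy_MeV": line.mean_energy,
        "yield": line.yield_per_nt,
    }


def _nuclide_to_dict(nuc: Radionuclide) -> dict:
    d: dict = {
        "name": nuc.name,
        "half_life_days": nuc.half_life,
        "emissions": [_line_to_dict(l) for l in nuc.emissions],
    }
    if nuc.progeny:
        d["progeny"] = [
            {"name": c, "branching": f} for c, f in nuc.progeny
        ]
    return d


def _nuclide_from_dict(d: dict, origin: str = "<dict>") -> Radionuclide:
    try:
        name = d["name"]
        half_life = float(d["half_life_days"])
        emissions = tuple(
            EmissionLine(
                radiation_type=e["type"],
                mean_energy=float(e["energy_MeV"]),
                yield_per_nt=float(e["yield"]),
            )
            for e in d.get("emissions", [])
        )
        progeny = tuple(
            (p["name"], float(p["branching"])) for p in d.get("progeny", [])
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{origin}: malformed nuclide record: {exc}") from exc
    return Radionuclide(
        name=name, half_life=half_life, emissions=emissions, progeny=progeny
    )


def load_nuclide_file(path: str | Path) -> Radionuclide:
    """Load a single-nuclide YAML file; invariants are enforced on load."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValidationError(f"{path}: parse error: {exc}") from exc
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping at top level")
    return _nuclide_from_dict(data, origin=str(path))


def write_nuclide_file(nuclide: Radionuclide, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(_nuclide_to_dict(nuclide), fh, sort_keys=False)


def load_chain_file(path: str | Path) -> DecayChain:
    """Load a decay-chain YAML file (list of nuclide records, parent first)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValidationError(f"{path}: parse error: {exc}") from exc
    members = data.get("members") if isinstance(data, dict) else data
    if not isinstance(members, list):
        raise ValidationError(f"{path}: expected a list of nuclide records")
    return DecayChain(
        members=tuple(
            _nuclide_from_dict(m, origin=str(path)) for m in members
        ),
        terminal_stable=True,
    )


# ---------------------------------------------------------------------------
# Packaged defaults
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("doseuq").joinpath("data", name)))


def builtin_nuclides() -> dict[str, DecayChain]:
    """Packaged decay chains keyed by parent name.

    Returns the 141Ce single-member chain and the 144Ce chain
    (144Ce -> {144mPr, 144Pr} -> stable 144Nd).  Line energies and yields
    for the cerium isotopes are the published evaluation values; the
    praseodymium emission data and the Ce-144 branching fractions are
    configuration defaults read from the packaged chain file (flagged there
    as provenance placeholders, overridable by the user).
    """
    ce141 = load_nuclide_file(_data_path("ce141.yaml"))
    ce144_chain = load_chain_file(_data_path("ce144_chain.yaml"))
    return {
        "Ce-141": DecayChain.single(ce141),
        "Ce-144": ce144_chain,
    }
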