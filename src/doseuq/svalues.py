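"""Per-phantom S values and their inter-phantom variability.

The S value ``S_w(r_T <- r_S)`` is the mean weighted equivalent dose to
target tissue ``r_T`` per nuclear transformation in source region ``r_S``:

    S_w = sum_R w_R sum_i E_i Y_i Phi(r_T <- r_S, E_i) ,

with ``Phi`` the specific absorbed fraction (SAF, kg^-1), ``E_i``/``Y_i``
the line energies (MeV, converted to joule here) and yields, and the
radiation weighting factor ``w_R = 1`` for both photons and electrons.

Photon SAFs come from per-phantom pre-calculated grids (log-log interpolated
in energy).  Electron SAFs use the grids when present and otherwise the
standard local-absorption approximations: ``1/M_T`` for self-irradiation,
``0.5/M_c`` for a wall irradiated by its content, ``1/M_TB`` for a total-body
source, and zero for other cross-fire.

Across an ensemble of phantoms, the per-pair S values are modelled as normal
(sample mean/SD) when the normal 2.5th percentile stays positive, and as
lognormal (geometric mean/SD) otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nuclear_data import MEV_TO_J, Radionuclide, ValidationError
from .sampling import (
    ParameterSpec,
    SampleMatrix,
    Z95,
    latin_hypercube,
    lognormal_bounds,
    normal_bounds,
)

__all__ = [
    "PhantomSAFLibrary",
    "SValueTable",
    "SValueDistribution",
    "electron_saf",
    "photon_saf",
    "resolve_surrogate",
    "compute_svalue",
    "svalue_table",
    "fit_svalue_distribution",
    "fit_all_distributions",
    "sample_svalues",
    "RADIATION_WEIGHTS",
    "TOTAL_BODY",
]

logger = logging.getLogger(__name__)

#: Radiation weighting factors w_R (low-LET convention).
RADIATION_WEIGHTS = {"photon": 1.0, "electron": 1.0}

#: Source label triggering the 1/M_TB electron rule.
TOTAL_BODY = "total_body"


@dataclass
class PhantomSAFLibrary:
    """One phantom: organ masses (kg) and SAF grids Phi(r_T <- r_S, E).

    ``photon_saf`` maps ``(target, source)`` to an ``(energies, values)``
    grid pair with strictly increasing energies (MeV) and SAFs in kg^-1;
    ``electron_saf_grids`` optionally has the same shape.  ``walled_organs``
    maps a wall target to the content organ whose activity irradiates it;
    ``surrogate_map`` maps an unsegmented target to the organ actually used.
    """

    phantom_id: str
    sex: str  # "male" | "female"
    organ_masses: dict[str, float]
    photon_saf: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]
    electron_saf_grids: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] | None = None
    walled_organs: dict[str, str] = field(default_factory=dict)
    surrogate_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"unknown sex {self.sex!r}")
        for organ, mass in self.organ_masses.items():
            if not mass > 0:
                raise ValidationError(
                    f"{self.phantom_id}: non-positive mass for {organ}: {mass}"
                )
        for pair, (energies, values) in self.photon_saf.items():
            e = np.asarray(energies, dtype=float)
            v = np.asarray(values, dtype=float)
            if e.size < 2 or np.any(np.diff(e) <= 0):
                raise ValidationError(
                    f"{self.phantom_id}: photon grid for {pair} needs >= 2 "
                    "strictly increasing energies"
                )
            if np.any(v < 0):
                raise ValidationError(
                    f"{self.phantom_id}: negative SAF in grid for {pair}"
                )
            self.photon_saf[pair] = (e, v)

    def mass(self, organ: str) -> float:
        try:
            return self.organ_masses[organ]
        except KeyError as exc:
            raise ValidationError(
                f"{self.phantom_id}: no mass for organ {organ!r}"
            ) from exc


def resolve_surrogate(target: str, phantom: PhantomSAFLibrary) -> str:
    """The organ actually used for a target in this phantom.

    Segmented targets (those with a mass entry) resolve to themselves;
    otherwise the configured surrogate is returned.  Deterministic.
    """
    if target in phantom.organ_masses:
        return target
    if target in phantom.surrogate_map:
        return phantom.surrogate_map[target]
    raise ValidationError(
        f"{phantom.phantom_id}: target {target!r} is not segmented and has "
        "no configured surrogate"
    )


def electron_saf(target: str, source: str, phantom: PhantomSAFLibrary) -> float:
    """Electron SAF (kg^-1) by the local-absorption approximations.

    1/M_T for target == source; 0.5/M_c for a wall irradiated by its
    content; 1/M_TB for a total-body source; otherwise 0.
    """
    if target == source:
        return 1.0 / phantom.mass(target)
    if target in phantom.walled_organs:
        content = phantom.walled_organs[target]
        if content == source:
            return 0.5 / phantom.mass(content)
    if source == TOTAL_BODY:
        return 1.0 / phantom.mass(TOTAL_BODY)
    return 0.0


def photon_saf(
    target: str, source: str, energy: float, phantom: PhantomSAFLibrary
) -> float:
    """Interpolate the photon SAF grid at an energy (MeV).

    Exact at grid nodes; log-log linear between nodes; constant beyond the
    grid ends (logged).  Zero grid values force linear interpolation for the
    bracketing interval.
    """
    key = (target, source)
    if key not in phantom.photon_saf:
        resolved = resolve_surrogate(target, phantom)
        key = (resolved, source)
        if key not in phantom.photon_saf:
            raise ValidationError(
                f"{phantom.phantom_id}: no photon SAF grid for "
                f"({target!r} <- {source!r})"
            )
    energies, values = phantom.photon_saf[key]
    if not energy > 0:
        raise ValidationError(f"photon energy must be positive, got {energy}")
    if energy <= energies[0]:
        if energy < energies[0]:
            logger.warning(
                "photon SAF query %.4g MeV below grid start %.4g MeV for %s; "
                "using end value",
                energy,
                energies[0],
                key,
            )
        return float(values[0])
    if energy >= energies[-1]:
        if energy > energies[-1]:
            logger.warning(
                "photon SAF query %.4g MeV above grid end %.4g MeV for %s; "
                "using end value",
                energy,
                energies[-1],
                key,
            )
        return float(values[-1])
    idx = int(np.searchsorted(energies, energy)) - 1
    e0, e1 = energies[idx], energies[idx + 1]
    v0, v1 = values[idx], values[idx + 1]
    if energy == e0:
        return float(v0)
    if v0 > 0 and v1 > 0:
        frac = (math.log(energy) - math.log(e0)) / (math.log(e1) - math.log(e0))
        return float(math.exp(math.log(v0) + frac * (math.log(v1) - math.log(v0))))
    frac = (energy - e0) / (e1 - e0)
    return float(v0 + frac * (v1 - v0))


def _electron_phi(
    target: str, source: str, energy: float, phantom: PhantomSAFLibrary
) -> float:
    grids = phantom.electron_saf_grids
    if grids:
        key = (target, source)
        if key not in grids:
            key = (resolve_surrogate(target, phantom), source)
        if key in grids:
            energies, values = grids[key]
            return float(np.interp(energy, energies, values))
    return electron_saf(target, source, phantom)


def compute_svalue(
    nuclide: Radionuclide,
    target: str,
    source: str,
    phantom: PhantomSAFLibrary,
) -> float:
    """S_w(r_T <- r_S) in Sv per nuclear transformation for one phantom."""
    if not nuclide.emissions:
        logger.warning("%s has no emission data; S value is 0", nuclide.name)
        return 0.0
    resolved = resolve_surrogate(target, phantom)
    total = 0.0
    for line in nuclide.emissions:
        w_r = RADIATION_WEIGHTS[line.radiation_type]
        if line.radiation_type == "photon":
            phi = photon_saf(resolved, source, line.mean_energy, phantom)
        else:
            phi = _electron_phi(resolved, source, line.mean_energy, phantom)
        total += w_r * line.mean_energy * line.yield_per_nt * phi
    return total * MEV_TO_J


@dataclass(frozen=True)
class SValueTable:
    """S values per (nuclide, target, source), Sv per transformation."""

    values: dict[tuple[str, str, str], float]

    def __post_init__(self) -> None:
        for key, s in self.values.items():
            if s < 0:
                raise ValidationError(f"negative S value for {key}: {s}")

    def get(self, nuclide: str, target: str, source: str) -> float:
        return self.values[(nuclide, target, source)]

    def to_frame(self) -> pd.DataFrame:
        rows = [(n, t, s, v) for (n, t, s), v in self.values.items()]
        return pd.DataFrame(rows, columns=["nuclide", "target", "source", "sv_per_nt"])


def svalue_table(
    nuclides, targets, sources, phantom: PhantomSAFLibrary
) -> SValueTable:
    """All (nuclide, target, source) S values for one phantom."""
    values = {
        (nuc.name, t, s): compute_svalue(nuc, t, s, phantom)
        for nuc in nuclides
        for t in targets
        for s in sources
    }
    return SValueTable(values=values)


@dataclass(frozen=True)
class SValueDistribution:
    """Fitted inter-phantom distribution of one organ pair's S value.

    ``params`` is (mu, sigma) for a normal fit and (geometric mean,
    geometric SD) for a lognormal fit; ``min``/``max`` are the 2.5th/97.5th
    percentiles.
    """

    phantom_values: tuple[float, ...]
    distribution: str  # "normal" | "lognormal"
    params: tuple[float, float]
    min: float
    max: float

    def to_parameter_spec(self, name: str) -> ParameterSpec:
        loc, scale = self.params
        if self.distribution == "normal":
            cv = scale / loc if loc > 0 else 0.0
            return ParameterSpec(
                name=name,
                distribution="normal",
                mean=loc,
                cv=cv,
                min=self.min,
                max=self.max,
            )
        return ParameterSpec(
            name=name,
            distribution="lognormal",
            mean=loc,
            cv=scale,
            min=self.min,
            max=self.max,
        )


def fit_svalue_distribution(values) -> SValueDistribution:
    """Fit the inter-phantom distribution of one organ pair.

    First a normal fit (sample mean, n-1 sample SD).  If its 2.5th
    percentile ``mu - 1.96 sigma`` is non-positive — i.e. the normal model
    would admit negative S values — refit as lognormal (geometric mean,
    geometric SD from the n-1 SD of the log values).  Fewer than two values
    yield a degenerate distribution with a warning.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValidationError("no S values to fit")
    if np.any(vals < 0):
        raise ValidationError(f"negative S values: {vals}")
    if vals.size == 1:
        logger.warning("single S value; degenerate distribution assumed")
        v = float(vals[0])
        return SValueDistribution(
            phantom_values=tuple(vals),
            distribution="normal",
            params=(v, 0.0),
            min=v,
            max=v,
        )
    mu = float(np.mean(vals))
    sigma = float(np.std(vals, ddof=1))
    if mu - Z95 * sigma > 0 or sigma == 0.0:
        lo, hi = mu - Z95 * sigma, mu + Z95 * sigma
        return SValueDistribution(
            phantom_values=tuple(vals),
            distribution="normal",
            params=(mu, sigma),
            min=lo,
            max=hi,
        )
    if np.any(vals <= 0):
        raise ValidationError(
            "lognormal fallback required but some S values are non-positive"
        )
    logs = np.log(vals)
    gm = float(np.exp(np.mean(logs)))
    gsd = float(np.exp(np.std(logs, ddof=1)))
    lo, hi = lognormal_bounds(gm, gsd)
    return SValueDistribution(
        phantom_values=tuple(vals),
        distribution="lognormal",
        params=(gm, gsd),
        min=lo,
        max=hi,
    )


def fit_all_distributions(
    nuclides, targets, sources, phantoms
) -> dict[tuple[str, str, str], SValueDistribution]:
    """Fit per-pair S-value distributions across a phantom ensemble."""
    dists: dict[tuple[str, str, str], SValueDistribution] = {}
    for nuc in nuclides:
        for t in targets:
            for s in sources:
                per_phantom = [
                    compute_svalue(nuc, t, s, ph) for ph in phantoms
                ]
                dists[(nuc.name, t, s)] = fit_svalue_distribution(per_phantom)
    return dists


def sample_svalues(
    dists: dict[tuple[str, str, str], SValueDistribution],
    n: int,
    seed: int,
) -> dict[tuple[str, str, str], np.ndarray]:
    """LHS samples of every organ pair's S value, pairs independent.

    Degenerate pairs (zero spread, including all-zero S values) repeat their
    central value.  Reproducible under (dists, n, seed).
    """
    keys = sorted(dists.keys())
    specs = []
    degenerate: dict[tuple[str, str, str], float] = {}
    for key in keys:
        d = dists[key]
        loc = d.params[0]
        if d.min == d.max or loc <= 0:
            degenerate[key] = max(loc, 0.0)
            continue
        specs.append(d.to_parameter_spec(name="|".join(key)))
    out: dict[tuple[str, str, str], np.ndarray] = {
        key: np.full(n, val) for key, val in degenerate.items()
    }
    if specs:
        matrix = latin_hypercube(specs, n, seed)
        for spec in specs:
            key = tuple(spec.name.split("|"))
            out[key] = matrix.column(spec.name)
    return out
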