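"""Readers and writers for the CSV/YAML interfaces, and run configuration.

All CSVs are comma-delimited UTF-8 with a mandatory header row and '.'
decimals; scientific notation is accepted on read and emitted with six
significant digits.  Readers enforce the domain invariants (no NaN, no
negative values where positivity is required), and every writer/reader pair
round-trips text-representable values bit-exactly.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biokinetics import (
    BiokineticModel,
    ResidenceTimes,
    T_D_DEFAULT,
    builtin_cerium_model,
    load_model,
)
from .nuclear_data import (
    DecayChain,
    ValidationError,
    builtin_nuclides,
    load_chain_file,
    load_nuclide_file,
)
from .pipeline import (
    AnalysisConfig,
    AnalysisResult,
    DEFAULT_COLON_FRACTIONS,
    TissueWeights,
    UncertaintySummary,
    load_tissue_weights,
)
from .sampling import ParameterSpec, SampleMatrix, Z95
from .svalues import PhantomSAFLibrary, SValueTable, fit_all_distributions
from .synthetic import (
    DEFAULT_TARGETS,
    SyntheticPhantomSpec,
    generate_phantom_library,
)

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "build_analysis",
    "load_parameter_specs",
    "write_summary",
    "read_summary",
    "write_residence_times",
    "write_sample_matrix",
    "write_phantom_library",
    "read_phantom_library",
    "write_svalue_table",
    "config_hash",
]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


def _data_path(name: str) -> Path:
    return Path(str(resources.files("doseuq").joinpath("data", name)))


# ---------------------------------------------------------------------------
# Parameter specs
# ---------------------------------------------------------------------------

def load_parameter_specs(
    path: str | Path,
) -> tuple[list[ParameterSpec], dict[str, tuple[int, int]]]:
    """Load parameter specs from CSV.

    Columns: ``name, dist, mean`` plus either ``cv`` (or ``gsd`` for
    lognormal rows) or explicit ``min``/``max``; optional ``from``/``to``
    compartment ids linking each parameter to the transfer it drives.  When
    ``cv`` is absent it is inferred from the printed upper bound as
    ``(max - mean) / (1.96 mean)``; printed ``min``/``max`` are honoured as
    the truncation bounds even when asymmetric about the mean.
    """
    df = pd.read_csv(path)
    if df.isna().all(axis=None):
        raise ValidationError(f"{path}: empty parameter file")
    specs: list[ParameterSpec] = []
    transfer_map: dict[str, tuple[int, int]] = {}
    for idx, row in df.iterrows():
        name = str(row["name"])
        dist = str(row.get("dist", "normal"))
        mean = float(row["mean"])
        lo = float(row["min"]) if "min" in df.columns and pd.notna(row.get("min")) else None
        hi = float(row["max"]) if "max" in df.columns and pd.notna(row.get("max")) else None
        if "cv" in df.columns and pd.notna(row.get("cv")):
            cv = float(row["cv"])
        elif "gsd" in df.columns and pd.notna(row.get("gsd")):
            cv = float(row["gsd"])
        elif hi is not None:
            cv = (hi - mean) / (Z95 * mean)
        else:
            raise ValidationError(
                f"{path}: row {idx} ({name}): need cv/gsd or min/max"
            )
        if not np.isfinite(mean) or mean <= 0:
            raise ValidationError(f"{path}: row {idx} ({name}): bad mean {mean}")
        specs.append(
            ParameterSpec(
                name=name, distribution=dist, mean=mean, cv=cv, min=lo, max=hi
            )
        )
        if "from" in df.columns and pd.notna(row.get("from")):
            transfer_map[name] = (int(row["from"]), int(row["to"]))
    return specs, transfer_map


def builtin_cerium_parameters() -> tuple[list[ParameterSpec], dict[str, tuple[int, int]]]:
    """The packaged cerium transfer-coefficient uncertainty table."""
    return load_parameter_specs(_data_path("cerium_parameters.csv"))


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_summary(
    summaries: dict[str, UncertaintySummary] | AnalysisResult,
    path: str | Path,
    reference: dict[str, float] | None = None,
) -> None:
    """Write the per-target summary table (mean, SD, percentiles, UF).

    ``reference`` optionally adds a side-by-side reference-value column.
    """
    if isinstance(summaries, AnalysisResult):
        summaries = summaries.summaries
    rows = []
    for s in summaries.values():
        row = {
            "target": s.target,
            "mean_Sv_per_Bq": s.mean,
            "sd": s.sd,
            "p2.5": s.p2_5,
            "p50": s.p50,
            "p97.5": s.p97_5,
            "UF": s.uf,
        }
        if reference is not None:
            row["reference_Sv_per_Bq"] = reference.get(s.target, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_summary(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"target", "mean_Sv_per_Bq", "sd", "p2.5", "p50", "p97.5", "UF"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing summary columns {sorted(missing)}")
    if df[sorted(required - {"target"})].isna().any(axis=None):
        raise ValidationError(f"{path}: NaN values in summary")
    return df


def write_residence_times(rt: ResidenceTimes, path: str | Path) -> None:
    rows = [
        {"nuclide": member, "region": key, "a_tilde_bq_d": value}
        for (member, key), value in sorted(rt.a_tilde.items(), key=lambda kv: (kv[0][0], str(kv[0][1])))
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_sample_matrix(matrix: SampleMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, index=False, float_format="%.17g")


def write_svalue_table(table: SValueTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# Phantom libraries
# ---------------------------------------------------------------------------

def write_phantom_library(phantom: PhantomSAFLibrary, directory: str | Path) -> None:
    """Write one phantom as masses + SAF CSVs under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    masses = pd.DataFrame(
        sorted(phantom.organ_masses.items()), columns=["organ", "mass_kg"]
    )
    masses.to_csv(directory / "masses.csv", index=False, float_format="%.17g")
    rows = []
    for (target, source), (energies, values) in sorted(phantom.photon_saf.items()):
        for e, v in zip(energies, values):
            rows.append((source, target, e, v, "photon"))
    if phantom.electron_saf_grids:
        for (target, source), (energies, values) in sorted(
            phantom.electron_saf_grids.items()
        ):
            for e, v in zip(energies, values):
                rows.append((source, target, e, v, "electron"))
    pd.DataFrame(
        rows, columns=["source", "target", "energy_MeV", "saf_per_kg", "radiation_type"]
    ).to_csv(directory / "saf.csv", index=False, float_format="%.17g")
    meta = {
        "phantom_id": phantom.phantom_id,
        "sex": phantom.sex,
        "walled_organs": dict(phantom.walled_organs),
        "surrogate_map": dict(phantom.surrogate_map),
    }
    with (directory / "phantom.yaml").open("w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_phantom_library(directory: str | Path) -> PhantomSAFLibrary:
    directory = Path(directory)
    with (directory / "phantom.yaml").open("r", encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    masses_df = pd.read_csv(directory / "masses.csv", float_precision="round_trip")
    if masses_df["mass_kg"].isna().any() or (masses_df["mass_kg"] <= 0).any():
        raise ValidationError(f"{directory}: masses must be positive and finite")
    masses = dict(zip(masses_df["organ"], masses_df["mass_kg"].astype(float)))
    saf_df = pd.read_csv(directory / "saf.csv", float_precision="round_trip")
    if saf_df["saf_per_kg"].isna().any() or (saf_df["saf_per_kg"] < 0).any():
        raise ValidationError(f"{directory}: SAFs must be non-negative")
    photon: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    electron: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for (rad, target, source), grp in saf_df.groupby(
        ["radiation_type", "target", "source"]
    ):
        grp = grp.sort_values("energy_MeV")
        grid = (
            grp["energy_MeV"].to_numpy(float),
            grp["saf_per_kg"].to_numpy(float),
        )
        (photon if rad == "photon" else electron)[(target, source)] = grid
    return PhantomSAFLibrary(
        phantom_id=str(meta["phantom_id"]),
        sex=str(meta["sex"]),
        organ_masses=masses,
        photon_saf=photon,
        electron_saf_grids=electron or None,
        walled_organs=meta.get("walled_organs") or {},
        surrogate_map=meta.get("surrogate_map") or {},
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """A fully validated run description (see the packaged example YAML)."""

    nuclide: str
    model: str | dict
    phantoms: dict | list
    weights: str
    n: int
    seed: int
    t_d: float = T_D_DEFAULT
    targets: list[str] | str = "default"
    out_dir: str = "results"

    def to_dict(self) -> dict:
        return {
            "nuclide": self.nuclide,
            "model": self.model,
            "phantoms": self.phantoms,
            "weights": self.weights,
            "n": self.n,
            "seed": self.seed,
            "t_d": self.t_d,
            "targets": self.targets,
            "out_dir": self.out_dir,
        }


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run-config YAML; errors are aggregated."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping")
    errors = []
    for fname in ("nuclide", "phantoms", "n", "seed"):
        if fname not in data:
            errors.append(f"{fname}: required field missing")
    n = data.get("n")
    if n is not None and (not isinstance(n, int) or n < 2):
        errors.append(f"n: must be an integer >= 2, got {n!r}")
    seed = data.get("seed")
    if seed is not None and not isinstance(seed, int):
        errors.append(f"seed: must be an integer, got {seed!r}")
    t_d = data.get("t_d", T_D_DEFAULT)
    if not (isinstance(t_d, (int, float)) and t_d > 0):
        errors.append(f"t_d: must be positive, got {t_d!r}")
    if errors:
        raise ValidationError(
            f"{path}: invalid run config:\n  " + "\n  ".join(errors)
        )
    return RunConfig(
        nuclide=str(data["nuclide"]),
        model=data.get("model", "builtin:cerium"),
        phantoms=data["phantoms"],
        weights=str(data.get("weights", "builtin:icrp103")),
        n=int(n),
        seed=int(seed),
        t_d=float(t_d),
        targets=data.get("targets", "default"),
        out_dir=str(data.get("out_dir", "results")),
    )


def save_config(config: RunConfig, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the run configuration, for run metadata."""
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _resolve_chain(ref: str) -> DecayChain:
    chains = builtin_nuclides()
    if ref in chains:
        return chains[ref]
    p = Path(ref)
    if p.exists():
        try:
            return load_chain_file(p)
        except ValidationError:
            return DecayChain.single(load_nuclide_file(p))
    raise ValidationError(f"unknown nuclide/chain reference {ref!r}")


def _resolve_model(ref) -> tuple[BiokineticModel, list[ParameterSpec], dict]:
    if ref == "builtin:cerium":
        model = builtin_cerium_model()
        specs, tmap = builtin_cerium_parameters()
        return model, specs, tmap
    if isinstance(ref, dict):
        model = load_model(
            ref["compartments"], ref["parameters"], int(ref["intake"])
        )
        specs, tmap = load_parameter_specs(ref["parameters"])
        return model, specs, tmap
    raise ValidationError(f"unknown model reference {ref!r}")


def _resolve_phantoms(ref) -> list[PhantomSAFLibrary]:
    if isinstance(ref, dict) and "synthetic" in ref:
        spec_kwargs = dict(ref["synthetic"] or {})
        spec = SyntheticPhantomSpec(**spec_kwargs)
        return generate_phantom_library(spec)
    if isinstance(ref, list):
        return [read_phantom_library(p) for p in ref]
    raise ValidationError(f"unknown phantom reference {ref!r}")


def build_analysis(config: RunConfig) -> AnalysisConfig:
    """Resolve a RunConfig into the concrete analysis ingredients.

    S-value distributions are fitted over the resolved phantom ensemble for
    every (chain member, target, source region) triple of the model, and
    the colon composite is registered with its default mass fractions when
    its segments are among the targets.
    """
    chain = _resolve_chain(config.nuclide)
    model, specs, tmap = _resolve_model(config.model)
    phantoms = _resolve_phantoms(config.phantoms)
    weights = (
        load_tissue_weights()
        if config.weights == "builtin:icrp103"
        else load_tissue_weights(config.weights)
    )
    targets = (
        list(DEFAULT_TARGETS) if config.targets == "default" else list(config.targets)
    )
    sources = sorted(
        {
            c.source_region
            for c in model.compartments
            if not c.is_excreta
        }
    )
    dists = fit_all_distributions(list(chain), targets, sources, phantoms)
    composites = (
        {"colon": dict(DEFAULT_COLON_FRACTIONS)}
        if all(m in targets for m in DEFAULT_COLON_FRACTIONS)
        else {}
    )
    return AnalysisConfig(
        chain=chain,
        model=model,
        parameter_specs=specs,
        parameter_transfers=tmap,
        svalue_dists=dists,
        weights=weights,
        targets=targets,
        seed=config.seed,
        n=config.n,
        t_d=config.t_d,
        composites=composites,
    )
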