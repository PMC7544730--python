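"""Dose-coefficient assembly and the sampled uncertainty analysis.

Committed equivalent-dose coefficients combine residence times and S values:

    h(r_T) = sum_i sum_{r_S} A-tilde(r_S) * 86400 * S_w(r_T <- r_S)_i ,

with A-tilde in Bq*d per Bq intake (86400 transformations per Bq*d) and
S_w in Sv per transformation, summed over chain members ``i``.

The effective dose coefficient is the tissue-weighted male/female average;
the detriment-weighted dose coefficient ``e_DW`` applies the same tissue
weights to a *randomized* male/female mixture (sex drawn per sample), which
is the appropriate aggregate when doses are sampled over phantom ensembles
rather than evaluated on the fixed reference pair.

The uncertainty analysis draws n Latin-hypercube rows of the biokinetic
transfer coefficients and of every organ pair's S value, rebuilds the chain
kinetics per row, and summarizes each target's sampled dose coefficient with
mean, SD, percentiles and the uncertainty factor UF = sqrt(P97.5 / P2.5).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biokinetics import (
    BiokineticModel,
    T_D_DEFAULT,
    aggregate_to_source_regions,
    build_chain_system,
    integrated_activity,
)
from .nuclear_data import DecayChain, ValidationError
from .sampling import ParameterSpec, latin_hypercube
from .svalues import SValueDistribution, SValueTable, sample_svalues

__all__ = [
    "TissueWeights",
    "DoseCoefficientSamples",
    "UncertaintySummary",
    "AnalysisConfig",
    "AnalysisResult",
    "equivalent_dose",
    "apply_composites",
    "detriment_weighted",
    "effective_dose",
    "uncertainty_factor",
    "summarize",
    "run_analysis",
    "load_tissue_weights",
    "SECONDS_PER_DAY",
    "DEFAULT_COLON_FRACTIONS",
    "EDW_KEY",
]

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86400.0

#: Key under which the detriment-weighted dose coefficient is summarized.
EDW_KEY = "detriment_weighted"

#: Colon composite: mass-fraction weights of the three colon wall segments
#: (right colon / left colon / rectosigmoid, reference wall masses
#: 150/145/70 g).
DEFAULT_COLON_FRACTIONS = {
    "rc_wall": 150.0 / 365.0,
    "lc_wall": 145.0 / 365.0,
    "rs_wall": 70.0 / 365.0,
}

#: Optional reporting transform replicating the legacy two-segment colon
#: convention (upper/lower large intestine), provided for side-by-side
#: comparison only.
LEGACY_COLON_FRACTIONS = {"uli_wall": 0.57, "lli_wall": 0.43}


@dataclass(frozen=True)
class TissueWeights:
    """ICRP-style tissue-weighting factors with a remainder group.

    ``weights`` maps named targets to w_T; the remainder contributes
    ``remainder_weight`` times the arithmetic mean of ``remainder_members``
    (a per-sex organ list).  ``sex_specific`` maps a weighted target to the
    organ used for each sex (e.g. the gonad target to testes/ovaries).
    """

    weights: dict[str, float]
    remainder_weight: float
    remainder_members: dict[str, tuple[str, ...]]
    sex_specific: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.weights.values()) + self.remainder_weight
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"tissue weights must sum to 1, got {total!r}"
            )
        for sex in ("male", "female"):
            if sex not in self.remainder_members:
                raise ValidationError(f"remainder members missing for {sex}")

    def resolve(self, target: str, sex: str) -> str:
        return self.sex_specific.get(target, {}).get(sex, target)


def load_tissue_weights(path: str | Path | None = None) -> TissueWeights:
    """Load tissue weights from YAML (packaged ICRP 103 values by default)."""
    if path is None:
        path = Path(str(resources.files("doseuq").joinpath(
            "data", "tissue_weights_icrp103.yaml")))
    with Path(path).open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return TissueWeights(
        weights={k: float(v) for k, v in data["weights"].items()},
        remainder_weight=float(data["remainder_weight"]),
        remainder_members={
            sex: tuple(organs)
            for sex, organs in data["remainder_members"].items()
        },
        sex_specific=data.get("sex_specific", {}),
    )


def equivalent_dose(
    rt,
    sv: SValueTable | dict,
    targets,
) -> dict[str, float]:
    """h(r_T) in Sv per Bq intake from aggregated residence times and S values.

    ``rt`` must be keyed by (member, source region); ``sv`` provides
    S values per (nuclide, target, source).  Linear in both inputs.  A
    missing (nuclide, target, source) S value after surrogate resolution is
    an error listing every missing pair.
    """
    values = sv.values if isinstance(sv, SValueTable) else sv
    h: dict[str, float] = {}
    missing = []
    for target in targets:
        acc = 0.0
        for (member, region), a_tilde in rt.a_tilde.items():
            key = (member, target, region)
            if key not in values:
                missing.append(key)
                continue
            acc += a_tilde * SECONDS_PER_DAY * values[key]
        h[target] = acc
    if missing:
        raise ValidationError(
            f"missing S values for pairs: {sorted(set(missing))[:10]}"
            + ("..." if len(set(missing)) > 10 else "")
        )
    return h


def apply_composites(
    h: dict[str, float], composites: dict[str, dict[str, float]]
) -> dict[str, float]:
    """Assemble composite targets (e.g. colon) as weighted sums of members."""
    out = dict(h)
    for name, members in composites.items():
        try:
            out[name] = sum(f * h[m] for m, f in members.items())
        except KeyError as exc:
            raise ValidationError(
                f"composite {name!r} references missing target {exc}"
            ) from exc
    return out


def _weighted_sum(h: dict[str, float], weights: TissueWeights, sex: str) -> float:
    total = 0.0
    for target, w in weights.weights.items():
        organ = weights.resolve(target, sex)
        if organ not in h:
            raise ValidationError(f"missing weighted organ {organ!r} for {sex}")
        total += w * h[organ]
    members = weights.remainder_members[sex]
    if not members:
        if weights.remainder_weight != 0.0:
            raise ValidationError("remainder weight set but no member organs")
        return total
    try:
        remainder = sum(h[m] for m in members) / len(members)
    except KeyError as exc:
        raise ValidationError(f"missing remainder organ {exc}") from exc
    return total + weights.remainder_weight * remainder


def detriment_weighted(
    h: dict[str, float], weights: TissueWeights, sex: str
) -> float:
    """Tissue-weighted sum of one sample's organ doses at the sampled sex."""
    if sex not in ("male", "female"):
        raise ValidationError(f"unknown sex {sex!r}")
    return _weighted_sum(h, weights, sex)


def effective_dose(
    h_male: dict[str, float],
    h_female: dict[str, float],
    weights: TissueWeights,
) -> float:
    """Reference-person effective dose: tissue-weighted male/female average."""
    return 0.5 * (
        _weighted_sum(h_male, weights, "male")
        + _weighted_sum(h_female, weights, "female")
    )


def uncertainty_factor(samples) -> float:
    """UF = sqrt(P97.5 / P2.5) with linear-interpolation empirical quantiles."""
    vals = np.asarray(list(samples), dtype=float)
    if vals.size < 2:
        raise ValidationError("need at least 2 samples for a UF")
    if np.any(vals <= 0):
        raise ValidationError("UF requires strictly positive samples")
    lo = np.quantile(vals, 0.025)
    hi = np.quantile(vals, 0.975)
    return float(np.sqrt(hi / lo))


@dataclass(frozen=True)
class UncertaintySummary:
    """Mean, SD, percentiles and UF of one target's sampled dose coefficient."""

    target: str
    mean: float
    sd: float
    p2_5: float
    p50: float
    p97_5: float
    uf: float


def summarize(target: str, samples: np.ndarray) -> UncertaintySummary:
    vals = np.asarray(samples, dtype=float)
    return UncertaintySummary(
        target=target,
        mean=float(np.mean(vals)),
        sd=float(np.std(vals, ddof=1)),
        p2_5=float(np.quantile(vals, 0.025)),
        p50=float(np.quantile(vals, 0.5)),
        p97_5=float(np.quantile(vals, 0.975)),
        uf=uncertainty_factor(vals),
    )


@dataclass(frozen=True)
class DoseCoefficientSamples:
    """Per-target sampled dose coefficients plus e_DW and per-sample sex."""

    h: dict[str, np.ndarray]  # target -> (n,) Sv per Bq intake
    e_dw: np.ndarray
    sexes: np.ndarray  # array of "male"/"female"

    @property
    def n(self) -> int:
        return len(self.e_dw)


@dataclass
class AnalysisConfig:
    """Resolved ingredients of one uncertainty-analysis run."""

    chain: DecayChain
    model: BiokineticModel
    parameter_specs: list[ParameterSpec]
    # parameter name -> (from_id, to_id) transfer it drives
    parameter_transfers: dict[str, tuple[int, int]]
    svalue_dists: dict[tuple[str, str, str], SValueDistribution]
    weights: TissueWeights
    targets: list[str]
    seed: int
    n: int = 500
    t_d: float = T_D_DEFAULT
    composites: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("n must be >= 2")
        for spec in self.parameter_specs:
            if spec.name not in self.parameter_transfers:
                raise ValidationError(
                    f"parameter {spec.name} has no transfer mapping"
                )


@dataclass(frozen=True)
class AnalysisResult:
    summaries: dict[str, UncertaintySummary]
    samples: DoseCoefficientSamples
    seed: int
    n: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                s.target,
                s.mean,
                s.sd,
                s.p2_5,
                s.p50,
                s.p97_5,
                s.uf,
            )
            for s in self.summaries.values()
        ]
        return pd.DataFrame(
            rows,
            columns=["target", "mean_Sv_per_Bq", "sd", "p2.5", "p50", "p97.5", "UF"],
        )


def _derived_seeds(seed: int) -> tuple[int, int, int]:
    # three independent substreams (biokinetic LHS, S-value LHS, sex draw)
    state = np.random.SeedSequence(seed).generate_state(3)
    return tuple(int(s) % (2**31) for s in state)


def run_analysis(config: AnalysisConfig) -> AnalysisResult:
    """Run the n-sample uncertainty analysis.

    Per sample: take one LHS row of the biokinetic parameters, rebuild the
    transfer coefficients, solve the chain kinetics and integrate residence
    times; take one (independently permuted) LHS row of every organ pair's
    S value; draw the sample's sex (fair Bernoulli); assemble organ
    equivalent-dose coefficients, composites and e_DW.  Fully reproducible
    under (config, seed).
    """
    t0 = time.perf_counter()
    bio_seed, sv_seed, sex_seed = _derived_seeds(config.seed)

    bio_matrix = latin_hypercube(config.parameter_specs, config.n, bio_seed)
    sv_samples = sample_svalues(config.svalue_dists, config.n, sv_seed)
    sexes = np.where(
        np.random.default_rng(sex_seed).random(config.n) < 0.5, "male", "female"
    )

    base_transfers = dict(config.model.transfers)
    all_targets = list(config.targets)
    h_samples: dict[str, list[float]] = {t: [] for t in all_targets}
    for name in config.composites:
        h_samples.setdefault(name, [])
    e_dw = np.empty(config.n)

    for i in range(config.n):
        try:
            transfers = dict(base_transfers)
            for spec in config.parameter_specs:
                key = config.parameter_transfers[spec.name]
                transfers[key] = float(bio_matrix.column(spec.name)[i])
            model_i = config.model.with_transfers(transfers)
            system = build_chain_system(model_i, config.chain)
            rt = integrated_activity(system, config.t_d)
            rt = aggregate_to_source_regions(rt, model_i)

            sv_i = {key: float(arr[i]) for key, arr in sv_samples.items()}
            h = equivalent_dose(rt, sv_i, all_targets)
            h = apply_composites(h, config.composites)
            for target, value in h.items():
                if target in h_samples:
                    h_samples[target].append(value)
            e_dw[i] = detriment_weighted(h, config.weights, str(sexes[i]))
        except Exception as exc:
            raise RuntimeError(
                f"uncertainty analysis failed at sample {i}: {exc}"
            ) from exc

    h_arrays = {t: np.asarray(v) for t, v in h_samples.items()}
    samples = DoseCoefficientSamples(h=h_arrays, e_dw=e_dw, sexes=sexes)
    summaries = {
        t: summarize(t, arr) for t, arr in h_arrays.items()
    }
    summaries[EDW_KEY] = summarize(EDW_KEY, e_dw)
    logger.info(
        "uncertainty analysis: n=%d, %d targets, %.2f s",
        config.n,
        len(h_arrays),
        time.perf_counter() - t0,
    )
    return AnalysisResult(
        summaries=summaries, samples=samples, seed=config.seed, n=config.n
    )
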