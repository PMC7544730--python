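"""Linear compartmental biokinetics and time-integrated activities.

The transport of a radionuclide through the body is modelled as a first-order
linear compartmental system

    dq_i/dt = - (sum_j k_{j<-i} + lambda_p) q_i + sum_j k_{i<-j} q_j ,

where ``q_i`` is the activity (Bq) in compartment ``i``, ``k`` are transfer
coefficients in d^-1 and ``lambda_p`` is the physical decay constant.  Intake
is an acute unit bolus at t = 0 into the intake compartment (ingestion), so
the inflow term becomes an initial condition.

Decay chains couple N copies of the compartmental system into one stacked
block lower-triangular matrix.  Because the state is *activity* rather than
atom number, ingrowth of daughter ``d`` from parent ``p`` in the same
compartment enters with rate ``lambda_d * branching(p->d)`` (converting the
atom-based ingrowth ``branching * lambda_p * N_p`` with ``q = lambda N``).

Because the system is linear, the primary solution path is the matrix
exponential, and time-integrated activities over the commitment period T_D
are obtained from the exact identity ``A x = q(T_D) - q(0)``.  A stiff
implicit Runge-Kutta backend (scipy's Radau) is retained as an alternative
and must agree with the closed form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .nuclear_data import DecayChain, Radionuclide, ValidationError

__all__ = [
    "Compartment",
    "BiokineticModel",
    "ChainSystem",
    "ActivitySolution",
    "ResidenceTimes",
    "build_system_matrix",
    "build_chain_system",
    "solve_activities",
    "integrated_activity",
    "aggregate_to_source_regions",
    "builtin_cerium_model",
    "load_model",
    "T_D_DEFAULT",
]

logger = logging.getLogger(__name__)

#: Default dose-integration (commitment) period: 50 years in days.
T_D_DEFAULT = 50 * 365.25

#: Negative-activity tolerance for solver output.
NEGATIVITY_TOL = 1e-10

EXCRETA_REGIONS = ("excreta", "environment")


@dataclass(frozen=True)
class Compartment:
    """A model compartment and the dosimetric source region it maps to.

    ``source_region`` is a phantom organ label, or ``"excreta"`` /
    ``"environment"`` for compartments that are outside the body for
    dosimetric purposes (cumulative urine and faeces).
    """

    id: int
    name: str
    source_region: str

    @property
    def is_excreta(self) -> bool:
        return self.source_region in EXCRETA_REGIONS


@dataclass(frozen=True)
class BiokineticModel:
    """Compartments plus first-order transfer coefficients (d^-1).

    ``transfers`` maps ``(from_id, to_id) -> k``.  The intake compartment
    receives the unit activity bolus at t = 0.
    """

    compartments: tuple[Compartment, ...]
    transfers: dict[tuple[int, int], float]
    intake_compartment: int

    def __post_init__(self) -> None:
        ids = [c.id for c in self.compartments]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate compartment ids: {ids}")
        known = set(ids)
        for (i, j), k in self.transfers.items():
            if i == j:
                raise ValidationError(f"self-transfer ({i},{i}) not allowed")
            if i not in known or j not in known:
                raise ValidationError(
                    f"transfer ({i},{j}) references unknown compartment"
                )
            if k < 0:
                raise ValidationError(f"negative transfer coefficient k({i}->{j})={k}")
        if self.intake_compartment not in known:
            raise ValidationError(
                f"intake compartment {self.intake_compartment} not in model"
            )

    @property
    def n(self) -> int:
        return len(self.compartments)

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(c.id for c in self.compartments)

    def compartment(self, cid: int) -> Compartment:
        for c in self.compartments:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def with_transfers(
        self, transfers: dict[tuple[int, int], float]
    ) -> "BiokineticModel":
        """A copy of the model with replaced transfer coefficients."""
        return BiokineticModel(
            compartments=self.compartments,
            transfers=dict(transfers),
            intake_compartment=self.intake_compartment,
        )

    def source_region_map(self) -> dict[int, str]:
        return {c.id: c.source_region for c in self.compartments}


def build_system_matrix(model: BiokineticModel, lambda_p: float) -> np.ndarray:
    """Rate matrix A (d^-1) of the single-nuclide system dq/dt = A q.

    Columns are ordered as ``model.compartments``.  With all losses modelled
    as explicit compartments, every column sums to ``-lambda_p``.
    """
    if lambda_p < 0:
        raise ValidationError(f"decay constant must be >= 0, got {lambda_p}")
    ids = model.ids
    index = {cid: pos for pos, cid in enumerate(ids)}
    n = len(ids)
    a = np.zeros((n, n))
    for (i, j), k in model.transfers.items():
        if k < 0:
            raise ValidationError(f"negative transfer coefficient k({i}->{j})={k}")
        a[index[j], index[i]] += k
        a[index[i], index[i]] -= k
    a[np.diag_indices(n)] -= lambda_p
    return a


@dataclass(frozen=True)
class ChainSystem:
    """Stacked rate matrix for N chain members x C compartments.

    State ordering is member-major: entry ``m * C + c`` is member ``m`` in
    compartment position ``c``.  ``initial_activity`` is Bq per Bq intake.
    """

    rate_matrix: np.ndarray
    initial_activity: np.ndarray
    member_names: tuple[str, ...]
    compartment_ids: tuple[int, ...]
    model: BiokineticModel

    @property
    def n_members(self) -> int:
        return len(self.member_names)

    @property
    def n_compartments(self) -> int:
        return len(self.compartment_ids)

    def state_index(self, member: str, compartment_id: int) -> int:
        m = self.member_names.index(member)
        c = self.compartment_ids.index(compartment_id)
        return m * self.n_compartments + c


def build_chain_system(
    models: dict[str, BiokineticModel] | BiokineticModel,
    chain: DecayChain,
) -> ChainSystem:
    """Assemble the block lower-triangular activity system for a decay chain.

    ``models`` is either a single model shared by every chain member (the
    lanthanide case: chemically similar parent and progeny) or a mapping
    member name -> model; all members must share the compartment set.
    """
    if isinstance(models, BiokineticModel):
        models = {m.name: models for m in chain}
    for m in chain:
        if m.name not in models:
            raise ValidationError(f"no biokinetic model for chain member {m.name}")
    ref = models[chain.parent.name]
    ids = ref.ids
    for name, model in models.items():
        if model.ids != ids:
            raise ValidationError(
                f"model for {name} does not share the compartment set of the parent"
            )

    c = len(ids)
    n = len(chain)
    names = tuple(m.name for m in chain)
    a = np.zeros((n * c, n * c))
    for mi, member in enumerate(chain):
        block = build_system_matrix(models[member.name], member.decay_constant)
        a[mi * c : (mi + 1) * c, mi * c : (mi + 1) * c] = block
        for child, frac in member.progeny:
            if frac == 0:
                continue
            try:
                di = names.index(child)
            except ValueError as exc:
                raise ValidationError(
                    f"progeny {child} of {member.name} not in chain"
                ) from exc
            lam_d = chain.member(child).decay_constant
            # activity-unit Bateman coupling: lambda_d * branching * I
            a[di * c : (di + 1) * c, mi * c : (mi + 1) * c] += (
                lam_d * frac * np.eye(c)
            )

    q0 = np.zeros(n * c)
    q0[ids.index(ref.intake_compartment)] = 1.0
    return ChainSystem(
        rate_matrix=a,
        initial_activity=q0,
        member_names=names,
        compartment_ids=ids,
        model=ref,
    )


@dataclass(frozen=True)
class ActivitySolution:
    """Activity per (member, compartment, time), Bq per Bq intake."""

    times: np.ndarray
    q: np.ndarray  # shape (n_members, n_compartments, n_times)
    member_names: tuple[str, ...]
    compartment_ids: tuple[int, ...]

    def activity(self, member: str, compartment_id: int) -> np.ndarray:
        m = self.member_names.index(member)
        c = self.compartment_ids.index(compartment_id)
        return self.q[m, c]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mi, name in enumerate(self.member_names):
            for ci, cid in enumerate(self.compartment_ids):
                for ti, t in enumerate(self.times):
                    rows.append((name, cid, t, self.q[mi, ci, ti]))
        return pd.DataFrame(
            rows, columns=["nuclide", "compartment", "time_d", "activity_bq"]
        )


class SolverError(RuntimeError):
    """ODE backend failed to converge; carries the solver diagnostics."""


def solve_activities(
    system: ChainSystem,
    times: np.ndarray,
    method: str = "expm",
) -> ActivitySolution:
    """Solve the chain system at the requested times (days).

    ``method="expm"`` evaluates the exact matrix-exponential solution;
    ``method="stiff"`` integrates with scipy's Radau implicit Runge-Kutta
    (rtol 1e-8, atol 1e-12, analytic Jacobian).  Both paths clip solver noise
    below ``NEGATIVITY_TOL`` to zero and raise on larger negative activities.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) < 0) or np.any(times < 0):
        raise ValidationError("times must be a sorted, non-negative 1-D array")

    a = system.rate_matrix
    q0 = system.initial_activity
    if method == "expm":
        cols = []
        for t in times:
            if t == 0.0:
                cols.append(q0.copy())
            else:
                cols.append(expm(a * t) @ q0)
        qmat = np.stack(cols, axis=-1)
    elif method == "stiff":
        t_end = float(times[-1]) if times[-1] > 0 else 1.0
        sol = solve_ivp(
            lambda _t, y: a @ y,
            (0.0, t_end),
            q0,
            method="Radau",
            t_eval=times if times[-1] > 0 else None,
            rtol=1e-8,
            atol=1e-12,
            jac=lambda _t, _y: a,
        )
        if not sol.success:
            raise SolverError(f"stiff solver failed: {sol.message}")
        qmat = sol.y if times[-1] > 0 else np.repeat(q0[:, None], len(times), axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")

    if qmat.min() < -NEGATIVITY_TOL * max(1.0, abs(qmat).max()):
        raise SolverError(
            f"negative activity {qmat.min():.3e} beyond tolerance"
        )
    qmat = np.clip(qmat, 0.0, None)
    n_c = system.n_compartments
    q = qmat.reshape(system.n_members, n_c, len(times))
    return ActivitySolution(
        times=times,
        q=q,
        member_names=system.member_names,
        compartment_ids=system.compartment_ids,
    )


@dataclass(frozen=True)
class ResidenceTimes:
    """Time-integrated activities A-tilde in Bq*d per Bq intake.

    Keys of ``a_tilde`` are ``(member name, key)`` where ``key`` is a
    compartment id (per-compartment form) or a source-region label
    (aggregated form).
    """

    a_tilde: dict[tuple[str, object], float]
    t_d: float

    def total(self) -> float:
        return float(sum(self.a_tilde.values()))

    def by_member(self, member: str) -> dict[object, float]:
        return {k: v for (m, k), v in self.a_tilde.items() if m == member}


def integrated_activity(system: ChainSystem, t_d: float = T_D_DEFAULT) -> ResidenceTimes:
    """A-tilde = integral of q(t) from 0 to T_D, per (member, compartment).

    For the linear system ``dq/dt = A q`` the integral satisfies the exact
    identity ``A x = q(T_D) - q(0)``.  When A is singular (e.g. a stable
    nuclide with closed kinetics) the augmented-matrix exponential
    ``expm([[A, I], [0, 0]])`` is used instead, which evaluates
    ``int_0^T e^{At} dt`` exactly as well.
    """
    if not t_d > 0:
        raise ValidationError(f"T_D must be positive, got {t_d}")
    a = system.rate_matrix
    q0 = system.initial_activity
    n = a.shape[0]

    if math.isinf(t_d):
        x = np.linalg.solve(a, -q0)
    else:
        q_end = expm(a * t_d) @ q0
        dq = q_end - q0
        x = None
        # the shortcut A x = q(T) - q(0) cancels catastrophically when the
        # state barely moves (quasi-stable nuclide, closed kinetics)
        if np.linalg.norm(dq) >= 1e-6 * np.linalg.norm(q0):
            try:
                cand = np.linalg.solve(a, dq)
                if np.all(np.isfinite(cand)):
                    x = cand
            except np.linalg.LinAlgError:
                x = None
        if x is None:
            logger.info(
                "singular or near-stationary rate matrix: "
                "falling back to augmented expm"
            )
            aug = np.zeros((2 * n, 2 * n))
            aug[:n, :n] = a * t_d
            aug[:n, n:] = np.eye(n) * t_d
            phi = expm(aug)[:n, n:]  # = int_0^{T_D} e^{At} dt
            x = phi @ q0

    x = np.asarray(x, dtype=float)
    if x.min() < -1e-8 * max(1.0, abs(x).max()):
        raise SolverError(f"negative integrated activity {x.min():.3e}")
    x = np.clip(x, 0.0, None)

    c = system.n_compartments
    a_tilde: dict[tuple[str, object], float] = {}
    for mi, name in enumerate(system.member_names):
        for ci, cid in enumerate(system.compartment_ids):
            a_tilde[(name, cid)] = float(x[mi * c + ci])
    return ResidenceTimes(a_tilde=a_tilde, t_d=t_d)


def aggregate_to_source_regions(
    rt: ResidenceTimes, model: BiokineticModel
) -> ResidenceTimes:
    """Sum per-compartment residence times into dosimetric source regions.

    Excreta compartments (cumulative urine/faeces) are dropped: they are
    outside the body and receive no dosimetric source-region status.  The
    grand total over all regions *including* excreta is conserved before the
    drop; unmapped compartments are an error.
    """
    region = model.source_region_map()
    out: dict[tuple[str, object], float] = {}
    for (member, cid), value in rt.a_tilde.items():
        if not isinstance(cid, (int, np.integer)):
            raise ValidationError("residence times are already aggregated")
        if cid not in region:
            raise ValidationError(f"compartment {cid} has no source-region mapping")
        label = region[cid]
        if label in EXCRETA_REGIONS:
            continue
        key = (member, label)
        out[key] = out.get(key, 0.0) + value
    return ResidenceTimes(a_tilde=out, t_d=rt.t_d)


# ---------------------------------------------------------------------------
# Packaged cerium model
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("doseuq").joinpath("data", name)))


def load_model(
    compartments_csv: str | Path,
    transfers: pd.DataFrame | str | Path,
    intake_compartment: int,
) -> BiokineticModel:
    """Build a model from a compartments CSV and a transfers table.

    The transfers table needs columns ``from``, ``to`` and one of
    ``k_per_day`` / ``mean``.
    """
    comp_df = pd.read_csv(compartments_csv)
    comps = tuple(
        Compartment(int(r.id), str(r.name), str(r.source_region))
        for r in comp_df.itertuples()
    )
    if not isinstance(transfers, pd.DataFrame):
        transfers = pd.read_csv(transfers)
    kcol = "k_per_day" if "k_per_day" in transfers.columns else "mean"
    renamed = transfers.rename(columns={"from": "src", "to": "dst"})
    tmap: dict[tuple[int, int], float] = {}
    for r in renamed.itertuples():
        tmap[(int(r.src), int(r.dst))] = float(getattr(r, kcol))
    return BiokineticModel(
        compartments=comps, transfers=tmap, intake_compartment=intake_compartment
    )


def builtin_cerium_model() -> BiokineticModel:
    """The packaged lanthanide (cerium) ingestion model.

    Systemic structure: blood exchanging with liver (two stages), three
    soft-tissue pools of increasing half-time, cortical and trabecular bone
    (surface -> volume -> marrow -> blood), kidneys (urinary path and other
    tissue) and gonads; an alimentary-tract transit chain from mouth through
    oesophagus (fast/slow), stomach, small intestine and the three colon
    segments to faeces; urinary excretion via the urinary bladder.  Ingestion
    enters through the mouth and is routed through the oesophagus.  Transfer
    coefficients are the packaged nominal means.
    """
    params = pd.read_csv(_data_path("cerium_parameters.csv"))
    return load_model(
        _data_path("cerium_compartments.csv"),
        params,
        intake_compartment=22,
    )
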