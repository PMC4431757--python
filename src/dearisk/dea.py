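"""Input-oriented, constant-returns-to-scale (CCR) data envelopment analysis.

Each decision-making unit (DMU) — here an individual study subject — converts
a vector of positive inputs (physical-activity expenditure and the inverse of
caloric intake) into a vector of positive outputs (the inverse of BMI).  The
radial efficiency score ``theta`` of a DMU is the optimal value of the
envelopment linear program

    minimise    theta
    subject to  sum_j lambda_j x_ij  <=  theta * x_io   for every input i
                sum_j lambda_j y_rj  >=  y_ro           for every output r
                lambda_j >= 0

A score of 1 means the unit lies on the empirical efficiency frontier; a
score below 1 measures the proportional input contraction that would move it
onto the frontier.  The multiplier (dual) form is also provided and is used
as an internal verification oracle through LP strong duality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "DMURecord",
    "DMUSet",
    "EfficiencyResult",
    "SolverOptions",
    "SolverStatus",
    "CCREfficiency",
    "CCREfficiencyResults",
    "solve_ccr",
    "solve_ccr_multiplier",
    "efficiency_scores",
]


class DEAValidationError(ValueError):
    """Raised when DMU data violate the positivity/shape contracts."""


class SolverStatus(str, Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    NUMERICAL_FAILURE = "numerical_failure"


@dataclass(frozen=True)
class DMURecord:
    """One decision-making unit: strictly positive inputs and outputs."""

    dmu_id: str
    inputs: tuple[float, ...]
    outputs: tuple[float, ...]

    def __post_init__(self) -> None:
        inputs = tuple(float(v) for v in self.inputs)
        outputs = tuple(float(v) for v in self.outputs)
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "outputs", outputs)
        if len(inputs) < 1 or len(outputs) < 1:
            raise DEAValidationError(
                f"DMU {self.dmu_id!r}: needs at least one input and one output"
            )
        for name, vec in (("input", inputs), ("output", outputs)):
            for i, v in enumerate(vec):
                if not np.isfinite(v) or v <= 0:
                    raise DEAValidationError(
                        f"DMU {self.dmu_id!r}: {name}_{i + 1} = {v} must be "
                        "strictly positive and finite"
                    )


class DMUSet:
    """Ordered, dimension-consistent collection of DMUs with unique ids."""

    def __init__(self, records: Iterable[DMURecord]):
        records = list(records)
        if not records:
            raise DEAValidationError("DMUSet requires at least one DMU")
        m = len(records[0].inputs)
        s = len(records[0].outputs)
        seen: set[str] = set()
        for r in records:
            if len(r.inputs) != m or len(r.outputs) != s:
                raise DEAValidationError(
                    f"DMU {r.dmu_id!r}: dimension mismatch (expected "
                    f"{m} inputs / {s} outputs)"
                )
            if r.dmu_id in seen:
                raise DEAValidationError(f"duplicate dmu_id {r.dmu_id!r}")
            seen.add(r.dmu_id)
        self._records = records
        self.ids = [r.dmu_id for r in records]
        self.X = np.array([r.inputs for r in records], dtype=float)   # n x m
        self.Y = np.array([r.outputs for r in records], dtype=float)  # n x s

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def __contains__(self, dmu_id: str) -> bool:
        return dmu_id in set(self.ids)

    def index_of(self, dmu_id: str) -> int:
        try:
            return self.ids.index(dmu_id)
        except ValueError:
            raise KeyError(f"dmu_id {dmu_id!r} not in DMUSet") from None

    @property
    def n_inputs(self) -> int:
        return self.X.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.Y.shape[1]

    # -- serialization -----------------------------------------------------
    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "DMUSet":
        """Build from a table with columns dmu_id, input_1.., output_1.."""
        in_cols = sorted(
            (c for c in frame.columns if c.startswith("input_")),
            key=lambda c: int(c.split("_")[1]),
        )
        out_cols = sorted(
            (c for c in frame.columns if c.startswith("output_")),
            key=lambda c: int(c.split("_")[1]),
        )
        if "dmu_id" not in frame.columns or not in_cols or not out_cols:
            raise DEAValidationError(
                "expected columns dmu_id, input_1..input_m, output_1..output_s"
            )
        return cls(
            DMURecord(str(row["dmu_id"]),
                      tuple(row[c] for c in in_cols),
                      tuple(row[c] for c in out_cols))
            for _, row in frame.iterrows()
        )

    @classmethod
    def from_csv(cls, path) -> "DMUSet":
        return cls.from_dataframe(pd.read_csv(path))

    def to_dataframe(self) -> pd.DataFrame:
        data: dict[str, list] = {"dmu_id": self.ids}
        for i in range(self.n_inputs):
            data[f"input_{i + 1}"] = self.X[:, i].tolist()
        for r in range(self.n_outputs):
            data[f"output_{r + 1}"] = self.Y[:, r].tolist()
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class SolverOptions:
    """LP solver settings.

    rescale : divide every input/output column by its mean before solving
        (scores are unchanged by units invariance; the raw columns here
        differ by ~5 orders of magnitude, so this is on by default).
    tol : feasibility tolerance handed to the LP backend.
    efficient_tol : scores within this distance of 1 are reported efficient.
    lambda_tol : peer weights above this enter the reference set.
    """

    backend: str = "highs"
    tol: float = 1e-9
    rescale: bool = True
    efficient_tol: float = 1e-6
    lambda_tol: float = 1e-7


@dataclass
class EfficiencyResult:
    dmu_id: str
    theta: float
    lambdas: np.ndarray
    reference_set: list[str]
    solver_status: SolverStatus
    theta_raw: float = field(repr=False, default=np.nan)


def _column_scales(dmus: DMUSet, options: SolverOptions):
    if options.rescale:
        return dmus.X.mean(axis=0), dmus.Y.mean(axis=0)
    return np.ones(dmus.n_inputs), np.ones(dmus.n_outputs)


def _clip_theta(theta_raw: float, options: SolverOptions) -> float:
    theta = min(theta_raw, 1.0)
    if theta >= 1.0 - options.efficient_tol:
        theta = 1.0
    return max(theta, 1e-12)


def solve_ccr(
    dmus: DMUSet, target_id: str, options: SolverOptions | None = None
) -> EfficiencyResult:
    """Solve the envelopment-form CCR program for one DMU.

    The target itself (theta=1, lambda_target=1) is always feasible, so a
    valid instance can never be infeasible; solver failure is surfaced in
    ``solver_status``, never as a silent NaN.
    """
    options = options or SolverOptions()
    o = dmus.index_of(target_id)
    n = len(dmus)
    if n == 1:
        return EfficiencyResult(target_id, 1.0, np.ones(1), [target_id],
                                SolverStatus.OPTIMAL, theta_raw=1.0)

    sx, sy = _column_scales(dmus, options)
    X = dmus.X / sx
    Y = dmus.Y / sy
    m, s = X.shape[1], Y.shape[1]

    # variables: [theta, lambda_1..lambda_n]
    c = np.zeros(n + 1)
    c[0] = 1.0
    A_ub = np.zeros((m + s, n + 1))
    b_ub = np.zeros(m + s)
    A_ub[:m, 0] = -X[o]
    A_ub[:m, 1:] = X.T
    A_ub[m:, 1:] = -Y.T
    b_ub[m:] = -Y[o]
    bounds = [(None, None)] + [(0, None)] * n
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds,
                  method=options.backend,
                  options={"primal_feasibility_tolerance": options.tol,
                           "dual_feasibility_tolerance": options.tol})
    if not res.success:
        status = (SolverStatus.INFEASIBLE if res.status == 2
                  else SolverStatus.NUMERICAL_FAILURE)
        return EfficiencyResult(target_id, np.nan, np.full(n, np.nan), [],
                                status)
    theta_raw = float(res.x[0])
    lambdas = np.maximum(res.x[1:], 0.0)
    refs = [dmus.ids[j] for j in range(n) if lambdas[j] > options.lambda_tol]
    return EfficiencyResult(target_id, _clip_theta(theta_raw, options),
                            lambdas, refs, SolverStatus.OPTIMAL,
                            theta_raw=theta_raw)


def solve_ccr_multiplier(
    dmus: DMUSet, target_id: str, options: SolverOptions | None = None
) -> EfficiencyResult:
    """Multiplier (dual) form of the CCR program; verification oracle.

    maximise u.y_o  subject to  v.x_o = 1,  u.y_j - v.x_j <= 0,  u, v >= 0.
    By strong duality the optimum equals the envelopment theta*.
    """
    options = options or SolverOptions()
    o = dmus.index_of(target_id)
    n = len(dmus)
    if n == 1:
        return EfficiencyResult(target_id, 1.0, np.ones(1), [target_id],
                                SolverStatus.OPTIMAL, theta_raw=1.0)
    sx, sy = _column_scales(dmus, options)
    X = dmus.X / sx
    Y = dmus.Y / sy
    m, s = X.shape[1], Y.shape[1]

    # variables: [u_1..u_s, v_1..v_m]
    c = np.concatenate([-Y[o], np.zeros(m)])
    A_ub = np.hstack([Y, -X])
    b_ub = np.zeros(n)
    A_eq = np.concatenate([np.zeros(s), X[o]])[None, :]
    b_eq = np.array([1.0])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=[(0, None)] * (s + m), method=options.backend)
    if not res.success:
        status = (SolverStatus.INFEASIBLE if res.status == 2
                  else SolverStatus.NUMERICAL_FAILURE)
        return EfficiencyResult(target_id, np.nan, np.full(n, np.nan), [],
                                status)
    theta_raw = float(-res.fun)
    return EfficiencyResult(target_id, _clip_theta(theta_raw, options),
                            np.full(n, np.nan), [], SolverStatus.OPTIMAL,
                            theta_raw=theta_raw)


def efficiency_scores(
    dmus: DMUSet, options: SolverOptions | None = None
) -> dict[str, float]:
    """One CCR score per DMU (one LP each); max over the set is 1."""
    options = options or SolverOptions()
    scores: dict[str, float] = {}
    for dmu_id in dmus.ids:
        res = solve_ccr(dmus, dmu_id, options)
        if res.solver_status is not SolverStatus.OPTIMAL:
            raise RuntimeError(
                f"CCR solve failed for DMU {dmu_id!r}: "
                f"{res.solver_status.value}"
            )
        scores[dmu_id] = res.theta
    return scores


class CCREfficiency:
    """Input-oriented CCR efficiency model over a set of DMUs.

    Parameters
    ----------
    dmus : DMUSet, or anything ``DMUSet.from_dataframe`` accepts.
    options : SolverOptions

    ``fit()`` solves one envelopment LP per DMU and returns a
    :class:`CCREfficiencyResults`.
    """

    def __init__(self, dmus: DMUSet | pd.DataFrame,
                 options: SolverOptions | None = None):
        if isinstance(dmus, pd.DataFrame):
            dmus = DMUSet.from_dataframe(dmus)
        self.dmus = dmus
        self.options = options or SolverOptions()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       options: SolverOptions | None = None):
        return cls(DMUSet.from_dataframe(frame), options)

    def fit(self) -> "CCREfficiencyResults":
        results = [solve_ccr(self.dmus, i, self.options)
                   for i in self.dmus.ids]
        for r in results:
            if r.solver_status is not SolverStatus.OPTIMAL:
                raise RuntimeError(
                    f"CCR solve failed for DMU {r.dmu_id!r}: "
                    f"{r.solver_status.value}"
                )
        return CCREfficiencyResults(self, results)


class CCREfficiencyResults:
    """Per-DMU efficiency scores, peer weights and reference sets."""

    def __init__(self, model: CCREfficiency,
                 results: Sequence[EfficiencyResult]):
        self.model = model
        self.results = list(results)
        self.scores = pd.Series({r.dmu_id: r.theta for r in self.results},
                                name="efficiency")

    @property
    def n_efficient(self) -> int:
        return int((self.scores >= 1.0).sum())

    def reference_sets(self) -> Mapping[str, list[str]]:
        return {r.dmu_id: r.reference_set for r in self.results}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dmu_id": [r.dmu_id for r in self.results],
            "efficiency": [r.theta for r in self.results],
            "n_peers": [len(r.reference_set) for r in self.results],
        })

    def summary(self) -> str:
        s = self.scores
        lines = [
            "Input-oriented CCR efficiency (constant returns to scale)",
            f"  DMUs: {len(s)}   inputs: {self.model.dmus.n_inputs}   "
            f"outputs: {self.model.dmus.n_outputs}",
            f"  efficient (theta = 1): {self.n_efficient}",
            f"  mean theta: {s.mean():.4f}   sd: {s.std(ddof=1):.4f}"
            if len(s) > 1 else f"  mean theta: {s.mean():.4f}",
            f"  min theta: {s.min():.4f}   median: {s.median():.4f}",
        ]
        return "\n".join(lines)
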