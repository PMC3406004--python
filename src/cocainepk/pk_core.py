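"""Two-compartment cocaine pharmacokinetics with Michaelis-Menten elimination.

The body is reduced to two well-stirred pools: plasma (effective volume
``V_p``, litres) and brain (``V_b``), exchanging cocaine free base across the
blood-brain barrier with first-order diffusion constants ``K_pb``
(plasma -> brain) and ``K_bp`` (brain -> plasma).  Cocaine is eliminated only
in plasma, by an enzyme (endogenous butyrylcholinesterase or an exogenous
cocaine hydrolase/esterase) following Michaelis-Menten kinetics with maximal
velocity ``V_max = k_cat * [E]`` and Michaelis constant ``K_M``.

With ``C1`` the plasma and ``C2`` the brain concentration (both in µM), the
model is

    dC1/dt = -V_max * C1 / (K_M + C1) - K_pb * C1 + K_bp * C2
    dC2/dt = (V_p / V_b) * (K_pb * C1 - K_bp * C2)

The ``V_p/V_b`` factor converts the exchanged *amount* into a brain
*concentration*; the exchange terms conserve total amount
``V_p*C1 + V_b*C2`` exactly when the enzymatic term is switched off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp

__all__ = [
    "COCAINE_MW",
    "REFERENCE_PK_PARAMS",
    "V_B_PLAUSIBLE_RANGE",
    "EnzymeKinetics",
    "PKParameters",
    "SimulationSpec",
    "TimeCourse",
    "IntegrationError",
    "rhs",
    "simulate",
    "mass_balance_residual",
]

#: Molecular weight of cocaine free base, g/mol.  Used only to convert an
#: administered dose in µg into an initial plasma concentration in µM.
COCAINE_MW = 303.35

#: Effective brain volume plausibility window, litres: from the striatum
#: alone (6.33 cm^3) up to the whole brain (1253.8 cm^3).
V_B_PLAUSIBLE_RANGE = (0.00633, 1.2538)


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid time."""

    def __init__(self, message: str, t_last: float | None = None):
        super().__init__(message)
        self.t_last = t_last


@dataclass(frozen=True)
class EnzymeKinetics:
    """Catalytic constants and plasma concentration of one enzyme.

    Parameters
    ----------
    name : str
        Label, e.g. ``"wtBChE"`` or ``"CocH3"``.
    k_cat : float
        Catalytic rate constant, min^-1.
    K_M : float
        Michaelis constant for cocaine, µM.
    E_conc : float
        Molar concentration of enzyme active sites in plasma, µM.
    """

    name: str
    k_cat: float
    K_M: float
    E_conc: float

    def __post_init__(self):
        if not self.k_cat > 0:
            raise ValueError(f"k_cat must be > 0, got {self.k_cat}")
        if not self.K_M > 0:
            raise ValueError(f"K_M must be > 0, got {self.K_M}")
        if self.E_conc < 0:
            raise ValueError(f"E_conc must be >= 0, got {self.E_conc}")

    @property
    def v_max(self) -> float:
        """Maximal elimination velocity V_max = k_cat * [E], µM/min."""
        return self.k_cat * self.E_conc

    def at_concentration(self, E_conc: float) -> "EnzymeKinetics":
        """Same enzyme at a different plasma concentration (µM)."""
        return replace(self, E_conc=E_conc)


@dataclass(frozen=True)
class PKParameters:
    """Transfer/volume parameters of the two-compartment model.

    All four must be strictly positive to be physically meaningful (and for
    the model to be structurally identifiable).
    """

    V_p: float  #: effective plasma volume, L
    V_b: float  #: effective brain volume, L
    K_pb: float  #: plasma -> brain diffusion constant, min^-1
    K_bp: float  #: brain -> plasma diffusion constant, min^-1

    def __post_init__(self):
        for name in ("V_p", "V_b", "K_pb", "K_bp"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def v_b_plausible(self) -> bool:
        """Whether V_b lies between the striatum and whole-brain volumes."""
        lo, hi = V_B_PLAUSIBLE_RANGE
        return lo <= self.V_b <= hi

    def as_array(self) -> np.ndarray:
        return np.array([self.V_b, self.V_p, self.K_pb, self.K_bp])


#: Calibrated parameter set obtained by fitting the model to human PET
#: time-activity curves of [11C]cocaine (striatum) and the matching plasma
#: series.  Shipped as reference metadata; all lookup-table and threshold
#: computations default to it.
REFERENCE_PK_PARAMS = PKParameters(V_p=11.89, V_b=0.3292, K_pb=0.01898, K_bp=0.01780)


@dataclass(frozen=True)
class SimulationSpec:
    """Scenario definition: initial condition, horizon, solver control.

    ``C1_0`` is the initial plasma cocaine concentration in µM (an
    instantaneous i.v. bolus; the brain starts empty).  Alternatively build
    the spec from an administered dose with :meth:`from_dose`.
    """

    C1_0: float
    t_end: float = 60.0
    dt: float | None = None  #: uniform output spacing (min); None -> geometric grid
    n_points: int = 2001  #: grid size when dt is None
    rtol: float = 1e-9
    atol: float = 1e-12

    def __post_init__(self):
        if self.C1_0 < 0:
            raise ValueError("C1_0 must be >= 0")
        if not self.t_end > 0:
            raise ValueError("t_end must be > 0")
        if not (self.rtol > 0 and self.atol > 0):
            raise ValueError("solver tolerances must be > 0")

    @classmethod
    def from_dose(
        cls, dose_ug: float, params: PKParameters, mw: float = COCAINE_MW, **kw
    ) -> "SimulationSpec":
        """Spec for an i.v. bolus of ``dose_ug`` µg: C1_0 = D / (MW * V_p)."""
        return cls(C1_0=dose_ug / (mw * params.V_p), **kw)

    def output_grid(self) -> np.ndarray:
        """Time grid starting at 0.

        With ``dt`` unset, a geometric grid is used so that sub-minute
        transients (high-activity enzymes collapse plasma in under a minute)
        and multi-hour tails are both resolved without a huge uniform grid.
        """
        if self.dt is not None:
            n = int(np.floor(self.t_end / self.dt + 1e-9)) + 1
            grid = np.arange(n) * self.dt
            if grid[-1] < self.t_end - 1e-12:
                grid = np.append(grid, self.t_end)
            return grid
        t0 = min(1e-3, self.t_end / 1e4)
        grid = np.geomspace(t0, self.t_end, self.n_points - 1)
        return np.concatenate([[0.0], grid])


@dataclass
class TimeCourse:
    """Paired plasma/brain concentration series on a common time grid.

    ``dense`` optionally holds the solver's dense-output interpolant, used by
    the metric extractors for peak/half-life refinement; it is not
    serialized.
    """

    t: np.ndarray  #: time, min, strictly increasing from 0
    C1: np.ndarray  #: plasma concentration, µM
    C2: np.ndarray  #: brain concentration, µM
    dense: object | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.C1 = np.asarray(self.C1, dtype=float)
        self.C2 = np.asarray(self.C2, dtype=float)
        if not (self.t.shape == self.C1.shape == self.C2.shape):
            raise ValueError("t, C1, C2 must have equal lengths")
        if self.t.size < 2 or self.t[0] != 0 or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing and start at 0")
        if np.any(self.C1 < 0) or np.any(self.C2 < 0):
            raise ValueError("concentrations must be nonnegative")

    def series(self, compartment: str) -> np.ndarray:
        if compartment == "plasma":
            return self.C1
        if compartment == "brain":
            return self.C2
        raise ValueError(f"unknown compartment {compartment!r}")

    def evaluate(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(C1, C2) at arbitrary times, via dense output when available."""
        t = np.asarray(t, dtype=float)
        if t.size == 0:
            return np.empty(0), np.empty(0)
        if self.dense is not None:
            y = np.clip(self.dense(t), 0.0, None)
            return y[0], y[1]
        return (
            np.interp(t, self.t, self.C1),
            np.interp(t, self.t, self.C2),
        )

    # -- serialization: 3-column delimited text, round-trippable -------------

    HEADER = "t_min,C1_uM,C2_uM"

    def to_csv(self, path) -> None:
        data = np.column_stack([self.t, self.C1, self.C2])
        np.savetxt(path, data, delimiter=",", header=self.HEADER, comments="",
                   fmt="%.10g")

    @classmethod
    def from_csv(cls, path) -> "TimeCourse":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(t=data[:, 0], C1=data[:, 1], C2=data[:, 2])


def rhs(
    C1: float, C2: float, params: PKParameters, enzyme: EnzymeKinetics
) -> tuple[float, float]:
    """Instantaneous derivatives (dC1/dt, dC2/dt) in µM/min.

    Raises
    ------
    ValueError
        If either concentration is negative.
    """
    if C1 < 0 or C2 < 0:
        raise ValueError("concentrations must be nonnegative")
    elim = enzyme.v_max * C1 / (enzyme.K_M + C1) if C1 > 0 else 0.0
    dC1 = -elim - params.K_pb * C1 + params.K_bp * C2
    dC2 = (params.V_p / params.V_b) * (params.K_pb * C1 - params.K_bp * C2)
    return dC1, dC2


def _rhs_vec(t, y, params: PKParameters, enzyme: EnzymeKinetics):
    c1, c2 = y
    elim = enzyme.v_max * c1 / (enzyme.K_M + c1)
    return (
        -elim - params.K_pb * c1 + params.K_bp * c2,
        (params.V_p / params.V_b) * (params.K_pb * c1 - params.K_bp * c2),
    )


def _jac(t, y, params: PKParameters, enzyme: EnzymeKinetics):
    c1 = y[0]
    km = enzyme.K_M
    delim = enzyme.v_max * km / (km + c1) ** 2
    r = params.V_p / params.V_b
    return [
        [-delim - params.K_pb, params.K_bp],
        [r * params.K_pb, -r * params.K_bp],
    ]


def simulate(
    spec: SimulationSpec, params: PKParameters, enzyme: EnzymeKinetics
) -> TimeCourse:
    """Integrate the model over ``[0, t_end]`` for an i.v. bolus.

    Uses a stiff-capable adaptive solver (LSODA with an analytic Jacobian)
    with dense output.  Small negative undershoots are clipped to zero; an
    undershoot below ``-1000 * atol`` triggers a warning.

    Raises
    ------
    IntegrationError
        If the solver does not reach ``t_end``.
    """
    grid = spec.output_grid()
    if spec.C1_0 == 0.0:
        z = np.zeros_like(grid)
        return TimeCourse(t=grid, C1=z, C2=z.copy())
    sol = solve_ivp(
        _rhs_vec,
        (0.0, spec.t_end),
        [spec.C1_0, 0.0],
        args=(params, enzyme),
        method="LSODA",
        jac=_jac,
        rtol=spec.rtol,
        atol=spec.atol,
        dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE solver failed: {sol.message}", t_last=float(sol.t[-1])
        )
    y = sol.sol(grid)
    if y.min() < -1e3 * spec.atol:
        warnings.warn(
            f"solver undershoot {y.min():.3e} below -1000*atol; clipping to 0",
            RuntimeWarning,
        )
    y = np.clip(y, 0.0, None)
    return TimeCourse(t=grid, C1=y[0], C2=y[1], dense=sol.sol)


def mass_balance_residual(
    tc: TimeCourse, params: PKParameters, enzyme: EnzymeKinetics
) -> np.ndarray:
    """Amount-conservation residual along a trajectory, in µM-equivalents.

    The total amount in both compartments plus the cumulative amount
    eliminated must equal the initial amount:

        V_p*C1(t) + V_b*C2(t) + V_p * int_0^t V_max*C1/(K_M+C1) ds
            - V_p*C1(0)  ~  0

    The eliminated amount is quadratured with the trapezoidal rule on the
    stored grid, so the residual reflects both solver and quadrature error.
    Returned in µM-equivalents referred to V_p (i.e. divided by V_p).
    """
    elim_rate = enzyme.v_max * tc.C1 / (enzyme.K_M + tc.C1)
    eliminated = cumulative_trapezoid(elim_rate, tc.t, initial=0.0)
    total = tc.C1 + (params.V_b / params.V_p) * tc.C2 + eliminated
    return total - tc.C1[0]
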