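"""Kinetic models for regional PET time-activity curves.

Model classes follow the usual estimator pattern: construct a model from
data, call :meth:`fit`, get back a results object carrying estimates,
standard errors, relative SEs, WRSS and AIC.

Models
------
``OneTissueModel``
    One-tissue compartment model fitted against a plasma input:
    dC_T/dt = K1*Cp - k2*C_T. The invasive baseline.
``SRTM``
    Simplified reference tissue model (Lammertsma-Hume operational
    equation): C_T = R1*C_R + (k2 - R1*k2a) * C_R (x) exp(-k2a t), free
    parameters (R1, k2, k2a); BP_ND = k2/k2a - 1, k2' = k2/R1 derived.
``SRTM2``
    SRTM with the reference efflux rate k2' fixed (typically to a
    population mean): C_T = R1*C_R + R1*(k2' - k2a) * C_R (x) exp(-k2a t),
    free (R1, k2a); BP_ND = R1*k2'/k2a - 1.
``SRTMC``
    Coupled SRTM: all target regions of one scan fitted jointly with a
    single shared k2'; per-region (R1_j, k2a_j) plus the one shared k2'.

All fits are bounded weighted nonlinear least squares with analytic
model curves, multi-start initialisation, and SEs from the Gauss-Newton
covariance sigma^2 (J'WJ)^-1 with sigma^2 = WRSS/(n-p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .aif import FengInput
from .frames import FrameSchedule, TimeActivityCurve
from .kinetics import RefGrid, frame_average, one_tissue_curve

__all__ = [
    "F18_HALF_LIFE_MIN",
    "CS_K2PRIME",
    "CEREBELLUM_K2PRIME",
    "compute_aic",
    "population_k2prime",
    "compute_weights",
    "KineticFitResult",
    "SRTMCResults",
    "OneTissueModel",
    "SRTM",
    "SRTM2",
    "SRTMC",
    "fit_1tc",
    "fit_srtm",
    "fit_srtm2",
    "fit_srtmc",
]

F18_HALF_LIFE_MIN = 109.77

#: Population reference-region clearance defaults (1/min): mean one-tissue
#: k2 of the reference regions reported for this tracer — centrum
#: semiovale and cerebellum respectively.
CS_K2PRIME = 0.059
CEREBELLUM_K2PRIME = 0.052

_XTOL = 1e-10
_FTOL = 1e-8


def compute_aic(wrss: float, n: int, p: int) -> float:
    """Least-squares Akaike information criterion, n*ln(WRSS/n) + 2p."""
    if wrss <= 0:
        raise ValueError("WRSS must be positive (a perfect fit has no defined AIC)")
    if p < 1 or n <= p:
        raise ValueError(f"need n > p >= 1 (got n={n}, p={p})")
    return n * math.log(wrss / n) + 2 * p


def population_k2prime(k2_values) -> float:
    """Population k2': arithmetic mean of reference-region 1TC k2 estimates."""
    k2_values = np.asarray(k2_values, dtype=float)
    if k2_values.size == 0:
        raise ValueError("no reference-region k2 estimates supplied")
    return float(np.mean(k2_values))


def compute_weights(
    schedule: FrameSchedule,
    kind: str | np.ndarray = "duration",
    half_life: float = F18_HALF_LIFE_MIN,
) -> np.ndarray:
    """Frame weights for the WLS objective, normalised to mean 1.

    ``uniform``: equal; ``duration``: frame length (default — longer
    frames collect more counts); ``duration-decay``: frame length
    damped by isotope decay at the frame mid-time.
    """
    if isinstance(kind, np.ndarray) or isinstance(kind, (list, tuple)):
        w = np.asarray(kind, dtype=float)
        if w.shape != schedule.start.shape or np.any(w < 0):
            raise ValueError("weight array must be non-negative, one entry per frame")
    elif kind == "uniform":
        w = np.ones(schedule.n_frames)
    elif kind == "duration":
        w = schedule.duration.copy()
    elif kind == "duration-decay":
        lam = math.log(2.0) / half_life
        w = schedule.duration * np.exp(-lam * schedule.mid)
    else:
        raise ValueError(f"unknown weighting {kind!r}")
    return w / w.mean()


# ---------------------------------------------------------------------------
# results containers


@dataclass
class KineticFitResult:
    """Fit of one kinetic model to one regional TAC.

    ``params`` holds free and derived parameters; ``bse`` their standard
    errors (delta method for derived ones); ``rse`` relative SEs in
    percent.
    """

    model: str
    region_id: str
    params: dict[str, float]
    bse: dict[str, float]
    free_names: list[str]
    wrss: float
    n_frames: int
    n_free: int
    converged: bool
    t_end: float
    fittedvalues: np.ndarray = field(repr=False)
    observed: np.ndarray = field(repr=False)
    schedule: FrameSchedule = field(repr=False)
    k2prime_fixed: float | None = None
    cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return compute_aic(self.wrss, self.n_frames, self.n_free)

    @property
    def rse(self) -> dict[str, float]:
        """Relative SE per parameter, 100*SE/|estimate| (%)."""
        out = {}
        for k, se in self.bse.items():
            est = self.params[k]
            out[k] = float("inf") if est == 0 else 100.0 * se / abs(est)
        return out

    @property
    def residuals(self) -> np.ndarray:
        return self.observed - self.fittedvalues

    def summary(self) -> str:
        lines = [
            f"{self.model} fit — region {self.region_id}"
            + ("" if self.k2prime_fixed is None else f"  (k2' fixed at {self.k2prime_fixed:.4g}/min)"),
            f"  frames: {self.n_frames}   t_end: {self.t_end:g} min   "
            f"free params: {self.n_free}   converged: {self.converged}",
            f"  WRSS: {self.wrss:.6g}   AIC: {self.aic:.4g}",
            f"  {'param':<8}{'estimate':>12}{'SE':>12}{'rSE %':>10}",
        ]
        rse = self.rse
        for k, v in self.params.items():
            se = self.bse.get(k, float("nan"))
            r = rse.get(k, float("nan"))
            lines.append(f"  {k:<8}{v:>12.5g}{se:>12.3g}{r:>10.2f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot observed frame values and the fitted curve vs mid-times."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.schedule.mid
        ax.plot(t, self.observed, "o", label=f"{self.region_id} (observed)", mfc="none")
        ax.plot(t, self.fittedvalues, "-", label=f"{self.model} fit")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("activity (kBq/mL)")
        ax.legend()
        return ax


@dataclass
class SRTMCResults:
    """Joint coupled-fit results: one shared k2' plus per-region results."""

    k2prime: float
    k2prime_se: float
    results: list[KineticFitResult]
    total_wrss: float
    converged: bool

    @property
    def k2prime_rse(self) -> float:
        return 100.0 * self.k2prime_se / abs(self.k2prime)

    def __iter__(self):
        return iter(self.results)

    def summary(self) -> str:
        head = (
            f"SRTMC joint fit — {len(self.results)} regions, shared k2' = "
            f"{self.k2prime:.5g} ± {self.k2prime_se:.2g}/min "
            f"(rSE {self.k2prime_rse:.2f}%), total WRSS {self.total_wrss:.6g}, "
            f"converged: {self.converged}"
        )
        return "\n\n".join([head] + [r.summary() for r in self.results])


# ---------------------------------------------------------------------------
# shared NLLS machinery


def _near_bounds(x: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> bool:
    span = ub - lb
    return bool(np.any((x - lb) < 1e-6 * span) or np.any((ub - x) < 1e-9 * span))


def _run_nlls(residual, jac, starts, lb, ub):
    """Multi-start bounded least squares; returns (best solution, converged)."""
    best = None
    for x0 in starts:
        try:
            res = least_squares(
                residual, np.asarray(x0, dtype=float), jac=jac,
                bounds=(lb, ub), method="trf", xtol=_XTOL, ftol=_FTOL, gtol=1e-10,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("optimizer failed from every start")
    converged = bool(best.success) and np.isfinite(best.cost) and not _near_bounds(
        best.x, np.asarray(lb, float), np.asarray(ub, float)
    )
    return best, converged


def _covariance(res, wrss: float, n: int, p: int) -> np.ndarray:
    """Gauss-Newton covariance sigma^2 (J'J)^-1 from weighted residual Jacobian."""
    J = res.jac
    if n <= p:
        return np.full((p, p), np.nan)
    sigma2 = wrss / (n - p)
    try:
        cov = sigma2 * np.linalg.pinv(J.T @ J)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return cov


def _delta_se(cov: np.ndarray, grad: np.ndarray) -> float:
    v = float(grad @ cov @ grad)
    return math.sqrt(v) if v >= 0 else float("nan")


# ---------------------------------------------------------------------------
# models


class _TacModelBase:
    """Common data handling: one target TAC, weights, schedule."""

    def __init__(self, tac: TimeActivityCurve, schedule: FrameSchedule | None,
                 weights) -> None:
        self.tac = tac
        self.schedule = schedule or tac.schedule
        if tac.values.size != self.schedule.n_frames:
            raise ValueError("TAC and schedule disagree on frame count")
        self.weights = compute_weights(self.schedule, weights)
        self._sw = np.sqrt(self.weights)
        self.y = tac.values

    def _wrss(self, fitted: np.ndarray) -> float:
        return float(np.sum(self.weights * (self.y - fitted) ** 2))


class OneTissueModel(_TacModelBase):
    """One-tissue compartment model fitted against the plasma input.

    ``input_function`` is either a :class:`~refkin.aif.FengInput` (exact
    analytic tissue response) or a sampled input as a
    :class:`TimeActivityCurve` (piecewise-linear grid convolution).
    """

    #: bounds for (K1 [mL/cm^3/min], k2 [1/min])
    BOUNDS = (np.array([1e-4, 1e-4]), np.array([2.0, 1.0]))
    STARTS = [(0.1, 0.03), (0.3, 0.06), (0.6, 0.12)]

    def __init__(self, tac, input_function, schedule=None, weights="duration"):
        super().__init__(tac, schedule, weights)
        self.input_function = input_function
        if isinstance(input_function, FengInput):
            self._grid = None
        elif isinstance(input_function, TimeActivityCurve):
            self._grid = RefGrid(input_function)
            if self._grid.schedule.t_end < self.schedule.t_end - 1e-9:
                raise ValueError("sampled input does not cover the scan duration")
            # frame-average indices for THIS model's schedule on the input grid
            self._i0 = np.rint(self.schedule.start / self._grid.dt).astype(int)
            self._i1 = np.rint(self.schedule.end / self._grid.dt).astype(int)
        else:
            raise TypeError("input_function must be FengInput or TimeActivityCurve")

    def predict(self, K1: float, k2: float) -> np.ndarray:
        if self._grid is None:
            return frame_average(
                lambda t: one_tissue_curve(self.input_function, K1, k2, t),
                self.schedule,
            )
        conv = self._grid.conv_grid(self._grid.r, k2)
        cum = np.concatenate(
            [[0.0], np.cumsum((conv[1:] + conv[:-1]) / 2.0 * self._grid.dt)]
        )
        return K1 * (cum[self._i1] - cum[self._i0]) / self.schedule.duration

    def fit(self) -> KineticFitResult:
        def residual(p):
            return self._sw * (self.y - self.predict(p[0], p[1]))

        lb, ub = self.BOUNDS
        best, converged = _run_nlls(residual, "2-point", self.STARTS, lb, ub)
        K1, k2 = best.x
        fitted = self.predict(K1, k2)
        wrss = self._wrss(fitted)
        n, p = self.schedule.n_frames, 2
        cov = _covariance(best, wrss, n, p)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        dv = K1 / k2
        dv_se = _delta_se(cov, np.array([1.0 / k2, -K1 / k2**2]))
        return KineticFitResult(
            model="1TC", region_id=self.tac.region_id,
            params={"K1": K1, "k2": k2, "DV": dv},
            bse={"K1": se[0], "k2": se[1], "DV": dv_se},
            free_names=["K1", "k2"], wrss=wrss, n_frames=n, n_free=p,
            converged=converged, t_end=self.schedule.t_end,
            fittedvalues=fitted, observed=self.y, schedule=self.schedule, cov=cov,
        )


class _RefTissueBase(_TacModelBase):
    def __init__(self, tac, ref: TimeActivityCurve, schedule=None, weights="duration"):
        super().__init__(tac, schedule, weights)
        if ref.values.size != self.schedule.n_frames:
            raise ValueError("reference TAC and schedule disagree on frame count")
        self.ref = ref
        self.grid = RefGrid(ref, self.schedule)
        self.refF = self.grid.ref_frame


class SRTM(_RefTissueBase):
    """Simplified reference tissue model, free (R1, k2, k2a)."""

    BOUNDS = (np.array([0.01, 1e-4, 1e-4]), np.array([5.0, 1.0, 1.0]))
    #: BP_ND starting points for the multi-start
    BP_STARTS = (0.5, 1.5, 3.0)

    def predict(self, R1, k2, k2a):
        return R1 * self.refF + (k2 - R1 * k2a) * self.grid.conv(k2a)

    def fit(self) -> KineticFitResult:
        sw, y = self._sw, self.y

        def residual(p):
            R1, k2, k2a = p
            return sw * (y - (R1 * self.refF + (k2 - R1 * k2a) * self.grid.conv(k2a)))

        def jac(p):
            R1, k2, k2a = p
            B, dB = self.grid.conv_and_deriv(k2a)
            J = np.empty((y.size, 3))
            J[:, 0] = self.refF - k2a * B
            J[:, 1] = B
            J[:, 2] = -R1 * B + (k2 - R1 * k2a) * dB
            return -sw[:, None] * J

        starts = [(1.0, 0.06, 0.06 / (1.0 + bp)) for bp in self.BP_STARTS]
        lb, ub = self.BOUNDS
        best, converged = _run_nlls(residual, jac, starts, lb, ub)
        R1, k2, k2a = best.x
        fitted = self.predict(R1, k2, k2a)
        wrss = self._wrss(fitted)
        n, p = self.schedule.n_frames, 3
        cov = _covariance(best, wrss, n, p)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        bp = k2 / k2a - 1.0
        bp_se = _delta_se(cov, np.array([0.0, 1.0 / k2a, -k2 / k2a**2]))
        k2p = k2 / R1
        k2p_se = _delta_se(cov, np.array([-k2 / R1**2, 1.0 / R1, 0.0]))
        return KineticFitResult(
            model="SRTM", region_id=self.tac.region_id,
            params={"R1": R1, "k2": k2, "k2a": k2a, "BP_ND": bp, "k2prime": k2p},
            bse={"R1": se[0], "k2": se[1], "k2a": se[2], "BP_ND": bp_se, "k2prime": k2p_se},
            free_names=["R1", "k2", "k2a"], wrss=wrss, n_frames=n, n_free=p,
            converged=converged, t_end=self.schedule.t_end,
            fittedvalues=fitted, observed=y, schedule=self.schedule, cov=cov,
        )


class SRTM2(_RefTissueBase):
    """SRTM with fixed reference clearance k2'; free (R1, k2a)."""

    BOUNDS = (np.array([0.01, 1e-4]), np.array([5.0, 1.0]))
    BP_STARTS = (0.5, 1.5, 3.0)

    def __init__(self, tac, ref, k2prime: float, schedule=None, weights="duration"):
        if not k2prime > 0:
            raise ValueError("k2prime must be positive")
        super().__init__(tac, ref, schedule, weights)
        self.k2prime = float(k2prime)

    def predict(self, R1, k2a):
        return R1 * self.refF + R1 * (self.k2prime - k2a) * self.grid.conv(k2a)

    def fit(self) -> KineticFitResult:
        sw, y, k2p = self._sw, self.y, self.k2prime

        def residual(p):
            R1, k2a = p
            return sw * (y - (R1 * self.refF + R1 * (k2p - k2a) * self.grid.conv(k2a)))

        def jac(p):
            R1, k2a = p
            B, dB = self.grid.conv_and_deriv(k2a)
            J = np.empty((y.size, 2))
            J[:, 0] = self.refF + (k2p - k2a) * B
            J[:, 1] = R1 * (-B + (k2p - k2a) * dB)
            return -sw[:, None] * J

        starts = [(1.0, k2p / (1.0 + bp)) for bp in self.BP_STARTS]
        lb, ub = self.BOUNDS
        best, converged = _run_nlls(residual, jac, starts, lb, ub)
        R1, k2a = best.x
        fitted = self.predict(R1, k2a)
        wrss = self._wrss(fitted)
        n, p = self.schedule.n_frames, 2
        cov = _covariance(best, wrss, n, p)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        params, bse = _srtm2_derived(R1, k2a, k2p, cov, se)
        return KineticFitResult(
            model="SRTM2", region_id=self.tac.region_id,
            params=params, bse=bse, free_names=["R1", "k2a"],
            wrss=wrss, n_frames=n, n_free=p, converged=converged,
            t_end=self.schedule.t_end, fittedvalues=fitted, observed=y,
            schedule=self.schedule, k2prime_fixed=k2p, cov=cov,
        )


def _srtm2_derived(R1, k2a, k2p, cov2, se2):
    """Derived params/SEs for the fixed-k2' parameterisation (R1, k2a)."""
    bp = R1 * k2p / k2a - 1.0
    bp_se = _delta_se(cov2, np.array([k2p / k2a, -R1 * k2p / k2a**2]))
    k2 = R1 * k2p
    k2_se = k2p * se2[0]
    return (
        {"R1": R1, "k2a": k2a, "BP_ND": bp, "k2": k2},
        {"R1": se2[0], "k2a": se2[1], "BP_ND": bp_se, "k2": k2_se},
    )


class SRTMC(_TacModelBase):
    """Coupled SRTM: joint fit of all target regions sharing one k2'.

    Parameters are ``[k2', R1_1, k2a_1, ..., R1_J, k2a_J]``; the joint
    objective is the sum of the per-region weighted residual sums. At a
    fixed k2' the problem decouples into independent SRTM2 fits, which
    is used to initialise the joint solve. Per-region AICs count the
    shared k2' as a third parameter (conservative, comparable to SRTM).
    """

    K2P_BOUNDS = (1e-3, 0.5)
    K2P_STARTS = (0.04, 0.06, 0.09)

    def __init__(self, tacs: list[TimeActivityCurve], ref: TimeActivityCurve,
                 schedule: FrameSchedule | None = None, weights="duration"):
        if len(tacs) < 2:
            raise ValueError(
                "SRTMC requires at least two target regions; use SRTM or SRTM2 "
                "for a single region"
            )
        schedule = schedule or ref.schedule
        self.schedule = schedule
        self.tacs = tacs
        self.ref = ref
        self.weights = compute_weights(schedule, weights)
        self._sw = np.sqrt(self.weights)
        self.grid = RefGrid(ref, schedule)
        self.refF = self.grid.ref_frame
        for t in tacs:
            if t.values.size != schedule.n_frames:
                raise ValueError(f"region {t.region_id!r}: TAC/schedule frame mismatch")
        self.Y = np.stack([t.values for t in tacs])  # (J, n)

    # parameter vector layout: [k2p, R1_0, k2a_0, R1_1, k2a_1, ...]
    def _unpack(self, p):
        return p[0], p[1::2][: len(self.tacs)], p[2::2][: len(self.tacs)]

    def _predict_all(self, k2p, R1s, k2as):
        out = np.empty_like(self.Y)
        for j, (R1, k2a) in enumerate(zip(R1s, k2as)):
            out[j] = R1 * self.refF + R1 * (k2p - k2a) * self.grid.conv(k2a)
        return out

    def fit(self) -> SRTMCResults:
        J_regions = len(self.tacs)
        n = self.schedule.n_frames
        sw = self._sw

        def residual(p):
            k2p, R1s, k2as = self._unpack(p)
            pred = self._predict_all(k2p, R1s, k2as)
            return (sw[None, :] * (self.Y - pred)).ravel()

        def jac(p):
            k2p, R1s, k2as = self._unpack(p)
            Jm = np.zeros((J_regions * n, p.size))
            for j, (R1, k2a) in enumerate(zip(R1s, k2as)):
                B, dB = self.grid.conv_and_deriv(k2a)
                rows = slice(j * n, (j + 1) * n)
                Jm[rows, 0] = R1 * B
                Jm[rows, 1 + 2 * j] = self.refF + (k2p - k2a) * B
                Jm[rows, 2 + 2 * j] = R1 * (-B + (k2p - k2a) * dB)
                Jm[rows, :] *= -sw[:, None]
            return Jm

        # initialise from decoupled SRTM2 prefits at a few candidate k2'
        starts = []
        for k2p0 in self.K2P_STARTS:
            x0 = [k2p0]
            for t in self.tacs:
                r = SRTM2(t, self.ref, k2p0, self.schedule, self.weights).fit()
                x0 += [r.params["R1"], r.params["k2a"]]
            starts.append(x0)

        lb = np.concatenate([[self.K2P_BOUNDS[0]], np.tile([0.01, 1e-4], J_regions)])
        ub = np.concatenate([[self.K2P_BOUNDS[1]], np.tile([5.0, 1.0], J_regions)])
        best, converged = _run_nlls(residual, jac, starts, lb, ub)

        k2p, R1s, k2as = self._unpack(best.x)
        pred = self._predict_all(k2p, R1s, k2as)
        per_wrss = np.sum(self.weights[None, :] * (self.Y - pred) ** 2, axis=1)
        total_wrss = float(per_wrss.sum())
        P = best.x.size
        N = J_regions * n
        cov = _covariance(best, total_wrss, N, P)
        results = []
        for j, t in enumerate(self.tacs):
            R1, k2a = R1s[j], k2as[j]
            iR, iK = 1 + 2 * j, 2 + 2 * j
            sub = cov[np.ix_([0, iR, iK], [0, iR, iK])]  # (k2p, R1, k2a)
            se_R1 = math.sqrt(max(cov[iR, iR], 0.0))
            se_k2a = math.sqrt(max(cov[iK, iK], 0.0))
            bp = R1 * k2p / k2a - 1.0
            bp_se = _delta_se(sub, np.array([R1 / k2a, k2p / k2a, -R1 * k2p / k2a**2]))
            k2 = R1 * k2p
            k2_se = _delta_se(sub, np.array([R1, k2p, 0.0]))
            results.append(KineticFitResult(
                model="SRTMC", region_id=t.region_id,
                params={"R1": R1, "k2a": k2a, "BP_ND": bp, "k2": k2},
                bse={"R1": se_R1, "k2a": se_k2a, "BP_ND": bp_se, "k2": k2_se},
                free_names=["R1", "k2a"], wrss=float(per_wrss[j]),
                n_frames=n, n_free=3,  # shared k2' counted per region
                converged=converged, t_end=self.schedule.t_end,
                fittedvalues=pred[j], observed=self.Y[j], schedule=self.schedule,
                k2prime_fixed=None, cov=sub,
            ))
        k2p_se = math.sqrt(max(cov[0, 0], 0.0))
        return SRTMCResults(
            k2prime=float(k2p), k2prime_se=k2p_se, results=results,
            total_wrss=total_wrss, converged=converged,
        )


# ---------------------------------------------------------------------------
# functional wrappers


def fit_1tc(tac, input_function, schedule=None, weights="duration") -> KineticFitResult:
    return OneTissueModel(tac, input_function, schedule, weights).fit()


def fit_srtm(tac, ref, schedule=None, weights="duration") -> KineticFitResult:
    return SRTM(tac, ref, schedule, weights).fit()


def fit_srtm2(tac, ref, k2prime, schedule=None, weights="duration") -> KineticFitResult:
    return SRTM2(tac, ref, k2prime, schedule, weights).fit()


def fit_srtmc(tacs, ref, schedule=None, weights="duration") -> SRTMCResults:
    return SRTMC(tacs, ref, schedule, weights).fit()
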