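"""Bifurcation analysis: continuation, fold/Hopf/LPC detection, Q10 scans.

Two complementary views of how the cooled model's discharge activity
reorganises as the intrinsic-excitability factor ``Q10,int`` varies:

* a *stochastic scan*: seeded simulations over a ``Q10,int`` grid with
  forward/backward sweeps that inherit the final state, exposing
  bistability through hysteresis;
* *deterministic continuation* of the noiseless model (input fixed at its
  mean): pseudo-arclength continuation of equilibria with eigenvalue
  monitoring, saddle-node (fold) and Hopf detection refined by bisection,
  and single-shooting continuation of the periodic orbits born at the
  Hopf point, whose fold in the parameter is the limit point of cycles
  (LPC).

The continuation engine is generic over a vector field ``f(x, mu)`` so
the same code that handles the 10-dimensional neural mass model is
exercised on normal-form toys in the test-suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from . import _kernels
from .model_core import ModelParameters, TemperatureSpec
from .simulator import SimulationConfig, TimeSeries, simulate, BlowUpError
from .features import detect_discharges, effective_magnitude

__all__ = ["EquilibriumBranch", "CycleBranch", "BifurcationPoint",
           "ScanResult", "newton_solve", "find_equilibrium",
           "make_model_field", "make_model_flow", "continue_equilibria",
           "detect_folds", "detect_hopf", "continue_limit_cycles",
           "bracket_lpc_by_sweep", "stochastic_scan", "classify_scan",
           "termination_sweep", "termination_point"]


# ---------------------------------------------------------------------------
# basic numerics

def _fd_jacobian(fun, x, rel: float = 1e-6):
    """Central finite-difference Jacobian of ``fun`` at ``x``."""
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(fun(x))
    J = np.empty((f0.size, x.size))
    for j in range(x.size):
        h = rel * max(1.0, abs(x[j]))
        xp = x.copy()
        xm = x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (np.asarray(fun(xp)) - np.asarray(fun(xm))) / (2.0 * h)
    return J


def newton_solve(fun, x0, tol: float = 1e-10, max_iter: int = 100,
                 jac=None):
    """Damped Newton iteration for ``fun(x) = 0``; returns the root.

    Steps are halved until the residual norm decreases (saturating
    nonlinearities make the full step overshoot from poor guesses).
    Raises ``RuntimeError`` on non-convergence within ``max_iter``.
    """
    x = np.asarray(x0, dtype=float).copy()
    r = np.asarray(fun(x))
    nr = np.max(np.abs(r))
    for _ in range(max_iter):
        if nr < tol:
            return x
        J = _fd_jacobian(fun, x) if jac is None else jac(x)
        try:
            dx = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            dx = np.linalg.lstsq(J, -r, rcond=None)[0]
        step = 1.0
        while step > 1e-6:
            x_try = x + step * dx
            r_try = np.asarray(fun(x_try))
            nr_try = np.max(np.abs(r_try))
            if nr_try < nr or nr_try < tol:
                x, r, nr = x_try, r_try, nr_try
                break
            step *= 0.5
        else:
            break
    if nr < tol:
        return x
    raise RuntimeError(f"Newton did not converge (residual {nr:.3g})")


# ---------------------------------------------------------------------------
# model field / flow wrappers

def make_model_field(params: ModelParameters, temp_template: TemperatureSpec,
                     parameter: str = "q_int"):
    """Vector field ``f(x, mu)`` of the noiseless model with ``mu`` mapped
    onto one TemperatureSpec attribute (default the intrinsic Q10)."""
    cache: dict = {}

    def coeffs(mu: float):
        if mu not in cache:
            if len(cache) > 512:
                cache.clear()
            temp = temp_template.replace(**{parameter: float(mu)})
            cache[mu] = _kernels.pack_coeffs(params, temp)
        return cache[mu]

    p_mean = params.input_mean

    def f(x, mu):
        return _kernels.drift10(np.asarray(x, dtype=float), p_mean,
                                *coeffs(float(mu)))

    f.coeffs = coeffs
    return f


def make_model_flow(params: ModelParameters, temp_template: TemperatureSpec,
                    parameter: str = "q_int", dt: float = 1e-5):
    """Flow map ``phi(x, T, mu)`` via fixed-step RK4 (step <= ``dt``)."""
    f = make_model_field(params, temp_template, parameter)
    p_mean = params.input_mean

    def flow(x, T, mu):
        n = max(1, int(np.ceil(T / dt)))
        return _kernels.rk4_flow(np.asarray(x, dtype=float), float(T), n,
                                 p_mean, *f.coeffs(float(mu)))

    return flow


def generic_flow(f, rtol: float = 1e-10, atol: float = 1e-12):
    """Adaptive flow map for an arbitrary field (used for toy systems)."""

    def flow(x, T, mu):
        sol = solve_ivp(lambda t, s: f(s, mu), (0.0, T), np.asarray(x, float),
                        rtol=rtol, atol=atol, dense_output=False)
        return sol.y[:, -1]

    return flow


def _reduced_equilibria(params: ModelParameters, temp: TemperatureSpec,
                        y0_range=(-0.5, 1.0), n_scan: int = 4000):
    """All equilibria via the scalar pyramidal fixed-point equation.

    At equilibrium every PSP block sits at ``A*u/g``, so the full state is
    a function of the pyramidal output PSP ``y0`` alone; roots of the
    scalar residual enumerate the equilibria (full states returned in
    ascending ``y0`` order).
    """
    from scipy.optimize import brentq

    A, g, C, e0, v_th, s_th, f_int = _kernels.pack_coeffs(params, temp)

    def S(v):
        return 2 * e0 / (1 + np.exp(np.clip((v_th - f_int * v) / s_th,
                                            -700, 700)))

    def assemble(y0):
        y1 = A[1] / g[1] * (params.input_mean + C[1] * S(C[0] * y0))
        y2 = A[2] / g[2] * C[4] * S(C[2] * y0)
        y4 = A[2] / g[2] * S(C[2] * y0)
        y3 = A[3] / g[3] * C[5] * S(C[3] * y0 - C[6] * y4)
        return np.array([y0, y1, y2, y3, y4, 0, 0, 0, 0, 0])

    def residual(y0):
        x = assemble(y0)
        return A[0] / g[0] * S(x[1] - x[2] - x[3]) - y0

    ys = np.linspace(*y0_range, n_scan)
    r = np.array([residual(y) for y in ys])
    roots = []
    sign = np.sign(r)
    for i in np.flatnonzero(np.diff(sign) != 0):
        roots.append(brentq(residual, ys[i], ys[i + 1], xtol=1e-14))
    return [assemble(y) for y in roots]


def find_equilibrium(params: ModelParameters, temp: TemperatureSpec,
                     guess=None, tol: float = 1e-10) -> np.ndarray:
    """Newton solve of the noiseless model's equilibrium (input at mean).

    Without a guess, the scalar pyramidal fixed-point reduction supplies
    the starting point (the equilibrium of smallest pyramidal PSP — the
    baseline branch — when several coexist).
    """
    f = make_model_field(params, temp)
    if guess is None:
        eqs = _reduced_equilibria(params, temp)
        if not eqs:
            raise RuntimeError("no equilibrium found in the scan range")
        x0 = eqs[0]
    else:
        x0 = np.asarray(guess, dtype=float)
    return newton_solve(lambda x: f(x, getattr(temp, "q_int")), x0, tol=tol)


# ---------------------------------------------------------------------------
# equilibrium continuation

@dataclass
class BifurcationPoint:
    """A classified bifurcation: fold, hopf or lpc."""

    kind: str
    mu: float
    state: np.ndarray
    info: dict = field(default_factory=dict)


@dataclass
class EquilibriumBranch:
    """Ordered equilibrium points with eigenvalue data along a branch."""

    mus: np.ndarray
    states: np.ndarray          # (n_points, n)
    eigvals: np.ndarray         # (n_points, n) complex
    tangents: np.ndarray        # (n_points, n+1) unit tangents in (x, mu)
    f: object                   # the vector field f(x, mu)
    complete: bool = True

    @property
    def stable(self) -> np.ndarray:
        return np.all(self.eigvals.real < 0, axis=1)

    def __len__(self) -> int:
        return self.mus.size


def _eig(f, x, mu):
    J = _fd_jacobian(lambda s: f(s, mu), x)
    return np.linalg.eigvals(J)


def continue_equilibria(f, x0, mu0: float, mu_range: tuple,
                        ds: float = 0.02, ds_min: float = 1e-8,
                        ds_max: float = 0.05, max_points: int = 3000,
                        direction: float = 1.0,
                        newton_tol: float = 1e-10) -> EquilibriumBranch:
    """Pseudo-arclength continuation of ``f(x, mu) = 0``.

    Starts from a converged equilibrium at ``mu0`` and traverses folds;
    records the drift-Jacobian eigenvalues at every accepted point.  Stops
    when ``mu`` leaves ``mu_range``, ``max_points`` is reached, or the
    step collapses below ``ds_min`` (partial branch, ``complete=False``).
    """
    x0 = newton_solve(lambda x: f(x, mu0), x0, tol=newton_tol)
    n = x0.size
    u = np.concatenate([x0, [mu0]])

    # initial tangent: dx/dmu from J_x dx = -J_mu, oriented by `direction`
    Jx = _fd_jacobian(lambda s: f(s, mu0), x0)
    Jmu = _fd_jacobian(lambda m: f(x0, m[0]), np.array([mu0]))[:, 0]
    try:
        dxdmu = np.linalg.solve(Jx, -Jmu)
    except np.linalg.LinAlgError:
        dxdmu = np.linalg.lstsq(Jx, -Jmu, rcond=None)[0]
    t = np.concatenate([dxdmu, [1.0]])
    t /= np.linalg.norm(t)
    if np.sign(t[-1]) != np.sign(direction):
        t = -t

    mus = [mu0]
    states = [x0]
    eigs = [_eig(f, x0, mu0)]
    tangents = [t]
    complete = True
    lo, hi = min(mu_range), max(mu_range)

    while len(mus) < max_points:
        accepted = False
        while ds >= ds_min:
            u_pred = u + ds * t

            def ext(w):
                return np.concatenate([f(w[:n], w[n]),
                                       [t @ (w - u_pred)]])

            try:
                u_new = newton_solve(ext, u_pred, tol=newton_tol, max_iter=12)
                accepted = True
                break
            except RuntimeError:
                ds *= 0.5
        if not accepted:
            complete = False
            break
        t_new = u_new - u
        norm = np.linalg.norm(t_new)
        if norm == 0:
            complete = False
            break
        t_new /= norm
        u = u_new
        t = t_new
        mus.append(u[n])
        states.append(u[:n].copy())
        eigs.append(_eig(f, u[:n], u[n]))
        tangents.append(t.copy())
        ds = min(ds * 1.4, ds_max)
        if not (lo - 1e-9 <= u[n] <= hi + 1e-9):
            break

    return EquilibriumBranch(np.array(mus), np.array(states),
                             np.array(eigs), np.array(tangents), f, complete)


def _solve_pinned(f, n: int, k: int, xi: float, u_guess,
                  tol: float = 1e-9):
    """Solve ``f(x, mu) = 0`` with state coordinate ``k`` pinned at ``xi``.

    Unknowns are the remaining state coordinates and ``mu``; this local
    parametrization stays regular through a fold.
    """
    free = [j for j in range(n) if j != k]

    def res(w):
        x = np.empty(n)
        x[free] = w[:-1]
        x[k] = xi
        return f(x, w[-1])

    w0 = np.concatenate([u_guess[free], [u_guess[n]]])
    w = newton_solve(res, w0, tol=tol, max_iter=50)
    x = np.empty(n)
    x[free] = w[:-1]
    x[k] = xi
    return x, float(w[-1])


def _critical_real_eig(eigvals):
    """Signed real eigenvalue of smallest magnitude (fold test function)."""
    re = eigvals[np.abs(eigvals.imag) < 1e-6 * np.maximum(
        1.0, np.abs(eigvals.real))].real
    if re.size == 0:
        return None
    return float(re[np.argmin(np.abs(re))])


def _leading_complex_real_part(eigvals):
    """Max real part over complex-conjugate pairs (Hopf test function)."""
    mask = np.abs(eigvals.imag) > 1e-6 * np.maximum(1.0,
                                                    np.abs(eigvals.real))
    if not mask.any():
        return None, None
    idx = np.argmax(eigvals[mask].real)
    lam = eigvals[mask][idx]
    return float(lam.real), float(abs(lam.imag))


def _refine_by_bisection(f, branch, i, test, tol: float = 1e-12,
                         max_iter: int = 80):
    """Bisect a test-function sign change between branch points i and i+1.

    Uses the pinned-coordinate local parametrization along the state
    coordinate that varies most between the two points.
    """
    n = branch.states.shape[1]
    xa, xb = branch.states[i], branch.states[i + 1]
    k = int(np.argmax(np.abs(xb - xa)))
    xi_a, xi_b = xa[k], xb[k]
    ua = np.concatenate([xa, [branch.mus[i]]])
    ub = np.concatenate([xb, [branch.mus[i + 1]]])
    ta = test(branch.eigvals[i])
    tb = test(branch.eigvals[i + 1])
    if ta is None or tb is None or np.sign(ta) == np.sign(tb):
        return None
    guess = ua
    x_mid, mu_mid, eig_mid = xa, branch.mus[i], branch.eigvals[i]
    for _ in range(max_iter):
        xi = 0.5 * (xi_a + xi_b)
        x_mid, mu_mid = _solve_pinned(f, n, k, xi, guess)
        eig_mid = _eig(f, x_mid, mu_mid)
        tm = test(eig_mid)
        if tm is None:
            return None
        if abs(tm) < 1e-9 or abs(xi_b - xi_a) < tol * max(1.0, abs(xi)):
            break
        if np.sign(tm) == np.sign(ta):
            xi_a = xi
            ta = tm
        else:
            xi_b = xi
        guess = np.concatenate([x_mid, [mu_mid]])
    return x_mid, mu_mid, eig_mid


def detect_folds(branch: EquilibriumBranch) -> list:
    """Saddle-node points: zero crossings of the critical real eigenvalue.

    Candidates are bracketed where the branch tangent's parameter
    component changes sign (turning points) and refined by bisection on
    the eigenvalue until it vanishes to ~1e-9.
    """
    out = []
    dmu = branch.tangents[:, -1]
    for i in range(len(branch) - 1):
        if np.sign(dmu[i]) != np.sign(dmu[i + 1]) and dmu[i] != 0:
            # the eigenvalue zero-crossing may sit a segment or two away
            # from the tangent reversal; search its neighborhood
            ref = None
            for j in sorted(range(max(0, i - 5),
                                  min(len(branch) - 1, i + 5)),
                            key=lambda j: abs(j - i)):
                ta = _critical_real_eig(branch.eigvals[j])
                tb = _critical_real_eig(branch.eigvals[j + 1])
                if ta is None or tb is None or np.sign(ta) == np.sign(tb):
                    continue
                ref = _refine_by_bisection(branch.f, branch, j,
                                           _critical_real_eig)
                if ref is not None:
                    break
            if ref is None:
                continue
            x, mu, eig = ref
            out.append(BifurcationPoint(
                "fold", mu, x,
                {"eigenvalue": _critical_real_eig(eig),
                 "eigvals": eig}))
    out.sort(key=lambda b: b.mu)
    return out


def detect_hopf(branch: EquilibriumBranch) -> list:
    """Hopf points: a complex-conjugate pair crossing the imaginary axis.

    Refined by bisection on the pair's real part; reports the angular
    frequency ``omega`` of the pair at the crossing.
    """
    out = []

    def test(eig):
        return _leading_complex_real_part(eig)[0]

    for i in range(len(branch) - 1):
        ra = test(branch.eigvals[i])
        rb = test(branch.eigvals[i + 1])
        if ra is None or rb is None or np.sign(ra) == np.sign(rb):
            continue
        # skip if the sign change is a fold artifact (tangent reversal)
        ref = _refine_by_bisection(branch.f, branch, i, test)
        if ref is None:
            continue
        x, mu, eig = ref
        re, omega = _leading_complex_real_part(eig)
        out.append(BifurcationPoint("hopf", mu, x,
                                    {"real_part": re, "omega": omega,
                                     "eigvals": eig}))
    out.sort(key=lambda b: b.mu)
    return out


# ---------------------------------------------------------------------------
# limit-cycle continuation by single shooting

@dataclass
class CycleBranch:
    """Periodic-orbit branch from single-shooting continuation.

    ``lpc`` holds folds of the cycle branch in the parameter (limit points
    of cycles, from tangent reversals); ``stability_loss`` holds points
    where the leading nontrivial Floquet multiplier leaves the unit circle
    (classified ``period_doubling`` / ``cycle_fold`` / ``torus``).  The
    stable portion of the branch ends at whichever of these comes first.
    """

    mus: np.ndarray
    periods: np.ndarray
    states: np.ndarray          # cycle anchor points (n_points, n)
    amplitudes: np.ndarray      # max - min of the monitored output per cycle
    multipliers: np.ndarray | None = None   # (n_points, n) complex
    lpc: list = field(default_factory=list)
    stability_loss: list = field(default_factory=list)
    complete: bool = True
    fallback_used: bool = False

    def stable_cycle_end(self):
        """Where the stable cycle branch terminates (an LPC or a
        stability-loss point, whichever occurs first along the branch)."""
        candidates = self.lpc + self.stability_loss
        if not candidates:
            return None
        return min(candidates, key=lambda b: b.info.get("branch_index",
                                                        np.inf))


def _sample_cycle(flow, x0, T, mu, output, m: int = 200):
    """Min/max of ``output`` over one period, sampled at m points."""
    x = np.asarray(x0, float).copy()
    vals = np.empty(m)
    h = T / m
    for i in range(m):
        vals[i] = output(x)
        x = flow(x, h, mu)
    return float(vals.min()), float(vals.max())


def _find_cycle_by_simulation(flow, f, x_eq, mu, omega, output,
                              n_periods_settle: int = 300,
                              perturb: float = 1e-2):
    """Settle onto a stable cycle near an equilibrium; return (x0, T) guess.

    Integrates from a perturbed equilibrium, then measures the period from
    successive maxima of the monitored output.  Returns None if the
    trajectory converges back to the equilibrium (no stable cycle).
    """
    period_guess = 2 * np.pi / omega
    x = np.asarray(x_eq, float) + perturb * max(1e-2, np.linalg.norm(x_eq)) \
        * _unit_perturbation(f, x_eq, mu)
    x = flow(x, n_periods_settle * period_guess, mu)
    # sample a few periods finely
    m = 64
    n_rec = 6 * m
    h = period_guess / m
    vals = np.empty(n_rec)
    states = np.empty((n_rec, x.size))
    for i in range(n_rec):
        states[i] = x
        vals[i] = output(x)
        x = flow(x, h, mu)
    amp = vals.max() - vals.min()
    scale = max(1.0, np.max(np.abs(vals)))
    if amp < 1e-7 * scale:
        return None
    # indices of local maxima
    peaks = [i for i in range(1, n_rec - 1)
             if vals[i] >= vals[i - 1] and vals[i] > vals[i + 1]]
    if len(peaks) < 2:
        return None
    T = h * float(np.mean(np.diff(peaks)))
    return states[peaks[0]].copy(), T


def _unit_perturbation(f, x_eq, mu):
    J = _fd_jacobian(lambda s: f(s, mu), x_eq)
    w, v = np.linalg.eig(J)
    lead = np.argmax(w.real)
    vec = np.real(v[:, lead])
    nrm = np.linalg.norm(vec)
    return vec / nrm if nrm > 0 else np.ones(x_eq.size) / np.sqrt(x_eq.size)


def _shoot(flow, f, x0, T, mu, j_phase, tol=1e-9, max_iter=25):
    """Solve the periodic-orbit conditions at fixed ``mu``.

    Unknowns ``(x0, T)``; residuals: return map ``phi_T(x0) - x0`` and the
    phase anchor ``f(x0)[j_phase] = 0`` (x0 sits at an extremum of the
    monitored coordinate).  Trial periods far from the initial guess are
    rejected outright so a diverging iterate cannot trigger an unbounded
    integration.
    """
    n = np.asarray(x0).size
    T_ref = float(T)

    def res(w):
        x, period = w[:n], abs(w[n])
        if not np.isfinite(period) or not (0.05 * T_ref < period
                                           < 20.0 * T_ref) \
                or not np.all(np.isfinite(x)):
            return np.full(n + 1, 1e6)
        return np.concatenate([flow(x, period, mu) - x,
                               [f(x, mu)[j_phase]]])

    w = np.concatenate([x0, [T]])
    for _ in range(max_iter):
        r = res(w)
        if np.max(np.abs(r)) < tol:
            return w[:n], abs(w[n])
        J = _fd_jacobian(res, w, rel=1e-7)
        try:
            dw = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            dw = np.linalg.lstsq(J, -r, rcond=None)[0]
        step = 1.0
        # damped update guarding against period collapse
        while abs(w[n] + step * dw[n]) < 0.1 * abs(w[n]) and step > 1e-3:
            step *= 0.5
        w = w + step * dw
    raise RuntimeError("shooting Newton did not converge")


def continue_limit_cycles(f, flow, hopf: BifurcationPoint,
                          direction: float = 1.0,
                          mu_limits: tuple = (0.0, 10.0),
                          output=None,
                          delta0: float = 0.02,
                          ds: float = 0.05, ds_min: float = 1e-5,
                          ds_max: float = 0.25,
                          max_points: int = 400,
                          continue_direction: float | None = None,
                          settle_periods: int = 300,
                          perturb: float = 1e-2) -> CycleBranch:
    """Continue the periodic orbits emanating from a Hopf point.

    The first cycle is located by direct simulation a little beyond the
    Hopf point (supercritical side), refined by single shooting, then
    continued in ``mu`` by pseudo-arclength on the shooting system
    ``(x0, T, mu)``.  A sign change of the parameter component of the
    branch tangent is a limit point of cycles; the reported LPC parameter
    is refined by a local quadratic fit of ``mu`` along the branch.

    Falls back to :func:`bracket_lpc_by_sweep` (flagged) when shooting
    cannot follow the branch.
    """
    n = hopf.state.size
    omega = hopf.info.get("omega")
    if output is None:
        output = lambda x: x[0]
    mu1 = hopf.mu + direction * delta0
    got = _find_cycle_by_simulation(flow, f, hopf.state, mu1, omega, output,
                                    settle_periods, perturb)
    if got is None:
        # try a larger offset before giving up
        mu1 = hopf.mu + direction * 3 * delta0
        got = _find_cycle_by_simulation(flow, f, hopf.state, mu1, omega,
                                        output, settle_periods, perturb)
    if got is None:
        raise RuntimeError("no stable cycle found near the Hopf point; "
                           "is it subcritical in this direction?")
    x0, T = got
    j_phase = _phase_index(f, x0, mu1)
    x0, T = _shoot(flow, f, x0, T, mu1, j_phase)

    # second point by a small natural-parameter step (the continuation may
    # run against the direction used to locate the first cycle)
    cont = direction if continue_direction is None else continue_direction
    mu2 = mu1 + cont * delta0 / 2
    x0b, Tb = _shoot(flow, f, x0, T, mu2, j_phase)

    # scaled pseudo-arclength on w = (x0, T, mu)
    scale = np.concatenate([np.maximum(np.abs(x0), 1e-2), [max(T, 1e-3)],
                            [max(abs(mu1), 1e-2)]])

    def pack(x, period, mu):
        return np.concatenate([x, [period], [mu]])

    w_prev = pack(x0, T, mu1)
    w = pack(x0b, Tb, mu2)
    mus = [mu1, mu2]
    periods = [T, Tb]
    states = [x0, x0b]
    amps = []
    mults = []
    for m_, x_, T_ in zip(mus, states, periods):
        lo_, hi_ = _sample_cycle(flow, x_, T_, m_, output)
        amps.append(hi_ - lo_)
        mults.append(_monodromy_multipliers(flow, x_, T_, m_))
    lpc_points = []
    complete = True

    t = (w - w_prev) / scale
    t /= np.linalg.norm(t)
    turn_brackets = []

    while len(mus) < max_points:
        accepted = False
        ds_try = ds
        while ds_try >= ds_min:
            w_pred = w + ds_try * t * scale

            def res(wv):
                x, period, mu = wv[:n], abs(wv[n]), wv[n + 1]
                if not np.all(np.isfinite(wv)) or not (0.05 * T
                                                       < period < 20.0 * T):
                    return np.full(n + 2, 1e6)
                return np.concatenate([
                    flow(x, period, mu) - x,
                    [f(x, mu)[j_phase]],
                    [t @ ((wv - w_pred) / scale)]])

            try:
                w_new = _newton_damped(res, w_pred, tol=1e-9, max_iter=15)
                accepted = True
                break
            except RuntimeError:
                ds_try *= 0.5
        if not accepted:
            complete = False
            break
        t_new = (w_new - w) / scale
        nrm = np.linalg.norm(t_new)
        if nrm == 0:
            complete = False
            break
        t_new /= nrm
        if np.sign(t_new[-1]) != np.sign(t[-1]) and t[-1] != 0:
            # mu extremum lies between the two secant endpoints
            turn_brackets.append((w_prev.copy(), w_new.copy(),
                                  len(mus) - 1))
        w_prev, w, t = w, w_new, t_new
        mus.append(w[n + 1])
        periods.append(abs(w[n]))
        states.append(w[:n].copy())
        lo_, hi_ = _sample_cycle(flow, w[:n], abs(w[n]), w[n + 1], output)
        amps.append(hi_ - lo_)
        mults.append(_monodromy_multipliers(flow, w[:n], abs(w[n]),
                                            w[n + 1]))
        ds = min(ds_try * 1.3, ds_max)
        if turn_brackets:
            break
        if not (mu_limits[0] <= w[n + 1] <= mu_limits[1]):
            break
        if amps[-1] < 1e-8:
            break

    for w_lo, w_hi, idx in turn_brackets:
        try:
            mu_lpc, w_lpc = _refine_lpc(f, flow, j_phase, n, w_lo, w_hi,
                                        scale)
            lpc_points.append(BifurcationPoint(
                "lpc", mu_lpc, w_lpc[:n].copy(),
                {"period": abs(w_lpc[n]), "branch_index": idx}))
        except RuntimeError:
            # keep the coarse bracket midpoint, flagged
            lpc_points.append(BifurcationPoint(
                "lpc", float(0.5 * (w_lo[n + 1] + w_hi[n + 1])),
                w_lo[:n].copy(),
                {"period": abs(w_lo[n]), "branch_index": idx,
                 "refined": False}))

    mult_arr = np.array(mults)
    stability_loss = _detect_stability_loss(f, flow, j_phase,
                                            np.array(mus),
                                            np.array(periods),
                                            np.array(states), mult_arr)

    return CycleBranch(np.array(mus), np.array(periods), np.array(states),
                       np.array(amps), mult_arr, lpc_points,
                       stability_loss, complete)


def _monodromy_multipliers(flow, x0, T, mu):
    """Floquet multipliers from a finite-difference monodromy matrix."""
    M = _fd_jacobian(lambda s: flow(s, T, mu), np.asarray(x0, float),
                     rel=1e-7)
    return np.linalg.eigvals(M)


def _lead_nontrivial(mults):
    """Leading multiplier after discarding the trivial one (closest to +1)."""
    idx = int(np.argmin(np.abs(mults - 1.0)))
    rest = np.delete(mults, idx)
    if rest.size == 0:
        return 1.0 + 0.0j
    return rest[int(np.argmax(np.abs(rest)))]


def _detect_stability_loss(f, flow, j_phase, mus, periods, states, mults):
    """Find and refine the first crossing of the unit circle by the
    leading nontrivial Floquet multiplier along the cycle branch.

    Only the first crossing is refined: beyond it the branch no longer
    carries the stable oscillation, which is the quantity of interest.
    """
    out = []
    lead = np.array([_lead_nontrivial(m) for m in mults])
    mag = np.abs(lead)
    for i in range(mus.size - 1):
        if (mag[i] - 1.0) * (mag[i + 1] - 1.0) >= 0:
            continue
        lo_mu, hi_mu = mus[i], mus[i + 1]
        if not np.isfinite(lo_mu + hi_mu) or lo_mu == hi_mu:
            continue
        x_g, T_g = states[i].copy(), periods[i]
        mu_star, lam = lo_mu, lead[i]
        a_mu, b_mu = lo_mu, hi_mu
        sa = mag[i] - 1.0
        for _ in range(40):
            mid = 0.5 * (a_mu + b_mu)
            try:
                x_g, T_g = _shoot(flow, f, x_g, T_g, mid, j_phase)
            except RuntimeError:
                break
            lam = _lead_nontrivial(_monodromy_multipliers(flow, x_g, T_g,
                                                          mid))
            sm = abs(lam) - 1.0
            mu_star = mid
            if abs(sm) < 1e-8 or abs(b_mu - a_mu) < 1e-10:
                break
            if np.sign(sm) == np.sign(sa):
                a_mu, sa = mid, sm
            else:
                b_mu = mid
        if abs(lam.imag) > 1e-6:
            kind = "torus"
        elif lam.real < 0:
            kind = "period_doubling"
        else:
            kind = "cycle_fold"
        out.append(BifurcationPoint(kind, float(mu_star), x_g.copy(),
                                    {"multiplier": complex(lam),
                                     "period": float(T_g),
                                     "branch_index": i}))
        break
    return out


def _solve_cycle_pinned(f, flow, j_phase, n, k, xi, w_guess):
    """Shooting solve with coordinate ``k`` of ``(x0, T, mu)`` pinned."""
    free = [j for j in range(n + 2) if j != k]

    T_ref = abs(w_guess[n])

    def res(wf):
        w = np.empty(n + 2)
        w[free] = wf
        w[k] = xi
        x, period, mu = w[:n], abs(w[n]), w[n + 1]
        if not np.all(np.isfinite(w)) or not (0.05 * T_ref < period
                                              < 20.0 * T_ref):
            return np.full(n + 1, 1e6)
        return np.concatenate([flow(x, period, mu) - x,
                               [f(x, mu)[j_phase]]])

    wf = _newton_damped(res, np.asarray(w_guess)[free], tol=1e-9,
                        max_iter=20)
    w = np.empty(n + 2)
    w[free] = wf
    w[k] = xi
    return w


def _refine_lpc(f, flow, j_phase, n, w_lo, w_hi, scale):
    """Locate the extremum of ``mu`` along the cycle branch between two
    solutions bracketing a tangent reversal (the limit point of cycles).

    The branch is locally parametrized by the ``(x0, T)`` coordinate that
    changes most across the bracket; the parameter extremum over that
    coordinate is found with bounded scalar minimisation.
    """
    diffs = np.abs((w_hi[: n + 1] - w_lo[: n + 1]) / scale[: n + 1])
    k = int(np.argmax(diffs))
    a, b = sorted((w_lo[k], w_hi[k]))
    warm = {"w": w_lo.copy()}
    mu_a = w_lo[n + 1]
    mu_b = w_hi[n + 1]

    def mu_of(xi):
        w = _solve_cycle_pinned(f, flow, j_phase, n, k, xi, warm["w"])
        warm["w"] = w
        return w[n + 1]

    mu_mid = mu_of(0.5 * (a + b))
    sign = -1.0 if mu_mid >= max(mu_a, mu_b) else 1.0

    res = minimize_scalar(lambda xi: sign * mu_of(xi), bounds=(a, b),
                          method="bounded",
                          options={"xatol": 1e-7 * max(1.0, abs(b - a))})
    w_star = _solve_cycle_pinned(f, flow, j_phase, n, k, float(res.x),
                                 warm["w"])
    return float(w_star[n + 1]), w_star


def _phase_index(f, x0, mu) -> int:
    """Coordinate anchoring the shooting phase condition.

    The anchor point sits at an extremum of the monitored output, so the
    natural phase condition pins the coordinate whose time derivative is
    already (nearly) zero there.
    """
    fx = np.abs(np.asarray(f(x0, mu)))
    return int(np.argmin(fx))


def _newton_damped(res, w0, tol=1e-9, max_iter=15):
    w = np.asarray(w0, float).copy()
    r = np.asarray(res(w))
    nr = np.max(np.abs(r))
    for _ in range(max_iter):
        if nr < tol:
            return w
        J = _fd_jacobian(res, w, rel=1e-7)
        try:
            dw = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            dw = np.linalg.lstsq(J, -r, rcond=None)[0]
        step = 1.0
        while step > 1e-4:
            w_try = w + step * dw
            r_try = np.asarray(res(w_try))
            nr_try = np.max(np.abs(r_try))
            if nr_try < nr or nr_try < tol:
                w, r, nr = w_try, r_try, nr_try
                break
            step *= 0.5
        else:
            raise RuntimeError("damped Newton stalled")
    if nr < tol:
        return w
    raise RuntimeError("damped Newton did not converge")


def bracket_lpc_by_sweep(f, flow, x_cycle, T_cycle, mu_start: float,
                         mu_stop: float, step: float = 0.005,
                         output=None, settle_periods: int = 200):
    """Bracket the LPC by a deterministic sweep with inherited states.

    Starting on a stable cycle at ``mu_start``, steps the parameter toward
    ``mu_stop``; the first value at which the inherited trajectory settles
    onto the equilibrium instead of a cycle brackets the fold of the
    cycle branch within one step.
    """
    if output is None:
        output = lambda x: x[0]
    direction = np.sign(mu_stop - mu_start)
    mu = mu_start
    x = np.asarray(x_cycle, float).copy()
    last_on_cycle = mu_start
    while (mu_stop - mu) * direction > -1e-12:
        x = flow(x, settle_periods * T_cycle, mu)
        lo, hi = _sample_cycle(flow, x, 4 * T_cycle, mu, output, m=400)
        if hi - lo < 1e-6:
            return last_on_cycle, mu
        last_on_cycle = mu
        mu += direction * step
    return last_on_cycle, None


# ---------------------------------------------------------------------------
# stochastic scans and sweeps

@dataclass
class ScanResult:
    """Per-grid-point, per-seed, per-pass discharge statistics.

    ``effmag`` and ``freq`` have shape (n_grid, n_seeds, 3) with the last
    axis indexing three passes: the forward (0) and backward (1)
    inherited-state sweeps, and the cooling-onset pass (2) in which every
    grid point is simulated independently from the same seed's
    before-cooling activity — the state the system is actually in when
    cooling switches on, and the initial condition that can land on the
    low-amplitude oscillatory attractor inside the bistable window.
    EffMag is in units of the before-cooling SD; frequency counts events
    exceeding three before-cooling SDs.
    """

    q_grid: np.ndarray
    effmag: np.ndarray
    freq: np.ndarray
    seeds: tuple
    failed: np.ndarray | None = None


def _sub_seed(*parts) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0]
               % np.uint32(2 ** 31))


def stochastic_scan(params: ModelParameters, temp_template: TemperatureSpec,
                    q_grid, seeds, segment: float = 60.0,
                    settle: float = 2.0, k: float = 3.0,
                    dt: float = 5e-4) -> ScanResult:
    """Seeded forward/backward sweeps of the stochastic model over a
    ``Q10,int`` grid.

    Each sweep inherits the final state of the previous grid point as the
    next initial state (with a short settling interval discarded) to
    expose bistability as hysteresis.  Every simulated segment is
    referenced to a before-cooling simulation at baseline temperature with
    the same seed: EffMag is reported in before-cooling SD units and
    events are counted above ``k`` of those units.  A blown-up point is
    flagged and the sweep continues from a reset state.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    nq, ns = q_grid.size, len(seeds)
    effmag = np.full((nq, ns, 3), np.nan)
    freq = np.full((nq, ns, 3), np.nan)
    failed = np.zeros((nq, ns, 3), dtype=bool)
    base_temp = TemperatureSpec(T=temp_template.T0, T0=temp_template.T0)
    for si, seed in enumerate(seeds):
        bc, bc_state = simulate(
            params, base_temp,
            SimulationConfig(duration=segment, dt=dt, burn_in=5.0,
                             seed=_sub_seed(seed, 77)),
            return_state=True)
        sd_bc = bc.sd()

        def run_point(qi, di, state):
            temp = temp_template.replace(q_int=float(q_grid[qi]))
            cfg = SimulationConfig(duration=segment, dt=dt, burn_in=settle,
                                   seed=_sub_seed(seed, di, qi))
            try:
                ts, out_state = simulate(params, temp, cfg,
                                         initial_state=state,
                                         return_state=True)
            except BlowUpError:
                failed[qi, si, di] = True
                return np.zeros(10)
            vn = TimeSeries(ts.values / sd_bc, ts.rate, "au")
            effmag[qi, si, di] = effective_magnitude(vn)
            ev = detect_discharges(vn, k=k, reference_sd=1.0)
            freq[qi, si, di] = ev.n_events / vn.duration
            return out_state

        # inherited-state hysteresis sweeps
        for di, order in enumerate((range(nq), range(nq - 1, -1, -1))):
            state = np.zeros(10)
            for qi in order:
                state = run_point(qi, di, state)
        # cooling-onset pass: independent starts from before-cooling activity
        for qi in range(nq):
            run_point(qi, 2, bc_state)
    return ScanResult(q_grid, effmag, freq, tuple(seeds), failed)


def classify_scan(scan: ScanResult) -> dict:
    """Locate the bistable window and the discharge-reactivation point.

    Runs are classified baseline/active by thresholding EffMag at the
    geometric mean of the scan's two unambiguous anchors (the median
    EffMag at the grid's low end = baseline, and at the high end =
    discharge activity).  A grid point is *bistable* when both classes
    occur among its runs.  Reported landmarks (NaN if absent):

    * ``bistable_onset``: first grid value that is bistable (as is its
      successor, to reject single-point flicker);
    * ``bistable_close``: first value above onset where all runs are
      back in the baseline class (again two consecutive points);
    * ``discharge_reappearance``: first value above the closed window
      where every run is in the active class at two consecutive points
      (the reappeared rhythmic discharge activity is continuous, so the
      magnitude class — not the sparse-event count — marks it reliably).
    """
    em = scan.effmag.reshape(scan.q_grid.size, -1)
    low = np.nanmedian(em[0])
    high = np.nanmedian(em[-1])
    thr = float(np.sqrt(low * high))
    active = em > thr
    bistable = active.any(axis=1) & (~active).any(axis=1)
    all_baseline = (~active).all(axis=1)
    all_active = active.all(axis=1)
    n = scan.q_grid.size
    onset = close = reappear = float("nan")
    for i in range(n - 1):
        if bistable[i] and bistable[i + 1]:
            onset = float(scan.q_grid[i])
            break
    if np.isfinite(onset):
        i0 = int(np.searchsorted(scan.q_grid, onset))
        for i in range(i0 + 1, n - 1):
            if all_baseline[i] and all_baseline[i + 1]:
                close = float(scan.q_grid[i])
                break
    start = close if np.isfinite(close) else onset
    i0 = int(np.searchsorted(scan.q_grid, start)) if np.isfinite(start) else 0
    for i in range(i0, n - 1):
        if all_active[i] and all_active[i + 1]:
            reappear = float(scan.q_grid[i])
            break
    return {"bistable_onset": onset, "bistable_close": close,
            "discharge_reappearance": reappear, "threshold": thr,
            "bistable_mask": bistable, "active": active}


def termination_sweep(params: ModelParameters, T: float, q_syn_grid,
                      seeds, segment: float = 60.0, T0: float = 31.0,
                      k: float = 3.0, dt: float = 5e-4) -> dict:
    """Sweep the homogeneous synaptic Q10 (SYN variant, intrinsic Q10 = 1).

    For each grid value, during-cooling segments are simulated from rest
    for each seed and referenced to same-seed before-cooling activity.
    Returns per-point discharge frequencies and mean isolated-discharge
    peak magnitudes (NaN where no events occur).
    """
    q_syn_grid = np.asarray(q_syn_grid, dtype=float)
    nq, ns = q_syn_grid.size, len(seeds)
    freq = np.full((nq, ns), np.nan)
    ev_mag = np.full((nq, ns), np.nan)
    base_temp = TemperatureSpec(T=T0, T0=T0)
    sd_bc = {}
    for si, seed in enumerate(seeds):
        bc = simulate(params, base_temp,
                      SimulationConfig(duration=segment, dt=dt, burn_in=5.0,
                                       seed=_sub_seed(seed, 77)))
        sd_bc[seed] = bc.sd()
    for qi, q in enumerate(q_syn_grid):
        temp = TemperatureSpec(T=T, T0=T0, variant="SYN", q_syn=float(q))
        for si, seed in enumerate(seeds):
            cfg = SimulationConfig(duration=segment, dt=dt, burn_in=5.0,
                                   seed=_sub_seed(seed, qi, 13))
            ts = simulate(params, temp, cfg)
            vn = TimeSeries(ts.values / sd_bc[seed], ts.rate, "au")
            ev = detect_discharges(vn, k=k, reference_sd=1.0)
            freq[qi, si] = ev.n_events / vn.duration
            if ev.n_events:
                ev_mag[qi, si] = float(np.mean(ev.magnitudes))
    return {"q_syn": q_syn_grid, "freq": freq, "event_magnitude": ev_mag,
            "seeds": tuple(seeds)}


def model_bifurcation_analysis(params: ModelParameters | None = None,
                               q_syn: float = 1.8, T: float = 15.0,
                               T0: float = 31.0,
                               q_range: tuple = (1.0, 2.0),
                               flow_dt: float = 2e-5) -> dict:
    """Full deterministic bifurcation picture in the intrinsic Q10.

    Continues the equilibrium branch of the noiseless SYN_INT model from
    the low end of ``q_range``, classifies its folds and Hopf points, and
    continues the limit cycles born at the (lowest) Hopf point until the
    stable cycle terminates.  Returns the branch objects and the
    landmark parameter values (NaN where a landmark is absent).
    """
    params = params or ModelParameters()
    temp = TemperatureSpec(T=T, T0=T0, variant="SYN_INT", q_syn=q_syn,
                           q_int=q_range[0])
    f = make_model_field(params, temp)
    flow = make_model_flow(params, temp, dt=flow_dt)
    x0 = find_equilibrium(params, temp)
    branch = continue_equilibria(f, x0, q_range[0], q_range)
    folds = detect_folds(branch)
    hopfs = detect_hopf(branch)
    out = {"branch": branch, "folds": folds, "hopfs": hopfs,
           "cycles": None,
           "fold_lower": float("nan"), "fold_upper": float("nan"),
           "hopf": float("nan"), "lpc": float("nan")}
    if folds:
        out["fold_lower"] = folds[0].mu
        out["fold_upper"] = folds[-1].mu
    if hopfs:
        out["hopf"] = hopfs[0].mu
        eeg = lambda x: x[1] - x[2] - x[3]
        try:
            cycles = continue_limit_cycles(f, flow, hopfs[0], direction=+1,
                                           mu_limits=(q_range[0] - 0.05,
                                                      q_range[1] + 0.05),
                                           output=eeg)
            out["cycles"] = cycles
            end = cycles.stable_cycle_end()
            if end is not None:
                out["lpc"] = end.mu
                out["lpc_kind"] = end.kind
        except RuntimeError as exc:
            warnings.warn(f"cycle continuation failed ({exc}); "
                          "falling back to a hysteresis sweep")
            got = _find_cycle_by_simulation(
                flow, f, hopfs[0].state, hopfs[0].mu + 0.05,
                hopfs[0].info["omega"], eeg)
            if got is not None:
                xc, Tc = got
                last, first_off = bracket_lpc_by_sweep(
                    f, flow, xc, Tc, hopfs[0].mu + 0.05, q_range[1],
                    step=0.005, output=eeg)
                if first_off is not None:
                    out["lpc"] = 0.5 * (last + first_off)
                    out["lpc_kind"] = "sweep_bracket"
    return out


def termination_point(sweep: dict) -> float:
    """Smallest synaptic Q10 with no detected discharges in any seed."""
    freq = sweep["freq"]
    zero = (freq == 0).all(axis=1)
    idx = np.flatnonzero(zero)
    if idx.size == 0:
        return float("nan")
    return float(sweep["q_syn"][idx[0]])
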