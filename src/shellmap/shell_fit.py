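"""Fitting shell decompositions to oscillating radial profiles.

A target profile — the interference function G, or a numerically computed
limited-resolution atomic image — is approximated by

    f(r)  ~=  sum_m  kappa_m * Omega(r; mu_m, nu_m),

with the first term pinned to ``mu = 0`` (the central peak) and the
remaining terms seeded on the Fourier ripples of the target.  The fit is a
bound-constrained least-squares problem with analytic derivatives; an
optional Lawson-style reweighting pass polishes the solution toward the
minimax (max-residual) objective, which is the metric the accuracy of a
decomposition is quoted in: max |residual| relative to the target's value at
the origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares

from .radial_core import ShellDecomposition, ShellTerm, omega

__all__ = [
    "RadialProfile",
    "FitConfig",
    "FitError",
    "initial_guess",
    "fit_decomposition",
    "nested_fits",
    "evaluate_decomposition",
    "decomposition_report",
    "DecompositionReport",
    "write_decomposition",
    "read_decomposition",
    "packaged_g_decomposition",
]

_NU_MIN = 1e-3  # positivity floor for nu during optimization


@dataclass(frozen=True)
class RadialProfile:
    """A sampled spherically symmetric target function."""

    radii: np.ndarray
    values: np.ndarray
    origin_value: float

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "values", values)
        if radii.ndim != 1 or radii.size < 1 or np.any(np.diff(radii) <= 0):
            raise ValueError("radii must be a strictly increasing 1D grid")
        if radii[0] < 0:
            raise ValueError("radii must start at >= 0")
        if values.shape != radii.shape or not np.all(np.isfinite(values)):
            raise ValueError("values must be finite and match radii")
        if self.origin_value == 0:
            raise ValueError("origin_value must be nonzero")

    def interpolator(self) -> CubicSpline:
        return CubicSpline(self.radii, self.values)


@dataclass(frozen=True)
class FitConfig:
    """Controls for :func:`fit_decomposition`."""

    n_terms: int
    domain_radius: float
    grid_step: float = 0.0  # 0 -> domain_radius / 500
    objective: str = "minimax-polish"  # or "least-squares"
    max_iterations: int = 400
    n_restarts: int = 3
    seed: int = 0
    # fraction of domain_radius the fit grid extends past the domain, keeping
    # the decomposition anchored where later blurring (nu + B) spills over
    tail_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")
        if not self.domain_radius > 0:
            raise ValueError("domain_radius must be > 0")
        if self.grid_step < 0:
            raise ValueError("grid_step must be >= 0")
        if self.tail_fraction < 0:
            raise ValueError("tail_fraction must be >= 0")
        if self.objective not in ("least-squares", "minimax-polish"):
            raise ValueError(f"unknown objective {self.objective!r}")

    @property
    def step(self) -> float:
        return self.grid_step if self.grid_step > 0 else self.domain_radius / 500.0


class FitError(RuntimeError):
    """Raised on non-convergence; carries the best decomposition found."""

    def __init__(self, message: str, best: ShellDecomposition | None = None):
        super().__init__(message)
        self.best = best


# ---------------------------------------------------------------------------
# evaluation


def evaluate_decomposition(dec: ShellDecomposition, radii) -> np.ndarray:
    """Evaluate ``sum_m kappa_m Omega(r; mu_m, nu_m)`` elementwise."""
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    out = np.zeros_like(radii)
    for t in dec.terms:
        out += t.kappa * omega(radii, t.mu, t.nu)
    return out


@dataclass(frozen=True)
class DecompositionReport:
    max_abs_residual: float
    max_location: float
    max_relative: float  # relative to |origin_value|
    rms_residual: float


def decomposition_report(
    dec: ShellDecomposition, profile: RadialProfile
) -> DecompositionReport:
    """Residual summary of a decomposition against a target profile."""
    r = profile.radii
    inside = r <= dec.domain_radius + 1e-12
    r = r[inside]
    res = evaluate_decomposition(dec, r) - profile.values[inside]
    i = int(np.argmax(np.abs(res)))
    return DecompositionReport(
        max_abs_residual=float(np.abs(res[i])),
        max_location=float(r[i]),
        max_relative=float(np.abs(res[i]) / abs(profile.origin_value)),
        rms_residual=float(np.sqrt(np.mean(res**2))),
    )


# ---------------------------------------------------------------------------
# analytic derivatives of Omega (needed only by the optimizer)


def _omega_and_grads(r, mu, nu):
    """Omega and its partial derivatives wrt mu and nu, elementwise in r.

    Uses the same two-branch evaluation as :func:`shellmap.radial_core.omega`
    (sinh-product form for moderate t = 2*A*mu*r, explicit exponential
    difference for large t) so values and gradients never overflow.
    """
    r = np.asarray(r, dtype=float)
    A = 4.0 * np.pi**2 / nu
    t = 2.0 * A * mu * r
    val = np.empty_like(r)
    dmu = np.empty_like(r)
    dnu = np.empty_like(r)

    big = t > 30.0
    if np.any(big):
        rb = r[big]
        C = np.sqrt(np.pi / nu) / (2.0 * np.pi)
        em = np.exp(-A * (rb - mu) ** 2)
        ep = np.exp(-A * (rb + mu) ** 2)
        base = C / (mu * rb)
        v = base * (em - ep)
        val[big] = v
        dmu[big] = base * 2.0 * A * ((rb - mu) * em + (rb + mu) * ep) - v / mu
        dnu[big] = -v / (2.0 * nu) + base * (A / nu) * (
            (rb - mu) ** 2 * em - (rb + mu) ** 2 * ep
        )
    sm = ~big
    if np.any(sm):
        rs = r[sm]
        ts = t[sm]
        P = (4.0 * np.pi / nu) ** 1.5 * np.exp(-A * (rs * rs + mu * mu))
        tiny = ts < 1e-4
        S = np.empty_like(ts)
        dS = np.empty_like(ts)  # (cosh t - S) -- enters both gradients
        S[tiny] = 1.0 + ts[tiny] ** 2 / 6.0 + ts[tiny] ** 4 / 120.0
        dS[tiny] = ts[tiny] ** 2 / 3.0 + ts[tiny] ** 4 / 30.0
        tb = ts[~tiny]
        S[~tiny] = np.sinh(tb) / tb
        dS[~tiny] = np.cosh(tb) - S[~tiny]
        val[sm] = P * S
        # d(cosh t - S)/dmu collapses to (cosh t - S)/mu * ... ; use series-safe form
        if mu > 0:
            dmu[sm] = P * (dS / mu - 2.0 * A * mu * S)
        else:
            dmu[sm] = 0.0  # symmetric point: dOmega/dmu = 0 at mu = 0
        dnu[sm] = (P / nu) * (S * (A * (rs * rs + mu * mu) - 1.5) - dS)
    return val, dmu, dnu


# ---------------------------------------------------------------------------
# initial guess


def _interior_extrema(r: np.ndarray, f: np.ndarray, rel_floor: float = 1e-7):
    """Radii and values of interior extrema with non-negligible amplitude."""
    df = np.diff(f)
    sign = np.sign(df)
    idx = np.where(sign[:-1] * sign[1:] < 0)[0] + 1
    floor = rel_floor * np.max(np.abs(f))
    keep = np.abs(f[idx]) > floor
    idx = idx[keep]
    idx = idx[r[idx] > 0]
    return r[idx], f[idx]


def initial_guess(profile: RadialProfile, M: int) -> list[ShellTerm]:
    """Seed M shell terms on the target's central peak and ripple extrema.

    Term 1 sits at ``mu = 0`` (central peak); when ``M >= 3`` a second,
    low-weight correcting term is placed inside the central peak; the
    remaining terms are centered on successive ripple extrema, with ``nu``
    from each extremum's half-width and ``kappa`` from its signed amplitude.
    If the profile shows fewer ripples than requested terms, extra terms are
    inserted at the widest gaps between already-placed shells; a profile with
    no ripples at all cannot seed more than two terms.
    """
    r, f = profile.radii, profile.values
    f0 = profile.origin_value
    er, ev = _interior_extrema(r, f)

    # central-peak width from the half-maximum radius
    below = np.where(np.abs(f) < 0.5 * abs(f0))[0]
    r_half = r[below[0]] if below.size else r[-1] / 4.0
    nu0 = 4.0 * np.pi**2 * r_half**2 / np.log(2.0)

    def kappa_for(mu: float, nu: float, target: float) -> float:
        w = omega(np.array([mu]), mu, nu)[0]
        return target / w if w != 0 else 0.0

    terms: list[ShellTerm] = [ShellTerm(0.0, nu0, kappa_for(0.0, nu0, f0))]
    if M == 1:
        return terms

    mus: list[float] = []
    if M >= 3 and er.size:
        mus.append(0.4 * er[0])  # correcting term inside the central peak
    mus.extend(er.tolist())

    n_needed = M - 1
    if n_needed > len(mus):
        if not er.size:
            raise ValueError(
                f"profile shows 0 ripple extrema; cannot seed {M} terms "
                "(at most 2 for a ripple-free profile)"
            )
        # densify: split the widest inter-shell gaps
        while len(mus) < n_needed:
            pts = [0.0] + sorted(mus)
            gaps = np.diff(pts)
            j = int(np.argmax(gaps))
            mus.append(pts[j] + gaps[j] / 2.0)
        mus.sort()
    mus = sorted(mus)[:n_needed]

    spline = profile.interpolator()
    ripple_spacing = np.median(np.diff(er)) if er.size > 1 else r_half * 2
    for mu in mus:
        amp = float(spline(mu))
        # half-width of the local oscillation sets the blur
        sigma = 0.3 * ripple_spacing
        nu = 8.0 * np.pi**2 * sigma**2
        terms.append(ShellTerm(mu, nu, kappa_for(mu, nu, amp)))
    return terms


# ---------------------------------------------------------------------------
# fitting


def _pack(terms: list[ShellTerm]) -> np.ndarray:
    # first term: mu pinned to 0 -> parameters are (nu1, k1, mu2, nu2, k2, ...)
    x = [terms[0].nu, terms[0].kappa]
    for t in terms[1:]:
        x.extend((t.mu, t.nu, t.kappa))
    return np.array(x, dtype=float)


def _unpack(x: np.ndarray) -> list[ShellTerm]:
    terms = [ShellTerm(0.0, max(x[0], _NU_MIN), x[1])]
    for i in range(2, len(x), 3):
        terms.append(
            ShellTerm(max(x[i], 0.0), max(x[i + 1], _NU_MIN), x[i + 2])
        )
    return terms


def _model_and_jac(x: np.ndarray, r: np.ndarray):
    m = np.zeros_like(r)
    J = np.empty((r.size, x.size))
    v, _, dnu = _omega_and_grads(r, 0.0, x[0])
    m += x[1] * v
    J[:, 0] = x[1] * dnu
    J[:, 1] = v
    for j, i in enumerate(range(2, len(x), 3)):
        mu, nu, k = x[i], x[i + 1], x[i + 2]
        v, dmu, dnu = _omega_and_grads(r, mu, nu)
        m += k * v
        J[:, i] = k * dmu
        J[:, i + 1] = k * dnu
        J[:, i + 2] = v
    return m, J


def _bounds(n_params: int, mu_max: float):
    lo = np.full(n_params, -np.inf)
    hi = np.full(n_params, np.inf)
    lo[0] = _NU_MIN
    for i in range(2, n_params, 3):
        lo[i] = 0.0
        hi[i] = mu_max
        lo[i + 1] = _NU_MIN
    return lo, hi


def fit_decomposition(
    profile: RadialProfile,
    config: FitConfig,
    target_id: str = "",
    initial_terms: list[ShellTerm] | None = None,
) -> ShellDecomposition:
    """Fit an M-term shell decomposition to a radial profile.

    Weighted (uniform) least squares on a regular radial grid extending
    ``tail_fraction`` past ``domain_radius`` (clipped to the profile's
    range), started from
    :func:`initial_guess` (or from ``initial_terms`` when warm-starting),
    with seeded random restarts if the optimizer stalls.  With ``objective="minimax-polish"`` a Lawson reweighting loop
    then pulls the solution toward equal-ripple residuals.  ``max_error`` of
    the result is the maximum absolute residual inside the domain, relative
    to the profile's origin value, measured on a grid twice as fine as the
    fit grid.  Deterministic for a fixed config (restart seeds derive from
    ``config.seed``).
    """
    if profile.radii[-1] < config.domain_radius:
        raise ValueError("profile does not cover [0, domain_radius]")
    spline = profile.interpolator()
    step = config.step
    r_hi = min(
        (1.0 + config.tail_fraction) * config.domain_radius,
        float(profile.radii[-1]),
    )
    r_fit = np.arange(0.0, r_hi + step / 2, step)
    y_fit = spline(r_fit)
    scale = abs(profile.origin_value)

    if initial_terms is not None:
        if len(initial_terms) != config.n_terms:
            raise ValueError("initial_terms length must equal n_terms")
        terms0 = sorted(initial_terms, key=lambda t: t.mu)
    else:
        terms0 = initial_guess(profile, config.n_terms)
    x0 = _pack(terms0)
    lo, hi = _bounds(x0.size, 1.2 * config.domain_radius)
    rng = np.random.default_rng(config.seed)

    # residuals measured inside the domain only, on a finer grid
    r_chk = np.arange(0.0, config.domain_radius + step / 4, step / 2)
    y_chk = spline(r_chk)

    def max_err(x: np.ndarray) -> float:
        m, _ = _model_and_jac(x, r_chk)
        return float(np.max(np.abs(m - y_chk)) / scale)

    def solve(x_init: np.ndarray, w: np.ndarray):
        res = least_squares(
            lambda x: (_model_and_jac(x, r_fit)[0] - y_fit) * w,
            np.clip(x_init, lo, hi),
            jac=lambda x: _model_and_jac(x, r_fit)[1] * w[:, None],
            bounds=(lo, hi),
            method="trf",
            max_nfev=config.max_iterations,
            x_scale="jac",
        )
        return res.x

    w = np.ones_like(r_fit)
    best_x, best_err = None, np.inf
    for attempt in range(1 + config.n_restarts):
        if attempt == 0:
            xi = x0
        else:  # seeded perturbation of the ripple guesses
            xi = x0 * (1.0 + 0.05 * rng.standard_normal(x0.size))
        x = solve(xi, w)
        e = max_err(x)
        if e < best_err:
            best_x, best_err = x, e
        if e < 1e2 * np.finfo(float).eps:
            break

    if config.objective == "minimax-polish":
        x, wl = best_x.copy(), np.ones_like(r_fit)
        for _ in range(12):
            m, _ = _model_and_jac(x, r_fit)
            resid = np.abs(m - y_fit)
            wl = wl * np.sqrt(resid / max(resid.max(), 1e-300) + 1e-3)
            wl = wl / wl.max()
            x = solve(x, wl)
            e = max_err(x)
            if e < best_err:
                best_x, best_err = x.copy(), e

    if best_x is None or not np.isfinite(best_err):
        raise FitError("optimizer failed to produce a finite fit", None)

    terms = sorted(_unpack(best_x), key=lambda t: t.mu)
    dec = ShellDecomposition(
        terms=tuple(terms),
        domain_radius=config.domain_radius,
        target_id=target_id,
        max_error=best_err,
        metadata={
            "convention": "B-additive",
            "objective": config.objective,
            "seed": config.seed,
            "grid_step": step,
        },
    )
    return dec


def nested_fits(
    profile: RadialProfile,
    m_values: list[int],
    base_config: FitConfig,
    target_id: str = "",
) -> list[ShellDecomposition]:
    """Warm-started sequence of fits with growing term counts.

    The first fit starts from :func:`initial_guess`; each subsequent fit
    starts from the previous solution plus one term seeded greedily at the
    radius of the largest remaining residual.  Because every fit starts from
    a feasible superset of the previous solution, the achieved residual
    never increases as M grows.
    """
    if sorted(m_values) != list(m_values):
        raise ValueError("m_values must be increasing")
    spline = profile.interpolator()
    out: list[ShellDecomposition] = []
    prev: ShellDecomposition | None = None
    for M in m_values:
        cfg = replace_config(base_config, n_terms=M)
        init = None
        if prev is not None:
            terms = list(prev.terms)
            while len(terms) < M:
                r = np.arange(0.0, cfg.domain_radius + cfg.step / 2, cfg.step)
                res = spline(r) - evaluate_decomposition(
                    ShellDecomposition(tuple(terms), cfg.domain_radius), r
                )
                i = int(np.argmax(np.abs(res)))
                mu_new = float(r[i])
                nu_new = max(np.median([t.nu for t in terms]), 2 * _NU_MIN)
                w = omega(np.array([mu_new]), mu_new, nu_new)[0]
                terms.append(ShellTerm(mu_new, nu_new, float(res[i] / w)))
            init = terms
        dec = fit_decomposition(
            profile, cfg, target_id=f"{target_id} M={M}", initial_terms=init
        )
        if prev is not None and dec.max_error > prev.max_error:
            # the optimizer polishes a weighted L2 objective, so the minimax
            # metric can regress slightly; fall back to the previous solution
            # carrying one near-null extra term, which by construction is at
            # least as good
            terms = list(prev.terms)
            while len(terms) < M:
                terms.append(ShellTerm(0.0, prev.terms[0].nu, 0.0))
            carried = ShellDecomposition(
                tuple(sorted(terms, key=lambda t: t.mu)),
                cfg.domain_radius,
                target_id=f"{target_id} M={M}",
                max_error=prev.max_error,
                metadata=dict(prev.metadata),
            )
            fallback = fit_decomposition(
                profile, cfg, target_id=f"{target_id} M={M}",
                initial_terms=terms,
            )
            dec = min((dec, fallback, carried), key=lambda d: d.max_error)
        out.append(dec)
        prev = dec
    return out


def replace_config(cfg: FitConfig, **kw) -> FitConfig:
    from dataclasses import replace as _replace

    return _replace(cfg, **kw)


# ---------------------------------------------------------------------------
# coefficient files


def write_decomposition(dec: ShellDecomposition, path) -> None:
    """Write a decomposition to JSON at full float precision."""
    payload = {
        "target_id": dec.target_id,
        "n_terms": dec.n_terms,
        "domain_radius": dec.domain_radius,
        "max_error": dec.max_error,
        "terms": [{"mu": t.mu, "nu": t.nu, "kappa": t.kappa} for t in dec.terms],
        "metadata": dec.metadata or {"convention": "B-additive"},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_decomposition(path) -> ShellDecomposition:
    payload = json.loads(Path(path).read_text())
    terms = tuple(
        ShellTerm(t["mu"], t["nu"], t["kappa"]) for t in payload["terms"]
    )
    if len(terms) != payload["n_terms"]:
        raise ValueError(f"{path}: n_terms does not match the term list")
    return ShellDecomposition(
        terms=terms,
        domain_radius=payload["domain_radius"],
        target_id=payload.get("target_id", ""),
        max_error=payload.get("max_error", 0.0),
        metadata=payload.get("metadata", {}),
    )


def packaged_g_decomposition() -> ShellDecomposition:
    """The shipped 21-term reference decomposition of G over |x| <= 10.

    Coefficients are printed to three decimals; the recorded accuracy of the
    sum is about 2e-4 of G(0) = 1.
    """
    with resources.as_file(
        resources.files("shellmap.data") / "g21.json"
    ) as p:
        return read_decomposition(p)
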