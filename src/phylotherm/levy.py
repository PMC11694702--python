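"""Levy-process increment densities via characteristic-function inversion.

Each trait-evolution family with jumps is a Levy process defined by its
characteristic exponent psi(k) (log characteristic function per unit time);
the increment over elapsed time T has density

    f(x; T) = (1/pi) * Integral_0^inf exp(T*psi(k)) * cos(k*x) dk,

evaluated here by trapezoid quadrature after the substitution k = u/sqrt(T),
which keeps one frequency grid usable across contrasts with very different
elapsed times.  Pure-jump processes carry an atom at zero (no jump occurred,
probability exp(-rate*T) for the compound-Poisson case); a small Gaussian
"nugget" variance convolved into the density regularizes that atom so the
log-likelihood of observed contrasts stays finite.

Exponents implemented (all symmetric, psi(0) = 0, psi <= 0):

=======  =========================================  ====================
family   psi(k)                                     parameters
=======  =========================================  ====================
BM       -sigma2 k^2 / 2                            sigma2
JN       jump_rate (exp(-jump_var k^2 / 2) - 1)     jump_rate, jump_var
VG       -(1/vg_nu) log(1 + vg_sigma2 vg_nu k^2/2)  vg_sigma2, vg_nu
NIG      -nig_delta (sqrt(nig_alpha^2+k^2)          nig_alpha, nig_delta
           - nig_alpha)
BMJN     BM + JN                                    3 params
BMVG     BM + VG                                    3 params
BMNIG    BM + NIG                                   3 params
=======  =========================================  ====================
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterDomainError, NumericalSupportError

__all__ = ["LEVY_FAMILIES", "cumulant_exponent", "unit_variance",
           "increment_density", "increment_logpdf"]

LEVY_FAMILIES = ("BM", "JN", "VG", "NIG", "BMJN", "BMVG", "BMNIG")

_PARAM_NAMES = {
    "BM": ("sigma2",),
    "JN": ("jump_rate", "jump_var"),
    "VG": ("vg_sigma2", "vg_nu"),
    "NIG": ("nig_alpha", "nig_delta"),
    "BMJN": ("sigma2", "jump_rate", "jump_var"),
    "BMVG": ("sigma2", "vg_sigma2", "vg_nu"),
    "BMNIG": ("sigma2", "nig_alpha", "nig_delta"),
}


def _validate(family: str, params: dict) -> dict:
    if family not in _PARAM_NAMES:
        raise ParameterDomainError(f"unknown Levy family {family!r}")
    need = _PARAM_NAMES[family]
    missing = [p for p in need if p not in params]
    if missing:
        raise ParameterDomainError(f"{family}: missing parameters {missing}")
    p = {k: float(params[k]) for k in need}
    for name, v in p.items():
        if not np.isfinite(v) or v < 0:
            raise ParameterDomainError(f"{family}: {name}={v} must be >= 0")
    if "vg_nu" in p and p["vg_nu"] <= 0:
        raise ParameterDomainError("vg_nu must be > 0")
    if "nig_alpha" in p and p["nig_alpha"] <= 0:
        raise ParameterDomainError("nig_alpha must be > 0")
    return p


def cumulant_exponent(family: str, params: dict, k) -> np.ndarray:
    """Characteristic exponent psi(k); vectorized in k.

    psi(0) = 0, psi(k) <= 0 and psi is even for every implemented family.
    """
    p = _validate(family, params)
    k = np.asarray(k, dtype=float)
    out = np.zeros_like(k)
    if "sigma2" in p:
        out = out - 0.5 * p["sigma2"] * k ** 2
    if "jump_rate" in p:
        out = out + p["jump_rate"] * np.expm1(-0.5 * p["jump_var"] * k ** 2)
    if "vg_sigma2" in p:
        out = out - np.log1p(0.5 * p["vg_sigma2"] * p["vg_nu"] * k ** 2) \
            / p["vg_nu"]
    if "nig_alpha" in p:
        a = p["nig_alpha"]
        out = out - p["nig_delta"] * (np.sqrt(a * a + k * k) - a)
    return out


def unit_variance(family: str, params: dict) -> float:
    """Variance of the increment per unit time, -psi''(0)."""
    p = _validate(family, params)
    v = 0.0
    if "sigma2" in p:
        v += p["sigma2"]
    if "jump_rate" in p:
        v += p["jump_rate"] * p["jump_var"]
    if "vg_sigma2" in p:
        v += p["vg_sigma2"]
    if "nig_alpha" in p:
        v += p["nig_delta"] / p["nig_alpha"]
    return v


_U_CAP = 1e7


def _find_support(expo, log_cutoff: float,
                  tail_tol: float | None = None) -> float:
    """Truncation point U for the frequency integral.

    Accepts U once the integrand either falls below exp(-log_cutoff), or —
    for slowly (polynomially) decaying characteristic functions such as
    variance-gamma with small T/nu — once the analytically bounded tail
    integral ``val(U) * U / (p - 1) / pi`` (local decay exponent
    ``p = -d log val / d log k``) drops below ``tail_tol``.
    """
    U = 16.0
    while U < _U_CAP:
        e = float(np.max(expo(np.array([U]))))
        if e < -log_cutoff:
            return U
        if tail_tol is not None and e < -2.0:
            e2 = float(np.max(expo(np.array([U * 1.05]))))
            p = -(e2 - e) / np.log(1.05)
            if p > 1.2 and np.exp(e) * U / (p - 1.0) / np.pi < tail_tol:
                return U
        U *= 2.0
    raise NumericalSupportError(
        "characteristic function does not decay on the frequency grid; "
        "all diffusion/nugget components are ~0 (pure-jump atom) — "
        "set a positive nugget variance")


def increment_density(family: str, params: dict, T: float, x=None, *,
                      nugget: float = 0.0, n_points: int = 2 ** 12,
                      span_sd: float = 8.0, log_cutoff: float = 40.0):
    """Increment density on a symmetric grid by discretized inversion.

    Parameters
    ----------
    T : elapsed time (> 0)
    x : evaluation grid; default symmetric over +/- span_sd standard
        deviations of the increment (from psi''(0) and the nugget)
    nugget : Gaussian variance convolved into the density (regularizes the
        pure-jump atom at 0)

    Returns
    -------
    (x, f) : grid and densities; negatives from quadrature ringing are
    clipped to 0.
    """
    if T <= 0:
        raise ParameterDomainError("T must be > 0")
    var = unit_variance(family, params) * T + nugget
    if var <= 0:
        raise NumericalSupportError("all components degenerate (variance 0)")
    sd = np.sqrt(var)
    if x is None:
        x = np.linspace(-span_sd * sd, span_sd * sd, n_points)
    else:
        x = np.asarray(x, dtype=float)

    def expo(k):
        e = T * cumulant_exponent(family, params, k)
        if nugget:
            e = e - 0.5 * nugget * k ** 2
        return e

    k_max = _find_support(expo, log_cutoff, tail_tol=3e-8 / sd)
    x_max = max(np.max(np.abs(x)), sd)
    dk = min(np.pi / (6.0 * x_max), k_max / 512.0)
    nk = int(np.ceil(k_max / dk)) + 1
    k = np.linspace(0.0, k_max, nk)
    f = np.zeros(len(x))
    for lo in range(0, nk, 2 ** 16):  # chunked: nk can be large for
        sl = slice(lo, min(lo + 2 ** 16, nk))  # heavy-tailed families
        w = np.exp(expo(k[sl]))
        if lo == 0:
            w[0] *= 0.5
        if sl.stop == nk:
            w[-1] *= 0.5
        f += (w[None, :] * np.cos(np.outer(x, k[sl]))).sum(axis=1)
    f *= (k[1] - k[0]) / np.pi
    return x, np.maximum(f, 0.0)


def increment_logpdf(family: str, params: dict, T, x, *,
                     nugget: float = 0.0, log_cutoff: float = 40.0,
                     points_per_period: int = 6,
                     max_points: int = 2 ** 14) -> np.ndarray:
    """Pointwise log density of increments x_i over times T_i.

    Uses the scaled frequency u = k*sqrt(T_i) so a single u-grid serves all
    increments; the integral for increment i is

        f_i = (1/(pi sqrt(T_i))) Integral exp(T_i psi(u/sqrt(T_i))
              - nugget u^2 / (2 T_i)) cos(u x_i / sqrt(T_i)) du.

    Densities are floored at 1e-300 before the log (quadrature ringing can
    produce tiny negative values deep in the tails).

    The default resolution targets likelihood evaluation inside optimizers
    (relative density error around 1e-4 in the worst short-branch cases);
    raise ``points_per_period`` / ``max_points`` for reference-grade values
    matching :func:`increment_density`.
    """
    T = np.atleast_1d(np.asarray(T, dtype=float))
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(T <= 0):
        raise ParameterDomainError("all T must be > 0")
    _validate(family, params)
    sT = np.sqrt(T)

    def expo(u, Tsub, sTsub):
        kk = u[None, :] / sTsub[:, None]
        e = Tsub[:, None] * cumulant_exponent(family, params, kk)
        if nugget:
            e = e - 0.5 * nugget * kk ** 2
        return e

    uv = unit_variance(family, params)
    sd_min = np.sqrt(np.min(T) * uv + nugget) if uv + nugget > 0 else 1.0
    U = _find_support(lambda u: expo(u, T, sT), log_cutoff,
                      tail_tol=1e-7 / sd_min)
    omega = np.max(np.abs(x) / sT)  # fastest oscillation in u
    du = 2.0 * np.pi / (points_per_period * max(omega, 1e-12))
    n = int(np.ceil(U / du)) + 1
    n = int(np.clip(n, 1024, max_points))
    u = np.linspace(0.0, U, n)
    f = np.empty(len(T))
    chunk = max(1, int(4e6) // n)
    for lo in range(0, len(T), chunk):
        sl = slice(lo, min(lo + chunk, len(T)))
        W = np.exp(expo(u, T[sl], sT[sl]))
        W *= np.cos(u[None, :] * (x[sl] / sT[sl])[:, None])
        W[:, 0] *= 0.5
        W[:, -1] *= 0.5
        f[sl] = W.sum(axis=1) * (u[1] - u[0]) / (np.pi * sT[sl])
    return np.log(np.maximum(f, 1e-300))
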