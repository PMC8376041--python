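"""Multi-exponential models of AP intensity profiles and the staging features.

An intensity profile I(x) along the AP axis (x in %EL) is approximated by a
sum of exponentials,

    I(x) = sum_i C0_i * exp(alpha_i * x)  [+ B],

with up to three components.  Three model kinds are supported:

* ``1expB`` — one decaying exponential plus a uniform background B, the
  classical description of the Bcd protein gradient;
* ``2exp``  — two decaying exponentials, a steep *anterior* component that
  carries most of the signal and a *shallow* posterior one;
* ``3exp``  — additionally a posteriorly *rising* component (alpha > 0),
  needed for some Staufen profiles.

Fitting is bounded nonlinear least squares with an analytic Jacobian,
restarted from several log-linear initializations (multi-exponential fitting
is ill-conditioned, so a single start is not trustworthy).  The decay rates
of decaying components are constrained to [-1, 0] per %EL; the closed upper
bound makes the 1expB model an exact boundary case of 2exp (alpha2 = 0), and
2exp a boundary case of 3exp (C3 = 0).  Because the higher model's restarts
include the lower model's optimum mapped onto that boundary, the fitted SSE
values are nested by construction:  SSE(3exp) <= SSE(2exp) <= SSE(1expB).

The four staging features derived from a pair of (apical, basal) fits are

* lambda1_apical, lambda1_basal — exponential base exp(alpha1) of the
  anterior component in each layer (closer to 1 = shallower gradient);
* cab = ln(C1_apical / C1_basal) — log ratio of anterior amplitudes, whose
  sign encodes which cortical layer is brighter;
* shallow_ratio = (C2_apical*alpha2_apical) / (C2_basal*alpha2_basal) —
  amplitude-slope ratio of the shallow components.

cab and shallow_ratio are invariant under a common positive rescaling of
both layers' intensities, i.e. robust to arbitrary microscope gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls

from .profiles import AxisProfile

__all__ = [
    "ExpComponent",
    "MultiExpFit",
    "FeatureVector",
    "eval_model",
    "multiexp",
    "fit_profile",
    "order_components",
    "select_model",
    "compute_features",
    "fits_to_frame",
    "features_to_frame",
    "DEFAULT_WINDOW_BCD",
    "DEFAULT_WINDOW_STAU",
]

log = logging.getLogger(__name__)

#: Default fit windows in %EL (bcd mRNA vs Staufen protein profiles).
DEFAULT_WINDOW_BCD = (10.0, 90.0)
DEFAULT_WINDOW_STAU = (10.0, 80.0)

_ALPHA_DECAY_LO, _ALPHA_DECAY_HI = -1.0, 0.0
_ALPHA_RISE_LO, _ALPHA_RISE_HI = 0.0, 0.2
_N_FREE = {"1expB": 3, "2exp": 4, "3exp": 6}


@dataclass(frozen=True)
class ExpComponent:
    """One exponential component C0 * exp(alpha * x)."""

    c0: float
    alpha: float

    @property
    def lam(self) -> float:
        """Exponential base per %EL, lambda = exp(alpha)."""
        return float(np.exp(self.alpha))

    @property
    def length_constant(self) -> float:
        """-1/alpha in %EL; NaN for a non-decaying component."""
        return -1.0 / self.alpha if self.alpha < 0 else float("nan")


@dataclass
class MultiExpFit:
    """A fitted multi-exponential model over a %EL window.

    Components are kept in canonical order: the *anterior* component first
    (largest contribution at the window start among decaying components,
    ties broken steeper-alpha-first), then the *shallow* decaying component,
    then a rising component if present.
    """

    kind: str
    components: list[ExpComponent]
    background: float = 0.0
    window: tuple[float, float] = DEFAULT_WINDOW_BCD
    sse: float = float("nan")
    n_points: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _N_FREE:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not self.window[0] < self.window[1]:
            raise ValueError("fit window lo must be < hi")

    @property
    def c0(self) -> np.ndarray:
        return np.array([c.c0 for c in self.components])

    @property
    def alpha(self) -> np.ndarray:
        return np.array([c.alpha for c in self.components])

    @property
    def lam(self) -> np.ndarray:
        return np.exp(self.alpha)

    @property
    def anterior(self) -> ExpComponent:
        return self.components[0]

    @property
    def shallow(self) -> ExpComponent | None:
        """Second decaying component, if the model has one."""
        if len(self.components) >= 2 and self.components[1].alpha <= 0:
            return self.components[1]
        return None


def multiexp(
    x: np.ndarray,
    c0: Sequence[float],
    alpha: Sequence[float],
    background: float = 0.0,
) -> np.ndarray:
    """Evaluate sum_i c0_i * exp(alpha_i * x) + background."""
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, float(background))
    for c, a in zip(c0, alpha):
        out = out + c * np.exp(a * x)
    return out


def eval_model(fit: MultiExpFit, positions: np.ndarray) -> np.ndarray:
    """Evaluate a fitted model at the given %EL positions."""
    return multiexp(positions, fit.c0, fit.alpha, fit.background)


# ---------------------------------------------------------------------------
# fitting internals


def _residual_and_jac(kind: str, x: np.ndarray, y: np.ndarray):
    """Residual and analytic Jacobian callables for least_squares.

    Parameter vector layout: [C_1..C_k, alpha_1..alpha_k, (B)].
    """
    k = {"1expB": 1, "2exp": 2, "3exp": 3}[kind]
    has_b = kind == "1expB"

    def resid(p):
        c, a = p[:k], p[k : 2 * k]
        b = p[-1] if has_b else 0.0
        return multiexp(x, c, a, b) - y

    def jac(p):
        c, a = p[:k], p[k : 2 * k]
        e = np.exp(np.outer(x, a))  # (n, k)
        cols = [e, e * (c[None, :] * x[:, None])]
        if has_b:
            cols.append(np.ones((x.size, 1)))
        return np.concatenate(cols, axis=1)

    return resid, jac


def _bounds(kind: str) -> tuple[np.ndarray, np.ndarray]:
    k = {"1expB": 1, "2exp": 2, "3exp": 3}[kind]
    lo_c = np.zeros(k)
    hi_c = np.full(k, np.inf)
    lo_a = np.full(k, _ALPHA_DECAY_LO)
    hi_a = np.full(k, _ALPHA_DECAY_HI)
    if kind == "3exp":  # third component may rise posteriorly
        lo_a[2], hi_a[2] = _ALPHA_RISE_LO, _ALPHA_RISE_HI
    lo = [lo_c, lo_a]
    hi = [hi_c, hi_a]
    if kind == "1expB":
        lo.append(np.zeros(1))
        hi.append(np.full(1, np.inf))
    return np.concatenate(lo), np.concatenate(hi)


def _solve_linear(x: np.ndarray, y: np.ndarray, alphas, with_background: bool):
    """Given decay rates, solve amplitudes (and background) by NNLS."""
    cols = [np.exp(a * x) for a in alphas]
    if with_background:
        cols.append(np.ones_like(x))
    design = np.column_stack(cols)
    coef, _ = nnls(design, y)
    return coef


def _alpha_grid(n: int, lo: float = -0.5, hi: float = -0.005) -> np.ndarray:
    """Log-spaced decay-rate grid between lo and hi (both negative)."""
    return -np.exp(np.linspace(np.log(-lo), np.log(-hi), n))


def _starts_1expB(x, y, restarts):
    starts = []
    for a in _alpha_grid(max(restarts, 3)):
        c, b = _solve_linear(x, y, [a], with_background=True)
        starts.append(np.array([max(c, 1e-12), a, b]))
    return starts


def _starts_2exp(x, y, restarts, fit1: np.ndarray | None):
    starts = []
    steep = _alpha_grid(max(restarts // 2, 2), lo=-0.6, hi=-0.04)
    shallow = _alpha_grid(max(restarts // 2, 2), lo=-0.05, hi=-0.002)
    pairs = [(a1, a2) for a1 in steep for a2 in shallow][: max(restarts, 4)]
    for a1, a2 in pairs:
        c1, c2 = _solve_linear(x, y, [a1, a2], with_background=False)
        starts.append(np.array([max(c1, 1e-12), max(c2, 0.0), a1, a2]))
    if fit1 is not None:
        # 1expB optimum mapped onto the alpha2 = 0 boundary of 2exp: an
        # exactly equal-SSE start, which guarantees SSE(2exp) <= SSE(1expB).
        c, a, b = fit1
        starts.append(np.array([c, b, a, 0.0]))
    return starts


def _starts_3exp(x, y, restarts, fit2: np.ndarray | None):
    starts = []
    if fit2 is not None:
        c1, c2, a1, a2 = fit2
        # C3 = 0 boundary: equal SSE to the 2exp optimum by construction.
        starts.append(np.array([c1, c2, 0.0, a1, a2, 0.05]))
        for a3 in (0.01, 0.03, 0.08):
            c = _solve_linear(x, y, [a1, a2, a3], with_background=False)
            starts.append(np.array([c[0], c[1], c[2], a1, a2, a3]))
    for a1, a2 in [(-0.2, -0.01), (-0.1, -0.005)][: max(restarts // 4, 1)]:
        for a3 in (0.02, 0.06):
            c = _solve_linear(x, y, [a1, a2, a3], with_background=False)
            starts.append(np.array([c[0], c[1], c[2], a1, a2, a3]))
    return starts


def _run_fit(kind: str, x: np.ndarray, y: np.ndarray, starts):
    resid, jac = _residual_and_jac(kind, x, y)
    lo, hi = _bounds(kind)
    best = None
    for p0 in starts:
        p0 = np.clip(p0, lo, hi)
        try:
            res = least_squares(
                resid,
                p0,
                jac=jac,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=600,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        # candidate set includes the raw start, so an optimizer failure can
        # never make the returned SSE worse than a seeded boundary point
        candidates = [
            (res.x, float(res.cost), res.status > 0),
            (p0, float(0.5 * np.sum(resid(p0) ** 2)), res.status > 0),
        ]
        for p, cost, ok in candidates:
            if best is None or cost < best[1]:
                best = (p, cost, ok)
    if best is None:
        raise RuntimeError(f"all {kind} fit attempts failed")
    p, cost, ok = best
    # polish with a fresh trust region: termination near the optimum leaves
    # ~1e-9 relative parameter error, which the scale-invariance of the
    # derived features relies on being driven to machine precision
    try:
        res = least_squares(
            resid, p, jac=jac, bounds=(lo, hi), method="trf",
            xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=100,
        )
        if res.cost <= cost:
            p, cost = res.x, float(res.cost)
    except Exception:  # pragma: no cover - defensive
        pass
    return p, 2.0 * cost, ok


def fit_profile(
    profile: AxisProfile,
    kind: str = "2exp",
    window: tuple[float, float] = DEFAULT_WINDOW_BCD,
    restarts: int = 8,
    seed: int | None = None,
) -> MultiExpFit:
    """Fit a multi-exponential model to a profile over a %EL window.

    Missing samples (NaN) inside the window are skipped.  The fit is run
    from several deterministic log-linear initializations (``restarts``
    controls the grid density) plus, for 2exp/3exp, the optimum of the next
    simpler model mapped onto the shared boundary; the best-SSE solution is
    returned.  ``seed`` adds random jitter starts on top of the grid when
    given (the grid itself is deterministic).

    Raises
    ------
    ValueError
        If fewer than twice the number of free parameters of ``kind`` are
        available in the window, or the windowed intensities are all zero.
    """
    if kind not in _N_FREE:
        raise ValueError(f"unknown model kind {kind!r}")
    sub = profile.window(*window)
    ok = sub.valid
    x, y = sub.positions[ok], sub.intensities[ok]
    if x.size < 2 * _N_FREE[kind]:
        raise ValueError(
            f"need >= {2 * _N_FREE[kind]} non-missing samples in window, got {x.size}"
        )
    if not np.any(y > 0):
        raise ValueError("all-zero intensities: log-linear initialization undefined")

    # Normalize the intensity scale so the optimizer path (and hence the
    # scale-invariant features) does not depend on the arbitrary a.u. gain.
    yscale = float(np.max(y))
    yn = y / yscale

    p1 = p2 = None
    if kind in ("2exp", "3exp"):
        p1, _, _ = _run_fit("1expB", x, yn, _starts_1expB(x, yn, restarts))
    if kind == "3exp":
        p2, _, _ = _run_fit("2exp", x, yn, _starts_2exp(x, yn, restarts, p1))

    if kind == "1expB":
        starts = _starts_1expB(x, yn, restarts)
    elif kind == "2exp":
        starts = _starts_2exp(x, yn, restarts, p1)
    else:
        starts = _starts_3exp(x, yn, restarts, p2)

    if seed is not None:
        rng = np.random.default_rng(seed)
        base = starts[0]
        for _ in range(max(restarts - len(starts), 0)):
            jit = base.copy()
            k = {"1expB": 1, "2exp": 2, "3exp": 3}[kind]
            jit[k : 2 * k] *= rng.uniform(0.5, 2.0, size=k)
            starts.append(jit)

    p, sse_n, converged = _run_fit(kind, x, yn, starts)

    k = {"1expB": 1, "2exp": 2, "3exp": 3}[kind]
    comps = [ExpComponent(c0=p[i] * yscale, alpha=p[k + i]) for i in range(k)]
    fit = MultiExpFit(
        kind=kind,
        components=comps,
        background=(p[-1] * yscale) if kind == "1expB" else 0.0,
        window=tuple(window),
        sse=sse_n * yscale**2,
        n_points=int(x.size),
        converged=bool(converged),
    )
    return order_components(fit)


def order_components(fit: MultiExpFit) -> MultiExpFit:
    """Canonicalize component order: anterior, shallow, then rising.

    The anterior component is the decaying component with the largest
    contribution C0*exp(alpha*lo) at the window start; ties are broken by
    the steeper (more negative) alpha.  A rising component (alpha > 0) is
    always ranked last regardless of magnitude.
    """
    lo = fit.window[0]
    decaying = [c for c in fit.components if c.alpha <= 0]
    rising = [c for c in fit.components if c.alpha > 0]
    decaying.sort(key=lambda c: (-(c.c0 * np.exp(c.alpha * lo)), c.alpha))
    return replace(fit, components=decaying + rising)


def select_model(
    profile: AxisProfile,
    window: tuple[float, float] = DEFAULT_WINDOW_BCD,
    rel_sse_improvement: float = 0.05,
    restarts: int = 8,
    seed: int | None = None,
) -> str:
    """Choose between 2exp and 3exp for a profile.

    Returns ``"3exp"`` only if the 3exp fit converges, carries a genuinely
    rising third component (alpha > 0 with non-negligible amplitude) and
    reduces the SSE by more than ``rel_sse_improvement`` relative to 2exp;
    otherwise ``"2exp"``.  The 1expB model is for diagnostics only and is
    never selected.
    """
    fit2 = fit_profile(profile, "2exp", window, restarts, seed)
    try:
        fit3 = fit_profile(profile, "3exp", window, restarts, seed)
    except (ValueError, RuntimeError):
        return "2exp"
    third = fit3.components[-1]
    scale = max(c.c0 for c in fit3.components) or 1.0
    rises = third.alpha > 0 and third.c0 > 1e-6 * scale
    if fit3.converged and rises and fit3.sse < (1.0 - rel_sse_improvement) * fit2.sse:
        return "3exp"
    return "2exp"


# ---------------------------------------------------------------------------
# staging features


@dataclass
class FeatureVector:
    """The four developmental-staging features of one embryo."""

    lambda1_apical: float
    lambda1_basal: float
    cab: float
    shallow_ratio: float  # NaN when either layer lacks a shallow component
    embryo_id: str = ""
    stage: str | None = None
    subgroup: str | None = None

    @property
    def has_shallow(self) -> bool:
        return bool(np.isfinite(self.shallow_ratio))

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.lambda1_apical, self.lambda1_basal, self.cab, self.shallow_ratio]
        )

    FEATURE_NAMES = ("lambda1_apical", "lambda1_basal", "cab", "shallow_ratio")


def compute_features(
    fit_apical: MultiExpFit, fit_basal: MultiExpFit, embryo_id: str = "", **meta
) -> FeatureVector:
    """Derive the four staging features from a pair of converged fits.

    Raises ``ValueError`` if either anterior amplitude is non-positive (the
    log ratio cab would be undefined).  A missing shallow component in
    either layer yields ``shallow_ratio = NaN`` (flagged missing, not zero).
    """
    for f in (fit_apical, fit_basal):
        if not f.converged:
            raise ValueError("features require converged fits")
        if len(f.components) < 2:
            raise ValueError("features require >= 2 fitted components")
    a1, b1 = fit_apical.anterior, fit_basal.anterior
    if a1.c0 <= 0 or b1.c0 <= 0:
        raise ValueError("anterior amplitudes must be positive for cab")
    sa, sb = fit_apical.shallow, fit_basal.shallow
    denom = 0.0 if sb is None else sb.c0 * sb.alpha
    numer = 0.0 if sa is None else sa.c0 * sa.alpha
    # a shallow component that collapsed onto the alpha=0 or C=0 boundary
    # carries no slope information; treat the ratio as missing, not huge
    scale = a1.c0 * abs(a1.alpha) + b1.c0 * abs(b1.alpha)
    if sa is None or sb is None or abs(denom) < 1e-9 * scale:
        shallow_ratio = float("nan")
        log.info("shallow component missing/degenerate; shallow_ratio flagged NaN")
    else:
        shallow_ratio = numer / denom
    return FeatureVector(
        lambda1_apical=a1.lam,
        lambda1_basal=b1.lam,
        cab=float(np.log(a1.c0 / b1.c0)),
        shallow_ratio=float(shallow_ratio),
        embryo_id=embryo_id,
        **meta,
    )


# ---------------------------------------------------------------------------
# tabular output


def fits_to_frame(fits: dict[tuple[str, str], MultiExpFit]) -> pd.DataFrame:
    """One row per (embryo_id, layer) fit."""
    rows = []
    for (eid, layer), f in fits.items():
        row = {
            "embryo_id": eid,
            "layer": layer,
            "kind": f.kind,
            "window_lo": f.window[0],
            "window_hi": f.window[1],
            "sse": f.sse,
            "n_points": f.n_points,
            "converged": f.converged,
            "background": f.background,
        }
        for i, c in enumerate(f.components, start=1):
            row[f"c0_{i}"] = c.c0
            row[f"alpha_{i}"] = c.alpha
            row[f"lambda_{i}"] = c.lam
        rows.append(row)
    return pd.DataFrame(rows)


def features_to_frame(features: Sequence[FeatureVector]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "embryo_id": fv.embryo_id,
                "stage": fv.stage,
                "subgroup": fv.subgroup,
                "lambda1_apical": fv.lambda1_apical,
                "lambda1_basal": fv.lambda1_basal,
                "cab": fv.cab,
                "shallow_ratio": fv.shallow_ratio,
            }
            for fv in features
        ]
    )
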