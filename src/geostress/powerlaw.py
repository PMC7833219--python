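"""Power-law relation between the geometric stress index and behavioural
entropy.

Across subjects (or synthetic replicates) the pair (τ_j, bE_j) — geometric
stress index against behavioural entropy of some channel — is summarised by
a two-parameter power law

    α · τ^β ≈ bE,        (α, β) = argmin Σ_j (a · τ_j^b − bE_j)²

over the whole real (a, b) plane. Amplitudes may be negative (a decreasing
channel, e.g. SpO2 entropy falling as stress rises, fits with α < 0), so a
log-log linearisation alone is insufficient; the solver is a deterministic
multistart nonlinear least squares whose start grid includes the log-linear
solution whenever all bE share one sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = ["PowerLawFit", "fit_power_law", "predict_bE", "powerlaw_table"]

#: fixed multistart grid — amplitudes by magnitude and sign, exponents
#: spanning the decaying-to-super-linear range
_AMP_STARTS = (1e-3, 1e-2, 0.1, 1.0, 10.0)
_EXP_STARTS = (-2.0, -1.0, -0.5, -0.1, 0.0, 0.1, 0.5, 1.0, 2.0, 5.0)


@dataclass
class PowerLawFit:
    """Fitted amplitude/exponent with the residual and the data used."""

    amplitude: float
    exponent: float
    residual: float  # l2 norm of (fitted − observed)
    tau: np.ndarray = field(repr=False)
    be: np.ndarray = field(repr=False)

    def predict(self, tau: np.ndarray | float) -> np.ndarray | float:
        return predict_bE(self, tau)

    def to_json_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "exponent": self.exponent,
            "residual_l2": self.residual,
            "n_pairs": int(self.tau.size),
        }


def _residuals(params: np.ndarray, tau: np.ndarray, be: np.ndarray) -> np.ndarray:
    a, b = params
    with np.errstate(over="ignore", invalid="ignore"):
        r = a * tau**b - be
    # distant multistart points can overflow; a huge finite penalty keeps
    # the solver moving instead of erroring out
    return np.nan_to_num(r, nan=1e150, posinf=1e150, neginf=-1e150)


def fit_power_law(
    tau: np.ndarray,
    be: np.ndarray,
    *,
    extra_starts: list[tuple[float, float]] | None = None,
) -> PowerLawFit:
    """Least-squares fit of bE ≈ α·τ^β over (α, β) ∈ R².

    Parameters
    ----------
    tau : array
        Stress-index values, all in (0, 1].
    be : array
        Behavioural-entropy values, same length.
    extra_starts : list of (a, b), optional
        Additional multistart initial points; adding starts can only keep
        or lower the final residual.

    Deterministic for fixed inputs: the multistart grid is fixed, ties
    between local optima are broken by smallest residual then smallest |β|.
    """
    tau = np.asarray(tau, dtype=float)
    be = np.asarray(be, dtype=float)
    if tau.size != be.size:
        raise ValueError("tau and be must have equal length")
    if tau.size < 2:
        raise ValueError("need at least 2 (tau, bE) pairs")
    if np.any(tau <= 0) or np.any(tau > 1):
        raise ValueError("all tau values must lie in (0, 1]")
    if np.ptp(tau) == 0:
        raise ValueError("all tau equal: exponent unidentifiable")

    starts: list[tuple[float, float]] = []
    # data-driven starts: flat law at the mean, and the log-linear solution
    # when every bE shares one nonzero sign
    starts.append((float(be.mean()), 0.0))
    if np.all(be > 0) or np.all(be < 0):
        sign = 1.0 if be[0] > 0 else -1.0
        X = np.column_stack([np.ones(tau.size), np.log(tau)])
        coef, *_ = np.linalg.lstsq(X, np.log(np.abs(be)), rcond=None)
        starts.append((sign * float(np.exp(coef[0])), float(coef[1])))
    for amp in _AMP_STARTS:
        for b0 in _EXP_STARTS:
            starts.append((amp, b0))
            starts.append((-amp, b0))
    if extra_starts:
        starts.extend((float(a), float(b)) for a, b in starts_dedup(extra_starts))

    best: tuple[float, float, float] | None = None
    for a0, b0 in starts:
        try:
            sol = least_squares(
                _residuals, x0=[a0, b0], args=(tau, be), method="lm",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
            )
        except Exception:
            continue
        a, b = sol.x
        res = float(np.linalg.norm(_residuals(sol.x, tau, be)))
        cand = (res, abs(b), a)
        if best is None or (cand[0], cand[1]) < (best[0], abs(best[2])):
            best = (res, a, b)
    assert best is not None
    res, a, b = best
    return PowerLawFit(amplitude=float(a), exponent=float(b), residual=res, tau=tau, be=be)


def starts_dedup(pairs: list[tuple[float, float]]) -> list[tuple[float, float]]:
    seen: set[tuple[float, float]] = set()
    out = []
    for p in pairs:
        key = (round(p[0], 12), round(p[1], 12))
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def predict_bE(fit: PowerLawFit, tau: np.ndarray | float):
    """Evaluate the fitted law α·τ^β; τ must be positive (non-integer
    exponents are undefined at and below zero)."""
    t = np.asarray(tau, dtype=float)
    if np.any(t <= 0):
        raise ValueError("tau must be > 0")
    out = fit.amplitude * t**fit.exponent
    return float(out) if np.isscalar(tau) else out


def powerlaw_table(
    be_by_channel: dict[str, np.ndarray],
    tau: np.ndarray,
) -> pd.DataFrame:
    """One power-law row per channel against a shared τ series.

    Columns: amplitude, exponent, ``scaled_l2`` (residual of the fitted
    law) and ``raw_l2`` (distance between the unscaled τ and bE series —
    what the fit improves on), plus an ``error`` column carrying per-row
    failures without aborting the table.
    """
    tau = np.asarray(tau, dtype=float)
    rows = []
    for channel, be in be_by_channel.items():
        be = np.asarray(be, dtype=float)
        row: dict = {"channel": channel}
        try:
            fit = fit_power_law(tau, be)
            row.update(
                amplitude=fit.amplitude,
                exponent=fit.exponent,
                scaled_l2=fit.residual,
                raw_l2=float(np.linalg.norm(tau - be)),
                error=None,
            )
        except ValueError as exc:
            row.update(
                amplitude=np.nan, exponent=np.nan, scaled_l2=np.nan,
                raw_l2=np.nan, error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("channel")
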