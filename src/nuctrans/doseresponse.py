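"""Four-parameter logistic (4PL) dose-response fitting.

The model for normalized translocation y at ligand concentration c is

    y(c) = bottom + (top - bottom) / (1 + (ec50 / c)^hill)

an increasing sigmoid on log-concentration with half-maximal response at
c = ec50. Vehicle points (c = 0) cannot enter the log-dose term; when they
are present they anchor ``bottom`` as a fixed constraint (the curve's limit
as c -> 0) rather than being dropped silently. Fitting is nonlinear least
squares over (top, log ec50, hill) [and bottom when free], multi-started
over hill to avoid plateau-dominated local minima. A monotone-decreasing
response is reported with bottom < top and an ``inverse`` flag rather than
ever returning top < bottom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


def four_pl(conc, bottom: float, top: float, ec50: float, hill: float):
    """Evaluate the 4PL; c = 0 returns ``bottom`` exactly."""
    c = np.asarray(conc, dtype=float)
    out = np.full(c.shape, float(bottom))
    pos = c > 0
    out[pos] = bottom + (top - bottom) / (1.0 + (ec50 / c[pos]) ** hill)
    return out


@dataclass
class DoseResponseResults:
    """Fitted 4PL parameters with residual diagnostics."""

    bottom: float
    top: float
    ec50: float
    hill: float
    inverse: bool
    converged: bool
    bottom_fixed: bool
    sse: float
    residuals: np.ndarray
    conc: np.ndarray
    response: np.ndarray
    ec50_extrapolated: bool
    n_starts_converged: int = 0
    _raw_bottom: float = field(default=0.0, repr=False)
    _raw_top: float = field(default=0.0, repr=False)

    def predict(self, conc):
        return four_pl(conc, self._raw_bottom, self._raw_top, self.ec50, self.hill)

    def summary(self) -> str:
        lines = [
            "Dose-response fit (4-parameter logistic)",
            "----------------------------------------",
            f"n observations     {len(self.conc)}",
            f"bottom             {self.bottom:.6g}"
            + ("  (anchored at vehicle)" if self.bottom_fixed else ""),
            f"top                {self.top:.6g}",
            f"EC50 [nM]          {self.ec50:.6g}"
            + ("  (extrapolated)" if self.ec50_extrapolated else ""),
            f"hill               {self.hill:.6g}",
            f"orientation        {'decreasing (inverse)' if self.inverse else 'increasing'}",
            f"SSE                {self.sse:.6g}",
            f"converged          {self.converged}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data points and fitted curve on a log-concentration axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pos = self.conc > 0
        cmin = self.conc[pos].min() if pos.any() else self.ec50 / 100
        cmax = self.conc[pos].max() if pos.any() else self.ec50 * 100
        grid = np.geomspace(cmin / 3, cmax * 3, 200)
        ax.semilogx(grid, self.predict(grid), "-", label="4PL fit")
        ax.semilogx(self.conc[pos], self.response[pos], "o", label="data")
        if (~pos).any():
            ax.axhline(self.response[~pos].mean(), ls=":", c="grey", label="vehicle")
        ax.set_xlabel("concentration [nM]")
        ax.set_ylabel("normalized translocation")
        ax.legend()
        return ax


class DoseResponseModel:
    """Nonlinear 4PL model bound to (concentration, response) observations."""

    def __init__(self, conc, response):
        self.conc = np.asarray(conc, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if self.conc.shape != self.response.shape or self.conc.ndim != 1:
            raise ValueError("conc and response must be 1-D and the same length")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be >= 0")
        if np.unique(self.conc).size < 5:
            raise ValueError("need >= 5 distinct concentrations for a 4PL fit")

    @classmethod
    def from_dataframe(
        cls, df, conc_col: str = "concentration", response_col: str = "y"
    ) -> "DoseResponseModel":
        return cls(df[conc_col].to_numpy(), df[response_col].to_numpy())

    def fit(
        self, hill_starts=(0.5, 1.0, 2.0), anchor_bottom: float | None = None
    ) -> DoseResponseResults:
        c, y = self.conc, self.response
        has_vehicle = np.any(c == 0)
        if anchor_bottom is not None:
            bottom_fixed, bottom0 = True, float(anchor_bottom)
        elif has_vehicle:
            bottom_fixed, bottom0 = True, float(y[c == 0].mean())
        else:
            bottom_fixed, bottom0 = False, float(y.min())

        pos = c > 0
        cpos = c[pos]
        log_ec50_0 = float(np.mean(np.log(cpos)))
        top0 = float(y.max())
        span = max(top0 - bottom0, 1e-6)

        def residuals(theta):
            if bottom_fixed:
                top, log_e, hill = theta
                bottom = bottom0
            else:
                bottom, top, log_e, hill = theta
            return four_pl(c, bottom, top, np.exp(log_e), hill) - y

        best = None
        n_ok = 0
        for h0 in hill_starts:
            x0 = (
                [top0, log_ec50_0, h0]
                if bottom_fixed
                else [bottom0, top0, log_ec50_0, h0]
            )
            lo = (
                [-np.inf, -np.inf, 0.05]
                if bottom_fixed
                else [-np.inf, -np.inf, -np.inf, 0.05]
            )
            hi = [np.inf] * (len(x0) - 1) + [10.0]
            try:
                res = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
            except Exception:
                continue
            if res.success:
                n_ok += 1
            sse = float(np.sum(res.fun**2))
            if best is None or sse < best[0] - 1e-15:
                best = (sse, res)
        if best is None:
            raise RuntimeError("4PL fit failed to converge from every start")
        sse, res = best
        if bottom_fixed:
            top, log_e, hill = res.x
            bottom = bottom0
        else:
            bottom, top, log_e, hill = res.x
        ec50 = float(np.exp(log_e))
        inverse = top < bottom
        lo_rep, hi_rep = (top, bottom) if inverse else (bottom, top)
        extrapolated = not (cpos.min() <= ec50 <= cpos.max())
        if abs(span) > 1e-6 and abs(top - bottom) < 1e-9 * max(abs(top), 1.0):
            n_ok = 0  # flat fit on non-flat data: treat as non-converged
        return DoseResponseResults(
            bottom=float(lo_rep),
            top=float(hi_rep),
            ec50=ec50,
            hill=float(hill),
            inverse=bool(inverse),
            converged=n_ok > 0,
            bottom_fixed=bottom_fixed,
            sse=sse,
            residuals=res.fun.copy(),
            conc=c.copy(),
            response=y.copy(),
            ec50_extrapolated=bool(extrapolated),
            n_starts_converged=n_ok,
            _raw_bottom=float(bottom),
            _raw_top=float(top),
        )


def fit_dose_response(concs, y, **kwargs) -> DoseResponseResults:
    """Functional wrapper: fit a 4PL to (concentration, response)."""
    return DoseResponseModel(concs, y).fit(**kwargs)
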