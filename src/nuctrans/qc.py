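"""Plate quality control and comparisons versus control.

Z'-factor: Z' = 1 - 3 (sd_pos + sd_neg) / |mean_pos - mean_neg| over the
positive- and negative-control replicate wells; Z' > 0.5 is the usual
"excellent assay" screening threshold and the band the assay is designed to
sit in. Group comparisons follow the screening convention: one-way ANOVA
gate at alpha, then per-sample t-tests versus the control group using the
pooled ANOVA error variance, with Holm-Sidak step-down adjustment of the
p-values (family = all non-control samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def z_prime(pos_wells, neg_wells) -> float:
    """Z'-factor between positive- and negative-control well values."""
    pos = np.asarray(pos_wells, dtype=float)
    neg = np.asarray(neg_wells, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need >= 2 wells per control group")
    sep = abs(pos.mean() - neg.mean())
    if sep == 0:
        raise ValueError("control means are equal; Z' undefined")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep)


@dataclass
class QCReport:
    """ANOVA gate, Holm-Sidak-adjusted comparisons vs control, optional Z'."""

    anova_F: float
    anova_p: float
    alpha: float
    control: str
    comparisons: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample", "mean_diff", "t", "p_raw", "p_adj", "significant"]
        )
    )
    z_prime: float | None = None

    @property
    def any_significant(self) -> bool:
        return bool(len(self.comparisons) and self.comparisons["significant"].any())

    def summary(self) -> str:
        lines = [
            "Plate QC report",
            "---------------",
            f"one-way ANOVA      F = {self.anova_F:.4g}, p = {self.anova_p:.4g}",
            f"alpha              {self.alpha}",
        ]
        if self.z_prime is not None:
            lines.append(f"Z'-factor          {self.z_prime:.3f}")
        if len(self.comparisons):
            lines.append("comparisons vs control (Holm-Sidak adjusted):")
            lines.append(self.comparisons.to_string(index=False))
        else:
            lines.append("no post-hoc comparisons (ANOVA gate not passed)")
        return "\n".join(lines)


def anova_holm_sidak(
    groups: dict, control_id: str, alpha: float = 0.05, z_prime_value: float | None = None
) -> QCReport:
    """One-way ANOVA; if significant, pooled-variance t-tests vs control with
    Holm-Sidak step-down adjustment.

    ``groups`` maps sample id -> replicate well values. The pooled error
    variance is the ANOVA within-group mean square with N - k degrees of
    freedom, as screening packages compute "versus control" comparisons.
    """
    if control_id not in groups:
        raise ValueError(f"control group {control_id!r} absent from groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups including the control")
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")

    F, p = sps.f_oneway(*arrays.values())
    if not np.isfinite(F):  # all groups constant and equal
        F, p = 0.0, 1.0
    report = QCReport(
        anova_F=float(F),
        anova_p=float(p),
        alpha=alpha,
        control=control_id,
        z_prime=z_prime_value,
    )
    if p >= alpha:
        return report

    N = sum(v.size for v in arrays.values())
    k = len(arrays)
    mse = sum((v.size - 1) * v.var(ddof=1) for v in arrays.values()) / (N - k)
    ctrl = arrays[control_id]
    rows = []
    for name, v in arrays.items():
        if name == control_id:
            continue
        diff = v.mean() - ctrl.mean()
        se = np.sqrt(mse * (1.0 / v.size + 1.0 / ctrl.size))
        t = diff / se if se > 0 else np.inf * np.sign(diff)
        praw = 2.0 * sps.t.sf(abs(t), N - k) if np.isfinite(t) else 0.0
        rows.append({"sample": name, "mean_diff": diff, "t": t, "p_raw": praw})
    comp = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(
        comp["p_raw"].to_numpy(), alpha=alpha, method="holm-sidak"
    )
    comp["p_adj"] = p_adj
    comp["significant"] = reject
    report.comparisons = comp
    return report
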