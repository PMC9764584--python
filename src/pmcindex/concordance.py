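"""Formulation–implementation concordance.

The PMC index measures how well a policy *text* is formulated; the expert
field evaluation measures how well it is *implemented* on site.  Their
association is quantified by the Pearson product-moment correlation with the
exact two-tailed t-test (t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of
freedom).  Normality is not pre-tested here; the coefficient and test are
computed unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

__all__ = ["ConcordanceResult", "pearson_concordance", "scatter_plot"]


@dataclass(frozen=True)
class ConcordanceResult:
    """Pearson correlation between paired score vectors with its two-tailed test."""

    n: int
    r: float
    p_two_tailed: float
    alpha: float
    significant: bool


def pearson_concordance(pmc, expert, alpha: float = 0.05) -> ConcordanceResult:
    """Pearson r between PMC indices and expert totals, with a two-tailed test.

    Pearson r is invariant under positive affine rescaling of either vector,
    so it does not matter whether expert totals are on the raw or the
    percentage scale.  Requires n >= 3 and two non-constant vectors.
    """
    x = np.asarray(pmc, dtype=float)
    y = np.asarray(expert, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"paired 1-d vectors required, got {x.shape} and {y.shape}")
    if len(x) < 3:
        raise ValueError("at least 3 pairs are needed for the t-test (n-2 df)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    return ConcordanceResult(len(x), r, p, alpha, p < alpha)


def scatter_plot(pmc, expert, out: str | Path, *,
                 xlabel: str = "PMC index",
                 ylabel: str = "Expert field-evaluation total") -> Path:
    """Deterministic scatter of expert totals against PMC with an OLS trend line.

    With fewer than 3 pairs the trend line (and any inference annotation) is
    omitted — a line through <= 2 points carries no information.
    """
    x = np.asarray(pmc, dtype=float)
    y = np.asarray(expert, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors required")
    out = Path(out)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(x, y, color="tab:blue", zorder=3)
    if len(x) >= 3 and np.ptp(x) > 0:
        slope, intercept = np.polyfit(x, y, 1)
        grid = np.linspace(x.min(), x.max(), 50)
        ax.plot(grid, intercept + slope * grid, color="tab:red", lw=1.5)
        if np.ptp(y) > 0:
            res = pearson_concordance(x, y)
            ax.set_title(f"r = {res.r:.3f}, two-tailed p = {res.p_two_tailed:.3f} "
                         f"(n = {res.n})")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    try:
        fig.savefig(out, dpi=120)
    except OSError as exc:
        raise OSError(f"cannot write scatter plot to {out}: {exc}") from exc
    finally:
        plt.close(fig)
    return out
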