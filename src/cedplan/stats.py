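"""Paired-outcome statistics and reporting for the trajectory comparison.

Safety verdicts are paired binary outcomes (0 = unsafe, 1 = safe) per
hemisphere for the frontal and occipital approaches; they feed a 2x2
contingency table and a mid-p McNemar test.  Coverage fractions are paired
real outcomes compared with a paired t-test, and summary means carry
t-based 95% confidence intervals.  Heat maps of connection-presence counts
render with a fixed 0..2n color scale.

The mid-p McNemar test used here is the standard two-sided form: with
n_d = b + c discordant pairs, m = max(b, c) and X ~ Binomial(n_d, 1/2),

    p_mid = 2 P(X >= m) - P(X = m),   capped at 1,  and 1 when n_d = 0.

It is less conservative than the exact conditional test because the point
probability is only half-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "PairedSample",
    "build_contingency",
    "proportions",
    "midp_mcnemar",
    "paired_t",
    "summarize_mean_ci",
    "render_heatmap",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Paired safety counts: a both-safe, b first-only-safe, c
    second-only-safe, d both-unsafe."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("contingency counts must be non-negative integers")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class PairedSample:
    """Per-hemisphere (frontal, occipital) outcome pairs, binary or real."""

    frontal: np.ndarray
    occipital: np.ndarray

    def __post_init__(self) -> None:
        self.frontal = np.asarray(self.frontal, dtype=float)
        self.occipital = np.asarray(self.occipital, dtype=float)
        if self.frontal.shape != self.occipital.shape or self.frontal.ndim != 1:
            raise ValueError("paired vectors must be 1-D and equal length")

    def __len__(self) -> int:
        return len(self.frontal)


def build_contingency(pairs: PairedSample) -> ContingencyTable:
    """Count the four paired binary outcomes (1 = safe, 0 = unsafe)."""
    f, o = pairs.frontal, pairs.occipital
    if not (np.isin(f, (0, 1)).all() and np.isin(o, (0, 1)).all()):
        raise ValueError("build_contingency expects binary outcomes in {0, 1}")
    return ContingencyTable(
        a=int(np.sum((f == 1) & (o == 1))),
        b=int(np.sum((f == 1) & (o == 0))),
        c=int(np.sum((f == 0) & (o == 1))),
        d=int(np.sum((f == 0) & (o == 0))),
    )


def proportions(t: ContingencyTable) -> dict:
    """Marginal safe proportions and the discordant-pair split.

    The discordant fractions are undefined (None, flagged) when b = c = 0.
    """
    if t.n == 0:
        raise ValueError("empty contingency table")
    n_disc = t.b + t.c
    out = {
        "p_frontal_safe": (t.a + t.b) / t.n,
        "p_occipital_safe": (t.a + t.c) / t.n,
        "n_discordant": n_disc,
        "frac_discordant_frontal": t.b / n_disc if n_disc else None,
        "frac_discordant_occipital": t.c / n_disc if n_disc else None,
        "discordant_defined": n_disc > 0,
    }
    return out


def midp_mcnemar(t: ContingencyTable) -> float:
    """Two-sided mid-p McNemar p-value on the discordant pairs (see module
    docstring); 1.0 when there are no discordant pairs."""
    n_d = t.b + t.c
    if n_d == 0:
        return 1.0
    m = max(t.b, t.c)
    p = 2.0 * sps.binom.sf(m - 1, n_d, 0.5) - sps.binom.pmf(m, n_d, 0.5)
    return float(min(p, 1.0))


def paired_t(pairs: PairedSample) -> dict:
    """One-sample t on the frontal-minus-occipital differences with a
    two-sided p and a t-based 95% CI.

    Zero-variance differences return a flagged degenerate result (t and p
    undefined) rather than NaN surprises.
    """
    if len(pairs) < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    diff = pairs.frontal - pairs.occipital
    n = len(diff)
    mean = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    if sd == 0.0:
        return {
            "mean_diff": mean, "ci95_lo": mean, "ci95_hi": mean,
            "t_stat": 0.0 if mean == 0 else np.inf,
            "p": 1.0 if mean == 0 else 0.0,
            "degenerate": True, "n": n,
        }
    se = sd / np.sqrt(n)
    t_stat = mean / se
    p = float(2.0 * sps.t.sf(abs(t_stat), df=n - 1))
    q = float(sps.t.ppf(0.975, df=n - 1))
    return {
        "mean_diff": mean,
        "ci95_lo": mean - q * se,
        "ci95_hi": mean + q * se,
        "t_stat": float(t_stat),
        "p": p,
        "degenerate": False,
        "n": n,
    }


def summarize_mean_ci(values) -> dict:
    """Mean with t-based 95% CI; a constant vector has a zero-width CI."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need at least 2 values")
    mean = float(np.mean(v))
    se = float(np.std(v, ddof=1) / np.sqrt(len(v)))
    q = float(sps.t.ppf(0.975, df=len(v) - 1))
    return {"mean": mean, "ci95_lo": mean - q * se, "ci95_hi": mean + q * se, "n": len(v)}


def render_heatmap(counts: pd.DataFrame, scale_max: int, out_png=None, out_csv=None,
                   title: str = "Connection presence (hemispheres)"):
    """Render a region x segment count matrix with a fixed 0..scale_max
    color scale; the CSV mirrors the matrix bit-exactly."""
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if out_csv is not None:
        counts.to_csv(out_csv)
    fig = None
    if out_png is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1.2 * len(counts.columns) + 3, 0.6 * len(counts) + 2))
        im = ax.imshow(arr, cmap="viridis", vmin=0, vmax=scale_max, aspect="auto")
        ax.set_xticks(range(len(counts.columns)), counts.columns, rotation=30, ha="right")
        ax.set_yticks(range(len(counts.index)), counts.index)
        for (i, j), v in np.ndenumerate(arr):
            ax.text(j, i, str(int(v)), ha="center", va="center",
                    color="white" if v < scale_max / 2 else "black", fontsize=8)
        fig.colorbar(im, ax=ax, label=f"hemispheres (0-{scale_max})")
        ax.set_title(title)
        fig.tight_layout()
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return counts
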