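"""Quintile risk gradients: aggregation, reference-1 normalization, output.

The gradient is the vector of five quintile-specific relative risks of the
outcome, normalized so the quintile with the lowest mean risk (the
reference, usually the wealthiest) equals exactly 1.  Uncertainty intervals
are 95% percentile intervals across the solution ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import N_QUINTILES, write_gradients

ROMAN = ("I", "II", "III", "IV", "V")


@dataclass
class QuintileGradient:
    """Normalized per-quintile relative risks with uncertainty summaries.

    ``reference`` is the quintile (1..5) whose mean risk attained the
    minimum and was set to 1.
    """

    mean: np.ndarray
    median: np.ndarray
    ui_low: np.ndarray
    ui_high: np.ndarray
    reference: int

    def __post_init__(self) -> None:
        for name in ("mean", "median", "ui_low", "ui_high"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_QUINTILES,):
                raise ValueError(f"gradient {name}: need 5 quintile values")
            setattr(self, name, arr)
        if not (1 <= self.reference <= N_QUINTILES):
            raise ValueError("reference quintile must be in 1..5")


def quintile_risks(deaths: np.ndarray, pop: np.ndarray) -> np.ndarray:
    """Per-replicate risk per child: deaths[r, q] / pop[q].

    ``deaths`` is K x 5 (one row per ensemble replicate), ``pop`` the
    weighted child count per quintile.
    """
    deaths = np.atleast_2d(np.asarray(deaths, dtype=float))
    pop = np.asarray(pop, dtype=float)
    if pop.shape != (N_QUINTILES,) or deaths.shape[1] != N_QUINTILES:
        raise ValueError("need 5 quintiles in deaths and pop")
    if np.any(pop <= 0):
        raise ValueError("zero-population quintile; risks undefined")
    return deaths / pop[None, :]


def normalize_gradient(risks: np.ndarray) -> QuintileGradient:
    """Normalize per-replicate risk vectors to the reference-value-1 scale.

    The reference quintile minimizes the across-replicate mean risk; the
    mean gradient is the mean risks divided by that minimum (so its minimum
    is exactly 1).  Medians and percentile intervals are computed on the
    per-replicate vectors, each divided by its own value at the reference
    quintile.
    """
    risks = np.atleast_2d(np.asarray(risks, dtype=float))
    if risks.shape[1] != N_QUINTILES:
        raise ValueError("need 5 quintile risks per replicate")
    if np.any(risks <= 0):
        raise ValueError("risks must be positive for normalization")
    mean = risks.mean(axis=0)
    ref = int(np.argmin(mean))
    mean_grad = mean / mean[ref]
    mean_grad[ref] = 1.0  # exact, despite floating division
    rel = risks / risks[:, [ref]]
    return QuintileGradient(
        mean=mean_grad,
        median=np.median(rel, axis=0),
        ui_low=np.percentile(rel, 2.5, axis=0),
        ui_high=np.percentile(rel, 97.5, axis=0),
        reference=ref + 1,
    )


def main_analysis(grad_a: QuintileGradient, grad_c: QuintileGradient) -> QuintileGradient:
    """Average two normalized gradients and renormalize to reference 1.

    Used for the headline result: the mean of the direct (A) and
    u5mr-extrapolated (C) linking approaches.
    """
    stacks = {}
    for name in ("mean", "median", "ui_low", "ui_high"):
        a, c = getattr(grad_a, name), getattr(grad_c, name)
        if a.shape != c.shape:
            raise ValueError("gradient length mismatch")
        stacks[name] = (np.asarray(a, float) + np.asarray(c, float)) / 2.0
    ref = int(np.argmin(stacks["mean"]))
    scale = stacks["mean"][ref]
    out = {name: arr / scale for name, arr in stacks.items()}
    out["mean"][ref] = 1.0
    return QuintileGradient(reference=ref + 1, **out)


def render_outputs(
    gradients: dict[str, QuintileGradient],
    outdir: str | Path,
    *,
    figure_format: str = "png",
) -> list[Path]:
    """Write one CSV per disease plus a combined bar-chart figure.

    Deterministic file naming: ``gradient_<disease>.csv`` and
    ``gradients.<fmt>``; re-running with identical inputs reproduces the
    CSVs byte for byte.
    """
    if not gradients:
        raise ValueError("no gradients to render")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for disease in sorted(gradients):
        path = outdir / f"gradient_{disease}.csv"
        write_gradients(gradients[disease], path)
        written.append(path)
    written.append(_render_figure(gradients, outdir / f"gradients.{figure_format}"))
    return written


def _render_figure(gradients: dict[str, QuintileGradient], path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = sorted(gradients)
    fig, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 3.2), squeeze=False)
    for ax, name in zip(axes[0], names):
        g = gradients[name]
        x = np.arange(N_QUINTILES)
        yerr = np.vstack(
            [np.maximum(g.mean - g.ui_low, 0.0), np.maximum(g.ui_high - g.mean, 0.0)]
        )
        ax.bar(x, g.mean, color="#4878a8", yerr=yerr, capsize=3)
        ax.axhline(1.0, color="0.4", lw=0.8, ls="--")
        ax.set_xticks(x, ROMAN)
        ax.set_xlabel("wealth quintile")
        ax.set_ylabel("relative risk of death")
        ax.set_title(name)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
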