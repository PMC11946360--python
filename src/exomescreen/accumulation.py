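"""Carrier-accumulation (panel-saturation) curves.

As the screened panel grows, the fraction of animals with at least one
detected variant rises toward the full-panel detection proportion. The curve
is estimated by drawing random variant subsets of increasing size — either
NESTED (each subset extends the previous one within a replicate, so every
replicate's curve is monotone) or INDEPENDENT (a fresh draw per size) — and
averaging the per-subset proportion of samples with >=1 detection over
replicates. The final point is always the full panel and is therefore
independent of the seed, the mode and the replicate count.

For INDEPENDENT mode an exact (exhaustive-expectation) evaluation is
available: for a sample with d detected variants out of n, the probability
that a uniform size-k subset misses all of them is C(n-d, k) / C(n, k), so
the expected proportion needs no sampling at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["Mode", "AccumulationCurve", "accumulate", "default_sizes", "write_curve", "plot_curve"]


class Mode(str, Enum):
    NESTED = "NESTED"
    INDEPENDENT = "INDEPENDENT"


@dataclass
class AccumulationCurve:
    subset_sizes: tuple[int, ...]
    proportions: tuple[float, ...]          # mean over replicates
    replicate_min: tuple[float, ...]
    replicate_max: tuple[float, ...]
    replicate_curves: np.ndarray            # (n_replicates, n_sizes)
    n_replicates: int
    seed: int
    mode: Mode

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subset_size": self.subset_sizes,
                "proportion": self.proportions,
                "replicate_min": self.replicate_min,
                "replicate_max": self.replicate_max,
            }
        )


def default_sizes(panel_size: int, step: int = 50) -> list[int]:
    """The default subset-size grid: multiples of ``step`` up to the panel size."""
    return list(range(step, panel_size, step))


def accumulate(
    dm: pd.DataFrame,
    sizes: Sequence[int] | None = None,
    seed: int = 0,
    n_replicates: int = 100,
    mode: Mode = Mode.NESTED,
    step: int = 50,
    exhaustive: bool = False,
) -> AccumulationCurve:
    """Estimate the proportion of samples with >=1 detection per subset size.

    ``dm`` is a samples x variants dosage matrix (NaN treated as 0). The
    full-panel point is always appended. With ``exhaustive=True`` (INDEPENDENT
    mode only) proportions are exact expectations over all subsets of each
    size rather than Monte Carlo averages.
    """
    if dm.empty:
        raise ValidationError("detection matrix is empty")
    detected = (dm.fillna(0).to_numpy() >= 1)
    n_samples, n_panel = detected.shape
    if sizes is None:
        sizes = default_sizes(n_panel, step=step)
    sizes = list(sizes)
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValidationError("subset sizes must be strictly increasing")
    if sizes and sizes[-1] > n_panel:
        raise ValidationError(f"subset size {sizes[-1]} exceeds panel size {n_panel}")
    if not sizes or sizes[-1] != n_panel:
        sizes.append(n_panel)

    full_point = int(detected.any(axis=1).sum()) / n_samples  # exact count ratio

    if exhaustive:
        if mode is not Mode.INDEPENDENT:
            raise ValidationError("exhaustive evaluation requires INDEPENDENT mode")
        props = [_exact_proportion(detected, k) for k in sizes]
        props[-1] = full_point
        curves = np.asarray([props])
        return AccumulationCurve(
            subset_sizes=tuple(sizes),
            proportions=tuple(props),
            replicate_min=tuple(props),
            replicate_max=tuple(props),
            replicate_curves=curves,
            n_replicates=1,
            seed=seed,
            mode=mode,
        )

    rng = np.random.default_rng(seed)
    curves = np.empty((n_replicates, len(sizes)))
    for r in range(n_replicates):
        if mode is Mode.NESTED:
            order = rng.permutation(n_panel)
            for j, k in enumerate(sizes):
                subset = order[:k]
                curves[r, j] = float(np.mean(detected[:, subset].any(axis=1)))
        else:
            for j, k in enumerate(sizes):
                subset = rng.choice(n_panel, size=k, replace=False)
                curves[r, j] = float(np.mean(detected[:, subset].any(axis=1)))
    curves[:, -1] = full_point  # full panel: no sampling variability
    proportions = [float(p) for p in curves.mean(axis=0)]
    proportions[-1] = full_point  # keep the exact count ratio
    return AccumulationCurve(
        subset_sizes=tuple(sizes),
        proportions=tuple(proportions),
        replicate_min=tuple(curves.min(axis=0)),
        replicate_max=tuple(curves.max(axis=0)),
        replicate_curves=curves,
        n_replicates=n_replicates,
        seed=seed,
        mode=mode,
    )


def _exact_proportion(detected: np.ndarray, k: int) -> float:
    """Exact E[fraction of samples with >=1 hit] over uniform size-k subsets."""
    n = detected.shape[1]
    total = 0.0
    denom = comb(n, k)
    for d in detected.sum(axis=1):
        miss = comb(n - int(d), k) / denom if n - int(d) >= k else 0.0
        total += 1.0 - miss
    return total / detected.shape[0]


def write_curve(curve: AccumulationCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def plot_curve(curve: AccumulationCurve, path: str | Path) -> None:
    """Save the saturation curve as a figure (mean with replicate min/max band)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(
        curve.subset_sizes, curve.replicate_min, curve.replicate_max,
        alpha=0.25, label="replicate range",
    )
    ax.plot(curve.subset_sizes, curve.proportions, marker="o", label="mean")
    ax.set_xlabel("number of variants screened")
    ax.set_ylabel("proportion of samples with ≥1 detected variant")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
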