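"""Exponential decay of shared-homozygosity loss and cohort-size prediction.

As same-breed individuals are added to a shared-homozygosity calculation,
the LnH retained by the growing cohort shrinks, and the per-individual
loss y_t follows an approximately geometric decline

    y_t = a * exp(-k * (t - 1)),

where t = 1 indexes the loss caused by the second individual and a is
that first loss. The decay rate k is estimated by ordinary least squares
on ln(y_t) versus (t - 1). Inverting the model at a target per-individual
loss y* gives the cohort size needed before additional individuals stop
removing homozygosity:

    t* = 1 + ln(a / y*) / k,   cohort = 1 + ceil(t*).

Two standard thresholds are exposed: y* equal to 1% of the first
individual's LnH, and y* = 1 bp. Because e^-k, not k, is the per-step
multiplier, the per-individual fractional decrease 1 - e^-k is reported
alongside k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .homozygosity import RoHParams, incremental_shared_curve

__all__ = [
    "DecayCurve",
    "DecayFit",
    "CohortPrediction",
    "build_decay_curve",
    "fit_decay",
    "predict_cohort_size",
    "decay_over_orders",
]


@dataclass
class DecayCurve:
    lnh_1: float                 # first-individual private LnH (bp)
    losses: np.ndarray           # y_t for t = 1..n-1 (bp)

    @property
    def a(self) -> float:
        return float(self.losses[0])


@dataclass
class DecayFit:
    k: float
    a_hat: float
    r_squared: float
    n_points: int
    lnh_1: float
    t_1pct: "CohortPrediction | None" = None
    t_1nt: "CohortPrediction | None" = None
    defined: bool = True
    reason: str = ""

    @property
    def per_dog_fraction(self) -> float:
        """Fractional decrease of the loss per added individual, 1 - e^-k."""
        return 1.0 - math.exp(-self.k)


@dataclass
class CohortPrediction:
    t_star: float                # additional individuals (continuous)
    cohort_size: int             # 1 + ceil(t_star)
    threshold_bp: float
    capped: bool = False
    note: str = ""


def build_decay_curve(points: Sequence[tuple[int, float]]) -> DecayCurve:
    """Successive LnH differences from a (t, LnH_t) shared curve.

    ``points`` must cover at least three cohort sizes with non-increasing
    LnH; an increase raises a ValueError naming the offending step.
    """
    pts = sorted((int(t), float(v)) for t, v in points)
    if len(pts) < 3:
        raise ValueError("need at least 3 cohort sizes to form a decay curve")
    lnh = np.asarray([v for _, v in pts])
    ts = [t for t, _ in pts]
    losses = -np.diff(lnh)
    bad = np.flatnonzero(losses < 0)
    if len(bad):
        raise ValueError(
            f"shared LnH increases between t={ts[bad[0]]} and t={ts[bad[0]+1]}"
        )
    return DecayCurve(lnh_1=float(lnh[0]), losses=losses)


def fit_decay(curve: DecayCurve, fix_intercept: bool = False) -> DecayFit:
    """Estimate the decay rate k by log-linear least squares.

    Zero losses cannot enter the log fit and are excluded with a warning;
    fewer than two usable points raises. With ``fix_intercept`` the
    intercept is pinned at ln(a) (the observed first loss) and only the
    slope is estimated.
    """
    y = np.asarray(curve.losses, dtype=float)
    t = np.arange(1, len(y) + 1)
    use = y > 0
    if (~use).any():
        warnings.warn(
            f"{int((~use).sum())} zero loss point(s) excluded from log fit",
            stacklevel=2,
        )
    y, t = y[use], t[use]
    if len(y) < 2:
        raise ValueError("fewer than 2 positive losses; decay fit impossible")
    x = (t - 1).astype(float)
    ln_y = np.log(y)
    if fix_intercept:
        ln_a = math.log(curve.a)
        slope = float(np.dot(x, ln_y - ln_a) / np.dot(x, x))
        intercept = ln_a
    else:
        slope, intercept = np.polyfit(x, ln_y, 1)
    fitted = intercept + slope * x
    ss_res = float(((ln_y - fitted) ** 2).sum())
    ss_tot = float(((ln_y - ln_y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    fit = DecayFit(
        k=float(-slope),
        a_hat=float(np.exp(intercept)),
        r_squared=r2,
        n_points=len(y),
        lnh_1=curve.lnh_1,
    )
    if fit.k > 0:
        fit.t_1pct = predict_cohort_size(fit, curve.lnh_1, "one_percent")
        fit.t_1nt = predict_cohort_size(fit, curve.lnh_1, "one_nucleotide")
    else:
        fit.defined = False
        fit.reason = "non-positive decay rate"
    return fit


def predict_cohort_size(
    fit: DecayFit,
    lnh_1: float,
    threshold: str | float = "one_percent",
) -> CohortPrediction:
    """Cohort size at which per-individual LnH loss falls to a target.

    ``threshold`` is "one_percent" (1% of the first individual's LnH),
    "one_nucleotide" (1 bp), or an explicit bp value. Solves
    a e^{-k (t-1)} = y* for t; the reported cohort is the initial
    individual plus the ceiling of the additional individuals.
    """
    if fit.k <= 0 or fit.a_hat <= 0:
        raise ValueError("prediction requires k > 0 and a > 0")
    if threshold == "one_percent":
        y_star = 0.01 * lnh_1
    elif threshold == "one_nucleotide":
        y_star = 1.0
    else:
        y_star = float(threshold)
    if y_star >= fit.a_hat:
        return CohortPrediction(
            t_star=1.0,
            cohort_size=2,
            threshold_bp=y_star,
            capped=True,
            note="threshold met at second individual",
        )
    t_star = 1.0 + math.log(fit.a_hat / y_star) / fit.k
    return CohortPrediction(
        t_star=t_star,
        cohort_size=int(math.ceil(t_star)) + 1,
        threshold_bp=y_star,
    )


@dataclass
class DecayEnsemble:
    fits: list[DecayFit | None]       # None where the fit was undefined
    order_seeds: list[int]

    @property
    def k_values(self) -> np.ndarray:
        return np.asarray([f.k for f in self.fits if f is not None])

    def summary(self) -> dict:
        ks = self.k_values
        return {
            "n_orders": len(self.fits),
            "n_defined": int(len(ks)),
            "k_mean": float(ks.mean()) if len(ks) else None,
            "k_sd": float(ks.std(ddof=1)) if len(ks) > 1 else None,
        }


def decay_over_orders(
    g: GenotypeMatrix,
    ids: Sequence[str],
    params: RoHParams | None = None,
    n_orders: int = 20,
    seed: int | None = None,
) -> DecayEnsemble:
    """Decay fits over repeated random addition orders.

    Stabilizes the single random order of the incremental shared curve by
    refitting over ``n_orders`` seeded permutations; undefined fits (all
    losses zero, e.g. identical genotypes) are kept as None entries.
    """
    if len(ids) < 3:
        raise ValueError("need at least 3 individuals")
    rng = np.random.default_rng(seed)
    order_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_orders)]
    fits: list[DecayFit | None] = []
    for s in order_seeds:
        curve_df = incremental_shared_curve(g, ids, params, order_seed=s)
        curve = build_decay_curve(list(zip(curve_df["t"], curve_df["lnh"])))
        if (curve.losses > 0).sum() < 2:
            fits.append(None)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits.append(fit_decay(curve))
    return DecayEnsemble(fits=fits, order_seeds=order_seeds)
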