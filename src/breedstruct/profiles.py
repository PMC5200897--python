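"""Per-breed profile assembly, cross-metric correlation, Ne timelines.

A :class:`BreedProfile` aggregates everything the pipeline computes for
one breed — pedigree demography (g_e, depth-limited F, Ne, effective
founder counts), genomic homozygosity per marker panel (genotype F,
RoH/LnH, the shared-cohort curve) and the decay fit with predicted
cohort sizes. Any metric that was not computed is explicitly recorded as
absent, never silently zero. Profiles serialize to JSON and can be
correlated across breeds with Pearson statistics (pairwise-complete,
raw p-values with a Bonferroni column emitted for transparency).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import pedigree as pm
from .decay import decay_over_orders
from .genotypes import GenotypeMatrix
from .homozygosity import (
    RoHParams,
    call_roh,
    genotype_inbreeding,
    incremental_shared_curve,
)

__all__ = [
    "PearsonResult",
    "NeTimeline",
    "BreedProfile",
    "pearson_correlation",
    "ne_timeline_slopes",
    "build_breed_profile",
    "correlate_profiles",
]

GENERATION_INTERVAL_YEARS = 3.76


@dataclass
class PearsonResult:
    r: float | None
    t_statistic: float | None
    p_value: float | None
    n: int
    defined: bool = True
    reason: str = ""


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> PearsonResult:
    """Product-moment correlation with t statistic and two-sided p.

    Pairs with any missing value are dropped; needs >= 3 complete pairs.
    t = r sqrt((n-2)/(1-r^2)), p from Student's t with n-2 df. Zero
    variance in either vector yields an explicitly undefined result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return PearsonResult(
            r=None, t_statistic=None, p_value=None, n=n,
            defined=False, reason="zero variance",
        )
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return PearsonResult(r=r, t_statistic=math.inf * np.sign(r),
                             p_value=0.0, n=n)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return PearsonResult(r=r, t_statistic=t, p_value=p, n=n)


# ---------------------------------------------------------------------------
# Ne timelines
# ---------------------------------------------------------------------------

@dataclass
class NeTimeline:
    """Externally estimated Ne per generations-before-sampling.

    The table is anchored to calendar years through ``anchor_year`` (the
    sampling year) and a generation interval in years.
    """

    generations_ago: np.ndarray
    ne: np.ndarray
    anchor_year: int
    generation_interval: float = GENERATION_INTERVAL_YEARS

    def __post_init__(self) -> None:
        g = np.asarray(self.generations_ago, dtype=float)
        if np.any(np.diff(g) <= 0):
            raise ValueError("generations_ago must be strictly increasing")
        self.generations_ago = g
        self.ne = np.asarray(self.ne, dtype=float)

    @classmethod
    def from_tsv(cls, path, anchor_year: int,
                 generation_interval: float = GENERATION_INTERVAL_YEARS):
        df = pd.read_csv(path, sep="\t")
        return cls(
            generations_ago=df.iloc[:, 0].to_numpy(),
            ne=df.iloc[:, 1].to_numpy(),
            anchor_year=anchor_year,
            generation_interval=generation_interval,
        )

    def ne_at(self, gen: float) -> float:
        g = self.generations_ago
        if gen < g[0] or gen > g[-1]:
            raise ValueError(
                f"generation {gen:.2f} outside tabulated range "
                f"[{g[0]:.0f}, {g[-1]:.0f}]"
            )
        return float(np.interp(gen, g, self.ne))


@dataclass
class NeSlopes:
    gen_at_recognition: float
    ne_at_recognition: float
    slope_post: float           # ΔNe per generation, gen 13 -> recognition
    slope_pre: float            # over the mirror-image earlier span
    slope_difference: float     # pre − post


def ne_timeline_slopes(
    tl: NeTimeline, recognition_year: int, base_generation: float = 13.0
) -> NeSlopes:
    """Rates of Ne change on either side of breed recognition.

    The recognition year converts to generations before sampling through
    the generation interval; Ne is linearly interpolated between
    tabulated generations. The post-recognition slope spans generation
    ``base_generation`` to the recognition point; the pre-recognition
    slope spans an equally long window further back. Slopes are
    ΔNe/Δgeneration with the older time point first, so a population
    shrinking toward the present has a positive slope.
    """
    if recognition_year >= tl.anchor_year:
        raise ValueError("recognition_year must precede the anchor year")
    gen_rec = (tl.anchor_year - recognition_year) / tl.generation_interval
    if gen_rec <= base_generation:
        raise ValueError(
            f"recognition at generation {gen_rec:.2f} is not older than the "
            f"base generation {base_generation}"
        )
    gen_pre = 2.0 * gen_rec - base_generation
    ne_base = tl.ne_at(base_generation)
    ne_rec = tl.ne_at(gen_rec)
    ne_pre = tl.ne_at(gen_pre)
    slope_post = (ne_rec - ne_base) / (gen_rec - base_generation)
    slope_pre = (ne_pre - ne_rec) / (gen_pre - gen_rec)
    return NeSlopes(
        gen_at_recognition=gen_rec,
        ne_at_recognition=ne_rec,
        slope_post=slope_post,
        slope_pre=slope_pre,
        slope_difference=slope_pre - slope_post,
    )


# ---------------------------------------------------------------------------
# breed profiles
# ---------------------------------------------------------------------------

@dataclass
class BreedProfile:
    breed: str
    metrics: dict = field(default_factory=dict)
    absent: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def get(self, name: str) -> float | None:
        return self.metrics.get(name)

    def to_json(self, path=None) -> str:
        payload = {
            "breed": self.breed,
            "metrics": self.metrics,
            "absent_metrics": sorted(self.absent),
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2, sort_keys=True, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


PEDIGREE_METRICS = [
    "g_e", "F_full", "F_10", "F_5", "Ne_ped",
    "EDR_e", "EDR_a", "EDR_g", "bottleneck_ratio",
]
GENOMIC_METRICS = [
    "F_genotype", "RoH", "LnH", "shared_RoH", "shared_LnH",
    "decay_a", "decay_k", "cohort_1pct", "cohort_1nt",
]


def build_breed_profile(
    breed: str,
    ped: pm.PedigreeTable | None = None,
    genotypes: GenotypeMatrix | None = None,
    window: tuple[int, int] | None = None,
    roh_params: RoHParams | None = None,
    cohort_size: int = 10,
    n_orders: int = 10,
    gene_drop_reps: int = 1000,
    seed: int = 0,
) -> BreedProfile:
    """Run the configured subset of the pipeline and assemble a profile.

    Pedigree metrics require ``ped`` (and a birth-year window); genomic
    metrics require ``genotypes``. When both inputs are present the
    genotype sample ids must be pedigree members; conflicts raise with
    the offending ids listed. Absent families of metrics are recorded in
    ``profile.absent``.
    """
    roh_params = roh_params or RoHParams()
    prof = BreedProfile(breed=str(breed))
    prof.provenance = {
        "seed": seed,
        "cohort_size": cohort_size,
        "n_orders": n_orders,
        "gene_drop_reps": gene_drop_reps,
        "roh_mode": roh_params.mode,
        "window": list(window) if window else None,
    }
    if ped is not None and genotypes is not None:
        missing = [s for s in genotypes.samples if s not in set(ped.ids)]
        if missing:
            raise ValueError(
                f"genotype sample ids not present in the pedigree: {missing}"
            )
    if ped is not None:
        years = ped.df["birth_year"]
        win = window or (int(years.min()), int(years.max()))
        refped = pm.build_reference_pedigree(ped, win)
        prof.metrics["g_e"] = pm.completeness(refped).g_e
        series = {}
        for depth, name in (("full", "F_full"), (10, "F_10"), (5, "F_5")):
            s = pm.inbreeding(refped, depth=depth)
            series[name] = s
            prof.metrics[name] = float(
                np.mean([s.f[i] for i in refped.reference_ids])
            )
        ne = pm.ne_from_reference(series["F_full"])
        prof.metrics["Ne_ped"] = ne.ne if ne.defined else None
        if not ne.defined:
            prof.absent.append("Ne_ped")
        contrib = pm.edr_ancestors(refped)
        genomes = pm.edr_genomes(refped, reps=gene_drop_reps, seed=seed)
        prof.metrics["EDR_e"] = contrib.edr_e
        prof.metrics["EDR_a"] = contrib.edr_a
        prof.metrics["EDR_g"] = genomes.edr_g
        prof.metrics["bottleneck_ratio"] = pm.bottleneck_ratio(contrib)
    else:
        prof.absent.extend(PEDIGREE_METRICS)
    if genotypes is not None:
        rng = np.random.default_rng(seed)
        fser = genotype_inbreeding(genotypes)
        prof.metrics["F_genotype"] = float(fser.mean())
        per_ind = [call_roh(genotypes, s, roh_params) for s in genotypes.samples]
        prof.metrics["RoH"] = float(np.mean([p.roh for p in per_ind]))
        prof.metrics["LnH"] = float(np.mean([p.lnh for p in per_ind]))
        n = min(cohort_size, len(genotypes.samples))
        cohort = [
            genotypes.samples[k]
            for k in rng.choice(len(genotypes.samples), size=n, replace=False)
        ]
        if n >= 2:
            curve = incremental_shared_curve(
                genotypes, cohort, roh_params,
                order_seed=int(rng.integers(2**31 - 1)),
            )
            final = curve.iloc[-1]
            prof.metrics["shared_RoH"] = float(final["roh"])
            prof.metrics["shared_LnH"] = float(final["lnh"])
            if n >= 3:
                ens = decay_over_orders(
                    genotypes, cohort, roh_params,
                    n_orders=n_orders,
                    seed=int(rng.integers(2**31 - 1)),
                )
                summ = ens.summary()
                good = [f for f in ens.fits if f is not None]
                if good:
                    prof.metrics["decay_k"] = summ["k_mean"]
                    prof.metrics["decay_a"] = float(
                        np.mean([f.a_hat for f in good])
                    )
                    prof.metrics["cohort_1pct"] = float(
                        np.mean([f.t_1pct.cohort_size for f in good
                                 if f.t_1pct is not None])
                    )
                    prof.metrics["cohort_1nt"] = float(
                        np.mean([f.t_1nt.cohort_size for f in good
                                 if f.t_1nt is not None])
                    )
                else:
                    prof.absent.extend(
                        ["decay_k", "decay_a", "cohort_1pct", "cohort_1nt"]
                    )
    else:
        prof.absent.extend(GENOMIC_METRICS)
    return prof


def correlate_profiles(
    profiles: Sequence[BreedProfile],
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Pearson correlation table across breeds for requested metric pairs.

    Each row reports one metric pair with pairwise-complete n; pairs with
    fewer than 3 complete profiles, or zero variance, are kept in the
    table with the reason in the ``note`` column. Unknown metric names
    raise with the valid names listed.
    """
    valid = sorted({m for p in profiles for m in p.metrics})
    rows = []
    for mx, my in pairs:
        for m in (mx, my):
            if m not in valid:
                raise ValueError(
                    f"unknown metric {m!r}; valid metrics: {valid}"
                )
        x = np.asarray(
            [p.metrics.get(mx, np.nan) if p.metrics.get(mx) is not None
             else np.nan for p in profiles], dtype=float
        )
        y = np.asarray(
            [p.metrics.get(my, np.nan) if p.metrics.get(my) is not None
             else np.nan for p in profiles], dtype=float
        )
        n_complete = int((~(np.isnan(x) | np.isnan(y))).sum())
        if n_complete < 3:
            rows.append((mx, my, np.nan, np.nan, np.nan, n_complete,
                         "skipped: fewer than 3 complete pairs"))
            continue
        res = pearson_correlation(x, y)
        if not res.defined:
            rows.append((mx, my, np.nan, np.nan, np.nan, res.n,
                         f"skipped: {res.reason}"))
        else:
            rows.append((mx, my, res.r, res.t_statistic, res.p_value,
                         res.n, ""))
    out = pd.DataFrame(
        rows, columns=["x", "y", "r", "t", "p", "n", "note"]
    )
    m_tests = int((out["note"] == "").sum())
    out["p_bonferroni"] = np.minimum(out["p"] * max(m_tests, 1), 1.0)
    return out
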